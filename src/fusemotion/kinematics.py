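"""Rigid-body domain kinematics between conformational states.

The central readout is the motion of a mobile domain (e.g. D3) between the
prefusion and postfusion states of a class II fusogen, expressed in the
reference frame of a fixed domain (e.g. D1): the displacement of the mobile
domain's center of mass in Å and the axis–angle decomposition of its
rotation in degrees.  Superposition is least-squares over paired Cα atoms
with reflections forbidden (Kabsch); the angle is recovered from the trace
of the rotation matrix, the axis from its rotation vector.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, EmptyStructureError
from .structures import (
    DomainDefinition,
    ResidueCorrespondence,
    Structure,
    select_domain,
)

_ORTHO_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t in Å."""

    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(R) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation determinant differs from +1 (reflection?)")
        if np.max(np.abs(R.T @ R - np.eye(3))) > _ORTHO_TOL:
            raise ValueError("rotation matrix is not orthogonal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other (apply ``other`` first)."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(
            rotation=self.rotation.T, translation=-self.rotation.T @ self.translation
        )

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclasses.dataclass(frozen=True)
class DomainMotion:
    """Axis–angle + center-of-mass readout of one domain's motion."""

    com_pre: np.ndarray  # Å
    com_post: np.ndarray  # Å
    com_displacement: float  # Å
    rotation_angle: float  # degrees in [0, 180]
    rotation_axis: np.ndarray  # unit vector
    axis_anchor: np.ndarray  # Å, placed at com_post
    transform: RigidTransform
    rmsd: float  # Å, residual of the mobile-domain fit

    def __post_init__(self) -> None:
        if not 0.0 <= self.rotation_angle <= 180.0 + 1e-9:
            raise ValueError(f"rotation angle {self.rotation_angle} outside [0, 180]")
        disp = float(np.linalg.norm(np.asarray(self.com_post) - np.asarray(self.com_pre)))
        if abs(disp - self.com_displacement) > 1e-6 * max(1.0, disp):
            raise ValueError("com_displacement inconsistent with com_pre/com_post")

    def as_dict(self) -> dict:
        return {
            "com_pre": list(map(float, self.com_pre)),
            "com_post": list(map(float, self.com_post)),
            "com_displacement_A": float(self.com_displacement),
            "rotation_angle_deg": float(self.rotation_angle),
            "rotation_axis": list(map(float, self.rotation_axis)),
            "axis_anchor": list(map(float, self.axis_anchor)),
            "fit_rmsd_A": float(self.rmsd),
        }


def _check_nondegenerate(x: np.ndarray) -> None:
    if len(x) < 3:
        raise DegenerateGeometryError(f"need ≥3 paired atoms, got {len(x)}")
    centered = x - x.mean(axis=0)
    # rank < 2 ⇔ all points collinear
    if np.linalg.matrix_rank(centered, tol=1e-8 * max(1.0, np.abs(centered).max())) < 2:
        raise DegenerateGeometryError("paired atoms are collinear")


def fit_rigid_transform(
    from_coords: np.ndarray, to_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid transform carrying ``from_coords`` onto
    ``to_coords`` and the residual RMSD (Å)."""
    x = np.asarray(from_coords, dtype=float)
    y = np.asarray(to_coords, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have equal shapes")
    _check_nondegenerate(x)
    cx, cy = x.mean(axis=0), y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - cy, x - cx)  # Kabsch, proper rotation
    R = rot.as_matrix()
    t = cy - R @ cx
    tf = RigidTransform(rotation=R, translation=t)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(x) - y) ** 2, axis=1))))
    return tf, rmsd


def superpose(
    mobile: Structure,
    reference: Structure,
    corr: ResidueCorrespondence,
) -> tuple[RigidTransform, float]:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    The correspondence is read as (reference residue, mobile residue) pairs
    when ``corr`` was built as ``build_correspondence(reference, mobile)``;
    for self-correspondences the order is immaterial.  Returns the transform
    to apply to ``mobile`` coordinates and the Cα RMSD after fitting.
    """
    ref_xyz, mob_xyz = corr.paired_ca_coords(reference, mobile)
    return fit_rigid_transform(mob_xyz, ref_xyz)


def transform_structure(s: Structure, tf: RigidTransform) -> Structure:
    """Return a copy of ``s`` with ``tf`` applied to every atom."""
    atoms = [
        dataclasses.replace(a, position=tf.apply(a.position[None, :])[0])
        for a in s.atoms
    ]
    return Structure(atoms=atoms, label=s.label)


def axis_angle(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, in [0, 180]) and unit axis of a rotation matrix.

    The axis sign is fixed so its largest-magnitude component is positive
    (an unsigned-angle report cannot distinguish ±axis); near 180° the
    rotation-vector route degrades gracefully and the same tie-break applies.
    """
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    rotvec = Rotation.from_matrix(R).as_rotvec()
    norm = np.linalg.norm(rotvec)
    if norm < 1e-12:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = rotvec / norm
    i = int(np.argmax(np.abs(axis)))
    if axis[i] < 0:
        axis = -axis
    return angle, axis


def domain_motion(
    pre: Structure,
    post: Structure,
    ref_domain: DomainDefinition,
    mobile_domain: DomainDefinition,
    corr_ref: ResidueCorrespondence,
    corr_mobile: ResidueCorrespondence,
) -> DomainMotion:
    """Decompose the motion of ``mobile_domain`` between two states.

    Step 1: the post-state structure is superposed onto the pre state over
    the reference-domain Cα pairs, so both states share the reference
    domain's frame.  Step 2: the least-squares rigid transform carrying the
    pre-state mobile-domain Cα set onto the (reference-aligned) post-state
    set is decomposed into a center-of-mass displacement and an axis–angle
    rotation, the axis anchored at the post-state center of mass.

    Correspondences are (pre residue, post residue) pairs, restricted here
    to the respective domains.
    """
    pre_ref = select_domain(pre, ref_domain, "CA-only")
    post_ref = select_domain(post, ref_domain, "CA-only")
    ref_pairs = tuple(
        (ka, kb)
        for ka, kb in corr_ref.pairs
        if ref_domain.contains(ka[0], ka[1]) and ref_domain.contains(kb[0], kb[1])
    )
    if not ref_pairs:
        raise DegenerateGeometryError("no reference-domain pairs in correspondence")
    pre_xyz, post_xyz = ResidueCorrespondence(
        pairs=ref_pairs, mode=corr_ref.mode
    ).paired_ca_coords(pre_ref, post_ref)
    align_tf, _ = fit_rigid_transform(post_xyz, pre_xyz)

    mob_pairs = tuple(
        (ka, kb)
        for ka, kb in corr_mobile.pairs
        if mobile_domain.contains(ka[0], ka[1]) and mobile_domain.contains(kb[0], kb[1])
    )
    if not mob_pairs:
        raise DegenerateGeometryError("no mobile-domain pairs in correspondence")
    pre_mob = select_domain(pre, mobile_domain, "CA-only")
    post_mob = select_domain(post, mobile_domain, "CA-only")
    pre_m_xyz, post_m_xyz = ResidueCorrespondence(
        pairs=mob_pairs, mode=corr_mobile.mode
    ).paired_ca_coords(pre_mob, post_mob)
    post_m_xyz = align_tf.apply(post_m_xyz)

    tf, rmsd = fit_rigid_transform(pre_m_xyz, post_m_xyz)
    angle, axis = axis_angle(tf.rotation)
    com_pre = pre_m_xyz.mean(axis=0)
    com_post = post_m_xyz.mean(axis=0)
    disp = float(np.linalg.norm(com_post - com_pre))
    return DomainMotion(
        com_pre=com_pre,
        com_post=com_post,
        com_displacement=disp,
        rotation_angle=angle,
        rotation_axis=axis,
        axis_anchor=com_post,
        transform=tf,
        rmsd=rmsd,
    )


def max_extent(
    s: Structure, atom_filter: Literal["CA-only", "all-atoms"] = "CA-only"
) -> float:
    """Maximum pairwise atom–atom distance (Å) over the filtered atom set.

    Defaults to Cα-only, which also excludes glycans and other heteroatoms.
    Uses the convex hull when the point count warrants it; the maximum
    pairwise distance is attained between hull vertices.
    """
    if atom_filter == "CA-only":
        pts = s.ca_coords()
    elif atom_filter == "all-atoms":
        pts = s.coords()
    else:
        raise ValueError(f"unknown atom_filter {atom_filter!r}")
    if len(pts) < 2:
        raise EmptyStructureError("need ≥2 atoms to measure an extent")
    if len(pts) > 64:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (flat/collinear) clouds: brute force below
    return float(pdist(pts).max())


def rmsd_between(
    a: Structure,
    b: Structure,
    corr: ResidueCorrespondence,
    superpose_first: bool = True,
) -> float:
    """Cα RMSD (Å) over the corresponding residues, optionally after
    least-squares superposition of ``b`` onto ``a``."""
    xa, xb = corr.paired_ca_coords(a, b)
    if superpose_first:
        _, rmsd = fit_rigid_transform(xb, xa)
        return rmsd
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))
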