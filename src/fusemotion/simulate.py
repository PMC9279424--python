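"""Synthetic-data generators with embedded ground truth.

Every analysis stage in this package has a forward model; this module runs
those models forward from known parameters so each analyzer can be tested
as an inverse problem.  Defaults reproduce the study conditions of the
fusogen system the package targets: a four-domain rod of ~155 Å extent, a
D3-like domain reorientation of 168° with a 76 Å center-of-mass shift, a
trimer glycoprotein + detergent-micelle conjugate (186,300 + 75,770 Da),
and two-state melt curves on a 20–95 °C ramp.

All generators are pure functions of their arguments: the same seed gives
bitwise-identical output, and no global random state is touched.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .em_projection import DensityGrid, Orientation, ProjectionImage, project
from .errors import ParameterError
from .kinematics import RigidTransform, fit_rigid_transform
from .mals import MalsSlice, OpticalComponent
from .structures import AtomRecord, DomainDefinition, Structure
from .thermal import MeltCurve

SCENARIOS = ("rod_structure", "domain_motion", "class_average", "chromatogram", "melt_curve")


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Seed + scenario + parameter map fully determining one fixture."""

    seed: int
    scenario: str
    parameters: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")


def gen_rod_structure(
    n_domains: int = 4,
    domain_length: float = 38.75,
    residues_per_domain: int = 60,
    seed: int = 0,
    chain_id: str = "A",
    start_residue: int = 1,
    helix_radius: float = 4.0,
) -> tuple[Structure, list[DomainDefinition]]:
    """Collinear multi-domain Cα rod with per-domain definitions.

    Domains are consecutive stretches of a Cα helix wound along the z axis,
    so the total extent is n_domains × domain_length (the default 4 × 38.75 Å
    gives the ~155 Å rod of an extended prefusion ectodomain).  Residue
    numbering is consecutive from ``start_residue``.
    """
    if n_domains < 2 or residues_per_domain < 4 or domain_length <= 0:
        raise ParameterError("degenerate rod parameters")
    n_res = n_domains * residues_per_domain
    total = n_domains * domain_length
    z = np.linspace(0.0, total, n_res)
    turn = 2.0 * np.pi / 3.6  # residues per helical turn
    ang = turn * np.arange(n_res)
    x = helix_radius * np.cos(ang)
    y = helix_radius * np.sin(ang)
    _ = np.random.default_rng(seed)  # reserved: rod geometry is deterministic

    atoms = [
        AtomRecord(
            chain_id=chain_id,
            residue_number=start_residue + i,
            insertion_code="",
            residue_name="ALA",
            atom_name="CA",
            element="C",
            occupancy=1.0,
            position=np.array([x[i], y[i], z[i]]),
        )
        for i in range(n_res)
    ]
    defs = [
        DomainDefinition(
            name=f"D{d + 1}",
            intervals=(
                (
                    chain_id,
                    start_residue + d * residues_per_domain,
                    start_residue + (d + 1) * residues_per_domain - 1,
                ),
            ),
        )
        for d in range(n_domains)
    ]
    return Structure(atoms=atoms, label=f"rod{n_domains}x{domain_length:g}"), defs


def apply_motion(
    s: Structure,
    d: DomainDefinition,
    angle: float,
    axis: np.ndarray,
    com_displacement: float,
    noise: float = 0.0,
    seed: int = 0,
    displacement_direction: np.ndarray | None = None,
) -> Structure:
    """Re-place one domain by a known rotation about its centroid plus a
    centroid displacement; optionally perturb every atom with Gaussian noise.

    The inverse pair of the domain-motion decomposition: analysing the
    returned structure against ``s`` must recover ``angle`` and
    ``com_displacement`` exactly in the noise-free case.
    """
    if not 0.0 <= angle <= 180.0:
        raise ParameterError("angle must lie in [0, 180] degrees")
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ParameterError("rotation axis must be a unit vector")
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
    in_domain = [d.contains(a.chain_id, a.residue_number) for a in s.atoms]
    dom_xyz = np.array([a.position for a, m in zip(s.atoms, in_domain) if m])
    if len(dom_xyz) == 0:
        raise ParameterError(f"domain {d.name!r} selects no atoms")
    com = dom_xyz.mean(axis=0)
    if displacement_direction is None:
        # deterministic default: displace perpendicular to the rotation axis
        trial = np.array([1.0, 0.0, 0.0])
        if abs(trial @ axis) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        direction = trial - (trial @ axis) * axis
        direction /= np.linalg.norm(direction)
    else:
        direction = np.asarray(displacement_direction, dtype=float)
        direction = direction / np.linalg.norm(direction)

    rng = np.random.default_rng(seed)
    new_atoms = []
    for a, m in zip(s.atoms, in_domain):
        pos = a.position
        if m:
            pos = R @ (pos - com) + com + com_displacement * direction
        if noise > 0:
            pos = pos + rng.normal(0.0, noise, size=3)
        new_atoms.append(dataclasses.replace(a, position=pos))
    return Structure(atoms=new_atoms, label=f"{s.label}+motion")


def synthetic_state_pair(
    angle: float = 168.0,
    com_displacement: float = 76.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[Structure, Structure, dict[str, DomainDefinition], dict[str, float]]:
    """Synthetic prefusion/postfusion analogue with known D3-like motion.

    A stand-in for a deposited pre/postfusion structure pair: a four-domain
    ~155 Å rod whose last domain is re-placed by a constructed transform
    (defaults: the 168° rotation and 76 Å center-of-mass displacement
    characteristic of a class II fusogen D3 foldback).  Returns
    (pre, post, domains-by-name, truth).
    """
    pre, defs = gen_rod_structure(seed=seed)
    by_name = {d.name: d for d in defs}
    axis = np.array([0.0, 1.0, 0.0])
    post = apply_motion(
        pre, by_name["D4"], angle, axis, com_displacement, noise=noise, seed=seed + 1
    )
    truth = {"angle": angle, "com_displacement": com_displacement, "noise": noise}
    return pre, post, {"ref": by_name["D1"], "mobile": by_name["D4"]}, truth


def synthetic_predicted_model(
    s: Structure, target_rmsd: float, seed: int = 0
) -> Structure:
    """Synthetic stand-in for an independently predicted model of ``s``.

    Perturbs every atom with a smooth random displacement field, removes the
    best-fit rigid component, and rescales so the Cα RMSD after optimal
    superposition equals ``target_rmsd`` exactly.
    """
    rng = np.random.default_rng(seed)
    xyz = s.coords()
    n = len(xyz)
    # smooth field: random low-order Fourier modes along the chain index
    t = np.linspace(0.0, 1.0, n)[:, None]
    disp = np.zeros_like(xyz)
    for k in range(1, 6):
        amp = rng.normal(0.0, 1.0 / k, size=(1, 3))
        phase = rng.uniform(0, 2 * np.pi)
        disp += amp * np.sin(2 * np.pi * k * t + phase)
    perturbed = xyz + disp
    tf, rmsd = fit_rigid_transform(perturbed, xyz)
    residual = tf.apply(perturbed) - xyz
    if rmsd <= 0:
        raise ParameterError("degenerate perturbation field")
    final = xyz + residual * (target_rmsd / rmsd)
    atoms = [
        dataclasses.replace(a, position=p) for a, p in zip(s.atoms, final)
    ]
    return Structure(atoms=atoms, label=f"{s.label}-predicted")


def gen_class_average(
    g: DensityGrid,
    orientation: Orientation,
    snr: float = 3.0,
    seed: int = 0,
) -> ProjectionImage:
    """Noisy projection of a known density at a known orientation.

    SNR is the ratio of the noise-free pixel standard deviation to the
    additive Gaussian noise standard deviation; ``snr=np.inf`` gives the
    clean projection.
    """
    if not snr > 0:
        raise ParameterError("snr must be positive")
    img = project(g, orientation)
    if np.isinf(snr):
        return img
    rng = np.random.default_rng(seed)
    sigma = float(img.pixels.std()) / snr
    noisy = img.pixels + rng.normal(0.0, sigma, size=img.pixels.shape)
    return ProjectionImage(noisy, img.pixel_size, orientation, label="class-average")


def gen_chromatogram(
    m_conjugate: float = 186_300.0,
    m_modifier: float = 75_770.0,
    conjugate: OpticalComponent = OpticalComponent("glycoprotein", dndc=0.1801, epsilon=1.237),
    modifier: OpticalComponent = OpticalComponent("beta-DDM", dndc=0.133, epsilon=0.0),
    c_peak_total: float = 0.5,
    peak_volume: float = 12.0,
    peak_sigma: float = 0.35,
    volume_range: tuple[float, float] = (10.0, 14.0),
    n_slices: int = 101,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[MalsSlice], dict[str, float]]:
    """Forward-model a Gaussian elution peak of a two-component conjugate.

    Each eluting particle carries the conjugate and modifier in fixed mass
    ratio, so the two concentrations co-elute in proportion to their masses
    and each slice's total molar mass is m_conjugate + m_modifier.  The
    defaults emulate a detergent-solubilized glycoprotein trimer (3 × 62,100
    Da glycoprotein + 75,770 Da micelle).  ``noise`` is the fractional
    Gaussian noise level applied per channel relative to its peak signal.
    """
    if m_conjugate <= 0 or m_modifier < 0 or c_peak_total <= 0:
        raise ParameterError("masses and concentrations must be positive")
    m_total = m_conjugate + m_modifier
    f_conj = m_conjugate / m_total
    rng = np.random.default_rng(seed)
    volumes = np.linspace(*volume_range, n_slices)
    profile = np.exp(-0.5 * ((volumes - peak_volume) / peak_sigma) ** 2)
    c_conj = c_peak_total * f_conj * profile
    c_mod = c_peak_total * (1.0 - f_conj) * profile
    c_total = c_conj + c_mod
    uv = conjugate.epsilon * c_conj
    ri = conjugate.dndc * c_conj + modifier.dndc * c_mod
    with np.errstate(invalid="ignore", divide="ignore"):
        dndc_w = np.where(c_total > 0, ri / np.maximum(c_total, 1e-300), 0.0)
    ls = m_total * dndc_w**2 * c_total
    if noise > 0:
        uv = uv + rng.normal(0.0, noise * uv.max(), n_slices)
        ri = ri + rng.normal(0.0, noise * ri.max(), n_slices)
        ls = ls + rng.normal(0.0, noise * ls.max(), n_slices)
    slices = [
        MalsSlice(
            volume=float(v),
            ls_excess_rayleigh=float(max(l, 0.0)),
            uv_absorbance=float(max(u, 0.0)),
            ri_differential=float(max(r, 0.0)),
        )
        for v, l, u, r in zip(volumes, ls, uv, ri)
    ]
    truth = {
        "m_conjugate": m_conjugate,
        "m_modifier": m_modifier,
        "m_total": m_total,
        "f_conjugate": f_conj,
        "c_peak_total": c_peak_total,
        "peak_volume": peak_volume,
        "peak_sigma": peak_sigma,
    }
    return slices, truth


def gen_melt_curve(
    tm: float = 60.0,
    t_range: tuple[float, float] = (20.0, 95.0),
    step: float = 0.5,
    transition_width: float = 1.5,
    folded_baseline: tuple[float, float] = (0.85, 0.0003),
    unfolded_baseline: tuple[float, float] = (1.02, 0.0008),
    noise: float = 0.0,
    seed: int = 0,
    label: str = "synthetic",
) -> tuple[MeltCurve, dict[str, float]]:
    """Two-state melt curve with linear baselines and known Tm.

    FIR follows fir(T) = (1−φ)·(a_f + b_f·T) + φ·(a_u + b_u·T) with the
    unfolded fraction φ a logistic of width ``transition_width`` centred at
    ``tm`` — a van 't Hoff two-state transition.  ``noise`` is the fractional
    Gaussian noise level on the FIR signal (1% ≙ 0.01); the two fluorescence
    channels are derived consistently from the noisy ratio.  Defaults follow
    a nanoDSF ramp from 20 to 95 °C at 0.5 °C resolution.
    """
    lo, hi = t_range
    if not lo < tm < hi:
        raise ParameterError("tm must lie inside the temperature range")
    T = np.arange(lo, hi + step / 2, step)
    phi = 1.0 / (1.0 + np.exp(-(T - tm) / transition_width))
    folded = folded_baseline[0] + folded_baseline[1] * T
    unfolded = unfolded_baseline[0] + unfolded_baseline[1] * T
    fir = (1.0 - phi) * folded + phi * unfolded
    rng = np.random.default_rng(seed)
    if noise > 0:
        fir = fir * (1.0 + rng.normal(0.0, noise, T.shape))
    f330 = 1000.0 * (1.0 - 0.002 * (T - lo))
    f350 = fir * f330
    curve = MeltCurve(
        temperature=T, fir=f350 / f330, f350=f350, f330=f330, label=label
    )
    truth = {"tm": tm, "transition_width": transition_width, "noise": noise}
    return curve, truth


def generate(spec: GeneratorSpec):
    """Dispatch a :class:`GeneratorSpec` to its generator."""
    p = dict(spec.parameters)
    if spec.scenario == "rod_structure":
        return gen_rod_structure(seed=spec.seed, **p)
    if spec.scenario == "domain_motion":
        return synthetic_state_pair(seed=spec.seed, **p)
    if spec.scenario == "chromatogram":
        return gen_chromatogram(seed=spec.seed, **p)
    if spec.scenario == "melt_curve":
        return gen_melt_curve(seed=spec.seed, **p)
    if spec.scenario == "class_average":
        return gen_class_average(seed=spec.seed, **p)
    raise ParameterError(f"unknown scenario {spec.scenario!r}")
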