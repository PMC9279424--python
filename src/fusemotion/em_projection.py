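"""Model-to-density synthesis and 2D projection matching for negative-stain EM.

An atomic model is rendered as a sum of per-atom isotropic Gaussians
(integrated weight = atomic number) and low-pass filtered in Fourier space
with a cosine-edged mask, emulating a density map filtered to the stain
resolution (typically 25 Å).  Projection templates are generated on a
quasi-uniform hemisphere grid (projections are Friedel-symmetric, so the
other hemisphere is redundant) and class-average images are scored against
the bank by Pearson normalized cross-correlation under a circular mask,
searching in-plane rotation and integer-pixel translation.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation
from skimage import measure

from .errors import (
    EmptyStructureError,
    ParameterError,
    SamplingError,
    UndefinedCorrelationError,
)
from .structures import Structure

Orientation = tuple[float, float, float]  # (theta, phi, psi) in degrees


@dataclasses.dataclass
class DensityGrid:
    """Cubic voxel grid of densities with physical spacing in Å.

    ``voxels`` is indexed (z, y, x); ``origin`` is the xyz position of voxel
    (0, 0, 0); ``resolution`` records the low-pass target of the synthesis.
    """

    voxels: np.ndarray
    voxel_size: float  # Å / voxel
    origin: np.ndarray  # (3,) Å, xyz
    resolution: float  # Å

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("non-finite densities")

    def total_density(self) -> float:
        """Integral of the density over the grid (weight units)."""
        return float(self.voxels.sum() * self.voxel_size**3)


@dataclasses.dataclass
class ProjectionImage:
    """2D projection with physical pixel size and generating orientation."""

    pixels: np.ndarray
    pixel_size: float  # Å / pixel
    orientation: Orientation  # (theta, phi, psi), degrees
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("non-finite pixels")


@dataclasses.dataclass
class MatchResult:
    """Best-matching template orientation and the full correlation table."""

    best_orientation: Orientation
    best_cc: float
    best_shift: tuple[int, int]
    cc_table: dict[Orientation, float]

    def __post_init__(self) -> None:
        if abs(self.best_cc) > 1.0 + 1e-9:
            raise ValueError("|cc| must be ≤ 1")
        if self.cc_table and abs(max(self.cc_table.values()) - self.best_cc) > 1e-9:
            raise ValueError("best_cc must equal the table maximum")


def _gaussian_sigma(resolution: float) -> float:
    return resolution / (math.pi * math.sqrt(2.0))


def synthesize_density(
    s: Structure, voxel_size: float, resolution: float
) -> DensityGrid:
    """Render a structure as a Gaussian-atom density low-passed to ``resolution``.

    Each non-hydrogen atom contributes an isotropic Gaussian of integrated
    weight equal to its atomic number and σ = resolution/(π√2); the grid is
    then filtered with a Fourier cosine-edge mask fully attenuating beyond
    1/resolution.  The grid is cubic and padded so no atom sits within 2σ of
    an edge.
    """
    if voxel_size > resolution / 3.0:
        raise SamplingError(
            f"voxel size {voxel_size} Å too coarse for resolution {resolution} Å "
            f"(need ≤ {resolution / 3.0:.3g} Å)"
        )
    coords = s.coords()
    elements = s.element_symbols()
    keep = [i for i, e in enumerate(elements) if e not in ("H", "D")]
    if not keep:
        raise EmptyStructureError("no non-hydrogen atoms to render")
    coords = coords[keep]
    weights = np.array(
        [max(gemmi.Element(elements[i]).atomic_number, 1) for i in keep], dtype=float
    )

    sigma = _gaussian_sigma(resolution)
    margin = max(2.0 * sigma, resolution) + 2.0 * voxel_size
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    n = int(np.ceil((hi - lo).max() / voxel_size)) + 1
    n += n % 2  # even size keeps the Fourier grid simple
    center = (lo + hi) / 2.0
    origin = center - (n - 1) * voxel_size / 2.0

    vox = np.zeros((n, n, n), dtype=float)
    half = int(np.ceil(4.0 * sigma / voxel_size))
    offsets = np.arange(-half, half + 1)
    norm = 1.0 / ((2.0 * math.pi) ** 1.5 * sigma**3)
    for xyz, w in zip(coords, weights):
        idx = (xyz - origin) / voxel_size  # fractional (x, y, z) voxel index
        base = np.round(idx).astype(int)
        gx, gy, gz = (
            np.exp(-0.5 * (((base[d] + offsets) - idx[d]) * voxel_size / sigma) ** 2)
            for d in range(3)
        )
        sl = tuple(
            slice(base[d] - half, base[d] + half + 1) for d in (2, 1, 0)
        )  # (z, y, x)
        vox[sl] += (w * norm) * (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )

    vox = lowpass_filter(vox, voxel_size, resolution)
    return DensityGrid(voxels=vox, voxel_size=voxel_size, origin=origin, resolution=resolution)


def lowpass_filter(
    voxels: np.ndarray, voxel_size: float, resolution: float, edge_frac: float = 0.25
) -> np.ndarray:
    """Cosine-edged Fourier low-pass with full attenuation beyond 1/resolution.

    The mask is 1 below (1 − edge_frac)/resolution, falls as a half-cosine
    across the edge, and is exactly 0 beyond 1/resolution.
    """
    freqs = [np.fft.fftfreq(n, d=voxel_size) for n in voxels.shape]
    grids = np.meshgrid(*freqs, indexing="ij")
    f = np.sqrt(sum(g**2 for g in grids))
    fc = 1.0 / resolution
    f1 = (1.0 - edge_frac) * fc
    mask = np.zeros_like(f)
    mask[f <= f1] = 1.0
    edge = (f > f1) & (f < fc)
    mask[edge] = 0.5 * (1.0 + np.cos(math.pi * (f[edge] - f1) / (fc - f1)))
    return np.real(np.fft.ifftn(np.fft.fftn(voxels) * mask))


def _orientation_matrix(orientation: Orientation) -> np.ndarray:
    """xyz rotation matrix whose action on ẑ is the viewing direction."""
    theta, phi, psi = orientation
    return Rotation.from_euler("ZYZ", [phi, theta, psi], degrees=True).as_matrix()


def viewing_direction(orientation: Orientation) -> np.ndarray:
    """Unit viewing axis (xyz) of a projection orientation."""
    return _orientation_matrix(orientation) @ np.array([0.0, 0.0, 1.0])


def orientation_distance(a: Orientation, b: Orientation) -> float:
    """Angle (degrees) between viewing axes, under Friedel ±axis equivalence."""
    cosang = abs(float(viewing_direction(a) @ viewing_direction(b)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def project(g: DensityGrid, orientation: Orientation) -> ProjectionImage:
    """Rotate the density to ``orientation`` and integrate along the view axis.

    Pixel values are sums of (interpolated) voxel values, so the pixel sum
    equals the voxel sum up to interpolation loss at the padded border.
    """
    M = _orientation_matrix(orientation)
    # voxels are indexed (z, y, x): conjugate the xyz matrix by axis reversal
    J = np.eye(3)[::-1]
    M_idx = J @ M @ J
    c = (np.array(g.voxels.shape, dtype=float) - 1.0) / 2.0
    rotated = ndimage.affine_transform(
        g.voxels, M_idx, offset=c - M_idx @ c, order=3, mode="constant", cval=0.0
    )
    return ProjectionImage(
        pixels=rotated.sum(axis=0),
        pixel_size=g.voxel_size,
        orientation=orientation,
        label="projection",
    )


def hemisphere_orientations(angular_step: float) -> list[Orientation]:
    """Deterministic quasi-uniform hemisphere grid of (theta, phi, 0).

    Latitude rings at multiples of ``angular_step`` from the pole (theta=0)
    to the equator (theta=90); each ring carries ceil(360·sin(theta)/step)
    azimuthal samples so nearest-neighbor spacing stays ≤ the step.
    """
    if not 0.0 < angular_step <= 30.0:
        raise ParameterError("angular_step must be in (0, 30] degrees")
    orientations: list[Orientation] = []
    n_rings = int(math.ceil(90.0 / angular_step))
    for r in range(n_rings + 1):
        theta = min(r * angular_step, 90.0)
        if theta == 0.0:
            orientations.append((0.0, 0.0, 0.0))
            continue
        n_phi = max(1, int(math.ceil(360.0 * math.sin(math.radians(theta)) / angular_step)))
        for k in range(n_phi):
            orientations.append((theta, 360.0 * k / n_phi, 0.0))
    return orientations


def build_template_bank(
    g: DensityGrid, angular_step: float
) -> list[ProjectionImage]:
    """Project the density at every hemisphere-grid orientation."""
    return [project(g, o) for o in hemisphere_orientations(angular_step)]


def _circular_mask(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2


def _fit_to_shape(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Center-pad or center-crop a 2D array to the target shape."""
    out = np.zeros(shape, dtype=float)
    src = [slice(None)] * 2
    dst = [slice(None)] * 2
    for d in range(2):
        n_in, n_out = img.shape[d], shape[d]
        if n_in <= n_out:
            start = (n_out - n_in) // 2
            dst[d] = slice(start, start + n_in)
            src[d] = slice(0, n_in)
        else:
            start = (n_in - n_out) // 2
            src[d] = slice(start, start + n_out)
            dst[d] = slice(0, n_out)
    out[tuple(dst)] = img[tuple(src)]
    return out


def _pearson_under_mask(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((av * bv).sum() / denom, -1.0, 1.0))


def match_image(
    img: ProjectionImage,
    bank: Sequence[ProjectionImage],
    mask_radius: float | None = None,
    in_plane_step: float | None = None,
    max_shift: int | None = None,
) -> MatchResult:
    """Score an image against a template bank by masked Pearson NCC.

    For each template the in-plane rotation is searched at ``in_plane_step``
    (default: the bank's angular step inferred from its polar spacing) and
    the best integer-pixel translation is located by FFT cross-correlation;
    the reported score is the exact Pearson correlation under the circular
    mask at that translation.  ``mask_radius`` is in Å (default: 96% of the
    largest inscribed circle).
    """
    if not bank:
        raise ParameterError("empty template bank")
    t0 = bank[0]
    if abs(img.pixel_size - t0.pixel_size) > 1e-6 * t0.pixel_size:
        zoom = img.pixel_size / t0.pixel_size
        resampled = ndimage.zoom(img.pixels, zoom, order=1)
        img = ProjectionImage(resampled, t0.pixel_size, img.orientation, img.label)

    shape = t0.pixels.shape
    pixels = _fit_to_shape(img.pixels, shape)
    if mask_radius is None:
        radius_px = 0.48 * min(shape)
    else:
        radius_px = mask_radius / t0.pixel_size
    mask = _circular_mask(shape, radius_px)
    if float(pixels[mask].std()) == 0.0:
        raise UndefinedCorrelationError("image has zero variance under the mask")

    if in_plane_step is None:
        thetas = sorted({o.orientation[0] for o in bank})
        in_plane_step = thetas[1] - thetas[0] if len(thetas) > 1 else 15.0
    if max_shift is None:
        max_shift = min(shape) // 4

    img_m = np.where(mask, pixels - pixels[mask].mean(), 0.0)
    F_img = np.fft.rfft2(img_m)
    psis = np.arange(0.0, 360.0, in_plane_step)

    # admissible wrap-around shifts within ±max_shift
    sy = np.fft.fftfreq(shape[0], 1 / shape[0]).astype(int)
    sx = np.fft.fftfreq(shape[1], 1 / shape[1]).astype(int)
    shift_ok = (np.abs(sy)[:, None] <= max_shift) & (np.abs(sx)[None, :] <= max_shift)

    best = (-2.0, (0.0, 0.0, 0.0), (0, 0))
    cc_table: dict[Orientation, float] = {}
    for tmpl in bank:
        tmpl_px = _fit_to_shape(tmpl.pixels, shape)
        best_tmpl = -2.0
        for psi in psis:
            rot = (
                tmpl_px
                if psi == 0.0
                else ndimage.rotate(tmpl_px, psi, reshape=False, order=1)
            )
            rot_m = np.where(mask, rot - rot[mask].mean(), 0.0)
            corr = np.fft.irfft2(F_img * np.conj(np.fft.rfft2(rot_m)), s=shape)
            corr = np.where(shift_ok, corr, -np.inf)
            dy, dx = np.unravel_index(int(np.argmax(corr)), shape)
            shift = (sy[dy], sx[dx])
            cc = _pearson_under_mask(
                pixels, np.roll(rot, shift, axis=(0, 1)), mask
            )
            if cc > best_tmpl:
                best_tmpl = cc
            if cc > best[0]:
                theta, phi, _ = tmpl.orientation
                best = (cc, (theta, phi, float(psi)), shift)
        cc_table[tmpl.orientation] = best_tmpl
    return MatchResult(
        best_orientation=best[1],
        best_cc=best[0],
        best_shift=best[2],
        cc_table=cc_table,
    )


def particle_length(img: ProjectionImage, threshold_frac: float = 0.2) -> float:
    """Maximal caliper length (Å) of the largest above-threshold blob.

    The image is binarized at ``threshold_frac`` × its maximum, the largest
    connected component kept, and the maximum pairwise distance between
    member pixel centers returned in Å.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ParameterError("threshold_frac must be in (0, 1)")
    peak = img.pixels.max()
    if peak <= 0:
        raise ParameterError("no positive pixels to threshold")
    binary = img.pixels >= threshold_frac * peak
    if not binary.any():
        raise ParameterError("no pixels above threshold")
    labels = measure.label(binary, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    pts = np.argwhere(labels == largest).astype(float)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 256:
        from scipy.spatial import ConvexHull, QhullError

        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max() * img.pixel_size)


def write_mrc(g: DensityGrid, path: str | Path) -> None:
    """Write a density grid as an MRC/CCP4 map (mode 2)."""
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = gemmi.FloatGrid(np.ascontiguousarray(g.voxels, dtype=np.float32))
    # cell axes follow the grid dimensions in storage order
    ccp4.grid.set_unit_cell(
        gemmi.UnitCell(
            g.voxels.shape[0] * g.voxel_size,
            g.voxels.shape[1] * g.voxel_size,
            g.voxels.shape[2] * g.voxel_size,
            90,
            90,
            90,
        )
    )
    ccp4.update_ccp4_header(2, True)
    ccp4.write_ccp4_map(str(path))


def read_mrc(path: str | Path, resolution: float = 0.0) -> DensityGrid:
    """Read an MRC/CCP4 map into a :class:`DensityGrid`."""
    ccp4 = gemmi.read_ccp4_map(str(path))
    vox = np.array(ccp4.grid, copy=True, dtype=float)
    voxel_size = ccp4.grid.unit_cell.a / ccp4.grid.nu
    return DensityGrid(
        voxels=vox, voxel_size=voxel_size, origin=np.zeros(3), resolution=resolution
    )
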