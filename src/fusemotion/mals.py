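"""SEC-MALS protein-conjugate analysis.

Resolves, slice by slice across an elution peak, the concentrations and
molar masses of a two-component conjugate: an absorbing glycoprotein and a
non-absorbing modifier (glycan already folded into the glycoprotein's
optical constants, or a detergent micelle).  The UV trace determines the
conjugate concentration, the refractive-index (RI) residual the modifier
concentration, and the excess Rayleigh ratio the total molar mass through
the zero-angle light-scattering relation

    LS = k_LS · M_total · (dn/dc)_w² · c_total,

with the weight-averaged refractive-index increment
(dn/dc)_w = (dndc_conj·c_conj + dndc_mod·c_mod) / c_total.  Component
masses follow from the solved concentration weight fractions,
M_conj = M_total · c_conj/c_total.  The conjugate's own optical constants
come from weight-fraction mixing of its protein and glycan parts:

    (dn/dc)_glycoprot = (dn/dc)_prot·f_prot + (dn/dc)_glycan·f_glycan
    ε_glycoprot       = ε_prot·f_prot + ε_glycan·f_glycan.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InconsistentSignalsError, ParameterError

_CLAMP_TOL = 1e-6  # g/L; solved concentrations above -tol are clamped to 0


@dataclasses.dataclass(frozen=True)
class OpticalComponent:
    """Optical constants of one solute component.

    dndc: refractive-index increment, mL/g.
    epsilon: A280 mass extinction coefficient, mL·mg⁻¹·cm⁻¹ (0 for
    non-absorbing components such as glycan or β-DDM).
    """

    name: str
    dndc: float
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.dndc < 0 or self.epsilon < 0:
            raise ParameterError(f"{self.name}: negative optical constant")


@dataclasses.dataclass(frozen=True)
class WeightFractions:
    f_prot: float
    f_glycan: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_prot <= 1.0 and 0.0 <= self.f_glycan <= 1.0):
            raise ParameterError("weight fractions must lie in [0, 1]")
        if abs(self.f_prot + self.f_glycan - 1.0) > 1e-9:
            raise ParameterError("weight fractions must sum to 1")


@dataclasses.dataclass(frozen=True)
class MalsSlice:
    """One elution slice of detector readings.

    Signals are already baseline-subtracted; calibration constants convert
    them to physical units (all default to 1 for dimensionless test mode).
    """

    volume: float  # mL
    ls_excess_rayleigh: float
    uv_absorbance: float  # AU
    ri_differential: float
    k_ls: float = 1.0
    k_uv: float = 1.0  # path length factor
    k_ri: float = 1.0

    def __post_init__(self) -> None:
        if min(self.k_ls, self.k_uv, self.k_ri) <= 0:
            raise ParameterError("calibration constants must be positive")


@dataclasses.dataclass(frozen=True)
class SliceComposition:
    volume: float  # mL
    c_conjugate: float  # g/L
    c_modifier: float  # g/L
    dndc_weighted: float  # mL/g
    m_total: float  # Da
    m_conjugate: float  # Da
    m_modifier: float  # Da

    def __post_init__(self) -> None:
        if self.c_conjugate < 0 or self.c_modifier < 0:
            raise ParameterError("negative concentration")
        if self.m_total > 0 and abs(
            self.m_conjugate + self.m_modifier - self.m_total
        ) > 1e-6 * self.m_total:
            raise ParameterError("component masses do not sum to the total")


@dataclasses.dataclass(frozen=True)
class ConjugateMassResult:
    """Peak-averaged masses and weight fractions of the two components."""

    m_conjugate: float  # Da, weight-average over the peak
    m_modifier: float  # Da
    f_conjugate: float
    f_modifier: float
    n_slices: int


def mix_dndc(
    prot: OpticalComponent, glycan: OpticalComponent, f: WeightFractions
) -> float:
    """Weight-fraction mixing of refractive-index increments (mL/g)."""
    return prot.dndc * f.f_prot + glycan.dndc * f.f_glycan


def mix_extinction(
    prot: OpticalComponent, glycan: OpticalComponent, f: WeightFractions
) -> float:
    """Weight-fraction mixing of A280 mass extinction (mL·mg⁻¹·cm⁻¹)."""
    return prot.epsilon * f.f_prot + glycan.epsilon * f.f_glycan


def fractions_from_masses(m_prot: float, m_glycan: float) -> WeightFractions:
    """Protein/glycan weight fractions from component masses (Da)."""
    if m_prot <= 0 or m_glycan < 0:
        raise ParameterError("masses must be positive (glycan may be 0)")
    total = m_prot + m_glycan
    return WeightFractions(f_prot=m_prot / total, f_glycan=m_glycan / total)


def solve_slice(
    sl: MalsSlice, conjugate: OpticalComponent, modifier: OpticalComponent
) -> SliceComposition:
    """Invert UV/RI/LS readings of one slice into a two-component composition.

    c_conj comes from UV (the modifier does not absorb), c_mod from the RI
    residual after the conjugate's contribution, and M_total from the
    zero-angle light-scattering relation with the dn/dc-weighted response.
    A negative RI residual beyond the clamp tolerance means the signals are
    inconsistent with the declared optical constants.
    """
    if conjugate.epsilon <= 0:
        raise ParameterError("conjugate extinction coefficient must be positive")
    if modifier.dndc <= 0:
        raise ParameterError("modifier dn/dc must be positive")
    if min(sl.ls_excess_rayleigh, sl.uv_absorbance, sl.ri_differential) < 0:
        raise InconsistentSignalsError("negative detector signal")

    c_conj = sl.uv_absorbance / (sl.k_uv * conjugate.epsilon)
    residual = sl.ri_differential / sl.k_ri - conjugate.dndc * c_conj
    c_mod = residual / modifier.dndc
    if c_mod < -_CLAMP_TOL:
        raise InconsistentSignalsError(
            f"UV implies more RI than measured (residual {residual:.3g})"
        )
    c_mod = max(c_mod, 0.0)
    c_conj = max(c_conj, 0.0)
    c_total = c_conj + c_mod

    if c_total <= _CLAMP_TOL:
        # clamp-level tails still scatter a little; only scattering with
        # strictly zero solute is inconsistent
        if c_total == 0.0 and sl.ls_excess_rayleigh > 0.0:
            raise InconsistentSignalsError("light scattering without solute")
        return SliceComposition(sl.volume, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    dndc_w = (conjugate.dndc * c_conj + modifier.dndc * c_mod) / c_total
    if dndc_w <= 0:
        raise InconsistentSignalsError("zero weighted dn/dc with nonzero solute")
    m_total = sl.ls_excess_rayleigh / (sl.k_ls * dndc_w**2 * c_total)
    return SliceComposition(
        volume=sl.volume,
        c_conjugate=c_conj,
        c_modifier=c_mod,
        dndc_weighted=dndc_w,
        m_total=m_total,
        m_conjugate=m_total * c_conj / c_total,
        m_modifier=m_total * c_mod / c_total,
    )


def solve_chromatogram(
    slices: Sequence[MalsSlice],
    conjugate: OpticalComponent,
    modifier: OpticalComponent,
    peak_range: tuple[float, float] | None = None,
    skip_inconsistent: bool = True,
) -> list[SliceComposition]:
    """Solve every slice of a chromatogram, optionally within a peak window.

    Noisy baseline slices outside the peak routinely violate the
    two-component model (e.g. zero clamped UV with residual LS noise); with
    ``skip_inconsistent`` they are dropped rather than fatal.
    """
    out: list[SliceComposition] = []
    for sl in slices:
        if peak_range is not None and not peak_range[0] <= sl.volume <= peak_range[1]:
            continue
        try:
            out.append(solve_slice(sl, conjugate, modifier))
        except InconsistentSignalsError:
            if not skip_inconsistent:
                raise
    return out


def peak_masses(
    slices: Sequence[SliceComposition],
    peak_range: tuple[float, float] | None = None,
) -> ConjugateMassResult:
    """Concentration-weighted average component masses over a peak.

    ``peak_range`` is an inclusive elution-volume interval (mL); by default
    all slices with solute are used.
    """
    if peak_range is not None:
        lo, hi = peak_range
        slices = [s for s in slices if lo <= s.volume <= hi]
    slices = [s for s in slices if s.c_conjugate + s.c_modifier > 0]
    if len(slices) < 3:
        raise ParameterError("need ≥3 solute-bearing slices in the peak range")
    c_conj = np.array([s.c_conjugate for s in slices])
    c_mod = np.array([s.c_modifier for s in slices])
    m_conj = np.array([s.m_conjugate for s in slices])
    m_mod = np.array([s.m_modifier for s in slices])
    mw_conj = float((c_conj * m_conj).sum() / c_conj.sum()) if c_conj.sum() > 0 else 0.0
    mw_mod = float((c_mod * m_mod).sum() / c_mod.sum()) if c_mod.sum() > 0 else 0.0
    mass_conj = (c_conj * m_conj).sum()
    mass_mod = (c_mod * m_mod).sum()
    total = mass_conj + mass_mod
    return ConjugateMassResult(
        m_conjugate=mw_conj,
        m_modifier=mw_mod,
        f_conjugate=float(mass_conj / total) if total > 0 else 0.0,
        f_modifier=float(mass_mod / total) if total > 0 else 0.0,
        n_slices=len(slices),
    )


def read_chromatogram(path, **slice_kwargs) -> list[MalsSlice]:
    """Read a delimited table with columns volume, LS, UV, RI into slices."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        v, ls, uv, ri = (cols[k] for k in ("volume", "ls", "uv", "ri"))
    except KeyError as exc:
        raise ParameterError(f"{path}: missing column {exc}") from exc
    return [
        MalsSlice(
            volume=float(r[v]),
            ls_excess_rayleigh=float(r[ls]),
            uv_absorbance=float(r[uv]),
            ri_differential=float(r[ri]),
            **slice_kwargs,
        )
        for _, r in df.iterrows()
    ]
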