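"""Thermal-unfolding analysis of tryptophan-fluorescence melt curves.

The fluorescence intensity ratio FIR = F350/F330 red-shifts as buried
tryptophans become solvent-exposed, so a two-state unfolding transition
appears as a sigmoidal rise in FIR; its midpoint temperature Tm is located
at the maximum of the smoothed first derivative dFIR/dT, and the onset of
denaturation at the lowest temperature where the derivative first reaches a
fraction of its peak height.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import NoTransitionError, ParameterError


@dataclasses.dataclass
class MeltCurve:
    """FIR vs temperature for one capillary/condition."""

    temperature: np.ndarray  # °C, strictly ascending
    fir: np.ndarray
    f350: np.ndarray | None = None
    f330: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fir = np.asarray(self.fir, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.shape != self.fir.shape:
            raise ParameterError("temperature and fir must be matching 1D arrays")
        if np.any(np.diff(self.temperature) <= 0):
            raise ParameterError("temperatures must be strictly increasing")


@dataclasses.dataclass(frozen=True)
class TmResult:
    tm: float  # °C
    onset: float  # °C
    derivative_peak_height: float  # FIR units per °C
    all_tms: tuple[float, ...] = ()
    multi_transition: bool = False
    replicate_spread: float | None = None  # ± °C, half-range over replicates

    def __post_init__(self) -> None:
        if self.onset > self.tm + 1e-9:
            raise ParameterError("onset cannot exceed Tm")


def compute_fir(
    temperature: np.ndarray,
    f350: np.ndarray,
    f330: np.ndarray,
    label: str = "",
) -> MeltCurve:
    """Elementwise F350/F330 ratio; both channels must be positive."""
    f350 = np.asarray(f350, dtype=float)
    f330 = np.asarray(f330, dtype=float)
    if np.any(f330 <= 0) or np.any(f350 <= 0):
        raise ParameterError("fluorescence channels must be positive")
    return MeltCurve(
        temperature=temperature, fir=f350 / f330, f350=f350, f330=f330, label=label
    )


def melt_derivative(curve: MeltCurve, smooth_window: float = 2.5) -> np.ndarray:
    """Smoothed first derivative dFIR/dT on the curve's own grid.

    Local quadratic polynomial (Savitzky–Golay) differentiation over a
    window of ``smooth_window`` °C; the grid must be uniform.
    """
    T = curve.temperature
    if len(T) < 5:
        raise ParameterError("need ≥5 points to differentiate a melt curve")
    steps = np.diff(T)
    dT = float(np.median(steps))
    if np.max(np.abs(steps - dT)) > 1e-6 * max(dT, 1.0):
        raise ParameterError("temperature grid must be uniform")
    if smooth_window < dT:
        raise ParameterError("smoothing window must be ≥ the grid spacing")
    window = int(round(smooth_window / dT)) | 1  # odd point count
    window = max(window, 5)
    window = min(window, len(T) if len(T) % 2 else len(T) - 1)
    return savgol_filter(curve.fir, window, polyorder=2, deriv=1, delta=dT)


def _refine_peak(T: np.ndarray, deriv: np.ndarray, i: int) -> float:
    """Sub-grid peak position by parabolic interpolation through 3 points."""
    if i == 0 or i == len(T) - 1:
        return float(T[i])
    y0, y1, y2 = deriv[i - 1], deriv[i], deriv[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(T[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return float(T[i] + delta * (T[i + 1] - T[i]))


def find_tm(
    curve: MeltCurve,
    smooth_window: float = 2.5,
    min_prominence: float = 0.5,
    onset_threshold: float = 0.10,
    increasing: bool = True,
) -> TmResult:
    """Locate the unfolding midpoint(s) and onset from the FIR derivative.

    Tm is the temperature of the global positive derivative peak; further
    peaks with prominence ≥ ``min_prominence`` × the global peak height are
    reported and flagged as a multi-transition curve.  The onset is the
    lowest temperature at which the smoothed derivative first exceeds
    ``onset_threshold`` × the peak height on the way up to Tm.  Set
    ``increasing=False`` for probes whose signal falls on unfolding.
    """
    deriv = melt_derivative(curve, smooth_window)
    if not increasing:
        deriv = -deriv
    # the boundary polynomial fits of the smoother are noise-inflated;
    # exclude half a window at each end from the peak search
    T = curve.temperature
    dT = float(np.median(np.diff(T)))
    edge = max(1, int(round(smooth_window / (2 * dT))))
    interior = np.full_like(deriv, -np.inf)
    interior[edge:-edge] = deriv[edge:-edge]
    peak_height = float(interior.max())
    if not np.isfinite(peak_height) or peak_height <= 0:
        raise NoTransitionError(f"{curve.label}: no positive derivative peak")
    idx, _props = find_peaks(deriv, prominence=min_prominence * peak_height)
    idx = idx[(idx >= edge) & (idx < len(deriv) - edge)]
    if len(idx) == 0:
        raise NoTransitionError(f"{curve.label}: no transition of sufficient prominence")
    order = np.argsort(deriv[idx])[::-1]
    idx = idx[order]
    tm_i = int(idx[0])
    tm = _refine_peak(T, deriv, tm_i)

    thresh = onset_threshold * deriv[tm_i]
    onset = float(T[0])
    below = np.nonzero(deriv[: tm_i + 1] < thresh)[0]
    if len(below):
        onset = float(T[min(below[-1] + 1, tm_i)])
    onset = min(onset, tm)
    return TmResult(
        tm=tm,
        onset=onset,
        derivative_peak_height=float(deriv[tm_i]),
        all_tms=tuple(float(T[i]) for i in idx),
        multi_transition=len(idx) > 1,
    )


def replicate_tm(results: list[TmResult]) -> TmResult:
    """Combine replicate measurements as mean ± half-range."""
    if not results:
        raise ParameterError("no replicates")
    tms = np.array([r.tm for r in results])
    onsets = np.array([r.onset for r in results])
    heights = np.array([r.derivative_peak_height for r in results])
    return TmResult(
        tm=float(tms.mean()),
        onset=float(onsets.mean()),
        derivative_peak_height=float(heights.mean()),
        all_tms=tuple(map(float, tms)),
        multi_transition=any(r.multi_transition for r in results),
        replicate_spread=float((tms.max() - tms.min()) / 2.0),
    )
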