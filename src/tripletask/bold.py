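"""Demand-to-BOLD conversion: gamma-kernel convolution, scan sampling,
percent-signal-change baselining, and area under the curve.

A module's activity over a trial is a 0-1 demand function D(t).  The BOLD
response to that demand is the convolution of D with a gamma kernel

    h(t) = m * (t/s)**a * exp(-t/s)

with magnitude m = 1, time scale s = 0.75 s and shape a = 6 (the
architecture's default hemodynamic parameters, deliberately not fitted to
data, so only the shape of a prediction is meaningful, not its units).
The kernel peaks at t = a*s = 4.5 s.  Curves are sampled at the scanner
TR (2 s), expressed as percent signal change against the mean of a
trial's first two scans, and summarized by the area under the curve,
which is sensitive to both the magnitude and the duration of the
response.

Numerics: demand indicators use area-exact fractional bin coverage and
the kernel is sampled at bin centres, so the discrete convolution
conserves area exactly — the integral of the output equals the module's
total busy time times the (discrete) kernel integral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .engine import DemandTrace

__all__ = [
    "GammaParams",
    "RoiInfo",
    "ROI_MAP",
    "BoldSeries",
    "BoldCurve",
    "gamma_kernel",
    "kernel_support_s",
    "kernel_samples",
    "demand_indicator",
    "convolve_demand",
    "to_scan_curve",
    "auc",
]


@dataclass(frozen=True)
class GammaParams:
    """Hemodynamic gamma-kernel parameters: magnitude m, time scale s
    (seconds), shape a."""

    m: float = 1.0
    s: float = 0.75
    a: float = 6.0

    def __post_init__(self) -> None:
        if self.m <= 0 or self.s <= 0 or self.a <= 0:
            raise ValueError("gamma parameters m, s, a must all be > 0")

    @property
    def mode_s(self) -> float:
        """Time of the kernel peak: a * s."""
        return self.a * self.s


@dataclass(frozen=True)
class RoiInfo:
    module: str
    region: str
    brodmann: str
    voxels: str  # extent in 3x3x3 mm voxels
    talairach: tuple[int, int, int]
    mni: tuple[int, int, int]


#: The five modules with predicted regions (left hemisphere).
ROI_MAP: dict[str, RoiInfo] = {
    "aural": RoiInfo("aural", "Secondary auditory cortex", "21/22/42", "5x5x5", (-45, -22, 9), (-48, -21, 7)),
    "manual": RoiInfo("manual", "Precentral gyrus", "3", "5x5x4", (-42, -20, 50), (-42, -23, 54)),
    "visual": RoiInfo("visual", "Fusiform gyrus", "37", "5x5x4", (-41, -61, -9), (-43, -60, -16)),
    "problem_state": RoiInfo("problem_state", "Intraparietal sulcus", "7/39/40", "5x5x4", (-24, -63, 40), (-24, -67, 44)),
    "declarative": RoiInfo("declarative", "Inferior frontal sulcus", "45/46", "5x5x4", (-42, 23, 24), (-43, 24, 25)),
}


def gamma_kernel(t_s, params: GammaParams = GammaParams()):
    """Kernel intensity m*(t/s)^a*exp(-t/s) at time(s) ``t_s`` (seconds).

    Zero at t = 0, unimodal with mode at a*s.  Raises for negative t.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("gamma kernel is defined for t >= 0 only")
    x = t / params.s
    with np.errstate(divide="ignore"):
        out = params.m * np.power(x, params.a) * np.exp(-x)
    return out if out.shape else float(out)


def kernel_support_s(params: GammaParams = GammaParams(), rel_cut: float = 1e-8) -> float:
    """Upper time bound where the kernel falls below ``rel_cut`` of its
    peak; beyond it the kernel is truncated for exact reproducibility."""
    peak = gamma_kernel(params.mode_s, params)
    target = rel_cut * peak

    def f(t):
        return gamma_kernel(t, params) - target

    hi = params.mode_s * 2
    while f(hi) > 0:
        hi *= 2
    return float(brentq(f, params.mode_s, hi, xtol=1e-9))


def kernel_samples(params: GammaParams = GammaParams(), dt_s: float = 0.05) -> np.ndarray:
    """Kernel sampled at bin centres over its truncated support."""
    support = kernel_support_s(params)
    n = max(1, int(math.ceil(support / dt_s)))
    t = (np.arange(n) + 0.5) * dt_s
    return gamma_kernel(t, params)


def demand_indicator(
    trace: DemandTrace | list[tuple[float, float]],
    resource: str | None = None,
    dt_s: float = 0.05,
    t_max_s: float | None = None,
) -> np.ndarray:
    """Binned 0-1 demand function with fractional (area-exact) coverage.

    ``trace`` is a :class:`DemandTrace` (with ``resource`` naming the
    module) or a raw list of (start_ms, end_ms) intervals.  Bin i covers
    [i*dt, (i+1)*dt) seconds; its value is the covered fraction, so
    ``indicator.sum()*dt`` equals the busy time exactly.
    """
    if isinstance(trace, DemandTrace):
        if resource is None:
            raise ValueError("resource required when passing a DemandTrace")
        intervals = trace.intervals.get(resource, [])
        if t_max_s is None:
            t_max_s = trace.trial_length_ms / 1000.0
    else:
        intervals = trace
        if t_max_s is None:
            t_max_s = max((e for _, e in intervals), default=0.0) / 1000.0
    n = max(1, int(math.ceil(t_max_s / dt_s - 1e-9)))
    out = np.zeros(n)
    for s_ms, e_ms in intervals:
        s, e = s_ms / 1000.0, e_ms / 1000.0
        if e <= s:
            continue
        i0 = int(s / dt_s)
        i1 = min(n - 1, int((e - 1e-12) / dt_s))
        if i0 >= n:
            continue
        if i0 == i1:
            out[i0] += (min(e, t_max_s) - s) / dt_s
            continue
        out[i0] += ((i0 + 1) * dt_s - s) / dt_s
        if i1 > i0 + 1:
            out[i0 + 1 : i1] += 1.0
        out[i1] += (min(e, (i1 + 1) * dt_s, t_max_s) - i1 * dt_s) / dt_s
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class BoldSeries:
    """Continuous (finely sampled) BOLD series: values at bin centres."""

    values: np.ndarray
    dt_s: float

    @property
    def t_s(self) -> np.ndarray:
        return (np.arange(len(self.values)) + 0.5) * self.dt_s

    def integral(self) -> float:
        return float(self.values.sum() * self.dt_s)


def convolve_demand(
    trace: DemandTrace | np.ndarray,
    resource: str | None = None,
    params: GammaParams = GammaParams(),
    dt_s: float = 0.05,
) -> BoldSeries:
    """Convolve a module's demand function with the gamma kernel.

    Accepts a :class:`DemandTrace` plus resource name, or a pre-binned
    indicator array.  The output covers the trial plus the kernel tail
    and is linear in demand.  An empty trace gives an all-zero series.
    """
    if dt_s <= 0 or dt_s > 0.1:
        raise ValueError("dt_s must be in (0, 0.1] s")
    if isinstance(trace, np.ndarray):
        d = trace
    else:
        d = demand_indicator(trace, resource, dt_s)
    k = kernel_samples(params, dt_s)
    return BoldSeries(np.convolve(d, k) * dt_s, dt_s)


@dataclass
class BoldCurve:
    """Scan-sampled percent-signal-change curve for one ROI/condition."""

    values: np.ndarray
    tr_s: float = 2.0
    baseline_scans: int = 2
    roi: str | None = None
    condition: str | None = None

    @property
    def n_scans(self) -> int:
        return len(self.values)


def to_scan_curve(
    series: BoldSeries,
    tr_s: float = 2.0,
    n_scans: int | None = None,
    baseline_scans: int = 2,
    raw_offset: float = 100.0,
    roi: str | None = None,
    condition: str | None = None,
) -> BoldCurve:
    """Sample a series at scan onsets and baseline to percent change.

    The raw signal is the predicted series on top of a nominal resting
    offset (grand-mean scaled to 100, as fMRI pipelines do), so predicted
    and synthetic curves share units.  Percent change is taken against
    the mean of the first ``baseline_scans`` scans; with no demand in
    those scans this leaves predicted values unchanged.
    """
    if n_scans is None:
        n_scans = int(math.ceil(len(series.values) * series.dt_s / tr_s)) + 1
    t_scan = np.arange(n_scans) * tr_s
    raw = raw_offset + np.interp(t_scan, series.t_s, series.values, left=0.0, right=0.0)
    base = float(raw[:baseline_scans].mean())
    if base <= 0:
        raise ValueError("degenerate baseline: mean raw signal of first scans <= 0")
    pct = (raw - base) / base * 100.0
    return BoldCurve(pct, tr_s, baseline_scans, roi=roi, condition=condition)


def auc(curve: BoldCurve, window: tuple[int, int] | None = None) -> float:
    """Area under the curve: plain sum of per-scan percent-change values
    over ``window`` = (first scan, stop scan), default the whole curve."""
    if window is None:
        window = (0, curve.n_scans)
    lo, hi = window
    if not (0 <= lo < hi <= curve.n_scans):
        raise ValueError(f"empty or out-of-range AUC window {window}")
    return float(curve.values[lo:hi].sum())
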