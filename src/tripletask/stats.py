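"""Behavioural and ROI statistics: RT trimming, arcsine-transformed
accuracies, and within-subject 2x2(x2) repeated-measures ANOVAs.

All F tests are computed from per-subject contrast scores: for a
two-level within factor the main-effect contrast is the per-subject
difference of level means, and the interaction contrast is
hh - he - eh + ee.  With n subjects each effect is tested on (1, n-1)
degrees of freedom; F equals the squared paired t statistic on the same
contrast, and partial eta squared is F / (F + df2).  Accuracy proportions
are variance-stabilized with arcsin(sqrt(p)) before testing.  No
multiple-testing correction is applied (each test at alpha = .05).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TrimResult",
    "trim_rt",
    "arcsine_acc",
    "rm_anova_2x2",
    "rm_anova_2x2x2",
    "interaction_contrast",
]


@dataclass
class TrimResult:
    kept: pd.DataFrame | np.ndarray
    discarded_fraction: float
    flagged_cells: list[tuple]

    def __iter__(self):  # tuple-style unpacking: kept, fraction
        return iter((self.kept, self.discarded_fraction))


def trim_rt(
    samples,
    rt_col: str = "rt_ms",
    bounds_ms: tuple[float, float] = (250.0, 10_000.0),
    sd_cut: float = 3.0,
    cell_cols: Sequence[str] = ("subject", "condition", "task"),
) -> TrimResult:
    """Two-pass RT outlier removal.

    Pass 1 removes responses faster than 250 ms or slower than 10,000 ms;
    pass 2 removes survivors more than 3 SD from the mean of their
    subject x condition (x task) cell.  Cells left with fewer than two
    survivors after pass 1 are flagged and skip the SD pass.  Accepts a
    DataFrame (with ``rt_col`` and the ``cell_cols`` present) or a plain
    sequence of RTs treated as one cell.
    """
    as_array = not isinstance(samples, pd.DataFrame)
    if as_array:
        arr = np.asarray(list(samples), dtype=float)
        if arr.size == 0:
            raise ValueError("samples must be non-empty")
        df = pd.DataFrame({rt_col: arr, "_cell": 0})
        cell_cols = ("_cell",)
    else:
        if len(samples) == 0:
            raise ValueError("samples must be non-empty")
        df = samples
        cell_cols = [c for c in cell_cols if c in df.columns]

    n0 = len(df)
    lo, hi = bounds_ms
    p1 = df[(df[rt_col] >= lo) & (df[rt_col] <= hi)]

    flagged: list[tuple] = []
    kept_parts = []
    grouped = p1.groupby(list(cell_cols), sort=False, observed=True) if cell_cols else [((), p1)]
    for key, cell in grouped:
        if len(cell) < 2:
            flagged.append(key if isinstance(key, tuple) else (key,))
            kept_parts.append(cell)
            continue
        m, sd = cell[rt_col].mean(), cell[rt_col].std(ddof=1)
        kept_parts.append(cell[(cell[rt_col] - m).abs() <= sd_cut * sd])
    kept = pd.concat(kept_parts).sort_index() if kept_parts else p1
    frac = 1.0 - len(kept) / n0
    if as_array:
        return TrimResult(kept[rt_col].to_numpy(), frac, flagged)
    return TrimResult(kept, frac, flagged)


def arcsine_acc(p):
    """Arcsine variance-stabilizing transform of a proportion:
    arcsin(sqrt(p)); 0 -> 0 and 1 -> pi/2."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return out if out.shape else float(out)


def _wide_cells(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> tuple[pd.DataFrame, list[tuple]]:
    """Pivot to subjects x cells; validate complete balanced crossing of
    the two-level within factors."""
    levels = []
    for f in within:
        lv = sorted(data[f].unique())
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, got {lv}")
        levels.append(lv)
    cells = list(itertools.product(*levels))
    wide = data.pivot_table(index=subject, columns=list(within), values=dv, aggfunc="mean")
    wide = wide.reindex(columns=pd.MultiIndex.from_tuples(cells) if len(within) > 1 else levels[0] + levels[1:])
    if len(within) == 1:
        wide.columns = [(c,) for c in wide.columns]
    if wide.isna().any().any():
        raise ValueError("missing cells: design must be complete and balanced")
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects")
    return wide, cells


def _contrast_f(scores: np.ndarray) -> tuple[float, float, float]:
    """(F, p, eta_p2) from per-subject contrast scores on (1, n-1) df."""
    n = len(scores)
    mean = scores.mean()
    var = scores.var(ddof=1)
    if var == 0.0:
        f = 0.0 if mean == 0.0 else float("inf")
    else:
        f = n * mean**2 / var
    p = float(sps.f.sf(f, 1, n - 1)) if np.isfinite(f) else 0.0
    eta = f / (f + (n - 1)) if np.isfinite(f) else 1.0
    return float(f), p, float(eta)


def _rm_anova_contrasts(
    data: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> pd.DataFrame:
    wide, cells = _wide_cells(data, dv, within, subject)
    n = len(wide)
    rows = []
    k = len(within)
    for mask in range(1, 2**k):
        involved = [within[i] for i in range(k) if mask >> i & 1]
        coefs = []
        for cell in cells:
            c = 1.0
            for i in range(k):
                if mask >> i & 1:
                    # +1 for the high (second) level of an involved factor
                    c *= 1.0 if cell[i] == sorted(data[within[i]].unique())[1] else -1.0
            coefs.append(c)
        # normalize so a main effect is a difference of level means
        scale = 2.0 ** (k - len(involved)) if k > len(involved) else 1.0
        scores = wide.to_numpy() @ (np.array(coefs) / scale)
        f, p, eta = _contrast_f(scores)
        rows.append(
            {
                "effect": " x ".join(involved),
                "F": f,
                "df1": 1,
                "df2": n - 1,
                "p": p,
                "eta_p2": eta,
            }
        )
    return pd.DataFrame(rows)


def rm_anova_2x2(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] = ("subtraction", "text_entry"),
    subject: str = "subject",
) -> pd.DataFrame:
    """Repeated-measures 2x2 ANOVA: two main effects and the interaction,
    each on (1, n-1) df, from per-subject paired contrasts.

    ``data`` is long format with one (averaged) value per subject x cell.
    Returns a frame with columns effect, F, df1, df2, p, eta_p2.
    """
    if len(within) != 2:
        raise ValueError("rm_anova_2x2 needs exactly two within factors")
    return _rm_anova_contrasts(data, dv, within, subject)


def rm_anova_2x2x2(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] = ("listening", "subtraction", "text_entry"),
    subject: str = "subject",
) -> pd.DataFrame:
    """Three-way within-subject ANOVA over the 8 cells (same contrast
    machinery; 7 effects, each on (1, n-1) df)."""
    if len(within) != 3:
        raise ValueError("rm_anova_2x2x2 needs exactly three within factors")
    return _rm_anova_contrasts(data, dv, within, subject)


def interaction_contrast(
    data: pd.DataFrame,
    dv: str,
    within: Sequence[str] = ("subtraction", "text_entry"),
    subject: str = "subject",
) -> tuple[float, pd.Series]:
    """Per-subject over-additivity score hh - he - eh + ee and its mean.

    A positive mean means the joint hard-hard cost exceeds the sum of the
    single-task costs — the bottleneck's signature.
    """
    wide, cells = _wide_cells(data, dv, within, subject)
    hi = [sorted(data[f].unique())[1] for f in within]
    coefs = np.array(
        [np.prod([1.0 if cell[i] == hi[i] else -1.0 for i in range(len(within))]) for cell in cells]
    )
    scores = pd.Series(wide.to_numpy() @ coefs, index=wide.index, name="interaction")
    return float(scores.mean()), scores
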