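"""Synthetic per-subject ROI time courses and a parameter-recovery harness.

The study's scanner data are emulated as: model-predicted condition mean
curves (per ROI, rescaled to a realistic percent-signal-change amplitude),
multiplied by a subject-level lognormal gain, plus stationary AR(1)
Gaussian scan noise, an optional linear drift, and an optional carryover
contamination of the baseline scans (the mechanism behind measured curves
that fail to return to baseline).  Everything is seeded and reproducible.

The recovery harness feeds these synthetic datasets through the same
AUC + repeated-measures ANOVA pipeline used for the real analysis and
reports the rejection rate of the difficulty x difficulty interaction
test: under an additive null the rate calibrates the test's type-I error,
and as the injected interaction component grows the rate traces a power
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bold import BoldCurve, auc
from .stats import rm_anova_2x2
from .trial_sim import Condition, TASK_CONDITIONS

__all__ = [
    "NoiseModel",
    "EffectSpec",
    "gen_subject_curves",
    "auc_table",
    "RecoveryResult",
    "recovery_experiment",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters for synthetic ROI curves.

    All levels are assumptions (the study reports no variance components):
    per-scan percent-change SD of a subject's trial-averaged condition
    curve (~10 trials per cell average out most single-trial noise),
    lag-1 autocorrelation of scan noise, SD of the subject-level
    multiplicative (lognormal) gain, and a linear baseline drift per
    scan.  The per-scan SD is calibrated so that with 10 subjects the
    interaction test has realistic (neither floor nor ceiling) power.
    """

    sigma_scan: float = 0.06
    ar1_rho: float = 0.3
    sigma_subject: float = 0.2
    baseline_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_scan < 0 or self.sigma_subject < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (-1.0 < self.ar1_rho < 1.0):
            raise ValueError("|ar1_rho| must be < 1")


@dataclass(frozen=True)
class EffectSpec:
    """Condition mean curves to inject, keyed by (roi, Condition).

    ``interaction_scale`` multiplies the over-additive component of each
    ROI's hard-hard cell within a listening stratum: 0 replaces the means
    by their additive surrogate (a true null), 1 keeps the model
    prediction.  ``carryover`` adds that fraction of a curve's peak to the
    baseline scans, emulating BOLD carryover from the previous trial.
    """

    curves: Mapping[tuple[str, Condition], np.ndarray]
    tr_s: float = 2.0
    baseline_scans: int = 2
    interaction_scale: float = 1.0
    carryover: float = 0.0

    def __post_init__(self) -> None:
        if self.interaction_scale < 0:
            raise ValueError("interaction_scale must be >= 0")

    @staticmethod
    def from_predictions(
        pred: Mapping[tuple[str, Condition], BoldCurve],
        amplitude_pct: float = 0.5,
        interaction_scale: float = 1.0,
        carryover: float = 0.0,
    ) -> "EffectSpec":
        """Build an EffectSpec from predicted curves, rescaling each ROI so
        its largest condition peak equals ``amplitude_pct`` percent signal
        change (model predictions carry arbitrary units; only their shape
        is meaningful)."""
        rois = {r for r, _ in pred}
        curves: dict[tuple[str, Condition], np.ndarray] = {}
        tr_s = next(iter(pred.values())).tr_s
        for roi in rois:
            peak = max(float(np.max(c.values)) for (r, _), c in pred.items() if r == roi)
            scale = amplitude_pct / peak if peak > 0 else 0.0
            for (r, cond), c in pred.items():
                if r == roi:
                    curves[(roi, cond)] = c.values * scale
        return EffectSpec(
            curves, tr_s=tr_s, interaction_scale=interaction_scale, carryover=carryover
        )

    def with_scale(self, interaction_scale: float) -> "EffectSpec":
        return replace(self, interaction_scale=interaction_scale)

    def mean_curve(self, roi: str, cond: Condition) -> np.ndarray:
        """Injected mean for one cell, with the interaction component of
        the hard-hard cell scaled by ``interaction_scale``."""
        base = np.asarray(self.curves[(roi, cond)], dtype=float)
        if self.interaction_scale == 1.0 or cond.only_listening:
            return base
        if not (cond.subtraction == "hard" and cond.text_entry == "hard"):
            return base
        cells = {}
        n = len(base)
        for s in ("easy", "hard"):
            for t in ("easy", "hard"):
                c = self.curves.get((roi, Condition(s, t, cond.listening)))
                if c is None:
                    return base  # stratum incomplete: nothing to scale
                v = np.zeros(n)
                v[: min(n, len(c))] = np.asarray(c[: min(n, len(c))], dtype=float)
                cells[(s, t)] = v
        additive = cells[("hard", "easy")] + cells[("easy", "hard")] - cells[("easy", "easy")]
        return additive + self.interaction_scale * (cells[("hard", "hard")] - additive)


def _ar1(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sigma`` and lag-1
    autocorrelation ``rho``."""
    if sigma == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i - 1]
    return x


def gen_subject_curves(
    effects: EffectSpec,
    noise: NoiseModel = NoiseModel(),
    n_subjects: int = 10,
    seed: int = 0,
) -> dict[tuple[int, str, Condition], BoldCurve]:
    """Synthetic per-subject ROI curves.

    curve = subject gain x condition mean, on a raw offset of 100, plus
    AR(1) scan noise, linear drift, and optional carryover contamination
    of the two baseline scans; then re-expressed as percent change
    against those baseline scans (exactly as measured curves would be).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    master = np.random.SeedSequence(seed)
    out: dict[tuple[int, str, Condition], BoldCurve] = {}
    keys = sorted(effects.curves.keys(), key=lambda k: (k[0], k[1].label))
    for subj, subj_ss in enumerate(master.spawn(n_subjects)):
        rng = np.random.default_rng(subj_ss)
        gain = float(np.exp(rng.normal(0.0, noise.sigma_subject))) if noise.sigma_subject else 1.0
        for roi, cond in keys:
            mean = effects.mean_curve(roi, cond)
            n = len(mean)
            raw = 100.0 + gain * mean
            raw = raw + _ar1(rng, n, noise.sigma_scan, noise.ar1_rho)
            if noise.baseline_drift:
                raw = raw + noise.baseline_drift * np.arange(n)
            if effects.carryover:
                raw[: effects.baseline_scans] += effects.carryover * gain * float(np.max(mean, initial=0.0))
            base = float(raw[: effects.baseline_scans].mean())
            pct = (raw - base) / base * 100.0
            out[(subj, roi, cond)] = BoldCurve(
                pct, effects.tr_s, effects.baseline_scans, roi=roi, condition=cond.label
            )
    return out


def auc_table(
    curves: Mapping[tuple[int, str, Condition], BoldCurve],
    windows: Mapping[Condition, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Subject x condition x ROI AUC table feeding the ANOVAs."""
    rows = []
    for (subj, roi, cond), curve in curves.items():
        w = None if windows is None else windows.get(cond)
        rows.append(
            {
                "subject": subj,
                "roi": roi,
                "subtraction": cond.subtraction,
                "text_entry": cond.text_entry,
                "listening": cond.listening,
                "condition": cond.label,
                "auc": auc(curve, w),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryResult:
    rejection_rate: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float


def recovery_experiment(
    effects: EffectSpec,
    noise: NoiseModel = NoiseModel(),
    n_subjects: int = 10,
    interaction_scale: float = 1.0,
    n_reps: int = 1000,
    seed: int = 0,
    roi: str = "problem_state",
    listening: bool = False,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Rejection rate of the difficulty x difficulty interaction test on
    synthetic data.

    Each replicate draws ``n_subjects`` synthetic subjects for the four
    task cells of one listening stratum of one ROI, computes per-curve
    AUCs, runs the 2x2 repeated-measures ANOVA, and records whether the
    interaction p-value falls below ``alpha``.  Returns the rejection
    proportion with a normal-approximation Monte-Carlo CI.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cells = [c for c in (TASK_CONDITIONS if not listening else
                         [Condition(s, t, True) for s in ("easy", "hard") for t in ("easy", "hard")])]
    sub = {
        (roi, cond): np.asarray(v, dtype=float)
        for (r, cond), v in effects.curves.items()
        if r == roi and cond in cells
    }
    if len(sub) != 4:
        raise ValueError(f"effects must contain the 4 task cells for roi {roi!r}")
    eff = replace(effects, curves=sub, interaction_scale=interaction_scale)

    master = np.random.SeedSequence(seed)
    hits = 0
    for rep_ss in master.spawn(n_reps):
        rep_seed = int(rep_ss.generate_state(1)[0] % (2**31))
        curves = gen_subject_curves(eff, noise, n_subjects, rep_seed)
        table = auc_table(curves)
        res = rm_anova_2x2(table, "auc")
        p = float(res.loc[res.effect == "subtraction x text_entry", "p"].iloc[0])
        hits += p < alpha
    rate = hits / n_reps
    half = 1.959963984540054 * np.sqrt(max(rate * (1 - rate), 1e-12) / n_reps)
    return RecoveryResult(rate, max(0.0, rate - half), min(1.0, rate + half), n_reps, alpha)
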