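"""End-to-end orchestration: simulate -> predict -> synth -> analyze.

``run_pipeline`` runs the whole chain from one config: simulate the
behavioural experiment, turn per-condition demand into predicted ROI
curves, generate synthetic per-subject measurements from those
predictions, run the behavioural and AUC ANOVAs, and write all tables
plus a plain-text report comparing predicted and measured effect
directions per ROI.  Every output carries the config hash and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bold import ROI_MAP, BoldCurve, GammaParams, auc, convolve_demand, demand_indicator, to_scan_curve
from .config import PipelineConfig
from .io import trace_events_frame, write_table
from .stats import arcsine_acc, interaction_contrast, rm_anova_2x2, rm_anova_2x2x2, trim_rt
from .synth import EffectSpec, NoiseModel, auc_table, gen_subject_curves
from .trial_sim import (
    CONDITIONS,
    Condition,
    TrialParams,
    gen_stimuli,
    simulate_experiment,
    simulate_trial,
)

log = logging.getLogger("tripletask")

__all__ = [
    "PredictedCurves",
    "predict_condition_curves",
    "behavioral_anova",
    "roi_auc_anova",
    "run_pipeline",
    "PipelineResult",
]


@dataclass
class PredictedCurves:
    """Model-predicted mean percent-change curve per ROI per condition,
    plus the per-condition feedback scan (demand is clipped there; the
    curve still contains that demand's full hemodynamic tail)."""

    curves: dict[tuple[str, Condition], BoldCurve]
    feedback_scan: dict[Condition, int]
    gamma: GammaParams

    def auc_frame(self) -> pd.DataFrame:
        rows = [
            {
                "roi": roi,
                "subtraction": cond.subtraction,
                "text_entry": cond.text_entry,
                "listening": cond.listening,
                "condition": cond.label,
                "auc": auc(curve),
            }
            for (roi, cond), curve in self.curves.items()
        ]
        return pd.DataFrame(rows)

    def long_frame(self) -> pd.DataFrame:
        rows = []
        for (roi, cond), curve in self.curves.items():
            for scan, v in enumerate(curve.values):
                rows.append({"roi": roi, "condition": cond.label, "scan": scan, "pct": v})
        return pd.DataFrame(rows)


def predict_condition_curves(
    params: TrialParams = TrialParams(),
    gamma: GammaParams = GammaParams(),
    seed: int = 0,
    n_rep: int = 3,
    dt_s: float = 0.05,
    conditions=CONDITIONS,
) -> PredictedCurves:
    """Predicted ROI curves per condition.

    For each condition, ``n_rep`` trials are simulated (stimuli vary by
    seed), their demand traces are clipped at feedback onset, averaged as
    binned demand fractions, and convolved with the gamma kernel; the
    result is sampled at the TR and baselined against the first two scans.
    """
    master = np.random.SeedSequence(seed)
    curves: dict[tuple[str, Condition], BoldCurve] = {}
    feedback_scan: dict[Condition, int] = {}
    for cond in conditions:
        cond_ss = master.spawn(1)[0]
        acc: dict[str, np.ndarray] = {}
        fb_ms = 0.0
        n_max = 0
        reps = []
        for rep_ss in cond_ss.spawn(n_rep):
            s_stim, s_run = rep_ss.spawn(2)
            stim = gen_stimuli(cond, s_stim, params)
            result, trace, _ = simulate_trial(cond, stim, params, s_run)
            clipped = trace.clipped(result.feedback_onset_ms)
            reps.append(clipped)
            fb_ms += result.feedback_onset_ms / n_rep
            n_max = max(n_max, int(np.ceil(result.feedback_onset_ms / 1000.0 / dt_s)))
        for roi in ROI_MAP:
            d = np.zeros(n_max)
            for clipped in reps:
                di = demand_indicator(clipped, roi, dt_s)
                d[: len(di)] += di / n_rep
            series = convolve_demand(d, params=gamma, dt_s=dt_s)
            curves[(roi, cond)] = to_scan_curve(
                series, tr_s=params.tr_ms / 1000.0, roi=roi, condition=cond.label
            )
        feedback_scan[cond] = int(np.ceil(fb_ms / params.tr_ms))
    return PredictedCurves(curves, feedback_scan, gamma)


def behavioral_anova(responses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """The behavioural statistics chain per task: drop first responses,
    trim RT outliers, average per subject x cell, then the three-way
    (Listening x Subtraction x Text Entry) within-subject ANOVA on RTs
    and on arcsine-transformed accuracies."""
    out: dict[str, pd.DataFrame] = {}
    task_resp = responses[responses.subtraction != "absent"]
    for task in ("subtraction", "text_entry"):
        r = task_resp[task_resp.task == task]
        rt = r[~r.first_response]
        trimmed = trim_rt(rt, cell_cols=("subject", "condition", "task")).kept
        cell_rt = (
            trimmed.groupby(["subject", "listening", "subtraction", "text_entry"], observed=True)
            .rt_ms.mean()
            .reset_index()
        )
        acc = (
            r.groupby(["subject", "listening", "subtraction", "text_entry"], observed=True)
            .correct.mean()
            .reset_index()
        )
        acc["acc_t"] = arcsine_acc(acc.correct.to_numpy())
        n_subj = cell_rt.subject.nunique()
        if n_subj >= 2:
            a_rt = rm_anova_2x2x2(cell_rt, "rt_ms")
            a_acc = rm_anova_2x2x2(acc, "acc_t")
            a_rt["measure"], a_acc["measure"] = "rt", "accuracy"
            out[task] = pd.concat([a_rt, a_acc], ignore_index=True)
        else:
            out[task] = pd.DataFrame()
    return out


def roi_auc_anova(table: pd.DataFrame) -> pd.DataFrame:
    """2x2 (Subtraction x Text Entry) ANOVA of AUC values per ROI,
    separately within each listening stratum (mirroring how the AUC
    results are tabulated)."""
    rows = []
    for roi in sorted(table.roi.unique()):
        for lis in (True, False):
            sub = table[(table.roi == roi) & (table.listening == lis) & (table.subtraction != "absent")]
            if sub.empty or sub.subject.nunique() < 2:
                continue
            res = rm_anova_2x2(sub, "auc")
            res.insert(0, "roi", roi)
            res.insert(1, "listening", lis)
            rows.append(res)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


@dataclass
class PipelineResult:
    config: PipelineConfig
    paths: dict[str, Path] = field(default_factory=dict)
    trials: pd.DataFrame | None = None
    responses: pd.DataFrame | None = None
    predicted: PredictedCurves | None = None
    auc_synthetic: pd.DataFrame | None = None
    anova_auc: pd.DataFrame | None = None
    anova_behavior: dict[str, pd.DataFrame] | None = None
    report: str = ""


def _effect_direction(x: float, tol: float = 1e-9) -> str:
    return "+" if x > tol else ("-" if x < -tol else "0")


def run_pipeline(config: PipelineConfig = PipelineConfig(), out_dir: str | Path | None = None) -> PipelineResult:
    """Run simulate -> predict -> synth -> analyze and write the report
    bundle (trials, responses, events, demand traces, predicted and
    synthetic curves, AUC tables, ANOVA tables, report.txt)."""
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    meta = {"config_hash": chash, "seed": config.seed}
    log.info("pipeline start: config_hash=%s seed=%d", chash, config.seed)
    config.to_yaml(out / "config.yaml")
    result = PipelineResult(config=config)
    params = config.trial_params()
    ss = np.random.SeedSequence(config.seed)
    s_sim, s_pred, s_synth = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    # --- simulate -------------------------------------------------------
    sample_traces: list[pd.DataFrame] = []
    event_rows: list[dict] = []

    def hook(subj, cond, trace, res, timeline):
        if subj == 0 and len(sample_traces) < len(CONDITIONS):
            sample_traces.append(trace_events_frame(trace, f"s0-{cond.label}"))
        event_rows.append(
            {
                "subject": subj,
                "condition": cond.label,
                "cue_onset_ms": timeline.cue_onset_ms,
                "task_onset_ms": timeline.task_onset_ms,
                "feedback_onset_ms": timeline.feedback_onset_ms,
                "iti_ms": timeline.iti_ms,
            }
        )

    data = simulate_experiment(config.n_subjects, config.blocks, params, s_sim, trace_hook=hook)
    result.trials, result.responses = data.trials, data.responses
    result.paths["trials"] = write_table(data.trials, out / "trials.tsv", meta)
    result.paths["responses"] = write_table(data.responses, out / "responses.tsv", meta)
    result.paths["events"] = write_table(pd.DataFrame(event_rows), out / "events.tsv", meta)
    result.paths["traces"] = write_table(pd.concat(sample_traces, ignore_index=True), out / "traces.tsv", meta)

    # --- predict --------------------------------------------------------
    predicted = predict_condition_curves(params, config.gamma, s_pred, config.pred_reps, config.dt_s)
    result.predicted = predicted
    result.paths["curves_predicted"] = write_table(predicted.long_frame(), out / "curves_predicted.tsv", meta)
    pred_auc = predicted.auc_frame()
    result.paths["auc_predicted"] = write_table(pred_auc, out / "auc_predicted.tsv", meta)

    # --- synth ----------------------------------------------------------
    effects = EffectSpec.from_predictions(
        predicted.curves,
        amplitude_pct=config.amplitude_pct,
        interaction_scale=config.interaction_scale,
        carryover=config.carryover,
    )
    syn = gen_subject_curves(effects, config.noise, config.n_subjects, s_synth)
    syn_rows = []
    for (subj, roi, cond), curve in syn.items():
        for scan, v in enumerate(curve.values):
            syn_rows.append({"subject": subj, "roi": roi, "condition": cond.label, "scan": scan, "pct": v})
    result.paths["curves_synthetic"] = write_table(pd.DataFrame(syn_rows), out / "curves_synthetic.tsv", meta)
    syn_auc = auc_table(syn)
    result.auc_synthetic = syn_auc
    result.paths["auc_synthetic"] = write_table(syn_auc, out / "auc_synthetic.tsv", meta)

    # --- analyze --------------------------------------------------------
    anova_beh = behavioral_anova(data.responses)
    beh_frames = []
    for task, frame in anova_beh.items():
        if not frame.empty:
            frame = frame.copy()
            frame.insert(0, "task", task)
            beh_frames.append(frame)
    beh = pd.concat(beh_frames, ignore_index=True) if beh_frames else pd.DataFrame()
    result.anova_behavior = anova_beh
    result.paths["anova_behavior"] = write_table(beh, out / "anova_behavior.tsv", meta)
    aov_auc = roi_auc_anova(syn_auc)
    result.anova_auc = aov_auc
    result.paths["anova_auc"] = write_table(aov_auc, out / "anova_auc.tsv", meta)

    # --- report ---------------------------------------------------------
    lines = [
        "tripletask pipeline report",
        f"config_hash: {chash}  seed: {config.seed}",
        f"subjects: {config.n_subjects}  blocks: {config.blocks}",
        "",
    ]
    for roi, info in ROI_MAP.items():
        lines.append(f"== {roi}: {info.region} (BA {info.brodmann}, MNI {info.mni}) ==")
        for lis in (False, True):
            cells = {
                (c.subtraction, c.text_entry): auc(predicted.curves[(roi, c)])
                for c in CONDITIONS
                if c.listening == lis and not c.only_listening
            }
            pred_contrast = (
                cells[("hard", "hard")] - cells[("hard", "easy")] - cells[("easy", "hard")] + cells[("easy", "easy")]
            )
            mcells = syn_auc[(syn_auc.roi == roi) & (syn_auc.listening == lis) & (syn_auc.subtraction != "absent")]
            est, _ = interaction_contrast(mcells, "auc")
            stratum = "with listening" if lis else "without listening"
            denom = max(abs(v) for v in cells.values()) or 1.0
            lines.append(
                f"  [{stratum}] predicted interaction: {_effect_direction(pred_contrast / denom, 1e-3)} "
                f"({pred_contrast:.3f} a.u.)  measured interaction: {_effect_direction(est, 1e-6)} ({est:.4f} %-scans)"
            )
        only = auc(predicted.curves[(roi, Condition("absent", "absent", True))])
        lines.append(f"  only-listening predicted AUC: {only:.3f} a.u.")
        aroi = aov_auc[aov_auc.roi == roi] if not aov_auc.empty else pd.DataFrame()
        for _, row in aroi.iterrows():
            stratum = "with listening" if row.listening else "without listening"
            lines.append(
                f"  ANOVA [{stratum}] {row.effect}: F(1,{row.df2}) = {row.F:.2f}, p = {row.p:.4f}, eta_p2 = {row.eta_p2:.2f}"
            )
        lines.append("")
    result.report = "\n".join(lines)
    (out / "report.txt").write_text(result.report)
    result.paths["report"] = out / "report.txt"
    log.info("pipeline done: %d outputs in %s", len(result.paths), out)
    return result
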