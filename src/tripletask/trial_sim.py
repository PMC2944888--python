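"""Trial and session assembly for the 2x2x2+1 design.

A trial: difficulty cue 5 s, fixation 1 s, then the tasks start (the task
onset falls on a scan boundary, TR = 2 s).  The participant always starts
with the subtraction task and alternates digit, letter, ... until 10
digits and 10 letters are entered; a 3 s feedback screen follows.  In the
listening conditions a story plays from task onset.  Trials are separated
by 13-17 s inter-trial intervals.

Response times follow the behavioural definitions: a text-entry RT is the
time from entering a digit to entering a letter, a subtraction RT the time
from entering a letter to entering a digit; the first response of each
task in a trial is flagged so it can be excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .engine import DemandTrace, DeadlockError, run_threads
from .task_models import (
    StepTimings,
    SubtractionProblem,
    TextEntryStimulus,
    TrialContext,
    WordStream,
    aural_intervals,
    gen_subtraction,
    gen_textentry,
    gen_wordstream,
    listening_thread,
    sample_story_length_ms,
    subtraction_thread,
    textentry_thread,
)

__all__ = [
    "Condition",
    "CONDITIONS",
    "TASK_CONDITIONS",
    "TrialParams",
    "TrialTimeline",
    "TrialStimuli",
    "TrialResult",
    "gen_stimuli",
    "simulate_trial",
    "simulate_experiment",
    "ExperimentData",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the design: subtraction/text-entry difficulty (or
    ``absent`` for only-listening) and whether the listening task runs."""

    subtraction: str  # easy | hard | absent
    text_entry: str  # easy | hard | absent
    listening: bool

    def __post_init__(self) -> None:
        if self.subtraction not in ("easy", "hard", "absent"):
            raise ValueError(f"bad subtraction level {self.subtraction!r}")
        if self.text_entry not in ("easy", "hard", "absent"):
            raise ValueError(f"bad text_entry level {self.text_entry!r}")
        if (self.subtraction == "absent") != (self.text_entry == "absent"):
            raise ValueError("tasks are either both present or both absent")
        if self.subtraction == "absent" and not self.listening:
            raise ValueError("the no-task cell is the only-listening condition")

    @property
    def only_listening(self) -> bool:
        return self.subtraction == "absent"

    @property
    def label(self) -> str:
        if self.only_listening:
            return "only-listening"
        core = f"{self.subtraction}-{self.text_entry}"
        return core + ("+listening" if self.listening else "")


#: the nine cells of the design
CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(s, t, lis)
    for lis in (False, True)
    for s in ("easy", "hard")
    for t in ("easy", "hard")
) + (Condition("absent", "absent", True),)

#: the four task cells without listening (the 2x2 core)
TASK_CONDITIONS: tuple[Condition, ...] = tuple(
    c for c in CONDITIONS if not c.listening and not c.only_listening
)


@dataclass(frozen=True)
class TrialParams:
    timings: StepTimings = StepTimings()
    p_wrong_state: float = 0.05
    tr_ms: float = 2000.0
    cue_ms: float = 5000.0
    fixation_ms: float = 1000.0
    feedback_ms: float = 3000.0
    iti_range_ms: tuple[float, float] = (13_000.0, 17_000.0)
    word_gap_ms: float = 359.0
    word_gap_sd_ms: float = 30.0

    @property
    def task_onset_ms(self) -> float:
        # cue (5 s) + fixation (1 s); both multiples of the TR, so the
        # task onset is synchronized with a volume acquisition
        return self.cue_ms + self.fixation_ms


@dataclass(frozen=True)
class TrialTimeline:
    cue_onset_ms: float
    task_onset_ms: float
    feedback_onset_ms: float
    question_onset_ms: float | None
    iti_ms: float
    tr_ms: float = 2000.0

    def __post_init__(self) -> None:
        if self.cue_onset_ms % self.tr_ms or self.task_onset_ms % self.tr_ms:
            raise ValueError("cue and task onsets must fall on scan boundaries")
        if not (13_000.0 <= self.iti_ms <= 17_000.0):
            raise ValueError("iti must be within 13-17 s")


@dataclass(frozen=True)
class TrialStimuli:
    problem: SubtractionProblem | None
    textentry: TextEntryStimulus | None
    stream: WordStream | None


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def gen_stimuli(condition: Condition, seed, params: TrialParams = TrialParams()) -> TrialStimuli:
    """Seeded stimuli for one trial of the given condition."""
    ss = _as_seedseq(seed)
    s_prob, s_text, s_story = ss.spawn(3)
    problem = textstim = stream = None
    if not condition.only_listening:
        problem = gen_subtraction(condition.subtraction, s_prob)
        textstim = gen_textentry(condition.text_entry, s_text)
    if condition.listening:
        rng = np.random.default_rng(s_story)
        dur = sample_story_length_ms(rng)
        stream = gen_wordstream(
            rng, duration_ms=dur, mean_gap_ms=params.word_gap_ms, gap_sd_ms=params.word_gap_sd_ms
        )
    return TrialStimuli(problem, textstim, stream)


@dataclass(frozen=True)
class TrialResult:
    condition: Condition
    rts_ms: dict[str, list[float]]  # task -> per-response RT
    correct: dict[str, list[bool]]
    response_times_ms: dict[str, list[float]]  # absolute, from trial start
    swap_count: int
    n_words: int
    n_missed_words: int
    feedback_onset_ms: float
    trial_length_ms: float


def _round_to_grid(x: float, step: float, rng_low: float, rng_high: float) -> float:
    snapped = round(x / step) * step
    return min(max(snapped, math.ceil(rng_low / step) * step), math.floor(rng_high / step) * step)


def simulate_trial(
    condition: Condition,
    stimuli: TrialStimuli,
    params: TrialParams = TrialParams(),
    seed=0,
) -> tuple[TrialResult, DemandTrace, TrialTimeline]:
    """Run one trial; the returned demand trace is on the trial clock
    (0 = cue onset, task onset at 6 s) and extends to the later of task
    feedback and story end."""
    if condition.only_listening != (stimuli.problem is None):
        raise ValueError("stimuli do not match condition")
    if condition.listening != (stimuli.stream is not None):
        raise ValueError("stimuli do not match condition")

    ss = _as_seedseq(seed)
    s_model, s_iti = ss.spawn(2)
    ctx = TrialContext.make(
        timings=params.timings,
        p_wrong_state=params.p_wrong_state,
        rng=np.random.default_rng(s_model),
    )
    programs = []
    if not condition.only_listening:
        programs.append(subtraction_thread(stimuli.problem, ctx))
        programs.append(textentry_thread(stimuli.textentry, ctx))
    if condition.listening:
        programs.append(listening_thread(stimuli.stream, ctx))

    trace = run_threads(programs, condition=condition)

    onset = params.task_onset_ms
    trace = trace.shifted(onset)
    if stimuli.stream is not None:
        aural = [
            (s + onset, e + onset)
            for s, e in aural_intervals(stimuli.stream, ctx.missed_words, params.timings)
        ]
        trace.intervals["aural"] = aural
        story_end = aural[-1][1]
    else:
        story_end = 0.0

    # responses and RTs (alternation: digit, letter, digit, ...)
    resp_t: dict[str, list[float]] = {"subtraction": [], "text_entry": []}
    correct: dict[str, list[bool]] = {"subtraction": [], "text_entry": []}
    for r in ctx.responses:
        resp_t[r.task].append(r.time_ms + onset)
        correct[r.task].append(r.correct)
    rts: dict[str, list[float]] = {"subtraction": [], "text_entry": []}
    if not condition.only_listening:
        sub_t, te_t = resp_t["subtraction"], resp_t["text_entry"]
        for i, t_digit in enumerate(sub_t):
            prev = te_t[i - 1] if i > 0 else onset
            rts["subtraction"].append(t_digit - prev)
        for i, t_letter in enumerate(te_t):
            rts["text_entry"].append(t_letter - sub_t[i])
        task_end = max(sub_t[-1], te_t[-1])
        feedback_onset = task_end
    else:
        feedback_onset = story_end

    trial_length = max(feedback_onset + params.feedback_ms, story_end)
    trace.trial_length_ms = trial_length

    question_onset = None
    if condition.listening:
        question_onset = max(feedback_onset + params.feedback_ms, story_end)

    iti_rng = np.random.default_rng(s_iti)
    iti = _round_to_grid(
        iti_rng.uniform(*params.iti_range_ms), params.tr_ms, *params.iti_range_ms
    )
    timeline = TrialTimeline(
        cue_onset_ms=0.0,
        task_onset_ms=onset,
        feedback_onset_ms=feedback_onset,
        question_onset_ms=question_onset,
        iti_ms=iti,
        tr_ms=params.tr_ms,
    )
    result = TrialResult(
        condition=condition,
        rts_ms=rts,
        correct=correct,
        response_times_ms=resp_t,
        swap_count=ctx.swap_count,
        n_words=stimuli.stream.n_words if stimuli.stream else 0,
        n_missed_words=len(ctx.missed_words),
        feedback_onset_ms=feedback_onset,
        trial_length_ms=trial_length,
    )
    return result, trace, timeline


@dataclass
class ExperimentData:
    trials: pd.DataFrame
    responses: pd.DataFrame
    params: TrialParams
    seed: int


def simulate_experiment(
    n_subjects: int,
    blocks: int = 10,
    params: TrialParams = TrialParams(),
    seed: int = 0,
    trace_hook: Callable[[int, Condition, DemandTrace, TrialResult, TrialTimeline], None] | None = None,
) -> ExperimentData:
    """Simulate ``n_subjects`` participants, each running ``blocks`` blocks
    of the nine conditions in randomized order (10 blocks = the full
    90-trial experiment).  Seeds derive deterministically from the master
    seed.  ``trace_hook`` receives every trial's demand trace as it is
    produced (used by the prediction pipeline to aggregate demand without
    retaining 900 traces)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)

    trial_rows = []
    resp_rows = []
    for subj, subj_ss in enumerate(subject_seeds):
        order_rng = np.random.default_rng(subj_ss.spawn(1)[0])
        trial_idx = 0
        for block in range(blocks):
            order = order_rng.permutation(len(CONDITIONS))
            for k in order:
                cond = CONDITIONS[int(k)]
                t_ss = subj_ss.spawn(1)[0]
                stim_seed, run_seed = t_ss.spawn(2)
                stimuli = gen_stimuli(cond, stim_seed, params)
                result, trace, timeline = simulate_trial(cond, stimuli, params, run_seed)
                if trace_hook is not None:
                    trace_hook(subj, cond, trace, result, timeline)
                trial_rows.append(
                    {
                        "subject": subj,
                        "block": block,
                        "trial": trial_idx,
                        "subtraction": cond.subtraction,
                        "text_entry": cond.text_entry,
                        "listening": cond.listening,
                        "condition": cond.label,
                        "swap_count": result.swap_count,
                        "n_words": result.n_words,
                        "n_missed_words": result.n_missed_words,
                        "feedback_onset_ms": result.feedback_onset_ms,
                        "trial_length_ms": result.trial_length_ms,
                        "iti_ms": timeline.iti_ms,
                    }
                )
                for task in ("subtraction", "text_entry"):
                    for i, rt in enumerate(result.rts_ms[task]):
                        resp_rows.append(
                            {
                                "subject": subj,
                                "block": block,
                                "trial": trial_idx,
                                "subtraction": cond.subtraction,
                                "text_entry": cond.text_entry,
                                "listening": cond.listening,
                                "condition": cond.label,
                                "task": task,
                                "response_index": i,
                                "rt_ms": rt,
                                "correct": result.correct[task][i],
                                "first_response": i == 0,
                            }
                        )
                trial_idx += 1
    trials = pd.DataFrame(trial_rows)
    responses = pd.DataFrame(
        resp_rows,
        columns=[
            "subject", "block", "trial", "subtraction", "text_entry", "listening",
            "condition", "task", "response_index", "rt_ms", "correct", "first_response",
        ],
    )
    return ExperimentData(trials=trials, responses=responses, params=params, seed=seed)
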