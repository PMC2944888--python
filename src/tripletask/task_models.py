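"""The three task threads, the problem-state slot, and stimulus generators.

The triple task pairs a 10-column subtraction task with a 10-letter text
entry task (responses strictly alternate digit, letter, digit, ...) and,
on half the trials, a concurrent listening-comprehension task.  Each task
has an easy version that needs no intermediate representation and a hard
version that does: hard subtraction problems require exactly six borrow
operations (a "borrowing in progress" flag must be remembered), and hard
text entry shows the word only once, so word and position must be
remembered.  Those intermediate representations live in a single-slot
problem-state resource: installing or updating a chunk costs 200 ms, and
when two tasks both need the slot the current occupant has to be suspended
to declarative memory and the other task's state retrieved back — the
problem-state bottleneck.  Retrieving a suspended state can, with
probability ``p_wrong_state``, return a stale state, which makes the next
affected response incorrect.

The listening thread perceives each word aurally and then performs four
procedural steps and two declarative retrievals per word (320 ms of
central processing at the default timings, enough to keep up with the
359 ms/word speech rate).  A word is dropped ("missed") when its central
processing cannot start before the following word has been perceived,
which happens when the other tasks keep declarative memory busy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .engine import StepRequest, ThreadProgram, WaitFor, WaitUntilTime
from .words import WORDS_10

__all__ = [
    "StepTimings",
    "SubtractionProblem",
    "TextEntryStimulus",
    "WordStream",
    "PSChunk",
    "ProblemStateSlot",
    "DeclarativeStore",
    "SwapResult",
    "swap_problem_state",
    "TrialContext",
    "gen_subtraction",
    "gen_textentry",
    "gen_wordstream",
    "sample_story_length_ms",
    "subtraction_thread",
    "textentry_thread",
    "listening_thread",
    "aural_intervals",
]


@dataclass(frozen=True)
class StepTimings:
    """Default durations of the elementary module actions (ms).

    The problem-state update cost of 200 ms is the architecture's
    established estimate; the listening thread's four procedural steps and
    two retrievals must add up to the ~320 ms per-word central processing
    cost, which fixes 4*50 + 2*60.  The remaining values are conventional
    module-action durations and are all configuration-exposed.
    """

    procedural_ms: float = 50.0
    visual_encode_ms: float = 85.0
    retrieval_ms: float = 60.0
    manual_click_ms: float = 250.0
    ps_update_ms: float = 200.0
    #: aural demand of a word that is never centrally processed
    aural_initial_ms: float = 85.0


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubtractionProblem:
    """A 10-column subtraction problem; digit strings are most-significant
    first, while ``borrow_columns`` indexes columns from the right (0 =
    units column)."""

    upper: str
    lower: str
    answer: str
    difficulty: str
    borrow_columns: frozenset[int]

    def digit(self, which: str, col: int) -> int:
        """Digit of ``upper``/``lower``/``answer`` at right-based column."""
        return int(getattr(self, which)[9 - col])


def gen_subtraction(difficulty: str, seed) -> SubtractionProblem:
    """Generate a seeded subtraction problem.

    Easy: no column requires borrowing (upper digit >= lower digit
    everywhere).  Hard: exactly six of the nine borrow-capable columns
    borrow.  Both versions produce 10-digit answers.
    """
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"difficulty must be easy|hard, got {difficulty!r}")
    rng = np.random.default_rng(seed)
    if difficulty == "hard":
        borrows = frozenset(int(c) for c in rng.choice(9, size=6, replace=False))
    else:
        borrows = frozenset()

    upper: list[int] = [0] * 10  # index = right-based column
    lower: list[int] = [0] * 10
    answer: list[int] = [0] * 10
    for c in range(10):
        b_in = 1 if (c - 1) in borrows else 0
        pairs = []
        for u in range(10):
            for lo in range(10):
                d = u - b_in - lo
                if c in borrows:
                    if d >= 0:
                        continue
                    d += 10
                else:
                    if d < 0:
                        continue
                if c == 9 and (u == 0 or lo == 0 or d == 0):
                    # leftmost column: 10-digit operands and answer
                    continue
                pairs.append((u, lo, d))
        u, lo, d = pairs[rng.integers(len(pairs))]
        upper[c], lower[c], answer[c] = u, lo, d

    def s(digits: list[int]) -> str:
        return "".join(str(digits[9 - c]) for c in range(10))

    return SubtractionProblem(s(upper), s(lower), s(answer), difficulty, borrows)


@dataclass(frozen=True)
class TextEntryStimulus:
    word: str
    presented_sequence: tuple[str, ...]
    difficulty: str


def _scramble(letters: Sequence[str], rng: np.random.Generator, tries: int = 200):
    """Permutation with no letter equal to its predecessor, or None."""
    letters = list(letters)
    for _ in range(tries):
        perm = list(rng.permutation(letters))
        if all(a != b for a, b in zip(perm, perm[1:])):
            return tuple(perm)
    return None


def gen_textentry(
    difficulty: str,
    seed,
    wordlist: Sequence[str] = WORDS_10,
    max_word_resamples: int = 20,
) -> TextEntryStimulus:
    """Pick a 10-letter word; hard keeps letter order, easy scrambles it
    under the constraint that a letter never appears twice in a row."""
    if difficulty not in ("easy", "hard"):
        raise ValueError(f"difficulty must be easy|hard, got {difficulty!r}")
    rng = np.random.default_rng(seed)
    for _ in range(max_word_resamples):
        word = str(wordlist[rng.integers(len(wordlist))])
        if len(word) != 10:
            raise ValueError(f"wordlist entries must have 10 letters: {word!r}")
        if difficulty == "hard":
            return TextEntryStimulus(word, tuple(word), difficulty)
        seq = _scramble(word, rng)
        if seq is not None:
            return TextEntryStimulus(word, seq, difficulty)
    raise RuntimeError("could not scramble any sampled word without adjacent repeats")


@dataclass(frozen=True)
class WordStream:
    """Arrival schedule of the spoken words of one story (ms from story
    onset)."""

    arrival_times_ms: tuple[float, ...]
    mean_gap_ms: float

    @property
    def n_words(self) -> int:
        return len(self.arrival_times_ms)

    def __post_init__(self) -> None:
        a = self.arrival_times_ms
        if any(t2 <= t1 for t1, t2 in zip(a, a[1:])):
            raise ValueError("arrival times must be strictly increasing")


def sample_story_length_ms(
    rng: np.random.Generator,
    mean_ms: float = 52_600.0,
    sd_ms: float = 9_700.0,
    lo_ms: float = 26_000.0,
    hi_ms: float = 72_000.0,
) -> float:
    """Story duration: truncated normal matching the stimulus set
    (M = 52.6 s, SD = 9.7 s, range 26-72 s)."""
    while True:
        x = rng.normal(mean_ms, sd_ms)
        if lo_ms <= x <= hi_ms:
            return float(x)


def gen_wordstream(
    seed,
    duration_ms: float | None = None,
    n_words: int | None = None,
    mean_gap_ms: float = 359.0,
    gap_sd_ms: float = 30.0,
) -> WordStream:
    """Word arrivals at the speech rate (~359 ms/word), jittered.

    Provide either a total ``duration_ms`` (words fill the story) or an
    explicit ``n_words``.
    """
    if (duration_ms is None) == (n_words is None):
        raise ValueError("give exactly one of duration_ms or n_words")
    rng = np.random.default_rng(seed)

    def gap() -> float:
        return float(np.clip(rng.normal(mean_gap_ms, gap_sd_ms), 200.0, 600.0))

    arrivals = [0.0]
    if n_words is not None:
        for _ in range(n_words - 1):
            arrivals.append(arrivals[-1] + gap())
    else:
        while True:
            nxt = arrivals[-1] + gap()
            if nxt + mean_gap_ms > duration_ms:
                break
            arrivals.append(nxt)
    return WordStream(tuple(arrivals), mean_gap_ms)


# ---------------------------------------------------------------------------
# problem-state slot and declarative store
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSChunk:
    """One problem-state chunk: which thread owns it and its content.

    ``stale`` marks a chunk restored from memory that is actually an
    older, incorrect state; the owning thread's next response will be
    wrong.
    """

    owner: str
    content: tuple[tuple[str, object], ...]
    stale: bool = False

    @staticmethod
    def make(owner: str, content: dict | None = None, stale: bool = False) -> "PSChunk":
        return PSChunk(owner, tuple(sorted((content or {}).items())), stale)

    def get(self, key: str, default=None):
        return dict(self.content).get(key, default)


@dataclass
class ProblemStateSlot:
    """Single-chunk store: holds at most one problem state at a time."""

    occupant: PSChunk | None = None
    update_cost_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.update_cost_ms <= 0:
            raise ValueError("update_cost_ms must be > 0")


@dataclass
class DeclarativeStore:
    """Simplified declarative memory: fact retrievals take a fixed time;
    suspended problem states are held per owning thread."""

    retrieval_time_ms: float = 60.0
    p_wrong_state: float = 0.05
    suspended: dict[str, PSChunk] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_wrong_state <= 1.0):
            raise ValueError("p_wrong_state must be in [0, 1]")
        if self.retrieval_time_ms <= 0:
            raise ValueError("retrieval_time_ms must be > 0")


@dataclass(frozen=True)
class SwapResult:
    delay_ms: float
    restored: PSChunk
    swapped: bool  # a non-empty slot's occupant was replaced
    retrieved: bool  # a suspended state was retrieved from memory
    wrong: bool  # the retrieved state was an older, incorrect one
    fresh: bool  # no suspended state existed; a fresh chunk was installed


def swap_problem_state(
    slot: ProblemStateSlot,
    owner: str,
    store: DeclarativeStore,
    rng: np.random.Generator,
    fresh_content: dict | None = None,
) -> SwapResult:
    """Make the slot hold ``owner``'s problem state, swapping if needed.

    If the occupant already belongs to ``owner`` this is free.  Otherwise
    the occupant (if any) is suspended to declarative memory and the
    needed state is retrieved back (one declarative retrieval, wrong with
    probability ``p_wrong_state``) and installed at the update cost; if no
    suspended state exists a fresh one is installed (update cost only) and
    flagged ``fresh``.  Total delay = retrieval_time + update_cost for a
    retrieved state.
    """
    occ = slot.occupant
    if occ is not None and occ.owner == owner:
        return SwapResult(0.0, occ, False, False, False, False)
    swapped = occ is not None
    if occ is not None:
        store.suspended[occ.owner] = occ
    if owner in store.suspended:
        chunk = store.suspended.pop(owner)
        wrong = bool(store.p_wrong_state > 0 and rng.random() < store.p_wrong_state)
        chunk = replace(chunk, stale=wrong)
        delay = store.retrieval_time_ms + slot.update_cost_ms
        retrieved, fresh = True, False
    else:
        chunk = PSChunk.make(owner, fresh_content)
        wrong = False
        delay = slot.update_cost_ms
        retrieved, fresh = False, True
    slot.occupant = chunk
    return SwapResult(delay, chunk, swapped, retrieved, wrong, fresh)


# ---------------------------------------------------------------------------
# trial context shared by the threads
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Response:
    task: str
    index: int
    time_ms: float
    correct: bool


@dataclass
class TrialContext:
    """Mutable state shared by the threads of one trial: the slot, the
    declarative store, the turn token of the forced task alternation, and
    the behavioural log."""

    slot: ProblemStateSlot
    store: DeclarativeStore
    timings: StepTimings
    rng: np.random.Generator
    turn: str = "subtraction"
    responses: list[Response] = field(default_factory=list)
    swap_count: int = 0
    missed_words: list[int] = field(default_factory=list)
    pending_wrong: dict[str, bool] = field(default_factory=dict)

    @staticmethod
    def make(
        timings: StepTimings | None = None,
        p_wrong_state: float = 0.05,
        rng: np.random.Generator | int | None = None,
    ) -> "TrialContext":
        t = timings or StepTimings()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        return TrialContext(
            slot=ProblemStateSlot(update_cost_ms=t.ps_update_ms),
            store=DeclarativeStore(retrieval_time_ms=t.retrieval_ms, p_wrong_state=p_wrong_state),
            timings=t,
            rng=rng,
        )

    def record(self, task: str, index: int, time_ms: float, correct: bool) -> None:
        self.responses.append(Response(task, index, time_ms, correct))


def _acquire_ps(ctx: TrialContext, owner: str, fresh_content: dict | None = None):
    """Ensure the slot holds ``owner``'s chunk, yielding the swap's
    resource steps; returns the SwapResult."""
    res = swap_problem_state(ctx.slot, owner, ctx.store, ctx.rng, fresh_content)
    if res.swapped:
        ctx.swap_count += 1
    if res.retrieved:
        yield StepRequest("declarative", ctx.store.retrieval_time_ms, f"{owner}:restore-problem-state")
    if res.retrieved or res.fresh:
        yield StepRequest("problem_state", ctx.slot.update_cost_ms, f"{owner}:install-problem-state")
    if res.wrong:
        ctx.pending_wrong[owner] = True
    return res


def _write_ps(ctx: TrialContext, owner: str, content: dict, tag: str):
    """Write/overwrite the slot with ``owner``'s chunk (one update step);
    suspends (and counts a swap for) another thread's occupant."""
    occ = ctx.slot.occupant
    if occ is not None and occ.owner != owner:
        ctx.store.suspended[occ.owner] = occ
        ctx.swap_count += 1
    yield StepRequest("problem_state", ctx.slot.update_cost_ms, tag)
    ctx.slot.occupant = PSChunk.make(owner, content)


# ---------------------------------------------------------------------------
# thread programs
# ---------------------------------------------------------------------------


def _subtraction_body(problem: SubtractionProblem, ctx: TrialContext) -> Iterator:
    t = ctx.timings
    hard = problem.difficulty == "hard"
    for c in range(10):  # right to left
        yield WaitFor(lambda: ctx.turn == "subtraction", "turn=subtraction")
        borrow_in = False
        if hard:
            # the slot is checked at every resume; first resume installs
            # a fresh "no borrowing in progress" state
            res = yield from _acquire_ps(ctx, "subtraction", {"borrow": False})
            borrow_in = bool(res.restored.get("borrow", False))
            if borrow_in:
                yield StepRequest("procedural", t.procedural_ms, f"sub:col{c}:decrement-upper")
        yield StepRequest("visual", t.visual_encode_ms, f"sub:col{c}:encode-digits")
        yield StepRequest("declarative", t.retrieval_ms, f"sub:col{c}:fact-retrieval")
        borrow_out = c in problem.borrow_columns
        if hard and borrow_out:
            # negative outcome: look at the digits again, add ten,
            # retrieve the new fact, and note the borrowing in progress
            yield StepRequest("visual", t.visual_encode_ms, f"sub:col{c}:reencode-digits")
            yield StepRequest("procedural", t.procedural_ms, f"sub:col{c}:add-ten")
            yield StepRequest("declarative", t.retrieval_ms, f"sub:col{c}:fact-retrieval-2")
            yield from _write_ps(ctx, "subtraction", {"borrow": True}, f"sub:col{c}:store-borrow")
        elif hard and borrow_in:
            yield from _write_ps(ctx, "subtraction", {"borrow": False}, f"sub:col{c}:clear-borrow")
        g = yield StepRequest("manual", t.manual_click_ms, f"sub:col{c}:click-digit")
        correct = not ctx.pending_wrong.pop("subtraction", False)
        ctx.record("subtraction", c, g.end_ms, correct)
        ctx.turn = "text_entry"


def subtraction_thread(problem: SubtractionProblem, ctx: TrialContext) -> ThreadProgram:
    """Per column: encode the digits, retrieve the fact, click the answer;
    the hard version additionally handles borrowings through the problem
    state (see module docstring)."""
    return ThreadProgram("subtraction", _subtraction_body(problem, ctx))


def _textentry_body(stim: TextEntryStimulus, ctx: TrialContext) -> Iterator:
    t = ctx.timings
    hard = stim.difficulty == "hard"
    for i in range(10):
        yield WaitFor(lambda: ctx.turn == "text_entry", "turn=text_entry")
        if hard:
            if i == 0:
                yield StepRequest("visual", t.visual_encode_ms, "te:encode-word")
            has_chunk = (
                (ctx.slot.occupant is not None and ctx.slot.occupant.owner == "text_entry")
                or "text_entry" in ctx.store.suspended
            )
            if has_chunk:
                yield from _acquire_ps(ctx, "text_entry")
            yield StepRequest("declarative", t.retrieval_ms, f"te:pos{i}:spelling-retrieval")
        else:
            yield StepRequest("visual", t.visual_encode_ms, f"te:pos{i}:encode-letter")
        g = yield StepRequest("manual", t.manual_click_ms, f"te:pos{i}:click-letter")
        correct = not ctx.pending_wrong.pop("text_entry", False)
        ctx.record("text_entry", i, g.end_ms, correct)
        if hard:
            yield from _write_ps(
                ctx, "text_entry", {"word": stim.word, "pos": i + 1}, f"te:pos{i}:advance-position"
            )
        ctx.turn = "subtraction"


def textentry_thread(stim: TextEntryStimulus, ctx: TrialContext) -> ThreadProgram:
    """Easy: encode the shown letter and click it.  Hard: consult the
    (word, position) problem state, retrieve the next letter's spelling
    fact, click, and advance the position in the slot."""
    return ThreadProgram("text_entry", _textentry_body(stim, ctx))


def _perception_ends(stream: WordStream) -> list[float]:
    a = stream.arrival_times_ms
    return [a[i + 1] if i + 1 < len(a) else a[i] + stream.mean_gap_ms for i in range(len(a))]


def _listening_body(stream: WordStream, ctx: TrialContext) -> Iterator:
    t = ctx.timings
    ends = _perception_ends(stream)
    n = stream.n_words
    for i in range(n):
        yield WaitUntilTime(ends[i])
        deadline = ends[i + 1] if i + 1 < n else None
        g = yield StepRequest(
            "declarative", t.retrieval_ms, f"listen:word{i}:lexical-retrieval", deadline_ms=deadline
        )
        if not g.granted:
            ctx.missed_words.append(i)
            continue
        yield StepRequest("procedural", t.procedural_ms, f"listen:word{i}:encode")
        yield StepRequest("procedural", t.procedural_ms, f"listen:word{i}:attach")
        yield StepRequest("declarative", t.retrieval_ms, f"listen:word{i}:syntax-retrieval")
        yield StepRequest("procedural", t.procedural_ms, f"listen:word{i}:integrate")
        yield StepRequest("procedural", t.procedural_ms, f"listen:word{i}:wrap-up")


def listening_thread(stream: WordStream, ctx: TrialContext) -> ThreadProgram:
    """Per word: after the word is perceived, four procedural steps and
    two declarative retrievals (320 ms central processing at defaults).
    A word whose central processing cannot start before the next word has
    been perceived is missed and produces no further demand."""
    return ThreadProgram("listening", _listening_body(stream, ctx))


def aural_intervals(
    stream: WordStream, missed: Sequence[int], timings: StepTimings
) -> list[tuple[float, float]]:
    """Aural-module busy intervals for one story.

    A processed word occupies the aural module for its full duration; a
    missed word only for a short initial perception.  The aural module is
    never contested by the other tasks, so these intervals are derived
    from the schedule rather than scheduled through the engine.
    """
    ends = _perception_ends(stream)
    missed_set = set(missed)
    out = []
    for i, a in enumerate(stream.arrival_times_ms):
        end = min(a + timings.aural_initial_ms, ends[i]) if i in missed_set else ends[i]
        out.append((a, end))
    return out
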