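"""Discrete-event core for threaded cognition.

Several task threads are active at once, but every cognitive resource
(procedural, declarative, problem state, visual, aural, manual) is serial:
it can serve only one request at a time.  The engine advances simulated
time, arbitrates between threads that contend for the same resource, and
logs per-resource busy intervals, which together form the demand trace
that downstream modules convolve into BOLD predictions.

Threads are Python generators that yield :class:`StepRequest` (use a
resource for a fixed duration), :class:`WaitUntilTime` (sleep until a
wall-clock point, e.g. a word arrival) or :class:`WaitFor` (block until a
shared predicate turns true, e.g. a turn-taking token).  After a granted
step completes, the engine sends a :class:`Grant` with the realised start
and end times back into the generator.

Time is kept internally as integer microseconds so that traces are exactly
reproducible; the public interface is in milliseconds.
"""

from __future__ import annotations

from collections.abc import Callable, Generator, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

RESOURCES = (
    "procedural",
    "declarative",
    "problem_state",
    "visual",
    "aural",
    "manual",
)

#: canonical arbitration order of the task threads (fixed tie-break)
THREAD_ORDER = ("subtraction", "text_entry", "listening")

_US_PER_MS = 1000


class DeadlockError(RuntimeError):
    """No thread can progress and none is finished."""

    def __init__(self, message: str, resource: str | None = None):
        super().__init__(message)
        self.resource = resource


@dataclass(frozen=True)
class StepRequest:
    """A thread's request to occupy one resource for a fixed duration.

    ``deadline_ms``, when given, cancels the request if it cannot *start*
    strictly before that time (the grant then comes back with
    ``granted=False``); this implements the listening thread's word-miss
    rule.
    """

    resource: str
    duration_ms: float
    tag: str
    deadline_ms: float | None = None

    def __post_init__(self) -> None:
        if self.resource not in RESOURCES:
            raise ValueError(f"unknown resource {self.resource!r}")
        if self.duration_ms <= 0:
            raise ValueError("step duration must be > 0")
        if not self.tag:
            raise ValueError("step tag must be non-empty")


@dataclass(frozen=True)
class WaitUntilTime:
    t_ms: float


@dataclass(frozen=True)
class WaitFor:
    predicate: Callable[[], bool]
    label: str = "condition"


@dataclass(frozen=True)
class Grant:
    """Outcome of a StepRequest, sent back into the thread generator."""

    granted: bool
    start_ms: float
    end_ms: float


ThreadBody = Generator[StepRequest | WaitUntilTime | WaitFor, "Grant | None", None]


@dataclass
class ThreadProgram:
    """A named thread: an id used for arbitration plus its step generator."""

    id: str
    body: ThreadBody


@dataclass(frozen=True)
class TraceEvent:
    resource: str
    start_ms: float
    end_ms: float
    tag: str
    thread: str


@dataclass
class DemandTrace:
    """Per-resource busy intervals over one trial.

    Intervals are half-open ``[start, end)`` in ms from trial start,
    non-overlapping and time-ordered within each resource.
    """

    intervals: dict[str, list[tuple[float, float]]]
    events: list[TraceEvent]
    trial_length_ms: float
    condition: object | None = None

    def busy_ms(self, resource: str) -> float:
        return sum(e - s for s, e in self.intervals.get(resource, []))

    def shifted(self, offset_ms: float) -> "DemandTrace":
        return DemandTrace(
            intervals={
                r: [(s + offset_ms, e + offset_ms) for s, e in iv]
                for r, iv in self.intervals.items()
            },
            events=[
                TraceEvent(ev.resource, ev.start_ms + offset_ms, ev.end_ms + offset_ms, ev.tag, ev.thread)
                for ev in self.events
            ],
            trial_length_ms=self.trial_length_ms + offset_ms,
            condition=self.condition,
        )

    def clipped(self, t_max_ms: float) -> "DemandTrace":
        """Drop demand beyond ``t_max_ms`` (truncating straddling intervals)."""
        out: dict[str, list[tuple[float, float]]] = {}
        for r, iv in self.intervals.items():
            out[r] = [(s, min(e, t_max_ms)) for s, e in iv if s < t_max_ms]
        ev = [
            TraceEvent(e.resource, e.start_ms, min(e.end_ms, t_max_ms), e.tag, e.thread)
            for e in self.events
            if e.start_ms < t_max_ms
        ]
        return DemandTrace(out, ev, t_max_ms, self.condition)


def arbitrate(
    pending: Sequence[str],
    last_served: Mapping[str, float] | None = None,
    order: Sequence[str] = THREAD_ORDER,
) -> str:
    """Pick which of the pending threads gets a contested resource.

    Policy: least recently served on that resource wins; never-served
    threads count as served at -inf.  Ties break by the fixed thread order
    (subtraction < text_entry < listening), then lexicographically for ids
    outside that order.
    """
    if not pending:
        raise ValueError("no pending threads")
    last_served = last_served or {}

    def key(tid: str):
        rank = order.index(tid) if tid in order else len(order)
        return (last_served.get(tid, float("-inf")), rank, tid)

    return min(pending, key=key)


@dataclass
class _ThreadState:
    program: ThreadProgram
    pending: StepRequest | WaitUntilTime | WaitFor | None = None
    resume_at: int = 0  # µs time at which the generator may be advanced
    send_value: Grant | None = None
    started: bool = False
    done: bool = False


def _us(ms: float) -> int:
    return round(ms * _US_PER_MS)


def run_threads(
    programs: Iterable[ThreadProgram],
    horizon_ms: float | None = None,
    condition: object | None = None,
) -> DemandTrace:
    """Run thread programs to completion (or ``horizon_ms``) and log demand.

    Returns a :class:`DemandTrace` in which no resource ever serves two
    requests simultaneously.  Deterministic: identical programs yield an
    identical trace.  Raises :class:`DeadlockError` if unfinished threads
    can never progress.
    """
    programs = list(programs)
    if not programs:
        raise ValueError("programs must be non-empty")
    horizon_us = None if horizon_ms is None else _us(horizon_ms)

    threads = [_ThreadState(p) for p in programs]
    busy_until: dict[str, int] = {r: 0 for r in RESOURCES}
    # per-resource map thread-id -> last grant start time (for arbitration)
    last_served: dict[str, dict[str, int]] = {r: {} for r in RESOURCES}
    events: list[tuple[str, int, int, str, str]] = []
    now = 0

    def advance(th: _ThreadState) -> None:
        """Advance the generator to its next yield (or completion)."""
        try:
            if not th.started:
                th.started = True
                item = th.program.body.send(None)
            else:
                item = th.program.body.send(th.send_value)
        except StopIteration:
            th.done = True
            th.pending = None
            return
        th.send_value = None
        th.pending = item

    while True:
        progressed = True
        while progressed:
            progressed = False
            for th in threads:
                if th.done:
                    continue
                if th.pending is None:
                    if th.resume_at <= now:
                        advance(th)
                        progressed = True
                    continue
                item = th.pending
                if isinstance(item, WaitUntilTime):
                    if _us(item.t_ms) <= now:
                        th.pending = None
                        th.resume_at = now
                        progressed = True
                elif isinstance(item, WaitFor):
                    if item.predicate():
                        th.pending = None
                        th.resume_at = now
                        progressed = True
                elif isinstance(item, StepRequest):
                    # expired deadline: the step can no longer start in time
                    if item.deadline_ms is not None and now >= _us(item.deadline_ms):
                        th.pending = None
                        th.resume_at = now
                        th.send_value = Grant(False, now / _US_PER_MS, now / _US_PER_MS)
                        progressed = True
            # grant free resources to waiting threads (one winner each)
            for res in RESOURCES:
                if busy_until[res] > now:
                    continue
                waiters = [
                    th
                    for th in threads
                    if not th.done
                    and isinstance(th.pending, StepRequest)
                    and th.pending.resource == res
                ]
                if not waiters:
                    continue
                by_id = {th.program.id: th for th in waiters}
                winner = by_id[arbitrate(list(by_id), last_served[res])]
                req = winner.pending
                assert isinstance(req, StepRequest)
                start, end = now, now + _us(req.duration_ms)
                busy_until[res] = end
                last_served[res][winner.program.id] = start
                events.append((res, start, end, req.tag, winner.program.id))
                winner.pending = None
                winner.resume_at = end
                winner.send_value = Grant(True, start / _US_PER_MS, end / _US_PER_MS)
                progressed = True

        if all(th.done for th in threads):
            break
        if horizon_us is not None and now >= horizon_us:
            break

        # next event time: generator resumptions, resource releases,
        # timed waits, and request deadlines
        candidates: list[int] = []
        for th in threads:
            if th.done:
                continue
            if th.pending is None:
                candidates.append(th.resume_at)
            elif isinstance(th.pending, WaitUntilTime):
                candidates.append(_us(th.pending.t_ms))
            elif isinstance(th.pending, StepRequest):
                candidates.append(busy_until[th.pending.resource])
                if th.pending.deadline_ms is not None:
                    candidates.append(_us(th.pending.deadline_ms))
        future = [c for c in candidates if c > now]
        if not future:
            blocked = [
                th for th in threads if not th.done and isinstance(th.pending, StepRequest)
            ]
            if blocked:
                res = blocked[0].pending.resource  # type: ignore[union-attr]
                raise DeadlockError(
                    f"deadlock: no thread can progress; blocking resource: {res}",
                    resource=res,
                )
            labels = [
                th.pending.label
                for th in threads
                if not th.done and isinstance(th.pending, WaitFor)
            ]
            raise DeadlockError(
                "deadlock: threads blocked on conditions that can never change: "
                + ", ".join(labels or ["<unknown>"])
            )
        now = min(future)
        if horizon_us is not None:
            now = min(now, horizon_us)

    end_us = max([e for _, _, e, _, _ in events], default=now)
    length_us = end_us if horizon_us is None else min(max(now, end_us), horizon_us)

    intervals: dict[str, list[tuple[float, float]]] = {r: [] for r in RESOURCES}
    trace_events: list[TraceEvent] = []
    for res, s, e, tag, tid in sorted(events, key=lambda x: (x[1], x[0], x[4])):
        e_cl = e if horizon_us is None else min(e, horizon_us)
        if e_cl <= s:
            continue
        intervals[res].append((s / _US_PER_MS, e_cl / _US_PER_MS))
        trace_events.append(TraceEvent(res, s / _US_PER_MS, e_cl / _US_PER_MS, tag, tid))
    return DemandTrace(
        intervals=intervals,
        events=trace_events,
        trial_length_ms=length_us / _US_PER_MS,
        condition=condition,
    )
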