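"""Task-model tests: stimulus invariants against independent oracles,
problem-state swap semantics, and per-thread demand-trace structure."""

from collections import Counter, defaultdict

import numpy as np
import pytest

from tripletask.engine import StepRequest, ThreadProgram, run_threads
from tripletask.task_models import (
    DeclarativeStore,
    ProblemStateSlot,
    StepTimings,
    TrialContext,
    aural_intervals,
    gen_subtraction,
    gen_textentry,
    gen_wordstream,
    listening_thread,
    sample_story_length_ms,
    subtraction_thread,
    swap_problem_state,
    textentry_thread,
)
from tripletask.words import WORDS_10


def count_borrows(upper: str, lower: str):
    """Independent column-subtraction oracle: simulate right-to-left
    borrowing, returning (answer digits, set of borrow columns)."""
    borrow, cols, answer = 0, set(), []
    for c in range(10):
        u, lo = int(upper[9 - c]), int(lower[9 - c])
        d = u - borrow - lo
        if d < 0:
            d += 10
            borrow = 1
            cols.add(c)
        else:
            borrow = 0
        answer.append(d)
    return "".join(str(d) for d in reversed(answer)), cols


class TestSubtractionStimuli:
    @pytest.mark.parametrize("seed", range(8))
    def test_easy_has_no_borrows(self, seed):
        p = gen_subtraction("easy", seed)
        answer, cols = count_borrows(p.upper, p.lower)
        assert cols == set() and p.borrow_columns == frozenset()
        assert answer == p.answer
        assert all(int(u) >= int(lo) for u, lo in zip(p.upper, p.lower))

    @pytest.mark.parametrize("seed", range(8))
    def test_hard_has_exactly_six_borrows(self, seed):
        p = gen_subtraction("hard", seed)
        answer, cols = count_borrows(p.upper, p.lower)
        assert len(cols) == 6 and cols == set(p.borrow_columns)
        assert answer == p.answer
        assert len(p.answer) == 10 and p.answer[0] != "0"
        assert int(p.upper) - int(p.lower) == int(p.answer)

    def test_oracle_classifies_all_larger_digits_as_easy(self):
        _, cols = count_borrows("9999999999", "1111111111")
        assert cols == set()

    def test_seeded_reproducibility(self):
        assert gen_subtraction("hard", 5) == gen_subtraction("hard", 5)


class TestTextEntryStimuli:
    def test_hard_preserves_letter_order(self):
        stim = gen_textentry("hard", 1, ["university"])
        assert stim.presented_sequence == tuple("university")

    @pytest.mark.parametrize("seed", range(10))
    def test_easy_is_permutation_without_adjacent_repeats(self, seed):
        stim = gen_textentry("easy", seed)
        assert sorted(stim.presented_sequence) == sorted(stim.word)
        assert all(a != b for a, b in zip(stim.presented_sequence, stim.presented_sequence[1:]))

    def test_packaged_words_are_ten_letters(self):
        assert all(len(w) == 10 for w in WORDS_10)
        # no letter more than 5 times: the no-adjacent-repeat scramble exists
        assert all(max(Counter(w).values()) <= 5 for w in WORDS_10)


class TestWordStream:
    def test_arrivals_increase_and_match_rate(self):
        ws = gen_wordstream(0, n_words=200)
        gaps = np.diff(ws.arrival_times_ms)
        assert np.all(gaps > 0)
        assert abs(gaps.mean() - 359.0) < 15.0

    def test_story_length_distribution_bounds(self):
        rng = np.random.default_rng(0)
        lengths = [sample_story_length_ms(rng) for _ in range(200)]
        assert all(26_000 <= x <= 72_000 for x in lengths)
        assert 45_000 < np.mean(lengths) < 60_000


class TestProblemStateSwap:
    def test_occupant_already_owned_is_free(self):
        ctx = TrialContext.make(rng=0)
        swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng, {"borrow": False})
        res = swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng)
        assert res.delay_ms == 0.0 and not res.retrieved and not res.swapped

    def test_fresh_install_into_empty_slot_is_not_a_swap(self):
        ctx = TrialContext.make(rng=0)
        res = swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng, {"borrow": False})
        assert res.fresh and not res.swapped
        assert res.delay_ms == ctx.slot.update_cost_ms

    def test_swap_suspends_and_restores_with_full_delay(self):
        ctx = TrialContext.make(p_wrong_state=0.0, rng=0)
        swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng, {"borrow": True})
        swap_problem_state(ctx.slot, "text_entry", ctx.store, ctx.rng, {"pos": 3})
        res = swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng)
        assert res.swapped and res.retrieved and not res.wrong
        assert res.delay_ms == ctx.store.retrieval_time_ms + ctx.slot.update_cost_ms
        assert res.restored.get("borrow") is True

    def test_certain_wrong_state_always_flagged(self):
        ctx = TrialContext.make(p_wrong_state=1.0, rng=0)
        for _ in range(5):
            swap_problem_state(ctx.slot, "subtraction", ctx.store, ctx.rng, {})
            res = swap_problem_state(ctx.slot, "text_entry", ctx.store, ctx.rng, {})
            if res.retrieved:
                assert res.wrong

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            ProblemStateSlot(update_cost_ms=0)
        with pytest.raises(ValueError):
            DeclarativeStore(p_wrong_state=1.5)


def _tags(trace, substr):
    return [e for e in trace.events if substr in e.tag]


class TestSubtractionThread:
    def test_easy_one_retrieval_per_column(self):
        ctx = TrialContext.make(rng=0)
        ctx.turn = "subtraction"
        prob = gen_subtraction("easy", 1)
        # run alone: release the turn token back after each digit
        body = subtraction_thread(prob, ctx)
        trace = run_threads([body, _turn_returner(ctx)])
        assert len(_tags(trace, "fact-retrieval")) == 10
        assert len(_tags(trace, "fact-retrieval-2")) == 0
        assert trace.busy_ms("problem_state") == 0.0

    def test_hard_double_retrievals_match_borrow_columns(self):
        ctx = TrialContext.make(rng=0)
        prob = gen_subtraction("hard", 2)
        trace = run_threads([subtraction_thread(prob, ctx), _turn_returner(ctx)])
        assert len(_tags(trace, "fact-retrieval-2")) == len(prob.borrow_columns) == 6
        # each borrow column logs one problem-state store
        assert len(_tags(trace, "store-borrow")) == 6
        # extra looks at the digits for the borrowings
        assert len(_tags(trace, "reencode-digits")) == 6


def _turn_returner(ctx):
    """Companion thread standing in for the other task: takes its turn
    instantly (one tiny procedural step) and hands the token back."""

    def body():
        from tripletask.engine import WaitFor

        for i in range(10):
            yield WaitFor(lambda: ctx.turn == "text_entry", "turn=text_entry")
            yield StepRequest("procedural", 1, f"other{i}")
            ctx.turn = "subtraction"

    return ThreadProgram("text_entry", body())


class TestTextEntryThread:
    def _run_alone(self, difficulty, p_wrong=0.0, seed=0):
        ctx = TrialContext.make(p_wrong_state=p_wrong, rng=seed)
        ctx.turn = "text_entry"
        stim = gen_textentry(difficulty, seed)

        def other():
            from tripletask.engine import WaitFor

            for i in range(10):
                yield WaitFor(lambda: ctx.turn == "subtraction", "turn=subtraction")
                yield StepRequest("procedural", 1, f"other{i}")
                ctx.turn = "text_entry"

        trace = run_threads(
            [ThreadProgram("subtraction", other()), textentry_thread(stim, ctx)]
        )
        return ctx, trace

    def test_easy_never_touches_problem_state(self):
        ctx, trace = self._run_alone("easy")
        assert trace.busy_ms("problem_state") == 0.0
        assert len(_tags(trace, "encode-letter")) == 10

    def test_hard_ten_updates_and_ten_spelling_retrievals(self):
        ctx, trace = self._run_alone("hard")
        assert len(_tags(trace, "advance-position")) == 10
        assert len(_tags(trace, "spelling-retrieval")) == 10
        assert ctx.swap_count == 0

    def test_hard_all_correct_without_error_source(self):
        ctx, _ = self._run_alone("hard", p_wrong=0.0)
        assert all(r.correct for r in ctx.responses)


class TestListeningThread:
    def test_isolated_word_central_time_is_320ms(self):
        ctx = TrialContext.make(rng=0)
        ws = gen_wordstream(0, n_words=20, mean_gap_ms=2000.0, gap_sd_ms=0.0)
        trace = run_threads([listening_thread(ws, ctx)])
        per_word = defaultdict(list)
        for e in trace.events:
            per_word[e.tag.split(":")[1]].append((e.start_ms, e.end_ms))
        spans = [max(e for _, e in v) - min(s for s, _ in v) for v in per_word.values()]
        assert np.mean(spans) == pytest.approx(320.0)

    def test_no_missed_words_at_speech_rate(self):
        ctx = TrialContext.make(rng=0)
        ws = gen_wordstream(0, n_words=100, mean_gap_ms=359.0, gap_sd_ms=0.0)
        run_threads([listening_thread(ws, ctx)])
        assert ctx.missed_words == []

    def test_busy_declarative_for_a_gap_misses_the_word(self):
        ctx = TrialContext.make(rng=0)
        ws = gen_wordstream(0, n_words=3, mean_gap_ms=400.0, gap_sd_ms=0.0)

        # hold declarative memory over word 1's entire central window
        def hog():
            yield StepRequest("declarative", 1300, "hold")

        run_threads([ThreadProgram("subtraction", hog()), listening_thread(ws, ctx)])
        assert 0 in ctx.missed_words

    def test_missed_word_has_only_initial_aural_demand(self):
        t = StepTimings()
        ws = gen_wordstream(0, n_words=3, mean_gap_ms=400.0, gap_sd_ms=0.0)
        ivs = aural_intervals(ws, missed=[1], timings=t)
        assert ivs[0][1] - ivs[0][0] == pytest.approx(400.0)
        assert ivs[1][1] - ivs[1][0] == pytest.approx(t.aural_initial_ms)
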