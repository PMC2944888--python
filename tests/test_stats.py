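"""Statistics tests: RT trimming forced cases, the arcsine transform,
and the repeated-measures ANOVA against a brute-force sums-of-squares
oracle, the paired-t identity, and pingouin as an independent package."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tripletask.stats import (
    arcsine_acc,
    interaction_contrast,
    rm_anova_2x2,
    rm_anova_2x2x2,
    trim_rt,
)


def rm_anova_ss_oracle(wide: np.ndarray):
    """Independent 2x2 within-subject ANOVA by explicit sums of squares.

    ``wide``: subjects x 4 cells ordered (a1b1, a1b2, a2b1, a2b2).
    Returns (F_A, F_B, F_AB) with error terms from the effect x subject
    interactions.
    """
    n = wide.shape[0]
    Y = wide.reshape(n, 2, 2)
    gm = Y.mean()
    A = Y.mean(axis=(0, 2))
    B = Y.mean(axis=(0, 1))
    S = Y.mean(axis=(1, 2))
    AB = Y.mean(axis=0)
    AS = Y.mean(axis=2)
    BS = Y.mean(axis=1)
    ss_a = 2 * n * ((A - gm) ** 2).sum()
    ss_b = 2 * n * ((B - gm) ** 2).sum()
    ss_ab = n * ((AB - A[:, None] - B[None, :] + gm) ** 2).sum()
    ss_as = 2 * ((AS - A[None, :] - S[:, None] + gm) ** 2).sum()
    ss_bs = 2 * ((BS - B[None, :] - S[:, None] + gm) ** 2).sum()
    ss_abs = (
        (
            Y
            - AB[None, :, :]
            - AS[:, :, None]
            - BS[:, None, :]
            + A[None, :, None]
            + B[None, None, :]
            + S[:, None, None]
            - gm
        )
        ** 2
    ).sum()
    df_e = n - 1
    return ss_a / (ss_as / df_e), ss_b / (ss_bs / df_e), ss_ab / (ss_abs / df_e)


def _long(wide: np.ndarray) -> pd.DataFrame:
    rows = []
    for s in range(wide.shape[0]):
        for i, a in enumerate(("easy", "hard")):
            for j, b in enumerate(("easy", "hard")):
                rows.append(
                    {"subject": s, "subtraction": a, "text_entry": b, "v": wide[s, 2 * i + j]}
                )
    return pd.DataFrame(rows)


class TestTrimRt:
    def test_absolute_bounds_forced_case(self):
        res = trim_rt([100, 500, 600, 12_000])
        assert list(res.kept) == [500.0, 600.0]
        assert res.discarded_fraction == pytest.approx(0.5)

    def test_identical_values_survive_sd_pass(self):
        res = trim_rt([500.0] * 6)
        assert len(res.kept) == 6

    def test_sd_pass_matches_hand_computed_criterion(self):
        rng = np.random.default_rng(1)
        base = np.exp(rng.normal(6.5, 0.1, size=200))  # lognormal, ~665 ms
        outlier = base.mean() + 8 * base.std(ddof=1)
        sample = np.concatenate([base, [outlier]])
        res = trim_rt(sample)
        # oracle: both passes by hand (bounds change nothing here)
        m, sd = sample.mean(), sample.std(ddof=1)
        expected = sample[np.abs(sample - m) <= 3 * sd]
        assert np.array_equal(np.sort(res.kept), np.sort(expected))
        assert outlier not in res.kept

    def test_small_cells_flagged_and_skip_sd_pass(self):
        df = pd.DataFrame(
            {"subject": [0, 0, 1], "condition": ["x", "x", "y"], "task": "t",
             "rt_ms": [400.0, 9000.0, 500.0]}
        )
        res = trim_rt(df)
        assert ((1, "y", "t") in res.flagged_cells)
        assert len(res.kept) == 3  # nothing SD-trimmed

    def test_trimming_is_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "subject": rng.integers(0, 3, 300),
                "condition": rng.choice(["a", "b"], 300),
                "task": "t",
                "rt_ms": np.exp(rng.normal(6.5, 0.4, 300)),
            }
        )
        once = trim_rt(df).kept
        twice = trim_rt(once).kept
        assert once.equals(twice)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            trim_rt([])


class TestArcsine:
    def test_endpoints_and_midpoint(self):
        assert arcsine_acc(0.0) == 0.0
        assert arcsine_acc(1.0) == pytest.approx(np.pi / 2)
        assert arcsine_acc(0.5) == pytest.approx(np.pi / 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_acc(1.2)


class TestRmAnova:
    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_matches_sums_of_squares_oracle(self, n):
        rng = np.random.default_rng(n)
        wide = rng.normal(size=(n, 4))
        res = rm_anova_2x2(_long(wide), "v")
        fa, fb, fab = rm_anova_ss_oracle(wide)
        got = dict(zip(res.effect, res.F))
        assert got["subtraction"] == pytest.approx(fa, rel=1e-10)
        assert got["text_entry"] == pytest.approx(fb, rel=1e-10)
        assert got["subtraction x text_entry"] == pytest.approx(fab, rel=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        df = _long(rng.normal(size=(6, 4)))
        mine = rm_anova_2x2(df, "v").set_index("effect")
        ref = pg.rm_anova(
            data=df, dv="v", within=["subtraction", "text_entry"], subject="subject", detailed=True
        ).set_index("Source")
        for eff, src in [
            ("subtraction", "subtraction"),
            ("text_entry", "text_entry"),
            ("subtraction x text_entry", "subtraction * text_entry"),
        ]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"], rel=1e-9)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[src, "p_unc"], rel=1e-9)

    def test_equals_squared_paired_t(self):
        rng = np.random.default_rng(4)
        wide = rng.normal(size=(8, 4))
        res = rm_anova_2x2(_long(wide), "v").set_index("effect")
        # interaction contrast = paired t on hh-he vs eh-ee differences
        scores = wide[:, 3] - wide[:, 2] - wide[:, 1] + wide[:, 0]
        t, p = sps.ttest_1samp(scores, 0.0)
        assert res.loc["subtraction x text_entry", "F"] == pytest.approx(t**2, rel=1e-10)
        assert res.loc["subtraction x text_entry", "p"] == pytest.approx(p, rel=1e-9)

    def test_additive_table_gives_zero_interaction(self):
        wide = np.array([[s + 2 * a + 3 * b for a in (0, 1) for b in (0, 1)] for s in range(5)], float)
        res = rm_anova_2x2(_long(wide), "v").set_index("effect")
        assert res.loc["subtraction x text_entry", "F"] == 0.0

    def test_eta_squared_identity(self):
        rng = np.random.default_rng(9)
        res = rm_anova_2x2(_long(rng.normal(size=(7, 4))), "v")
        for _, row in res.iterrows():
            assert row.eta_p2 == pytest.approx(row.F / (row.F + row.df2), abs=1e-10)

    def test_duplicating_subjects_increases_f(self):
        rng = np.random.default_rng(12)
        wide = rng.normal(size=(5, 4)) + np.array([0.0, 0.0, 0.0, 1.0])
        f1 = rm_anova_2x2(_long(wide), "v").set_index("effect").loc["subtraction x text_entry", "F"]
        doubled = np.vstack([wide, wide])
        f2 = rm_anova_2x2(_long(doubled), "v").set_index("effect").loc["subtraction x text_entry", "F"]
        assert f2 > f1

    def test_zero_variance_nonzero_mean_reports_inf(self):
        wide = np.tile([0.0, 0.0, 0.0, 1.0], (4, 1))
        res = rm_anova_2x2(_long(wide), "v").set_index("effect")
        assert np.isinf(res.loc["subtraction x text_entry", "F"])
        assert res.loc["subtraction x text_entry", "p"] == 0.0

    def test_missing_cell_rejected(self):
        df = _long(np.random.default_rng(0).normal(size=(3, 4)))
        with pytest.raises(ValueError):
            rm_anova_2x2(df.iloc[:-1], "v")

    def test_three_way_reduces_to_two_way_within_stratum(self):
        rng = np.random.default_rng(5)
        frames = []
        for lis in (False, True):
            d = _long(rng.normal(size=(6, 4)))
            d["listening"] = lis
            frames.append(d)
        df = pd.concat(frames)
        res3 = rm_anova_2x2x2(df, "v", within=("listening", "subtraction", "text_entry"))
        assert len(res3) == 7
        assert set(res3.effect) >= {"listening", "subtraction", "listening x subtraction x text_entry"}


class TestInteractionContrast:
    def test_all_zero_table(self):
        est, scores = interaction_contrast(_long(np.zeros((4, 4))), "v")
        assert est == 0.0 and (scores == 0).all()

    def test_positive_for_overadditive_cells(self):
        wide = np.tile([0.0, 1.0, 1.0, 5.0], (3, 1))
        est, scores = interaction_contrast(_long(wide), "v")
        assert est == pytest.approx(3.0)
        assert (scores > 0).all()
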