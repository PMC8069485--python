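"""Correlation framework: difference parameters, Spearman, bootstrap, tables."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pa_concordance import (
    DegenerateBootstrapError,
    PairedSample,
    SimConfig,
    UndefinedCorrelationError,
    bootstrap_ci,
    build_summary_table,
    difference_parameter,
    normality_check,
    reliability_analysis,
    render_summary_table,
    simulate_dataset,
    spearman,
    stability_analysis,
    tool_pairs,
    validity_analysis,
)
from pa_concordance.errors import ValidationError
from pa_concordance.quality_criteria import round_half_away


# --- independent oracle: explicit rank formula + exhaustive permutations ----

def brute_ranks(v):
    out = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        out.append(less + (equal + 1) / 2.0)
    return out


def brute_spearman(x, y):
    rx, ry = brute_ranks(x), brute_ranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


def brute_permutation_p(x, y):
    r_obs = abs(brute_spearman(x, y))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(brute_spearman(x, list(perm))) >= r_obs - 1e-12:
            hits += 1
    return hits / total


def estimates_frame(rows):
    return pd.DataFrame(
        rows, columns=["participant_id", "week", "tool", "intensity", "minutes_per_week"]
    )


class TestDifferenceParameter:
    def setup_method(self):
        self.est = estimates_frame(
            [
                ("p1", "T0", "acc10", "MPA", 300.0),
                ("p1", "T0", "acc60", "MPA", 250.0),
                ("p2", "T0", "acc10", "MPA", np.nan),
                ("p2", "T0", "acc60", "MPA", 250.0),
            ]
        )

    def test_direct_subtraction(self):
        d = difference_parameter(self.est, "acc10", "acc60", "MPA", "T0")
        assert d.values["p1"] == 50.0

    def test_missing_propagates(self):
        d = difference_parameter(self.est, "acc10", "acc60", "MPA", "T0")
        assert np.isnan(d.values["p2"])

    def test_self_difference_is_zero(self):
        d = difference_parameter(self.est, "acc60", "acc60", "MPA", "T0")
        assert d.values["p1"] == 0.0

    def test_unknown_tool_rejected(self):
        with pytest.raises(ValidationError):
            difference_parameter(self.est, "acc10", "pedometer", "MPA", "T0")


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        x = np.arange(1.0, 6.0)
        assert spearman(PairedSample(x, x)).r_s == pytest.approx(1.0, abs=1e-12)
        assert spearman(PairedSample(x, x[::-1])).r_s == pytest.approx(-1.0, abs=1e-12)

    def test_perfect_correlation_p_is_permutation_bound(self):
        x = np.arange(1.0, 6.0)
        assert spearman(PairedSample(x, x)).p_value == pytest.approx(2 / math.factorial(5))

    def test_undefined_cases(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman(PairedSample([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(UndefinedCorrelationError):
            spearman(PairedSample([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pairwise_deletion_inside_sample(self):
        s = PairedSample([1, 2, 3, np.nan, 4], [2, 4, 6, 1.0, 8])
        res = spearman(s)
        assert res.n == 4 and res.r_s == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=3, max_size=8).filter(lambda v: len(set(v)) > 1),
        st.lists(st.integers(0, 8), min_size=8, max_size=8).filter(lambda v: len(set(v[:8])) > 1),
    )
    def test_agrees_with_brute_force_and_is_rank_invariant(self, xs, ys):
        ys = ys[: len(xs)]
        if len(set(ys)) < 2:
            ys[0] = ys[0] + 1
        x, y = np.array(xs, float), np.array(ys, float)
        r = spearman(PairedSample(x, y)).r_s
        assert r == pytest.approx(brute_spearman(xs, ys), abs=1e-12)
        # strictly increasing transforms leave r_s unchanged
        fx, gy = np.exp(x / 4.0), y**3 + 2 * y
        assert spearman(PairedSample(fx, gy)).r_s == pytest.approx(r, abs=1e-12)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman(PairedSample(x, y))
        ref = sps.spearmanr(x, y)
        assert res.r_s == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_permutation_p_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = list(rng.integers(0, 6, size=5).astype(float))
            y = list(rng.integers(0, 6, size=5).astype(float))
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            mine = spearman(PairedSample(x, y), method="exact").p_value
            assert mine == pytest.approx(brute_permutation_p(x, y), abs=1e-12)


class TestBootstrap:
    def test_perfectly_correlated_interval_collapses_to_one(self):
        x = np.arange(10.0)
        lo, hi, used = bootstrap_ci(PairedSample(x, 2 * x + 1), n_boot=200, seed=1)
        assert lo == pytest.approx(1.0, abs=1e-12) and hi == pytest.approx(1.0, abs=1e-12)
        assert used == 200

    def test_independent_data_interval_contains_zero(self):
        rng = np.random.default_rng(2)
        s = PairedSample(rng.normal(size=200), rng.normal(size=200))
        lo, hi, _ = bootstrap_ci(s, n_boot=1000, seed=3)
        assert lo < 0 < hi

    def test_single_replicate_collapses(self):
        x = np.arange(6.0)
        y = np.array([0.0, 2, 1, 4, 3, 5])
        lo, hi, used = bootstrap_ci(PairedSample(x, y), n_boot=1, seed=4)
        assert used == 1 and lo == hi

    def test_mostly_constant_margins_raise_degenerate_error(self):
        s = PairedSample([0.0, 0.0, 1.0], [0.0, 1.0, 1.0])
        with pytest.raises(DegenerateBootstrapError):
            bootstrap_ci(s, n_boot=400, seed=5)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        s = PairedSample(rng.normal(size=30), rng.normal(size=30))
        assert bootstrap_ci(s, seed=7) == bootstrap_ci(s, seed=7)


class TestNormalityCheck:
    def test_normal_samples_rarely_rejected(self):
        ps = []
        for seed in range(20):
            v = np.random.default_rng(seed).normal(10, 2, size=1000)
            ps.append(normality_check(v)[1])
        assert np.mean(np.array(ps) > 0.05) >= 0.9

    def test_exponential_sample_rejected(self):
        v = np.random.default_rng(1).exponential(size=200)
        assert normality_check(v)[1] < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            normality_check([3.0, 3.0, 3.0])


def _noise_free_config(**over):
    kwargs = dict(
        n_adults=12,
        n_children=8,
        base_epoch_s=10,
        week_noise_sd=0.0,
        diary_omission_prob=0.0,
        diary_intensity_confusion=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        ipaq_rounding_grid_min=1.0,
        seed=31,
    )
    kwargs.update(over)
    return SimConfig(**kwargs)


@pytest.fixture(scope="module")
def noise_free():
    return simulate_dataset(_noise_free_config()).estimates


class TestAnalyses:

    def test_noise_free_cohort_has_perfect_stability_and_reliability(self, noise_free):
        adults = noise_free[noise_free.population == "adult"]
        pairs = tool_pairs(["acc10", "acc60", "diary", "ipaq"])
        stab = stability_analysis(adults, pairs, "MPA", n_boot=0)
        ok = stab[stab.error == ""]
        assert len(ok) >= 5  # a pair can degenerate to constant differences
        assert np.allclose(ok.r_s, 1.0, atol=1e-12)
        rel = reliability_analysis(adults, ["acc10", "acc60"], "MPA", n_boot=0)
        assert np.allclose(rel.r_s, 1.0, atol=1e-12)

    def test_row_count_contract(self, noise_free):
        adults = noise_free[noise_free.population == "adult"]
        children = noise_free[noise_free.population == "child"]
        assert len(stability_analysis(adults, tool_pairs(["acc10", "acc60", "diary", "ipaq"]), "MPA", n_boot=0)) == 6
        assert len(stability_analysis(children, tool_pairs(["acc10", "acc60", "diary"]), "VPA", n_boot=0)) == 3
        assert len(validity_analysis(adults, ["acc10", "acc60", "diary", "ipaq"], "MPA", "T0", n_boot=0)) == 6

    def test_pair_swap_negates_differences_but_keeps_stability(self, noise_free):
        adults = simulate_dataset(
            _noise_free_config(week_noise_sd=30.0, seed=8, n_children=0)
        ).estimates
        d_ab = difference_parameter(adults, "acc10", "acc60", "MPA", "T0")
        d_ba = difference_parameter(adults, "acc60", "acc10", "MPA", "T0")
        pd.testing.assert_series_equal(d_ab.values, -d_ba.values)
        s_ab = stability_analysis(adults, [("acc10", "acc60")], "MPA", n_boot=0)
        s_ba = stability_analysis(adults, [("acc60", "acc10")], "MPA", n_boot=0)
        assert s_ab.r_s[0] == pytest.approx(s_ba.r_s[0], abs=1e-12)

    def test_participant_with_missing_values_never_changes_statistics(self):
        est = simulate_dataset(
            _noise_free_config(week_noise_sd=25.0, seed=77, n_children=0)
        ).estimates
        extra = est[est.participant_id == "A000"].copy()
        extra["participant_id"] = "A999"
        extra.loc[extra.tool == "acc60", "minutes_per_week"] = np.nan
        padded = pd.concat([est, extra], ignore_index=True)
        pairs = [("acc10", "acc60")]
        base = stability_analysis(est, pairs, "MPA", n_boot=0)
        with_extra = stability_analysis(padded, pairs, "MPA", n_boot=0)
        assert base.r_s[0] == with_extra.r_s[0] and base.n[0] == with_extra.n[0]

    def test_degenerate_tool_surfaces_error_and_run_continues(self):
        # acc10 varies, diary constant zero
        rows = []
        for i in range(4):
            for wk in ("T0", "T1"):
                rows.append((f"p{i}", wk, "acc10", "MPA", float(i + 1)))
                rows.append((f"p{i}", wk, "diary", "MPA", 0.0))
        est = estimates_frame(rows)
        rel = reliability_analysis(est, ["acc10", "diary"], "MPA", n_boot=0)
        assert rel.loc[rel.tool_a == "acc10", "error"].iloc[0] == ""
        assert "constant" in rel.loc[rel.tool_a == "diary", "error"].iloc[0]


class TestSummaryTable:
    def test_diff_mean_is_t1_minus_t0_on_complete_pairs(self):
        est = simulate_dataset(_noise_free_config(week_noise_sd=30.0, seed=55, n_children=0)).estimates
        rows = build_summary_table(est, [("acc10", "acc60")], "MPA", n_boot=0)
        r = rows[0]
        assert r.diff_mean == pytest.approx(r.t1_mean - r.t0_mean, abs=1e-9)

    def test_empty_subset_row(self):
        rows_src = [("p1", "T0", "acc10", "MPA", 1.0), ("p1", "T0", "acc60", "MPA", 2.0),
                    ("p1", "T1", "acc10", "MPA", np.nan), ("p1", "T1", "acc60", "MPA", 2.0)]
        rows = build_summary_table(estimates_frame(rows_src), [("acc10", "acc60")], "MPA", n_boot=0)
        assert rows[0].n == 0 and math.isnan(rows[0].diff_mean)

    def test_rendering_rounds_half_away_from_zero(self):
        assert round_half_away(-17.665) == -17.67
        assert round_half_away(2.675) == 2.68
        assert round_half_away(0.125) == 0.13
        est = simulate_dataset(_noise_free_config(week_noise_sd=30.0, seed=55, n_children=0)).estimates
        df = render_summary_table(build_summary_table(est, [("acc10", "acc60")], "MPA", n_boot=0))
        assert df.loc[0, "label"] == "Acc 10–Acc 60"
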