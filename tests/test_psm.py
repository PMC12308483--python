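"""Propensity matching, activity strata and matched biomarker comparisons."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from madwt.psm import (
    PropensityMatcher,
    compare_biomarkers,
    estimate_propensity,
    mann_whitney,
    match_pairs,
    select_top_active,
)
from madwt.synth import default_config, generate_cohort


def exact_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group labels."""
    pooled = np.concatenate([x, y])
    n = len(x)
    u_obs = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").statistic
    mu = len(x) * len(y) / 2.0
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        u = stats.mannwhitneyu(pooled[mask], pooled[~mask], method="exact").statistic
        total += 1
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-9
    return count / total


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

class TestPropensity:
    def test_recovers_logistic_coefficients(self):
        cfg = default_config(n=20_000, seed=31, segment_level=False)
        df, truth = generate_cohort(cfg)
        m = PropensityMatcher(confounders=["age", "bmi"]).fit(df, df.hypertension)
        res = m.result_
        # truth is per-SD; the model is fitted per-unit
        for name, sd in [("age", 7.7), ("bmi", 4.4)]:
            beta_true = cfg.htn_logistic_coef[name] / sd
            assert abs(res.params[name] - beta_true) < 3 * res.bse[name]

    def test_confounder_free_scores_near_prevalence(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"age": rng.normal(60, 8, 5000)})
        treated = (rng.random(5000) < 0.3).astype(int)
        scores = estimate_propensity(df.assign(hypertension=treated), ["age"])
        # the fitted slope is pure noise: scores hug the prevalence
        assert np.abs(scores - treated.mean()).mean() < 0.02
        assert np.abs(scores - treated.mean()).max() < 0.08

    def test_separation_raises(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"age": x, "hypertension": (x > 0).astype(int)})
        with pytest.raises(RuntimeError, match="separation|converge"):
            estimate_propensity(df, ["age"])


# ---------------------------------------------------------------------------
# greedy matching
# ---------------------------------------------------------------------------

class TestMatching:
    def test_nearest_control_chosen(self):
        res = match_pairs(np.array([0.5, 0.4, 0.9]), np.array([1, 0, 0]))
        assert res.pairs.iloc[0].tolist() == [0, 1, pytest.approx(0.1)]

    def test_identical_multisets_perfect(self):
        scores = np.array([0.2, 0.5, 0.8, 0.2, 0.5, 0.8])
        res = match_pairs(scores, np.array([1, 1, 1, 0, 0, 0]))
        assert np.allclose(res.pairs.score_diff, 0.0)
        assert len(res.pairs) == 3

    def test_adversarial_case_matches_greedy_oracle(self):
        """Greedy (not optimal) assignment, treated in descending order.

        treated scores {0.60, 0.50}, controls {0.55, 0.38}.  Greedy gives
        0.60->0.55 then 0.50->0.38 (total |d| 0.17); optimal assignment
        would pair 0.50->0.55 and 0.60->... the same here, so use the
        classic trap: treated {0.50, 0.60}, controls {0.55, 0.80}: greedy
        processes 0.60 first taking 0.55, forcing 0.50->0.80.
        """
        scores = np.array([0.50, 0.60, 0.55, 0.80])
        res = match_pairs(scores, np.array([1, 1, 0, 0]))
        got = {(r.treated_id, r.control_id) for r in res.pairs.itertuples()}
        assert got == {(1, 2), (0, 3)}  # greedy, NOT the optimal {(1,3),(0,2)}

    def test_no_control_reused_and_deterministic(self):
        rng = np.random.default_rng(5)
        scores = rng.random(500)
        treated = (rng.random(500) < 0.4).astype(int)
        a = match_pairs(scores, treated)
        b = match_pairs(scores, treated)
        assert a.pairs.control_id.is_unique
        assert a.pairs.treated_id.is_unique
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_fewer_controls_partial_match(self, caplog):
        scores = np.array([0.1, 0.2, 0.3, 0.25])
        res = match_pairs(scores, np.array([1, 1, 1, 0]))
        assert len(res.pairs) == 1
        assert res.n_unmatched_treated == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            match_pairs(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_balance_improves_on_confounded_cohort(self):
        cfg = default_config(n=10_000, seed=41, segment_level=False)
        df, _ = generate_cohort(cfg)
        m = PropensityMatcher().fit(df, df.hypertension)
        res = m.match_result_
        assert res.smd_pre[["age", "bmi"]].abs().min() > 0.2  # confounded going in
        assert res.smd_post.abs().max() < 0.1


# ---------------------------------------------------------------------------
# activity strata
# ---------------------------------------------------------------------------

class TestTopActive:
    def test_top_fraction_counts_and_dominance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"TPA": rng.permutation(np.arange(1000, dtype=float))})
        top = select_top_active(df, "TPA", 0.01)
        assert len(top) == 10  # 1000 distinct values: quantile cut keeps 10
        assert top.TPA.min() >= df.TPA.drop(top.index).max()

    def test_fraction_one_identity(self):
        df = pd.DataFrame({"TPA": [1.0, 2.0, 3.0]})
        assert select_top_active(df, "TPA", 1.0).equals(df)

    def test_ties_at_threshold_all_included(self):
        df = pd.DataFrame({"TPA": [0.0] * 90 + [5.0] * 10})
        top = select_top_active(df, "TPA", 0.05)
        assert len(top) == 10  # all tied rows at the cut survive

    def test_accel_metric_restricted_to_valid_wear(self):
        df = pd.DataFrame(
            {"accel_mean": [30.0, 40.0, np.nan, 50.0], "accel_valid": [True, False, True, True]}
        )
        top = select_top_active(df, "accel_mean", 1.0)
        assert top.index.tolist() == [0, 3]

    def test_empty_stratum_rejected(self):
        df = pd.DataFrame({"accel_mean": [np.nan], "accel_valid": [False]})
        with pytest.raises(ValueError):
            select_top_active(df, "accel_mean", 0.1)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            select_top_active(pd.DataFrame({"x": [1.0]}), "x", 0.1)


# ---------------------------------------------------------------------------
# Mann-Whitney and comparisons
# ---------------------------------------------------------------------------

class TestComparisons:
    def test_mw_separated_triplets(self):
        u, p = mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert u == 0.0
        assert p == pytest.approx(0.10, abs=1e-12)  # 2 / C(6,3)

    def test_mw_exact_matches_enumeration(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 7), rng.normal(0.8, 1, 6)
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(exact_mw_p(x, y), abs=1e-9)

    def test_mw_exact_vs_asymptotic_close(self):
        rng = np.random.default_rng(10)
        for _ in range(5):
            x, y = rng.normal(0, 1, 18), rng.normal(0.5, 1, 17)
            pe = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            pa = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            assert pe == pytest.approx(pa, abs=0.01)

    def test_identical_groups_null(self):
        g = np.tile(np.arange(30, dtype=float), 2)
        df = pd.DataFrame({"MadWT": g, "hypertension": np.repeat([1, 0], 30)})
        ct = compare_biomarkers(df, ["MadWT"], seed=0)
        row = ct.table.loc["MadWT"]
        assert row.rel_diff == 0.0
        assert row.p == pytest.approx(1.0, abs=1e-9)
        assert row.ci_htn_low <= row.median_htn <= row.ci_htn_high

    def test_all_nan_biomarker_skipped(self):
        df = pd.DataFrame(
            {"MadWT": [1.0, 2.0], "GLS": [np.nan, np.nan], "hypertension": [1, 0]}
        )
        ct = compare_biomarkers(df, ["MadWT", "GLS"], n_boot=50, seed=0)
        assert "GLS" not in ct.table.index
        assert ct.alpha_family == 1

    def test_bootstrap_median_ci_coverage(self):
        """~95% coverage for the median of a log-normal (200 replicates)."""
        rng = np.random.default_rng(12)
        true_median = 1.0  # lognormal(0, 0.6)
        hits = 0
        reps = 200
        for _ in range(reps):
            x = rng.lognormal(0.0, 0.6, 120)
            df = pd.DataFrame({"MadWT": x, "hypertension": np.arange(120) % 2})
            ct = compare_biomarkers(df, ["MadWT"], n_boot=400, seed=rng)
            row = ct.table.loc["MadWT"]
            hits += row.ci_htn_low <= true_median <= row.ci_htn_high
        assert hits / reps == pytest.approx(0.95, abs=0.03)
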