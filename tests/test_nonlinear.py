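"""Stratification methods, Cochran's Q, trend test and assumption checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats

from stratmr import (
    ExposureSpec,
    InstrumentSet,
    SimulationConfig,
    VariantSpec,
    cochran_q,
    compute_score,
    constant_effect_check,
    doubly_ranked_stratify,
    observed_stratify,
    pleiotropy_biomarker_check,
    residual_stratify,
    simulate_cohort,
    stratum_estimates,
    trend_test,
)

from conftest import tiny_cohort


def _score(cohort, weights):
    iv = InstrumentSet(list(weights), dict(weights), 1, 1)
    return compute_score(cohort.genotypes, iv)


class TestResidualStratify:
    def test_zero_score_effect_gives_observed_quartiles(self):
        # score uncorrelated with the stratifier: residual = centred observed
        # value, so residual quartiles equal observed-value quartiles
        rng = np.random.default_rng(0)
        n = 200
        g = rng.binomial(2, 0.3, n)
        strat = rng.normal(100, 20, n)
        cohort = tiny_cohort({"v": g}, {"exposure": rng.normal(5, 1, n), "tg": strat})
        score = pd.Series(rng.normal(size=n), index=cohort.phenotypes.index)
        score -= score.mean()
        # force exact orthogonality to the stratifier
        s = strat - strat.mean()
        score = score - (score @ s) / (s @ s) * s
        res = residual_stratify(cohort, "tg", score, n_strata=4)
        obs = observed_stratify(cohort, "tg", n_strata=4)
        pd.testing.assert_series_equal(res.index, obs.index)

    def test_eight_rows_four_strata_two_each(self):
        cohort = tiny_cohort(
            {"v": [0, 1] * 4},
            {"exposure": list(range(8)), "tg": [5.0, 3, 8, 1, 9, 2, 7, 4]},
        )
        score = pd.Series(0.0, index=cohort.phenotypes.index)
        score.iloc[0] = 1e-9  # non-constant
        res = residual_stratify(cohort, "tg", score, n_strata=4, min_stratum_size=1)
        assert res.index.value_counts().tolist() == [2, 2, 2, 2]

    def test_full_sample_residual_orthogonal_to_score(self, demo_cohort):
        score = _score(demo_cohort, {"rs_a1": -0.1, "rs_b1": -0.08})
        res = residual_stratify(demo_cohort, "tg", score, ["age", "sex"], 4)
        # reconstruct the residual used for stratification via OLS orthogonality
        from stratmr._regression import build_design, ols_full

        X = build_design(demo_cohort.phenotypes, ["age", "sex"])
        X.insert(1, "score", score)
        fit, idx = ols_full(demo_cohort.phenotypes["tg"], X)
        corr = np.corrcoef(fit.resid, score.loc[idx])[0, 1]
        assert abs(corr) < 1e-8

    def test_too_many_strata_refused(self, demo_cohort):
        score = _score(demo_cohort, {"rs_a1": -0.1})
        with pytest.raises(ValueError, match="refused"):
            residual_stratify(demo_cohort, "tg", score, n_strata=1000)

    def test_strata_partition_cohort(self, demo_cohort):
        score = _score(demo_cohort, {"rs_a1": -0.1, "rs_b1": -0.08})
        res = residual_stratify(demo_cohort, "tg", score, n_strata=4)
        assert sorted(res.index.unique()) == [0, 1, 2, 3]
        assert len(res.index) == demo_cohort.n
        sizes = res.index.value_counts()
        assert sizes.max() - sizes.min() <= 3  # at most n_strata - 1


class TestDoublyRanked:
    def test_sixteen_row_hand_trace(self):
        # scores 1..16 for individuals A..P; pre-strata {A-D},{E-H},{I-L},{M-P};
        # within each, ranking the stratifier and assigning rank j to stratum j
        # was traced by hand to give the frozen assignment below
        ids = list("ABCDEFGHIJKLMNOP")
        strat = [5, 2, 9, 1, 10, 3, 7, 8, 4, 4, 2, 6, 1, 9, 5, 3]
        geno = pd.DataFrame({"v": [0] * 16}, index=pd.Index(ids, name="iid"))
        pheno = pd.DataFrame(
            {"exposure": range(16), "tg": strat}, index=geno.index
        )
        from stratmr import Cohort

        cohort = Cohort(genotypes=geno, phenotypes=pheno)
        score = pd.Series(range(1, 17), index=geno.index, dtype=float)
        out = doubly_ranked_stratify(cohort, score, "tg", 4, min_stratum_size=1)
        expected = {
            "D": 0, "B": 1, "A": 2, "C": 3,
            "F": 0, "G": 1, "H": 2, "E": 3,
            "K": 0, "I": 1, "J": 2, "L": 3,
            "M": 0, "P": 1, "O": 2, "N": 3,
        }
        assert out.index.to_dict() == expected

    def test_tied_stratifier_uses_id_tiebreak(self):
        # all stratifier values equal: within each pre-stratum the assignment
        # is by the declared stable tie-break (individual ID order)
        ids = ["I0", "I1", "I2", "I3"]
        geno = pd.DataFrame({"v": [0] * 4}, index=pd.Index(ids, name="iid"))
        pheno = pd.DataFrame({"exposure": range(4), "tg": [7.0] * 4}, index=geno.index)
        from stratmr import Cohort

        cohort = Cohort(genotypes=geno, phenotypes=pheno)
        score = pd.Series([1.0, 2.0, 3.0, 4.0], index=geno.index)
        out = doubly_ranked_stratify(cohort, score, "tg", 4, min_stratum_size=1)
        assert out.index.to_dict() == {"I0": 0, "I1": 1, "I2": 2, "I3": 3}

    def test_remainder_goes_to_lowest_strata(self):
        ids = [f"I{i}" for i in range(6)]
        geno = pd.DataFrame({"v": [0] * 6}, index=pd.Index(ids, name="iid"))
        pheno = pd.DataFrame(
            {"exposure": range(6), "tg": [3.0, 1, 2, 4, 9, 5]}, index=geno.index
        )
        from stratmr import Cohort

        cohort = Cohort(genotypes=geno, phenotypes=pheno)
        score = pd.Series(np.arange(6, dtype=float), index=geno.index)
        out = doubly_ranked_stratify(cohort, score, "tg", 4, min_stratum_size=1)
        sizes = out.index.value_counts().sort_index()
        # 6 = 4 + 2: the partial pre-stratum fills strata 0 and 1
        assert sizes.tolist() == [2, 2, 1, 1]

    def test_score_distributions_similar_across_strata_when_independent(self):
        cfg = SimulationConfig(
            n_individuals=20_000,
            variants=[VariantSpec(id="v", maf=0.3, beta=0.0)],
            exposure=ExposureSpec(noise_sd=1.0, confounder_effect=0.0),
            biomarkers={"tg": dict(intercept=100.0, loading=0.0, noise_sd=80.0)},
            seed=8,
        )
        cohort = simulate_cohort(cfg)
        score = pd.Series(
            np.random.default_rng(9).normal(size=20_000), index=cohort.phenotypes.index
        )
        out = doubly_ranked_stratify(cohort, score, "tg", 4)
        s0 = score[out.members(0)]
        s3 = score[out.members(3)]
        assert stats.ks_2samp(s0, s3).pvalue > 0.01


class TestCochranQ:
    def test_identical_estimates_give_zero_q(self):
        out = cochran_q([{"theta": 0.3, "se": 0.1}] * 4)
        assert out["q"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_hand_computed_two_estimate_case(self):
        out = cochran_q([{"theta": 0.0, "se": 1.0}, {"theta": 1.0, "se": 1.0}])
        assert out["q"] == pytest.approx(0.5, abs=1e-12)
        assert out["df"] == 1
        assert out["p"] == pytest.approx(stats.chi2.sf(0.5, 1), abs=1e-12)

    def test_fewer_than_two_estimates_rejected(self):
        with pytest.raises(ValueError):
            cochran_q([{"theta": 0.1, "se": 0.2}])

    @given(
        shift=hst.floats(-5, 5),
        thetas=hst.lists(hst.floats(-2, 2), min_size=2, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_shift_invariance(self, shift, thetas):
        ses = [0.5] * len(thetas)
        base = cochran_q([{"theta": t, "se": s} for t, s in zip(thetas, ses)])
        moved = cochran_q(
            [{"theta": t + shift, "se": s} for t, s in zip(thetas, ses)]
        )
        assert moved["q"] == pytest.approx(base["q"], abs=1e-8)


class TestTrendTest:
    def test_equal_thetas_give_null_slope(self):
        out = trend_test([{"theta": 0.2, "se": 0.1}] * 4, [1.0, 2.0, 3.0, 4.0])
        assert out["slope"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_trend"] == pytest.approx(1.0, abs=1e-9)

    def test_exact_linear_trend_recovered(self):
        m = [1.0, 2.0, 3.0, 4.0]
        ests = [{"theta": 0.05 + 0.125 * mi, "se": 1e-6} for mi in m]
        out = trend_test(ests, m)
        assert out["slope"] == pytest.approx(0.125, abs=1e-4)
        assert out["p_trend"] < 1e-10
        assert out["quadratic"] == pytest.approx(0.0, abs=1e-4)

    def test_insufficient_strata_rejected(self):
        with pytest.raises(ValueError):
            trend_test([{"theta": 0.1, "se": 0.1}] * 2, [1.0, 2.0])

    def test_quadratic_reported_with_four_strata(self):
        m = np.array([1.0, 2.0, 3.0, 4.0])
        ests = [{"theta": float(0.1 * mi**2), "se": 1e-6} for mi in m]
        out = trend_test(ests, m)
        assert "quadratic" in out
        assert out["quadratic"] == pytest.approx(0.1, abs=1e-4)


class TestStratumEstimatesAndChecks:
    def test_at_most_n_strata_estimates_and_rare_outcome_flagged(self, demo_cohort):
        iv = InstrumentSet(
            ["rs_a1", "rs_b1", "rs_c1"],
            {"rs_a1": -0.1, "rs_b1": -0.08, "rs_c1": -0.07},
            1e-3, 0.1,
        )
        score = compute_score(demo_cohort.genotypes, iv)
        # cerebral infarction is rare in the demo: some strata may have a
        # single class and must come back flagged rather than raising
        assignment = residual_stratify(demo_cohort, "tg", score, n_strata=4)
        ests, skipped = stratum_estimates(
            demo_cohort, assignment, iv, "cerebral_infarction", scale=1.0
        )
        assert len(ests) == 4
        for j in skipped:
            assert ests[j] is None

    def test_constant_effect_check_requires_doubly_ranked(self, demo_cohort):
        iv = InstrumentSet(["rs_a1"], {"rs_a1": -0.1}, 1e-3, 0.1)
        score = compute_score(demo_cohort.genotypes, iv)
        res = residual_stratify(demo_cohort, "tg", score, n_strata=4)
        with pytest.raises(ValueError, match="doubly-ranked"):
            constant_effect_check(demo_cohort, res, iv)

    def test_constant_effect_check_passes_on_demo(self, demo_cohort):
        iv = InstrumentSet(
            ["rs_a1", "rs_b1", "rs_c1"],
            {"rs_a1": -0.1, "rs_b1": -0.08, "rs_c1": -0.07},
            1e-3, 0.1,
        )
        score = compute_score(demo_cohort.genotypes, iv)
        dr = doubly_ranked_stratify(demo_cohort, score, "tg", 4)
        out = constant_effect_check(demo_cohort, dr, iv, alpha=0.001)
        assert len(out["gammas"]) == 4
        assert out["passed"]

    def test_pleiotropy_check_constant_biomarker_degenerate(self, demo_cohort):
        cohort = demo_cohort.subset(demo_cohort.phenotypes.index)
        cohort.phenotypes = cohort.phenotypes.copy()
        cohort.phenotypes["flat"] = 1.0
        iv = InstrumentSet(["rs_a1"], {"rs_a1": -0.1}, 1e-3, 0.1)
        score = compute_score(cohort.genotypes, iv)
        out = pleiotropy_biomarker_check(cohort, score, ["ldl", "flat"])
        assert out.loc[out["biomarker"] == "flat", "status"].iloc[0].startswith("degenerate")
        assert out.loc[out["biomarker"] == "ldl", "status"].iloc[0] == "ok"
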