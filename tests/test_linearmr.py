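"""Score construction, logistic/OLS effects, Wald ratio and linear MR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stratmr import (
    ExposureSpec,
    InstrumentSet,
    OutcomeSpec,
    SimulationConfig,
    ThetaSpec,
    VariantSpec,
    compute_score,
    linear_mr,
    score_exposure_effect,
    score_outcome_effect,
    simulate_cohort,
    wald_ratio,
)
from stratmr._regression import EffectEstimate, RegressionError

from conftest import tiny_cohort


def _ivset(weights):
    return InstrumentSet(list(weights), dict(weights), 1e-3, 0.1)


def irls_logistic_oracle(X, y, tol=1e-12, maxiter=200):
    """Plain iteratively-reweighted least squares, independent of statsmodels."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        beta_new = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(X.T @ ((mu * (1 - mu))[:, None] * X))
    return beta, np.sqrt(np.diag(cov))


class TestComputeScore:
    def test_weighted_sum_arithmetic(self):
        geno = pd.DataFrame({"a": [2], "b": [1]}, index=["I0"])
        score = compute_score(geno, _ivset({"a": 0.5, "b": -0.2}))
        assert score.iloc[0] == pytest.approx(0.8, abs=1e-15)

    def test_zero_weights_zero_scores(self):
        geno = pd.DataFrame({"a": [0, 1, 2], "b": [2, 1, 0]})
        score = compute_score(geno, _ivset({"a": 0.0, "b": 0.0}))
        assert (score == 0).all()

    def test_single_variant_unit_weight_is_dosage(self):
        geno = pd.DataFrame({"a": [0, 1, 2, 1]})
        score = compute_score(geno, _ivset({"a": 1.0}))
        np.testing.assert_array_equal(score.to_numpy(), geno["a"].to_numpy())

    def test_missing_dosage_policies(self):
        geno = pd.DataFrame({"a": [0.0, np.nan, 2.0]})
        dropped = compute_score(geno, _ivset({"a": 1.0}), missing_policy="drop")
        assert len(dropped) == 2
        imputed = compute_score(geno, _ivset({"a": 1.0}), missing_policy="mean_impute")
        assert len(imputed) == 3
        assert imputed.iloc[1] == pytest.approx(1.0)

    def test_absent_variant_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            compute_score(pd.DataFrame({"a": [1]}), _ivset({"zzz": 1.0}))


class TestScoreEffects:
    def test_noiseless_gamma_exact(self, noiseless_config):
        cohort = simulate_cohort(noiseless_config)
        # single-variant score: exposure = 5 + 0.5 g1 - 0.2 g2; regressing on
        # the two-variant score with true weights gives gamma = 1 exactly
        iv = _ivset({"v1": 0.5, "v2": -0.2})
        score = compute_score(cohort.genotypes, iv)
        est = score_exposure_effect(cohort, score)
        assert est.beta == pytest.approx(1.0, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_constant_score_rejected(self, demo_cohort):
        score = pd.Series(2.0, index=demo_cohort.phenotypes.index)
        with pytest.raises(RegressionError, match="constant"):
            score_exposure_effect(demo_cohort, score)

    def test_in_sample_self_weighting_gives_gamma_near_one(self):
        # weights taken from the same cohort's GWAS make the score-exposure
        # slope ~1 (verified by simulation; the identity is exact in the limit)
        from stratmr import clump, run_region_gwas

        cfg = SimulationConfig(
            n_individuals=30_000,
            variants=[VariantSpec(id=f"v{j}", maf=0.3, beta=0.15) for j in range(3)],
            exposure=ExposureSpec(noise_sd=1.2, confounder_effect=0.0),
            seed=21,
        )
        cohort = simulate_cohort(cfg)
        assocs = run_region_gwas(cohort, cohort.variant_ids)
        iv = clump(assocs, cohort.genotypes, 1e-3, 0.3)
        score = compute_score(cohort.genotypes, iv)
        est = score_exposure_effect(cohort, score)
        assert est.beta == pytest.approx(1.0, abs=0.05)

    def test_single_class_outcome_rejected(self):
        cohort = tiny_cohort(
            {"a": [0, 1, 2, 1] * 5}, {"exposure": list(range(20)), "y": [0] * 20}
        )
        score = compute_score(cohort.genotypes, _ivset({"a": 1.0}))
        with pytest.raises(RegressionError, match="single class"):
            score_outcome_effect(cohort, score, "y")

    def test_logistic_matches_irls_oracle(self):
        # 20-row fixture with a hand-checkable likelihood
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, 20)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 1, 0, 1, 0])
        cohort = tiny_cohort({"a": g}, {"exposure": g * 0.5, "y": y})
        score = compute_score(cohort.genotypes, _ivset({"a": 1.0}))
        est = score_outcome_effect(cohort, score, "y")
        X = np.column_stack([np.ones(20), g.astype(float)])
        beta_o, se_o = irls_logistic_oracle(X, y.astype(float))
        assert est.beta == pytest.approx(beta_o[1], abs=1e-6)
        assert est.se == pytest.approx(se_o[1], abs=1e-6)

    def test_null_theta_big_gamma_centred_on_zero(self):
        zs = []
        for i in range(30):
            cfg = SimulationConfig(
                n_individuals=3000,
                variants=[VariantSpec(id="v", maf=0.3, beta=0.3)],
                exposure=ExposureSpec(noise_sd=1.0, confounder_effect=0.0),
                outcomes={
                    "y": OutcomeSpec(
                        baseline_log_odds=-1.5, theta=ThetaSpec(kind="constant", value=0.0)
                    )
                },
                seed=3000 + i,
            )
            cohort = simulate_cohort(cfg)
            score = compute_score(cohort.genotypes, _ivset({"v": 0.3}))
            est = score_outcome_effect(cohort, score, "y")
            zs.append(est.beta / est.se)
        assert abs(np.mean(zs)) < 3 / np.sqrt(30)


def _est(beta, se):
    return EffectEstimate(term="x", beta=beta, se=se, p_value=0.5, n_used=100)


class TestWaldRatio:
    def test_null_numerator_gives_unit_or(self):
        out = wald_ratio(_est(2.0, 0.1), _est(0.0, 0.2))
        assert out.odds_ratio == pytest.approx(1.0)
        assert out.p_value == pytest.approx(1.0)

    def test_error_free_denominator_collapses_delta_formula(self):
        out = wald_ratio(_est(2.0, 0.0), _est(1.0, 0.1))
        assert out.theta == pytest.approx(0.5)
        assert out.theta_se == pytest.approx(0.05)

    def test_zero_gamma_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(_est(0.0, 0.1), _est(1.0, 0.1))

    def test_weak_instrument_warning_attached(self):
        out = wald_ratio(_est(0.1, 0.2), _est(1.0, 0.1))
        assert any("weak instrument" in w for w in out.warnings)

    @given(
        big_gamma=hst.floats(-2, 2),
        gamma=hst.floats(0.2, 3),
        se_g=hst.floats(0.001, 0.5),
        se_G=hst.floats(0.001, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_direction_flip_inverts_or_and_se_orders(self, big_gamma, gamma, se_g, se_G):
        inc = wald_ratio(_est(gamma, se_g), _est(big_gamma, se_G), direction="increase")
        dec = wald_ratio(_est(gamma, se_g), _est(big_gamma, se_G), direction="decrease")
        assert dec.odds_ratio == pytest.approx(1.0 / inc.odds_ratio, rel=1e-12)
        assert inc.ci_low < inc.odds_ratio < inc.ci_high
        first = wald_ratio(
            _est(gamma, se_g), _est(big_gamma, se_G), second_order=False
        ).theta_se
        assert first <= inc.theta_se + 1e-15

    @given(d=hst.floats(0.01, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_or_monotone_in_big_gamma(self, d):
        lo = wald_ratio(_est(2.0, 0.1), _est(0.5, 0.1), direction="increase")
        hi = wald_ratio(_est(2.0, 0.1), _est(0.5 + d, 0.1), direction="increase")
        assert hi.odds_ratio > lo.odds_ratio


@pytest.fixture(scope="module")
def cohort_iv():
    cfg = SimulationConfig(
        n_individuals=12_000,
        variants=[VariantSpec(id=f"v{j}", maf=0.3, beta=0.3) for j in range(3)],
        exposure=ExposureSpec(noise_sd=1.2, confounder_effect=0.0),
        biomarkers={
            "bmi": dict(intercept=27.0, loading=0.0, noise_sd=4.5),
        },
        outcomes={
            "y1": OutcomeSpec(
                baseline_log_odds=-2.5, theta=ThetaSpec(kind="constant", value=0.3),
                prevalent_fraction=0.02,
            ),
            "y2": OutcomeSpec(
                baseline_log_odds=-2.0, theta=ThetaSpec(kind="constant", value=0.0)
            ),
        },
        seed=55,
    )
    cohort = simulate_cohort(cfg)
    iv = _ivset({"v0": 0.3, "v1": 0.3, "v2": 0.3})
    return cohort, iv


class TestLinearMr:
    def test_one_row_per_outcome(self, cohort_iv):
        cohort, iv = cohort_iv
        table = linear_mr(cohort, iv, ["y1", "y2"], scale=1.0)
        assert list(table["outcome"]) == ["y1", "y2"]
        assert (table["n_cases"] + table["n_controls"] == table["n"]).all()

    def test_prevalent_cases_excluded_per_outcome(self, cohort_iv):
        cohort, iv = cohort_iv
        table = linear_mr(cohort, iv, ["y1", "y2"], scale=1.0)
        n_prev = int(cohort.phenotypes["prevalent_y1"].sum())
        assert table.loc[0, "n"] == cohort.n - n_prev
        assert table.loc[1, "n"] == cohort.n

    def test_bmi_adjustment_invariant_when_bmi_independent(self, cohort_iv):
        cohort, iv = cohort_iv
        plain = linear_mr(cohort, iv, ["y1"], scale=1.0)
        adj = linear_mr(cohort, iv, ["y1"], extra_adjust=["bmi"], scale=1.0)
        assert np.log(adj["OR"].iloc[0]) == pytest.approx(
            np.log(plain["OR"].iloc[0]), abs=0.05
        )

    def test_positive_effect_reports_protective_or_per_decrease(self, cohort_iv):
        cohort, iv = cohort_iv
        table = linear_mr(cohort, iv, ["y1"], scale=1.0, direction="decrease")
        assert table["OR"].iloc[0] < 1.0
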