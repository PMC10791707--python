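"""Weighted genetic score and ratio-of-coefficients (Wald) causal estimation.

The score for individual i is GeneticScore_i = Σ_k β_k g_ik, with g_ik the
effect-allele count and β_k the exposure-GWAS coefficient. Used as a single
instrument, the causal log-odds per exposure unit is estimated as the ratio
Γ/γ of the score→outcome (logistic) and score→exposure (OLS) coefficients;
for uncorrelated valid instruments this is asymptotically the same as the
inverse-variance-weighted combination of per-variant Wald ratios.

Reporting convention: ``theta`` is always log-odds per one-unit *increase*
in the exposure; odds ratios are reported on a configurable scale (default
0.1 exposure units) and direction (default per-decrease, matching the
pharmacological framing of an exposure-lowering intervention) via a sign
flip applied only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import EffectEstimate, RegressionError, build_design, logit_effect, ols_effect
from .cohort import Cohort
from .gwas import filter_cohort, variant_association
from .instruments import InstrumentSet

__all__ = [
    "WaldEstimate",
    "compute_score",
    "score_exposure_effect",
    "score_outcome_effect",
    "wald_ratio",
    "linear_mr",
    "per_variant_ivw",
]

DEFAULT_SCALE = 0.1  # exposure units per reported unit (0.1 mg/dL for urate)


@dataclass
class WaldEstimate:
    """Ratio estimate with delta-method uncertainty, on a declared scale."""

    gamma: float
    gamma_se: float
    big_gamma: float
    big_gamma_se: float
    theta: float  # log-odds per exposure-unit increase
    theta_se: float
    scale: float = DEFAULT_SCALE
    direction: str = "decrease"  # {"increase", "decrease"}
    odds_ratio: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    p_value: float = np.nan
    warnings: list[str] = field(default_factory=list)

    @property
    def sign(self) -> int:
        return -1 if self.direction == "decrease" else 1


def compute_score(
    genotypes: pd.DataFrame,
    ivset: InstrumentSet,
    missing_policy: str = "drop",
) -> pd.Series:
    """Per-individual weighted allele score Σ_k β_k g_ik (exact inner product).

    ``missing_policy``: "drop" removes individuals missing any instrument
    dosage; "mean_impute" replaces a missing dosage by the variant's mean.
    """
    missing_vars = [v for v in ivset.variant_ids if v not in genotypes.columns]
    if missing_vars:
        raise ValueError(f"instrument variant(s) absent from genotype matrix: {missing_vars}")
    sub = genotypes[ivset.variant_ids].astype(float)
    if sub.isna().any().any():
        if missing_policy == "drop":
            sub = sub.dropna()
        elif missing_policy == "mean_impute":
            sub = sub.fillna(sub.mean())
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")
    w = np.array([ivset.weights[v] for v in ivset.variant_ids])
    return pd.Series(sub.to_numpy() @ w, index=sub.index, name="score")


def score_exposure_effect(
    cohort: Cohort,
    score: pd.Series,
    covariate_names: Sequence[str] = (),
    exposure_name: str = "exposure",
) -> EffectEstimate:
    """OLS of the exposure on the score plus the GWAS covariates (γ)."""
    s = score.reindex(cohort.phenotypes.index)
    if float(s.std(ddof=0)) == 0.0:
        raise RegressionError("score is constant; exposure effect undefined")
    X = build_design(cohort.phenotypes, list(covariate_names))
    X.insert(1, "score", s)
    return ols_effect(cohort.phenotypes[exposure_name], X, term="score")


def score_outcome_effect(
    cohort: Cohort,
    score: pd.Series,
    outcome_name: str,
    covariate_names: Sequence[str] = (),
) -> EffectEstimate:
    """Logistic regression of the binary outcome on the score plus covariates (Γ)."""
    cohort.require_columns([outcome_name])
    s = score.reindex(cohort.phenotypes.index)
    X = build_design(cohort.phenotypes, list(covariate_names))
    X.insert(1, "score", s)
    return logit_effect(cohort.phenotypes[outcome_name], X, term="score")


def wald_ratio(
    gamma_est: EffectEstimate,
    big_gamma_est: EffectEstimate,
    scale: float = DEFAULT_SCALE,
    direction: str = "decrease",
    second_order: bool = True,
    weak_f_floor: float = 10.0,
) -> WaldEstimate:
    """Ratio-of-coefficients estimate θ = Γ/γ with delta-method uncertainty.

    Second-order delta SE (default): se² = se_Γ²/γ² + Γ²·se_γ²/γ⁴; the
    first-order form drops the second term. The odds ratio per reported unit
    is exp(s·θ·scale) with s = −1 for per-decrease reporting; its 95% CI uses
    θ ± 1.96·se, and p is the two-sided normal test of θ/se. A denominator
    z-score γ/se_γ below sqrt(weak_f_floor) attaches a weak-instrument
    warning rather than failing.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    gamma, se_g = gamma_est.beta, gamma_est.se
    big_gamma, se_G = big_gamma_est.beta, big_gamma_est.se
    if gamma == 0:
        raise ZeroDivisionError("score→exposure effect is zero; Wald ratio undefined")
    theta = big_gamma / gamma
    var = se_G**2 / gamma**2
    if second_order:
        var += big_gamma**2 * se_g**2 / gamma**4
    se = float(np.sqrt(var))
    warnings = []
    if se_g > 0 and (gamma / se_g) ** 2 < weak_f_floor:
        warnings.append(
            f"weak instrument: (gamma/se)^2 = {(gamma / se_g) ** 2:.2f} < {weak_f_floor}"
        )
    s = -1 if direction == "decrease" else 1
    odds_ratio = float(np.exp(s * theta * scale))
    lo, hi = sorted(
        (np.exp(s * scale * (theta - 1.96 * se)), np.exp(s * scale * (theta + 1.96 * se)))
    )
    if se > 0:
        p = float(2 * stats.norm.sf(abs(theta) / se))
    else:
        p = 1.0 if theta == 0 else 0.0
    return WaldEstimate(
        gamma=gamma,
        gamma_se=se_g,
        big_gamma=big_gamma,
        big_gamma_se=se_G,
        theta=theta,
        theta_se=se,
        scale=scale,
        direction=direction,
        odds_ratio=odds_ratio,
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=p,
        warnings=warnings,
    )


def linear_mr(
    cohort: Cohort,
    ivset: InstrumentSet,
    outcome_names: Sequence[str],
    covariate_names: Sequence[str] = (),
    extra_adjust: Optional[Sequence[str]] = None,
    scale: float = DEFAULT_SCALE,
    direction: str = "decrease",
    drop_prevalent: bool = True,
) -> pd.DataFrame:
    """Score-based Wald MR for each outcome.

    Per outcome: exclude that outcome's prevalent cases, rebuild the score on
    the retained rows, estimate γ (OLS) and Γ (logistic) with identical
    covariates — the GWAS covariates, plus ``extra_adjust`` (e.g. BMI) in
    both regressions when given — and form the ratio.
    """
    covs = list(covariate_names) + list(extra_adjust or [])
    rows = []
    for outcome in outcome_names:
        sub, _counts = filter_cohort(cohort, outcome, drop_prevalent=drop_prevalent)
        score = compute_score(sub.genotypes, ivset)
        gamma = score_exposure_effect(sub, score, covs)
        big_gamma = score_outcome_effect(sub, score, outcome, covs)
        est = wald_ratio(gamma, big_gamma, scale=scale, direction=direction)
        y = sub.phenotypes[outcome]
        rows.append(
            {
                "outcome": outcome,
                "n": gamma.n_used,
                "n_cases": int(y.sum()),
                "n_controls": int((1 - y).sum()),
                "OR": est.odds_ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p": est.p_value,
                "gamma": est.gamma,
                "gamma_se": est.gamma_se,
                "big_gamma": est.big_gamma,
                "big_gamma_se": est.big_gamma_se,
                "theta": est.theta,
                "theta_se": est.theta_se,
                "flags": ";".join(est.warnings),
            }
        )
    return pd.DataFrame(rows)


def per_variant_ivw(
    cohort: Cohort,
    ivset: InstrumentSet,
    outcome_name: str,
    covariate_names: Sequence[str] = (),
) -> dict[str, float]:
    """Inverse-variance-weighted combination of per-variant Wald ratios.

    θ_k = Γ_k/β_k with first-order se_k = se_{Γ_k}/|β_k|; the IVW estimate is
    Σ θ_k/se_k² / Σ 1/se_k². Serves as the multi-instrument cross-check of
    the score-based single-instrument estimate.
    """
    thetas, ses = [], []
    for vid in ivset.variant_ids:
        assoc = variant_association(cohort, vid, covariate_names)
        dosage = cohort.genotypes[vid].astype(float)
        X = build_design(cohort.phenotypes, list(covariate_names))
        X.insert(1, "dosage", dosage)
        out_est = logit_effect(cohort.phenotypes[outcome_name], X, term="dosage")
        thetas.append(out_est.beta / assoc.beta)
        ses.append(out_est.se / abs(assoc.beta))
    w = 1.0 / np.asarray(ses) ** 2
    theta = float(np.sum(w * np.asarray(thetas)) / np.sum(w))
    return {"theta": theta, "se": float(1.0 / np.sqrt(np.sum(w)))}
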