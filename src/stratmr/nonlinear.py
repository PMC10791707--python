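"""Nonlinear (stratified) MR: stratum-specific Wald estimates and tests.

Individuals are stratified into quantile groups of a stratification variable
(a lipid biomarker, or the exposure itself) by one of three methods:

``observed``
    Quantiles of the raw stratifier. Can induce collider bias if the genetic
    score affects the stratifier.
``residual``
    Quantiles of the stratifier after subtracting the genetic-score effect
    and covariate effects (intercept retained, so residuals keep their
    location). Assumes the genetic effect on the exposure is constant.
``doubly_ranked``
    Rank by score into consecutive pre-strata of size J, then within each
    pre-stratum rank by the stratifier and send the j-th ranked member to
    stratum j. Relaxes the constant-genetic-effect assumption and is used
    here to test it.

Within each stratum the score→exposure and score→outcome regressions are
re-fit and the Wald ratio formed. Heterogeneity of the stratum effects is
tested by Cochran's Q; nonlinearity by a weighted trend of the stratum
effects on the stratum means of the stratifier (a linear trend in stratum
effects corresponds to a quadratic overall exposure–outcome shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import RegressionError, build_design, ols_full
from .cohort import Cohort, CohortError
from .gwas import filter_cohort
from .instruments import InstrumentSet
from .linearmr import (
    DEFAULT_SCALE,
    WaldEstimate,
    compute_score,
    score_exposure_effect,
    score_outcome_effect,
    wald_ratio,
)

__all__ = [
    "StratumAssignment",
    "StratifiedResult",
    "residual_stratify",
    "doubly_ranked_stratify",
    "observed_stratify",
    "stratum_estimates",
    "cochran_q",
    "trend_test",
    "constant_effect_check",
    "pleiotropy_biomarker_check",
    "run_nonlinear_mr",
]


@dataclass
class StratumAssignment:
    method: str
    stratifier_name: str
    n_strata: int
    index: pd.Series  # per-individual stratum label in 0..n_strata-1
    summary: pd.DataFrame  # per-stratum n, mean/min/max of the observed stratifier

    def members(self, j: int) -> pd.Index:
        return self.index.index[self.index == j]


@dataclass
class StratifiedResult:
    assignment: StratumAssignment
    estimates: list[Optional[WaldEstimate]]
    cochran: dict
    trend: dict
    constant_effect: Optional[dict] = None
    pleiotropy: Optional[pd.DataFrame] = None
    skipped_strata: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, est in enumerate(self.estimates):
            s = self.assignment.summary.iloc[j]
            row = {
                "stratifier": self.assignment.stratifier_name,
                "method": self.assignment.method,
                "stratum": j + 1,
                "n": int(s["n"]),
                "stratifier_mean": s["mean"],
                "stratifier_min": s["min"],
                "stratifier_max": s["max"],
            }
            if est is None:
                row.update({"OR": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan})
            else:
                row.update(
                    {"OR": est.odds_ratio, "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "p": est.p_value, "theta": est.theta, "theta_se": est.theta_se}
                )
            rows.append(row)
        return pd.DataFrame(rows)


def _summarise(observed: pd.Series, labels: pd.Series, n_strata: int) -> pd.DataFrame:
    rows = []
    for j in range(n_strata):
        vals = observed[labels == j]
        rows.append(
            {"stratum": j, "n": len(vals), "mean": float(vals.mean()),
             "min": float(vals.min()), "max": float(vals.max())}
        )
    return pd.DataFrame(rows)


def _check_n_strata(n: int, n_strata: int, min_stratum_size: int = 10) -> None:
    if n_strata < 2:
        raise ValueError("need at least 2 strata")
    if n_strata * min_stratum_size > n:
        raise ValueError(
            f"{n_strata} strata for n={n} refused "
            f"(fewer than {min_stratum_size} per stratum; lower min_stratum_size to override)"
        )


def _rank_chunks(values: pd.Series, n_strata: int) -> pd.Series:
    """Equal-size quantile groups by stable sort on (value, individual ID).

    Sizes differ by at most one; ties at quantile boundaries are broken by
    individual ID, making membership deterministic.
    """
    order = values.sort_values(kind="mergesort").index  # index breaks ties
    labels = pd.Series(0, index=order, dtype=int)
    for j, chunk in enumerate(np.array_split(np.arange(len(order)), n_strata)):
        labels.iloc[chunk] = j
    return labels.reindex(values.index)


def observed_stratify(
    cohort: Cohort, stratifier_name: str, n_strata: int = 4, min_stratum_size: int = 10
) -> StratumAssignment:
    """Quantile strata of the raw stratifier (no collider-bias protection)."""
    cohort.require_columns([stratifier_name])
    obs = cohort.phenotypes[stratifier_name].astype(float)
    _check_n_strata(len(obs), n_strata, min_stratum_size)
    labels = _rank_chunks(obs, n_strata)
    return StratumAssignment(
        "observed", stratifier_name, n_strata, labels, _summarise(obs, labels, n_strata)
    )


def residual_stratify(
    cohort: Cohort,
    stratifier_name: str,
    score: pd.Series,
    covariate_names: Sequence[str] = (),
    n_strata: int = 4,
    min_stratum_size: int = 10,
) -> StratumAssignment:
    """Quantile strata of the stratifier residual given score and covariates.

    The residual subtracts the fitted score and covariate contributions but
    keeps the intercept, so residuals preserve the stratifier's location.
    Observed-value ranges may therefore overlap across strata.
    """
    cohort.require_columns([stratifier_name])
    obs = cohort.phenotypes[stratifier_name].astype(float)
    if float(obs.std(ddof=0)) == 0.0:
        raise CohortError(f"stratifier {stratifier_name!r} is constant")
    _check_n_strata(len(obs), n_strata, min_stratum_size)
    X = build_design(cohort.phenotypes, list(covariate_names))
    X.insert(1, "score", score.reindex(cohort.phenotypes.index))
    res, used_idx = ols_full(obs, X)
    intercept = float(res.params[list(X.columns).index("const")])
    residual = pd.Series(res.resid + intercept, index=used_idx)
    labels = _rank_chunks(residual, n_strata)
    return StratumAssignment(
        "residual",
        stratifier_name,
        n_strata,
        labels,
        _summarise(obs.loc[used_idx], labels, n_strata),
    )


def doubly_ranked_stratify(
    cohort: Cohort,
    score: pd.Series,
    stratifier_name: str,
    n_strata: int = 4,
    min_stratum_size: int = 10,
) -> StratumAssignment:
    """Two-stage ranking: score pre-strata, then stratifier rank within each.

    Individuals are sorted by score (ties by ID), cut into consecutive
    pre-strata of size ``n_strata``; within each pre-stratum they are sorted
    by stratifier (ties by ID) and the j-th ranked member joins stratum j.
    A final partial pre-stratum distributes its members, in stratifier
    order, to the lowest-indexed strata.
    """
    cohort.require_columns([stratifier_name])
    obs = cohort.phenotypes[stratifier_name].astype(float)
    _check_n_strata(len(obs), n_strata, min_stratum_size)
    s = score.reindex(cohort.phenotypes.index)
    order = s.sort_values(kind="mergesort").index
    labels = pd.Series(-1, index=cohort.phenotypes.index, dtype=int)
    for start in range(0, len(order), n_strata):
        pre = order[start : start + n_strata]
        ranked = obs.loc[pre].sort_values(kind="mergesort").index
        for j, iid in enumerate(ranked):
            labels.loc[iid] = j
    return StratumAssignment(
        "doubly_ranked", stratifier_name, n_strata, labels, _summarise(obs, labels, n_strata)
    )


def stratum_estimates(
    cohort: Cohort,
    assignment: StratumAssignment,
    ivset: InstrumentSet,
    outcome_name: str,
    covariate_names: Sequence[str] = (),
    scale: float = DEFAULT_SCALE,
    direction: str = "decrease",
) -> tuple[list[Optional[WaldEstimate]], list[int]]:
    """Re-fit both score regressions within each stratum; Wald ratio each.

    Strata whose outcome has a single class (or where a fit degenerates) get
    ``None`` and are listed in the returned ``skipped`` indices; tests
    downstream exclude them with a warning.
    """
    estimates: list[Optional[WaldEstimate]] = []
    skipped: list[int] = []
    for j in range(assignment.n_strata):
        members = assignment.members(j)
        sub = cohort.subset(members)
        try:
            score = compute_score(sub.genotypes, ivset)
            gamma = score_exposure_effect(sub, score, covariate_names)
            big_gamma = score_outcome_effect(sub, score, outcome_name, covariate_names)
            estimates.append(
                wald_ratio(gamma, big_gamma, scale=scale, direction=direction)
            )
        except (RegressionError, ZeroDivisionError):
            estimates.append(None)
            skipped.append(j)
    return estimates, skipped


def cochran_q(estimates: Sequence[dict | WaldEstimate]) -> dict:
    """Cochran's Q homogeneity test on effect estimates.

    With weights w_j = 1/se_j² and pooled θ̄ = Σw_jθ_j/Σw_j,
    Q = Σ w_j (θ_j − θ̄)², compared to chi-square with J−1 df.
    """
    thetas, ses = _extract(estimates)
    if len(thetas) < 2:
        raise ValueError("Cochran's Q needs at least 2 usable estimates")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * thetas) / np.sum(w))
    q = float(np.sum(w * (thetas - pooled) ** 2))
    df = len(thetas) - 1
    return {"q": q, "df": df, "p": float(stats.chi2.sf(q, df)), "pooled_theta": pooled}


def _extract(estimates: Sequence[dict | WaldEstimate]) -> tuple[np.ndarray, np.ndarray]:
    thetas, ses = [], []
    for e in estimates:
        if e is None:
            continue
        if isinstance(e, WaldEstimate):
            t, s = e.theta, e.theta_se
        else:
            t, s = e["theta"], e["se"]
        if np.isfinite(t) and np.isfinite(s) and s > 0:
            thetas.append(t)
            ses.append(s)
    return np.asarray(thetas), np.asarray(ses)


def trend_test(
    estimates: Sequence[dict | WaldEstimate],
    stratum_means: Sequence[float],
) -> dict:
    """Weighted trend of stratum effects on the stratifier's stratum means.

    WLS of θ_j on m_j with weights 1/se_j²; ``p_trend`` is the two-sided
    normal test of the linear slope. With ≥ 4 strata a quadratic model
    (m_j and m_j²) is also fit and its quadratic coefficient reported.
    """
    thetas, ses = _extract(estimates)
    m = np.asarray(stratum_means, dtype=float)
    if len(thetas) != len(m):
        raise ValueError("estimates and stratum means are misaligned")
    if len(thetas) < 3:
        raise ValueError("trend test needs at least 3 strata with usable estimates")
    w = 1.0 / ses**2
    X = np.column_stack([np.ones_like(m), m])
    beta, cov = _wls(X, thetas, w)
    slope, slope_se = beta[1], np.sqrt(cov[1, 1])
    p_trend = float(2 * stats.norm.sf(abs(slope) / slope_se)) if slope_se > 0 else (
        1.0 if slope == 0 else 0.0
    )
    out = {"slope": float(slope), "slope_se": float(slope_se), "p_trend": p_trend}
    if len(thetas) >= 4:
        mc = m - m.mean()
        Xq = np.column_stack([np.ones_like(m), mc, mc**2])
        bq, covq = _wls(Xq, thetas, w)
        q_se = float(np.sqrt(covq[2, 2]))
        out.update(
            {
                "quadratic": float(bq[2]),
                "quadratic_se": q_se,
                "p_quadratic": float(2 * stats.norm.sf(abs(bq[2]) / q_se))
                if q_se > 0
                else 1.0,
            }
        )
    return out


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sw = np.sqrt(w)
    Xw, yw = X * sw[:, None], y * sw
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta = xtx_inv @ (Xw.T @ yw)
    # fixed known variances (1/w): covariance is (X'WX)^-1
    return beta, xtx_inv


def constant_effect_check(
    cohort: Cohort,
    assignment: StratumAssignment,
    ivset: InstrumentSet,
    covariate_names: Sequence[str] = (),
    alpha: float = 0.05,
) -> dict:
    """Test the constant-genetic-effect assumption via doubly-ranked strata.

    The score→exposure coefficient γ_j is re-estimated per doubly-ranked
    stratum and compared by Cochran's Q. A small p signals that the genetic
    effect varies across the stratifier, invalidating residual-based
    stratification.
    """
    if assignment.method != "doubly_ranked":
        raise ValueError("constant-effect check requires a doubly-ranked assignment")
    if assignment.n_strata < 2:
        raise ValueError("need at least 2 strata")
    gammas = []
    for j in range(assignment.n_strata):
        sub = cohort.subset(assignment.members(j))
        score = compute_score(sub.genotypes, ivset)
        est = score_exposure_effect(sub, score, covariate_names)
        gammas.append({"theta": est.beta, "se": est.se})
    het = cochran_q(gammas)
    return {
        "gammas": [g["theta"] for g in gammas],
        "gamma_ses": [g["se"] for g in gammas],
        "q": het["q"],
        "df": het["df"],
        "p": het["p"],
        "passed": bool(het["p"] >= alpha),
    }


def pleiotropy_biomarker_check(
    cohort: Cohort,
    score: pd.Series,
    biomarker_names: Sequence[str],
    covariate_names: Sequence[str] = (),
) -> pd.DataFrame:
    """Score→biomarker associations as evidence against lipid pleiotropy."""
    cohort.require_columns(biomarker_names)
    rows = []
    for name in biomarker_names:
        obs = cohort.phenotypes[name].astype(float)
        if float(obs.std(ddof=0)) == 0.0:
            rows.append({"biomarker": name, "beta": np.nan, "se": np.nan, "p": np.nan,
                         "status": "degenerate: constant biomarker"})
            continue
        est = score_exposure_effect(cohort, score, covariate_names, exposure_name=name)
        rows.append({"biomarker": name, "beta": est.beta, "se": est.se,
                     "p": est.p_value, "status": "ok"})
    return pd.DataFrame(rows)


def run_nonlinear_mr(
    cohort: Cohort,
    ivset: InstrumentSet,
    outcome_name: str,
    stratifier_name: str,
    covariate_names: Sequence[str] = (),
    n_strata: int = 4,
    method: str = "residual",
    scale: float = DEFAULT_SCALE,
    direction: str = "decrease",
    alpha: float = 0.05,
    drop_prevalent: bool = True,
) -> StratifiedResult:
    """Full stratified analysis for one outcome and one stratifier.

    Excludes the outcome's prevalent cases, stratifies by the requested
    method, estimates a Wald ratio per stratum, and runs Cochran's Q, the
    trend test, and (always via doubly-ranked strata) the
    constant-genetic-effect check.
    """
    sub, _ = filter_cohort(cohort, outcome_name, drop_prevalent=drop_prevalent)
    score = compute_score(sub.genotypes, ivset)
    if method == "residual":
        assignment = residual_stratify(sub, stratifier_name, score, covariate_names, n_strata)
    elif method == "doubly_ranked":
        assignment = doubly_ranked_stratify(sub, score, stratifier_name, n_strata)
    elif method == "observed":
        assignment = observed_stratify(sub, stratifier_name, n_strata)
    else:
        raise ValueError(f"unknown stratification method {method!r}")
    estimates, skipped = stratum_estimates(
        sub, assignment, ivset, outcome_name, covariate_names, scale, direction
    )
    usable = [e for e in estimates if e is not None]
    het = cochran_q(usable) if len(usable) >= 2 else {"q": np.nan, "df": 0, "p": np.nan}
    means = [
        assignment.summary.iloc[j]["mean"]
        for j, e in enumerate(estimates)
        if e is not None
    ]
    trend = (
        trend_test(usable, means)
        if len(usable) >= 3
        else {"slope": np.nan, "slope_se": np.nan, "p_trend": np.nan}
    )
    dr = doubly_ranked_stratify(sub, score, stratifier_name, n_strata)
    cec = constant_effect_check(sub, dr, ivset, covariate_names, alpha=alpha)
    return StratifiedResult(
        assignment=assignment,
        estimates=estimates,
        cochran=het,
        trend=trend,
        constant_effect=cec,
        skipped_strata=skipped,
    )
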