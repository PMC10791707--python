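"""Thin wrappers over statsmodels shared by the GWAS, scoring and MR stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class RegressionError(ValueError):
    pass


class RankDeficientError(RegressionError):
    """Design matrix is rank deficient; names the offending columns."""


@dataclass
class EffectEstimate:
    """A single regression coefficient with its uncertainty."""

    term: str
    beta: float
    se: float
    p_value: float
    n_used: int

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)


def build_design(
    phenotypes: pd.DataFrame, covariate_names: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Covariate design matrix with intercept.

    Categorical/object columns are one-hot encoded with the first level as
    reference; numeric columns pass through unchanged.
    """
    parts = [pd.Series(1.0, index=phenotypes.index, name="const")]
    for name in covariate_names:
        if name not in phenotypes.columns:
            raise RegressionError(f"unknown covariate column {name!r}")
        col = phenotypes[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            parts.append(dummies)
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    # identify offenders: zero-variance columns and (near-)perfectly
    # correlated pairs among the non-constant columns
    offenders: list[str] = []
    nonconst = [c for c in X.columns if c != "const"]
    for c in nonconst:
        if np.nanstd(X[c].to_numpy(dtype=float)) == 0:
            offenders.append(c)
    corr = X[nonconst].corr().abs()
    for i, a in enumerate(nonconst):
        for b in nonconst[i + 1 :]:
            if corr.loc[a, b] > 1 - 1e-10:
                offenders.extend([a, b])
    raise RankDeficientError(
        f"design matrix is rank deficient; collinear column(s): {sorted(set(offenders))}"
    )


def ols_effect(
    y: pd.Series, X: pd.DataFrame, term: str, check_rank: bool = True
) -> EffectEstimate:
    """OLS of ``y`` on ``X``; returns the coefficient of ``term``.

    Complete-case: rows with any missing regressor or response are dropped.
    Two-sided p from the t distribution with residual degrees of freedom.
    """
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n = len(frame)
    if n <= X.shape[1]:
        raise RegressionError(f"only {n} complete rows for {X.shape[1]} regressors")
    Xc = frame[X.columns]
    if check_rank:
        _check_rank(Xc)
    res = sm.OLS(frame["__y__"].to_numpy(dtype=float), Xc.to_numpy(dtype=float)).fit()
    idx = list(X.columns).index(term)
    return EffectEstimate(
        term=term,
        beta=float(res.params[idx]),
        se=float(res.bse[idx]),
        p_value=float(res.pvalues[idx]),
        n_used=n,
    )


def ols_full(y: pd.Series, X: pd.DataFrame):
    """Full statsmodels OLS results on complete cases (for R², residuals)."""
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    res = sm.OLS(
        frame["__y__"].to_numpy(dtype=float), frame[X.columns].to_numpy(dtype=float)
    ).fit()
    return res, frame.index


def logit_effect(y: pd.Series, X: pd.DataFrame, term: str) -> EffectEstimate:
    """Maximum-likelihood logistic regression; coefficient of ``term``.

    Newton fit, log-likelihood tolerance 1e-8, at most 100 iterations.
    Raises on a single-class response or (quasi-)perfect separation.
    """
    frame = pd.concat([y.rename("__y__"), X], axis=1).dropna()
    n = len(frame)
    yv = frame["__y__"].to_numpy(dtype=float)
    classes = np.unique(yv)
    if not np.isin(classes, [0.0, 1.0]).all():
        raise RegressionError("outcome must be binary 0/1")
    if len(classes) < 2:
        raise RegressionError("outcome has a single class among used rows")
    Xc = frame[X.columns]
    _check_rank(Xc)
    model = sm.Logit(yv, Xc.to_numpy(dtype=float))
    try:
        res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
    except Exception as exc:  # statsmodels raises PerfectSeparationError subclasses
        raise RegressionError(f"logistic fit failed ({exc})") from exc
    idx = list(X.columns).index(term)
    se = float(res.bse[idx])
    if not np.isfinite(se) or se > 1e6:
        raise RegressionError(
            f"logistic fit is degenerate for term {term!r} (possible separation)"
        )
    return EffectEstimate(
        term=term,
        beta=float(res.params[idx]),
        se=se,
        p_value=float(res.pvalues[idx]),
        n_used=n,
    )
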