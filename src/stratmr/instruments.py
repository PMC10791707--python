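"""Instrument selection: LD clumping, pleiotropy exclusion, strength, controls.

Selection follows the cis (drug-target) MR recipe: restrict to the gene
region (done upstream), keep variants passing a significance threshold
(genome-wide 5e-8 or a gene-specific Bonferroni 0.05/#variants), greedily
clump so all retained pairs have in-sample dosage r² below a threshold, and
drop caller-supplied potentially pleiotropic variants. Instrument strength is
summarised by the incremental R² and joint F of the selected dosages over the
covariate-only exposure model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._regression import RegressionError, build_design, ols_effect, ols_full
from .cohort import Cohort
from .gwas import VariantAssociation

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "GENOME_WIDE_P",
    "gene_bonferroni_threshold",
    "clump",
    "apply_exclusion_list",
    "instrument_strength",
    "negative_control_check",
    "read_exclusion_list",
]

#: conventional genome-wide significance level
GENOME_WIDE_P = 5e-8


def gene_bonferroni_threshold(n_variants_in_region: int, alpha: float = 0.05) -> float:
    """Gene-specific Bonferroni level alpha / (variants tested in the region).

    With 5279 variants in the region this reproduces 9.47e-6.
    """
    if n_variants_in_region < 1:
        raise ValueError("need at least one variant in the region")
    return alpha / n_variants_in_region


@dataclass
class InstrumentSet:
    """Selected variants with their genetic-score weights (the GWAS betas)."""

    variant_ids: list[str]
    weights: dict[str, float]
    p_threshold: float
    r2_threshold: float
    f_statistic: Optional[float] = None
    r_squared: Optional[float] = None
    status: str = "ok"
    notes: list[str] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.variant_ids) == 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "variant_ids": self.variant_ids,
                "weights": self.weights,
                "p_threshold": self.p_threshold,
                "r2_threshold": self.r2_threshold,
                "f_statistic": self.f_statistic,
                "r_squared": self.r_squared,
                "status": self.status,
                "notes": self.notes,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "InstrumentSet":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            variant_ids=d["variant_ids"],
            weights=d["weights"],
            p_threshold=d["p_threshold"],
            r2_threshold=d["r2_threshold"],
            f_statistic=d.get("f_statistic"),
            r_squared=d.get("r_squared"),
            status=d.get("status", "ok"),
            notes=d.get("notes", []),
        )


def clump(
    associations: Sequence[VariantAssociation],
    genotypes: pd.DataFrame,
    p_threshold: float,
    r2_threshold: float,
) -> InstrumentSet:
    """Greedy p-value-ordered LD clumping on in-sample dosage correlations.

    Significant variants are taken best-p first; each pick discards every
    remaining variant whose squared Pearson dosage correlation with it is
    ≥ ``r2_threshold``. Ties on p break lexicographically by variant ID. An
    empty result is reported via ``status`` rather than an exception.
    """
    if not (0 < p_threshold <= 1) or not (0 < r2_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    usable = [a for a in associations if a.usable and a.p_value < p_threshold]
    for a in usable:
        if a.variant_id not in genotypes.columns:
            raise ValueError(f"no genotype column for {a.variant_id!r}")
    if not usable:
        return InstrumentSet(
            [], {}, p_threshold, r2_threshold, status="empty: no variant passes p threshold"
        )
    remaining = sorted(usable, key=lambda a: (a.p_value, a.variant_id))
    kept: list[VariantAssociation] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        g_best = genotypes[best.variant_id].astype(float)
        survivors = []
        for a in remaining:
            r = g_best.corr(genotypes[a.variant_id].astype(float))
            r2 = 0.0 if np.isnan(r) else r * r
            if r2 < r2_threshold:
                survivors.append(a)
        remaining = survivors
    return InstrumentSet(
        variant_ids=[a.variant_id for a in kept],
        weights={a.variant_id: a.beta for a in kept},
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
    )


def apply_exclusion_list(
    ivset: InstrumentSet, excluded_variant_ids: Iterable[str]
) -> InstrumentSet:
    """Drop caller-supplied (potentially pleiotropic) variants from the set."""
    excluded = set(excluded_variant_ids)
    unknown = excluded - set(ivset.variant_ids)
    if unknown:
        logger.warning("exclusion list entries not in instrument set: %s", sorted(unknown))
    kept = [v for v in ivset.variant_ids if v not in excluded]
    status = "ok" if kept else "empty: all variants excluded"
    return InstrumentSet(
        variant_ids=kept,
        weights={v: ivset.weights[v] for v in kept},
        p_threshold=ivset.p_threshold,
        r2_threshold=ivset.r2_threshold,
        status=status,
        notes=ivset.notes + [f"excluded {len(excluded & set(ivset.variant_ids))} variant(s)"],
    )


def read_exclusion_list(path: str | Path) -> list[str]:
    """Plain-text exclusion list, one variant ID per line; '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def instrument_strength(
    cohort: Cohort,
    ivset: InstrumentSet,
    covariate_names: Sequence[str] = (),
    exposure_name: str = "exposure",
) -> dict[str, float]:
    """Incremental R² and joint F of the instruments in the exposure model.

    R² is the variance explained by the k dosages over the covariate-only
    model; F = ((R²_full − R²_cov)/k) / ((1 − R²_full)/(n − p_full)) with
    p_full counting all regressors including the intercept. A perfect fit
    reports F = +inf.
    """
    if ivset.is_empty:
        raise ValueError("instrument set is empty")
    y = cohort.phenotypes[exposure_name]
    X_cov = build_design(cohort.phenotypes, list(covariate_names))
    X_full = X_cov.copy()
    for vid in ivset.variant_ids:
        X_full[vid] = cohort.genotypes[vid].astype(float)

    sub = X_full[ivset.variant_ids]
    corr = sub.corr().abs().to_numpy()
    k = len(ivset.variant_ids)
    for i in range(k):
        for j in range(i + 1, k):
            if corr[i, j] > 1 - 1e-10:
                raise RegressionError(
                    "collinear instruments: "
                    f"{ivset.variant_ids[i]!r} and {ivset.variant_ids[j]!r}"
                )

    res_cov, idx_cov = ols_full(y, X_cov)
    res_full, idx_full = ols_full(y, X_full)
    r2_cov = float(res_cov.rsquared) if X_cov.shape[1] > 1 else 0.0
    r2_full = float(res_full.rsquared)
    n = len(idx_full)
    p_full = X_full.shape[1]
    incr = r2_full - r2_cov
    denom = (1.0 - r2_full) / (n - p_full)
    f_stat = np.inf if denom <= 0 else (incr / k) / denom
    return {"f_statistic": float(f_stat), "r_squared": float(incr), "n_used": n}


def negative_control_check(
    cohort: Cohort,
    score: pd.Series,
    control_names: Sequence[str] = ("age", "sex"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Association of negative-control traits (age, sex) with the score.

    Unadjusted OLS of each control on the score. A significant association is
    flagged (``passed = False``): it signals possible collider/selection bias
    in instrument construction, but the pipeline is not halted. A constant
    score yields a degenerate flagged row.
    """
    cohort.require_columns(control_names)
    rows = []
    degenerate = float(pd.Series(score).std(ddof=0)) == 0.0
    for name in control_names:
        if degenerate:
            rows.append(
                {"control": name, "beta": np.nan, "se": np.nan, "p": np.nan,
                 "passed": False, "status": "degenerate: constant score"}
            )
            continue
        X = pd.DataFrame({"const": 1.0, "score": score}, index=score.index)
        est = ols_effect(cohort.phenotypes[name].astype(float), X, term="score")
        rows.append(
            {"control": name, "beta": est.beta, "se": est.se, "p": est.p_value,
             "passed": bool(est.p_value >= alpha), "status": "ok"}
        )
    return pd.DataFrame(rows)
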