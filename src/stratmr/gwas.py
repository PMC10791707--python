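"""Per-variant exposure GWAS with covariate adjustment and row filtering.

The association model is ordinary least squares of the continuous exposure on
each variant's dosage plus the configured covariates (age, sex, ancestry PCs,
genotyping batch, assessment centre in the emulated design). Individuals
flagged as diagnosed before exposure measurement are excluded beforehand so
treatment cannot distort the dosage–exposure association.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._regression import EffectEstimate, RegressionError, build_design, ols_effect
from .cohort import Cohort, CohortError

logger = logging.getLogger(__name__)

__all__ = [
    "VariantAssociation",
    "filter_cohort",
    "variant_association",
    "run_region_gwas",
    "write_gwas_tsv",
    "read_gwas_tsv",
]


@dataclass
class VariantAssociation:
    """Effect of one variant's dosage on the exposure.

    ``beta`` is in exposure units per effect allele and doubles as the
    genetic-score weight downstream. ``status`` is "ok" for a usable fit;
    flagged records ("monomorphic", "error: ...") carry NaN estimates and are
    skipped by instrument selection.
    """

    variant_id: str
    beta: float
    se: float
    p_value: float
    allele_freq: float
    n_used: int
    status: str = "ok"

    @property
    def usable(self) -> bool:
        return self.status == "ok" and np.isfinite(self.beta) and self.se > 0


def filter_cohort(
    cohort: Cohort,
    outcome_name: Optional[str] = None,
    drop_prevalent: bool = True,
    qc_flags: Optional[Sequence[str]] = None,
) -> tuple[Cohort, dict[str, int]]:
    """Drop rows failing any requested filter; report counts per filter.

    ``drop_prevalent`` removes individuals whose ``prevalent_<outcome>`` flag
    is set (diagnosed before exposure measurement). ``qc_flags`` are boolean
    phenotype columns where a truthy value marks the row for exclusion.
    Per-filter counts are marginal; the total removed is the union.
    """
    pheno = cohort.phenotypes
    masks: dict[str, pd.Series] = {}
    if drop_prevalent and outcome_name is not None:
        col = f"prevalent_{outcome_name}"
        if outcome_name not in pheno.columns or col not in pheno.columns:
            raise CohortError(f"unknown outcome {outcome_name!r} or missing {col!r}")
        masks["prevalent"] = pheno[col].astype(bool)
    for flag in qc_flags or []:
        if flag not in pheno.columns:
            raise CohortError(f"unknown QC flag column {flag!r}")
        masks[flag] = pheno[flag].astype(bool)

    counts = {name: int(mask.sum()) for name, mask in masks.items()}
    if masks:
        drop = np.logical_or.reduce([m.to_numpy() for m in masks.values()])
    else:
        drop = np.zeros(cohort.n, dtype=bool)
    counts["total_removed"] = int(drop.sum())
    kept = pheno.index[~drop]
    for name, c in counts.items():
        logger.info("filter %s removed %d rows", name, c)
    return cohort.subset(kept), counts


def variant_association(
    cohort: Cohort,
    variant_id: str,
    covariate_names: Sequence[str] = (),
    exposure_name: str = "exposure",
) -> VariantAssociation:
    """OLS of the exposure on one variant's dosage plus covariates.

    Complete-case over all regressors; two-sided p from the t distribution
    with residual degrees of freedom. Monomorphic variants return a flagged
    record rather than raising, so a region scan never aborts.
    """
    if variant_id not in cohort.genotypes.columns:
        raise CohortError(f"unknown variant {variant_id!r}")
    cohort.require_columns([exposure_name, *covariate_names])
    dosage = cohort.genotypes[variant_id].astype(float)
    X = build_design(cohort.phenotypes, list(covariate_names))
    X.insert(1, "dosage", dosage)
    y = cohort.phenotypes[exposure_name]

    used = pd.concat([y, X], axis=1).dropna()
    af = float(used["dosage"].mean() / 2.0) if len(used) else np.nan
    if used["dosage"].nunique() < 2:
        return VariantAssociation(
            variant_id, np.nan, np.nan, np.nan, af, len(used), status="monomorphic"
        )
    est = ols_effect(y, X, term="dosage")
    return VariantAssociation(
        variant_id=variant_id,
        beta=est.beta,
        se=est.se,
        p_value=est.p_value,
        allele_freq=af,
        n_used=est.n_used,
    )


def run_region_gwas(
    cohort: Cohort,
    variant_ids: Sequence[str],
    covariate_names: Sequence[str] = (),
    exposure_name: str = "exposure",
) -> list[VariantAssociation]:
    """One association per variant in the region, same row filter for all.

    Per-variant failures become flagged records; the scan never aborts.
    """
    if len(variant_ids) == 0:
        raise CohortError("empty variant region")
    out = []
    for vid in variant_ids:
        try:
            out.append(variant_association(cohort, vid, covariate_names, exposure_name))
        except (RegressionError, CohortError) as exc:
            out.append(
                VariantAssociation(
                    vid, np.nan, np.nan, np.nan, np.nan, 0, status=f"error: {exc}"
                )
            )
    return out


def write_gwas_tsv(associations: Sequence[VariantAssociation], path: str | Path) -> None:
    rows = [
        {
            "variant_id": a.variant_id,
            "effect_allele": "ALT",
            "beta": a.beta,
            "se": a.se,
            "p": a.p_value,
            "af": a.allele_freq,
            "n": a.n_used,
            "status": a.status,
        }
        for a in associations
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> list[VariantAssociation]:
    df = pd.read_csv(path, sep="\t")
    return [
        VariantAssociation(
            variant_id=str(r.variant_id),
            beta=float(r.beta),
            se=float(r.se),
            p_value=float(r.p),
            allele_freq=float(r.af),
            n_used=int(r.n),
            status=str(r.status),
        )
        for r in df.itertuples()
    ]
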