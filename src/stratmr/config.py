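"""Configuration models for the synthetic-cohort simulator and the pipeline.

All simulator randomness flows from ``SimulationConfig.seed`` through named
substreams (see :mod:`stratmr.simulate`), so a config plus a seed pins the
cohort byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator, model_validator


class VariantSpec(BaseModel):
    """One simulated bi-allelic variant.

    ``beta`` is the additive effect of each effect allele on the continuous
    exposure, in exposure units (mg/dL for a urate-like exposure).
    """

    id: str
    maf: float = Field(gt=0.0, le=0.5)
    beta: float = 0.0
    chrom: str = "2"
    pos: int = Field(default=0, ge=0)


class LDBlockSpec(BaseModel):
    """Variants sharing a latent factor; ``rho`` is the latent correlation."""

    variant_ids: list[str]
    rho: float = Field(ge=0.0, lt=1.0)


class CovariateSpec(BaseModel):
    """Demographic/technical covariates emulating a biobank cohort."""

    age_mean: float = 56.54
    age_sd: float = 8.09
    sex_prob: float = Field(default=0.5, gt=0.0, lt=1.0)
    n_pcs: int = Field(default=5, ge=0)
    n_batches: int = Field(default=2, ge=1)
    n_centres: int = Field(default=3, ge=1)
    # Stress switch: per-allele effect of each causal variant on age, used to
    # exercise the negative-control check. Off (0) by default so genotype is
    # independent of age.
    age_allele_effect: float = 0.0


class GeneticEffectModifier(BaseModel):
    """Optional violation of the constant-genetic-effect assumption.

    Multiplies every variant's exposure effect by ``1 + kappa * m_i`` where
    ``m_i`` is the standardised independent component of the named biomarker.
    ``kappa = 0`` (default) keeps the genetic effect constant.
    """

    biomarker: str
    kappa: float = 0.0


class ExposureSpec(BaseModel):
    """Continuous exposure model: intercept + genetics + covariates + noise."""

    intercept: float = 5.20
    noise_sd: float = Field(default=1.30, ge=0.0)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    pc_effects: list[float] = Field(default_factory=list)
    confounder_effect: float = 0.0
    genetic_effect_modifier: Optional[GeneticEffectModifier] = None


class BiomarkerSpec(BaseModel):
    """Biomarker = intercept + loading*exposure + covariates + noise.

    With ``log_normal`` the noise component is exponentiated before being
    added, giving a heavier right tail (triglyceride-like); off by default.
    """

    intercept: float
    loading: float = 0.0
    noise_sd: float = Field(ge=0.0)
    age_effect: float = 0.0
    sex_effect: float = 0.0
    confounder_effect: float = 0.0
    log_normal: bool = False


class ThetaSpec(BaseModel):
    """Causal effect of the exposure on an outcome's log-odds.

    ``constant``: a single log-odds per exposure unit. ``piecewise``: one
    value per quantile band of the named modifier biomarker (bands are the
    empirical quantiles of the realised modifier). ``polynomial``: log-odds
    slope evaluated as a polynomial in the standardised modifier.
    """

    kind: Literal["constant", "piecewise", "polynomial"] = "constant"
    value: float = 0.0
    values: list[float] = Field(default_factory=list)
    coeffs: list[float] = Field(default_factory=list)
    modifier: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ThetaSpec":
        if self.kind == "piecewise":
            if not self.values or self.modifier is None:
                raise ValueError("piecewise theta needs `values` and `modifier`")
        if self.kind == "polynomial":
            if not self.coeffs or self.modifier is None:
                raise ValueError("polynomial theta needs `coeffs` and `modifier`")
        return self


class OutcomeSpec(BaseModel):
    """Binary outcome drawn from a logistic model of the exposure."""

    baseline_log_odds: float
    theta: ThetaSpec = Field(default_factory=ThetaSpec)
    confounder_effect: float = 0.0
    prevalent_fraction: float = Field(default=0.0, ge=0.0, lt=1.0)
    # Stress switch: make the prevalent-case flag depend on the exposure
    # (logistic in standardised exposure) instead of being independent.
    prevalent_exposure_effect: float = 0.0


class SimulationConfig(BaseModel):
    """Full recipe for one synthetic cohort."""

    n_individuals: int = Field(ge=1)
    variants: list[VariantSpec]
    ld_blocks: list[LDBlockSpec] = Field(default_factory=list)
    covariates: CovariateSpec = Field(default_factory=CovariateSpec)
    exposure: ExposureSpec = Field(default_factory=ExposureSpec)
    biomarkers: dict[str, BiomarkerSpec] = Field(default_factory=dict)
    outcomes: dict[str, OutcomeSpec] = Field(default_factory=dict)
    missing_rate: float = Field(default=0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @field_validator("variants")
    @classmethod
    def _unique_ids(cls, v: list[VariantSpec]) -> list[VariantSpec]:
        ids = [s.id for s in v]
        if len(set(ids)) != len(ids):
            raise ValueError("variant ids must be unique")
        return v

    @model_validator(mode="after")
    def _check_blocks(self) -> "SimulationConfig":
        known = {s.id for s in self.variants}
        seen: set[str] = set()
        for block in self.ld_blocks:
            for vid in block.variant_ids:
                if vid not in known:
                    raise ValueError(f"LD block references unknown variant {vid!r}")
                if vid in seen:
                    raise ValueError(f"variant {vid!r} appears in more than one LD block")
                seen.add(vid)
        for spec in self.outcomes.values():
            mod = spec.theta.modifier
            if mod is not None and mod not in self.biomarkers and mod != "exposure":
                raise ValueError(f"theta modifier {mod!r} is not a configured biomarker")
        if self.exposure.genetic_effect_modifier is not None:
            b = self.exposure.genetic_effect_modifier.biomarker
            if b not in self.biomarkers:
                raise ValueError(f"genetic-effect modifier {b!r} is not a configured biomarker")
        return self

    def to_json(self, **kwargs) -> str:
        return self.model_dump_json(**kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SimulationConfig":
        return cls.model_validate_json(text)

    def config_hash(self) -> str:
        """Stable SHA-256 over the canonical JSON form (manifest use)."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def demo_simulation_config(n_individuals: int = 20_000, seed: int = 7) -> SimulationConfig:
    """A small biobank-like demo cohort.

    Eight variants in one gene region (two LD blocks plus independents),
    three of them causal for a urate-like exposure; four correlated lipid
    biomarkers and BMI; a gout-like positive-control outcome plus ischemic
    outcomes, one with an effect confined to the top TG quartile.
    """
    variants = [
        VariantSpec(id="rs_a1", maf=0.30, beta=-0.10, pos=31_500_000),
        VariantSpec(id="rs_a2", maf=0.25, beta=0.00, pos=31_520_000),
        VariantSpec(id="rs_b1", maf=0.20, beta=-0.08, pos=31_600_000),
        VariantSpec(id="rs_b2", maf=0.22, beta=0.00, pos=31_610_000),
        VariantSpec(id="rs_c1", maf=0.40, beta=-0.07, pos=31_700_000),
        VariantSpec(id="rs_n1", maf=0.15, beta=0.00, pos=31_800_000),
        VariantSpec(id="rs_n2", maf=0.35, beta=0.00, pos=31_850_000),
        VariantSpec(id="rs_n3", maf=0.10, beta=0.00, pos=31_900_000),
    ]
    blocks = [
        LDBlockSpec(variant_ids=["rs_a1", "rs_a2"], rho=0.85),
        LDBlockSpec(variant_ids=["rs_b1", "rs_b2"], rho=0.60),
    ]
    # lipid-urate correlation flows through the shared confounder (an
    # adiposity-like latent), not through a causal exposure->lipid path, so
    # the genetic score has no effect on the lipids (no horizontal pleiotropy)
    biomarkers = {
        "ldl": BiomarkerSpec(intercept=137.5, confounder_effect=12.0, noise_sd=31.0),
        "hdl": BiomarkerSpec(intercept=56.0, confounder_effect=-5.0, noise_sd=13.8),
        "tg": BiomarkerSpec(intercept=155.0, confounder_effect=30.0, noise_sd=84.0,
                            log_normal=True),
        "tc_hdl": BiomarkerSpec(intercept=4.24, confounder_effect=0.4, noise_sd=1.16),
        "bmi": BiomarkerSpec(intercept=27.0, confounder_effect=1.5, noise_sd=4.2),
    }
    outcomes = {
        "gout": OutcomeSpec(
            baseline_log_odds=-8.5,
            theta=ThetaSpec(kind="constant", value=1.0),
            prevalent_fraction=0.024,
        ),
        "ami": OutcomeSpec(
            baseline_log_odds=-3.6,
            theta=ThetaSpec(kind="piecewise", values=[0.0, 0.0, 0.0, 0.35], modifier="tg"),
            prevalent_fraction=0.01,
        ),
        "cerebral_infarction": OutcomeSpec(
            baseline_log_odds=-4.8,
            theta=ThetaSpec(kind="constant", value=0.15),
            prevalent_fraction=0.005,
        ),
    }
    return SimulationConfig(
        n_individuals=n_individuals,
        variants=variants,
        ld_blocks=blocks,
        exposure=ExposureSpec(
            intercept=5.20,
            noise_sd=1.25,
            age_effect=0.01,
            sex_effect=-0.8,
            pc_effects=[0.02, -0.02],
            confounder_effect=0.3,
        ),
        biomarkers=biomarkers,
        outcomes=outcomes,
        seed=seed,
    )
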