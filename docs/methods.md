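# Methods notes

This note records the modelling assumptions, numerical conventions and design
choices behind `stratmr`, in the spirit of a statistical-software methods
appendix. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The estimand and its assumptions

The package estimates the causal effect of a continuous exposure X (a
urate-like biomarker, mg/dL) on binary outcomes Y using cis genetic variants
in one gene region as instruments, under the usual IV conditions: the
variants associate with X (relevance), are independent of confounders
(exchangeability) and affect Y only through X (exclusion). With a weighted
allele score S as a single instrument, the Wald ratio θ = Γ/γ — the
score→outcome log-odds coefficient over the score→exposure coefficient —
identifies the log-odds of Y per unit of X.

Two caveats are inherent to the logistic-outcome setting:

- **Non-collapsibility.** Γ is a marginal coefficient over the residual
  (non-score) variation of X, so θ is mildly attenuated relative to the
  conditional log-odds slope; the attenuation factor is approximately
  `(1 + θ²σ²_x/2.89)^{-1/2}`. At the effect sizes the package's studies use
  (|θ| ≈ 0.16 per mg/dL, residual SD ≈ 1.3 mg/dL) this is a <1% relative
  bias, far below Monte-Carlo error. Users simulating much larger θ should
  expect visible attenuation: it is a property of the estimand, not a bug.
- **One-sample weighting.** Score weights are the same cohort's GWAS betas.
  In-sample self-weighting makes γ ≈ 1 (verified by simulation in the test
  suite) and can transmit winner's-curse bias when instruments are selected
  aggressively at small n; the studies use generous selection thresholds so
  selection is effectively deterministic.

## 2. Instrument selection

- Region membership is the caller's responsibility (`variants_in_region`
  applies a gene ± 500 kb window, 1-based inclusive coordinates).
- Significance thresholds: genome-wide 5e-8, or a gene-specific Bonferroni
  `0.05 / #variants tested in the region` (with 5279 region variants this is
  9.47e-6).
- Clumping is greedy: sort significant variants by ascending p (ties broken
  lexicographically by variant ID — the convention had to be fixed for
  reproducibility); keep the best, drop everything with squared Pearson
  dosage correlation ≥ the r² threshold (0.1 default, 0.3 supported) against
  it; repeat. LD is computed **in-sample** from the analysis cohort rather
  than from an external reference panel; with desk-scale simulated data
  there is no external panel, and in-sample r² is the quantity that actually
  governs redundancy of the score.
- The F-statistic is the **covariate-adjusted incremental** F of the k
  selected dosages over the covariate-only exposure model. Conventions
  differ in the literature (score-on-exposure F, unadjusted F); the
  incremental joint F is the one that measures what the score regression
  uses. A perfect fit is reported as `F = +inf`.
- The pleiotropy exclusion list is caller-supplied (one variant ID per
  line); querying expression/association databases is out of scope.

## 3. Regression conventions

- OLS p-values use the t distribution with residual degrees of freedom, not
  the normal approximation; this matters only at small n but must be pinned.
- Rows with any missing regressor are dropped per fit (complete case), and
  `n_used` records the count. Missing instrument dosages in the score are
  dropped by default (`mean_impute` optional).
- Categorical covariates (genotyping batch, assessment centre) enter as
  one-hot indicators with the first level as reference.
- Logistic fits are Newton maximum likelihood, tolerance 1e-8, ≤ 100
  iterations; single-class outcomes and (quasi-)separation raise with a
  diagnostic rather than returning a wild coefficient.
- Monomorphic variants yield flagged association records (`status =
  "monomorphic"`), never exceptions, so a region scan cannot abort halfway.

## 4. Wald ratio and reporting

- Default SE is the second-order delta method
  `se² = se_Γ²/γ² + Γ²·se_γ²/γ⁴`; the first-order form (which is never
  larger) is available by flag. CI and p use the normal approximation on
  θ/se. Fieller-type intervals are deliberately not the default: at the
  instrument strengths where they differ materially the weak-instrument
  warning (denominator (γ/se_γ)² below 10) already fires.
- Internally θ is always log-odds per unit *increase* of the exposure.
  Reporting applies a scale (default 0.1 exposure units) and a direction
  sign (default per-decrease, matching the framing of an exposure-lowering
  intervention) only at output time, so `OR_decrease = 1/OR_increase`
  exactly.
- Per outcome, that outcome's prevalent cases (diagnosed before exposure
  measurement) are excluded before estimation, and both regressions use
  identical covariates — including any extra adjustment such as BMI.

## 5. Stratification

- Quantile groups are formed by stable sort on (value, individual ID) and
  split into contiguous chunks, so stratum sizes differ by at most one and
  boundary ties resolve deterministically by ID.
- The residual method regresses the stratifier on score + covariates and
  stratifies on `residual + intercept` (location preserved); observed-value
  ranges consequently overlap across strata and the stratum summaries always
  report the observed stratifier (mean, min–max), not the residual.
- The doubly-ranked method uses consecutive score-sorted pre-strata of size
  J; the j-th stratifier-ranked member of each pre-stratum joins stratum j.
  A final partial pre-stratum distributes its members, in stratifier order,
  to the lowest-indexed strata — the method leaves this remainder rule to
  the implementation, so it is declared here.
- By default a stratification refuses to produce strata with fewer than 10
  members (`min_stratum_size` overridable); tiny strata make the stratum
  Wald ratios meaningless.
- Strata whose outcome has a single class get a flagged missing estimate and
  are excluded from Q and trend with a recorded skip, since how such strata
  should be handled is genuinely open.

## 6. Heterogeneity and trend

- Cochran's Q uses weights 1/se_j² and a χ²(J−1) reference; it is invariant
  to shifting all θ_j by a constant (property-tested).
- The trend test is a weighted least-squares regression of θ_j on the
  stratum means m_j of the **observed** stratifier, with fixed-variance
  covariance (X'WX)⁻¹; `p_trend` is the two-sided test of the linear slope.
  A linear trend in stratum-specific effects corresponds to a quadratic
  overall exposure–outcome shape, hence the name "quadratic-trend test";
  with ≥ 4 strata an explicit quadratic coefficient (on centred m_j²) is
  additionally reported, since which of the two a given publication means by
  the term is ambiguous. Regressing on quartile index instead of m_j is a
  caller-side substitution of `stratum_means`.
- No multiple-testing correction is applied across outcomes or stratifiers;
  the CLI prints the number of stratified tests performed so users can
  correct externally.

## 7. The synthetic-cohort generator

What it emulates: a biobank-scale cross-section with (i) Hardy–Weinberg
bi-allelic dosages, within-block LD produced by thresholding correlated
standard-normal latents at the HW genotype-frequency cutpoints (marginals
are exact; the dosage-scale correlation induced by latent ρ was measured by
brute-force simulation — ≈ 0.87 at ρ = 0.95, MAF 0.3 — before freezing test
thresholds); (ii) a continuous exposure that is linear in dosages,
demographic covariates and a latent confounder, plus Gaussian noise;
(iii) lipid-like biomarkers that may load on the exposure, the covariates
and the shared confounder, with an optional exponentiated (heavier-tailed)
noise component for TG; (iv) logistic binary outcomes whose exposure slope θ
may be constant, piecewise-constant over empirical quantile bands of a
modifier biomarker, or polynomial in the standardised modifier; and
(v) per-outcome prevalent-case flags, independent of genotype by default so
the prevalent-case filter is exercised without biasing the GWAS (an
exposure-dependent switch exists for stress tests).

Default marginals follow published biobank summary moments (age 56.5 ± 8.1 y;
exposure 5.2 ± ~1.35 mg/dL; LDL-C 137.5 ± 33.6, TG 154.8 ± 91.0,
HDL-C 56.0 ± 14.8 mg/dL; TC/HDL 4.24 ± 1.23). The joint lipid–exposure
distribution is **not** pinned to any real cohort — it is free
configuration; the demo routes lipid–exposure correlation through the shared
confounder so the genetic score has no horizontal path to the lipids.

Determinism: every column draws from a named substream
(`SeedSequence(entropy=seed, spawn_key=(crc32(name),))`, names keyed by
variant/block/covariate/biomarker/outcome), so identical (config, seed)
reproduce the cohort byte-for-byte and adding a variant or outcome leaves
all other columns untouched (tested).

What it does **not** emulate — and hence what passing tests do not show
about real data: realistic LD maps or allele-frequency spectra, population
stratification beyond supplied PC covariates, genotyping error and
missingness mechanisms other than missing-completely-at-random, age/sex
structure in disease onset, time-to-event outcomes, or selection into the
cohort (the collider-bias checks are exercised by explicit synthetic
violations, not by modelling UK-Biobank-style self-selection).

Two built-in violation switches support assumption-check calibration:
`genetic_effect_modifier` multiplies every variant's exposure effect by
`1 + κ·z` (z the standardised independent component of a named biomarker),
violating the constant-genetic-effect assumption; `age_allele_effect` gives
each causal allele a direct effect on age, which the negative-control check
should detect.

## 8. Simulation-study conditions

The studies in `stratmr.studies` (run by both the operating-characteristic
tests and `scripts/acceptance.py`) fix these desk-scale conditions:

| study | n per cohort | replicates | instruments (β per allele, MAF 0.3) | key effect |
|---|---|---|---|---|
| linear recovery | 20 000 | 200 | 3 × 0.12 (~1% of exposure variance) | true OR 0.85/unit decrease, confounded |
| IVW equivalence | 50 000 | 20 | 3 × 0.15 | same |
| heterogeneity null | 12 000 | 500 | 3 × 0.30 | homogeneous θ |
| nonlinear power | 40 000 | 50 | 3 × 0.40 | θ = −log 0.79 in top TG quartile only; positive control θ = 1.1 |
| assumption checks | 8 000 | 200 null / 40 violation | 3 × 0.30 | κ = 0.5; age 0.4 y/allele |

Instrument strength is deliberately far above a real cis region (where the
instruments explained ~0.02% of exposure variance with joint F ≈ 23):
stratum-specific ratio estimates are simply not identifiable at desk-scale n
with 0.02% R², so the studies trade realism of instrument strength for
identifiability, keeping everything else (effect sizes, confounding,
quartile structure) at realistic magnitudes. Sample sizes and replicate
counts were chosen from a priori power algebra — e.g. the top-stratum power
study needs `(n/4)·p(1−p)·var(S)` large enough that |θ|/se ≈ 3.8 — and are
reported alongside every quantity the acceptance script writes.

## 9. Known limitations

- One-sample MR only; no external/summary-statistic weighting.
- No pleiotropy-robust estimators (Egger, weighted median, constrained ML):
  pleiotropy handling is by exclusion list and by the score→biomarker and
  negative-control regressions.
- No fractional-polynomial dose–response curve; nonlinearity is summarised
  at stratum level (Q, trend) only.
- In-sample LD is a documented divergence from reference-panel clumping.
- The trend test treats stratum means as fixed regressors; their sampling
  error is ignored (negligible at the study sizes, not in tiny strata).
- Lognormal-noise biomarkers can still take values slightly below zero
  through the confounder and covariate terms; the generator does not clip.
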