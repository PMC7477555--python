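# Methods

## Synthetic cohort: the stated world

The generator emulates a pooled two-study cohort of women without breast
cancer (a healthy-donor tissue bank, labelled KTB, and a benign-breast-
disease biopsy study, labelled STAMP; default split 1089/309, n = 1398).
Per woman it draws:

- **PRS.** Either computed from simulated genotypes (per-variant
  binomial(2, MAF) dosages, MAF uniform on (0.01, 0.5), no linkage
  disequilibrium) scored against a 313-variant weight table, or drawn
  directly standard normal. ER-specific scores are correlated ~0.95 /
  ~0.85 with the overall score. All scores are standardized to sample mean
  0, SD 1 (denominator n − 1).
- **Tissue area** lognormal(log 35, 0.4) mm²: a free design choice (the
  source tables never describe the area distribution), sized so the median
  TDLU rate lands near 8.5 per 100 mm².
- **TDLU count**: structural zero with probability 0.171, else negative
  binomial (NB2, dispersion α = 1.61) with
  log mean = log(area/100) + log(26.2) + log(1.12)·PRS_std.
  The zero-inflated negative binomial family was chosen because the
  published descriptives show a 32.5% zero mass next to a strongly
  right-skewed positive part (median 3, upper quartile 11). The three
  count parameters were fit once, by Nelder–Mead on simulated quantiles,
  to those descriptives and frozen; they are not tuning knobs. The PRS
  effect enters the count component only; structural zeros are independent
  of the PRS, so the marginal per-SD rate ratio is still exactly 1.12
  (the zero-inflation multiplies the mean by a constant).
- **Acini per TDLU** lognormal(log 12, 0.72), independent of the PRS —
  deliberately emulating the null finding for acini — and missing when the
  TDLU count is zero (an "including zeros" column is also emitted).
- **Covariates**: age from the published five-band frequencies with
  uniform jitter inside bands; menopausal status Bernoulli per age band
  (premenopausal probability 1/1/0.95/0.33/0.02, giving ~76% premenopausal
  overall); parity and family history independent Bernoulli (58.4%,
  22.4%).

**What a green test does not establish.** The generator matches marginal
quantiles and one conditional structure (count | PRS, area). It does not
reproduce real within-study heterogeneity, age–involution trends,
genotype–age correlation, LD, or measurement error in TDLU counting. A
consequence that matters for the mediation numbers: matching a 32.5% zero
mass, median 3 and upper quartile 11 forces a long upper tail
(mean/SD ≈ 0.59 for TDLU counts). The percent-mediated point estimate
scales with mean/SD of the mediator under the per-SD convention, so this
world yields ~2.6–5.2% across the external-OR grid — inside every published
interval, but below the published centers, which imply a lighter-tailed
count distribution (mean/SD ≈ 0.84) that the ZINB family pinned to the
published quantiles cannot reach.

## Association models

TDLU counts are modelled by Poisson regression with log link and offset
log(area), so coefficients are log rate ratios per mm² of tissue.
Overdispersion is expected (the generator's counts are strongly
overdispersed) and handled by the HC0 sandwich covariance
(bread⁻¹·meat·bread⁻¹; bread = Xᵀdiag(μ̂)X, the expected = observed
information under the canonical link; meat = Σᵢ xᵢxᵢᵀ(yᵢ−μ̂ᵢ)²). No
small-sample correction is applied; at n ≈ 1400 the HC1 factor is
immaterial. Wald 95% CIs use the 1.96 normal multiplier.

Acini-per-TDLU outcomes are per-woman medians and may be non-integer; they
enter the same quasi-likelihood score equations, by default without an
offset and excluding women with zero TDLUs (acini per TDLU is undefined
there); an option includes them as zeros.

Quartiles are cut at the pooled 25/50/75th percentiles (linear
interpolation between order statistics), left-open right-closed except the
first interval, ties at a cut going low. The trend test refits with
integer scores 0–3 and reports the robust Wald p of that slope. Age enters
continuously; study as an indicator. The linear sensitivity fit is OLS of
the rate (count/area) on the same design with HC0 SEs, used only to check
the direction of association is not a Poisson artifact (measured null
coverage of its 95% CI is ~0.92–0.94 at n = 350, the usual mild HC0
anti-conservatism).

Per-variant scans report raw two-sided p values with no multiplicity
adjustment, matching how such exploratory scans are usually tabulated;
monomorphic variants are skipped with a logged count.

## Mediation estimator

Inputs: external OR of breast cancer per SD of PRS (defaults 1.61 /
1.68 / 1.45 for overall / ER+ / ER−), a candidate external OR of breast
cancer per TDLU-count unit (grid 1.25 / 1.35 / 1.45), an assumed
prevalence κ, and the in-cohort joint distribution of (PRS, TDLU count).

**Unit convention.** The external TDLU→cancer OR is interpreted per SD of
TDLU count (configurable to per single count). A per-single-count reading
of OR 1.25 would make one extra TDLU as risk-relevant as ~0.5 SD of PRS
and push mediated fractions to implausible sizes; the per-SD reading is
the package default and the one all reported numbers use.

**Calibration.** (β₀, β, γ) of the joint logistic model solve three
equations: the induced single-variable logistic slope on PRS equals
log OR_PRS-BC; the induced slope on M equals log OR_TDLU-BC; the mean risk
equals κ (residual kept on the logit scale so all three residuals share
units). "Induced slope" means: evaluate pᵢ = expit(β₀ + β·Mᵢ + γ·PRSᵢ) on
every cohort row and fit a two-parameter fractional-outcome logistic MLE
of {pᵢ} on the single variable (damped Newton, gradient tolerance
10⁻¹⁰·n). This respects non-collapsibility: the marginal slope of a joint
logistic model is not the conditional coefficient, and β must also offset
whatever slope the empirical PRS–TDLU association leaks into the M
marginal. Root-finding is Powell-hybrid from the plug-in start
(logit κ, log OR_TDLU, log OR_PRS); convergence requires every residual
below 10⁻⁸, else an error carrying the last residuals.

**Decomposition.** The counterfactual mediator law f(M | x) is the fitted
Poisson count distribution at mean exp(α̂₀ + α̂₁x + α̂·c̄ + ō) (covariates at
cohort means, offset at the cohort-mean log area), truncated where the
upper tail is below 10⁻¹⁰. For the contrast (x₀, x₁) = (−0.5, +0.5) — a
centered 1-SD change —

- ACME = ½ Σ_x (E_{M|x₁} − E_{M|x₀})[p(M, x)]
- ADE  = ½ Σ_{x'} E_{M|x'}[p(M, x₁) − p(M, x₀)]
- TE   = E_{M|x₁}[p(M, x₁)] − E_{M|x₀}[p(M, x₀)]

so ACME + ADE = TE holds as an algebraic identity, and
% explained = 100·ACME/TE (flagged undefined when |TE| < 10⁻¹²). Effects
are on the risk-difference scale; for κ ≤ 0.1 the result tracks the
log-odds approximation 100·β·δ/log OR_PRS-BC (δ the per-SD-of-PRS change
in mean mediator on β's unit) within ~10%.

Using a plain Poisson counterfactual law for a mediator generated as
zero-inflated negative binomial is a deliberate mean-model approximation:
the mean structure (which drives δ, hence the numerator) is consistently
estimated by the quasi-Poisson fit, while the law's shape enters only
through the mild curvature of expit over the support.

**Bootstrap.** Percentile CIs from resampling cohort rows with replacement
(default 10,000 resamples), refitting the mediator model and recalibrating
per resample with the external estimates held fixed — so the intervals
reflect internal sampling variability only, not uncertainty in the
external ORs. Resamples that fail calibration are dropped and counted;
more than 1% failing is an error. κ defaults to 0.10 (order of lifetime
risk); the percent mediated moves by under 15% relative across
κ ∈ [0.01, 0.15] (tested).

## Numerical and degenerate-input choices

- Missing dosages: per-variant mean imputation (rank-stable, unbiased
  under missingness at random). Dosage files whose counted allele is the
  weight's other allele are flipped to 2 − d; A/T and C/G variants cannot
  be checked by allele match and are matched by id with a logged warning.
- All-tied scores: every sample goes to Q1 with a warning; an empty
  quartile under a categorical fit is an error.
- Rank-deficient designs abort with the collinear columns named (QR
  diagonal test). Non-convergent GLM fits are flagged, not silently used.
- ER-specific scores are standardized on their own SDs (the alternative —
  the overall score's SD — changes per-SD RRs by only the SD ratio).
- Degenerate mediation inputs: constant TDLU counts make the per-SD unit
  undefined (error); a cohort with a constant score cannot support the
  mediator fit (rank deficiency), which is why bootstrap determinism is
  guaranteed by seeding rather than by single-row degenerate cohorts.

## Known limitations

- The percent-mediated center depends on the mediator's mean/SD ratio,
  which the published marginal quantiles do not pin down (see above).
- External-estimate uncertainty is not propagated into the bootstrap CIs.
- No unmeasured-confounding sensitivity analysis for the mediator–outcome
  relation; the external TDLU→cancer OR is taken at face value.
- The generator draws covariates independently of the PRS and of TDLU
  counts (aside from the age-band/menopause link), so covariate adjustment
  in the synthetic world is exercised but not stressed.
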