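# Methods

This note documents the models implemented in `kidbioage`, the assumptions
behind them, the defaults of the synthetic-cohort generator, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The synthetic cohort

The simulator (`kidbioage.synth`) emulates a multi-centre pediatric
exposome study. It is first-class, tested code — the study conditions for
every downstream check — not a throwaway fixture.

**Design.** `n_children = 1000` children with ages uniform on 5–12 years
(the emulated study reports this range with a mean near 8; no distribution
is published, so uniform was chosen as the simplest shape spanning the
range) across 6 study centres; ~55% boys; ethnicity 89% white European;
covariates include maternal education, birthweight, maternal and passive
smoking, physical activity, diet score, family affluence and social
capital, and methylation-derived blood cell fractions (Dirichlet-drawn,
provided directly as covariate columns — cell-type deconvolution is out of
scope). A `covariate_missing_rate = 0.02` injects completely-at-random
missingness into questionnaire-style covariates; downstream models use
complete cases.

**Latent Δ age.** Each child carries a latent `true_delta_age ~ N(0,
0.8²)` years. Omic features respond to *biological* age
(chronological + Δ), so a clock trained on chronological age transfers
part of the latent Δ into its predictions; outcomes depend on the same
latent Δ, closing the causal loop the association stage is meant to
detect. The 0.8-year SD matches the residual spread child clocks typically
show against chronological age. An `epigenetic_age` column
(0.85·Δ-attenuated, 0.8-year noise) is simulated directly: methylation
clock training is out of scope, and the analysis accepts epigenetic age as
a precomputed input.

**Omic blocks.** Defaults mirror the emulated post-QC panels: 36 plasma
proteins, 177 serum metabolites, 44 urinary metabolites — and 500
transcripts standing in for a ~50k-feature expression array. The
transcript count is a deliberate scale-down: the methods operate
identically, per-feature signal parameters are what matter, and the
smaller block keeps the default study tractable. Each feature is
`baseline + slope·bio_age + plate + N(0, noise_sd=1)` on a log2-like
scale; `n_age_features` per block (12/40/10/100) carry nonzero slopes of
magnitude `age_effect_scale = 0.3` (×U(0.5, 1.5), random sign) log2-units
per year — a per-feature age R² around 0.25, so that no single feature
predicts age but a sparse panel does. Plate effects are N(0, 0.25²) shifts
per (plate, feature) over 12 plates. Proteins are quantile-censored at
(0.05, 0.98) against per-feature LOQ1/LOQ2; serum features carry CV% and
LOD metadata with ~5% "poor assays" violating the exclusion rule; urinary
concentrations are multiplied by per-child lognormal (σ_log = 0.4)
dilution factors; transcripts carry feature and sample call rates with a
few below the filter thresholds. Inter-feature correlation beyond the
shared age signal is not modelled (a documented non-goal), so passing
recovery tests demonstrates correctness of the machinery, not performance
on correlated real omics.

**Follow-up panel.** A random 15% of children are re-simulated
0.5 years older with the same feature coefficients (fresh noise, plates
and censoring), emulating a second clinical examination; this subset is
the temporal test bed for the progression test.

**qPCR wells.** True T/S ratios are lognormal (σ_log = 0.15) with a weak
negative age trend; per-child single-copy input varies lognormally. Runs
of ≤84 children carry a run-level Cq shift (SD 0.5 cycles), 8 inter-run
calibrators, and 6-point half-log dilution standards per target;
triplicate Cq noise is 0.05 cycles. Target efficiencies are 0.95 (T) and
0.92 (S).

**Randomness.** Every component draws from a named stream
(`SeedSequence((seed, crc32(name)))`), so adding a block or component
never perturbs another's draws, and identical configs are byte-identical.

## Preprocessing

Stage order is fixed as: quantifiability filter → (proteins, on the log2
scale: plate correction → truncated-normal imputation) → (urine: median
fold-change normalization → ½-minimum offset → log2) → (serum: log2) →
mean-centre and unit-SD scale. The emulated study describes the stages
but not one canonical order across blocks; correction-before-imputation
was chosen so that imputation moments are estimated from batch-clean
values. Protein values are carried on the log2 scale throughout, with
LOQ bounds on the same scale.

- *Linear-range filter*: keep proteins with >30% of measurements inside
  [LOQ1, LOQ2]; censored cells count as out-of-range.
- *Serum exclusion*: drop only when **both** CV% > 30 and >30% of values
  fall below the LOD.
- *Plate correction* subtracts `(plate mean − grand mean)` per feature; it
  is idempotent, preserves each feature's grand mean, tolerates
  single-sample plates, and leaves a feature untouched on plates where it
  was never observed (with a warning).
- *Truncated-normal imputation* estimates μ, σ per feature from in-range
  values only (sample SD, n−1 — the convention used throughout the
  package) and draws below-LOQ1 cells from N(μ,σ) truncated to (−∞,LOQ1]
  and above-LOQ2 cells from [LOQ2,∞), seeded. Features with fewer than 3
  in-range values are dropped as un-imputable. Estimating moments from
  in-range values is slightly biased when censoring is heavy; at the
  default 5%/2% censoring the bias is negligible relative to feature noise.
- *Median fold-change normalization* uses the feature-wise median profile
  as the reference (the method's reference choice is not published;
  configurable). The estimated dilution factor is scale-equivariant by
  construction.
- *Scaling* parameters (means, SDs) are stored and re-applied to held-out
  and follow-up data; they are never re-estimated outside training.

## Clocks

Training concatenates the scaled blocks column-wise and scales per feature
across the concatenated matrix. The hyperparameter search follows the
standard penalized-regression recipe: α ∈ {0.0, 0.1, …, 1.0} (inclusive —
α = 0 is pure ridge, solved in closed form via one SVD per fold along the
whole λ path), a 30-point descending log-spaced λ path per α from the
glmnet-style λ_max down to 10⁻³·λ_max, and 10-fold CV MSE with folds
stratified by age decile (seed-controlled) to stabilize the curve. λ is
chosen at the CV-MSE *minimum* (not a one-SE rule); ties break toward
larger λ, then larger α — the sparser model. The final model is refit on
all training data at the selected pair. No internal re-standardization:
data are scaled once upstream; the intercept is unpenalized.

Prediction requires every training feature to be present (no silent
zero-fill). Validation reports Pearson r, MAE and per-group (e.g. centre)
correlations; constant predictions are flagged rather than crashing. The
progression test is a paired one-tailed t-test of
second-visit − first-visit predicted age with alternative mean > 0.

In the pipeline, 25% of children are held out for validation and the
panel follow-up supplies the progression pairs; follow-up blocks skip
re-filtering (training feature set is retained) but are imputed and
normalized independently before the training scaler is applied.

Recovery accounting: true-predictor recall is computed against the planted
coefficient set intersected with the features surviving QC — a feature
dropped by the filters cannot be recovered by any selector.

## Telomere quantification

The implementation is the standard efficiency-corrected,
calibrator-normalized relative quantification model (the emulated study
used proprietary software; this is a documented reimplementation, not a
byte-level clone). Efficiencies come from least-squares fits of Cq on
log10(input) over ≥3 monotone dilution points, E = 10^(−1/slope) − 1.
Per-well relative quantities are referenced to the run's calibrator-mean
Cq, replicates averaged per (sample, target), T/S divided by the
*geometric* mean of the run's calibrator ratios (standard for ratio-scale
quantities), and finally by the cohort mean — so reported values average
exactly 1 and whole-run Cq shifts cancel. Replicate CVs are reported on
the quantity scale (the Cq-vs-quantity convention is not published; the
choice is labelled in the output). No replicate-outlier rejection by
default.

## Associations

Markers enter as Δ age in years; telomere length is flipped (×−1) and
unit-SD scaled so every marker points in the "older" direction.
Continuous outcomes are mean-centred and unit-scaled **except** the BMI
and height z-scores (already reference-scaled); CBCL behavior scores are
log(x+1)-transformed first (the transform must accept the zeros CBCL
produces). Developmental-outcome models put the outcome on the left
(logistic for puberty onset, effects exponentiated to odds ratios);
risk-factor models put the marker on the left. All models adjust for
chronological age, sex, ethnicity and study centre; categorical covariates
use treatment coding; ordinal three-level factors (affluence, social
capital, maternal education) are trend-coded 0/1/2 when used as exposures.
Complete cases per model; Wald 95% CIs throughout; perfect or
quasi-separation in logistic fits yields a flagged result rather than a
crash; exactly collinear covariates raise an error naming the pair.

BH FDR is computed across the entire primary family (all marker × outcome
and marker × risk-factor models pooled); the four sensitivity variants —
sex stratification, centre stratification, cell-fraction adjustment,
extended risk-factor adjustment — re-run every outcome-direction model
outside the FDR family (configurable). Stratified fits drop the
stratifying covariate and skip strata smaller than the parameter count,
with a log entry. Partial correlations residualize both markers on the
covariates (indicator-coded) and use t with df = n − 2 − k.

## Enrichment

The hypergeometric upper tail is exact (`P(X ≥ k)`), one-sided —
over-representation only. The universe is an explicit, mandatory argument
(web ORA tools leave it implicit; here it must be supplied, e.g. all
measured annotated genes), and genes outside it are dropped with a count.
Significance requires both q < 0.05 within the collection and an overlap
of ≥ 3 genes. Gene symbols are uppercased on read; results are invariant
to gene order. The pipeline's default collection is *synthetic* (one set
deliberately loaded with 80% planted age genes, the rest random) purely to
exercise the stage; any GMT file can be supplied instead.

## Derived scores

KIDMED sums +1 over 11 positive and −1 over 4 negative diet items (range
−4…11, verified exhaustively); FAS maps the 0–9 composite to
low/medium/high at 0–2/3–5/6–9 (the per-item point mapping is not
published, so only the composite mapping is implemented); PDS averages
1–4 items (girls' menarche coded 1/4 and included) with onset defined as
mean > 1; d′ = Φ⁻¹(hit) − Φ⁻¹(FA) with extreme rates clamped to
[1/(2n), 1−1/(2n)] when the trial count is supplied and a hard error
otherwise (the applied correction is not published); HRT-SE is
SD(hit RTs)/√n. CBCL subscale item membership is not published; subscale
totals are accepted as inputs with only the log transform applied.

## Problem sizes and determinism

The default study is n = 1000 with the block sizes above; acceptance-style
recovery checks train the immunometabolic clock (~250 surviving features)
on 75% of children, CI-coverage uses 200 replicates of n = 250
cohort-only studies, and null calibration uses ≥ 2000 tests from 75
replicates plus 2500 partial correlations — sizes chosen so the whole
suite runs in minutes on a single CPU while keeping Monte-Carlo error well
inside the asserted bands. All randomness flows from named, seeded
streams; identical configurations reproduce outputs bit-for-bit.

## Known limitations

- No inter-feature correlation structure beyond the shared age signal, no
  raw microarray/NMR/MS low-level processing, no methylation clock
  training, no cell-type deconvolution, no WHO growth-reference scoring —
  all accepted as inputs or out of scope.
- The truncated-normal moment estimates and the CV-minimum λ rule are
  exactly as specified, not robustified; heavy censoring or tiny n will
  degrade both (guarded by explicit preconditions).
- Simulated outcomes are conditionally Gaussian (or logistic) with linear
  covariate effects; real developmental outcomes are not, so association
  results on synthetic data validate the inferential machinery, not
  real-world effect sizes.
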