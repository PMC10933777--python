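# Methods

## Problem and model

Two-sample Mendelian randomisation estimates the causal effect β of an
exposure X on an outcome Y from per-SNP marginal association summaries
estimated in two separate cohorts.  The identifying assumptions are the
classical instrumental-variable triple: each instrument is (1) associated
with the exposure, (2) independent of confounders of the
instrument–outcome relation, and (3) associated with the outcome only
through the exposure (exclusion restriction).  Violations of (3) —
horizontal pleiotropy — are the central practical threat and drive both
the robust estimators and the sensitivity workflow implemented here.

## Instrument preparation

* **Selection.** Instruments are SNPs with exposure p < 5×10⁻⁸ (strict
  inequality; configurable, with 10⁻⁶ and 10⁻¹² used by the threshold
  scan).
* **LD pruning.** Greedy clumping in ascending p-value order (ties broken
  by snp_id for determinism): a SNP is kept iff its LD r² with every
  already-kept SNP is ≤ 0.001.  The LD matrix is a user input; without
  one, pruning is a logged no-op — summary sources are very often
  pre-clumped, and the simulator emits mutually independent SNPs.  The
  package does not compute LD from a reference panel.
* **Harmonisation.** Outcome effect alleles are aligned to the exposure's:
  swapped labels negate the outcome beta and complement the EAF; strand
  complements are tried before declaring a mismatch.  Palindromic (A/T,
  C/G) SNPs are strand-ambiguous, so they are resolved by effect-allele-
  frequency agreement and dropped when either EAF is missing or within
  0.08 of 0.5.  The window is a declared package default in line with
  common two-sample practice; it is configurable.
* **Strength.** Per-SNP R² = t²/(t²+n−2) and F = (n−2)R²/(1−R²), which
  reduces to t².  This test-statistic form needs no allele frequency and
  is robust to unit conventions; an EAF-based R² (2·EAF·(1−EAF)·β²) is
  available separately for comparison.  Mean F > 10 is the conventional
  weak-instrument guard.

## Estimators

All multi-SNP methods work on the per-SNP Wald ratios β̂_j = γ̂_Oj/γ̂_Ej.
Ratio SEs default to first order (σ_Oj/|γ̂_Ej|, the NOME approximation);
second-order SEs adding the exposure-noise term are available.

* **IVW fixed effects**: β̂ = Σwβ̂_j/Σw with w_j = 1/se_j²,
  se = (Σw)^{−1/2}, normal inference.  Identical to weighted
  through-origin WLS of γ̂_O on γ̂_E (tested against statsmodels).
* **IVW multiplicative random effects** (default): same point estimate;
  the SE is scaled by √(max(1, Q/(J−1))).  Because that over-dispersion
  scale is estimated from the data — the model is exactly a
  through-origin WLS with unknown residual scale — inference uses
  t(J−1).  With normal quantiles the test over-rejects measurably at
  J≈50 (type-I ≈ 0.066 rather than 0.05 in our calibration runs); the
  t correction restores nominal behaviour while leaving the estimate and
  SE untouched.  The scale is floored at 1: under-dispersion never
  tightens intervals.
* **IVW additive random effects**: DerSimonian–Laird
  τ² = max(0, (Q−(J−1))/(Σw − Σw²/Σw)), re-weighting w*_j = 1/(se_j²+τ²);
  normal inference, τ² reported.
* **MR-Egger**: WLS of γ̂_O on γ̂_E with a free intercept, weights 1/σ_O²,
  after orienting every SNP to γ̂_E ≥ 0.  Coefficient SEs carry
  multiplicative over-dispersion √(max(1, RSS_w/(J−2))) and inference is
  on t(J−2) — deliberate small-J honesty for a 3-parameter-sensitive fit.
  The intercept estimates the mean directional pleiotropic effect under
  InSIDE (pleiotropy independent of instrument strength).
* **Weighted median**: interpolated 0.5 point of the ratio distribution
  under standardised cumulative weights; consistent when ≥ half the
  weight is on valid instruments.
* **Weighted mode**: argmax of a weighted Gaussian KDE over the ratios on
  a 512-point grid spanning the range ± 3 bandwidths.  Bandwidth is the
  modified Silverman rule φ·0.9·min(sd, IQR/1.34)·J^{−1/5} with user
  factor φ (default 1); a bandwidth choice is required because none is
  canonical for this estimator.
* **Bootstrap SEs** (median, mode): parametric resampling of the summary
  statistics themselves — γ̂_E and γ̂_O are redrawn from normals at their
  reported SEs — which matches the summary-data likelihood; 1000 draws by
  default, seed always in the public signature.
* **Multivariable IVW**: WLS of γ̂_O on the J×K exposure-association
  matrix without intercept, weights 1/σ_O², over-dispersion with df J−K;
  rank-deficient designs are rejected as collinear.
* **Mediation**: difference (β̂_tot − ĉ) and product (â·b̂) indirect
  effects computed exactly; in linear-Gaussian systems the two agree
  asymptotically, which the tests verify by simulation.

## MR-PRESSO

The global statistic is the weighted residual sum of squares
RSS = Σ_j (γ̂_Oj − β̂_{−j}γ̂_Ej)²/σ_Oj², with β̂_{−j} the leave-one-out
IVW estimate.  Its null distribution is simulated parametrically by
redrawing both association vectors (γ̂*_E ~ N(γ̂_E, σ_E),
γ̂*_O ~ N(β̂_{−j}γ̂_E, σ_O)) and recomputing the statistic, including the
leave-one-out refits, on each draw.  Empirical p-values use the plus-one
rule (r+1)/(n_sim+1) and are never exactly zero.  The per-SNP outlier test
compares each observed residual term with its own simulated distribution,
Bonferroni-adjusted over J (mirroring the reference implementation's
reporting); the distortion test compares the relative shift of the
outlier-corrected estimate against 1000 random same-size removals.  The
corrected estimate is the default multiplicative-RE IVW on the remaining
instruments.

## Sensitivity workflow

Cochran's Q = Σw_j(β̂_j−β̂)² with df = J − (parameters estimated) and
I² = max(0, (Q−df)/Q); leave-one-out re-estimation per SNP; single-SNP
Wald table; funnel data (ratio vs precision 1/se).  The Steiger
directionality test recovers per-SNP trait correlations from test
statistics (r = t/√(t²+n−2)), aggregates R² = Σr² per trait, and compares
the aggregate correlations √R² by Fisher-z; the aggregate test gives the
directionality headline while the per-SNP comparison (r²_exp > r²_out)
drives Steiger filtering — the two uses are deliberately distinct.  For
binary outcomes the t-based r is used unchanged (an observed-scale
approximation, flagged here because no scale conversion is canonical at
the summary level).  Bi-directional orchestration runs selection →
harmonisation → the full battery with each trait as exposure in turn;
directions without instruments are a first-class "not estimable" state,
never an exception, so screening over many pairs cannot abort.

## Screening

Heritability filtering keeps traits with h² p < 0.05, annotation
confidence ≥ medium and LD-score intercept ≤ 1.1 (an elevated intercept
suggests stratification or confounding).  Correlation filtering keeps
pairs with |ρ| > 0.10 and −log₁₀ p > 12.  All printed thresholds are
strict inequalities; boundary equality excludes (the intercept rule is a
maximum allowed value, so 1.1 itself passes).  The confidence metric is an
ordered label supplied in the input table (none < low < medium < high),
since it is an annotation of the source, not something computable here.
Screen results are explicitly exploratory: per-direction IVW with an
unadjusted significance flag (matching screening practice) plus a
Bonferroni-adjusted column over all estimated tests.

## Bayesian networks with anchors

Continuous-only linear-Gaussian scoring: each node's local BIC is the
Gaussian log-likelihood of its regression on its parents minus
(k/2)·log n with k = parents + intercept + variance; the total score is
node-decomposable.  SNP dosages enter as numeric 0/1/2 regressors, which
matches their role as anchors; multinomial nodes are out of scope.  Hill
climbing starts from the whitelist-only graph and greedily applies the
best single add/delete/reverse move that respects acyclicity, the
whitelist (never deletable or reversible) and the blacklist (never
addable); plain hill climbing by default with optional seeded random
restarts.  Anchoring follows the standard genetic recipe: known
SNP→phenotype edges whitelisted, all edges into anchor nodes blacklisted.
Bootstrap support uses nonparametric row resampling at the original n
(the standard choice); presence probability is the fraction of bootstrap
graphs containing an adjacency in either direction, and direction
probability is the orientation share given presence (the two orientations
sum to 1).  The consensus graph keeps adjacencies with presence ≥ 0.8 —
the threshold applies to presence — oriented by simple majority; rare
consensus cycles are broken by dropping the lowest-presence edge.

## Synthetic data generator

The generator realises the standard structural model with independent
biallelic SNPs: Z_ij ~ Binomial(2, maf_j), maf_j ~ U(0.05, 0.5), latent
confounder U ~ N(0,1),

    X = Σ γ_j Z_j + κ_x U + ε_x,    Y = βX + Σ α_j Z_j + κ_y U + ε_y,

with unit noise SDs and κ_x = κ_y = 0.3 by default, so confounding is
present but MR remains identified.  Pleiotropy regimes set α: none,
balanced (mean 0), directional (mean μ_α ≠ 0), correlated (α = θγ +
noise, violating InSIDE); a fraction parameter limits how many SNPs are
affected.  Two cohorts are generated at the individual level and
summarised by per-SNP simple regressions, so sample overlap (shared
leading block), collider selection (logistic participation in X, Y, U) and
winner's curse (instrument selection on the simulated exposure p-values)
arise exactly as mechanisms, not as add-on noise.  A third "selection
cohort" option supports the three-sample design that avoids winner's
curse.  A direct summary-statistic mode draws γ̂_E, γ̂_O straight from
their asymptotic normals with analytic SEs; it is exact for the
no-selection, no-overlap case and used for calibration loops.  The
generator does not model LD structure, dynastic/assortative-mating
effects or time-varying exposures, so passing tests say nothing about
those features of real data.

## Validation regimes (fixed a priori; run by the test suite)

* Parameter recovery: J=100, n=50,000 per cohort, γ ~ N(0.07, 0.01)
  (mean F ≈ 80 > 30), no pleiotropy, β=0.1, 200 individual-level
  replicates — mean multiplicative-IVW within ±0.005 of β, CI coverage in
  [0.92, 0.975].
* Type-I error: β=0, balanced pleiotropy σ_α=0.01, J=50, 500 direct-mode
  replicates — rejection in [0.03, 0.08].
* Pleiotropy detection: directional μ_α=0.02, σ_α=0.02, J=100, exposure
  n=500,000 (a large-consortium exposure GWAS keeps instrument
  measurement error negligible, isolating the Egger intercept's target),
  outcome n=50,000, 200 replicates.
* Robustness: 30 % invalid instruments, μ_α=0.06 — weighted-median bias
  under half the IVW's.
* MR-PRESSO: J=50, n_sim=1000; null calibration and single planted
  outlier at 10× the outcome SE, 200 replicates each.
* Q calibration: J=10 with a near-noiseless exposure side (n=10⁷ in
  direct mode), 2000 replicates — the first-order-weighted Q is only
  asymptotically χ², so calibration is checked in the strong-instrument
  limit the statistic assumes.
* Steiger: exposure R² ≈ 5× outcome R² (β=0.48 regime), n=50,000.
* Network: chain Z→X→Y, n=1000, 200 bootstrap resamples (a scaled-down
  bootstrap; the package default stays 1000).

## Numerical choices and degenerate inputs

Deterministic tie-breaking by (p-value, snp_id) everywhere; 95 % normal
quantile used at full precision (1.959964…); empirical p-values carry the
plus-one correction; a single instrument degenerates IVW to the Wald
ratio with a log note; identical ratios give Q = 0 and I² = 0; all-equal
ratios give the weighted mode directly; zero exposure betas raise a
validation error naming the SNP; rank-deficient BN parent designs fall
back to a pseudo-inverse fit with a degeneracy flag.  Every stochastic
routine takes an explicit seed; bootstrap replicate seeds are spawned
from the master seed via `SeedSequence`.

## Known limitations

First-order ratio SEs understate uncertainty for weak instruments
(second-order SEs available); Steiger is sensitive to measurement error
and can discard valid instruments; the screening stage is exploratory by
design and unadjusted for multiplicity; the BN module assumes linear-
Gaussian mechanisms, no latent confounders and complete continuous data;
the simulator's allele labels are constant (A/G), so harmonisation edge
cases are exercised by dedicated fixtures rather than by the generator.
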