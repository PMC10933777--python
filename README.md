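# causalmr

Two-sample Mendelian randomisation (MR) on GWAS summary statistics, with
the full sensitivity workflow, bulk bi-directional screening, anchored
Bayesian-network structure learning, and a ground-truth synthetic
summary-statistic generator.

## Who this is for

Epidemiologists and (neuro)imaging-genetics researchers who want to test a
causal hypothesis — does exposure X causally affect outcome Y? — using only
per-SNP summary statistics from two GWAS sources, without individual-level
data.  Genetic variants serve as instrumental variables: because genotype
is fixed at conception, a variant Z that influences Y *only through* X
identifies the causal effect of X on Y even in the presence of unmeasured
confounding.

## The core model

For instrument j, let γ̂_Ej and γ̂_Oj be the marginal SNP–exposure and
SNP–outcome association estimates with standard errors σ_Ej, σ_Oj.  Each
valid instrument yields a Wald ratio

    β̂_j = γ̂_Oj / γ̂_Ej,    se(β̂_j) ≈ σ_Oj / |γ̂_Ej|,

and the inverse-variance-weighted (IVW) estimate pools them with weights
w_j = 1/se(β̂_j)²:

    β̂_IVW = Σ w_j β̂_j / Σ w_j,

equivalently a weighted through-origin regression of γ̂_O on γ̂_E.  Because
real instruments may be invalid (horizontal pleiotropy), the package also
fits MR-Egger (a free intercept absorbs directional pleiotropy under the
InSIDE assumption), the weighted median (consistent if ≥ 50 % of weight is
valid), the weighted mode (plurality-valid), multivariable IVW, and
MR-PRESSO (simulation-based outlier detection and removal).  Sensitivity
tooling covers Cochran's Q / I², leave-one-out and single-SNP tables,
funnel data, Steiger directionality, instrument-threshold scans and
bi-directional analysis.  A separate module learns linear-Gaussian Bayesian
networks by BIC hill climbing with genetic directional anchors
(white/black lists) and bootstrap edge probabilities.

## Worked example

Simulate a two-sample study with a true causal effect of 0.15, then fit the
whole battery:

```python
import causalmr as cm

cfg = cm.SimulationConfig(n_snps=60, n_exposure=50_000, n_outcome=50_000,
                          gamma_mean=0.1, gamma_sd=0.03, beta=0.15, seed=42)
study = cm.simulate_two_sample(cfg)

model = cm.MRModel.from_summary_datasets(study.exposure_summary,
                                         study.outcome_summary)  # p < 5e-8
print(model.fit_all(seed=0).summary())
```

```
Two-sample Mendelian randomisation
  exposure: exposure
  outcome:  outcome
  instruments kept: 58

method                  estimate        se    ci_low   ci_high        pval
ivw_multiplicative        0.1497    0.0117    0.1263    0.1732    2.22e-18
ivw_fixed                 0.1497    0.0103    0.1295    0.1700    1.77e-47
ivw_additive              0.1482    0.0120    0.1246    0.1717    5.26e-35
egger                     0.1645    0.0479    0.0686    0.2603     0.00112
weighted_median           0.1506    0.0167    0.1179    0.1833    1.72e-19
weighted_mode             0.1461    0.0324    0.0826    0.2096    6.54e-06

  Egger intercept: -0.0015 (se 0.0047, p 0.752)
```

Every method's 95 % CI covers the true effect 0.15; the Egger intercept is
compatible with zero, i.e. no evidence of directional pleiotropy.  The
sensitivity report adds the heterogeneity and directionality diagnostics:

```python
rep = model.sensitivity()
het = rep.heterogeneity["ivw_fixed"]
# Cochran Q = 73.1 (df 57, p = 0.0741), I2 = 0.22
# Steiger: direction forward (p ~ 0)
```

A command-line interface wraps the same pipeline
(`causalmr run|simulate|screen|bn|presso`, see `causalmr --help`).

## Layout

* `causalmr.summary_data` — readers, allele harmonisation, LD pruning,
  instrument selection, R²/F strength metrics
* `causalmr.estimators` — Wald ratio, IVW (fixed / additive / multiplicative),
  MR-Egger, weighted median/mode, multivariable IVW, mediation arithmetic
* `causalmr.presso` — MR-PRESSO global / outlier / distortion tests
* `causalmr.sensitivity` — Q/I², leave-one-out, single-SNP, funnel data,
  Steiger test and filter, threshold scan, bi-directional orchestration
* `causalmr.screening` — heritability/correlation pre-filters and bulk
  bi-directional IVW screening
* `causalmr.bayesnet` — BIC hill climbing with anchors, bootstrap edge support
* `causalmr.simulate` — individual-level and direct-mode synthetic
  two-sample GWAS generator with known ground truth
* `causalmr.model` — `MRModel` / `MRResults` front end
* `causalmr.cli` — `causalmr` command-line tool

See `docs/methods.md` for the statistical details, generator assumptions
and numerical choices.
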