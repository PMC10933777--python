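"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator realises the standard instrumental-variable model: independent
biallelic SNPs Z_j (dosage 0/1/2), a latent confounder U, exposure
X = Σ_j γ_j Z_j + κ_x U + ε_x and outcome Y = βX + Σ_j α_j Z_j + κ_y U + ε_y.
Per-SNP pleiotropic effects α_j realise the classical bias regimes:

* ``none`` — α_j = 0 (all instruments valid);
* ``balanced`` — α_j ~ N(0, σ_α): heterogeneity without directional bias;
* ``directional`` — α_j ~ N(μ_α, σ_α) with μ_α ≠ 0: biases IVW, detectable
  by the Egger intercept (InSIDE holds when α is independent of γ);
* ``correlated`` — α_j = θγ_j + noise: violates InSIDE.

Two cohorts are simulated at the individual level and summarised by per-SNP
simple regressions, so sample overlap, collider selection and winner's
curse arise exactly as they would in real data.  A fast direct
summary-statistic mode (:func:`simulate_summary_direct`) draws the marginal
estimates straight from their asymptotic normal distributions for
calibration loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .summary_data import SUMMARY_COLUMNS, SummaryDataset

logger = logging.getLogger(__name__)


@dataclass
class PleiotropyConfig:
    """Per-SNP direct-effect regime.

    ``fraction`` is the share of SNPs carrying a pleiotropic effect (the
    rest stay valid); ``cor_slope`` is θ in the correlated regime."""

    kind: str = "none"  # none | balanced | directional | correlated
    mean: float = 0.0
    sd: float = 0.0
    cor_slope: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "correlated"):
            raise ValidationError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0:
            raise ValidationError("pleiotropy sd must be >= 0")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValidationError("pleiotropy fraction must be in [0,1]")


@dataclass
class SelectionConfig:
    """Logistic participation rule P(keep) = expit(intercept + c_x X + c_y Y + c_u U).

    Non-zero coefficients on two variables make participation a collider,
    inducing the classical selection biases."""

    intercept: float = 1.0
    coef_x: float = 0.0
    coef_y: float = 0.0
    coef_u: float = 0.0


@dataclass
class SimulationConfig:
    """Full description of one synthetic two-sample study."""

    n_snps: int = 100
    n_exposure: int = 50_000
    n_outcome: int = 50_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta: float = 0.0
    gamma_mean: float = 0.05
    gamma_sd: float = 0.01
    pleiotropy: PleiotropyConfig = field(default_factory=PleiotropyConfig)
    kappa_x: float = 0.3
    kappa_y: float = 0.3
    noise_sd_x: float = 1.0
    noise_sd_y: float = 1.0
    overlap_fraction: float = 0.0
    selection: SelectionConfig | None = None
    n_selection_sample: int | None = None
    reverse: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValidationError("overlap_fraction must be in [0,1]")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated study."""

    beta: float
    gamma: np.ndarray
    alpha: np.ndarray
    r2_instruments: float


@dataclass
class SimulatedStudy:
    """Exposure and outcome summary datasets plus the generating truth."""

    exposure_summary: SummaryDataset
    outcome_summary: SummaryDataset
    truth: SimulationTruth
    config: SimulationConfig
    seed: int | None
    #: independent third-cohort exposure GWAS for instrument selection
    #: (three-sample design avoiding winner's curse); None unless requested
    selection_summary: SummaryDataset | None = None

    def write(self, exposure_path, outcome_path, truth_path=None) -> None:
        self.exposure_summary.to_tsv(exposure_path)
        self.outcome_summary.to_tsv(outcome_path)
        if truth_path is not None:
            import json

            with open(truth_path, "w") as fh:
                json.dump(
                    {
                        "beta": self.truth.beta,
                        "gamma": list(map(float, self.truth.gamma)),
                        "alpha": list(map(float, self.truth.alpha)),
                        "r2_instruments": self.truth.r2_instruments,
                        "seed": self.seed,
                    },
                    fh,
                    indent=1,
                )


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    p = cfg.pleiotropy
    j = cfg.n_snps
    alpha = np.zeros(j)
    if p.kind == "none":
        return alpha
    n_affected = int(round(p.fraction * j))
    idx = rng.choice(j, size=n_affected, replace=False) if n_affected < j else np.arange(j)
    if p.kind == "balanced":
        alpha[idx] = rng.normal(0.0, p.sd, size=len(idx))
    elif p.kind == "directional":
        alpha[idx] = rng.normal(p.mean, p.sd, size=len(idx))
    else:  # correlated
        alpha[idx] = p.cor_slope * gamma[idx] + rng.normal(0.0, p.sd, size=len(idx))
    return alpha


def _marginal_regressions(Z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple-regression slope, SE and two-sided p (vectorised)."""
    n = len(y)
    zbar = Z.mean(axis=0)
    yc = y - y.mean()
    szz = (Z * Z).sum(axis=0) - n * zbar**2
    szy = Z.T @ yc
    szz = np.maximum(szz, np.finfo(float).tiny)
    slope = szy / szz
    syy = float(yc @ yc)
    sse = np.maximum(syy - slope * szy, 0.0)
    se = np.sqrt(sse / (n - 2) / szz)
    se = np.maximum(se, np.finfo(float).tiny)
    t = slope / se
    pval = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), np.finfo(float).tiny, 1.0)
    return slope, se, pval


def _summary_frame(snp_ids, maf_hat, slope, se, pval, n) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": maf_hat,
            "beta": slope,
            "se": se,
            "pval": pval,
            "n": n,
        },
        columns=SUMMARY_COLUMNS,
    )


def _apply_selection(sel: SelectionConfig, x, y, u, rng) -> np.ndarray:
    score = sel.intercept + sel.coef_x * x + sel.coef_y * y + sel.coef_u * u
    keep = rng.random(len(x)) < 1.0 / (1.0 + np.exp(-score))
    if keep.mean() < 0.1:
        raise ValidationError("selection rule removes more than 90% of a cohort")
    return keep


def simulate_two_sample(config: SimulationConfig) -> SimulatedStudy:
    """Generate a two-sample study at the individual level and summarise it.

    The two cohorts share the first ⌊overlap_fraction·min(n)⌋ individuals;
    the per-SNP summaries are simple linear regressions within each cohort
    (exposure on dosage in cohort 1, outcome on dosage in cohort 2)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    if min(cfg.n_exposure, cfg.n_outcome) < 10 * j:
        logger.warning("cohort size < 10×n_snps: weak-summary regime")

    maf = rng.uniform(*cfg.maf_range, size=j)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=j)
    alpha = _draw_alpha(cfg, gamma, rng)

    n_shared = int(np.floor(cfg.overlap_fraction * min(cfg.n_exposure, cfg.n_outcome)))

    def gen_individuals(n: int):
        Z = rng.binomial(2, maf, size=(n, j)).astype(np.float64)
        u = rng.standard_normal(n)
        eps_x = rng.normal(0.0, cfg.noise_sd_x, size=n)
        eps_y = rng.normal(0.0, cfg.noise_sd_y, size=n)
        if not cfg.reverse:
            x = Z @ gamma + cfg.kappa_x * u + eps_x
            y = cfg.beta * x + Z @ alpha + cfg.kappa_y * u + eps_y
        else:
            y = Z @ gamma + cfg.kappa_y * u + eps_y
            x = cfg.beta * y + Z @ alpha + cfg.kappa_x * u + eps_x
        return Z, u, x, y

    Zs, us, xs, ys = gen_individuals(n_shared) if n_shared else (None,) * 4

    def cohort(n_total: int):
        n_new = n_total - n_shared
        Zn, un, xn, yn = gen_individuals(n_new)
        if n_shared:
            return (
                np.vstack([Zs, Zn]),
                np.concatenate([us, un]),
                np.concatenate([xs, xn]),
                np.concatenate([ys, yn]),
            )
        return Zn, un, xn, yn

    Z1, u1, x1, y1 = cohort(cfg.n_exposure)
    Z2, u2, x2, y2 = cohort(cfg.n_outcome)

    if cfg.selection is not None:
        keep1 = _apply_selection(cfg.selection, x1, y1, u1, rng)
        Z1, x1 = Z1[keep1], x1[keep1]
        keep2 = _apply_selection(cfg.selection, x2, y2, u2, rng)
        Z2, y2 = Z2[keep2], y2[keep2]

    snp_ids = [f"rs{i+1:05d}" for i in range(j)]
    b1, s1, p1 = _marginal_regressions(Z1, x1)
    b2, s2, p2 = _marginal_regressions(Z2, y2)

    exposure = SummaryDataset(
        "exposure", _summary_frame(snp_ids, Z1.mean(0) / 2, b1, s1, p1, len(x1))
    )
    outcome = SummaryDataset(
        "outcome", _summary_frame(snp_ids, Z2.mean(0) / 2, b2, s2, p2, len(y2))
    )

    selection_summary = None
    if cfg.n_selection_sample:
        Z3, _, x3, _ = gen_individuals(cfg.n_selection_sample)
        b3, s3, p3 = _marginal_regressions(Z3, x3)
        selection_summary = SummaryDataset(
            "exposure_selection", _summary_frame(snp_ids, Z3.mean(0) / 2, b3, s3, p3, len(x3))
        )

    var_x = float(np.var(x1))
    vz = Z1.var(axis=0)
    r2 = float((gamma**2 * vz).sum() / var_x) if var_x > 0 else 0.0
    truth = SimulationTruth(beta=cfg.beta, gamma=gamma, alpha=alpha, r2_instruments=r2)
    return SimulatedStudy(exposure, outcome, truth, cfg, cfg.seed, selection_summary)


def simulate_summary_direct(config: SimulationConfig) -> SimulatedStudy:
    """Draw the per-SNP summary estimates directly from their asymptotic
    normal distributions (no individual-level data).

    Much faster than :func:`simulate_two_sample` and exact for the
    no-selection, no-overlap case; selection and overlap are not
    representable here and raise."""
    cfg = config
    if cfg.selection is not None or cfg.overlap_fraction > 0:
        raise ValidationError("direct mode does not support selection or sample overlap")
    if cfg.reverse:
        raise ValidationError("direct mode generates forward (X→Y) truth only")
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=j)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=j)
    alpha = _draw_alpha(cfg, gamma, rng)

    vz = 2.0 * maf * (1.0 - maf)
    var_x = float((gamma**2 * vz).sum() + cfg.kappa_x**2 + cfg.noise_sd_x**2)
    b_total = cfg.beta * gamma + alpha  # total SNP effect on Y
    var_y = float(
        (b_total**2 * vz).sum()
        + (cfg.kappa_y + cfg.beta * cfg.kappa_x) ** 2
        + cfg.noise_sd_y**2
        + (cfg.beta * cfg.noise_sd_x) ** 2
    )
    se_e = np.sqrt(np.maximum(var_x - gamma**2 * vz, 1e-12) / (cfg.n_exposure * vz))
    se_o = np.sqrt(np.maximum(var_y - b_total**2 * vz, 1e-12) / (cfg.n_outcome * vz))
    beta_e = rng.normal(gamma, se_e)
    beta_o = rng.normal(b_total, se_o)
    p_e = np.clip(2.0 * stats.norm.sf(np.abs(beta_e / se_e)), np.finfo(float).tiny, 1.0)
    p_o = np.clip(2.0 * stats.norm.sf(np.abs(beta_o / se_o)), np.finfo(float).tiny, 1.0)

    snp_ids = [f"rs{i+1:05d}" for i in range(j)]
    exposure = SummaryDataset(
        "exposure", _summary_frame(snp_ids, maf, beta_e, se_e, p_e, cfg.n_exposure)
    )
    outcome = SummaryDataset(
        "outcome", _summary_frame(snp_ids, maf, beta_o, se_o, p_o, cfg.n_outcome)
    )
    r2 = float((gamma**2 * vz).sum() / var_x)
    truth = SimulationTruth(beta=cfg.beta, gamma=gamma, alpha=alpha, r2_instruments=r2)
    return SimulatedStudy(exposure, outcome, truth, cfg, cfg.seed)


CONFIDENCE_LEVELS = ("none", "low", "medium", "high")


def simulate_screen_fixture(
    n_traits: int = 10,
    n_causal_pairs: int = 2,
    snps_per_trait: int = 5,
    n_per_cohort: int = 4000,
    beta: float = 0.3,
    gamma: float = 0.2,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, SummaryDataset], dict]:
    """Multi-trait fixture for the screening pipeline.

    Builds ``n_traits`` continuous traits, each with ``snps_per_trait``
    dedicated instrument SNPs of effect ``gamma``, and wires the first
    ``n_causal_pairs`` disjoint trait pairs with a true causal effect
    ``beta`` (T01→T02, T03→T04, ...).  Each trait's GWAS is computed on its
    own independent cohort over the shared SNP panel, giving a two-sample
    structure for every pair.

    Returns ``(heritability_table, correlation_table, datasets, truth)``.
    The heritability table carries extra filler traits that each fail
    exactly one of the standard filters (p-value, confidence, LD intercept)
    so every screening threshold has passing and failing exemplars; the
    correlation table likewise includes a planted pair that passes the
    |ρ| filter but fails the significance filter.
    """
    if 2 * n_causal_pairs > n_traits:
        raise ValidationError("need at least two traits per causal pair")
    rng = np.random.default_rng(seed)
    traits = [f"T{i+1:02d}" for i in range(n_traits)]
    causal_pairs = [(traits[2 * i], traits[2 * i + 1]) for i in range(n_causal_pairs)]
    j_panel = n_traits * snps_per_trait
    maf = rng.uniform(0.2, 0.5, size=j_panel)
    snp_ids = [f"rs{i+1:05d}" for i in range(j_panel)]

    # per-trait instrument loadings over the shared panel
    gam = np.zeros((n_traits, j_panel))
    for t in range(n_traits):
        gam[t, t * snps_per_trait : (t + 1) * snps_per_trait] = gamma

    cause_of = {b: a for a, b in causal_pairs}

    def trait_values(Z: np.ndarray, eps: np.ndarray) -> np.ndarray:
        vals = np.empty((Z.shape[0], n_traits))
        for t, name in enumerate(traits):
            vals[:, t] = Z @ gam[t] + eps[:, t]
        for a, b in causal_pairs:
            vals[:, traits.index(b)] += beta * vals[:, traits.index(a)]
        return vals

    datasets: dict[str, SummaryDataset] = {}
    for t, name in enumerate(traits):
        Z = rng.binomial(2, maf, size=(n_per_cohort, j_panel)).astype(np.float64)
        eps = rng.standard_normal((n_per_cohort, n_traits))
        vals = trait_values(Z, eps)
        b, s, p = _marginal_regressions(Z, vals[:, t])
        datasets[name] = SummaryDataset(
            name, _summary_frame(snp_ids, Z.mean(0) / 2, b, s, p, n_per_cohort)
        )

    # one joint cohort for observational phenotype-phenotype correlations
    Zc = rng.binomial(2, maf, size=(n_per_cohort, j_panel)).astype(np.float64)
    epsc = rng.standard_normal((n_per_cohort, n_traits))
    valsc = trait_values(Zc, epsc)
    corr_rows = []
    for i in range(n_traits):
        for k in range(i + 1, n_traits):
            r, p = stats.pearsonr(valsc[:, i], valsc[:, k])
            corr_rows.append(
                {"trait_a": traits[i], "trait_b": traits[k], "rho": float(r),
                 "pval": float(p), "n": n_per_cohort}
            )
    # planted pair: passes |rho| > 0.10 but fails -log10(p) > 12
    corr_rows.append(
        {"trait_a": "F_weakp_a", "trait_b": "F_weakp_b", "rho": 0.15, "pval": 1e-10, "n": 500}
    )
    correlations = pd.DataFrame(corr_rows)

    herit_rows = [
        {"trait": name, "h2": float(rng.uniform(0.05, 0.40)), "h2_pval": 1e-6,
         "confidence": "high", "ld_intercept": float(rng.uniform(1.00, 1.05))}
        for name in traits
    ]
    herit_rows += [
        {"trait": "F_highp", "h2": 0.20, "h2_pval": 0.50, "confidence": "high", "ld_intercept": 1.02},
        {"trait": "F_lowconf", "h2": 0.20, "h2_pval": 1e-6, "confidence": "low", "ld_intercept": 1.02},
        {"trait": "F_stratified", "h2": 0.20, "h2_pval": 1e-6, "confidence": "high", "ld_intercept": 1.30},
    ]
    heritability = pd.DataFrame(herit_rows)

    truth = {
        "causal_pairs": causal_pairs,
        "beta": beta,
        "gamma": gamma,
        "snps_per_trait": snps_per_trait,
        "seed": seed,
    }
    return heritability, correlations, datasets, truth
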