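"""Causal-effect estimators for summary-level Mendelian randomisation.

All estimators consume allele-aligned per-SNP association pairs
(γ̂_E, γ̂_O with standard errors) and return an :class:`MREstimate`.  The
single-SNP building block is the Wald ratio β̂_j = γ̂_Oj/γ̂_Ej; multi-SNP
methods combine the per-SNP ratios meta-analytically (IVW in fixed,
additive-random and multiplicative-random variants) or fit robust
alternatives that tolerate some invalid instruments (MR-Egger with a free
pleiotropy intercept, weighted median, weighted mode).  Multivariable IVW
and the two classical mediation decompositions round out the battery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .summary_data import HarmonisedInstruments

logger = logging.getLogger(__name__)

_Z975 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One method's causal-effect estimate with uncertainty.

    ``estimate`` is in outcome units per exposure unit.  Method-specific
    extras (Egger intercept triple, additive-RE tau2, multiplicative
    over-dispersion scale, ...) live in ``extras``.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "n_snps": self.n_snps,
        }
        for k, v in self.extras.items():
            d[f"{self.method}_{k}"] = v
        return d


@dataclass
class RatioSet:
    """Per-SNP Wald ratios, their SEs and inverse-variance weights."""

    snp_ids: list[str]
    beta: np.ndarray
    se: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.beta)


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition of an exposure→outcome effect."""

    total: float
    direct: float
    indirect_difference: float
    indirect_product: float
    a: float
    b: float


def _normal_estimate(method: str, est: float, se: float, n_snps: int, extras=None) -> MREstimate:
    z = est / se
    return MREstimate(
        method=method,
        estimate=float(est),
        se=float(se),
        ci_low=float(est - _Z975 * se),
        ci_high=float(est + _Z975 * se),
        pval=float(min(1.0, 2.0 * stats.norm.sf(abs(z)))),
        n_snps=n_snps,
        extras=extras or {},
    )


def wald_ratio(
    beta_exposure: float, se_exposure: float, beta_outcome: float, se_outcome: float
) -> MREstimate:
    """Single-instrument ratio estimate γ̂_O/γ̂_E.

    The SE is the first-order delta-method approximation se_O/|γ̂_E|
    (exposure uncertainty neglected); CI and p-value are normal.
    """
    if beta_exposure == 0:
        raise ValidationError("undefined ratio: beta_exposure is zero")
    if se_outcome <= 0:
        raise ValidationError("se_outcome must be > 0")
    est = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    return _normal_estimate("wald_ratio", est, se, 1)


def _kept_arrays(h: HarmonisedInstruments):
    kept = h.kept
    if kept.empty:
        raise ValidationError("no kept instruments")
    return (
        list(kept["snp_id"]),
        kept["beta_exposure"].to_numpy(dtype=float),
        kept["se_exposure"].to_numpy(dtype=float),
        kept["beta_outcome"].to_numpy(dtype=float),
        kept["se_outcome"].to_numpy(dtype=float),
    )


def ratio_set(h: HarmonisedInstruments, weight_order: str = "first_order") -> RatioSet:
    """Per-SNP ratio estimates with inverse-variance weights.

    ``first_order`` uses se_j = se_Oj/|γ̂_Ej| (NOME approximation);
    ``second_order`` adds the exposure-uncertainty term
    √(se_O²/γ̂_E² + γ̂_O²·se_E²/γ̂_E⁴).
    """
    ids, be, se_e, bo, se_o = _kept_arrays(h)
    zero = np.flatnonzero(be == 0)
    if zero.size:
        raise ValidationError(f"beta_exposure is zero for SNP {ids[zero[0]]!r}")
    beta = bo / be
    if weight_order == "first_order":
        se = se_o / np.abs(be)
    elif weight_order == "second_order":
        se = np.sqrt(se_o**2 / be**2 + bo**2 * se_e**2 / be**4)
    else:
        raise ValidationError(f"unknown weight_order {weight_order!r}")
    return RatioSet(ids, beta, se, 1.0 / se**2)


def _ivw_fixed(beta: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    return float((w * beta).sum() / sw), float(sw**-0.5)


def _cochran_q(beta: np.ndarray, w: np.ndarray) -> float:
    est, _ = _ivw_fixed(beta, w)
    return float((w * (beta - est) ** 2).sum())


def ivw(
    h: HarmonisedInstruments,
    model: str = "multiplicative",
    weight_order: str = "first_order",
) -> MREstimate:
    """Inverse-variance-weighted meta-analysis of per-SNP ratio estimates.

    * ``fixed`` — β̂ = Σwβ̂_j/Σw, se = (Σw)^{-1/2};
    * ``multiplicative`` — same point estimate, se scaled by
      √(max(1, Q/(J−1))): heterogeneity widens the interval but never moves
      the estimate;
    * ``additive`` — DerSimonian–Laird τ² added to each variance before
      re-weighting.

    A single instrument degenerates to :func:`wald_ratio` (logged).
    """
    rs = ratio_set(h, weight_order)
    j = len(rs)
    if j == 0:
        raise ValidationError("no instruments")
    if j == 1:
        logger.info("ivw with a single instrument: returning the Wald ratio")
        est, se = rs.beta[0], rs.se[0]
        return _normal_estimate(f"ivw_{model}", est, se, 1)

    if model == "fixed":
        est, se = _ivw_fixed(rs.beta, rs.weights)
        return _normal_estimate("ivw_fixed", est, se, j)
    if model == "multiplicative":
        # through-origin WLS with estimated residual scale: t(J-1) inference
        est, se = _ivw_fixed(rs.beta, rs.weights)
        q = _cochran_q(rs.beta, rs.weights)
        scale = float(np.sqrt(max(1.0, q / (j - 1))))
        se_m = se * scale
        tdist = stats.t(df=j - 1)
        tcrit = tdist.ppf(0.975)
        return MREstimate(
            method="ivw_multiplicative",
            estimate=float(est),
            se=float(se_m),
            ci_low=float(est - tcrit * se_m),
            ci_high=float(est + tcrit * se_m),
            pval=float(min(1.0, 2.0 * tdist.sf(abs(est / se_m)))),
            n_snps=j,
            extras={"scale": scale, "q": q},
        )
    if model == "additive":
        w = rs.weights
        q = _cochran_q(rs.beta, w)
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (j - 1)) / denom)
        w_star = 1.0 / (rs.se**2 + tau2)
        est, se = _ivw_fixed(rs.beta, w_star)
        return _normal_estimate("ivw_additive", est, se, j, {"tau2": tau2, "q": q})
    raise ValidationError(f"unknown IVW model {model!r}")


def egger(h: HarmonisedInstruments) -> MREstimate:
    """MR-Egger: WLS of γ̂_O on γ̂_E with a free intercept.

    SNPs are oriented so γ̂_E ≥ 0 (joint sign flip, allele-label
    invariant).  Weights are 1/se_O²; both coefficient SEs carry a
    multiplicative over-dispersion factor √(max(1, RSS_w/(J−2))) and
    inference is on t(J−2).  A non-zero intercept flags directional
    pleiotropy (valid under InSIDE).
    """
    ids, be, se_e, bo, se_o = _kept_arrays(h)
    j = len(ids)
    if j < 3:
        raise ValidationError("MR-Egger requires at least 3 instruments")
    sign = np.where(be < 0, -1.0, 1.0)
    x = be * sign
    y = bo * sign
    if np.allclose(x, x[0]):
        raise ValidationError("unidentifiable slope: no variance in oriented beta_exposure")
    w = 1.0 / se_o**2

    design = np.column_stack([np.ones(j), x])
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    resid = y - design @ coef
    rss_w = float((w * resid**2).sum())
    scale2 = max(1.0, rss_w / (j - 2))
    cov = np.linalg.inv(design.T @ (design * w[:, None])) * scale2
    se = np.sqrt(np.diag(cov))

    tdist = stats.t(df=j - 2)
    tcrit = tdist.ppf(0.975)
    slope, slope_se = float(coef[1]), float(se[1])
    icept, icept_se = float(coef[0]), float(se[0])
    return MREstimate(
        method="egger",
        estimate=slope,
        se=slope_se,
        ci_low=slope - tcrit * slope_se,
        ci_high=slope + tcrit * slope_se,
        pval=float(min(1.0, 2.0 * tdist.sf(abs(slope / slope_se)))),
        n_snps=j,
        extras={
            "intercept": icept,
            "intercept_se": icept_se,
            "intercept_pval": float(min(1.0, 2.0 * tdist.sf(abs(icept / icept_se)))),
            "scale": float(np.sqrt(scale2)),
        },
    )


def _weighted_median(beta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(beta, kind="stable")
    b = beta[order]
    ww = w[order]
    s = (np.cumsum(ww) - 0.5 * ww) / ww.sum()
    return float(np.interp(0.5, s, b))


def weighted_median(
    h: HarmonisedInstruments,
    n_boot: int = 1000,
    seed: int | None = None,
    weight_order: str = "first_order",
) -> MREstimate:
    """Weighted median of the per-SNP ratios (consistent if ≥50% of the
    weight lies on valid instruments).

    The point estimate interpolates the ratio against standardised
    cumulative weights at 0.5; the SE is a parametric bootstrap that
    resamples γ̂_E and γ̂_O from normals with their reported SEs.
    """
    ids, be, se_e, bo, se_o = _kept_arrays(h)
    if len(ids) < 3:
        raise ValidationError("weighted median requires at least 3 instruments")
    rs = ratio_set(h, weight_order)
    est = _weighted_median(rs.beta, rs.weights)
    se = _bootstrap_se(_weighted_median, be, se_e, bo, se_o, n_boot, seed)
    return _normal_estimate("weighted_median", est, se, len(ids), {"n_boot": n_boot})


def _mode_bandwidth(beta: np.ndarray, phi: float) -> float:
    # modified Silverman rule on the ratio estimates
    sd = float(np.std(beta, ddof=1)) if len(beta) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(beta, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * len(beta) ** (-1 / 5)


def _weighted_mode(beta: np.ndarray, w: np.ndarray, phi: float = 1.0) -> float:
    h_bw = _mode_bandwidth(beta, phi)
    if h_bw <= 0:
        return float(beta[0])
    grid = np.linspace(beta.min() - 3 * h_bw, beta.max() + 3 * h_bw, 512)
    wn = w / w.sum()
    dens = (wn[:, None] * stats.norm.pdf((grid[None, :] - beta[:, None]) / h_bw)).sum(0) / h_bw
    return float(grid[np.argmax(dens)])


def weighted_mode(
    h: HarmonisedInstruments,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    weight_order: str = "first_order",
) -> MREstimate:
    """Mode of a weighted Gaussian KDE over the per-SNP ratios (consistent
    if a plurality of the weight lies on valid instruments).

    Bandwidth is φ·0.9·min(sd, IQR/1.34)·J^{−1/5}; the estimate is the
    argmax on a 512-point grid spanning the ratio range ± 3 bandwidths.
    SE by parametric bootstrap as for the weighted median.
    """
    ids, be, se_e, bo, se_o = _kept_arrays(h)
    if len(ids) < 3:
        raise ValidationError("weighted mode requires at least 3 instruments")
    rs = ratio_set(h, weight_order)
    est = _weighted_mode(rs.beta, rs.weights, bandwidth_factor)
    se = _bootstrap_se(
        lambda b, w: _weighted_mode(b, w, bandwidth_factor), be, se_e, bo, se_o, n_boot, seed
    )
    return _normal_estimate(
        "weighted_mode", est, se, len(ids), {"bandwidth_factor": bandwidth_factor, "n_boot": n_boot}
    )


def _bootstrap_se(statistic, be, se_e, bo, se_o, n_boot: int, seed) -> float:
    """Parametric bootstrap over the summary likelihood: redraw both
    association vectors from normals at their reported SEs, recompute the
    statistic on first-order weights, take the SD."""
    rng = np.random.default_rng(seed)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        be_s = rng.normal(be, se_e)
        bo_s = rng.normal(bo, se_o)
        be_s = np.where(be_s == 0, np.finfo(float).tiny, be_s)
        beta = bo_s / be_s
        w = (be_s / se_o) ** 2
        vals[b] = statistic(beta, w)
    return float(np.std(vals, ddof=1))


def mvmr_ivw(
    beta_exposures: np.ndarray | pd.DataFrame,
    beta_outcome: np.ndarray,
    se_outcome: np.ndarray,
    exposure_names: Sequence[str] | None = None,
) -> list[MREstimate]:
    """Multivariable IVW: WLS of γ̂_O on the J×K exposure-association matrix
    (no intercept, weights 1/se_O²), estimating each exposure's direct
    effect while controlling for the others.

    SEs carry multiplicative over-dispersion √(max(1, RSS_w/(J−K))).
    """
    if isinstance(beta_exposures, pd.DataFrame):
        if exposure_names is None:
            exposure_names = list(beta_exposures.columns)
        X = beta_exposures.to_numpy(dtype=float)
    else:
        X = np.asarray(beta_exposures, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    j, k = X.shape
    if exposure_names is None:
        exposure_names = [f"exposure_{i+1}" for i in range(k)]
    y = np.asarray(beta_outcome, dtype=float)
    se_o = np.asarray(se_outcome, dtype=float)
    if j < k + 1:
        raise ValidationError(f"need at least K+1={k+1} instruments, got {j}")
    if np.linalg.matrix_rank(X) < k:
        raise ValidationError("collinear exposures: design matrix is rank deficient")

    w = 1.0 / se_o**2
    xtwx = X.T @ (X * w[:, None])
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    resid = y - X @ coef
    rss_w = float((w * resid**2).sum())
    scale2 = max(1.0, rss_w / (j - k))
    cov = np.linalg.inv(xtwx) * scale2
    ses = np.sqrt(np.diag(cov))
    return [
        _normal_estimate(f"mvmr_ivw[{name}]", coef[i], ses[i], j, {"scale": float(np.sqrt(scale2))})
        for i, name in enumerate(exposure_names)
    ]


def mediation(
    beta_total: float,
    c_direct: float,
    a_exposure_mediator: float,
    b_mediator_outcome: float,
) -> MediationResult:
    """Classical mediation arithmetic on causal-effect estimates.

    Difference method: β̂_med = β̂_tot − ĉ.  Product method: β̂_med = â·b̂
    (the two-step framing: exposure→mediator times mediator→outcome).  The
    two agree asymptotically in linear-Gaussian systems.
    """
    return MediationResult(
        total=float(beta_total),
        direct=float(c_direct),
        indirect_difference=float(beta_total - c_direct),
        indirect_product=float(a_exposure_mediator * b_mediator_outcome),
        a=float(a_exposure_mediator),
        b=float(b_mediator_outcome),
    )


def estimates_to_frame(estimates: Sequence[MREstimate], **labels) -> pd.DataFrame:
    """Tidy one-row-per-method table; ``labels`` (exposure, outcome,
    direction, ...) are prepended as constant columns."""
    rows = []
    for est in estimates:
        row = dict(labels)
        row.update(est.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)
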