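"""Sensitivity workflow for a two-sample MR analysis.

Heterogeneity statistics (Cochran's Q, Higgins' I²), leave-one-out and
single-SNP tables, funnel-plot data, Steiger directionality testing and
filtering, instrument-threshold scans and the bi-directional orchestration
that runs the full estimator battery in both causal directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .estimators import (
    MREstimate,
    RatioSet,
    egger,
    estimates_to_frame,
    ivw,
    ratio_set,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from .summary_data import (
    HarmonisedInstruments,
    SummaryDataset,
    harmonise,
    select_instruments,
)

logger = logging.getLogger(__name__)


@dataclass
class HeterogeneityStats:
    """Cochran's Q with chi-square p and Higgins' I² = max(0, (Q−df)/Q)."""

    q: float
    df: int
    pval: float
    i2: float


@dataclass
class SteigerResult:
    """Directionality test on aggregate variance explained per trait."""

    r2_exposure: float
    r2_outcome: float
    z: float
    pval: float
    direction: str  # forward | reverse | inconclusive


@dataclass
class SensitivityReport:
    """Bundle of the standard sensitivity outputs for one analysis."""

    heterogeneity: dict[str, HeterogeneityStats]
    egger_intercept: dict | None
    leave_one_out: pd.DataFrame
    single_snp: pd.DataFrame
    funnel: pd.DataFrame
    steiger: SteigerResult | None
    threshold_scan: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "heterogeneity": {
                k: vars(v) for k, v in self.heterogeneity.items()
            },
            "egger_intercept": self.egger_intercept,
            "leave_one_out": self.leave_one_out.to_dict(orient="records"),
            "single_snp": self.single_snp.to_dict(orient="records"),
            "funnel": self.funnel.to_dict(orient="records"),
            "steiger": None if self.steiger is None else vars(self.steiger),
            "threshold_scan": None
            if self.threshold_scan is None
            else self.threshold_scan.to_dict(orient="records"),
        }


def cochran_q(ratios: RatioSet, pooled: MREstimate, df_adjust: int = 1) -> HeterogeneityStats:
    """Q = Σ w_j (β̂_j − β̂)² against the pooled estimate, df = J − df_adjust."""
    j = len(ratios)
    if j <= df_adjust:
        raise ValidationError(f"need more than {df_adjust} instruments for Q")
    q = float((ratios.weights * (ratios.beta - pooled.estimate) ** 2).sum())
    df = j - df_adjust
    pval = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q == 0 else max(0.0, (q - df) / q)
    return HeterogeneityStats(q=q, df=df, pval=pval, i2=i2)


def _method_fn(method: str, seed=None) -> Callable[[HarmonisedInstruments], MREstimate]:
    name = method.replace("-", "_")
    if name in ("ivw", "ivw_multiplicative"):
        return lambda h: ivw(h, model="multiplicative")
    if name == "ivw_fixed":
        return lambda h: ivw(h, model="fixed")
    if name == "ivw_additive":
        return lambda h: ivw(h, model="additive")
    if name == "egger":
        return egger
    if name == "weighted_median":
        return lambda h: weighted_median(h, seed=seed)
    if name == "weighted_mode":
        return lambda h: weighted_mode(h, seed=seed)
    raise ValidationError(f"unknown method {method!r}")


def leave_one_out(
    h: HarmonisedInstruments, method: str = "ivw-multiplicative"
) -> pd.DataFrame:
    """Re-estimate omitting each instrument in turn; one row per omitted SNP."""
    kept_ids = list(h.kept["snp_id"])
    if len(kept_ids) < 3:
        raise ValidationError("leave-one-out requires at least 3 instruments")
    fn = _method_fn(method)
    rows = []
    for snp in kept_ids:
        est = fn(h.drop([snp]))
        rows.append(
            {
                "omitted_snp": snp,
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "n_snps": est.n_snps,
            }
        )
    return pd.DataFrame(rows)


def single_snp(h: HarmonisedInstruments) -> pd.DataFrame:
    """Per-SNP Wald ratio table with 95% CIs, in kept order."""
    rows = []
    for _, r in h.kept.iterrows():
        est = wald_ratio(
            r["beta_exposure"], r["se_exposure"], r["beta_outcome"], r["se_outcome"]
        )
        rows.append(
            {
                "snp_id": r["snp_id"],
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
            }
        )
    return pd.DataFrame(rows)


def funnel_data(h: HarmonisedInstruments, weight_order: str = "first_order") -> pd.DataFrame:
    """Funnel-plot table: per-SNP ratio estimate against its precision 1/SE.

    Under balanced pleiotropy the scatter is symmetric about the pooled
    estimate, with precision shrinking the spread (triangular envelope)."""
    rs = ratio_set(h, weight_order)
    return pd.DataFrame(
        {"snp_id": rs.snp_ids, "estimate": rs.beta, "precision": 1.0 / rs.se}
    )


def _per_snp_r(beta: np.ndarray, se: np.ndarray, n: float) -> np.ndarray:
    t = beta / se
    return t / np.sqrt(t**2 + n - 2.0)


def steiger(h: HarmonisedInstruments, alpha: float = 0.05) -> SteigerResult:
    """Aggregate Steiger directionality test.

    Per-SNP correlations are recovered from test statistics
    (r = t/√(t²+n−2)), aggregated as R² = Σ r² per trait, and the two
    aggregate correlations √R² are compared with a Fisher-z test.
    ``forward`` means the instruments explain more variance in the exposure
    — the orientation a valid instrument set should show.
    """
    if h.n_exposure is None or h.n_outcome is None:
        raise ValidationError("Steiger test requires sample sizes for both traits")
    n_exp, n_out = float(h.n_exposure), float(h.n_outcome)
    if n_exp <= 3 or n_out <= 3:
        raise ValidationError("sample sizes must exceed 3")
    kept = h.kept
    r_exp = _per_snp_r(
        kept["beta_exposure"].to_numpy(float), kept["se_exposure"].to_numpy(float), n_exp
    )
    r_out = _per_snp_r(
        kept["beta_outcome"].to_numpy(float), kept["se_outcome"].to_numpy(float), n_out
    )
    r2_exp = float((r_exp**2).sum())
    r2_out = float((r_out**2).sum())
    z = (np.arctanh(min(np.sqrt(r2_exp), 1 - 1e-12)) - np.arctanh(min(np.sqrt(r2_out), 1 - 1e-12))) / np.sqrt(
        1.0 / (n_exp - 3) + 1.0 / (n_out - 3)
    )
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    if pval >= alpha:
        direction = "inconclusive"
    else:
        direction = "forward" if r2_exp > r2_out else "reverse"
    return SteigerResult(
        r2_exposure=r2_exp, r2_outcome=r2_out, z=float(z), pval=pval, direction=direction
    )


def steiger_filter(h: HarmonisedInstruments) -> HarmonisedInstruments:
    """Drop instruments whose per-SNP outcome r² is at least the exposure r²
    (the SNP looks more primary for the outcome than the exposure)."""
    if h.n_exposure is None or h.n_outcome is None:
        raise ValidationError("Steiger filtering requires sample sizes for both traits")
    kept = h.kept
    r_exp = _per_snp_r(
        kept["beta_exposure"].to_numpy(float), kept["se_exposure"].to_numpy(float), float(h.n_exposure)
    )
    r_out = _per_snp_r(
        kept["beta_outcome"].to_numpy(float), kept["se_outcome"].to_numpy(float), float(h.n_outcome)
    )
    forward = r_exp**2 > r_out**2
    removed = list(kept["snp_id"][~forward])
    if removed:
        logger.info("Steiger filter removed %d instrument(s): %s", len(removed), removed)
    if not forward.any():
        logger.warning("Steiger filter removed every instrument")
    return h.subset(list(kept["snp_id"][forward]))


#: default estimator battery for orchestrated analyses
DEFAULT_METHODS = (
    "ivw_multiplicative",
    "ivw_fixed",
    "ivw_additive",
    "egger",
    "weighted_median",
    "weighted_mode",
)


def estimate_battery(
    h: HarmonisedInstruments,
    methods: Sequence[str] = DEFAULT_METHODS,
    seed: int | None = None,
    n_boot: int = 1000,
) -> list[MREstimate]:
    """Run every applicable method from ``methods`` on ``h``.

    Methods whose instrument-count preconditions fail are skipped with a
    log entry rather than raising, so the battery degrades gracefully on
    sparse instrument sets (a single instrument yields only the Wald
    ratio via IVW's degenerate case).
    """
    results = []
    for i, m in enumerate(methods):
        name = m.replace("-", "_")
        try:
            if name in ("ivw", "ivw_multiplicative", "ivw_fixed", "ivw_additive"):
                results.append(ivw(h, model=name.removeprefix("ivw_") or "multiplicative"))
            elif name == "egger":
                results.append(egger(h))
            elif name == "weighted_median":
                results.append(weighted_median(h, n_boot=n_boot, seed=None if seed is None else seed + i))
            elif name == "weighted_mode":
                results.append(weighted_mode(h, n_boot=n_boot, seed=None if seed is None else seed + i))
            else:
                raise ValidationError(f"unknown method {m!r}")
        except ValidationError as exc:
            logger.info("skipping %s: %s", m, exc)
    return results


def sensitivity_report(
    h: HarmonisedInstruments,
    alpha: float = 0.05,
    include_leave_one_out: bool = True,
) -> SensitivityReport:
    """Assemble the standard sensitivity bundle for one instrument set."""
    rs = ratio_set(h)
    het: dict[str, HeterogeneityStats] = {}
    if len(rs) >= 2:
        het["ivw_fixed"] = cochran_q(rs, ivw(h, model="fixed"), df_adjust=1)
    egger_triple = None
    if len(rs) >= 3:
        e = egger(h)
        het["egger"] = cochran_q(rs, e, df_adjust=2)
        egger_triple = {
            "estimate": e.extras["intercept"],
            "se": e.extras["intercept_se"],
            "pval": e.extras["intercept_pval"],
        }
    loo = (
        leave_one_out(h)
        if include_leave_one_out and len(rs) >= 3
        else pd.DataFrame(columns=["omitted_snp", "estimate", "se", "ci_low", "ci_high", "pval", "n_snps"])
    )
    st = None
    if h.n_exposure is not None and h.n_outcome is not None:
        st = steiger(h, alpha=alpha)
    return SensitivityReport(
        heterogeneity=het,
        egger_intercept=egger_triple,
        leave_one_out=loo,
        single_snp=single_snp(h),
        funnel=funnel_data(h),
        steiger=st,
    )


@dataclass
class DirectionResult:
    """One causal direction of a bi-directional analysis."""

    exposure: str
    outcome: str
    status: str  # estimated | not_estimable
    n_snps: int
    estimates: pd.DataFrame = field(default_factory=pd.DataFrame)
    sensitivity: SensitivityReport | None = None


def _run_direction(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    p_threshold: float,
    methods: Sequence[str],
    seed: int | None,
    n_boot: int,
    with_sensitivity: bool,
) -> DirectionResult:
    sel = select_instruments(exposure, p_threshold)
    if len(sel) == 0:
        return DirectionResult(exposure.trait_name, outcome.trait_name, "not_estimable", 0)
    h = harmonise(sel, outcome)
    if h.n_kept == 0:
        return DirectionResult(exposure.trait_name, outcome.trait_name, "not_estimable", 0)
    ests = estimate_battery(h, methods, seed=seed, n_boot=n_boot)
    frame = estimates_to_frame(
        ests, exposure=exposure.trait_name, outcome=outcome.trait_name
    )
    report = sensitivity_report(h) if with_sensitivity else None
    return DirectionResult(
        exposure.trait_name, outcome.trait_name, "estimated", h.n_kept, frame, report
    )


def bidirectional(
    a: SummaryDataset,
    b: SummaryDataset,
    p_threshold: float = 5e-8,
    methods: Sequence[str] = DEFAULT_METHODS,
    seed: int | None = None,
    n_boot: int = 1000,
    with_sensitivity: bool = True,
) -> dict[str, DirectionResult]:
    """Run the full battery with ``a`` as exposure, then with ``b``.

    Directions without instruments come back as ``not_estimable`` — never
    an exception, so bulk screening over many pairs cannot abort."""
    return {
        "forward": _run_direction(a, b, p_threshold, methods, seed, n_boot, with_sensitivity),
        "reverse": _run_direction(b, a, p_threshold, methods, seed, n_boot, with_sensitivity),
    }


def threshold_scan(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    thresholds: Sequence[float] = (1e-6, 5e-8, 1e-12),
    method: str = "ivw-multiplicative",
) -> pd.DataFrame:
    """Repeat instrument selection and estimation at each p-threshold.

    One row per requested threshold; thresholds with no instruments are
    reported with status ``no_instruments`` and NaN estimates."""
    fn = _method_fn(method)
    rows = []
    for thr in thresholds:
        sel = select_instruments(exposure, thr)
        row = {"p_threshold": thr, "n_snps": 0, "status": "no_instruments",
               "estimate": np.nan, "se": np.nan, "ci_low": np.nan,
               "ci_high": np.nan, "pval": np.nan}
        if len(sel):
            h = harmonise(sel, outcome)
            if h.n_kept:
                est = fn(h)
                row.update(
                    n_snps=h.n_kept,
                    status="estimated",
                    estimate=est.estimate,
                    se=est.se,
                    ci_low=est.ci_low,
                    ci_high=est.ci_high,
                    pval=est.pval,
                )
        rows.append(row)
    return pd.DataFrame(rows)
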