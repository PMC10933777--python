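"""Exploratory screening pipeline over many trait pairs.

Pre-selection filters candidate traits on LD-score-regression heritability
(significance, annotation confidence, intercept) and candidate pairs on
phenotype-phenotype correlation, then a bulk bi-directional IVW screen
estimates a causal effect for every surviving pair in both directions.

Screening results are exploratory: significance flags are unadjusted by
design (a Bonferroni-adjusted column is emitted alongside), and pairs
without genome-wide-significant instruments are reported as
``no_instruments`` rather than errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .estimators import ivw
from .summary_data import SummaryDataset, harmonise, select_instruments

logger = logging.getLogger(__name__)

CONFIDENCE_ORDER = {"none": 0, "low": 1, "medium": 2, "high": 3}

HERITABILITY_COLUMNS = ["trait", "h2", "h2_pval", "confidence", "ld_intercept"]
CORRELATION_COLUMNS = ["trait_a", "trait_b", "rho", "pval", "n"]


@dataclass
class HeritabilityRecord:
    trait: str
    h2: float
    h2_pval: float
    confidence: str
    ld_intercept: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValidationError(f"{self.trait}: h2 must be in [0,1]")
        if self.confidence not in CONFIDENCE_ORDER:
            raise ValidationError(f"{self.trait}: unknown confidence {self.confidence!r}")


@dataclass
class PhenoCorrelation:
    trait_a: str
    trait_b: str
    rho: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise ValidationError(f"{self.trait_a}-{self.trait_b}: |rho| > 1")


def filter_heritable(
    records: pd.DataFrame,
    p_max: float = 0.05,
    min_confidence: str = "medium",
    intercept_max: float = 1.1,
) -> pd.DataFrame:
    """Keep traits with h2_pval < p_max, confidence ≥ min_confidence and
    LD-score intercept ≤ intercept_max (a larger intercept suggests
    stratification or confounding).  All inequalities on p are strict,
    matching the printed thresholds; exclusion reasons are logged."""
    df = records.copy()
    conf = df["confidence"].map(CONFIDENCE_ORDER)
    if conf.isna().any():
        bad = df.loc[conf.isna(), "confidence"].iloc[0]
        raise ValidationError(f"unknown confidence label {bad!r}")
    keep_p = df["h2_pval"] < p_max
    keep_c = conf >= CONFIDENCE_ORDER[min_confidence]
    keep_i = df["ld_intercept"] <= intercept_max
    keep = keep_p & keep_c & keep_i
    for _, row in df[~keep].iterrows():
        reasons = []
        if not (row["h2_pval"] < p_max):
            reasons.append("pval")
        if CONFIDENCE_ORDER[row["confidence"]] < CONFIDENCE_ORDER[min_confidence]:
            reasons.append("confidence")
        if not (row["ld_intercept"] <= intercept_max):
            reasons.append("intercept")
        logger.info("excluded trait %s: %s", row["trait"], ",".join(reasons))
    return df[keep].reset_index(drop=True)


def filter_correlated(
    correlations: pd.DataFrame,
    rho_min: float = 0.10,
    neglog10p_min: float = 12.0,
) -> pd.DataFrame:
    """Keep pairs with |ρ| > rho_min and −log10(p) > neglog10p_min (both
    strict).  A p-value of exactly zero is treated as infinitely
    significant (kept) and logged."""
    df = correlations.copy()
    zero_p = df["pval"] == 0
    if zero_p.any():
        logger.info("%d pair(s) with p=0 treated as -log10 p = inf", int(zero_p.sum()))
    with np.errstate(divide="ignore"):
        neglog = -np.log10(df["pval"].to_numpy(dtype=float))
    keep = (df["rho"].abs() > rho_min) & (neglog > neglog10p_min)
    return df[keep].reset_index(drop=True)


SCREEN_COLUMNS = [
    "trait_a",
    "trait_b",
    "direction",
    "status",
    "n_snps",
    "estimate",
    "se",
    "ci_low",
    "ci_high",
    "pval",
    "significant",
    "pval_bonferroni",
]


def screen_pairs(
    pairs: Sequence[tuple[str, str]],
    datasets: Mapping[str, SummaryDataset],
    p_instrument: float = 5e-8,
    alpha: float = 0.05,
    ivw_model: str = "multiplicative",
) -> pd.DataFrame:
    """Bi-directional IVW screen over candidate trait pairs.

    Emits exactly two rows per pair (``a_to_b`` and ``b_to_a``).  A
    direction without instruments at ``p_instrument`` gets status
    ``no_instruments`` with NaN estimates; ``significant`` is defined only
    for estimated rows (unadjusted, with a Bonferroni column over all
    estimated tests alongside)."""
    for a, b in pairs:
        for t in (a, b):
            if t not in datasets:
                raise ValidationError(f"missing dataset for trait {t!r}")

    rows = []
    for a, b in pairs:
        for exposure, outcome, direction in ((a, b, "a_to_b"), (b, a, "b_to_a")):
            row = {
                "trait_a": a,
                "trait_b": b,
                "direction": direction,
                "status": "no_instruments",
                "n_snps": 0,
                "estimate": np.nan,
                "se": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "pval": np.nan,
                "significant": pd.NA,
            }
            sel = select_instruments(datasets[exposure], p_instrument)
            if len(sel):
                h = harmonise(sel, datasets[outcome])
                if h.n_kept:
                    est = ivw(h, model=ivw_model)
                    row.update(
                        status="estimated",
                        n_snps=h.n_kept,
                        estimate=est.estimate,
                        se=est.se,
                        ci_low=est.ci_low,
                        ci_high=est.ci_high,
                        pval=est.pval,
                        significant=bool(est.pval < alpha),
                    )
            rows.append(row)

    out = pd.DataFrame(rows)
    n_tests = int((out["status"] == "estimated").sum())
    out["pval_bonferroni"] = np.minimum(1.0, out["pval"] * max(n_tests, 1))
    return out[SCREEN_COLUMNS]
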