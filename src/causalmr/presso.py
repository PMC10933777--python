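"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

Three stages, all simulation-based with a shared seed:

* **global test** — the observed weighted residual sum of squares
  RSS = Σ_j w_j (γ̂_Oj − β̂_{−j} γ̂_Ej)², with β̂_{−j} the leave-one-out
  IVW estimate, is compared against a parametric null in which both
  association vectors are redrawn from normals centred at
  (γ̂_Ej, β̂_{−j} γ̂_Ej) with their reported SEs;
* **outlier test** — each SNP's observed residual term against its own
  simulated distribution, Bonferroni-adjusted over the J instruments;
* **distortion test** — the relative shift of the outlier-corrected IVW
  estimate against the shift distribution under random removal of the same
  number of instruments.

Empirical p-values use the plus-one rule (r+1)/(n_sim+1), so they are never
exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .estimators import MREstimate, ivw
from .summary_data import HarmonisedInstruments


@dataclass
class PressoResult:
    """Global, per-SNP and distortion test results with the corrected fit."""

    global_rss_observed: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    estimate_raw: MREstimate
    estimate_outlier_corrected: MREstimate | None
    distortion_pval: float | None
    n_sim: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "global_rss_observed": self.global_rss_observed,
            "global_pval": self.global_pval,
            "outlier_pvals": self.outlier_pvals,
            "outlier_ids": self.outlier_ids,
            "estimate_raw": self.estimate_raw.to_dict(),
            "estimate_outlier_corrected": (
                None
                if self.estimate_outlier_corrected is None
                else self.estimate_outlier_corrected.to_dict()
            ),
            "distortion_pval": self.distortion_pval,
            "n_sim": self.n_sim,
            "seed": self.seed,
        }


def _loo_ivw(be: np.ndarray, bo: np.ndarray, se_o: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effects IVW estimates, vectorised over SNPs.

    Works on 1-D arrays or 2-D (n_sim × J) matrices (row-wise)."""
    ratio = bo / be
    w = (be / se_o) ** 2
    sw = w.sum(axis=-1, keepdims=True)
    swb = (w * ratio).sum(axis=-1, keepdims=True)
    return (swb - w * ratio) / (sw - w)


def _weighted_rss_terms(be, bo, se_o) -> np.ndarray:
    beta_loo = _loo_ivw(be, bo, se_o)
    return (bo - beta_loo * be) ** 2 / se_o**2


def presso(
    h: HarmonisedInstruments,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
    distortion_n_sim: int = 1000,
) -> PressoResult:
    """Run the MR-PRESSO global, outlier and distortion tests.

    Requires ≥ 4 instruments (up to half may be pleiotropic).  The
    outlier-corrected estimate is the package-default multiplicative-RE IVW
    on the instruments minus the flagged set; when no SNP is flagged, the
    distortion test is skipped and reported as None.
    """
    kept = h.kept
    j = len(kept)
    if j < 4:
        raise ValidationError("MR-PRESSO requires at least 4 instruments")
    ids = list(kept["snp_id"])
    be = kept["beta_exposure"].to_numpy(dtype=float)
    se_e = kept["se_exposure"].to_numpy(dtype=float)
    bo = kept["beta_outcome"].to_numpy(dtype=float)
    se_o = kept["se_outcome"].to_numpy(dtype=float)
    if (be == 0).any():
        raise ValidationError("beta_exposure of zero among instruments")

    obs_terms = _weighted_rss_terms(be, bo, se_o)
    obs_rss = float(obs_terms.sum())
    beta_loo = _loo_ivw(be, bo, se_o)

    rng = np.random.default_rng(seed)
    be_sim = rng.normal(be, se_e, size=(n_sim, j))
    bo_sim = rng.normal(beta_loo * be, se_o, size=(n_sim, j))
    be_sim = np.where(be_sim == 0, np.finfo(float).tiny, be_sim)
    sim_terms = _weighted_rss_terms(be_sim, bo_sim, se_o)
    sim_rss = sim_terms.sum(axis=1)

    global_pval = float((1 + (sim_rss >= obs_rss).sum()) / (n_sim + 1))

    raw_p = (1 + (sim_terms >= obs_terms).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * j)
    outlier_pvals = dict(zip(ids, adj_p.astype(float)))
    outlier_ids = [s for s, p in outlier_pvals.items() if p < outlier_alpha]

    estimate_raw = ivw(h, model="multiplicative")
    corrected = None
    distortion_pval = None
    if outlier_ids:
        reduced = h.drop(outlier_ids)
        if reduced.n_kept >= 1:
            corrected = ivw(reduced, model="multiplicative")
            distortion_pval = _distortion_test(
                h, estimate_raw.estimate, corrected.estimate, len(outlier_ids), rng,
                distortion_n_sim,
            )
    return PressoResult(
        global_rss_observed=obs_rss,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_ids=outlier_ids,
        estimate_raw=estimate_raw,
        estimate_outlier_corrected=corrected,
        distortion_pval=distortion_pval,
        n_sim=n_sim,
        seed=seed,
    )


def _distortion_test(
    h: HarmonisedInstruments,
    beta_raw: float,
    beta_corrected: float,
    n_remove: int,
    rng: np.random.Generator,
    n_sim: int,
) -> float:
    """Empirical p for the relative estimate shift after outlier removal,
    against random same-size removals."""
    if beta_raw == 0:
        return 1.0
    obs = abs((beta_corrected - beta_raw) / abs(beta_raw))
    kept = h.kept
    be = kept["beta_exposure"].to_numpy(dtype=float)
    bo = kept["beta_outcome"].to_numpy(dtype=float)
    se_o = kept["se_outcome"].to_numpy(dtype=float)
    ratio = bo / be
    w = (be / se_o) ** 2
    j = len(ratio)
    if n_remove >= j:
        return 1.0
    sw, swb = w.sum(), (w * ratio).sum()
    stats_null = np.empty(n_sim)
    for i in range(n_sim):
        rm = rng.choice(j, size=n_remove, replace=False)
        est = (swb - (w[rm] * ratio[rm]).sum()) / (sw - w[rm].sum())
        stats_null[i] = abs((est - beta_raw) / abs(beta_raw))
    return float((1 + (stats_null >= obs).sum()) / (n_sim + 1))
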