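"""statsmodels-style front end: an :class:`MRModel` built from summary data
whose ``fit`` returns an :class:`MRResults` carrying estimates,
uncertainties, diagnostics and a ``summary()`` table.

>>> study = simulate_two_sample(SimulationConfig(beta=0.1, seed=7))
>>> model = MRModel.from_summary_datasets(study.exposure_summary,
...                                       study.outcome_summary)
>>> res = model.fit()           # default: multiplicative-RE IVW
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .estimators import MREstimate, estimates_to_frame, ivw, egger, wald_ratio, weighted_median, weighted_mode
from .presso import PressoResult, presso
from .sensitivity import (
    DEFAULT_METHODS,
    SensitivityReport,
    estimate_battery,
    sensitivity_report,
    threshold_scan,
)
from .summary_data import (
    HarmonisedInstruments,
    SummaryDataset,
    harmonise,
    instrument_strength,
    ld_prune,
    select_instruments,
)


class MRModel:
    """Two-sample MR model for one exposure-outcome pair.

    Construct directly from :class:`HarmonisedInstruments`, or use
    :meth:`from_summary_datasets` to run the standard preparation pipeline
    (instrument selection → LD pruning → harmonisation) first.
    """

    def __init__(self, instruments: HarmonisedInstruments):
        if instruments.n_kept == 0:
            raise ValidationError("model requires at least one kept instrument")
        self.instruments = instruments

    @classmethod
    def from_summary_datasets(
        cls,
        exposure: SummaryDataset,
        outcome: SummaryDataset,
        p_threshold: float = 5e-8,
        ld: pd.DataFrame | None = None,
        r2_threshold: float = 0.001,
        palindromic_eaf_window: float = 0.08,
    ) -> "MRModel":
        sel = select_instruments(exposure, p_threshold)
        if len(sel) == 0:
            raise ValidationError(f"no instruments at p < {p_threshold:g}")
        sel = ld_prune(sel, ld, r2_threshold)
        h = harmonise(sel, outcome, palindromic_eaf_window)
        return cls(h)

    @property
    def exog_names(self) -> list[str]:
        return list(self.instruments.kept["snp_id"])

    def strength(self) -> pd.DataFrame:
        """Per-SNP R²/F of the kept instruments (needs exposure sample size)."""
        kept = self.instruments.kept
        from .summary_data import SUMMARY_COLUMNS, SummaryDataset as _SD
        import numpy as np

        rec = pd.DataFrame(
            {
                "snp_id": kept["snp_id"],
                "effect_allele": "A",
                "other_allele": "G",
                "eaf": kept["eaf"],
                "beta": kept["beta_exposure"],
                "se": kept["se_exposure"],
                "pval": np.nan,
                "n": self.instruments.n_exposure,
            },
            columns=SUMMARY_COLUMNS,
        )
        s = instrument_strength(_SD("exposure", rec))
        frame = s.to_frame()
        frame.attrs["mean_f"] = s.mean_f
        frame.attrs["total_r2"] = s.total_r2
        return frame

    def fit(self, method: str = "ivw", seed: int | None = None, **kwargs) -> "MRResults":
        """Fit one estimator (``ivw`` with a ``model=`` variant, ``egger``,
        ``weighted_median``, ``weighted_mode``, ``wald_ratio``)."""
        h = self.instruments
        name = method.replace("-", "_")
        if name == "ivw":
            est = ivw(h, **kwargs)
        elif name in ("ivw_fixed", "ivw_additive", "ivw_multiplicative"):
            est = ivw(h, model=name.removeprefix("ivw_"), **kwargs)
        elif name == "egger":
            est = egger(h)
        elif name == "weighted_median":
            est = weighted_median(h, seed=seed, **kwargs)
        elif name == "weighted_mode":
            est = weighted_mode(h, seed=seed, **kwargs)
        elif name == "wald_ratio":
            kept = h.kept
            if len(kept) != 1:
                raise ValidationError("wald_ratio requires exactly one instrument")
            r = kept.iloc[0]
            est = wald_ratio(r["beta_exposure"], r["se_exposure"],
                             r["beta_outcome"], r["se_outcome"])
        else:
            raise ValidationError(f"unknown method {method!r}")
        return MRResults(self, [est])

    def fit_all(
        self,
        methods: Sequence[str] = DEFAULT_METHODS,
        seed: int | None = None,
        n_boot: int = 1000,
    ) -> "MRResults":
        """Run the whole estimator battery (methods whose preconditions
        fail on this instrument set are skipped)."""
        return MRResults(self, estimate_battery(self.instruments, methods, seed, n_boot))

    def sensitivity(self, alpha: float = 0.05) -> SensitivityReport:
        return sensitivity_report(self.instruments, alpha=alpha)

    def presso(self, n_sim: int = 1000, seed: int | None = None, **kwargs) -> PressoResult:
        return presso(self.instruments, n_sim=n_sim, seed=seed, **kwargs)


@dataclass
class MRResults:
    """Fitted causal-effect estimates for one exposure-outcome pair."""

    model: MRModel
    estimates: list[MREstimate] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        h = self.model.instruments
        return estimates_to_frame(
            self.estimates, exposure=h.exposure_name, outcome=h.outcome_name
        )

    def __getitem__(self, method: str) -> MREstimate:
        for est in self.estimates:
            if est.method == method:
                return est
        raise KeyError(method)

    def summary(self) -> str:
        h = self.model.instruments
        lines = [
            "Two-sample Mendelian randomisation",
            f"  exposure: {h.exposure_name}",
            f"  outcome:  {h.outcome_name}",
            f"  instruments kept: {h.n_kept}",
            "",
            f"{'method':<22}{'estimate':>10}{'se':>10}{'ci_low':>10}{'ci_high':>10}{'pval':>12}",
        ]
        for est in self.estimates:
            lines.append(
                f"{est.method:<22}{est.estimate:>10.4f}{est.se:>10.4f}"
                f"{est.ci_low:>10.4f}{est.ci_high:>10.4f}{est.pval:>12.3g}"
            )
        for est in self.estimates:
            if "intercept" in est.extras:
                lines.append(
                    f"\n  Egger intercept: {est.extras['intercept']:.4f}"
                    f" (se {est.extras['intercept_se']:.4f},"
                    f" p {est.extras['intercept_pval']:.3g})"
                )
        return "\n".join(lines)
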