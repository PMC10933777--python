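"""GWAS summary-statistic containers and instrument preparation.

The two-sample design works from per-SNP marginal association estimates
(effect size, standard error, p-value, effect-allele frequency, sample
size) for an exposure trait and an outcome trait, estimated in separate
cohorts.  Before any causal estimation the two tables must be reduced to a
set of independent, genome-wide-significant instruments whose effect
alleles agree between the two sources.  This module provides:

* :class:`SummaryDataset` / :class:`SnpAssociation` — one GWAS source;
* :func:`read_summary_table` — delimited-text reader with column mapping;
* :func:`select_instruments` — p-value thresholding (default 5e-8);
* :func:`ld_prune` — greedy clumping at an LD r² cutoff (default 0.001),
  keeping the smallest-p SNP of each correlated cluster;
* :func:`harmonise` — allele alignment between exposure and outcome,
  including strand-flip resolution and palindromic-SNP handling;
* :func:`instrument_strength` — per-SNP R² and F statistics (F > 10 is the
  conventional weak-instrument guard).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of a summary table, in storage order
SUMMARY_COLUMNS = [
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

_CANONICAL_KEYS = {"snp", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"}
_REQUIRED_KEYS = {"snp", "effect_allele", "other_allele", "beta", "se"}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SnpAssociation:
    """Marginal association of one SNP with one trait.

    ``beta`` is the per-effect-allele estimate (trait SD or log odds per
    allele), ``se`` its standard error.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.pval is not None and not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are identical")


@dataclass
class SummaryDataset:
    """One GWAS summary-statistics source for a named trait.

    ``records`` is a DataFrame with the :data:`SUMMARY_COLUMNS` layout and
    unique ``snp_id``.
    """

    trait_name: str
    records: pd.DataFrame
    trait_type: str = "continuous"

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"trait_type must be continuous|binary, got {self.trait_type!r}")
        missing = [c for c in SUMMARY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records missing columns: {missing}")
        dup = self.records["snp_id"][self.records["snp_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate snp_id: {dup.iloc[0]!r}")
        self.records = self.records.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    @classmethod
    def from_associations(
        cls, trait_name: str, assocs: Sequence[SnpAssociation], trait_type: str = "continuous"
    ) -> "SummaryDataset":
        rows = [
            {
                "snp_id": a.snp_id,
                "effect_allele": a.effect_allele,
                "other_allele": a.other_allele,
                "eaf": np.nan if a.eaf is None else a.eaf,
                "beta": a.beta,
                "se": a.se,
                "pval": np.nan if a.pval is None else a.pval,
                "n": np.nan if a.n is None else a.n,
            }
            for a in assocs
        ]
        return cls(trait_name, pd.DataFrame(rows, columns=SUMMARY_COLUMNS), trait_type)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


#: harmonisation flags
FLAG_KEPT = "kept"
FLAG_FLIPPED = "flipped"
FLAG_DROPPED_PALINDROMIC = "dropped_palindromic"
FLAG_DROPPED_UNMATCHED = "dropped_unmatched"

RETAINED_FLAGS = (FLAG_KEPT, FLAG_FLIPPED)


@dataclass
class HarmonisedInstruments:
    """Allele-aligned per-SNP exposure/outcome association pairs.

    ``table`` has one row per shared SNP with columns ``snp_id,
    beta_exposure, se_exposure, beta_outcome, se_outcome, eaf, flag``.
    Rows flagged ``dropped_*`` carry NaN association values and are
    excluded from :attr:`kept`, the view every estimator consumes.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    n_exposure: float | None = None
    n_outcome: float | None = None

    def __post_init__(self) -> None:
        kept = self.kept
        if len(kept) and not ((kept["se_exposure"] > 0).all() and (kept["se_outcome"] > 0).all()):
            raise ValidationError("kept rows must have positive standard errors")

    @property
    def kept(self) -> pd.DataFrame:
        return self.table[self.table["flag"].isin(RETAINED_FLAGS)].reset_index(drop=True)

    @property
    def n_kept(self) -> int:
        return int(self.table["flag"].isin(RETAINED_FLAGS).sum())

    def subset(self, snp_ids: Sequence[str]) -> "HarmonisedInstruments":
        """Restrict the kept instruments to ``snp_ids`` (dropped rows retained)."""
        keep = set(snp_ids)
        tab = self.table[
            ~self.table["flag"].isin(RETAINED_FLAGS) | self.table["snp_id"].isin(keep)
        ].reset_index(drop=True)
        return replace(self, table=tab)

    def drop(self, snp_ids: Sequence[str]) -> "HarmonisedInstruments":
        """Remove the named instruments from the kept set."""
        kept_ids = [s for s in self.kept["snp_id"] if s not in set(snp_ids)]
        return self.subset(kept_ids)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class InstrumentStrength:
    """Per-SNP and aggregate instrument-strength metrics."""

    snp_ids: list[str]
    r2: np.ndarray
    f_stat: np.ndarray
    mean_f: float
    total_r2: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp_id": self.snp_ids, "r2": self.r2, "f_stat": self.f_stat})


def read_summary_table(
    path,
    column_map: Mapping[str, str],
    trait_name: str,
    trait_type: str = "continuous",
) -> SummaryDataset:
    """Read a delimited summary-statistics table into a :class:`SummaryDataset`.

    ``column_map`` maps canonical names (``snp, effect_allele, other_allele,
    beta, se`` required; ``eaf, pval, n`` optional) to file column headers.
    Tab- and comma-delimited files are auto-detected.  Missing p-values are
    backfilled from a two-sided normal test on beta/se; rows with missing
    beta or se are rejected with the count logged.
    """
    unknown = set(column_map) - _CANONICAL_KEYS
    if unknown:
        raise ConfigurationError(f"unknown column_map keys: {sorted(unknown)}")
    missing_req = _REQUIRED_KEYS - set(column_map)
    if missing_req:
        raise ConfigurationError(f"column_map missing required keys: {sorted(missing_req)}")

    raw = pd.read_csv(path, sep=None, engine="python")
    absent = [col for col in column_map.values() if col not in raw.columns]
    if absent:
        raise ConfigurationError(f"columns not found in {path}: {absent}")

    df = pd.DataFrame(
        {
            "snp_id": raw[column_map["snp"]].astype(str),
            "effect_allele": raw[column_map["effect_allele"]].astype(str).str.upper(),
            "other_allele": raw[column_map["other_allele"]].astype(str).str.upper(),
            "eaf": pd.to_numeric(raw[column_map["eaf"]], errors="coerce")
            if "eaf" in column_map
            else np.nan,
            "beta": pd.to_numeric(raw[column_map["beta"]], errors="coerce"),
            "se": pd.to_numeric(raw[column_map["se"]], errors="coerce"),
            "pval": pd.to_numeric(raw[column_map["pval"]], errors="coerce")
            if "pval" in column_map
            else np.nan,
            "n": pd.to_numeric(raw[column_map["n"]], errors="coerce")
            if "n" in column_map
            else np.nan,
        },
        columns=SUMMARY_COLUMNS,
    )

    bad = df["beta"].isna() | df["se"].isna()
    if bad.any():
        logger.warning("%s: dropped %d rows with missing beta or se", trait_name, int(bad.sum()))
        df = df[~bad].reset_index(drop=True)

    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate snp_id in {path}: {dup.iloc[0]!r}")

    fill = df["pval"].isna()
    if fill.any():
        z = np.abs(df.loc[fill, "beta"] / df.loc[fill, "se"])
        df.loc[fill, "pval"] = 2.0 * stats.norm.sf(z)
        logger.info("%s: backfilled %d p-values from beta/se", trait_name, int(fill.sum()))

    return SummaryDataset(trait_name, df, trait_type)


def select_instruments(dataset: SummaryDataset, p_threshold: float = 5e-8) -> SummaryDataset:
    """Subset to SNPs with exposure p-value strictly below ``p_threshold``."""
    if dataset.records["pval"].isna().any():
        raise ValidationError("select_instruments requires a p-value for every record")
    kept = dataset.records[dataset.records["pval"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        logger.warning("%s: no instruments at p < %g", dataset.trait_name, p_threshold)
    return SummaryDataset(dataset.trait_name, kept, dataset.trait_type)


def ld_prune(
    dataset: SummaryDataset,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
) -> SummaryDataset:
    """Greedy LD clumping: scan SNPs in ascending p-value order (ties broken
    by snp_id) and keep a SNP iff its LD r² with every already-kept SNP is
    ≤ ``r2_threshold``.

    ``ld`` is a symmetric SNP×SNP r² matrix indexed by snp_id.  Without it
    the input is returned unchanged and a warning that independence is
    assumed is logged (pre-clumped sources are common).
    """
    if ld is None:
        logger.warning(
            "%s: no LD matrix supplied; assuming instruments are independent",
            dataset.trait_name,
        )
        return dataset

    ids = list(dataset.records["snp_id"])
    missing = [s for s in ids if s not in ld.index or s not in ld.columns]
    if missing:
        raise ValidationError(f"LD matrix missing snp_id(s): {missing[:5]}")

    order = dataset.records.sort_values(["pval", "snp_id"], kind="mergesort")
    kept_ids: list[str] = []
    for snp in order["snp_id"]:
        if all(float(ld.loc[snp, k]) <= r2_threshold for k in kept_ids):
            kept_ids.append(snp)
    kept_set = set(kept_ids)
    out = dataset.records[dataset.records["snp_id"].isin(kept_set)].reset_index(drop=True)
    return SummaryDataset(dataset.trait_name, out, dataset.trait_type)


def _is_palindromic(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def _complement_alleles(a1: str, a2: str) -> tuple[str, str] | None:
    if a1 in _COMPLEMENT and a2 in _COMPLEMENT:
        return _COMPLEMENT[a1], _COMPLEMENT[a2]
    return None


def harmonise(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    palindromic_eaf_window: float = 0.08,
) -> HarmonisedInstruments:
    """Align outcome effect alleles to the exposure's over the shared SNPs.

    Rules, per shared SNP (exposure alleles are the reference):

    * same effect/other labels → kept unchanged;
    * swapped labels → outcome beta negated, eaf complemented, ``flipped``;
    * strand-complementary labels → complemented first, then as above;
    * palindromic SNPs (A/T, C/G) are strand-ambiguous, so labels are
      uninformative: they are resolved by effect-allele-frequency agreement
      and dropped (``dropped_palindromic``) when either EAF is missing or
      lies within ``palindromic_eaf_window`` of 0.5;
    * irreconcilable alleles → ``dropped_unmatched``.

    SNPs present in only one dataset are recorded as ``dropped_unmatched``.
    """
    exp = exposure.records.set_index("snp_id")
    out = outcome.records.set_index("snp_id")
    shared = [s for s in exposure.records["snp_id"] if s in out.index]
    if not shared:
        raise ValidationError("no shared instruments between exposure and outcome")

    rows = []

    def _row(snp, be, se_e, bo, se_o, eaf, flag):
        keep = flag in RETAINED_FLAGS
        rows.append(
            {
                "snp_id": snp,
                "beta_exposure": be if keep else np.nan,
                "se_exposure": se_e if keep else np.nan,
                "beta_outcome": bo if keep else np.nan,
                "se_outcome": se_o if keep else np.nan,
                "eaf": eaf if keep else np.nan,
                "flag": flag,
            }
        )

    for snp in shared:
        e = exp.loc[snp]
        o = out.loc[snp]
        ea_e, oa_e = e["effect_allele"], e["other_allele"]
        ea_o, oa_o = o["effect_allele"], o["other_allele"]
        eaf_e = e["eaf"] if np.isfinite(e["eaf"]) else None
        eaf_o = o["eaf"] if np.isfinite(o["eaf"]) else None

        if _is_palindromic(ea_e, oa_e):
            ambiguous = (
                eaf_e is None
                or eaf_o is None
                or abs(eaf_e - 0.5) <= palindromic_eaf_window
                or abs(eaf_o - 0.5) <= palindromic_eaf_window
            )
            if ambiguous:
                _row(snp, None, None, None, None, None, FLAG_DROPPED_PALINDROMIC)
            elif (eaf_e < 0.5) == (eaf_o < 0.5):
                _row(snp, e["beta"], e["se"], o["beta"], o["se"], eaf_e, FLAG_KEPT)
            else:
                _row(snp, e["beta"], e["se"], -o["beta"], o["se"], eaf_e, FLAG_FLIPPED)
            continue

        pair_o = (ea_o, oa_o)
        if pair_o not in ((ea_e, oa_e), (oa_e, ea_e)):
            comp = _complement_alleles(ea_o, oa_o)
            pair_o = comp if comp is not None else pair_o

        if pair_o == (ea_e, oa_e):
            _row(snp, e["beta"], e["se"], o["beta"], o["se"], eaf_e, FLAG_KEPT)
        elif pair_o == (oa_e, ea_e):
            eaf = eaf_e
            _row(snp, e["beta"], e["se"], -o["beta"], o["se"], eaf, FLAG_FLIPPED)
        else:
            _row(snp, None, None, None, None, None, FLAG_DROPPED_UNMATCHED)

    for snp in exposure.records["snp_id"]:
        if snp not in out.index:
            _row(snp, None, None, None, None, None, FLAG_DROPPED_UNMATCHED)
    for snp in outcome.records["snp_id"]:
        if snp not in exp.index:
            _row(snp, None, None, None, None, None, FLAG_DROPPED_UNMATCHED)

    table = pd.DataFrame(
        rows,
        columns=[
            "snp_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf",
            "flag",
        ],
    )
    n_exp = _median_n(exposure)
    n_out = _median_n(outcome)
    return HarmonisedInstruments(
        exposure.trait_name, outcome.trait_name, table, n_exposure=n_exp, n_outcome=n_out
    )


def _median_n(dataset: SummaryDataset) -> float | None:
    n = dataset.records["n"].dropna()
    return float(n.median()) if len(n) else None


def instrument_strength(dataset: SummaryDataset, n: float | None = None) -> InstrumentStrength:
    """Per-SNP variance explained and F statistic from the test statistic.

    With t = beta/se: r² = t²/(t² + n − 2) and F = (n−2)·r²/(1−r²), which
    reduces algebraically to t².  This form needs no allele frequency and is
    unit-free; mean F > 10 is the conventional strength guard.
    """
    rec = dataset.records
    n_vec = rec["n"].to_numpy(dtype=float)
    if n is not None:
        n_vec = np.where(np.isfinite(n_vec), n_vec, float(n))
    if not np.isfinite(n_vec).all():
        raise ValidationError("instrument_strength requires n per record or a dataset-level n")
    if (n_vec <= 2).any():
        raise ValidationError("sample size must exceed 2")

    t2 = (rec["beta"].to_numpy() / rec["se"].to_numpy()) ** 2
    r2 = t2 / (t2 + n_vec - 2.0)
    f = (n_vec - 2.0) * r2 / (1.0 - r2)
    return InstrumentStrength(
        snp_ids=list(rec["snp_id"]),
        r2=r2,
        f_stat=f,
        mean_f=float(np.mean(f)) if len(f) else float("nan"),
        total_r2=float(np.sum(r2)),
    )


def eaf_r2(dataset: SummaryDataset) -> np.ndarray:
    """Alternative per-SNP R² from 2·EAF·(1−EAF)·beta² (assumes a unit-variance
    trait scale); provided for comparison with the test-statistic form."""
    rec = dataset.records
    eaf = rec["eaf"].to_numpy(dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * rec["beta"].to_numpy() ** 2
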