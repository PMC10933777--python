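"""Instrument preparation: reading, harmonisation, pruning, strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from causalmr import (
    ConfigurationError,
    SummaryDataset,
    ValidationError,
    harmonise,
    instrument_strength,
    ld_prune,
    read_summary_table,
    select_instruments,
)
from causalmr.summary_data import FLAG_DROPPED_PALINDROMIC, FLAG_FLIPPED, FLAG_KEPT

from conftest import make_dataset

COLMAP = {
    "snp": "rsid",
    "effect_allele": "ea",
    "other_allele": "oa",
    "beta": "b",
    "se": "se",
    "eaf": "freq",
    "pval": "p",
    "n": "n",
}


def _write_table(tmp_path, rows, name="stats.tsv", sep="\t"):
    path = tmp_path / name
    header = ["rsid", "ea", "oa", "freq", "b", "se", "p", "n"]
    lines = [sep.join(header)]
    for r in rows:
        lines.append(sep.join(str(r.get(c, "")) for c in header))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadSummaryTable:
    def test_roundtrip_three_rows(self, tmp_path):
        rows = [
            {"rsid": f"rs{i}", "ea": "A", "oa": "G", "freq": 0.3, "b": 0.1, "se": 0.01, "p": 1e-9, "n": 1000}
            for i in range(3)
        ]
        ds = read_summary_table(_write_table(tmp_path, rows), COLMAP, "bp")
        assert len(ds) == 3
        assert list(ds.records["snp_id"]) == ["rs0", "rs1", "rs2"]
        assert ds.records["beta"].tolist() == [0.1, 0.1, 0.1]

    def test_comma_delimited_autodetected(self, tmp_path):
        rows = [{"rsid": "rs1", "ea": "A", "oa": "G", "freq": 0.3, "b": 0.1, "se": 0.01, "p": 1e-9, "n": 1000}]
        ds = read_summary_table(_write_table(tmp_path, rows, "s.csv", sep=","), COLMAP, "bp")
        assert len(ds) == 1

    def test_missing_pval_backfilled_from_normal_test(self, tmp_path):
        rows = [{"rsid": "rs1", "ea": "A", "oa": "G", "b": 1.96, "se": 1.0}]
        colmap = {k: v for k, v in COLMAP.items() if k not in ("pval", "eaf", "n")}
        ds = read_summary_table(_write_table(tmp_path, rows), colmap, "bp")
        # 2*Phi(-1.96) evaluated independently
        assert ds.records["pval"].iloc[0] == pytest.approx(0.04999579, abs=1e-7)

    def test_duplicate_snp_id_rejected(self, tmp_path):
        rows = [
            {"rsid": "rs1", "ea": "A", "oa": "G", "b": 0.1, "se": 0.01, "p": 0.5},
            {"rsid": "rs1", "ea": "A", "oa": "G", "b": 0.2, "se": 0.01, "p": 0.5},
        ]
        with pytest.raises(ValidationError, match="rs1"):
            read_summary_table(_write_table(tmp_path, rows), COLMAP, "bp")

    def test_unknown_column_map_key_is_configuration_error(self, tmp_path):
        rows = [{"rsid": "rs1", "ea": "A", "oa": "G", "b": 0.1, "se": 0.01}]
        path = _write_table(tmp_path, rows)
        with pytest.raises(ConfigurationError):
            read_summary_table(path, {**COLMAP, "bogus": "x"}, "bp")

    def test_rows_missing_beta_dropped(self, tmp_path):
        rows = [
            {"rsid": "rs1", "ea": "A", "oa": "G", "b": 0.1, "se": 0.01, "p": 0.5},
            {"rsid": "rs2", "ea": "A", "oa": "G", "b": "", "se": 0.01, "p": 0.5},
        ]
        ds = read_summary_table(_write_table(tmp_path, rows), COLMAP, "bp")
        assert list(ds.records["snp_id"]) == ["rs1"]


class TestHarmonise:
    def test_identical_alleles_kept_unchanged(self):
        exp = make_dataset("e", [{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_dataset("o", [{"effect_allele": "A", "other_allele": "G", "beta": 0.05}])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_KEPT]
        assert h.table["beta_outcome"].iloc[0] == 0.05

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_dataset("e", [{"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.3}])
        out = make_dataset("o", [{"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.7}])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_FLIPPED]
        assert h.table["beta_outcome"].iloc[0] == -0.05

    def test_strand_complement_resolved_before_mismatch(self):
        exp = make_dataset("e", [{"effect_allele": "A", "other_allele": "G", "beta": 0.1}])
        out = make_dataset("o", [{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_KEPT]
        assert h.table["beta_outcome"].iloc[0] == 0.05

    def test_palindromic_at_window_boundary_dropped(self):
        exp = make_dataset("e", [{"effect_allele": "A", "other_allele": "T", "eaf": 0.3}])
        out = make_dataset("o", [{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_DROPPED_PALINDROMIC]
        assert np.isnan(h.table["beta_outcome"].iloc[0])

    def test_palindromic_informative_eaf_resolved(self):
        exp = make_dataset("e", [{"effect_allele": "A", "other_allele": "T", "eaf": 0.2, "beta": 0.1}])
        out = make_dataset("o", [{"effect_allele": "A", "other_allele": "T", "eaf": 0.8, "beta": 0.05}])
        h = harmonise(exp, out)
        assert list(h.table["flag"]) == [FLAG_FLIPPED]
        assert h.table["beta_outcome"].iloc[0] == -0.05

    def test_no_shared_instruments_errors(self):
        exp = make_dataset("e", [{}])
        out = make_dataset("o", [{}])
        out.records["snp_id"] = ["rsX"]
        with pytest.raises(ValidationError, match="no shared"):
            harmonise(exp, out)

    def test_idempotence(self):
        exp = make_dataset("e", [{"beta": 0.1}, {"beta": 0.2}])
        out = make_dataset("o", [{"effect_allele": "G", "other_allele": "A", "beta": 0.05, "eaf": 0.7}, {"beta": 0.1}])
        h1 = harmonise(exp, out)
        # rebuild the outcome dataset from the harmonised (aligned) values
        out2 = make_dataset(
            "o",
            [
                {"beta": b, "se": s}
                for b, s in zip(h1.kept["beta_outcome"], h1.kept["se_outcome"])
            ],
        )
        h2 = harmonise(exp, out2)
        np.testing.assert_allclose(h2.kept["beta_outcome"], h1.kept["beta_outcome"])
        assert (h2.kept["flag"] == FLAG_KEPT).all()

    @given(flip=st.lists(st.booleans(), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=16, derandomize=True)
    def test_sign_coherence_under_relabelled_outcome_alleles(self, flip):
        """Swapping the reported effect allele of any outcome rows leaves the
        kept (beta_exposure, beta_outcome) pairs unchanged."""
        exp = make_dataset("e", [{"beta": 0.1}, {"beta": 0.2}, {"beta": 0.3}])
        rows = []
        for i, f in enumerate(flip):
            if f:
                rows.append({"effect_allele": "G", "other_allele": "A", "beta": -0.05 * (i + 1), "eaf": 0.7})
            else:
                rows.append({"effect_allele": "A", "other_allele": "G", "beta": 0.05 * (i + 1), "eaf": 0.3})
        h = harmonise(exp, make_dataset("o", rows))
        np.testing.assert_allclose(h.kept["beta_outcome"], [0.05, 0.10, 0.15])


class TestLdPrune:
    def test_perfect_ld_keeps_smaller_p(self):
        ds = make_dataset("e", [{"pval": 1e-10}, {"pval": 1e-8}])
        ld = pd.DataFrame(np.ones((2, 2)), index=["rs001", "rs002"], columns=["rs001", "rs002"])
        out = ld_prune(ds, ld, 0.001)
        assert list(out.records["snp_id"]) == ["rs001"]

    def test_identity_matrix_keeps_all(self):
        ds = make_dataset("e", [{"pval": 1e-10}, {"pval": 1e-8}, {"pval": 1e-9}])
        ids = list(ds.records["snp_id"])
        ld = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        assert len(ld_prune(ds, ld)) == 3

    def test_greedy_rule_matches_brute_force(self):
        ds = make_dataset(
            "e", [{"pval": 1e-12}, {"pval": 1e-10}, {"pval": 1e-8}, {"pval": 1e-6}]
        )
        ids = list(ds.records["snp_id"])
        r2 = np.array(
            [
                [1.0, 0.5, 0.0, 0.0],
                [0.5, 1.0, 0.0, 0.3],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.3, 0.0, 1.0],
            ]
        )
        ld = pd.DataFrame(r2, index=ids, columns=ids)
        kept = set(ld_prune(ds, ld, 0.1).records["snp_id"])
        # brute-force replay of the greedy scan in ascending-p order
        expected = []
        for snp in ids:  # ids already in ascending p order
            if all(ld.loc[snp, k] <= 0.1 for k in expected):
                expected.append(snp)
        assert kept == set(expected) == {"rs001", "rs003", "rs004"}
        # pruned set is pairwise independent at the threshold
        for a in kept:
            for b in kept:
                if a != b:
                    assert ld.loc[a, b] <= 0.1

    def test_missing_snp_in_ld_matrix_errors(self):
        ds = make_dataset("e", [{}, {}])
        ld = pd.DataFrame([[1.0]], index=["rs001"], columns=["rs001"])
        with pytest.raises(ValidationError):
            ld_prune(ds, ld)

    def test_no_ld_matrix_is_a_noop(self):
        ds = make_dataset("e", [{}, {}])
        assert len(ld_prune(ds, None)) == 2


class TestSelectInstruments:
    @pytest.mark.parametrize(
        "threshold,expected", [(5e-8, 1), (1e-6, 2), (1e-12, 0)]
    )
    def test_threshold_counts(self, threshold, expected):
        ds = make_dataset("e", [{"pval": 1e-9}, {"pval": 1e-7}])
        assert len(select_instruments(ds, threshold)) == expected


class TestInstrumentStrength:
    def test_null_association_gives_zero(self):
        ds = make_dataset("e", [{"beta": 0.0, "se": 0.01, "n": 1000}])
        s = instrument_strength(ds)
        assert s.r2[0] == 0.0 and s.f_stat[0] == 0.0

    def test_f_equals_squared_t_statistic(self):
        ds = make_dataset("e", [{"beta": 0.05, "se": 0.005, "n": 10_000}])
        s = instrument_strength(ds)
        assert s.f_stat[0] == pytest.approx(100.0, rel=1e-12)

    def test_mean_f_is_arithmetic_mean(self):
        # t^2 of 4 and 16 respectively
        ds = make_dataset(
            "e",
            [{"beta": 0.02, "se": 0.01, "n": 100}, {"beta": 0.04, "se": 0.01, "n": 100}],
        )
        s = instrument_strength(ds)
        assert s.mean_f == pytest.approx((s.f_stat[0] + s.f_stat[1]) / 2)
        assert s.f_stat == pytest.approx([4.0, 16.0])
        assert s.mean_f == pytest.approx(10.0)

    def test_small_n_rejected(self):
        ds = make_dataset("e", [{"n": 2}])
        with pytest.raises(ValidationError):
            instrument_strength(ds)

    @given(
        beta=st.floats(-1, 1),
        se=st.floats(0.001, 1),
        n=st.integers(4, 10**6),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_f_identity_holds_for_any_record(self, beta, se, n):
        """(n-2)·r²/(1-r²) reduces to t² under r² = t²/(t²+n-2)."""
        ds = make_dataset("e", [{"beta": beta, "se": se, "n": n}])
        s = instrument_strength(ds)
        t2 = (beta / se) ** 2
        assert s.f_stat[0] == pytest.approx(t2, rel=1e-9, abs=1e-12)
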