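"""Format round-trips and genotype-level QC filters."""

import numpy as np
import pandas as pd
import pytest

from paleokin import genotype_io as gio
from paleokin import simulate
from paleokin.genotype_io import ALT, MISSING, REF, PseudoHaploidMatrix

from conftest import tiny_panel


def write_trio(tmp_path, geno_lines, snp_lines, ind_lines):
    (tmp_path / "t.geno").write_text("\n".join(geno_lines) + "\n")
    (tmp_path / "t.snp").write_text("\n".join(snp_lines) + "\n")
    (tmp_path / "t.ind").write_text("\n".join(ind_lines) + "\n")
    return tmp_path / "t.geno", tmp_path / "t.snp", tmp_path / "t.ind"


class TestEigenstrat:
    def test_digit_mapping(self, tmp_path):
        """geno lines '209'/'920' map to the documented call codes, sample-major."""
        paths = write_trio(
            tmp_path,
            ["209", "920"],
            ["rs1 1 0.0001 100 A G", "rs2 1 0.0002 200 C T"],
            ["S1 M P1", "S2 F P1", "S3 U P2"],
        )
        matrix, meta = gio.read_eigenstrat(*paths)
        expected = np.array([[REF, MISSING], [ALT, REF], [MISSING, ALT]], dtype=np.int8)
        np.testing.assert_array_equal(matrix.calls, expected)
        assert matrix.samples == ["S1", "S2", "S3"]
        assert meta["genetic_sex"].tolist() == ["male", "female", "unknown"]
        assert meta["n_snps_called"].tolist() == [1, 2, 1]

    def test_het_digit_strict_vs_lenient(self, tmp_path):
        paths = write_trio(tmp_path, ["21"], ["rs1 1 0.0001 100 A G"],
                           ["S1 M P1", "S2 M P1"])
        with pytest.raises(gio.FormatError, match="digit"):
            gio.read_eigenstrat(*paths, mode="strict")
        matrix, _ = gio.read_eigenstrat(*paths, mode="lenient")
        np.testing.assert_array_equal(matrix.calls, [[REF], [MISSING]])

    def test_dimension_mismatch(self, tmp_path):
        paths = write_trio(tmp_path, ["20"], ["rs1 1 0.0001 100 A G"],
                           ["S1 M P1"])
        with pytest.raises(gio.FormatError):
            gio.read_eigenstrat(*paths)

    def test_round_trip_identity(self, tmp_path, small_matrix):
        matrix, meta = small_matrix
        gio.write_eigenstrat(matrix, meta, tmp_path / "rt")
        back, meta2 = gio.read_eigenstrat(tmp_path / "rt.geno", tmp_path / "rt.snp",
                                          tmp_path / "rt.ind")
        np.testing.assert_array_equal(back.calls, matrix.calls)
        assert back.samples == matrix.samples
        pd.testing.assert_frame_equal(back.panel, matrix.panel)
        assert meta2["genetic_sex"].tolist() == meta["genetic_sex"].tolist()

    def test_empty_matrix_round_trip(self, tmp_path):
        panel = tiny_panel({"1": [100, 200]})
        m = PseudoHaploidMatrix(samples=[], panel=panel,
                                calls=np.empty((0, 2), dtype=np.int8))
        gio.write_eigenstrat(m, pd.DataFrame(columns=["sample_id", "group",
                                                      "genetic_sex", "n_snps_called"]),
                             tmp_path / "e")
        assert (tmp_path / "e.ind").read_text() == ""
        # geno lines exist (one per SNP) but carry zero samples
        assert (tmp_path / "e.geno").read_text() == "\n\n"

    def test_missing_written_as_9(self, tmp_path):
        panel = tiny_panel({"1": [100]})
        m = PseudoHaploidMatrix(samples=["S1"], panel=panel,
                                calls=np.array([[MISSING]], dtype=np.int8))
        gio.write_eigenstrat(m, gio.make_sample_meta(m), tmp_path / "m")
        assert (tmp_path / "m.geno").read_text().strip() == "9"


class TestPanelValidation:
    def test_duplicate_snp_ids_rejected(self):
        df = tiny_panel({"1": [100, 200]})
        df.loc[1, "snp_id"] = df.loc[0, "snp_id"]
        with pytest.raises(gio.FormatError, match="duplicated"):
            gio.build_panel(df)

    def test_positions_must_increase(self):
        df = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": ["1", "1"],
            "genetic_pos": [0.002, 0.001], "physical_pos": [200, 100],
            "ref_allele": ["A", "A"], "alt_allele": ["G", "G"]})
        with pytest.raises(gio.FormatError, match="increasing"):
            gio.build_panel(df)

    def test_x_and_par_flags(self):
        panel = tiny_panel({"1": [100], "X": [100_000, 5_000_000, 155_000_000]})
        assert panel["is_x"].tolist() == [False, True, True, True]
        assert panel["in_par"].tolist() == [False, True, False, True]


class TestHLATable:
    def test_read_write_round_trip(self, tmp_path):
        table = pd.DataFrame({
            "sample_id": ["S1", "S1"], "locus": ["DQB1", "A"],
            "allele1": ["DQB1*04:02", "A*02:01"],
            "allele2": ["DQB1*06:03", "A*02:01"]})
        gio.write_hla_table(table, tmp_path / "h.tsv")
        back = gio.read_hla_table(tmp_path / "h.tsv")
        pd.testing.assert_frame_equal(back, table)

    @pytest.mark.parametrize("bad", ["bad", "DQB1*4:2x", "A*02", "DQB1-04:02"])
    def test_malformed_allele_rejected(self, bad):
        table = pd.DataFrame({"sample_id": ["S1"], "locus": ["DQB1"],
                              "allele1": [bad], "allele2": ["DQB1*06:03"]})
        with pytest.raises(gio.FormatError, match="malformed|belong"):
            gio.validate_hla_table(table)

    def test_duplicate_sample_locus_rejected(self):
        table = pd.DataFrame({
            "sample_id": ["S1", "S1"], "locus": ["DQB1", "DQB1"],
            "allele1": ["DQB1*04:02"] * 2, "allele2": ["DQB1*06:03"] * 2})
        with pytest.raises(gio.FormatError, match="duplicate"):
            gio.validate_hla_table(table)


def test_ancestry_track_round_trip(tmp_path, small_cohort):
    mask = (small_cohort.panel["chrom"] == "6").to_numpy()
    track = simulate.truth_track(small_cohort, mask)
    gio.write_ancestry_track(track, tmp_path / "track.tsv")
    back = gio.read_ancestry_track(tmp_path / "track.tsv")
    assert back.samples == track.samples
    np.testing.assert_allclose(back.prob_whg, track.prob_whg, atol=1e-6)


class TestSampleSnpFilters:
    def test_snp_count_threshold_boundary(self):
        """A sample one call short of the 20,000-SNP threshold is excluded."""
        panel = simulate.make_panel(20_000, 0)
        calls = np.full((2, 20_000), REF, dtype=np.int8)
        calls[0, 0] = MISSING   # sample 0 has 19,999 calls
        m = PseudoHaploidMatrix(samples=["low", "ok"], panel=panel, calls=calls)
        meta = gio.make_sample_meta(m)
        out, meta2, dropped = gio.filter_samples_by_snp_count(m, meta, min_snps=20_000)
        assert dropped == ["low"]
        assert out.samples == ["ok"]
        assert meta2["sample_id"].tolist() == ["ok"]

    def test_min_zero_is_identity(self, small_matrix):
        matrix, meta = small_matrix
        out, _, dropped = gio.filter_samples_by_snp_count(matrix, meta, min_snps=0)
        assert dropped == []
        assert out.samples == matrix.samples

    def test_all_below_threshold_warns_empty(self, small_matrix):
        matrix, meta = small_matrix
        with pytest.warns(UserWarning, match="all samples"):
            out, _, dropped = gio.filter_samples_by_snp_count(
                matrix, meta, min_snps=matrix.n_snps + 1)
        assert out.n_samples == 0


class TestMafFilter:
    def make(self, columns):
        panel = tiny_panel({"1": [100 * (i + 1) for i in range(len(columns[0]))]})
        return PseudoHaploidMatrix(samples=[f"S{i}" for i in range(len(columns))],
                                   panel=panel,
                                   calls=np.array(columns, dtype=np.int8))

    def test_rare_allele_dropped(self):
        calls = np.full((200, 1), REF, dtype=np.int8)
        calls[0, 0] = ALT    # freq 1/200 = 0.005 < 0.01
        panel = tiny_panel({"1": [100]})
        m = PseudoHaploidMatrix(samples=[f"S{i}" for i in range(200)],
                                panel=panel, calls=calls)
        assert gio.maf_filter(m, 0.01).n_snps == 0

    def test_zero_maf_drops_only_all_missing(self):
        m = self.make([[REF, MISSING], [REF, MISSING], [ALT, MISSING]])
        with pytest.warns(UserWarning, match="no calls"):
            out = gio.maf_filter(m, 0.0)
        assert out.n_snps == 1

    def test_hand_enumerated_retention(self):
        # SNP freqs among called: 0.5, 0.25, 0.0, 1.0 -> MAFs 0.5, 0.25, 0, 0
        m = self.make([
            [ALT, ALT, REF, ALT],
            [ALT, REF, REF, ALT],
            [REF, REF, REF, ALT],
            [REF, REF, REF, ALT],
        ])
        out = gio.maf_filter(m, 0.10)
        assert out.panel["snp_id"].tolist() == m.panel["snp_id"].tolist()[:2]

    def test_idempotent(self, small_matrix):
        once = gio.maf_filter(small_matrix[0], 0.05)
        twice = gio.maf_filter(once, 0.05)
        assert once.panel["snp_id"].tolist() == twice.panel["snp_id"].tolist()


class TestRemovePar:
    def test_par_snp_removed_autosomes_kept(self):
        panel = tiny_panel({"2": [500], "X": [100_000, 5_000_000]})
        m = PseudoHaploidMatrix(samples=["S1"], panel=panel,
                                calls=np.zeros((1, 3), dtype=np.int8))
        out = gio.remove_par(m)
        assert out.panel["snp_id"].tolist() == ["snp_2_500", "snp_X_5000000"]

    def test_no_x_identity(self):
        panel = tiny_panel({"3": [100, 200]})
        m = PseudoHaploidMatrix(samples=["S1"], panel=panel,
                                calls=np.zeros((1, 2), dtype=np.int8))
        assert gio.remove_par(m).n_snps == 2


class TestLdPrune:
    def random_matrix(self, n_samples, n_snps, seed, duplicate_pairs=()):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 2, size=(n_samples, n_snps)).astype(np.int8)
        for a, b in duplicate_pairs:
            calls[:, b] = calls[:, a]
        panel = tiny_panel({"1": [1000 * (i + 1) for i in range(n_snps)]})
        return PseudoHaploidMatrix(samples=[f"S{i}" for i in range(n_samples)],
                                   panel=panel, calls=calls)

    def test_duplicate_column_removed(self):
        m = self.random_matrix(50, 10, 0, duplicate_pairs=[(2, 3)])
        kept = gio.ld_prune(m, r2_threshold=0.9, window_snps=10, step_snps=5)
        assert m.panel["snp_id"].iloc[3] not in kept
        assert m.panel["snp_id"].iloc[2] in kept

    def test_independent_columns_mostly_retained(self):
        m = self.random_matrix(400, 100, 1)
        kept = gio.ld_prune(m, r2_threshold=0.4, window_snps=50, step_snps=10)
        assert len(kept) >= 98

    def test_threshold_one_keeps_non_duplicates(self):
        m = self.random_matrix(100, 20, 2, duplicate_pairs=[(0, 1)])
        kept = gio.ld_prune(m, r2_threshold=1.0, window_snps=20, step_snps=5)
        assert len(kept) == 19

    def test_sample_order_invariance(self):
        m = self.random_matrix(60, 30, 3, duplicate_pairs=[(4, 7), (10, 20)])
        kept1 = gio.ld_prune(m, 0.4, 15, 5)
        perm = np.random.default_rng(9).permutation(m.n_samples)
        m2 = m.take_samples(perm)
        kept2 = gio.ld_prune(m2, 0.4, 15, 5)
        assert kept1 == kept2

    def test_window_smaller_than_step_rejected(self):
        m = self.random_matrix(10, 10, 4)
        with pytest.raises(ValueError):
            gio.ld_prune(m, 0.4, window_snps=5, step_snps=10)
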