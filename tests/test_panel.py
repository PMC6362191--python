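"""Panel encoding, correlation-matrix construction, and store serialisation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dish.panel import (
    Marker,
    MarkerKind,
    MatrixStore,
    PanelError,
    ReferencePanel,
    StoreFormatError,
    binarize_amino_acids,
    binarize_hla_alleles,
    build_matrix_store,
    load_store,
    parse_hla_allele,
    read_haplotype_table,
    read_phased_vcf,
    save_store,
)

from conftest import random_panel


class TestBinarizeHla:
    def test_two_field_and_one_field_presence_coding(self):
        cols = dict_of(binarize_hla_alleles(["DRB1*15:01", "DRB1*04:01", "DRB1*15:02"]))
        np.testing.assert_array_equal(cols["HLA_DRB1_1501"], [1, 0, 0])
        np.testing.assert_array_equal(cols["HLA_DRB1_15"], [1, 0, 1])
        np.testing.assert_array_equal(cols["HLA_DRB1_04"], [0, 1, 0])

    def test_monomorphic_allele_flagged_by_frequency(self):
        out = binarize_hla_alleles(["DRB1*15:01"] * 4)
        freqs = {mk.id: mk.frequency for mk, _ in out}
        assert freqs == {"HLA_DRB1_1501": 1.0, "HLA_DRB1_15": 1.0}
        assert all(not mk.is_polymorphic for mk, _ in out)

    def test_one_field_frequency_counting(self):
        out = binarize_hla_alleles(["A*01", "A*02", "A*01", "A*03"])
        freqs = {mk.id: mk.frequency for mk, _ in out}
        assert freqs == {"HLA_A_01": 0.5, "HLA_A_02": 0.25, "HLA_A_03": 0.25}
        assert all(mk.kind is MarkerKind.HLA_1FIELD for mk, _ in out)

    def test_missing_call_is_missing_in_every_column(self):
        out = binarize_hla_alleles(["B*07:02", None, "B*08:01"])
        for _, col in out:
            assert np.isnan(col[1])
            assert np.isfinite(col[[0, 2]]).all()

    def test_unparseable_token_is_named_in_error(self):
        with pytest.raises(PanelError, match="DRB1-garbage"):
            binarize_hla_alleles(["DRB1*15:01", "DRB1-garbage"])

    def test_mixed_genes_rejected(self):
        with pytest.raises(PanelError, match="one gene at a time"):
            binarize_hla_alleles(["DRB1*15:01", "DQB1*06:02"])

    @given(
        st.lists(
            st.tuples(st.integers(1, 4), st.integers(1, 3)),
            min_size=2,
            max_size=40,
        )
    )
    @settings(deadline=None, derandomize=True)
    def test_one_field_frequency_bounds_two_field_children(self, fields):
        calls = [f"C*{f1:02d}:{f2:02d}" for f1, f2 in fields]
        out = binarize_hla_alleles(calls)
        freqs = {mk.id: mk.frequency for mk, _ in out}
        for mk, _ in out:
            if mk.kind is MarkerKind.HLA_2FIELD:
                parent = "_".join(mk.id.split("_")[:2]) + "_" + mk.id.split("_")[2][:2]
                assert freqs[parent] >= mk.frequency

    def test_parse_hla_allele(self):
        assert parse_hla_allele("DRB1*15:01") == ("DRB1", "15", "01")
        assert parse_hla_allele("A*02") == ("A", "02", None)


class TestBinarizeAminoAcids:
    def test_residue_counting(self):
        out = binarize_amino_acids(["S", "G", "S", "S"], "DRB1", 11)
        freqs = {mk.id: mk.frequency for mk, _ in out}
        assert freqs == {"AA_DRB1_11_S": 0.75, "AA_DRB1_11_G": 0.25}

    def test_monomorphic_position_yields_no_markers(self):
        assert binarize_amino_acids(["V", "V", "V", "V"], "B", 45) == []

    def test_k_residues_give_k_markers(self):
        out = binarize_amino_acids(["K", "R", "A", "K"], "DQB1", 57)
        assert sorted(mk.id for mk, _ in out) == [
            "AA_DQB1_57_A", "AA_DQB1_57_K", "AA_DQB1_57_R",
        ]

    def test_indel_symbol_is_one_more_residue(self):
        out = binarize_amino_acids(["-", "L", "L", "-"], "DRB1", 74)
        assert {mk.id for mk, _ in out} == {"AA_DRB1_74_-", "AA_DRB1_74_L"}


class TestReferencePanel:
    def test_frequencies_recomputed_from_columns(self, rng):
        panel = random_panel(rng)
        np.testing.assert_allclose(
            panel.frequencies, np.nanmean(panel.haplotypes, axis=0)
        )

    def test_odd_haplotype_count_warns_not_fails(self):
        mk = Marker("rs1", MarkerKind.SNP, 1, "A", "G", 0.5)
        with pytest.warns(UserWarning, match="odd number of haplotypes"):
            ReferencePanel(markers=[mk], haplotypes=np.array([[1.0], [0.0], [1.0]]))

    def test_duplicate_ids_rejected(self):
        mk = Marker("rs1", MarkerKind.SNP, 1, "A", "G", 0.5)
        with pytest.raises(PanelError, match="duplicate"):
            ReferencePanel(markers=[mk, mk], haplotypes=np.zeros((4, 2)) + [1, 0])

    def test_snp_kind_requires_nucleotide_alleles(self):
        with pytest.raises(PanelError, match="SNP iff"):
            Marker("rs1", MarkerKind.SNP, 1, "P", "A", 0.5)
        with pytest.raises(PanelError, match="SNP iff"):
            Marker("HLA_A_01", MarkerKind.HLA_1FIELD, 1, "A", "G", 0.5)


class TestBuildMatrixStore:
    def _panel(self, snp_cols, hla_cols):
        cols = [
            (Marker(f"rs{i}", MarkerKind.SNP, 10 + i, "A", "G", 0.5), np.array(c, float))
            for i, c in enumerate(snp_cols)
        ] + [
            (
                Marker(f"HLA_A_{i:02d}", MarkerKind.HLA_1FIELD, 50 + i, "P", "A", 0.5),
                np.array(c, float),
            )
            for i, c in enumerate(hla_cols)
        ]
        return ReferencePanel.from_columns(cols)

    def test_orthogonal_columns_have_zero_cross_correlation(self):
        panel = self._panel([[0, 0, 1, 1], [1, 0, 1, 0]], [[0, 1, 1, 0]])
        store = build_matrix_store(panel, maf_min=0.0)
        assert store.sigma_hs[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_identical_columns_have_unit_cross_correlation(self):
        panel = self._panel([[1, 1, 0, 0], [1, 0, 1, 0]], [[1, 1, 0, 0]])
        store = build_matrix_store(panel, maf_min=0.0)
        assert store.sigma_hs[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_hand_pearson_of_snp_pair(self):
        # rs0=[1,1,0,0], rs1=[1,0,1,0]: E[xy]=1/4 = mu_x mu_y -> r = 0
        panel = self._panel([[1, 1, 0, 0], [1, 0, 1, 0]], [[0, 1, 1, 0]])
        store = build_matrix_store(panel, maf_min=0.0)
        assert store.sigma_ss[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert store.sigma_ss[0, 0] == 1.0 and store.sigma_ss[1, 1] == 1.0

    def test_frequency_filter_drops_monomorphic_and_rare(self):
        panel = self._panel(
            [[1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]],  # rs2 monomorphic
            [[1, 0, 0, 0]],
        )
        store = build_matrix_store(panel, maf_min=0.3)
        assert [m.id for m in store.snp_markers] == ["rs0", "rs1"]
        assert store.hla_markers == []  # freq 0.25 <= 0.3

    def test_too_few_snps_errors(self):
        panel = self._panel([[1, 1, 0, 0]], [[0, 1, 1, 0]])
        with pytest.raises(PanelError, match="nothing to condition on"):
            build_matrix_store(panel, maf_min=0.0)

    def test_invalid_maf_min(self, rng):
        with pytest.raises(PanelError, match="maf_min"):
            build_matrix_store(random_panel(rng), maf_min=0.5)

    def test_joint_correlation_matrix_is_psd(self, rng):
        """Empirical correlation matrices are PSD, hence r2pred <= 1 at lambda=0."""
        for _ in range(20):
            panel = random_panel(rng, n_hap=30, n_snp=5, n_hla=3)
            store = build_matrix_store(panel, maf_min=0.0)
            s, h = len(store.snp_markers), len(store.hla_markers)
            joint = np.empty((s + h, s + h))
            joint[:s, :s] = store.sigma_ss
            joint[s:, :s] = store.sigma_hs
            joint[:s, s:] = store.sigma_hs.T
            corr_hh = np.corrcoef(
                np.column_stack(
                    [
                        panel.haplotypes[:, [m.id for m in panel.markers].index(mk.id)]
                        for mk in store.hla_markers
                    ]
                ),
                rowvar=False,
            )
            joint[s:, s:] = np.atleast_2d(corr_hh)
            assert np.linalg.eigvalsh(joint).min() > -1e-8
            # explained variance of any HLA row cannot exceed 1
            sol = np.linalg.lstsq(store.sigma_ss, store.sigma_hs.T, rcond=None)[0]
            r2 = np.einsum("ht,th->h", store.sigma_hs, sol)
            assert (r2 <= 1.0 + 1e-8).all()

    def test_missing_calls_use_pairwise_complete_correlation(self):
        col0 = np.array([1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0], float)
        col1 = col0.copy()
        col1[0] = np.nan  # < 5% missing: marker kept, correlation pairwise
        col2 = 1.0 - col0
        panel = ReferencePanel.from_columns(
            [
                (Marker("rs0", MarkerKind.SNP, 1, "A", "G", 0.5), col0),
                (Marker("rs1", MarkerKind.SNP, 2, "C", "T", 0.5), col1),
                (Marker("HLA_A_01", MarkerKind.HLA_1FIELD, 3, "P", "A", 0.5), col2),
            ]
        )
        store = build_matrix_store(panel, maf_min=0.0)
        assert store.sigma_ss[0, 1] == pytest.approx(1.0)
        assert store.sigma_hs[0, 0] == pytest.approx(-1.0)

    def test_high_missingness_marker_dropped(self):
        base = np.tile([1.0, 0.0], 10)
        noisy = base.copy()
        noisy[:3] = np.nan  # 15% missing
        panel = ReferencePanel.from_columns(
            [
                (Marker("rs0", MarkerKind.SNP, 1, "A", "G", 0.5), base),
                (Marker("rs1", MarkerKind.SNP, 2, "C", "T", 0.5), 1.0 - base),
                (Marker("rs2", MarkerKind.SNP, 3, "G", "A", 0.5), noisy),
            ]
        )
        store = build_matrix_store(panel, maf_min=0.0)
        assert [m.id for m in store.snp_markers] == ["rs0", "rs1"]


class TestStoreRoundTrip:
    def test_round_trip_is_bit_exact(self, small_store, tmp_path):
        path = tmp_path / "store.h5"
        save_store(small_store, path)
        loaded = load_store(path)
        assert loaded.snp_markers == small_store.snp_markers
        assert loaded.hla_markers == small_store.hla_markers
        assert (loaded.sigma_ss == small_store.sigma_ss).all()
        assert (loaded.sigma_hs == small_store.sigma_hs).all()
        assert loaded.n_haplotypes == small_store.n_haplotypes
        assert loaded.region == small_store.region

    def test_empty_hla_block_round_trips(self, tmp_path):
        ss = np.array([[1.0, 0.2], [0.2, 1.0]])
        store = MatrixStore(
            snp_markers=[
                Marker("rs1", MarkerKind.SNP, 1, "A", "G", 0.5),
                Marker("rs2", MarkerKind.SNP, 2, "C", "T", 0.4),
            ],
            hla_markers=[],
            sigma_ss=ss,
            sigma_hs=np.empty((0, 2)),
            n_haplotypes=10,
            region=("6", 1, 2),
        )
        path = tmp_path / "empty.h5"
        save_store(store, path)
        loaded = load_store(path)
        assert loaded.hla_markers == []
        assert loaded.sigma_hs.shape == (0, 2)

    def test_sigma_hs_shape_preserved(self, tmp_path, rng):
        panel = random_panel(rng, n_snp=3, n_hla=2)
        store = build_matrix_store(panel, maf_min=0.0)
        assert store.sigma_hs.shape == (2, 3)
        path = tmp_path / "s.h5"
        save_store(store, path)
        assert load_store(path).sigma_hs.shape == (2, 3)

    def test_version_mismatch_rejected(self, small_store, tmp_path):
        import h5py

        path = tmp_path / "old.h5"
        save_store(small_store, path)
        with h5py.File(path, "r+") as f:
            f.attrs["format_version"] = 99
        with pytest.raises(StoreFormatError, match="version 99"):
            load_store(path)

    def test_truncated_file_rejected(self, small_store, tmp_path):
        path = tmp_path / "trunc.h5"
        save_store(small_store, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(StoreFormatError):
            load_store(path)

    def test_non_store_file_rejected(self, tmp_path):
        path = tmp_path / "nothing.h5"
        path.write_text("not hdf5")
        with pytest.raises(StoreFormatError):
            load_store(path)


class TestHaplotypeTableInput:
    def test_pa_and_binary_aliases_parse_identically(self, tmp_path):
        meta = tmp_path / "markers.tsv"
        meta.write_text(
            "id\tposition\tcounted_allele\tother_allele\n"
            "rs1\t100\tA\tG\n"
        )
        t1 = tmp_path / "h1.tsv"
        t1.write_text("rs1\t1\t0\t1\t0\nHLA_A_01\tP\tA\tP\tA\n")
        t2 = tmp_path / "h2.tsv"
        t2.write_text("rs1\tP\tA\tP\tA\nHLA_A_01\t1\t0\t1\t0\n")
        meta_map = {"rs1": (100, "A", "G")}
        p1 = read_haplotype_table(t1, meta_map)
        p2 = read_haplotype_table(t2, meta_map)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)
        assert p1.markers[0].kind is MarkerKind.SNP
        assert p1.markers[1].kind is MarkerKind.HLA_1FIELD

    def test_header_row_detected_and_skipped(self, tmp_path):
        t = tmp_path / "h.tsv"
        t.write_text("id\thap1\thap2\nHLA_B_07\t1\t0\nAA_DRB1_11_S\tP\tA\n")
        p = read_haplotype_table(t)
        assert p.n_haplotypes == 2
        assert p.markers[1].kind is MarkerKind.AA_RESIDUE

    def test_invalid_call_named_in_error(self, tmp_path):
        t = tmp_path / "h.tsv"
        t.write_text("HLA_B_07\t1\tX\n")
        with pytest.raises(PanelError, match="'X'"):
            read_haplotype_table(t)

    def test_snp_without_metadata_rejected(self, tmp_path):
        t = tmp_path / "h.tsv"
        t.write_text("rs999\t1\t0\n")
        with pytest.raises(PanelError, match="rs999"):
            read_haplotype_table(t)


class TestPhasedVcf:
    VCF = (
        "##fileformat=VCFv4.2\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "##contig=<ID=6>\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
        "6\t100\trs1\tA\tG\t.\t.\t.\tGT\t0|1\t1|1\n"
        "6\t200\trs2\tC\tT\t.\t.\t.\tGT\t0|0\t1|0\n"
        "6\t300\trs3\tA\tAT\t.\t.\t.\tGT\t0|0\t0|1\n"  # indel: skipped
    )

    def test_reads_phased_snps_alt_counted(self, tmp_path):
        path = tmp_path / "p.vcf"
        path.write_text(self.VCF)
        cols = read_phased_vcf(path)
        assert [mk.id for mk, _ in cols] == ["rs1", "rs2"]
        mk, col = cols[0]
        assert mk.counted_allele == "G" and mk.other_allele == "A"
        np.testing.assert_array_equal(col, [0, 1, 1, 1])

    def test_unphased_rejected(self, tmp_path):
        path = tmp_path / "u.vcf"
        path.write_text(self.VCF.replace("0|1", "0/1"))
        with pytest.raises(PanelError, match="phased"):
            read_phased_vcf(path)


def dict_of(pairs):
    return {mk.id: col for mk, col in pairs}
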