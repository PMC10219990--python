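import gzip

import numpy as np
import pytest

from cohortval.genotype_io import (FormatError, GenotypeMatrix, MISSING,
                                   SampleMeta, VariantKey,
                                   intersect_and_harmonize, read_plink_bed,
                                   read_plink_text, read_vcf_dosages,
                                   write_plink_bed, write_plink_text,
                                   write_vcf)

from conftest import make_matrix, make_variants


class TestContainers:
    def test_rejects_inconsistent_dimensions(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GenotypeMatrix(np.zeros((2, 3), dtype=np.int8),
                           make_variants(2), [SampleMeta("a"), SampleMeta("b")])

    def test_rejects_duplicate_variant_ids(self):
        variants = make_variants(2)
        variants[1] = VariantKey("1", 2000, "A", "G", id=variants[0].id)
        with pytest.raises(ValueError, match="duplicate variant ids"):
            GenotypeMatrix(np.zeros((1, 2), dtype=np.int8), variants,
                           [SampleMeta("a")])

    def test_rejects_out_of_range_calls(self):
        with pytest.raises(ValueError, match="calls must be"):
            make_matrix([[0, 3]])

    def test_variant_key_validation(self):
        with pytest.raises(ValueError, match="chromosome"):
            VariantKey("25", 100, "A", "G")
        with pytest.raises(ValueError, match="position"):
            VariantKey("1", 0, "A", "G")


class TestPlinkRoundTrip:
    @pytest.mark.parametrize("writer,reader", [
        (write_plink_text, read_plink_text),
        (write_plink_bed, read_plink_bed),
    ])
    def test_round_trip_with_missing_call(self, tmp_path, writer, reader):
        # counted (alt) allele is the minor allele at every variant: the
        # .ped dialect does not record allele roles, so its reader infers
        # the counted allele as the minor one
        matrix = make_matrix([[0, 1, 0, -1],
                              [1, 0, 0, 0],
                              [0, 0, 1, 1]])
        prefix = tmp_path / "cohort"
        writer(matrix, prefix)
        back = reader(prefix)
        np.testing.assert_array_equal(back.calls, matrix.calls)
        assert back.sample_ids == matrix.sample_ids
        assert [v.id for v in back.variants] == \
            [v.id for v in matrix.variants]
        assert [(v.chromosome, v.position) for v in back.variants] == \
            [(v.chromosome, v.position) for v in matrix.variants]

    def test_bed_round_trip_exact_for_any_orientation(self, tmp_path,
                                                      tiny_matrix):
        # .bim stores A1/A2 explicitly, so binary round trips are exact
        # even where the counted allele is the major one
        write_plink_bed(tiny_matrix, tmp_path / "b")
        back = read_plink_bed(tmp_path / "b")
        np.testing.assert_array_equal(back.calls, tiny_matrix.calls)

    def test_bed_round_trip_preserves_alleles(self, tmp_path, tiny_matrix):
        write_plink_bed(tiny_matrix, tmp_path / "c")
        back = read_plink_bed(tmp_path / "c")
        assert [(v.ref_allele, v.alt_allele) for v in back.variants] == \
            [(v.ref_allele, v.alt_allele) for v in tiny_matrix.variants]

    def test_bed_bytes_oracle(self, tmp_path):
        # 1 variant, 4 samples with calls (2, 1, 0, missing):
        # A1-counted two-bit codes 00, 10, 11, 01 packed little-end first
        # -> byte 0b01111000 = 0x78
        m = make_matrix([[2], [1], [0], [-1]])
        write_plink_bed(m, tmp_path / "o")
        payload = (tmp_path / "o.bed").read_bytes()
        assert payload == b"\x6c\x1b\x01\x78"

    def test_truncated_bed_errors(self, tmp_path, tiny_matrix):
        write_plink_bed(tiny_matrix, tmp_path / "t")
        raw = (tmp_path / "t.bed").read_bytes()
        (tmp_path / "t.bed").write_bytes(raw[:-1])
        with pytest.raises(FormatError, match="payload"):
            read_plink_bed(tmp_path / "t")

    def test_bad_magic_errors(self, tmp_path, tiny_matrix):
        write_plink_bed(tiny_matrix, tmp_path / "m")
        (tmp_path / "m.bed").write_bytes(b"\x00\x00\x00")
        with pytest.raises(FormatError, match="magic"):
            read_plink_bed(tmp_path / "m")

    def test_duplicate_bim_id_errors(self, tmp_path, tiny_matrix):
        write_plink_bed(tiny_matrix, tmp_path / "d")
        bim = (tmp_path / "d.bim").read_text().splitlines()
        bim[1] = bim[0]
        (tmp_path / "d.bim").write_text("\n".join(bim) + "\n")
        with pytest.raises(FormatError, match="v0"):
            read_plink_bed(tmp_path / "d")

    def test_ped_field_count_mismatch_errors(self, tmp_path, tiny_matrix):
        write_plink_text(tiny_matrix, tmp_path / "p")
        ped = (tmp_path / "p.ped").read_text().splitlines()
        ped[0] = " ".join(ped[0].split()[:-2])
        (tmp_path / "p.ped").write_text("\n".join(ped) + "\n")
        with pytest.raises(FormatError, match="expected"):
            read_plink_text(tmp_path / "p")


class TestVcf:
    def test_ds_and_r2_retained(self, tmp_path):
        m = make_matrix([[1], [2]])
        dos = np.array([[1.37], [1.9]])
        write_vcf(m, tmp_path / "d.vcf", dosages=dos, r2=np.array([0.99]))
        dm = read_vcf_dosages(tmp_path / "d.vcf")
        assert dm.dosages[0, 0] == pytest.approx(1.37)
        assert dm.imputation_r2[0] == pytest.approx(0.99)

    def test_r2_filter_is_strict(self, tmp_path):
        m = make_matrix([[1, 1], [2, 0]])
        write_vcf(m, tmp_path / "f.vcf",
                  dosages=m.calls.astype(float), r2=np.array([0.99, 0.95]))
        dm = read_vcf_dosages(tmp_path / "f.vcf", r2_min=0.97)
        assert dm.n_variants == 1
        assert dm.imputation_r2[0] == pytest.approx(0.99)

    def test_r2_threshold_boundary_is_exclusive(self):
        from cohortval.genotype_io import DosageMatrix
        m = make_matrix([[1, 1]])
        dm = DosageMatrix(np.array([[1.0, 1.0]]), m.variants, ["S0"],
                          np.array([0.97, 0.99]))
        kept = dm.filter_r2(0.97)
        assert kept.n_variants == 1  # the variant exactly at 0.97 is dropped

    def test_missing_r2_with_filter_errors(self, tmp_path):
        m = make_matrix([[1]])
        write_vcf(m, tmp_path / "n.vcf", dosages=m.calls.astype(float))
        with pytest.raises(FormatError, match="R2"):
            read_vcf_dosages(tmp_path / "n.vcf", r2_min=0.9)

    def test_hard_call_fallback_without_ds(self, tmp_path, tiny_matrix):
        write_vcf(tiny_matrix, tmp_path / "h.vcf")
        dm = read_vcf_dosages(tmp_path / "h.vcf")
        expected = tiny_matrix.calls.astype(float)
        expected[tiny_matrix.calls == MISSING] = np.nan
        np.testing.assert_array_equal(dm.dosages, expected)

    def test_gzip_output_readable(self, tmp_path, tiny_matrix):
        write_vcf(tiny_matrix, tmp_path / "z.vcf.gz")
        with gzip.open(tmp_path / "z.vcf.gz", "rt") as fh:
            assert fh.readline().startswith("##fileformat")
        dm = read_vcf_dosages(tmp_path / "z.vcf.gz")
        assert dm.n_variants == tiny_matrix.n_variants


class TestHarmonization:
    def test_counted_allele_flip(self):
        a = make_matrix([[0, 2], [1, 1]], ref="A", alt="G")
        b = make_matrix([[2, 2], [1, 1]], ref="A", alt="G")
        # swap counted allele at the first variant of b
        v = b.variants[0]
        b.variants[0] = VariantKey(v.chromosome, v.position, "G", "A", id="x0")
        ha, hb, rep = intersect_and_harmonize(a, b)
        assert rep.n_shared == 2 and rep.n_flipped == 1
        np.testing.assert_array_equal(hb.calls[:, 0], [0, 1])
        assert hb.variants[0].alt_allele == "G"

    def test_flip_preserves_missing(self):
        a = make_matrix([[0], [1]], ref="A", alt="G")
        b = make_matrix([[-1], [2]], ref="A", alt="G")
        v = b.variants[0]
        b.variants[0] = VariantKey(v.chromosome, v.position, "G", "A", id="x0")
        _, hb, _ = intersect_and_harmonize(a, b)
        assert hb.calls[0, 0] == MISSING and hb.calls[1, 0] == 0

    def test_disjoint_sets_warn_and_empty(self):
        a = make_matrix([[0]], chrom="1")
        b = make_matrix([[0]], chrom="2")
        with pytest.warns(UserWarning, match="no shared"):
            ha, hb, rep = intersect_and_harmonize(a, b)
        assert ha.n_variants == 0 and hb.n_variants == 0

    def test_strand_ambiguous_snp_dropped(self):
        a = make_matrix([[1, 1]], ref="A", alt="T")
        b = make_matrix([[1, 1]], ref="A", alt="T")
        ha, hb, rep = intersect_and_harmonize(a, b)
        assert rep.n_ambiguous == 2 and ha.n_variants == 0

    def test_irreconcilable_alleles_dropped_not_fatal(self):
        a = make_matrix([[1]], ref="A", alt="G")
        b = make_matrix([[1]], ref="A", alt="C")
        with pytest.warns(UserWarning):
            ha, hb, rep = intersect_and_harmonize(a, b)
        assert len(rep.irreconcilable_dropped) == 1
        assert ha.n_variants == 0

    def test_idempotence(self, rng):
        calls = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        a = make_matrix(calls)
        b = make_matrix(rng.integers(0, 3, size=(5, 20)).astype(np.int8))
        ha, hb, _ = intersect_and_harmonize(a, b)
        ha2, hb2, rep2 = intersect_and_harmonize(ha, hb)
        np.testing.assert_array_equal(ha.calls, ha2.calls)
        np.testing.assert_array_equal(hb.calls, hb2.calls)
        assert rep2.n_flipped == 0
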