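import numpy as np
import pytest

from cohortval.hla_concordance import (GenotypeOfInterest, HLAAllele,
                                       HLAImputedRecord, HLATypedRecord,
                                       acc_locus, acc_sample, alleles_match,
                                       concordance_genotype,
                                       concordance_report, match_alleles,
                                       read_hla_table, write_hla_table)
from cohortval.synthetic_cohort import simulate_hla_calls, simulate_hla_truth


def A(text):
    return HLAAllele.parse(text)


def typed(donor, locus, a1, a2):
    return HLATypedRecord(donor, {locus: (A(a1), A(a2))})


def imputed(donor, locus, a1, p1, a2, p2):
    return HLAImputedRecord(donor, {locus: ((A(a1), p1), (A(a2), p2))})


class TestAlleleParsing:
    @pytest.mark.parametrize("text,expected", [
        ("A*02:01", "A*02:01"),
        ("HLA-DRB1*04:xx", "DRB1*04:xx"),
        ("drb1*4:1", "DRB1*04:01"),
        ("DQB1*02", "DQB1*02"),
        ("A*02:01:01:02", "A*02:01"),  # suffix fields truncated
    ])
    def test_normalization(self, text, expected):
        assert str(A(text)) == expected

    def test_unparseable_rejected(self):
        with pytest.raises(ValueError, match="cannot parse"):
            A("notanallele")

    @pytest.mark.parametrize("imp,typ,res,match", [
        ("A*02:01", "A*02:05", 2, True),    # same group at 2-digit
        ("A*02:01", "A*02:05", 4, False),
        ("A*02:01", "A*03:01", 2, False),
        ("DRB1*04:05", "DRB1*04:xx", 4, True),  # wildcard truth
        ("DRB1*04:05", "DQB1*04:05", 4, False),  # locus mismatch
    ])
    def test_resolution_semantics(self, imp, typ, res, match):
        assert alleles_match(imp, typ, res) is match


class TestMatching:
    def test_both_concordant(self):
        out = match_alleles([(A("A*02:01"), 0.9), (A("A*24:02"), 0.8)],
                            [A("A*02:01"), A("A*24:02")], 4)
        assert all(m.concordant for m in out)

    def test_homozygous_imputed_cannot_double_claim(self):
        out = match_alleles([(A("A*02:01"), 1.0), (A("A*02:01"), 1.0)],
                            [A("A*02:01"), A("A*03:01")], 4)
        assert sum(m.concordant for m in out) == 1

    def test_wildcard_truth_absorbs_one(self):
        out = match_alleles([(A("DRB1*04:05"), 1.0), (A("DRB1*04:03"), 1.0)],
                            [A("DRB1*04:xx"), A("DRB1*03:01")], 4)
        assert sum(m.concordant for m in out) == 1

    def test_missing_probability_treated_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="missing imputation probability"):
            out = match_alleles([(A("A*02:01"), float("nan")),
                                 (A("A*03:01"), 0.7)],
                                [A("A*02:01"), A("A*03:01")], 4)
        assert out[0].probability == 0.0 and out[0].concordant


class TestAccLocus:
    def test_perfect_imputation(self):
        t = [typed("d1", "A", "A*02:01", "A*24:02")]
        i = [imputed("d1", "A", "A*02:01", 1.0, "A*24:02", 1.0)]
        assert acc_locus(i, t, "A", 4).acc == 1.0

    def test_all_discordant_zero(self):
        t = [typed("d1", "A", "A*02:01", "A*24:02")]
        i = [imputed("d1", "A", "A*03:01", 1.0, "A*11:01", 1.0)]
        assert acc_locus(i, t, "A", 4).acc == 0.0

    def test_hand_example_point_six(self):
        t = [typed("d1", "A", "A*02:01", "A*24:02"),
             typed("d2", "A", "A*03:01", "A*11:01")]
        i = [imputed("d1", "A", "A*02:01", 0.9, "A*24:02", 0.8),
             imputed("d2", "A", "A*03:01", 0.7, "A*26:01", 0.9)]
        assert acc_locus(i, t, "A", 4).acc == pytest.approx(0.6)

    def test_missing_donor_excluded_and_reported(self):
        t = [typed("d1", "A", "A*02:01", "A*24:02"),
             typed("d2", "A", "A*03:01", "A*11:01")]
        i = [imputed("d1", "A", "A*02:01", 1.0, "A*24:02", 1.0)]
        res = acc_locus(i, t, "A", 4)
        assert res.excluded_donors == ("d2",)
        assert res.n_donors == 1 and res.acc == 1.0

    def test_monotone_under_resolution_increase(self):
        donors = [f"d{i}" for i in range(60)]
        t = simulate_hla_truth(donors, ["A", "DRB1"], seed=41)
        i = simulate_hla_calls(t, 0.9, error_rate=0.15, seed=42)
        for locus in ("A", "DRB1"):
            acc2 = acc_locus(i, t, locus, 2).acc
            acc4 = acc_locus(i, t, locus, 4).acc
            assert acc4 <= acc2 + 1e-12


class TestGenotypeConcordance:
    DR3 = GenotypeOfInterest("DR3", "DRB1", A("DRB1*03:01"), "risk")

    def test_full_recovery(self):
        t = [typed("d1", "DRB1", "DRB1*03:01", "DRB1*04:01")]
        i = [imputed("d1", "DRB1", "DRB1*03:01", 1.0, "DRB1*04:01", 1.0)]
        assert concordance_genotype(i, t, self.DR3, 4).concordance == 1.0

    def test_three_of_four_recovered(self):
        t = [typed("d1", "DRB1", "DRB1*03:01", "DRB1*03:01"),
             typed("d2", "DRB1", "DRB1*03:01", "DRB1*03:01")]
        i = [imputed("d1", "DRB1", "DRB1*03:01", 1.0, "DRB1*03:01", 1.0),
             imputed("d2", "DRB1", "DRB1*03:01", 1.0, "DRB1*07:01", 1.0)]
        res = concordance_genotype(i, t, self.DR3, 4)
        assert res.n_typed_alleles == 4 and res.n_recovered == 3
        assert res.concordance == pytest.approx(0.75)

    def test_no_typed_carrier_flagged_undefined(self):
        goi = GenotypeOfInterest("DQ6", "DQB1", A("DQB1*06:02"), "protective")
        t = [typed("d1", "DQB1", "DQB1*02:01", "DQB1*03:02")]
        i = [imputed("d1", "DQB1", "DQB1*02:01", 1.0, "DQB1*03:02", 1.0)]
        res = concordance_genotype(i, t, goi, 4)
        assert not res.defined and np.isnan(res.concordance)

    def test_capped_at_one_for_homozygous_imputation(self):
        # imputed DR3/DR3 against typed DR3/DR4: only one imputed allele
        # can pair with the single typed DR3, so the ratio stays <= 1
        t = [typed("d1", "DRB1", "DRB1*03:01", "DRB1*04:01")]
        i = [imputed("d1", "DRB1", "DRB1*03:01", 1.0, "DRB1*03:01", 1.0)]
        res = concordance_genotype(i, t, self.DR3, 4)
        assert res.concordance <= 1.0


class TestAccSample:
    LOCI = ["A", "DRB1", "DQA1", "DQB1"]

    def _full(self, donor, wrong_locus=None):
        alleles_t, alleles_i = {}, {}
        names = {"A": ("A*02:01", "A*24:02"),
                 "DRB1": ("DRB1*03:01", "DRB1*04:01"),
                 "DQA1": ("DQA1*05:01", "DQA1*03:01"),
                 "DQB1": ("DQB1*02:01", "DQB1*03:02")}
        for locus, (a1, a2) in names.items():
            alleles_t[locus] = (A(a1), A(a2))
            if locus == wrong_locus:
                alleles_i[locus] = ((A(f"{locus}*01:01"), 1.0),
                                    (A(f"{locus}*01:01"), 1.0))
            else:
                alleles_i[locus] = ((A(a1), 1.0), (A(a2), 1.0))
        return (HLATypedRecord(donor, alleles_t),
                HLAImputedRecord(donor, alleles_i))

    def test_perfect_donor(self):
        t, i = self._full("d1")
        assert acc_sample([i], [t], self.LOCI, 4)[0].acc == 1.0

    def test_one_fully_discordant_locus(self):
        t, i = self._full("d1", wrong_locus="DQB1")
        res = acc_sample([i], [t], self.LOCI, 4)[0]
        assert res.acc == pytest.approx(0.75)  # 6 of 8 allele-probabilities

    def test_partial_typing_adjusts_denominator(self):
        t, i = self._full("d1")
        del t.alleles["DQB1"]
        res = acc_sample([i], [t], self.LOCI, 4)[0]
        assert res.n_loci == 3 and res.acc == 1.0


class TestReportAndGenerator:
    def test_single_group_equals_unstratified(self):
        donors = [f"d{i}" for i in range(30)]
        t = simulate_hla_truth(donors, ["A", "DRB1"], seed=51)
        i = simulate_hla_calls(t, 0.95, 0.05, seed=52)
        plain = concordance_report(i, t, [], resolution=4)
        grouped = concordance_report(i, t, [], resolution=4,
                                     grouping={d: "g" for d in donors})
        assert plain.group_summary["median"].iloc[0] == \
            grouped.group_summary["median"].iloc[0]

    def test_planted_group_error_ordering(self):
        donors_lo = [f"lo{i}" for i in range(120)]
        donors_hi = [f"hi{i}" for i in range(120)]
        t_lo = simulate_hla_truth(donors_lo, ["A", "DRB1"], seed=53)
        t_hi = simulate_hla_truth(donors_hi, ["A", "DRB1"], seed=54)
        i_lo = simulate_hla_calls(t_lo, 0.95, error_rate=0.02, seed=55)
        i_hi = simulate_hla_calls(t_hi, 0.95, error_rate=0.10, seed=56)
        grouping = {d: "low_error" for d in donors_lo}
        grouping |= {d: "high_error" for d in donors_hi}
        rep = concordance_report(i_lo + i_hi, t_lo + t_hi, [], resolution=4,
                                 grouping=grouping)
        med = dict(zip(rep.group_summary.group, rep.group_summary["median"]))
        assert med["low_error"] > med["high_error"]

    def test_empty_goi_table_still_reports_accuracy(self):
        donors = ["d1", "d2"]
        t = simulate_hla_truth(donors, ["A"], seed=57)
        i = simulate_hla_calls(t, 1.0, 0.0, seed=58)
        rep = concordance_report(i, t, [], resolution=4)
        assert len(rep.genotype_table) == 0
        assert len(rep.locus_accuracy) == 1
        assert rep.locus_accuracy.acc.iloc[0] == 1.0

    def test_error_free_generator_gives_unit_accuracy(self):
        t = simulate_hla_truth(["d1", "d2", "d3"], ["A", "DQB1"], seed=59)
        i = simulate_hla_calls(t, probability_calibration=1.0,
                               error_rate=0.0, seed=60)
        assert acc_locus(i, t, "A", 4).acc == 1.0
        assert acc_locus(i, t, "DQB1", 4).acc == 1.0

    def test_total_error_generator_gives_zero_accuracy(self):
        t = simulate_hla_truth(["d1", "d2", "d3"], ["A"], seed=61)
        i = simulate_hla_calls(t, 0.95, error_rate=1.0, seed=62)
        assert acc_locus(i, t, "A", 2).acc == 0.0

    def test_table_round_trip(self, tmp_path):
        donors = ["d1", "d2"]
        t = simulate_hla_truth(donors, ["A", "DRB1"], seed=63)
        i = simulate_hla_calls(t, 0.95, 0.1, seed=64)
        write_hla_table(t, tmp_path / "t.tsv")
        write_hla_table(i, tmp_path / "i.tsv", imputed=True)
        t2 = read_hla_table(tmp_path / "t.tsv")
        i2 = read_hla_table(tmp_path / "i.tsv", imputed=True)
        assert acc_locus(i2, t2, "A", 4).acc == acc_locus(i, t, "A", 4).acc
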