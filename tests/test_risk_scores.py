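import numpy as np
import pytest

from cohortval.genotype_io import DosageMatrix
from cohortval.risk_scores import (GRSModel, InteractionTerm, SNPTerm,
                                   compute_grs, example_model,
                                   grs_group_summary, resolve_variants,
                                   score_additive, score_hla_interactions)
from cohortval.synthetic_cohort import simulate_grs_inputs

from conftest import make_variants


def dosage_matrix(values, ids, r2=None, ref="A", alt="G"):
    values = np.asarray(values, dtype=float)
    variants = make_variants(values.shape[1], ref=ref, alt=alt)
    variants = [type(v)(v.chromosome, v.position, v.ref_allele, v.alt_allele,
                        id=ids[j]) for j, v in enumerate(variants)]
    r2 = np.ones(values.shape[1]) if r2 is None else np.asarray(r2, float)
    return DosageMatrix(values, variants,
                        [f"S{i}" for i in range(values.shape[0])], r2)


class TestResolveVariants:
    def test_direct_variant_passing_r2(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)], r2_min=0.97)
        dm = dosage_matrix([[1.0]], ["rs1"], r2=[0.99])
        r = resolve_variants(model, dm)[0]
        assert r.column == 0 and r.used_proxy is None and not r.flipped

    def test_proxy_fallback_when_direct_absent(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)],
                         proxy_map={"rs1": "rsP"})
        dm = dosage_matrix([[1.0]], ["rsP"])
        r = resolve_variants(model, dm)[0]
        assert r.column == 0 and r.used_proxy == "rsP"

    def test_low_r2_direct_falls_back_to_proxy(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)],
                         proxy_map={"rs1": "rsP"}, r2_min=0.97)
        dm = dosage_matrix([[0.5, 1.5]], ["rs1", "rsP"], r2=[0.90, 0.99])
        r = resolve_variants(model, dm)[0]
        assert r.column == 1 and r.used_proxy == "rsP"

    def test_r2_exactly_at_threshold_fails_strict_filter(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)], r2_min=0.97)
        dm = dosage_matrix([[1.0]], ["rs1"], r2=[0.97])
        assert resolve_variants(model, dm)[0].column is None

    def test_effect_allele_flip_detected(self):
        model = GRSModel("m", [SNPTerm("rs1", "A", 1.0)])  # counted is G
        dm = dosage_matrix([[0.4]], ["rs1"])
        r = resolve_variants(model, dm)[0]
        assert r.flipped

    def test_allele_mismatch_marks_missing(self):
        model = GRSModel("m", [SNPTerm("rs1", "T", 1.0)])
        dm = dosage_matrix([[1.0]], ["rs1"])
        assert resolve_variants(model, dm)[0].column is None

    def test_proxy_chain_rejected(self):
        with pytest.raises(ValueError, match="chain"):
            GRSModel("m", proxy_map={"a": "b", "b": "c"})


class TestAdditiveScore:
    def test_all_zero_weights(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 0.0)])
        dm = dosage_matrix([[2.0]], ["rs1"])
        assert score_additive(model, dm)[0] == 0.0

    def test_hand_weighted_sum(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 0.5),
                               SNPTerm("rs2", "G", 1.0),
                               SNPTerm("rs3", "G", -0.2)])
        dm = dosage_matrix([[2.0, 1.0, 0.0]], ["rs1", "rs2", "rs3"])
        assert score_additive(model, dm)[0] == pytest.approx(2.0)

    def test_flipped_effect_allele_contribution(self):
        model = GRSModel("m", [SNPTerm("rs1", "A", 1.5)])  # counted is G
        dm = dosage_matrix([[0.4]], ["rs1"])
        assert score_additive(model, dm)[0] == pytest.approx(1.5 * 1.6)

    def test_missing_term_contributes_zero(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0),
                               SNPTerm("rs_absent", "G", 5.0)])
        dm = dosage_matrix([[1.0]], ["rs1"])
        assert score_additive(model, dm)[0] == pytest.approx(1.0)

    def test_additivity_in_dosage(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 0.7),
                               SNPTerm("rs2", "G", 0.3)])
        base = dosage_matrix([[1.0, 1.0]], ["rs1", "rs2"])
        bumped = dosage_matrix([[2.0, 1.0]], ["rs1", "rs2"])
        diff = score_additive(model, bumped)[0] - score_additive(model, base)[0]
        assert diff == pytest.approx(0.7)


class TestHLAComponent:
    MODEL = GRSModel("m", interaction_terms=[
        InteractionTerm(frozenset({"DR3", "DR4"}), 3.0)])

    def test_diplotype_lookup(self):
        scores, unmatched = score_hla_interactions(
            self.MODEL, {"S0": ("DR3", "DR4")})
        assert scores["S0"] == 3.0 and unmatched == []

    def test_unordered_pair(self):
        s1, _ = score_hla_interactions(self.MODEL, {"S0": ("DR3", "DR4")})
        s2, _ = score_hla_interactions(self.MODEL, {"S0": ("DR4", "DR3")})
        assert s1 == s2

    def test_unmatched_scores_zero_and_flagged(self):
        scores, unmatched = score_hla_interactions(
            self.MODEL, {"S0": ("DR7", "DR9")})
        assert scores["S0"] == 0.0 and unmatched == ["S0"]

    def test_homozygous_diplotype_uses_singleton_set(self):
        model = GRSModel("m", interaction_terms=[
            InteractionTerm(frozenset({"DR3"}), 2.5)])
        scores, _ = score_hla_interactions(model, {"S0": ("DR3", "DR3")})
        assert scores["S0"] == 2.5

    def test_additive_haplotype_weights(self):
        model = GRSModel("m", haplotype_weights={"DR4": 1.2})
        scores, _ = score_hla_interactions(model, {"S0": ("DR4", "DR4"),
                                                   "S1": ("DR4", "DRX")})
        assert scores["S0"] == pytest.approx(2.4)
        assert scores["S1"] == pytest.approx(1.2)


class TestComputeGrs:
    def test_components_summed_then_normalized(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)],
                         interaction_terms=[
                             InteractionTerm(frozenset({"DR3", "DR4"}), 3.0)])
        dm = dosage_matrix([[2.0]], ["rs1"])
        res = compute_grs(model, dm, {"S0": ("DR3", "DR4")})[0]
        assert res.total == pytest.approx(5.0)
        affine = GRSModel("m", model.snp_terms,
                          interaction_terms=model.interaction_terms,
                          normalization=(0.0, 0.1))
        res2 = compute_grs(affine, dm, {"S0": ("DR3", "DR4")})[0]
        assert res2.total == pytest.approx(0.5)

    def test_substitution_invariance(self):
        direct = GRSModel("m", [SNPTerm("rs1", "G", 1.3)])
        proxied = GRSModel("m", [SNPTerm("rs1", "G", 1.3)],
                           proxy_map={"rs1": "rsP"})
        dm_direct = dosage_matrix([[1.2]], ["rs1"])
        dm_proxy = dosage_matrix([[1.2]], ["rsP"])
        assert compute_grs(direct, dm_direct)[0].total == \
            compute_grs(proxied, dm_proxy)[0].total

    def test_audit_fields(self):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0),
                               SNPTerm("rs2", "G", 1.0)],
                         proxy_map={"rs1": "rsP"})
        dm = dosage_matrix([[1.0]], ["rsP"])
        res = compute_grs(model, dm)[0]
        assert res.substitutions_used == ("rs1->rsP",)
        assert res.missing_terms == ("rs2",)
        assert res.n_terms_scored == 1

    def test_determinism_from_generator(self):
        model = example_model()
        dm1, tags1 = simulate_grs_inputs(model, 20, 77)
        dm2, tags2 = simulate_grs_inputs(model, 20, 77)
        np.testing.assert_array_equal(dm1.dosages, dm2.dosages)
        r1 = compute_grs(model, dm1, tags1)
        r2 = compute_grs(model, dm2, tags2)
        assert [r.total for r in r1] == [r.total for r in r2]

    def test_example_model_config_loads(self):
        model = example_model()
        assert model.r2_min == 0.97
        assert model.normalization == (0.0, 0.1)
        assert len(model.snp_terms) == 7
        assert model.proxy_map == {"rsA7": "rsA7proxy"}


class TestGroupSummary:
    def _results(self, totals, prefix="S"):
        model = GRSModel("m", [SNPTerm("rs1", "G", 1.0)])
        dm = dosage_matrix([[t] for t in totals],
                           ["rs1"])
        dm.sample_ids[:] = [f"{prefix}{i}" for i in range(len(totals))]
        return compute_grs(model, dm)

    def test_single_group_matches_overall_median(self):
        res = self._results([0.0, 1.0, 2.0])
        df = grs_group_summary(res, {r.sample_id: "g" for r in res})
        assert df["median"].iloc[0] == pytest.approx(1.0)

    def test_planted_group_shift_recovered(self):
        rng = np.random.default_rng(81)
        base = rng.uniform(0, 1, size=40)
        # case group dosages are exactly control + 1, so with weight 1 the
        # group median difference equals the planted shift
        res = self._results(list(base) + list(base + 1.0))
        grouping = {f"S{i}": ("control" if i < 40 else "case")
                    for i in range(80)}
        df = grs_group_summary(res, grouping)
        med = dict(zip(df.group, df["median"]))
        assert med["case"] - med["control"] == pytest.approx(1.0)

    def test_empty_group_row_emitted(self):
        res = self._results([1.0, 1.5])
        grouping = {"S0": "g1", "S1": "g1"}
        clinical = {"S0": "T1D", "S1": "T1D"}
        df = grs_group_summary(res, grouping, clinical)
        assert (df.n > 0).all()  # no phantom cells, present cell populated
        assert df[df.clinical_group == "T1D"].n.iloc[0] == 2
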