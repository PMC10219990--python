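"""Seeded synthetic-cohort generation with recorded ground truth.

Every input the validation pipeline consumes can be generated here with a
known truth record, enabling parameter-recovery tests: a K-population
reference panel with Balding-Nichols allele-frequency divergence,
Dirichlet-admixed target samples, gene-dropped pedigree pairs (duplicate
through third degree), sex-linked X genotypes (males hemizygous, coded
0/2), typed+imputed HLA pairs with controllable error rate and probability
calibration, dosages under a known risk-score model, paired platform
callsets with controllable discordance, and annotated variant tables with
a planted rare+deleterious subset.

Balding-Nichols: each variant draws an ancestral frequency p ~ U(0.05,
0.95); population k's frequency is Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k),
so F_k -> 0 recovers the ancestral frequency and larger F_k means more
divergence.  Genotypes are binomial in the population frequency; no
linkage structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestry import AncestryModel
from .genotype_io import (MISSING, AUTOSOMES, GenotypeMatrix, SampleMeta,
                          VariantKey)
from .hla_concordance import HLAAllele, HLAImputedRecord, HLATypedRecord
from .risk_scores import GRSModel

RELATIONSHIPS = ("duplicate", "parent_offspring", "full_sibling",
                 "second_degree", "third_degree")

#: degree labels the kinship classifier should recover per relationship
RELATIONSHIP_TO_DEGREE = {
    "duplicate": "duplicate_MZ",
    "parent_offspring": "first",
    "full_sibling": "first",
    "second_degree": "second",
    "third_degree": "third",
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters for the synthetic cohort."""

    n_samples: int = 300
    n_variants: int = 5000
    n_populations: int = 5
    fst_per_population: tuple[float, ...] | float = 0.1
    admixture_dirichlet_alpha: tuple[float, ...] | float = 1.0
    pedigree_plan: tuple[tuple[str, int], ...] = ()
    replicate_error_rate: float = 0.001
    missing_rate: float = 0.002
    x_variant_count: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 2:
            raise ValueError("n_populations: need K >= 2")
        fst = self.fst_tuple
        if len(fst) != self.n_populations:
            raise ValueError("fst_per_population: need one value per population")
        if any(not 0.0 < f < 1.0 for f in fst):
            raise ValueError("fst_per_population: values must lie in (0,1)")
        alpha = self.alpha_tuple
        if len(alpha) != self.n_populations:
            raise ValueError("admixture_dirichlet_alpha: length must equal K")
        if any(a <= 0 for a in alpha):
            raise ValueError("admixture_dirichlet_alpha: must be strictly positive")
        for name in ("replicate_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0,1], got {v}")
        for rel, count in self.pedigree_plan:
            if rel not in RELATIONSHIPS:
                raise ValueError(f"pedigree_plan: unknown relationship {rel!r}")
            if count < 0:
                raise ValueError("pedigree_plan: counts must be >= 0")
        if self.seed < 0:
            raise ValueError("seed: must be non-negative")

    @property
    def fst_tuple(self) -> tuple[float, ...]:
        f = self.fst_per_population
        return tuple(f) if isinstance(f, (tuple, list)) \
            else (float(f),) * self.n_populations

    @property
    def alpha_tuple(self) -> tuple[float, ...]:
        a = self.admixture_dirichlet_alpha
        return tuple(a) if isinstance(a, (tuple, list)) \
            else (float(a),) * self.n_populations


@dataclass
class TruthBundle:
    true_Q: dict[str, np.ndarray] = field(default_factory=dict)
    true_relationships: list[tuple[str, str, str]] = field(default_factory=list)
    true_sex: dict[str, str] = field(default_factory=dict)
    true_hla: list[HLATypedRecord] = field(default_factory=list)
    grs_model_truth: GRSModel | None = None

    def validate(self, sample_ids: set[str]) -> None:
        for a, b, _rel in self.true_relationships:
            if a not in sample_ids or b not in sample_ids:
                raise ValueError(f"relationship references unknown samples "
                                 f"({a}, {b})")
        for sid, q in self.true_Q.items():
            if abs(float(np.sum(q)) - 1.0) > 1e-9:
                raise ValueError(f"true_Q for {sid} does not sum to 1")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)


def _variant_keys(m: int, chromosomes=AUTOSOMES, prefix: str = "rs",
                  start: int = 1) -> list[VariantKey]:
    """Evenly spread m sorted variant keys over the given chromosomes."""
    keys = []
    per = -(-m // len(chromosomes))
    j = 0
    for chrom in chromosomes:
        for i in range(per):
            if j >= m:
                break
            keys.append(VariantKey(chrom, 1000 * (i + 1), "A", "G",
                                   id=f"{prefix}{start + j}"))
            j += 1
    return keys


def balding_nichols_frequencies(spec: CohortSpec, rng=None) -> np.ndarray:
    """K x M population allele frequencies under the divergence model."""
    rng = _rng(spec.seed if rng is None else rng)
    m = spec.n_variants
    p = rng.uniform(0.05, 0.95, size=m)
    F = np.empty((spec.n_populations, m))
    for k, fst in enumerate(spec.fst_tuple):
        if fst < 1e-9:
            F[k] = p
        else:
            a = p * (1 - fst) / fst
            b = (1 - p) * (1 - fst) / fst
            F[k] = rng.beta(a, b)
    return np.clip(F, 1e-4, 1 - 1e-4)


def simulate_reference_panel(spec: CohortSpec,
                             n_per_population: int | None = None
                             ) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Unadmixed reference individuals, labeled with their population."""
    rng = _rng(spec.seed)
    F = balding_nichols_frequencies(spec, rng)
    K, m = F.shape
    if n_per_population is None:
        n_per_population = max(1, spec.n_samples // K)
    variants = _variant_keys(m)
    calls, samples, labels = [], [], {}
    for k in range(K):
        pop = f"POP{k + 1}"
        g = rng.binomial(2, F[k], size=(n_per_population, m)).astype(np.int8)
        calls.append(g)
        for i in range(n_per_population):
            sid = f"{pop}_S{i + 1}"
            samples.append(SampleMeta(sid))
            labels[sid] = pop
    return GenotypeMatrix(np.vstack(calls), variants, samples), labels


def simulate_admixed_samples(model: AncestryModel, alpha, n: int, seed
                             ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Dirichlet-admixed samples: genotype_m ~ Binomial(2, sum_k q_k f_km)."""
    rng = _rng(seed)
    alpha = np.asarray(alpha, dtype=float)
    K, m = model.F.shape
    if alpha.shape != (K,):
        raise ValueError(f"alpha length {alpha.size} != K={K}")
    if n == 0:
        empty = GenotypeMatrix(np.empty((0, m), dtype=np.int8),
                               list(model.variant_keys), [])
        return empty, np.empty((0, K))
    Q = rng.dirichlet(alpha, size=n)
    P = Q @ model.F
    calls = rng.binomial(2, P).astype(np.int8)
    samples = [SampleMeta(f"ADM_S{i + 1}") for i in range(n)]
    return GenotypeMatrix(calls, list(model.variant_keys), samples), Q


# ---------------------------------------------------------------------------
# pedigrees (gene dropping)
# ---------------------------------------------------------------------------

def _founder(freqs: np.ndarray, rng) -> np.ndarray:
    return rng.binomial(2, freqs).astype(np.int8)


def _child(parent_a: np.ndarray, parent_b: np.ndarray, rng) -> np.ndarray:
    """One meiosis per parent: transmit an allele ~ Bernoulli(g/2)."""
    ta = rng.random(parent_a.shape) < parent_a / 2.0
    tb = rng.random(parent_b.shape) < parent_b / 2.0
    return (ta.astype(np.int8) + tb.astype(np.int8))


def _corrupt(genotypes: np.ndarray, error_rate: float, rng) -> np.ndarray:
    """Independent per-genotype corruption to a different valid call."""
    out = genotypes.copy()
    hit = rng.random(out.shape) < error_rate
    if hit.any():
        shift = rng.integers(1, 3, size=int(hit.sum()))
        out[hit] = ((out[hit] + shift) % 3).astype(np.int8)
    return out


def simulate_pedigree_pairs(founder_freqs, plan, seed,
                            replicate_error_rate: float = 0.001
                            ) -> tuple[GenotypeMatrix, list[tuple[str, str, str]]]:
    """Sample pairs with known relatedness by Mendelian gene-dropping.

    Second- and third-degree pairs are grandparent-grandchild and
    great-grandparent-great-grandchild chains (one extra meiosis each);
    duplicates are copies with independent corruption at
    ``replicate_error_rate``.  Only the two members of each pair enter the
    output matrix, so different pairs are unrelated.
    """
    rng = _rng(seed)
    freqs = np.asarray(founder_freqs, dtype=float)
    if ((freqs <= 0) | (freqs >= 1)).any():
        raise ValueError("founder frequencies must lie strictly in (0,1)")
    variants = _variant_keys(freqs.size)
    rows, samples, rels = [], [], []
    idx = 0
    for rel, count in plan:
        if rel not in RELATIONSHIPS:
            raise ValueError(f"unknown relationship label {rel!r}")
        for _ in range(count):
            idx += 1
            a_id, b_id = f"{rel}_{idx}a", f"{rel}_{idx}b"
            if rel == "duplicate":
                a = _founder(freqs, rng)
                b = _corrupt(a, replicate_error_rate, rng)
            elif rel == "parent_offspring":
                a = _founder(freqs, rng)
                other = _founder(freqs, rng)
                b = _child(a, other, rng)
            elif rel == "full_sibling":
                pa, pb = _founder(freqs, rng), _founder(freqs, rng)
                a, b = _child(pa, pb, rng), _child(pa, pb, rng)
            elif rel == "second_degree":
                a = _founder(freqs, rng)
                parent = _child(a, _founder(freqs, rng), rng)
                b = _child(parent, _founder(freqs, rng), rng)
            else:  # third_degree
                a = _founder(freqs, rng)
                parent = _child(a, _founder(freqs, rng), rng)
                grandchild = _child(parent, _founder(freqs, rng), rng)
                b = _child(grandchild, _founder(freqs, rng), rng)
            rows += [a, b]
            samples += [SampleMeta(a_id), SampleMeta(b_id)]
            rels.append((a_id, b_id, rel))
    calls = np.vstack(rows) if rows else np.empty((0, freqs.size), dtype=np.int8)
    return GenotypeMatrix(calls, variants, samples), rels


def simulate_unrelated(founder_freqs, n: int, seed,
                       id_prefix: str = "UNR_S") -> GenotypeMatrix:
    rng = _rng(seed)
    freqs = np.asarray(founder_freqs, dtype=float)
    calls = rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)
    return GenotypeMatrix(calls, _variant_keys(freqs.size),
                          [SampleMeta(f"{id_prefix}{i + 1}") for i in range(n)])


# ---------------------------------------------------------------------------
# sex-linked genotypes
# ---------------------------------------------------------------------------

def simulate_x_genotypes(sexes: list[str], x_variant_count: int, seed
                         ) -> tuple[np.ndarray, list[VariantKey]]:
    """X calls: females Binomial(2,f); males hemizygous coded 0/2."""
    rng = _rng(seed)
    freqs = rng.uniform(0.1, 0.9, size=x_variant_count)
    calls = np.empty((len(sexes), x_variant_count), dtype=np.int8)
    for i, sex in enumerate(sexes):
        if sex == "male":
            calls[i] = 2 * rng.binomial(1, freqs)
        else:
            calls[i] = rng.binomial(2, freqs)
    keys = [VariantKey("X", 1000 * (j + 1), "A", "G", id=f"xs{j + 1}")
            for j in range(x_variant_count)]
    return calls, keys


# ---------------------------------------------------------------------------
# HLA truth and imputed calls
# ---------------------------------------------------------------------------

def hla_allele_dictionary() -> dict[str, list[HLAAllele]]:
    """Fixed per-locus 4-digit allele dictionary shipped with the package."""
    path = resources.files("cohortval.data") / "hla_alleles.tsv"
    df = pd.read_csv(str(path), sep="\t")
    out: dict[str, list[HLAAllele]] = {}
    for _, row in df.iterrows():
        out.setdefault(row.locus, []).append(HLAAllele.parse(row.allele))
    return out


def simulate_hla_truth(donor_ids: list[str], loci: list[str], seed
                       ) -> list[HLATypedRecord]:
    """Typed truth: two alleles per locus drawn from the shipped dictionary."""
    rng = _rng(seed)
    pool = hla_allele_dictionary()
    records = []
    for d in donor_ids:
        alleles = {}
        for locus in loci:
            opts = pool[locus]
            i, j = rng.integers(0, len(opts), size=2)
            alleles[locus] = (opts[i], opts[j])
        records.append(HLATypedRecord(d, alleles))
    return records


def simulate_hla_calls(truth: list[HLATypedRecord],
                       probability_calibration: float = 0.95,
                       error_rate: float = 0.02, seed=0,
                       concentration: float = 50.0
                       ) -> list[HLAImputedRecord]:
    """Imputed calls: correct with probability 1 - error_rate, else a decoy.

    Decoys come from the same locus but a different allele group (field1),
    so an error is an error at both 2- and 4-digit resolution.  Reported
    probabilities are Beta-distributed with mean ``probability_calibration``
    so the mean reported probability of correct calls matches the requested
    calibration; downstream E[Acc(L)] = (1 - error_rate) * calibration.
    """
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0,1], got {error_rate}")
    if not 0.0 < probability_calibration <= 1.0:
        raise ValueError("probability_calibration must be in (0,1]")
    rng = _rng(seed)
    pool = hla_allele_dictionary()
    c = probability_calibration

    def draw_prob() -> float:
        if c >= 1.0:
            return 1.0
        return float(rng.beta(c * concentration, (1 - c) * concentration))

    out = []
    for trec in truth:
        imputed = {}
        for locus, (t1, t2) in trec.alleles.items():
            truth_groups = {t1.field1, t2.field1}
            decoys = [a for a in pool.get(locus, [])
                      if a.field1 not in truth_groups]
            pair = []
            for t in (t1, t2):
                if error_rate > 0 and rng.random() < error_rate and decoys:
                    allele = decoys[int(rng.integers(0, len(decoys)))]
                else:
                    allele = t
                pair.append((allele, draw_prob()))
            imputed[locus] = (pair[0], pair[1])
        out.append(HLAImputedRecord(trec.donor_id, imputed))
    return out


# ---------------------------------------------------------------------------
# platform pair, missingness
# ---------------------------------------------------------------------------

def apply_missingness(matrix: GenotypeMatrix, missing_rate: float, seed
                      ) -> GenotypeMatrix:
    rng = _rng(seed)
    calls = matrix.calls.copy()
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    return GenotypeMatrix(calls, list(matrix.variants), list(matrix.samples))


def simulate_platform_pair(base: GenotypeMatrix, discordance_rate: float = 0.012,
                           missing_rate_b: float = 0.01, seed=0
                           ) -> GenotypeMatrix:
    """Second-platform callset: per-call corruption then missingness."""
    for name, v in (("discordance_rate", discordance_rate),
                    ("missing_rate_b", missing_rate_b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    rng = _rng(seed)
    calls = base.calls.copy()
    observed = calls != MISSING
    hit = (rng.random(calls.shape) < discordance_rate) & observed
    if hit.any():
        shift = rng.integers(1, 3, size=int(hit.sum()))
        calls[hit] = ((calls[hit] + shift) % 3).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate_b] = MISSING
    return GenotypeMatrix(calls, list(base.variants), list(base.samples))


# ---------------------------------------------------------------------------
# risk-score inputs
# ---------------------------------------------------------------------------

def simulate_grs_inputs(model: GRSModel, n: int, seed
                        ):
    """Dosages (with passing R²) and HLA tag diplotypes under a known model.

    Returns (DosageMatrix, hla_tags dict).  Dosages are hard-call counts
    from uniform allele frequencies; every model variant is present with R²
    above any plausible filter so scores are exactly reconstructible from
    the truth model.
    """
    from .genotype_io import DosageMatrix

    rng = _rng(seed)
    terms = model.snp_terms
    m = len(terms)
    freqs = rng.uniform(0.1, 0.9, size=m)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    keys = []
    for j, t in enumerate(terms):
        # effect allele is the counted allele by construction
        ref = "C" if t.effect_allele != "C" else "T"
        keys.append(VariantKey(AUTOSOMES[j % len(AUTOSOMES)], 1000 * (j + 1),
                               ref, t.effect_allele, id=t.variant_id))
    r2 = rng.uniform(0.98, 1.0, size=m)
    sample_ids = [f"GRS_S{i + 1}" for i in range(n)]
    dm = DosageMatrix(dosages, keys, sample_ids, r2)
    hap_pool = sorted({h for it in model.interaction_terms
                       for h in it.haplotypes} | set(model.haplotype_weights))
    tags = {}
    for sid in sample_ids:
        if hap_pool:
            i, j = rng.integers(0, len(hap_pool), size=2)
            tags[sid] = (hap_pool[i], hap_pool[j])
        else:
            tags[sid] = ("none", "none")
    return dm, tags


# ---------------------------------------------------------------------------
# annotated variant tables
# ---------------------------------------------------------------------------

VARIANT_TYPES = ("missense", "nonsense/stopgain", "frameshift",
                 "inframe indel", "splice", "synonymous", "other")


def simulate_annotated_variants(gene_panels, n: int, rare_fraction: float = 0.1,
                                deleterious_fraction: float = 0.2, seed=0,
                                freq_max_pct: float = 0.01,
                                score_min: float = 20.0
                                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Annotated variant rows with a planted rare+deleterious truth subset.

    Rarity and deleteriousness are independent Bernoulli draws, so the
    expected pass count under the default filter is
    n * rare_fraction * deleterious_fraction.  Returns (table, truth mask).
    """
    rng = _rng(seed)
    genes = sorted({g for p in gene_panels for g in p.genes})
    rare = rng.random(n) < rare_fraction
    deleterious = rng.random(n) < deleterious_fraction
    freq = np.where(rare, rng.uniform(0.0, freq_max_pct * 0.99, size=n),
                    rng.uniform(freq_max_pct * 2, 5.0, size=n))
    score = np.where(deleterious, rng.uniform(score_min, score_min + 20, size=n),
                     rng.uniform(0.0, score_min * 0.95, size=n))
    gi = rng.integers(0, len(genes), size=n)
    ti = rng.integers(0, len(VARIANT_TYPES), size=n)
    table = pd.DataFrame({
        "donor_id": [f"WES_S{int(rng.integers(1, max(2, n // 3)))}"
                     for _ in range(n)],
        "gene": [genes[i] for i in gi],
        "dna_change": [f"c.{100 + j}A>G" for j in range(n)],
        "protein_change": [f"p.X{j + 1}Y" for j in range(n)],
        "zygosity": np.where(rng.random(n) < 0.95, "Het", "Hom"),
        "variant_type": [VARIANT_TYPES[i] for i in ti],
        "population_frequency_pct": np.round(freq, 6),
        "deleteriousness_score": np.round(score, 2),
    })
    return table, rare & deleterious


# ---------------------------------------------------------------------------
# full cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    spec: CohortSpec
    reference: GenotypeMatrix
    reference_labels: dict[str, str]
    targets: GenotypeMatrix          # admixed samples + X variants, missingness
    truth: TruthBundle
    pedigree: GenotypeMatrix
    hla_typed: list[HLATypedRecord]
    hla_imputed: list[HLAImputedRecord]
    platform_b: GenotypeMatrix


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate every pipeline input for one seeded cohort."""
    rng = np.random.default_rng(spec.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=8)
    ref, labels = simulate_reference_panel(
        CohortSpec(**{**spec.__dict__, "seed": int(seeds[0])}))
    from .ancestry import fit_reference
    model = fit_reference(ref, labels)
    targets, Q = simulate_admixed_samples(model, spec.alpha_tuple,
                                          spec.n_samples, int(seeds[1]))
    sexes = ["male" if s else "female"
             for s in np.random.default_rng(int(seeds[2]))
             .integers(0, 2, size=spec.n_samples)]
    x_calls, x_keys = simulate_x_genotypes(sexes, spec.x_variant_count,
                                           int(seeds[3]))
    samples = [SampleMeta(s.sample_id, reported_sex=sx)
               for s, sx in zip(targets.samples, sexes)]
    calls = np.hstack([targets.calls, x_calls])
    targets = GenotypeMatrix(calls, list(targets.variants) + x_keys, samples)
    targets = apply_missingness(targets, spec.missing_rate, int(seeds[4]))
    founder_freqs = np.random.default_rng(int(seeds[5])).uniform(
        0.1, 0.5, size=spec.n_variants)
    pedigree, rels = simulate_pedigree_pairs(
        founder_freqs, spec.pedigree_plan, int(seeds[5]),
        spec.replicate_error_rate)
    loci = ["A", "DRB1", "DQA1", "DQB1"]
    hla_typed = simulate_hla_truth(targets.sample_ids, loci, int(seeds[6]))
    hla_imputed = simulate_hla_calls(hla_typed, 0.95, 0.02, int(seeds[6]))
    platform_b = simulate_platform_pair(targets, seed=int(seeds[7]))
    truth = TruthBundle(
        true_Q={s: Q[i] for i, s in enumerate(targets.sample_ids)},
        true_relationships=rels,
        true_sex=dict(zip(targets.sample_ids, sexes)),
        true_hla=hla_typed,
    )
    truth.validate(set(targets.sample_ids) | set(pedigree.sample_ids))
    return SyntheticCohort(spec, ref, labels, targets, truth, pedigree,
                           hla_typed, hla_imputed, platform_b)
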