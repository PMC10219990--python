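# Methods

This note documents the models, estimators, defaults, and numerical
choices behind each `cohortval` component, what the synthetic-cohort
generator does and does not emulate, and the limitations a user should
keep in mind.

## Genotype containers and formats

Hard calls are stored as an int8 samples × variants matrix counting copies
of each variant's *counted* allele (the `alt_allele` of its key), with
`-1` as the missing sentinel — missing is never conflated with the
homozygous-reference 0. Variant identity for merging is (chromosome,
position, unordered allele pair); rsIDs are carried but never used for
matching, because they differ across platforms.

PLINK 1 binary files (.bed/.bim/.fam, SNP-major) round-trip exactly: the
counted allele is written as A1, so the two-bit code `00` decodes to two
copies. The text dialect (.ped/.map) does not record allele roles, so its
reader infers the counted allele as the minor allele (lexicographic
tie-break); text round trips are exact only under that orientation, which
the tests encode explicitly. VCF 4.2 is read through cyvcf2 (DS dosages
with a GT hard-call fallback, per-variant R² from INFO); a small text
emitter writes VCF with DS/R2 for the synthetic outputs. All readers
accept gzip.

Harmonization of two callsets keeps variants shared by position, flips
calls 2↔0 where the counted alleles are swapped, and *drops* rather than
rescues strand-ambiguous SNPs (A/T, C/G) and sites with irreconcilable
allele pairs, reporting every removal. Frequency-based strand rescue was
deliberately left out: the drop rule is deterministic and auditable, and
ambiguous SNPs are a small minority of array content.

## Sample QC

Call-rate thresholds default to the stringency used in array release
pipelines: samples ≥ 0.97, variants ≥ 0.95, plates ≥ 0.985. The plate
statistic is the mean call rate of samples *passing* the sample threshold,
since plate acceptance is defined on passing samples. Vendor dish-QC
(DQC) is accepted as an optional per-sample input and thresholded at 0.82
when present; it is defined on raw probe intensities and is never
computed here.

Sex is inferred from the X-chromosome heterozygosity rate directly —
males (effectively hemizygous, coded 0/2 by array-export convention) fall
below 0.05, females above 0.20, anything between is ambiguous and counted
as discordant regardless of the reported sex. A het-rate reading was
chosen over an inbreeding-coefficient F statistic because it is the
direct operationalization of "X heterozygosity" and both thresholds are
configurable.

Bland–Altman limits of agreement use the sample standard deviation (n−1
denominator) and ±1.96·sd around the mean paired difference. The n vs n−1
choice is documented here because published replicate analyses rarely
state it; at replicate counts of ~24 the difference is negligible.

Cross-platform per-SNP concordance applies, as set intersection:
autosomal → biallelic → minor-allele-count ≥ 1 in the designated callset
(the sequencing callset by default, so array-monomorphic sites cannot
inflate agreement). The denominator counts calls non-missing in *both*
platforms; variants with no comparable calls are flagged, never divided.

## Relatedness

The kinship estimator is the robust between-family heterozygote-count
estimator (KING-robust). Supporting counts (per-sample heterozygote
counts restricted to pairwise-complete SNPs, double-heterozygote and
opposite-homozygote counts) are computed for all pairs at once with four
indicator-matrix products, so a 300-sample × 20k-SNP screen takes well
under a second. X-chromosome variants are excluded (the estimator assumes
autosomal diploidy), missing calls are skipped pairwise, and a pair in
which either member has zero heterozygous calls is returned as undefined
and excluded from classification rather than silently zeroed.

Degrees use lower cutoffs at the geometric midpoints 2^(−(2d+3)/2)
(0.354, 0.177, 0.0884, 0.0442); a value exactly at a cutoff takes the
closer-related class, matching the "lower cutoff" reading. Only the
between-family estimator is provided — the screen's use case is cohorts
of nominally unrelated donors, where the within-family variant adds
nothing. Ancestry-adjusted kinship (PC-Relate-style) is out of scope; on
ancestrally heterogeneous cohorts the robust estimator can go negative
for divergent pairs and mildly positive for same-ancestry pairs, which is
why the unrelated-cohort test uses a single-population cohort.

## Ancestry

LD pruning is greedy left-to-right within a sliding window (defaults
window 50 SNPs, step 10, r² > 0.1), removing the later variant of an
offending pair (lower MAF on position ties); windows never span
chromosome boundaries; monomorphic variants have undefined correlation
and are retained without entering comparisons; missing calls are
mean-imputed for the correlation only. The exact pruning tool the field
uses inherits its own tie-breaking; this implementation documents its
rules rather than replicating any tool bit-for-bit, and is idempotent on
its own output.

The reference model is fitted *supervised*: per-population counted-allele
frequencies with a 0.5 pseudocount, f = (count + 0.5)/(2n + 1), clamped
to [1e−4, 1−1e−4] to keep the projection likelihood finite at fixed
reference alleles. The classical workflow fits an unsupervised K-cluster
model on a labeled panel and then names clusters by their continental
majority; with labels available the supervised fit yields the identical
downstream contract (an F matrix plus projection) while removing label
switching and making the whole pipeline deterministic. An unsupervised
refinement mode (alternating F and Q EM updates, initialized from the
supervised fit) is available for fidelity.

Projection maximizes the binomial likelihood over the simplex by EM from
a uniform start; the update is the standard allele-responsibility
average, which keeps every iterate on the simplex and never decreases the
likelihood. Convergence is max|ΔQ| < 1e−6 or 1000 iterations (reported
per sample). Samples with zero overlapping non-missing calls are flagged
`no_overlapping_calls`; a model whose population frequencies are
identical everywhere is flagged `non_identifiable` and returns the
uniform start. The K=2 case is cross-checked in the tests against a dense
1-D grid search of the same likelihood, agreeing to 1e−3.

PCA of Q uses a full SVD with a fixed sign rule (largest-magnitude
loading positive) so coordinates are reproducible; the simplex constraint
caps the rank at K−1, which the tests assert numerically. Majority
ancestry is the argmax of Q with ties broken by population order and
flagged.

## HLA concordance

Allele names are normalized before comparison (case, zero-padded fields,
`HLA-` prefix stripped, fields beyond 4-digit truncated); `xx` marks a
wildcard second field. At 2-digit resolution only the allele group is
compared; at 4-digit both fields must agree, with wildcard truth
absorbing any sub-allele. Matching is *multiset*: each typed allele can
absorb at most one imputed allele, and of the two possible pairings of an
imputed pair against a typed pair the one with more concordant alleles
wins. Set-membership as sometimes written would let a homozygous imputed
pair double-claim a single typed allele and over-credit such errors.

Acc(L) and Acc(S) sum the reported probabilities of concordant alleles
over 2n alleles, with discordant probabilities zeroed and typed results
treated as ground truth. Donors missing from either table at a locus are
excluded and reported, with n adjusted; a donor typed at only a subset of
the requested loci contributes its own adjusted denominator. A missing
imputation probability is treated as 0 with a data-quality warning.

Genotype-of-interest concordance counts, in the numerator, only imputed
pattern matches pairable with a typed allele matching the same pattern —
the literal ratio of imputed to typed pattern counts could exceed 1 for
homozygote over-calls, contradicting its own 0–1 range, so the pairing
caps it. Homozygous typed genotypes contribute two alleles to n. The
DQA1–DQB1 haplotype-defined genotypes (DQ2, DQ8, …) are evaluated
per-locus, as concordance tables list them.

## Risk scores

The engine is deliberately weight-agnostic: SNP lists, weights, the
interaction table, proxy map, R² threshold and normalization all live in
a YAML/JSON model config. The shipped config is a *synthetic* example
(illustrative weights exercising every schema feature); published score
weights belong to their original publications and are not reproduced
here. Term resolution prefers the direct variant when present with
R² strictly above the threshold, then its proxy under the same filter,
then records the term missing; proxy chains are rejected at model load.
Missing terms contribute 0 with a per-sample audit (substitutions used,
missing list, terms scored) — no re-weighting or mean imputation, which
keeps scores conservative and comparable only at equal completeness.
Effect alleles on the non-counted strandless orientation contribute
w·(2−d). The HLA component is an unordered diplotype lookup plus optional
per-haplotype additive weights; unmatched diplotypes contribute 0 and are
reported. Normalization (affine a + b·score) is applied last.

## Variant prioritization

The rare + deleterious filter is pass ⇔ frequency < 0.01% (strict) AND
score ≥ 20 (inclusive); published usage varies between "> 20" and
"≥ 20", so the inclusive form is the default and the comparator is
configurable. Frequencies are percents (0–100), matching how annotation
reports print them; values above 100 are rejected. A missing frequency
means the variant is absent from the population database and is treated
as 0% with a provenance note. "0%" entries are numeric zero and pass the
rarity filter. Decisions are pure per-row functions, so table order can
never change results, and tightening either threshold provably shrinks
the pass set (property-tested). Summaries mirror the standard four-panel
report: variant-type distribution, frequency bins (edges printed in the
output), score-threshold count, and the combined filter, per panel
category; variant type is shown in the distribution but never filters the
core path.

## Synthetic cohort generator

The generator defines the study conditions under which everything above
is tested; its defaults are fixed once and shared by the tests and the
acceptance script.

* **Population divergence** is Balding–Nichols: ancestral frequency
  p ~ U(0.05, 0.95) per variant, population frequency
  Beta(p(1−F)/F, (1−p)(1−F)/F) with per-population divergence F
  (default 0.1 for routine runs, 0.2 for recovery experiments).
  Genotypes are binomial draws — there is *no* linkage structure, so
  pruning on synthetic panels removes only the correlation induced by
  population structure itself.
* **Admixture** draws Q ~ Dirichlet(α) (default α = 1 uniform) and
  genotypes Binomial(2, Σₖ qₖ f_km); the planted Q is recorded.
* **Pedigrees** use genotype-level gene dropping (each parent transmits
  an allele with probability g/2, exact for unlinked loci): duplicates
  are copies with independent per-call corruption at 0.001 — the scale of
  technical replicate discordance on production arrays, which yields
  replicate kinship ≈ 0.499; second/third degree are
  grandparent/great-grandparent chains (one extra meiosis each). Only the
  two members of each pair enter the output, so distinct pairs are
  unrelated.
* **X genotypes**: males are hemizygous coded 0/2, females diploid.
* **HLA**: truth alleles are drawn from a fixed per-locus 4-digit
  dictionary shipped with the package; imputed calls are correct with
  probability 1−e and otherwise a decoy from a *different allele group*
  at the same locus, so an error is an error at both resolutions and
  E[Acc(L)] = (1−e)·c exactly, with reported probabilities
  Beta-distributed with mean c (concentration 50). Allele frequencies
  are uniform — concordance arithmetic needs right-vs-wrong, not
  realistic haplotype frequencies.
* **Platform pairs** corrupt 1.2% of calls by default — the discordance
  scale at which array-vs-exome comparisons of production cohorts land
  (median per-SNP concordance ≈ 98.8%) — plus 1% missingness.
* **Annotated variants** plant independent Bernoulli rarity and
  deleteriousness flags, so the expected pass count is
  n·rare·deleterious and the truth subset is returned for recovery
  checks.

Everything is driven by `numpy.random.default_rng` seeds; identical
spec + seed gives byte-identical outputs, which the pipeline relies on
for reproducible reports.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium blocks (pruning behavior
on real genomes is only qualitatively represented), realistic HLA
haplotype frequencies and typing ambiguity, genotype-calling error that
correlates with probe intensity or GC content, batch and plate effects,
and any phenotype-genotype association.

## Pipeline and problem sizes

The pipeline runs stages in dependency order; a stage failure is recorded
with its traceback and independent stages still run. The report is JSON
with sorted keys plus per-stage TSVs; provenance records version, seed,
and a config hash, and the report is byte-identical across runs of the
same seed apart from the timestamp.

Default problem sizes — 300 samples × 5,000 autosomal + 200 X variants,
five pedigree pairs per class, 20k SNPs × 30 pairs per class and
K = 5 / 5k pruned SNPs / 200 samples in the acceptance script — were
chosen as the smallest scales at which the estimators' sampling noise is
comfortably below the decision thresholds they are tested against
(e.g. the third-degree kinship band is ±0.022 wide, while φ̂'s standard
error at 20k SNPs is an order of magnitude smaller).

## Known limitations

* No BGEN or phased-haplotype input; no CEL/IDAT intensity parsing.
* Strand-ambiguous SNPs are always dropped at merge, never
  frequency-rescued.
* The ancestry model assumes the reference panel is correctly labeled
  and its populations adequately span the targets; projection of a
  sample from an unrepresented population distributes its ancestry over
  the available ones without warning.
* HLA concordance validates imputation output; it does not impute.
* The risk-score engine ships no published weights; results are only as
  meaningful as the model config supplied.
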