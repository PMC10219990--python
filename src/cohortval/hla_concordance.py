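"""HLA imputation validation against typed truth alleles.

Three metrics, evaluated at 2-digit (allele group) or 4-digit (protein)
resolution:

* ``Acc(L)`` — locus-level accuracy: sum of reported probabilities of the
  two imputed alleles per donor, with discordant alleles contributing 0,
  divided by 2n alleles.
* ``Concordance`` — for a genotype of interest (an allele pattern such as
  DRB1*04:xx, possibly wildcarded): the fraction of typed pattern-matching
  alleles recovered by a concordant imputed allele.
* ``Acc(S)`` — donor-level accuracy: the same probability sum taken over a
  donor's typed loci (n loci, 2n alleles).

Typed results are taken as ground truth wherever imputation disagrees.
Concordance uses multiset matching: each typed allele can absorb at most
one imputed allele, so a homozygous imputed pair cannot double-claim a
single typed allele.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_ALLELE_RE = re.compile(
    r"^(?P<locus>[A-Z0-9]+)\*(?P<f1>\d{1,3})(?::(?P<f2>\d{1,4}|xx))?", re.I)


@dataclass(frozen=True)
class HLAAllele:
    """One HLA allele name, normalized to LOCUS*field1[:field2]."""

    locus: str
    field1: str
    field2: str | None = None
    wildcard: bool = False  # any field2 (renders as xx)

    def __post_init__(self) -> None:
        if not self.field1:
            raise ValueError("field1 required")
        if self.wildcard and self.field2 is not None:
            raise ValueError("wildcard allele cannot carry field2")

    @classmethod
    def parse(cls, text: str) -> "HLAAllele":
        m = _ALLELE_RE.match(text.strip().removeprefix("HLA-"))
        if not m:
            raise ValueError(f"cannot parse HLA allele {text!r}")
        locus = m.group("locus").upper()
        f1 = m.group("f1").zfill(2)
        f2 = m.group("f2")
        if f2 is not None and f2.lower() == "xx":
            return cls(locus, f1, None, wildcard=True)
        return cls(locus, f1, f2.zfill(2) if f2 is not None else None)

    def __str__(self) -> str:
        if self.wildcard:
            return f"{self.locus}*{self.field1}:xx"
        if self.field2 is None:
            return f"{self.locus}*{self.field1}"
        return f"{self.locus}*{self.field1}:{self.field2}"


def _as_allele(a) -> HLAAllele:
    return a if isinstance(a, HLAAllele) else HLAAllele.parse(str(a))


def alleles_match(imputed, typed, resolution: int) -> bool:
    """Truth-vs-imputed identity at the stated resolution.

    At 2-digit only the allele group is compared.  At 4-digit a wildcard
    truth (xx) absorbs any sub-allele of the same group; otherwise both
    fields must agree.
    """
    imputed, typed = _as_allele(imputed), _as_allele(typed)
    if imputed.locus != typed.locus or imputed.field1 != typed.field1:
        return False
    if resolution == 2:
        return True
    if resolution != 4:
        raise ValueError("resolution must be 2 or 4")
    if typed.wildcard:
        return True
    return imputed.field2 == typed.field2 and imputed.field2 is not None


def matches_pattern(allele, pattern) -> bool:
    """Pattern match at the pattern's own resolution (wildcard = any field2)."""
    allele, pattern = _as_allele(allele), _as_allele(pattern)
    if allele.locus != pattern.locus or allele.field1 != pattern.field1:
        return False
    if pattern.wildcard or pattern.field2 is None:
        return True
    return allele.field2 == pattern.field2


@dataclass(frozen=True)
class GenotypeOfInterest:
    label: str
    locus: str
    pattern: HLAAllele
    effect: str  # risk | protective


@dataclass(frozen=True)
class AlleleMatch:
    imputed: HLAAllele
    probability: float
    concordant: bool
    typed_partner: int | None  # index into the typed pair, or None


def match_alleles(imputed_pair, typed_pair, resolution: int
                  ) -> list[AlleleMatch]:
    """Multiset-match an imputed allele pair against the typed pair.

    ``imputed_pair`` is ``[(allele, probability), (allele, probability)]``.
    Each typed allele can be claimed by at most one imputed allele; of the
    two possible pairings the one with more concordant alleles wins (ties
    keep the given order).
    """
    (i1, p1), (i2, p2) = imputed_pair
    i1, i2 = _as_allele(i1), _as_allele(i2)
    typed = [_as_allele(t) for t in typed_pair]

    def pairing_flags(assign):
        flags = []
        for imp, t_idx in assign:
            ok = t_idx is not None and alleles_match(imp, typed[t_idx], resolution)
            flags.append(ok)
        return flags

    best = None
    for assign in ([(i1, 0), (i2, 1)], [(i1, 1), (i2, 0)]):
        flags = pairing_flags(assign)
        if best is None or sum(flags) > sum(best[1]):
            best = (assign, flags)
    assign, flags = best
    probs = (p1, p2)
    out = []
    for (imp, t_idx), ok, p in zip(assign, flags, probs):
        if p is None or not np.isfinite(p):
            warnings.warn(f"missing imputation probability for {imp}; treated as 0")
            p = 0.0
        out.append(AlleleMatch(imp, float(p), ok, t_idx if ok else None))
    return out


# ---------------------------------------------------------------------------
# record tables
# ---------------------------------------------------------------------------

@dataclass
class HLATypedRecord:
    donor_id: str
    alleles: dict[str, tuple[HLAAllele, HLAAllele]]  # locus -> typed pair


@dataclass
class HLAImputedRecord:
    donor_id: str
    # locus -> ((allele, prob), (allele, prob))
    alleles: dict[str, tuple[tuple[HLAAllele, float], tuple[HLAAllele, float]]]


def read_hla_table(path, imputed: bool = False):
    """TSV with columns donor_id, locus, allele1, allele2[, prob1, prob2]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    records: dict[str, dict] = {}
    for _, row in df.iterrows():
        a1, a2 = HLAAllele.parse(row.allele1), HLAAllele.parse(row.allele2)
        locus = row.locus.upper()
        entry = records.setdefault(row.donor_id, {})
        if imputed:
            entry[locus] = ((a1, float(row.prob1)), (a2, float(row.prob2)))
        else:
            entry[locus] = (a1, a2)
    cls = HLAImputedRecord if imputed else HLATypedRecord
    return [cls(d, alleles) for d, alleles in records.items()]


def write_hla_table(records, path, imputed: bool = False) -> None:
    rows = []
    for rec in records:
        for locus, pair in sorted(rec.alleles.items()):
            if imputed:
                (a1, p1), (a2, p2) = pair
                rows.append((rec.donor_id, locus, str(a1), str(a2), p1, p2))
            else:
                a1, a2 = pair
                rows.append((rec.donor_id, locus, str(a1), str(a2)))
    cols = ["donor_id", "locus", "allele1", "allele2"]
    if imputed:
        cols += ["prob1", "prob2"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusAccuracy:
    locus: str
    resolution: int
    acc: float
    n_donors: int
    excluded_donors: tuple[str, ...] = ()


def _index(records):
    return {r.donor_id: r for r in records}


def acc_locus(imputed: list[HLAImputedRecord], typed: list[HLATypedRecord],
              locus: str, resolution: int) -> LocusAccuracy:
    """Acc(L) = sum_i [P_i(A1) + P_i(A2)] / 2n, discordant P set to 0."""
    locus = locus.upper()
    t_idx, i_idx = _index(typed), _index(imputed)
    donors = [d for d in t_idx if locus in t_idx[d].alleles]
    excluded = tuple(d for d in donors
                     if d not in i_idx or locus not in i_idx[d].alleles)
    used = [d for d in donors if d not in excluded]
    if not used:
        return LocusAccuracy(locus, resolution, float("nan"), 0, excluded)
    total = 0.0
    for d in used:
        matches = match_alleles(i_idx[d].alleles[locus],
                                t_idx[d].alleles[locus], resolution)
        total += sum(m.probability for m in matches if m.concordant)
    return LocusAccuracy(locus, resolution, total / (2 * len(used)),
                         len(used), excluded)


@dataclass(frozen=True)
class GenotypeConcordance:
    label: str
    locus: str
    n_typed_alleles: int
    n_recovered: int
    concordance: float  # NaN when no typed carrier
    defined: bool


def concordance_genotype(imputed: list[HLAImputedRecord],
                         typed: list[HLATypedRecord],
                         goi: GenotypeOfInterest,
                         resolution: int) -> GenotypeConcordance:
    """Fraction of typed pattern-matching alleles recovered by imputation.

    The numerator counts only imputed pattern matches pairable with a typed
    matching allele, capping the ratio at 1; a zero denominator (no typed
    carrier) yields an undefined, flagged result rather than 0.
    """
    locus = goi.locus.upper()
    t_idx, i_idx = _index(typed), _index(imputed)
    n_typed = n_rec = 0
    for d, trec in t_idx.items():
        if locus not in trec.alleles:
            continue
        typed_pair = trec.alleles[locus]
        pattern_flags = [matches_pattern(t, goi.pattern) for t in typed_pair]
        n_typed += sum(pattern_flags)
        if d not in i_idx or locus not in i_idx[d].alleles:
            continue
        matches = match_alleles(i_idx[d].alleles[locus], typed_pair, resolution)
        recovered = {m.typed_partner for m in matches if m.concordant}
        n_rec += sum(1 for t_i, flag in enumerate(pattern_flags)
                     if flag and t_i in recovered)
    if n_typed == 0:
        return GenotypeConcordance(goi.label, locus, 0, 0, float("nan"), False)
    return GenotypeConcordance(goi.label, locus, n_typed, n_rec,
                               n_rec / n_typed, True)


@dataclass(frozen=True)
class SampleAccuracy:
    donor_id: str
    acc: float
    n_loci: int  # loci typed for this donor among those requested


def acc_sample(imputed: list[HLAImputedRecord], typed: list[HLATypedRecord],
               loci: list[str], resolution: int) -> list[SampleAccuracy]:
    """Acc(S) per donor over its typed loci, discordant P set to 0."""
    loci = [l.upper() for l in loci]
    i_idx = _index(imputed)
    out = []
    for trec in typed:
        present = [l for l in loci if l in trec.alleles]
        if not present:
            continue
        total = 0.0
        for locus in present:
            irec = i_idx.get(trec.donor_id)
            if irec is None or locus not in irec.alleles:
                continue  # counts as fully discordant (P = 0)
            matches = match_alleles(irec.alleles[locus],
                                    trec.alleles[locus], resolution)
            total += sum(m.probability for m in matches if m.concordant)
        out.append(SampleAccuracy(trec.donor_id,
                                  total / (2 * len(present)), len(present)))
    return out


@dataclass
class ConcordanceReport:
    genotype_table: pd.DataFrame
    locus_accuracy: pd.DataFrame
    sample_accuracy: pd.DataFrame
    group_summary: pd.DataFrame


def concordance_report(imputed: list[HLAImputedRecord],
                       typed: list[HLATypedRecord],
                       goi_table: list[GenotypeOfInterest],
                       resolution: int = 4,
                       loci: list[str] | None = None,
                       grouping: dict[str, str] | None = None
                       ) -> ConcordanceReport:
    """Stratified validation report: per-genotype concordance, Acc(L),
    Acc(S), and per-group Acc(S) median/IQR."""
    if loci is None:
        loci = sorted({l for t in typed for l in t.alleles})
    goi_rows = []
    for goi in goi_table:
        r = concordance_genotype(imputed, typed, goi, resolution)
        goi_rows.append((r.label, r.locus, str(goi.pattern), goi.effect,
                         r.n_typed_alleles, r.n_recovered, r.concordance,
                         r.defined))
    genotype_table = pd.DataFrame(
        goi_rows, columns=["label", "locus", "pattern", "effect",
                           "n_typed_alleles", "n_recovered", "concordance",
                           "defined"])
    locus_rows = []
    for locus in loci:
        r = acc_locus(imputed, typed, locus, resolution)
        locus_rows.append((r.locus, r.resolution, r.acc, r.n_donors,
                           len(r.excluded_donors)))
    locus_accuracy = pd.DataFrame(
        locus_rows, columns=["locus", "resolution", "acc", "n_donors",
                             "n_excluded"])
    accs = acc_sample(imputed, typed, loci, resolution)
    sample_accuracy = pd.DataFrame(
        [(a.donor_id, a.acc, a.n_loci) for a in accs],
        columns=["donor_id", "acc", "n_loci"])
    if grouping:
        sample_accuracy["group"] = sample_accuracy.donor_id.map(grouping)
    else:
        sample_accuracy["group"] = "all"
    grp = sample_accuracy.groupby("group")["acc"]
    group_summary = grp.agg(n="size", median="median",
                            q1=lambda s: s.quantile(0.25),
                            q3=lambda s: s.quantile(0.75)).reset_index()
    return ConcordanceReport(genotype_table, locus_accuracy,
                             sample_accuracy, group_summary)
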