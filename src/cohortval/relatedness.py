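"""Pairwise kinship estimation and relationship-degree classification.

The estimator is the robust between-family heterozygote-count kinship
(KING-robust).  Over the autosomal SNPs non-missing in both members of a
pair, with N_Aa,Aa the count of SNPs where both samples are heterozygous,
N_AA,aa the count with opposite homozygotes, and N_Aa(s) each sample's
heterozygote count on those SNPs:

    phi = (N_Aa,Aa - 2 N_AA,aa) / (2 min(N_Aa(a), N_Aa(b)))
          + 1/2 - (N_Aa(a) + N_Aa(b)) / (4 min(N_Aa(a), N_Aa(b)))

Duplicate samples give phi = 0.5 exactly; the estimator is symmetric and
can go negative for ancestrally divergent pairs.  Degrees are separated at
the geometric-midpoint ladder 2^(-(2d+3)/2): 0.354 (duplicate/MZ), 0.177
(first), 0.0884 (second), 0.0442 (third).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

DEGREE_LABELS = ("duplicate_MZ", "first", "second", "third", "unrelated")


@dataclass(frozen=True)
class DegreeCutoffs:
    """Lower kinship cutoffs per degree; strictly decreasing ladder."""

    duplicate: float = 2 ** -1.5      # 0.3536
    first: float = 2 ** -2.5          # 0.1768
    second: float = 2 ** -3.5         # 0.0884
    third: float = 2 ** -4.5          # 0.0442

    def __post_init__(self) -> None:
        ladder = (self.duplicate, self.first, self.second, self.third)
        if not all(x > y for x, y in zip(ladder, ladder[1:])):
            raise ValueError("cutoffs must be strictly decreasing")


@dataclass(frozen=True)
class KinshipEstimate:
    sample_a: str
    sample_b: str
    phi: float  # NaN when undefined (zero heterozygotes in a member)
    n_snps_used: int
    het_counts: tuple[int, int, int, int]  # N_Aa(a), N_Aa(b), N_AaAa, N_AAaa

    @property
    def defined(self) -> bool:
        return np.isfinite(self.phi)


def _pairwise_kinship_matrices(calls: np.ndarray):
    """All-pairs supporting counts via indicator matmuls (pairwise-complete)."""
    het = (calls == 1).astype(np.float64)
    hom0 = (calls == 0).astype(np.float64)
    hom2 = (calls == 2).astype(np.float64)
    valid = (calls != MISSING).astype(np.float64)
    n_aa_bb = hom0 @ hom2.T
    n_opp = n_aa_bb + n_aa_bb.T
    n_het_both = het @ het.T
    het_a = het @ valid.T          # het in row sample, called in column sample
    n_shared = valid @ valid.T
    return het_a, n_het_both, n_opp, n_shared


def estimate_kinship(matrix: GenotypeMatrix,
                     pairs: list[tuple[str, str]] | None = None
                     ) -> list[KinshipEstimate]:
    """Robust kinship for all pairs (default) or a requested pair list.

    X-chromosome variants are excluded (the estimator assumes autosomal
    diploidy) and SNPs missing in either member are skipped pairwise.  A
    pair where either member has zero heterozygous calls on the shared SNPs
    is returned with phi = NaN and excluded from classification downstream.
    """
    auto = matrix.take_variants(matrix.autosomal_mask)
    het_a, n_het_both, n_opp, n_shared = _pairwise_kinship_matrices(auto.calls)
    ids = auto.sample_ids
    index = {s: i for i, s in enumerate(ids)}
    if pairs is None:
        pair_idx = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))]
    else:
        pair_idx = [(index[a], index[b]) for a, b in pairs]
    out = []
    for i, j in pair_idx:
        na, nb = het_a[i, j], het_a[j, i]
        naa, nopp = n_het_both[i, j], n_opp[i, j]
        m = min(na, nb)
        if m > 0:
            phi = (naa - 2.0 * nopp) / (2.0 * m) + 0.5 - (na + nb) / (4.0 * m)
        else:
            phi = np.nan
        out.append(KinshipEstimate(
            ids[i], ids[j], float(phi), int(n_shared[i, j]),
            (int(na), int(nb), int(naa), int(nopp))))
    return out


def classify_degree(estimate: KinshipEstimate | float,
                    cutoffs: DegreeCutoffs = DegreeCutoffs()) -> str:
    """Assign relationship degree by the lower-cutoff ladder.

    A value exactly at a cutoff takes the closer-related class (the cutoffs
    are lower bounds).  Undefined estimates classify as ``unrelated`` only
    through :func:`relatedness_screen`, which excludes them explicitly.
    """
    phi = estimate.phi if isinstance(estimate, KinshipEstimate) else float(estimate)
    if not np.isfinite(phi):
        raise ValueError("cannot classify an undefined kinship estimate")
    if phi >= cutoffs.duplicate:
        return "duplicate_MZ"
    if phi >= cutoffs.first:
        return "first"
    if phi >= cutoffs.second:
        return "second"
    if phi >= cutoffs.third:
        return "third"
    return "unrelated"


@dataclass
class RelatednessReport:
    pairs: pd.DataFrame           # ids, phi, counts, degree
    degree_counts: dict[str, int]
    flagged: pd.DataFrame         # degree <= third
    summary: pd.DataFrame         # per-class phi median / IQR
    n_undefined: int = 0


def relatedness_screen(matrix: GenotypeMatrix,
                       cutoffs: DegreeCutoffs = DegreeCutoffs()
                       ) -> RelatednessReport:
    """All-pairs kinship screen with degree counts and flagged related pairs."""
    estimates = estimate_kinship(matrix)
    rows = []
    n_undefined = 0
    for e in estimates:
        if e.defined:
            degree = classify_degree(e, cutoffs)
        else:
            degree = "undefined"
            n_undefined += 1
        rows.append((e.sample_a, e.sample_b, e.phi, e.n_snps_used,
                     *e.het_counts, degree))
    cols = ["sample_a", "sample_b", "phi", "n_snps_used",
            "n_het_a", "n_het_b", "n_het_both", "n_opposite_hom", "degree"]
    pairs = pd.DataFrame(rows, columns=cols)
    counts = {label: int((pairs.degree == label).sum()) for label in DEGREE_LABELS}
    flagged = pairs[pairs.degree.isin(DEGREE_LABELS[:4])].reset_index(drop=True)
    defined = pairs[pairs.degree != "undefined"]
    if len(defined):
        summary = defined.groupby("degree")["phi"].describe(
            percentiles=[0.25, 0.5, 0.75])[["count", "25%", "50%", "75%"]]
        summary = summary.rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
        summary = summary.reset_index()
    else:
        summary = pd.DataFrame(columns=["degree", "count", "q1", "median", "q3"])
    return RelatednessReport(pairs, counts, flagged, summary, n_undefined)
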