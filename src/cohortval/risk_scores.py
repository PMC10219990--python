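"""Generic polygenic risk score engine with HLA interaction terms.

Covers the published T1D score families (GRS1: 30 SNPs, GRS2: 67 SNPs with
HLA diplotype interactions, AA-GRS: 7 SNPs) as configurable weighted-sum
models: a non-HLA component sum(w_i * effect-allele dosage), an HLA
component from a diplotype interaction table plus optional per-haplotype
additive weights, an ordered proxy-SNP substitution map with an imputation
R² filter (strict >), and an optional affine normalization a + b * score.
Weight tables live in model config files (YAML/JSON); the engine itself is
weight-agnostic and fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import DosageMatrix


@dataclass(frozen=True)
class SNPTerm:
    variant_id: str
    effect_allele: str
    weight: float


@dataclass(frozen=True)
class InteractionTerm:
    """Weight applied when a donor's unordered haplotype pair matches."""

    haplotypes: frozenset  # one (homozygous) or two haplotype labels
    weight: float


@dataclass
class GRSModel:
    name: str
    snp_terms: list[SNPTerm] = field(default_factory=list)
    interaction_terms: list[InteractionTerm] = field(default_factory=list)
    haplotype_weights: dict[str, float] = field(default_factory=dict)
    proxy_map: dict[str, str] = field(default_factory=dict)
    r2_min: float | None = None
    normalization: tuple[float, float] | None = None  # (a, b): a + b*score

    def __post_init__(self) -> None:
        for t in self.snp_terms:
            if not np.isfinite(t.weight):
                raise ValueError(f"non-finite weight for {t.variant_id}")
        proxies = set(self.proxy_map.values())
        chained = proxies & set(self.proxy_map.keys())
        if chained:
            raise ValueError(f"proxy chains not allowed: {sorted(chained)}")

    @classmethod
    def from_config(cls, path: str | Path) -> "GRSModel":
        """Load a model from a YAML or JSON config file."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
        norm = cfg.get("normalization")
        if isinstance(norm, dict):
            norm = (float(norm.get("a", 0.0)), float(norm.get("b", 1.0)))
        elif norm is not None:
            norm = (float(norm[0]), float(norm[1]))
        return cls(
            name=cfg["name"],
            snp_terms=[SNPTerm(t["variant_id"], t["effect_allele"],
                               float(t["weight"]))
                       for t in cfg.get("snp_terms", [])],
            interaction_terms=[
                InteractionTerm(frozenset(t["haplotypes"]), float(t["weight"]))
                for t in cfg.get("interaction_terms", [])],
            haplotype_weights={k: float(v) for k, v in
                               cfg.get("haplotype_weights", {}).items()},
            proxy_map=dict(cfg.get("proxy_map", {})),
            r2_min=cfg.get("r2_min"),
            normalization=norm,
        )


def example_model() -> GRSModel:
    """The shipped synthetic example model (illustrative weights only)."""
    from importlib import resources
    path = resources.files("cohortval.data") / "example_grs_model_synthetic.yaml"
    return GRSModel.from_config(str(path))


@dataclass(frozen=True)
class ResolvedTerm:
    term: SNPTerm
    column: int | None        # column in the dosage matrix, None if missing
    used_proxy: str | None = None
    flipped: bool = False     # effect allele is the non-counted allele


def resolve_variants(model: GRSModel, dosages: DosageMatrix
                     ) -> list[ResolvedTerm]:
    """Map each model term to a dosage column, via proxy where needed.

    Preference order per term: the direct variant if present with
    R² > r2_min, else its proxy under the same filter, else missing.
    Effect-allele orientation is recorded so scoring can flip 2 - d where
    the counted allele is the non-effect allele.
    """
    by_id = {v.id: j for j, v in enumerate(dosages.variants) if v.id != "."}

    def passing(vid: str) -> int | None:
        j = by_id.get(vid)
        if j is None:
            return None
        if model.r2_min is not None:
            r2 = dosages.imputation_r2[j]
            if not np.isfinite(r2) or not r2 > model.r2_min:
                return None
        return j

    out = []
    for term in model.snp_terms:
        j = passing(term.variant_id)
        proxy_used = None
        if j is None and term.variant_id in model.proxy_map:
            proxy = model.proxy_map[term.variant_id]
            j = passing(proxy)
            proxy_used = proxy if j is not None else None
        flipped = False
        if j is not None:
            v = dosages.variants[j]
            if term.effect_allele == v.alt_allele:
                flipped = False
            elif term.effect_allele == v.ref_allele:
                flipped = True
            else:
                j, proxy_used = None, None  # allele mismatch: unusable
        out.append(ResolvedTerm(term, j, proxy_used, flipped))
    return out


def score_additive(model: GRSModel, dosages: DosageMatrix,
                   resolved: list[ResolvedTerm] | None = None) -> np.ndarray:
    """Non-HLA component: sum w_i * effect-allele dosage per sample.

    Missing terms (and missing individual dosage values) contribute 0;
    no re-weighting is applied.
    """
    if resolved is None:
        resolved = resolve_variants(model, dosages)
    total = np.zeros(dosages.n_samples)
    for r in resolved:
        if r.column is None:
            continue
        d = dosages.dosages[:, r.column]
        d = np.where(np.isfinite(d), d, np.nan)
        eff = 2.0 - d if r.flipped else d
        total += np.where(np.isfinite(eff), r.term.weight * eff, 0.0)
    return total


def score_hla_interactions(model: GRSModel,
                           hla_tag_genotypes: dict[str, tuple[str, str]]
                           ) -> tuple[dict[str, float], list[str]]:
    """HLA component per sample from a diplotype lookup.

    ``hla_tag_genotypes`` maps sample id to its unordered pair of
    tag-defined haplotype labels.  Matched interaction weights are summed
    with any per-haplotype additive weights; samples whose diplotype
    matches nothing score 0 and are reported unmatched.
    """
    scores: dict[str, float] = {}
    unmatched: list[str] = []
    for sid, (h1, h2) in hla_tag_genotypes.items():
        diplotype = frozenset((h1, h2))
        component = 0.0
        hit = False
        for it in model.interaction_terms:
            if it.haplotypes == diplotype:
                component += it.weight
                hit = True
        for h in (h1, h2):
            if h in model.haplotype_weights:
                component += model.haplotype_weights[h]
                hit = True
        if not hit:
            unmatched.append(sid)
        scores[sid] = component
    return scores, unmatched


@dataclass(frozen=True)
class GRSResult:
    sample_id: str
    hla_component: float
    non_hla_component: float
    total: float
    n_terms_scored: int
    substitutions_used: tuple[str, ...]
    missing_terms: tuple[str, ...]


def compute_grs(model: GRSModel, dosages: DosageMatrix,
                hla_tags: dict[str, tuple[str, str]] | None = None
                ) -> list[GRSResult]:
    """Per-sample score with normalization applied last and a full audit."""
    resolved = resolve_variants(model, dosages)
    non_hla = score_additive(model, dosages, resolved)
    hla_scores, _ = score_hla_interactions(model, hla_tags or {})
    subs = tuple(f"{r.term.variant_id}->{r.used_proxy}"
                 for r in resolved if r.used_proxy)
    missing = tuple(r.term.variant_id for r in resolved if r.column is None)
    n_scored = sum(r.column is not None for r in resolved)
    a, b = model.normalization if model.normalization else (0.0, 1.0)
    out = []
    for i, sid in enumerate(dosages.sample_ids):
        hla = hla_scores.get(sid, 0.0)
        raw = hla + non_hla[i]
        out.append(GRSResult(sid, hla, float(non_hla[i]), a + b * raw,
                             n_scored, subs, missing))
    return out


def grs_group_summary(results: list[GRSResult],
                      grouping: dict[str, str],
                      clinical_groups: dict[str, str] | None = None
                      ) -> pd.DataFrame:
    """Median/IQR of total score per clinical group x grouping cell.

    Rows for empty groups are emitted with n = 0 rather than dropped, so a
    report's group structure never silently shrinks.
    """
    df = pd.DataFrame({
        "sample_id": [r.sample_id for r in results],
        "total": [r.total for r in results],
    })
    df["group"] = df.sample_id.map(grouping)
    df["clinical_group"] = (df.sample_id.map(clinical_groups)
                            if clinical_groups else "all")
    cells = []
    for (cg, g) in sorted({(c, g) for c in df.clinical_group.dropna().unique()
                           for g in df.group.dropna().unique()}):
        sub = df[(df.clinical_group == cg) & (df.group == g)]["total"]
        cells.append((cg, g, len(sub),
                      sub.median() if len(sub) else np.nan,
                      sub.quantile(0.25) if len(sub) else np.nan,
                      sub.quantile(0.75) if len(sub) else np.nan))
    return pd.DataFrame(cells, columns=["clinical_group", "group", "n",
                                        "median", "q1", "q3"])
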