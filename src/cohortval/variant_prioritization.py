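"""Rare + deleterious variant prioritization in configured gene panels.

The core filter keeps annotated coding variants that are simultaneously
rare in the population (gnomAD-style frequency, in percent, strictly below
0.01%) and predicted deleterious (CADD-scaled score at or above 20).
Variants absent from the population database (missing frequency) are
treated as frequency 0 with a provenance note.  Summaries mirror the
standard archive report: variant-type distribution, frequency bins, score
threshold counts, and the combined filter, per gene-panel category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["donor_id", "gene", "dna_change", "protein_change",
                    "zygosity", "variant_type", "population_frequency_pct",
                    "deleteriousness_score"]

_COLUMN_ALIASES = {
    "case id": "donor_id", "case_id": "donor_id",
    "dna variant": "dna_change", "dna_variant": "dna_change",
    "protein variant": "protein_change", "protein_variant": "protein_change",
    "gnomad frequency": "population_frequency_pct",
    "gnomad_frequency": "population_frequency_pct",
    "cadd score": "deleteriousness_score", "cadd_score": "deleteriousness_score",
}

FREQUENCY_BIN_EDGES_PCT = [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]


@dataclass(frozen=True)
class GenePanel:
    name: str
    genes: frozenset
    category: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        object.__setattr__(self, "genes",
                           frozenset(g.upper() for g in self.genes))


def load_panels(path: str | Path) -> list[GenePanel]:
    """YAML file: list of {name, genes: [...], category}."""
    import yaml
    cfg = yaml.safe_load(Path(path).read_text())
    return [GenePanel(p["name"], frozenset(p["genes"]), p.get("category", ""))
            for p in cfg]


def _parse_percent(value) -> float:
    if pd.isna(value) or value == "":
        return np.nan
    v = float(str(value).rstrip("%"))
    if not 0.0 <= v <= 100.0:
        raise ValueError(f"population frequency must be a percent in "
                         f"[0,100], got {v}")
    return v


def read_variant_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read an annotated variant table (TSV/CSV), normalizing column names.

    Frequency values may carry a trailing ``%``; both the archive-report
    headers (Case ID / gnomAD Frequency / CADD Score) and the internal
    snake_case names are accepted.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [_COLUMN_ALIASES.get(c.strip().lower(),
                                      c.strip().lower().replace(" ", "_"))
                  for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns
               and c not in ("variant_type",)]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    df["population_frequency_pct"] = df["population_frequency_pct"].map(
        _parse_percent)
    df["deleteriousness_score"] = df["deleteriousness_score"].astype(float)
    if (df["deleteriousness_score"].dropna() < 0).any():
        raise ValueError("deleteriousness score must be non-negative")
    if "variant_type" not in df.columns:
        df["variant_type"] = "other"
    return df


def bundled_variant_table(name: str) -> pd.DataFrame:
    """Load one of the shipped annotated-variant tables.

    ``published`` — the six previously published monogenic-diabetes gene
    variants confirmed in the archive's exome data; ``candidates`` — the
    two variants flagged as potential monogenic diabetes candidates by the
    rare+deleterious workflow.
    """
    from importlib import resources
    fname = {"published": "published_variants.tsv",
             "candidates": "candidate_variants.tsv"}[name]
    path = resources.files("cohortval.data") / fname
    return read_variant_table(str(path))


def bundled_gene_panels() -> list[GenePanel]:
    """The shipped autoimmune and MODY/neonatal diabetes gene panels."""
    from importlib import resources
    return load_panels(str(resources.files("cohortval.data") / "gene_panels.yaml"))


def filter_panel(table: pd.DataFrame, panel: GenePanel) -> pd.DataFrame:
    """Rows whose gene symbol is in the panel (case-insensitive)."""
    return table[table.gene.str.upper().isin(panel.genes)].copy()


def apply_rare_deleterious(table: pd.DataFrame, freq_max_pct: float = 0.01,
                           score_min: float = 20.0,
                           score_comparator: str = "ge") -> pd.DataFrame:
    """Per-row rare+deleterious decision with pass/fail reasons.

    Pass requires frequency strictly below ``freq_max_pct`` (percent) and
    score >= ``score_min`` (``score_comparator='gt'`` switches to strict).
    Missing frequency is read as 0 (absent from the population database)
    and noted in the provenance column.
    """
    out = table.copy()
    freq = out.population_frequency_pct.astype(float)
    out["frequency_note"] = np.where(
        freq.isna(), "absent_from_population_database", "")
    freq = freq.fillna(0.0)
    out["pass_rare"] = freq < freq_max_pct
    score = out.deleteriousness_score.astype(float)
    out["pass_deleterious"] = (score > score_min if score_comparator == "gt"
                               else score >= score_min)
    out["pass"] = out.pass_rare & out.pass_deleterious
    reasons = []
    for rare_ok, del_ok in zip(out.pass_rare, out.pass_deleterious):
        why = []
        if not rare_ok:
            why.append("frequency")
        if not del_ok:
            why.append("deleteriousness")
        reasons.append(",".join(why) if why else "pass")
    out["reason"] = reasons
    return out


@dataclass
class PrioritizationSummary:
    by_variant_type: pd.DataFrame
    by_frequency_bin: pd.DataFrame
    by_score_threshold: pd.DataFrame
    combined_filter: pd.DataFrame
    frequency_bin_edges_pct: list[float] = field(
        default_factory=lambda: list(FREQUENCY_BIN_EDGES_PCT))


def summarize(table: pd.DataFrame, panels: list[GenePanel],
              freq_max_pct: float = 0.01, score_min: float = 20.0
              ) -> PrioritizationSummary:
    """Four-section summary per panel category: variant-type distribution,
    frequency bins, deleteriousness-threshold count, combined filter."""
    sections: dict[str, list] = {"type": [], "freq": [], "score": [], "both": []}
    for panel in panels:
        sub = filter_panel(table, panel)
        cat = panel.category or panel.name
        tc = sub.variant_type.value_counts()
        for vt, n in tc.items():
            sections["type"].append((cat, vt, int(n)))
        freq = sub.population_frequency_pct.fillna(0.0)
        bins = pd.cut(freq, FREQUENCY_BIN_EDGES_PCT, right=False,
                      include_lowest=True)
        for interval, n in bins.value_counts().sort_index().items():
            sections["freq"].append((cat, str(interval), int(n)))
        flt = apply_rare_deleterious(sub, freq_max_pct, score_min)
        sections["score"].append((cat, score_min,
                                  int(flt.pass_deleterious.sum())))
        sections["both"].append((cat, int(flt["pass"].sum()), len(sub)))
    return PrioritizationSummary(
        pd.DataFrame(sections["type"], columns=["category", "variant_type", "n"]),
        pd.DataFrame(sections["freq"], columns=["category", "frequency_bin_pct", "n"]),
        pd.DataFrame(sections["score"], columns=["category", "score_min", "n_passing"]),
        pd.DataFrame(sections["both"], columns=["category", "n_passing", "n_total"]),
    )


def candidate_report(subset: pd.DataFrame,
                     known_variants: set[tuple[str, str]] | None = None
                     ) -> pd.DataFrame:
    """Per-donor candidate list with a previously-validated flag.

    ``known_variants`` holds (gene, dna_change) pairs already validated;
    everything else is marked as needing functional study.  An empty input
    still yields a well-formed (headed) report.
    """
    cols = ["donor_id", "gene", "dna_change", "protein_change", "zygosity",
            "population_frequency_pct", "deleteriousness_score",
            "previously_validated", "status"]
    if len(subset) == 0:
        return pd.DataFrame(columns=cols)
    known = known_variants or set()
    out = subset.copy()
    out["previously_validated"] = [
        (g.upper(), c) in {(a.upper(), b) for a, b in known}
        for g, c in zip(out.gene, out.dna_change)]
    out["status"] = np.where(out.previously_validated,
                             "previously_validated", "needs_functional_study")
    return out[[c for c in cols if c in out.columns]].reset_index(drop=True)
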