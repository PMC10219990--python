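"""End-to-end orchestration of the validation stages over a config file.

Stages run in dependency order (cohort generation/IO, QC, relatedness,
ancestry, HLA concordance, risk scores, platform concordance, variant
prioritization); a stage failure is recorded in the report and independent
stages still run.  The consolidated report is machine-readable JSON (plus
per-stage TSV tables) with provenance: package version, seed, config hash,
and a timestamp.  With a fixed seed the report is byte-identical across
runs apart from the timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .ancestry import (assign_majority_ancestry, fit_reference, ld_prune,
                       pca_of_Q, project)
from .genotype_io import GenotypeMatrix
from .hla_concordance import GenotypeOfInterest, HLAAllele, concordance_report
from .relatedness import DegreeCutoffs, classify_degree, estimate_kinship, \
    relatedness_screen
from .risk_scores import compute_grs, example_model, grs_group_summary, GRSModel
from .sample_qc import (QCThresholds, call_rates, infer_sex,
                        per_snp_concordance, replicate_bland_altman,
                        ConcordanceFilters)
from .synthetic_cohort import (CohortSpec, RELATIONSHIP_TO_DEGREE,
                               generate_cohort, simulate_annotated_variants,
                               simulate_grs_inputs)
from .variant_prioritization import (apply_rare_deleterious,
                                     bundled_gene_panels, candidate_report,
                                     summarize)

STAGES = ("qc", "relatedness", "ancestry", "hla", "grs",
          "platform_concordance", "prioritization")

DEFAULTS = {
    "seed": 0,
    "output_dir": "cohortval_out",
    "stages": {s: True for s in STAGES},
    "cohort": {
        "n_samples": 300,
        "n_variants": 5000,
        "n_populations": 5,
        "fst_per_population": 0.1,
        "admixture_dirichlet_alpha": 1.0,
        "pedigree_plan": [["duplicate", 5], ["parent_offspring", 5],
                          ["full_sibling", 5], ["second_degree", 5],
                          ["third_degree", 5]],
        "replicate_error_rate": 0.001,
        "missing_rate": 0.002,
        "x_variant_count": 200,
    },
    "qc": {"sample_call_rate_min": 0.97, "variant_call_rate_min": 0.95,
           "plate_mean_call_rate_min": 0.985},
    "prune": {"window": 50, "step": 10, "r2_max": 0.1},
    "prioritization": {"freq_max_pct": 0.01, "score_min": 20.0,
                       "n_variants": 1000, "rare_fraction": 0.1,
                       "deleterious_fraction": 0.2},
    "grs_model": None,  # path to a model config; None = shipped example
}


class ConfigError(ValueError):
    """One or more configuration violations; all are listed at once."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _merge(defaults: dict, overrides: dict) -> dict:
    out = {}
    for k, v in defaults.items():
        o = overrides.get(k)
        if isinstance(v, dict) and isinstance(o, dict):
            out[k] = _merge(v, o)
        else:
            out[k] = o if k in overrides else v
    for k in overrides:
        if k not in defaults:
            out[k] = overrides[k]
    return out


def validate_config(config: dict | None) -> dict:
    """Fill defaults and collect every violation before raising."""
    cfg = _merge(DEFAULTS, config or {})
    errors = []
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        errors.append(f"seed must be a non-negative integer, got {cfg['seed']}")
    p = cfg["prune"]
    if p["window"] < p["step"]:
        errors.append(f"prune: window < step ({p['window']} < {p['step']})")
    if p["window"] < 2:
        errors.append("prune: window must be >= 2")
    if not 0 < p["r2_max"] <= 1:
        errors.append("prune: r2_max must be in (0,1]")
    for k, v in cfg["qc"].items():
        if not 0 <= v <= 1:
            errors.append(f"qc.{k} must be in [0,1], got {v}")
    pr = cfg["prioritization"]
    if pr["freq_max_pct"] < 0 or pr["freq_max_pct"] > 100:
        errors.append("prioritization.freq_max_pct must be a percent in [0,100]")
    if pr["score_min"] < 0:
        errors.append("prioritization.score_min must be >= 0")
    for k in ("replicate_error_rate", "missing_rate"):
        v = cfg["cohort"][k]
        if not 0 <= v <= 1:
            errors.append(f"cohort.{k} must be in [0,1], got {v}")
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        errors.append(f"unknown stages: {sorted(unknown)}")
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path: str | Path) -> dict:
    import yaml
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ValidationReport:
    provenance: dict
    stages: dict = field(default_factory=dict)

    @property
    def failed_stages(self) -> list[str]:
        return [s for s, block in self.stages.items()
                if block.get("status") == "failed"]

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not serializable: {type(o)}")
        return json.dumps({"provenance": self.provenance,
                           "stages": self.stages},
                          indent=2, sort_keys=True, default=default)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None,
                 output_dir: str | Path | None = None) -> ValidationReport:
    cfg = validate_config(config or {})
    out_dir = Path(output_dir or cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    report = ValidationReport(provenance={
        "package": "cohortval",
        "version": __version__,
        "seed": cfg["seed"],
        "config_hash": _config_hash({k: v for k, v in cfg.items()
                                     if k != "output_dir"}),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    })
    spec = CohortSpec(seed=cfg["seed"],
                      pedigree_plan=tuple((r, c) for r, c in
                                          cfg["cohort"]["pedigree_plan"]),
                      **{k: v for k, v in cfg["cohort"].items()
                         if k != "pedigree_plan"})
    cohort = generate_cohort(spec)
    enabled = [s for s in STAGES if cfg["stages"].get(s, True)]
    for stage in enabled:
        try:
            block = _STAGE_RUNNERS[stage](cfg, cohort, out_dir)
            block["status"] = "ok"
        except Exception as exc:  # recorded, independent stages continue
            block = {"status": "failed", "error": f"{type(exc).__name__}: {exc}",
                     "traceback": traceback.format_exc(limit=3)}
        report.stages[stage] = block
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    return report


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_qc(cfg, cohort, out_dir):
    thresholds = QCThresholds(**cfg["qc"])
    rates = call_rates(cohort.targets, thresholds)
    rates.per_sample.to_csv(out_dir / "qc_sample_call_rates.tsv",
                            sep="\t", index=False)
    sex = infer_sex(cohort.targets)
    n_concordant = sum(r.concordant_with_reported for r in sex)
    # replicate reproducibility from the planted duplicate pairs
    dup_pairs = [(a, b) for a, b, rel in cohort.truth.true_relationships
                 if rel == "duplicate"]
    ba = None
    dup_phi = []
    if len(dup_pairs) >= 2:
        ped_rates = call_rates(cohort.pedigree, thresholds).per_sample
        rate_of = dict(zip(ped_rates.sample_id, ped_rates.call_rate))
        res = replicate_bland_altman([rate_of[a] for a, _ in dup_pairs],
                                     [rate_of[b] for _, b in dup_pairs])
        ba = {"bias": res.bias, "sd_diff": res.sd_diff,
              "loa_low": res.loa_low, "loa_high": res.loa_high,
              "pairs_n": res.pairs_n}
        for e in estimate_kinship(cohort.pedigree, pairs=dup_pairs):
            dup_phi.append(e.phi)
    return {
        "n_samples": cohort.targets.n_samples,
        "n_variants": cohort.targets.n_variants,
        "n_samples_passing": int(rates.per_sample["pass"].sum()),
        "n_variants_passing": int(rates.per_variant["pass"].sum()),
        "sex_concordant": n_concordant,
        "sex_total": len(sex),
        "replicate_bland_altman": ba,
        "replicate_kinship_median": (float(np.median(dup_phi))
                                     if dup_phi else None),
    }


def _stage_relatedness(cfg, cohort, out_dir):
    screen = relatedness_screen(cohort.targets)
    screen.pairs.to_csv(out_dir / "relatedness_pairs.tsv", sep="\t",
                        index=False)
    recovery = {}
    if cohort.truth.true_relationships:
        pairs = [(a, b) for a, b, _ in cohort.truth.true_relationships]
        ests = estimate_kinship(cohort.pedigree, pairs=pairs)
        n_ok = 0
        for est, (_, _, rel) in zip(ests, cohort.truth.true_relationships):
            if est.defined and classify_degree(est) == RELATIONSHIP_TO_DEGREE[rel]:
                n_ok += 1
        recovery = {"n_pairs": len(ests),
                    "n_correct_degree": n_ok,
                    "fraction_correct": n_ok / len(ests)}
    return {
        "n_pairs": len(screen.pairs),
        "degree_counts": screen.degree_counts,
        "n_flagged": len(screen.flagged),
        "n_undefined": screen.n_undefined,
        "pedigree_recovery": recovery,
    }


def _stage_ancestry(cfg, cohort, out_dir):
    p = cfg["prune"]
    auto = cohort.reference.take_variants(cohort.reference.autosomal_mask)
    kept = ld_prune(auto, p["window"], p["step"], p["r2_max"])
    kept_keys = {(v.chromosome, v.position) for v in kept}
    auto_pruned = auto.take_variants(
        auto.variant_mask(lambda v: (v.chromosome, v.position) in kept_keys))
    model = fit_reference(auto_pruned, cohort.reference_labels)
    targets = cohort.targets.take_variants(
        cohort.targets.variant_mask(
            lambda v: (v.chromosome, v.position) in kept_keys))
    props = project(targets, model)
    Q = np.vstack([pr.Q for pr in props])
    labels = assign_majority_ancestry(props, model.population_names)
    coords, evr = pca_of_Q(Q)
    truth_Q = np.vstack([cohort.truth.true_Q[s] for s in targets.sample_ids])
    rmse = float(np.sqrt(np.mean((Q - truth_Q) ** 2)))
    import pandas as pd
    qdf = pd.DataFrame(Q, columns=model.population_names)
    qdf.insert(0, "sample_id", targets.sample_ids)
    qdf["majority"] = [l for _, l, _ in labels]
    qdf.to_csv(out_dir / "ancestry_Q.tsv", sep="\t", index=False)
    return {
        "n_pruned_variants": len(kept),
        "populations": model.population_names,
        "n_converged": sum(pr.converged for pr in props),
        "q_rmse_vs_truth": rmse,
        "pc_explained_variance": evr.tolist(),
    }


DEFAULT_GOI = [
    GenotypeOfInterest("DR3", "DRB1", HLAAllele.parse("DRB1*03:01"), "risk"),
    GenotypeOfInterest("DR4", "DRB1", HLAAllele.parse("DRB1*04:xx"), "risk"),
    GenotypeOfInterest("DQ8", "DQB1", HLAAllele.parse("DQB1*03:02"), "risk"),
    GenotypeOfInterest("DQ6", "DQB1", HLAAllele.parse("DQB1*06:02"),
                       "protective"),
]


def _stage_hla(cfg, cohort, out_dir):
    rep = concordance_report(cohort.hla_imputed, cohort.hla_typed,
                             DEFAULT_GOI, resolution=4)
    rep.genotype_table.to_csv(out_dir / "hla_genotype_concordance.tsv",
                              sep="\t", index=False)
    rep.sample_accuracy.to_csv(out_dir / "hla_sample_accuracy.tsv",
                               sep="\t", index=False)
    return {
        "n_donors": len(rep.sample_accuracy),
        "acc_locus": {row.locus: row.acc
                      for row in rep.locus_accuracy.itertuples()},
        "acc_sample_median": float(rep.sample_accuracy.acc.median()),
        "n_goi_defined": int(rep.genotype_table.defined.sum()),
    }


def _stage_grs(cfg, cohort, out_dir):
    model = (GRSModel.from_config(cfg["grs_model"]) if cfg["grs_model"]
             else example_model())
    rng_seed = cfg["seed"] + 101
    dosages, tags = simulate_grs_inputs(model, cohort.targets.n_samples,
                                        rng_seed)
    results = compute_grs(model, dosages, tags)
    grouping = {r.sample_id: "all" for r in results}
    summary = grs_group_summary(results, grouping)
    import pandas as pd
    pd.DataFrame([(r.sample_id, r.hla_component, r.non_hla_component,
                   r.total) for r in results],
                 columns=["sample_id", "hla", "non_hla", "total"]).to_csv(
        out_dir / "grs_scores.tsv", sep="\t", index=False)
    return {
        "model": model.name,
        "n_samples": len(results),
        "n_terms_scored": results[0].n_terms_scored if results else 0,
        "substitutions_used": list(results[0].substitutions_used) if results else [],
        "total_median": float(np.median([r.total for r in results])),
        "group_summary_rows": len(summary),
    }


def _stage_platform(cfg, cohort, out_dir):
    table = per_snp_concordance(cohort.targets, cohort.platform_b,
                                ConcordanceFilters(mac_in="b"))
    table.to_csv(out_dir / "platform_concordance.tsv", sep="\t", index=False)
    valid = table[~table.no_comparable_calls]
    return {
        "n_variants_compared": len(table),
        "concordance_median": float(valid.concordance.median()),
        "concordance_q1": float(valid.concordance.quantile(0.25)),
        "concordance_q3": float(valid.concordance.quantile(0.75)),
    }


def _stage_prioritization(cfg, cohort, out_dir):
    p = cfg["prioritization"]
    panels = bundled_gene_panels()
    table, truth = simulate_annotated_variants(
        panels, p["n_variants"], p["rare_fraction"],
        p["deleterious_fraction"], cfg["seed"] + 202,
        p["freq_max_pct"], p["score_min"])
    flt = apply_rare_deleterious(table, p["freq_max_pct"], p["score_min"])
    passing = flt[flt["pass"]]
    rep = candidate_report(passing)
    rep.to_csv(out_dir / "prioritization_candidates.tsv", sep="\t", index=False)
    summary = summarize(table, panels, p["freq_max_pct"], p["score_min"])
    return {
        "n_variants": len(table),
        "n_passing": int(flt["pass"].sum()),
        "n_truth_planted": int(truth.sum()),
        "recovered_truth_exactly": bool((flt["pass"].to_numpy() == truth).all()),
        "combined_filter": summary.combined_filter.to_dict(orient="records"),
    }


_STAGE_RUNNERS = {
    "qc": _stage_qc,
    "relatedness": _stage_relatedness,
    "ancestry": _stage_ancestry,
    "hla": _stage_hla,
    "grs": _stage_grs,
    "platform_concordance": _stage_platform,
    "prioritization": _stage_prioritization,
}
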