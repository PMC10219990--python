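"""Sample/variant/plate QC, sex concordance, and replicate reproducibility.

Call-rate thresholds default to the array-processing stringency used for
cohort genotyping archives: samples pass at >= 97% call rate, variants at
>= 95%, and plates at a mean passing-sample call rate >= 98.5%.  Sex is
inferred from X-chromosome heterozygosity (males are effectively homozygous
on X outside the PAR), and technical replicates are compared both by
Bland-Altman limits of agreement on call rates and by per-SNP concordance
between harmonized callsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


@dataclass(frozen=True)
class QCThresholds:
    sample_call_rate_min: float = 0.97
    variant_call_rate_min: float = 0.95
    plate_mean_call_rate_min: float = 0.985
    dqc_min: float = 0.82  # vendor dish-QC, thresholded only when supplied

    def __post_init__(self) -> None:
        for name in ("sample_call_rate_min", "variant_call_rate_min",
                     "plate_mean_call_rate_min", "dqc_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


@dataclass
class CallRateReport:
    per_sample: pd.DataFrame
    per_variant: pd.DataFrame
    per_plate: pd.DataFrame | None = None


def call_rates(matrix: GenotypeMatrix,
               thresholds: QCThresholds = QCThresholds(),
               plate_map: dict[str, str] | None = None,
               dqc: dict[str, float] | None = None) -> CallRateReport:
    """Non-missing fraction per sample and per variant, with pass flags.

    Plate labels come from ``plate_map`` (sample id -> plate) or from the
    sample metadata; the plate rate is the mean call rate of samples passing
    the sample threshold, as plate acceptance is defined on passing samples.
    """
    called = matrix.calls != MISSING
    sample_rate = called.mean(axis=1) if matrix.n_variants else np.ones(matrix.n_samples)
    variant_rate = called.mean(axis=0) if matrix.n_samples else np.ones(matrix.n_variants)
    per_sample = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "call_rate": sample_rate,
        "pass_call_rate": sample_rate >= thresholds.sample_call_rate_min,
    })
    if dqc is not None:
        per_sample["dqc"] = [dqc.get(s, np.nan) for s in matrix.sample_ids]
        per_sample["pass_dqc"] = per_sample["dqc"] >= thresholds.dqc_min
        per_sample["pass"] = per_sample.pass_call_rate & per_sample.pass_dqc
    else:
        per_sample["pass"] = per_sample.pass_call_rate
    per_variant = pd.DataFrame({
        "variant_id": [v.id for v in matrix.variants],
        "call_rate": variant_rate,
        "pass": variant_rate >= thresholds.variant_call_rate_min,
    })
    plates = None
    labels = plate_map or {s.sample_id: s.plate for s in matrix.samples
                           if s.plate is not None}
    if labels:
        df = per_sample.assign(plate=[labels.get(s) for s in matrix.sample_ids])
        df = df[df.plate.notna()]
        passing = df[df["pass_call_rate"]]
        grouped = passing.groupby("plate")["call_rate"].agg(["mean", "size"])
        plates = pd.DataFrame({
            "plate": grouped.index,
            "mean_call_rate": grouped["mean"].to_numpy(),
            "n_passing_samples": grouped["size"].to_numpy(),
        }).reset_index(drop=True)
        plates["pass"] = plates.mean_call_rate >= thresholds.plate_mean_call_rate_min
    return CallRateReport(per_sample, per_variant, plates)


# ---------------------------------------------------------------------------
# sex inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SexCheckResult:
    sample_id: str
    x_het_rate: float
    inferred_sex: str  # male | female | ambiguous
    concordant_with_reported: bool


def infer_sex(matrix: GenotypeMatrix, male_max_het: float = 0.05,
              female_min_het: float = 0.20) -> list[SexCheckResult]:
    """Infer sex from X heterozygosity; flag discordance with reported sex.

    A rate below ``male_max_het`` calls male, above ``female_min_het`` calls
    female, anything between is ambiguous and never concordant.
    """
    x = matrix.take_variants(matrix.x_mask)
    if x.n_variants == 0:
        raise ValueError("no X-chromosome variants in matrix")
    results = []
    for i, s in enumerate(matrix.samples):
        col = x.calls[i]
        called = col != MISSING
        het_rate = float((col[called] == 1).mean()) if called.any() else np.nan
        if np.isnan(het_rate):
            inferred = "ambiguous"
        elif het_rate < male_max_het:
            inferred = "male"
        elif het_rate > female_min_het:
            inferred = "female"
        else:
            inferred = "ambiguous"
        concordant = inferred != "ambiguous" and inferred == s.reported_sex
        results.append(SexCheckResult(s.sample_id, het_rate, inferred, concordant))
    return results


# ---------------------------------------------------------------------------
# replicate reproducibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pairs_n: int


def replicate_bland_altman(values_a, values_b) -> BlandAltmanResult:
    """Paired-difference bias and 95% limits of agreement (a - b).

    Sample standard deviation (n-1 denominator); limits at bias +/- 1.96 sd.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd, a.size)


# ---------------------------------------------------------------------------
# cross-platform per-SNP concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceFilters:
    autosomal_only: bool = True
    biallelic_only: bool = True
    mac_min: int = 1
    mac_in: str = "b"  # which callset the MAC filter is evaluated in


def _minor_allele_counts(calls: np.ndarray) -> np.ndarray:
    valid = calls != MISSING
    alt = np.where(valid, calls, 0).sum(axis=0)
    total = 2 * valid.sum(axis=0)
    return np.minimum(alt, total - alt)


def per_snp_concordance(a: GenotypeMatrix, b: GenotypeMatrix,
                        filters: ConcordanceFilters = ConcordanceFilters()
                        ) -> pd.DataFrame:
    """Per-variant call concordance between two harmonized callsets.

    Inputs must already share samples (same order) and variants (same keys).
    Filters are applied as set intersection: autosomal, biallelic, minor
    allele count >= ``mac_min`` in the designated callset.  The denominator
    counts calls non-missing in both platforms; variants with no comparable
    calls carry NaN concordance and a flag rather than a division by zero.
    """
    if a.sample_ids != b.sample_ids:
        raise ValueError("callsets must share samples in identical order")
    if [(v.chromosome, v.position) for v in a.variants] != \
       [(v.chromosome, v.position) for v in b.variants]:
        raise ValueError("callsets must be harmonized to shared variants")
    if a.n_samples == 0:
        raise ValueError("no shared samples")
    keep = np.ones(a.n_variants, dtype=bool)
    if filters.autosomal_only:
        keep &= a.autosomal_mask
    if filters.biallelic_only:
        keep &= np.array([len(v.allele_pair) == 2 for v in a.variants])
    mac_source = b if filters.mac_in == "b" else a
    keep &= _minor_allele_counts(mac_source.calls) >= filters.mac_min
    idx = np.flatnonzero(keep)
    ga, gb = a.calls[:, idx], b.calls[:, idx]
    both = (ga != MISSING) & (gb != MISSING)
    n_comp = both.sum(axis=0)
    n_equal = ((ga == gb) & both).sum(axis=0)
    with np.errstate(invalid="ignore"):
        conc = np.where(n_comp > 0, n_equal / np.maximum(n_comp, 1), np.nan)
    return pd.DataFrame({
        "variant_id": [a.variants[j].id for j in idx],
        "chromosome": [a.variants[j].chromosome for j in idx],
        "position": [a.variants[j].position for j in idx],
        "n_comparable": n_comp,
        "n_equal": n_equal,
        "concordance": conc,
        "no_comparable_calls": n_comp == 0,
    })
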