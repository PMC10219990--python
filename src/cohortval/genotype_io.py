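"""Genotype containers and standard-format IO.

Hard calls live in a :class:`GenotypeMatrix`: a samples x variants int8
array counting copies of each variant's *counted* allele (by convention the
``alt_allele`` of its :class:`VariantKey`), with ``-1`` marking a missing
call.  Imputed dosages live in a :class:`DosageMatrix` with per-variant
imputation R².

Supported formats: PLINK text (.ped/.map), PLINK 1 binary (.bed/.bim/.fam,
SNP-major), and VCF 4.2 (GT hard calls, DS dosages with an R²-style INFO
field).  All readers accept gzip-compressed input.  In the binary PLINK
dialect the counted allele is written as A1, so the two-bit code ``00``
(homozygous A1) decodes to 2 copies.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

MISSING = -1
AUTOSOMES = tuple(str(c) for c in range(1, 23))
ALLOWED_CHROMOSOMES = AUTOSOMES + ("X",)
#: allele pairs that cannot be disambiguated across array strands
STRAND_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

_BED_MAGIC = b"\x6c\x1b\x01"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantKey:
    """Identity of one biallelic variant on the forward build coordinates."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.chromosome not in ALLOWED_CHROMOSOMES:
            raise ValueError(f"chromosome {self.chromosome!r} not in 1-22, X")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("alleles must be non-empty")

    @property
    def allele_pair(self) -> frozenset:
        return frozenset({self.ref_allele, self.alt_allele})

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES

    @property
    def is_strand_ambiguous(self) -> bool:
        return set(self.allele_pair) in STRAND_AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    reported_sex: str = "unknown"  # male | female | unknown
    reported_race: str = ""
    clinical_group: str = ""
    plate: str | None = None

    def __post_init__(self) -> None:
        if self.reported_sex not in ("male", "female", "unknown"):
            raise ValueError(f"reported_sex {self.reported_sex!r} invalid")


@dataclass
class GenotypeMatrix:
    """Hard-call matrix: counted-allele copies in {0,1,2}, -1 missing."""

    calls: np.ndarray
    variants: list[VariantKey]
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x variants)")
        n, m = self.calls.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples / {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2} or -1 (missing)")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        vids = [v.id for v in self.variants if v.id != "."]
        if len(set(vids)) != len(vids):
            dups = sorted({v for v in vids if vids.count(v) > 1})
            raise ValueError(f"duplicate variant ids: {dups}")

    # -- convenience -------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def variant_mask(self, predicate) -> np.ndarray:
        return np.fromiter((predicate(v) for v in self.variants),
                           dtype=bool, count=self.n_variants)

    @property
    def autosomal_mask(self) -> np.ndarray:
        return self.variant_mask(lambda v: v.is_autosomal)

    @property
    def x_mask(self) -> np.ndarray:
        return self.variant_mask(lambda v: v.chromosome == "X")

    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[:, index],
            [self.variants[i] for i in index],
            list(self.samples),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.calls[index, :],
            list(self.variants),
            [self.samples[i] for i in index],
        )

    def allele_frequencies(self) -> np.ndarray:
        """Counted-allele frequency per variant over non-missing calls (NaN if none)."""
        g = self.calls.astype(float)
        g[self.calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(g, axis=0) / 2.0


@dataclass
class DosageMatrix:
    """Imputed counted-allele dosages in [0,2] with per-variant imputation R²."""

    dosages: np.ndarray
    variants: list[VariantKey]
    sample_ids: list[str]
    imputation_r2: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.imputation_r2 = np.asarray(self.imputation_r2, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variants):
            raise ValueError("dosage dimensions inconsistent with metadata")
        if self.imputation_r2.shape != (m,):
            raise ValueError("imputation_r2 must have one entry per variant")
        finite = np.isfinite(self.dosages)
        if ((self.dosages[finite] < 0) | (self.dosages[finite] > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        fin_r2 = np.isfinite(self.imputation_r2)
        if ((self.imputation_r2[fin_r2] < 0) | (self.imputation_r2[fin_r2] > 1)).any():
            raise ValueError("imputation R2 must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def filter_r2(self, r2_min: float) -> "DosageMatrix":
        """Keep variants with imputation R² strictly above ``r2_min``."""
        if not np.isfinite(self.imputation_r2).all():
            missing = [self.variants[i].id
                       for i in np.flatnonzero(~np.isfinite(self.imputation_r2))]
            raise FormatError(
                f"R2 filter requested but R2 missing for variants {missing[:5]}"
            )
        keep = self.imputation_r2 > r2_min
        return DosageMatrix(
            self.dosages[:, keep],
            [v for v, k in zip(self.variants, keep) if k],
            list(self.sample_ids),
            self.imputation_r2[keep],
        )


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_PED_TO_SEX = {"1": "male", "2": "female"}


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def write_plink_text(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "wt") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position}\n")
    with open(prefix.with_suffix(".ped"), "wt") as fh:
        for i, s in enumerate(matrix.samples):
            fields = [s.sample_id, s.sample_id, "0", "0",
                      _SEX_TO_PED[s.reported_sex], "-9"]
            for j, v in enumerate(matrix.variants):
                g = matrix.calls[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    # counted allele is alt; g copies of alt, 2-g of ref
                    fields += [v.alt_allele] * int(g) + [v.ref_allele] * int(2 - g)
            fh.write(" ".join(fields) + "\n")


def read_plink_text(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    map_path, ped_path = prefix.with_suffix(".map"), prefix.with_suffix(".ped")
    sites: list[tuple[str, str, int]] = []
    with _open_text(map_path) as fh:
        for line in fh:
            chrom, vid, _cm, pos = line.split()
            sites.append((chrom, vid, int(pos)))
    rows, samples = [], []
    allele_sets: list[dict] = [dict() for _ in sites]
    raw: list[list[tuple[str, str]]] = []
    with _open_text(ped_path) as fh:
        for line in fh:
            parts = line.split()
            expected = 6 + 2 * len(sites)
            if len(parts) != expected:
                raise FormatError(
                    f"{ped_path}: expected {expected} fields, got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex, _pheno = parts[:6]
            samples.append(SampleMeta(iid, _PED_TO_SEX.get(sex, "unknown")))
            pairs = [(parts[6 + 2 * j], parts[7 + 2 * j]) for j in range(len(sites))]
            raw.append(pairs)
            for j, (a1, a2) in enumerate(pairs):
                for a in (a1, a2):
                    if a != "0":
                        allele_sets[j][a] = allele_sets[j].get(a, 0) + 1
    variants = []
    for (chrom, vid, pos), counts in zip(sites, allele_sets):
        alleles = sorted(counts, key=lambda a: (-counts[a], a))
        if len(alleles) > 2:
            raise FormatError(f"{ped_path}: variant {vid} has >2 alleles")
        if not alleles:
            alleles = ["N", "N"]
        elif len(alleles) == 1:
            alleles = [alleles[0], alleles[0]]
        # minor allele counted (alt); ties broken lexicographically above
        variants.append(VariantKey(chrom, pos, ref_allele=alleles[0],
                                   alt_allele=alleles[1], id=vid))
    calls = np.full((len(samples), len(sites)), MISSING, dtype=np.int8)
    for i, pairs in enumerate(raw):
        for j, (a1, a2) in enumerate(pairs):
            if a1 == "0" or a2 == "0":
                continue
            calls[i, j] = sum(a == variants[j].alt_allele for a in (a1, a2))
    return GenotypeMatrix(calls, variants, samples)


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam, SNP-major)
# ---------------------------------------------------------------------------

# two-bit code -> counted-allele copies (A1 = counted allele)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink_bed(matrix: GenotypeMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".bim"), "wt") as fh:
        for v in matrix.variants:
            fh.write(f"{v.chromosome}\t{v.id}\t0\t{v.position}\t"
                     f"{v.alt_allele}\t{v.ref_allele}\n")
    with open(prefix.with_suffix(".fam"), "wt") as fh:
        for s in matrix.samples:
            fh.write(f"{s.sample_id} {s.sample_id} 0 0 "
                     f"{_SEX_TO_PED[s.reported_sex]} -9\n")
    n = matrix.n_samples
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(matrix.n_variants):
            buf[:] = 0
            col = matrix.calls[:, j]
            for i in range(n):
                code = _BED_ENCODE[int(col[i])]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink_bed(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim, fam, bed = (prefix.with_suffix(s) for s in (".bim", ".fam", ".bed"))
    variants = []
    seen_ids: dict[str, int] = {}
    with _open_text(bim) as fh:
        for line in fh:
            chrom, vid, _cm, pos, a1, a2 = line.split()
            if vid != "." and vid in seen_ids:
                raise FormatError(f"{bim}: duplicate variant id {vid!r}")
            seen_ids[vid] = 1
            variants.append(VariantKey(chrom, int(pos), ref_allele=a2,
                                       alt_allele=a1, id=vid))
    samples = []
    with _open_text(fam) as fh:
        for line in fh:
            _fid, iid, _pat, _mat, sex, _pheno = line.split()
            samples.append(SampleMeta(iid, _PED_TO_SEX.get(sex, "unknown")))
    n, m = len(samples), len(variants)
    n_bytes = (n + 3) // 4
    with open(bed, "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise FormatError(f"{bed}: bad magic bytes (not SNP-major PLINK 1)")
        payload = fh.read()
    if len(payload) != m * n_bytes:
        raise FormatError(
            f"{bed}: payload is {len(payload)} bytes, expected {m * n_bytes} "
            f"for {n} samples x {m} variants"
        )
    data = np.frombuffer(payload, dtype=np.uint8).reshape(m, n_bytes)
    # expand each byte into four 2-bit codes, little-end first
    codes = np.stack([(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, n_bytes * 4)[:, :n]
    calls = _BED_DECODE[codes].T.copy()
    return GenotypeMatrix(calls, variants, samples)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              dosages: np.ndarray | None = None,
              r2: np.ndarray | None = None) -> None:
    """Write hard calls (and optionally DS dosages + R2 INFO) as VCF 4.2.

    Counted allele is written as ALT, so the GT allele count equals the
    stored call and DS is the counted-allele dosage.
    """
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if dosages is not None:
        lines.append('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Imputed dosage">')
    if r2 is not None:
        lines.append('##INFO=<ID=R2,Number=1,Type=Float,'
                     'Description="Imputation quality">')
    for c in dict.fromkeys(v.chromosome for v in matrix.variants):
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fmt = "GT:DS" if dosages is not None else "GT"
    order = sorted(range(matrix.n_variants),
                   key=lambda j: (ALLOWED_CHROMOSOMES.index(
                       matrix.variants[j].chromosome),
                       matrix.variants[j].position))
    for j in order:
        v = matrix.variants[j]
        info = f"R2={r2[j]:.6g}" if r2 is not None else "."
        cells = []
        for i in range(matrix.n_samples):
            cell = gt_map[int(matrix.calls[i, j])]
            if dosages is not None:
                d = dosages[i, j]
                cell += ":." if not np.isfinite(d) else f":{d:.4g}"
            cells.append(cell)
        lines.append(f"{v.chromosome}\t{v.position}\t{v.id}\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\t.\t{info}\t{fmt}\t" + "\t".join(cells))
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf_dosages(path: str | Path, r2_field: str = "R2",
                     r2_min: float | None = None) -> DosageMatrix:
    """Extract per-sample dosages (DS; GT hard calls as fallback) plus R².

    ``r2_min`` applies a strict ``R2 > r2_min`` variant filter; requesting it
    when the R² field is absent for any variant is an error rather than a
    silent pass-through.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants, dose_cols, r2_vals = [], [], []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else rec.REF
        variants.append(VariantKey(rec.CHROM.removeprefix("chr"), rec.POS,
                                   ref_allele=rec.REF, alt_allele=alt,
                                   id=rec.ID or "."))
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(sample_ids))
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
            col = np.asarray(
                [np.nan if t == 2 else (2.0 if t == 3 else float(t))
                 for t in rec.gt_types], dtype=float)
        dose_cols.append(col)
        r2 = rec.INFO.get(r2_field)
        r2_vals.append(float(r2) if r2 is not None else np.nan)
    dosages = (np.column_stack(dose_cols) if dose_cols
               else np.empty((len(sample_ids), 0)))
    dm = DosageMatrix(dosages, variants, sample_ids,
                      np.asarray(r2_vals, dtype=float))
    if r2_min is not None:
        dm = dm.filter_r2(r2_min)
    return dm


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizationReport:
    n_shared: int = 0
    n_flipped: int = 0
    ambiguous_dropped: list[VariantKey] = field(default_factory=list)
    irreconcilable_dropped: list[tuple[VariantKey, VariantKey]] = field(
        default_factory=list)

    @property
    def n_ambiguous(self) -> int:
        return len(self.ambiguous_dropped)


def intersect_and_harmonize(
    a: GenotypeMatrix, b: GenotypeMatrix
) -> tuple[GenotypeMatrix, GenotypeMatrix, HarmonizationReport]:
    """Restrict two callsets to shared variants with aligned counted alleles.

    Variant identity is (chromosome, position, unordered allele pair).  Calls
    in ``b`` are flipped ``2 <-> 0`` where its counted allele is the other
    member of the pair.  Strand-ambiguous SNPs (A/T, C/G) and shared sites
    with irreconcilable allele pairs are dropped and reported, never fatal.
    """
    report = HarmonizationReport()
    index_b = {}
    for j, v in enumerate(b.variants):
        index_b.setdefault((v.chromosome, v.position), []).append(j)
    keep_a, keep_b, flip_b = [], [], []
    for i, va in enumerate(a.variants):
        hits = index_b.get((va.chromosome, va.position), [])
        if len(hits) != 1:
            continue
        j = hits[0]
        vb = b.variants[j]
        if va.allele_pair != vb.allele_pair:
            report.irreconcilable_dropped.append((va, vb))
            continue
        if va.is_strand_ambiguous:
            report.ambiguous_dropped.append(va)
            continue
        keep_a.append(i)
        keep_b.append(j)
        flip_b.append(va.alt_allele != vb.alt_allele)
    if not keep_a:
        warnings.warn("no shared variants after harmonization")
    out_a = a.take_variants(np.asarray(keep_a, dtype=int))
    out_b = b.take_variants(np.asarray(keep_b, dtype=int))
    flip = np.asarray(flip_b, dtype=bool)
    if flip.any():
        cols = out_b.calls[:, flip]
        flipped = np.where(cols == MISSING, MISSING, 2 - cols).astype(np.int8)
        out_b.calls[:, flip] = flipped
        new_variants = list(out_b.variants)
        for j in np.flatnonzero(flip):
            v = new_variants[j]
            new_variants[j] = replace(v, ref_allele=v.alt_allele,
                                      alt_allele=v.ref_allele)
        out_b.variants = new_variants
    report.n_shared = len(keep_a)
    report.n_flipped = int(flip.sum())
    return out_a, out_b, report
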