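"""Variant filtering and per-site Weir-Cockerham F_ST for diagnostic SNPs.

Multi-sample variant calls are classified (biallelic SNP / indel /
multiallelic SNP), passed through stringent filters (biallelic, no missing
genotypes, minor allele frequency >= 5%, site quality > 500 by default),
and the surviving sites are scored with the Weir & Cockerham (1984)
variance-components estimator of F_ST, treating species as populations.

For a biallelic site with r populations, per-population sample sizes n_i
(diploid individuals with called genotypes), allele frequencies p_i and
observed heterozygote proportions h_i, the estimator partitions allelic
variance into

* a — among populations,
* b — among individuals within populations,
* c — within individuals (observed heterozygosity),

using the unequal-sample-size weights n_bar (average), n_c (variance-
corrected average) and the weighted means p_bar, s^2 and h_bar.  The
per-site estimate is theta = a / (a + b + c), undefined when the
denominator is zero (monomorphic sites).  Negative estimates are possible
for weakly differentiated sites and are reported as computed, never
clamped.  Sites where every population is fixed, but not all for the same
allele, yield theta = 1; such fixed differences are the natural candidates
for species-diagnostic assays.

Populations represented by fewer called genotypes than a configurable
minimum (default 2) are excluded from the estimate with a logged warning:
a single-specimen "population" contributes no within-population variance
and inflates the count of theta = 1 sites.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "VariantRecord",
    "FstResult",
    "FilterReport",
    "VariantClassCounts",
    "classify_variants",
    "minor_allele_frequency",
    "stringent_filter",
    "weir_cockerham_fst",
    "fst_scan",
    "fst_distribution",
    "FstSummary",
    "candidate_diagnostic_snps",
    "read_vcf",
    "read_population_map",
    "write_fst_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.05      # retained iff MAF >= this
DEFAULT_QUAL_MIN = 500.0    # retained iff QUAL > this (strict)
DEFAULT_MIN_POP_SIZE = 2    # populations with fewer called genotypes are excluded
FIXED_TOL = 1e-9            # |theta - 1| tolerance when counting fixed sites

Genotype = "tuple[int, int] | None"


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site with per-specimen diploid genotype calls.

    ``qual`` is the phred-scaled site quality, -10*log10(P(call is wrong)).
    ``genotypes`` holds allele-index pairs aligned with the sample order, or
    ``None`` for a missing call (./.).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float
    genotypes: tuple

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.chrom}:{self.pos}: position must be >= 1")
        if not self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: no alternate allele")
        if not self.ref or any(not a for a in self.alts):
            raise ValueError(f"{self.chrom}:{self.pos}: empty allele")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            if gt is None:
                continue
            if any(not 0 <= a < n_alleles for a in gt):
                raise ValueError(
                    f"{self.chrom}:{self.pos}: genotype allele index out of range"
                )

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == len(self.alts[0])
            and len(self.ref) == 1
        )

    @property
    def has_missing(self) -> bool:
        return any(gt is None for gt in self.genotypes)


@dataclass(frozen=True)
class VariantClassCounts:
    biallelic_snp: int
    indel: int
    multiallelic_snp: int


@dataclass(frozen=True)
class FilterReport:
    """Independent per-filter failure counts over one record set."""

    n_input: int
    n_retained: int
    fail_not_biallelic: int
    fail_missing: int
    fail_maf: int
    fail_qual: int


@dataclass(frozen=True)
class FstResult:
    """Per-site Weir-Cockerham variance components and theta.

    ``theta`` is ``None`` exactly when a + b + c = 0 (no allelic variance to
    partition, e.g. a monomorphic site).
    """

    chrom: str
    pos: int
    a: float
    b: float
    c: float
    theta: float | None

    @property
    def site_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_variants(records: Iterable[VariantRecord]) -> VariantClassCounts:
    """Count records as biallelic SNPs, indels, or multiallelic SNPs.

    A site with any length-changing allele is an indel; substitution-only
    sites are biallelic or multiallelic SNPs by alternate-allele count.
    """
    bi = indel = multi = 0
    for rec in records:
        if any(len(alt) != len(rec.ref) for alt in rec.alts):
            indel += 1
        elif len(rec.alts) == 1:
            bi += 1
        else:
            multi += 1
    return VariantClassCounts(biallelic_snp=bi, indel=indel, multiallelic_snp=multi)


def minor_allele_frequency(genotypes: Sequence) -> float:
    """MAF over called alleles only; missing genotypes leave the denominator.

    For a biallelic site, returns min(p, 1-p) where p is the frequency of
    either allele among called diploid genotypes.
    """
    alt = 0
    total = 0
    for gt in genotypes:
        if gt is None:
            continue
        alt += sum(1 for a in gt if a != 0)
        total += len(gt)
    if total == 0:
        raise ValueError("all genotypes missing")
    p = alt / total
    return min(p, 1.0 - p)


def stringent_filter(
    records: Sequence[VariantRecord],
    maf_min: float = DEFAULT_MAF_MIN,
    qual_min: float = DEFAULT_QUAL_MIN,
    return_report: bool = False,
):
    """Retain biallelic SNPs with no missing genotypes, MAF >= ``maf_min``
    and QUAL > ``qual_min``; input order is preserved.

    The MAF bound is inclusive and the quality bound strict; both are
    configurable.  With ``return_report`` the independent per-filter failure
    counts are returned alongside the retained records.
    """
    retained: list[VariantRecord] = []
    fail_bi = fail_miss = fail_maf = fail_qual = 0
    for rec in records:
        ok = True
        if not rec.is_biallelic_snp:
            fail_bi += 1
            ok = False
        if rec.has_missing:
            fail_miss += 1
            ok = False
        else:
            try:
                if minor_allele_frequency(rec.genotypes) < maf_min:
                    fail_maf += 1
                    ok = False
            except ValueError:
                fail_miss += 0  # unreachable: has_missing covers all-missing
                ok = False
        if not rec.qual > qual_min:
            fail_qual += 1
            ok = False
        if ok:
            retained.append(rec)
    if return_report:
        report = FilterReport(
            n_input=len(records),
            n_retained=len(retained),
            fail_not_biallelic=fail_bi,
            fail_missing=fail_miss,
            fail_maf=fail_maf,
            fail_qual=fail_qual,
        )
        return retained, report
    return retained


def weir_cockerham_fst(
    record: VariantRecord,
    populations: Sequence[str],
    min_pop_size: int = DEFAULT_MIN_POP_SIZE,
) -> FstResult:
    """Per-site Weir-Cockerham (1984) theta for a biallelic site.

    ``populations`` assigns each sample (aligned with ``record.genotypes``)
    to a population.  Populations with fewer than ``min_pop_size`` called
    genotypes at the site are excluded with a warning.  Requires at least
    two populations in the assignment and at least two surviving the
    exclusion.
    """
    if len(populations) != len(record.genotypes):
        raise ValueError("population assignment length != number of genotypes")
    if len(set(populations)) < 2:
        raise ValueError("Weir-Cockerham F_ST needs >= 2 populations")
    if not record.is_biallelic_snp:
        raise ValueError(f"{record.chrom}:{record.pos}: not a biallelic SNP")

    # Per-population called sample size, alt-allele frequency, het proportion.
    stats_by_pop: dict[str, tuple[int, float, float]] = {}
    for pop in sorted(set(populations)):
        gts = [
            gt
            for gt, p in zip(record.genotypes, populations)
            if p == pop and gt is not None
        ]
        n_i = len(gts)
        if n_i < min_pop_size:
            logger.warning(
                "site %s:%d: population %r has %d called genotype(s) "
                "(< %d); excluded from F_ST",
                record.chrom, record.pos, pop, n_i, min_pop_size,
            )
            continue
        p_i = sum(sum(1 for a in gt if a != 0) for gt in gts) / (2 * n_i)
        h_i = sum(1 for gt in gts if gt[0] != gt[1]) / n_i
        stats_by_pop[pop] = (n_i, p_i, h_i)

    if len(stats_by_pop) < 2:
        raise ValueError(
            f"site {record.chrom}:{record.pos}: fewer than two populations "
            f"with >= {min_pop_size} called genotypes"
        )

    n = np.array([v[0] for v in stats_by_pop.values()], dtype=float)
    p = np.array([v[1] for v in stats_by_pop.values()], dtype=float)
    h = np.array([v[2] for v in stats_by_pop.values()], dtype=float)
    r = n.size

    n_bar = n.mean()
    n_c = (r * n_bar - (n ** 2).sum() / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum() / (r * n_bar)
    s2 = (n * (p - p_bar) ** 2).sum() / ((r - 1) * n_bar)
    h_bar = (n * h).sum() / (r * n_bar)

    if n_bar <= 1:
        raise ValueError("average sample size must exceed 1 diploid individual")

    a = (n_bar / n_c) * (
        s2
        - (1.0 / (n_bar - 1.0))
        * (p_bar * (1.0 - p_bar) - ((r - 1.0) / r) * s2 - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1.0)) * (
        p_bar * (1.0 - p_bar)
        - ((r - 1.0) / r) * s2
        - ((2.0 * n_bar - 1.0) / (4.0 * n_bar)) * h_bar
    )
    c = h_bar / 2.0

    denom = a + b + c
    theta = None if denom == 0.0 else a / denom
    return FstResult(chrom=record.chrom, pos=record.pos, a=a, b=b, c=c, theta=theta)


def fst_scan(
    records: Iterable[VariantRecord],
    populations: Sequence[str],
    min_pop_size: int = DEFAULT_MIN_POP_SIZE,
) -> list[FstResult]:
    """Per-site theta over a record set (biallelic sites only)."""
    return [
        weir_cockerham_fst(rec, populations, min_pop_size=min_pop_size)
        for rec in records
        if rec.is_biallelic_snp
    ]


@dataclass(frozen=True)
class FstSummary:
    mean_theta: float
    n_defined: int
    n_undefined: int
    n_ge_half: int
    n_fixed: int
    bin_edges: tuple
    bin_counts: tuple


def fst_distribution(results: Sequence[FstResult], bin_width: float = 0.05) -> FstSummary:
    """Summarise defined theta values: mean, histogram, counts at >= 0.5 and = 1.

    Undefined thetas are excluded from every summary and reported as a
    separate count.  Theta = 1 is tested with a 1e-9 tolerance.  Histogram
    bins clip at [-0.05, 1] (negative estimates land in the first bin).
    """
    defined = [r.theta for r in results if r.theta is not None]
    n_undef = len(results) - len(defined)
    if not defined:
        raise ValueError("no defined theta values")
    thetas = np.asarray(defined)
    edges = np.arange(-0.05, 1.0 + bin_width / 2, bin_width)
    counts, edges = np.histogram(np.clip(thetas, -0.05, 1.0), bins=edges)
    return FstSummary(
        mean_theta=float(thetas.mean()),
        n_defined=len(defined),
        n_undefined=n_undef,
        n_ge_half=int((thetas >= 0.5).sum()),
        n_fixed=int((np.abs(thetas - 1.0) <= FIXED_TOL).sum()),
        bin_edges=tuple(float(e) for e in edges),
        bin_counts=tuple(int(c) for c in counts),
    )


def candidate_diagnostic_snps(
    results: Sequence[FstResult], threshold: float = 0.5
) -> list[FstResult]:
    """Sites with defined theta >= threshold, sorted by theta descending
    then site key."""
    hits = [r for r in results if r.theta is not None and r.theta >= threshold]
    return sorted(hits, key=lambda r: (-r.theta, r.site_key))


# ---------------------------------------------------------------------------
# VCF and population-map I/O
# ---------------------------------------------------------------------------

def read_vcf(path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF (v4.2, GT + QUAL required) into VariantRecords.

    Returns (records, sample order).  Missing genotypes (./.) become None.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        gts = []
        for g in v.genotypes:
            a0, a1 = g[0], g[1]
            gts.append(None if a0 < 0 or a1 < 0 else (a0, a1))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=float(v.QUAL) if v.QUAL is not None else math.nan,
                genotypes=tuple(gts),
            )
        )
    return records, samples


def read_population_map(path) -> dict[str, str]:
    """Read a two-column TSV (specimen, population) into a dict."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"population map line lacks two columns: {line!r}")
            out[fields[0]] = fields[1]
    return out


def write_fst_table(results: Sequence[FstResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\ta\tb\tc\ttheta\n")
        for r in results:
            theta = "NA" if r.theta is None else f"{r.theta:.6f}"
            fh.write(f"{r.chrom}\t{r.pos}\t{r.a:.6f}\t{r.b:.6f}\t{r.c:.6f}\t{theta}\n")
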