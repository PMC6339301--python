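"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the data shapes a target-capture study consumes —
transcriptome FASTA, covstats-style coverage tables, multi-sample VCFs,
per-base organelle pileups — with the structure the analysis is meant to
recover planted explicitly:

* transcripts carry a true genomic copy number, and simulated genomic-read
  coverage scales with it (negative-binomial counts around
  rate * length/1000 * copy_number), so RPK ranking can be scored against
  truth;
* capture experiments draw per-read categories (on-target / organelle /
  off-target) with a per-group enrichment bias, emulating the drop in
  capture efficiency for taxa distant from the probe-design species;
* genotype panels plant per-species allele frequencies per site, with
  "fixed" sites fully differentiated between species (the theta = 1 class),
  "shared" sites polymorphic at a common frequency, and "private" sites
  polymorphic in a single species;
* organelle pileups draw per-position depths around a given profile and
  plant substitutions, recording the truth consensus (reference with
  variants applied, N where simulated depth < 2).

Randomness: every generator takes a seed; a master seed fans out to
per-operation child seeds by stable hashing of the operation name, so runs
are reproducible while streams stay independent.  Fixed seed implies
byte-identical output.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .organelle_consensus import BASES, Pileup
from .target_selection import CoverageRecord, MIN_TARGET_LENGTH, TargetSet

__all__ = [
    "Transcript",
    "TranscriptomeFixture",
    "SpecimenSpec",
    "PanelSpec",
    "SiteTruth",
    "GenotypeTruth",
    "ReadTally",
    "CaptureSimResult",
    "VcfSimResult",
    "OrganelleSimResult",
    "child_seed",
    "make_transcriptome",
    "simulate_genomic_coverage",
    "simulate_capture_experiment",
    "read_labels_from_tally",
    "make_genotype_truth",
    "simulate_genotype_vcf",
    "simulate_organelle_pileup",
    "write_transcriptome_fasta",
]

IN_GENUS = "in_genus"
OUT_GENUS = "out_genus"

FIXED = "fixed"
SHARED = "shared"
PRIVATE = "private"

DEFAULT_READS_PER_KBP_PER_COPY = 0.8  # matches the selected-target mean RPK
DEFAULT_DISPERSION = 5.0  # negative-binomial size; heavy-tailed mapping counts
DEFAULT_QUAL_PARAMS = {
    "low_rate": 0.2,
    "low_range": (50.0, 500.0),
    "high_range": (501.0, 3000.0),
}


def child_seed(master_seed: int, operation: str) -> int:
    """Derive a per-operation seed from a master seed by stable hashing."""
    digest = hashlib.sha256(f"{master_seed}:{operation}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# Transcriptome with planted copy numbers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    sequence: str
    true_copy_number: int


@dataclass(frozen=True)
class TranscriptomeFixture:
    transcripts: tuple[Transcript, ...]
    seed: int

    def __post_init__(self) -> None:
        ids = [t.transcript_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids must be unique")
        for t in self.transcripts:
            if len(t.sequence) < MIN_TARGET_LENGTH:
                raise ValueError(
                    f"{t.transcript_id}: length {len(t.sequence)} below the "
                    f"{MIN_TARGET_LENGTH}-bp cutoff"
                )
            if t.true_copy_number < 1:
                raise ValueError(f"{t.transcript_id}: copy number must be >= 1")

    def sequences(self) -> dict[str, str]:
        return {t.transcript_id: t.sequence for t in self.transcripts}

    def copy_numbers(self) -> dict[str, int]:
        return {t.transcript_id: t.true_copy_number for t in self.transcripts}


def make_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int] = (200, 1000),
    copy_number_weights: Mapping[int, float] | None = None,
    seed: int = 0,
) -> TranscriptomeFixture:
    """Generate random transcripts with planted genomic copy numbers.

    Lengths are uniform over ``length_range`` (inclusive; minimum 200 bp),
    and each transcript's copy number is drawn from the categorical
    distribution given by ``copy_number_weights`` (default: all single
    copy).  Deterministic for a fixed seed.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be >= 1")
    lo, hi = length_range
    if lo < MIN_TARGET_LENGTH:
        raise ValueError(f"minimum transcript length is {MIN_TARGET_LENGTH} bp")
    if hi < lo:
        raise ValueError("length_range max below min")
    if copy_number_weights is None:
        copy_number_weights = {1: 1.0}
    copies = np.array(sorted(copy_number_weights), dtype=int)
    weights = np.array([copy_number_weights[c] for c in copies], dtype=float)
    if (weights < 0).any() or weights.sum() <= 0:
        raise ValueError("copy_number_weights must be non-negative and sum > 0")
    weights = weights / weights.sum()

    rng = np.random.default_rng(child_seed(seed, "make_transcriptome"))
    lengths = rng.integers(lo, hi + 1, size=n_transcripts)
    copy_draws = rng.choice(copies, size=n_transcripts, p=weights)
    bases = np.array(list(BASES))
    width = max(5, len(str(n_transcripts)))
    transcripts = tuple(
        Transcript(
            transcript_id=f"tx{i:0{width}d}",
            sequence="".join(rng.choice(bases, size=int(lengths[i]))),
            true_copy_number=int(copy_draws[i]),
        )
        for i in range(n_transcripts)
    )
    return TranscriptomeFixture(transcripts=transcripts, seed=seed)


def simulate_genomic_coverage(
    fixture: TranscriptomeFixture,
    reads_per_kbp_per_copy: float = DEFAULT_READS_PER_KBP_PER_COPY,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    subread_length: int = 50,
) -> list[CoverageRecord]:
    """Simulate genomic-read mapping counts against a transcriptome.

    The expected mapped-read count for transcript t is
    ``rate * (length_t / 1000) * copy_number_t``; counts are
    negative-binomial with the given dispersion (Poisson as
    dispersion -> infinity).  Covered bases follow the random-coverage
    saturation curve ``L * (1 - exp(-reads * subread_length / L))``.
    """
    if reads_per_kbp_per_copy <= 0:
        raise ValueError("reads_per_kbp_per_copy must be > 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    rng = np.random.default_rng(child_seed(seed, "simulate_genomic_coverage"))
    records: list[CoverageRecord] = []
    for t in fixture.transcripts:
        length = len(t.sequence)
        mu = reads_per_kbp_per_copy * (length / 1000.0) * t.true_copy_number
        if math.isinf(dispersion):
            reads = int(rng.poisson(mu))
        else:
            p = dispersion / (dispersion + mu)
            reads = int(rng.negative_binomial(dispersion, p)) if mu > 0 else 0
        plus = int(rng.binomial(reads, 0.5))
        if reads > 0:
            covered = int(round(length * (1.0 - math.exp(-reads * subread_length / length))))
            covered = min(length, max(covered, min(subread_length, length)))
        else:
            covered = 0
        records.append(
            CoverageRecord(
                target_id=t.transcript_id,
                target_length=length,
                reads_plus=plus,
                reads_minus=reads - plus,
                covered_bases=covered,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Capture experiment with per-group enrichment bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecimenSpec:
    specimen_id: str
    species_id: str
    genus_group: str  # IN_GENUS or OUT_GENUS

    def __post_init__(self) -> None:
        if self.genus_group not in (IN_GENUS, OUT_GENUS):
            raise ValueError(f"genus_group must be {IN_GENUS!r} or {OUT_GENUS!r}")


@dataclass(frozen=True)
class PanelSpec:
    """A capture diversity panel: specimens, library size, and biases.

    ``enrichment_bias`` maps genus group to the per-read capture
    probability multiplier; the out-genus multiplier may not exceed the
    in-genus one (probes designed within the genus cannot work better on
    distant relatives).
    """

    specimens: tuple[SpecimenSpec, ...]
    library_size: int
    organelle_fraction: float
    enrichment_bias: Mapping[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen ids must be unique")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not 0.0 <= self.organelle_fraction <= 1.0:
            raise ValueError("organelle_fraction must be in [0, 1]")
        for group, mult in self.enrichment_bias.items():
            if not 0.0 < mult <= 1.0:
                raise ValueError(f"enrichment bias for {group!r} must be in (0, 1]")
        bias_in = self.enrichment_bias.get(IN_GENUS)
        bias_out = self.enrichment_bias.get(OUT_GENUS)
        if bias_in is not None and bias_out is not None and bias_out > bias_in:
            raise ValueError("out-genus bias may not exceed in-genus bias")


@dataclass(frozen=True)
class ReadTally:
    """Per-specimen read-category tallies; categories sum to the library size."""

    total: int
    on_target: int
    organelle: int
    other: int

    def __post_init__(self) -> None:
        if self.on_target + self.organelle + self.other != self.total:
            raise ValueError("category tallies must sum to total")


@dataclass(frozen=True)
class CaptureSimResult:
    coverage_by_specimen: dict[str, list[CoverageRecord]]
    tallies: dict[str, ReadTally]
    species_of: dict[str, str]


def simulate_capture_experiment(
    targets: TargetSet,
    panel: PanelSpec,
    read_length: int = 101,
) -> CaptureSimResult:
    """Simulate enrichment outcomes for every specimen of a panel.

    Each read falls into the organelle category with probability
    ``organelle_fraction``, otherwise on-target with probability equal to
    the specimen group's enrichment bias, otherwise off-target.  On-target
    reads are spread over targets proportionally to target length.
    """
    if len(targets) == 0:
        raise ValueError("empty target set")
    lengths = targets.lengths()
    tids = list(targets.target_ids)
    lens = np.array([lengths[t] for t in tids], dtype=float)
    target_p = lens / lens.sum()

    rng = np.random.default_rng(child_seed(panel.seed, "simulate_capture_experiment"))
    coverage: dict[str, list[CoverageRecord]] = {}
    tallies: dict[str, ReadTally] = {}
    for spec in panel.specimens:
        bias = panel.enrichment_bias[spec.genus_group]
        p_org = panel.organelle_fraction
        p_on = (1.0 - p_org) * bias
        p_off = 1.0 - p_org - p_on
        n_org, n_on, n_off = rng.multinomial(
            panel.library_size, [p_org, p_on, p_off]
        )
        tallies[spec.specimen_id] = ReadTally(
            total=panel.library_size,
            on_target=int(n_on),
            organelle=int(n_org),
            other=int(n_off),
        )
        per_target = rng.multinomial(int(n_on), target_p)
        records = []
        for tid, length, reads in zip(tids, lens.astype(int), per_target):
            reads = int(reads)
            plus = int(rng.binomial(reads, 0.5))
            if reads > 0:
                covered = int(
                    round(length * (1.0 - math.exp(-reads * read_length / length)))
                )
                covered = min(int(length), max(covered, min(read_length, int(length))))
            else:
                covered = 0
            records.append(
                CoverageRecord(
                    target_id=tid,
                    target_length=int(length),
                    reads_plus=plus,
                    reads_minus=reads - plus,
                    covered_bases=covered,
                )
            )
        coverage[spec.specimen_id] = records
    species_of = {s.specimen_id: s.species_id for s in panel.specimens}
    return CaptureSimResult(
        coverage_by_specimen=coverage, tallies=tallies, species_of=species_of
    )


def read_labels_from_tally(tally: ReadTally) -> np.ndarray:
    """Expand a category tally into one label per read."""
    return np.concatenate(
        [
            np.repeat("on_target", tally.on_target),
            np.repeat("organelle", tally.organelle),
            np.repeat("other", tally.other),
        ]
    )


# ---------------------------------------------------------------------------
# Genotype panels with planted per-species allele frequencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteTruth:
    site_id: str
    allele_freqs: Mapping[str, float]  # species -> planted ALT frequency
    fst_class: str  # FIXED / SHARED / PRIVATE

    def __post_init__(self) -> None:
        for sp, p in self.allele_freqs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.site_id}: allele freq {p} for {sp} outside [0,1]")
        if self.fst_class == FIXED:
            freqs = set(self.allele_freqs.values())
            if not (0.0 in freqs and 1.0 in freqs and freqs <= {0.0, 1.0}):
                raise ValueError(
                    f"{self.site_id}: fixed sites need every species at freq 0 or 1, "
                    "with both present"
                )


@dataclass(frozen=True)
class GenotypeTruth:
    sites: tuple[SiteTruth, ...]
    missing_rate: float = 0.0
    qual_params: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_QUAL_PARAMS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site ids must be unique")


def make_genotype_truth(
    n_sites: int,
    species: Sequence[str],
    fixed_fraction: float = 0.2,
    private_fraction: float = 0.2,
    missing_rate: float = 0.0,
    qual_params: Mapping[str, object] | None = None,
    seed: int = 0,
) -> GenotypeTruth:
    """Plant per-species allele frequencies for a SNP panel.

    The first ``fixed_fraction`` of sites are fully fixed differences
    (every species at ALT frequency 0 or 1, both classes present), the next
    ``private_fraction`` are polymorphic in one species only, and the rest
    share a common intermediate frequency across species.
    """
    if len(species) < 2:
        raise ValueError("need >= 2 species")
    if fixed_fraction + private_fraction > 1.0:
        raise ValueError("class fractions exceed 1")
    rng = np.random.default_rng(child_seed(seed, "make_genotype_truth"))
    n_fixed = int(round(n_sites * fixed_fraction))
    n_private = int(round(n_sites * private_fraction))
    sites: list[SiteTruth] = []
    for i in range(n_sites):
        sid = f"site{i:05d}"
        if i < n_fixed:
            # at least one species on each side of the fixed difference
            assign = rng.integers(0, 2, size=len(species))
            if assign.min() == assign.max():
                assign[rng.integers(0, len(species))] = 1 - assign[0]
            freqs = {sp: float(a) for sp, a in zip(species, assign)}
            cls = FIXED
        elif i < n_fixed + n_private:
            owner = species[int(rng.integers(0, len(species)))]
            p = float(rng.uniform(0.3, 0.7))
            freqs = {sp: (p if sp == owner else 0.0) for sp in species}
            cls = PRIVATE
        else:
            p = float(rng.uniform(0.2, 0.8))
            freqs = {sp: p for sp in species}
            cls = SHARED
        sites.append(SiteTruth(site_id=sid, allele_freqs=freqs, fst_class=cls))
    return GenotypeTruth(
        sites=tuple(sites),
        missing_rate=missing_rate,
        qual_params=dict(qual_params or DEFAULT_QUAL_PARAMS),
    )


@dataclass(frozen=True)
class VcfSimResult:
    vcf_text: str
    samples: tuple[str, ...]
    sample_species: dict[str, str]
    truth: tuple[SiteTruth, ...]


def _realized_fixed_difference(gt_matrix: list, pops: list) -> bool:
    """True when every population is monomorphic but not all identical."""
    pop_alleles: dict[str, set[int]] = {}
    for gt, pop in zip(gt_matrix, pops):
        if gt is None:
            continue
        pop_alleles.setdefault(pop, set()).update(gt)
    if any(len(alleles) != 1 for alleles in pop_alleles.values()):
        return False
    distinct = {next(iter(a)) for a in pop_alleles.values()}
    return len(distinct) > 1


def simulate_genotype_vcf(
    truth: GenotypeTruth,
    specimens_per_species: Mapping[str, int],
    seed: int = 0,
) -> VcfSimResult:
    """Draw a diploid multi-sample VCF from planted allele frequencies.

    Genotypes are Hardy-Weinberg draws at each species' planted ALT
    frequency; missingness and site quality are injected per the truth
    parameters.  Sites planted as shared/private are redrawn (bounded) if
    sampling noise happens to realise a complete fixed difference, so the
    planted class labels stay truthful for downstream scoring.  Output is
    VCF v4.2 text with GT fields and ./. missing codes, plus the truth
    sidecar.
    """
    if len(specimens_per_species) < 2:
        raise ValueError("need >= 2 species")
    if any(n < 1 for n in specimens_per_species.values()):
        raise ValueError("need >= 1 specimen per species")
    for site in truth.sites:
        missing_sp = set(specimens_per_species) - set(site.allele_freqs)
        if missing_sp:
            raise ValueError(f"{site.site_id}: no planted frequency for {sorted(missing_sp)}")

    rng = np.random.default_rng(child_seed(seed, "simulate_genotype_vcf"))
    samples: list[str] = []
    sample_species: dict[str, str] = {}
    for sp in sorted(specimens_per_species):
        for k in range(specimens_per_species[sp]):
            sid = f"{sp}_{k + 1}"
            samples.append(sid)
            sample_species[sid] = sp
    pops = [sample_species[s] for s in samples]

    qp = truth.qual_params
    low_rate = float(qp.get("low_rate", 0.0))
    low_lo, low_hi = qp.get("low_range", (50.0, 500.0))
    high_lo, high_hi = qp.get("high_range", (501.0, 3000.0))

    lines = [
        "##fileformat=VCFv4.2",
        "##source=capkit-synthetic",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines.extend(f"##contig=<ID={site.site_id},length=1000>" for site in truth.sites)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for i, site in enumerate(truth.sites):
        for attempt in range(100):
            gts: list = []
            for s in samples:
                if truth.missing_rate > 0 and rng.random() < truth.missing_rate:
                    gts.append(None)
                    continue
                p = site.allele_freqs[sample_species[s]]
                alleles = rng.binomial(1, p, size=2)
                gts.append((int(alleles.min()), int(alleles.max())))
            if site.fst_class == FIXED or not _realized_fixed_difference(gts, pops):
                break
        qual = (
            rng.uniform(low_lo, low_hi)
            if rng.random() < low_rate
            else rng.uniform(high_lo, high_hi)
        )
        chrom = site.site_id
        pos = 1 + (i % 997)
        gt_fields = ["./." if g is None else f"{g[0]}/{g[1]}" for g in gts]
        lines.append(
            f"{chrom}\t{pos}\t{site.site_id}\tA\tG\t{qual:.1f}\t.\t.\tGT\t"
            + "\t".join(gt_fields)
        )
    return VcfSimResult(
        vcf_text="\n".join(lines) + "\n",
        samples=tuple(samples),
        sample_species=sample_species,
        truth=truth.sites,
    )


# ---------------------------------------------------------------------------
# Organelle pileups with planted substitutions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganelleSimResult:
    pileup: Pileup
    truth_consensus: str


def simulate_organelle_pileup(
    reference: str,
    depth_profile,
    variants: Sequence[tuple[int, str]] = (),
    seed: int = 0,
    error_rate: float = 0.0,
) -> OrganelleSimResult:
    """Simulate a per-base pileup over an organelle reference.

    ``depth_profile`` is a scalar expected depth or a per-position array;
    realised depths are Poisson draws around it.  ``variants`` plants
    substitutions as (1-based position, new base) pairs; reads carry the
    variant base at those positions.  The truth consensus is the reference
    with variants applied and N wherever the realised depth falls below 2.
    """
    if not reference:
        raise ValueError("empty reference")
    reference = reference.upper()
    L = len(reference)
    profile = np.broadcast_to(np.asarray(depth_profile, dtype=float), (L,))
    if (profile < 0).any():
        raise ValueError("depth profile must be non-negative")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")

    true_seq = list(reference)
    for pos, base in variants:
        if not 1 <= pos <= L:
            raise ValueError(f"variant position {pos} outside 1..{L}")
        base = base.upper()
        if base not in BASES:
            raise ValueError(f"variant base {base!r} not in {BASES}")
        true_seq[pos - 1] = base

    rng = np.random.default_rng(child_seed(seed, "simulate_organelle_pileup"))
    depths = rng.poisson(profile)
    counts = np.zeros((L, 4), dtype=np.int64)
    base_index = {b: i for i, b in enumerate(BASES)}
    for i in range(L):
        d = int(depths[i])
        if d == 0:
            continue
        true_i = base_index[true_seq[i]]
        if error_rate > 0.0:
            errors = int(rng.binomial(d, error_rate))
            counts[i, true_i] = d - errors
            if errors:
                others = [j for j in range(4) if j != true_i]
                err_split = rng.multinomial(errors, [1 / 3] * 3)
                for j, e in zip(others, err_split):
                    counts[i, j] = int(e)
        else:
            counts[i, true_i] = d
    truth = "".join(
        "N" if int(depths[i]) < 2 else true_seq[i] for i in range(L)
    )
    pileup = Pileup(reference_id="organelle_ref", counts=counts)
    return OrganelleSimResult(pileup=pileup, truth_consensus=truth)


def write_transcriptome_fasta(fixture: TranscriptomeFixture, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in fixture.transcripts:
            fh.write(f">{t.transcript_id} copy_number={t.true_copy_number}\n")
            for i in range(0, len(t.sequence), width):
                fh.write(t.sequence[i : i + width] + "\n")
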