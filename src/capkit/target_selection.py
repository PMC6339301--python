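"""Low-copy gene-target selection from genomic-read coverage of a transcriptome.

Shotgun genomic reads mapped against a transcriptome give, for every
transcript model, a mapped-read count that scales with the genomic copy
number of the underlying gene.  Normalising that count by transcript length
(reads per kilobase, RPK) and sorting transcripts by RPK in ascending order
places putative contaminants and unmappable models at the bottom, single-copy
genes in a broad low plateau, and high-copy families (e.g. pentatricopeptide
repeats, organellar genes) in the upper tail.  A rank window over the sorted
list — skipping the lowest ranks, stopping well before the high-copy tail —
selects targets suitable for hybridization-capture probe design.

The coverage input is a "covstats"-style per-target table: target id, target
length, mapped reads on the plus and minus strands, and covered bases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CoverageRecord",
    "RankedTarget",
    "RpkRanking",
    "TargetSet",
    "RpkSummary",
    "compute_rpk",
    "rank_by_rpk",
    "select_rank_window",
    "rpk_summary",
    "masked_fraction",
    "drop_masked_targets",
    "read_coverage_table",
    "write_coverage_table",
    "write_ranking",
]

MIN_TARGET_LENGTH = 200  # shortest transcript model admitted to a panel (bp)


@dataclass(frozen=True)
class CoverageRecord:
    """Per-target alignment summary: the atom of RPK and depth computations.

    ``covered_bases`` is the number of reference positions with at least one
    mapped read, never exceeding ``target_length``.
    """

    target_id: str
    target_length: int
    reads_plus: int
    reads_minus: int
    covered_bases: int

    def __post_init__(self) -> None:
        if self.target_length < 1:
            raise ValueError(
                f"{self.target_id}: target_length must be >= 1, got {self.target_length}"
            )
        if self.reads_plus < 0 or self.reads_minus < 0:
            raise ValueError(f"{self.target_id}: read counts must be non-negative")
        if not 0 <= self.covered_bases <= self.target_length:
            raise ValueError(
                f"{self.target_id}: covered_bases {self.covered_bases} outside "
                f"[0, {self.target_length}]"
            )

    @property
    def mapped_reads(self) -> int:
        """Total mapped reads (plus plus minus strand)."""
        return self.reads_plus + self.reads_minus


@dataclass(frozen=True)
class RankedTarget:
    target_id: str
    rpk: float
    rank: int  # 1-based, ascending RPK


@dataclass(frozen=True)
class RpkRanking:
    """Targets ordered by ascending RPK, ties broken by target id."""

    entries: tuple[RankedTarget, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]


@dataclass(frozen=True)
class TargetSet:
    """Selected gene targets, ordered by rank.

    ``sequences`` is optional: selection operates on a ranking alone, but
    probe design downstream requires sequences.
    """

    target_ids: tuple[str, ...]
    sequences: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("target ids must be unique")
        if self.sequences is not None:
            for tid in self.target_ids:
                if tid not in self.sequences:
                    raise ValueError(f"no sequence for selected target {tid!r}")

    def __len__(self) -> int:
        return len(self.target_ids)

    def __contains__(self, tid: str) -> bool:
        return tid in set(self.target_ids)

    def lengths(self) -> dict[str, int]:
        if self.sequences is None:
            raise ValueError("TargetSet carries no sequences")
        return {t: len(self.sequences[t]) for t in self.target_ids}


@dataclass(frozen=True)
class RpkSummary:
    mean: float
    min: float
    max: float


def compute_rpk(record: CoverageRecord) -> float:
    """Mapped reads per kilobase of target length.

    rpk = (reads_plus + reads_minus) / (target_length / 1000)
    """
    if record.target_length < 1:
        raise ValueError("target_length must be >= 1")
    return record.mapped_reads / (record.target_length / 1000.0)


def rank_by_rpk(records: Iterable[CoverageRecord]) -> RpkRanking:
    """Sort targets by ascending RPK and assign 1-based ranks.

    Ties are broken by lexicographic target id so the ranking (and any
    selection derived from it) is reproducible.
    """
    records = list(records)
    if not records:
        raise ValueError("coverage table is empty")
    ids = [r.target_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate target ids in coverage table: {dupes[:5]}")
    keyed = sorted(((compute_rpk(r), r.target_id) for r in records))
    entries = tuple(
        RankedTarget(target_id=tid, rpk=rpk, rank=i + 1)
        for i, (rpk, tid) in enumerate(keyed)
    )
    return RpkRanking(entries=entries)


def select_rank_window(
    ranking: RpkRanking,
    lo: int,
    hi: int,
    sequences: Mapping[str, str] | None = None,
) -> TargetSet:
    """Select targets with rank in the inclusive window [lo, hi].

    Both ends inclusive: a window of 5000..15000 over a full ranking yields
    10,001 targets.
    """
    n = len(ranking)
    if not (1 <= lo <= hi <= n):
        raise ValueError(f"rank window [{lo}, {hi}] outside 1..{n}")
    chosen = ranking.entries[lo - 1 : hi]
    seqs = None
    if sequences is not None:
        seqs = {e.target_id: sequences[e.target_id] for e in chosen}
    return TargetSet(target_ids=tuple(e.target_id for e in chosen), sequences=seqs)


def rpk_summary(ranking: RpkRanking, subset: TargetSet | None = None) -> RpkSummary:
    """Arithmetic mean and extrema of RPK over a subset (or the full ranking)."""
    if subset is None:
        vals = [e.rpk for e in ranking]
    else:
        wanted = set(subset.target_ids)
        vals = [e.rpk for e in ranking if e.target_id in wanted]
    if not vals:
        raise ValueError("empty RPK subset")
    return RpkSummary(mean=sum(vals) / len(vals), min=min(vals), max=max(vals))


def masked_fraction(sequence: str) -> float:
    """Fraction of bases soft-masked (lower case) or hard-masked (N/n)."""
    if not sequence:
        raise ValueError("empty sequence")
    masked = sum(1 for b in sequence if b.islower() or b in "Nn")
    return masked / len(sequence)


def drop_masked_targets(
    sequences: Mapping[str, str], max_masked_fraction: float = 0.5
) -> dict[str, str]:
    """Drop targets whose masked-base fraction exceeds the threshold.

    Masking itself (repeat / low-complexity annotation) is an upstream step;
    this is a convenience filter over already-masked sequences.
    """
    return {
        tid: seq
        for tid, seq in sequences.items()
        if masked_fraction(seq) <= max_masked_fraction
    }


# ---------------------------------------------------------------------------
# Coverage-table I/O (tab-separated; header: #id length plus_reads minus_reads
# covered_bases; extra columns ignored)
# ---------------------------------------------------------------------------

def read_coverage_table(path) -> list[CoverageRecord]:
    records: list[CoverageRecord] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected >= 5 columns, got {len(row)}")
            try:
                rec = CoverageRecord(
                    target_id=row[0],
                    target_length=int(row[1]),
                    reads_plus=int(row[2]),
                    reads_minus=int(row[3]),
                    covered_bases=int(row[4]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_coverage_table(records: Sequence[CoverageRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("#id\tlength\tplus_reads\tminus_reads\tcovered_bases\n")
        for r in records:
            fh.write(
                f"{r.target_id}\t{r.target_length}\t{r.reads_plus}\t"
                f"{r.reads_minus}\t{r.covered_bases}\n"
            )


def write_ranking(ranking: RpkRanking, path, selected: TargetSet | None = None) -> None:
    chosen = set(selected.target_ids) if selected is not None else set()
    with open(path, "w", newline="") as fh:
        fh.write("#id\trpk\trank\tselected\n")
        for e in ranking:
            flag = 1 if e.target_id in chosen else 0
            fh.write(f"{e.target_id}\t{e.rpk:.6g}\t{e.rank}\t{flag}\n")
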