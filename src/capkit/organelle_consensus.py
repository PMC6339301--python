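"""Reference-guided organelle consensus calling and alignment site counting.

Given a per-base pileup (base counts per reference position), the consensus
base at each position is the plurality base when total depth reaches a
minimum (2X by default); positions below the minimum, and ties at the top,
are coded as the ambiguity base N.  The module also computes the coverage
statistics conventionally reported for draft organelle genomes (mean depth,
percent of the reference covered at >= 1X, percent N in the consensus),
joins assembly contigs with fixed-length N spacers, and counts variable
sites in a multiple sequence alignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .capture_qc import round_half_up

__all__ = [
    "Pileup",
    "ConsensusSequence",
    "CoverageStats",
    "call_consensus",
    "coverage_stats",
    "count_n_bases",
    "join_contigs",
    "count_alignment_snps",
    "read_pileup",
    "write_pileup",
    "write_consensus_fasta",
    "read_alignment_fasta",
]

BASES = "ACGT"
DEFAULT_MIN_DEPTH = 2  # positions below this depth are masked to N
DEFAULT_SPACER_N = 100  # N bases inserted between joined contigs


@dataclass(frozen=True)
class Pileup:
    """Per-position base counts over a reference: an (L, 4) array in A,C,G,T order."""

    reference_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array in A,C,G,T order")
        if (counts < 0).any():
            raise ValueError("base counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Total depth per position (length L)."""
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class ConsensusSequence:
    """Consensus over {A,C,G,T,N} with the per-position depth it was called from."""

    reference_id: str
    sequence: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.depth):
            raise ValueError("sequence and depth profile lengths differ")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoverageStats:
    total_mapped_bases: int  # sum of all base counts; read-count proxy
    mean_depth: float
    pct_covered: float  # percent of positions at >= 1X, to 1 decimal


def call_consensus(pileup: Pileup, min_depth: int = DEFAULT_MIN_DEPTH) -> ConsensusSequence:
    """Plurality-base consensus with an N mask below ``min_depth``.

    Position i gets the most frequent base when its total count is at least
    ``min_depth``; below that, or when two bases tie for the top count, the
    position is coded N.  Tie-to-N is the conservative choice: a tied
    plurality carries no evidence for either base.
    """
    counts = pileup.counts
    depth = counts.sum(axis=1)
    top = counts.argmax(axis=1)
    top_count = counts.max(axis=1)
    tied = (counts == top_count[:, None]).sum(axis=1) > 1
    bases = np.array(list(BASES))
    seq = bases[top]
    seq[(depth < min_depth) | tied] = "N"
    return ConsensusSequence(
        reference_id=pileup.reference_id,
        sequence="".join(seq),
        depth=depth,
    )


def coverage_stats(pileup: Pileup) -> CoverageStats:
    """Mean depth and percent of reference positions covered at >= 1X."""
    if len(pileup) == 0:
        raise ValueError("empty pileup")
    depth = pileup.depth
    return CoverageStats(
        total_mapped_bases=int(depth.sum()),
        mean_depth=float(depth.mean()),
        pct_covered=round_half_up(100.0 * float((depth >= 1).mean()), 1),
    )


def count_n_bases(sequence: str) -> float:
    """Percent of N bases in a sequence, to 1 decimal."""
    if not sequence:
        raise ValueError("empty sequence")
    n = sequence.upper().count("N")
    return round_half_up(100.0 * n / len(sequence), 1)


def join_contigs(contigs: Sequence[str], spacer_n: int = DEFAULT_SPACER_N) -> str:
    """Concatenate contigs with ``spacer_n`` N bases between neighbours."""
    if not contigs:
        raise ValueError("no contigs to join")
    if spacer_n < 0:
        raise ValueError("spacer length must be non-negative")
    return ("N" * spacer_n).join(contigs)


def count_alignment_snps(
    alignment: Mapping[str, str] | Sequence[tuple[str, str]],
    subset: Sequence[str] | None = None,
) -> int:
    """Count variable columns in an equal-length alignment.

    A column is variable when it holds at least two distinct unambiguous
    bases (A/C/G/T, case-insensitive) among the selected taxa; N and gap
    characters are ignored entirely, so a column differing only by N or '-'
    does not count.
    """
    items = list(alignment.items()) if isinstance(alignment, Mapping) else list(alignment)
    if not items:
        raise ValueError("empty alignment")
    if subset is not None:
        wanted = set(subset)
        unknown = wanted - {tid for tid, _ in items}
        if unknown:
            raise ValueError(f"subset taxa not in alignment: {sorted(unknown)[:5]}")
        items = [(tid, seq) for tid, seq in items if tid in wanted]
    lengths = {len(seq) for _, seq in items}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    seqs = [seq.upper() for _, seq in items]
    n_var = 0
    for col in zip(*seqs):
        bases = {b for b in col if b in BASES}
        if len(bases) >= 2:
            n_var += 1
    return n_var


# ---------------------------------------------------------------------------
# Pileup / FASTA I/O (pileup TSV: 1-based pos, A, C, G, T counts)
# ---------------------------------------------------------------------------

def read_pileup(path, reference_id: str | None = None) -> Pileup:
    rows: list[tuple[int, list[int]]] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 5:
                raise ValueError(f"{path}:{lineno}: expected pos + 4 base counts")
            rows.append((int(row[0]), [int(x) for x in row[1:5]]))
    rows.sort()
    positions = [p for p, _ in rows]
    if positions != list(range(1, len(rows) + 1)):
        raise ValueError(f"{path}: positions must be contiguous from 1")
    counts = np.array([c for _, c in rows], dtype=np.int64)
    return Pileup(reference_id=reference_id or "reference", counts=counts)


def write_pileup(pileup: Pileup, path) -> None:
    with open(path, "w") as fh:
        fh.write("#pos\tA\tC\tG\tT\n")
        for i, row in enumerate(pileup.counts, start=1):
            fh.write(f"{i}\t{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\n")


def write_consensus_fasta(consensus: ConsensusSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{consensus.reference_id}_consensus\n")
        for i in range(0, len(consensus.sequence), width):
            fh.write(consensus.sequence[i : i + width] + "\n")


def read_alignment_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA into an id -> sequence mapping (order kept)."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate alignment id {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out
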