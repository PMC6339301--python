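"""Tiled hybridization-probe design over selected gene targets.

Probes are fixed-length oligo sequences (100 bp by default) tiled end-to-end
from the 5' end of each gene target, at most a fixed number per target (two
by default).  Only full-length tiles are emitted: a 150-bp target yields one
probe, a 250-bp target two.  Probes containing ambiguous or soft-masked
bases are flagged rather than silently dropped, since vendor-side QC rules
vary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .target_selection import TargetSet

__all__ = [
    "Probe",
    "ProbePanelSummary",
    "tile_probes",
    "design_probe_panel",
    "probe_panel_summary",
    "write_probe_fasta",
    "write_probe_bed",
]

DEFAULT_PROBE_LENGTH = 100
DEFAULT_PROBES_PER_TARGET = 2

_UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class Probe:
    """One tile: 0-based half-open interval [start, end) on its target."""

    probe_id: str
    target_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.probe_id}: bad interval [{self.start}, {self.end})")
        if self.end - self.start != len(self.sequence):
            raise ValueError(f"{self.probe_id}: interval/sequence length mismatch")

    @property
    def has_ambiguous(self) -> bool:
        """True if the probe contains any base other than upper-case A/C/G/T."""
        return any(b not in _UNAMBIGUOUS for b in self.sequence)


@dataclass(frozen=True)
class ProbePanelSummary:
    n_probes: int
    n_targets: int
    mean_probes_per_target: float | None  # None for an empty panel


def tile_probes(
    target_id: str,
    sequence: str,
    probe_length: int = DEFAULT_PROBE_LENGTH,
    probes_per_target: int = DEFAULT_PROBES_PER_TARGET,
) -> list[Probe]:
    """Tile probes end-to-end from the 5' end of one target.

    Tiles start at 0, probe_length, 2*probe_length, ...; no overlap, no gap,
    no partial terminal tile.  A target must be at least one probe length.
    """
    if probe_length < 1 or probes_per_target < 1:
        raise ValueError("probe_length and probes_per_target must be >= 1")
    if len(sequence) < probe_length:
        raise ValueError(
            f"target {target_id!r} ({len(sequence)} bp) shorter than one probe "
            f"({probe_length} bp)"
        )
    n_tiles = min(probes_per_target, len(sequence) // probe_length)
    probes = []
    for k in range(n_tiles):
        start = k * probe_length
        end = start + probe_length
        probes.append(
            Probe(
                probe_id=f"{target_id}_p{k + 1}",
                target_id=target_id,
                start=start,
                end=end,
                sequence=sequence[start:end],
            )
        )
    return probes


def design_probe_panel(
    targets: TargetSet | Mapping[str, str],
    probe_length: int = DEFAULT_PROBE_LENGTH,
    probes_per_target: int = DEFAULT_PROBES_PER_TARGET,
    drop_ambiguous: bool = False,
) -> list[Probe]:
    """Tile every target in a set; optionally drop probes with ambiguous bases."""
    if isinstance(targets, TargetSet):
        if targets.sequences is None:
            raise ValueError("probe design requires target sequences")
        items = [(t, targets.sequences[t]) for t in targets.target_ids]
    else:
        items = list(targets.items())
    panel: list[Probe] = []
    for tid, seq in items:
        for probe in tile_probes(tid, seq, probe_length, probes_per_target):
            if drop_ambiguous and probe.has_ambiguous:
                continue
            panel.append(probe)
    return panel


def probe_panel_summary(probes: Iterable[Probe]) -> ProbePanelSummary:
    probes = list(probes)
    n_targets = len({p.target_id for p in probes})
    mean = len(probes) / n_targets if n_targets else None
    return ProbePanelSummary(
        n_probes=len(probes), n_targets=n_targets, mean_probes_per_target=mean
    )


def write_probe_fasta(probes: Sequence[Probe], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f">{p.probe_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def write_probe_bed(probes: Sequence[Probe], path) -> None:
    """BED-like TSV: target_id, start, end, probe_id (0-based half-open)."""
    with open(path, "w") as fh:
        for p in probes:
            fh.write(f"{p.target_id}\t{p.start}\t{p.end}\t{p.probe_id}\n")
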