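"""Capture-enrichment QC: on-target yield, depth, reliable targets, t-tests.

Quantifies how well a hybridization probe panel enriched each sequencing
library and how transferable the panel is across taxa:

* on-target yield and percentage per specimen (reads mapping to the designed
  gene targets, as a share of the library);
* per-target depth from mapped-read counts and covered bases
  (``read_length * mapped_reads / covered_bases``, 101-bp reads by default);
* "reliably enriched" target sets per species — targets whose depth exceeds
  a threshold (10X by default) in *every* specimen of the species;
* organelle depletion followed by fixed-size subsampling, which normalises
  libraries before cross-taxon efficiency comparisons;
* Welch's unequal-variance t-test (Satterthwaite df) between specimen
  groups, e.g. in-genus vs out-genus on-target yield.

Percentages are rounded half-away-from-zero to one decimal and depths to the
nearest integer, matching how such panel metrics are conventionally tabled.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .target_selection import CoverageRecord

__all__ = [
    "SpecimenSummary",
    "DepthMatrix",
    "TTestResult",
    "SubsampleShortfallError",
    "round_half_up",
    "round_to_sig",
    "on_target_yield",
    "percent_on_target",
    "target_depth",
    "depth_matrix_from_coverage",
    "reliably_enriched_targets",
    "deplete_and_subsample",
    "welch_t_test",
    "build_specimen_summary",
    "panel_summary",
    "load_panel_metrics",
    "read_category_tallies",
    "read_grouping",
]

DEFAULT_READ_LENGTH = 101  # bp, sequencing read length used in depth estimates
DEFAULT_DEPTH_THRESHOLD = 10.0  # X, strict > comparison
DEFAULT_SUBSAMPLE = 1_000_000  # reads drawn after organelle depletion

ON_TARGET = "on_target"
ORGANELLE = "organelle"
OTHER = "other"


class SubsampleShortfallError(ValueError):
    """Raised when a library has fewer non-organelle reads than the subsample size."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (so 0.25 -> 0.3 at one decimal)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_to_sig(x: float, sig: int = 2) -> float:
    """Round to a number of significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, sig - 1 - exponent)


@dataclass(frozen=True)
class SpecimenSummary:
    """Per-library enrichment metrics (one table row for a capture panel)."""

    specimen_id: str
    species_id: str
    total_reads: int
    on_target_reads: int
    on_target_pct: float
    organelle_reads: int
    organelle_pct: float
    organelle_depth: int | None = None
    organelle_pct_covered: float | None = None
    n_base_pct: float | None = None

    def __post_init__(self) -> None:
        if self.on_target_reads > self.total_reads:
            raise ValueError(
                f"{self.specimen_id}: on-target reads exceed total reads"
            )
        for name in ("on_target_pct", "organelle_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{self.specimen_id}: {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class DepthMatrix:
    """Targets x specimens per-target depths with a species grouping."""

    depths: pd.DataFrame  # index: target ids; columns: specimen ids
    species_of: Mapping[str, str]  # specimen -> species

    def __post_init__(self) -> None:
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("depths must be non-negative")
        missing = [s for s in self.depths.columns if s not in self.species_of]
        if missing:
            raise ValueError(f"specimens without species assignment: {missing[:5]}")


def on_target_yield(coverage: Iterable[CoverageRecord]) -> int:
    """Sum of mapped reads (plus + minus strand) over all gene targets."""
    return sum(r.mapped_reads for r in coverage)


def percent_on_target(on_target: int, total: int) -> float:
    """Share of the library mapping to gene targets, percent to 1 decimal."""
    if total <= 0:
        raise ValueError("total reads must be positive")
    return round_half_up(100.0 * on_target / total, 1)


def target_depth(
    mapped_reads: int, covered_bases: int, read_length: int = DEFAULT_READ_LENGTH
) -> float:
    """Depth = read_length * mapped_reads / covered_bases; 0 with no reads."""
    if mapped_reads == 0:
        return 0.0
    if covered_bases <= 0:
        raise ValueError("covered_bases must be positive when reads are mapped")
    return read_length * mapped_reads / covered_bases


def depth_matrix_from_coverage(
    coverage_by_specimen: Mapping[str, Sequence[CoverageRecord]],
    species_of: Mapping[str, str],
    read_length: int = DEFAULT_READ_LENGTH,
) -> DepthMatrix:
    """Assemble a targets x specimens depth matrix from per-specimen coverage.

    Targets absent from a specimen's table get depth 0.
    """
    cols = {}
    for spec, records in coverage_by_specimen.items():
        cols[spec] = {
            r.target_id: target_depth(r.mapped_reads, r.covered_bases, read_length)
            if r.mapped_reads
            else 0.0
            for r in records
        }
    df = pd.DataFrame(cols).fillna(0.0).sort_index()
    return DepthMatrix(depths=df, species_of=dict(species_of))


def reliably_enriched_targets(
    matrix: DepthMatrix, threshold: float = DEFAULT_DEPTH_THRESHOLD
) -> dict[str, set[str]]:
    """Per species, targets whose depth strictly exceeds ``threshold`` in
    every specimen of the species.

    The comparison is strict (> threshold): a target sitting exactly at the
    threshold in any specimen is excluded.
    """
    groups: dict[str, list[str]] = {}
    for spec in matrix.depths.columns:
        groups.setdefault(matrix.species_of[spec], []).append(spec)
    if any(not members for members in groups.values()):
        raise ValueError("empty species group")
    out: dict[str, set[str]] = {}
    for species, members in groups.items():
        sub = matrix.depths[members]
        keep = (sub > threshold).all(axis=1)
        out[species] = set(sub.index[keep])
    return out


def deplete_and_subsample(
    read_labels: Sequence[str],
    n: int = DEFAULT_SUBSAMPLE,
    seed: int = 0,
) -> np.ndarray:
    """Remove organelle-labelled reads, then draw exactly ``n`` reads
    uniformly without replacement from the remainder.

    ``read_labels`` holds one category per read (``on_target`` /
    ``organelle`` / ``other``).  Returns the sorted indices of retained
    reads.  Raises :class:`SubsampleShortfallError` when fewer than ``n``
    non-organelle reads are available — mirroring the exclusion of
    under-sequenced libraries from normalised-efficiency comparisons.
    """
    labels = np.asarray(read_labels)
    keep = np.flatnonzero(labels != ORGANELLE)
    if keep.size < n:
        raise SubsampleShortfallError(
            f"library has {keep.size} non-organelle reads; {n} required"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(keep, size=n, replace=False)
    chosen.sort()
    return chosen


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Unequal-variance (Welch) two-sample t-test with Satterthwaite df.

    Two-sided p from the t distribution.  Each group needs n >= 2 and at
    least one group must have nonzero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def build_specimen_summary(
    specimen_id: str,
    species_id: str,
    total_reads: int,
    on_target_reads: int,
    organelle_reads: int,
    organelle_depth: float | None = None,
    organelle_pct_covered: float | None = None,
    n_base_pct: float | None = None,
) -> SpecimenSummary:
    """Compute the derived percentage columns for one specimen row."""
    return SpecimenSummary(
        specimen_id=specimen_id,
        species_id=species_id,
        total_reads=total_reads,
        on_target_reads=on_target_reads,
        on_target_pct=percent_on_target(on_target_reads, total_reads),
        organelle_reads=organelle_reads,
        organelle_pct=percent_on_target(organelle_reads, total_reads),
        organelle_depth=None if organelle_depth is None else int(round_half_up(organelle_depth, 0)),
        organelle_pct_covered=organelle_pct_covered,
        n_base_pct=n_base_pct,
    )


def panel_summary(
    summaries: Sequence[SpecimenSummary],
    group_of: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-specimen rows and per-group arithmetic means.

    ``group_of`` maps specimen id to a grouping label (defaults to the
    species id).  Returns (per-specimen table, per-group means of the
    numeric columns).
    """
    if not summaries:
        raise ValueError("no specimen summaries")
    rows = pd.DataFrame([s.__dict__ for s in summaries]).set_index("specimen_id")
    if group_of is None:
        rows["group"] = rows["species_id"]
    else:
        rows["group"] = [group_of[s] for s in rows.index]
    numeric = rows.select_dtypes("number").columns
    means = rows.groupby("group")[list(numeric)].mean()
    return rows, means


# ---------------------------------------------------------------------------
# Published panel metrics and small-table I/O
# ---------------------------------------------------------------------------

def load_panel_metrics() -> pd.DataFrame:
    """Published sequencing metrics for the 43-specimen Meliaceae capture
    diversity panel (24 Cedrela and 19 other-genera libraries).

    Columns: specimen, species, genus_group (in_genus/out_genus), accession,
    sequence_yield, on_target_yield, on_target_pct, cp_yield, cp_pct,
    cp_depth, cp_pct_covered, n_base_pct.
    """
    ref = importlib.resources.files("capkit") / "data" / "panel_metrics.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    return df


def read_category_tallies(path) -> dict[str, dict[str, int]]:
    """Read a per-specimen category tally TSV: specimen, total, on_target, organelle."""
    out: dict[str, dict[str, int]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = {
                "total": int(row[1]),
                "on_target": int(row[2]),
                "organelle": int(row[3]),
            }
    return out


def read_grouping(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a grouping TSV (specimen, species, group) -> two specimen maps."""
    species_of: dict[str, str] = {}
    group_of: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            species_of[row[0]] = row[1]
            group_of[row[0]] = row[2] if len(row) > 2 else row[1]
    return species_of, group_of
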