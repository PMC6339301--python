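"""End-to-end pipeline orchestration: config, stage running, manifests.

Ties the stages together in dependency order (select-targets ->
design-probes -> capture-qc -> snp-fst, with organelle consensus
independent), records a manifest of input/output checksums so deterministic
stages are verifiably reproducible, and validates the text formats the
pipeline consumes.  Stages whose outputs already exist are skipped, so
re-running after deleting an intermediate re-executes only what is missing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from . import capture_qc, organelle_consensus, probe_design, snp_diagnostics
from . import target_selection

__all__ = [
    "RunConfig",
    "RunManifest",
    "ConfigError",
    "StageError",
    "run_pipeline",
    "validate_formats",
    "FormatViolation",
]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage executes)."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Parameters for a full run; defaults mirror the study design values.

    Input paths are optional — stages whose inputs are absent are skipped —
    so a config may drive any subset of the pipeline.
    """

    out_dir: str = "capkit_out"
    seed: int = 0
    # target selection
    coverage_table: str | None = None
    transcriptome_fasta: str | None = None
    rank_lo: int = 5000
    rank_hi: int = 15000
    # probe design
    probe_length: int = 100
    probes_per_target: int = 2
    drop_ambiguous: bool = False
    # capture QC
    qc_coverage_dir: str | None = None
    category_tallies: str | None = None
    grouping: str | None = None
    depth_threshold: float = 10.0
    read_length: int = 101
    subsample_size: int = 1_000_000
    # SNP diagnostics
    vcf: str | None = None
    population_map: str | None = None
    maf_min: float = 0.05
    qual_min: float = 500.0
    min_pop_size: int = 2
    fst_threshold: float = 0.5
    # organelle consensus
    pileup: str | None = None
    consensus_min_depth: int = 2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 1 <= self.rank_lo <= self.rank_hi:
            raise ConfigError(
                f"rank window [{self.rank_lo}, {self.rank_hi}] invalid (need 1 <= lo <= hi)"
            )
        if self.probe_length < 1 or self.probes_per_target < 1:
            raise ConfigError("probe_length and probes_per_target must be >= 1")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigError("maf_min must be in [0, 0.5]")
        if self.qual_min < 0:
            raise ConfigError("qual_min must be >= 0")
        if self.min_pop_size < 1:
            raise ConfigError("min_pop_size must be >= 1")
        if self.consensus_min_depth < 1:
            raise ConfigError("consensus_min_depth must be >= 1")
        if self.subsample_size < 1:
            raise ConfigError("subsample_size must be >= 1")
        for name in ("coverage_table", "transcriptome_fasta", "vcf",
                     "population_map", "pileup", "category_tallies", "grouping"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{name}: no such file {p!r}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    started: float
    finished: float | None = None
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, inputs: Mapping[str, str],
               outputs: Mapping[str, str]) -> None:
        self.stages[stage] = {
            "status": status,
            "inputs": dict(inputs),
            "outputs": dict(outputs),
            "time": time.time(),
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksums(paths: Mapping[str, str | Path]) -> dict[str, str]:
    return {name: _sha256(p) for name, p in paths.items() if Path(p).exists()}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the configured stages in dependency order and write a manifest.

    A stage runs only when its inputs are configured; a stage whose outputs
    all exist already is skipped.  Failures abort the run but leave
    completed stage outputs (and the manifest) intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__, config_hash=config.config_hash(), started=time.time()
    )
    manifest_path = out / "manifest.json"

    def stage(name, inputs, outputs, fn):
        if not inputs:
            manifest.record(name, "not_configured", {}, {})
            return
        if all(Path(p).exists() for p in outputs.values()):
            manifest.record(name, "skipped", _checksums(inputs), _checksums(outputs))
            logger.info("stage %s: outputs present, skipped", name)
            return
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            manifest.record(name, "failed", _checksums(inputs), {})
            manifest.write(manifest_path)
            raise StageError(name, str(exc)) from exc
        manifest.record(name, "ran", _checksums(inputs), _checksums(outputs))
        logger.info("stage %s: complete", name)

    # --- select-targets -> design-probes ---------------------------------
    targets_fa = out / "targets.fasta"
    ranking_tsv = out / "ranking.tsv"

    def _select():
        records = target_selection.read_coverage_table(config.coverage_table)
        ranking = target_selection.rank_by_rpk(records)
        seqs = None
        if config.transcriptome_fasta:
            from Bio import SeqIO

            seqs = {
                r.id: str(r.seq)
                for r in SeqIO.parse(str(config.transcriptome_fasta), "fasta")
            }
        chosen = target_selection.select_rank_window(
            ranking, config.rank_lo, config.rank_hi, sequences=seqs
        )
        target_selection.write_ranking(ranking, ranking_tsv, selected=chosen)
        if chosen.sequences is not None:
            with open(targets_fa, "w") as fh:
                for tid in chosen.target_ids:
                    fh.write(f">{tid}\n{chosen.sequences[tid]}\n")

    stage(
        "select_targets",
        {k: v for k, v in {
            "coverage": config.coverage_table,
            "fasta": config.transcriptome_fasta,
        }.items() if v},
        {"ranking": ranking_tsv, **({"targets": targets_fa} if config.transcriptome_fasta else {})},
        _select,
    )

    probes_fa = out / "probes.fasta"
    probes_bed = out / "probes.bed.tsv"

    def _probes():
        from Bio import SeqIO

        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(targets_fa), "fasta")}
        panel = probe_design.design_probe_panel(
            seqs,
            probe_length=config.probe_length,
            probes_per_target=config.probes_per_target,
            drop_ambiguous=config.drop_ambiguous,
        )
        probe_design.write_probe_fasta(panel, probes_fa)
        probe_design.write_probe_bed(panel, probes_bed)

    stage(
        "design_probes",
        {"targets": targets_fa} if targets_fa.exists() or config.transcriptome_fasta else {},
        {"probes": probes_fa, "bed": probes_bed},
        _probes,
    )

    # --- capture-qc -------------------------------------------------------
    summary_tsv = out / "panel_summary.tsv"
    ttest_json = out / "ttest.json"
    enriched_dir = out / "reliably_enriched"

    def _qc():
        qc_dir = Path(config.qc_coverage_dir)
        coverage_by_specimen = {
            p.stem: target_selection.read_coverage_table(p)
            for p in sorted(qc_dir.glob("*.tsv"))
        }
        if not coverage_by_specimen:
            raise ValueError(f"no coverage tables under {qc_dir}")
        tallies = capture_qc.read_category_tallies(config.category_tallies)
        species_of, group_of = capture_qc.read_grouping(config.grouping)
        summaries = []
        for spec, records in coverage_by_specimen.items():
            tally = tallies[spec]
            summaries.append(
                capture_qc.build_specimen_summary(
                    spec,
                    species_of[spec],
                    total_reads=tally["total"],
                    on_target_reads=capture_qc.on_target_yield(records),
                    organelle_reads=tally["organelle"],
                )
            )
        rows, _means = capture_qc.panel_summary(summaries, group_of)
        rows.to_csv(summary_tsv, sep="\t")
        matrix = capture_qc.depth_matrix_from_coverage(
            coverage_by_specimen, species_of, read_length=config.read_length
        )
        enriched = capture_qc.reliably_enriched_targets(matrix, config.depth_threshold)
        enriched_dir.mkdir(exist_ok=True)
        for species, ids in sorted(enriched.items()):
            (enriched_dir / f"{species}.txt").write_text(
                "\n".join(sorted(ids)) + ("\n" if ids else "")
            )
        groups = sorted(set(group_of.values()))
        if len(groups) == 2:
            a = [s.on_target_reads for s in summaries if group_of[s.specimen_id] == groups[0]]
            b = [s.on_target_reads for s in summaries if group_of[s.specimen_id] == groups[1]]
            res = capture_qc.welch_t_test(a, b)
            ttest_json.write_text(json.dumps({
                "groups": groups, "t": res.t, "df": res.df, "p": res.p,
            }, indent=2) + "\n")

    stage(
        "capture_qc",
        {k: v for k, v in {
            "coverage_dir": config.qc_coverage_dir,
            "tallies": config.category_tallies,
            "grouping": config.grouping,
        }.items() if v} if config.qc_coverage_dir else {},
        {"summary": summary_tsv},
        _qc,
    )

    # --- snp-fst ----------------------------------------------------------
    fst_tsv = out / "fst.tsv"
    fst_json = out / "fst_summary.json"
    candidates_tsv = out / "fst_candidates.tsv"

    def _fst():
        records, samples = snp_diagnostics.read_vcf(config.vcf)
        pop_map = snp_diagnostics.read_population_map(config.population_map)
        pops = [pop_map[s] for s in samples]
        retained, report = snp_diagnostics.stringent_filter(
            records, maf_min=config.maf_min, qual_min=config.qual_min,
            return_report=True,
        )
        results = snp_diagnostics.fst_scan(
            retained, pops, min_pop_size=config.min_pop_size
        )
        snp_diagnostics.write_fst_table(results, fst_tsv)
        summary = snp_diagnostics.fst_distribution(results)
        fst_json.write_text(json.dumps({
            "filter": asdict(report),
            "mean_theta": summary.mean_theta,
            "n_defined": summary.n_defined,
            "n_undefined": summary.n_undefined,
            "n_ge_half": summary.n_ge_half,
            "n_fixed": summary.n_fixed,
        }, indent=2) + "\n")
        hits = snp_diagnostics.candidate_diagnostic_snps(results, config.fst_threshold)
        with open(candidates_tsv, "w") as fh:
            fh.write("#chrom\tpos\ttheta\n")
            for r in hits:
                fh.write(f"{r.chrom}\t{r.pos}\t{r.theta:.6f}\n")

    stage(
        "snp_fst",
        {k: v for k, v in {
            "vcf": config.vcf, "pops": config.population_map,
        }.items() if v} if config.vcf else {},
        {"fst": fst_tsv, "summary": fst_json, "candidates": candidates_tsv},
        _fst,
    )

    # --- consensus (independent) ------------------------------------------
    consensus_fa = out / "consensus.fasta"
    cp_stats_json = out / "cp_stats.json"

    def _consensus():
        pileup = organelle_consensus.read_pileup(config.pileup)
        consensus = organelle_consensus.call_consensus(
            pileup, min_depth=config.consensus_min_depth
        )
        organelle_consensus.write_consensus_fasta(consensus, consensus_fa)
        stats = organelle_consensus.coverage_stats(pileup)
        cp_stats_json.write_text(json.dumps({
            "total_mapped_bases": stats.total_mapped_bases,
            "mean_depth": stats.mean_depth,
            "pct_covered": stats.pct_covered,
            "n_base_pct": organelle_consensus.count_n_bases(consensus.sequence),
        }, indent=2) + "\n")

    stage(
        "consensus",
        {"pileup": config.pileup} if config.pileup else {},
        {"consensus": consensus_fa, "stats": cp_stats_json},
        _consensus,
    )

    manifest.finished = time.time()
    manifest.write(manifest_path)
    return manifest


# ---------------------------------------------------------------------------
# Format validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormatViolation:
    path: str
    line: int | None
    message: str


def validate_formats(paths) -> list[FormatViolation]:
    """Check FASTA / VCF / coverage-TSV files for dialect violations.

    Dispatch is by extension (.fa/.fasta, .vcf, .tsv).  Returns one
    violation per problem, with line numbers where applicable.
    """
    violations: list[FormatViolation] = []
    for path in paths:
        p = Path(path)
        if not p.exists():
            violations.append(FormatViolation(str(p), None, "unreadable: no such file"))
            continue
        suffix = p.suffix.lower()
        if suffix in (".fa", ".fasta"):
            violations.extend(_validate_fasta(p))
        elif suffix == ".vcf":
            violations.extend(_validate_vcf(p))
        elif suffix == ".tsv":
            violations.extend(_validate_coverage_tsv(p))
        else:
            violations.append(FormatViolation(str(p), None, f"unknown format {suffix!r}"))
    return violations


def _validate_fasta(path: Path) -> list[FormatViolation]:
    out = []
    header_line = None
    has_seq = False
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header_line is not None and not has_seq:
                    out.append(FormatViolation(
                        str(path), header_line, "truncated record: header without sequence"
                    ))
                header_line, has_seq = lineno, False
                n_records += 1
                if len(line) == 1:
                    out.append(FormatViolation(str(path), lineno, "empty FASTA header"))
            elif line:
                if header_line is None:
                    out.append(FormatViolation(
                        str(path), lineno, "sequence before any FASTA header"
                    ))
                has_seq = True
    if header_line is not None and not has_seq:
        out.append(FormatViolation(
            str(path), header_line, "truncated record: header without sequence"
        ))
    if n_records == 0:
        out.append(FormatViolation(str(path), None, "no FASTA records"))
    return out


def _validate_vcf(path: Path) -> list[FormatViolation]:
    out = []
    n_cols = None
    saw_fileformat = saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1:
                saw_fileformat = line.startswith("##fileformat=VCF")
                if not saw_fileformat:
                    out.append(FormatViolation(
                        str(path), 1, "missing ##fileformat=VCF header"
                    ))
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                n_cols = len(line.split("\t"))
                if n_cols < 10:
                    out.append(FormatViolation(
                        str(path), lineno, "VCF has no sample columns"
                    ))
                continue
            if not line:
                continue
            fields = line.split("\t")
            if n_cols is not None and len(fields) != n_cols:
                out.append(FormatViolation(
                    str(path), lineno,
                    f"expected {n_cols} columns, got {len(fields)}",
                ))
                continue
            if len(fields) > 8 and "GT" not in fields[8].split(":"):
                out.append(FormatViolation(
                    str(path), lineno, "FORMAT lacks required GT field"
                ))
    if not saw_header:
        out.append(FormatViolation(str(path), None, "missing #CHROM column header"))
    return out


def _validate_coverage_tsv(path: Path) -> list[FormatViolation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                out.append(FormatViolation(
                    str(path), lineno, f"expected >= 5 columns, got {len(fields)}"
                ))
                continue
            for col in fields[1:5]:
                try:
                    int(col)
                except ValueError:
                    out.append(FormatViolation(
                        str(path), lineno, f"non-integer count field {col!r}"
                    ))
                    break
    return out
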