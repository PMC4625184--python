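"""End-to-end orchestration: simulate -> call junctions -> analyze sites.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives all
stages; one global seed fans out to per-stage seeds by fixed offsets so
stages are independently reproducible, and identical config+seed produce
byte-identical sequence outputs and manifest checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import io as pio
from .junctions import build_hybrid_reference, find_split_reads, resolve_breakpoint, trim_and_filter
from .reporter import TransposonReporter, default_reporter
from .simulate import (
    SimulationConfig,
    _sample_sequence,
    generate_reads,
    simulate_integrations,
)
from .sites import aggregate_sites, build_logo, classify_sites
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

ARTIFACT_VERSION = "0.1.0"


class PipelineConfigError(ValueError):
    pass


@dataclass
class AnnotationParams:
    flank: int = 50
    cutoff: float = 0.70

    def validate(self) -> None:
        if self.flank < 0:
            raise PipelineConfigError("annotation.flank must be >= 0")
        if not 0 < self.cutoff <= 1:
            raise PipelineConfigError("annotation.cutoff must be in (0, 1]")


@dataclass
class CallingParams:
    min_anchor: int = 20
    max_mismatch_rate: float = 0.04
    dedup: bool = True
    k: int = 21

    def validate(self) -> None:
        if self.min_anchor <= 0 or self.k <= 0:
            raise PipelineConfigError("calling.min_anchor and calling.k must be positive")
        if not 0 <= self.max_mismatch_rate < 1:
            raise PipelineConfigError("calling.max_mismatch_rate must be in [0, 1)")


@dataclass
class AnalysisParams:
    logo_flank: int = 10
    correction: bool = False
    strict_class: bool = True
    min_support: int = 2

    def validate(self) -> None:
        if self.logo_flank < 0:
            raise PipelineConfigError("analysis.logo_flank must be >= 0")
        if self.min_support < 1:
            raise PipelineConfigError("analysis.min_support must be >= 1")


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    calling: CallingParams = field(default_factory=CallingParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    reporter_cargo_length: int = 600
    reporter_variant: str = "intact"
    seed: int = 0
    outdir: str = "piggytools_run"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.simulation.validate()
        self.annotation.validate()
        self.calling.validate()
        self.analysis.validate()
        if self.reporter_cargo_length <= 0:
            raise PipelineConfigError("reporter_cargo_length must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        sections = {
            "simulation": SimulationConfig,
            "annotation": AnnotationParams,
            "calling": CallingParams,
            "analysis": AnalysisParams,
        }
        for name, klass in sections.items():
            sub = data.pop(name, {})
            if sub:
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(sub) - known
                if unknown:
                    raise PipelineConfigError(f"unknown keys in {name}: {sorted(unknown)}")
                kwargs[name] = klass(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        cfg = cls(**kwargs)
        # global seed fans out to the simulation stage
        cfg.simulation.seed = cfg.seed
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def snapshot(self) -> dict:
        """Config snapshot for manifests; output location excluded so that
        identical runs in different directories have identical checksums."""
        d = self.to_dict()
        d.pop("outdir", None)
        return d


@dataclass
class RunManifest:
    config: dict
    artifact_version: str
    checksums: dict[str, str]
    counts: dict[str, int]
    started: float
    finished: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def make_pipeline_reporter(config: PipelineConfig) -> TransposonReporter:
    """Reporter with a random cargo drawn from the global seed."""
    rng = np.random.default_rng(config.seed + 10)
    cargo = _sample_sequence(rng, config.reporter_cargo_length, 0.5)
    return default_reporter(cargo, variant=config.reporter_variant)


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> call-junctions -> analyze-sites with files on disk.

    Any stage failure aborts with the stage name and cause; partial
    outputs are retained under ``<outdir>/failed/``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        sim = config.simulation
        reporter = make_pipeline_reporter(config)
        genome = _stage_simulate_genome(sim, outdir)
        modified, events = simulate_integrations(genome, reporter, sim)
        pio.write_fasta(modified, outdir / "modified.fa")
        events_df = pd.DataFrame(
            {
                "contig": [e.contig for e in events],
                "tsd_start": [e.tsd_start for e in events],
                "orientation": [e.orientation for e in events],
                "reporter": [e.reporter_name for e in events],
                "on_ttaa": [e.on_ttaa for e in events],
            }
        )
        pio.write_tsv(events_df, outdir / "events.tsv")
        pairs = generate_reads(modified, events, reporter, sim)
        pio.write_fastq_pairs(pairs, outdir / "reads_R1.fastq", outdir / "reads_R2.fastq")
        pio.write_json({"config": config.snapshot()}, outdir / "run_config.json")
        counts["events"] = len(events)
        counts["read_pairs"] = len(pairs)

        stage = "call-junctions"
        kept, trim_report = trim_and_filter(pairs, dedup=config.calling.dedup)
        counts["pairs_after_trim"] = trim_report.surviving_pairs
        counts["pairs_after_dedup"] = trim_report.deduplicated_pairs
        pio.write_json(dataclasses.asdict(trim_report), outdir / "trim_report.json")
        hybrid = build_hybrid_reference(
            genome, reporter.element, plasmid_name="reporter_plasmid", k=config.calling.k
        )
        calls = [
            resolve_breakpoint(c, hybrid)
            for c in find_split_reads(
                kept, hybrid,
                min_anchor=config.calling.min_anchor,
                max_mismatch_rate=config.calling.max_mismatch_rate,
            )
        ]
        counts["junction_calls"] = len(calls)
        calls_df = pd.DataFrame(
            {
                "read_id": [c.read_id for c in calls],
                "contig": [c.contig for c in calls],
                "genome_pos": [c.genome_pos for c in calls],
                "tsd_start": [c.tsd_start for c in calls],
                "transposon_end": [c.transposon_end for c in calls],
                "transposon_offset": [c.transposon_offset for c in calls],
                "orientation": [c.orientation for c in calls],
                "target_tetra": [c.target_tetra for c in calls],
                "microhomology": [c.microhomology for c in calls],
            }
        )
        pio.write_tsv(calls_df, outdir / "calls.tsv")

        stage = "analyze-sites"
        sites = classify_sites(
            aggregate_sites(calls, min_support=config.analysis.min_support),
            strict=config.analysis.strict_class,
        )
        counts["insertion_sites"] = len(sites)
        sites_df = pd.DataFrame(
            {
                "contig": [s.contig for s in sites],
                "start": [s.tsd_start for s in sites],
                "end": [s.tsd_start + 4 for s in sites],
                "name": [s.site_class for s in sites],
                "score": [s.n_reads for s in sites],
                "strand": "+",
            }
        )
        pio.write_bed(sites_df, outdir / "sites.bed")
        summary = _summarize(events, sites)
        if sites:
            logo = build_logo(sites, genome, flank=config.analysis.logo_flank,
                              correction=config.analysis.correction)
            logo_df = logo.base_freq.copy()
            logo_df.insert(0, "offset", logo.positions)
            logo_df["info_bits"] = logo.info_bits
            pio.write_tsv(logo_df.reset_index(drop=True), outdir / "logo.tsv")
        pio.write_json(summary, outdir / "summary.json")
    except Exception as exc:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for f in outdir.iterdir():
            if f.is_file():
                shutil.move(str(f), failed / f.name)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    checksums = {
        f.name: _sha256(f) for f in sorted(outdir.iterdir()) if f.is_file() and f.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.snapshot(),
        artifact_version=ARTIFACT_VERSION,
        checksums=checksums,
        counts=counts,
        started=started,
        finished=time.time(),
    )
    pio.write_json(manifest.to_dict(), outdir / "manifest.json")
    return manifest


def _stage_simulate_genome(sim: SimulationConfig, outdir: Path):
    from .simulate import make_genome

    genome = make_genome(sim)
    pio.write_fasta(genome, outdir / "genome.fa")
    return genome


def _summarize(events, sites) -> dict:
    truth = {(e.contig, e.tsd_start) for e in events}
    found = {(s.contig, s.tsd_start) for s in sites}
    recovered = truth & found
    n_ttaa_itr = sum(1 for s in sites if s.site_class == "TTAA_ITR")
    return {
        "n_events": len(truth),
        "n_sites": len(sites),
        "n_recovered": len(recovered),
        "site_recovery": len(recovered) / len(truth) if truth else None,
        "false_positive_sites": len(found - truth),
        "ttaa_itr_fraction": n_ttaa_itr / len(sites) if sites else None,
    }
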