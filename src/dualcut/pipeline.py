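"""End-to-end orchestration: simulate/read -> filter -> consolidate ->
classify -> quantify, with conservation counters and bit-stable reports.

A run is driven by a plain configuration mapping (YAML on the CLI); unknown
keys are rejected before any computation, a stage failure aborts the run
with a stage-labeled error and removes partial outputs, and every file the
run writes is a deterministic function of (config, seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from . import io as dio
from .lesion_classifier import AmpliconReference, classify_sample
from .quantification import (
    CLASS_SCHEMA,
    LesionCountTable,
    compute_rates,
    subtract_background,
)
from .read_processing import (
    MoleculeConsensus,
    consolidate,
    extract_umis,
    group_by_umi,
    quality_filter,
)
from .site_model import (
    ENZYMES,
    compare_targeting_range,
    enumerate_composite_sites,
    enumerate_guide_sites,
)
from .synthetic_data import ReferenceSpec, SimulationConfig, simulate_library

__all__ = ["ConfigError", "PipelineError", "RunReport",
           "run_classification_pipeline", "run_sitefinder"]


class ConfigError(ValueError):
    """Invalid or unknown run configuration."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunReport:
    """Per-stage counters and provenance for one run."""

    seed: int
    config_digest: str
    counters: Dict[str, int] = field(default_factory=dict)
    tables: List[str] = field(default_factory=list)
    version: str = "1.0.0"

    def to_json(self) -> str:
        payload = {
            "config_digest": self.config_digest,
            "counters": dict(sorted(self.counters.items())),
            "seed": self.seed,
            "tables": sorted(self.tables),
            "version": self.version,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def _digest(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _check_keys(section: Mapping, allowed: Sequence[str], name: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown keys in {name}: {sorted(unknown)}")


_SIM_KEYS = ("n_molecules", "substitution_rate", "read_error_rate", "mixture",
             "reference", "copy_range", "umi_length", "quality",
             "indel_geom_p", "indel_max", "imprecise_offset_max", "window")
_REF_KEYS = ("length", "gc", "cut_a", "cut_b")
_PROCESS_KEYS = ("umi", "umi_length", "umi_end", "min_support", "mean_q", "min_q")
_CLASSIFY_KEYS = ("window", "min_identity", "unedited_identity_min",
                  "large_deletion_mode")
_INPUT_KEYS = ("reads", "reference", "cut_a", "cut_b")
_TOP_KEYS = ("seed", "sample_id", "simulate", "input", "process", "classify",
             "controls")


def _build_sim_config(section: Mapping) -> SimulationConfig:
    _check_keys(section, _SIM_KEYS, "simulate")
    kwargs = dict(section)
    ref = kwargs.pop("reference", None)
    if ref is not None:
        _check_keys(ref, _REF_KEYS, "simulate.reference")
        kwargs["reference"] = ReferenceSpec(**ref)
    if "copy_range" in kwargs:
        kwargs["copy_range"] = tuple(kwargs["copy_range"])
    try:
        return SimulationConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid simulate section: {exc}") from exc


class _OutputTracker:
    """Removes partially written outputs when a later stage fails."""

    def __init__(self) -> None:
        self.paths: List[Path] = []

    def add(self, path: Path) -> Path:
        self.paths.append(path)
        return path

    def rollback(self) -> None:
        for path in self.paths:
            path.unlink(missing_ok=True)


def run_classification_pipeline(config: Mapping, outdir: Path) -> RunReport:
    """Execute the full amplicon pipeline into ``outdir`` and return the report.

    Stages: acquire reads (simulated library or FASTQ input), quality filter,
    optional UMI extract/group/consolidate (``process.umi: false`` treats
    every read as one molecule), classify, compute rates, and optionally
    subtract a control background given per-replicate counts tables.
    """
    _check_keys(config, _TOP_KEYS, "run config")
    if ("simulate" in config) == ("input" in config):
        raise ConfigError("exactly one of 'simulate' or 'input' is required")
    seed = int(config.get("seed", 0))
    sample_id = str(config.get("sample_id", "sample"))
    process_cfg = dict(config.get("process", {}))
    _check_keys(process_cfg, _PROCESS_KEYS, "process")
    classify_cfg = dict(config.get("classify", {}))
    _check_keys(classify_cfg, _CLASSIFY_KEYS, "classify")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker()
    report = RunReport(seed=seed, config_digest=_digest(config))
    try:
        # --- stage: acquire reads -----------------------------------------
        if "simulate" in config:
            sim_config = _build_sim_config(config["simulate"])
            library = simulate_library(sim_config, seed)
            reads = list(library.reads)
            ref = library.reference
            dio.write_fastq(reads, tracker.add(outdir / "reads.fastq"))
            library.truth.to_csv(tracker.add(outdir / "truth.tsv"),
                                 sep="\t", index=False)
            report.tables += ["reads.fastq", "truth.tsv"]
            umi_default = True
            umi_length = sim_config.umi_length
        else:
            input_cfg = dict(config["input"])
            _check_keys(input_cfg, _INPUT_KEYS, "input")
            try:
                reads = dio.read_fastq(input_cfg["reads"])
                contigs = dio.read_fasta(input_cfg["reference"])
            except (KeyError, OSError, ValueError) as exc:
                raise PipelineError(f"stage input: {exc}") from exc
            if len(contigs) != 1:
                raise PipelineError(
                    "stage input: amplicon reference FASTA must hold one record")
            ((ref_id, seq),) = contigs.items()
            ref = AmpliconReference(ref_id, seq, int(input_cfg["cut_a"]),
                                    int(input_cfg["cut_b"]))
            umi_default = False
            umi_length = int(process_cfg.get("umi_length", 10))
        report.counters["reads_in"] = len(reads)

        # --- stage: quality filter ----------------------------------------
        kept = quality_filter(reads,
                              mean_min=float(process_cfg.get("mean_q", 30)),
                              base_min=float(process_cfg.get("min_q", 24)))
        report.counters["reads_quality_kept"] = len(kept)
        report.counters["reads_quality_dropped"] = len(reads) - len(kept)

        # --- stage: UMI consolidation -------------------------------------
        use_umi = bool(process_cfg.get("umi", umi_default))
        if use_umi:
            umi_reads, skipped = extract_umis(
                kept, umi_length=int(process_cfg.get("umi_length", umi_length)),
                umi_end=str(process_cfg.get("umi_end", "5prime")))
            groups = group_by_umi(umi_reads)
            molecules, rejected = consolidate(
                groups, min_support=int(process_cfg.get("min_support", 4)))
            report.counters["reads_too_short_for_umi"] = skipped
            report.counters["umi_groups"] = len(groups)
            report.counters["umi_groups_rejected"] = rejected
            mol_inputs: List = molecules
            dio.write_molecules_fasta(molecules,
                                      tracker.add(outdir / "molecules.fasta"))
            report.tables.append("molecules.fasta")
        else:
            mol_inputs = [(r.read_id, r.sequence) for r in kept]
        report.counters["molecules"] = len(mol_inputs)

        # --- stage: classification ----------------------------------------
        if not mol_inputs:
            raise PipelineError("stage classify: no molecules left to classify")
        result = classify_sample(
            mol_inputs, ref,
            window=int(classify_cfg.get("window", 5)),
            min_identity=float(classify_cfg.get("min_identity", 0.9)),
            unedited_identity_min=float(
                classify_cfg.get("unedited_identity_min", 0.9)),
            large_deletion_mode=bool(
                classify_cfg.get("large_deletion_mode", False)),
            sample_id=sample_id)
        for cls in CLASS_SCHEMA:
            report.counters[f"class_{cls}"] = result.table.count(cls)
        report.counters["class_UNCLASSIFIED"] = result.table.unclassified

        with open(tracker.add(outdir / "calls.tsv"), "w") as fh:
            fh.write("molecule_id\tlesion_class\tcandidate\tidentity\tindels\n")
            for call in result.calls:
                indels = ";".join(f"{e.kind}:{e.position}:{e.length}"
                                  for e in call.indel_detail)
                fh.write(f"{call.molecule_id}\t{call.lesion_class}\t"
                         f"{call.evidence.candidate or 'WT'}\t"
                         f"{call.evidence.normalized_identity:.6f}\t{indels}\n")
        dio.write_counts_tsv(result.table, tracker.add(outdir / "counts.tsv"))
        result.catalog.to_csv(tracker.add(outdir / "catalog.tsv"),
                              sep="\t", index=False, float_format="%.6f")
        report.tables += ["calls.tsv", "counts.tsv", "catalog.tsv"]

        # --- stage: quantification ----------------------------------------
        rates = compute_rates(result.table)
        outputs = [rates]
        controls = config.get("controls") or []
        if controls:
            control_rates = [compute_rates(dio.read_counts_tsv(p))
                             for p in controls]
            outputs.append(subtract_background(rates, control_rates))
        dio.write_rates_tsv(outputs, tracker.add(outdir / "rates.tsv"))
        report.tables.append("rates.tsv")

        report_path = tracker.add(outdir / "report.json")
        report_path.write_text(report.to_json())
    except ConfigError:
        tracker.rollback()
        raise
    except PipelineError:
        tracker.rollback()
        raise
    except Exception as exc:  # pragma: no cover - defensive
        tracker.rollback()
        raise PipelineError(f"pipeline failed: {exc}") from exc
    return report


_SITE_KEYS = ("genome", "partner", "mode", "spacing", "orientations",
              "functional_window", "seed")


def run_sitefinder(config: Mapping, outdir: Path) -> RunReport:
    """Enumerate composite sites from a genome FASTA; writes the site BED and
    a targeting-range summary."""
    _check_keys(config, _SITE_KEYS, "site-finder config")
    try:
        genome = dio.read_fasta(config["genome"])
    except (KeyError, OSError, ValueError) as exc:
        raise PipelineError(f"stage genome: {exc}") from exc
    if not genome or all(not s for s in genome.values()):
        raise PipelineError("stage genome: genome FASTA is empty")
    partner_name = str(config.get("partner", "sacas9")).lower()
    if partner_name not in ENZYMES or partner_name == "spcas9":
        raise ConfigError(f"unknown partner enzyme {config.get('partner')!r}")
    partner = ENZYMES[partner_name]
    mode = str(config.get("mode", "canonical"))
    spacing = config.get("spacing")
    spacing_range = tuple(int(v) for v in spacing) if spacing else None
    orientations = tuple(config.get("orientations", ("D1", "D2")))
    window = int(config.get("functional_window", 200))

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracker = _OutputTracker()
    report = RunReport(seed=int(config.get("seed", 0)),
                       config_digest=_digest(config))
    try:
        composites = enumerate_composite_sites(
            genome, partner, mode, spacing_range=spacing_range,
            orientations=orientations, functional_window=window)
        dio.write_composite_sites_bed(
            composites, tracker.add(outdir / "composite_sites.bed"), mode=mode)
        summary = compare_targeting_range(genome, partner,
                                          functional_window=window)
        with open(tracker.add(outdir / "targeting_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        report.counters["contigs"] = len(genome)
        report.counters["composite_sites"] = len(composites)
        report.counters["sp_only_sites"] = int(summary["n_sp_only_NGG"])
        report.tables += ["composite_sites.bed", "targeting_summary.json"]
        (outdir / "report.json").write_text(report.to_json())
        tracker.add(outdir / "report.json")
    except (ConfigError, PipelineError):
        tracker.rollback()
        raise
    except Exception as exc:  # pragma: no cover - defensive
        tracker.rollback()
        raise PipelineError(f"site finder failed: {exc}") from exc
    return report
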