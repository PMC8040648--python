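"""End-to-end orchestration: detect -> assign -> count -> call -> compare -> stats.

The heavy lifting lives in the stage modules; this module wires them
together, tracks per-stage read conservation, and produces a serializable
run report in which every printed percentage is recomputable from the
printed counts next to it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import (
    AssignParams,
    CountMatrix,
    TranscriptIndex,
    assign_readset,
    build_count_matrix,
    filter_rrna,
)
from .confidence import (
    HighConfidenceConfig,
    NoiseEstimate,
    PhaseComparison,
    call_high_confidence,
    compare_phases,
    estimate_background,
    ratio_table,
)
from .genome import Transcriptome
from .records import ReadRecord
from .stats import codon_presence, differential_expression, fc_correlation
from .tagdetect import TagSpec, classify_readset
from . import io as nio

logger = logging.getLogger("nadcap")


def summarize_fraction(numerator: int, denominator: int, decimals: int = 2) -> str:
    """Percentage string, round-half-even at ``decimals``, e.g. '0.46%'."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = np.round(100.0 * numerator / denominator, decimals)
    return f"{pct:.{decimals}f}%"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run; round-trips through YAML."""

    reads: dict[str, str]  # sample_id -> FASTQ path
    annotation: str  # GFF3
    transcripts: str  # FASTA
    sample_sheet: str  # TSV
    output_dir: str
    tag: TagSpec = field(default_factory=TagSpec)
    calling: HighConfidenceConfig = field(default_factory=HighConfidenceConfig)
    assign_params: AssignParams = field(default_factory=AssignParams)
    noise_flag_min_reads: int = 2
    de_alpha: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        data["tag"] = TagSpec(**data.get("tag", {}))
        data["calling"] = HighConfidenceConfig(**data.get("calling", {}))
        data["assign_params"] = AssignParams(**data.get("assign_params", {}))
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the semantically meaningful fields (logging excluded)."""
        payload = self.to_dict()
        payload.pop("log_level", None)
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory results of every stage, for programmatic use."""

    sample_stats: pd.DataFrame
    tag_calls: dict[str, pd.DataFrame]
    assignments: dict[str, pd.DataFrame]
    counts: CountMatrix
    noise: NoiseEstimate | None
    called: dict[str, set[str]]
    call_reports: dict[str, pd.DataFrame]
    comparison: PhaseComparison | None
    de: pd.DataFrame | None
    fc: dict | None
    codon: pd.DataFrame | None
    ratios: pd.DataFrame


def run_stages(
    reads_by_sample: dict[str, list[ReadRecord]],
    transcriptome: Transcriptome,
    sample_sheet: pd.DataFrame,
    tag: TagSpec | None = None,
    calling: HighConfidenceConfig | None = None,
    assign_params: AssignParams | None = None,
    noise_flag_min_reads: int = 2,
    de_alpha: float = 0.05,
) -> PipelineResult:
    """Run all computational stages on in-memory inputs."""
    tag = tag or TagSpec()
    calling = calling or HighConfidenceConfig()
    index = TranscriptIndex(transcriptome, assign_params or AssignParams())

    tag_calls: dict[str, pd.DataFrame] = {}
    assignments: dict[str, pd.DataFrame] = {}
    stats_rows = []
    for sample in sample_sheet["sample_id"]:
        reads = reads_by_sample[sample]
        try:
            tagged, untagged, calls = classify_readset(reads, tag)
        except Exception as exc:  # pragma: no cover - guarded orchestration
            raise PipelineStageError("detect", exc)
        try:
            assigned = assign_readset(tagged + untagged, index)
            assigned, rrna_removed_frac = filter_rrna(assigned, transcriptome)
        except Exception as exc:  # pragma: no cover
            raise PipelineStageError("assign", exc)
        kept = set(assigned["read_id"])
        calls_kept = calls[calls["read_id"].isin(kept)].reset_index(drop=True)
        n_assigned = int(assigned["gene_id"].notna().sum())
        n_rrna = len(reads) - len(assigned)
        stats_rows.append(
            {
                "sample_id": sample,
                "input_reads": len(reads),
                "rrna_removed": n_rrna,
                "post_rrna_reads": len(assigned),
                "assigned_reads": n_assigned,
                "tagged_reads": int(calls_kept["is_tagged"].sum()),
                "tagged_pct": summarize_fraction(
                    int(calls_kept["is_tagged"].sum()), max(len(assigned), 1)
                ),
            }
        )
        logger.info(
            "sample %s: %d reads in, %d rRNA removed, %d assigned, %d tagged",
            sample,
            len(reads),
            n_rrna,
            n_assigned,
            int(calls_kept["is_tagged"].sum()),
        )
        tag_calls[sample] = calls_kept
        assignments[sample] = assigned

    try:
        counts = build_count_matrix(
            tag_calls, assignments, sample_sheet, transcriptome.gene_ids
        )
    except Exception as exc:
        raise PipelineStageError("count", exc)

    minus = sample_sheet[sample_sheet["adprc"] == "minus"]
    noise = None
    if len(minus):
        try:
            noise = estimate_background(
                counts.subset_samples(list(minus["sample_id"])),
                flag_min_reads=noise_flag_min_reads,
            )
        except Exception as exc:
            raise PipelineStageError("noise", exc)
    else:
        warnings.warn(
            "no ADPRC- samples: noise estimation skipped, calling proceeds "
            "without per-gene background flagging",
            stacklevel=2,
        )

    plus = sample_sheet[sample_sheet["adprc"] == "plus"]
    called: dict[str, set[str]] = {}
    call_reports: dict[str, pd.DataFrame] = {}
    for condition, group in plus.groupby("condition", sort=False):
        try:
            genes, report = call_high_confidence(
                counts.subset_samples(list(group["sample_id"])), calling, noise
            )
        except Exception as exc:
            raise PipelineStageError("call", exc)
        called[condition] = genes
        call_reports[condition] = report

    comparison = None
    conditions = list(called)
    if len(conditions) == 2:
        comparison = compare_phases(
            called[conditions[0]], called[conditions[1]], *conditions
        )

    de = fc = codon = None
    if len(conditions) == 2 and (plus.groupby("condition").size() >= 2).all():
        try:
            de = differential_expression(counts, sample_sheet, alpha=de_alpha)
            union = set().union(*called.values()) if called else set()
            if comparison and len(union) >= 3:
                fc = fc_correlation(de, union)
            codon = codon_presence(assignments, tag_calls, transcriptome, sample_sheet)
        except Exception as exc:
            raise PipelineStageError("stats", exc)

    ratios = ratio_table(counts, sample_sheet)
    return PipelineResult(
        sample_stats=pd.DataFrame(stats_rows),
        tag_calls=tag_calls,
        assignments=assignments,
        counts=counts,
        noise=noise,
        called=called,
        call_reports=call_reports,
        comparison=comparison,
        de=de,
        fc=fc,
        codon=codon,
        ratios=ratios,
    )


def build_report(result: PipelineResult, config: PipelineConfig | None = None) -> dict:
    """JSON-serializable run report mirroring the per-stage summary counters."""
    report: dict = {
        "version": __version__,
        "samples": result.sample_stats.to_dict(orient="records"),
    }
    if config is not None:
        report["config_hash"] = config.config_hash()
    if result.noise is not None:
        noise = result.noise
        report["noise"] = {
            "tagged_reads": noise.tagged_reads,
            "total_reads": noise.total_reads,
            "rate_pct": summarize_fraction(noise.tagged_reads, noise.total_reads, 2),
            "flagged_genes": noise.flagged_genes,
        }
    report["high_confidence"] = {
        condition: sorted(genes) for condition, genes in result.called.items()
    }
    if result.comparison is not None:
        report["comparison"] = result.comparison.summary()
    if result.de is not None:
        report["differential_expression"] = {
            "n_tested": int(len(result.de)),
            "n_significant": int(result.de["significant"].sum()),
        }
    if result.fc is not None:
        report["fold_change_correlation"] = result.fc
    if result.codon is not None:
        report["codon_presence"] = result.codon.to_dict(orient="records")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based end-to-end run; writes intermediates and the JSON report."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        transcriptome = nio.read_transcriptome(config.annotation, config.transcripts)
        sheet = nio.read_sample_sheet(config.sample_sheet)
        reads = {s: nio.read_fastq(config.reads[s]) for s in sheet["sample_id"]}
    except Exception as exc:
        raise PipelineStageError("load", exc)

    result = run_stages(
        reads,
        transcriptome,
        sheet,
        tag=config.tag,
        calling=config.calling,
        assign_params=config.assign_params,
        noise_flag_min_reads=config.noise_flag_min_reads,
        de_alpha=config.de_alpha,
    )

    nio.write_table(result.sample_stats, out / "sample_stats.tsv")
    nio.write_table(result.counts.to_frame(), out / "count_matrix.tsv")
    for sample, calls in result.tag_calls.items():
        nio.write_table(calls, out / f"tag_calls.{sample}.tsv")
    for sample, assigned in result.assignments.items():
        nio.write_table(assigned, out / f"assignments.{sample}.tsv")
    for condition, rep in result.call_reports.items():
        nio.write_table(rep.reset_index(), out / f"calling.{condition}.tsv")
    nio.write_table(result.ratios, out / "ratio_table.tsv")
    if result.de is not None:
        nio.write_table(result.de.reset_index(names="gene_id"), out / "de_table.tsv")
    if result.codon is not None:
        nio.write_table(result.codon, out / "codon_presence.tsv")

    report = build_report(result, config)
    with open(out / "report.json", "w") as handle:
        json.dump(report, handle, indent=2, sort_keys=True)
    return report
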