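"""Background-noise estimation and high-confidence NAD-RNA gene calling.

The enzyme-minus (ADPRC-) controls define the assay's noise floor: any
tagged read there is background (spurious chemistry or detector error), not
NAD capping.  A gene is then called a high-confidence NAD-RNA producer in a
condition when, in at least ``min_replicates`` replicates, both of these hold
within the same replicate: the NAD fraction of its transcripts reaches
``min_ratio`` (default 0.2%, roughly 20x the noise floor) and at least
``min_nad_reads`` tagged reads were seen.  The criteria are deliberate
thresholds rather than a statistical test: a gene with a vanishing capped
fraction may produce NAD-RNA incidentally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assign import CountMatrix


@dataclass
class NoiseEstimate:
    """Background tagging rate measured on ADPRC- control samples."""

    overall_rate: float
    tagged_reads: int
    total_reads: int
    per_gene_rates: pd.Series
    flagged_genes: list[str]

    def percent(self, decimals: int = 2) -> float:
        return float(np.round(100 * self.overall_rate, decimals))


@dataclass
class HighConfidenceConfig:
    min_ratio: float = 0.002
    min_nad_reads: int = 2
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.min_ratio < 1:
            raise ValueError("min_ratio must be in (0, 1)")
        if self.min_nad_reads < 1:
            raise ValueError("min_nad_reads must be >= 1")
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


def estimate_background(
    control_counts: CountMatrix, flag_min_reads: int = 2
) -> NoiseEstimate:
    """Overall and per-gene background tagging rates from ADPRC- samples.

    Genes with ``flag_min_reads`` or more tagged reads in any single control
    sample are flagged: in a clean run scarcely any gene yields more than a
    single background read, so repeat offenders (typically extremely abundant
    transcripts) are excluded from downstream calling.
    """
    total = int(control_counts.total.to_numpy().sum())
    if total == 0:
        raise ValueError("control samples contain no assigned reads")
    tagged = int(control_counts.nad.to_numpy().sum())
    gene_tagged = control_counts.nad.sum(axis=1)
    gene_total = control_counts.total.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_gene = (gene_tagged / gene_total).fillna(0.0)
    flagged = control_counts.nad.index[
        (control_counts.nad >= flag_min_reads).any(axis=1)
    ]
    return NoiseEstimate(
        overall_rate=tagged / total,
        tagged_reads=tagged,
        total_reads=total,
        per_gene_rates=per_gene,
        flagged_genes=sorted(flagged),
    )


def call_high_confidence(
    condition_counts: CountMatrix,
    config: HighConfidenceConfig | None = None,
    noise: NoiseEstimate | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Call high-confidence NAD-RNA-producing genes for one condition.

    ``condition_counts`` holds that condition's ADPRC+ replicates as columns.
    Both criteria must hold jointly within a replicate.  A replicate with
    zero total reads for a gene counts as failing.  Genes flagged by the
    noise estimate are excluded and listed separately in the report.
    """
    config = config or HighConfidenceConfig()
    n_reps = len(condition_counts.samples)
    if n_reps < config.min_replicates:
        raise ValueError(
            f"need >= {config.min_replicates} replicates, have {n_reps}"
        )
    nad = condition_counts.nad
    total = condition_counts.total
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (nad / total).where(total > 0, 0.0).fillna(0.0)
    passes = (total > 0) & (ratio >= config.min_ratio) & (nad >= config.min_nad_reads)
    n_pass = passes.sum(axis=1)
    flagged = set(noise.flagged_genes) if noise is not None else set()
    meets = n_pass >= config.min_replicates
    called = set(nad.index[meets]) - flagged
    excluded = sorted(set(nad.index[meets]) & flagged)

    pooled_total = total.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_ratio = (nad.sum(axis=1) / pooled_total).fillna(0.0)
    report = pd.DataFrame(
        {
            "n_replicates_passing": n_pass,
            "mean_ratio": ratio.mean(axis=1),
            "pooled_ratio": pooled_ratio,
            "pooled_nad_reads": nad.sum(axis=1),
            "pooled_total_reads": pooled_total,
            "called": [g in called for g in nad.index],
            "excluded_by_noise": [g in excluded for g in nad.index],
        },
        index=nad.index,
    )
    return called, report


@dataclass
class PhaseComparison:
    """Set algebra between the high-confidence gene sets of two conditions."""

    label_a: str
    label_b: str
    set_a: set[str]
    set_b: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.set_a & self.set_b

    @property
    def only_a(self) -> set[str]:
        return self.set_a - self.set_b

    @property
    def only_b(self) -> set[str]:
        return self.set_b - self.set_a

    @property
    def union(self) -> set[str]:
        return self.set_a | self.set_b

    def summary(self) -> dict[str, int]:
        return {
            self.label_a: len(self.set_a),
            self.label_b: len(self.set_b),
            "intersection": len(self.intersection),
            f"{self.label_a}_only": len(self.only_a),
            f"{self.label_b}_only": len(self.only_b),
            "union": len(self.union),
        }


def compare_phases(
    set_a: set[str], set_b: set[str], label_a: str = "A", label_b: str = "B"
) -> PhaseComparison:
    """Exclusives, intersection, and union of two called gene sets."""
    return PhaseComparison(label_a, label_b, set(set_a), set(set_b))


def ratio_table(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    genes: list[str] | None = None,
    decimals: int = 1,
) -> pd.DataFrame:
    """Per-gene NAD-RNA/total ratios by condition, pooled across replicates.

    Returns one row per (gene, condition) with pooled counts, the pooled
    ratio, its percentage (round-half-even at ``decimals``), the mean
    per-replicate ratio, and the square-root-transformed ratio used for
    plotting.  Rows are sorted by descending pooled ratio, ties broken by
    gene id (stable).
    """
    plus = sample_sheet[sample_sheet["adprc"] == "plus"]
    rows = []
    for condition, group in plus.groupby("condition", sort=False):
        cols = [s for s in group["sample_id"] if s in counts.samples]
        sub = counts.subset_samples(cols)
        nad = sub.nad.sum(axis=1)
        total = sub.total.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled = (nad / total).fillna(0.0)
            per_rep = (sub.nad / sub.total).where(sub.total > 0, np.nan)
        for gene in genes if genes is not None else counts.genes:
            rows.append(
                {
                    "gene_id": gene,
                    "condition": condition,
                    "nad_reads": int(nad[gene]),
                    "total_reads": int(total[gene]),
                    "ratio": float(pooled[gene]),
                    "nad_pct": float(np.round(100 * pooled[gene], decimals)),
                    "mean_replicate_ratio": float(per_rep.loc[gene].mean())
                    if per_rep.loc[gene].notna().any()
                    else 0.0,
                    "sqrt_ratio": float(np.sqrt(pooled[gene])),
                }
            )
    columns = [
        "gene_id",
        "condition",
        "nad_reads",
        "total_reads",
        "ratio",
        "nad_pct",
        "mean_replicate_ratio",
        "sqrt_ratio",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["ratio", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
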