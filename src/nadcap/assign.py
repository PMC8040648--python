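"""Read-to-gene assignment, rRNA removal, and the NAD/total count matrix.

Reads are assigned to transcripts with a minimal seed-and-extend scheme:
exact k-mer seeds nominate candidate genes, each candidate is then aligned
with edlib in infix mode (the read as a gapped substring of the transcript)
and scored by identity over the aligned span.  The best gene wins if its
identity clears ``min_identity``; an exact tie between distinct genes leaves
the read unassigned (conservative undercount rather than double counting).
Results from an external long-read aligner can be imported instead via the
I/O layer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .genome import Transcriptome
from .records import ReadRecord

ASSIGN_COLUMNS = [
    "read_id",
    "gene_id",
    "identity",
    "t_start",
    "t_end",
    "multi_locus",
]


@dataclass
class AssignParams:
    k: int = 15  # seed length
    seed_stride: int = 7  # query every stride-th k-mer of the read
    seed_span: int = 400  # only seed from the first bases of the read
    min_seed_hits: int = 2
    max_candidates: int = 3
    min_identity: float = 0.7

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ValueError("seed length k must be >= 8")
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")


def trim_polya(sequence: str) -> str:
    """Strip the 3' poly(A) tail added before nanopore sequencing."""
    return sequence.rstrip("A")


class TranscriptIndex:
    """Exact k-mer index over transcript sequences for seed lookup."""

    def __init__(self, transcriptome: Transcriptome, params: AssignParams | None = None):
        self.params = params or AssignParams()
        self.transcriptome = transcriptome
        self.gene_ids = transcriptome.gene_ids
        self.sequences = [transcriptome.sequences[g] for g in self.gene_ids]
        k = self.params.k
        index: dict[str, list[int]] = {}
        for gi, seq in enumerate(self.sequences):
            seen: set[str] = set()
            for pos in range(0, max(1, len(seq) - k + 1)):
                kmer = seq[pos : pos + k]
                if len(kmer) == k and kmer not in seen:
                    seen.add(kmer)
                    index.setdefault(kmer, []).append(gi)
        self._index = index

    def candidates(self, sequence: str) -> list[int]:
        """Candidate gene indices ranked by number of seed hits."""
        p = self.params
        span = sequence[: p.seed_span]
        hits: Counter[int] = Counter()
        get = self._index.get
        for pos in range(0, max(1, len(span) - p.k + 1), p.seed_stride):
            genes = get(span[pos : pos + p.k])
            if genes:
                hits.update(genes)
        ranked = [g for g, c in hits.most_common() if c >= p.min_seed_hits]
        return ranked[: p.max_candidates]


def _align_identity(
    read_seq: str, transcript: str, min_identity: float
) -> tuple[float, int, int]:
    """Identity of the read aligned as an infix of the transcript.

    The edit-distance search is banded at the distance that would already
    push identity below ``min_identity``; candidates beyond the band report
    identity 0 (they could never be accepted).
    """
    # 15% headroom: identity is scored over max(read, span), which can
    # slightly exceed the read length when the alignment spans deletions
    limit = int((1.0 - min_identity) * len(read_seq) * 1.15) + 2
    result = edlib.align(read_seq, transcript, mode="HW", task="locations", k=limit)
    dist = result["editDistance"]
    if dist < 0:
        return 0.0, -1, -1
    start, end = result["locations"][0]
    span = end - start + 1
    identity = 1.0 - dist / max(len(read_seq), span)
    return identity, start, end + 1


def assign_read(
    read: ReadRecord | str,
    index: TranscriptIndex,
    params: AssignParams | None = None,
) -> dict:
    """Assign one (tag-trimmed) read to a gene, or leave it unassigned.

    Returns a dict with ``gene_id`` (None when unassigned), the identity, the
    transcript-coordinate span of the alignment, and a ``multi_locus`` flag
    set when a second, distinct gene also clears the identity threshold.
    """
    params = params or index.params
    read_id = read.id if isinstance(read, ReadRecord) else ""
    seq = trim_polya(read.sequence if isinstance(read, ReadRecord) else read)
    none = {
        "read_id": read_id,
        "gene_id": None,
        "identity": np.nan,
        "t_start": -1,
        "t_end": -1,
        "multi_locus": False,
    }
    if not seq:
        return none
    scored = []
    for gi in index.candidates(seq):
        identity, start, end = _align_identity(
            seq, index.sequences[gi], params.min_identity
        )
        scored.append((identity, gi, start, end))
    if not scored:
        return none
    scored.sort(key=lambda s: (-s[0], s[1]))
    best = scored[0]
    if best[0] < params.min_identity:
        return none
    if len(scored) > 1 and scored[1][0] == best[0] and scored[1][1] != best[1]:
        return none  # equal-best across distinct genes
    multi = len(scored) > 1 and scored[1][0] >= params.min_identity
    return {
        "read_id": read_id,
        "gene_id": index.gene_ids[best[1]],
        "identity": best[0],
        "t_start": best[2],
        "t_end": best[3],
        "multi_locus": bool(multi),
    }


def assign_readset(
    reads: list[ReadRecord],
    index: TranscriptIndex,
    params: AssignParams | None = None,
) -> pd.DataFrame:
    """Assignment table with one row per read (unassigned rows keep NaN gene)."""
    rows = []
    for read in reads:
        row = assign_read(read, index, params)
        row["read_id"] = read.id
        rows.append(row)
    return pd.DataFrame(rows, columns=ASSIGN_COLUMNS)


def filter_rrna(
    assignments: pd.DataFrame, transcriptome: Transcriptome
) -> tuple[pd.DataFrame, float]:
    """Drop reads assigned to rRNA genes; report the removed fraction.

    The fraction is relative to all assigned reads (rRNA depletion is
    incomplete in the assay, and the share removed in silico is a standard
    per-sample quality metric).
    """
    rrna_ids = transcriptome.rrna_gene_ids
    if not rrna_ids:
        return assignments, 0.0
    assigned = assignments["gene_id"].notna()
    is_rrna = assignments["gene_id"].isin(rrna_ids)
    removed_fraction = float(is_rrna.sum() / assigned.sum()) if assigned.any() else 0.0
    return assignments[~is_rrna].reset_index(drop=True), removed_fraction


@dataclass
class CountMatrix:
    """Per (gene, sample) NAD-tagged and total assigned read counts."""

    nad: pd.DataFrame  # genes x samples
    total: pd.DataFrame  # genes x samples

    def __post_init__(self) -> None:
        if not self.nad.index.equals(self.total.index) or not self.nad.columns.equals(
            self.total.columns
        ):
            raise ValueError("nad and total matrices must share genes and samples")
        if (self.nad.to_numpy() < 0).any() or (
            self.nad.to_numpy() > self.total.to_numpy()
        ).any():
            raise ValueError("require 0 <= nad_reads <= total_reads per cell")

    @property
    def samples(self) -> list[str]:
        return list(self.nad.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.nad.index)

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        return CountMatrix(self.nad[sample_ids].copy(), self.total[sample_ids].copy())

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (gene, sample, nad_reads, total_reads)."""
        long = pd.concat(
            {
                "nad_reads": self.nad.stack(),
                "total_reads": self.total.stack(),
            },
            axis=1,
        ).reset_index()
        long.columns = ["gene_id", "sample_id", "nad_reads", "total_reads"]
        return long


def build_count_matrix(
    tag_calls: dict[str, pd.DataFrame],
    assignments: dict[str, pd.DataFrame],
    sample_sheet: pd.DataFrame,
    gene_ids: list[str],
) -> CountMatrix:
    """Aggregate per-sample tag calls and assignments into a CountMatrix.

    ``tag_calls`` and ``assignments`` map sample_id to that sample's tables
    (post rRNA removal).  Every read with a tag call must appear in the
    assignment table; a read missing there is a consistency error.
    """
    samples = list(sample_sheet["sample_id"])
    nad = pd.DataFrame(0, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    total = nad.copy()
    for sample in samples:
        calls = tag_calls[sample]
        assigned = assignments[sample]
        missing = set(calls["read_id"]) - set(assigned["read_id"])
        if missing:
            raise ValueError(
                f"sample {sample}: {len(missing)} reads have tag calls but no "
                "assignment record"
            )
        merged = assigned.merge(
            calls[["read_id", "is_tagged"]], on="read_id", how="left"
        )
        merged = merged[merged["gene_id"].notna()]
        merged = merged[merged["gene_id"].isin(nad.index)]
        counts = merged.groupby("gene_id").size()
        total.loc[counts.index, sample] = counts
        tagged = merged[merged["is_tagged"].fillna(False)]
        counts = tagged.groupby("gene_id").size()
        nad.loc[counts.index, sample] = counts
    return CountMatrix(nad, total)
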