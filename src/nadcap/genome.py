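"""Gene models and the transcriptome container.

Coordinates are 0-based half-open internally (GFF3's 1-based closed
convention is converted at I/O time).  CDS codon positions are stored
transcript-relative: ``cds_start`` is the offset of the first base of the
start codon, ``cds_stop`` the offset of the first base of the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GeneModel:
    id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    biotype: str = "mRNA"  # one of mRNA / ncRNA / rRNA
    cds_start: int | None = None
    cds_stop: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.id}: start must be < end")
        if self.biotype not in ("mRNA", "ncRNA", "rRNA"):
            raise ValueError(f"{self.id}: unknown biotype {self.biotype!r}")
        if self.biotype == "mRNA":
            if self.cds_start is None or self.cds_stop is None:
                raise ValueError(f"{self.id}: mRNA requires CDS annotations")
            length = self.end - self.start
            if not (0 <= self.cds_start < self.cds_stop <= length - 3):
                raise ValueError(f"{self.id}: CDS outside transcript span")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Transcriptome:
    """Gene models plus their sequences and simulation ground truth.

    ``base_expression`` holds per-gene relative abundances in the reference
    condition; ``condition_log2fc`` the per-gene log2 shift applied in the
    second condition; ``capped_fraction`` the per-gene probability that a
    transcript molecule carries the NAD+ cap.
    """

    genes: list[GeneModel]
    sequences: dict[str, str]
    contigs: dict[str, str] = field(default_factory=dict)
    conditions: tuple[str, str] = ("exponential", "stationary")
    base_expression: np.ndarray | None = None
    condition_log2fc: np.ndarray | None = None
    capped_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        missing = [g.id for g in self.genes if g.id not in self.sequences]
        if missing:
            raise ValueError(f"genes without sequence: {missing[:3]}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def gene(self, gene_id: str) -> GeneModel:
        if not hasattr(self, "_index"):
            self._index = {g.id: g for g in self.genes}
        return self._index[gene_id]

    def biotype_of(self, gene_id: str) -> str:
        return self.gene(gene_id).biotype

    @property
    def rrna_gene_ids(self) -> set[str]:
        return {g.id for g in self.genes if g.biotype == "rRNA"}

    def expression_weights(self, condition: str) -> np.ndarray:
        """Relative expression of every gene under ``condition``."""
        if self.base_expression is None:
            raise ValueError("transcriptome carries no expression model")
        if condition == self.conditions[0]:
            return self.base_expression
        if condition == self.conditions[1]:
            return self.base_expression * np.exp2(self.condition_log2fc)
        raise ValueError(
            f"unknown condition {condition!r}; expected one of {self.conditions}"
        )
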