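"""File formats: FASTQ(.gz), FASTA, GFF3, TSV tables, YAML configs, SAM import.

Readers and writers are mutual inverses on valid inputs.  Coordinates are
converted between the internal 0-based half-open convention and GFF3's
1-based closed convention here and nowhere else.
"""

from __future__ import annotations

import gzip
import os
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneModel, Transcriptome
from .records import ReadRecord

DEFAULT_QUALITY = 12  # constant Phred score written for simulated reads


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTQ/FASTA


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = read.quality or chr(33 + DEFAULT_QUALITY) * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    reads = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(33 + q) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(ReadRecord(rec.id, str(rec.seq), qual))
    return reads


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


# ---------------------------------------------------------------------- GFF3


def _cds_genomic_span(gene: GeneModel) -> tuple[int, int]:
    """Genomic half-open span of the CDS (start codon through stop codon)."""
    cs, ce = gene.cds_start, gene.cds_stop + 3
    if gene.strand == "+":
        return gene.start + cs, gene.start + ce
    return gene.end - ce, gene.end - cs


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for gene in genes:
            attrs = f"ID={gene.id};biotype={gene.biotype}"
            handle.write(
                "\t".join(
                    [
                        gene.contig,
                        "nadcap",
                        "gene",
                        str(gene.start + 1),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            if gene.biotype == "mRNA" and gene.cds_start is not None:
                g0, g1 = _cds_genomic_span(gene)
                handle.write(
                    "\t".join(
                        [
                            gene.contig,
                            "nadcap",
                            "CDS",
                            str(g0 + 1),
                            str(g1),
                            ".",
                            gene.strand,
                            "0",
                            f"ID=cds-{gene.id};Parent={gene.id}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        biotype = feat.attributes.get("biotype", ["mRNA"])[0]
        cds_start = cds_stop = None
        if biotype == "mRNA":
            for cds in db.children(feat, featuretype="CDS"):
                g0, g1 = cds.start - 1, cds.end
                if feat.strand == "+":
                    cds_start, cds_stop = g0 - start, g1 - start - 3
                else:
                    cds_start, cds_stop = end - g1, end - g0 - 3
        genes.append(
            GeneModel(
                id=feat.id,
                contig=feat.seqid,
                start=start,
                end=end,
                strand=feat.strand,
                biotype=biotype,
                cds_start=cds_start,
                cds_stop=cds_stop,
            )
        )
    return genes


def write_transcriptome(
    transcriptome: Transcriptome, prefix: str | Path
) -> dict[str, str]:
    """Write <prefix>.gff3, <prefix>.transcripts.fasta, <prefix>.genome.fasta."""
    prefix = str(prefix)
    paths = {
        "gff3": prefix + ".gff3",
        "transcripts": prefix + ".transcripts.fasta",
        "genome": prefix + ".genome.fasta",
    }
    write_gff3(transcriptome.genes, paths["gff3"])
    write_fasta(transcriptome.sequences, paths["transcripts"])
    if transcriptome.contigs:
        write_fasta(transcriptome.contigs, paths["genome"])
    return paths


def read_transcriptome(
    gff3_path: str | Path, transcripts_fasta: str | Path
) -> Transcriptome:
    genes = read_gff3(gff3_path)
    sequences = read_fasta(transcripts_fasta)
    return Transcriptome(genes=genes, sequences=sequences)


# ---------------------------------------------------------------------- TSVs


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    write_table(sheet, path)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = read_table(path)
    required = {"sample_id", "condition", "replicate", "adprc"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if not sheet["sample_id"].is_unique:
        raise ValueError("sample ids must be unique")
    return sheet


# --------------------------------------------------------------------- YAML


def write_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as handle:
        return yaml.safe_load(handle)


# ----------------------------------------------------------------- SAM import


def read_sam_assignments(path: str | Path) -> pd.DataFrame:
    """Import primary alignments from an external aligner as an assignment table.

    The reference names must be gene/transcript ids.  Identity is computed
    from the NM tag when present; reads without a primary alignment appear as
    unassigned rows.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_unmapped:
                rows.append(
                    {
                        "read_id": aln.query_name,
                        "gene_id": None,
                        "identity": float("nan"),
                        "t_start": -1,
                        "t_end": -1,
                        "multi_locus": False,
                    }
                )
                continue
            span = aln.reference_end - aln.reference_start
            if aln.has_tag("NM"):
                denom = max(aln.query_alignment_length, span)
                identity = 1.0 - aln.get_tag("NM") / denom if denom else 0.0
            else:
                identity = float("nan")
            rows.append(
                {
                    "read_id": aln.query_name,
                    "gene_id": aln.reference_name,
                    "identity": identity,
                    "t_start": aln.reference_start,
                    "t_end": aln.reference_end,
                    "multi_locus": False,
                }
            )
    from .assign import ASSIGN_COLUMNS

    return pd.DataFrame(rows, columns=ASSIGN_COLUMNS)
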