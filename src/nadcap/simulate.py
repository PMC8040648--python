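"""Synthetic tag-labeled direct-RNA sequencing experiments with ground truth.

The generator emulates the statistical structure of a two-condition bacterial
NAD+ capping experiment read by nanopore direct-RNA sequencing:

* a transcriptome of mRNA / ncRNA / rRNA genes with log-normal expression and
  a per-gene probability that a transcript molecule is NAD-capped (zero for
  most genes, with a designated subset where the capped fraction can exceed
  one half);
* enzyme-plus (ADPRC+) samples in which capped molecules carry the 39-nt tag
  at their 5' end, and enzyme-minus (ADPRC-) controls in which tags appear
  only at a small background rate, independent of capping;
* nanopore-like artefacts: per-base substitutions and indels, elevated
  miscalls in a short window downstream of the cap-tag junction, geometric
  5'-end truncation (a dozen or so bases on average), a poly(A) tail added
  before sequencing, ~30-50% rRNA reads, and a minimum read length of 98 nt.

Every emitted read has exactly one ground-truth row, so downstream stages can
be scored exactly.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, Transcriptome
from .records import ReadRecord
from .tagdetect import TAG39, TagSpec

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENC = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions.

    Rates are per base.  ``expression_dispersion`` is the log-normal sigma of
    per-gene mean expression.  The capped-fraction model is a three-part
    mixture over non-rRNA genes: fraction 0 with probability
    1 - capped_gene_fraction, otherwise a "low" uniform component and, for
    capped_high_share of capped genes, a "high" component reaching above 0.5
    (some genes produce the majority of their transcripts NAD-capped).
    """

    n_genes: int = 200
    n_rrna_genes: int = 3
    n_ncrna_genes: int | None = None  # default: up to 10, bounded by gene count
    transcript_length_range: tuple[int, int] = (300, 1500)
    expression_dispersion: float = 1.5
    capped_gene_fraction: float = 0.15
    capped_high_share: float = 0.25
    capped_low_range: tuple[float, float] = (0.005, 0.2)
    capped_high_range: tuple[float, float] = (0.3, 0.75)
    de_gene_fraction: float = 0.3
    de_log2fc_sd: float = 1.0
    rrna_read_fraction: float = 0.4
    sub_rate: float = 0.05
    ins_rate: float = 0.03
    del_rate: float = 0.04
    junction_error_rate: float = 0.15
    junction_window: int = 8
    five_prime_truncation_mean: float = 12.0
    min_read_length: int = 98
    background_tag_rate: float = 1e-4
    tagging_efficiency: float = 1.0
    polya_length: int = 30
    reads_per_sample: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_ncrna_genes is None:
            self.n_ncrna_genes = max(0, min(10, self.n_genes - self.n_rrna_genes - 1))
        if self.n_rrna_genes + self.n_ncrna_genes > self.n_genes:
            raise ValueError("biotype counts exceed n_genes")
        lo, hi = self.transcript_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid transcript_length_range")
        if lo < self.min_read_length:
            raise ValueError("transcript_length_range min must be >= min_read_length")
        for name in (
            "capped_gene_fraction",
            "capped_high_share",
            "de_gene_fraction",
            "rrna_read_fraction",
            "sub_rate",
            "ins_rate",
            "del_rate",
            "junction_error_rate",
            "background_tag_rate",
            "tagging_efficiency",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.five_prime_truncation_mean < 0:
            raise ValueError("five_prime_truncation_mean must be >= 0")


@dataclass
class SampleRow:
    """One row of the sample sheet."""

    sample_id: str
    condition: str
    replicate: int
    adprc: str  # "plus" or "minus"

    def __post_init__(self) -> None:
        if self.adprc not in ("plus", "minus"):
            raise ValueError("adprc must be 'plus' or 'minus'")


def make_sample_sheet(
    conditions: tuple[str, str] = ("exponential", "stationary"),
    plus_replicates: int = 3,
    minus_replicates: int = 2,
) -> pd.DataFrame:
    """Sample sheet for a two-condition experiment with ADPRC- controls."""
    rows = []
    for condition in conditions:
        for rep in range(1, plus_replicates + 1):
            rows.append((f"{condition}_plus_{rep}", condition, rep, "plus"))
        for rep in range(1, minus_replicates + 1):
            rows.append((f"{condition}_minus_{rep}", condition, rep, "minus"))
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "replicate", "adprc"]
    )


def sample_rng(config: SimConfig, sample_id: str) -> np.random.Generator:
    """Per-sample RNG stream: adding a sample never perturbs the others."""
    key = zlib.crc32(sample_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([config.seed, key]))


def make_transcriptome(config: SimConfig) -> Transcriptome:
    """Generate gene models, sequences, and ground-truth expression/capping.

    Genes are laid head-to-tail on a single contig with short spacers.  mRNA
    genes carry an annotated CDS with an in-frame start and stop codon.
    Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB10]))
    lo, hi = config.transcript_length_range
    n = config.n_genes

    biotypes = (
        ["rRNA"] * config.n_rrna_genes
        + ["ncRNA"] * config.n_ncrna_genes
        + ["mRNA"] * (n - config.n_rrna_genes - config.n_ncrna_genes)
    )

    genes: list[GeneModel] = []
    sequences: dict[str, str] = {}
    contig_parts: list[str] = []
    cursor = 0
    spacer = 50
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = _DECODE[rng.integers(0, 4, size=length)].tobytes().decode()
        biotype = biotypes[i]
        cds_start = cds_stop = None
        if biotype == "mRNA":
            # 5' UTR, then an open span ending in a planted stop codon.
            utr5 = int(rng.integers(10, max(11, min(51, length - 20))))
            coding_span = length - utr5 - 12  # leave >= 12 nt of 3' UTR
            n_codons = max(2, coding_span // 3)
            cds_start = utr5
            cds_stop = utr5 + 3 * (n_codons - 1)
            stop = STOP_CODONS[int(rng.integers(0, len(STOP_CODONS)))]
            seq = (
                seq[:cds_start]
                + "ATG"
                + seq[cds_start + 3 : cds_stop]
                + stop
                + seq[cds_stop + 3 :]
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene{i:04d}"
        genes.append(
            GeneModel(
                id=gene_id,
                contig="chr1",
                start=cursor,
                end=cursor + length,
                strand=strand,
                biotype=biotype,
                cds_start=cds_start,
                cds_stop=cds_stop,
            )
        )
        sequences[gene_id] = seq
        contig_parts.append(seq if strand == "+" else _revcomp(seq))
        contig_parts.append(
            _DECODE[rng.integers(0, 4, size=spacer)].tobytes().decode()
        )
        cursor += length + spacer

    base = rng.lognormal(mean=0.0, sigma=config.expression_dispersion, size=n)
    log2fc = np.where(
        rng.random(n) < config.de_gene_fraction,
        rng.normal(0.0, config.de_log2fc_sd, size=n),
        0.0,
    )

    capped = np.zeros(n)
    rrna_mask = np.array([b == "rRNA" for b in biotypes])
    is_capped_gene = (~rrna_mask) & (rng.random(n) < config.capped_gene_fraction)
    high = is_capped_gene & (rng.random(n) < config.capped_high_share)
    low = is_capped_gene & ~high
    capped[low] = rng.uniform(*config.capped_low_range, size=int(low.sum()))
    capped[high] = rng.uniform(*config.capped_high_range, size=int(high.sum()))

    return Transcriptome(
        genes=genes,
        sequences=sequences,
        contigs={"chr1": "".join(contig_parts)},
        base_expression=base,
        condition_log2fc=log2fc,
        capped_fraction=capped,
    )


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def corrupt_read(
    sequence: str,
    config: SimConfig,
    junction_offset: int | None,
    rng: np.random.Generator,
) -> str:
    """Apply nanopore-like substitution/insertion/deletion noise to one read.

    Bases within ``config.junction_window`` downstream of ``junction_offset``
    (the cap-tag junction) are substituted at the elevated
    ``junction_error_rate`` instead of ``sub_rate``.  Pure function of the
    RNG state.
    """
    arr = _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    out = _corrupt_encoded(arr, config, junction_offset, rng)
    return _DECODE[out].tobytes().decode()


def _corrupt_encoded(
    arr: np.ndarray,
    config: SimConfig,
    junction_offset: int | None,
    rng: np.random.Generator,
) -> np.ndarray:
    n = arr.size
    if n == 0:
        return arr
    p_sub = np.full(n, config.sub_rate)
    if junction_offset is not None:
        j0 = max(0, junction_offset)
        p_sub[j0 : j0 + config.junction_window] = config.junction_error_rate
    sub_mask = rng.random(n) < p_sub
    arr = arr.copy()
    arr[sub_mask] = (arr[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4

    del_mask = rng.random(n) < config.del_rate
    ins_mask = rng.random(n) < config.ins_rate
    counts = (~del_mask).astype(np.int64) + ins_mask
    out = np.repeat(arr, counts)
    if ins_mask.any():
        starts = np.cumsum(counts) - counts
        ins_pos = starts[ins_mask]
        out[ins_pos] = rng.integers(0, 4, size=ins_pos.size)
    return out


def _corrupt_batch(
    molecules: list[np.ndarray],
    junctions: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Apply the error model to many molecules in one set of vector draws.

    Statistically identical to applying :func:`corrupt_read` per molecule;
    draws are made over the concatenation for speed.
    """
    lens = np.array([m.size for m in molecules], dtype=np.int64)
    nonempty = lens > 0
    if not nonempty.any():
        return [m.copy() for m in molecules]
    big = np.concatenate([m for m in molecules if m.size])
    ne_lens = lens[nonempty]
    offsets = np.cumsum(ne_lens) - ne_lens
    total = big.size

    p_sub = np.full(total, config.sub_rate, dtype=np.float32)
    ne_junc = junctions[nonempty]
    for row in np.flatnonzero(ne_junc >= 0):
        pos = offsets[row] + ne_junc[row]
        end = min(pos + config.junction_window, offsets[row] + ne_lens[row])
        if pos < end:
            p_sub[pos:end] = config.junction_error_rate
    sub_mask = rng.random(total, dtype=np.float32) < p_sub
    big = big.copy()
    big[sub_mask] = (big[sub_mask] + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4

    del_mask = rng.random(total, dtype=np.float32) < np.float32(config.del_rate)
    ins_mask = rng.random(total, dtype=np.float32) < np.float32(config.ins_rate)
    counts = (~del_mask).astype(np.int32) + ins_mask
    out = np.repeat(big, counts)
    if ins_mask.any():
        starts = np.cumsum(counts) - counts
        ins_pos = starts[ins_mask]
        out[ins_pos] = rng.integers(0, 4, size=ins_pos.size)

    cum = np.concatenate([[0], np.cumsum(counts)])
    out_bounds = cum[np.concatenate([offsets, [total]])]
    results: list[np.ndarray] = []
    ne_row = 0
    empty = np.empty(0, dtype=np.uint8)
    for i in range(len(molecules)):
        if lens[i] == 0:
            results.append(empty)
        else:
            results.append(out[out_bounds[ne_row] : out_bounds[ne_row + 1]])
            ne_row += 1
    return results


def simulate_sample(
    transcriptome: Transcriptome,
    sheet_row: SampleRow | pd.Series,
    config: SimConfig,
    tag: TagSpec | None = None,
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one sample's read set plus its ground-truth table.

    Reads are drawn per gene proportionally to condition-specific expression
    (with the rRNA read share fixed at ``rrna_read_fraction``); capped
    molecules are tag-prepended in ADPRC+ samples at ``tagging_efficiency``
    while in ADPRC- controls tags appear only at ``background_tag_rate``,
    independent of capping.  Reads shorter than ``min_read_length`` after the
    error model are discarded.
    """
    if len(transcriptome) == 0:
        raise ValueError("transcriptome is empty")
    if isinstance(sheet_row, pd.Series):
        sheet_row = SampleRow(
            sample_id=str(sheet_row["sample_id"]),
            condition=str(sheet_row["condition"]),
            replicate=int(sheet_row["replicate"]),
            adprc=str(sheet_row["adprc"]),
        )
    tag = tag or TagSpec(tag_sequence=TAG39)
    n_reads = config.reads_per_sample if n_reads is None else n_reads
    rng = rng if rng is not None else sample_rng(config, sheet_row.sample_id)

    weights = transcriptome.expression_weights(sheet_row.condition).astype(float)
    rrna = np.array([g.biotype == "rRNA" for g in transcriptome.genes])
    probs = np.zeros_like(weights)
    if rrna.any() and config.rrna_read_fraction > 0:
        probs[rrna] = config.rrna_read_fraction * weights[rrna] / weights[rrna].sum()
        probs[~rrna] = (1 - config.rrna_read_fraction) * weights[~rrna] / weights[~rrna].sum()
    else:
        probs[~rrna] = weights[~rrna] / weights[~rrna].sum()

    gene_idx = rng.choice(len(weights), size=n_reads, p=probs)
    capped = rng.random(n_reads) < transcriptome.capped_fraction[gene_idx]
    if sheet_row.adprc == "plus":
        tagged = np.where(
            capped,
            rng.random(n_reads) < config.tagging_efficiency,
            rng.random(n_reads) < config.background_tag_rate,
        )
    else:
        tagged = rng.random(n_reads) < config.background_tag_rate

    if config.five_prime_truncation_mean > 0:
        p_geom = 1.0 / (config.five_prime_truncation_mean + 1.0)
        trunc = rng.geometric(p_geom, size=n_reads) - 1
    else:
        trunc = np.zeros(n_reads, dtype=np.int64)

    tag_arr = _ENC[np.frombuffer(tag.tag_sequence.encode(), dtype=np.uint8)]
    polya = np.zeros(config.polya_length, dtype=np.uint8)  # A == 0
    plain: dict[int, np.ndarray] = {}
    with_tag: dict[int, np.ndarray] = {}
    gene_ids = transcriptome.gene_ids

    # assemble per-read molecules (views into cached per-gene arrays), then
    # run the error model over concatenated batches for speed
    molecules: list[np.ndarray] = []
    junctions = np.full(n_reads, -1, dtype=np.int64)
    for i in range(n_reads):
        g = int(gene_idx[i])
        if g not in plain:
            t_arr = _ENC[
                np.frombuffer(transcriptome.sequences[gene_ids[g]].encode(), dtype=np.uint8)
            ]
            plain[g] = np.concatenate([t_arr, polya])
            with_tag[g] = np.concatenate([tag_arr, t_arr, polya])
        base = with_tag[g] if tagged[i] else plain[g]
        k = int(trunc[i])
        molecules.append(base[k:])
        if tagged[i]:
            junctions[i] = max(0, tag_arr.size - k)

    reads: list[ReadRecord] = []
    truth_cols: dict[str, list] = {k: [] for k in
                                   ("read_id", "gene_id", "is_capped",
                                    "is_tagged_in_output", "truncation")}
    batch_bases = 20_000_000
    start = 0
    while start < n_reads:
        stop = start
        total = 0
        while stop < n_reads and (total == 0 or total < batch_bases):
            total += molecules[stop].size
            stop += 1
        outputs = _corrupt_batch(molecules[start:stop], junctions[start:stop], config, rng)
        for i, out in zip(range(start, stop), outputs):
            if out.size < config.min_read_length:
                continue
            read_id = f"{sheet_row.sample_id}:{i:07d}"
            reads.append(ReadRecord(read_id, _DECODE[out].tobytes().decode()))
            truth_cols["read_id"].append(read_id)
            truth_cols["gene_id"].append(gene_ids[int(gene_idx[i])])
            truth_cols["is_capped"].append(bool(capped[i]))
            truth_cols["is_tagged_in_output"].append(bool(tagged[i]))
            truth_cols["truncation"].append(int(trunc[i]))
        start = stop

    truth = pd.DataFrame(truth_cols)
    if not reads:
        warnings.warn(
            f"sample {sheet_row.sample_id}: no reads survived the length filter",
            stacklevel=2,
        )
    return reads, truth


def simulate_experiment(
    config: SimConfig,
    sheet: pd.DataFrame | None = None,
    tag: TagSpec | None = None,
    outdir: str | None = None,
) -> tuple[Transcriptome, pd.DataFrame, dict[str, list[ReadRecord]], dict[str, pd.DataFrame]]:
    """Simulate a whole multi-sample experiment; optionally write it to disk.

    Returns (transcriptome, sample sheet, reads by sample, truth by sample).
    With ``outdir`` set, writes gene models (GFF3 + FASTA), per-sample FASTQ
    and truth TSVs, the sample sheet, and a YAML echo of the configuration.
    """
    from . import io as nio
    from dataclasses import asdict
    from pathlib import Path

    sheet = sheet if sheet is not None else make_sample_sheet()
    tag = tag or TagSpec(tag_sequence=TAG39)
    transcriptome = make_transcriptome(config)
    reads_by_sample: dict[str, list[ReadRecord]] = {}
    truth_by_sample: dict[str, pd.DataFrame] = {}
    for _, row in sheet.iterrows():
        reads, truth = simulate_sample(transcriptome, row, config, tag=tag)
        reads_by_sample[row["sample_id"]] = reads
        truth_by_sample[row["sample_id"]] = truth

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_transcriptome(transcriptome, out / "reference")
        nio.write_sample_sheet(sheet, out / "samples.tsv")
        for sample, reads in reads_by_sample.items():
            nio.write_fastq(reads, out / f"{sample}.fastq")
            nio.write_table(truth_by_sample[sample], out / f"truth.{sample}.tsv")
        echo = asdict(config)
        echo["transcript_length_range"] = list(echo["transcript_length_range"])
        for key in ("capped_low_range", "capped_high_range"):
            echo[key] = list(echo[key])
        nio.write_yaml(echo, out / "sim_config.yaml")
    return transcriptome, sheet, reads_by_sample, truth_by_sample
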