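"""Synthetic-data generator: determinism, error model, distributional recovery."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from nadcap.simulate import (
    SampleRow,
    SimConfig,
    corrupt_read,
    make_sample_sheet,
    make_transcriptome,
    sample_rng,
    simulate_sample,
)
from nadcap.tagdetect import TAG39, TagSpec


def binom_ci(p: float, n: int) -> tuple[float, float]:
    half = 1.96 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half


NOISELESS = dict(
    sub_rate=0.0,
    ins_rate=0.0,
    del_rate=0.0,
    junction_error_rate=0.0,
    five_prime_truncation_mean=0.0,
)


class TestMakeTranscriptome:
    def test_minimal_single_gene(self):
        config = SimConfig(
            n_genes=1, n_rrna_genes=0, transcript_length_range=(100, 100)
        )
        tx = make_transcriptome(config)
        assert len(tx) == 1
        gene = tx.genes[0]
        assert gene.biotype == "mRNA"
        assert gene.length == 100
        seq = tx.sequences[gene.id]
        assert seq[gene.cds_start : gene.cds_start + 3] == "ATG"
        assert seq[gene.cds_stop : gene.cds_stop + 3] in ("TAA", "TAG", "TGA")

    def test_deterministic_for_fixed_seed(self):
        config = SimConfig(n_genes=20, seed=42)
        a = make_transcriptome(config)
        b = make_transcriptome(config)
        assert a.sequences == b.sequences
        assert np.array_equal(a.base_expression, b.base_expression)
        assert np.array_equal(a.capped_fraction, b.capped_fraction)

    def test_biotype_counts(self):
        config = SimConfig(n_genes=200, n_rrna_genes=2)
        tx = make_transcriptome(config)
        biotypes = [g.biotype for g in tx.genes]
        assert biotypes.count("rRNA") == 2
        assert len(biotypes) - biotypes.count("rRNA") == 198

    def test_unique_ids_and_cds_in_frame(self):
        tx = make_transcriptome(SimConfig(n_genes=50, seed=3))
        assert len(set(tx.gene_ids)) == 50
        for g in tx.genes:
            if g.biotype == "mRNA":
                assert (g.cds_stop - g.cds_start) % 3 == 0

    def test_invalid_length_range_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(transcript_length_range=(200, 100))
        with pytest.raises(ValueError):
            SimConfig(transcript_length_range=(50, 100))  # below min read length

    def test_capped_fraction_mixture_shape(self):
        tx = make_transcriptome(SimConfig(n_genes=500, seed=1))
        capped = tx.capped_fraction
        rrna = np.array([g.biotype == "rRNA" for g in tx.genes])
        assert (capped[rrna] == 0).all()
        assert (capped == 0).mean() > 0.5  # most genes produce no NAD-RNA
        assert capped.max() >= 0.5  # designated high-capping subset


class TestCorruptRead:
    def test_zero_rates_identity(self):
        config = SimConfig(**NOISELESS)
        rng = np.random.default_rng(0)
        seq = "ACGTACGTACGTAAAA" * 10
        assert corrupt_read(seq, config, None, rng) == seq

    def test_forced_substitution_changes_every_base(self):
        config = SimConfig(sub_rate=1.0, ins_rate=0.0, del_rate=0.0,
                           junction_error_rate=1.0)
        rng = np.random.default_rng(0)
        seq = "ACGT" * 50
        out = corrupt_read(seq, config, None, rng)
        assert len(out) == len(seq)
        assert all(a != b for a, b in zip(seq, out))

    def test_substitution_rate_within_binomial_ci(self):
        config = SimConfig(sub_rate=0.1, ins_rate=0.0, del_rate=0.0)
        rng = np.random.default_rng(123)
        n = 10_000
        seq = "".join(np.random.default_rng(5).choice(list("ACGT"), size=n))
        out = corrupt_read(seq, config, None, rng)
        mismatches = sum(a != b for a, b in zip(seq, out))
        lo, hi = binom_ci(0.1, n)
        assert lo <= mismatches / n <= hi

    def test_junction_window_uses_elevated_rate(self):
        config = SimConfig(sub_rate=0.0, ins_rate=0.0, del_rate=0.0,
                           junction_error_rate=1.0, junction_window=8)
        rng = np.random.default_rng(7)
        seq = "A" * 50
        out = corrupt_read(seq, config, 20, rng)
        assert out[:20] == "A" * 20
        assert all(b != "A" for b in out[20:28])
        assert out[28:] == "A" * 22

    def test_indel_rates_shift_length(self):
        config = SimConfig(sub_rate=0.0, ins_rate=0.05, del_rate=0.0)
        rng = np.random.default_rng(11)
        n = 20_000
        seq = "G" * n
        out = corrupt_read(seq, config, None, rng)
        lo, hi = binom_ci(0.05, n)
        assert lo <= (len(out) - n) / n <= hi


class TestSimulateSample:
    def test_noise_free_reads_are_tag_plus_transcript_plus_polya(self):
        config = SimConfig(
            n_genes=1,
            n_rrna_genes=0,
            transcript_length_range=(200, 200),
            capped_gene_fraction=1.0,
            capped_low_range=(1.0, 1.0),
            capped_high_share=0.0,
            rrna_read_fraction=0.0,
            **NOISELESS,
        )
        tx = make_transcriptome(config)
        tx.capped_fraction[:] = 1.0
        row = SampleRow("s1", "exponential", 1, "plus")
        reads, truth = simulate_sample(tx, row, config, n_reads=200)
        expected = TAG39 + tx.sequences[tx.gene_ids[0]] + "A" * config.polya_length
        assert truth["is_tagged_in_output"].all()
        assert all(r.sequence == expected for r in reads)

    def test_truth_table_one_row_per_read(self):
        config = SimConfig(n_genes=20, seed=5)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "stationary", 1, "plus")
        reads, truth = simulate_sample(tx, row, config, n_reads=2000)
        assert len(reads) == len(truth)
        assert truth["read_id"].is_unique
        assert set(truth["gene_id"]).issubset(set(tx.gene_ids))

    def test_determinism_per_sample_stream(self):
        config = SimConfig(n_genes=20, seed=9)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "exponential", 1, "plus")
        r1, t1 = simulate_sample(tx, row, config, n_reads=500)
        r2, t2 = simulate_sample(tx, row, config, n_reads=500)
        assert [r.sequence for r in r1] == [r.sequence for r in r2]
        assert t1.equals(t2)

    def test_adprc_minus_background_tagging_rate(self):
        # Tag carriage in controls is a pure background process at the
        # configured rate, independent of capping.
        config = SimConfig(
            n_genes=10,
            n_rrna_genes=0,
            rrna_read_fraction=0.0,
            background_tag_rate=1e-3,
            seed=21,
            **NOISELESS,
        )
        tx = make_transcriptome(config)
        row = SampleRow("ctrl", "exponential", 1, "minus")
        n = 200_000
        _, truth = simulate_sample(tx, row, config, n_reads=n)
        rate = truth["is_tagged_in_output"].mean()
        lo, hi = binom_ci(1e-3, n)
        assert lo <= rate <= hi
        capped = truth[truth["is_capped"]]
        if len(capped) > 1000:
            lo2, hi2 = binom_ci(1e-3, len(capped))
            assert lo2 - 1e-3 <= capped["is_tagged_in_output"].mean() <= hi2 + 1e-3

    def test_rrna_read_fraction_recovered(self):
        config = SimConfig(n_genes=50, n_rrna_genes=3, rrna_read_fraction=0.4, seed=13)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "exponential", 1, "plus")
        n = 100_000
        _, truth = simulate_sample(tx, row, config, n_reads=n)
        rrna_ids = tx.rrna_gene_ids
        frac = truth["gene_id"].isin(rrna_ids).mean()
        lo, hi = binom_ci(0.4, n)
        assert lo <= frac <= hi

    def test_min_read_length_enforced(self):
        config = SimConfig(n_genes=10, seed=2)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "exponential", 1, "plus")
        reads, _ = simulate_sample(tx, row, config, n_reads=2000)
        assert min(len(r) for r in reads) >= config.min_read_length

    def test_unknown_condition_rejected(self):
        config = SimConfig(n_genes=5)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "lag", 1, "plus")
        with pytest.raises(ValueError, match="unknown condition"):
            simulate_sample(tx, row, config, n_reads=10)

    def test_truncation_mean_matches_geometric_model(self):
        config = SimConfig(n_genes=10, seed=31, five_prime_truncation_mean=12.0)
        tx = make_transcriptome(config)
        row = SampleRow("s1", "exponential", 1, "plus")
        _, truth = simulate_sample(tx, row, config, n_reads=20_000)
        mean = truth["truncation"].mean()
        se = truth["truncation"].std() / np.sqrt(len(truth))
        assert abs(mean - 12.0) < 4 * se + 0.2


class TestSampleSheet:
    def test_default_sheet_structure(self):
        sheet = make_sample_sheet()
        assert len(sheet) == 10
        counts = sheet.groupby(["condition", "adprc"]).size()
        assert (counts.xs("plus", level="adprc") == 3).all()
        assert (counts.xs("minus", level="adprc") == 2).all()
        assert sheet["sample_id"].is_unique

    def test_sample_rng_streams_independent(self):
        config = SimConfig(seed=4)
        a = sample_rng(config, "s1").integers(0, 2**31, size=5)
        b = sample_rng(config, "s2").integers(0, 2**31, size=5)
        a2 = sample_rng(config, "s1").integers(0, 2**31, size=5)
        assert np.array_equal(a, a2)
        assert not np.array_equal(a, b)
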