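"""Normalization, NB differential test, BH adjustment, correlations, codons."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nadcap.genome import GeneModel, Transcriptome
from nadcap.stats import (
    bh_adjust,
    codon_presence,
    fc_correlation,
    nb_test,
    nb_test_table,
    size_factors,
)

from _oracles import brute_force_bh


class TestSizeFactors:
    def test_identical_libraries_give_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        assert np.allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_library_closed_form(self):
        # library b = 2 x library a -> factors (1/sqrt(2), sqrt(2)) after
        # geometric-mean rescaling of the median-of-ratios formula.
        rng = np.random.default_rng(3)
        a = rng.integers(1, 500, size=40)
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        f = size_factors(counts)
        assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 300, size=(50, 3)), columns=list("abc"))
        shuffled = counts.sample(frac=1, random_state=1)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(1, 300, size=(60, 3)), columns=list("abc"))
        scaled = counts.copy()
        scaled["b"] = scaled["b"] * 3
        f0 = size_factors(counts)
        f1 = size_factors(scaled)
        # ratio between sample factors changes by exactly 3 (global rescale aside)
        assert np.isclose((f1["b"] / f1["a"]) / (f0["b"] / f0["a"]), 3.0)

    def test_fallback_to_total_count_with_warning(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 7]})
        with pytest.warns(UserWarning, match="falling back"):
            f = size_factors(counts)
        assert np.allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [1, 2]}))


class TestNbTest:
    def test_null_case_identical_counts(self):
        counts = [50, 50, 50, 50, 50, 50]
        groups = ["A"] * 3 + ["B"] * 3
        lfc, p = nb_test(counts, groups, factors=np.ones(6))
        assert lfc == 0.0
        assert p > 0.9

    def test_fourfold_change_recovered_at_large_counts(self):
        rng = np.random.default_rng(11)
        lfcs = []
        for _ in range(30):
            a = rng.poisson(4000, size=3)
            b = rng.poisson(16000, size=3)
            lfc, _ = nb_test(np.concatenate([a, b]), ["A"] * 3 + ["B"] * 3,
                             factors=np.ones(6))
            lfcs.append(lfc)
        assert np.mean(lfcs) == pytest.approx(2.0, abs=0.05)

    def test_all_zero_gene(self):
        lfc, p = nb_test([0] * 6, ["A"] * 3 + ["B"] * 3, factors=np.ones(6))
        assert (lfc, p) == (0.0, 1.0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            nb_test([1, 2, 3], ["A", "A", "B"], factors=np.ones(3))

    def test_poisson_null_type_one_error_calibrated(self):
        # Seeded Poisson null, no true differences: the rejection rate at
        # nominal 0.05 should be statistically consistent with 0.05.
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(3):
            mu = rng.lognormal(np.log(10.0), 1.0, size=2000)
            k = rng.poisson(mu[:, None] * np.ones(6)[None, :])
            res = nb_test_table(pd.DataFrame(k), np.array(["A"] * 3 + ["B"] * 3))
            ps.append(res["pvalue"].to_numpy())
        p = np.concatenate(ps)
        rate = (p <= 0.05).mean()
        half = 1.96 * np.sqrt(rate * (1 - rate) / p.size)
        assert rate - half <= 0.05 <= rate + half

    def test_pvalues_uniform_under_null_ks(self):
        rng = np.random.default_rng(8)
        mu = rng.lognormal(np.log(30.0), 0.8, size=3000)
        k = rng.poisson(mu[:, None] * np.ones(6)[None, :])
        res = nb_test_table(pd.DataFrame(k), np.array(["A"] * 3 + ["B"] * 3))
        from scipy import stats as sps

        # discreteness and plug-in variance keep this from exact uniformity;
        # require no gross deviation
        stat = sps.kstest(res["pvalue"], "uniform").statistic
        assert stat < 0.05


class TestBhAdjust:
    def test_worked_example(self):
        adjusted = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), brute_force_bh(pvals))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone_in_order_statistics(self, pvals):
        adjusted = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(adjusted)[order]) >= -1e-12).all()
        assert (np.asarray(adjusted) >= np.asarray(pvals) - 1e-12).all()
        assert (np.asarray(adjusted) <= 1.0).all()


class TestFcCorrelation:
    def _frame(self, x, y):
        return pd.DataFrame({"log2FC_total": x, "log2FC_nad": y})

    def test_perfect_correlation(self):
        x = np.linspace(-2, 2, 20)
        assert fc_correlation(self._frame(x, x))["r"] == pytest.approx(1.0)
        assert fc_correlation(self._frame(x, -x))["r"] == pytest.approx(-1.0)

    def test_attenuation_matches_closed_form(self):
        # Shared true fold change + independent noise attenuates r to
        # tau^2 / sqrt((tau^2+sx^2)(tau^2+sy^2)).
        rng = np.random.default_rng(12)
        n, tau, sx, sy = 4000, 1.0, 0.6, 0.9
        fc = rng.normal(0, tau, n)
        x = fc + rng.normal(0, sx, n)
        y = fc + rng.normal(0, sy, n)
        expected = tau**2 / np.sqrt((tau**2 + sx**2) * (tau**2 + sy**2))
        r = fc_correlation(self._frame(x, y))["r"]
        assert r == pytest.approx(expected, abs=3 / np.sqrt(n))

    def test_nonfinite_excluded_and_counted(self):
        x = [0.0, 1.0, 2.0, np.nan, 3.0]
        y = [0.1, 0.9, 2.2, 1.0, np.inf]
        out = fc_correlation(self._frame(x, y))
        assert out["n_used"] == 3
        assert out["n_excluded"] == 2

    def test_zero_variance_undefined(self):
        out = fc_correlation(self._frame([1.0, 1.0, 1.0], [0.5, 0.7, 0.2]))
        assert np.isnan(out["r"])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            fc_correlation(self._frame([1.0, np.nan], [1.0, 2.0]))


def _mrna_tx(cds_start=20, cds_stop=80, length=200):
    gene = GeneModel(
        id="g", contig="c", start=0, end=length, biotype="mRNA",
        cds_start=cds_start, cds_stop=cds_stop,
    )
    return Transcriptome(genes=[gene], sequences={"g": "A" * length})


class TestCodonPresence:
    def _run(self, spans, tagged):
        tx = _mrna_tx()
        assignments = {
            "s1": pd.DataFrame(
                {
                    "read_id": [f"r{i}" for i in range(len(spans))],
                    "gene_id": ["g"] * len(spans),
                    "t_start": [s for s, _ in spans],
                    "t_end": [e for _, e in spans],
                }
            )
        }
        calls = {
            "s1": pd.DataFrame(
                {"read_id": [f"r{i}" for i in range(len(spans))], "is_tagged": tagged}
            )
        }
        sheet = pd.DataFrame(
            {"sample_id": ["s1"], "condition": ["exp"], "replicate": [1], "adprc": ["plus"]}
        )
        return codon_presence(assignments, calls, tx, sheet)

    def test_full_length_read_contains_both(self):
        out = self._run([(0, 200)], [True])
        row = out[out.read_class == "NAD-mRNA"].iloc[0]
        assert row.start_codon_fraction == 1.0
        assert row.stop_codon_fraction == 1.0

    def test_read_starting_inside_cds_misses_start(self):
        out = self._run([(30, 200)], [False])
        row = out[out.read_class == "non-NAD-mRNA"].iloc[0]
        assert row.start_codon_fraction == 0.0
        assert row.stop_codon_fraction == 1.0

    def test_truncation_tail_mass_matches_geometric_model(self):
        # 5' truncation ~ Geometric(mean 12): the start codon (at offset 20)
        # survives with probability P(K <= 20) = 1 - (12/13)^21.
        rng = np.random.default_rng(9)
        n = 20000
        k = rng.geometric(1 / 13.0, size=n) - 1
        spans = [(int(min(ki, 200)), 200) for ki in k]
        out = self._run(spans, [True] * n)
        row = out[out.read_class == "NAD-mRNA"].iloc[0]
        expected = 1 - (12 / 13) ** 21
        half = 1.96 * np.sqrt(expected * (1 - expected) / n)
        assert abs(row.start_codon_fraction - expected) <= half + 1e-9
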