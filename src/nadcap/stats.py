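"""Between-condition differential statistics and codon-presence analysis.

Counts are normalized with the median-of-ratios size factors familiar from
bulk RNA-seq; per-gene differential expression between two conditions uses a
negative-binomial Wald test with a method-of-moments gene-wise dispersion (a
deliberate simplification of the empirical-Bayes shrinkage machinery of the
established tools, validated by type-I-error simulation rather than by
matching their output).  Multiple testing is controlled with the
Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .assign import CountMatrix
from .genome import Transcriptome

PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8


def size_factors(counts: pd.DataFrame, method: str = "median_of_ratios") -> pd.Series:
    """Per-sample scale factors, rescaled to geometric mean 1.

    ``median_of_ratios``: for genes with all-positive counts, each sample's
    factor is the median of count / (gene geometric mean).  When no gene is
    positive in every sample the function falls back to total-count scaling
    with a warning.  ``total_count`` scales by library size directly.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    arr = counts.to_numpy(dtype=float)
    if method == "median_of_ratios":
        positive = (arr > 0).all(axis=1)
        if not positive.any():
            warnings.warn(
                "no gene has positive counts in all samples; "
                "falling back to total-count scaling",
                stacklevel=2,
            )
            return size_factors(counts, method="total_count")
        sub = arr[positive]
        log_geomean = np.log(sub).mean(axis=1)
        factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    elif method == "total_count":
        factors = arr.sum(axis=0)
        if (factors == 0).any():
            raise ValueError("sample with zero total counts")
    else:
        raise ValueError(f"unknown method {method!r}")
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


PRIOR_DF = 10.0


def _moments_dispersion(y: np.ndarray, groups: np.ndarray, inv_s: np.ndarray) -> np.ndarray:
    """Gene-wise NB dispersion by method of moments, pooled across groups.

    ``y`` is genes x samples of normalized counts.  Within each group,
    Var(y) ~ mu * mean(1/s) + alpha * mu^2; solve for alpha and pool by
    degrees of freedom.  The raw gene-wise estimate has only a handful of
    degrees of freedom, so it is moderated toward the trimmed cross-gene
    common dispersion with PRIOR_DF pseudo-degrees (flooring a noisier
    estimate would otherwise bias the variance upward).  Floored at
    MIN_DISPERSION.
    """
    num = np.zeros(y.shape[0])
    den = 0.0
    for g in np.unique(groups):
        cols = groups == g
        n = int(cols.sum())
        if n < 2:
            continue
        mu = y[:, cols].mean(axis=1)
        var = y[:, cols].var(axis=1, ddof=1)
        shot = mu * inv_s[cols].mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            alpha = np.where(mu > 0, (var - shot) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += (n - 1) * alpha
        den += n - 1
    gene_alpha = num / max(den, 1.0)
    expressed = y.mean(axis=1) > 0
    common = (
        float(sps.trim_mean(gene_alpha[expressed], 0.1)) if expressed.sum() >= 10 else 0.0
    )
    moderated = (den * gene_alpha + PRIOR_DF * common) / (den + PRIOR_DF)
    return np.maximum(moderated, MIN_DISPERSION)


def nb_test_table(
    counts: pd.DataFrame,
    groups: pd.Series | np.ndarray,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """NB Wald test for every gene: condition B vs A log2 fold change and p.

    ``groups`` holds exactly two labels; fold changes are reported for the
    second label (sorted order) over the first.  Normalized group means get a
    pseudocount of 0.5 in the fold change so zero-count genes stay finite.
    The Wald statistic is referred to the standard normal (the variance in
    the denominator is model-based, mu/s + alpha*mu^2, not a raw sample
    variance, so the normal reference is the calibrated choice even at few
    replicates; checked by null simulation).  All-zero genes report log2FC 0,
    p 1.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {list(labels)}")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 replicates")
    if factors is None:
        factors = size_factors(counts)
    s = factors.to_numpy(dtype=float)
    k = counts.to_numpy(dtype=float)
    y = k / s[None, :]
    inv_s = 1.0 / s

    a_cols = groups == labels[0]
    b_cols = groups == labels[1]
    mu_a = y[:, a_cols].mean(axis=1)
    mu_b = y[:, b_cols].mean(axis=1)
    alpha = _moments_dispersion(y, groups, inv_s)

    lfc = np.log2(mu_b + PSEUDOCOUNT) - np.log2(mu_a + PSEUDOCOUNT)
    n_a, n_b = int(a_cols.sum()), int(b_cols.sum())
    var_mu_a = (mu_a * inv_s[a_cols].mean() + alpha * mu_a**2) / n_a
    var_mu_b = (mu_b * inv_s[b_cols].mean() + alpha * mu_b**2) / n_b
    ln2 = np.log(2.0)
    se = np.sqrt(
        var_mu_a / (mu_a + PSEUDOCOUNT) ** 2 + var_mu_b / (mu_b + PSEUDOCOUNT) ** 2
    ) / ln2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    all_zero = (k == 0).all(axis=1)
    lfc[all_zero] = 0.0
    p[all_zero] = 1.0
    base_mean = y.mean(axis=1)
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": np.clip(p, 0.0, 1.0),
            "dispersion": alpha,
        },
        index=counts.index,
    )


def nb_test(
    counts: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
    factors: pd.Series | np.ndarray | None = None,
) -> tuple[float, float]:
    """Single-gene convenience wrapper around :func:`nb_test_table`."""
    arr = np.asarray(counts, dtype=float)[None, :]
    frame = pd.DataFrame(arr, index=["gene"], columns=range(arr.shape[1]))
    if factors is not None:
        factors = pd.Series(np.asarray(factors, dtype=float), index=frame.columns)
    row = nb_test_table(frame, groups, factors).iloc[0]
    return float(row["log2FoldChange"]), float(row["pvalue"])


def bh_adjust(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    counts: CountMatrix,
    sample_sheet: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-condition DE of total transcripts and NAD-RNAs per gene.

    ADPRC+ samples only.  Size factors come from the total-count matrix
    (library size is a property of the sample) and are shared with the
    NAD-RNA test.  Significance (BH-adjusted p <= ``alpha``) is defined on
    the total-transcript test, matching the role of the NAD fold change as
    the quantity whose association with expression change is examined.
    """
    plus = sample_sheet[sample_sheet["adprc"] == "plus"]
    cols = [s for s in plus["sample_id"] if s in counts.samples]
    groups = plus.set_index("sample_id").loc[cols, "condition"]
    sub = counts.subset_samples(cols)
    factors = size_factors(sub.total)
    total_de = nb_test_table(sub.total, groups, factors)
    nad_de = nb_test_table(sub.nad, groups, factors)
    padj = bh_adjust(total_de["pvalue"].to_numpy())
    result = pd.DataFrame(
        {
            "baseMean": total_de["baseMean"],
            "log2FC_total": total_de["log2FoldChange"],
            "log2FC_nad": nad_de["log2FoldChange"],
            "pvalue": total_de["pvalue"],
            "padj": padj,
            "significant": padj <= alpha,
        },
        index=sub.total.index,
    )
    return result


def fc_correlation(de: pd.DataFrame, genes: set[str] | None = None) -> dict:
    """Pearson correlation between NAD-RNA and total log2 fold changes.

    Restricted to ``genes`` when given (typically the high-confidence union).
    Genes with non-finite fold changes are excluded and counted.  Zero
    variance in either series makes the correlation undefined (NaN).
    """
    table = de.loc[de.index.intersection(list(genes))] if genes is not None else de
    x = table["log2FC_total"].to_numpy()
    y = table["log2FC_nad"].to_numpy()
    finite = np.isfinite(x) & np.isfinite(y)
    n_used = int(finite.sum())
    if n_used < 3:
        raise ValueError("need at least 3 genes with finite fold changes")
    x, y = x[finite], y[finite]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r = float("nan")
    else:
        r = float(sps.pearsonr(x, y).statistic)
    return {"r": r, "n_used": n_used, "n_excluded": int((~finite).sum())}


def codon_presence(
    assignments: dict[str, pd.DataFrame],
    tag_calls: dict[str, pd.DataFrame],
    transcriptome: Transcriptome,
    sample_sheet: pd.DataFrame,
) -> pd.DataFrame:
    """Fraction of mRNA reads whose aligned span covers the start/stop codon.

    A read "contains" a codon iff its transcript-coordinate alignment span
    covers all three codon bases.  Reads are split into NAD-mRNA (tagged) and
    non-NAD-mRNA classes per condition; reads on genes without a CDS are
    excluded.  5'-truncation makes the start codon the discriminating end:
    tagged reads lose the tag first, so their transcript part keeps more of
    the 5' end than an equally truncated untagged read.
    """
    cds = {
        g.id: (g.cds_start, g.cds_stop)
        for g in transcriptome.genes
        if g.biotype == "mRNA"
    }
    plus = sample_sheet[sample_sheet["adprc"] == "plus"]
    rows = []
    for condition, group in plus.groupby("condition", sort=False):
        frames = []
        for sample in group["sample_id"]:
            merged = assignments[sample].merge(
                tag_calls[sample][["read_id", "is_tagged"]], on="read_id", how="inner"
            )
            frames.append(merged)
        reads = pd.concat(frames, ignore_index=True)
        reads = reads[reads["gene_id"].isin(cds)]
        for is_nad, label in ((True, "NAD-mRNA"), (False, "non-NAD-mRNA")):
            sub = reads[reads["is_tagged"].fillna(False) == is_nad]
            if len(sub) == 0:
                rows.append(
                    {
                        "condition": condition,
                        "read_class": label,
                        "n_reads": 0,
                        "start_codon_fraction": np.nan,
                        "stop_codon_fraction": np.nan,
                    }
                )
                continue
            starts = np.array([cds[g][0] for g in sub["gene_id"]])
            stops = np.array([cds[g][1] for g in sub["gene_id"]])
            t_start = sub["t_start"].to_numpy()
            t_end = sub["t_end"].to_numpy()
            has_start = (t_start <= starts) & (t_end >= starts + 3)
            has_stop = (t_start <= stops) & (t_end >= stops + 3)
            rows.append(
                {
                    "condition": condition,
                    "read_class": label,
                    "n_reads": int(len(sub)),
                    "start_codon_fraction": float(has_start.mean()),
                    "stop_codon_fraction": float(has_stop.mean()),
                }
            )
    return pd.DataFrame(rows)
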