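"""Expression preprocessing: FPKM normalization, low-expression and IQR
filters, Ward-clustering sample classification, and allele-balance testing."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .containers import ExpressionMatrix
from .errors import NormalizationError, SignatureError


def fpkm_normalize(
    expr: ExpressionMatrix,
    gene_lengths: pd.Series | None = None,
    total_mapped: pd.Series | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    FPKM(g, s) = count(g, s) / (length_kb(g) * mapped_millions(s)). When
    ``total_mapped`` is absent, per-sample column sums are used.
    """
    if expr.unit != "counts":
        raise ValueError(f"fpkm_normalize expects counts, got {expr.unit!r}")
    lengths = gene_lengths if gene_lengths is not None else expr.gene_lengths
    if lengths is None:
        raise KeyError("gene lengths are required for FPKM normalization")
    missing = [g for g in expr.gene_ids if g not in lengths.index]
    if missing:
        raise KeyError(f"missing gene lengths for: {missing[:5]}")
    lengths = lengths.reindex(expr.values.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    totals = total_mapped if total_mapped is not None else expr.total_mapped
    if totals is None:
        totals = expr.values.sum(axis=0)
    totals = totals.reindex(expr.values.columns).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise NormalizationError(f"zero mapped-read total for sample(s) {bad}")
    fpkm = expr.values / np.outer(lengths / 1e3, totals / 1e6)
    return ExpressionMatrix(fpkm, unit="fpkm", gene_lengths=lengths, total_mapped=totals)


def filter_low_expression(
    expr: ExpressionMatrix,
    min_fraction: float = 0.10,
    expressed_threshold: float = 0.0,
) -> ExpressionMatrix:
    """Drop genes expressed (value > threshold) in fewer than ``min_fraction``
    of samples. The boundary is inclusive: a gene expressed in exactly the
    minimum fraction of samples is retained."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must be in [0, 1]")
    if expr.n_samples == 0 or expr.n_genes == 0:
        return expr
    frac = (expr.values > expressed_threshold).mean(axis=1)
    return expr.subset_genes(expr.values.index[frac >= min_fraction])


def iqr_filter(expr: ExpressionMatrix, min_iqr: float = 0.0) -> ExpressionMatrix:
    """Keep genes whose interquartile range across samples exceeds ``min_iqr``.

    IQR = Q3 - Q1 with linear-interpolation quantiles; with the default cutoff
    of 0 only unchanged (constant-spread) genes are excluded.
    """
    if expr.n_samples < 4:
        raise ValueError("IQR filter needs at least 4 samples")
    q1, q3 = np.percentile(expr.values.to_numpy(), [25, 75], axis=1, method="linear")
    return expr.subset_genes(expr.values.index[(q3 - q1) > min_iqr])


def _ordered_labels(assign: pd.Series, centroid_mean: pd.Series, k: int) -> pd.Series:
    order = centroid_mean.sort_values(ascending=False).index
    if k == 2:
        names = {order[0]: "ETP-like", order[1]: "non-ETP"}
    else:
        names = {c: f"cluster{i + 1}" for i, c in enumerate(order)}
    return assign.map(names)


def classify_etp(
    expr: ExpressionMatrix,
    signature_genes,
    k: int = 2,
) -> pd.Series:
    """Classify samples by Ward hierarchical clustering on signature genes.

    Samples are points in the space of signature-gene expression; Ward linkage
    on Euclidean distance is cut at ``k`` clusters. To make the dendrogram
    independent of input column order, samples are sorted lexicographically
    before linkage. For ``k=2`` the cluster whose centroid has the higher mean
    signature expression is labeled ``"ETP-like"``; for other ``k`` clusters
    are named ``cluster1..clusterK`` in decreasing centroid order.
    """
    present = [g for g in signature_genes if g in expr.values.index]
    if not present:
        raise SignatureError("no signature genes present in the expression matrix")
    if expr.n_samples < k:
        raise ValueError("need at least k samples")
    samples = sorted(expr.sample_ids)
    X = expr.values.loc[present, samples].T.to_numpy(dtype=float)
    if len(samples) == k:
        assign = pd.Series(range(1, k + 1), index=samples)
    else:
        Z = linkage(X, method="ward")
        assign = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=samples)
    centroid_mean = pd.Series(
        {c: X[assign.to_numpy() == c].mean() for c in assign.unique()}
    )
    labels = _ordered_labels(assign, centroid_mean, k)
    return labels.reindex(expr.sample_ids)


def allele_balance_test(alt_count: int, total: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value for allele balance.

    Two-sided by the minimum-likelihood method: the sum of P(k) over all
    outcomes k no more probable than the observed count under
    Binomial(total, p0).
    """
    if total < 1 or not 0 <= alt_count <= total:
        raise ValueError("need 0 <= alt_count <= total and total >= 1")
    return stats.binomtest(alt_count, total, p0, alternative="two-sided").pvalue
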