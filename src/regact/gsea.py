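"""Gene set enrichment: signature construction from knock-down profiles,
signal-to-noise ranking, and weighted Kolmogorov-Smirnov enrichment with
gene-set permutation.

The enrichment score (ES) is the signed maximum deviation of the standard
weighted running sum: hits increment by ``|metric|^p`` (normalized over hits),
misses decrement by ``1/(N - N_hits)``. Significance comes from a null of
random same-size gene sets drawn from the ranked universe; the normalized
score (NES) divides ES by the mean |ES| of same-sign null draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSet
from .errors import RegactError

log = logging.getLogger(__name__)


class SetCoverageError(RegactError, ValueError):
    """The ranked list covers no member of the gene set."""


def build_eprotein_signature(
    fc_e2a: pd.Series,
    fc_heb: pd.Series,
    fc_tal1: pd.Series,
    down_threshold: float = -0.5,
    up_threshold: float = 0.0,
    name: str = "eprotein_targets",
) -> GeneSet:
    """E-protein target signature from three knock-down log2FC profiles.

    A gene qualifies when it is down-regulated after knock-down of both
    E-proteins (E2A and HEB log2FC strictly below ``down_threshold``) and
    up-regulated after TAL1 knock-down (log2FC strictly above
    ``up_threshold``) — i.e. genes activated by E-proteins and repressed by
    TAL1. The three profiles are intersected on their shared gene universe.
    """
    universe = fc_e2a.index.intersection(fc_heb.index).intersection(fc_tal1.index)
    if len(universe) == 0:
        raise ValueError("the three log2FC tables share no genes")
    mask = (
        (fc_e2a.loc[universe] < down_threshold)
        & (fc_heb.loc[universe] < down_threshold)
        & (fc_tal1.loc[universe] > up_threshold)
    )
    members = frozenset(universe[mask])
    if not members:
        raise ValueError("signature is empty under the given thresholds")
    return GeneSet(name, members)


def signal2noise(mu1: float, mu2: float, sd1: float, sd2: float) -> float:
    """GSEA signal-to-noise: (mu1 - mu2) / (s1 + s2) with each standard
    deviation floored at max(0.2 * |its group mean|, 0.2)."""
    s1 = max(sd1, 0.2 * abs(mu1), 0.2)
    s2 = max(sd2, 0.2 * abs(mu2), 0.2)
    return (mu1 - mu2) / (s1 + s2)


def rank_by_signal2noise(
    expr: ExpressionMatrix,
    groups: pd.Series,
    group1: str | None = None,
    group2: str | None = None,
    min_fpkm: float = 1.0,
    log_transform: bool = True,
) -> pd.Series:
    """Rank genes by the signal-to-noise metric between two groups.

    Genes with mean FPKM below ``min_fpkm`` across all samples are dropped
    first. By default the metric is computed on log2(FPKM + 1); matrices
    already on a log or z scale are used as-is and the FPKM floor is skipped.
    Returns a metric Series sorted descending, ties broken by gene id.
    """
    groups = groups.reindex(expr.values.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique())
    if group1 is None or group2 is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, found {labels}")
        group1, group2 = labels
    a_cols = groups.index[groups == group1]
    b_cols = groups.index[groups == group2]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    values = expr.values
    if expr.unit == "fpkm":
        values = values.loc[values.mean(axis=1) >= min_fpkm]
        if log_transform:
            values = np.log2(values + 1.0)
    a = values[a_cols].to_numpy(dtype=float)
    b = values[b_cols].to_numpy(dtype=float)
    s2n = np.array(
        [
            signal2noise(a[i].mean(), b[i].mean(), a[i].std(ddof=1), b[i].std(ddof=1))
            for i in range(values.shape[0])
        ]
    )
    out = pd.Series(s2n, index=values.index, name="signal2noise")
    # descending metric, ascending gene id on ties -> strictly ordered list
    order = sorted(out.index, key=lambda g: (-out[g], g))
    return out.loc[order]


@dataclass
class ESResult:
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    hit_indices: np.ndarray


def enrichment_score(
    ranked: pd.Series, gene_set: GeneSet, weight: float = 1.0
) -> ESResult:
    """Weighted KS enrichment score of ``gene_set`` along a ranked list.

    The running sum increments by ``|metric|^weight`` (normalized over hits)
    at set members and decrements by ``1/(N - N_hits)`` elsewhere; ES is the
    running-sum value of largest magnitude (the earlier extremum on exact
    ties). The leading edge contains the set members at or before the
    extremum for positive ES, and at or after it for negative ES.
    """
    genes = ranked.index.to_numpy()
    metrics = ranked.to_numpy(dtype=float)
    hits = np.isin(genes, list(gene_set.members))
    n, n_hits = len(genes), int(hits.sum())
    if n_hits == 0:
        raise SetCoverageError(f"no member of {gene_set.name!r} in the ranked list")
    steps = np.empty(n)
    if n_hits == n:
        steps[:] = 0.0
    else:
        steps[~hits] = -1.0 / (n - n_hits)
    w = np.abs(metrics[hits]) ** weight
    total = w.sum()
    steps[hits] = w / total if total > 0 else 1.0 / n_hits
    running = np.cumsum(steps)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    hit_idx = np.flatnonzero(hits)
    if es >= 0:
        leading = [genes[i] for i in hit_idx if i <= i_ext]
    else:
        leading = [genes[i] for i in hit_idx if i >= i_ext]
    return ESResult(es=es, running_sum=running, leading_edge=leading, hit_indices=hit_idx)


def _null_es(metrics: np.ndarray, size: int, n_perm: int, rng, weight: float) -> np.ndarray:
    """ES of ``n_perm`` random gene sets of ``size`` members, vectorized.

    Between hits the running sum falls linearly, so its extrema lie just
    after or just before hit positions; evaluating only those candidates
    gives the exact ES in O(size) per permutation.
    """
    n = len(metrics)
    absw = np.abs(metrics) ** weight
    # sample `size` distinct positions per permutation
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :size]
    pos.sort(axis=1)
    w = absw[pos]
    tot = w.sum(axis=1, keepdims=True)
    zero_tot = tot[:, 0] == 0
    cw = np.where(tot > 0, np.cumsum(w, axis=1) / np.where(tot == 0, 1.0, tot), 0.0)
    if zero_tot.any():
        cw[zero_tot] = np.arange(1, size + 1) / size
    if n == size:
        return np.zeros(n_perm)
    d = 1.0 / (n - size)
    ranks = np.arange(1, size + 1)
    r_after = cw - (pos + 1 - ranks) * d
    r_before = cw - np.diff(np.concatenate([np.zeros((n_perm, 1)), cw], axis=1)) - (pos - (ranks - 1)) * d
    pos_max = r_after.max(axis=1)
    neg_min = np.minimum(r_before.min(axis=1), 0.0)
    return np.where(pos_max >= -neg_min, pos_max, neg_min)


def gsea(
    ranked: pd.Series,
    sets: Sequence[GeneSet],
    n_permutations: int = 1000,
    permute: str = "gene_set",
    set_min: int = 4,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Gene-set-permutation GSEA over a ranked list.

    Sets with fewer than ``set_min`` covered members are skipped (recorded in
    the result's ``attrs["skipped"]``). For each reported set, the null is the
    ES of ``n_permutations`` random same-size gene sets; the one-tailed
    same-sign permutation p is ``(1 + extreme) / (1 + same_sign)``, NES is
    ES over the mean |same-sign null ES|, and FDR is Benjamini-Hochberg
    across reported sets.
    """
    if permute != "gene_set":
        raise ValueError(f"unsupported permutation mode {permute!r}")
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations to report p-values")
    metrics = ranked.to_numpy(dtype=float)
    universe = set(ranked.index)
    rng = np.random.default_rng(seed)

    rows, skipped = [], []
    null_cache: dict[int, np.ndarray] = {}
    for gs in sets:
        covered = len(gs.members & universe)
        if covered < set_min:
            skipped.append((gs.name, f"only {covered} members covered (< set_min={set_min})"))
            log.info("skipping set %s: %d covered members < %d", gs.name, covered, set_min)
            continue
        res = enrichment_score(ranked, gs, weight=weight)
        if covered not in null_cache:
            null_cache[covered] = _null_es(metrics, covered, n_permutations, rng, weight)
        null = null_cache[covered]
        same = null[null >= 0] if res.es >= 0 else null[null < 0]
        extreme = int((same >= res.es).sum()) if res.es >= 0 else int((same <= res.es).sum())
        p = (1 + extreme) / (1 + len(same))
        mean_abs = np.abs(same).mean() if len(same) else np.nan
        nes = res.es / mean_abs if mean_abs and mean_abs > 0 else np.nan
        rows.append(
            (gs.name, covered, res.es, nes, p, ";".join(res.leading_edge), n_permutations)
        )
    out = pd.DataFrame(
        rows, columns=["set", "size", "es", "nes", "p", "leading_edge", "n_permutations"]
    )
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["fdr"] = pd.Series(dtype=float)
    out = out[["set", "size", "es", "nes", "p", "fdr", "leading_edge", "n_permutations"]]
    out.attrs["skipped"] = skipped
    return out
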