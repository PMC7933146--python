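"""AP-MS interactome statistics: size-normalized spectral abundance, G-test
calling of bait-enriched interactors against an IgG control, and interactome
overlap testing."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import SpectralCountTable
from .errors import NormalizationError
from .peaks import fisher_exact


def normalize_spectral_counts(table: SpectralCountTable) -> pd.DataFrame:
    """Length-normalized relative abundance per run.

    abundance(p) = (count(p) / length(p)) / sum_q (count(q) / length(q)),
    so abundances are proportions summing to 1 within each run.
    """
    rates = table.counts.div(table.lengths.reindex(table.counts.index), axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise NormalizationError(f"all-zero run(s): {bad}")
    return rates / totals


def g_statistic(
    bait_count: float,
    control_count: float,
    bait_total: float,
    control_total: float,
    pseudo: float = 0.5,
) -> float:
    """Two-cell G statistic for one protein's bait vs control counts.

    Expected values split the protein's total in proportion to the bait and
    control run totals; ``pseudo`` is added to zero observed cells.
    """
    o = np.array([bait_count, control_count], dtype=float)
    o[o == 0] += pseudo
    t = o.sum()
    e = t * np.array([bait_total, control_total]) / (bait_total + control_total)
    return float(2.0 * np.sum(o * np.log(o / e)))


def _loading_factors(bait: np.ndarray, control: np.ndarray, method: str) -> tuple[float, float]:
    """Relative loading of the bait vs control condition.

    ``"median_ratio"`` (default) is the median-of-ratios size factor: robust
    to a minority of genuinely enriched proteins, which would otherwise
    inflate the bait total and mask their own enrichment. ``"total"`` uses
    the raw condition sums.
    """
    if method == "total":
        return float(bait.sum()), float(control.sum())
    if method != "median_ratio":
        raise ValueError("loading must be 'median_ratio' or 'total'")
    ref = np.sqrt(bait * control)
    ok = ref > 0
    if not ok.any():  # no protein seen in both conditions; fall back to sums
        return float(bait.sum()), float(control.sum())
    return float(np.median(bait[ok] / ref[ok])), float(np.median(control[ok] / ref[ok]))


def g_test_interactors(
    table: SpectralCountTable,
    alpha: float = 0.05,
    pseudo: float = 0.5,
    loading: str = "median_ratio",
) -> pd.DataFrame:
    """Call bait-enriched interactors by a per-protein G-test.

    Replicate runs are summed per condition, then each protein's summed bait
    vs control counts are tested with a 2-cell G against expectations
    proportional to the estimated condition loading (chi-square, 1 df). A
    protein is ``enriched`` when its loading-normalized bait rate exceeds its
    control rate and p < alpha; ``enriched_fdr`` applies the same direction
    rule to the BH-adjusted p.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    bait = table.counts[table.bait_runs].sum(axis=1).astype(float)
    control = table.counts[table.control_runs].sum(axis=1).astype(float)
    if bait.sum() == 0 or control.sum() == 0:
        raise NormalizationError("bait and control totals must both be positive")
    f_bait, f_control = _loading_factors(bait.to_numpy(), control.to_numpy(), loading)
    g = np.array(
        [g_statistic(b, c, f_bait, f_control, pseudo) for b, c in zip(bait, control)]
    )
    g = np.maximum(g, 0.0)
    p = stats.chi2.sf(g, df=1)
    direction = (bait / f_bait) > (control / f_control)
    adj_p = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "protein": table.proteins,
            "bait_count": bait.to_numpy(),
            "control_count": control.to_numpy(),
            "g_stat": g,
            "p": p,
            "adj_p": adj_p,
            "enriched": direction.to_numpy() & (p < alpha),
            "enriched_fdr": direction.to_numpy() & (adj_p < alpha),
        }
    )
    return out.sort_values(["p", "protein"], kind="mergesort").reset_index(drop=True)


@dataclass
class InteractomeOverlap:
    n_overlap: int
    fraction_of_b: float
    fisher_p: float
    contingency: list


def interactome_overlap(set_a, set_b, universe_size: int) -> InteractomeOverlap:
    """Overlap of two interactor sets against a common protein universe.

    Returns the shared count, the fraction of set B shared with set A, and a
    two-sided Fisher exact p from the 2x2 membership table over the universe.
    """
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if universe_size < union:
        raise ValueError(f"universe ({universe_size}) smaller than the union ({union})")
    n = len(a & b)
    table = [
        [n, len(a) - n],
        [len(b) - n, universe_size - len(a) - len(b) + n],
    ]
    return InteractomeOverlap(
        n_overlap=n,
        fraction_of_b=n / len(b) if b else 0.0,
        fisher_p=fisher_exact(table),
        contingency=table,
    )
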