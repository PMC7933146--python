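"""Regulon-based transcription-factor activity scoring and differential
activity testing between two sample groups."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, RegulonSet

log = logging.getLogger(__name__)


def infer_activity(expr: ExpressionMatrix, regulons: RegulonSet) -> pd.DataFrame:
    """Per-sample activity of each regulator: the unweighted mean of the
    z-scored expression of its targets.

    Expression is z-scored per gene across the cohort unless already in
    z-score units. Regulators with no target present in the matrix are dropped
    with a logged warning. Returns a regulator-by-sample DataFrame.
    """
    if len(regulons) == 0:
        raise ValueError("empty regulon set")
    z = expr if expr.unit == "zscore" else expr.zscore()
    zv = z.values
    rows = {}
    for reg in regulons.regulators:
        covered = [t for t in regulons.targets(reg) if t in zv.index]
        if not covered:
            log.warning("regulator %s has no targets in the matrix; dropped", reg)
            continue
        rows[reg] = zv.loc[covered].mean(axis=0)
    if not rows:
        raise ValueError("no regulon has any covered target")
    return pd.DataFrame(rows).T.loc[:, zv.columns]


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate zero-variance case: identical constants are a perfect null
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def differential_activity(
    activity: pd.DataFrame,
    groups: pd.Series,
    group1: str | None = None,
    group2: str | None = None,
    method: str = "student_t",
) -> pd.DataFrame:
    """Unpaired two-sided t test of activity between two groups per regulator.

    ``delta`` is mean(group1) - mean(group2). ``method`` selects the pooled-
    variance Student t (default) or Welch t. P-values are Benjamini-Hochberg
    adjusted across regulators; rows come back sorted by p ascending.
    """
    if method not in ("student_t", "welch_t"):
        raise ValueError("method must be 'student_t' or 'welch_t'")
    groups = groups.reindex(activity.columns)
    if groups.isna().any():
        raise ValueError("every activity sample needs a group label")
    labels = sorted(groups.unique())
    if group1 is None or group2 is None:
        if len(labels) != 2:
            raise ValueError(f"expected exactly two groups, found {labels}")
        group1, group2 = labels
    a_cols = groups.index[groups == group1]
    b_cols = groups.index[groups == group2]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")

    recs = []
    for reg in activity.index:
        a = activity.loc[reg, a_cols].to_numpy(dtype=float)
        b = activity.loc[reg, b_cols].to_numpy(dtype=float)
        t, p = _two_sample_t(a, b, equal_var=(method == "student_t"))
        recs.append((reg, float(a.mean() - b.mean()), t, p))
    out = pd.DataFrame(recs, columns=["regulator", "delta_activity", "t_stat", "p"])
    out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values(["p", "regulator"], kind="mergesort").reset_index(drop=True)


def select_interacting_tfs(
    regulators: Sequence[str],
    interaction_edges,
    anchor: str,
    min_confidence: float = 0.4,
    include_anchor: bool = False,
) -> list[str]:
    """Regulators with a protein-interaction edge to ``anchor`` at or above
    ``min_confidence`` (STRING-style confidence in [0, 1]).

    ``interaction_edges`` is an iterable of (a, b, confidence) or a DataFrame
    with those first three columns. An absent anchor yields an empty list with
    a warning.
    """
    if isinstance(interaction_edges, pd.DataFrame):
        rows = interaction_edges.iloc[:, :3].itertuples(index=False)
    else:
        rows = interaction_edges
    partners: dict[str, float] = {}
    seen_anchor = False
    for a, b, conf in rows:
        conf = float(conf)
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {conf} outside [0, 1]")
        if a == anchor or b == anchor:
            seen_anchor = True
            other = b if a == anchor else a
            partners[other] = max(partners.get(other, 0.0), conf)
    if not seen_anchor:
        log.warning("anchor %s absent from the interaction table", anchor)
        return []
    selected = [r for r in regulators if partners.get(r, -1.0) >= min_confidence]
    if include_anchor and anchor in regulators and anchor not in selected:
        selected.append(anchor)
    return selected
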