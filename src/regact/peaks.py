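"""Peak co-occupancy: BED/narrowPeak reading, sorted-sweep overlap counting,
and genome-binned Fisher testing of co-occupancy significance."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeakSet
from .errors import ValidationError

log = logging.getLogger(__name__)

_NARROWPEAK_EXTRA = ["signal_value", "p_value", "q_value", "peak_offset"]


@dataclass
class OverlapResult:
    n_query: int
    n_overlapping: int
    fraction: float
    p: float | None = None
    contingency: list | None = None
    method: str = "sweep"


def read_peak_file(path, format: str = "bed6", genome_sizes: dict | None = None) -> PeakSet:
    """Parse a BED6 or ENCODE narrowPeak file into a sorted :class:`PeakSet`.

    Intervals are validated (start < end, within chromosome bounds when sizes
    are given); identical duplicate intervals are collapsed with a logged
    count; malformed lines are reported with their line number.
    """
    if format not in ("bed6", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    min_cols = 3 if format == "bed6" else 10
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < min_cols:
                raise ValidationError(
                    f"{path}:{lineno}: expected >= {min_cols} columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValidationError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            row = {
                "chrom": fields[0],
                "start": start,
                "end": end,
                "name": fields[3] if len(fields) > 3 else ".",
                "score": fields[4] if len(fields) > 4 else 0,
                "strand": fields[5] if len(fields) > 5 else ".",
            }
            if format == "narrowPeak":
                for col, val in zip(_NARROWPEAK_EXTRA, fields[6:10]):
                    row[col] = val
            rows.append(row)
    if not rows:
        raise ValidationError(f"{path}: no intervals parsed")
    df = pd.DataFrame(rows)
    before = len(df)
    df = df.drop_duplicates(subset=["chrom", "start", "end"])
    if len(df) < before:
        log.info("%s: collapsed %d duplicate interval(s)", path, before - len(df))
    return PeakSet(df.reset_index(drop=True), genome_sizes=genome_sizes)


def overlap_fraction(query: PeakSet, reference: PeakSet) -> OverlapResult:
    """Fraction of query peaks intersecting >= 1 bp of any reference peak.

    Half-open semantics: [0, 100) and [100, 200) do not overlap. Counting is
    a sorted sweep against the merged reference intervals.
    """
    if len(query) == 0:
        raise ValueError("empty query peak set")
    if len(reference) == 0:
        raise ValueError("empty reference peak set")
    merged = reference.merged_by_chrom()
    n_overlapping = 0
    for chrom, sub in query.df.groupby("chrom", sort=False):
        if chrom not in merged:
            continue
        starts, ends = merged[chrom]
        q_start = sub["start"].to_numpy(dtype=np.int64)
        q_end = sub["end"].to_numpy(dtype=np.int64)
        # rightmost merged reference starting before the query end
        j = np.searchsorted(starts, q_end, side="left") - 1
        valid = j >= 0
        hit = np.zeros(len(sub), dtype=bool)
        hit[valid] = ends[j[valid]] > q_start[valid]
        n_overlapping += int(hit.sum())
    return OverlapResult(
        n_query=len(query),
        n_overlapping=n_overlapping,
        fraction=n_overlapping / len(query),
        method="sweep",
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table: the sum of hypergeometric
    probabilities of tables (fixed margins) no more likely than the observed
    one. A zero row or column margin makes the table degenerate -> p = 1.0."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def _occupied_bins(peaks: PeakSet, genome_sizes: dict, bin_size: int) -> np.ndarray:
    chrom_order = sorted(genome_sizes)
    offsets, total = {}, 0
    for chrom in chrom_order:
        offsets[chrom] = total
        total += math.ceil(genome_sizes[chrom] / bin_size)
    occupied = np.zeros(total, dtype=bool)
    for chrom, start, end in peaks.intervals():
        if chrom not in offsets:
            raise ValueError(f"peak on unknown chromosome {chrom!r}")
        first = offsets[chrom] + start // bin_size
        last = offsets[chrom] + (end - 1) // bin_size
        occupied[first : last + 1] = True
    return occupied


def overlap_fisher(
    query: PeakSet,
    reference: PeakSet,
    genome_sizes: dict | None = None,
    bin_size: int = 2000,
) -> OverlapResult:
    """Binned co-occupancy test: tile the genome into fixed-size bins, cross-
    classify bins by query / reference occupancy, and apply a two-sided Fisher
    exact test. The result also carries the peak-level overlap fraction."""
    sizes = genome_sizes or query.genome_sizes or reference.genome_sizes
    if sizes is None:
        raise ValueError("genome sizes are required for the binned Fisher test")
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    q_occ = _occupied_bins(query, sizes, bin_size)
    r_occ = _occupied_bins(reference, sizes, bin_size)
    table = [
        [int((q_occ & r_occ).sum()), int((q_occ & ~r_occ).sum())],
        [int((~q_occ & r_occ).sum()), int((~q_occ & ~r_occ).sum())],
    ]
    frac = overlap_fraction(query, reference)
    return OverlapResult(
        n_query=frac.n_query,
        n_overlapping=frac.n_overlapping,
        fraction=frac.fraction,
        p=fisher_exact(table),
        contingency=table,
        method=f"binned_fisher(bin_size={bin_size})",
    )
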