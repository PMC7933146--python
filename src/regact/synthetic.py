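"""Ground-truth data generators.

Every downstream stage of the pipeline is benchmarked against cohorts produced
here: a planted transcription-factor -> target network drives log-scale
expression with additive Gaussian noise, knock-down profiles perturb one
factor, peak sets carry a controlled co-occupancy fraction, spectral-count
tables plant bait-enriched interactors, and allele counts follow a binomial
read-sampling model. Each generator is a pure function of its arguments
(including ``seed``) and each returned truth object records those parameters,
so regenerating from a truth file reproduces the dataset byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PeakSet, SpectralCountTable
from .errors import PlacementError, SizingError


@dataclass
class TruthNetwork:
    """Planted regulator -> target network.

    ``targets_of[r]`` is a list of ``(target_id, effect_size, sign)`` with
    effect sizes > 0 and sign +1 (activation) or -1 (repression). Regulators
    never target themselves.
    """

    regulators: list[str]
    targets_of: dict[str, list[tuple[str, float, int]]]
    n_genes: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        for r, targets in self.targets_of.items():
            for t, eff, sign in targets:
                if t == r:
                    raise ValueError(f"regulator {r} targets itself")
                if t not in genes:
                    raise ValueError(f"target {t} outside the gene universe")
                if eff <= 0:
                    raise ValueError("effect sizes must be > 0")
                if sign not in (-1, 1):
                    raise ValueError("sign must be +1 or -1")

    @property
    def gene_ids(self) -> list[str]:
        n_fill = self.n_genes - len(self.regulators)
        width = max(4, len(str(n_fill)))
        return list(self.regulators) + [f"G{i:0{width}d}" for i in range(1, n_fill + 1)]

    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, targets in self.targets_of.items() for t, _, _ in targets}

    def to_dict(self) -> dict:
        return {
            "regulators": self.regulators,
            "targets_of": {
                r: [[t, eff, sign] for t, eff, sign in targets]
                for r, targets in self.targets_of.items()
            },
            "n_genes": self.n_genes,
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TruthNetwork":
        return cls(
            regulators=list(d["regulators"]),
            targets_of={
                r: [(t, float(eff), int(sign)) for t, eff, sign in targets]
                for r, targets in d["targets_of"].items()
            },
            n_genes=int(d["n_genes"]),
            params=dict(d.get("params", {})),
        )


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort: group labels and per-sample activities."""

    sample_ids: list[str]
    group_of: dict[str, str]
    true_activity: pd.DataFrame  # regulators x samples
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.group_of) != set(self.sample_ids):
            raise ValueError("group labels must cover all samples exactly")
        if list(self.true_activity.columns) != self.sample_ids:
            raise ValueError("true_activity columns must match sample ids")

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "group_of": self.group_of,
            "regulators": list(self.true_activity.index),
            "true_activity": self.true_activity.to_numpy().tolist(),
            "params": self.params,
        }


def make_truth_network(
    n_regulators: int,
    n_targets_per_regulator: int,
    n_genes: int,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    effect_range: tuple[float, float] = (0.5, 1.5),
    repressed_fraction: float = 0.0,
) -> TruthNetwork:
    """Plant a regulator->target network over ``n_genes`` gene ids.

    A fraction ``overlap_fraction`` of each regulator's targets is shared with
    the previous regulator's regulon; the remainder come from a fresh pool, so
    the number of shared ids between consecutive regulons is exactly
    ``round(overlap_fraction * n_targets_per_regulator)``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    k, m = n_regulators, n_targets_per_regulator
    if k < 1 or m < 1:
        raise SizingError("need at least one regulator and one target each")
    if k * m > 2 * n_genes:
        raise SizingError(
            f"target budget {k * m} exceeds twice the gene count {n_genes}"
        )
    n_shared = int(round(overlap_fraction * m))
    n_pool = n_genes - k
    n_distinct = m + (k - 1) * (m - n_shared)
    if n_distinct > n_pool:
        raise SizingError(
            f"need {n_distinct} distinct non-regulator targets but only {n_pool} available"
        )

    rng = np.random.default_rng(seed)
    regulators = [f"TF{i:02d}" for i in range(1, k + 1)]
    net = TruthNetwork(regulators, {r: [] for r in regulators}, n_genes)
    pool = [g for g in net.gene_ids if g not in set(regulators)]
    rng.shuffle(pool)
    cursor = 0
    prev_targets: list[str] = []
    targets_of: dict[str, list[tuple[str, float, int]]] = {}
    for i, r in enumerate(regulators):
        if i == 0 or n_shared == 0:
            chosen = pool[cursor : cursor + m]
            cursor += m
        else:
            shared = list(rng.choice(prev_targets, size=n_shared, replace=False))
            fresh = pool[cursor : cursor + (m - n_shared)]
            cursor += m - n_shared
            chosen = shared + fresh
        effects = rng.uniform(*effect_range, size=m)
        signs = np.where(rng.random(m) < repressed_fraction, -1, 1)
        targets_of[r] = [
            (t, float(e), int(s)) for t, e, s in zip(chosen, effects, signs)
        ]
        prev_targets = chosen
    return TruthNetwork(
        regulators,
        targets_of,
        n_genes,
        params={
            "n_regulators": k,
            "n_targets_per_regulator": m,
            "n_genes": n_genes,
            "overlap_fraction": overlap_fraction,
            "seed": seed,
            "effect_range": list(effect_range),
            "repressed_fraction": repressed_fraction,
        },
    )


def simulate_expression_cohort(
    network: TruthNetwork,
    groups: Mapping[str, int],
    activity_profiles: Mapping[str, Mapping[str, float]],
    noise_sd: float,
    seed: int = 0,
    activity_sd: float = 0.0,
) -> tuple[ExpressionMatrix, CohortTruth]:
    """Simulate a log2-scale expression cohort from a planted network.

    Per sample, each regulator's true activity is its group profile value plus
    ``activity_sd`` Gaussian jitter. A target's expression is the sum over its
    regulators of sign * effect * activity, plus N(0, noise_sd) noise;
    non-target genes are pure noise; a regulator's own transcript tracks its
    activity plus noise (so expression-based and regulon-based inference can be
    contrasted).
    """
    if noise_sd < 0 or activity_sd < 0:
        raise ValueError("noise_sd and activity_sd must be >= 0")
    for g, n in groups.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs at least 2 samples")
        profile = activity_profiles[g]
        for r in network.regulators:
            if r not in profile:
                raise KeyError(f"activity profile for group {g!r} missing regulator {r}")

    rng = np.random.default_rng(seed)
    sample_ids: list[str] = []
    group_of: dict[str, str] = {}
    for g, n in groups.items():
        for i in range(1, n + 1):
            sid = f"{g}_s{i:03d}"
            sample_ids.append(sid)
            group_of[sid] = g

    gene_ids = network.gene_ids
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    n_samples = len(sample_ids)

    activity = np.empty((len(network.regulators), n_samples))
    for ri, r in enumerate(network.regulators):
        base = np.array([activity_profiles[group_of[s]][r] for s in sample_ids])
        activity[ri] = base + (activity_sd * rng.standard_normal(n_samples) if activity_sd > 0 else 0.0)

    expr = np.zeros((len(gene_ids), n_samples))
    for ri, r in enumerate(network.regulators):
        expr[gene_index[r]] += activity[ri]
        for t, eff, sign in network.targets_of[r]:
            expr[gene_index[t]] += sign * eff * activity[ri]
    if noise_sd > 0:
        expr += noise_sd * rng.standard_normal(expr.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_ids, columns=sample_ids), unit="log2fpkm"
    )
    truth = CohortTruth(
        sample_ids=sample_ids,
        group_of=group_of,
        true_activity=pd.DataFrame(activity, index=network.regulators, columns=sample_ids),
        params={
            "groups": dict(groups),
            "activity_profiles": {g: dict(p) for g, p in activity_profiles.items()},
            "noise_sd": noise_sd,
            "activity_sd": activity_sd,
            "seed": seed,
        },
    )
    return matrix, truth


def simulate_knockdown_profiles(
    network: TruthNetwork,
    kd_regulator: str,
    kd_log2fc: float,
    background_sd: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Log2 fold-change profile after knocking down one regulator.

    Positively regulated targets shift by ``kd_log2fc * effect``; repressed
    targets shift by the opposite sign; all other genes carry only
    N(0, background_sd) background. The knocked-down regulator itself reports
    ``kd_log2fc``.
    """
    if kd_regulator not in network.targets_of:
        raise KeyError(f"unknown regulator {kd_regulator!r}")
    rng = np.random.default_rng(seed)
    gene_ids = network.gene_ids
    fc = (
        background_sd * rng.standard_normal(len(gene_ids))
        if background_sd > 0
        else np.zeros(len(gene_ids))
    )
    fc = pd.Series(fc, index=gene_ids, name="log2fc")
    for t, eff, sign in network.targets_of[kd_regulator]:
        fc[t] += sign * kd_log2fc * eff
    fc[kd_regulator] += kd_log2fc
    return fc


def _place_nonoverlapping(rng, n, width, genome_length, forbidden, max_tries):
    """Place n width-bp intervals avoiding every (start, end) in ``forbidden``."""
    placed = []
    occupied = list(forbidden)
    for _ in range(n):
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - width + 1))
            e = s + width
            if all(not (s < fe and fs < e) for fs, fe in occupied):
                placed.append((s, e))
                occupied.append((s, e))
                break
        else:
            raise PlacementError(
                f"could not place interval after {max_tries} tries; genome too crowded"
            )
    return placed


def simulate_peak_sets(
    genome_length: int,
    n_reference: int,
    n_query: int,
    query_overlap_fraction: float,
    peak_width: int = 200,
    seed: int = 0,
    chrom: str = "chr1",
    max_tries: int = 1000,
) -> tuple[PeakSet, PeakSet]:
    """Reference and query peak sets with a planted co-occupancy fraction.

    Exactly ``round(query_overlap_fraction * n_query)`` query peaks intersect a
    reference peak by >= 1 bp; the rest are placed in reference-free space.
    Query names encode the truth (``q_ov_*`` vs ``q_bg_*``).
    """
    if not 0.0 <= query_overlap_fraction <= 1.0:
        raise ValueError("query_overlap_fraction must be in [0, 1]")
    if (n_reference + n_query) * peak_width >= genome_length / 2:
        raise SizingError("total peak footprint must stay below half the genome")

    rng = np.random.default_rng(seed)
    refs = _place_nonoverlapping(rng, n_reference, peak_width, genome_length, [], max_tries)

    n_over = int(round(query_overlap_fraction * n_query))
    queries: list[tuple[int, int, str]] = []
    for i in range(n_over):
        for _ in range(max_tries):
            rs, re = refs[int(rng.integers(0, len(refs)))]
            lo = max(0, rs - peak_width + 1)
            hi = min(genome_length - peak_width, re - 1)
            s = int(rng.integers(lo, hi + 1))
            e = s + peak_width
            if s < re and rs < e:  # >= 1 bp with the chosen reference peak
                queries.append((s, e, f"q_ov_{i:04d}"))
                break
        else:
            raise PlacementError("could not place an overlapping query peak")
    bg = _place_nonoverlapping(
        rng, n_query - n_over, peak_width, genome_length, refs, max_tries
    )
    queries += [(s, e, f"q_bg_{i:04d}") for i, (s, e) in enumerate(bg)]

    sizes = {chrom: int(genome_length)}
    ref_df = pd.DataFrame(
        [(chrom, s, e, f"ref_{i:04d}", 0, ".") for i, (s, e) in enumerate(refs)],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    qry_df = pd.DataFrame(
        [(chrom, s, e, name, 0, ".") for s, e, name in queries],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return PeakSet(ref_df, genome_sizes=sizes), PeakSet(qry_df, genome_sizes=sizes)


def simulate_spectral_counts(
    n_proteins: int,
    n_enriched: int,
    bait_mean: float,
    control_mean: float,
    protein_lengths: Sequence[int] | int | None = None,
    n_replicates: int = 2,
    seed: int = 0,
) -> SpectralCountTable:
    """Bait-vs-IgG spectral-count table with planted enriched interactors.

    Enriched proteins draw Poisson(bait_mean) in bait runs and
    Poisson(control_mean) in control runs; the rest draw Poisson(control_mean)
    everywhere. Which proteins are enriched is recorded in
    ``truth_enriched``.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched cannot exceed n_proteins")
    if bait_mean < 0 or control_mean < 0:
        raise ValueError("Poisson means must be >= 0")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:04d}" for i in range(1, n_proteins + 1)]
    if protein_lengths is None:
        lengths = rng.integers(100, 1501, size=n_proteins)
    elif np.isscalar(protein_lengths):
        lengths = np.full(n_proteins, int(protein_lengths))
    else:
        lengths = np.asarray(protein_lengths, dtype=int)
        if len(lengths) != n_proteins:
            raise ValueError("protein_lengths must have n_proteins entries")
    enriched = set(rng.choice(proteins, size=n_enriched, replace=False)) if n_enriched else set()

    bait_runs = [f"bait_r{i}" for i in range(1, n_replicates + 1)]
    control_runs = [f"igg_r{i}" for i in range(1, n_replicates + 1)]
    counts = {}
    for run in bait_runs:
        mean = np.where([p in enriched for p in proteins], bait_mean, control_mean)
        counts[run] = rng.poisson(mean)
    for run in control_runs:
        counts[run] = rng.poisson(np.full(n_proteins, control_mean))
    return SpectralCountTable(
        counts=pd.DataFrame(counts, index=proteins),
        lengths=pd.Series(lengths, index=proteins, name="length_aa"),
        bait_runs=bait_runs,
        control_runs=control_runs,
        truth_enriched=frozenset(enriched),
    )


def simulate_allele_counts(
    depth: int,
    true_mut_fraction: float,
    n_sites: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-site (ref_count, alt_count) with alt ~ Binomial(depth, fraction)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= true_mut_fraction <= 1.0:
        raise ValueError("true_mut_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    alt = rng.binomial(depth, true_mut_fraction, size=n_sites)
    return pd.DataFrame(
        {"ref_count": depth - alt, "alt_count": alt},
        index=[f"site_{i:03d}" for i in range(1, n_sites + 1)],
    )
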