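"""In-memory containers for the pipeline's data: expression matrices, regulons,
peak sets, spectral-count tables, and gene sets.

All tabular data is backed by :class:`pandas.DataFrame`; the wrappers add the
unit bookkeeping and invariants the analysis relies on (e.g. non-negative FPKM,
sorted half-open genomic intervals).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

VALID_UNITS = ("counts", "fpkm", "log2fpkm", "zscore")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression table with a unit tag.

    Parameters
    ----------
    values : DataFrame
        Genes as rows (index), samples as columns.
    unit : str
        One of ``counts``, ``fpkm``, ``log2fpkm``, ``zscore``. Values must be
        non-negative for ``counts`` and ``fpkm``.
    gene_lengths : Series, optional
        Transcript length in bp per gene (for FPKM normalization).
    total_mapped : Series, optional
        Mapped-read totals per sample; defaults to column sums when needed.
    """

    values: pd.DataFrame
    unit: str = "counts"
    gene_lengths: pd.Series | None = None
    total_mapped: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.unit in ("counts", "fpkm") and (self.values.to_numpy() < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def zscore(self, ddof: int = 1) -> "ExpressionMatrix":
        """Per-gene z-score across samples; constant genes map to all-zero rows."""
        v = self.values.to_numpy(dtype=float)
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, ddof=ddof, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (v - mu) / sd
        z[~np.isfinite(z)] = 0.0
        return ExpressionMatrix(
            pd.DataFrame(z, index=self.values.index, columns=self.values.columns),
            unit="zscore",
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = self.values.index.isin(set(genes))
        return ExpressionMatrix(
            self.values.loc[keep],
            unit=self.unit,
            gene_lengths=None if self.gene_lengths is None else self.gene_lengths.loc[self.values.index[keep]],
            total_mapped=self.total_mapped,
        )

    def to_tsv(self, path, float_format: str = "%.6g") -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)

    @classmethod
    def from_tsv(cls, path, unit: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, unit=unit)


@dataclass
class RegulonSet:
    """Regulator -> {target: MI weight} mapping plus a provenance snapshot.

    ``provenance`` records the inference configuration (estimator, bins, alpha,
    permutations, DPI tolerance, seed, calibrated threshold) so a serialized
    network is self-describing.
    """

    regulons: dict[str, dict[str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for reg, targets in self.regulons.items():
            if reg in targets:
                raise ValueError(f"regulator {reg} may not target itself")

    @property
    def regulators(self) -> list[str]:
        return list(self.regulons)

    def __len__(self) -> int:
        return len(self.regulons)

    def targets(self, regulator: str) -> set[str]:
        return set(self.regulons[regulator])

    def n_edges(self) -> int:
        return sum(len(t) for t in self.regulons.values())

    def to_tsv(self, path) -> None:
        rows = [
            (r, t, mi)
            for r in sorted(self.regulons)
            for t, mi in sorted(self.regulons[r].items())
        ]
        df = pd.DataFrame(rows, columns=["regulator", "target", "mi"])
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path, provenance: dict | None = None) -> "RegulonSet":
        df = pd.read_csv(path, sep="\t")
        regulons: dict[str, dict[str, float]] = {}
        for r, t, mi in df[["regulator", "target", "mi"]].itertuples(index=False):
            regulons.setdefault(r, {})[t] = float(mi)
        return cls(regulons, provenance=provenance or {})

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for r in sorted(self.regulons):
                targets = "\t".join(sorted(self.regulons[r]))
                fh.write(f"{r}\tregulon\t{targets}\n")


@dataclass(frozen=True)
class GeneSet:
    """Named gene set; members are non-empty and unique."""

    name: str
    members: frozenset

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class PeakSet:
    """Sorted genomic intervals, 0-based half-open, for co-occupancy statistics."""

    df: pd.DataFrame
    genome_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        df = self.df
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"peak table missing column {col!r}")
        if (df["start"] < 0).any():
            raise ValidationError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            raise ValidationError("interval with start >= end")
        if self.genome_sizes is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.genome_sizes:
                    raise ValidationError(f"unknown chromosome {chrom!r}")
                if (sub["end"] > self.genome_sizes[chrom]).any():
                    raise ValidationError(f"interval beyond end of {chrom}")
        self.df = df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> list[tuple[str, int, int]]:
        return list(zip(self.df["chrom"], self.df["start"].astype(int), self.df["end"].astype(int)))

    def merged_by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Union of intervals per chromosome as sorted (starts, ends) arrays."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            m_starts, m_ends = [], []
            cur_s, cur_e = starts[0], ends[0]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:  # touching intervals merge; overlap test stays half-open
                    cur_e = max(cur_e, e)
                else:
                    m_starts.append(cur_s)
                    m_ends.append(cur_e)
                    cur_s, cur_e = s, e
            m_starts.append(cur_s)
            m_ends.append(cur_e)
            out[chrom] = (np.asarray(m_starts), np.asarray(m_ends))
        return out

    def to_bed(self, path) -> None:
        df = self.df.copy()
        for col, default in (("name", "."), ("score", 0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df[_BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


@dataclass
class SpectralCountTable:
    """Protein-by-run spectral counts with per-protein lengths and run conditions."""

    counts: pd.DataFrame
    lengths: pd.Series
    bait_runs: list[str]
    control_runs: list[str]
    truth_enriched: frozenset | None = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            if not np.allclose(c, np.round(c)) or (c < 0).any():
                raise ValueError("spectral counts must be non-negative integers")
        if (self.lengths.reindex(self.counts.index) <= 0).any():
            raise ValueError("every protein needs a positive length")
        if not self.bait_runs or not self.control_runs:
            raise ValueError("need at least one bait and one control run")
        missing = [r for r in self.bait_runs + self.control_runs if r not in self.counts.columns]
        if missing:
            raise ValueError(f"runs not in count table: {missing}")

    @property
    def proteins(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "length_aa", self.lengths.reindex(out.index))
        out.to_csv(path, sep="\t", index_label="protein_id")


def write_truth_json(obj: dict, path) -> None:
    """Serialize a ground-truth record deterministically (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
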