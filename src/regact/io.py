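"""Readers and writers for the plain-text exchange formats the pipeline uses:
two-column sample annotations, GMT gene sets, RNK ranked lists, chrom-sizes
tables, STRING-style interaction edges, and spectral-count tables."""

from __future__ import annotations

import pandas as pd

from .containers import GeneSet, SpectralCountTable
from .errors import ValidationError


def read_sample_annotations(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"], dtype=str)
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample ids in annotation file")
    if (df["group"].fillna("") == "").any():
        raise ValidationError("empty group label in annotation file")
    return df.set_index("sample_id")["group"]


def write_sample_annotations(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", header=False)


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT lines need name, description, >=1 gene")
            sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write(f"{gs.name}\tna\t" + "\t".join(sorted(gs.members)) + "\n")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"])
    s = df.set_index("gene")["metric"].astype(float)
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def write_rnk(ranked: pd.Series, path) -> None:
    ranked.to_csv(path, sep="\t", header=False, float_format="%.6g")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValidationError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def read_interaction_edges(path) -> list[tuple[str, str, float]]:
    """STRING-style (protein_a, protein_b, confidence) edge table."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise ValidationError(f"{path}:{lineno}: expected a, b, confidence")
            try:
                conf = float(fields[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric confidence") from exc
            if not 0.0 <= conf <= 1.0:
                raise ValidationError(f"{path}:{lineno}: confidence {conf} outside [0, 1]")
            edges.append((fields[0], fields[1], conf))
    return edges


def read_spectral_counts(counts_path, runs_path) -> SpectralCountTable:
    """Count TSV (protein_id, length_aa, run columns) plus a run-annotation
    TSV mapping each run to 'bait' or 'control'."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if "length_aa" not in df.columns:
        raise ValidationError("count table needs a length_aa column")
    runs = pd.read_csv(runs_path, sep="\t", header=None, names=["run", "condition"], dtype=str)
    bad = sorted(set(runs["condition"]) - {"bait", "control"})
    if bad:
        raise ValidationError(f"unknown run condition(s): {bad}")
    return SpectralCountTable(
        counts=df.drop(columns="length_aa").astype(int),
        lengths=df["length_aa"],
        bait_runs=list(runs.loc[runs["condition"] == "bait", "run"]),
        control_runs=list(runs.loc[runs["condition"] == "control", "run"]),
    )
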