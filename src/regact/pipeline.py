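"""End-to-end orchestration: preprocess -> network -> activity -> differential
activity -> signature + GSEA (-> peak overlap, AP-MS), with per-stage
plain-text outputs, a provenance-stamped report, and a benchmark mode that
scores every stage against planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import benchmark as bench
from . import synthetic
from .activity import differential_activity, infer_activity
from .containers import (
    ExpressionMatrix,
    GeneSet,
    RegulonSet,
    write_truth_json,
)
from .errors import ConfigError, RegactError
from .gsea import build_eprotein_signature, gsea, rank_by_signal2noise
from .io import (
    read_sample_annotations,
    read_spectral_counts,
    write_gmt,
    write_rnk,
    write_sample_annotations,
)
from .network import NetworkConfig, infer_regulons
from .peaks import overlap_fisher, read_peak_file
from .proteomics import g_test_interactors

log = logging.getLogger(__name__)

DEFAULT_SYNTHETIC = {
    "n_regulators": 6,
    "n_targets": 30,
    "n_genes": 400,
    "overlap_fraction": 0.5,
    "n_dev_samples": 200,
    "dev_activity_sd": 1.0,
    "n_per_group": 20,
    "gap": 2.0,
    "noise_sd": 0.5,
    "activity_sd": 0.5,
    "n_attenuated": 2,
    "kd_log2fc": -1.0,
    "background_sd": 0.1,
    "peaks": {
        "genome_length": 1_000_000,
        "n_reference": 150,
        "n_query": 100,
        "overlap_fraction": 0.8,
        "peak_width": 200,
    },
    "apms": {
        "n_proteins": 200,
        "n_enriched": 20,
        "bait_mean": 20.0,
        "control_mean": 1.0,
        "n_replicates": 2,
    },
}


@dataclass
class PipelineConfig:
    """Configuration for a full cohort run.

    Either ``synthetic`` (parameters for the planted-truth generator) or the
    trio ``expression`` / ``annotations`` / (``regulators`` or ``regulons``)
    must be provided. All stage parameters have working defaults.
    """

    seed: int
    outdir: str
    synthetic: dict | None = None
    expression: str | None = None
    expression_network: str | None = None  # cohort the network is inferred from
    annotations: str | None = None
    regulators: list[str] | str | None = None
    regulons: str | None = None
    filters: dict = field(default_factory=lambda: {"min_fraction": 0.10, "expressed_threshold": 0.0, "min_iqr": 0.0})
    network: dict = field(default_factory=dict)
    diff: dict = field(default_factory=lambda: {"group1": "wt", "group2": "mut", "method": "student_t"})
    gsea: dict = field(default_factory=lambda: {"n_permutations": 1000, "set_min": 4, "weight": 1.0})
    peaks: dict | None = None
    apms: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if "seed" not in raw:
            raise ConfigError("config field 'seed' is required")
        if "outdir" not in raw:
            raise ConfigError("config field 'outdir' is required")
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config field(s): {unknown}")
        cfg = cls(**raw)
        if cfg.synthetic is None:
            if cfg.expression is None or cfg.annotations is None:
                raise ConfigError("config needs 'synthetic' or 'expression'+'annotations'")
            if cfg.regulators is None and cfg.regulons is None:
                raise ConfigError("config needs 'regulators' or 'regulons'")
        return cfg

    def canonical_hash(self) -> str:
        """Hash of the analysis parameters (the output location is excluded:
        two runs of the same analysis into different directories share it)."""
        payload = {
            f: getattr(self, f) for f in self.__dataclass_fields__ if f != "outdir"
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


class StageError(RegactError, RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.monotonic()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.monotonic() - t0)
            return out
        return wrapped
    return deco


def _synthesize_inputs(cfg: PipelineConfig, outdir: Path) -> dict:
    params = {**DEFAULT_SYNTHETIC, **(cfg.synthetic or {})}
    params["peaks"] = {**DEFAULT_SYNTHETIC["peaks"], **(cfg.synthetic or {}).get("peaks", {})}
    params["apms"] = {**DEFAULT_SYNTHETIC["apms"], **(cfg.synthetic or {}).get("apms", {})}
    seed = cfg.seed
    net = synthetic.make_truth_network(
        params["n_regulators"], params["n_targets"], params["n_genes"],
        overlap_fraction=params["overlap_fraction"], seed=seed,
    )
    attenuated = net.regulators[: params["n_attenuated"]]
    # normal-development-style cohort with continuous regulator activity:
    # the reference the regulatory network is reverse-engineered from
    dev_expr, _ = synthetic.simulate_expression_cohort(
        net,
        groups={"dev": params["n_dev_samples"]},
        activity_profiles={"dev": {r: 0.0 for r in net.regulators}},
        noise_sd=params["noise_sd"],
        seed=seed + 7,
        activity_sd=params["dev_activity_sd"],
    )
    profiles = {
        "wt": {r: (params["gap"] / 2 if r in attenuated else 0.0) for r in net.regulators},
        "mut": {r: (-params["gap"] / 2 if r in attenuated else 0.0) for r in net.regulators},
    }
    expr, truth = synthetic.simulate_expression_cohort(
        net,
        groups={"wt": params["n_per_group"], "mut": params["n_per_group"]},
        activity_profiles=profiles,
        noise_sd=params["noise_sd"],
        seed=seed + 1,
        activity_sd=params["activity_sd"],
    )
    groups = pd.Series(truth.group_of)

    # knock-down profiles for the signature: the two attenuated regulators act
    # as the E-protein-like activators; a repressor sharing their common
    # targets stands in for the TAL1-like factor
    e1, e2 = attenuated[0], attenuated[1 % len(attenuated)]
    shared = sorted(
        {t for t, _, s in net.targets_of[e1] if s > 0}
        & {t for t, _, s in net.targets_of[e2] if s > 0}
    )
    tal_net = synthetic.TruthNetwork(
        regulators=net.regulators + ["TALL"],
        targets_of={**net.targets_of, "TALL": [(t, 1.0, -1) for t in shared]},
        n_genes=net.n_genes + 1,
    )
    kd = {
        "e1": synthetic.simulate_knockdown_profiles(net, e1, params["kd_log2fc"], params["background_sd"], seed + 2),
        "e2": synthetic.simulate_knockdown_profiles(net, e2, params["kd_log2fc"], params["background_sd"], seed + 3),
        "tal": synthetic.simulate_knockdown_profiles(tal_net, "TALL", params["kd_log2fc"], params["background_sd"], seed + 4),
    }
    pk = params["peaks"]
    ref_peaks, qry_peaks = synthetic.simulate_peak_sets(
        pk["genome_length"], pk["n_reference"], pk["n_query"], pk["overlap_fraction"],
        pk["peak_width"], seed=seed + 5,
    )
    ap = params["apms"]
    sc = synthetic.simulate_spectral_counts(
        ap["n_proteins"], ap["n_enriched"], ap["bait_mean"], ap["control_mean"],
        n_replicates=ap["n_replicates"], seed=seed + 6,
    )

    expr.to_tsv(outdir / "expression.tsv")
    dev_expr.to_tsv(outdir / "expression_dev.tsv")
    write_sample_annotations(groups, outdir / "annotations.tsv")
    for label, series in kd.items():
        series.to_csv(outdir / f"kd_{label}.tsv", sep="\t", header=False, float_format="%.6g")
    ref_peaks.to_bed(outdir / "reference_peaks.bed")
    qry_peaks.to_bed(outdir / "query_peaks.bed")
    sc.to_tsv(outdir / "spectral_counts.tsv")
    write_truth_json(
        {
            "network": net.to_dict(),
            "cohort": truth.to_dict(),
            "attenuated": attenuated,
            "enriched_proteins": sorted(sc.truth_enriched),
            "params": params,
            "seed": seed,
        },
        outdir / "truth.json",
    )
    return {
        "expr": expr, "expr_network": dev_expr, "groups": groups, "net": net, "kd": kd,
        "ref_peaks": ref_peaks, "qry_peaks": qry_peaks, "spectral": sc,
        "regulator_ids": net.regulators, "attenuated": attenuated,
    }


def _load_inputs(cfg: PipelineConfig) -> dict:
    expr = ExpressionMatrix.from_tsv(cfg.expression, unit="log2fpkm")
    net_expr = (
        ExpressionMatrix.from_tsv(cfg.expression_network, unit="log2fpkm")
        if cfg.expression_network
        else expr
    )
    groups = read_sample_annotations(cfg.annotations)
    if isinstance(cfg.regulators, str):
        regulator_ids = [l.strip() for l in open(cfg.regulators) if l.strip()]
    else:
        regulator_ids = cfg.regulators
    out = {"expr": expr, "expr_network": net_expr, "groups": groups,
           "regulator_ids": regulator_ids, "kd": None, "attenuated": None}
    if cfg.peaks:
        sizes = cfg.peaks.get("genome_sizes")
        out["qry_peaks"] = read_peak_file(cfg.peaks["query"], cfg.peaks.get("format", "bed6"))
        out["ref_peaks"] = read_peak_file(cfg.peaks["reference"], cfg.peaks.get("format", "bed6"))
        out["genome_sizes"] = sizes
    if cfg.apms:
        out["spectral"] = read_spectral_counts(cfg.apms["counts"], cfg.apms["runs"])
    return out


def run_cohort_analysis(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the report dict (also written to
    ``07_report/report.json``). Identical config + seed gives byte-identical
    outputs."""
    outdir = Path(cfg.outdir)
    dirs = {
        name: outdir / name
        for name in (
            "00_inputs", "01_preprocess", "02_network", "03_activity",
            "04_diff_activity", "05_gsea", "06_peaks", "06_apms", "07_report",
        )
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)

    inputs = _stage("inputs")(
        lambda: _synthesize_inputs(cfg, dirs["00_inputs"]) if cfg.synthetic is not None else _load_inputs(cfg)
    )()
    expr, groups = inputs["expr"], inputs["groups"]

    @_stage("preprocess")
    def _preprocess():
        from .preprocess import filter_low_expression, iqr_filter

        f = cfg.filters
        outs = []
        for matrix, name in (
            (expr, "expression_filtered.tsv"),
            (inputs["expr_network"], "expression_network_filtered.tsv"),
        ):
            out = filter_low_expression(
                matrix, f.get("min_fraction", 0.10), f.get("expressed_threshold", 0.0)
            )
            out = iqr_filter(out, f.get("min_iqr", 0.0))
            out.to_tsv(dirs["01_preprocess"] / name)
            outs.append(out)
        return outs

    filtered, filtered_net = _preprocess()

    @_stage("network")
    def _network():
        if cfg.regulons:
            regulons = RegulonSet.from_tsv(cfg.regulons)
        else:
            net_cfg = NetworkConfig(**{"seed": cfg.seed, "min_regulon_size": 5, **cfg.network})
            regulons = infer_regulons(filtered_net, inputs["regulator_ids"], net_cfg)
        regulons.to_tsv(dirs["02_network"] / "regulons.tsv")
        regulons.to_gmt(dirs["02_network"] / "regulons.gmt")
        write_truth_json(regulons.provenance, dirs["02_network"] / "provenance.json")
        return regulons

    regulons = _network()

    @_stage("activity")
    def _activity():
        act = infer_activity(filtered, regulons)
        act.to_csv(dirs["03_activity"] / "activity.tsv", sep="\t",
                   index_label="regulator", float_format="%.6g")
        return act

    act = _activity()

    @_stage("diff_activity")
    def _diff():
        d = cfg.diff
        table = differential_activity(
            act, groups, group1=d.get("group1"), group2=d.get("group2"),
            method=d.get("method", "student_t"),
        )
        table.to_csv(dirs["04_diff_activity"] / "differential_activity.tsv",
                     sep="\t", index=False, float_format="%.6g")
        return table

    diff_table = _diff()

    @_stage("gsea")
    def _gsea():
        g = cfg.gsea
        d = cfg.diff
        ranked = rank_by_signal2noise(filtered, groups, group1=d.get("group1"), group2=d.get("group2"))
        write_rnk(ranked, dirs["05_gsea"] / "ranked.rnk")
        sets = []
        if inputs["kd"] is not None:
            signature = build_eprotein_signature(
                inputs["kd"]["e1"], inputs["kd"]["e2"], inputs["kd"]["tal"]
            )
            sets.append(signature)
        for reg in regulons.regulators:
            sets.append(GeneSet(f"regulon_{reg}", frozenset(regulons.targets(reg))))
        write_gmt(sets, dirs["05_gsea"] / "gene_sets.gmt")
        table = gsea(
            ranked, sets, n_permutations=g.get("n_permutations", 1000),
            set_min=g.get("set_min", 4), seed=cfg.seed, weight=g.get("weight", 1.0),
        )
        table.to_csv(dirs["05_gsea"] / "gsea_results.tsv", sep="\t",
                     index=False, float_format="%.6g")
        return table

    gsea_table = _gsea()

    peak_result = None
    if "qry_peaks" in inputs:
        @_stage("peak_overlap")
        def _peaks():
            res = overlap_fisher(
                inputs["qry_peaks"], inputs["ref_peaks"],
                genome_sizes=inputs.get("genome_sizes"),
                bin_size=(cfg.peaks or {}).get("bin_size", 2000),
            )
            pd.DataFrame([{
                "n_query": res.n_query, "n_overlapping": res.n_overlapping,
                "fraction": res.fraction, "p": res.p, "method": res.method,
            }]).to_csv(dirs["06_peaks"] / "overlap.tsv", sep="\t", index=False,
                       float_format="%.6g")
            return res

        peak_result = _peaks()

    apms_table = None
    if "spectral" in inputs:
        @_stage("apms")
        def _apms():
            calls = g_test_interactors(inputs["spectral"], alpha=(cfg.apms or {}).get("alpha", 0.05))
            calls.to_csv(dirs["06_apms"] / "interactor_calls.tsv", sep="\t",
                         index=False, float_format="%.6g")
            return calls

        apms_table = _apms()

    @_stage("report")
    def _report():
        tables = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "report.json")
        report = {
            "provenance": {
                "config_hash": cfg.canonical_hash(),
                "seed": cfg.seed,
                "file_checksums": {str(p.relative_to(outdir)): _sha256(p) for p in tables},
            },
            "top_regulator": diff_table.iloc[0]["regulator"],
            "top_regulator_p": float(diff_table.iloc[0]["p"]),
            "top_regulator_delta": float(diff_table.iloc[0]["delta_activity"]),
            "gsea": gsea_table[["set", "es", "nes", "p", "fdr"]].to_dict("records"),
            "peak_overlap": None if peak_result is None else {
                "fraction": peak_result.fraction, "p": peak_result.p,
            },
            "apms_n_enriched_fdr": None if apms_table is None else int(apms_table["enriched_fdr"].sum()),
        }
        with open(dirs["07_report"] / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return report

    return _report()


def run_benchmark(seed: int = 0, suite_kwargs: dict | None = None) -> pd.DataFrame:
    """Score every stage against planted truth; see :func:`regact.benchmark.run_benchmark`."""
    return bench.run_benchmark(seed=seed, suite_kwargs=suite_kwargs)
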