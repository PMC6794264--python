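"""End-to-end orchestration: simulate/read -> taxonomy -> normalize ->
periodicity -> phase binning & cascade -> seasonal window -> markers.

All intermediates are plain TSV so every summary number can be
recomputed with standard shell tools; reruns with the same seeds are
byte-identical (no wall-clock content in any output file; timing goes
to the log only).
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

import dieltx
from dieltx.circular import bin_peak_time, cascade_test
from dieltx.harmonics import call_periodic, taxon_total_periodicity, write_fits
from dieltx.lpi import assign_all, read_hit_table, write_assignments
from dieltx.matrix import (
    ingroup_synchrony,
    normalize,
    read_expression,
    write_expression,
)
from dieltx.seasonal import SeasonalWindow, classify_window, marker_ratio
from dieltx.synthetic import SimulationConfig, TaxonSpec, simulate_expression
from dieltx.timeline import Timeline

log = logging.getLogger("dieltx")


@dataclass
class PipelineConfig:
    out_dir: Path
    expression_path: Path | None = None
    hits_path: Path | None = None
    lineage_path: Path | None = None
    timeline: Timeline | None = None
    simulation: SimulationConfig | None = None
    q_threshold: float = 0.1
    fdr_scope: str = "taxon"
    test: str = "ftest"
    seed: int = 0
    tiebreak_iterations: int = 1000
    window: SeasonalWindow = field(default_factory=SeasonalWindow)
    dawn: float | None = None  # defaults to the timeline's dawn
    marker_numerator: str = "flavodoxin"
    marker_denominator: str = "ferredoxin"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path = Path(".")) -> "PipelineConfig":
        paths = raw.get("paths", {})
        sim = None
        if "simulation" in raw and raw["simulation"] is not None:
            s = dict(raw["simulation"])
            taxa = s.pop("taxa", None)
            if taxa is not None:
                s["taxa"] = [TaxonSpec(**t) for t in taxa]
            sim = SimulationConfig(**s)
        timeline = Timeline.from_dict(raw["timeline"]) if "timeline" in raw else None
        hra = raw.get("hra", {})
        phase = raw.get("phase", {})
        win = raw.get("window", {})
        markers = raw.get("markers", {})
        return cls(
            out_dir=base / raw.get("out_dir", "dieltx_out"),
            expression_path=(base / paths["expression"]) if "expression" in paths else None,
            hits_path=(base / paths["hits"]) if "hits" in paths else None,
            lineage_path=(base / paths["lineage_map"]) if "lineage_map" in paths else None,
            timeline=timeline,
            simulation=sim,
            q_threshold=float(hra.get("q_threshold", 0.1)),
            fdr_scope=hra.get("fdr_scope", "taxon"),
            test=hra.get("test", "ftest"),
            seed=int(raw.get("seed", hra.get("seed", 0))),
            tiebreak_iterations=int(phase.get("tiebreak_iterations", 1000)),
            window=SeasonalWindow(
                start_after_dawn=float(win.get("start_after_dawn", 9.9)),
                end_after_dawn=float(win.get("end_after_dawn", 14.4)),
            ),
            dawn=win.get("dawn"),
            marker_numerator=markers.get("numerator_label", "flavodoxin"),
            marker_denominator=markers.get("denominator_label", "ferredoxin"),
        )


def _stage(name: str):
    log.info("stage=%s start", name)
    return time.monotonic()


def _done(name: str, t0: float, n_rows: int | None = None) -> None:
    log.info("stage=%s done wall_s=%.2f rows=%s", name, time.monotonic() - t0, n_rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the summary dict.

    Writes, under ``config.out_dir``: expression.tsv (when simulated),
    taxonomy.tsv (when hits given), normalized_library.tsv,
    normalized_taxon.tsv, hra_fits.tsv, taxon_aggregate_fits.tsv,
    cascade.tsv, window.tsv, summary.json, provenance.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    # --- input stage: simulate or read -------------------------------
    if config.simulation is not None:
        t0 = _stage("simulate")
        sim = config.simulation
        matrix, truth = simulate_expression(sim)
        timeline = sim.timeline()
        write_expression(matrix, out / "expression.tsv")
        truth.write(out / "truth.tsv")
        _done("simulate", t0, matrix.n_orfs)
    else:
        if config.expression_path is None or config.timeline is None:
            raise ValueError("need either a simulation block or an expression path plus timeline")
        t0 = _stage("read")
        timeline = config.timeline
        matrix = read_expression(config.expression_path, timeline)
        _done("read", t0, matrix.n_orfs)

    # --- taxonomy (optional) -----------------------------------------
    if config.hits_path is not None and config.lineage_path is not None:
        t0 = _stage("assign_taxonomy")
        table = read_hit_table(config.hits_path, config.lineage_path)
        assignments = assign_all(table)
        write_assignments(assignments, out / "taxonomy.tsv")
        summary["n_queries_assigned"] = len(assignments)
        _done("assign_taxonomy", t0, len(assignments))

    # --- normalization ------------------------------------------------
    t0 = _stage("normalize")
    lib = normalize(matrix, mode="library", compartments=("nuclear", "none"))
    taxn = normalize(matrix, mode="taxon_group")
    write_expression(lib, out / "normalized_library.tsv")
    write_expression(taxn, out / "normalized_taxon.tsv")
    synchrony = {
        g: ingroup_synchrony(lib, g)
        for g in sorted(lib.taxon_group.unique())
    }
    summary["ingroup_synchrony"] = {k: None if np.isnan(v) else round(v, 6) for k, v in synchrony.items()}
    _done("normalize", t0, lib.n_orfs)

    # --- harmonic regression ------------------------------------------
    t0 = _stage("hra")
    callset = call_periodic(
        taxn,
        timeline,
        q_threshold=config.q_threshold,
        fdr_scope=config.fdr_scope,
        test=config.test,
        seed=config.seed,
    )
    fits = callset.fits
    fits = fits.join(matrix.meta[["function_label", "compartment"]])
    callset.fits = fits
    tax_summary = callset.taxon_summary(taxn)
    summary["per_taxon"] = {
        r["taxon_group"]: {
            "pct_orfs_periodic": round(float(r["pct_orfs_periodic"]), 4),
            "pct_expression_periodic": round(float(r["pct_expression_periodic"]), 4),
            "n_called": int(r["n_called"]),
            "n_tested": int(r["n_orfs_tested"]),
        }
        for _, r in tax_summary.iterrows()
    }
    agg = taxon_total_periodicity(taxn, timeline)
    agg.to_csv(out / "taxon_aggregate_fits.tsv", sep="\t", float_format="%.10g")
    summary["n_taxa_aggregate_periodic"] = int(agg["called"].sum())
    _done("hra", t0, len(fits))

    # --- phase bins + cascade -----------------------------------------
    t0 = _stage("phase")
    called = fits.loc[fits["called"] & fits["peak_time"].notna()].copy()
    fits["phase_bin"] = [
        bin_peak_time(pt).value if np.isfinite(pt) else "" for pt in fits["peak_time"]
    ]
    write_fits(callset, out / "hra_fits.tsv")
    bins = fits.loc[fits["called"], "phase_bin"].value_counts()
    n_called = int(fits["called"].sum())
    summary["phase_bins"] = {
        b: {"n": int(bins.get(b, 0)), "fraction": round(float(bins.get(b, 0)) / n_called, 6) if n_called else 0.0}
        for b in ("early_day", "late_day", "early_night", "late_night")
    }
    cascade = None
    cats = called.loc[called["function_label"] != "", "function_label"]
    if cats.nunique() >= 2 and (cats.value_counts() >= 2).sum() >= 2:
        cascade = cascade_test(
            called.loc[cats.index, "peak_time"],
            cats,
            tiebreak_iterations=config.tiebreak_iterations,
            seed=config.seed,
        )
        cascade.to_csv(out / "cascade.tsv", sep="\t", float_format="%.10g")
        summary["cascade_flagged"] = sorted(cascade.index[cascade["flagged"]].tolist())
    else:
        (out / "cascade.tsv").write_text("# too few labelled periodic categories for cascade test\n")
        summary["cascade_flagged"] = []
    _done("phase", t0, len(called))

    # --- seasonal window ----------------------------------------------
    t0 = _stage("window")
    dawn = config.dawn if config.dawn is not None else timeline.dawn
    nuclear_called = called.loc[called["compartment"] == "nuclear"]
    wc, per_taxon, top_fn = classify_window(
        nuclear_called, dawn=dawn, window=config.window, matrix=matrix
    )
    wc_out = wc.reset_index().rename(columns={wc.index.name or "index": "orf_id"})
    keep_cols = [
        c
        for c in (
            "orf_id",
            "taxon_group",
            "function_label",
            "peak_time",
            "dawn_relative_peak",
            "in_window",
        )
        if c in wc_out.columns
    ]
    wc_out[keep_cols].to_csv(out / "window.tsv", sep="\t", index=False, float_format="%.10g")
    summary["window"] = {
        "dawn": dawn,
        "start_after_dawn": config.window.start_after_dawn,
        "end_after_dawn": config.window.end_after_dawn,
        "n_called_nuclear": int(len(wc)),
        "n_in_window": int(wc["in_window"].sum()),
    }
    _done("window", t0, len(wc))

    # --- marker ratio --------------------------------------------------
    t0 = _stage("markers")
    try:
        mr = marker_ratio(matrix, config.marker_numerator, config.marker_denominator)
        summary["marker_ratio"] = {
            "numerator": mr.numerator_label,
            "denominator": mr.denominator_label,
            "pooled": None if np.isnan(mr.pooled) else round(mr.pooled, 6),
            "n_zero_denominator_timepoints": len(mr.zero_denominator_timepoints),
        }
    except ValueError as exc:
        summary["marker_ratio"] = {"error": str(exc)}
    _done("markers", t0)

    # --- summary + provenance ------------------------------------------
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    prov = {
        "dieltx_version": dieltx.__version__,
        "seed": config.seed,
        "q_threshold": config.q_threshold,
        "fdr_scope": config.fdr_scope,
        "test": config.test,
        "config_hash": _config_hash(config),
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _config_hash(config: PipelineConfig) -> str:
    # hash only analysis-relevant fields, not filesystem locations
    fields = dict(
        simulation=repr(config.simulation),
        timeline=repr(config.timeline),
        q_threshold=config.q_threshold,
        fdr_scope=config.fdr_scope,
        test=config.test,
        seed=config.seed,
        tiebreak_iterations=config.tiebreak_iterations,
        window=repr(config.window),
        dawn=config.dawn,
        markers=(config.marker_numerator, config.marker_denominator),
    )
    return hashlib.sha256(repr(sorted(fields.items())).encode()).hexdigest()[:16]


def plot_peak_polar(peak_times, path, dawn: float = 6.9, dusk: float = 19.0) -> None:
    """Minimal polar scatter of peak times on the 24-h clock."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = np.asarray(peak_times, dtype=float) * 2.0 * np.pi / 24.0
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    rng = np.random.default_rng(0)
    ax.scatter(theta, 0.8 + 0.15 * rng.random(theta.size), s=8, alpha=0.6)
    ax.set_xticks(np.arange(0, 2 * np.pi, np.pi / 4))
    ax.set_xticklabels([f"{h:02d}:00" for h in range(0, 24, 3)])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
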