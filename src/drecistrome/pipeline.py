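"""End-to-end orchestration: simulate or load inputs, partition, scan, call,
integrate, and write tables, plots and a run manifest.

Every stage-level constant the analysis depends on (MS-score threshold
0.8473, merge gap 300 bp, 5-probe rules, 120 bp minimum width, FDR 0.01,
|FC| 1.5, P1(t) 0.999, the 10 kb upstream window and the TSS profile bins)
is a named config key; the defaults are the analysis values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dre_scanner import (
    EXAMPLE_TRAINING_SEQS,
    MS_THRESHOLD,
    build_pwm,
    scan_cores,
    write_hits_bed,
)
from .enrichment_calls import (
    DEFAULT_FDR,
    MA_WINDOW_PROBES,
    MAX_FAIL_PROBES,
    MAX_GAP_BP,
    MIN_CONTINUOUS_PROBES,
    MIN_WIDTH_BP,
    call_regions,
    read_probe_track,
    write_regions_bed,
)
from .genome_model import (
    build_partition,
    read_annotation,
    read_chrom_sizes,
    segment_gene,
    write_partition_bed,
)
from .integration import (
    FC_THRESHOLD,
    P1_THRESHOLD,
    dre_count_table,
    integrate_expression,
    map_regions_to_segments,
    overlap_timepoints,
    read_expression_table,
    rollup_genes,
    tss_profile,
)
from .synthetic_data import SimConfig, simulate_all, write_outputs

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},  # SimConfig field overrides; omit section to use real inputs
    "inputs": {
        "genome": None,
        "annotation": None,
        "chrom_sizes": None,
        "probes_2hr": None,
        "probes_24hr": None,
        "expression": None,
    },
    "scan": {"ms_threshold": MS_THRESHOLD},
    "call": {
        "fdr": DEFAULT_FDR,
        "window_probes": MA_WINDOW_PROBES,
        "max_gap_bp": MAX_GAP_BP,
        "max_fail_probes": MAX_FAIL_PROBES,
        "min_width_bp": MIN_WIDTH_BP,
        "min_continuous_probes": MIN_CONTINUOUS_PROBES,
        "n_perm": 3,
    },
    "integrate": {
        "fc_threshold": FC_THRESHOLD,
        "p1_threshold": P1_THRESHOLD,
        "upstream_bp": 10_000,
        "tss_window": [-10_000, 5_000],
        "region_bin_bp": 200,
        "dre_bin_bp": 100,
    },
    "report": {"plots": True},
}


def load_config(path: Optional[str | Path] = None, seed: Optional[int] = None) -> dict:
    """Merge a YAML config over the defaults; an explicit seed wins."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _validate_config(user)
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def _validate_config(user: dict) -> None:
    known = set(DEFAULT_CONFIG)
    for key in user:
        if key not in known:
            raise ValueError(f"config: unknown section {key!r} (known: {sorted(known)})")
        if isinstance(DEFAULT_CONFIG[key], dict) and key != "simulate":
            bad = set(user[key] or {}) - set(DEFAULT_CONFIG[key])
            if bad:
                raise ValueError(f"config section {key!r}: unknown keys {sorted(bad)}")
    if "simulate" in user and user["simulate"]:
        bad = set(user["simulate"]) - set(SimConfig.__dataclass_fields__)
        if bad:
            raise ValueError(f"config section 'simulate': unknown keys {sorted(bad)}")


@dataclass
class RunManifest:
    config: dict
    seed: int
    package_version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    status: str = "running"

    def write(self, outdir: Path) -> None:
        (outdir / "manifest.json").write_text(json.dumps(asdict(self), indent=1, default=str))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    partition: object
    regions_2hr: list
    regions_24hr: list
    labels_2hr: list
    density_2hr: object
    dre_hits: dict
    profile: object
    gene_calls: dict
    crosstab: pd.DataFrame
    overlap: dict
    manifest: RunManifest
    truth: object = None


def run_pipeline(config: dict, outdir: str | Path) -> PipelineResult:
    """Execute all stages in dependency order; deterministic per config+seed.

    With a ``simulate`` section the inputs are generated on the fly (and
    written alongside the results); otherwise the ``inputs`` paths are read.
    Partial outputs are preserved on stage failure, with the manifest marking
    which stage failed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    t0 = time.time()
    stage = "simulate"
    try:
        truth = None
        if config.get("simulate") is not None:
            sim_cfg = SimConfig(seed=seed, **(config["simulate"] or {}))
            data = simulate_all(sim_cfg)
            paths = write_outputs(data, outdir / "inputs")
            sequences = data.sequences
            genes = data.genes
            tracks_2hr, tracks_24hr = data.tracks, data.tracks_24hr
            from .integration import ExpressionRecord

            expression = [
                ExpressionRecord(r["gene_symbol"], r["time_hr"], r["fold_change"], r["p1_t"])
                for r in data.expression
            ]
            truth = data.truth
            manifest.input_digests = {k: _digest(p) for k, p in paths.items()}
        else:
            inputs = config["inputs"]
            for key in ("genome", "annotation", "probes_2hr", "expression"):
                if not inputs.get(key):
                    raise ValueError(f"config inputs.{key} is required without a simulate section")
            from pyfaidx import Fasta

            fa = Fasta(inputs["genome"])
            sequences = {name: str(fa[name][:]) for name in fa.keys()}
            genes = read_annotation(inputs["annotation"])
            tracks_2hr = {t.chrom: t for t in read_probe_track(inputs["probes_2hr"])}
            tracks_24hr = (
                {t.chrom: t for t in read_probe_track(inputs["probes_24hr"])}
                if inputs.get("probes_24hr")
                else {}
            )
            expression = read_expression_table(inputs["expression"])
            manifest.input_digests = {
                k: _digest(Path(v)) for k, v in inputs.items() if v
            }
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
        manifest.stage_seconds[stage] = time.time() - t0

        stage, t0 = "partition", time.time()
        gene_regions = [segment_gene(g, chrom_lengths[g.chrom]) for g in genes]
        partition = build_partition(gene_regions, chrom_lengths)
        write_partition_bed(partition, outdir / "partition")
        manifest.stage_seconds[stage] = time.time() - t0

        stage, t0 = "scan", time.time()
        pwm = build_pwm(EXAMPLE_TRAINING_SEQS)
        dre_hits = {c: scan_cores(s, pwm, chrom=c) for c, s in sequences.items()}
        all_hits = [h for hits in dre_hits.values() for h in hits]
        write_hits_bed(all_hits, outdir / "dre_hits.bed")
        logger.info("scan: %d DRE cores across %d chromosomes", len(all_hits), len(dre_hits))
        manifest.stage_seconds[stage] = time.time() - t0

        stage, t0 = "call", time.time()
        call_cfg = config["call"]
        rng = np.random.default_rng(seed + 1)
        regions_2hr, regions_24hr = [], []
        for label, tracks, dest in (
            ("2hr", tracks_2hr, regions_2hr),
            ("24hr", tracks_24hr, regions_24hr),
        ):
            for chrom in sorted(tracks):
                regs, cutoff = call_regions(
                    tracks[chrom],
                    fdr=call_cfg["fdr"],
                    rng=rng,
                    n_perm=call_cfg["n_perm"],
                    window_probes=call_cfg["window_probes"],
                    max_gap_bp=call_cfg["max_gap_bp"],
                    max_fail_probes=call_cfg["max_fail_probes"],
                    min_width_bp=call_cfg["min_width_bp"],
                    min_continuous_probes=call_cfg["min_continuous_probes"],
                )
                logger.info("call %s %s: cutoff %.3f, %d regions", label, chrom, cutoff, len(regs))
                dest.extend(regs)
        write_regions_bed(regions_2hr, outdir / "regions_2hr.bed")
        write_regions_bed(regions_24hr, outdir / "regions_24hr.bed")
        manifest.stage_seconds[stage] = time.time() - t0

        stage, t0 = "integrate", time.time()
        icfg = config["integrate"]
        labels, density = map_regions_to_segments(regions_2hr, partition)
        profile = tss_profile(
            regions_2hr,
            dre_hits,
            gene_regions,
            window=tuple(icfg["tss_window"]),
            region_bin_bp=icfg["region_bin_bp"],
            dre_bin_bp=icfg["dre_bin_bp"],
        )
        overlap = overlap_timepoints(regions_2hr, regions_24hr)
        gene_calls = rollup_genes(
            regions_2hr, gene_regions, dre_hits, ms_threshold=config["scan"]["ms_threshold"]
        )
        gene_calls, crosstab = integrate_expression(
            gene_calls,
            expression,
            fc_threshold=icfg["fc_threshold"],
            p1_threshold=icfg["p1_threshold"],
        )
        manifest.stage_seconds[stage] = time.time() - t0

        stage, t0 = "report", time.time()
        result = PipelineResult(
            outdir=outdir,
            partition=partition,
            regions_2hr=regions_2hr,
            regions_24hr=regions_24hr,
            labels_2hr=labels,
            density_2hr=density,
            dre_hits=dre_hits,
            profile=profile,
            gene_calls=gene_calls,
            crosstab=crosstab,
            overlap=overlap,
            manifest=manifest,
            truth=truth,
        )
        write_tables(result)
        if config.get("report", {}).get("plots", True):
            try:
                plot_summaries(result)
            except Exception:  # plotting must never abort the data run
                logger.exception("plot_summaries failed; data outputs are complete")
        manifest.stage_seconds[stage] = time.time() - t0
        manifest.status = "complete"
    except Exception:
        manifest.status = f"failed at stage {stage}"
        manifest.write(outdir)
        raise
    manifest.outputs = sorted(
        str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
    )
    manifest.write(outdir)
    return result


def write_tables(result: PipelineResult) -> dict[str, Path]:
    """Emit the density table, DRE-count table, TSS profile, gene calls and
    expression cross-tab as TSVs (percentages to 1 decimal).

    Empty inputs produce zero-count tables, not absent files.
    """
    outdir = result.outdir
    paths: dict[str, Path] = {}

    density_df = result.density_2hr.to_frame()
    density_df["density_per_mbp"] = density_df["density_per_mbp"].round(4)
    paths["density"] = outdir / "density_table.tsv"
    density_df.to_csv(paths["density"], sep="\t", index=False)

    dre_df = dre_count_table(result.regions_2hr, result.dre_hits)
    total = int(dre_df["n_regions"].sum())
    dre_df["pct_of_regions"] = (
        (100 * dre_df["n_regions"] / total).round(1) if total else 0.0
    )
    paths["dre_counts"] = outdir / "dre_count_table.tsv"
    dre_df.to_csv(paths["dre_counts"], sep="\t", index=False)

    paths["tss_profile"] = outdir / "tss_profile.tsv"
    prof = result.profile.to_frame()
    prof.to_csv(paths["tss_profile"], sep="\t", index=False)

    rows = []
    for rec in result.gene_calls.values():
        rows.append(
            {
                "gene_symbol": rec.gene_symbol,
                "has_enrichment": rec.has_enrichment,
                "dre_class": rec.dre_class or "",
                "final_class": rec.final_class,
                "n_deg_timepoints": sum(1 for v in rec.expression.values() if v["deg"]),
            }
        )
    paths["gene_calls"] = outdir / "gene_calls.tsv"
    pd.DataFrame(
        rows,
        columns=["gene_symbol", "has_enrichment", "dre_class", "final_class", "n_deg_timepoints"],
    ).to_csv(paths["gene_calls"], sep="\t", index=False)

    paths["crosstab"] = outdir / "expression_crosstab.tsv"
    result.crosstab.to_csv(paths["crosstab"], sep="\t", index=False)

    summary = {
        "n_regions_2hr": len(result.regions_2hr),
        "n_regions_24hr": len(result.regions_24hr),
        "n_overlap": result.overlap["n_overlap"],
        "pearson_r": result.overlap["pearson_r"],
        "p_value": result.overlap["p_value"],
    }
    paths["overlap"] = outdir / "timepoint_overlap.json"
    paths["overlap"].write_text(json.dumps(summary, indent=1))
    return paths


def published_table_statistics(counts: dict) -> dict:
    """Summary ratios from printed region/gene counts (table arithmetic layer).

    ``counts`` carries raw integers (region totals, per-class counts, DRE-core
    histogram, gene and DEG tallies); the returned percentages are rounded to
    1 decimal, matching report style. This is the same arithmetic the
    write_tables layer applies to pipeline counts, factored out so it can run
    on any externally supplied count set.
    """
    out: dict[str, float] = {}

    def pct(num, den):
        return round(100.0 * num / den, 1)

    if {"intragenic_2hr", "total_2hr"} <= counts.keys():
        out["pct_intragenic_2hr"] = pct(counts["intragenic_2hr"], counts["total_2hr"])
    if {"intragenic_24hr", "total_24hr"} <= counts.keys():
        out["pct_intragenic_24hr"] = pct(counts["intragenic_24hr"], counts["total_24hr"])
    if "dre_core_histogram_2hr" in counts:
        hist = counts["dre_core_histogram_2hr"]
        out["total_regions_2hr_from_histogram"] = float(sum(hist.values()))
        out["pct_no_core_2hr"] = pct(hist.get(0, 0), sum(hist.values()))
    if "dre_core_histogram_24hr" in counts:
        hist = counts["dre_core_histogram_24hr"]
        out["total_regions_24hr_from_histogram"] = float(sum(hist.values()))
        out["pct_no_core_24hr"] = pct(hist.get(0, 0), sum(hist.values()))
    if {"with_core_2hr", "with_core_24hr"} <= counts.keys():
        out["total_regions_with_core"] = float(
            counts["with_core_2hr"] + counts["with_core_24hr"]
        )
    if {"intragenic_with_core_2hr", "intragenic_text_2hr"} <= counts.keys():
        out["pct_intragenic_with_core_2hr"] = pct(
            counts["intragenic_with_core_2hr"], counts["intragenic_text_2hr"]
        )
    if {"intragenic_with_core_24hr", "intragenic_text_24hr"} <= counts.keys():
        out["pct_intragenic_with_core_24hr"] = pct(
            counts["intragenic_with_core_24hr"], counts["intragenic_text_24hr"]
        )
    if {"alt_element_no_core_2hr", "no_core_2hr"} <= counts.keys():
        out["pct_alt_element_2hr"] = pct(
            counts["alt_element_no_core_2hr"], counts["no_core_2hr"]
        )
    if {"alt_element_no_core_24hr", "no_core_24hr"} <= counts.keys():
        out["pct_alt_element_24hr"] = pct(
            counts["alt_element_no_core_24hr"], counts["no_core_24hr"]
        )
    if {"deg_with_enrichment", "deg_total"} <= counts.keys():
        out["pct_deg_with_enrichment"] = pct(
            counts["deg_with_enrichment"], counts["deg_total"]
        )
    if {"genes_with_core_2hr", "genes_enriched_2hr"} <= counts.keys():
        out["pct_genes_with_core_2hr"] = pct(
            counts["genes_with_core_2hr"], counts["genes_enriched_2hr"]
        )
    return out


def plot_summaries(result: PipelineResult) -> list[Path]:
    """TSS-profile figure + per-chromosome track summary (static matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = result.outdir
    written = []

    prof = result.profile
    fig, ax1 = plt.subplots(figsize=(8, 4))
    centers = (prof.region_bin_edges[:-1] + prof.region_bin_edges[1:]) / 2
    ax1.bar(centers, prof.region_counts, width=np.diff(prof.region_bin_edges), color="tab:red",
            alpha=0.7, label="enriched regions / 200 bp")
    ax1.set_xlabel("position relative to TSS (bp)")
    ax1.set_ylabel("enriched regions")
    ax2 = ax1.twinx()
    dcenters = (prof.dre_bin_edges[:-1] + prof.dre_bin_edges[1:]) / 2
    ax2.plot(dcenters, prof.dre_counts, color="tab:purple", label="DRE cores / 100 bp")
    ax2.set_ylabel("DRE cores")
    fig.tight_layout()
    p = outdir / "tss_profile.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)

    chroms = sorted(result.partition.chrom_lengths)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 1.6 * max(1, len(chroms))),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        L = result.partition.chrom_lengths[chrom]
        for s, e in result.partition.intragenic.get(chrom, []):
            ax.axvspan(s, e, color="0.85", zorder=0)
        for r in result.regions_2hr:
            if r.chrom == chrom:
                ax.plot([r.start, r.end], [1, 1], color="tab:red", lw=3)
        hits = result.dre_hits.get(chrom, [])
        if hits:
            ax.plot([h.core_center for h in hits], [0.5] * len(hits), "|",
                    color="tab:purple", ms=4)
        ax.set_xlim(0, L)
        ax.set_ylim(0, 1.5)
        ax.set_yticks([])
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    p = outdir / "chromosome_summary.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    written.append(p)
    return written
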