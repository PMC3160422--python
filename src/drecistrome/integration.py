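"""Cistrome-transcriptome integration.

Maps enriched regions onto the genome partition (density tables), builds
TSS-centered binding profiles, measures peak-to-DRE distances, compares
region sets across time points, rolls enrichment and DRE content up to genes,
and joins differential-expression calls (|FC| >= 1.5, P1(t) > 0.999) to
classify genes as AhR+DRE (putative direct, DRE-mediated), AhR-only,
expression-only or none.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dre_scanner import DreHit, classify_dre_content, MS_THRESHOLD
from .enrichment_calls import EnrichedRegion
from .genome_model import GenomePartition, GeneRegion, REGION_CLASSES, SEGMENT_CLASSES
from .intervals import IntervalIndex

logger = logging.getLogger(__name__)

FC_THRESHOLD = 1.5
P1_THRESHOLD = 0.999
TIME_POINTS = (2, 4, 8, 12, 18, 24, 72, 168)

TSS_WINDOW = (-10_000, 5_000)
REGION_BIN_BP = 200
DRE_BIN_BP = 100

DRE_CLASS_RANK = {"high_dre": 2, "low_dre": 1, "no_core": 0}


@dataclass
class DensityTable:
    """Region counts, class lengths and densities (count per Mbp) per class."""

    counts: dict[str, int]
    lengths: dict[str, int]

    @property
    def densities(self) -> dict[str, float]:
        return {
            cls: (self.counts[cls] / (self.lengths[cls] / 1e6) if self.lengths[cls] else 0.0)
            for cls in self.counts
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_class": list(self.counts),
                "n_regions": [self.counts[c] for c in self.counts],
                "length_bp": [self.lengths[c] for c in self.counts],
                "density_per_mbp": [self.densities[c] for c in self.counts],
            }
        )


@dataclass
class TssProfile:
    """Binding density around TSSs: region counts per 200 bp, cores per 100 bp."""

    window: tuple[int, int]
    region_bin_edges: np.ndarray
    region_counts: np.ndarray
    dre_bin_edges: np.ndarray
    dre_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.region_bin_edges[:-1].astype(int),
                "bin_end": self.region_bin_edges[1:].astype(int),
                "n_regions": self.region_counts.astype(int),
            }
        )


@dataclass
class ExpressionRecord:
    gene_symbol: str
    time_hr: int
    fold_change: float  # signed linear fold change
    p1_t: float


@dataclass
class GeneCallRecord:
    gene_symbol: str
    has_enrichment: bool
    dre_class: Optional[str] = None  # defined only when has_enrichment
    expression: dict[int, dict] = field(default_factory=dict)  # time -> {fc, p1, deg, direction}
    final_class: str = "none"


def _tss_relative(pos: int, gene: GeneRegion) -> int:
    """Signed TSS-relative coordinate; - strand genes flip orientation."""
    return pos - gene.tss if gene.strand == "+" else gene.tss - pos


def map_regions_to_segments(
    regions: Sequence[EnrichedRegion],
    partition: GenomePartition,
) -> tuple[list[str], DensityTable]:
    """Assign regions to partition classes (any-overlap rule) and tabulate.

    A region overlapping >= 1 intragenic bp is intragenic, else intergenic,
    so intergenic + intragenic counts equal the genome count. Segment-class
    counts apply the same any-overlap rule per class independently. Regions
    on chromosomes absent from the partition are excluded with a log message.
    """
    intr_idx = {c: IntervalIndex(ivs) for c, ivs in partition.intragenic.items()}
    seg_idx = {
        cls: {c: IntervalIndex(ivs) for c, ivs in partition.segment_index.get(cls, {}).items()}
        for cls in SEGMENT_CLASSES
    }
    labels: list[str] = []
    counts = {cls: 0 for cls in REGION_CLASSES}
    for r in regions:
        if r.chrom not in partition.chrom_lengths:
            logger.warning("map_regions_to_segments: unknown chrom %s; region excluded", r.chrom)
            labels.append("excluded")
            continue
        counts["genome"] += 1
        if intr_idx[r.chrom].overlaps(r.start, r.end):
            labels.append("intragenic")
            counts["intragenic"] += 1
        else:
            labels.append("intergenic")
            counts["intergenic"] += 1
        for cls in SEGMENT_CLASSES:
            idx = seg_idx[cls].get(r.chrom)
            if idx is not None and idx.overlaps(r.start, r.end):
                counts[cls] += 1
    from .genome_model import region_lengths

    return labels, DensityTable(counts=counts, lengths=region_lengths(partition))


def tss_profile(
    regions: Sequence[EnrichedRegion],
    dre_hits: Mapping[str, Sequence[DreHit]],
    gene_regions: Sequence[GeneRegion],
    window: tuple[int, int] = TSS_WINDOW,
    region_bin_bp: int = REGION_BIN_BP,
    dre_bin_bp: int = DRE_BIN_BP,
) -> TssProfile:
    """Histogram enrichment maxima and DRE core centers around every TSS.

    Each region contributes through its max-enrichment position once for
    every gene whose window contains it; each DRE core through its central
    base. Coordinates are strand-flipped for - genes.
    """
    lo, hi = window
    region_edges = np.arange(lo, hi + region_bin_bp, region_bin_bp)
    dre_edges = np.arange(lo, hi + dre_bin_bp, dre_bin_bp)
    region_rel: list[int] = []
    dre_rel: list[int] = []
    by_chrom_regions: dict[str, list[EnrichedRegion]] = {}
    for r in regions:
        by_chrom_regions.setdefault(r.chrom, []).append(r)
    for g in gene_regions:
        for r in by_chrom_regions.get(g.chrom, []):
            rel = _tss_relative(r.max_position, g)
            if lo <= rel < hi:
                region_rel.append(rel)
        for h in dre_hits.get(g.chrom, []):
            rel = _tss_relative(h.core_center, g)
            if lo <= rel < hi:
                dre_rel.append(rel)
    region_counts, _ = np.histogram(region_rel, bins=region_edges)
    dre_counts, _ = np.histogram(dre_rel, bins=dre_edges)
    return TssProfile(
        window=window,
        region_bin_edges=region_edges,
        region_counts=region_counts,
        dre_bin_edges=dre_edges,
        dre_counts=dre_counts,
    )


def peak_to_dre_distance(
    region: EnrichedRegion,
    dre_hits: Sequence[DreHit],
) -> Optional[int]:
    """Distance (bp) from the max-enrichment position to the nearest in-region core.

    None when the region contains no core.
    """
    dists = [
        abs(region.max_position - h.core_center)
        for h in dre_hits
        if region.start <= h.core_start < region.end
    ]
    return min(dists) if dists else None


def overlap_timepoints(
    regions_t1: Sequence[EnrichedRegion],
    regions_t2: Sequence[EnrichedRegion],
) -> dict:
    """Pair later-time regions with overlapping earlier-time regions.

    Overlap means >= 1 bp interval intersection on the same chromosome; a t2
    region overlapping several t1 regions pairs with the t1 region of
    greatest fold enrichment. Pearson r is computed on the paired log2 fold
    enrichments with its two-sided t-transform p-value (undefined below 3
    pairs).
    """
    by_chrom: dict[str, list[EnrichedRegion]] = {}
    for r in regions_t1:
        by_chrom.setdefault(r.chrom, []).append(r)
    idx = {
        c: IntervalIndex([(r.start, r.end) for r in rs]) for c, rs in by_chrom.items()
    }
    pairs: list[tuple[EnrichedRegion, EnrichedRegion]] = []
    for r2 in regions_t2:
        if r2.chrom not in idx:
            continue
        cand = [by_chrom[r2.chrom][i] for i in idx[r2.chrom].overlapping(r2.start, r2.end)]
        if cand:
            best = max(cand, key=lambda r: r.fold_enrichment)
            pairs.append((best, r2))
    out = {
        "n_t1": len(regions_t1),
        "n_t2": len(regions_t2),
        "n_overlap": len(pairs),
        "pairs": pairs,
        "pearson_r": None,
        "p_value": None,
    }
    if len(pairs) >= 3:
        x = np.log2([p[0].fold_enrichment for p in pairs])
        y = np.log2([p[1].fold_enrichment for p in pairs])
        if np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
            out["pearson_r"], out["p_value"] = float(r), float(p)
    return out


def rollup_genes(
    regions: Sequence[EnrichedRegion],
    gene_regions: Sequence[GeneRegion],
    dre_hits: Mapping[str, Sequence[DreHit]],
    ms_threshold: float = MS_THRESHOLD,
) -> dict[str, GeneCallRecord]:
    """Per-gene enrichment/DRE rollup (expression fields left empty).

    A gene is enriched iff >= 1 region overlaps its full span; its DRE class
    is the best class over those regions (high > low > no_core), so a gene
    with one coreless and one high-scoring region is high_dre — multiple
    enrichment events per gene may mix classes.
    """
    by_chrom_regions: dict[str, list[EnrichedRegion]] = {}
    for r in regions:
        by_chrom_regions.setdefault(r.chrom, []).append(r)
    region_class: dict[int, str] = {}
    for chrom, rs in by_chrom_regions.items():
        hits = dre_hits.get(chrom, [])
        for r in rs:
            cls, _ = classify_dre_content((r.start, r.end), hits, ms_threshold)
            region_class[id(r)] = cls

    out: dict[str, GeneCallRecord] = {}
    for g in gene_regions:
        rec = out.setdefault(g.gene_symbol, GeneCallRecord(g.gene_symbol, False))
        span_s, span_e = g.full_span
        for r in by_chrom_regions.get(g.chrom, []):
            if r.start < span_e and r.end > span_s:
                rec.has_enrichment = True
                cls = region_class[id(r)]
                if rec.dre_class is None or DRE_CLASS_RANK[cls] > DRE_CLASS_RANK[rec.dre_class]:
                    rec.dre_class = cls
    return out


def read_expression_table(path) -> list[ExpressionRecord]:
    """Expression TSV: gene_symbol, time_hr, fold_change, p1_t (long format)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ExpressionRecord(
            gene_symbol=str(row.gene_symbol),
            time_hr=int(row.time_hr),
            fold_change=float(row.fold_change),
            p1_t=float(row.p1_t),
        )
        for row in df.itertuples()
    ]


def integrate_expression(
    gene_calls: Mapping[str, GeneCallRecord],
    expression: Iterable[ExpressionRecord],
    fc_threshold: float = FC_THRESHOLD,
    p1_threshold: float = P1_THRESHOLD,
) -> tuple[dict[str, GeneCallRecord], pd.DataFrame]:
    """Join expression onto gene calls and produce the per-time-point cross-tab.

    A gene is differentially expressed at a time point when |FC| >= 1.5 and
    P1(t) > 0.999. The cross-tab counts, per time point and direction: DEGs
    total, DEGs with enrichment, and DEGs with enrichment plus a DRE core.
    Final gene classes: AhR+DRE (enriched, core-bearing, DEG somewhere),
    AhR-only (enriched, not that), expression-only, none. Duplicate
    (gene, time) expression rows keep the max-|FC| record.
    """
    calls = {s: rec for s, rec in gene_calls.items()}

    best: dict[tuple[str, int], ExpressionRecord] = {}
    n_dup = 0
    for e in expression:
        key = (e.gene_symbol, e.time_hr)
        if key in best:
            n_dup += 1
            if abs(e.fold_change) > abs(best[key].fold_change):
                best[key] = e
        else:
            best[key] = e
    if n_dup:
        logger.info("integrate_expression: %d duplicate expression rows collapsed", n_dup)

    n_unmatched = 0
    for (symbol, t), e in best.items():
        rec = calls.get(symbol)
        if rec is None:
            n_unmatched += 1
            rec = calls[symbol] = GeneCallRecord(symbol, False)
        deg = abs(e.fold_change) >= fc_threshold and e.p1_t > p1_threshold
        rec.expression[t] = {
            "fold_change": e.fold_change,
            "p1_t": e.p1_t,
            "deg": deg,
            "direction": "up" if e.fold_change >= 0 else "down",
        }
    if n_unmatched:
        logger.info("integrate_expression: %d expression genes absent from gene calls", n_unmatched)

    rows = []
    times = sorted({t for rec in calls.values() for t in rec.expression})
    for t in times:
        for direction in ("up", "down"):
            degs = [
                rec
                for rec in calls.values()
                if t in rec.expression
                and rec.expression[t]["deg"]
                and rec.expression[t]["direction"] == direction
            ]
            with_enr = [r for r in degs if r.has_enrichment]
            with_dre = [r for r in with_enr if r.dre_class in ("high_dre", "low_dre")]
            rows.append(
                {
                    "time_hr": t,
                    "direction": direction,
                    "n_deg": len(degs),
                    "n_deg_with_enrichment": len(with_enr),
                    "n_deg_with_enrichment_and_dre": len(with_dre),
                }
            )
    crosstab = pd.DataFrame(rows)

    for rec in calls.values():
        deg_any = any(v["deg"] for v in rec.expression.values())
        if rec.has_enrichment and rec.dre_class in ("high_dre", "low_dre") and deg_any:
            rec.final_class = "AhR+DRE"
        elif rec.has_enrichment:
            rec.final_class = "AhR-only"
        elif deg_any:
            rec.final_class = "expression-only"
        else:
            rec.final_class = "none"
    return calls, crosstab


def overrep_zscore(
    regions: Sequence[EnrichedRegion],
    motif_counter,
    background_rate_per_bp: float,
) -> dict:
    """Motif over-representation in regions vs a genomic background rate.

    ``motif_counter(chrom, start, end) -> int`` counts motif occurrences in an
    interval. Expected count = background rate per bp x total region bp;
    z = (obs - exp)/sqrt(exp) under the Poisson approximation, flagged
    significant at z > 3; over-representation ratio obs/exp is reported.
    z is undefined (None) when the expectation is zero.
    """
    total_bp = sum(r.end - r.start for r in regions)
    obs = sum(motif_counter(r.chrom, r.start, r.end) for r in regions)
    exp = background_rate_per_bp * total_bp
    if exp <= 0:
        logger.warning("overrep_zscore: zero expected count; z undefined")
        return {"observed": obs, "expected": 0.0, "z": None, "ratio": None, "significant": False}
    z = (obs - exp) / math.sqrt(exp)
    return {
        "observed": int(obs),
        "expected": float(exp),
        "z": float(z),
        "ratio": float(obs / exp),
        "significant": bool(z > 3),
    }


def dre_count_table(
    regions: Sequence[EnrichedRegion],
    dre_hits: Mapping[str, Sequence[DreHit]],
) -> pd.DataFrame:
    """Regions binned by number of in-region DRE cores (bin rows sum to total)."""
    counts = []
    for r in regions:
        _, n = classify_dre_content((r.start, r.end), dre_hits.get(r.chrom, []))
        counts.append(n)
    max_n = max(counts, default=0)
    rows = [
        {"n_dre_cores": k, "n_regions": sum(1 for c in counts if c == k)}
        for k in range(max_n + 1)
    ]
    return pd.DataFrame(rows, columns=["n_dre_cores", "n_regions"])
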