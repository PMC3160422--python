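"""Gene models, gene-region segmentation and the intragenic/intergenic partition.

A *gene region* spans the 10 kb upstream of a transcript's TSS through the end
of the transcript, strand-aware. Merging all gene regions (both strands
pooled; overlapping isoforms fused into their longest spanning range) yields
the *intragenic* DNA of each chromosome; the complement is the non-transcribed
*intergenic* DNA. Per-gene segments (10 kb upstream window, 5' UTR, CDS,
3' UTR) are exonic unions used for enrichment-density bookkeeping.

Coordinates are 0-based half-open throughout (UCSC refGene convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .intervals import (
    Interval,
    IntervalIndex,
    clip_interval,
    complement_intervals,
    merge_intervals,
    total_length,
)

logger = logging.getLogger(__name__)

UPSTREAM_BP = 10_000

SEGMENT_CLASSES = ("upstream10k", "utr5", "cds", "utr3")
REGION_CLASSES = ("genome", "intergenic", "intragenic") + SEGMENT_CLASSES


@dataclass
class GeneAnnotation:
    """One transcript model from a refGene-style annotation row."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[Interval]

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: txStart {self.tx_start} >= txEnd {self.tx_end}"
            )
        if not self.cds_start <= self.cds_end:
            raise ValueError(f"{self.transcript_id}: cdsStart > cdsEnd")
        if not (self.tx_start <= self.cds_start and self.cds_end <= self.tx_end):
            raise ValueError(f"{self.transcript_id}: CDS outside transcript bounds")
        prev_end = None
        for s, e in self.exons:
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.transcript_id}: exon ({s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """TSS coordinate: tx_start on +, tx_end - 1's right edge on - (tx_end)."""
        return self.tx_start if self.strand == "+" else self.tx_end


@dataclass
class GeneRegion:
    """Strand-aware segmentation of one gene region."""

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tss: int
    segments: dict[str, list[Interval]]
    full_span: Interval


@dataclass
class GenomePartition:
    """Disjoint intragenic/intergenic labelling of every base plus segment index."""

    chrom_lengths: dict[str, int]
    intragenic: dict[str, list[Interval]]
    intergenic: dict[str, list[Interval]]
    segment_index: dict[str, dict[str, list[Interval]]] = field(default_factory=dict)

    def intragenic_index(self, chrom: str) -> IntervalIndex:
        return IntervalIndex(self.intragenic.get(chrom, []))


# refGene dump column order (after the optional leading `bin` column)
_REFGENE_COLS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds"
).split()


def _parse_block_list(text: str) -> list[int]:
    return [int(x) for x in text.rstrip(",").split(",") if x]


def read_annotation(
    path: str | Path,
    symbol_map: str | Path | None = None,
) -> list[GeneAnnotation]:
    """Read a refGene-style TSV, keeping mature (NM_-prefixed) transcripts only.

    The dialect is the UCSC refGene dump: tab-separated, optional leading
    numeric ``bin`` column, then name/chrom/strand/txStart/txEnd/cdsStart/
    cdsEnd/exonCount/exonStarts/exonEnds, optionally followed by score and
    name2 (gene symbol). ``symbol_map`` is a refLink-style two-plus-column TSV
    mapping transcript id -> gene symbol and overrides any name2 column.

    XM_/NR_ (predicted / non-coding) transcripts are skipped with a logged
    count; malformed rows raise with their line number.
    """
    symbols: dict[str, str] = {}
    if symbol_map is not None:
        with open(symbol_map) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    # refLink: name(symbol), product, mrnaAcc ... or acc<TAB>symbol
                    if parts[0].startswith(("NM_", "NR_", "XM_", "XR_")):
                        symbols[parts[0]] = parts[1]
                    else:
                        acc = next((p for p in parts if p.startswith("NM_")), None)
                        if acc:
                            symbols[acc] = parts[0]

    genes: list[GeneAnnotation] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts and parts[0].isdigit():  # leading UCSC bin column
                parts = parts[1:]
            if len(parts) < len(_REFGENE_COLS):
                raise ValueError(
                    f"{path} line {lineno}: expected >= {len(_REFGENE_COLS)} columns, "
                    f"got {len(parts)}"
                )
            row = dict(zip(_REFGENE_COLS, parts))
            name = row["name"]
            if not name.startswith("NM_"):
                n_skipped += 1
                continue
            try:
                starts = _parse_block_list(row["exonStarts"])
                ends = _parse_block_list(row["exonEnds"])
                if len(starts) != len(ends):
                    raise ValueError("exonStarts/exonEnds length mismatch")
                symbol = symbols.get(name) or (parts[11] if len(parts) > 11 else name)
                g = GeneAnnotation(
                    transcript_id=name,
                    gene_symbol=symbol,
                    chrom=row["chrom"],
                    strand=row["strand"],
                    tx_start=int(row["txStart"]),
                    tx_end=int(row["txEnd"]),
                    cds_start=int(row["cdsStart"]),
                    cds_end=int(row["cdsEnd"]),
                    exons=list(zip(starts, ends)),
                )
                g.validate()
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            genes.append(g)
    if n_skipped:
        logger.info("read_annotation: skipped %d non-NM_ transcripts", n_skipped)
    return genes


def segment_gene(g: GeneAnnotation, chrom_length: int) -> GeneRegion:
    """Derive the 10 kb upstream window and exonic UTR5/CDS/UTR3 unions.

    On the + strand the upstream window is ``[tx_start - 10k, tx_start)``; on
    the - strand it mirrors to ``[tx_end, tx_end + 10k)``. Windows running off
    the chromosome are clipped (with a warning) rather than the gene dropped.
    UTR/CDS segments are intersections of the exons with the strand-oriented
    CDS bounds; a transcript with an empty CDS yields empty UTR/CDS lists.
    """
    g.validate()
    if g.strand == "+":
        up = clip_interval(g.tx_start - UPSTREAM_BP, g.tx_start, chrom_length)
    else:
        up = clip_interval(g.tx_end, g.tx_end + UPSTREAM_BP, chrom_length)
    if up[1] - up[0] < UPSTREAM_BP:
        logger.warning(
            "segment_gene: %s upstream window clipped to %d bp at chromosome edge",
            g.transcript_id,
            max(0, up[1] - up[0]),
        )

    utr5: list[Interval] = []
    cds: list[Interval] = []
    utr3: list[Interval] = []
    if g.cds_start < g.cds_end:
        # left/right of CDS in genome coordinates; swap labels on - strand
        for es, ee in g.exons:
            left = (es, min(ee, g.cds_start))
            mid = (max(es, g.cds_start), min(ee, g.cds_end))
            right = (max(es, g.cds_end), ee)
            if left[1] > left[0]:
                (utr5 if g.strand == "+" else utr3).append(left)
            if mid[1] > mid[0]:
                cds.append(mid)
            if right[1] > right[0]:
                (utr3 if g.strand == "+" else utr5).append(right)
        utr5.sort()
        utr3.sort()

    span_parts = [up, (g.tx_start, g.tx_end)] if up[1] > up[0] else [(g.tx_start, g.tx_end)]
    full = (min(s for s, _ in span_parts), max(e for _, e in span_parts))
    return GeneRegion(
        transcript_id=g.transcript_id,
        gene_symbol=g.gene_symbol,
        chrom=g.chrom,
        strand=g.strand,
        tss=g.tss,
        segments={
            "upstream10k": [up] if up[1] > up[0] else [],
            "utr5": utr5,
            "cds": cds,
            "utr3": utr3,
        },
        full_span=full,
    )


def build_partition(
    regions: Iterable[GeneRegion],
    chrom_lengths: Mapping[str, int],
) -> GenomePartition:
    """Merge gene-region full spans into the intragenic set and complement it.

    Both strands are pooled and overlapping (or half-open-adjacent) spans are
    fused, so tissue-specific isoforms collapse to their longest spanning
    range and opposite-strand overlapping genes form a single block. With no
    genes the whole genome is intergenic.
    """
    by_chrom: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    seg_by_class: dict[str, dict[str, list[Interval]]] = {
        cls: {c: [] for c in chrom_lengths} for cls in SEGMENT_CLASSES
    }
    for r in regions:
        if r.chrom not in chrom_lengths:
            logger.warning("build_partition: %s on unknown chrom %s", r.transcript_id, r.chrom)
            continue
        L = chrom_lengths[r.chrom]
        s, e = clip_interval(*r.full_span, L)
        if e > s:
            by_chrom[r.chrom].append((s, e))
        for cls in SEGMENT_CLASSES:
            for iv in r.segments[cls]:
                civ = clip_interval(*iv, L)
                if civ[1] > civ[0]:
                    seg_by_class[cls][r.chrom].append(civ)

    intragenic = {c: merge_intervals(ivs) for c, ivs in by_chrom.items()}
    intergenic = {
        c: complement_intervals(intragenic[c], chrom_lengths[c]) for c in chrom_lengths
    }
    segment_index = {
        cls: {c: merge_intervals(ivs) for c, ivs in per_chrom.items()}
        for cls, per_chrom in seg_by_class.items()
    }
    return GenomePartition(
        chrom_lengths=dict(chrom_lengths),
        intragenic=intragenic,
        intergenic=intergenic,
        segment_index=segment_index,
    )


def region_lengths(p: GenomePartition) -> dict[str, int]:
    """Cumulative bp per region class.

    Segment-class totals are over the merged per-class union, so a base shared
    by two genes' upstream windows counts once for upstream10k — but the same
    base may also count under another class (e.g. inside a third gene's CDS):
    classes are merged independently.
    """
    out = {
        "genome": sum(p.chrom_lengths.values()),
        "intergenic": sum(total_length(ivs) for ivs in p.intergenic.values()),
        "intragenic": sum(total_length(ivs) for ivs in p.intragenic.values()),
    }
    for cls in SEGMENT_CLASSES:
        out[cls] = sum(total_length(ivs) for ivs in p.segment_index.get(cls, {}).values())
    return out


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chrom <TAB> length."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, length = line.split()[:2]
            out[chrom] = int(length)
    return out


def write_partition_bed(p: GenomePartition, outdir: str | Path) -> list[Path]:
    """Export each partition class as a BED file (one file per class)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    classes: dict[str, dict[str, list[Interval]]] = {
        "intragenic": p.intragenic,
        "intergenic": p.intergenic,
        **{cls: p.segment_index.get(cls, {}) for cls in SEGMENT_CLASSES},
    }
    for cls, per_chrom in classes.items():
        path = outdir / f"{cls}.bed"
        with open(path, "w") as fh:
            for chrom in sorted(per_chrom):
                for s, e in per_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
        written.append(path)
    return written
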