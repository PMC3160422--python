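"""Synthetic mini-genomes with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of an in vivo AhR ChIP-chip
study: enriched regions with log-normal widths (~90% <= 1,500 bp) and folds
(median ~5.7x, clipped to the observed 1.7-111.4x range), unevenly tiled
probes with occasional coverage gaps, DRE cores concentrated near TSSs over a
thinned background rate, a decayed second time point with correlated folds,
and an eight-time-point expression table with planted differential calls.
Everything is deterministic under a fixed seed, and every planted quantity is
serialized as ground truth so downstream recovery can be scored.

It does not model array biochemistry: probe intensities are Gaussian on the
log2 scale with a shared per-probe affinity term, and genome background is
i.i.d. uniform (no GC skew or repeats), which keeps motif-rate checks exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .dre_scanner import CORE, CORE_RC, EXAMPLE_TRAINING_SEQS, build_pwm, PWM_WIDTH
from .enrichment_calls import ProbeTrack
from .genome_model import GeneAnnotation

_BASES = np.frombuffer(b"ACGT", dtype="S1")

TIME_POINTS = (2, 4, 8, 12, 18, 24, 72, 168)


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's study conditions."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 750_000
    n_genes: int = 30
    gene_min_len: int = 3_000
    gene_max_len: int = 15_000
    # tiling probes
    probe_length: int = 25
    probe_extra_spacing: tuple[int, int] = (5, 16)  # uniform bp added between probes
    gap_prob: float = 0.0015  # per probe, start a coverage gap
    gap_length: tuple[int, int] = (500, 3_000)
    n_replicates: int = 3
    noise_sd: float = 0.35  # replicate log2 noise
    probe_affinity_sd: float = 0.3  # shared treatment/control probe effect
    # planted enriched regions
    n_regions: int = 200
    width_log_median: float = 600.0  # log-normal median width (bp)
    width_log_sigma: float = 0.7  # => ~90% of widths <= 1,500 bp
    width_clip: tuple[int, int] = (108, 6_990)
    fold_log_median: float = 5.7
    fold_log_sigma: float = 0.8
    fold_clip: tuple[float, float] = (1.7, 111.4)
    frac_regions_tss_proximal: float = 0.5
    frac_genes_targeted: float = 0.6  # genes eligible for TSS-proximal regions
    region_min_separation: int = 1_000
    frac_regions_with_dre: float = 0.5  # planted high-scoring 19-mer at center
    # DRE landscape
    dre_background_rate: float = 4e-4  # cores per bp retained in background
    dre_tss_lambda: float = 3.0  # planted 19-mers per gene within +/- 1.5 kb of TSS
    dre_tss_halfwidth: int = 1_500
    # 24 hr decay
    frac_regions_24hr: float = 0.3
    fold_corr_24hr: float = 0.5
    # expression
    p_deg_enriched: float = 0.6  # DEG probability for genes with planted enrichment
    p_deg_background: float = 0.15
    p_up: float = 0.75
    deg_fc_log_sigma: float = 0.5  # |FC| = 1.5 * lognormal

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedRegion:
    chrom: str
    start: int
    end: int
    fold: float
    has_planted_dre: bool
    n_cores: int = 0  # cores in final sequence (planted + retained background)
    present_24hr: bool = False
    fold_24hr: Optional[float] = None


@dataclass
class GeneTruth:
    gene_symbol: str
    has_enrichment: bool
    has_dre: bool  # >= 1 core in an overlapping planted region
    deg_times: list[int]
    final_class: str  # AhR+DRE / AhR-only / expression-only / none


@dataclass
class GroundTruth:
    seed: int
    regions: list[PlantedRegion]
    genes: list[GeneTruth]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "regions": [asdict(r) for r in self.regions],
                "genes": [asdict(g) for g in self.genes],
            },
            indent=1,
        )


@dataclass
class SimulatedData:
    cfg: SimConfig
    sequences: dict[str, str]
    genes: list[GeneAnnotation]
    tracks: dict[str, ProbeTrack]  # 2 hr condition
    tracks_24hr: dict[str, ProbeTrack]
    expression: "list[dict]"  # rows: gene_symbol, time_hr, fold_change, p1_t
    truth: GroundTruth


def _count_cores(seq: str, start: int, end: int) -> int:
    sub = seq[max(0, start) : end]
    n = 0
    for pat in (CORE, CORE_RC):
        i = sub.find(pat)
        while i >= 0:
            n += 1
            i = sub.find(pat, i + 1)
    return n


def _scrub_cores(seq: np.ndarray, keep_mask: np.ndarray, rng: np.random.Generator) -> None:
    """Disrupt every GCGTG/CACGC whose start base is not protected.

    Mutates the core's middle base and rescans the local neighbourhood until
    clean, so the realized background core rate is exactly the retained set.
    """
    s = seq.tobytes().decode()
    pending: set[int] = set()
    for pat in (CORE, CORE_RC):
        i = s.find(pat)
        while i >= 0:
            if not keep_mask[i]:
                pending.add(i)
            i = s.find(pat, i + 1)
    n_core = len(CORE)
    while pending:
        i = pending.pop()
        sub = seq[i : i + n_core].tobytes().decode()
        if sub not in (CORE, CORE_RC):  # already disrupted by a neighbour fix
            continue
        old = seq[i + 2].tobytes()
        choices = [b for b in b"ACGT" if bytes([b]) != old]
        seq[i + 2] = bytes([int(rng.choice(choices))])
        lo, hi = max(0, i - n_core + 1), min(len(seq), i + 2 * n_core)
        neigh = seq[lo:hi].tobytes().decode()
        for pat in (CORE, CORE_RC):
            j = neigh.find(pat)
            while j >= 0:
                if not keep_mask[lo + j]:
                    pending.add(lo + j)
                j = neigh.find(pat, j + 1)


def _place_genes(cfg: SimConfig, chrom: str, length: int,
                 rng: np.random.Generator, id_offset: int) -> list[GeneAnnotation]:
    n = cfg.n_genes // cfg.n_chroms
    footprint = cfg.gene_max_len + 22_000  # tx + upstream margin either strand + gap
    if n * footprint > length:
        raise ValueError(
            f"infeasible packing: {n} genes x {footprint} bp footprint > {length} bp"
        )
    slack = length - n * footprint
    extra = rng.multinomial(slack, np.ones(n + 1) / (n + 1))
    genes = []
    cursor = 0
    for k in range(n):
        cursor += int(extra[k]) + 11_000
        tx_len = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1))
        tx_start = cursor
        tx_end = tx_start + tx_len
        cursor = tx_end + 11_000
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 7))
        # internal cut points leaving >= 600 bp terminal exons and >= 50 bp pieces
        inner = np.sort(rng.integers(tx_start + 600, tx_end - 600, size=2 * (n_exons - 1)))
        bounds = [tx_start, *inner.tolist(), tx_end]
        exons = []
        for e in range(n_exons):
            s, ee = bounds[2 * e], bounds[2 * e + 1]
            if ee - s < 20:
                ee = s + 20
            exons.append((int(s), int(min(ee, tx_end))))
        exons = sorted(set(exons))
        exons[0] = (tx_start, exons[0][1])
        exons[-1] = (exons[-1][0], tx_end)
        cds_start = tx_start + int(rng.integers(100, 500))
        cds_end = tx_end - int(rng.integers(100, 500))
        gid = id_offset + k
        g = GeneAnnotation(
            transcript_id=f"NM_{gid:06d}",
            gene_symbol=f"Gene{gid:04d}",
            chrom=chrom,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            cds_start=cds_start,
            cds_end=cds_end,
            exons=_fix_exons(exons, tx_start, tx_end),
        )
        g.validate()
        genes.append(g)
    return genes


def _fix_exons(exons, tx_start, tx_end):
    out = []
    prev = tx_start
    for s, e in exons:
        s = max(s, prev)
        e = max(e, s + 1)
        e = min(e, tx_end)
        if e > s:
            out.append((s, e))
            prev = e
    if not out:
        out = [(tx_start, tx_end)]
    return out


def _sample_pwm_19mer(pwm_freq: np.ndarray, rng: np.random.Generator) -> str:
    bases = "ACGT"
    s = "".join(rng.choice(list(bases), p=pwm_freq[i]) for i in range(PWM_WIDTH))
    # force the invariant core so every planted element is a real hit
    return s[:7] + CORE + s[12:]


def _place_regions(
    cfg: SimConfig,
    chrom: str,
    length: int,
    chrom_genes: list[GeneAnnotation],
    rng: np.random.Generator,
) -> list[PlantedRegion]:
    """Place planted regions: log-normal widths/folds, half TSS-proximal.

    TSS-proximal placements target a random subset of genes; the remaining
    (non-target) gene loci are avoided so unbound genes exist in the truth.
    Regions keep a minimum separation so downstream merging cannot bridge two
    planted regions.
    """
    L = length
    widths = np.clip(
        rng.lognormal(np.log(cfg.width_log_median), cfg.width_log_sigma,
                      size=cfg.n_regions // cfg.n_chroms),
        *cfg.width_clip,
    ).astype(int)
    folds = np.clip(
        rng.lognormal(np.log(cfg.fold_log_median), cfg.fold_log_sigma, size=len(widths)),
        *cfg.fold_clip,
    )
    targeted = rng.random(len(chrom_genes)) < cfg.frac_genes_targeted
    tss_list = [g.tss for g, t in zip(chrom_genes, targeted) if t]
    avoid_spans = [
        (g.tx_start - 10_000, g.tx_end) if g.strand == "+" else (g.tx_start, g.tx_end + 10_000)
        for g, t in zip(chrom_genes, targeted)
        if not t
    ]
    placed: list[tuple[int, int]] = []
    out: list[PlantedRegion] = []
    for w, fold in zip(widths, folds):
        for _attempt in range(200):
            if tss_list and rng.random() < cfg.frac_regions_tss_proximal:
                center = int(rng.choice(tss_list)) + int(
                    rng.integers(-cfg.dre_tss_halfwidth, cfg.dre_tss_halfwidth)
                )
            else:
                center = int(rng.integers(w, L - w))
            start, end = center - int(w) // 2, center - int(w) // 2 + int(w)
            if start < 0 or end > L:
                continue
            if any(start < e and end > s for s, e in avoid_spans):
                continue
            sep = cfg.region_min_separation
            if all(end + sep <= s or e + sep <= start for s, e in placed):
                placed.append((start, end))
                out.append(
                    PlantedRegion(
                        chrom, start, end, float(fold),
                        bool(rng.random() < cfg.frac_regions_with_dre),
                    )
                )
                break
    return out


def simulate_truth_regions(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[GeneAnnotation], list[PlantedRegion]]:
    """Gene placement + planted regions only, no sequence synthesis.

    The fast path for ChIP-signal recovery benchmarks where the DRE landscape
    is irrelevant; width/fold distributions and placement rules are identical
    to simulate_genome's.
    """
    rng = rng if rng is not None else cfg.rng()
    genes: list[GeneAnnotation] = []
    regions: list[PlantedRegion] = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_genes = _place_genes(cfg, chrom, cfg.chrom_length, rng, id_offset=ci * 1000)
        genes.extend(chrom_genes)
        regions.extend(_place_regions(cfg, chrom, cfg.chrom_length, chrom_genes, rng))
    return genes, regions


def simulate_genome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[GeneAnnotation], list[PlantedRegion], dict[str, list[int]]]:
    """Background sequence + gene models + planted regions and DRE landscape.

    Returns (sequences, genes, planted_regions, planted_dre_positions);
    planted DRE 19-mers are written into the sequence, background cores are
    thinned to the configured per-bp rate, and each planted region's final
    in-sequence core count is recorded on the PlantedRegion.
    """
    rng = rng if rng is not None else cfg.rng()
    pwm = build_pwm(EXAMPLE_TRAINING_SEQS)
    sequences: dict[str, str] = {}
    genes: list[GeneAnnotation] = []
    regions: list[PlantedRegion] = []
    planted_dre: dict[str, list[int]] = {}

    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        L = cfg.chrom_length
        seq = rng.choice(_BASES, size=L)
        chrom_genes = _place_genes(cfg, chrom, L, rng, id_offset=ci * 1000)
        genes.extend(chrom_genes)

        # thin natural background cores to the configured rate, then plant
        keep = np.zeros(L, dtype=bool)
        natural_rate = 2.0 / 4 ** len(CORE)  # both strands, per bp (~1/512)
        p_keep = min(1.0, cfg.dre_background_rate / natural_rate)
        keep[rng.random(L) < p_keep] = True  # positional lottery, seed-stable
        _scrub_cores(seq, keep, rng)

        planted_dre[chrom] = []

        def plant(pos: int) -> None:
            if 0 <= pos and pos + PWM_WIDTH <= L:
                mer = _sample_pwm_19mer(pwm.freq, rng)
                seq[pos : pos + PWM_WIDTH] = np.frombuffer(mer.encode(), dtype="S1")
                planted_dre[chrom].append(pos)

        # elevated TSS-proximal DRE rate
        for g in chrom_genes:
            for _ in range(rng.poisson(cfg.dre_tss_lambda)):
                plant(int(g.tss + rng.integers(-cfg.dre_tss_halfwidth, cfg.dre_tss_halfwidth)))

        chrom_regions = _place_regions(cfg, chrom, L, chrom_genes, rng)
        for r in chrom_regions:
            if r.has_planted_dre:
                plant((r.start + r.end) // 2 - PWM_WIDTH // 2)
        regions.extend(chrom_regions)

        sequences[chrom] = seq.tobytes().decode()

    # final core census per planted region + 24 hr thinning with correlated folds
    for r in regions:
        r.n_cores = _count_cores(sequences[r.chrom], r.start, r.end)
        r.present_24hr = bool(rng.random() < cfg.frac_regions_24hr)
        if r.present_24hr:
            rho = cfg.fold_corr_24hr
            z = rho * np.log2(r.fold) + np.sqrt(1 - rho**2) * rng.normal(
                np.log2(cfg.fold_log_median), cfg.fold_log_sigma / np.log(2)
            )
            r.fold_24hr = float(np.clip(2.0**z, *cfg.fold_clip))
    return sequences, genes, regions, planted_dre


def simulate_probe_layout(
    cfg: SimConfig, chrom: str, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Unevenly tiled probe coordinates with stochastic coverage gaps."""
    starts = []
    pos = int(rng.integers(0, 30))
    lo, hi = cfg.probe_extra_spacing
    while pos + cfg.probe_length <= length:
        starts.append(pos)
        pos += cfg.probe_length + int(rng.integers(lo, hi))
        if rng.random() < cfg.gap_prob:
            pos += int(rng.integers(*cfg.gap_length))
    starts = np.array(starts, dtype=np.int64)
    return starts, starts + cfg.probe_length


def simulate_chip_track(
    cfg: SimConfig,
    chrom: str,
    length: int,
    planted: list[PlantedRegion],
    rng: np.random.Generator,
    timepoint_24hr: bool = False,
) -> ProbeTrack:
    """Treatment/IgG replicate log2 intensities over a tiled probe layout.

    Probes whose midpoint falls in a planted region carry log2(fold) signal in
    the treatment replicates; both conditions share a per-probe affinity term;
    replicate noise is i.i.d. Gaussian.
    """
    starts, ends = simulate_probe_layout(cfg, chrom, length, rng)
    mids = (starts + ends) // 2
    base = np.zeros(len(starts))
    for r in planted:
        if r.chrom != chrom:
            continue
        fold = r.fold_24hr if timepoint_24hr else r.fold
        if fold is None:
            continue
        in_reg = (mids >= r.start) & (mids < r.end)
        base[in_reg] = np.log2(fold)
    affinity = rng.normal(0.0, cfg.probe_affinity_sd, size=len(starts))
    shape = (len(starts), cfg.n_replicates)
    treatment = (base + affinity)[:, None] + rng.normal(0.0, cfg.noise_sd, size=shape)
    control = affinity[:, None] + rng.normal(0.0, cfg.noise_sd, size=shape)
    return ProbeTrack(chrom, starts, ends, treatment, control)


def simulate_expression(
    cfg: SimConfig,
    genes: list[GeneAnnotation],
    regions: list[PlantedRegion],
    rng: np.random.Generator,
) -> tuple[list[dict], list[GeneTruth]]:
    """Eight-time-point expression table plus per-gene truth classes.

    Genes overlapped by a planted region (10 kb upstream through transcript
    end) are DEG with elevated probability; DEG genes receive |FC| >= 1.5 and
    P1(t) > 0.999 at their active time points, others sub-threshold values.
    """
    from .genome_model import segment_gene

    rows: list[dict] = []
    truths: list[GeneTruth] = []
    for g in genes:
        gr = segment_gene(g, chrom_length=cfg.chrom_length)
        span_s, span_e = gr.full_span
        overlapping = [
            r for r in regions if r.chrom == g.chrom and r.start < span_e and r.end > span_s
        ]
        enriched = bool(overlapping)
        has_dre = any(r.n_cores > 0 for r in overlapping)
        p_deg = cfg.p_deg_enriched if enriched else cfg.p_deg_background
        deg = rng.random() < p_deg
        deg_times: list[int] = []
        if deg:
            k = int(rng.integers(1, 5))
            deg_times = sorted(rng.choice(TIME_POINTS, size=k, replace=False).tolist())
        direction = 1.0 if rng.random() < cfg.p_up else -1.0
        for t in TIME_POINTS:
            if t in deg_times:
                # |FC| >= 1.5 guaranteed: half-normal multiplier on the log scale
                fc = direction * 1.5 * float(np.exp(abs(rng.normal(0.0, cfg.deg_fc_log_sigma))))
                p1 = float(rng.uniform(0.9992, 1.0))
            else:
                fc = direction * float(np.clip(1.0 + abs(rng.normal(0, 0.12)), 1.0, 1.45))
                p1 = float(rng.uniform(0.0, 0.99))
            rows.append(
                {"gene_symbol": g.gene_symbol, "time_hr": t, "fold_change": fc, "p1_t": p1}
            )
        if enriched and has_dre and deg_times:
            final = "AhR+DRE"
        elif enriched:
            final = "AhR-only"
        elif deg_times:
            final = "expression-only"
        else:
            final = "none"
        truths.append(GeneTruth(g.gene_symbol, enriched, has_dre, deg_times, final))
    return rows, truths


def simulate_all(cfg: SimConfig) -> SimulatedData:
    """Run all three generators under one seed."""
    rng = cfg.rng()
    sequences, genes, regions, _planted_dre = simulate_genome(cfg, rng)
    tracks = {
        c: simulate_chip_track(cfg, c, len(s), regions, rng) for c, s in sequences.items()
    }
    tracks_24 = {
        c: simulate_chip_track(cfg, c, len(s), regions, rng, timepoint_24hr=True)
        for c, s in sequences.items()
    }
    expr_rows, gene_truths = simulate_expression(cfg, genes, regions, rng)
    return SimulatedData(
        cfg=cfg,
        sequences=sequences,
        genes=genes,
        tracks=tracks,
        tracks_24hr=tracks_24,
        expression=expr_rows,
        truth=GroundTruth(seed=cfg.seed, regions=regions, genes=gene_truths),
    )


def write_outputs(data: SimulatedData, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA, refGene-style TSV, probe TSVs, expression TSV and truth JSON."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in data.sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = fasta

    sizes = outdir / "chrom.sizes"
    with open(sizes, "w") as fh:
        for chrom, seq in data.sequences.items():
            fh.write(f"{chrom}\t{len(seq)}\n")
    paths["chrom_sizes"] = sizes

    ann = outdir / "refgene.tsv"
    with open(ann, "w") as fh:
        for g in data.genes:
            exon_starts = ",".join(str(s) for s, _ in g.exons) + ","
            exon_ends = ",".join(str(e) for _, e in g.exons) + ","
            fh.write(
                "\t".join(
                    [
                        g.transcript_id, g.chrom, g.strand,
                        str(g.tx_start), str(g.tx_end),
                        str(g.cds_start), str(g.cds_end),
                        str(len(g.exons)), exon_starts, exon_ends,
                        "0", g.gene_symbol,
                    ]
                )
                + "\n"
            )
    paths["annotation"] = ann

    for label, tracks in (("2hr", data.tracks), ("24hr", data.tracks_24hr)):
        rows = []
        for chrom, tr in tracks.items():
            for i in range(tr.n_probes):
                row = {"chrom": chrom, "start": int(tr.starts[i]), "end": int(tr.ends[i])}
                for j in range(tr.treatment.shape[1]):
                    row[f"t_{j + 1}"] = tr.treatment[i, j]
                    row[f"c_{j + 1}"] = tr.control[i, j]
                rows.append(row)
        path = outdir / f"probes_{label}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.5f")
        paths[f"probes_{label}"] = path

    expr = outdir / "expression.tsv"
    pd.DataFrame(data.expression).to_csv(expr, sep="\t", index=False, float_format="%.5f")
    paths["expression"] = expr

    truth = outdir / "ground_truth.json"
    truth.write_text(data.truth.to_json())
    paths["ground_truth"] = truth
    return paths
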