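"""Enriched-region calling from tiling-probe ChIP signal.

Treatment (ChIP) and control (IgG) log2 intensities over replicate arrays are
compared per probe with a variance-floored t-like statistic, smoothed with a
moving average over a 5-probe window, and thresholded at a cutoff chosen by
empirical FDR against a replicate-label-permutation null. Runs of passing
probes become candidate regions, which are then merged and filtered with
fixed rules: merge when the inter-region gap is < 300 bp and fewer than 5
probes in between fail the cutoff; discard regions < 120 bp wide or lacking
>= 5 continuous above-cutoff probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MA_WINDOW_PROBES = 5
MAX_GAP_BP = 300
MAX_FAIL_PROBES = 5
MIN_WIDTH_BP = 120
MIN_CONTINUOUS_PROBES = 5
DEFAULT_FDR = 0.01


@dataclass
class ProbeTrack:
    """Tiling probes on one chromosome with replicate treatment/control signal."""

    chrom: str
    starts: np.ndarray  # (n,) sorted probe starts
    ends: np.ndarray  # (n,)
    treatment: np.ndarray  # (n, n_rep) log2 intensities
    control: np.ndarray  # (n, n_rep)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        self.treatment = np.atleast_2d(np.asarray(self.treatment, dtype=float))
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        if np.any(np.diff(self.starts) < 0):
            raise ValueError("probes must be sorted by start")
        if self.treatment.shape != self.control.shape:
            raise ValueError("treatment/control replicate shapes differ")
        if self.treatment.shape[0] != len(self.starts):
            raise ValueError("signal rows != probe count")

    @property
    def n_probes(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def log2_ratio(self) -> np.ndarray:
        """Per-probe log2 fold enrichment: mean(treatment) - mean(control)."""
        return self.treatment.mean(axis=1) - self.control.mean(axis=1)


@dataclass
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    n_probes: int
    fold_enrichment: float  # linear scale
    max_position: int
    ma_stat: float  # region max of the MA statistic
    fdr_pass: bool = True
    probe_slice: tuple[int, int] = field(default=(0, 0), repr=False)

    @property
    def width(self) -> int:
        return self.end - self.start


def probe_stat(track: ProbeTrack) -> np.ndarray:
    """Two-sample t-like statistic per probe on log2 replicate values.

    The per-probe variance is floored at the across-probe median of the pooled
    per-probe variance, stabilising the denominator at replicate counts as low
    as 3 (the shrinkage spirit of tiling-array moving-average testers).
    """
    n = track.treatment.shape[1]
    diff = track.treatment.mean(axis=1) - track.control.mean(axis=1)
    if n < 2:
        return diff
    var = (track.treatment.var(axis=1, ddof=1) + track.control.var(axis=1, ddof=1)) / n
    floor = float(np.median(var))
    if floor <= 0:
        floor = 1e-12
    return diff / np.sqrt(np.maximum(var, floor))


def moving_average(
    track: ProbeTrack,
    window_probes: int = MA_WINDOW_PROBES,
    stat: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Centered moving average of the per-probe statistic in probe-index space.

    The window truncates at track edges (mean over the probes actually
    present). With fewer probes than the window, the raw statistic is
    returned with a warning.
    """
    if stat is None:
        stat = probe_stat(track)
    n = len(stat)
    if n < window_probes:
        logger.warning(
            "moving_average: %d probes < window %d; returning raw statistic",
            n,
            window_probes,
        )
        return np.asarray(stat, dtype=float).copy()
    half = window_probes // 2
    csum = np.concatenate([[0.0], np.cumsum(stat)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def permutation_null_stats(
    track: ProbeTrack,
    rng: np.random.Generator,
    n_perm: int = 3,
    window_probes: int = MA_WINDOW_PROBES,
) -> np.ndarray:
    """Null MA statistics from treatment/control replicate-label permutation.

    Each permutation swaps a random non-trivial subset of replicate columns
    between treatment and control and recomputes the MA statistic; results
    are pooled across permutations.
    """
    n_rep = track.treatment.shape[1]
    out = []
    for _ in range(n_perm):
        while True:
            swap = rng.random(n_rep) < 0.5
            if 0 < swap.sum():  # identity permutation carries real signal
                break
        t = track.treatment.copy()
        c = track.control.copy()
        t[:, swap], c[:, swap] = track.control[:, swap], track.treatment[:, swap]
        null_track = ProbeTrack(track.chrom, track.starts, track.ends, t, c)
        out.append(moving_average(null_track, window_probes))
    return np.concatenate(out)


def empirical_fdr_threshold(
    treatment_stats: np.ndarray,
    null_stats: np.ndarray,
    fdr: float = DEFAULT_FDR,
) -> float:
    """Smallest cutoff c with (frac null >= c) / (frac treatment >= c) <= fdr.

    Monotone in fdr. Returns +inf (zero calls) with a warning when no cutoff
    achieves the target.
    """
    treat = np.sort(np.asarray(treatment_stats, dtype=float))
    null = np.sort(np.asarray(null_stats, dtype=float))
    n_t, n_0 = len(treat), len(null)
    if n_t == 0 or n_0 == 0:
        raise ValueError("empty statistic arrays")
    # candidate cutoffs: observed treatment values (densest where it matters)
    cand = np.unique(treat)
    frac_null = 1.0 - np.searchsorted(null, cand, side="left") / n_0
    frac_treat = 1.0 - np.searchsorted(treat, cand, side="left") / n_t
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = frac_null / frac_treat
    ok = np.where(ratio <= fdr)[0]
    if len(ok) == 0:
        logger.warning("empirical_fdr_threshold: no achievable cutoff at FDR %g", fdr)
        return float("inf")
    return float(cand[ok[0]])


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index slices."""
    runs = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _longest_true_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def call_and_merge(
    track: ProbeTrack,
    cutoff: float,
    ma_stats: Optional[np.ndarray] = None,
    max_gap_bp: int = MAX_GAP_BP,
    max_fail_probes: int = MAX_FAIL_PROBES,
    min_width_bp: int = MIN_WIDTH_BP,
    min_continuous_probes: int = MIN_CONTINUOUS_PROBES,
) -> list[EnrichedRegion]:
    """Call enriched regions from MA statistics with fixed merge/discard rules.

    Candidates are maximal runs of probes with MA statistic >= cutoff, spanning
    first probe start to last probe end. Adjacent candidates merge when the bp
    gap between them (left region end to right region first-probe start) is
    < max_gap_bp AND the intervening failing probes number < max_fail_probes.
    Post merge, a region is discarded when narrower than min_width_bp or when
    it lacks a run of >= min_continuous_probes consecutive passing probes.
    """
    if ma_stats is None:
        ma_stats = moving_average(track)
    ma_stats = np.asarray(ma_stats, dtype=float)
    passing = ma_stats >= cutoff
    candidates = _runs_above(passing)  # probe-index slices

    merged: list[tuple[int, int]] = []
    for lo, hi in candidates:
        if merged:
            plo, phi = merged[-1]
            gap = track.starts[lo] - track.ends[phi - 1]
            n_fail = lo - phi  # all probes between two maximal runs fail
            if gap < max_gap_bp and n_fail < max_fail_probes:
                merged[-1] = (plo, hi)
                continue
        merged.append((lo, hi))

    regions: list[EnrichedRegion] = []
    log2r = track.log2_ratio
    mids = track.midpoints
    for lo, hi in merged:
        start = int(track.starts[lo])
        end = int(track.ends[hi - 1])
        if end - start < min_width_bp:
            continue
        if _longest_true_run(passing[lo:hi]) < min_continuous_probes:
            continue
        seg = ma_stats[lo:hi]
        imax = lo + int(np.argmax(seg))  # argmax returns first (leftmost) max
        regions.append(
            EnrichedRegion(
                chrom=track.chrom,
                start=start,
                end=end,
                n_probes=hi - lo,
                fold_enrichment=float(2.0 ** log2r[lo:hi].mean()),
                max_position=int(mids[imax]),
                ma_stat=float(seg.max()),
                probe_slice=(lo, hi),
            )
        )
    return regions


def max_enrichment_position(region: EnrichedRegion, track: ProbeTrack,
                            ma_stats: Optional[np.ndarray] = None) -> int:
    """Midpoint of the region's maximal-MA probe; ties broken leftmost."""
    if ma_stats is None:
        ma_stats = moving_average(track)
    lo, hi = region.probe_slice
    if hi <= lo:
        in_reg = np.where((track.starts < region.end) & (track.ends > region.start))[0]
        if len(in_reg) == 0:
            raise ValueError("region has no probes")
        lo, hi = int(in_reg[0]), int(in_reg[-1]) + 1
    imax = lo + int(np.argmax(ma_stats[lo:hi]))
    return int(track.midpoints[imax])


def call_regions(
    track: ProbeTrack,
    fdr: float = DEFAULT_FDR,
    rng: Optional[np.random.Generator] = None,
    n_perm: int = 3,
    window_probes: int = MA_WINDOW_PROBES,
    **rule_kwargs,
) -> tuple[list[EnrichedRegion], float]:
    """End-to-end calling on one track: MA stats, FDR cutoff, merge rules.

    Returns the called regions and the cutoff used.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    ma = moving_average(track, window_probes)
    null = permutation_null_stats(track, rng, n_perm=n_perm, window_probes=window_probes)
    cutoff = empirical_fdr_threshold(ma, null, fdr=fdr)
    if not np.isfinite(cutoff):
        return [], cutoff
    return call_and_merge(track, cutoff, ma_stats=ma, **rule_kwargs), cutoff


def read_probe_track(path: str | Path, chrom: Optional[str] = None) -> list[ProbeTrack]:
    """Read a probe TSV: chrom, start, end, t_1..t_k, c_1..c_k columns."""
    df = pd.read_csv(path, sep="\t")
    t_cols = [c for c in df.columns if c.startswith("t_")]
    c_cols = [c for c in df.columns if c.startswith("c_")]
    if not t_cols or len(t_cols) != len(c_cols):
        raise ValueError(f"{path}: need matched t_* and c_* replicate columns")
    tracks = []
    for chrom_name, sub in df.groupby("chrom", sort=True):
        if chrom is not None and chrom_name != chrom:
            continue
        sub = sub.sort_values("start")
        tracks.append(
            ProbeTrack(
                chrom=str(chrom_name),
                starts=sub["start"].to_numpy(),
                ends=sub["end"].to_numpy(),
                treatment=sub[t_cols].to_numpy(),
                control=sub[c_cols].to_numpy(),
            )
        )
    return tracks


def write_regions_bed(regions: Sequence[EnrichedRegion], path: str | Path) -> None:
    """Export regions as BED + extra columns (fold enrichment, max position)."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tfold_enrichment\tstrand\tmax_position\n")
        for i, r in enumerate(regions):
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i}\t"
                f"{r.fold_enrichment:.4f}\t.\t{r.max_position}\n"
            )


def read_regions_bed(path: str | Path) -> list[EnrichedRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            regions.append(
                EnrichedRegion(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    n_probes=0,
                    fold_enrichment=float(f[4]),
                    max_position=int(f[6]) if len(f) > 6 else (int(f[1]) + int(f[2])) // 2,
                    ma_stat=float("nan"),
                )
            )
    return regions
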