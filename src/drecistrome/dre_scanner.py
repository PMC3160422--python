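"""Dioxin response element (DRE) scanning and matrix-similarity scoring.

The DRE is the substitution-intolerant 5'-GCGTG-3' core embedded in a 19 bp
functional context. A position-weight matrix built from functional DRE
sequences scores every 19-mer around a core with a MatInspector-style
information-weighted matrix-similarity (MS) score normalised to [0, 1];
scores >= 0.8473 mark putative functional elements. An alternate,
degenerate AhR-associated element 5'-CATGN6C[T|A]TG-3' is scanned literally.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

PWM_WIDTH = 19
CORE = "GCGTG"
CORE_RC = "CACGC"
CORE_OFFSET = 7  # 0-based start of GCGTG inside the 19-mer (1-based positions 8-12)
MS_THRESHOLD = 0.8473

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# Synthetic example training set (not experimentally derived): 19-mers with the
# invariant GCGTG core at positions 8-12 and a biased flanking context, shipped
# so build_pwm has a worked default. Substitute a real functional-DRE set for
# production scans.
EXAMPLE_TRAINING_SEQS = [
    "TTGCTCG" + "GCGTG" + "CGCAACC",
    "CTCCTCG" + "GCGTG" + "CGCCAGT",
    "AGGCTAG" + "GCGTG" + "CGACATG",
    "TCTCGGC" + "GCGTG" + "CGAGCTC",
    "GATCGCG" + "GCGTG" + "CCATCGA",
    "CCGCTCG" + "GCGTG" + "CGCAATT",
    "TGACTGG" + "GCGTG" + "CGGTGAC",
    "CGCCTGC" + "GCGTG" + "CGCGCTA",
    "ATTCACG" + "GCGTG" + "CGTCCGG",
    "GCGCGTG" + "GCGTG" + "CGATAAC",
    "CTACTCG" + "GCGTG" + "ACGCAGT",
    "TACCGGG" + "GCGTG" + "CGTGATC",
]


@dataclass
class PWM:
    """19-column base-frequency matrix with per-position information weights."""

    freq: np.ndarray  # (19, 4) frequencies over A,C,G,T
    info_weight: np.ndarray  # (19,) information values, >= 0
    ms_min: float
    ms_max: float

    @property
    def width(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.freq.argmax(axis=1))


@dataclass
class DreHit:
    """One GCGTG core occurrence (either strand, + strand coordinates)."""

    chrom: str
    core_start: int  # + strand coordinate of the first base of GCGTG / CACGC
    strand: str
    ms_score: Optional[float] = None
    is_putative_functional: bool = False

    @property
    def core_center(self) -> int:
        """Central base of the 5-mer core; strand-symmetric reference point."""
        return self.core_start + 2


@dataclass
class AltHit:
    """One alternate response element (CATGN6C[T|A]TG) occurrence."""

    chrom: str
    start: int
    strand: str
    matched: str


def build_pwm(training_seqs: Sequence[str], pseudocount: float = 0.25) -> PWM:
    """Build the DRE PWM from 19 bp functional sequences.

    Every sequence must carry GCGTG at positions 8-12 (1-based). Frequencies
    are pseudocount-smoothed counts; the information weight of position i is
    ``(100/ln 4) * (sum_b f_i(b) ln f_i(b) + ln 4)`` (0 for a uniform column,
    maximal for an invariant one). Raw-score bounds for MS normalisation are
    the per-position extrema of ``info_weight * freq``.
    """
    if not training_seqs:
        raise ValueError("empty training set")
    counts = np.zeros((PWM_WIDTH, 4))
    for seq in training_seqs:
        seq = seq.upper()
        if len(seq) != PWM_WIDTH:
            raise ValueError(f"training sequence length {len(seq)} != {PWM_WIDTH}: {seq}")
        if seq[CORE_OFFSET : CORE_OFFSET + len(CORE)] != CORE:
            raise ValueError(f"GCGTG core absent at positions 8-12: {seq}")
        for i, b in enumerate(seq):
            if b not in _BASE_IDX:
                raise ValueError(f"ambiguous base {b!r} in training sequence {seq}")
            counts[i, _BASE_IDX[b]] += 1
    freq = (counts + pseudocount) / (counts.sum(axis=1, keepdims=True) + 4 * pseudocount)
    info = (100.0 / math.log(4)) * ((freq * np.log(freq)).sum(axis=1) + math.log(4))
    info = np.maximum(info, 0.0)  # guard tiny negative rounding
    contrib = info[:, None] * freq
    ms_min = float(contrib.min(axis=1).sum())
    ms_max = float(contrib.max(axis=1).sum())
    if not ms_min < ms_max:
        raise ValueError("degenerate PWM: ms_min == ms_max")
    return PWM(freq=freq, info_weight=info, ms_min=ms_min, ms_max=ms_max)


def ms_score(p: PWM, s: str) -> Optional[float]:
    """Matrix-similarity score of a 19-mer in [0, 1].

    ``raw = sum_i info_weight_i * freq_i(s_i)``, min-max normalised so the
    consensus scores exactly 1 and the per-position anti-consensus exactly 0.
    Returns None (undefined) when the sequence contains an ambiguous base.
    """
    s = s.upper()
    if len(s) != p.width:
        raise ValueError(f"sequence length {len(s)} != PWM width {p.width}")
    raw = 0.0
    for i, b in enumerate(s):
        j = _BASE_IDX.get(b)
        if j is None:
            return None
        raw += p.info_weight[i] * p.freq[i, j]
    return (raw - p.ms_min) / (p.ms_max - p.ms_min)


def _find_all(seq: str, pattern: str) -> Iterable[int]:
    start = 0
    while True:
        i = seq.find(pattern, start)
        if i < 0:
            return
        yield i
        start = i + 1  # overlapping occurrences all reported


def scan_cores(seq: str, pwm: Optional[PWM] = None, chrom: str = "chr") -> list[DreHit]:
    """Locate every GCGTG core on both strands of ``seq``.

    A - strand core appears as CACGC on the + strand; ``core_start`` is always
    the + strand coordinate of the 5-mer's first base. When a PWM is supplied
    the surrounding 19-mer (7 bp flanks; reverse-complemented for - hits) is
    MS-scored; hits whose flanks run off the sequence keep an undefined score.
    """
    seq = seq.upper()
    hits: list[DreHit] = []
    for strand, pattern in (("+", CORE), ("-", CORE_RC)):
        for pos in _find_all(seq, pattern):
            score: Optional[float] = None
            if pwm is not None:
                lo, hi = pos - CORE_OFFSET, pos - CORE_OFFSET + PWM_WIDTH
                if lo >= 0 and hi <= len(seq):
                    window = seq[lo:hi]
                    if strand == "-":
                        window = revcomp(window)
                    score = ms_score(pwm, window)
            hits.append(
                DreHit(
                    chrom=chrom,
                    core_start=pos,
                    strand=strand,
                    ms_score=score,
                    is_putative_functional=(score is not None and score >= MS_THRESHOLD),
                )
            )
    hits.sort(key=lambda h: (h.core_start, h.strand))
    return hits


_ALT_FWD = re.compile(r"(?=(CATG[ACGT]{6}C[TA]TG))")
_ALT_REV = re.compile(r"(?=(CA[TA]G[ACGT]{6}CATG))")  # revcomp of the pattern


def scan_alternate(seq: str, chrom: str = "chr") -> list[AltHit]:
    """Locate the alternate element CATGN6C[T|A]TG on both strands.

    Pattern N matches any unambiguous base; overlapping matches are all kept.
    - strand matches are reported at their + strand start with the on-strand
    (reverse-complemented) 14-mer.
    """
    seq = seq.upper()
    hits = [
        AltHit(chrom=chrom, start=m.start(), strand="+", matched=m.group(1))
        for m in _ALT_FWD.finditer(seq)
    ]
    hits += [
        AltHit(chrom=chrom, start=m.start(), strand="-", matched=revcomp(m.group(1)))
        for m in _ALT_REV.finditer(seq)
    ]
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def classify_dre_content(
    region: tuple[int, int],
    hits: Sequence[DreHit],
    threshold: float = MS_THRESHOLD,
) -> tuple[str, int]:
    """Classify a region by its DRE content and count in-region cores.

    ``high_dre`` if any in-region core scores >= threshold, else ``low_dre``
    if the region holds >= 1 core, else ``no_core``. A core is in-region when
    its core_start lies inside the half-open interval.
    """
    start, end = region
    in_region = [h for h in hits if start <= h.core_start < end]
    count = len(in_region)
    if any(h.ms_score is not None and h.ms_score >= threshold for h in in_region):
        return "high_dre", count
    if count:
        return "low_dre", count
    return "no_core", count


def write_hits_bed(hits: Sequence[DreHit], path: str | Path) -> None:
    """Export core hits as 6-column BED (name = class, score = round(1000*MS))."""
    with open(path, "w") as fh:
        for h in hits:
            name = (
                "high_dre"
                if h.is_putative_functional
                else ("low_dre" if h.ms_score is not None else "core")
            )
            score = 0 if h.ms_score is None else round(1000 * h.ms_score)
            fh.write(
                f"{h.chrom}\t{h.core_start}\t{h.core_start + len(CORE)}\t"
                f"{name}\t{score}\t{h.strand}\n"
            )
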