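# Methods

`drecistrome` re-implements, as a tested pipeline, the genome-wide integration
of three data layers for the aryl hydrocarbon receptor (AhR): ChIP-chip
enrichment over tiling arrays, computational scanning for dioxin response
elements (DREs), and time-course differential gene expression. This note
documents the models, the parameters that matter, the synthetic data the
package tests itself against, and the design choices made where the design
was genuinely open.

## Genome partition

A *gene region* is the sequence from 10 kb upstream of a transcript's TSS
through the end of the transcript, built from refGene-style annotation
restricted to mature (NM_-prefixed) RefSeq transcripts. Per-gene segments —
the 10 kb upstream window, 5' UTR, CDS and 3' UTR — are exonic unions
oriented by strand. Merging all gene-region spans, both strands pooled,
yields the *intragenic* DNA of each chromosome; the complement is
*intergenic*. Enrichment density for a region class is the count of enriched
regions overlapping that class per megabase of the class's merged length.

Numerical conventions:

- Coordinates are 0-based half-open throughout; refGene input is already in
  this convention, BED output inherits it.
- Isoform merging keys on genomic overlap only, not gene symbol, so
  tissue-specific isoforms collapse to their longest spanning range and
  opposite-strand overlapping genes form one block.
- Half-open **adjacency counts as contiguous** (gap = 0 bp merges). This
  guarantees the intergenic complement never contains zero-length intervals,
  and makes the conservation identity `|intragenic| + |intergenic| = L`
  exact for every chromosome — a property the test suite checks on 1,000
  random gene configurations.
- Segment-class totals merge intervals *within* a class but classes are
  independent: one gene's upstream window lying inside another gene's CDS
  counts toward both classes, because per-class densities are reported
  independently.
- A 10 kb upstream window running off a chromosome end is clipped with a
  warning rather than the gene being dropped. The alternative (discarding
  edge genes) silently biases densities on short contigs.

## DRE scanning and matrix-similarity scoring

The DRE core 5'-GCGTG-3' is treated as substitution-intolerant: a core scan
reports every occurrence of GCGTG (+ strand) and CACGC (− strand on the +
representation), overlapping and nested occurrences included. A hit's
coordinate is the + strand position of the 5-mer's first base; distance
computations use the core's central base (`core_start + 2`), which is
strand-symmetric.

The 19 bp functional context is scored with an information-weighted
matrix-similarity (MS) score. From a training set of 19-mers (core fixed at
positions 8–12), per-position base frequencies `f_i(b)` are estimated with a
pseudocount (default 0.25), and each position is weighted by its information
value

    I_i = (100 / ln 4) * ( Σ_b f_i(b) ln f_i(b) + ln 4 )

which is 0 for a uniform column and maximal for an invariant one. A
sequence's raw score is `Σ_i I_i · f_i(s_i)`, min–max normalised with the
per-position extrema of `I_i · f_i` so the consensus scores exactly 1 and the
per-position anti-consensus exactly 0. Scores ≥ **0.8473** (the default
threshold) mark putative functional DREs; regions are classed `high_dre`
(≥ 1 in-region core at or above threshold), `low_dre` (≥ 1 core, none above)
or `no_core`. Ambiguous bases make a score undefined, and a core whose 7 bp
flanks run off the sequence carries an undefined score rather than a padded
one.

The package does not ship an experimentally derived training matrix — the
functional-DRE collections used for genome-wide scans are not redistributable
here. It ships `build_pwm` plus a clearly labelled synthetic example training
set (`EXAMPLE_TRAINING_SEQS`) so the scoring pipeline is runnable end to end,
and accepts any user-supplied matrix. Scores from the example matrix
demonstrate the machinery; they are not biological predictions.

The alternate response element 5'-CATGN₆C[T|A]TG-3' is scanned literally on
both strands; pattern N matches any unambiguous base only.

## Enrichment calling from tiling probes

Treatment (ChIP) and control (IgG) replicate log2 intensities are compared
per probe with a two-sample t-like statistic whose per-probe variance is
floored at the across-probe median pooled variance — a deliberate,
documented simplification standing in for a full tiling-array hierarchical
tester, stable at triplicate depth. The statistic is smoothed with a
centered moving average over a 5-probe window (index space, truncated at
track edges).

The significance cutoff is chosen empirically: null moving-average statistics
come from permuting treatment/control replicate labels (non-trivial swaps
only, since the identity permutation carries real signal; 3 permutations
pooled by default), and the cutoff is the smallest value `c` with
`frac(null ≥ c) / frac(treatment ≥ c) ≤ FDR`, FDR = 0.01 by default. If no
cutoff achieves the target the caller returns +∞ (zero regions) with a
warning.

Candidate regions are maximal runs of passing probes, spanning first probe
start to last probe end. The merge/discard rules are applied exactly as
stated for the original analysis:

- merge two adjacent candidates when the bp gap between them is **< 300 bp**
  AND the intervening failing probes number **< 5** ("gap" = left region's
  last probe end to right region's first probe start);
- post-merge, discard a region narrower than **120 bp** or lacking a run of
  **≥ 5 continuous** above-cutoff probes (evaluated on the post-merge
  region).

Single-pass left-to-right merging is order-independent here because merging
two candidates never changes the gap or failing-probe count to the next one;
the test suite verifies equality with a fixpoint rule-application oracle on
1,000 randomized tracks. A region's summary fold enrichment is
`2^(mean per-probe log2 ratio)` over its probes; its maximum-enrichment
position is the midpoint of its maximal-MA probe, leftmost on ties (whether
the original analysis used the raw or smoothed statistic for the maximum is
not recoverable; the smoothed statistic was chosen as the quantity the
calling itself thresholds).

## Integration

- **Region ↔ class assignment** uses any-overlap (≥ 1 bp): a region touching
  any intragenic base is intragenic, else intergenic, so the two counts sum
  exactly to the total. Segment-class counts apply the same rule per class.
  A region overlapping multiple genes counts once per gene in gene-centric
  tables but once in region-centric tables.
- **TSS profiles** histogram each region's maximum-enrichment position (200 bp
  bins) and each DRE core's central base (100 bp bins) over a −10 kb … +5 kb
  strand-flipped window around every TSS; an item falling in several genes'
  windows counts in each (the per-window reading of the profile).
- **Peak-to-DRE distance** is the minimum |max-position − core center| over
  in-region cores, undefined for coreless regions.
- **Time-point overlap** pairs each later region with the overlapping earlier
  region of greatest fold enrichment; Pearson r on paired log2 folds with the
  exact two-sided t-transform p-value (undefined below 3 pairs).
- **Gene rollup**: a gene is enriched iff ≥ 1 region overlaps its full gene
  region; its DRE class is the best over those regions (high > low >
  no_core), so multiple enrichment events per gene may mix classes.
- **Expression integration**: a gene is differentially expressed at a time
  point when |fold change| ≥ 1.5 and P1(t) > 0.999 (P1(t) is taken as an
  input column; its provenance is outside this package's scope). Final
  classes: `AhR+DRE` (enriched, core-bearing, DEG at ≥ 1 time point),
  `AhR-only`, `expression-only`, `none`. Duplicate expression rows per
  (gene, time) keep the max-|FC| record, logged.
- **Over-representation** of a motif in regions vs the genome is a Poisson
  z-score: `z = (obs − exp)/√exp` with `exp` = background per-bp rate ×
  total region bp, significant at z > 3. This is a deliberate generic
  simplification of commercial module-family over-representation scoring;
  only the z > 3 significance convention is retained.

## Synthetic data: what it emulates and what it does not

The generator produces complete inputs with known truth under one seed:

| parameter | default | rationale |
|---|---|---|
| chromosomes × length | 2 × 750 kb | desk-scale mini-genome; ~40% intragenic with 30 genes |
| planted regions | 200 | enough for stable recall/FDR estimates per run |
| width distribution | log-normal, median 600 bp, σ = 0.7, clipped to [108, 6990] bp | ≈ 90% of widths ≤ 1,500 bp, min/max matching the observed range |
| fold distribution | log-normal, median 5.7, σ = 0.8, clipped to [1.7, 111.4] | central value and support of the observed fold range |
| probe tiling | 25-mers, ~35 bp start-to-start, occasional 0.5–3 kb gaps | uneven tiling with coverage holes, which can split one true region into two calls |
| replicate noise | σ = 0.35 (log2), 3 replicates/condition | weakest planted folds (1.7×, log2 ≈ 0.77) sit ~2σ above probe noise, so detection is non-trivial but feasible |
| probe affinity | σ = 0.3, shared treatment/control | sequence-driven probe effects cancel in the comparison, as on real arrays |
| DRE background rate | 4 × 10⁻⁴ cores/bp (thinned from the ~1/512 natural rate of uniform sequence) | leaves a realistic mix of core-bearing and coreless regions |
| TSS-proximal DREs | Poisson(3) planted 19-mers within ± 1.5 kb of each TSS | concentrates DRE density in proximal promoters |
| 24 hr time point | regions thinned to 30%, log2 folds correlated ρ = 0.5 | receptor-degradation decay with correlated strengths |
| expression | 8 time points; DEG probability 0.6 (bound genes) / 0.15 (others); 75% induced | planted DEGs are guaranteed to meet the |FC| ≥ 1.5 and P1 > 0.999 thresholds at their active time points |

Half the planted regions are TSS-proximal, targeting a random 60% subset of
genes; binding avoids the remaining genes' loci so the truth contains
genuinely unbound genes and all four final classes occur. Planted regions
keep ≥ 1 kb separation so merging cannot bridge two distinct truths.

Not modelled: array biochemistry and normalisation, mouse-like base
composition (background is i.i.d. uniform, which keeps Poisson motif-rate
checks exact; a GC-skew option was considered and deliberately left out),
repeat structure, and probe cross-hybridisation. Passing recovery tests
therefore demonstrates the *method logic* — thresholding, merging,
bookkeeping, integration — not performance on real tiling arrays, where
normalisation artefacts and repeats dominate the error budget.

## Problem sizes used by the checks

The recovery benchmarks run at the defaults above: 200 replicate simulations
(~40,000 probes each) for recall/FDR, 100 runs of 900 correlated pairs for
correlation recovery, and one full end-to-end run for gene-class agreement.
The printed-table arithmetic layer runs on the bundled published count set
and is exact. Genome-scale headline counts (tens of thousands of regions on
a mammalian assembly) depend on the original array data and genome build and
are out of desk-scale scope by design.

## Known limitations

- The per-probe statistic is a simplification; absolute cutoff values are
  not comparable to hierarchical-model testers, though the empirical-FDR
  calibration makes the *region lists* comparable in spirit.
- The example PWM is synthetic; MS scores from it are demonstrations.
- With fewer than 3 replicate label permutations the null tail is coarse;
  the default (3 swaps pooled over ~40 k probes) is adequate at FDR 0.01 on
  the simulated tracks but should be raised for sparser tracks.
- A region count is *not* monotone in FDR: relaxing the FDR lowers the
  cutoff, which can fuse neighbouring regions and reduce the count. The
  monotone quantity is called-base coverage, which is what the pipeline test
  asserts.
- Palindromic-context double hits (GCGTG overlapping CACGC) are counted once
  per strand, i.e. twice; a census that counts per-site once will differ
  slightly.
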