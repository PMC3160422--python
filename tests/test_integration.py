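"""Region-to-partition mapping, TSS profiles, gene rollups and expression joins."""

import numpy as np
import pandas as pd
import pytest

from drecistrome.dre_scanner import DreHit, MS_THRESHOLD
from drecistrome.enrichment_calls import EnrichedRegion
from drecistrome.genome_model import build_partition, segment_gene
from drecistrome.integration import (
    ExpressionRecord,
    dre_count_table,
    integrate_expression,
    map_regions_to_segments,
    overlap_timepoints,
    overrep_zscore,
    peak_to_dre_distance,
    rollup_genes,
    tss_profile,
)

from conftest import make_gene, make_region_stub


def region(chrom, start, end, fold=5.0, max_pos=None):
    return EnrichedRegion(
        chrom=chrom, start=start, end=end, n_probes=8, fold_enrichment=fold,
        max_position=max_pos if max_pos is not None else (start + end) // 2,
        ma_stat=1.0,
    )


def hit(pos, score=None, chrom="chr1"):
    return DreHit(chrom, pos, "+", score,
                  score is not None and score >= MS_THRESHOLD)


@pytest.fixture()
def toy_partition():
    stubs = [make_region_stub("chr1", 40_000, 60_000)]
    return build_partition(stubs, {"chr1": 100_000})


class TestMapRegionsToSegments:
    def test_intergenic_region(self, toy_partition):
        labels, table = map_regions_to_segments([region("chr1", 1_000, 1_400)], toy_partition)
        assert labels == ["intergenic"]
        assert table.counts["intergenic"] == 1 and table.counts["genome"] == 1

    def test_boundary_straddle_is_intragenic(self, toy_partition):
        labels, _ = map_regions_to_segments([region("chr1", 39_900, 40_100)], toy_partition)
        assert labels == ["intragenic"]

    def test_unknown_chromosome_excluded(self, toy_partition):
        labels, table = map_regions_to_segments([region("chrZ", 0, 100)], toy_partition)
        assert labels == ["excluded"]
        assert table.counts["genome"] == 0

    def test_counts_equal_per_base_oracle_on_random_regions(self, rng):
        genes = [
            make_gene(f"NM_{i:06d}", tx_start=int(s), tx_end=int(s) + 5_000,
                      cds=(int(s) + 300, int(s) + 4_700),
                      exons=[(int(s), int(s) + 2_000), (int(s) + 3_000, int(s) + 5_000)])
            for i, s in enumerate(range(15_000, 90_000, 25_000))
        ]
        part = build_partition([segment_gene(g, 100_000) for g in genes], {"chr1": 100_000})
        intr = np.zeros(100_000, dtype=bool)
        for s, e in part.intragenic["chr1"]:
            intr[s:e] = True
        regions = []
        for _ in range(500):
            s = int(rng.integers(0, 99_000))
            regions.append(region("chr1", s, s + int(rng.integers(100, 1_000))))
        labels, table = map_regions_to_segments(regions, part)
        want = ["intragenic" if intr[r.start : r.end].any() else "intergenic" for r in regions]
        assert labels == want
        assert table.counts["intragenic"] + table.counts["intergenic"] == 500

    def test_density_identity_exact(self, toy_partition):
        _, table = map_regions_to_segments(
            [region("chr1", 45_000, 45_500), region("chr1", 70_000, 70_400)], toy_partition
        )
        for cls, d in table.densities.items():
            if table.lengths[cls]:
                assert d * table.lengths[cls] / 1e6 == pytest.approx(table.counts[cls])


class TestTssProfile:
    def test_plus_strand_region_bins_upstream(self):
        g = make_gene(tx_start=50_000, tx_end=60_000)
        gr = segment_gene(g, 200_000)
        prof = tss_profile([region("chr1", 49_000, 49_950, max_pos=49_900)], {}, [gr])
        idx = np.searchsorted(prof.region_bin_edges, -200, side="right") - 1
        assert prof.region_counts[idx] == 1
        assert prof.region_counts.sum() == 1

    def test_minus_strand_flips_sign(self):
        g = make_gene(strand="-", tx_start=40_000, tx_end=50_000)
        gr = segment_gene(g, 200_000)
        # max at 49,900: TSS-relative +100 on the minus strand
        prof = tss_profile([region("chr1", 49_000, 49_950, max_pos=49_900)], {}, [gr])
        idx = np.searchsorted(prof.region_bin_edges, 100, side="right") - 1
        assert prof.region_counts[idx] == 1

    def test_histogram_equals_per_gene_loop_oracle(self, rng):
        genes = [
            make_gene(f"NM_{i:06d}", strand="+" if i % 2 else "-",
                      tx_start=20_000 + 30_000 * i, tx_end=25_000 + 30_000 * i)
            for i in range(4)
        ]
        grs = [segment_gene(g, 200_000) for g in genes]
        regions = [
            region("chr1", int(p), int(p) + 300)
            for p in rng.integers(0, 190_000, size=120)
        ]
        hits = {"chr1": [hit(int(p)) for p in rng.integers(0, 190_000, size=200)]}
        prof = tss_profile(regions, hits, grs)

        reg_count = np.zeros(len(prof.region_bin_edges) - 1, dtype=int)
        dre_count = np.zeros(len(prof.dre_bin_edges) - 1, dtype=int)
        for gr in grs:
            for r in regions:
                rel = r.max_position - gr.tss if gr.strand == "+" else gr.tss - r.max_position
                if -10_000 <= rel < 5_000:
                    reg_count[int((rel + 10_000) // 200)] += 1
            for h in hits["chr1"]:
                rel = h.core_center - gr.tss if gr.strand == "+" else gr.tss - h.core_center
                if -10_000 <= rel < 5_000:
                    dre_count[int((rel + 10_000) // 100)] += 1
        assert np.array_equal(prof.region_counts, reg_count)
        assert np.array_equal(prof.dre_counts, dre_count)


class TestPeakToDreDistance:
    def test_zero_when_core_center_at_max(self):
        r = region("chr1", 100, 600, max_pos=302)
        assert peak_to_dre_distance(r, [hit(300)]) == 0  # core_center = 302

    def test_minimum_over_cores(self):
        r = region("chr1", 0, 1_000, max_pos=500)
        hits = [hit(198), hit(598), hit(798)]  # centers 200, 600, 800
        assert peak_to_dre_distance(r, hits) == 100

    def test_none_without_core(self):
        assert peak_to_dre_distance(region("chr1", 0, 500), []) is None

    def test_equals_exhaustive_min_oracle(self, rng):
        for _ in range(50):
            s = int(rng.integers(0, 5_000))
            r = region("chr1", s, s + 800, max_pos=s + int(rng.integers(0, 800)))
            hits = [hit(int(p)) for p in rng.integers(0, 6_000, size=30)]
            got = peak_to_dre_distance(r, hits)
            inside = [h for h in hits if r.start <= h.core_start < r.end]
            want = min((abs(r.max_position - h.core_center) for h in inside), default=None)
            assert got == want


class TestOverlapTimepoints:
    def test_identical_sets_fully_paired_with_r_one(self, rng):
        regions = [
            region("chr1", i * 2_000, i * 2_000 + 500, fold=float(f))
            for i, f in enumerate(rng.uniform(2, 50, size=20))
        ]
        res = overlap_timepoints(regions, regions)
        assert res["n_overlap"] == 20
        assert res["pearson_r"] == pytest.approx(1.0)

    def test_disjoint_sets_have_no_pairs(self):
        a = [region("chr1", 0, 100)]
        b = [region("chr1", 500, 600)]
        res = overlap_timepoints(a, b)
        assert res["n_overlap"] == 0 and res["pearson_r"] is None

    def test_multi_overlap_pairs_with_strongest(self):
        t1 = [region("chr1", 0, 400, fold=3.0), region("chr1", 450, 900, fold=30.0)]
        t2 = [region("chr1", 350, 500, fold=10.0)]
        res = overlap_timepoints(t1, t2)
        assert res["pairs"][0][0].fold_enrichment == 30.0

    def test_fewer_than_three_pairs_undefined(self):
        t1 = [region("chr1", 0, 100, fold=2.0), region("chr1", 200, 300, fold=4.0)]
        res = overlap_timepoints(t1, t1)
        assert res["n_overlap"] == 2 and res["pearson_r"] is None


class TestRollupGenes:
    def test_best_class_wins_across_multiple_regions(self):
        g = make_gene(tx_start=50_000, tx_end=60_000, symbol="Cyp1a1")
        gr = segment_gene(g, 200_000)
        regions = [
            region("chr1", 41_000, 41_500),  # no core
            region("chr1", 52_000, 52_600),  # high-scoring core
        ]
        hits = {"chr1": [hit(52_100, 0.95)]}
        calls = rollup_genes(regions, [gr], hits)
        assert calls["Cyp1a1"].has_enrichment
        assert calls["Cyp1a1"].dre_class == "high_dre"

    def test_gene_without_overlap_is_unenriched(self):
        gr = segment_gene(make_gene(symbol="Far1"), 200_000)
        calls = rollup_genes([region("chr1", 100, 400)], [gr], {})
        assert not calls["Far1"].has_enrichment
        assert calls["Far1"].dre_class is None

    def test_equals_nested_loop_oracle(self, rng):
        genes = [
            make_gene(f"NM_{i:06d}", tx_start=15_000 + 25_000 * i,
                      tx_end=20_000 + 25_000 * i, symbol=f"S{i}")
            for i in range(6)
        ]
        grs = [segment_gene(g, 200_000) for g in genes]
        regions = [
            region("chr1", int(p), int(p) + 400) for p in rng.integers(0, 195_000, 80)
        ]
        hits = {"chr1": [hit(int(p), float(s)) for p, s in
                         zip(rng.integers(0, 199_000, 150), rng.random(150))]}
        calls = rollup_genes(regions, grs, hits)
        for gr in grs:
            s, e = gr.full_span
            overl = [r for r in regions if r.start < e and r.end > s]
            assert calls[gr.gene_symbol].has_enrichment == bool(overl)


def _call(symbol, enrich=True, dre="high_dre"):
    from drecistrome.integration import GeneCallRecord

    return GeneCallRecord(symbol, enrich, dre if enrich else None)


class TestIntegrateExpression:
    def test_deg_with_enrichment_and_dre_counts_in_all_cells(self):
        calls = {"A": _call("A")}
        expr = [ExpressionRecord("A", 2, 2.0, 1.0)]
        out, tab = integrate_expression(calls, expr)
        row = tab[(tab.time_hr == 2) & (tab.direction == "up")].iloc[0]
        assert (row.n_deg, row.n_deg_with_enrichment, row.n_deg_with_enrichment_and_dre) == (1, 1, 1)
        assert out["A"].final_class == "AhR+DRE"

    def test_subthreshold_fold_change_is_not_deg(self):
        calls = {"A": _call("A")}
        out, tab = integrate_expression(calls, [ExpressionRecord("A", 2, 1.4, 1.0)])
        assert tab.n_deg.sum() == 0
        assert out["A"].final_class == "AhR-only"

    def test_subthreshold_posterior_is_not_deg(self):
        calls = {"A": _call("A", enrich=False)}
        out, _ = integrate_expression(calls, [ExpressionRecord("A", 8, -3.0, 0.99)])
        assert out["A"].final_class == "none"

    def test_duplicate_symbols_keep_max_fold_change(self):
        calls = {}
        expr = [ExpressionRecord("B", 4, 1.2, 1.0), ExpressionRecord("B", 4, -2.5, 1.0)]
        out, tab = integrate_expression(calls, expr)
        assert out["B"].expression[4]["fold_change"] == -2.5
        row = tab[(tab.direction == "down") & (tab.time_hr == 4)].iloc[0]
        assert row.n_deg == 1

    def test_crosstab_cells_are_monotone(self, rng):
        calls = {}
        expr = []
        for i in range(120):
            sym = f"G{i}"
            enrich = rng.random() < 0.5
            dre = "low_dre" if rng.random() < 0.5 else "no_core"
            calls[sym] = _call(sym, enrich=enrich, dre=dre)
            for t in (2, 24):
                fc = float(rng.uniform(-4, 4))
                expr.append(ExpressionRecord(sym, t, fc, float(rng.uniform(0.99, 1.0))))
        _, tab = integrate_expression(calls, expr)
        assert (tab.n_deg >= tab.n_deg_with_enrichment).all()
        assert (tab.n_deg_with_enrichment >= tab.n_deg_with_enrichment_and_dre).all()


class TestOverrepZscore:
    def test_exact_expectation_gives_zero(self):
        regions = [region("chr1", 0, 10_000)]
        res = overrep_zscore(regions, lambda c, s, e: 10, background_rate_per_bp=1e-3)
        assert res["z"] == pytest.approx(0.0)
        assert res["ratio"] == pytest.approx(1.0)
        assert not res["significant"]

    def test_planted_motif_in_every_region_is_significant(self):
        regions = [region("chr1", i * 1_000, i * 1_000 + 500) for i in range(20)]
        res = overrep_zscore(regions, lambda c, s, e: 5, background_rate_per_bp=1e-4)
        assert res["z"] > 3 and res["significant"]

    def test_zero_expectation_is_undefined(self):
        res = overrep_zscore([region("chr1", 0, 100)], lambda c, s, e: 1,
                             background_rate_per_bp=0.0)
        assert res["z"] is None

    def test_null_calibration_rarely_exceeds_three_sigma(self, rng):
        """Regions drawn from the background rate stay within |z| < 3."""
        rate = 2e-3
        total_bp = 50_000
        n_exceed = 0
        for _ in range(200):
            counts = rng.poisson(rate * 500, size=100)  # 100 regions x 500 bp
            it = iter(counts)
            res = overrep_zscore(
                [region("chr1", i * 1_000, i * 1_000 + 500) for i in range(100)],
                lambda c, s, e: int(next(it)),
                background_rate_per_bp=rate,
            )
            if abs(res["z"]) >= 3:
                n_exceed += 1
        assert n_exceed <= 8  # ~99.7% coverage nominally


class TestDreCountTable:
    def test_bin_rows_sum_to_region_total(self, rng):
        regions = [region("chr1", int(p), int(p) + 300) for p in rng.integers(0, 50_000, 40)]
        hits = {"chr1": [hit(int(p)) for p in rng.integers(0, 50_000, 120)]}
        tab = dre_count_table(regions, hits)
        assert tab.n_regions.sum() == 40
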