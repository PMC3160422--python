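"""Gene segmentation and intragenic/intergenic partition behaviour."""

import numpy as np
import pytest

from drecistrome.genome_model import (
    build_partition,
    read_annotation,
    region_lengths,
    segment_gene,
    SEGMENT_CLASSES,
)
from drecistrome.intervals import merge_intervals, total_length

from conftest import make_gene, make_region_stub


def _write_refgene(path, rows):
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")


class TestReadAnnotation:
    def test_keeps_only_mature_nm_transcripts(self, tmp_path):
        rows = [
            ("NM_000001", "chr1", "+", 1000, 9000, 1500, 8500, 1, "1000,", "9000,"),
            ("NR_000002", "chr1", "+", 1000, 9000, 1000, 1000, 1, "1000,", "9000,"),
            ("XM_000003", "chr1", "-", 1000, 9000, 1500, 8500, 1, "1000,", "9000,"),
        ]
        p = tmp_path / "refgene.tsv"
        _write_refgene(p, rows)
        genes = read_annotation(p)
        assert [g.transcript_id for g in genes] == ["NM_000001"]

    def test_invalid_transcript_coordinates_raise_with_line(self, tmp_path):
        rows = [("NM_000009", "chr1", "+", 9000, 1000, 1000, 1000, 1, "9000,", "1000,")]
        p = tmp_path / "bad.tsv"
        _write_refgene(p, rows)
        with pytest.raises(ValueError, match="NM_000009"):
            read_annotation(p)

    def test_missing_columns_raise(self, tmp_path):
        p = tmp_path / "short.tsv"
        p.write_text("NM_000001\tchr1\t+\n")
        with pytest.raises(ValueError, match="columns"):
            read_annotation(p)

    def test_symbol_map_overrides_name2(self, tmp_path):
        rows = [
            ("NM_000001", "chr1", "+", 1000, 9000, 1500, 8500, 1, "1000,", "9000,", 0, "Foo")
        ]
        p = tmp_path / "refgene.tsv"
        _write_refgene(p, rows)
        m = tmp_path / "reflink.tsv"
        m.write_text("NM_000001\tCyp1a1\n")
        (g,) = read_annotation(p, symbol_map=m)
        assert g.gene_symbol == "Cyp1a1"

    def test_leading_bin_column_is_tolerated(self, tmp_path):
        rows = [
            ("585", "NM_000001", "chr1", "+", 1000, 9000, 1500, 8500, 1, "1000,", "9000,")
        ]
        p = tmp_path / "refgene.tsv"
        _write_refgene(p, rows)
        (g,) = read_annotation(p)
        assert (g.tx_start, g.tx_end) == (1000, 9000)


class TestSegmentGene:
    @pytest.mark.parametrize(
        "strand,expected_upstream",
        [("+", (40_000, 50_000)), ("-", (60_000, 70_000))],
    )
    def test_upstream_window_is_strand_aware(self, strand, expected_upstream):
        g = make_gene(strand=strand, tx_start=50_000, tx_end=60_000)
        r = segment_gene(g, chrom_length=100_000)
        assert r.segments["upstream10k"] == [expected_upstream]
        assert r.full_span == (min(expected_upstream[0], 50_000), max(expected_upstream[1], 60_000))

    def test_upstream_clipped_at_chromosome_edge(self, caplog):
        g = make_gene(tx_start=4_000, tx_end=9_000, cds=(4_100, 8_900),
                      exons=[(4_000, 9_000)])
        with caplog.at_level("WARNING"):
            r = segment_gene(g, chrom_length=100_000)
        assert r.segments["upstream10k"] == [(0, 4_000)]
        assert "clipped" in caplog.text

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_utr_cds_match_per_base_oracle(self, strand):
        # 2-exon toy: exons [(0,100),(200,300)], cds (50,250)
        g = make_gene(strand=strand, tx_start=0, tx_end=300, cds=(50, 250),
                      exons=[(0, 100), (200, 300)])
        r = segment_gene(g, chrom_length=1_000)

        def oracle_class(b):
            exonic = (0 <= b < 100) or (200 <= b < 300)
            if not exonic:
                return None
            if 50 <= b < 250:
                return "cds"
            left = b < 50
            if strand == "+":
                return "utr5" if left else "utr3"
            return "utr3" if left else "utr5"

        for cls in ("utr5", "cds", "utr3"):
            got = {b for s, e in r.segments[cls] for b in range(s, e)}
            want = {b for b in range(300) if oracle_class(b) == cls}
            assert got == want, cls

    def test_noncoding_cds_yields_empty_utr_cds(self):
        g = make_gene(tx_start=1_000, tx_end=5_000, cds=(1_000, 1_000),
                      exons=[(1_000, 5_000)])
        r = segment_gene(g, chrom_length=50_000)
        assert r.segments["utr5"] == r.segments["cds"] == r.segments["utr3"] == []


class TestBuildPartition:
    def test_single_gene_partition(self):
        stub = make_region_stub("chr1", 40_000, 60_000)
        p = build_partition([stub], {"chr1": 100_000})
        assert p.intragenic["chr1"] == [(40_000, 60_000)]
        assert p.intergenic["chr1"] == [(0, 40_000), (60_000, 100_000)]

    def test_opposite_strand_overlap_merges_to_one_block(self):
        a = make_region_stub("chr1", 10_000, 30_000, strand="+")
        b = make_region_stub("chr1", 25_000, 50_000, strand="-", symbol="G2")
        p = build_partition([a, b], {"chr1": 100_000})
        assert p.intragenic["chr1"] == [(10_000, 50_000)]

    def test_adjacent_regions_merge_leaving_no_zero_length_gap(self):
        a = make_region_stub("chr1", 0, 10_000)
        b = make_region_stub("chr1", 10_000, 20_000, symbol="G2")
        p = build_partition([a, b], {"chr1": 30_000})
        assert p.intragenic["chr1"] == [(0, 20_000)]
        assert all(e > s for s, e in p.intergenic["chr1"])

    def test_empty_input_is_all_intergenic(self):
        p = build_partition([], {"chr1": 5_000})
        assert p.intragenic["chr1"] == []
        assert p.intergenic["chr1"] == [(0, 5_000)]

    def test_conservation_on_random_gene_sets(self, rng):
        for _ in range(200):
            L = int(rng.integers(10_000, 200_000))
            n = int(rng.integers(0, 25))
            stubs = []
            for i in range(n):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, min(L, s + 30_000) + 1))
                stubs.append(make_region_stub("chr1", s, min(e, L), symbol=f"G{i}"))
            p = build_partition(stubs, {"chr1": L})
            got = total_length(p.intragenic["chr1"]) + total_length(p.intergenic["chr1"])
            assert got == L

    def test_partition_idempotent_when_refed(self, rng):
        stubs = [
            make_region_stub("chr1", int(s), int(s) + int(w), symbol=f"G{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 90_000, 30), rng.integers(100, 20_000, 30))
            )
        ]
        p1 = build_partition(stubs, {"chr1": 120_000})
        refed = [
            make_region_stub("chr1", s, e, symbol=f"R{i}")
            for i, (s, e) in enumerate(p1.intragenic["chr1"])
        ]
        p2 = build_partition(refed, {"chr1": 120_000})
        assert p2.intragenic == p1.intragenic
        assert p2.intergenic == p1.intergenic

    def test_strand_reflection_symmetry(self, rng):
        """Reversing all strands and reflecting coordinates reflects the partition."""
        L = 200_000
        genes = []
        for i in range(15):
            s = int(rng.integers(11_000, L - 25_000))
            e = s + int(rng.integers(2_000, 10_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                make_gene(f"NM_{i:06d}", strand=strand, tx_start=s, tx_end=e,
                          cds=(s + 100, e - 100), exons=[(s, e)])
            )
        fwd = build_partition([segment_gene(g, L) for g in genes], {"chr1": L})
        reflected = [
            make_gene(
                f"NM_{i:06d}",
                strand="-" if g.strand == "+" else "+",
                tx_start=L - g.tx_end,
                tx_end=L - g.tx_start,
                cds=(L - g.cds_end, L - g.cds_start),
                exons=[(L - e, L - s) for s, e in reversed(g.exons)],
            )
            for i, g in enumerate(genes)
        ]
        rev = build_partition([segment_gene(g, L) for g in reflected], {"chr1": L})
        want = merge_intervals((L - e, L - s) for s, e in fwd.intragenic["chr1"])
        assert rev.intragenic["chr1"] == want


class TestRegionLengths:
    def test_single_gene_lengths_read_directly(self):
        g = make_gene(tx_start=50_000, tx_end=60_000, cds=(50_100, 59_900),
                      exons=[(50_000, 60_000)])
        p = build_partition([segment_gene(g, 100_000)], {"chr1": 100_000})
        lens = region_lengths(p)
        assert lens["genome"] == 100_000
        assert lens["intragenic"] == 20_000
        assert lens["intergenic"] == 80_000
        assert lens["upstream10k"] == 10_000
        assert lens["cds"] == 9_800
        assert lens["utr5"] == lens["utr3"] == 100

    def test_shared_upstream_counts_once_per_class(self):
        # two isoforms with the same TSS: identical upstream windows merge
        a = make_gene("NM_000001", tx_start=50_000, tx_end=60_000)
        b = make_gene("NM_000002", tx_start=50_000, tx_end=65_000,
                      cds=(50_100, 64_900), exons=[(50_000, 65_000)])
        p = build_partition(
            [segment_gene(a, 200_000), segment_gene(b, 200_000)], {"chr1": 200_000}
        )
        assert region_lengths(p)["upstream10k"] == 10_000

    def test_empty_partition_is_zero_except_genome(self):
        p = build_partition([], {"chr1": 42_000})
        lens = region_lengths(p)
        assert lens["genome"] == lens["intergenic"] == 42_000
        assert lens["intragenic"] == 0
        assert all(lens[c] == 0 for c in SEGMENT_CLASSES)

    def test_class_lengths_match_per_base_oracle(self, rng):
        """On a small chromosome, interval algebra equals literal base labelling."""
        L = 50_000
        genes = []
        for i in range(6):
            s = int(rng.integers(0, L - 6_000))
            e = s + int(rng.integers(1_000, 5_000))
            mid = (s + e) // 2
            genes.append(
                make_gene(f"NM_{i:06d}", strand="+" if i % 2 else "-",
                          tx_start=s, tx_end=e, cds=(s + 200, e - 200),
                          exons=[(s, mid - 100), (mid, e)])
            )
        regions = [segment_gene(g, L) for g in genes]
        p = build_partition(regions, {"chr1": L})

        base_classes = {cls: np.zeros(L, dtype=bool) for cls in SEGMENT_CLASSES}
        intr = np.zeros(L, dtype=bool)
        for r in regions:
            s, e = r.full_span
            intr[max(0, s) : min(L, e)] = True
            for cls in SEGMENT_CLASSES:
                for s2, e2 in r.segments[cls]:
                    base_classes[cls][max(0, s2) : min(L, e2)] = True
        lens = region_lengths(p)
        assert lens["intragenic"] == int(intr.sum())
        assert lens["intergenic"] == L - int(intr.sum())
        for cls in SEGMENT_CLASSES:
            assert lens[cls] == int(base_classes[cls].sum()), cls
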