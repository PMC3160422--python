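"""Reference counts from the mouse hepatic TCDD/AhR ChIP-chip study.

Raw printed counts (region totals, partition-class tallies, the DRE-core
histogram, gene and differentially-expressed-gene tallies at 2 and 24 hr
post-gavage) used as inputs to the table-arithmetic layer, which recomputes
the study's summary percentages and totals from them. Where the study's
genome-wide tally and its section-level tally disagree (intragenic region
counts), each ratio uses the count pair it was originally derived from.
"""

PUBLISHED_COUNTS: dict = {
    "total_2hr": 14_446,
    "total_24hr": 974,
    "intergenic_2hr": 4_163,
    "intergenic_24hr": 344,
    # intragenic counts backing the printed 71.8% / 64.7% shares
    "intragenic_2hr": 10_369,
    "intragenic_24hr": 630,
    # intragenic counts backing the printed DRE-core shares (43.8% / 52.4%)
    "intragenic_text_2hr": 10_369,
    "intragenic_text_24hr": 634,
    "intragenic_with_core_2hr": 4_544,
    "intragenic_with_core_24hr": 332,
    # regions binned by number of contained DRE cores
    "dre_core_histogram_2hr": {
        0: 8_353, 1: 3_705, 2: 1_372, 3: 544, 4: 223, 5: 109, 6: 67, 7: 25,
        8: 15, 9: 11, 10: 7, 11: 5, 12: 3, 13: 0, 14: 3, 15: 3, 16: 1,
    },
    "dre_core_histogram_24hr": {
        0: 472, 1: 289, 2: 121, 3: 46, 4: 16, 5: 12, 6: 7, 7: 5,
        8: 0, 9: 3, 10: 1, 11: 0, 12: 1, 13: 0, 14: 1, 15: 0, 16: 0,
    },
    "with_core_2hr": 6_093,
    "with_core_24hr": 502,
    "no_core_2hr": 8_353,
    "no_core_24hr": 472,
    # coreless regions containing the alternate element CATGN6C[T|A]TG
    "alt_element_no_core_2hr": 482,
    "alt_element_no_core_24hr": 237,
    # gene-level tallies at 2 hr
    "genes_enriched_2hr": 4_732,
    "genes_with_core_2hr": 2_856,
    # expression integration
    "deg_total": 1_896,
    "deg_with_enrichment": 900,
    "deg_with_enrichment_and_dre": 625,
    # time-point comparison
    "n_24hr_overlapping_2hr": 899,
    "pearson_r_overlap": 0.4853,
}

# Percentages exactly as printed, for cross-checking the arithmetic layer.
PUBLISHED_PERCENTAGES: dict = {
    "pct_intragenic_2hr": 71.8,
    "pct_intragenic_24hr": 64.7,
    "pct_no_core_2hr": 57.8,
    "pct_no_core_24hr": 48.5,
    "total_regions_2hr_from_histogram": 14_446.0,
    "total_regions_24hr_from_histogram": 974.0,
    "total_regions_with_core": 6_595.0,
    "pct_intragenic_with_core_2hr": 43.8,
    "pct_intragenic_with_core_24hr": 52.4,
    "pct_alt_element_2hr": 5.8,
    "pct_alt_element_24hr": 50.2,
    "pct_deg_with_enrichment": 47.5,
    "pct_genes_with_core_2hr": 60.4,
}
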