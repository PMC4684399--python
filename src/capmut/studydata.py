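"""Published per-sample counts from the six-cell-line basal-like breast
cancer screen, as worked-example inputs.

These are the printed per-sample marginals of the study's summary tables:
effect-category counts of high-confidence somatic variants (with the novel
subset), zygosity counts, and the Sanger validation counts per confidence
tier.  They serve as inputs for the aggregation operations
(:func:`capmut.somatic.summarize_counts`,
:func:`capmut.report.sanger_concordance`), which recompute the pooled
totals, means, and validation rates from them.

Note: the printed per-sample novel counts for one cell line sum to one
less than its printed novel total; the "others" novel count for that
sample is reconciled upward by one so that both the per-sample totals and
the per-category totals match the printed table.
"""

from __future__ import annotations

SAMPLES = ("HCC1143", "HCC1187", "HCC1395", "HCC1937", "HCC1954", "HCC38")

#: per category: {sample: (count, novel_count)}; the published "others"
#: bucket (intronic/upstream/downstream/intergenic/ncRNA) is carried under
#: the intronic category label.
TABLE1_CATEGORY_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "frameshift_deletion": {
        "HCC1143": (1, 1), "HCC1187": (1, 0), "HCC1395": (1, 1),
        "HCC1937": (0, 0), "HCC1954": (1, 0), "HCC38": (2, 1),
    },
    "frameshift_insertion": {
        "HCC1143": (0, 0), "HCC1187": (4, 2), "HCC1395": (0, 0),
        "HCC1937": (0, 0), "HCC1954": (1, 0), "HCC38": (0, 0),
    },
    "nonframeshift_deletion": {
        "HCC1143": (0, 0), "HCC1187": (2, 0), "HCC1395": (0, 0),
        "HCC1937": (0, 0), "HCC1954": (0, 0), "HCC38": (0, 0),
    },
    "nonsynonymous_SNV": {
        "HCC1143": (37, 2), "HCC1187": (46, 3), "HCC1395": (133, 26),
        "HCC1937": (46, 16), "HCC1954": (33, 0), "HCC38": (38, 9),
    },
    "stopgain_SNV": {
        "HCC1143": (3, 0), "HCC1187": (5, 0), "HCC1395": (6, 0),
        "HCC1937": (5, 1), "HCC1954": (1, 0), "HCC38": (1, 0),
    },
    "stoploss_SNV": {
        "HCC1143": (0, 0), "HCC1187": (0, 0), "HCC1395": (0, 0),
        "HCC1937": (0, 0), "HCC1954": (0, 0), "HCC38": (1, 0),
    },
    "synonymous_SNV": {
        "HCC1143": (5, 3), "HCC1187": (4, 3), "HCC1395": (29, 21),
        "HCC1937": (18, 14), "HCC1954": (5, 3), "HCC38": (7, 3),
    },
    "unknown": {
        "HCC1143": (0, 0), "HCC1187": (0, 0), "HCC1395": (1, 1),
        "HCC1937": (0, 0), "HCC1954": (0, 0), "HCC38": (0, 0),
    },
    "splicing": {
        "HCC1143": (0, 0), "HCC1187": (0, 0), "HCC1395": (6, 0),
        "HCC1937": (2, 1), "HCC1954": (1, 0), "HCC38": (1, 0),
    },
    "UTR3": {
        "HCC1143": (5, 5), "HCC1187": (4, 4), "HCC1395": (26, 26),
        "HCC1937": (18, 18), "HCC1954": (3, 3), "HCC38": (3, 3),
    },
    "UTR5": {
        "HCC1143": (1, 1), "HCC1187": (0, 0), "HCC1395": (8, 8),
        "HCC1937": (4, 4), "HCC1954": (2, 2), "HCC38": (2, 2),
    },
    "intronic": {  # published "others" bucket; HCC1187 novel reconciled 5 -> 6
        "HCC1143": (9, 9), "HCC1187": (6, 6), "HCC1395": (76, 72),
        "HCC1937": (25, 23), "HCC1954": (11, 11), "HCC38": (8, 7),
    },
}

#: per sample: (heterozygous, homozygous) high-confidence somatic counts
TABLE1_ZYGOSITY: dict[str, tuple[int, int]] = {
    "HCC1143": (51, 10),
    "HCC1187": (49, 23),
    "HCC1395": (198, 88),
    "HCC1937": (87, 31),
    "HCC1954": (54, 4),
    "HCC38": (51, 12),
}

#: Sanger validation: per sample (validated_somatic, analyzed)
SANGER_HIGH_CONFIDENCE: dict[str, tuple[int, int]] = {
    "HCC1143": (7, 8), "HCC1187": (7, 7), "HCC1395": (49, 54),
    "HCC1937": (40, 40), "HCC1954": (1, 2), "HCC38": (7, 7),
}
SANGER_LOW_CONFIDENCE: dict[str, tuple[int, int]] = {
    "HCC1143": (3, 13), "HCC1187": (0, 6), "HCC1395": (6, 14),
    "HCC1937": (2, 7), "HCC1954": (1, 4), "HCC38": (2, 10),
}
#: catalogued variants not found by the screen, re-checked by Sanger
SANGER_CATALOGUE_MISSED: dict[str, tuple[int, int]] = {
    "HCC1143": (2, 3), "HCC1187": (4, 5), "HCC1395": (4, 10),
    "HCC1937": (6, 8), "HCC1954": (3, 5), "HCC38": (4, 5),
}


def table1_variant_records() -> list[dict]:
    """Expand the per-sample marginals into one record per variant.

    Records carry the fields :func:`capmut.somatic.summarize_counts`
    aggregates: sample, kind, somatic, confidence, zygosity, category,
    novel.  Zygosity is assigned to match the per-sample heterozygous/
    homozygous marginals (it is independent of category in the source
    table, so the pairing within a sample is arbitrary).
    """
    records: list[dict] = []
    indel_categories = {
        "frameshift_deletion": "deletion",
        "frameshift_insertion": "insertion",
        "nonframeshift_deletion": "deletion",
        "nonframeshift_insertion": "insertion",
    }
    per_sample: dict[str, list[dict]] = {s: [] for s in SAMPLES}
    for category, counts in TABLE1_CATEGORY_COUNTS.items():
        kind = indel_categories.get(category, "SNV")
        for sample, (total, novel) in counts.items():
            for i in range(total):
                per_sample[sample].append(
                    {
                        "sample": sample,
                        "kind": kind,
                        "somatic": True,
                        "confidence": "high",
                        "category": category,
                        "novel": i < novel,
                    }
                )
    for sample, rows in per_sample.items():
        het, hom = TABLE1_ZYGOSITY[sample]
        if het + hom != len(rows):
            raise AssertionError(
                f"{sample}: zygosity marginals {het}+{hom} != {len(rows)} variants"
            )
        for i, row in enumerate(rows):
            row["zygosity"] = "homozygous" if i < hom else "heterozygous"
        records.extend(rows)
    return records


def sanger_validation_rows(tier: str, counts: dict[str, tuple[int, int]]) -> list[dict]:
    """Expand per-sample (validated, analyzed) counts into per-variant rows
    for :func:`capmut.report.sanger_concordance`.  Non-validated variants
    are recorded as wildtype; the rate only depends on the somatic count."""
    rows = []
    for sample, (validated, analyzed) in counts.items():
        for i in range(analyzed):
            rows.append(
                {
                    "sample": sample,
                    "tier": tier,
                    "category": "pooled",
                    "outcome": "somatic" if i < validated else "wildtype",
                }
            )
    return rows
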