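"""Hard-filtering and somatic classification of paired tumor/normal calls.

A call is somatic when the tumor's most likely genotype includes the
alternate allele while the matched normal is homozygous reference.  Somatic
calls are tiered into high and low confidence: high confidence requires the
hard filters to pass, an informative normal depth of at least 10 with at
most one read supporting the alternate allele, and at least three
alt-supporting reads in the tumor.  Everything else somatic is low
confidence.

Hard filters follow the GATK-style substitution/indel rule sets; every
comparison is strict, and an absent annotation passes its filter (the
expression "value < threshold" is false for a missing value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import pandas as pd

from .formats import PairedVariantCall

#: Table-style effect vocabulary (see capmut.effects); needed here to
#: validate summary input and to define the non-silent bucket.
from .effects import EFFECT_CATEGORIES, is_non_silent


@dataclass(frozen=True)
class SnvFilterThresholds:
    min_quality: float = 40.0
    min_qd: float = 5.0
    max_hrun: int = 5
    max_fs: float = 200.0


@dataclass(frozen=True)
class IndelFilterThresholds:
    min_quality: float = 40.0
    min_qd: float = 2.0
    min_read_pos_rank_sum: float = -20.0
    max_fs: float = 200.0


@dataclass(frozen=True)
class SomaticHighThresholds:
    min_normal_depth: int = 10
    max_normal_alt_reads: int = 1
    min_tumor_alt_reads: int = 3


@dataclass(frozen=True)
class FilterThresholds:
    min_call_quality_emit: float = 10.0
    snv: SnvFilterThresholds = field(default_factory=SnvFilterThresholds)
    indel: IndelFilterThresholds = field(default_factory=IndelFilterThresholds)
    somatic_high: SomaticHighThresholds = field(default_factory=SomaticHighThresholds)


DEFAULT_THRESHOLDS = FilterThresholds()


def apply_hard_filters(
    call: PairedVariantCall, thresholds: FilterThresholds = DEFAULT_THRESHOLDS
) -> list[str]:
    """Return the list of violated filter criteria (empty list = pass).

    SNVs and MNVs are judged by the substitution rule set, insertions and
    deletions by the indel rule set.  Calls below the emit quality are
    failed with reason ``below emit threshold``.
    """
    reasons: list[str] = []
    if call.call_quality < thresholds.min_call_quality_emit:
        reasons.append("below emit threshold")
    if call.is_indel:
        t = thresholds.indel
        if call.call_quality < t.min_quality:
            reasons.append("quality")
        if call.qd is not None and call.qd < t.min_qd:
            reasons.append("QD")
        if (
            call.read_pos_rank_sum is not None
            and call.read_pos_rank_sum < t.min_read_pos_rank_sum
        ):
            reasons.append("ReadPosRankSum")
        if call.fs is not None and call.fs > t.max_fs:
            reasons.append("FS")
    else:
        t = thresholds.snv
        if call.call_quality < t.min_quality:
            reasons.append("quality")
        if call.qd is not None and call.qd < t.min_qd:
            reasons.append("QD")
        if call.hrun is not None and call.hrun > t.max_hrun:
            reasons.append("HRun")
        if call.fs is not None and call.fs > t.max_fs:
            reasons.append("FS")
    return reasons


@dataclass(frozen=True)
class SomaticVariant:
    """A classified somatic event with zygosity and confidence tier."""

    call: PairedVariantCall
    zygosity: str  # heterozygous | homozygous
    confidence: str  # high | low
    passed_filters: bool
    filter_reasons: tuple[str, ...] = ()
    stratum: Optional[str] = None  # region class when resolved against a RegionSet

    def __post_init__(self) -> None:
        if self.confidence == "high" and not self.passed_filters:
            raise ValueError("high confidence implies passing filters")


def classify_somatic(
    call: PairedVariantCall,
    thresholds: FilterThresholds = DEFAULT_THRESHOLDS,
    region_set=None,
) -> Optional[SomaticVariant]:
    """Classify one paired call; None means non-somatic (germline or ref).

    Somatic iff the tumor genotype contains the alt allele and the normal
    genotype is homozygous reference.  Confidence is high iff the hard
    filters pass and the tumor/normal read-support rule holds.
    """
    if call.alt not in call.tumor_genotype:
        return None
    if call.normal_genotype != (call.ref, call.ref):
        return None
    reasons = apply_hard_filters(call, thresholds)
    passed = not reasons
    t = thresholds.somatic_high
    high = (
        passed
        and call.normal_depth >= t.min_normal_depth
        and call.normal_alt_reads <= t.max_normal_alt_reads
        and call.tumor_alt_reads >= t.min_tumor_alt_reads
    )
    zygosity = (
        "homozygous"
        if call.tumor_genotype == (call.alt, call.alt)
        else "heterozygous"
    )
    stratum = None
    if region_set is not None:
        stratum = region_set.classify(call.chrom, call.pos - 1)
    return SomaticVariant(
        call=call,
        zygosity=zygosity,
        confidence="high" if high else "low",
        passed_filters=passed,
        filter_reasons=tuple(reasons),
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# summary table

_EXONIC_CATEGORIES = (
    "frameshift_deletion",
    "frameshift_insertion",
    "nonframeshift_deletion",
    "nonframeshift_insertion",
    "nonsynonymous_SNV",
    "stopgain_SNV",
    "stoploss_SNV",
    "synonymous_SNV",
    "unknown",
)
_OTHER_CATEGORIES = ("intronic", "upstream", "intergenic", "ncRNA")

SUMMARY_ROWS = (
    ("snvs_called", None),
    ("indels_called", None),
    ("variants_called", None),
    ("somatic_heterozygous_high", None),
    ("somatic_homozygous_high", None),
    ("total_somatic_high", None),
    ("exonic", None),
    *((c, c) for c in _EXONIC_CATEGORIES),
    ("splicing", "splicing"),
    ("UTR3", "UTR3"),
    ("UTR5", "UTR5"),
    ("others", None),
    ("non_silent", None),
)


def summarize_counts(
    variants: Union[pd.DataFrame, Iterable[dict]],
) -> pd.DataFrame:
    """Per-sample and pooled summary of classified, effect-annotated calls.

    Input rows need columns: sample, kind (SNV/MNV/insertion/deletion),
    somatic (bool), confidence (high/low), zygosity, category (effect
    vocabulary; may be missing for non-somatic rows), novel (bool).

    Returns a table with one row per summary metric; columns are a
    MultiIndex of (sample | total | mean) × (all | novel).  Pooled counts
    are sums over samples; the mean is the per-sample average.
    """
    df = pd.DataFrame(variants).copy()
    if df.empty:
        df = pd.DataFrame(
            columns=["sample", "kind", "somatic", "confidence", "zygosity", "category", "novel"]
        )
    for col, default in (
        ("somatic", False),
        ("confidence", ""),
        ("zygosity", ""),
        ("category", None),
        ("novel", False),
    ):
        if col not in df.columns:
            df[col] = default
    bad = set(df["category"].dropna()) - set(EFFECT_CATEGORIES)
    if bad:
        raise ValueError(f"unknown effect categories: {sorted(bad)}")

    samples = sorted(df["sample"].dropna().unique()) if len(df) else []
    high = df[(df["somatic"] == True) & (df["confidence"] == "high")]  # noqa: E712

    def counts(sub: pd.DataFrame) -> dict[str, int]:
        hs = sub[(sub["somatic"] == True) & (sub["confidence"] == "high")]  # noqa: E712
        cat = hs["category"]
        out = {
            "snvs_called": int((sub["kind"].isin(["SNV", "MNV"])).sum()),
            "indels_called": int((sub["kind"].isin(["insertion", "deletion"])).sum()),
            "variants_called": len(sub),
            "somatic_heterozygous_high": int((hs["zygosity"] == "heterozygous").sum()),
            "somatic_homozygous_high": int((hs["zygosity"] == "homozygous").sum()),
            "total_somatic_high": len(hs),
            "exonic": int(cat.isin(_EXONIC_CATEGORIES).sum()),
            "others": int(cat.isin(_OTHER_CATEGORIES).sum()),
            "non_silent": int(cat.map(lambda c: bool(c) and is_non_silent(c)).sum()),
        }
        for row_name, category in SUMMARY_ROWS:
            if category is not None:
                out[row_name] = int((cat == category).sum())
        return out

    row_names = [name for name, _ in SUMMARY_ROWS]
    data: dict[tuple[str, str], list] = {}
    for s in samples:
        sub = df[df["sample"] == s]
        c_all = counts(sub)
        c_nov = counts(sub[sub["novel"] == True])  # noqa: E712
        data[(s, "all")] = [c_all[r] for r in row_names]
        data[(s, "novel")] = [c_nov[r] for r in row_names]
    c_all = counts(df)
    c_nov = counts(df[df["novel"] == True])  # noqa: E712
    data[("total", "all")] = [c_all[r] for r in row_names]
    data[("total", "novel")] = [c_nov[r] for r in row_names]
    n = max(len(samples), 1)
    data[("mean", "all")] = [c_all[r] / n for r in row_names]
    data[("mean", "novel")] = [c_nov[r] / n for r in row_names]

    out = pd.DataFrame(data, index=row_names)
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out
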