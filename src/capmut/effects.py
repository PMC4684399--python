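"""Effect categorization of variants against transcript models.

Each variant receives exactly one category from a closed vocabulary.  CDS
substitutions are judged by translating the affected codon(s) on the coding
strand before and after the change; CDS indels by divisibility of the
length change by three; variants within a small window inside an intron of
a coding transcript are splicing; everything else is classified by region
(UTR5/UTR3, upstream of the transcription start, intronic, intergenic).
When several transcripts are hit, the most severe category wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Union

from Bio.Seq import Seq

from .formats import GeneModel, PairedVariantCall, ReferenceGenome

EFFECT_CATEGORIES = (
    "frameshift_deletion",
    "frameshift_insertion",
    "nonframeshift_deletion",
    "nonframeshift_insertion",
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "stopgain_SNV",
    "stoploss_SNV",
    "splicing",
    "UTR5",
    "UTR3",
    "upstream",
    "intronic",
    "intergenic",
    "ncRNA",
    "unknown",
)

#: most severe first; used when a variant hits several transcripts
SEVERITY_ORDER = (
    "frameshift_deletion",
    "frameshift_insertion",
    "stopgain_SNV",
    "stoploss_SNV",
    "splicing",
    "nonframeshift_deletion",
    "nonframeshift_insertion",
    "nonsynonymous_SNV",
    "synonymous_SNV",
    "UTR5",
    "UTR3",
    "upstream",
    "intronic",
    "ncRNA",
    "intergenic",
    "unknown",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

_NON_SILENT = frozenset(
    {
        "frameshift_deletion",
        "frameshift_insertion",
        "nonframeshift_deletion",
        "nonframeshift_insertion",
        "nonsynonymous_SNV",
        "stopgain_SNV",
        "stoploss_SNV",
        "splicing",
    }
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def is_non_silent(category: str) -> bool:
    """True exactly for exonic indels, nonsynonymous/stopgain/stoploss SNVs
    and splicing mutations."""
    if category not in EFFECT_CATEGORIES:
        raise ValueError(f"unknown effect category {category!r}")
    return category in _NON_SILENT


@dataclass(frozen=True)
class EffectAnnotation:
    category: str
    gene: str = ""
    transcript_id: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""


@lru_cache(maxsize=4096)
def _cds_layout(model: GeneModel) -> tuple[tuple[int, ...], dict[int, int]]:
    """Genomic positions of coding bases in translation order, plus the
    inverse map genomic position -> CDS index (0-based)."""
    pos = [p for s, e in model.cds_exons for p in range(s, e)]
    if model.strand == "-":
        pos.reverse()
    return tuple(pos), {p: i for i, p in enumerate(pos)}


def _coding_base(model: GeneModel, reference: ReferenceGenome, gpos: int) -> str:
    b = reference.fetch(model.chrom, gpos, gpos + 1)
    return b.translate(_COMPLEMENT) if model.strand == "-" else b


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


def _changed_interval(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim the common prefix of a raw (1-based pos, ref, alt) record and
    return the 0-based start of the changed bases with the trimmed alleles."""
    p = pos - 1
    while ref and alt and ref[0] == alt[0] and (len(ref) > 1 or len(alt) > 1):
        p += 1
        ref, alt = ref[1:], alt[1:]
    return p, ref, alt


def _overlap(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def _classify_for_transcript(
    chrom: str,
    span: tuple[int, int],
    pos0: int,
    ref: str,
    alt: str,
    kind: str,
    model: GeneModel,
    reference: ReferenceGenome,
    splice_window: int,
    upstream_window: int,
) -> Optional[EffectAnnotation]:
    if model.chrom != chrom:
        return None
    s, e = span

    def ann(category: str, hgvs_c: str = "", hgvs_p: str = "") -> EffectAnnotation:
        return EffectAnnotation(category, model.gene, model.transcript_id, hgvs_c, hgvs_p)

    # CDS hit
    if model.coding and any(_overlap(s, e, cs, ce) for cs, ce in model.cds_exons):
        if kind in ("SNV", "MNV"):
            return _classify_cds_substitution(pos0, ref, alt, model, reference, ann)
        net = abs(len(ref) - len(alt))
        shape = "insertion" if len(alt) > len(ref) else "deletion"
        frame = "nonframeshift" if net % 3 == 0 else "frameshift"
        return ann(f"{frame}_{shape}")

    # splicing: within the window *inside* an intron of a coding transcript
    if model.coding:
        for istart, iend in model.introns:
            donor_end = min(istart + splice_window, iend)
            acceptor_start = max(iend - splice_window, istart)
            if _overlap(s, e, istart, donor_end) or _overlap(s, e, acceptor_start, iend):
                return ann("splicing")

    # exonic, outside CDS
    if any(_overlap(s, e, xs, xe) for xs, xe in model.exons):
        if not model.coding:
            return ann("ncRNA")
        if e <= model.cds_start:
            before_cds = True
        elif s >= model.cds_end:
            before_cds = False
        else:  # straddles a CDS bound without touching coding bases: treat by start
            before_cds = s < model.cds_start
        if model.strand == "+":
            return ann("UTR5" if before_cds else "UTR3")
        return ann("UTR3" if before_cds else "UTR5")

    # intronic
    if _overlap(s, e, model.tx_start, model.tx_end):
        return ann("intronic")

    # upstream of the transcription start
    if model.strand == "+":
        if _overlap(s, e, model.tx_start - upstream_window, model.tx_start):
            return ann("upstream")
    else:
        if _overlap(s, e, model.tx_end, model.tx_end + upstream_window):
            return ann("upstream")
    return None


def _classify_cds_substitution(pos0, ref, alt, model, reference, ann):
    positions, index_of = _cds_layout(model)
    # CDS indices affected by the substitution
    changed: dict[int, str] = {}
    for offset in range(len(ref)):
        g = pos0 + offset
        i = index_of.get(g)
        if i is None:
            continue
        base = alt[offset]
        changed[i] = base.translate(_COMPLEMENT) if model.strand == "-" else base
    if not changed:
        return None  # substitution bases all fall outside the CDS
    codon_ids = sorted({i // 3 for i in changed})
    old_aa, new_aa = [], []
    hgvs_c = hgvs_p = ""
    for ci in codon_ids:
        idx = range(3 * ci, min(3 * ci + 3, len(positions)))
        old_codon = "".join(_coding_base(model, reference, positions[i]) for i in idx)
        new_codon = "".join(
            changed.get(i, _coding_base(model, reference, positions[i])) for i in idx
        )
        if len(old_codon) < 3:
            return ann("unknown")  # truncated terminal codon in the model
        old_aa.append(_translate(old_codon))
        new_aa.append(_translate(new_codon))
    old_p, new_p = "".join(old_aa), "".join(new_aa)
    if len(changed) == 1:
        (i, new_base), = changed.items()
        old_base = _coding_base(model, reference, positions[i])
        hgvs_c = f"c.{old_base}{i + 1}{new_base}"
        hgvs_p = f"p.{old_p}{codon_ids[0] + 1}{new_p}"
    if new_p == old_p:
        return ann("synonymous_SNV", hgvs_c, hgvs_p)
    if "*" in new_p and "*" not in old_p:
        return ann("stopgain_SNV", hgvs_c, hgvs_p)
    if "*" in old_p and "*" not in new_p:
        return ann("stoploss_SNV", hgvs_c, hgvs_p)
    return ann("nonsynonymous_SNV", hgvs_c, hgvs_p)


def annotate_effect(
    variant: Union[PairedVariantCall, tuple],
    gene_models: Iterable[GeneModel],
    reference: ReferenceGenome,
    splice_window: int = 2,
    upstream_window: int = 1000,
) -> EffectAnnotation:
    """Categorize one variant; the most severe category across transcripts wins.

    ``variant`` is a PairedVariantCall or a (chrom, pos, ref, alt) tuple with
    a 1-based position.
    """
    if isinstance(variant, PairedVariantCall):
        chrom, pos, ref, alt = variant.chrom, variant.pos, variant.ref, variant.alt
    else:
        chrom, pos, ref, alt = variant
    if pos < 1 or pos - 1 + len(ref) > reference.length(chrom):
        raise ValueError(f"variant {chrom}:{pos} {ref}>{alt} outside reference bounds")
    kind = (
        ("SNV" if len(ref) == 1 else "MNV")
        if len(ref) == len(alt)
        else ("insertion" if len(alt) > len(ref) else "deletion")
    )
    p0, tref, talt = _changed_interval(pos, ref, alt)
    if tref:
        span = (p0, p0 + len(tref))
    else:  # pure insertion: attribute to the base at the insertion point
        span = (max(p0 - 1, 0), p0 + 1)

    candidates = []
    for model in gene_models:
        a = _classify_for_transcript(
            chrom, span, p0, tref, talt, kind, model, reference,
            splice_window, upstream_window,
        )
        if a is not None:
            candidates.append(a)
    if not candidates:
        return EffectAnnotation("intergenic")
    return min(candidates, key=lambda a: _SEVERITY_RANK[a.category])
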