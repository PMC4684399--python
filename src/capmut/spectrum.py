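"""Mutation spectra and composition-normalized enrichment statistics.

Substitutions are strand-collapsed onto the six pyrimidine-centered classes
(C>A, C>G, C>T, T>A, T>C, T>G); trinucleotide contexts onto the 32
pyrimidine-centered X[Y]Z combinations.  Frequencies are normalized by the
composition of the targeted strata: the number of G/C or A/T source bases
for a class, and the number of occurrences of each trinucleotide for a
context.  The coding-versus-non-coding comparison is a 2x2 table per class
or context (mutated vs eligible-minus-mutated); the odds ratio is reported
with a Woolf (log-OR normal approximation) 95% CI, a Wald p-value, and a
Bonferroni-adjusted p over the family of simultaneously reported tests.
A per-sample stratum x sample interaction check is available as a
heterogeneity diagnostic.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: all 32 pyrimidine-centered trinucleotide contexts, lexicographic
ALL_CONTEXTS = tuple(
    f"{l}[{c}]{r}" for c in "CT" for l in "ACGT" for r in "ACGT"
)

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def collapse_substitution(ref_base: str, alt_base: str) -> str:
    """Map an ordered substitution onto its strand-collapsed class."""
    for b in (ref_base, alt_base):
        if b not in "ACGT":
            raise ValueError(f"non-ACGT base {b!r}")
    if ref_base == alt_base:
        raise ValueError("ref == alt")
    if ref_base in "CT":
        return f"{ref_base}>{alt_base}"
    return f"{_comp(ref_base)}>{_comp(alt_base)}"


def paired_class_notation(cls: str) -> str:
    """Render a collapsed class in both-strands notation, e.g. C>T -> 'C/G→T/A'."""
    ref, alt = cls.split(">")
    return f"{ref}/{_comp(ref)}→{alt}/{_comp(alt)}"


def collapse_context(trinuc: str) -> str:
    """Canonical pyrimidine-centered X[Y]Z form of a 3-base window."""
    if len(trinuc) != 3 or not set(trinuc) <= set("ACGT"):
        raise ValueError(f"bad trinucleotide {trinuc!r}")
    if trinuc[1] in "CT":
        t = trinuc
    else:
        t = _revcomp(trinuc)
    return f"{t[0]}[{t[1]}]{t[2]}"


def paired_context_notation(context: str) -> str:
    """Both-strands rendering, e.g. 'T[C]T' -> 'T[C]T/A[G]A'."""
    l, c, r = context[0], context[2], context[4]
    return f"{context}/{_comp(r)}[{_comp(c)}]{_comp(l)}"


def context_of(chrom: str, pos: int, reference) -> Optional[str]:
    """Collapsed trinucleotide context of a 1-based SNV position.

    Returns None (with a logged reason) when a flank is off-contig or
    contains N — such variants are excluded from context tallies.
    """
    pos0 = pos - 1
    if pos0 - 1 < 0 or pos0 + 2 > reference.length(chrom):
        log.info("context excluded at %s:%d: flank off contig", chrom, pos)
        return None
    window = reference.fetch(chrom, pos0 - 1, pos0 + 2)
    if not set(window) <= set("ACGT"):
        log.info("context excluded at %s:%d: non-ACGT flank", chrom, pos)
        return None
    return collapse_context(window)


def titv_ratio(snvs: Iterable) -> Optional[float]:
    """Transitions / transversions over (ref, alt) pairs; None if no
    transversions (undefined, not an error)."""
    ti = tv = 0
    for v in snvs:
        ref, alt = (v.ref, v.alt) if hasattr(v, "ref") else (v[0], v[1])
        if (ref, alt) in _TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ti / tv


def mutation_rate(variant_count: int, stratum_bases: int) -> float:
    """Mutations per megabase of stratum sequence."""
    if stratum_bases <= 0:
        raise ValueError("stratum has zero bases")
    return variant_count / (stratum_bases / 1e6)


# ---------------------------------------------------------------------------
# stratum composition


@dataclass
class StratumComposition:
    """Base and trinucleotide composition of one stratum of the panel."""

    stratum: str  # coding | non_coding
    total_bases: int = 0
    gc_bases: int = 0
    at_bases: int = 0
    trinuc: Counter = field(default_factory=Counter)

    @property
    def gc_fraction(self) -> float:
        return self.gc_bases / self.total_bases if self.total_bases else float("nan")

    def eligible_for_class(self, cls: str) -> int:
        """Source-base denominator for a substitution class."""
        return self.gc_bases if cls.startswith("C") else self.at_bases

    def eligible_for_context(self, context: str) -> int:
        return self.trinuc.get(context, 0)


def stratum_composition(
    region_set,
    reference,
    stratum: str,
    include_flanks: bool = True,
) -> StratumComposition:
    """Composition of the coding (CDS) or non-coding (all other targeted)
    bases: GC/AT tallies excluding N, and collapsed trinucleotide counts
    over every window whose *center* lies in the stratum (flanks may extend
    outside it, but must be on the reference and N-free)."""
    if stratum not in ("coding", "non_coding"):
        raise ValueError(f"stratum must be coding or non_coding, got {stratum!r}")
    from .formats import CLASS_PRECEDENCE

    cds_code = CLASS_PRECEDENCE["CDS"]
    flank_code = CLASS_PRECEDENCE["intronic_flank"]
    base_code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        base_code[ord(b)] = i

    comp = StratumComposition(stratum=stratum)
    trinuc_counts = np.zeros(64, dtype=np.int64)
    for chrom in region_set.chroms:
        seq = reference.fetch(chrom, 0, reference.length(chrom))
        codes = base_code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        classes = region_set.class_array(chrom)
        classes = np.pad(classes, (0, max(0, len(seq) - len(classes))), constant_values=-1)
        if stratum == "coding":
            mask = classes == cds_code
        else:
            mask = classes >= 0
            mask &= classes != cds_code
            if not include_flanks:
                mask &= classes != flank_code
        mask = mask[: len(seq)]
        valid = codes < 4
        sel = mask & valid  # N bases excluded from all tallies
        gc = sel & ((codes == 1) | (codes == 2))
        comp.gc_bases += int(gc.sum())
        comp.at_bases += int((sel & ~gc).sum())
        comp.total_bases += int(sel.sum())
        # trinucleotide windows centered on stratum bases (flanks may lie
        # outside the stratum but must be on the reference and N-free)
        centers = np.nonzero(sel[1:-1])[0] + 1
        ok = valid[centers - 1] & valid[centers + 1]
        centers = centers[ok]
        words = codes[centers - 1] * 16 + codes[centers] * 4 + codes[centers + 1]
        trinuc_counts += np.bincount(words, minlength=64)
    for word in np.nonzero(trinuc_counts)[0]:
        tri = "ACGT"[word // 16] + "ACGT"[(word // 4) % 4] + "ACGT"[word % 4]
        comp.trinuc[collapse_context(tri)] += int(trinuc_counts[word])
    return comp


# ---------------------------------------------------------------------------
# enrichment statistics

_Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 comparison of mutation frequency between coding and non-coding."""

    label: str
    mutated_coding: int
    eligible_coding: int
    mutated_noncoding: int
    eligible_noncoding: int
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    se_log_or: Optional[float]
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    m_tests: int
    defined: bool


def enrichment_test(
    label: str,
    mutated_coding: int,
    eligible_coding: int,
    mutated_noncoding: int,
    eligible_noncoding: int,
    m_tests: int = 1,
) -> EnrichmentResult:
    """Odds-ratio enrichment of one class/context, coding vs non-coding.

    The table is (mutated, eligible - mutated) by stratum.  OR = (a/b)/(c/d)
    with Woolf 95% CI and the Wald test of the log odds ratio (equivalent to
    the stratum coefficient of a binomial logistic model on the aggregated
    counts); Bonferroni adjustment multiplies by ``m_tests``, capped at 1.
    A zero cell flags the result undefined instead of raising.
    """
    a = mutated_coding
    b = eligible_coding - mutated_coding
    c = mutated_noncoding
    d = eligible_noncoding - mutated_noncoding
    if min(a, b, c, d) < 0:
        raise ValueError("mutated count exceeds eligible count")
    if min(a, b, c, d) == 0:
        return EnrichmentResult(
            label, a, eligible_coding, c, eligible_noncoding,
            None, None, None, None, None, None, m_tests, defined=False,
        )
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    ci_low = math.exp(log_or - _Z975 * se)
    ci_high = math.exp(log_or + _Z975 * se)
    p_raw = 2.0 * stats.norm.sf(abs(log_or) / se)
    p_adj = min(1.0, m_tests * p_raw)
    return EnrichmentResult(
        label, a, eligible_coding, c, eligible_noncoding,
        or_, ci_low, ci_high, se, p_raw, p_adj, m_tests, defined=True,
    )


def sample_heterogeneity(per_sample_tables: Sequence[tuple[int, int, int, int]]) -> Optional[float]:
    """Likelihood-ratio p-value for a stratum x sample interaction.

    Input: per sample, (mutated_coding, eligible_coding, mutated_noncoding,
    eligible_noncoding).  Fits binomial logistic models with and without the
    interaction via statsmodels GLM and compares deviances (chi2 with
    n_samples - 1 df).  Returns None when fewer than two informative samples.
    """
    import statsmodels.api as sm

    rows = []
    for i, (mc, ec, mn, en) in enumerate(per_sample_tables):
        if ec > 0:
            rows.append((i, 1, mc, ec - mc))
        if en > 0:
            rows.append((i, 0, mn, en - mn))
    df = pd.DataFrame(rows, columns=["sample", "stratum", "mutated", "unmutated"])
    informative = df.groupby("sample")["mutated"].sum()
    if (informative > 0).sum() < 2:
        return None
    endog = df[["mutated", "unmutated"]].to_numpy(float)
    sample_dummies = pd.get_dummies(df["sample"], drop_first=True, dtype=float)
    base = np.column_stack([np.ones(len(df)), df["stratum"], sample_dummies])
    inter = np.column_stack(
        [base] + [df["stratum"].to_numpy(float) * sample_dummies[c] for c in sample_dummies]
    )
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.GLM(endog, base, family=sm.families.Binomial()).fit()
            fit1 = sm.GLM(endog, inter, family=sm.families.Binomial()).fit()
    except Exception:  # separation or singular design on degenerate input
        return None
    lr = max(fit0.deviance - fit1.deviance, 0.0)
    ddf = inter.shape[1] - base.shape[1]
    if ddf <= 0:
        return None
    return float(stats.chi2.sf(lr, ddf))


# ---------------------------------------------------------------------------
# report tables


@dataclass
class SpectrumReport:
    class_counts: pd.DataFrame
    context_counts: pd.DataFrame
    class_enrichment: pd.DataFrame
    context_enrichment: pd.DataFrame
    gc_replacement_fraction: pd.Series
    excluded_contexts: int


def _enrichment_frame(
    labels: Sequence[str],
    pooled: pd.DataFrame,
    eligible: dict[str, dict[str, int]],
    m_tests: int,
    per_sample: Optional[dict[str, list[tuple[int, int, int, int]]]] = None,
    notation=lambda label: label,
) -> pd.DataFrame:
    rows = []
    for label in labels:
        mc = int(pooled.loc[label, "coding"]) if label in pooled.index else 0
        mn = int(pooled.loc[label, "non_coding"]) if label in pooled.index else 0
        res = enrichment_test(
            label, mc, eligible["coding"][label], mn, eligible["non_coding"][label], m_tests
        )
        row = {
            "label": label,
            "paired_label": notation(label),
            "mutated_coding": res.mutated_coding,
            "eligible_coding": res.eligible_coding,
            "mutated_noncoding": res.mutated_noncoding,
            "eligible_noncoding": res.eligible_noncoding,
            "odds_ratio": res.odds_ratio,
            "ci_low": res.ci_low,
            "ci_high": res.ci_high,
            "se_log_or": res.se_log_or,
            "p_raw": res.p_raw,
            "p_adjusted": res.p_adjusted,
            "defined": res.defined,
            "marker_size": (1.0 / res.se_log_or) if res.se_log_or else float("nan"),
        }
        if per_sample is not None:
            row["heterogeneity_p"] = sample_heterogeneity(per_sample.get(label, []))
        rows.append(row)
    return pd.DataFrame(rows).set_index("label")


def spectrum_report(
    snvs: pd.DataFrame,
    compositions: dict[str, StratumComposition],
    reference,
    m_tests_classes: int = 6,
    m_tests_contexts: int = 32,
) -> SpectrumReport:
    """Spectrum count tables and enrichment rows for a set of somatic SNVs.

    ``snvs`` needs columns sample, chrom, pos, ref, alt, stratum
    (coding | non_coding); only single-base substitutions are used.
    """
    df = snvs.copy()
    df = df[(df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)]
    df["cls"] = [collapse_substitution(r, a) for r, a in zip(df["ref"], df["alt"])]
    contexts = [context_of(ch, p, reference) for ch, p in zip(df["chrom"], df["pos"])]
    df["context"] = contexts
    excluded = sum(c is None for c in contexts)

    strata = ["coding", "non_coding"]
    samples = sorted(df["sample"].unique())

    def count_table(col: str, labels: Sequence[str]) -> pd.DataFrame:
        sub = df.dropna(subset=[col])
        out = {}
        for stratum in strata:
            ss = sub[sub["stratum"] == stratum]
            out[(stratum, "pooled")] = ss[col].value_counts()
            for s in samples:
                out[(stratum, s)] = ss[ss["sample"] == s][col].value_counts()
        table = pd.DataFrame(out).reindex(labels).fillna(0).astype(int)
        table.columns = pd.MultiIndex.from_tuples(table.columns)
        return table

    class_counts = count_table("cls", SUBSTITUTION_CLASSES)
    context_counts = count_table("context", ALL_CONTEXTS)

    pooled_cls = pd.DataFrame(
        {s: class_counts[(s, "pooled")] for s in strata}
    )
    pooled_ctx = pd.DataFrame(
        {s: context_counts[(s, "pooled")] for s in strata}
    )

    eligible_cls = {
        s: {c: compositions[s].eligible_for_class(c) for c in SUBSTITUTION_CLASSES}
        for s in strata
    }
    eligible_ctx = {
        s: {c: compositions[s].eligible_for_context(c) for c in ALL_CONTEXTS}
        for s in strata
    }

    def per_sample_tables(col: str, eligible) -> dict[str, list]:
        out: dict[str, list] = {}
        sub = df.dropna(subset=[col])
        for label in sub[col].unique():
            tabs = []
            for s in samples:
                ss = sub[(sub["sample"] == s) & (sub[col] == label)]
                tabs.append(
                    (
                        int((ss["stratum"] == "coding").sum()),
                        eligible["coding"][label],
                        int((ss["stratum"] == "non_coding").sum()),
                        eligible["non_coding"][label],
                    )
                )
            out[label] = tabs
        return out

    class_enrichment = _enrichment_frame(
        SUBSTITUTION_CLASSES, pooled_cls, eligible_cls, m_tests_classes,
        per_sample_tables("cls", eligible_cls), paired_class_notation,
    )
    context_enrichment = _enrichment_frame(
        ALL_CONTEXTS, pooled_ctx, eligible_ctx, m_tests_contexts,
        None, paired_context_notation,
    )

    gc_frac = {}
    for stratum in strata:
        ss = df[df["stratum"] == stratum]
        gc_frac[stratum] = (
            float(ss["ref"].isin(["G", "C"]).mean()) if len(ss) else float("nan")
        )

    return SpectrumReport(
        class_counts=class_counts,
        context_counts=context_counts,
        class_enrichment=class_enrichment,
        context_enrichment=context_enrichment,
        gc_replacement_fraction=pd.Series(gc_frac),
        excluded_contexts=excluded,
    )
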