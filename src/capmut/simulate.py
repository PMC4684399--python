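"""Self-contained synthetic panels, tumor/normal cohorts, and coverage
tracks with known ground truth.

The generator emulates a targeted-capture screen of cancer genes: each
simulated gene carries 300 bp of upstream sequence, its complete 5'UTR,
all coding exons, and the first 1200 bp of 3'UTR, with stratum GC
composition matching the targeted design (51.1% coding, 47.0% non-coding).
Somatic substitutions are planted per stratum and collapsed class at the
study's average rates (20.6/Mbp coding, 8.7/Mbp non-coding), germline SNPs
at a typical panel rate with a known-SNP Ti/Tv of 2.66, and read evidence
is generated to land on the intended side of every classifier threshold.
Coverage tracks draw Poisson (optionally negative-binomial) depths around
tumor/normal means of 127x/98x, scaled by 2^log2 inside planted events.

All randomness flows from one seeded generator consumed in documented
order (panel, then cohort, then coverage), so outputs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .formats import (
    CatalogueEntry,
    GeneModel,
    PairedVariantCall,
    RegionSet,
    TargetRegion,
    Segment,
    SegmentTrack,
    write_bed,
    write_catalogue,
    write_fasta,
    write_gene_models,
    write_vcf_pairs,
)
from .cnv import CoverageWindow, write_windows

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class CnvEvent:
    """A planted copy-number event over one gene's transcript span."""

    gene: str
    log2: float


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Rates are per-megabase of stratum sequence (matching how targeted
    screens report them); per-class shares split the stratum totals.
    """

    seed: int
    n_samples: int = 6
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (2, 5)  # inclusive range
    cds_exon_bp: tuple[int, int] = (120, 480)  # rounded to codon multiples
    intron_bp: int = 300
    utr5_bp: int = 150
    utr3_bp: int = 1200
    upstream_bp: int = 300
    spacer_bp: int = 400
    #: analysis flank: targeted regions are extended this many bases up- and
    #: downstream (the capture pipeline analyzes these intronic margins, so
    #: variants are planted over the extended regions too)
    flank_bp: int = 30
    gc_coding: float = 0.511
    gc_noncoding: float = 0.470
    somatic_rate_per_mbp: dict = field(
        default_factory=lambda: {"coding": 20.6, "non_coding": 8.7}
    )
    class_shares: dict = field(
        default_factory=lambda: {
            "coding": {
                "C>A": 0.14, "C>G": 0.262, "C>T": 0.349,
                "T>A": 0.06, "T>C": 0.12, "T>G": 0.069,
            },
            "non_coding": {
                "C>A": 0.12, "C>G": 0.12, "C>T": 0.351,
                "T>A": 0.10, "T>C": 0.215, "T>G": 0.094,
            },
        }
    )
    germline_rate: float = 1e-3
    germline_titv: float = 2.66
    homozygous_fraction: float = 168 / 658
    low_confidence_fraction: float = 0.15
    filter_fail_fraction: float = 0.05
    somatic_indel_fraction: float = 0.05
    tumor_mean_depth: float = 127.0
    normal_mean_depth: float = 98.0
    depth_dispersion: Optional[float] = None  # None => Poisson; else NB size
    catalogue_fraction: float = 0.5
    catalogue_shift_fraction: float = 0.05
    #: planted adjacent-SNV pairs whose joint MNV goes into the catalogue;
    #: off by default because each pair adds coding mutations beyond the
    #: configured per-class rates — enable when exercising loose matching
    n_split_mnv_decoys: int = 0
    cnv_events: tuple = ()
    window_target_bp: int = 100
    window_max_bp: int = 150

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for shares in self.class_shares.values():
            total = sum(shares.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ValueError(f"class shares must sum to 1, got {total}")
        for p in (
            self.germline_rate,
            self.homozygous_fraction,
            self.low_confidence_fraction,
            self.filter_fail_fraction,
            self.catalogue_fraction,
            self.catalogue_shift_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.low_confidence_fraction + self.filter_fail_fraction >= 1.0:
            raise ValueError("low-confidence and filter-fail fractions must sum below 1")

    @property
    def planting_boost(self) -> float:
        """Somatic rates are the *high-confidence* rates a screen reports;
        planting is inflated so that after the low-confidence and
        filter-failing fractions are tiered away, the recovered
        high-confidence rate matches the configured one in expectation."""
        return 1.0 / (1.0 - self.low_confidence_fraction - self.filter_fail_fraction)


# ---------------------------------------------------------------------------
# panel


@dataclass
class Panel:
    """In-memory synthetic panel: reference, target regions, gene models."""

    sequences: dict[str, str]
    region_set: RegionSet
    gene_models: list[GeneModel]
    config: SimulationConfig

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "reference": outdir / "reference.fa",
            "regions": outdir / "targets.bed",
            "gene_models": outdir / "gene_models.tsv",
        }
        write_fasta(self.sequences, paths["reference"])
        write_bed(self.region_set, paths["regions"])
        write_gene_models(self.gene_models, paths["gene_models"])
        return paths

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(f"fetch {chrom}:{start}-{end} out of bounds")
        return seq[start:end]

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def analysis_region_set(self) -> RegionSet:
        """Target regions extended by the configured analysis flank (the
        regions over which variants are planted and strata are resolved)."""
        cached = self.__dict__.get("_analysis_regions")
        if cached is not None:
            return cached
        if self.config.flank_bp <= 0:
            rs = self.region_set
        else:
            extended = list(self.region_set)
            for r in self.region_set:
                fs = max(0, r.start - self.config.flank_bp)
                if fs < r.start:
                    extended.append(TargetRegion(r.chrom, fs, r.start, "intronic_flank", r.gene))
                extended.append(
                    TargetRegion(r.chrom, r.end, r.end + self.config.flank_bp, "intronic_flank", r.gene)
                )
            rs = RegionSet(extended)
        self.__dict__["_analysis_regions"] = rs
        return rs


def _seq_with_gc(n: int, gc: float, rng: np.random.Generator) -> list[str]:
    """Random sequence of length n whose GC count is round(n * gc)."""
    n_gc = int(round(n * gc))
    if not 0 <= n_gc <= n:
        raise SimulationError(f"infeasible GC target {gc} for length {n}")
    bases = np.empty(n, dtype="<U1")
    bases[:n_gc] = rng.choice(list("GC"), size=n_gc)
    bases[n_gc:] = rng.choice(list("AT"), size=n - n_gc)
    rng.shuffle(bases)
    return list(bases)


def simulate_panel(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Panel:
    """Generate the reference, target regions, and gene models of a panel.

    Gene structure (genomic order, plus strand): upstream 300 bp, first exon
    holding the 5'UTR plus the first coding chunk, introns, internal coding
    exons, last exon holding the final coding chunk plus the 3'UTR.  Minus
    strand genes are the mirror image.  CDS lengths are codon multiples with
    start and stop codons in place.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = "chr1"
    seq: list[str] = []
    regions: list[TargetRegion] = []
    models: list[GeneModel] = []

    def emit(n: int, gc: float) -> tuple[int, int]:
        start = len(seq)
        seq.extend(_seq_with_gc(n, gc, rng))
        return start, len(seq)

    for gi in range(config.n_genes):
        gene = f"SIMG{gi + 1:03d}"
        strand = "+" if gi % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        lo, hi = config.cds_exon_bp
        chunks = [3 * int(rng.integers(lo // 3, hi // 3 + 1)) for _ in range(n_exons)]

        emit(config.spacer_bp, config.gc_noncoding)

        # genomic-order blocks: (kind, length)
        if strand == "+":
            blocks = [("upstream", config.upstream_bp), ("UTR5", config.utr5_bp)]
            for k, c in enumerate(chunks):
                blocks.append(("CDS", c))
                if k < n_exons - 1:
                    blocks.append(("intron", config.intron_bp))
            blocks.append(("UTR3", config.utr3_bp))
        else:
            blocks = [("UTR3", config.utr3_bp)]
            for k, c in enumerate(reversed(chunks)):
                blocks.append(("CDS", c))
                if k < n_exons - 1:
                    blocks.append(("intron", config.intron_bp))
            blocks.append(("UTR5", config.utr5_bp))
            blocks.append(("upstream", config.upstream_bp))

        coords: list[tuple[str, int, int]] = []
        for kind, length in blocks:
            gc = config.gc_coding if kind == "CDS" else config.gc_noncoding
            s, e = emit(length, gc)
            coords.append((kind, s, e))

        cds_parts = [(s, e) for kind, s, e in coords if kind == "CDS"]
        cds_start, cds_end = cds_parts[0][0], cds_parts[-1][1]
        # exons = maximal runs of transcript blocks (everything except upstream/intron)
        exons: list[tuple[int, int]] = []
        for kind, s, e in coords:
            if kind in ("upstream", "intron"):
                continue
            if exons and exons[-1][1] == s:
                exons[-1] = (exons[-1][0], e)
            else:
                exons.append((s, e))

        # start and stop codons on the coding strand
        if strand == "+":
            seq[cds_start : cds_start + 3] = list("ATG")
            seq[cds_end - 3 : cds_end] = list("TAA")
        else:
            seq[cds_end - 3 : cds_end] = list("CAT")  # revcomp(ATG)
            seq[cds_start : cds_start + 3] = list("TTA")  # revcomp(TAA)

        for kind, s, e in coords:
            if kind in ("upstream", "UTR5", "UTR3", "CDS"):
                regions.append(TargetRegion(chrom, s, e, kind, gene))
        models.append(
            GeneModel(
                gene=gene,
                transcript_id=f"{gene}.1",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    emit(config.spacer_bp, config.gc_noncoding)

    sequences = {chrom: "".join(seq)} if seq else {}
    region_set = RegionSet(regions)
    return Panel(sequences, region_set, models, config)


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Planted tumor/normal cohort with ground truth and catalogue."""

    samples: list[str]
    calls: dict[str, list[PairedVariantCall]]
    truth: pd.DataFrame
    catalogue: list[CatalogueEntry]
    panel: Panel

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        contigs = {c: self.panel.length(c) for c in self.panel.chroms}
        paths: dict[str, Path] = {}
        for s in self.samples:
            records = []
            for v in sorted(self.calls[s], key=lambda v: (v.chrom, v.pos, v.alt)):
                alleles = [v.ref, v.alt]
                idx = {a: i for i, a in enumerate(alleles)}
                records.append(
                    {
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": [v.alt],
                        "qual": v.call_quality,
                        "info": {
                            "QD": v.qd,
                            "HRun": v.hrun,
                            "FS": v.fs,
                            "ReadPosRankSum": v.read_pos_rank_sum,
                        },
                        "tumor_gt": [idx[a] for a in v.tumor_genotype],
                        "normal_gt": [idx[a] for a in v.normal_genotype],
                        "tumor_ad": [v.tumor_ref_reads, v.tumor_alt_reads],
                        "normal_ad": [v.normal_ref_reads, v.normal_alt_reads],
                    }
                )
            path = outdir / f"{s}.vcf"
            write_vcf_pairs(records, f"{s}_T", f"{s}_N", path, contigs)
            paths[s] = path
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["catalogue"] = outdir / "catalogue.tsv"
        write_catalogue(self.catalogue, paths["catalogue"])
        return paths


def _stratum_positions(panel: Panel) -> dict[str, dict[str, np.ndarray]]:
    """Per stratum, per source-base family (C/G vs A/T), the eligible
    0-based positions, plus 'all' targeted positions.  Memoized on the
    panel (its regions and sequences are immutable after construction)."""
    cached = panel.__dict__.get("_stratum_pools")
    if cached is not None:
        return cached
    from .formats import CLASS_PRECEDENCE

    cds_code = CLASS_PRECEDENCE["CDS"]
    base_code = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        base_code[ord(b)] = i
    pools: dict[str, dict[str, np.ndarray]] = {
        s: {"CT_source": [], "AT_source": [], "all": []}
        for s in ("coding", "non_coding")
    }
    region_set = panel.analysis_region_set
    for chrom in region_set.chroms:
        seq = panel.sequences[chrom]
        codes = base_code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        classes = region_set.class_array(chrom)
        classes = np.pad(classes, (0, max(0, len(seq) - len(classes))), constant_values=-1)
        classes = classes[: len(seq)]
        valid = codes < 4
        for stratum, mask in (
            ("coding", (classes == cds_code) & valid),
            ("non_coding", (classes >= 0) & (classes != cds_code) & valid),
        ):
            gc = mask & ((codes == 1) | (codes == 2))
            pools[stratum]["all"].append(np.nonzero(mask)[0])
            pools[stratum]["CT_source"].append(np.nonzero(gc)[0])
            pools[stratum]["AT_source"].append(np.nonzero(mask & ~gc)[0])
    pools = {
        s: {k: np.concatenate(v) if v else np.array([], dtype=int) for k, v in d.items()}
        for s, d in pools.items()
    }
    panel.__dict__["_stratum_pools"] = pools
    return pools


def _draw_depth(mean: float, rng: np.random.Generator, dispersion: Optional[float]) -> int:
    if dispersion is None:
        return int(rng.poisson(mean))
    # negative binomial with size=dispersion, mean preserved
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _alt_for_class(ref_base: str, cls: str) -> str:
    pyr_ref, pyr_alt = cls.split(">")
    if ref_base == pyr_ref:
        return pyr_alt
    return pyr_alt.translate(_COMPLEMENT)


def _pick_positions(
    eligible: np.ndarray, n: int, used: set[int], rng: np.random.Generator
) -> list[int]:
    out: list[int] = []
    for _ in range(n):
        for attempt in range(100):
            p = int(eligible[rng.integers(len(eligible))])
            if p not in used:
                used.add(p)
                out.append(p)
                break
        else:
            raise SimulationError(
                "mutation placement collided 100 times; rate too high for panel"
            )
    return out


def simulate_cohort(
    panel: Panel,
    config: Optional[SimulationConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> Cohort:
    """Plant germline and somatic variants and generate read evidence.

    Somatic substitution counts per stratum and class are binomial over the
    eligible source bases at the configured per-base rates; placement is
    uniform over eligible bases.  Evidence fields are drawn to land on the
    intended side of every classifier threshold (high confidence, low
    confidence via a violated support rule, or hard-filter failure).  A
    configured fraction of planted somatic variants is copied into the
    catalogue, some as position-shifted or MNV-split decoys.
    """
    config = config if config is not None else panel.config
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chrom = panel.chroms[0] if panel.chroms else "chr1"
    pools = _stratum_positions(panel)
    stratum_bases = {s: len(pools[s]["all"]) for s in pools}

    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    calls: dict[str, list[PairedVariantCall]] = {s: [] for s in samples}
    truth_rows: list[dict] = []
    catalogue: list[CatalogueEntry] = []
    cat_n = 0

    def evidence(intent: str, zygosity: str, kind: str) -> dict:
        """Evidence fields landing on the intended side of the thresholds."""
        ev: dict = {}
        qual = float(rng.uniform(60, 2000))
        qd = float(rng.uniform(6, 25))
        hrun = int(rng.integers(0, 4))
        fs = float(rng.uniform(0, 50))
        rprs = float(rng.normal(0, 3))
        nd = max(10, _draw_depth(config.normal_mean_depth, rng, config.depth_dispersion))
        n_alt = int(rng.random() < 0.15)
        td = max(8, _draw_depth(config.tumor_mean_depth, rng, config.depth_dispersion))
        vaf = 0.95 if zygosity == "homozygous" else 0.5
        t_alt = int(rng.binomial(td, vaf))
        t_alt = min(max(t_alt, 3), td)
        if intent == "filter_fail":
            qd = float(rng.uniform(0.05, 1.9)) if kind in ("insertion", "deletion") else float(
                rng.uniform(0.5, 4.9)
            )
        elif intent == "low":
            which = rng.integers(3)
            if which == 0:
                nd = int(rng.integers(0, 10))
                n_alt = 0
            elif which == 1:
                t_alt = int(rng.integers(1, 3))
            else:
                n_alt = int(rng.integers(2, 5))
                nd = max(nd, n_alt)
        ev.update(
            call_quality=qual, qd=qd, hrun=hrun, fs=fs, read_pos_rank_sum=rprs,
            normal_ref_reads=nd - n_alt, normal_alt_reads=n_alt,
            tumor_ref_reads=td - t_alt, tumor_alt_reads=t_alt,
        )
        return ev

    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

    for sample in samples:
        used: set[int] = set()

        # --- somatic SNVs per stratum and class
        for stratum in ("coding", "non_coding"):
            total_rate = config.somatic_rate_per_mbp[stratum] * 1e-6
            n_total_bases = stratum_bases[stratum]
            for cls, share in config.class_shares[stratum].items():
                source = pools[stratum]["CT_source" if cls.startswith("C") else "AT_source"]
                if len(source) == 0:
                    continue
                # SNVs carry (1 - indel fraction) of the somatic rate budget;
                # indels are planted below to make up the remainder
                per_source = (
                    share * total_rate * n_total_bases / len(source)
                ) * config.planting_boost * (1.0 - config.somatic_indel_fraction)
                n = int(rng.binomial(len(source), min(per_source, 1.0)))
                for pos0 in _pick_positions(source, n, used, rng):
                    ref = panel.fetch(chrom, pos0, pos0 + 1)
                    alt = _alt_for_class(ref, cls)
                    zyg = "homozygous" if rng.random() < config.homozygous_fraction else "heterozygous"
                    r = rng.random()
                    intent = (
                        "filter_fail"
                        if r < config.filter_fail_fraction
                        else "low"
                        if r < config.filter_fail_fraction + config.low_confidence_fraction
                        else "high"
                    )
                    ev = evidence(intent, zyg, "SNV")
                    tumor_gt = (alt, alt) if zyg == "homozygous" else (ref, alt)
                    call = PairedVariantCall(
                        chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                        tumor_genotype=tumor_gt, normal_genotype=(ref, ref),
                        sample=sample, **ev,
                    )
                    calls[sample].append(call)
                    truth_rows.append(
                        {
                            "sample": sample, "chrom": chrom, "pos": pos0 + 1,
                            "ref": ref, "alt": alt, "kind": "SNV", "role": "somatic",
                            "stratum": stratum, "cls": cls, "zygosity": zyg,
                            "intent": intent, "catalogue_status": "none",
                        }
                    )

        # --- somatic indels
        n_som = sum(1 for t in truth_rows if t["sample"] == sample and t["role"] == "somatic")
        f = config.somatic_indel_fraction
        n_indel = int(rng.poisson(f / (1.0 - f) * n_som)) if f > 0 else 0
        for _ in range(n_indel):
            stratum = "coding" if rng.random() < 0.5 else "non_coding"
            pool = pools[stratum]["all"]
            if len(pool) == 0:
                continue
            length = int(rng.integers(1, 7))
            for attempt in range(100):
                anchor = int(pool[rng.integers(len(pool))])
                if anchor in used or anchor + 1 + length > panel.length(chrom):
                    continue
                used.add(anchor)
                break
            else:
                raise SimulationError("indel placement collided 100 times")
            is_del = rng.random() < 0.5
            anchor_base = panel.fetch(chrom, anchor, anchor + 1)
            if is_del:
                ref = panel.fetch(chrom, anchor, anchor + 1 + length)
                alt = anchor_base
            else:
                ref = anchor_base
                alt = anchor_base + "".join(rng.choice(list("ACGT"), size=length))
            zyg = "homozygous" if rng.random() < config.homozygous_fraction else "heterozygous"
            r = rng.random()
            intent = (
                "filter_fail"
                if r < config.filter_fail_fraction
                else "low"
                if r < config.filter_fail_fraction + config.low_confidence_fraction
                else "high"
            )
            ev = evidence(intent, zyg, "deletion" if is_del else "insertion")
            tumor_gt = (alt, alt) if zyg == "homozygous" else (ref, alt)
            call = PairedVariantCall(
                chrom=chrom, pos=anchor + 1, ref=ref, alt=alt,
                tumor_genotype=tumor_gt, normal_genotype=(ref, ref),
                sample=sample, **ev,
            )
            calls[sample].append(call)
            truth_rows.append(
                {
                    "sample": sample, "chrom": chrom, "pos": anchor + 1,
                    "ref": ref, "alt": alt,
                    "kind": "deletion" if is_del else "insertion",
                    "role": "somatic", "stratum": stratum, "cls": None,
                    "zygosity": zyg, "intent": intent, "catalogue_status": "none",
                }
            )

        # --- germline SNPs (present in tumor and normal alike)
        all_pos = np.concatenate([pools["coding"]["all"], pools["non_coding"]["all"]]) if stratum_bases["coding"] + stratum_bases["non_coding"] else np.array([], dtype=int)
        n_germ = int(rng.binomial(len(all_pos), config.germline_rate)) if len(all_pos) else 0
        p_ti = config.germline_titv / (config.germline_titv + 1.0)
        for pos0 in _pick_positions(all_pos, n_germ, used, rng):
            ref = panel.fetch(chrom, pos0, pos0 + 1)
            if ref not in "ACGT":
                continue
            if rng.random() < p_ti:
                alt = transitions[ref]
            else:
                alt = transversions[ref][int(rng.integers(2))]
            zyg = "homozygous" if rng.random() < 1 / 3 else "heterozygous"
            gt = (alt, alt) if zyg == "homozygous" else (ref, alt)
            ev = evidence("high", zyg, "SNV")
            # the normal carries the allele too: mirror the genotype and depths
            nd = ev["normal_ref_reads"] + ev["normal_alt_reads"]
            n_alt = int(rng.binomial(nd, 0.95 if zyg == "homozygous" else 0.5))
            ev["normal_ref_reads"], ev["normal_alt_reads"] = nd - n_alt, n_alt
            call = PairedVariantCall(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                tumor_genotype=gt, normal_genotype=gt, sample=sample, **ev,
            )
            calls[sample].append(call)
            truth_rows.append(
                {
                    "sample": sample, "chrom": chrom, "pos": pos0 + 1,
                    "ref": ref, "alt": alt, "kind": "SNV", "role": "germline",
                    "stratum": None, "cls": None, "zygosity": zyg,
                    "intent": "germline", "catalogue_status": "none",
                }
            )

        # --- split-MNV decoys: adjacent SNV pairs with the joint MNV catalogued
        pool = pools["coding"]["all"]
        for _ in range(config.n_split_mnv_decoys):
            if len(pool) < 2:
                break
            for attempt in range(100):
                i = int(rng.integers(len(pool) - 1))
                p0, p1 = int(pool[i]), int(pool[i]) + 1
                if p1 in pool and p0 not in used and p1 not in used:
                    used.add(p0)
                    used.add(p1)
                    break
            else:
                break
            pieces = []
            for p in (p0, p1):
                ref = panel.fetch(chrom, p, p + 1)
                alt = transitions[ref]
                ev = evidence("high", "heterozygous", "SNV")
                call = PairedVariantCall(
                    chrom=chrom, pos=p + 1, ref=ref, alt=alt,
                    tumor_genotype=(ref, alt), normal_genotype=(ref, ref),
                    sample=sample, **ev,
                )
                calls[sample].append(call)
                pieces.append((ref, alt))
                truth_rows.append(
                    {
                        "sample": sample, "chrom": chrom, "pos": p + 1,
                        "ref": ref, "alt": alt, "kind": "SNV", "role": "somatic",
                        "stratum": "coding", "cls": None, "zygosity": "heterozygous",
                        "intent": "high", "catalogue_status": "split_mnv",
                    }
                )
            cat_n += 1
            catalogue.append(
                CatalogueEntry(
                    chrom=chrom, pos=p0 + 1,
                    ref=pieces[0][0] + pieces[1][0],
                    alt=pieces[0][1] + pieces[1][1],
                    gene="", catalogue_id=f"SIMC{cat_n:05d}",
                )
            )

    # --- catalogue: copy a fraction of planted somatic variants, some shifted
    for row in truth_rows:
        if row["role"] != "somatic" or row["catalogue_status"] == "split_mnv":
            continue
        if rng.random() >= config.catalogue_fraction:
            continue
        cat_n += 1
        pos = row["pos"]
        status = "exact"
        if rng.random() < config.catalogue_shift_fraction:
            shift = int(rng.integers(1, 5)) * (1 if rng.random() < 0.5 else -1)
            pos = max(1, pos + shift)
            status = "shifted"
        catalogue.append(
            CatalogueEntry(
                chrom=row["chrom"], pos=pos, ref=row["ref"], alt=row["alt"],
                gene="", catalogue_id=f"SIMC{cat_n:05d}",
            )
        )
        row["catalogue_status"] = status

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample", "chrom", "pos", "ref", "alt", "kind", "role", "stratum",
            "cls", "zygosity", "intent", "catalogue_status",
        ],
    )
    return Cohort(samples, calls, truth, catalogue, panel)


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageSim:
    """Paired coverage windows with the planted copy-number truth."""

    windows: list[CoverageWindow]
    truth_track: SegmentTrack
    events: tuple[CnvEvent, ...]

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"windows": outdir / "coverage_windows.tsv"}
        write_windows(self.windows, paths["windows"])
        return paths


def _tile(start: int, end: int, target: int, max_size: int) -> list[tuple[int, int]]:
    """Split [start, end) into near-equal windows of at most max_size bp."""
    length = end - start
    n = max(1, math.ceil(length / target))
    while math.ceil(length / n) > max_size:
        n += 1
    bounds = np.linspace(start, end, n + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if b > a]


def simulate_coverage(
    panel: Panel,
    config: Optional[SimulationConfig] = None,
    events: Optional[Sequence[CnvEvent]] = None,
    rng: Optional[np.random.Generator] = None,
) -> CoverageSim:
    """Tumor/normal depths over target-derived windows with planted events.

    Depths are Poisson (or negative-binomial) around the configured means;
    tumor depths are scaled by 2^log2 inside each event's gene span.
    Events on overlapping spans are rejected.
    """
    config = config if config is not None else panel.config
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    events = tuple(events if events is not None else config.cnv_events)
    gene_span = {
        m.gene: (m.chrom, m.tx_start, m.tx_end) for m in panel.gene_models
    }
    spans: list[tuple[str, int, int, float]] = []
    for ev in events:
        if ev.gene not in gene_span:
            raise SimulationError(f"event gene {ev.gene!r} not in panel")
        chrom, s, e = gene_span[ev.gene]
        for c2, s2, e2, _ in spans:
            if c2 == chrom and s < e2 and s2 < e:
                raise SimulationError(f"overlapping CNV events at {ev.gene}")
        spans.append((chrom, s, e, ev.log2))

    def true_log2(chrom: str, start: int, end: int) -> float:
        for c2, s2, e2, l2 in spans:
            mid = (start + end) // 2
            if c2 == chrom and s2 <= mid < e2:
                return l2
        return 0.0

    windows: list[CoverageWindow] = []
    for region in panel.region_set:
        for ws, we in _tile(region.start, region.end, config.window_target_bp, config.window_max_bp):
            l2 = true_log2(region.chrom, ws, we)
            normal = _draw_depth(config.normal_mean_depth, rng, config.depth_dispersion)
            tumor = _draw_depth(
                config.tumor_mean_depth * (2.0 ** l2), rng, config.depth_dispersion
            )
            seq = panel.fetch(region.chrom, ws, we)
            gc = (seq.count("G") + seq.count("C")) / len(seq)
            windows.append(
                CoverageWindow(
                    chrom=region.chrom, start=ws, end=we,
                    tumor_mean_depth=float(tumor), normal_mean_depth=float(normal),
                    gc=gc,
                )
            )
    windows.sort(key=lambda w: (w.chrom, w.start))
    # deduplicate identical windows arising from same-coordinate regions
    dedup: list[CoverageWindow] = []
    for w in windows:
        if dedup and (dedup[-1].chrom, dedup[-1].start, dedup[-1].end) == (w.chrom, w.start, w.end):
            continue
        dedup.append(w)

    # truth track: piecewise-constant over each chromosome
    truth_segs: list[Segment] = []
    for chrom in panel.chroms:
        cuts = sorted(
            {0, panel.length(chrom)}
            | {s for c, s, e, _ in spans if c == chrom}
            | {e for c, s, e, _ in spans if c == chrom}
        )
        for a, b in zip(cuts[:-1], cuts[1:]):
            truth_segs.append(Segment(chrom, a, b, true_log2(chrom, a, b)))
    return CoverageSim(dedup, SegmentTrack(truth_segs), events)
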