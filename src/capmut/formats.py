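"""Readers and writers for the genomic file formats the pipeline touches.

Coordinate conventions are strict and converted only at the file boundary:
variant positions are 1-based (VCF dialect); every interval type — BED
records, target regions, gene models, coverage windows, segments — is
0-based half-open.

Region classes form a closed vocabulary.  A targeted base may fall into
several classes (e.g. a capture flank under a CDS of a neighbouring gene);
class precedence resolves each base to a unique stratum:
CDS > UTR5 > UTR3 > upstream > intronic_flank > other.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pyfaidx import Fasta

log = logging.getLogger(__name__)

#: closed vocabulary of target-region classes, in precedence order
REGION_CLASSES = ("CDS", "UTR5", "UTR3", "upstream", "intronic_flank", "other")
CLASS_PRECEDENCE = {c: i for i, c in enumerate(REGION_CLASSES)}

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed input file, record, or coordinate."""


# ---------------------------------------------------------------------------
# target regions


@dataclass(frozen=True, order=True)
class TargetRegion:
    """One captured interval, 0-based half-open, with its region class."""

    chrom: str
    start: int
    end: int
    region_class: str = "other"
    gene: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"region {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.region_class not in REGION_CLASSES:
            raise FormatError(f"unknown region class {self.region_class!r}")

    def __len__(self) -> int:
        return self.end - self.start


class RegionSet:
    """Labeled target intervals with unique-stratum base classification.

    Overlapping intervals of the same (class, gene) are merged on
    construction; overlaps between different classes are allowed and
    resolved by :data:`CLASS_PRECEDENCE` at query time.
    """

    def __init__(self, regions: Iterable[TargetRegion]):
        self.regions: list[TargetRegion] = self._merge(list(regions))
        self._by_chrom: dict[str, list[TargetRegion]] = {}
        for r in self.regions:
            self._by_chrom.setdefault(r.chrom, []).append(r)
        self._check_same_class_overlap()
        # interval-query acceleration: per chrom, region starts (sorted) and
        # the maximum region length bound the backward scan in overlapping()
        self._starts = {c: [r.start for r in rs] for c, rs in self._by_chrom.items()}
        self._maxlen = {
            c: max(len(r) for r in rs) for c, rs in self._by_chrom.items()
        }
        self._class_arrays: dict[str, "np.ndarray"] = {}

    @staticmethod
    def _merge(regions: list[TargetRegion]) -> list[TargetRegion]:
        merged: list[TargetRegion] = []
        key = lambda r: (r.chrom, r.region_class, r.gene, r.start, r.end)
        for r in sorted(regions, key=key):
            if (
                merged
                and merged[-1].chrom == r.chrom
                and merged[-1].region_class == r.region_class
                and merged[-1].gene == r.gene
                and r.start <= merged[-1].end
            ):
                prev = merged.pop()
                r = TargetRegion(
                    r.chrom, prev.start, max(prev.end, r.end), r.region_class, r.gene
                )
            merged.append(r)
        merged.sort(key=lambda r: (r.chrom, r.start, r.end, CLASS_PRECEDENCE[r.region_class]))
        return merged

    def _check_same_class_overlap(self) -> None:
        last: dict[tuple[str, str], TargetRegion] = {}
        for r in self.regions:
            k = (r.chrom, r.region_class)
            prev = last.get(k)
            if prev is not None and r.start < prev.end:
                raise FormatError(
                    f"overlapping {r.region_class} regions of different genes: "
                    f"{prev} / {r}"
                )
            if prev is None or r.end > prev.end:
                last[k] = r

    def __iter__(self) -> Iterator[TargetRegion]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TargetRegion]:
        regions = self._by_chrom.get(chrom)
        if not regions:
            return []
        starts = self._starts[chrom]
        lo = bisect_right(starts, start - self._maxlen[chrom])
        hi = bisect_right(starts, end - 1)
        return [r for r in regions[lo:hi] if r.start < end and start < r.end]

    def classify(self, chrom: str, pos0: int) -> Optional[str]:
        """Unique region class of a 0-based position, by precedence; None if untargeted."""
        hits = [r.region_class for r in self.overlapping(chrom, pos0, pos0 + 1)]
        if not hits:
            return None
        return min(hits, key=CLASS_PRECEDENCE.__getitem__)

    def stratum_of(self, chrom: str, pos0: int, include_flanks: bool = True) -> Optional[str]:
        """Coding/non-coding stratum of a base: CDS bases are 'coding', every
        other targeted base 'non_coding'.  Flank bases can be excluded from
        the non-coding stratum."""
        cls = self.classify(chrom, pos0)
        if cls is None:
            return None
        if cls == "CDS":
            return "coding"
        if cls == "intronic_flank" and not include_flanks:
            return None
        return "non_coding"

    def filter_classes(self, classes: Sequence[str]) -> "RegionSet":
        wanted = set(classes)
        return RegionSet(r for r in self.regions if r.region_class in wanted)

    def total_bases(self, classes: Optional[Sequence[str]] = None) -> int:
        """Unique targeted bases (precedence-resolved) in the given classes."""
        wanted = (
            [CLASS_PRECEDENCE[c] for c in classes]
            if classes is not None
            else list(range(len(REGION_CLASSES)))
        )
        n = 0
        for chrom in self._by_chrom:
            arr = self.class_array(chrom)
            n += int(np.isin(arr, wanted).sum())
        return n

    def class_array(self, chrom: str) -> "np.ndarray":
        """Per-base precedence-resolved class codes (int8 index into
        REGION_CLASSES; -1 = untargeted), length = max region end."""
        cached = self._class_arrays.get(chrom)
        if cached is not None:
            return cached
        regions = self._by_chrom.get(chrom, [])
        n = max((r.end for r in regions), default=0)
        arr = np.full(n, -1, dtype=np.int8)
        # paint lowest-precedence classes first so higher ones overwrite
        for code in range(len(REGION_CLASSES) - 1, -1, -1):
            cls = REGION_CLASSES[code]
            for r in regions:
                if r.region_class == cls:
                    arr[r.start : r.end] = code
        self._class_arrays[chrom] = arr
        return arr

    def iter_classified(self, chrom: str) -> Iterator[tuple[int, str]]:
        """Yield (pos0, precedence-resolved class) for each targeted base."""
        arr = self.class_array(chrom)
        for p in np.nonzero(arr >= 0)[0]:
            yield int(p), REGION_CLASSES[arr[p]]

    def to_bed(self, path: Union[str, Path]) -> None:
        write_bed(self, path)


def read_regions(
    bed_source: Union[str, Path],
    flank: int = 0,
) -> RegionSet:
    """Read a BED file of target regions (0-based half-open).

    The optional 4th column carries ``class|gene``; absent class defaults to
    ``other``.  With ``flank > 0`` every region is extended by that many
    bases up- and downstream, the extensions labeled ``intronic_flank`` —
    mirroring how capture analyses widen targets into the adjacent introns.
    """
    regions: list[TargetRegion] = []
    with open(bed_source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{bed_source}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{bed_source}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{bed_source}:{lineno}: start {start} >= end {end}"
                )
            region_class, gene = "other", ""
            if len(fields) >= 4 and fields[3]:
                parts = fields[3].split("|", 1)
                region_class = parts[0]
                gene = parts[1] if len(parts) > 1 else ""
            if region_class not in REGION_CLASSES:
                raise FormatError(
                    f"{bed_source}:{lineno}: unknown region class {region_class!r}"
                )
            regions.append(TargetRegion(chrom, start, end, region_class, gene))
            if flank > 0:
                fs = max(0, start - flank)
                if fs < start:
                    regions.append(
                        TargetRegion(chrom, fs, start, "intronic_flank", gene)
                    )
                regions.append(
                    TargetRegion(chrom, end, end + flank, "intronic_flank", gene)
                )
    return RegionSet(regions)


def write_bed(region_set: RegionSet, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in region_set:
            label = r.region_class if not r.gene else f"{r.region_class}|{r.gene}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{label}\n")


# ---------------------------------------------------------------------------
# reference sequence


class ReferenceGenome:
    """FASTA-backed reference with strict-bounds, uppercase substring fetch."""

    def __init__(self, path: Union[str, Path]):
        self._fa = Fasta(str(path), as_raw=True, sequence_always_upper=True)

    @property
    def chroms(self) -> list[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        if chrom not in self._fa:
            raise FormatError(f"unknown sequence {chrom!r}")
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end), 0-based half-open, uppercased."""
        n = self.length(chrom)
        if not (0 <= start <= end <= n):
            raise FormatError(
                f"fetch {chrom}:{start}-{end} outside sequence of length {n}"
            )
        return str(self._fa[chrom][start:end])


def read_fasta(path: Union[str, Path]) -> ReferenceGenome:
    return ReferenceGenome(path)


def write_fasta(sequences: dict[str, str], path: Union[str, Path], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# paired variant calls


@dataclass(frozen=True)
class PairedVariantCall:
    """One candidate variant with tumor and normal evidence at the site.

    ``pos`` is 1-based (VCF).  Genotypes are unordered, unphased allele
    pairs given as allele strings.  Site annotations (QD, HRun, FS,
    ReadPosRankSum) may be absent (None) — absence is not zero.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    tumor_genotype: tuple[str, str]
    normal_genotype: tuple[str, str]
    tumor_ref_reads: int
    tumor_alt_reads: int
    normal_ref_reads: int
    normal_alt_reads: int
    call_quality: float = 0.0
    qd: Optional[float] = None
    hrun: Optional[int] = None
    fs: Optional[float] = None
    read_pos_rank_sum: Optional[float] = None
    sample: str = ""

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise FormatError("empty allele")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _BASES:
                raise FormatError(f"allele {allele!r} outside A/C/G/T")
        for n in (
            self.tumor_ref_reads,
            self.tumor_alt_reads,
            self.normal_ref_reads,
            self.normal_alt_reads,
        ):
            if n < 0:
                raise FormatError("negative read count")
        if self.call_quality < 0:
            raise FormatError("negative call quality")

    @property
    def kind(self) -> str:
        """SNV, MNV, insertion, or deletion — derivable from allele lengths."""
        if len(self.ref) == len(self.alt):
            return "SNV" if len(self.ref) == 1 else "MNV"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def is_indel(self) -> bool:
        return self.kind in ("insertion", "deletion")

    @property
    def normal_depth(self) -> int:
        """Informative depth of the normal: sum of the allele-depth fields."""
        return self.normal_ref_reads + self.normal_alt_reads

    @property
    def tumor_depth(self) -> int:
        return self.tumor_ref_reads + self.tumor_alt_reads


def read_vcf_pairs(
    vcf_source: Union[str, Path],
    tumor_sample_name: str,
    normal_sample_name: str,
    errors: Optional[list[str]] = None,
) -> list[PairedVariantCall]:
    """Read paired tumor/normal calls from a VCF 4.x file.

    Multi-allelic records are decomposed into one call per ALT allele.
    Records with malformed genotype or allele-depth fields are skipped;
    their descriptions are appended to ``errors`` (and logged) rather than
    aborting the read.  A missing sample name is fatal.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_source))
    samples = list(vcf.samples)
    for name in (tumor_sample_name, normal_sample_name):
        if name not in samples:
            raise FormatError(
                f"sample {name!r} not found in {vcf_source} (has {samples})"
            )
    ti = samples.index(tumor_sample_name)
    ni = samples.index(normal_sample_name)
    collected = errors if errors is not None else []
    calls: list[PairedVariantCall] = []

    for rec in vcf:
        site = f"{rec.CHROM}:{rec.POS}"
        try:
            alleles = [rec.REF] + list(rec.ALT)
            gts = rec.genotypes
            gt_t, gt_n = gts[ti], gts[ni]
            if min(gt_t[0], gt_t[1], gt_n[0], gt_n[1]) < 0:
                raise FormatError("missing genotype")
            ad = rec.format("AD")
            if ad is None:
                raise FormatError("missing AD field")
            qd = rec.INFO.get("QD")
            hrun = rec.INFO.get("HRun")
            fs = rec.INFO.get("FS")
            rprs = rec.INFO.get("ReadPosRankSum")
            qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
            for k, alt in enumerate(rec.ALT):
                ai = k + 1
                if ad.shape[1] <= ai:
                    raise FormatError("AD field shorter than allele list")
                t_ref, t_alt = int(ad[ti][0]), int(ad[ti][ai])
                n_ref, n_alt = int(ad[ni][0]), int(ad[ni][ai])
                if min(t_ref, t_alt, n_ref, n_alt) < 0:
                    raise FormatError("missing AD value")
                calls.append(
                    PairedVariantCall(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        tumor_genotype=(alleles[gt_t[0]], alleles[gt_t[1]]),
                        normal_genotype=(alleles[gt_n[0]], alleles[gt_n[1]]),
                        tumor_ref_reads=t_ref,
                        tumor_alt_reads=t_alt,
                        normal_ref_reads=n_ref,
                        normal_alt_reads=n_alt,
                        call_quality=qual,
                        qd=float(qd) if qd is not None else None,
                        hrun=int(hrun) if hrun is not None else None,
                        fs=float(fs) if fs is not None else None,
                        read_pos_rank_sum=float(rprs) if rprs is not None else None,
                        sample=tumor_sample_name,
                    )
                )
        except (FormatError, ValueError, IndexError) as exc:
            msg = f"{site}: skipped record ({exc})"
            collected.append(msg)
            log.warning(msg)
    return calls


def write_vcf_pairs(
    calls_by_record: Iterable[dict],
    tumor_sample_name: str,
    normal_sample_name: str,
    path: Union[str, Path],
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write VCF 4.2 records with GT:AD for the tumor/normal sample pair.

    Each element of ``calls_by_record`` is a dict with keys chrom, pos, ref,
    alt (list of strings), qual, info (dict), tumor_gt/normal_gt (allele
    index pairs), tumor_ad/normal_ad (per-allele depth lists).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for key, typ in (
            ("QD", "Float"),
            ("HRun", "Integer"),
            ("FS", "Float"),
            ("ReadPosRankSum", "Float"),
        ):
            fh.write(
                f'##INFO=<ID={key},Number=1,Type={typ},Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{tumor_sample_name}\t{normal_sample_name}\n"
        )
        for rec in calls_by_record:
            info_items = [
                f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                for k, v in rec.get("info", {}).items()
                if v is not None
            ]
            info = ";".join(info_items) if info_items else "."
            alt = ",".join(rec["alt"])
            t_gt = "/".join(str(a) for a in rec["tumor_gt"])
            n_gt = "/".join(str(a) for a in rec["normal_gt"])
            t_ad = ",".join(str(d) for d in rec["tumor_ad"])
            n_ad = ",".join(str(d) for d in rec["normal_ad"])
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t.\t{rec['ref']}\t{alt}\t"
                f"{rec['qual']:g}\t.\t{info}\tGT:AD\t{t_gt}:{t_ad}\t{n_gt}:{n_ad}\n"
            )


# ---------------------------------------------------------------------------
# gene models


@dataclass(frozen=True)
class GeneModel:
    """One transcript: exon structure plus CDS bounds, 0-based half-open."""

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if s >= e:
                raise FormatError(f"{self.transcript_id}: empty exon [{s},{e})")
            if s < prev_end:
                raise FormatError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e
        if self.cds_start > self.cds_end:
            raise FormatError(f"{self.transcript_id}: cds_start > cds_end")
        if self.coding and not (
            self.tx_start <= self.cds_start and self.cds_end <= self.tx_end
        ):
            raise FormatError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            cs, ce = max(s, self.cds_start), min(e, self.cds_end)
            if cs < ce:
                out.append((cs, ce))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )


_GENE_MODEL_COLUMNS = [
    "gene",
    "transcript_id",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
    "cds_start",
    "cds_end",
]


def read_gene_models(path: Union[str, Path]) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_GENE_MODEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"gene model table missing columns {sorted(missing)}")
    models = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",") if x]
        ends = [int(x) for x in str(row.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise FormatError(f"{row.transcript_id}: exon_starts/ends length mismatch")
        models.append(
            GeneModel(
                gene=row.gene,
                transcript_id=row.transcript_id,
                chrom=row.chrom,
                strand=row.strand,
                exons=tuple(zip(starts, ends)),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
            )
        )
    return models


def write_gene_models(models: Iterable[GeneModel], path: Union[str, Path]) -> None:
    rows = []
    for m in models:
        rows.append(
            {
                "gene": m.gene,
                "transcript_id": m.transcript_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exon_starts": ",".join(str(s) for s, _ in m.exons),
                "exon_ends": ",".join(str(e) for _, e in m.exons),
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
            }
        )
    pd.DataFrame(rows, columns=_GENE_MODEL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# mutation catalogue


@dataclass(frozen=True)
class CatalogueEntry:
    """One catalogued somatic mutation (COSMIC-style).  pos is 1-based.

    Alleles follow the same rules as variant calls except that either side
    may be empty (written ``-`` on disk) for unanchored indel notation.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    catalogue_id: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise FormatError(f"catalogue entry ref == alt at {self.chrom}:{self.pos}")
        for allele in (self.ref, self.alt):
            if allele and not set(allele) <= _BASES:
                raise FormatError(f"allele {allele!r} outside A/C/G/T")


def read_catalogue(path: Union[str, Path]) -> list[CatalogueEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"chrom", "pos", "ref", "alt"}
    if not needed <= set(df.columns):
        raise FormatError(f"catalogue table must have columns {sorted(needed)}")
    entries = []
    for row in df.itertuples(index=False):
        ref = "" if row.ref in ("-", "") else row.ref
        alt = "" if row.alt in ("-", "") else row.alt
        entries.append(
            CatalogueEntry(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=ref,
                alt=alt,
                gene=getattr(row, "gene", "") or "",
                catalogue_id=getattr(row, "catalogue_id", "") or "",
            )
        )
    return entries


def write_catalogue(entries: Iterable[CatalogueEntry], path: Union[str, Path]) -> None:
    rows = [
        {
            "chrom": e.chrom,
            "pos": e.pos,
            "ref": e.ref or "-",
            "alt": e.alt or "-",
            "gene": e.gene,
            "catalogue_id": e.catalogue_id,
        }
        for e in entries
    ]
    pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "gene", "catalogue_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# segment tracks


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    log2: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"segment {self.chrom}:{self.start}-{self.end} empty")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class SegmentTrack:
    """Ordered piecewise-constant log2-ratio segments, per chromosome."""

    def __init__(self, segments: Iterable[Segment]):
        self.segments = sorted(segments, key=lambda s: (s.chrom, s.start))
        self._starts: dict[str, list[int]] = {}
        self._per_chrom: dict[str, list[Segment]] = {}
        for s in self.segments:
            self._per_chrom.setdefault(s.chrom, []).append(s)
        for chrom, segs in self._per_chrom.items():
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise FormatError(f"overlapping segments on {chrom}: {a} / {b}")
            self._starts[chrom] = [s.start for s in segs]

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    def lookup(self, chrom: str, pos0: int) -> Optional[Segment]:
        """Segment containing a 0-based position, or None."""
        starts = self._starts.get(chrom)
        if not starts:
            return None
        i = bisect_right(starts, pos0) - 1
        if i < 0:
            return None
        seg = self._per_chrom[chrom][i]
        return seg if pos0 < seg.end else None

    def overlapping(self, chrom: str, start: int, end: int) -> list[Segment]:
        segs = self._per_chrom.get(chrom)
        if not segs:
            return []
        starts = self._starts[chrom]
        lo = max(bisect_right(starts, start) - 1, 0)
        out = []
        for s in segs[lo:]:
            if s.start >= end:
                break
            if start < s.end:
                out.append(s)
        return out


def read_segments(path: Union[str, Path]) -> SegmentTrack:
    df = pd.read_csv(path, sep="\t")
    needed = {"chrom", "start", "end", "log2"}
    if not needed <= set(df.columns):
        raise FormatError(f"segment table must have columns {sorted(needed)}")
    return SegmentTrack(
        Segment(str(r.chrom), int(r.start), int(r.end), float(r.log2))
        for r in df.itertuples(index=False)
    )


def write_segments(track: SegmentTrack, path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {"chrom": s.chrom, "start": s.start, "end": s.end, "log2": s.log2}
            for s in track
        ],
        columns=["chrom", "start", "end", "log2"],
    ).to_csv(path, sep="\t", index=False)
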