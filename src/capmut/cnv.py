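"""Copy-number estimation from paired tumor/normal target coverage.

Window log2 ratios are computed after library-size scaling (total-depth
ratio) with an epsilon guard, optionally GC-corrected by subtracting the
median log-ratio per GC decile.  Windows with low normal coverage are
removed, windows are segmented by a simple greedy merge (a deliberately
plain stand-in for a full segmentation algorithm — pre-segmented external
tracks are accepted verbatim as first-class input), and genes are called
amplified (> +2, every exon passing) or homozygously deleted (< -2 on a
segment of at least 400 bp overlapping exonic sequence).  Concordance
between two segmented tracks is the Pearson correlation of the log2 values
paired by segment-midpoint lookup.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GeneModel, Segment, SegmentTrack

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageWindow:
    """One target-derived coverage window (0-based half-open, <= 150 bp)."""

    chrom: str
    start: int
    end: int
    tumor_mean_depth: float
    normal_mean_depth: float
    log2_ratio: Optional[float] = None
    gc: Optional[float] = None

    MAX_SIZE = 150

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"window {self.chrom}:{self.start}-{self.end} empty")
        if self.end - self.start > self.MAX_SIZE:
            raise ValueError(
                f"window {self.chrom}:{self.start}-{self.end} exceeds "
                f"{self.MAX_SIZE} bp"
            )
        if self.tumor_mean_depth < 0 or self.normal_mean_depth < 0:
            raise ValueError("negative depth")

    def __len__(self) -> int:
        return self.end - self.start


def read_windows(path) -> list[CoverageWindow]:
    df = pd.read_csv(path, sep="\t")
    return [
        CoverageWindow(
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            tumor_mean_depth=float(r.tumor_mean_depth),
            normal_mean_depth=float(r.normal_mean_depth),
            log2_ratio=float(r.log2_ratio) if "log2_ratio" in df.columns and not pd.isna(r.log2_ratio) else None,
            gc=float(r.gc) if "gc" in df.columns and not pd.isna(r.gc) else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_windows(windows: Iterable[CoverageWindow], path) -> None:
    pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "tumor_mean_depth": w.tumor_mean_depth,
                "normal_mean_depth": w.normal_mean_depth,
                "log2_ratio": w.log2_ratio,
                "gc": w.gc,
            }
            for w in windows
        ]
    ).to_csv(path, sep="\t", index=False)


def window_log_ratios(
    windows: Sequence[CoverageWindow],
    gc_correct: bool = False,
    epsilon: float = 0.5,
) -> list[CoverageWindow]:
    """Attach log2((tumor+eps)/(normal+eps)) after library-size scaling.

    Library sizes are the summed mean depths per track; tumor depths are
    divided by their ratio so a flat genome centers at log2 = 0.  With
    ``gc_correct`` the median log-ratio per GC decile (windows must carry
    ``gc``) is subtracted.
    """
    if not windows:
        return []
    t_total = sum(w.tumor_mean_depth for w in windows)
    n_total = sum(w.normal_mean_depth for w in windows)
    scale = (t_total / n_total) if n_total > 0 else 1.0
    out = [
        replace(
            w,
            log2_ratio=math.log2(
                (w.tumor_mean_depth / scale + epsilon) / (w.normal_mean_depth + epsilon)
            ),
        )
        for w in windows
    ]
    if gc_correct:
        if any(w.gc is None for w in out):
            raise ValueError("GC correction requires per-window gc values")
        gcs = np.array([w.gc for w in out])
        ratios = np.array([w.log2_ratio for w in out])
        deciles = np.clip((gcs * 10).astype(int), 0, 9)
        for d in np.unique(deciles):
            mask = deciles == d
            ratios[mask] -= np.median(ratios[mask])
        out = [replace(w, log2_ratio=float(r)) for w, r in zip(out, ratios)]
    return out


def filter_low_coverage(
    windows: Sequence[CoverageWindow], min_normal_depth: float = 20.0
) -> list[CoverageWindow]:
    """Drop windows whose matched-normal coverage is below the threshold."""
    kept = [w for w in windows if w.normal_mean_depth >= min_normal_depth]
    removed = len(windows) - len(kept)
    if removed:
        log.info("filtered %d low-coverage windows (normal < %g)", removed, min_normal_depth)
    return kept


def segment(
    windows: Sequence[CoverageWindow],
    merge_tolerance: float = 0.4,
) -> SegmentTrack:
    """Greedy piecewise-constant segmentation of log2 ratios.

    Adjacent windows join a segment while |window log2 - running segment
    mean| <= tolerance; the segment value is the (unweighted) mean of its
    member windows.  Windows must be sorted per chromosome.
    """
    segs: list[Segment] = []
    prev: Optional[CoverageWindow] = None
    members: list[CoverageWindow] = []

    def flush() -> None:
        if members:
            value = float(np.mean([w.log2_ratio for w in members]))
            segs.append(
                Segment(members[0].chrom, members[0].start, members[-1].end, value)
            )

    for w in windows:
        if w.log2_ratio is None:
            raise ValueError("segment() needs windows with log2_ratio computed")
        if prev is not None and (
            w.chrom < prev.chrom or (w.chrom == prev.chrom and w.start < prev.start)
        ):
            raise ValueError("windows must be sorted by (chrom, start)")
        if members and (
            w.chrom != members[-1].chrom
            or abs(w.log2_ratio - float(np.mean([m.log2_ratio for m in members])))
            > merge_tolerance
        ):
            flush()
            members = []
        members.append(w)
        prev = w
    flush()
    return SegmentTrack(segs)


@dataclass(frozen=True)
class CnvThresholds:
    gain_log2: float = 2.0
    deletion_log2: float = -2.0
    min_gene_bp: int = 400
    min_deletion_segment_bp: int = 400


@dataclass(frozen=True)
class GeneCnvCall:
    """Per-gene copy-number estimate and amplification/deletion status."""

    gene: str
    mean_log2: Optional[float]
    status: str  # amplification | homozygous_deletion | neutral | not_evaluable
    segments: tuple[Segment, ...] = ()


def _exon_mean_log2(track: SegmentTrack, chrom: str, exon: tuple[int, int]) -> Optional[float]:
    overlaps = track.overlapping(chrom, *exon)
    if not overlaps:
        return None
    total = value = 0.0
    for seg in overlaps:
        ov = min(seg.end, exon[1]) - max(seg.start, exon[0])
        total += ov
        value += ov * seg.log2
    return value / total


def _deletion_regions(track: SegmentTrack, threshold: float) -> list[tuple[str, int, int]]:
    """Maximal runs of consecutive below-threshold segments, per chromosome.

    Deep deletions fragment into several short segments when the residual
    depth is low (Poisson noise at a handful of reads exceeds the merge
    tolerance); the deletion rule evaluates the spanned region, so
    consecutive pass-threshold segments are coalesced.  A segment at or
    above the threshold breaks the run.
    """
    runs: list[tuple[str, int, int]] = []
    cur: Optional[list] = None
    for seg in track:
        if seg.log2 < threshold:
            if cur is not None and cur[0] == seg.chrom:
                cur[2] = seg.end
            else:
                if cur is not None:
                    runs.append(tuple(cur))
                cur = [seg.chrom, seg.start, seg.end]
        else:
            if cur is not None:
                runs.append(tuple(cur))
                cur = None
    if cur is not None:
        runs.append(tuple(cur))
    return runs


def gene_calls(
    track: SegmentTrack,
    gene_models: Iterable[GeneModel],
    thresholds: CnvThresholds = CnvThresholds(),
) -> list[GeneCnvCall]:
    """Gene-level calls from a segmented track.

    The gene estimate is the overlap-length-weighted mean log2 over the
    segments covering its exons (genes whose summed exon length is at most
    400 bp are not evaluable).  Amplification requires *every* exon mean to
    exceed the gain threshold; homozygous deletion requires a
    below-threshold region (a maximal run of pass-threshold segments) of at
    least 400 bp overlapping at least one exonic base.  Thresholds are
    strict inequalities.
    """
    del_regions = _deletion_regions(track, thresholds.deletion_log2)
    calls = []
    for m in gene_models:
        if m.exonic_length <= thresholds.min_gene_bp:
            calls.append(GeneCnvCall(m.gene, None, "not_evaluable"))
            continue
        covering: list[Segment] = []
        total = value = 0.0
        exon_means = []
        for exon in m.exons:
            overlaps = track.overlapping(m.chrom, *exon)
            for seg in overlaps:
                ov = min(seg.end, exon[1]) - max(seg.start, exon[0])
                total += ov
                value += ov * seg.log2
                if seg not in covering:
                    covering.append(seg)
            exon_means.append(_exon_mean_log2(track, m.chrom, exon))
        if total == 0:
            calls.append(GeneCnvCall(m.gene, None, "not_evaluable"))
            continue
        mean_log2 = value / total

        amplified = all(
            em is not None and em > thresholds.gain_log2 for em in exon_means
        )
        deleted = any(
            chrom == m.chrom
            and (end - start) >= thresholds.min_deletion_segment_bp
            and any(start < xe and xs < end for xs, xe in m.exons)
            for chrom, start, end in del_regions
        )
        if deleted:
            status = "homozygous_deletion"
        elif amplified:
            status = "amplification"
        else:
            status = "neutral"
        calls.append(GeneCnvCall(m.gene, mean_log2, status, tuple(covering)))
    return calls


@dataclass(frozen=True)
class ConcordanceResult:
    r: Optional[float]
    p: Optional[float]
    n: int
    n_dropped: int
    pairs: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.r is not None


def concordance(track_a: SegmentTrack, track_b: SegmentTrack) -> ConcordanceResult:
    """Pearson correlation between two segmented tracks.

    Each segment of ``track_a`` contributes its genomic midpoint; the
    ``track_b`` segment containing that midpoint provides the partner
    value.  Midpoints not covered by ``track_b`` are dropped and counted.
    Fewer than 3 pairs leaves r undefined (flagged, not an error).
    """
    rows, dropped = [], 0
    for seg in track_a:
        partner = track_b.lookup(seg.chrom, seg.midpoint)
        if partner is None:
            dropped += 1
            continue
        rows.append(
            {
                "chrom": seg.chrom,
                "midpoint": seg.midpoint,
                "log2_a": seg.log2,
                "log2_b": partner.log2,
            }
        )
    pairs = pd.DataFrame(rows, columns=["chrom", "midpoint", "log2_a", "log2_b"])
    if len(pairs) < 3:
        return ConcordanceResult(None, None, len(pairs), dropped, pairs)
    a, b = pairs["log2_a"].to_numpy(), pairs["log2_b"].to_numpy()
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):  # zero variance
        return ConcordanceResult(None, None, len(pairs), dropped, pairs)
    r, p = stats.pearsonr(a, b)
    return ConcordanceResult(float(r), float(p), len(pairs), dropped, pairs)


def gene_calls_to_frame(calls: Sequence[GeneCnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"gene": c.gene, "mean_log2": c.mean_log2, "status": c.status}
            for c in calls
        ],
        columns=["gene", "mean_log2", "status"],
    )
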