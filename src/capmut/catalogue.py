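"""Matching called variants against a COSMIC-style mutation catalogue.

Exact matching compares canonical representations: alleles are trimmed of
their common prefix/suffix and indels are left-aligned against the
reference, so that equivalent spellings of the same event (anchored VCF
style, unanchored ``CT>-`` style, or shifted within a repeat) compare
equal.  Loose matching additionally accepts small positional shifts
(representation-equivalent inside homopolymers/tandem repeats, or
"positional-only" otherwise) and multi-nucleotide substitutions that the
caller reported as separate adjacent SNVs.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .formats import CatalogueEntry, PairedVariantCall, ReferenceGenome


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Optional[ReferenceGenome] = None,
) -> tuple[str, int, str, str]:
    """Canonical (chrom, 1-based pos, ref, alt) representation.

    Common suffix then prefix are trimmed (alleles may become empty, the
    position pointing at the first changed/deleted base or the base after
    which an insertion occurs); pure indels are then left-aligned against
    the reference when one is supplied.
    """
    pos0 = pos - 1
    r, a = ref, alt
    while r and a and r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos0 += 1
    if reference is not None and bool(r) != bool(a):
        u = r or a
        while pos0 > 0:
            prev = reference.fetch(chrom, pos0 - 1, pos0)
            if prev == u[-1]:
                u = prev + u[:-1]
                pos0 -= 1
            else:
                break
        if r:
            r = u
        else:
            a = u
    return chrom, pos0 + 1, r, a


def equivalent_positions(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: ReferenceGenome,
    max_shift: int = 50,
) -> set[int]:
    """1-based positions at which an indel has a representation-equivalent
    spelling (sliding through a homopolymer or tandem repeat).  For
    non-indels the set is just {pos}."""
    chrom, p, r, a = normalize_variant(chrom, pos, ref, alt, reference)
    if bool(r) == bool(a):
        return {pos}
    out = {p}
    u = r or a
    pos0 = p - 1
    limit = reference.length(chrom)
    for _ in range(max_shift):  # right shifts from the left-aligned form
        if r:  # deletion of u at pos0
            if pos0 + len(u) >= limit:
                break
            if reference.fetch(chrom, pos0, pos0 + 1) != reference.fetch(
                chrom, pos0 + len(u), pos0 + len(u) + 1
            ):
                break
            u = u[1:] + reference.fetch(chrom, pos0 + len(u), pos0 + len(u) + 1)
            pos0 += 1
        else:  # insertion of u before pos0
            if pos0 >= limit:
                break
            nxt_base = reference.fetch(chrom, pos0, pos0 + 1)
            if u[0] != nxt_base:
                break
            u = u[1:] + u[0]
            pos0 += 1
        out.add(pos0 + 1)
    return out


@dataclass(frozen=True)
class MatchResult:
    entry: CatalogueEntry
    kind: str  # exact | shifted | split_mnv
    repeat_supported: bool = True  # False => positional-only shifted match

    @property
    def status(self) -> str:
        if self.kind == "exact":
            return "exact"
        return "loose_split" if self.kind == "split_mnv" else "loose_shifted"


def _variant_tuple(variant) -> tuple[str, int, str, str]:
    if isinstance(variant, PairedVariantCall):
        return variant.chrom, variant.pos, variant.ref, variant.alt
    if isinstance(variant, CatalogueEntry):
        return variant.chrom, variant.pos, variant.ref, variant.alt
    return tuple(variant)  # type: ignore[return-value]


class Catalogue:
    """Indexed mutation catalogue supporting exact and loose lookup."""

    def __init__(
        self,
        entries: Iterable[CatalogueEntry],
        reference: Optional[ReferenceGenome] = None,
    ):
        self.reference = reference
        self.entries = list(entries)
        self._exact: dict[tuple[str, int, str, str], CatalogueEntry] = {}
        self._by_chrom: dict[str, list[tuple[int, str, str, CatalogueEntry]]] = {}
        for e in self.entries:
            key = normalize_variant(e.chrom, e.pos, e.ref, e.alt, reference)
            self._exact.setdefault(key, e)
            _, p, r, a = key
            self._by_chrom.setdefault(e.chrom, []).append((p, r, a, e))
        for lst in self._by_chrom.values():
            lst.sort(key=lambda t: t[0])

    def match_exact(self, variant) -> Optional[CatalogueEntry]:
        chrom, pos, ref, alt = _variant_tuple(variant)
        key = normalize_variant(chrom, pos, ref, alt, self.reference)
        return self._exact.get(key)

    def match_loose(
        self,
        variant,
        window: int = 5,
        companions: Optional[set[tuple[str, int, str, str]]] = None,
    ) -> Optional[MatchResult]:
        """Exact, shifted (|Δpos| < window), or split-MNV match.

        ``companions`` is the normalized set of all calls of the sample and
        enables reconstruction of a catalogue MNV from its constituent
        adjacent SNVs.  Every exact match is also a loose match.
        """
        chrom, pos, ref, alt = _variant_tuple(variant)
        exact = self.match_exact(variant)
        if exact is not None:
            return MatchResult(exact, "exact")
        _, npos, nref, nalt = normalize_variant(chrom, pos, ref, alt, self.reference)

        # shifted: same alleles within the window
        near = self._near(chrom, npos, window)
        best: Optional[MatchResult] = None
        for p, r, a, e in near:
            if (r, a) != (nref, nalt) or p == npos or abs(p - npos) >= window:
                continue
            supported = False
            if self.reference is not None and bool(r) != bool(a):
                supported = p in equivalent_positions(
                    chrom, pos, ref, alt, self.reference
                )
            cand = MatchResult(e, "shifted", repeat_supported=supported)
            if best is None or (cand.repeat_supported and not best.repeat_supported):
                best = cand
        if best is not None:
            return best

        # split MNV: a catalogue MNV jointly reconstructed by adjacent SNVs
        if len(nref) == 1 == len(nalt) and companions is not None:
            for p, r, a, e in self._near(chrom, npos, window + 10):
                if len(r) < 2 or len(r) != len(a):
                    continue
                if not (p <= npos < p + len(r)):
                    continue
                pieces = [
                    (chrom, p + j, r[j], a[j])
                    for j in range(len(r))
                    if r[j] != a[j]
                ]
                if (chrom, npos, nref, nalt) not in pieces:
                    continue
                if all(piece in companions for piece in pieces):
                    return MatchResult(e, "split_mnv")
        return None

    def _near(self, chrom: str, pos: int, window: int):
        lst = self._by_chrom.get(chrom, [])
        keys = [t[0] for t in lst]
        lo = bisect_left(keys, pos - window)
        hi = bisect_right(keys, pos + window)
        return lst[lo:hi]


def flag_novel(
    variants: Sequence,
    catalogue: Catalogue,
    window: int = 5,
) -> pd.DataFrame:
    """Annotate each variant as exact / loose_shifted / loose_split / novel.

    Returns a DataFrame aligned with the input order, with columns
    match_status, catalogue_id, repeat_supported.  The loose matcher sees
    the full call set so split substitutions can be reconstructed.
    """
    companions = {
        normalize_variant(*_variant_tuple(v), catalogue.reference) for v in variants
    }
    rows = []
    for v in variants:
        m = catalogue.match_loose(v, window=window, companions=companions)
        if m is None:
            rows.append(
                {"match_status": "novel", "catalogue_id": "", "repeat_supported": None}
            )
        else:
            rows.append(
                {
                    "match_status": m.status,
                    "catalogue_id": m.entry.catalogue_id,
                    "repeat_supported": m.repeat_supported,
                }
            )
    return pd.DataFrame(rows)


def detection_counts(flags: pd.DataFrame) -> dict[str, int]:
    """Bookkeeping: known_exact + known_loose_only + novel = total."""
    status = flags["match_status"]
    return {
        "known_exact": int((status == "exact").sum()),
        "known_loose_only": int(status.isin(["loose_shifted", "loose_split"]).sum()),
        "novel": int((status == "novel").sum()),
        "total": len(flags),
    }
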