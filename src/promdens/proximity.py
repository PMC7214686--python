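"""Strand-aware distance geometry between peaks and TSS.

All of the downstream analysis rests on one measurement: the signed
distance from a peak *center* to a transcription start site, oriented by
the gene.  Negative distances are upstream of the TSS (5' of the gene),
positive distances downstream.  Distances are always center-to-point,
never edge-to-point.

Nearest-neighbor queries use per-chromosome sorted coordinate arrays with
binary search; they are contractually equivalent to a brute-force linear
scan, including tie handling.

Tie-breaking at equal ``|distance|`` is deterministic:

* ``nearest_peak`` (subject = peak): prefer the upstream peak (negative
  signed distance), then the smaller peak-center coordinate, then the
  lexicographically smaller peak name.
* ``nearest_tss`` (subject = TSS): prefer the smaller TSS coordinate,
  then the lexicographically smaller transcript id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome_io import GenomicInterval, PeakSet, TssRecord

DEFAULT_WINDOW = 2000


@dataclass(frozen=True, slots=True)
class NearestHit:
    """Result of a nearest-neighbor query.

    ``distance`` is signed in gene orientation (negative = upstream of the
    TSS).  ``overlap_flag`` is true when the query point lies inside the
    subject interval (or, for TSS queries, when the TSS position lies
    inside the hit peak).  ``subject`` carries the matched record itself
    for downstream overlap logic.
    """

    query_id: str
    subject_id: str
    distance: int
    overlap_flag: bool
    subject: object = None


def peak_center(interval: GenomicInterval) -> int:
    """Center of a peak interval: ``floor((start + end) / 2)``.

    Always lies inside ``[start, end)`` for a non-empty interval.
    """
    return (interval.start + interval.end) // 2


def signed_distance(point: int, tss: TssRecord, chrom: str | None = None) -> int:
    """Signed bp distance of ``point`` from a TSS, in gene orientation.

    Plus strand: ``point - position``; minus strand: ``position - point``.
    Negative means the point is upstream (5') of the gene.
    """
    if chrom is not None and chrom != tss.chrom:
        raise ValueError(
            f"cross-chromosome distance: point on {chrom!r}, TSS on {tss.chrom!r}")
    if tss.strand == "+":
        return point - tss.position
    return tss.position - point


class TssIndex:
    """Per-chromosome sorted arrays of TSS positions for windowed queries."""

    def __init__(self, records: Iterable[TssRecord]):
        by_chrom: dict[str, list[TssRecord]] = {}
        for rec in records:
            by_chrom.setdefault(rec.chrom, []).append(rec)
        self._records: dict[str, list[TssRecord]] = {}
        self._positions: dict[str, np.ndarray] = {}
        self.n = 0
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda r: (r.position, r.transcript_id))
            self._records[chrom] = recs
            self._positions[chrom] = np.array([r.position for r in recs], dtype=np.int64)
            self.n += len(recs)

    def chroms(self) -> set[str]:
        return set(self._records)

    def records(self, chrom: str) -> list[TssRecord]:
        return self._records.get(chrom, [])

    def records_all(self) -> Iterable[TssRecord]:
        for recs in self._records.values():
            yield from recs

    def nearest(self, center: int, chrom: str, window: int) -> NearestHit | None:
        positions = self._positions.get(chrom)
        if positions is None or len(positions) == 0:
            return None
        lo = int(np.searchsorted(positions, center - window, side="left"))
        hi = int(np.searchsorted(positions, center + window, side="right"))
        if lo >= hi:
            return None
        cands = self._records[chrom][lo:hi]
        dists = np.abs(positions[lo:hi] - center)
        best = int(dists.min())
        if best > window:
            return None
        # ties resolved by smaller TSS coordinate, then transcript_id
        # (candidate lists are pre-sorted exactly that way)
        idx = int(np.argmax(dists == best))
        rec = cands[idx]
        return NearestHit(
            query_id="", subject_id=rec.transcript_id,
            distance=signed_distance(center, rec),
            overlap_flag=(center == rec.position), subject=rec)


class PeakIndex:
    """Per-chromosome sorted peak-center arrays for windowed TSS queries."""

    def __init__(self, peaks: PeakSet | Iterable[GenomicInterval]):
        intervals = peaks.intervals if isinstance(peaks, PeakSet) else tuple(peaks)
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        self._intervals: dict[str, list[GenomicInterval]] = {}
        self._centers: dict[str, np.ndarray] = {}
        self.n = 0
        for chrom, ivs in by_chrom.items():
            ivs.sort(key=lambda iv: (peak_center(iv), iv.name))
            self._intervals[chrom] = ivs
            self._centers[chrom] = np.array([peak_center(iv) for iv in ivs],
                                            dtype=np.int64)
            self.n += len(ivs)

    def chroms(self) -> set[str]:
        return set(self._intervals)

    def nearest(self, tss: TssRecord, window: int) -> NearestHit | None:
        centers = self._centers.get(tss.chrom)
        if centers is None or len(centers) == 0:
            return None
        pos = tss.position
        lo = int(np.searchsorted(centers, pos - window, side="left"))
        hi = int(np.searchsorted(centers, pos + window, side="right"))
        if lo >= hi:
            return None
        cands = self._intervals[tss.chrom][lo:hi]
        dists = np.abs(centers[lo:hi] - pos)
        best = int(dists.min())
        if best > window:
            return None
        tied = np.flatnonzero(dists == best)
        if len(tied) == 1:
            iv = cands[int(tied[0])]
        else:
            # prefer the upstream peak (negative signed distance), then the
            # smaller center coordinate, then lexicographic name
            iv = min((cands[int(i)] for i in tied),
                     key=lambda c: (signed_distance(peak_center(c), tss),
                                    peak_center(c), c.name))
        return NearestHit(
            query_id=tss.transcript_id, subject_id=iv.name,
            distance=signed_distance(peak_center(iv), tss),
            overlap_flag=(iv.start <= pos < iv.end), subject=iv)


def nearest_tss(center: int, chrom: str, tss_index: TssIndex | Sequence[TssRecord],
                window: int = DEFAULT_WINDOW, query_id: str = "") -> NearestHit | None:
    """Nearest TSS to a peak center, or ``None`` if none within ``window``."""
    index = tss_index if isinstance(tss_index, TssIndex) else TssIndex(tss_index)
    hit = index.nearest(center, chrom, window)
    if hit is None:
        return None
    return NearestHit(query_id=query_id, subject_id=hit.subject_id,
                      distance=hit.distance, overlap_flag=hit.overlap_flag,
                      subject=hit.subject)


def nearest_peak(tss: TssRecord, peaks: PeakIndex | PeakSet,
                 window: int = DEFAULT_WINDOW) -> NearestHit | None:
    """Nearest peak (by center) to a TSS, or ``None`` if none within ``window``.

    ``overlap_flag`` is true iff the TSS position lies inside the hit
    peak's interval.
    """
    index = peaks if isinstance(peaks, PeakIndex) else PeakIndex(peaks)
    return index.nearest(tss, window)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the intervals share >= 1 bp (half-open semantics)."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end
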