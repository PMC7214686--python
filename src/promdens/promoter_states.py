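"""Promoter-state classification from histone-mark peak geometry.

A bivalent ("poised") promoter carries both H3K4me3 and H3K27me3; an
epigenetically active promoter carries H3K4me3 without H3K27me3.  Two
classification rules are implemented, both operating purely on peak
intervals:

* ``by_k4me3``: a TSS is poised iff its nearest H3K4me3 peak overlaps
  (>= 1 bp) some H3K27me3 peak; active iff a nearest H3K4me3 exists
  within the window but is not poised; ``other`` otherwise.
* ``by_k4me1``: a TSS is poised iff its nearest H3K4me1 peak overlaps a
  poised H3K4me3 peak; active iff it is not poised AND the nearest
  H3K4me3 center lies within ``active_radius`` (500 bp) of the TSS;
  ``other`` otherwise.  Poised takes precedence: a TSS cannot be both.

"Within 500 bp" is interpreted center-to-TSS, consistent with every
other distance in the pipeline; an edge-based variant is available via
``active_criterion="edge"``.

Expression bins partition TPM at 1, 5 and 10 with inclusive upper
boundaries: B1 = tpm <= 1, B2 = 1 < tpm <= 5, B3 = 5 < tpm <= 10,
B4 = tpm > 10.  Unquantified TSS (tpm=None) get no bin and are excluded
from expression-stratified analyses but retained in state calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome_io import GenomicInterval, PeakSet, TssRecord
from .proximity import (DEFAULT_WINDOW, NearestHit, PeakIndex, overlaps,
                        peak_center, signed_distance)

EXPRESSION_BINS = ("B1", "B2", "B3", "B4")
_BIN_EDGES = (1.0, 5.0, 10.0)

STATES = ("poised", "active", "other")


@dataclass(frozen=True, slots=True)
class PromoterStateCall:
    """Per-TSS state label plus the nearest-peak distances behind it."""

    tss_id: str
    state: str
    rule: str
    d_k4me1: int | None = None
    d_k4me3: int | None = None
    tpm: float | None = None
    expression_bin: str | None = None


@dataclass
class JointDistanceMap:
    """2D bin counts of (nearest-H3K4me1, nearest-H3K4me3) distance per TSS.

    Only TSS with both marks within the window contribute, so
    ``counts.sum() == n_tss`` always.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_tss: int


# ---------------------------------------------------------------------------
# poised-region lists (bedtools -wa semantics)


def _build_tree(peaks: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return trees


def _overlapping_subset(query: PeakSet, subject: PeakSet) -> tuple[GenomicInterval, ...]:
    trees = _build_tree(subject)
    kept = []
    for iv in query:
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlap(iv.start, iv.end):
            kept.append(iv)
    return tuple(kept)


def poised_peaks(k4me3: PeakSet, k27me3: PeakSet) -> PeakSet:
    """H3K4me3 peaks overlapping (>= 1 bp) any H3K27me3 peak.

    Each qualifying H3K4me3 interval is reported once with its original
    coordinates, regardless of how many H3K27me3 peaks it touches
    (``bedtools intersect -wa`` + dedup semantics).
    """
    return PeakSet(mark="H3K4me3", intervals=_overlapping_subset(k4me3, k27me3),
                   source=f"poised({k4me3.source})")


def poised_k4me1(k4me1: PeakSet, poised: PeakSet) -> PeakSet:
    """H3K4me1 peaks overlapping any poised H3K4me3 peak (-wa semantics)."""
    return PeakSet(mark="H3K4me1", intervals=_overlapping_subset(k4me1, poised),
                   source=f"poised_k4me1({k4me1.source})")


# ---------------------------------------------------------------------------
# classification rules


def classify_by_k4me3(
    tss_records: Sequence[TssRecord],
    k4me3: PeakSet,
    k27me3: PeakSet,
    window: int = DEFAULT_WINDOW,
    k4me1: PeakSet | None = None,
) -> list[PromoterStateCall]:
    """Classify each TSS by whether its nearest H3K4me3 peak is bivalent.

    ``k4me1`` may be supplied purely to annotate calls with the nearest
    H3K4me1 distance (used for stratified distance maps); it plays no
    part in the state decision under this rule.
    """
    poised_names = {(iv.chrom, iv.start, iv.end) for iv in poised_peaks(k4me3, k27me3)}
    k4me3_index = PeakIndex(k4me3)
    k4me1_index = PeakIndex(k4me1) if k4me1 is not None else None
    calls = []
    for tss in tss_records:
        hit3 = k4me3_index.nearest(tss, window)
        hit1 = k4me1_index.nearest(tss, window) if k4me1_index is not None else None
        if hit3 is None:
            state = "other"
        else:
            iv = hit3.subject
            state = "poised" if (iv.chrom, iv.start, iv.end) in poised_names else "active"
        calls.append(PromoterStateCall(
            tss_id=tss.transcript_id, state=state, rule="by_k4me3",
            d_k4me1=None if hit1 is None else hit1.distance,
            d_k4me3=None if hit3 is None else hit3.distance,
            tpm=tss.tpm,
            expression_bin=None if tss.tpm is None else assign_expression_bin(tss.tpm)))
    return calls


def classify_by_k4me1(
    tss_records: Sequence[TssRecord],
    k4me1: PeakSet,
    k4me3: PeakSet,
    k27me3: PeakSet,
    active_radius: int = 500,
    window: int = DEFAULT_WINDOW,
    active_criterion: str = "center",
) -> list[PromoterStateCall]:
    """Classify each TSS by its nearest H3K4me1 peak's poised-region overlap.

    Poised: the nearest H3K4me1 peak (within ``window``) overlaps a poised
    H3K4me3 peak.  Active: not poised, and the nearest H3K4me3 lies within
    ``active_radius`` of the TSS (center-to-TSS by default; interval edge
    if ``active_criterion="edge"``).  Everything else: ``other``.
    """
    if active_criterion not in ("center", "edge"):
        raise ValueError(f"active_criterion must be 'center' or 'edge', got {active_criterion!r}")
    poised = poised_peaks(k4me3, k27me3)
    poised_trees = _build_tree(poised)
    k4me1_index = PeakIndex(k4me1)
    k4me3_index = PeakIndex(k4me3)
    calls = []
    for tss in tss_records:
        hit1 = k4me1_index.nearest(tss, window)
        hit3 = k4me3_index.nearest(tss, window)
        is_poised = False
        if hit1 is not None:
            iv = hit1.subject
            tree = poised_trees.get(iv.chrom)
            is_poised = tree is not None and bool(tree.overlap(iv.start, iv.end))
        if is_poised:
            state = "poised"
        elif hit3 is not None and _within_radius(hit3, tss, active_radius, active_criterion):
            state = "active"
        else:
            state = "other"
        calls.append(PromoterStateCall(
            tss_id=tss.transcript_id, state=state, rule="by_k4me1",
            d_k4me1=None if hit1 is None else hit1.distance,
            d_k4me3=None if hit3 is None else hit3.distance,
            tpm=tss.tpm,
            expression_bin=None if tss.tpm is None else assign_expression_bin(tss.tpm)))
    return calls


def _within_radius(hit: NearestHit, tss: TssRecord, radius: int, criterion: str) -> bool:
    if criterion == "center":
        return abs(hit.distance) <= radius
    iv = hit.subject
    edge_gap = 0 if iv.start <= tss.position < iv.end else \
        min(abs(tss.position - iv.start), abs(tss.position - (iv.end - 1)))
    return edge_gap <= radius


# ---------------------------------------------------------------------------
# expression binning


def assign_expression_bin(tpm: float, edges: Sequence[float] = _BIN_EDGES) -> str:
    """Four-way TPM bin with inclusive upper boundaries.

    B1: tpm <= 1; B2: 1 < tpm <= 5; B3: 5 < tpm <= 10; B4: tpm > 10.
    Silent promoters (tpm = 0) fall in B1; there is no fifth bin.
    Custom ``edges`` produce bins B1..B(len(edges)+1) with the same
    lower-bin-inclusive convention.
    """
    if tpm < 0:
        raise ValueError(f"tpm must be >= 0, got {tpm}")
    for k, edge in enumerate(edges):
        if tpm <= edge:
            return f"B{k + 1}"
    return f"B{len(edges) + 1}"


# ---------------------------------------------------------------------------
# joint distance map & grouped distances


def joint_distance_map(
    tss_records: Sequence[TssRecord],
    k4me1: PeakSet,
    k4me3: PeakSet,
    window: int = DEFAULT_WINDOW,
    nbins: int = 30,
) -> JointDistanceMap:
    """2D bin counts of per-TSS (d_k4me1, d_k4me3) over [-window, window].

    Only TSS with both nearest-mark hits inside the window contribute;
    ``counts`` conserves that TSS count exactly.
    """
    if nbins < 2:
        raise ValueError("nbins must be >= 2")
    k4me1_index = PeakIndex(k4me1)
    k4me3_index = PeakIndex(k4me3)
    xs, ys = [], []
    for tss in tss_records:
        h1 = k4me1_index.nearest(tss, window)
        h3 = k4me3_index.nearest(tss, window)
        if h1 is not None and h3 is not None:
            xs.append(h1.distance)
            ys.append(h3.distance)
    edges = np.linspace(-window, window, nbins + 1)
    counts, x_edges, y_edges = np.histogram2d(xs, ys, bins=(edges, edges))
    return JointDistanceMap(x_edges=x_edges, y_edges=y_edges,
                            counts=counts.astype(int), n_tss=len(xs))


@dataclass(frozen=True)
class GroupDistances:
    """Distance vectors for one (state, expression-bin) group."""

    state: str | None
    expression_bin: str
    signed: tuple[int, ...]
    absolute: tuple[int, ...]


def distance_by_group(
    calls: Sequence[PromoterStateCall],
    grouping: str = "expression_bin",
    distance: str = "d_k4me1",
) -> list[GroupDistances]:
    """Group nearest-peak distances by expression bin (and optionally state).

    ``grouping`` is ``"expression_bin"`` (four groups) or
    ``"state_x_expression_bin"`` (poised/active x four bins; ``other``
    calls are dropped).  Groups with zero members are emitted empty, not
    dropped.  Calls lacking a bin or the requested distance are skipped.
    """
    if grouping not in ("expression_bin", "state_x_expression_bin"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if distance not in ("d_k4me1", "d_k4me3"):
        raise ValueError(f"unknown distance field {distance!r}")
    states: tuple[str | None, ...]
    states = ("poised", "active") if grouping == "state_x_expression_bin" else (None,)
    buckets: dict[tuple[str | None, str], list[int]] = {
        (s, b): [] for s in states for b in EXPRESSION_BINS}
    for call in calls:
        d = getattr(call, distance)
        if d is None or call.expression_bin is None:
            continue
        key = (call.state if states != (None,) else None, call.expression_bin)
        if key in buckets:
            buckets[key].append(d)
    return [
        GroupDistances(state=s, expression_bin=b,
                       signed=tuple(v), absolute=tuple(abs(x) for x in v))
        for (s, b), v in buckets.items()
    ]
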