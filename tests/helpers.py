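"""Independent brute-force oracles and random-instance builders for tests.

The nearest-neighbor oracles are deliberate O(n*m) linear scans written
against the documented tie-break contract, independent of the indexed
implementations they check.
"""

from __future__ import annotations

import numpy as np

from promdens import GenomicInterval, TssRecord, peak_center, signed_distance


def brute_nearest_tss(center: int, chrom: str, records, window: int):
    """Linear scan: min |center - position|; ties -> smaller position, then id."""
    best_key, best = None, None
    for rec in records:
        if rec.chrom != chrom:
            continue
        d = abs(center - rec.position)
        if d > window:
            continue
        key = (d, rec.position, rec.transcript_id)
        if best_key is None or key < best_key:
            best_key, best = key, rec
    if best is None:
        return None
    return best, signed_distance(center, best)


def brute_nearest_peak(tss: TssRecord, intervals, window: int):
    """Linear scan: min |d|; ties -> upstream (negative d), center, name."""
    best_key, best = None, None
    for iv in intervals:
        if iv.chrom != tss.chrom:
            continue
        c = peak_center(iv)
        d = signed_distance(c, tss)
        if abs(d) > window:
            continue
        key = (abs(d), d, c, iv.name)
        if best_key is None or key < best_key:
            best_key, best = key, (iv, d)
    return best


def random_instance(rng: np.random.Generator, max_peaks=1000, max_tss=1000,
                    span=20_000, chroms=("chrA", "chrB")):
    """A random peak/TSS configuration; a small span makes ties common."""
    n_peaks = int(rng.integers(1, max_peaks + 1))
    n_tss = int(rng.integers(1, max_tss + 1))
    peaks = []
    for i in range(n_peaks):
        start = int(rng.integers(0, span))
        peaks.append(GenomicInterval(
            chrom=str(rng.choice(chroms)), start=start,
            end=start + int(rng.integers(1, 500)), name=f"p{i:04d}"))
    tss = []
    for i in range(n_tss):
        tss.append(TssRecord(
            chrom=str(rng.choice(chroms)), position=int(rng.integers(0, span)),
            strand=str(rng.choice(["+", "-"])), transcript_id=f"t{i:04d}"))
    window = int(rng.integers(100, 3000))
    return peaks, tss, window
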