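"""Seeded generator of synthetic chromatin landscapes with known truth.

The simulator lays out genes on one linear chromosome (``chrS``) at a
fixed intergenic spacing and places histone-mark peaks according to the
promoter state it assigns:

* **active** promoters get one H3K4me3 peak just downstream of the TSS,
  two H3K4me1 peaks displaced 300-1000 bp on either side (the "cleared",
  bimodal configuration), one H3K27ac peak near the TSS, and no
  H3K27me3;
* **poised** (bivalent) promoters get overlapping H3K4me3 and H3K27me3
  peaks (overlap >= 1 bp enforced by construction) and a single
  TSS-centered H3K4me1 peak;
* **silent** promoters get no peaks at all.

Background H3K4me1 peaks — distal, enhancer-like — are scattered
uniformly at least 2 kb from every TSS.  TPM values are drawn from
state-dependent distributions that overlap between states, so expression
alone cannot separate poised from active promoters and discordant cases
(highly expressed poised genes, weakly expressed active genes) exist.

All draws come from per-component substreams of one master seed in a
fixed order, so identical configs produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .genome_io import (GenomicInterval, PeakSet, TssRecord,
                        write_intervals, write_tss_bed6)

CHROM = "chrS"

_DEFAULT_WIDTHS = {
    "H3K4me1": (400, 800),
    "H3K4me3": (500, 900),
    "H3K27me3": (800, 2000),
    "H3K27ac": (300, 700),
}

# substream indices: fixed so adding a mark never perturbs earlier draws
_STREAMS = {"states": 0, "H3K4me3": 1, "H3K4me1": 2, "H3K27me3": 3,
            "H3K27ac": 4, "background": 5, "tpm": 6}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic landscape.

    Distances are bp.  ``k4me3_offset_mean``/``sd`` describe the
    gene-oriented displacement of the H3K4me3 peak center from the TSS;
    ``flank_offset_range`` bounds the uniform displacement of the two
    H3K4me1 flank peaks at active promoters; ``poised_k4me1_sd`` is the
    spread of the single TSS-centered H3K4me1 peak at poised promoters.
    """

    n_genes: int = 2000
    intergenic_spacing: int = 10_000
    fraction_poised: float = 0.3
    fraction_silent: float = 0.1
    flank_offset_range: tuple[int, int] = (300, 1000)
    poised_k4me1_sd: float = 100.0
    k4me3_offset_mean: float = 100.0
    k4me3_offset_sd: float = 50.0
    k27ac_offset_sd: float = 50.0
    peak_width_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_WIDTHS))
    n_background_k4me1: int = 1000
    background_min_tss_distance: int = 2000
    active_tpm_mu: float = 2.0
    active_tpm_sigma: float = 1.0
    poised_zero_fraction: float = 0.7
    poised_tpm_mu: float = 0.5
    poised_tpm_sigma: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_poised <= 1 and 0 <= self.fraction_silent <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.fraction_poised + self.fraction_silent > 1:
            raise ValueError("fraction_poised + fraction_silent must be <= 1")
        lo, hi = self.flank_offset_range
        if not (0 < lo <= hi):
            raise ValueError("flank_offset_range must be positive and ordered")
        for mark, (wlo, whi) in self.peak_width_ranges.items():
            if not (0 < wlo <= whi):
                raise ValueError(f"width range for {mark} must be positive and ordered")
        max_offset = max(hi, abs(self.k4me3_offset_mean))
        max_width = max(w for _, w in self.peak_width_ranges.values())
        if self.intergenic_spacing <= 2 * (max_offset + max_width):
            raise ValueError(
                "intergenic_spacing must exceed 2*(max offset + max width) "
                f"= {2 * (max_offset + max_width)} so neighboring genes cannot interfere")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "flank_offset_range" in data:
            data["flank_offset_range"] = tuple(data["flank_offset_range"])
        if "peak_width_ranges" in data:
            data["peak_width_ranges"] = {
                k: tuple(v) for k, v in data["peak_width_ranges"].items()}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["flank_offset_range"] = list(self.flank_offset_range)
        data["peak_width_ranges"] = {k: list(v) for k, v in self.peak_width_ranges.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one promoter: state, expression, placed peaks."""

    tss_id: str
    true_state: str  # active | poised | silent
    tpm: float
    peak_ids: tuple[str, ...]


@dataclass
class Landscape:
    """In-memory simulated landscape: peaks, TSS, expression and truth."""

    config: SimulationConfig
    peaks: dict[str, PeakSet]
    tss: list[TssRecord]
    tpm: dict[str, float]
    truth: list[SyntheticTruth]

    def truth_by_id(self) -> dict[str, SyntheticTruth]:
        return {t.tss_id: t for t in self.truth}


def _rng(config: SimulationConfig, component: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[component]])


def _draw_width(rng: np.random.Generator, config: SimulationConfig, mark: str) -> int:
    lo, hi = config.peak_width_ranges[mark]
    return int(rng.integers(lo, hi + 1))


def _interval(mark: str, center: int, width: int, name: str) -> GenomicInterval:
    start = max(0, center - width // 2)
    return GenomicInterval(CHROM, start, start + width, name=name)


def simulate(config: SimulationConfig) -> Landscape:
    """Generate an in-memory landscape; deterministic for a fixed seed."""
    n = config.n_genes
    spacing = config.intergenic_spacing
    tss_pos = [spacing // 2 + i * spacing for i in range(n)]
    strands = ["+" if i % 2 == 0 else "-" for i in range(n)]
    tss_ids = [f"tx{i:05d}" for i in range(n)]

    # exact state counts, assigned by a shuffled index
    n_poised = round(config.fraction_poised * n)
    n_silent = round(config.fraction_silent * n)
    order = _rng(config, "states").permutation(n)
    state = ["active"] * n
    for i in order[:n_poised]:
        state[i] = "poised"
    for i in order[n_poised:n_poised + n_silent]:
        state[i] = "silent"

    rng3 = _rng(config, "H3K4me3")
    rng1 = _rng(config, "H3K4me1")
    rng27 = _rng(config, "H3K27me3")
    rngac = _rng(config, "H3K27ac")
    peaks: dict[str, list[GenomicInterval]] = {m: [] for m in _DEFAULT_WIDTHS}
    peak_ids: list[list[str]] = [[] for _ in range(n)]

    def add(mark: str, gene: int, center: int, width: int, tag: str) -> None:
        name = f"{mark}_{tag}_{tss_ids[gene]}"
        peaks[mark].append(_interval(mark, center, width, name))
        peak_ids[gene].append(name)

    for i in range(n):
        if state[i] == "silent":
            continue
        pos, sgn = tss_pos[i], (1 if strands[i] == "+" else -1)
        # H3K4me3 just downstream of the TSS in gene orientation
        off3 = rng3.normal(config.k4me3_offset_mean, config.k4me3_offset_sd)
        c3 = pos + sgn * int(round(off3))
        w3 = _draw_width(rng3, config, "H3K4me3")
        add("H3K4me3", i, c3, w3, "prom")
        if state[i] == "active":
            lo, hi = config.flank_offset_range
            up = int(rng1.integers(lo, hi + 1))
            down = int(rng1.integers(lo, hi + 1))
            add("H3K4me1", i, pos - up, _draw_width(rng1, config, "H3K4me1"), "flankL")
            add("H3K4me1", i, pos + down, _draw_width(rng1, config, "H3K4me1"), "flankR")
            cac = pos + int(round(rngac.normal(0.0, config.k27ac_offset_sd)))
            add("H3K27ac", i, cac, _draw_width(rngac, config, "H3K27ac"), "prom")
        else:  # poised
            # H3K27me3 centered inside the H3K4me3 interval: >= 1 bp overlap
            iv3 = peaks["H3K4me3"][-1]
            c27 = int(rng27.integers(iv3.start, iv3.end))
            add("H3K27me3", i, c27, _draw_width(rng27, config, "H3K27me3"), "prom")
            c1 = pos + int(round(rng1.normal(0.0, config.poised_k4me1_sd)))
            add("H3K4me1", i, c1, _draw_width(rng1, config, "H3K4me1"), "center")

    # distal background H3K4me1, uniform but >= background_min_tss_distance
    # from every TSS: draw a gene segment and an offset inside its allowed band
    rng_bg = _rng(config, "background")
    d_min = config.background_min_tss_distance
    if spacing - 2 * d_min <= 1 and config.n_background_k4me1 > 0:
        raise ValueError("spacing too small to place background peaks away from TSS")
    for b in range(config.n_background_k4me1):
        g = int(rng_bg.integers(0, n))
        offset = int(rng_bg.integers(d_min + 1, spacing - d_min))
        name = f"H3K4me1_bg{b:05d}"
        peaks["H3K4me1"].append(
            _interval("H3K4me1", tss_pos[g] + offset,
                      _draw_width(rng_bg, config, "H3K4me1"), name))

    # expression: overlapping state-dependent distributions
    rng_tpm = _rng(config, "tpm")
    tpm: dict[str, float] = {}
    for i in range(n):
        if state[i] == "active":
            value = float(rng_tpm.lognormal(config.active_tpm_mu, config.active_tpm_sigma))
        elif state[i] == "poised":
            if rng_tpm.random() < config.poised_zero_fraction:
                value = 0.0
            else:
                value = float(rng_tpm.lognormal(config.poised_tpm_mu,
                                                config.poised_tpm_sigma))
        else:
            value = 0.0
        tpm[tss_ids[i]] = value

    tss_records = [
        TssRecord(chrom=CHROM, position=tss_pos[i], strand=strands[i],
                  transcript_id=tss_ids[i], gene_id=f"gene{i:05d}",
                  tpm=tpm[tss_ids[i]])
        for i in range(n)
    ]
    truth = [
        SyntheticTruth(tss_id=tss_ids[i], true_state=state[i],
                       tpm=tpm[tss_ids[i]], peak_ids=tuple(peak_ids[i]))
        for i in range(n)
    ]
    peak_sets = {m: PeakSet(mark=m, intervals=tuple(ivs), source="synthetic")
                 for m, ivs in peaks.items()}
    return Landscape(config=config, peaks=peak_sets, tss=tss_records,
                     tpm=tpm, truth=truth)


def write_tpm_tsv(tpm: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("target_id\ttpm\n")
        for tx in sorted(tpm):
            fh.write(f"{tx}\t{tpm[tx]:.6f}\n")


def write_truth_tsv(truth: Sequence[SyntheticTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("tss_id\ttrue_state\ttpm\tpeak_ids\n")
        for t in truth:
            fh.write(f"{t.tss_id}\t{t.true_state}\t{t.tpm:.6f}\t"
                     f"{','.join(t.peak_ids)}\n")


def read_truth_tsv(path: str | Path) -> list[SyntheticTruth]:
    truth = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            tss_id, true_state, tpm, peak_ids = line.rstrip("\n").split("\t")
            truth.append(SyntheticTruth(
                tss_id=tss_id, true_state=true_state, tpm=float(tpm),
                peak_ids=tuple(p for p in peak_ids.split(",") if p)))
    return truth


def generate_landscape(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate and write every input format the pipeline consumes.

    Writes one BED file per mark, a bed6 TSS file, a kallisto-style TPM
    TSV and a ground-truth TSV into ``outdir``; returns their paths.
    Byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    land = simulate(config)
    paths: dict[str, Path] = {}
    for mark, pset in land.peaks.items():
        p = outdir / f"{mark}.bed"
        write_intervals(pset.intervals, p)
        paths[mark] = p
    paths["tss"] = outdir / "tss.bed"
    write_tss_bed6(land.tss, paths["tss"])
    paths["tpm"] = outdir / "tpm.tsv"
    write_tpm_tsv(land.tpm, paths["tpm"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth_tsv(land.truth, paths["truth"])
    return paths


def make_discordant_subset(
    truth: Sequence[SyntheticTruth],
    tpm: Mapping[str, float],
    n_poised_high: int = 50,
    n_active_low: int = 50,
    high_tpm: float = 20.0,
    low_tpm: float = 0.5,
    seed: int = 0,
) -> dict[str, float]:
    """Force expression/state discordance without touching peaks.

    Reassigns ``n_poised_high`` truth-poised TSS a TPM of ``high_tpm``
    (bin B4) and ``n_active_low`` truth-active TSS a TPM of ``low_tpm``
    (bin B1), chosen at random with ``seed``.  Returns a new TPM mapping;
    raises when a requested count exceeds the TSS available in that state.
    """
    if high_tpm <= 10 or low_tpm > 1:
        raise ValueError("high_tpm must exceed 10 and low_tpm must be <= 1")
    poised = [t.tss_id for t in truth if t.true_state == "poised"]
    active = [t.tss_id for t in truth if t.true_state == "active"]
    if n_poised_high > len(poised):
        raise ValueError(
            f"requested {n_poised_high} poised overrides but only {len(poised)} available")
    if n_active_low > len(active):
        raise ValueError(
            f"requested {n_active_low} active overrides but only {len(active)} available")
    rng = np.random.default_rng(seed)
    out = dict(tpm)
    for tss_id in rng.choice(poised, size=n_poised_high, replace=False):
        out[str(tss_id)] = float(high_tpm)
    for tss_id in rng.choice(active, size=n_active_low, replace=False):
        out[str(tss_id)] = float(low_tpm)
    return out
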