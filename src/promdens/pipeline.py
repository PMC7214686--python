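"""End-to-end orchestration: density -> classify -> jointmap -> groupstats.

``run`` ties the stages together from a :class:`PipelineConfig`, writes
every result as TSV/BED under one output directory alongside a manifest
(config echo, input hashes, package version), and logs input and
exclusion counts per stage.  All non-log outputs are deterministic for
fixed inputs and config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .genome_io import (MARKS, PeakSet, TssRecord, attach_tpm,
                        check_chrom_compatibility, read_peaks, read_tpm,
                        read_tss, write_intervals)
from .density_profiles import (default_grid, gaussian_density,
                               peak_to_tss_distances, shape_summary)
from .promoter_states import (EXPRESSION_BINS, classify_by_k4me1,
                              classify_by_k4me3, distance_by_group,
                              joint_distance_map, poised_k4me1, poised_peaks)
from .stats_tests import kruskal_wallis

log = logging.getLogger("promdens")

_HEADER_NOTE = ("# distances in bp; sign convention: negative = upstream of the "
                "TSS in gene orientation")


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs, parameters, output location."""

    peaks: dict[str, str] = field(default_factory=dict)  # mark -> path
    tss: str = ""
    tss_format: str = "bed6"  # or gtf
    tpm: str | None = None
    outdir: str = "promdens_out"
    window: int = 2000
    bandwidth: float = 15.0
    active_radius: int = 500
    nbins: int = 30
    grid_step: int = 10
    expression_bin_edges: tuple[float, float, float] = (1.0, 5.0, 10.0)
    tpm_combine: str = "sum"
    strict: bool = False
    plot: bool = False

    def __post_init__(self) -> None:
        for name in ("window", "bandwidth", "active_radius", "nbins", "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for mark in self.peaks:
            if mark not in MARKS:
                raise ValueError(f"unknown mark {mark!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "expression_bin_edges" in data:
            data["expression_bin_edges"] = tuple(data["expression_bin_edges"])
        return cls(**data)


def _peak_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    return {"": "bed", ".bed": "bed", ".narrowpeak": "narrowPeak",
            ".broadpeak": "broadPeak"}.get(suffix, "bed")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_inputs(config: PipelineConfig) -> tuple[dict[str, PeakSet], list[TssRecord]]:
    """Read peak sets and TSS records, attach TPM, check chromosome names."""
    if not config.tss:
        raise ValueError("no TSS annotation configured")
    missing = [p for p in [config.tss, config.tpm, *config.peaks.values()]
               if p and not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    peaks = {
        mark: read_peaks(path, format=_peak_format(path), mark=mark)
        for mark, path in sorted(config.peaks.items())
    }
    tss = read_tss(config.tss, format=config.tss_format)
    if config.tpm:
        tss = attach_tpm(tss, read_tpm(config.tpm), combine=config.tpm_combine)
    tss_chroms = {t.chrom for t in tss}
    for mark, pset in peaks.items():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            unshared = check_chrom_compatibility(pset.chroms(), tss_chroms, label=mark)
        for w in caught:
            log.warning(str(w.message))
        if unshared and config.strict:
            raise ValueError(
                f"chromosome-name mismatch for {mark} under --strict: {sorted(unshared)}")
        log.info("loaded %d %s peaks from %s", len(pset), mark, pset.source)
    log.info("loaded %d TSS from %s", len(tss), config.tss)
    return peaks, tss


def _require(peaks: dict[str, PeakSet], marks: Sequence[str], stage: str) -> None:
    missing = [m for m in marks if m not in peaks]
    if missing:
        raise ValueError(f"stage {stage!r} requires peak files for {missing}")


def _write_profile(path: Path, grid: np.ndarray, density: np.ndarray,
                   mark: str, n: int, bandwidth: float) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER_NOTE + f"; mark={mark}; n={n}; bandwidth_bp={bandwidth:g}\n")
        fh.write("offset_bp\tdensity\n")
        for x, y in zip(grid, density):
            fh.write(f"{int(x)}\t{y:.10g}\n")


ALL_STAGES = ("density", "classify", "jointmap", "groupstats")


def run(config: PipelineConfig, stages: Sequence[str] = ALL_STAGES) -> Path:
    """Execute the requested stages in pipeline order; return the outdir.

    ``classify`` is implied by ``groupstats`` (which consumes its calls);
    each stage checks only the inputs it actually needs.
    """
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; expected subset of {ALL_STAGES}")
    stages = set(stages)
    if "groupstats" in stages:
        stages.add("classify")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    peaks, tss = load_inputs(config)
    artifacts: list[str] = []

    # ---- density stage ------------------------------------------------
    if "density" in stages:
        _run_density(config, peaks, tss, outdir, artifacts)
    if "classify" in stages:
        calls1 = _run_classify(config, peaks, tss, outdir, artifacts)
    if "jointmap" in stages:
        _run_jointmap(config, peaks, tss, outdir, artifacts)
    if "groupstats" in stages:
        _run_groupstats(config, calls1, outdir, artifacts)

    manifest = {
        "package": "promdens",
        "version": __version__,
        "config": {**asdict(config),
                   "expression_bin_edges": list(config.expression_bin_edges)},
        "stages": sorted(stages),
        "inputs": {str(p): _sha256(p)
                   for p in [config.tss, config.tpm, *config.peaks.values()] if p},
        "artifacts": sorted(artifacts),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("run complete: %d artifacts in %s", len(artifacts), outdir)
    return outdir


def _run_density(config, peaks, tss, outdir: Path, artifacts: list[str]) -> None:
    grid = default_grid(config.window, config.grid_step)
    with open(outdir / "shape_summary.tsv", "w") as fh:
        fh.write("# fractions of |distance| mass: center |d|<300 bp, "
                 "flank 300<=|d|<=1000 bp\n")
        fh.write("mark\tn_distances\tn_excluded\tcenter_fraction\t"
                 "flank_fraction\tbimodality_ratio\n")
        for mark, pset in peaks.items():
            distances, n_excluded = peak_to_tss_distances(pset, tss, config.window)
            log.info("density[%s]: %d distances, %d peaks with no TSS in window",
                     mark, len(distances), n_excluded)
            if not distances:
                log.warning("density[%s]: no peak within window of any TSS", mark)
                continue
            profile = gaussian_density(distances, config.bandwidth, grid)
            name = f"density_{mark}.tsv"
            _write_profile(outdir / name, profile.grid, profile.density,
                           mark, profile.n, profile.bandwidth)
            artifacts.append(name)
            s = shape_summary(distances)
            fh.write(f"{mark}\t{s.n}\t{n_excluded}\t{s.center_fraction:.6f}\t"
                     f"{s.flank_fraction:.6f}\t{s.bimodality_ratio:.6f}\n")
            if config.plot:
                _plot_profile(profile, mark, outdir / f"density_{mark}.png")
    artifacts.append("shape_summary.tsv")


def _run_classify(config, peaks, tss, outdir: Path, artifacts: list[str]):
    _require(peaks, ("H3K4me1", "H3K4me3", "H3K27me3"), "classify")
    poised = poised_peaks(peaks["H3K4me3"], peaks["H3K27me3"])
    write_intervals(poised.intervals, outdir / "poised_peaks.bed")
    pk1 = poised_k4me1(peaks["H3K4me1"], poised)
    write_intervals(pk1.intervals, outdir / "poised_k4me1.bed")
    artifacts += ["poised_peaks.bed", "poised_k4me1.bed"]
    log.info("classify: %d poised H3K4me3 peaks, %d poised H3K4me1 peaks",
             len(poised), len(pk1))

    calls3 = classify_by_k4me3(tss, peaks["H3K4me3"], peaks["H3K27me3"],
                               window=config.window, k4me1=peaks["H3K4me1"])
    calls1 = classify_by_k4me1(tss, peaks["H3K4me1"], peaks["H3K4me3"],
                               peaks["H3K27me3"], active_radius=config.active_radius,
                               window=config.window)
    with open(outdir / "promoter_calls.tsv", "w") as fh:
        fh.write(_HEADER_NOTE + f"; window_bp={config.window}; "
                 f"active_radius_bp={config.active_radius}; "
                 f"bin_edges_tpm={list(config.expression_bin_edges)}\n")
        fh.write("tss_id\trule\tstate\td_k4me1\td_k4me3\ttpm\texpression_bin\n")
        for call in [*calls3, *calls1]:
            fh.write("\t".join([
                call.tss_id, call.rule, call.state,
                "" if call.d_k4me1 is None else str(call.d_k4me1),
                "" if call.d_k4me3 is None else str(call.d_k4me3),
                "" if call.tpm is None else f"{call.tpm:.6f}",
                call.expression_bin or ""]) + "\n")
    artifacts.append("promoter_calls.tsv")
    return calls1


def _run_jointmap(config, peaks, tss, outdir: Path, artifacts: list[str]) -> None:
    _require(peaks, ("H3K4me1", "H3K4me3"), "jointmap")
    jmap = joint_distance_map(tss, peaks["H3K4me1"], peaks["H3K4me3"],
                              window=config.window, nbins=config.nbins)
    with open(outdir / "joint_map.tsv", "w") as fh:
        fh.write(f"# 2D bin counts of (nearest H3K4me1, nearest H3K4me3) signed "
                 f"distance per TSS; n_tss={jmap.n_tss}; bins uniform over "
                 f"[-{config.window}, {config.window}] bp\n")
        fh.write("d_k4me1_low\\d_k4me3_low\t"
                 + "\t".join(f"{e:g}" for e in jmap.y_edges[:-1]) + "\n")
        for i, row in enumerate(jmap.counts):
            fh.write(f"{jmap.x_edges[i]:g}\t" + "\t".join(str(c) for c in row) + "\n")
    artifacts.append("joint_map.tsv")
    log.info("jointmap: %d TSS with both marks within %d bp", jmap.n_tss, config.window)


def _run_groupstats(config, calls1, outdir: Path, artifacts: list[str]) -> None:
    with open(outdir / "group_stats.tsv", "w") as fh:
        fh.write(_HEADER_NOTE + "; groups from by_k4me1 calls\n")
        fh.write("state\texpression_bin\tn\tmedian_abs_d_k4me1\n")
        rows = distance_by_group(calls1, grouping="state_x_expression_bin")
        for g in rows:
            med = f"{np.median(g.absolute):.1f}" if g.absolute else ""
            fh.write(f"{g.state}\t{g.expression_bin}\t{len(g.absolute)}\t{med}\n")
    artifacts.append("group_stats.tsv")

    with open(outdir / "kw_tests.tsv", "w") as fh:
        fh.write("# Kruskal-Wallis on ABSOLUTE nearest-H3K4me1 distances |d| (bp)\n")
        fh.write("analysis\tk\tgroup_sizes\tH\tdf\tp_value\n")
        for label, groups in _kw_analyses(calls1):
            if len(groups) < 2 or any(len(g) == 0 for g in groups):
                log.warning("groupstats[%s]: empty group, test skipped", label)
                continue
            res = kruskal_wallis(groups)
            fh.write(f"{label}\t{len(groups)}\t"
                     f"{','.join(str(s) for s in res.group_sizes)}\t"
                     f"{res.H:.6g}\t{res.df}\t{res.p_value:.6g}\n")
    artifacts.append("kw_tests.tsv")


def _kw_analyses(calls1) -> list[tuple[str, list[list[float]]]]:
    """The two rank-test contrasts: across bins, and poised vs active."""
    by_bin = distance_by_group(calls1, grouping="expression_bin")
    bins_groups = [list(g.absolute) for g in by_bin if g.absolute]
    poised = [abs(c.d_k4me1) for c in calls1
              if c.state == "poised" and c.d_k4me1 is not None]
    active = [abs(c.d_k4me1) for c in calls1
              if c.state == "active" and c.d_k4me1 is not None]
    return [("abs_d_k4me1_across_expression_bins", bins_groups),
            ("abs_d_k4me1_poised_vs_active", [poised, active])]


def _plot_profile(profile, mark: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3))
    ax.plot(profile.grid, profile.density)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("peak density")
    ax.set_title(f"{mark} (n={profile.n}, bw={profile.bandwidth:g} bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
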