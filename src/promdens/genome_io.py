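"""Readers and writers for the genomic file formats the pipeline touches.

Everything is normalized to BED-native coordinates on read: 0-based,
half-open intervals, and 0-based point positions for transcription start
sites (TSS).  GTF input (1-based, inclusive) is converted once, here, and
never re-interpreted downstream.

Peak calls arrive as BED3+, ENCODE narrowPeak (10 columns) or broadPeak
(9 columns).  TSS annotations arrive as GTF ``transcript`` features or as
6-column BED.  Transcript abundances arrive as a kallisto-style TSV with
``target_id``/``transcript_id`` and ``tpm`` columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac")

_NARROWPEAK_COLS = 10
_BROADPEAK_COLS = 9


class ParseError(ValueError):
    """A malformed record, located by file and line number."""

    def __init__(self, message: str, path: str | Path | None = None,
                 line_number: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}:"
        if line_number is not None:
            loc += f"line {line_number}: "
        super().__init__(loc + message)
        self.path = str(path) if path is not None else None
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open, 0-based interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class TssRecord:
    """A strand-bearing transcription start point.

    ``position`` is a 0-based genomic coordinate.  ``transcript_id`` may
    carry several comma-joined identifiers when exact-duplicate TSS were
    merged.  ``tpm`` is ``None`` when the transcript was absent from the
    abundance table -- unquantified, which is not the same as zero.
    """

    chrom: str
    position: int
    strand: str
    transcript_id: str
    gene_id: str | None = None
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError("TSS position must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")
        if self.tpm is not None and self.tpm < 0:
            raise ValueError("tpm must be >= 0")


@dataclass
class PeakSet:
    """An ordered collection of peak intervals for one histone mark."""

    mark: str
    intervals: tuple[GenomicInterval, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if self.mark not in MARKS:
            raise ValueError(f"unknown mark {self.mark!r}; expected one of {MARKS}")
        self.intervals = tuple(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> set[str]:
        return {iv.chrom for iv in self.intervals}


# ---------------------------------------------------------------------------
# peak readers


def _parse_bed_line(fields: Sequence[str], fmt: str, path, lineno: int,
                    auto_name: str) -> GenomicInterval:
    if fmt == "narrowPeak" and len(fields) != _NARROWPEAK_COLS:
        raise ParseError(
            f"narrowPeak requires {_NARROWPEAK_COLS} fields, got {len(fields)}",
            path, lineno)
    if fmt == "broadPeak" and len(fields) != _BROADPEAK_COLS:
        raise ParseError(
            f"broadPeak requires {_BROADPEAK_COLS} fields, got {len(fields)}",
            path, lineno)
    if len(fields) < 3:
        raise ParseError(f"need >= 3 tab-separated fields, got {len(fields)}",
                         path, lineno)
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ParseError(
            f"non-integer coordinates {fields[1]!r}, {fields[2]!r}", path, lineno
        ) from None
    if start >= end:
        raise ParseError(f"empty or inverted interval [{start}, {end})", path, lineno)
    if start < 0:
        raise ParseError(f"negative start {start}", path, lineno)
    name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else auto_name
    score: float | None = None
    if len(fields) > 4 and fields[4] not in ("", "."):
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(f"non-numeric score {fields[4]!r}", path, lineno) from None
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    return GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)


def read_peaks(path: str | Path, format: str = "bed", mark: str = "H3K4me1") -> PeakSet:
    """Read peak calls into a :class:`PeakSet`.

    Parameters
    ----------
    path
        BED-family file; ``#``-prefixed, ``track`` and ``browser`` lines and
        blank lines are skipped.
    format
        One of ``bed``, ``narrowPeak``, ``broadPeak``.  The ENCODE formats
        are validated for their exact column counts.
    mark
        Histone-mark label attached to the returned set.

    Raises
    ------
    ParseError
        On the first malformed line, naming the file and line number.
        Parsing is total: every line is either converted or located.
    """
    if format not in ("bed", "narrowPeak", "broadPeak"):
        raise ValueError(f"unknown peak format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            intervals.append(
                _parse_bed_line(fields, format, path, lineno,
                                auto_name=f"peak_{len(intervals) + 1}")
            )
    return PeakSet(mark=mark, intervals=tuple(intervals), source=str(path))


# ---------------------------------------------------------------------------
# TSS readers


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _iter_gtf_tss(path: Path) -> Iterator[TssRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"GTF requires 9 fields, got {len(fields)}",
                                 path, lineno)
            if fields[2] != "transcript":
                continue
            chrom, start, end, strand = fields[0], fields[3], fields[4], fields[6]
            attrs = _parse_gtf_attributes(fields[8])
            tx_id = attrs.get("transcript_id", f"tx_line{lineno}")
            if strand not in ("+", "-"):
                raise ParseError(
                    f"transcript {tx_id!r} lacks a usable strand ({strand!r})",
                    path, lineno)
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {start!r}, {end!r}", path, lineno
                ) from None
            # GTF is 1-based inclusive: TSS = start-1 (+) or end-1 (-) in 0-based.
            position = start_i - 1 if strand == "+" else end_i - 1
            yield TssRecord(chrom=chrom, position=position, strand=strand,
                            transcript_id=tx_id, gene_id=attrs.get("gene_id"))


def _iter_bed6_tss(path: Path) -> Iterator[TssRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"bed6 requires 6 fields, got {len(fields)}",
                                 path, lineno)
            strand = fields[5]
            name = fields[3]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"TSS record {name!r} lacks a usable strand ({strand!r})",
                    path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                    path, lineno) from None
            if start >= end:
                raise ParseError(f"empty or inverted interval [{start}, {end})",
                                 path, lineno)
            position = start if strand == "+" else end - 1
            yield TssRecord(chrom=fields[0], position=position, strand=strand,
                            transcript_id=name)


def dedup_tss(records: Iterable[TssRecord]) -> list[TssRecord]:
    """Merge records identical in (chrom, position, strand) into one TSS.

    Transcript identifiers of merged records are comma-joined in input
    order; distinct TSS of the same gene are kept separate.  This prevents
    coordinate-identical transcript isoforms from multiply-counting the
    same data point in density estimation.
    """
    merged: dict[tuple[str, int, str], TssRecord] = {}
    for rec in records:
        key = (rec.chrom, rec.position, rec.strand)
        if key in merged:
            prev = merged[key]
            merged[key] = replace(
                prev,
                transcript_id=prev.transcript_id + "," + rec.transcript_id,
                gene_id=prev.gene_id or rec.gene_id,
            )
        else:
            merged[key] = rec
    return sorted(merged.values(), key=lambda r: (r.chrom, r.position, r.strand))


def read_tss(path: str | Path, format: str = "gtf", dedup: bool = True) -> list[TssRecord]:
    """Read TSS records from a GTF (``transcript`` features) or bed6 file.

    GTF coordinates (1-based inclusive) are converted so the TSS lands on
    the first transcribed base in 0-based coordinates: ``start-1`` on the
    plus strand, ``end-1`` on the minus strand.  Exact coordinate
    duplicates are merged unless ``dedup=False``.
    """
    if format not in ("gtf", "bed6"):
        raise ValueError(f"unknown TSS format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    it = _iter_gtf_tss(path) if format == "gtf" else _iter_bed6_tss(path)
    records = list(it)
    return dedup_tss(records) if dedup else records


# ---------------------------------------------------------------------------
# expression table


def read_tpm(path: str | Path) -> dict[str, float]:
    """Read a kallisto-style abundance TSV into ``{transcript_id: tpm}``.

    The transcript column may be named ``target_id`` or ``transcript_id``;
    the abundance column must be named ``tpm`` (case-insensitive).
    Transcripts absent from the table are simply absent from the mapping:
    downstream code treats them as unquantified, never as zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("target_id") or cols.get("transcript_id")
    tpm_col = cols.get("tpm")
    if id_col is None or tpm_col is None:
        raise ParseError(
            f"expected target_id/transcript_id and tpm columns, got {list(df.columns)}",
            path)
    if df[id_col].duplicated().any():
        dup = df.loc[df[id_col].duplicated(), id_col].iloc[0]
        raise ParseError(f"duplicate transcript_id {dup!r}", path)
    tpm = df[tpm_col].astype(float)
    if (tpm < 0).any():
        bad = df.loc[tpm < 0, id_col].iloc[0]
        raise ParseError(f"negative tpm for transcript {bad!r}", path)
    return dict(zip(df[id_col].astype(str), tpm))


def attach_tpm(records: Sequence[TssRecord], tpm: Mapping[str, float],
               combine: str = "sum") -> list[TssRecord]:
    """Annotate TSS records with TPM values.

    A merged TSS carries several transcript ids; its TPM is the ``sum`` of
    the members' values (total promoter output) or their ``max``.  A TSS
    whose transcripts are all absent from the table keeps ``tpm=None``.
    """
    if combine not in ("sum", "max"):
        raise ValueError(f"combine must be 'sum' or 'max', got {combine!r}")
    out: list[TssRecord] = []
    for rec in records:
        values = [tpm[t] for t in rec.transcript_id.split(",") if t in tpm]
        if values:
            out.append(replace(rec, tpm=sum(values) if combine == "sum" else max(values)))
        else:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# writers & consistency checks


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as 6-column BED, sorted by (chrom, start).

    Round-trips through :func:`read_peaks`: chrom, start, end, name and
    strand are preserved field-for-field; a missing score is written as
    ``.``.
    """
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in rows:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


def write_tss_bed6(records: Iterable[TssRecord], path: str | Path) -> None:
    """Write TSS records as single-base bed6 intervals ``[pos, pos+1)``."""
    rows = sorted(records, key=lambda r: (r.chrom, r.position))
    with open(path, "w") as fh:
        for rec in rows:
            fh.write(f"{rec.chrom}\t{rec.position}\t{rec.position + 1}\t"
                     f"{rec.transcript_id}\t.\t{rec.strand}\n")


def check_chrom_compatibility(peak_chroms: set[str], tss_chroms: set[str],
                              label: str = "") -> set[str]:
    """Warn when peak and TSS chromosome name sets differ.

    Silent zero-overlap from mismatched naming (``chr1`` vs ``1``) is the
    classic failure mode of this kind of analysis; no prefix normalization
    is attempted, but the unshared names are surfaced.  Returns the set of
    unshared names.
    """
    unshared = peak_chroms.symmetric_difference(tss_chroms)
    if unshared and not peak_chroms.intersection(tss_chroms):
        warnings.warn(
            f"{label + ': ' if label else ''}no chromosome names shared between "
            f"peaks and TSS; unshared: {sorted(unshared)}", stacklevel=2)
    elif unshared:
        warnings.warn(
            f"{label + ': ' if label else ''}chromosome name sets differ between "
            f"peaks and TSS; unshared: {sorted(unshared)}", stacklevel=2)
    return unshared
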