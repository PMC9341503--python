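"""Readers and writers for the plain-text formats the pipeline touches.

Supported: BED3/BED4/BED6 read/write, narrowPeak/broadPeak read (columns
beyond 3 optional), 4-column state BED and ChromHMM dense segmentation read,
and indexed FASTA via :mod:`pyfaidx`.  All writers emit sorted BED with
header comment lines prefixed ``#``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

from .intervals import (
    GenomicInterval,
    GeneModel,
    PeakTrack,
    SegmentationTrack,
    StateSegment,
)

_STATE_RE = re.compile(r"^E?(\d+)$")


class ParseError(ValueError):
    """Malformed input line; carries the file path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = path
        self.lineno = lineno


def normalise_state(label: str) -> int | str:
    """ChromHMM-style labels ('E11', '11') become ints; others stay strings."""
    m = _STATE_RE.match(label)
    return int(m.group(1)) if m else label


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _parse_interval(path, lineno: int, fields: Sequence[str], min_cols: int) -> GenomicInterval:
    if len(fields) < min_cols:
        raise ParseError(path, lineno, f"expected >= {min_cols} columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ParseError(path, lineno, f"non-integer coordinates: {exc}") from None
    if start < 0 or end <= start:
        raise ParseError(path, lineno, f"invalid interval [{start}, {end})")
    strand = "."
    if len(fields) >= 6 and fields[5] in ("+", "-", "."):
        strand = fields[5]
    return GenomicInterval(chrom, start, end, strand)


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED4/BED6 intervals (extra columns ignored)."""
    return sorted(_parse_interval(path, n, f, 3) for n, f in _data_lines(path))


def read_named_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED4+ keeping the name column."""
    out = []
    for lineno, fields in _data_lines(path):
        iv = _parse_interval(path, lineno, fields, 4)
        out.append((iv, fields[3]))
    out.sort(key=lambda t: t[0])
    return out


def read_peaks(path, sample_id: str, mark: str) -> PeakTrack:
    """Read a narrowPeak/broadPeak/BED peak file (columns beyond 3 optional)."""
    return PeakTrack(sample_id=sample_id, mark=mark, peaks=read_bed(path))


def read_segmentation(
    path,
    dialect: str = "bed4_state",
    sample_id: str | None = None,
    **track_kwargs,
) -> SegmentationTrack:
    """Read a chromatin-state segmentation.

    ``bed4_state``: chrom, start, end, state.  ``dense_segmentation``:
    ChromHMM dense output (same leading four columns, extra columns ignored,
    ``track`` header lines skipped).  State labels matching ``E?\\d+`` are
    normalised to integers.  Book-ended or overlapping same-state segments are
    merged; overlapping different-state segments raise an error.
    """
    if dialect not in ("bed4_state", "dense_segmentation"):
        raise ValueError(f"unknown segmentation dialect {dialect!r}")
    segments = []
    for lineno, fields in _data_lines(path):
        iv = _parse_interval(path, lineno, fields, 4)
        segments.append(StateSegment(iv, normalise_state(fields[3])))
    sid = sample_id if sample_id is not None else Path(path).stem
    return SegmentationTrack.from_segments(sid, segments, **track_kwargs)


def read_genes(path) -> list[GeneModel]:
    """Read gene models from BED6 (name = gene id, strand required)."""
    genes = []
    for lineno, fields in _data_lines(path):
        iv = _parse_interval(path, lineno, fields, 6)
        if iv.strand not in ("+", "-"):
            raise ParseError(path, lineno, f"gene requires +/- strand, got {fields[5]!r}")
        genes.append(GeneModel(gene_id=fields[3], body=iv, strand=iv.strand))
    return sorted(genes, key=lambda g: (g.body.chrom, g.body.start, g.gene_id))


def write_bed(
    path,
    records: Iterable[tuple[GenomicInterval, str, int] | tuple[GenomicInterval, str] | GenomicInterval],
    header: str | None = None,
) -> None:
    """Write sorted BED; records may be bare intervals, (iv, name) or
    (iv, name, score) tuples."""
    rows = []
    for rec in records:
        if isinstance(rec, GenomicInterval):
            iv, name, score = rec, ".", 0
        elif len(rec) == 2:
            (iv, name), score = rec, 0
        else:
            iv, name, score = rec
        rows.append((iv, name, score))
    rows.sort(key=lambda r: r[0])
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv, name, score in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def write_segmentation(path, track: SegmentationTrack, header: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for seg in track.segments:
            iv = seg.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{seg.state}\n")


def write_fasta(path, sequences: dict[str, str], width: int = 80) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(sequences):
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_fasta(path):
    """Open an indexed FASTA for region queries (lazy, via pyfaidx)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))
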