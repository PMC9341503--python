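"""AID hotspot (RGYW) motif-cluster scanning.

Activation-induced cytidine deaminase targets DNA hotspots matching the
degenerate 4-mer RGYW (R = A/G, Y = C/T, W = A/T).  Clusters are detected as
tiled 2.5-kb windows containing strictly more than 200 RGYW matches, merged
when adjacent — the density signature of immunoglobulin switch-region-like
sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .intervals import GenomicInterval, merge_with_gap

DEFAULT_WINDOW = 2500
DEFAULT_THRESHOLD = 200

# overlapping occurrences are all counted, hence the lookahead patterns
_RGYW = re.compile(r"(?=[AG]G[CT][AT])")
# reverse complement of RGYW (WRCY) read on the same strand
_WRCY = re.compile(r"(?=[AT][AG]C[CT])")
_ALPHABET = frozenset("ACGTN")


def count_rgyw(sequence: str, strand_mode: str = "forward") -> int:
    """Count (possibly overlapping) RGYW matches in ``sequence``.

    ``both`` additionally counts the reverse-complement pattern WRCY on the
    same strand.  ``N`` never matches; other characters are rejected.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    n = len(_RGYW.findall(seq))
    if strand_mode == "both":
        n += len(_WRCY.findall(seq))
    return n


@dataclass(frozen=True)
class MotifWindow:
    interval: GenomicInterval
    count: int
    qualifies: bool


@dataclass
class MotifClusterTrack:
    windows: list[MotifWindow]
    clusters: list[GenomicInterval]
    window: int
    step: int
    threshold: int
    strand_mode: str


def scan_clusters(
    fasta,
    region: GenomicInterval,
    window: int = DEFAULT_WINDOW,
    step: int | None = None,
    threshold: int = DEFAULT_THRESHOLD,
    strand_mode: str = "forward",
) -> MotifClusterTrack:
    """Scan ``region`` for RGYW motif clusters by windowed density.

    ``fasta`` is any mapping from chromosome name to sliceable sequence
    (a ``pyfaidx.Fasta`` or a plain ``dict`` of strings).  Windows are tiled
    from the region start every ``step`` bp (default: non-overlapping tiles of
    one window); only full windows are scored.  Windows with count strictly
    greater than ``threshold`` qualify and are merged (gap 0) into clusters.
    """
    if step is None:
        step = window
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    try:
        chrom_seq = fasta[region.chrom]
    except KeyError:
        raise ValueError(f"chromosome {region.chrom!r} absent from sequence source")
    chrom_len = len(chrom_seq)
    if region.end > chrom_len:
        raise ValueError(
            f"region {region} extends beyond {region.chrom} length {chrom_len}"
        )
    seq = str(chrom_seq[region.start : region.end]).upper()
    windows: list[MotifWindow] = []
    for off in range(0, region.length - window + 1, step):
        count = count_rgyw(seq[off : off + window], strand_mode)
        iv = GenomicInterval(region.chrom, region.start + off, region.start + off + window)
        windows.append(MotifWindow(interval=iv, count=count, qualifies=count > threshold))
    qualifying = [w.interval for w in windows if w.qualifies]
    clusters = merge_with_gap(qualifying, 0) if qualifying else []
    return MotifClusterTrack(
        windows=windows,
        clusters=clusters,
        window=window,
        step=step,
        threshold=threshold,
        strand_mode=strand_mode,
    )
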