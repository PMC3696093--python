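"""Mapped-tag I/O and genome windowing.

Reads mapped ChIP-Seq tags from BED, collapses PCR duplicates, bins tags
into fixed non-overlapping genome windows and round-trips the resulting
track through bedGraph.  Coordinates are 0-based half-open throughout
(BED/bedGraph native).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple

import numpy as np

logger = logging.getLogger(__name__)


class Tag(NamedTuple):
    """One mapped sequencing tag (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    strand: str = "."  # '+', '-' or '.' (unknown)


class BedParseError(ValueError):
    """Raised for a malformed BED/bedGraph line; message names the line number."""


@dataclass(frozen=True)
class GenomeTable:
    """Ordered mapping of chromosome name to length in bp."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def items(self):
        return self.lengths.items()

    def n_windows(self, chrom: str, w: int) -> int:
        return math.ceil(self.lengths[chrom] / w)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeTable":
        """Read a two-column chrom.sizes table (name, length)."""
        lengths: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                name = fields[0]
                if name in lengths:
                    raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
                try:
                    lengths[name] = int(fields[1])
                except ValueError as exc:
                    raise BedParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
        return cls(lengths)


@dataclass
class WindowedTrack:
    """Per-chromosome vectors of per-window tag values on a fixed grid.

    ``values[chrom]`` has ``ceil(chrom_length / window_size)`` entries.
    ``value_kind`` is ``"raw"`` (integer tag counts) or ``"normalized"``
    (control-corrected ratios).
    """

    window_size: int
    values: dict[str, np.ndarray]
    total_tags: int
    value_kind: str = "raw"
    genome: GenomeTable | None = field(default=None, repr=False)

    @property
    def n_windows(self) -> int:
        return sum(v.size for v in self.values.values())

    def genome_mean(self) -> float:
        """Mean window value over the whole genome."""
        total = sum(float(v.sum()) for v in self.values.values())
        return total / self.n_windows

    def concatenated(self) -> np.ndarray:
        """All window values as one vector (chromosome order preserved)."""
        return np.concatenate([self.values[c] for c in self.values])


def read_tags(path: str | Path, genome: GenomeTable) -> list[Tag]:
    """Parse mapped tags from a BED file (>= 3 columns, optional column 6 = strand).

    Tags on chromosomes absent from *genome* are dropped; the drop count is
    logged.  Malformed lines raise :class:`BedParseError` naming the line.
    """
    tags: list[Tag] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if not (0 <= start < end):
                raise BedParseError(f"{path}:{lineno}: require 0 <= start < end, got {start}, {end}")
            if chrom not in genome:
                dropped += 1
                continue
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            tags.append(Tag(chrom, start, end, strand))
    if dropped:
        logger.info("read_tags: dropped %d tags on chromosomes absent from genome", dropped)
    return tags


def deduplicate(tags: Iterable[Tag], ignore_strand: bool = False) -> list[Tag]:
    """Collapse tags mapping to the same genomic region to a single tag.

    The duplicate key is (chrom, start, end, strand); with *ignore_strand*
    the strand is dropped from the key.  Output order is sorted and
    deterministic.
    """
    if ignore_strand:
        seen: dict[tuple, Tag] = {}
        for t in sorted(tags):
            seen.setdefault((t.chrom, t.start, t.end), t)
        return sorted(seen.values())
    return sorted(set(tags))


def _assignment_point(tag: Tag) -> int:
    # 5' end: start on the forward strand, end-1 on the reverse strand;
    # unstranded tags fall back to start.
    return tag.end - 1 if tag.strand == "-" else tag.start


def count_windows(tags: Iterable[Tag], genome: GenomeTable, w: int = 200) -> WindowedTrack:
    """Bin deduplicated tags into non-overlapping *w*-bp windows.

    Each tag increments exactly the window containing its 5' end.  Tags whose
    assignment point lies beyond the chromosome end are clamped to the last
    window (with a warning).
    """
    if w <= 0:
        raise ValueError("window size must be positive")
    values = {c: np.zeros(genome.n_windows(c, w), dtype=np.int64) for c in genome}
    clamped = 0
    total = 0
    for tag in tags:
        vec = values[tag.chrom]
        idx = _assignment_point(tag) // w
        if idx >= vec.size:
            idx = vec.size - 1
            clamped += 1
        vec[idx] += 1
        total += 1
    if clamped:
        logger.warning("count_windows: clamped %d tags beyond chromosome end", clamped)
    return WindowedTrack(window_size=w, values=values, total_tags=total, value_kind="raw", genome=genome)


def write_bedgraph(track: WindowedTrack, path: str | Path) -> None:
    """Write a 4-column bedGraph; zero-valued windows are omitted.

    The final window of a chromosome is truncated at the chromosome end when
    the genome table is available.
    """
    w = track.window_size
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            chrom_len = track.genome[chrom] if track.genome is not None else None
            (nz,) = np.nonzero(vec)
            for i in nz:
                start = int(i) * w
                end = start + w
                if chrom_len is not None:
                    end = min(end, chrom_len)
                val = vec[i]
                sval = str(int(val)) if track.value_kind == "raw" else repr(float(val))
                fh.write(f"{chrom}\t{start}\t{end}\t{sval}\n")


def read_bedgraph(path: str | Path, genome: GenomeTable, w: int = 200,
                  value_kind: str = "raw") -> WindowedTrack:
    """Read a bedGraph written on a fixed *w* grid back into a WindowedTrack.

    Intervals must start on a multiple of *w* and span at most one window.
    """
    dtype = np.int64 if value_kind == "raw" else np.float64
    values = {c: np.zeros(genome.n_windows(c, w), dtype=dtype) for c in genome}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: expected 4 columns")
            chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if chrom not in genome:
                continue
            if start % w != 0 or end - start > w:
                raise BedParseError(f"{path}:{lineno}: interval not aligned to {w}-bp grid")
            values[chrom][start // w] = dtype(float(val) if value_kind != "raw" else int(val))
    total = int(sum(v.sum() for v in values.values())) if value_kind == "raw" else 0
    return WindowedTrack(window_size=w, values=values, total_tags=total,
                         value_kind=value_kind, genome=genome)
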