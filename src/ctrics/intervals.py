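"""Generic genomic interval sets (binding sites, domains, unmappable regions)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np


class Interval(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    intensity: float | None = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class IntervalSet:
    """A named collection of genomic intervals, kept sorted per chromosome."""

    name: str
    records: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.records:
            if iv.start >= iv.end:
                raise ValueError(f"{self.name}: interval {iv} has start >= end")
        self.records = sorted(self.records, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.records:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def midpoints(self, chrom: str) -> np.ndarray:
        return np.array([iv.midpoint for iv in self.records if iv.chrom == chrom])

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "IntervalSet":
        """Read intervals from a BED-like file; column 5 (score), if numeric,
        is kept as the intensity."""
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
                intensity = None
                if len(fields) >= 5:
                    try:
                        intensity = float(fields[4])
                    except ValueError:
                        pass
                records.append(Interval(fields[0], int(fields[1]), int(fields[2]), intensity))
        return cls(name or Path(path).stem, records)


def point_to_interval_distance(point: float, iv: Interval) -> float:
    """bp distance from a point to the nearest base of a half-open interval
    (0 when the point falls inside)."""
    return max(iv.start - point, point - (iv.end - 1), 0.0)
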