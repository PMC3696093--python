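"""Poly(dA:dT) tract content along the genome.

Counts overlapping AAAA/TTTT 4-mers in sliding windows (200 bp window,
25 bp step by default) and normalizes to the genome-average window count.
A run of k consecutive A's contributes k - 3 occurrences, so the score is
monotone in tract length; ambiguity codes (N etc.) never match and break
tracts.  Poly(dA:dT) tracts resist nucleosome formation, which is why their
density is informative around facultative-heterochromatin boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

K = 4  # tract-defining homopolymer length


@dataclass
class TractProfile:
    """Sliding-window poly(dA:dT) counts, raw and genome-normalized."""

    window: int
    step: int
    starts: dict[str, np.ndarray]    # window start coordinates per chromosome
    raw: dict[str, np.ndarray]       # overlapping AAAA/TTTT counts per window
    genome_mean: float
    normalized: dict[str, np.ndarray]

    def n_windows(self) -> int:
        return sum(v.size for v in self.raw.values())


def fourmer_hits(seq: str) -> np.ndarray:
    """Boolean vector: position p starts an AAAA or TTTT (case-insensitive)."""
    b = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    if b.size < K:
        return np.zeros(0, dtype=bool)
    is_a = b == ord("A")
    is_t = b == ord("T")
    hits_a = is_a[: -K + 1].copy()
    hits_t = is_t[: -K + 1].copy()
    for off in range(1, K):
        hits_a &= is_a[off : b.size - K + 1 + off]
        hits_t &= is_t[off : b.size - K + 1 + off]
    return hits_a | hits_t


def window_counts(seq: str, window: int = 200, step: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Per-window counts of 4-mer hits fully inside each window.

    Windows start at 0, step, 2*step, ...; the last window is the one whose
    start still leaves a full *window* bp inside the sequence (short
    sequences get a single truncated window).  Returns (starts, counts).
    """
    hits = fourmer_hits(seq)
    L = len(seq)
    if L <= window:
        starts = np.array([0])
    else:
        starts = np.arange(0, L - window + 1, step)
    c = np.concatenate([[0], np.cumsum(hits)])
    counts = np.empty(starts.size, dtype=np.int64)
    for i, s in enumerate(starts):
        # hit at position p covers p..p+3; inside the window iff p <= end - K
        last = min(s + window, L) - K + 1
        counts[i] = c[max(last, s)] - c[s] if last > s else 0
    return starts, counts


def polyat_profile(fasta: str | Path | dict[str, str], window: int = 200,
                   step: int = 25) -> TractProfile:
    """Sliding-window poly(dA:dT) content, normalized to the genome average.

    *fasta* may be a FASTA path or a {name: sequence} mapping (used by the
    synthetic tests).
    """
    if isinstance(fasta, (str, Path)):
        from pyfaidx import Fasta

        fa = Fasta(str(fasta), read_ahead=10_000_000)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        if not seqs:
            raise ValueError(f"no sequences in {fasta}")
    else:
        seqs = fasta
        if not seqs:
            raise ValueError("empty sequence set")
    starts, raw = {}, {}
    for name, seq in seqs.items():
        starts[name], raw[name] = window_counts(seq, window, step)
    total = sum(int(v.sum()) for v in raw.values())
    n_win = sum(v.size for v in raw.values())
    genome_mean = total / n_win
    if genome_mean > 0:
        normalized = {c: v / genome_mean for c, v in raw.items()}
    else:
        normalized = {c: v.astype(float) for c, v in raw.items()}
    return TractProfile(window=window, step=step, starts=starts, raw=raw,
                        genome_mean=genome_mean, normalized=normalized)


def write_profile_bedgraph(profile: TractProfile, path: str | Path) -> None:
    """Write the normalized tract density as bedGraph over the step-sized
    interval at each window start (windows overlap, so each line covers the
    step, not the full window)."""
    with open(path, "w") as fh:
        for chrom in profile.starts:
            for s, v in zip(profile.starts[chrom], profile.normalized[chrom]):
                fh.write(f"{chrom}\t{int(s)}\t{int(s) + profile.step}\t{float(v)!r}\n")
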