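"""Associate CTRs with binding sites and build oriented composite profiles.

A binding site is positively associated with a CTR when its midpoint lies
within 1 kb (inclusive) of the CTR midpoint.  Sites not associated with any
CTR are heterochromatic if their midpoint falls inside an H3K27me3-enriched
domain and euchromatic otherwise.  Composite profiles aggregate any windowed
genomic track around oriented anchors, mirroring heterochromatin-upstream
anchors so that negative offsets always denote the euchromatic side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ctr_core import ORIENT_HE, CtrCall
from .intervals import Interval, IntervalSet
from .tag_io import WindowedTrack

LABEL_CTR = "CTR-associated"
LABEL_HET = "heterochromatic"
LABEL_EU = "euchromatic"


@dataclass
class SiteAssociation:
    """Association record for one binding site."""

    site: Interval
    nearest_ctr: CtrCall | None
    distance: float  # midpoint-to-midpoint bp; inf when no CTR exists
    associated: bool
    side: str | None  # 'euchromatic'/'heterochromatic' relative to CTR orientation


@dataclass
class AssociationResult:
    sites: list[SiteAssociation]
    per_ctr: dict[tuple[str, int], list[str]]  # (chrom, start) -> site-set names

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sa in self.sites:
            rows.append({
                "chrom": sa.site.chrom, "start": sa.site.start, "end": sa.site.end,
                "distance": sa.distance, "associated": sa.associated,
                "side": sa.side or "",
                "ctr_start": sa.nearest_ctr.start if sa.nearest_ctr else -1,
            })
        return pd.DataFrame(rows)


def _nearest_ctr(site: Interval, ctrs: list[CtrCall]) -> tuple[CtrCall | None, float]:
    # ties on exact distance go to the CTR with the smaller coordinate
    best, best_d = None, float("inf")
    for ctr in ctrs:
        if ctr.chrom != site.chrom:
            continue
        d = abs(site.midpoint - ctr.midpoint)
        if d < best_d or (d == best_d and best is not None and ctr.start < best.start):
            best, best_d = ctr, d
    return best, best_d


def _side_of(site: Interval, ctr: CtrCall) -> str:
    """Which chromatin side of the CTR the site sits on.

    Orientation H>E means heterochromatin upstream of the CTR, so a site
    with smaller coordinate than the CTR midpoint is on the heterochromatic
    side; E>H reverses this.  A site exactly at the midpoint is reported on
    the heterochromatic side.
    """
    delta = site.midpoint - ctr.midpoint
    downstream_is_het = ctr.orientation != ORIENT_HE
    if delta == 0:
        return LABEL_HET
    return LABEL_HET if (delta > 0) == downstream_is_het else LABEL_EU


def associate(ctrs: list[CtrCall], sites: IntervalSet, cutoff: float = 1000) -> AssociationResult:
    """Label each site with its nearest CTR; associated iff the
    midpoint-to-midpoint distance is at most *cutoff* bp (inclusive)."""
    records: list[SiteAssociation] = []
    per_ctr: dict[tuple[str, int], list[str]] = {}
    for site in sites:
        ctr, d = _nearest_ctr(site, ctrs)
        assoc = ctr is not None and d <= cutoff
        side = _side_of(site, ctr) if assoc else None
        records.append(SiteAssociation(site, ctr if assoc else None, d, assoc, side))
        if assoc:
            per_ctr.setdefault((ctr.chrom, ctr.start), []).append(sites.name)
    return AssociationResult(records, per_ctr)


def classify_sites(sites: IntervalSet, ctrs: list[CtrCall],
                   h3k27me3_domains: IntervalSet, cutoff: float = 1000) -> list[str]:
    """Per-site label: CTR-associated takes precedence; otherwise
    heterochromatic when the midpoint is inside an enriched domain,
    else euchromatic."""
    assoc = associate(ctrs, sites, cutoff)
    dom_by_chrom = h3k27me3_domains.by_chrom()
    labels = []
    for sa in assoc.sites:
        if sa.associated:
            labels.append(LABEL_CTR)
            continue
        m = sa.site.midpoint
        inside = any(iv.start <= m < iv.end for iv in dom_by_chrom.get(sa.site.chrom, []))
        labels.append(LABEL_HET if inside else LABEL_EU)
    return labels


@dataclass
class Anchor:
    """An oriented aggregation anchor (typically a CTR midpoint)."""

    chrom: str
    position: float
    orientation: str  # ORIENT_EH or ORIENT_HE

    @classmethod
    def from_call(cls, call: CtrCall) -> "Anchor":
        return cls(call.chrom, call.midpoint, call.orientation)


@dataclass
class CompositeProfile:
    """Mean track value per signed offset bin around oriented anchors.

    Negative offsets are the euchromatic side, positive the heterochromatic
    side; anchors with heterochromatin upstream are coordinate-flipped
    before aggregation.
    """

    offsets: np.ndarray  # bin-centre offsets in bp, signed
    mean: np.ndarray
    n_anchors: np.ndarray  # contributing anchors per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean": self.mean,
                             "n_anchors": self.n_anchors})


def track_value_at(track: WindowedTrack, chrom: str, pos: float) -> float:
    """Track value at a genomic position (value of the covering window);
    NaN outside the chromosome."""
    vec = track.values[chrom]
    i = int(pos // track.window_size)
    if pos < 0 or i >= vec.size:
        return float("nan")
    return float(vec[i])


def anchor_profile_matrix(anchors: list[Anchor], track: WindowedTrack,
                          span: int = 5000, bin: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor rows of track values at each signed-offset bin centre.

    Bins tile [-span, span); the centre of bin k is -span + (k + 0.5) * bin.
    For a heterochromatin-downstream anchor (E>H) offset +x reads the track at
    position + x; for heterochromatin-upstream (H>E) the anchor is mirrored,
    reading position - x, so positive offsets always face heterochromatin.
    Out-of-chromosome bins are NaN.
    """
    n_bins = (2 * span) // bin
    offsets = -span + (np.arange(n_bins) + 0.5) * bin
    mat = np.full((len(anchors), n_bins), np.nan)
    for a_i, a in enumerate(anchors):
        flip = -1.0 if a.orientation == ORIENT_HE else 1.0
        for b_i, off in enumerate(offsets):
            mat[a_i, b_i] = track_value_at(track, a.chrom, a.position + flip * off)
    return offsets, mat


def composite_profile(anchors: list[Anchor], track: WindowedTrack,
                      span: int = 5000, bin: int = 100) -> CompositeProfile:
    """Average a track around oriented anchors (metaplot).

    Each bin's value is the mean over anchors whose bin centre lies inside
    the chromosome; truncated anchors contribute only to in-range bins.
    """
    if not anchors:
        raise ValueError("anchor set is empty")
    offsets, mat = anchor_profile_matrix(anchors, track, span=span, bin=bin)
    n = np.sum(~np.isnan(mat), axis=0)
    total = np.nansum(mat, axis=0)
    mean = np.divide(total, n, out=np.full(n.shape, np.nan), where=n > 0)
    return CompositeProfile(offsets=offsets, mean=mean, n_anchors=n)
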