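"""Region merging and six-state genome segmentation tracks.

Same-category CpGs within 500 bp of each other are merged into regions
("CpG Regions" track); merges never cross blacklisted intervals.  The
"CpG Regions Extended" track then tiles each chromosome completely: region
boundaries meet at the midpoint of gaps of at most 1 kb; where consecutive
CpGs are more than 1 kb apart a CpG desert state ``D`` fills the gap,
starting 50 bp away from each flanking CpG; blacklisted intervals override
everything as ``B``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._intervals import merge_intervals, sort_intervals
from .classify import CategorizedCpGs
from .io import SegmentTrack

logger = logging.getLogger(__name__)

MERGE_GAP = 500
DESERT_GAP = 1000
DESERT_MARGIN = 50

REGION_COLS = ["chrom", "start", "end", "category", "n_cpgs", "cpg_first", "cpg_last"]


def merge_regions(
    sites: pd.DataFrame,
    cats: CategorizedCpGs | np.ndarray,
    blacklist: pd.DataFrame | None = None,
    merge_gap: int = MERGE_GAP,
) -> pd.DataFrame:
    """Merge same-category CpGs within ``merge_gap`` bp into regions.

    Two consecutive same-category CpGs join one region iff the number of
    intervening bases (next.start - prev.end) is at most ``merge_gap`` and
    the open gap between them does not intersect any blacklist interval.
    A category change always breaks a region; singletons become 2-bp
    regions.

    Returns a DataFrame with one row per region (all categories together;
    ``category`` column distinguishes them) sorted by genomic position,
    with ``cpg_first``/``cpg_last`` the inclusive row range of member CpGs
    in ``sites``.
    """
    labels = cats.categories if isinstance(cats, CategorizedCpGs) else np.asarray(cats)
    if len(labels) != len(sites):
        raise ValueError("categories and sites length mismatch")
    if len(sites) == 0:
        return pd.DataFrame(columns=REGION_COLS)
    chrom = sites["chrom"].to_numpy()
    start = sites["start"].to_numpy()
    end = sites["end"].to_numpy()
    order = np.lexsort((start, chrom))
    if not (order == np.arange(len(sites))).all():
        raise ValueError("sites must be sorted by (chrom, start)")

    breaks = np.ones(len(sites), dtype=bool)  # breaks[i]: region starts at i
    same_chrom = chrom[1:] == chrom[:-1]
    same_cat = labels[1:] == labels[:-1]
    gap_ok = (start[1:] - end[:-1]) <= merge_gap
    joined = same_chrom & same_cat & gap_ok
    if blacklist is not None and len(blacklist) > 0:
        bl = merge_intervals(blacklist)
        crossing = np.zeros(len(sites) - 1, dtype=bool)
        for c, grp in bl.groupby("chrom", sort=False, observed=True):
            b_start = grp["start"].to_numpy()
            b_end = grp["end"].to_numpy()
            pair = np.nonzero(same_chrom & (chrom[:-1] == c))[0]
            if len(pair) == 0:
                continue
            g_lo = end[pair]  # open gap (prev.end, next.start)
            g_hi = start[pair + 1]
            i = np.searchsorted(b_end, g_lo, side="right")
            hit = (i < len(b_start)) & (b_start[np.minimum(i, len(b_start) - 1)] < g_hi)
            crossing[pair] = hit
        joined &= ~crossing
    breaks[1:] = ~joined
    region_id = np.cumsum(breaks) - 1
    first = np.nonzero(breaks)[0]
    last = np.r_[first[1:] - 1, len(sites) - 1]
    return pd.DataFrame(
        {
            "chrom": chrom[first],
            "start": start[first],
            "end": end[last],
            "category": labels[first],
            "n_cpgs": last - first + 1,
            "cpg_first": first,
            "cpg_last": last,
        }
    )


def regions_track(regions: pd.DataFrame) -> SegmentTrack:
    """The merged regions as a (gappy) segmentation track."""
    segs = regions.rename(columns={"category": "state"})[["chrom", "start", "end", "state"]]
    return SegmentTrack(sort_intervals(segs))


def build_extended_track(
    regions: pd.DataFrame,
    chrom_lengths: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    desert_gap: int = DESERT_GAP,
    desert_margin: int = DESERT_MARGIN,
) -> SegmentTrack:
    """Extend merged regions into a complete six-state tiling per chromosome.

    Adjacent regions whose facing CpGs are at most ``desert_gap`` apart
    meet at the midpoint of the gap (odd gaps give the extra base to the
    left region).  Larger gaps become desert ``D`` starting
    ``desert_margin`` bp beyond each flanking CpG.  Chromosome ends beyond
    the terminal CpG +/- margin are desert; blacklist intervals carve out
    ``B`` segments last.
    """
    if desert_gap < 2 * desert_margin:
        raise ValueError("desert_gap must be at least twice desert_margin")
    segs: list[tuple[str, int, int, str]] = []
    regions = sort_intervals(regions)
    by_chrom = dict(tuple(regions.groupby("chrom", sort=False, observed=True)))
    for chrom, length in chrom_lengths.items():
        grp = by_chrom.get(chrom)
        if grp is None or len(grp) == 0:
            segs.append((chrom, 0, length, "D"))
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        states = grp["category"].to_numpy()
        if ends[-1] > length:
            raise ValueError(f"region beyond chromosome end on {chrom}")
        # left chromosome end
        if starts[0] - desert_margin > 0:
            segs.append((chrom, 0, starts[0] - desert_margin, "D"))
            cur = starts[0] - desert_margin
        else:
            cur = 0
        for i in range(len(grp) - 1):
            gap = starts[i + 1] - ends[i]
            if gap <= desert_gap:
                boundary = (ends[i] + starts[i + 1] + 1) // 2
                segs.append((chrom, cur, boundary, states[i]))
                cur = boundary
            else:
                segs.append((chrom, cur, ends[i] + desert_margin, states[i]))
                segs.append((chrom, ends[i] + desert_margin, starts[i + 1] - desert_margin, "D"))
                cur = starts[i + 1] - desert_margin
        # right chromosome end
        if length - ends[-1] > desert_margin:
            segs.append((chrom, cur, ends[-1] + desert_margin, states[-1]))
            segs.append((chrom, ends[-1] + desert_margin, length, "D"))
        else:
            segs.append((chrom, cur, length, states[-1]))
    track = pd.DataFrame(segs, columns=["chrom", "start", "end", "state"])
    if blacklist is not None and len(blacklist) > 0:
        track = _overlay_blacklist(track, blacklist, chrom_lengths)
    out = SegmentTrack(sort_intervals(track), chrom_lengths)
    out.validate(dialect="extended")
    return out


def _overlay_blacklist(
    track: pd.DataFrame, blacklist: pd.DataFrame, chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Carve blacklist intervals out of every state as ``B`` segments."""
    bl = merge_intervals(blacklist)
    pieces: list[tuple[str, int, int, str]] = []
    for chrom, grp in track.groupby("chrom", sort=False, observed=True):
        sub = bl[bl["chrom"] == chrom]
        b_start = np.clip(sub["start"].to_numpy(), 0, chrom_lengths[str(chrom)])
        b_end = np.clip(sub["end"].to_numpy(), 0, chrom_lengths[str(chrom)])
        keep = b_end > b_start
        b_start, b_end = b_start[keep], b_end[keep]
        for bs, be in zip(b_start, b_end):
            pieces.append((str(chrom), int(bs), int(be), "B"))
        for _, seg in grp.iterrows():
            s, e = int(seg["start"]), int(seg["end"])
            cur = s
            # subtract every blacklist interval intersecting this segment
            for bs, be in zip(b_start, b_end):
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    pieces.append((str(chrom), cur, int(bs), str(seg["state"])))
                cur = max(cur, int(be))
            if cur < e:
                pieces.append((str(chrom), cur, e, str(seg["state"])))
    return pd.DataFrame(pieces, columns=["chrom", "start", "end", "state"])


def track_coverage_summary(track: SegmentTrack) -> pd.DataFrame:
    """Per-state base-pair totals and genome fractions (sum to 1)."""
    segs = track.segments
    lengths = (segs["end"] - segs["start"]).groupby(segs["state"], observed=True).sum()
    total = int(lengths.sum())
    df = lengths.rename("bp").reset_index()
    df["fraction"] = df["bp"] / total
    return df.sort_values("state").reset_index(drop=True)
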