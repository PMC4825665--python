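"""Sorted-interval arithmetic on half-open [start, end) coordinates.

All public functions take interval sets as pandas DataFrames with columns
``chrom``, ``start``, ``end`` (0-based half-open).  Subject sets are merged
internally where the operation requires it; overlap predicates are >= 1 bp.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

INTERVAL_COLS = ["chrom", "start", "end"]


def sort_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Return a copy sorted by (chrom, start, end)."""
    return df.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or book-ended intervals per chromosome (labels dropped)."""
    if len(df) == 0:
        return pd.DataFrame(columns=INTERVAL_COLS)
    out = []
    for chrom, grp in sort_intervals(df).groupby("chrom", sort=True, observed=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        run_end = np.maximum.accumulate(ends)
        # a new block begins where start exceeds the running max end so far
        new_block = np.ones(len(grp), dtype=bool)
        new_block[1:] = starts[1:] > run_end[:-1]
        first = np.nonzero(new_block)[0]
        last = np.r_[first[1:] - 1, len(grp) - 1]
        out.append(pd.DataFrame({"chrom": chrom, "start": starts[first], "end": run_end[last]}))
    return pd.concat(out, ignore_index=True)


def total_bp(df: pd.DataFrame, merge: bool = True) -> int:
    """Total bases covered by the set (after merging overlaps by default)."""
    d = merge_intervals(df) if merge else df
    if len(d) == 0:
        return 0
    return int((d["end"] - d["start"]).sum())


def _per_chrom_arrays(df: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom, grp in df.groupby("chrom", sort=False, observed=True):
        out[str(chrom)] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    return out


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: does it overlap (>=1 bp) the subject set?"""
    result = np.zeros(len(query), dtype=bool)
    if len(query) == 0 or len(subject) == 0:
        return result
    subj = _per_chrom_arrays(merge_intervals(subject))
    query = query.reset_index(drop=True)
    for chrom, grp in query.groupby("chrom", sort=False, observed=True):
        if str(chrom) not in subj:
            continue
        s_start, s_end = subj[str(chrom)]
        q_start = grp["start"].to_numpy()
        q_end = grp["end"].to_numpy()
        # first subject whose end > q_start; overlap iff its start < q_end
        i = np.searchsorted(s_end, q_start, side="right")
        hit = (i < len(s_start)) & (s_start[np.minimum(i, len(s_start) - 1)] < q_end)
        result[query.index.get_indexer(grp.index)] = hit
    return result


def points_in_intervals(
    chroms: np.ndarray, positions: np.ndarray, subject: pd.DataFrame
) -> np.ndarray:
    """Boolean per point: does position fall inside [start, end) of the subject set?"""
    result = np.zeros(len(positions), dtype=bool)
    if len(positions) == 0 or len(subject) == 0:
        return result
    subj = _per_chrom_arrays(merge_intervals(subject))
    chroms = np.asarray(chroms, dtype=object)
    for chrom in np.unique(chroms):
        if str(chrom) not in subj:
            continue
        s_start, s_end = subj[str(chrom)]
        mask = chroms == chrom
        pos = positions[mask]
        i = np.searchsorted(s_end, pos, side="right")
        hit = (i < len(s_start)) & (s_start[np.minimum(i, len(s_start) - 1)] <= pos)
        result[mask] = hit
    return result


def intersection_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Total bases in the intersection of two sets (each merged first)."""
    am = _per_chrom_arrays(merge_intervals(a))
    bm = _per_chrom_arrays(merge_intervals(b))
    total = 0
    for chrom in set(am) & set(bm):
        a_start, a_end = am[chrom]
        b_start, b_end = bm[chrom]
        i = j = 0
        while i < len(a_start) and j < len(b_start):
            lo = max(a_start[i], b_start[j])
            hi = min(a_end[i], b_end[j])
            if hi > lo:
                total += hi - lo
            if a_end[i] < b_end[j]:
                i += 1
            else:
                j += 1
    return int(total)


def prepare_subject(subject: pd.DataFrame) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pre-merge a subject set for repeated overlap queries."""
    return _per_chrom_arrays(merge_intervals(subject))


def overlaps_any_arrays(
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    subject: dict[str, tuple[np.ndarray, np.ndarray]],
) -> np.ndarray:
    """Vectorized overlap predicate against a :func:`prepare_subject` set."""
    result = np.zeros(len(starts), dtype=bool)
    chroms = np.asarray(chroms, dtype=object)
    for chrom in np.unique(chroms):
        if str(chrom) not in subject:
            continue
        s_start, s_end = subject[str(chrom)]
        if len(s_start) == 0:
            continue
        mask = chroms == chrom
        i = np.searchsorted(s_end, starts[mask], side="right")
        hit = (i < len(s_start)) & (s_start[np.minimum(i, len(s_start) - 1)] < ends[mask])
        result[mask] = hit
    return result


def batch_place_uniform(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    lengths: np.ndarray,
    avoid: pd.DataFrame | None = None,
    max_rounds: int = 200,
) -> pd.DataFrame:
    """Place one interval per entry of ``lengths`` uniformly over the genome,
    avoiding (zero overlap with) the ``avoid`` set, by vectorized rejection
    sampling.  Chromosomes are chosen with probability proportional to the
    number of admissible start positions for each interval's length."""
    lengths = np.asarray(lengths, dtype=np.int64)
    names = np.array(list(chrom_lengths), dtype=object)
    clen = np.array([chrom_lengths[str(c)] for c in names], dtype=np.int64)
    if (lengths > clen.max()).any():
        raise ValueError("an interval is longer than every chromosome")
    subj = prepare_subject(avoid) if avoid is not None and len(avoid) else None
    out_chrom = np.empty(len(lengths), dtype=object)
    out_start = np.empty(len(lengths), dtype=np.int64)
    pending = np.arange(len(lengths))
    for _ in range(max_rounds):
        if len(pending) == 0:
            break
        ell = lengths[pending]
        # admissible starts per chromosome for each pending length
        slots = np.maximum(clen[None, :] - ell[:, None] + 1, 0).astype(float)
        probs = slots / slots.sum(axis=1, keepdims=True)
        u = rng.random(len(pending))
        ci = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
        start = (rng.random(len(pending)) * slots[np.arange(len(pending)), ci]).astype(np.int64)
        chrom = names[ci]
        if subj is None:
            ok = np.ones(len(pending), dtype=bool)
        else:
            ok = ~overlaps_any_arrays(chrom, start, start + ell, subj)
        placed = pending[ok]
        out_chrom[placed] = chrom[ok]
        out_start[placed] = start[ok]
        pending = pending[~ok]
    if len(pending):
        raise ValueError(
            f"could not place {len(pending)} intervals after {max_rounds} rounds "
            "of rejection sampling against the exclusion set"
        )
    return pd.DataFrame(
        {"chrom": out_chrom.astype(str), "start": out_start, "end": out_start + lengths}
    )


def assert_disjoint(df: pd.DataFrame, what: str = "intervals") -> None:
    """Raise ValueError if any two intervals in the set overlap."""
    for chrom, grp in sort_intervals(df).groupby("chrom", sort=False, observed=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
            k = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValueError(
                f"overlapping {what} on {chrom}: "
                f"[{starts[k]},{ends[k]}) and [{starts[k + 1]},{ends[k + 1]})"
            )
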