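"""VMR characterization: hypomethylation calls per cell type, size and
genomic-context statistics, cross-study region-set overlap, and size-matched
random background sampling.

A VMR is hypomethylated in a cell type when the two-stage mean — mean over
member CpGs per sample, then mean over samples of the cell type — falls
below the hypo threshold (30%).  A VMR is flagged cell-type specific when
it is hypomethylated in at least one and at most ``max_hypo_cell_types``
(3) cell types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import (
    batch_place_uniform,
    intersection_bp,
    merge_intervals,
    overlaps_any,
    total_bp,
)
from .io import MethylomeMatrix

logger = logging.getLogger(__name__)

HYPO_THRESHOLD = 30.0
MAX_HYPO_CELL_TYPES = 3
PROMOTER_BP = 2000

FEATURES = ("promoter", "exon", "intron", "intergenic")


@dataclass
class HypoCallMatrix:
    """Per-(VMR, cell type) mean methylation and hypomethylation calls.

    ``mean_meth`` has shape (n_vmrs, n_cell_types); ``hypo`` is the boolean
    call matrix; ``specific`` flags VMRs hypomethylated in 1..max cell
    types; ``hypo_cell_types`` lists the called cell types per VMR.
    """

    regions: pd.DataFrame
    cell_types: list[str]
    mean_meth: np.ndarray
    hypo: np.ndarray
    specific: np.ndarray

    def hypo_cell_types(self, i: int) -> frozenset[str]:
        return frozenset(np.array(self.cell_types)[self.hypo[i]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.mean_meth, columns=self.cell_types)
        df.insert(0, "chrom", self.regions["chrom"].to_numpy())
        df.insert(1, "start", self.regions["start"].to_numpy())
        df.insert(2, "end", self.regions["end"].to_numpy())
        df["n_hypo_cell_types"] = self.hypo.sum(axis=1)
        df["specific"] = self.specific
        return df


def _member_slices(regions: pd.DataFrame, matrix: MethylomeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Inclusive CpG row ranges per region, from merge bookkeeping when
    present, else by coordinate lookup."""
    if {"cpg_first", "cpg_last"}.issubset(regions.columns):
        return regions["cpg_first"].to_numpy(), regions["cpg_last"].to_numpy()
    sites = matrix.sites
    first = np.empty(len(regions), dtype=np.int64)
    last = np.empty(len(regions), dtype=np.int64)
    for chrom, grp in regions.groupby("chrom", sort=False, observed=True):
        rows = sites.index[sites["chrom"] == chrom]
        s_start = sites.loc[rows, "start"].to_numpy()
        lo = np.searchsorted(s_start, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(s_start, grp["end"].to_numpy(), side="left") - 1
        idx = regions.index.get_indexer(grp.index)
        first[idx] = rows.to_numpy()[np.minimum(lo, len(rows) - 1)] if len(rows) else -1
        last[idx] = rows.to_numpy()[np.clip(hi, 0, len(rows) - 1)] if len(rows) else -2
        if len(rows) == 0 or (lo > hi).any():
            raise ValueError("a region contains no CpGs present in the matrix")
    return first, last


def call_hypomethylated(
    vmrs: pd.DataFrame,
    matrix: MethylomeMatrix,
    hypo_threshold: float = HYPO_THRESHOLD,
    max_hypo_cell_types: int = MAX_HYPO_CELL_TYPES,
) -> HypoCallMatrix:
    """Call cell-type hypomethylation for each VMR.

    Per VMR: mean methylation over member CpGs for each sample, then mean
    over the samples of each cell type; hypo call where the cell-type mean
    is below ``hypo_threshold``.
    """
    if len(vmrs) == 0:
        raise ValueError("no VMRs to call")
    first, last = _member_slices(vmrs.reset_index(drop=True), matrix)
    if (last < first).any():
        raise ValueError("a VMR contains no CpGs")
    cs = np.vstack([np.zeros((1, matrix.n_samples)), np.cumsum(matrix.values, axis=0)])
    sums = cs[last + 1] - cs[first]
    counts = (last - first + 1)[:, None]
    per_sample_mean = sums / counts

    cell_types = list(dict.fromkeys(matrix.samples["cell_type"]))
    ct_arr = matrix.samples["cell_type"].to_numpy()
    ct_mean = np.column_stack(
        [per_sample_mean[:, ct_arr == ct].mean(axis=1) for ct in cell_types]
    )
    hypo = ct_mean < hypo_threshold
    n_hypo = hypo.sum(axis=1)
    specific = (n_hypo >= 1) & (n_hypo <= max_hypo_cell_types)
    return HypoCallMatrix(
        vmrs.reset_index(drop=True), cell_types, ct_mean, hypo, specific
    )


def size_and_cpg_stats(
    regions: pd.DataFrame,
    bins: tuple[int, ...] = (0, 100, 200, 500, 1000, 2000, 5000, 10_000),
) -> dict:
    """Length histogram, fractions under 1 kb / 2 kb, mean CpGs per region."""
    if len(regions) == 0:
        raise ValueError("no regions")
    lengths = (regions["end"] - regions["start"]).to_numpy()
    edges = list(bins) + [np.inf]
    hist, _ = np.histogram(lengths, bins=edges)
    out = {
        "n_regions": int(len(regions)),
        "total_bp": int(lengths.sum()),
        "length_histogram": {
            f"[{int(edges[i])},{edges[i + 1] if np.isfinite(edges[i + 1]) else 'inf'})": int(h)
            for i, h in enumerate(hist)
        },
        "frac_lt_1kb": float((lengths < 1000).mean()),
        "frac_lt_2kb": float((lengths < 2000).mean()),
        "frac_single_cpg": float((lengths == 2).mean()),
    }
    if "n_cpgs" in regions.columns:
        out["mean_cpgs_per_region"] = float(regions["n_cpgs"].mean())
    return out


# ---------------------------------------------------------------------------
# genomic context


def _gene_feature_sets(genes: pd.DataFrame, promoter_bp: int) -> dict[str, pd.DataFrame]:
    prom, exon, intron = [], [], []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            tss = int(g["tx_start"])
            prom.append((g["chrom"], max(tss - promoter_bp, 0), tss))
        else:
            tss = int(g["tx_end"])
            prom.append((g["chrom"], tss, tss + promoter_bp))
        ex_starts, ex_ends = g["exon_starts"], g["exon_ends"]
        for s, e in zip(ex_starts, ex_ends):
            exon.append((g["chrom"], s, e))
        prev = int(g["tx_start"])
        for s, e in zip(ex_starts, ex_ends):
            if s > prev:
                intron.append((g["chrom"], prev, s))
            prev = e
        if prev < int(g["tx_end"]):
            intron.append((g["chrom"], prev, int(g["tx_end"])))
    mk = lambda rows: pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return {"promoter": mk(prom), "exon": mk(exon), "intron": mk(intron)}


def tss_positions(genes: pd.DataFrame) -> pd.DataFrame:
    """TSS per gene: tx_start on +, tx_end on - (half-open convention)."""
    tss = np.where(genes["strand"] == "+", genes["tx_start"], genes["tx_end"])
    return pd.DataFrame({"chrom": genes["chrom"], "tss": tss})


def annotate_features(
    regions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_bp: int = PROMOTER_BP,
    tss_distance_from: str = "midpoint",
    allow_empty_genes: bool = False,
) -> pd.DataFrame:
    """Assign one genomic feature per region and the distance to the
    nearest TSS.

    Features by overlap (>= 1 bp) with precedence
    promoter > exon > intron > intergenic; distance is the unsigned
    distance from the region midpoint (or nearest edge, per
    ``tss_distance_from``) to the closest TSS of any gene.
    """
    if len(genes) == 0:
        if not allow_empty_genes:
            raise ValueError("empty gene set (pass allow_empty_genes=True to accept)")
        return pd.DataFrame(
            {"feature": ["intergenic"] * len(regions), "tss_distance": np.nan},
            index=regions.index,
        )
    sets = _gene_feature_sets(genes, promoter_bp)
    feature = np.full(len(regions), "intergenic", dtype="<U10")
    unset = np.ones(len(regions), dtype=bool)
    for name in ("promoter", "exon", "intron"):
        hit = overlaps_any(regions, sets[name]) & unset
        feature[hit] = name
        unset &= ~hit

    tss = tss_positions(genes)
    dist = np.full(len(regions), np.inf)
    mid = ((regions["start"] + regions["end"]) // 2).to_numpy()
    for chrom, grp in regions.reset_index(drop=True).groupby("chrom", sort=False, observed=True):
        t = np.sort(tss.loc[tss["chrom"] == chrom, "tss"].to_numpy())
        if len(t) == 0:
            continue
        idx = grp.index.to_numpy()
        if tss_distance_from == "midpoint":
            pts = mid[idx][:, None]
            d = np.abs(t[None, :] - pts).min(axis=1)
        elif tss_distance_from == "edge":
            s = grp["start"].to_numpy()[:, None]
            e = grp["end"].to_numpy()[:, None]
            inside = (t[None, :] >= s) & (t[None, :] < e)
            d = np.minimum(np.abs(t[None, :] - s), np.abs(t[None, :] - (e - 1)))
            d[inside] = 0
            d = d.min(axis=1)
        else:
            raise ValueError("tss_distance_from must be 'midpoint' or 'edge'")
        dist[idx] = d
    return pd.DataFrame({"feature": feature, "tss_distance": dist})


def region_set_overlap(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Symmetric overlap report between two interval sets.

    Each set is merged internally first; the overlap predicate is >= 1 bp.
    """
    am, bm = merge_intervals(a), merge_intervals(b)
    frac_a = float(overlaps_any(am, bm).mean()) if len(am) else 0.0
    frac_b = float(overlaps_any(bm, am).mean()) if len(bm) else 0.0
    return {
        "n_a": len(am),
        "n_b": len(bm),
        "frac_a_overlapping_b": frac_a,
        "frac_b_overlapping_a": frac_b,
        "bp_a": total_bp(am, merge=False),
        "bp_b": total_bp(bm, merge=False),
        "bp_intersection": intersection_bp(am, bm),
    }


def background_regions(
    template: pd.DataFrame,
    chrom_lengths: dict[str, int],
    blacklist: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
    match_chrom: bool = False,
) -> pd.DataFrame:
    """Random regions size-matched to ``template``: same count and the
    identical length multiset, placed uniformly over the non-blacklist
    genome (per-chromosome matched when ``match_chrom``)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = (template["end"] - template["start"]).to_numpy()
    if not match_chrom:
        return batch_place_uniform(rng, chrom_lengths, lengths, blacklist)
    parts = []
    for chrom, grp in template.groupby("chrom", sort=False, observed=True):
        sub = batch_place_uniform(
            rng,
            {str(chrom): chrom_lengths[str(chrom)]},
            (grp["end"] - grp["start"]).to_numpy(),
            None if blacklist is None else blacklist[blacklist["chrom"] == chrom],
        )
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
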