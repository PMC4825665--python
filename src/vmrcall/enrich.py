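"""Enrichment statistics for VMRs against annotation interval sets.

All fold enrichments are computed against size-matched randomly selected
background regions: fold = (number of foreground regions overlapping the
annotation) / (number of background regions overlapping it).  Significance
comes from a one-sided Fisher's exact test on the 2x2 overlap table
(two-sided by flag).  Chromatin-state enrichment uses region centers;
GWAS-trait enrichment uses a hypergeometric test against the full catalog
with Benjamini-Hochberg FDR within each cell type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._intervals import assert_disjoint, overlaps_any, points_in_intervals
from .io import CPG_WIDTH

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One enrichment comparison: counts, fold, test, p (and q when part
    of a corrected batch).  ``fold`` is +inf with ``undefined=True`` when
    the background count is zero."""

    unit: str
    fg_count: int
    bg_count: int
    fg_total: int
    bg_total: int
    fold: float
    test: str
    p: float
    q: float | None = None
    undefined: bool = False


def fold_enrichment(
    foreground: pd.DataFrame,
    annotation: pd.DataFrame,
    background: pd.DataFrame,
    unit: str = "",
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fold enrichment of an annotation in foreground vs background regions.

    ``background`` must be size-matched (same region count) to the
    foreground; the overlap predicate is >= 1 bp.
    """
    if len(background) != len(foreground):
        raise ValueError("background must be size-matched (same count) to foreground")
    a = int(overlaps_any(foreground, annotation).sum())
    b = int(overlaps_any(background, annotation).sum())
    n_fg, n_bg = len(foreground), len(background)
    undefined = b == 0
    fold = float("inf") if undefined else a / b
    table = [[a, n_fg - a], [b, n_bg - b]]
    p = float(stats.fisher_exact(table, alternative=alternative)[1])
    return EnrichmentResult(
        unit, a, b, n_fg, n_bg, fold, f"fisher_{alternative}", p, undefined=undefined
    )


def region_centers(regions: pd.DataFrame) -> np.ndarray:
    """Center point per region: (start + end) // 2 (a length-2 region
    [100, 102) has center 101)."""
    return ((regions["start"] + regions["end"]) // 2).to_numpy()


def center_state_enrichment(
    foreground: pd.DataFrame,
    states: pd.DataFrame,
    background: pd.DataFrame,
    background_rule: str = "center",
) -> pd.DataFrame:
    """Per-state log2 fold enrichment by region-center containment.

    States must be disjoint labeled intervals.  Both foreground and
    background regions are counted by where their center point falls
    (``background_rule="overlap"`` switches the background to the >= 1 bp
    any-overlap rule instead).
    """
    if "label" not in states.columns:
        raise ValueError("states need a 'label' column")
    assert_disjoint(states, "state intervals")

    def center_counts(regions: pd.DataFrame) -> pd.Series:
        centers = region_centers(regions)
        chroms = regions["chrom"].to_numpy()
        hit = np.full(len(regions), "", dtype=object)
        for chrom, grp in states.groupby("chrom", sort=False, observed=True):
            s = grp.sort_values("start")
            mask = chroms == chrom
            i = np.searchsorted(s["end"].to_numpy(), centers[mask], side="right")
            ok = (i < len(s)) & (s["start"].to_numpy()[np.minimum(i, len(s) - 1)] <= centers[mask])
            lab = np.where(ok, s["label"].to_numpy()[np.minimum(i, len(s) - 1)], "")
            hit[mask] = lab
        return pd.Series(hit).value_counts()

    fg_counts = center_counts(foreground)
    if background_rule == "center":
        bg_counts = center_counts(background)
    elif background_rule == "overlap":
        bg_counts = pd.Series(
            {
                lab: int(overlaps_any(background, grp).sum())
                for lab, grp in states.groupby("label", observed=True)
            }
        )
    else:
        raise ValueError("background_rule must be 'center' or 'overlap'")
    labels = sorted(states["label"].unique())
    rows = []
    for lab in labels:
        fg = int(fg_counts.get(lab, 0))
        bg = int(bg_counts.get(lab, 0))
        if bg == 0:
            log2_fold = np.inf if fg > 0 else np.nan
        elif fg == 0:
            log2_fold = -np.inf
        else:
            log2_fold = float(np.log2(fg / bg))
        rows.append(
            {"state": lab, "fg_count": fg, "bg_count": bg,
             "log2_fold": log2_fold, "undefined": bg == 0}
        )
    return pd.DataFrame(rows)


def tfbs_overlap_profile(
    vmrs: pd.DataFrame, peak_sets: dict[str, pd.DataFrame]
) -> dict:
    """Per-VMR count of distinct TF peak sets overlapped (>= 1 bp) and the
    fractions of VMRs overlapping 0, 1, 2, or >= 3 TFs."""
    counts = np.zeros(len(vmrs), dtype=np.int64)
    for tf, peaks in peak_sets.items():
        counts += overlaps_any(vmrs, peaks)
    n = max(len(vmrs), 1)
    fractions = {
        "0": float((counts == 0).sum() / n),
        "1": float((counts == 1).sum() / n),
        "2": float((counts == 2).sum() / n),
        "3+": float((counts >= 3).sum() / n),
    }
    return {"counts": counts, "fractions": fractions,
            "frac_at_least_one": float((counts >= 1).sum() / n)}


def tissue_anova(
    folds: pd.DataFrame,
    tissue_of: dict[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-TF one-way ANOVA of fold enrichments grouped by tissue type.

    ``folds`` has columns tf, cell_type, fold (one fold per cell type —
    the replication unit); ``tissue_of`` maps cell type to tissue.
    Benjamini-Hochberg correction is applied across the TF family.  TFs
    whose folds span fewer than two tissues, or with every group a single
    observation, are excluded with a reason.
    """
    tissue_of = dict(tissue_of)
    rows = []
    for tf, grp in folds.groupby("tf", observed=True):
        tissues = grp["cell_type"].map(tissue_of)
        groups = [g["fold"].to_numpy(dtype=float) for _, g in grp.groupby(tissues, observed=True)]
        if len(groups) < 2:
            rows.append({"tf": tf, "F": np.nan, "p": np.nan, "excluded": "single tissue"})
            continue
        if all(len(g) == 1 for g in groups):
            rows.append({"tf": tf, "F": np.nan, "p": np.nan,
                         "excluded": "all groups single observation"})
            continue
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb = len(groups) - 1
        dfw = len(allv) - len(groups)
        if ssw == 0 and ssb > 0:
            rows.append({"tf": tf, "F": np.inf, "p": 0.0, "excluded": "",
                         "exact_separation": True})
            continue
        if ssb == 0:
            rows.append({"tf": tf, "F": 0.0, "p": 1.0, "excluded": ""})
            continue
        F = (ssb / dfb) / (ssw / dfw)
        p = float(stats.f.sf(F, dfb, dfw))
        rows.append({"tf": tf, "F": float(F), "p": p, "excluded": ""})
    out = pd.DataFrame(rows)
    if "exact_separation" not in out.columns:
        out["exact_separation"] = False
    out["exact_separation"] = out["exact_separation"].fillna(False)
    tested = out["excluded"] == ""
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# GWAS variants


def gwas_variant_enrichment(
    variants: pd.DataFrame,
    hypo_vmrs: pd.DataFrame,
    background: pd.DataFrame,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Fold enrichment of GWAS variants (1-bp points) in hypomethylated
    VMRs versus size-matched background regions, with Fisher's exact p."""
    if len(background) != len(hypo_vmrs):
        raise ValueError("background must be size-matched to the VMR set")
    chroms = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    in_fg = points_in_intervals(chroms, pos, hypo_vmrs)
    in_bg = points_in_intervals(chroms, pos, background)
    a, b = int(in_fg.sum()), int(in_bg.sum())
    n = len(variants)
    undefined = b == 0
    fold = float("inf") if undefined else a / b
    p = float(stats.fisher_exact([[a, n - a], [b, n - b]], alternative=alternative)[1])
    return EnrichmentResult(
        "gwas_variants", a, b, n, n, fold, f"fisher_{alternative}", p, undefined=undefined
    )


def variants_in_regions(variants: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Subset of variant rows whose position falls inside the region set."""
    mask = points_in_intervals(
        variants["chrom"].to_numpy(), variants["pos"].to_numpy(), regions
    )
    return variants.loc[mask].reset_index(drop=True)


def trait_enrichment(
    variants_in_vmrs: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Per-trait hypergeometric enrichment of the VMR variant subset
    against the full catalog, BH-corrected within the call.

    Population N = catalog rows, K = rows with the trait, n = rows in the
    VMR subset, k = subset rows with the trait; p = P(X >= k) under
    Hypergeometric(N, K, n); fold = (k/n) / (K/N).
    """
    cat_keys = set(zip(catalog["rsid"], catalog["trait"]))
    sub_keys = list(zip(variants_in_vmrs["rsid"], variants_in_vmrs["trait"]))
    missing = [k for k in sub_keys if k not in cat_keys]
    if missing:
        raise ValueError(
            f"{len(missing)} (rsid, trait) rows absent from the catalog, "
            f"e.g. {missing[0]}: inconsistent subset"
        )
    N = len(catalog)
    n = len(variants_in_vmrs)
    rows = []
    K_by_trait = catalog["trait"].value_counts()
    k_by_trait = variants_in_vmrs["trait"].value_counts()
    for trait, K in K_by_trait.items():
        k = int(k_by_trait.get(trait, 0))
        p = float(stats.hypergeom.sf(k - 1, N, int(K), n))
        fold = (k / n) / (K / N) if n > 0 else np.nan
        rows.append({"trait": trait, "k": k, "K": int(K), "n": n, "N": N,
                     "fold": fold, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def cpg_context_variants(
    variants: pd.DataFrame,
    sites: pd.DataFrame,
    categories: np.ndarray | None = None,
) -> pd.DataFrame:
    """Variants whose position falls within a CpG dinucleotide
    [site.start, site.end); retained rows are annotated with the CpG's
    category when ``categories`` is given."""
    result = []
    site_idx = np.full(len(variants), -1, dtype=np.int64)
    for chrom, grp in variants.reset_index(drop=True).groupby("chrom", sort=False, observed=True):
        sub = sites[sites["chrom"] == chrom]
        if len(sub) == 0:
            continue
        s_start = sub["start"].to_numpy()
        pos = grp["pos"].to_numpy()
        i = np.searchsorted(s_start, pos, side="right") - 1
        ok = (i >= 0) & (pos < s_start[np.maximum(i, 0)] + CPG_WIDTH)
        idx = grp.index.to_numpy()
        site_idx[idx[ok]] = sub.index.to_numpy()[i[ok]]
    keep = site_idx >= 0
    out = variants.reset_index(drop=True).loc[keep].copy()
    if categories is not None:
        out["cpg_category"] = np.asarray(categories)[site_idx[keep]]
    return out.reset_index(drop=True)
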