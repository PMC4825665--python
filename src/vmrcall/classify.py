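"""Four-way CpG categorization from cross-sample methylation vectors.

Every autosomal CpG is assigned one of four categories from its vector of
methylation percentages across samples:

* ``U`` constitutively unmethylated — every value below the low cutoff (30%);
* ``M`` constitutively methylated — every value above the high cutoff (70%);
* ``I`` intermediately methylated — at least ``i_min_libraries`` values
  (50 of 54 in the reference configuration) inside [low, high];
* ``V`` variably methylated — the gap between the third-highest and the
  third-lowest value is at least ``v_gap`` (40 percentage points).

CpGs matched by none of the seed rules are then labeled by k-nearest
neighbors (k = 4, Euclidean distance on the full cross-sample vector),
iterated up to 10 times with newly labeled CpGs joining the reference set,
stopping early once no label changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .io import MethylomeMatrix

logger = logging.getLogger(__name__)

CATEGORIES: tuple[str, ...] = ("U", "M", "I", "V")
UNASSIGNED = "?"

#: Reference number of libraries behind the default i_min_libraries.
REFERENCE_N_SAMPLES = 54


@dataclass(frozen=True)
class CategoryThresholds:
    """Cutoffs for the seed rules and the k-NN refinement.

    ``i_min_libraries`` is calibrated for 54 samples; use
    :meth:`scaled_to` when classifying a different number of samples.
    ``i_precedence`` resolves CpGs matching both the I and the V rule
    toward I (True, default) or V (False).
    """

    low: float = 30.0
    high: float = 70.0
    v_gap: float = 40.0
    i_min_libraries: int = 50
    v_rank: int = 3
    knn_k: int = 4
    knn_max_iter: int = 10
    i_precedence: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high < 100):
            raise ValueError("need 0 < low < high < 100")
        if self.v_gap <= 0 or self.v_rank < 1 or self.knn_k < 1:
            raise ValueError("v_gap > 0, v_rank >= 1 and knn_k >= 1 required")

    def scaled_to(self, n_samples: int) -> "CategoryThresholds":
        """Rescale i_min_libraries as ceil(50/54 * n_samples)."""
        scaled = math.ceil(self.i_min_libraries / REFERENCE_N_SAMPLES * n_samples)
        return replace(self, i_min_libraries=scaled)


@dataclass
class CategorizedCpGs:
    """Per-CpG category labels with provenance.

    ``categories`` holds one of U/M/I/V (or ``?`` mid-refinement);
    ``source`` is "seed" or "knn"; ``iteration`` is the k-NN iteration at
    which the label last changed (0 for seed labels).
    ``iteration_changes`` records, per k-NN iteration, how many labels
    changed.
    """

    categories: np.ndarray
    source: np.ndarray
    iteration: np.ndarray
    iteration_changes: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.categories)

    @property
    def complete(self) -> bool:
        return not (self.categories == UNASSIGNED).any()


def _rule_masks(values: np.ndarray, t: CategoryThresholds) -> dict[str, np.ndarray]:
    """Boolean predicate per seed rule, evaluated on all rows."""
    below = values < t.low
    above = values > t.high
    mid = (values >= t.low) & (values <= t.high)
    u = below.all(axis=1)
    m = above.all(axis=1)
    i = mid.sum(axis=1) >= t.i_min_libraries
    srt = np.sort(values, axis=1)
    third_low = srt[:, t.v_rank - 1]
    third_high = srt[:, -t.v_rank]
    v = (third_high - third_low) >= t.v_gap
    return {"U": u, "M": m, "I": i, "V": v}


def seed_classify_matrix(values: np.ndarray, t: CategoryThresholds) -> np.ndarray:
    """Vectorized seed classification of every row; returns U/M/I/V/?.

    Rule precedence is U, M, I, V (or U, M, V, I when ``i_precedence`` is
    False); rows matching no rule get the UNASSIGNED sentinel.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D sites x samples array")
    if np.isnan(values).any():
        raise ValueError("seed classification requires complete rows (no NaN)")
    if values.shape[1] < 2 * t.v_rank:
        logger.warning(
            "only %d samples; the rank-%d gap rule needs >= %d to be meaningful",
            values.shape[1], t.v_rank, 2 * t.v_rank,
        )
    masks = _rule_masks(values, t)
    order = ("U", "M", "I", "V") if t.i_precedence else ("U", "M", "V", "I")
    labels = np.full(values.shape[0], UNASSIGNED, dtype="<U1")
    for cat in order:
        labels[(labels == UNASSIGNED) & masks[cat]] = cat
    n_conflict = int((masks["I"] & masks["V"]).sum())
    if n_conflict:
        logger.info("%d CpGs match both the I and the V rule; precedence=%s",
                    n_conflict, "I" if t.i_precedence else "V")
    return labels


def seed_classify(row: np.ndarray, t: CategoryThresholds | None = None) -> str:
    """Classify a single cross-sample methylation vector by the seed rules."""
    t = t or CategoryThresholds()
    return str(seed_classify_matrix(np.asarray(row, dtype=float)[None, :], t)[0])


def seed_classify_all(matrix: MethylomeMatrix, t: CategoryThresholds | None = None) -> CategorizedCpGs:
    """Seed-classify every CpG of a methylome matrix."""
    t = t or CategoryThresholds()
    matrix.require_complete()
    labels = seed_classify_matrix(matrix.values, t)
    source = np.where(labels == UNASSIGNED, "", "seed").astype("<U4")
    return CategorizedCpGs(labels, source, np.zeros(len(labels), dtype=np.int32))


def _vote(neigh_labels: np.ndarray) -> np.ndarray:
    """Majority vote per row; ties go to the nearest neighbor whose label
    is among the tied majority labels.  ``neigh_labels`` rows are already
    ordered by increasing distance."""
    n = neigh_labels.shape[0]
    out = np.empty(n, dtype="<U1")
    cats = np.array(CATEGORIES)
    counts = np.stack([(neigh_labels == c).sum(axis=1) for c in cats], axis=1)
    top = counts.max(axis=1)
    is_tied = (counts == top[:, None]).sum(axis=1) > 1
    out[~is_tied] = cats[np.argmax(counts[~is_tied], axis=1)]
    for i in np.nonzero(is_tied)[0]:
        tied = set(cats[counts[i] == top[i]])
        for lab in neigh_labels[i]:
            if lab in tied:
                out[i] = lab
                break
    return out


def knn_refine(
    matrix: MethylomeMatrix,
    seeds: CategorizedCpGs,
    t: CategoryThresholds | None = None,
    relabel_seeds: bool = False,
) -> CategorizedCpGs:
    """Assign every unassigned CpG by k-NN on cross-sample vectors.

    Iteration 1 uses only seed-labeled CpGs as the reference set; later
    iterations include every labeled CpG (self excluded) and re-vote, up to
    ``knn_max_iter`` rounds with early stop when no label changes.  Seed
    labels are frozen unless ``relabel_seeds`` is set.
    """
    t = t or CategoryThresholds()
    labels = seeds.categories.copy()
    source = seeds.source.copy()
    iteration = seeds.iteration.copy()
    seed_mask = labels != UNASSIGNED
    if not seed_mask.any():
        raise ValueError("no seed-labeled CpGs: k-NN has no reference set")
    for cat in CATEGORIES:
        n_cat = int((labels == cat).sum())
        if 0 < n_cat < t.knn_k:
            logger.warning("category %s has only %d seed CpGs (< k=%d)", cat, n_cat, t.knn_k)
    query_mask = ~seed_mask | relabel_seeds
    query_idx = np.nonzero(query_mask)[0]
    if len(query_idx) == 0:
        return CategorizedCpGs(labels, source, iteration, [])

    X = np.asarray(matrix.values, dtype=float)
    changes: list[int] = []
    for it in range(1, t.knn_max_iter + 1):
        if it == 1 and not relabel_seeds:
            ref_idx = np.nonzero(seed_mask)[0]
            self_in_ref = False
        else:
            ref_idx = np.nonzero(labels != UNASSIGNED)[0]
            self_in_ref = True
        k = t.knn_k + (1 if self_in_ref else 0)
        nn = NearestNeighbors(n_neighbors=min(k, len(ref_idx))).fit(X[ref_idx])
        _, ind = nn.kneighbors(X[query_idx])
        neigh_global = ref_idx[ind]
        if self_in_ref and neigh_global.shape[1] > 1:
            # drop the self match; where the self row was not returned
            # (identical duplicate vectors), drop the farthest instead so
            # every row keeps exactly the same number of neighbors
            keep = neigh_global != query_idx[:, None]
            surplus = keep.sum(axis=1) == neigh_global.shape[1]
            keep[surplus, -1] = False
            neigh_global = neigh_global[keep].reshape(len(query_idx), neigh_global.shape[1] - 1)
        neigh_labels = labels[neigh_global]
        new_labels = _vote(neigh_labels)
        changed = int((new_labels != labels[query_idx]).sum())
        iteration[query_idx[new_labels != labels[query_idx]]] = it
        labels[query_idx] = new_labels
        changes.append(changed)
        if changed == 0:
            break
    source[query_idx] = "knn"
    out = CategorizedCpGs(labels, source, iteration, changes)
    assert out.complete
    return out


def classify(
    matrix: MethylomeMatrix,
    t: CategoryThresholds | None = None,
    scale_i_min: bool = True,
    relabel_seeds: bool = False,
) -> CategorizedCpGs:
    """Seed classification followed by k-NN refinement (the full classifier)."""
    t = t or CategoryThresholds()
    if scale_i_min and matrix.n_samples != REFERENCE_N_SAMPLES:
        t = t.scaled_to(matrix.n_samples)
    seeds = seed_classify_all(matrix, t)
    if seeds.complete:
        return seeds
    return knn_refine(matrix, seeds, t, relabel_seeds=relabel_seeds)


# ---------------------------------------------------------------------------
# summaries


def category_summary(cats: CategorizedCpGs) -> pd.DataFrame:
    """Per-category counts and fractions; fractions sum to 1."""
    if len(cats) == 0:
        raise ValueError("no CpGs to summarize")
    if not cats.complete:
        raise ValueError("classification incomplete: UNASSIGNED CpGs remain")
    counts = {c: int((cats.categories == c).sum()) for c in CATEGORIES}
    df = pd.DataFrame({"category": list(counts), "count": list(counts.values())})
    df["fraction"] = df["count"] / df["count"].sum()
    return df


def per_sample_level_summary(matrix: MethylomeMatrix, t: CategoryThresholds | None = None) -> pd.DataFrame:
    """Per-sample fractions of CpGs below/within/above [low, high] plus mean.

    Mirrors the per-methylome summaries: the "unmethylated" fraction is
    values < low, "intermediate" is [low, high], "methylated" is > high.
    """
    t = t or CategoryThresholds()
    v = matrix.values
    with np.errstate(invalid="ignore"):
        n_ok = (~np.isnan(v)).sum(axis=0)
        frac_low = np.nansum(v < t.low, axis=0) / n_ok
        frac_mid = np.nansum((v >= t.low) & (v <= t.high), axis=0) / n_ok
        frac_high = np.nansum(v > t.high, axis=0) / n_ok
        mean = np.nanmean(v, axis=0)
    return pd.DataFrame(
        {
            "sample_id": matrix.samples["sample_id"].to_numpy(),
            "frac_unmethylated": frac_low,
            "frac_intermediate": frac_mid,
            "frac_methylated": frac_high,
            "mean_methylation": mean,
        }
    )


def min_methylation_fraction(matrix: MethylomeMatrix, threshold: float = 30.0) -> float:
    """Fraction of CpGs whose minimum methylation across samples is below
    ``threshold`` — the CpGs that are unmethylated in at least one sample."""
    if matrix.n_sites == 0:
        raise ValueError("empty matrix")
    return float((np.nanmin(matrix.values, axis=1) < threshold).mean())
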