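"""Cross-platform concordance, subsampling saturation, and the 1-kb
windowed methylation matrix.

Concordance between two per-CpG methylation vectors (e.g. a CRF-predicted
methylome and a bisulfite reference) is the fraction of comparable CpGs
whose absolute difference is strictly below the tolerance (25 percentage
points), restricted to reference CpGs with read coverage of at least 10.

Saturation draws random sample subsets of increasing size and records the
fraction of CpGs the variability (rank-gap) seed rule calls variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CategoryThresholds
from .io import MethylomeMatrix

logger = logging.getLogger(__name__)

CONCORDANCE_TOLERANCE = 25.0
MIN_COVERAGE = 10


@dataclass
class ConcordanceReport:
    n_compared: int
    n_concordant: int
    concordance: float
    tolerance: float
    min_coverage: int


def concordance(
    a: np.ndarray,
    b: np.ndarray,
    coverage: np.ndarray | None = None,
    tolerance: float = CONCORDANCE_TOLERANCE,
    min_coverage: int = MIN_COVERAGE,
) -> ConcordanceReport:
    """Fraction of CpGs with |a - b| strictly below ``tolerance``.

    ``a`` and ``b`` must be aligned on the same CpG index; ``coverage``
    carries per-CpG read coverage of the reference ``b`` and restricts the
    comparison to CpGs with coverage >= ``min_coverage``.  NaNs on either
    side are excluded.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must share a CpG index (same length)")
    ok = ~np.isnan(a) & ~np.isnan(b)
    if coverage is not None:
        ok &= np.asarray(coverage) >= min_coverage
    n = int(ok.sum())
    if n == 0:
        raise ValueError("zero comparable CpGs after coverage filtering")
    conc = int((np.abs(a[ok] - b[ok]) < tolerance).sum())
    return ConcordanceReport(n, conc, conc / n, tolerance, min_coverage)


def v_seed_fraction(values: np.ndarray, t: CategoryThresholds) -> float:
    """Fraction of rows where the variability seed rule fires: the gap
    between the rank-3-from-top and rank-3-from-bottom value >= v_gap."""
    srt = np.sort(values, axis=1)
    gap = srt[:, -t.v_rank] - srt[:, t.v_rank - 1]
    return float((gap >= t.v_gap).mean())


@dataclass
class SaturationCurve:
    """Per-subset-size mean/SD of the V-called CpG fraction."""

    table: pd.DataFrame  # columns: n, mean, sd, plus one column per iteration
    iterations: int

    @property
    def means(self) -> pd.Series:
        return self.table.set_index("n")["mean"]


def saturation(
    matrix: MethylomeMatrix,
    t: CategoryThresholds | None = None,
    n_range: tuple[int, int] | list[int] | None = None,
    iterations: int = 10,
    seed: int = 0,
    full_pipeline: bool = False,
) -> SaturationCurve:
    """Fraction of CpGs called variable as a function of sample count.

    For each subset size n, ``iterations`` random subsets are drawn without
    replacement and the V seed rule applied per subset (the full
    seed+k-NN classifier with ``full_pipeline=True``).  At n equal to the
    full sample count every draw is the complete set, so the spread is
    exactly zero.
    """
    t = t or CategoryThresholds()
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if n_range is None:
        n_range = (min(6, matrix.n_samples), matrix.n_samples)
    ns = list(range(n_range[0], n_range[1] + 1)) if isinstance(n_range, tuple) else list(n_range)
    if min(ns) < 3:
        raise ValueError("subset size below 3: rank-3 statistics undefined")
    if min(ns) < 6:
        logger.warning("subset sizes below 6: rank-3 gap statistics are degenerate")
    if max(ns) > matrix.n_samples:
        raise ValueError("subset size exceeds the number of samples")
    rng = np.random.default_rng(seed)
    rows = []
    for n in ns:
        fracs = []
        for _ in range(iterations):
            cols = rng.choice(matrix.n_samples, size=n, replace=False)
            if full_pipeline:
                from .classify import classify

                sub = MethylomeMatrix(
                    matrix.sites, matrix.samples.iloc[cols].reset_index(drop=True),
                    matrix.values[:, cols],
                )
                cats = classify(sub, t)
                fracs.append(float((cats.categories == "V").mean()))
            else:
                fracs.append(v_seed_fraction(matrix.values[:, cols], t))
        rows.append(
            {"n": n, "mean": float(np.mean(fracs)), "sd": float(np.std(fracs)),
             **{f"iter_{i + 1}": f for i, f in enumerate(fracs)}}
        )
    return SaturationCurve(pd.DataFrame(rows), iterations)


def window_matrix(
    matrix: MethylomeMatrix,
    window: int = 1000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Mean methylation per fixed genomic window per sample.

    Windows tile each chromosome from 0 in steps of ``window``; a window's
    value is the mean over CpGs whose start falls inside it, NaN when the
    window holds no CpG.  Rows are in genomic order with an ``n_cpgs``
    column for CpG-weighted aggregation.  When ``chrom_lengths`` is given
    empty trailing windows are included; otherwise windows run to the last
    CpG per chromosome.
    """
    frames = []
    sample_ids = list(matrix.samples["sample_id"])
    for chrom, grp in matrix.sites.groupby("chrom", sort=True, observed=True):
        idx = grp.index.to_numpy()
        win = (grp["start"].to_numpy() // window).astype(np.int64)
        length = (chrom_lengths or {}).get(str(chrom))
        n_win = int(-(-length // window)) if length else int(win.max()) + 1
        counts = np.bincount(win, minlength=n_win)
        sums = np.zeros((n_win, matrix.n_samples))
        for j in range(matrix.n_samples):
            sums[:, j] = np.bincount(win, weights=matrix.values[idx, j], minlength=n_win)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(counts[:, None] > 0, sums / np.maximum(counts[:, None], 1), np.nan)
        df = pd.DataFrame(means, columns=sample_ids)
        df.insert(0, "chrom", str(chrom))
        df.insert(1, "start", np.arange(n_win) * window)
        df.insert(2, "end", np.minimum(np.arange(1, n_win + 1) * window, length or (n_win * window)))
        df["n_cpgs"] = counts
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
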