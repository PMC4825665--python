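"""Seed-rule classification and k-NN refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmrcall.classify import (
    CategorizedCpGs,
    CategoryThresholds,
    UNASSIGNED,
    category_summary,
    classify,
    knn_refine,
    min_methylation_fraction,
    per_sample_level_summary,
    seed_classify,
    seed_classify_matrix,
)
from vmrcall.io import MethylomeMatrix
from vmrcall.simulate import SimConfig, simulate_methylomes

T = CategoryThresholds()


def brute_force_seed(vec, t=T):
    """Independent scalar re-evaluation of the four seed-rule predicates."""
    vec = list(vec)
    u = all(v < t.low for v in vec)
    m = all(v > t.high for v in vec)
    i = sum(t.low <= v <= t.high for v in vec) >= t.i_min_libraries
    s = sorted(vec)
    v = (s[-t.v_rank] - s[t.v_rank - 1]) >= t.v_gap
    for fired, label in ((u, "U"), (m, "M"), (i, "I"), (v, "V")):
        if fired:
            return label
    return UNASSIGNED


@pytest.mark.parametrize(
    "vec, expected",
    [
        ([10.0] * 54, "U"),
        ([90.0] * 54, "M"),
        ([50.0] * 54, "I"),
        # 3rd-highest 85, 3rd-lowest 20, gap 65 >= 40, few mid-range values
        ([20.0] * 10 + [85.0] * 44, "V"),
        # 50 of 54 mid-range: I fires (and takes precedence over V)
        ([50.0] * 50 + [10.0, 10.0, 90.0, 90.0], "I"),
        # alternating 28/72: 3rd-highest 72 - 3rd-lowest 28 = 44 >= 40 -> V
        ([28.0, 72.0] * 27, "V"),
        # matches nothing: two low outliers only
        ([80.0] * 52 + [60.0, 10.0], UNASSIGNED),
    ],
)
def test_seed_rules(vec, expected):
    assert seed_classify(np.array(vec)) == expected


def test_i_vs_v_precedence_switch():
    vec = np.array([50.0] * 50 + [10.0, 10.0, 90.0, 90.0])
    assert seed_classify(vec, T) == "I"
    t_v = CategoryThresholds(i_precedence=False)
    # with V precedence the same vector goes to V (3rd-gap 90-10 is not
    # reached: 3rd highest is 50 -> check the actual gap first)
    s = np.sort(vec)
    if s[-3] - s[2] >= t_v.v_gap:
        assert seed_classify(vec, t_v) == "V"
    else:
        assert seed_classify(vec, t_v) == "I"


def _mixed_vectors(rng, n, width=54):
    """Vectors spanning all rule branches: constant-low/high, mid-band,
    bimodal, and fully uniform rows."""
    kinds = rng.integers(0, 5, size=n)
    out = np.empty((n, width))
    out[kinds == 0] = rng.uniform(0, 35, size=(int((kinds == 0).sum()), width))
    out[kinds == 1] = rng.uniform(65, 100, size=(int((kinds == 1).sum()), width))
    out[kinds == 2] = rng.uniform(25, 75, size=(int((kinds == 2).sum()), width))
    k3 = int((kinds == 3).sum())
    lowhigh = np.where(rng.random((k3, width)) < 0.5, rng.uniform(0, 30, (k3, width)),
                       rng.uniform(70, 100, (k3, width)))
    out[kinds == 3] = lowhigh
    out[kinds == 4] = rng.uniform(0, 100, size=(int((kinds == 4).sum()), width))
    return out


def test_seed_classify_matches_brute_force_oracle(rng):
    vectors = _mixed_vectors(rng, 10_000)
    fast = seed_classify_matrix(vectors, T)
    slow = np.array([brute_force_seed(v) for v in vectors])
    assert (fast == slow).all()


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.floats(min_value=0, max_value=100, allow_nan=False), min_size=6, max_size=60))
def test_seed_classify_single_vector_property(vec):
    t = CategoryThresholds(i_min_libraries=max(1, len(vec) - 4))
    assert seed_classify(np.array(vec), t) == brute_force_seed(vec, t)


def test_v_fraction_monotone_in_gap(small_fixture):
    matrix, _ = small_fixture
    fracs = []
    for gap in (20.0, 40.0, 60.0, 80.0):
        labels = seed_classify_matrix(matrix.values, CategoryThresholds(v_gap=gap))
        fracs.append((labels == "V").mean())
    assert all(a >= b for a, b in zip(fracs, fracs[1:]))


def test_missing_values_rejected():
    vals = np.full((3, 6), 50.0)
    vals[1, 2] = np.nan
    with pytest.raises(ValueError, match="complete"):
        seed_classify_matrix(vals, CategoryThresholds(i_min_libraries=5))


# ---------------------------------------------------------------------------
# k-NN refinement


def _toy_matrix(values):
    import pandas as pd

    n, k = values.shape
    sites = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(n) * 100, "end": np.arange(n) * 100 + 2}
    )
    samples = pd.DataFrame(
        {"sample_id": [f"s{j}" for j in range(k)],
         "cell_type": [f"c{j}" for j in range(k)],
         "tissue_type": ["t"] * k}
    )
    return MethylomeMatrix(sites, samples, values.astype(float))


def test_knn_unanimous_vote():
    t = CategoryThresholds(knn_k=4, i_min_libraries=4)
    vals = np.vstack([
        np.full((6, 4), 10.0) + np.arange(6)[:, None],  # U seeds
        np.full((6, 4), 90.0) - np.arange(6)[:, None],  # M seeds
        np.full((1, 4), 31.0),                          # unassigned, near U
    ])
    m = _toy_matrix(vals)
    seeds = CategorizedCpGs(
        np.array(["U"] * 6 + ["M"] * 6 + [UNASSIGNED]),
        np.array(["seed"] * 12 + [""]),
        np.zeros(13, dtype=np.int32),
    )
    out = knn_refine(m, seeds, t)
    assert out.categories[-1] == "U"
    assert out.source[-1] == "knn"
    assert out.complete


def test_knn_tie_goes_to_nearest_neighbor():
    t = CategoryThresholds(knn_k=4, i_min_libraries=4)
    # 4 nearest of the query at 10.9 are 10 (U, d=0.9), 12 (M, d=1.1),
    # 13 (U, d=2.1), 15 (M, d=4.1): a 2-2 tie, the single nearest is U
    vals = np.array([[10.0], [15.0], [12.0], [13.0], [10.9], [30.0], [40.0]])
    vals = np.repeat(vals, 4, axis=1)
    m = _toy_matrix(vals)
    labels = np.array(["U", "M", "M", "U", UNASSIGNED, "U", "M"])
    seeds = CategorizedCpGs(labels, np.where(labels == UNASSIGNED, "", "seed").astype("<U4"),
                            np.zeros(7, dtype=np.int32))
    out = knn_refine(m, seeds, t)
    assert out.categories[4] == "U"


def test_knn_masked_label_recovery(default_fixture, rng):
    matrix, truth = default_fixture
    labels = truth.categories.copy()
    mask = rng.random(len(labels)) < 0.05
    masked = labels.copy()
    masked[mask] = UNASSIGNED
    seeds = CategorizedCpGs(
        masked, np.where(mask, "", "seed").astype("<U4"), np.zeros(len(labels), dtype=np.int32)
    )
    out = knn_refine(matrix, seeds, CategoryThresholds())
    recovery = (out.categories[mask] == labels[mask]).mean()
    assert recovery >= 0.99
    # seed labels stay frozen
    assert (out.categories[~mask] == labels[~mask]).all()


def test_knn_row_permutation_equivariance(rng):
    cfg = SimConfig(n_cpgs=2000, noise_sd=8.0, seed=21)
    matrix, _ = simulate_methylomes(cfg)
    cats = classify(matrix)
    perm = rng.permutation(len(cats.categories))
    import pandas as pd

    permuted = MethylomeMatrix(
        matrix.sites.iloc[perm].reset_index(drop=True), matrix.samples, matrix.values[perm]
    )
    cats_p = classify(permuted)
    assert (cats_p.categories == cats.categories[perm]).all()


def test_knn_requires_seeds():
    m = _toy_matrix(np.full((5, 4), 50.0))
    seeds = CategorizedCpGs(
        np.array([UNASSIGNED] * 5), np.array([""] * 5), np.zeros(5, dtype=np.int32)
    )
    with pytest.raises(ValueError, match="no seed"):
        knn_refine(m, seeds, CategoryThresholds())


def test_u_set_invariant_to_shifting_an_m_cpg(small_fixture):
    matrix, _ = small_fixture
    cats = classify(matrix)
    u_before = set(np.nonzero(cats.categories == "U")[0])
    m_idx = int(np.nonzero(cats.categories == "M")[0][0])
    shifted = matrix.values.copy()
    shifted[m_idx] = np.clip(shifted[m_idx] + 1.0, 0, 100)
    matrix2 = MethylomeMatrix(matrix.sites, matrix.samples, shifted)
    cats2 = classify(matrix2)
    assert set(np.nonzero(cats2.categories == "U")[0]) == u_before


# ---------------------------------------------------------------------------
# summaries


def test_category_summary_counts():
    cats = CategorizedCpGs(
        np.array(["M"] * 7 + ["I", "U", "V"]), np.array(["seed"] * 10),
        np.zeros(10, dtype=np.int32),
    )
    df = category_summary(cats).set_index("category")
    assert df.loc["M", "fraction"] == pytest.approx(0.7)
    assert df["fraction"].sum() == pytest.approx(1.0)
    assert df["count"].sum() == 10


def test_category_summary_rejects_empty_and_incomplete():
    with pytest.raises(ValueError):
        category_summary(CategorizedCpGs(np.array([]), np.array([]), np.array([], dtype=np.int32)))
    with pytest.raises(ValueError, match="UNASSIGNED"):
        category_summary(
            CategorizedCpGs(np.array(["M", UNASSIGNED]), np.array(["seed", ""]),
                            np.zeros(2, dtype=np.int32))
        )


def test_planted_v_fraction_exact(default_fixture):
    matrix, truth = default_fixture
    cats = classify(matrix)
    df = category_summary(cats).set_index("category")
    planted = (truth.categories == "V").mean()
    assert df.loc["V", "fraction"] == pytest.approx(planted)


def test_per_sample_level_summary_trivials():
    m = _toy_matrix(np.array([[10.0, 0.0], [50.0, 0.0], [90.0, 0.0]]))
    t = CategoryThresholds(i_min_libraries=2)
    df = per_sample_level_summary(m, t)
    row = df.iloc[0]
    assert row["frac_unmethylated"] == pytest.approx(1 / 3)
    assert row["frac_intermediate"] == pytest.approx(1 / 3)
    assert row["frac_methylated"] == pytest.approx(1 / 3)
    assert row["mean_methylation"] == pytest.approx(50.0)
    zero = df.iloc[1]
    assert zero["frac_unmethylated"] == 1.0 and zero["mean_methylation"] == 0.0


def test_per_sample_unmethylated_band_matches_construction(default_fixture):
    """The per-sample unmethylated fraction equals p_U plus the planted
    hypomethylated share of V CpGs, by construction of the generator."""
    matrix, truth = default_fixture
    df = per_sample_level_summary(matrix)
    p = truth.config.class_proportions
    v_mask = truth.categories == "V"
    hypo_frac = (matrix.values[v_mask] < 30).mean()  # share of V cells that are hypo
    expected = p[2] + p[3] * hypo_frac
    assert df["frac_unmethylated"].mean() == pytest.approx(expected, abs=0.01)
    assert df["frac_unmethylated"].between(expected - 0.05, expected + 0.05).all()


def test_min_methylation_fraction():
    # one sample all-zero: every CpG's minimum falls below the threshold
    m = _toy_matrix(np.array([[50.0, 0.0], [50.0, 0.0]]))
    assert min_methylation_fraction(m) == 1.0
    m2 = _toy_matrix(np.full((4, 3), 50.0))
    assert min_methylation_fraction(m2) == 0.0
    # monotone in the threshold
    m3 = _toy_matrix(np.array([[10.0], [40.0], [80.0]]).repeat(4, axis=1))
    fr = [min_methylation_fraction(m3, thr) for thr in (5, 30, 50, 90)]
    assert fr == sorted(fr)


def test_min_methylation_fraction_planted(default_fixture):
    matrix, truth = default_fixture
    p = truth.config.class_proportions
    # noise-free: U CpGs and V CpGs (hypo in >= 1 cell type) dip below 30
    assert min_methylation_fraction(matrix) == pytest.approx(p[2] + p[3], abs=1e-9)


def test_i_min_libraries_scaling():
    t = CategoryThresholds()
    assert t.scaled_to(54).i_min_libraries == 50
    assert t.scaled_to(27).i_min_libraries == 25
    assert t.scaled_to(10).i_min_libraries == 10  # ceil(50/54*10)=10
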