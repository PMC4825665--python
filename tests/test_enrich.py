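"""Fold enrichment, exact tests, ANOVA, and GWAS statistics."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vmrcall.enrich import (
    center_state_enrichment,
    cpg_context_variants,
    fold_enrichment,
    gwas_variant_enrichment,
    region_centers,
    tfbs_overlap_profile,
    tissue_anova,
    trait_enrichment,
    variants_in_regions,
)


def iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def spaced(n, hit, length=10, step=100):
    """n regions; the first ``hit`` overlap [0, hit*step) annotations."""
    return iv([("chr1", i * step, i * step + length) for i in range(n)])


def test_fold_enrichment_ratio():
    fg = spaced(100, 50)
    bg = iv([("chr2", i * 100, i * 100 + 10) for i in range(100)])
    ann = iv(
        [("chr1", i * 100, i * 100 + 5) for i in range(50)]
        + [("chr2", i * 100, i * 100 + 5) for i in range(25)]
    )
    r = fold_enrichment(fg, ann, bg)
    assert (r.fg_count, r.bg_count) == (50, 25)
    assert r.fold == pytest.approx(2.0)


def test_fold_enrichment_identity():
    fg = spaced(20, 0)
    ann = iv([("chr1", 0, 5), ("chr1", 100, 105)])
    r = fold_enrichment(fg, ann, fg, alternative="two-sided")
    assert r.fold == 1.0
    assert r.p == 1.0  # identical rows: the two-sided table is the mode
    r1 = fold_enrichment(fg, ann, fg)
    assert r1.p == pytest.approx(brute_fisher_greater(2, 18, 2, 18), abs=1e-12)


def test_fold_enrichment_zero_background_flagged():
    fg = spaced(10, 10)
    bg = iv([("chr2", i * 100, i * 100 + 10) for i in range(10)])
    ann = iv([("chr1", 0, 1000)])
    r = fold_enrichment(fg, ann, bg)
    assert r.undefined and np.isinf(r.fold)


def test_fold_enrichment_requires_size_match():
    with pytest.raises(ValueError, match="size-matched"):
        fold_enrichment(spaced(10, 0), iv([]), spaced(5, 0))


def brute_fisher_greater(a, b, c, d):
    """One-sided Fisher p by exhaustive hypergeometric enumeration of all
    tables with the observed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p = 0.0
    for k in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        if k >= a:
            p += comb(col1, k) * comb(n - col1, row1 - k) / comb(n, row1)
    return p


def test_fisher_worked_example():
    p = stats.fisher_exact([[3, 7], [0, 10]], alternative="greater")[1]
    assert p == pytest.approx(0.1053, abs=5e-5)
    assert p == pytest.approx(brute_fisher_greater(3, 7, 0, 10), abs=1e-12)


def test_fisher_matches_enumeration_small_margins(rng):
    for _ in range(300):
        a, b, c, d = rng.integers(0, 16, size=4)
        if a + b == 0 or c + d == 0:
            continue
        p_scipy = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert p_scipy == pytest.approx(brute_fisher_greater(int(a), int(b), int(c), int(d)),
                                        abs=1e-10)


# ---------------------------------------------------------------------------
# chromatin-state enrichment by centers


def test_region_center_convention():
    r = iv([("chr1", 100, 102)])
    assert region_centers(r)[0] == 101


def test_center_state_closed_form():
    # 15 equal states; all 15 foreground centers in E8, background centers
    # uniform (one per state) -> log2 fold = log2(15) for E8
    states = pd.DataFrame(
        {"chrom": "chr1", "start": np.arange(15) * 100,
         "end": (np.arange(15) + 1) * 100, "label": [f"E{i + 1}" for i in range(15)]}
    )
    fg = iv([("chr1", 720, 760)] * 15)  # center 740 -> E8
    bg = iv([("chr1", i * 100 + 40, i * 100 + 60) for i in range(15)])
    res = center_state_enrichment(fg, states, bg).set_index("state")
    assert res.loc["E8", "log2_fold"] == pytest.approx(np.log2(15))


def test_center_state_identity():
    states = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 100], "end": [100, 200], "label": ["A", "B"]}
    )
    fg = iv([("chr1", 10, 30), ("chr1", 110, 130)])
    res = center_state_enrichment(fg, states, fg).set_index("state")
    assert (res["log2_fold"] == 0).all()


def test_center_state_rejects_overlapping_states():
    states = pd.DataFrame(
        {"chrom": "chr1", "start": [0, 50], "end": [100, 200], "label": ["A", "B"]}
    )
    with pytest.raises(ValueError, match="overlapping"):
        center_state_enrichment(iv([("chr1", 0, 10)]), states, iv([("chr1", 0, 10)]))


# ---------------------------------------------------------------------------
# TFBS overlap profile


def test_tfbs_profile_bins():
    vmrs = iv([("chr1", 0, 10), ("chr1", 100, 110), ("chr1", 200, 210)])
    peaks = {
        "TF1": iv([("chr1", 5, 8)]),
        "TF2": iv([("chr1", 0, 3), ("chr1", 100, 103)]),
        "TF3": iv([("chr1", 9, 12)]),
    }
    prof = tfbs_overlap_profile(vmrs, peaks)
    assert prof["counts"].tolist() == [3, 1, 0]
    assert prof["fractions"]["3+"] == pytest.approx(1 / 3)
    assert sum(prof["fractions"].values()) == pytest.approx(1.0)
    empty = tfbs_overlap_profile(vmrs, {})
    assert empty["fractions"]["0"] == 1.0


def test_tfbs_profile_null_matches_closed_form(default_fixture, default_blacklist):
    """With uniformly placed peak sets, the chance a VMR overlaps >= 1 of T
    independent sets follows 1 - (1 - p_t)^T with p_t from the placement
    geometry."""
    from vmrcall.simulate import simulate_annotations

    matrix, truth = default_fixture
    vmrs = truth.regions[["chrom", "start", "end"]]
    peak_sets = {}
    for t in range(3):
        ann = simulate_annotations(
            truth, 1.0, 800, seed=100 + t, blacklist=default_blacklist
        )
        peak_sets[f"TF{t}"] = ann.peaks
    prof = tfbs_overlap_profile(vmrs, peak_sets)
    genome = sum(truth.chrom_lengths.values())
    lengths = (vmrs["end"] - vmrs["start"]).to_numpy()
    p_per_set = 1 - (1 - (lengths + 200 - 1) / genome) ** 800
    expected = (1 - (1 - p_per_set) ** 3).mean()
    assert prof["frac_at_least_one"] == pytest.approx(expected, rel=0.1)


# ---------------------------------------------------------------------------
# tissue ANOVA


def test_anova_worked_example():
    folds = pd.DataFrame(
        {"tf": ["a"] * 6, "cell_type": [f"c{i}" for i in range(6)],
         "fold": [1, 2, 3, 2, 3, 4]}
    )
    tissues = {f"c{i}": ("t1" if i < 3 else "t2") for i in range(6)}
    res = tissue_anova(folds, tissues).iloc[0]
    assert res["F"] == pytest.approx(1.5)
    assert res["p"] == pytest.approx(0.2878, abs=2e-4)


def test_anova_degenerate_groups():
    folds = pd.DataFrame(
        {"tf": ["a"] * 6, "cell_type": [f"c{i}" for i in range(6)],
         "fold": [1, 1, 1, 5, 5, 5]}
    )
    tissues = {f"c{i}": ("t1" if i < 3 else "t2") for i in range(6)}
    res = tissue_anova(folds, tissues).iloc[0]
    assert res["exact_separation"] and res["p"] == 0.0
    flat = folds.assign(fold=2.0)
    res2 = tissue_anova(flat, tissues).iloc[0]
    assert res2["F"] == 0.0 and res2["p"] == 1.0


def test_anova_exclusions_and_fdr():
    folds = pd.DataFrame(
        {
            "tf": ["a"] * 4 + ["b"] * 2 + ["c"] * 2,
            "cell_type": ["c1", "c2", "c3", "c4"] + ["c1", "c2"] + ["c1", "c3"],
            "fold": [1.0, 2.0, 3.0, 2.5, 1.0, 2.0, 1.5, 2.5],
        }
    )
    tissues = {"c1": "t1", "c2": "t1", "c3": "t2", "c4": "t2"}
    res = tissue_anova(folds, tissues).set_index("tf")
    assert res.loc["b", "excluded"] == "single tissue"
    assert res.loc["c", "excluded"] == "all groups single observation"
    assert not np.isnan(res.loc["a", "q"])


# ---------------------------------------------------------------------------
# GWAS


def gwas(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "rsid", "trait"])


def test_variant_fold():
    variants = gwas([("chr1", i, f"rs{i}", "t") for i in range(100)])
    fg = iv([("chr1", 0, 14)])    # 14 variants inside
    bg = iv([("chr1", 50, 60)])   # 10 variants inside
    r = gwas_variant_enrichment(variants, fg, bg)
    assert (r.fg_count, r.bg_count) == (14, 10)
    assert r.fold == pytest.approx(1.4)


def test_variant_fold_degenerate():
    variants = gwas([("chr1", i, f"rs{i}", "t") for i in range(10)])
    fg = iv([("chr1", 0, 100)])
    bg = iv([("chr2", 0, 100)])
    r = gwas_variant_enrichment(variants, fg, bg)
    assert r.undefined and np.isinf(r.fold)


def brute_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration over draw compositions."""
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / comb(N, n)


def test_trait_hypergeom_worked_example():
    catalog = gwas(
        [("chr1", i, f"rs{i}", "X" if i < 4 else "Y") for i in range(10)]
    )
    inside = catalog.iloc[[0, 1, 2, 4, 5]]  # n=5, k=3 with trait X
    res = trait_enrichment(inside, catalog).set_index("trait")
    assert res.loc["X", "p"] == pytest.approx(66 / 252, abs=1e-12)
    assert res.loc["X", "p"] == pytest.approx(brute_hypergeom_tail(10, 4, 5, 3), abs=1e-12)
    assert res.loc["X", "fold"] == pytest.approx((3 / 5) / (4 / 10))


def test_trait_hypergeom_boundaries():
    catalog = gwas([("chr1", i, f"rs{i}", "X") for i in range(6)])
    inside = catalog.iloc[:3]
    res = trait_enrichment(inside, catalog).set_index("trait")
    assert res.loc["X", "p"] == pytest.approx(1.0)  # K=N forces k=n
    catalog2 = gwas(
        [("chr1", i, f"rs{i}", "X" if i < 3 else "Y") for i in range(6)]
    )
    inside2 = catalog2.iloc[[3]]  # k=0 for X
    res2 = trait_enrichment(inside2, catalog2).set_index("trait")
    assert res2.loc["X", "p"] == pytest.approx(1.0)  # P(X >= 0) = 1


def test_trait_enrichment_matches_enumeration(rng):
    traits = ["A", "B", "C"]
    catalog = gwas(
        [("chr1", i, f"rs{i}", traits[int(rng.integers(0, 3))]) for i in range(25)]
    )
    inside = catalog.iloc[sorted(rng.choice(25, size=10, replace=False))]
    res = trait_enrichment(inside, catalog).set_index("trait")
    for trait in res.index:
        K = int((catalog["trait"] == trait).sum())
        k = int((inside["trait"] == trait).sum())
        assert res.loc[trait, "p"] == pytest.approx(
            brute_hypergeom_tail(25, K, 10, k), abs=1e-12
        )
    # BH q-values non-decreasing with p
    srt = res.sort_values("p")
    assert (np.diff(srt["q"]) >= -1e-12).all()


def test_trait_enrichment_rejects_inconsistent_subset():
    catalog = gwas([("chr1", 1, "rs1", "X")])
    bogus = gwas([("chr1", 2, "rs2", "Y")])
    with pytest.raises(ValueError, match="inconsistent subset"):
        trait_enrichment(bogus, catalog)


# ---------------------------------------------------------------------------
# CpG-context variants


def test_cpg_context_boundaries():
    sites = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [102]})
    variants = gwas([("chr1", 100, "rs1", "t"), ("chr1", 101, "rs2", "t"),
                     ("chr1", 102, "rs3", "t")])
    out = cpg_context_variants(variants, sites, categories=np.array(["V"]))
    assert out["rsid"].tolist() == ["rs1", "rs2"]  # 102 excluded (half-open)
    assert (out["cpg_category"] == "V").all()


def test_cpg_context_matches_linear_scan(small_fixture, rng):
    matrix, truth = small_fixture
    chrom_lengths = truth.chrom_lengths
    chroms = rng.choice(list(chrom_lengths), size=1000)
    pos = np.array([rng.integers(0, chrom_lengths[c]) for c in chroms])
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": pos,
         "rsid": [f"rs{i}" for i in range(1000)], "trait": "t"}
    )
    out = cpg_context_variants(variants, matrix.sites)
    # linear-scan oracle
    expected = 0
    site_map = {
        c: list(zip(g["start"], g["end"]))
        for c, g in matrix.sites.groupby("chrom", observed=True)
    }
    for c, p in zip(chroms, pos):
        expected += any(s <= p < e for s, e in site_map.get(c, []))
    assert len(out) == expected


def test_variants_in_regions():
    variants = gwas([("chr1", 5, "rs1", "t"), ("chr1", 50, "rs2", "t")])
    sub = variants_in_regions(variants, iv([("chr1", 0, 10)]))
    assert sub["rsid"].tolist() == ["rs1"]
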