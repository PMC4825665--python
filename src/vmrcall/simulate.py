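"""Synthetic methylomes and annotations with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a genome of CpG positions carrying a mixture of constitutively
methylated (M), intermediately methylated (I), constitutively unmethylated
(U) and variably methylated (V) CpGs across many samples grouped into cell
types and tissues.  V CpGs occur in contiguous planted runs (3-30 CpGs,
intra-run spacing well under the 500-bp merge gap) that are hypomethylated
in a planted subset of cell types and highly methylated elsewhere, so the
seed rules, region merging and hypomethylation calling all have an exact
ground truth to recover.  Annotation interval sets (peaks, chromatin
states, point variants, a blacklist) can be placed with a controlled
enrichment inside the planted hypomethylated regions.

Base levels per class (percent scale, before optional truncated Gaussian
noise): M uniform(82, 98); U uniform(2, 18); I uniform(40, 60); V CpGs
uniform(3, 12) in planted hypo cell types and uniform(88, 97) elsewhere.
With zero noise every CpG is recovered by the seed rules alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._intervals import batch_place_uniform, total_bp
from .io import CPG_WIDTH, MethylomeMatrix

logger = logging.getLogger(__name__)

# base-level bands per class (percent)
M_BAND = (82.0, 98.0)
U_BAND = (2.0, 18.0)
I_BAND = (40.0, 60.0)
V_HYPO_BAND = (3.0, 12.0)
V_HIGH_BAND = (88.0, 97.0)


def default_cell_type_map(n_samples: int = 54) -> pd.DataFrame:
    """Sample metadata emulating a multi-tissue study design.

    Cell types hold 3 samples each (so the rank-3 gap statistic can fire on
    a single hypomethylated cell type); cell types are grouped 3-per-tissue.
    """
    n_cell_types = -(-n_samples // 3)
    rows = []
    for i in range(n_samples):
        ct = i // 3
        rows.append(
            {
                "sample_id": f"s{i + 1:02d}",
                "cell_type": f"ct{ct + 1:02d}",
                "tissue_type": f"tissue{ct // 3 + 1}",
            }
        )
    assert len({r["cell_type"] for r in rows}) == n_cell_types
    return pd.DataFrame(rows)


@dataclass
class SimConfig:
    """Parameters of the synthetic methylome generator.

    ``class_proportions`` is (p_M, p_I, p_U, p_V) and must sum to 1.
    ``hypo_cell_types_per_V`` is the maximum number of hypomethylated cell
    types per planted V region; each region draws its count uniformly from
    1..max.  ``noise_sd`` is the SD of truncated Gaussian noise on the
    percent scale.
    """

    n_chroms: int = 2
    chrom_length_bp: int = 3_200_000
    n_cpgs: int = 50_000
    cpg_spacing_model: str = "uniform"  # or "clustered"
    n_samples: int = 54
    cell_type_map: pd.DataFrame | None = None
    class_proportions: tuple[float, float, float, float] = (0.70, 0.03, 0.075, 0.195)
    hypo_cell_types_per_V: int = 5
    noise_sd: float = 0.0
    seed: int = 0
    v_run_min: int = 3
    v_run_max: int = 30
    v_intra_spacing_max: int = 300
    mean_spacing: int = 120
    clustered_long_gap_prob: float = 0.02
    clustered_long_gap: tuple[int, int] = (1200, 4000)

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if min(self.n_chroms, self.n_cpgs, self.n_samples) <= 0:
            raise ValueError("all counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cpg_spacing_model not in ("uniform", "clustered"):
            raise ValueError("cpg_spacing_model must be 'uniform' or 'clustered'")
        if self.cell_type_map is None:
            self.cell_type_map = default_cell_type_map(self.n_samples)
        if len(self.cell_type_map) != self.n_samples:
            raise ValueError("cell_type_map rows must equal n_samples")


@dataclass
class GroundTruth:
    """Planted truth accompanying a simulated methylome.

    ``categories``: per-CpG true class (U/M/I/V).
    ``run_id``: per-CpG planted V-run index (-1 for non-V CpGs).
    ``regions``: one row per planted V run (chrom, start, end, run_id,
    n_cpgs, hypo_cell_types as a frozenset).
    ``chrom_lengths``: simulated chromosome sizes.
    ``annotation_linkage``: filled by :func:`simulate_annotations` — per
    peak interval, whether it was placed inside a planted hypo region.
    """

    categories: np.ndarray
    run_id: np.ndarray
    regions: pd.DataFrame
    chrom_lengths: dict[str, int]
    config: SimConfig
    annotation_linkage: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def cell_types(self) -> list[str]:
        return list(dict.fromkeys(self.config.cell_type_map["cell_type"]))


def _allocate_counts(n: int, proportions: tuple[float, ...]) -> list[int]:
    """Largest-remainder allocation so counts are exact and sum to n."""
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[:rem]:
        counts[i] += 1
    return counts


def simulate_methylomes(config: SimConfig | None = None) -> tuple[MethylomeMatrix, GroundTruth]:
    """Generate a methylome matrix with planted per-CpG classes.

    Deterministic given ``config.seed``: all randomness flows from a single
    spawned RNG tree.
    """
    config = config or SimConfig()
    root = np.random.default_rng(config.seed)
    rng_layout, rng_pos, rng_values, rng_noise = root.spawn(4)

    n = config.n_cpgs
    n_m, n_i, n_u, n_v = _allocate_counts(
        n, (config.class_proportions[0], config.class_proportions[1],
            config.class_proportions[2], config.class_proportions[3])
    )

    # --- plant V runs: lengths uniform in [run_min, run_max], exact total n_v
    run_lengths: list[int] = []
    remaining = n_v
    while remaining > 0:
        if remaining <= config.v_run_max + config.v_run_min:
            # close out exactly, keeping the final run(s) in range
            if remaining < config.v_run_min and run_lengths:
                run_lengths[-1] += remaining
            elif remaining <= config.v_run_max:
                run_lengths.append(remaining)
            else:
                half = remaining // 2
                run_lengths.extend([half, remaining - half])
            break
        run_lengths.append(int(rng_layout.integers(config.v_run_min, config.v_run_max + 1)))
        remaining = n_v - sum(run_lengths)
    n_runs = len(run_lengths)

    # --- non-V categories, shuffled
    rest = np.array(["M"] * n_m + ["I"] * n_i + ["U"] * n_u)
    rng_layout.shuffle(rest)

    # --- distribute rest CpGs and runs across chromosomes, insert runs at
    # distinct slots between rest CpGs so runs are never adjacent
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    rest_split = np.array_split(rest, config.n_chroms)
    run_assign = rng_layout.integers(0, config.n_chroms, size=n_runs)
    categories_per_chrom: list[np.ndarray] = []
    run_ids_per_chrom: list[np.ndarray] = []
    run_counter = 0
    for ci in range(config.n_chroms):
        rest_c = rest_split[ci]
        runs_c = [run_lengths[k] for k in range(n_runs) if run_assign[k] == ci]
        n_slots = len(rest_c) + 1
        if len(runs_c) > n_slots:
            raise ValueError("too many planted runs for the number of background CpGs")
        slots = np.sort(rng_layout.choice(n_slots, size=len(runs_c), replace=False))
        cats: list[str] = []
        rids: list[int] = []
        prev = 0
        for slot, run_len in zip(slots, runs_c):
            cats.extend(rest_c[prev:slot])
            rids.extend([-1] * (slot - prev))
            cats.extend(["V"] * run_len)
            rids.extend([run_counter] * run_len)
            run_counter += 1
            prev = slot
        cats.extend(rest_c[prev:])
        rids.extend([-1] * (len(rest_c) - prev))
        categories_per_chrom.append(np.array(cats, dtype="<U1"))
        run_ids_per_chrom.append(np.array(rids, dtype=np.int64))

    # --- positions: spacings by model, capped inside V runs so planted
    # runs always merge into single regions downstream
    chroms: list[str] = []
    starts_all: list[np.ndarray] = []
    chrom_lengths: dict[str, int] = {}
    for ci, name in enumerate(chrom_names):
        cats = categories_per_chrom[ci]
        rids = run_ids_per_chrom[ci]
        m = len(cats)
        if m == 0:
            chrom_lengths[name] = config.chrom_length_bp
            starts_all.append(np.array([], dtype=np.int64))
            continue
        spacing = rng_pos.integers(CPG_WIDTH, 2 * config.mean_spacing - CPG_WIDTH + 1, size=m)
        if config.cpg_spacing_model == "clustered":
            long_mask = rng_pos.random(m) < config.clustered_long_gap_prob
            spacing[long_mask] = rng_pos.integers(
                config.clustered_long_gap[0], config.clustered_long_gap[1] + 1,
                size=int(long_mask.sum()),
            )
        # cap spacing within a planted run (same run as previous CpG)
        in_run = np.zeros(m, dtype=bool)
        in_run[1:] = (rids[1:] >= 0) & (rids[1:] == rids[:-1])
        capped = np.minimum(spacing, config.v_intra_spacing_max)
        spacing = np.where(in_run, np.maximum(capped, CPG_WIDTH), spacing)
        spacing[0] = int(rng_pos.integers(500, 1500))
        starts = np.cumsum(spacing)
        chroms.extend([name] * m)
        starts_all.append(starts)
        chrom_lengths[name] = int(max(config.chrom_length_bp, starts[-1] + CPG_WIDTH + 1000))

    starts = np.concatenate(starts_all) if starts_all else np.array([], dtype=np.int64)
    categories = np.concatenate(categories_per_chrom)
    run_id = np.concatenate(run_ids_per_chrom)
    sites = pd.DataFrame(
        {"chrom": np.array(chroms), "start": starts, "end": starts + CPG_WIDTH}
    )

    # --- values
    samples = config.cell_type_map.reset_index(drop=True)
    cell_types = list(dict.fromkeys(samples["cell_type"]))
    values = np.empty((n, config.n_samples))
    for band, cls in ((M_BAND, "M"), (U_BAND, "U"), (I_BAND, "I")):
        mask = categories == cls
        values[mask] = rng_values.uniform(band[0], band[1], size=(int(mask.sum()), config.n_samples))

    # hypo cell-type sets per planted run
    hypo_sets: list[frozenset[str]] = []
    for _ in range(run_counter):
        k = int(rng_values.integers(1, config.hypo_cell_types_per_V + 1))
        hypo_sets.append(frozenset(rng_values.choice(cell_types, size=k, replace=False)))
    ct_per_sample = samples["cell_type"].to_numpy()
    v_mask = categories == "V"
    v_idx = np.nonzero(v_mask)[0]
    hypo_cols = np.zeros((run_counter, config.n_samples), dtype=bool)
    for r, hs in enumerate(hypo_sets):
        hypo_cols[r] = np.isin(ct_per_sample, list(hs))
    low = rng_values.uniform(V_HYPO_BAND[0], V_HYPO_BAND[1], size=(len(v_idx), config.n_samples))
    high = rng_values.uniform(V_HIGH_BAND[0], V_HIGH_BAND[1], size=(len(v_idx), config.n_samples))
    values[v_idx] = np.where(hypo_cols[run_id[v_idx]], low, high)

    if config.noise_sd > 0:
        values = values + rng_noise.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 100.0)

    # planted region table
    region_rows = []
    for r in range(run_counter):
        idx = np.nonzero(run_id == r)[0]
        region_rows.append(
            {
                "chrom": sites["chrom"].iloc[idx[0]],
                "start": int(sites["start"].iloc[idx[0]]),
                "end": int(sites["end"].iloc[idx[-1]]),
                "run_id": r,
                "n_cpgs": len(idx),
                "hypo_cell_types": hypo_sets[r],
            }
        )
    regions = pd.DataFrame(
        region_rows,
        columns=["chrom", "start", "end", "run_id", "n_cpgs", "hypo_cell_types"],
    )

    n_hypo_sides = min(3 * 1, config.n_samples)  # smallest hypo side: one cell type
    if n_hypo_sides < 3:
        logger.warning(
            "fewer than 3 samples on the hypomethylated side of planted V "
            "patterns; the rank-3 gap rule may not fire"
        )

    matrix = MethylomeMatrix(sites, samples, values)
    truth = GroundTruth(categories, run_id, regions, chrom_lengths, config)
    return matrix, truth


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationSets:
    """Interval fixtures placed relative to the planted hypo regions."""

    peaks: pd.DataFrame
    states: pd.DataFrame
    variants: pd.DataFrame
    blacklist: pd.DataFrame


def simulate_blacklist(
    truth: GroundTruth,
    seed: int,
    sites: pd.DataFrame | None = None,
    n_intervals: int = 10,
    interval_length: int = 2000,
    clearance: int = 600,
) -> pd.DataFrame:
    """A small blacklist placed clear of planted V regions (with margin
    larger than the merge gap) and, when ``sites`` is given, of every CpG
    site — blacklisted regions carry anomalous signal, so the generator
    keeps CpG calls out of them and categorized regions never intersect
    the blacklist."""
    rng = np.random.default_rng(seed)
    expanded = truth.regions[["chrom", "start", "end"]].copy()
    if len(expanded):
        expanded["start"] = (expanded["start"] - clearance).clip(lower=0)
        expanded["end"] = expanded["end"] + clearance
    avoid_parts = [expanded]
    if sites is not None:
        avoid_parts.append(sites[["chrom", "start", "end"]])
    placed: list[pd.DataFrame] = []
    for _ in range(n_intervals):
        avoid = pd.concat(avoid_parts + placed, ignore_index=True)
        one = batch_place_uniform(
            rng, truth.chrom_lengths, np.array([interval_length]), avoid
        )
        placed.append(one)
    out = pd.concat(placed, ignore_index=True)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_annotations(
    truth: GroundTruth,
    enrichment_factor: float = 1.0,
    n_intervals: int = 1000,
    seed: int = 0,
    peak_length: int = 200,
    n_states: int = 15,
    n_variants: int | None = None,
    n_traits: int = 10,
    blacklist: pd.DataFrame | None = None,
) -> AnnotationSets:
    """Place annotation intervals with controlled enrichment in planted
    hypomethylated regions.

    With ``enrichment_factor == 1`` peaks and variants are placed uniformly
    over the non-blacklist genome (an exact null for fold-enrichment
    statistics).  With a factor f > 1, each peak lands inside a planted V
    region with probability min(f * rho, 1), where rho is the genomic
    density of planted regions, and otherwise uniformly outside both the
    planted regions and the blacklist.  The per-peak placement flag is
    recorded in ``truth.annotation_linkage``.
    """
    if enrichment_factor < 1:
        raise ValueError("enrichment_factor must be >= 1")
    rng = np.random.default_rng(seed)
    if blacklist is None:
        blacklist = simulate_blacklist(truth, seed=int(rng.integers(2**31)))
    genome_bp = sum(truth.chrom_lengths.values())
    planted = truth.regions[["chrom", "start", "end"]] if len(truth.regions) else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    rho = total_bp(planted) / genome_bp if genome_bp else 0.0
    q = min(enrichment_factor * rho, 1.0)
    if enrichment_factor > 1 and q >= 1.0:
        raise ValueError("enrichment_factor too large: inside-placement probability reaches 1")

    eligible = planted[(planted["end"] - planted["start"]) >= peak_length].reset_index(drop=True)
    if enrichment_factor > 1 and len(eligible) == 0:
        raise ValueError("no planted region can hold a peak of the requested length")
    elig_weights = (eligible["end"] - eligible["start"] - peak_length + 1).to_numpy(dtype=float)

    avoid_out = pd.concat([blacklist, planted], ignore_index=True)

    def place_points_or_peaks(n: int, length: int) -> tuple[pd.DataFrame, np.ndarray]:
        inside = (
            rng.random(n) < q if enrichment_factor > 1 else np.zeros(n, dtype=bool)
        )
        n_in = int(inside.sum())
        rows = []
        if n_in:
            ks = rng.choice(len(eligible), size=n_in, p=elig_weights / elig_weights.sum())
            reg_start = eligible["start"].to_numpy()[ks]
            reg_slots = elig_weights[ks]
            s = reg_start + (rng.random(n_in) * reg_slots).astype(np.int64)
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": eligible["chrom"].to_numpy()[ks],
                        "start": s,
                        "end": s + length,
                    }
                )
            )
        n_out = n - n_in
        if n_out:
            avoid = avoid_out if enrichment_factor > 1 else blacklist
            rows.append(
                batch_place_uniform(
                    rng, truth.chrom_lengths, np.full(n_out, length, dtype=np.int64), avoid
                )
            )
        df = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["chrom", "start", "end"]
        )
        flags = np.concatenate([np.ones(n_in, dtype=bool), np.zeros(n_out, dtype=bool)])
        order = np.lexsort((df["start"].to_numpy(), df["chrom"].to_numpy().astype(str)))
        return df.iloc[order].reset_index(drop=True), flags[order]

    peaks, peak_inside = place_points_or_peaks(n_intervals, peak_length)
    if n_variants is None:
        n_variants = n_intervals
    var_iv, var_inside = place_points_or_peaks(n_variants, 1)
    variants = pd.DataFrame(
        {
            "chrom": var_iv["chrom"],
            "pos": var_iv["start"],
            "rsid": [f"rs{i + 1}" for i in range(len(var_iv))],
            "trait": rng.choice([f"trait_{j + 1}" for j in range(n_traits)], size=len(var_iv)),
        }
    )

    # chromatin states: complete tiling with segments of 500-5000 bp
    state_rows = []
    labels = [f"E{j + 1}" for j in range(n_states)]
    for chrom, length in truth.chrom_lengths.items():
        pos = 0
        while pos < length:
            seg = int(rng.integers(500, 5001))
            end = min(pos + seg, length)
            state_rows.append(
                {"chrom": chrom, "start": pos, "end": end, "label": labels[int(rng.integers(n_states))]}
            )
            pos = end
    states = pd.DataFrame(state_rows)

    truth.annotation_linkage["peaks"] = peak_inside
    truth.annotation_linkage["variants"] = var_inside
    return AnnotationSets(peaks=peaks, states=states, variants=variants, blacklist=blacklist)


def expected_fold_enrichment(
    truth: GroundTruth,
    enrichment_factor: float,
    n_intervals: int,
    peak_length: int = 200,
    blacklist_bp: int = 0,
) -> float:
    """Closed-form expectation of the fold-enrichment statistic on this
    fixture (ratio of expected foreground and background overlap counts).

    Foreground term (exact for the generator's placement scheme, factor > 1):
    an inside-peak lands in planted region r with probability
    q * w_r / W, where w_r is the number of start positions fully inside r
    and W their total; outside-peaks never touch a planted region, so
    P(region r overlaps >= 1 of n peaks) = 1 - (1 - q w_r / W)^n.

    Background term (uniform placement of a length-l region versus n
    independently placed peaks): P(overlap one peak on the same chromosome)
    ~ (l + L - 1) / chrom_length, combined over the chromosome-choice
    distributions of both sides.
    """
    planted = truth.regions
    if len(planted) == 0:
        return float("nan")
    genome_bp = sum(truth.chrom_lengths.values()) - blacklist_bp
    rho = total_bp(planted[["chrom", "start", "end"]]) / sum(truth.chrom_lengths.values())
    q = min(enrichment_factor * rho, 1.0)
    lengths = (planted["end"] - planted["start"]).to_numpy()
    w = np.maximum(lengths - peak_length + 1, 0).astype(float)
    W = w.sum()
    p_fg = 1.0 - (1.0 - q * w / W) ** n_intervals
    e_fg = p_fg.sum()

    # background: chromosome-choice distribution of peaks
    chroms = list(truth.chrom_lengths)
    chrom_len = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    p_bg_chrom = chrom_len / chrom_len.sum()
    w_per_chrom = np.array(
        [w[(planted["chrom"] == c).to_numpy()].sum() for c in chroms], dtype=float
    )
    p_in_chrom = w_per_chrom / W
    p_out_chrom = p_bg_chrom  # outside placement ~ proportional to length
    p_peak_chrom = q * p_in_chrom + (1 - q) * p_out_chrom
    e_bg = 0.0
    for l in lengths:
        p_hit = float(np.sum(p_bg_chrom * p_peak_chrom * (l + peak_length - 1) / chrom_len))
        e_bg += 1.0 - (1.0 - p_hit) ** n_intervals
    return float(e_fg / e_bg)
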