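"""Readers and writers for the on-disk formats and the shared domain types.

The pipeline works on per-CpG methylation percentages across many samples.
On disk, a methylome set is one 4-column bedGraph per sample (chrom, start,
end, percent in [0, 100]) plus a TSV of sample metadata; interval
annotations (blacklist, ChIP-seq peaks, chromatin states, enhancers, DMR
sets) are BED3/BED4; gene models and GWAS catalog subsets are TSV.

All coordinates are 0-based half-open.  A CpG site is the 2-bp interval of
the dinucleotide on the plus strand, carrying one (strand-combined)
methylation value per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._intervals import assert_disjoint, sort_intervals

logger = logging.getLogger(__name__)

#: Chromosomes retained by default: human autosomes.
DEFAULT_AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))

CPG_WIDTH = 2


@dataclass
class MethylomeMatrix:
    """Per-CpG methylation percentages for a set of samples.

    Attributes
    ----------
    sites : DataFrame with columns chrom, start, end, sorted by (chrom, start),
        one row per CpG; end - start == 2.
    samples : DataFrame with columns sample_id, cell_type, tissue_type.
    values : float array of shape (n_sites, n_samples) in [0, 100];
        missing values are NaN.
    """

    sites: pd.DataFrame
    samples: pd.DataFrame
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.sites)} sites, {len(self.samples)} samples)"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("methylation values must lie in [0, 100]")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def require_complete(self) -> None:
        """Raise if any value is missing (the classifier needs complete rows)."""
        if np.isnan(self.values).any():
            n = int(np.isnan(self.values).any(axis=1).sum())
            raise ValueError(f"{n} CpG rows carry missing values; drop or error per policy")

    def drop_incomplete(self) -> "MethylomeMatrix":
        """Return a copy with rows containing missing values removed."""
        keep = ~np.isnan(self.values).any(axis=1)
        return MethylomeMatrix(
            self.sites.loc[keep].reset_index(drop=True),
            self.samples,
            self.values[keep],
        )

    def subset_chroms(self, chroms: tuple[str, ...] = DEFAULT_AUTOSOMES) -> "MethylomeMatrix":
        """Restrict to the given chromosomes (default: human autosomes)."""
        keep = self.sites["chrom"].isin(chroms).to_numpy()
        return MethylomeMatrix(
            self.sites.loc[keep].reset_index(drop=True), self.samples, self.values[keep]
        )


@dataclass
class SegmentTrack:
    """A labeled segmentation of the genome.

    ``segments`` has columns chrom, start, end, state; states are
    M/I/U/V for methylation categories, D for CpG deserts, B for blacklist.
    The "extended" dialect must tile each chromosome completely; the
    "regions" dialect may leave gaps.
    """

    segments: pd.DataFrame
    chrom_lengths: dict[str, int] | None = None

    def validate(self, dialect: str = "regions") -> None:
        segs = sort_intervals(self.segments)
        assert_disjoint(segs, "segments")
        if dialect == "extended":
            for chrom, grp in segs.groupby("chrom", sort=False, observed=True):
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                if starts[0] != 0:
                    raise ValueError(f"extended track on {chrom} does not start at 0")
                if (starts[1:] != ends[:-1]).any():
                    k = int(np.argmax(starts[1:] != ends[:-1]))
                    raise ValueError(
                        f"gap in extended track on {chrom} between "
                        f"{ends[k]} and {starts[k + 1]}"
                    )
                if self.chrom_lengths is not None and ends[-1] != self.chrom_lengths[str(chrom)]:
                    raise ValueError(
                        f"extended track on {chrom} ends at {ends[-1]}, "
                        f"chromosome length is {self.chrom_lengths[str(chrom)]}"
                    )
        elif dialect != "regions":
            raise ValueError(f"unknown track dialect {dialect!r}")


# ---------------------------------------------------------------------------
# methylome bedGraphs


def _read_bedgraph(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed bedGraph {path}: {exc}") from exc
    bad = df["value"].notna() & ((df["value"] < 0) | (df["value"] > 100))
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"{path} line {i + 1}: methylation value {df['value'].iloc[i]} outside [0, 100]"
        )
    if (df["end"] - df["start"] != CPG_WIDTH).any():
        i = int(np.argmax((df["end"] - df["start"] != CPG_WIDTH).to_numpy()))
        raise ValueError(
            f"{path} line {i + 1}: CpG site is not a 2-bp interval "
            f"([{df['start'].iloc[i]}, {df['end'].iloc[i]}))"
        )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, cell_type, tissue_type)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cell_type", "tissue_type"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in metadata")
    if meta[["cell_type", "tissue_type"]].isna().any().any() or (
        meta[["cell_type", "tissue_type"]] == ""
    ).any().any():
        raise ValueError("every sample needs a non-empty cell_type and tissue_type")
    return meta.reset_index(drop=True)


def read_methylome_set(
    paths: list[str | Path],
    meta: str | Path | pd.DataFrame,
    union: bool = False,
    chroms: tuple[str, ...] | None = None,
) -> MethylomeMatrix:
    """Read one bedGraph per sample into a sites x samples matrix.

    Files are matched to metadata rows by filename stem == sample_id when
    all stems are present in the metadata, otherwise positionally; column
    order always follows the metadata order.

    Parameters
    ----------
    union : if False (default) all samples must share an identical CpG site
        list and the first discordant site raises; if True the site union is
        used with NaN where a sample lacks a site.
    chroms : optional chromosome whitelist (e.g. autosomes) applied on read.
    """
    if len(paths) == 0:
        raise ValueError("empty sample list: no methylomes to read")
    meta_df = meta if isinstance(meta, pd.DataFrame) else read_sample_metadata(meta)
    if len(paths) != len(meta_df):
        raise ValueError(f"{len(paths)} files but {len(meta_df)} metadata rows")
    stems = [Path(p).stem.removesuffix(".bedGraph") for p in paths]
    if set(stems) == set(meta_df["sample_id"]):
        order = {s: p for s, p in zip(stems, paths)}
        paths = [order[s] for s in meta_df["sample_id"]]
    tables = [_read_bedgraph(p) for p in paths]
    if chroms is not None:
        tables = [t[t["chrom"].isin(chroms)].reset_index(drop=True) for t in tables]

    ref = tables[0][["chrom", "start", "end"]]
    if not union:
        for path, tab in zip(paths[1:], tables[1:]):
            other = tab[["chrom", "start", "end"]]
            if len(other) != len(ref) or not other.equals(ref):
                merged = ref.merge(other, how="outer", indicator=True)
                disc = merged[merged["_merge"] != "both"].iloc[0]
                raise ValueError(
                    f"CpG site lists differ (no union policy): first discordant "
                    f"site {disc['chrom']}:{disc['start']} (vs {path})"
                )
        sites = ref
        values = np.column_stack([t["value"].to_numpy() for t in tables])
    else:
        sites = (
            pd.concat([t[["chrom", "start", "end"]] for t in tables])
            .drop_duplicates()
            .sort_values(["chrom", "start"], kind="mergesort")
            .reset_index(drop=True)
        )
        key = pd.MultiIndex.from_frame(sites[["chrom", "start"]])
        values = np.full((len(sites), len(tables)), np.nan)
        for j, t in enumerate(tables):
            idx = key.get_indexer(pd.MultiIndex.from_frame(t[["chrom", "start"]]))
            values[idx, j] = t["value"].to_numpy()
    if sites.duplicated(["chrom", "start"]).any():
        raise ValueError("duplicate CpG sites within one methylome")
    return MethylomeMatrix(sites.reset_index(drop=True), meta_df, values)


def write_methylome_set(matrix: MethylomeMatrix, outdir: str | Path) -> list[Path]:
    """Write one bedGraph per sample under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sid in enumerate(matrix.samples["sample_id"]):
        df = matrix.sites.copy()
        df["value"] = matrix.values[:, j]
        p = outdir / f"{sid}.bedGraph"
        df.to_csv(p, sep="\t", header=False, index=False, float_format="%.4g")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# BED interval sets


def read_bed(path: str | Path, label_column: int | None = None) -> pd.DataFrame:
    """Read a BED3+ file into a sorted interval DataFrame.

    ``label_column`` is the 0-based column index carrying a label (state
    name, TF name); when given the result has a ``label`` column.
    Zero-length or inverted intervals raise; unsorted input is sorted with
    a log message.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    cols = {0: "chrom", 1: "start", 2: "end"}
    if label_column is not None:
        if label_column >= df.shape[1]:
            raise ValueError(f"{path}: no column {label_column} for labels")
        cols[label_column] = "label"
    df = df.rename(columns=cols)[list(cols.values())]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.argmax(bad.to_numpy()))
        raise ValueError(
            f"{path} line {i + 1}: empty or inverted interval "
            f"[{df['start'].iloc[i]}, {df['end'].iloc[i]})"
        )
    if not df[["chrom", "start"]].equals(
        df[["chrom", "start"]].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    ):
        logger.info("%s is unsorted; sorting by (chrom, start)", path)
    return sort_intervals(df)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write an interval DataFrame as BED3/BED4 (label in the name column)."""
    cols = ["chrom", "start", "end"] + (["label"] if "label" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def write_segment_track(track: SegmentTrack, path: str | Path, dialect: str = "extended") -> None:
    """Write a segmentation as BED4 with the state in the name column.

    The "extended" dialect requires a complete tiling of each chromosome;
    "regions" accepts gaps.  Overlapping segments always raise.
    """
    track.validate(dialect=dialect)
    out = track.segments.rename(columns={"state": "label"})
    write_bed(sort_intervals(out), path)


def read_segment_track(path: str | Path, chrom_lengths: dict[str, int] | None = None) -> SegmentTrack:
    df = read_bed(path, label_column=3).rename(columns={"label": "state"})
    return SegmentTrack(df, chrom_lengths)


# ---------------------------------------------------------------------------
# gene models, GWAS tables, chrom sizes


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read a gene-model TSV (gene_id, chrom, strand, txStart, txEnd,
    exonStarts, exonEnds with comma-separated blocks, UCSC style).

    Exon blocks are validated: within [txStart, txEnd), sorted,
    non-overlapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    df = df.rename(
        columns={"txStart": "tx_start", "txEnd": "tx_end",
                 "exonStarts": "exon_starts", "exonEnds": "exon_ends"}
    )
    required = {"gene_id", "chrom", "strand", "tx_start", "tx_end", "exon_starts", "exon_ends"}
    if not required.issubset(df.columns):
        raise ValueError(f"gene model table needs columns {sorted(required)}")

    def parse_blocks(s: str) -> list[int]:
        return [int(x) for x in str(s).rstrip(",").split(",") if x != ""]

    starts = df["exon_starts"].map(parse_blocks)
    ends = df["exon_ends"].map(parse_blocks)
    for gid, st, en, lo, hi in zip(df["gene_id"], starts, ends, df["tx_start"], df["tx_end"]):
        if len(st) != len(en):
            raise ValueError(f"gene {gid}: exonStarts/exonEnds length mismatch")
        prev_end = lo
        for s, e in zip(st, en):
            if s >= e or s < lo or e > hi or s < prev_end:
                raise ValueError(f"gene {gid}: invalid exon block [{s}, {e})")
            prev_end = e
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("strand must be + or -")
    df["exon_starts"] = starts
    df["exon_ends"] = ends
    return df.reset_index(drop=True)


def read_gwas_table(path: str | Path) -> pd.DataFrame:
    """Read a GWAS-catalog-style TSV (chrom, pos, rsid, trait); one row per
    (rsid, trait) association, pos 0-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "rsid": str, "trait": str})
    required = {"chrom", "pos", "rsid", "trait"}
    if not required.issubset(df.columns):
        raise ValueError(f"GWAS table needs columns {sorted(required)}")
    df["pos"] = df["pos"].astype(np.int64)
    if (df["pos"] < 0).any():
        raise ValueError("GWAS variant position < 0")
    return df.reset_index(drop=True)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom-sizes file (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], dtype={0: str})
    return dict(zip(df["chrom"], df["length"].astype(int)))


def write_chrom_sizes(chrom_lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")
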