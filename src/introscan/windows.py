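"""Windowed aggregation of per-SNP local-ancestry proportions.

An admixed recipient population (here, a European pig breed with historical
Chinese introgression) carries, at every SNP, an estimated proportion of
ancestry copied from each of three donor populations: Meishan (MS),
Bamaxiang (BMX) and European wild boar (EUW).  This module lays a grid of
non-overlapping fixed-size windows (50 kb by default) over the genome,
averages the per-SNP proportions within each window, and produces
genome-wide summaries (per-donor mean and standard error across SNPs).

Coordinates are 0-based half-open internally; on-disk conversions live in
:mod:`introscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Donor population labels, in fixed column order.
DONORS = ("MS", "BMX", "EUW")

#: Ancestry-proportion column names in AncestryTrack / WindowTable frames.
PROP_COLS = tuple(f"p_{d}" for d in DONORS)

#: Default window size in bp.
WINDOW_SIZE = 50_000

#: Tolerance for the per-SNP proportions summing to one.
PROP_SUM_TOL = 1e-6


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths and autosome flags.

    The order is meaningful: it defines the concatenation used by the
    circular permutation test (SSC1..SSC18 semantics).
    """

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    autosome: tuple[bool, ...] = field(default=())

    def __post_init__(self):
        if len(self.names) == 0:
            raise ValueError("empty genome layout")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate chromosome names in layout")
        if len(self.lengths) != len(self.names):
            raise ValueError("names and lengths differ in length")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if len(self.autosome) == 0:
            object.__setattr__(self, "autosome", tuple(True for _ in self.names))
        elif len(self.autosome) != len(self.names):
            raise ValueError("autosome flags and names differ in length")

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.names.index(chrom)]

    def is_autosome(self, chrom: str) -> bool:
        return self.autosome[self.names.index(chrom)]

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))


def validate_track(track: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Validate an AncestryTrack frame (chrom, pos, p_MS, p_BMX, p_EUW).

    Checks the sum-to-one constraint per SNP and strictly increasing
    positions within each chromosome; returns the frame sorted in layout
    order (or input chromosome order if no layout is given).
    """
    required = ["chrom", "pos", *PROP_COLS]
    missing = [c for c in required if c not in track.columns]
    if missing:
        raise ValueError(f"ancestry track missing columns: {missing}")
    sums = track[list(PROP_COLS)].sum(axis=1).to_numpy()
    bad = np.flatnonzero(np.abs(sums - 1.0) > PROP_SUM_TOL)
    if bad.size:
        raise ValueError(
            f"ancestry proportions do not sum to 1 at row(s) {bad[:5].tolist()}"
            f" (first bad sum {sums[bad[0]]:.6g})"
        )
    if layout is not None:
        unknown = set(track["chrom"]) - set(layout.names)
        if unknown:
            raise ValueError(f"ancestry track has unknown chromosome(s): {sorted(unknown)}")
        order = {c: i for i, c in enumerate(layout.names)}
        key = track["chrom"].map(order)
        track = track.iloc[np.lexsort((track["pos"].to_numpy(), key.to_numpy()))]
        for chrom, sub in track.groupby("chrom", sort=False):
            length = layout.length_of(str(chrom))
            pos = sub["pos"].to_numpy()
            if pos.size and (pos[-1] >= length or pos[0] < 0):
                off = pos[(pos >= length) | (pos < 0)][0]
                raise ValueError(f"SNP at {chrom}:{off} outside chromosome (length {length})")
    else:
        track = track.sort_values(["chrom", "pos"], kind="mergesort")
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if pos.size > 1 and not np.all(np.diff(pos) > 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0])
            raise ValueError(f"duplicate/unsorted position on {chrom} near pos {pos[i]}")
    return track.reset_index(drop=True)


def window_grid(layout: GenomeLayout, size_bp: int = WINDOW_SIZE) -> pd.DataFrame:
    """Skeleton WindowTable: the non-overlapping window grid over a layout.

    Per chromosome the windows are [0, size), [size, 2*size), ...; the final
    window is truncated at the chromosome length, so the total count is
    sum(ceil(length / size)).  Columns: chrom, start, end, window_index
    (global, in layout order), plus empty n_snps and ancestry/FST slots.
    """
    if size_bp <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in zip(layout.names, layout.lengths):
        starts = np.arange(0, length, size_bp, dtype=np.int64)
        ends = np.minimum(starts + size_bp, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    grid = pd.concat(rows, ignore_index=True)
    grid.attrs["size_bp"] = int(size_bp)
    grid["window_index"] = np.arange(len(grid), dtype=np.int64)
    grid["n_snps"] = 0
    for c in PROP_COLS:
        grid[c] = np.nan
    grid["p_CHN"] = np.nan
    return grid


def _window_of(positions: np.ndarray, size_bp: int) -> np.ndarray:
    return positions // size_bp


def assign_windows(track: pd.DataFrame, grid: pd.DataFrame, layout: GenomeLayout) -> np.ndarray:
    """Global window index of each SNP in ``track`` on ``grid``."""
    size_bp = int(grid.attrs.get("size_bp", (grid["end"] - grid["start"]).max()))
    first_idx = grid.groupby("chrom", sort=False)["window_index"].min()
    idx = np.empty(len(track), dtype=np.int64)
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        length = layout.length_of(str(chrom))
        if pos.size and pos.max() >= length:
            bad = pos[pos >= length][0]
            raise ValueError(f"SNP at {chrom}:{bad} beyond chromosome length {length}")
        idx[sub.index.to_numpy()] = first_idx[chrom] + _window_of(pos, size_bp)
    return idx


def aggregate_ancestry(
    track: pd.DataFrame, grid: pd.DataFrame, layout: GenomeLayout
) -> pd.DataFrame:
    """Fill per-window mean donor proportions into a window-grid skeleton.

    Each donor mean is the unweighted mean over the SNPs whose position falls
    in the window.  Windows without SNPs keep NaN means (they are excluded
    from candidate calling and from empirical quantiles downstream).
    Chinese ancestry p_CHN is the sum of the MS and BMX means.
    """
    track = track.reset_index(drop=True)
    out = grid.copy()
    widx = assign_windows(track, grid, layout)
    counts = np.bincount(widx, minlength=len(grid))
    out["n_snps"] = counts
    with np.errstate(invalid="ignore"):
        for c in PROP_COLS:
            sums = np.bincount(widx, weights=track[c].to_numpy(), minlength=len(grid))
            out[c] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out["p_CHN"] = out["p_MS"] + out["p_BMX"]
    return out


def genomewide_summary(track: pd.DataFrame, table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-donor genome-wide mean and standard error.

    The primary summary is across SNPs: mean of the per-SNP proportions and
    SE = sample standard deviation / sqrt(n SNPs).  If a filled WindowTable
    is given, the mean across SNP-bearing windows is reported alongside.
    """
    if len(track) == 0:
        raise ValueError("empty ancestry track")
    rows = {}
    for d, c in zip(DONORS, PROP_COLS):
        x = track[c].to_numpy(dtype=float)
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        rows[d] = {"mean_snp": x.mean(), "se_snp": sd / np.sqrt(x.size)}
        if table is not None:
            w = table.loc[table["n_snps"] > 0, c].to_numpy(dtype=float)
            rows[d]["mean_window"] = w.mean() if w.size else np.nan
    return pd.DataFrame(rows).T.rename_axis("donor")
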