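"""Candidate adaptive-introgression windows and extended top-ancestry regions.

A candidate window has strictly more than 50% Chinese ancestry
(p_MS + p_BMX) and Meishan-Bamaxiang FST not in the top 5% of the empirical
window distribution (extreme MS-BMX differentiation would indicate the
reverse, European-to-China, direction of gene flow rather than a shared
Chinese haplotype).  Top-ancestry regions grow outward from the
highest-donor-ancestry seed windows until ancestry drops below 50% or FST
turns extreme; only regions of at least two windows are reported among the
top five.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fst import fst_quantile
from .windows import GenomeLayout  # noqa: F401  (re-exported for callers)


@dataclass
class CandidateRegionSet:
    """Sorted, non-overlapping regions plus their member window indices."""

    regions: pd.DataFrame  # chrom, start, end, n_windows, seed ancestry, means
    window_indices: np.ndarray  # global indices of all member windows
    provenance: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _extreme_mask(table: pd.DataFrame, fst_col: str, q: float) -> tuple[np.ndarray, float]:
    """Windows strictly above the empirical q-quantile of ``fst_col``."""
    vals = table[fst_col].to_numpy(dtype=float)
    thr = fst_quantile(vals[table["n_snps"].to_numpy() > 0], q)
    return (vals > thr), thr


def _runs_to_regions(table: pd.DataFrame, member: np.ndarray) -> pd.DataFrame:
    """Merge adjacent member windows (same chromosome, consecutive index)."""
    idx = np.flatnonzero(member)
    rows = []
    if idx.size:
        chroms = table["chrom"].to_numpy()
        breaks = np.flatnonzero(
            (np.diff(idx) != 1) | (chroms[idx[1:]] != chroms[idx[:-1]])
        )
        for run in np.split(idx, breaks + 1):
            sub = table.iloc[run]
            rows.append(
                {
                    "chrom": sub["chrom"].iloc[0],
                    "start": int(sub["start"].iloc[0]),
                    "end": int(sub["end"].iloc[-1]),
                    "n_windows": len(run),
                    "window_indices": run.tolist(),
                    "mean_p_CHN": float(sub["p_CHN"].mean()),
                    "mean_p_MS": float(sub["p_MS"].mean()),
                    "mean_p_BMX": float(sub["p_BMX"].mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "n_windows", "window_indices",
            "mean_p_CHN", "mean_p_MS", "mean_p_BMX",
        ],
    )


def call_candidates(
    table: pd.DataFrame,
    chinese_min: float = 0.5,
    fst_col: str = "fst_MS_BMX",
    fst_q: float = 0.95,
) -> CandidateRegionSet:
    """Candidate windows: Chinese ancestry > ``chinese_min``, FST not extreme.

    Both thresholds are strict per the stated rules: ancestry must exceed
    the cutoff, and a window is excluded only when its MS-BMX FST is
    strictly above the empirical ``fst_q`` quantile.  Windows with no SNPs
    or undefined FST never qualify.  Adjacent surviving windows are also
    reported merged into runs.
    """
    has_snps = table["n_snps"].to_numpy() > 0
    if not has_snps.any():
        raise ValueError("no SNP-bearing windows in the table")
    extreme, thr = _extreme_mask(table, fst_col, fst_q)
    chn = table["p_CHN"].to_numpy(dtype=float)
    fst_defined = ~np.isnan(table[fst_col].to_numpy(dtype=float))
    member = has_snps & fst_defined & (chn > chinese_min) & ~extreme
    regions = _runs_to_regions(table, member)
    return CandidateRegionSet(
        regions=regions,
        window_indices=table["window_index"].to_numpy()[member],
        provenance={
            "filter": "candidate",
            "chinese_min": chinese_min,
            "fst_col": fst_col,
            "fst_quantile": fst_q,
            "fst_threshold": thr,
            "n_candidate_windows": int(member.sum()),
        },
    )


def extend_top_regions(
    table: pd.DataFrame,
    donor: str = "MS",
    k: int = 5,
    min_windows: int = 2,
    ancestry_min: float = 0.5,
    fst_col: str = "fst_MS_BMX",
    fst_q: float = 0.95,
) -> CandidateRegionSet:
    """Top-``k`` extended regions of highest single-donor ancestry.

    Seeds are the highest-``donor``-ancestry windows that are SNP-bearing
    and not extreme in MS-BMX FST; each seed is extended left and right
    while the next window on the same chromosome has donor ancestry
    >= ``ancestry_min`` and is not extreme-FST (SNP-less windows terminate
    the extension).  Regions with fewer than ``min_windows`` windows are
    dropped; the top ``k`` survivors are returned ranked by seed-window
    ancestry, ties broken by earlier genomic coordinate.  If fewer than
    ``k`` qualify, all found are returned and ``provenance['short']`` is set.
    """
    if donor not in ("MS", "BMX"):
        raise ValueError("donor must be 'MS' or 'BMX'")
    col = f"p_{donor}"
    anc = table[col].to_numpy(dtype=float)
    has_snps = table["n_snps"].to_numpy() > 0
    if not has_snps.any():
        raise ValueError("no SNP-bearing windows in the table")
    extreme, thr = _extreme_mask(table, fst_col, fst_q)
    chroms = table["chrom"].to_numpy()
    eligible_seed = has_snps & ~extreme & ~np.isnan(anc)
    extendable = eligible_seed & (anc >= ancestry_min)

    assigned = np.zeros(len(table), dtype=bool)
    found: list[dict] = []
    # seeds in descending ancestry; ties resolved by earlier coordinate
    order = np.lexsort((np.arange(len(table)), -np.where(eligible_seed, anc, -np.inf)))
    for seed in order:
        if not eligible_seed[seed] or assigned[seed]:
            continue
        lo = hi = seed
        while lo - 1 >= 0 and chroms[lo - 1] == chroms[seed] and extendable[lo - 1] and not assigned[lo - 1]:
            lo -= 1
        while hi + 1 < len(table) and chroms[hi + 1] == chroms[seed] and extendable[hi + 1] and not assigned[hi + 1]:
            hi += 1
        run = np.arange(lo, hi + 1)
        assigned[run] = True
        sub = table.iloc[run]
        found.append(
            {
                "chrom": chroms[seed],
                "start": int(sub["start"].iloc[0]),
                "end": int(sub["end"].iloc[-1]),
                "n_windows": len(run),
                "window_indices": run.tolist(),
                "seed_window_index": int(table["window_index"].iloc[seed]),
                "seed_ancestry": float(anc[seed]),
                "mean_p_CHN": float(sub["p_CHN"].mean()),
                "mean_p_MS": float(sub["p_MS"].mean()),
                "mean_p_BMX": float(sub["p_BMX"].mean()),
            }
        )
    qualifying = [r for r in found if r["n_windows"] >= min_windows]
    top = qualifying[:k]
    regions = pd.DataFrame(
        top,
        columns=[
            "chrom", "start", "end", "n_windows", "window_indices",
            "seed_window_index", "seed_ancestry",
            "mean_p_CHN", "mean_p_MS", "mean_p_BMX",
        ],
    )
    member = np.concatenate([r["window_indices"] for r in top]) if top else np.array([], dtype=np.int64)
    return CandidateRegionSet(
        regions=regions,
        window_indices=table["window_index"].to_numpy()[member.astype(np.int64)]
        if member.size
        else member.astype(np.int64),
        provenance={
            "filter": f"extend_top_{donor}",
            "k": k,
            "min_windows": min_windows,
            "ancestry_min": ancestry_min,
            "fst_threshold": thr,
            "short": len(qualifying) < k,
        },
    )
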