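"""QTL filtering, peak derivation and circular-rotation enrichment testing.

QTL records (emulating Animal QTLdb dumps) carry a trait, one of five trait
groups, a mapping method and a genomic interval.  The analysis keeps only
association-mapped records on autosomes spanning at most 1 Mb (linkage-mapped
records have uncertain genomic locations), collapses records with identical
(trait group, interval) to one, takes each record's interval midpoint as its
peak, and counts peaks inside candidate introgression regions.

Significance of the in-region count comes from a circular permutation: the
autosomes are concatenated in layout order into a circle of 50-kb windows,
and the whole candidate-window set is rotated by a random number of windows,
preserving the spacing between candidate regions while randomizing their
position relative to the fixed QTL peaks.  The empirical p-value is the
fraction of rotations whose count reaches the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The five Animal QTLdb trait classes.
TRAIT_GROUPS = ("meat and carcass", "production", "reproduction", "health", "exterior")

QTL_COLUMNS = ["qtl_id", "trait", "trait_group", "method", "chrom", "start", "end"]


@dataclass
class PermutationResult:
    """Outcome of the circular-rotation test for one scope (all or a group)."""

    scope: str
    observed: int
    n_perm: int
    null_counts: np.ndarray
    p_value: float | None
    seed: int | None = None
    reason: str | None = None


def filter_qtls(
    records: pd.DataFrame,
    layout,
    max_span_bp: int = 1_000_000,
) -> tuple[pd.DataFrame, dict]:
    """Two-stage QTL filter with audit bookkeeping.

    Stage 1 drops linkage-mapped records (uncertain genomic locations);
    stage 2 drops records on non-autosomes (unknown chromosome names count
    as non-autosomal) or spanning more than ``max_span_bp``.  Intervals are
    0-based half-open, so the span is end - start.
    """
    missing = [c for c in QTL_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"QTL table missing columns: {missing}")
    n_input = len(records)
    assoc = records[records["method"] != "linkage"]
    n_linkage = n_input - len(assoc)

    autosomes = {c for c, a in zip(layout.names, layout.autosome) if a}
    on_autosome = assoc["chrom"].isin(autosomes).to_numpy()
    span_ok = (assoc["end"] - assoc["start"]).to_numpy() <= max_span_bp
    kept = assoc[on_autosome & span_ok].reset_index(drop=True)
    audit = {
        "n_input": n_input,
        "n_dropped_linkage": n_linkage,
        "n_after_linkage": len(assoc),
        "n_dropped_location_or_span": int(len(assoc) - len(kept)),
        "n_dropped_non_autosome": int((~on_autosome).sum()),
        "n_dropped_span": int((on_autosome & ~span_ok).sum()),
        "n_output": len(kept),
    }
    return kept, audit


def dedup_and_peaks(records: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Collapse identical (trait group, interval) records; derive peaks.

    Two records in the same trait group with the same genomic interval count
    as one QTL; the same rule applied within each group is automatic with
    the group-inclusive key.  The peak is the interval midpoint.  The audit
    also reports the tally under a group-agnostic interval key, since
    identical intervals in different groups count separately by default.
    """
    key = ["trait_group", "chrom", "start", "end"]
    deduped = records.drop_duplicates(subset=key, keep="first").reset_index(drop=True)
    deduped = deduped.copy()
    deduped["peak"] = (deduped["start"].to_numpy() + deduped["end"].to_numpy()) // 2
    audit = {
        "n_input": len(records),
        "n_collapsed": len(records) - len(deduped),
        "n_output": len(deduped),
        "n_output_interval_key": int(
            len(records.drop_duplicates(subset=["chrom", "start", "end"]))
        ),
        "per_group": deduped["trait_group"].value_counts().to_dict(),
    }
    return deduped, audit


def count_in_regions(peaks: pd.DataFrame, regions: pd.DataFrame) -> dict:
    """Count QTL peaks falling inside candidate regions (half-open).

    ``peaks`` needs chrom, peak and trait_group columns; ``regions`` needs
    chrom, start, end.  A peak on a region start is inside; on the end, not.
    Returns {'all': n, '<group>': n, ...} over the five trait groups.
    """
    inside = np.zeros(len(peaks), dtype=bool)
    pk_chrom = peaks["chrom"].to_numpy()
    pk_pos = peaks["peak"].to_numpy()
    for chrom, sub in regions.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        m = pk_chrom == chrom
        if not m.any():
            continue
        j = np.searchsorted(starts, pk_pos[m], side="right") - 1
        hit = (j >= 0) & (pk_pos[m] < ends[np.maximum(j, 0)])
        inside[np.flatnonzero(m)] = hit
    counts = {"all": int(inside.sum())}
    groups = peaks["trait_group"].to_numpy()
    for g in TRAIT_GROUPS:
        counts[g] = int((inside & (groups == g)).sum())
    return counts


def _window_circle(grid: pd.DataFrame, layout) -> tuple[pd.DataFrame, dict[int, int]]:
    """Autosomal windows in layout order; map global window index -> circle slot."""
    autosomes = {c for c, a in zip(layout.names, layout.autosome) if a}
    circ = grid[grid["chrom"].isin(autosomes)].reset_index(drop=True)
    pos_of = {int(w): i for i, w in enumerate(circ["window_index"].to_numpy())}
    return circ, pos_of


def peak_window_indices(peaks: pd.DataFrame, grid: pd.DataFrame, layout) -> np.ndarray:
    """Global window index housing each peak (-1 if off-layout)."""
    size_bp = int(grid.attrs.get("size_bp", (grid["end"] - grid["start"]).max()))
    first_idx = grid.groupby("chrom", sort=False)["window_index"].min().to_dict()
    out = np.full(len(peaks), -1, dtype=np.int64)
    chrom = peaks["chrom"].to_numpy()
    pos = peaks["peak"].to_numpy()
    for c in np.unique(chrom):
        if c not in first_idx:
            continue
        m = chrom == c
        out[m] = first_idx[c] + pos[m] // size_bp
    return out


def exact_rotation_counts(
    candidate_slots: np.ndarray, peak_hist: np.ndarray
) -> np.ndarray:
    """In-region peak count for every rotation offset 0..W-1 (enumeration)."""
    W = len(peak_hist)
    counts = np.empty(W, dtype=np.int64)
    for d in range(W):
        counts[d] = peak_hist[(candidate_slots + d) % W].sum()
    return counts


def circular_permutation_test(
    candidate_window_indices: np.ndarray,
    peaks: pd.DataFrame,
    grid: pd.DataFrame,
    layout,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, PermutationResult]:
    """Circular-rotation enrichment test, all traits and per trait group.

    The candidate window set is rotated jointly by a uniform offset in
    1..W-1 whole windows on the concatenated autosomal window circle (the
    identity offset 0 is excluded so the null never contains the observation
    tautologically); peaks stay fixed.  One stream of offsets is shared
    across all scopes so the per-group results are comparable under
    identical nulls.  Membership is window-level: a peak is inside a rotated
    region iff its home window is in the rotated candidate set.
    Empirical p = (# rotations with null count >= observed) / n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    circ, pos_of = _window_circle(grid, layout)
    W = len(circ)
    scopes = ["all", *TRAIT_GROUPS]

    cand = np.asarray(candidate_window_indices, dtype=np.int64)
    if cand.size == 0:
        return {
            s: PermutationResult(s, 0, n_perm, np.zeros(0, dtype=np.int64), None,
                                 seed_val, reason="empty candidate set")
            for s in scopes
        }
    try:
        slots = np.array([pos_of[int(w)] for w in cand], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"candidate window {e} is not on the autosomal circle") from e

    pw = peak_window_indices(peaks, grid, layout)
    groups = peaks["trait_group"].to_numpy()
    hists = {}
    for s in scopes:
        m = np.ones(len(peaks), dtype=bool) if s == "all" else groups == s
        m &= pw >= 0
        hist = np.zeros(W, dtype=np.int64)
        on_circle = np.array([pos_of.get(int(w), -1) for w in pw[m]], dtype=np.int64)
        on_circle = on_circle[on_circle >= 0]
        np.add.at(hist, on_circle, 1)
        hists[s] = hist

    offsets = rng.integers(1, W, size=n_perm) if W > 1 else np.zeros(n_perm, dtype=np.int64)
    results = {}
    for s in scopes:
        hist = hists[s]
        observed = int(hist[slots].sum())
        null = np.empty(n_perm, dtype=np.int64)
        chunk = max(1, int(2_000_000 // max(slots.size, 1)))
        for i in range(0, n_perm, chunk):
            off = offsets[i : i + chunk]
            null[i : i + chunk] = hist[(slots[None, :] + off[:, None]) % W].sum(axis=1)
        p = float((null >= observed).sum() / n_perm)
        results[s] = PermutationResult(s, observed, n_perm, null, p, seed_val)
    return results
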