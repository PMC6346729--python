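"""Hudson's two-population FST per biallelic site, with window averaging.

The per-site estimator uses sample allele frequencies p1 = ref1/n1,
p2 = ref2/n2 with an unbiased within-population heterozygosity correction:

    numerator   = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    denominator = p1(1-p2) + p2(1-p1)
    FST         = numerator / denominator

Site values may be negative (sampling noise around zero differentiation);
clamping to [0, 1] happens only at the window level, where negative window
means are set to 0.  Sites with fewer than two allele calls in either
population, or with zero denominator (both populations monomorphic for the
same allele), are undefined and excluded from window means.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import pysam


def hudson_fst_site(
    ref1: np.ndarray | float,
    n1: np.ndarray | float,
    ref2: np.ndarray | float,
    n2: np.ndarray | float,
) -> np.ndarray:
    """Per-site Hudson FST from allele counts; NaN where undefined.

    Parameters are reference-allele counts and total called allele counts
    per population (scalars or aligned arrays).  Undefined when n < 2 in
    either population or the denominator is zero.
    """
    ref1 = np.asarray(ref1, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    ref2 = np.asarray(ref2, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(ref1 > n1) or np.any(ref2 > n2) or np.any(ref1 < 0) or np.any(ref2 < 0):
        raise ValueError("allele counts must satisfy 0 <= ref <= total")
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, ref1 / n1, np.nan)
        p2 = np.where(n2 > 0, ref2 / n2, np.nan)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = np.where(ok & (den != 0), num / den, np.nan)
    return fst if fst.ndim else float(fst)


def site_counts_from_haplotypes(haps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ref count, total count) per site from a 0/1 haplotype matrix.

    ``haps`` is haplotypes x sites with 0 = reference allele, 1 = alternate;
    negative entries mark missing calls and reduce the total.
    """
    haps = np.asarray(haps)
    called = haps >= 0
    total = called.sum(axis=0)
    ref = ((haps == 0) & called).sum(axis=0)
    return ref.astype(np.int64), total.astype(np.int64)


def site_counts_from_vcf(
    vcf_path: str, samples_by_pop: dict[str, list[str]]
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read biallelic SNPs and per-population allele counts from a VCF.

    Returns (sites frame with chrom/pos columns, ref-count arrays by
    population, total-count arrays by population).  Positions are converted
    to 0-based.  Missing genotype calls reduce the population total at that
    site; multi-allelic records are skipped.
    """
    pops = list(samples_by_pop)
    chroms, poss = [], []
    refc = {p: [] for p in pops}
    totc = {p: [] for p in pops}
    with pysam.VariantFile(vcf_path) as vf:
        sample_idx = {
            p: [s for s in samples_by_pop[p] if s in vf.header.samples] for p in pops
        }
        for p in pops:
            if len(sample_idx[p]) != len(samples_by_pop[p]):
                missing = set(samples_by_pop[p]) - set(sample_idx[p])
                raise ValueError(f"samples not in VCF for population {p}: {sorted(missing)}")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            chroms.append(rec.chrom)
            poss.append(rec.pos - 1)
            for p in pops:
                r = t = 0
                for s in sample_idx[p]:
                    for a in rec.samples[s]["GT"]:
                        if a is None:
                            continue
                        t += 1
                        if a == 0:
                            r += 1
                refc[p].append(r)
                totc[p].append(t)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64)})
    return (
        sites,
        {p: np.asarray(refc[p], dtype=np.int64) for p in pops},
        {p: np.asarray(totc[p], dtype=np.int64) for p in pops},
    )


def window_fst(
    site_values: np.ndarray, window_index: np.ndarray, n_windows: int
) -> np.ndarray:
    """Unweighted window mean over defined site FST values, clamped at 0.

    ``window_index`` gives each site's global window; NaN site values are
    ignored.  Windows with no defined site stay NaN; negative window means
    are set to 0 so window values lie in [0, 1].
    """
    site_values = np.asarray(site_values, dtype=float)
    defined = ~np.isnan(site_values)
    counts = np.bincount(window_index[defined], minlength=n_windows)
    sums = np.bincount(
        window_index[defined], weights=site_values[defined], minlength=n_windows
    )
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return np.where(np.isnan(means), np.nan, np.maximum(means, 0.0))


def fst_quantile(window_means: np.ndarray, q: float = 0.95) -> float:
    """Empirical q-quantile of the defined window means.

    Linear interpolation between closest order statistics.  Windows strictly
    above the returned threshold count as "extreme" downstream.
    """
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    vals = np.asarray(window_means, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no defined window means to take a quantile of")
    return float(np.quantile(vals, q, method="linear"))


def composite_duroc_chinese(fst_du_ms: np.ndarray, fst_du_bmx: np.ndarray) -> np.ndarray:
    """Duroc-Chinese differentiation: per-window mean of DU-MS and DU-BMX.

    Undefined (NaN) wherever either pair is undefined.
    """
    a = np.asarray(fst_du_ms, dtype=float)
    b = np.asarray(fst_du_bmx, dtype=float)
    if a.shape != b.shape:
        raise ValueError("window grids differ between the two FST tracks")
    return (a + b) / 2.0
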