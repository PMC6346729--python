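"""Regional haplotype extraction, distances to a reference, and display order.

For a genomic region of interest (in the source analysis, the NR6A1 locus on
SSC1), phased haplotypes from several populations are displayed as a 0/1
matrix with one row per haplotype and one column per SNP.  Each haplotype's
distance to a reference population is the Hamming distance to the
reference-population majority consensus; rows are grouped by average-linkage
hierarchical clustering on pairwise Hamming distances and ordered so that
haplotypes most similar to the reference appear first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass
class HaplotypeBlock:
    """Phased 0/1 haplotypes (rows) over the SNPs (columns) of one region."""

    chrom: str
    start: int
    end: int
    positions: np.ndarray  # 0-based, strictly increasing
    matrix: np.ndarray  # haplotypes x SNPs, values in {0, 1}
    populations: list[str]  # per haplotype row
    sample_names: list[str]  # per haplotype row, e.g. "DUR_3/1"

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if len(self.populations) != self.matrix.shape[0]:
            raise ValueError("one population label per haplotype row required")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("alleles must be 0/1 (no missing data post-phasing)")


def extract_block(
    vcf_path: str,
    chrom: str,
    start: int,
    end: int,
    populations: dict[str, str],
) -> HaplotypeBlock:
    """Extract phased biallelic haplotypes for a region from a VCF.

    ``populations`` maps sample name -> population label and selects the
    samples.  Coordinates are 0-based half-open.  Sites monomorphic across
    the selected haplotypes are dropped.  Unphased or missing genotypes are
    rejected (inputs are assumed phased and imputed upstream).
    """
    if end <= start:
        raise ValueError("empty region")
    samples = list(populations)
    positions, columns = [], []
    with pysam.VariantFile(vcf_path) as vf:
        absent = [s for s in samples if s not in vf.header.samples]
        if absent:
            raise ValueError(f"samples not in VCF: {absent}")
        for rec in vf:
            if rec.chrom != chrom or not (start <= rec.pos - 1 < end):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            col = []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if len(gt) != 2 or any(a is None for a in gt):
                    raise ValueError(
                        f"missing or non-diploid genotype for sample {s} at {chrom}:{rec.pos}"
                    )
                if not call.phased:
                    raise ValueError(f"unphased genotype for sample {s} at {chrom}:{rec.pos}")
                col.extend(int(a) for a in gt)
            col = np.asarray(col, dtype=np.int8)
            if col.min() == col.max():  # monomorphic in selection
                continue
            positions.append(rec.pos - 1)
            columns.append(col)
    matrix = (
        np.column_stack(columns) if columns else np.zeros((2 * len(samples), 0), dtype=np.int8)
    )
    pops, names = [], []
    for s in samples:
        for h in (1, 2):
            pops.append(populations[s])
            names.append(f"{s}/{h}")
    return HaplotypeBlock(
        chrom=chrom,
        start=start,
        end=end,
        positions=np.asarray(positions, dtype=np.int64),
        matrix=matrix,
        populations=pops,
        sample_names=names,
    )


def reference_consensus(block: HaplotypeBlock, reference_population: str) -> np.ndarray:
    """Majority allele per SNP among reference-population haplotypes.

    Ties (equal 0 and 1 counts) resolve to allele 0.
    """
    rows = [i for i, p in enumerate(block.populations) if p == reference_population]
    if not rows:
        raise ValueError(f"reference population {reference_population!r} absent from block")
    sub = block.matrix[rows]
    ones = sub.sum(axis=0)
    return (ones * 2 > len(rows)).astype(np.int8)


def hamming_to_reference(
    block: HaplotypeBlock,
    reference_population: str,
    mode: str = "consensus",
) -> np.ndarray:
    """Per-haplotype distance to the reference population.

    ``mode='consensus'`` (default): Hamming distance to the majority
    consensus.  ``mode='min'``: minimum Hamming distance to any individual
    reference haplotype.
    """
    if mode == "consensus":
        cons = reference_consensus(block, reference_population)
        return (block.matrix != cons[None, :]).sum(axis=1)
    if mode == "min":
        rows = [i for i, p in enumerate(block.populations) if p == reference_population]
        if not rows:
            raise ValueError(f"reference population {reference_population!r} absent from block")
        ref = block.matrix[rows]
        return np.array(
            [(h[None, :] != ref).sum(axis=1).min() for h in block.matrix], dtype=np.int64
        )
    raise ValueError("mode must be 'consensus' or 'min'")


def distances_and_order(
    block: HaplotypeBlock,
    reference_population: str,
    cluster_height: float = 0.0,
    mode: str = "consensus",
) -> dict:
    """Cluster haplotypes and order them by similarity to the reference.

    Rows are grouped by average-linkage hierarchical clustering on pairwise
    Hamming distances, cut at ``cluster_height`` (in SNP units; the default
    0 groups exactly identical haplotypes).  Cluster blocks are ordered by
    increasing mean distance-to-reference; within a block rows sort by
    increasing distance, then by allele string, then by input order — a
    deterministic rule that keeps identical haplotypes adjacent.

    Returns row order, per-row distances, labels and the matrix reordered
    for rendering.
    """
    n = block.matrix.shape[0]
    dist = hamming_to_reference(block, reference_population, mode=mode).astype(np.int64)
    if n > 1 and block.matrix.shape[1] > 0:
        pair = pdist(block.matrix, metric="hamming") * block.matrix.shape[1]
        labels = fcluster(linkage(pair, method="average"), t=cluster_height, criterion="distance")
    else:
        labels = np.ones(n, dtype=int)
    # order clusters by mean distance to reference, ties by first input index
    cluster_ids = np.unique(labels)
    cluster_rank = sorted(
        cluster_ids,
        key=lambda c: (float(dist[labels == c].mean()), int(np.flatnonzero(labels == c)[0])),
    )
    rank_of = {c: r for r, c in enumerate(cluster_rank)}
    keys = [
        (rank_of[labels[i]], int(dist[i]), block.matrix[i].tobytes(), i) for i in range(n)
    ]
    order = np.array([k[3] for k in sorted(keys)], dtype=np.int64)
    return {
        "order": order,
        "distances": dist,
        "cluster_labels": labels,
        "matrix": block.matrix[order],
        "populations": [block.populations[i] for i in order],
        "sample_names": [block.sample_names[i] for i in order],
        "positions": block.positions,
    }


def write_display_table(result: dict, path: str) -> None:
    """Tab-separated ordered haplotype table: label, population, distance, alleles."""
    with open(path, "w") as fh:
        fh.write("haplotype\tpopulation\tdistance\talleles\n")
        for i, row in enumerate(result["matrix"]):
            fh.write(
                f"{result['sample_names'][i]}\t{result['populations'][i]}\t"
                f"{result['distances'][result['order'][i]]}\t"
                f"{''.join(str(int(a)) for a in row)}\n"
            )


def plot_haplotypes(result: dict, path: str) -> None:
    """Optional raster rendering of the ordered haplotype matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(2, 0.08 * len(result["matrix"]))))
    ax.imshow(result["matrix"], aspect="auto", interpolation="nearest", cmap="Greys")
    ax.set_xlabel("SNP")
    ax.set_ylabel("haplotype (ordered by distance to reference)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
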