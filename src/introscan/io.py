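"""Readers and writers for the pipeline's on-disk formats, plus the runner.

Conventions: SNP and QTL tables are 1-based inclusive on disk and converted
to 0-based half-open in memory at the I/O boundary; BED outputs are 0-based
half-open.  Every file carries a header line stating its columns, and every
writer round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fst import (
    composite_duroc_chinese,
    hudson_fst_site,
    site_counts_from_vcf,
    window_fst,
)
from .qtl import (
    TRAIT_GROUPS,
    circular_permutation_test,
    count_in_regions,
    dedup_and_peaks,
    filter_qtls,
)
from .regions import CandidateRegionSet, call_candidates, extend_top_regions
from .windows import (
    PROP_COLS,
    GenomeLayout,
    aggregate_ancestry,
    assign_windows,
    genomewide_summary,
    validate_track,
    window_grid,
)

log = logging.getLogger("introscan")

ANCESTRY_HEADER = ["chrom", "pos", "p_MS", "p_BMX", "p_EUW"]
QTL_HEADER = ["qtl_id", "trait", "trait_group", "method", "chrom", "start", "end"]


# ---------------------------------------------------------------- layouts

def read_chrom_lengths(path: str | Path) -> GenomeLayout:
    """Two/three-column text: chromosome, length[, autosome flag 0/1]."""
    names, lengths, auto = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed line {lineno}: {line.rstrip()!r}")
            names.append(parts[0])
            lengths.append(int(parts[1]))
            auto.append(bool(int(parts[2])) if len(parts) > 2 else True)
    return GenomeLayout(names=tuple(names), lengths=tuple(lengths), autosome=tuple(auto))


def write_chrom_lengths(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tlength\tautosome\n")
        for n, l, a in zip(layout.names, layout.lengths, layout.autosome):
            fh.write(f"{n}\t{l}\t{int(a)}\n")


# ------------------------------------------------------- ancestry tables

def read_ancestry_table(path: str | Path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Per-SNP donor-proportion table (1-based positions on disk).

    Rows whose proportions do not sum to 1 within tolerance are rejected
    with their line number; positions must be sorted within chromosomes.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ANCESTRY_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sums = df[list(PROP_COLS)].sum(axis=1).to_numpy()
    bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-6)
    if bad.size:
        lines = (bad[:5] + 2).tolist()  # +1 header, +1 one-based
        raise ValueError(f"{path}: proportions do not sum to 1 at line(s) {lines}")
    df = df[ANCESTRY_HEADER].copy()
    df["pos"] = df["pos"].astype(np.int64) - 1
    return validate_track(df, layout)


def write_ancestry_table(track: pd.DataFrame, path: str | Path) -> None:
    out = track[ANCESTRY_HEADER].copy()
    out["pos"] = out["pos"].astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("# per-SNP donor ancestry proportions; pos is 1-based\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------------ QTL tables

def read_qtl_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated QTL table (1-based inclusive intervals on disk)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in QTL_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df = df[QTL_HEADER].copy()
    df["start"] = df["start"].astype(np.int64) - 1  # to half-open
    df["end"] = df["end"].astype(np.int64)
    if (df["start"] > df["end"]).any():
        raise ValueError(f"{path}: interval with start > end")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_qtl_table(records: pd.DataFrame, path: str | Path) -> None:
    out = records[QTL_HEADER].copy()
    out["start"] = out["start"].astype(np.int64) + 1
    with open(path, "w") as fh:
        fh.write("# QTL records; start/end are 1-based inclusive\n")
        out.to_csv(fh, sep="\t", index=False)


def read_qtl_gff(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Tolerant reader for Animal QTLdb-style GFF dumps.

    Parses attribute fields for QTL id, trait, trait group (``trait_type``
    or ``Trait_class``) and mapping method (``Map_Type``); records without a
    recognizable interval or attributes are skipped and counted in the audit.
    """
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            chrom, _, _, start, end, _, _, _, attrs = parts[:9]
            try:
                start_i, end_i = int(float(start)), int(float(end))
            except ValueError:
                skipped += 1
                continue
            kv = {}
            for item in attrs.replace("; ", ";").split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    kv[k.strip().lower()] = v.strip().strip('"')
            group = kv.get("trait_type", kv.get("trait_class", "")).lower()
            method = "linkage" if "link" in kv.get("map_type", "").lower() else "association"
            if group not in TRAIT_GROUPS:
                skipped += 1
                continue
            rows.append(
                {
                    "qtl_id": kv.get("qtl_id", kv.get("id", f"row{len(rows)}")),
                    "trait": kv.get("trait", kv.get("name", "")),
                    "trait_group": group,
                    "method": method,
                    "chrom": chrom.removeprefix("Chr."),
                    "start": start_i - 1,
                    "end": end_i,
                }
            )
    df = pd.DataFrame(rows, columns=QTL_HEADER)
    return df, {"n_parsed": len(df), "n_skipped": skipped}


# ---------------------------------------------------------- window tables

def write_window_table(table: pd.DataFrame, path: str | Path) -> None:
    """BED-like window table (0-based half-open starts)."""
    with open(path, "w") as fh:
        fh.write("# 50-kb window table; start/end are 0-based half-open (BED dialect)\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values="NA")
    df.attrs["size_bp"] = int((df["end"] - df["start"]).max())
    return df


def write_regions(rset: CandidateRegionSet, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Regions as BED plus an annotation table carrying filter provenance."""
    prov = rset.provenance.get("filter", "region")
    with open(bed_path, "w") as fh:
        for _, r in rset.regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{prov}\n")
    tbl = rset.regions.drop(columns=["window_indices"], errors="ignore").copy()
    with open(tsv_path, "w") as fh:
        fh.write(f"# provenance: {json.dumps(rset.provenance, sort_keys=True)}\n")
        tbl.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ------------------------------------------------------------------- VCF

def write_vcf(
    path: str | Path,
    sites: pd.DataFrame,
    haplotypes: np.ndarray,
    sample_names: list[str],
) -> None:
    """Minimal phased VCF 4.2: biallelic SNPs, GT only.

    ``haplotypes`` rows 2i and 2i+1 form diploid sample i; positions in
    ``sites`` are 0-based and written 1-based.
    """
    if haplotypes.shape[0] != 2 * len(sample_names):
        raise ValueError("need exactly two haplotype rows per sample")
    chrom_order = list(dict.fromkeys(sites["chrom"]))
    try:
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=introscan-simulate\n")
            for c in chrom_order:
                sub = sites[sites["chrom"] == c]
                fh.write(f"##contig=<ID={c},length={int(sub['pos'].max()) + 2}>\n")
            fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(sample_names)
                + "\n"
            )
            chroms = sites["chrom"].to_numpy()
            poss = sites["pos"].to_numpy()
            for j in range(len(sites)):
                gts = "\t".join(
                    f"{haplotypes[2 * i, j]}|{haplotypes[2 * i + 1, j]}"
                    for i in range(len(sample_names))
                )
                fh.write(f"{chroms[j]}\t{poss[j] + 1}\t.\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")
    except OSError as e:
        raise OSError(f"cannot write VCF to {path}: {e}") from e


def read_vcf_haplotypes(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a phased biallelic VCF back into (sites, haplotype matrix, samples)."""
    import pysam

    chroms, poss, cols = [], [], []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            chroms.append(rec.chrom)
            poss.append(rec.pos - 1)
            col = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                col.extend(-1 if a is None else int(a) for a in gt)
            cols.append(col)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.asarray(poss, dtype=np.int64)})
    matrix = (
        np.asarray(cols, dtype=np.int8).T if cols else np.zeros((2 * len(samples), 0), np.int8)
    )
    return sites, matrix, samples


def read_samples_table(path: str | Path) -> dict[str, str]:
    """Two-column sample -> population map."""
    out = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, pop = line.split()[:2]
            out[sample] = pop
    return out


def write_samples_table(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tpopulation\n")
        for s, p in mapping.items():
            fh.write(f"{s}\t{p}\n")


# --------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Analysis parameters (window size, thresholds, permutations) and paths."""

    window_size: int = 50_000
    chinese_min: float = 0.5
    fst_quantile: float = 0.95  # study value of the MS-BMX threshold itself: 0.51
    n_perm: int = 10_000
    qtl_max_span: int = 1_000_000
    top_k: int = 5
    min_windows: int = 2
    seed: int = 0
    ancestry: str = ""
    vcf: str = ""
    samples: str = ""
    qtl: str = ""
    chrom_lengths: str = ""
    outdir: str = "results"
    recipient: str = "DUR"

    def __post_init__(self):
        if self.window_size <= 0 or self.n_perm < 1 or self.top_k < 1 or self.min_windows < 1:
            raise ValueError("window_size, n_perm, top_k, min_windows must be positive")
        if not 0 <= self.chinese_min <= 1 or not 0 < self.fst_quantile < 1:
            raise ValueError("thresholds out of range")


def read_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)


# --------------------------------------------------------------- pipeline

FST_PAIRS = (("DUR", "MS"), ("DUR", "BMX"), ("MS", "BMX"))


def compute_fst_tracks(
    vcf_path: str | Path,
    samples_by_pop: dict[str, list[str]],
    grid: pd.DataFrame,
    layout: GenomeLayout,
    recipient: str = "DUR",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Site and window FST for the three analysis pairs plus the composite.

    Returns (per-site frame, grid with fst_* columns filled).
    """
    pairs = tuple((recipient if a == "DUR" else a, b) for a, b in FST_PAIRS)
    needed = sorted({p for pair in pairs for p in pair})
    sites, refc, totc = site_counts_from_vcf(str(vcf_path), {p: samples_by_pop[p] for p in needed})
    widx = assign_windows(sites, grid, layout)
    out = grid.copy()
    site_frame = sites.copy()
    cols = {}
    for a, b in pairs:
        name = f"fst_{'DUR' if a == recipient else a}_{b}"
        vals = hudson_fst_site(refc[a], totc[a], refc[b], totc[b])
        site_frame[name] = vals
        cols[name] = window_fst(vals, widx, len(grid))
    for name, v in cols.items():
        out[name] = v
    out["fst_DUR_CHN"] = composite_duroc_chinese(out["fst_DUR_MS"], out["fst_DUR_BMX"])
    return site_frame, out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute aggregate -> FST -> candidates -> enrichment and write outputs.

    Returns the manifest dict.  Identical config and seed give identical
    output bytes; per-stage timings go to the log, not into files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "audit": {},
    }

    current = {"stage": "init"}

    def stage(name):
        current["stage"] = name
        log.info("stage %s", name)
        return time.perf_counter()

    try:
        t = stage("load")
        layout = read_chrom_lengths(config.chrom_lengths)
        track = read_ancestry_table(config.ancestry, layout)
        samples = read_samples_table(config.samples)
        by_pop: dict[str, list[str]] = {}
        for s, p in samples.items():
            by_pop.setdefault(p, []).append(s)
        qtls = read_qtl_table(config.qtl)
        log.info("loaded in %.2fs", time.perf_counter() - t)

        t = stage("windows")
        grid = window_grid(layout, config.window_size)
        table = aggregate_ancestry(track, grid, layout)
        summary = genomewide_summary(track, table)
        manifest["audit"]["n_windows"] = int(len(table))
        manifest["audit"]["n_snps"] = int(len(track))
        log.info("windows in %.2fs", time.perf_counter() - t)

        t = stage("fst")
        site_fst, table = compute_fst_tracks(
            config.vcf, by_pop, table, layout, recipient=config.recipient
        )
        log.info("fst in %.2fs", time.perf_counter() - t)

        t = stage("candidates")
        candidates = call_candidates(
            table, chinese_min=config.chinese_min, fst_q=config.fst_quantile
        )
        tops = {
            d: extend_top_regions(
                table, donor=d, k=config.top_k, min_windows=config.min_windows,
                fst_q=config.fst_quantile,
            )
            for d in ("MS", "BMX")
        }
        manifest["audit"]["n_candidate_windows"] = candidates.provenance["n_candidate_windows"]
        manifest["audit"]["fst_threshold_MS_BMX"] = candidates.provenance["fst_threshold"]
        log.info("candidates in %.2fs", time.perf_counter() - t)

        t = stage("enrichment")
        kept, filter_audit = filter_qtls(qtls, layout, max_span_bp=config.qtl_max_span)
        peaks, dedup_audit = dedup_and_peaks(kept)
        observed = count_in_regions(peaks, candidates.regions)
        results = circular_permutation_test(
            candidates.window_indices, peaks, grid, layout,
            n_perm=config.n_perm, seed=config.seed,
        )
        manifest["audit"]["qtl_filter"] = filter_audit
        manifest["audit"]["qtl_dedup"] = dedup_audit
        manifest["audit"]["observed_counts"] = observed
        manifest["audit"]["p_values"] = {s: r.p_value for s, r in results.items()}
        log.info("enrichment in %.2fs", time.perf_counter() - t)

        t = stage("write")
        write_window_table(table, outdir / "windows.tsv")
        site_fst_out = site_fst.copy()
        site_fst_out["pos"] = site_fst_out["pos"] + 1
        with open(outdir / "site_fst.tsv", "w") as fh:
            fh.write("# per-site Hudson FST; pos is 1-based\n")
            site_fst_out.to_csv(fh, sep="\t", index=False, float_format="%.10g", na_rep="NA")
        write_regions(candidates, outdir / "candidates.bed", outdir / "candidates.tsv")
        for d, rset in tops.items():
            write_regions(rset, outdir / f"top_regions_{d}.bed", outdir / f"top_regions_{d}.tsv")
        summary.to_csv(outdir / "ancestry_summary.tsv", sep="\t", float_format="%.10g")
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("scope\tobserved\tn_perm\tp_value\tnull_mean\n")
            for s, r in results.items():
                nm = f"{r.null_counts.mean():.6g}" if r.null_counts.size else "NA"
                pv = "NA" if r.p_value is None else f"{r.p_value:.6g}"
                fh.write(f"{s}\t{r.observed}\t{r.n_perm}\t{pv}\t{nm}\n")
        for s, r in results.items():
            if r.null_counts.size:
                vals, cnts = np.unique(r.null_counts, return_counts=True)
                hist = pd.DataFrame({"count": vals, "n_perms": cnts})
                hist.to_csv(
                    outdir / f"null_hist_{s.replace(' ', '_')}.tsv", sep="\t", index=False
                )
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("written in %.2fs", time.perf_counter() - t)
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {current['stage']!r}: {e}") from e
    return manifest
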