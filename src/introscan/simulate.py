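"""Synthetic data emulating the study design: three diverged donor panels,
an admixed recipient with known ancestry tracts, truth copying proportions,
and a QTL table.

The donor allele-frequency model is Balding-Nichols on a two-level
population tree: an "Asian" branch (shared by Meishan and Bamaxiang) drifts
from the ancestral frequency, then each donor drifts from its branch point.
This makes Meishan and Bamaxiang mutually closer than either is to European
wild boar, matching the study populations qualitatively.

Recipient ancestry along each chromosome is a Markov tract process: tract
lengths are exponential with rate ``switch_rate_per_bp`` and each tract's
donor is drawn from the stationary ancestry proportions — overridden by a
boosted probability inside planted sweep regions (tracts truncate at sweep
boundaries so the boost applies exactly inside the region).  Alleles within
a tract are copied from one randomly chosen donor haplotype, re-chosen at
each ancestry switch, preserving within-tract haplotype structure.

All randomness flows from ``SimConfig.seed`` through named generator
streams; identical configs give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .qtl import TRAIT_GROUPS
from .windows import DONORS, GenomeLayout

_STREAMS = {"panels": 1, "admixed": 2, "qtl": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic dataset.

    The genome is 18 autosomes (a scaled-down 5 Mb each); genome-wide donor
    fractions default to 0.12/0.13/0.75 (MS/BMX/EUW); the QTL
    table mirrors the database composition: ~35% linkage-mapped records,
    five trait groups in the observed proportions, log-normal lengths
    capped at 1 Mb.
    """

    seed: int = 0
    n_chromosomes: int = 18
    chrom_length_bp: int = 5_000_000
    snp_density: float = 2e-4
    donor_divergence: tuple[float, float, float] = (0.05, 0.05, 0.20)  # MS, BMX, EUW
    asian_divergence: float = 0.10
    donor_haplotypes: int = 40
    recipient_haplotypes: int = 60
    stationary_ancestry: tuple[float, float, float] = (0.12, 0.13, 0.75)
    switch_rate_per_bp: float = 1e-5
    sweep_regions: tuple[tuple[str, int, int, str, float], ...] = ()
    qtl_count: int = 2_000
    qtl_group_weights: tuple[float, ...] = (0.4827, 0.0604, 0.0528, 0.3011, 0.1030)
    qtl_linkage_fraction: float = 0.35
    qtl_length_log_mean: float = 9.0
    qtl_length_log_sd: float = 1.5
    qtl_length_cap_bp: int = 1_000_000
    qtl_min_length_bp: int = 40
    qtl_nonautosome_fraction: float = 0.02
    enrichment_rho: float = 0.0
    ancestry_noise_concentration: float | None = None

    def __post_init__(self):
        if abs(sum(self.stationary_ancestry) - 1.0) > 1e-12:
            raise ValueError("stationary_ancestry must sum to 1")
        if abs(sum(self.qtl_group_weights) - 1.0) > 1e-9:
            raise ValueError("qtl_group_weights must sum to 1")
        probs = [
            *self.stationary_ancestry,
            *self.qtl_group_weights,
            self.qtl_linkage_fraction,
            self.qtl_nonautosome_fraction,
            self.enrichment_rho,
        ]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not all(0 <= f < 1 for f in self.donor_divergence) or not 0 <= self.asian_divergence < 1:
            raise ValueError("divergence parameters must lie in [0, 1)")
        names = set(self.chrom_names())
        for chrom, start, end, donor, prob in self.sweep_regions:
            if chrom not in names:
                raise ValueError(f"sweep region on unknown chromosome {chrom}")
            if not 0 <= start < end <= self.chrom_length_bp:
                raise ValueError(f"sweep region {chrom}:{start}-{end} outside chromosome")
            if donor not in DONORS:
                raise ValueError(f"unknown sweep donor {donor}")
            if not 0 <= prob <= 1:
                raise ValueError("boosted probability must lie in [0, 1]")
        if self.donor_haplotypes % 2 or self.recipient_haplotypes % 2:
            raise ValueError("haplotype counts must be even (diploid VCF output)")

    def chrom_names(self) -> list[str]:
        return [f"SSC{i + 1}" for i in range(self.n_chromosomes)]

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            names=tuple(self.chrom_names()),
            lengths=tuple(self.chrom_length_bp for _ in range(self.n_chromosomes)),
        )


def default_sweeps(config: SimConfig, n: int = 5, span_bp: int = 250_000,
                   donor: str = "MS", prob: float = 0.95,
                   align_bp: int = 50_000) -> SimConfig:
    """Convenience: plant ``n`` sweeps mid-chromosome on distinct chromosomes.

    Sweep boundaries are aligned to the ``align_bp`` window grid so each
    sweep covers whole analysis windows.
    """
    sweeps = []
    for i in range(n):
        chrom = config.chrom_names()[i % config.n_chromosomes]
        start = (config.chrom_length_bp // 2 - span_bp // 2) // align_bp * align_bp
        sweeps.append((chrom, start, start + span_bp, donor, prob))
    return replace(config, sweep_regions=tuple(sweeps))


@dataclass
class Panels:
    """Donor haplotype panels and the shared variant sites."""

    sites: pd.DataFrame  # chrom, pos (0-based)
    freqs: dict[str, np.ndarray]  # alt-allele frequency per donor
    ancestral: np.ndarray
    haplotypes: dict[str, np.ndarray]  # donor -> (n_hap, n_sites) int8


@dataclass
class SyntheticTruth:
    """Known ancestry tracts per recipient haplotype, plus the sweep list."""

    tracts: list[list[tuple[str, int, int, str]]]  # per haplotype: (chrom, start, end, donor)
    sweeps: tuple[tuple[str, int, int, str, float], ...]
    planted_qtl_ids: list[str] = field(default_factory=list)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted allele frequencies around ``p`` with divergence ``F``."""
    if F == 0:
        return p.copy()
    a = p * (1 - F) / F
    b = (1 - p) * (1 - F) / F
    return rng.beta(a, b)


def simulate_panels(config: SimConfig) -> Panels:
    """Variant sites and donor haplotype panels under the two-level tree."""
    rng = _rng(config.seed, "panels")
    expected = config.snp_density * config.chrom_length_bp * config.n_chromosomes
    if expected < 1:
        raise ValueError(
            f"expected site count {expected:.3g} < 1; increase snp_density or genome size"
        )
    chroms, poss = [], []
    for chrom in config.chrom_names():
        n = rng.poisson(config.snp_density * config.chrom_length_bp)
        pos = np.sort(rng.choice(config.chrom_length_bp, size=min(n, config.chrom_length_bp),
                                 replace=False))
        chroms.extend([chrom] * len(pos))
        poss.append(pos)
    sites = pd.DataFrame({"chrom": chroms, "pos": np.concatenate(poss).astype(np.int64)})
    if len(sites) == 0:
        raise ValueError("zero sites generated; increase snp_density or genome size")

    n_sites = len(sites)
    ancestral = rng.uniform(0.05, 0.95, size=n_sites)
    asian = _balding_nichols(rng, ancestral, config.asian_divergence)
    f_ms, f_bmx, f_euw = config.donor_divergence
    freqs = {
        "MS": _balding_nichols(rng, asian, f_ms),
        "BMX": _balding_nichols(rng, asian, f_bmx),
        "EUW": _balding_nichols(rng, ancestral, f_euw),
    }
    haplotypes = {
        d: (rng.random((config.donor_haplotypes, n_sites)) < freqs[d]).astype(np.int8)
        for d in DONORS
    }
    return Panels(sites=sites, freqs=freqs, ancestral=ancestral, haplotypes=haplotypes)


def _segment_bounds(config: SimConfig, chrom: str) -> list[tuple[int, int, str | None, float]]:
    """Chromosome split at sweep boundaries: (start, end, boosted donor, prob)."""
    sweeps = sorted(
        [s for s in config.sweep_regions if s[0] == chrom], key=lambda s: s[1]
    )
    bounds, x = [], 0
    for _, s, e, d, p in sweeps:
        if s > x:
            bounds.append((x, s, None, 0.0))
        bounds.append((s, e, d, p))
        x = e
    if x < config.chrom_length_bp:
        bounds.append((x, config.chrom_length_bp, None, 0.0))
    return bounds


def _donor_dist(config: SimConfig, boosted: str | None, prob: float) -> np.ndarray:
    stat = np.asarray(config.stationary_ancestry, dtype=float)
    if boosted is None:
        return stat
    i = DONORS.index(boosted)
    out = np.empty(3)
    rest = stat.sum() - stat[i]
    for j in range(3):
        out[j] = prob if j == i else (stat[j] / rest * (1 - prob) if rest > 0 else (1 - prob) / 2)
    return out


def simulate_admixed(
    config: SimConfig, panels: Panels
) -> tuple[np.ndarray, SyntheticTruth, pd.DataFrame]:
    """Recipient haplotypes, truth tracts, and the truth ancestry track.

    Returns (recipient haplotype matrix, SyntheticTruth, AncestryTrack
    frame).  The track's per-SNP proportions are the across-haplotype donor
    fractions of the true tracts (optionally blurred with Dirichlet noise
    when ``ancestry_noise_concentration`` is set).
    """
    rng = _rng(config.seed, "admixed")
    sites = panels.sites
    n_sites = len(sites)
    n_rec = config.recipient_haplotypes
    recipient = np.zeros((n_rec, n_sites), dtype=np.int8)
    donor_label = np.zeros((n_rec, n_sites), dtype=np.int8)

    site_pos = {c: sub["pos"].to_numpy() for c, sub in sites.groupby("chrom", sort=False)}
    site_off = {}
    off = 0
    for c, sub in sites.groupby("chrom", sort=False):
        site_off[c] = off
        off += len(sub)

    tracts_all: list[list[tuple[str, int, int, str]]] = []
    for _ in range(n_rec):
        tracts: list[tuple[str, int, int, str]] = []
        for chrom in config.chrom_names():
            for seg_start, seg_end, boosted, bprob in _segment_bounds(config, chrom):
                cdist = np.cumsum(_donor_dist(config, boosted, bprob))
                x = seg_start
                while x < seg_end:
                    if config.switch_rate_per_bp > 0:
                        length = max(1, int(np.ceil(rng.exponential(1.0 / config.switch_rate_per_bp))))
                    else:
                        length = seg_end - x
                    end = min(x + length, seg_end)
                    d_idx = min(int(np.searchsorted(cdist, rng.random(), side="right")), 2)
                    donor = DONORS[d_idx]
                    # one tract per Markov segment: the copying source
                    # haplotype is re-chosen at every switch, including
                    # same-donor switches, so segments are the tract unit
                    tracts.append((chrom, x, end, donor))
                    if chrom in site_pos:
                        pos = site_pos[chrom]
                        lo = site_off[chrom] + np.searchsorted(pos, x, side="left")
                        hi = site_off[chrom] + np.searchsorted(pos, end, side="left")
                        if hi > lo:
                            src = rng.integers(config.donor_haplotypes)
                            h = len(tracts_all)
                            recipient[h, lo:hi] = panels.haplotypes[donor][src, lo - site_off[chrom]:hi - site_off[chrom]]
                            donor_label[h, lo:hi] = d_idx
                    x = end
        tracts_all.append(tracts)

    props = np.stack([(donor_label == i).mean(axis=0) for i in range(3)], axis=1)
    if config.ancestry_noise_concentration is not None:
        c = float(config.ancestry_noise_concentration)
        alpha = c * props + 1e-6
        g = rng.gamma(alpha)
        props = g / g.sum(axis=1, keepdims=True)
    track = pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "p_MS": props[:, 0],
            "p_BMX": props[:, 1],
            "p_EUW": props[:, 2],
        }
    )
    truth = SyntheticTruth(tracts=tracts_all, sweeps=config.sweep_regions)
    return recipient, truth, track


def simulate_qtl_table(
    config: SimConfig,
    layout: GenomeLayout | None = None,
    sweeps: tuple[tuple[str, int, int, str, float], ...] | None = None,
) -> pd.DataFrame:
    """QTL records with method, trait group, interval and planted flag.

    A fraction ``qtl_linkage_fraction`` of records is linkage-mapped; a
    fraction ``enrichment_rho`` of the association records has its midpoint
    planted uniformly inside a sweep region; a small fraction lands on a
    non-autosomal decoy chromosome "X" to exercise the location filter.
    Intervals are 0-based half-open in memory.
    """
    layout = layout or config.layout()
    sweeps = config.sweep_regions if sweeps is None else sweeps
    if config.enrichment_rho > 0 and not sweeps:
        raise ValueError("enrichment_rho > 0 requires at least one sweep region")
    for chrom, *_ in sweeps:
        if chrom not in layout.names:
            raise ValueError(f"sweep chromosome {chrom} absent from layout")
    rng = _rng(config.seed, "qtl")
    n = config.qtl_count
    method = np.where(rng.random(n) < config.qtl_linkage_fraction, "linkage", "association")
    group = rng.choice(len(TRAIT_GROUPS), size=n, p=np.asarray(config.qtl_group_weights))
    lengths = np.exp(rng.normal(config.qtl_length_log_mean, config.qtl_length_log_sd, size=n))
    lengths = np.clip(np.round(lengths).astype(np.int64),
                      config.qtl_min_length_bp, config.qtl_length_cap_bp)
    decoy = rng.random(n) < config.qtl_nonautosome_fraction
    planted = (method == "association") & ~decoy & (rng.random(n) < config.enrichment_rho)

    cum = np.concatenate([[0], np.cumsum(layout.lengths)])
    total = cum[-1]
    sweep_lens = np.array([e - s for _, s, e, *_ in sweeps], dtype=np.int64) if sweeps else None

    chroms = np.empty(n, dtype=object)
    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    for i in range(n):
        if decoy[i]:
            chrom, L = "X", config.chrom_length_bp
            mid = rng.integers(L)
        elif planted[i]:
            j = rng.choice(len(sweeps), p=sweep_lens / sweep_lens.sum())
            chrom, s, e, *_ = sweeps[j]
            L = layout.length_of(chrom)
            mid = rng.integers(s, e)
        else:
            gpos = rng.integers(total)
            ci = int(np.searchsorted(cum, gpos, side="right") - 1)
            chrom, L = layout.names[ci], layout.lengths[ci]
            mid = gpos - cum[ci]
        half = lengths[i] // 2
        start = int(np.clip(mid - half, 0, max(L - lengths[i], 0)))
        chroms[i] = chrom
        starts[i] = start
        ends[i] = min(start + lengths[i], L)

    return pd.DataFrame(
        {
            "qtl_id": [f"QTL{i + 1}" for i in range(n)],
            "trait": [f"trait_{TRAIT_GROUPS[g][:4]}_{i % 40}" for i, g in enumerate(group)],
            "trait_group": [TRAIT_GROUPS[g] for g in group],
            "method": method,
            "chrom": chroms,
            "start": starts,
            "end": ends,
            "planted_in_sweep": planted,
        }
    )


def simulate_all(config: SimConfig):
    """Run the full generator: panels, recipient, truth track, QTL table."""
    panels = simulate_panels(config)
    recipient, truth, track = simulate_admixed(config, panels)
    qtls = simulate_qtl_table(config)
    truth.planted_qtl_ids = qtls.loc[qtls["planted_in_sweep"], "qtl_id"].tolist()
    return panels, recipient, truth, track, qtls


def truth_to_json(truth: SyntheticTruth) -> str:
    return json.dumps(
        {
            "tracts": [
                [{"chrom": c, "start": int(s), "end": int(e), "donor": d} for c, s, e, d in hap]
                for hap in truth.tracts
            ],
            "sweeps": [
                {"chrom": c, "start": int(s), "end": int(e), "donor": d, "prob": p}
                for c, s, e, d, p in truth.sweeps
            ],
            "planted_qtl_ids": truth.planted_qtl_ids,
        },
        indent=0,
    )


def truth_from_json(text: str) -> SyntheticTruth:
    obj = json.loads(text)
    return SyntheticTruth(
        tracts=[
            [(t["chrom"], t["start"], t["end"], t["donor"]) for t in hap]
            for hap in obj["tracts"]
        ],
        sweeps=tuple(
            (s["chrom"], s["start"], s["end"], s["donor"], s["prob"]) for s in obj["sweeps"]
        ),
        planted_qtl_ids=obj.get("planted_qtl_ids", []),
    )


def write_fixture_set(config: SimConfig, outdir) -> dict[str, str]:
    """Simulate everything and write the on-disk fixture set.

    Writes a phased VCF of donors plus recipients, the ancestry table, the
    QTL table, the chromosome-length table, a sample->population map and the
    truth JSON; all tables round-trip losslessly through :mod:`introscan.io`.
    Returns the path of each file by short name.
    """
    from pathlib import Path

    from . import io as iomod

    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create fixture directory {out}: {e}") from e
    panels, recipient, truth, track, qtls = simulate_all(config)

    hap_rows = [panels.haplotypes[d] for d in DONORS] + [recipient]
    matrix = np.vstack(hap_rows)
    samples: dict[str, str] = {}
    for d in DONORS:
        for i in range(config.donor_haplotypes // 2):
            samples[f"{d}_{i + 1}"] = d
    for i in range(config.recipient_haplotypes // 2):
        samples[f"DUR_{i + 1}"] = "DUR"

    paths = {
        "vcf": str(out / "genome.vcf"),
        "ancestry": str(out / "ancestry.tsv"),
        "qtl": str(out / "qtl.tsv"),
        "chrom_lengths": str(out / "chrom_lengths.tsv"),
        "samples": str(out / "samples.tsv"),
        "truth": str(out / "truth.json"),
    }
    iomod.write_vcf(paths["vcf"], panels.sites, matrix, list(samples))
    iomod.write_ancestry_table(track, paths["ancestry"])
    iomod.write_qtl_table(qtls, paths["qtl"])
    iomod.write_chrom_lengths(config.layout(), paths["chrom_lengths"])
    iomod.write_samples_table(samples, paths["samples"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth_to_json(truth))
    return paths
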