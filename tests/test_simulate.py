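import dataclasses

import numpy as np
import pytest

from introscan.qtl import TRAIT_GROUPS
from introscan.simulate import (
    SimConfig,
    default_sweeps,
    simulate_admixed,
    simulate_panels,
    simulate_qtl_table,
)


def tiny(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=1_000_000,
        donor_haplotypes=10,
        recipient_haplotypes=20,
        qtl_count=200,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfig:
    def test_bad_stationary_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            tiny(stationary_ancestry=(0.5, 0.5, 0.5))

    def test_sweep_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tiny(sweep_regions=(("SSC1", 0, 2_000_000, "MS", 0.9),))

    def test_zero_expected_sites_rejected(self):
        with pytest.raises(ValueError, match="site"):
            simulate_panels(tiny(snp_density=1e-8))


class TestPanels:
    def test_zero_divergence_gives_ancestral_frequencies(self):
        cfg = tiny(donor_divergence=(0.0, 0.0, 0.0), asian_divergence=0.0)
        panels = simulate_panels(cfg)
        for d in ("MS", "BMX", "EUW"):
            np.testing.assert_array_equal(panels.freqs[d], panels.ancestral)

    def test_seeded_determinism(self):
        a = simulate_panels(tiny(seed=42))
        b = simulate_panels(tiny(seed=42))
        assert a.sites.equals(b.sites)
        for d in ("MS", "BMX", "EUW"):
            np.testing.assert_array_equal(a.haplotypes[d], b.haplotypes[d])
            np.testing.assert_array_equal(a.freqs[d], b.freqs[d])

    def test_sister_donor_frequencies_closer_than_outgroup(self):
        # Monte-Carlo over >= 10,000 sites; the shared Asian branch must pull
        # MS and BMX together relative to EUW
        cfg = tiny(seed=7, n_chromosomes=4, chrom_length_bp=2_000_000, snp_density=2e-3)
        panels = simulate_panels(cfg)
        assert len(panels.sites) >= 10_000
        d_ms_bmx = np.abs(panels.freqs["MS"] - panels.freqs["BMX"]).mean()
        d_ms_euw = np.abs(panels.freqs["MS"] - panels.freqs["EUW"]).mean()
        assert d_ms_bmx < d_ms_euw

    def test_positions_sorted_within_chromosome(self):
        panels = simulate_panels(tiny(seed=3))
        for _, sub in panels.sites.groupby("chrom", sort=False):
            assert (np.diff(sub["pos"].to_numpy()) > 0).all()


class TestAdmixed:
    def test_zero_switch_rate_single_tract(self):
        cfg = tiny(seed=5, switch_rate_per_bp=0.0)
        panels = simulate_panels(cfg)
        _, truth, track = simulate_admixed(cfg, panels)
        for hap in truth.tracts:
            assert len(hap) == cfg.n_chromosomes
            for chrom, start, end, _ in hap:
                assert start == 0 and end == cfg.chrom_length_bp
        # per-SNP truth equals the empirical whole-chromosome donor fractions
        donors = np.array([[t[3] for t in hap] for hap in truth.tracts])
        for ci, chrom in enumerate(cfg.chrom_names()):
            sub = track[track["chrom"] == chrom]
            for d, col in zip(("MS", "BMX", "EUW"), ("p_MS", "p_BMX", "p_EUW")):
                frac = (donors[:, ci] == d).mean()
                assert np.allclose(sub[col], frac)

    def test_tracts_tile_chromosomes(self, small_config, small_sim):
        _, _, truth, _, _ = small_sim
        L = small_config.chrom_length_bp
        for hap in truth.tracts:
            for chrom in small_config.chrom_names():
                tr = [t for t in hap if t[0] == chrom]
                assert tr[0][1] == 0 and tr[-1][2] == L
                for a, b in zip(tr, tr[1:]):
                    assert a[2] == b[1]  # no gaps, no overlaps

    def test_track_rows_sum_to_one(self, small_sim):
        _, _, _, track, _ = small_sim
        sums = track[["p_MS", "p_BMX", "p_EUW"]].sum(axis=1).to_numpy()
        assert np.abs(sums - 1).max() < 1e-9

    def test_mean_tract_length_matches_switch_rate(self):
        cfg = tiny(seed=9, n_chromosomes=6, chrom_length_bp=2_000_000,
                   switch_rate_per_bp=2e-5, recipient_haplotypes=20)
        panels = simulate_panels(cfg)
        _, truth, _ = simulate_admixed(cfg, panels)
        # interior tracts only: the last tract per chromosome is censored
        # at the chromosome end and would bias the mean downward
        lengths = []
        for hap in truth.tracts:
            for chrom in cfg.chrom_names():
                tr = [t for t in hap if t[0] == chrom]
                lengths.extend(t[2] - t[1] for t in tr[:-1])
        lengths = np.asarray(lengths, dtype=float)
        assert len(lengths) >= 1000
        expected = 1 / cfg.switch_rate_per_bp
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - expected) < 4 * se

    def test_genomewide_fractions_near_stationary(self):
        # 10 Mb genome, 100 haplotypes; mean truth proportions within 3
        # empirical standard errors of (0.12, 0.13, 0.75) across seeds
        means = []
        for seed in range(8):
            cfg = tiny(seed=seed, n_chromosomes=5, chrom_length_bp=2_000_000,
                       recipient_haplotypes=100, snp_density=5e-5)
            panels = simulate_panels(cfg)
            _, _, track = simulate_admixed(cfg, panels)
            means.append(track[["p_MS", "p_BMX", "p_EUW"]].mean().to_numpy())
        means = np.asarray(means)
        grand = means.mean(axis=0)
        se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
        for g, s, target in zip(grand, se, (0.12, 0.13, 0.75)):
            assert abs(g - target) < 3 * max(s, 1e-3)

    def test_sweep_boost_raises_donor_ancestry_inside(self):
        inside, outside = [], []
        for seed in range(20):
            cfg = default_sweeps(
                tiny(seed=seed, recipient_haplotypes=40), n=1, span_bp=200_000
            )
            panels = simulate_panels(cfg)
            _, _, track = simulate_admixed(cfg, panels)
            chrom, s, e, _, _ = cfg.sweep_regions[0]
            m = (track["chrom"] == chrom) & (track["pos"] >= s) & (track["pos"] < e)
            inside.append(track.loc[m, "p_MS"].mean())
            outside.append(track.loc[~m, "p_MS"].mean())
        inside, outside = np.asarray(inside), np.asarray(outside)
        diff = inside - outside
        t = diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff)))
        assert diff.mean() > 0.5 and t > 10  # boosted 0.95 vs stationary 0.12

    def test_dirichlet_noise_keeps_rows_normalized(self):
        cfg = tiny(seed=2, ancestry_noise_concentration=50.0)
        panels = simulate_panels(cfg)
        _, _, track = simulate_admixed(cfg, panels)
        sums = track[["p_MS", "p_BMX", "p_EUW"]].sum(axis=1).to_numpy()
        assert np.abs(sums - 1).max() < 1e-9

    def test_seeded_determinism(self):
        cfg = tiny(seed=13)
        panels = simulate_panels(cfg)
        r1, t1, k1 = simulate_admixed(cfg, panels)
        r2, t2, k2 = simulate_admixed(cfg, panels)
        np.testing.assert_array_equal(r1, r2)
        assert t1.tracts == t2.tracts
        assert k1.equals(k2)


class TestQtlTable:
    def test_no_enrichment_means_no_planted_flags(self):
        qtls = simulate_qtl_table(tiny(seed=1, enrichment_rho=0.0))
        assert not qtls["planted_in_sweep"].any()

    def test_rho_without_sweeps_rejected(self):
        cfg = tiny(enrichment_rho=0.5)
        with pytest.raises(ValueError, match="sweep"):
            simulate_qtl_table(cfg)

    def test_all_linkage_leaves_nothing_downstream(self):
        from introscan.qtl import filter_qtls

        cfg = tiny(seed=4, qtl_linkage_fraction=1.0, qtl_nonautosome_fraction=0.0)
        qtls = simulate_qtl_table(cfg)
        kept, audit = filter_qtls(qtls, cfg.layout())
        assert len(kept) == 0
        assert audit["n_dropped_linkage"] == len(qtls)

    def test_group_counts_within_multinomial_ci(self):
        weights = (0.48, 0.06, 0.05, 0.31, 0.10)
        cfg = tiny(seed=6, qtl_count=10_000, qtl_group_weights=weights)
        qtls = simulate_qtl_table(cfg)
        counts = qtls["trait_group"].value_counts()
        # exact multinomial 99% marginal interval via the binomial
        from scipy.stats import binom

        for g, w in zip(TRAIT_GROUPS, weights):
            lo, hi = binom.ppf([0.005, 0.995], 10_000, w)
            assert lo <= counts.get(g, 0) <= hi

    def test_lengths_capped_and_positive(self):
        cfg = tiny(seed=8, qtl_count=5_000)
        qtls = simulate_qtl_table(cfg)
        span = qtls["end"] - qtls["start"]
        assert (span >= 1).all()
        assert (span <= cfg.qtl_length_cap_bp).all()

    def test_planted_midpoints_inside_sweeps(self):
        cfg = default_sweeps(tiny(seed=3, enrichment_rho=1.0,
                                  qtl_linkage_fraction=0.0,
                                  qtl_nonautosome_fraction=0.0), n=1)
        qtls = simulate_qtl_table(cfg)
        chrom, s, e, _, _ = cfg.sweep_regions[0]
        planted = qtls[qtls["planted_in_sweep"]]
        assert len(planted) == len(qtls)
        mid = (planted["start"] + planted["end"]) // 2
        assert (planted["chrom"] == chrom).all()
        # midpoints drawn inside the sweep; interval clipping at chromosome
        # edges cannot move them here (sweep is mid-chromosome)
        assert ((mid >= s - 1) & (mid < e + 1)).all()
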