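import numpy as np
import pandas as pd
import pytest

from introscan.simulate import SimConfig, default_sweeps, simulate_all, write_fixture_set
from introscan.windows import GenomeLayout, aggregate_ancestry, window_grid


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A small but non-trivial simulated study: 4 chromosomes, 2 Mb each."""
    return default_sweeps(
        SimConfig(
            seed=11,
            n_chromosomes=4,
            chrom_length_bp=2_000_000,
            donor_haplotypes=20,
            recipient_haplotypes=40,
            qtl_count=800,
            enrichment_rho=0.3,
        ),
        n=2,
        span_bp=200_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(panels, recipient, truth, track, qtls) for the small config."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def small_table(small_config, small_sim):
    """Window table with ancestry aggregated for the small simulation."""
    _, _, _, track, _ = small_sim
    layout = small_config.layout()
    grid = window_grid(layout)
    return aggregate_ancestry(track, grid, layout)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    """On-disk fixture set written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture_set(small_config, outdir)
    return paths


def make_window_table(p_ms, p_bmx=None, fst=None, chrom="SSC1", size=50_000):
    """Hand-built window table for region-calling tests.

    ``p_ms`` is a list of Meishan window means; BMX defaults to 0 and EUW
    absorbs the remainder.  ``fst`` fills fst_MS_BMX (default 0.0).
    """
    p_ms = np.asarray(p_ms, dtype=float)
    p_bmx = np.zeros_like(p_ms) if p_bmx is None else np.asarray(p_bmx, dtype=float)
    n = len(p_ms)
    table = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, str) else list(chrom),
            "start": np.arange(n) * size,
            "end": (np.arange(n) + 1) * size,
            "window_index": np.arange(n),
            "n_snps": 10,
            "p_MS": p_ms,
            "p_BMX": p_bmx,
            "p_EUW": 1.0 - p_ms - p_bmx,
        }
    )
    table["p_CHN"] = table["p_MS"] + table["p_BMX"]
    table["fst_MS_BMX"] = 0.0 if fst is None else np.asarray(fst, dtype=float)
    table.attrs["size_bp"] = size
    return table


@pytest.fixture
def window_table_factory():
    return make_window_table
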