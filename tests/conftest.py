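"""Shared fixtures: one small synthetic dataset reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from nucmut import nucstats, simulate


@pytest.fixture(scope="session")
def sim_config():
    return simulate.SimConfig(chrom_lengths={"chrT": 200_000}, seed=101)


@pytest.fixture(scope="session")
def genome(sim_config):
    return simulate.gen_genome(sim_config)


@pytest.fixture(scope="session")
def landscape(genome, sim_config):
    dyads, mids, strong, rotational = simulate.gen_nucleosome_landscape(
        genome, sim_config)
    return {"dyads": dyads, "midpoints": mids, "strong": strong,
            "rotational": rotational}


@pytest.fixture(scope="session")
def site_stats(landscape):
    """Batch positioning stats over every interior base of the test genome."""
    mids = landscape["midpoints"].positions["chrT"]
    positions = np.arange(100, 200_000 - 100)
    st = nucstats.batch_positioning_stats(positions, mids)
    return st[st["usable"] & st["d_var"].notna()].reset_index(drop=True)


@pytest.fixture(scope="session")
def dvar_features(site_stats):
    return pd.DataFrame({
        "chrom": "chrT",
        "pos0": site_stats["pos0"].to_numpy(),
        "log_d_var": np.log(site_stats["d_var"].to_numpy() + 1.0),
    })
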