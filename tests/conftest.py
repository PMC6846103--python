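import numpy as np
import pandas as pd
import pytest

import nicheshift as ns


@pytest.fixture(scope="session")
def small_cfg() -> ns.ScenarioConfig:
    """A fast two-range scenario used across tests."""
    return ns.ScenarioConfig(
        seed=11, region_shape=(30, 30), n_env_layers=12, shift_magnitude=2.0
    )


@pytest.fixture(scope="session")
def scenario(small_cfg):
    return ns.make_shift_scenario(small_cfg)


@pytest.fixture(scope="session")
def spaces(scenario):
    """Fitted PCA-env plus both ranges' occupancy grids on a shared extent."""
    bg_n = scenario.grid_native.env_table()
    bg_i = scenario.grid_introduced.env_table()
    space = ns.calibrate_env_space(bg_n, bg_i)
    extent = ns.grid_extent(
        np.vstack([space.transform(bg_n), space.transform(bg_i)])
    )
    z_nat = ns.occupancy_grid(space, scenario.occ_native, bg_n, 100, extent)
    z_int = ns.occupancy_grid(space, scenario.occ_introduced, bg_i, 100, extent)
    return {
        "space": space,
        "bg_native": bg_n,
        "bg_introduced": bg_i,
        "extent": extent,
        "z_native": z_nat,
        "z_introduced": z_int,
    }


def make_occurrences(env: pd.DataFrame, range_label: str) -> ns.OccurrenceSet:
    """Wrap an environment table as an annotated occurrence set."""
    n = len(env)
    data = pd.DataFrame(
        {
            "id": np.arange(n),
            "species": "virtual",
            "lon": np.zeros(n),
            "lat": np.zeros(n),
            "range": range_label,
        }
    )
    return ns.OccurrenceSet(data=data, env=env.reset_index(drop=True))
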