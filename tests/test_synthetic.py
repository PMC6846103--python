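import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

import nicheshift as ns
from nicheshift.synthetic import _STREAMS


def lag1_autocorr(field: np.ndarray) -> float:
    """Moran's-I-style lag-1 spatial autocorrelation of a 2-D field."""
    z = field - field.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    den = (z**2).sum()
    n_pairs = z[:, :-1].size + z[:-1, :].size
    return (num / n_pairs) / (den / z.size)


class TestGenerateClimate:
    def test_deterministic_given_seed(self):
        cfg = ns.ScenarioConfig(seed=1, region_shape=(20, 20), n_env_layers=12)
        a = ns.generate_climate(cfg, "native")
        b = ns.generate_climate(cfg, "native")
        for name in a.layer_names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_smoothing_raises_spatial_autocorrelation(self):
        smooth = ns.ScenarioConfig(seed=2, region_shape=(40, 40), n_env_layers=12,
                                   autocorr_scale=5.0)
        rough = ns.ScenarioConfig(seed=2, region_shape=(40, 40), n_env_layers=12,
                                  autocorr_scale=0.0)
        ac_s = lag1_autocorr(ns.generate_climate(smooth, "native").layers["bio1"])
        ac_r = lag1_autocorr(ns.generate_climate(rough, "native").layers["bio1"])
        assert ac_s > ac_r
        assert abs(ac_r) < 0.2  # white noise has ~zero lag-1 autocorrelation
        assert ac_s > 0.5

    def test_layers_respect_stated_ranges(self):
        cfg = ns.ScenarioConfig(seed=3, region_shape=(25, 25), n_env_layers=12)
        grid = ns.generate_climate(cfg, "native")
        lo, hi = ns.BIOCLIM_RANGES["bio1"]
        assert grid.layers["bio1"].min() == pytest.approx(lo)
        assert grid.layers["bio1"].max() == pytest.approx(hi)

    def test_introduced_cooling_extends_cold_end(self):
        cfg = ns.ScenarioConfig(seed=4, region_shape=(25, 25), n_env_layers=12,
                                introduced_cooling=5.0)
        nat = ns.generate_climate(cfg, "native")
        intro = ns.generate_climate(cfg, "introduced")
        assert intro.layers["bio1"].min() < nat.layers["bio1"].min()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="region_shape"):
            ns.ScenarioConfig(region_shape=(0, 10))
        with pytest.raises(ValueError, match="autocorr"):
            ns.ScenarioConfig(region_shape=(10, 10), autocorr_scale=10.0)
        with pytest.raises(ValueError, match="shift_magnitude inconsistent"):
            ns.ScenarioConfig(
                niche_center_introduced=(13.0, 800.0), shift_magnitude=2.0
            )
        cfg = ns.ScenarioConfig(seed=1, region_shape=(15, 15), n_env_layers=12)
        with pytest.raises(ValueError, match="region_id"):
            ns.generate_climate(cfg, "elsewhere")


@pytest.fixture(scope="module")
def grid():
    cfg = ns.ScenarioConfig(seed=5, region_shape=(30, 30), n_env_layers=12)
    return ns.generate_climate(cfg, "native")


class TestSampleOccurrences:

    def test_deterministic_given_seed(self, grid):
        niche = ns.VirtualNiche(("bio1",), [13.0], [2.0])
        a = ns.sample_occurrences(grid, niche, 50, seed=7)
        b = ns.sample_occurrences(grid, niche, 50, seed=7)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_sample_mean_matches_exact_expectation(self, grid):
        """The empirical mean agrees with the closed-form expectation
        computed from the sampling probabilities (within 3 SE)."""
        niche = ns.VirtualNiche(("bio1", "bio12"), [13.0, 800.0], [3.0, 300.0])
        env = grid.env_table()
        p = niche.suitability(env)
        p = p / p.sum()
        exact_mean = (p * env["bio1"]).sum()
        exact_sd = np.sqrt((p * (env["bio1"] - exact_mean) ** 2).sum())
        n = 2000
        occ = ns.sample_occurrences(grid, niche, n, seed=13)
        se = exact_sd / np.sqrt(n)
        assert abs(occ.env["bio1"].mean() - exact_mean) < 3 * se

    def test_cell_frequencies_match_suitability(self):
        """Chi-square goodness of fit of sampled cell counts against the
        normalized suitability on a 10x10 grid (n = 10,000)."""
        cfg = ns.ScenarioConfig(seed=6, region_shape=(10, 10), n_env_layers=12,
                                autocorr_scale=2.0)
        grid = ns.generate_climate(cfg, "native")
        niche = ns.VirtualNiche(("bio1",), [13.0], [4.0])
        env = grid.env_table()
        p = niche.suitability(env)
        p = p / p.sum()
        occ = ns.sample_occurrences(grid, niche, 10_000, seed=21)
        row, col = grid.rowcol(occ.data["lon"], occ.data["lat"])
        counts = np.zeros(100)
        np.add.at(counts, row * 10 + col, 1)
        stat, pval = chisquare(counts, f_exp=10_000 * p)
        assert pval > 0.01

    def test_flat_niche_samples_uniformly(self, grid):
        niche = ns.VirtualNiche(("bio1",), [13.0], [1e9], max_prob=1.0)
        occ = ns.sample_occurrences(grid, niche, 9000, seed=3)
        row, col = grid.rowcol(occ.data["lon"], occ.data["lat"])
        counts = np.zeros(900)
        np.add.at(counts, row * 30 + col, 1)
        _, pval = chisquare(counts)
        assert pval > 0.01

    def test_empty_support_rejected(self, grid):
        niche = ns.VirtualNiche(("bio1",), [1e6], [1e-3])
        with pytest.raises(ValueError, match="empty support"):
            ns.sample_occurrences(grid, niche, 10, seed=0)

    def test_bias_shifts_samples_along_first_layer(self, grid):
        niche = ns.VirtualNiche(("bio1",), [13.0], [1e9])
        unbiased = ns.sample_occurrences(grid, niche, 3000, bias_strength=0.0, seed=4)
        biased = ns.sample_occurrences(grid, niche, 3000, bias_strength=2.0, seed=4)
        assert biased.env["bio1"].mean() > unbiased.env["bio1"].mean()


class TestShiftScenario:
    def test_zero_shift_gives_identical_niches(self):
        cfg = ns.ScenarioConfig(seed=8, region_shape=(20, 20), n_env_layers=12,
                                shift_magnitude=0.0)
        scen = ns.make_shift_scenario(cfg)
        np.testing.assert_array_equal(
            scen.niche_native.center, scen.niche_introduced.center
        )

    def test_default_sample_sizes(self, scenario):
        assert len(scenario.occ_native) == 52
        assert len(scenario.occ_introduced) == 492

    def test_shared_landscape_reuses_climate_fields(self):
        cfg = ns.ScenarioConfig(seed=9, region_shape=(20, 20), n_env_layers=12,
                                shared_landscape=True)
        scen = ns.make_shift_scenario(cfg)
        np.testing.assert_array_equal(
            scen.grid_native.layers["bio1"], scen.grid_introduced.layers["bio1"]
        )

    def test_substreams_are_fixed_offsets(self):
        # occurrence draws must not change when only the physiology
        # stream is consumed differently
        assert _STREAMS["occ_native"] != _STREAMS["occ_introduced"]
        cfg = ns.ScenarioConfig(seed=10, region_shape=(20, 20), n_env_layers=12)
        a = ns.make_shift_scenario(cfg)
        b = ns.make_shift_scenario(cfg)
        pd.testing.assert_frame_equal(a.occ_native.data, b.occ_native.data)


class TestPhysTable:
    def test_zero_noise_reproduces_configured_means(self):
        tbl = ns.generate_phys_table(n_per_range=2, noise_sd=0.0, seed=0)
        warm = tbl[(tbl["variable"] == "aToc") & (tbl["temperature"] == 12.6)]
        assert (warm["value"] == 3.0).all()
        cold = tbl[
            (tbl["variable"] == "aToc")
            & (tbl["temperature"] == 4.7)
            & (tbl["range"] == "native")
        ]
        assert cold["value"].iloc[0] == pytest.approx(3.0 + 0.8 * (10.0 - 4.7))

    def test_deterministic_given_seed(self):
        a = ns.generate_phys_table(seed=42)
        b = ns.generate_phys_table(seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown marker variable"):
            ns.generate_phys_table(effects={"kryptonite": {"native": 1.0}})

    def test_table_shape_matches_experiment_design(self):
        tbl = ns.generate_phys_table(n_per_range=6, seed=1)
        assert len(tbl) == 2 * 6 * 5 * len(ns.MARKER_VARIABLES)
        assert set(tbl["temperature"]) == set(ns.EXPERIMENT1_TEMPERATURES)
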