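import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import nicheshift as ns


class TestSchoenerD:
    def test_identical_grids_give_full_overlap(self):
        z = np.array([[0.2, 0.3], [0.5, 0.0]])
        assert ns.schoener_d(z, z) == 1.0

    def test_disjoint_supports_give_zero(self):
        z1 = np.array([1.0, 0.0, 0.0, 0.0])
        z2 = np.array([0.0, 0.0, 1.0, 0.0])
        assert ns.schoener_d(z1, z2) == 0.0

    def test_four_cell_worked_example(self):
        z1 = np.array([0.5, 0.5, 0.0, 0.0])
        z2 = np.array([0.5, 0.0, 0.5, 0.0])
        assert ns.schoener_d(z1, z2) == pytest.approx(0.5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="shapes differ"):
            ns.schoener_d(np.ones(3), np.ones(4))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.float64, (4, 4), elements=st.floats(0, 1)),
        hnp.arrays(np.float64, (4, 4), elements=st.floats(0, 1)),
    )
    def test_symmetric_and_bounded(self, a, b):
        if a.sum() == 0 or b.sum() == 0:
            return
        d_ab = ns.schoener_d(a, b)
        d_ba = ns.schoener_d(b, a)
        assert d_ab == d_ba
        assert 0.0 <= d_ab <= 1.0

    def test_overlap_decreases_as_mass_is_displaced(self):
        base = np.zeros(10)
        base[0] = 1.0
        prev = 1.0
        for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
            z2 = np.zeros(10)
            z2[0] = 1.0 - frac
            z2[5] = frac
            d = ns.schoener_d(base, z2)
            assert d <= prev + 1e-12
            prev = d


class TestNicheDynamics:
    def test_identical_grids(self):
        z = np.array([0.6, 0.4, 0.0])
        dyn = ns.niche_dynamics(z, z)
        assert dyn.expansion == 0.0
        assert dyn.stability == 1.0
        assert dyn.unfilling == 0.0

    def test_disjoint_occupancies(self):
        zn = np.array([1.0, 0.0, 0.0, 0.0])
        zi = np.array([0.0, 0.0, 1.0, 0.0])
        dyn = ns.niche_dynamics(zn, zi)
        assert dyn.expansion == 1.0
        assert dyn.unfilling == 1.0

    def test_three_cell_worked_example(self):
        zn = np.array([0.6, 0.4, 0.0])
        zi = np.array([0.0, 0.4, 0.6])
        dyn = ns.niche_dynamics(zn, zi)
        assert dyn.expansion == pytest.approx(0.6)
        assert dyn.stability == pytest.approx(0.4)
        assert dyn.unfilling == pytest.approx(0.6)

    def test_expansion_stability_sum_and_swap_duality(self, spaces):
        for level in (1.0, 0.75):
            fwd = ns.niche_dynamics(
                spaces["z_native"], spaces["z_introduced"], analog_level=level
            )
            rev = ns.niche_dynamics(
                spaces["z_introduced"], spaces["z_native"], analog_level=level
            )
            assert fwd.expansion + fwd.stability == pytest.approx(1.0, abs=1e-12)
            assert fwd.unfilling == pytest.approx(rev.expansion, abs=1e-12)
            assert fwd.D == rev.D

    def test_empty_analog_intersection_rejected(self):
        g = spaces_like_disjoint()
        with pytest.raises(ValueError, match="no analogous climate"):
            ns.niche_dynamics(*g)


def spaces_like_disjoint():
    """Two occupancy grids whose background masks do not intersect."""
    R = 10
    extent = (0.0, 1.0, 0.0, 1.0)
    e1 = np.zeros((R, R))
    e2 = np.zeros((R, R))
    e1[:3] = 1.0
    e2[7:] = 1.0
    e1 /= e1.sum()
    e2 /= e2.sum()
    z1 = e1.copy()
    z2 = e2.copy()
    masks1 = ns.background_masks(e1)
    masks2 = ns.background_masks(e2)
    g1 = ns.OccupancyGrid(z1, z1, e1, extent, R, *masks1, np.array([0.1, 0.1]))
    g2 = ns.OccupancyGrid(z2, z2, e2, extent, R, *masks2, np.array([0.1, 0.1]))
    return g1, g2


class TestEquivalence:
    def test_identical_occurrence_sets_give_p_one(self, scenario, spaces):
        occ = scenario.occ_native
        res = ns.equivalence_test(
            occ, occ, spaces["space"],
            spaces["bg_native"], spaces["bg_native"],
            n_iter=99, seed=0,
        )
        assert res.D_obs == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_deterministic_given_seed(self, scenario, spaces):
        args = (
            scenario.occ_native, scenario.occ_introduced, spaces["space"],
            spaces["bg_native"], spaces["bg_introduced"],
        )
        a = ns.equivalence_test(*args, n_iter=99, seed=5)
        b = ns.equivalence_test(*args, n_iter=99, seed=5)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.D_null, b.D_null)

    def test_p_value_counting_rule(self, scenario, spaces):
        res = ns.equivalence_test(
            scenario.occ_native, scenario.occ_introduced, spaces["space"],
            spaces["bg_native"], spaces["bg_introduced"], n_iter=99, seed=1,
        )
        k = int(np.sum(res.D_null <= res.D_obs + 1e-12))
        assert res.p_value == pytest.approx((k + 1) / 100)

    def test_too_few_iterations_rejected(self, scenario, spaces):
        with pytest.raises(ValueError, match="at least 99"):
            ns.equivalence_test(
                scenario.occ_native, scenario.occ_introduced, spaces["space"],
                spaces["bg_native"], spaces["bg_introduced"], n_iter=50,
            )

    def test_tiny_group_warns(self, scenario, spaces):
        occ_small = scenario.occ_native._take(np.arange(3))
        with pytest.warns(UserWarning, match="fewer than 5"):
            ns.equivalence_test(
                occ_small, scenario.occ_introduced, spaces["space"],
                spaces["bg_native"], spaces["bg_introduced"], n_iter=99,
            )


class TestSimilarity:
    def test_deterministic_given_seed(self, scenario, spaces):
        args = (
            scenario.occ_native, scenario.occ_introduced, spaces["space"],
            spaces["bg_native"], spaces["bg_introduced"],
        )
        a = ns.similarity_test(*args, n_iter=99, seed=9)
        b = ns.similarity_test(*args, n_iter=99, seed=9)
        assert a.p_value == b.p_value

    def test_identical_sharp_niches_are_more_similar_than_chance(self):
        cfg = ns.ScenarioConfig(
            seed=17, region_shape=(30, 30), n_env_layers=12,
            shift_magnitude=0.0, shared_landscape=True,
            niche_sd=(1.0, 100.0), n_occ_native=150, n_occ_introduced=150,
        )
        scen = ns.make_shift_scenario(cfg)
        bg = scen.grid_native.env_table()
        space = ns.calibrate_env_space(bg, scen.grid_introduced.env_table())
        res = ns.similarity_test(
            scen.occ_native, scen.occ_introduced, space, bg,
            scen.grid_introduced.env_table(), n_iter=99, seed=2,
        )
        assert res.p_value <= 0.05

    def test_null_values_cover_relocations(self, scenario, spaces):
        res = ns.similarity_test(
            scenario.occ_native, scenario.occ_introduced, spaces["space"],
            spaces["bg_native"], spaces["bg_introduced"], n_iter=99, seed=3,
        )
        assert len(res.D_null) == 99
        assert np.all((res.D_null >= 0) & (res.D_null <= 1))
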