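import numpy as np
import pandas as pd
import pytest

import nicheshift as ns

from conftest import make_occurrences


class TestMarkerFormulas:
    def test_dps_worked_example(self):
        assert ns.dps(2.0, 1.0, 7.0) == pytest.approx(0.3)

    def test_dps_fully_deepoxidated_when_violaxanthin_absent(self):
        assert ns.dps(3.0, 1.0, 0.0) == 1.0

    def test_dps_zero_without_deepoxidated_forms(self):
        assert ns.dps(0.0, 0.0, 5.0) == 0.0

    def test_dps_rejects_empty_pool_and_negative_content(self):
        with pytest.raises(ValueError, match="pool"):
            ns.dps(0.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="non-negative"):
            ns.dps(-1.0, 0.0, 1.0)

    def test_hydration_worked_examples(self):
        assert ns.leaf_hydration(10.0, 2.0) == pytest.approx(4.0)
        assert ns.leaf_hydration(2.0, 2.0) == 0.0
        assert ns.leaf_hydration(3.0, 2.0) == pytest.approx(0.5)

    def test_hydration_rejects_impossible_weights(self):
        with pytest.raises(ValueError, match="dry weight"):
            ns.leaf_hydration(1.0, 0.0)
        with pytest.raises(ValueError, match="below dry weight"):
            ns.leaf_hydration(1.0, 2.0)

    def test_formulas_vectorize(self):
        np.testing.assert_allclose(
            ns.dps([2.0, 0.0], [1.0, 0.0], [7.0, 5.0]), [0.3, 0.0]
        )


def occ_with_bio11(values_by_range) -> ns.OccurrenceSet:
    parts = []
    for label, vals in values_by_range.items():
        env = pd.DataFrame({"bio11": np.asarray(vals, dtype=float)})
        parts.append(make_occurrences(env, label))
    return ns.OccurrenceSet.concat(parts)


class TestPerformanceCurve:
    def test_equal_width_hand_binning(self):
        occ = occ_with_bio11({"native": np.arange(1, 11)})
        perf = ns.performance_curve(occ, bins=5)
        np.testing.assert_allclose(perf.density["native"], [0.2] * 5)

    def test_single_bin_concentration(self):
        occ = occ_with_bio11({"native": [5.0] * 10})
        perf = ns.performance_curve(occ, bins=4)
        d = perf.density["native"]
        assert d.max() == pytest.approx(1.0)
        assert (d > 0).sum() == 1

    def test_identical_ranges_have_identical_curves(self):
        vals = np.linspace(0, 12, 30)
        occ = occ_with_bio11({"native": vals, "introduced": vals})
        perf = ns.performance_curve(occ, bins=6)
        np.testing.assert_allclose(
            perf.density["native"], perf.density["introduced"]
        )

    def test_temperature_outside_span_flagged_with_zero_performance(self):
        occ = occ_with_bio11({"native": np.linspace(6, 12, 20),
                              "introduced": np.linspace(0, 12, 20)})
        perf = ns.performance_curve(occ, bins=6, temperatures=(4.7, 10.0))
        row = perf.performance.query("range == 'native' and temperature == 4.7")
        assert row["performance"].iloc[0] == 0.0
        assert bool(row["extrapolated"].iloc[0])
        row = perf.performance.query("range == 'introduced' and temperature == 4.7")
        assert row["performance"].iloc[0] > 0.0

    def test_densities_sum_to_one_per_range(self, scenario):
        occ = ns.OccurrenceSet.concat([scenario.occ_native, scenario.occ_introduced])
        perf = ns.performance_curve(occ)
        for label, d in perf.density.items():
            assert d.sum() == pytest.approx(1.0)
            assert np.all(d >= 0)


def constant_effects(separator=None, sep_values=(10.0, 2.0)):
    """Every marker flat at its baseline in both ranges, except an
    optional separator variable with range-specific means."""
    effects = {}
    for v in ns.MARKER_VARIABLES:
        base = ns.synthetic.DEFAULT_MARKER_EFFECTS[v]["native"][0]
        effects[v] = {"native": (base, 0.0), "introduced": (base, 0.0)}
    if separator:
        effects[separator] = {
            "native": (sep_values[0], 0.0),
            "introduced": (sep_values[1], 0.0),
        }
    return effects


class TestLinkClassification:
    def test_perfect_separator_ranks_first(self):
        markers = ns.generate_phys_table(
            n_per_range=8,
            effects=constant_effects("aToc"),
            noise_sd=0.05,
            seed=5,
        )
        res = ns.link_classification(markers, seed=1, n_trees=300, n_permutations=5)
        assert res.variable_importance.index[0] == "aToc"
        assert res.oob_error <= 0.05

    def test_shuffled_labels_give_chance_accuracy(self):
        markers = ns.generate_phys_table(n_per_range=10, seed=6)
        rng = np.random.default_rng(0)
        plants = markers["plant"].unique()
        relabel = dict(zip(plants, rng.permutation(
            ["native", "introduced"] * (len(plants) // 2))))
        markers["range"] = markers["plant"].map(relabel)
        res = ns.link_classification(markers, seed=2, n_trees=300, n_permutations=5)
        assert abs((1.0 - res.oob_error) - 0.5) <= 0.2

    def test_deterministic_given_seed(self):
        markers = ns.generate_phys_table(n_per_range=4, seed=7)
        a = ns.link_classification(markers, seed=3, n_trees=200, n_permutations=5)
        b = ns.link_classification(markers, seed=3, n_trees=200, n_permutations=5)
        pd.testing.assert_series_equal(a.variable_importance, b.variable_importance)

    def test_single_class_rejected(self):
        markers = ns.generate_phys_table(n_per_range=4, seed=8)
        markers = markers[markers["range"] == "native"]
        with pytest.raises(ValueError, match="two range labels"):
            ns.link_classification(markers)


def monotone_perf_setup(n_plants=20, noise=0.0, seed=0):
    """Markers where H tracks temperature exactly and a performance
    curve rising monotonically with temperature."""
    temps = (4.7, 8.6, 10.3, 10.6, 12.6)
    effects = constant_effects()
    effects["H"] = {"native": lambda t: t, "introduced": lambda t: t}
    markers = ns.generate_phys_table(
        n_per_range=n_plants, effects=effects, noise_sd=noise, seed=seed,
        temperatures=temps,
    )
    # occurrence density increasing with bio11 -> monotone performance
    vals = np.repeat(np.linspace(2, 14, 25), np.arange(1, 26))
    occ = occ_with_bio11({"native": vals, "introduced": vals})
    perf = ns.performance_curve(occ, bins=25, temperatures=temps)
    return markers, perf


class TestLinkRegression:
    def test_noiseless_monotone_driver_explains_variance(self):
        markers, perf = monotone_perf_setup()
        res = ns.link_regression(markers, perf, "native", seed=1, n_trees=500)
        assert res.explained_variance_pct >= 95.0
        assert res.variable_importance.index[0] == "H"

    def test_uninformative_markers_explain_nothing(self):
        markers, perf = monotone_perf_setup()
        # flat markers (no H signal): performance varies, markers do not
        flat = ns.generate_phys_table(
            n_per_range=20, effects=constant_effects(), noise_sd=0.5, seed=3,
        )
        res = ns.link_regression(flat, perf, "native", seed=2, n_trees=500)
        assert res.explained_variance_pct <= 10.0

    def test_distinct_drivers_give_distinct_top_variables(self):
        temps = (4.7, 8.6, 10.3, 10.6, 12.6)
        effects = constant_effects()
        effects["aToc"] = {"native": lambda t: t, "introduced": (3.0, 0.0)}
        effects["gs"] = {"native": (150.0, 0.0), "introduced": lambda t: 10 * t}
        markers = ns.generate_phys_table(
            n_per_range=15, effects=effects, noise_sd=0.0, seed=4,
            temperatures=temps,
        )
        vals = np.repeat(np.linspace(2, 14, 25), np.arange(1, 26))
        occ = occ_with_bio11({"native": vals, "introduced": vals})
        perf = ns.performance_curve(occ, bins=25, temperatures=temps)
        nat = ns.link_regression(markers, perf, "native", seed=5, n_trees=300)
        intro = ns.link_regression(markers, perf, "introduced", seed=5, n_trees=300)
        assert nat.variable_importance.index[0] == "aToc"
        assert intro.variable_importance.index[0] == "gs"

    def test_too_few_temperatures_rejected(self):
        markers = ns.generate_phys_table(
            n_per_range=4, seed=9, temperatures=(5.0, 10.0)
        )
        occ = occ_with_bio11({"native": np.linspace(0, 12, 30)})
        perf = ns.performance_curve(occ, bins=5, temperatures=(5.0, 10.0))
        with pytest.raises(ValueError, match="fewer than 3 temperatures"):
            ns.link_regression(markers, perf, "native")
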