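"""Transfer matrices, percent change, Markov estimation and scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import categorical_raster
from oasisrisk.transitions import (
    GOVERNMENT_SCENARIO,
    MarkovMatrix,
    ScenarioSpec,
    apply_scenario,
    cross_tabulate,
    estimate_markov,
    percent_change,
    project_areas,
    zone_composition,
)

CLASSES = [
    "cropland", "forestland", "grassland_high", "grassland_lowmed",
    "water", "builtup", "unused",
]


def markov_from(arr, labels=None) -> MarkovMatrix:
    labels = labels or CLASSES[: len(arr)]
    return MarkovMatrix(pd.DataFrame(arr, index=labels, columns=labels))


def random_stochastic(rng, labels=CLASSES) -> MarkovMatrix:
    k = len(labels)
    raw = rng.dirichlet(np.ones(k) * 2.0, size=k)
    # make persistence dominant, as land-use chains are
    P = 0.5 * np.eye(k) + 0.5 * raw
    return markov_from(P / P.sum(axis=1, keepdims=True), labels)


class TestCrossTabulate:
    def test_identical_maps_give_diagonal_flows(self):
        r = categorical_raster([[1, 2], [2, 1]])
        tm = cross_tabulate(r, r)
        flows = tm.flows.to_numpy()
        assert np.trace(flows) == pytest.approx(flows.sum())

    def test_toy_maps_match_hand_enumeration(self):
        t0 = categorical_raster([[1, 1], [2, 3]])
        t1 = categorical_raster([[1, 2], [2, 1]])
        tm = cross_tabulate(t0, t1)
        # cell-by-cell: (1->1), (1->2), (2->2), (3->1); each cell is 1 km^2
        assert tm.flows.loc[1, 1] == pytest.approx(1.0)
        assert tm.flows.loc[1, 2] == pytest.approx(1.0)
        assert tm.flows.loc[2, 2] == pytest.approx(1.0)
        assert tm.flows.loc[3, 1] == pytest.approx(1.0)
        assert tm.flows.to_numpy().sum() == pytest.approx(4.0)

    def test_swapping_epochs_transposes_flows(self):
        rng = np.random.default_rng(0)
        a = categorical_raster(rng.integers(1, 4, (8, 8)))
        b = categorical_raster(rng.integers(1, 4, (8, 8)))
        f_ab = cross_tabulate(a, b).flows.to_numpy()
        f_ba = cross_tabulate(b, a).flows.to_numpy()
        np.testing.assert_allclose(f_ab, f_ba.T)

    def test_nodata_in_either_map_excluded(self):
        t0 = categorical_raster([[1, 255]], nodata=255)
        t1 = categorical_raster([[1, 1]], nodata=255)
        assert cross_tabulate(t0, t1).flows.to_numpy().sum() == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="co-registered"):
            cross_tabulate(
                categorical_raster([[1]]), categorical_raster([[1, 2]])
            )


class TestPercentChange:
    def test_printed_belt_and_landuse_changes(self, printed_changes):
        for a0, a1, printed, decimals in printed_changes:
            assert round(percent_change(a0, a1), decimals) == printed

    def test_no_change_is_zero(self):
        assert percent_change(5.0, 5.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="zero initial area"):
            percent_change(0.0, 1.0)


class TestEstimateMarkov:
    def test_diagonal_flows_give_identity(self):
        from oasisrisk.transitions import TransitionMatrix

        tm = TransitionMatrix(pd.DataFrame(np.diag([3.0, 7.0]), index=["a", "b"],
                                           columns=["a", "b"]))
        np.testing.assert_allclose(estimate_markov(tm).P.to_numpy(), np.eye(2))

    def test_row_normalization(self):
        from oasisrisk.transitions import TransitionMatrix

        tm = TransitionMatrix(pd.DataFrame([[90.0, 10.0], [20.0, 80.0]],
                                           index=["a", "b"], columns=["a", "b"]))
        np.testing.assert_allclose(
            estimate_markov(tm).P.to_numpy(), [[0.9, 0.1], [0.2, 0.8]]
        )

    def test_empty_source_class_gets_identity_row(self):
        from oasisrisk.transitions import TransitionMatrix

        tm = TransitionMatrix(pd.DataFrame([[1.0, 1.0], [0.0, 0.0]],
                                           index=["a", "b"], columns=["a", "b"]))
        with pytest.warns(UserWarning, match="identity row"):
            M = estimate_markov(tm)
        np.testing.assert_allclose(M.P.loc["b"].to_numpy(), [0.0, 1.0])


class TestApplyScenario:
    def test_empty_spec_is_identity_operation(self):
        rng = np.random.default_rng(1)
        M = random_stochastic(rng)
        out = apply_scenario(M, ScenarioSpec([]))
        np.testing.assert_allclose(out.P.to_numpy(), M.P.to_numpy())

    def test_cropland_row_arithmetic_under_20pct_cut(self):
        # 0.7 stay, 0.2 -> builtup, 0.1 -> unused; x0.8 -> 0.16, 0.08, diag 0.76
        labels = ["cropland", "builtup", "unused"]
        P = markov_from(
            [[0.7, 0.2, 0.1], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]], labels
        )
        spec = ScenarioSpec([(("cropland",), ("builtup", "unused"), 0.8)])
        out = apply_scenario(P, spec).P
        assert out.loc["cropland", "builtup"] == pytest.approx(0.16)
        assert out.loc["cropland", "unused"] == pytest.approx(0.08)
        assert out.loc["cropland", "cropland"] == pytest.approx(0.76)

    def test_government_rules_keep_rows_stochastic(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            out = apply_scenario(random_stochastic(rng), GOVERNMENT_SCENARIO)
            np.testing.assert_allclose(out.P.to_numpy().sum(axis=1), 1.0, atol=1e-9)

    def test_government_scenario_redirects_flows(self):
        # one-step flows: vegetated -> builtup decreases, unused -> vegetated grows
        rng = np.random.default_rng(3)
        vegetated = CLASSES[:4]
        for _ in range(50):
            M = random_stochastic(rng)
            G = apply_scenario(M, GOVERNMENT_SCENARIO)
            areas = pd.Series(rng.uniform(10, 100, len(CLASSES)), index=CLASSES)
            nat_to_built = sum(
                areas[v] * M.P.loc[v, "builtup"] for v in vegetated
            )
            gov_to_built = sum(
                areas[v] * G.P.loc[v, "builtup"] for v in vegetated
            )
            nat_unused_veg = sum(
                areas["unused"] * M.P.loc["unused", v] for v in vegetated
            )
            gov_unused_veg = sum(
                areas["unused"] * G.P.loc["unused", v] for v in vegetated
            )
            assert gov_to_built <= nat_to_built + 1e-12
            assert gov_unused_veg >= nat_unused_veg - 1e-12

    def test_nonpositive_multiplier_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ScenarioSpec([(("a",), ("b",), 0.0)])

    def test_negative_persistence_falls_back_to_row_rescaling(self):
        labels = ["unused", "cropland", "forestland"]
        P = markov_from(
            [[0.05, 0.5, 0.45], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]], labels
        )
        spec = ScenarioSpec([(("unused",), ("cropland", "forestland"), 1.3)])
        with pytest.warns(UserWarning, match="rescaled"):
            out = apply_scenario(P, spec)
        np.testing.assert_allclose(out.P.to_numpy().sum(axis=1), 1.0, atol=1e-9)


class TestProjectAreas:
    def test_identity_chain_preserves_areas(self):
        M = markov_from(np.eye(3), ["a", "b", "c"])
        areas = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = project_areas(areas, M, n_steps=7)
        np.testing.assert_allclose(out.to_numpy(), areas.to_numpy())

    def test_one_step_arithmetic(self):
        M = markov_from([[0.9, 0.1], [0.2, 0.8]], ["a", "b"])
        out = project_areas(np.array([100.0, 0.0]), M, n_steps=1)
        np.testing.assert_allclose(out.to_numpy(), [90.0, 10.0])

    def test_long_run_converges_to_stationary_distribution(self):
        M = markov_from([[0.9, 0.1], [0.2, 0.8]], ["a", "b"])
        out = project_areas(np.array([100.0, 0.0]), M, n_steps=200)
        np.testing.assert_allclose(
            out.to_numpy(), [100 * 2 / 3, 100 / 3], atol=1e-6
        )

    def test_negative_areas_rejected(self):
        M = markov_from(np.eye(2), ["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            project_areas(np.array([-1.0, 1.0]), M)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_area_conserved(self, seed, steps):
        rng = np.random.default_rng(seed)
        M = random_stochastic(rng)
        areas = rng.uniform(0, 50, len(CLASSES))
        out = project_areas(areas, M, n_steps=steps)
        assert out.sum() == pytest.approx(areas.sum(), rel=1e-9)


class TestZoneComposition:
    def test_matched_maps_put_everything_in_one_zone(self):
        lu = categorical_raster([[1, 1], [1, 1]])
        zones = categorical_raster([[1, 1], [1, 1]])
        pct = zone_composition(zones, lu)
        assert pct.loc["cropland", "oasis"] == pytest.approx(100.0)

    def test_toy_enumeration(self):
        lu = categorical_raster([[1, 1], [7, 7]])
        zones = categorical_raster([[1, 2], [3, 3]])
        pct = zone_composition(zones, lu)
        assert pct.loc["cropland", "oasis"] == pytest.approx(50.0)
        assert pct.loc["cropland", "transition"] == pytest.approx(50.0)
        assert pct.loc["unused", "desert"] == pytest.approx(100.0)

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(4)
        lu = categorical_raster(rng.integers(1, 8, (20, 20)))
        zones = categorical_raster(rng.integers(1, 4, (20, 20)))
        pct = zone_composition(zones, lu)
        np.testing.assert_allclose(pct.sum(axis=1).to_numpy(), 100.0, atol=1e-9)
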