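"""Nearest-neighbor distances, the interaction variable, radial profiles,
patient aggregation and median dichotomization."""

import math

import numpy as np
import pytest

from immunoprox import (
    SpatialParams,
    aggregate_patient,
    dichotomize_by_median,
    interaction_variable,
    nearest_neighbor_distances,
    radial_profile,
)
from immunoprox.spatial import EmptyReferenceError
from immunoprox.synthetic import brute_force_nn

TOY_B = np.array([[0.0, 0.0], [100.0, 0.0]])
TOY_A = np.array([[10.0, 0.0], [30.0, 0.0], [90.0, 0.0], [200.0, 0.0]])


class TestNearestNeighbor:
    def test_coincident_cell_has_distance_zero(self):
        d = nearest_neighbor_distances(np.array([[3.0, 4.0]]),
                                       np.array([[3.0, 4.0], [9.0, 9.0]]))
        assert d[0] == 0.0

    def test_3_4_5_triangle(self):
        d = nearest_neighbor_distances(np.array([[0.0, 0.0]]),
                                       np.array([[3.0, 4.0], [10.0, 0.0]]))
        assert d[0] == pytest.approx(5.0)

    def test_matches_brute_force_all_pairs(self, rng):
        A = rng.uniform(0, 600, size=(200, 2))
        B = rng.uniform(0, 600, size=(200, 2))
        np.testing.assert_array_equal(
            nearest_neighbor_distances(A, B), brute_force_nn(A, B)
        )

    def test_toroidal_metric_matches_brute_force(self, rng):
        A = rng.uniform(0, 600, size=(150, 2))
        B = rng.uniform(0, 600, size=(150, 2))
        period = (600.0, 600.0)
        np.testing.assert_allclose(
            nearest_neighbor_distances(A, B, period=period),
            brute_force_nn(A, B, period=period),
            rtol=0, atol=1e-9,
        )

    def test_self_population_excludes_self_pairs(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 0.0]])
        d = nearest_neighbor_distances(pts, pts, exclude_self=True)
        np.testing.assert_allclose(d, [1.0, 1.0, 4.0])

    def test_empty_reference_signalled(self):
        with pytest.raises(EmptyReferenceError):
            nearest_neighbor_distances(TOY_A, np.empty((0, 2)))


class TestInteractionVariable:
    def test_toy_example_k2_of_6(self):
        # nearest-B distances are {10, 30, 10, 100}: two within r=25
        res = interaction_variable(TOY_A, TOY_B, SpatialParams(radius_r=25))
        assert (res.n_a, res.n_b, res.k) == (4, 2, 2)
        assert res.value == pytest.approx(100 * 2 / 6)

    def test_single_pair_within_radius_gives_50(self):
        res = interaction_variable(np.array([[10.0, 0.0]]),
                                   np.array([[0.0, 0.0]]))
        assert res.value == pytest.approx(50.0)

    def test_no_cell_within_radius_gives_zero(self):
        res = interaction_variable(np.array([[500.0, 500.0]]), TOY_B)
        assert res.k == 0 and res.value == 0.0

    def test_empty_both_populations_is_missing(self):
        res = interaction_variable(np.empty((0, 2)), np.empty((0, 2)))
        assert res.missing

    def test_empty_anchor_population_scores_zero(self):
        res = interaction_variable(TOY_A, np.empty((0, 2)))
        assert not res.missing and res.value == 0.0 and res.n_b == 0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            SpatialParams(radius_r=-1)

    def test_boundary_convention_flag(self):
        A = np.array([[25.0, 0.0]])
        B = np.array([[0.0, 0.0]])
        inc = interaction_variable(A, B, SpatialParams(radius_r=25))
        exc = interaction_variable(
            A, B, SpatialParams(radius_r=25, inclusive_boundary=False)
        )
        assert inc.k == 1 and exc.k == 0

    def test_value_bounds_and_k_identity(self, rng):
        for _ in range(20):
            A = rng.uniform(0, 200, size=(rng.integers(1, 80), 2))
            B = rng.uniform(0, 200, size=(rng.integers(1, 40), 2))
            res = interaction_variable(A, B)
            assert 0.0 <= res.value <= 100.0
            k_back = res.value * (res.n_a + res.n_b) / 100
            assert k_back == pytest.approx(res.k, abs=1e-9)

    def test_nondecreasing_in_radius(self, rng):
        A = rng.uniform(0, 300, size=(100, 2))
        B = rng.uniform(0, 300, size=(30, 2))
        values = [
            interaction_variable(A, B, SpatialParams(radius_r=r,
                                                     max_radius=r)).value
            for r in (5, 10, 25, 50, 100)
        ]
        assert all(a <= b for a, b in zip(values, values[1:]))

    def test_rigid_motion_invariance(self, rng):
        A = rng.uniform(0, 300, size=(80, 2))
        B = rng.uniform(0, 300, size=(25, 2))
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        shift = np.array([123.4, -56.7])
        res = interaction_variable(A, B)
        res2 = interaction_variable(A @ R.T + shift, B @ R.T + shift)
        assert res2.k == res.k
        assert res2.value == pytest.approx(res.value, rel=1e-9)

    def test_permutation_invariance(self, rng):
        A = rng.uniform(0, 300, size=(60, 2))
        B = rng.uniform(0, 300, size=(20, 2))
        res = interaction_variable(A, B)
        res2 = interaction_variable(A[rng.permutation(60)],
                                    B[rng.permutation(20)])
        assert (res2.k, res2.value) == (res.k, res.value)


class TestRadialProfile:
    def test_toy_binning_and_cumulative(self):
        prof = radial_profile(TOY_A, TOY_B, SpatialParams())
        # nearest distances {10, 30, 10, 100}: bin [10,15) holds 2, overflow 2
        np.testing.assert_array_equal(prof.counts, [0, 0, 2, 0, 0])
        assert prof.overflow == 2
        assert prof.cumulative_fraction(25) == pytest.approx(0.5)

    def test_all_cells_close_gives_cumulative_one(self, rng):
        B = rng.uniform(0, 100, size=(10, 2))
        A = B[rng.integers(0, 10, 50)] + rng.uniform(-1, 1, size=(50, 2))
        prof = radial_profile(A, B, SpatialParams())
        assert prof.cumulative_fraction(25) == 1.0
        assert prof.overflow == 0

    def test_counts_match_brute_force_histogram(self, rng):
        A = rng.uniform(0, 400, size=(300, 2))
        B = rng.uniform(0, 400, size=(40, 2))
        params = SpatialParams(bin_width=5, max_radius=50, radius_r=50)
        prof = radial_profile(A, B, params)
        d = brute_force_nn(A, B)
        expected = [
            np.count_nonzero((d >= lo) & (d < lo + 5))
            for lo in np.arange(0, 50, 5)
        ]
        np.testing.assert_array_equal(prof.counts, expected)
        assert prof.overflow == np.count_nonzero(d >= 50)
        assert prof.counts.sum() + prof.overflow == 300

    def test_consistency_with_interaction_k(self, rng):
        A = rng.uniform(0, 300, size=(120, 2))
        B = rng.uniform(0, 300, size=(30, 2))
        params = SpatialParams()
        res = interaction_variable(A, B, params)
        prof = radial_profile(A, B, params)
        assert res.k == round(res.n_a * prof.cumulative_fraction(params.radius_r))

    def test_empty_reference_raises(self):
        with pytest.raises(EmptyReferenceError):
            radial_profile(TOY_A, np.empty((0, 2)))

    def test_bad_bin_configuration_rejected(self):
        with pytest.raises(ValueError):
            SpatialParams(bin_width=7, max_radius=25)


class TestAggregation:
    def test_single_image_passes_through(self):
        assert aggregate_patient([40.0]) == (40.0, 1)

    def test_mean_of_two(self):
        value, n = aggregate_patient([10.0, 30.0], method="mean")
        assert value == 20.0 and n == 2

    def test_missing_images_dropped(self):
        vals = [10.0, float("nan"), 20.0, 30.0, 40.0]
        value, n = aggregate_patient(vals, method="mean")
        assert value == pytest.approx(np.mean([10, 20, 30, 40]))
        assert n == 4

    def test_all_missing_yields_missing(self):
        value, n = aggregate_patient([float("nan")] * 3)
        assert math.isnan(value) and n == 0

    def test_median_method(self):
        value, _ = aggregate_patient([1.0, 2.0, 100.0], method="median")
        assert value == 2.0


class TestMedianDichotomization:
    def test_three_values_middle_goes_high(self):
        groups, med = dichotomize_by_median({"a": 1.0, "b": 2.0, "c": 3.0})
        assert med == 2.0
        assert groups == {"a": "low", "b": "high", "c": "high"}

    def test_113_distinct_values_split_56_57(self, rng):
        vals = {f"p{i}": v for i, v in enumerate(rng.permutation(113) * 1.0)}
        groups, _ = dichotomize_by_median(vals)
        counts = {g: sum(1 for v in groups.values() if v == g)
                  for g in ("low", "high")}
        assert counts == {"low": 56, "high": 57}

    def test_even_n_distinct_values_split_equally(self, rng):
        vals = {f"p{i}": float(v)
                for i, v in enumerate(rng.permutation(500))}
        groups, _ = dichotomize_by_median(vals)
        assert sum(1 for v in groups.values() if v == "high") == 250

    def test_all_equal_values_all_high_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            groups, _ = dichotomize_by_median({"a": 5.0, "b": 5.0, "c": 5.0})
        assert set(groups.values()) == {"high"}

    def test_missing_patients_excluded(self):
        groups, _ = dichotomize_by_median(
            {"a": 1.0, "b": float("nan"), "c": 3.0}
        )
        assert "b" not in groups and len(groups) == 2

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_by_median({"a": 1.0})
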