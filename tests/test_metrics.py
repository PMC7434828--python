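"""Signature distances, the maximal-invariant grid, and threshold concentration."""

import numpy as np
import pytest

from orbipool import (NonlinearitySpec, SimpleCellBank, ThresholdGrid,
                      cosine_similarity_curve, distance_report,
                      expected_threshold_distance, full_threshold_grid,
                      hoeffding_bound, log_overlap_coefficient,
                      make_cyclic_permutation_group, orbit_bank,
                      sample_orbit_dataset, sampled_threshold_distance,
                      signature_distance)
from tests.conftest import sorted_responses


class TestSignatureDistance:
    @pytest.mark.parametrize("norm", ["l1", "l2"])
    def test_zero_within_an_orbit(self, cyclic6, cyclic6_orbit_bank, rng, norm):
        x = rng.standard_normal(6)
        grid = ThresholdGrid.uniform_random(-2, 2, 15, rng_seed=0)
        for g in cyclic6.elements:
            assert signature_distance(x, g @ x, cyclic6_orbit_bank, grid,
                                      norm) == 0.0

    def test_identity(self, cyclic6_orbit_bank, rng):
        x = rng.standard_normal(6)
        grid = ThresholdGrid.uniform_random(-2, 2, 10, rng_seed=1)
        assert signature_distance(x, x, cyclic6_orbit_bank, grid) == 0.0

    def test_positive_across_orbits_on_the_full_grid(self, cyclic6,
                                                     cyclic6_orbit_bank, rng):
        x, y = rng.standard_normal((2, 6))
        grid = full_threshold_grid(cyclic6_orbit_bank, np.column_stack([x, y]))
        assert signature_distance(x, y, cyclic6_orbit_bank, grid) > 0

    def test_collapsed_variant_is_weaker(self, cyclic6_orbit_bank, rng):
        """The scalar (threshold-summed) code can cancel where the vector
        code separates."""
        x, y = rng.standard_normal((2, 6))
        grid = full_threshold_grid(cyclic6_orbit_bank, np.column_stack([x, y]))
        full = signature_distance(x, y, cyclic6_orbit_bank, grid, "l1")
        coll = signature_distance(x, y, cyclic6_orbit_bank, grid,
                                  collapsed=True)
        assert coll <= full

    def test_l2_satisfies_the_triangle_inequality(self, cyclic6_orbit_bank,
                                                  rng):
        grid = ThresholdGrid.uniform_random(-2, 2, 20, rng_seed=2)
        for _ in range(20):
            x, y, z = rng.standard_normal((3, 6))
            dxy = signature_distance(x, y, cyclic6_orbit_bank, grid, "l2")
            dyz = signature_distance(y, z, cyclic6_orbit_bank, grid, "l2")
            dxz = signature_distance(x, z, cyclic6_orbit_bank, grid, "l2")
            assert dxz <= dxy + dyz + 1e-12

    def test_invalid_norm(self, cyclic6_orbit_bank, rng):
        grid = ThresholdGrid(np.array([0.0]))
        with pytest.raises(ValueError):
            signature_distance(np.zeros(6), np.zeros(6), cyclic6_orbit_bank,
                               grid, norm="linf")


class TestFullThresholdGrid:
    def test_midpoint_construction_on_known_responses(self):
        bank = SimpleCellBank(np.array([[1.0, 2.0, 3.0]]))
        grid = full_threshold_grid(bank, np.array([[1.0]]))
        z = grid.thresholds
        assert len(z) == 4
        assert z[0] < 1.0 and 1.0 < z[1] < 2.0 and 2.0 < z[2] < 3.0 \
            and z[3] > 3.0

    def test_constant_responses_give_two_flanks(self):
        bank = SimpleCellBank(np.ones((2, 3)))
        grid = full_threshold_grid(bank, np.array([[0.5], [0.5]]))
        assert grid.K == 2
        assert grid.thresholds[0] < 1.0 < grid.thresholds[1]

    def test_grid_separates_distinct_response_multisets(self, cyclic6, rng):
        """Counting oracle: distance is 0 iff the sorted drive vectors match."""
        bank = orbit_bank(cyclic6, rng.standard_normal(6))
        for _ in range(50):
            x = rng.standard_normal(6)
            y = cyclic6.elements[rng.integers(6)] @ x if rng.random() < 0.5 \
                else rng.standard_normal(6)
            grid = full_threshold_grid(bank, np.column_stack([x, y]))
            d = signature_distance(x, y, bank, grid)
            same_multiset = np.allclose(sorted_responses(bank, x),
                                        sorted_responses(bank, y), atol=1e-9)
            assert (d == 0.0) == same_multiset


class TestDistanceReport:
    def test_ideal_setting_is_perfectly_separated(self, cyclic6,
                                                  cyclic6_orbit_bank):
        ds = sample_orbit_dataset(cyclic6, Q=10, rng_seed=3)
        grid = full_threshold_grid(cyclic6_orbit_bank, ds.stimuli)
        rep = distance_report(ds, cyclic6_orbit_bank, grid, n_pairs=50,
                              rng_seed=0)
        assert np.all(rep.intra == 0.0)
        assert np.all(rep.inter > 0.0)
        assert rep.summary()["overlap"] == 0.0

    def test_empty_report(self, cyclic6, cyclic6_orbit_bank):
        ds = sample_orbit_dataset(cyclic6, Q=2, rng_seed=0)
        grid = ThresholdGrid(np.array([0.0]))
        rep = distance_report(ds, cyclic6_orbit_bank, grid, n_pairs=0,
                              rng_seed=0)
        assert rep.intra.size == 0 and rep.inter.size == 0
        frame = rep.to_frame()
        assert list(frame.columns) == ["pair_id", "type", "distance"]

    def test_requires_two_orbits(self, cyclic6, cyclic6_orbit_bank):
        ds = sample_orbit_dataset(cyclic6, Q=1, rng_seed=0)
        with pytest.raises(ValueError):
            distance_report(ds, cyclic6_orbit_bank,
                            ThresholdGrid(np.array([0.0])), 5, 0)

    def test_overlap_coefficient_extremes(self):
        assert log_overlap_coefficient(np.zeros(50), np.full(50, 10.0)) == 0.0
        same = np.linspace(1, 2, 50)
        assert log_overlap_coefficient(same, same) == 1.0


class TestCosineCurve:
    def test_identical_stimuli_have_similarity_one(self, cyclic6_orbit_bank,
                                                   rng):
        x = rng.standard_normal(6)
        curve = cosine_similarity_curve(x, x, cyclic6_orbit_bank,
                                        [1, 4, 16], reps=20, rng_seed=0)
        ok = curve.dropna(subset=["mean_cosine"])
        assert np.allclose(ok["mean_cosine"], 1.0)

    def test_K_list_must_increase(self, cyclic6_orbit_bank, rng):
        with pytest.raises(ValueError):
            cosine_similarity_curve(rng.standard_normal(6),
                                    rng.standard_normal(6),
                                    cyclic6_orbit_bank, [4, 2], 5, 0)


class TestHoeffding:
    def test_bound_limits_and_algebra(self):
        assert hoeffding_bound(10, 1e-9, 12.0) == pytest.approx(2.0)
        Q, eps, w = 25, 0.2, 12.0
        p = w ** 2 / 4
        ratio = hoeffding_bound(2 * Q, eps, w) / hoeffding_bound(Q, eps, w)
        assert ratio == pytest.approx(np.exp(-Q * eps ** 2 / (2 * p)))

    def test_bound_monotone_in_Q_and_eps(self):
        assert hoeffding_bound(100, 0.1, 12) < hoeffding_bound(10, 0.1, 12)
        assert hoeffding_bound(10, 0.2, 12) < hoeffding_bound(10, 0.1, 12)

    def test_bound_rejects_nonpositive_arguments(self):
        for bad in [(0, 0.1, 1.0), (10, 0.0, 1.0), (10, 0.1, 0.0)]:
            with pytest.raises(ValueError):
                hoeffding_bound(*bad)

    def test_closed_form_expectation_against_numerical_integration(
            self, cyclic6_orbit_bank, rng):
        x, y = rng.standard_normal((2, 6))
        lo, hi = -2.0, 2.0
        zs = np.linspace(lo, hi, 20001)
        from orbipool import signature_counts
        counts = signature_counts(cyclic6_orbit_bank.W,
                                  np.column_stack([x, y]), zs)
        numeric = np.trapezoid(counts[:, 0] - counts[:, 1], zs) / (hi - lo)
        closed = expected_threshold_distance(x, y, cyclic6_orbit_bank, lo, hi,
                                             signed=True)
        assert closed == pytest.approx(numeric, abs=1e-3)

    def test_sampled_mean_converges_to_the_expectation(self,
                                                       cyclic6_orbit_bank,
                                                       rng):
        x, y = rng.standard_normal((2, 6))
        lo, hi = -2.0, 2.0
        exact = expected_threshold_distance(x, y, cyclic6_orbit_bank, lo, hi)
        est = sampled_threshold_distance(x, y, cyclic6_orbit_bank, lo, hi,
                                         200_000, rng)
        assert est == pytest.approx(exact, abs=0.05)
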