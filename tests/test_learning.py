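"""Loss class, gradients, training dynamics, and the Stiefel maximization."""

import numpy as np
import pytest

from orbipool import (LossSpec, NonlinearitySpec, StiefelConfig, TrainConfig,
                      constrained_maximize, grad,
                      gradient_equivariance_residual, loss,
                      make_cyclic_permutation_group,
                      make_dihedral_permutation_group,
                      make_planar_rotation_group, sample_orbit_dataset,
                      subsample_orbits, train)


def _random_instance(rng, d=5, n_cells=4, R=30):
    return rng.standard_normal((d, n_cells)), rng.standard_normal((d, R))


class TestLoss:
    def test_saturated_heaviside_counts_everything(self, rng):
        W, S = _random_instance(rng)
        z = -(1.0 + np.abs(W.T @ S).max())
        spec = LossSpec(f="square", nonlinearity=NonlinearitySpec(
            kind="heaviside", threshold=z))
        assert loss(W, S, spec) == W.shape[1] * S.shape[1]

    def test_summation_equals_frobenius_form(self, rng):
        """Σ_{ij} σ(w_iᵀx_j)² computed entrywise vs ‖σ(WᵀS)‖²_F via BLAS."""
        spec = LossSpec(f="square")
        for _ in range(100):
            W, S = _random_instance(rng)
            frob = float(np.linalg.norm(
                spec.nonlinearity.apply(W.T @ S), ord="fro") ** 2)
            assert loss(W, S, spec) == pytest.approx(frob, rel=1e-12)

    def test_invariant_under_weight_transformation_on_full_orbits(self, rng):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=8, rng_seed=0)
        W = rng.standard_normal((6, 4))
        base = loss(W, ds.stimuli)
        for M in g.elements:
            assert loss(M @ W, ds.stimuli) == pytest.approx(base, abs=1e-10)

    def test_nonnegative_for_all_f(self, rng):
        W, S = _random_instance(rng)
        for f in ("square", "abs", "huber"):
            assert loss(W, S, LossSpec(f=f)) >= 0.0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            loss(rng.standard_normal((4, 2)), rng.standard_normal((5, 3)))


class TestGradient:
    @pytest.mark.parametrize("f", ["square", "huber"])
    def test_matches_finite_differences(self, rng, f):
        spec = LossSpec(f=f)
        W, S = _random_instance(rng, d=4, n_cells=3, R=12)
        G = grad(W, S, spec)
        h = 1e-6
        for _ in range(10):
            i = rng.integers(4)
            j = rng.integers(3)
            Wp, Wm = W.copy(), W.copy()
            Wp[i, j] += h
            Wm[i, j] -= h
            fd = (loss(Wp, S, spec) - loss(Wm, S, spec)) / (2 * h)
            assert G[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-9)

    def test_closed_form_at_zero_weights(self, rng):
        """At W = 0 every drive is 0, so each gradient column is
        f'(σ(0))·σ'(0)·Σ_j x_j."""
        spec = LossSpec(f="square", nonlinearity=NonlinearitySpec(
            kind="logistic_surrogate", threshold=-0.5, steepness=10.0))
        S = rng.standard_normal((5, 20))
        W = np.zeros((5, 3))
        s0 = spec.nonlinearity.apply(0.0)
        expected = float(spec.f_prime(s0) * spec.nonlinearity.derivative(0.0)) \
            * S.sum(axis=1)
        G = grad(W, S, spec)
        for i in range(3):
            np.testing.assert_allclose(G[:, i], expected, rtol=1e-12)

    def test_heaviside_gradient_is_a_configuration_error(self, rng):
        W, S = _random_instance(rng)
        with pytest.raises(ValueError, match="surrogate"):
            grad(W, S, LossSpec(nonlinearity=NonlinearitySpec(kind="heaviside")))


class TestEquivariance:
    @pytest.mark.parametrize("factory", [make_cyclic_permutation_group,
                                         make_dihedral_permutation_group])
    def test_full_orbit_residual_is_tiny(self, factory, rng):
        g = factory(6)
        ds = sample_orbit_dataset(g, Q=10, rng_seed=1)
        W = rng.standard_normal((6, g.N))
        rep = gradient_equivariance_residual(W, ds.stimuli, g)
        assert rep.orbit_complete
        assert rep.residual <= 1e-10

    def test_truncated_orbits_violate_the_identity(self, rng):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=10, rng_seed=1)
        half = subsample_orbits(ds, 0.5, rng_seed=2)
        W = rng.standard_normal((6, 6))
        full = gradient_equivariance_residual(W, ds.stimuli, g)
        trunc = gradient_equivariance_residual(W, half.stimuli, g)
        assert not trunc.orbit_complete
        assert trunc.residual > full.residual

    def test_trivial_group_residual_is_zero(self, rng):
        g = make_planar_rotation_group(1)
        S = rng.standard_normal((2, 10))
        rep = gradient_equivariance_residual(rng.standard_normal((2, 3)), S, g)
        assert rep.residual == 0.0


class TestTrain:
    def test_loss_is_nondecreasing(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        state = train(ds.stimuli, TrainConfig(epochs=15, seed=0),
                      group_size=g.N)
        assert np.all(np.diff(state.loss_trajectory) >= 0)

    def test_checkpoints_fall_on_orbit_complete_counts(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        state = train(ds.stimuli, TrainConfig(epochs=4, seed=0),
                      group_size=g.N)
        assert state.t == 4 * g.N * 5
        assert len(state.checkpoints) == 5       # init + 4 epochs

    def test_equivariance_holds_at_every_checkpoint(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        state = train(ds.stimuli, TrainConfig(epochs=5, seed=3),
                      group_size=g.N)
        for W in state.checkpoints:
            rep = gradient_equivariance_residual(W, ds.stimuli, g,
                                                 check_orbit_complete=False)
            assert rep.residual <= 1e-8

    def test_deterministic_trajectories(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        s1 = train(ds.stimuli, TrainConfig(epochs=8, seed=11), group_size=g.N)
        s2 = train(ds.stimuli, TrainConfig(epochs=8, seed=11), group_size=g.N)
        for a, b in zip(s1.checkpoints, s2.checkpoints):
            assert np.array_equal(a, b)

    def test_zero_init_reproduces_the_convention(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=3, rng_seed=0)
        state = train(ds.stimuli, TrainConfig(epochs=1, seed=0, init="zero"),
                      group_size=g.N)
        assert not state.checkpoints[0].any()


class TestConstrainedMaximize:
    def test_orthonormality_and_monotone_objective(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        res = constrained_maximize(ds.stimuli, None, 0.0, 4,
                                   StiefelConfig(iters=80, restarts=2, seed=0))
        assert res.orthonormality_residual <= 1e-8
        assert np.all(np.diff(res.trace) >= 0)

    def test_deterministic(self):
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=5, rng_seed=0)
        r1 = constrained_maximize(ds.stimuli, None, 0.0, 3,
                                  StiefelConfig(iters=40, seed=5))
        r2 = constrained_maximize(ds.stimuli, None, 0.0, 3,
                                  StiefelConfig(iters=40, seed=5))
        assert np.array_equal(r1.U, r2.U)

    def test_overcomplete_frame_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds dimension"):
            constrained_maximize(rng.standard_normal((4, 10)), None, 0.0, 5)

    def test_objective_invariant_under_group_action_on_the_frame(self, rng):
        """On orbit-complete stimuli the objective value of g·U equals that
        of U for every group element — the solution space is a union of
        orbits of frames."""
        g = make_cyclic_permutation_group(6)
        ds = sample_orbit_dataset(g, Q=6, rng_seed=2)
        U, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        spec = LossSpec(f="square")
        base = loss(U, ds.stimuli, spec)
        for M in g.elements:
            assert loss(M @ U, ds.stimuli, spec) == pytest.approx(
                base, abs=1e-10)
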