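import numpy as np
import pytest

from orbipool import (NonlinearitySpec, SimpleCellBank,
                      make_cyclic_permutation_group,
                      make_dihedral_permutation_group, orbit, orbit_bank,
                      sample_orbit_dataset)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cyclic6():
    return make_cyclic_permutation_group(6)


@pytest.fixture
def dihedral6():
    return make_dihedral_permutation_group(6)


@pytest.fixture
def cyclic6_dataset(cyclic6):
    return sample_orbit_dataset(cyclic6, Q=10, rng_seed=7)


@pytest.fixture
def cyclic6_orbit_bank(cyclic6, rng):
    """Heaviside bank whose weights are one full cyclic orbit."""
    w = rng.standard_normal(6)
    w /= np.linalg.norm(w)
    return orbit_bank(cyclic6, w, NonlinearitySpec(kind="heaviside",
                                                   threshold=0.0))


def sorted_responses(bank: SimpleCellBank, x: np.ndarray) -> np.ndarray:
    """Oracle helper: the sorted raw drive multiset of a stimulus."""
    return np.sort(bank.W.T @ x)


def constructed_candidate_pool(group, rng, distractor_scale=0.25,
                               max_tries=50):
    """Target orbit plus a strictly weaker distractor orbit, gap verified.

    The target template is the S_new base point itself; the pooled-response
    nonlinearity has a positive threshold so that weak drives score low.  The
    distractor is resampled until every element of its orbit pools strictly
    below every element of the target orbit.
    """
    from orbipool import LossSpec, orbit, pooled_response

    spec = LossSpec(f="square", nonlinearity=NonlinearitySpec(
        kind="logistic_surrogate", threshold=0.3, steepness=5.0))
    base = rng.standard_normal(group.d)
    base /= np.linalg.norm(base)
    S_new = orbit(group, base)
    target_orbit = orbit(group, base)
    t_scores = [pooled_response(target_orbit[:, i], S_new, spec)
                for i in range(group.N)]
    for _ in range(max_tries):
        distractor = rng.standard_normal(group.d)
        distractor *= distractor_scale / np.linalg.norm(distractor)
        d_orbit = orbit(group, distractor)
        d_scores = [pooled_response(d_orbit[:, i], S_new, spec)
                    for i in range(group.N)]
        if max(d_scores) < min(t_scores):
            pool = np.concatenate([target_orbit, d_orbit], axis=1)
            return pool, S_new, spec
    raise AssertionError("could not construct a verified response gap")
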