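"""Complex-cell wiring: iterated maximal-response selection over a frozen pool.

After the first plasticity phase the simple-cell weights are frozen and form a
candidate pool E_simple.  A complex cell wires the cell whose pooled response
to a fresh orbit-structured stimulus set S_new is maximal (template w̄), then
repeats the argmax excluding already-selected and near-duplicate candidates.
Because the pooled response over a complete orbit set is invariant under
w̄ → g·w̄, each subsequent argmax lands on another element of w̄'s orbit: the
selected weights form an orbit, and the resulting complex cell is invariant.

Near-duplicate exclusion (cosine similarity above 1 − dedup_tol) operationalizes
the "repeatedly sampled orbit elements do not impact the result" remark; the
dedup tolerance is an implementation choice, not part of the theory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cells import NonlinearitySpec, SimpleCellBank, complex_response
from .groups import FiniteOrthogonalGroup
from .learning import LossSpec

__all__ = [
    "AggregationResult",
    "select_max_cell",
    "aggregate_orbit",
    "is_weight_orbit",
    "invariance_residual",
    "pooled_response",
    "best_nondegenerate_template",
    "orbit_spread",
]


@dataclass(frozen=True)
class AggregationResult:
    """Outcome of the iterated-argmax wiring procedure.

    ``selected_weights`` columns are in selection order (template w̄ first);
    ``matching`` holds, per selected weight, the group-element index g_i and
    the residual ‖w_i − g_i·w̄‖₂ from the orbit verification (empty when no
    group was supplied).
    """

    selected_weights: np.ndarray          # (d, N)
    selected_indices: np.ndarray          # indices into the candidate pool
    is_orbit: Optional[bool]
    matching: list                        # [(element_index, residual), ...]
    dedup_count: int


def pooled_response(w: np.ndarray, S_new: np.ndarray,
                    spec: Optional[LossSpec] = None) -> float:
    """Σ_j f(σ(wᵀ s_j)): the pooled response of one candidate over S_new."""
    spec = spec or LossSpec()
    s = spec.nonlinearity.apply(np.asarray(w, dtype=float) @ S_new)
    return float(np.sum(spec.f_value(s)))


def select_max_cell(candidates: np.ndarray, S_new: np.ndarray,
                    spec: Optional[LossSpec] = None) -> int:
    """Index of the candidate with maximal pooled response over S_new.

    Ties are broken by the lowest index, which is what makes the procedure
    deterministic when whole orbits of equally-responding candidates are in
    the pool.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    S_new = np.atleast_2d(np.asarray(S_new, dtype=float))
    if candidates.size == 0 or S_new.size == 0:
        raise ValueError("candidates and S_new must be nonempty")
    spec = spec or LossSpec()
    scores = np.array([pooled_response(candidates[:, i], S_new, spec)
                       for i in range(candidates.shape[1])])
    return int(np.argmax(scores))       # argmax returns the first maximum


def aggregate_orbit(
    candidates: np.ndarray,
    S_new: np.ndarray,
    group_size: Optional[int] = None,
    spec: Optional[LossSpec] = None,
    dedup_tol: float = 1e-8,
    group: Optional[FiniteOrthogonalGroup] = None,
    orbit_tol: float = 1e-6,
) -> AggregationResult:
    """Iterated argmax selection of ``group_size`` simple cells.

    Each round selects the maximal pooled responder among candidates not yet
    selected and not a near-duplicate (cosine similarity > 1 − dedup_tol) of
    an already-selected weight.  If a ``group`` is supplied the selected
    weights are verified to form an orbit (``is_orbit`` / ``matching``);
    ``group_size`` then defaults to the group order.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    S_new = np.atleast_2d(np.asarray(S_new, dtype=float))
    if group is not None and group_size is None:
        group_size = group.N
    if group_size is None:
        raise ValueError("either group_size or group must be given")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")

    spec = spec or LossSpec()
    n_cand = candidates.shape[1]
    norms = np.linalg.norm(candidates, axis=0)
    scores = np.array([pooled_response(candidates[:, i], S_new, spec)
                       for i in range(n_cand)])
    order = []          # selected candidate indices, in selection order
    available = np.ones(n_cand, dtype=bool)
    dedup_count = 0
    while len(order) < group_size:
        if not available.any():
            raise RuntimeError(
                f"candidate pool exhausted: {len(order)} distinct cells "
                f"selected, {group_size} required")
        masked = np.where(available, scores, -np.inf)
        pick = int(np.argmax(masked))
        available[pick] = False
        if order:
            sel = candidates[:, order]
            w = candidates[:, pick]
            denom = np.linalg.norm(sel, axis=0) * norms[pick]
            with np.errstate(invalid="ignore", divide="ignore"):
                cos = np.where(denom > 0, (sel.T @ w) / denom, 1.0)
            if np.any(cos > 1.0 - dedup_tol):
                dedup_count += 1
                continue
        order.append(pick)

    selected = candidates[:, order]
    is_orb, matching = (None, [])
    if group is not None:
        is_orb, matching = is_weight_orbit(selected, group, orbit_tol)
    return AggregationResult(
        selected_weights=selected,
        selected_indices=np.asarray(order),
        is_orbit=is_orb,
        matching=matching,
        dedup_count=dedup_count,
    )


def is_weight_orbit(weights: np.ndarray, group: FiniteOrthogonalGroup,
                    tol: float = 1e-6) -> tuple[bool, list]:
    """Do the N weight columns form one orbit {g·w̄} of the group?

    The first column is taken as the template (if the columns do form an
    orbit, any of them generates the same orbit).  Columns are assigned to
    orbit elements by minimum-cost bipartite matching; True iff the matching
    is a bijection with every residual ≤ tol.  Returns the per-column list of
    (element index, residual).  An all-zero template matches degenerately
    (every residual 0).
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != group.N:
        raise ValueError(
            f"expected {group.N} weight columns, got {weights.shape[1]}")
    wbar = weights[:, 0]
    orb = np.einsum("nij,j->in", group.elements, wbar)          # (d, N)
    cost = np.linalg.norm(weights[:, :, None] - orb[:, None, :], axis=0)
    rows, cols = linear_sum_assignment(cost)
    matching = [(int(c), float(cost[r, c])) for r, c in sorted(zip(rows, cols))]
    ok = bool(all(res <= tol for _, res in matching))
    return ok, matching


def orbit_spread(group: FiniteOrthogonalGroup, w: np.ndarray) -> float:
    """min over nonidentity g of ‖g·w − w‖₂: how nondegenerate w's orbit is.

    Zero for a group-invariant template, whose orbit collapses onto a single
    repeated cell and yields a degenerate (weakly selective) complex cell.
    """
    w = np.asarray(w, dtype=float)
    diffs = np.einsum("nij,j->in", group.elements[1:], w) - w[:, None]
    if diffs.shape[1] == 0:
        return 0.0
    return float(np.linalg.norm(diffs, axis=0).min())


def best_nondegenerate_template(
    candidates: np.ndarray,
    S_new: np.ndarray,
    group: FiniteOrthogonalGroup,
    spec: Optional[LossSpec] = None,
    min_spread: float = 0.5,
) -> int:
    """Best pooled responder whose orbit does not collapse onto itself.

    Candidates are ranked by pooled response over S_new; the first whose
    orbit spread exceeds ``min_spread`` (scale: unit-norm weights) wins.  A
    nearly group-invariant template would wire N near-copies of one simple
    cell — formally an orbit, but a degenerate complex cell; the selectivity
    analysis assumes the aggregated weights are genuinely distinct.  Falls
    back to the overall best responder if every candidate is degenerate.
    """
    candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    spec = spec or LossSpec()
    scores = np.array([pooled_response(candidates[:, i], S_new, spec)
                       for i in range(candidates.shape[1])])
    for i in np.argsort(-scores):
        if orbit_spread(group, candidates[:, i]) > min_spread:
            return int(i)
    return int(np.argmax(scores))


def invariance_residual(
    bank: SimpleCellBank,
    group: FiniteOrthogonalGroup,
    test_points: np.ndarray,
) -> float:
    """max over g and test points x of |c(g·x) − c(x)| for the complex cell.

    Exactly zero for permutation groups with an orbit-structured Heaviside
    bank (the response multiset is permuted, the sum unchanged); bounded by
    trigonometric round-off for rotation groups.
    """
    test_points = np.atleast_2d(np.asarray(test_points, dtype=float))
    worst = 0.0
    for j in range(test_points.shape[1]):
        x = test_points[:, j]
        c0 = complex_response(bank, x)
        for g in group.elements:
            worst = max(worst, abs(complex_response(bank, g @ x) - c0))
    return worst
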