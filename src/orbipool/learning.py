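"""Unsupervised learning of simple-cell weights.

The admissible learning rules all descend from a loss of the form

    L(W, S) = Σ_{i,j} f(σ(w_iᵀ x_j)),

with f nonnegative and Lipschitz on bounded sets (square, absolute value, or
Huber here) and σ a pointwise nonlinearity.  For f = square this is the
squared Frobenius norm of σ(WᵀS).  The Hebbian family (Oja, Földiák, ICA-type
rules) are members of this class.

Because the Heaviside has a degenerate derivative, gradients always use the
logistic surrogate; the Heaviside is reserved for evaluation.  The update is
gradient *ascent* (Hebbian potentiation): the constrained problem solved by
:func:`constrained_maximize` maximizes the same response-energy objective, so
ascent is the consistent sign convention throughout.

Two optimizers are provided:

* :func:`train` — plain full-batch ascent of L(W, S) with a normalized step
  and backtracking halving, visiting the stimuli in orbit-complete passes so
  every checkpoint falls at a multiple of |G|·Q elementary updates (the
  hypothesis of the solution-space equivariance theorem checked by
  :func:`gradient_equivariance_residual`);
* :func:`constrained_maximize` — projected gradient ascent with a QR
  retraction on the Stiefel manifold {U : UᵀU = I}, maximizing
  ‖σ(UᵀS)‖²_F + λ‖σ(UᵀS_new)‖²_F.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cells import NonlinearitySpec
from .groups import FiniteOrthogonalGroup

__all__ = [
    "LossSpec",
    "TrainConfig",
    "TrainState",
    "StiefelConfig",
    "StiefelResult",
    "EquivarianceReport",
    "loss",
    "grad",
    "train",
    "gradient_equivariance_residual",
    "constrained_maximize",
]


def _surrogate() -> NonlinearitySpec:
    return NonlinearitySpec(kind="logistic_surrogate", threshold=0.0,
                            steepness=10.0)


@dataclass(frozen=True)
class LossSpec:
    """Scalar map f applied to every simple-cell response, plus σ.

    f="square" (default), "abs", or "huber" with scale ``delta``.
    """

    f: str = "square"
    delta: float = 1.0
    nonlinearity: NonlinearitySpec = field(default_factory=_surrogate)

    def __post_init__(self) -> None:
        if self.f not in ("square", "abs", "huber"):
            raise ValueError(f"unknown loss kind {self.f!r}")
        if self.f == "huber" and self.delta <= 0:
            raise ValueError("huber delta must be positive")

    def f_value(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.f == "square":
            return s ** 2
        if self.f == "abs":
            return np.abs(s)
        a = np.abs(s)
        return np.where(a <= self.delta, 0.5 * s ** 2,
                        self.delta * (a - 0.5 * self.delta))

    def f_prime(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.f == "square":
            return 2.0 * s
        if self.f == "abs":
            return np.sign(s)
        return np.clip(s, -self.delta, self.delta)


def loss(W: np.ndarray, S: np.ndarray, spec: Optional[LossSpec] = None) -> float:
    """L(W, S) = Σ_{i,j} f(σ(w_iᵀ x_j)); nonnegative.

    For f = square this equals ‖σ(WᵀS)‖²_F (asserted in the test suite via an
    explicit Frobenius-norm route).
    """
    spec = spec or LossSpec()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if W.shape[0] != S.shape[0]:
        raise ValueError(
            f"weight dimension {W.shape[0]} != stimulus dimension {S.shape[0]}")
    return float(np.sum(spec.f_value(spec.nonlinearity.apply(W.T @ S))))


def grad(W: np.ndarray, S: np.ndarray, spec: Optional[LossSpec] = None) -> np.ndarray:
    """∇_W L: column i = Σ_j f′(σ(w_iᵀx_j))·σ′(w_iᵀx_j)·x_j.

    Requires a differentiable (surrogate) nonlinearity; requesting gradients
    of a Heaviside raises with a pointer to the surrogate.
    """
    spec = spec or LossSpec()
    if spec.nonlinearity.kind == "heaviside":
        raise ValueError(
            "gradients of a Heaviside nonlinearity are degenerate (σ' = 0 "
            "a.e.); configure the loss with kind='logistic_surrogate'")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if W.shape[0] != S.shape[0]:
        raise ValueError(
            f"weight dimension {W.shape[0]} != stimulus dimension {S.shape[0]}")
    T = W.T @ S                                   # (n_cells, R)
    coeff = spec.f_prime(spec.nonlinearity.apply(T)) * spec.nonlinearity.derivative(T)
    return S @ coeff.T                            # (d, n_cells)


# ---------------------------------------------------------------------------
# plain (unconstrained) training


@dataclass(frozen=True)
class TrainConfig:
    alpha: float = 0.1            # initial step length (normalized gradient)
    epochs: int = 50              # orbit-complete passes over the stimuli
    n_cells: Optional[int] = None  # default |G| (one cell per group element)
    seed: int = 0
    spec: LossSpec = field(default_factory=LossSpec)
    init: str = "gaussian"        # or "zero" to reproduce the w0 = 0 convention
    init_scale: float = 1e-2

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.init not in ("gaussian", "zero"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class TrainState:
    """Weights trajectory of a training run.

    ``t`` counts elementary (per-stimulus) updates; one full-batch epoch over
    R = Q·|G| stimuli advances t by R, so every logged checkpoint sits at
    t = k·|G|·Q as the equivariance theorem requires.
    """

    W: np.ndarray
    t: int
    alpha: float
    seed: int
    loss_trajectory: np.ndarray            # loss after each epoch (epoch 0 = init)
    checkpoints: list                       # W copies, one per epoch


def train(S: np.ndarray, config: TrainConfig,
          group_size: Optional[int] = None) -> TrainState:
    """Full-batch gradient ascent on L(W, S) in orbit-complete passes.

    The step is backtracking: the proposed normalized-gradient step is halved
    until the loss does not decrease, so the logged loss trajectory is
    nondecreasing by construction.  Deterministic given ``config.seed``.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    d, R = S.shape
    n_cells = config.n_cells or (group_size if group_size else d)
    rng = np.random.default_rng(config.seed)
    if config.init == "zero":
        W = np.zeros((d, n_cells))
    else:
        W = rng.standard_normal((d, n_cells)) * (config.init_scale / np.sqrt(d))

    cur = loss(W, S, config.spec)
    traj = [cur]
    checkpoints = [W.copy()]
    t = 0
    for epoch in range(1, config.epochs + 1):
        G = grad(W, S, config.spec)
        gn = np.linalg.norm(G)
        if gn > 1e-15:
            step = config.alpha
            for _ in range(60):
                W_try = W + step * G / gn
                new = loss(W_try, S, config.spec)
                if new >= cur:
                    W, cur = W_try, new
                    break
                step *= 0.5
        if not np.isfinite(cur):
            raise RuntimeError(f"training diverged at epoch {epoch}")
        t += R
        traj.append(cur)
        checkpoints.append(W.copy())
    return TrainState(W=W, t=t, alpha=config.alpha, seed=config.seed,
                      loss_trajectory=np.asarray(traj),
                      checkpoints=checkpoints)


# ---------------------------------------------------------------------------
# equivariance of the learning dynamics


@dataclass(frozen=True)
class EquivarianceReport:
    residual: float            # max over g, i of ‖grad(gW,S)_i − g·grad(W,S)_i‖₂
    orbit_complete: bool       # hypothesis of the theorem; False => warning
    per_element: np.ndarray    # residual per group element


def _is_orbit_complete(S: np.ndarray, group: FiniteOrthogonalGroup,
                       tol: float = 1e-8) -> bool:
    """Is S (as a set of columns) invariant under every group element?

    Checked by comparing lexicographically sorted columns of S and gS.
    """
    if S.shape[1] % group.N != 0:
        return False
    key = np.lexsort(np.round(S / tol).astype(np.int64))
    S_sorted = S[:, key]
    for g in group.elements:
        gS = g @ S
        key_g = np.lexsort(np.round(gS / tol).astype(np.int64))
        if not np.allclose(gS[:, key_g], S_sorted, atol=10 * tol):
            return False
    return True


def gradient_equivariance_residual(
    W: np.ndarray,
    S: np.ndarray,
    group: FiniteOrthogonalGroup,
    spec: Optional[LossSpec] = None,
    check_orbit_complete: bool = True,
) -> EquivarianceReport:
    """Numerical check of the solution-space equivariance identity.

    On a stimulus set that is a union of complete orbits, transforming the
    weights by g merely reindexes the stimuli in the gradient sum, so
    ∇L(gW, S) = g·∇L(W, S) exactly; the report carries the worst residual over
    group elements and cells.  If S is not orbit-complete the theorem's
    hypothesis fails and the report flags it (the residual is still returned —
    it is the quantity that grows as orbits are truncated).
    """
    spec = spec or LossSpec()
    W = np.atleast_2d(np.asarray(W, dtype=float))
    S = np.atleast_2d(np.asarray(S, dtype=float))
    base = grad(W, S, spec)
    per_el = np.empty(group.N)
    for k, g in enumerate(group.elements):
        lhs = grad(g @ W, S, spec)
        rhs = g @ base
        per_el[k] = np.linalg.norm(lhs - rhs, axis=0).max()
    complete = _is_orbit_complete(S, group) if check_orbit_complete else True
    return EquivarianceReport(residual=float(per_el.max()),
                              orbit_complete=complete, per_element=per_el)


# ---------------------------------------------------------------------------
# orthogonality-constrained maximization


@dataclass(frozen=True)
class StiefelConfig:
    beta: float = 10.0            # surrogate steepness
    z: float = 0.0                # surrogate threshold
    alpha: float = 0.5            # initial step length (normalized gradient)
    iters: int = 300
    restarts: int = 3             # random restarts; the best objective wins
    seed: int = 0
    f: str = "square"


@dataclass
class StiefelResult:
    U: np.ndarray
    objective: float
    trace: np.ndarray                # objective per accepted iterate
    orthonormality_residual: float   # ‖UᵀU − I‖_max at the solution


def constrained_maximize(
    S: np.ndarray,
    S_new: Optional[np.ndarray],
    lam: float,
    n_cells: int,
    config: Optional[StiefelConfig] = None,
) -> StiefelResult:
    """Maximize ‖σ(UᵀS)‖²_F + λ‖σ(UᵀS_new)‖²_F subject to UᵀU = I.

    Projected gradient ascent: the normalized Euclidean gradient step is
    retracted onto the orthonormal frame by a sign-fixed thin QR
    decomposition, and the step is halved until the objective does not
    decrease, so the objective trace is nondecreasing.  Several random
    orthonormal initializations are run and the best objective kept
    (the landscape has many local maxima).

    Requires n_cells <= d: no orthonormal frame with more columns than rows
    exists.
    """
    config = config or StiefelConfig()
    S = np.atleast_2d(np.asarray(S, dtype=float))
    d = S.shape[0]
    if n_cells > d:
        raise ValueError(
            f"n_cells={n_cells} exceeds dimension d={d}: UᵀU = I is infeasible")
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    spec = LossSpec(f=config.f, nonlinearity=NonlinearitySpec(
        kind="logistic_surrogate", threshold=config.z, steepness=config.beta))
    terms = [(S, 1.0)]
    if S_new is not None and lam > 0:
        S_new = np.atleast_2d(np.asarray(S_new, dtype=float))
        terms.append((S_new, lam))

    def objective_grad(U):
        o, G = 0.0, np.zeros_like(U)
        for M, wgt in terms:
            o += wgt * loss(U, M, spec)
            G += wgt * grad(U, M, spec)
        return o, G

    rng = np.random.default_rng(config.seed)
    best: Optional[StiefelResult] = None
    for _ in range(max(1, config.restarts)):
        U, _ = np.linalg.qr(rng.standard_normal((d, n_cells)))
        obj, G = objective_grad(U)
        trace = [obj]
        for _ in range(config.iters):
            gn = np.linalg.norm(G)
            if gn < 1e-13:
                break
            step, accepted = config.alpha, False
            for _ in range(50):
                V, Rm = np.linalg.qr(U + step * G / gn)
                V = V * np.sign(np.diag(Rm))       # deterministic QR branch
                o2, G2 = objective_grad(V)
                if o2 > obj + 1e-15:
                    U, obj, G = V, o2, G2
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            trace.append(obj)
        res = StiefelResult(
            U=U, objective=obj, trace=np.asarray(trace),
            orthonormality_residual=float(
                np.abs(U.T @ U - np.eye(n_cells)).max()))
        if best is None or res.objective > best.objective:
            best = res
    return best
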