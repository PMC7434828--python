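"""Simple cells, complex cells, and threshold-indexed signatures.

A simple cell computes σ(wᵀx); a complex cell sums the simple-cell outputs of
a bank of N cells.  With a Heaviside nonlinearity H(·−z) the complex-cell
output at threshold z counts the simple-cell responses exceeding z, i.e. it is
N·(1 − empirical CDF) of the response set evaluated at z.  Sweeping z over a
grid therefore yields a signature that encodes the response multiset — the
object whose permutation invariance underlies the invariance and selectivity
results implemented in :mod:`orbipool.metrics`.

Boundary convention: H(0) = 1 (a response exactly at threshold counts).  Ties
are measure-zero for randomly drawn thresholds; the closed-at-zero convention
makes a threshold below the minimum response yield the full count.

The logistic surrogate σ(t) = 1/(1+exp(−β(t−z))) exists only to give the
learning rules a usable derivative; all signature and selectivity evaluation
uses the exact Heaviside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NonlinearitySpec",
    "SimpleCellBank",
    "ThresholdGrid",
    "ComplexCellSignature",
    "heaviside",
    "simple_response",
    "complex_response",
    "signature",
    "signature_counts",
    "response_range",
    "orbit_bank",
    "big_negative_threshold",
]


def heaviside(t: np.ndarray) -> np.ndarray:
    """H(t) with the closed-at-zero convention H(0) = 1."""
    return (np.asarray(t) >= 0).astype(float)


@dataclass(frozen=True)
class NonlinearitySpec:
    """Pointwise nonlinearity σ applied to the membrane drive wᵀx.

    kind="heaviside":          σ(t) = H(t − threshold)
    kind="logistic_surrogate": σ(t) = 1 / (1 + exp(−steepness·(t − threshold)))
    """

    kind: str = "heaviside"
    threshold: float = 0.0
    steepness: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("heaviside", "logistic_surrogate"):
            raise ValueError(f"unknown nonlinearity kind {self.kind!r}")
        if self.kind == "logistic_surrogate" and self.steepness <= 0:
            raise ValueError("steepness must be positive")

    def apply(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "heaviside":
            return heaviside(t - self.threshold)
        from scipy.special import expit   # overflow-safe logistic

        return expit(self.steepness * (t - self.threshold))

    def derivative(self, t: np.ndarray) -> np.ndarray:
        """σ′(t).  Undefined (degenerate) for the Heaviside."""
        if self.kind == "heaviside":
            raise ValueError(
                "the Heaviside has no usable derivative; use "
                "kind='logistic_surrogate' for gradient computations")
        s = self.apply(t)
        return self.steepness * s * (1.0 - s)


@dataclass(frozen=True)
class SimpleCellBank:
    """Weight matrix W (d × n_cells, column i = w_i) plus a nonlinearity."""

    W: np.ndarray
    nonlinearity: NonlinearitySpec = field(default_factory=NonlinearitySpec)

    def __post_init__(self) -> None:
        W = np.atleast_2d(np.asarray(self.W, dtype=float))
        if W.size == 0 or not np.all(np.isfinite(W)):
            raise ValueError("W must be a nonempty finite matrix")
        object.__setattr__(self, "W", W)

    @property
    def d(self) -> int:
        return self.W.shape[0]

    @property
    def n_cells(self) -> int:
        return self.W.shape[1]


def orbit_bank(group, w: np.ndarray,
               nonlinearity: Optional[NonlinearitySpec] = None) -> SimpleCellBank:
    """Bank whose weights are the full group orbit of a template w."""
    from .groups import orbit as _orbit
    W = _orbit(group, np.asarray(w, dtype=float))
    return SimpleCellBank(W, nonlinearity or NonlinearitySpec())


@dataclass(frozen=True)
class ThresholdGrid:
    """Strictly increasing threshold values z_1 < ... < z_K."""

    thresholds: np.ndarray
    mode: str = "custom"
    rng_seed: Optional[int] = None

    def __post_init__(self) -> None:
        z = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        if z.size == 0:
            raise ValueError("threshold grid must be nonempty")
        if z.size > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "thresholds", z)

    @property
    def K(self) -> int:
        return self.thresholds.size

    @classmethod
    def uniform_random(cls, lo: float, hi: float, K: int,
                       rng_seed: int) -> "ThresholdGrid":
        """K thresholds sampled uniformly at random in [lo, hi], sorted.

        Duplicate draws (probability zero) are jittered apart to keep the
        strictly-increasing invariant.
        """
        if K < 1:
            raise ValueError("K must be >= 1")
        rng = np.random.default_rng(rng_seed)
        z = np.sort(rng.uniform(lo, hi, size=K))
        eps = 1e-12 * max(1.0, abs(hi - lo))
        for i in range(1, K):
            if z[i] <= z[i - 1]:
                z[i] = z[i - 1] + eps
        return cls(z, mode="uniform_random_in_range", rng_seed=rng_seed)


@dataclass(frozen=True)
class ComplexCellSignature:
    """Values c_z over a threshold grid; entry k counts responses ≥ z_k."""

    values: np.ndarray
    grid: ThresholdGrid

    def __post_init__(self) -> None:
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float))


# ---------------------------------------------------------------------------
# responses


def _check_dim(bank: SimpleCellBank, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape[0] != bank.d:
        raise ValueError(f"stimulus dimension {x.shape[0]} != bank dimension {bank.d}")
    return x


def simple_response(bank: SimpleCellBank, x: np.ndarray) -> np.ndarray:
    """Vector of simple-cell outputs σ(w_iᵀx), one entry per cell."""
    x = _check_dim(bank, x)
    return bank.nonlinearity.apply(bank.W.T @ x)


def complex_response(bank: SimpleCellBank, x: np.ndarray) -> float:
    """Complex-cell output: the sum of the bank's simple-cell responses."""
    return float(np.sum(simple_response(bank, x)))


def signature_counts(W: np.ndarray, X: np.ndarray,
                     thresholds: np.ndarray) -> np.ndarray:
    """Threshold-count matrix: entry (k, j) = #{i : w_iᵀx_j ≥ z_k}.

    Vectorized core shared by :func:`signature` and the distance metrics.
    ``X`` may be a single column or a stimulus matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != W.shape[0]:
        X = X.T  # tolerate a 1-D stimulus passed as a row
    R = W.T @ X                                     # (n_cells, n_stimuli)
    z = np.asarray(thresholds, dtype=float)
    return (R[None, :, :] >= z[:, None, None]).sum(axis=1).astype(float)


def signature(bank: SimpleCellBank, x: np.ndarray,
              grid: ThresholdGrid) -> ComplexCellSignature:
    """Threshold-indexed complex-cell signature of a single stimulus.

    values[k] = Σ_i H(w_iᵀx − z_k) — the number of simple-cell drives at or
    above z_k; equivalently n_cells·(1 − empirical CDF) at z_k under the
    closed-at-zero tie convention.  The grid's thresholds override any
    threshold stored in the bank's nonlinearity.
    """
    x = _check_dim(bank, x)
    vals = signature_counts(bank.W, x[:, None], grid.thresholds)[:, 0]
    return ComplexCellSignature(vals, grid)


def response_range(bank: SimpleCellBank, S: np.ndarray) -> tuple[float, float]:
    """(min, max) of the raw drives w_iᵀx_j over all cells i and stimuli j."""
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if S.size == 0:
        raise ValueError("stimulus set is empty")
    if S.shape[0] != bank.d:
        raise ValueError(f"stimulus dimension {S.shape[0]} != bank dimension {bank.d}")
    R = bank.W.T @ S
    return float(R.min()), float(R.max())


def big_negative_threshold(bank: SimpleCellBank, S: np.ndarray) -> float:
    """A threshold below every training drive: z = −(1 + max|w_iᵀx_j|).

    With this threshold every training activation passes the Heaviside, which
    is the 'use the full range of activations' convention for the loss.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    return -(1.0 + float(np.abs(bank.W.T @ S).max()))
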