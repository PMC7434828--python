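"""Finite orthogonal groups acting on stimulus space.

A nuisance group here is a finite set of orthogonal matrices closed under
multiplication, containing the identity, and closed under transposition
(g⁻¹ = gᵀ).  Four concrete families are provided:

* cyclic shift permutations of the coordinates of R^d,
* dihedral permutations (rotations and reflections of a labelled n-cycle),
* planar rotations by multiples of 2π/N acting on R²,
* exact rotations of a disk-shaped image patch represented on a polar grid.

Raster rotation of a square pixel patch requires interpolation and is not
orthogonal; the polar-grid representation (concentric rings, a fixed number of
angular sectors, one centre pixel) makes every patch rotation an exact pixel
permutation, so the orthogonal-group assumptions of the theory hold literally.

Element ordering is deterministic: element 0 is always the identity, cyclic and
rotation elements come in increasing shift/angle order, dihedral rotations
precede reflections.  Deterministic ordering makes orbit witnesses reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "FiniteOrthogonalGroup",
    "GroupAxiomReport",
    "SameOrbitResult",
    "make_cyclic_permutation_group",
    "make_dihedral_permutation_group",
    "make_planar_rotation_group",
    "make_patch_rotation_group",
    "patch_dim",
    "verify_group_axioms",
    "orbit",
    "same_orbit",
]

#: orthogonality / identity tolerance used by the constructors' self-check
_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class FiniteOrthogonalGroup:
    """An ordered set of N orthogonal d×d matrices forming a group.

    Parameters
    ----------
    elements
        Array of shape ``(N, d, d)``; ``elements[0]`` is the identity.
    kind
        One of ``cyclic_perm``, ``dihedral_perm``, ``planar_rotation``,
        ``patch_rotation``, ``custom``.
    meta
        Constructor parameters (e.g. patch radius), for serialization.
    """

    elements: np.ndarray
    kind: str = "custom"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        els = np.asarray(self.elements, dtype=float)
        if els.ndim != 3 or els.shape[1] != els.shape[2]:
            raise ValueError("elements must have shape (N, d, d)")
        object.__setattr__(self, "elements", els)

    @property
    def d(self) -> int:
        return self.elements.shape[1]

    @property
    def N(self) -> int:
        return self.elements.shape[0]

    def __len__(self) -> int:
        return self.N

    def __iter__(self):
        return iter(self.elements)

    def apply(self, i: int, x: np.ndarray) -> np.ndarray:
        """Action of element ``i`` on a vector (or stacked columns) ``x``."""
        return self.elements[i] @ x

    def compose_index(self, i: int, j: int, tol: float = 1e-8) -> int:
        """Index k with elements[k] = elements[i] @ elements[j]."""
        prod = self.elements[i] @ self.elements[j]
        return _match_element(self.elements, prod, tol)

    def inverse_index(self, i: int, tol: float = 1e-8) -> int:
        """Index of the inverse (= transpose) of element ``i``."""
        return _match_element(self.elements, self.elements[i].T, tol)


class GroupAxiomReport(NamedTuple):
    """Numerical group-axiom check: per-axiom pass flags and worst residuals."""

    closure: bool
    identity: bool
    inverse: bool
    associativity: bool
    orthogonality: bool
    closure_residual: float
    identity_residual: float
    inverse_residual: float
    associativity_residual: float
    orthogonality_residual: float

    @property
    def all_pass(self) -> bool:
        return (self.closure and self.identity and self.inverse
                and self.associativity and self.orthogonality)


class SameOrbitResult(NamedTuple):
    same: bool
    witness: int       # argmin over g of ‖x − g·y‖₂
    residual: float

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.same


# ---------------------------------------------------------------------------
# constructors


def _shift_matrix(d: int, s: int) -> np.ndarray:
    """Permutation matrix sending coordinate i to coordinate (i+s) mod d."""
    return np.roll(np.eye(d), s, axis=0)


def make_cyclic_permutation_group(d: int) -> FiniteOrthogonalGroup:
    """Cyclic group of the d coordinate shifts of R^d (order d, abelian)."""
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    els = np.stack([_shift_matrix(d, s) for s in range(d)])
    return FiniteOrthogonalGroup(els, kind="cyclic_perm", meta={"d": d})


def make_dihedral_permutation_group(n: int) -> FiniteOrthogonalGroup:
    """Dihedral group D_n acting by permutation on the n vertices of a cycle.

    2n elements: the n index rotations (identity first) followed by the n
    reflections.  Non-abelian for n >= 3.
    """
    if n < 3:
        raise ValueError(f"n must be >= 3 for a dihedral group, got {n}")
    reflect = np.eye(n)[:, ::-1]      # i -> n-1-i
    rotations = [_shift_matrix(n, s) for s in range(n)]
    reflections = [r @ reflect for r in rotations]
    return FiniteOrthogonalGroup(np.stack(rotations + reflections),
                                 kind="dihedral_perm", meta={"n": n})


def make_planar_rotation_group(N: int) -> FiniteOrthogonalGroup:
    """The finite group of N rotations of the plane, angles θ_i = i·2π/N.

    Matrix convention: first row (cos θ, sin θ), second row (−sin θ, cos θ).
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    els = []
    for i in range(N):
        th = 2.0 * np.pi * i / N
        c, s = np.cos(th), np.sin(th)
        els.append(np.array([[c, s], [-s, c]]))
    return FiniteOrthogonalGroup(np.stack(els), kind="planar_rotation",
                                 meta={"N": N})


def patch_dim(radius: int, n_angles: int) -> int:
    """Length of the pixel vector of a polar-grid patch: rings×sectors + centre."""
    return radius * n_angles + 1


def make_patch_rotation_group(radius: int, N: int) -> FiniteOrthogonalGroup:
    """Exact rotations of a disk patch on a polar grid with N angular sectors.

    The patch pixel vector is laid out as ``[centre, ring0 sector0..N-1,
    ring1 sector0..N-1, ...]`` with ``radius`` rings.  Element i rotates the
    patch by i·2π/N by cycling the sector index of every ring; the centre pixel
    is fixed.  Each element is a permutation matrix, hence exactly orthogonal.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    d = patch_dim(radius, N)
    els = np.zeros((N, d, d))
    for i in range(N):
        els[i, 0, 0] = 1.0
        for r in range(radius):
            base = 1 + r * N
            for a in range(N):
                els[i, base + (a + i) % N, base + a] = 1.0
    return FiniteOrthogonalGroup(els, kind="patch_rotation",
                                 meta={"radius": radius, "N": N})


# ---------------------------------------------------------------------------
# axiom verification and orbits


def _match_element(elements: np.ndarray, M: np.ndarray, tol: float) -> int:
    """Index of the element matching M within max-abs tol, or -1."""
    res = np.abs(elements - M[None]).max(axis=(1, 2))
    k = int(res.argmin())
    return k if res[k] <= tol else -1


def verify_group_axioms(
    group: FiniteOrthogonalGroup,
    tol: float = 1e-8,
    max_triples: int = 1000,
    rng_seed: int = 0,
) -> GroupAxiomReport:
    """Numerically check closure, identity, inverse, associativity, orthogonality.

    Associativity of matrix multiplication is exact in exact arithmetic but not
    in floats; it is checked on all triples for N <= 16 and on ``max_triples``
    random triples otherwise (the check is O(N³)).
    """
    els = group.elements
    N, d = group.N, group.d
    if N == 0:
        raise ValueError("group is empty")

    ortho_res = max(np.abs(M.T @ M - np.eye(d)).max() for M in els)

    id_res = np.abs(els - np.eye(d)[None]).max(axis=(1, 2)).min()

    closure_res = 0.0
    for i in range(N):
        prods = els[i] @ els                         # (N, d, d)
        for j in range(N):
            r = np.abs(els - prods[j][None]).max(axis=(1, 2)).min()
            closure_res = max(closure_res, r)

    inverse_res = 0.0
    for M in els:
        r = np.abs(els - M.T[None]).max(axis=(1, 2)).min()
        inverse_res = max(inverse_res, r)

    if N <= 16:
        triples = itertools.product(range(N), repeat=3)
    else:
        rng = np.random.default_rng(rng_seed)
        triples = rng.integers(0, N, size=(max_triples, 3))
    assoc_res = 0.0
    for i, j, k in triples:
        lhs = (els[i] @ els[j]) @ els[k]
        rhs = els[i] @ (els[j] @ els[k])
        assoc_res = max(assoc_res, float(np.abs(lhs - rhs).max()))

    return GroupAxiomReport(
        closure=closure_res <= tol,
        identity=id_res <= tol,
        inverse=inverse_res <= tol,
        associativity=assoc_res <= tol,
        orthogonality=ortho_res <= tol,
        closure_residual=float(closure_res),
        identity_residual=float(id_res),
        inverse_residual=float(inverse_res),
        associativity_residual=float(assoc_res),
        orthogonality_residual=float(ortho_res),
    )


def orbit(group: FiniteOrthogonalGroup, x: np.ndarray) -> np.ndarray:
    """All transformations of ``x``: matrix of shape (d, N), column i = gᵢ·x."""
    x = np.asarray(x, dtype=float)
    if x.shape != (group.d,):
        raise ValueError(f"x has shape {x.shape}, expected ({group.d},)")
    return np.einsum("nij,j->in", group.elements, x)


def same_orbit(
    group: FiniteOrthogonalGroup,
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
) -> SameOrbitResult:
    """Are x and y equivalent under the group (x = g·y for some g)?

    Returns the minimizing element index as witness and the achieved residual
    ``min_g ‖x − g·y‖₂``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != (group.d,) or y.shape != (group.d,):
        raise ValueError("x and y must both have length equal to group.d")
    diffs = orbit(group, y) - x[:, None]
    norms = np.linalg.norm(diffs, axis=0)
    k = int(norms.argmin())
    return SameOrbitResult(bool(norms[k] <= tol), k, float(norms[k]))
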