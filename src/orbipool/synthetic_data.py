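"""Orbit-structured synthetic stimulus sets.

The study conditions assume the stimulus set is a union of complete group
orbits of Q distinct base points.  Base points for the toy experiments are
drawn uniformly from the unit ℓ₂-ball of R^d; the natural-image experiment is
replaced by a synthetic stand-in: smoothed Gaussian random fields on a polar
grid ("patches"), rotated by the exact patch-rotation group or, optionally, by
interpolated rotation of an angularly oversampled field.

The interpolated mode exists because rotating a rasterized image patch is not
an exact orthogonal map — rotation of sampled data requires interpolation.  In
that mode the model's permutation group describes the stimulus transformation
only approximately, which is precisely the regime of rotated natural patches.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .groups import FiniteOrthogonalGroup, make_patch_rotation_group, same_orbit

__all__ = [
    "OrbitDataset",
    "sample_base_points",
    "build_orbit_dataset",
    "sample_orbit_dataset",
    "make_toy_patches",
    "subsample_orbits",
]


@dataclass(frozen=True)
class OrbitDataset:
    """Stimulus matrix S whose columns are group transformations of base points.

    Columns are grouped per orbit, ordered by group element index within each
    orbit.  ``complete`` is False after orbit subsampling, in which case the
    Q·N column-count invariant is deliberately relaxed.
    """

    group: FiniteOrthogonalGroup
    base_points: np.ndarray            # (d, Q)
    stimuli: np.ndarray                # (d, n_columns)
    orbit_labels: np.ndarray           # (n_columns,) in [0, Q)
    element_indices: np.ndarray        # (n_columns,) group element per column
    rng_seed: Optional[int] = None
    complete: bool = True

    @property
    def Q(self) -> int:
        return self.base_points.shape[1]

    @property
    def d(self) -> int:
        return self.stimuli.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.stimuli.shape[1]

    def orbit_columns(self, q: int) -> np.ndarray:
        """Stimulus columns belonging to orbit q."""
        return self.stimuli[:, self.orbit_labels == q]


def sample_base_points(Q: int, d: int, rng_seed: int) -> np.ndarray:
    """Q i.i.d. points uniform in the closed unit ℓ₂-ball of R^d, as columns.

    A Gaussian direction scaled by U^(1/d) is exactly uniform in the ball:
    the radial CDF of the uniform ball measure is r^d.
    """
    if Q < 1 or d < 1:
        raise ValueError(f"Q and d must be positive, got Q={Q}, d={d}")
    rng = np.random.default_rng(rng_seed)
    g = rng.standard_normal((d, Q))
    g /= np.linalg.norm(g, axis=0)
    r = rng.uniform(size=Q) ** (1.0 / d)
    return g * r


def build_orbit_dataset(
    group: FiniteOrthogonalGroup,
    base_points: np.ndarray,
    rng_seed: Optional[int] = None,
) -> OrbitDataset:
    """Expand base points into their full group orbits.

    The stimulus matrix has Q·N columns; orbit q occupies the contiguous block
    ``[q·N, (q+1)·N)`` with columns in group-element order.
    """
    base_points = np.atleast_2d(np.asarray(base_points, dtype=float))
    if base_points.shape[0] != group.d:
        raise ValueError(
            f"base points have dimension {base_points.shape[0]}, "
            f"group acts on R^{group.d}")
    Q, N = base_points.shape[1], group.N
    # (N, d, d) @ (d, Q) -> (N, d, Q); reorder to orbit-blocks of N columns
    transformed = np.einsum("nij,jq->inq", group.elements, base_points)
    stimuli = transformed.transpose(0, 2, 1).reshape(group.d, Q * N)
    labels = np.repeat(np.arange(Q), N)
    el_idx = np.tile(np.arange(N), Q)
    return OrbitDataset(group, base_points, stimuli, labels, el_idx,
                        rng_seed=rng_seed, complete=True)


def sample_orbit_dataset(
    group: FiniteOrthogonalGroup,
    Q: int,
    rng_seed: int,
    distinct_tol: float = 1e-6,
    max_resample: int = 100,
) -> OrbitDataset:
    """Sample Q unit-ball base points and expand into full orbits.

    Base points falling in the same orbit (probability zero for continuous
    draws, but guarded anyway) are resampled so the Q orbits are distinct.
    """
    pts = sample_base_points(Q, group.d, rng_seed)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    for _ in range(max_resample):
        dup = _first_orbit_duplicate(group, pts, distinct_tol)
        if dup is None:
            break
        g = rng.standard_normal(group.d)
        g /= np.linalg.norm(g)
        pts[:, dup] = g * rng.uniform() ** (1.0 / group.d)
    return build_orbit_dataset(group, pts, rng_seed=rng_seed)


def _first_orbit_duplicate(group, pts, tol):
    Q = pts.shape[1]
    for i in range(Q):
        for j in range(i + 1, Q):
            if same_orbit(group, pts[:, i], pts[:, j], tol).same:
                return j
    return None


# ---------------------------------------------------------------------------
# synthetic patches


def _fine_patch_field(radius, n_fine, smoothness, rng):
    """Smoothed Gaussian random field on an oversampled polar grid.

    ``smoothness`` is the Gaussian correlation length in pixels: rings are one
    pixel apart radially, and a fine angular bin spans 2π·radius/n_fine pixels
    at the outer ring, so the angular sigma is smoothness·n_fine/(2π·radius)
    bins.  The field wraps in angle.
    """
    f = rng.standard_normal((radius, n_fine))
    if smoothness > 0:
        sig_ang = smoothness * n_fine / (2.0 * np.pi * radius)
        f = gaussian_filter(f, sigma=(smoothness, sig_ang),
                            mode=("nearest", "wrap"))
    centre = float(rng.standard_normal())
    return centre, f


def _interp_circular(f: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of each ring of f at fractional angular positions."""
    n = f.shape[1]
    lo = np.floor(pos).astype(int)
    frac = pos - lo
    return (1.0 - frac) * f[:, lo % n] + frac * f[:, (lo + 1) % n]


def _readout(centre, f, n_angles, shift_bins, samples_per_sector=8):
    """Coarse polar readout of the fine field rotated by ``shift_bins``.

    Rotation mimics rasterized image rotation: the rotated field is first
    resampled onto the fine integer grid by circular linear interpolation
    (for non-integer shifts this loses information, exactly as resampling a
    rotated image onto the pixel grid does), and each coarse sector then
    averages ``samples_per_sector`` samples of the resampled field.  Integer
    shifts — in particular shift 0 — are exact.
    """
    radius, n_fine = f.shape
    if shift_bins != int(shift_bins):
        f = _interp_circular(f, np.arange(n_fine) - shift_bins)
        shift_bins = 0.0
    m = samples_per_sector
    offs = (np.arange(m) + 0.5) / m
    vals = np.empty((radius, n_angles))
    for a in range(n_angles):
        pos = (a + offs) * n_fine / n_angles - shift_bins
        vals[:, a] = _interp_circular(f, pos).mean(axis=1)
    return np.concatenate(([centre], vals.ravel()))


def make_toy_patches(
    Q: int,
    radius: int = 10,
    n_angles: int = 6,
    smoothness: float = 2.0,
    rng_seed: int = 0,
    rotation: str = "exact",
    angular_oversample: int = 64,
    normalize: bool = True,
) -> OrbitDataset:
    """Synthetic disk-patch orbits under the N-fold patch-rotation group.

    Base patches are ring-wise smoothed Gaussian random fields on the polar
    grid, a stand-in for natural-image patches with spatial correlation length
    ``smoothness`` (pixels).  ``smoothness`` → 0 gives i.i.d. pixel noise.

    rotation="exact"
        The base readout is transported by the exact permutation group:
        stimuli are exact orbits and every invariance theorem applies exactly.
    rotation="interpolated"
        Each of the N rotated views is read out from the oversampled field
        (``angular_oversample`` fine bins, default 64 ≈ the pixel resolution
        of the outer ring of a radius-10 patch) after a linearly interpolated
        circular shift; stimuli are then only approximately orbits.
    """
    if Q < 1 or radius < 1 or n_angles < 1:
        raise ValueError("Q, radius and n_angles must be positive")
    if smoothness < 0:
        raise ValueError("smoothness must be nonnegative")
    if rotation not in ("exact", "interpolated"):
        raise ValueError(f"unknown rotation mode {rotation!r}")
    if angular_oversample < n_angles:
        raise ValueError("angular_oversample must be >= n_angles")

    group = make_patch_rotation_group(radius, n_angles)
    rng = np.random.default_rng(rng_seed)
    bases, blocks = [], []
    for _ in range(Q):
        centre, f = _fine_patch_field(radius, angular_oversample, smoothness, rng)
        base = _readout(centre, f, n_angles, 0.0)
        scale = np.linalg.norm(base) if normalize else 1.0
        if scale == 0:
            scale = 1.0
        base = base / scale
        if rotation == "exact":
            cols = np.einsum("nij,j->in", group.elements, base)
        else:
            cols = np.stack(
                [_readout(centre, f, n_angles, i * angular_oversample / n_angles)
                 for i in range(n_angles)], axis=1) / scale
        bases.append(base)
        blocks.append(cols)

    stimuli = np.concatenate(blocks, axis=1)
    labels = np.repeat(np.arange(Q), n_angles)
    el_idx = np.tile(np.arange(n_angles), Q)
    return OrbitDataset(group, np.stack(bases, axis=1), stimuli, labels,
                        el_idx, rng_seed=rng_seed,
                        complete=(rotation == "exact"))


def subsample_orbits(
    dataset: OrbitDataset,
    fraction: float,
    rng_seed: int,
) -> OrbitDataset:
    """Keep ceil(fraction·N) columns per orbit, sampled without replacement.

    Models the realistic regime where the complete set of orbit views is not
    observed.  The resulting dataset is flagged ``complete=False`` (unless
    fraction == 1, which returns an identical dataset).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return replace(dataset, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed)
    keep_cols = []
    for q in range(dataset.Q):
        cols = np.flatnonzero(dataset.orbit_labels == q)
        k = int(np.ceil(fraction * len(cols)))
        chosen = rng.choice(cols, size=k, replace=False)
        keep_cols.append(np.sort(chosen))
    keep = np.concatenate(keep_cols)
    return OrbitDataset(
        dataset.group,
        dataset.base_points,
        dataset.stimuli[:, keep],
        dataset.orbit_labels[keep],
        dataset.element_indices[keep],
        rng_seed=rng_seed,
        complete=False,
    )
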