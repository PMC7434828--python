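"""Invariance and selectivity metrics for threshold-CDF signatures.

The complex-cell signature of a stimulus is the vector of threshold counts
c_z(x) = Σ_i H(xᵀw_i − z) over a grid of thresholds z.  Distances between
signatures are the working definition of the code distance: zero between
stimuli in the same orbit (invariance) and, with enough thresholds, nonzero
between stimuli of different orbits (selectivity).

The full midpoint grid realizes, at finite resolution, the continuous-
threshold result: signatures on that grid determine the response multisets
exactly, so distance zero is equivalent to the sorted response vectors
coinciding — the empirical CDF of the responses is a maximal invariant of the
permutation action.

With a small number of randomly drawn thresholds, the mean per-threshold
signature difference concentrates around its continuous-range expectation;
Hoeffding's inequality bounds the deviation probability, and
:func:`hoeffding_bound` evaluates that bound with the standard range constant
p = (b − a)²/4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cells import (SimpleCellBank, ThresholdGrid, response_range,
                    signature_counts)
from .synthetic_data import OrbitDataset

__all__ = [
    "DistanceReport",
    "signature_distance",
    "full_threshold_grid",
    "distance_report",
    "cosine_similarity_curve",
    "hoeffding_bound",
    "expected_threshold_distance",
    "sampled_threshold_distance",
    "log_overlap_coefficient",
]

#: floor added to distances before taking log10 (intra distances are exactly 0)
LOG_FLOOR = 1e-12


def signature_distance(
    x: np.ndarray,
    y: np.ndarray,
    bank: SimpleCellBank,
    grid: ThresholdGrid,
    norm: str = "l1",
    collapsed: bool = False,
) -> float:
    """Distance between the signatures of x and y over a shared grid.

    norm="l1" is the experimental form Σ_z |c_z(x) − c_z(y)|; norm="l2" the
    Euclidean form of the selectivity lemma.  ``collapsed=True`` first sums
    the signature over thresholds and returns |Σ_z c_z(x) − Σ_z c_z(y)| (the
    scalar code used in the finite-threshold concentration argument); it
    discards per-threshold information and is strictly less selective.
    """
    if norm not in ("l1", "l2"):
        raise ValueError(f"norm must be 'l1' or 'l2', got {norm!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    counts = signature_counts(bank.W, np.column_stack([x, y]), grid.thresholds)
    diff = counts[:, 0] - counts[:, 1]
    if collapsed:
        return float(abs(diff.sum()))
    if norm == "l1":
        return float(np.abs(diff).sum())
    return float(np.linalg.norm(diff))


def full_threshold_grid(bank: SimpleCellBank, points: np.ndarray,
                        tol: float = 1e-9) -> ThresholdGrid:
    """Midpoints between consecutive distinct observed responses, plus flanks.

    On this grid the signature of any of ``points`` determines its response
    multiset exactly: between two consecutive distinct observed response
    values the count function is constant, so one threshold per gap (plus one
    below the minimum and one above the maximum) is sufficient for the
    maximal-invariant property to hold at finite K.

    Responses closer than ``tol`` are treated as the same value: dot products
    of permuted vectors agree only up to summation-order round-off, and a
    midpoint placed inside such a float-noise gap would spuriously separate
    stimuli that are exactly equivalent.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("points must be nonempty")
    resp = np.unique((bank.W.T @ points).ravel())
    if resp.size > 1 and tol > 0:
        keep = np.concatenate(([True], np.diff(resp) > tol))
        resp = resp[keep]
    if resp.size == 1:
        z = np.array([resp[0] - 1.0, resp[0] + 1.0])
    else:
        mids = 0.5 * (resp[:-1] + resp[1:])
        z = np.concatenate(([resp[0] - 1.0], mids, [resp[-1] + 1.0]))
        # distinct responses closer than float resolution can collapse their
        # midpoints; dedup keeps the grid strictly increasing
        z = np.unique(z)
    return ThresholdGrid(z, mode="full_grid_of_observed_responses")


@dataclass(frozen=True)
class DistanceReport:
    """Sampled intra-orbit and inter-orbit signature distances."""

    intra: np.ndarray
    inter: np.ndarray
    n_pairs: int
    rng_seed: int
    norm: str = "l1"
    log_floor: float = LOG_FLOOR

    def to_frame(self) -> pd.DataFrame:
        rows = [{"pair_id": i, "type": "intra", "distance": float(v)}
                for i, v in enumerate(self.intra)]
        rows += [{"pair_id": i, "type": "inter", "distance": float(v)}
                 for i, v in enumerate(self.inter)]
        return pd.DataFrame(rows, columns=["pair_id", "type", "distance"])

    def log_intra(self) -> np.ndarray:
        return np.log10(self.intra + self.log_floor)

    def log_inter(self) -> np.ndarray:
        return np.log10(self.inter + self.log_floor)

    def summary(self) -> dict:
        out = {
            "n_intra": int(self.intra.size),
            "n_inter": int(self.inter.size),
        }
        if self.intra.size and self.inter.size:
            out.update({
                "intra_median": float(np.median(self.intra)),
                "inter_median": float(np.median(self.inter)),
                "intra_max": float(self.intra.max()),
                "inter_min": float(self.inter.min()),
                "overlap": log_overlap_coefficient(self.intra, self.inter,
                                                   self.log_floor),
            })
        return out


def distance_report(
    dataset: OrbitDataset,
    bank: SimpleCellBank,
    grid: ThresholdGrid,
    n_pairs: int,
    rng_seed: int,
    norm: str = "l1",
) -> DistanceReport:
    """Sample n_pairs same-orbit and n_pairs cross-orbit signature distances.

    Same-orbit pairs are two distinct views of one orbit; cross-orbit pairs
    one view from each of two distinct orbits.  Deterministic given the seed.
    """
    if dataset.Q < 2:
        raise ValueError("dataset must contain at least 2 orbits")
    rng = np.random.default_rng(rng_seed)
    intra, inter = [], []
    for _ in range(n_pairs):
        q = int(rng.integers(dataset.Q))
        cols = np.flatnonzero(dataset.orbit_labels == q)
        i, j = rng.choice(cols, size=2, replace=False)
        intra.append(signature_distance(dataset.stimuli[:, i],
                                        dataset.stimuli[:, j],
                                        bank, grid, norm))
        q1, q2 = rng.choice(dataset.Q, size=2, replace=False)
        c1 = rng.choice(np.flatnonzero(dataset.orbit_labels == q1))
        c2 = rng.choice(np.flatnonzero(dataset.orbit_labels == q2))
        inter.append(signature_distance(dataset.stimuli[:, c1],
                                        dataset.stimuli[:, c2],
                                        bank, grid, norm))
    return DistanceReport(np.asarray(intra, dtype=float),
                          np.asarray(inter, dtype=float),
                          n_pairs=n_pairs, rng_seed=rng_seed, norm=norm)


def log_overlap_coefficient(
    intra: np.ndarray,
    inter: np.ndarray,
    floor: float = LOG_FLOOR,
    bins: int = 30,
) -> float:
    """Overlap coefficient of the log-distance histograms, in [0, 1].

    Shared equal-width bins on log10(distance + floor); the coefficient sums
    min(p_intra, p_inter) over bins.  0 means perfectly separated intra and
    inter distance distributions, 1 identical ones.
    """
    a = np.log10(np.asarray(intra, dtype=float) + floor)
    b = np.log10(np.asarray(inter, dtype=float) + floor)
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        return 1.0
    edges = np.linspace(lo, hi, bins + 1)
    pa, _ = np.histogram(a, bins=edges)
    pb, _ = np.histogram(b, bins=edges)
    return float(min(1.0, np.minimum(pa / pa.sum(), pb / pb.sum()).sum()))


def cosine_similarity_curve(
    x: np.ndarray,
    y: np.ndarray,
    bank: SimpleCellBank,
    K_list: Sequence[int],
    reps: int,
    rng_seed: int,
    response_bounds: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Mean cosine similarity between K-threshold signatures of x and y.

    For each K in the increasing ``K_list``, thresholds are drawn uniformly at
    random in the simple-cell response range — ``response_bounds`` if given
    (typically the range over a whole stimulus ensemble), otherwise the range
    of the bank on {x, y} — ``reps`` times; the
    cosine similarity of the two signatures is averaged over draws.  A draw
    where exactly one signature is all-zero (one stimulus silent, the other
    active) contributes similarity 0; a draw where both are zero carries no
    directional information and is recorded as missing.  At small K the
    silent/active events are common and pull the mean down, which is why the
    mean similarity grows with K before plateauing at its continuous-range
    value.  Returns a DataFrame with columns K, mean_cosine, n_valid.
    """
    K_list = list(K_list)
    if any(k2 <= k1 for k1, k2 in zip(K_list, K_list[1:])):
        raise ValueError("K_list must be strictly increasing")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pair = np.column_stack([x, y])
    lo, hi = response_bounds if response_bounds is not None \
        else response_range(bank, pair)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for K in K_list:
        sims = []
        for _ in range(reps):
            z = np.sort(rng.uniform(lo, hi, size=K))
            counts = signature_counts(bank.W, pair, z)
            na = np.linalg.norm(counts[:, 0])
            nb = np.linalg.norm(counts[:, 1])
            if na == 0 and nb == 0:
                sims.append(np.nan)
            elif na == 0 or nb == 0:
                sims.append(0.0)
            else:
                sims.append(float(counts[:, 0] @ counts[:, 1] / (na * nb)))
        sims = np.asarray(sims)
        rows.append({"K": K,
                     "mean_cosine": float(np.nanmean(sims))
                     if np.any(np.isfinite(sims)) else np.nan,
                     "n_valid": int(np.isfinite(sims).sum())})
    return pd.DataFrame(rows)


def similarity_trend(curve: pd.DataFrame) -> float:
    """Spearman rank correlation between K and the mean cosine similarity."""
    ok = curve.dropna(subset=["mean_cosine"])
    rho, _ = stats.spearmanr(ok["K"], ok["mean_cosine"])
    return float(rho)


# ---------------------------------------------------------------------------
# finite-threshold concentration


def hoeffding_bound(Q_thresholds: int, eps: float, range_width: float) -> float:
    """2·exp(−Q·ε² / (2p)) with the range constant p = range_width²/4.

    This is the standard Hoeffding deviation bound for the mean of Q i.i.d.
    summands supported on an interval of width ``range_width``: for the
    per-threshold signature difference of a bank of N cells the a-priori
    width is 2N.  Monotone decreasing in both Q and ε.
    """
    if Q_thresholds <= 0 or eps <= 0 or range_width <= 0:
        raise ValueError("Q_thresholds, eps and range_width must be positive")
    p = range_width ** 2 / 4.0
    return float(2.0 * np.exp(-Q_thresholds * eps ** 2 / (2.0 * p)))


def expected_threshold_distance(
    x: np.ndarray,
    y: np.ndarray,
    bank: SimpleCellBank,
    lo: float,
    hi: float,
    signed: bool = False,
) -> float:
    """E_z[c_z(x) − c_z(y)] for z ~ Uniform(lo, hi), in closed form.

    E_z H(r − z) = (clip(r, lo, hi) − lo)/(hi − lo), so the expectation is a
    sum of clipped response differences.  This is the continuous-range value
    that the sampled mean of :func:`sampled_threshold_distance` concentrates
    around.  Returns the absolute value unless ``signed``.
    """
    if hi <= lo:
        raise ValueError("need hi > lo")
    rx = np.clip(bank.W.T @ np.asarray(x, dtype=float), lo, hi)
    ry = np.clip(bank.W.T @ np.asarray(y, dtype=float), lo, hi)
    val = float((rx - ry).sum() / (hi - lo))
    return val if signed else abs(val)


def sampled_threshold_distance(
    x: np.ndarray,
    y: np.ndarray,
    bank: SimpleCellBank,
    lo: float,
    hi: float,
    Q_thresholds: int,
    rng: np.random.Generator,
    signed: bool = False,
) -> float:
    """Mean per-threshold signature difference over Q random thresholds."""
    z = rng.uniform(lo, hi, size=Q_thresholds)
    counts = signature_counts(bank.W, np.column_stack([x, y]), z)
    val = float((counts[:, 0] - counts[:, 1]).mean())
    return val if signed else abs(val)
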