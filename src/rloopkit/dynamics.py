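"""Stage-wise R-loop dynamics: region x stage matrices and fuzzy c-means.

Peaks from all stages are union-merged into a total region set; each
region's normalized (final-normalization-factor-scaled) mean coverage per
stage forms the matrix, whose rows are z-standardized before clustering.

Clustering uses standard (Bezdek) fuzzy c-means with Euclidean distance:

    v_k  = sum_i U_ik^m x_i / sum_i U_ik^m
    U_ik = 1 / sum_j (||x_i - v_k|| / ||x_i - v_j||)^(2/(m-1))

iterated from a seeded random membership matrix until the memberships
stabilize. The objective J = sum_ik U_ik^m ||x_i - v_k||^2 is non-increasing
across iterations; multiple restarts keep the lowest-objective solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Region, RegionSet, SignalTrack


@dataclass
class StageMatrix:
    regions: RegionSet
    stages: list[str]
    values: np.ndarray  # regions x stages
    standardized: bool = False
    n_dropped: int = 0  # zero-variance rows removed during standardization


def build_stage_matrix(
    tracks: dict[str, SignalTrack],
    peak_sets: dict[str, RegionSet],
    standardize: bool = True,
) -> StageMatrix:
    """Union-merge per-stage peaks and tabulate mean coverage per stage.

    Standardization is per-row (region) with population sd; zero-variance
    rows are dropped and counted.
    """
    stages = list(tracks)
    if len(stages) < 2:
        raise ValueError("need at least two stages")
    all_regions = RegionSet(
        [r for s in peak_sets for r in peak_sets[s]]
    )
    merged = all_regions.merge()
    if len(merged) == 0:
        raise ValueError("empty merged peak set")
    values = np.array([
        [tracks[s].values_over(r.chrom, r.start, r.end) for s in stages]
        for r in merged
    ])
    n_dropped = 0
    if standardize:
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)  # population sd
        keep = sd[:, 0] > 0
        n_dropped = int((~keep).sum())
        values = (values[keep] - mean[keep]) / sd[keep]
        merged = RegionSet([r for r, k in zip(merged, keep) if k], sorted_=True)
    return StageMatrix(merged, stages, values, standardized=standardize,
                       n_dropped=n_dropped)


def standardize_rows(values: np.ndarray) -> np.ndarray:
    """Row z-scores with population sd (rows must have nonzero variance)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance row")
    return (values - mean) / sd


@dataclass
class ClusterResult:
    c: int
    m: float
    centers: np.ndarray  # c x stages
    memberships: np.ndarray  # regions x c
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def hard_labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; exact-hit rows get 1/0."""
    zero = d2 < 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.maximum(d2, 1e-300) ** (-1.0 / (m - 1))
        U = inv / inv.sum(axis=1, keepdims=True)
    for i in np.flatnonzero(zero.any(axis=1)):
        U[i] = 0.0
        U[i, int(np.argmax(zero[i]))] = 1.0  # first coinciding center
    return U


def _fcm_once(X: np.ndarray, c: int, m: float, tol: float, max_iter: int, rng):
    # Random-membership init leaves every center at the data centroid — a
    # degenerate fixed point of the updates — so initialize centers at
    # distinct random data points and derive the first U from them.
    centers = X[rng.choice(X.shape[0], size=c, replace=False)]
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    U = _memberships_from_distances(d2, m)
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        trace.append(float((Um * d2).sum()))
        U_new = _memberships_from_distances(d2, m)
        delta = np.abs(U_new - U).max()
        U = U_new
        if delta < tol:
            break
    Um = U ** m
    centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    trace.append(float((Um * d2).sum()))
    return U, centers, trace, it


def fuzzy_cmeans(
    matrix: StageMatrix | np.ndarray,
    c: int = 6,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 5,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means on the (standardized) stage matrix.

    ``n_init`` random-membership restarts are run; the solution with the
    lowest final objective is kept. Deterministic for a fixed seed.
    """
    X = matrix.values if isinstance(matrix, StageMatrix) else np.asarray(matrix, float)
    if np.isnan(X).any():
        raise ValueError("NaN in input matrix")
    if c < 2 or m <= 1:
        raise ValueError("need c >= 2 and m > 1")
    if X.shape[0] < c:
        raise ValueError(f"fewer regions ({X.shape[0]}) than clusters ({c})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        U, centers, trace, it = _fcm_once(X, c, m, tol, max_iter, rng)
        if best is None or trace[-1] < best[2][-1]:
            best = (U, centers, trace, it)
    U, centers, trace, it = best
    return ClusterResult(c=c, m=m, centers=centers, memberships=U,
                         objective_trace=trace, n_iter=it)


def cluster_report(
    result: ClusterResult,
    matrix: StageMatrix | None = None,
    membership_threshold: float = 0.5,
) -> dict:
    """Per-cluster counts, center profiles, and high-membership core members."""
    labels = result.hard_labels
    counts = np.bincount(labels, minlength=result.c)
    core = [
        np.flatnonzero(
            (labels == k) & (result.memberships[:, k] >= membership_threshold)
        )
        for k in range(result.c)
    ]
    report = {
        "counts": counts,
        "centers": result.centers,
        "core_members": core,
        "core_counts": np.array([len(ix) for ix in core]),
    }
    if matrix is not None:
        report["cluster_regions"] = [
            RegionSet([matrix.regions[i] for i in np.flatnonzero(labels == k)])
            for k in range(result.c)
        ]
    return report
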