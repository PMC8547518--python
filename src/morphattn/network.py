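"""Individual-level morphological covariance brain networks.

For one subject, each brain region contributes a sample of gray-matter voxel
values. The regional probability density is estimated by Gaussian-kernel KDE
on a grid of N points shared by all regions of that subject. For regions P
and Q the symmetrised Kullback-Leibler divergence

    D(P, Q) = sum_i [ P(i) log(P(i)/Q(i)) + Q(i) log(Q(i)/P(i)) ]

is mapped to a similarity x_PQ = exp(-D(P, Q)) in (0, 1] (KLS). Collecting
x_PQ over all region pairs yields the subject's M x M morphological
covariance matrix X, symmetric with unit diagonal; its rows X_p are the
region feature vectors fed to the classifier.

Conventions (the cited construction leaves them open): the discrete densities
are the KDE values at the grid points floored at 1e-12 and renormalised to
sum to one, the divergence is a plain sum over the N points with natural
logarithms, and the evaluation grid spans all of the subject's samples
padded by three bandwidths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde

from .io import RegionalSampleSet

__all__ = [
    "DensityGrid",
    "MorphNetwork",
    "make_evaluation_grid",
    "estimate_density",
    "symmetric_kl",
    "kls_similarity",
    "build_network",
    "silverman_bandwidth",
]

DENSITY_FLOOR = 1e-12
#: fallback bandwidth for constant samples, as a fraction of the grid range
CONSTANT_BW_FRACTION = 1e-3


@dataclass
class DensityGrid:
    """A regional PDF discretised on shared evaluation points."""

    points: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.mass = np.asarray(self.mass, dtype=np.float64)
        if self.points.shape != self.mass.shape:
            raise ValueError("points and mass must have equal length")
        if np.any(np.diff(self.points) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("density mass must sum to 1")
        if np.any(self.mass <= 0):
            raise ValueError("density mass must be strictly positive")


@dataclass
class MorphNetwork:
    """The M x M KLS similarity matrix of one subject."""

    X: np.ndarray
    region_labels: list[int]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        M = len(self.region_labels)
        if self.X.shape != (M, M):
            raise ValueError(f"matrix shape {self.X.shape} != ({M}, {M})")
        if not np.array_equal(self.X, self.X.T):
            raise ValueError("network matrix must be exactly symmetric")
        if not np.all(np.diag(self.X) == 1.0):
            raise ValueError("network diagonal must be 1")
        if np.any(self.X <= 0) or np.any(self.X > 1.0):
            raise ValueError("network entries must lie in (0, 1]")

    @property
    def M(self) -> int:
        return len(self.region_labels)


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, as used by scipy's gaussian_kde.

    h = (3n/4)^(-1/5) * sd(samples, ddof=1); zero for constant samples
    (callers substitute the fallback).
    """
    samples = np.asarray(samples, dtype=np.float64)
    n = len(samples)
    sd = samples.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        return 0.0
    return float((n * 3.0 / 4.0) ** (-1.0 / 5.0) * sd)


def make_evaluation_grid(sampleset: RegionalSampleSet, n_points: int = 128) -> np.ndarray:
    """Equally spaced evaluation points shared by all regions of a subject.

    Spans [min - 3h, max + 3h] over all regional samples, where h is the
    largest per-region bandwidth, so every regional density has effectively
    full support on the grid.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if not sampleset.retained_labels:
        raise ValueError("empty sample set")
    all_min = min(float(sampleset.samples[l].min()) for l in sampleset.retained_labels)
    all_max = max(float(sampleset.samples[l].max()) for l in sampleset.retained_labels)
    h = max(silverman_bandwidth(sampleset.samples[l])
            for l in sampleset.retained_labels)
    if h == 0.0:
        if all_max == all_min:
            raise ValueError(
                "all regional samples are constant and equal: degenerate input")
        h = CONSTANT_BW_FRACTION * (all_max - all_min)
    return np.linspace(all_min - 3.0 * h, all_max + 3.0 * h, n_points)


def estimate_density(samples: np.ndarray, grid: np.ndarray) -> DensityGrid:
    """Gaussian-kernel KDE evaluated on the grid, floored and renormalised.

    Uses Silverman's rule; constant samples fall back to a narrow kernel of
    width CONSTANT_BW_FRACTION times the grid range. The returned mass is a
    discrete probability vector (sums to 1, strictly positive).
    """
    samples = np.asarray(samples, dtype=np.float64)
    grid = np.asarray(grid, dtype=np.float64)
    if samples.std(ddof=1) > 0:
        density = gaussian_kde(samples, bw_method="silverman")(grid)
    else:
        h = CONSTANT_BW_FRACTION * (grid[-1] - grid[0])
        z = (grid[None, :] - samples[:, None]) / h
        density = np.exp(-0.5 * z * z).mean(axis=0) / (h * np.sqrt(2 * np.pi))
    density = np.maximum(density, DENSITY_FLOOR)
    return DensityGrid(points=grid, mass=density / density.sum())


def symmetric_kl(P: DensityGrid, Q: DensityGrid) -> float:
    """Symmetrised KL divergence between two densities on the same grid."""
    if not np.array_equal(P.points, Q.points):
        raise ValueError("densities must share the same evaluation grid")
    p, q = P.mass, Q.mass
    log_ratio = np.log(p) - np.log(q)
    return float(np.sum(p * log_ratio - q * log_ratio))


def kls_similarity(P: DensityGrid, Q: DensityGrid) -> float:
    """KL-divergence-based similarity exp(-D(P, Q)), in (0, 1]."""
    return float(np.exp(-symmetric_kl(P, Q)))


def build_network(sampleset: RegionalSampleSet, n_points: int = 128) -> MorphNetwork:
    """Assemble a subject's full morphological covariance matrix.

    Densities are computed once per region on the shared grid; only the upper
    triangle of pairwise similarities is evaluated and mirrored, and the
    diagonal is set to 1 (a region is maximally similar to itself).
    """
    grid = make_evaluation_grid(sampleset, n_points=n_points)
    labels = sampleset.retained_labels
    densities = [estimate_density(sampleset.samples[l], grid) for l in labels]
    M = len(labels)
    X = np.eye(M)
    for i in range(M):
        for j in range(i + 1, M):
            X[i, j] = X[j, i] = kls_similarity(densities[i], densities[j])
    return MorphNetwork(X=X, region_labels=list(labels),
                        subject_id=sampleset.subject_id)
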