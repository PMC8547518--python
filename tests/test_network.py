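"""Network construction: KDE densities, symmetric KL, KLS, matrix assembly."""

import math

import numpy as np
import pytest

import morphattn as m
from morphattn.io import RegionalSampleSet
from morphattn.network import (
    DENSITY_FLOOR,
    DensityGrid,
    build_network,
    estimate_density,
    kls_similarity,
    make_evaluation_grid,
    symmetric_kl,
)

TWO_POINT_GRID = np.array([0.0, 1.0])
# symmetrised KL of (0.5, 0.5) vs (0.25, 0.75), summed by hand over the four
# log terms: 0.5 ln2 - 0.25 ln2 - 0.5 ln(3/2)... = 0.25 ln 3
TWO_POINT_KL = 0.25 * math.log(3.0)


def density(mass):
    return DensityGrid(points=TWO_POINT_GRID, mass=np.asarray(mass))


class TestSymmetricKL:
    def test_two_point_hand_computed_value(self):
        D = symmetric_kl(density([0.5, 0.5]), density([0.25, 0.75]))
        assert D == pytest.approx(TWO_POINT_KL, abs=1e-6)
        assert D == pytest.approx(0.274653, abs=1e-6)

    def test_identical_densities_give_zero(self):
        P = density([0.3, 0.7])
        assert symmetric_kl(P, P) == 0.0

    def test_symmetry_in_arguments(self, rng):
        for _ in range(20):
            p = rng.random(16) + 1e-3
            q = rng.random(16) + 1e-3
            grid = np.arange(16.0)
            P = DensityGrid(points=grid, mass=p / p.sum())
            Q = DensityGrid(points=grid, mass=q / q.sum())
            assert symmetric_kl(P, Q) == pytest.approx(symmetric_kl(Q, P),
                                                       rel=1e-14)
            assert symmetric_kl(P, Q) >= 0

    def test_grid_mismatch_rejected(self):
        P = density([0.5, 0.5])
        Q = DensityGrid(points=np.array([0.0, 2.0]), mass=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="grid"):
            symmetric_kl(P, Q)


class TestKLS:
    def test_identity_gives_one(self):
        P = density([0.4, 0.6])
        assert kls_similarity(P, P) == 1.0

    def test_two_point_hand_computed_value(self):
        x = kls_similarity(density([0.5, 0.5]), density([0.25, 0.75]))
        assert x == pytest.approx(math.exp(-TWO_POINT_KL), abs=1e-6)
        assert x == pytest.approx(0.75983, abs=1e-4)

    def test_near_disjoint_supports_stay_positive(self):
        # floored masses: extreme concentration at opposite points
        eps = 1e-9
        P = density([1 - eps, eps])
        Q = density([eps, 1 - eps])
        x = kls_similarity(P, Q)
        assert 0 < x < 1e-6


class TestDensityEstimation:
    def test_kde_recovers_gaussian_mean(self, rng):
        samples = rng.normal(0.0, 1.0, size=10_000)
        grid = np.linspace(-6, 6, 256)
        d = estimate_density(samples, grid)
        assert float(np.sum(d.points * d.mass)) == pytest.approx(0.0, abs=0.05)

    def test_mass_normalised_and_floored(self, rng):
        d = estimate_density(rng.normal(size=100), np.linspace(-30, 30, 128))
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert d.mass.min() > 0

    def test_deterministic(self, rng):
        samples = rng.normal(size=200)
        grid = np.linspace(-4, 4, 64)
        np.testing.assert_array_equal(estimate_density(samples, grid).mass,
                                      estimate_density(samples, grid).mass)

    def test_constant_samples_fall_back_without_nan(self):
        d = estimate_density(np.full(50, 0.5), np.linspace(0, 1, 64))
        assert np.all(np.isfinite(d.mass))
        # mass concentrates near the constant value
        assert d.points[np.argmax(d.mass)] == pytest.approx(0.5, abs=0.02)


class TestEvaluationGrid:
    def make_set(self, arrays):
        return RegionalSampleSet(subject_id="s",
                                 samples=dict(enumerate(arrays)),
                                 retained_labels=list(range(len(arrays))))

    def test_grid_covers_samples(self, rng):
        ss = self.make_set([rng.uniform(0, 1, 100), rng.uniform(0.2, 0.8, 100)])
        grid = make_evaluation_grid(ss, 128)
        assert len(grid) == 128
        assert grid[0] < 0 < 1 < grid[-1]
        assert np.all(np.diff(grid) > 0)

    def test_too_few_points_rejected(self, rng):
        ss = self.make_set([rng.random(50)])
        with pytest.raises(ValueError, match="n_points"):
            make_evaluation_grid(ss, 2)

    def test_deterministic(self, rng):
        ss = self.make_set([rng.random(60)])
        np.testing.assert_array_equal(make_evaluation_grid(ss),
                                      make_evaluation_grid(ss))

    def test_all_constant_equal_samples_degenerate(self):
        ss = self.make_set([np.full(20, 1.0), np.full(20, 1.0)])
        with pytest.raises(ValueError, match="degenerate"):
            make_evaluation_grid(ss)


def naive_network(sampleset, n_points):
    """Straight-line re-derivation of the matrix: literal per-point sums."""
    grid = make_evaluation_grid(sampleset, n_points)
    dens = {l: estimate_density(sampleset.samples[l], grid).mass
            for l in sampleset.retained_labels}
    M = len(sampleset.retained_labels)
    X = np.zeros((M, M))
    for i, li in enumerate(sampleset.retained_labels):
        for j, lj in enumerate(sampleset.retained_labels):
            if i == j:
                X[i, j] = 1.0
                continue
            P, Q = dens[li], dens[lj]
            D = 0.0
            for k in range(len(grid)):
                D += P[k] * math.log(P[k] / Q[k]) + Q[k] * math.log(Q[k] / P[k])
            X[i, j] = math.exp(-D)
    return X


class TestBuildNetwork:
    def test_matches_naive_per_pair_oracle(self, rng):
        arrays = [rng.normal(loc, 0.2, size=80) for loc in (0, 0.3, 0.5, 1.0, 2.0)]
        ss = RegionalSampleSet(subject_id="s", samples=dict(enumerate(arrays)),
                               retained_labels=list(range(5)))
        net = build_network(ss, n_points=64)
        np.testing.assert_allclose(net.X, naive_network(ss, 64),
                                   rtol=0, atol=1e-12)

    def test_identical_regions_give_all_ones(self, rng):
        base = rng.normal(size=100)
        ss = RegionalSampleSet(subject_id="s",
                               samples={i: base.copy() for i in range(4)},
                               retained_labels=list(range(4)))
        np.testing.assert_allclose(build_network(ss, 32).X, np.ones((4, 4)))

    def test_invariants_over_random_subjects(self, rng):
        for _ in range(10):
            arrays = [rng.normal(rng.uniform(0, 1), rng.uniform(0.05, 0.3), 60)
                      for _ in range(4)]
            ss = RegionalSampleSet(subject_id="s",
                                   samples=dict(enumerate(arrays)),
                                   retained_labels=list(range(4)))
            X = build_network(ss, 32).X
            np.testing.assert_array_equal(X, X.T)
            np.testing.assert_array_equal(np.diag(X), np.ones(4))
            assert np.all(X > 0) and np.all(X <= 1)

    def test_similarity_decreases_with_mean_shift(self, rng):
        """KLS to a N(0,1) reference falls monotonically with the mean gap."""
        ref = rng.normal(0, 1, size=20_000)
        values = []
        for shift in (0.0, 0.5, 1.0, 2.0):
            shifted = ref + shift
            ss = RegionalSampleSet(subject_id="s",
                                   samples={0: ref, 1: shifted},
                                   retained_labels=[0, 1])
            values.append(build_network(ss, 128).X[0, 1])
        assert values[0] > values[1] > values[2] > values[3]

    def test_stable_under_grid_refinement(self, rng):
        arrays = [rng.normal(loc, 0.3, size=2000) for loc in (0.0, 0.4, 0.9)]
        ss = RegionalSampleSet(subject_id="s", samples=dict(enumerate(arrays)),
                               retained_labels=[0, 1, 2])
        X128 = build_network(ss, 128).X
        X256 = build_network(ss, 256).X
        assert np.max(np.abs(X128 - X256)) < 0.01
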