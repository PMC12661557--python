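"""Jensen–Shannon divergence, convergence curves and agreement matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cycloscape import (
    DensityProfile,
    converged,
    density_profile,
    jsd,
    jsd_curves,
    mean_profile,
    agreement,
    make_basin,
    make_ring_reference,
    simulate_trajectory,
)
from cycloscape.convergence import subsample_even

rng = np.random.default_rng(99)
EDGES = np.linspace(0.0, 5.0, 51)


def profile_from_masses(masses, edges=None):
    edges = EDGES if edges is None else edges
    masses = np.asarray(masses, dtype=float)
    masses = masses / masses.sum()
    return DensityProfile(bin_edges=edges, density=masses / np.diff(edges))


def random_profile(r):
    return profile_from_masses(r.dirichlet(np.full(EDGES.size - 1, 0.3)))


class TestJSD:
    def test_identical_profiles_give_zero(self):
        p = random_profile(rng)
        assert jsd(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        p = profile_from_masses([1.0] + [0.0] * 49)
        q = profile_from_masses([0.0] * 49 + [1.0])
        assert jsd(p, q) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_two_bin_value(self):
        # P=(1,0), Q=(1/2,1/2): ½·log2(4/3) + ½·(½·log2(2/3) + ½·log2 2) = 0.3113
        edges = np.array([0.0, 1.0, 2.0])
        p = profile_from_masses([1.0, 0.0], edges)
        q = profile_from_masses([0.5, 0.5], edges)
        assert jsd(p, q) == pytest.approx(0.31128, abs=1e-4)

    def test_symmetry_and_bounds_on_random_pairs(self):
        for _ in range(50):
            p, q = random_profile(rng), random_profile(rng)
            assert abs(jsd(p, q) - jsd(q, p)) < 1e-12
            assert 0.0 <= jsd(p, q) <= 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sqrt_jsd_triangle_inequality(self, seed):
        r = np.random.default_rng(seed)
        a, b, c = (random_profile(r) for _ in range(3))
        assert np.sqrt(jsd(a, c)) <= np.sqrt(jsd(a, b)) + np.sqrt(jsd(b, c)) + 1e-12

    def test_mismatched_edges_rejected(self):
        p = random_profile(rng)
        q = density_profile([1.0], np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            jsd(p, q)


class TestMeanProfile:
    def test_identical_runs_reproduce_each_profile(self):
        values = rng.gamma(4, 0.5, 2000)
        m = mean_profile([values] * 5, EDGES)
        single = density_profile(values, EDGES)
        assert np.allclose(m.density, single.density)

    def test_min_length_rule_balances_contributions(self):
        long = np.zeros(100)
        short = np.full(50, 4.9)
        m = mean_profile([long, short], EDGES)
        # each run contributes 50 values -> equal masses in the two end bins
        assert m.masses[0] == pytest.approx(0.5)
        assert m.masses[-1] == pytest.approx(0.5)

    def test_pooled_masses_match_population_average(self, ring7):
        basins = lambda p: [
            make_basin(ring7, 0.5, p, 0.1, seed=31),
            make_basin(ring7, 3.5, 1 - p, 0.1, seed=32),
        ]
        from cycloscape import observables

        runs = []
        for i, p in enumerate([0.8, 0.6]):
            t = simulate_trajectory(
                basins(p), 0.9, 30000, seed=40 + i, atom_labels=ring7.atom_labels
            )
            runs.append(observables(t.to_trajectory(), ring7.coordinates, 0.0).rmsd)
        m = mean_profile(runs, EDGES)
        near_mass = m.masses[EDGES[:-1] < 2.0].sum()
        assert near_mass == pytest.approx(0.7, abs=0.02)


class TestJSDCurves:
    def test_identical_runs_give_zero_curves(self):
        values = rng.gamma(4, 0.5, 1000)
        curves = jsd_curves([values] * 3, EDGES, n_windows=20)
        for c in curves:
            assert np.all(c.jsd < 1e-12)

    def test_endpoint_matches_full_profile_jsd(self):
        runs = [rng.gamma(4, 0.5, 1500) for _ in range(4)]
        curves = jsd_curves(runs, EDGES, n_windows=25)
        m = mean_profile(runs, EDGES)
        for run, curve in zip(runs, curves):
            assert curve.final == pytest.approx(
                jsd(density_profile(run, EDGES), m), abs=1e-12
            )

    def test_fractions_increase_to_one(self):
        curves = jsd_curves([rng.gamma(4, 0.5, 500)] * 2, EDGES, n_windows=10)
        f = curves[0].fractions
        assert np.all(np.diff(f) > 0) and f[-1] == 1.0

    def test_outlier_run_flagged(self, ring7):
        from cycloscape import BasinSpec, observables

        near = make_basin(ring7, 0.5, 0.6, 0.2, seed=51)
        far = make_basin(ring7, 3.0, 0.4, 0.2, seed=52)
        extra = make_basin(ring7, 6.0, 1.0, 0.2, seed=53)

        def run_rmsd(basins, seed):
            t = simulate_trajectory(
                basins, 0.9, 20000, seed=seed, atom_labels=ring7.atom_labels
            )
            return observables(t.to_trajectory(), ring7.coordinates, 0.0).rmsd

        normal = [run_rmsd([near, far], 60 + i) for i in range(4)]
        # one run visits a disjoint extra basin 40% of the time
        odd = run_rmsd(
            [BasinSpec(near.centroid, 0.5, 0.36, 0.2),
             BasinSpec(far.centroid, 3.0, 0.24, 0.2),
             BasinSpec(extra.centroid, 6.0, 0.40, 0.2)],
            70,
        )
        edges = np.linspace(0.0, 8.0, 81)
        curves = jsd_curves(normal + [odd], edges, n_windows=50)
        per_run, overall = converged(curves, threshold=0.05)
        assert per_run[:4] == [True] * 4
        assert per_run[4] is False and overall is False


class TestConverged:
    def test_threshold_rule(self):
        mk = lambda v: type(
            "C", (), {"final": v}
        )()
        curves = [mk(0.02), mk(0.06)]
        per_run, overall = converged(curves, 0.05)
        assert per_run == [True, False] and overall is False

    def test_relaxed_threshold_flips_verdict(self):
        mk = lambda v: type("C", (), {"final": v})()
        per_run, overall = converged([mk(0.08), mk(0.09)], threshold=0.1)
        assert overall is True


class TestSubsampleEven:
    def test_indices_deterministic_and_bounded(self):
        idx = subsample_even(100, 50)
        assert idx.size == 50 and idx[0] == 0 and idx.max() < 100
        assert np.array_equal(idx, (np.arange(50) * 100) // 50)

    def test_full_keep_is_identity(self):
        assert np.array_equal(subsample_even(10, 10), np.arange(10))


class TestAgreement:
    @staticmethod
    def _runs(ring, pops, seeds, n=15000):
        from cycloscape import observables

        near = make_basin(ring, 0.5, pops[0], 0.2, seed=81)
        far = make_basin(ring, 3.0, pops[1], 0.2, seed=82)
        out = []
        for s in seeds:
            t = simulate_trajectory(
                [near, far], 0.9, n, seed=s, atom_labels=ring.atom_labels
            )
            out.append(observables(t.to_trajectory(), ring.coordinates, 0.0).rmsd)
        return out

    def test_identical_generators_agree(self, ring7):
        groups = {
            "a": self._runs(ring7, (0.6, 0.4), [1, 2]),
            "b": self._runs(ring7, (0.6, 0.4), [3, 4]),
        }
        mat = agreement(groups, summary="mean")
        assert mat.values[0, 1] < 0.05

    def test_shifted_populations_disagree(self, ring7):
        groups = {
            "a": self._runs(ring7, (0.9, 0.1), [5]),
            "b": self._runs(ring7, (0.1, 0.9), [6]),
        }
        mat = agreement(groups, summary="mean")
        # two-bin closed form: each group's profile (0.9, 0.1) against the
        # pooled average (0.5, 0.5) — the construction the entry uses
        edges = np.array([0.0, 1.0, 2.0])
        oracle = jsd(
            profile_from_masses([0.9, 0.1], edges),
            profile_from_masses([0.5, 0.5], edges),
        )
        assert mat.values[0, 1] == pytest.approx(oracle, abs=0.03)
        assert mat.values[0, 1] > 0.1

    def test_diagonal_zero_and_symmetric(self, ring7):
        groups = {
            "a": self._runs(ring7, (0.6, 0.4), [7], n=5000),
            "b": self._runs(ring7, (0.5, 0.5), [8], n=5000),
            "c": self._runs(ring7, (0.4, 0.6), [9], n=5000),
        }
        mat = agreement(groups, summary="max")
        assert np.allclose(np.diag(mat.values), 0.0)
        assert np.allclose(mat.values, mat.values.T)
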