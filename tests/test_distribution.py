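"""Outbreak-size distributions: enumeration oracle, fits, cutoff and lump."""

import numpy as np
import pytest

import epithresh as et
from epithresh import CutoffConfig, InvalidParameterError, Network, OutbreakEnsemble
from epithresh.distribution import (
    OutbreakDistribution,
    log_binned_density,
    lump_model_variability_curve,
)


def _ens(values, n_nodes, lam=0.1):
    return OutbreakEnsemble(lambda_=lam, n_nodes=n_nodes,
                            values=np.asarray(values, dtype=float))


def _dist(n_nodes, masses: dict):
    mass = np.zeros(n_nodes)
    for m, p in masses.items():
        mass[m - 1] = p
    return OutbreakDistribution(n_nodes=n_nodes, mass=mass)


class TestEmpiricalDistribution:
    def test_point_mass_at_minimum(self):
        d = et.empirical_distribution(_ens([0.2] * 5, n_nodes=5))
        assert d.mass[0] == 1.0

    def test_masses_sum_to_one(self, rng):
        vals = rng.integers(1, 51, size=1000) / 50
        d = et.empirical_distribution(_ens(vals, n_nodes=50))
        assert d.mass.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dyad_frequencies_match_percolation(self, dyad):
        ens = et.run_ensemble(dyad, [0.3], 1.0, "SIR", 1, 50_000, master_seed=1)
        d = et.empirical_distribution(ens[0])
        assert d.mass[0] == pytest.approx(0.7, abs=0.01)
        assert d.mass[1] == pytest.approx(0.3, abs=0.01)


class TestExactFinalSizeDistribution:
    def test_single_edge_closed_form(self, dyad):
        d = et.exact_final_size_distribution(dyad, 0.3)
        assert np.allclose(d.mass, [0.7, 0.3])

    def test_triangle_enumeration(self, triangle):
        d = et.exact_final_size_distribution(triangle, 0.5)
        assert np.allclose(d.mass, [0.25, 0.25, 0.5])

    def test_beta_one_percolates_fully(self, path11):
        d = et.exact_final_size_distribution(path11, 1.0)
        assert d.mass[-1] == pytest.approx(1.0)

    def test_beta_zero_only_the_seed(self, triangle):
        d = et.exact_final_size_distribution(triangle, 0.0)
        assert d.mass[0] == pytest.approx(1.0)

    def test_refuses_large_graphs(self):
        net = et.generate_rrn(30, 4, rng_seed=1)  # 60 edges
        with pytest.raises(InvalidParameterError, match="20 edges"):
            et.exact_final_size_distribution(net, 0.5)

    def test_disconnected_graph_cluster_sizes(self):
        # two disjoint edges: seed's cluster never exceeds 2 nodes
        net = Network.from_edges(4, [(0, 1), (2, 3)])
        d = et.exact_final_size_distribution(net, 1.0)
        assert d.mass[1] == pytest.approx(1.0)  # always size 2 of N=4


class TestLogBinnedDensity:
    def test_bin_mass_conserved(self):
        d = _dist(100, {1: 0.5, 2: 0.2, 10: 0.2, 50: 0.1})
        _, _, bin_mass = log_binned_density(d, 15)
        assert bin_mass.sum() == pytest.approx(1.0)

    def test_density_flat_for_uniform_mass_per_site(self):
        n = 1000
        d = OutbreakDistribution(n, np.full(n, 1 / n))
        centers, density, _ = log_binned_density(d, 30)
        assert np.allclose(density, 1 / n, rtol=1e-9)


class TestPowerLawFit:
    def test_recovers_synthetic_exponent(self):
        n = 10_000
        m = np.arange(1, n + 1, dtype=float)
        mass = m ** -1.5
        d = OutbreakDistribution(n, mass / mass.sum())
        fit = et.fit_powerlaw_exponent(d, (1 / n, 0.01))
        assert fit.alpha == pytest.approx(-1.5, abs=0.05)

    def test_uniform_distribution_has_zero_slope(self):
        n = 10_000
        d = OutbreakDistribution(n, np.full(n, 1 / n))
        fit = et.fit_powerlaw_exponent(d, (1 / n, 0.1))
        assert fit.alpha == pytest.approx(0.0, abs=0.05)

    def test_insufficient_support_is_an_error(self):
        d = _dist(100, {1: 0.5, 2: 0.5})
        with pytest.raises(InvalidParameterError):
            et.fit_powerlaw_exponent(d, (0.01, 0.05))


class TestTruncatedSusceptibility:
    def test_rc_one_equals_plain_susceptibility(self, rng):
        e = _ens(rng.uniform(0.01, 1.0, 500), n_nodes=200)
        assert et.truncated_susceptibility(e, CutoffConfig(1.0)) == \
            pytest.approx(et.susceptibility(e))

    def test_single_survivor_gives_zero(self):
        e = _ens([0.1, 0.3], n_nodes=100)
        assert et.truncated_susceptibility(e, CutoffConfig(0.2)) == 0.0

    def test_empty_subensemble_is_an_error(self):
        e = _ens([0.5, 0.6], n_nodes=100)
        with pytest.raises(InvalidParameterError):
            et.truncated_susceptibility(e, CutoffConfig(0.1))


class TestLumpedVariability:
    def test_mass_entirely_below_rc_is_unchanged(self):
        d = _dist(100, {1: 0.6, 5: 0.4})
        assert et.lumped_variability(d, CutoffConfig(0.5)) == \
            pytest.approx(d.variability())

    def test_point_mass_gives_zero(self):
        d = _dist(100, {1: 1.0})
        assert et.lumped_variability(d, CutoffConfig(0.2)) == 0.0

    def test_two_point_closed_form(self):
        """P(1/N)=0.9 plus a 0.1 tail above r_c collapses to the two-point
        law {1/N: 0.9, r_c: 0.1}, whose Delta has a closed form."""
        n, rc, p = 100, 0.2, 0.1
        d = _dist(n, {1: 0.9, 40: 0.05, 70: 0.05})
        lo = 1 / n
        expected = (np.sqrt(p * (1 - p)) * (rc - lo)
                    / ((1 - p) * lo + p * rc))
        assert et.lumped_variability(d, CutoffConfig(rc)) == pytest.approx(expected)

    def test_tail_collapses_onto_rc(self):
        # strict inequality: rho < r_c stays; mass at and above r_c becomes
        # the lump at r_c
        n = 10
        d = _dist(n, {1: 0.5, 2: 0.2, 3: 0.3})  # rho = 0.1, 0.2, 0.3
        got = et.lumped_variability(d, CutoffConfig(0.2))
        collapsed = _dist(n, {1: 0.5, 2: 0.5})
        assert got == pytest.approx(collapsed.variability())


class TestDetectModes:
    def test_point_mass_single_mode(self):
        d = _dist(1000, {1: 1.0})
        modes = et.detect_modes(d, 20)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(1e-3)

    def test_constructed_bimodal_mixture(self, rng):
        """0.9 geometric(small) + 0.1 gaussian(0.2, 0.02): modes near 1/N
        and 0.2 by construction."""
        n = 10_000
        m = np.arange(1, n + 1)
        small = 0.5 ** m
        bump = np.exp(-0.5 * ((m / n - 0.2) / 0.02) ** 2)
        mass = 0.9 * small / small.sum() + 0.1 * bump / bump.sum()
        d = OutbreakDistribution(n, mass / mass.sum())
        modes = et.detect_modes(d, 40)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(1 / n, rel=0.5)
        assert modes[1] == pytest.approx(0.2, abs=0.03)

    def test_min_mass_filters_sparse_tail_noise(self):
        n = 10_000
        d = _dist(n, {1: 0.999, 5000: 0.001})  # isolated 0.1% spike at 0.5
        assert len(et.detect_modes(d, 40, min_mass=0.01)) == 1

    def test_log_bins_floor(self):
        with pytest.raises(InvalidParameterError):
            et.detect_modes(_dist(100, {1: 1.0}), 5)


class TestLumpModelCurve:
    def test_subthreshold_entries_keep_plain_variability(self):
        n = 1000
        dists = [_dist(n, {1: 0.8, 3: 0.2}), _dist(n, {1: 0.6, 3: 0.4}),
                 _dist(n, {1: 0.5, 500: 0.5})]
        lams = np.array([0.08, 0.10, 0.12])
        curve = lump_model_variability_curve(lams, dists, CutoffConfig(0.2),
                                             lambda_c=0.10)
        assert curve[0] == pytest.approx(dists[0].variability())
        assert curve[1] == pytest.approx(dists[1].variability())
        assert curve[2] == pytest.approx(
            et.lumped_variability(dists[2], CutoffConfig(0.2)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidParameterError):
            lump_model_variability_curve([0.1], [], CutoffConfig(0.2), 0.1)


class TestMonteCarloAgainstOracle:
    """For mu = 1 the dynamics IS bond percolation: the empirical final-size
    distribution must converge to the exact enumeration."""

    @pytest.mark.parametrize("beta", [0.2, 0.5, 0.8])
    def test_total_variation_small_on_square_with_diagonal(self, beta):
        net = Network.from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        exact = et.exact_final_size_distribution(net, beta)
        ens = et.run_ensemble(net, [beta], 1.0, "SIR", 1, 30_000, master_seed=17)
        emp = et.empirical_distribution(ens[0])
        tv = 0.5 * np.abs(emp.mass - exact.mass).sum()
        assert tv < 0.015
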