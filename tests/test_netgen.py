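"""Network generation, edge-list I/O and degree statistics."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

import epithresh as et
from epithresh import (
    EdgeListParseError,
    InvalidParameterError,
    Network,
    SFNConfig,
)


class TestNetwork:
    def test_invariants_on_construction(self, triangle):
        assert triangle.n_nodes == 3
        assert triangle.n_edges == 3
        # symmetry of the CSR adjacency
        for i in range(3):
            for j in triangle.neighbors(i):
                assert i in triangle.neighbors(j)

    @pytest.mark.parametrize("edges, err", [
        ([(0, 0)], "self-loop"),
        ([(0, 1), (1, 0)], "duplicate"),
        ([(0, 5)], "outside"),
    ])
    def test_rejects_malformed_edge_sets(self, edges, err):
        with pytest.raises(InvalidParameterError, match=err):
            Network.from_edges(3, edges)

    def test_networkx_round_trip(self, star5):
        back = Network.from_networkx(star5.to_networkx())
        assert np.array_equal(back.edge_array, star5.edge_array)


class TestRRN:
    @pytest.mark.parametrize("n, k", [(6, 2), (10, 3), (50, 7), (101, 4)])
    def test_every_node_has_exact_degree(self, n, k):
        net = et.generate_rrn(n, k, rng_seed=1)
        assert np.all(net.degrees == k)

    def test_degree_moments_are_constant(self):
        stats = et.degree_stats(et.generate_rrn(400, 10, rng_seed=2))
        assert stats.mean_k == 10.0
        assert stats.mean_k2 == 100.0

    def test_odd_stub_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            et.generate_rrn(5, 3, rng_seed=0)

    def test_degree_must_be_below_n(self):
        with pytest.raises(InvalidParameterError):
            et.generate_rrn(5, 5, rng_seed=0)


def _truncated_powerlaw_mle(degrees, k_min, k_max):
    """Independent oracle: exact MLE of gamma for the discrete law
    P(k) proportional to k^-gamma on the finite range [k_min, k_max]."""
    ks = np.arange(k_min, k_max + 1, dtype=float)
    log_deg_sum = np.sum(np.log(degrees))

    def nll(gamma):
        z = np.sum(ks ** (-gamma))
        return gamma * log_deg_sum + len(degrees) * np.log(z)

    res = minimize_scalar(nll, bounds=(2.01, 6.0), method="bounded")
    return res.x


class TestSFN:
    def test_structural_cap_is_sqrt_n(self):
        cfg = SFNConfig(n_nodes=10_000, gamma=2.5, cutoff_mode="structural")
        assert cfg.degree_cap == 100
        net = et.generate_sfn(cfg, rng_seed=3)
        assert net.degrees.max() <= 100

    def test_natural_cap(self):
        cfg = SFNConfig(n_nodes=10_000, gamma=3.5, cutoff_mode="natural")
        assert cfg.degree_cap == 39  # floor(10^(4/2.5))
        net = et.generate_sfn(cfg, rng_seed=3)
        assert net.degrees.max() <= 39

    def test_sampled_degree_exponent_recovers_gamma(self):
        """MLE on the sampled degree sequences, averaged over seeds."""
        cfg = SFNConfig(n_nodes=10_000, gamma=2.5, cutoff_mode="structural")
        estimates = []
        for seed in range(50):
            degs = et.sample_powerlaw_degrees(cfg, np.random.default_rng(seed))
            estimates.append(_truncated_powerlaw_mle(degs, cfg.k_min, cfg.degree_cap))
        assert abs(np.mean(estimates) - 2.5) < 0.05

    def test_structural_cutoff_kills_degree_correlations(self):
        net = et.generate_sfn(
            SFNConfig(n_nodes=10_000, gamma=2.5, cutoff_mode="structural"), 11)
        assert abs(et.degree_assortativity(net)) < 0.05

    def test_natural_cutoff_is_disassortative_below_gamma_3(self):
        net = et.generate_sfn(
            SFNConfig(n_nodes=10_000, gamma=2.25, cutoff_mode="natural"), 11)
        assert et.degree_assortativity(net) < -0.02

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidParameterError):
            SFNConfig(n_nodes=100, gamma=1.9)
        with pytest.raises(InvalidParameterError):
            SFNConfig(n_nodes=16, gamma=2.5, k_min=4)  # k_min >= cap


class TestEdgeListIO:
    def test_reads_triangle(self, tmp_path):
        p = tmp_path / "tri.txt"
        p.write_text("# a triangle\n0 1\n1 2\n2 0\n")
        net = et.read_edge_list(p)
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_drops_duplicates_and_self_loops(self, tmp_path):
        p = tmp_path / "messy.txt"
        p.write_text("0 1\n1 0\n3 3\n")
        net = et.read_edge_list(p)
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_path_graph(self, tmp_path):
        p = tmp_path / "path.txt"
        p.write_text("".join(f"{i} {i + 1}\n" for i in range(10)))
        net = et.read_edge_list(p)
        assert net.n_nodes == 11
        deg = net.degrees
        assert np.sum(deg == 1) == 2
        assert np.sum(deg == 2) == 9

    def test_arbitrary_labels_relabeled_in_first_appearance_order(self, tmp_path):
        p = tmp_path / "lab.txt"
        p.write_text("100 7\n7 -3\n")
        net = et.read_edge_list(p)
        assert net.n_nodes == 3
        assert sorted(map(tuple, net.edge_array)) == [(0, 1), (1, 2)]

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1\n1 2 3\n")
        with pytest.raises(EdgeListParseError, match=":2:"):
            et.read_edge_list(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("# nothing\n")
        with pytest.raises(EdgeListParseError):
            et.read_edge_list(p)

    def test_write_read_round_trip(self, tmp_path):
        net = et.generate_rrn(30, 4, rng_seed=5)
        p = tmp_path / "rrn.txt"
        et.write_edge_list(net, p)
        back = et.read_edge_list(p)
        assert np.array_equal(back.edge_array, net.edge_array)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.sets(
    st.tuples(st.integers(0, 14), st.integers(0, 14)).filter(lambda e: e[0] != e[1]),
    min_size=1, max_size=30))
def test_round_trip_preserves_any_simple_graph(tmp_path_factory, edge_set):
    """Writing then reading any generated simple graph is the identity on
    the canonical sorted edge set."""
    canon = {tuple(sorted(e)) for e in edge_set}
    nodes = sorted({v for e in canon for v in e})
    remap = {v: i for i, v in enumerate(nodes)}
    net = Network.from_edges(len(nodes), [(remap[a], remap[b]) for a, b in canon])
    p = tmp_path_factory.mktemp("rt") / "g.txt"
    et.write_edge_list(net, p)
    back = et.read_edge_list(p)
    assert np.array_equal(back.edge_array, net.edge_array)


class TestDegreeStats:
    def test_triangle(self, triangle):
        s = et.degree_stats(triangle)
        assert (s.mean_k, s.mean_k2, s.k_max) == (2.0, 4.0, 2)

    def test_star(self, star5):
        s = et.degree_stats(star5)
        assert (s.mean_k, s.mean_k2, s.k_max) == (1.6, 4.0, 4)

    def test_variance_nonnegative_and_kmax_bound(self, rrn_small):
        s = et.degree_stats(rrn_small)
        assert s.mean_k2 >= s.mean_k ** 2
        assert s.k_max >= s.mean_k


class TestAssortativity:
    def test_regular_graph_is_nan(self, rrn_small):
        assert math.isnan(et.degree_assortativity(rrn_small))

    def test_star_is_minus_one(self, star5):
        assert et.degree_assortativity(star5) == pytest.approx(-1.0)

    def test_matches_networkx_on_heterogeneous_graph(self):
        """Dual route: our oriented-edge Pearson correlation vs networkx."""
        net = et.generate_sfn(SFNConfig(n_nodes=2000, gamma=2.5), 13)
        ours = et.degree_assortativity(net)
        theirs = nx.degree_assortativity_coefficient(net.to_networkx())
        assert ours == pytest.approx(theirs, abs=1e-10)
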