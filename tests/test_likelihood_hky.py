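"""HKY transition probabilities, pruning, and the blocked site-sum reduction."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from imcoal.genealogy import Genealogy, simulate_genealogy
from imcoal.likelihood_hky import (
    HKYModel,
    blocked_total_loglik,
    empirical_base_frequencies,
    hky_total_loglik,
    hky_transition_matrix,
    prune_conditional_likelihoods,
    site_log_likelihoods,
)
from imcoal.simulator import simulate_sequences_hky

from conftest import make_three_leaf


def random_model(rng) -> HKYModel:
    pi = rng.dirichlet([5.0] * 4)
    return HKYModel(tuple(pi / pi.sum()), float(rng.uniform(0.3, 8.0)))


def hky_rate_matrix(model: HKYModel) -> np.ndarray:
    """Independent construction of the normalized HKY generator."""
    pi = model.pi_array
    purine = [True, False, True, False]
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i != j:
                Q[i, j] = (model.kappa if purine[i] == purine[j] else 1.0) * pi[j]
        Q[i, i] = -Q[i].sum()
    return Q / -np.sum(pi * np.diag(Q))


def brute_force_loglik(G, aln, model, u):
    """Sum over all internal-state assignments (oracle for pruning)."""
    pi = model.pi_array
    internal = [v for v in range(G.n_nodes) if not G.is_leaf(v)]
    root = G.root
    P = {
        v: hky_transition_matrix(float(G.time[G.parent[v]] - G.time[v]) * u, model)
        for v in range(G.n_nodes)
        if G.parent[v] >= 0
    }
    total = 0.0
    for j in range(aln.shape[1]):
        s = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            state = dict(zip(internal, assign))
            for i in range(G.N):
                state[i] = aln[i, j]
            pr = pi[state[root]]
            for v, Pv in P.items():
                pr *= Pv[state[int(G.parent[v])], state[v]]
            s += pr
        total += math.log(s)
    return total


class TestTransitionMatrix:
    def test_zero_branch_is_identity(self, rng):
        P = hky_transition_matrix(0.0, random_model(rng))
        assert np.allclose(P, np.eye(4), atol=1e-14)

    def test_jc69_limit_diagonal(self):
        model = HKYModel((0.25,) * 4, 1.0)
        for t in np.linspace(0.01, 3.0, 20):
            P = hky_transition_matrix(t, model)
            expect = 0.25 + 0.75 * math.exp(-4 * t / 3)
            assert np.allclose(np.diag(P), expect, atol=1e-13)

    def test_long_branch_reaches_stationarity(self, rng):
        model = random_model(rng)
        P = hky_transition_matrix(1e4, model)
        assert np.allclose(P, np.tile(model.pi_array, (4, 1)), atol=1e-8)

    def test_matches_matrix_exponential(self, rng):
        for _ in range(20):
            model = random_model(rng)
            Q = hky_rate_matrix(model)
            t = float(rng.uniform(0.01, 5.0))
            assert np.allclose(
                hky_transition_matrix(t, model), expm(Q * t), atol=1e-12
            )

    def test_detailed_balance(self, rng):
        model = random_model(rng)
        pi = model.pi_array
        P = hky_transition_matrix(0.8, model)
        flux = pi[:, None] * P
        assert np.allclose(flux, flux.T, atol=1e-14)

    def test_negative_branch_rejected(self, rng):
        with pytest.raises(ValueError):
            hky_transition_matrix(-0.1, random_model(rng))


class TestPruning:
    def test_zero_branches_identity_case(self):
        G = make_three_leaf(0.0, 0.0)
        # degenerate zero-length tree: identity transitions, all leaves A
        aln = np.zeros((3, 2), dtype=np.uint8)
        CL = prune_conditional_likelihoods(G, aln, HKYModel())
        np.testing.assert_allclose(CL.partials[CL.root][:, 0], 1.0)
        np.testing.assert_allclose(CL.partials[CL.root][:, 1:], 0.0)

    def test_matches_brute_force_enumeration(self, im_params, rng):
        for _ in range(10):
            G = simulate_genealogy(im_params, 2, 2, rng)
            model = random_model(rng)
            aln = simulate_sequences_hky(G, 5, model, 0.5, rng)
            got = hky_total_loglik(G, aln, model, 0.5)
            want = brute_force_loglik(G, aln, model, 0.5)
            assert got == pytest.approx(want, rel=1e-10)

    def test_site_columns_independent(self, im_params, rng):
        G = simulate_genealogy(im_params, 3, 2, rng)
        model = random_model(rng)
        aln = simulate_sequences_hky(G, 12, model, 1.0, rng)
        perm = rng.permutation(12)
        CL1 = prune_conditional_likelihoods(G, aln, model)
        CL2 = prune_conditional_likelihoods(G, aln[:, perm], model)
        SL1 = site_log_likelihoods(CL1, model)
        SL2 = site_log_likelihoods(CL2, model)
        np.testing.assert_allclose(SL1[perm], SL2, rtol=1e-12)

    def test_row_count_mismatch_rejected(self, im_params, rng):
        G = simulate_genealogy(im_params, 3, 2, rng)
        with pytest.raises(ValueError):
            prune_conditional_likelihoods(G, np.zeros((4, 3), np.uint8), HKYModel())

    def test_rerooting_invariance(self, rng):
        """Time reversibility: the likelihood depends only on the unrooted tree.

        Build one 4-leaf unrooted topology with fixed branch lengths and
        realize it with the root placed on two different edges.
        """
        model = random_model(rng)
        bl = dict(a=0.21, b=0.37, c=0.14, d=0.45, mid=0.3)

        def build(split):
            # unrooted tree ((a,b),(c,d)) with central edge `mid`;
            # root placed on the central edge at fraction `split`
            time = np.zeros(7)
            parent = np.array([4, 4, 5, 5, 6, 6, -1], dtype=np.int64)
            children = np.array(
                [[-1, -1], [-1, -1], [-1, -1], [-1, -1], [0, 1], [2, 3], [4, 5]],
                dtype=np.int64,
            )
            # assign times downward from the root so branch lengths match
            time[6] = 10.0
            time[4] = time[6] - split * bl["mid"]
            time[5] = time[6] - (1 - split) * bl["mid"]
            time[0] = time[4] - bl["a"]
            time[1] = time[4] - bl["b"]
            time[2] = time[5] - bl["c"]
            time[3] = time[5] - bl["d"]
            return Genealogy(time, parent, children, np.array([1, 1, 2, 2]), [])

        aln = np.array(
            [[0, 1, 2, 3, 0], [1, 1, 2, 0, 0], [2, 3, 2, 1, 0], [3, 0, 2, 2, 1]],
            dtype=np.uint8,
        )
        lls = [hky_total_loglik(build(s), aln, model) for s in (0.15, 0.5, 0.9)]
        assert lls[0] == pytest.approx(lls[1], rel=1e-10)
        assert lls[0] == pytest.approx(lls[2], rel=1e-10)


class TestSiteLikelihoods:
    def test_indicator_root(self):
        G = make_three_leaf(0.3, 0.9)
        model = HKYModel()
        aln = np.zeros((3, 1), dtype=np.uint8)
        CL = prune_conditional_likelihoods(G, aln, model)
        CL.partials[CL.root] = np.array([[1.0, 0, 0, 0]])
        CL.log_scale[:] = 0.0
        assert site_log_likelihoods(CL, model)[0] == pytest.approx(math.log(0.25))

    def test_patterns_sum_to_one(self, im_params, rng):
        G = simulate_genealogy(im_params, 2, 1, rng)
        model = random_model(rng)
        total = 0.0
        for pat in itertools.product(range(4), repeat=3):
            aln = np.array(pat, dtype=np.uint8)[:, None]
            total += math.exp(hky_total_loglik(G, aln, model))
        assert total == pytest.approx(1.0, abs=1e-10)


class TestBlockedSum:
    def test_single_block_and_identity_partition(self, rng):
        SL = rng.normal(size=100)
        total, blocks = blocked_total_loglik(SL, 100)
        assert len(blocks) == 1 and total == pytest.approx(SL.sum())
        total1, blocks1 = blocked_total_loglik(SL, 1)
        np.testing.assert_allclose(blocks1, SL)

    def test_invalid_block_size(self, rng):
        with pytest.raises(ValueError):
            blocked_total_loglik(rng.normal(size=10), 0)

    @given(st.integers(1, 2000))
    @settings(max_examples=50, deadline=None)
    def test_block_size_invariance(self, block_size):
        rng = np.random.default_rng(99)
        SL = rng.normal(loc=-3.0, size=1777)
        direct = float(SL.sum())
        total, _ = blocked_total_loglik(SL, block_size)
        assert total == pytest.approx(direct, rel=1e-9)


def test_empirical_base_frequencies_positive(rng):
    aln = np.zeros((3, 10), dtype=np.uint8)  # all A
    pi = empirical_base_frequencies(aln)
    assert pi.sum() == pytest.approx(1.0)
    assert np.all(pi > 0)
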