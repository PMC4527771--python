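"""Structured-coalescent genealogies: validity, density, simulation and moves."""

import math

import numpy as np
import pytest

from imcoal.genealogy import (
    Migration,
    MoveTuning,
    coal_stats,
    density_from_stats,
    edge_migrations,
    log_genealogy_density,
    propose_divergence_update,
    propose_genealogy_update,
    simulate_genealogy,
    to_newick,
    total_branch_length,
    validate,
    _migration_move,
    _regraft_move,
    _slide_move,
)
from imcoal.im_parameters import IMParameters

from conftest import make_three_leaf, make_two_leaf


class TestValidate:
    def test_simulated_genealogies_are_valid(self, im_params, rng):
        for _ in range(50):
            G = simulate_genealogy(im_params, 3, 2, rng)
            assert validate(G, im_params) == []

    def test_time_order_violation_detected(self, im_params, rng):
        G = simulate_genealogy(im_params, 3, 2, rng)
        kids = [v for v in range(G.n_nodes) if G.parent[v] >= 0 and not G.is_leaf(v)]
        v = kids[0]
        G.time[v], G.time[G.parent[v]] = G.time[G.parent[v]], G.time[v]
        assert validate(G, im_params)

    def test_migration_above_t_split_detected(self, im_params):
        G = make_two_leaf(2.5, pops=(1, 2))
        G.migrations.append(Migration(0, 2.0, 1, 2))
        bad = validate(G, im_params)  # t_split = 1.0
        assert any("t_split" in v for v in bad)


class TestTotalBranchLength:
    def test_two_leaves(self):
        assert total_branch_length(make_two_leaf(0.5)) == pytest.approx(1.0)

    def test_three_leaves(self):
        assert total_branch_length(make_three_leaf(0.2, 0.6)) == pytest.approx(1.4)

    def test_matches_edge_enumeration(self, im_params, rng):
        for _ in range(100):
            G = simulate_genealogy(im_params, 4, 3, rng)
            manual = sum(
                float(G.time[G.parent[v]] - G.time[v])
                for v in range(G.n_nodes)
                if G.parent[v] >= 0
            )
            assert total_branch_length(G) == pytest.approx(manual, rel=1e-12)

    def test_bt_at_least_twice_tmrca(self, im_params, rng):
        for _ in range(50):
            G = simulate_genealogy(im_params, 3, 3, rng)
            assert total_branch_length(G) >= 2 * G.tmrca() - 1e-12


class TestDensity:
    def test_single_interval_pair(self):
        """Two pop-1 leaves with t_split=0: pure ancestral exponential."""
        tau, thetaA = 0.7, 3.0
        G = make_two_leaf(tau)
        p = IMParameters(1, 1, thetaA, 0, 0, 0.0)
        expect = math.log(2 / thetaA) - (2 / thetaA) * tau
        assert log_genealogy_density(G, p) == pytest.approx(expect)

    def test_two_interval_migration_case(self):
        """One migration then a within-population coalescence, hand-scanned."""
        a, b = 0.3, 0.8
        p = IMParameters(theta1=2.0, theta2=1.5, thetaA=3.0, m1=0.7, m2=0.4, t_split=2.0)
        G = make_two_leaf(b, pops=(1, 2))
        G.migrations.append(Migration(0, a, 1, 2))
        # [0, a): one lineage per population -> rate m1 + m2; event: leaf-0 migrates (m1)
        # [a, b): both in population 2 -> rate 2/theta2 + 2*m2; event: coalescence (2/theta2)
        expect = (
            math.log(p.m1)
            - a * (p.m1 + p.m2)
            + math.log(2 / p.theta2)
            - (b - a) * (2 / p.theta2 + 2 * p.m2)
        )
        assert log_genealogy_density(G, p) == pytest.approx(expect)

    def test_zero_theta_with_realized_event(self):
        G = make_two_leaf(0.5, pops=(1, 1))
        p = IMParameters(0.0, 1, 1, 0, 0, 1.0)  # coalescence in pop 1 at rate 2/0
        s = coal_stats(G, p.t_split)
        assert density_from_stats(s, p) == -math.inf

    def test_invalid_genealogy_raises(self, im_params):
        G = make_two_leaf(0.5, pops=(1, 2))  # discordant pops below t_split
        with pytest.raises(ValueError):
            log_genealogy_density(G, im_params)


class TestSimulate:
    def test_pair_tmrca_mean(self, rng):
        """Single-population pair coalescence: E[TMRCA] = thetaA / 2."""
        thetaA = 2.0
        p = IMParameters(1, 1, thetaA, 0, 0, 0.0)
        t = np.array([simulate_genealogy(p, 2, 0, rng).tmrca() for _ in range(20_000)])
        se = t.std() / math.sqrt(len(t))
        assert abs(t.mean() - thetaA / 2) < 3 * se

    def test_no_cross_population_coalescence_without_migration(self, rng):
        p = IMParameters(1, 1, 1, 0.0, 0.0, 50.0)
        for _ in range(500):
            G = simulate_genealogy(p, 1, 1, rng)
            assert G.tmrca() > p.t_split
            assert not G.migrations

    def test_deterministic_given_seed(self, im_params):
        a = simulate_genealogy(im_params, 3, 3, np.random.default_rng(4))
        b = simulate_genealogy(im_params, 3, 3, np.random.default_rng(4))
        assert np.array_equal(a.time, b.time)
        assert np.array_equal(a.parent, b.parent)
        assert len(a.migrations) == len(b.migrations)


class TestMoves:
    def test_slide_keeps_topology_and_interval(self, im_params, rng):
        for _ in range(100):
            G = simulate_genealogy(im_params, 2, 2, rng)
            G2, logh = _slide_move(G, im_params, MoveTuning(), rng)
            if math.isinf(logh):
                continue
            assert np.array_equal(G.parent, G2.parent)
            changed = np.flatnonzero(G.time != G2.time)
            assert len(changed) == 1

    def test_proposals_yield_valid_states(self, im_params, rng):
        for i in range(300):
            G = simulate_genealogy(im_params, 3, 2, rng)
            G2, logh = propose_genealogy_update(G, im_params, MoveTuning(), rng)
            if math.isfinite(logh):
                assert validate(G2, im_params) == []

    def test_forward_reverse_hastings_cancel(self, im_params, rng):
        """Each move, undone with forced choices, has opposite Hastings ratio."""
        tun = MoveTuning()
        checked = 0
        for trial in range(600):
            G = simulate_genealogy(im_params, 3, 3, rng)
            kind = trial % 3
            if kind == 0:
                node = G.N + int(rng.integers(G.N - 1))
                old_t = float(G.time[node])
                G2, h1 = _slide_move(G, im_params, tun, rng, node=node)
                if not math.isfinite(h1) or validate(G2, im_params):
                    continue
                _, h2 = _slide_move(G2, im_params, tun, rng, node=node, forced_time=old_t)
            elif kind == 1:
                cand = [x for x in range(G.n_nodes) if x != G.root]
                v = cand[int(rng.integers(len(cand)))]
                emig = edge_migrations(G)
                old = [(m.time, m.source, m.dest) for m in emig.get(v, [])]
                pa = int(G.parent[v])
                sib = int(G.children[pa, 0]) if int(G.children[pa, 1]) == v else int(G.children[pa, 1])
                G2, h1 = _regraft_move(G, im_params, tun, rng, v=v)
                if not math.isfinite(h1):
                    continue
                _, h2 = _regraft_move(
                    G2, im_params, tun, rng, v=v,
                    forced_path=(old, float(G.time[pa]), sib),
                )
            else:
                G2, h1 = _migration_move(G, im_params, tun, rng)
                if not math.isfinite(h1):
                    continue
                if len(G2.migrations) > len(G.migrations):
                    m1 = G2.migrations[-2]
                    em = edge_migrations(G2)
                    i = [k for k, m in enumerate(em[m1.node]) if m.time == m1.time][0]
                    _, h2 = _migration_move(
                        G2, im_params, tun, rng, forced=("death", m1.node, i)
                    )
                else:
                    old_keys = {(m.node, m.time) for m in G.migrations}
                    new_keys = {(m.node, m.time) for m in G2.migrations}
                    (u, t1), (_, t2) = sorted(old_keys - new_keys, key=lambda x: x[1])
                    _, h2 = _migration_move(
                        G2, im_params, tun, rng, forced=("birth", u, t1, t2)
                    )
            assert h1 + h2 == pytest.approx(0.0, abs=1e-9)
            checked += 1
        assert checked > 300


class TestDivergenceUpdate:
    def test_lowering_deletes_window_migrations(self, rng):
        p = IMParameters(2, 2, 2, 1.0, 1.0, 2.0)
        for _ in range(50):
            G = simulate_genealogy(p, 3, 3, rng)
            if not G.migrations:
                continue
            t_new = 0.5 * max(m.time for m in G.migrations)
            out, logh = propose_divergence_update([G], p, t_new, rng)
            assert out is not None and math.isfinite(logh)
            assert all(m.time < t_new for m in out[0].migrations)

    def test_raise_then_lower_hastings_cancel(self, rng):
        p = IMParameters(2, 2, 2, 1.0, 1.0, 1.0)
        checked = 0
        for _ in range(200):
            G = simulate_genealogy(p, 3, 3, rng)
            t_new = 1.8
            out, h1 = propose_divergence_update([G], p, t_new, rng)
            if out is None:
                continue
            p2 = p.with_value("t_split", t_new)
            back, h2 = propose_divergence_update(out, p2, 1.0, rng)
            assert back is not None
            assert h1 + h2 == pytest.approx(0.0, abs=1e-9)
            # the round trip restores the original migration configuration
            a = sorted((m.node, m.time) for m in G.migrations)
            b = sorted((m.node, m.time) for m in back[0].migrations)
            assert a == b
            checked += 1
        assert checked > 50


def test_newick_export_smoke(im_params, rng):
    G = simulate_genealogy(im_params, 2, 2, rng)
    s = to_newick(G)
    assert s.endswith(";") and s.count("(") == G.N - 1
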