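"""Timed coalescent genealogies with migration under the isolation-with-migration model.

A genealogy for N sampled sequences is a timed binary tree with 2N-1 nodes:
leaves 0..N-1 at time 0 (population 1 first, then population 2) and N-1
internal coalescence nodes.  Time runs backward: 0 is the present and values
increase into the past, in mutational units (expected mutations per site).
Each non-root node has an edge toward its parent; migration events live on
edges and record the population switch of that lineage, backward in time,
at a specific time.  Below the divergence time ``t_split`` every lineage
carries a population label in {1, 2}; at ``t_split`` all surviving lineages
merge into the ancestral population and labels become irrelevant.

The genealogy prior is the structured coalescent: in any interval with k1
and k2 lineages in the two populations (below t_split) the total event rate
is k1(k1-1)/theta1 + k2(k2-1)/theta2 + k1*m1 + k2*m2; above t_split the k
remaining lineages coalesce at total rate k(k-1)/thetaA.  The log density
is the usual sum of log event rates minus rate integrals over inter-event
intervals.  Its sufficient statistics (event counts and rate integrals) are
extracted by a single sweep over the event times, so re-evaluating the
density after a scalar parameter update is O(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit

from .im_parameters import IMParameters

__all__ = [
    "Migration",
    "Genealogy",
    "MoveTuning",
    "validate",
    "total_branch_length",
    "coal_stats",
    "density_from_stats",
    "log_genealogy_density",
    "simulate_genealogy",
    "propose_genealogy_update",
    "node_populations",
    "edge_migrations",
    "to_newick",
]


@dataclass
class Migration:
    """A migration event on the edge above ``node``.

    Backward in time, at ``time`` the lineage switches from population
    ``source`` to population ``dest``.
    """

    node: int
    time: float
    source: int
    dest: int


@dataclass(eq=False)
class Genealogy:
    """Array-backed timed tree with population labels and migration events.

    time : (2N-1,) float, node times (leaves at 0)
    parent : (2N-1,) int, -1 for the root
    children : (2N-1, 2) int, -1 for leaves
    leaf_pop : (N,) int in {1, 2}
    migrations : list of Migration
    """

    time: np.ndarray
    parent: np.ndarray
    children: np.ndarray
    leaf_pop: np.ndarray
    migrations: list[Migration] = field(default_factory=list)

    # lazy caches, never copied; valid because moves build fresh copies
    # and mutate them only before handing the genealogy out
    _mig_arrays_cache: tuple | None = field(default=None, repr=False, compare=False)
    _pops_cache: np.ndarray | None = field(default=None, repr=False, compare=False)
    _emig_cache: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return int(self.time.shape[0])

    @property
    def N(self) -> int:
        return (self.n_nodes + 1) // 2

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def tmrca(self) -> float:
        return float(self.time.max())

    def is_leaf(self, v: int) -> bool:
        return self.children[v, 0] < 0

    def copy(self) -> "Genealogy":
        return Genealogy(
            self.time.copy(),
            self.parent.copy(),
            self.children.copy(),
            self.leaf_pop.copy(),
            [Migration(m.node, m.time, m.source, m.dest) for m in self.migrations],
        )


@dataclass
class MoveTuning:
    """Tuning knobs for the genealogy update moves."""

    root_scale: float = 0.7  # half-width of log-multiplier for root-time move


# ---------------------------------------------------------------------------
# helpers


def _mig_arrays(G: Genealogy) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Migration fields as flat arrays (cached on the genealogy)."""
    if G._mig_arrays_cache is None:
        n_mig = len(G.migrations)
        node = np.empty(n_mig, dtype=np.int64)
        time = np.empty(n_mig, dtype=np.float64)
        src = np.empty(n_mig, dtype=np.int64)
        dst = np.empty(n_mig, dtype=np.int64)
        for i, m in enumerate(G.migrations):
            node[i] = m.node
            time[i] = m.time
            src[i] = m.source
            dst[i] = m.dest
        G._mig_arrays_cache = (node, time, src, dst)
    return G._mig_arrays_cache


def edge_migrations(G: Genealogy) -> dict[int, list[Migration]]:
    """Migration events grouped per edge (keyed by the lower node), time-sorted."""
    if G._emig_cache is None:
        out: dict[int, list[Migration]] = {}
        for m in G.migrations:
            out.setdefault(m.node, []).append(m)
        for lst in out.values():
            lst.sort(key=lambda m: m.time)
        G._emig_cache = out
    return G._emig_cache


def _pop_on_edge(pop_at_node: int, migs: list[Migration], t: float) -> int:
    """Population of a lineage at time t, given its pop at the lower node."""
    p = pop_at_node
    for m in migs:
        if m.time <= t:
            p = m.dest
        else:
            break
    return p


@njit(cache=False)
def _pops_kernel(N, time, ch0, ch1, leaf_pop, mig_node, mig_time, mig_dst):
    n_nodes = time.shape[0]
    n_mig = mig_node.shape[0]
    n_ev = (N - 1) + n_mig
    ev_time = np.empty(n_ev)
    ev_id = np.empty(n_ev, np.int64)  # >=0 node (coal), <0 ~migration index
    k = 0
    for v in range(N, n_nodes):
        ev_time[k] = time[v]
        ev_id[k] = v
        k += 1
    for i in range(n_mig):
        ev_time[k] = mig_time[i]
        ev_id[k] = -(i + 1)
        k += 1
    order = np.argsort(ev_time)
    cur = np.zeros(n_nodes, np.int64)  # lineage pop, flipped by migrations
    out = np.zeros(n_nodes, np.int64)  # pop at the node's own time
    for i in range(N):
        cur[i] = leaf_pop[i]
        out[i] = leaf_pop[i]
    for j in range(n_ev):
        e = ev_id[order[j]]
        if e >= 0:
            out[e] = cur[ch0[e]]
            cur[e] = out[e]
        else:
            i = -e - 1
            cur[mig_node[i]] = mig_dst[i]
    return out


def node_populations(G: Genealogy) -> np.ndarray:
    """Population label of each node at its own time.

    Leaves carry ``leaf_pop``; an internal node inherits the label of its
    first child's lineage just below the coalescence.  (For a genealogy that
    satisfies the invariants both children agree below t_split; above
    t_split the label is vestigial.)  Cached per genealogy.
    """
    if G._pops_cache is None:
        node, time, src, dst = _mig_arrays(G)
        G._pops_cache = _pops_kernel(
            G.N,
            G.time,
            np.ascontiguousarray(G.children[:, 0]),
            np.ascontiguousarray(G.children[:, 1]),
            G.leaf_pop,
            node,
            time,
            dst,
        )
    return G._pops_cache


def total_branch_length(G: Genealogy) -> float:
    """Sum of edge lengths (parent time minus node time) over all non-root nodes."""
    mask = G.parent >= 0
    return float(np.sum(G.time[G.parent[mask]] - G.time[mask]))


def validate(G: Genealogy, params: IMParameters) -> list[str]:
    """Return a list of invariant violations (empty iff the genealogy is valid)."""
    out: list[str] = []
    N = G.N
    n_nodes = G.n_nodes
    if n_nodes != 2 * N - 1:
        out.append("node count is not 2N-1")
        return out
    leaves = [v for v in range(n_nodes) if G.is_leaf(v)]
    if sorted(leaves) != list(range(N)):
        out.append("leaves are not nodes 0..N-1")
    if not np.all(G.time[:N] == 0.0):
        out.append("leaves not at time 0")
    roots = np.flatnonzero(G.parent < 0)
    if len(roots) != 1:
        out.append("not exactly one root")
        return out
    root = int(roots[0])
    if G.time[root] < G.time.max():
        out.append("root time not maximal")
    for v in range(n_nodes):
        p = int(G.parent[v])
        if p >= 0:
            if v not in (int(G.children[p, 0]), int(G.children[p, 1])):
                out.append(f"node {v} not listed among its parent's children")
            if not G.time[v] < G.time[p]:
                out.append(f"node {v} time not below its parent's time")
        if not G.is_leaf(v):
            for c in G.children[v]:
                if int(G.parent[c]) != v:
                    out.append(f"child {int(c)} of node {v} has wrong parent")
    emig = edge_migrations(G)
    for m in G.migrations:
        p = int(G.parent[m.node])
        if p < 0:
            out.append(f"migration on root edge at t={m.time}")
            continue
        if not (G.time[m.node] < m.time < G.time[p]):
            out.append(f"migration at t={m.time} outside its edge")
        if m.time >= params.t_split:
            out.append(f"migration at t={m.time} not below t_split")
        if {m.source, m.dest} != {1, 2}:
            out.append(f"migration at t={m.time} has bad labels")
    # population-label consistency along every lineage
    pops = np.zeros(n_nodes, dtype=np.int64)
    pops[:N] = G.leaf_pop
    order = np.argsort(G.time, kind="stable")
    for v in order:
        v = int(v)
        if G.is_leaf(v):
            continue
        labels = []
        for c in G.children[v]:
            c = int(c)
            p = int(pops[c])
            for m in emig.get(c, []):
                if m.source != p:
                    out.append(
                        f"migration at t={m.time} source label mismatch on edge {c}"
                    )
                p = m.dest
            labels.append(p)
        if G.time[v] < params.t_split and labels[0] != labels[1]:
            out.append(f"coalescence {v} below t_split joins different populations")
        pops[v] = labels[0]
    times = np.concatenate([G.time[N:], [m.time for m in G.migrations]])
    if len(np.unique(times)) != len(times):
        out.append("tied event times")
    return out


# ---------------------------------------------------------------------------
# density


class CoalStats(NamedTuple):
    """Sufficient statistics of the structured-coalescent density.

    valid    : population labels / t_split consistent
    nc1, nc2 : coalescences in populations 1 and 2 (below t_split)
    ncA      : coalescences in the ancestral population
    nm12     : migrations of a lineage out of population 1 (rate m1)
    nm21     : migrations out of population 2 (rate m2)
    A1, A2   : integrals of k(k-1) dt per population below t_split
    AA       : integral of k(k-1) dt above t_split
    B1, B2   : integrals of k dt per population below t_split
    """

    valid: bool
    nc1: int
    nc2: int
    ncA: int
    nm12: int
    nm21: int
    A1: float
    A2: float
    AA: float
    B1: float
    B2: float


@njit(cache=False)
def _stats_kernel(N, time, ch0, ch1, leaf_pop, mig_node, mig_time, mig_src, mig_dst, t_split):
    n_nodes = time.shape[0]
    n_mig = mig_node.shape[0]
    n_ev = (N - 1) + n_mig
    ev_time = np.empty(n_ev)
    ev_kind = np.empty(n_ev, np.int64)  # 0 = coalescence, 1 = migration
    ev_id = np.empty(n_ev, np.int64)
    k = 0
    for v in range(N, n_nodes):
        ev_time[k] = time[v]
        ev_kind[k] = 0
        ev_id[k] = v
        k += 1
    for i in range(n_mig):
        ev_time[k] = mig_time[i]
        ev_kind[k] = 1
        ev_id[k] = i
        k += 1
    order = np.argsort(ev_time)

    pop = np.zeros(n_nodes, np.int64)
    k1 = 0
    k2 = 0
    for i in range(N):
        pop[i] = leaf_pop[i]
        if leaf_pop[i] == 1:
            k1 += 1
        else:
            k2 += 1
    t_prev = 0.0
    A1 = 0.0
    A2 = 0.0
    AA = 0.0
    B1 = 0.0
    B2 = 0.0
    nc1 = 0
    nc2 = 0
    ncA = 0
    nm12 = 0
    nm21 = 0
    for j in range(n_ev):
        idx = order[j]
        t = ev_time[idx]
        if t < t_prev:
            return (False, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
        if t_prev < t_split:
            seg = min(t, t_split) - t_prev
            A1 += k1 * (k1 - 1) * seg
            A2 += k2 * (k2 - 1) * seg
            B1 += k1 * seg
            B2 += k2 * seg
        if t > t_split:
            seg = t - max(t_prev, t_split)
            kk = k1 + k2
            AA += kk * (kk - 1) * seg
        if ev_kind[idx] == 0:
            v = ev_id[idx]
            p0 = pop[ch0[v]]
            p1 = pop[ch1[v]]
            if t < t_split:
                if p0 != p1:
                    return (False, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
                if p0 == 1:
                    nc1 += 1
                    k1 -= 1
                else:
                    nc2 += 1
                    k2 -= 1
            else:
                ncA += 1
                if p0 == 1:
                    k1 -= 1
                else:
                    k2 -= 1
            pop[v] = p0
        else:
            i = ev_id[idx]
            if t >= t_split:
                return (False, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
            u = mig_node[i]
            if pop[u] != mig_src[i]:
                return (False, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0)
            pop[u] = mig_dst[i]
            if mig_src[i] == 1:
                nm12 += 1
                k1 -= 1
                k2 += 1
            else:
                nm21 += 1
                k2 -= 1
                k1 += 1
        t_prev = t
    return (True, nc1, nc2, ncA, nm12, nm21, A1, A2, AA, B1, B2)


def coal_stats(G: Genealogy, t_split: float) -> CoalStats:
    """Sufficient statistics of the genealogy prior at a given divergence time."""
    mig_node, mig_time, mig_src, mig_dst = _mig_arrays(G)
    res = _stats_kernel(
        G.N,
        G.time,
        np.ascontiguousarray(G.children[:, 0]),
        np.ascontiguousarray(G.children[:, 1]),
        G.leaf_pop,
        mig_node,
        mig_time,
        mig_src,
        mig_dst,
        float(t_split),
    )
    return CoalStats(*res)


def density_from_stats(s: CoalStats, params: IMParameters) -> float:
    """Structured-coalescent log density from cached sufficient statistics."""
    if not s.valid:
        return -math.inf
    lp = 0.0
    for n_c, A, theta in (
        (s.nc1, s.A1, params.theta1),
        (s.nc2, s.A2, params.theta2),
        (s.ncA, s.AA, params.thetaA),
    ):
        if theta <= 0.0:
            if n_c > 0 or A > 0.0:
                return -math.inf
        else:
            if n_c:
                lp += n_c * math.log(2.0 / theta)
            lp -= A / theta
    for n_m, B, m in ((s.nm12, s.B1, params.m1), (s.nm21, s.B2, params.m2)):
        if m <= 0.0:
            if n_m > 0:
                return -math.inf
        else:
            if n_m:
                lp += n_m * math.log(m)
            lp -= B * m
    return lp


def log_genealogy_density(G: Genealogy, params: IMParameters, strict: bool = True) -> float:
    """Log prior density of a genealogy under the IM structured coalescent.

    With ``strict`` the genealogy is validated first and a ``ValueError``
    is raised on structural violations; otherwise inconsistent states
    simply get density ``-inf``.
    """
    if strict:
        bad = validate(G, params)
        if bad:
            raise ValueError("invalid genealogy: " + "; ".join(bad))
    return density_from_stats(coal_stats(G, params.t_split), params)


# ---------------------------------------------------------------------------
# simulation


def simulate_genealogy(
    params: IMParameters, N1: int, N2: int, rng: np.random.Generator
) -> Genealogy:
    """Draw a genealogy from the IM structured coalescent.

    Standard Gillespie simulation backward in time: exponential waiting
    times with the interval rates of :func:`log_genealogy_density`, event
    type chosen proportionally to its rate; at ``t_split`` all surviving
    lineages become ancestral.
    """
    N = N1 + N2
    if N < 2:
        raise ValueError("need at least two sequences")
    if params.thetaA <= 0:
        raise ValueError("thetaA must be positive")
    n_nodes = 2 * N - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    leaf_pop = np.array([1] * N1 + [2] * N2, dtype=np.int64)
    migrations: list[Migration] = []

    active: list[int] = list(range(N))
    pop = {i: int(leaf_pop[i]) for i in range(N)}
    t = 0.0
    next_node = N
    t_split = params.t_split

    # phase 1: two structured populations, below t_split
    while len(active) > 1 and t < t_split:
        k1 = sum(1 for v in active if pop[v] == 1)
        k2 = len(active) - k1
        if k1 >= 2 and params.theta1 <= 0:
            raise ValueError("theta1 must be positive with >=2 lineages in population 1")
        if k2 >= 2 and params.theta2 <= 0:
            raise ValueError("theta2 must be positive with >=2 lineages in population 2")
        rc1 = k1 * (k1 - 1) / params.theta1 if k1 >= 2 else 0.0
        rc2 = k2 * (k2 - 1) / params.theta2 if k2 >= 2 else 0.0
        rm1 = k1 * params.m1
        rm2 = k2 * params.m2
        total = rc1 + rc2 + rm1 + rm2
        if total <= 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_split:
            break
        t += dt
        u = rng.uniform(0.0, total)
        if u < rc1 + rc2:
            p = 1 if u < rc1 else 2
            members = [v for v in active if pop[v] == p]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
            v = next_node
            next_node += 1
            time[v] = t
            children[v] = (a, b)
            parent[a] = v
            parent[b] = v
            active.remove(a)
            active.remove(b)
            active.append(v)
            pop[v] = p
        else:
            p = 1 if u < rc1 + rc2 + rm1 else 2
            members = [v for v in active if pop[v] == p]
            w = members[int(rng.integers(len(members)))]
            migrations.append(Migration(w, t, p, 3 - p))
            pop[w] = 3 - p

    # phase 2: ancestral population
    t = max(t, t_split) if len(active) > 1 else t
    while len(active) > 1:
        k = len(active)
        total = k * (k - 1) / params.thetaA
        t += rng.exponential(1.0 / total)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        v = next_node
        next_node += 1
        time[v] = t
        children[v] = (a, b)
        parent[a] = v
        parent[b] = v
        active.remove(a)
        active.remove(b)
        active.append(v)
        pop[v] = pop[a]

    return Genealogy(time, parent, children, leaf_pop, migrations)


# ---------------------------------------------------------------------------
# MCMC moves
#
# Three reversible moves, chosen uniformly:
#   * node-time slide (internal nodes; log-multiplier for the root),
#   * lineage regraft by re-simulation under the structured coalescent
#     conditional on the remainder tree (exact path-density Hastings ratio),
#   * migration-pair birth/death on one edge.
# Each private move returns (new genealogy, log Hastings ratio); proposals
# that cannot produce a valid state return the input with -inf so the
# acceptance step rejects them.


def _subtree_nodes(G: Genealogy, v: int) -> set[int]:
    out = set()
    stack = [v]
    while stack:
        x = stack.pop()
        out.add(x)
        if not G.is_leaf(x):
            stack.append(int(G.children[x, 0]))
            stack.append(int(G.children[x, 1]))
    return out


def _slide_move(
    G: Genealogy,
    params: IMParameters,
    tuning: MoveTuning,
    rng: np.random.Generator,
    node: int | None = None,
    forced_time: float | None = None,
) -> tuple[Genealogy, float]:
    N = G.N
    if node is None:
        node = N + int(rng.integers(G.N - 1))
    emig = edge_migrations(G)
    lo = 0.0
    for c in G.children[node]:
        c = int(c)
        cl = float(G.time[c])
        migs = emig.get(c, [])
        if migs:
            cl = max(cl, migs[-1].time)
        lo = max(lo, cl)
    p = int(G.parent[node])
    if p >= 0:
        hi = float(G.time[p])
        own = emig.get(node, [])
        if own:
            hi = min(hi, own[0].time)
        if forced_time is None:
            new_t = rng.uniform(lo, hi)
        else:
            new_t = forced_time
            if not (lo < new_t < hi):
                return G, -math.inf
        logh = 0.0
    else:  # root: log-multiplier move
        old_t = float(G.time[node])
        if forced_time is None:
            new_t = old_t * math.exp(tuning.root_scale * (2.0 * rng.random() - 1.0))
        else:
            new_t = forced_time
            if abs(math.log(new_t / old_t)) > tuning.root_scale:
                return G, -math.inf
        if new_t <= lo:
            return G, -math.inf
        logh = math.log(new_t / old_t)
    G2 = G.copy()
    G2.time[node] = new_t
    return G2, logh


# --- regraft by lineage re-simulation ---------------------------------------


def _remainder_epochs(
    G: Genealogy, v: int, t_split: float
) -> tuple[list[tuple[float, float, dict[int, int]]], int]:
    """Epoch decomposition of the genealogy with lineage v's parent edge removed.

    Returns (epochs, s) where each epoch is (t0, t1, {lineage node: pop})
    covering [0, inf) with breaks at every remaining event time and at
    t_split, and s is the node whose edge absorbed the removed parent.
    """
    p = int(G.parent[v])
    s = int(G.children[p, 0]) if int(G.children[p, 1]) == v else int(G.children[p, 1])
    sub = _subtree_nodes(G, v)
    excluded = sub | {p}
    events: list[tuple[float, int, object]] = []  # (time, kind, payload)
    for x in range(G.n_nodes):
        if x < G.N or x in excluded:
            continue
        c0, c1 = int(G.children[x, 0]), int(G.children[x, 1])
        if c0 == p:
            c0 = s
        if c1 == p:
            c1 = s
        events.append((float(G.time[x]), 0, (x, c0, c1)))
    for m in G.migrations:
        if m.node in sub:
            continue
        u = s if m.node == p else m.node
        events.append((m.time, 1, (u, m.source, m.dest)))
    events.append((t_split, 2, None))
    events.sort(key=lambda e: e[0])

    active: dict[int, int] = {}
    for i in range(G.N):
        if i not in sub:
            active[i] = int(G.leaf_pop[i])
    epochs: list[tuple[float, float, dict[int, int]]] = []
    t0 = 0.0
    for t1, kind, payload in events:
        if t1 > t0:
            epochs.append((t0, t1, dict(active)))
            t0 = t1
        if kind == 0:
            x, c0, c1 = payload
            pcur = active.pop(c0)
            active.pop(c1)
            active[x] = pcur
        elif kind == 1:
            u, src, dst = payload
            active[u] = dst
    epochs.append((t0, math.inf, dict(active)))
    return epochs, s


def _epoch_rates(
    epoch: tuple[float, float, dict[int, int]],
    pop: int,
    params: IMParameters,
    t_split: float,
) -> tuple[float, float, list[int]]:
    """(migration rate, per-partner coalescence rate, eligible partners)."""
    t0, _, active = epoch
    if t0 < t_split:
        mu = params.m1 if pop == 1 else params.m2
        partners = [u for u, q in active.items() if q == pop]
        theta = params.theta1 if pop == 1 else params.theta2
        each = 2.0 / theta if theta > 0 else math.inf
    else:
        mu = 0.0
        partners = list(active.keys())
        each = 2.0 / params.thetaA
    return mu, each, partners


def _score_path(
    epochs,
    params: IMParameters,
    t_split: float,
    t0: float,
    pop0: int,
    migs: list[tuple[float, int, int]],
    coal_time: float,
    partner: int,
) -> float:
    """Log proposal density of a lineage path under the conditional simulation law."""
    lp = 0.0
    pop = pop0
    ei = 0
    while epochs[ei][1] <= t0:
        ei += 1
    t = t0
    path = [(mt, 1, (src, dst)) for mt, src, dst in migs] + [(coal_time, 0, partner)]
    for etime, kind, payload in path:
        if etime < t:
            return -math.inf
        while epochs[ei][1] <= etime:
            mu, each, partners = _epoch_rates(epochs[ei], pop, params, t_split)
            total = mu + each * len(partners)
            if not math.isfinite(total):
                return -math.inf
            lp -= total * (epochs[ei][1] - t)
            t = epochs[ei][1]
            ei += 1
        mu, each, partners = _epoch_rates(epochs[ei], pop, params, t_split)
        total = mu + each * len(partners)
        if not math.isfinite(total):
            return -math.inf
        lp -= total * (etime - t)
        t = etime
        if kind == 1:
            src, dst = payload
            if src != pop or mu <= 0.0:
                return -math.inf
            lp += math.log(mu)
            pop = dst
        else:
            if payload not in partners or each <= 0.0:
                return -math.inf
            lp += math.log(each)
    return lp


def _sim_path(
    epochs,
    params: IMParameters,
    t_split: float,
    t0: float,
    pop0: int,
    rng: np.random.Generator,
    max_events: int = 10000,
) -> tuple[list[tuple[float, int, int]], float, int] | None:
    """Simulate a lineage path; returns (migrations, coalescence time, partner)."""
    pop = pop0
    migs: list[tuple[float, int, int]] = []
    ei = 0
    while epochs[ei][1] <= t0:
        ei += 1
    t = t0
    for _ in range(max_events):
        e = epochs[ei]
        mu, each, partners = _epoch_rates(e, pop, params, t_split)
        total = mu + each * len(partners)
        if total <= 0.0 or not math.isfinite(total):
            if not math.isfinite(total) or not math.isfinite(e[1]):
                return None  # degenerate rates; caller rejects
            t = e[1]
            ei += 1
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= e[1]:
            t = e[1]
            ei += 1
            continue
        t += dt
        if rng.uniform(0.0, total) < mu:
            migs.append((t, pop, 3 - pop))
            pop = 3 - pop
        else:
            partner = partners[int(rng.integers(len(partners)))]
            return migs, t, partner
    return None


def _regraft_move(
    G: Genealogy,
    params: IMParameters,
    tuning: MoveTuning,
    rng: np.random.Generator,
    v: int | None = None,
    forced_path: tuple[list[tuple[float, int, int]], float, int] | None = None,
) -> tuple[Genealogy, float]:
    root = G.root
    if v is None:
        cand = [x for x in range(G.n_nodes) if x != root]
        v = cand[int(rng.integers(len(cand)))]
    t_split = params.t_split
    pops = node_populations(G)
    pop0 = int(pops[v])
    p = int(G.parent[v])
    emig = edge_migrations(G)
    old_migs = [(m.time, m.source, m.dest) for m in emig.get(v, [])]
    old_coal_time = float(G.time[p])

    epochs, s = _remainder_epochs(G, v, t_split)
    if forced_path is None:
        sim = _sim_path(epochs, params, t_split, float(G.time[v]), pop0, rng)
        if sim is None:
            return G, -math.inf
    else:
        sim = forced_path
    new_migs, new_coal_time, partner = sim

    logq_fwd = _score_path(
        epochs, params, t_split, float(G.time[v]), pop0, new_migs, new_coal_time, partner
    )
    logq_rev = _score_path(
        epochs, params, t_split, float(G.time[v]), pop0, old_migs, old_coal_time, s
    )
    if not math.isfinite(logq_fwd):
        return G, -math.inf

    # rebuild: detach p, extend s to g, then insert p on the partner lineage
    G2 = G.copy()
    sub = _subtree_nodes(G, v)
    g = int(G2.parent[p])
    G2.parent[s] = g
    if g >= 0:
        G2.children[g, 0 if int(G2.children[g, 0]) == p else 1] = s
    G2.migrations = [m for m in G2.migrations if not (m.node == v)]
    for m in G2.migrations:
        if m.node == p:
            m.node = s
    # the partner lineage is identified by its lower node; find its current parent
    w = partner
    pw = int(G2.parent[w])
    G2.time[p] = new_coal_time
    G2.children[p] = (v, w)
    G2.parent[v] = p
    G2.parent[w] = p
    G2.parent[p] = pw
    if pw >= 0:
        G2.children[pw, 0 if int(G2.children[pw, 0]) == w else 1] = p
    # migrations on w's edge above the new coalescence move to p's edge
    for m in G2.migrations:
        if m.node == w and m.time > new_coal_time:
            m.node = p
    for mt, src, dst in new_migs:
        G2.migrations.append(Migration(v, mt, src, dst))
    # the remainder's root lineage is unbounded during simulation; if its
    # migration history ends up above the new root, the state is invalid
    new_root = int(np.flatnonzero(G2.parent < 0)[0])
    for m in G2.migrations:
        if m.node == new_root:
            return G, -math.inf
    return G2, logq_rev - logq_fwd


# --- migration-pair birth/death ---------------------------------------------


def _mig_pair_intervals(G: Genealogy, t_split: float) -> list[tuple[int, float, float]]:
    """Edges with positive overlap with [node time, min(parent time, t_split))."""
    nonroot = np.flatnonzero(G.parent >= 0)
    lo = G.time[nonroot]
    hi = np.minimum(G.time[G.parent[nonroot]], t_split)
    keep = hi > lo
    return list(zip(nonroot[keep].tolist(), lo[keep].tolist(), hi[keep].tolist()))


def _adjacent_pairs(G: Genealogy) -> list[tuple[int, int]]:
    """(edge node, index of first event) for every adjacent same-edge event pair."""
    emig = edge_migrations(G)
    out = []
    for u, migs in emig.items():
        for i in range(len(migs) - 1):
            out.append((u, i))
    return out


def _migration_move(
    G: Genealogy,
    params: IMParameters,
    tuning: MoveTuning,
    rng: np.random.Generator,
    forced: tuple | None = None,
) -> tuple[Genealogy, float]:
    t_split = params.t_split
    intervals = _mig_pair_intervals(G, t_split)
    if not intervals:
        return G, -math.inf
    n_edges = len(intervals)
    if forced is None:
        birth = rng.random() < 0.5
    else:
        birth = forced[0] == "birth"
    if birth:
        if forced is None:
            u, lo, hi = intervals[int(rng.integers(n_edges))]
            t1, t2 = sorted(rng.uniform(lo, hi, size=2))
        else:
            _, u, t1, t2 = forced
            match = [iv for iv in intervals if iv[0] == u]
            if not match or not (match[0][1] < t1 < t2 < match[0][2]):
                return G, -math.inf
            lo, hi = match[0][1], match[0][2]
        emig = edge_migrations(G)
        own = emig.get(u, [])
        if any(t1 < m.time < t2 for m in own):
            return G, -math.inf
        pops = node_populations(G)
        a = _pop_on_edge(int(pops[u]), own, t1)
        b = 3 - a
        G2 = G.copy()
        G2.migrations.append(Migration(u, t1, a, b))
        G2.migrations.append(Migration(u, t2, b, a))
        n_pairs_new = len(_adjacent_pairs(G2))
        ell = hi - lo
        logh = math.log(n_edges * ell * ell / (2.0 * n_pairs_new))
        return G2, logh
    else:
        pairs = _adjacent_pairs(G)
        if not pairs:
            return G, -math.inf
        if forced is None:
            u, i = pairs[int(rng.integers(len(pairs)))]
        else:
            _, u, i = forced
            if (u, i) not in pairs:
                return G, -math.inf
        emig = edge_migrations(G)
        m1, m2 = emig[u][i], emig[u][i + 1]
        match = [iv for iv in intervals if iv[0] == u]
        if not match:
            return G, -math.inf
        lo, hi = match[0][1], match[0][2]
        ell = hi - lo
        G2 = G.copy()
        removed = 0
        kept = []
        for m in G2.migrations:
            if removed < 2 and m.node == u and m.time in (m1.time, m2.time):
                removed += 1
                continue
            kept.append(m)
        G2.migrations = kept
        n_pairs = len(pairs)
        logh = math.log(2.0 * n_pairs / (n_edges * ell * ell))
        return G2, logh


_MOVES = (_slide_move, _regraft_move, _migration_move)


def _propose_with_stats(
    G: Genealogy,
    params: IMParameters,
    tuning: MoveTuning,
    rng: np.random.Generator,
    move: int | None = None,
) -> tuple[Genealogy, float, CoalStats | None]:
    if move is None:
        move = int(rng.integers(3))
    G2, logh = _MOVES[move](G, params, tuning, rng)
    if math.isinf(logh) and logh < 0:
        return G, -math.inf, None
    stats = coal_stats(G2, params.t_split)
    if not stats.valid:
        return G, -math.inf, None
    return G2, logh, stats


def propose_genealogy_update(
    G: Genealogy,
    params: IMParameters,
    tuning: MoveTuning,
    rng: np.random.Generator,
    move: int | None = None,
) -> tuple[Genealogy, float]:
    """One reversible genealogy move (slide / regraft / migration birth-death).

    Returns the proposed genealogy and the exact log Hastings ratio;
    proposals that cannot yield a valid state return the input with -inf.
    """
    G2, logh, _ = _propose_with_stats(G, params, tuning, rng, move)
    return G2, logh


# ---------------------------------------------------------------------------
# divergence-time move with migration-path augmentation
#
# A plain sliding-window update of t_split cannot raise the divergence past
# an ancestral coalescence whose lineages carry discordant (frozen)
# population labels: every such proposal is invalid until the genealogy
# itself rearranges, which freezes the chain.  The move implemented here
# sweeps the window (t_old, t_new) jointly with the genealogies: raising
# t_split simulates fresh migration paths for every lineage segment in the
# window (free two-state migration at rates m1, m2, rejecting on label
# mismatch at coalescences); lowering it deletes the paths in the window.
# The Hastings ratio is the exact free-path density of the deleted pieces
# minus that of the created pieces, making the joint move reversible.


def _window_prep(G: Genealogy, t_lo: float, t_hi: float):
    """Per-edge overlaps with [t_lo, t_hi) and lineage pops at segment starts.

    Returns (nodes, starts, ends, start_pop) with segments sorted by start
    time; ``start_pop[v]`` is the population of lineage v at
    max(node time, t_lo), derived from the sub-window migration history
    (each migration below t_lo toggles the label).
    """
    parent = G.parent
    nonroot = np.flatnonzero(parent >= 0)
    a = np.maximum(G.time[nonroot], t_lo)
    b = np.minimum(G.time[parent[nonroot]], t_hi)
    keep = b > a
    vs = nonroot[keep]
    a = a[keep]
    b = b[keep]
    order = np.argsort(a, kind="stable")
    vs, a, b = vs[order], a[order], b[order]
    pops = node_populations(G)
    node_arr, time_arr, _, _ = _mig_arrays(G)
    if node_arr.size:
        flips = np.bincount(node_arr[time_arr < t_lo], minlength=G.n_nodes)
        start_pop = np.where((flips % 2) == 1, 3 - pops, pops)
    else:
        start_pop = pops
    return vs, a, b, start_pop


def _replay_window_paths(
    G: Genealogy,
    t_lo: float,
    t_hi: float,
    params: IMParameters,
    events_by_edge: dict[int, list[tuple[float, int, int]]],
    prep=None,
) -> float:
    """Free-migration-path log density of the given window events.

    Scores, per lineage segment inside [t_lo, t_hi), the two-state
    migration process (rates m1 out of population 1, m2 out of 2) realizing
    exactly the listed (time, source, dest) events, and checks label
    concordance at coalescences inside the window.  Returns -inf for an
    inconsistent configuration.
    """
    vs, starts, ends, start_pop = prep if prep is not None else _window_prep(G, t_lo, t_hi)
    end_pop: dict[int, int] = {}
    lq = 0.0
    N = G.N
    for a, b, v in zip(starts, ends, vs):
        v = int(v)
        if v >= N and G.time[v] >= t_lo:
            c0, c1 = int(G.children[v, 0]), int(G.children[v, 1])
            p0 = end_pop.get(c0, int(start_pop[c0]))
            p1 = end_pop.get(c1, int(start_pop[c1]))
            if p0 != p1:
                return -math.inf
            pop = p0
        else:
            pop = int(start_pop[v])
        t = a
        for mt, src, dst in events_by_edge.get(v, ()):
            if not (a <= mt < b) or src != pop:
                return -math.inf
            m_rate = params.m1 if pop == 1 else params.m2
            if m_rate <= 0:
                return -math.inf
            lq += math.log(m_rate) - m_rate * (mt - t)
            t = mt
            pop = dst
        m_rate = params.m1 if pop == 1 else params.m2
        lq -= m_rate * (b - t)
        end_pop[v] = pop
    return lq


def _simulate_window_paths(
    G: Genealogy,
    t_lo: float,
    t_hi: float,
    params: IMParameters,
    rng: np.random.Generator,
    prep=None,
) -> dict[int, list[tuple[float, int, int]]] | None:
    """Draw free migration paths for every lineage segment in [t_lo, t_hi).

    Returns the per-edge event lists, or None when the drawn labels
    disagree at a coalescence inside the window (the caller rejects).
    """
    vs, starts, ends, start_pop = prep if prep is not None else _window_prep(G, t_lo, t_hi)
    end_pop: dict[int, int] = {}
    events: dict[int, list[tuple[float, int, int]]] = {}
    N = G.N
    for a, b, v in zip(starts, ends, vs):
        v = int(v)
        if v >= N and G.time[v] >= t_lo:
            c0, c1 = int(G.children[v, 0]), int(G.children[v, 1])
            p0 = end_pop.get(c0, int(start_pop[c0]))
            p1 = end_pop.get(c1, int(start_pop[c1]))
            if p0 != p1:
                return None
            pop = p0
        else:
            pop = int(start_pop[v])
        t = a
        while True:
            m_rate = params.m1 if pop == 1 else params.m2
            if m_rate <= 0:
                break
            t = t + rng.exponential(1.0 / m_rate)
            if t >= b:
                break
            events.setdefault(v, []).append((t, pop, 3 - pop))
            pop = 3 - pop
        end_pop[v] = pop
    return events


def propose_divergence_update(
    genealogies: list[Genealogy],
    params: IMParameters,
    t_new: float,
    rng: np.random.Generator,
) -> tuple[list[Genealogy] | None, float]:
    """Joint (t_split, migration paths) update for all loci.

    Given a proposed divergence time, returns the updated genealogies and
    the log Hastings ratio of the path augmentation, or (None, -inf) when
    the drawn paths are inconsistent and the move must be rejected.
    """
    t_old = params.t_split
    if t_new == t_old:
        return genealogies, 0.0
    t_lo, t_hi = (t_new, t_old) if t_new < t_old else (t_old, t_new)
    logh = 0.0
    out = []
    for G in genealogies:
        prep = _window_prep(G, t_lo, t_hi)
        if t_new < t_old:
            doomed: dict[int, list[tuple[float, int, int]]] = {}
            for m in G.migrations:
                if t_lo <= m.time < t_hi:
                    doomed.setdefault(m.node, []).append((m.time, m.source, m.dest))
            for lst in doomed.values():
                lst.sort()
            lq = _replay_window_paths(G, t_lo, t_hi, params, doomed, prep)
            if not math.isfinite(lq):
                return None, -math.inf
            G2 = G.copy()
            G2.migrations = [m for m in G2.migrations if not (t_lo <= m.time < t_hi)]
            logh += lq
        else:
            drawn = _simulate_window_paths(G, t_lo, t_hi, params, rng, prep)
            if drawn is None:
                return None, -math.inf
            lq = _replay_window_paths(G, t_lo, t_hi, params, drawn, prep)
            if not math.isfinite(lq):
                return None, -math.inf
            G2 = G.copy()
            for v, lst in drawn.items():
                for mt, src, dst in lst:
                    G2.migrations.append(Migration(v, mt, src, dst))
            logh -= lq
        out.append(G2)
    return out, logh


# ---------------------------------------------------------------------------
# export


def to_newick(G: Genealogy) -> str:
    """Newick string with migration events as comments (debugging aid)."""
    emig = edge_migrations(G)

    def rec(v: int) -> str:
        if G.is_leaf(v):
            lab = f"n{v}_p{int(G.leaf_pop[v])}"
        else:
            c0, c1 = int(G.children[v, 0]), int(G.children[v, 1])
            lab = f"({rec(c0)},{rec(c1)})n{v}"
        p = int(G.parent[v])
        if p < 0:
            return lab
        bl = float(G.time[p] - G.time[v])
        migs = emig.get(v, [])
        com = ""
        if migs:
            com = "[&mig={" + ",".join(f"{m.time:.6g}:{m.source}->{m.dest}" for m in migs) + "}]"
        return f"{lab}:{bl:.10g}{com}"

    return rec(G.root) + ";"
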