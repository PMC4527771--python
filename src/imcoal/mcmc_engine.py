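"""Metropolis-Hastings sampling over (parameters, genealogies) with optional
Metropolis coupling.

Each generation performs a fixed deterministic scan: one reflected
sliding-window move per model parameter, one per-locus kappa move when the
HKY transition/transversion ratio is sampled, and one genealogy move per
locus.  The target is the joint posterior

    P(theta, G | D)  propto  prod_l P(D_l | G_l) P(G_l | theta) P(theta)

with the sequence likelihood evaluated under HKY (pruning) or infinite
sites (mutation mapping) per locus tag, and the genealogy prior given by
the structured coalescent.  Heated chains raise the posterior ratio to a
tempering exponent beta in (0, 1]; adjacent-temperature chains attempt one
state swap per generation, and only the cold chain (beta = 1) is recorded.

Per-locus likelihoods, genealogy-prior sufficient statistics, and the
parameter log prior are cached and updated incrementally; every
``audit_every`` generations the caches are recomputed from scratch and a
mismatch beyond 1e-8 raises, which catches incremental-update bugs in long
runs.  A chain-local random stream per chain (all derived from one master
seed) makes runs bit-reproducible.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .genealogy import (
    CoalStats,
    Genealogy,
    Migration,
    MoveTuning,
    _propose_with_stats,
    coal_stats,
    density_from_stats,
    propose_divergence_update,
    simulate_genealogy,
)
from .im_parameters import (
    PARAM_NAMES,
    IMParameters,
    PriorSpec,
    _reflect,
    log_prior,
    propose_scalar_update,
    sample_prior,
)
from .io_formats import Dataset, Locus, TraceRecord
from .likelihood_hky import HKYModel, empirical_base_frequencies, hky_total_loglik
from .likelihood_is import (
    clade_index,
    clade_masks,
    is_log_likelihood,
    polarize_and_map_sites,
)

__all__ = [
    "RunConfig",
    "ChainState",
    "mh_accept_probability",
    "heating_schedule",
    "mc3_swap",
    "mcmc_run",
]


@dataclass
class RunConfig:
    """Run-length, proposal and engine settings.

    Defaults mirror the benchmark runs this sampler family is evaluated
    with: 10,000 burn-in and 10,000 sampling generations, uniform prior
    bounds of 10, a single chain.
    """

    burn_in: int = 10_000
    generations: int = 10_000
    n_chains: int = 1
    heat_lambda: float = 0.05
    sample_every: int = 10
    seed: int = 0
    windows: dict[str, float] | None = None  # default: prior bound / 5
    move_tuning: MoveTuning = field(default_factory=MoveTuning)
    kappa: object = "sample"  # "sample" or a fixed float
    kappa_bound: float = 100.0
    kappa_window: float = 10.0
    pi: object = "empirical"  # "empirical" or a 4-tuple
    block_size: int = 256
    audit_every: int = 2000
    likelihood: str = "on"  # "off" disables the sequence likelihood
    tempering: str = "posterior"  # or "likelihood"
    polarity: str = "ancestral"  # IS polarization mode
    init: str = "moment"  # starting point: "moment" (data-informed) or "prior"
    init_attempts: int = 100
    log_every: int = 0  # progress lines to stderr; 0 = silent

    def __post_init__(self):
        if self.burn_in < 0 or self.generations < 0:
            raise ValueError("generation counts must be >= 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.likelihood not in ("on", "off"):
            raise ValueError("likelihood must be 'on' or 'off'")
        if self.tempering not in ("posterior", "likelihood"):
            raise ValueError("tempering must be 'posterior' or 'likelihood'")


@dataclass
class ChainState:
    """Full state of one chain plus its caches."""

    params: IMParameters
    genealogies: list[Genealogy]
    kappas: list[float | None]
    loglik_per_locus: list[float]
    gen_stats: list[CoalStats]
    gen_dens: list[float]
    logprior: float
    beta: float
    rng: np.random.Generator


def mh_accept_probability(
    log_post_new: float, log_post_old: float, log_hastings: float, beta: float = 1.0
) -> float:
    """Metropolis-Hastings acceptance probability with posterior tempering.

    min(1, exp(beta * (log_post_new - log_post_old) + log_hastings)).
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("beta must be in (0, 1]")
    if math.isinf(log_post_new) and math.isinf(log_post_old):
        if log_post_new < 0 and log_post_old < 0:
            raise ValueError("chain must never occupy a zero-posterior state")
    if math.isinf(log_post_new) and log_post_new < 0:
        return 0.0
    exponent = beta * (log_post_new - log_post_old) + log_hastings
    return 1.0 if exponent >= 0 else math.exp(exponent)


def heating_schedule(n_chains: int, heat_lambda: float) -> tuple[float, ...]:
    """Incremental heating: beta_k = 1 / (1 + lambda * k), k = 0..n-1."""
    if n_chains < 1:
        raise ValueError("need at least one chain")
    if heat_lambda <= 0:
        raise ValueError("heating increment must be positive")
    return tuple(1.0 / (1.0 + heat_lambda * k) for k in range(n_chains))


def _unheated_logpost(ch: ChainState) -> float:
    return sum(ch.loglik_per_locus) + sum(ch.gen_dens) + ch.logprior


def mc3_swap(
    cold: ChainState, hot: ChainState, rng: np.random.Generator
) -> tuple[ChainState, ChainState, bool]:
    """Attempt a Metropolis-coupled state exchange between two chains.

    Accepted with probability min(1, exp((beta_cold - beta_hot) *
    (logpost_hot_state - logpost_cold_state))).  On acceptance the full
    states (parameters, genealogies, caches) exchange while the tempering
    exponents and random streams stay with the chain slots.
    """
    lp_cold = _unheated_logpost(cold)
    lp_hot = _unheated_logpost(hot)
    exponent = (cold.beta - hot.beta) * (lp_hot - lp_cold)
    accepted = exponent >= 0 or math.log(rng.random()) < exponent
    if accepted:
        for name in ("params", "genealogies", "kappas", "loglik_per_locus",
                     "gen_stats", "gen_dens", "logprior"):
            a, b = getattr(cold, name), getattr(hot, name)
            setattr(cold, name, b)
            setattr(hot, name, a)
    return cold, hot, accepted


# ---------------------------------------------------------------------------
# per-locus preprocessing


class _LocusWork:
    """Preprocessed per-locus data and the likelihood dispatch."""

    def __init__(self, locus: Locus, config: RunConfig):
        self.locus = locus
        self.kind = locus.model
        self.u = locus.u
        self.n1 = locus.N1
        self.n2 = locus.N2
        self.block_size = config.block_size
        self.polarity = config.polarity
        aln = locus.alignment
        if self.kind == "HKY":
            if config.pi == "empirical":
                self.pi = tuple(empirical_base_frequencies(aln))
            else:
                self.pi = tuple(float(x) for x in config.pi)
        else:
            self._prep_is(aln)

    def _prep_is(self, aln: np.ndarray):
        poly = np.flatnonzero(np.any(aln != aln[0], axis=0))
        counts: dict[tuple[bytes, ...], int] = {}
        if self.polarity == "ancestral":
            anc = self.locus.ancestral
            if anc is None:
                raise ValueError(
                    f"IS locus {self.locus.name}: ancestral designation required"
                )
            for j in poly:
                col = aln[:, j]
                alleles = np.unique(col)
                if len(alleles) != 2 or anc[j] not in alleles:
                    raise ValueError(
                        f"IS locus {self.locus.name}: site {j} incompatible with the "
                        "infinite-sites model under any genealogy"
                    )
                derived = alleles[0] if alleles[1] == anc[j] else alleles[1]
                carriers = col == derived
                if carriers.all():
                    raise ValueError(
                        f"IS locus {self.locus.name}: site {j} derived in all samples"
                    )
                key = (np.packbits(carriers).tobytes(),)
                counts[key] = counts.get(key, 0) + 1
        else:
            for j in poly:
                col = aln[:, j]
                alleles = np.unique(col)
                if len(alleles) != 2:
                    raise ValueError(
                        f"IS locus {self.locus.name}: site {j} has >2 alleles"
                    )
                m0 = col == alleles[0]
                small, large = sorted((m0, ~m0), key=lambda m: int(m.sum()))
                key = (np.packbits(small).tobytes(), np.packbits(large).tobytes())
                counts[key] = counts.get(key, 0) + 1
        self.patterns = sorted(counts.items())
        # carrier sets as boolean masks, for the perfect-phylogeny initializer
        self.carrier_masks = [
            np.unpackbits(
                np.frombuffer(key[0], dtype=np.uint8), count=aln.shape[0]
            ).astype(bool)
            for key, _ in self.patterns
        ]
        # vectorized lookup path for modest sample sizes under fixed polarity
        self._fast = self.polarity == "ancestral" and aln.shape[0] <= 63
        if self._fast:
            N = aln.shape[0]
            masks, cnts = [], []
            for mask_bool, (_, cnt) in zip(self.carrier_masks, self.patterns):
                bits = np.uint64(0)
                for i in np.flatnonzero(mask_bool):
                    bits |= np.uint64(1) << np.uint64(i)
                masks.append(bits)
                cnts.append(cnt)
            self._pat_masks = np.array(masks, dtype=np.uint64)
            self._pat_counts = np.array(cnts, dtype=np.float64)
            self._pat_lgam = gammaln(self._pat_counts + 1.0).sum()

    def loglik(self, G: Genealogy, kappa: float | None = None) -> float:
        if self.kind == "HKY":
            model = HKYModel(self.pi, kappa)
            return hky_total_loglik(
                G, self.locus.alignment, model, self.u, self.block_size
            )
        if self.polarity == "either":
            mapping = polarize_and_map_sites(
                G, self.locus.alignment, None, "either"
            )
            return is_log_likelihood(mapping, G, self.u)
        # fast path: distinct patterns map to distinct branches, so the
        # per-pattern factorial term equals the per-branch one
        mask = G.parent >= 0
        edge_len = np.where(mask, G.time[G.parent] - G.time, 0.0)
        BT = float(edge_len.sum())
        if self._fast:
            if not self._pat_masks.size:
                return -BT * self.u
            node_masks = clade_masks(G)
            order = np.argsort(node_masks)
            pos = np.searchsorted(node_masks[order], self._pat_masks)
            if np.any(pos >= node_masks.size):
                return -math.inf
            nodes = order[pos]
            if not np.array_equal(node_masks[nodes], self._pat_masks):
                return -math.inf
            B = edge_len[nodes]
            if np.any(B <= 0):
                return -math.inf
            return float(
                -BT * self.u
                + np.sum(self._pat_counts * np.log(B * self.u))
                - self._pat_lgam
            )
        idx = clade_index(G)
        ll = -BT * self.u
        for key, cnt in self.patterns:
            v = idx.get(key[0])
            if v is None:
                return -math.inf
            B = float(edge_len[v])
            ll += cnt * math.log(B * self.u) - float(gammaln(cnt + 1.0))
        return ll


# ---------------------------------------------------------------------------
# initialization


def _harmonic(n: int) -> float:
    return sum(1.0 / k for k in range(1, n)) if n > 1 else 0.0


def _moment_initial_params(
    works: list[_LocusWork], priors: PriorSpec, rng: np.random.Generator
) -> IMParameters:
    """Watterson-style moment estimates as the chain's starting point.

    theta_p from within-population segregating sites, theta_A from their
    mean, the divergence time from net between-population differences, and
    small migration rates.  Each value is jittered by up to +-20% per chain
    and clamped into the prior support; only the transient is affected.
    """
    th1s, th2s, dbs = [], [], []
    for w in works:
        aln = w.locus.alignment
        n1 = w.n1
        u = w.u
        pop1, pop2 = aln[:n1], aln[n1:]
        S1 = int(np.any(pop1 != pop1[0], axis=0).sum()) if n1 > 1 else 0
        S2 = int(np.any(pop2 != pop2[0], axis=0).sum()) if w.n2 > 1 else 0
        if n1 > 1:
            th1s.append(S1 / (_harmonic(n1) * u))
        if w.n2 > 1:
            th2s.append(S2 / (_harmonic(w.n2) * u))
        # mean pairwise between-population difference, in mutation units
        diffs = [
            int((pop1[i] != pop2[j]).sum())
            for i in range(min(n1, 5))
            for j in range(min(w.n2, 5))
        ]
        dbs.append(float(np.mean(diffs)) / u)
    th1 = float(np.mean(th1s)) if th1s else priors.theta1 / 2
    th2 = float(np.mean(th2s)) if th2s else priors.theta2 / 2
    thA = 0.5 * (th1 + th2)
    db = float(np.mean(dbs)) if dbs else priors.t_split / 2
    t0 = max(0.05, (db - thA) / 2.0)
    vals = {
        "theta1": th1, "theta2": th2, "thetaA": thA,
        "m1": 0.1, "m2": 0.1, "t_split": t0,
    }
    out = {}
    for name, v in vals.items():
        v *= math.exp(rng.uniform(-0.2, 0.2))
        bound = priors.bound(name)
        out[name] = min(max(v, 0.02 * bound), 0.95 * bound)
    return IMParameters(**out)


def _perfect_phylogeny_genealogy(
    work: _LocusWork, params: IMParameters, rng: np.random.Generator
) -> Genealogy:
    """Build a genealogy compatible with an IS locus's carrier sets.

    The carrier sets of a data set generated under infinite sites form a
    laminar family, so a tree realizing every set as a clade exists; joins
    inside each set are resolved randomly, times follow a coalescent-like
    clock under thetaA, and population labels are harmonized by inserting
    migration events below discordant coalescences.
    """
    locus = work.locus
    N = locus.N
    n_nodes = 2 * N - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    leaf_pop = locus.pop_labels.copy()

    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(N)}
    next_node = N
    t = 0.0
    theta = max(params.thetaA, 1e-3)

    def join(a: int, b: int) -> int:
        nonlocal next_node, t
        k = len(clusters)
        t += rng.exponential(theta / (k * (k - 1)))
        v = next_node
        next_node += 1
        time[v] = t
        children[v] = (a, b)
        parent[a] = v
        parent[b] = v
        clusters[v] = clusters.pop(a) | clusters.pop(b)
        return v

    sets = sorted(
        {frozenset(np.flatnonzero(m)) for m in work.carrier_masks}, key=len
    )
    for S in sets:
        if len(S) < 2:
            continue
        members = [c for c, ls in clusters.items() if ls <= S]
        covered = frozenset().union(*(clusters[c] for c in members)) if members else frozenset()
        if covered != S:
            raise ValueError(
                f"IS locus {locus.name}: carrier sets are not laminar; "
                "no genealogy is compatible with the data"
            )
        while len(members) > 1:
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
            v = join(a, b)
            members = [c for c in members if c not in (a, b)] + [v]
    remaining = list(clusters.keys())
    while len(remaining) > 1:
        i, j = rng.choice(len(remaining), size=2, replace=False)
        a, b = remaining[int(i)], remaining[int(j)]
        v = join(a, b)
        remaining = [c for c in remaining if c not in (a, b)] + [v]

    G = Genealogy(time, parent, children, leaf_pop, [])
    # harmonize population labels below t_split with migration events
    t_split = params.t_split
    cur_pop = np.zeros(n_nodes, dtype=np.int64)
    cur_pop[:N] = leaf_pop
    for v in np.argsort(G.time, kind="stable"):
        v = int(v)
        if G.is_leaf(v):
            continue
        c0, c1 = int(children[v, 0]), int(children[v, 1])
        p0, p1 = int(cur_pop[c0]), int(cur_pop[c1])
        if time[v] < t_split and p0 != p1:
            lower = float(time[c1])
            for m in G.migrations:
                if m.node == c1:
                    lower = max(lower, m.time)
            tau = rng.uniform(lower, time[v])
            G.migrations.append(Migration(c1, tau, p1, p0))
            p1 = p0
        cur_pop[v] = p0
    return G


def _init_chain(
    works: list[_LocusWork],
    config: RunConfig,
    priors: PriorSpec,
    beta: float,
    rng: np.random.Generator,
) -> ChainState:
    lik_on = config.likelihood == "on"
    for attempt in range(config.init_attempts):
        if lik_on and config.init == "moment" and attempt < config.init_attempts // 2:
            params = _moment_initial_params(works, priors, rng)
        else:
            params = sample_prior(priors, rng)
        logprior = log_prior(params, priors)
        genealogies: list[Genealogy] = []
        kappas: list[float | None] = []
        ok = True
        for w in works:
            if w.kind == "IS" and lik_on:
                try:
                    G = _perfect_phylogeny_genealogy(w, params, rng)
                except ValueError:
                    raise
            else:
                G = simulate_genealogy(params, w.n1, w.n2, rng)
            genealogies.append(G)
            if w.kind == "HKY":
                kappas.append(
                    float(rng.uniform(0.0, config.kappa_bound))
                    if config.kappa == "sample"
                    else float(config.kappa)
                )
            else:
                kappas.append(None)
        stats = [coal_stats(G, params.t_split) for G in genealogies]
        dens = [density_from_stats(s, params) for s in stats]
        if not all(math.isfinite(d) for d in dens):
            continue
        if lik_on:
            lls = [w.loglik(G, kappas[i]) for i, (w, G) in enumerate(zip(works, genealogies))]
        else:
            lls = [0.0 for _ in works]
        if not all(math.isfinite(x) for x in lls):
            continue
        if ok:
            return ChainState(
                params, genealogies, kappas, lls, stats, dens, logprior, beta, rng
            )
    raise RuntimeError("could not find a finite-posterior initial state")


# ---------------------------------------------------------------------------
# the generation sweep


def _accept(rng: np.random.Generator, exponent: float) -> bool:
    if exponent >= 0:
        rng.random()  # keep the stream in lockstep across branches
        return True
    if math.isinf(exponent):
        return False
    return math.log(rng.random()) < exponent


def _resolved_windows(config: RunConfig, priors: PriorSpec) -> dict[str, float]:
    w = {name: priors.bound(name) / 5.0 for name in PARAM_NAMES}
    if config.windows:
        w.update(config.windows)
    return w


def _sweep(
    ch: ChainState,
    works: list[_LocusWork],
    config: RunConfig,
    priors: PriorSpec,
    windows: dict[str, float],
    tally: dict[str, list[int]] | None,
) -> None:
    rng = ch.rng
    lik_on = config.likelihood == "on"
    beta_prior = ch.beta if config.tempering == "posterior" else 1.0

    for name in PARAM_NAMES:
        new_params, logh = propose_scalar_update(
            ch.params, name, windows[name], priors, rng
        )
        new_logprior = log_prior(new_params, priors)
        if tally is not None:
            tally[name][1] += 1
        if name == "t_split":
            # joint move: sweeping the divergence time resamples (or deletes)
            # the migration paths inside the swept window; the sequence
            # likelihood is unaffected because it ignores migration events
            new_gen, logh_path = propose_divergence_update(
                ch.genealogies, ch.params, new_params.t_split, rng
            )
            if new_gen is None:
                continue
            logh += logh_path
            new_stats = [coal_stats(G, new_params.t_split) for G in new_gen]
        else:
            new_gen = ch.genealogies
            new_stats = ch.gen_stats
        new_dens = [density_from_stats(s, new_params) for s in new_stats]
        delta = (new_logprior - ch.logprior) + (sum(new_dens) - sum(ch.gen_dens))
        if _accept(rng, beta_prior * delta + logh):
            ch.params = new_params
            ch.logprior = new_logprior
            ch.genealogies = new_gen
            ch.gen_stats = new_stats
            ch.gen_dens = new_dens
            if tally is not None:
                tally[name][0] += 1

    if lik_on and config.kappa == "sample":
        for li, w in enumerate(works):
            if w.kind != "HKY":
                continue
            old_k = ch.kappas[li]
            new_k = _reflect(
                old_k + rng.uniform(-config.kappa_window / 2.0, config.kappa_window / 2.0),
                0.0,
                config.kappa_bound,
            )
            if tally is not None:
                tally["kappa"][1] += 1
            if new_k <= 0.0:
                continue
            new_ll = w.loglik(ch.genealogies[li], new_k)
            if _accept(rng, ch.beta * (new_ll - ch.loglik_per_locus[li])):
                ch.kappas[li] = new_k
                ch.loglik_per_locus[li] = new_ll
                if tally is not None:
                    tally["kappa"][0] += 1

    for li, w in enumerate(works):
        G2, logh, s2 = _propose_with_stats(
            ch.genealogies[li], ch.params, config.move_tuning, rng
        )
        if tally is not None:
            tally["genealogy"][1] += 1
        if s2 is None:
            continue
        d2 = density_from_stats(s2, ch.params)
        if math.isinf(d2):
            continue
        ll2 = w.loglik(G2, ch.kappas[li]) if lik_on else 0.0
        if math.isinf(ll2):
            continue
        delta_lik = ll2 - ch.loglik_per_locus[li]
        delta_prior = d2 - ch.gen_dens[li]
        exponent = ch.beta * delta_lik + beta_prior * delta_prior + logh
        if _accept(rng, exponent):
            ch.genealogies[li] = G2
            ch.gen_stats[li] = s2
            ch.gen_dens[li] = d2
            ch.loglik_per_locus[li] = ll2
            if tally is not None:
                tally["genealogy"][0] += 1


def _audit(ch: ChainState, works: list[_LocusWork], config: RunConfig, priors: PriorSpec):
    lp = log_prior(ch.params, priors)
    if abs(lp - ch.logprior) > 1e-8:
        raise RuntimeError("cache audit failed: parameter log prior drifted")
    for li, (w, G) in enumerate(zip(works, ch.genealogies)):
        s = coal_stats(G, ch.params.t_split)
        d = density_from_stats(s, ch.params)
        if abs(d - ch.gen_dens[li]) > 1e-8:
            raise RuntimeError(f"cache audit failed: genealogy prior, locus {li}")
        if config.likelihood == "on":
            ll = w.loglik(G, ch.kappas[li])
            if abs(ll - ch.loglik_per_locus[li]) > 1e-8:
                raise RuntimeError(f"cache audit failed: likelihood, locus {li}")


def mcmc_run(
    data: Dataset, config: RunConfig, priors: PriorSpec | None = None
) -> list[TraceRecord]:
    """Run the sampler and return the cold-chain trace.

    Each generation: a deterministic scan over the six parameters, then the
    per-locus kappa moves (HKY loci with sampled kappa), then one genealogy
    move per locus; with multiple chains one adjacent-pair swap is attempted
    per generation.  Records are taken every ``sample_every`` generations
    after burn-in.  Fully reproducible given ``config.seed``.
    """
    priors = priors or PriorSpec()
    works = [_LocusWork(loc, config) for loc in data.loci]
    betas = heating_schedule(config.n_chains, config.heat_lambda)
    windows = _resolved_windows(config, priors)
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.n_chains + 1)
    master_rng = np.random.default_rng(streams[0])
    chains = [
        _init_chain(works, config, priors, betas[k], np.random.default_rng(streams[k + 1]))
        for k in range(config.n_chains)
    ]
    tally: dict[str, list[int]] = {name: [0, 0] for name in PARAM_NAMES}
    tally["kappa"] = [0, 0]
    tally["genealogy"] = [0, 0]
    tally["swap"] = [0, 0]

    records: list[TraceRecord] = []
    total = config.burn_in + config.generations
    for gen in range(total):
        for ci, ch in enumerate(chains):
            _sweep(ch, works, config, priors, windows, tally if ci == 0 else None)
        if config.n_chains > 1:
            i = int(master_rng.integers(config.n_chains - 1))
            _, _, accepted = mc3_swap(chains[i], chains[i + 1], master_rng)
            tally["swap"][1] += 1
            tally["swap"][0] += int(accepted)
        if config.audit_every and (gen + 1) % config.audit_every == 0:
            for ch in chains:
                _audit(ch, works, config, priors)
        if gen >= config.burn_in and (gen - config.burn_in) % config.sample_every == 0:
            cold = chains[0]
            records.append(
                TraceRecord(
                    generation=gen,
                    params=cold.params,
                    loglik_per_locus=list(cold.loglik_per_locus),
                    loglik_total=float(sum(cold.loglik_per_locus)),
                    logprior=cold.logprior,
                    chain_id=0,
                    beta=cold.beta,
                    accept_counts={k: (v[0], v[1]) for k, v in tally.items()},
                )
            )
        if config.log_every and (gen + 1) % config.log_every == 0:
            cold = chains[0]
            acc = ", ".join(
                f"{k}={v[0]}/{v[1]}" for k, v in tally.items() if v[1]
            )
            print(
                f"[imcoal] gen {gen + 1}/{total} logpost={_unheated_logpost(cold):.4f} {acc}",
                file=sys.stderr,
            )
    return records
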