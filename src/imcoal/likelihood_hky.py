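"""Felsenstein-pruning likelihood under the HKY85 substitution model.

The likelihood of an alignment on a genealogy is computed by the pruning
dynamic program: each node carries, per site, a 4-vector of conditional
likelihoods (CL) — the probability of the data below the node given each
possible nucleotide state at the node.  Leaves are indicator vectors of the
observed base; an internal node multiplies, over its two children, the
transition-matrix-weighted sums of the child vectors.  The per-site
likelihood (SL) is the stationary-frequency-weighted sum of the root
vector, and the total log likelihood (GL) is the sum of per-site logs,
optionally via partial sums over contiguous site blocks — a chunked
reduction whose result is required to be invariant to the block size.

The HKY rate matrix (base frequencies pi, transition/transversion ratio
kappa) is normalized to mean rate 1, so branch lengths are expected
substitutions per site and coincide with the mutational time units of the
genealogy (up to the per-locus rate scale u).  Transition probabilities use
the closed-form spectral solution.  Conditional likelihoods are rescaled
per site during the postorder pass so that long trees with many taxa do
not underflow; the running log of the scalers is added back to SL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genealogy import Genealogy

__all__ = [
    "HKYModel",
    "ConditionalLikelihoodTable",
    "hky_transition_matrix",
    "prune_conditional_likelihoods",
    "site_log_likelihoods",
    "blocked_total_loglik",
    "hky_total_loglik",
    "empirical_base_frequencies",
]

#: Nucleotide code order used throughout: A=0, C=1, G=2, T=3.
BASES = "ACGT"
_PURINE = np.array([True, False, True, False])


@dataclass(frozen=True)
class HKYModel:
    """HKY85 model: stationary base frequencies and transition/transversion ratio."""

    pi: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: float = 1.0

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("pi must be 4 positive frequencies")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @property
    def pi_array(self) -> np.ndarray:
        return np.asarray(self.pi, dtype=float)


@dataclass
class ConditionalLikelihoodTable:
    """Per-node, per-site conditional likelihood vectors.

    partials : (2N-1, n, 4) array; leaves hold indicator vectors.
    log_scale : (n,) running log of the per-site scalers factored out
        during pruning (add back when forming site log likelihoods).
    root : root node index.
    """

    partials: np.ndarray
    log_scale: np.ndarray
    root: int


def empirical_base_frequencies(alignment: np.ndarray) -> np.ndarray:
    """Base frequencies observed in an alignment of codes 0..3.

    One pseudocount per base keeps every frequency strictly positive, as the
    HKY likelihood requires.
    """
    counts = np.bincount(alignment.ravel(), minlength=4).astype(float) + 1.0
    return counts / counts.sum()


def _rate_normalizer(pi: np.ndarray, kappa: float) -> float:
    piA, piC, piG, piT = pi
    piR = piA + piG
    piY = piC + piT
    return 2.0 * kappa * (piA * piG + piC * piT) + 2.0 * piR * piY


def hky_transition_matrix(branch: float, model: HKYModel) -> np.ndarray:
    """Closed-form HKY transition probabilities for one branch.

    ``branch`` is in expected substitutions per site (the rate matrix is
    normalized to mean rate 1).  Rows index the parent state, columns the
    child state.
    """
    if branch < 0:
        raise ValueError("branch length must be nonnegative")
    pi = model.pi_array
    kappa = model.kappa
    beta = 1.0 / _rate_normalizer(pi, kappa)
    d = beta * branch

    piR = pi[0] + pi[2]
    piY = pi[1] + pi[3]
    group = np.where(_PURINE, piR, piY)  # Pi_j per target base
    A = 1.0 + group * (kappa - 1.0)
    e1 = np.exp(-d)
    e2 = np.exp(-d * A)  # per target base

    P = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if _PURINE[i] == _PURINE[j]:
                term = pi[j] + pi[j] * (1.0 / group[j] - 1.0) * e1
                if i == j:
                    P[i, j] = term + ((group[j] - pi[j]) / group[j]) * e2[j]
                else:
                    P[i, j] = term - (pi[j] / group[j]) * e2[j]
            else:
                P[i, j] = pi[j] * (1.0 - e1)
    return P


def prune_conditional_likelihoods(
    G: Genealogy, alignment: np.ndarray, model: HKYModel, u: float = 1.0
) -> ConditionalLikelihoodTable:
    """Postorder pruning pass over the genealogy.

    ``alignment`` holds nucleotide codes 0..3, one row per leaf in leaf
    order; ``u`` is the per-locus rate scale multiplying branch lengths.
    """
    N = G.N
    if alignment.shape[0] != N:
        raise ValueError(
            f"alignment has {alignment.shape[0]} rows but genealogy has {N} leaves"
        )
    n = alignment.shape[1]
    partials = np.zeros((G.n_nodes, n, 4))
    partials[np.arange(N)[:, None], np.arange(n)[None, :], alignment] = 1.0
    log_scale = np.zeros(n)

    order = np.argsort(G.time, kind="stable")
    for v in order:
        v = int(v)
        if G.is_leaf(v):
            continue
        acc = np.ones((n, 4))
        for c in G.children[v]:
            c = int(c)
            P = hky_transition_matrix(float(G.time[v] - G.time[c]) * u, model)
            if G.is_leaf(c):
                acc *= P.T[alignment[c]]
            else:
                acc *= partials[c] @ P.T
        scale = acc.max(axis=1)
        nz = scale > 0
        acc[nz] /= scale[nz, None]
        with np.errstate(divide="ignore"):
            log_scale += np.where(nz, np.log(scale, where=nz, out=np.zeros(n)), -np.inf)
        partials[v] = acc
    return ConditionalLikelihoodTable(partials, log_scale, G.root)


def site_log_likelihoods(CL: ConditionalLikelihoodTable, model: HKYModel) -> np.ndarray:
    """Per-site log likelihood: log(pi . CL(root)) plus the scaling log."""
    with np.errstate(divide="ignore"):
        return np.log(CL.partials[CL.root] @ model.pi_array) + CL.log_scale


def blocked_total_loglik(
    SL: np.ndarray, block_size: int
) -> tuple[float, np.ndarray]:
    """Total log likelihood via partial sums over contiguous site blocks.

    The chunked reduction mirrors a block-wise parallel sum; its contract is
    exact invariance (to floating tolerance) of the total with respect to
    the block size.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    SL = np.asarray(SL, dtype=float)
    starts = np.arange(0, SL.shape[0], block_size)
    block_sums = np.add.reduceat(SL, starts)
    return float(block_sums.sum()), block_sums


def hky_total_loglik(
    G: Genealogy,
    alignment: np.ndarray,
    model: HKYModel,
    u: float = 1.0,
    block_size: int = 256,
) -> float:
    """Convenience wrapper: pruning + site likelihoods + blocked reduction."""
    CL = prune_conditional_likelihoods(G, alignment, model, u)
    SL = site_log_likelihoods(CL, model)
    total, _ = blocked_total_loglik(SL, block_size)
    return total
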