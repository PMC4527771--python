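"""Infinite-sites likelihood: mutation mapping and Poisson evaluation.

Under the infinite-sites (IS) model every mutation strikes a previously
unmutated site, so a polymorphic site is biallelic and its derived allele
must be carried by exactly the leaves of one clade of the genealogy; the
site's single mutation then maps to the edge above that clade.  Any other
pattern — derived carriers not forming a clade, more than two alleles, or
derived alleles in every sampled sequence — is incompatible with the
genealogy and forces likelihood zero: the evaluation breaks off and the
proposal is rejected.

Given a compatible mapping, mutation counts per branch are independent
Poisson draws with exposure (branch length x u), where u is the per-locus
mutation scale, so the log likelihood is

    log L = -BT*u + sum_b [ m_b log(B_b u) - log(m_b!) ]

with BT the total branch length.  Sites are polarized by an explicit
ancestral allele (an ancestral sequence or a designated alignment row);
without one, an either-polarity mode accepts a site if either choice of
ancestral allele maps to a clade, preferring the smaller derived set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import gammaln

from .genealogy import Genealogy, total_branch_length

__all__ = [
    "MutationMapping",
    "clade_index",
    "polarize_and_map_sites",
    "is_log_likelihood",
]

# site status codes
MONOMORPHIC = 0
MAPPED = 1
INCOMPATIBLE = 2


@dataclass
class MutationMapping:
    """Result of mapping each alignment site onto the genealogy.

    site_status : (n,) int8 — MONOMORPHIC, MAPPED or INCOMPATIBLE.
    site_branch : (n,) int — for mapped sites the node index whose parent
        edge carries the mutation, else -1.
    site_blen : (n,) float — length of that edge (0 where unmapped).
    branch_counts : (2N-1,) int — mutations attributed to each edge.
    """

    site_status: np.ndarray
    site_branch: np.ndarray
    site_blen: np.ndarray
    branch_counts: np.ndarray

    @property
    def n_incompatible(self) -> int:
        return int(np.sum(self.site_status == INCOMPATIBLE))

    @property
    def M(self) -> np.ndarray:
        """Mutation count attributed to each site (1 for mapped sites)."""
        return (self.site_status == MAPPED).astype(np.int64)


@njit(cache=False)
def _clade_mask_kernel(N, time, ch0, ch1):
    """Leaf-set bitmask per node (uint64; valid for N <= 63)."""
    n_nodes = time.shape[0]
    order = np.argsort(time)
    mask = np.zeros(n_nodes, np.uint64)
    for i in range(N):
        mask[i] = np.uint64(1) << np.uint64(i)
    for j in range(n_nodes):
        v = order[j]
        if ch0[v] >= 0:
            mask[v] = mask[ch0[v]] | mask[ch1[v]]
    return mask


def clade_masks(G: Genealogy) -> np.ndarray:
    """Per-node leaf-set bitmasks (uint64), for samples of at most 63 leaves."""
    if G.N > 63:
        raise ValueError("bitmask clades support at most 63 leaves")
    return _clade_mask_kernel(
        G.N,
        G.time,
        np.ascontiguousarray(G.children[:, 0]),
        np.ascontiguousarray(G.children[:, 1]),
    )


def clade_index(G: Genealogy) -> dict[bytes, int]:
    """Map from packed leaf-set bitmasks to the non-root node subtending them."""
    N = G.N
    leafsets = np.zeros((G.n_nodes, N), dtype=bool)
    leafsets[np.arange(N), np.arange(N)] = True
    order = np.argsort(G.time, kind="stable")
    for v in order:
        v = int(v)
        if not G.is_leaf(v):
            leafsets[v] = leafsets[int(G.children[v, 0])] | leafsets[int(G.children[v, 1])]
    root = G.root
    return {
        np.packbits(leafsets[v]).tobytes(): v for v in range(G.n_nodes) if v != root
    }


def _ancestral_codes(alignment: np.ndarray, ancestral) -> np.ndarray:
    if ancestral is None:
        raise ValueError("ancestral allele designation required for IS polarization")
    anc = np.asarray(ancestral)
    if anc.ndim == 0:  # a row index
        anc = alignment[int(anc)]
    if anc.shape != (alignment.shape[1],):
        raise ValueError("ancestral sequence length does not match the alignment")
    return anc


def polarize_and_map_sites(
    G: Genealogy,
    alignment: np.ndarray,
    ancestral=None,
    polarity: str = "ancestral",
) -> MutationMapping:
    """Assign each site's mutation (if any) to a unique branch of G.

    ``ancestral`` is either an ancestral sequence of codes 0..3, or an
    integer row index into the alignment; with ``polarity="either"`` no
    designation is needed and a site is accepted if either polarization
    maps to a clade (ties resolved toward the smaller derived set).
    """
    if polarity not in ("ancestral", "either"):
        raise ValueError(f"unknown polarity mode {polarity!r}")
    N, n = alignment.shape
    if N != G.N:
        raise ValueError("alignment row count does not match genealogy leaf count")
    index = clade_index(G)
    edge_len = np.zeros(G.n_nodes)
    mask = G.parent >= 0
    edge_len[mask] = G.time[G.parent[mask]] - G.time[mask]

    status = np.zeros(n, dtype=np.int8)
    branch = np.full(n, -1, dtype=np.int64)
    blen = np.zeros(n)
    counts = np.zeros(G.n_nodes, dtype=np.int64)

    poly = np.flatnonzero(np.any(alignment != alignment[0], axis=0))
    anc = _ancestral_codes(alignment, ancestral) if polarity == "ancestral" else None

    for j in poly:
        col = alignment[:, j]
        alleles = np.unique(col)
        if len(alleles) != 2:
            status[j] = INCOMPATIBLE
            continue
        if polarity == "ancestral":
            a = anc[j]
            if a not in alleles:
                # neither observed allele is ancestral: two mutations at the site
                status[j] = INCOMPATIBLE
                continue
            derived = alleles[0] if alleles[1] == a else alleles[1]
            carrier_sets = [col == derived]
        else:
            m0 = col == alleles[0]
            carrier_sets = sorted([m0, ~m0], key=lambda m: int(m.sum()))
        hit = None
        for carriers in carrier_sets:
            if carriers.all():
                continue  # derived everywhere: mutation above the root
            v = index.get(np.packbits(carriers).tobytes())
            if v is not None:
                hit = v
                break
        if hit is None:
            status[j] = INCOMPATIBLE
            continue
        status[j] = MAPPED
        branch[j] = hit
        blen[j] = edge_len[hit]
        counts[hit] += 1
    return MutationMapping(status, branch, blen, counts)


def is_log_likelihood(mapping: MutationMapping, G: Genealogy, u: float = 1.0) -> float:
    """Poisson log likelihood of the mapped mutation counts; -inf on break-off.

    Any incompatible site forces likelihood zero, so the value is -inf and
    the Metropolis-Hastings step rejects the state.
    """
    if u <= 0:
        raise ValueError("mutation scale u must be positive")
    if mapping.n_incompatible:
        return -math.inf
    BT = total_branch_length(G)
    ll = -BT * u
    nz = np.flatnonzero(mapping.branch_counts)
    if nz.size:
        m = mapping.branch_counts[nz]
        mask = G.parent >= 0
        edge_len = np.zeros(G.n_nodes)
        edge_len[mask] = G.time[G.parent[mask]] - G.time[mask]
        B = edge_len[nz]
        if np.any(B <= 0):
            return -math.inf
        ll += float(np.sum(m * np.log(B * u) - gammaln(m + 1.0)))
    return ll
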