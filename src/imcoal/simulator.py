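"""Synthetic data generation with the exact structure the sampler assumes.

Genealogies are drawn from the IM structured coalescent; sequences are then
evolved along them either under HKY (root state from the stationary
frequencies, children by the closed-form transition probabilities) or under
infinite sites (each site independently receives at most one mutation,
placed on a branch chosen proportionally to branch length, with the derived
allele painted onto the subtended leaves).  IS data are generated natively
under the model rather than by post-processing HKY alignments, which
guarantees that every polymorphic column is compatible with the generating
genealogy — the invariant the mapping oracle tests rely on.

`make_benchmark_fixture` emits the benchmark design used throughout the
package's acceptance checks: single-locus datasets of 150 + 40 sequences at
lengths 1000/6000/11000/16000 under both models, multi-locus combinations
of 1/2/4/8 loci, and a small 10+10 x 500-site variant for quick runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .genealogy import Genealogy, simulate_genealogy, total_branch_length
from .im_parameters import IMParameters
from .io_formats import Dataset, Locus, write_dataset
from .likelihood_hky import HKYModel, hky_transition_matrix

__all__ = [
    "simulate_sequences_hky",
    "simulate_sequences_is",
    "simulate_dataset",
    "make_benchmark_fixture",
    "DEFAULT_TRUTH",
]

#: Documented default parameter point for generated benchmark data.
DEFAULT_TRUTH = IMParameters(
    theta1=2.0, theta2=2.0, thetaA=2.0, m1=0.5, m2=0.5, t_split=1.0
)


def _leaf_order_states(G: Genealogy, n: int, model: HKYModel, u: float, rng) -> np.ndarray:
    """Evolve states down the tree; returns codes for all nodes, (2N-1, n)."""
    states = np.zeros((G.n_nodes, n), dtype=np.uint8)
    order = np.argsort(G.time, kind="stable")[::-1]  # root first
    root = G.root
    pi = model.pi_array
    states[root] = rng.choice(4, size=n, p=pi)
    for v in order:
        v = int(v)
        if v == root or G.parent[v] < 0:
            continue
        p = int(G.parent[v])
        P = hky_transition_matrix(float(G.time[p] - G.time[v]) * u, model)
        C = np.cumsum(P, axis=1)
        r = rng.random(n)
        states[v] = (r[:, None] > C[states[p]]).sum(axis=1).astype(np.uint8)
    return states


def simulate_sequences_hky(
    G: Genealogy,
    n: int,
    model: HKYModel,
    u: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Alignment of codes 0..3 evolved under HKY along the genealogy."""
    if n < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng() if rng is None else rng
    states = _leaf_order_states(G, n, model, u, rng)
    return states[: G.N].copy()


def simulate_sequences_is(
    G: Genealogy,
    n: int,
    u: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infinite-sites alignment on a genealogy.

    Each of the n sites independently mutates with probability
    1 - exp(-BT*u/n) (so the expected total is ~ BT*u, the Poisson exposure
    the likelihood assumes); a mutated site's event lands on one branch,
    chosen proportionally to branch length, and the derived allele is
    painted onto the leaves below it.

    Returns (alignment, ancestral sequence, true site-to-branch map) where
    the map holds the branch node index per site, -1 for unmutated sites.
    """
    if n < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng() if rng is None else rng
    N = G.N
    BT = total_branch_length(G)
    p_mut = -np.expm1(-BT * u / n)
    mutated = rng.random(n) < p_mut

    mask = G.parent >= 0
    edge_len = np.where(mask, G.time[G.parent] - G.time, 0.0)
    edge_p = edge_len / edge_len.sum()

    # leaves subtended by each node
    leafsets = np.zeros((G.n_nodes, N), dtype=bool)
    leafsets[np.arange(N), np.arange(N)] = True
    for v in np.argsort(G.time, kind="stable"):
        v = int(v)
        if not G.is_leaf(v):
            leafsets[v] = leafsets[int(G.children[v, 0])] | leafsets[int(G.children[v, 1])]

    ancestral = rng.choice(4, size=n).astype(np.uint8)
    alignment = np.tile(ancestral, (N, 1))
    site_branch = np.full(n, -1, dtype=np.int64)
    for j in np.flatnonzero(mutated):
        b = int(rng.choice(G.n_nodes, p=edge_p))
        site_branch[j] = b
        derived = (ancestral[j] + 1 + rng.integers(3)) % 4
        alignment[leafsets[b], j] = derived
    return alignment, ancestral, site_branch


def simulate_dataset(
    params: IMParameters,
    n1: int,
    n2: int,
    n_sites: int,
    n_loci: int,
    model: str,
    u: float = 1.0,
    rng: np.random.Generator | None = None,
    name_prefix: str = "locus",
    hky_model: HKYModel | None = None,
) -> Dataset:
    """Simulate a multilocus dataset (independent genealogy per locus)."""
    rng = np.random.default_rng() if rng is None else rng
    if model not in ("HKY", "IS"):
        raise ValueError(f"unknown model {model!r}")
    hky = hky_model or HKYModel()
    pops = np.array([1] * n1 + [2] * n2)
    loci = []
    for i in range(n_loci):
        G = simulate_genealogy(params, n1, n2, rng)
        if model == "HKY":
            aln = simulate_sequences_hky(G, n_sites, hky, u, rng)
            loci.append(Locus(f"{name_prefix}{i}", aln, pops.copy(), "HKY", u))
        else:
            aln, anc, _ = simulate_sequences_is(G, n_sites, u, rng)
            loci.append(
                Locus(f"{name_prefix}{i}", aln, pops.copy(), "IS", u, None, anc)
            )
    return Dataset(loci, metadata=f"simulated at {params}")


# benchmark design constants
_FULL_N1, _FULL_N2 = 150, 40
_FULL_LENGTHS = (1000, 6000, 11000, 16000)
_LOCI_COUNTS = (1, 2, 4, 8)
#: Per-model mutation scales for generated fixtures: HKY's u multiplies
#: per-site branch lengths (keep divergence moderate); IS's u is the
#: per-locus Poisson exposure scale.
_FIXTURE_U = {"HKY": 0.01, "IS": 1.0}


def make_benchmark_fixture(scale: str, seed: int, outdir) -> dict:
    """Emit the benchmark datasets and a manifest; returns the manifest.

    ``scale="full"``: {HKY, IS} x lengths {1000, 6000, 11000, 16000} with
    150 + 40 sequences and one locus each, plus multi-locus combinations of
    {1, 2, 4, 8} loci at length 1000.  ``scale="small"``: one 10+10 x 500
    dataset per model.  Deterministic per seed.
    """
    if scale not in ("full", "small"):
        raise ValueError(f"unknown scale {scale!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    truth = DEFAULT_TRUTH
    manifest: dict = {
        "scale": scale,
        "seed": seed,
        "truth": {k: float(v) for k, v in asdict(truth).items()},
        "u": dict(_FIXTURE_U),
        "files": [],
    }
    if scale == "full":
        jobs = [
            (f"{model.lower()}_L{length}.im", model, _FULL_N1, _FULL_N2, length, 1)
            for model in ("HKY", "IS")
            for length in _FULL_LENGTHS
        ] + [
            (f"{model.lower()}_loci{k}.im", model, _FULL_N1, _FULL_N2, 1000, k)
            for model in ("HKY", "IS")
            for k in _LOCI_COUNTS
        ]
    else:
        jobs = [(f"{model.lower()}_small.im", model, 10, 10, 500, 1) for model in ("HKY", "IS")]
    for fname, model, n1, n2, length, k in jobs:
        ds = simulate_dataset(
            truth, n1, n2, length, k, model, u=_FIXTURE_U[model], rng=rng
        )
        write_dataset(ds, outdir / fname)
        manifest["files"].append(
            {"file": fname, "model": model, "n1": n1, "n2": n2, "sites": length, "loci": k}
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
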