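# Methods

## The model

`imcoal` estimates the six parameters of the two-population
isolation-with-migration (IM) model from multilocus alignments.  Looking
backward in time, lineages sampled from two present-day populations
coalesce within their current population (pairwise rate 2/θ₁ or 2/θ₂),
migrate between populations (per-lineage rates m₁ out of population 1 and
m₂ out of population 2), and at the divergence time t merge into a single
ancestral population of size θ_A in which the remaining lineages coalesce
at pairwise rate 2/θ_A.  All parameters are scaled by the neutral mutation
rate u: θ = 4Nu, migration rates are m/u, and times are in expected
mutations per site.  The founding-proportion refinement of the model (a
population-size discontinuity at the split) is deliberately out of scope;
the parameter vector is exactly {θ₁, θ₂, θ_A, m₁, m₂, t}.

The joint posterior over parameters θ and per-locus genealogies G is

    P(θ, G | D) ∝ ∏_l P(D_l | G_l) · P(G_l | θ) · P(θ)

with independent Uniform(0, bound) priors (default bound 10 for every
parameter, matching the runs this sampler family is usually benchmarked
with).  P(G|θ) is the structured-coalescent density: a sweep over event
times accumulates, per inter-event interval with k₁, k₂ lineages, the
total rate k₁(k₁−1)/θ₁ + k₂(k₂−1)/θ₂ + k₁m₁ + k₂m₂ (below t) or
k(k−1)/θ_A (above t), and adds the log rate of each realized event.  The
sweep returns sufficient statistics (event counts and rate integrals), so
re-evaluating the density after a scalar parameter change is O(1); the
sweep itself is a numba kernel.

## Likelihoods

**HKY.**  Felsenstein pruning with the closed-form HKY85 transition
probabilities.  The rate matrix is normalized to mean rate 1, so branch
lengths are expected substitutions per site and the genealogy's mutational
time units and the substitution units coincide (scaled per locus by the
relative rate u).  Conditional-likelihood vectors are rescaled per site by
their maximum during the postorder pass, with the log scalers added back
to the per-site log likelihoods — necessary at the largest benchmark size
(190 sequences × 16,000 sites).  The total log likelihood is assembled by
a chunked reduction over contiguous site blocks whose result is required
(and tested) to be invariant to the block size; block partial sums are the
natural unit for data-parallel implementations of this likelihood, and the
invariance contract is what makes any such layout safe.  Base frequencies
default to the empirical frequencies of the locus alignment (with one
pseudocount per base, keeping them strictly positive); κ is by default a
per-locus nuisance parameter with a Uniform(0, 100) prior updated by the
same reflected sliding-window move, switchable to a fixed value.

**Infinite sites.**  Sites are polarized by an explicit ancestral allele
(an ancestral sequence or a designated alignment row; an either-polarity
fallback accepts a site if either polarization maps, preferring the
smaller derived set).  A polymorphic site is compatible iff its derived
carriers are exactly the leaf set of one clade; the site's single mutation
then maps to the edge above that clade.  Any incompatible site forces
likelihood zero — the evaluation breaks off and the proposal is rejected.
Given the mapping, branch counts are independent Poisson draws with
exposure (branch length × u), so

    log L = −BT·u + Σ_b [ m_b log(B_b u) − log(m_b!) ] ,

with BT the total branch length.  Expressions for this likelihood are
sometimes printed with the sign of the BT·u term flipped and without the
factorial; those forms are not normalizable and are read here as
abbreviations of the Poisson form above, which is the one implemented and
tested (per-branch product oracle; exhaustive total-probability checks for
small mutation counts).  Note the unit asymmetry, which follows the
formulas themselves: the HKY u multiplies per-site branch lengths, while
the IS exposure BT·u is a per-locus expected mutation count.

## Sampler

Metropolis–Hastings over (θ, G) with a fixed deterministic scan per
generation: one move per scalar parameter, one κ move per HKY locus, one
genealogy move per locus, and (with multiple chains) one
adjacent-temperature swap attempt.  Scalar moves are sliding windows
reflected at 0 and at the prior bound (symmetric, Hastings 1); default
window bound/5.

**Genealogy moves** (one of three, chosen uniformly):

* *Node-time slide* — an internal node's time is redrawn uniformly in the
  interval bounded by its children's times (and their edges' last
  migration times) and its parent's time (and its own edge's first
  migration); the root time uses a log-multiplier with the matching
  Hastings term.
* *Lineage regraft* — a non-root node's parent edge is dissolved and the
  lineage's path is re-simulated under the structured coalescent
  conditional on the remainder tree: it migrates at the current rates and
  coalesces with eligible lineages until it reattaches.  The Hastings
  ratio is the exact ratio of old-path to new-path conditional densities.
  Proposals that would orphan migration events above the new root are
  rejected.
* *Migration pair birth/death* — inserts two mutually inverse migration
  events at uniform positions on one edge below t, or deletes an adjacent
  same-edge pair, with the standard birth–death Hastings ratio.  Pairs are
  used because a single inserted event cannot preserve the population
  labels at the coalescence above.

**Divergence-time update.**  A plain sliding-window move on t cannot in
practice raise the divergence past an ancestral coalescence whose lineages
carry discordant (frozen) population labels — every such proposal is
invalid until the genealogies rearrange, and the chain's t component
freezes.  The move used here proposes t' with the reflected window and
then sweeps the window (t, t') jointly with all genealogies: raising t
simulates fresh migration paths for every lineage segment inside the
window (free two-state migration at rates m₁, m₂, rejecting on label
mismatch at coalescences); lowering t deletes the window's migration
events.  The Hastings ratio is the exact free-path density of the deleted
pieces minus that of the created pieces.  Because neither likelihood
depends on migration events, cached likelihoods remain valid under this
move.  Its correctness is checked by prior recovery (below) and by
raise-then-lower round-trip tests that must restore the state and cancel
the Hastings terms exactly.

**Caching and audit.**  Per-locus likelihoods, genealogy-prior statistics
and the parameter prior are cached and updated incrementally; every
`audit_every` generations (default 2000) everything is recomputed from
scratch and any disagreement beyond 1e−8 raises.  One independent random
stream per chain, spawned from the master seed, makes runs bit-identical.

**Initialization.**  By default the chain starts from Watterson-type
moment estimates (per-population θ from within-population segregating
sites, divergence from mean between-population differences, small
migration rates), jittered ±20% per chain and clamped into the prior box —
the standard practice for samplers of this family, which shortens the
transient of finite runs.  Prior-draw initialization is available
(`init="prior"`) and is used in the likelihood-off validation runs.  IS
loci additionally need a starting genealogy compatible with the data;
it is built by a perfect-phylogeny construction over the derived-carrier
sets (which form a laminar family for IS-generated data), binarized
randomly, given coalescent-like times, and population-harmonized by
inserting migration events below discordant coalescences.

**Heating.**  Optional Metropolis coupling with β_k = 1/(1 + λk) and full
posterior tempering (likelihood-only tempering is a config switch).  The
swap exchanges complete states while temperatures stay with the chain
slots.

## Synthetic data

The simulator draws genealogies from the same structured coalescent the
density describes (Gillespie simulation; validated against the density by
simulation-vs-MCMC distribution tests) and evolves sequences either under
HKY (root from π, children by the closed-form transition probabilities) or
natively under infinite sites: each of the n sites mutates independently
with probability 1 − exp(−BT·u/n), the event lands on a branch chosen
proportionally to length, and the derived allele is painted onto the
subtended leaves.  Native IS generation (rather than post-processing HKY
alignments) guarantees every polymorphic column is compatible with the
generating genealogy, the invariant the mapping tests rely on.  What the
generator does not emulate: recombination within loci, gene conversion,
sequencing error, rate heterogeneity across sites, and ancestral-state
misidentification; tests passing on these data validate the sampler's
self-consistency, not robustness to those real-data features.

The benchmark design (`make_benchmark_fixture`) emits single-locus
datasets of 150 + 40 sequences at lengths 1000/6000/11000/16000 under both
models, multi-locus combinations of 1/2/4/8 loci, and a small 10+10 × 500
variant.  The generating parameter point is (θ₁, θ₂, θ_A, m₁, m₂, t) =
(2, 2, 2, 0.5, 0.5, 1); the per-model rate scales are u = 0.01 for HKY
(moderate per-site divergence) and u = 1 for IS (a realistic handful of
mutations per locus).  These fixture parameters are this package's own
documented defaults, not reproductions of any external benchmark's
unpublished settings.

## Validation design

* **Oracle equivalence** — pruning versus brute-force ancestral-state
  enumeration (≤4 leaves, ≤6 sites); closed-form transition probabilities
  versus the matrix exponential of an independently constructed generator;
  the IS likelihood versus an independent per-branch Poisson pmf product;
  per-site likelihoods summing to 1 over all site patterns.
* **Move correctness** — forward/reverse Hastings cancellation for every
  move type (including forced-reversal round trips), and
  sampler-versus-simulator distribution tests: a genealogy-only MCMC at
  fixed parameters must reproduce the TMRCA and branch-length
  distributions of direct simulation.
* **Prior recovery** — with the likelihood switched off the sampler must
  reproduce the Uniform(0, 10) marginals of all six parameters.  The run
  uses a single 1+1-sequence locus and strong thinning: the parameter
  marginals are exactly uniform for any data size, but a
  Kolmogorov–Smirnov test needs effectively independent draws, so the
  validation uses the smallest genealogy dimension (fastest mixing) and
  wide sample spacing.
* **Parameter recovery** — replicated datasets at a documented truth point
  with 90% interval coverage counted per parameter.  The per-locus rate
  for this experiment is u = 5, giving ≈200–300 segregating sites per
  500-site locus; at much lower rates the experiment has no power (the
  marginal posteriors barely contract from the prior, and the truth values
  m = 0.5 and t = 1 sit at or near the prior's own 5% quantile, so 90%
  coverage is unattainable by any correct sampler).  Each replicate is
  analyzed with two independent 10,000-generation chains whose
  post-burn-in draws are pooled: the migration-direction posterior can be
  bimodal, and pooling independently initialized chains approximates the
  posterior's dispersion far better than one chain of twice the length at
  the same cost.

## Numerical choices

Tolerances: oracle equivalences at 1e−10 relative (pruning) and 1e−12
(per-branch Poisson); block-sum invariance at 1e−9 relative; cache audits
at 1e−8.  Degenerate inputs: zero-length branches give identity transition
matrices; conflicting leaves on a zero-length tree give likelihood 0
(−inf), as do incompatible IS sites; θ = 0 with a realized coalescence in
that class gives density −inf rather than an error inside the sampler.
Ties between event times have measure zero under all proposals and are
rejected by the validator.  The histogram-mode estimate in posterior
summaries uses equal-width bins over [0, bound] with the bin midpoint
reported.

## Known limitations

Single-threaded; no recombination; two populations only; no convergence
diagnostics beyond the trace (effective sample sizes and R-hat are left to
downstream tools); the migration-direction posterior can be strongly
bimodal for weakly informative data, where single finite chains may
under-disperse relative to the exact posterior — the Metropolis-coupled
mode exists for exactly that situation.
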