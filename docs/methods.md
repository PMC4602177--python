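# Methods

`pdlrs` models the evolution of an extended gene family — genes together
with the pseudogenes they gave rise to — inside a dated species tree, and
infers when pseudogenization happened.

## The generative model

A single gene lineage enters the species tree `S` at its degree-one root
`ρ` and evolves towards the leaves. While alive it is exposed to three
kinds of events, each a Poisson process per lineage:

* **duplication** at rate `δ` — the lineage splits into two independent
  copies;
* **loss** at rate `μ` — the lineage dies;
* **pseudogenization** at rate `ψ` — the lineage converts, irreversibly,
  from gene to pseudogene. Pseudogene lineages keep duplicating and dying
  at the same `δ` and `μ` but cannot convert back.

At every speciation vertex of `S` a lineage deterministically bifurcates,
one copy into each descendant species. Lineages that leave no extant
descendant are pruned; what remains is the gene tree `G`, with a
degree-two vertex (the set `Ψ`) marking each surviving conversion.
A valid state therefore satisfies: `Ψ` is an antichain (conversions are
irreversible), every pseudogene leaf has an ancestor in `Ψ`, and no gene
leaf descends from one.

Branch lengths come from a relaxed molecular clock: each edge draws an
independent rate `r` from a Gamma distribution parameterized by mean `m`
and coefficient of variation `c` (shape `1/c²`, scale `mc²`), and an edge
spanning time `t` gets length `l = r·t` (expected substitutions per codon
site).

Sequences evolve down `G` under Goldman–Yang-style codon models with a
mode switch at `Ψ` vertices. Both modes share one parameterization —
zero rate between codons differing at more than one position, otherwise
`π_j` times `κ` for a transition and times `ω` for a nonsynonymous
change, normalized to one expected substitution per unit length. The
gene mode runs on the 61 sense codons (`ω` free); the pseudogene mode is
neutral (`ω = 1`) on all 64 codons, so premature stops can arise and
revert. Equilibrium frequencies are empirical F64 counts from the whole
alignment with add-one pseudocounts, shared between the modes (the gene
mode renormalizes over sense codons). Pruning runs entirely in the
64-state space — the gene matrix simply carries no rates touching stops
— so one partial-likelihood vector passes through mode switches.

## The gene-tree prior

`p(G, l | θ, Ψ, S)` is computed by dynamic programming over a
discretized species tree `S'`: every edge of `S` is augmented with
equidistant interior points (by default proportional to edge duration,
with a floor of 3 and target slice width `height/30`). The DP table
`s(x, y, u)` — the probability that a lineage at point `x` generates the
subtree above and including gene-tree vertex `u`, with `u`'s event at
point `y` — factorizes into a diagonal (the event cases: leaf match,
speciation bifurcation, duplication with factor `2δ·Δt`, and
pseudogenization with factor `ψ·Δt`, the unary analogue of duplication)
and a path extension

    s(x, y, u) = K(x, y) · g(l_u, t(x, y)) · s(y, y, u),

where `g(l, t) = ρ_rate(l/t)/t` is the relaxed-clock length density and
`K(x, y)` multiplies the per-segment 1-to-1 survival factors with, at
every speciation vertex crossed strictly between `x` and `y`, the
probability that the copy split into the other child edge goes extinct.
Interior points carry their slice width so sums approximate time
integrals; the discretization error is `O(1/n_points)` and shrinks
empirically under refinement. The prior is `Σ_y s(ρ, y, c)` over points
below the root, `c` the root's single child.

Two conventions deserve note:

* **Off-side extinction placement.** The extension factor applies the
  off-side extinction only at speciation vertices *strictly between* the
  endpoints, never at the event vertex itself — at a speciation event
  both sides are occupied by the two gene-tree children. Verified by
  forward simulation.
* **Labelled trees vs shapes.** The DP value for a leaf-labelled tree
  equals the sum over process histories of P(history) times the number
  of within-species label assignments realizing the tree. Summing over
  the equivalent labelled trees of one species-labelled shape gives
  P(shape) = DP / |Aut(shape)|. The consistency test bins simulated
  families by shape and checks exactly this identity.

### Birth–death quantities

Because conversion changes neither the duplication nor the loss rate,
the gene- and pseudogene-type extinction probabilities coincide, and the
one-type linear birth–death closed form (Kendall's generating-function
solution) propagates extinction exactly across each slice, together with
the closed-form time integral of the extinction curve that the 1-to-1
(`p11`) factors need:

    p11 segment factor = exp(2δ∫ε − (δ+μ)Δt),     pseudogene type
    p11_gene = p11_pseudo · exp(−ψΔt).

The production path uses these closed forms; a two-type RK4 integrator
is kept as an independent validation route (they agree to ~1e-10), and a
forward Monte-Carlo oracle validates both. The oracle's 1-to-1 estimator
counts *valid designations* at the snapshot point (1 when exactly one
crossing lineage has extant descendants and it has the tracked type, the
number of tracked-type crossers when none survives, else 0), matching
the designation-counting derivation of the `p11` ODE.

## MCMC

The sampler is Metropolis–Hastings over `(G, l, Ψ, θ)`; defaults follow
the standard full analysis (5M iterations, 2.5M burn-in, thinning 500).
One move per iteration, chosen by weight (30% lengths, 20% θ scalars,
20% `Ψ`, 30% topology; topology 0 in fixed-tree mode):

* **Scalars** use truncated-normal random walks inside their supports
  (`ω ∈ [0,10]`, `κ ∈ [0,100]`, rates and lengths in `[0,∞)`) with the
  truncation-normalizer Hastings correction. Default step sizes target
  roughly 20–40% acceptance on typical family posteriors; they are
  config-exposed and should be re-tuned per study.
* **`Ψ` slides** move a pseudogenization vertex one edge down (splitting
  it onto the two child edges, drawing the two new positions uniformly)
  or up (merging two sibling `Ψ` onto the parent edge), proposed up and
  down with probability ½ each; the dimension change carries the exact
  reversible-jump Jacobian (`l_c1·l_c2 / L` for a split). A
  deterministic-midpoint variant (`fixed_fractions`) keeps the chain on
  a finite canonical state space, which is what the enumeration test
  exercises.
* **Topology** moves (NNI, SPR, re-rooting on the suppressed tree) are
  drawn uniformly from explicitly enumerated menus of *valid* results,
  with both menu sizes in the Hastings ratio — a proposed gene tree is
  always valid by construction. Moves whose reverse could not exist
  (regrafting onto the stem edge; moves across `Ψ`-carrying edges) are
  excluded symmetrically. SPR and re-rooting split the target edge at a
  uniform fraction and carry the corresponding Jacobian.

The initial tree is neighbor joining (scikit-bio) on codon-level
p-distances, midpoint-rooted, with one `Ψ` at the midpoint of the parent
edge of each maximal all-pseudogene clade — the unique minimal valid
placement. Priors on `θ` are independent (exponential on `δ, μ, ψ`,
log-normal on `m`, exponential on `c`, uniform on the `ω` and `κ`
boxes) and config-exposed. Convergence diagnostics are effective sample
size (arviz) and split-R̂ on the scalar traces.

Realizations — assignments of gene-tree vertices to dated points of
`S'` — are sampled per thinned state by the standard top-down backtrace
of the DP table; a `Ψ` vertex then gets a continuous time by linear
interpolation between its parent's and child's realized times, weighted
by its two incident edge lengths.

## Distances between pseudogenization configurations

Two configurations of one family are compared on the common suppressed
tree `G*` (identical after removing the degree-two vertices). Each maps
to a set of `G*` edges; a roof/shade relation pairs each edge of one set
with the edges of the other it covers (or is covered by), and distances
aggregate per roof: `D_a` (mean of per-roof mean edge distances), `D_m`
(max of per-roof maxima), with temporal analogues `T_a`, `T_m` using
absolute differences of the origins' times (species-tree time units,
1.0 = full depth). The edge distance is the number of internal vertices
on the shortest path containing both edges. Posterior summaries weight
per-sample distances by empirical sample frequency (`E_*`) or take the
maximum over the support (`M_*`); the printed "maximum" definition
multiplies by the posterior weight, which has no coherent reading as a
distance, so the maximum is taken over the support instead. Samples
whose suppressed topology differs from the reference are excluded and
counted.

## Synthetic data

The simulator is a first-class implementation of the generative process
(it doubles as the oracle for the DP). The grid study emulates the
standard synthetic protocol: a nine-vertebrate host tree scaled to depth
1.0 (≈400 My; stem 0.1), pseudogenization rate 0.5, and 25 families over
`ω ∈ {0.3, 0.6, 0.8, 1.2, 1.8} × κ ∈ {0.2, 0.8, 1.2, 1.6, 2.0}` with
uniform codon frequencies. Duplication and loss rates are not pinned by
the protocol; the defaults `δ = μ = 0.5` per unit time are comparable to
`ψ` and give family sizes of one to a handful of copies per species.
Alignment length defaults to 300 codons; the relaxed clock defaults to
mean 1.0 (one expected substitution per site over the full depth) and
CV 0.5. Families are redrawn (with a cap, logged) until extant, within
size bounds and — for the grid study — containing both a gene and a
pseudogene leaf; the parameter-recovery study instead uses the minimal
selection (extant, ≥2 leaves), because the likelihood does not model
ascertainment.

What the simulator does *not* emulate: alignment error and gaps,
frameshifts and fragmentary pseudogenes, rate heterogeneity across
sites, and lineage sorting — so passing tests demonstrate correctness of
the inference machinery under the model, not robustness to real-data
violations of it.

## Problem sizes used by the checks

The test suite and the acceptance script scale the studies down: the
grid study runs fixed-tree chains (the same usage as the biological
pipeline, which fixed candidate trees) of 1 200 iterations at 150 codons
in the suite and 2 000 iterations at 300 codons in the acceptance
script; the recovery study runs 40 free-topology chains of 5 000
iterations at 60 codons on a three-species host with unit-mean
exponential rate priors (a prior concentrated an order of magnitude
above the simulated rates would make fixed-truth interval coverage
uninformative); prior recovery uses 10⁴ thinned samples; the toy
enumeration compares a 30 000-iteration chain on a 3-leaf, 2-codon
problem against the directly normalized posterior over its four
canonical states.

## Numerical choices and limitations

* Per-vertex DP vectors carry a running log-scale; likelihood pruning
  scales per node. Degenerate inputs (zero-probability states, `ψ = 0`
  with `Ψ ≠ ∅`) return `-inf` rather than raising.
* The spectral decomposition of the reversible codon generator is reused
  across branch lengths; matrices are clipped to `[0, 1]` and
  row-renormalized against round-off.
* Ultrametricity tolerance is relative 1e-6; a missing stem defaults to
  10% of tree height.
* Ties in `select_map_tree` go to the first-seen candidate (logged).
* Known limitations: no transfer events, no per-branch rate categories,
  no site-rate heterogeneity, no indel model; the MCMC is single-chain
  (no tempering), and mixing over topology for families above ~30 leaves
  is slow.
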