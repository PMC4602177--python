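"""Forward simulation of the generative process.

A single gene lineage enters the species tree at its degree-one root and
evolves towards the leaves: duplication at rate ``delta``, loss at rate
``mu``, irreversible gene-to-pseudogene conversion at rate ``psi`` (genes
only), deterministic bifurcation at every speciation vertex.  Lineages
with no extant descendant are pruned, which also suppresses the
pass-through vertices they leave behind; conversions that survive remain
as degree-two Psi vertices.  Branch lengths come from the relaxed clock
(independent Gamma rates per edge), and sequences evolve down the tree
under the dual codon models, switching mode at Psi vertices.

The synthetic-study driver reproduces the study design used throughout:
a nine-species vertebrate host tree of depth 1.0 (about 400 My),
pseudogenization rate 0.5, and a 5 x 5 grid of gene-mode dN/dS and
transition/transversion ratios.  Duplication and loss default to 0.5 per
unit time, comparable to the pseudogenization rate and giving family
sizes of a handful of copies per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_models import CodonModel, CodonModelParams, GENE_MODE, PSEUDO_MODE
from .gene_tree import GENE, PSEUDO, GNode, GeneTreeState
from .params import ModelParams, RateModel
from .species_tree import DatedSpeciesTree, parse_dated_species_tree
from .two_type_bd import BDRates

__all__ = [
    "SimulatedFamily",
    "simulate_gene_tree",
    "assign_lengths",
    "simulate_alignment",
    "synthetic_study",
    "default_species_tree",
    "OMEGA_GRID",
    "KAPPA_GRID",
]

OMEGA_GRID = (0.3, 0.6, 0.8, 1.2, 1.8)
KAPPA_GRID = (0.2, 0.8, 1.2, 1.6, 2.0)

#: Nine-vertebrate host tree, depth scaled to 1.0 (~400 My), stem 0.1.
DEFAULT_SPECIES_NEWICK = (
    "(((((((human:0.015,chimp:0.015):0.06,macaque:0.075):0.15,"
    "(mouse:0.05,rat:0.05):0.175):0.0175,dog:0.2425):0.1575,"
    "opossum:0.4):0.4,chicken:0.8):0.2,zebrafish:1.0):0.1;"
)


def default_species_tree() -> DatedSpeciesTree:
    return parse_dated_species_tree(DEFAULT_SPECIES_NEWICK)


@dataclass
class SimulatedFamily:
    """One simulated gene family with its ground truth."""

    state: GeneTreeState | None
    node_times: dict[GNode, float]
    extinct: bool
    n_redraws: int = 0
    alignment: dict[str, str] | None = None
    omega: float | None = None
    kappa: float | None = None

    def psi_times(self) -> dict[frozenset[str], float]:
        """Truth record: pseudogene clade below each Psi vertex -> time."""
        out = {}
        for n in self.state.root.postorder():
            if n.is_psi:
                clade = frozenset(l.name for l in n.leaves())
                out[clade] = self.node_times[n]
        return out


def simulate_gene_tree(S: DatedSpeciesTree, rates: BDRates, seed=None, rng=None) -> SimulatedFamily:
    """Simulate the two-type branching process and prune extinct lineages."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    d, m, p = rates.delta, rates.mu, rates.psi
    times: dict[GNode, float] = {}
    leaf_counter: dict[str, int] = {}
    leaf_species: dict[str, str] = {}
    leaf_class: dict[str, str] = {}

    def evolve(v: int, t: float, is_gene: bool) -> GNode | None:
        total = d + m + (p if is_gene else 0.0)
        t_ev = t - rng.exponential(1.0 / total) if total > 0 else -np.inf
        tv = float(S.node_time[v])
        if t_ev <= tv:
            ch = S.children[v]
            if not ch:
                sp = S.leaf_name[v]
                leaf_counter[sp] = leaf_counter.get(sp, 0) + 1
                name = f"{sp}_{leaf_counter[sp]}{'P' if not is_gene else ''}"
                leaf = GNode(name=name)
                leaf_species[name] = sp
                leaf_class[name] = GENE if is_gene else PSEUDO
                times[leaf] = 0.0
                return leaf
            a = evolve(ch[0], tv, is_gene)
            b = evolve(ch[1], tv, is_gene)
            if a is None:
                return b
            if b is None:
                return a
            node = GNode()
            node.add_child(a)
            node.add_child(b)
            times[node] = tv
            return node
        u = rng.random() * total
        if u < d:
            a = evolve(v, t_ev, is_gene)
            b = evolve(v, t_ev, is_gene)
            if a is None:
                return b
            if b is None:
                return a
            node = GNode()
            node.add_child(a)
            node.add_child(b)
            times[node] = t_ev
            return node
        if u < d + m:
            return None
        node = GNode(is_psi=True)
        sub = evolve(v, t_ev, False)
        if sub is None:
            return None
        node.add_child(sub)
        times[node] = t_ev
        return node

    first = S.children[0][0]
    top = evolve(first, float(S.node_time[0]), True)
    if top is None:
        return SimulatedFamily(None, {}, extinct=True)
    root = GNode()
    root.add_child(top)
    times[root] = float(S.node_time[0])
    state = GeneTreeState(root, leaf_species, leaf_class)
    return SimulatedFamily(state, times, extinct=False)


def assign_lengths(fam: SimulatedFamily, rate_model: RateModel, seed=None, rng=None) -> None:
    """Draw an independent Gamma rate per edge and set l = r * t in place."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    for n in fam.state.root.postorder():
        if n.parent is None:
            continue
        t = fam.node_times[n.parent] - fam.node_times[n]
        r = rng.gamma(rate_model.shape, rate_model.scale)
        n.length = max(r * t, 1e-12)


def simulate_alignment(
    state: GeneTreeState,
    gene_model: CodonModel,
    pseudo_model: CodonModel,
    n_codons: int,
    seed=None,
    rng=None,
) -> dict[str, str]:
    """Evolve codon sequences down the tree; returns leaf id -> sequence."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    space = gene_model.params.space
    pi = gene_model.pi64()
    root_seq = rng.choice(64, size=n_codons, p=pi)
    out: dict[str, str] = {}

    def down(node: GNode, seq: np.ndarray) -> None:
        for child in node.children:
            model = gene_model if state.edge_mode(child) == GENE_MODE else pseudo_model
            P = model.transition64(float(child.length))
            cum = P.cumsum(axis=1)
            u = rng.random(len(seq))
            new = np.array(
                [np.searchsorted(cum[s], x) for s, x in zip(seq, u)], dtype=int
            )
            np.clip(new, 0, 63, out=new)
            if child.is_leaf:
                out[child.name] = "".join(space.codons[c] for c in new)
            else:
                down(child, new)

    down(state.root, root_seq)
    return out


def _uniform_codon_params(omega: float, kappa: float):
    pi = np.full(64, 1.0 / 64)
    gene = CodonModel(CodonModelParams(kappa=kappa, omega=omega, pi=pi, mode=GENE_MODE))
    pseudo = CodonModel(CodonModelParams(kappa=kappa, omega=1.0, pi=pi, mode=PSEUDO_MODE))
    return gene, pseudo


def simulate_family(
    S: DatedSpeciesTree,
    theta: ModelParams,
    omega: float,
    kappa: float,
    n_codons: int,
    rng,
    min_leaves: int = 3,
    max_leaves: int = 40,
    max_redraws: int = 1000,
    require_classes: bool = True,
) -> SimulatedFamily:
    """One usable family: extant, of workable size and (by default, as in
    the grid study) with at least one gene and one pseudogene leaf;
    redrawn (with a cap) otherwise.  ``require_classes=False`` keeps the
    selection minimal (extant and sized), the appropriate design when the
    downstream analysis should not be ascertainment-biased."""
    gene_model, pseudo_model = _uniform_codon_params(omega, kappa)
    for attempt in range(max_redraws):
        fam = simulate_gene_tree(S, theta.rates, rng=rng)
        if fam.extinct:
            continue
        classes = set(fam.state.leaf_class.values())
        n_leaves = len(fam.state.leaves())
        if not (min_leaves <= n_leaves <= max_leaves):
            continue
        if require_classes and GENE not in classes:
            continue
        if require_classes and theta.psi > 0 and PSEUDO not in classes:
            continue
        assign_lengths(fam, theta.rate_model, rng=rng)
        fam.alignment = simulate_alignment(
            fam.state, gene_model, pseudo_model, n_codons, rng=rng
        )
        fam.n_redraws = attempt
        fam.omega = omega
        fam.kappa = kappa
        return fam
    raise RuntimeError("no usable family within the redraw cap")


def synthetic_study(
    S: DatedSpeciesTree | None = None,
    seed: int = 0,
    n_codons: int = 300,
    delta: float = 0.5,
    mu: float = 0.5,
    psi: float = 0.5,
    rate_mean: float = 1.0,
    rate_cv: float = 0.5,
    omega_grid=OMEGA_GRID,
    kappa_grid=KAPPA_GRID,
    **family_kwargs,
) -> list[SimulatedFamily]:
    """The full grid: one family per (omega, kappa) combination."""
    S = S if S is not None else default_species_tree()
    rng = np.random.default_rng(seed)
    families = []
    for omega in omega_grid:
        for kappa in kappa_grid:
            theta = ModelParams(
                rates=BDRates(delta, mu, psi),
                rate_model=RateModel(rate_mean, rate_cv),
                kappa=kappa,
                omega=omega,
            )
            families.append(
                simulate_family(S, theta, omega, kappa, n_codons, rng, **family_kwargs)
            )
    return families
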