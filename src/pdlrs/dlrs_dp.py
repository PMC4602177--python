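"""Gene-tree prior p(G, l | theta, Psi, S) by dynamic programming.

The table ``s(x, y, u)`` is the probability (density over the lengths
``l``) that a single lineage starting at point ``x`` of the discretized
species tree generates the subtree ``G_u`` (including the edge above
``u``) with ``u``'s event at point ``y``.  Writing ``g(l, t)`` for the
relaxed-clock length density and ``K(x, y)`` for the chain factor (1-to-1
survival along the path times extinction of the copies split off at
speciation vertices crossed strictly between ``x`` and ``y``), the
recursion factorizes as

    s(x, y, u) = K_mode(x, y) * g(l_u, t(x, y)) * s(y, y, u),   x != y,

with the diagonal given by the event cases:

* leaf ``u`` at its species leaf: 1;
* bifurcation of ``u`` (not Psi) at the speciation vertex ``sigma(u)``:
  the product of the two one-sided descendant sums, each child matched to
  the side holding its species;
* duplication of ``u`` (not Psi) at an interior point: ``2 delta dt(x)``
  times the product of both children's descendant sums;
* pseudogenization ``u`` in Psi at an interior point: ``psi dt(x)`` times
  the single child's descendant sum (the unary analogue of the
  duplication case - conversion events, like duplications, happen in the
  interior of time slices, never exactly at speciation vertices);
* everywhere else: 0.

Interior event points carry their slice width ``dt`` so that sums over
descendants approximate the time integrals.  The prior is the sum of
``s(rho, y, c)`` over all points ``y`` below the degree-one root, where
``c`` is the root's single child.

Everything is carried per gene-tree vertex as a vector over points with a
running log-scale, so small densities do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_tree import GNode, GeneTreeState, sigma, validate_state
from .params import ModelParams
from .species_tree import DiscretizedSpeciesTree
from .two_type_bd import BDTables, compute_bd_tables
from .gene_tree import PSEUDO

__all__ = ["STable", "compute_s_table", "gene_tree_log_prior", "simulation_consistency_check"]


@dataclass
class STable:
    """Per-vertex DP vectors (diagonal of s) plus the pieces to rebuild
    the off-diagonal entries on demand."""

    state: GeneTreeState
    theta: ModelParams
    Sp: DiscretizedSpeciesTree
    bd: BDTables
    sig: dict[GNode, int]
    sdiag: dict[GNode, np.ndarray]
    logscale: dict[GNode, float]
    U: dict[GNode, np.ndarray]       # descendant sums per start point
    side_sums: dict[GNode, dict[int, tuple[float, float]]]
    edge_is_pseudo: dict[GNode, bool]
    marginalize_lengths: bool = False

    def W(self, u: GNode) -> np.ndarray:
        """The extension matrix W[x, y] = K_mode(x, y) g(l_u, t(x, y))."""
        Sp = self.Sp
        K = self.bd.K_p if self.edge_is_pseudo[u] else self.bd.K_g
        if self.marginalize_lengths:
            g = np.where(Sp.desc_strict, 1.0, 0.0)
        else:
            T = np.where(Sp.desc_strict, Sp.time_between_mat, np.nan)
            g = np.where(
                Sp.desc_strict,
                self.theta.rate_model.length_density(float(u.length), T),
                0.0,
            )
        return K * np.nan_to_num(g)

    def to_tsv(self) -> str:
        """Debug dump: one row per (gene-tree vertex, point) diagonal entry."""
        lines = ["vertex\tpoint\tsdiag\tlogscale"]
        for u, vec in self.sdiag.items():
            label = ",".join(sorted(l.name for l in u.leaves()))
            for y in np.nonzero(vec)[0]:
                lines.append(f"{label}\t{y}\t{vec[y]:.8g}\t{self.logscale[u]:.6g}")
        return "\n".join(lines) + "\n"

    def s(self, x: int, y: int, u: GNode) -> float:
        """A single table entry s(x, y, u) (unscaled by the running log)."""
        if x == y:
            return float(self.sdiag[u][y]) * float(np.exp(self.logscale[u]))
        if not self.Sp.desc_strict[x, y]:
            return 0.0
        return float(self.W(u)[x, y] * self.sdiag[u][y]) * float(
            np.exp(self.logscale[u])
        )


def compute_s_table(
    state: GeneTreeState,
    theta: ModelParams,
    Sp: DiscretizedSpeciesTree,
    bd: BDTables | None = None,
    marginalize_lengths: bool = False,
) -> STable:
    """Fill the DP table bottom-up over the gene tree.

    With ``marginalize_lengths=True`` every length-density factor is
    replaced by 1 (each edge's density integrates to one for a fixed
    realization), yielding the probability of the topology-with-Psi alone
    - the quantity the forward simulator can verify by frequency.
    """
    problems = validate_state(state)
    if problems:
        raise ValueError("invalid gene-tree state: " + "; ".join(problems))
    if bd is None:
        bd = compute_bd_tables(Sp, theta.rates)
    sig_S = sigma(state, Sp.S)
    P = Sp.n
    w = Sp.slice_width  # zero at species-tree vertices
    delta, psi = theta.delta, theta.psi
    desc = Sp.desc_strict

    sdiag: dict[GNode, np.ndarray] = {}
    logscale: dict[GNode, float] = {}
    U: dict[GNode, np.ndarray] = {}
    side_sums: dict[GNode, dict[int, tuple[float, float]]] = {}
    edge_is_pseudo: dict[GNode, bool] = {}

    table = STable(
        state=state,
        theta=theta,
        Sp=Sp,
        bd=bd,
        sig=sig_S,
        sdiag=sdiag,
        logscale=logscale,
        U=U,
        side_sums=side_sums,
        edge_is_pseudo=edge_is_pseudo,
        marginalize_lengths=marginalize_lengths,
    )

    # per-edge length-density over the flat comparable-pair arrays
    rm = theta.rate_model
    shape_m1 = rm.shape - 1.0
    inv_scale = 1.0 / rm.scale
    from scipy.special import gammaln

    log_const = -gammaln(rm.shape) - rm.shape * np.log(rm.scale)
    pair_x, pair_y = Sp.pair_x, Sp.pair_y
    for u in state.root.postorder():
        if u is state.root:
            continue
        edge_is_pseudo[u] = state.edge_mode(u) == PSEUDO
        if u.is_leaf:
            vec = np.zeros(P)
            vec[Sp.point_of_vertex[sig_S[u]]] = 1.0
            ls = 0.0
        elif u.is_psi:
            (v,) = u.children
            vec = psi * w * U[v]
            ls = logscale[v]
        else:
            v, w2 = u.children
            vec = 2.0 * delta * w * U[v] * U[w2]
            x0 = int(Sp.point_of_vertex[sig_S[u]])
            if Sp.is_speciation[x0]:
                lv, rv = side_sums[v][x0]
                lw, rw = side_sums[w2][x0]
                vec[x0] = lv * rw + lw * rv
            ls = logscale[v] + logscale[w2]
        m = float(vec.max())
        if m > 0 and np.isfinite(m):
            vec = vec / m
            ls += float(np.log(m))
        sdiag[u] = vec
        logscale[u] = ls
        # sums the parent will need: over strict descendants of each point
        K_pair = bd.K_p_pair if edge_is_pseudo[u] else bd.K_g_pair
        if marginalize_lengths:
            w_pair = K_pair * vec[pair_y]
        else:
            l_u = float(u.length)
            logg = (
                shape_m1 * (np.log(l_u) - Sp.pair_logT)
                - l_u * inv_scale * Sp.pair_invT
                - Sp.pair_logT
                + log_const
            )
            w_pair = K_pair * np.exp(logg) * vec[pair_y]
        U[u] = np.bincount(pair_x, weights=w_pair, minlength=P)
        ss: dict[int, tuple[float, float]] = {}
        for x, (li, ri) in Sp.side_pairs.items():
            ss[x] = (float(w_pair[li].sum()), float(w_pair[ri].sum()))
        side_sums[u] = ss
    return table


def gene_tree_log_prior(
    state: GeneTreeState,
    theta: ModelParams,
    Sp: DiscretizedSpeciesTree,
    bd: BDTables | None = None,
    table: STable | None = None,
    marginalize_lengths: bool = False,
) -> float:
    """log p(G, l | theta, Psi, S) = log sum_y s(rho, y, c)."""
    if table is None:
        table = compute_s_table(state, theta, Sp, bd, marginalize_lengths)
    c = table.state.root.children[0]
    total = float(table.U[c][table.Sp.root_point])
    if total <= 0 or not np.isfinite(total):
        return -np.inf
    return float(np.log(total) + table.logscale[c])


# ---------------------------------------------------------------------------
# consistency between the DP prior and the forward simulator


def _canonical_shape(node: GNode, state: GeneTreeState) -> tuple[str, int]:
    """Canonical string of the species-labelled shape (with Psi marks) and
    the automorphism count 2^k (k = internal vertices with equal halves)."""

    def rec(n: GNode) -> tuple[str, int]:
        if n.is_leaf:
            return state.leaf_species[n.name], 0
        parts = [rec(c) for c in n.children]
        keys = sorted(p[0] for p in parts)
        sym = sum(p[1] for p in parts)
        if len(keys) == 2 and keys[0] == keys[1]:
            sym += 1
        tag = "PSI" if n.is_psi else ""
        return "(" + ",".join(keys) + ")" + tag, sym

    key, sym = rec(node)
    return key, 2**sym


def shape_key(state: GeneTreeState) -> str:
    """Canonical species-labelled shape of a state (root child downward)."""
    return _canonical_shape(state.root.children[0], state)[0]


def shape_probability_factor(state: GeneTreeState) -> float:
    """Factor converting the DP value of a labelled tree into the
    probability of observing its species-labelled shape.

    With leaf labels exchangeable within species, the DP value equals the
    sum over histories of P(history) times the number of label
    assignments realizing the labelled tree, so summing over the
    ``prod n_s! / aut`` equivalent labelled trees gives
    P(shape) = DP / aut, with ``aut`` the shape's automorphism count."""
    _, aut = _canonical_shape(state.root.children[0], state)
    return 1.0 / aut


def simulation_consistency_check(
    theta: ModelParams,
    S,
    n_reps: int,
    seed: int,
    Sp: DiscretizedSpeciesTree | None = None,
    top_k: int = 5,
):
    """Compare DP topology probabilities with forward-simulation
    frequencies.

    Families are simulated under the generative process, binned by their
    species-labelled shape (with Psi marks), and the most frequent shapes'
    empirical frequencies are compared with the DP probability (lengths
    marginalized, divided by the shape's automorphism count).  Returns a list
    of dicts with shape, frequency, DP probability and z-score.
    """
    from .simulator import simulate_gene_tree
    from .species_tree import discretize

    if Sp is None:
        Sp = discretize(S, n_points=8)
    bd = compute_bd_tables(Sp, theta.rates)
    counts: dict[str, int] = {}
    reps: dict[str, GeneTreeState] = {}
    for i in range(n_reps):
        fam = simulate_gene_tree(S, theta.rates, seed=seed + i)
        if fam.extinct:
            key = "<extinct>"
        else:
            key = shape_key(fam.state)
            reps.setdefault(key, fam.state)
        counts[key] = counts.get(key, 0) + 1
    report = []
    ranked = sorted(counts.items(), key=lambda kv: -kv[1])
    for key, cnt in ranked[:top_k]:
        if key == "<extinct>":
            continue
        st = reps[key].copy()
        for n in st.root.postorder():
            if n.parent is not None and (n.length is None or n.length <= 0):
                n.length = 1.0
        lp = gene_tree_log_prior(st, theta, Sp, bd, marginalize_lengths=True)
        prob = float(np.exp(lp)) * shape_probability_factor(st)
        freq = cnt / n_reps
        se = float(np.sqrt(max(freq * (1 - freq), 1e-12) / n_reps))
        report.append(
            {
                "shape": key,
                "freq": freq,
                "dp_prob": prob,
                "z": (freq - prob) / se if se > 0 else np.nan,
                "n": cnt,
            }
        )
    return report
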