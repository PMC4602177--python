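"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different routes than the
package: the likelihood by direct enumeration over internal codon states,
and the gene-tree prior by a literal, memoized implementation of the
per-segment recursion (one species-tree segment at a time, with the
length-density ratio form), instead of the package's vectorized
chain-factor sweep.
"""

from __future__ import annotations

import numpy as np

from pdlrs.codon_models import GENE_MODE
from pdlrs.gene_tree import GeneTreeState, sigma
from pdlrs.species_tree import DiscretizedSpeciesTree
from pdlrs.two_type_bd import BDTables


def enumeration_log_likelihood(D, state, gene_model, pseudo_model):
    """P(D | G, l, Psi) by summation over every joint assignment of codon
    states to the internal vertices (including Psi vertices).

    The full joint probability array over all 64^k internal assignments
    is materialized by broadcasting and summed - no recursive
    marginalization, so it is an independent route from pruning."""
    internals = [n for n in state.nodes() if not n.is_leaf]
    axis = {n: i for i, n in enumerate(internals)}
    k = len(internals)
    if k > 4:
        raise ValueError("enumeration oracle limited to 4 internal vertices")
    leaves = state.leaves()
    P = {}
    for n in state.nodes():
        if n.parent is None:
            continue
        model = gene_model if state.edge_mode(n) == GENE_MODE else pseudo_model
        P[n] = model.transition64(float(n.length))
    pi = gene_model.pi64()
    row = {sid: i for i, sid in enumerate(D.ids)}

    def on_axes(arr, axes):
        order = sorted(range(len(axes)), key=lambda i: axes[i])
        shape = [1] * k
        for idx in order:
            shape[axes[idx]] = arr.shape[idx]
        return np.transpose(arr, order).reshape(shape)

    total = 0.0
    for site in range(D.codes.shape[1]):
        joint = on_axes(pi, [axis[state.root]])
        for n in state.nodes():
            if n.parent is None:
                continue
            pa = axis[n.parent]
            if n.is_leaf:
                obs = int(D.codes[row[n.name], site])
                vec = np.ones(64) if obs < 0 else P[n][:, obs]
                joint = joint * on_axes(vec, [pa])
            else:
                joint = joint * on_axes(P[n], [pa, axis[n]])
        total += np.log(joint.sum())
    return float(total)


def recursive_log_prior(
    state: GeneTreeState,
    theta,
    Sp: DiscretizedSpeciesTree,
    bd: BDTables,
):
    """p(G, l | theta, Psi, S) by the literal per-segment recursion.

    s(x, y, u) steps a single segment at a time from the top; crossing a
    speciation vertex multiplies the off-side extinction, and the length
    density enters as a ratio g(l, t(x, y)) / g(l, t(z, y)), mirroring
    the one-step reduction of the written recursion."""
    sig = sigma(state, Sp.S)
    rm = theta.rate_model
    g = rm.length_density
    delta, psi = theta.delta, theta.psi
    memo_s = {}
    memo_d = {}

    def is_pseudo_edge(u):
        return state.edge_mode(u) == "pseudogene"

    def p11seg(x, z, u):
        seg = bd.seg_log_p11_p if is_pseudo_edge(u) else bd.seg_log_p11_g
        return float(np.exp(seg[z]))

    def sdiag(x, u):
        key = (x, id(u))
        if key in memo_d:
            return memo_d[key]
        val = 0.0
        if u.is_leaf:
            val = 1.0 if x == int(Sp.point_of_vertex[sig[u]]) else 0.0
        elif u.is_psi:
            if Sp.vertex_of[x] < 0:  # interior points only
                (v,) = u.children
                tot = sum(s(x, y, v) for y in np.nonzero(Sp.desc_strict[x])[0])
                val = psi * float(Sp.slice_width[x]) * tot
        else:
            v, w = u.children
            if Sp.vertex_of[x] >= 0:
                if Sp.is_speciation[x] and x == int(Sp.point_of_vertex[sig[u]]):
                    lmask, rmask = Sp.side_desc[x]
                    sums = {}
                    for child in (v, w):
                        sums[("L", id(child))] = sum(
                            s(x, y, child) for y in np.nonzero(lmask)[0]
                        )
                        sums[("R", id(child))] = sum(
                            s(x, y, child) for y in np.nonzero(rmask)[0]
                        )
                    val = (
                        sums[("L", id(v))] * sums[("R", id(w))]
                        + sums[("L", id(w))] * sums[("R", id(v))]
                    )
            else:
                desc = np.nonzero(Sp.desc_strict[x])[0]
                val = (
                    2.0
                    * delta
                    * float(Sp.slice_width[x])
                    * sum(s(x, y, v) for y in desc)
                    * sum(s(x, y, w) for y in desc)
                )
        memo_d[key] = val
        return val

    def s(x, y, u):
        if x == y:
            return sdiag(x, u)
        key = (x, y, id(u))
        if key in memo_s:
            return memo_s[key]
        z = int(Sp.path_child[x, y])
        base = s(z, y, u)
        if base == 0.0:
            memo_s[key] = 0.0
            return 0.0
        l_u = float(u.length)
        val = p11seg(x, z, u) * base
        if z != y and Sp.is_speciation[z]:
            # passing through a speciation: the off-path copy dies out
            on_path = int(Sp.path_child[z, y])
            arc = bd.eps_arc_p if is_pseudo_edge(u) else bd.eps_arc_g
            for o in Sp.point_children[z]:
                if o != on_path:
                    val *= arc[(z, o)]
        t_xy = float(Sp.point_time[x] - Sp.point_time[y])
        if z == y:
            val *= float(g(l_u, t_xy))
        else:
            t_zy = float(Sp.point_time[z] - Sp.point_time[y])
            ratio = float(g(l_u, t_xy)) / float(g(l_u, t_zy))
            val *= ratio
        memo_s[key] = val
        return val

    rho = Sp.root_point
    c = state.root.children[0]
    total = sum(s(rho, y, c) for y in np.nonzero(Sp.desc_strict[rho])[0])
    return float(np.log(total)) if total > 0 else -np.inf
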