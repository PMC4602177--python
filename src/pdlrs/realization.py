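"""Sampling dated realizations from the DP table.

A realization maps the gene-tree vertices to points of the discretized
species tree, drawn from their joint posterior given the state by the
standard top-down stochastic backtrace: the root's child is assigned
point ``y`` with probability proportional to ``s(rho, y, c)``, and each
child is then assigned conditionally on its parent's point.  A
pseudogenization vertex finally receives a continuous time by linear
interpolation between its parent's and child's realized times, weighted
by the lengths of its two incident edges (the longer the edge above, the
closer to the child).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dlrs_dp import STable
from .gene_tree import GNode

__all__ = ["Realization", "sample_realization"]


@dataclass
class Realization:
    """Vertex-to-point assignment plus event times.

    ``points`` covers every non-root vertex of ``G``; ``times`` gives the
    event time of each vertex, with Psi vertices carrying their
    interpolated (continuous) time instead of their grid point's time.
    """

    points: dict[GNode, int]
    times: dict[GNode, float]

    def psi_clade_times(self) -> dict[frozenset, float]:
        out = {}
        for n, t in self.times.items():
            if n.is_psi:
                out[frozenset(l.name for l in n.leaves())] = t
        return out


def sample_realization(table: STable, rng: np.random.Generator) -> Realization:
    """Draw one realization by backtracing the DP table."""
    Sp = table.Sp
    state = table.state
    points: dict[GNode, int] = {}

    def draw(weights: np.ndarray) -> int:
        total = weights.sum()
        if not (total > 0):
            raise RuntimeError("zero-probability backtrace: inconsistent DP table")
        return int(rng.choice(len(weights), p=weights / total))

    def assign_children(u: GNode, y_u: int) -> None:
        if u.is_leaf:
            return
        if u.is_psi or not Sp.is_speciation[y_u]:
            # duplication or pseudogenization point: children start at y_u
            for v in u.children:
                w = table.W(v)[y_u] * table.sdiag[v]
                w = np.where(Sp.desc_strict[y_u], w, 0.0)
                y_v = draw(w)
                points[v] = y_v
                assign_children(v, y_v)
        else:
            # speciation: one child per side, matched by feasibility
            v, w2 = u.children
            lmask, rmask = Sp.side_desc[y_u]
            lv, rv = table.side_sums[v][y_u]
            lw, rw = table.side_sums[w2][y_u]
            a, b = lv * rw, lw * rv
            if not (a + b > 0):
                raise RuntimeError("zero-probability backtrace at a speciation")
            v_left = rng.random() < a / (a + b)
            for child, mask in ((v, lmask), (w2, rmask)) if v_left else (
                (v, rmask),
                (w2, lmask),
            ):
                w = table.W(child)[y_u] * table.sdiag[child]
                w = np.where(mask, w, 0.0)
                y_c = draw(w)
                points[child] = y_c
                assign_children(child, y_c)

    c = state.root.children[0]
    rho = Sp.root_point
    w0 = np.where(Sp.desc_strict[rho], table.W(c)[rho] * table.sdiag[c], 0.0)
    y_c = draw(w0)
    points[c] = y_c
    assign_children(c, y_c)

    times: dict[GNode, float] = {
        n: float(Sp.point_time[p]) for n, p in points.items()
    }
    for u in list(points):
        if u.is_psi:
            t_p = (
                float(Sp.point_time[Sp.root_point])
                if u.parent is state.root
                else times[u.parent]
            )
            (child,) = u.children
            t_c = times[child]
            lu = float(u.length)
            lc = float(child.length)
            frac = lu / (lu + lc) if lu + lc > 0 else 0.5
            times[u] = t_p - (t_p - t_c) * frac
    return Realization(points=points, times=times)
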