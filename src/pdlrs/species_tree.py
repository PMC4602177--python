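"""Dated species trees and their discretization.

The host tree ``S`` is a rooted, binary, ultrametric tree with absolute
times on its vertices: leaves sit at time 0 and times strictly increase
towards the root.  The root is a degree-one vertex ``rho`` sitting on a
stem edge above the first speciation; the stem is where a gene family
originates.

The discretized tree ``S'`` augments every edge of ``S`` with equidistant
interior time points.  Sums over these points approximate the time
integrals of the birth-death dynamic programs, so every interior point
carries the width of the time slice it represents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "DatedSpeciesTree",
    "DiscretizedSpeciesTree",
    "parse_dated_species_tree",
    "discretize",
]

DEFAULT_STEM_FRACTION = 0.1
ULTRAMETRIC_RTOL = 1e-6


class SpeciesTreeError(ValueError):
    """Raised for malformed species-tree input."""


@dataclass
class DatedSpeciesTree:
    """A dated, rooted, binary species tree with a degree-one root.

    Vertices are indexed ``0..n_vertices-1``; the root has index 0 and a
    single child, every other internal vertex has exactly two children.

    Attributes
    ----------
    parent : array of int, -1 for the root.
    children : list of lists of child indices.
    node_time : absolute time of each vertex (leaves at 0).
    leaf_name : dict vertex -> species label for leaves.
    """

    parent: np.ndarray
    children: list[list[int]]
    node_time: np.ndarray
    leaf_name: dict[int, str]
    name_to_leaf: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.name_to_leaf = {v: k for k, v in self.leaf_name.items()}
        if len(self.name_to_leaf) != len(self.leaf_name):
            raise SpeciesTreeError("duplicate leaf names")
        if len(self.children[0]) != 1:
            raise SpeciesTreeError("root must have exactly one child")
        for v, ch in enumerate(self.children):
            if v != 0 and len(ch) not in (0, 2):
                raise SpeciesTreeError(f"vertex {v} is not binary")

    @property
    def n_vertices(self) -> int:
        return len(self.children)

    @property
    def root(self) -> int:
        return 0

    @property
    def leaves(self) -> list[int]:
        return [v for v, ch in enumerate(self.children) if not ch]

    @property
    def height(self) -> float:
        return float(self.node_time[0])

    def postorder(self) -> list[int]:
        out: list[int] = []
        stack = [0]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return out[::-1]

    def is_ancestor(self, x: int, y: int) -> bool:
        """True if ``x`` is an ancestor of ``y`` or equal to it."""
        while y != -1:
            if y == x:
                return True
            y = int(self.parent[y])
        return False

    def mrca(self, vertices: list[int]) -> int:
        paths = []
        for v in vertices:
            path = []
            while v != -1:
                path.append(v)
                v = int(self.parent[v])
            paths.append(path[::-1])
        anc = 0
        for depth in range(min(len(p) for p in paths)):
            cand = paths[0][depth]
            if all(p[depth] == cand for p in paths):
                anc = cand
            else:
                break
        return anc


def parse_dated_species_tree(
    newick_text: str,
    stem_fraction: float = DEFAULT_STEM_FRACTION,
    rtol: float = ULTRAMETRIC_RTOL,
) -> DatedSpeciesTree:
    """Parse a Newick string with branch lengths interpreted as times.

    The tree must be binary and ultrametric (all root-to-leaf path sums
    equal within relative tolerance ``rtol``).  A branch length on the
    outermost clade is taken as the stem above the degree-one root; if
    absent, a stem of ``stem_fraction`` times the tree height is added.
    """
    tree = dendropy.Tree.get(
        data=newick_text, schema="newick", suppress_internal_node_taxa=True
    )
    seed = tree.seed_node
    explicit_stem = seed.edge.length  # may be None
    # collapse degree-one chains above the first speciation into the stem
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        explicit_stem = (explicit_stem or 0.0) + float(child.edge.length or 0.0)
        seed = child
    sc = seed.child_nodes()

    if sc and len(sc) != 2:
        raise SpeciesTreeError("polytomy at the root; tree must be binary")

    # depth of each node below `seed`
    depth: dict[dendropy.Node, float] = {seed: 0.0}
    order = [seed]
    for nd in seed.preorder_iter():
        if nd is seed:
            continue
        if nd.edge.length is None:
            raise SpeciesTreeError("missing branch length")
        depth[nd] = depth[nd.parent_node] + float(nd.edge.length)
        order.append(nd)
        if nd.child_nodes() and len(nd.child_nodes()) != 2:
            raise SpeciesTreeError("polytomy; tree must be binary")

    leaf_depths = {
        nd.taxon.label: depth[nd] for nd in seed.leaf_iter()
    }
    height = max(leaf_depths.values())
    bad = {
        name: d
        for name, d in leaf_depths.items()
        if abs(d - height) > rtol * max(height, 1.0)
    }
    if bad:
        report = ", ".join(f"{k}: depth {v:g}" for k, v in sorted(bad.items()))
        raise SpeciesTreeError(
            f"tree is not ultrametric (height {height:g}); offending leaves: {report}"
        )

    stem = float(explicit_stem) if explicit_stem else stem_fraction * height
    if stem <= 0:
        raise SpeciesTreeError("stem duration must be positive")

    # build index arrays: 0 = degree-one root, 1 = first speciation (seed)
    nodes = [None] + order  # placeholder for the synthetic root
    index = {nd: i + 1 for i, nd in enumerate(order)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    node_time = np.zeros(n)
    leaf_name: dict[int, str] = {}
    node_time[0] = height + stem
    children[0] = [1]
    parent[1] = 0
    for nd in order:
        i = index[nd]
        node_time[i] = height - depth[nd]
        for c in nd.child_nodes():
            parent[index[c]] = i
            children[i].append(index[c])
        if not nd.child_nodes():
            node_time[i] = 0.0
            leaf_name[i] = nd.taxon.label
    return DatedSpeciesTree(parent, children, node_time, leaf_name)


def write_newick(S: DatedSpeciesTree) -> str:
    """Serialize the dated tree; the stem appears as a root branch length."""

    def rec(v: int) -> str:
        if not S.children[v]:
            bl = S.node_time[S.parent[v]] - S.node_time[v]
            return f"{S.leaf_name[v]}:{bl:.10g}"
        inner = ",".join(rec(c) for c in S.children[v])
        if S.parent[v] == 0:
            bl = S.node_time[0] - S.node_time[v]
        else:
            bl = S.node_time[S.parent[v]] - S.node_time[v]
        return f"({inner}):{bl:.10g}"

    return rec(S.children[0][0]) + ";"


@dataclass
class DiscretizedSpeciesTree:
    """The species tree augmented with equidistant interior points.

    Points are indexed ``0..n_points-1``.  Vertices of ``S`` keep their
    role (``vertex_of[p]`` is the ``S`` vertex index, or -1 for interior
    points).  ``point_parent[p]`` is the next point rootwards; segment
    ``(point_parent[p], p)`` has duration ``seg_dt[p]``.
    """

    S: DatedSpeciesTree
    point_time: np.ndarray
    point_parent: np.ndarray
    vertex_of: np.ndarray            # -1 for interior points
    point_of_vertex: np.ndarray      # S vertex -> point index
    point_children: list[list[int]]
    slice_width: np.ndarray          # event weight of interior points (0 at vertices)
    seg_dt: np.ndarray               # duration of the segment above each point

    # --- derived structures used by the DP ---
    n: int = field(init=False)
    is_speciation: np.ndarray = field(init=False)
    desc_strict: np.ndarray = field(init=False)       # bool [x, y]: y strictly below x
    time_between_mat: np.ndarray = field(init=False)  # t(x, y) for comparable pairs
    postorder_points: list[int] = field(init=False)
    side_desc: dict[int, tuple[np.ndarray, np.ndarray]] = field(init=False)
    path_child: np.ndarray = field(init=False)  # child of x towards y; -1 if n/a

    def __post_init__(self) -> None:
        P = len(self.point_time)
        self.n = P
        self.is_speciation = np.array(
            [
                self.vertex_of[p] >= 0 and len(self.point_children[p]) == 2
                for p in range(P)
            ]
        )
        desc = np.zeros((P, P), dtype=bool)
        order: list[int] = []
        stack = [self.point_of_vertex[0]]
        while stack:
            p = int(stack.pop())
            order.append(p)
            stack.extend(self.point_children[p])
        order = order[::-1]  # leaves first
        self.postorder_points = order
        path_child = np.full((P, P), -1, dtype=int)
        for p in order:
            for c in self.point_children[p]:
                desc[p, c] = True
                desc[p] |= desc[c]
                path_child[p, desc[c]] = c
                path_child[p, c] = c
        self.desc_strict = desc
        t = self.point_time
        self.time_between_mat = np.where(
            desc | np.eye(P, dtype=bool), t[:, None] - t[None, :], np.nan
        )
        self.path_child = path_child
        self.side_desc = {}
        for p in range(P):
            if self.is_speciation[p]:
                l, r = self.point_children[p]
                lmask = desc[l].copy()
                lmask[l] = True
                rmask = desc[r].copy()
                rmask[r] = True
                self.side_desc[p] = (lmask, rmask)
        # flat arrays over strictly-comparable pairs (x ancestor of y),
        # the sparse layout the DP sweeps over
        xs, ys = np.nonzero(desc)
        self.pair_x = xs
        self.pair_y = ys
        pair_T = t[xs] - t[ys]
        self.pair_T = pair_T
        with np.errstate(divide="ignore"):
            self.pair_logT = np.log(pair_T)
        self.pair_invT = 1.0 / pair_T
        self.side_pairs = {}
        for p, (lmask, rmask) in self.side_desc.items():
            at_p = xs == p
            self.side_pairs[p] = (
                np.nonzero(at_p & lmask[ys])[0],
                np.nonzero(at_p & rmask[ys])[0],
            )

    @property
    def root_point(self) -> int:
        return int(self.point_of_vertex[0])

    def is_ancestor(self, x: int, y: int) -> bool:
        return bool(x == y or self.desc_strict[x, y])

    def time_between(self, x: int, y: int) -> float:
        """Time t(x, y) between an ancestor point ``x`` and descendant ``y``."""
        if not self.is_ancestor(x, y):
            raise ValueError(f"point {x} is not an ancestor of point {y}")
        return float(self.point_time[x] - self.point_time[y])


def _points_for_edge(duration: float, n_points: int | None, height: float,
                     floor: int, target_slices: int) -> int:
    if n_points is not None:
        return n_points
    return max(floor, int(round(duration / (height / target_slices))))


def discretize(
    S: DatedSpeciesTree,
    n_points: int | None = None,
    floor: int = 3,
    target_slices: int = 30,
) -> DiscretizedSpeciesTree:
    """Augment every edge of ``S`` with equidistant interior points.

    With ``n_points`` given, every edge receives exactly that many interior
    points.  Otherwise the count is proportional to the edge duration
    (target slice width ``height / target_slices``) with a floor.
    """
    if n_points is not None and n_points < 1:
        raise ValueError("n_points must be >= 1")
    height = S.height
    times: list[float] = []
    parents: list[int] = []
    vertex_of: list[int] = []
    widths: list[float] = []
    point_of_vertex = np.full(S.n_vertices, -1, dtype=int)

    def new_point(t: float, par: int, vert: int, w: float) -> int:
        times.append(t)
        parents.append(par)
        vertex_of.append(vert)
        widths.append(w)
        return len(times) - 1

    rp = new_point(S.node_time[0], -1, 0, 0.0)
    point_of_vertex[0] = rp
    stack = [(S.children[0][0], 0, rp)]
    while stack:
        v, pv, ppoint = stack.pop()
        dur = float(S.node_time[pv] - S.node_time[v])
        if dur <= 0:
            raise SpeciesTreeError("non-positive edge duration")
        k = _points_for_edge(dur, n_points, height, floor, target_slices)
        w = dur / (k + 1)
        cur = ppoint
        for i in range(1, k + 1):
            cur = new_point(S.node_time[pv] - i * w, cur, -1, w)
        vp = new_point(S.node_time[v], cur, v, 0.0)
        point_of_vertex[v] = vp
        for c in S.children[v]:
            stack.append((c, v, vp))

    P = len(times)
    point_children: list[list[int]] = [[] for _ in range(P)]
    for p, par in enumerate(parents):
        if par >= 0:
            point_children[par].append(p)
    seg_dt = np.zeros(P)
    for p, par in enumerate(parents):
        if par >= 0:
            seg_dt[p] = times[par] - times[p]
    return DiscretizedSpeciesTree(
        S=S,
        point_time=np.array(times),
        point_parent=np.array(parents),
        vertex_of=np.array(vertex_of),
        point_of_vertex=point_of_vertex,
        point_children=point_children,
        slice_width=np.array(widths),
        seg_dt=seg_dt,
    )


def time_between(Sp: DiscretizedSpeciesTree, x: int, y: int) -> float:
    """Module-level alias for :meth:`DiscretizedSpeciesTree.time_between`."""
    return Sp.time_between(x, y)
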