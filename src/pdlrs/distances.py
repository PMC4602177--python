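"""Distances between pseudogenization configurations.

Two configurations of one gene family - each a gene tree with its set of
pseudogenization vertices - are compared after suppressing the
pseudogenization vertices, which must yield the same binary tree ``G*``.
Each configuration then corresponds to a set of ``G*`` edges (those
created by the suppression), identified here by the clade of leaf names
below them.

Between the two edge sets a roof/shade relation is formed: an edge of one
set that covers edges of the other set (on every path to its leaves) is a
roof and the covered edges are its shade; an edge lying below an edge of
the other set belongs to that edge's shade.  Distances are aggregated per
roof - the mean (or max) of the roof-to-shade edge distances - and then
averaged (or maximized) over roofs, giving the average and maximum
topological distances ``D_a`` and ``D_m``.  The temporal variants replace
the edge distance by the absolute difference between the pseudogenization
times of the roof's and shade's origins.

The edge distance between two edges of ``G*`` is the number of internal
vertices on the unique shortest path containing both edges (0 for the
same edge, 1 for adjacent edges).
"""

from __future__ import annotations

from dataclasses import dataclass

from .gene_tree import GeneTreeState, suppress

__all__ = [
    "ConfigurationPair",
    "edge_distance",
    "roofs_and_shades",
    "topological_distance",
    "temporal_distance",
    "posterior_summaries",
    "PosteriorDistanceSummary",
]

Clade = frozenset


def gstar_clades(state: GeneTreeState) -> frozenset:
    """The set of edge clades of the suppressed tree (identifies G*)."""
    st = suppress(state)
    return frozenset(st.clade(n) for n in st.edges())


def psi_config(state: GeneTreeState, times: dict[Clade, float] | None = None):
    """The configuration of a state: clade -> pseudogenization time (or None)."""
    st = suppress(state)
    out = {}
    for node in st.origin:
        clade = st.clade(node)
        out[clade] = None if times is None else times.get(clade)
    return out


@dataclass
class ConfigurationPair:
    """Two pseudogenization configurations on a common suppressed tree.

    ``edges``: all edge clades of ``G*``; ``config_a``/``config_b``: maps
    from the edge clades carrying a pseudogenization to the origin's time
    (``None`` in purely topological mode).
    """

    edges: frozenset
    config_a: dict[Clade, float | None]
    config_b: dict[Clade, float | None]

    def __post_init__(self) -> None:
        for cfg in (self.config_a, self.config_b):
            missing = set(cfg) - set(self.edges)
            if missing:
                raise ValueError(f"configuration edges not in G*: {missing}")

    @classmethod
    def from_states(
        cls,
        a: GeneTreeState,
        b: GeneTreeState,
        times_a: dict[Clade, float] | None = None,
        times_b: dict[Clade, float] | None = None,
    ) -> "ConfigurationPair":
        ea, eb = gstar_clades(a), gstar_clades(b)
        if ea != eb:
            raise ValueError("the two states do not share a suppressed tree")
        return cls(ea, psi_config(a, times_a), psi_config(b, times_b))


def edge_distance(e_a: Clade, e_b: Clade, edges: frozenset) -> int:
    """Number of internal vertices on the shortest path containing both."""
    if e_a not in edges or e_b not in edges:
        raise ValueError("edge not in the tree")
    if e_a == e_b:
        return 0
    if e_a < e_b or e_b < e_a:  # proper subset: one edge above the other
        lo, hi = (e_a, e_b) if e_a < e_b else (e_b, e_a)
        between = sum(1 for e in edges if lo <= e <= hi)
        return between - 1
    # unrelated: path runs through the lowest edge containing both
    union = e_a | e_b
    covering = [e for e in edges if union <= e]
    if covering:
        lca = min(covering, key=len)
        na = sum(1 for e in edges if e_a <= e < lca)
        nb = sum(1 for e in edges if e_b <= e < lca)
    else:
        # the lowest common vertex is the child of the degree-one root
        na = sum(1 for e in edges if e_a <= e)
        nb = sum(1 for e in edges if e_b <= e)
    return na + nb - 1


def roofs_and_shades(pair: ConfigurationPair):
    """The roof/shade partition of the two configurations' edges.

    Returns a list of ``(roof_clade, shade_clades, roof_side)`` with
    ``roof_side`` "a" or "b"; every configuration edge belongs to exactly
    one relation (a shared edge is a roof whose shade is itself).
    """
    A, B = set(pair.config_a), set(pair.config_b)
    relations = []
    covered_b: dict[Clade, list[Clade]] = {}
    for f in A:
        above = [e for e in B if f <= e]
        if above:
            roof = min(above, key=len)  # antichain: at most one, keep lowest
            covered_b.setdefault(roof, []).append(f)
        else:
            shade = [e for e in B if e < f]
            if not shade:
                raise ValueError(
                    "invalid pair: pseudogene leaves below an edge of one "
                    "configuration are uncovered in the other"
                )
            relations.append((f, shade, "a"))
    for roof, shade in covered_b.items():
        relations.append((roof, shade, "b"))
    return relations


def _aggregate(pair: ConfigurationPair, per_pair):
    rels = roofs_and_shades(pair)
    if not rels:
        return 0.0, 0.0
    d_as = []
    d_ms = []
    for roof, shade, _side in rels:
        ds = [per_pair(roof, e) for e in shade]
        d_as.append(sum(ds) / len(ds))
        d_ms.append(max(ds))
    return sum(d_as) / len(d_as), max(d_ms)


def topological_distance(pair: ConfigurationPair) -> tuple[float, float]:
    """(D_a, D_m): per-roof mean/max edge distance, averaged/maximized
    over roofs."""
    return _aggregate(pair, lambda r, e: edge_distance(r, e, pair.edges))


def temporal_distance(pair: ConfigurationPair) -> tuple[float, float]:
    """(T_a, T_m): like the topological distances but with absolute time
    differences between the roof's and shade's origins."""

    def td(roof: Clade, e: Clade) -> float:
        # the roof belongs to one configuration and the shade edge to the
        # other (for a shared edge, one time is read from each side)
        if roof in pair.config_a and e in pair.config_b:
            ta, tb = pair.config_a[roof], pair.config_b[e]
        else:
            ta, tb = pair.config_b[roof], pair.config_a[e]
        if ta is None or tb is None:
            raise ValueError("temporal distance requires origin times")
        return abs(ta - tb)

    return _aggregate(pair, td)


@dataclass
class PosteriorDistanceSummary:
    """Posterior-weighted distance summaries against a fixed truth.

    ``E_*`` are posterior means of the per-sample distances; ``M_*`` are
    the maxima over the posterior support.  ``n_excluded`` counts the
    samples whose suppressed topology differs from the truth's (no common
    ``G*``, so no distance is defined).
    """

    E_Da: float
    M_Da: float
    E_Dm: float
    M_Dm: float
    E_Ta: float | None
    M_Ta: float | None
    E_Tm: float | None
    M_Tm: float | None
    n_used: int
    n_excluded: int


def posterior_summaries(
    truth: GeneTreeState,
    samples,
    truth_times: dict[Clade, float] | None = None,
    temporal: bool = True,
) -> PosteriorDistanceSummary:
    """Summarize distances from posterior samples to the truth.

    ``samples``: iterable of ``(state, times, weight)`` where ``times``
    maps the sample's psi clades to event times (may be ``None`` when
    ``temporal=False``).  Samples not sharing the truth's suppressed
    topology are excluded and counted.
    """
    truth_edges = gstar_clades(truth)
    truth_cfg = psi_config(truth, truth_times)
    rows = []
    excluded = 0
    total_w = 0.0
    for state, times, weight in samples:
        if gstar_clades(state) != truth_edges:
            excluded += 1
            continue
        pair = ConfigurationPair(truth_edges, truth_cfg, psi_config(state, times))
        da, dm = topological_distance(pair)
        if temporal:
            ta, tm = temporal_distance(pair)
        else:
            ta = tm = None
        rows.append((da, dm, ta, tm, weight))
        total_w += weight
    if not rows:
        raise ValueError("no posterior sample shares the truth's suppressed tree")

    def mean_of(i):
        return sum(r[i] * r[4] for r in rows) / total_w

    def max_of(i):
        return max(r[i] for r in rows)

    return PosteriorDistanceSummary(
        E_Da=mean_of(0),
        M_Da=max_of(0),
        E_Dm=mean_of(1),
        M_Dm=max_of(1),
        E_Ta=mean_of(2) if temporal else None,
        M_Ta=max_of(2) if temporal else None,
        E_Tm=mean_of(3) if temporal else None,
        M_Tm=max_of(3) if temporal else None,
        n_used=len(rows),
        n_excluded=excluded,
    )
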