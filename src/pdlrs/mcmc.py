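"""Metropolis-Hastings sampling over (G, l, theta, Psi).

The chain state is a gene tree with edge lengths and pseudogenization
vertices plus the compound parameter theta.  The unnormalized posterior
is P(D | G, l, Psi) p(G, l, Psi | theta, S) p(theta); the data
normalizer cancels in the acceptance ratio, so only these three factors
are ever computed.

Proposal repertoire (one move per iteration, chosen by weight):

* edge lengths and the theta scalars: truncated-normal random walks
  inside their supports (omega in [0, 10], kappa in [0, 100], the rest in
  [0, inf)), with the truncation-normalizer Hastings correction;
* pseudogenization vertices: a Psi vertex slides one edge down (splitting
  onto the two child edges) or one edge up (merging two sibling Psi
  vertices onto the parent edge); up and down are proposed with equal
  probability, the new positions along their edges are drawn uniformly,
  and the dimension change carries the exact reversible-jump Jacobian;
* topology: NNI, SPR and re-rooting on the suppressed tree.  Candidate
  moves are enumerated and filtered so that the proposed gene tree is
  always valid (no pseudogene lineage leads to a gene lineage); the menu
  sizes of the current and the proposed state enter the Hastings ratio.

The initial tree comes from neighbor joining on codon-level distances,
with one Psi vertex at the midpoint of the parent edge of each maximal
all-pseudogene clade (the unique minimal valid placement).  A fixed-tree
mode disables the topology menu and samples Psi, lengths and theta only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .codon_models import (
    CodonModel,
    CodonModelParams,
    GENE_MODE,
    PSEUDO_MODE,
)
from .dlrs_dp import compute_s_table
from .gene_tree import PSEUDO, GNode, GeneTreeState, validate_state, write_gene_tree
from .params import ModelParams, RateModel
from .pruning import CodonAlignment, sequence_log_likelihood
from .realization import sample_realization
from .species_tree import DatedSpeciesTree, DiscretizedSpeciesTree, discretize
from .two_type_bd import BDRates, compute_bd_tables

__all__ = [
    "PriorConfig",
    "MCMCConfig",
    "PosteriorTrace",
    "TraceRecord",
    "run_chain",
    "select_map_tree",
    "log_unnormalized_posterior",
    "nj_initial_state",
    "place_minimal_psi",
]

logger = logging.getLogger("pdlrs.mcmc")

OMEGA_RANGE = (0.0, 10.0)
KAPPA_RANGE = (0.0, 100.0)


# ---------------------------------------------------------------------------
# priors and configuration


@dataclass(frozen=True)
class PriorConfig:
    """Independent priors on the components of theta: exponential on the
    duplication/loss/pseudogenization rates, log-normal on the edge-rate
    mean, exponential on the CV, uniform on the omega and kappa boxes."""

    bd_rate: float = 0.1
    rate_mean_logsd: float = 1.0
    cv_rate: float = 1.0

    def log_theta_prior(self, theta: ModelParams) -> float:
        lp = 0.0
        for x in (theta.delta, theta.mu, theta.psi):
            if x < 0:
                return -np.inf
            lp += math.log(self.bd_rate) - self.bd_rate * x
        m, c = theta.rate_model.mean, theta.rate_model.cv
        if m <= 0 or c <= 0:
            return -np.inf
        s = self.rate_mean_logsd
        lp += -math.log(m * s * math.sqrt(2 * math.pi)) - math.log(m) ** 2 / (2 * s**2)
        lp += math.log(self.cv_rate) - self.cv_rate * c
        if not (OMEGA_RANGE[0] <= theta.omega <= OMEGA_RANGE[1]):
            return -np.inf
        if not (KAPPA_RANGE[0] <= theta.kappa <= KAPPA_RANGE[1]):
            return -np.inf
        lp -= math.log(OMEGA_RANGE[1] - OMEGA_RANGE[0])
        lp -= math.log(KAPPA_RANGE[1] - KAPPA_RANGE[0])
        return lp


@dataclass
class MCMCConfig:
    """Run configuration; the chain-length defaults mirror the standard
    full analysis (5M iterations, 2.5M burn-in, thinning 500)."""

    iterations: int = 5_000_000
    burn_in: int = 2_500_000
    thinning: int = 500
    seed: int = 0
    fixed_tree: bool = False
    move_weights: dict = field(
        default_factory=lambda: {
            "length": 0.30,
            "theta": 0.20,
            "psi": 0.20,
            "topology": 0.30,
        }
    )
    topology_weights: dict = field(
        default_factory=lambda: {"nni": 0.5, "spr": 0.3, "reroot": 0.2}
    )
    scales: dict = field(
        default_factory=lambda: {
            "length": 0.2,
            "delta": 0.3,
            "mu": 0.3,
            "psi": 0.3,
            "rate_mean": 0.25,
            "rate_cv": 0.25,
            "kappa": 2.0,
            "omega": 0.5,
        }
    )
    theta_components: tuple = (
        "delta",
        "mu",
        "psi",
        "rate_mean",
        "rate_cv",
        "kappa",
        "omega",
    )
    prior: PriorConfig = field(default_factory=PriorConfig)
    init_theta: ModelParams | None = None
    n_discretization_points: int | None = None
    discretization_floor: int = 3
    discretization_target_slices: int = 30
    likelihood_on: bool = True
    tree_prior_on: bool = True
    fixed_fractions: bool = False  # deterministic midpoint Psi slides (toy mode)
    sample_realizations: bool = True
    log_every: int = 0  # 0 = silent


def default_theta() -> ModelParams:
    return ModelParams(
        rates=BDRates(0.5, 0.5, 0.3),
        rate_model=RateModel(1.0, 0.7),
        kappa=2.0,
        omega=0.5,
    )


# ---------------------------------------------------------------------------
# truncated-normal scalar proposals


def _truncnorm_sample(rng, x, scale, lo, hi):
    a = ndtr((lo - x) / scale)
    b = ndtr((hi - x) / scale) if np.isfinite(hi) else 1.0
    u = a + (b - a) * rng.random()
    u = min(max(u, 1e-15), 1 - 1e-15)
    return x + scale * float(ndtri(u))


def _truncnorm_logz(x, scale, lo, hi):
    b = ndtr((hi - x) / scale) if np.isfinite(hi) else 1.0
    return math.log(max(b - ndtr((lo - x) / scale), 1e-300))


def propose_scalar(rng, x, scale, lo=0.0, hi=np.inf):
    """Truncated-normal walk; returns (new value, log Hastings ratio)."""
    new = _truncnorm_sample(rng, x, scale, lo, hi)
    logh = _truncnorm_logz(x, scale, lo, hi) - _truncnorm_logz(new, scale, lo, hi)
    return new, logh


# ---------------------------------------------------------------------------
# helpers on the suppressed view


def _unpsi(n: GNode) -> GNode:
    """The G* vertex at the bottom of the edge starting at ``n``."""
    return n.children[0] if n.is_psi else n


def _gstar_nodes(state: GeneTreeState) -> list[GNode]:
    return [n for n in state.nodes() if not n.is_psi]


def _attachment(n: GNode) -> GNode:
    """Topmost node of the G* edge above ``n`` (the Psi vertex if any)."""
    return n.parent if n.parent is not None and n.parent.is_psi else n


def _gstar_parent(n: GNode) -> GNode | None:
    p = n.parent
    while p is not None and p.is_psi:
        p = p.parent
    return p


def _node_stats(state: GeneTreeState):
    """Per G*-vertex booleans: subtree has gene leaf / has Psi (internal or
    on own edge) / has a pseudogene leaf not covered by a Psi within."""
    has_gene: dict[GNode, bool] = {}
    has_psi: dict[GNode, bool] = {}
    uncovered: dict[GNode, bool] = {}
    for n in state.root.postorder():
        if n.is_psi:
            continue
        if n.is_leaf:
            g = state.leaf_class[n.name] == PSEUDO
            has_gene[n] = not g
            has_psi[n] = False
            uncovered[n] = g
        else:
            ch = [_unpsi(c) for c in n.children]
            has_gene[n] = any(has_gene[c] for c in ch)
            has_psi[n] = any(
                has_psi[c] or c.parent.is_psi for c in ch
            )
            uncovered[n] = any(
                uncovered[c] and not c.parent.is_psi for c in ch
            )
    return has_gene, has_psi, uncovered


def _under_psi(n: GNode) -> bool:
    p = n.parent
    while p is not None:
        if p.is_psi:
            return True
        p = p.parent
    return False


# ---------------------------------------------------------------------------
# Psi slide moves (reversible-jump up/down)


def _psi_down_menu(state: GeneTreeState):
    return [
        u
        for u in state.nodes()
        if u.is_psi and not u.children[0].is_leaf
    ]


def _psi_up_menu(state: GeneTreeState):
    return [
        v
        for v in state.nodes()
        if not v.is_psi
        and len(v.children) == 2
        and all(c.is_psi for c in v.children)
        and v.parent is not None
    ]


def propose_psi_slide(state: GeneTreeState, rng, fixed_fractions=False):
    """Slide a Psi vertex one edge down (split) or up (merge).

    Returns (new_state, log Hastings ratio including the RJ Jacobian), or
    None when the chosen direction has no candidate (a no-op rejection).
    """
    down = rng.random() < 0.5
    new = state.copy()
    if down:
        menu = _psi_down_menu(new)
        if not menu:
            return None
        u = menu[int(rng.integers(len(menu)))]
        v = u.children[0]
        p = u.parent
        merged = float(u.length) + float(v.length)
        p.children[p.children.index(u)] = v
        v.parent = p
        v.length = merged
        logj = -math.log(merged)
        for c in list(v.children):
            lc = float(c.length)
            f = 0.5 if fixed_fractions else float(rng.random())
            w = GNode(length=f * lc, is_psi=True)
            v.children[v.children.index(c)] = w
            w.parent = v
            w.add_child(c)
            c.length = (1 - f) * lc
            logj += math.log(lc)
        n_rev = len(_psi_up_menu(new))
        logh = math.log(len(menu)) - math.log(n_rev)
        if not fixed_fractions:
            logh += logj
        return new, logh
    menu = _psi_up_menu(new)
    if not menu:
        return None
    v = menu[int(rng.integers(len(menu)))]
    logj = 0.0
    for w in list(v.children):
        (c,) = w.children
        merged = float(w.length) + float(c.length)
        v.children[v.children.index(w)] = c
        c.parent = v
        c.length = merged
        logj -= math.log(merged)
    lv = float(v.length)
    f = 0.5 if fixed_fractions else float(rng.random())
    p = v.parent
    u = GNode(length=f * lv, is_psi=True)
    p.children[p.children.index(v)] = u
    u.parent = p
    u.add_child(v)
    v.length = (1 - f) * lv
    logj += math.log(lv)
    n_rev = len(_psi_down_menu(new))
    logh = math.log(len(menu)) - math.log(n_rev)
    if not fixed_fractions:
        logh += logj
    return new, logh


# ---------------------------------------------------------------------------
# NNI


def _nni_menu(state: GeneTreeState):
    """Valid (b, c) pairs: child edge c of internal b swaps with b's
    sibling edge.  A swap across a Psi-carrying edge above b would strand
    the moved-out clade's pseudogene leaves, so those are excluded."""
    out = []
    for b in _gstar_nodes(state):
        if b.is_leaf or b.parent is None:
            continue
        a = _gstar_parent(b)
        if a is None or a.parent is None:
            continue
        if b.parent.is_psi:  # Psi on the edge (a, b)
            continue
        for c in b.children:
            out.append((b, c))
    return out


def _nni_key(state: GeneTreeState, pair):
    nodes = state.nodes()
    return (nodes.index(pair[0]), nodes.index(pair[1]))


def _apply_nni(state: GeneTreeState, key):
    new = state.copy()
    nodes = new.nodes()
    b, cattach = nodes[key[0]], nodes[key[1]]
    a = _gstar_parent(b)
    (sattach,) = [x for x in a.children if x is not b]
    a.children[a.children.index(sattach)] = cattach
    cattach.parent = a
    b.children[b.children.index(cattach)] = sattach
    sattach.parent = b
    if validate_state(new):
        return None
    return new


def propose_nni(state: GeneTreeState, rng):
    menu = [p for p in _nni_menu(state)]
    # filter to valid results
    keyed = [_nni_key(state, p) for p in menu]
    results = [(k, _apply_nni(state, k)) for k in keyed]
    valid = [(k, s) for k, s in results if s is not None]
    if not valid:
        return None
    k, new = valid[int(rng.integers(len(valid)))]
    n_rev = sum(
        1
        for kk in (_nni_key(new, p) for p in _nni_menu(new))
        if _apply_nni(new, kk) is not None
    )
    logh = math.log(len(valid)) - math.log(n_rev)
    return new, logh


# ---------------------------------------------------------------------------
# SPR


def _spr_menu(state: GeneTreeState):
    """Valid (v, t) pairs: prune the subtree hanging on v's G* edge,
    regraft onto the edge above t at a uniform fraction."""
    has_gene, has_psi, uncovered = _node_stats(state)
    out = []
    nodes = _gstar_nodes(state)
    for v in nodes:
        if v.parent is None:
            continue
        p = v.parent
        # the two edges merging at the pruning site, and p's own edge,
        # must be Psi-free; p must not be the root child (the stem edge
        # is not merged away)
        if p.is_psi or p.parent is None or p.parent.is_psi:
            continue
        if p.parent.parent is None:
            continue
        (s,) = [x for x in p.children if x is not v]
        if s.is_psi:
            continue
        vsub = set(v.postorder())
        for t in nodes:
            if t.parent is None or t is v or t is p or t in vsub:
                continue
            if t.parent.parent is None:
                continue  # the stem edge: the new attachment could not be
                # pruned back, so the move would not be reversible
            if t.parent.is_psi:
                continue
            if _under_psi(t):
                # regrafting below an existing Psi: the moved clade must be
                # purely pseudogene and Psi-free (no nesting)
                if has_gene[v] or has_psi[v]:
                    continue
            elif uncovered[v]:
                continue
            out.append((v, t))
    return out


def _spr_key(state, pair):
    nodes = state.nodes()
    return (nodes.index(pair[0]), nodes.index(pair[1]))


def _apply_spr(state: GeneTreeState, key, f: float):
    new = state.copy()
    nodes = new.nodes()
    v, t = nodes[key[0]], nodes[key[1]]
    p = v.parent
    pp = p.parent
    (s,) = [x for x in p.children if x is not v]
    lp, ls = float(p.length), float(s.length)
    pp.children[pp.children.index(p)] = s
    s.parent = pp
    s.length = lp + ls
    t_len = float(t.length)
    tp = t.parent
    m = GNode(length=(1 - f) * t_len)
    tp.children[tp.children.index(t)] = m
    m.parent = tp
    m.add_child(t)
    t.length = f * t_len
    m.add_child(v)
    v.parent = m
    if validate_state(new):
        return None
    logj = math.log(t_len) - math.log(lp + ls)
    return new, logj


def propose_spr(state: GeneTreeState, rng):
    menu = _spr_menu(state)
    if not menu:
        return None
    pair = menu[int(rng.integers(len(menu)))]
    f = float(rng.random())
    res = _apply_spr(state, _spr_key(state, pair), f)
    if res is None:
        return None
    new, logj = res
    n_rev = len(_spr_menu(new))
    if n_rev == 0:
        return None
    logh = math.log(len(menu)) - math.log(n_rev) + logj
    return new, logh


# ---------------------------------------------------------------------------
# re-rooting


def _reroot_menu(state: GeneTreeState):
    """Valid targets t: the root moves onto the edge above t.  The path
    from the current root to t (whose edges all reverse orientation) must
    be Psi-free, as must the two edges merging at the old attachment."""
    r = state.root.children[0]
    if r.is_psi or len(r.children) != 2 or any(c.is_psi for c in r.children):
        return []
    out = []
    for t in _gstar_nodes(state):
        if t.parent is None or t is r or t.parent is state.root:
            continue
        if t.parent is r:  # the merged edge is never a target
            continue
        if t.parent.is_psi:
            continue
        # psi-free path from t up to r
        x = t.parent
        ok = True
        while x is not r:
            if x.is_psi or (x.parent is not None and x.parent.is_psi):
                ok = False
                break
            x = x.parent
            if x is None:
                ok = False
                break
        if ok:
            out.append(t)
    return out


def _apply_reroot(state: GeneTreeState, t_idx: int, f: float):
    """Move the root onto the edge above node ``t_idx``.

    The old root-child ``r`` is suppressed (its two child edges merge
    into one of total length) and the target edge splits at fraction
    ``f``; the stem length rides with the root.  The parent chain from
    ``t`` up to ``r`` reverses orientation, every node on it becoming the
    child of its former child."""
    new = state.copy()
    nodes = new.nodes()
    t = nodes[t_idx]
    root = new.root
    r = root.children[0]
    stem = float(r.length)
    t_len = float(t.length)

    path = []  # [t.parent, ..., r]; guaranteed Psi-free, length >= 2
    x = t.parent
    while x is not r:
        path.append(x)
        x = x.parent
    path.append(r)
    other = [c for c in r.children if c is not path[-2]][0] if len(path) > 1 else None
    merged_old = float(other.length) + float(path[-2].length)
    orig_len = {p: float(p.length) for p in path[:-1]}

    tp = t.parent
    tp.children.remove(t)
    new_root = GNode()
    m = GNode(length=stem)
    new_root.add_child(m)
    m.add_child(t)
    t.length = (1 - f) * t_len

    prev = m
    prev_edge_len = f * t_len
    for i, node in enumerate(path):
        if node is r:
            break
        nxt = path[i + 1]  # node's old parent
        nxt.children.remove(node)
        node.parent = None
        prev.add_child(node)
        node.length = prev_edge_len
        prev_edge_len = orig_len[node]
        prev = node
    # r is suppressed: attach its other child with the merged edge length
    r.children.remove(other)
    other.parent = None
    prev.add_child(other)
    other.length = merged_old

    new_state = GeneTreeState(new_root, dict(new.leaf_species), dict(new.leaf_class))
    if validate_state(new_state):
        return None
    logj = math.log(t_len) - math.log(merged_old)
    return new_state, logj


def propose_reroot(state: GeneTreeState, rng):
    menu = _reroot_menu(state)
    if not menu:
        return None
    t = menu[int(rng.integers(len(menu)))]
    f = float(rng.random())
    res = _apply_reroot(state, state.nodes().index(t), f)
    if res is None:
        return None
    new, logj = res
    n_rev = len(_reroot_menu(new))
    if n_rev == 0:
        return None
    logh = math.log(len(menu)) - math.log(n_rev) + logj
    return new, logh


def propose_identity(state: GeneTreeState):
    """An identical-state proposal (always accepted; testing hook)."""
    return state.copy(), 0.0


# ---------------------------------------------------------------------------
# initial state


def place_minimal_psi(state: GeneTreeState) -> GeneTreeState:
    """Remove any Psi and insert one at the midpoint of the parent edge of
    each maximal all-pseudogene clade (the unique minimal valid placement)."""
    new = state.copy()
    # drop existing psi vertices
    for n in list(new.root.postorder()):
        if n.is_psi:
            (c,) = n.children
            p = n.parent
            c.length = float(c.length) + float(n.length)
            p.children[p.children.index(n)] = c
            c.parent = p

    def all_pseudo(n: GNode) -> bool:
        return all(new.leaf_class[l.name] == PSEUDO for l in n.leaves())

    def rec(n: GNode) -> None:
        for c in list(n.children):
            if all_pseudo(c):
                l = float(c.length)
                w = GNode(length=l / 2, is_psi=True)
                n.children[n.children.index(c)] = w
                w.parent = n
                w.add_child(c)
                c.length = l / 2
            else:
                rec(c)

    rec(new.root)
    return new


def nj_initial_state(
    D: CodonAlignment,
    leaf_species: dict[str, str],
    leaf_class: dict[str, str],
    min_length: float = 1e-3,
) -> GeneTreeState:
    """Neighbor-joining tree on codon-level p-distances, midpoint-rooted,
    with the minimal valid Psi placement."""
    ids = D.ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two sequences")
    codes = D.codes
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = codes[i], codes[j]
            ok = (a >= 0) & (b >= 0)
            d = float(np.mean(a[ok] != b[ok])) if ok.any() else 0.5
            dist[i, j] = dist[j, i] = max(d, 1e-6)
    if n == 2:
        root = GNode()
        top = GNode(length=max(dist[0, 1], min_length))
        root.add_child(top)
        for sid in ids:
            top.add_child(GNode(length=max(dist[0, 1] / 2, min_length), name=sid))
        state = GeneTreeState(root, dict(leaf_species), dict(leaf_class))
        return place_minimal_psi(state)
    from skbio import DistanceMatrix
    from skbio.tree import nj

    sk = nj(DistanceMatrix(dist, ids))
    sk = sk.root_at_midpoint()

    def conv(node) -> GNode:
        g = GNode(
            length=max(float(node.length or 0.0), min_length),
            name=node.name if node.is_tip() else None,
        )
        for c in node.children:
            g.add_child(conv(c))
        return g

    top = conv(sk)
    # midpoint rooting yields a bifurcating top; wrap with the stem
    if len(top.children) != 2:
        # fall back: root on the first edge
        ch = top.children
        left = ch[0]
        rest = GNode(length=min_length)
        for c in ch[1:]:
            rest.add_child(c)
        top.children = []
        top.add_child(left)
        top.add_child(rest)
    lens = [float(x.length) for x in top.postorder() if x.length]
    top.length = max(float(np.mean(lens)), min_length)
    root = GNode()
    root.add_child(top)
    state = GeneTreeState(root, dict(leaf_species), dict(leaf_class))
    return place_minimal_psi(state)


# ---------------------------------------------------------------------------
# posterior evaluation


def log_unnormalized_posterior(
    state: GeneTreeState,
    theta: ModelParams,
    D: CodonAlignment | None,
    Sp: DiscretizedSpeciesTree,
    pi: np.ndarray,
    prior: PriorConfig | None = None,
    likelihood_on: bool = True,
    tree_prior_on: bool = True,
):
    """The three log factors (likelihood, tree prior, theta prior) and the
    DP table of the tree prior.  Returns (total, loglik, logtree,
    logtheta, stable).  An invalid state yields -inf."""
    prior = prior or PriorConfig()
    if validate_state(state):
        return -np.inf, -np.inf, -np.inf, -np.inf, None
    logtheta = prior.log_theta_prior(theta)
    if not np.isfinite(logtheta):
        return -np.inf, -np.inf, -np.inf, logtheta, None
    loglik = 0.0
    if likelihood_on and D is not None:
        gene = CodonModel(
            CodonModelParams(kappa=theta.kappa, omega=theta.omega, pi=pi, mode=GENE_MODE)
        )
        pseudo = CodonModel(
            CodonModelParams(kappa=theta.kappa, omega=1.0, pi=pi, mode=PSEUDO_MODE)
        )
        loglik = sequence_log_likelihood(D, state, gene, pseudo)
    logtree = 0.0
    stable = None
    if tree_prior_on:
        bd = compute_bd_tables(Sp, theta.rates)
        stable = compute_s_table(state, theta, Sp, bd)
        c = state.root.children[0]
        total = float(stable.U[c][Sp.root_point])
        logtree = (
            float(np.log(total) + stable.logscale[c]) if total > 0 else -np.inf
        )
    total = loglik + logtree + logtheta
    return total, loglik, logtree, logtheta, stable


# ---------------------------------------------------------------------------
# trace


@dataclass
class TraceRecord:
    iteration: int
    log_posterior: float
    log_likelihood: float
    log_tree_prior: float
    log_theta_prior: float
    delta: float
    mu: float
    psi: float
    rate_mean: float
    rate_cv: float
    kappa: float
    omega: float
    n_psi: int
    newick: str
    state: GeneTreeState
    psi_times: dict | None = None  # clade -> realized pseudogenization time
    realization: list | None = None  # (vertex clade, is_psi, point id, time)


@dataclass
class PosteriorTrace:
    records: list
    acceptance: dict
    config: MCMCConfig

    def scalars(self):
        import pandas as pd

        rows = [
            {
                k: getattr(r, k)
                for k in (
                    "iteration",
                    "log_posterior",
                    "log_likelihood",
                    "log_tree_prior",
                    "log_theta_prior",
                    "delta",
                    "mu",
                    "psi",
                    "rate_mean",
                    "rate_cv",
                    "kappa",
                    "omega",
                    "n_psi",
                )
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def write_tsv(self, path, header_lines=()):
        df = self.scalars()
        df["newick"] = [r.newick for r in self.records]
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    def acceptance_rates(self):
        return {
            k: (acc / prop if prop else 0.0)
            for k, (acc, prop) in self.acceptance.items()
        }

    def param_array(self, name):
        return np.array([getattr(r, name) for r in self.records])

    def ess(self, name):
        import arviz as az

        return float(az.ess(self.param_array(name)))

    def split_rhat(self, name):
        x = self.param_array(name)
        half = len(x) // 2
        if half < 2:
            return np.nan
        chains = np.stack([x[:half], x[half : 2 * half]])
        w = chains.var(axis=1, ddof=1).mean()
        b = half * chains.mean(axis=1).var(ddof=1)
        if w == 0:
            return 1.0
        return float(np.sqrt((w * (half - 1) / half + b / half) / w))

    def map_record(self):
        best = self.records[0]
        for r in self.records[1:]:
            if r.log_posterior > best.log_posterior:
                best = r
        return best


def select_map_tree(traces):
    """The candidate trace whose best sampled state has the highest
    posterior; ties go to the first-seen candidate (logged)."""
    if not traces:
        raise ValueError("no traces given")
    best_i, best_r = 0, traces[0].map_record()
    for i, tr in enumerate(traces[1:], start=1):
        r = tr.map_record()
        if r.log_posterior > best_r.log_posterior:
            best_i, best_r = i, r
        elif r.log_posterior == best_r.log_posterior:
            logger.info("select_map_tree: tie at %s, keeping first-seen", r.log_posterior)
    return best_i, best_r


# ---------------------------------------------------------------------------
# the chain


class _Chain:
    def __init__(self, D, S, config, initial_state=None):
        self.D = D
        self.S = S
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.Sp = discretize(
            S,
            n_points=config.n_discretization_points,
            floor=config.discretization_floor,
            target_slices=config.discretization_target_slices,
        )
        if D is not None:
            counts = np.ones(64)
            vals, cnts = np.unique(D.codes[D.codes >= 0], return_counts=True)
            counts[vals] += cnts
            self.pi = counts / counts.sum()
        else:
            self.pi = np.full(64, 1 / 64)
        self.theta = config.init_theta or default_theta()
        if initial_state is not None:
            self.state = initial_state.copy()
        else:
            self.state = nj_initial_state(D, *self._maps_from(D))
        problems = validate_state(self.state)
        if problems:
            raise ValueError("invalid initial state: " + "; ".join(problems))
        self._model_cache = {}
        self.bd = compute_bd_tables(self.Sp, self.theta.rates) if config.tree_prior_on else None
        self.loglik = self._loglik(self.state, self.theta)
        self.logtree, self.stable = self._tree_prior(self.state, self.theta, self.bd)
        self.logtheta = config.prior.log_theta_prior(self.theta)
        self.acc = {
            k: [0, 0]
            for k in ("length", "theta", "psi", "nni", "spr", "reroot")
        }

    def _maps_from(self, D):
        raise ValueError("an initial state (or leaf maps) is required")

    # -- posterior components -------------------------------------------
    def _models(self, theta):
        key = (round(theta.kappa, 12), round(theta.omega, 12))
        if key not in self._model_cache:
            gene = CodonModel(
                CodonModelParams(
                    kappa=theta.kappa, omega=theta.omega, pi=self.pi, mode=GENE_MODE
                )
            )
            pseudo = CodonModel(
                CodonModelParams(kappa=theta.kappa, omega=1.0, pi=self.pi, mode=PSEUDO_MODE)
            )
            if len(self._model_cache) > 64:
                self._model_cache.clear()
            self._model_cache[key] = (gene, pseudo)
        return self._model_cache[key]

    def _loglik(self, state, theta):
        if not self.cfg.likelihood_on or self.D is None:
            return 0.0
        gene, pseudo = self._models(theta)
        return sequence_log_likelihood(self.D, state, gene, pseudo)

    def _tree_prior(self, state, theta, bd):
        if not self.cfg.tree_prior_on:
            return 0.0, None
        stable = compute_s_table(state, theta, self.Sp, bd)
        c = state.root.children[0]
        total = float(stable.U[c][self.Sp.root_point])
        if total <= 0 or not np.isfinite(total):
            return -np.inf, stable
        return float(np.log(total) + stable.logscale[c]), stable

    def total(self):
        return self.loglik + self.logtree + self.logtheta

    # -- move dispatch ---------------------------------------------------
    def _pick_category(self):
        weights = dict(self.cfg.move_weights)
        if self.cfg.fixed_tree:
            weights["topology"] = 0.0
        if not self.cfg.likelihood_on and not self.cfg.tree_prior_on:
            weights = {"theta": 1.0}
        cats = [k for k, w in weights.items() if w > 0]
        ws = np.array([weights[k] for k in cats])
        return cats[int(self.rng.choice(len(cats), p=ws / ws.sum()))]

    def step(self):
        cat = self._pick_category()
        if cat == "length":
            self._step_length()
        elif cat == "theta":
            self._step_theta()
        elif cat == "psi":
            self._step_state(propose_psi_slide(self.state, self.rng, self.cfg.fixed_fractions), "psi")
        else:
            tw = self.cfg.topology_weights
            kinds = [k for k, w in tw.items() if w > 0]
            ws = np.array([tw[k] for k in kinds])
            kind = kinds[int(self.rng.choice(len(kinds), p=ws / ws.sum()))]
            fn = {"nni": propose_nni, "spr": propose_spr, "reroot": propose_reroot}[kind]
            self._step_state(fn(self.state, self.rng), kind)

    def _accept(self, logr):
        return math.log(self.rng.random() + 1e-300) < logr

    def _step_length(self):
        edges = [n for n in self.state.nodes() if n.parent is not None]
        node = edges[int(self.rng.integers(len(edges)))]
        old = float(node.length)
        new, logh = propose_scalar(self.rng, old, self.cfg.scales["length"])
        self.acc["length"][1] += 1
        node.length = new
        loglik = self._loglik(self.state, self.theta)
        logtree, stable = self._tree_prior(self.state, self.theta, self.bd)
        logr = (loglik + logtree) - (self.loglik + self.logtree) + logh
        if self._accept(logr):
            self.acc["length"][0] += 1
            self.loglik, self.logtree, self.stable = loglik, logtree, stable
        else:
            node.length = old

    def _step_theta(self):
        comp = self.cfg.theta_components[
            int(self.rng.integers(len(self.cfg.theta_components)))
        ]
        t = self.theta
        cur = {
            "delta": t.delta,
            "mu": t.mu,
            "psi": t.psi,
            "rate_mean": t.rate_model.mean,
            "rate_cv": t.rate_model.cv,
            "kappa": t.kappa,
            "omega": t.omega,
        }[comp]
        lo, hi = {
            "kappa": KAPPA_RANGE,
            "omega": OMEGA_RANGE,
        }.get(comp, (0.0, np.inf))
        new_val, logh = propose_scalar(self.rng, cur, self.cfg.scales[comp], lo, hi)
        if comp in ("rate_mean", "rate_cv") and new_val <= 0:
            return
        rates = BDRates(
            new_val if comp == "delta" else t.delta,
            new_val if comp == "mu" else t.mu,
            new_val if comp == "psi" else t.psi,
        )
        rm = RateModel(
            new_val if comp == "rate_mean" else t.rate_model.mean,
            new_val if comp == "rate_cv" else t.rate_model.cv,
        )
        new_theta = ModelParams(
            rates=rates,
            rate_model=rm,
            kappa=new_val if comp == "kappa" else t.kappa,
            omega=new_val if comp == "omega" else t.omega,
        )
        self.acc["theta"][1] += 1
        logtheta = self.cfg.prior.log_theta_prior(new_theta)
        loglik = self.loglik
        logtree, stable, bd = self.logtree, self.stable, self.bd
        if comp in ("kappa", "omega"):
            loglik = self._loglik(self.state, new_theta)
        elif self.cfg.tree_prior_on:
            if comp in ("delta", "mu", "psi"):
                bd = compute_bd_tables(self.Sp, new_theta.rates)
            logtree, stable = self._tree_prior(self.state, new_theta, bd)
        logr = (loglik + logtree + logtheta) - self.total() + logh
        if self._accept(logr):
            self.acc["theta"][0] += 1
            self.theta = new_theta
            self.loglik, self.logtree, self.logtheta = loglik, logtree, logtheta
            self.stable, self.bd = stable, bd

    def _step_state(self, proposal, label):
        self.acc[label][1] += 1
        if proposal is None:
            return
        new_state, logh = proposal
        loglik = self._loglik(new_state, self.theta)
        logtree, stable = self._tree_prior(new_state, self.theta, self.bd)
        logr = (loglik + logtree) - (self.loglik + self.logtree) + logh
        if self._accept(logr):
            self.acc[label][0] += 1
            self.state = new_state
            self.loglik, self.logtree, self.stable = loglik, logtree, stable

    # -- main loop -------------------------------------------------------
    def run(self):
        cfg = self.cfg
        records = []
        for it in range(cfg.iterations):
            self.step()
            if cfg.log_every and (it + 1) % cfg.log_every == 0:
                logger.info(
                    "iter %d logpost %.3f acc %s",
                    it + 1,
                    self.total(),
                    {k: f"{a}/{p}" for k, (a, p) in self.acc.items() if p},
                )
            if it + 1 > cfg.burn_in and (it + 1 - cfg.burn_in) % cfg.thinning == 0:
                psi_times = None
                rows = None
                if cfg.sample_realizations and self.stable is not None:
                    real = sample_realization(self.stable, self.rng)
                    psi_times = real.psi_clade_times()
                    rows = [
                        (
                            ",".join(sorted(l.name for l in n.leaves())),
                            n.is_psi,
                            int(real.points[n]),
                            float(real.times[n]),
                        )
                        for n in real.points
                    ]
                records.append(
                    TraceRecord(
                        iteration=it + 1,
                        log_posterior=self.total(),
                        log_likelihood=self.loglik,
                        log_tree_prior=self.logtree,
                        log_theta_prior=self.logtheta,
                        delta=self.theta.delta,
                        mu=self.theta.mu,
                        psi=self.theta.psi,
                        rate_mean=self.theta.rate_model.mean,
                        rate_cv=self.theta.rate_model.cv,
                        kappa=self.theta.kappa,
                        omega=self.theta.omega,
                        n_psi=len(self.state.psi_vertices()),
                        newick=write_gene_tree(self.state),
                        state=self.state.copy(),
                        psi_times=psi_times,
                        realization=rows,
                    )
                )
        return PosteriorTrace(
            records=records,
            acceptance={k: tuple(v) for k, v in self.acc.items()},
            config=cfg,
        )


def run_chain(
    D: CodonAlignment | None,
    S: DatedSpeciesTree,
    config: MCMCConfig,
    leaf_species: dict[str, str] | None = None,
    leaf_class: dict[str, str] | None = None,
    initial_state: GeneTreeState | None = None,
) -> PosteriorTrace:
    """Run the sampler; deterministic given ``config.seed``.

    Either an ``initial_state`` (also used as the fixed tree when
    ``config.fixed_tree``) or the leaf annotation maps (for the
    neighbor-joining start) must be provided.
    """
    if initial_state is None:
        if D is None or leaf_species is None or leaf_class is None:
            raise ValueError("need an initial state or alignment plus leaf maps")
        initial_state = nj_initial_state(D, leaf_species, leaf_class)
    chain = _Chain(D, S, config, initial_state=initial_state)
    return chain.run()
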