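"""Two-type (gene/pseudogene) linear birth-death process on the species tree.

Both types duplicate at rate ``delta`` and are lost at rate ``mu``; a gene
additionally converts irreversibly into a pseudogene at rate ``psi``.  The
gene-tree prior needs two families of quantities on the discretized tree:

* ``eps(x)``: the probability that a lineage at point ``x`` leaves no
  extant descendant.  Backwards (leaf-to-root) ODEs:

    dEp/ds = mu - (delta + mu) Ep + delta Ep^2
    dEg/ds = mu - (delta + mu + psi) Eg + delta Eg^2 + psi Ep

  Because conversion changes neither the duplication nor the loss rate,
  ``Eg = Ep`` exactly; both are integrated anyway, which doubles as a
  solver self-check and keeps the machinery general.

* ``p11(x, y)``: the probability that a single lineage at ``x`` evolves
  "1-to-1" to ``y`` - every side branch spawned by a duplication goes
  completely extinct and the tracked lineage reaches ``y`` unconverted
  (whatever happens below ``y`` is accounted for elsewhere).  Per slice,

    dP/ds = (2 delta eps(s) - (delta + mu + psi)) P   (gene)
    dP/ds = (2 delta eps(s) - (delta + mu)) P         (pseudogene)

  so the per-segment factor is ``exp(2 delta I - rate * dt)`` with ``I``
  the integral of ``eps`` over the segment, and factors compose
  multiplicatively along a path.

The chain factors ``K(x, y)`` additionally multiply, at every speciation
vertex crossed strictly between ``x`` and ``y``, the probability that the
copy split off into the other child edge goes extinct.  All quantities are
validated against a forward Monte-Carlo simulation of the process.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .species_tree import DatedSpeciesTree, DiscretizedSpeciesTree

__all__ = ["BDRates", "BDTables", "extinction_tables", "p11_tables", "compute_bd_tables", "mc_oracle"]

SUBSTEPS = 24  # RK4 substeps per discretization slice (even, for Simpson)


@dataclass(frozen=True)
class BDRates:
    """Duplication, loss and pseudogenization rates per lineage per time unit."""

    delta: float
    mu: float
    psi: float

    def __post_init__(self) -> None:
        if self.delta < 0 or self.mu < 0 or self.psi < 0:
            raise ValueError("rates must be nonnegative")


@dataclass
class BDTables:
    """Extinction and 1-to-1 tables over the discretized species tree."""

    Sp: DiscretizedSpeciesTree
    rates: BDRates
    eps_g: np.ndarray
    eps_p: np.ndarray
    eps_arc_g: dict[tuple[int, int], float]  # (speciation point, child point) -> arc extinction
    eps_arc_p: dict[tuple[int, int], float]
    seg_log_p11_g: np.ndarray  # log 1-to-1 factor of the segment above each point
    seg_log_p11_p: np.ndarray
    K_g: np.ndarray = field(init=False)  # chain factors (p11 + off-path extinction)
    K_p: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        Sp = self.Sp
        P = Sp.n
        K_g = np.zeros((P, P))
        K_p = np.zeros((P, P))
        par = Sp.point_parent
        for y in range(P):
            K_g[y, y] = 1.0
            K_p[y, y] = 1.0
            cg = cp = 1.0
            z = y
            while par[z] >= 0:
                x = int(par[z])
                cg *= float(np.exp(self.seg_log_p11_g[z]))
                cp *= float(np.exp(self.seg_log_p11_p[z]))
                K_g[x, y] = cg
                K_p[x, y] = cp
                if Sp.is_speciation[x]:
                    others = [c for c in Sp.point_children[x] if c != z]
                    for o in others:
                        cg *= self.eps_arc_g[(x, o)]
                        cp *= self.eps_arc_p[(x, o)]
                z = x
        self.K_g = K_g
        self.K_p = K_p
        self.K_g_pair = K_g[Sp.pair_x, Sp.pair_y]
        self.K_p_pair = K_p[Sp.pair_x, Sp.pair_y]

    def p11_g(self, x: int, y: int) -> float:
        """1-to-1 probability of a gene lineage between comparable points."""
        return self._p11(x, y, self.seg_log_p11_g)

    def p11_p(self, x: int, y: int) -> float:
        return self._p11(x, y, self.seg_log_p11_p)

    def _p11(self, x: int, y: int, seg: np.ndarray) -> float:
        if not self.Sp.is_ancestor(x, y):
            raise ValueError(f"point {x} is not an ancestor of point {y}")
        acc = 0.0
        z = y
        while z != x:
            acc += seg[z]
            z = int(self.Sp.point_parent[z])
        return float(np.exp(acc))


def _rk4_segment(E0: np.ndarray, dt: float, rates: BDRates, nsub: int = SUBSTEPS):
    """Integrate (Ep, Eg) upward over a segment; returns top value and
    Simpson integrals of Ep and Eg over the segment."""
    d, m, p = rates.delta, rates.mu, rates.psi

    def f(E):
        Ep, Eg = E
        return np.array(
            [
                m - (d + m) * Ep + d * Ep * Ep,
                m - (d + m + p) * Eg + d * Eg * Eg + p * Ep,
            ]
        )

    h = dt / nsub
    E = np.array(E0, dtype=float)
    grid = np.empty((nsub + 1, 2))
    grid[0] = E
    for k in range(nsub):
        k1 = f(E)
        k2 = f(E + 0.5 * h * k1)
        k3 = f(E + 0.5 * h * k2)
        k4 = f(E + h * k3)
        E = E + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        grid[k + 1] = E
    # composite Simpson on the substep grid (nsub is even)
    w = np.ones(nsub + 1)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    integrals = (h / 3.0) * (w @ grid)
    return E, integrals[0], integrals[1]


def _closed_segment(E0: float, t: float, delta: float, mu: float):
    """Exact extinction propagation over one slice of the one-type linear
    birth-death process: returns (E(t), integral of E over the slice).

    Uses the Kendall generating-function solution; the integral follows
    from d/ds log(1 - E) = delta E - mu.
    """
    if delta * t < 1e-9:
        # (near-)pure death: the generic integral would divide a vanishing
        # cancellation by delta
        if mu <= 0.0:
            return E0, E0 * t
        em = -np.expm1(-mu * t)  # 1 - exp(-mu t), stable for tiny mu t
        Et = E0 + (1.0 - E0) * em
        return Et, t - (1.0 - E0) * em / mu
    if abs(delta - mu) * t < 1e-9:
        q = delta * t * (1.0 - E0)
        Et = (q + E0) / (q + 1.0)
    else:
        w = np.exp(-(delta - mu) * t)
        num = mu * (1.0 - E0) - (mu - delta * E0) * w
        den = delta * (1.0 - E0) - (mu - delta * E0) * w
        Et = num / den
    Et = min(max(Et, 0.0), 1.0 - 1e-15)
    integral = (mu * t + (np.log1p(-Et) - np.log1p(-E0))) / delta
    return Et, integral


def compute_bd_tables(
    Sp: DiscretizedSpeciesTree, rates: BDRates, method: str = "closed"
) -> BDTables:
    """Extinction and 1-to-1 tables for the whole discretized tree.

    ``method="closed"`` uses the exact per-slice solution (conversion does
    not change the duplication/loss rates, so the gene- and
    pseudogene-type extinction probabilities coincide and the one-type
    closed form applies to both).  ``method="rk4"`` integrates the
    two-type ODE system numerically; it exists as an independent route
    for validation.
    """
    P = Sp.n
    eps_g = np.zeros(P)
    eps_p = np.zeros(P)
    seg_top = {}  # point -> (Ep, Eg) at the parent end of its segment
    eps_arc_g: dict[tuple[int, int], float] = {}
    eps_arc_p: dict[tuple[int, int], float] = {}
    seg_log_p11_g = np.zeros(P)
    seg_log_p11_p = np.zeros(P)
    d, m, p = rates.delta, rates.mu, rates.psi
    for pt in Sp.postorder_points:
        ch = Sp.point_children[pt]
        if not ch:
            E = np.zeros(2)  # extant at a species leaf
        elif len(ch) == 1:
            E = seg_top[ch[0]]
        else:
            a, b = seg_top[ch[0]], seg_top[ch[1]]
            for c in ch:
                eps_arc_p[(pt, c)] = float(seg_top[c][0])
                eps_arc_g[(pt, c)] = float(seg_top[c][1])
            E = a * b
        eps_p[pt], eps_g[pt] = E
        par = Sp.point_parent[pt]
        if par >= 0:
            dt = float(Sp.seg_dt[pt])
            if method == "closed":
                Et, integral = _closed_segment(float(E[0]), dt, d, m)
                seg_top[pt] = np.array([Et, Et])
                seg_log_p11_p[pt] = 2 * d * integral - (d + m) * dt
                seg_log_p11_g[pt] = seg_log_p11_p[pt] - p * dt
            else:
                top, int_p, int_g = _rk4_segment(E, dt, rates)
                seg_top[pt] = top
                seg_log_p11_g[pt] = 2 * d * int_g - (d + m + p) * dt
                seg_log_p11_p[pt] = 2 * d * int_p - (d + m) * dt
    return BDTables(
        Sp=Sp,
        rates=rates,
        eps_g=eps_g,
        eps_p=eps_p,
        eps_arc_g=eps_arc_g,
        eps_arc_p=eps_arc_p,
        seg_log_p11_g=seg_log_p11_g,
        seg_log_p11_p=seg_log_p11_p,
    )


def extinction_tables(Sp: DiscretizedSpeciesTree, rates: BDRates) -> BDTables:
    """Convenience alias: tables with the extinction part filled."""
    return compute_bd_tables(Sp, rates)


def p11_tables(Sp: DiscretizedSpeciesTree, rates: BDRates, eps: BDTables | None = None) -> BDTables:
    """Convenience alias: tables with the 1-to-1 part filled."""
    return eps if eps is not None else compute_bd_tables(Sp, rates)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle


def mc_oracle(
    S: DatedSpeciesTree,
    rates: BDRates,
    start: tuple[int, float],
    n_reps: int,
    seed: int,
    target: tuple[int, float] | None = None,
    start_type: str = "gene",
):
    """Forward-simulate the two-type process and estimate extinction and
    1-to-1 frequencies.

    ``start = (v, t)`` places the initial lineage at absolute time ``t``
    inside the edge above species vertex ``v`` (use the root's child and
    its stem for the origin).  ``target = (w, t1)`` optionally defines the
    snapshot point for the 1-to-1 estimate: at time ``t1`` in the edge
    above ``w``, the crossing lineages are collected, and the 1-to-1
    weight is 1 when exactly one of them has extant descendants and it has
    the tracked type, the number of tracked-type crossers when none
    survives, and 0 otherwise (matching the designation-counting
    derivation of the ODE).

    Returns a dict with ``extinct_freq``/``extinct_se`` and, when a target
    is given, ``p11_mean``/``p11_se``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    d, m, p = rates.delta, rates.mu, rates.psi
    extinct = 0
    weights = np.zeros(n_reps)
    tv, tt = (target if target is not None else (-1, np.nan))
    node_time = S.node_time
    children = S.children
    for rep in range(n_reps):
        crossings: list[list] = []  # [type, survives]
        # stack entries: (vertex_below, time, is_gene, crossing_record or None)
        stack = [[start[0], start[1], start_type == "gene", None]]
        any_extant = False
        while stack:
            v, t, is_gene, rec = stack.pop()
            while True:
                rate = d + m + (p if is_gene else 0.0)
                t_event = t - rng.exponential(1.0 / rate) if rate > 0 else -np.inf
                t_vertex = node_time[v]
                t_next = max(t_event, t_vertex)
                if target is not None and v == tv and t >= tt > t_next:
                    rec = [is_gene, False]
                    crossings.append(rec)
                if t_event <= t_vertex:
                    # reached the species vertex below
                    ch = children[v]
                    if not ch:
                        any_extant = True
                        if rec is not None:
                            rec[1] = True  # shared by all copies of the crosser
                        break
                    stack.append([ch[0], t_vertex, is_gene, rec])
                    v, t = ch[1], t_vertex
                    continue
                u = rng.random() * rate
                if u < d:
                    stack.append([v, t_event, is_gene, rec])
                    t = t_event
                elif u < d + m:
                    break  # loss
                else:
                    is_gene = False
                    t = t_event
        extinct += 0 if any_extant else 1
        if target is not None:
            survivors = [r for r in crossings if r[1]]
            if len(survivors) > 1:
                w = 0.0
            elif len(survivors) == 1:
                w = 1.0 if (survivors[0][0] == (start_type == "gene")) else 0.0
            else:
                w = float(sum(1 for r in crossings if r[0] == (start_type == "gene")))
            weights[rep] = w
    out = {
        "extinct_freq": extinct / n_reps,
        "extinct_se": float(np.sqrt(extinct / n_reps * (1 - extinct / n_reps) / n_reps)),
    }
    if target is not None:
        out["p11_mean"] = float(weights.mean())
        out["p11_se"] = float(weights.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else np.nan
    return out
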