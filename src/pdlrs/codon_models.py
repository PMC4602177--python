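"""Goldman-Yang style codon substitution models for genes and pseudogenes.

Both modes share one parameterization of the instantaneous rate from codon
``i`` to codon ``j``: zero if the triplets differ at more than one
position, otherwise ``mu * pi_j`` times ``kappa`` for a transition and
times ``omega`` for a nonsynonymous change, with ``mu`` the normalizer
that makes one unit of branch length equal one expected substitution per
codon site.  The gene mode excludes stop codons from the state space
(61 sense codons under the standard code); the pseudogene mode fixes
``omega = 1`` and runs over all 64 codons, so premature stop codons can
arise and revert.  Equilibrium frequencies are empirical (F64 counts with
add-one pseudocounts) and shared by the two modes; the gene mode
renormalizes them over the sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonSpace",
    "CodonModelParams",
    "CodonModel",
    "estimate_frequencies",
    "build_rate_matrix",
    "transition_matrix",
]

BASES = "ACGT"
PURINES = {"A", "G"}
GENE_MODE = "gene"
PSEUDO_MODE = "pseudogene"


@dataclass(frozen=True)
class CodonSpace:
    """The 64 codons under a genetic code, split into sense and stop."""

    table_id: int = 1
    codons: tuple[str, ...] = field(init=False)
    stop_indices: tuple[int, ...] = field(init=False)
    sense_indices: tuple[int, ...] = field(init=False)
    aa: tuple[str, ...] = field(init=False)  # '*' for stops

    def __post_init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        codons = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
        stops = tuple(i for i, c in enumerate(codons) if c in table.stop_codons)
        sense = tuple(i for i in range(64) if i not in stops)
        aa = tuple(
            "*" if i in stops else table.forward_table[codons[i]] for i in range(64)
        )
        object.__setattr__(self, "codons", codons)
        object.__setattr__(self, "stop_indices", stops)
        object.__setattr__(self, "sense_indices", sense)
        object.__setattr__(self, "aa", aa)

    def index(self, codon: str) -> int:
        return self.codons.index(codon)

    @property
    def structure(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cached 64x64 boolean masks: single-position difference,
        transition (among single-diff pairs), nonsynonymous change."""
        if not hasattr(self, "_structure"):
            diff = np.zeros((64, 64), dtype=bool)
            ti = np.zeros((64, 64), dtype=bool)
            ns = np.zeros((64, 64), dtype=bool)
            for a in range(64):
                for b in range(64):
                    if a == b:
                        continue
                    pos = _single_diff(self.codons[a], self.codons[b])
                    if pos is None:
                        continue
                    diff[a, b] = True
                    ti[a, b] = _is_transition(self.codons[a][pos], self.codons[b][pos])
                    ns[a, b] = self.aa[a] != self.aa[b]
            object.__setattr__(self, "_structure", (diff, ti, ns))
        return self._structure


@lru_cache(maxsize=4)
def default_space(table_id: int = 1) -> CodonSpace:
    return CodonSpace(table_id)


def _single_diff(a: str, b: str) -> int | None:
    """Position of the single differing site, or None if 0 or >1 differ."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    return diffs[0] if len(diffs) == 1 else None


def _is_transition(x: str, y: str) -> bool:
    return (x in PURINES) == (y in PURINES)


@dataclass
class CodonModelParams:
    """Parameters of one mode's rate matrix.

    kappa : transition/transversion ratio (>= 0)
    omega : dN/dS ratio (>= 0); forced to 1 in pseudogene mode
    pi    : equilibrium frequencies over all 64 codons (sum to 1)
    mode  : "gene" (61 sense states) or "pseudogene" (64 states)
    """

    kappa: float
    omega: float
    pi: np.ndarray
    mode: str = GENE_MODE
    space: CodonSpace = field(default_factory=default_space)

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.omega < 0:
            raise ValueError("kappa and omega must be nonnegative")
        if self.mode not in (GENE_MODE, PSEUDO_MODE):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == PSEUDO_MODE:
            self.omega = 1.0
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (64,):
            raise ValueError("pi must cover all 64 codons")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must be a distribution over the 64 codons")
        if self.mode == GENE_MODE and self.pi[list(self.space.stop_indices)].sum() >= 1.0:
            raise ValueError("gene mode needs positive frequency mass on sense codons")

    @property
    def states(self) -> np.ndarray:
        if self.mode == GENE_MODE:
            return np.array(self.space.sense_indices)
        return np.arange(64)

    def state_pi(self) -> np.ndarray:
        """pi restricted to the mode's state space and renormalized."""
        p = self.pi[self.states]
        return p / p.sum()


def estimate_frequencies(sequences, space: CodonSpace | None = None) -> np.ndarray:
    """Empirical codon frequencies (F64) with add-one pseudocounts.

    ``sequences``: iterable of nucleotide strings whose length is a
    multiple of 3.  Codons containing gaps or ambiguity characters are
    skipped.  Genes and pseudogenes are counted jointly.
    """
    space = space or default_space()
    counts = np.ones(64)
    idx = {c: i for i, c in enumerate(space.codons)}
    for seq in sequences:
        s = str(seq).upper().replace("U", "T")
        if len(s) % 3 != 0:
            raise ValueError("sequence length not divisible by 3")
        for k in range(0, len(s), 3):
            i = idx.get(s[k : k + 3])
            if i is not None:
                counts[i] += 1
    return counts / counts.sum()


def build_rate_matrix(params: CodonModelParams) -> np.ndarray:
    """The normalized generator Q over the mode's state space.

    Rows sum to zero and ``-sum_i pi_i q_ii = 1`` so branch lengths are in
    expected substitutions per codon site.  The matrix is reversible with
    respect to the mode's equilibrium frequencies.
    """
    space = params.space
    states = params.states
    pi = params.state_pi()
    diff, ti, ns = space.structure
    ix = np.ix_(states, states)
    factor = np.where(ti[ix], params.kappa, 1.0) * np.where(ns[ix], params.omega, 1.0)
    Q = np.where(diff[ix], pi[None, :] * factor, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    norm = -float(pi @ np.diag(Q))
    if norm <= 0:
        raise ValueError("degenerate rate matrix (zero total flux)")
    return Q / norm


@dataclass
class CodonModel:
    """A mode's generator plus its spectral decomposition.

    Transition probabilities are computed via the symmetrized eigensystem
    of the reversible generator, which is cheap to reuse across the many
    branch lengths an MCMC sweep visits.  ``transition64`` embeds the
    result in the shared 64-codon space (absent states are absorbing),
    which lets a single pruning pass cross mode switches.
    """

    params: CodonModelParams
    Q: np.ndarray = field(init=False)
    _evals: np.ndarray = field(init=False)
    _left: np.ndarray = field(init=False)
    _right: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Q = build_rate_matrix(self.params)
        pi = self.params.state_pi()
        d = np.sqrt(pi)
        sym = (self.Q * d[:, None]) / d[None, :]
        sym = 0.5 * (sym + sym.T)
        evals, evecs = np.linalg.eigh(sym)
        self._evals = evals
        self._right = evecs / d[:, None] * 1.0
        self._left = (evecs * d[:, None]).T

    def transition(self, branch_length: float) -> np.ndarray:
        """P = exp(Q * l) over the mode's state space."""
        if branch_length < 0:
            raise ValueError("branch length must be nonnegative")
        P = (self._right * np.exp(self._evals * branch_length)) @ self._left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def transition64(self, branch_length: float) -> np.ndarray:
        states = self.params.states
        if len(states) == 64:
            return self.transition(branch_length)
        P = np.eye(64)
        P[np.ix_(states, states)] = self.transition(branch_length)
        return P

    def pi64(self) -> np.ndarray:
        """Equilibrium distribution embedded in the 64-codon space."""
        out = np.zeros(64)
        out[self.params.states] = self.params.state_pi()
        return out


def transition_matrix(Q: np.ndarray, branch_length: float) -> np.ndarray:
    """Matrix exponential ``expm(Q * l)`` for an arbitrary generator."""
    from scipy.linalg import expm

    if branch_length < 0:
        raise ValueError("branch length must be nonnegative")
    return expm(Q * branch_length)
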