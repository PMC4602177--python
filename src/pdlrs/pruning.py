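"""Sequence likelihood P(D | G, l, Psi) by pruning with a mode switch.

The whole computation runs in the shared 64-codon state space; the gene
model's transition matrix simply carries no rates into or out of stop
codons.  An edge whose parental vertex is a gene (including the edge from
a gene parent down to a Psi vertex) uses the gene matrix for its full
length; edges below a Psi vertex use the pseudogene matrix.  The root
state distribution is the gene-mode equilibrium (the root predates every
pseudogenization by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_models import GENE_MODE, CodonModel, CodonSpace, default_space
from .gene_tree import GeneTreeState

__all__ = ["CodonAlignment", "sequence_log_likelihood", "read_fasta"]

_SCALE_FLOOR = 1e-300


def read_fasta(text: str) -> dict[str, str]:
    """Parse FASTA text into an id -> sequence dict (order preserved)."""
    from io import StringIO

    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(StringIO(text), "fasta")}


@dataclass
class CodonAlignment:
    """A codon-aware alignment with site-pattern compression.

    ``codes[i, j]`` is the 64-state index of sequence ``i``'s ``j``-th
    codon, or -1 for a codon containing a gap or ambiguity (treated as
    fully missing in the pruning pass).
    """

    ids: list[str]
    codes: np.ndarray
    space: CodonSpace = field(default_factory=default_space)
    patterns: np.ndarray = field(init=False)
    pattern_counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        self.patterns, self.pattern_counts = np.unique(
            self.codes, axis=1, return_counts=True
        )

    @classmethod
    def from_sequences(cls, seqs: dict[str, str], space: CodonSpace | None = None):
        space = space or default_space()
        ids = list(seqs)
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")
        (L,) = lengths
        if L % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        idx = {c: i for i, c in enumerate(space.codons)}
        codes = np.full((len(ids), L // 3), -1, dtype=np.int16)
        for i, sid in enumerate(ids):
            s = seqs[sid].upper().replace("U", "T")
            for j in range(0, L, 3):
                codes[i, j // 3] = idx.get(s[j : j + 3], -1)
        return cls(ids=ids, codes=codes, space=space)

    @property
    def n_codons(self) -> int:
        return self.codes.shape[1]

    def row(self, sid: str) -> np.ndarray:
        return self.patterns[self.ids.index(sid)]


def sequence_log_likelihood(
    D: CodonAlignment,
    state: GeneTreeState,
    gene_model: CodonModel,
    pseudo_model: CodonModel,
    per_site: bool = False,
):
    """Felsenstein pruning over ``G`` including the degree-two Psi vertices.

    Returns the total log likelihood, or (with ``per_site=True``) the
    vector of per-codon-column log likelihoods.
    """
    leaf_names = sorted(l.name for l in state.leaves())
    if leaf_names != sorted(D.ids):
        raise ValueError("alignment ids and gene-tree leaves do not match")
    npat = D.patterns.shape[1]
    log_scale = np.zeros(npat)
    row_of = {sid: i for i, sid in enumerate(D.ids)}

    def partial(node) -> np.ndarray:
        if node.is_leaf:
            row = D.patterns[row_of[node.name]]
            out = np.zeros((64, npat))
            missing = row < 0
            out[:, missing] = 1.0
            cols = np.where(~missing)[0]
            out[row[cols], cols] = 1.0
            return out
        acc = np.ones((64, npat))
        for child in node.children:
            model = gene_model if state.edge_mode(child) == GENE_MODE else pseudo_model
            P = model.transition64(float(child.length))
            acc *= P @ partial(child)
        s = acc.max(axis=0)
        s = np.where(s > 0, s, _SCALE_FLOOR)
        acc /= s
        log_scale[:] += np.log(s)
        return acc

    root_partial = partial(state.root)
    pi = gene_model.pi64()
    site_l = pi @ root_partial
    with np.errstate(divide="ignore"):
        pattern_loglik = np.log(site_l) + log_scale
    if per_site:
        # expand patterns back to columns
        _, inverse = np.unique(D.codes, axis=1, return_inverse=True)
        return pattern_loglik[inverse]
    return float(pattern_loglik @ D.pattern_counts)
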