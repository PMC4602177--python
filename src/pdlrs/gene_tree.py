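"""Gene trees with pseudogenization vertices.

A gene tree ``G`` is rooted with a degree-one root (the stem lineage that
enters the species tree at its root).  Internal vertices are binary except
for the members of ``Psi``, the set of degree-two pseudogenization
vertices marking where a gene lineage irreversibly became a pseudogene.
Each non-root vertex carries the length of the edge above it, in expected
substitutions per codon site.

A state is valid when Psi is an antichain (no two members on one
root-to-leaf path), every pseudogene leaf has an ancestor in Psi, and no
gene leaf descends from a Psi vertex.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .species_tree import DatedSpeciesTree

__all__ = [
    "GNode",
    "GeneTreeState",
    "SuppressedTree",
    "validate_state",
    "suppress",
    "sigma",
    "parse_gene_tree",
    "write_gene_tree",
]

GENE = "gene"
PSEUDO = "pseudogene"
PSI_LABEL = "PSG"

_counter = itertools.count()


class GNode:
    """A vertex of the gene tree; ``length`` is the edge above it."""

    __slots__ = ("parent", "children", "length", "is_psi", "name", "uid")

    def __init__(self, length=None, is_psi=False, name=None):
        self.parent: GNode | None = None
        self.children: list[GNode] = []
        self.length: float | None = length
        self.is_psi: bool = is_psi
        self.name: str | None = name
        self.uid: int = next(_counter)

    def add_child(self, child: "GNode") -> "GNode":
        child.parent = self
        self.children.append(child)
        return child

    def detach_child(self, child: "GNode") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]


@dataclass
class GeneTreeState:
    """Gene tree, edge lengths, Psi and the leaf annotations."""

    root: GNode
    leaf_species: dict[str, str]
    leaf_class: dict[str, str]

    def nodes(self) -> list[GNode]:
        return list(self.root.postorder())

    def leaves(self) -> list[GNode]:
        return self.root.leaves()

    def psi_vertices(self) -> list[GNode]:
        return [n for n in self.nodes() if n.is_psi]

    def edges(self) -> list[GNode]:
        """Edges identified by their child vertex (all non-root vertices)."""
        return [n for n in self.nodes() if n.parent is not None]

    def is_pseudogene(self, node: GNode) -> bool:
        """True if the vertex has a (strict) ancestor in Psi."""
        n = node.parent
        while n is not None:
            if n.is_psi:
                return True
            n = n.parent
        return False

    def edge_mode(self, node: GNode) -> str:
        """Sequence-evolution mode of the edge above ``node``.

        Gene mode while the parental vertex is a gene; the switch happens
        exactly at the Psi vertex, so the edge below a Psi vertex (and any
        edge deeper) evolves in pseudogene mode.
        """
        p = node.parent
        if p is None:
            raise ValueError("root has no edge")
        return PSEUDO if (p.is_psi or self.is_pseudogene(p)) else GENE

    def copy(self) -> "GeneTreeState":
        mapping: dict[GNode, GNode] = {}

        def rec(n: GNode) -> GNode:
            m = GNode(n.length, n.is_psi, n.name)
            mapping[n] = m
            for c in n.children:
                m.add_child(rec(c))
            return m

        return GeneTreeState(rec(self.root), dict(self.leaf_species), dict(self.leaf_class))


def validate_state(state: GeneTreeState) -> list[str]:
    """Check the state invariants; returns a list of violations (empty if ok)."""
    v: list[str] = []
    root = state.root
    if len(root.children) != 1:
        v.append("root must have exactly one child")
    for n in state.nodes():
        if n is root:
            continue
        if n.length is None or not (n.length > 0):
            v.append(f"non-positive edge length above node {n.name or n.uid}")
        if n.is_psi and len(n.children) != 1:
            v.append("pseudogenization vertex must have exactly one child")
        if not n.is_psi and n.children and len(n.children) != 2:
            v.append("internal non-Psi vertex must be binary")
        if n.is_psi and state.is_pseudogene(n):
            v.append("two pseudogenization vertices on one root-to-leaf path")
    for leaf in state.leaves():
        if leaf.name not in state.leaf_class:
            v.append(f"leaf {leaf.name} missing class annotation")
            continue
        cls = state.leaf_class[leaf.name]
        is_p = state.is_pseudogene(leaf)
        if cls == PSEUDO and not is_p:
            v.append(f"pseudogene leaf {leaf.name} has no Psi ancestor")
        if cls == GENE and is_p:
            v.append(f"gene leaf {leaf.name} descends from a Psi vertex")
    return v


@dataclass
class SuppressedTree:
    """The binary tree ``G*`` obtained by suppressing Psi.

    ``origin`` maps the child vertex of each merged edge of ``G*`` to a
    record ``(upper_length, lower_length)`` of the suppressed Psi vertex's
    incident edge lengths.  Edges of ``G*`` are also exposed as leaf-name
    clades so configurations from different states can be compared.
    """

    root: GNode
    origin: dict[GNode, tuple[float, float]]

    def edges(self) -> list[GNode]:
        return [n for n in self.root.postorder() if n.parent is not None]

    def clade(self, node: GNode) -> frozenset[str]:
        return frozenset(l.name for l in node.leaves()) if node.children else frozenset([node.name])

    def psi_edge_clades(self) -> dict[frozenset[str], tuple[float, float]]:
        return {self.clade(n): rec for n, rec in self.origin.items()}


def suppress(state: GeneTreeState) -> SuppressedTree:
    """Remove the degree-two Psi vertices, joining their endpoints.

    The merged edge's length is the sum of the two incident lengths; the
    origin map records both parts (their ratio fixes where on the merged
    edge the pseudogenization sat).
    """
    origin: dict[GNode, tuple[float, float]] = {}

    def rec(n: GNode) -> GNode:
        if n.is_psi:
            child = rec(n.children[0])
            upper = float(n.length) if n.length is not None else 0.0
            child.length = upper + float(child.length)
            origin[child] = (upper, float(child.length) - upper)
            return child
        m = GNode(n.length, False, n.name)
        for c in n.children:
            m.add_child(rec(c))
        return m

    new_root = rec(state.root)
    return SuppressedTree(new_root, origin)


def sigma(state: GeneTreeState, S: DatedSpeciesTree) -> dict[GNode, int]:
    """Map every gene-tree vertex to a species-tree vertex.

    Leaves map to their species; an internal vertex maps to the MRCA in
    ``S`` of the species of the leaves below it.
    """
    out: dict[GNode, int] = {}
    for n in state.root.postorder():
        if n.is_leaf:
            sp = state.leaf_species.get(n.name)
            if sp is None or sp not in S.name_to_leaf:
                raise ValueError(f"unknown species for leaf {n.name!r}")
            out[n] = S.name_to_leaf[sp]
        else:
            out[n] = S.mrca([out[c] for c in n.children])
    return out


def write_gene_tree(state: GeneTreeState) -> str:
    """Newick with Psi vertices as degree-two nodes labelled ``PSG``."""

    def rec(n: GNode) -> str:
        if n.is_leaf:
            return f"{n.name}:{n.length:.10g}"
        inner = ",".join(rec(c) for c in n.children)
        label = PSI_LABEL if n.is_psi else ""
        bl = f":{n.length:.10g}" if n.length is not None else ""
        return f"({inner}){label}{bl}"

    return rec(state.root.children[0]) + ";"


def parse_gene_tree(
    newick_text: str,
    leaf_species: dict[str, str],
    leaf_class: dict[str, str],
    stem_length: float | None = None,
) -> GeneTreeState:
    """Parse a gene tree; degree-two nodes labelled ``PSG`` become Psi.

    The degree-one root is implicit: a stem edge of length ``stem_length``
    (default: the mean of the other edge lengths) is added above the
    outermost clade.
    """
    tree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def rec(nd) -> GNode:
        is_psi = (nd.label == PSI_LABEL)
        n = GNode(
            length=float(nd.edge.length) if nd.edge.length is not None else None,
            is_psi=is_psi,
            name=nd.taxon.label if nd.taxon is not None else None,
        )
        for c in nd.child_nodes():
            n.add_child(rec(c))
        return n

    top = rec(tree.seed_node)
    if stem_length is None:
        lens = [n.length for n in top.postorder() if n.length]
        stem_length = float(sum(lens) / max(len(lens), 1)) or 1.0
    if top.length is None:
        top.length = stem_length
    root = GNode()
    root.add_child(top)
    return GeneTreeState(root, dict(leaf_species), dict(leaf_class))


def read_leaf_map(text: str) -> tuple[dict[str, str], dict[str, str]]:
    """Parse the 3-column (sequence id, species, gene|pseudogene) TSV map."""
    species: dict[str, str] = {}
    cls: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"bad leaf-map line: {line!r}")
        sid, sp, c = parts
        if c not in (GENE, PSEUDO):
            raise ValueError(f"class must be gene or pseudogene, got {c!r}")
        species[sid] = sp
        cls[sid] = c
    return species, cls
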