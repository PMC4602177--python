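import numpy as np
import pytest

from pdlrs.gene_tree import parse_gene_tree
from pdlrs.species_tree import parse_dated_species_tree


@pytest.fixture
def two_species_tree():
    return parse_dated_species_tree("(A:1,B:1):0.5;")


@pytest.fixture
def three_species_tree():
    return parse_dated_species_tree("((A:1,B:1):1,C:2):0.5;")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_state(newick, species, classes):
    """Gene-tree state from a PSG-labelled Newick plus annotation dicts."""
    return parse_gene_tree(newick, species, classes)


def simple_maps(names, pseudo=()):
    """species = first letter of each leaf name; class from ``pseudo``."""
    species = {n: n[0].upper() for n in names}
    classes = {n: ("pseudogene" if n in pseudo else "gene") for n in names}
    return species, classes
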