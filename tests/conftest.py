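"""Shared fixtures: small trees, alignments and simulated datasets.

Everything is generated programmatically and seeded; no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from dnds.codon_models import codon_frequencies, m0_model
from dnds.evolver_sim import simulate
from dnds.seqdata import CodonAlignment, tree_from_newick
from dnds.synthetic_data import default_codon_usage


@pytest.fixture(scope="session")
def usage():
    return default_codon_usage()


@pytest.fixture(scope="session")
def quartet_tree():
    return tree_from_newick("(A:0.12,B:0.3,(C:0.21,D:0.4):0.15);")


@pytest.fixture(scope="session")
def quartet_fg_tree():
    return tree_from_newick("(A:0.12,B:0.3,(C:0.21,D:0.4)#1:0.15);")


@pytest.fixture(scope="session")
def seven_taxon_tree():
    return tree_from_newick(
        "((A:0.2,B:0.35):0.1,(C:0.15,D:0.28):0.12,"
        "(E:0.3,(F:0.2,G:0.1)#1:0.15):0.2);"
    )


@pytest.fixture(scope="session")
def small_m0_data(seven_taxon_tree, usage):
    """7 taxa x 120 codons simulated under M0 (omega 0.3, kappa 2)."""
    return simulate(seven_taxon_tree, m0_model(2.0, 0.3, usage), 120, seed=42)


@pytest.fixture(scope="session")
def toy_alignment():
    """A tiny 4-taxon hand-written in-frame alignment (6 codons)."""
    return CodonAlignment.from_sequences(
        [
            ("A", "ATGGCTGAACGTTTAGGA"),
            ("B", "ATGGCTGAGCGTTTAGGA"),
            ("C", "ATGGCAGAACGCTTAGGC"),
            ("D", "ATGGGTGAACGTCTAGGA"),
        ]
    )
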