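import numpy as np
import pytest

from cladescan import CladeDefinition, CodonAlignment, tree_from_newick
from cladescan._codons import get_genetic_code


@pytest.fixture(scope="session")
def code():
    return get_genetic_code(1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def five_taxon_tree():
    return tree_from_newick(
        "((s1:0.05,s2:0.05):0.05,(s3:0.05,(s4:0.05,s5:0.05):0.05):0.05);"
    )


@pytest.fixture
def toy_private_alignment(code):
    # one diagnostic column (T,T,G,G,G) at nt position 3 (codon 1, 3rd base)
    seqs = {
        "s1": "ATTGAA",
        "s2": "ATTGAA",
        "s3": "ATGGAA",
        "s4": "ATGGAA",
        "s5": "ATGGAA",
    }
    return CodonAlignment("toy", list(seqs), seqs, code)


@pytest.fixture
def clade_s12():
    return CladeDefinition("X", frozenset({"s1", "s2"}))


def random_codon_alignment(rng, code, n_taxa=8, n_codons=50, gene="rand"):
    """Uniform random codon alignment (not evolved; for pattern oracles)."""
    taxa = [f"s{i + 1}" for i in range(n_taxa)]
    seqs = {
        t: "".join(
            code.codons[i] for i in rng.integers(0, code.n_states, n_codons)
        )
        for t in taxa
    }
    return CodonAlignment(gene, taxa, seqs, code)
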