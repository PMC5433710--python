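import numpy as np
import pytest

from mtconserv.io import CodonAlignment, Phylogeny


@pytest.fixture
def four_taxon() -> Phylogeny:
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


def make_alignment(taxa, seqs, gene="g"):
    n_cols = len(seqs[0]) // 3
    mat = np.array(
        [[s[3 * j : 3 * j + 3] for j in range(n_cols)] for s in seqs],
        dtype="<U3",
    )
    return CodonAlignment(gene=gene, taxa=list(taxa), codons=mat)


@pytest.fixture
def bound_pair(four_taxon):
    aln = make_alignment(
        ["A", "B", "C", "D"],
        ["TCCTCC", "TCCTCC", "CCCTCC", "CCCTCC"],
    )
    return four_taxon.bind(aln), aln
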