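import numpy as np
import pytest

from pepmimic import ProteinRecord, Repertoire
from pepmimic.io_formats import AMINO_ACIDS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_peptide(rng, L=7):
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=L)])


def random_repertoire(rng, n, L=7, label="T"):
    seqs = set()
    while len(seqs) < n:
        seqs.add(random_peptide(rng, L))
    return Repertoire.from_sequences(sorted(seqs), label=label)


def random_proteome(rng, n_proteins, length):
    return [
        ProteinRecord(
            gene_id=f"ENSG{j:05d}",
            transcript_id=f"ENST{j:05d}",
            gene_symbol=f"G{j}",
            protein_id=f"ENSP{j:05d}",
            sequence="".join(
                np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=length)]
            ),
        )
        for j in range(n_proteins)
    ]


@pytest.fixture
def small_proteome(rng):
    return random_proteome(rng, 5, 60)
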