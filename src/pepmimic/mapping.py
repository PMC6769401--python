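"""All-window ungapped PAM30 similarity mapping of peptides on a proteome.

The similarity of a peptide ``p`` against an equal-length protein window
``w`` is the positional PAM30 score sum, clipped at zero, normalised by the
peptide's self-score::

    sim(p, w) = max(0, sum_i M[p_i, w_i]) / sum_i M[p_i, p_i]

Because PAM30 is diagonally dominant this lies in [0, 1] and equals 1.0 for
the identity window.  A scan emits a :class:`~pepmimic.io_formats.Hit` for
every peptide/window pair with similarity >= h, exhaustively over all
windows of every protein.

Peptide-peptide clustering uses a symmetric variant (the larger of the two
self-scores in the denominator) and single-linkage connected components at
the same threshold h.

The production scan is vectorised over integer-encoded sequences with a
window-sum formulation; it is algorithmically distinct from the explicit
double-loop reference used in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .io_formats import AMINO_ACIDS, Hit, ProteinRecord, Repertoire

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer substitution matrix over :data:`AMINO_ACIDS` order.

    Must be symmetric with each diagonal entry the maximum of its row
    (guaranteed for PAM30), which is what keeps normalised similarities
    within [0, 1].
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        s = self.scores
        if s.shape != (20, 20):
            raise ValueError(f"expected a 20x20 matrix, got {s.shape}")
        if not np.array_equal(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if not all(s[i, i] == s[i].max() for i in range(20)):
            raise ValueError("diagonal entries must dominate their rows")

    def score(self, a: str, b: str) -> int:
        return int(self.scores[_AA_INDEX[a], _AA_INDEX[b]])


def _matrix_from_biopython(m) -> SubstitutionMatrix:
    idx = [m.alphabet.index(aa) for aa in AMINO_ACIDS]
    arr = np.asarray(m)[np.ix_(idx, idx)].astype(np.int64)
    return SubstitutionMatrix(arr)


def load_pam30() -> SubstitutionMatrix:
    """The NCBI PAM30 matrix restricted to the 20 standard residues."""
    return _matrix_from_biopython(substitution_matrices.load("PAM30"))


def read_matrix(path) -> SubstitutionMatrix:
    """Load a substitution matrix from an NCBI-format text file."""
    return _matrix_from_biopython(substitution_matrices.read(str(path)))


PAM30 = load_pam30()


def encode(seq: str) -> np.ndarray:
    """Integer-encode a standard-residue sequence in AMINO_ACIDS order."""
    try:
        return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc} in {seq!r}") from exc


def similarity(
    peptide: str, window: str, matrix: Optional[SubstitutionMatrix] = None
) -> float:
    """Normalised, zero-clipped PAM30 similarity of a peptide to a window."""
    if len(peptide) != len(window):
        raise ValueError(
            f"length mismatch: {len(peptide)} vs {len(window)}"
        )
    m = (matrix or PAM30).scores
    p = encode(peptide)
    w = encode(window)
    raw = int(m[p, w].sum())
    self_score = int(m[p, p].sum())
    return max(0, raw) / self_score


def symmetric_similarity(
    p: str, q: str, matrix: Optional[SubstitutionMatrix] = None
) -> float:
    """Symmetric similarity: clipped score sum over the larger self-score.

    Bounded above by both directed similarities, so clustering at a given h
    is at least as strict as either directed comparison.
    """
    if len(p) != len(q):
        raise ValueError(f"length mismatch: {len(p)} vs {len(q)}")
    m = (matrix or PAM30).scores
    a = encode(p)
    b = encode(q)
    raw = int(m[a, b].sum())
    denom = max(int(m[a, a].sum()), int(m[b, b].sum()))
    return max(0, raw) / denom


class _ProteomeIndex:
    """Concatenated integer encoding of a proteome with valid window starts."""

    def __init__(self, proteome: Sequence[ProteinRecord], L: int):
        self.L = L
        codes = []
        win_protein: list[np.ndarray] = []
        win_local: list[np.ndarray] = []
        win_global: list[np.ndarray] = []
        offset = 0
        self.protein_ids = [p.protein_id for p in proteome]
        for j, prot in enumerate(proteome):
            c = encode(prot.sequence)
            codes.append(c)
            n = len(c)
            if n >= L:
                starts = np.arange(n - L + 1)
                win_global.append(offset + starts)
                win_local.append(starts + 1)  # 1-based
                win_protein.append(np.full(len(starts), j))
            offset += n
        self.cat = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
        if win_global:
            self.win_global = np.concatenate(win_global)
            self.win_local = np.concatenate(win_local)
            self.win_protein = np.concatenate(win_protein)
            sw = np.lib.stride_tricks.sliding_window_view(self.cat, L)
            self.windows = sw[self.win_global]
        else:
            self.win_global = np.empty(0, dtype=np.int64)
            self.win_local = np.empty(0, dtype=np.int64)
            self.win_protein = np.empty(0, dtype=np.int64)
            self.windows = np.empty((0, L), dtype=np.int64)


def scan_proteome(
    repertoire: Repertoire,
    proteome: Sequence[ProteinRecord],
    h: float,
    matrix: Optional[SubstitutionMatrix] = None,
) -> list[Hit]:
    """Exhaustive ungapped scan of every peptide against every window.

    A hit is emitted iff ``similarity(peptide, window) >= h`` (unrounded
    comparison, ties included).  Proteins shorter than the peptide length
    contribute no windows.  Hits are ordered by repertoire order, then
    protein order, then start.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"h must lie in [0, 1], got {h}")
    if not len(repertoire):
        raise ValueError("empty repertoire")
    if not proteome:
        raise ValueError("empty proteome")
    m = (matrix or PAM30).scores
    L = repertoire.length
    index = _ProteomeIndex(proteome, L)
    hits: list[Hit] = []
    if index.windows.shape[0] == 0:
        return hits
    windows = index.windows
    for seq in repertoire.sequences:
        p = encode(seq)
        raw = m[p[np.newaxis, :], windows].sum(axis=1)
        self_score = int(m[p, p].sum())
        sims = np.maximum(raw, 0) / self_score
        sel = np.nonzero(sims >= h)[0]
        for i in sel:
            hits.append(
                Hit(
                    protein_id=index.protein_ids[index.win_protein[i]],
                    start=int(index.win_local[i]),
                    peptide=seq,
                    similarity=float(sims[i]),
                )
            )
    return hits


def cluster_peptides(
    repertoire: Repertoire,
    h: float,
    matrix: Optional[SubstitutionMatrix] = None,
) -> Repertoire:
    """Fill each peptide's ``cluster_size`` by single-linkage clustering.

    Two peptides are linked iff their symmetric similarity >= h; clusters
    are the connected components of that graph and every peptide's
    ``cluster_size`` is the size of its component (>= 1).
    """
    m = (matrix or PAM30).scores
    seqs = repertoire.sequences
    n = len(seqs)
    P = np.stack([encode(s) for s in seqs])
    L = P.shape[1]
    self_scores = m[P, P].sum(axis=1)
    pair = np.zeros((n, n), dtype=np.int64)
    for i in range(L):
        col = P[:, i]
        pair += m[col[:, np.newaxis], col[np.newaxis, :]]
    denom = np.maximum(self_scores[:, np.newaxis], self_scores[np.newaxis, :])
    sims = np.maximum(pair, 0) / denom
    adj = sims >= h
    np.fill_diagonal(adj, False)
    ii, jj = np.nonzero(adj)
    graph = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    for seq, lab in zip(seqs, labels):
        repertoire.peptides[seq].cluster_size = int(sizes[lab])
    return repertoire


def annotate_mapping_stats(repertoire: Repertoire, hits: Sequence[Hit]) -> Repertoire:
    """Fill each peptide's ``n_proteins`` with the number of distinct
    proteins it maps to in ``hits`` (0 for unmapped peptides)."""
    per_peptide: dict[str, set[str]] = {}
    for hit in hits:
        per_peptide.setdefault(hit.peptide, set()).add(hit.protein_id)
    for seq, pep in repertoire.peptides.items():
        pep.n_proteins = len(per_peptide.get(seq, ()))
    return repertoire
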