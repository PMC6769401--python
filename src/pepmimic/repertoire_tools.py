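"""Amino-acid frequencies, Mock-repertoire generation, Control balancing.

The Mock repertoire estimates the background of random mappings: it matches
the Test repertoire in unique-peptide count and peptide length, with
residues drawn i.i.d. from the library's amino-acid frequency table and
uniqueness enforced by rejection sampling.  All randomness is driven by an
explicit integer seed, so a fixed seed reproduces the Mock byte for byte.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .seeding import stream_rng
from .io_formats import (
    AMINO_ACIDS,
    AAFTable,
    FormatError,
    MAX_PEPTIDE_LENGTH,
    MIN_PEPTIDE_LENGTH,
    Repertoire,
)

logger = logging.getLogger(__name__)


def compute_aaf(repertoire: Repertoire) -> AAFTable:
    """Occurrence-weighted residue frequencies of a repertoire, as
    percentages summing to 100.

    Each peptide contributes its residues ``occurrences`` times, so a counts
    table yields abundance-weighted library frequencies while a plain unique
    list (all occurrences 1) yields per-unique-sequence frequencies.
    """
    if not len(repertoire):
        raise ValueError("empty repertoire")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    total = 0
    for seq, pep in repertoire.peptides.items():
        for aa in seq:
            counts[aa] += pep.occurrences
        total += len(seq) * pep.occurrences
    return AAFTable({aa: 100.0 * counts[aa] / total for aa in AMINO_ACIDS})


def generate_mock(
    test: Repertoire,
    aaf: AAFTable,
    seed: int,
    label: str = "M",
) -> Repertoire:
    """Generate a Mock repertoire matched to the Test in size and length.

    Peptides are drawn residue-wise i.i.d. from ``aaf``; duplicates (within
    the Mock) are redrawn until the requested number of unique sequences is
    reached.  Deterministic for a fixed seed.
    """
    n = len(test)
    L = test.length
    n_usable = sum(1 for aa in AMINO_ACIDS if aaf.frequencies[aa] > 0)
    if n > n_usable ** L:
        raise ValueError(
            f"cannot draw {n} unique length-{L} peptides from "
            f"{n_usable} usable residues"
        )
    rng = stream_rng(seed, "mock")
    probs = aaf.probabilities()
    alphabet = np.array(list(AMINO_ACIDS))
    seen: dict[str, None] = {}
    while len(seen) < n:
        batch = max(n - len(seen), 64)
        draws = rng.choice(20, size=(batch, L), p=probs)
        for row in draws:
            if len(seen) >= n:
                break
            seq = "".join(alphabet[row])
            if seq not in seen:
                seen[seq] = None
    return Repertoire.from_sequences(list(seen), label=label)


def balance_control(control: Repertoire, test: Repertoire, seed: int) -> Repertoire:
    """Pad an undersized Control with unique Test sequences (seeded uniform
    sample) until it matches the Test size; identity when already equal.

    A Control larger than the Test is returned unchanged with a warning.
    """
    if len(control) > len(test):
        logger.warning(
            "control repertoire (%d) larger than test (%d); not padded",
            len(control),
            len(test),
        )
        return control
    if len(control) == len(test):
        return control
    candidates = [s for s in test.sequences if s not in control]
    deficit = len(test) - len(control)
    if deficit > len(candidates):
        raise ValueError(
            f"cannot pad control: need {deficit} sequences, only "
            f"{len(candidates)} unused test sequences available"
        )
    rng = stream_rng(seed, "balance")
    picked = rng.choice(len(candidates), size=deficit, replace=False)
    padded = control.sequences + [candidates[i] for i in sorted(picked)]
    return Repertoire.from_sequences(padded, label=control.label)


def make_placeholder_control(L: int) -> Repertoire:
    """Single poly-W placeholder Control of peptide length ``L``.

    Used when no Control selection exists; its near-empty profile is
    subtracted like any other control's.
    """
    if not MIN_PEPTIDE_LENGTH <= L <= MAX_PEPTIDE_LENGTH:
        raise FormatError(
            f"peptide length {L} outside [{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]"
        )
    rep = Repertoire.from_sequences(["W" * L], label="C")
    rep.placeholder = True
    return rep
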