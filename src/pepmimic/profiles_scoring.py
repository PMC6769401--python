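"""Signal profiles, background subtraction, m-scores and outlier selection.

A protein's signal profile ("aah", amino-acid hits) counts, at every
residue, how many peptide matches cover that position.  The Mock profile
(random-mapping background) and, when available, the Control profile are
subtracted position-wise with clipping at zero.  The m-score of a protein
is the total subtracted signal divided by the number of residues carrying
any signal — the mean hit depth over covered residues — and proteins are
selected as outliers of the m-score distribution via z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import Hit, ProteinRecord

Profiles = dict[str, np.ndarray]


@dataclass(frozen=True)
class ProteinScore:
    protein_id: str
    m_score: float
    z_score: float


def build_profile(hits: Sequence[Hit], proteome: Sequence[ProteinRecord]) -> Profiles:
    """Accumulate hits into per-protein coverage vectors.

    Every hit at 1-based start ``s`` with peptide length ``L`` adds one to
    positions ``s .. s+L-1``; proteins without hits get all-zero profiles.
    The profile sum of a protein therefore equals (number of its hits) x L.
    """
    lengths = {p.protein_id: len(p) for p in proteome}
    profiles: Profiles = {
        p.protein_id: np.zeros(len(p), dtype=float) for p in proteome
    }
    for h in hits:
        if h.protein_id not in profiles:
            raise ValueError(f"hit on unknown protein {h.protein_id}")
        L = len(h.peptide)
        if h.start < 1 or h.start + L - 1 > lengths[h.protein_id]:
            raise ValueError(
                f"hit at {h.protein_id}:{h.start} (L={L}) beyond protein bounds"
            )
        profiles[h.protein_id][h.start - 1 : h.start - 1 + L] += 1.0
    return profiles


def subtract_profiles(
    t: Profiles, m: Profiles, c: Optional[Profiles] = None
) -> Profiles:
    """Position-wise ``max(0, T - M - C)`` (C omitted when None).

    All profile sets must cover the same proteins with equal lengths.
    """
    for other, name in ((m, "mock"), (c, "control")):
        if other is None:
            continue
        if set(other) != set(t):
            raise ValueError(f"{name} profiles cover a different protein set")
    out: Profiles = {}
    for pid, vec in t.items():
        res = vec - m[pid]
        if c is not None:
            res = res - c[pid]
        out[pid] = np.maximum(res, 0.0)
    return out


def m_score(profile: np.ndarray) -> float:
    """Sum of the signal divided by the number of covered residues; 0 for an
    all-zero profile."""
    covered = int(np.count_nonzero(profile > 0))
    if covered == 0:
        return 0.0
    return float(profile.sum()) / covered


def z_scores(mscores: Mapping[str, float]) -> dict[str, ProteinScore]:
    """Standardise m-scores over the proteins with m > 0 (population sd).

    Proteins with m = 0 receive a -inf sentinel z so they can never be
    selected.  If every nonzero m is identical all their z-scores are 0.
    Fewer than two nonzero m-scores is an error.
    """
    nonzero = {pid: m for pid, m in mscores.items() if m > 0}
    if len(nonzero) < 2:
        raise ValueError(
            f"need at least 2 proteins with m > 0, got {len(nonzero)}"
        )
    vals = np.array(list(nonzero.values()))
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    out: dict[str, ProteinScore] = {}
    for pid, m in mscores.items():
        if m <= 0:
            z = -math.inf
        elif sd == 0:
            z = 0.0
        else:
            z = (m - mean) / sd
        out[pid] = ProteinScore(pid, m_score=float(m), z_score=z)
    return out


def select_outliers(
    scores: Mapping[str, ProteinScore], z_cut: float = 2.58
) -> list[ProteinScore]:
    """Proteins with z >= z_cut, sorted by m-score descending (ties by id)."""
    if z_cut <= 0:
        raise ValueError(f"z_cut must be positive, got {z_cut}")
    sel = [s for s in scores.values() if s.z_score >= z_cut]
    return sorted(sel, key=lambda s: (-s.m_score, s.protein_id))


def score_distribution(
    mscores: Mapping[str, float], bin_width: float
) -> list[tuple[float, float, int]]:
    """Histogram of the nonzero m-scores in left-closed bins from 0.

    Returns (bin_low, bin_high, count) rows for non-empty bins; the counts
    sum to the number of proteins with m > 0.
    """
    if bin_width <= 0:
        raise ValueError(f"bin width must be positive, got {bin_width}")
    vals = [m for m in mscores.values() if m > 0]
    if not vals:
        return []
    idx = np.floor(np.asarray(vals) / bin_width).astype(int)
    counts = np.bincount(idx)
    return [
        (i * bin_width, (i + 1) * bin_width, int(c))
        for i, c in enumerate(counts)
        if c > 0
    ]
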