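"""Deterministic synthetic benchmark: toy proteome with planted motifs.

The generator emulates the experimental design of a Test-vs-Control
biopanning screen at desk scale: an i.i.d. background proteome in which a
few target proteins carry an embedded length-L motif, a Test repertoire
mixing motif-derived peptides (point-substituted copies of the planted
windows) into an i.i.d. background drawn from the library's amino-acid
frequencies, and a Control repertoire that shares the control-target-derived
peptides (non-specific binders present in both selections) so that Control
subtraction can be exercised.  A GMT file assigns all Test-target genes to
the term ``T_PLANTED`` alongside random decoy terms, and a truth table
records the planted proteins and motif positions.

Everything is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .seeding import stream_rng
from .io_formats import (
    AMINO_ACIDS,
    AAFTable,
    ProteinRecord,
    Repertoire,
    write_aaf,
    write_proteome,
    write_repertoire,
)

_ALPHABET = np.array(list(AMINO_ACIDS))


@dataclass
class FixtureConfig:
    """Study conditions of the synthetic benchmark.

    Defaults keep the peptide-to-residue ratio of a realistic screen
    (thousands of unique peptides against a 20k-protein proteome) while
    staying small enough that a full pipeline run takes seconds.
    """

    n_proteins: int = 100
    protein_length: int = 300
    n_targets: int = 5
    n_control_targets: int = 2
    peptide_length: int = 7
    n_peptides: int = 2000
    planted_fraction: float = 0.1
    substitution_rate: float = 0.1
    aaf: AAFTable = field(default_factory=AAFTable.uniform)
    n_decoy_terms: int = 20
    decoy_term_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets + self.n_control_targets > self.n_proteins:
            raise ValueError("more targets than proteins")
        if not 0 < self.planted_fraction < 1:
            raise ValueError("planted_fraction must lie in (0, 1)")
        if not 0 <= self.substitution_rate < 1:
            raise ValueError("substitution_rate must lie in [0, 1)")
        if self.planted_fraction * self.n_peptides < 10 * self.n_targets:
            raise ValueError(
                "too few planted peptides: need planted_fraction * n_peptides"
                " >= 10 * n_targets"
            )


@dataclass
class Fixture:
    proteome: list[ProteinRecord]
    test: Repertoire
    control: Repertoire
    aaf: AAFTable
    gmt: dict[str, tuple[str, frozenset[str]]]
    truth: list[dict]   # protein_id, gene_symbol, role, position, motif
    paths: dict[str, Path] = field(default_factory=dict)

    @property
    def target_protein_ids(self) -> list[str]:
        return [t["protein_id"] for t in self.truth if t["role"] == "test"]

    @property
    def control_protein_ids(self) -> list[str]:
        return [t["protein_id"] for t in self.truth if t["role"] == "control"]


def _draw_peptides(rng, probs, L, count, taken: set[str]) -> list[str]:
    """i.i.d. background peptides, unique and disjoint from ``taken``."""
    out: list[str] = []
    while len(out) < count:
        batch = max(count - len(out), 64)
        draws = rng.choice(20, size=(batch, L), p=probs)
        for row in draws:
            if len(out) >= count:
                break
            seq = "".join(_ALPHABET[row])
            if seq not in taken:
                taken.add(seq)
                out.append(seq)
    return out


def _derive_peptides(rng, motif: str, rate: float, count: int, taken: set[str]) -> list[str]:
    """Up to ``count`` point-substituted copies of a motif, unique and
    disjoint from ``taken``.

    May return fewer when the substitution rate cannot supply ``count``
    distinct variants (at rate 0 only the motif itself exists); the caller
    tops the repertoire up with background peptides.
    """
    out: list[str] = []
    L = len(motif)
    stagnation = 0
    while len(out) < count and stagnation < 2000:
        chars = list(motif)
        for i in range(L):
            if rng.random() < rate:
                alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
                chars[i] = alternatives[rng.integers(0, 19)]
        seq = "".join(chars)
        if seq not in taken:
            taken.add(seq)
            out.append(seq)
            stagnation = 0
        else:
            stagnation += 1
    return out


def generate_fixture(
    cfg: FixtureConfig, outdir: Optional[str | Path] = None
) -> Fixture:
    """Generate the full fixture; optionally write every file to ``outdir``.

    Written files: ``proteome.fasta``, ``test_repertoire.txt``,
    ``control_repertoire.txt``, ``aaf.tsv``, ``annotations.gmt``,
    ``truth.tsv``.
    """
    rng = stream_rng(cfg.seed, "fixture")
    probs = cfg.aaf.probabilities()
    L = cfg.peptide_length

    # --- proteome -----------------------------------------------------
    proteome: list[ProteinRecord] = []
    for j in range(cfg.n_proteins):
        seq = "".join(_ALPHABET[rng.choice(20, size=cfg.protein_length, p=probs)])
        proteome.append(
            ProteinRecord(
                gene_id=f"ENSG{j:08d}",
                transcript_id=f"ENST{j:08d}",
                gene_symbol=f"GENE{j:03d}",
                protein_id=f"ENSP{j:08d}",
                sequence=seq,
            )
        )

    # --- plant motifs -------------------------------------------------
    truth: list[dict] = []
    roles = ["test"] * cfg.n_targets + ["control"] * cfg.n_control_targets
    motifs: list[str] = []
    for j, role in enumerate(roles):
        prot = proteome[j]
        pos = int(rng.integers(0, cfg.protein_length - L + 1))  # 0-based
        motif = "".join(_ALPHABET[rng.choice(20, size=L, p=probs)])
        prot.sequence = prot.sequence[:pos] + motif + prot.sequence[pos + L :]
        motifs.append(motif)
        truth.append(
            {
                "protein_id": prot.protein_id,
                "gene_symbol": prot.gene_symbol,
                "role": role,
                "position": pos + 1,  # 1-based
                "motif": motif,
            }
        )

    # --- repertoires --------------------------------------------------
    n_planted = round(cfg.planted_fraction * cfg.n_peptides)
    n_sources = len(roles)
    per_source = [
        n_planted // n_sources + (1 if i < n_planted % n_sources else 0)
        for i in range(n_sources)
    ]
    taken: set[str] = set()
    test_seqs: list[str] = []
    control_planted: list[str] = []
    for motif, role, count in zip(motifs, roles, per_source):
        derived = _derive_peptides(rng, motif, cfg.substitution_rate, count, taken)
        test_seqs.extend(derived)
        if role == "control":
            # non-specific binders: present identically in both selections
            control_planted.extend(derived)
    test_seqs.extend(
        _draw_peptides(rng, probs, L, cfg.n_peptides - len(test_seqs), taken)
    )
    control_seqs = list(control_planted)
    control_seqs.extend(
        _draw_peptides(rng, probs, L, cfg.n_peptides - len(control_seqs), taken)
    )
    test = Repertoire.from_sequences(test_seqs, label="T")
    control = Repertoire.from_sequences(control_seqs, label="C")

    # --- annotations --------------------------------------------------
    all_genes = [p.gene_symbol for p in proteome]
    planted_genes = frozenset(
        t["gene_symbol"] for t in truth if t["role"] == "test"
    )
    gmt: dict[str, tuple[str, frozenset[str]]] = {
        "T_PLANTED": ("planted target genes", planted_genes)
    }
    for d in range(cfg.n_decoy_terms):
        members = rng.choice(len(all_genes), size=cfg.decoy_term_size, replace=False)
        gmt[f"DECOY_{d:03d}"] = (
            f"random decoy term {d}",
            frozenset(all_genes[i] for i in members),
        )

    fixture = Fixture(
        proteome=proteome, test=test, control=control,
        aaf=cfg.aaf, gmt=gmt, truth=truth,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteome": outdir / "proteome.fasta",
            "test": outdir / "test_repertoire.txt",
            "control": outdir / "control_repertoire.txt",
            "aaf": outdir / "aaf.tsv",
            "gmt": outdir / "annotations.gmt",
            "truth": outdir / "truth.tsv",
        }
        write_proteome(proteome, paths["proteome"])
        write_repertoire(test, paths["test"])
        write_repertoire(control, paths["control"])
        write_aaf(cfg.aaf, paths["aaf"])
        with open(paths["gmt"], "w") as fh:
            for term, (desc, genes) in gmt.items():
                fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")
        with open(paths["truth"], "w") as fh:
            fh.write("protein_id\tgene_symbol\trole\tposition\tmotif\n")
            for t in truth:
                fh.write(
                    f"{t['protein_id']}\t{t['gene_symbol']}\t{t['role']}\t"
                    f"{t['position']}\t{t['motif']}\n"
                )
        fixture.paths = paths
    return fixture
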