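"""Readers and writers for every external format the pipeline touches.

Peptide repertoires come in three flavours (plain list, FASTA, two-column
count table), the proteome is FASTA with a mandatory pipe-delimited header
``>GeneID|TranscriptID|GeneSymbol|ProteinID``, amino-acid frequency tables
are two-column TSV, and annotations arrive as GMT (term, description, genes)
with an optional OBO ontology restricted to ``is_a`` edges.

All tabular outputs are TSV.  Positions in every file are 1-based and
inclusive; similarities are printed with four decimals so that a written hit
table round-trips exactly through :func:`read_hits`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Peptide lengths supported by commercial display libraries.
MIN_PEPTIDE_LENGTH = 5
MAX_PEPTIDE_LENGTH = 15


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Peptide:
    """A unique peptide with the metadata reported alongside each hit.

    ``cluster_size`` (size of the largest similarity cluster the peptide
    belongs to in the Test repertoire) and ``n_proteins`` (number of distinct
    proteins it maps onto) are filled in by the mapping stage and remain
    ``None`` until then.
    """

    sequence: str
    occurrences: int = 1
    cluster_size: Optional[int] = None
    n_proteins: Optional[int] = None

    def __post_init__(self) -> None:
        validate_peptide_sequence(self.sequence)
        if self.occurrences < 1:
            raise FormatError(
                f"peptide {self.sequence}: occurrences must be >= 1, "
                f"got {self.occurrences}"
            )


def validate_peptide_sequence(seq: str) -> None:
    if not MIN_PEPTIDE_LENGTH <= len(seq) <= MAX_PEPTIDE_LENGTH:
        raise FormatError(
            f"peptide length {len(seq)} outside "
            f"[{MIN_PEPTIDE_LENGTH}, {MAX_PEPTIDE_LENGTH}]: {seq!r}"
        )
    bad = set(seq) - _AA_SET
    if bad:
        raise FormatError(
            f"non-standard residue(s) {sorted(bad)} in peptide {seq!r}"
        )


@dataclass
class Repertoire:
    """A labeled set of unique, equal-length peptides.

    ``label`` is conventionally ``"T"`` (Test), ``"C"`` (Control) or
    ``"M"`` (Mock) but any string is accepted.  Uniqueness is enforced by
    keying on sequence; insertion order is preserved and meaningful for
    reproducibility.
    """

    label: str = "T"
    peptides: dict[str, Peptide] = field(default_factory=dict)
    placeholder: bool = False

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.peptides}
        if len(lengths) > 1:
            raise FormatError(f"mixed peptide lengths {sorted(lengths)}")

    @classmethod
    def from_sequences(
        cls,
        sequences: Iterable[str],
        label: str = "T",
        counts: Optional[Sequence[int]] = None,
    ) -> "Repertoire":
        """Build a repertoire, collapsing duplicate sequences.

        Duplicates are merged into a single :class:`Peptide` whose
        ``occurrences`` is the sum of the individual counts (1 per line when
        ``counts`` is not given).
        """
        peptides: dict[str, Peptide] = {}
        seqs = list(sequences)
        if counts is None:
            counts = [1] * len(seqs)
        if len(counts) != len(seqs):
            raise FormatError("counts and sequences differ in length")
        for seq, cnt in zip(seqs, counts):
            seq = seq.strip().upper()
            if not seq:
                continue
            if seq in peptides:
                peptides[seq].occurrences += int(cnt)
            else:
                peptides[seq] = Peptide(seq, occurrences=int(cnt))
        rep = cls(label=label, peptides=peptides)
        if not rep.peptides:
            raise FormatError("empty repertoire")
        return rep

    @property
    def length(self) -> int:
        """Common peptide length L."""
        return len(next(iter(self.peptides)))

    @property
    def sequences(self) -> list[str]:
        return list(self.peptides)

    def __len__(self) -> int:
        return len(self.peptides)

    def __contains__(self, seq: str) -> bool:
        return seq in self.peptides


@dataclass
class AAFTable:
    """Amino-acid frequency table of a phage library, in percentages."""

    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        keys = set(self.frequencies)
        if keys != _AA_SET:
            missing = sorted(_AA_SET - keys)
            extra = sorted(keys - _AA_SET)
            raise FormatError(
                f"aaf table must cover exactly the 20 standard residues; "
                f"missing={missing} extra={extra}"
            )
        for aa, pct in self.frequencies.items():
            if pct < 0:
                raise FormatError(f"negative frequency for {aa}: {pct}")
        total = sum(self.frequencies.values())
        if abs(total - 100.0) > 0.1:
            raise FormatError(f"aaf percentages sum to {total}, not 100 +/- 0.1")

    @classmethod
    def uniform(cls) -> "AAFTable":
        return cls({aa: 5.0 for aa in AMINO_ACIDS})

    def probabilities(self) -> list[float]:
        """Per-residue probabilities in :data:`AMINO_ACIDS` order,
        renormalised to sum exactly to 1."""
        vals = [self.frequencies[aa] for aa in AMINO_ACIDS]
        total = sum(vals)
        return [v / total for v in vals]


@dataclass
class ProteinRecord:
    """One proteome entry parsed from the pipe-delimited FASTA header."""

    gene_id: str
    transcript_id: str
    gene_symbol: str
    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        for name in ("gene_id", "transcript_id", "gene_symbol", "protein_id"):
            if not getattr(self, name):
                raise FormatError(f"empty header field {name}")
        if not self.sequence:
            raise FormatError(f"{self.protein_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Hit:
    """One ungapped peptide match on a protein (1-based window start)."""

    protein_id: str
    start: int
    peptide: str
    similarity: float


# ---------------------------------------------------------------------------
# repertoire / aaf / proteome readers
# ---------------------------------------------------------------------------

def read_repertoire(path: str | Path, format: str = "list", label: str = "T") -> Repertoire:
    """Read a repertoire from a plain list, FASTA, or sequence/count TSV.

    Duplicate sequences are collapsed with summed occurrences.  Mixed
    peptide lengths, non-standard residues, out-of-range lengths, and empty
    files all raise :class:`FormatError`.
    """
    path = Path(path)
    if format == "list":
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        return Repertoire.from_sequences([ln for ln in lines if ln], label=label)
    if format == "fasta":
        seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        return Repertoire.from_sequences(seqs, label=label)
    if format == "counts":
        seqs, counts = [], []
        for ln in path.read_text().splitlines():
            ln = ln.strip()
            if not ln:
                continue
            parts = ln.split("\t")
            if len(parts) != 2:
                raise FormatError(f"counts line needs 2 columns: {ln!r}")
            seqs.append(parts[0])
            try:
                counts.append(int(parts[1]))
            except ValueError as exc:
                raise FormatError(f"bad count in line {ln!r}") from exc
        return Repertoire.from_sequences(seqs, label=label, counts=counts)
    raise FormatError(f"unknown repertoire format {format!r}")


def write_repertoire(rep: Repertoire, path: str | Path, format: str = "list") -> None:
    path = Path(path)
    if format == "list":
        path.write_text("".join(f"{s}\n" for s in rep.sequences))
    elif format == "counts":
        path.write_text(
            "".join(f"{s}\t{p.occurrences}\n" for s, p in rep.peptides.items())
        )
    else:
        raise FormatError(f"unknown repertoire format {format!r}")


def read_aaf(path: str | Path) -> AAFTable:
    """Read a residue -> percentage TSV into a validated :class:`AAFTable`."""
    freqs: dict[str, float] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise FormatError(f"aaf line needs 2 columns: {ln!r}")
        aa, pct = parts[0].strip().upper(), float(parts[1])
        if aa in freqs:
            raise FormatError(f"duplicate residue {aa} in aaf table")
        freqs[aa] = pct
    return AAFTable(freqs)


def write_aaf(aaf: AAFTable, path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{aa}\t{aaf.frequencies[aa]:.6f}\n" for aa in AMINO_ACIDS)
    )


def read_proteome(path: str | Path) -> list[ProteinRecord]:
    """Parse a proteome FASTA with ``>GeneID|TranscriptID|Symbol|ProteinID``
    headers.

    Whitespace around the pipes is stripped.  Records whose sequence
    contains non-standard residues (B, J, O, U, X, Z, ...) are skipped with
    a logged warning, as real proteome exports routinely contain X runs.
    Headers with a field count other than 4 and duplicated protein ids are
    hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = [f.strip() for f in rec.description.split("|")]
        if len(fields) != 4:
            raise FormatError(
                f"proteome header must have 4 pipe-delimited fields, got "
                f"{len(fields)}: {rec.description!r}"
            )
        seq = str(rec.seq).upper()
        bad = set(seq) - _AA_SET
        if bad:
            logger.warning(
                "skipping %s: non-standard residue(s) %s", fields[3], sorted(bad)
            )
            continue
        record = ProteinRecord(*fields, sequence=seq)
        if record.protein_id in seen:
            raise FormatError(f"duplicate protein id {record.protein_id}")
        seen.add(record.protein_id)
        records.append(record)
    if not records:
        raise FormatError(f"no usable proteome records in {path}")
    return records


def write_proteome(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.gene_id}|{r.transcript_id}|{r.gene_symbol}|{r.protein_id}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# hit / profile / score / distribution tables
# ---------------------------------------------------------------------------

HIT_COLUMNS = [
    "protein_id",
    "start",
    "similarity",
    "peptide",
    "occurrences",
    "cluster_size",
    "n_proteins",
]


def write_hits(hits: Sequence[Hit], peptide_meta: Repertoire, path: str | Path) -> None:
    """Write a hit table with per-peptide metadata, sorted by protein then
    position.  Similarity is printed with 4 decimals (stable round-trip)."""
    rows = []
    for h in sorted(hits, key=lambda h: (h.protein_id, h.start, h.peptide)):
        if h.peptide not in peptide_meta:
            raise FormatError(f"hit references unknown peptide {h.peptide}")
        p = peptide_meta.peptides[h.peptide]
        rows.append(
            (
                h.protein_id,
                h.start,
                f"{h.similarity:.4f}",
                h.peptide,
                p.occurrences,
                p.cluster_size if p.cluster_size is not None else 0,
                p.n_proteins if p.n_proteins is not None else 0,
            )
        )
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "peptide": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"hit table missing columns {sorted(missing)}")
    return df


def write_profiles(profiles: Mapping[str, Sequence[float]], path: str | Path) -> None:
    """Write per-residue signal profiles as (protein_id, position, aah) rows;
    positions are 1-based."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\taah\n")
        for pid in profiles:
            for pos, v in enumerate(profiles[pid], start=1):
                fh.write(f"{pid}\t{pos}\t{v:g}\n")


def read_profiles(path: str | Path) -> dict[str, list[float]]:
    import numpy as np

    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    out: dict[str, list[float]] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("position")
        if list(grp["position"]) != list(range(1, len(grp) + 1)):
            raise FormatError(f"profile for {pid} has gaps in positions")
        out[pid] = [float(v) for v in grp["aah"]]
    return out


def write_scores(
    scores: Mapping[str, "object"],
    gene_symbols: Mapping[str, str],
    path: str | Path,
) -> None:
    """Write the m-/z-score table sorted by m-score descending (ties by
    protein id).  ``scores`` maps protein_id -> object with ``m_score`` and
    ``z_score`` attributes; sentinel -inf z-scores are printed as ``-inf``."""
    rows = sorted(
        (
            (pid, gene_symbols.get(pid, ""), s.m_score, s.z_score)
            for pid, s in scores.items()
        ),
        key=lambda r: (-r[2], r[0]),
    )
    with open(path, "w") as fh:
        fh.write("protein_id\tgene_symbol\tm_score\tz_score\n")
        for pid, sym, m, z in rows:
            fh.write(f"{pid}\t{sym}\t{m:.6f}\t{z:.6f}\n")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_symbol": str})


def write_distribution(
    histogram: Sequence[tuple[float, float, int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("bin_low\tbin_high\tcount\n")
        for low, high, count in histogram:
            fh.write(f"{low:g}\t{high:g}\t{count}\n")


# ---------------------------------------------------------------------------
# annotations: GMT + OBO
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT file into ``term_id -> (description, gene set)``."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.rstrip("\n")
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"GMT line needs >= 3 fields: {ln!r}")
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in terms:
            raise FormatError(f"duplicate GMT term {term}")
        terms[term] = (desc, frozenset(genes))
    if not terms:
        raise FormatError(f"no terms in GMT file {path}")
    return terms


def read_obo(path: str | Path) -> dict[str, frozenset[str]]:
    """Read an OBO ontology and return the ``is_a`` parent map
    ``term -> set of direct parents``, verifying acyclicity."""
    graph = obonet.read_obo(str(path))
    parents: dict[str, set[str]] = {}
    dag = nx.DiGraph()
    for child, parent, key in graph.edges(keys=True):
        if key != "is_a":
            continue
        parents.setdefault(child, set()).add(parent)
        dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise FormatError("OBO is_a graph contains a cycle")
    return {t: frozenset(ps) for t, ps in parents.items()}


def ancestors(parent_map: Mapping[str, frozenset[str]], term: str) -> frozenset[str]:
    """All is_a ancestors of ``term`` under ``parent_map`` (term excluded)."""
    out: set[str] = set()
    stack = list(parent_map.get(term, ()))
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(parent_map.get(t, ()))
    return frozenset(out)
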