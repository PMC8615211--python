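"""Reading and writing the formats the pipeline touches.

Plain and gapped (aligned) FASTA for protein sequences, Newick with branch
lengths and integer bootstrap labels for trees, and the tab-separated
classification report. Sequence identifiers are the pre-whitespace header
token; the remainder of the header is kept as a description but never used
downstream.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

from Bio import SeqIO

from ._tree import Tree

GAP = "-"
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated everywhere: it never matches a catalytic residue, counts
#: as a mismatch in distances, and carries zero hydropathy.
VALID_RESIDUES = AMINO_ACIDS | {"X"}


@dataclass(frozen=True)
class ProteinRecord:
    """One ungapped protein sequence with optional species metadata."""

    id: str
    sequence: str
    species: Optional[str] = None
    lineage: Optional[str] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"record '{self.id}': empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"record '{self.id}': invalid residue(s) {sorted(bad)!r} "
                "(20 standard amino acids + X allowed, no gaps)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignedSet:
    """An ordered multiple alignment; rows are (id, gapped sequence)."""

    records: list[tuple[str, str]]
    alignment_length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            two = sorted(lengths)[:2]
            raise ValueError(
                f"ragged alignment: rows of length {two[0]} and {two[1]}"
            )
        ids = [i for i, _ in self.records]
        if len(ids) != len(set(ids)):
            seen = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate id in alignment: '{dup}'")
        self.alignment_length = lengths.pop()

    def ids(self) -> list[str]:
        return [i for i, _ in self.records]

    def row(self, rec_id: str) -> str:
        for i, s in self.records:
            if i == rec_id:
                return s
        raise KeyError(f"id '{rec_id}' not in alignment")

    def ungapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace(GAP, "")

    def to_records(self) -> list[ProteinRecord]:
        return [ProteinRecord(i, s.replace(GAP, "")) for i, s in self.records]


def _parse_fasta(path: str, allow_gaps: bool) -> list[tuple[str, str, str]]:
    entries = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path, "fasta"):
        rec_id = rec.id
        if rec_id in seen:
            raise ValueError(f"duplicate id in '{path}': '{rec_id}'")
        seen.add(rec_id)
        seq = str(rec.seq).upper()
        allowed = VALID_RESIDUES | ({GAP} if allow_gaps else set())
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record '{rec_id}' in '{path}': invalid character(s) {sorted(bad)!r}"
            )
        entries.append((rec_id, seq, rec.description))
    if not entries:
        raise ValueError(f"no FASTA records found in '{path}'")
    return entries


def read_fasta(path: str) -> list[ProteinRecord]:
    """Read ungapped protein FASTA into a list of :class:`ProteinRecord`."""
    return [
        ProteinRecord(i, s, description=d) for i, s, d in _parse_fasta(path, False)
    ]


def read_aligned_fasta(path: str) -> AlignedSet:
    """Read gapped FASTA into an :class:`AlignedSet` (gap character '-')."""
    return AlignedSet([(i, s) for i, s, _ in _parse_fasta(path, True)])


def write_fasta(records, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_aligned_fasta(aligned: AlignedSet, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, row in aligned.records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def write_newick(tree: Tree, path: str) -> None:
    """Write Newick with 6-decimal branch lengths and integer support labels."""
    if tree.n_leaves() < 2:
        raise ValueError("tree must have at least 2 leaves")
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_species_map(path: str) -> dict[str, tuple[str, Optional[str]]]:
    """TSV with columns id, species, lineage (header optional)."""
    out: dict[str, tuple[str, Optional[str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "id":
                continue
            rec_id = parts[0]
            species = parts[1] if len(parts) > 1 else ""
            lineage = parts[2] if len(parts) > 2 and parts[2] else None
            out[rec_id] = (species, lineage)
    return out


REPORT_COLUMNS = [
    "id",
    "species",
    "lineage",
    "class",
    "subclass_flags",
    "pts1_tripeptide",
    "tm_spans",
    "basic_cluster",
    "nterm_extension_len",
    "organellar_score",
    "catalytic_ok",
    "atypical_flags",
    "evidence",
]


def write_report(classifications, path: str) -> None:
    """Write the per-sequence classification report as deterministic TSV.

    Flag sets are joined by ';' in sorted order and floats use fixed
    precision, so identical inputs yield byte-identical files.
    """
    if not classifications:
        raise ValueError("cannot write a report for an empty classification list")
    rows = []
    for c in classifications:
        sig = c.signals
        rec = sig.record
        atyp = []
        if sig.atypical.length_atypical:
            atyp.append("length_atypical")
        if sig.atypical.dual_catalytic_core:
            atyp.append("dual_catalytic_core")
        rows.append(
            [
                c.id,
                rec.species or "",
                rec.lineage or "",
                c.primary_class,
                ";".join(sorted(c.subclass_flags)),
                sig.pts1.tripeptide,
                ";".join(f"{s.start}-{s.end}" for s in sig.tm_spans),
                sig.mpts.cluster_seq,
                str(sig.nterm.length),
                f"{sig.nterm.organellar_score:.4f}",
                "yes" if sig.catalytic.ok else "no",
                ";".join(atyp),
                ";".join(c.evidence),
            ]
        )
    with open(path, "w", newline="") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def ensure_parent_dir(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    os.makedirs(parent, exist_ok=True)
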