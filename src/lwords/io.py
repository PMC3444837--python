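"""Sequence containers and file I/O.

Reads multi-record DNA FASTA into :class:`SequenceSet` and writes the
pipeline's tabular and tree outputs: frequency/occurrence tables as TSV,
distance matrices in square PHYLIP format, trees as Newick, and MDS
coordinates as TSV.

The record order of the input FASTA is preserved everywhere downstream: it
defines the row order of the occurrence, frequency and distance matrices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .errors import FastaError, LwordsError, TreeError

#: IUPAC one-letter DNA codes accepted on ingest (uppercase).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_NEWICK_UNSAFE = re.compile(r"[\s()\[\]':;,]")


@dataclass(frozen=True)
class SequenceRecord:
    """One named DNA sequence.

    Parameters
    ----------
    id : str
        Short unique label: the first whitespace-delimited token of the
        FASTA header line.
    description : str
        Remainder of the header line (may be empty).
    residues : str
        Upper-case sequence over the IUPAC DNA alphabet (ACGT plus
        ambiguity codes and N).
    """

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence record with empty id")
        if not self.residues:
            raise FastaError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise FastaError(
                f"record {self.id!r}: non-IUPAC character(s) "
                f"{', '.join(sorted(map(repr, bad)))}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceSet:
    """Ordered collection of uniquely named sequences."""

    records: tuple[SequenceRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise FastaError("a SequenceSet needs at least one record")
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise FastaError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def lengths(self) -> list[int]:
        return [len(r) for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a DNA FASTA file into a :class:`SequenceSet`.

    Residues are upper-cased, line breaks within a record are concatenated,
    and the first whitespace-delimited header token becomes the record id.

    Raises
    ------
    FastaError
        If the file is empty, does not start with ``>``, contains an empty
        record, a non-IUPAC character, or a duplicate id.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
    if head == "":
        raise FastaError(f"{path}: empty file")
    if head != ">":
        raise FastaError(f"{path}: not FASTA (first character is not '>')")

    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    description=rec.description[len(rec.id):].strip(),
                    residues=str(rec.seq).upper(),
                )
            )
        except FastaError as exc:
            raise FastaError(f"{path}, record #{i}: {exc}") from None
    try:
        return SequenceSet(tuple(records))
    except FastaError as exc:
        raise FastaError(f"{path}: {exc}") from None


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    """Write a :class:`SequenceSet` as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for rec in seqs:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def write_phylip_matrix(dm, path: str | Path, strict: bool = False) -> None:
    """Write a distance matrix in square PHYLIP format.

    By default labels are written in the "relaxed" dialect (full id followed
    by a single space), because modern accession ids routinely exceed the
    classic 10-character field. ``strict=True`` selects the classic dialect
    (labels padded/truncated to exactly 10 characters).

    Distances are printed with 6 significant digits.
    """
    labels = list(dm.ids)
    data = dm.data
    with open(path, "w") as fh:
        fh.write(f"{len(labels)}\n")
        for i, label in enumerate(labels):
            name = f"{label[:10]:<10}" if strict else f"{label} "
            row = " ".join(f"{x:.6g}" for x in data[i])
            fh.write(name + row + "\n")


def read_phylip_matrix(path: str | Path):
    """Read a square PHYLIP distance matrix written by this package."""
    from skbio import DistanceMatrix

    with open(path) as fh:
        n = int(fh.readline().split()[0])
        labels, rows = [], []
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(rows) != n:
        raise LwordsError(f"{path}: expected {n} matrix rows, found {len(rows)}")
    return DistanceMatrix(rows, ids=labels)


def _quote_newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree, path: str | Path) -> None:
    """Serialize a tree (skbio ``TreeNode``) as Newick.

    Branch lengths are written with 6 significant digits; labels containing
    Newick metacharacters (whitespace, parentheses, quotes, ...) are single-
    quoted with internal quotes doubled.

    Raises
    ------
    TreeError
        If the tree has fewer than 2 leaves or any unlabeled leaf.
    """
    Path(path).write_text(newick_string(tree) + "\n")


def newick_string(tree) -> str:
    """Newick serialization of an skbio ``TreeNode``, as a string."""
    tips = list(tree.tips())
    if len(tips) < 2:
        raise TreeError("tree must have at least 2 leaves")
    if any(t.name is None or t.name == "" for t in tips):
        raise TreeError("every leaf must be labeled")

    def render(node) -> str:
        if node.is_tip():
            s = _quote_newick_label(node.name)
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                s += _quote_newick_label(node.name)
        if node.length is not None:
            s += f":{node.length:.6g}"
        return s

    return render(tree) + ";"


def write_table_tsv(table: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a labeled matrix (occurrence/frequency profile) as TSV."""
    table.to_csv(path, sep="\t", index_label=index_label)


def write_mds_tsv(embedding, path: str | Path) -> None:
    """Write MDS coordinates as TSV with columns id, dim1..dimk."""
    embedding.coordinates.to_csv(path, sep="\t", index_label="id")
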