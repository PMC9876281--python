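"""Domain types and readers/writers for the file formats the pipeline touches.

Sequences are plain protein strings over the 20-letter alphabet, with ``-``
for alignment gaps and ``X`` for database ambiguity codes. Structures are
read from fixed-column PDB ATOM records (heavy atoms, first model,
primary alternate locations only), the convention under which
peptide-contact distances on crystal structures are reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_LEGAL = set(AMINO_ACIDS) | {GAP, UNKNOWN}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _normalize_residues(raw: str, record_id: str) -> str:
    """Upper-case, map the '.' gap dialect to '-', and validate the alphabet."""
    cleaned = raw.upper().replace(".", GAP)
    for pos, ch in enumerate(cleaned):
        if ch not in _LEGAL:
            raise FormatError(
                f"illegal character {ch!r} at position {pos + 1} "
                f"in sequence {record_id!r}"
            )
    return cleaned


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence, optionally gapped.

    Parameters
    ----------
    id:
        Non-empty identifier, unique within any collection.
    residues:
        Residue string over ``ACDEFGHIKLMNPQRSTVWY`` plus ``-`` and ``X``.
    description:
        Free text carried after the id on the FASTA header line.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        object.__setattr__(
            self, "residues", _normalize_residues(self.residues, self.id)
        )

    def __len__(self) -> int:
        return len(self.residues)

    def degapped(self) -> "ProteinSequence":
        """The same sequence with every gap character removed."""
        return ProteinSequence(self.id, self.residues.replace(GAP, ""), self.description)


@dataclass
class Alignment:
    """Equal-length rows of gapped sequences, with optional clade labels."""

    rows: list[ProteinSequence]
    clade_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs at least one row")
        width = len(self.rows[0])
        for row in self.rows:
            if len(row) != width:
                raise ValueError(
                    f"ragged alignment: row {row.id!r} has length {len(row)}, "
                    f"expected {width}"
                )
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate row ids: {dupes}")
        unknown = sorted(set(self.clade_labels) - set(ids))
        if unknown:
            raise ValueError(f"clade labels for unknown ids: {unknown}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, seq_id: str) -> ProteinSequence:
        for r in self.rows:
            if r.id == seq_id:
                return r
        raise KeyError(f"no row with id {seq_id!r}")

    def column(self, col: int) -> str:
        if not 0 <= col < self.n_columns:
            raise IndexError(f"column {col} out of range 0..{self.n_columns - 1}")
        return "".join(r.residues[col] for r in self.rows)


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom from a PDB ATOM record."""

    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float


def read_fasta(stream: TextIO | str) -> list[ProteinSequence]:
    """Parse a multi-record FASTA stream into :class:`ProteinSequence` objects.

    Raises :class:`FormatError` on an empty stream, a duplicate id, or a
    character outside the accepted alphabet.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinSequence(rec.id, str(rec.seq), desc))
    if not records:
        raise FormatError("no FASTA records found")
    return records


def write_fasta(
    records: Iterable[ProteinSequence], stream: TextIO, wrap: int = 60
) -> None:
    """Write records as wrapped FASTA; inverse of :func:`read_fasta`."""
    records = list(records)
    if not records:
        raise ValueError("nothing to write")
    for rec in records:
        header = f">{rec.id} {rec.description}".rstrip()
        stream.write(header + "\n")
        for start in range(0, len(rec.residues), wrap):
            stream.write(rec.residues[start:start + wrap] + "\n")


def read_clade_labels(stream: TextIO | str) -> dict[str, str]:
    """Read a two-column TSV (sequence id, clade name) into a dict."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    labels: dict[str, str] = {}
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise FormatError(f"line {lineno}: expected 'id<TAB>clade', got {line!r}")
        if parts[0] in labels:
            raise FormatError(f"line {lineno}: duplicate id {parts[0]!r}")
        labels[parts[0]] = parts[1]
    return labels


def write_clade_labels(labels: Mapping[str, str], stream: TextIO) -> None:
    for seq_id, clade in labels.items():
        stream.write(f"{seq_id}\t{clade}\n")


_HYDROGEN_ELEMENTS = {"H", "D"}


def _infer_element(atom_name: str) -> str:
    """Element from the atom-name field when columns 77-78 are blank.

    PDB convention right-justifies one-letter elements in the atom-name
    field: ' CA ' is a carbon alpha, 'CA  ' a calcium. Digits in the leading
    position (e.g. '1HB1') mark hydrogens.
    """
    name = atom_name.strip()
    if not name:
        return ""
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if atom_name[:1].strip() and len(atom_name) >= 2 and not atom_name[0].isdigit():
        # name starts in column 13: two-letter element (CA=calcium, FE, ...)
        return atom_name[:2].strip().upper()
    return stripped[0].upper()


def read_pdb_atoms(stream: TextIO | str) -> list[AtomRecord]:
    """Read ATOM records of the first model from fixed-column PDB text.

    HETATM records, hydrogens/deuteriums, and alternate locations other than
    blank or 'A' are dropped. Raises :class:`FormatError` if no ATOM records
    survive, or on a malformed coordinate field (with the line number).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    atoms: list[AtomRecord] = []
    model_seen = 0
    for lineno, line in enumerate(stream, 1):
        tag = line[:6]
        if tag.startswith("MODEL"):
            model_seen += 1
            if model_seen > 1:
                break
        elif tag.startswith("ENDMDL"):
            break
        if tag != "ATOM  ":
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        atom_name = line[12:16]
        element = line[76:78].strip().upper() if len(line) >= 78 else ""
        if not element:
            element = _infer_element(atom_name)
        if element in _HYDROGEN_ELEMENTS:
            continue
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            resnum = int(line[22:26])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: malformed ATOM field ({exc})") from exc
        atoms.append(
            AtomRecord(
                chain=line[21],
                residue_number=resnum,
                residue_name=line[17:20].strip(),
                atom_name=atom_name.strip(),
                element=element,
                x=x,
                y=y,
                z=z,
            )
        )
    if not atoms:
        raise FormatError("no ATOM records found")
    return atoms
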