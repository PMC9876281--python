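"""Structure-based census of receptor residues contacting a bound peptide.

A receptor residue is a contact when any of its heavy atoms lies within a
fixed cutoff (default 4.0 Å, inclusive) of any heavy atom of the peptide
chain — the reproducible convention for crystal structures solved without
hydrogens. Contacts can then be projected onto alignment columns to read
off their conservation class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rbh3kit.conservation import ConsensusProfile
from rbh3kit.formats import AtomRecord

DEFAULT_CUTOFF = 4.0


@dataclass
class StructureModel:
    """Heavy atoms grouped by chain, residues ordered by residue number."""

    atoms: list[AtomRecord]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("structure model has no atoms")

    @property
    def chains(self) -> list[str]:
        return sorted({a.chain for a in self.atoms})

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        atoms = [a for a in self.atoms if a.chain == chain]
        if not atoms:
            raise ValueError(
                f"chain {chain!r} not in structure; available: {self.chains}"
            )
        return atoms


@dataclass
class ContactCensus:
    receptor_chain: str
    peptide_chain: str
    cutoff: float
    contacts: list[tuple[int, str]]  # (residue_number, residue_name)
    min_distances: dict[int, float]

    @property
    def count(self) -> int:
        return len(self.contacts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_number": [r for r, _ in self.contacts],
                "residue_name": [n for _, n in self.contacts],
                "min_distance": [
                    round(self.min_distances[r], 3) for r, _ in self.contacts
                ],
            }
        )


def contact_census(
    model: StructureModel,
    receptor_chain: str,
    peptide_chain: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactCensus:
    """Receptor residues with any heavy atom within ``cutoff`` Å (inclusive)
    of any peptide heavy atom, in residue-number order."""
    if receptor_chain == peptide_chain:
        raise ValueError("receptor and peptide chains must differ")
    rec = model.chain_atoms(receptor_chain)
    pep = model.chain_atoms(peptide_chain)
    pep_xyz = np.array([[a.x, a.y, a.z] for a in pep])

    by_residue: dict[int, tuple[str, list[AtomRecord]]] = {}
    for atom in rec:
        by_residue.setdefault(atom.residue_number, (atom.residue_name, []))[1].append(atom)

    contacts = []
    min_d: dict[int, float] = {}
    for resnum in sorted(by_residue):
        resname, atoms = by_residue[resnum]
        xyz = np.array([[a.x, a.y, a.z] for a in atoms])
        diffs = xyz[:, None, :] - pep_xyz[None, :, :]
        dmin = float(np.sqrt((diffs ** 2).sum(axis=2)).min())
        if dmin <= cutoff:
            contacts.append((resnum, resname))
            min_d[resnum] = dmin
    return ContactCensus(receptor_chain, peptide_chain, cutoff, contacts, min_d)


def census_conservation_overlay(
    census: ContactCensus,
    profile: ConsensusProfile,
    seq_id: str,
    residue_offset: int = 0,
) -> pd.DataFrame:
    """Annotate each contact residue with the conservation class of its
    alignment column.

    ``residue_offset`` reconciles structure numbering with the mature
    sequence in the alignment (structure residue number = alignment-derived
    residue number + offset). Contacts falling outside the aligned region
    are reported as ``unmapped``.
    """
    pos_map = profile.position_map(seq_id)  # column -> residue number (0 at gaps)
    residue_to_column = {
        num: col for col, num in enumerate(pos_map) if num > 0
    }
    rows = []
    for resnum, resname in census.contacts:
        seq_number = resnum - residue_offset
        col = residue_to_column.get(seq_number)
        if col is None:
            rows.append((resnum, resname, None, "unmapped"))
        else:
            rows.append(
                (resnum, resname, col, profile.classes[col].value)
            )
    return pd.DataFrame(
        rows, columns=["residue_number", "residue_name", "column", "conservation"]
    )
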