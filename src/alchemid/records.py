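"""Molecule container shared by every stage of the generator.

A :class:`MoleculeRecord` wraps an RDKit molecule together with a name and an
optional free-form metadata dict.  The canonical form (isomeric canonical
SMILES) is the identity used everywhere for comparison and deduplication:
it is invariant under atom reordering and survives an SDF round trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

from rdkit import Chem


@dataclass
class MoleculeRecord:
    """A named chemical graph with stereo annotations and optional coordinates."""

    mol: Chem.Mol
    name: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_smiles(cls, smiles: str, name: str = "") -> "MoleculeRecord":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smiles!r}")
        return cls(mol=mol, name=name or smiles)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, name: Optional[str] = None) -> "MoleculeRecord":
        if name is None:
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        return cls(mol=Chem.Mol(mol), name=name)

    @property
    def canonical_form(self) -> str:
        """Isomeric canonical SMILES; the record's identity."""
        return Chem.MolToSmiles(self.mol)

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def has_coordinates(self) -> bool:
        return self.mol.GetNumConformers() > 0

    def is_single_component(self) -> bool:
        return len(Chem.GetMolFrags(self.mol)) == 1

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeRecord):
            return NotImplemented
        return self.canonical_form == other.canonical_form

    def __hash__(self) -> int:
        return hash(self.canonical_form)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"MoleculeRecord({self.name!r}, {self.canonical_form!r})"
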