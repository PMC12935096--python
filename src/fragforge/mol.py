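"""Molecular data model and file I/O.

The shared currency of the pipeline is :class:`Molecule`: an ordered list of
heavy atoms with 3D coordinates, an optional bond list, and an optional
canonical isomeric SMILES identity. Ligands and fragments are backed by an
RDKit mol (bonds, aromaticity, identity all come from RDKit perception);
receptors parsed from PDB files are bond-less atom clouds read with gemmi —
downstream geometry (contact filters, voxel grids) only needs elements and
coordinates.

Hydrogens are excluded from all stored atom lists; ligands keep implicit
hydrogen accounting on their RDKit mol so molecular weights and valences stay
correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .elements import vdw_radius

BondOrder = Literal[1, 2, 3, "aromatic"]

_RDKIT_ORDER: dict = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: "aromatic",
}


class FormatError(ValueError):
    """A molecular file could not be parsed."""


class InputError(ValueError):
    """Parsed input violates a precondition (e.g. missing 3D coordinates)."""


@dataclass(frozen=True)
class Atom:
    element: str
    coords: np.ndarray  # (3,) Angstrom
    is_aromatic: bool = False
    formal_charge: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=np.float64)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise InputError(f"atom coordinates must be a finite 3-vector, got {self.coords!r}")
        object.__setattr__(self, "coords", c)

    @property
    def vdw_radius(self) -> float:
        return vdw_radius(self.element)


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: BondOrder
    in_ring: bool = False


@dataclass
class Molecule:
    """Heavy-atom molecule; receptors may have an empty bond list.

    ``identity`` is the canonical isomeric SMILES, or ``None`` for species
    that have no molecular-graph representation (receptor atom clouds,
    unparseable polymers).
    """

    atoms: list[Atom]
    bonds: list[Bond] = field(default_factory=list)
    identity: str | None = None
    rdkit_mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise InputError(f"bond ({b.i},{b.j}) out of range for {n} atoms")

    @property
    def n_heavy(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_heavy, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_rdkit(cls, mol: Chem.Mol, *, require_coords: bool = True) -> "Molecule":
        """Build from an RDKit mol; explicit hydrogens are stripped first."""
        mol = Chem.RemoveHs(mol)
        if mol.GetNumConformers() == 0:
            if require_coords:
                raise InputError("molecule has no 3D coordinates")
            xyz = np.zeros((mol.GetNumAtoms(), 3))
        else:
            xyz = mol.GetConformer().GetPositions()
        atoms = [
            Atom(
                element=a.GetSymbol(),
                coords=xyz[a.GetIdx()],
                is_aromatic=a.GetIsAromatic(),
                formal_charge=a.GetFormalCharge(),
            )
            for a in mol.GetAtoms()
        ]
        bonds = [
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=_RDKIT_ORDER.get(b.GetBondType(), 1),
                in_ring=b.IsInRing(),
            )
            for b in mol.GetBonds()
        ]
        return cls(atoms=atoms, bonds=bonds, identity=canonical_smiles(mol), rdkit_mol=mol)

    @classmethod
    def from_atom_cloud(cls, elements: Sequence[str], coords: np.ndarray) -> "Molecule":
        coords = np.asarray(coords, dtype=np.float64)
        atoms = [Atom(element=e, coords=c) for e, c in zip(elements, coords, strict=True)]
        return cls(atoms=atoms)


@dataclass
class ComplexEntry:
    """One receptor with its bound ligand(s), tagged with a protein family."""

    entry_id: str
    receptor: Molecule
    ligands: list[Molecule]
    family_id: str

    def __post_init__(self) -> None:
        if not self.ligands:
            raise InputError(f"entry {self.entry_id}: at least one ligand required")
        if not self.family_id:
            raise InputError(f"entry {self.entry_id}: family_id must be non-empty")


# -- SMILES helpers --------------------------------------------------------


def canonical_smiles(mol: Chem.Mol) -> str | None:
    """Canonical isomeric SMILES, stable under atom reordering."""
    try:
        return Chem.MolToSmiles(Chem.RemoveHs(mol))
    except Exception:
        return None


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InputError(f"invalid SMILES: {smiles!r}")
    return mol


def embed_molecule(smiles: str, seed: int = 0) -> Chem.Mol:
    """Parse SMILES and generate one 3D conformer by distance geometry."""
    mol = mol_from_smiles(smiles)
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    if AllChem.EmbedMolecule(molh, params) != 0:
        # fall back to unseeded coordinates-from-scratch for pathological input
        params.useRandomCoords = True
        if AllChem.EmbedMolecule(molh, params) != 0:
            raise InputError(f"could not embed 3D coordinates for {smiles!r}")
    return Chem.RemoveHs(molh)


# -- file I/O --------------------------------------------------------------


def read_receptor_pdb(path: str | Path) -> Molecule:
    """All heavy atoms of a PDB file (ATOM and HETATM records) as an atom cloud."""
    try:
        structure = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError on parse failure
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.element.is_hydrogen:
                        continue
                    elements.append(atom.element.name)
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
        break  # first model only
    if not elements:
        raise InputError(f"PDB file {path} contains no heavy atoms")
    return Molecule.from_atom_cloud(elements, np.asarray(coords))


def read_ligand(path: str | Path) -> Molecule:
    """Read an SDF/MOL ligand; requires explicit 3D coordinates."""
    mol = Chem.MolFromMolFile(str(path), removeHs=True)
    if mol is None:
        raise FormatError(f"cannot parse SDF/MOL file {path}")
    if mol.GetNumConformers() == 0 or not mol.GetConformer().Is3D():
        raise InputError(f"ligand in {path} has no 3D coordinates")
    return Molecule.from_rdkit(mol)


def read_complex(
    receptor_path: str | Path,
    ligand_path: str | Path,
    *,
    entry_id: str | None = None,
    family_id: str | None = None,
) -> ComplexEntry:
    """Assemble a :class:`ComplexEntry` from a receptor PDB and a ligand SDF."""
    receptor = read_receptor_pdb(receptor_path)
    ligand = read_ligand(ligand_path)
    eid = entry_id or Path(receptor_path).stem
    return ComplexEntry(
        entry_id=eid,
        receptor=receptor,
        ligands=[ligand],
        family_id=family_id or eid,
    )


def write_ligand_sdf(molecule: Molecule, path: str | Path) -> None:
    if molecule.rdkit_mol is None:
        raise InputError("molecule has no graph representation to write as SDF")
    writer = Chem.SDWriter(str(path))
    writer.write(molecule.rdkit_mol)
    writer.close()


def write_receptor_pdb(molecule: Molecule, path: str | Path) -> None:
    """Write an atom cloud as single-chain HETATM-free PDB ATOM records."""
    structure = gemmi.Structure()
    structure.name = "receptor"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for idx, atom in enumerate(molecule.atoms):
        residue = gemmi.Residue()
        residue.name = "UNK"
        residue.seqid = gemmi.SeqId(idx + 1, " ")
        at = gemmi.Atom()
        at.name = f"{atom.element}{idx % 99 + 1}"
        at.element = gemmi.Element(atom.element)
        at.pos = gemmi.Position(*atom.coords)
        residue.add_atom(at)
        chain.add_residue(residue)
    model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))


def read_smiles_list(path: str | Path) -> list[tuple[str, str | None]]:
    """One SMILES per line, optional tab-separated name; blank lines skipped."""
    out: list[tuple[str, str | None]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        out.append((parts[0], parts[1] if len(parts) > 1 else None))
    return out


def min_heavy_atom_distance(a: Molecule | np.ndarray, b: Molecule | np.ndarray) -> float:
    """Minimum pairwise heavy-atom distance between two molecules, Angstrom."""
    xa = a.coords if isinstance(a, Molecule) else np.asarray(a)
    xb = b.coords if isinstance(b, Molecule) else np.asarray(b)
    if len(xa) == 0 or len(xb) == 0:
        return float("inf")
    d2 = ((xa[:, None, :] - xb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))
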