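"""Ligand fragmentation, filtering, property classification and fingerprints.

Each acyclic single bond of a bound ligand is cut once, producing a
(trimmed ligand, fragment) pair: the larger connected component keeps the
bound pose and is the *trimmed ligand*; the smaller component is the
*fragment*, which carries a dummy-atom attachment marker at its cut atom.
The trimmed-ligand atom that lost the fragment is the *branching atom* — the
point where a replacement fragment would be grown, and the center of the
voxel grid downstream.

Filters mirror the dataset-construction rules of the fragment-addition
training protocol: fragments heavier than 150 Da are rejected (strict
inequality), fragments with no heavy atom are rejected (a bare hydrogen is
not a fragment), and fragments with no heavy atom within 4.0 Angstrom of any
receptor heavy atom are rejected (inclusive cutoff).

Fragment targets are 2048-bit topological path fingerprints (RDKit
RDKFingerprint, maximum path length 10) computed on the hydrogen-capped
fragment, i.e. with the attachment marker replaced by a hydrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .fixtures import CONTACT_CUTOFF
from .mol import ComplexEntry, InputError, Molecule, min_heavy_atom_distance

#: fingerprint length (bits) and maximum path length of the topological fp
FP_BITS = 2048
FP_MAX_PATH = 10

#: fragment molecular-weight ceiling, Da (strict: > MW_CUTOFF fails)
MW_CUTOFF = 150.0

#: heavy-atom boundary between "small" and "large" fragments
SMALL_MAX_HEAVY = 3


@dataclass(frozen=True)
class PropertyLabel:
    """Physicochemical class of a fragment.

    ``aromatic`` and ``aliphatic`` partition all fragments; ``acidic`` and
    ``basic`` may both be true (such ambivalent fragments are excluded when
    assembling acid- or base-targeted datasets, not here).
    """

    aromatic: bool
    acidic: bool
    basic: bool
    size_class: str  # "small" (<= 3 heavy atoms) or "large" (>= 4)

    @property
    def aliphatic(self) -> bool:
        return not self.aromatic


@dataclass
class FragmentationExample:
    """One (receptor, trimmed ligand, fragment) training example."""

    entry_id: str
    ligand_identity: str | None
    trimmed_ligand: Molecule
    fragment: Molecule  # carries one attachment-point dummy atom
    branch_atom: int  # index into trimmed_ligand.atoms
    connection_coords: np.ndarray  # (3,) position of the branching atom
    fragment_heavy_atoms: int
    fragment_mw: float
    properties: PropertyLabel | None = None
    _fp: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def fragment_identity(self) -> str | None:
        return self.fragment.identity

    def fingerprint(self) -> np.ndarray:
        if self._fp is None:
            self._fp = fragment_fingerprint(self.fragment)
        return self._fp


# -- bond enumeration and cutting ------------------------------------------


def enumerate_cuttable_bonds(ligand: Molecule) -> list[int]:
    """RDKit bond indices of all acyclic single heavy-atom bonds.

    Ordered deterministically by ascending (min, max) atom-index pairs.
    """
    mol = _require_rdkit(ligand)
    found: list[tuple[int, int, int]] = []
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if mol.GetAtomWithIdx(i).GetAtomicNum() <= 1 or mol.GetAtomWithIdx(j).GetAtomicNum() <= 1:
            continue
        found.append((min(i, j), max(i, j), bond.GetIdx()))
    return [idx for _, _, idx in sorted(found)]


def cut_bond(ligand: Molecule, bond: int) -> tuple[Molecule, Molecule, int]:
    """Cut one acyclic single bond; returns (trimmed, fragment, branch_atom).

    The component with more heavy atoms becomes the trimmed ligand. Ties are
    broken by molecular weight (the lighter component is the fragment), then
    by canonical identity (lexicographically smaller is the fragment). The
    fragment keeps a dummy-atom marker at its cut atom; the trimmed ligand
    has its marker removed, and ``branch_atom`` indexes the trimmed-ligand
    atom of the cut bond.
    """
    mol = _require_rdkit(ligand)
    b = mol.GetBondWithIdx(bond)
    if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
        raise InputError(f"bond {bond} is not an acyclic single bond")
    pieces = Chem.FragmentOnBonds(mol, [bond], addDummies=True, dummyLabels=[(0, 0)])
    halves = Chem.GetMolFrags(pieces, asMols=True, sanitizeFrags=True)
    if len(halves) != 2:
        raise InputError(f"cutting bond {bond} did not yield two components")

    def heavy(m: Chem.Mol) -> int:
        return sum(1 for a in m.GetAtoms() if a.GetAtomicNum() > 1)

    a, bmol = halves
    ha, hb = heavy(a), heavy(bmol)
    if ha != hb:
        trimmed_mol, fragment_mol = (a, bmol) if ha > hb else (bmol, a)
    else:
        mwa, mwb = _capped_mw(a), _capped_mw(bmol)
        if mwa != mwb:
            trimmed_mol, fragment_mol = (a, bmol) if mwa > mwb else (bmol, a)
        else:
            ca, cb = Chem.MolToSmiles(a), Chem.MolToSmiles(bmol)
            trimmed_mol, fragment_mol = (a, bmol) if ca > cb else (bmol, a)

    trimmed_mol, branch_atom = _strip_marker(trimmed_mol)
    trimmed = Molecule.from_rdkit(trimmed_mol)
    fragment = Molecule.from_rdkit(fragment_mol)
    return trimmed, fragment, branch_atom


def _strip_marker(mol: Chem.Mol) -> tuple[Chem.Mol, int]:
    """Remove the dummy attachment atom; return (clean mol, ex-neighbor index)."""
    rw = Chem.RWMol(mol)
    dummy = next(a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0)
    neighbor = rw.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
    rw.RemoveAtom(dummy)
    if neighbor > dummy:
        neighbor -= 1
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out, neighbor


def hydrogen_capped(fragment: Molecule | Chem.Mol) -> Chem.Mol:
    """Fragment with its attachment marker replaced by an (implicit) hydrogen."""
    mol = fragment.rdkit_mol if isinstance(fragment, Molecule) else fragment
    if mol is None:
        raise InputError("fragment has no graph representation")
    rw = Chem.RWMol(mol)
    dummies = [a.GetIdx() for a in rw.GetAtoms() if a.GetAtomicNum() == 0]
    for idx in sorted(dummies, reverse=True):
        rw.RemoveAtom(idx)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def _capped_mw(mol: Chem.Mol) -> float:
    return float(Descriptors.MolWt(hydrogen_capped(mol)))


def fragment_heavy_atom_count(fragment: Molecule | Chem.Mol) -> int:
    mol = fragment.rdkit_mol if isinstance(fragment, Molecule) else fragment
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


# -- filters ----------------------------------------------------------------


def passes_filters(
    example: FragmentationExample, receptor: Molecule
) -> tuple[bool, str | None]:
    """Apply the dataset filters in order; returns (passed, failing rule).

    Rules, in order: fragment MW > 150 Da ("mass"); no heavy atoms
    ("no_heavy_atoms"); minimum fragment-receptor heavy-atom distance above
    4.0 Angstrom ("contact").
    """
    if example.fragment_mw > MW_CUTOFF:
        return False, "mass"
    if example.fragment_heavy_atoms < 1:
        return False, "no_heavy_atoms"
    frag_xyz = _fragment_heavy_coords(example.fragment)
    if min_heavy_atom_distance(frag_xyz, receptor) > CONTACT_CUTOFF:
        return False, "contact"
    return True, None


def _fragment_heavy_coords(fragment: Molecule) -> np.ndarray:
    keep = [i for i, a in enumerate(fragment.atoms) if a.element != "*"]
    return fragment.coords[keep]


# -- property classification ------------------------------------------------

_ACID_SMARTS = [
    Chem.MolFromSmarts(s)
    for s in (
        "[CX3](=[OX1])[OX2H1,OX1-]",          # carboxylic acid / carboxylate
        "[c][OX2H1]",                          # aryl alcohol
        "[c][SX2H1]",                          # aryl thiol
        "[#15,#16](=[OX1])(~[#8])[OX2H1]",     # phosphate/phosphonate/sulf(on)ate O-H
        "[#6]1~[#7]~[#7]~[#7]~[#7]1",          # tetrazole
        "[#16](=[OX1])~[#7]",                  # sulfonamide / sulfinamide S(=O)-N
    )
]

# aliphatic N double-bonded to anything but O or N (imines, amidines, ...)
_BASE_IMINE = Chem.MolFromSmarts("[N;A]=[!#7;!#8]")


def _is_aliphatic_amine(atom: Chem.Atom) -> bool:
    """Primary/secondary/tertiary aliphatic amine nitrogen.

    sp3, non-aromatic N whose heavy neighbors are all non-aromatic carbons,
    none of which is a carbonyl/thiocarbonyl/imine carbon (excludes amides and
    anilines; amidines are captured by the imine rule instead).
    """
    if atom.GetAtomicNum() != 7 or atom.GetIsAromatic():
        return False
    if atom.GetHybridization() != Chem.HybridizationType.SP3:
        return False
    for nb in atom.GetNeighbors():
        if nb.GetAtomicNum() != 6 or nb.GetIsAromatic():
            return False
        for bond in nb.GetBonds():
            if bond.GetBondTypeAsDouble() >= 2.0:
                return False
    return True


def classify_property(fragment: Molecule | Chem.Mol) -> PropertyLabel:
    """Aromatic/aliphatic, acidic, basic flags plus the size class.

    Computed on the hydrogen-capped fragment so that protonation at the cut
    site is well defined.
    """
    capped = hydrogen_capped(fragment)
    aromatic = any(a.GetIsAromatic() for a in capped.GetAtoms())
    acidic = any(capped.HasSubstructMatch(p) for p in _ACID_SMARTS)
    basic = any(_is_aliphatic_amine(a) for a in capped.GetAtoms()) or capped.HasSubstructMatch(
        _BASE_IMINE
    )
    n_heavy = capped.GetNumAtoms()
    size_class = "small" if n_heavy <= SMALL_MAX_HEAVY else "large"
    return PropertyLabel(aromatic=aromatic, acidic=acidic, basic=basic, size_class=size_class)


# -- fingerprints ------------------------------------------------------------


def _capped_explicit_h(fragment: Molecule | Chem.Mol) -> Chem.Mol:
    """Attachment marker replaced by an *explicit* hydrogen.

    The explicit cap hydrogen participates in fingerprint paths, so even
    single-heavy-atom fragments (methyl, hydroxyl) set bits.
    """
    mol = fragment.rdkit_mol if isinstance(fragment, Molecule) else fragment
    if mol is None:
        raise InputError("fragment has no graph representation")
    rw = Chem.RWMol(mol)
    for a in rw.GetAtoms():
        if a.GetAtomicNum() == 0:
            a.SetAtomicNum(1)
            a.SetIsotope(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def fragment_fingerprint(fragment: Molecule | Chem.Mol) -> np.ndarray:
    """2048-bit topological path fingerprint (max path 10), uint8 {0,1}.

    Computed on the hydrogen-capped fragment with the cap hydrogen kept
    explicit, so identical fragments give identical bit vectors regardless
    of atom ordering or cut provenance, and every fragment — including
    single-heavy-atom ones — has a nonzero fingerprint.
    """
    capped = _capped_explicit_h(fragment)
    bv = Chem.RDKFingerprint(capped, maxPath=FP_MAX_PATH, fpSize=FP_BITS)
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


# -- whole-complex fragmentation ---------------------------------------------


def fragment_complex(entry: ComplexEntry) -> list[FragmentationExample]:
    """All filtered fragmentation examples of one complex, in a stable order."""
    examples: list[FragmentationExample] = []
    for ligand in entry.ligands:
        if ligand.rdkit_mol is None:
            continue
        for bond in enumerate_cuttable_bonds(ligand):
            trimmed, fragment, branch_atom = cut_bond(ligand, bond)
            example = FragmentationExample(
                entry_id=entry.entry_id,
                ligand_identity=ligand.identity,
                trimmed_ligand=trimmed,
                fragment=fragment,
                branch_atom=branch_atom,
                connection_coords=trimmed.atoms[branch_atom].coords,
                fragment_heavy_atoms=fragment_heavy_atom_count(fragment),
                fragment_mw=_capped_mw(fragment.rdkit_mol),
            )
            example.properties = classify_property(fragment)
            ok, _ = passes_filters(example, entry.receptor)
            if ok:
                examples.append(example)
    return examples


def _require_rdkit(molecule: Molecule) -> Chem.Mol:
    if molecule.rdkit_mol is None:
        raise InputError("operation requires an RDKit-backed molecule")
    return molecule.rdkit_mol
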