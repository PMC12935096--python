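"""Synthetic protein-ligand fixtures.

Real training data for fragment-addition models comes from curated
protein-ligand databases. The fixture generator reproduces the statistical
structure that pipeline assumes without any download: a small ligand with
distance-geometry 3D coordinates, surrounded by a shell of receptor heavy
atoms (C/N/O/S/P) placed 2-6 Angstrom from ligand atoms, with at least one
receptor atom guaranteed within the 4.0 Angstrom contact cutoff that the
dataset filters enforce.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .elements import RECEPTOR_ELEMENTS
from .mol import ComplexEntry, InputError, Molecule, embed_molecule

#: ligand-receptor contact cutoff used throughout the pipeline, Angstrom
CONTACT_CUTOFF = 4.0

# element sampling weights: mostly carbon, as in real binding pockets
_ELEMENT_WEIGHTS = np.array([0.62, 0.16, 0.16, 0.04, 0.02])


def make_fixture(
    seed: int,
    n_receptor_atoms: int = 50,
    ligand_smiles: str = "CCc1ccccc1",
    *,
    entry_id: str | None = None,
    family_id: str = "FAM0",
) -> ComplexEntry:
    """Generate one synthetic complex.

    The ligand is embedded with a seeded distance-geometry conformer. Receptor
    atoms are sampled on shells 2-6 Angstrom around randomly chosen ligand
    atoms, rejecting positions that clash (< 2 Angstrom) with the ligand; the
    first receptor atom is forced within the contact cutoff so that every
    fixture passes the receptor-contact filter by construction.
    """
    if n_receptor_atoms < 1:
        raise InputError("n_receptor_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    ligand = Molecule.from_rdkit(embed_molecule(ligand_smiles, seed=seed))
    lig_xyz = ligand.coords

    coords = np.empty((n_receptor_atoms, 3))
    placed = 0
    while placed < n_receptor_atoms:
        anchor = lig_xyz[rng.integers(len(lig_xyz))]
        # guarantee a contact <= 4.0 A for the first atom
        radius = rng.uniform(2.0, CONTACT_CUTOFF if placed == 0 else 6.0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + radius * direction
        if np.min(np.linalg.norm(lig_xyz - pos, axis=1)) < 2.0:
            continue
        coords[placed] = pos
        placed += 1

    elements = list(rng.choice(RECEPTOR_ELEMENTS, size=n_receptor_atoms, p=_ELEMENT_WEIGHTS))
    receptor = Molecule.from_atom_cloud(elements, coords)
    return ComplexEntry(
        entry_id=entry_id or f"FIX{seed:04d}",
        receptor=receptor,
        ligands=[ligand],
        family_id=family_id,
    )


#: a spread of drug-like small molecules used by the batch generator; each
#: yields at least one cuttable bond and a fragment within the 150 Da cutoff
FIXTURE_SMILES: tuple[str, ...] = (
    "CCc1ccccc1",            # ethylbenzene
    "Cc1ccc(O)cc1",          # p-cresol
    "CCOC(=O)c1ccccc1",      # ethyl benzoate
    "CC(C)Cc1ccccc1",        # isobutylbenzene
    "OCCc1ccncc1",           # pyridine ethanol
    "CNc1ccccc1",            # N-methylaniline
    "CC(=O)Nc1ccccc1",       # acetanilide
    "OC(=O)Cc1ccccc1",       # phenylacetic acid
    "NCCc1ccccc1",           # phenethylamine
    "CSc1ccccc1",            # thioanisole
)


#: ligand panel for the small learnability benchmark: five binding-site
#: classes whose designated cut yields five structurally distinct
#: (trimmed ligand, fragment) pairs. Fragments all have >= 4 heavy atoms,
#: mirroring the large-fragment constraint of receptor-class fine-tuning
#: datasets (which discard fragments with three or fewer heavy atoms).
LEARNABLE_CLASSES: tuple[tuple[str, str], ...] = (
    ("CCCCc1ccccc1", "*CCCC"),             # butyl off benzene
    ("OC(=O)CCc1ccccc1", "*CC(=O)O"),      # acetic-acid arm off toluene
    ("CS(=O)(=O)c1ccncc1", "*S(C)(=O)=O"),  # methylsulfonyl off pyridine
    ("CN(C)CC1CCCCC1", "*CN(C)C"),         # dimethylaminomethyl off cyclohexane
    ("OCCOC1CCCC1", "*OCCO"),              # glycol ether off cyclopentane
)

#: coordinate jitter between replicate structures of one binding site, Angstrom
REPLICA_JITTER = 0.4


def make_learnable_set(
    seed: int,
    replicas: int = 4,
    n_receptor_atoms: int = 40,
):
    """Fixture set for overfitting benchmarks: ``5 * replicas`` examples
    covering exactly five distinct fragments.

    Each class models one binding site: a ligand in its bound pose inside a
    receptor shell. Replicas of a class are replicate structures of that
    site — the receptor coordinates perturbed by 0.4 Angstrom Gaussian
    jitter, emulating independent crystal structures of one receptor family.
    Returns ``(examples, receptors)`` with receptors keyed by entry id.
    """
    from .fragmenter import fragment_complex  # local import: avoid cycle

    examples = []
    receptors = {}
    for c, (smiles, fragment_smiles) in enumerate(LEARNABLE_CLASSES):
        base = make_fixture(
            seed=seed + 1000 * c,
            n_receptor_atoms=n_receptor_atoms,
            ligand_smiles=smiles,
            entry_id=f"LRN{c}0",
            family_id=f"CLS{c}",
        )
        rng = np.random.default_rng(seed + 1000 * c + 1)
        for r in range(replicas):
            coords = base.receptor.coords
            if r > 0:
                coords = coords + rng.normal(scale=REPLICA_JITTER, size=coords.shape)
            receptor = Molecule.from_atom_cloud(base.receptor.elements, coords)
            entry = ComplexEntry(
                entry_id=f"LRN{c}{r}",
                receptor=receptor,
                ligands=base.ligands,
                family_id=f"CLS{c}",
            )
            found = [
                x for x in fragment_complex(entry) if x.fragment_identity == fragment_smiles
            ]
            if not found:
                raise InputError(
                    f"class {c} replica {r} (seed {seed + 1000 * c}) lost its "
                    f"designated fragment {fragment_smiles}"
                )
            examples.append(found[0])
            receptors[entry.entry_id] = receptor
    return examples, receptors


def make_fixture_set(
    seed: int,
    count: int,
    *,
    n_receptor_atoms: int = 50,
    n_families: int = 3,
    smiles: tuple[str, ...] = FIXTURE_SMILES,
) -> list[ComplexEntry]:
    """A batch of fixtures cycling through a ligand panel and family labels."""
    entries = []
    for k in range(count):
        entries.append(
            make_fixture(
                seed=seed + k,
                n_receptor_atoms=n_receptor_atoms,
                ligand_smiles=smiles[k % len(smiles)],
                entry_id=f"FIX{seed + k:04d}",
                family_id=f"FAM{k % n_families}",
            )
        )
    return entries
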