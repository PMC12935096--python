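"""Fragmentation, filters, property classification and fingerprints."""

import numpy as np
import pytest
from rdkit import Chem

from fragforge.fixtures import make_fixture
from fragforge.fragmenter import (
    FragmentationExample,
    classify_property,
    cut_bond,
    enumerate_cuttable_bonds,
    fragment_complex,
    fragment_fingerprint,
    fragment_heavy_atom_count,
    hydrogen_capped,
    passes_filters,
)
from fragforge.mol import Molecule, embed_molecule


def mol3d(smiles: str, seed: int = 1) -> Molecule:
    return Molecule.from_rdkit(embed_molecule(smiles, seed=seed))


class TestEnumerateCuttableBonds:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCc1ccccc1", 2),  # terminal C-C and C-ring
            ("c1ccccc1", 0),  # all aromatic ring bonds
            ("CCCC", 3),
            ("CC(=O)O", 1),  # C=O double and C-OH cut? C-C single + C-O single
        ],
    )
    def test_counts(self, smiles, expected):
        bonds = enumerate_cuttable_bonds(mol3d(smiles))
        if smiles == "CC(=O)O":
            assert len(bonds) == 2  # C-C and C-O singles
        else:
            assert len(bonds) == expected

    def test_order_is_deterministic_ascending(self):
        lig = mol3d("CC(C)CO")
        bonds = enumerate_cuttable_bonds(lig)
        mol = lig.rdkit_mol
        pairs = []
        for idx in bonds:
            b = mol.GetBondWithIdx(idx)
            pairs.append((min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
                          max(b.GetBeginAtomIdx(), b.GetEndAtomIdx())))
        assert pairs == sorted(pairs)


class TestCutBond:
    def test_ethylbenzene_ring_cut_gives_benzene_and_ethyl(self):
        lig = mol3d("CCc1ccccc1")
        results = {}
        for b in enumerate_cuttable_bonds(lig):
            trimmed, fragment, branch = cut_bond(lig, b)
            results[fragment.identity] = (trimmed.identity, branch)
        assert results["*CC"][0] == "c1ccccc1"  # ethyl off the ring
        assert results["*C"][0] == "Cc1ccccc1"  # methyl off the ethyl tail

    def test_branch_atom_indexes_trimmed_ligand(self):
        lig = mol3d("CCc1ccccc1")
        for b in enumerate_cuttable_bonds(lig):
            trimmed, fragment, branch = cut_bond(lig, b)
            assert 0 <= branch < trimmed.n_heavy

    def test_heavy_atom_conservation(self):
        lig = mol3d("CCOC(=O)c1ccccc1")
        n = lig.n_heavy
        for b in enumerate_cuttable_bonds(lig):
            trimmed, fragment, _ = cut_bond(lig, b)
            assert trimmed.n_heavy + fragment_heavy_atom_count(fragment) == n

    def test_symmetric_ethane_tie_break_is_deterministic(self):
        lig = mol3d("CC")
        (bond,) = enumerate_cuttable_bonds(lig)
        t1, f1, _ = cut_bond(lig, bond)
        t2, f2, _ = cut_bond(lig, bond)
        assert t1.n_heavy == fragment_heavy_atom_count(f1) == 1
        assert (t1.identity, f1.identity) == (t2.identity, f2.identity)

    def test_ring_bond_cut_rejected(self):
        lig = mol3d("c1ccccc1")
        ring_bond = lig.rdkit_mol.GetBondBetweenAtoms(0, 1).GetIdx()
        with pytest.raises(Exception):
            cut_bond(lig, ring_bond)


def _example_from(lig: Molecule, bond: int, entry_id="E") -> FragmentationExample:
    from rdkit.Chem import Descriptors

    trimmed, fragment, branch = cut_bond(lig, bond)
    return FragmentationExample(
        entry_id=entry_id,
        ligand_identity=lig.identity,
        trimmed_ligand=trimmed,
        fragment=fragment,
        branch_atom=branch,
        connection_coords=trimmed.atoms[branch].coords,
        fragment_heavy_atoms=fragment_heavy_atom_count(fragment),
        fragment_mw=float(Descriptors.MolWt(hydrogen_capped(fragment))),
    )


class TestFilters:
    def test_nearby_fragment_passes(self):
        entry = make_fixture(1, 50, "CCc1ccccc1")
        lig = entry.ligands[0]
        ex = _example_from(lig, enumerate_cuttable_bonds(lig)[0])
        ok, reason = passes_filters(ex, entry.receptor)
        assert ok and reason is None

    def test_mass_boundary_strict(self):
        entry = make_fixture(1, 30, "CCO")
        lig = entry.ligands[0]
        ex = _example_from(lig, enumerate_cuttable_bonds(lig)[0])
        ex.fragment_mw = 151.0
        ok, reason = passes_filters(ex, entry.receptor)
        assert not ok and reason == "mass"
        ex.fragment_mw = 150.0
        ok, _ = passes_filters(ex, entry.receptor)
        assert ok

    def test_distant_receptor_fails_contact(self):
        entry = make_fixture(1, 30, "CCO")
        lig = entry.ligands[0]
        ex = _example_from(lig, enumerate_cuttable_bonds(lig)[0])
        far = Molecule.from_atom_cloud(["C"], ex.fragment.coords[:1] + 100.0)
        ok, reason = passes_filters(ex, far)
        assert not ok and reason == "contact"

    def test_filter_oracle_on_random_fixtures(self):
        """passes_filters agrees with a brute-force recomputation of the mass
        and all-pairs distance rules on 50 random fixtures."""
        from fragforge.fixtures import FIXTURE_SMILES

        checked = 0
        for seed in range(50):
            entry = make_fixture(seed, 25, FIXTURE_SMILES[seed % len(FIXTURE_SMILES)])
            lig = entry.ligands[0]
            for bond in enumerate_cuttable_bonds(lig):
                ex = _example_from(lig, bond, entry.entry_id)
                got_ok, _ = passes_filters(ex, entry.receptor)
                # independent oracle: explicit loops, no shared helpers
                capped = hydrogen_capped(ex.fragment)
                mw = sum(a.GetMass() for a in Chem.AddHs(capped).GetAtoms())
                frag_coords = [
                    a.coords for a in ex.fragment.atoms if a.element != "*"
                ]
                dmin = min(
                    float(np.linalg.norm(fc - rc.coords))
                    for fc in frag_coords
                    for rc in entry.receptor.atoms
                )
                want_ok = (mw <= 150.0 + 1e-6) and len(frag_coords) >= 1 and dmin <= 4.0
                assert got_ok == want_ok
                checked += 1
        assert checked >= 50


class TestClassifyProperty:
    @pytest.mark.parametrize(
        "smiles,aromatic,acidic,basic",
        [
            ("*C(=O)O", False, True, False),        # carboxylic acid
            ("*C(=O)[O-]", False, True, False),     # carboxylate
            ("*c1nnn[nH]1", True, True, False),     # tetrazole
            ("*CN", False, False, True),            # aliphatic amine
            ("*c1ccccc1", True, False, False),      # phenyl
            ("*Cc1ccc(O)cc1", True, True, False),   # aryl alcohol
            ("*CS(=O)(=O)N", False, True, False),   # sulfonamide
            ("*CC=NC", False, False, True),         # imine nitrogen
            ("*CC(=O)NC", False, False, False),     # amide: neither
            ("*COP(=O)(O)O", False, True, False),   # phosphate monoester
        ],
    )
    def test_rule_matrix(self, smiles, aromatic, acidic, basic):
        frag = Molecule.from_rdkit(Chem.MolFromSmiles(smiles), require_coords=False)
        label = classify_property(frag)
        assert (label.aromatic, label.acidic, label.basic) == (aromatic, acidic, basic)

    def test_aromatic_aliphatic_partition(self, fixture_examples):
        for x in fixture_examples:
            assert x.properties.aromatic != x.properties.aliphatic

    def test_size_class_consistent(self, fixture_examples):
        for x in fixture_examples:
            expect = "small" if x.fragment_heavy_atoms <= 3 else "large"
            assert x.properties.size_class == expect


class TestFingerprint:
    def test_shape_dtype_and_nonzero(self, fixture_examples):
        for x in fixture_examples[:8]:
            fp = x.fingerprint()
            assert fp.shape == (2048,)
            assert set(np.unique(fp)) <= {0, 1}
            assert fp.sum() > 0

    def test_identical_fragment_identical_bits(self):
        a = mol3d("CCc1ccccc1", seed=1)
        b = mol3d("CCc1ccccc1", seed=9)
        fa = {f.identity: fragment_fingerprint(f) for _, f, _ in
              (cut_bond(a, i) for i in enumerate_cuttable_bonds(a))}
        fb = {f.identity: fragment_fingerprint(f) for _, f, _ in
              (cut_bond(b, i) for i in enumerate_cuttable_bonds(b))}
        for key in fa:
            np.testing.assert_array_equal(fa[key], fb[key])

    def test_methyl_vs_ethyl_differ(self):
        lig = mol3d("CCc1ccccc1")
        fps = {}
        for i in enumerate_cuttable_bonds(lig):
            _, f, _ = cut_bond(lig, i)
            fps[f.identity] = fragment_fingerprint(f)
        a, b = fps["*C"].astype(float), fps["*CC"].astype(float)
        tanimoto = (a * b).sum() / ((a + b > 0).sum())
        assert tanimoto < 1.0


CONSERVATION_SMILES = [
    "CCO", "CCCC", "CC(C)CO", "CCOC(=O)c1ccccc1", "NCCc1ccccc1", "CSc1ccccc1",
    "CC(=O)Nc1ccccc1", "OC(=O)Cc1ccccc1", "Cc1ccc(O)cc1", "CCN(CC)CC",
    "OCCOCCO", "CC(C)(C)c1ccccc1", "ClCCCl", "CCS(=O)(=O)N", "c1ccc(CNC)cc1",
    "CC1CCCCC1C", "COc1ccccc1", "CC(N)C(=O)O", "NCCS", "CCCCCCCC",
    "CN1CCCC1", "OCc1ccncc1", "CC=CC", "CC(=O)OC", "NC(=O)CCc1ccccc1",
] * 2  # 50 fragmentation targets


class TestWholeComplex:
    def test_mass_conservation_over_random_ligands(self):
        for k, smiles in enumerate(CONSERVATION_SMILES):
            lig = mol3d(smiles, seed=k)
            for bond in enumerate_cuttable_bonds(lig):
                trimmed, fragment, _ = cut_bond(lig, bond)
                assert trimmed.n_heavy + fragment_heavy_atom_count(fragment) == lig.n_heavy
                assert trimmed.n_heavy >= fragment_heavy_atom_count(fragment)

    def test_fragment_complex_counts(self, ethylbenzene_entry):
        examples = fragment_complex(ethylbenzene_entry)
        assert len(examples) == 2
        assert sorted(x.fragment_identity for x in examples) == ["*C", "*CC"]

    def test_no_cuttable_bonds_gives_no_examples(self):
        entry = make_fixture(2, 40, "c1ccccc1")
        assert fragment_complex(entry) == []

    def test_distant_ligand_filtered_out(self, ethylbenzene_entry):
        from fragforge.mol import ComplexEntry, Molecule as M

        shifted = M.from_atom_cloud(
            ethylbenzene_entry.receptor.elements,
            ethylbenzene_entry.receptor.coords + 100.0,
        )
        entry = ComplexEntry(
            entry_id="FAR",
            receptor=shifted,
            ligands=ethylbenzene_entry.ligands,
            family_id="F",
        )
        assert fragment_complex(entry) == []

    def test_idempotent_output(self, ethylbenzene_entry):
        a = fragment_complex(ethylbenzene_entry)
        b = fragment_complex(ethylbenzene_entry)
        assert [x.fragment_identity for x in a] == [x.fragment_identity for x in b]
        for xa, xb in zip(a, b):
            np.testing.assert_array_equal(xa.connection_coords, xb.connection_coords)
            np.testing.assert_array_equal(xa.fingerprint(), xb.fingerprint())
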