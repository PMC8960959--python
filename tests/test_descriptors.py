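import numpy as np
import pytest
from rdkit import Chem

from extrapolab import chem
from extrapolab.descriptors import (
    DescriptorVector,
    FragmentDictionary,
    FragmentDictionaryUnderfullError,
    build_fragment_dictionary,
    canonical_path_codes,
    carbon_skeleton,
    descriptor_matrix,
    enumerate_fragment_codes,
    fnv1a_32,
    fragment_fp,
    load_default_dictionary,
    path_fp,
    skeleton_spheres,
    sphere_codes,
    tanimoto,
)

from . import oracles


class TestTanimoto:
    def test_identity(self):
        v = DescriptorVector("SkelSpheres", np.arange(1024) % 5)
        assert tanimoto(v, v) == 1.0

    def test_disjoint_bits(self):
        a = np.zeros(512, dtype=int)
        b = np.zeros(512, dtype=int)
        a[:10] = 1
        b[10:20] = 1
        assert tanimoto(DescriptorVector("PathFp", a), DescriptorVector("PathFp", b)) == 0.0

    def test_count_formula_hand_example(self):
        a = np.zeros(1024, dtype=int)
        b = np.zeros(1024, dtype=int)
        a[:3] = [2, 0, 1]
        b[:3] = [1, 1, 1]
        got = tanimoto(DescriptorVector("SkelSpheres", a), DescriptorVector("SkelSpheres", b))
        assert got == pytest.approx(0.5)  # (1+0+1)/(2+1+1)

    def test_all_zero_vectors_are_identical(self):
        z = DescriptorVector("PathFp", np.zeros(512, dtype=int))
        assert tanimoto(z, z) == 1.0

    def test_kind_mismatch_raises(self):
        a = DescriptorVector("PathFp", np.zeros(512, dtype=int))
        b = DescriptorVector("FragFp", np.zeros(512, dtype=int))
        with pytest.raises(ValueError):
            tanimoto(a, b)


class TestPathFp:
    def test_methane_single_path_single_bit(self):
        v = path_fp(chem.parse_smiles("C"))
        assert v.values.sum() == 1

    def test_ethane_two_paths(self):
        codes = canonical_path_codes(chem.parse_smiles("CC"))
        assert codes == {"C", "C-C"}
        assert path_fp(chem.parse_smiles("CC")).values.sum() <= 2

    def test_bits_match_exhaustive_enumeration(self, apix_small):
        """Oracle equivalence: independent networkx path enumeration must
        reproduce the exact bit pattern for small molecules."""
        mols = [m for m in apix_small.molecules if m.GetNumHeavyAtoms() <= 12][:15]
        assert len(mols) >= 5
        for mol in mols:
            expected = np.zeros(512, dtype=int)
            oracle_codes = oracles.enumerate_path_codes(mol)
            for code in oracle_codes:
                expected[fnv1a_32(code) % 512] = 1
            got = path_fp(mol).values
            assert np.array_equal(got, expected)
            assert got.sum() <= len(oracle_codes)

    def test_atom_removal_cannot_create_paths(self, apix_small):
        """A child from pure atom removal has a path set that is a subset of
        the parent's (ring cuts are excluded: they can create new paths)."""
        from extrapolab import molgen

        rng = np.random.default_rng(3)
        checked = 0
        for mol in apix_small.molecules[:20]:
            kek, moves = molgen._legal_moves(mol)
            atom_moves = [mv for mv in moves if mv[0] == "atom"]
            if not atom_moves:
                continue
            child = molgen._apply_move(kek, atom_moves[int(rng.integers(len(atom_moves)))])
            assert canonical_path_codes(child) <= canonical_path_codes(mol)
            assert path_fp(child).values.sum() <= path_fp(mol).values.sum()
            checked += 1
        assert checked >= 10


class TestSkeletonSpheres:
    def test_methane_total_eight(self):
        assert skeleton_spheres(chem.parse_smiles("C")).values.sum() == 8

    def test_hydrocarbon_entries_all_even(self):
        v = skeleton_spheres(chem.parse_smiles("C1CCCCC1")).values
        assert v.sum() == 48
        assert (v % 2 == 0).all()

    def test_mass_conservation_on_generated_set(self, apix_set_300):
        """Sum of the vector is always 8 x heavy atoms (4 radii x 2 passes)."""
        rng = np.random.default_rng(5)
        idx = rng.choice(300, size=100, replace=False)
        for i in idx:
            mol = apix_set_300.molecules[int(i)]
            assert skeleton_spheres(mol).values.sum() == 8 * mol.GetNumHeavyAtoms()

    def test_layer_count_configurable(self):
        v = skeleton_spheres(chem.parse_smiles("CCO"), n_radii=2)
        assert v.values.sum() == 2 * 2 * 3

    def test_carbon_skeleton_is_identity_on_hydrocarbons(self):
        mol = chem.parse_smiles("CC1=CC(C)CC1")
        assert chem.canonical_code(carbon_skeleton(mol)) == chem.canonical_code(mol)

    def test_carbon_skeleton_replaces_heteroatoms(self):
        skel = carbon_skeleton(chem.parse_smiles("c1ccncc1"))  # pyridine -> benzene
        assert chem.canonical_code(skel) == chem.canonical_code(chem.parse_smiles("c1ccccc1"))

    def test_carbon_skeleton_clips_excess_valence(self):
        # sulfate-like S(=O)(=O) center: C with two double bonds exceeds
        # valence 4 and must be downgraded deterministically
        skel = carbon_skeleton(chem.parse_smiles("CS(C)(=O)=O"))
        assert all(a.GetSymbol() == "C" for a in skel.GetAtoms())
        assert Chem.SanitizeMol(skel, catchErrors=True) == Chem.SanitizeFlags.SANITIZE_NONE


class TestPermutationInvariance:
    @pytest.mark.parametrize("kind", ["PathFp", "SkelSpheres"])
    def test_hashed_descriptors(self, kind, apix_small):
        rng = np.random.default_rng(7)
        for mol in apix_small.molecules[:10]:
            ref = descriptor_matrix([mol], kind)[0]
            for _ in range(3):
                perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
                shuffled = Chem.RenumberAtoms(mol, perm)
                assert np.array_equal(descriptor_matrix([shuffled], kind)[0], ref)

    def test_fragment_fp(self, apix_small):
        rng = np.random.default_rng(8)
        for mol in apix_small.molecules[:3]:
            ref = fragment_fp(mol).values
            perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
            assert np.array_equal(fragment_fp(Chem.RenumberAtoms(mol, perm)).values, ref)


@pytest.fixture(scope="module")
def small_dict(dict_corpus):
    return build_fragment_dictionary(dict_corpus, size=64, max_atoms=5)


class TestFragmentDictionary:
    def test_deterministic(self, dict_corpus, small_dict):
        again = build_fragment_dictionary(dict_corpus, size=64, max_atoms=5)
        assert again.patterns == small_dict.patterns

    def test_degenerate_corpus_raises(self):
        corpus = [chem.parse_smiles("c1ccccc1") for _ in range(500)]
        with pytest.raises(FragmentDictionaryUnderfullError):
            build_fragment_dictionary(corpus, size=64)

    def test_accepted_pairs_below_correlation_threshold(self, dict_corpus, small_dict):
        """Recompute match vectors with actual substructure matching (not the
        build's subgraph enumeration) and verify all pairwise |r| < 0.8."""
        queries = small_dict.queries[:24]
        match = np.array(
            [[mol.HasSubstructMatch(q) for q in queries] for mol in dict_corpus], dtype=float
        )
        corr = np.corrcoef(match.T)
        off_diag = np.abs(corr[~np.eye(len(queries), dtype=bool)])
        assert np.nanmax(off_diag) < 0.8

    def test_save_load_roundtrip(self, small_dict, tmp_path):
        path = tmp_path / "dict.smarts"
        small_dict.save(path)
        back = FragmentDictionary.load(path)
        assert back.patterns == small_dict.patterns
        assert back.build_metadata == small_dict.build_metadata

    def test_enumerated_codes_are_true_substructures(self, dict_corpus):
        mol = dict_corpus[0]
        for code in sorted(enumerate_fragment_codes(mol, max_atoms=5))[:40]:
            q = Chem.MolFromSmarts(code)
            assert q is not None and mol.HasSubstructMatch(q)


class TestFragmentFp:
    def test_methane_matches_nothing_multiatom(self):
        d = FragmentDictionary(["CC", "CCO", "c1ccccc1"])
        assert fragment_fp(chem.parse_smiles("C"), d).values.sum() == 0

    def test_self_match_sets_bit(self):
        d = FragmentDictionary(["CC", "CCO"])
        v = fragment_fp(chem.parse_smiles("CCO"), d).values
        assert v[0] == 1 and v[1] == 1

    def test_default_dictionary_loads_512(self):
        d = load_default_dictionary()
        assert len(d) == 512

    def test_bits_match_vf2_oracle(self, dict_corpus):
        """Oracle equivalence: brute-force VF2 subgraph monomorphism agrees
        with the fingerprint's substructure matching on small molecules."""
        d = build_fragment_dictionary(dict_corpus, size=32, max_atoms=4)
        mols = [m for m in dict_corpus if m.GetNumHeavyAtoms() <= 12][:10]
        assert len(mols) >= 5
        for mol in mols:
            got = fragment_fp(mol, FragmentDictionary(d.patterns[:32])).values[:32]
            expected = np.array(
                [oracles.has_substructure(mol, p) for p in d.patterns[:32]], dtype=int
            )
            assert np.array_equal(got, expected)
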