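"""Subfragment enumeration against a brute-force oracle, vocabulary and matrix IO."""

from itertools import combinations

import numpy as np
import pytest
from rdkit import Chem

from fragqsar import fragments as fr
from fragqsar.fragments import (
    build_vocabulary,
    enumerate_fragments,
    export_matrix,
    featurize,
    fragment_key,
    import_matrix,
)


def brute_force_keys(mol, min_bonds=1, max_bonds=7):
    """Independent oracle: every connected edge subset, by exhaustive search.

    Connectivity is checked with union-find over the subset's bonds, so
    nothing is shared with the subgraph walk under test except the
    canonical key writer.
    """
    m = fr._strip_mol(mol)
    bonds = [(b.GetIdx(), b.GetBeginAtomIdx(), b.GetEndAtomIdx())
             for b in m.GetBonds()]
    keys = set()
    for size in range(min_bonds, min(max_bonds, len(bonds)) + 1):
        for subset in combinations(bonds, size):
            parent = {}

            def find(x):
                parent.setdefault(x, x)
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            atoms = set()
            for _, a, b in subset:
                atoms.add(a)
                atoms.add(b)
                ra, rb = find(a), find(b)
                parent[ra] = rb
            if len({find(a) for a in atoms}) == 1:  # connected
                keys.add(fragment_key(m, [i for i, _, _ in subset]))
    return keys


SMALL_MOLECULES = [
    # <= 8 heavy atoms; chains, branches, rings, heteroatoms, charges,
    # aromatics, multiple bonds
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CC(C)(C)C", "CCO", "CCN", "CCS",
    "CCCl", "CCBr", "CCF", "CC=C", "CC#C", "CC=O", "CC(=O)O", "CC(=O)N",
    "CC#N", "CCOC", "CCNC", "COC=O", "CSC", "CS(=O)C", "C=C", "C#N",
    "C1CC1", "C1CCC1", "C1CCCC1", "C1CCCCC1", "C1CCOC1", "C1CCNC1",
    "C1CCSC1", "C1COCCN1", "c1ccccc1", "c1ccncc1", "c1ccnnc1", "c1cnccn1",
    "c1cc[nH]c1", "c1ccoc1", "c1ccsc1", "c1cnc[nH]1", "c1ncncn1",
    "Cc1ccccc1", "Oc1ccccc1", "Nc1ccncc1", "Fc1ccccc1", "CC1CCCO1",
    "C[N+](C)(C)C", "CC(=O)[O-]", "OC(=O)C(N)C",
]


def test_small_molecule_sweep_matches_brute_force():
    assert len(SMALL_MOLECULES) == 50
    for smi in SMALL_MOLECULES:
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        assert mol.GetNumHeavyAtoms() <= 8, smi
        got = {f.key for f in enumerate_fragments(mol)}
        assert got == brute_force_keys(mol), smi


@pytest.mark.parametrize("smiles,expected", [
    ("CCC", {"CC", "CCC"}),
    ("CCO", {"CC", "CO", "CCO"}),
    ("C1CCCCC1", {"CC", "CCC", "CCCC", "CCCCC", "CCCCCC", "C1CCCCC1"}),
])
def test_known_fragment_sets(smiles, expected):
    got = {f.key for f in enumerate_fragments(Chem.MolFromSmiles(smiles))}
    assert got == expected


def test_fragment_counts_carry_bond_and_atom_sizes():
    frags = {f.key: f for f in enumerate_fragments(Chem.MolFromSmiles("CCO"))}
    assert frags["CCO"].n_bonds == 2
    assert frags["CCO"].n_atoms == 3
    assert frags["CC"].n_bonds == 1


def test_empty_and_single_atom_molecules():
    assert enumerate_fragments(Chem.MolFromSmiles("C")) == set()
    assert enumerate_fragments(Chem.MolFromSmiles("")) == set()


def test_bond_window_bounds():
    mol = Chem.MolFromSmiles("CCCCCC")
    keys = {f.key for f in enumerate_fragments(mol, 2, 3)}
    assert keys == {"CCC", "CCCC"}
    with pytest.raises(ValueError):
        enumerate_fragments(mol, 0, 3)


def test_canonical_invariance_under_atom_renumbering():
    mol = Chem.MolFromSmiles("Cc1ccncc1CCO")
    base = {f.key for f in enumerate_fragments(mol)}
    rng = np.random.default_rng(7)
    for _ in range(5):
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        renum = Chem.RenumberAtoms(mol, perm)
        assert {f.key for f in enumerate_fragments(renum)} == base


def test_kekulization_invariance():
    for arom in ["c1ccccc1", "c1ccncc1C", "c1cc2[nH]ccc2cc1"]:
        mol = Chem.MolFromSmiles(arom)
        kek = Chem.MolToSmiles(mol, kekuleSmiles=True)
        assert "=" in kek  # genuinely kekulized input
        a = {f.key for f in enumerate_fragments(mol)}
        k = {f.key for f in enumerate_fragments(Chem.MolFromSmiles(kek))}
        assert a == k


@pytest.mark.parametrize("sub,mol", [
    ("CCO", "CCCO"),
    ("c1ccccc1", "Cc1ccccc1"),
    ("CC(=O)N", "CCC(=O)NC"),
])
def test_subgraph_monotonicity(sub, mol):
    """Fragments of a connected subgraph are fragments of the whole molecule."""
    sub_keys = {f.key for f in enumerate_fragments(Chem.MolFromSmiles(sub))}
    mol_keys = {f.key for f in enumerate_fragments(Chem.MolFromSmiles(mol))}
    assert sub_keys <= mol_keys


def test_isotopes_and_stereo_dropped_charges_kept():
    plain = {f.key for f in enumerate_fragments(Chem.MolFromSmiles("CC(N)C(=O)O"))}
    labeled = {f.key for f in
               enumerate_fragments(Chem.MolFromSmiles("[13CH3][C@@H](N)C(=O)O"))}
    assert plain == labeled
    charged = {f.key for f in enumerate_fragments(Chem.MolFromSmiles("CC(=O)[O-]"))}
    assert any("[O-]" in k for k in charged)


def _sets(*smiles):
    return [enumerate_fragments(Chem.MolFromSmiles(s)) for s in smiles]


def test_build_vocabulary_support_filter():
    vocab = build_vocabulary(_sets("CCC", "CCO", "C1CCCCC1"), min_support=2)
    assert "CC" in vocab.entries
    assert vocab.support["CC"] == 3
    # no fragment unique to a single molecule survives
    assert all(s >= 2 for s in vocab.support.values())
    assert vocab.keys == sorted(vocab.keys)


def test_build_vocabulary_identical_molecules_keep_everything():
    sets = _sets("CCO", "CCO")
    vocab = build_vocabulary(sets, min_support=2)
    assert set(vocab.entries) == {f.key for f in sets[0]}


def test_build_vocabulary_empty_errors():
    with pytest.raises(ValueError, match="support"):
        build_vocabulary(_sets("CCCC", "c1ccncc1"), min_support=2)


def test_featurize_known_row():
    vocab = build_vocabulary(_sets("CCO", "CCO"), min_support=2)
    row = featurize(_sets("CCC"), vocab).X.toarray().ravel()
    expected = np.array([1.0 if k == "CC" else 0.0 for k in vocab.keys])
    np.testing.assert_array_equal(row, expected)


def test_featurize_training_molecules_have_no_zero_rows():
    sets = _sets("CCC", "CCO", "CCN")
    vocab = build_vocabulary(sets, min_support=2)
    matrix = featurize(sets, vocab)
    assert matrix.zero_rows().size == 0
    empty = featurize([], vocab)
    assert empty.shape == (0, len(vocab))


def test_matrix_round_trip(tmp_path):
    sets = _sets("CCC", "CCO", "C1CCCCC1", "CCCO")
    vocab = build_vocabulary(sets, min_support=2)
    matrix = featurize(sets, vocab, ["a", "b", "c", "d"])
    export_matrix(matrix, tmp_path / "m")
    back = import_matrix(tmp_path / "m")
    assert (back.X != matrix.X).nnz == 0
    assert back.row_ids == matrix.row_ids
    assert back.vocabulary.entries == matrix.vocabulary.entries
    assert back.vocabulary.support == matrix.vocabulary.support


def test_import_matrix_corrupted_header(tmp_path):
    sets = _sets("CCC", "CCO")
    vocab = build_vocabulary(sets, min_support=2)
    export_matrix(featurize(sets, vocab), tmp_path / "m")
    vocab_file = tmp_path / "m.vocab.tsv"
    vocab_file.write_text("bogus\theader\n" +
                          vocab_file.read_text().split("\n", 1)[1])
    with pytest.raises(ValueError, match="format error"):
        import_matrix(tmp_path / "m")
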