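"""Exhaustive subfragment fingerprints.

Every connected edge-induced subgraph of a molecule with a bond count
inside a configurable window (default 1-7 bonds) is a *fragment*.
Fragments are identified by a canonical key — the canonical SMILES of
the subgraph written with the parent molecule's perceived aromaticity —
so the same substructure reached from different atom numberings, input
SMILES or kekulization states collapses to one key.  Element, charge,
aromaticity and bond order are retained; hydrogens stay implicit;
isotopes and stereochemistry are dropped; no attachment points are
marked.

A :class:`FragmentVocabulary` maps each fragment key occurring in at
least ``min_support`` distinct training molecules to a column of the
sparse binary :class:`DescriptorMatrix`: X[i, j] = 1 iff fragment j is
a subgraph of molecule i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from rdkit import Chem

DEFAULT_MIN_BONDS = 1
DEFAULT_MAX_BONDS = 7
DEFAULT_MIN_SUPPORT = 2


@dataclass(frozen=True)
class Fragment:
    key: str
    n_bonds: int
    n_atoms: int


def _strip_mol(mol: Chem.Mol) -> Chem.Mol:
    """Copy with isotopes and stereo removed; aromaticity already perceived."""
    m = Chem.Mol(mol)
    Chem.RemoveStereochemistry(m)
    for atom in m.GetAtoms():
        atom.SetIsotope(0)
    return m


def fragment_key(mol: Chem.Mol, bond_indices: Sequence[int]) -> str:
    """Canonical key of the edge-induced subgraph spanned by ``bond_indices``."""
    atoms: set[int] = set()
    for b in bond_indices:
        bond = mol.GetBondWithIdx(b)
        atoms.add(bond.GetBeginAtomIdx())
        atoms.add(bond.GetEndAtomIdx())
    return Chem.MolFragmentToSmiles(
        mol,
        atomsToUse=sorted(atoms),
        bondsToUse=list(bond_indices),
        canonical=True,
        isomericSmiles=False,
    )


def enumerate_fragments(
    mol: Chem.Mol,
    min_bonds: int = DEFAULT_MIN_BONDS,
    max_bonds: int = DEFAULT_MAX_BONDS,
) -> set[Fragment]:
    """All distinct connected subfragments with bond count in [min_bonds, max_bonds].

    Subgraph enumeration delegates to RDKit's connected-subgraph walk;
    duplicates (the same subgraph reached along different bond subsets,
    or symmetric copies producing identical canonical keys) collapse.
    An empty molecule yields an empty set.
    """
    if not 1 <= min_bonds <= max_bonds:
        raise ValueError("need 1 <= min_bonds <= max_bonds")
    if mol is None or mol.GetNumBonds() == 0:
        return set()
    m = _strip_mol(mol)
    out: dict[str, Fragment] = {}
    paths = Chem.FindAllSubgraphsOfLengthMToN(m, min_bonds, max_bonds)
    for by_length in paths:
        for bond_ids in by_length:
            key = fragment_key(m, bond_ids)
            if key not in out:
                atoms = set()
                for b in bond_ids:
                    bond = m.GetBondWithIdx(b)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                out[key] = Fragment(key, len(bond_ids), len(atoms))
    return set(out.values())


@lru_cache(maxsize=200_000)
def fragment_set_of_smiles(
    smiles: str,
    min_bonds: int = DEFAULT_MIN_BONDS,
    max_bonds: int = DEFAULT_MAX_BONDS,
) -> frozenset[Fragment]:
    """Memoized fragment set for a SMILES string (used by the pipeline)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return frozenset(enumerate_fragments(mol, min_bonds, max_bonds))


@lru_cache(maxsize=200_000)
def fragment_keys_of_smiles(
    smiles: str,
    min_bonds: int = DEFAULT_MIN_BONDS,
    max_bonds: int = DEFAULT_MAX_BONDS,
) -> frozenset[str]:
    """Memoized fragment-key set for a SMILES string."""
    return frozenset(f.key for f in fragment_set_of_smiles(smiles, min_bonds,
                                                           max_bonds))


@dataclass
class FragmentVocabulary:
    """Ordered fragment key -> column index map with per-key support counts.

    Columns are assigned in lexicographic key order, so the vocabulary
    (and every matrix built from it) is deterministic for a given
    training set.
    """

    entries: dict[str, int]
    support: dict[str, int]
    n_bonds: dict[str, int] = field(default_factory=dict)
    min_support: int = DEFAULT_MIN_SUPPORT

    @property
    def keys(self) -> list[str]:
        return sorted(self.entries, key=self.entries.get)

    def __len__(self) -> int:
        return len(self.entries)


def build_vocabulary(
    fragment_sets: Sequence[Iterable[Fragment | str]],
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> FragmentVocabulary:
    """Vocabulary of fragments present in >= min_support distinct molecules."""
    support: dict[str, int] = {}
    bonds: dict[str, int] = {}
    for frags in fragment_sets:
        seen = set()
        for f in frags:
            key = f if isinstance(f, str) else f.key
            if key in seen:
                continue
            seen.add(key)
            support[key] = support.get(key, 0) + 1
            if not isinstance(f, str):
                bonds.setdefault(key, f.n_bonds)
    kept = sorted(k for k, s in support.items() if s >= min_support)
    if not kept:
        raise ValueError("no fragments above support threshold")
    entries = {k: j for j, k in enumerate(kept)}
    return FragmentVocabulary(entries, {k: support[k] for k in kept},
                              {k: bonds.get(k, 0) for k in kept}, min_support)


@dataclass
class DescriptorMatrix:
    """Sparse binary molecule x fragment presence matrix."""

    X: sp.csr_matrix
    row_ids: list[str]
    vocabulary: FragmentVocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def zero_rows(self) -> np.ndarray:
        """Indices of molecules contributing no known fragment."""
        return np.flatnonzero(np.asarray(self.X.sum(axis=1)).ravel() == 0)


def featurize(
    fragment_sets: Sequence[Iterable[Fragment | str]],
    vocabulary: FragmentVocabulary,
    row_ids: Sequence[str] | None = None,
) -> DescriptorMatrix:
    """Binary presence matrix of the vocabulary over per-molecule fragment sets."""
    if len(vocabulary) == 0:
        raise ValueError("empty vocabulary")
    rows, cols = [], []
    for i, frags in enumerate(fragment_sets):
        for f in frags:
            key = f if isinstance(f, str) else f.key
            j = vocabulary.entries.get(key)
            if j is not None:
                rows.append(i)
                cols.append(j)
    n = len(fragment_sets)
    X = sp.csr_matrix(
        (np.ones(len(rows), dtype=np.float64), (rows, cols)),
        shape=(n, len(vocabulary)),
    )
    X.data = np.minimum(X.data, 1.0)  # collapse accidental dupes
    ids = list(row_ids) if row_ids is not None else [str(i) for i in range(n)]
    return DescriptorMatrix(X, ids, vocabulary)


def molecules_to_matrix(
    mols: Sequence[Chem.Mol],
    vocabulary: FragmentVocabulary,
    row_ids: Sequence[str] | None = None,
    min_bonds: int = DEFAULT_MIN_BONDS,
    max_bonds: int = DEFAULT_MAX_BONDS,
) -> DescriptorMatrix:
    sets = [fragment_keys_of_smiles(Chem.MolToSmiles(m), min_bonds, max_bonds)
            for m in mols]
    return featurize(sets, vocabulary, row_ids)


def export_matrix(matrix: DescriptorMatrix, path_prefix) -> None:
    """Write the matrix (Matrix Market) plus vocabulary and row-id sidecars."""
    prefix = str(path_prefix)
    scipy.io.mmwrite(prefix + ".mtx", matrix.X.tocoo())
    with open(prefix + ".vocab.tsv", "w", encoding="utf-8") as fh:
        fh.write("index\tfragment_key\tsupport\tn_bonds\n")
        for key in matrix.vocabulary.keys:
            fh.write(f"{matrix.vocabulary.entries[key]}\t{key}\t"
                     f"{matrix.vocabulary.support[key]}\t"
                     f"{matrix.vocabulary.n_bonds.get(key, 0)}\n")
    with open(prefix + ".rows.txt", "w", encoding="utf-8") as fh:
        fh.writelines(rid + "\n" for rid in matrix.row_ids)


def import_matrix(path_prefix) -> DescriptorMatrix:
    prefix = str(path_prefix)
    X = sp.csr_matrix(scipy.io.mmread(prefix + ".mtx"))
    entries: dict[str, int] = {}
    support: dict[str, int] = {}
    bonds: dict[str, int] = {}
    with open(prefix + ".vocab.tsv", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["index", "fragment_key", "support", "n_bonds"]:
            raise ValueError("descriptor matrix format error: bad vocabulary header")
        for line in fh:
            idx, key, sup, nb = line.rstrip("\n").split("\t")
            entries[key] = int(idx)
            support[key] = int(sup)
            bonds[key] = int(nb)
    with open(prefix + ".rows.txt", encoding="utf-8") as fh:
        row_ids = [line.rstrip("\n") for line in fh]
    if X.shape[1] != len(entries) or X.shape[0] != len(row_ids):
        raise ValueError("descriptor matrix format error: dimension mismatch")
    vocab = FragmentVocabulary(entries, support, bonds)
    return DescriptorMatrix(X.astype(np.float64), row_ids, vocab)
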