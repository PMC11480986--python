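"""Synthetic benchmark data with planted fragment effects.

Real kinase-inhibitor collections are proprietary, so every pipeline
stage is exercised on generated data that mimics their statistical
structure: molecules assembled from a scaffold/substituent grammar
(heteroaromatic cores typical of kinase-inhibitor chemistry), potency
driven by an additive fragment-effect model

    pIC50 = beta0 + sum_f beta_f * 1[f subgraph of molecule] + N(0, sigma^2)

clipped to a realistic assay window of [3, 10], and a censoring mixture
emulating database entry practice: a fraction of records keep their
exact value, the rest are recorded only as "<0.1 uM" (actives; "<0.001
uM" for the strongest) or ">10 uM" (inactives).

Because activity is written directly in terms of enumerable fragment
keys, recovery experiments are well-posed: with sigma = 0 and the
planted fragments in the vocabulary, a linear model on the descriptor
matrix reproduces the activity exactly, and alert extraction should
rank the planted keys at the top.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem_io import ActivityRecord, CuratedDataset
from .fragments import DEFAULT_MAX_BONDS, DEFAULT_MIN_BONDS, fragment_keys_of_smiles

PIC50_WINDOW = (3.0, 10.0)

# censoring bounds mirroring database entry practice (molar IC50)
ACTIVE_BOUND = 1e-7        # "<0.1 uM"
STRONG_ACTIVE_BOUND = 1e-9  # "<0.001 uM", used when the true pIC50 >= 9
INACTIVE_BOUND = 1e-5      # ">10 uM"


@dataclass
class FragmentGrammar:
    """Scaffold/substituent grammar; sites [*:1], [*:2] joined by single bonds."""

    scaffolds: list[str]
    substituents: list[str]  # each contains exactly one [*:1] attachment dummy

    def products(self) -> list[str]:
        """All distinct canonical products, sorted (deterministic order)."""
        out: set[str] = set()
        for scaf in self.scaffolds:
            n_sites = sum(scaf.count(f"[*:{k}]") for k in (1, 2))
            for s1 in self.substituents:
                if n_sites == 1:
                    out.add(_join(scaf, [s1]))
                else:
                    for s2 in self.substituents:
                        out.add(_join(scaf, [s1, s2]))
        return sorted(out)

    def to_dict(self) -> dict:
        return {"scaffolds": self.scaffolds, "substituents": self.substituents}

    @classmethod
    def from_dict(cls, d: dict) -> "FragmentGrammar":
        return cls(list(d["scaffolds"]), list(d["substituents"]))


def _join(scaffold: str, subs: Sequence[str]) -> str:
    parts = [scaffold]
    for i, sub in enumerate(subs, start=1):
        parts.append(sub.replace("[*:1]", f"[*:{i}]"))
    combined = Chem.MolFromSmiles(".".join(parts))
    if combined is None:
        raise ValueError(f"grammar parse failure: {scaffold} + {subs}")
    product = Chem.molzip(combined)
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


#: heteroaromatic cores in the style of kinase-inhibitor scaffolds
_SCAFFOLDS = [
    "c1cc([*:1])nc([*:2])n1",            # pyrimidine
    "c1ccc2nc([*:1])nc([*:2])c2c1",      # quinazoline
    "c1ccc2[nH]c([*:1])nc2c1([*:2])",    # benzimidazole (site on ring)
    "c1cc([*:1])cc([*:2])n1",            # pyridine
    "c1cc([*:1])n([*:2])n1",             # pyrazole
    "c1sc([*:1])nc1[*:2]",               # thiazole
    "c1cc2cc([*:1])cnc2n1[*:2]",         # pyrrolopyridine
    "c1nc([*:1])c2ncn([*:2])c2n1",       # purine
    "c1cc([*:1])c2[nH]c([*:2])cc2c1",    # indole
]

_SUBSTITUENTS = [
    "[*:1]F",
    "[*:1]Cl",
    "[*:1]Br",
    "[*:1]C",
    "[*:1]CC",
    "[*:1]OC",
    "[*:1]N",
    "[*:1]O",
    "[*:1]C#N",
    "[*:1]C(F)(F)F",
    "[*:1]S(C)(=O)=O",
    "[*:1]N1CCOCC1",
    "[*:1]OC(C)C",
    "[*:1]C(N)=O",
    "[*:1]N(C)C",
    "[*:1]c1ccccc1",
]

#: (substituent, characteristic motif) pairs for the default planted effects;
#: each motif is the full subgraph of its substituent and arises from no
#: other grammar element
_DEFAULT_EFFECTS = [
    ("[*:1]C(F)(F)F", "C(F)(F)F"),
    ("[*:1]S(C)(=O)=O", "CS(=O)=O"),
    ("[*:1]N1CCOCC1", "C1COCCN1"),
    ("[*:1]OC(C)C", "CC(C)O"),
    ("[*:1]C(N)=O", "NC=O"),
]


def motif_fragment_key(motif: str, example_smiles: str) -> str:
    """Fragment key of a motif, derived from a molecule that contains it.

    Keys are spelled by the enumeration's canonical writer, which can
    differ from the motif's standalone canonical SMILES (e.g. hydrogen
    annotations on hypervalent sulfur), so the key is extracted from a
    real embedding rather than from the motif string.
    """
    from .fragments import _strip_mol, fragment_key

    mol = _strip_mol(Chem.MolFromSmiles(example_smiles))
    query = Chem.MolFromSmiles(motif)
    matches = mol.GetSubstructMatches(query, uniquify=True)
    if not matches:
        raise ValueError(f"motif {motif!r} not found in {example_smiles!r}")
    # prefer the embedding off the aromatic core: the substituent subgraph
    # itself, not an attachment-context variant of it
    match = min(matches, key=lambda m: sum(
        mol.GetAtomWithIdx(i).GetIsAromatic() for i in m))
    atoms = set(match)
    bonds = [b.GetIdx() for b in mol.GetBonds()
             if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms]
    if len(bonds) != query.GetNumBonds():
        raise ValueError(f"motif {motif!r} embedding is not edge-induced")
    return fragment_key(mol, bonds)


def default_grammar() -> FragmentGrammar:
    return FragmentGrammar(list(_SCAFFOLDS), list(_SUBSTITUENTS))


def sample_molecules(grammar: FragmentGrammar, n: int, seed: int,
                     replace: bool = False) -> list[str]:
    """n canonical product SMILES drawn uniformly, without replacement by default."""
    if n < 1:
        raise ValueError("n must be >= 1")
    products = grammar.products()
    if n > len(products) and not replace:
        raise ValueError(f"{n} molecules requested but the grammar yields only "
                         f"{len(products)} distinct products")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(products), size=n, replace=replace)
    return [products[i] for i in idx]


@dataclass
class PlantedModel:
    """Ground-truth activity model: additive fragment effects plus noise."""

    baseline: float = 5.5
    effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.3
    fraction_exact: float = 0.4
    fraction_censored_active: float = 0.35
    fraction_censored_inactive: float = 0.25
    active_threshold: float = 7.0  # eligibility threshold for censoring mimicry

    def __post_init__(self) -> None:
        total = (self.fraction_exact + self.fraction_censored_active
                 + self.fraction_censored_inactive)
        if not np.isclose(total, 1.0):
            raise ValueError("censoring fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_planted_model(effect_size: float = 1.5, n_effects: int = 5) -> PlantedModel:
    """Five substituent-specific fragment keys with equal effects of +1.5 pIC50."""
    scaffold = _SCAFFOLDS[0]
    keys = []
    for sub, motif in _DEFAULT_EFFECTS[:n_effects]:
        probe = _join(scaffold, [sub, "[*:1]C"])
        keys.append(motif_fragment_key(motif, probe))
    return PlantedModel(effects={k: effect_size for k in keys})


@dataclass
class SyntheticDataset:
    dataset: CuratedDataset
    ground_truth: list[dict]  # per record: noiseless, recorded, fragments, clipped
    planted: PlantedModel
    seed: int

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for r, g in zip(self.dataset.records, self.ground_truth):
            h.update(f"{r.record_id}|{r.source_smiles}|{r.ic50_qualifier}|"
                     f"{r.pic50!r}|{g['noiseless']!r}".encode())
        return h.hexdigest()


def assign_activity(
    smiles_list: Sequence[str],
    planted: PlantedModel,
    seed: int,
    min_bonds: int = DEFAULT_MIN_BONDS,
    max_bonds: int = DEFAULT_MAX_BONDS,
) -> SyntheticDataset:
    """Attach planted activities and censoring to sampled molecules.

    Censored-active records are drawn (seeded) from molecules whose true
    pIC50 clears the active threshold, censored-inactive from those
    below it; the recorded value becomes the corresponding entry bound.
    When too few molecules are eligible the censored groups are simply
    smaller — realized fractions land in the ground-truth manifest.
    """
    rng = np.random.default_rng(seed)
    n = len(smiles_list)
    keysets = [fragment_keys_of_smiles(s, min_bonds, max_bonds) for s in smiles_list]
    for f in planted.effects:
        producible = any(f in ks for ks in keysets) or not smiles_list
        if not producible:
            raise ValueError(f"planted fragment {f!r} occurs in no sampled molecule")
    noiseless = np.array([
        planted.baseline + sum(b for f, b in planted.effects.items() if f in ks)
        for ks in keysets
    ])
    noisy = noiseless + rng.normal(0.0, planted.noise_sd, size=n)
    lo, hi = PIC50_WINDOW
    recorded = np.clip(noisy, lo, hi)

    active = np.flatnonzero(noiseless >= planted.active_threshold)
    inactive = np.flatnonzero(noiseless < planted.active_threshold)
    n_ca = min(int(round(planted.fraction_censored_active * n)), len(active))
    n_ci = min(int(round(planted.fraction_censored_inactive * n)), len(inactive))
    censored_active = set(rng.choice(active, size=n_ca, replace=False)) if n_ca else set()
    censored_inactive = set(rng.choice(inactive, size=n_ci, replace=False)) if n_ci else set()

    records, truth = [], []
    for i, smi in enumerate(smiles_list):
        rid = f"syn{i:05d}"
        mol = Chem.MolFromSmiles(smi)
        if i in censored_active:
            bound = STRONG_ACTIVE_BOUND if recorded[i] >= 9 else ACTIVE_BOUND
            rec = ActivityRecord(rid, mol, smi, bound, "less_than")
        elif i in censored_inactive:
            rec = ActivityRecord(rid, mol, smi, INACTIVE_BOUND, "greater_than")
        else:
            rec = ActivityRecord(rid, mol, smi, 10.0 ** -recorded[i], "exact")
        records.append(rec)
        truth.append({
            "id": rid,
            "smiles": smi,
            "noiseless": float(noiseless[i]),
            "recorded_pic50": float(recorded[i]),
            "clipped": bool(noisy[i] != recorded[i]),
            "planted_present": sorted(f for f in planted.effects if f in keysets[i]),
            "qualifier": rec.ic50_qualifier,
        })
    return SyntheticDataset(CuratedDataset(records, []), truth, planted, seed)


@dataclass
class BenchmarkConfig:
    n: int = 600
    effect_size: float = 1.5
    n_effects: int = 5
    noise_sd: float = 0.3
    baseline: float = 5.5
    fraction_exact: float = 0.4
    fraction_censored_active: float = 0.35
    fraction_censored_inactive: float = 0.25
    min_bonds: int = DEFAULT_MIN_BONDS
    max_bonds: int = DEFAULT_MAX_BONDS

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown benchmark config fields: {sorted(unknown)}")
        return cls(**d)


def generate_benchmark(
    config: BenchmarkConfig | dict | None = None,
    seed: int = 0,
) -> tuple[SyntheticDataset, dict]:
    """End-to-end benchmark fixture plus a manifest for recovery tests."""
    if config is None:
        config = BenchmarkConfig()
    elif isinstance(config, dict):
        config = BenchmarkConfig.from_dict(config)
    planted = default_planted_model(config.effect_size, config.n_effects)
    planted.baseline = config.baseline
    planted.noise_sd = config.noise_sd
    planted.fraction_exact = config.fraction_exact
    planted.fraction_censored_active = config.fraction_censored_active
    planted.fraction_censored_inactive = config.fraction_censored_inactive
    grammar = default_grammar()
    smiles = sample_molecules(grammar, config.n, seed)
    data = assign_activity(smiles, planted, seed + 1,
                           config.min_bonds, config.max_bonds)
    manifest = {
        "seed": seed,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "planted_fragments": planted.effects,
        "baseline": planted.baseline,
        "noise_sd": planted.noise_sd,
        "n_records": len(data.dataset),
        "n_exact": sum(r.ic50_qualifier == "exact" for r in data.dataset.records),
        "active_fraction": float(np.mean([
            r.binary_label for r in data.dataset.records
            if r.binary_label is not None])),
        "dataset_hash": data.content_hash(),
    }
    return data, manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
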