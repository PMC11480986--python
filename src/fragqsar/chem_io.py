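"""Reading, standardization and curation of compound-activity records.

Activity is measured as IC50 (half-maximal inhibitory concentration,
stored in mol/L) and modeled on the pIC50 scale (-log10 of the molar
IC50).  Many database entries are censored: recorded only as a bound
("<0.1 uM" for actives, ">10 uM" for inactives) rather than an exact
measurement.  Censored records are usable for classification, where the
bound may determine the class, but never for regression.

Class conventions (configurable in :mod:`fragqsar.pipeline`):

* binary: active = 1 iff pIC50 >= 7 (IC50 <= 0.1 uM), else inactive = 0
* ternary: category 1 if pIC50 < 7, 2 if 7 <= pIC50 < 8, 3 if pIC50 >= 8

The boundary pIC50 = 7.0 itself counts as active; equality is
measure-zero in real data and a fixed convention keeps labels
deterministic.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

QUALIFIERS = ("exact", "less_than", "greater_than", "missing")

#: multiplicative factors to mol/L
_UNIT_FACTORS = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}

BINARY_BREAKPOINT = 7.0
TERNARY_BREAKPOINTS = (7.0, 8.0)


class UnitError(ValueError):
    """Raised for an activity value with an unrecognized concentration unit."""


def ic50_to_pic50(ic50: float) -> float:
    """pIC50 = -log10(IC50 in mol/L).  Requires ic50 > 0."""
    if ic50 is None or not ic50 > 0:
        raise ValueError(f"IC50 must be a positive molar concentration, got {ic50!r}")
    return -math.log10(ic50)


def assign_labels(
    pic50: float,
    qualifier: str = "exact",
    binary_breakpoint: float = BINARY_BREAKPOINT,
    ternary_breakpoints: tuple[float, float] = TERNARY_BREAKPOINTS,
) -> tuple[int | None, int | None]:
    """Derive (binary_label, ternary_label) from a pIC50 value or censoring bound.

    For exact records the value itself is classified.  For censored
    records the qualifier bounds the true pIC50: ``less_than`` on the
    IC50 means the true pIC50 lies *above* the bound, ``greater_than``
    means it lies *below*.  A label is assigned only when the entire
    feasible interval falls inside one class; otherwise it is left
    unset (None).
    """
    if qualifier not in QUALIFIERS:
        raise ValueError(f"unknown qualifier {qualifier!r}")
    if qualifier == "missing" or pic50 is None:
        return None, None
    b = binary_breakpoint
    t1, t2 = ternary_breakpoints

    def _interval_class(edges: Sequence[float]) -> int | None:
        # class c covers [edges[c-1], edges[c]) with edges[-1]=-inf, edges[last]=+inf
        bounds = [-math.inf, *edges, math.inf]
        for c in range(len(bounds) - 1):
            left, right = bounds[c], bounds[c + 1]
            if qualifier == "exact":
                if left <= pic50 < right:
                    return c + 1
            elif qualifier == "less_than":
                # true pIC50 in (bound, inf): class determined iff bound >= left
                # and the class is unbounded above
                if pic50 >= left and right == math.inf:
                    return c + 1
            else:
                # greater_than: true pIC50 in (-inf, bound): class determined
                # iff bound <= right and the class is unbounded below
                if pic50 <= right and left == -math.inf:
                    return c + 1
        return None

    bin_class = _interval_class([b])
    binary = None if bin_class is None else (1 if bin_class == 2 else 0)
    tern_class = _interval_class([t1, t2])
    return binary, tern_class


@dataclass
class ActivityRecord:
    """One curated compound with structure, activity and derived labels."""

    record_id: str
    mol: Chem.Mol | None
    source_smiles: str
    ic50_value: float | None  # mol/L
    ic50_qualifier: str = "exact"
    pic50: float | None = None
    binary_label: int | None = None
    ternary_label: int | None = None

    def __post_init__(self) -> None:
        if self.ic50_value is not None and self.pic50 is None:
            self.pic50 = ic50_to_pic50(self.ic50_value)
        if self.pic50 is not None and self.binary_label is None and self.ternary_label is None:
            self.binary_label, self.ternary_label = assign_labels(
                self.pic50, self.ic50_qualifier
            )

    @property
    def regression_eligible(self) -> bool:
        return self.ic50_qualifier == "exact" and self.pic50 is not None

    @property
    def canonical_key(self) -> str | None:
        if self.mol is None:
            return None
        return canonical_structure_key(self.mol)


@dataclass
class RawRecord:
    """One input row before curation; ``error`` carries a row-level flag."""

    row_index: int
    record_id: str
    smiles: str
    ic50_value: float | None  # mol/L
    ic50_qualifier: str
    mol: Chem.Mol | None = None
    error: str | None = None


@dataclass
class CuratedDataset:
    records: list[ActivityRecord]
    rejections: list[tuple[int | str, str]] = field(default_factory=list)

    @property
    def regression_subset_ids(self) -> list[str]:
        return [r.record_id for r in self.records if r.regression_eligible]

    def __len__(self) -> int:
        return len(self.records)


def canonical_structure_key(mol: Chem.Mol) -> str:
    """Deduplication key: canonical SMILES, aromatic, stereo/isotopes stripped."""
    m = Chem.Mol(mol)
    Chem.RemoveStereochemistry(m)
    for atom in m.GetAtoms():
        atom.SetIsotope(0)
    return Chem.MolToSmiles(m, isomericSmiles=False, canonical=True)


def _parse_value_qualifier(raw_value, raw_qualifier) -> tuple[float | None, str]:
    """Parse an activity value that may carry a '<'/'>' prefix or a qualifier column."""
    qualifier = "exact"
    if raw_qualifier is not None and str(raw_qualifier).strip() not in ("", "nan", "=", "None"):
        q = str(raw_qualifier).strip()
        mapping = {"<": "less_than", ">": "greater_than",
                   "less_than": "less_than", "greater_than": "greater_than",
                   "exact": "exact", "missing": "missing"}
        if q not in mapping:
            raise ValueError(f"unknown qualifier {q!r}")
        qualifier = mapping[q]
    text = "" if raw_value is None else str(raw_value).strip()
    if text.startswith("<"):
        qualifier, text = "less_than", text[1:].strip()
    elif text.startswith(">"):
        qualifier, text = "greater_than", text[1:].strip()
    if text in ("", "nan", "NA"):
        return None, "missing"
    return float(text), qualifier


def _to_molar(value: float | None, unit: str) -> float | None:
    if value is None:
        return None
    factor = _UNIT_FACTORS.get(str(unit).strip().lower())
    if factor is None:
        raise UnitError(f"unknown concentration unit {unit!r}")
    return value * factor


_DEFAULT_COLUMNS = {
    "id": "id",
    "structure": "smiles",
    "value": "ic50",
    "qualifier": "qualifier",
    "units": "units",
}


def read_activity_table(
    path,
    format: str = "csv",
    column_map: Mapping[str, str] | None = None,
) -> list[RawRecord]:
    """Read raw compound-activity records from CSV, SDF or a plain SMILES list.

    CSV columns are resolved through ``column_map`` (keys: id, structure,
    value, qualifier, units).  Units are converted to mol/L (M, mM, uM,
    nM, pM accepted); a censoring qualifier may come from its own column
    or from a '<'/'>' prefix on the value.  Unparseable structures are
    forwarded to curation flagged "no structural information"; an
    unknown unit raises :class:`UnitError` with the row index.
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    records: list[RawRecord] = []

    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                rid = str(row.get(cols["id"], f"row{i}"))
                smiles = (row.get(cols["structure"]) or "").strip()
                try:
                    value, qualifier = _parse_value_qualifier(
                        row.get(cols["value"]), row.get(cols["qualifier"])
                    )
                    unit = row.get(cols["units"], "M") or "M"
                    molar = _to_molar(value, unit)
                except UnitError as exc:
                    raise UnitError(f"row {i}: {exc}") from exc
                records.append(_make_raw(i, rid, smiles, molar, qualifier))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append(RawRecord(i, f"sdf{i}", "", None, "missing",
                                         None, "no structural information"))
                continue
            props = mol.GetPropsAsDict()
            rid = str(props.get(cols["id"], mol.GetProp("_Name") if mol.HasProp("_Name") else f"sdf{i}"))
            value, qualifier = _parse_value_qualifier(
                props.get(cols["value"]), props.get(cols["qualifier"])
            )
            molar = _to_molar(value, str(props.get(cols["units"], "M")))
            records.append(RawRecord(i, rid, Chem.MolToSmiles(mol), molar, qualifier, mol))
    elif format == "smiles-list":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                smiles = line.strip()
                if not smiles:
                    continue
                records.append(_make_raw(i, f"mol{i}", smiles, None, "missing"))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records


def _make_raw(i: int, rid: str, smiles: str, molar: float | None, qualifier: str) -> RawRecord:
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    error = None if mol is not None else "no structural information"
    return RawRecord(i, rid, smiles, molar, qualifier, mol, error)


def _bound_tightness(rec: RawRecord) -> float:
    # higher = more informative censoring bound
    p = ic50_to_pic50(rec.ic50_value)
    return p if rec.ic50_qualifier == "less_than" else -p


def curate(raw_records: Iterable[RawRecord]) -> CuratedDataset:
    """Standardize and filter raw records into a curated dataset.

    Rejects (with a logged reason): structureless rows, multi-component
    entries (salts/mixtures), non-organic structures (no carbon), and
    duplicates by canonical structure key.  Duplicates with several
    exact activities collapse to a single record carrying the median
    pIC50; duplicate groups with only censored activities keep the
    tightest bound.
    """
    rejections: list[tuple[int | str, str]] = []
    groups: dict[str, list[RawRecord]] = {}
    order: list[str] = []

    for rec in raw_records:
        if rec.mol is None and rec.smiles:
            rec.mol = Chem.MolFromSmiles(rec.smiles)
        if rec.mol is None:
            rejections.append((rec.row_index, "no structural information"))
            continue
        if len(Chem.GetMolFrags(rec.mol)) > 1:
            rejections.append((rec.row_index, "salt/mixture"))
            continue
        if not any(a.GetAtomicNum() == 6 for a in rec.mol.GetAtoms()):
            rejections.append((rec.row_index, "not an organic structure"))
            continue
        key = canonical_structure_key(rec.mol)
        if key in groups:
            rejections.append((rec.row_index, "duplicate"))
        else:
            order.append(key)
        groups.setdefault(key, []).append(rec)

    records: list[ActivityRecord] = []
    for key in order:
        members = groups[key]
        exact = [m for m in members if m.ic50_qualifier == "exact" and m.ic50_value]
        censored = [m for m in members if m.ic50_qualifier in ("less_than", "greater_than")
                    and m.ic50_value]
        if exact:
            rep = exact[0]
            pic = median(ic50_to_pic50(m.ic50_value) for m in exact)
            records.append(ActivityRecord(rep.record_id, rep.mol, rep.smiles,
                                          10.0 ** -pic, "exact"))
        elif censored:
            rep = max(censored, key=_bound_tightness)
            records.append(ActivityRecord(rep.record_id, rep.mol, rep.smiles,
                                          rep.ic50_value, rep.ic50_qualifier))
        else:
            rep = members[0]
            records.append(ActivityRecord(rep.record_id, rep.mol, rep.smiles,
                                          None, "missing"))
    return CuratedDataset(records, rejections)


def regression_subset(dataset: CuratedDataset) -> CuratedDataset:
    """Restrict to exact-measurement records (the only regression-eligible ones)."""
    records = [r for r in dataset.records if r.regression_eligible]
    if not records:
        raise ValueError("no exact measurements: regression subset is empty")
    return CuratedDataset(records, [])


def write_curated_csv(dataset: CuratedDataset, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "ic50_molar", "qualifier",
                         "pic50", "binary_label", "ternary_label"])
        for r in dataset.records:
            writer.writerow([
                r.record_id, Chem.MolToSmiles(r.mol) if r.mol is not None else "",
                r.ic50_value if r.ic50_value is not None else "",
                r.ic50_qualifier,
                f"{r.pic50:.6g}" if r.pic50 is not None else "",
                r.binary_label if r.binary_label is not None else "",
                r.ternary_label if r.ternary_label is not None else "",
            ])


def write_rejection_log(dataset: CuratedDataset, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("row\treason\n")
        for row, reason in dataset.rejections:
            fh.write(f"{row}\t{reason}\n")


def read_curated_csv(path) -> CuratedDataset:
    """Read back a dataset written by :func:`write_curated_csv` (no re-curation)."""
    records = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            mol = Chem.MolFromSmiles(row["smiles"]) if row["smiles"] else None
            value = float(row["ic50_molar"]) if row["ic50_molar"] else None
            records.append(ActivityRecord(row["id"], mol, row["smiles"],
                                          value, row["qualifier"]))
    return CuratedDataset(records, [])
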