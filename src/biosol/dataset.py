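"""Loading, validation and summary of biorelevant solubility datasets.

A dataset is a collection of compounds with physicochemical properties and
apparent solubility (log10 molar) in up to three media: blank phosphate
buffer pH 6.5 (``phb``), fasted-state simulated intestinal fluid
(``fassif``) and aspirated human intestinal fluid (``hif``). Missing
measurements are explicit (``None`` in records, empty cells in CSV), never
imputed at this layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Medium",
    "CompoundRecord",
    "SolubilityDataset",
    "SummaryStats",
    "load_dataset",
    "load_fixture",
    "save_dataset",
    "summarize",
    "paired_values",
    "filter_lipophilic",
]


class Medium(str, Enum):
    """Solubility medium identifiers."""

    PHB65 = "phb"
    FASSIF = "fassif"
    HIF = "hif"

    @classmethod
    def coerce(cls, value: "Medium | str") -> "Medium":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        aliases = {
            "phb": cls.PHB65, "phb65": cls.PHB65, "phb_ph6.5": cls.PHB65,
            "buffer": cls.PHB65, "fassif": cls.FASSIF, "hif": cls.HIF,
        }
        if key not in aliases:
            raise ValueError(f"unknown medium: {value!r}")
        return aliases[key]


_MEDIUM_COLUMN = {
    Medium.PHB65: "logs_phb",
    Medium.FASSIF: "logs_fassif",
    Medium.HIF: "logs_hif",
}

#: canonical CSV column order
CSV_COLUMNS = [
    "name", "smiles", "set", "mw", "logd65", "psa", "rotb",
    "logs_phb", "logs_fassif", "logs_hif", "tm_c",
]

_MANDATORY = ["name", "mw", "logd65", "psa", "rotb"]


class DatasetError(ValueError):
    """Validation, schema or parse failure while handling a dataset."""


@dataclass(frozen=True)
class CompoundRecord:
    """One drug: identity, physicochemical properties, per-medium log S_app.

    Solubilities are log10 molar; ``tm_c`` is the melting point in deg C of
    the free acid/base. Any solubility and the melting point may be absent.
    """

    name: str
    mw: float
    logd65: float
    psa: float
    rotb: int
    smiles: str | None = None
    set_label: str | None = None
    logs_phb: float | None = None
    logs_fassif: float | None = None
    logs_hif: float | None = None
    tm_c: float | None = None

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise DatasetError("compound name must be non-empty")
        if self.set_label is not None and self.set_label not in ("Tr", "Te"):
            raise DatasetError(
                f"{self.name}: set label must be 'Tr' or 'Te', got {self.set_label!r}")
        if not self.mw > 0:
            raise DatasetError(f"{self.name}: mw must be positive")
        if self.psa < 0:
            raise DatasetError(f"{self.name}: psa must be non-negative")
        if self.rotb < 0 or int(self.rotb) != self.rotb:
            raise DatasetError(f"{self.name}: rotb must be a non-negative integer")
        for med, col in _MEDIUM_COLUMN.items():
            v = getattr(self, col)
            if v is not None and not (-12.0 <= v <= 0.0):
                raise DatasetError(
                    f"{self.name}: log solubility in {med.value} out of [-12, 0]: {v}")
        if self.tm_c is not None and not (0.0 <= self.tm_c <= 400.0):
            raise DatasetError(f"{self.name}: tm_c out of [0, 400]: {self.tm_c}")

    def solubility(self, medium: Medium | str) -> float | None:
        return getattr(self, _MEDIUM_COLUMN[Medium.coerce(medium)])


@dataclass(frozen=True)
class SummaryStats:
    """Min/max/median of log S_app in one medium over non-missing values."""

    medium: Medium
    n: int
    min: float
    max: float
    median: float

    @property
    def fold_range(self) -> float:
        """Linear-scale ratio between the most and least soluble compound."""
        return 10.0 ** (self.max - self.min)


class SolubilityDataset:
    """Ordered, name-unique collection of :class:`CompoundRecord`."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self.records: list[CompoundRecord] = list(records)
        if not self.records:
            raise DatasetError("dataset must contain at least one record")
        seen: dict[str, str] = {}
        for r in self.records:
            key = r.name.casefold()
            if key in seen:
                raise DatasetError(f"duplicate compound name: {r.name!r}")
            seen[key] = r.name

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, name: str) -> CompoundRecord:
        key = name.casefold()
        for r in self.records:
            if r.name.casefold() == key:
                return r
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def medium_mask(self, medium: Medium | str) -> list[bool]:
        med = Medium.coerce(medium)
        return [r.solubility(med) is not None for r in self.records]

    def subset(self, names: Sequence[str]) -> "SolubilityDataset":
        wanted = {n.casefold() for n in names}
        return SolubilityDataset([r for r in self.records if r.name.casefold() in wanted])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "name": r.name, "smiles": r.smiles, "set": r.set_label,
                "mw": r.mw, "logd65": r.logd65, "psa": r.psa, "rotb": r.rotb,
                "logs_phb": r.logs_phb, "logs_fassif": r.logs_fassif,
                "logs_hif": r.logs_hif, "tm_c": r.tm_c,
            })
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _cell(value, row: int, column: str, kind=float):
    if value is None:
        return None
    if isinstance(value, str):
        value = value.replace("−", "-").strip()
        if value == "":
            return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        return kind(float(value))
    except (TypeError, ValueError):
        raise DatasetError(
            f"non-numeric value {value!r} at row {row}, column {column!r}") from None


def _records_from_frame(df: pd.DataFrame) -> list[CompoundRecord]:
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise DatasetError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        name = row.get("name")
        if name is None or (isinstance(name, float) and math.isnan(name)) or not str(name).strip():
            raise DatasetError(f"empty compound name at row {i}")
        smiles = row.get("smiles")
        if smiles is not None and (not isinstance(smiles, str) or not smiles.strip()):
            smiles = None
        set_label = row.get("set")
        if isinstance(set_label, float) and math.isnan(set_label):
            set_label = None
        if isinstance(set_label, str):
            set_label = set_label.strip() or None
        records.append(CompoundRecord(
            name=str(name).strip(),
            smiles=smiles,
            set_label=set_label,
            mw=_cell(row["mw"], i, "mw"),
            logd65=_cell(row["logd65"], i, "logd65"),
            psa=_cell(row["psa"], i, "psa"),
            rotb=int(_cell(row["rotb"], i, "rotb")),
            logs_phb=_cell(row.get("logs_phb"), i, "logs_phb"),
            logs_fassif=_cell(row.get("logs_fassif"), i, "logs_fassif"),
            logs_hif=_cell(row.get("logs_hif"), i, "logs_hif"),
            tm_c=_cell(row.get("tm_c"), i, "tm_c"),
        ))
    return records


def load_dataset(source: str | Path) -> SolubilityDataset:
    """Load a dataset from a CSV file or the bundled fixture id ``"table1"``.

    Missing cells become explicit ``None`` values. Raises
    :class:`DatasetError` for duplicate names, non-numeric cells or missing
    mandatory columns.
    """
    if str(source) == "table1":
        return load_fixture()
    path = Path(source)
    if not path.exists():
        raise DatasetError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise DatasetError(f"empty file: {path}") from None
    return SolubilityDataset(_records_from_frame(df))


def load_fixture() -> SolubilityDataset:
    """Load the bundled curated 86-compound table."""
    with resources.files("biosol.data").joinpath("table1.csv").open("r") as fh:
        df = pd.read_csv(fh, dtype=str)
    return SolubilityDataset(_records_from_frame(df))


def save_dataset(ds: SolubilityDataset, path: str | Path) -> None:
    """Write a dataset as canonical CSV; absent values become empty cells."""
    ds.to_frame().to_csv(path, index=False)


def load_smiles_sidecar(ds: SolubilityDataset, path: str | Path) -> SolubilityDataset:
    """Attach SMILES from a two-column (name, smiles) sidecar CSV.

    Names not present in the dataset are ignored; existing SMILES are
    overwritten by sidecar entries.
    """
    import dataclasses

    df = pd.read_csv(path, dtype=str)
    df = df.rename(columns={c: str(c).strip().lower() for c in df.columns})
    if not {"name", "smiles"} <= set(df.columns):
        raise DatasetError("sidecar must have 'name' and 'smiles' columns")
    lookup = {str(n).casefold(): s for n, s in zip(df["name"], df["smiles"])
              if isinstance(s, str) and s.strip()}
    records = []
    for r in ds:
        smiles = lookup.get(r.name.casefold())
        records.append(dataclasses.replace(r, smiles=smiles) if smiles else r)
    return SolubilityDataset(records)


def summarize(ds: SolubilityDataset, medium: Medium | str) -> SummaryStats:
    """Min/max/median log solubility over the non-missing values of a medium.

    The median for even n is the mean of the two central values.
    """
    med = Medium.coerce(medium)
    values = sorted(v for r in ds if (v := r.solubility(med)) is not None)
    if not values:
        raise DatasetError(f"no values present in medium {med.value}")
    n = len(values)
    median = (values[(n - 1) // 2] + values[n // 2]) / 2.0
    return SummaryStats(medium=med, n=n, min=values[0], max=values[-1], median=median)


def paired_values(
    ds: SolubilityDataset, medium_a: Medium | str, medium_b: Medium | str
) -> tuple[list[float], list[float], list[str]]:
    """Complete-case value vectors for two media, in dataset order.

    Returns ``(values_a, values_b, names)`` restricted to compounds with a
    measurement in both media.
    """
    med_a, med_b = Medium.coerce(medium_a), Medium.coerce(medium_b)
    if med_a == med_b:
        raise DatasetError("media must differ")
    xs, ys, names = [], [], []
    for r in ds:
        va, vb = r.solubility(med_a), r.solubility(med_b)
        if va is not None and vb is not None:
            xs.append(va)
            ys.append(vb)
            names.append(r.name)
    if not names:
        raise DatasetError(f"no complete cases for {med_a.value} vs {med_b.value}")
    return xs, ys, names


def filter_lipophilic(
    ds: SolubilityDataset, logp_values: Mapping[str, float], threshold: float = 2.0
) -> SolubilityDataset:
    """Retain compounds with calculated logP strictly above ``threshold``.

    ``logp_values`` maps compound name to calculated logP and must cover the
    whole dataset; a missing entry is an error, never a silent drop.
    """
    lookup = {k.casefold(): v for k, v in logp_values.items()}
    absent = [r.name for r in ds if r.name.casefold() not in lookup]
    if absent:
        raise DatasetError(f"missing logP for: {', '.join(absent)}")
    kept = [r for r in ds if lookup[r.name.casefold()] > threshold]
    if not kept:
        raise DatasetError("no compounds pass the lipophilicity filter")
    return SolubilityDataset(kept)
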