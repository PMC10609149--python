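"""Data model and I/O: metabolite tables, descriptor matrices, SMILES descriptors.

The working representations are :class:`MetaboliteTable` (raw records with
p-values, fold changes and labels) and :class:`DescriptorMatrix` (a named,
fully numeric feature matrix).  A small built-in descriptor backend computes
deterministic string-derived features from SMILES so the whole pipeline is
runnable without any cheminformatics engine; an optional RDKit-backed engine
provides real molecular descriptors.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CapabilityError, FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TopLabel",
    "SubLabel",
    "MetaboliteRecord",
    "MetaboliteTable",
    "DescriptorMatrix",
    "LabeledDataset",
    "parse_label",
    "read_metabolite_table",
    "write_metabolite_table",
    "read_descriptor_matrix",
    "write_descriptor_matrix",
    "compute_descriptors",
    "BUILTIN_DESCRIPTOR_NAMES",
]


class TopLabel(str, enum.Enum):
    """Top-level split: non-small-cell (NS) vs small-cell (SC)."""

    NS = "NS"
    SC = "SC"


class SubLabel(str, enum.Enum):
    """Subtype within NS: adenocarcinoma (AD) or squamous (SQ); NONE otherwise."""

    AD = "AD"
    SQ = "SQ"
    NONE = "NONE"


#: Accepted label spellings (case-insensitive) -> (top, sub).
_LABEL_SYNONYMS: dict[str, tuple[TopLabel, SubLabel]] = {
    "NS": (TopLabel.NS, SubLabel.NONE),
    "NSCLC": (TopLabel.NS, SubLabel.NONE),
    "SC": (TopLabel.SC, SubLabel.NONE),
    "SCLC": (TopLabel.SC, SubLabel.NONE),
    "AD": (TopLabel.NS, SubLabel.AD),
    "ADENOCARCINOMA": (TopLabel.NS, SubLabel.AD),
    "LUAD": (TopLabel.NS, SubLabel.AD),
    "SQ": (TopLabel.NS, SubLabel.SQ),
    "SCC": (TopLabel.NS, SubLabel.SQ),
    "LUSC": (TopLabel.NS, SubLabel.SQ),
    "SQUAMOUS": (TopLabel.NS, SubLabel.SQ),
}


def parse_label(raw: str) -> tuple[TopLabel, SubLabel]:
    """Map a free-form class label to (top_label, sub_label).

    AD/SQ imply top label NS; unknown labels raise :class:`FormatError`.
    """
    key = str(raw).strip().upper()
    try:
        return _LABEL_SYNONYMS[key]
    except KeyError:
        raise FormatError(f"unrecognized class label {raw!r}") from None


@dataclass
class MetaboliteRecord:
    """One metabolite: identity, filter statistics and class labels."""

    name: str
    p_value: float
    fold_change: float
    top_label: TopLabel
    sub_label: SubLabel = SubLabel.NONE
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("metabolite name must be non-empty")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(
                f"p_value must be in [0, 1], got {self.p_value} for {self.name!r}"
            )
        if not self.fold_change > 0:
            raise ValidationError(
                f"fold_change must be > 0, got {self.fold_change} for {self.name!r}"
            )
        if self.sub_label != SubLabel.NONE and self.top_label != TopLabel.NS:
            raise ValidationError(
                f"sub_label {self.sub_label.value} requires top_label NS "
                f"(got {self.top_label.value}) for {self.name!r}"
            )


@dataclass
class MetaboliteTable:
    """Ordered collection of records with unique names."""

    records: list[MetaboliteRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate metabolite names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]


@dataclass
class DescriptorMatrix:
    """Real-valued feature matrix with named rows (metabolites) and columns."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("descriptor values must be a 2-D matrix")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("row_ids must be unique")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValidationError("col_ids must be unique")
        if not np.isfinite(self.values).all():
            raise ValidationError("descriptor matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def select_columns(self, cols: Sequence[str]) -> "DescriptorMatrix":
        """Restrict to the given columns, in the given order."""
        index = {c: i for i, c in enumerate(self.col_ids)}
        missing = [c for c in cols if c not in index]
        if missing:
            raise ValidationError(f"unknown descriptor columns: {missing}")
        idx = [index[c] for c in cols]
        return DescriptorMatrix(list(self.row_ids), list(cols), self.values[:, idx])

    def select_rows(self, mask: np.ndarray) -> "DescriptorMatrix":
        mask = np.asarray(mask)
        rows = [r for r, m in zip(self.row_ids, mask) if m]
        return DescriptorMatrix(rows, list(self.col_ids), self.values[mask])


@dataclass
class LabeledDataset:
    """Descriptor matrix plus aligned two-level labels."""

    descriptors: DescriptorMatrix
    top_labels: list[TopLabel]
    sub_labels: list[SubLabel]

    def __post_init__(self) -> None:
        n = len(self.descriptors.row_ids)
        if len(self.top_labels) != n or len(self.sub_labels) != n:
            raise ValidationError("label arrays must align with matrix rows")
        for name, top, sub in zip(self.descriptors.row_ids, self.top_labels, self.sub_labels):
            if sub != SubLabel.NONE and top != TopLabel.NS:
                raise ValidationError(
                    f"sub_label {sub.value} requires top_label NS for row {name!r}"
                )

    def __len__(self) -> int:
        return len(self.top_labels)

    def subset(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = list(idx)
        mask = np.zeros(len(self), dtype=bool)
        mask[idx] = True
        return LabeledDataset(
            self.descriptors.select_rows(mask),
            [self.top_labels[i] for i in range(len(self)) if mask[i]],
            [self.sub_labels[i] for i in range(len(self)) if mask[i]],
        )

    def leaf_labels(self) -> list[str]:
        """Flattened labels: AD/SQ for NS subtypes, otherwise the top label."""
        return [
            sub.value if sub != SubLabel.NONE else top.value
            for top, sub in zip(self.top_labels, self.sub_labels)
        ]


_REQUIRED_TABLE_COLUMNS = ("name", "p_value", "fold_change", "label")


def read_metabolite_table(path: str | Path, dialect: str = "csv") -> MetaboliteTable:
    """Read a metabolite table from CSV/TSV.

    Required columns: name, p_value, fold_change, label; optional: smiles.
    Labels are mapped case-insensitively (AD/SQ imply NS at the top level).
    Rows whose numeric fields do not parse are dropped with a logged warning
    naming the offending row indices.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in _REQUIRED_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    records: list[MetaboliteRecord] = []
    rejected: list[int] = []
    for i, row in df.iterrows():
        try:
            p = float(row["p_value"])
            fc = float(row["fold_change"])
        except (TypeError, ValueError):
            rejected.append(int(i))
            continue
        top, sub = parse_label(row["label"])
        smiles = row.get("smiles")
        if smiles is not None and (pd.isna(smiles) or smiles == ""):
            smiles = None
        records.append(
            MetaboliteRecord(
                name=str(row["name"]),
                p_value=p,
                fold_change=fc,
                top_label=top,
                sub_label=sub,
                smiles=smiles,
            )
        )
    if rejected:
        logger.warning(
            "rejected %d row(s) with unparseable numerics at indices %s",
            len(rejected),
            rejected,
        )
    return MetaboliteTable(records)


def write_metabolite_table(
    table: MetaboliteTable, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a table in the format :func:`read_metabolite_table` accepts."""
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValidationError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    rows = []
    for r in table:
        label = r.sub_label.value if r.sub_label != SubLabel.NONE else r.top_label.value
        rows.append(
            {
                "name": r.name,
                "smiles": r.smiles or "",
                "p_value": repr(r.p_value),
                "fold_change": repr(r.fold_change),
                "label": label,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_descriptor_matrix(path: str | Path) -> DescriptorMatrix:
    """Read a descriptor matrix CSV (first column = metabolite name).

    Missing cells are imputed with the column median; columns that are
    entirely missing are dropped.  Both events are logged.  Non-numeric
    cells raise :class:`FormatError` with their coordinates.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValidationError(f"empty or column-less descriptor matrix in {path}")
    name_col = df.columns[0]
    row_ids = [str(v) for v in df[name_col]]
    data = df.drop(columns=[name_col])

    values = np.empty(data.shape, dtype=float)
    for j, col in enumerate(data.columns):
        for i, cell in enumerate(data[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or (
                isinstance(cell, str) and cell.strip() == ""
            ):
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col!r}"
                ) from None

    n_imputed = 0
    keep: list[int] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        missing = np.isnan(col)
        if missing.all():
            logger.warning("dropping all-missing descriptor column %r", data.columns[j])
            continue
        if missing.any():
            col[missing] = np.median(col[~missing])
            n_imputed += int(missing.sum())
        keep.append(j)
    if n_imputed:
        logger.info("imputed %d missing descriptor cell(s) with column medians", n_imputed)
    return DescriptorMatrix(row_ids, [data.columns[j] for j in keep], values[:, keep])


def write_descriptor_matrix(matrix: DescriptorMatrix, path: str | Path) -> None:
    """Write a matrix in the format :func:`read_descriptor_matrix` accepts."""
    df = pd.DataFrame(matrix.values, columns=matrix.col_ids)
    df.insert(0, "name", matrix.row_ids)
    df.to_csv(path, index=False, float_format="%.17g")


# --- SMILES -> descriptor adapters -----------------------------------------

BUILTIN_DESCRIPTOR_NAMES = [
    "smiles_length",
    "n_carbon",
    "n_nitrogen",
    "n_oxygen",
    "n_sulfur",
    "n_phosphorus",
    "n_ring_digits",
    "branch_depth",
    "n_charge_symbols",
    "n_aromatic_lower",
    "n_double_bonds",
    "n_triple_bonds",
]

# two-letter organic-subset symbols masked before single-letter atom counting
_TWO_LETTER = re.compile(r"Cl|Br|Si|Se|Na|Li|Mg|Ca|Fe|Zn")


def _builtin_row(smiles: str) -> list[float]:
    masked = _TWO_LETTER.sub("", smiles)
    depth = best = 0
    for ch in smiles:
        if ch == "(":
            depth += 1
            best = max(best, depth)
        elif ch == ")":
            depth = max(depth - 1, 0)
    return [
        float(len(smiles)),
        float(masked.count("C")),
        float(masked.count("N")),
        float(masked.count("O")),
        float(masked.count("S")),
        float(masked.count("P")),
        float(sum(ch.isdigit() for ch in smiles)),
        float(best),
        float(smiles.count("+") + smiles.count("-")),
        float(sum(smiles.count(ch) for ch in "cnosp")),
        float(smiles.count("=")),
        float(smiles.count("#")),
    ]


def compute_descriptors(
    smiles_list: Sequence[str],
    backend: str = "builtin_count",
    names: Iterable[str] | None = None,
) -> DescriptorMatrix:
    """Compute a descriptor matrix from SMILES strings.

    ``builtin_count`` derives >=10 deterministic string features per SMILES
    (no chemistry engine needed).  ``external_engine`` delegates to RDKit's
    full 2-D descriptor set when RDKit is importable.
    """
    row_ids = list(names) if names is not None else [f"mol{i}" for i in range(len(smiles_list))]
    if len(row_ids) != len(smiles_list):
        raise ValidationError("names and smiles_list lengths differ")
    empty = [row_ids[i] for i, s in enumerate(smiles_list) if not s]
    if empty:
        raise ValidationError(f"empty SMILES for records: {empty}")

    if backend == "builtin_count":
        values = np.array([_builtin_row(s) for s in smiles_list], dtype=float)
        return DescriptorMatrix(row_ids, list(BUILTIN_DESCRIPTOR_NAMES), values)

    if backend == "external_engine":
        try:
            from rdkit import Chem
            from rdkit.Chem import Descriptors
        except ImportError:
            raise CapabilityError(
                "no external descriptor engine installed; use backend="
                "'builtin_count' or supply a precomputed descriptor matrix"
            ) from None
        mols, bad = [], []
        for rid, s in zip(row_ids, smiles_list):
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                bad.append(rid)
            mols.append(mol)
        if bad:
            raise FormatError(f"unparseable SMILES for records: {bad}")
        rows = [Descriptors.CalcMolDescriptors(m) for m in mols]
        cols = list(rows[0].keys())
        values = np.array([[float(r[c]) for c in cols] for r in rows], dtype=float)
        # RDKit can emit NaN for a few descriptors on exotic inputs
        for j in range(values.shape[1]):
            col = values[:, j]
            miss = ~np.isfinite(col)
            if miss.any() and not miss.all():
                col[miss] = np.median(col[~miss])
            elif miss.all():
                col[:] = 0.0
        return DescriptorMatrix(row_ids, cols, values)

    raise ValidationError(
        f"backend must be 'builtin_count' or 'external_engine', got {backend!r}"
    )
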