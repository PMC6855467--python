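"""Compound–descriptor–property tables and reproducible train/test splits.

A QSPR dataset is a plain table: one row per compound, an identifier
column, numeric molecular-descriptor columns (computed externally, e.g. by
Dragon), and one property column holding the experimental flammability
limit in volume percent.  This module reads and writes such tables
(CSV/TSV and XLSX), validates them strictly, and produces the random
80/20-style partitions used for model training and testing.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PropertyKind",
    "DescriptorDataset",
    "SplitIndices",
    "DatasetFormatError",
    "DatasetValidationError",
    "EmptyDatasetError",
    "read_dataset",
    "write_dataset",
    "split_dataset",
    "write_split",
]


class DatasetFormatError(ValueError):
    """Raised when a table lacks required columns or has a bad layout."""


class DatasetValidationError(ValueError):
    """Raised when table contents violate dataset invariants."""


class EmptyDatasetError(DatasetValidationError):
    """Raised when validation leaves zero usable rows."""


class PropertyKind(enum.Enum):
    LFL = "LFL"
    UFL = "UFL"
    OTHER = "other"


@dataclass
class DescriptorDataset:
    """Compounds × descriptors matrix plus the measured property vector.

    Attributes
    ----------
    compound_ids : list of str
        Opaque identifiers (CAS numbers or names), unique.
    descriptor_names : list of str
        Ordered labels of the ``n`` descriptor columns, unique.
    X : (N, n) ndarray
        Descriptor values, finite, no missing entries.
    Y : (N,) ndarray
        Experimental property values (volume percent for LFL/UFL).
    property_kind : PropertyKind
        LFL and UFL require strictly positive Y.
    property_name : str
        Original property column name, kept for round-tripping.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    Y: np.ndarray
    property_kind: PropertyKind = PropertyKind.OTHER
    property_name: str = "Y"
    id_name: str = "compound_id"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2:
            raise DatasetValidationError("X must be a 2-D matrix")
        N, n = self.X.shape
        if N < 1 or n < 1:
            raise EmptyDatasetError("dataset must have at least one row and one descriptor")
        if len(self.compound_ids) != N or len(self.Y) != N:
            raise DatasetValidationError(
                f"row-count mismatch: X has {N} rows, "
                f"{len(self.compound_ids)} ids, {len(self.Y)} property values"
            )
        if len(self.descriptor_names) != n:
            raise DatasetValidationError("descriptor_names length must match X columns")
        dupes = _duplicates(self.compound_ids)
        if dupes:
            raise DatasetValidationError(f"duplicate compound ids: {sorted(dupes)}")
        dupes = _duplicates(self.descriptor_names)
        if dupes:
            raise DatasetValidationError(f"duplicate descriptor names: {sorted(dupes)}")
        if not np.all(np.isfinite(self.X)):
            raise DatasetValidationError("X contains non-finite values")
        if not np.all(np.isfinite(self.Y)):
            raise DatasetValidationError("Y contains non-finite values")
        if self.property_kind in (PropertyKind.LFL, PropertyKind.UFL) and np.any(self.Y <= 0):
            bad = [self.compound_ids[i] for i in np.nonzero(self.Y <= 0)[0][:5]]
            raise DatasetValidationError(
                f"{self.property_kind.value} values must be positive volume percent; "
                f"offending compounds include {bad}"
            )

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def descriptor_index(self, name: str) -> int:
        try:
            return self.descriptor_names.index(name)
        except ValueError:
            raise DatasetFormatError(f"descriptor column {name!r} not found") from None

    def subset(self, idx: np.ndarray) -> "DescriptorDataset":
        """Row subset preserving column order (used for train/test views)."""
        idx = np.asarray(idx, dtype=int)
        return DescriptorDataset(
            compound_ids=[self.compound_ids[i] for i in idx],
            descriptor_names=list(self.descriptor_names),
            X=self.X[idx],
            Y=self.Y[idx],
            property_kind=self.property_kind,
            property_name=self.property_name,
            id_name=self.id_name,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.descriptor_names)
        df.insert(0, self.id_name, self.compound_ids)
        df[self.property_name] = self.Y
        return df


@dataclass(frozen=True)
class SplitIndices:
    """A disjoint train/test partition of ``0..N-1``.

    Train size is ``round-half-up(fraction * N)``; this reproduces 846/211
    from N=1057 and 412/103 from N=515 at fraction 0.8.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float
    seed: int
    n_total: int = field(default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "train_idx", np.asarray(self.train_idx, dtype=int))
        object.__setattr__(self, "test_idx", np.asarray(self.test_idx, dtype=int))
        if self.n_total == 0:
            object.__setattr__(self, "n_total", len(self.train_idx) + len(self.test_idx))
        combined = np.concatenate([self.train_idx, self.test_idx])
        if len(np.unique(combined)) != self.n_total or combined.min(initial=0) < 0:
            raise DatasetValidationError("train/test indices must partition 0..N-1")


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup


def _train_size(fraction: float, N: int) -> int:
    # round-half-up, matching the printed split sizes (845.6 -> 846)
    return int(math.floor(fraction * N + 0.5))


def read_dataset(
    path,
    id_column: str = "compound_id",
    property_column: str = "LFL",
    property_kind: PropertyKind | str | None = None,
    sheet_name: str | int = 0,
    lenient: bool = False,
) -> DescriptorDataset:
    """Read a delimited table or spreadsheet into a validated dataset.

    Parameters
    ----------
    path
        CSV/TSV file (header row, ``.`` decimal separator) or an XLSX
        workbook; the extension selects the reader.
    id_column, property_column
        Names of the identifier and property columns; every remaining
        column is taken as a numeric descriptor.
    property_kind
        LFL/UFL/other; inferred from ``property_column`` when omitted.
    lenient
        When true, rows with missing or non-numeric entries are dropped
        (count logged) instead of rejecting the file.
    """
    spath = str(path)
    if spath.endswith((".xlsx", ".xls")):
        df = pd.read_excel(path, sheet_name=sheet_name)
    elif spath.endswith((".tsv", ".tab")):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    return dataset_from_frame(
        df,
        id_column=id_column,
        property_column=property_column,
        property_kind=property_kind,
        lenient=lenient,
    )


def dataset_from_frame(
    df: pd.DataFrame,
    id_column: str = "compound_id",
    property_column: str = "LFL",
    property_kind: PropertyKind | str | None = None,
    lenient: bool = False,
) -> DescriptorDataset:
    """Validate an in-memory table (same contract as :func:`read_dataset`)."""
    for col in (id_column, property_column):
        if col not in df.columns:
            raise DatasetFormatError(f"required column {col!r} missing from table")
    if property_kind is None:
        upper = property_column.upper()
        property_kind = PropertyKind(upper) if upper in ("LFL", "UFL") else PropertyKind.OTHER
    elif isinstance(property_kind, str):
        property_kind = PropertyKind(property_kind) if property_kind in ("LFL", "UFL") else PropertyKind.OTHER

    descriptor_cols = [c for c in df.columns if c not in (id_column, property_column)]
    if not descriptor_cols:
        raise DatasetFormatError("table has no descriptor columns")

    numeric = df[descriptor_cols + [property_column]].apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.isna().any(axis=1)
    if bad_rows.any():
        if not lenient:
            bad_cols = numeric.columns[numeric.isna().any(axis=0)].tolist()
            raise DatasetValidationError(
                f"{int(bad_rows.sum())} row(s) contain missing or non-numeric values "
                f"in columns {bad_cols}; pass lenient=True to drop them"
            )
        logger.warning("dropping %d row(s) with missing/non-numeric entries", int(bad_rows.sum()))
        df = df.loc[~bad_rows]
        numeric = numeric.loc[~bad_rows]
    if len(df) == 0:
        raise EmptyDatasetError("no usable rows after validation")

    return DescriptorDataset(
        compound_ids=[str(v) for v in df[id_column]],
        descriptor_names=descriptor_cols,
        X=numeric[descriptor_cols].to_numpy(dtype=float),
        Y=numeric[property_column].to_numpy(dtype=float),
        property_kind=property_kind,
        property_name=property_column,
        id_name=id_column,
    )


def write_dataset(ds: DescriptorDataset, path) -> None:
    """Write as CSV; floats use shortest round-trip repr so read/write is lossless."""
    ds.to_frame().to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def split_dataset(ds: DescriptorDataset, fraction: float = 0.8, seed: int = 0) -> SplitIndices:
    """Uniform random train/test partition, deterministic given ``seed``.

    Raises if the fraction would leave either side empty.
    """
    N = ds.n_compounds
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if N < 2:
        raise DatasetValidationError("need at least 2 rows to split")
    n_train = _train_size(fraction, N)
    if n_train < 1 or n_train >= N:
        raise DatasetValidationError(
            f"fraction {fraction} yields an empty train or test set for N={N}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(N)
    return SplitIndices(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
        fraction=fraction,
        seed=seed,
        n_total=N,
    )


def write_split(ds: DescriptorDataset, split: SplitIndices, path) -> None:
    """Export a split as a two-column CSV (compound_id, subset)."""
    subset = np.empty(ds.n_compounds, dtype=object)
    subset[split.train_idx] = "train"
    subset[split.test_idx] = "test"
    pd.DataFrame({"compound_id": ds.compound_ids, "subset": subset}).to_csv(path, index=False)
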