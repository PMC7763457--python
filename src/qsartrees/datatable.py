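"""Typed molecular-descriptor tables: reading, validation, summaries, splits.

A descriptor table is the currency of the whole pipeline: an N x p matrix of
numeric descriptor values, a binary activity label per row (``RB`` = ready
biodegradable, the positive minority class; ``NRB`` = not ready biodegradable),
and a schema assigning each descriptor one of three measurement kinds —
``continuous``, ``ordinal`` (non-negative counts) or ``flag`` (0/1 presence).
The kind matters downstream: screening routes continuous features to an
F-test and ordinal/flag features to a likelihood-ratio chi-square test, and
the tree builders threshold continuous/ordinal features while flags induce
the natural 0/1 partition.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

RB = "RB"
NRB = "NRB"
KINDS = ("continuous", "ordinal", "flag")

#: default mapping of file label tokens onto the internal classes
DEFAULT_LABEL_MAP: dict[str, str] = {
    "RB": RB,
    "NRB": NRB,
    "1": RB,
    "0": NRB,
    "positive": RB,
    "negative": NRB,
}


class DescriptorTableError(ValueError):
    """Raised on malformed descriptor files or invariant violations."""


@dataclass(frozen=True)
class DescriptorSchema:
    """Ordered feature names with their measurement kinds."""

    features: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.features]
        if any(not n for n in names):
            raise DescriptorTableError("feature names must be non-empty")
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DescriptorTableError(f"duplicate feature names: {dupes}")
        for name, kind in self.features:
            if kind not in KINDS:
                raise DescriptorTableError(
                    f"feature {name!r}: kind {kind!r} not in {KINDS}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.features)

    @property
    def kinds(self) -> tuple[str, ...]:
        return tuple(k for _, k in self.features)

    def __len__(self) -> int:
        return len(self.features)


def canonical_schema() -> DescriptorSchema:
    """The packaged 41-descriptor schema of the biodegradation dataset."""
    ref = importlib.resources.files("qsartrees.resources") / "biodeg_schema.yaml"
    spec = yaml.safe_load(ref.read_text())
    return DescriptorSchema(
        tuple((f["name"], f["kind"]) for f in spec["features"])
    )


@dataclass
class DescriptorTable:
    """Validated N x p descriptor matrix with RB/NRB labels and a schema."""

    values: np.ndarray
    labels: np.ndarray
    schema: DescriptorSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype="U3")
        if self.values.ndim != 2:
            raise DescriptorTableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise DescriptorTableError("table must have N >= 1 rows and p >= 1 columns")
        if len(self.labels) != n:
            raise DescriptorTableError("labels length must equal the number of rows")
        bad = set(self.labels) - {RB, NRB}
        if bad:
            raise DescriptorTableError(f"labels must be RB/NRB, got {sorted(bad)}")
        if p != len(self.schema):
            raise DescriptorTableError(
                f"schema has {len(self.schema)} features but table has {p} columns"
            )
        if not np.isfinite(self.values).all():
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise DescriptorTableError(
                f"missing/non-finite value at row {r + 1}, column "
                f"{self.schema.names[c]!r}"
            )
        for j, (name, kind) in enumerate(self.schema.features):
            col = self.values[:, j]
            if kind == "flag" and not np.isin(col, (0.0, 1.0)).all():
                raise DescriptorTableError(f"flag column {name!r} has values outside {{0,1}}")
            if kind == "ordinal" and (
                (col < 0).any() or (col != np.round(col)).any()
            ):
                raise DescriptorTableError(
                    f"ordinal column {name!r} must hold non-negative integers"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Boolean positive-class indicator (True = RB)."""
        return self.labels == RB

    def class_counts(self) -> tuple[int, int]:
        """(n_RB, n_NRB)."""
        y = self.y
        return int(y.sum()), int((~y).sum())

    def subset(self, idx: np.ndarray) -> "DescriptorTable":
        return DescriptorTable(self.values[idx], self.labels[idx], self.schema)


def infer_schema(
    values: np.ndarray,
    names: Sequence[str] | None = None,
    max_ordinal_unique: int = 25,
) -> DescriptorSchema:
    """Infer measurement kinds from raw column values.

    A column whose value set is within {0,1} is a flag; a column of
    non-negative integers with at most ``max_ordinal_unique`` distinct values
    is ordinal; anything else is continuous. Deterministic for fixed input.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 1:
        raise DescriptorTableError("need a non-empty 2-D value matrix")
    if not np.isfinite(values).all():
        raise DescriptorTableError("non-numeric or missing cell in value matrix")
    p = values.shape[1]
    if names is None:
        names = [f"x{j + 1}" for j in range(p)]
    feats = []
    for j in range(p):
        col = values[:, j]
        distinct = np.unique(col)
        if np.isin(distinct, (0.0, 1.0)).all():
            kind = "flag"
        elif (
            (col >= 0).all()
            and (col == np.round(col)).all()
            and distinct.size <= max_ordinal_unique
        ):
            kind = "ordinal"
        else:
            kind = "continuous"
        feats.append((names[j], kind))
    return DescriptorSchema(tuple(feats))


def read_descriptor_table(
    path,
    schema: DescriptorSchema | None = None,
    delimiter: str = ";",
    label_map: Mapping[str, str] | None = None,
    header: bool | None = None,
) -> DescriptorTable:
    """Read a delimited descriptor file (last column = class label).

    ``header`` None auto-detects a header row (first row whose value fields
    fail to parse as numbers). Label tokens are mapped via ``label_map``
    (default accepts RB/NRB, 1/0, positive/negative).
    """
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delimiter)]
    rows = [r for r in rows if r and any(f.strip() for f in r)]
    if not rows:
        raise DescriptorTableError(f"{path}: empty file")

    names = None
    start = 0
    first = rows[0]
    is_header = header
    if header is None:
        # a blank field is a missing value, not evidence of a header row
        is_header = any(
            f.strip() and not _is_number(f) for f in first[:-1]
        )
    if is_header:
        names = [f.strip() for f in first[:-1]]
        start = 1
        if not rows[start:]:
            raise DescriptorTableError(f"{path}: header but no data rows")

    width = len(rows[start])
    data, labels = [], []
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) != width:
            raise DescriptorTableError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
        *fields, token = [f.strip() for f in row]
        vals = []
        for j, f in enumerate(fields):
            if f == "":
                col = names[j] if names else f"column {j + 1}"
                raise DescriptorTableError(
                    f"{path}: line {lineno}: missing value in {col}"
                )
            try:
                vals.append(float(f))
            except ValueError:
                raise DescriptorTableError(
                    f"{path}: line {lineno}: non-numeric value {f!r}"
                ) from None
        if token not in label_map:
            raise DescriptorTableError(
                f"{path}: line {lineno}: unknown label {token!r}; accepted: "
                f"{sorted(label_map)}"
            )
        data.append(vals)
        labels.append(label_map[token])

    values = np.asarray(data, dtype=float)
    if schema is None:
        schema = infer_schema(values, names)
    return DescriptorTable(values, np.asarray(labels), schema)


def write_descriptor_table(
    table: DescriptorTable, path, delimiter: str = ";", header: bool = True
) -> None:
    """Write a table in the delimited format `read_descriptor_table` accepts."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        if header:
            w.writerow(list(table.schema.names) + ["class"])
        for row, lab in zip(table.values, table.labels):
            w.writerow([_fmt(v) for v in row] + [lab])


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _is_number(field: str) -> bool:
    try:
        float(field)
    except ValueError:
        return False
    return True


def split_train_test(
    tables: Sequence[DescriptorTable], grouping: Sequence[str]
) -> tuple[DescriptorTable, DescriptorTable]:
    """Concatenate tables into (train, test) per a 'train'/'test' assignment.

    This mirrors how the study regrouped the donors' three subsets: the
    calibration subset becomes training, validation + external validation
    become the test set. Row order is preserved within each group; a group
    with no tables assigned is returned as None (tables always have N >= 1).
    """
    if len(tables) != len(grouping):
        raise DescriptorTableError("one grouping entry per table required")
    bad = set(grouping) - {"train", "test"}
    if bad:
        raise DescriptorTableError(f"grouping entries must be train/test, got {bad}")
    schema = tables[0].schema
    for t in tables[1:]:
        if t.schema != schema:
            raise DescriptorTableError("all tables must share one schema")

    def cat(group: str) -> DescriptorTable | None:
        parts = [t for t, g in zip(tables, grouping) if g == group]
        if not parts:
            return None
        return DescriptorTable(
            np.vstack([t.values for t in parts]),
            np.concatenate([t.labels for t in parts]),
            schema,
        )

    return cat("train"), cat("test")


def summarize(table: DescriptorTable) -> pd.DataFrame:
    """Per-feature descriptive statistics in the reference-table layout.

    Every feature reports min, max, mean, std-dev, mode and distinct-value
    count (mode = smallest most frequent value); the report mirrors the
    min/max/mean/std/mode/unique column order of the study's descriptor
    summary table.
    """
    recs = []
    for j, (name, kind) in enumerate(table.schema.features):
        col = table.values[:, j]
        vals, counts = np.unique(col, return_counts=True)
        recs.append(
            {
                "feature": name,
                "kind": kind,
                "min": col.min(),
                "max": col.max(),
                "mean": col.mean(),
                "std": col.std(ddof=1) if len(col) > 1 else 0.0,
                "mode": vals[np.argmax(counts)],
                "unique": vals.size,
            }
        )
    return pd.DataFrame.from_records(recs)
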