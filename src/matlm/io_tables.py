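"""Tabular input/output for matrix linear model analyses.

Defines the three on-disk inputs every analysis consumes — a sample x
metabolite abundance matrix, a sample covariate table, and a metabolite
annotation table — together with the CSV dialect used for all result
tables (comma delimiter, ``.`` decimal separator, mandatory header,
UTF-8).  Sample and metabolite identifiers are matched by exact string
equality after trimming surrounding whitespace; nothing is ever joined
fuzzily.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceMatrix",
    "SampleTable",
    "AnnotationTable",
    "ValidationError",
    "ParseError",
    "DEFAULT_MISSING_TOKENS",
    "read_matrix_csv",
    "read_table_csv",
    "write_matrix_csv",
    "write_table_csv",
]

#: Cell contents treated as missing values on read.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN"})


class ValidationError(ValueError):
    """An input violates a structural contract (duplicate ids, bad schema...)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message carries its location."""


def _check_unique(ids, what: str) -> list[str]:
    ids = [str(x).strip() for x in ids]
    if len(ids) == 0:
        raise ValidationError(f"no {what} found")
    seen: set[str] = set()
    for x in ids:
        if not x:
            raise ValidationError(f"empty {what} identifier")
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)
    return ids


@dataclass
class AbundanceMatrix:
    """The response matrix Y: n samples (rows) x m metabolites (columns).

    ``missing_mask[i, j]`` is True where the value is missing; observed
    entries must be finite.
    """

    values: np.ndarray
    sample_ids: list[str]
    metabolite_ids: list[str]
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("abundance values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError("abundance matrix must be at least 1 x 1")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        self.metabolite_ids = _check_unique(self.metabolite_ids, "metabolite")
        if len(self.sample_ids) != n or len(self.metabolite_ids) != m:
            raise ValidationError(
                f"id lengths ({len(self.sample_ids)}, {len(self.metabolite_ids)}) "
                f"do not match matrix shape {self.values.shape}"
            )
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValidationError("missing_mask shape does not match values")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("non-finite value at an observed (unmasked) cell")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.metabolite_ids
        )
        return df.mask(pd.DataFrame(self.missing_mask, index=df.index, columns=df.columns))

    def copy(self) -> "AbundanceMatrix":
        return AbundanceMatrix(
            self.values.copy(),
            list(self.sample_ids),
            list(self.metabolite_ids),
            self.missing_mask.copy(),
        )


class _TypedTable:
    """Common behaviour of sample and annotation tables.

    Wraps a DataFrame indexed by identifier with a per-column schema of
    ``"categorical"`` or ``"continuous"``.  Categorical level order is the
    order of first appearance in the file.
    """

    _id_kind = "row"

    def __init__(self, data: pd.DataFrame, schema: dict[str, str] | None = None):
        ids = _check_unique(list(data.index), self._id_kind)
        self.data = data.copy()
        self.data.index = pd.Index(ids, name=data.index.name or "id")
        self.schema: dict[str, str] = {}
        self.levels: dict[str, list[str]] = {}
        schema = schema or {
            c: ("continuous" if pd.api.types.is_numeric_dtype(data[c]) else "categorical")
            for c in data.columns
        }
        for col, kind in schema.items():
            if col not in self.data.columns:
                raise ValidationError(f"schema column not found in table: {col!r}")
            if kind not in ("categorical", "continuous"):
                raise ValidationError(f"unknown schema kind {kind!r} for column {col!r}")
            self.schema[col] = kind
            if kind == "continuous":
                try:
                    self.data[col] = pd.to_numeric(self.data[col], errors="raise")
                except (ValueError, TypeError) as exc:
                    raise ParseError(
                        f"non-numeric value in continuous column {col!r}: {exc}"
                    ) from None
            else:
                vals = self.data[col].astype(str).str.strip()
                self.data[col] = vals
                self.levels[col] = list(dict.fromkeys(vals))

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def column(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise ValidationError(f"unknown column {name!r}; available: {list(self.data.columns)}")
        return self.data[name]

    def reindexed(self, ids: list[str]):
        """Return a copy reordered to ``ids``; every id must be present."""
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise ValidationError(
                f"{self._id_kind} id not found in table: {missing[0]!r}"
                + (f" (and {len(missing) - 1} more)" if len(missing) > 1 else "")
            )
        out = type(self)(self.data.loc[ids], dict(self.schema))
        out.levels = {k: list(v) for k, v in self.levels.items()}
        return out


class SampleTable(_TypedTable):
    """Per-sample covariates (raw material for the X design matrix)."""

    _id_kind = "sample"


class AnnotationTable(_TypedTable):
    """Per-metabolite annotations (raw material for the Z design matrix)."""

    _id_kind = "metabolite"


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_matrix_csv(
    path,
    missing_tokens=DEFAULT_MISSING_TOKENS,
    transpose: bool = False,
    delimiter: str | None = None,
) -> AbundanceMatrix:
    """Read an abundance matrix CSV/TSV.

    Layout: first row holds metabolite ids, first column sample ids
    (``transpose=True`` for metabolites-as-rows files).  Cells matching a
    missing token are masked; any other non-numeric cell raises
    :class:`ParseError` with its location.
    """
    import csv

    sep = _delimiter_for(path, delimiter)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh, delimiter=sep) if row]
    if len(rows) < 2 or len(rows[0]) < 2:
        raise ValidationError(f"matrix file {path} needs a header row and data")
    header = rows[0][1:]
    body_ids = [row[0] for row in rows[1:]]
    cells = [row[1:] for row in rows[1:]]
    for i, row in enumerate(cells):
        if len(row) != len(header):
            raise ParseError(
                f"row {body_ids[i]!r} has {len(row)} cells, expected {len(header)}"
            )
    if transpose:
        header, body_ids = body_ids, header
        cells = [list(col) for col in zip(*cells)]
    row_ids = _check_unique(body_ids, "sample")
    col_ids = _check_unique(header, "metabolite")
    shape = (len(row_ids), len(col_ids))
    values = np.empty(shape, dtype=float)
    mask = np.zeros(shape, dtype=bool)
    tokens = set(missing_tokens)
    for i in range(shape[0]):
        for j in range(shape[1]):
            cell = cells[i][j].strip()
            if cell in tokens:
                values[i, j] = np.nan
                mask[i, j] = True
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric cell {cell!r} at sample {row_ids[i]!r}, "
                    f"metabolite {col_ids[j]!r}"
                ) from None
    return AbundanceMatrix(values, row_ids, col_ids, mask)


def read_table_csv(
    path,
    schema: dict[str, str] | None = None,
    kind: str = "sample",
    delimiter: str | None = None,
):
    """Read a covariate or annotation table (id column first, header present).

    ``schema`` maps column name -> ``"categorical"`` | ``"continuous"``;
    unlisted columns are typed by inspection.  ``kind`` selects
    :class:`SampleTable` (``"sample"``) or :class:`AnnotationTable`
    (``"annotation"``).
    """
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    cls = {"sample": SampleTable, "annotation": AnnotationTable}.get(kind)
    if cls is None:
        raise ValidationError(f"kind must be 'sample' or 'annotation', got {kind!r}")
    if schema is not None:
        full = {
            c: schema.get(
                c,
                "continuous" if pd.api.types.is_numeric_dtype(df[c]) else "categorical",
            )
            for c in df.columns
        }
        for col in schema:
            if col not in df.columns:
                raise ValidationError(f"schema column not found in table: {col!r}")
        schema = full
    return cls(df, schema)


def write_matrix_csv(matrix: AbundanceMatrix, path, missing_token: str = "NA") -> None:
    """Write an abundance matrix in the same layout :func:`read_matrix_csv` expects."""
    df = matrix.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, na_rep=missing_token, float_format="%.17g")


def write_table_csv(table, path) -> None:
    """Write any result table (DataFrame or typed table) as RFC-4180-style CSV.

    Header row always present; '.' decimal separator; column order as held
    by the table.
    """
    if isinstance(table, _TypedTable):
        table.data.to_csv(path)
        return
    df = pd.DataFrame(table)
    df.to_csv(path, index=False, float_format="%.17g")
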