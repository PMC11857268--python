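"""Design-matrix construction for both sides of the bilinear model.

X encodes sample covariates (intercept, reference-coded categorical
indicators, continuous columns).  Z encodes metabolite annotations:
categorical columns or binned numeric attributes (e.g. triglyceride total
carbon count and double-bond count).  An *unadjusted* Z holds a single
cell-means block — one indicator per category, no intercept — so each
coefficient is that category's effect.  An *adjusted* Z holds the first
variable as a cell-means block and every further variable as a
reference-coded block (reference = lowest bin / first level), which keeps
the matrix full rank while estimating each annotation effect controlling
for the others.  The intercept lives in X only; Z never adds one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import AnnotationTable, SampleTable, ValidationError

__all__ = [
    "DesignMatrixX",
    "DesignMatrixZ",
    "ZSpec",
    "ZVariable",
    "bin_numeric",
    "build_x",
    "build_z",
    "per_level_effects",
]

logger = logging.getLogger("matlm")


def _first_dependent_column(M: np.ndarray, labels: list[str]) -> str:
    """Name the first column linearly dependent on its predecessors."""
    for j in range(1, M.shape[1]):
        if np.linalg.matrix_rank(M[:, : j + 1]) <= np.linalg.matrix_rank(M[:, :j]):
            return labels[j]
    return labels[-1]


def _check_full_rank(M: np.ndarray, labels: list[str], what: str) -> None:
    r = np.linalg.matrix_rank(M)
    if r < M.shape[1]:
        dep = _first_dependent_column(M, labels)
        raise ValidationError(
            f"{what} design matrix is rank deficient (rank {r} < {M.shape[1]} "
            f"columns); column {dep!r} is linearly dependent on earlier columns"
        )


@dataclass
class DesignMatrixX:
    """Sample-side design matrix (n x p) with column labels and provenance."""

    values: np.ndarray
    column_labels: list[str]
    source_spec: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_full_rank(self.values, self.column_labels, "X")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignMatrixZ:
    """Metabolite-side design matrix (m x q).

    ``blocks`` maps each annotation variable to its column slice;
    ``coding`` maps it to ``"cell_means"`` or ``"reference"``.  For a
    reference-coded block, ``reference_levels`` records the omitted level.
    """

    values: np.ndarray
    column_labels: list[str]
    blocks: dict[str, slice] = field(default_factory=dict)
    coding: dict[str, str] = field(default_factory=dict)
    reference_levels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _check_full_rank(self.values, self.column_labels, "Z")
        for var, sl in self.blocks.items():
            if self.coding.get(var) == "cell_means":
                block = self.values[:, sl]
                if not np.all(np.isin(block, (0.0, 1.0))):
                    raise ValidationError(f"cell-means block {var!r} is not 0/1")
                if not np.allclose(block.sum(axis=1), 1.0):
                    raise ValidationError(
                        f"cell-means block {var!r} rows do not sum to 1"
                    )

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @classmethod
    def identity(cls, metabolite_ids: list[str]) -> "DesignMatrixZ":
        """Z = I: the model reduces to one linear model per metabolite."""
        m = len(metabolite_ids)
        return cls(np.eye(m), list(metabolite_ids), {"identity": slice(0, m)},
                   {"identity": "cell_means"})


@dataclass
class ZVariable:
    """One annotation variable of a ZSpec.

    ``edges`` (strictly increasing) bins a numeric column via
    :func:`bin_numeric`; omit for an already-categorical column.
    """

    column: str
    edges: list[float] | None = None
    open_upper: bool = True

    def __post_init__(self) -> None:
        if self.edges is not None:
            e = list(self.edges)
            if len(e) < 1 or any(b <= a for a, b in zip(e, e[1:])):
                raise ValidationError(
                    f"bin edges for {self.column!r} must be strictly increasing"
                )


@dataclass
class ZSpec:
    """Ordered annotation variables plus the adjusted/unadjusted mode."""

    variables: list[ZVariable]
    mode: str = "unadjusted"

    def __post_init__(self) -> None:
        if self.mode not in ("unadjusted", "adjusted"):
            raise ValidationError(f"mode must be adjusted|unadjusted, got {self.mode!r}")
        if not self.variables:
            raise ValidationError("ZSpec needs at least one variable")
        if self.mode == "unadjusted" and len(self.variables) != 1:
            raise ValidationError("unadjusted mode requires exactly one variable")


def _fmt(x: float) -> str:
    return f"{x:g}"


def bin_numeric(values, edges, open_upper: bool = True) -> list[str]:
    """Assign half-open, left-closed bins ``[e_b, e_{b+1})`` to values.

    With ``open_upper`` true, values >= the last edge map to
    ``[e_B,inf)``; otherwise such values are an error.  Values below the
    first edge are always an error.  Every admissible value maps to
    exactly one label.
    """
    v = np.asarray(values, dtype=float)
    e = np.asarray(edges, dtype=float)
    if e.ndim != 1 or len(e) < 1 or np.any(np.diff(e) <= 0):
        raise ValidationError("edges must be strictly increasing")
    below = np.where(v < e[0])[0]
    if below.size:
        raise ValidationError(
            f"value(s) below the first bin edge {e[0]:g} at positions {below.tolist()}"
        )
    if not open_upper:
        above = np.where(v >= e[-1])[0]
        if above.size:
            raise ValidationError(
                f"value(s) >= the last bin edge {e[-1]:g} at positions {above.tolist()} "
                "(open_upper=False)"
            )
    idx = np.searchsorted(e, v, side="right") - 1
    labels = []
    for b in idx:
        if b == len(e) - 1:
            labels.append(f"[{_fmt(e[-1])},inf)")
        else:
            labels.append(f"[{_fmt(e[b])},{_fmt(e[b + 1])})")
    return labels


def bin_labels_for_edges(edges, open_upper: bool = True) -> list[str]:
    """The ordered label set :func:`bin_numeric` can produce for ``edges``."""
    e = [float(x) for x in edges]
    out = [f"[{_fmt(a)},{_fmt(b)})" for a, b in zip(e, e[1:])]
    if open_upper:
        out.append(f"[{_fmt(e[-1])},inf)")
    return out


def build_x(
    samples: SampleTable,
    covariates: list[str],
    intercept: bool = True,
    references: dict[str, str] | None = None,
    center: bool = False,
) -> DesignMatrixX:
    """Build X from sample covariates.

    Categorical covariates contribute an indicator per non-reference level
    (reference defaults to the first level in sorted order); continuous
    covariates contribute one column, centered if requested.
    """
    references = references or {}
    n = len(samples)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if intercept:
        cols.append(np.ones(n))
        labels.append("intercept")
    for cov in covariates:
        series = samples.column(cov)
        kind = samples.schema.get(cov, "categorical")
        if kind == "continuous":
            x = series.to_numpy(dtype=float)
            if center:
                x = x - x.mean()
            cols.append(x)
            labels.append(cov)
        else:
            levels = sorted(set(series))
            ref = references.get(cov, levels[0])
            if ref not in levels:
                raise ValidationError(
                    f"unknown reference level {ref!r} for covariate {cov!r}; "
                    f"levels: {levels}"
                )
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((series == lev).to_numpy(dtype=float))
                labels.append(f"{cov}:{lev}")
    if not cols:
        raise ValidationError("X has no columns: no covariates and no intercept")
    X = np.column_stack(cols)
    return DesignMatrixX(
        X,
        labels,
        {
            "covariates": list(covariates),
            "intercept": intercept,
            "references": dict(references),
        },
    )


def _variable_levels(annotations: AnnotationTable, var: ZVariable) -> tuple[list[str], list[str]]:
    """Per-metabolite labels and the ordered level set for one Z variable."""
    series = annotations.column(var.column)
    if var.edges is not None:
        vals = series.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError(f"annotation {var.column!r} has non-finite values")
        labels = bin_numeric(vals, var.edges, var.open_upper)
        ordered = bin_labels_for_edges(var.edges, var.open_upper)
    else:
        kind = annotations.schema.get(var.column, "categorical")
        if kind == "continuous":
            raise ValidationError(
                f"numeric annotation {var.column!r} needs bin edges to enter Z"
            )
        labels = list(series.astype(str))
        ordered = sorted(set(labels))
    present = set(labels)
    kept = [lev for lev in ordered if lev in present]
    for lev in ordered:
        if lev not in present:
            logger.warning(
                "dropping empty level %r of Z variable %r", lev, var.column
            )
    return labels, kept


def build_z(annotations: AnnotationTable, spec: ZSpec) -> DesignMatrixZ:
    """Build Z from metabolite annotations according to ``spec``.

    Unadjusted: one cell-means block.  Adjusted: first variable cell-means,
    subsequent variables reference-coded against their lowest bin / first
    level.  Empty levels are dropped with a warning.
    """
    cols: list[np.ndarray] = []
    col_labels: list[str] = []
    blocks: dict[str, slice] = {}
    coding: dict[str, str] = {}
    refs: dict[str, str] = {}
    for v_idx, var in enumerate(spec.variables):
        labels, kept = _variable_levels(annotations, var)
        lab = np.asarray(labels)
        start = len(cols)
        cm = spec.mode == "unadjusted" or v_idx == 0
        use = kept if cm else kept[1:]
        if not cm:
            refs[var.column] = kept[0]
        for lev in use:
            cols.append((lab == lev).astype(float))
            col_labels.append(f"{var.column}:{lev}")
        blocks[var.column] = slice(start, len(cols))
        coding[var.column] = "cell_means" if cm else "reference"
    Z = np.column_stack(cols)
    return DesignMatrixZ(Z, col_labels, blocks, coding, refs)


def per_level_effects(inference: pd.DataFrame, Z: DesignMatrixZ) -> pd.DataFrame:
    """Recover per-level effects for reference-coded Z blocks.

    For a reference-coded block the fitted coefficients are differences
    from the omitted reference level; this view re-expresses them as
    per-level effects with the reference level fixed at 0 (se 0), which
    makes adjusted-model output directly comparable to the cell-means
    per-category view.
    """
    rows = []
    for var, code in Z.coding.items():
        if code != "reference":
            continue
        ref = Z.reference_levels[var]
        prefix = f"{var}:"
        sub = inference[inference["z_label"].str.startswith(prefix)]
        for x_label in sub["x_label"].unique():
            rows.append(
                {"x_label": x_label, "z_label": f"{prefix}{ref}",
                 "effect": 0.0, "se": 0.0}
            )
        keep = sub[["x_label", "z_label", "effect", "se"]].to_dict("records")
        rows.extend(keep)
    return pd.DataFrame(rows, columns=["x_label", "z_label", "effect", "se"])
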