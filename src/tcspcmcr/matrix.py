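"""Row-stacked decay matrices and autoscaling preprocessing.

PCA and MCR-ALS operate on a matrix D (m x n) whose rows are decay
traces ordered by pH (acidic first) and whose columns are time bins.
For PCA the matrix is autoscaled (column mean-centring followed by
division by the column standard deviation); MCR-ALS works on the raw
non-negative counts, where the non-negativity constraints are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .axes import DecayTrace, TimeAxis

__all__ = ["RowMeta", "Preprocessing", "DecayMatrix", "build_matrix", "autoscale"]


@dataclass(frozen=True)
class RowMeta:
    sequence_id: str
    ph: float
    wavelength: float


@dataclass(frozen=True)
class Preprocessing:
    """Record of the transform applied to a DecayMatrix; enables exact undo."""

    kind: Literal["none", "autoscale"] = "none"
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None
    ddof: int = 1
    constant_columns: np.ndarray | None = None  # boolean flags


@dataclass(frozen=True)
class DecayMatrix:
    """Traces as rows (sorted by pH, then wavelength, then sequence)."""

    values: np.ndarray
    row_meta: tuple[RowMeta, ...]
    axis: TimeAxis
    preprocessing: Preprocessing = field(default_factory=Preprocessing)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D")
        if values.shape[0] != len(self.row_meta):
            raise ValueError(
                f"{values.shape[0]} rows but {len(self.row_meta)} row_meta entries"
            )
        if values.shape[1] != self.axis.n_bins:
            raise ValueError("column count must equal axis.n_bins")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_meta", tuple(self.row_meta))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def ph_values(self) -> np.ndarray:
        return np.array([m.ph for m in self.row_meta])

    @property
    def is_autoscaled(self) -> bool:
        return self.preprocessing.kind == "autoscale"

    def select_rows(self, predicate: Callable[[RowMeta], bool]) -> "DecayMatrix":
        """Row subset by metadata predicate; preprocessing record is reset."""
        idx = [i for i, m in enumerate(self.row_meta) if predicate(m)]
        if not idx:
            raise ValueError("row filter retained no rows")
        return DecayMatrix(
            values=self.values[idx],
            row_meta=tuple(self.row_meta[i] for i in idx),
            axis=self.axis,
            preprocessing=self.preprocessing,
        )


def build_matrix(
    traces: Sequence[DecayTrace],
    scope: Literal["all-sequences", "single-sequence"] = "all-sequences",
    sequence_id: str | None = None,
) -> DecayMatrix:
    """Stack traces into a DecayMatrix with deterministic row order.

    Rows are sorted by pH ascending, then wavelength ascending, then
    sequence id, so shuffled inputs produce an identical matrix.  With
    ``scope="single-sequence"`` all traces must come from one sequence
    (optionally named explicitly via ``sequence_id``).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    axis = traces[0].axis
    if any(tr.axis != axis for tr in traces):
        raise ValueError("all traces must share one time axis")
    if any(np.isnan(tr.ph) for tr in traces):
        raise ValueError("every trace needs a pH value to be stacked")
    if scope == "single-sequence":
        ids = {tr.sequence_id for tr in traces}
        if sequence_id is not None:
            traces = [tr for tr in traces if tr.sequence_id == sequence_id]
            if not traces:
                raise ValueError(f"no traces with sequence_id {sequence_id!r}")
        elif len(ids) > 1:
            raise ValueError(
                f"single-sequence scope but {len(ids)} sequence ids present: "
                f"{sorted(ids)}"
            )
    elif scope != "all-sequences":
        raise ValueError(f"unknown scope {scope!r}")
    traces.sort(key=lambda tr: (tr.ph, tr.wavelength, tr.sequence_id))
    return DecayMatrix(
        values=np.array([tr.counts for tr in traces], dtype=float),
        row_meta=tuple(
            RowMeta(tr.sequence_id, tr.ph, tr.wavelength) for tr in traces
        ),
        axis=axis,
    )


def autoscale(D: DecayMatrix, ddof: int = 1) -> DecayMatrix:
    """Column mean-centring followed by division by column std.

    Zero-variance columns are centred only and flagged; ``ddof=1``
    (sample std) is the default, ``ddof=0`` selects the population
    convention.  The stored parameters allow an exact inverse.
    """
    m = D.shape[0]
    if m < 2:
        raise ValueError("autoscaling needs at least 2 rows")
    means = D.values.mean(axis=0)
    stds = D.values.std(axis=0, ddof=ddof)
    constant = stds == 0.0
    safe = np.where(constant, 1.0, stds)
    scaled = (D.values - means) / safe
    return DecayMatrix(
        values=scaled,
        row_meta=D.row_meta,
        axis=D.axis,
        preprocessing=Preprocessing(
            kind="autoscale",
            column_means=means,
            column_stds=stds,
            ddof=ddof,
            constant_columns=constant,
        ),
    )


def inverse_autoscale(D: DecayMatrix) -> DecayMatrix:
    """Undo :func:`autoscale` exactly on the retained columns."""
    p = D.preprocessing
    if p.kind != "autoscale":
        raise ValueError("matrix is not autoscaled")
    safe = np.where(p.constant_columns, 1.0, p.column_stds)
    return DecayMatrix(
        values=D.values * safe + p.column_means,
        row_meta=D.row_meta,
        axis=D.axis,
        preprocessing=Preprocessing(),
    )
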