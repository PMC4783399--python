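"""From-scratch correspondence analysis with inertia and contribution decomposition.

Correspondence analysis (CA) ordinates a nonnegative table by decomposing
the matrix of standardized chi-square residuals.  With correspondence
matrix ``P = X / n`` (``n`` the grand total), row masses ``r`` and column
masses ``c``:

    S = D_r^{-1/2} (P - r c') D_c^{-1/2} = U Σ V'

Total inertia equals ``Σ σ_k²``, which is the Pearson chi-square statistic
of the table divided by ``n``.  Principal coordinates are the mass-rescaled
singular vectors scaled by the singular values; the contribution of a row
(column) to an axis is its mass times its squared standard coordinate,
expressed as a percentage of the axis inertia.

Classic CA requires nonnegative input.  The study feeds per-animal
log-z-scaled profiles (which contain negative values) into CA, so
:func:`offset_shift` adds a single recorded global constant to make the
minimum zero.  CA is *not* shift-invariant; the shift is therefore part of
the recorded analysis definition, and running CA on raw counts instead is
always available.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import json

import numpy as np
import pandas as pd

from .transform import CompositionMatrix

_EPS_INERTIA = 1e-14


@dataclass
class CAResult:
    """Output of a correspondence analysis.

    Coordinates and contributions are DataFrames with one column per axis
    (``axis1`` …); contributions are percentages that sum to 100 per axis.
    """

    singular_values: np.ndarray
    axis_inertia_pct: np.ndarray
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    row_contrib_pct: pd.DataFrame
    col_contrib_pct: pd.DataFrame
    total_inertia: float
    row_masses: pd.Series
    col_masses: pd.Series
    meta: dict = field(default_factory=dict)

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def offset_shift(
    matrix: CompositionMatrix | pd.DataFrame, epsilon: float = 0.0
) -> CompositionMatrix:
    """Add one global constant so the minimum value becomes ``epsilon``.

    Already-nonnegative input is returned unchanged (shift 0, unless a
    positive ``epsilon`` is requested).  The applied shift is recorded in
    the result's ``meta['shift']``.
    """
    if isinstance(matrix, CompositionMatrix):
        values, meta = matrix.values, dict(matrix.meta)
    else:
        values, meta = pd.DataFrame(matrix).astype(float), {}
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    minimum = float(values.to_numpy().min())
    shift = epsilon - minimum if minimum < 0 else 0.0
    meta["shift"] = shift
    return CompositionMatrix(values + shift, semantics="shifted", meta=meta)


def _as_frame(matrix) -> tuple[pd.DataFrame, dict]:
    if isinstance(matrix, CompositionMatrix):
        return matrix.values, dict(matrix.meta, semantics=matrix.semantics)
    return pd.DataFrame(matrix).astype(float), {}


def correspondence_analysis(matrix) -> CAResult:
    """Run standard CA on a nonnegative table.

    Parameters
    ----------
    matrix
        A :class:`~hippocomp.transform.CompositionMatrix`, DataFrame or
        array with nonnegative entries and strictly positive row and column
        sums.

    Raises
    ------
    ValueError
        For negative entries (suggesting :func:`offset_shift`) or a zero
        row/column sum (naming the offending label).
    """
    frame, meta = _as_frame(matrix)
    X = frame.to_numpy(dtype=float)
    if X.ndim != 2 or min(X.shape) < 2:
        raise ValueError("matrix must be 2-d with at least two rows and columns")
    if (X < 0).any():
        raise ValueError(
            "correspondence analysis requires nonnegative values; apply "
            "offset_shift to shifted/log-scaled data first"
        )
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    for sums, labels, side in ((row_sums, frame.index, "row"),
                               (col_sums, frame.columns, "column")):
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValueError(f"zero {side} sum for {labels[bad[0]]!r}")

    n = X.sum()
    P = X / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(X.shape) - 1
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k, :]

    inertias = sv**2
    total = float(inertias.sum())
    pct = 100.0 * inertias / total if total > _EPS_INERTIA else np.zeros(k)

    # standard coordinates (unit inertia per axis)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = U / np.sqrt(r)[:, None]
        gamma = Vt.T / np.sqrt(c)[:, None]

    # contributions: mass × squared standard coordinate (sums to 1 per axis)
    row_ctr = 100.0 * r[:, None] * phi**2
    col_ctr = 100.0 * c[:, None] * gamma**2

    # deterministic sign: the column with the largest contribution on each
    # axis points in the positive direction
    for ax in range(k):
        lead = int(np.argmax(col_ctr[:, ax]))
        if gamma[lead, ax] < 0:
            phi[:, ax] *= -1.0
            gamma[:, ax] *= -1.0

    F = phi * sv  # row principal coordinates
    G = gamma * sv  # column principal coordinates

    axes = [f"axis{i + 1}" for i in range(k)]
    return CAResult(
        singular_values=sv,
        axis_inertia_pct=pct,
        row_coords=pd.DataFrame(F, index=frame.index, columns=axes),
        col_coords=pd.DataFrame(G, index=frame.columns, columns=axes),
        row_contrib_pct=pd.DataFrame(row_ctr, index=frame.index, columns=axes),
        col_contrib_pct=pd.DataFrame(col_ctr, index=frame.columns, columns=axes),
        total_inertia=total,
        row_masses=pd.Series(r, index=frame.index, name="mass"),
        col_masses=pd.Series(c, index=frame.columns, name="mass"),
        meta=meta,
    )


def axis_contributions(
    result: CAResult, axis: int, side: Literal["rows", "cols"]
) -> pd.Series:
    """Per-label contribution percentages to one axis (0-based index)."""
    if not 0 <= axis < result.n_axes:
        raise IndexError(f"axis {axis} out of range (have {result.n_axes} axes)")
    table = result.row_contrib_pct if side == "rows" else result.col_contrib_pct
    if side not in ("rows", "cols"):
        raise ValueError("side must be 'rows' or 'cols'")
    return table.iloc[:, axis]


def save_ca_result(result: CAResult, outdir: str | Path) -> dict[str, Path]:
    """Serialize a CAResult to a directory of CSVs plus a JSON metadata file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    inertia = pd.DataFrame(
        {
            "singular_value": result.singular_values,
            "inertia": result.singular_values**2,
            "inertia_pct": result.axis_inertia_pct,
        },
        index=result.row_coords.columns,
    )
    inertia.index.name = "axis"
    for name, frame in (
        ("inertia", inertia),
        ("row_coords", result.row_coords),
        ("col_coords", result.col_coords),
        ("row_contributions", result.row_contrib_pct),
        ("col_contributions", result.col_contrib_pct),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path)
        paths[name] = path

    meta = dict(result.meta, total_inertia=result.total_inertia)
    meta_path = outdir / "ca_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    paths["meta"] = meta_path
    return paths
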