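"""Per-animal scaling and profile normalizations.

Absolute hippocampal cell numbers span four orders of magnitude across the
study's species.  To compare the *composition* of the hippocampus rather
than its size, each animal's five population counts are log-transformed and
z-scaled within the animal: the mean over the five populations is
subtracted and the result divided by their standard deviation (n−1
denominator).  Every animal then has a profile with mean 0 and SD 1, while
relative size differences between its populations are retained.

Percent profiles (each population as a share of the animal's total) serve
the species profile plots, and neurogenesis counts are expressed as a
percentage of the granule-cell population.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

Semantics = Literal["raw", "log_scaled", "percent", "shifted"]

_ATOL = 1e-9


class ZeroVarianceError(ValueError):
    """All values equal: the z-scaling denominator is zero."""


@dataclass
class CompositionMatrix:
    """A labelled animals-or-groups × populations value table.

    ``semantics`` records what the numbers mean:

    - ``raw``: positive counts;
    - ``log_scaled``: per-row log + z-scaled values (row mean 0, SD 1);
    - ``percent``: rows sum to 100;
    - ``shifted``: log-scaled values made nonnegative by a recorded global
      offset (see :func:`hippocomp.correspondence.offset_shift`).
    """

    values: pd.DataFrame
    semantics: Semantics = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.validate()

    def validate(self) -> None:
        v = self.values.to_numpy()
        if self.semantics in ("raw", "percent") and (v < 0).any():
            raise ValueError(f"{self.semantics} semantics require nonnegative values")
        if self.semantics == "percent":
            sums = v.sum(axis=1)
            if not np.allclose(sums, 100.0, atol=_ATOL):
                raise ValueError("percent rows must sum to 100")
        if self.semantics == "log_scaled":
            if not np.allclose(v.mean(axis=1), 0.0, atol=_ATOL):
                raise ValueError("log_scaled rows must have mean 0")
            if not np.allclose(v.std(axis=1, ddof=1), 1.0, atol=_ATOL):
                raise ValueError("log_scaled rows must have SD 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def scale_animal(counts, apply_log: bool = False) -> np.ndarray:
    """Z-scale one animal's population counts (optionally after natural log).

    Returns a vector with mean 0 and sample SD 1 (n−1 denominator).  The
    log base is irrelevant to the result: any base change rescales both the
    deviations and the SD by the same constant.

    Raises
    ------
    ZeroVarianceError
        If all (transformed) values are equal.
    ValueError
        For nonpositive counts when ``apply_log`` is set, or fewer than two
        values.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("counts must be a 1-d vector of at least two values")
    if apply_log:
        if (x <= 0).any():
            raise ValueError("log transform requires strictly positive counts")
        x = np.log(x)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ZeroVarianceError("all values equal; cannot scale to unit SD")
    return (x - x.mean()) / sd


def scale_matrix(matrix: CompositionMatrix, apply_log: bool = True) -> CompositionMatrix:
    """Apply :func:`scale_animal` to every row of a raw count matrix."""
    if matrix.semantics != "raw":
        raise ValueError("scale_matrix expects raw count semantics")
    scaled = np.apply_along_axis(scale_animal, 1, matrix.values.to_numpy(), apply_log)
    out = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.values.columns)
    meta = dict(matrix.meta, log_applied=apply_log)
    return CompositionMatrix(out, semantics="log_scaled", meta=meta)


def percent_profile(counts) -> np.ndarray:
    """Express a nonnegative count vector as percentages of its total."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("cannot form a percent profile from an all-zero vector")
    return 100.0 * x / total


def percent_matrix(matrix: CompositionMatrix) -> CompositionMatrix:
    """Row-wise percent profiles of a raw count matrix."""
    if matrix.semantics != "raw":
        raise ValueError("percent_matrix expects raw count semantics")
    pct = np.apply_along_axis(percent_profile, 1, matrix.values.to_numpy())
    out = pd.DataFrame(pct, index=matrix.values.index, columns=matrix.values.columns)
    return CompositionMatrix(out, semantics="percent", meta=dict(matrix.meta))


def normalize_neurogenesis(marker_count: float, gc_count: float) -> float:
    """A neurogenesis marker count as a percentage of the granule-cell count."""
    if marker_count < 0:
        raise ValueError("marker count must be nonnegative")
    if not gc_count > 0:
        raise ValueError("granule-cell count must be positive")
    return 100.0 * marker_count / gc_count


# ---------------------------------------------------------------------------
# CSV IO with a semantics sidecar line
# ---------------------------------------------------------------------------

def save_matrix(matrix: CompositionMatrix, path: str | Path) -> None:
    """Write a composition matrix with its semantics in a header comment."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# semantics: {matrix.semantics}\n")
        for key, value in matrix.meta.items():
            fh.write(f"# {key}: {value}\n")
        matrix.values.to_csv(fh)


def load_matrix(path: str | Path) -> CompositionMatrix:
    """Read a matrix written by :func:`save_matrix`."""
    path = Path(path)
    meta: dict = {}
    semantics: Semantics = "raw"
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "semantics":
                semantics = value  # type: ignore[assignment]
            else:
                meta[key] = value
    values = pd.read_csv(path, skiprows=skip, index_col=0)
    return CompositionMatrix(values, semantics=semantics, meta=meta)
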