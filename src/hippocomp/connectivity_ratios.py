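"""Convergence/divergence ratios between connected principal populations.

Along the trisynaptic pathway, information passes from dentate granule
cells (GC) to the hilus and CA3, from CA3 to CA1, and from CA1 to the
subiculum.  The ratio of downstream to upstream population size measures
whether the projection converges (many-to-few, ratio < 1) or diverges
(few-to-many, ratio > 1).  The CA3→CA1 ratio is the "expansion rate" of
the Schaffer collaterals: theoretical work places efficient information
transfer at an expansion of about two, with rapid deterioration below one.
"""
from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .datasets import POPULATIONS

#: Ratio columns, downstream over upstream, pathway order.
RATIO_COLUMNS = ("r_gc_hil", "r_gc_ca3", "r_ca3_ca1", "r_ca1_sub")

_PAIRS = {
    "r_gc_hil": ("HIL", "GC"),
    "r_gc_ca3": ("CA3", "GC"),
    "r_ca3_ca1": ("CA1", "CA3"),
    "r_ca1_sub": ("SUB", "CA1"),
}

ExpansionClass = Literal["below_one", "one_to_two", "above_two"]


def convergence_ratios(counts: Mapping[str, float]) -> dict[str, float]:
    """The four downstream/upstream ratios from one set of population counts.

    The last three ratios telescope: their product equals SUB/GC exactly.
    Ratios are invariant to scaling all counts by a positive constant.
    """
    missing = [p for p in POPULATIONS if p not in counts]
    if missing:
        raise ValueError(f"missing populations: {missing}")
    for pop in POPULATIONS:
        if not counts[pop] > 0:
            raise ValueError(f"count for {pop} must be positive")
    return {
        name: counts[num] / counts[den] for name, (num, den) in _PAIRS.items()
    }


def ratio_table(
    counts: pd.DataFrame, mode: Literal["auto", "per_row", "group_mean"] = "auto",
    group_ids: pd.Series | None = None,
) -> tuple[pd.DataFrame, str]:
    """Ratio table from a counts table (rows × the five populations).

    With per-animal rows and ``group_ids``, group-level ratios default to
    the mean of per-animal ratios; without animal-level data they are the
    ratios of the supplied (group-mean) rows.  The mode actually used is
    returned alongside the table.
    """
    per_row = pd.DataFrame(
        [convergence_ratios(row) for _, row in counts.iterrows()],
        index=counts.index,
    )[list(RATIO_COLUMNS)]
    if group_ids is None:
        used = "group_mean" if mode in ("auto", "group_mean") else "per_row"
        return per_row, used
    if mode == "group_mean":
        raise ValueError("group_mean mode does not take per-animal group_ids")
    grouped = per_row.groupby(pd.Series(group_ids, index=counts.index), sort=False).mean()
    grouped.index.name = "group_id"
    return grouped, "mean_of_animal_ratios"


def classify_expansion(r_ca3_ca1: float) -> ExpansionClass:
    """Classify a CA3→CA1 expansion rate.

    Closed-interval convention at the boundaries: exactly 1 and exactly 2
    both fall in ``one_to_two``.
    """
    if not r_ca3_ca1 > 0:
        raise ValueError("expansion ratio must be positive")
    if r_ca3_ca1 < 1:
        return "below_one"
    if r_ca3_ca1 <= 2:
        return "one_to_two"
    return "above_two"


def classify_table(ratios: pd.DataFrame) -> pd.DataFrame:
    """Append an ``expansion_class`` column classifying CA3→CA1 per row."""
    out = ratios.copy()
    out["expansion_class"] = [
        classify_expansion(v) for v in np.asarray(ratios["r_ca3_ca1"], dtype=float)
    ]
    return out
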