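"""Packaged study tables and grouping rules.

The package ships four plain-CSV fixtures transcribed from the study's
printed tables:

``table1``
    Species metadata: sex composition, cohort size and mean age (months)
    for the 21 raw species/strain entries that pool into 20 analyzed groups.
``table2``
    Unilateral optical-fractionator estimates (mean, SD) of the five
    principal hippocampal populations for the 13 groups counted in-house,
    with the stereological sampling parameters and precision diagnostics
    (mean CE for smoothness m=0, CE²/CV²).
``table3``
    Neurogenesis-related counts (Ki67+ proliferating cells, DCX+ young
    neurons) for 9 rodent groups.
``table4``
    Convergence/divergence ratios between connected principal populations
    for all 20 groups.

Seven groups (human, rhesus monkey, pig, dog, sengi, harvest mouse, brown
rat) appear in the study only through literature-sourced per-population
means that are not reprinted here; analyses needing raw counts for those
groups must be given user-supplied values.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: The five principal hippocampal cell populations, in anatomical order of
#: the classic trisynaptic pathway (dentate granule cells, hilus, CA3, CA1,
#: subiculum).
POPULATIONS: tuple[str, ...] = ("GC", "HIL", "CA3", "CA1", "SUB")

#: Immunohistochemical markers used to quantify adult neurogenesis.
NEUROGENESIS_MARKERS: tuple[str, ...] = ("Ki67", "DCX")

TABLE_IDS = ("table1", "table2", "table3", "table4")

_TABLE_FILES = {
    "table1": "table1.csv",
    "table2": "table2.csv",
    "table3": "table3.csv",
    "table4": "table4.csv",
}

_SEXES = ("f", "m", "unknown")


class UnknownTableError(KeyError):
    """Requested fixture table id does not exist."""


class UnknownSpeciesError(KeyError):
    """A species label is not part of the study's species list."""


@dataclass
class AnimalRecord:
    """One animal: group membership, age, sex and its cell-count profile.

    ``counts`` maps each of the five principal populations to a positive
    unilateral cell-number estimate.  ``ki67``/``dcx`` are the optional
    neurogenesis counts (proliferating cells / young neurons).
    """

    group_id: str
    species_name: str
    sex: str
    age_months: float
    counts: dict[str, float]
    ki67: Optional[float] = None
    dcx: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if not self.age_months > 0:
            raise ValueError("age_months must be positive")
        if set(self.counts) != set(POPULATIONS):
            raise ValueError(
                f"counts must have exactly the keys {POPULATIONS}, got {sorted(self.counts)}"
            )
        for pop, value in self.counts.items():
            if not value > 0:
                raise ValueError(f"count for {pop} must be positive, got {value}")
        for name, value in (("ki67", self.ki67), ("dcx", self.dcx)):
            if value is not None and value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value}")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group summary row: moments, cohort size and precision diagnostics."""

    group_id: str
    n_animals: int
    mean_age_months: Optional[float]
    means: Mapping[str, float]
    sds: Mapping[str, float]
    mean_ce: Mapping[str, float] = field(default_factory=dict)
    ce2_cv2: Mapping[str, float] = field(default_factory=dict)
    frame_um: Mapping[str, float] = field(default_factory=dict)
    grid_um: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ValueError("n_animals must be a positive integer")
        for pop in self.means:
            if not self.means[pop] > 0:
                raise ValueError(f"mean for {pop} must be positive")
            if self.sds.get(pop, 0.0) < 0:
                raise ValueError(f"SD for {pop} must be nonnegative")
            ce = self.mean_ce.get(pop)
            if ce is not None and not (0 < ce < 1):
                raise ValueError(f"mean CE for {pop} must lie in (0, 1)")


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("hippocomp").joinpath("data", filename)))


def load_fixture(table_id: str) -> pd.DataFrame:
    """Return one of the packaged study tables as a DataFrame.

    Parameters
    ----------
    table_id
        One of ``table1`` … ``table4``.

    Raises
    ------
    UnknownTableError
        If ``table_id`` is not a packaged table.
    """
    try:
        filename = _TABLE_FILES[table_id]
    except KeyError:
        raise UnknownTableError(
            f"unknown table id {table_id!r}; valid ids: {sorted(_TABLE_FILES)}"
        ) from None
    return read_table(_data_path(filename))


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a fixture-style CSV (UTF-8, header row, plain decimal numbers)."""
    df = pd.read_csv(path)
    if "note" in df.columns:
        df["note"] = df["note"].fillna("")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table in the fixture CSV dialect (round-trips exactly)."""
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Grouping
# ---------------------------------------------------------------------------

def species_to_group_map() -> dict[str, str]:
    """Mapping from printed species labels to analyzed group ids.

    The house mouse is analyzed as three separate groups (wild-type,
    C57BL/6, DBA) while Sprague-Dawley and Wistar rats are pooled into a
    single brown-rat group, turning 21 raw entries into 20 groups.
    """
    t1 = load_fixture("table1")
    return dict(zip(t1["species_label"], t1["group_id"]))


def apply_grouping(raw_species_list: Iterable[str]) -> list[str]:
    """Map raw species labels onto analyzed group ids (order-preserving, unique).

    Raises :class:`UnknownSpeciesError` for labels outside the study list.
    """
    mapping = species_to_group_map()
    seen: list[str] = []
    for label in raw_species_list:
        try:
            gid = mapping[label]
        except KeyError:
            raise UnknownSpeciesError(
                f"unknown species label {label!r}"
            ) from None
        if gid not in seen:
            seen.append(gid)
    return seen


def all_groups() -> list[str]:
    """The 20 analyzed species/strain groups."""
    return apply_grouping(load_fixture("table1")["species_label"])


def printed_groups() -> list[str]:
    """Groups whose per-population means/SDs are printed (13 groups)."""
    return list(pd.unique(load_fixture("table2")["group_id"]))


def literature_only_groups() -> list[str]:
    """Groups whose per-population means are literature-sourced and unavailable."""
    printed = set(printed_groups())
    return [g for g in all_groups() if g not in printed]


def rodent_groups() -> list[str]:
    """The 14 rodent groups among the 20."""
    t1 = load_fixture("table1")
    rodent = t1.loc[t1["order_name"] == "Rodentia", "species_label"]
    return apply_grouping(rodent)


def neurogenesis_groups() -> list[str]:
    """The 9 rodent groups with packaged Ki67/DCX estimates."""
    return list(pd.unique(load_fixture("table3")["group_id"]))


def group_sizes() -> dict[str, int]:
    """Animals per analyzed group (sexes summed; pooled strains summed)."""
    t1 = load_fixture("table1")
    n = t1[["n_female", "n_male", "n_unknown"]].sum(axis=1)
    return (
        pd.DataFrame({"group_id": t1["group_id"], "n": n})
        .groupby("group_id", sort=False)["n"]
        .sum()
        .astype(int)
        .to_dict()
    )


def group_mean_ages() -> dict[str, Optional[float]]:
    """Mean age in months per group (n-weighted across pooled strains).

    The harvest mouse age is recorded only as "adult" in the study and is
    returned as ``None``.
    """
    t1 = load_fixture("table1")
    n = t1[["n_female", "n_male", "n_unknown"]].sum(axis=1)
    ages: dict[str, Optional[float]] = {}
    for gid, sub in t1.assign(n=n).groupby("group_id", sort=False):
        if sub["mean_age_months"].isna().any():
            ages[gid] = None
        else:
            ages[gid] = float(
                (sub["mean_age_months"] * sub["n"]).sum() / sub["n"].sum()
            )
    return ages


def group_summaries() -> dict[str, GroupSummary]:
    """Build :class:`GroupSummary` objects for the 13 groups with printed counts."""
    t2 = load_fixture("table2")
    sizes = group_sizes()
    ages = group_mean_ages()
    out: dict[str, GroupSummary] = {}
    for gid, sub in t2.groupby("group_id", sort=False):
        sub = sub.set_index("population")
        out[gid] = GroupSummary(
            group_id=gid,
            n_animals=sizes[gid],
            mean_age_months=ages[gid],
            means=sub["mean_count"].to_dict(),
            sds=sub["sd_count"].to_dict(),
            mean_ce=sub["mean_ce"].to_dict(),
            ce2_cv2=sub["ce2_cv2"].to_dict(),
            frame_um=sub["frame_um"].to_dict(),
            grid_um=sub["grid_um"].to_dict(),
        )
    return out


def count_matrix(groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Group-mean count table (groups × populations) from the packaged data.

    Raises ``ValueError`` listing any requested group whose means are
    literature-sourced and therefore unavailable.
    """
    t2 = load_fixture("table2")
    wide = t2.pivot(index="group_id", columns="population", values="mean_count")
    wide = wide.loc[pd.unique(t2["group_id"]), list(POPULATIONS)]
    wide.columns.name = None
    wide.index.name = "group_id"
    if groups is None:
        return wide
    missing = [g for g in groups if g not in wide.index]
    if missing:
        raise ValueError(
            "per-population counts are literature-sourced and unavailable for: "
            + ", ".join(sorted(missing))
        )
    return wide.loc[list(groups)]
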