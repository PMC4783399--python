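"""Synthetic cohorts, decline series and virtual tissue.

Every pipeline stage is testable without the study's raw data through
three generators, all pure functions of their parameters and a seed:

- :func:`generate_animals` draws per-animal population counts from
  lognormal distributions moment-matched to the packaged group means/SDs.
  The lognormal guarantees the positivity the log transform requires, and
  matching the first two moments reproduces the printed group-level mean
  and SD at large n.  Populations are drawn independently within an animal;
  the study gives no within-animal covariances.
- :func:`generate_decline_series` draws (age, count) pairs from the
  power-law neurogenesis decline with multiplicative lognormal noise of a
  given coefficient of variation.
- :func:`generate_fractionator_tissue` scatters a known number of cells
  uniformly in a virtual tissue block and applies systematic uniform
  random section, frame and disector sampling, producing per-section
  counts whose fractionator estimate is unbiased for the true number.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets
from .age_normalization import LITERATURE_Y, DEFAULT_REFERENCE_AGE_MONTHS
from .datasets import POPULATIONS, AnimalRecord
from .stereology import FractionatorSample


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and SD.

    sigma² = ln(1 + (sd/mean)²);  mu = ln(mean) − sigma²/2.
    """
    if not mean > 0:
        raise ValueError("mean must be positive")
    if not sd >= 0:
        raise ValueError("SD must be nonnegative")
    sigma2 = np.log1p((sd / mean) ** 2)
    return float(np.log(mean) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``group_means``/``group_sds`` map group id → population → target
    moments; ``group_ages`` maps group id → (mean, sd) of the age
    distribution in months.  Optional neurogenesis parameters give the
    marker moments observed at the group's mean age; generated marker
    counts follow the power-law decline from that anchor to each animal's
    drawn age.
    """

    group_means: Mapping[str, Mapping[str, float]]
    group_sds: Mapping[str, Mapping[str, float]]
    n_per_group: Mapping[str, int]
    group_ages: Mapping[str, tuple[float, float]]
    marker_means: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    marker_sds: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    decline_exponents: Mapping[str, float] = field(default_factory=lambda: dict(LITERATURE_Y))

    def __post_init__(self) -> None:
        for gid, means in self.group_means.items():
            for pop in POPULATIONS:
                if pop not in means:
                    raise ValueError(f"group {gid!r} lacks a mean for {pop}")
            if self.n_per_group.get(gid, 0) < 1:
                raise ValueError(f"group {gid!r} needs a positive n")
            mean_age, sd_age = self.group_ages[gid]
            if not mean_age > 0 or sd_age < 0:
                raise ValueError(f"group {gid!r} has an invalid age distribution")

    @classmethod
    def from_fixtures(
        cls,
        groups: Optional[Sequence[str]] = None,
        include_neurogenesis: bool = False,
    ) -> "CohortSpec":
        """Build the study-condition cohort spec from the packaged tables.

        Defaults to the 13 groups with printed count moments; cohort sizes
        and age distributions come from the species metadata table.
        """
        summaries = datasets.group_summaries()
        if groups is None:
            groups = list(summaries)
        missing = [g for g in groups if g not in summaries]
        if missing:
            raise ValueError(f"no printed moments for groups: {missing}")
        t1 = datasets.load_fixture("table1")
        age_sd = {
            gid: float(sub["age_sd_months"].fillna(0.0).iloc[0])
            for gid, sub in t1.groupby("group_id")
        }
        spec = cls(
            group_means={g: dict(summaries[g].means) for g in groups},
            group_sds={g: dict(summaries[g].sds) for g in groups},
            n_per_group={g: summaries[g].n_animals for g in groups},
            group_ages={
                g: (float(summaries[g].mean_age_months), age_sd.get(g, 0.0))
                for g in groups
            },
        )
        if include_neurogenesis:
            t3 = datasets.load_fixture("table3")
            for marker, sub in t3.groupby("marker"):
                sub = sub.set_index("group_id")
                spec.marker_means[marker] = {
                    g: float(sub.loc[g, "mean_count"]) for g in groups if g in sub.index
                }
                spec.marker_sds[marker] = {
                    g: float(sub.loc[g, "sd_count"]) for g in groups if g in sub.index
                }
        return spec


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    mu, sigma = lognormal_from_moments(mean, sd)
    return float(rng.lognormal(mu, sigma))


def generate_animals(spec: CohortSpec, seed: int) -> list[AnimalRecord]:
    """Draw a reproducible synthetic cohort following ``spec``.

    Ages are lognormal with the group's mean/SD (degenerate at the mean
    when the SD is 0).  Marker counts, when parameterized, decline from
    the group's age anchor with the spec's exponents and carry the
    group-level noise CV.
    """
    rng = np.random.default_rng(seed)
    records: list[AnimalRecord] = []
    for gid in spec.group_means:
        mean_age, sd_age = spec.group_ages[gid]
        for _ in range(spec.n_per_group[gid]):
            age = _draw_positive(rng, mean_age, sd_age)
            counts = {
                pop: _draw_positive(
                    rng, spec.group_means[gid][pop], spec.group_sds[gid][pop]
                )
                for pop in POPULATIONS
            }
            markers: dict[str, Optional[float]] = {"Ki67": None, "DCX": None}
            for marker in markers:
                mean = spec.marker_means.get(marker, {}).get(gid)
                if mean is None:
                    continue
                sd = spec.marker_sds.get(marker, {}).get(gid, 0.0)
                decline = (age / mean_age) ** spec.decline_exponents[marker]
                noise = _draw_positive(rng, 1.0, sd / mean) if sd else 1.0
                markers[marker] = mean * decline * noise
            records.append(
                AnimalRecord(
                    group_id=gid,
                    species_name=gid,
                    sex="unknown",
                    age_months=age,
                    counts=counts,
                    ki67=markers["Ki67"],
                    dcx=markers["DCX"],
                )
            )
    return records


def animals_to_frame(records: Sequence[AnimalRecord]) -> pd.DataFrame:
    """Flatten animal records to a tidy table (one row per animal)."""
    rows = []
    for i, rec in enumerate(records):
        row = {
            "animal_id": f"{rec.group_id}/{i}",
            "group_id": rec.group_id,
            "sex": rec.sex,
            "age_months": rec.age_months,
            **{pop: rec.counts[pop] for pop in POPULATIONS},
            "Ki67": rec.ki67,
            "DCX": rec.dcx,
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("animal_id")


def generate_decline_series(
    exponent: float,
    reference_count: float,
    ages,
    noise_cv: float,
    seed: int,
    reference_age_months: float = DEFAULT_REFERENCE_AGE_MONTHS,
) -> pd.DataFrame:
    """(age, count) pairs from the power-law decline with lognormal noise.

    ``count = reference_count · (age/reference_age)^Y · ε`` with
    multiplicative lognormal ε of unit mean and CV ``noise_cv``.
    """
    ages = np.asarray(ages, dtype=float)
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    if not reference_count > 0:
        raise ValueError("reference count must be positive")
    if noise_cv < 0:
        raise ValueError("noise CV must be nonnegative")
    rng = np.random.default_rng(seed)
    curve = reference_count * (ages / reference_age_months) ** exponent
    if noise_cv > 0:
        mu, sigma = lognormal_from_moments(1.0, noise_cv)
        curve = curve * rng.lognormal(mu, sigma, size=ages.shape)
    return pd.DataFrame({"age_months": ages, "count": curve})


def generate_fractionator_tissue(
    true_n: int,
    n_sections: int,
    section_period: int = 12,
    frame_side_um: float = 12.0,
    grid_step_um: float = 120.0,
    disector_height_um: float = 10.0,
    section_thickness_um: float = 20.0,
    guard_um: float = 2.0,
    tissue_xy_um: float | None = None,
    seed: int = 0,
) -> tuple[FractionatorSample, int]:
    """Scatter ``true_n`` cells in a virtual block and sample them.

    Sections of the given thickness are cut along z; every
    ``section_period``-th section (random systematic start) is probed with
    counting frames on a square grid (random offset) and a disector of the
    given height below the guard zone.  Cells inside a guard zone are never
    counted.  The inclusion probability of every cell is exactly
    (1/period) · (frame/grid)² · (height/thickness), so the fractionator
    estimate of the returned sample is unbiased for ``true_n``.
    """
    if true_n < 1:
        raise ValueError("true_n must be a positive integer")
    if guard_um + disector_height_um > section_thickness_um:
        raise ValueError("disector plus guard zone exceeds the section thickness")
    if frame_side_um > grid_step_um:
        raise ValueError("frame must fit inside the grid step")
    if section_period < 1 or n_sections < section_period:
        raise ValueError("need at least one sampled section")
    rng = np.random.default_rng(seed)
    if tissue_xy_um is None:
        tissue_xy_um = 10.0 * grid_step_um

    xy = rng.uniform(0.0, tissue_xy_um, size=(true_n, 2))
    z = rng.uniform(0.0, n_sections * section_thickness_um, size=true_n)
    section_idx = np.minimum((z / section_thickness_um).astype(int), n_sections - 1)
    z_in = z - section_idx * section_thickness_um

    phase = int(rng.integers(section_period))
    offsets = rng.uniform(0.0, grid_step_um, size=2)
    sampled = np.arange(phase, n_sections, section_period)

    in_frame = (
        ((xy[:, 0] - offsets[0]) % grid_step_um < frame_side_um)
        & ((xy[:, 1] - offsets[1]) % grid_step_um < frame_side_um)
    )
    in_disector = (z_in >= guard_um) & (z_in < guard_um + disector_height_um)
    counted = in_frame & in_disector

    per_section = np.zeros(len(sampled), dtype=int)
    for j, s in enumerate(sampled):
        per_section[j] = int(np.sum(counted & (section_idx == s)))

    sample = FractionatorSample(
        per_section_counts=per_section.tolist(),
        section_period=section_period,
        frame_side_um=frame_side_um,
        grid_step_um=grid_step_um,
        disector_height_um=disector_height_um,
        thicknesses_um=[section_thickness_um] * len(sampled),
        thickness_site_counts=per_section.tolist(),
    )
    return sample, true_n
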