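"""Optical-fractionator estimation and its precision diagnostics.

The optical fractionator estimates a total cell number from disector
counts on a systematic random sample of sections:

    N = ΣQ⁻ · (1/ssf) · (1/asf) · (1/tsf)

where ssf = 1/section_period is the section sampling fraction,
asf = (frame/grid)² the area sampling fraction, and tsf = h / t̄_Q the
thickness sampling fraction with disector height h and the number-weighted
mean section thickness t̄_Q = Σ tᵢqᵢ / Σqᵢ (thickness weighted by the cells
counted at each measurement site, so shrinkage-prone thick regions weigh in
proportion to their cell load).

The precision of a single estimate is predicted by the Gundersen
coefficient of error for systematic uniform random sampling with
smoothness class m = 0: with section counts q₁…q_n,

    noise  = Σq
    A = Σqᵢ², B = Σqᵢqᵢ₊₁, C = Σqᵢqᵢ₊₂
    Var_SURS = (3(A − noise) − 4B + C) / 240
    CE = sqrt(noise + Var_SURS) / Σq

CE²/CV² compares that estimation noise with the observed between-animal
variability of a group (CV = group SD / group mean); values well below 0.5
mean the sampling scheme contributes little to the observed variance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class FractionatorSample:
    """Disector counts and sampling geometry for one specimen.

    ``per_section_counts`` must be in systematic (serial) section order —
    the CE formula uses neighbour covariances.  ``thicknesses_um`` and
    ``thickness_site_counts`` hold the measured section thicknesses and the
    cells counted at each measurement site.
    """

    per_section_counts: Sequence[int]
    section_period: int
    frame_side_um: float
    grid_step_um: float
    disector_height_um: float
    thicknesses_um: Sequence[float] = field(default_factory=list)
    thickness_site_counts: Sequence[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        q = np.asarray(self.per_section_counts)
        if q.size < 1 or (q < 0).any():
            raise ValueError("need at least one section with nonnegative counts")
        if self.section_period < 1:
            raise ValueError("section period must be a positive integer")
        if not (0 < self.frame_side_um <= self.grid_step_um):
            raise ValueError("frame side must be positive and at most the grid step")
        if self.disector_height_um <= 0:
            raise ValueError("disector height must be positive")
        if len(self.thicknesses_um) != len(self.thickness_site_counts):
            raise ValueError("thicknesses and site counts must pair up")


@dataclass(frozen=True)
class CEResult:
    """Gundersen CE split into its counting-noise and SURS variance terms."""

    ce: float
    noise_term: float
    surs_var_term: float
    smoothness_m: int = 0


def number_weighted_thickness(thicknesses, site_counts) -> float:
    """Mean section thickness weighted by cells counted per measurement site."""
    t = np.asarray(thicknesses, dtype=float)
    q = np.asarray(site_counts, dtype=float)
    if t.shape != q.shape or t.size == 0:
        raise ValueError("thicknesses and site counts must be equal-length, nonempty")
    if (t <= 0).any() or (q < 0).any():
        raise ValueError("thicknesses must be positive and site counts nonnegative")
    total = q.sum()
    if total <= 0:
        raise ValueError("all site counts are zero; weighted thickness undefined")
    return float((t * q).sum() / total)


def fractionator_estimate(sample: FractionatorSample) -> float:
    """Optical-fractionator total number estimate for one specimen.

    Returns 0.0 (with a warning) when no cells were counted at all.
    """
    q_total = float(np.sum(sample.per_section_counts))
    if q_total == 0:
        warnings.warn("zero cells counted; estimate is 0", stacklevel=2)
        return 0.0
    t_bar = number_weighted_thickness(
        sample.thicknesses_um, sample.thickness_site_counts
    )
    asf_inv = (sample.grid_step_um / sample.frame_side_um) ** 2
    tsf_inv = t_bar / sample.disector_height_um
    return q_total * sample.section_period * asf_inv * tsf_inv


def gundersen_ce(per_section_counts, m: int = 0) -> CEResult:
    """Gundersen CE (smoothness class m = 0) of one fractionator count series."""
    if m != 0:
        raise ValueError("only the m = 0 smoothness class is implemented")
    q = np.asarray(per_section_counts, dtype=float)
    if q.size < 3:
        raise ValueError("need at least three sections for the SURS variance term")
    if (q < 0).any():
        raise ValueError("section counts must be nonnegative")
    total = q.sum()
    if total == 0:
        raise ValueError("all section counts are zero")
    noise = total  # Poisson-like counting noise: Var ≈ ΣQ⁻
    a = float(np.dot(q, q))
    b = float(np.dot(q[:-1], q[1:]))
    c = float(np.dot(q[:-2], q[2:]))
    surs = (3.0 * (a - noise) - 4.0 * b + c) / 240.0
    ce = float(np.sqrt(noise + surs) / total)
    return CEResult(ce=ce, noise_term=float(noise), surs_var_term=surs)


def ce2_cv2(ce_values, estimates) -> float:
    """mean(CE²) over the squared observed CV of a group of estimates.

    Returns ``inf`` (with a warning) when the between-animal variance is
    zero — estimation noise then trivially dominates.
    """
    ce = np.asarray(ce_values, dtype=float)
    est = np.asarray(estimates, dtype=float)
    if ce.shape != est.shape or ce.size < 2:
        raise ValueError("need CEs and estimates for at least two animals")
    cv = est.std(ddof=1) / est.mean()
    if cv == 0:
        warnings.warn(
            "zero between-animal variance; CE²/CV² is infinite", stacklevel=2
        )
        return float("inf")
    return float(np.mean(ce**2) / cv**2)


def group_diagnostics(ce_values, estimates) -> dict[str, float]:
    """The group-level precision columns of the study's count tables."""
    est = np.asarray(estimates, dtype=float)
    return {
        "mean": float(est.mean()),
        "sd": float(est.std(ddof=1)),
        "mean_ce": float(np.mean(ce_values)),
        "ce2_cv2": ce2_cv2(ce_values, estimates),
    }
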