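"""Power-law age-normalization of adult-neurogenesis counts.

Adult hippocampal neurogenesis declines steeply with age in every mammal
examined; counts of proliferating (Ki67+) cells and young (DCX+) neurons
from animals of different ages are therefore not directly comparable.  The
decline is well described by a power law in age — linear in log-log space:

    N(age) = N(ref) * (age / ref)^Y,   Y < 0

so a count measured at ``age`` months is moved along the curve to a common
reference age (3 months by default):

    N_ref = N_actual * exp[(ln(ref) - ln(age)) * Y]
          = N_actual * (ref / age)^Y

Two sets of decline exponents are packaged: the published C57BL/6 curve
constants (`LITERATURE_Y`) and the constants refit across all rodents of
this study (`STUDY_Y`).  :func:`fit_decline_exponent` estimates ``Y`` from
data by ordinary least squares of ln(count) on ln(age), the only fitting
procedure consistent with the model above.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Decline exponents of the published C57BL/6 ageing curve.
LITERATURE_Y = {"Ki67": -1.3933, "DCX": -1.2407}

#: Decline exponents refit from all rodents of this study.
STUDY_Y = {"Ki67": -1.1929, "DCX": -1.0798}

DEFAULT_REFERENCE_AGE_MONTHS = 3.0


@dataclass(frozen=True)
class DeclineModel:
    """A fitted or packaged power-law decline of a neurogenesis marker."""

    marker: str
    exponent: float
    reference_age_months: float = DEFAULT_REFERENCE_AGE_MONTHS
    fit_stddev: Optional[float] = None
    n_fit: Optional[int] = None
    log_intercept: Optional[float] = None

    def __post_init__(self) -> None:
        if self.marker not in ("Ki67", "DCX"):
            raise ValueError("marker must be 'Ki67' or 'DCX'")
        if not self.reference_age_months > 0:
            raise ValueError("reference age must be positive")

    @classmethod
    def literature(cls, marker: str, reference_age_months: float = DEFAULT_REFERENCE_AGE_MONTHS) -> "DeclineModel":
        return cls(marker, LITERATURE_Y[marker], reference_age_months)

    @classmethod
    def study_refit(cls, marker: str, reference_age_months: float = DEFAULT_REFERENCE_AGE_MONTHS) -> "DeclineModel":
        return cls(marker, STUDY_Y[marker], reference_age_months)


def extrapolation_factor(age_months, model: DeclineModel):
    """Multiplier moving a count from ``age_months`` to the reference age."""
    age = np.asarray(age_months, dtype=float)
    if (age <= 0).any():
        raise ValueError("age must be positive")
    return np.exp((np.log(model.reference_age_months) - np.log(age)) * model.exponent)


def extrapolate_count(count, age_months, model: DeclineModel):
    """Move a neurogenesis count along the decline curve to the reference age.

    Equivalent to ``count * (reference_age / age) ** Y``.  Accepts scalars
    or arrays; exact identity when ``age == reference_age`` or ``Y == 0``.
    """
    c = np.asarray(count, dtype=float)
    if (c <= 0).any():
        raise ValueError("count must be positive")
    out = c * extrapolation_factor(age_months, model)
    return float(out) if np.isscalar(count) or out.ndim == 0 else out


def fit_decline_exponent(
    ages,
    counts,
    marker: str,
    reference_age_months: float = DEFAULT_REFERENCE_AGE_MONTHS,
) -> DeclineModel:
    """Fit the decline exponent by log-log ordinary least squares.

    Regresses ln(count) on ln(age); the slope is ``Y`` and its standard
    error is stored as ``fit_stddev``.  Requires at least three points and
    non-degenerate ages.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if ages.shape != counts.shape or ages.ndim != 1:
        raise ValueError("ages and counts must be 1-d arrays of equal length")
    if ages.size < 3:
        raise ValueError("need at least three (age, count) points")
    if (ages <= 0).any() or (counts <= 0).any():
        raise ValueError("ages and counts must be positive")
    log_age = np.log(ages)
    if np.ptp(log_age) == 0:
        raise ValueError("ages have zero variance; the slope is undefined")
    design = sm.add_constant(log_age)
    fit = sm.OLS(np.log(counts), design).fit()
    return DeclineModel(
        marker=marker,
        exponent=float(fit.params[1]),
        reference_age_months=reference_age_months,
        fit_stddev=float(fit.bse[1]),
        n_fit=int(ages.size),
        log_intercept=float(fit.params[0]),
    )


def extrapolation_audit(counts, ages, model: DeclineModel) -> pd.DataFrame:
    """Audit table of the extrapolation: raw count, age, factor, normalized count."""
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    factor = extrapolation_factor(ages, model)
    return pd.DataFrame(
        {
            "raw_count": counts,
            "age_months": ages,
            "factor": factor,
            "normalized_count": counts * factor,
        }
    )
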