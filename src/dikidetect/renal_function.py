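"""Pediatric renal-function math.

Implements the height-independent full-age-spectrum eGFR

    eGFR = 107.3 * (1 - exp(-Age/0.5)) / (SCr / Q)

where Q(age, sex) is the median serum creatinine (SCr, umol/L) of healthy
children, modelled as a sex-specific quartic polynomial in age (years), and
the laboratory trigger for suspected drug-induced kidney injury (DIKI):

    SCr > 130 umol/L, or eGFR outside the age-banded pediatric reference
    interval.

The published girls' quartic has a fourth-order coefficient (-0.00993) that
drives Q non-positive above ~8.5 years; evaluating it there raises
:class:`QDomainError` rather than returning a silent NaN.  A corrected
coefficient set (-0.000993, a plausible one-digit slip that keeps Q in the
60s umol/L at age 18) is available via :meth:`QCoefficients.corrected` and
is used by the synthetic-data presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "AGE_MIN_YEARS",
    "AGE_MAX_YEARS",
    "SCR_THRESHOLD_UMOL_L",
    "QCoefficients",
    "QDomainError",
    "ReferenceInterval",
    "RenalAssessment",
    "RenalParams",
    "REFERENCE_BANDS",
    "compute_q",
    "compute_egfr",
    "reference_interval",
    "classify_trigger",
    "assess_frame",
]

#: Eligibility bounds: 28 days to <18 years.
AGE_MIN_YEARS = 28.0 / 365.25
AGE_MAX_YEARS = 18.0

#: Serum-creatinine trigger threshold, umol/L (strict >).
SCR_THRESHOLD_UMOL_L = 130.0

Sex = Literal["male", "female"]


class QDomainError(ValueError):
    """Raised when the Q polynomial evaluates non-positive for a given age/sex."""


@dataclass(frozen=True)
class QCoefficients:
    """Quartic coefficients (c0..c4) for Q(age) per sex, Q in umol/L, age in years."""

    male: tuple[float, float, float, float, float] = (17.8, 6.68, -0.907, 0.0687, -0.00152)
    female: tuple[float, float, float, float, float] = (18.2, 5.54, -0.602, 0.0421, -0.00993)

    def __post_init__(self) -> None:
        if len(self.male) != 5 or len(self.female) != 5:
            raise ValueError("Q polynomials require exactly five coefficients per sex")

    @classmethod
    def printed(cls) -> "QCoefficients":
        """The coefficients as published (girls' quartic invalid above ~8.5 y)."""
        return cls()

    @classmethod
    def corrected(cls) -> "QCoefficients":
        """Girls' fourth-order term read as -0.000993, valid over the full age span."""
        return cls(female=(18.2, 5.54, -0.602, 0.0421, -0.000993))

    def for_sex(self, sex: str) -> tuple[float, ...]:
        if sex == "male":
            return self.male
        if sex == "female":
            return self.female
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")


@dataclass(frozen=True)
class ReferenceInterval:
    """One age band of the pediatric eGFR reference interval.

    Ages are in months, half-open on the right: [age_lo, age_hi).
    """

    age_lo: float
    age_hi: float
    egfr_lo: float
    egfr_hi: float

    def contains_age(self, age_months: float) -> bool:
        return self.age_lo <= age_months < self.age_hi


#: Age-banded pediatric eGFR reference intervals (months; half-open right).
REFERENCE_BANDS: tuple[ReferenceInterval, ...] = (
    ReferenceInterval(3, 6, 33.0, 84.0),
    ReferenceInterval(6, 12, 57.0, 122.0),
    ReferenceInterval(12, 15, 78.0, 132.0),
    ReferenceInterval(15, 24, 84.0, 150.0),
    ReferenceInterval(24, 18 * 12, 83.0, 143.0),
)

_BAND_EDGES = np.array([b.age_lo for b in REFERENCE_BANDS] + [REFERENCE_BANDS[-1].age_hi])
_BAND_LO = np.array([b.egfr_lo for b in REFERENCE_BANDS])
_BAND_HI = np.array([b.egfr_hi for b in REFERENCE_BANDS])


@dataclass(frozen=True)
class RenalAssessment:
    """Outcome of the DIKI laboratory trigger for one SCr measurement."""

    scr: float
    q: float
    egfr: float
    scr_abnormal: bool
    egfr_abnormal: bool
    diki_trigger: bool


@dataclass(frozen=True)
class RenalParams:
    """Configuration bundle for the trigger.

    egfr_abnormal_direction: 'both' flags eGFR on either side of its band
    (the literal reading of the trigger); 'below_only' flags only reduced
    filtration.
    """

    coefficients: QCoefficients = QCoefficients()
    scr_threshold: float = SCR_THRESHOLD_UMOL_L
    egfr_abnormal_direction: Literal["both", "below_only"] = "both"


def _check_age(age: float) -> None:
    if not (AGE_MIN_YEARS <= age < AGE_MAX_YEARS):
        raise ValueError(
            f"age {age!r} outside eligible range [{AGE_MIN_YEARS:.4f}, {AGE_MAX_YEARS}) years"
        )


def compute_q(age: float, sex: str, coefficients: QCoefficients | None = None) -> float:
    """Median healthy SCr (umol/L) at `age` years for `sex`.

    Raises QDomainError if the polynomial evaluates <= 0 (see module notes on
    the published girls' coefficients).
    """
    _check_age(age)
    coefs = (coefficients or QCoefficients()).for_sex(sex)
    q = float(np.polynomial.polynomial.polyval(age, coefs))
    if not np.isfinite(q) or q <= 0:
        raise QDomainError(
            f"Q polynomial non-positive ({q:.3g} umol/L) at age {age:.3g} y, sex {sex}; "
            "the published girls' quartic is invalid above ~8.5 y — "
            "use QCoefficients.corrected() or restrict the age range"
        )
    return q


def compute_egfr(scr: float, age: float, sex: str, coefficients: QCoefficients | None = None) -> float:
    """Estimated GFR from SCr (umol/L), age (years) and sex."""
    if not np.isfinite(scr) or scr <= 0:
        raise ValueError(f"scr must be finite and positive, got {scr!r}")
    q = compute_q(age, sex, coefficients)
    return 107.3 * (1.0 - np.exp(-age / 0.5)) / (scr / q)


def reference_interval(age: float) -> tuple[float, float] | None:
    """eGFR reference bounds for `age` (years); None below 3 months (no band)."""
    _check_age(age)
    months = age * 12.0
    for band in REFERENCE_BANDS:
        if band.contains_age(months):
            return (band.egfr_lo, band.egfr_hi)
    return None


def classify_trigger(
    scr: float, age: float, sex: str, params: RenalParams | None = None
) -> RenalAssessment:
    """Evaluate the DIKI laboratory trigger for a single SCr result.

    scr_abnormal: SCr strictly above the threshold (130 umol/L default).
    egfr_abnormal: eGFR strictly outside its age band (direction per params);
    always False for ages without a printed band (28 d - 3 mo).
    """
    params = params or RenalParams()
    q = compute_q(age, sex, params.coefficients)
    egfr = 107.3 * (1.0 - np.exp(-age / 0.5)) / (scr / q)
    scr_abnormal = scr > params.scr_threshold
    bounds = reference_interval(age)
    if bounds is None:
        egfr_abnormal = False
    else:
        lo, hi = bounds
        egfr_abnormal = egfr < lo or (params.egfr_abnormal_direction == "both" and egfr > hi)
    return RenalAssessment(
        scr=scr,
        q=q,
        egfr=egfr,
        scr_abnormal=scr_abnormal,
        egfr_abnormal=egfr_abnormal,
        diki_trigger=scr_abnormal or egfr_abnormal,
    )


def _q_array(age: np.ndarray, female: np.ndarray, coefficients: QCoefficients) -> np.ndarray:
    q_m = np.polynomial.polynomial.polyval(age, coefficients.male)
    q_f = np.polynomial.polynomial.polyval(age, coefficients.female)
    q = np.where(female, q_f, q_m)
    if np.any(~np.isfinite(q) | (q <= 0)):
        bad = np.flatnonzero(~np.isfinite(q) | (q <= 0))
        a = age[bad[0]]
        s = "female" if female[bad[0]] else "male"
        raise QDomainError(
            f"Q polynomial non-positive for {bad.size} row(s), e.g. age {a:.3g} y ({s}); "
            "use QCoefficients.corrected() for girls over ~8.5 y"
        )
    return q


def assess_frame(
    df: pd.DataFrame, params: RenalParams | None = None
) -> pd.DataFrame:
    """Vectorised trigger evaluation.

    `df` needs columns scr, age, sex; returns a copy with q, egfr,
    scr_abnormal, egfr_abnormal, diki_trigger appended.
    """
    params = params or RenalParams()
    out = df.copy()
    age = out["age"].to_numpy(dtype=float)
    if len(out) == 0:
        for col in ("q", "egfr"):
            out[col] = np.array([], dtype=float)
        for col in ("scr_abnormal", "egfr_abnormal", "diki_trigger"):
            out[col] = np.array([], dtype=bool)
        return out
    if np.any((age < AGE_MIN_YEARS) | (age >= AGE_MAX_YEARS)):
        raise ValueError("assess_frame: ages outside the eligible pediatric range")
    female = out["sex"].to_numpy() == "female"
    scr = out["scr"].to_numpy(dtype=float)
    q = _q_array(age, female, params.coefficients)
    egfr = 107.3 * (1.0 - np.exp(-age / 0.5)) / (scr / q)

    months = age * 12.0
    idx = np.searchsorted(_BAND_EDGES, months, side="right") - 1
    has_band = (idx >= 0) & (idx < len(REFERENCE_BANDS)) & (months >= _BAND_EDGES[0])
    idx_safe = np.clip(idx, 0, len(REFERENCE_BANDS) - 1)
    below = egfr < _BAND_LO[idx_safe]
    above = egfr > _BAND_HI[idx_safe]
    if params.egfr_abnormal_direction == "both":
        egfr_abn = has_band & (below | above)
    else:
        egfr_abn = has_band & below
    scr_abn = scr > params.scr_threshold

    out["q"] = q
    out["egfr"] = egfr
    out["scr_abnormal"] = scr_abn
    out["egfr_abnormal"] = egfr_abn
    out["diki_trigger"] = scr_abn | egfr_abn
    return out
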