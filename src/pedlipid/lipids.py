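"""Lipid-panel domain types, unit conversion, and LDL-C estimating equations.

The two calculated-LDL methods implemented here are the classic Friedewald
formula,

    LDL-C = TC - HDL-C - TG/5        (all in mg/dL, valid for TG <= 400),

and the Sampson-NIH equation,

    LDL-C = TC/0.948 - HDL/0.971
            - (TG/8.56 + TG*nonHDL/2140 - TG^2/16100) - 9.44,

a polynomial fit to beta-quantification that extends the usable
triglyceride range to 800 mg/dL.  Both are computed in mg/dL; the Sampson
constants are mg/dL-specific, so inputs in mmol/L must be converted first.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Analyte",
    "LdlMethod",
    "LipidPanel",
    "LdlEstimate",
    "MGDL_PER_MMOLL",
    "convert_concentration",
    "non_hdl",
    "friedewald_ldl",
    "sampson_ldl",
    "estimate_all",
    "FRIEDEWALD_TG_LIMIT",
    "SAMPSON_TG_LIMIT",
]


class Sex(str, enum.Enum):
    GIRL = "girl"
    BOY = "boy"


class Analyte(str, enum.Enum):
    """Analyte class, needed because mg/dL <-> mmol/L factors differ."""

    CHOLESTEROL = "cholesterol"
    TRIGLYCERIDE = "triglyceride"


class LdlMethod(str, enum.Enum):
    DIRECT = "direct"
    FRIEDEWALD = "friedewald"
    SAMPSON = "sampson"


#: mg/dL per mmol/L, from the molar masses used in clinical chemistry
#: (cholesterol 386.65 g/mol, average triglyceride 885.7 g/mol).
MGDL_PER_MMOLL = {
    Analyte.CHOLESTEROL: 38.67,
    Analyte.TRIGLYCERIDE: 88.57,
}

#: Friedewald is not applicable when TG exceeds 400 mg/dL (strict: 400 is valid).
FRIEDEWALD_TG_LIMIT = 400.0
#: Sampson-NIH remains usable up to TG of 800 mg/dL.
SAMPSON_TG_LIMIT = 800.0


@dataclass(frozen=True)
class LipidPanel:
    """One subject's lipid panel plus demographics, all concentrations in mg/dL.

    ``ldl_direct`` is the directly measured (homogeneous-assay) LDL-C and is
    optional: panels used purely for estimation may omit it.
    """

    subject_id: str
    sex: Sex
    age_years: float
    tc: float
    hdl: float
    tg: float
    ldl_direct: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.age_years < 0:
            raise ValueError(f"age_years must be >= 0, got {self.age_years}")
        for name in ("tc", "hdl", "tg"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        if self.ldl_direct is not None and not (
            self.ldl_direct > 0 and math.isfinite(self.ldl_direct)
        ):
            raise ValueError(f"ldl_direct must be finite and > 0, got {self.ldl_direct}")
        if self.hdl >= self.tc:
            raise ValueError(
                f"hdl ({self.hdl}) must be < tc ({self.tc}): non-HDL must be positive"
            )

    @property
    def non_hdl(self) -> float:
        return self.tc - self.hdl


@dataclass(frozen=True)
class LdlEstimate:
    """An LDL-C value tagged with its method and validity.

    ``value`` may be <= 0 (it is never clipped, so that difference-based
    agreement analyses stay unbiased); such estimates carry ``valid=False``.
    ``reason`` is non-empty exactly when the estimate is invalid.
    """

    method: LdlMethod
    value: float
    valid: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.valid and self.reason:
            raise ValueError("valid estimate must not carry a reason")
        if not self.valid and not self.reason:
            raise ValueError("invalid estimate must carry a reason")


def convert_concentration(
    value: float,
    analyte: Analyte,
    from_unit: str,
    to_unit: str,
) -> float:
    """Convert a concentration between mg/dL and mmol/L.

    Cholesterol converts at 38.67 mg/dL per mmol/L, triglycerides at 88.57.
    Round trips are exact to floating-point precision.
    """
    units = {"mg/dL", "mmol/L"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be one of {sorted(units)}")
    if value < 0:
        raise ValueError(f"concentration must be >= 0, got {value}")
    if from_unit == to_unit:
        return value
    factor = MGDL_PER_MMOLL[Analyte(analyte)]
    if from_unit == "mg/dL":
        return value / factor
    return value * factor


def non_hdl(tc: float, hdl: float) -> float:
    """Non-HDL cholesterol = TC - HDL-C (mg/dL); requires hdl < tc."""
    if hdl >= tc:
        raise ValueError(f"hdl ({hdl}) must be < tc ({tc})")
    return tc - hdl


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{name} must be finite and > 0, got {v}")


def friedewald_ldl(tc: float, hdl: float, tg: float) -> LdlEstimate:
    """Friedewald calculated LDL-C in mg/dL: TC - HDL - TG/5.

    Flagged invalid (value still returned, unclipped) when TG exceeds
    400 mg/dL or the calculated value is non-positive.
    """
    _check_positive(tc=tc, hdl=hdl, tg=tg)
    value = tc - hdl - tg / 5.0
    if tg > FRIEDEWALD_TG_LIMIT:
        return LdlEstimate(LdlMethod.FRIEDEWALD, value, valid=False, reason="TG>400")
    if value <= 0:
        return LdlEstimate(LdlMethod.FRIEDEWALD, value, valid=False, reason="nonpositive")
    return LdlEstimate(LdlMethod.FRIEDEWALD, value)


def sampson_ldl(tc: float, hdl: float, tg: float) -> LdlEstimate:
    """Sampson-NIH calculated LDL-C in mg/dL.

    Flagged invalid when TG exceeds 800 mg/dL or the calculated value is
    non-positive; the value itself is always returned unclipped.
    """
    _check_positive(tc=tc, hdl=hdl, tg=tg)
    nonhdl = tc - hdl
    value = (
        tc / 0.948
        - hdl / 0.971
        - (tg / 8.56 + tg * nonhdl / 2140.0 - tg * tg / 16100.0)
        - 9.44
    )
    if tg > SAMPSON_TG_LIMIT:
        return LdlEstimate(LdlMethod.SAMPSON, value, valid=False, reason="TG>800")
    if value <= 0:
        return LdlEstimate(LdlMethod.SAMPSON, value, valid=False, reason="nonpositive")
    return LdlEstimate(LdlMethod.SAMPSON, value)


def estimate_all(panel: LipidPanel) -> list[LdlEstimate]:
    """LDL-C by every method for one panel.

    Returns the direct measurement (always valid) plus the Friedewald and
    Sampson-NIH estimates.  If the panel lacks a direct measurement the
    direct entry is omitted and a warning is logged.
    """
    estimates: list[LdlEstimate] = []
    if panel.ldl_direct is not None:
        estimates.append(LdlEstimate(LdlMethod.DIRECT, panel.ldl_direct))
    else:
        logger.warning("panel %s has no direct LDL measurement", panel.subject_id)
    estimates.append(friedewald_ldl(panel.tc, panel.hdl, panel.tg))
    estimates.append(sampson_ldl(panel.tc, panel.hdl, panel.tg))
    return estimates
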