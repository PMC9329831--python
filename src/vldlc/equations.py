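"""Closed-form VLDL-C estimators and clinical-chemistry unit conversions.

All equations work internally in conventional US units (mg/dL for every
lipid and for apoB).  SI units (mmol/L for lipids, g/L for apoB) appear only
at the conversion boundary, :func:`convert_units`, and inside the dual apoB
ratio screening rule which is defined on SI ratios.

Three estimators of the cholesterol carried on very-low-density lipoprotein
(VLDL-C) are provided:

* **Friedewald**: ``TG / 5``, i.e. a fixed VLDL-C/TG ratio of 0.2.
* **Sampson-NIH equation 1**: a quadratic-in-TG expression with a
  TG x non-HDL-C interaction, designed against beta-quantification in
  hypertriglyceridemic patients.  Its coefficients are not authored here;
  they ship as a transcribed, cited constants record and the function
  refuses to run without one.
* **Enhanced Sampson**: the Sampson-NIH equation 1 term set augmented with
  apoB and an apoB x TG interaction.  ApoB counts particles (one copy per
  VLDL/LDL/chylomicron), so its two negative coefficients subtract the
  particle-number-driven share of the estimate — the feature that makes the
  equation sensitive to the cholesterol-enriched remnants of
  dysbetalipoproteinemia.

Negative equation outputs are returned as-is (never clamped): downstream
evaluation must be able to see estimator failure modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    InvalidPanelError,
    MissingAnalyteError,
    UndefinedRatioError,
)

__all__ = [
    "LipidPanel",
    "VldlEstimate",
    "SampsonConstants",
    "EnhancedSampsonConstants",
    "SAMPSON_NIH_EQ1",
    "ENHANCED_SAMPSON",
    "CHOL_MGDL_TO_MMOLL",
    "TG_MGDL_TO_MMOLL",
    "APOB_MGDL_TO_GL",
    "non_hdl",
    "friedewald_vldlc",
    "sampson_vldlc",
    "enhanced_sampson_vldlc",
    "vldlc_tg_ratio",
    "convert_units",
]

ArrayLike = Union[float, np.ndarray]

# Standard clinical conversion factors (per mg/dL).
CHOL_MGDL_TO_MMOLL = 0.02586
TG_MGDL_TO_MMOLL = 0.01129
APOB_MGDL_TO_GL = 0.01

_CONVERSION_FACTORS = {
    "cholesterol": CHOL_MGDL_TO_MMOLL,
    "triglyceride": TG_MGDL_TO_MMOLL,
    "apob": APOB_MGDL_TO_GL,
}


@dataclass(frozen=True)
class LipidPanel:
    """One patient's standard lipid panel, optionally with apoB.

    Parameters
    ----------
    tc : float
        Total cholesterol, mg/dL.
    hdl_c : float
        HDL cholesterol, mg/dL.
    tg : float
        Plasma triglycerides, mg/dL.
    apob : float, optional
        Apolipoprotein B, mg/dL.  ``None`` when not measured.
    """

    tc: float
    hdl_c: float
    tg: float
    apob: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("tc", "hdl_c", "tg"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidPanelError(f"{name} must be finite and >= 0, got {v!r}")
        if self.apob is not None and (not np.isfinite(self.apob) or self.apob < 0):
            raise InvalidPanelError(f"apob must be finite and >= 0, got {self.apob!r}")
        if self.hdl_c > self.tc:
            raise InvalidPanelError(
                f"hdl_c ({self.hdl_c}) exceeds tc ({self.tc}); non-HDL-C would be negative"
            )

    @property
    def non_hdl_c(self) -> float:
        """Non-HDL cholesterol, ``tc - hdl_c`` (mg/dL)."""
        return self.tc - self.hdl_c


@dataclass(frozen=True)
class VldlEstimate:
    """A VLDL-C value (mg/dL) tagged with the method that produced it.

    ``value`` may be negative: equations are evaluated exactly and never
    clamped, so that failure modes remain visible to evaluation code.
    """

    value: ArrayLike
    method: str

    def __post_init__(self) -> None:
        if not self.method:
            raise ValueError("method tag must be set")
        if not np.all(np.isfinite(self.value)):
            raise DomainError(f"estimate is not finite: {self.value!r}")


@dataclass(frozen=True)
class SampsonConstants:
    """Coefficients of Sampson-NIH equation 1 in denominator form.

    ``VLDL-C = TG/tg_divisor + (TG x non-HDL-C)/interaction_divisor
    - TG^2/tg_squared_divisor + intercept``

    The coefficients are transcribed from the cited reference, never
    invented; ``citation`` must be non-empty for the record to be usable.
    """

    tg_divisor: float
    interaction_divisor: float
    tg_squared_divisor: float
    intercept: float
    citation: str
    version: str = "1"

    def validate(self) -> None:
        if not self.citation.strip():
            raise ConfigurationError(
                "Sampson equation-1 constants record has no citation; refusing to "
                "compute with unverified coefficients"
            )
        for name in ("tg_divisor", "interaction_divisor", "tg_squared_divisor"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


#: Sampson-NIH equation 1 (VLDL-C component only; the LDL-C equation's
#: intercept does not belong to it, hence intercept 0).
SAMPSON_NIH_EQ1 = SampsonConstants(
    tg_divisor=8.56,
    interaction_divisor=2140.0,
    tg_squared_divisor=16100.0,
    intercept=0.0,
    citation=(
        "Transcribed from Sampson et al., JAMA Cardiology 2020;5(5):540-548 "
        "(equation 1, VLDL-C component)"
    ),
)


@dataclass(frozen=True)
class EnhancedSampsonConstants:
    """Published denominators and intercept of the enhanced (apoB) equation."""

    non_hdl_divisor: float = 3.81
    hdl_divisor: float = 8.93
    tg_divisor: float = 7.73
    non_hdl_tg_divisor: float = 2050.0
    tg_squared_divisor: float = 13300.0
    apob_divisor: float = 2.49
    apob_tg_divisor: float = 3550.0
    intercept: float = 7.46


ENHANCED_SAMPSON = EnhancedSampsonConstants()


def _check_nonnegative(**values: ArrayLike) -> None:
    for name, v in values.items():
        arr = np.asarray(v, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise DomainError(f"{name} must be finite")
        if np.any(arr < 0):
            raise DomainError(f"{name} must be >= 0, got {v!r}")


def non_hdl(tc: ArrayLike, hdl_c: ArrayLike) -> ArrayLike:
    """Non-HDL cholesterol, ``tc - hdl_c`` (mg/dL).

    Raises :class:`InvalidPanelError` when ``hdl_c > tc`` anywhere.
    """
    _check_nonnegative(tc=tc, hdl_c=hdl_c)
    tc_a, hdl_a = np.asarray(tc, dtype=float), np.asarray(hdl_c, dtype=float)
    if np.any(hdl_a > tc_a):
        raise InvalidPanelError("hdl_c exceeds tc; non-HDL-C would be negative")
    out = tc_a - hdl_a
    return float(out) if out.ndim == 0 else out


def friedewald_vldlc(tg: ArrayLike) -> VldlEstimate:
    """Friedewald VLDL-C: ``TG / 5`` (fixed VLDL-C/TG ratio of 0.2)."""
    _check_nonnegative(tg=tg)
    tg_a = np.asarray(tg, dtype=float)
    value = tg_a / 5.0
    return VldlEstimate(float(value) if value.ndim == 0 else value, "friedewald")


def sampson_vldlc(
    non_hdl_c: ArrayLike,
    tg: ArrayLike,
    constants: Optional[SampsonConstants] = SAMPSON_NIH_EQ1,
) -> VldlEstimate:
    """Sampson-NIH equation 1 for VLDL-C (mg/dL).

    ``constants`` defaults to the shipped, cited record
    :data:`SAMPSON_NIH_EQ1`; passing ``None`` (or a record without a
    citation) raises :class:`ConfigurationError` rather than silently
    defaulting — the coefficients are transcribed, not part of this package's
    own derivation.
    """
    if constants is None:
        raise ConfigurationError(
            "no Sampson equation-1 constants record supplied; load a cited record"
        )
    constants.validate()
    _check_nonnegative(non_hdl_c=non_hdl_c, tg=tg)
    nh = np.asarray(non_hdl_c, dtype=float)
    tg_a = np.asarray(tg, dtype=float)
    value = (
        tg_a / constants.tg_divisor
        + (tg_a * nh) / constants.interaction_divisor
        - tg_a**2 / constants.tg_squared_divisor
        + constants.intercept
    )
    return VldlEstimate(float(value) if value.ndim == 0 else value, "sampson")


def enhanced_sampson_vldlc(
    non_hdl_c: ArrayLike,
    hdl_c: ArrayLike,
    tg: ArrayLike,
    apob: Optional[ArrayLike],
    constants: EnhancedSampsonConstants = ENHANCED_SAMPSON,
) -> VldlEstimate:
    """Enhanced (apoB-augmented) Sampson VLDL-C equation (mg/dL).

    ``value = non_hdl_c/3.81 - hdl_c/8.93 + tg/7.73 + (non_hdl_c*tg)/2050
    - tg^2/13300 - apob/2.49 - (apob*tg)/3550 + 7.46``

    The two apoB terms carry negative coefficients, so the estimate is
    strictly decreasing in apoB at fixed lipids.  A missing apoB raises
    :class:`MissingAnalyteError`; there is deliberately no silent fallback to
    :func:`sampson_vldlc`.
    """
    if apob is None:
        raise MissingAnalyteError(
            "apoB is required for the enhanced equation and is missing"
        )
    _check_nonnegative(non_hdl_c=non_hdl_c, hdl_c=hdl_c, tg=tg, apob=apob)
    nh = np.asarray(non_hdl_c, dtype=float)
    hdl = np.asarray(hdl_c, dtype=float)
    tg_a = np.asarray(tg, dtype=float)
    b = np.asarray(apob, dtype=float)
    c = constants
    value = (
        nh / c.non_hdl_divisor
        - hdl / c.hdl_divisor
        + tg_a / c.tg_divisor
        + (nh * tg_a) / c.non_hdl_tg_divisor
        - tg_a**2 / c.tg_squared_divisor
        - b / c.apob_divisor
        - (b * tg_a) / c.apob_tg_divisor
        + c.intercept
    )
    return VldlEstimate(float(value) if value.ndim == 0 else value, "enhanced_sampson")


def vldlc_tg_ratio(vldl_c: ArrayLike, tg: ArrayLike) -> ArrayLike:
    """VLDL-C to plasma-TG ratio (dimensionless).

    Negative ``vldl_c`` (e.g. a failed estimate) yields a negative ratio —
    no clamping.  ``tg = 0`` anywhere raises :class:`UndefinedRatioError`.
    """
    tg_a = np.asarray(tg, dtype=float)
    if np.any(tg_a <= 0):
        raise UndefinedRatioError("VLDL-C/TG ratio undefined at TG <= 0")
    v = np.asarray(vldl_c, dtype=float)
    out = v / tg_a
    return float(out) if out.ndim == 0 else out


def convert_units(value: ArrayLike, analyte: str, direction: str) -> ArrayLike:
    """Convert between conventional (mg/dL) and SI units.

    ``analyte`` is one of ``cholesterol``, ``triglyceride``, ``apob``;
    ``direction`` is ``to_si`` (mg/dL -> mmol/L, or g/L for apoB) or
    ``to_conventional`` (exact reciprocal).
    """
    try:
        factor = _CONVERSION_FACTORS[analyte]
    except KeyError:
        raise DomainError(
            f"unknown analyte {analyte!r}; expected one of {sorted(_CONVERSION_FACTORS)}"
        ) from None
    _check_nonnegative(value=value)
    v = np.asarray(value, dtype=float)
    if direction == "to_si":
        out = v * factor
    elif direction == "to_conventional":
        out = v / factor
    else:
        raise DomainError(
            f"unknown direction {direction!r}; expected 'to_si' or 'to_conventional'"
        )
    return float(out) if out.ndim == 0 else out
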