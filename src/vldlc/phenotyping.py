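"""Dysbetalipoproteinemia (HLP3) decision rules and cohort exclusion filters.

HLP3 — type III hyperlipoproteinemia, "broad-beta disease" — is defined here
against the beta-quantification (BQ) reference: a VLDL-C to plasma-TG ratio
of at least 0.3 with plasma TG in the 150-1000 mg/dL window.  The module
also implements the two estimated-ratio screeners (standard-panel Sampson
ratio and apoB-enhanced ratio, each with its own cut-point), the dual apoB
ratio screen (TC/apoB >= 6.2 and TG/apoB <= 10 in SI units), the cohort
exclusion filters (Lp-X, extreme TG/TC), and the lipoprotein-fraction
composition ratios used to characterise the HLP3 lipid phenotype.

Threshold inclusivity: both the ratio cut-point and the TG window are
inclusive by default (a recorded HLP3 minimum ratio of exactly 0.30 is a
positive); both are switchable through :class:`~vldlc.config.RunConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .config import DEFAULT_CONFIG, RunConfig
from .equations import (
    LipidPanel,
    convert_units,
    enhanced_sampson_vldlc,
    sampson_vldlc,
    vldlc_tg_ratio,
)
from .errors import InvalidPanelError, MissingAnalyteError

__all__ = [
    "BQRecord",
    "PhenotypeCall",
    "ExclusionReport",
    "apply_exclusions",
    "bq_hlp3_call",
    "estimated_ratio_call",
    "dual_apob_call",
    "fraction_composition",
]


@dataclass(frozen=True)
class BQRecord:
    """A full beta-quantification record: panel plus fraction lipids.

    All fraction lipids are mg/dL; any may be ``None`` when unmeasured.
    ``vldl_c`` is the BQ measurement (total cholesterol minus infranatant
    cholesterol), the ground truth every estimator is judged against.
    """

    panel: LipidPanel
    vldl_c: Optional[float] = None
    vldl_tg: Optional[float] = None
    ldl_c: Optional[float] = None
    ldl_tg: Optional[float] = None
    hdl_tg: Optional[float] = None
    age: Optional[float] = None
    sex: str = "unknown"
    lpx_detected: bool = False

    def __post_init__(self) -> None:
        for name in ("vldl_c", "vldl_tg", "ldl_c", "ldl_tg", "hdl_tg"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise InvalidPanelError(f"{name} must be finite and >= 0, got {v!r}")
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")

    def check_cholesterol_closure(self, tol: float = 2.0) -> bool:
        """Whether HDL-C + LDL-C + VLDL-C matches TC within ``tol`` mg/dL.

        The default 2 mg/dL tolerance absorbs independent rounding of the
        reported fractions in real data; synthetic cohorts close exactly.
        """
        if self.ldl_c is None or self.vldl_c is None:
            raise MissingAnalyteError("closure check needs ldl_c and vldl_c")
        total = self.panel.hdl_c + self.ldl_c + self.vldl_c
        return abs(total - self.panel.tc) <= tol


@dataclass(frozen=True)
class PhenotypeCall:
    """An HLP3 decision: status, the rule that produced it, and its inputs."""

    status: str                      # positive | negative | not_evaluable
    method: str                      # bq_ratio | s_ratio | es_ratio | dual_apob
    score: Optional[float] = None    # ratio value when computable
    cutpoint: Optional[float] = None
    tg_in_window: Optional[bool] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "not_evaluable"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "positive" and self.tg_in_window is False:
            raise ValueError("a positive ratio call requires TG inside the window")

    @property
    def is_positive(self) -> bool:
        return self.status == "positive"


@dataclass(frozen=True)
class ExclusionReport:
    """Counts from the cohort exclusion pass.

    A record failing several rules increments each rule's counter but is
    removed exactly once, so the counters may sum to more than
    ``n_input - n_retained``.
    """

    n_input: int
    n_lpx: int
    n_tg_high: int
    n_tc_high: int
    n_retained: int


def _in_window(tg: float, window: Tuple[float, float], inclusive: bool) -> bool:
    lo, hi = window
    if inclusive:
        return lo <= tg <= hi
    return lo < tg < hi


def _ratio_meets(ratio: float, cutpoint: float, inclusive: bool) -> bool:
    return ratio >= cutpoint if inclusive else ratio > cutpoint


def apply_exclusions(
    records: Sequence[BQRecord], config: RunConfig = DEFAULT_CONFIG
) -> Tuple[List[BQRecord], ExclusionReport]:
    """Drop Lp-X-positive records and extreme-lipemia records.

    Exclusion rules: detectable lipoprotein-X, TG above the TG limit
    (default 3000 mg/dL) or TC above the TC limit (default 1500 mg/dL).
    Idempotent: re-running on the retained set removes nothing.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    retained: List[BQRecord] = []
    n_lpx = n_tg = n_tc = 0
    for rec in records:
        bad = False
        if rec.lpx_detected:
            n_lpx += 1
            bad = True
        if rec.panel.tg > config.exclusion_tg_limit:
            n_tg += 1
            bad = True
        if rec.panel.tc > config.exclusion_tc_limit:
            n_tc += 1
            bad = True
        if not bad:
            retained.append(rec)
    report = ExclusionReport(
        n_input=len(records),
        n_lpx=n_lpx,
        n_tg_high=n_tg,
        n_tc_high=n_tc,
        n_retained=len(retained),
    )
    return retained, report


def bq_hlp3_call(
    vldl_c: float, tg: float, config: RunConfig = DEFAULT_CONFIG
) -> PhenotypeCall:
    """The reference HLP3 rule on measured BQ values.

    Positive iff VLDL-C/TG meets the 0.3 cut-point and TG lies in the
    150-1000 mg/dL window.  TG = 0 makes the ratio undefined, so the call is
    ``not_evaluable``.
    """
    if vldl_c < 0 or tg < 0:
        raise InvalidPanelError("measured vldl_c and tg must be >= 0")
    if tg == 0:
        return PhenotypeCall(
            status="not_evaluable",
            method="bq_ratio",
            cutpoint=config.bq_cutpoint,
            reason="TG = 0: VLDL-C/TG undefined",
        )
    ratio = vldlc_tg_ratio(vldl_c, tg)
    in_window = _in_window(tg, config.tg_window, config.window_inclusive)
    positive = in_window and _ratio_meets(ratio, config.bq_cutpoint, config.ratio_inclusive)
    return PhenotypeCall(
        status="positive" if positive else "negative",
        method="bq_ratio",
        score=ratio,
        cutpoint=config.bq_cutpoint,
        tg_in_window=in_window,
    )


def estimated_ratio_call(
    panel: LipidPanel,
    method: str,
    cutpoint: Optional[float] = None,
    config: RunConfig = DEFAULT_CONFIG,
) -> PhenotypeCall:
    """HLP3 screen from an estimated VLDL-C/TG ratio.

    ``method`` is ``s_ratio`` (standard-panel Sampson estimate, default
    cut-point 0.194) or ``es_ratio`` (apoB-enhanced estimate, default
    cut-point 0.209).  The TG 150-1000 mg/dL window applies exactly as in
    the BQ definition; records outside it are negative (with
    ``tg_in_window=False``), not ``not_evaluable``, so that screening
    sensitivity/specificity share the BQ rule's denominators.
    """
    if method == "s_ratio":
        cut = config.s_ratio_cutpoint if cutpoint is None else cutpoint
    elif method == "es_ratio":
        cut = config.es_ratio_cutpoint if cutpoint is None else cutpoint
    else:
        raise ValueError(f"method must be s_ratio or es_ratio, got {method!r}")
    if not (0 < cut < 1):
        raise ValueError(f"cutpoint must lie in (0, 1), got {cut}")
    if panel.tg == 0:
        return PhenotypeCall(
            status="not_evaluable", method=method, cutpoint=cut,
            reason="TG = 0: estimated ratio undefined",
        )
    if method == "es_ratio":
        if panel.apob is None:
            return PhenotypeCall(
                status="not_evaluable", method=method, cutpoint=cut,
                reason="apoB missing: enhanced estimate not computable",
            )
        est = enhanced_sampson_vldlc(panel.non_hdl_c, panel.hdl_c, panel.tg, panel.apob)
    else:
        est = sampson_vldlc(panel.non_hdl_c, panel.tg)
    ratio = vldlc_tg_ratio(est.value, panel.tg)
    in_window = _in_window(panel.tg, config.tg_window, config.window_inclusive)
    positive = in_window and _ratio_meets(ratio, cut, config.ratio_inclusive)
    return PhenotypeCall(
        status="positive" if positive else "negative",
        method=method,
        score=ratio,
        cutpoint=cut,
        tg_in_window=in_window,
    )


def dual_apob_call(
    tc: float, tg: float, apob: float, config: RunConfig = DEFAULT_CONFIG
) -> PhenotypeCall:
    """Dual apoB ratio screen: TC/apoB >= 6.2 AND TG/apoB <= 10 (SI units).

    Inputs are mg/dL; the rule converts to mmol/L (lipids) and g/L (apoB)
    internally, so the call is invariant to the caller's unit system as long
    as the I/O layer normalised to mg/dL first.
    """
    if tc < 0 or tg < 0 or apob < 0:
        raise InvalidPanelError("tc, tg and apob must be >= 0")
    if apob == 0:
        return PhenotypeCall(
            status="not_evaluable", method="dual_apob",
            reason="apoB = 0: ratios undefined",
        )
    tc_si = convert_units(tc, "cholesterol", "to_si")
    tg_si = convert_units(tg, "triglyceride", "to_si")
    apob_si = convert_units(apob, "apob", "to_si")
    positive = (tc_si / apob_si >= config.dual_tc_apob_min) and (
        tg_si / apob_si <= config.dual_tg_apob_max
    )
    return PhenotypeCall(
        status="positive" if positive else "negative",
        method="dual_apob",
        score=tc_si / apob_si,
    )


#: Keys of the composition-ratio dictionary, in reporting order.
COMPOSITION_KEYS = (
    "non_hdl_c_frac_of_tc",
    "non_hdl_tg_frac_of_tg",
    "vldl_c_frac_of_non_hdl_c",
    "vldl_c_over_vldl_tg",
    "ldl_c_over_ldl_tg",
    "hdl_c_over_hdl_tg",
)


def fraction_composition(record: BQRecord) -> Dict[str, Optional[float]]:
    """Six lipoprotein-composition ratios characterising the HLP3 phenotype.

    Returns the fraction of TC on non-HDL particles, the fraction of TG on
    non-HDL particles, the share of non-HDL-C carried by VLDL, and the
    cholesterol/TG ratios within VLDL, LDL and HDL.  A ratio whose
    denominator is zero (or whose inputs are missing) is returned as
    ``None``; the others are still computed.
    """
    p = record.panel

    def safe(num: Optional[float], den: Optional[float]) -> Optional[float]:
        if num is None or den is None or den == 0:
            return None
        return num / den

    non_hdl_tg = (
        None
        if record.ldl_tg is None or record.vldl_tg is None
        else record.ldl_tg + record.vldl_tg
    )
    return {
        "non_hdl_c_frac_of_tc": safe(p.non_hdl_c, p.tc),
        "non_hdl_tg_frac_of_tg": safe(non_hdl_tg, p.tg),
        "vldl_c_frac_of_non_hdl_c": safe(record.vldl_c, p.non_hdl_c),
        "vldl_c_over_vldl_tg": safe(record.vldl_c, record.vldl_tg),
        "ldl_c_over_ldl_tg": safe(record.ldl_c, record.ldl_tg),
        "hdl_c_over_hdl_tg": safe(p.hdl_c, record.hdl_tg),
    }
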