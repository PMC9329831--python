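"""Run-level configuration: diagnostic thresholds and rule switches.

Defaults encode the published operating points: VLDL-C/TG cut-point 0.3 for
the beta-quantification (BQ) definition of dysbetalipoproteinemia, screening
cut-points 0.194 (standard-panel estimator) and 0.209 (apoB-enhanced one),
the TG 150-1000 mg/dL evaluability window, dual apoB ratio thresholds
(TC/apoB >= 6.2, TG/apoB <= 10, SI units), and the cohort exclusion limits
(Lp-X detected, TG > 3000 mg/dL, TC > 1500 mg/dL).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


@dataclass(frozen=True)
class RunConfig:
    bq_cutpoint: float = 0.3
    s_ratio_cutpoint: float = 0.194
    es_ratio_cutpoint: float = 0.209
    tg_window: Tuple[float, float] = (150.0, 1000.0)
    dual_tc_apob_min: float = 6.2   # TC[mmol/L] / apoB[g/L]
    dual_tg_apob_max: float = 10.0  # TG[mmol/L] / apoB[g/L]
    exclusion_tg_limit: float = 3000.0
    exclusion_tc_limit: float = 1500.0
    ratio_inclusive: bool = True    # positive at ratio == cut-point
    window_inclusive: bool = True   # positive at TG == window edge
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.tg_window
        if not (0 < lo < hi):
            raise ValueError(f"tg_window must be ordered and positive, got {self.tg_window}")
        for name in (
            "bq_cutpoint", "s_ratio_cutpoint", "es_ratio_cutpoint",
            "dual_tc_apob_min", "dual_tg_apob_max",
            "exclusion_tg_limit", "exclusion_tc_limit",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = RunConfig()
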