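"""Least-squares derivation of VLDL-C (and VLDL-TG) estimating equations.

The derivation mirrors how clinical estimating equations of this family are
built: evaluate a small basis of terms over the standard panel (linear
analytes, a TG x non-HDL-C interaction, TG^2, and — for the enhanced basis —
apoB and an apoB x TG interaction), then ordinary least squares against the
beta-quantification measurement.  The published equation retains every
candidate term, so full-basis OLS is the reference path; backward stepwise
elimination is available behind a flag.

Numerical conditioning: TG^2 columns reach ~1e7 while linear columns sit
near 1e2, so term columns are scaled to unit L2 norm for the solve and the
coefficients are back-transformed to the raw scale.

Fitted coefficients are also exposed in the field's reciprocal "denominator"
presentation (an equation written as ``x/3.81 - y/8.93 + ...``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, TypeVar

import numpy as np
from scipy import stats

from .config import DEFAULT_CONFIG, RunConfig
from .equations import LipidPanel
from .errors import (
    MissingAnalyteError,
    RankDeficientError,
    TooFewRecordsError,
)
from .phenotyping import BQRecord, PhenotypeCall, bq_hlp3_call

__all__ = [
    "Term",
    "TermBasis",
    "SAMPSON_BASIS",
    "ENHANCED_BASIS",
    "SplitSpec",
    "AccuracyDiagnostics",
    "FitResult",
    "build_design_matrix",
    "fit_vldlc_equation",
    "random_split",
    "hlp3_subset_fit",
    "estimate_accuracy",
    "fit_ratio_call",
]

ANALYTES = ("non_hdl_c", "hdl_c", "tg", "apob")

T = TypeVar("T")


@dataclass(frozen=True)
class Term:
    """One regression term over the panel analytes."""

    kind: str  # linear | product | square | intercept
    vars: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = {"linear": 1, "product": 2, "square": 1, "intercept": 0}
        if self.kind not in expected:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if len(self.vars) != expected[self.kind]:
            raise ValueError(f"{self.kind} term takes {expected[self.kind]} variable(s)")
        for v in self.vars:
            if v not in ANALYTES:
                raise ValueError(f"unknown analyte {v!r}; expected one of {ANALYTES}")

    @property
    def label(self) -> str:
        if self.kind == "intercept":
            return "intercept"
        if self.kind == "square":
            return f"{self.vars[0]}^2"
        return "*".join(self.vars)

    def evaluate(self, values: Dict[str, np.ndarray]) -> np.ndarray:
        if self.kind == "intercept":
            n = len(next(iter(values.values())))
            return np.ones(n)
        if self.kind == "linear":
            return values[self.vars[0]]
        if self.kind == "square":
            return values[self.vars[0]] ** 2
        return values[self.vars[0]] * values[self.vars[1]]


def linear(var: str) -> Term:
    return Term("linear", (var,))


def product(a: str, b: str) -> Term:
    return Term("product", (a, b))


def square(var: str) -> Term:
    return Term("square", (var,))


def intercept() -> Term:
    return Term("intercept")


@dataclass(frozen=True)
class TermBasis:
    """An ordered, duplicate-free set of regression terms."""

    name: str
    terms: Tuple[Term, ...]

    def __post_init__(self) -> None:
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in basis")
        if sum(1 for t in self.terms if t.kind == "intercept") > 1:
            raise ValueError("at most one intercept term allowed")

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def labels(self) -> Tuple[str, ...]:
        return tuple(t.label for t in self.terms)

    @property
    def analytes(self) -> Tuple[str, ...]:
        used = {v for t in self.terms for v in t.vars}
        return tuple(a for a in ANALYTES if a in used)


#: Term structure of Sampson-NIH equation 1 (coefficients live in equations).
SAMPSON_BASIS = TermBasis(
    "sampson",
    (linear("tg"), product("tg", "non_hdl_c"), square("tg"), intercept()),
)

#: Term structure of the apoB-enhanced equation.
ENHANCED_BASIS = TermBasis(
    "enhanced",
    (
        linear("non_hdl_c"),
        linear("hdl_c"),
        linear("tg"),
        product("non_hdl_c", "tg"),
        square("tg"),
        linear("apob"),
        product("apob", "tg"),
        intercept(),
    ),
)


@dataclass(frozen=True)
class SplitSpec:
    """Parameters of the random train/validation partition."""

    fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction <= 1):
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")


@dataclass(frozen=True)
class AccuracyDiagnostics:
    """Agreement metrics between an estimator and the reference method.

    ``slope``/``intercept``/``r2`` come from OLS of the reference on the
    estimate by default (reference on the y-axis, calculated value on the
    x-axis), the orientation used when plotting calculated vs measured
    values; the ``orientation`` field records which way the line was fit.
    """

    mad: float
    rmse: float
    r2: float
    slope: float
    intercept: float
    n: int
    orientation: str = "ref_on_est"


def estimate_accuracy(
    estimates: Sequence[float],
    reference: Sequence[float],
    orientation: str = "ref_on_est",
) -> AccuracyDiagnostics:
    """MAD, RMSE and the linear-fit diagnostics of estimate vs reference.

    MAD is the mean absolute difference, RMSE the root-mean-square error.
    ``orientation`` is ``ref_on_est`` (default) or ``est_on_ref``.
    """
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 2:
        raise ValueError("need at least 2 points")
    diff = est - ref
    mad = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    x, y = (est, ref) if orientation == "ref_on_est" else (ref, est)
    if orientation not in ("ref_on_est", "est_on_ref"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if np.ptp(x) == 0:
        slope = intercept_ = r2 = float("nan")
    else:
        res = stats.linregress(x, y)
        slope, intercept_ = float(res.slope), float(res.intercept)
        r2 = float(res.rvalue**2)
    return AccuracyDiagnostics(
        mad=mad, rmse=rmse, r2=r2, slope=slope, intercept=intercept_,
        n=est.size, orientation=orientation,
    )


@dataclass(frozen=True)
class FitResult:
    """Fitted coefficients of a term basis, with diagnostics.

    ``coefficients`` are on the raw analyte scale, ordered as the basis.
    ``reciprocal_form`` presents each non-intercept coefficient as the
    signed denominator ``1/coefficient`` (the style estimating equations are
    printed in); the intercept is shown as-is.
    """

    basis: TermBasis
    coefficients: Tuple[float, ...]
    n_train: int
    diagnostics: AccuracyDiagnostics
    outcome: str = "vldl_c"
    hlp3_specific: bool = False

    @property
    def coef_by_label(self) -> Dict[str, float]:
        return dict(zip(self.basis.labels, self.coefficients))

    @property
    def reciprocal_form(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for term, coef in zip(self.basis.terms, self.coefficients):
            out[term.label] = coef if term.kind == "intercept" else 1.0 / coef
        return out

    def predict(self, panels: Sequence[LipidPanel]) -> np.ndarray:
        X = build_design_matrix(panels, self.basis)
        return X @ np.asarray(self.coefficients)


def build_design_matrix(
    panels: Sequence[LipidPanel], basis: TermBasis
) -> np.ndarray:
    """Evaluate each basis term on each panel; columns follow basis order."""
    if len(panels) == 0:
        raise ValueError("panels must be non-empty")
    values: Dict[str, np.ndarray] = {}
    for analyte in basis.analytes:
        col = []
        for i, p in enumerate(panels):
            v = getattr(p, analyte)
            if v is None:
                term = next(t for t in basis.terms if analyte in t.vars)
                raise MissingAnalyteError(
                    f"record {i}: analyte {analyte!r} required by term "
                    f"{term.label!r} is missing"
                )
            col.append(float(v))
        values[analyte] = np.asarray(col)
    if not values:  # intercept-only basis
        values = {"_ones": np.ones(len(panels))}
    cols = [t.evaluate(values) for t in basis.terms]
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Column-scaled least squares with an explicit rank check."""
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        dead = [labels[j] for j in np.flatnonzero(norms == 0)]
        raise RankDeficientError(f"all-zero term column(s): {dead}")
    Xs = X / norms
    beta_s, _, rank, _ = np.linalg.lstsq(Xs, y, rcond=None)
    if rank < X.shape[1]:
        raise RankDeficientError(
            f"design matrix rank {rank} < {X.shape[1]} terms; "
            f"collinear terms among {list(labels)}"
        )
    return beta_s / norms


def fit_vldlc_equation(
    records: Sequence[Tuple[LipidPanel, float]],
    basis: TermBasis,
    stepwise: bool = False,
    p_remove: float = 0.05,
) -> FitResult:
    """OLS fit of a term basis to measured VLDL-C (or any outcome).

    ``records`` pairs each panel with its reference measurement.  The
    default keeps every candidate term (the published equation retains all
    of them); ``stepwise=True`` applies backward elimination, repeatedly
    dropping the least significant non-intercept term with p > ``p_remove``.
    Diagnostics are computed on the training records.
    """
    panels = [r[0] for r in records]
    y = np.asarray([r[1] for r in records], dtype=float)
    if len(panels) <= len(basis):
        raise TooFewRecordsError(
            f"{len(panels)} records cannot identify {len(basis)} terms"
        )
    work = basis
    while True:
        X = build_design_matrix(panels, work)
        beta = _ols(X, y, work.labels)
        if not stepwise or len(work) <= 1:
            break
        drop = _least_significant(X, y, beta, work, p_remove)
        if drop is None:
            break
        work = TermBasis(work.name, tuple(t for t in work.terms if t is not drop))
    pred = X @ beta
    diag = estimate_accuracy(pred, y)
    return FitResult(
        basis=work,
        coefficients=tuple(float(b) for b in beta),
        n_train=len(panels),
        diagnostics=diag,
    )


def _least_significant(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, basis: TermBasis, p_remove: float
) -> Optional[Term]:
    """The droppable term with the largest p-value above the threshold."""
    n, k = X.shape
    resid = y - X @ beta
    dof = n - k
    if dof <= 0:
        return None
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    worst, worst_p = None, p_remove
    for term, p in zip(basis.terms, pvals):
        if term.kind == "intercept":
            continue
        if p > worst_p:
            worst, worst_p = term, p
    return worst


def random_split(
    records: Sequence[T], spec: SplitSpec = SplitSpec()
) -> Tuple[List[T], List[T]]:
    """Uniform random partition into training and validation sets.

    Reproducible under ``spec.seed``; the two parts partition the input
    exactly (sizes differ by at most one at fraction 0.5).  ``fraction=1``
    returns an empty validation set with a warning.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(records))
    n_train = int(round(spec.fraction * len(records)))
    train = [records[i] for i in sorted(order[:n_train])]
    valid = [records[i] for i in sorted(order[n_train:])]
    if not valid:
        warnings.warn("validation set is empty at this split fraction", stacklevel=2)
    return train, valid


def hlp3_subset_fit(
    records: Sequence[BQRecord],
    outcome: str,
    basis: TermBasis = ENHANCED_BASIS,
    config: RunConfig = DEFAULT_CONFIG,
) -> FitResult:
    """Fit a monitoring equation on the HLP3-positive subset only.

    Records are classified by the BQ ratio rule first; only positives enter
    the regression.  ``outcome`` is ``vldl_c`` or ``vldl_tg``.  The result
    is flagged ``hlp3_specific`` and :func:`fit_ratio_call` refuses to use
    it for screening: fitted on an enriched subset, it overestimates in the
    general population.
    """
    if outcome not in ("vldl_c", "vldl_tg"):
        raise ValueError(f"outcome must be vldl_c or vldl_tg, got {outcome!r}")
    positives: List[BQRecord] = []
    for rec in records:
        if rec.vldl_c is None:
            continue
        if bq_hlp3_call(rec.vldl_c, rec.panel.tg, config).is_positive:
            positives.append(rec)
    minimum = 2 * len(basis)
    if len(positives) < minimum:
        raise TooFewRecordsError(
            f"{len(positives)} HLP3-positive records; need at least {minimum} "
            f"for a {len(basis)}-term basis"
        )
    pairs = []
    for rec in positives:
        val = getattr(rec, outcome)
        if val is None:
            raise MissingAnalyteError(f"HLP3 record lacks measured {outcome}")
        pairs.append((rec.panel, val))
    fit = fit_vldlc_equation(pairs, basis)
    return replace(fit, outcome=outcome, hlp3_specific=True)


def fit_ratio_call(
    panel: LipidPanel,
    fit: FitResult,
    cutpoint: float,
    config: RunConfig = DEFAULT_CONFIG,
) -> PhenotypeCall:
    """Screen a panel with a custom fitted equation's estimate/TG ratio.

    HLP3-specific fits are rejected outright — they are monitoring
    equations for already-diagnosed patients, not screeners.
    """
    if fit.hlp3_specific:
        raise ValueError(
            "HLP3-specific equations must not be used for screening; "
            "they overestimate in the general population"
        )
    if panel.tg == 0:
        return PhenotypeCall(
            status="not_evaluable", method="fit_ratio", cutpoint=cutpoint,
            reason="TG = 0: ratio undefined",
        )
    est = float(fit.predict([panel])[0])
    ratio = est / panel.tg
    lo, hi = config.tg_window
    in_window = lo <= panel.tg <= hi if config.window_inclusive else lo < panel.tg < hi
    meets = ratio >= cutpoint if config.ratio_inclusive else ratio > cutpoint
    positive = in_window and meets
    return PhenotypeCall(
        status="positive" if positive else "negative",
        method="fit_ratio",
        score=ratio,
        cutpoint=cutpoint,
        tg_in_window=in_window,
    )
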