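"""Stage 1: pseudo-first-order rate constants from single time courses.

Activity mode follows the published analysis: unweighted linear
regression of ln(residual activity) on time, the slope's negative being
k. Absorbance mode fits the chromophore-release curve
A(t) = A_inf·(1 − exp(−k·t)) by nonlinear least squares, co-estimating
the plateau by default (robust to pipetting error in the thiol
concentration) or holding it fixed at the Beer-Lambert value for
stoichiometry checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .errors import (
    DomainError,
    EstimationError,
    InsufficientDataError,
    UsageError,
)
from .model import ProtectionConditions, SignalModel
from .simulate import TimeCourse

__all__ = [
    "RateEstimate",
    "ModeAgreement",
    "fit_rate_activity",
    "fit_rate_absorbance",
    "fit_rate",
    "compare_modes",
]


@dataclass(frozen=True)
class RateEstimate:
    """A pseudo-first-order rate constant with its fit diagnostics.

    ``r_squared`` is computed on the fitted (transformed) scale and is
    diagnostic only; ``n_dropped`` counts nonpositive activity values
    excluded before the log transform; ``flags`` carries warnings such
    as ``no_inactivation`` or ``ill_conditioned``.
    """

    k: float
    se_k: float
    r_squared: float
    n_points: int
    mode: Literal["activity", "absorbance"]
    conditions: ProtectionConditions
    variant: str = "enzyme"
    replicate: int = 0
    n_dropped: int = 0
    a_inf: float | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.k < 0 or self.se_k < 0:
            raise DomainError("k and se_k must be nonnegative")
        if not (0.0 <= self.r_squared <= 1.0):
            raise DomainError("r_squared must lie in [0, 1]")
        if self.n_points < 3:
            raise DomainError("a rate estimate needs at least 3 points")


def _r2_clamped(rvalue: float) -> float:
    if not math.isfinite(rvalue):
        return 0.0
    return min(max(rvalue * rvalue, 0.0), 1.0)


def fit_rate_activity(tc: TimeCourse) -> RateEstimate:
    """Log-linear fit of an activity-mode course.

    Points with nonpositive activity (possible under additive noise)
    are dropped, not clamped; their count is carried on the estimate.
    A significantly positive slope (beyond 2 SE) is reported as k = 0
    with a ``no_inactivation`` flag rather than a negative rate.
    """
    if tc.mode != "activity":
        raise UsageError(f"fit_rate_activity needs an activity-mode course, got {tc.mode!r}")
    usable = tc.values > 0
    n_dropped = int(np.sum(~usable))
    t = tc.times[usable]
    y = np.log(tc.values[usable])
    if t.size < 3:
        raise InsufficientDataError(
            f"only {t.size} usable points after dropping nonpositive activities"
        )
    res = stats.linregress(t, y)
    slope = float(res.slope)
    se = float(res.stderr) if math.isfinite(res.stderr) else 0.0
    flags: tuple[str, ...] = ()
    if slope > 2.0 * se:
        k, se_k = 0.0, se
        flags = ("no_inactivation",)
    else:
        k, se_k = max(-slope, 0.0), se
    return RateEstimate(
        k=k,
        se_k=se_k,
        r_squared=_r2_clamped(float(res.rvalue)),
        n_points=int(t.size),
        mode="activity",
        conditions=tc.conditions,
        variant=tc.variant,
        replicate=tc.replicate,
        n_dropped=n_dropped,
        flags=flags,
    )


def fit_rate_absorbance(
    tc: TimeCourse,
    sig: SignalModel,
    fix_a_inf: bool = False,
) -> RateEstimate:
    """Exponential-rise fit of a chromophore-release trace.

    By default both k and the plateau A_inf are estimated; with
    ``fix_a_inf`` the plateau is held at sig's Beer-Lambert value and
    the fit reduces to log-linear regression of ln(1 − A/A_inf) on t.
    A trace that never reaches half the fixed plateau is flagged
    ``ill_conditioned``.
    """
    if tc.mode != "absorbance":
        raise UsageError(f"fit_rate_absorbance needs an absorbance-mode course, got {tc.mode!r}")
    t, a = tc.times, tc.values
    if t.size < 5:
        raise InsufficientDataError(f"absorbance fit needs at least 5 points, got {t.size}")
    if np.all(a <= 0):
        raise InsufficientDataError("trace carries no signal (all values nonpositive)")

    flags: tuple[str, ...] = ()
    if fix_a_inf:
        a_inf = sig.plateau
        if float(np.max(a)) < 0.5 * a_inf:
            flags = ("ill_conditioned",)
        frac = 1.0 - a / a_inf
        usable = frac > 0
        tt, yy = t[usable], np.log(frac[usable])
        if tt.size < 3:
            raise InsufficientDataError("too few points below the fixed plateau")
        res = stats.linregress(tt, yy)
        k = max(-float(res.slope), 0.0)
        se_k = float(res.stderr) if math.isfinite(res.stderr) else 0.0
        r2 = _r2_clamped(float(res.rvalue))
        n = int(tt.size)
        n_dropped = int(t.size - tt.size)
    else:
        a_max = float(np.max(a))
        k0 = 1.0 / max(float(t[-1]), 1e-12)
        try:
            popt, pcov = optimize.curve_fit(
                lambda tt, a_inf, k: a_inf * (1.0 - np.exp(-k * tt)),
                t,
                a,
                p0=(a_max if a_max > 0 else 1.0, k0),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover - pathological traces
            raise EstimationError(
                f"absorbance fit failed to converge for {tc.variant} trace: {exc}"
            ) from exc
        a_inf, k = float(popt[0]), float(popt[1])
        if k < 0:
            k = 0.0
        perr = np.sqrt(np.diag(pcov))
        se_k = float(perr[1]) if math.isfinite(perr[1]) else 0.0
        pred = a_inf * (1.0 - np.exp(-popt[1] * t))
        ss_res = float(np.sum((a - pred) ** 2))
        ss_tot = float(np.sum((a - np.mean(a)) ** 2))
        r2 = 1.0 if ss_tot == 0 else min(max(1.0 - ss_res / ss_tot, 0.0), 1.0)
        n = int(t.size)
        n_dropped = 0
    return RateEstimate(
        k=k,
        se_k=se_k,
        r_squared=r2,
        n_points=n,
        mode="absorbance",
        conditions=tc.conditions,
        variant=tc.variant,
        replicate=tc.replicate,
        n_dropped=n_dropped,
        a_inf=a_inf,
        flags=flags,
    )


def fit_rate(tc: TimeCourse, sig: SignalModel | None = None, **kwargs) -> RateEstimate:
    """Dispatch on the course's observation mode."""
    if tc.mode == "activity":
        return fit_rate_activity(tc)
    if sig is None:
        raise UsageError("absorbance-mode fitting needs the SignalModel")
    return fit_rate_absorbance(tc, sig, **kwargs)


@dataclass(frozen=True)
class ModeAgreement:
    """Cross-check that the two observation modes report the same process."""

    ratio: float
    se_ratio: float
    tolerance: float
    passed: bool


def compare_modes(
    a: RateEstimate,
    b: RateEstimate,
    tolerance: float | None = None,
) -> ModeAgreement:
    """Ratio of two rate estimates of the same reaction in different modes.

    The delta-method SE of the ratio combines the two relative SEs in
    quadrature. Default acceptance: the ratio lies within 1 ± 2× that
    combined relative SE; pass a ``tolerance`` to use a fixed band
    (e.g. 0.1 for ±10%) instead.
    """
    if a.mode == b.mode:
        raise UsageError("compare_modes needs estimates from different observation modes")
    if a.conditions != b.conditions:
        raise UsageError("compare_modes needs estimates under identical conditions")
    if b.k <= 0:
        raise DomainError("reference rate constant must be positive")
    ratio = a.k / b.k
    rel = math.hypot(
        a.se_k / a.k if a.k > 0 else 0.0,
        b.se_k / b.k,
    )
    se_ratio = ratio * rel
    # floor keeps the noiseless (se = 0) case from demanding bit-exact equality
    tol = max(2.0 * rel, 1e-9) if tolerance is None else tolerance
    return ModeAgreement(ratio=ratio, se_ratio=se_ratio, tolerance=tol,
                         passed=abs(ratio - 1.0) <= tol)
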