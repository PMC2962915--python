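"""Stage 2: binding parameters from fitted rate constants.

Two linearisations carry the analysis, both fitted by unweighted least
squares on reciprocal-transformed data, matching the published
procedure (a weighted/nonlinear alternative is available as an
extension, not the default):

* saturation: 1/k vs 1/[DTNB] is a line with intercept 1/j and slope
  K_DTNB/j, giving the baseline parameters of each enzyme variant;
* protection: 1/k_Co vs [Co] is a line with intercept 1/k_max and slope
  (1/j)(K_DTNB/[DTNB])(1/Kd), giving the ligand dissociation constant
  once j and K_DTNB are known.

Standard errors propagate by the delta method from the regression
covariance, treating the protection-line slope and the baseline (j,
K_DTNB) as independent (only marginal uncertainties are available); a
parametric bootstrap is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .errors import (
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
    UsageError,
)
from .model import CoenzymeBinding, InactivationParams, k_inactivation
from .ratefit import RateEstimate
from .units import mM, to_mM

__all__ = [
    "SaturationFit",
    "ProtectionSeries",
    "KdResult",
    "Ratio",
    "fit_saturation",
    "fit_kd",
    "bootstrap_se_kd",
    "discrimination_ratio",
    "fold_change",
    "build_comparison_table",
    "round_sig",
]


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 and non-finite pass through)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def _ols_line(x: np.ndarray, y: np.ndarray):
    """OLS of y on x; returns (intercept, slope, se_int, se_slope, cov_int_slope)."""
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    b, m = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params())
    se_b = math.sqrt(max(cov[0, 0], 0.0))
    se_m = math.sqrt(max(cov[1, 1], 0.0))
    return b, m, se_b, se_m, float(cov[0, 1])


@dataclass(frozen=True)
class SaturationFit:
    """Baseline parameters (j, K_DTNB) of one variant with uncertainties.

    ``line_*`` fields describe the double-reciprocal regression the
    parameters came from. ``degenerate`` marks data with no detectable
    saturation (slope ≤ 0), in which case ``k_dtnb`` is reported as the
    0 limit and ``params`` is unavailable.
    """

    j: float
    se_j: float
    k_dtnb: float
    se_k_dtnb: float
    line_slope: float
    line_intercept: float
    se_slope: float
    se_intercept: float
    method: Literal["double_reciprocal", "nonlinear"]
    variant: str = "enzyme"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.line_intercept > 0:
            raise DegenerateFitError("saturation fit requires a positive ordinate intercept")
        if not self.degenerate and not (self.j > 0 and self.k_dtnb > 0):
            raise DomainError("a non-degenerate fit must have positive j and K_DTNB")

    @property
    def params(self) -> InactivationParams:
        if self.degenerate:
            raise DegenerateFitError(
                f"saturation fit for {self.variant!r} is degenerate (no saturation observed)"
            )
        return InactivationParams(j=self.j, k_dtnb=self.k_dtnb)


def fit_saturation(
    rates: Sequence[RateEstimate],
    method: Literal["double_reciprocal", "nonlinear"] = "double_reciprocal",
) -> SaturationFit:
    """Extract (j, K_DTNB) from ligand-free rates at varying [DTNB].

    Default is the double-reciprocal regression of 1/k on 1/[DTNB]:
    j = 1/intercept, K_DTNB = slope/intercept, SEs by the delta method
    from the regression covariance. The nonlinear option fits the
    hyperbola k = j[DTNB]/(K_DTNB + [DTNB]) directly and agrees with
    the linearised method exactly on noiseless data.
    """
    rates = [r for r in rates if r.conditions.co_conc == 0]
    if not rates:
        raise InsufficientDataError("no ligand-free rate estimates supplied")
    variant = rates[0].variant
    if any(r.variant != variant for r in rates):
        raise UsageError("saturation fit mixes rates from different variants")
    d = np.array([r.conditions.dtnb_conc for r in rates], dtype=float)
    k = np.array([r.k for r in rates], dtype=float)
    if len(np.unique(d)) < 3:
        raise InsufficientDataError("saturation fit needs at least 3 distinct DTNB levels")
    if np.any(k <= 0):
        raise DegenerateFitError("saturation fit needs strictly positive rate constants")

    b, m, se_b, se_m, cov_bm = _ols_line(1.0 / d, 1.0 / k)
    if b <= 0:
        raise DegenerateFitError(
            f"nonpositive ordinate intercept ({b:.3g}): data do not show saturation"
        )
    degenerate = m <= 0
    j = 1.0 / b
    se_j = se_b / b**2
    if degenerate:
        k_dtnb, se_k = 0.0, se_m / b
    else:
        k_dtnb = m / b
        # delta method for m/b with full covariance
        var_k = (se_m / b) ** 2 + (m * se_b / b**2) ** 2 - 2.0 * (m / b**3) * cov_bm
        se_k = math.sqrt(max(var_k, 0.0))

    if method == "nonlinear" and not degenerate:
        popt, pcov = optimize.curve_fit(
            lambda dd, jj, kk: jj * dd / (kk + dd), d, k, p0=(j, k_dtnb), maxfev=20000
        )
        j, k_dtnb = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        se_j = float(perr[0]) if math.isfinite(perr[0]) else se_j
        se_k = float(perr[1]) if math.isfinite(perr[1]) else se_k
        b, m = 1.0 / j, k_dtnb / j

    return SaturationFit(
        j=j, se_j=se_j, k_dtnb=k_dtnb, se_k_dtnb=se_k,
        line_slope=m, line_intercept=b, se_slope=se_m, se_intercept=se_b,
        method=method, variant=variant, degenerate=degenerate,
    )


@dataclass(frozen=True)
class ProtectionSeries:
    """Rate constants at graded ligand concentrations, fixed [DTNB]."""

    variant: str
    coenzyme: str
    dtnb_conc: float
    rates: tuple[RateEstimate, ...]

    def __post_init__(self) -> None:
        if any(r.conditions.dtnb_conc != self.dtnb_conc for r in self.rates):
            raise UsageError("protection series mixes DTNB concentrations")
        if len({r.conditions.co_conc for r in self.rates}) < 3:
            raise InsufficientDataError(
                "protection series needs at least 3 distinct coenzyme levels"
            )

    @classmethod
    def from_rates(cls, rates: Iterable[RateEstimate]) -> "ProtectionSeries":
        rates = tuple(rates)
        if not rates:
            raise InsufficientDataError("no rate estimates supplied")
        first = rates[0]
        # the zero-ligand course may carry no coenzyme label
        named = {r.conditions.coenzyme for r in rates if r.conditions.coenzyme}
        if len(named) > 1:
            raise UsageError(f"protection series mixes coenzymes: {sorted(named)}")
        return cls(
            variant=first.variant,
            coenzyme=named.pop() if named else "ligand",
            dtnb_conc=first.conditions.dtnb_conc,
            rates=rates,
        )

    @property
    def co_concs(self) -> np.ndarray:
        return np.array([r.conditions.co_conc for r in self.rates], dtype=float)


@dataclass(frozen=True)
class KdResult:
    """A ligand dissociation constant from one protection series.

    ``consistency_ratio`` compares the protection-line intercept
    (1/k_max as fitted) against the saturation fit's prediction of
    k_max at the working [DTNB]; on clean data it is 1.
    """

    binding: CoenzymeBinding
    se_kd: float
    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    kmax_pred: float
    kmax_expected: float
    variant: str
    dtnb_conc: float

    @property
    def kd(self) -> float:
        return self.binding.kd

    @property
    def consistency_ratio(self) -> float:
        return self.kmax_pred / self.kmax_expected

    @property
    def is_non_binding(self) -> bool:
        return self.binding.is_non_binding


def fit_kd(series: ProtectionSeries, sat: SaturationFit) -> KdResult:
    """Dissociation constant of the protecting ligand from one series.

    Regresses 1/k_Co on [Co]; Kd = (1/j)(K_DTNB/[DTNB])/slope. The SE
    combines the slope's with se_j and se_K_DTNB in quadrature
    (independence assumed). A slope indistinguishable from zero or
    negative (≤ 2 SE) yields the non-binding sentinel.
    """
    if sat.variant != series.variant:
        raise UsageError(
            f"saturation fit is for {sat.variant!r} but series is for {series.variant!r}"
        )
    params = sat.params  # raises if degenerate
    co = series.co_concs
    k = np.array([r.k for r in series.rates], dtype=float)
    if np.any(k <= 0):
        raise DegenerateFitError("protection fit needs strictly positive rate constants")
    b, m, se_b, se_m, _ = _ols_line(co, 1.0 / k)
    if b <= 0:
        raise DegenerateFitError("nonpositive protection-line intercept")
    kmax_expected = k_inactivation(params, series.dtnb_conc)
    kmax_pred = 1.0 / b
    if m <= 2.0 * se_m:
        return KdResult(
            binding=CoenzymeBinding.non_binding(series.coenzyme),
            se_kd=math.nan,
            slope=m, intercept=b, se_slope=se_m, se_intercept=se_b,
            kmax_pred=kmax_pred, kmax_expected=kmax_expected,
            variant=series.variant, dtnb_conc=series.dtnb_conc,
        )
    scale = params.k_dtnb / (params.j * series.dtnb_conc)
    kd = scale / m
    rel = math.sqrt(
        (se_m / m) ** 2 + (sat.se_j / params.j) ** 2 + (sat.se_k_dtnb / params.k_dtnb) ** 2
    )
    return KdResult(
        binding=CoenzymeBinding(coenzyme=series.coenzyme, kd=kd),
        se_kd=kd * rel,
        slope=m, intercept=b, se_slope=se_m, se_intercept=se_b,
        kmax_pred=kmax_pred, kmax_expected=kmax_expected,
        variant=series.variant, dtnb_conc=series.dtnb_conc,
    )


def bootstrap_se_kd(
    series: ProtectionSeries,
    sat: SaturationFit,
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SE of Kd, as a cross-check on the delta method.

    Each replicate perturbs every stage-1 rate constant and the baseline
    (j, K_DTNB) by Gaussian draws at their reported SEs, then repeats
    the protection fit. Returns the SD of the resampled Kd values
    (non-binding replicates excluded).
    """
    rng = np.random.default_rng(seed)
    co = series.co_concs
    k = np.array([r.k for r in series.rates], dtype=float)
    se = np.array([r.se_k for r in series.rates], dtype=float)
    params = sat.params
    kds = []
    for _ in range(n_boot):
        k_star = rng.normal(k, se)
        if np.any(k_star <= 0):
            continue
        b, m, _, _, _ = _ols_line(co, 1.0 / k_star)
        if m <= 0 or b <= 0:
            continue
        j_star = rng.normal(params.j, sat.se_j)
        kdtnb_star = rng.normal(params.k_dtnb, sat.se_k_dtnb)
        if j_star <= 0 or kdtnb_star <= 0:
            continue
        kds.append(kdtnb_star / (j_star * series.dtnb_conc) / m)
    if len(kds) < 2:
        raise DegenerateFitError("bootstrap produced too few valid replicates")
    return float(np.std(kds, ddof=1))


@dataclass(frozen=True)
class Ratio:
    """A ratio of two dissociation constants with optional propagated SE."""

    value: float
    se: float | None = None
    defined: bool = True


def _ratio(num: float, den: float, se_num: float | None, se_den: float | None) -> Ratio:
    if math.isinf(num) or math.isinf(den):
        return Ratio(value=math.nan, se=None, defined=False)
    value = num / den
    if se_num is None or se_den is None:
        return Ratio(value=value)
    se = value * math.hypot(se_num / num, se_den / den)
    return Ratio(value=value, se=se)


def discrimination_ratio(
    kd_nadph: float,
    kd_nadh: float,
    se_nadph: float | None = None,
    se_nadh: float | None = None,
) -> Ratio:
    """Kd(NADPH)/Kd(NADH): binding preference between the reduced coenzymes.

    Values below 1 favour the phosphorylated coenzyme. A non-binding
    sentinel on either side makes the ratio undefined.
    """
    if not (kd_nadph > 0 and kd_nadh > 0):
        raise DomainError("dissociation constants must be positive")
    return _ratio(kd_nadph, kd_nadh, se_nadph, se_nadh)


def fold_change(
    kd_variant: float,
    kd_reference: float,
    se_variant: float | None = None,
    se_reference: float | None = None,
) -> Ratio:
    """Kd of a variant relative to the reference enzyme for one ligand."""
    if not kd_reference > 0 or math.isinf(kd_reference):
        raise DomainError("reference Kd must be positive and finite")
    if not kd_variant > 0:
        raise DomainError("variant Kd must be positive")
    return _ratio(kd_variant, kd_reference, se_variant, se_reference)


def build_comparison_table(
    results: Sequence[KdResult],
    reference: str,
    sig_figs: int | None = 2,
) -> pd.DataFrame:
    """Cross-variant summary of dissociation constants.

    One row per variant: Kd ± SE per coenzyme (mM), the NADPH/NADH
    discrimination ratio, and per-coenzyme fold changes relative to the
    ``reference`` variant. Ratios and fold changes are rounded to
    ``sig_figs`` significant figures; missing (variant, coenzyme)
    combinations appear as NaN, non-binding sentinels as inf.
    """
    seen: set[tuple[str, str]] = set()
    by_variant: dict[str, dict[str, KdResult]] = {}
    order: list[str] = []
    for r in results:
        key = (r.variant, r.binding.coenzyme)
        if key in seen:
            raise UsageError(f"duplicate result for variant/coenzyme {key}")
        seen.add(key)
        if r.variant not in by_variant:
            by_variant[r.variant] = {}
            order.append(r.variant)
        by_variant[r.variant][r.binding.coenzyme] = r
    if reference not in by_variant:
        raise UsageError(f"reference variant {reference!r} absent from results")

    def _round(x: float) -> float:
        return x if sig_figs is None else round_sig(x, sig_figs)

    coenzymes = sorted({c for d in by_variant.values() for c in d})
    rows = []
    for variant in order:
        row: dict[str, float | str] = {"variant": variant}
        res = by_variant[variant]
        for c in coenzymes:
            if c in res:
                row[f"Kd_{c}_mM"] = to_mM(res[c].kd)
                row[f"se_Kd_{c}_mM"] = (
                    to_mM(res[c].se_kd) if math.isfinite(res[c].se_kd) else math.nan
                )
            else:
                row[f"Kd_{c}_mM"] = math.nan
                row[f"se_Kd_{c}_mM"] = math.nan
        if "NADPH" in res and "NADH" in res:
            dr = discrimination_ratio(res["NADPH"].kd, res["NADH"].kd)
            row["Kd_NADPH/Kd_NADH"] = _round(dr.value) if dr.defined else math.nan
        else:
            row["Kd_NADPH/Kd_NADH"] = math.nan
        for c in coenzymes:
            ref_res = by_variant[reference].get(c)
            if c in res and ref_res is not None and not ref_res.is_non_binding:
                fc = fold_change(res[c].kd, ref_res.kd)
                row[f"fold_{c}"] = _round(fc.value) if fc.defined else math.inf
            else:
                row[f"fold_{c}"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("variant")
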