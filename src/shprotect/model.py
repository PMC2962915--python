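"""Closed-form kinetic model for active-site-directed chemical modification.

The scheme is a three-species competition: free enzyme E binds the thiol
reagent (DTNB) reversibly to give E·DTNB, which decays irreversibly by a
first-order covalent step; a protecting ligand Co competes for the same
site, giving an unreactive E·Co complex.

::

    E·Co  <--Kd-->  E  <--K_DTNB-->  E·DTNB  --j-->  inactive adduct

Because covalent chemistry is slow relative to the binding equilibria,
the observed loss of activity is pseudo-first-order with rate constant

    k     = j [DTNB] / (K_DTNB + [DTNB])                       (no ligand)
    k_Co  = j [DTNB] / (K_DTNB (1 + [Co]/Kd) + [DTNB])         (with ligand)

The second expression linearises as 1/k_Co = slope·[Co] + 1/k_max, with
slope (1/j)(K_DTNB/[DTNB])(1/Kd), which is what the downstream fitting
exploits to extract Kd from protection data.

All concentrations are molar (see :mod:`shprotect.units`); time is in
seconds and rate constants in s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "InactivationParams",
    "CoenzymeBinding",
    "SignalModel",
    "ProtectionConditions",
    "k_inactivation",
    "k_protected",
    "k_max",
    "protection_line",
    "activity_fraction",
    "a412_signal",
    "tnb_released",
]


@dataclass(frozen=True)
class InactivationParams:
    """Baseline modification parameters of one enzyme variant.

    Parameters
    ----------
    j
        First-order rate constant of the covalent step within the
        noncovalent enzyme-reagent complex (s⁻¹).
    k_dtnb
        Dissociation constant of that noncovalent complex (molar).
    """

    j: float
    k_dtnb: float

    def __post_init__(self) -> None:
        if not (self.j > 0 and math.isfinite(self.j)):
            raise DomainError(f"j must be positive and finite, got {self.j}")
        if not (self.k_dtnb > 0 and math.isfinite(self.k_dtnb)):
            raise DomainError(f"k_dtnb must be positive and finite, got {self.k_dtnb}")


@dataclass(frozen=True)
class CoenzymeBinding:
    """Dissociation constant of a binary enzyme-ligand complex.

    ``kd`` is molar; ``math.inf`` is the explicit non-binding sentinel
    (a ligand that does not occupy the site protects not at all, and
    with ``kd = inf`` the protection-line slope is *exactly* zero since
    ``[Co]/inf == 0.0`` in IEEE arithmetic).
    """

    coenzyme: str
    kd: float

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise DomainError(f"kd must be positive (or inf for non-binding), got {self.kd}")

    @classmethod
    def non_binding(cls, coenzyme: str) -> "CoenzymeBinding":
        """A ligand with no measurable affinity for the protected site."""
        return cls(coenzyme=coenzyme, kd=math.inf)

    @property
    def is_non_binding(self) -> bool:
        return math.isinf(self.kd)


@dataclass(frozen=True)
class SignalModel:
    """How a modification reaction is observed.

    ``activity`` mode samples residual catalytic activity (dimensionless
    fraction of the unmodified rate); ``absorbance`` mode follows release
    of the thionitrobenzoate (TNB) anion at 412 nm.

    Parameters
    ----------
    mode
        ``"activity"`` or ``"absorbance"``.
    extinction_coeff
        Molar absorptivity of the TNB anion at 412 nm, mM⁻¹cm⁻¹.
        Default 13.6, the standard literature value.
    path_length
        Cuvette path length in cm (default 1.0).
    sh_conc
        Concentration of modifiable thiol groups (molar). Required in
        absorbance mode, where it sets the absorbance plateau.
    """

    mode: Literal["activity", "absorbance"] = "activity"
    extinction_coeff: float = 13.6
    path_length: float = 1.0
    sh_conc: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("activity", "absorbance"):
            raise ConfigurationError(f"unknown observation mode {self.mode!r}")
        if not self.extinction_coeff > 0:
            raise DomainError("extinction_coeff must be positive")
        if not self.path_length > 0:
            raise DomainError("path_length must be positive")
        if self.mode == "absorbance":
            if self.sh_conc is None or not self.sh_conc > 0:
                raise ConfigurationError(
                    "absorbance mode requires a positive sh_conc (thiol concentration, molar)"
                )

    @property
    def plateau(self) -> float:
        """Absorbance at complete modification: ε·ℓ·[SH]₀ (AU)."""
        if self.sh_conc is None:
            raise ConfigurationError("plateau undefined without sh_conc")
        # extinction_coeff is per mM, sh_conc is molar
        return self.extinction_coeff * self.path_length * (self.sh_conc / 1e-3)


@dataclass(frozen=True)
class ProtectionConditions:
    """One incubation condition: reagent and ligand concentrations (molar)."""

    dtnb_conc: float
    co_conc: float = 0.0
    coenzyme: str | None = None
    temperature_c: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.dtnb_conc > 0:
            raise DomainError(f"dtnb_conc must be positive, got {self.dtnb_conc}")
        if self.co_conc < 0:
            raise DomainError(f"co_conc must be nonnegative, got {self.co_conc}")


def k_inactivation(params: InactivationParams, dtnb_conc: float) -> float:
    """Pseudo-first-order inactivation rate constant, no protecting ligand.

    ``k = j·[DTNB] / (K_DTNB + [DTNB])`` — hyperbolic saturation of the
    noncovalent complex; monotone nondecreasing in [DTNB], bounded by j.
    """
    if dtnb_conc < 0:
        raise DomainError(f"dtnb_conc must be nonnegative, got {dtnb_conc}")
    return params.j * dtnb_conc / (params.k_dtnb + dtnb_conc)


def k_protected(
    params: InactivationParams,
    binding: CoenzymeBinding,
    cond: ProtectionConditions,
) -> float:
    """Inactivation rate constant in the presence of a competing ligand.

    ``k_Co = j·[DTNB] / (K_DTNB·(1 + [Co]/Kd) + [DTNB])``. Reduces to
    :func:`k_inactivation` at [Co] = 0 and for the non-binding sentinel;
    strictly decreasing in [Co] for finite Kd.
    """
    occupancy = cond.co_conc / binding.kd  # exactly 0.0 for kd = inf
    return params.j * cond.dtnb_conc / (
        params.k_dtnb * (1.0 + occupancy) + cond.dtnb_conc
    )


def k_max(params: InactivationParams, dtnb_conc: float) -> float:
    """Zero-ligand rate constant at the working reagent concentration.

    Identified with :func:`k_inactivation` evaluated at ``dtnb_conc``:
    the ordinate intercept 1/k_max of the protection line is the
    zero-ligand limit of 1/k_Co.
    """
    if not dtnb_conc > 0:
        raise DomainError(f"dtnb_conc must be positive, got {dtnb_conc}")
    return k_inactivation(params, dtnb_conc)


def protection_line(
    params: InactivationParams,
    binding: CoenzymeBinding,
    dtnb_conc: float,
) -> tuple[float, float]:
    """Slope and intercept of the reciprocal protection plot.

    Returns ``(slope, intercept)`` of 1/k_Co versus [Co] (both molar
    scale: slope in s·M⁻¹, intercept in s):

        slope     = (1/j)·(K_DTNB/[DTNB])·(1/Kd)
        intercept = 1/k_max

    For any [Co], ``slope·[Co] + intercept == 1/k_protected`` to machine
    precision — this identity is what the stage-2 fit inverts.
    """
    if not dtnb_conc > 0:
        raise DomainError(f"dtnb_conc must be positive, got {dtnb_conc}")
    slope = (1.0 / params.j) * (params.k_dtnb / dtnb_conc) / binding.kd
    intercept = 1.0 / k_max(params, dtnb_conc)
    return slope, intercept


def activity_fraction(k: float, t):
    """Residual activity fraction exp(−k·t) of a pseudo-first-order decay.

    ``t`` may be a scalar or array of times (s); ``k`` in s⁻¹.
    """
    if k < 0:
        raise DomainError(f"rate constant must be nonnegative, got {k}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("times must be nonnegative")
    out = np.exp(-k * t_arr)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def a412_signal(k: float, t, sig: SignalModel):
    """Chromophore-release trace: A412(t) = ε·ℓ·[SH]₀·(1 − exp(−k·t)).

    Monotone nondecreasing in t with plateau ``sig.plateau``. Requires
    ``sig`` in absorbance mode (it carries the thiol concentration).
    """
    if sig.mode != "absorbance":
        raise ConfigurationError("a412_signal requires a SignalModel in absorbance mode")
    if k < 0:
        raise DomainError(f"rate constant must be nonnegative, got {k}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("times must be nonnegative")
    out = sig.plateau * (1.0 - np.exp(-k * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def tnb_released(
    delta_a412: float,
    sig: SignalModel,
    subunit_conc: float | None = None,
) -> float | tuple[float, float]:
    """Concentration of released TNB anion from an absorbance change.

    Beer-Lambert inversion: [TNB] = ΔA/(ε·ℓ), returned in molar. With a
    ``subunit_conc`` (molar) supplied, also returns the modification
    stoichiometry in moles of thiol per subunit.
    """
    if delta_a412 < 0:
        raise DomainError(f"delta_a412 must be nonnegative, got {delta_a412}")
    conc = delta_a412 / (sig.extinction_coeff * sig.path_length) * 1e-3  # per-mM ε → molar
    if subunit_conc is None:
        return conc
    if not subunit_conc > 0:
        raise DomainError("subunit_conc must be positive")
    return conc, conc / subunit_conc
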