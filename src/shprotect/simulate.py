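"""Seeded synthetic time-course generation.

No raw inactivation traces are deposited with the study this package
reanalyses, so every downstream stage is exercised against synthetic
data drawn from the forward model in :mod:`shprotect.model` under the
original concentration designs: a reagent-saturation series (DTNB 50-600
µM, no ligand) per variant, and protection series at fixed 200 µM DTNB
with graded coenzyme concentrations.

Noiseless generation is the forward model evaluated exactly; noisy
generation adds a configurable measurement-error draw. Every course
carries its generating rate constant in ``truth`` so recovery can be
asserted without re-deriving it.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .catalog import VariantRecord
from .errors import ConfigurationError, DomainError, UsageError
from .model import (
    CoenzymeBinding,
    InactivationParams,
    ProtectionConditions,
    SignalModel,
    a412_signal,
    activity_fraction,
    k_inactivation,
    k_protected,
)
from .units import uM

__all__ = [
    "ExperimentDesign",
    "NoiseSpec",
    "TimeCourse",
    "StudyBundle",
    "generate_timecourse",
    "generate_dtnb_series",
    "generate_protection_series",
    "generate_study",
]

#: fallback incubation length (s) when the truth rate constant is zero
_FALLBACK_DURATION = 7200.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Concentration grids and sampling schedule for one study.

    Defaults reproduce the original wet-lab designs: six DTNB levels
    from 50 to 600 µM for the baseline saturation fits, protection runs
    at a fixed 200 µM DTNB, and 12 activity samples spread over three
    half-lives of each course (log-linear fits stay well conditioned
    over that span). Coenzyme grids may be given explicitly per
    coenzyme; otherwise they are laid out as multiples of the true Kd,
    zero level always included.
    """

    variant: str | None = None
    dtnb_grid: tuple[float, ...] = tuple(c * uM for c in (50, 100, 200, 300, 400, 600))
    coenzyme_grids: Mapping[str, Sequence[float]] | None = None
    co_grid_multipliers: tuple[float, ...] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0)
    fixed_dtnb: float = 200 * uM
    time_points: tuple[float, ...] | None = None
    n_points: int = 12
    n_half_lives: float = 3.0
    trace_interval: float = 5.0
    trace_duration: float | None = None
    replicates: int = 1

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.dtnb_grid):
            raise DomainError("dtnb_grid concentrations must be nonnegative")
        if not self.fixed_dtnb > 0:
            raise DomainError("fixed_dtnb must be positive")
        if self.time_points is not None:
            tp = np.asarray(self.time_points, dtype=float)
            if tp.size and np.any(np.diff(tp) <= 0):
                raise ConfigurationError("time_points must be strictly increasing")
        if self.n_points < 3:
            raise ConfigurationError("n_points must be at least 3")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be at least 1")
        if not self.trace_interval > 0:
            raise DomainError("trace_interval must be positive")

    def sampling_times(self, k_truth: float, mode: str) -> np.ndarray:
        """Sampling schedule for a course whose true rate constant is ``k_truth``."""
        if mode == "activity":
            if self.time_points is not None:
                return np.asarray(self.time_points, dtype=float)
            span = (
                self.n_half_lives * np.log(2.0) / k_truth
                if k_truth > 0
                else _FALLBACK_DURATION
            )
            return np.linspace(0.0, span, self.n_points)
        duration = self.trace_duration
        if duration is None:
            duration = (
                self.n_half_lives * np.log(2.0) / k_truth
                if k_truth > 0
                else _FALLBACK_DURATION
            )
        return np.arange(0.0, duration + 0.5 * self.trace_interval, self.trace_interval)

    def co_grid(self, binding: CoenzymeBinding) -> tuple[float, ...]:
        """Coenzyme concentrations for a protection series (zero included)."""
        if self.coenzyme_grids is not None and binding.coenzyme in self.coenzyme_grids:
            grid = tuple(float(c) for c in self.coenzyme_grids[binding.coenzyme])
        elif binding.is_non_binding:
            # no natural scale; probe a fixed millimolar ladder
            grid = tuple(m * 1e-3 for m in self.co_grid_multipliers)
        else:
            grid = tuple(m * binding.kd for m in self.co_grid_multipliers)
        if any(c < 0 for c in grid):
            raise DomainError("coenzyme concentrations must be nonnegative")
        if 0.0 not in grid:
            grid = (0.0,) + grid
        return grid


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-error model for synthetic observations.

    ``multiplicative_gaussian`` scales each value by (1 + N(0, sigma)) —
    appropriate for enzymatic activity assays, whose error grows with
    signal; ``additive_gaussian`` adds N(0, sigma) in signal units —
    appropriate for photometric traces. Defaults elsewhere in the
    package use sigma = 0.02 (2%) for activity and 0.002 AU for
    absorbance.
    """

    model: Literal["none", "additive_gaussian", "multiplicative_gaussian"] = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "additive_gaussian", "multiplicative_gaussian"):
            raise ConfigurationError(f"unknown noise model {self.model!r}")
        if self.sigma < 0:
            raise DomainError("sigma must be nonnegative")
        if self.model == "none" and self.sigma != 0:
            raise ConfigurationError("noise model 'none' forces sigma = 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Return a noisy copy of ``values`` using this spec's own seed."""
        if self.model == "none":
            return values.copy()
        rng = np.random.default_rng(self.seed)
        draw = rng.normal(0.0, self.sigma, size=values.shape)
        if self.model == "additive_gaussian":
            return values + draw
        return values * (1.0 + draw)

    def child(self, label: str, master_seed: int | None = None) -> "NoiseSpec":
        """Derive a per-series spec whose seed depends only on ``label``.

        Stable hashing (CRC-32 of the label, mixed with the master seed
        through a SeedSequence) means inserting one series into a study
        never perturbs another's draws.
        """
        master = self.seed if master_seed is None else master_seed
        crc = zlib.crc32(label.encode("utf-8"))
        child_seed = int(np.random.SeedSequence([master, crc]).generate_state(1)[0])
        return replace(self, seed=child_seed)


@dataclass(frozen=True)
class TimeCourse:
    """One monitored modification reaction.

    ``values`` are residual-activity fractions (activity mode) or A412
    absorbances (absorbance mode). ``truth`` holds the generating rate
    constant for synthetic courses and is ``None`` for imported data.
    """

    times: np.ndarray
    values: np.ndarray
    mode: Literal["activity", "absorbance"]
    conditions: ProtectionConditions
    variant: str
    truth: float | None = None
    replicate: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise UsageError("times and values must have identical shape")
        if times.size and np.any(np.diff(times) <= 0):
            raise DomainError("times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def generate_timecourse(
    params: InactivationParams,
    binding: CoenzymeBinding | None,
    cond: ProtectionConditions,
    design: ExperimentDesign,
    sig: SignalModel,
    noise: NoiseSpec,
    variant: str = "enzyme",
    replicate: int = 0,
) -> TimeCourse:
    """Simulate one incubation under the given conditions.

    Noiseless values coincide exactly with the forward model; the
    generating rate constant is recorded in ``truth``.
    """
    if binding is None:
        k = k_inactivation(params, cond.dtnb_conc)
    else:
        k = k_protected(params, binding, cond)
    times = design.sampling_times(k, sig.mode)
    if sig.mode == "activity":
        clean = activity_fraction(k, times)
    else:
        clean = a412_signal(k, times, sig)
    values = noise.apply(np.asarray(clean, dtype=float))
    return TimeCourse(
        times=times,
        values=values,
        mode=sig.mode,
        conditions=cond,
        variant=variant,
        truth=k,
        replicate=replicate,
        seed=noise.seed if noise.model != "none" else None,
    )


def _series_label(variant: str, mode: str, dtnb: float, coenzyme: str | None,
                  co: float, replicate: int) -> str:
    return f"{variant}|{mode}|{dtnb:.9e}|{coenzyme or '-'}|{co:.9e}|{replicate}"


def generate_dtnb_series(
    params: InactivationParams,
    design: ExperimentDesign,
    sig: SignalModel,
    noise: NoiseSpec,
    variant: str = "enzyme",
) -> list[TimeCourse]:
    """One course per DTNB level of the saturation design, ligand-free."""
    if not design.dtnb_grid:
        raise ConfigurationError("dtnb_grid is empty")
    courses = []
    for dtnb in design.dtnb_grid:
        cond = ProtectionConditions(dtnb_conc=dtnb)
        for rep in range(design.replicates):
            child = noise.child(_series_label(variant, sig.mode, dtnb, None, 0.0, rep))
            courses.append(
                generate_timecourse(params, None, cond, design, sig, child,
                                    variant=variant, replicate=rep)
            )
    return courses


def generate_protection_series(
    params: InactivationParams,
    binding: CoenzymeBinding,
    design: ExperimentDesign,
    sig: SignalModel,
    noise: NoiseSpec,
    variant: str = "enzyme",
) -> list[TimeCourse]:
    """One course per coenzyme level (zero always included) at fixed DTNB.

    The zero-ligand course pins the fitted intercept of the protection
    line so it can be checked against the saturation fit's k_max.
    """
    grid = design.co_grid(binding)
    if not grid:
        raise ConfigurationError("coenzyme grid is empty")
    courses = []
    for co in grid:
        cond = ProtectionConditions(
            dtnb_conc=design.fixed_dtnb, co_conc=co, coenzyme=binding.coenzyme
        )
        for rep in range(design.replicates):
            child = noise.child(
                _series_label(variant, sig.mode, design.fixed_dtnb, binding.coenzyme, co, rep)
            )
            courses.append(
                generate_timecourse(params, binding, cond, design, sig, child,
                                    variant=variant, replicate=rep)
            )
    return courses


@dataclass(frozen=True)
class StudyBundle:
    """All synthetic series of one simulated study."""

    timecourses: tuple[TimeCourse, ...]
    master_seed: int

    def to_frame(self):
        """Tidy long-format table (one row per observation)."""
        from .io import timecourses_to_frame

        return timecourses_to_frame(self.timecourses)

    def __len__(self) -> int:
        return len(self.timecourses)


CatalogLike = Mapping[str, VariantRecord] | Mapping[
    str, tuple[InactivationParams, Mapping[str, CoenzymeBinding]]
]


def _normalise_catalog(
    catalog: CatalogLike,
) -> list[tuple[str, InactivationParams, dict[str, CoenzymeBinding]]]:
    rows = []
    seen: set[str] = set()
    for name, entry in catalog.items():
        if name in seen:
            raise ConfigurationError(f"duplicate variant name {name!r}")
        seen.add(name)
        if isinstance(entry, VariantRecord):
            rows.append((name, entry.params, dict(entry.bindings)))
        else:
            params, bindings = entry
            rows.append((name, params, dict(bindings)))
    return rows


def generate_study(
    catalog: CatalogLike,
    design: ExperimentDesign,
    noise: NoiseSpec,
    sig: SignalModel | None = None,
) -> StudyBundle:
    """Simulate the full study: a saturation series plus one protection
    series per (variant, coenzyme) pair in the catalog.

    Deterministic under the master seed carried by ``noise``; per-series
    seeds are derived by stable hashing of the series identity.
    """
    rows = _normalise_catalog(catalog)
    if not rows:
        raise ConfigurationError("catalog is empty")
    sig = sig or SignalModel(mode="activity")
    courses: list[TimeCourse] = []
    for name, params, bindings in rows:
        courses.extend(generate_dtnb_series(params, design, sig, noise, variant=name))
        for binding in bindings.values():
            courses.extend(
                generate_protection_series(params, binding, design, sig, noise, variant=name)
            )
    return StudyBundle(timecourses=tuple(courses), master_seed=noise.seed)
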