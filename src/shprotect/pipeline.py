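"""End-to-end orchestration: simulate → fit rates → fit binding → report.

Each stage reads and writes plain delimited text, so any stage can be
re-run from the persisted outputs of the one before it and produces the
same result as an uninterrupted run. A machine-readable manifest
(resolved configuration, its hash, the seed, package version) is written
beside the results; it contains everything needed to regenerate them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .binding import (
    KdResult,
    ProtectionSeries,
    SaturationFit,
    build_comparison_table,
    fit_kd,
    fit_saturation,
)
from .catalog import WILD_TYPE, reference_catalog
from .errors import PipelineError
from .io import (
    TIMECOURSE_COLUMNS,
    frame_to_rates,
    frame_to_timecourses,
    kd_results_to_frame,
    rates_to_frame,
    read_timecourses,
    saturation_to_frame,
    timecourses_to_frame,
    write_timecourses,
)
from .model import CoenzymeBinding, InactivationParams, SignalModel
from .ratefit import RateEstimate, fit_rate
from .simulate import ExperimentDesign, NoiseSpec, TimeCourse, generate_study
from .units import mM, uM

__all__ = ["RunConfig", "RunReport", "ValidationReport", "run_pipeline", "validate_inputs",
           "load_catalog"]

log = logging.getLogger("shprotect")


class RunConfig(BaseModel):
    """Configuration of one pipeline run (concentrations in interface units)."""

    mode: Literal["simulate", "analyze", "full"] = "full"
    input_path: str | None = None
    out_dir: str = "shprotect_out"
    catalog: str = "builtin"
    reference_variant: str = WILD_TYPE
    seed: int = 0
    observation: Literal["activity", "absorbance"] = "activity"
    sh_uM: float = 2.0
    dtnb_grid_uM: list[float] = Field(default=[50, 100, 200, 300, 400, 600])
    fixed_dtnb_uM: float = 200.0
    co_grid_multipliers: list[float] = Field(default=[0.0, 0.25, 0.5, 1.0, 2.0, 4.0])
    n_points: int = 12
    n_half_lives: float = 3.0
    replicates: int = 1
    noise_model: Literal["none", "additive_gaussian", "multiplicative_gaussian"] = "none"
    noise_sigma: float = 0.0
    sig_figs: int = 2
    format: Literal["csv", "json"] = "csv"

    @field_validator("dtnb_grid_uM")
    @classmethod
    def _nonempty_grid(cls, v: list[float]) -> list[float]:
        if not v:
            raise ValueError("dtnb_grid_uM must be nonempty")
        return v

    def design(self) -> ExperimentDesign:
        return ExperimentDesign(
            dtnb_grid=tuple(c * uM for c in self.dtnb_grid_uM),
            co_grid_multipliers=tuple(self.co_grid_multipliers),
            fixed_dtnb=self.fixed_dtnb_uM * uM,
            n_points=self.n_points,
            n_half_lives=self.n_half_lives,
            replicates=self.replicates,
        )

    def noise(self) -> NoiseSpec:
        return NoiseSpec(model=self.noise_model, sigma=self.noise_sigma, seed=self.seed)

    def signal(self) -> SignalModel:
        if self.observation == "absorbance":
            return SignalModel(mode="absorbance", sh_conc=self.sh_uM * uM)
        return SignalModel(mode="activity")


def load_catalog(source: str):
    """Resolve a catalog reference: ``"builtin"`` or a YAML/JSON file.

    File layout: ``{variant: {j_s: float, K_DTNB_uM: float,
    kd_mM: {coenzyme: float}}}``.
    """
    if source == "builtin":
        return reference_catalog()
    path = Path(source)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    catalog = {}
    for name, entry in raw.items():
        params = InactivationParams(j=float(entry["j_s"]),
                                    k_dtnb=float(entry["K_DTNB_uM"]) * uM)
        bindings = {
            c: CoenzymeBinding(coenzyme=c, kd=float(v) * mM)
            for c, v in entry.get("kd_mM", {}).items()
        }
        catalog[name] = (params, bindings)
    return catalog


@dataclass(frozen=True)
class RunReport:
    """Paths and in-memory tables produced by one pipeline run."""

    out_dir: Path
    files: dict[str, Path]
    rates: pd.DataFrame | None = None
    saturation: pd.DataFrame | None = None
    kd: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None


def _fit_all_rates(courses: list[TimeCourse], sig: SignalModel) -> list[RateEstimate]:
    rates = []
    for tc in courses:
        est = fit_rate(tc, sig if tc.mode == "absorbance" else None)
        if est.flags:
            log.warning("course %s dtnb=%.3g co=%.3g: flags %s",
                        tc.variant, tc.conditions.dtnb_conc, tc.conditions.co_conc,
                        est.flags)
        if est.n_dropped:
            log.warning("course %s: dropped %d nonpositive points",
                        tc.variant, est.n_dropped)
        rates.append(est)
    return rates


def _fit_binding(rates: list[RateEstimate]):
    """Group a flat rates table into saturation and protection fits."""
    sat_fits: dict[str, SaturationFit] = {}
    variants = sorted({r.variant for r in rates})
    for variant in variants:
        baseline = [r for r in rates
                    if r.variant == variant and r.conditions.coenzyme is None]
        if len({r.conditions.dtnb_conc for r in baseline}) >= 3:
            sat_fits[variant] = fit_saturation(baseline)

    kd_results: list[KdResult] = []
    for variant in variants:
        labelled = [r for r in rates
                    if r.variant == variant and r.conditions.coenzyme is not None]
        for coenzyme in sorted({r.conditions.coenzyme for r in labelled}):
            series_rates = [r for r in labelled if r.conditions.coenzyme == coenzyme]
            if variant not in sat_fits:
                raise PipelineError(
                    f"protection series {variant}/{coenzyme} has no matching "
                    f"saturation fit; run the DTNB series for {variant!r} first"
                )
            series = ProtectionSeries.from_rates(series_rates)
            result = fit_kd(series, sat_fits[variant])
            if result.is_non_binding:
                log.warning("series %s/%s: no significant protection (non-binding)",
                            variant, coenzyme)
            kd_results.append(result)
    return list(sat_fits.values()), kd_results


def _write_table(df: pd.DataFrame, path: Path, fmt: str, index: bool = False) -> Path:
    if fmt == "json":
        path = path.with_suffix(".json")
        out = df.reset_index() if index else df
        out.to_json(path, orient="records", indent=2)
    else:
        df.to_csv(path, index=index)
    return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages and persist all outputs.

    ``simulate`` writes synthetic observations only; ``analyze`` starts
    from an existing observation table; ``full`` does both. Idempotent
    for a fixed config and seed (outputs are byte-identical).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    sig = config.signal()

    if config.mode in ("simulate", "full"):
        catalog = load_catalog(config.catalog)
        bundle = generate_study(catalog, config.design(), config.noise(), sig=sig)
        courses = list(bundle.timecourses)
        files["timecourses"] = write_timecourses(courses, out_dir / "timecourses.csv")
        log.info("simulated %d time courses", len(courses))
    else:
        if not config.input_path:
            raise PipelineError("analyze mode requires input_path")
        courses = read_timecourses(config.input_path)

    if config.mode == "simulate":
        _write_manifest(config, files, out_dir)
        return RunReport(out_dir=out_dir, files=files)

    if not courses:
        raise PipelineError("no time courses to analyse")
    rates = _fit_all_rates(courses, sig)
    rates_df = rates_to_frame(rates)
    files["rates"] = _write_table(rates_df, out_dir / "rates.csv", config.format)

    sat_fits, kd_results = _fit_binding(rates)
    if not sat_fits:
        raise PipelineError("no variant had enough DTNB levels for a saturation fit")
    sat_df = saturation_to_frame(sat_fits)
    kd_df = kd_results_to_frame(kd_results)
    files["saturation"] = _write_table(sat_df, out_dir / "saturation.csv", config.format)
    files["kd"] = _write_table(kd_df, out_dir / "kd_results.csv", config.format)

    comparison = None
    if kd_results and any(r.variant == config.reference_variant for r in kd_results):
        comparison = build_comparison_table(
            kd_results, reference=config.reference_variant, sig_figs=config.sig_figs
        )
        files["comparison"] = _write_table(
            comparison, out_dir / "comparison.csv", config.format, index=True
        )

    _write_manifest(config, files, out_dir)
    return RunReport(out_dir=out_dir, files=files, rates=rates_df,
                     saturation=sat_df, kd=kd_df, comparison=comparison)


def _write_manifest(config: RunConfig, files: dict[str, Path], out_dir: Path) -> None:
    resolved = config.model_dump(mode="json")
    canonical = json.dumps(resolved, sort_keys=True).encode()
    manifest = {
        "config": resolved,
        "config_sha256": hashlib.sha256(canonical).hexdigest(),
        "seed": config.seed,
        "package": {"name": "shprotect", "version": __version__},
        "outputs": {k: p.name for k, p in sorted(files.items())},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    files["manifest"] = path


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of schema/consistency checks on an observation table."""

    path: Path
    errors: tuple[str, ...]
    warnings: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(path: str | Path) -> ValidationReport:
    """Check an observation CSV before analysis.

    Errors: missing required columns, non-monotone times within a
    series, duplicated observations, negative concentrations or times.
    Warnings: activity values outside [0, 1.2], unknown modes.
    """
    path = Path(path)
    errors: list[str] = []
    warnings: list[str] = []
    try:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() in (".tsv", ".tab") else ",")
    except OSError as exc:
        raise PipelineError(f"cannot read {path}: {exc}") from exc

    required = [c for c in TIMECOURSE_COLUMNS if c != "seed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"missing required columns: {missing}")
        return ValidationReport(path=path, errors=tuple(errors), warnings=tuple(warnings))

    if (df["time_s"] < 0).any():
        errors.append("negative times present")
    for col in ("dtnb_uM", "co_mM"):
        if (df[col] < 0).any():
            errors.append(f"negative concentrations in {col}")
    bad_modes = set(df["mode"].unique()) - {"activity", "absorbance"}
    if bad_modes:
        warnings.append(f"unknown observation modes: {sorted(bad_modes)}")

    keys = ["variant", "mode", "dtnb_uM", "coenzyme", "co_mM", "replicate"]
    for key, grp in df.groupby(keys, dropna=False):
        t = grp["time_s"].to_numpy()
        if len(t) != len(set(t)):
            errors.append(f"duplicate time points in series {key}")
        elif not (t[:-1] < t[1:]).all():
            errors.append(f"non-monotone times in series {key}")
    act = df[df["mode"] == "activity"]["value"]
    if len(act) and ((act < 0) | (act > 1.2)).any():
        warnings.append("activity values outside [0, 1.2] present")
    return ValidationReport(path=path, errors=tuple(errors), warnings=tuple(warnings))
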