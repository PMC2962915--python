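"""Tidy delimited-text interfaces.

All data crossing the package boundary is plain CSV/TSV in long format.
Concentrations appear in the field's customary units in files — DTNB in
µM (``dtnb_uM``), coenzymes in mM (``co_mM``) — and are converted to
molar on read. One row per observation:

    time_s, value, mode, variant, dtnb_uM, coenzyme, co_mM, replicate, seed

Rate and binding results are emitted as flat tables mirroring the
classic per-variant summary layouts (j/K_DTNB per variant; Kd per
variant and coenzyme).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .binding import KdResult, SaturationFit
from .errors import UsageError
from .model import ProtectionConditions
from .ratefit import RateEstimate
from .simulate import TimeCourse
from .units import mM, to_mM, to_uM, uM

__all__ = [
    "TIMECOURSE_COLUMNS",
    "timecourses_to_frame",
    "frame_to_timecourses",
    "write_timecourses",
    "read_timecourses",
    "rates_to_frame",
    "frame_to_rates",
    "saturation_to_frame",
    "kd_results_to_frame",
]

TIMECOURSE_COLUMNS = (
    "time_s", "value", "mode", "variant", "dtnb_uM", "coenzyme", "co_mM",
    "replicate", "seed",
)


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def timecourses_to_frame(courses: Iterable[TimeCourse]) -> pd.DataFrame:
    """Long-format observation table for a collection of courses."""
    chunks = []
    for tc in courses:
        chunks.append(pd.DataFrame({
            "time_s": tc.times,
            "value": tc.values,
            "mode": tc.mode,
            "variant": tc.variant,
            "dtnb_uM": to_uM(tc.conditions.dtnb_conc),
            "coenzyme": tc.conditions.coenzyme or "",
            "co_mM": to_mM(tc.conditions.co_conc),
            "replicate": tc.replicate,
            "seed": "" if tc.seed is None else tc.seed,
        }))
    if not chunks:
        return pd.DataFrame(columns=list(TIMECOURSE_COLUMNS))
    return pd.concat(chunks, ignore_index=True)


def frame_to_timecourses(df: pd.DataFrame) -> list[TimeCourse]:
    """Group a long-format table back into TimeCourse objects.

    ``truth`` is not serialised (it exists only for synthetic data), so
    round-tripped courses come back with ``truth=None``.
    """
    missing = [c for c in TIMECOURSE_COLUMNS[:8] if c not in df.columns]
    if missing:
        raise UsageError(f"observation table lacks required columns: {missing}")
    courses = []
    keys = ["variant", "mode", "dtnb_uM", "coenzyme", "co_mM", "replicate"]
    for (variant, mode, dtnb, coz, co, rep), grp in df.groupby(keys, sort=True, dropna=False):
        grp = grp.sort_values("time_s")
        coz = None if (pd.isna(coz) or coz == "") else str(coz)
        seed_col = grp["seed"].iloc[0] if "seed" in grp.columns else ""
        seed = None if (pd.isna(seed_col) or seed_col == "") else int(seed_col)
        courses.append(TimeCourse(
            times=grp["time_s"].to_numpy(dtype=float),
            values=grp["value"].to_numpy(dtype=float),
            mode=str(mode),
            conditions=ProtectionConditions(
                dtnb_conc=float(dtnb) * uM,
                co_conc=float(co) * mM,
                coenzyme=coz,
            ),
            variant=str(variant),
            replicate=int(rep),
            seed=seed,
        ))
    return courses


def write_timecourses(courses: Iterable[TimeCourse], path: str | Path) -> Path:
    path = Path(path)
    timecourses_to_frame(courses).to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_timecourses(path: str | Path) -> list[TimeCourse]:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return frame_to_timecourses(df)


def rates_to_frame(rates: Sequence[RateEstimate]) -> pd.DataFrame:
    """Rates table: one row per fitted course."""
    return pd.DataFrame([
        {
            "variant": r.variant,
            "mode": r.mode,
            "dtnb_uM": to_uM(r.conditions.dtnb_conc),
            "coenzyme": r.conditions.coenzyme or "",
            "co_mM": to_mM(r.conditions.co_conc),
            "replicate": r.replicate,
            "k_s": r.k,
            "se_k": r.se_k,
            "r2": r.r_squared,
            "n": r.n_points,
            "n_dropped": r.n_dropped,
            "flags": ";".join(r.flags),
        }
        for r in rates
    ])


def frame_to_rates(df: pd.DataFrame) -> list[RateEstimate]:
    required = ["variant", "mode", "dtnb_uM", "coenzyme", "co_mM", "k_s", "se_k", "r2", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise UsageError(f"rates table lacks required columns: {missing}")
    out = []
    for _, row in df.iterrows():
        coz = row["coenzyme"]
        coz = None if (pd.isna(coz) or coz == "") else str(coz)
        flags = row.get("flags", "")
        flags = () if (pd.isna(flags) or flags == "") else tuple(str(flags).split(";"))
        out.append(RateEstimate(
            k=float(row["k_s"]),
            se_k=float(row["se_k"]),
            r_squared=float(row["r2"]),
            n_points=int(row["n"]),
            mode=str(row["mode"]),
            conditions=ProtectionConditions(
                dtnb_conc=float(row["dtnb_uM"]) * uM,
                co_conc=float(row["co_mM"]) * mM,
                coenzyme=coz,
            ),
            variant=str(row["variant"]),
            replicate=int(row.get("replicate", 0)),
            n_dropped=int(row.get("n_dropped", 0)),
            flags=flags,
        ))
    return out


def saturation_to_frame(fits: Sequence[SaturationFit]) -> pd.DataFrame:
    """Per-variant baseline parameters, in customary units (j s⁻¹, K_DTNB µM)."""
    return pd.DataFrame([
        {
            "variant": f.variant,
            "j_s": f.j,
            "se_j": f.se_j,
            "K_DTNB_uM": to_uM(f.k_dtnb),
            "se_K_DTNB_uM": to_uM(f.se_k_dtnb),
            "method": f.method,
            "degenerate": f.degenerate,
        }
        for f in fits
    ])


def kd_results_to_frame(results: Sequence[KdResult]) -> pd.DataFrame:
    """Per (variant, coenzyme) dissociation constants in mM."""
    return pd.DataFrame([
        {
            "variant": r.variant,
            "coenzyme": r.binding.coenzyme,
            "dtnb_uM": to_uM(r.dtnb_conc),
            "Kd_mM": to_mM(r.kd) if not r.is_non_binding else math.inf,
            "se_Kd_mM": to_mM(r.se_kd) if math.isfinite(r.se_kd) else math.nan,
            "kmax_pred_s": r.kmax_pred,
            "kmax_expected_s": r.kmax_expected,
            "consistency_ratio": r.consistency_ratio,
            "non_binding": r.is_non_binding,
        }
        for r in results
    ])
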