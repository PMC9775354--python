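"""Chamber microclimate derivations: vapour pressure, VPD, day/night splits.

Saturation vapour pressure uses the Tetens form over water by default
(Magnus constants selectable); actual vapour pressure is VP = RH/100 · es(T)
and the deficit VPD = es − VP. Night is the half-open clock window
[21:00, 08:00) in local (naive) time — appropriate for polar-summer loggers.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidInputError

TETENS = (0.61078, 17.27, 237.3)
MAGNUS = (0.61094, 17.625, 243.04)

LOGGER_COLUMNS = ["timestamp_iso8601", "location", "t_air_C", "t_soil_C", "rh_pct"]

DEFAULT_NIGHT_WINDOW = (time(21, 0), time(8, 0))


def saturation_vapour_pressure(t, constants=TETENS):
    """es(T) in kPa, strictly increasing on the supported range [−60, 60] °C."""
    a, b, c = constants
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -60) or np.any(t_arr > 60):
        raise InvalidInputError("temperature outside the supported range [-60, 60] °C")
    out = a * np.exp(b * t_arr / (t_arr + c))
    return float(out) if out.ndim == 0 else out


def vapour_pressure(t, rh, constants=TETENS):
    """Actual vapour pressure VP = RH/100 · es(T), kPa."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise InvalidInputError("relative humidity must lie in [0, 100] %")
    out = rh_arr / 100.0 * saturation_vapour_pressure(t, constants)
    return float(out) if out.ndim == 0 else out


def vpd(t, rh, constants=TETENS):
    """Vapour pressure deficit es(T) − VP, kPa (non-negative)."""
    es = saturation_vapour_pressure(t, constants)
    out = es - np.asarray(rh, dtype=float) / 100.0 * es
    if np.any(np.asarray(rh, dtype=float) < 0) or np.any(np.asarray(rh, dtype=float) > 100):
        raise InvalidInputError("relative humidity must lie in [0, 100] %")
    return float(out) if np.ndim(out) == 0 else out


def is_night(timestamps, night_window=DEFAULT_NIGHT_WINDOW):
    """Boolean mask: clock time in the half-open window [start, end)."""
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    start, end = night_window
    tod = ts.time
    if start > end:  # window wraps midnight
        mask = (tod >= start) | (tod < end)
    else:
        mask = (tod >= start) & (tod < end)
    return np.asarray(mask)


def derive(df: pd.DataFrame, night_window=DEFAULT_NIGHT_WINDOW, constants=TETENS
           ) -> pd.DataFrame:
    """Append es, vp, vpd and is_night columns to a logger table."""
    out = df.copy()
    out["es_kPa"] = saturation_vapour_pressure(df["t_air_C"].to_numpy(), constants)
    out["vp_kPa"] = vapour_pressure(df["t_air_C"].to_numpy(), df["rh_pct"].to_numpy(), constants)
    out["vpd_kPa"] = out["es_kPa"] - out["vp_kPa"]
    out["is_night"] = is_night(df["timestamp_iso8601"], night_window)
    return out


def percent_elevation(mean_inside: float, mean_outside: float) -> float:
    """100·(inside − outside)/outside."""
    if mean_outside == 0:
        raise InvalidInputError("outside mean is zero: elevation undefined")
    return 100.0 * (mean_inside - mean_outside) / mean_outside


def _mean_se(x: np.ndarray):
    n = len(x)
    mean = float(np.mean(x)) if n else float("nan")
    se = float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se, n


def chamber_differential(inside: pd.DataFrame, outside: pd.DataFrame,
                         night_window=DEFAULT_NIGHT_WINDOW, constants=TETENS) -> dict:
    """Paired inside-vs-outside summary of a chamber logger pair.

    The two series are inner-joined on timestamp (no resampling); ΔT = in − out
    is partitioned into the night window and day, and the humidity metrics are
    summarised as percent elevation of mean VP and VPD inside over outside.
    """
    left = derive(inside, night_window, constants)
    right = derive(outside, night_window, constants)
    merged = pd.merge(left, right, on="timestamp_iso8601", suffixes=("_in", "_out"))
    if merged.empty:
        raise AlignmentError("inside and outside series share no timestamps")
    dt = (merged["t_air_C_in"] - merged["t_air_C_out"]).to_numpy()
    night = merged["is_night_in"].to_numpy()
    night_mean, night_se, n_night = _mean_se(dt[night])
    day_mean, day_se, n_day = _mean_se(dt[~night])
    return {
        "night_mean_dt_C": night_mean,
        "night_se_dt_C": night_se,
        "n_night": n_night,
        "day_mean_dt_C": day_mean,
        "day_se_dt_C": day_se,
        "n_day": n_day,
        "max_dt_C": float(dt.max()),
        "vp_elevation_pct": percent_elevation(
            float(merged["vp_kPa_in"].mean()), float(merged["vp_kPa_out"].mean())),
        "vpd_elevation_pct": percent_elevation(
            float(merged["vpd_kPa_in"].mean()), float(merged["vpd_kPa_out"].mean())),
    }


def read_logger(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in LOGGER_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"logger CSV is missing columns: {missing}")
    return df[LOGGER_COLUMNS]


def split_locations(df: pd.DataFrame):
    """Split a long logger table into (inside, outside) frames."""
    return (df[df["location"] == "inside"].reset_index(drop=True),
            df[df["location"] == "outside"].reset_index(drop=True))


def parse_night_window(text: str):
    """Parse "21:00-08:00" into a (time, time) pair."""
    try:
        a, b = text.split("-")
        h1, m1 = (int(x) for x in a.split(":"))
        h2, m2 = (int(x) for x in b.split(":"))
        return time(h1, m1), time(h2, m2)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse night window {text!r}") from exc
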