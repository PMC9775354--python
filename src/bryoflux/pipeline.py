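"""Orchestration: simulate → fit → acclimation → stats → report.

``run_pipeline`` is a pure function of its configuration: the report embeds a
hash of the canonical config serialization, carries no timestamps, and two
runs with identical configs produce byte-identical report files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acclimation as acc
from . import core, light, microclimate, stats, synthetic, temperature
from .errors import PipelineError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 42
    lsp_fraction: float = 0.9
    delta: float = 5.0
    t_ref: float = 10.0
    night_window: str = "21:00-08:00"
    model_selection: str = "aic"
    classification_tol: float = 0.1
    out_dir: str | None = None
    # optional pre-existing inputs; when None the scenario is simulated
    light_csv: str | None = None
    temperature_csv: str | None = None
    logger_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _group_summary(values) -> dict:
    x = np.asarray(values, dtype=float)
    return {
        "mean": float(x.mean()),
        "se": float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
        "n": int(len(x)),
    }


def _ttest_between(light_fits: pd.DataFrame, column: str) -> dict:
    a = light_fits.loc[light_fits["group"] == "control", column]
    b = light_fits.loc[light_fits["group"] == "treatment", column]
    res = stats.ttest_from_summary(
        stats.SummaryStats(**_group_summary(a)),
        stats.SummaryStats(**_group_summary(b)),
    )
    return {"t": res.t, "df": res.df, "p": res.p}


def _fit_light_stage(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rows = []
    for (sample, group), _ in df.groupby(["sample_id", "group"]):
        try:
            pts = core.light_curve_points(df, sample)
            fit = light.fit_light_response(pts)
            cp = light.cardinal_points(fit, config.lsp_fraction)
        except Exception as exc:
            raise PipelineError("light_response", str(exc), sample_id=sample) from exc
        rows.append({
            "sample_id": sample, "group": group,
            "phi": fit.phi, "pg_max": fit.pg_max, "theta": fit.theta,
            "rd": fit.rd, "r2": fit.r2, "np_max_net": fit.np_max_net,
            "lcp": cp.lcp, "lsp": cp.lsp,
            "observed_max_exceeds_asymptote": fit.observed_max_exceeds_asymptote,
        })
    return pd.DataFrame(rows).sort_values(["group", "sample_id"]).reset_index(drop=True)


def _fit_temperature_stage(table: pd.DataFrame, config: RunConfig):
    fits = {}
    for group, sub in table.groupby("group"):
        try:
            np_fit = temperature.fit_np_temperature(
                sub[["temperature_C", "np"]].to_numpy(), config.model_selection)
            dr_fit = temperature.fit_dr_exponential(
                sub[["temperature_C", "dr"]].to_numpy(), config.t_ref)
        except Exception as exc:
            raise PipelineError("temperature_response", str(exc), sample_id=group) from exc
        fits[group] = {"np": np_fit, "dr": dr_fit}
    return fits


def _cue_stage(table: pd.DataFrame):
    rows = []
    crossings = {}
    for group, sub in table.groupby("group"):
        means = sub.groupby("temperature_C")[["np", "dr"]].mean().reset_index()
        entries = []
        for _, r in means.iterrows():
            cue = acc.carbon_use_efficiency(r["np"], r["dr"])
            entries.append((float(r["temperature_C"]), cue))
            rows.append({"group": group, "temperature_C": float(r["temperature_C"]),
                         "np": float(r["np"]), "dr": float(r["dr"]), "cue_pct": cue})
        crossings[group] = acc.cue_crossing(entries)
    return pd.DataFrame(rows), crossings


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return (and optionally write) the report."""
    warnings: list = []
    spec = synthetic.default_scenario(seed=config.seed)

    light_df = (core.read_gas_exchange(config.light_csv) if config.light_csv
                else synthetic.gen_light_response(spec))
    temp_df = (core.read_gas_exchange(config.temperature_csv) if config.temperature_csv
               else synthetic.gen_temperature_response(spec))
    logger_df = (microclimate.read_logger(config.logger_csv) if config.logger_csv
                 else synthetic.gen_microclimate(spec))
    seasonal_df = synthetic.gen_seasonal(spec)

    # --- light-response fits and group comparisons
    light_fits = _fit_light_stage(light_df, config)
    light_tests = {c: _ttest_between(light_fits, c) for c in ("lcp", "lsp", "phi", "np_max_net")}

    # --- temperature-response fits, cardinal points
    temp_table = core.temperature_table(temp_df)
    temp_fits = _fit_temperature_stage(temp_table, config)
    cardinal = {
        group: {
            "t_opt_C": fits["np"].t_opt,
            "np_at_topt": fits["np"].np_at_topt,
            "t_upper_C": fits["np"].t_upper,
            "np_model": fits["np"].model,
            "np_r2": fits["np"].r2,
            "dr_q10": fits["dr"].q10,
            "dr_r_ref": fits["dr"].r_ref,
            "dr_r2": fits["dr"].r2,
        }
        for group, fits in temp_fits.items()
    }

    # --- CUE table and 50% crossings
    cue_table, crossings = _cue_stage(temp_table)

    # --- acclimation ratios and classification
    profile = acc.build_acclimation_profile(
        temp_fits["control"]["np"], temp_fits["treatment"]["np"],
        temp_fits["control"]["dr"], temp_fits["treatment"]["dr"],
        list(spec.temperature_grid), delta=config.delta, tol=config.classification_tol,
    )
    nan_temps = [t for t, a, _ in profile.entries if not np.isfinite(a)]
    if nan_temps:
        warnings.append({"stage": "acclimation",
                         "message": f"NP acclimation ratio undefined at {nan_temps} °C "
                                    "(control NP non-positive)"})

    # --- microclimate
    inside, outside = microclimate.split_locations(logger_df)
    microclim = microclimate.chamber_differential(
        inside, outside, microclimate.parse_night_window(config.night_window))

    # --- seasonal trends
    trends = {}
    for col in ("np", "dr", "gp", "chl_mg_m2"):
        tr = stats.linear_trend(seasonal_df["day"], seasonal_df[col])
        trends[col] = {"slope": tr.slope, "intercept": tr.intercept,
                       "adj_r2": tr.adj_r2, "f": tr.f, "p": tr.p, "n": tr.n}

    # --- ANCOVA on the temperature-response rates
    ancova = {}
    for response in ("np", "dr"):
        cmp_ = stats.ancova_group_by_temperature(
            temp_table.rename(columns={"temperature_C": "temperature"}), response)
        ancova[response] = {
            "aic_table": [{"model": n, "aic": a, "n_params": k} for n, a, k in cmp_.table],
            "selected": cmp_.selected,
            "group_selected": cmp_.group_selected,
            "terms": [{"effect": e, "F": f, "p": p} for e, f, p in cmp_.terms],
        }

    def _clean(x):
        return None if (isinstance(x, float) and not np.isfinite(x)) else x

    report = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "light_fits": light_fits.drop(columns=["observed_max_exceeds_asymptote"]).to_dict("records"),
        "light_ttests": light_tests,
        "cardinal_points": cardinal,
        "cue": {
            "table": cue_table.to_dict("records"),
            "crossings": {g: (list(c) if c else None) for g, c in crossings.items()},
        },
        "acclimation": {
            "delta_C": profile.delta,
            "entries": [{"temperature_C": t, "ar_np": _clean(a), "ar_dr": _clean(d)}
                        for t, a, d in profile.entries],
            "q10_control": profile.q10_control,
            "q10_treatment": profile.q10_treatment,
            "classification_dr": profile.classification_dr,
            "type1_signature": profile.type1_signature,
            "np_acclimation": profile.np_acclimation,
        },
        "microclimate": microclim,
        "seasonal_trends": trends,
        "ancova": ancova,
        "warnings": warnings,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n", encoding="utf-8")
        light_fits.to_csv(out / "fits_light.csv", index=False)
        pd.DataFrame(cardinal).T.rename_axis("group").reset_index().to_csv(
            out / "fits_temp.csv", index=False)
        cue_table.to_csv(out / "cue.csv", index=False)
        (out / "acclim.json").write_text(
            json.dumps(report["acclimation"], sort_keys=True, indent=2) + "\n",
            encoding="utf-8")
        (out / "microclim.json").write_text(
            json.dumps(microclim, sort_keys=True, indent=2) + "\n", encoding="utf-8")
    return report
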