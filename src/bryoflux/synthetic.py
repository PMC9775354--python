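"""Seeded generators emulating a pulse-warming gas-exchange study.

Every generator draws from its own named child stream of one integer seed, so
adding a generator (or reordering calls) never perturbs existing streams, and
identical seeds give bit-identical output. With all noise levels at zero the
emitted values lie exactly on the generating functions, which makes the
generators usable as ground-truth oracles for the analysis stages.

The default scenario mirrors a two-group (ambient control vs +5 °C chamber
treatment) experiment: light-response curves measured at 15 °C over a
0–1500 µmol photons m⁻² s⁻¹ grid, NP/DR temperature responses over
{2, 5, 10, 15, 20, 25, 30} °C with the step order randomized per replicate,
chamber loggers with a +4.88 °C programmed night offset and a solar-gain
daytime overshoot, drying (desiccation) curves, and five seasonal sampling
dates with rising GP and DR but flat NP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .light import nrh
from .microclimate import saturation_vapour_pressure

_STREAMS = {
    "light": 11,
    "temperature": 23,
    "drying": 37,
    "microclimate": 41,
    "seasonal": 53,
}

MEASUREMENT_TEMPERATURE_C = 15.0   # cuvette temperature for light curves
LIGHT_GRID = (0, 25, 50, 100, 200, 400, 600, 800, 1000, 1250, 1500)
TEMPERATURE_GRID = (2, 5, 10, 15, 20, 25, 30)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth response parameters for one experimental group."""

    # light response (NRH)
    phi: float
    np_max_net: float
    theta: float
    # NP temperature response: peaked quadratic through
    # (t_opt, np_at_topt) with zero crossing at t_upper
    t_opt: float
    np_at_topt: float
    t_upper: float
    # DR temperature response (exponential)
    dr_ref: float          # DR at t_ref
    dr_q10: float
    t_ref: float = 10.0

    @property
    def rd(self) -> float:
        """Dark respiration during the light curve (DR at the cuvette temperature)."""
        return self.dr(MEASUREMENT_TEMPERATURE_C)

    @property
    def pg_max(self) -> float:
        return self.np_max_net + self.rd

    def light_response(self, irradiance):
        return nrh(irradiance, self.phi, self.pg_max, self.theta, self.rd)

    def np_temperature(self, t):
        t = np.asarray(t, dtype=float)
        width = self.t_upper - self.t_opt
        out = self.np_at_topt * (1.0 - ((t - self.t_opt) / width) ** 2)
        return float(out) if out.ndim == 0 else out

    def dr(self, t):
        t = np.asarray(t, dtype=float)
        out = self.dr_ref * self.dr_q10 ** ((t - self.t_ref) / 10.0)
        return float(out) if out.ndim == 0 else out


# Default group contrasts: the treatment (chamber-warmed) group has a higher
# quantum efficiency and net asymptote, a warmer NP optimum and upper
# threshold, and DR elevated ~28.6% with a slightly lower Q10.
CONTROL_TRUTH = GroupTruth(
    phi=0.035, np_max_net=3.23, theta=0.7,
    t_opt=3.03, np_at_topt=1.71, t_upper=17.9,
    dr_ref=1.0, dr_q10=2.81,
)
TREATMENT_TRUTH = GroupTruth(
    phi=0.11, np_max_net=10.57, theta=0.7,
    t_opt=11.65, np_at_topt=4.38, t_upper=26.9,
    dr_ref=1.286, dr_q10=2.49,
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything the generators need, with ground truth for recovery tests."""

    seed: int = 42
    groups: dict = field(default_factory=lambda: {
        "control": CONTROL_TRUTH, "treatment": TREATMENT_TRUTH})
    n_replicates: int = 6
    light_grid: tuple = LIGHT_GRID
    temperature_grid: tuple = TEMPERATURE_GRID
    # measurement noise
    light_noise_sd: float = 0.5        # µmol m⁻² s⁻¹, on NP along light curves
    temp_noise_sd: float = 0.3         # µmol m⁻² s⁻¹, on NP at temperature steps
    dr_noise_sigma_log: float = 0.05   # log-sd of multiplicative DR noise
    dr_noise_sd: float = 0.0           # optional additive DR noise, µmol m⁻² s⁻¹
    # cuvette geometry (used to encode fluxes as raw CO2 signals)
    canopy_area_m2: float = 0.002
    molar_flow_mol_s: float = 0.01
    lsp_irradiance: float = 600.0      # illumination for temperature steps
    # drying curve
    wc_grid: tuple = tuple(range(10, 122, 2))
    wc_opt: float = 60.0
    wc_width: float = 50.0
    drying_np_max: float = 3.0
    drying_noise_sd: float = 0.2
    # chamber loggers
    logger_days: int = 4
    logger_step_min: int = 15
    t_out_mean: float = 1.0
    t_out_amplitude: float = 4.0
    night_offset: float = 4.88
    day_overshoot_max: float = 25.0
    logger_noise_sd: float = 0.3
    vp_inside_kPa: float = 0.65
    vp_outside_kPa: float = 0.43
    rh_noise_sd: float = 1.0
    # seasonal campaign
    season_day_offsets: tuple = (0, 15, 33, 46, 63)
    n_seasonal: int = 5
    season_np0: float = 2.2
    season_dr0: float = 0.8
    season_chl0: float = 1100.0
    season_np_slope: float = 0.0
    season_dr_slope: float = 0.12
    season_chl_slope: float = -8.85
    season_flux_sd: float = 0.4
    season_chl_sd: float = 150.0

    @property
    def season_gp_slope(self) -> float:
        return self.season_np_slope + self.season_dr_slope

    def drying_truth_interval(self, fraction: float = 0.9):
        """Closed-form water-content interval of the generating parabola."""
        half = self.wc_width * np.sqrt(1.0 - fraction)
        return (self.wc_opt - half, self.wc_opt + half)

    def noise_free(self) -> "ScenarioSpec":
        return replace(self, light_noise_sd=0.0, temp_noise_sd=0.0,
                       dr_noise_sigma_log=0.0, dr_noise_sd=0.0, drying_noise_sd=0.0,
                       logger_noise_sd=0.0, rh_noise_sd=0.0,
                       season_flux_sd=0.0, season_chl_sd=0.0)


def default_scenario(seed: int = 42, **overrides) -> ScenarioSpec:
    return replace(ScenarioSpec(seed=seed), **overrides)


def _sample_ids(spec: ScenarioSpec, group: str):
    prefix = "C" if group == "control" else "T"
    return [f"{prefix}{k + 1}" for k in range(spec.n_replicates)]


def _flux_to_diff(flux, spec: ScenarioSpec):
    """Invert the open-system flux equation into a raw CO2 differential."""
    return np.asarray(flux) * spec.canopy_area_m2 / spec.molar_flow_mol_s


def _row(spec, sample, group, mode, irr, temp, flux, wc=100.0):
    return {
        "sample_id": sample,
        "group": group,
        "mode": mode,
        "irradiance_umol_m2_s": float(irr),
        "temperature_C": float(temp),
        "co2_diff_umol_mol": float(_flux_to_diff(flux, spec)),
        "flow_mol_s": spec.molar_flow_mol_s,
        "area_m2": spec.canopy_area_m2,
        "water_content_pct": wc,
    }


def gen_light_response(spec: ScenarioSpec) -> pd.DataFrame:
    """Per-replicate NRH light curves (dark reading included) at 15 °C."""
    rng = _rng(spec.seed, "light")
    rows = []
    for group, truth in spec.groups.items():
        for sample in _sample_ids(spec, group):
            for irr in spec.light_grid:
                true_np = truth.light_response(irr)
                obs = true_np + rng.normal(0.0, spec.light_noise_sd) if spec.light_noise_sd else true_np
                mode = "dark" if irr == 0 else "light"
                rows.append(_row(spec, sample, group, mode, irr,
                                 MEASUREMENT_TEMPERATURE_C, obs))
    return pd.DataFrame(rows)


def gen_temperature_response(spec: ScenarioSpec) -> pd.DataFrame:
    """NP (light) and DR (dark) readings at randomized temperature steps."""
    rng = _rng(spec.seed, "temperature")
    rows = []
    for group, truth in spec.groups.items():
        for sample in _sample_ids(spec, group):
            order = rng.permutation(len(spec.temperature_grid))
            for idx in order:
                t = spec.temperature_grid[idx]
                np_true = truth.np_temperature(t)
                np_obs = np_true + rng.normal(0.0, spec.temp_noise_sd) if spec.temp_noise_sd else np_true
                dr_true = truth.dr(t)
                dr_obs = (dr_true * np.exp(rng.normal(0.0, spec.dr_noise_sigma_log))
                          if spec.dr_noise_sigma_log else dr_true)
                if spec.dr_noise_sd:
                    dr_obs = dr_obs + rng.normal(0.0, spec.dr_noise_sd)
                rows.append(_row(spec, sample, group, "dark", 0.0, t, -dr_obs))
                rows.append(_row(spec, sample, group, "light", spec.lsp_irradiance, t, np_obs))
    return pd.DataFrame(rows)


def gen_drying_curve(spec: ScenarioSpec, monotone: bool = False) -> pd.DataFrame:
    """Unimodal (or optionally monotone-increasing) NP-vs-water-content curves."""
    rng = _rng(spec.seed, "drying")
    rows = []
    for wc in spec.wc_grid:
        if monotone:
            true_np = spec.drying_np_max * wc / max(spec.wc_grid)
        else:
            true_np = spec.drying_np_max * (1.0 - ((wc - spec.wc_opt) / spec.wc_width) ** 2)
        obs = true_np + rng.normal(0.0, spec.drying_noise_sd) if spec.drying_noise_sd else true_np
        rows.append({"sample_id": "D1", "water_content_pct": float(wc), "np": float(obs)})
    return pd.DataFrame(rows)


def gen_microclimate(spec: ScenarioSpec) -> pd.DataFrame:
    """Inside/outside logger traces with night offset and daytime overshoot.

    Outside air temperature is a diurnal sinusoid (peak mid-afternoon);
    the chamber adds the programmed offset during the night window
    [21:00, 08:00) and a half-sine solar-gain overshoot (zero at the window
    edges, peaking at ``day_overshoot_max``) during the day. Relative
    humidity is back-computed from target vapour pressures so the chamber
    air holds ~50% more water vapour.
    """
    rng = _rng(spec.seed, "microclimate")
    n = spec.logger_days * 24 * 60 // spec.logger_step_min
    ts = pd.date_range("2018-11-26 00:00", periods=n, freq=f"{spec.logger_step_min}min")
    hour = ts.hour + ts.minute / 60.0
    hour = np.asarray(hour, dtype=float)
    night = (hour >= 21.0) | (hour < 8.0)

    t_out_clean = spec.t_out_mean + spec.t_out_amplitude * np.sin(
        2.0 * np.pi * (hour - 9.0) / 24.0)
    overshoot = spec.day_overshoot_max * np.sin(np.pi * (hour - 8.0) / 13.0)
    delta = np.where(night, spec.night_offset, np.clip(overshoot, 0.0, None))
    t_in_clean = t_out_clean + delta

    eps_out = rng.normal(0.0, spec.logger_noise_sd, n) if spec.logger_noise_sd else 0.0
    eps_in = rng.normal(0.0, spec.logger_noise_sd, n) if spec.logger_noise_sd else 0.0
    t_out = t_out_clean + eps_out
    t_in = t_in_clean + eps_in

    def rh_for(t_air, vp_target):
        rh = 100.0 * vp_target / saturation_vapour_pressure(t_air)
        if spec.rh_noise_sd:
            rh = rh + rng.normal(0.0, spec.rh_noise_sd, n)
        return np.clip(rh, 1.0, 100.0)

    rh_out = rh_for(t_out, spec.vp_outside_kPa)
    rh_in = rh_for(t_in, spec.vp_inside_kPa)

    frames = []
    for loc, t_air, rh in (("inside", t_in, rh_in), ("outside", t_out, rh_out)):
        frames.append(pd.DataFrame({
            "timestamp_iso8601": ts.strftime("%Y-%m-%dT%H:%M:%S"),
            "location": loc,
            "t_air_C": t_air,
            "t_soil_C": 0.5 * t_air,
            "rh_pct": rh,
        }))
    return pd.concat(frames, ignore_index=True)


def gen_seasonal(spec: ScenarioSpec) -> pd.DataFrame:
    """Five seasonal sampling dates with programmed GP/DR/chlorophyll trends."""
    rng = _rng(spec.seed, "seasonal")
    rows = []
    for d in spec.season_day_offsets:
        for k in range(spec.n_seasonal):
            np_true = spec.season_np0 + spec.season_np_slope * d
            dr_true = spec.season_dr0 + spec.season_dr_slope * d
            chl_true = spec.season_chl0 + spec.season_chl_slope * d
            np_obs = np_true + (rng.normal(0.0, spec.season_flux_sd) if spec.season_flux_sd else 0.0)
            dr_obs = dr_true + (rng.normal(0.0, spec.season_flux_sd) if spec.season_flux_sd else 0.0)
            chl_obs = chl_true + (rng.normal(0.0, spec.season_chl_sd) if spec.season_chl_sd else 0.0)
            rows.append({
                "day": float(d),
                "sample_id": f"S{k + 1}",
                "np": float(np_obs),
                "dr": float(dr_obs),
                "gp": float(np_obs + dr_obs),
                "chl_mg_m2": float(chl_obs),
            })
    return pd.DataFrame(rows)
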