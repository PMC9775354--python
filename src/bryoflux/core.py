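"""Domain types, cuvette flux arithmetic and CSV I/O.

Fluxes follow the open-system cuvette convention: net photosynthesis (NP) is
positive when the canopy draws CO2 down, dark respiration (DR) is stored as a
positive magnitude, and gross photosynthesis is their sum, GP = NP + DR.
All fluxes are expressed per canopy surface area, in µmol CO2 m⁻² s⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SignConventionError

logger = logging.getLogger(__name__)

GAS_EXCHANGE_COLUMNS = [
    "sample_id",
    "group",
    "mode",
    "irradiance_umol_m2_s",
    "temperature_C",
    "co2_diff_umol_mol",
    "flow_mol_s",
    "area_m2",
    "water_content_pct",
]

CHLOROPHYLL_COLUMNS = ["sample_id", "group", "a665", "a649", "volume_ml", "area_m2"]

#: Chlorophyll equations for DMSO extracts (µg mL⁻¹ from absorbances at
#: 665 and 649 nm). Overridable wherever chlorophyll is computed.
WELLBURN_DMSO = {
    "chl_a": (12.47, -3.62),   # coefficients on (A665, A649)
    "chl_b": (-6.50, 25.06),
}


@dataclass(frozen=True)
class GasExchangeRecord:
    """One cuvette reading (conditions plus raw CO2 signal) for one sample."""

    sample_id: str
    group: str                  # "control" | "treatment"
    irradiance: float           # µmol photons m⁻² s⁻¹
    temperature: float          # °C
    co2_differential: float     # µmol CO2 mol⁻¹ air
    molar_flow: float           # mol air s⁻¹
    canopy_area: float          # m²
    water_content: float | None = None   # % of dry mass
    mode: str = "light"         # "light" | "dark"

    def __post_init__(self):
        if self.canopy_area <= 0 or self.molar_flow <= 0:
            raise InvalidInputError("canopy area and molar flow must be strictly positive")
        if self.irradiance < 0:
            raise InvalidInputError("irradiance must be non-negative")
        if self.mode == "dark" and self.irradiance != 0:
            raise InvalidInputError("dark-mode readings must have zero irradiance")
        if self.mode not in ("light", "dark"):
            raise InvalidInputError(f"unknown mode {self.mode!r}")

    @property
    def flux(self) -> float:
        """Signed area-based flux (positive = net CO2 uptake)."""
        return compute_area_flux(self.co2_differential, self.molar_flow, self.canopy_area)


@dataclass(frozen=True)
class FluxTriple:
    """NP, DR (positive magnitude) and their sum GP for one condition."""

    np: float
    dr: float
    gp: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.dr < 0:
            raise SignConventionError("dark respiration must be a positive magnitude")
        object.__setattr__(self, "gp", self.np + self.dr)


@dataclass(frozen=True)
class DryingCurve:
    """NP measured along a desiccation cycle, as (water content %, NP) pairs."""

    points: tuple

    def __post_init__(self):
        pts = tuple(sorted((float(w), float(n)) for w, n in self.points))
        object.__setattr__(self, "points", pts)

    @property
    def np_max(self) -> float:
        return max(n for _, n in self.points)


@dataclass(frozen=True)
class ChlAssay:
    """One DMSO-extract absorbance pair with extract volume and canopy area."""

    a665: float
    a649: float
    extract_volume: float   # mL
    canopy_area: float      # m²

    def __post_init__(self):
        if self.a665 < 0 or self.a649 < 0:
            raise InvalidInputError("absorbances must be non-negative")
        if self.extract_volume <= 0 or self.canopy_area <= 0:
            raise InvalidInputError("extract volume and canopy area must be positive")

    @property
    def chl_total(self) -> float:
        return chlorophyll_content(self)


def compute_area_flux(co2_differential, molar_flow, canopy_area):
    """Open-system cuvette flux: differential × molar flow / canopy area.

    Units: µmol mol⁻¹ × mol s⁻¹ / m² = µmol m⁻² s⁻¹. CO2 drawdown in the
    light yields positive NP; CO2 release in the dark yields a negative net
    flux whose magnitude is the DR.
    """
    co2_differential = np.asarray(co2_differential, dtype=float)
    molar_flow = np.asarray(molar_flow, dtype=float)
    canopy_area = np.asarray(canopy_area, dtype=float)
    if np.any(canopy_area <= 0) or np.any(molar_flow <= 0):
        raise InvalidInputError("canopy area and molar flow must be strictly positive")
    out = co2_differential * molar_flow / canopy_area
    return float(out) if out.ndim == 0 else out


def gross_photosynthesis(np_flux: float, dr: float) -> float:
    """GP = NP + DR, with DR supplied as a positive magnitude."""
    if dr < 0:
        raise SignConventionError("dark respiration must be a positive magnitude")
    return np_flux + dr


def dark_flux_to_dr(flux: float) -> float:
    """Negate a raw dark-mode net flux (CO2 release, negative) into a DR magnitude."""
    return -flux


def optimal_water_content(curve: DryingCurve | Sequence, fraction: float = 0.9):
    """Water-content interval sustaining NP ≥ fraction × NP_max.

    The drying curve is linearly interpolated between measured points; the
    returned pair is the smallest and largest water content (in % dry mass)
    at which the interpolated NP reaches the threshold. The measured NP_max
    always lies inside the interval.
    """
    if not isinstance(curve, DryingCurve):
        curve = DryingCurve(tuple(curve))
    if not 0 < fraction <= 1:
        raise InvalidInputError("fraction must be in (0, 1]")
    pts = curve.points
    if len(pts) < 3:
        raise InvalidInputError("need at least 3 drying-curve points")
    wc = np.array([p[0] for p in pts])
    flux = np.array([p[1] for p in pts])
    if np.allclose(wc, wc[0]):
        raise InvalidInputError("degenerate drying curve: constant water content")
    threshold = fraction * curve.np_max

    lo = hi = None
    for i in range(len(pts) - 1):
        w0, n0 = wc[i], flux[i]
        w1, n1 = wc[i + 1], flux[i + 1]
        seg = []
        if n0 >= threshold:
            seg.append(w0)
        if n1 >= threshold:
            seg.append(w1)
        # crossing inside the segment
        if (n0 - threshold) * (n1 - threshold) < 0:
            seg.append(w0 + (threshold - n0) * (w1 - w0) / (n1 - n0))
        if seg:
            smin, smax = min(seg), max(seg)
            lo = smin if lo is None else min(lo, smin)
            hi = smax if hi is None else max(hi, smax)
    # np_max is attained at a measured point, so the interval is never empty
    return float(lo), float(hi)


def chlorophyll_content(assay: ChlAssay | None = None, *, a665=None, a649=None,
                        extract_volume=None, canopy_area=None,
                        coefficients=WELLBURN_DMSO):
    """Total chlorophyll (a+b) per canopy area, mg m⁻².

    Concentrations in the extract (µg mL⁻¹) come from the two absorbances via
    the configured coefficient set, are scaled by extract volume to µg, and
    divided by canopy area (converted to mg m⁻²).
    """
    if assay is not None:
        a665, a649 = assay.a665, assay.a649
        extract_volume, canopy_area = assay.extract_volume, assay.canopy_area
    if a665 < 0 or a649 < 0:
        raise InvalidInputError("absorbances must be non-negative")
    if extract_volume <= 0 or canopy_area <= 0:
        raise InvalidInputError("extract volume and canopy area must be positive")
    ca = coefficients["chl_a"][0] * a665 + coefficients["chl_a"][1] * a649
    cb = coefficients["chl_b"][0] * a665 + coefficients["chl_b"][1] * a649
    total_ug_per_ml = ca + cb
    total_mg = total_ug_per_ml * extract_volume / 1000.0
    return total_mg / canopy_area


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _check_columns(df: pd.DataFrame, required: list, what: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} CSV is missing columns: {missing}")
    unknown = [c for c in df.columns if c not in required]
    if unknown:
        logger.warning("%s CSV: ignoring unknown columns %s", what, unknown)
    return df[required]


def read_gas_exchange(path) -> pd.DataFrame:
    """Read a long-format gas-exchange CSV (header-named columns, UTF-8)."""
    df = pd.read_csv(path, encoding="utf-8")
    df = _check_columns(df, GAS_EXCHANGE_COLUMNS, "gas-exchange")
    if (df["area_m2"] <= 0).any() or (df["flow_mol_s"] <= 0).any():
        raise InvalidInputError("area and flow must be strictly positive")
    return df


def write_gas_exchange(df: pd.DataFrame, path) -> None:
    df[GAS_EXCHANGE_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def read_chlorophyll(path) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    return _check_columns(df, CHLOROPHYLL_COLUMNS, "chlorophyll")


def write_chlorophyll(df: pd.DataFrame, path) -> None:
    df[CHLOROPHYLL_COLUMNS].to_csv(path, index=False, encoding="utf-8")


def add_fluxes(df: pd.DataFrame) -> pd.DataFrame:
    """Append a signed `flux` column computed from the raw CO2 signal."""
    out = df.copy()
    out["flux"] = compute_area_flux(
        df["co2_diff_umol_mol"].to_numpy(),
        df["flow_mol_s"].to_numpy(),
        df["area_m2"].to_numpy(),
    )
    return out


def light_curve_points(df: pd.DataFrame, sample_id: str):
    """(irradiance, NP) pairs for one sample's light-response curve.

    Dark readings enter as the irradiance-zero point, whose net flux is −DR.
    """
    sub = add_fluxes(df[df["sample_id"] == sample_id])
    pts = sub[["irradiance_umol_m2_s", "flux"]].to_numpy(dtype=float)
    return pts[np.argsort(pts[:, 0])]


def temperature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Pair light/dark readings per (sample, temperature) into NP/DR/GP rows.

    Raw dark-mode fluxes are negative net uptake; they are negated on
    ingestion so DR is stored as a positive magnitude and GP = NP + DR.
    """
    sub = add_fluxes(df)
    light = sub[sub["mode"] == "light"]
    dark = sub[sub["mode"] == "dark"]
    keys = ["sample_id", "group", "temperature_C"]
    merged = pd.merge(
        light.groupby(keys, as_index=False)["flux"].mean().rename(columns={"flux": "np"}),
        dark.groupby(keys, as_index=False)["flux"].mean().rename(columns={"flux": "dr_raw"}),
        on=keys,
        how="inner",
    )
    merged["dr"] = merged["dr_raw"].map(dark_flux_to_dr)
    merged["gp"] = merged["np"] + merged["dr"]
    return merged.drop(columns=["dr_raw"])
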