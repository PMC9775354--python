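"""Carbon-use efficiency, acclimation ratios and acclimation classification.

CUE = 100·NP/GP is the instantaneous fraction of gross carbon gain retained
after respiratory losses; 50% marks NP–DR parity. The acclimation ratio
AR(T) = rate_treatment(T + Δ) / rate_control(T) compares warmed plants at
their (Δ-offset) growth temperature against controls: AR ≈ 1 is thermal
homeostasis (full acclimation); for respiration, AR below the control group's
Q10 over the same span indicates partial acclimation, AR at or above it none.
A decline of AR with measurement temperature is the classic Type 1 signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InvalidInputError, UndefinedCUEError

FULL = "full"
PARTIAL = "partial"
NONE = "none"


def carbon_use_efficiency(np_flux: float, dr: float) -> float:
    """CUE = 100·NP/(NP + DR), %. Negative when NP < 0."""
    gp = np_flux + dr
    if gp == 0:
        raise UndefinedCUEError("NP + DR = 0: CUE undefined")
    return 100.0 * np_flux / gp


@dataclass(frozen=True)
class CUEEntry:
    temperature: float
    cue: float
    group: str = ""


def cue_crossing(entries):
    """First measured temperature pair between which CUE crosses 50% from above.

    ``entries`` may be CUEEntry objects or (temperature, cue) pairs, sorted by
    temperature. Returns (t_low, t_high) or None when CUE never crosses.
    """
    pairs = [(e.temperature, e.cue) if isinstance(e, CUEEntry) else (float(e[0]), float(e[1]))
             for e in entries]
    temps = [t for t, _ in pairs]
    if temps != sorted(temps):
        raise InvalidInputError("entries must be sorted by temperature")
    for (t0, c0), (t1, c1) in zip(pairs, pairs[1:]):
        if c0 >= 50.0 > c1:
            return (t0, t1)
    return None


def _as_callable(curve):
    if callable(curve):
        return curve
    if hasattr(curve, "predict"):
        return curve.predict
    raise InvalidInputError("curve must be callable or expose .predict")


def acclimation_ratio(control_curve, treatment_curve, temperatures, delta: float = 5.0):
    """AR(T) = treatment(T + Δ) / control(T) on the fitted response curves.

    Temperatures where the control rate is non-positive yield NaN entries
    (reported, not fatal). Returns a list of (temperature, ar).
    """
    control = _as_callable(control_curve)
    treatment = _as_callable(treatment_curve)
    out = []
    for t in temperatures:
        c = float(control(t))
        if c <= 0:
            out.append((float(t), math.nan))
        else:
            out.append((float(t), float(treatment(t + delta)) / c))
    return out


def classify_acclimation(ar_values, q10_control: float, tol: float = 0.1,
                         temperatures=None):
    """Classify respiratory acclimation from an AR profile.

    Median AR within 1 ± tol → full (thermal homeostasis; medians below the
    band, i.e. treatment rates under control rates, also count as full);
    between 1 + tol and the control Q10 → partial; at or above the control
    Q10 → none. The Type 1 signature is a negative Theil–Sen slope of AR
    against temperature (AR order is otherwise irrelevant).
    """
    ar = np.asarray([a for a in ar_values if np.isfinite(a)], dtype=float)
    if ar.size == 0:
        raise InvalidInputError("ar_values must contain at least one finite value")
    if q10_control <= 1:
        raise InvalidInputError("q10_control must exceed 1")
    med = float(np.median(ar))
    if med >= q10_control:
        label = NONE
    elif med > 1 + tol:
        label = PARTIAL
    else:
        label = FULL

    type1 = False
    if temperatures is not None:
        t = np.asarray(temperatures, dtype=float)
        finite = np.isfinite(np.asarray(ar_values, dtype=float))
        t = t[finite]
        if t.size >= 2 and np.unique(t).size >= 2:
            slope = sps.theilslopes(ar, t)[0]
            type1 = bool(slope < 0)
    return label, type1


def np_acclimation_flag(ar_values) -> bool:
    """True when the median NP acclimation ratio exceeds 1 (increased rates)."""
    ar = np.asarray([a for a in ar_values if np.isfinite(a)], dtype=float)
    if ar.size == 0:
        raise InvalidInputError("ar_values must contain at least one finite value")
    return bool(np.median(ar) > 1.0)


@dataclass(frozen=True)
class AcclimationProfile:
    """AR-by-temperature profile with Q10s and the acclimation verdict."""

    delta: float
    entries: tuple                     # (temperature, ar_np, ar_dr)
    q10_control: float
    q10_treatment: float
    classification_dr: str = field(default="")
    type1_signature: bool = field(default=False)
    np_acclimation: bool = field(default=False)


def build_acclimation_profile(np_control, np_treatment, dr_control, dr_treatment,
                              temperatures, delta: float = 5.0, tol: float = 0.1
                              ) -> AcclimationProfile:
    """Assemble the full AR profile from fitted NP and DR response curves.

    ``dr_control``/``dr_treatment`` must expose a fitted ``q10`` attribute
    (e.g. :class:`~bryoflux.temperature.DRTemperatureFit`).
    """
    ar_np = acclimation_ratio(np_control, np_treatment, temperatures, delta)
    ar_dr = acclimation_ratio(dr_control, dr_treatment, temperatures, delta)
    entries = tuple((t, a_np, a_dr) for (t, a_np), (_, a_dr) in zip(ar_np, ar_dr))
    dr_vals = [a for _, _, a in entries]
    label, type1 = classify_acclimation(dr_vals, dr_control.q10, tol=tol,
                                        temperatures=[t for t, _, _ in entries])
    np_vals = [a for _, a, _ in entries]
    return AcclimationProfile(
        delta=delta,
        entries=entries,
        q10_control=dr_control.q10,
        q10_treatment=dr_treatment.q10,
        classification_dr=label,
        type1_signature=type1,
        np_acclimation=np_acclimation_flag(np_vals),
    )
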