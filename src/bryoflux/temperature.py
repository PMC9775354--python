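"""Temperature responses of net photosynthesis and dark respiration.

DR follows an exponential (Q10) law, DR(T) = R_ref · Q10^((T − T_ref)/10),
fitted on the log scale. NP follows a peaked polynomial (quadratic by
default, cubic when an information-criterion rule prefers it), from which
the thermal optimum T_opt and the high-temperature zero crossing T_upper
are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    DegreesOfFreedomError,
    InvalidInputError,
    NoOptimumError,
)


def q10(rate1: float, t1: float, rate2: float, t2: float) -> float:
    """Multiplicative rate change per 10 °C: (r2/r1)^(10/(t2−t1)).

    Symmetric under swapping the two observations.
    """
    if rate1 <= 0 or rate2 <= 0:
        raise InvalidInputError("rates must be strictly positive")
    if t1 == t2:
        raise InvalidInputError("the two temperatures must differ")
    return float((rate2 / rate1) ** (10.0 / (t2 - t1)))


@dataclass(frozen=True)
class DRTemperatureFit:
    """Exponential DR-vs-temperature fit referenced at ``t_ref``."""

    r_ref: float
    t_ref: float
    q10: float
    r2: float = float("nan")

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        out = self.r_ref * self.q10 ** ((t - self.t_ref) / 10.0)
        return float(out) if out.ndim == 0 else out


def fit_dr_exponential(points, t_ref: float = 10.0) -> DRTemperatureFit:
    """Fit DR(T) = R_ref·Q10^((T−T_ref)/10) by least squares on log DR.

    R² is reported on the natural (untransformed) scale.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array of (temperature, DR)")
    if len(pts) < 3:
        raise DegreesOfFreedomError("need at least 3 (temperature, DR) points")
    t, dr = pts[:, 0], pts[:, 1]
    if np.any(dr <= 0):
        raise InvalidInputError("all DR values must be strictly positive")
    x = (t - t_ref) / 10.0
    slope, intercept = np.polyfit(x, np.log(dr), 1)
    fit = DRTemperatureFit(r_ref=float(np.exp(intercept)), t_ref=float(t_ref),
                           q10=float(np.exp(slope)))
    pred = fit.predict(t)
    sst = float(np.sum((dr - dr.mean()) ** 2))
    r2 = 1.0 - float(np.sum((dr - pred) ** 2)) / sst if sst > 0 else float("nan")
    return DRTemperatureFit(fit.r_ref, fit.t_ref, fit.q10, r2)


@dataclass(frozen=True)
class NPTemperatureFit:
    """Peaked polynomial NP-vs-temperature fit with thermal cardinal points."""

    model: str                 # "quadratic" | "cubic"
    coefficients: tuple        # numpy polyval order (highest degree first)
    t_opt: float
    np_at_topt: float
    t_upper: float | None      # smallest NP = 0 crossing above t_opt, if any
    r2: float
    t_min: float
    t_max: float
    aic_table: dict | None = None

    def predict(self, t):
        out = np.polyval(self.coefficients, np.asarray(t, dtype=float))
        return float(out) if out.ndim == 0 else out


def _gaussian_aic(rss: float, n: int, n_coefs: int) -> float:
    # concentrated Gaussian log-likelihood; +1 parameter for the variance
    return n * np.log(rss / n) + 2 * (n_coefs + 1)


def _argmax_in_range(coefs, t_min, t_max):
    deriv = np.polyder(np.poly1d(coefs))
    crit = [r.real for r in deriv.roots if abs(r.imag) < 1e-9 and t_min <= r.real <= t_max]
    candidates = np.array(crit + [t_min, t_max])
    values = np.polyval(coefs, candidates)
    k = int(np.argmax(values))
    return float(candidates[k]), float(values[k]), bool(crit)


def _upper_zero_crossing(coefs, t_opt, t_max, window: float = 10.0):
    roots = [r.real for r in np.poly1d(coefs).roots
             if abs(r.imag) < 1e-9 and t_opt < r.real <= t_max + window]
    if not roots:
        return None
    root = min(roots)
    # polish with bracketed root finding when a sign change brackets the root
    f = lambda t: np.polyval(coefs, t)
    lo, hi = max(t_opt, root - 0.5), root + 0.5
    if f(lo) * f(hi) < 0:
        root = optimize.brentq(f, lo, hi, xtol=1e-10)
    return float(root)


def fit_np_temperature(points, model_selection: str = "quadratic") -> NPTemperatureFit:
    """Fit NP(T) with a peaked polynomial and extract T_opt and T_upper.

    A quadratic is fitted by default. With ``model_selection="aic"`` a cubic
    is fitted additionally and adopted only when its AIC undercuts the
    quadratic's by at least 2 (models within 2 AIC are treated as equivalent
    and the simpler one kept). T_opt is the argmax of the fitted polynomial
    inside the measured range; T_upper is the smallest zero crossing above
    T_opt within the range extended by 10 °C, or None.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array of (temperature, NP)")
    if len(pts) < 5:
        raise DegreesOfFreedomError("need at least 5 (temperature, NP) points")
    t, y = pts[:, 0], pts[:, 1]
    t_min, t_max = float(t.min()), float(t.max())

    quad = np.polyfit(t, y, 2)
    rss_q = float(np.sum((y - np.polyval(quad, t)) ** 2))
    aic_table = {"quadratic": _gaussian_aic(max(rss_q, 1e-300), len(t), 3)}
    coefs, model = quad, "quadratic"
    if model_selection == "aic" and len(t) >= 6:
        cubic = np.polyfit(t, y, 3)
        rss_c = float(np.sum((y - np.polyval(cubic, t)) ** 2))
        aic_table["cubic"] = _gaussian_aic(max(rss_c, 1e-300), len(t), 4)
        if aic_table["cubic"] <= aic_table["quadratic"] - 2:
            coefs, model = cubic, "cubic"
    elif model_selection not in ("quadratic", "aic"):
        raise InvalidInputError(f"unknown model_selection {model_selection!r}")

    if model == "quadratic" and coefs[0] >= 0:
        raise NoOptimumError("fitted quadratic is concave-up: no interior maximum")
    t_opt, np_at_topt, _ = _argmax_in_range(coefs, t_min, t_max)

    rss = float(np.sum((y - np.polyval(coefs, t)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / sst if sst > 0 else float("nan")
    return NPTemperatureFit(
        model=model,
        coefficients=tuple(float(c) for c in coefs),
        t_opt=t_opt,
        np_at_topt=np_at_topt,
        t_upper=_upper_zero_crossing(coefs, t_opt, t_max),
        r2=float(r2),
        t_min=t_min,
        t_max=t_max,
        aic_table=aic_table,
    )
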