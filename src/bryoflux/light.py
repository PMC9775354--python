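"""Non-rectangular hyperbola (NRH) light-response fitting and cardinal points.

Net photosynthesis as a function of incident irradiance I is modelled as the
lower root of the quadratic

    θ·NP_g² − (φI + P_gmax)·NP_g + φI·P_gmax = 0,     NP(I) = NP_g − R_d,

with quantum efficiency φ (initial slope), gross asymptote P_gmax, convexity
θ ∈ [0, 1) and dark respiration R_d. The root is evaluated in the
cancellation-free form 2φI·P_gmax / (x + √(x² − 4θφI·P_gmax)), x = φI + P_gmax,
which is exact in the rectangular-hyperbola limit θ → 0.

The light compensation point (LCP) is the irradiance where the fitted curve
crosses zero; the light saturation point (LSP) is where NP first reaches a
stated fraction (default 90%) of the net asymptote P_gmax − R_d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    ConvergenceError,
    DegreesOfFreedomError,
    InvalidInputError,
    NoCompensationPointError,
    UnreachableLevelError,
)

THETA_MAX = 0.999


def nrh(irradiance, phi, pg_max, theta, rd):
    """Evaluate the NRH net flux at one or more irradiances."""
    if not 0 <= theta < 1:
        raise InvalidInputError("theta must lie in [0, 1)")
    if phi <= 0 or pg_max <= 0:
        raise InvalidInputError("phi and pg_max must be positive")
    i = np.asarray(irradiance, dtype=float)
    if np.any(i < 0):
        raise InvalidInputError("irradiance must be non-negative")
    x = phi * i + pg_max
    disc = np.maximum(x * x - 4.0 * theta * phi * i * pg_max, 0.0)
    gross = 2.0 * phi * i * pg_max / (x + np.sqrt(disc))
    out = gross - rd
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class NRHFit:
    """Fitted NRH parameters with goodness of fit."""

    phi: float      # µmol CO2 (µmol photons)⁻¹
    pg_max: float   # µmol m⁻² s⁻¹, gross asymptote
    theta: float    # convexity, [0, 1)
    rd: float       # µmol m⁻² s⁻¹, dark respiration (≥ 0)
    r2: float = float("nan")
    observed_max_exceeds_asymptote: bool = False

    def __post_init__(self):
        if not 0 <= self.theta < 1:
            raise InvalidInputError("theta must lie in [0, 1)")
        if self.phi <= 0 or self.pg_max <= 0:
            raise InvalidInputError("phi and pg_max must be positive")
        if self.rd < 0:
            raise InvalidInputError("rd must be non-negative")

    @property
    def np_max_net(self) -> float:
        """Net asymptote P_gmax − R_d."""
        return self.pg_max - self.rd

    def predict(self, irradiance):
        return nrh(irradiance, self.phi, self.pg_max, self.theta, self.rd)


def nrh_predict(fit: NRHFit, irradiance):
    """Module-level alias for :meth:`NRHFit.predict`."""
    return fit.predict(irradiance)


def _starts(i, y, rd_seed):
    """Eight deterministic starting points from quantile heuristics."""
    rd0 = rd_seed if rd_seed is not None else max(0.05 * max(y.max(), 0.1), 1e-3)
    pos = i > 0
    i_lo = i[pos].min()
    slope0 = (np.interp(i_lo, i, y) + rd0) / i_lo
    slope0 = float(np.clip(slope0, 1e-4, 2.0))
    pg0 = max(y.max() + rd0, 0.1)
    starts = []
    for theta0 in (0.1, 0.4, 0.7, 0.9):
        for fphi in (1.0, 1.6):
            starts.append((slope0 * fphi, pg0, theta0, rd0))
    return starts


def fit_light_response(points, theta_bounds=(0.0, THETA_MAX), rd_seed=None,
                       max_irradiance=None) -> NRHFit:
    """Least-squares NRH fit to (irradiance, NP) pairs.

    Uses 8 deterministic multi-starts (quantile heuristics for the initial
    slope, asymptote and convexity); ties are broken by lowest residual sum
    of squares, then fewest solver evaluations. When a dark reading
    (irradiance 0) is present its negated flux seeds R_d. Points above
    ``max_irradiance`` (if given) are excluded before fitting, e.g. to drop
    a photoinhibited tail.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidInputError("points must be an (n, 2) array of (irradiance, NP)")
    if max_irradiance is not None:
        pts = pts[pts[:, 0] <= max_irradiance]
    i, y = pts[:, 0], pts[:, 1]
    if len(np.unique(i)) < 5:
        raise DegreesOfFreedomError("need at least 5 distinct irradiance levels")
    if rd_seed is None and np.any(i == 0):
        rd_seed = max(-float(np.mean(y[i == 0])), 0.0)
    elif rd_seed is None:
        raise DegreesOfFreedomError("need a dark (irradiance 0) reading or an explicit rd seed")

    lo = [1e-6, 1e-6, theta_bounds[0], 0.0]
    hi = [5.0, 1e4, theta_bounds[1], 1e3]

    def residuals(p):
        phi, pg, th, rd = p
        x = phi * i + pg
        disc = np.maximum(x * x - 4.0 * th * phi * i * pg, 0.0)
        return 2.0 * phi * i * pg / (x + np.sqrt(disc)) - rd - y

    best = None
    diagnostics = []
    for start in _starts(i, y, rd_seed):
        p0 = np.clip(start, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, p0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - solver-internal failure
            diagnostics.append({"start": list(p0), "error": str(exc)})
            continue
        if not res.success and not np.isfinite(res.cost):
            diagnostics.append({"start": list(p0), "status": res.status})
            continue
        key = (res.cost, res.nfev)
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise ConvergenceError("NRH fit failed on all starts", diagnostics)

    phi, pg, th, rd = best[1].x
    sse = 2.0 * best[1].cost
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    fit = NRHFit(phi=float(phi), pg_max=float(pg), theta=float(min(th, THETA_MAX)),
                 rd=float(rd), r2=float(r2),
                 observed_max_exceeds_asymptote=bool(y.max() > pg - rd))
    return fit


def _bracket_upper(f, lo=1.0, max_doublings=60):
    hi = lo
    for _ in range(max_doublings):
        if f(hi) > 0:
            return hi
        hi *= 2.0
    raise UnreachableLevelError("target level not reached within the search window")


def light_compensation_point(fit: NRHFit) -> float:
    """Irradiance at which the fitted curve crosses NP = 0."""
    if fit.rd == 0:
        return 0.0
    if fit.np_max_net <= 0 or fit.rd >= fit.pg_max:
        raise NoCompensationPointError("rd at or above the gross asymptote: no zero crossing")
    f = lambda i: fit.predict(i)
    hi = _bracket_upper(f)
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-15))


def light_saturation_point(fit: NRHFit, fraction: float = 0.9) -> float:
    """Smallest irradiance where NP reaches ``fraction`` of the net asymptote."""
    if fraction >= 1:
        raise UnreachableLevelError("the asymptote is never attained at finite irradiance")
    if fraction <= 0:
        raise InvalidInputError("fraction must be in (0, 1)")
    if fit.np_max_net <= 0:
        raise NoCompensationPointError("net asymptote is non-positive")
    target = fraction * fit.np_max_net
    f = lambda i: fit.predict(i) - target
    if f(0.0) >= 0:
        return 0.0
    hi = _bracket_upper(f)
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-15))


@dataclass(frozen=True)
class LightCardinalPoints:
    """LCP and LSP extracted from one fitted curve."""

    lcp: float
    lsp: float
    fraction: float = 0.9


def cardinal_points(fit: NRHFit, fraction: float = 0.9) -> LightCardinalPoints:
    return LightCardinalPoints(
        lcp=light_compensation_point(fit),
        lsp=light_saturation_point(fit, fraction),
        fraction=fraction,
    )
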