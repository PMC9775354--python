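"""NRH light-response model, fitting and light cardinal points."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bryoflux import light
from bryoflux.errors import (
    DegreesOfFreedomError,
    InvalidInputError,
    NoCompensationPointError,
    UnreachableLevelError,
)

PAPER_GRID = np.array([0, 25, 50, 100, 200, 400, 600, 800, 1000, 1250, 1500], float)

params_st = st.tuples(
    st.floats(0.02, 0.15),   # phi
    st.floats(2.0, 15.0),    # pg_max
    st.floats(0.0, 0.95),    # theta
    st.floats(0.1, 2.0),     # rd
)


def _grid_scan_crossing(fit, target, step=0.001, i_max=6000.0):
    """Independent oracle: first grid irradiance where NP reaches target."""
    for lo in np.arange(0, i_max, 500.0):
        grid = np.arange(lo, lo + 500.0, step)
        vals = fit.predict(grid)
        hit = np.nonzero(vals >= target)[0]
        if hit.size:
            return grid[hit[0]]
    raise AssertionError("grid scan found no crossing")


class TestNRHModel:
    def test_dark_prediction_equals_minus_rd(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=1.3)
        assert fit.predict(0.0) == pytest.approx(-1.3)

    def test_rectangular_hyperbola_limit_arithmetic(self):
        # θ=0: NP = φI·Pg/(φI+Pg) − Rd = 0.05·200·10/(0.05·200+10) − 1 = 4.0
        assert light.nrh(200, 0.05, 10, 0.0, 1.0) == pytest.approx(4.0)

    def test_initial_slope_equals_phi(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.9, rd=1.0)
        i = 1e-6
        assert fit.predict(i) == pytest.approx(0.05 * i - 1.0, abs=1e-10)

    def test_theta_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            light.nrh(100, 0.05, 10, 1.0, 1.0)
        with pytest.raises(InvalidInputError):
            light.NRHFit(phi=0.05, pg_max=10, theta=-0.1, rd=1.0)

    @given(params=params_st)
    def test_monotone_nondecreasing_and_concave(self, params):
        phi, pg, theta, rd = params
        grid = np.linspace(0, 2000, 400)
        vals = light.nrh(grid, phi, pg, theta, rd)
        d1 = np.diff(vals)
        assert np.all(d1 >= -1e-9)
        assert np.all(np.diff(d1) <= 1e-9)

    def test_continuous_in_theta_at_zero(self):
        lim = light.nrh(300, 0.05, 10, 0.0, 1.0)
        near = light.nrh(300, 0.05, 10, 1e-12, 1.0)
        assert near == pytest.approx(lim, abs=1e-9)


class TestFitLightResponse:
    def test_noise_free_round_trip_recovers_parameters(self):
        truth = (0.11, 12.0, 0.7, 1.2)
        y = light.nrh(PAPER_GRID, *truth)
        fit = light.fit_light_response(np.column_stack([PAPER_GRID, y]))
        for got, want in zip((fit.phi, fit.pg_max, fit.theta, fit.rd), truth):
            assert got == pytest.approx(want, rel=1e-4)
        assert fit.r2 == pytest.approx(1.0)

    def test_rectangular_data_recovered_with_small_theta(self):
        truth = (0.08, 9.0, 0.0, 0.8)
        y = light.nrh(PAPER_GRID, *truth)
        fit = light.fit_light_response(np.column_stack([PAPER_GRID, y]))
        assert fit.theta <= 0.05
        assert fit.phi == pytest.approx(truth[0], rel=0.01)
        assert fit.pg_max == pytest.approx(truth[1], rel=0.01)
        assert fit.rd == pytest.approx(truth[3], rel=0.01)

    def test_too_few_points_raises(self):
        pts = np.array([[0, -1.0], [100, 2.0], [500, 5.0]])
        with pytest.raises(DegreesOfFreedomError):
            light.fit_light_response(pts)

    def test_missing_dark_reading_requires_rd_seed(self):
        i = PAPER_GRID[1:]
        y = light.nrh(i, 0.1, 10, 0.5, 1.0)
        with pytest.raises(DegreesOfFreedomError):
            light.fit_light_response(np.column_stack([i, y]))
        fit = light.fit_light_response(np.column_stack([i, y]), rd_seed=1.0)
        assert fit.phi == pytest.approx(0.1, rel=1e-3)

    def test_median_phi_error_under_measurement_noise_below_15pct(self, rng):
        truth = (0.11, 12.0, 0.7, 1.2)
        clean = light.nrh(PAPER_GRID, *truth)
        errors = []
        for _ in range(200):
            y = clean + rng.normal(0, 0.5, size=clean.shape)
            fit = light.fit_light_response(np.column_stack([PAPER_GRID, y]))
            errors.append(abs(fit.phi - truth[0]) / truth[0])
        assert np.median(errors) < 0.15


class TestCardinalPoints:
    def test_lcp_zero_when_no_respiration(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=0.0)
        assert light.light_compensation_point(fit) == 0.0

    def test_lcp_matches_grid_scan(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=1.0)
        lcp = light.light_compensation_point(fit)
        assert fit.predict(lcp) == pytest.approx(0.0, abs=1e-9)
        assert lcp == pytest.approx(_grid_scan_crossing(fit, 0.0), abs=0.01)

    def test_lcp_increases_with_rd(self):
        lcps = [light.light_compensation_point(
            light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=rd))
            for rd in (0.5, 1.0, 2.0)]
        assert lcps == sorted(lcps)

    def test_lcp_impossible_when_rd_exceeds_asymptote(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=11.0)
        with pytest.raises(NoCompensationPointError):
            light.light_compensation_point(fit)

    def test_lsp_matches_grid_scan(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=1.0)
        lsp = light.light_saturation_point(fit, 0.9)
        assert lsp == pytest.approx(
            _grid_scan_crossing(fit, 0.9 * fit.np_max_net), abs=0.01)

    @given(params=params_st)
    def test_lsp_monotone_in_fraction(self, params):
        phi, pg, theta, rd = params
        rd = min(rd, 0.5 * pg)  # keep the net asymptote positive
        fit = light.NRHFit(phi=phi, pg_max=pg, theta=theta, rd=rd)
        assert (light.light_saturation_point(fit, 0.5)
                < light.light_saturation_point(fit, 0.9))

    def test_lsp_unreachable_at_the_asymptote(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=1.0)
        with pytest.raises(UnreachableLevelError):
            light.light_saturation_point(fit, 1.0)

    def test_lcp_below_lsp_with_respiration(self):
        fit = light.NRHFit(phi=0.05, pg_max=10, theta=0.7, rd=1.0)
        cp = light.cardinal_points(fit, 0.9)
        assert cp.lcp < cp.lsp
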