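"""Wire-field closed form against Ampère's law and a Biot–Savart oracle."""

import math

import numpy as np
import pytest

from rfcurrent import (
    BackgroundField,
    FieldPoint,
    WireGeometry,
    WireModelParams,
    biot_savart_field,
    lambda_total,
    lambda_total_xy,
    wire_field_magnitude,
)
from rfcurrent.constants import UT
from rfcurrent.wire_model import _wire_field

from conftest import random_wire_params


class TestWireFieldMagnitude:
    def test_ampere_closed_form_parallel(self):
        # straight wire along B0: B = mu0 I / (2 pi r)
        b = wire_field_magnitude(FieldPoint(10.0, 0.3), WireGeometry(0.0), 0.1)
        assert b == pytest.approx(2.0e-6, rel=1e-12)

    def test_tilted_wire_perpendicular_azimuth(self):
        # at theta_r - theta_j = pi/2 the geometric factor is 1: cos(45deg)
        # times the parallel-wire value
        g = WireGeometry(math.pi / 4, 0.0)
        b = wire_field_magnitude(FieldPoint(10.0, math.pi / 2), g, 0.1)
        assert b == pytest.approx(2.0e-6 * math.cos(math.pi / 4), rel=1e-12)

    def test_near_perpendicular_wire_vanishes(self):
        g = WireGeometry(math.pi / 2 - 1e-9, 0.0)
        b = wire_field_magnitude(FieldPoint(5.0, 1.0), g, 0.1)
        assert b < 1e-14

    def test_strictly_decreasing_in_r(self):
        g = WireGeometry(0.3, 0.5)
        r = np.linspace(1.0, 20.0, 50)
        vals = _wire_field(r, 0.7, g.xi_j, g.theta_j, 0.1)
        assert np.all(np.diff(vals) < 0)

    def test_singularity_on_axis(self):
        with pytest.raises(ValueError):
            FieldPoint(0.0)
        with pytest.raises(ZeroDivisionError):
            _wire_field(0.0, 0.0, 0.0, 0.0, 0.1)


class TestBiotSavartOracle:
    @pytest.mark.parametrize("xi_deg", [0.0, 20.0, 45.0])
    @pytest.mark.parametrize("r", [2.0, 6.0, 12.0])
    def test_infinite_wire_limit(self, xi_deg, r):
        """A ±1 m segment reproduces the closed form to within 0.5%."""
        xi = math.radians(xi_deg)
        g = WireGeometry(xi, 0.0)
        half = 1000.0  # mm
        seg = [
            (-half * math.sin(xi), 0.0, -half * math.cos(xi)),
            (half * math.sin(xi), 0.0, half * math.cos(xi)),
        ]
        for theta_r in np.linspace(0.0, 2 * math.pi, 7, endpoint=False):
            p = (r * math.cos(theta_r), r * math.sin(theta_r), 0.0)
            bv = biot_savart_field(seg, 0.1, p)
            transverse = math.hypot(bv[0], bv[1])
            closed = wire_field_magnitude(FieldPoint(r, theta_r), g, 0.1)
            assert transverse == pytest.approx(closed, rel=5e-3)

    def test_zero_current(self):
        b = biot_savart_field([(0, 0, -1000), (0, 0, 1000)], 0.0, (10, 0, 0))
        assert np.all(b == 0)

    def test_point_on_wire_raises(self):
        with pytest.raises(ZeroDivisionError):
            biot_savart_field([(0, 0, -10), (0, 0, 10)], 0.1, (0, 0, 0))


class TestLambdaTotal:
    def test_no_current_gives_background(self):
        p = WireModelParams(i_rms=0.0, background=BackgroundField(1.0))
        assert lambda_total(5.0, -3.0, p, 2.29) == pytest.approx(1.0)

    def test_near_perpendicular_wire_invisible(self):
        p = WireModelParams(
            i_rms=0.2,
            geometry=WireGeometry(math.pi / 2 - 1e-9),
            background=BackgroundField(0.8),
        )
        assert lambda_total(4.0, 4.0, p, 2.29) == pytest.approx(0.8, abs=1e-7)

    def test_far_field_limit(self):
        p = WireModelParams(i_rms=0.3, background=BackgroundField(1.1))
        assert abs(lambda_total(1e6, 0.0, p, 2.29) - 1.1) < 1e-4

    def test_background_gradient(self):
        bg = BackgroundField(1.0, 0.01, -0.005)
        p = WireModelParams(i_rms=0.0, background=bg)
        assert lambda_total(10.0, 4.0, p, 2.29) == pytest.approx(
            1.0 + 0.01 * 10 - 0.005 * 4
        )

    def test_hotspot_null_asymmetry(self):
        """Along sin(θr − φj′) the field splits into a null and a hotspot;
        perpendicular to it the two sides are equal — the classic wire
        artifact."""
        p = WireModelParams(
            i_rms=0.1, phi_j_prime=0.4, geometry=WireGeometry(0.0, 0.0, 0.0, 0.0)
        )
        r = 6.0
        phi = p.phi_j_prime

        def lam_at(theta):
            return lambda_total(r * math.cos(theta), r * math.sin(theta), p, 2.29)

        sym0, sympi = lam_at(phi), lam_at(phi + math.pi)
        lo, hi = lam_at(phi + math.pi / 2), lam_at(phi - math.pi / 2)
        assert sym0 == pytest.approx(sympi, rel=1e-12)
        assert lo < sym0 < hi

    def test_scaling_invariance(self, rng):
        """Joint rescaling of current and reference B1,rms leaves λ fixed."""
        p = random_wire_params(rng)
        k = 3.7
        p2 = WireModelParams(
            i_rms=k * p.i_rms,
            phi_j_prime=p.phi_j_prime,
            geometry=p.geometry,
            background=p.background,
        )
        x, y = 7.0, -5.0
        assert lambda_total(x, y, p, 2.29) == pytest.approx(
            lambda_total(x, y, p2, k * 2.29), rel=1e-12
        )

    def test_circular_decomposition_oracle(self, rng):
        """λ equals the magnitude of background B1+ plus the left-circular
        half of the azimuthal linear wire field (complex arithmetic,
        B1+ = (Bx − iBy)/2 convention)."""
        for _ in range(50):
            p = random_wire_params(rng)
            x, y = rng.uniform(-12, 12, 2)
            g = p.geometry
            r = math.hypot(x - g.x0, y - g.y0)
            if r < 1.0:
                continue
            th = math.atan2(y - g.y0, x - g.x0)
            lam_b = p.background.local(x, y)
            bj = _wire_field(r, th, g.xi_j, g.theta_j, p.i_rms)
            u = np.array([-math.sin(th), math.cos(th)])  # azimuthal direction
            bhat = bj * np.exp(1j * p.phi_j_prime) * u
            b1p_wire = (bhat[0] - 1j * bhat[1]) / 2.0
            b1p_bg = lam_b * 2.29 * UT
            oracle = abs(b1p_bg + b1p_wire) / (2.29 * UT)
            assert lambda_total(x, y, p, 2.29) == pytest.approx(oracle, rel=1e-12)

    def test_continuity_and_nonnegativity(self, rng):
        p = random_wire_params(rng)
        x = np.linspace(-12, 12, 101)
        y = np.linspace(-12, 12, 101)
        xx, yy = np.meshgrid(x, y)
        mask = np.hypot(xx - p.geometry.x0, yy - p.geometry.y0) > 0.5
        lam = lambda_total_xy(xx, yy, p, 2.29)
        assert np.all(lam[mask] >= 0)
        assert np.all(np.isfinite(lam[mask]))

    def test_sensitivity_scales_with_cos_xi(self):
        """dλ/dI at a point perpendicular to the wire projection scales
        with cos ξj."""
        x, y = 0.0, 8.0  # theta_r = pi/2, wire projection along +x
        eps = 1e-4

        def dlam_di(xi):
            p0 = WireModelParams(i_rms=0.1, geometry=WireGeometry(xi, 0.0))
            p1 = WireModelParams(i_rms=0.1 + eps, geometry=WireGeometry(xi, 0.0))
            return (lambda_total(x, y, p1, 2.29) - lambda_total(x, y, p0, 2.29)) / eps

        ratio = dlam_di(math.pi / 4) / dlam_di(0.0)
        assert ratio == pytest.approx(math.cos(math.pi / 4), rel=1e-2)


class TestValidation:
    def test_perpendicular_geometry_rejected(self):
        with pytest.raises(ValueError):
            WireGeometry(math.pi / 2)

    def test_negative_current_rejected(self):
        with pytest.raises(ValueError):
            WireModelParams(i_rms=-0.1)

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            BackgroundField(0.0)

    def test_identifiability_floor(self):
        assert WireModelParams(geometry=WireGeometry(0.0)).identifiable
        assert not WireModelParams(
            geometry=WireGeometry(math.radians(85.0))
        ).identifiable
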