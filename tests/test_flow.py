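import math

import numpy as np
import pytest

from rheodipole import (
    ConvergenceError,
    DomainError,
    FishState,
    ModelParams,
    SingularityError,
    TruncationPolicy,
    Vec2,
    background_velocity,
    circulation_rectangle,
    dipole_potential,
    dipole_velocity,
    field_grid,
    image_states,
    lateral_line_feedback,
    total_velocity,
    vorticity,
    wall_velocity,
    wall_velocity_series,
)

SERIES_ORACLE = TruncationPolicy(max_terms=800, tail_tol=None, richardson=2)


# ---------------------------------------------------------------------------
# dipole potential / velocity
# ---------------------------------------------------------------------------

class TestDipolePotential:
    def test_zero_on_perpendicular_line(self, params):
        fish = FishState(0.0, 0.5, 0.0)
        assert dipole_potential((0.0, 0.7), fish, params) == pytest.approx(0.0, abs=1e-15)

    def test_direct_evaluation(self):
        # fish at origin-ish, theta=0, v0=1, r0=0.1, point one unit ahead
        p = ModelParams(h=10.0, U0=0.0, eps=0.0, v0=1.0, r0=0.1, l=1.0)
        fish = FishState(0.0, 5.0, 0.0)
        assert dipole_potential((1.0, 5.0), fish, p) == pytest.approx(-0.01, rel=1e-12)

    def test_odd_under_point_reflection(self, params, fish, rng):
        for _ in range(10):
            d = rng.uniform(-0.3, 0.3, size=2)
            if np.hypot(*d) < 0.05:
                continue
            plus = dipole_potential((fish.x + d[0], fish.y + d[1]), fish, params)
            minus = dipole_potential((fish.x - d[0], fish.y - d[1]), fish, params)
            assert plus == pytest.approx(-minus, rel=1e-12)

    def test_singularity_rejected(self, params, fish):
        with pytest.raises(SingularityError, match="0.3"):
            dipole_potential((fish.x, fish.y), fish, params)


class TestDipoleVelocity:
    def test_matches_finite_difference_gradient(self, params, fish, rng):
        step = 1e-6 * params.h
        for _ in range(20):
            pt = rng.uniform([-1.0, 0.05], [1.0, 0.95])
            if np.hypot(pt[0] - fish.x, pt[1] - fish.y) < 0.05:
                continue
            u = dipole_velocity(pt, fish, params)
            gx = (
                dipole_potential((pt[0] + step, pt[1]), fish, params)
                - dipole_potential((pt[0] - step, pt[1]), fish, params)
            ) / (2 * step)
            gy = (
                dipole_potential((pt[0], pt[1] + step), fish, params)
                - dipole_potential((pt[0], pt[1] - step), fish, params)
            ) / (2 * step)
            assert u.x == pytest.approx(gx, rel=1e-6, abs=1e-9)
            assert u.y == pytest.approx(gy, rel=1e-6, abs=1e-9)

    def test_far_field_decay_quadratic(self, params, fish):
        ray = np.array([math.cos(0.3), math.sin(0.3)])
        for d in (0.5, 1.0):
            near = dipole_velocity((fish.x + d * ray[0], fish.y + d * ray[1]), fish, params)
            far = dipole_velocity((fish.x + 2 * d * ray[0], fish.y + 2 * d * ray[1]), fish, params)
            assert far.norm <= near.norm / 4 * (1 + 1e-12)

    def test_divergence_free(self, params, fish):
        step = 1e-5
        for pt in [(0.8, 0.6), (-0.2, 0.2), (0.5, 0.9)]:
            dux = (
                dipole_velocity((pt[0] + step, pt[1]), fish, params).x
                - dipole_velocity((pt[0] - step, pt[1]), fish, params).x
            ) / (2 * step)
            duy = (
                dipole_velocity((pt[0], pt[1] + step), fish, params).y
                - dipole_velocity((pt[0], pt[1] - step), fish, params).y
            ) / (2 * step)
            assert abs(dux + duy) < 1e-6


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

class TestImageStates:
    def test_n0_positions(self, params, fish):
        h, yf = params.h, fish.y
        imgs = image_states(fish, params, 0)
        assert sorted(im.y for im in imgs) == pytest.approx(
            sorted([yf - 2 * h, -yf, yf + 2 * h, -yf + 2 * h])
        )
        assert all(im.x == fish.x for im in imgs)

    def test_headings(self, params, fish):
        below_plus, below_minus, above_plus, above_minus = image_states(fish, params, 3)
        assert below_plus.theta == pytest.approx(fish.theta)
        assert above_plus.theta == pytest.approx(fish.theta)
        assert below_minus.theta == pytest.approx(-fish.theta)
        assert above_minus.theta == pytest.approx(-fish.theta)

    @pytest.mark.parametrize("n", [0, 1, 2, 7])
    def test_no_image_inside_channel(self, params, fish, n):
        for im in image_states(fish, params, n):
            assert not (0.0 < im.y < params.h)

    def test_negative_n_rejected(self, params, fish):
        with pytest.raises(DomainError):
            image_states(fish, params, -1)


# ---------------------------------------------------------------------------
# wall velocity
# ---------------------------------------------------------------------------

class TestWallVelocity:
    def test_no_penetration_exact(self, params, fish):
        """Total normal velocity vanishes at both walls (defining property)."""
        for ywall in (0.0, params.h):
            for x in np.linspace(-2.0, 2.0, 50):
                uf = dipole_velocity((x, ywall), fish, params)
                uw = wall_velocity((x, ywall), fish, params)
                assert abs(uf.y + uw.y) < 1e-12 * params.v0

    def test_series_matches_exact_at_wall(self, params, fish):
        """200-term raw series satisfies no-penetration to its own tail level."""
        pol = TruncationPolicy(max_terms=200, tail_tol=None, richardson=0)
        for x in np.linspace(-1.0, 1.0, 10):
            uf = dipole_velocity((x, 0.0), fish, params)
            uw = wall_velocity_series((x, 0.0), fish, params, pol)
            assert abs(uf.y + uw.y) < 1e-6 * params.v0

    def test_series_converges_to_exact(self, params, fish):
        exact = wall_velocity((0.9, 0.8), fish, params)
        approx = wall_velocity_series((0.9, 0.8), fish, params, SERIES_ORACLE)
        assert math.hypot(approx.x - exact.x, approx.y - exact.y) < 5e-8 * params.v0

    def test_increments_cauchy_and_monotone(self, params, fish):
        """Partial sums are Cauchy; group increments shrink monotonically."""
        pol = lambda n: TruncationPolicy(max_terms=n, tail_tol=None)
        vals = [wall_velocity_series((0.9, 0.8), fish, params, pol(n)) for n in (50, 100, 200, 400)]
        gaps = [
            math.hypot(a.x - b.x, a.y - b.y) for a, b in zip(vals, vals[1:])
        ]
        assert gaps[0] > gaps[1] > gaps[2] > 0

    def test_tail_tolerance_enforced(self, params, fish):
        with pytest.raises(ConvergenceError) as exc:
            wall_velocity_series((0.9, 0.8), fish, params, TruncationPolicy(max_terms=200, tail_tol=1e-10))
        assert exc.value.last_increment is not None and exc.value.last_increment > 0

    def test_centerline_symmetry(self, params):
        fish = FishState(0.0, 0.5 * params.h, 0.0)
        u = wall_velocity((0.4, 0.5 * params.h), fish, params)
        assert u.y == pytest.approx(0.0, abs=1e-14)

    def test_image_singularity_guarded(self, params, fish):
        # nearest image of the fish across y=0 sits at (xf, -yf)
        with pytest.raises(SingularityError):
            wall_velocity((fish.x, -fish.y + 1e-8), fish, params)


# ---------------------------------------------------------------------------
# background flow and vorticity
# ---------------------------------------------------------------------------

class TestBackground:
    def test_centerline_speed(self, params):
        u = background_velocity((0.0, 0.5 * params.h), params)
        assert u == Vec2(params.U0, 0.0)

    @pytest.mark.parametrize("y", [0.0, 1.0])
    def test_wall_speed(self, params, y):
        u = background_velocity((3.0, y * params.h), params)
        assert u.x == pytest.approx(params.U0 * (1 - params.eps), rel=1e-14)
        assert u.y == 0.0

    def test_uniform_when_eps_zero(self):
        p = ModelParams(h=1.0, U0=0.7, eps=0.0, v0=1.0, r0=0.05, l=0.2)
        for y in (0.1, 0.33, 0.9):
            assert background_velocity((0.0, y), p).x == pytest.approx(0.7)


class TestVorticity:
    def test_zero_at_centerline(self, params):
        assert vorticity((0.0, 0.5 * params.h), params) == 0.0

    def test_value_at_wall(self, params):
        expected = 4.0 * params.U0 * params.eps / params.h
        assert vorticity((0.0, params.h), params) == pytest.approx(expected, rel=1e-14)

    def test_matches_curl_of_background(self, params):
        step = 1e-6
        for y in (0.2, 0.5, 0.77):
            dux_dy = (
                background_velocity((0.0, y + step), params).x
                - background_velocity((0.0, y - step), params).x
            ) / (2 * step)
            assert vorticity((0.0, y), params) == pytest.approx(-dux_dy, rel=1e-6)

    def test_dipole_plus_images_irrotational(self, params, fish):
        step = 1e-5

        def u(pt):
            a = dipole_velocity(pt, fish, params)
            b = wall_velocity(pt, fish, params)
            return np.array([a.x + b.x, a.y + b.y])

        for pt in [(0.8, 0.6), (-0.3, 0.2), (0.6, 0.85)]:
            curl = (
                (u((pt[0] + step, pt[1]))[1] - u((pt[0] - step, pt[1]))[1]) / (2 * step)
                - (u((pt[0], pt[1] + step))[0] - u((pt[0], pt[1] - step))[0]) / (2 * step)
            )
            assert abs(curl) < 1e-6


# ---------------------------------------------------------------------------
# total velocity
# ---------------------------------------------------------------------------

class TestTotalVelocity:
    def test_reduces_without_background(self, params_noflow, fish):
        tot = total_velocity((0.7, 0.6), fish, params_noflow)
        uf = dipole_velocity((0.7, 0.6), fish, params_noflow)
        uw = wall_velocity((0.7, 0.6), fish, params_noflow)
        assert tot.x == pytest.approx(uf.x + uw.x, rel=1e-14)
        assert tot.y == pytest.approx(uf.y + uw.y, rel=1e-14)

    def test_no_penetration_including_background(self, params, fish):
        for x in np.linspace(-1.5, 1.5, 25):
            for ywall in (0.0, params.h):
                assert abs(total_velocity((x, ywall), fish, params).y) < 1e-12 * params.v0

    def test_linear_in_v0(self, fish):
        p1 = ModelParams(h=1.0, U0=0.0, eps=0.0, v0=1.0, r0=0.1, l=0.25)
        p2 = ModelParams(h=1.0, U0=0.0, eps=0.0, v0=2.0, r0=0.1, l=0.25)
        u1 = total_velocity((0.7, 0.6), fish, p1)
        u2 = total_velocity((0.7, 0.6), fish, p2)
        assert u2.x == pytest.approx(2 * u1.x, rel=1e-14)
        assert u2.y == pytest.approx(2 * u1.y, rel=1e-14)


# ---------------------------------------------------------------------------
# circulation
# ---------------------------------------------------------------------------

def _quadrature_circulation(center, heading, width, length, params, order=8):
    """Independent oracle: Gauss-Legendre product quadrature of the vorticity
    over the rotated rectangle (exact for the linear-in-y integrand)."""
    nodes, weights = np.polynomial.legendre.leggauss(order)
    ch, sh = math.cos(heading), math.sin(heading)
    total = 0.0
    for si, wi in zip(nodes, weights):
        for sj, wj in zip(nodes, weights):
            dx = 0.5 * length * si * ch - 0.5 * width * sj * sh
            dy = 0.5 * length * si * sh + 0.5 * width * sj * ch
            total += wi * wj * vorticity((center[0] + dx, center[1] + dy), params)
    return total * (0.25 * width * length)


class TestCirculationRectangle:
    def test_zero_without_shear(self, params_noflow):
        assert circulation_rectangle((0.0, 0.5), 0.3, 0.1, 0.25, params_noflow) == 0.0

    def test_zero_at_centerline(self, params):
        assert circulation_rectangle((0.0, 0.5 * params.h), 0.9, 0.1, 0.25, params) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_matches_quadrature(self, params, rng):
        for _ in range(10):
            y = rng.uniform(0.25, 0.75)
            th = rng.uniform(-math.pi, math.pi)
            gamma = circulation_rectangle((0.0, y), th, params.r0, params.l, params)
            oracle = _quadrature_circulation((0.0, y), th, params.r0, params.l, params)
            assert gamma == pytest.approx(oracle, rel=1e-12, abs=1e-15)

    def test_feedback_consistency(self, params):
        """K * Gamma at the fish equals the closed-form lateral-line feedback."""
        fish = FishState(0.2, 0.61, 1.1)
        gamma = circulation_rectangle((fish.x, fish.y), fish.theta, params.r0, params.l, params)
        assert params.K * gamma == pytest.approx(
            lateral_line_feedback(fish, params), rel=1e-12
        )

    def test_outside_channel_rejected(self, params):
        with pytest.raises(DomainError):
            circulation_rectangle((0.0, 0.02), 0.0, 0.1, 0.25, params)


# ---------------------------------------------------------------------------
# params and export
# ---------------------------------------------------------------------------

class TestModelParams:
    def test_derived_groups(self, params):
        assert params.rho == pytest.approx(0.1)
        assert params.alpha == pytest.approx(0.1)
        assert params.kappa == pytest.approx(0.05)
        assert params.beta == pytest.approx(params.alpha * (1 + params.kappa) / params.rho**2)

    def test_rho_limit_enforced(self):
        with pytest.raises(DomainError, match="rho"):
            ModelParams(h=1.0, U0=0.0, eps=0.0, v0=1.0, r0=0.6, l=0.2)

    def test_rho_warning_band(self):
        with pytest.warns(UserWarning, match="far-field"):
            ModelParams(h=1.0, U0=0.0, eps=0.0, v0=1.0, r0=0.3, l=0.2)

    @pytest.mark.parametrize("bad", [dict(h=-1.0), dict(v0=0.0), dict(eps=-0.1), dict(K=-1.0)])
    def test_invalid_params(self, bad):
        kw = dict(h=1.0, U0=0.5, eps=0.2, v0=1.0, r0=0.05, l=0.25, K=0.0)
        kw.update(bad)
        with pytest.raises(DomainError):
            ModelParams(**kw)


class TestFieldGrid:
    def test_columns_and_exclusion(self, params, fish):
        df = field_grid(fish, params, np.linspace(-0.5, 0.5, 11), np.linspace(0.1, 0.9, 9))
        assert list(df.columns) == ["x", "y", "ux", "uy", "vorticity"]
        dist = np.hypot(df.x - fish.x, df.y - fish.y)
        assert (dist > params.r0).all()
        assert np.isfinite(df.to_numpy()).all()
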