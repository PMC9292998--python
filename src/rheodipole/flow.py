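"""Potential-flow field of a vortex-dipole swimmer in an infinite 2-D channel.

The swimmer is a point dipole (far-field limit of a pair of counter-rotating
vortices a distance ``r0`` apart, each of circulation ``2*pi*r0*v0``).  Channel
walls at ``y = 0`` and ``y = h`` are enforced by the classical method of
images, which generates a doubly infinite ladder of image dipoles.  A weakly
rotational background flow is superposed on top of the irrotational
dipole-plus-images field.

Two evaluation routes are provided for the wall-induced velocity:

* an exact analytic resummation of the image ladder in terms of ``csch**2``
  (the default), which satisfies no-penetration to machine precision, and
* the explicitly truncated image series (:func:`wall_velocity_series`),
  governed by a :class:`TruncationPolicy`, kept as an independent oracle.

All velocities are returned as :class:`Vec2`; positions may be passed as
``Vec2`` or any ``(x, y)`` pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConvergenceError, DomainError, SingularityError

__all__ = [
    "Vec2",
    "FishState",
    "ModelParams",
    "TruncationPolicy",
    "dipole_potential",
    "dipole_velocity",
    "image_states",
    "wall_velocity",
    "wall_velocity_series",
    "background_velocity",
    "vorticity",
    "total_velocity",
    "circulation_rectangle",
    "field_grid",
]

#: Relative guard radius: evaluation closer than ``SINGULARITY_GUARD * h`` to a
#: vortex singularity is rejected rather than regularized.
SINGULARITY_GUARD = 1e-6


class Vec2(NamedTuple):
    """A 2-D vector with streamwise (``x``) and cross-stream (``y``) components."""

    x: float
    y: float

    @property
    def norm(self) -> float:
        return math.hypot(self.x, self.y)


def _wrap_angle(theta: float) -> float:
    """Wrap an angle to the half-open interval (-pi, pi]."""
    w = -((-theta + math.pi) % (2.0 * math.pi) - math.pi)
    return w


@dataclass(frozen=True)
class FishState:
    """Dimensional pose of the swimmer.

    Attributes
    ----------
    x, y
        Position in channel coordinates; walls at ``y = 0`` and ``y = h``.
    theta
        Heading measured counter-clockwise from +x, wrapped to (-pi, pi].
    """

    x: float
    y: float
    theta: float

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.theta)):
            raise DomainError(f"non-finite fish state {(self.x, self.y, self.theta)}")
        object.__setattr__(self, "theta", _wrap_angle(self.theta))

    @property
    def position(self) -> Vec2:
        return Vec2(self.x, self.y)

    @property
    def heading_vector(self) -> Vec2:
        return Vec2(math.cos(self.theta), math.sin(self.theta))


@dataclass(frozen=True)
class ModelParams:
    """Dimensional model constants and their derived nondimensional groups.

    Parameters
    ----------
    h : channel width.
    U0 : background speed at the channel centerline.
    eps : shear parameter of the background profile (0 = uniform flow).
    v0 : self-propulsion speed of the swimmer.
    r0 : dipole length scale (order of the tail-beat amplitude).
    l : body length, used by the circulation-sensing rectangle.
    K : lateral-line feedback gain (units chosen so ``K*r0*l`` is dimensionless
        after multiplying the circulation per unit area).
    """

    h: float
    U0: float
    eps: float
    v0: float
    r0: float
    l: float
    K: float = 0.0

    def __post_init__(self):
        for name in ("h", "v0", "r0", "l"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")
        if self.U0 < 0:
            raise DomainError(f"U0 must be nonnegative, got {self.U0}")
        if self.eps < 0:
            raise DomainError(f"eps must be nonnegative, got {self.eps}")
        if self.K < 0:
            raise DomainError(f"K must be nonnegative, got {self.K}")
        rho = self.r0 / self.h
        if rho >= 0.5:
            raise DomainError(
                f"rho = r0/h = {rho:.3g} violates the far-field assumption (rho << 1); "
                "require rho < 0.5"
            )
        if rho > 0.2:
            warnings.warn(
                f"rho = r0/h = {rho:.3g} > 0.2: far-field dipole model is questionable",
                stacklevel=2,
            )

    @property
    def rho(self) -> float:
        return self.r0 / self.h

    @property
    def alpha(self) -> float:
        return self.U0 * self.eps / self.v0

    @property
    def kappa(self) -> float:
        return self.K * self.r0 * self.l

    @property
    def beta(self) -> float:
        return self.alpha * (1.0 + self.kappa) / self.rho**2

    def nondim(self):
        """Return the associated :class:`~rheodipole.planar.NondimParams`."""
        from .planar import NondimParams

        return NondimParams(rho=self.rho, alpha=self.alpha, kappa=self.kappa)


@dataclass(frozen=True)
class TruncationPolicy:
    """Controls the explicitly truncated image series.

    ``max_terms`` image sets (four dipoles each) are summed.  Partial sums may
    be Richardson-extrapolated (``richardson`` levels) to accelerate the
    slowly decaying tail.  If ``tail_tol`` is not ``None``, the estimated
    remaining tail must fall below ``tail_tol * v0`` or a
    :class:`ConvergenceError` is raised.
    """

    max_terms: int = 200
    tail_tol: float | None = 1e-10
    richardson: int = 0

    def __post_init__(self):
        if self.max_terms < 4:
            raise DomainError(f"max_terms must be >= 4, got {self.max_terms}")
        if self.richardson not in (0, 1, 2):
            raise DomainError("richardson level must be 0, 1 or 2")


def _as_complex(p) -> complex:
    if isinstance(p, complex):
        return p
    x, y = p
    return complex(x, y)


def _guard(at: complex, sing: complex, h: float, what: str) -> None:
    if abs(at - sing) < SINGULARITY_GUARD * h:
        raise SingularityError(
            f"evaluation point ({at.real:.6g}, {at.imag:.6g}) is within "
            f"{SINGULARITY_GUARD:g}*h of the {what} singularity at "
            f"({sing.real:.6g}, {sing.imag:.6g})"
        )


# ---------------------------------------------------------------------------
# Free-space dipole
# ---------------------------------------------------------------------------

def _dipole_w(at: complex, pos: complex, theta: float, r0: float, v0: float) -> complex:
    """Complex velocity ``u + i v`` of a point dipole of scale r0, speed v0."""
    return np.conj(r0 * r0 * v0 * np.exp(1j * theta) / (at - pos) ** 2)


def dipole_potential(at, fish: FishState, params: ModelParams) -> float:
    """Scalar velocity potential of the swimmer's dipole at ``at``.

    ``phi = -r0^2 (d . v_f) / |d|^2`` with ``d = at - r_f`` and
    ``v_f = v0 (cos theta, sin theta)``.
    """
    z = _as_complex(at)
    zf = complex(fish.x, fish.y)
    _guard(z, zf, params.h, "fish dipole")
    d = z - zf
    vf = params.v0 * np.exp(1j * fish.theta)
    return float(-params.r0**2 * (d.real * vf.real + d.imag * vf.imag) / abs(d) ** 2)


def dipole_velocity(at, fish: FishState, params: ModelParams) -> Vec2:
    """Analytic gradient of :func:`dipole_potential` (the dipole's velocity field)."""
    z = _as_complex(at)
    zf = complex(fish.x, fish.y)
    _guard(z, zf, params.h, "fish dipole")
    w = _dipole_w(z, zf, fish.theta, params.r0, params.v0)
    return Vec2(float(w.real), float(w.imag))


# ---------------------------------------------------------------------------
# Wall images
# ---------------------------------------------------------------------------

def image_states(fish: FishState, params: ModelParams, n: int) -> tuple[FishState, FishState, FishState, FishState]:
    """The n-th set of four image dipoles (n >= 0).

    Returned in the order: below-wall same-orientation, below-wall mirrored,
    above-wall same-orientation, above-wall mirrored.  Mirrored ("-") images
    carry heading ``-theta``; same-orientation ("+") images carry ``+theta``.
    """
    if n < 0 or int(n) != n:
        raise DomainError(f"image-set index must be a nonnegative integer, got {n!r}")
    h = params.h
    xf, yf, th = fish.x, fish.y, fish.theta
    return (
        FishState(xf, yf - 2 * (n + 1) * h, th),
        FishState(xf, -yf - 2 * n * h, -th),
        FishState(xf, yf + 2 * (n + 1) * h, th),
        FishState(xf, -yf + 2 * (n + 1) * h, -th),
    )


def _nearest_image_distance(z: complex, zf: complex, h: float) -> float:
    """Distance from ``z`` to the nearest singularity of the wall (image) field.

    Image singularities sit on the two vertical ladders
    ``x_f + i (y_f + 2 m h)`` (m != 0) and ``x_f + i (-y_f + 2 m h)`` (all m).
    """
    dx = z.real - zf.real
    dy_plus = (z.imag - zf.imag + h) % (2.0 * h) - h  # residue for the +theta ladder
    dy_minus = (z.imag + zf.imag + h) % (2.0 * h) - h  # residue for the -theta ladder
    d_minus = math.hypot(dx, dy_minus)
    # the m = 0 member of the + ladder is the fish itself, not an image: if the
    # nearest + ladder point is the fish, the next one is 2h away in y.
    near_y = z.imag - dy_plus  # y of nearest + ladder point
    if abs(near_y - zf.imag) < h:  # it is the fish; exclude it
        d_plus = math.hypot(dx, 2.0 * h - abs(dy_plus))
    else:
        d_plus = math.hypot(dx, dy_plus)
    return min(d_plus, d_minus)


def _csch2_minus_inv2(x: complex) -> complex:
    """``csch(x)**2 - 1/x**2``, stable near x = 0 (removable singularity -> -1/3)."""
    if abs(x) < 1e-4:
        x2 = x * x
        return -1.0 / 3.0 + x2 / 15.0 - 2.0 * x2 * x2 / 189.0
    return 1.0 / np.sinh(x) ** 2 - 1.0 / (x * x)


def _wall_w_closed(z: complex, zf: complex, theta: float, h: float, r0: float, v0: float) -> complex:
    """Exact resummation of the image-ladder velocity (``u + i v``).

    Summing the dipole ladders with the lattice identity
    ``sum_m 1/(zeta - 2 i h m)^2 = (pi/2h)^2 csch^2(pi zeta / 2h)`` gives the
    combined fish-plus-images field; the swimmer's own free-space dipole is
    subtracted analytically (folded into ``csch^2(x) - 1/x^2``) so the result
    is regular at the fish location.
    """
    k = math.pi / (2.0 * h)
    with np.errstate(over="ignore", invalid="ignore"):
        term_plus = np.exp(1j * theta) * _csch2_minus_inv2(k * (z - zf))
        s_minus = np.sinh(k * (z - np.conj(zf)))
        term_minus = np.exp(-1j * theta) / (s_minus * s_minus)
    return np.conj(r0 * r0 * v0 * k * k * (term_plus + term_minus))


def wall_velocity(at, fish: FishState, params: ModelParams, trunc: TruncationPolicy | None = None) -> Vec2:
    """Velocity induced at ``at`` by the doubly infinite ladder of wall images.

    With ``trunc=None`` (default) the exact analytic resummation of the image
    series is used; otherwise the series is summed per the policy (see
    :func:`wall_velocity_series`).
    """
    if trunc is not None:
        return wall_velocity_series(at, fish, params, trunc)
    z = _as_complex(at)
    zf = complex(fish.x, fish.y)
    d = _nearest_image_distance(z, zf, params.h)
    if d < SINGULARITY_GUARD * params.h:
        raise SingularityError(
            f"evaluation point ({z.real:.6g}, {z.imag:.6g}) is within "
            f"{SINGULARITY_GUARD:g}*h of an image singularity"
        )
    w = _wall_w_closed(z, zf, fish.theta, params.h, params.r0, params.v0)
    return Vec2(float(w.real), float(w.imag))


def wall_velocity_series(at, fish: FishState, params: ModelParams, trunc: TruncationPolicy | None = None) -> Vec2:
    """Truncated image-series evaluation of the wall-induced velocity.

    Image sets are summed in order of the set index ``n``; group increments
    decay like ``1/n^2`` so the raw tail is ``O(1/max_terms)``.  Richardson
    extrapolation of the partial sums at ``max_terms``, ``max_terms/2`` and
    ``max_terms/4`` (levels 1-2) removes the leading tail terms.
    """
    trunc = trunc or TruncationPolicy()
    z = _as_complex(at)
    zf = complex(fish.x, fish.y)
    d = _nearest_image_distance(z, zf, params.h)
    if d < SINGULARITY_GUARD * params.h:
        raise SingularityError(
            f"evaluation point ({z.real:.6g}, {z.imag:.6g}) is within "
            f"{SINGULARITY_GUARD:g}*h of an image singularity"
        )
    h, r0, v0 = params.h, params.r0, params.v0
    xf, yf, th = fish.x, fish.y, fish.theta
    N = trunc.max_terms
    n = np.arange(N)
    c = r0 * r0 * v0
    ladders = (
        (yf - 2 * (n + 1) * h, th),
        (-yf - 2 * n * h, -th),
        (yf + 2 * (n + 1) * h, th),
        (-yf + 2 * (n + 1) * h, -th),
    )
    inc = np.zeros(N, dtype=complex)
    for ys, ang in ladders:
        inc += np.conj(c * np.exp(1j * ang) / (z - (xf + 1j * ys)) ** 2)
    partial = np.cumsum(inc)

    def value_at(m: int) -> complex:
        return partial[m - 1]

    if trunc.richardson == 0:
        total = value_at(N)
        tail_est = abs(inc[-1]) * N  # tail of a 1/n^2 series ~ n * last increment
    else:
        s1, s2, s4 = value_at(N // 4), value_at(N // 2), value_at(N)
        r_lo = 2.0 * s2 - s1
        r_hi = 2.0 * s4 - s2
        if trunc.richardson == 1:
            total = r_hi
            tail_est = abs(r_hi - r_lo)
        else:
            total = 2.0 * r_hi - r_lo
            tail_est = abs(r_hi - r_lo) / 2.0
    if trunc.tail_tol is not None and tail_est > trunc.tail_tol * v0:
        raise ConvergenceError(
            f"image series not converged after {N} image sets: estimated tail "
            f"{tail_est:.3e} exceeds {trunc.tail_tol:g}*v0 = {trunc.tail_tol * v0:.3e}",
            last_increment=float(abs(inc[-1])),
        )
    return Vec2(float(total.real), float(total.imag))


# ---------------------------------------------------------------------------
# Background flow and vorticity
# ---------------------------------------------------------------------------

def background_velocity(at, params: ModelParams) -> Vec2:
    """Weakly rotational background profile ``U0 (1 - 4 eps (y/h - 1/2)^2) i``."""
    z = _as_complex(at)
    xi = z.imag / params.h - 0.5
    return Vec2(params.U0 * (1.0 - 4.0 * params.eps * xi * xi), 0.0)


def vorticity(at, params: ModelParams) -> float:
    """Local vorticity ``8 U0 eps / h * (y/h - 1/2)``.

    Only the background profile is rotational; the dipole and its images are
    potential flow and contribute nothing.
    """
    z = _as_complex(at)
    return 8.0 * params.U0 * params.eps / params.h * (z.imag / params.h - 0.5)


def total_velocity(at, fish: FishState, params: ModelParams, trunc: TruncationPolicy | None = None) -> Vec2:
    """Superposition of dipole, wall-image and background velocities."""
    uf = dipole_velocity(at, fish, params)
    uw = wall_velocity(at, fish, params, trunc)
    ub = background_velocity(at, params)
    return Vec2(uf.x + uw.x + ub.x, uf.y + uw.y + ub.y)


# ---------------------------------------------------------------------------
# Circulation
# ---------------------------------------------------------------------------

def circulation_rectangle(center, heading: float, width: float, length: float, params: ModelParams) -> float:
    """Circulation (area integral of vorticity) over an oriented rectangle.

    The rectangle has extent ``length`` along ``heading`` and ``width`` across
    it.  The vorticity profile is linear in y, so the integral is exactly
    ``area * vorticity(centroid)``.
    """
    if width <= 0 or length <= 0:
        raise DomainError(f"rectangle dimensions must be positive, got {width} x {length}")
    z = _as_complex(center)
    ch, sh = math.cos(heading), math.sin(heading)
    half_l, half_w = 0.5 * length, 0.5 * width
    corners_y = [
        z.imag + sy * half_l * sh + sx * half_w * ch
        for sy in (-1, 1)
        for sx in (-1, 1)
    ]
    if min(corners_y) < 0.0 or max(corners_y) > params.h:
        raise DomainError(
            f"rectangle (center y={z.imag:.4g}, heading={heading:.4g}) extends outside "
            f"the channel 0 <= y <= {params.h}"
        )
    return width * length * vorticity(z, params)


# ---------------------------------------------------------------------------
# Field export
# ---------------------------------------------------------------------------

def field_grid(
    fish: FishState,
    params: ModelParams,
    x: Iterable[float],
    y: Iterable[float],
    trunc: TruncationPolicy | None = None,
    exclude_radius: float | None = None,
) -> pd.DataFrame:
    """Evaluate the total velocity and vorticity on a rectangular grid.

    Grid points inside a disk of radius ``exclude_radius`` (default ``r0``)
    around the swimmer are dropped: the far-field dipole model is not valid
    inside the dipole scale.
    """
    if exclude_radius is None:
        exclude_radius = params.r0
    xs, ys = np.meshgrid(np.asarray(list(x), float), np.asarray(list(y), float))
    rows = []
    for xv, yv in zip(xs.ravel(), ys.ravel()):
        if math.hypot(xv - fish.x, yv - fish.y) <= exclude_radius:
            continue
        u = total_velocity((xv, yv), fish, params, trunc)
        rows.append((xv, yv, u.x, u.y, vorticity((xv, yv), params)))
    return pd.DataFrame(rows, columns=["x", "y", "ux", "uy", "vorticity"])
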