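"""Dimensional equations of motion of the dipole swimmer.

The swimmer responds instantaneously (no inertia) to the flow it induces:

* translation: self-propulsion plus the advective velocity, i.e. the
  wall-image and background fields evaluated at the swimmer's own location
  (the swimmer's free-space dipole is removed — de-singularized);
* rotation: the hydrodynamic turn rate from the transverse velocity
  difference across the vortex pair, plus a linear lateral-line feedback
  proportional to the circulation sensed over a body-sized rectangle.

Closed forms are used for the ODE right-hand side; the truncated image
series and a finite-separation vortex pair serve as independent oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, RheodipoleError, SingularityError
from .flow import (
    FishState,
    ModelParams,
    TruncationPolicy,
    Vec2,
    _wrap_angle,
    background_velocity,
    wall_velocity,
)

__all__ = [
    "SolverPolicy",
    "Trajectory",
    "advective_velocity",
    "turn_rate",
    "turn_rate_finite_dipole",
    "lateral_line_feedback",
    "simulate",
]


@dataclass(frozen=True)
class SolverPolicy:
    """Integration settings for :func:`simulate`.

    The planar reduction has a neutral center, so default tolerances are tight
    to limit spurious drift of the conserved orbits.  ``wall_margin`` is the
    fraction of the channel width at which integration stops (the model is
    singular at the walls and does not describe contact).
    """

    method: str = "RK45"
    rtol: float = 1e-8
    atol: float = 1e-10
    wall_margin: float = 0.01
    max_step: float = math.inf

    def __post_init__(self):
        if not (0.0 < self.wall_margin < 0.5):
            raise DomainError(f"wall_margin must be in (0, 0.5), got {self.wall_margin}")


@dataclass(frozen=True)
class Trajectory:
    """Time series of swimmer states.

    ``theta`` is stored unwrapped (continuous); :attr:`states` wraps it for
    reporting.  ``termination`` is ``"horizon"`` or ``"wall_event"``; in the
    latter case ``event_time`` holds the stopping time.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    termination: str
    event_time: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("trajectory times must be strictly increasing")

    @property
    def states(self) -> list[FishState]:
        return [FishState(x, y, th) for x, y, th in zip(self.x, self.y, self.theta)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.times,
                "x": self.x,
                "y": self.y,
                "theta": self.theta,
                "theta_wrapped": [_wrap_angle(t) for t in self.theta],
            }
        )


def _check_interior(y: float, h: float) -> None:
    if not (0.0 < y < h):
        raise SingularityError(
            f"fish cross-stream position y={y:.6g} is not strictly inside the channel (0, {h})"
        )


def advective_velocity(fish: FishState, params: ModelParams) -> Vec2:
    """De-singularized fluid velocity at the swimmer (walls + background).

    Closed form::

        -(pi^2 v0 rho^2 / 12) [(1 + 3 csc^2(pi y/h)) cos th,
                               -(1 - 3 csc^2(pi y/h)) sin th]
        + [U0 (1 - 4 eps (y/h - 1/2)^2), 0]
    """
    _check_interior(fish.y, params.h)
    c = math.pi * fish.y / params.h
    csc2 = 1.0 / math.sin(c) ** 2
    pref = -(math.pi**2) * params.v0 * params.rho**2 / 12.0
    ux = pref * (1.0 + 3.0 * csc2) * math.cos(fish.theta)
    uy = -pref * (1.0 - 3.0 * csc2) * math.sin(fish.theta)
    ub = background_velocity((fish.x, fish.y), params)
    return Vec2(ux + ub.x, uy + ub.y)


def turn_rate(fish: FishState, params: ModelParams) -> float:
    """Hydrodynamic turn rate (small-separation closed form).

    Wall term ``-(pi^3 rho^2 v0 / 4h) cot(pi y/h) csc^2(pi y/h) cos th`` plus
    the shear term ``(8 U0 eps / h)(y/h - 1/2) cos^2 th``.
    """
    _check_interior(fish.y, params.h)
    c = math.pi * fish.y / params.h
    csc2 = 1.0 / math.sin(c) ** 2
    wall = (
        -(math.pi**3)
        * params.rho**2
        * params.v0
        / (4.0 * params.h)
        * (math.cos(c) / math.sin(c))
        * csc2
        * math.cos(fish.theta)
    )
    shear = (
        8.0 * params.U0 * params.eps / params.h
        * (fish.y / params.h - 0.5)
        * math.cos(fish.theta) ** 2
    )
    return wall + shear


def turn_rate_finite_dipole(
    fish: FishState,
    params: ModelParams,
    trunc: TruncationPolicy | None = None,
    separation: float | None = None,
) -> float:
    """Turn rate of a finite vortex pair: transverse velocity difference.

    The left/right vortices sit at ``r_f +/- (sep/2) v_perp`` with
    ``v_perp = (-sin th, cos th)``; the rate is
    ``((U(right) - U(left)) / sep) . v_hat`` with U the wall-image plus
    background field.  Converges to :func:`turn_rate` as ``sep -> 0`` with
    an O(sep^2) error, which makes it the finite-separation oracle.
    """
    if separation is None:
        separation = params.r0
    if separation <= 0:
        raise DomainError(f"vortex separation must be positive, got {separation}")
    ch, sh = math.cos(fish.theta), math.sin(fish.theta)
    px, py = -sh, ch  # v_perp
    half = 0.5 * separation
    left = (fish.x + half * px, fish.y + half * py)
    right = (fish.x - half * px, fish.y - half * py)
    for name, (_, yv) in (("left", left), ("right", right)):
        if not (0.0 < yv < params.h):
            raise DomainError(
                f"{name} vortex at y={yv:.6g} lies outside the channel (0, {params.h})"
            )

    def field(p) -> np.ndarray:
        uw = wall_velocity(p, fish, params, trunc)
        ub = background_velocity(p, params)
        return np.array([uw.x + ub.x, uw.y + ub.y])

    diff = (field(right) - field(left)) / separation
    return float(diff @ np.array([ch, sh]))


def lateral_line_feedback(fish: FishState, params: ModelParams) -> float:
    """Linear circulation feedback ``K * Gamma`` over the body rectangle.

    Closed form ``K r0 l * (8 U0 eps / h)(y/h - 1/2)`` — the gain times the
    circulation of the linearized vorticity over a rectangle of width ``r0``
    along the body length ``l``.
    """
    return (
        params.K
        * params.r0
        * params.l
        * 8.0 * params.U0 * params.eps / params.h
        * (fish.y / params.h - 0.5)
    )


def simulate(
    initial: FishState,
    params: ModelParams,
    horizon: float,
    solver: SolverPolicy | None = None,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the swimmer ODE from ``initial`` up to ``horizon``.

    Integration terminates early (``termination="wall_event"``) when the
    swimmer enters the wall-proximity band ``y/h < margin`` or
    ``y/h > 1 - margin``.  The streamwise coordinate decouples from the
    cross-stream/heading dynamics but is carried and reported.
    """
    solver = solver or SolverPolicy()
    _check_interior(initial.y, params.h)
    if horizon <= 0:
        raise DomainError(f"horizon must be positive, got {horizon}")

    def rhs(t, q):
        x, y, th = q
        fish = FishState(x, y, th)
        adv = advective_velocity(fish, params)
        return [
            adv.x + params.v0 * math.cos(th),
            adv.y + params.v0 * math.sin(th),
            turn_rate(fish, params) + lateral_line_feedback(fish, params),
        ]

    lo = solver.wall_margin * params.h
    hi = (1.0 - solver.wall_margin) * params.h

    def hit_low(t, q):
        return q[1] - lo

    def hit_high(t, q):
        return q[1] - hi

    hit_low.terminal = True
    hit_high.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [initial.x, initial.y, initial.theta],
        method=solver.method,
        rtol=solver.rtol,
        atol=solver.atol,
        max_step=solver.max_step,
        t_eval=t_eval,
        events=[hit_low, hit_high],
    )
    if not sol.success:
        raise RheodipoleError(
            f"integration failed: {sol.message}; last state t={sol.t[-1]:.6g}, "
            f"q={sol.y[:, -1].tolist()}"
        )
    wall_event = sol.status == 1
    event_time = None
    if wall_event:
        hits = [te[0] for te in sol.t_events if len(te)]
        event_time = float(min(hits))
    return Trajectory(
        times=sol.t,
        x=sol.y[0],
        y=sol.y[1],
        theta=sol.y[2],
        termination="wall_event" if wall_event else "horizon",
        event_time=event_time,
    )
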