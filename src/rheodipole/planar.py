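"""Reduced planar dynamics for cross-stream position and heading.

With ``xi = y/h - 1/2`` and time scaled by ``h/v0``, the swimmer obeys::

    xi'     = [1 - (pi^2 rho^2 / 12)(3 csc^2(pi(xi+1/2)) - 1)] sin th
    theta'  = -(pi^3 rho^2 / 4) cot(pi(xi+1/2)) csc^2(pi(xi+1/2)) cos th
              + 8 alpha xi (cos^2 th + kappa)

Up/downstream headings (theta = pi, 0) are invariant; their cross-stream
equilibria are roots of a transcendental equation whose slope at the origin
fixes the critical bifurcation value ``beta* = pi^4/32`` of
``beta = alpha (1 + kappa) / rho^2``.  All equilibria have a trace-free
linearization, so each is either a saddle (det < 0) or a neutral center
(det > 0); the neutral center at (pi, 0), present for beta > beta*, is
surrounded by the periodic cross-stream sweeping orbits whose small-amplitude
radian frequency is ``sqrt(det A) ~ (pi^2/2) rho sqrt(beta/beta* - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .errors import ContractError, DomainError, RheodipoleError

__all__ = [
    "PlanarState",
    "NondimParams",
    "Equilibrium",
    "BETA_STAR",
    "beta_star",
    "rhs",
    "equilibrium_curve",
    "find_equilibria",
    "linearize",
    "classify",
    "sweeping_frequency",
    "bifurcation_sweep",
    "phase_portrait",
    "transcendental_curves",
    "integrate_planar",
    "measure_period",
]

#: Critical bifurcation value pi^4/32 (~ 3.0440).
BETA_STAR = math.pi**4 / 32.0

#: |det A| below this is reported as degenerate (beta ~ beta*) rather than classified.
DEGENERATE_TOL = 1e-10


def beta_star() -> float:
    """The critical value pi^4/32 of the bifurcation parameter (closed form)."""
    return BETA_STAR


class PlanarState(NamedTuple):
    """Nondimensional state: cross-stream coordinate ``xi = y/h - 1/2`` and heading."""

    xi: float
    theta: float


@dataclass(frozen=True)
class NondimParams:
    """The nondimensional triple (rho, alpha, kappa).

    rho = r0/h (size ratio), alpha = U0*eps/v0 (shear-to-swim speed),
    kappa = K*r0*l (lateral-line gain).
    """

    rho: float
    alpha: float
    kappa: float = 0.0

    def __post_init__(self):
        if self.rho <= 0:
            raise DomainError(
                f"rho must be positive, got {self.rho}; note beta -> infinity as rho -> 0"
            )
        if self.alpha < 0:
            raise DomainError(f"alpha must be nonnegative, got {self.alpha}")
        if self.kappa < 0:
            raise DomainError(f"kappa must be nonnegative, got {self.kappa}")

    @property
    def beta(self) -> float:
        return self.alpha * (1.0 + self.kappa) / self.rho**2

    def with_beta(self, beta: float) -> "NondimParams":
        """Same rho and kappa, with alpha chosen so the combined parameter equals ``beta``."""
        if beta < 0:
            raise DomainError(f"beta must be nonnegative, got {beta}")
        return NondimParams(self.rho, beta * self.rho**2 / (1.0 + self.kappa), self.kappa)


def _check_xi(xi: float) -> None:
    if not -0.5 < xi < 0.5:
        raise DomainError(f"xi={xi:.6g} outside the open channel (-1/2, 1/2)")


def rhs(state: PlanarState, params: NondimParams) -> tuple[float, float]:
    """Right-hand side (xi', theta') of the planar system."""
    xi, th = state
    _check_xi(xi)
    # csc^2(pi(xi+1/2)) = sec^2(pi xi); cot(pi(xi+1/2)) = -tan(pi xi)
    sec2 = 1.0 / math.cos(math.pi * xi) ** 2
    rho2 = params.rho**2
    dxi = (1.0 - math.pi**2 * rho2 / 12.0 * (3.0 * sec2 - 1.0)) * math.sin(th)
    dth = (
        math.pi**3 * rho2 / 4.0 * math.tan(math.pi * xi) * sec2 * math.cos(th)
        + 8.0 * params.alpha * xi * (math.cos(th) ** 2 + params.kappa)
    )
    return dxi, dth


def equilibrium_curve(xi):
    """The odd transcendental curve ``(pi^3/32) cot(pi(xi+1/2)) csc^2(pi(xi+1/2))``.

    Cross-stream equilibria for heading 0 (downstream) / pi (upstream) solve
    ``curve(xi) = +beta xi`` / ``curve(xi) = -beta xi``.  Vectorized over xi.
    """
    xi = np.asarray(xi, float)
    return -(math.pi**3 / 32.0) * np.tan(math.pi * xi) / np.cos(math.pi * xi) ** 2


@dataclass(frozen=True)
class Equilibrium:
    """An equilibrium of the planar system with its linearization."""

    theta: float
    xi: float
    state_matrix: np.ndarray
    classification: str = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "classification", classify(self.state_matrix))

    @property
    def trace(self) -> float:
        return float(np.trace(self.state_matrix))

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.state_matrix))

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.state_matrix)


def linearize(eq_theta: float, eq_xi: float, params: NondimParams) -> np.ndarray:
    """State matrix A of the linearized dynamics about an equilibrium.

    Valid for equilibria with heading 0 or pi (sin theta = 0), where both
    diagonal entries vanish identically::

        A = [[0,            cos th (1 - (pi^2 rho^2/12)(3 sec^2(pi xi) - 1))],
             [dG/dxi,       0]]
        dG/dxi = cos th (pi^4 rho^2/4)(2 - cos 2 pi xi) sec^4(pi xi)
                 + 8 alpha (cos^2 th + kappa)

    which reproduces the printed centerline and off-center matrices.
    """
    f = rhs(PlanarState(eq_xi, eq_theta), params)
    ct = math.cos(eq_theta)
    rho2 = params.rho**2
    sec2 = 1.0 / math.cos(math.pi * eq_xi) ** 2
    a01 = ct * (1.0 - math.pi**2 * rho2 / 12.0 * (3.0 * sec2 - 1.0))
    a10 = (
        ct * math.pi**4 * rho2 / 4.0 * (2.0 - math.cos(2.0 * math.pi * eq_xi)) * sec2 * sec2
        + 8.0 * params.alpha * (ct * ct + params.kappa)
    )
    # equilibrium contract, with tolerance scaled by the local gradient (near
    # the walls the theta-derivative is O(beta), so a root located to machine
    # xi-precision still carries an O(beta * eps_xi) residual)
    if abs(f[0]) > 1e-8 * max(1.0, abs(a01)) or abs(f[1]) > 1e-8 * max(1.0, abs(a10)):
        raise ContractError(
            f"(theta={eq_theta:.6g}, xi={eq_xi:.6g}) is not an equilibrium: "
            f"rhs = ({f[0]:.3e}, {f[1]:.3e})"
        )
    return np.array([[0.0, a01], [a10, 0.0]])


def classify(A: np.ndarray, tol: float = DEGENERATE_TOL) -> str:
    """Classify a trace-free 2x2 state matrix by the sign of its determinant."""
    A = np.asarray(A, float)
    tr = float(np.trace(A))
    if abs(tr) > 1e-9:
        raise ContractError(f"state matrix has nonzero trace {tr:.3e}; model guarantees tr A = 0")
    det = float(A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0])
    if det < -tol:
        return "saddle"
    if det > tol:
        return "neutral_center"
    return "degenerate"


def find_equilibria(
    params: NondimParams,
    grid_points: int = 10_000,
    xtol: float = 1e-14,
) -> list[Equilibrium]:
    """All equilibria of the planar system, with linearization and class.

    Downstream (theta=0) always has the single centerline equilibrium xi=0
    (a saddle).  Upstream (theta=pi) has xi=0 and, iff beta > beta*, a
    symmetric off-center pair +/-xi* found by bracketed root finding of the
    transcendental equilibrium condition on a fine grid in (0, 1/2).
    """
    out = [
        Equilibrium(0.0, 0.0, linearize(0.0, 0.0, params)),
        Equilibrium(math.pi, 0.0, linearize(math.pi, 0.0, params)),
    ]
    beta = params.beta

    # upstream off-center roots of (pi^3/32) tan(pi xi) sec^2(pi xi) = beta xi
    def g(xi: float) -> float:
        return float(-equilibrium_curve(xi)) - beta * xi

    if beta > BETA_STAR:
        # g ~ (beta* - beta) xi < 0 near 0+ and -> +inf near 1/2: bracket the sign change
        grid = np.linspace(1e-9, 0.5 - 1e-9, grid_points)
        vals = np.array([g(x) for x in grid])
        sign_change = np.nonzero(np.diff(np.signbit(vals)))[0]
        if len(sign_change) == 0:
            raise RheodipoleError(
                f"no sign change found for off-center equilibria at beta={beta:.6g} "
                f"on ({grid[0]:.3g}, {grid[-1]:.6g}); g range [{vals.min():.3e}, {vals.max():.3e}]"
            )
        i = sign_change[0]
        root = brentq(g, grid[i], grid[i + 1], xtol=xtol)
        for xi_star in (root, -root):
            out.append(Equilibrium(math.pi, xi_star, linearize(math.pi, xi_star, params)))
    return out


def sweeping_frequency(params: NondimParams, small_rho: bool = False) -> float:
    """Radian frequency of small cross-stream sweeping oscillations.

    ``sqrt(det A)`` at the upstream centerline neutral center; with
    ``small_rho=True`` the leading-order approximation
    ``(pi^2/2) rho sqrt(beta/beta* - 1)`` is returned instead.  Defined only
    for beta >= beta* (no oscillation below the threshold).
    """
    beta = params.beta
    if beta < BETA_STAR:
        raise DomainError(
            f"beta={beta:.6g} < beta*={BETA_STAR:.6g}: upstream swimming is unstable "
            "and there is no sweeping oscillation"
        )
    if small_rho:
        return math.pi**2 / 2.0 * params.rho * math.sqrt(beta / BETA_STAR - 1.0)
    det = float(np.linalg.det(linearize(math.pi, 0.0, params)))
    return math.sqrt(max(det, 0.0))


def bifurcation_sweep(params: NondimParams, beta_grid: Sequence[float]) -> pd.DataFrame:
    """Equilibrium branches (xi, classification) across a grid of beta values.

    For each beta, alpha is rescaled at fixed rho and kappa.  Returns one row
    per (beta, equilibrium) with columns beta, theta, xi, det, classification.
    """
    rows = []
    for b in beta_grid:
        if b <= 0:
            raise DomainError(f"beta grid values must be positive, got {b}")
        p = params.with_beta(b)
        for eq in find_equilibria(p):
            rows.append((b, eq.theta, eq.xi, eq.det, eq.classification))
    return pd.DataFrame(rows, columns=["beta", "theta", "xi", "det", "classification"])


def phase_portrait(
    params: NondimParams,
    xi_grid: Iterable[float],
    theta_grid: Iterable[float],
) -> tuple[pd.DataFrame, list[Equilibrium]]:
    """Vector field of the planar system on a grid, with equilibria attached."""
    rows = []
    for xi in xi_grid:
        for th in theta_grid:
            dxi, dth = rhs(PlanarState(float(xi), float(th)), params)
            rows.append((float(xi), float(th), dxi, dth))
    table = pd.DataFrame(rows, columns=["xi", "theta", "dxi", "dtheta"])
    return table, find_equilibria(params)


def transcendental_curves(
    xi_grid: Iterable[float],
    slopes: Sequence[float] = (200.0, -200.0, -2.0),
) -> pd.DataFrame:
    """Tabulate the equilibrium curve and straight lines ``slope * xi``.

    Intersections of the curve with ``+beta xi`` (downstream) and ``-beta xi``
    (upstream) are the cross-stream equilibria; the curve's slope at the
    origin is ``-beta*``.
    """
    xi = np.asarray(list(xi_grid), float)
    if np.any(np.abs(xi) >= 0.5):
        raise DomainError("xi grid must lie strictly inside (-1/2, 1/2)")
    data = {"xi": xi, "curve": equilibrium_curve(xi)}
    for s in slopes:
        data[f"line_{s:g}"] = s * xi
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Integration utilities (oracles for the dimensional simulation and the
# sweeping-frequency law)
# ---------------------------------------------------------------------------

def integrate_planar(
    initial: PlanarState,
    params: NondimParams,
    horizon: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
):
    """Integrate the planar system; returns the scipy solution object."""
    _check_xi(initial.xi)

    def f(t, q):
        return rhs(PlanarState(q[0], q[1]), params)

    sol = solve_ivp(
        f,
        (0.0, horizon),
        [initial.xi, initial.theta],
        method="RK45",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RheodipoleError(f"planar integration failed: {sol.message}")
    return sol


def measure_period(
    params: NondimParams,
    amplitude: float = 1e-3,
    n_cycles: int = 12,
) -> float:
    """Oscillation period about the upstream neutral center, by zero crossings.

    Integrates a small-amplitude orbit started at (xi=amplitude, theta=pi) and
    averages the spacing of linearly interpolated upward zero crossings of
    xi(t) over at least ``n_cycles`` cycles.
    """
    w0 = sweeping_frequency(params)
    if w0 <= 0:
        raise DomainError("period undefined at beta = beta* (zero frequency)")
    horizon = (n_cycles + 2) * 2.0 * math.pi / w0
    n_samples = max(4000, 400 * n_cycles)
    sol = integrate_planar(
        PlanarState(amplitude, math.pi),
        params,
        horizon,
        t_eval=np.linspace(0.0, horizon, n_samples),
    )
    xi = sol.y[0]
    t = sol.t
    up = np.nonzero((xi[:-1] < 0.0) & (xi[1:] >= 0.0))[0]
    if len(up) < 3:
        raise RheodipoleError(f"too few zero crossings ({len(up)}) to measure a period")
    crossings = t[up] - xi[up] * (t[up + 1] - t[up]) / (xi[up + 1] - xi[up])
    periods = np.diff(crossings)
    return float(np.mean(periods))
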