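"""Semi-strong pulse-interaction reduction: inter-patch water profiles,
the pulse-location ODE, per-patch water and biomass budgets.

Between patches the water field is quasi-steady and obeys the linear balance

    0 = w_xx + s w_x + a - w

with (almost) no water at the patch locations; each gap therefore carries a
closed-form profile whose boundary slopes feed the pulse-location ODE

    dp_j/dt = kappa * [w_x(p_j^+)^2 - w_x(p_j^-)^2],   kappa = c D / m^{3/2},

so patches drift toward the side that delivers more water.  The absorbed
flux F_j = w_x(p_j^+) - w_x(p_j^-) sets the patch water level
w_j = 6 D m^{3/2} / F_j and the patch biomass B_j = F_j / m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import NondimParams, ConstantRainfall, pulse_ode_prefactor
from .patterns import PulseConfiguration, gap_statistics

__all__ = [
    "InterpatchProfile",
    "PulseVelocities",
    "PatchBudget",
    "PulseTrajectory",
    "solve_interpatch",
    "solve_wall_gap",
    "pulse_velocities",
    "patch_water_and_biomass",
    "integrate_pulse_ode",
    "collision_floor",
]


class SeparationError(ValueError):
    """Patches overlap or are ordered inconsistently."""


class DegeneratePatchError(ValueError):
    """A patch absorbs no water flux; the pulse ansatz does not apply."""


def collision_floor(p: NondimParams) -> float:
    """Minimum gap (4 pulse widths) below which the reduction is invalid."""
    return 4.0 * p.pulse_width


@dataclass(frozen=True)
class InterpatchProfile:
    """Closed-form water profile on a single gap.

    ``w(x) = a + c_left * exp(mu_minus (x - x_left))
           + c_right * exp(mu_plus (x - x_right))``
    with mu_plus > 0 > mu_minus the roots of ``mu^2 + s mu - 1 = 0``
    (exponentials anchored at opposite ends for numerical stability).
    For s = 0 this reduces to ``a (1 - cosh(x - c)/cosh(g/2))``.
    """

    x_left: float
    x_right: float
    a: float
    s: float
    c_left: float
    c_right: float
    mu_minus: float
    mu_plus: float
    deriv_left: float  # w_x at the left end (right side of the left patch)
    deriv_right: float  # w_x at the right end (left side of the right patch)

    @property
    def gap(self) -> float:
        return self.x_right - self.x_left

    def evaluate(self, x):
        x = np.asarray(x, dtype=float)
        return (
            self.a
            + self.c_left * np.exp(self.mu_minus * (x - self.x_left))
            + self.c_right * np.exp(self.mu_plus * (x - self.x_right))
        )

    def derivative(self, x):
        x = np.asarray(x, dtype=float)
        return self.c_left * self.mu_minus * np.exp(
            self.mu_minus * (x - self.x_left)
        ) + self.c_right * self.mu_plus * np.exp(self.mu_plus * (x - self.x_right))


def solve_interpatch(left: float, right: float, a: float, s: float = 0.0) -> InterpatchProfile:
    """Solve the gap water balance with w = 0 at both patch locations."""
    g = right - left
    if g <= 0:
        raise SeparationError(f"gap endpoints out of order: left={left}, right={right}")
    if a < 0:
        raise ValueError("rainfall a must be non-negative")
    disc = math.sqrt(s * s + 4.0)
    mu_plus = 0.5 * (-s + disc)
    mu_minus = 0.5 * (-s - disc)
    if a == 0.0:
        return InterpatchProfile(left, right, a, s, 0.0, 0.0, mu_minus, mu_plus, 0.0, 0.0)
    # w(left) = 0:  a + cl + cr * exp(-mu_plus g) = 0
    # w(right) = 0: a + cl * exp(mu_minus g) + cr = 0
    e_m = math.exp(mu_minus * g)   # <= 1
    e_p = math.exp(-mu_plus * g)   # <= 1
    det = 1.0 - e_m * e_p
    cl = -a * (1.0 - e_p) / det
    cr = -a * (1.0 - e_m) / det
    d_left = cl * mu_minus + cr * mu_plus * e_p
    d_right = cl * mu_minus * e_m + cr * mu_plus
    return InterpatchProfile(left, right, a, s, cl, cr, mu_minus, mu_plus, d_left, d_right)


def solve_wall_gap(wall: float, patch: float, a: float, s: float = 0.0) -> InterpatchProfile:
    """Water profile between a no-flux wall and the nearest patch.

    Boundary conditions: zero total water flux ``w_x + s w = 0`` at the
    wall and ``w = 0`` at the patch.  Used for the outermost segments of
    neumann domains.
    """
    if wall == patch:
        raise SeparationError("wall and patch coincide")
    x_left, x_right = (wall, patch) if wall < patch else (patch, wall)
    disc = math.sqrt(s * s + 4.0)
    mu_plus = 0.5 * (-s + disc)
    mu_minus = 0.5 * (-s - disc)
    g = x_right - x_left
    if a == 0.0:
        return InterpatchProfile(x_left, x_right, a, s, 0.0, 0.0, mu_minus, mu_plus, 0.0, 0.0)
    e_m = math.exp(mu_minus * g)
    e_p = math.exp(-mu_plus * g)
    if wall < patch:
        # flux BC at left end, w = 0 at right end
        # (mu_minus + s) cl + (mu_plus + s) e_p cr = -s a
        # e_m cl + cr = -a
        a11, a12, b1 = mu_minus + s, (mu_plus + s) * e_p, -s * a
        a21, a22, b2 = e_m, 1.0, -a
    else:
        # w = 0 at left end, flux BC at right end
        a11, a12, b1 = 1.0, e_p, -a
        a21, a22, b2 = (mu_minus + s) * e_m, mu_plus + s, -s * a
    det = a11 * a22 - a12 * a21
    cl = (b1 * a22 - a12 * b2) / det
    cr = (a11 * b2 - b1 * a21) / det
    d_left = cl * mu_minus + cr * mu_plus * e_p
    d_right = cl * mu_minus * e_m + cr * mu_plus
    return InterpatchProfile(x_left, x_right, a, s, cl, cr, mu_minus, mu_plus, d_left, d_right)


def _boundary_derivatives(cfg: PulseConfiguration, a: float, s: float):
    """Per-patch water slopes (w_x(p_j^+), w_x(p_j^-)) from the gap profiles."""
    return _derivs_from_positions(cfg.positions, cfg.domain_length, cfg.bc, a, s)


def _gaps_from_positions(pos: np.ndarray, l: float, bc: str) -> np.ndarray:
    """Gap list from a sorted position array; periodic positions may sit in
    any window of width < l (only differences matter)."""
    if pos.size == 0:
        return np.empty(0)
    if bc == "periodic":
        if pos.size == 1:
            return np.array([l])
        return np.append(np.diff(pos), l - (pos[-1] - pos[0]))
    inner = np.diff(pos)
    return np.concatenate([[2.0 * pos[0]], inner, [2.0 * (l - pos[-1])]])


def _derivs_from_positions(pos: np.ndarray, l: float, bc: str, a: float, s: float):
    n = pos.size
    if n == 0:
        return np.empty(0), np.empty(0)
    if bc == "periodic":
        gaps = _gaps_from_positions(pos, l, bc)
        if np.any(gaps <= 0):
            raise SeparationError("overlapping patches")
        if s == 0.0:
            # symmetric closed form: slope magnitude a*tanh(g/2) at both ends
            mag = a * np.tanh(gaps / 2.0)
            d_plus = mag  # right side of patch j, left end of gap j
            d_minus = -np.roll(mag, 1)  # left side of patch j, right end of gap j-1
            return d_plus, d_minus
        d_left_of_gap = np.empty(n)
        d_right_of_gap = np.empty(n)
        for j in range(n):
            prof = solve_interpatch(0.0, gaps[j], a, s)
            d_left_of_gap[j] = prof.deriv_left
            d_right_of_gap[j] = prof.deriv_right
        return d_left_of_gap, np.roll(d_right_of_gap, 1)
    # neumann
    d_plus = np.empty(n)
    d_minus = np.empty(n)
    for j in range(n):
        if j < n - 1:
            d_plus[j] = solve_interpatch(pos[j], pos[j + 1], a, s).deriv_left
        else:
            d_plus[j] = solve_wall_gap(l, pos[j], a, s).deriv_left if pos[j] < l else 0.0
        if j > 0:
            d_minus[j] = solve_interpatch(pos[j - 1], pos[j], a, s).deriv_right
        else:
            d_minus[j] = solve_wall_gap(0.0, pos[j], a, s).deriv_right
    return d_plus, d_minus


@dataclass(frozen=True)
class PulseVelocities:
    """Per-patch velocities and the boundary water slopes that drive them."""

    velocities: np.ndarray
    deriv_plus: np.ndarray
    deriv_minus: np.ndarray


def pulse_velocities(cfg: PulseConfiguration, p: NondimParams, a: float | None = None) -> PulseVelocities:
    """Patch velocities from the pulse-location ODE.

    Positive velocity moves a patch toward its larger adjacent gap (where
    more water accumulates).  ``a`` overrides the rainfall in ``p`` (used
    by ramped integrations).
    """
    a = p.a if a is None else a
    if cfg.n == 0:
        z = np.empty(0)
        return PulseVelocities(z, z, z)
    if cfg.n >= 2 and cfg.min_gap() <= 0:
        raise SeparationError("overlapping patches")
    d_plus, d_minus = _boundary_derivatives(cfg, a, p.s)
    kappa = pulse_ode_prefactor(p)
    vel = kappa * (d_plus ** 2 - d_minus ** 2)
    return PulseVelocities(velocities=vel, deriv_plus=d_plus, deriv_minus=d_minus)


@dataclass(frozen=True)
class PatchBudget:
    """Per-patch water budget: absorbed flux, water level, biomass."""

    flux: np.ndarray      # F_j = w_x(p_j^+) - w_x(p_j^-)
    w_patch: np.ndarray   # w_j = 6 D m^{3/2} / F_j
    biomass: np.ndarray   # B_j = F_j / m

    @property
    def total_biomass(self) -> float:
        return float(self.biomass.sum())


def patch_water_and_biomass(cfg: PulseConfiguration, p: NondimParams, a: float | None = None) -> PatchBudget:
    """Flux balance of the quasi-steady pulses.

    Water uptake integrated over pulse j equals the flux absorbed from the
    two adjacent gaps, which fixes ``w_j = 6 D m^{3/2} / F_j`` and the
    biomass (integral of v over the pulse) ``B_j = F_j / m``.
    """
    a = p.a if a is None else a
    if cfg.n == 0:
        z = np.empty(0)
        return PatchBudget(z, z, z)
    d_plus, d_minus = _boundary_derivatives(cfg, a, p.s)
    flux = d_plus - d_minus
    bad = np.nonzero(flux <= 0)[0]
    if bad.size:
        raise DegeneratePatchError(
            f"patch index {bad[0]} absorbs non-positive water flux "
            f"(F = {flux[bad[0]]:.3g}); the pulse ansatz does not apply"
        )
    w_patch = 6.0 * p.D * p.m ** 1.5 / flux
    return PatchBudget(flux=flux, w_patch=w_patch, biomass=flux / p.m)


@dataclass
class PulseTrajectory:
    """Sampled trajectory of a pulse configuration under the location ODE."""

    ts: np.ndarray
    positions: np.ndarray  # (n_samples, N)
    a_values: np.ndarray
    cfg0: PulseConfiguration
    collision: tuple[float, int] | None = None  # (time, index of closing gap)

    @property
    def collided(self) -> bool:
        return self.collision is not None

    def configuration_at(self, i: int) -> PulseConfiguration:
        pos = self.positions[i]
        l = self.cfg0.domain_length
        if self.cfg0.bc == "periodic":
            pos = np.sort(pos % l)
        return PulseConfiguration(domain_length=l, positions=pos, bc=self.cfg0.bc, t=float(self.ts[i]))

    def final_configuration(self) -> PulseConfiguration:
        return self.configuration_at(len(self.ts) - 1)

    def gap_cv(self) -> np.ndarray:
        out = np.empty(len(self.ts))
        for i in range(len(self.ts)):
            st = gap_statistics(self.configuration_at(i))
            out[i] = st.cv if st.defined else np.nan
        return out


def integrate_pulse_ode(
    cfg: PulseConfiguration,
    p: NondimParams,
    ramp=None,
    t_end: float = 1e4,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int = 200,
    method: str = "LSODA",
) -> PulseTrajectory:
    """Evolve patch positions under the pulse-location ODE.

    ``ramp`` is any callable ``a(t)`` (e.g. :class:`ClimateRamp`); omitted,
    the rainfall in ``p`` is held constant.  Integration stops with a
    recorded collision event (not an exception) if any gap closes to the
    collision floor, where the reduction stops being meaningful.
    At constant rainfall the gap variance decreases monotonically and the
    configuration converges to the regular pattern.
    """
    if ramp is None:
        ramp = ConstantRainfall(p.a)
    n = cfg.n
    l = cfg.domain_length
    floor = collision_floor(p)
    if n == 0:
        ts = np.array([0.0, t_end])
        return PulseTrajectory(ts, np.zeros((2, 0)), np.asarray([ramp(0.0), ramp(t_end)]), cfg)

    kappa = pulse_ode_prefactor(p)

    def rhs(t, y):
        d_plus, d_minus = _derivs_from_positions(y, l, cfg.bc, float(ramp(t)), p.s)
        return kappa * (d_plus ** 2 - d_minus ** 2)

    def min_gap_event(t, y):
        return float(_gaps_from_positions(y, l, cfg.bc).min()) - floor

    min_gap_event.terminal = True
    min_gap_event.direction = -1

    y0 = cfg.positions.astype(float)
    t_eval = np.linspace(0.0, t_end, max(2, n_samples))
    events = [min_gap_event] if n >= 2 else None
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method=method, rtol=rtol, atol=atol,
        t_eval=t_eval, events=events, dense_output=False,
    )
    ts = sol.t
    ys = sol.y.T
    collision = None
    if events and sol.t_events[0].size:
        t_c = float(sol.t_events[0][0])
        y_c = sol.y_events[0][0]
        keep = ts < t_c
        ts = np.append(ts[keep], t_c)
        ys = np.vstack([ys[keep], y_c])
        collision = (t_c, int(np.argmin(_gaps_from_positions(y_c, l, cfg.bc))))
    a_vals = np.asarray([float(ramp(t)) for t in ts])
    return PulseTrajectory(ts=ts, positions=ys, a_values=a_vals, cfg0=cfg, collision=collision)
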