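"""Model parameters and scalings for the extended Klausmeier model.

The dimensional model couples water ``W`` (mm) and vegetation ``V`` (kg m^-2)::

    W_T = D_W W_XX + (S W)_X + A - L W - R W V^2
    V_T = D_V V_XX - M V + R J W V^2

and is reduced to the non-dimensional form::

    w_t = w_xx + (s w)_x + a - w - w v^2
    v_t = D^2 v_xx - m v + w v^2

via ``w = J sqrt(R/L) W``, ``v = sqrt(R/L) V``, ``x = sqrt(L/D_W) X``,
``t = L T``, with ``a = sqrt(R) J A L^{-3/2}``, ``m = M/L``,
``s = S/sqrt(L D_W)`` and ``D = sqrt(D_V/D_W)``.

The pulse-interaction reduction that drives this package is valid for
``D << 1`` (strong scale separation between water and plant dispersal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "DimParams",
    "NondimParams",
    "ClimateRamp",
    "RateRegime",
    "ScalingMap",
    "PULSE_PREFACTOR_COEF",
    "nondimensionalize",
    "dimensionalize",
    "dimensional_pulse_prefactor",
    "reaction_terms",
    "classify_rate",
    "pulse_ode_prefactor",
]

#: Constant ``c`` in the pulse-location ODE prefactor ``c * D / m**1.5``.
#:
#: The printed source for this prefactor is typographically corrupted, so the
#: value is fixed here, in one place, by an independent semi-strong asymptotic
#: derivation: projecting the quasi-steady pulse equation onto its translation
#: mode, with the flux balance ``w_j = 6 D m^{3/2} / F_j``, gives
#: ``dp_j/dt = (D / (6 m^{3/2})) [w_x(p_j^+)^2 - w_x(p_j^-)^2]``,
#: i.e. ``c = 1/6``.  The full-PDE drift oracle in the test suite is the
#: arbiter for this constant.
PULSE_PREFACTOR_COEF = 1.0 / 6.0

#: Validity warning threshold for the scale-separation ratio D.
D_VALIDITY_MAX = 0.1


class ParameterError(ValueError):
    """A model parameter violates its domain constraint."""


@dataclass(frozen=True)
class DimParams:
    """Dimensional extended-Klausmeier parameters.

    Units: A mm/yr, L 1/yr, R mm/(yr kg^2), J kg/L, M 1/yr, S m/yr,
    D_W and D_V m^2/yr.
    """

    A: float
    L: float
    R: float
    J: float
    M: float
    S: float
    D_W: float
    D_V: float

    def __post_init__(self) -> None:
        for name in ("A", "L", "R", "J", "M", "D_W", "D_V"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.S < 0:
            raise ParameterError(f"S must be non-negative, got {self.S!r}")
        if not all(math.isfinite(getattr(self, n)) for n in ("A", "L", "R", "J", "M", "S", "D_W", "D_V")):
            raise ParameterError("all parameters must be finite")
        if self.D_V > self.D_W:
            raise ParameterError(
                f"scale separation requires D_V <= D_W (got D_V={self.D_V}, D_W={self.D_W})"
            )


@dataclass(frozen=True)
class NondimParams:
    """Non-dimensional parameters (a, m, s, D) of the scaled model."""

    a: float
    m: float
    D: float
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ParameterError(f"a must be non-negative, got {self.a!r}")
        if not self.m > 0:
            raise ParameterError(f"m must be strictly positive, got {self.m!r}")
        if self.s < 0:
            raise ParameterError(f"s must be non-negative, got {self.s!r}")
        if not 0 < self.D <= 1:
            raise ParameterError(f"D must lie in (0, 1], got {self.D!r}")
        if self.D > D_VALIDITY_MAX:
            warnings.warn(
                f"D = {self.D:g} exceeds {D_VALIDITY_MAX}; the pulse reduction assumes D << 1 "
                "and its predictions degrade for weak scale separation",
                stacklevel=3,
            )

    def with_a(self, a: float) -> "NondimParams":
        return NondimParams(a=a, m=self.m, D=self.D, s=self.s)

    @property
    def pulse_width(self) -> float:
        """Characteristic half-width ``2 D / sqrt(m)`` of the sech^2 pulse."""
        return 2.0 * self.D / math.sqrt(self.m)


@dataclass(frozen=True)
class ScalingMap:
    """Coordinate scales linking dimensional and non-dimensional frames.

    ``x = X / space_scale`` and ``t = T / time_scale`` map dimensional
    coordinates into the scaled frame; water and vegetation amplitudes map
    as ``w = water_scale * W`` and ``v = veg_scale * V``.
    """

    space_scale: float  # sqrt(D_W / L), metres per non-dimensional length
    time_scale: float  # 1 / L, years per non-dimensional time
    water_scale: float  # J * sqrt(R / L)
    veg_scale: float  # sqrt(R / L)


@dataclass(frozen=True)
class ClimateRamp:
    """Clamped linear rainfall ramp ``a(t)``.

    ``a(t) = a_start + (a_end - a_start) * t / T`` for ``0 <= t <= T``,
    clamped to the endpoint values outside that interval.  The paper-style
    drying scenario ``a(t) = a0 (1 - t/T)`` is ``ClimateRamp(a0, 0.0, T)``.
    """

    a_start: float
    a_end: float
    T: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ParameterError(f"ramp duration T must be positive, got {self.T!r}")
        if self.a_start < 0 or self.a_end < 0:
            raise ParameterError("rainfall values must be non-negative")

    def __call__(self, t: float):
        import numpy as np

        frac = np.clip(np.asarray(t, dtype=float) / self.T, 0.0, 1.0)
        out = self.a_start + (self.a_end - self.a_start) * frac
        return float(out) if out.ndim == 0 else out

    @property
    def rate(self) -> float:
        """|da/dt| on the active segment."""
        return abs(self.a_end - self.a_start) / self.T

    @property
    def a_mid(self) -> float:
        return 0.5 * (self.a_start + self.a_end)

    @staticmethod
    def constant(a: float) -> "ConstantRainfall":
        return ConstantRainfall(a)


@dataclass(frozen=True)
class ConstantRainfall:
    """Static climate; evaluates to a fixed rainfall for all t."""

    a: float

    def __call__(self, t: float):
        import numpy as np

        arr = np.asarray(t, dtype=float)
        return self.a if arr.ndim == 0 else np.full_like(arr, self.a)

    @property
    def rate(self) -> float:
        return 0.0

    @property
    def a_mid(self) -> float:
        return self.a


@dataclass(frozen=True)
class RateRegime:
    """Outcome of the slow/fast climate-change classification.

    ``rearrangement_rate`` is ``D a^2 m^{-3/2}``, the scale on which patches
    migrate toward regularity; the feasible region shrinks at relative rate
    ``|da/dt| / a``.  Climate change is slow when migration wins by at least
    a factor ``1/eps_slow``, fast when shrinkage wins outright, marginal in
    the order-of-magnitude band between.  ``patch_loss_ok`` records whether
    patch loss may be treated as instantaneous (``|da/dt| << m``).
    """

    regime: str  # "slow" | "marginal" | "fast"
    rearrangement_rate: float
    ramp_rate: float
    patch_loss_ok: bool
    a_eval: float = field(default=float("nan"))


def nondimensionalize(p: DimParams) -> tuple[NondimParams, ScalingMap]:
    """Map dimensional parameters to the scaled quadruple (a, m, s, D).

    Returns the non-dimensional parameters together with the coordinate
    scales needed to map trajectories back to physical units.
    """
    a = math.sqrt(p.R) * p.J * p.A * p.L ** -1.5
    m = p.M / p.L
    s = p.S / math.sqrt(p.L * p.D_W)
    D = math.sqrt(p.D_V / p.D_W)
    scales = ScalingMap(
        space_scale=math.sqrt(p.D_W / p.L),
        time_scale=1.0 / p.L,
        water_scale=p.J * math.sqrt(p.R / p.L),
        veg_scale=math.sqrt(p.R / p.L),
    )
    return NondimParams(a=a, m=m, D=D, s=s), scales


def dimensionalize(p: NondimParams, scales: ScalingMap) -> DimParams:
    """Invert :func:`nondimensionalize` given the coordinate scales."""
    L = 1.0 / scales.time_scale
    D_W = scales.space_scale ** 2 * L
    D_V = p.D ** 2 * D_W
    R = scales.veg_scale ** 2 * L
    J = scales.water_scale / scales.veg_scale
    M = p.m * L
    S = p.s * math.sqrt(L * D_W)
    A = p.a * L ** 1.5 / (math.sqrt(R) * J)
    return DimParams(A=A, L=L, R=R, J=J, M=M, S=S, D_W=D_W, D_V=D_V)


def pulse_ode_prefactor(p: NondimParams) -> float:
    """Prefactor ``c D m^{-3/2}`` of the non-dimensional pulse-location ODE."""
    return PULSE_PREFACTOR_COEF * p.D / p.m ** 1.5


def dimensional_pulse_prefactor(p: DimParams) -> float:
    """Prefactor alpha of the dimensional pulse ODE.

    ``dP_j/dT = alpha [W_X(P_j^+)^2 - W_X(P_j^-)^2]``.  Computed by
    composing the non-dimensional prefactor with the coordinate and
    amplitude scalings rather than transcribing the (corrupted) printed
    closed form.  The resulting expression is
    ``alpha = c R J^2 D_W sqrt(D_V) / M^{3/2}`` with ``c`` the documented
    pulse prefactor constant.
    """
    nd, scales = nondimensionalize(p)
    kappa = pulse_ode_prefactor(nd)
    # dp/dt = kappa * w_x^2-difference; transform each factor:
    #   dP/dT = space_scale / time_scale * dp/dt
    #   w_x = water_scale * space_scale * W_X
    return (scales.space_scale / scales.time_scale) * kappa * (scales.water_scale * scales.space_scale) ** 2


def reaction_terms(w, v, p: NondimParams):
    """Pointwise reaction terms (spatial operators excluded).

    ``dw = a - w - w v^2`` (rainfall, evaporation, uptake) and
    ``dv = -m v + w v^2`` (mortality, growth).
    """
    uptake = w * v * v
    dw = p.a - w - uptake
    dv = -p.m * v + uptake
    return dw, dv


def classify_rate(
    p: NondimParams,
    ramp,
    eps_slow: float = 0.1,
    a_eval: float | None = None,
) -> RateRegime:
    """Classify a climate ramp as slow, marginal or fast.

    Patches migrate toward the regular configuration at a rate of order
    ``D a^2 m^{-3/2}``; the feasibility boundary moves at relative rate
    ``|da/dt| / a``.  The ramp is *slow* when
    ``|da/dt| < eps_slow * D a^3 m^{-3/2}``, *fast* when ``|da/dt|``
    exceeds ``D a^3 m^{-3/2}`` itself, and *marginal* in between (the
    band spans the factor ``1/eps_slow``).  By default the threshold is
    evaluated at the ramp's midpoint rainfall; pass ``a_eval`` to pin it.

    ``patch_loss_ok`` is ``|da/dt| < eps_slow * m``: losses may then be
    treated as instantaneous relative to the climate trend.
    """
    a = float(a_eval) if a_eval is not None else float(ramp.a_mid)
    rearr = p.D * a * a / p.m ** 1.5
    rate = float(ramp.rate)
    boundary = rearr * a  # D a^3 m^{-3/2}
    if rate < eps_slow * boundary or rate == 0.0:
        regime = "slow"
    elif rate > boundary:
        regime = "fast"
    else:
        regime = "marginal"
    return RateRegime(
        regime=regime,
        rearrangement_rate=rearr,
        ramp_rate=rate,
        patch_loss_ok=rate < eps_slow * p.m,
        a_eval=a,
    )
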