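"""Baseline diffusion-limited coalescence (DLC) growth model.

Nanoprecipitation forms polymer nanoparticles that grow by Brownian
encounter and coalescence.  Treating every collision of two equal spheres
as a merging event gives a second-order decay of the particle number
concentration,

    dc_p/dt = -K * c_p**2,      K = 4 * pi * (2D) * (2R) = (8/3) kB T / mu,

with the single-particle diffusivity ``D`` from the Stokes-Einstein
relation.  Mass conservation (c_p * D_h**3 constant) turns this into a
closed-form growth law for the mean hydrodynamic diameter,

    D_h(t) = D_h0 * (1 + t / tau_cs)**(1/3),
    tau_cs = (3/8) * mu / (c_p0 * kB * T),

where ``c_p0`` follows from the polymer mass concentration and the initial
diameter.  This module provides those primitives plus the equivalent ODE
form, and a helper for the polymer overlap concentration ``c* ~ 1/[eta]``.

All quantities are SI; converters live in :mod:`nanocoal.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidInputError

__all__ = [
    "BOLTZMANN",
    "AVOGADRO",
    "Medium",
    "PolymerSpec",
    "GrowthParams",
    "GrowthState",
    "GrowthTrajectory",
    "stokes_einstein_diffusivity",
    "brownian_rate_constant",
    "number_concentration",
    "coalescence_timescale",
    "diameter_closed_form",
    "diameter_ode",
    "overlap_concentration",
]

#: Boltzmann constant, J/K (exact, 2019 SI).
BOLTZMANN = 1.380649e-23

#: Avogadro constant, 1/mol (exact, 2019 SI).
AVOGADRO = 6.02214076e23

#: Coefficient of the diameter ODE consistent with the closed-form
#: growth law and tau_cs = (3/8) mu / (c_p0 kB T).
PREFACTOR_CONSISTENT = 8.0 / 9.0

#: Alternative, larger ODE coefficient kept for auditing; produces faster
#: growth than the closed form and is not used by default.
PREFACTOR_AS_PRINTED = 8.0 / 3.0

_PREFACTORS = {
    "consistent": PREFACTOR_CONSISTENT,
    "as_printed": PREFACTOR_AS_PRINTED,
}


def _require_positive(value: float, name: str) -> None:
    if not (value > 0):
        raise InvalidInputError(name, f"must be > 0, got {value!r}")


def _require_nonnegative(value: float, name: str) -> None:
    if not (value >= 0):
        raise InvalidInputError(name, f"must be >= 0, got {value!r}")


@dataclass(frozen=True)
class Medium:
    """Continuous phase after solvent exchange.

    Parameters
    ----------
    viscosity : float
        Dynamic viscosity, Pa*s.
    temperature : float
        Absolute temperature, K.
    """

    viscosity: float
    temperature: float

    def __post_init__(self):
        _require_positive(self.viscosity, "viscosity")
        _require_positive(self.temperature, "temperature")

    @property
    def thermal_mobility(self) -> float:
        """kB*T/mu, m**3/s — the recurring kinetic prefactor."""
        return BOLTZMANN * self.temperature / self.viscosity


@dataclass(frozen=True)
class PolymerSpec:
    """Polymer material constants.

    ``density`` (kg/m**3) enters the particle number balance;
    ``molar_mass`` (g/mol) is used only by the overlap-concentration helper.
    """

    density: float
    molar_mass: float = 14000.0

    def __post_init__(self):
        _require_positive(self.density, "density")
        _require_positive(self.molar_mass, "molar_mass")


@dataclass(frozen=True)
class GrowthParams:
    """Process knobs of a single growth run.

    Parameters
    ----------
    initial_diameter : float
        Mean diameter of the primary particles at the end of mixing, m.
    growth_time : float
        Duration of the coalescence-driven growth stage, s.
    mass_concentration : float
        Polymer mass concentration, kg/m**3 (== g/L).
    dilution_factor : float
        Multiplier applied to ``mass_concentration`` before use; allows the
        nominal organic-phase concentration to be rescaled to the post-mixing
        concentration that actually governs collisions (default 1).
    """

    initial_diameter: float
    growth_time: float
    mass_concentration: float
    dilution_factor: float = 1.0

    def __post_init__(self):
        _require_positive(self.initial_diameter, "initial_diameter")
        _require_nonnegative(self.growth_time, "growth_time")
        _require_nonnegative(self.mass_concentration, "mass_concentration")
        _require_positive(self.dilution_factor, "dilution_factor")

    @property
    def effective_concentration(self) -> float:
        """mass_concentration * dilution_factor, kg/m**3."""
        return self.mass_concentration * self.dilution_factor

    def with_concentration(self, mass_concentration: float) -> "GrowthParams":
        """Copy with a different nominal mass concentration."""
        return GrowthParams(
            self.initial_diameter,
            self.growth_time,
            mass_concentration,
            self.dilution_factor,
        )


@dataclass(frozen=True)
class GrowthState:
    """A point on a growth trajectory (time s, diameter m, particles/m**3)."""

    time: float
    diameter: float
    number_concentration: float


@dataclass(frozen=True)
class GrowthTrajectory:
    """Diameter trajectory on a time grid with mass-conserving particle count."""

    times: np.ndarray
    diameters: np.ndarray
    number_concentrations: np.ndarray
    states: tuple = field(repr=False, default=())

    @property
    def final(self) -> GrowthState:
        return self.states[-1]


def stokes_einstein_diffusivity(medium: Medium, radius: float) -> float:
    """Stokes-Einstein diffusivity kB*T/(6 pi mu R) of a sphere, m**2/s."""
    _require_positive(radius, "radius")
    return BOLTZMANN * medium.temperature / (6.0 * math.pi * medium.viscosity * radius)


def brownian_rate_constant(medium: Medium) -> float:
    """Brownian collision rate constant for equal spheres, m**3/s.

    K = 4 pi D' R' with D' = 2D and R' = 2R; the radius cancels through
    the Stokes-Einstein relation, leaving K = (8/3) kB T / mu.  The result
    is therefore independent of particle size.
    """
    return (8.0 / 3.0) * medium.thermal_mobility


def number_concentration(params: GrowthParams, polymer: PolymerSpec) -> float:
    """Initial particle number concentration c_p0, particles/m**3.

    Distributes the (dilution-corrected) polymer mass over spheres of the
    initial diameter: c_p0 = 6 c_eff / (pi D_h0**3 rho).
    """
    d0 = params.initial_diameter
    return 6.0 * params.effective_concentration / (math.pi * d0**3 * polymer.density)


def coalescence_timescale(medium: Medium, c_p0: float) -> float:
    """Characteristic coalescence time tau_cs = (3/8) mu/(c_p0 kB T), s.

    ``c_p0 == 0`` means no particles to collide: returns ``math.inf`` (the
    dedicated no-coalescence result) rather than raising.
    """
    _require_nonnegative(c_p0, "c_p0")
    if c_p0 == 0.0:
        return math.inf
    return (3.0 / 8.0) * medium.viscosity / (c_p0 * BOLTZMANN * medium.temperature)


def diameter_closed_form(
    medium: Medium, polymer: PolymerSpec, params: GrowthParams
) -> float:
    """Final mean diameter from the closed-form DLC growth law, m.

    D_h(t) = D_h0 * (1 + 16 (kB T/mu) (c_eff/(pi rho)) t / D_h0**3)**(1/3).
    Degenerate inputs t == 0 or c == 0 return exactly D_h0.
    """
    d0 = params.initial_diameter
    bracket = 1.0 + (
        16.0
        * medium.thermal_mobility
        * params.effective_concentration
        / (math.pi * polymer.density)
        * params.growth_time
        / d0**3
    )
    return d0 * bracket ** (1.0 / 3.0)


def diameter_ode(
    medium: Medium,
    polymer: PolymerSpec,
    params: GrowthParams,
    prefactor_mode: str = "consistent",
    time_grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> GrowthTrajectory:
    """Integrate the growth ODE dD_h/dt = C (kB T/mu) c_p0 D_h0**3 / D_h**2.

    ``prefactor_mode='consistent'`` uses C = 8/9, under which the solution
    is exactly the closed-form law with tau_cs = (3/8) mu/(c_p0 kB T);
    ``'as_printed'`` uses the larger C = 8/3 for auditing.  The particle
    number concentration along the trajectory is maintained through mass
    conservation, c_p = c_p0 (D_h0/D_h)**3.

    Raises
    ------
    IntegrationError
        If the solver does not converge; carries the last accepted state.
    """
    if prefactor_mode not in _PREFACTORS:
        raise InvalidInputError(
            "prefactor_mode", f"must be one of {sorted(_PREFACTORS)}"
        )
    _require_positive(params.growth_time, "growth_time")
    prefactor = _PREFACTORS[prefactor_mode]
    d0 = params.initial_diameter
    c_p0 = number_concentration(params, polymer)
    rate = prefactor * medium.thermal_mobility * c_p0 * d0**3

    def rhs(t, y):
        return [rate / y[0] ** 2]

    t_end = params.growth_time
    if time_grid is None:
        time_grid = np.linspace(0.0, t_end, 101)
    else:
        time_grid = np.asarray(time_grid, dtype=float)
        if time_grid[0] != 0.0 or time_grid[-1] > t_end:
            raise InvalidInputError(
                "time_grid", "must start at 0 and not exceed growth_time"
            )

    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [d0],
        method="DOP853",
        t_eval=time_grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = GrowthState(
            time=float(sol.t[-1]) if sol.t.size else 0.0,
            diameter=float(sol.y[0, -1]) if sol.t.size else d0,
            number_concentration=c_p0 * (d0 / sol.y[0, -1]) ** 3
            if sol.t.size
            else c_p0,
        )
        raise IntegrationError(f"growth ODE failed: {sol.message}", last_state=last)

    diameters = sol.y[0]
    concentrations = c_p0 * (d0 / diameters) ** 3
    states = tuple(
        GrowthState(float(t), float(d), float(c))
        for t, d, c in zip(sol.t, diameters, concentrations)
    )
    return GrowthTrajectory(sol.t, diameters, concentrations, states)


def overlap_concentration(
    mark_houwink_K: float, exponent_a: float, molar_mass: float
) -> float:
    """Overlap concentration estimate c* ~ 1/[eta], g/L.

    ``mark_houwink_K`` is in (mL/g)*(g/mol)**(-a) so that the intrinsic
    viscosity [eta] = K * M**a comes out in mL/g; the reciprocal is then
    converted to g/L (1 g/mL = 1000 g/L).
    """
    _require_positive(mark_houwink_K, "mark_houwink_K")
    if exponent_a < 0:
        raise InvalidInputError("exponent_a", f"must be >= 0, got {exponent_a!r}")
    _require_positive(molar_mass, "molar_mass")
    intrinsic_viscosity_ml_g = mark_houwink_K * molar_mass**exponent_a
    return 1000.0 / intrinsic_viscosity_ml_g
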