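"""Surfactant surface-blocking: coverage-limited growth kinetics.

A non-ionic surfactant (e.g. Pluronic F-127) adsorbs onto freshly formed
particle surfaces and sterically blocks coalescence.  The collision
efficiency is taken linear in the free surface fraction:

    h = 1 - A_block/A   (0 once the surface is fully covered),

with the total and blocked areas counted per unit suspension volume using
the cross-section convention

    A       = c_p * pi * D_h**2 / 4,
    A_block = c_s,att * pi * a**2 / 4,

``a`` being the effective footprint diameter of an adsorbed molecule.
Growth and adsorption are coupled ODEs sharing the efficiency h:

    dD_h/dt     = C (kB T/mu) c_p0 D_h0**3 / D_h**2 * h
    dc_s,att/dt = (2/3)(kB T/mu) (D_h/D_s) (c_s,0 - c_s,att) c_p * h

where D_s is the equivalent diffusion diameter of the surfactant and c_p
follows the particle diameter through mass conservation.  Adsorption is
typically much faster than growth, so the coupled system is stiff and is
integrated with a stiff-capable solver whenever surfactant is present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .core_growth import (
    AVOGADRO,
    _PREFACTORS,
    GrowthParams,
    Medium,
    PolymerSpec,
    diameter_closed_form,
    number_concentration,
)
from .errors import IntegrationError, InvalidInputError, InvalidStateError

__all__ = [
    "SurfactantSpec",
    "SurfaceState",
    "CoupledTrajectory",
    "total_particle_area",
    "blocked_area",
    "blocking_coefficient",
    "surfactant_mass_to_number",
    "coupled_rhs",
    "integrate_coupled",
]


@dataclass(frozen=True)
class SurfactantSpec:
    """Surfactant properties relevant to adsorption and blocking.

    Parameters
    ----------
    blocking_diameter : float
        Effective footprint diameter ``a`` of an adsorbed molecule, m.
        Expected to exceed the physical molecule size because interfacial
        packing is loose.
    diffusion_diameter : float
        Equivalent Stokes diameter ``D_s`` for diffusion to the surface, m.
    bulk_number_concentration : float
        Initial free surfactant concentration c_s,0, molecules/m**3.
    molar_mass : float
        g/mol; used only to convert mass to number concentration.
    """

    blocking_diameter: float
    diffusion_diameter: float
    bulk_number_concentration: float
    molar_mass: float = 12600.0

    def __post_init__(self):
        for name in ("blocking_diameter", "diffusion_diameter", "molar_mass"):
            if not (getattr(self, name) > 0):
                raise InvalidInputError(name, f"must be > 0, got {getattr(self, name)!r}")
        if self.bulk_number_concentration < 0:
            raise InvalidInputError(
                "bulk_number_concentration",
                f"must be >= 0, got {self.bulk_number_concentration!r}",
            )


@dataclass(frozen=True)
class SurfaceState:
    """Snapshot of the particle-surface budget at one instant.

    Areas are per unit suspension volume (m**2/m**3); ``coverage`` is the
    blocked fraction x and ``blocking_coefficient`` the efficiency
    h = 1 - min(x, 1).
    """

    attached_concentration: float
    total_area: float
    blocked_area: float

    def __post_init__(self):
        if self.attached_concentration < 0:
            raise InvalidStateError(
                f"attached_concentration must be >= 0, got {self.attached_concentration!r}"
            )
        if self.total_area < 0 or self.blocked_area < 0:
            raise InvalidStateError("areas must be >= 0")

    @property
    def coverage(self) -> float:
        if self.total_area == 0.0:
            if self.blocked_area > 0.0:
                raise InvalidStateError("blocked area with zero total area")
            return 0.0
        return self.blocked_area / self.total_area

    @property
    def blocking_coefficient(self) -> float:
        return 1.0 - min(self.coverage, 1.0)


def total_particle_area(number_conc: float, diameter: float) -> float:
    """Particle cross-section area per volume, c_p pi D_h**2 / 4 (m**2/m**3)."""
    if number_conc < 0:
        raise InvalidInputError("number_conc", f"must be >= 0, got {number_conc!r}")
    if diameter < 0:
        raise InvalidInputError("diameter", f"must be >= 0, got {diameter!r}")
    return number_conc * math.pi * diameter**2 / 4.0


def blocked_area(attached_concentration: float, blocking_diameter: float) -> float:
    """Surface area blocked by adsorbed surfactant, c_s,att pi a**2 / 4."""
    if attached_concentration < 0:
        raise InvalidInputError(
            "attached_concentration", f"must be >= 0, got {attached_concentration!r}"
        )
    if blocking_diameter < 0:
        raise InvalidInputError(
            "blocking_diameter", f"must be >= 0, got {blocking_diameter!r}"
        )
    return attached_concentration * math.pi * blocking_diameter**2 / 4.0


def blocking_coefficient(total_area: float, blocked: float) -> float:
    """Collision efficiency h = 1 - A_block/A, clamped to 0 at full coverage."""
    if total_area == 0.0:
        if blocked > 0.0:
            raise InvalidStateError("blocked area with zero total area")
        return 1.0
    if total_area < 0:
        raise InvalidInputError("total_area", f"must be >= 0, got {total_area!r}")
    ratio = blocked / total_area
    return 1.0 - ratio if ratio < 1.0 else 0.0


def surfactant_mass_to_number(mass_concentration: float, molar_mass: float) -> float:
    """Convert a surfactant mass concentration (g/L) to molecules/m**3.

    1 g/L == 1 kg/m**3; divides by the molar mass (kg/mol) and scales by
    the Avogadro constant.
    """
    if not (mass_concentration >= 0):
        raise InvalidInputError(
            "mass_concentration", f"must be >= 0, got {mass_concentration!r}"
        )
    if not (molar_mass > 0):
        raise InvalidInputError("molar_mass", f"must be > 0, got {molar_mass!r}")
    return mass_concentration / (molar_mass * 1e-3) * AVOGADRO


def coupled_rhs(
    state: tuple[float, float],
    medium: Medium,
    polymer: PolymerSpec,
    params: GrowthParams,
    surfactant: SurfactantSpec,
    prefactor_mode: str = "consistent",
) -> tuple[float, float]:
    """Time derivatives (dD_h/dt, dc_s,att/dt) of the coupled system.

    ``state`` is (diameter m, attached surfactant molecules/m**3).  Both
    derivatives share the blocking coefficient h, so full coverage arrests
    growth and adsorption simultaneously.
    """
    diameter, attached = state
    d0 = params.initial_diameter
    if diameter < d0 * (1.0 - 1e-12):
        raise InvalidStateError(
            f"diameter {diameter!r} below initial diameter {d0!r}"
        )
    c_s0 = surfactant.bulk_number_concentration
    if not (-1e-9 * max(c_s0, 1.0) <= attached <= c_s0 * (1.0 + 1e-9) + 1e-300):
        raise InvalidStateError(
            f"attached concentration {attached!r} outside [0, {c_s0!r}]"
        )
    c_p0 = number_concentration(params, polymer)
    c_p = c_p0 * (d0 / diameter) ** 3
    h = blocking_coefficient(
        total_particle_area(c_p, diameter),
        blocked_area(attached, surfactant.blocking_diameter),
    )
    prefactor = _PREFACTORS[prefactor_mode]
    mobility = medium.thermal_mobility
    d_diameter = prefactor * mobility * c_p0 * d0**3 / diameter**2 * h
    d_attached = (
        (2.0 / 3.0)
        * mobility
        * (diameter / surfactant.diffusion_diameter)
        * (c_s0 - attached)
        * c_p
        * h
    )
    return d_diameter, d_attached


@dataclass(frozen=True)
class CoupledTrajectory:
    """Solution of the coupled growth/adsorption system on a time grid."""

    times: np.ndarray
    diameters: np.ndarray
    attached_concentrations: np.ndarray
    blocking_coefficients: np.ndarray
    arrest_time: float | None  # first time h reached 0, if it did

    @property
    def final_diameter(self) -> float:
        return float(self.diameters[-1])

    @property
    def final_blocking_coefficient(self) -> float:
        return float(self.blocking_coefficients[-1])

    @property
    def final_attached_concentration(self) -> float:
        return float(self.attached_concentrations[-1])


def integrate_coupled(
    medium: Medium,
    polymer: PolymerSpec,
    params: GrowthParams,
    surfactant: SurfactantSpec,
    time_grid: np.ndarray | None = None,
    prefactor_mode: str = "consistent",
    rtol: float = 1e-9,
) -> CoupledTrajectory:
    """Integrate growth + adsorption from (D_h0, 0) over [0, growth_time].

    Uses LSODA (stiff-capable) when surfactant is present — adsorption can
    be orders of magnitude faster than growth — and a high-order explicit
    method otherwise.  An event records the arrest time at which the
    blocking coefficient first hits zero; integration continues through it
    (both derivatives vanish, the trajectory is flat afterwards).
    """
    if prefactor_mode not in _PREFACTORS:
        raise InvalidInputError(
            "prefactor_mode", f"must be one of {sorted(_PREFACTORS)}"
        )
    d0 = params.initial_diameter
    c_s0 = surfactant.bulk_number_concentration
    c_p0 = number_concentration(params, polymer)
    t_end = params.growth_time
    if time_grid is None:
        time_grid = np.linspace(0.0, t_end, 101) if t_end > 0 else np.array([0.0])
    else:
        time_grid = np.asarray(time_grid, dtype=float)

    if t_end == 0.0 or c_p0 == 0.0:
        n = time_grid.size
        return CoupledTrajectory(
            times=time_grid,
            diameters=np.full(n, d0),
            attached_concentrations=np.zeros(n),
            blocking_coefficients=np.ones(n),
            arrest_time=None,
        )

    a = surfactant.blocking_diameter

    def rhs(t, y):
        diameter = max(y[0], d0)
        attached = min(max(y[1], 0.0), c_s0)
        c_p = c_p0 * (d0 / diameter) ** 3
        h = blocking_coefficient(
            total_particle_area(c_p, diameter), blocked_area(attached, a)
        )
        prefactor = _PREFACTORS[prefactor_mode]
        mobility = medium.thermal_mobility
        return [
            prefactor * mobility * c_p0 * d0**3 / diameter**2 * h,
            (2.0 / 3.0)
            * mobility
            * (diameter / surfactant.diffusion_diameter)
            * (c_s0 - attached)
            * c_p
            * h,
        ]

    def arrest_event(t, y):
        diameter = max(y[0], d0)
        attached = min(max(y[1], 0.0), c_s0)
        c_p = c_p0 * (d0 / diameter) ** 3
        return total_particle_area(c_p, diameter) - blocked_area(attached, a)

    method = "LSODA" if c_s0 > 0 else "DOP853"
    atol = [1e-12 * d0, max(1.0, 1e-12 * max(c_s0, 1.0))]
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        [d0, 0.0],
        method=method,
        t_eval=time_grid,
        events=arrest_event,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        last = (
            (float(sol.t[-1]), float(sol.y[0, -1]), float(sol.y[1, -1]))
            if sol.t.size
            else (0.0, d0, 0.0)
        )
        raise IntegrationError(
            f"coupled growth/adsorption ODE failed: {sol.message}", last_state=last
        )

    diameters = np.maximum(sol.y[0], d0)
    attached = np.clip(sol.y[1], 0.0, c_s0)
    c_p = c_p0 * (d0 / diameters) ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        coverage = np.where(
            c_p > 0,
            (attached * a**2) / (c_p * diameters**2),
            0.0,
        )
    h_values = 1.0 - np.minimum(coverage, 1.0)
    arrest = float(sol.t_events[0][0]) if sol.t_events and sol.t_events[0].size else None
    return CoupledTrajectory(
        times=sol.t,
        diameters=diameters,
        attached_concentrations=attached,
        blocking_coefficients=h_values,
        arrest_time=arrest,
    )
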