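"""Model-consistent synthetic DLS-style datasets.

Emulates triplicate dynamic-light-scattering measurements of mean
hydrodynamic diameter across a polymer-concentration grid (and optionally
a surfactant-concentration screen): for each condition the forward model
supplies the true mean and replicate diameters are drawn with additive
Gaussian noise, truncated at a 1 nm physical floor.  All randomness flows
from a single integer seed through ``numpy.random.default_rng``, so the
output is bit-reproducible and independent of wall clock, locale and
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import units
from .core_growth import GrowthParams, Medium, PolymerSpec
from .errors import InvalidInputError
from .finite_coalescence import CollisionClock, calibrate_ktau
from .inference_design import ConcentrationSeries, forward_diameter
from .surfactant_dynamics import SurfactantSpec, surfactant_mass_to_number

__all__ = ["SyntheticConfig", "generate_series", "generate_surfactant_screen"]

#: Physical floor (nm) applied to noisy diameter draws.
DIAMETER_FLOOR_NM = 1.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and sampling plan for a synthetic series.

    Defaults mirror the reference growth-model parameter set: truth
    (41.0 nm, 16.0 ms), ten concentrations between 1 and 50 g/L, triplicate
    measurements with 2 nm noise.
    """

    true_initial_diameter_nm: float = 41.0
    true_growth_time_ms: float = 16.0
    concentration_grid_g_per_L: tuple = tuple(np.linspace(1.0, 50.0, 10))
    noise_sd_nm: float = 2.0
    replicates: int = 3
    seed: int = 0
    surfactant_grid_g_per_L: tuple | None = None
    enable_correction: bool = False
    dilution_factor: float = 1.0

    def __post_init__(self):
        if not (self.true_initial_diameter_nm > 0 and self.true_growth_time_ms > 0):
            raise InvalidInputError("truth", "true parameters must be > 0")
        if self.noise_sd_nm < 0:
            raise InvalidInputError(
                "noise_sd_nm", f"must be >= 0, got {self.noise_sd_nm!r}"
            )
        if self.replicates < 1:
            raise InvalidInputError(
                "replicates", f"must be >= 1, got {self.replicates!r}"
            )
        grid = np.asarray(self.concentration_grid_g_per_L, dtype=float)
        if grid.size == 0 or np.any(grid <= 0):
            raise InvalidInputError(
                "concentration_grid_g_per_L", "must be non-empty and positive"
            )

    def params_template(self) -> GrowthParams:
        return GrowthParams(
            initial_diameter=self.true_initial_diameter_nm * units.M_PER_NM,
            growth_time=self.true_growth_time_ms * units.S_PER_MS,
            mass_concentration=1.0,
            dilution_factor=self.dilution_factor,
        )


def _noisy_series(
    concentrations: np.ndarray,
    true_means_nm: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    allow_zero: bool = False,
) -> ConcentrationSeries:
    means = np.empty_like(true_means_nm)
    sds = np.empty_like(true_means_nm)
    for i, mu in enumerate(true_means_nm):
        if config.noise_sd_nm == 0.0:
            means[i], sds[i] = max(mu, DIAMETER_FLOOR_NM), 0.0
            continue
        draws = mu + config.noise_sd_nm * rng.standard_normal(config.replicates)
        draws = np.maximum(draws, DIAMETER_FLOOR_NM)
        means[i] = draws.mean()
        sds[i] = draws.std(ddof=1) if config.replicates > 1 else 0.0
    return ConcentrationSeries(
        concentrations_g_per_L=concentrations,
        mean_diameters_nm=means,
        diameter_sds_nm=sds,
        replicate_counts=np.full(concentrations.size, config.replicates, dtype=float),
        allow_zero_concentration=allow_zero,
    )


def generate_series(
    config: SyntheticConfig,
    medium: Medium,
    polymer: PolymerSpec,
    clock: CollisionClock | None = None,
) -> ConcentrationSeries:
    """Triplicate-style noisy diameters over the polymer-concentration grid.

    With ``config.enable_correction`` a finite-coalescence clock is applied
    (calibrated at 20 g/L unless one is passed explicitly).  ``noise_sd_nm=0``
    returns the forward-model means exactly with zero SD.
    """
    template = config.params_template()
    if config.enable_correction and clock is None:
        clock = calibrate_ktau(medium, polymer, template)
    rng = np.random.default_rng(config.seed)
    grid = np.asarray(config.concentration_grid_g_per_L, dtype=float)
    true_means = np.array(
        [
            forward_diameter(
                medium,
                polymer,
                template.with_concentration(float(c)),
                clock=clock,
            )
            * units.NM_PER_M
            for c in grid
        ]
    )
    return _noisy_series(grid, true_means, config, rng)


def generate_surfactant_screen(
    config: SyntheticConfig,
    medium: Medium,
    polymer: PolymerSpec,
    surfactant_template: SurfactantSpec,
    polymer_concentration_g_per_L: float = 50.0,
) -> ConcentrationSeries:
    """Noisy diameters over the surfactant grid at fixed polymer concentration.

    The returned series' concentration column holds the surfactant mass
    concentration (g/L).  A zero surfactant level reduces to the plain
    growth model.  Emulates a stabilizer screen at a constant 50 g/L
    polymer load.
    """
    if config.surfactant_grid_g_per_L is None:
        raise InvalidInputError(
            "surfactant_grid_g_per_L", "must be set for a surfactant screen"
        )
    s_grid = np.asarray(config.surfactant_grid_g_per_L, dtype=float)
    if s_grid.size == 0 or np.any(s_grid < 0):
        raise InvalidInputError(
            "surfactant_grid_g_per_L", "must be non-empty and non-negative"
        )
    template = config.params_template().with_concentration(
        polymer_concentration_g_per_L
    )
    rng = np.random.default_rng(config.seed)
    true_means = np.empty(s_grid.size)
    for i, c_s in enumerate(s_grid):
        spec = (
            replace(
                surfactant_template,
                bulk_number_concentration=surfactant_mass_to_number(
                    float(c_s), surfactant_template.molar_mass
                ),
            )
            if c_s > 0
            else None
        )
        true_means[i] = (
            forward_diameter(medium, polymer, template, surfactant=spec)
            * units.NM_PER_M
        )
    return _noisy_series(s_grid, true_means, config, rng, allow_zero=True)
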