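"""Fitting, PDI estimation, inverse design and verification reporting.

This module is the bridge between the physical model (SI units) and lab
data (nm, ms, g/L).  It fits the two free parameters of the growth law —
the initial diameter D_h0 and the effective growth time t — to a
concentration-diameter series, estimates the polydispersity index by
propagating a growth-time spread through the forward model, inverts the
model for the polymer concentration that yields a target diameter, and
nests that inversion inside a surfactant-concentration solve to design a
full formulation for a target (diameter, PDI) pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares, minimize_scalar

from . import units
from .core_growth import (
    GrowthParams,
    Medium,
    PolymerSpec,
    diameter_closed_form,
    number_concentration,
)
from .errors import (
    FitError,
    InfeasibleTargetError,
    InsufficientDataError,
    InvalidInputError,
)
from .finite_coalescence import (
    CollisionClock,
    corrected_diameter,
    intercollision_time,
    neck_ratio_from_time,
)
from .surfactant_dynamics import SurfactantSpec, integrate_coupled

__all__ = [
    "ConcentrationSeries",
    "FittedParams",
    "GrowthTimeSpread",
    "DesignTarget",
    "DesignResult",
    "forward_diameter",
    "fit_growth_params",
    "estimate_pdi",
    "invert_for_concentration",
    "design_formulation",
    "relative_error",
    "verification_report",
]

#: Mandatory CSV columns of the series dialect.
_REQUIRED_COLUMNS = ("conc_g_per_L", "dh_nm", "dh_sd_nm")
_OPTIONAL_COLUMNS = ("pdi", "pdi_sd", "n")


@dataclass(frozen=True)
class ConcentrationSeries:
    """A (concentration, mean diameter, SD) calibration series.

    Concentrations are g/L, diameters nm.  Records are stored sorted by
    concentration so that downstream computations are independent of the
    input order.
    """

    concentrations_g_per_L: np.ndarray
    mean_diameters_nm: np.ndarray
    diameter_sds_nm: np.ndarray
    pdis: np.ndarray | None = None
    pdi_sds: np.ndarray | None = None
    replicate_counts: np.ndarray | None = None
    #: A surfactant-screen axis may legitimately contain a 0 g/L level;
    #: a polymer-concentration axis may not.
    allow_zero_concentration: bool = False

    def __post_init__(self):
        conc = np.asarray(self.concentrations_g_per_L, dtype=float)
        dh = np.asarray(self.mean_diameters_nm, dtype=float)
        sd = np.asarray(self.diameter_sds_nm, dtype=float)
        if not (conc.size == dh.size == sd.size):
            raise InvalidInputError("series", "column lengths differ")
        if conc.size and np.unique(conc).size != conc.size:
            raise InvalidInputError(
                "conc_g_per_L", "concentrations must be unique"
            )
        floor_ok = conc >= 0 if self.allow_zero_concentration else conc > 0
        if not np.all(floor_ok):
            raise InvalidInputError(
                "conc_g_per_L",
                "concentrations must be > 0"
                + (" (zero allowed on this axis)" if self.allow_zero_concentration else ""),
            )
        if np.any(dh <= 0):
            raise InvalidInputError("dh_nm", "diameters must be > 0")
        if np.any(sd < 0):
            raise InvalidInputError("dh_sd_nm", "standard deviations must be >= 0")
        order = np.argsort(conc)
        object.__setattr__(self, "concentrations_g_per_L", conc[order])
        object.__setattr__(self, "mean_diameters_nm", dh[order])
        object.__setattr__(self, "diameter_sds_nm", sd[order])
        for name in ("pdis", "pdi_sds", "replicate_counts"):
            values = getattr(self, name)
            if values is not None:
                values = np.asarray(values, dtype=float)
                if values.size != conc.size:
                    raise InvalidInputError(name, "column length differs")
                object.__setattr__(self, name, values[order])

    def __len__(self) -> int:
        return self.concentrations_g_per_L.size

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "conc_g_per_L": self.concentrations_g_per_L,
                "dh_nm": self.mean_diameters_nm,
                "dh_sd_nm": self.diameter_sds_nm,
            }
        )
        if self.pdis is not None:
            df["pdi"] = self.pdis
        if self.pdi_sds is not None:
            df["pdi_sd"] = self.pdi_sds
        if self.replicate_counts is not None:
            df["n"] = self.replicate_counts
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ConcentrationSeries":
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidInputError("csv", f"missing required columns {missing}")
        kwargs = {}
        if "pdi" in df.columns:
            kwargs["pdis"] = df["pdi"].to_numpy(dtype=float)
        if "pdi_sd" in df.columns:
            kwargs["pdi_sds"] = df["pdi_sd"].to_numpy(dtype=float)
        if "n" in df.columns:
            kwargs["replicate_counts"] = df["n"].to_numpy(dtype=float)
        return cls(
            concentrations_g_per_L=df["conc_g_per_L"].to_numpy(dtype=float),
            mean_diameters_nm=df["dh_nm"].to_numpy(dtype=float),
            diameter_sds_nm=df["dh_sd_nm"].to_numpy(dtype=float),
            **kwargs,
        )

    @classmethod
    def from_csv(cls, path_or_buffer, decimal_comma: bool = False) -> "ConcentrationSeries":
        """Read the series CSV dialect (UTF-8, header mandatory).

        ``decimal_comma=True`` accepts ','-decimal inputs with ';' as the
        field separator.
        """
        read_kwargs = {"decimal": ",", "sep": ";"} if decimal_comma else {}
        df = pd.read_csv(path_or_buffer, **read_kwargs)
        return cls.from_dataframe(df)

    def to_csv(self, path_or_buffer) -> None:
        self.to_dataframe().to_csv(path_or_buffer, index=False)


@dataclass(frozen=True)
class FittedParams:
    """Result of fitting (D_h0, t) to a concentration series."""

    initial_diameter_nm: float
    growth_time_ms: float
    sse_nm2: float
    stderr_initial_diameter_nm: float
    stderr_growth_time_ms: float
    n_points: int
    n_starts_converged: int
    success: bool

    def __post_init__(self):
        if not (self.initial_diameter_nm > 0 and self.growth_time_ms > 0):
            raise InvalidInputError("fit", "fitted parameters must be > 0")
        if self.sse_nm2 < 0:
            raise InvalidInputError("sse_nm2", "must be >= 0")


@dataclass(frozen=True)
class GrowthTimeSpread:
    """Distribution of growth times used for the PDI estimate.

    ``center_time_ms=None`` means "use the growth time of the params".
    For the uniform kind the time is spread over
    [t(1-delta), t(1+delta)]; for the lognormal kind ln(t) is normal with
    median the centre time and sigma = delta.
    """

    center_time_ms: float | None = None
    relative_half_width: float = 0.3
    distribution_kind: str = "uniform"

    def __post_init__(self):
        if not (0.0 <= self.relative_half_width < 1.0):
            raise InvalidInputError(
                "relative_half_width",
                f"must be in [0, 1), got {self.relative_half_width!r}",
            )
        if self.distribution_kind not in ("uniform", "lognormal"):
            raise InvalidInputError(
                "distribution_kind", "must be 'uniform' or 'lognormal'"
            )
        if self.center_time_ms is not None and not (self.center_time_ms > 0):
            raise InvalidInputError(
                "center_time_ms", f"must be > 0, got {self.center_time_ms!r}"
            )


@dataclass(frozen=True)
class DesignTarget:
    """A target (diameter nm, PDI) pair for inverse design."""

    target_diameter_nm: float
    target_pdi: float | None = None

    def __post_init__(self):
        if not (self.target_diameter_nm > 0):
            raise InvalidInputError(
                "target_diameter_nm", f"must be > 0, got {self.target_diameter_nm!r}"
            )
        if self.target_pdi is not None and not (0.0 <= self.target_pdi < 1.0):
            raise InvalidInputError(
                "target_pdi", f"must be in [0, 1), got {self.target_pdi!r}"
            )


@dataclass(frozen=True)
class DesignResult:
    """Solved formulation with forward-model predictions at the design point."""

    pcl_concentration_g_per_L: float
    surfactant_concentration_g_per_L: float
    predicted_diameter_nm: float
    predicted_pdi: float | None
    converged: bool
    target: DesignTarget | None = None
    binding_constraint: str | None = field(default=None)


def _closed_form_nm(
    conc_g_per_L,
    initial_diameter_nm: float,
    growth_time_ms: float,
    medium: Medium,
    polymer: PolymerSpec,
    dilution_factor: float = 1.0,
):
    """Vectorized closed-form diameter (nm) at concentrations in g/L."""
    d0 = initial_diameter_nm * units.M_PER_NM
    t = growth_time_ms * units.S_PER_MS
    c_eff = np.asarray(conc_g_per_L, dtype=float) * dilution_factor
    bracket = 1.0 + (
        16.0 * medium.thermal_mobility * c_eff / (math.pi * polymer.density) * t / d0**3
    )
    return initial_diameter_nm * bracket ** (1.0 / 3.0)


def forward_diameter(
    medium: Medium,
    polymer: PolymerSpec,
    params: GrowthParams,
    clock: CollisionClock | None = None,
    surfactant: SurfactantSpec | None = None,
    prefactor_mode: str = "consistent",
) -> float:
    """Final mean diameter (m) of the full forward model.

    Uses the closed form when no surfactant is active, the coupled
    growth/adsorption system otherwise, and multiplies by the
    finite-coalescence neck factor when a collision clock is supplied.
    """
    if surfactant is not None and surfactant.bulk_number_concentration > 0:
        traj = integrate_coupled(
            medium, polymer, params, surfactant, prefactor_mode=prefactor_mode
        )
        base = traj.final_diameter
    else:
        base = diameter_closed_form(medium, polymer, params)
    if clock is not None:
        c_p0 = number_concentration(params, polymer)
        base *= neck_ratio_from_time(intercollision_time(c_p0, clock))
    return base


def fit_growth_params(
    series: ConcentrationSeries,
    medium: Medium,
    polymer: PolymerSpec,
    weighting: str = "none",
    dilution_factor: float = 1.0,
) -> FittedParams:
    """Least-squares fit of (D_h0, t) to a concentration-diameter series.

    Minimizes sum_i w_i (D_model(c_i; D_h0, t) - D_obs,i)**2 with
    positivity bounds, from a deterministic 4x4 log-spaced start grid
    (D_h0 between 1 nm and the smallest observed diameter; t between 0.1
    and 1000 ms).  Ties are broken by lowest SSE, then lowest t.  With
    ``weighting='inverse_sd'`` residuals are scaled by 1/sd_i.

    Curvature-based standard errors come from the Gauss-Newton
    approximation of the Hessian at the optimum.
    """
    if weighting not in ("none", "inverse_sd"):
        raise InvalidInputError("weighting", "must be 'none' or 'inverse_sd'")
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentrations, got {len(series)}"
        )
    conc = series.concentrations_g_per_L
    dh_obs = series.mean_diameters_nm
    if weighting == "inverse_sd":
        sd = np.where(series.diameter_sds_nm > 0, series.diameter_sds_nm, np.nan)
        fallback = np.nanmean(sd) if np.any(np.isfinite(sd)) else 1.0
        weights = 1.0 / np.where(np.isfinite(sd), sd, fallback)
    else:
        weights = np.ones_like(dh_obs)

    def residuals(x):
        d0_nm, t_ms = x
        model = _closed_form_nm(conc, d0_nm, t_ms, medium, polymer, dilution_factor)
        return weights * (model - dh_obs)

    d0_hi = float(np.min(dh_obs))
    d0_starts = np.geomspace(max(1.0, 0.02 * d0_hi), d0_hi, 4)
    t_starts = np.geomspace(0.1, 1000.0, 4)
    bounds = ([1e-3, 1e-6], [np.inf, np.inf])

    best = None
    n_converged = 0
    failures = []
    for d0_start in d0_starts:
        for t_start in t_starts:
            try:
                res = least_squares(
                    residuals,
                    x0=[d0_start, t_start],
                    bounds=bounds,
                    method="trf",
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception as exc:  # noqa: BLE001 - collected as diagnostics
                failures.append((d0_start, t_start, repr(exc)))
                continue
            if not res.success:
                failures.append((d0_start, t_start, res.message))
                continue
            n_converged += 1
            sse = float(2.0 * res.cost)
            key = (round(sse, 12), round(float(res.x[1]), 12))
            if best is None or key < best[0]:
                best = (key, res)
    if best is None:
        raise FitError("no optimizer start converged", diagnostics=failures)
    res = best[1]
    sse = float(2.0 * res.cost)
    d0_nm, t_ms = (float(v) for v in res.x)
    stderr = _curvature_stderr(res.jac, sse, len(series))
    return FittedParams(
        initial_diameter_nm=d0_nm,
        growth_time_ms=t_ms,
        sse_nm2=sse,
        stderr_initial_diameter_nm=stderr[0],
        stderr_growth_time_ms=stderr[1],
        n_points=len(series),
        n_starts_converged=n_converged,
        success=True,
    )


def _curvature_stderr(jac: np.ndarray, sse: float, n: int) -> tuple[float, float]:
    """Standard errors from the Gauss-Newton curvature J^T J."""
    dof = n - jac.shape[1]
    if dof <= 0:
        return (math.nan, math.nan)
    try:
        cov = np.linalg.inv(jac.T @ jac) * (sse / dof)
    except np.linalg.LinAlgError:
        return (math.nan, math.nan)
    diag = np.clip(np.diag(cov), 0.0, None)
    return (float(math.sqrt(diag[0])), float(math.sqrt(diag[1])))


def _spread_nodes(spread: GrowthTimeSpread, center_s: float, n_nodes: int):
    """Quadrature nodes (times, normalized weights) of the time spread."""
    delta = spread.relative_half_width
    if spread.distribution_kind == "uniform":
        x, w = np.polynomial.legendre.leggauss(n_nodes)
        times = center_s * (1.0 + delta * x)
        weights = w / 2.0
    else:  # lognormal: ln t ~ Normal(ln center, delta)
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        times = center_s * np.exp(delta * x)
        weights = w / math.sqrt(2.0 * math.pi)
        weights = weights / weights.sum()
    return times, weights


def estimate_pdi(
    medium: Medium,
    polymer: PolymerSpec,
    params: GrowthParams,
    spread: GrowthTimeSpread,
    surfactant: SurfactantSpec | None = None,
    clock: CollisionClock | None = None,
    n_nodes: int = 64,
    prefactor_mode: str = "consistent",
) -> float:
    """PDI = variance/mean**2 of the simulated diameter distribution.

    The growth time is treated as distributed (uniform or lognormal around
    the centre time); the distribution is pushed through the forward model
    on a fixed quadrature grid and the relative variance of the resulting
    diameters is returned.  A multiplicative finite-coalescence factor
    cancels in variance/mean**2, so the clock does not alter the estimate;
    surfactant coupling does, because it flattens D(t).
    """
    del clock  # scale factor cancels in variance/mean**2
    delta = spread.relative_half_width
    if delta == 0.0:
        return 0.0
    center_s = (
        spread.center_time_ms * units.S_PER_MS
        if spread.center_time_ms is not None
        else params.growth_time
    )
    if not (center_s > 0):
        raise InvalidInputError("center_time_ms", "centre growth time must be > 0")
    times, weights = _spread_nodes(spread, center_s, n_nodes)

    if surfactant is not None and surfactant.bulk_number_concentration > 0:
        order = np.argsort(times)
        t_sorted = times[order]
        run_params = replace(params, growth_time=float(t_sorted[-1]))
        traj = integrate_coupled(
            medium,
            polymer,
            run_params,
            surfactant,
            time_grid=t_sorted,
            prefactor_mode=prefactor_mode,
        )
        diameters = np.empty_like(times)
        diameters[order] = traj.diameters
    else:
        d0 = params.initial_diameter
        rate = (
            16.0
            * medium.thermal_mobility
            * params.effective_concentration
            / (math.pi * polymer.density)
        )
        diameters = d0 * (1.0 + rate * times / d0**3) ** (1.0 / 3.0)

    mean = float(np.sum(weights * diameters))
    second = float(np.sum(weights * diameters**2))
    return max(second / mean**2 - 1.0, 0.0)


def invert_for_concentration(
    target_diameter_nm: float,
    medium: Medium,
    polymer: PolymerSpec,
    params_template: GrowthParams,
    clock: CollisionClock | None = None,
    surfactant: SurfactantSpec | None = None,
    max_concentration_g_per_L: float = 400.0,
    prefactor_mode: str = "consistent",
) -> float:
    """Polymer concentration (g/L) whose forward diameter hits the target.

    Without correction or surfactant the closed form is rearranged
    analytically.  With either active, the forward model is root-found by
    bisection on a bracket; for the unimodal corrected curve the solution
    on the ascending (low-concentration) branch is returned, and a target
    above the curve's maximum raises :class:`InfeasibleTargetError`
    carrying the achievable maximum (nm).
    """
    d0_nm = params_template.initial_diameter * units.NM_PER_M
    if not (target_diameter_nm > d0_nm):
        raise InfeasibleTargetError(
            f"target {target_diameter_nm} nm must exceed the initial diameter "
            f"{d0_nm:.4g} nm",
            achievable=d0_nm,
        )
    has_surfactant = (
        surfactant is not None and surfactant.bulk_number_concentration > 0
    )
    if clock is None and not has_surfactant:
        t = params_template.growth_time
        if t <= 0:
            raise InfeasibleTargetError("growth_time must be > 0 to grow particles")
        d0 = params_template.initial_diameter
        beta = 16.0 * medium.thermal_mobility * t / (math.pi * polymer.density * d0**3)
        ratio = target_diameter_nm / d0_nm
        c_eff = (ratio**3 - 1.0) / beta
        return c_eff / params_template.dilution_factor

    def fwd(c_g_per_L: float) -> float:
        p = params_template.with_concentration(c_g_per_L)
        return (
            forward_diameter(
                medium, polymer, p, clock=clock, surfactant=surfactant,
                prefactor_mode=prefactor_mode,
            )
            * units.NM_PER_M
        )

    c_hi = max_concentration_g_per_L
    if clock is not None:
        res = minimize_scalar(
            lambda c: -fwd(c), bounds=(1e-6, c_hi), method="bounded",
            options={"xatol": 1e-10},
        )
        c_peak = float(res.x)
        d_peak = -float(res.fun)
        if target_diameter_nm > d_peak:
            raise InfeasibleTargetError(
                f"target {target_diameter_nm} nm exceeds the achievable maximum "
                f"{d_peak:.4g} nm of the corrected curve",
                achievable=d_peak,
            )
        c_hi = c_peak
    elif fwd(c_hi) < target_diameter_nm:
        raise InfeasibleTargetError(
            f"target {target_diameter_nm} nm not reachable below "
            f"{max_concentration_g_per_L} g/L "
            f"(forward model gives {fwd(c_hi):.4g} nm there)",
            achievable=fwd(c_hi),
        )
    return float(
        brentq(
            lambda c: fwd(c) - target_diameter_nm,
            1e-9,
            c_hi,
            xtol=1e-12,
            rtol=1e-12,
        )
    )


def design_formulation(
    target: DesignTarget,
    medium: Medium,
    polymer: PolymerSpec,
    params_template: GrowthParams,
    surfactant_template: SurfactantSpec | None = None,
    clock: CollisionClock | None = None,
    spread: GrowthTimeSpread | None = None,
    max_surfactant_g_per_L: float = 10.0,
    pdi_rel_tol: float = 0.05,
    prefactor_mode: str = "consistent",
) -> DesignResult:
    """Solve (polymer conc, surfactant conc) for a (diameter, PDI) target.

    Two-stage nested solve: the outer loop adjusts the surfactant
    concentration to match the target PDI (via :func:`estimate_pdi`),
    while for every candidate the inner stage re-solves the polymer
    concentration so the coupled forward model hits the target diameter.
    With no surfactant template (or no PDI target) only the inner
    inversion runs.  Infeasible targets yield a structured result with
    ``converged=False`` and the binding constraint named, not an
    exception, so callers can inspect the closest achievable design.
    """
    spread = spread or GrowthTimeSpread()

    def solve_at(c_s_g_per_L: float) -> tuple[float, float, float]:
        """(c_pcl, predicted diameter nm, predicted pdi) at a surfactant level."""
        if surfactant_template is not None and c_s_g_per_L > 0:
            from .surfactant_dynamics import surfactant_mass_to_number

            spec = replace(
                surfactant_template,
                bulk_number_concentration=surfactant_mass_to_number(
                    c_s_g_per_L, surfactant_template.molar_mass
                ),
            )
        else:
            spec = None
        c_pcl = invert_for_concentration(
            target.target_diameter_nm,
            medium,
            polymer,
            params_template,
            clock=clock,
            surfactant=spec,
            prefactor_mode=prefactor_mode,
        )
        p = params_template.with_concentration(c_pcl)
        d_pred = (
            forward_diameter(
                medium, polymer, p, clock=clock, surfactant=spec,
                prefactor_mode=prefactor_mode,
            )
            * units.NM_PER_M
        )
        pdi_pred = estimate_pdi(
            medium, polymer, p, spread, surfactant=spec,
            prefactor_mode=prefactor_mode,
        )
        return c_pcl, d_pred, pdi_pred

    def result(c_s, c_pcl, d_pred, pdi_pred, converged, constraint=None):
        return DesignResult(
            pcl_concentration_g_per_L=c_pcl,
            surfactant_concentration_g_per_L=c_s,
            predicted_diameter_nm=d_pred,
            predicted_pdi=pdi_pred,
            converged=converged,
            target=target,
            binding_constraint=constraint,
        )

    try:
        c_pcl0, d_pred0, pdi0 = solve_at(0.0)
    except InfeasibleTargetError as exc:
        raise InfeasibleTargetError(
            f"target diameter infeasible at zero surfactant: {exc}",
            achievable=exc.achievable,
        ) from exc

    if target.target_pdi is None or surfactant_template is None:
        converged = target.target_pdi is None or (
            abs(pdi0 - target.target_pdi) <= pdi_rel_tol * max(target.target_pdi, 1e-12)
        )
        constraint = (
            None
            if converged
            else "target_pdi not matchable without a surfactant stage"
        )
        return result(0.0, c_pcl0, d_pred0, pdi0, converged, constraint)

    target_pdi = target.target_pdi
    if target_pdi >= pdi0:
        converged = abs(pdi0 - target_pdi) <= pdi_rel_tol * max(target_pdi, 1e-12)
        constraint = (
            None
            if converged
            else "target_pdi at or above the zero-surfactant maximum "
            f"({pdi0:.4g}); surfactant can only narrow the distribution"
        )
        return result(0.0, c_pcl0, d_pred0, pdi0, converged, constraint)

    c_pcl_hi, d_hi, pdi_hi = solve_at(max_surfactant_g_per_L)
    if target_pdi <= pdi_hi:
        converged = abs(pdi_hi - target_pdi) <= pdi_rel_tol * max(target_pdi, 1e-12)
        constraint = (
            None
            if converged
            else f"target_pdi below the minimum {pdi_hi:.4g} achievable at the "
            f"surfactant cap {max_surfactant_g_per_L} g/L"
        )
        return result(
            max_surfactant_g_per_L, c_pcl_hi, d_hi, pdi_hi, converged, constraint
        )

    c_s = float(
        brentq(
            lambda cs: solve_at(cs)[2] - target_pdi,
            0.0,
            max_surfactant_g_per_L,
            xtol=1e-6,
            rtol=1e-8,
        )
    )
    c_pcl, d_pred, pdi_pred = solve_at(c_s)
    converged = (
        abs(d_pred - target.target_diameter_nm) <= 1e-3 * target.target_diameter_nm
        and abs(pdi_pred - target_pdi) <= pdi_rel_tol * target_pdi
    )
    return result(c_s, c_pcl, d_pred, pdi_pred, converged)


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (display convention)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def relative_error(experimental_mean: float, target: float) -> float:
    """|experimental - target| / target * 100, in percent."""
    if target == 0:
        raise InvalidInputError("target", "must be non-zero")
    return abs(experimental_mean - target) / abs(target) * 100.0


def verification_report(
    designs: list[DesignResult],
    experimental: pd.DataFrame,
) -> pd.DataFrame:
    """Design-vs-experiment table with relative errors per formulation.

    ``experimental`` must have one row per design with columns
    ``dh_nm, dh_sd_nm, pdi, pdi_sd``.  The output keeps full precision;
    rounded integer-percent columns are added for display.
    """
    required = ("dh_nm", "dh_sd_nm", "pdi", "pdi_sd")
    missing = [c for c in required if c not in experimental.columns]
    if missing:
        raise InvalidInputError("experimental", f"missing columns {missing}")
    if len(designs) != len(experimental):
        raise InvalidInputError(
            "experimental",
            f"{len(designs)} designs vs {len(experimental)} experimental rows",
        )
    rows = []
    for i, (design, (_, exp)) in enumerate(
        zip(designs, experimental.iterrows()), start=1
    ):
        if design.target is None:
            raise InvalidInputError("designs", f"design {i} lacks its target")
        dh_err = relative_error(exp["dh_nm"], design.target.target_diameter_nm)
        pdi_err = (
            relative_error(exp["pdi"], design.target.target_pdi)
            if design.target.target_pdi is not None
            else math.nan
        )
        rows.append(
            {
                "formulation": i,
                "target_dh_nm": design.target.target_diameter_nm,
                "target_pdi": design.target.target_pdi,
                "pcl_g_per_L": design.pcl_concentration_g_per_L,
                "surfactant_g_per_L": design.surfactant_concentration_g_per_L,
                "exp_dh_nm": exp["dh_nm"],
                "exp_dh_sd_nm": exp["dh_sd_nm"],
                "exp_pdi": exp["pdi"],
                "exp_pdi_sd": exp["pdi_sd"],
                "dh_error_pct": dh_err,
                "pdi_error_pct": pdi_err,
                "dh_error_pct_rounded": _round_half_up(dh_err),
                "pdi_error_pct_rounded": _round_half_up(pdi_err)
                if not math.isnan(pdi_err)
                else None,
            }
        )
    return pd.DataFrame(rows)
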