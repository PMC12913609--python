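"""Tests for fitting, PDI estimation, inversion, design and reporting."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from nanocoal import (
    ConcentrationSeries,
    DesignTarget,
    GrowthParams,
    GrowthTimeSpread,
    SurfactantSpec,
    calibrate_ktau,
    coalescence_timescale,
    design_formulation,
    diameter_closed_form,
    estimate_pdi,
    fit_growth_params,
    forward_diameter,
    invert_for_concentration,
    number_concentration,
    relative_error,
    verification_report,
)
from nanocoal.errors import (
    InfeasibleTargetError,
    InsufficientDataError,
    InvalidInputError,
)
from nanocoal.inference_design import _closed_form_nm


def model_series(medium, polymer, concs, d0_nm=41.0, t_ms=16.0, sd=0.0):
    dh = _closed_form_nm(np.asarray(concs), d0_nm, t_ms, medium, polymer)
    return ConcentrationSeries(
        concentrations_g_per_L=np.asarray(concs, dtype=float),
        mean_diameters_nm=dh,
        diameter_sds_nm=np.full(len(concs), sd),
    )


class TestConcentrationSeries:
    def test_sorting_and_roundtrip(self):
        series = ConcentrationSeries(
            concentrations_g_per_L=np.array([10.0, 1.0, 5.0]),
            mean_diameters_nm=np.array([150.0, 60.0, 120.0]),
            diameter_sds_nm=np.array([3.0, 1.0, 2.0]),
        )
        assert list(series.concentrations_g_per_L) == [1.0, 5.0, 10.0]
        assert list(series.mean_diameters_nm) == [60.0, 120.0, 150.0]
        buffer = io.StringIO()
        series.to_csv(buffer)
        buffer.seek(0)
        back = ConcentrationSeries.from_csv(buffer)
        np.testing.assert_array_equal(
            back.mean_diameters_nm, series.mean_diameters_nm
        )

    def test_decimal_comma_dialect(self):
        text = "conc_g_per_L;dh_nm;dh_sd_nm\n0,5;60,5;1,2\n5;120;2\n10;150;3\n"
        series = ConcentrationSeries.from_csv(io.StringIO(text), decimal_comma=True)
        assert series.concentrations_g_per_L[0] == 0.5
        assert series.mean_diameters_nm[0] == 60.5

    @pytest.mark.parametrize(
        "conc,dh,sd,match",
        [
            ([1.0, 1.0], [60.0, 61.0], [1.0, 1.0], "unique"),
            ([0.0, 1.0], [60.0, 61.0], [1.0, 1.0], "> 0"),
            ([1.0, 2.0], [60.0, -1.0], [1.0, 1.0], "dh_nm"),
            ([1.0, 2.0], [60.0, 61.0], [1.0, -1.0], "dh_sd_nm"),
        ],
    )
    def test_validation(self, conc, dh, sd, match):
        with pytest.raises(InvalidInputError, match=match):
            ConcentrationSeries(
                concentrations_g_per_L=np.array(conc),
                mean_diameters_nm=np.array(dh),
                diameter_sds_nm=np.array(sd),
            )


class TestFit:
    def test_noise_free_identifiability(self, medium, polymer):
        series = model_series(medium, polymer, np.linspace(1, 50, 10))
        fitted = fit_growth_params(series, medium, polymer)
        assert fitted.initial_diameter_nm == pytest.approx(41.0, rel=1e-6)
        assert fitted.growth_time_ms == pytest.approx(16.0, rel=1e-6)
        assert fitted.sse_nm2 < 1e-10

    def test_order_invariance_bit_identical(self, medium, polymer):
        concs = np.linspace(1, 50, 8)
        rng = np.random.default_rng(7)
        dh = _closed_form_nm(concs, 41.0, 16.0, medium, polymer) + rng.normal(
            0, 2, concs.size
        )
        sd = np.full(concs.size, 2.0)
        perm = rng.permutation(concs.size)
        f1 = fit_growth_params(
            ConcentrationSeries(concs, dh, sd), medium, polymer
        )
        f2 = fit_growth_params(
            ConcentrationSeries(concs[perm], dh[perm], sd[perm]), medium, polymer
        )
        assert f1.initial_diameter_nm == f2.initial_diameter_nm
        assert f1.growth_time_ms == f2.growth_time_ms
        assert f1.sse_nm2 == f2.sse_nm2

    def test_insufficient_data(self, medium, polymer):
        series = model_series(medium, polymer, [1.0, 10.0])
        with pytest.raises(InsufficientDataError):
            fit_growth_params(series, medium, polymer)

    def test_inverse_sd_weighting_changes_objective(self, medium, polymer):
        concs = np.linspace(1, 50, 8)
        dh = _closed_form_nm(concs, 41.0, 16.0, medium, polymer)
        dh = dh + np.array([5.0, -4.0, 3.0, -2.0, 2.0, -1.0, 1.0, -3.0])
        sd = np.array([10.0, 10.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        f_plain = fit_growth_params(
            ConcentrationSeries(concs, dh, sd), medium, polymer, weighting="none"
        )
        f_weighted = fit_growth_params(
            ConcentrationSeries(concs, dh, sd), medium, polymer,
            weighting="inverse_sd",
        )
        assert f_plain.initial_diameter_nm != f_weighted.initial_diameter_nm

    def test_reports_curvature_uncertainty(self, medium, polymer):
        concs = np.linspace(1, 50, 10)
        rng = np.random.default_rng(3)
        dh = _closed_form_nm(concs, 41.0, 16.0, medium, polymer) + rng.normal(
            0, 1, concs.size
        )
        fitted = fit_growth_params(
            ConcentrationSeries(concs, dh, np.full(concs.size, 1.0)),
            medium,
            polymer,
        )
        assert 0 < fitted.stderr_initial_diameter_nm < 41.0
        assert 0 < fitted.stderr_growth_time_ms < 16.0


class TestEstimatePdi:
    def test_degenerate_spread_gives_zero(self, medium, polymer, params_55):
        spread = GrowthTimeSpread(relative_half_width=0.0)
        assert estimate_pdi(medium, polymer, params_55, spread) == 0.0

    def test_non_decreasing_in_width(self, medium, polymer, params_55):
        widths = np.linspace(0.0, 0.9, 10)
        pdis = [
            estimate_pdi(
                medium, polymer, params_55,
                GrowthTimeSpread(relative_half_width=float(w)),
            )
            for w in widths
        ]
        assert np.all(np.diff(pdis) >= 0)

    @pytest.mark.parametrize("delta", [0.01, 0.03, 0.05])
    def test_small_width_closed_form_expansion(
        self, medium, polymer, params_55, delta
    ):
        # delta-method oracle: PDI ~ (delta^2/27) * (x/(1+x))^2, x = t/tau_cs
        x = params_55.growth_time / coalescence_timescale(
            medium, number_concentration(params_55, polymer)
        )
        expected = delta**2 / 27.0 * (x / (1.0 + x)) ** 2
        pdi = estimate_pdi(
            medium, polymer, params_55, GrowthTimeSpread(relative_half_width=delta)
        )
        assert pdi == pytest.approx(expected, rel=0.01)

    def test_lognormal_kind_runs_and_exceeds_uniform(
        self, medium, polymer, params_55
    ):
        uniform = estimate_pdi(
            medium, polymer, params_55,
            GrowthTimeSpread(relative_half_width=0.3, distribution_kind="uniform"),
        )
        lognormal = estimate_pdi(
            medium, polymer, params_55,
            GrowthTimeSpread(relative_half_width=0.3, distribution_kind="lognormal"),
        )
        # same nominal width: the lognormal has heavier tails
        assert lognormal > uniform > 0

    def test_invalid_width_rejected(self):
        with pytest.raises(InvalidInputError, match="relative_half_width"):
            GrowthTimeSpread(relative_half_width=1.0)


class TestInvert:
    def test_reference_inversion(self, medium, polymer, params_template):
        conc = invert_for_concentration(150.0, medium, polymer, params_template)
        assert conc == pytest.approx(10.45, rel=1e-3)
        forward = diameter_closed_form(
            medium, polymer, params_template.with_concentration(conc)
        )
        assert forward * 1e9 == pytest.approx(150.0, rel=1e-9)

    def test_roundtrip_random_targets(self, medium, polymer, params_template):
        rng = np.random.default_rng(11)
        for target in rng.uniform(45.0, 400.0, 20):
            conc = invert_for_concentration(
                float(target), medium, polymer, params_template
            )
            forward = diameter_closed_form(
                medium, polymer, params_template.with_concentration(conc)
            )
            assert abs(forward * 1e9 - target) / target < 1e-9

    def test_continuity_near_initial_diameter(self, medium, polymer, params_template):
        d0_nm = 41.0
        conc = invert_for_concentration(
            d0_nm * (1 + 1e-9), medium, polymer, params_template
        )
        assert conc < 1e-6

    def test_target_below_initial_diameter_infeasible(
        self, medium, polymer, params_template
    ):
        with pytest.raises(InfeasibleTargetError):
            invert_for_concentration(30.0, medium, polymer, params_template)

    def test_corrected_branch_roundtrip_and_infeasible(
        self, medium, polymer, params_template
    ):
        clock = calibrate_ktau(medium, polymer, params_template, 20.0)
        conc = invert_for_concentration(
            150.0, medium, polymer, params_template, clock=clock
        )
        forward = forward_diameter(
            medium, polymer, params_template.with_concentration(conc), clock=clock
        )
        assert abs(forward * 1e9 - 150.0) / 150.0 < 1e-6
        # a target above the unimodal maximum reports the achievable peak
        with pytest.raises(InfeasibleTargetError) as excinfo:
            invert_for_concentration(
                1e4, medium, polymer, params_template, clock=clock
            )
        assert excinfo.value.achievable is not None
        assert excinfo.value.achievable < 1e4


class TestDesign:
    def test_reduction_without_surfactant(self, medium, polymer, params_template):
        result = design_formulation(
            DesignTarget(150.0), medium, polymer, params_template
        )
        expected = invert_for_concentration(150.0, medium, polymer, params_template)
        assert result.pcl_concentration_g_per_L == pytest.approx(expected, rel=1e-12)
        assert result.surfactant_concentration_g_per_L == 0.0
        assert result.converged

    def test_forward_model_reproduces_target(self, medium, polymer, params_template):
        surf_template = SurfactantSpec(3e-9, 3e-9, 0.0)
        target = DesignTarget(150.0, target_pdi=0.002)
        result = design_formulation(
            target, medium, polymer, params_template,
            surfactant_template=surf_template,
        )
        assert result.converged
        assert result.predicted_diameter_nm == pytest.approx(150.0, rel=1e-3)
        assert result.predicted_pdi == pytest.approx(0.002, rel=0.05)

    def test_raising_target_pdi_lowers_surfactant(
        self, medium, polymer, params_template
    ):
        surf_template = SurfactantSpec(3e-9, 3e-9, 0.0)
        results = [
            design_formulation(
                DesignTarget(150.0, target_pdi=pdi),
                medium, polymer, params_template,
                surfactant_template=surf_template,
            )
            for pdi in (0.0008, 0.0015, 0.0025)
        ]
        surfactant_levels = [r.surfactant_concentration_g_per_L for r in results]
        assert np.all(np.diff(surfactant_levels) <= 0)

    def test_unreachable_pdi_reports_binding_constraint(
        self, medium, polymer, params_template
    ):
        surf_template = SurfactantSpec(3e-9, 3e-9, 0.0)
        result = design_formulation(
            DesignTarget(150.0, target_pdi=0.5),
            medium, polymer, params_template,
            surfactant_template=surf_template,
        )
        assert not result.converged
        assert "target_pdi" in result.binding_constraint
        assert result.surfactant_concentration_g_per_L == 0.0


class TestRelativeError:
    @pytest.mark.parametrize(
        "experimental,target,expected",
        [(151.0, 150.0, 100.0 / 150.0), (0.196, 0.1, 96.0), (5.0, 5.0, 0.0)],
    )
    def test_values(self, experimental, target, expected):
        assert relative_error(experimental, target) == pytest.approx(
            expected, rel=1e-9
        )

    def test_zero_target_invalid(self):
        with pytest.raises(InvalidInputError, match="target"):
            relative_error(1.0, 0.0)


class TestVerificationReport:
    @staticmethod
    def designs_and_experiments():
        from nanocoal import DesignResult

        targets = [
            DesignTarget(150.0, 0.1),
            DesignTarget(150.0, 0.3),
            DesignTarget(200.0, 0.1),
        ]
        designs = [
            DesignResult(
                pcl_concentration_g_per_L=c,
                surfactant_concentration_g_per_L=s,
                predicted_diameter_nm=t.target_diameter_nm,
                predicted_pdi=t.target_pdi,
                converged=True,
                target=t,
            )
            for t, c, s in zip(targets, [5.5, 30.0, 9.5], [4.0, 6.0, 0.5])
        ]
        experimental = pd.DataFrame(
            {
                "dh_nm": [151.0, 142.0, 187.0],
                "dh_sd_nm": [2.0, 4.0, 5.0],
                "pdi": [0.122, 0.164, 0.196],
                "pdi_sd": [0.003, 0.020, 0.037],
            }
        )
        return designs, experimental

    def test_error_columns(self):
        designs, experimental = self.designs_and_experiments()
        report = verification_report(designs, experimental)
        np.testing.assert_allclose(
            report["dh_error_pct"], [100.0 / 150.0, 16.0 / 3.0, 6.5], rtol=1e-9
        )
        np.testing.assert_allclose(
            report["pdi_error_pct"], [22.0, 136.0 / 3.0, 96.0], rtol=1e-6
        )
        assert list(report["dh_error_pct_rounded"]) == [1, 5, 7]
        assert list(report["pdi_error_pct_rounded"]) == [22, 45, 96]

    def test_empty_input(self):
        report = verification_report(
            [], pd.DataFrame(columns=["dh_nm", "dh_sd_nm", "pdi", "pdi_sd"])
        )
        assert report.empty

    def test_mismatched_lengths_rejected(self):
        designs, experimental = self.designs_and_experiments()
        with pytest.raises(InvalidInputError):
            verification_report(designs[:2], experimental)
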