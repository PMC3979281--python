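"""Sedimentation equivalence: cut diameter, Stokes time, gravimetry,
and the virtual experiment."""

import math

import numpy as np
import pytest

import swerf
from swerf.exceptions import DomainError, InvalidStateError

from conftest import narrow_aero_psd, uniform_aero_psd


class TestCutDiameter:
    def test_default_value(self):
        """D_c = 1.5 x convention integral = 6.4215 µm for defaults."""
        assert swerf.cut_diameter() == pytest.approx(6.4215, abs=1e-3)

    def test_equals_numerical_equating_of_integrals(self):
        """The defining construction: the survival integral (2/3)·D_c
        matches the respirable-convention integral on a fine grid."""
        d_c = swerf.cut_diameter()
        grid = np.linspace(0.0, d_c, 20001)
        survival_integral = np.trapezoid(1.0 - (grid / d_c) ** 2, grid)
        assert survival_integral == pytest.approx(
            swerf.respirable_integral(), rel=1e-6
        )

    def test_pure_lognormal_closed_form(self):
        params = swerf.ConventionParams(inhalable_decay=1e-12)
        closed = 1.5 * 4.25 * math.exp(math.log(1.5) ** 2 / 2.0)
        assert swerf.cut_diameter(params) == pytest.approx(closed, rel=1e-5)

    def test_shrinks_with_median(self):
        small = swerf.ConventionParams(respirable_median=0.01)
        assert swerf.cut_diameter(small) < 0.1


class TestSettlingTime:
    def test_quartz_in_water_hand_computation(self):
        """Stokes velocity v = g(rho_p - rho_l) d^2 / (18 eta) with
        d = D_c / sqrt(2.66), then t = h / v."""
        liquid = swerf.LiquidProperties(1.00e-3, 1000.0, "water")
        d_c_um = 6.43
        t = swerf.settling_time(liquid, 2660.0, 0.05, d_c_um)
        d_phys = d_c_um * 1e-6 / math.sqrt(2.66)
        v = 9.81 * (2660.0 - 1000.0) * d_phys**2 / (18.0 * 1.00e-3)
        assert t == pytest.approx(0.05 / v, rel=1e-12)
        assert t == pytest.approx(3.556e3, rel=1e-3)

    def test_linear_in_height(self):
        liquid = swerf.WATER_20C
        t1 = swerf.settling_time(liquid, 2660.0, 0.05, 6.43)
        t2 = swerf.settling_time(liquid, 2660.0, 0.10, 6.43)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_inverse_square_in_cut_diameter(self):
        liquid = swerf.WATER_20C
        t1 = swerf.settling_time(liquid, 2660.0, 0.05, 6.43)
        t2 = swerf.settling_time(liquid, 2660.0, 0.05, 12.86)
        assert t2 == pytest.approx(t1 / 4, rel=1e-12)

    def test_non_settling_particles_rejected(self):
        light = swerf.LiquidProperties(1.0e-3, 1000.0)
        with pytest.raises(DomainError, match="settle"):
            swerf.settling_time(light, 900.0, 0.05, 6.43)

    def test_dimensional_consistency(self):
        """h given in mm then converted agrees exactly with h in m."""
        liquid = swerf.WATER_20C
        t_m = swerf.settling_time(liquid, 2660.0, 0.05, 6.43)
        t_mm = swerf.settling_time(liquid, 2660.0, 50.0 * 1e-3, 6.43)
        assert t_m == t_mm


class TestSedimentationPlan:
    def test_derive_populates_cut_and_time(self, water_plan):
        assert water_plan.is_derived
        assert water_plan.cut_diameter_um == pytest.approx(6.4215, abs=1e-3)
        assert water_plan.settling_time_s == pytest.approx(3568.0, rel=1e-3)

    def test_creeping_flow_at_default_scale(self, water_plan):
        assert water_plan.reynolds_number() < 1e-3

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            swerf.SedimentationPlan(
                liquid=swerf.WATER_20C,
                particle_density=2660.0,
                extraction_height=0.3,
                column_height=0.2,
            )


class TestSurvivalProbability:
    def test_boundary_values(self, water_plan):
        assert swerf.survival_probability(0.0, water_plan) == 1.0
        d_c = water_plan.cut_diameter_um
        assert swerf.survival_probability(d_c, water_plan) == 0.0
        assert swerf.survival_probability(2 * d_c, water_plan) == 0.0

    def test_half_depletion_matches_geometry_oracle(self, water_plan):
        """At D = D_c/sqrt(2) the Stokes velocity is half the cut
        velocity, so v·t sweeps half of h: survival 0.5."""
        d_c = water_plan.cut_diameter_um
        D = d_c / math.sqrt(2)
        # explicit depletion geometry: fraction swept = v(D)*t / h
        v_ratio = (D / d_c) ** 2
        swept = v_ratio * water_plan.settling_time_s * water_plan.settling_velocity()
        assert swept / water_plan.extraction_height == pytest.approx(0.5, rel=1e-12)
        assert swerf.survival_probability(D, water_plan) == pytest.approx(0.5)

    def test_non_increasing(self, water_plan):
        D = np.linspace(0, 10, 200)
        s = swerf.survival_probability(D, water_plan)
        assert np.all(np.diff(s) <= 0)

    def test_underived_plan_rejected(self):
        plan = swerf.SedimentationPlan(
            liquid=swerf.WATER_20C,
            particle_density=2660.0,
            extraction_height=0.05,
            column_height=0.2,
        )
        with pytest.raises(InvalidStateError):
            swerf.survival_probability(1.0, plan)


class TestGravimetricEvaluation:
    def test_stated_estimator(self):
        meas = swerf.SedimentationMeasurement(5000.0, 100.0, 200.0, 40.0)
        assert swerf.swerf_from_measurement(meas).swerf == pytest.approx(0.100)

    def test_zero_residue(self):
        meas = swerf.SedimentationMeasurement(5000.0, 0.0, 200.0, 40.0)
        assert swerf.swerf_from_measurement(meas).swerf == 0.0

    def test_homogeneous_extraction_limit(self):
        """If nothing has settled, m = M·h/H and the estimate is 1."""
        meas = swerf.SedimentationMeasurement(5000.0, 1000.0, 200.0, 40.0)
        assert swerf.swerf_from_measurement(meas).swerf == pytest.approx(1.0)

    def test_ratio_above_one_clamped_with_warning(self, caplog):
        meas = swerf.SedimentationMeasurement(5000.0, 1050.0, 200.0, 40.0)
        with caplog.at_level("WARNING"):
            result = swerf.swerf_from_measurement(meas)
        assert result.swerf == 1.0
        assert "clamping" in caplog.text

    def test_scale_invariance(self):
        a = swerf.SedimentationMeasurement(5000.0, 120.0, 200.0, 40.0)
        b = swerf.SedimentationMeasurement(2500.0, 60.0, 100.0, 20.0)
        assert (
            swerf.swerf_from_measurement(a).swerf
            == swerf.swerf_from_measurement(b).swerf
        )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"total_mass_mg": 100.0, "supernatant_residue_mg": 200.0,
             "column_height_mm": 200.0, "extraction_height_mm": 40.0},
            {"total_mass_mg": 100.0, "supernatant_residue_mg": 10.0,
             "column_height_mm": 40.0, "extraction_height_mm": 200.0},
        ],
    )
    def test_invalid_measurements_rejected(self, kwargs):
        with pytest.raises(DomainError):
            swerf.SedimentationMeasurement(**kwargs)

    def test_silica_share_product(self):
        """Published spiking rows: SWeRF x f_CS at one-decimal rounding."""
        assert round(100 * swerf.swerf_cs_from_measurement(0.345, 0.283), 1) == 9.8
        assert round(100 * swerf.swerf_cs_from_measurement(0.408, 0.794), 1) == 32.4
        assert swerf.swerf_cs_from_measurement(0.345, 0.0) == 0.0

    def test_silica_share_domain(self):
        with pytest.raises(DomainError):
            swerf.swerf_cs_from_measurement(1.2, 0.5)

    def test_batch_csv_reader(self, tmp_path):
        path = tmp_path / "runs.csv"
        path.write_text(
            "M_mg,m_mg,H_mm,h_mm,f_cs\n5000,100,200,40,0.283\n5000,50,200,40,\n"
        )
        records = swerf.read_measurements(path)
        assert len(records) == 2
        assert records[0].cs_fraction_in_residue == pytest.approx(0.283)
        assert records[1].cs_fraction_in_residue is None


class TestVirtualSedimentation:
    def test_uniform_psd_equivalence(self, water_plan):
        """The defining equivalence: for a uniform PSD covering both
        supports, the virtual experiment and the calculated SWeRF agree."""
        psd = uniform_aero_psd(30.0, 3000)
        virt = swerf.virtual_sedimentation(psd, water_plan).swerf
        calc = swerf.swerf_from_psd(psd).swerf
        assert virt == pytest.approx(calc, abs=1e-3)

    def test_all_mass_coarse_gives_zero(self, water_plan):
        assert swerf.virtual_sedimentation(
            narrow_aero_psd(100.0), water_plan
        ).swerf == 0.0

    def test_all_mass_fine_gives_one(self, water_plan):
        assert swerf.virtual_sedimentation(
            narrow_aero_psd(0.02), water_plan
        ).swerf == pytest.approx(1.0, abs=1e-4)

    def test_spherical_basis_rejected(self, lognormal_9p3, water_plan):
        with pytest.raises(InvalidStateError):
            swerf.virtual_sedimentation(lognormal_9p3, water_plan)

    @pytest.mark.parametrize("median", [2.0, 5.0, 9.3, 18.0, 30.0])
    @pytest.mark.parametrize("gsd", [1.5, 2.0, 2.5])
    def test_method_agreement_for_lognormal_powders(self, median, gsd, water_plan):
        """The two routes agree within 0.05 absolute across realistic
        aerodynamic lognormal powders — the method-agreement property."""
        psd = swerf.lognormal_psd(
            swerf.LognormalSpec(median=median, gsd=gsd),
            diameter_basis=swerf.DiameterBasis.AERODYNAMIC,
        )
        virt = swerf.virtual_sedimentation(psd, water_plan).swerf
        calc = swerf.swerf_from_psd(psd).swerf
        assert abs(virt - calc) < 0.05


class TestSolidsLoading:
    def test_default_protocol_within_guideline(self):
        fraction = swerf.sedimentation.check_solids_loading(5.0, 2660.0, 250.0)
        assert fraction < 0.01

    def test_overloaded_suspension_warns(self, caplog):
        with caplog.at_level("WARNING"):
            swerf.sedimentation.check_solids_loading(50.0, 2660.0, 250.0)
        assert "hindered" in caplog.text
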