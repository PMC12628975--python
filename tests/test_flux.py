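"""Flux formalisms, geometry corrections, buffer corrections, full pipeline."""

import math

import numpy as np
import pytest

import ionflux as ifx
from ionflux.errors import ConfigError

U_H = ifx.lookup_ion("H+").u


def dv_from_concs(c0, c1, slope=58.0, intercept=0.0):
    """DvEstimate an ideal electrode would produce for concentrations c0/c1."""
    v0 = intercept + slope * math.log10(c0)
    v1 = intercept + slope * math.log10(c1)
    return ifx.DvEstimate(center_segment_index=1, time_s=15.0, dV=v0 - v1,
                          V0=v0, V1=v1, slope=0.0, n_points_used=1500)


class TestCorrectedDistance:
    def test_flat_is_normal_displacement(self):
        assert ifx.corrected_distance(ifx.GeometrySpec(), 50e-6) == 50e-6
        assert ifx.corrected_distance(ifx.GeometrySpec(), 50e-6, 60.0) \
            == pytest.approx(25e-6)

    def test_cylinder_closed_form(self):
        geom = ifx.GeometrySpec(shape="cylinder", radius=50e-6, gap0=50e-6)
        # a ln(r1/r0) = 50 ln(150/100) um = 20.27 um
        assert ifx.corrected_distance(geom, 50e-6) == pytest.approx(
            20.27e-6, rel=1e-3
        )

    def test_sphere_closed_form(self):
        geom = ifx.GeometrySpec(shape="sphere", radius=50e-6, gap0=50e-6)
        # a^2 (r1-r0)/(r0 r1) = 2500*50/(100*150) um = 8.33 um
        assert ifx.corrected_distance(geom, 50e-6) == pytest.approx(
            8.333e-6, rel=1e-3
        )

    @pytest.mark.parametrize("shape", ["cylinder", "sphere"])
    def test_flat_limit_as_radius_grows(self, shape):
        d = 50e-6
        geom = ifx.GeometrySpec(shape=shape, radius=1e4 * d, gap0=50e-6)
        assert ifx.corrected_distance(geom, d) == pytest.approx(d, rel=1e-3)


class TestChemicalPotentialFlux:
    def test_barley_scale_oracle(self, ideal_cal, k_ion):
        """0.5 mol/m^3 K+, dV 3.94 mV over 50 um -> |J| ~ 3000 nmol m^-2 s^-1."""
        cfg = ifx.FluxConfig(method="chemical_potential", ion=k_ion, bath_conc=0.5)
        dv = ifx.DvEstimate(1, 15.0, dV=3.94, V0=2.0, V1=-1.94, slope=0.0,
                            n_points_used=1500)
        J = ifx.flux_chemical_potential(dv, cfg, ideal_cal)
        assert abs(J) == pytest.approx(0.5 * 7.62e-8 * 3.94e-3 / 50e-6, rel=1e-9)
        assert abs(J) == pytest.approx(3.0e-6, rel=0.01)
        assert J < 0  # dV > 0 with a non-inverting cation electrode: efflux

    def test_zero_dv_zero_flux(self, ideal_cal, k_ion):
        cfg = ifx.FluxConfig(method="chemical_potential", ion=k_ion, bath_conc=0.5)
        dv = dv_from_concs(0.5, 0.5)
        assert ifx.flux_chemical_potential(dv, cfg, ideal_cal) == 0.0

    def test_linear_in_bath_concentration(self, ideal_cal, k_ion):
        dv = dv_from_concs(0.505, 0.5)
        j1 = ifx.flux_chemical_potential(
            dv, ifx.FluxConfig("chemical_potential", k_ion, bath_conc=0.5),
            ideal_cal)
        j2 = ifx.flux_chemical_potential(
            dv, ifx.FluxConfig("chemical_potential", k_ion, bath_conc=1.0),
            ideal_cal)
        assert j2 == pytest.approx(2 * j1)

    def test_position1_concentration_override(self, ideal_cal, k_ion):
        dv = dv_from_concs(1.51, 1.49)
        cfg = ifx.FluxConfig("chemical_potential", k_ion, bath_conc=0.5,
                             use_position1_conc=True)
        j_local = ifx.flux_chemical_potential(dv, cfg, ideal_cal)
        cfg_bulk = ifx.FluxConfig("chemical_potential", k_ion, bath_conc=0.5)
        j_bulk = ifx.flux_chemical_potential(dv, cfg_bulk, ideal_cal)
        assert j_local / j_bulk == pytest.approx(1.49 / 0.5)


class TestDiffusionGradientFlux:
    def test_fick_oracle(self, ideal_cal, k_ion):
        """D = 1.92e-9, dC = 0.2 mol/m^3 over 50 um -> |J| = 7.68e-6."""
        cfg = ifx.FluxConfig(method="diffusion_gradient", ion=k_ion)
        dv = dv_from_concs(1.6, 1.4)
        J = ifx.flux_diffusion_gradient(dv, cfg, ideal_cal)
        assert abs(J) == pytest.approx(7.68e-6, rel=2e-3)
        assert J < 0  # higher concentration at position 0: efflux

    def test_equal_concentrations_zero_flux(self, ideal_cal, k_ion):
        cfg = ifx.FluxConfig(method="diffusion_gradient", ion=k_ion)
        dv = dv_from_concs(1.5, 1.5)
        assert ifx.flux_diffusion_gradient(dv, cfg, ideal_cal) \
            == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("rel_grad", [1e-3, 3e-3, 1e-2])
    def test_small_gradient_equivalence(self, ideal_cal, k_ion, rel_grad):
        """Einstein relation: the two formalisms coincide as the gradient vanishes."""
        c = 0.5
        dv = dv_from_concs(c * (1 + rel_grad / 2), c * (1 - rel_grad / 2))
        cfg_f = ifx.FluxConfig("diffusion_gradient", k_ion)
        cfg_c = ifx.FluxConfig("chemical_potential", k_ion, bath_conc=c)
        j_f = ifx.flux_diffusion_gradient(dv, cfg_f, ideal_cal)
        j_c = ifx.flux_chemical_potential(dv, cfg_c, ideal_cal)
        assert j_c == pytest.approx(j_f, rel=1e-3)

    @pytest.mark.parametrize("gain", [-33.0, 2.0, 0.5])
    def test_amplifier_gain_invariance(self, k_ion, gain):
        """Scaling all voltages and the calibration by any gain leaves J unchanged."""
        base_cal = ifx.fit_calibration([(c, 58 * math.log10(c))
                                        for c in (0.1, 1.0, 10.0)])
        gain_cal = ifx.fit_calibration([(c, gain * 58 * math.log10(c))
                                        for c in (0.1, 1.0, 10.0)])
        dv = dv_from_concs(0.52, 0.48)
        dv_g = ifx.DvEstimate(1, 15.0, dV=gain * dv.dV, V0=gain * dv.V0,
                              V1=gain * dv.V1, slope=0.0, n_points_used=1500)
        for method, kw in [("chemical_potential", {"bath_conc": 0.5}),
                           ("diffusion_gradient", {})]:
            cfg = ifx.FluxConfig(method, k_ion, **kw)
            f = (ifx.flux_chemical_potential if method == "chemical_potential"
                 else ifx.flux_diffusion_gradient)
            assert f(dv_g, cfg, gain_cal) == pytest.approx(
                f(dv, cfg, base_cal), rel=1e-12
            )


class TestBufferCorrection:
    mes = ifx.lookup_buffer("Mes", 6.1)

    def test_ratio_at_pK_quarter_term(self):
        r = ifx.buffer_ratio(self.mes, 1.0, pH=self.mes.pK)
        expected = (self.mes.u_HA / U_H) * 1.0 * 1e-3 * 10**self.mes.pK / 4.0
        assert r == pytest.approx(expected, rel=1e-12)

    def test_ratio_vanishes_without_buffer(self):
        r1 = ifx.buffer_ratio(self.mes, 1e-6, pH=6.1)
        assert r1 < 1e-3
        assert ifx.buffer_ratio(self.mes, 2.0, 6.1) \
            == pytest.approx(2 * ifx.buffer_ratio(self.mes, 1.0, 6.1))

    def test_ratio_against_hand_evaluation(self):
        """Independent evaluation of the printed formula for Mes at pH 6.3."""
        pK, C, pH = self.mes.pK, 1.0, 6.3
        expected = (self.mes.u_HA / U_H) * C * 1e-3 * 10**pK \
            * (10**pH / (10**pK + 10**pH)) ** 2
        assert ifx.buffer_ratio(self.mes, C, pH) == pytest.approx(
            expected, rel=1e-12
        )

    def test_total_flux_scaling(self):
        assert ifx.correct_flux_chemical(-2e-6, 0.0) == -2e-6
        assert ifx.correct_flux_chemical(-2e-6, 1.0) == -4e-6
        r = ifx.buffer_ratio(self.mes, 1.0, 6.1)
        assert ifx.correct_flux_chemical(-2e-6, r) == pytest.approx(
            (r + 1) * -2e-6, rel=1e-12
        )

    def test_protonated_concentration(self):
        assert ifx.protonated_conc(self.mes, 1.0, pH=self.mes.pK) \
            == pytest.approx(0.5)
        assert ifx.protonated_conc(self.mes, 1.0, pH=self.mes.pK + 1) \
            == pytest.approx(1.0 / 11.0)
        assert ifx.protonated_conc(self.mes, 1.0, pH=self.mes.pK - 4) \
            == pytest.approx(1.0, rel=1e-3)

    def test_fick_buffer_correction_oracle(self):
        """pK 6.1, 1 mM buffer, pH 6.0 vs 6.2 over 50 um, hand-computed HA flux."""
        ha0 = 1.0 * 10**6.1 / (10**6.0 + 10**6.1)
        ha1 = 1.0 * 10**6.1 / (10**6.2 + 10**6.1)
        j_ha = -self.mes.D_HA * (ha0 - ha1) / 50e-6
        J_H = -1e-7
        total = ifx.correct_flux_fick(J_H, self.mes, 1.0, 6.0, 6.2, 50e-6)
        assert total == pytest.approx(J_H + j_ha, rel=1e-12)
        assert abs(total) > abs(J_H)  # acid efflux: buffer adds same-signed flux

    def test_equal_pH_leaves_flux_unchanged(self):
        assert ifx.correct_flux_fick(-1e-7, self.mes, 1.0, 6.1, 6.1, 50e-6) \
            == -1e-7

    def test_correction_preserves_sign_and_magnitude_bound(self):
        for J_H in (-3e-6, 4e-7):
            for r in (0.0, 0.5, 21.0):
                total = ifx.correct_flux_chemical(J_H, r)
                assert math.copysign(1, total) == math.copysign(1, J_H)
                assert abs(total) >= abs(J_H)


class TestFluxConfigValidation:
    def test_chemical_needs_bath_conc(self, k_ion):
        with pytest.raises(ConfigError):
            ifx.FluxConfig(method="chemical_potential", ion=k_ion)

    def test_buffer_requires_proton_channel(self, k_ion):
        mes = ifx.lookup_buffer("Mes", 6.1)
        with pytest.raises(ConfigError, match="H\\+"):
            ifx.FluxConfig(method="diffusion_gradient", ion=k_ion,
                           buffer=mes, buffer_conc_mM=1.0)

    def test_unknown_method(self, k_ion):
        with pytest.raises(ConfigError):
            ifx.FluxConfig(method="osmosis", ion=k_ion)


class TestAnalysePipeline:
    def test_zero_flux_recording_yields_zero_fluxes(self, scenario_factory,
                                                    ideal_cal, k_ion):
        rec, _ = ifx.simulate(scenario_factory(true_flux=0.0, n_loops=4))
        cfg = ifx.FluxConfig("diffusion_gradient", k_ion,
                             geometry=ifx.GeometrySpec(gap0=50e-6))
        out = ifx.analyse(rec, ideal_cal, cfg, start_fit=5.0)
        assert len(out.table) == 2
        assert np.allclose(out.table["flux1_nmol_m2_s"], 0.0, atol=1e-9)
        assert np.allclose(out.table["conc1_mM"], 0.5, rtol=1e-9)

    def test_known_efflux_recovered(self, scenario_factory, ideal_cal, k_ion):
        el = ifx.ElectrodeModel(tau=0.5, drift=0.0, noise_sd=0.0)
        rec, truth = ifx.simulate(
            scenario_factory(true_flux=2e-7, electrode=el, n_loops=6)
        )
        cfg = ifx.FluxConfig("diffusion_gradient", k_ion,
                             geometry=ifx.GeometrySpec(gap0=50e-6))
        out = ifx.analyse(rec, ideal_cal, cfg, start_fit=5.0)
        J = out.table["flux1_nmol_m2_s"].to_numpy() * 1e-9
        assert J == pytest.approx(-truth.true_flux[1], rel=0.02)

    def test_curved_geometry_recovery_is_exact(self, scenario_factory,
                                               ideal_cal, k_ion):
        """Simulator field and analyser distance correction are consistent."""
        geom = ifx.GeometrySpec(shape="cylinder", radius=200e-6, gap0=50e-6)
        rec, truth = ifx.simulate(
            scenario_factory(true_flux=2e-7, geometry=geom, n_loops=4)
        )
        cfg = ifx.FluxConfig("diffusion_gradient", k_ion, geometry=geom)
        out = ifx.analyse(rec, ideal_cal, cfg, start_fit=5.0)
        J = out.table["flux1_nmol_m2_s"].to_numpy() * 1e-9
        assert J == pytest.approx(-truth.true_flux[1], rel=1e-6)

    def test_correction_closure_at_threefold_elevation(self, scenario_factory,
                                                       ideal_cal, k_ion):
        """Local concentration 3x bulk: position-1-corrected chemical potential
        agrees with Fick within 5%."""
        D = ifx.diffusion_coefficient(k_ion)
        J_src = D * 1.0 / 425e-6  # lifts the field to ~1.5 mM at the positions
        rec, _ = ifx.simulate(scenario_factory(true_flux=J_src, n_loops=4))
        geom = ifx.GeometrySpec(gap0=50e-6)
        out_f = ifx.analyse(
            rec, ideal_cal,
            ifx.FluxConfig("diffusion_gradient", k_ion, geometry=geom), 5.0)
        out_c = ifx.analyse(
            rec, ideal_cal,
            ifx.FluxConfig("chemical_potential", k_ion, bath_conc=0.5,
                           use_position1_conc=True, geometry=geom), 5.0)
        jf = out_f.table["flux1_nmol_m2_s"].to_numpy()
        jc = out_c.table["flux1_nmol_m2_s"].to_numpy()
        assert jc == pytest.approx(jf, rel=0.05)

    def test_missing_channel2_calibration_rejected(self, scenario_factory,
                                                   ideal_cal, k_ion):
        rec, _ = ifx.simulate(scenario_factory())
        rec.samples["ise2_mV"] = rec.samples["ise1_mV"]
        cfg = ifx.FluxConfig("diffusion_gradient", k_ion)
        with pytest.raises(ConfigError, match="second ISE channel"):
            ifx.analyse(rec, ideal_cal, cfg, start_fit=5.0)

    def test_event_marks_merged_onto_loops(self, scenario_factory,
                                           ideal_cal, k_ion):
        rec, _ = ifx.simulate(scenario_factory(n_loops=4))
        rec = ifx.Recording(meta=rec.meta, samples=rec.samples,
                            events=[(15.0, "NaCl added")])
        cfg = ifx.FluxConfig("diffusion_gradient", k_ion)
        out = ifx.analyse(rec, ideal_cal, cfg, start_fit=5.0)
        assert "event_mark" in out.table.columns
        marks = out.table["event_mark"].tolist()
        assert marks[0] == "NaCl added" and marks[1] == ""
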