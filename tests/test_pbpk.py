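"""PBPK engine: closed forms, mass conservation, first-pass, prodrug, EHC."""

from dataclasses import replace

import numpy as np
import pytest

from biphasepk import (
    DoseEvent,
    EnterohepaticRecirculation,
    GITransit,
    ParameterizationError,
    PBPKParameters,
    Prodrug,
    ShapeSpec,
    disposition_concentrations,
    mass_balance,
    parametric_profile,
    release_function,
    simulate_iv,
    simulate_oral_solution,
    simulate_with_release,
)


@pytest.fixture
def one_comp():
    return PBPKParameters(cl=1.0, vc=10.0)


@pytest.fixture
def grid():
    return np.linspace(0.0, 48.0, 481)


def auc(res):
    return np.trapezoid(res.plasma.concentrations, res.times)


class TestIV:
    def test_bolus_matches_monoexponential(self, one_comp, grid):
        """1-compartment bolus must agree with C0*exp(-k t) within 0.1%."""
        res = simulate_iv(one_comp, DoseEvent(route="iv_bolus", amount_mg=10.0),
                          grid)
        exact = 1.0 * np.exp(-0.1 * res.times)
        np.testing.assert_allclose(res.plasma.concentrations, exact, rtol=1e-3)
        assert res.plasma.concentrations[100] == pytest.approx(
            np.exp(-0.1 * res.times[100]), rel=1e-6)

    def test_bolus_at_ten_hours(self, one_comp):
        res = simulate_iv(one_comp, DoseEvent(route="iv_bolus", amount_mg=10.0),
                          np.linspace(0, 10, 101))
        assert res.plasma.concentrations[-1] == pytest.approx(np.exp(-1.0),
                                                              rel=1e-6)

    def test_infusion_closed_form_at_end(self, one_comp, grid):
        D, T = 10.0, 2.0
        res = simulate_iv(one_comp, DoseEvent(route="iv_infusion", amount_mg=D,
                                              infusion_duration=T), grid)
        k = one_comp.cl / one_comp.vc
        expected = D / (one_comp.cl * T) * (1 - np.exp(-k * T))
        i = np.argmin(np.abs(res.times - T))
        assert res.plasma.concentrations[i] == pytest.approx(expected, rel=1e-3)

    def test_zero_dose_zero_profile(self, one_comp, grid):
        res = simulate_iv(one_comp, DoseEvent(route="iv_bolus", amount_mg=0.0),
                          grid)
        assert np.all(res.plasma.concentrations == 0.0)
        assert mass_balance(res) == 0.0

    def test_analytic_path_matches_ode_two_compartment(self, grid):
        p = PBPKParameters(cl=2.0, vc=30.0, q=(4.0,), v=(80.0,))
        d = DoseEvent(route="iv_bolus", amount_mg=50.0)
        ode = simulate_iv(p, d, grid)
        ana = disposition_concentrations(p, d, grid)
        np.testing.assert_allclose(ode.plasma.concentrations, ana,
                                   rtol=1e-6, atol=1e-12)

    def test_analytic_infusion_matches_ode(self, grid):
        p = PBPKParameters(cl=2.0, vc=30.0, q=(4.0,), v=(80.0,))
        d = DoseEvent(route="iv_infusion", amount_mg=50.0, infusion_duration=3.0)
        ode = simulate_iv(p, d, grid)
        ana = disposition_concentrations(p, d, grid)
        np.testing.assert_allclose(ode.plasma.concentrations, ana,
                                   rtol=1e-6, atol=1e-12)


class TestMassBalance:
    @pytest.mark.parametrize("make", [
        lambda g: simulate_iv(PBPKParameters(cl=1.0, vc=10.0),
                              DoseEvent(route="iv_bolus", amount_mg=10.0), g),
        lambda g: simulate_iv(PBPKParameters(cl=2.0, vc=30.0, q=(4.0,), v=(80.0,)),
                              DoseEvent(route="iv_infusion", amount_mg=100.0,
                                        infusion_duration=2.0), g),
        lambda g: simulate_oral_solution(
            PBPKParameters(cl=2.0, vc=30.0, eh=0.5),
            DoseEvent(route="oral_solution", amount_mg=100.0), g),
        lambda g: simulate_oral_solution(
            PBPKParameters(cl=2.0, vc=30.0, eh=0.3,
                           gi=GITransit(coupling="lumen_transit"),
                           peff_cm_min=1.67e-3),
            DoseEvent(route="oral_solution", amount_mg=100.0), g),
        lambda g: simulate_with_release(
            PBPKParameters(cl=2.0, vc=30.0, eh=0.9,
                           ehc=EnterohepaticRecirculation(f_bile=0.4)),
            DoseEvent(route="oral_cr", amount_mg=100.0,
                      absorption_input=release_function(
                          parametric_profile(ShapeSpec("sigmoidal", 0.8)))), g),
    ])
    def test_conservation_below_1e6(self, make, grid):
        assert mass_balance(make(grid)) <= 1e-6

    def test_corrupted_trajectory_flagged(self, one_comp, grid):
        res = simulate_iv(one_comp, DoseEvent(route="iv_bolus", amount_mg=10.0),
                          grid)
        res.states["central"] = res.states["central"] * 1.01
        assert mass_balance(res) > 1e-6


class TestOralSolution:
    def test_auc_ratio_equals_one_minus_eh(self, grid):
        """F = Fa * (1 - E_h): oral/i.v. AUC ratio is 0.10 at E_h = 0.9."""
        p = PBPKParameters(cl=1.0, vc=10.0, eh=0.9)
        long_grid = np.linspace(0.0, 120.0, 2401)
        po = simulate_oral_solution(
            p, DoseEvent(route="oral_solution", amount_mg=10.0), long_grid)
        iv = simulate_iv(replace(p, eh=0.0),
                         DoseEvent(route="iv_bolus", amount_mg=10.0), long_grid)
        assert auc(po) / auc(iv) == pytest.approx(0.10, rel=1e-3)

    def test_fast_gastric_emptying_converges_to_bolus(self, grid):
        p = PBPKParameters(cl=1.0, vc=10.0, gi=GITransit(k_ge=1e3))
        po = simulate_oral_solution(
            p, DoseEvent(route="oral_solution", amount_mg=10.0), grid)
        iv = simulate_iv(PBPKParameters(cl=1.0, vc=10.0),
                         DoseEvent(route="iv_bolus", amount_mg=10.0), grid)
        # past the (few-minute) emptying transient the curves superimpose
        late = grid > 1.0
        np.testing.assert_allclose(po.plasma.concentrations[late],
                                   iv.plasma.concentrations[late], rtol=2e-2)

    def test_prodrug_molar_bookkeeping(self, grid):
        """200 mg prodrug fully absorbed forms 200 * 318.75 / 360.83 mg of acid."""
        p = PBPKParameters(cl=5.0, vc=50.0,
                           prodrug=Prodrug(mw_parent=360.83, mw_active=318.75))
        res = simulate_oral_solution(
            p, DoseEvent(route="oral_solution", amount_mg=200.0),
            np.linspace(0, 200, 1001))
        formed = res.states["central"][-1] + res.states["eliminated"][-1]
        assert formed == pytest.approx(200.0 * 318.75 / 360.83, rel=1e-9)
        assert res.plasma.analyte == "active_metabolite"
        assert mass_balance(res) <= 1e-6

    def test_first_order_conversion_conserves_and_delays(self):
        inst = PBPKParameters(cl=5.0, vc=50.0,
                              prodrug=Prodrug(mw_parent=360.83, mw_active=318.75))
        slow = replace(inst, prodrug=Prodrug(mw_parent=360.83, mw_active=318.75,
                                             conversion="first_order", k_act=0.5))
        g = np.linspace(0, 300, 1501)
        d = DoseEvent(route="oral_solution", amount_mg=200.0)
        r_inst = simulate_oral_solution(inst, d, g)
        r_slow = simulate_oral_solution(slow, d, g)
        assert mass_balance(r_slow) <= 1e-6
        assert auc(r_slow) == pytest.approx(auc(r_inst), rel=1e-2)
        assert np.argmax(r_slow.plasma.concentrations) > np.argmax(
            r_inst.plasma.concentrations)


class TestControlledRelease:
    def test_released_mass_conserved(self, grid):
        rel = release_function(parametric_profile(ShapeSpec("zero_order", 0.59)))
        p = PBPKParameters(cl=2.0, vc=30.0)
        res = simulate_with_release(
            p, DoseEvent(route="oral_cr", amount_mg=100.0, absorption_input=rel),
            np.linspace(0, 200, 1001))
        absorbed = res.states["central"][-1] + res.states["eliminated"][-1]
        assert absorbed == pytest.approx(59.0, rel=1e-4)
        assert res.states["unreleased"][-1] == pytest.approx(41.0, rel=1e-9)

    def test_step_release_equals_instant_oral_solution(self):
        """A unit step release with E_h = 0 reproduces instantaneous oral dosing."""
        p = PBPKParameters(cl=1.0, vc=10.0, gi=GITransit(k_ge=1e3))
        g = np.linspace(0.0, 100.0, 2001)
        from biphasepk import AbsorptionInput
        step = AbsorptionInput(times_min=[0.0, 0.5], release=[0.0, 1.0])
        cr = simulate_with_release(
            PBPKParameters(cl=1.0, vc=10.0),
            DoseEvent(route="oral_cr", amount_mg=10.0, absorption_input=step), g)
        po = simulate_oral_solution(
            p, DoseEvent(route="oral_solution", amount_mg=10.0), g)
        assert auc(cr) == pytest.approx(auc(po), rel=5e-3)

    def test_zero_release_zero_plasma(self, grid):
        rel = release_function(parametric_profile(ShapeSpec("zero_order", 0.0)))
        res = simulate_with_release(
            PBPKParameters(cl=2.0, vc=30.0),
            DoseEvent(route="oral_cr", amount_mg=100.0, absorption_input=rel),
            grid)
        assert np.all(res.plasma.concentrations == 0.0)

    def test_auc_decreases_with_eh_and_linear_in_dose(self):
        rel = release_function(parametric_profile(ShapeSpec("first_order", 0.5)))
        g = np.linspace(0, 150, 1501)
        aucs = []
        for eh in (0.0, 0.3, 0.6, 0.9):
            p = PBPKParameters(cl=2.0, vc=30.0, eh=eh)
            aucs.append(auc(simulate_with_release(
                p, DoseEvent(route="oral_cr", amount_mg=100.0,
                             absorption_input=rel), g)))
        assert all(a > b for a, b in zip(aucs, aucs[1:]))
        p = PBPKParameters(cl=2.0, vc=30.0, eh=0.3)
        a1 = auc(simulate_with_release(
            p, DoseEvent(route="oral_cr", amount_mg=50.0, absorption_input=rel), g))
        a2 = auc(simulate_with_release(
            p, DoseEvent(route="oral_cr", amount_mg=100.0, absorption_input=rel), g))
        assert a2 == pytest.approx(2.0 * a1, rel=1e-6)


class TestEnterohepaticRecirculation:
    def test_off_reduces_to_base_model(self, grid):
        base = PBPKParameters(cl=2.0, vc=20.0)
        off = replace(base, ehc=EnterohepaticRecirculation(f_bile=0.0))
        d = DoseEvent(route="iv_bolus", amount_mg=100.0)
        np.testing.assert_allclose(
            simulate_iv(off, d, grid).plasma.concentrations,
            simulate_iv(base, d, grid).plasma.concentrations, rtol=1e-6)

    def test_secondary_peak_after_each_emptying(self):
        p = PBPKParameters(cl=2.0, vc=20.0,
                           ehc=EnterohepaticRecirculation(
                               f_bile=0.5, emptying_times=(12.0, 24.0)))
        res = simulate_iv(p, DoseEvent(route="iv_bolus", amount_mg=100.0),
                          np.linspace(0, 48, 1921))
        c, t = res.plasma.concentrations, res.times
        for t0 in (12.0, 24.0):
            i = np.searchsorted(t, t0)
            j = np.searchsorted(t, t0 + 0.5)
            assert c[j] > c[i], f"no plasma rise after emptying at {t0} h"
        assert mass_balance(res) <= 1e-6


class TestValidation:
    def test_bad_parameters_rejected(self):
        with pytest.raises(ParameterizationError):
            PBPKParameters(cl=-1.0, vc=10.0)
        with pytest.raises(ParameterizationError):
            PBPKParameters(cl=1.0, vc=10.0, eh=1.0)
        with pytest.raises(ParameterizationError):
            PBPKParameters(cl=1.0, vc=10.0, q=(1.0,), v=())

    def test_missing_release_rejected(self):
        with pytest.raises(ParameterizationError):
            DoseEvent(route="oral_cr", amount_mg=10.0)

    def test_infusion_needs_duration(self):
        with pytest.raises(ParameterizationError):
            DoseEvent(route="iv_infusion", amount_mg=10.0)
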