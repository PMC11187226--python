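"""Tests for binding thermodynamics: ΔG/K_D, ΔΔG, ITC, and BLI."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from intronkit import (
    BindingThermodynamics,
    BLIKinetics,
    ITCTitration,
    ThermoConditions,
    ddG_from_Ki,
    deltaG_from_KD,
    fit_bli_biphasic,
    fit_itc_single_site,
    minus_T_deltaS,
    simulate_bli,
    simulate_itc,
)
from intronkit.thermo import _bound_concentration, itc_injection_heats


class TestFreeEnergyRelations:
    def test_standard_state_is_zero(self):
        assert deltaG_from_KD(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_printed_itc_affinity(self):
        # K_D = 7.58 μM at 25 °C gives ΔG ≈ −6.99 kcal/mol
        assert deltaG_from_KD(7.58e-6) == pytest.approx(-6.99, abs=0.005)

    def test_ln_identity(self):
        cond = ThermoConditions()
        assert deltaG_from_KD(math.e, cond) == pytest.approx(cond.RT, rel=1e-12)

    @pytest.mark.parametrize(
        "dG,dH,expected", [(-7.02, -10.04, 3.02), (-5.0, -5.0, 0.0), (-5.0, -2.0, -3.0)]
    )
    def test_entropic_term(self, dG, dH, expected):
        assert minus_T_deltaS(dG, dH) == pytest.approx(expected, abs=1e-12)

    def test_decomposition_invariant_by_construction(self):
        t = BindingThermodynamics.from_KD_dH(7.58e-6, -10.04)
        assert t.delta_G == pytest.approx(t.delta_H + t.minus_T_delta_S, abs=1e-12)


class TestRelativeBindingFreeEnergy:
    @pytest.mark.parametrize(
        "ki_a,ki_b,expected",
        [(5.3, 3.9, -0.18), (3.9, 2.1, -0.37)],  # compound 12→17, 17→intronistat A
    )
    def test_printed_ki_pairs(self, ki_a, ki_b, expected):
        rel = ddG_from_Ki(ki_a, ki_b)
        assert round(rel.ddG, 2) == expected

    def test_antisymmetry_exact(self):
        fwd = ddG_from_Ki(5.3, 3.9, 0.2, 0.5)
        rev = ddG_from_Ki(3.9, 5.3, 0.5, 0.2)
        assert fwd.ddG == -rev.ddG
        assert fwd.se == rev.se

    def test_cycle_closure_on_printed_triple(self):
        ab = ddG_from_Ki(5.3, 3.9).ddG
        bc = ddG_from_Ki(3.9, 2.1).ddG
        ac = ddG_from_Ki(5.3, 2.1).ddG
        assert ab + bc == pytest.approx(ac, abs=1e-12)

    def test_delta_method_error(self):
        rel = ddG_from_Ki(5.3, 3.9, 0.2, 0.5)
        cond = ThermoConditions()
        expected = cond.RT * math.sqrt((0.2 / 5.3) ** 2 + (0.5 / 3.9) ** 2)
        assert rel.se == pytest.approx(expected, rel=1e-12)

    def test_identical_ki_is_zero(self):
        assert ddG_from_Ki(2.0, 2.0).ddG == 0.0


def micro_injection_heats(tit, N, Kd, dH, nsub=2000):
    """Independent oracle: each injection as nsub discrete mixing steps at
    constant cell volume, tracking reaction heat explicitly."""
    V0 = tit.cell_volume
    M = tit.cell_concentration * V0  # moles
    X = 0.0
    Xs = tit.syringe_concentration

    def bound_moles(M, X):
        Mt, Xt = M / V0, X / V0
        return _bound_concentration(N, np.array([Mt]), np.array([Xt]), Kd)[0] * V0

    b = bound_moles(M, X)
    heats = []
    for v in tit.injection_volumes:
        dv = v / nsub
        q = 0.0
        for _ in range(nsub):
            f = V0 / (V0 + dv)
            M *= f
            X = (X + Xs * dv) * f
            b_carried = b * f
            b = bound_moles(M, X)
            q += dH * (b - b_carried)
        heats.append(q / (Xs * v))
    return np.array(heats)


class TestITCForwardModel:
    def test_quadratic_bound_matches_mass_action_root(self):
        # cross-check the closed-form bound concentration against brentq on
        # the mass-action equation at scattered conditions
        for N, Mt, Xt, Kd in [
            (1.0, 30e-6, 7.5e-6, 7.58e-6),
            (0.8, 25e-6, 60e-6, 1e-6),
            (2.0, 10e-6, 5e-6, 50e-6),
        ]:
            B = _bound_concentration(N, np.array([Mt]), np.array([Xt]), Kd)[0]
            xfree = brentq(
                lambda x: x + N * Mt * x / (Kd + x) - Xt, 0.0, Xt, xtol=1e-18
            )
            assert B == pytest.approx(Xt - xfree, rel=1e-9, abs=1e-15)

    def test_matches_micro_injection_oracle(self):
        tit = ITCTitration.standard_design()
        analytic = itc_injection_heats(tit, 1.0, 7.58e-6, -10.04)
        oracle = micro_injection_heats(tit, 1.0, 7.58e-6, -10.04, nsub=2000)
        assert np.max(np.abs(analytic - oracle)) < 5e-3

    def test_first_injection_saturation_limit(self):
        # tight binding (c >> 1): each early injection releases ≈ ΔH per mole
        tit = ITCTitration.standard_design()
        heats = itc_injection_heats(tit, 1.0, 1e-10, -10.0)
        assert heats[0] == pytest.approx(-10.0, rel=1e-2)

    def test_total_heat_conservation_at_saturation(self):
        # drive to full saturation: total heat ≈ N·ΔH·(cell moles)
        tit = ITCTitration(
            cell_concentration=30e-6,
            syringe_concentration=6000e-6,
            injection_volumes=np.full(16, 2.5e-6),
            cell_volume=1.4e-3,
        )
        heats = itc_injection_heats(tit, 1.0, 1e-9, -10.0)
        total = float(np.sum(heats * tit.syringe_concentration * tit.injection_volumes))
        expected = 1.0 * -10.0 * tit.cell_concentration * tit.cell_volume
        assert total == pytest.approx(expected, rel=0.01)

    def test_zero_enthalpy_gives_zero_heats(self):
        tit = ITCTitration.standard_design()
        params = BindingThermodynamics(
            K_D=7.58e-6, delta_H=0.0, delta_G=deltaG_from_KD(7.58e-6),
            minus_T_delta_S=minus_T_deltaS(deltaG_from_KD(7.58e-6), 0.0),
        )
        sim = simulate_itc(params, tit)
        assert np.allclose(sim.heats, 0.0)


class TestITCFit:
    def test_noiseless_round_trip(self):
        truth = BindingThermodynamics.from_KD_dH(7.58e-6, -10.04, N=1.0)
        sim = simulate_itc(truth, ITCTitration.standard_design())
        fit = fit_itc_single_site(sim)
        assert fit.thermodynamics.K_D == pytest.approx(7.58e-6, rel=1e-4)
        assert fit.thermodynamics.delta_H == pytest.approx(-10.04, rel=1e-4)
        assert fit.thermodynamics.N == pytest.approx(1.0, rel=1e-4)
        assert fit.thermodynamics.minus_T_delta_S == pytest.approx(3.05, abs=0.05)

    def test_flat_heats_flagged(self):
        tit = ITCTitration.standard_design()
        flat = ITCTitration(
            cell_concentration=tit.cell_concentration,
            syringe_concentration=tit.syringe_concentration,
            injection_volumes=tit.injection_volumes,
            cell_volume=tit.cell_volume,
            heats=np.zeros(16),
        )
        fit = fit_itc_single_site(flat)
        assert fit.non_identifiable

    def test_noisy_recovery(self):
        # 2%-of-|ΔH| heat noise: K_D recovered within 25% (median over seeds)
        truth = BindingThermodynamics.from_KD_dH(7.58e-6, -10.04, N=1.0)
        design = ITCTitration.standard_design()
        errs = []
        for seed in range(100):
            sim = simulate_itc(truth, design, noise_sd=0.02 * 10.04, seed=seed)
            fit = fit_itc_single_site(sim)
            errs.append(abs(fit.thermodynamics.K_D - 7.58e-6) / 7.58e-6)
        assert np.median(errs) < 0.25

    def test_offset_is_recovered(self):
        truth = BindingThermodynamics.from_KD_dH(5e-6, -8.0)
        sim = simulate_itc(truth, ITCTitration.standard_design())
        shifted = ITCTitration(
            cell_concentration=sim.cell_concentration,
            syringe_concentration=sim.syringe_concentration,
            injection_volumes=sim.injection_volumes,
            cell_volume=sim.cell_volume,
            heats=sim.heats + 0.35,
        )
        fit = fit_itc_single_site(shifted)
        assert fit.offset == pytest.approx(0.35, abs=1e-3)
        assert fit.thermodynamics.K_D == pytest.approx(5e-6, rel=1e-3)


PAPER_BLI = BLIKinetics(
    k_on1=10.1, k_on2=132.0, k_off1=0.001, k_off2=0.026, rmax1=0.4, rmax2=0.6
)


class TestBLI:
    def test_kd_is_rate_ratio(self):
        # printed second-phase rates give K_D2 = 0.026/132.0 ≈ 197 μM
        assert PAPER_BLI.K_D2 * 1e6 == pytest.approx(197.0, abs=0.5)
        assert PAPER_BLI.K_D1 * 1e6 == pytest.approx(99.0, abs=0.5)

    def test_noiseless_global_round_trip(self):
        sg = simulate_bli(PAPER_BLI, [12.5e-6, 25e-6, 50e-6, 100e-6])
        fit = fit_bli_biphasic(sg)
        for name in ("k_on1", "k_on2", "k_off1", "k_off2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(PAPER_BLI, name), rel=1e-4
            ), name
        assert fit.K_D1 == pytest.approx(PAPER_BLI.K_D1, rel=1e-3)
        assert fit.K_D2 == pytest.approx(PAPER_BLI.K_D2, rel=1e-3)

    def test_single_phase_nesting(self):
        truth = BLIKinetics(
            k_on1=50.0, k_on2=500.0, k_off1=0.005, k_off2=0.05, rmax1=1.0, rmax2=0.0
        )
        sg = simulate_bli(truth, [12.5e-6, 25e-6, 50e-6, 100e-6])
        fit = fit_bli_biphasic(sg)
        assert fit.single_phase_warning
        assert fit.k_on1 == pytest.approx(50.0, rel=1e-6)
        assert fit.k_off1 == pytest.approx(0.005, rel=1e-6)
        assert fit.rmax2 == pytest.approx(0.0, abs=1e-6)

    def test_requires_three_concentrations(self):
        sg = simulate_bli(PAPER_BLI, [50e-6])
        with pytest.raises(ValueError):
            fit_bli_biphasic(sg)
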