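"""Tests for the thermodynamic-integration estimator and λ-schedule."""

import math

import numpy as np
import pytest
from scipy.special import roots_legendre

from intronkit import (
    LambdaSchedule,
    TIWindowSample,
    ToyAlchemicalSystem,
    assemble_cycle,
    estimate_deltaG,
    gauss_legendre_schedule,
    run_ti,
    sample_dudl,
)

# the published 12-window λ-schedule and its (symmetric) weights
PUBLISHED_NODES = [
    0.00922, 0.04794, 0.11505, 0.20634, 0.31608, 0.43738,
    0.56262, 0.68392, 0.79366, 0.88495, 0.95206, 0.99078,
]
PUBLISHED_HALF_WEIGHTS = [0.02359, 0.05347, 0.08004, 0.10158, 0.11675, 0.12457]


class TestLambdaSchedule:
    def test_midpoint_rule(self):
        s = gauss_legendre_schedule(1)
        assert s.nodes[0] == pytest.approx(0.5)
        assert s.weights[0] == pytest.approx(1.0)

    def test_order_two_nodes(self):
        s = gauss_legendre_schedule(2)
        assert np.allclose(s.nodes, [0.21132, 0.78868], atol=5e-6)

    def test_order_twelve_matches_published_schedule(self):
        s = gauss_legendre_schedule(12)
        assert np.allclose(np.round(s.nodes, 5), PUBLISHED_NODES)
        assert np.allclose(
            np.round(s.weights[:6], 5), PUBLISHED_HALF_WEIGHTS
        )
        assert np.allclose(s.weights, s.weights[::-1])  # mirror symmetry

    @pytest.mark.parametrize("order", range(1, 25))
    def test_matches_reference_tables(self, order):
        s = gauss_legendre_schedule(order)
        x, w = roots_legendre(order)
        assert np.allclose(s.nodes, (x + 1) / 2, atol=1e-10)
        assert np.allclose(s.weights, w / 2, atol=1e-10)

    @pytest.mark.parametrize("order", [0, -1, 65])
    def test_order_out_of_range(self, order):
        with pytest.raises(ValueError):
            gauss_legendre_schedule(order)

    def test_asymmetric_schedule_rejected(self):
        with pytest.raises(ValueError):
            LambdaSchedule(2, np.array([0.2, 0.7]), np.array([0.5, 0.5]))


HARMONIC_14 = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 4.0})


class TestQuadratureEstimate:
    def test_exact_on_polynomial_integrands(self):
        # Gauss-Legendre of order n integrates degree <= 2n-1 exactly
        rng = np.random.default_rng(7)
        for order in (3, 8, 12):
            sched = gauss_legendre_schedule(order)
            coeffs = rng.normal(size=2 * order)  # degree 2n-1
            poly = np.polynomial.Polynomial(coeffs)
            samples = [
                TIWindowSample(lam=l, mean_dudl=poly(l), var_dudl=0.0, ess=1.0, n_samples=1)
                for l in sched.nodes
            ]
            dG, se = estimate_deltaG(sched, samples)
            exact = poly.integ()(1.0) - poly.integ()(0.0)
            assert abs(dG - exact) < 1e-12
            assert se == 0.0

    def test_closed_form_window_means_recover_harmonic_deltaG(self):
        sched = gauss_legendre_schedule(12)
        samples = [
            TIWindowSample(
                lam=l, mean_dudl=HARMONIC_14.exact_mean_dudl(l),
                var_dudl=0.0, ess=1.0, n_samples=1,
            )
            for l in sched.nodes
        ]
        dG, _ = estimate_deltaG(sched, samples)
        assert dG == pytest.approx(0.5 * math.log(4.0), abs=1e-6)

    def test_schedule_sample_mismatch_rejected(self):
        sched = gauss_legendre_schedule(2)
        bad = [TIWindowSample(0.3, 0.0, 0.0, 1.0, 1), TIWindowSample(0.7, 0.0, 0.0, 1.0, 1)]
        with pytest.raises(ValueError):
            estimate_deltaG(sched, bad)


class TestSampler:
    def test_window_mean_matches_gaussian_moment(self):
        # ⟨∂U/∂λ⟩ = (k_B−k_A)·kT/(2 k(λ)) for the stiffness morph
        for lam in (0.2, 0.5, 0.9):
            s = sample_dudl(HARMONIC_14, lam, n_steps=20000, seed=11)
            exact = HARMONIC_14.exact_mean_dudl(lam)
            se = math.sqrt(s.var_dudl / s.ess)
            assert abs(s.mean_dudl - exact) <= 3 * se

    def test_identical_end_states_give_zero_dudl(self):
        system = ToyAlchemicalSystem("harmonic_stiffness", {"k": 2.0}, {"k": 2.0})
        s = sample_dudl(system, 0.5, n_steps=500, seed=3)
        assert s.mean_dudl == 0.0
        assert s.var_dudl == 0.0

    def test_seed_determinism_is_bitwise(self):
        a = sample_dudl(HARMONIC_14, 0.3, n_steps=2000, seed=99)
        b = sample_dudl(HARMONIC_14, 0.3, n_steps=2000, seed=99)
        assert a == b

    def test_acceptance_rate_is_tuned(self):
        s = sample_dudl(HARMONIC_14, 0.5, n_steps=5000, seed=5)
        assert 0.1 <= s.acceptance_rate <= 0.9
        assert not s.acceptance_warning

    def test_ess_at_least_one(self):
        s = sample_dudl(HARMONIC_14, 0.5, n_steps=100, seed=1)
        assert s.ess >= 1.0


class TestClosedFormOracles:
    def test_harmonic_free_energy(self):
        assert HARMONIC_14.exact_deltaG() == pytest.approx(0.5 * math.log(4.0))
        d3 = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 4.0}, dim=3)
        assert d3.exact_deltaG() == pytest.approx(1.5 * math.log(4.0))

    def test_shifted_well_free_energy_is_zero_but_dudl_is_not(self):
        sys_ = ToyAlchemicalSystem(
            "shifted_well", {"k": 2.0, "x0": 0.0}, {"k": 2.0, "x0": 1.5}
        )
        assert sys_.exact_deltaG() == 0.0
        assert sys_.exact_mean_dudl(0.25) != 0.0
        sched = gauss_legendre_schedule(8)
        samples = [
            TIWindowSample(l, sys_.exact_mean_dudl(l), 0.0, 1.0, 1) for l in sched.nodes
        ]
        dG, _ = estimate_deltaG(sched, samples)
        assert dG == pytest.approx(0.0, abs=1e-12)

    def test_linear_field_free_energy(self):
        sys_ = ToyAlchemicalSystem(
            "linear_field", {"k": 2.0, "b": 0.0}, {"k": 2.0, "b": 1.0}
        )
        assert sys_.exact_deltaG() == pytest.approx(-0.25)
        sched = gauss_legendre_schedule(4)
        samples = [
            TIWindowSample(l, sys_.exact_mean_dudl(l), 0.0, 1.0, 1) for l in sched.nodes
        ]
        dG, _ = estimate_deltaG(sched, samples)
        assert dG == pytest.approx(-0.25, abs=1e-12)


class TestCycle:
    def test_assembly_arithmetic(self):
        c = assemble_cycle((-5.0, 0.1), (-3.0, 0.1))
        assert c.ddG == pytest.approx(-2.0)
        assert c.se == pytest.approx(math.sqrt(0.02))

    def test_equal_legs_cancel(self):
        assert assemble_cycle((-4.2, 0.0), (-4.2, 0.0)).ddG == 0.0

    def test_null_transformation(self):
        system = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 3.0})
        cycle, _ = run_ti(system, system, n_steps=2000, seed=21)
        assert abs(cycle.ddG) <= 3 * max(cycle.se, 1e-12)

    def test_known_difference_of_legs(self):
        bound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 4.0})
        unbound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 2.0})
        cycle, _ = run_ti(bound, unbound, n_steps=4000, seed=8)
        exact = 0.5 * math.log(4.0) - 0.5 * math.log(2.0)
        assert abs(cycle.ddG - exact) <= 3 * cycle.se

    def test_reversal_antisymmetry(self):
        bound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 4.0})
        unbound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 2.0})
        fwd, _ = run_ti(bound, unbound, n_steps=3000, seed=13)
        rev, _ = run_ti(bound.reversed(), unbound.reversed(), n_steps=3000, seed=14)
        combined = math.hypot(fwd.se, rev.se)
        assert abs(fwd.ddG + rev.ddG) <= 3 * combined

    def test_three_state_cycle_closure(self):
        kA, kB, kC = 1.0, 2.5, 4.0
        ref = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 1.0})

        def leg(ka, kb, seed):
            sys_ = ToyAlchemicalSystem("harmonic_stiffness", {"k": ka}, {"k": kb})
            cycle, _ = run_ti(sys_, ref, n_steps=3000, seed=seed)
            return cycle

        ab, bc, ca = leg(kA, kB, 31), leg(kB, kC, 32), leg(kC, kA, 33)
        total = ab.ddG + bc.ddG + ca.ddG
        se = math.sqrt(ab.se**2 + bc.se**2 + ca.se**2)
        assert abs(total) <= 3 * se

    def test_run_ti_seed_determinism(self):
        bound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 4.0})
        unbound = ToyAlchemicalSystem("harmonic_stiffness", {"k": 1.0}, {"k": 2.0})
        c1, _ = run_ti(bound, unbound, n_steps=1000, seed=5)
        c2, _ = run_ti(bound, unbound, n_steps=1000, seed=5)
        assert c1 == c2


def test_monte_carlo_error_shrinks_with_sample_size():
    """TI error scales roughly as 1/sqrt(n) over a seed ensemble."""
    sched = gauss_legendre_schedule(6)
    exact = HARMONIC_14.exact_deltaG()

    def rms(n_steps, seeds):
        errs = []
        for seed in seeds:
            samples = [
                sample_dudl(HARMONIC_14, l, n_steps=n_steps, seed=seed * 100 + i)
                for i, l in enumerate(sched.nodes)
            ]
            dG, _ = estimate_deltaG(sched, samples)
            errs.append((dG - exact) ** 2)
        return math.sqrt(float(np.mean(errs)))

    small = rms(250, range(12))
    large = rms(4000, range(12))
    assert large < small / 2  # expected factor 4 for a 16x sample increase
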