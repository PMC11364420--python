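"""Fragmentation-kernel unit and property tests."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depolysim import (
    EnzymePool,
    KineticParams,
    PolymerPool,
    degradation_time,
    depoly_flux,
    endo_rates,
    exo_rates,
    fragmentation_flux,
    fragmentation_step,
    init_pool,
    integrate_pbe,
)
from depolysim.params import ValidationError


class TestInitPool:
    @pytest.mark.parametrize(
        "M, n, expect_class, expect_conc",
        [
            (300.0, 200, 200, 1.5),   # reference substrate pool
            (500.0, 500, 500, 1.0),
            (7.0, 1, 1, 7.0),         # degenerate: pure monomers
        ],
    )
    def test_monodisperse_concentration(self, M, n, expect_class, expect_conc):
        pool = init_pool(M, n)
        assert pool.N[expect_class - 1] == pytest.approx(expect_conc)
        assert pool.total_mass == pytest.approx(M)
        assert np.count_nonzero(pool.N) == 1

    @pytest.mark.parametrize("M, n", [(-1.0, 10), (0.0, 10), (10.0, 0), (10.0, -3)])
    def test_invalid_inputs_rejected(self, M, n):
        with pytest.raises(ValidationError):
            init_pool(M, n)

    def test_n_max_cannot_be_below_n(self):
        with pytest.raises(ValidationError):
            init_pool(10.0, 20, n_max=10)


class TestRateLaws:
    def test_exo_rate_reference_value(self, kin):
        # k*E*N/(km + chains) = 0.82*3*1.5/(0.5+1.5)
        pool = init_pool(300.0, 200)
        v = exo_rates(pool, 3.0, kin)
        assert v[199] == pytest.approx(1.845)
        assert v[0] == 0.0

    def test_endo_rate_reference_value(self, kin):
        # k*(i-1)*E*N/(km + bonds) = 0.82*199*3*1.5/(0.5+199*1.5)
        pool = init_pool(300.0, 200)
        v = endo_rates(pool, 3.0, kin)
        assert v[199] == pytest.approx(0.82 * 3 * 199 * 1.5 / (0.5 + 199 * 1.5))
        assert v[199] == pytest.approx(2.4559, abs=1e-4)

    def test_endo_rate_hand_arithmetic(self, kin_unit):
        pool = PolymerPool([0.0, 0.0, 1.0])
        assert endo_rates(pool, 1.0, kin_unit)[2] == pytest.approx(0.8)

    def test_no_enzyme_means_no_rates(self, kin):
        pool = init_pool(300.0, 200)
        assert np.all(exo_rates(pool, 0.0, kin) == 0.0)
        assert np.all(endo_rates(pool, 0.0, kin) == 0.0)

    def test_pure_monomers_are_inert(self, kin):
        pool = init_pool(7.0, 1)
        assert np.all(exo_rates(pool, 5.0, kin) == 0.0)
        assert np.all(endo_rates(pool, 5.0, kin) == 0.0)

    def test_monomer_inclusive_denominator_switch(self):
        # the alternative reading of the saturation term lowers exo rates
        pool = PolymerPool([2.0, 0.0, 1.0])
        base = KineticParams()
        alt = KineticParams(exo_denominator_includes_monomers=True)
        v_base = exo_rates(pool, 1.0, base)[2]
        v_alt = exo_rates(pool, 1.0, alt)[2]
        assert v_alt == pytest.approx(v_base * (0.5 + 1.0) / (0.5 + 3.0))


class TestFragmentationFlux:
    def test_zero_enzymes_zero_flux(self, kin):
        pool = init_pool(300.0, 200)
        assert np.all(depoly_flux(pool, EnzymePool(), kin) == 0.0)

    def test_endo_trimer_kernel(self, kin_unit):
        # one cut of a trimer yields (1,2) or (2,1): classes 1 and 2 each
        # gain the full event rate
        pool = PolymerPool([0.0, 0.0, 1.0])
        dN = depoly_flux(pool, EnzymePool(E_endo=1.0), kin_unit)
        assert dN == pytest.approx([0.8, 0.8, -0.8])

    def test_exo_trimer_kernel(self, kin_unit):
        pool = PolymerPool([0.0, 0.0, 1.0])
        dN = depoly_flux(pool, EnzymePool(E_exo=1.0), kin_unit)
        v = 1.0 / 1.5
        assert dN == pytest.approx([v, v, -v])

    def test_exo_dimer_yields_two_monomers(self, kin_unit):
        pool = PolymerPool([0.0, 1.0])
        dN = depoly_flux(pool, EnzymePool(E_exo=1.0), kin_unit)
        v = 1.0 / 1.5
        assert dN == pytest.approx([2 * v, -v])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        data=st.lists(st.floats(0.0, 5.0), min_size=2, max_size=40),
        E_exo=st.floats(0.0, 10.0),
        E_endo=st.floats(0.0, 10.0),
    )
    def test_mass_conservation_property(self, data, E_exo, E_endo):
        """sum_i i * (dN/dt)_i = 0 for any pool and enzyme mix."""
        N = np.asarray(data)
        kin = KineticParams()
        dN = fragmentation_flux(N, E_exo, E_endo, kin)
        sizes = np.arange(1, N.size + 1)
        scale = max(float(np.abs(sizes * N).sum()), 1.0)
        assert abs(float(sizes @ dN)) <= 1e-12 * max(scale, 1.0) * 10

    def test_capped_step_preserves_mass_and_positivity(self, kin):
        # a deliberately oversized step must throttle, not go negative
        N = np.array([0.0, 1e-9, 0.0, 2.0])
        out = fragmentation_step(N, 5.0, 5.0, kin, dt=5.0)
        sizes = np.arange(1, 5)
        assert np.all(out >= 0.0)
        assert float(sizes @ out) == pytest.approx(float(sizes @ N), rel=1e-12)


class TestIntegration:
    def test_no_enzymes_is_a_fixed_point(self, kin):
        traj = integrate_pbe(init_pool(300.0, 200), EnzymePool(), kin, t_end=50.0)
        assert np.allclose(traj.N, traj.N[0], atol=1e-12)

    def test_mass_conserved_along_trajectory(self, kin):
        traj = integrate_pbe(
            init_pool(300.0, 200), EnzymePool(E_exo=1.5, E_endo=1.5), kin, t_end=200.0
        )
        assert np.max(np.abs(traj.total_mass - 300.0)) / 300.0 <= 1e-6
        assert np.min(traj.N) >= 0.0

    def test_dimer_pool_exo_endo_coincidence(self, kin):
        """A dimer has one bond: both kernels cut it into two monomers at
        the same Michaelis-Menten rate, so the trajectories coincide."""
        pool = PolymerPool([0.0, 2.0])
        tx = integrate_pbe(pool.copy(), EnzymePool(E_exo=1.0), kin, t_end=10.0,
                           stop_at_completion=False)
        tn = integrate_pbe(pool.copy(), EnzymePool(E_endo=1.0), kin, t_end=10.0,
                           stop_at_completion=False)
        assert np.allclose(tx.N, tn.N, rtol=1e-7, atol=1e-10)

    def test_exo_release_rate_is_constant(self, kin):
        """End-cleaving enzymes release monomers at a constant rate while
        the chain count is unchanged."""
        traj = integrate_pbe(init_pool(300.0, 200), EnzymePool(E_exo=3.0), kin,
                             t_end=120.0, stop_at_completion=False, n_samples=120)
        t, N1 = traj.t, traj.monomers
        mask = t <= 100.0
        slope, _ = np.polyfit(t[mask], N1[mask], 1)
        assert slope == pytest.approx(1.845, rel=1e-3)
        resid = N1[mask] - slope * t[mask]
        assert np.max(np.abs(resid)) < 0.05

    def test_endo_release_is_initially_convex(self, kin):
        """Random scission has a monomer-production lag: N_1(t) is convex
        over the early part of the run."""
        traj = integrate_pbe(init_pool(300.0, 200), EnzymePool(E_endo=3.0), kin,
                             t_end=15.0, stop_at_completion=False, n_samples=100)
        d2 = np.diff(traj.monomers, 2)
        assert np.all(d2 > 0)

    def test_endo_early_yield_decreases_with_concentration(self, kin):
        """Higher polymer loads dilute the per-bond cut rate, so fewer
        monomers appear in a fixed early window."""
        yields = []
        for M in (150.0, 300.0, 600.0):
            traj = integrate_pbe(init_pool(M, 200), EnzymePool(E_endo=3.0), kin,
                                 t_end=20.0, stop_at_completion=False)
            yields.append(traj.monomers[-1])
        assert yields[0] > yields[1] > yields[2]


class TestDegradationTime:
    def test_all_monomer_pool_is_already_degraded(self, kin):
        traj = integrate_pbe(init_pool(5.0, 1), EnzymePool(E_exo=1.0), kin, t_end=1.0)
        assert degradation_time(traj) == 0.0

    def test_not_reached_returns_infinity(self, kin):
        traj = integrate_pbe(init_pool(300.0, 200), EnzymePool(E_exo=3.0), kin, t_end=5.0)
        assert math.isinf(degradation_time(traj))
        assert not traj.degraded

    def test_endo_faster_than_exo_for_long_chains(self, kin):
        tx = integrate_pbe(init_pool(300.0, 200), EnzymePool(E_exo=3.0), kin, t_end=400.0)
        tn = integrate_pbe(init_pool(300.0, 200), EnzymePool(E_endo=3.0), kin, t_end=400.0)
        assert degradation_time(tn) < degradation_time(tx)
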