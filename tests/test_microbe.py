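"""Stoichiometric growth model: flux arithmetic, budget closure, dynamics."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depolysim import (
    EnzymePool,
    KineticParams,
    MetabolicParams,
    MicrobeState,
    WellMixedState,
    death_check,
    enzyme_decay,
    init_pool,
    integrate_pbe,
    partition_metabolism,
    produce_enzymes,
    uptake,
    wellmixed_step,
)
from depolysim import GrowthConfig, run_wellmixed
from depolysim.params import ValidationError


class TestUptake:
    def test_surface_limited_demand(self):
        # V_u * C_b^(2/3) * N1/(K_u+N1): 1 * 4 * 0.5 = 2 when substrate is ample
        p = MetabolicParams(V_u=1.0, a_u=2 / 3, K_u=0.5)
        C_up, _ = uptake(N_1=100.0, DIN=0.0, C_b=8.0, p=p, dt=1.0)
        # at N1 >> K_u the Michaelis-Menten factor saturates near 1
        assert C_up == pytest.approx(1.0 * 4.0 * 100.0 / 100.5)
        C_up, _ = uptake(N_1=0.5, DIN=0.0, C_b=8.0, p=p, dt=0.1)
        assert C_up == pytest.approx(0.2)  # demand 2/h, not yet pool-limited

    def test_capped_at_available_pool(self):
        p = MetabolicParams(V_u=1.0, a_u=2 / 3, K_u=0.5)
        C_up, N_up = uptake(N_1=0.5, DIN=0.3, C_b=8.0, p=p, dt=1.0)
        assert C_up == pytest.approx(0.5)   # demand 2 exceeds the pool
        assert N_up == pytest.approx(0.3)

    def test_no_substrate_or_no_biomass(self, metab):
        assert uptake(0.0, 0.0, 10.0, metab, 1.0) == (0.0, 0.0)
        C_up, N_up = uptake(5.0, 5.0, 0.0, metab, 1.0)
        assert C_up == 0.0 and N_up == 0.0

    def test_negative_dt_rejected(self, metab):
        with pytest.raises(ValidationError):
            uptake(1.0, 1.0, 1.0, metab, -0.5)


class TestPartition:
    def test_reference_budget(self):
        """Maintenance first, then enzyme allocation, then growth; leftovers
        respired (C) or returned to DIN (N)."""
        p = MetabolicParams(m=0.008, f_e=0.25, gamma_e=0.2, gamma_g=0.2,
                            CN_e=3.0, CN_m=8.0)
        rec = partition_metabolism(10.0, 10.0, C_b=250.0, p=p, dt=1.0)
        assert rec.C_maintenance == pytest.approx(2.0)
        assert rec.C_enzyme == pytest.approx(1.6)
        assert rec.N_enzyme == pytest.approx(1.6 / 3)
        assert rec.C_growth == pytest.approx(4.8)
        assert rec.N_growth == pytest.approx(0.6)
        assert rec.C_respired == pytest.approx(0.4 + 1.2)
        assert rec.N_to_DIN == pytest.approx(10 - 1.6 / 3 - 0.6)

    def test_zero_fluxes_zero_record(self):
        p = MetabolicParams(m=0.0)
        rec = partition_metabolism(0.0, 0.0, 5.0, p, 1.0)
        for name in ("C_maintenance", "C_enzyme", "C_growth", "C_respired", "N_to_DIN"):
            assert getattr(rec, name) == 0.0

    def test_nitrogen_starvation_blocks_anabolism(self, metab):
        """With no N, enzyme production and growth stop; post-maintenance
        carbon is respired and biomass is not built."""
        rec = partition_metabolism(10.0, 0.0, 10.0, metab, 1.0)
        assert rec.C_enzyme == 0.0
        assert rec.C_growth == 0.0
        maint = metab.m * 10.0
        assert rec.C_respired == pytest.approx(10.0 - maint)

    def test_maintenance_deficit_drawn_from_biomass(self, metab):
        rec = partition_metabolism(0.0, 0.0, 10.0, metab, 1.0)
        assert rec.C_drawn_from_biomass == pytest.approx(metab.m * 10.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        C_up=st.floats(0.0, 50.0),
        N_up=st.floats(0.0, 50.0),
        C_b=st.floats(0.0, 100.0),
        f_e=st.floats(0.0, 0.9),
        gamma=st.floats(0.0, 0.9),
        cn_e=st.floats(1.0, 20.0),
        cn_m=st.floats(1.0, 20.0),
    )
    def test_budgets_close_exactly(self, C_up, N_up, C_b, f_e, gamma, cn_e, cn_m):
        p = MetabolicParams(f_e=f_e, gamma_e=gamma, gamma_g=gamma,
                            CN_e=cn_e, CN_m=cn_m)
        rec = partition_metabolism(C_up, N_up, C_b, p, 1.0)
        assert abs(rec.carbon_closure()) < 1e-10 * max(C_up + C_b, 1.0)
        assert abs(rec.nitrogen_closure()) < 1e-10 * max(N_up, 1.0)
        assert rec.C_growth >= 0 and rec.C_enzyme >= 0


class TestEnzymeHandling:
    @pytest.mark.parametrize("fr, expected", [(1.0, (1.0, 0.0)), (0.0, (0.0, 1.0)),
                                              (0.8, (0.8, 0.2))])
    def test_production_split(self, fr, expected):
        assert produce_enzymes(1.0, fr) == pytest.approx(expected)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValidationError):
            produce_enzymes(1.0, 1.5)

    def test_exponential_decay(self):
        assert enzyme_decay(3.0, 0.1, 1.0) == pytest.approx(3.0 * math.exp(-0.1))
        assert enzyme_decay(3.0, 0.0, 5.0) == 3.0
        assert enzyme_decay(0.0, 0.5, 5.0) == 0.0


class TestDeath:
    def test_threshold_boundary_inclusive(self):
        p = MetabolicParams()
        assert death_check(MicrobeState(C_b=p.C_min), p).alive
        assert not death_check(MicrobeState(C_b=0.99 * p.C_min), p).alive
        assert death_check(MicrobeState(C_b=10 * p.C_min), p).alive

    def test_dead_biomass_removed(self):
        p = MetabolicParams()
        s = death_check(MicrobeState(C_b=0.5 * p.C_min), p)
        assert s.C_b == 0.0 and not s.alive


class TestWellMixedStep:
    def test_reduces_to_pbe_without_microbes(self, kin):
        """A dead/absent population with non-decaying enzymes is exactly an
        enzyme-only degradation run."""
        p = MetabolicParams(r_e=0.0)
        state = WellMixedState(N=init_pool(100.0, 50).N, E_exo=1.0, E_endo=1.0,
                               C_b=0.0, DIN=0.0, alive=False)
        for _ in range(500):
            wellmixed_step(state, p, kin, dt=0.01)
        traj = integrate_pbe(init_pool(100.0, 50), EnzymePool(E_exo=1.0, E_endo=1.0),
                             kin, t_end=5.0, stop_at_completion=False)
        assert state.N[0] == pytest.approx(traj.monomers[-1], rel=2e-3)

    def test_dead_microbe_no_enzymes_is_fixed_point(self, kin, metab):
        state = WellMixedState(N=init_pool(100.0, 50).N, E_exo=0.0, E_endo=0.0,
                               C_b=0.0, DIN=3.0, alive=False)
        N0 = state.N.copy()
        for _ in range(10):
            wellmixed_step(state, metab, kin, dt=0.1)
        assert np.array_equal(state.N, N0)
        assert state.DIN == 3.0

    def test_carbon_and_nitrogen_ledgers_closed(self, kin, metab):
        state = WellMixedState(N=init_pool(300.0, 100).N, E_exo=0.5, E_endo=0.5,
                               C_b=10.0, DIN=50.0)
        C0 = state.total_carbon()
        N0 = state.total_nitrogen(metab)
        for _ in range(2000):
            wellmixed_step(state, metab, kin, dt=0.1)
        assert state.total_carbon() == pytest.approx(C0, rel=1e-9)
        assert state.total_nitrogen(metab) == pytest.approx(N0, rel=1e-9)

    def test_starvation_is_monotonic_and_fatal(self, kin):
        """Without substrate or DIN the biomass declines at the
        maintenance rate until the population dies."""
        p = MetabolicParams()
        state = WellMixedState(N=np.zeros(10), E_exo=0.0, E_endo=0.0,
                               C_b=1.0, DIN=0.0)
        series = [state.C_b]
        while state.alive:
            wellmixed_step(state, p, kin, dt=0.5)
            series.append(state.C_b)
            assert state.t < 500.0, "population failed to die in finite time"
        assert all(b2 <= b1 for b1, b2 in zip(series, series[1:]))
        # decline follows exp(-m t) until the death threshold
        assert series[1] == pytest.approx(1.0 - p.m * 0.5, rel=1e-6)


class TestWellMixedScenario:
    def test_growth_run_reports_consistent_metrics(self, kin):
        cfg = GrowthConfig(M=1000.0, n=500, t_end=200.0)
        res = run_wellmixed(MetabolicParams(fr_exo=1.0), kin, cfg)
        ts = res.timeseries
        assert res.metrics["max_biomass"] == pytest.approx(ts["C_b"].max())
        assert res.metrics["survived"] == (ts["C_b"].max() >= 2 * cfg.C_b0)

    def test_specialist_niches_are_opposite(self, kin):
        """End-cleaver producers starve when chains are scarce; random-
        scission producers fail when the pool is large (monomer lag)."""
        exo_low = run_wellmixed(MetabolicParams(fr_exo=1.0), kin, GrowthConfig(M=150.0))
        exo_high = run_wellmixed(MetabolicParams(fr_exo=1.0), kin, GrowthConfig(M=1500.0))
        endo_low = run_wellmixed(MetabolicParams(fr_exo=0.0), kin, GrowthConfig(M=150.0))
        endo_high = run_wellmixed(MetabolicParams(fr_exo=0.0), kin, GrowthConfig(M=1500.0))
        assert not exo_low.metrics["survived"] and exo_high.metrics["survived"]
        assert endo_low.metrics["survived"] and not endo_high.metrics["survived"]
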