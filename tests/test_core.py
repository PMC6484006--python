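"""Pool-and-flux engine: single-step arithmetic, mass balance, steady states,
spin-up and batch runs."""

import math

import numpy as np
import pytest

from somic import (
    ConvergenceError,
    ForcingRecord,
    InvalidInputError,
    ModelParams,
    PoolState,
    effective_rates,
    equilibrate,
    run,
    run_many,
    step,
    total_soc,
)
from somic.rate_modifiers import (
    carbon_use_efficiency,
    moisture_modifier,
    sorbed_fraction,
    temperature_modifier,
)


def hand_coded_euler(state, f, p, dt):
    """Independent single-Euler-step oracle, written directly from the pool
    balance equations with no shared code path."""
    ft = temperature_modifier(f.temp, p.modifiers)
    fw = moisture_modifier(f.moisture, p.modifiers)
    fmb = state.mb / (p.modifiers.k_m + state.mb)
    cue = carbon_use_efficiency(f.temp, p.modifiers)
    fsorb = sorbed_fraction(f.clay, p.modifiers)
    k1p, k2p, k3p, k4p = (k * ft * fw * fmb for k in (p.k1, p.k2, p.k3, p.k4))
    k5p = p.k5 * ft * fw
    L = f.litter
    dc1 = p.f_s * L - k1p * state.spm
    dc2 = (1 - p.f_s) * L - k2p * state.ipm
    dc3 = (k1p * state.spm + k2p * state.ipm + k4p * state.mac + k5p * state.mb
           - k3p * state.doc)
    dc4 = fsorb * k3p * state.doc - k4p * state.mac
    dc5 = cue * (1 - fsorb) * k3p * state.doc - k5p * state.mb
    co2 = (1 - cue) * (1 - fsorb) * k3p * state.doc * dt
    return (
        PoolState(
            state.spm + dc1 * dt, state.ipm + dc2 * dt, state.doc + dc3 * dt,
            state.mac + dc4 * dt, state.mb + dc5 * dt,
        ),
        co2,
    )


class TestEffectiveRates:
    def test_zero_biomass_freezes_all_but_microbial_turnover(self, released):
        st = PoolState(1, 1, 1, 1, 0.0)
        f = ForcingRecord(time=0, temp=15, moisture=1.0, litter=0, clay=0.2)
        k = effective_rates(st, f, released)
        assert np.all(k[:4] == 0.0)
        assert k[4] == pytest.approx(released.k5)

    def test_saturation_limit_recovers_base_rates(self, released):
        st = PoolState(1, 1, 1, 1, 1e12)
        f = ForcingRecord(time=0, temp=15, moisture=1.0, litter=0, clay=0.2)
        k = effective_rates(st, f, released)
        assert k == pytest.approx(released.base_rates(), rel=1e-10)

    def test_direct_arithmetic_oracle(self):
        # f_mb = 0.5 at mb = k_m; temperature/moisture chosen for f_T*f_w = 2*0.8
        p = ModelParams(k1=0.1).with_(w_min=0.0, q10=4.0)
        st = PoolState(1, 1, 1, 1, p.modifiers.k_m)
        f = ForcingRecord(time=0, temp=20.0, moisture=0.8, litter=0, clay=0.0)
        k = effective_rates(st, f, p)
        assert k[0] == pytest.approx(0.8 * p.k1)


class TestStep:
    def test_empty_system_stays_empty(self, released):
        f = ForcingRecord(time=0, temp=10, moisture=0.5, litter=0.0, clay=0.2)
        new, fl = step(PoolState(), f, released)
        assert new.total() == 0.0
        assert fl.co2 == 0.0

    def test_full_cue_suppresses_respiration(self, constant_forcing):
        p = ModelParams().with_(cue_ref=0.999999, cue_slope=0.0)
        # cue -> 1 makes the CO2 factor (1 - CUE) vanish
        st = PoolState(1, 1, 5, 1, 2)
        new, fl = step(st, constant_forcing(1)[0], p)
        assert fl.co2 == pytest.approx(0.0, abs=1e-4)
        assert fl.uptake > 0

    def test_matches_hand_coded_euler_oracle(self, released):
        st = PoolState(0.4, 9.0, 0.8, 55.0, 1.1)
        f = ForcingRecord(time=0, temp=8.0, moisture=0.7, litter=0.3, clay=0.25)
        dt = 0.05  # below the sub-stepping threshold for every rate
        oracle_state, oracle_co2 = hand_coded_euler(st, f, released, dt)
        new, fl = step(st, f, released, dt=dt)
        assert new.as_array() == pytest.approx(oracle_state.as_array(), rel=1e-12)
        assert fl.co2 == pytest.approx(oracle_co2, rel=1e-12)

    def test_mass_balance_over_randomized_steps(self, released):
        """Per-step conservation: d(total SOC) = inputs - CO2, <=1e-10 relative,
        over 1e4 random states and drivers."""
        rng = np.random.default_rng(1)
        worst = 0.0
        for _ in range(10_000):
            st = PoolState(*rng.uniform(0, 80, 5))
            f = ForcingRecord(
                time=0, temp=rng.uniform(-5, 35), moisture=rng.uniform(0, 1),
                litter=rng.uniform(0, 1), clay=rng.uniform(0, 1),
                amendment=rng.uniform(0, 0.5),
            )
            new, fl = step(st, f, released)
            resid = (new.total() - st.total()) - (fl.total_in() - fl.co2)
            worst = max(worst, abs(resid) / max(1.0, st.total()))
        assert worst <= 1e-10

    def test_non_negative_under_admissible_forcing(self, released):
        rng = np.random.default_rng(2)
        st = PoolState(*rng.uniform(0, 30, 5))
        for t in range(500):
            f = ForcingRecord(
                time=t, temp=rng.uniform(-10, 40), moisture=rng.uniform(0, 1),
                litter=rng.uniform(0, 2), clay=rng.uniform(0, 1),
            )
            st, fl = step(st, f, released)
            assert min(st.as_array()) >= 0.0
            assert fl.clipped == 0.0

    def test_rejects_non_positive_dt(self, released, constant_forcing):
        with pytest.raises(InvalidInputError):
            step(PoolState(), constant_forcing(1)[0], released, dt=0.0)

    def test_sorption_shortcircuit_when_fsorb_is_one(self, constant_forcing):
        p = ModelParams().with_(s0=1.0, s1=0.0)
        st = PoolState(1, 1, 5, 1, 2)
        _, fl = step(st, constant_forcing(1)[0], p)
        assert fl.co2 == 0.0
        assert fl.uptake == 0.0
        assert fl.sorption > 0


class TestRun:
    def test_equals_manual_fold_of_step(self, released, constant_forcing):
        forcing = constant_forcing(36, litter=0.3)
        traj = run(PoolState(1, 5, 0.5, 30, 1), forcing, released)
        st = PoolState(1, 5, 0.5, 30, 1)
        for j, f in enumerate(forcing):
            st, _ = step(st, f, released)
            assert traj.states[j] == st
        assert len(traj) == len(forcing)

    def test_no_input_soc_never_increases(self, released, constant_forcing):
        traj = run(PoolState(2, 10, 1, 40, 1.5), constant_forcing(120, litter=0.0), released)
        soc = traj.total_soc()
        assert np.all(np.diff(soc) <= 1e-12)

    def test_steady_state_co2_matches_input_rate(self, released, constant_forcing):
        f = constant_forcing(1, litter=0.25)[0]
        st = equilibrate([f], released, tol=1e-12, max_cycles=50_000)
        _, fl = step(st, f, released)
        assert fl.co2 == pytest.approx(0.25, rel=1e-6)

    def test_rejects_empty_forcing(self, released):
        with pytest.raises(InvalidInputError):
            run(PoolState(), [], released)


class TestEquilibrate:
    def test_zero_input_from_empty_state_stays_empty(self, released, constant_forcing):
        st = equilibrate(constant_forcing(12, litter=0.0), released, tol=1e-10,
                         init=PoolState())
        assert st.total() == 0.0

    def test_zero_input_starves_microbes_and_freezes_decomposition(
        self, released, constant_forcing
    ):
        # reverse-MM kinetics: with no C input the microbial pool starves and
        # the remaining pools freeze rather than decaying to zero
        st = equilibrate(constant_forcing(12, litter=0.0), released, tol=1e-12,
                         init=PoolState(1, 1, 0, 1, 1), max_cycles=50_000)
        assert st.mb == pytest.approx(0.0, abs=1e-6)
        assert st.ipm > 0.5

    def test_agrees_with_long_run_tail(self, released, constant_forcing):
        cycle = constant_forcing(12, litter=0.25)
        st = equilibrate(cycle, released, tol=1e-9)
        long_forcing = constant_forcing(600, litter=0.25)
        long = run(st, long_forcing, released)
        assert long.states[-1].as_array() == pytest.approx(st.as_array(), rel=1e-6)

    def test_fixed_point_unique_across_initial_states(self, released, constant_forcing):
        cycle = constant_forcing(12, litter=0.25)
        tol = 1e-9
        a = equilibrate(cycle, released, tol=tol, init=PoolState(0.1, 0.1, 0.1, 1, 0.5),
                        max_cycles=100_000)
        b = equilibrate(cycle, released, tol=tol, init=PoolState(10, 50, 5, 200, 5),
                        max_cycles=100_000)
        assert a.as_array() == pytest.approx(b.as_array(), rel=1e-3)

    def test_non_convergence_raises_with_state(self, released, constant_forcing):
        with pytest.raises(ConvergenceError) as exc:
            equilibrate(constant_forcing(12, litter=0.25), released, tol=1e-14,
                        max_cycles=2, init=PoolState(1, 1, 1, 1, 1))
        assert isinstance(exc.value.state, PoolState)

    def test_halved_inputs_lengthen_realized_mac_residence(self, released, constant_forcing):
        """Microbial feedback: lower litter supply shrinks the microbial pool,
        which slows MAC turnover (longer realized MRT)."""
        f_full = constant_forcing(1, litter=0.25)[0]
        f_half = constant_forcing(1, litter=0.125)[0]
        st_full = equilibrate([f_full], released, tol=1e-10, max_cycles=50_000)
        st_half = equilibrate([f_half], released, tol=1e-10, max_cycles=50_000)
        k4_full = effective_rates(st_full, f_full, released)[3]
        k4_half = effective_rates(st_half, f_half, released)[3]
        assert 1.0 / k4_half > 1.0 / k4_full


class TestTotalSocAndBatch:
    def test_total_soc_is_component_sum(self, random_state):
        make, _ = random_state
        assert total_soc(PoolState(1, 1, 1, 1, 1)) == 5.0
        assert total_soc(PoolState()) == 0.0
        st = make()
        assert total_soc(st) == pytest.approx(st.as_array().sum())

    def test_run_many_matches_individual_runs(self, released, constant_forcing):
        forcing = constant_forcing(24, litter=0.3)
        init = PoolState(1, 5, 0.5, 30, 1)
        sites = [(f"cell{i}", init, forcing) for i in range(5)]
        results = run_many(sites, released)
        solo = run(init, forcing, released)
        assert all(r.ok for r in results)
        for r in results:
            assert r.trajectory.states[-1] == solo.states[-1]

    def test_run_many_captures_failures_without_aborting(self, released, constant_forcing):
        good = ("good", PoolState(1, 1, 1, 1, 1), constant_forcing(3))
        bad = ("bad", PoolState(1, 1, 1, 1, 1), [])
        results = run_many([bad, good], released)
        assert not results[0].ok and results[1].ok


class TestTrajectoryFrame:
    def test_frame_columns_and_length(self, released, constant_forcing):
        traj = run(PoolState(1, 5, 0.5, 30, 1), constant_forcing(18), released)
        df = traj.to_frame()
        assert len(df) == 18
        for col in ("time", "spm", "ipm", "doc", "mac", "mb", "total_soc", "co2",
                    "k1_eff", "k5_eff"):
            assert col in df.columns
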