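"""Kinetics tests: closed-form limits, conservation, monotonicity,
stochastic cross-check, membrane modes, and observable mappings."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccswitch import presets
from ccswitch.fitting import fit_constant, fit_rise
from ccswitch.kinetics import (Event, KineticParameters, SystemState,
                               TimeCourse, effective_rate, equilibrium_dimer,
                               observables, simulate_avidity,
                               simulate_solution, simulate_tether)
from _ssa import gillespie_solution


class TestSolutionScheme:
    def test_free_peptide_decays_at_kp_exactly(self):
        """Without partner, [B](t) = B0 exp(-kp t) in closed form and the
        rise fit of the product returns kp."""
        p = KineticParameters(kon=0.0, koff=1.0, kp=0.2)
        t = np.linspace(0, 30, 100)
        tc = simulate_solution(p, SystemState(B=50.0), t)
        assert np.allclose(tc["B"], 50.0 * np.exp(-0.2 * t), rtol=1e-6)
        assert fit_rise(t, tc["Bp"]).k == pytest.approx(0.2, rel=1e-5)

    def test_relaxation_to_binding_equilibrium(self):
        """kp = kdp = 0: final [AB] matches the quadratic mass-balance
        oracle for Kd = koff/kon."""
        p = KineticParameters(kon=2.0, koff=1.0, kp=0.0)
        t = np.linspace(0, 200, 50)
        tc = simulate_solution(p, SystemState(A=5.0, B=3.0), t)
        expected = equilibrium_dimer(5.0, 3.0, p.koff / p.kon)
        assert tc["AB"][-1] == pytest.approx(expected, rel=1e-6)

    def test_all_b_ends_phosphorylated(self):
        # late-time conversion of the remaining B is rate-limited at
        # ~kp * Kd/(Kd + A_total) = 5e-3/min, so run ~15 of those lifetimes
        p = KineticParameters(kon=10.0, koff=1.0, kp=0.5, kdp=0.0)
        t = np.linspace(0, 3000, 80)
        tc = simulate_solution(p, SystemState(A=10.0, B=10.0), t)
        b_family = tc["B"] + tc["AB"]
        assert tc["Bp"][-1] == pytest.approx(10.0, rel=1e-4)
        assert b_family[-1] == pytest.approx(0.0, abs=1e-3)

    def test_conservation_on_preset(self):
        p, init, _ = presets.get_preset("hplc_AS_25C")
        tc = simulate_solution(p, init, np.linspace(0, 600, 100))
        assert tc.meta["conservation_error"] < 1e-6

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        kon=st.floats(0.01, 50), koff=st.floats(0.01, 50),
        kp=st.floats(0.0, 1.0), kdp=st.floats(0.0, 0.5),
        a0=st.floats(0.1, 100), b0=st.floats(0.1, 100),
    )
    def test_conservation_property(self, kon, koff, kp, kdp, a0, b0):
        p = KineticParameters(kon=kon, koff=koff, kp=kp, kdp=kdp)
        tc = simulate_solution(p, SystemState(A=a0, B=b0),
                               np.linspace(0, 50, 30))
        assert tc.meta["conservation_error"] < 1e-6

    def test_negative_init_rejected(self):
        with pytest.raises(ValueError):
            SystemState(A=-1.0)


class TestEffectiveRate:
    def test_no_complex_limit_returns_kp(self):
        p = KineticParameters(kon=0.0, koff=1.0, kp=0.2)
        k = effective_rate(p, SystemState(B=50.0))
        assert k == pytest.approx(0.2, rel=1e-4)

    def test_fast_exchange_matches_quasi_steady_state_oracle(self):
        """In the fast-exchange limit the full model agrees within 5% with
        the reduced 1-D model dBp/dt = kp * freeB(equilibrium)."""
        from scipy.integrate import solve_ivp

        p, init, _ = presets.get_preset("hplc_AS_25C")
        kd = p.koff / p.kon
        a_tot = init.A + init.AB
        b_tot = init.B + init.AB
        # the trajectory is not a single exponential (free A accumulates),
        # so full model and reduced model must be fitted on the same window
        t = np.linspace(0, 300, 300)
        k_full = effective_rate(p, init, times=t)

        def rhs(_, y):
            b_un = b_tot - y[0]
            ab = equilibrium_dimer(a_tot, b_un, kd)
            return [p.kp * (b_un - ab)]

        sol = solve_ivp(rhs, (0, t[-1]), [0.0], t_eval=t, rtol=1e-10)
        k_qss = fit_rise(t, sol.y[0]).k
        assert k_full == pytest.approx(k_qss, rel=0.05)

    def test_monotone_decreasing_in_keq(self):
        ks = []
        for kon in [1.0, 3.0, 10.0, 30.0, 100.0]:
            p = KineticParameters(kon=kon, koff=10.0, kp=0.2)
            init = presets.equilibrium_state(50.0, 50.0, p)
            ks.append(effective_rate(p, init))
        assert all(a >= b - 1e-9 for a, b in zip(ks, ks[1:]))

    def test_monotone_increasing_under_dilution(self):
        p, _, _ = presets.get_preset("hplc_AS_25C")
        ks = []
        for tot in [50.0, 10.0, 2.0, 1.0]:
            init = presets.equilibrium_state(tot, tot, p)
            ks.append(effective_rate(p, init))
        assert all(b >= a - 1e-9 for a, b in zip(ks, ks[1:]))

    def test_dilution_speedup_severalfold(self):
        """Dropping from 50 uM to 1 uM at fixed stability speeds the
        observed reaction severalfold, as seen on membranes vs in bulk."""
        p, init50, _ = presets.get_preset("hplc_AS_25C")
        k50 = effective_rate(p, init50)
        k1 = effective_rate(p, presets.equilibrium_state(1.0, 1.0, p))
        assert k1 / k50 > 3.0

    def test_kinase_titration_subproportional_when_dissociation_limits(self):
        """Tripling the kinase multiplies the observed rate by < 3 when
        monomer rebinding competes with phosphorylation, and by ~3 in the
        fast-exchange regime."""
        p, init, _ = presets.get_preset("partial_limiting_25C")
        k1 = effective_rate(p, init)
        k3 = effective_rate(replace(p, kinase_scale=3.0), init)
        assert 1.0 < k3 / k1 < 2.9
        pf, initf, _ = presets.get_preset("hplc_AS_25C")
        kf1 = effective_rate(pf, initf)
        kf3 = effective_rate(replace(pf, kinase_scale=3.0), initf)
        assert kf3 / kf1 == pytest.approx(3.0, rel=0.15)

    def test_requires_active_kinase(self):
        p = KineticParameters(kp=0.0)
        with pytest.raises(ValueError):
            effective_rate(p, SystemState(B=1.0))


class TestGillespieCrossCheck:
    @pytest.mark.parametrize("kon,koff,kp,a0,b0", [
        (0.1, 1.0, 0.2, 10.0, 10.0),
        (0.5, 0.5, 0.1, 5.0, 8.0),
        (0.0, 1.0, 0.3, 0.0, 12.0),
    ])
    def test_ode_matches_stochastic_mean(self, kon, koff, kp, a0, b0):
        """Deterministic trajectories agree with the Gillespie ensemble
        mean within Monte-Carlo error - guards against transcription
        errors in the ODE right-hand side."""
        rng = np.random.default_rng(42)
        p = KineticParameters(kon=kon, koff=koff, kp=kp)
        t = np.linspace(0, 15, 16)
        tc = simulate_solution(p, SystemState(A=a0, B=b0), t)
        omega, n_runs = 50, 24
        runs = np.array([
            gillespie_solution(p, SystemState(A=a0, B=b0), t, omega, rng)
            for _ in range(n_runs)
        ])
        mean = runs.mean(axis=0)
        sem = runs.std(axis=0, ddof=1) / np.sqrt(n_runs)
        for i, name in enumerate(("A", "B", "AB", "Bp")):
            tol = 4 * sem[i] + 0.02 * max(a0 + b0, 1.0) / np.sqrt(omega)
            assert np.all(np.abs(tc[name] - mean[i]) <= tol), name


class TestTetherMode:
    def test_no_events_sits_at_equilibrium(self):
        p, init, _ = presets.get_preset("tether_slb")
        tc = simulate_tether(p, init, np.linspace(0, 60, 50))
        assert np.ptp(tc["cargo_membrane"]) < 1e-6 * init.anchor_cargo
        k, se = fit_constant(tc.times, tc["anchor_total"])
        assert k == pytest.approx(init.anchor_total)

    def test_kinase_event_releases_cargo_at_calibrated_rate(self):
        p, init, events = presets.get_preset("tether_slb")
        t = np.linspace(0, 70, 150)
        tc = simulate_tether(p, init, t, events=events)
        res = fit_rise(t, tc["cargo_membrane"])
        assert res.converged
        assert res.k == pytest.approx(0.07, rel=0.5)  # within 2x
        assert tc["cargo_membrane"][-1] < 0.2 * tc["cargo_membrane"][0]

    def test_phosphatase_event_rebinds_cargo(self):
        p, init, _ = presets.get_preset("tether_slb")
        events = (Event(0.0, kinase=1.0), Event(60.0, phosphatase=1.0))
        t = np.linspace(0, 160, 200)
        tc = simulate_tether(p, init, t, events=events)
        post_kinase_min = tc["cargo_membrane"][(t > 40) & (t < 60)].min()
        assert tc["cargo_membrane"][-1] > 2.0 * post_kinase_min

    def test_anchor_is_conserved(self):
        p, init, events = presets.get_preset("tether_slb")
        tc = simulate_tether(p, init, np.linspace(0, 70, 50), events=events)
        assert tc.meta["conservation_error"] < 1e-6

    def test_event_before_zero_rejected(self):
        with pytest.raises(ValueError):
            Event(-1.0, kinase=1.0)

    def test_requires_anchor(self):
        p, _, _ = presets.get_preset("tether_slb")
        with pytest.raises(ValueError):
            simulate_tether(p, SystemState(B=1.0), np.linspace(0, 10, 5))


class TestAvidityMode:
    def test_null_avidity_gives_monomer_baseline(self):
        p, _, _ = presets.get_preset("avidity_slb")
        p1 = replace(p, avidity_factor=1.0, kinase_scale=0.0)
        ss_pair = presets.avidity_steady_state(p1, 1.0, 1.0)
        mono_frac = p1.k1on / (p1.k1on + p1.k1off)
        pair_mem = ss_pair.A_mem + ss_pair.AB_mem
        pair_tot = ss_pair.A + ss_pair.AB + pair_mem
        assert pair_mem / pair_tot == pytest.approx(mono_frac, rel=0.05)

    def test_single_protein_negligible_membrane_binding(self):
        p, _, _ = presets.get_preset("avidity_slb")
        ss = presets.avidity_steady_state(p, 1.0, 0.0)
        assert (ss.A_mem + ss.AB_mem) / 1.0 <= 0.05

    def test_pair_exceeds_single_and_kinase_releases(self):
        p, init, events = presets.get_preset("avidity_slb")
        single = presets.avidity_steady_state(p, 1.0, 0.0)
        both_mem = init.B_mem + init.AB_mem
        assert both_mem > 2.0 * (single.A_mem + single.AB_mem)
        t = np.linspace(0, 50, 120)
        tc = simulate_avidity(p, init, t, events=events)
        assert tc["A_membrane_total"][-1] < 0.3 * tc["A_membrane_total"][0]
        assert tc["B_membrane_total"][-1] < 0.3 * tc["B_membrane_total"][0]

    def test_release_rates_recover_calibration(self):
        p, init, events = presets.get_preset("avidity_slb")
        t = np.linspace(0, 50, 150)
        tc = simulate_avidity(p, init, t, events=events)
        ka = fit_rise(t, tc["A_membrane_total"]).k
        kb = fit_rise(t, tc["B_membrane_total"]).k
        assert ka == pytest.approx(0.10, rel=0.2)
        assert kb == pytest.approx(0.10, rel=0.2)

    def test_phosphatase_partially_restores(self):
        p, init, _ = presets.get_preset("avidity_slb")
        events = (Event(0.0, kinase=1.0), Event(50.0, phosphatase=1.0))
        t = np.linspace(0, 220, 220)
        tc = simulate_avidity(p, init, t, events=events)
        low = tc["B_membrane_total"][(t > 40) & (t < 50)].min()
        assert tc["B_membrane_total"][-1] > 1.5 * low

    def test_conservation_with_events(self):
        p, init, events = presets.get_preset("avidity_slb")
        tc = simulate_avidity(p, init, np.linspace(0, 60, 60), events=events)
        assert tc.meta["conservation_error"] < 1e-6


class TestObservables:
    def test_cd_endpoints(self):
        t = np.linspace(0, 1, 5)
        tc = TimeCourse(t, dict(AB=np.full(5, 10.0)))
        obs = observables(tc, dict(kind="cd", mre_folded=-33000.0,
                                   mre_unfolded=-3000.0, ab_ref=10.0))
        assert np.allclose(obs["mre222"], -33000.0)

    def test_hplc_area_sum_conserved(self):
        p, init, _ = presets.get_preset("hplc_AS_25C")
        tc = simulate_solution(p, init, np.linspace(0, 300, 60))
        obs = observables(tc, dict(kind="hplc", area_per_uM=2.0))
        total = obs["substrate_area"] + obs["product_area"]
        assert np.ptp(total) / total[0] < 1e-6

    def test_full_pipeline_consistency(self):
        """simulate -> HPLC observables -> rise fit reproduces
        effective_rate within fit tolerance."""
        p, init, _ = presets.get_preset("hplc_AS_25C")
        t = np.linspace(0, 300, 400)
        k_direct = effective_rate(p, init, times=t)
        tc = simulate_solution(p, init, t)
        obs = observables(tc, dict(kind="hplc"))
        k_obs = fit_rise(t, obs["product_area"]).k
        assert k_obs == pytest.approx(k_direct, rel=1e-3)

    def test_unknown_mapping_rejected(self):
        tc = TimeCourse(np.arange(3.0) + 1.0, dict(AB=np.zeros(3)))
        with pytest.raises(KeyError):
            observables(tc, dict(kind="nmr"))
        with pytest.raises(KeyError):
            observables(tc, dict(kind="slb", channels={"c": {"X": 1.0}}))
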