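"""Crossbridge free energies, strain-dependent rates, Monte Carlo semantics."""
import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myoxray as mx
from myoxray import _engine


KAPPA = 1.3


class TestFreeEnergies:
    def test_zero_strain_weak_state(self, default_rates):
        assert mx.state_free_energy(2, 0.0, default_rates, KAPPA) == pytest.approx(-3.0)

    def test_weak_state_at_2nm(self, default_rates):
        # -3 + 1.3*4/(2*3.96)
        assert mx.state_free_energy(2, 2.0, default_rates, KAPPA) == pytest.approx(-2.3434, abs=1e-4)

    def test_post_stroke_minimum(self, default_rates):
        assert mx.state_free_energy(3, -10.5, default_rates, KAPPA) == pytest.approx(-18.0)

    def test_detached_reference(self, default_rates):
        assert mx.state_free_energy(1, 3.3, default_rates, KAPPA) == 0.0


class TestRates:
    def test_zero_strain_binding_equilibrium(self, default_rates):
        r = mx.transition_rates(0.0, default_rates, KAPPA)
        assert r.k12 == pytest.approx(134.0)
        assert r.k21 == pytest.approx(134.0 / math.e**3, rel=1e-12)
        assert default_rates.K_bind == pytest.approx(20.0855, abs=1e-3)

    def test_detailed_balance_everywhere(self, default_rates):
        x = np.linspace(-14.0, 14.0, 561)   # includes capped regions
        r = mx.transition_rates(x, default_rates, KAPPA)
        g2 = mx.state_free_energy(2, x, default_rates, KAPPA)
        g3 = mx.state_free_energy(3, x, default_rates, KAPPA)
        np.testing.assert_allclose(r.k12 / r.k21, np.exp(-g2), rtol=1e-10)
        np.testing.assert_allclose(r.k23 / r.k32, np.exp(-(g3 - g2)), rtol=1e-10)

    def test_caps_hold_on_dense_grid(self, default_rates):
        x = np.linspace(-40.0, 40.0, 4001)
        r = mx.transition_rates(x, default_rates, KAPPA)
        assert np.all(r.k23 <= default_rates.cap_k23_per_s + 1e-9)
        assert np.all(r.k32 <= default_rates.cap_k32_per_s + 1e-9)
        assert np.all(r.k31 <= default_rates.cap_k31_per_s + 1e-9)
        for arr in (r.k12, r.k21, r.k23, r.k32, r.k31, r.k13):
            assert np.all(arr >= 0) and np.all(np.isfinite(arr))

    def test_nan_strain_rejected(self, default_rates):
        with pytest.raises(ValueError):
            mx.transition_rates(float("nan"), default_rates, KAPPA)

    @given(st.floats(-20, 20))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_python_and_compiled_rates_agree(self, x):
        p = mx.RateParams()
        r = mx.transition_rates(x, p, KAPPA)
        args = (KAPPA, p.dG_bind_kBT, p.dG_stroke_kBT, p.k_bind_per_s,
                p.k_adp0_per_s, p.stroke_d_nm, p.delta2_nm,
                p.cap_k23_per_s, p.cap_k32_per_s, p.cap_k31_per_s, p.kBT_pN_nm)
        k21, k23 = _engine.rates_bound(2, x, *args)
        k31, k32 = _engine.rates_bound(3, x, *args)
        assert k21 == pytest.approx(r.k21, rel=1e-12)
        assert k23 == pytest.approx(r.k23, rel=1e-12)
        assert k32 == pytest.approx(r.k32, rel=1e-12)
        assert k31 == pytest.approx(r.k31, rel=1e-12)


class TestMonteCarloSemantics:
    def test_single_head_binding_probability(self, default_rates):
        """P(bind in one step) = 1 - exp(-k dt) for a lone head at fixed rate."""
        k, dt, n = 1.0e4, 1.0e-6, 100_000   # k*dt = 0.01
        rng = np.random.default_rng(42)
        p = 1.0 - math.exp(-k * dt)
        count = int(np.sum(rng.random(n) < p))
        expect = p * n
        se = math.sqrt(n * p * (1 - p))
        assert abs(count - expect) < 3 * se

    def test_mc_step_contract_via_engine(self):
        """A lone detached head binds at the aggregate first-order
        probability 1 - exp(-K dt) with K the candidate-summed rate."""
        lat = mx.build_half_sarcomere(n_thick=1)
        rates = mx.RateParams()
        # estimate candidate-summed binding rate for head 75 at relaxed geometry
        from myoxray.lattice import candidate_sites
        sites = candidate_sites(75, lat, reach=8.0)
        K = sum(rates.k_bind_per_s
                * math.exp(-KAPPA * x * x / (2 * rates.kBT_pN_nm))
                for _, _, x in sites)
        n_trials = 4000
        steps = 50
        hits = 0
        for s in range(n_trials):
            lat_i = mx.build_half_sarcomere(n_thick=1)
            ev = mx.mc_update(lat_i, rates, n_steps=steps, seed=1000 + s)
            binds = [e for e in ev if e[2] == "bind" and e[1] == 75]
            hits += bool(binds)
        p_step = 1 - math.exp(-K * rates.dt_s)
        p_expect = 1 - (1 - p_step) ** steps
        se = math.sqrt(n_trials * p_expect * (1 - p_expect))
        assert abs(hits - n_trials * p_expect) < 4 * se

    def test_identical_seeds_identical_event_logs(self):
        cfg = mx.SimulationConfig(geometry=mx.GeometryParams(n_thick=2))
        a = mx.run_isometric(cfg, 0.02, seed=11)
        b = mx.run_isometric(cfg, 0.02, seed=11)
        assert np.array_equal(a.events, b.events)
        assert np.array_equal(a.thin_force, b.thin_force)

    def test_zero_binding_rate_gives_zero_force(self):
        cfg = mx.SimulationConfig(
            geometry=mx.GeometryParams(n_thick=2),
            rates=dataclasses.replace(mx.RateParams(), k_bind_per_s=0.0))
        tr = mx.run_isometric(cfg, 0.05, seed=3)
        assert np.all(tr.thin_force == 0.0)
        assert np.all(tr.n2 == 0) and np.all(tr.n3 == 0)

    def test_too_large_timestep_rejected(self):
        cfg = mx.SimulationConfig(
            rates=dataclasses.replace(mx.RateParams(), dt_s=1e-5))
        with pytest.raises(ValueError, match="dt too large"):
            mx.run_isometric(cfg, 0.01, seed=0)

    def test_occupancy_conservation(self, tiny_sim_trace):
        """Every head is in exactly one state; every attachment references a
        distinct monomer."""
        lat = tiny_sim_trace.final_state
        seen_heads = set()
        seen_sites = set()
        for a in lat.attachments:
            assert a.head_id not in seen_heads
            assert (a.filament_id, a.monomer_index) not in seen_sites
            seen_heads.add(a.head_id)
            seen_sites.add((a.filament_id, a.monomer_index))
            assert a.state in (2, 3)
        lat.validate()


class TestStationaryDistribution:
    def test_long_run_matches_analytic_three_state_occupancy(self, default_rates):
        """Fixed strain, rigid filaments: Monte Carlo occupancy converges to
        the stationary distribution of the 3-state rate matrix."""
        x = -2.0
        r = mx.transition_rates(x, default_rates, KAPPA)
        Q = np.array([
            [-r.k12, r.k12, 0.0],
            [r.k21, -(r.k21 + r.k23), r.k23],
            [r.k31, r.k32, -(r.k31 + r.k32)],
        ])
        # stationary distribution: left null vector of Q
        w, v = np.linalg.eig(Q.T)
        pi = np.real(v[:, np.argmin(np.abs(w))])
        pi = pi / pi.sum()

        dt = default_rates.dt_s
        probs = np.array([
            [1 - (r.k12) * dt, r.k12 * dt, 0.0],
            [r.k21 * dt, 1 - (r.k21 + r.k23) * dt, r.k23 * dt],
            [r.k31 * dt, r.k32 * dt, 1 - (r.k31 + r.k32) * dt],
        ])
        rng = np.random.default_rng(5)
        n = 3_000_000
        # simulate the embedded chain cheaply: vectorised cumulative sampling
        state = 0
        occ = np.zeros(3)
        u = rng.random(n)
        for i in range(n):
            row = probs[state]
            if u[i] < row[0]:
                state = 0
            elif u[i] < row[0] + row[1]:
                state = 1
            else:
                state = 2
            occ[state] += 1
        occ /= n
        # 3 SE with correlation time ~ 1/(slowest relaxation rate)
        tau = 1.0 / np.min(np.abs(np.real(w[np.abs(w) > 1e-9])))
        n_eff = n * dt / tau
        for s in range(3):
            se = math.sqrt(max(pi[s] * (1 - pi[s]), 1e-12) / n_eff)
            assert abs(occ[s] - pi[s]) < 3 * se + 0.005

    def test_binding_rate_orders_plateau_force(self):
        """Plateau thin-filament force increases with the binding rate."""
        means = []
        for kb in (30.0, 70.0, 134.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = mx.SimulationConfig(
                    geometry=mx.GeometryParams(n_thick=2),
                    rates=dataclasses.replace(mx.RateParams(), k_bind_per_s=kb))
                tr = mx.run_isometric(cfg, 0.15, seed=seed)
                vals.append(tr.thin_force[tr.t >= 0.08].mean())
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestBoundFraction:
    def test_relaxed_trace_zero(self):
        cfg = mx.SimulationConfig(
            geometry=mx.GeometryParams(n_thick=2),
            rates=dataclasses.replace(mx.RateParams(), k_bind_per_s=0.0))
        tr = mx.run_isometric(cfg, 0.05, seed=1)
        frac, per = mx.bound_fraction(tr, window_s=0.02)
        assert frac == 0.0 and np.all(per == 0.0)

    def test_constant_occupancy_arithmetic(self, tiny_sim_trace):
        """A trace holding 72.5% of the 150 heads bound reads back exactly."""
        import copy

        tr = tiny_sim_trace
        t2 = copy.copy(tr)
        t2.n2 = np.full(tr.n2.shape, 54.0)
        t2.n3 = np.full(tr.n3.shape, 54.75)   # 108.75/150 = 72.5%
        frac, per = mx.bound_fraction(t2, window_s=0.05)
        assert frac == pytest.approx(0.725, abs=1e-12)
        assert np.allclose(per, 0.725)

    def test_fraction_bounded_and_window_validated(self, tiny_sim_trace):
        frac, per = mx.bound_fraction(tiny_sim_trace, window_s=0.04)
        assert 0.0 <= frac <= 1.0
        with pytest.raises(ValueError):
            mx.bound_fraction(tiny_sim_trace, window_s=99.0)
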