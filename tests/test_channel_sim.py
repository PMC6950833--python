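import json
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cavclamp.channel_sim import (
    SimConfig,
    VariantParams,
    _py_gate_path,
    apply_block,
    gate_update_exact,
    list_variants,
    load_variant,
    simulate_fluorescence,
    simulate_protocol,
    simulate_sweep,
    steady_state_activation,
)
from cavclamp.protocols import Segment, build_apw_train, build_iv_protocol


class TestGateUpdate:
    def test_full_relaxation(self):
        assert gate_update_exact(0.0, 1.0, 1.0, 1e6) == pytest.approx(1.0)

    def test_fixed_point(self):
        assert gate_update_exact(0.2, 0.2, 5.0, 3.0) == pytest.approx(0.2)

    def test_closed_form(self):
        # one time constant of relaxation toward 1
        assert gate_update_exact(0.0, 1.0, 2.0, 2.0) == pytest.approx(
            1.0 - np.exp(-1.0), abs=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            gate_update_exact(0.0, 1.0, 0.0, 1.0)

    @given(st.floats(0, 1), st.floats(0, 1),
           st.floats(0.01, 100), st.floats(0.001, 100))
    def test_stays_in_unit_interval(self, x0, xinf, tau, dt):
        x = gate_update_exact(x0, xinf, tau, dt)
        assert -1e-12 <= x <= 1.0 + 1e-12


class TestSteadyStates:
    def test_midpoint(self, wt_l):
        assert steady_state_activation(wt_l.v_half_act, wt_l) == pytest.approx(0.5)

    def test_saturation(self, wt_l):
        assert steady_state_activation(1e4, wt_l) == pytest.approx(1.0)

    def test_published_wt_l_at_minus20(self):
        # Boltzmann with V_0.5 = -0.18 mV, k = 9.63 mV evaluated at -20 mV
        p = VariantParams(
            name="tab", v_half_act=-0.18, slope_act=9.63, tau_act_max=1.0,
            tau_act_v=0.0, tau_act_k=30.0, g_max=1.0, v_rev=71.1,
            frac_fast=0.4, frac_slow=0.4, frac_persistent=0.2,
            tau_fast_0=100.0, tau_slow_0=1000.0, tau_v_dep=30.0,
            v_half_inact=-25.7, slope_inact=5.64)
        assert steady_state_activation(-20.0, p) == pytest.approx(0.1133, abs=5e-4)


class TestBlock:
    def test_half_block_at_ic50(self, wt_l):
        assert apply_block(wt_l, wt_l.ic50) == pytest.approx(0.5)

    def test_zero_concentration(self, wt_l):
        assert apply_block(wt_l, 0.0) == 0.0

    def test_hill_algebra(self, wt_l):
        assert apply_block(wt_l, 9.0 * wt_l.ic50) == pytest.approx(0.9)

    def test_negative_rejected(self, wt_l):
        with pytest.raises(ValueError):
            apply_block(wt_l, -1.0)


class TestParamValidation:
    def test_fractions_must_sum_to_one(self, wt_l):
        with pytest.raises(ValueError):
            replace(wt_l, frac_fast=0.5, frac_slow=0.5, frac_persistent=0.5)

    def test_packaged_variants_load_and_validate(self):
        assert list_variants() == sorted(
            ["WT_L", "WT_S", "S652L_L", "S652L_S", "S652W_L"])
        for name in list_variants():
            p = load_variant(name)
            assert p.name == name
            total = p.frac_fast + p.frac_slow + p.frac_persistent
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_unknown_key_rejected(self, wt_l):
        d = wt_l.to_dict()
        d["bogus"] = 1
        with pytest.raises(ValueError):
            VariantParams.from_dict(d)


class TestSimulation:
    def test_carrier_symmetry_without_cdi(self, wt_l):
        """With CDI coupling zero, Ca and Ba runs are bit-identical."""
        p = replace(wt_l, cdi_coupling=0.0, cdi_coupling_slow=0.0)
        sweep = [Segment.step(-79.7, 5.0), Segment.step(-0.7, 50.0),
                 Segment.step(-79.7, 5.0)]
        a = simulate_sweep(p, sweep, SimConfig(seed=3, carrier="Ca"))
        b = simulate_sweep(p, sweep, SimConfig(seed=3, carrier="Ba"))
        assert np.array_equal(a.current, b.current)

    def test_seeded_reproducibility(self, wt_l):
        sweep = [Segment.step(-79.7, 5.0), Segment.step(-0.7, 50.0),
                 Segment.step(-79.7, 5.0)]
        cfg = SimConfig(seed=11)
        a = simulate_sweep(wt_l, sweep, cfg)
        b = simulate_sweep(wt_l, sweep, cfg)
        assert np.array_equal(a.current, b.current)

    def test_zero_conductance_leaves_leak_only(self, wt_l):
        p = replace(wt_l, g_max=0.0, q_on_total=0.0)
        cfg = SimConfig(noise_sd=0.0, leak_conductance=1.0, junction_offset=0.0)
        sweep = [Segment.step(-89.0, 5.0), Segment.step(-9.0, 50.0),
                 Segment.step(-89.0, 5.0)]
        rec = simulate_sweep(p, sweep, cfg)
        expected = 1.0 * rec.command_v  # leak reverses at 0 mV
        assert np.allclose(rec.current, expected, atol=1e-9)

    def test_open_probability_bounded(self, s652l_l):
        """|channel current| never exceeds g_max * |driving force|."""
        p = replace(s652l_l, q_on_total=0.0)
        cfg = SimConfig(noise_sd=0.0, leak_conductance=0.0, junction_offset=0.0)
        sweep = [Segment.step(-89.0, 5.0), Segment.step(-10.0, 500.0),
                 Segment.step(-89.0, 5.0)]
        rec = simulate_sweep(p, sweep, cfg)
        bound = p.g_max * np.abs(rec.command_v - p.v_rev) + 1e-9
        assert np.all(np.abs(rec.current) <= bound)

    def test_gate_path_matches_dense_exact_stepping(self, wt_l):
        """Piecewise-exact updates at dt equal exact stepping at dt/100.

        On a piecewise-constant command the one-step relaxation update is the
        exact ODE solution, so refining the step 100-fold must not change the
        trajectory beyond float noise.
        """
        dt = 0.02
        # two-step protocol: 10 ms at -89, 15 ms at 0 (per-sample arrays)
        n1, n2 = 500, 750
        v = np.concatenate([np.full(n1, -89.0), np.full(n2, 0.0)])
        x_inf = wt_l.m_inf(v)
        tau = wt_l.tau_m(v)
        coarse = _py_gate_path(x_inf, np.exp(-dt / tau), 0.0)
        fine_v = np.repeat(v, 100)
        fine = _py_gate_path(wt_l.m_inf(fine_v),
                             np.exp(-(dt / 100) / wt_l.tau_m(fine_v)), 0.0)
        assert np.max(np.abs(coarse - fine[::100])) < 1e-6

    def test_protocol_sweep_count_and_rundown_off(self, wt_l):
        from cavclamp.protocols import build_pharm_protocol

        p = replace(wt_l, rundown_rate=0.0)
        prot = build_pharm_protocol(-0.7, 5, hp=-79.7)
        recs = simulate_protocol(p, prot, SimConfig(noise_sd=0.0))
        assert len(recs) == 5
        # without run-down, first and last control sweeps are identical
        assert np.allclose(recs[0].current, recs[-1].current, atol=1e-9)

    def test_rundown_scales_pharm_sweeps(self, wt_l):
        from cavclamp.protocols import build_pharm_protocol

        prot = build_pharm_protocol(-0.7, 7, hp=-79.7)
        recs = simulate_protocol(wt_l, prot, SimConfig(noise_sd=0.0))
        peaks = [abs(r.current.min()) for r in recs]
        assert peaks[-1] < peaks[0]

    def test_apw_train_count(self, wt_l):
        recs = simulate_protocol(wt_l, build_apw_train(30, 10.0),
                                 SimConfig(noise_sd=0.0))
        assert len(recs) == 30


class TestFluorescence:
    def test_zero_current_stays_at_baseline(self, wt_l):
        p = replace(wt_l, g_max=0.0, q_on_total=0.0)
        cfg = SimConfig(noise_sd=0.0, leak_conductance=0.0)
        recs = simulate_protocol(p, build_apw_train(5, 10.0), cfg)
        _, f = simulate_fluorescence(recs, kappa=0.01, extrusion_tau=100.0)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_infinite_extrusion_integrates_charge(self, wt_l):
        cfg = SimConfig(noise_sd=0.0, leak_conductance=0.0)
        p = replace(wt_l, q_on_total=0.0)
        recs = simulate_protocol(p, build_apw_train(3, 10.0), cfg)
        _, f = simulate_fluorescence(recs, kappa=0.01, extrusion_tau=np.inf)
        i_all = np.concatenate([r.current for r in recs])
        charge = np.cumsum(np.maximum(-i_all, 0.0)) * cfg.dt * 1e-3
        assert np.allclose(f - 1.0, 0.01 * charge, rtol=1e-9, atol=1e-12)
        assert np.all(np.diff(f) >= -1e-15)

    def test_barium_rejected(self, wt_l):
        recs = simulate_protocol(
            wt_l, build_apw_train(2, 10.0),
            SimConfig(noise_sd=0.0, carrier="Ba"))
        with pytest.raises(ValueError):
            simulate_fluorescence(recs, 0.01, 100.0)


def test_params_json_round_trip(tmp_path, wt_l):
    path = tmp_path / "p.json"
    path.write_text(json.dumps(wt_l.to_dict()))
    back = VariantParams.from_dict(json.loads(path.read_text()))
    assert back == wt_l
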