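import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from cavclamp import gating_analysis as ga
from cavclamp.channel_sim import SimConfig, simulate_protocol
from cavclamp.preprocessing import correct_junction
from cavclamp.protocols import build_tail_protocol

from conftest import make_processed_step


def iv_equation(v, g_max, v_rev, v_half, k):
    return g_max * (v - v_rev) / (1.0 + np.exp(-(v - v_half) / k))


def boltzmann(v, v_half, k):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


def ssi_curve(v, v_half, k, plateau):
    return (1.0 - plateau) / (1.0 + np.exp((v - v_half) / k)) + plateau


GRID = np.arange(-80.0, 66.0, 5.0)


class TestExtractIV:
    def test_vmax_from_noiseless_simulation(self, gating_fits_all):
        v_max = gating_fits_all["WT_L"].iv.points.attrs["v_max"]
        assert -10.0 <= v_max <= 20.0

    def test_all_zero_currents_rejected(self):
        recs = [make_processed_step(0.0, v_test=v) for v in (-40, -20, 0, 20, 40)]
        with pytest.raises(ga.InsufficientDataError):
            ga.extract_iv(recs)

    def test_too_few_voltages(self):
        with pytest.raises(ga.InsufficientDataError):
            ga.extract_iv([make_processed_step(-200.0)])

    def test_tie_broken_toward_hyperpolarized(self):
        recs = [make_processed_step(pk, v_test=v)
                for v, pk in [(-20, -300.0), (-10, -400.0), (0, -400.0),
                              (10, -300.0), (20, -100.0)]]
        points = ga.extract_iv(recs, blank_ms=0.0)
        assert points.attrs["v_max"] == -10.0


class TestFitIV:
    def test_exact_recovery_of_generating_parameters(self):
        truth = dict(g_max=5.0, v_rev=59.9, v_half=-16.3, k=8.27)
        i = iv_equation(GRID, **truth)
        points = pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12})
        fit = ga.fit_iv(points)
        for name, val in truth.items():
            got = {"g_max": fit.g_max, "v_rev": fit.v_rev,
                   "v_half": fit.v_half, "k": fit.slope}[name]
            assert got == pytest.approx(val, rel=1e-3)

    def test_pure_line_flagged_unidentifiable(self):
        i = 5.0 * (GRID - 60.0)
        points = pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12})
        fit = ga.fit_iv(points)
        assert not fit.identifiable

    def test_noisy_recovery_within_three_se(self):
        rng = np.random.default_rng(42)
        i = iv_equation(GRID, 5.0, 59.9, -16.3, 8.27) + rng.normal(0, 2, GRID.size)
        points = pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12})
        fit = ga.fit_iv(points)
        assert abs(fit.v_half - (-16.3)) < 3 * fit.stderr["v_half"]


class TestConductanceTransform:
    def test_singularity_guard(self):
        i = iv_equation(GRID, 5.0, 60.0, -16.3, 8.27)
        points = pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12})
        gv = ga.conductance_transform(points, v_rev=60.0)
        assert not np.any(np.abs(gv["v"] - 60.0) <= 2.0)

    def test_algebraic_inverse_is_exact(self):
        truth = dict(v_half=-0.18, k=9.63)
        i = iv_equation(GRID, 5.0, 71.1, **truth)
        points = pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12})
        gv = ga.conductance_transform(points, 71.1, g_max=5.0)
        assert np.allclose(gv["g_norm"], boltzmann(gv["v"], **truth), atol=1e-12)

    def test_wt_l_conductance_at_minus20(self):
        # closed form from the fitted activation parameters
        gv = boltzmann(-20.0, -0.18, 9.63)
        assert gv == pytest.approx(0.113, abs=1e-3)

    def test_all_points_excluded(self):
        points = pd.DataFrame({"v": [59.0, 60.0], "i_pa": [0.1, 0.0],
                               "i_density": [0.0, 0.0]})
        with pytest.raises(ga.InsufficientDataError):
            ga.conductance_transform(points, 60.0)


class TestFitBoltzmann:
    def test_exact_recovery(self):
        g = boltzmann(GRID, 4.23, 8.73)
        fit = ga.fit_boltzmann(pd.DataFrame({"v": GRID, "g_norm": g}))
        assert fit.v_half_act == pytest.approx(4.23, rel=1e-3)
        assert fit.slope_act == pytest.approx(8.73, rel=1e-3)

    def test_constant_data_unidentifiable(self):
        fit = ga.fit_boltzmann(pd.DataFrame({"v": GRID,
                                             "g_norm": np.full(GRID.size, 0.5)}))
        assert not fit.identifiable

    def test_noisy_recovery_low_bias(self):
        errs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            g = boltzmann(GRID, -16.3, 8.27) + rng.normal(0, 0.01, GRID.size)
            fit = ga.fit_boltzmann(pd.DataFrame({"v": GRID, "g_norm": g}))
            errs.append(fit.v_half_act - (-16.3))
        assert abs(np.mean(errs)) < 0.1


class TestSSI:
    def test_fit_exact_recovery(self):
        v = np.arange(-109.0, 32.0, 10.0)
        a = ssi_curve(v, -43.3, 4.99, 0.128)
        fit = ga.fit_ssi(pd.DataFrame({"v": v, "availability": a}))
        assert fit.v_half_inact == pytest.approx(-43.3, rel=1e-3)
        assert fit.slope_inact == pytest.approx(4.99, rel=1e-3)
        assert fit.plateau == pytest.approx(0.128, rel=1e-3)

    def test_zero_plateau(self):
        v = np.arange(-109.0, 32.0, 10.0)
        a = ssi_curve(v, -40.0, 5.0, 0.0)
        fit = ga.fit_ssi(pd.DataFrame({"v": v, "availability": a}))
        assert fit.plateau == pytest.approx(0.0, abs=1e-6)

    def test_pipeline_ratio_near_one_at_holding(self, gating_fits_all):
        pts = gating_fits_all["WT_L"].inactivation.points
        hp_row = pts.loc[(pts["v"] + 89.0).abs() < 1.0]
        assert hp_row["availability"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_depolarized_conditioning_approaches_plateau(self, gating_fits_all):
        fit = gating_fits_all["WT_L"].inactivation
        top = fit.points.loc[fit.points["v"] > 20.0, "availability"]
        assert top.iloc[-1] == pytest.approx(fit.plateau, abs=0.05)

    def test_too_few_points(self):
        with pytest.raises(ga.InsufficientDataError):
            ga.fit_ssi(pd.DataFrame({"v": [-80.0, -40.0],
                                     "availability": [1.0, 0.5]}))


class TestWindowCurrent:
    def _iv_points(self):
        i = iv_equation(GRID, 5.0, 60.0, -16.3, 8.27)
        return pd.DataFrame({"v": GRID, "i_pa": i, "i_density": i / 12.0})

    def test_zero_availability_gives_zero_window(self):
        ssi = pd.DataFrame({"v": GRID, "availability": np.zeros(GRID.size)})
        w = ga.window_current(ssi, self._iv_points())
        assert np.allclose(w["window_density"], 0.0)

    def test_full_availability_is_identity(self):
        ssi = pd.DataFrame({"v": GRID, "availability": np.ones(GRID.size)})
        w = ga.window_current(ssi, self._iv_points())
        assert np.allclose(w["window_density"], w["i_density"])

    def test_scales_linearly_with_density(self):
        ssi = pd.DataFrame({"v": GRID, "availability": np.full(GRID.size, 0.5)})
        pts = self._iv_points()
        w1 = ga.window_current(ssi, pts)
        pts2 = pts.copy()
        pts2["i_density"] *= 3.0
        w2 = ga.window_current(ssi, pts2)
        assert np.allclose(w2["window_density"], 3.0 * w1["window_density"])

    def test_disjoint_ranges_rejected(self):
        ssi = pd.DataFrame({"v": [100.0, 120.0], "availability": [0.5, 0.5]})
        with pytest.raises(ga.InsufficientDataError):
            ga.window_current(ssi, self._iv_points())

    def test_mutant_subthreshold_window_larger(self, gating_fits_all):
        """S652L_S window current exceeds WT_S at subthreshold voltages."""
        for v_sub in (-50.0, -45.0):
            mags = {}
            for name in ("WT_S", "S652L_S"):
                w = gating_fits_all[name].window
                row = w.loc[(w["v"] - v_sub).abs().idxmin()]
                mags[name] = abs(row["window_density"])
            assert mags["S652L_S"] > mags["WT_S"]


class TestRemainingFractions:
    def test_constant_current(self):
        ps = make_processed_step(-300.0, duration=5100.0)
        r = ga.remaining_fractions(ps)
        assert all(v == pytest.approx(100.0) for v in r.values())

    def test_single_exponential(self):
        ps = make_processed_step(lambda t: -300.0 * np.exp(-t / 250.0),
                                 duration=5100.0)
        r = ga.remaining_fractions(ps, blank_ms=0.0)
        assert r[250.0] == pytest.approx(100.0 * np.exp(-1.0), abs=0.5)

    def test_monotone_non_increasing_on_simulation(self, gating_fits_all):
        r = gating_fits_all["WT_L"].profile_ca.r_values
        vals = [r[t] for t in sorted(r)]
        assert all(a >= b - 1e-6 for a, b in zip(vals, vals[1:]))

    def test_zero_peak_rejected(self):
        ps = make_processed_step(0.0, duration=5100.0)
        with pytest.raises(ga.InsufficientDataError):
            ga.remaining_fractions(ps)


class TestCDIOps:
    def test_f_zero_when_curves_equal(self):
        assert ga.cdi_f(50.0, 50.0) == 0.0

    def test_f_from_published_wt_l_values(self):
        assert ga.cdi_f(79.10, 36.9) == pytest.approx(0.422, abs=1e-3)

    def test_f_negative_allowed(self):
        assert ga.cdi_f(30.0, 40.0) == pytest.approx(-0.1)

    def test_fraction_zero_when_equal(self):
        assert ga.cdi_fraction(50.0, 50.0) == 0.0

    def test_fraction_undefined_at_zero_barium(self):
        with pytest.raises(ZeroDivisionError):
            ga.cdi_fraction(10.0, 0.0)

    def test_fraction_and_f_agree_in_sign(self, gating_fits_all):
        for name in ("WT_L", "S652L_L", "WT_S", "S652L_S"):
            gf = gating_fits_all[name]
            r_ca = gf.profile_ca.r_values[250.0]
            r_ba = gf.profile_ba.r_values[250.0]
            assert np.sign(ga.cdi_f(r_ba, r_ca)) == np.sign(
                ga.cdi_fraction(r_ca, r_ba))

    def test_zero_cdi_configuration_gives_zero_fraction(self, wt_l,
                                                        noiseless_cfg):
        from cavclamp import pipeline

        p = replace(wt_l, cdi_coupling=0.0, cdi_coupling_slow=0.0)
        r_ca = pipeline.run_inactivation(
            p, replace(noiseless_cfg, carrier="Ca"), 15.0)["r_values"]
        r_ba = pipeline.run_inactivation(
            p, replace(noiseless_cfg, carrier="Ba"), 15.0)["r_values"]
        for t in r_ca:
            assert ga.cdi_fraction(r_ca[t], r_ba[t]) == pytest.approx(0.0,
                                                                      abs=1e-9)


class TestPersistentCurrent:
    def test_non_inactivating(self):
        ps = make_processed_step(-300.0, duration=5000.0,
                                 pre_pulse=(-10.0, 20.0, -300.0))
        assert ga.persistent_current(ps) == pytest.approx(100.0, abs=0.5)

    def test_fully_inactivating(self):
        ps = make_processed_step(lambda t: -300.0 * np.exp(-t / 100.0),
                                 duration=5000.0,
                                 pre_pulse=(-10.0, 20.0, -300.0))
        assert ga.persistent_current(ps) == pytest.approx(0.0, abs=0.5)

    def test_missing_pre_pulse(self):
        ps = make_processed_step(-300.0, duration=5000.0)
        with pytest.raises(ga.ProtocolMismatchError):
            ga.persistent_current(ps)

    def test_matches_r5000_internally(self, gating_fits_all, noiseless_cfg,
                                      wt_l):
        from cavclamp import pipeline
        from cavclamp.channel_sim import simulate_sweep

        v_max = gating_fits_all["WT_L"].iv.points.attrs["v_max"]
        segs = pipeline.inactivation_sweep(v_max, noiseless_cfg.junction_offset,
                                           pre_pulse=True)
        rec = simulate_sweep(wt_l, segs, noiseless_cfg)
        ps = correct_junction(rec, noiseless_cfg.junction_offset)
        pc = ga.persistent_current(ps)
        r5000 = gating_fits_all["WT_L"].profile_ca.r_values[5000.0]
        assert pc == pytest.approx(r5000, abs=2.0)


class TestTailFits:
    def test_published_biexponential_recovered_exactly(self):
        t = np.arange(0, 20.0, 0.02)
        y = (-0.29 * np.exp(-t / 0.39) - 0.54 * np.exp(-t / 1.95) - 0.047)
        fit = ga.fit_tail_arrays(t, y)
        assert fit.tau_fast == pytest.approx(0.39, rel=1e-3)
        assert fit.tau_slow == pytest.approx(1.95, rel=1e-3)
        assert fit.a_fast == pytest.approx(-0.29, rel=1e-3)
        assert fit.a_slow == pytest.approx(-0.54, rel=1e-3)
        assert fit.c == pytest.approx(-0.047, rel=1e-3)
        assert not fit.single_exp_fallback

    def test_single_exponential_fallback(self):
        t = np.arange(0, 20.0, 0.02)
        y = -np.exp(-t / 0.5)
        fit = ga.fit_tail_arrays(t, y)
        assert fit.single_exp_fallback or abs(fit.a_slow) < 0.05

    def test_area_closed_form(self):
        t = np.arange(0, 20.0, 0.02)
        y = -0.8 * np.exp(-t / 0.5)
        fit = ga.fit_tail_arrays(t, y)
        # integral of A exp(-t/tau) over a window >> tau is A*tau
        assert fit.norm_area == pytest.approx(-0.8 * 0.5, rel=1e-2)

    def test_half_width_of_pure_exponential(self):
        t = np.arange(0, 20.0, 0.02)
        y = -np.exp(-t / 1.0)
        fit = ga.fit_tail_arrays(t, y)
        assert fit.half_width == pytest.approx(np.log(2.0), rel=1e-2)

    def test_mutant_tails_slower_through_simulator(self, wt_l, s652l_l):
        """S652L_L deactivates more slowly at -40 mV than WT_L."""
        from cavclamp.pipeline import cmd

        fits = {}
        for p in (wt_l, s652l_l):
            prot = build_tail_protocol(cmd(80.0), [cmd(-40.0)], 20.0, 20.0,
                                       hp=cmd(-89.0), sample_rate=50.0)
            cfg = SimConfig(noise_sd=0.0)
            recs = simulate_protocol(replace(p, q_on_total=0.0), prot, cfg)
            ps = correct_junction(recs[0], cfg.junction_offset)
            fits[p.name] = ga.fit_tail(ps)
        assert fits["S652L_L"].tau_slow > fits["WT_L"].tau_slow
        assert abs(fits["S652L_L"].a_slow) > abs(fits["WT_L"].a_slow)
        assert fits["S652L_L"].half_width > fits["WT_L"].half_width
        assert abs(fits["S652L_L"].norm_area) > abs(fits["WT_L"].norm_area)


class TestPoProxy:
    def _group(self, rng, slope, n=25, r2_noise=55.0):
        q = rng.uniform(50.0, 350.0, n)
        it = slope * q + rng.normal(0.0, r2_noise, n)
        return q, it

    def test_too_few_cells(self):
        with pytest.raises(ga.InsufficientDataError):
            ga.po_proxy([1, 2, 3], [1, 2, 3])

    def test_planted_slopes_recovered(self):
        rng = np.random.default_rng(0)
        qa, ia = self._group(rng, -7.22)
        qb, ib = self._group(rng, -4.24)
        res = ga.po_proxy(qa, ia, qb, ib, labels=("WT", "MUT"))
        assert res.slopes["WT"] == pytest.approx(-7.22, abs=1.0)
        assert res.slopes["MUT"] == pytest.approx(-4.24, abs=1.0)
        assert res.p_value < 0.05

    def test_type_i_error_near_alpha(self):
        rejections = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            qa, ia = self._group(rng, -5.0)
            qb, ib = self._group(rng, -5.0)
            res = ga.po_proxy(qa, ia, qb, ib)
            rejections += res.p_value < 0.05
        # binomial 95% band around alpha = 0.05 for 200 trials
        assert 2 <= rejections <= 21


class TestNormalizedPlateau:
    def test_zero_conductance(self):
        ps = make_processed_step(-200.0, v_test=-20.0, duration=1000.0,
                                 pre_pulse=(-10.0, 20.0, -400.0))
        out = ga.normalized_plateau_current(ps, 0.0)
        assert np.allclose(out["trace"], 0.0)

    def test_unit_conductance_is_normalized_identity(self):
        ps = make_processed_step(-200.0, v_test=-20.0, duration=1000.0,
                                 pre_pulse=(-10.0, 20.0, -400.0))
        out = ga.normalized_plateau_current(ps, 1.0)
        assert out["peak"] == pytest.approx(-0.5, abs=1e-6)

    def test_mutant_scaled_subthreshold_current_larger(self, wt_l, s652l_l,
                                                       gating_fits_all,
                                                       noiseless_cfg):
        """Conductance-scaled I at -20 mV: S652L_L peak exceeds WT_L peak."""
        from cavclamp import pipeline
        from cavclamp.channel_sim import simulate_sweep

        peaks = {}
        for p in (wt_l, s652l_l):
            gf = gating_fits_all[p.name]
            v_max = gf.iv.points.attrs["v_max"]
            segs = pipeline.inactivation_sweep(
                v_max, noiseless_cfg.junction_offset, duration=5000.0,
                pre_pulse=True, test_v_corr=-20.0)
            rec = simulate_sweep(p, segs, noiseless_cfg)
            ps = correct_junction(rec, noiseless_cfg.junction_offset)
            g20 = float(np.interp(-20.0, gf.activation.points["v"],
                                  gf.activation.points["g_norm"]))
            peaks[p.name] = ga.normalized_plateau_current(ps, g20)["peak"]
        assert abs(peaks["S652L_L"]) > abs(peaks["WT_L"])
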