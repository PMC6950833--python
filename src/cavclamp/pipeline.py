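"""End-to-end per-variant analysis runs on simulated recordings.

These helpers wire the simulator, preprocessing and gating analysis together
for the standard study conditions: protocols are built in the command frame
(holding -89 mV *after* junction correction, i.e. command -79.7 mV with the
-9.3 mV offset), recordings are junction-corrected and offline leak
subtracted, and fits are performed on the corrected-voltage axis - the frame
in which gating parameters are conventionally reported.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import gating_analysis as ga
from . import preprocessing as pp
from . import protocols as pr
from .channel_sim import SimConfig, VariantParams, simulate_protocol, simulate_sweep
from .protocols import Segment

__all__ = [
    "cmd", "preprocess_all", "run_iv_analysis", "run_ssi_analysis",
    "run_inactivation", "variant_gating_fits", "run_dose_response",
    "DEFAULT_CONCENTRATIONS_NM",
]

HP_CORR = -89.0         # holding potential, corrected frame
IV_GRID = (-80.0, 65.0, 5.0)   # corrected-frame test grid, mV
SSI_GRID = (-109.0, 31.0, 10.0)
LEAK_STEP = (-10.0, 50.0)      # dV (mV), duration (ms)


def cmd(v_corrected: float, offset: float = -9.3) -> float:
    """Command voltage producing ``v_corrected`` after junction correction."""
    return v_corrected - offset


def preprocess_all(recs, cfg: SimConfig, leak: bool = True):
    out = []
    for r in recs:
        ps = pp.correct_junction(r, cfg.junction_offset)
        if leak:
            ps = pp.leak_subtract_offline(ps)
        out.append(ps)
    return out


def run_iv_analysis(p: VariantParams, cfg: SimConfig, qc: bool = True) -> dict:
    """I-V family -> peak points, I-V fit, normalized G-V Boltzmann fit."""
    off = cfg.junction_offset
    prot = pr.build_iv_protocol(
        cmd(HP_CORR, off), cmd(IV_GRID[0], off), cmd(IV_GRID[1], off),
        IV_GRID[2], 50.0, leak_step=LEAK_STEP, sample_rate=1.0 / cfg.dt)
    recs = simulate_protocol(p, prot, cfg)
    processed = preprocess_all(recs, cfg)
    points = ga.extract_iv(processed)
    if qc:
        # the amplitude window is a per-cell rule: the cell's maximal inward
        # current (at V_max) must lie inside [100, 1000] pA
        cell_peak = abs(points["i_pa"].min())
        if not pp.QC_MIN_PA <= cell_peak <= pp.QC_MAX_PA:
            raise ga.InsufficientDataError(
                f"cell excluded by amplitude window: |I(V_max)| = "
                f"{cell_peak:.0f} pA outside [{pp.QC_MIN_PA:.0f}, "
                f"{pp.QC_MAX_PA:.0f}] pA")
    ivfit = ga.fit_iv(points)
    gv = ga.conductance_transform(points, ivfit.v_rev, exclusion_mv=5.0,
                                  g_max=ivfit.g_max)
    act = ga.fit_boltzmann(gv)
    return {"points": points, "iv": ivfit, "gv": gv, "activation": act,
            "v_max": points.attrs["v_max"]}


def run_ssi_analysis(p: VariantParams, cfg: SimConfig, vmax_corr: float) -> dict:
    """Steady-state inactivation family -> availability points + fit.

    Run with the Ba2+ carrier by default study conditions (isolates the
    voltage-dependent availability; see methods note).
    """
    off = cfg.junction_offset
    prot = pr.build_ssi_protocol(
        cmd(HP_CORR, off), cmd(vmax_corr, off),
        cmd(SSI_GRID[0], off), cmd(SSI_GRID[1], off), SSI_GRID[2],
        sample_rate=1.0 / cfg.dt)
    recs = simulate_protocol(p, prot, cfg)
    processed = preprocess_all(recs, cfg, leak=False)
    points = ga.extract_ssi(processed)
    fit = ga.fit_ssi(points)
    return {"points": points, "inactivation": fit}


def inactivation_sweep(vmax_corr: float, offset: float = -9.3,
                       duration: float = 5000.0,
                       pre_pulse: bool = False,
                       test_v_corr: float | None = None) -> list[Segment]:
    """Segments of a long depolarization sweep (optionally with V_max pre-pulse)."""
    hp = cmd(HP_CORR, offset)
    test_v = cmd(test_v_corr if test_v_corr is not None else vmax_corr, offset)
    segs = [Segment.step(hp, 5.0)]
    if pre_pulse:
        segs += [Segment.step(cmd(vmax_corr, offset), 20.0)]
    segs += [Segment.step(test_v, duration), Segment.step(hp, 5.0)]
    return segs


def run_inactivation(p: VariantParams, cfg: SimConfig, vmax_corr: float,
                     duration: float = 5000.0,
                     test_v_corr: float | None = None) -> dict:
    """5-s depolarization -> r-values (percent remaining vs time)."""
    segs = inactivation_sweep(vmax_corr, cfg.junction_offset, duration,
                              test_v_corr=test_v_corr)
    rec = simulate_sweep(p, segs, cfg, protocol_name="inactivation")
    ps = pp.correct_junction(rec, cfg.junction_offset)
    r = ga.remaining_fractions(ps)
    return {"r_values": r, "sweep": ps}


def variant_gating_fits(p: VariantParams, cfg: SimConfig,
                        with_profiles: bool = True) -> ga.GatingFits:
    """Full activation/SSI/window/r-value summary for one variant."""
    iv = run_iv_analysis(p, cfg)
    ssi = run_ssi_analysis(p, replace(cfg, carrier="Ba"), iv["v_max"])
    window = ga.window_current(ssi["inactivation"], iv["points"])
    gf = ga.GatingFits(
        variant=p.name, activation=iv["activation"],
        inactivation=ssi["inactivation"], iv=iv["iv"], window=window)
    if with_profiles:
        r_ca = run_inactivation(p, replace(cfg, carrier="Ca"), iv["v_max"])
        r_ba = run_inactivation(p, replace(cfg, carrier="Ba"), iv["v_max"])
        gf.profile_ca = ga.InactivationProfile(r_values=r_ca["r_values"],
                                               carrier="Ca")
        gf.profile_ba = ga.InactivationProfile(r_values=r_ba["r_values"],
                                               carrier="Ba")
        gf.profile_ca.cdi_fraction = ga.cdi_fraction(
            r_ca["r_values"][250.0], r_ba["r_values"][250.0])
    return gf


DEFAULT_CONCENTRATIONS_NM = (1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0)


def _pharm_peaks(p: VariantParams, cfg: SimConfig, vmax_corr: float,
                 n_sweeps: int):
    """Peak-current series (sweep_index, time_s, peak_pa) at pharm cadence."""
    import pandas as pd

    from .preprocessing import peak_current

    off = cfg.junction_offset
    prot = pr.build_pharm_protocol(cmd(vmax_corr, off), n_sweeps,
                                   hp=cmd(HP_CORR, off), sample_rate=1.0 / cfg.dt)
    recs = simulate_protocol(p, prot, cfg)
    rows = []
    for r in recs:
        ps = pp.correct_junction(r, cfg.junction_offset)
        rows.append((r.sweep_index, r.meta["elapsed_s"],
                     peak_current(ps, blank_ms=1.5)))
    return pd.DataFrame(rows, columns=["sweep_index", "time_s", "peak_pa"])


def run_dose_response(p: VariantParams, cfg: SimConfig, vmax_corr: float,
                      concentrations=DEFAULT_CONCENTRATIONS_NM,
                      n_sweeps: int = 30, n_baseline: int = 3):
    """Run-down-corrected isradipine concentration-response for one variant.

    For each concentration the drug cell is recorded at the pharmacology
    cadence: ``n_baseline`` drug-free sweeps, then steady-state block.  A
    drug-free control cell recorded the same way provides the linear run-down
    correction.  Returns (DoseResponseFit, per-concentration inhibition %).
    """
    from . import pharmacology as ph

    control = _pharm_peaks(p, cfg, vmax_corr, n_sweeps)
    inhibition = []
    for c in concentrations:
        drug = _pharm_peaks(p, replace(cfg, drug_concentration_nM=float(c)),
                            vmax_corr, n_sweeps)
        series = drug.copy()
        series.iloc[:n_baseline] = control.iloc[:n_baseline]
        corrected = ph.rundown_correct(series, control, n_baseline=n_baseline)
        inhibition.append(100.0 * ph.steady_state_inhibition(corrected))
    fit = ph.fit_hill(list(concentrations), inhibition)
    return fit, inhibition
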