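"""Fitted and derived gating statistics.

Everything the voltage-clamp study reports per cell/variant lives here:
current-voltage (I-V) fits, normalized conductance (G-V) Boltzmann fits,
steady-state inactivation (SSI) fits with a non-inactivating plateau, window
currents, the inactivation time course (r-values), Ca2+- vs voltage-dependent
inactivation decomposition (f values, CDI fraction), persistent currents,
bi-exponential tail-current fits, and the I_tail/Q_ON open-probability proxy.

Conventions: voltages are junction-corrected mV, currents pA (inward
negative), densities pA/pF.  The I-V relationship is fitted to

    I(V) = G_max (V - V_rev) / (1 + exp[-(V - V_0.5)/k])

and the normalized conductance G(V) = I / (V - V_rev), G/G_max, to a
Boltzmann 1/(1 + exp[-(V - V_0.5)/k]).  Steady-state inactivation is fitted
to the modified Boltzmann with plateau (non-inactivating fraction)

    S(V) = (1 - plateau) / (1 + exp[(V - V_0.5,inact)/k_inact]) + plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import brentq

from .preprocessing import ProcessedSweep, median3, peak_current, test_window

__all__ = [
    "InsufficientDataError", "ProtocolMismatchError", "FitFailureError",
    "IVFit", "ActivationFit", "InactivationFit", "InactivationProfile",
    "TailFit", "PoProxy", "GatingFits",
    "extract_iv", "fit_iv", "conductance_transform", "fit_boltzmann",
    "extract_ssi", "fit_ssi", "window_current", "remaining_fractions",
    "cdi_f", "cdi_fraction", "persistent_current", "fit_tail",
    "fit_tail_arrays", "gating_charge_on", "po_proxy",
    "normalized_plateau_current",
    "R_TIMES_MS",
]

R_TIMES_MS = (50.0, 100.0, 250.0, 500.0, 1000.0, 5000.0)


class InsufficientDataError(ValueError):
    """Too few points/cells to compute the requested statistic."""


class ProtocolMismatchError(ValueError):
    """The recording does not contain the expected protocol structure."""


class FitFailureError(RuntimeError):
    """Nonlinear fit did not converge."""


# ----------------------------------------------------------------------
# result containers


@dataclass
class IVFit:
    g_max: float
    v_rev: float
    v_half: float
    slope: float
    residual_sse: float
    stderr: dict = field(default_factory=dict)
    points: pd.DataFrame | None = None
    identifiable: bool = True


@dataclass
class ActivationFit:
    v_half_act: float
    slope_act: float
    stderr: dict = field(default_factory=dict)
    points: pd.DataFrame | None = None
    identifiable: bool = True


@dataclass
class InactivationFit:
    v_half_inact: float
    slope_inact: float
    plateau: float
    stderr: dict = field(default_factory=dict)
    points: pd.DataFrame | None = None

    def availability(self, v):
        return (1.0 - self.plateau) / (
            1.0 + np.exp((np.asarray(v) - self.v_half_inact) / self.slope_inact)
        ) + self.plateau


@dataclass
class InactivationProfile:
    r_values: dict              # time ms -> % remaining
    carrier: str
    persistent_pct: float | None = None
    f_by_voltage: dict = field(default_factory=dict)
    cdi_fraction: float | None = None


@dataclass
class TailFit:
    tau_fast: float
    tau_slow: float
    a_fast: float
    a_slow: float
    c: float
    half_width: float
    norm_area: float
    residual_sse: float = np.nan
    single_exp_fallback: bool = False


@dataclass
class PoProxy:
    slopes: dict                # group -> regression slope (1/ms)
    slope_se: dict
    r2: dict
    f_statistic: float | None = None
    p_value: float | None = None


@dataclass
class GatingFits:
    """Per-variant summary consumed by the classifier."""

    variant: str
    activation: ActivationFit
    inactivation: InactivationFit
    iv: IVFit | None = None
    window: pd.DataFrame | None = None
    profile_ca: InactivationProfile | None = None
    profile_ba: InactivationProfile | None = None
    tail: dict | None = None    # repol mV -> TailFit


# ----------------------------------------------------------------------
# I-V


def extract_iv(recs: list[ProcessedSweep], blank_ms: float = 1.5) -> pd.DataFrame:
    """Per-voltage peak currents from an I-V family.

    Returns a DataFrame (v, i_pa, i_density) sorted by voltage, with V_max
    (the voltage of maximal inward current; ties broken toward the more
    hyperpolarized voltage) in ``.attrs['v_max']``.  The first ``blank_ms``
    of each test pulse are excluded from the peak search (onset transient).
    """
    rows = []
    for ps in recs:
        k0, k1 = test_window(ps)
        v_test = float(ps.v_corrected[(k0 + k1) // 2])
        rows.append((v_test, peak_current(ps, (k0, k1), blank_ms=blank_ms)))
    if len(rows) < 5:
        raise InsufficientDataError(f"I-V needs >= 5 voltages, got {len(rows)}")
    df = pd.DataFrame(rows, columns=["v", "i_pa"]).sort_values("v", ignore_index=True)
    df["i_density"] = df["i_pa"] / recs[0].capacitance
    if not (df["i_pa"] < 0).any():
        raise InsufficientDataError("no inward current at any voltage; "
                                    "V_max undefined")
    i_min = df["i_pa"].min()
    df.attrs["v_max"] = float(df.loc[df["i_pa"] == i_min, "v"].iloc[0])
    return df


def _iv_model(v, g_max, v_rev, v_half, k):
    return g_max * (v - v_rev) / (1.0 + np.exp(-(v - v_half) / k))


def fit_iv(points: pd.DataFrame) -> IVFit:
    """Least-squares fit of the I-V equation to per-voltage peak currents."""
    v = points["v"].to_numpy(float)
    i = points["i_pa"].to_numpy(float)
    if len(v) < 6:
        raise InsufficientDataError("I-V fit needs >= 6 points")
    v_max = points.attrs.get("v_max", v[np.argmin(i)])
    above = v > v_max
    if above.sum() >= 2 and (i[above] > 0).any():
        v_rev0 = float(np.interp(0.0, i[above], v[above]))
    else:
        v_rev0 = v.max() + 10.0
    g0 = abs(i.min()) / max(v_rev0 - v_max, 1.0)
    half = i.min() / 2.0
    below = v <= v_max
    v_half0 = float(np.interp(half, i[below][::-1], v[below][::-1])) \
        if below.sum() >= 2 else v_max - 10.0
    model = Model(_iv_model)
    pars = model.make_params(g_max=g0, v_rev=v_rev0, v_half=v_half0, k=8.0)
    pars["k"].set(min=0.5, max=30.0)
    pars["g_max"].set(min=1e-6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(i, pars, v=v)
    if not res.success:
        raise FitFailureError(f"I-V fit failed: {res.message}")
    p = res.params
    identifiable = (
        p["v_half"].value > v.min() - 25.0
        and p["v_half"].stderr is not None
        and p["v_half"].stderr < 25.0
    )
    return IVFit(
        g_max=p["g_max"].value, v_rev=p["v_rev"].value,
        v_half=p["v_half"].value, slope=p["k"].value,
        residual_sse=float(np.sum(res.residual ** 2)),
        stderr={n: p[n].stderr for n in p}, points=points,
        identifiable=bool(identifiable),
    )


def conductance_transform(points: pd.DataFrame, v_rev: float,
                          exclusion_mv: float = 2.0,
                          g_max: float | None = None) -> pd.DataFrame:
    """Normalized chord conductance G = I/(V - V_rev), G/G_max.

    Voltages within ``exclusion_mv`` of the reversal potential are excluded
    (singularity guard).  ``g_max`` defaults to the maximal chord conductance
    in the data; passing the fitted G_max of the I-V equation is more robust
    near the reversal potential.
    """
    df = points.loc[np.abs(points["v"] - v_rev) > exclusion_mv].copy()
    if df.empty:
        raise InsufficientDataError("all points within exclusion radius of V_rev")
    df["g"] = df["i_pa"] / (df["v"] - v_rev)
    if g_max is None:
        g_max = df["g"].max()
    if g_max <= 0:
        raise InsufficientDataError("non-positive maximal conductance")
    df["g_norm"] = df["g"] / g_max
    return df[["v", "g_norm"]].reset_index(drop=True)


def _boltzmann(v, v_half, k):
    return 1.0 / (1.0 + np.exp(-(v - v_half) / k))


def fit_boltzmann(gv_points: pd.DataFrame) -> ActivationFit:
    """Boltzmann fit of normalized G-V points (amplitude fixed at 1)."""
    v = gv_points["v"].to_numpy(float)
    g = gv_points["g_norm"].to_numpy(float)
    if len(v) < 6:
        raise InsufficientDataError("Boltzmann fit needs >= 6 points")
    v_half0 = float(np.interp(0.5, g, v)) if g.max() > 0.5 > g.min() else float(np.median(v))
    model = Model(_boltzmann)
    pars = model.make_params(v_half=v_half0, k=8.0)
    pars["k"].set(min=0.5, max=30.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(g, pars, v=v)
    if not res.success:
        raise FitFailureError(f"G-V Boltzmann fit failed: {res.message}")
    p = res.params
    spread = float(np.ptp(g))
    identifiable = spread > 0.2 and p["v_half"].stderr is not None \
        and p["v_half"].stderr < 25.0
    return ActivationFit(
        v_half_act=p["v_half"].value, slope_act=p["k"].value,
        stderr={n: p[n].stderr for n in p}, points=gv_points,
        identifiable=bool(identifiable),
    )


# ----------------------------------------------------------------------
# steady-state inactivation


def _ssi_windows(ps: ProcessedSweep):
    segs = ps.meta.get("segments")
    if not segs or len(segs) < 6:
        raise ProtocolMismatchError("not an SSI sweep (need control/conditioning/"
                                    "test segment structure)")
    ctrl, cond, test = segs[1], segs[3], segs[4]
    if ctrl["v_start"] != test["v_start"]:
        raise ProtocolMismatchError("control and test pulse voltages differ")
    dt = ps.dt
    t0 = 0.0
    bounds = []
    for seg in segs:
        bounds.append((int(round(t0 / dt)), int(round((t0 + seg["duration"]) / dt))))
        t0 += seg["duration"]
    return bounds[1], bounds[3], bounds[4], cond


def extract_ssi(recs: list[ProcessedSweep], min_control_pa: float = 20.0
                ) -> pd.DataFrame:
    """Availability (test/control peak ratio) per conditioning voltage."""
    rows = []
    for ps in recs:
        wc, _, wt, cond = _ssi_windows(ps)
        i_ctrl = peak_current(ps, wc, blank_ms=1.5)
        if abs(i_ctrl) < min_control_pa:
            continue  # control below noise floor: cell excluded
        i_test = peak_current(ps, wt, blank_ms=1.5)
        v_cond = cond["v_start"] + ps.junction_offset
        rows.append((float(v_cond), i_test / i_ctrl))
    if not rows:
        raise InsufficientDataError("no SSI sweeps with measurable control pulse")
    return pd.DataFrame(rows, columns=["v", "availability"]).sort_values(
        "v", ignore_index=True)


def _ssi_model(v, v_half, k, plateau):
    return (1.0 - plateau) / (1.0 + np.exp((v - v_half) / k)) + plateau


def fit_ssi(ssi_points: pd.DataFrame) -> InactivationFit:
    """Modified Boltzmann (with non-inactivating plateau) fit of SSI points."""
    v = ssi_points["v"].to_numpy(float)
    a = ssi_points["availability"].to_numpy(float)
    if len(v) < 6:
        raise InsufficientDataError("SSI fit needs >= 6 conditioning voltages")
    plateau0 = max(float(a.min()), 0.0)
    mid = plateau0 + (1.0 - plateau0) / 2.0
    order = np.argsort(-a)
    v_half0 = float(np.interp(-mid, -a[order], v[order]))
    model = Model(_ssi_model)
    pars = model.make_params(v_half=v_half0, k=8.0, plateau=plateau0)
    pars["k"].set(min=0.5, max=30.0)
    pars["plateau"].set(min=0.0, max=0.9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(a, pars, v=v)
    if not res.success:
        raise FitFailureError(f"SSI fit failed: {res.message}")
    p = res.params
    return InactivationFit(
        v_half_inact=p["v_half"].value, slope_inact=p["k"].value,
        plateau=p["plateau"].value,
        stderr={n: p[n].stderr for n in p}, points=ssi_points,
    )


def window_current(inact, iv_points: pd.DataFrame) -> pd.DataFrame:
    """Window current: SSI availability x current density, per voltage.

    ``inact`` is an :class:`InactivationFit` (curve evaluated on the I-V
    grid) or a DataFrame of SSI points (linearly interpolated; extrapolation
    disallowed, so the product is restricted to the overlapping voltages).
    """
    v = iv_points["v"].to_numpy(float)
    dens = iv_points["i_density"].to_numpy(float)
    if isinstance(inact, InactivationFit):
        avail = inact.availability(v)
        mask = np.ones_like(v, bool)
    else:
        sv = inact["v"].to_numpy(float)
        sa = inact["availability"].to_numpy(float)
        mask = (v >= sv.min()) & (v <= sv.max())
        if not mask.any():
            raise InsufficientDataError("no voltage overlap between SSI and I-V")
        avail = np.interp(v[mask], sv, sa)
    out = pd.DataFrame({
        "v": v[mask],
        "window_density": avail * dens[mask],
        "availability": avail,
        "i_density": dens[mask],
    })
    return out


# ----------------------------------------------------------------------
# inactivation time course / CDI


def remaining_fractions(ps: ProcessedSweep, times=R_TIMES_MS,
                        window_index: int | None = None,
                        blank_ms: float = 1.5) -> dict:
    """Percent of peak current remaining t ms after the peak of a long step.

    Offsets past the end of the depolarizing step are clipped to its final
    sample (the conventional "after 5000 ms" point of a 5-s pulse); the
    first ``blank_ms`` after step onset (gating/charging transient) are
    excluded from the peak search.
    """
    if window_index is None:
        # use the last non-holding segment (handles optional pre-pulse)
        idx = 0
        while True:
            try:
                test_window(ps, idx + 1)
                idx += 1
            except ValueError:
                break
        k0, k1 = test_window(ps, idx)
    else:
        k0, k1 = test_window(ps, window_index)
    dt = ps.dt
    k0 = min(k0 + int(round(blank_ms / dt)), k1 - 1)
    trace = median3(ps.i_leak_subtracted[k0:k1])
    pk_idx = int(np.argmax(np.abs(trace)))
    if pk_idx * dt > 50.0:
        warnings.warn(f"peak at {pk_idx * dt:.1f} ms after step onset "
                      "(> 50 ms); r-values may be unreliable")
    i_peak = trace[pk_idx]
    if i_peak == 0:
        raise InsufficientDataError("zero peak current; r-values undefined")
    out = {}
    for t in times:
        k = min(pk_idx + int(round(t / dt)), len(trace) - 1)
        out[float(t)] = 100.0 * float(trace[k] / i_peak)
    return out


def cdi_f(r_ba: float, r_ca: float) -> float:
    """Per-voltage CDI strength f = (r_Ba - r_Ca)/100 from r-values in %."""
    return (r_ba - r_ca) / 100.0


def cdi_fraction(r_ca: float, r_ba: float) -> float:
    """Fractional Ca2+-dependent component of inactivation, 1 - r_Ca/r_Ba."""
    if r_ba == 0:
        raise ZeroDivisionError("r_Ba is zero; CDI fraction undefined")
    return 1.0 - r_ca / r_ba


def persistent_current(ps: ProcessedSweep, tail_mean_ms: float = 10.0) -> float:
    """Fractional persistent current (%) after a long depolarization.

    The sweep must contain a 20-ms pre-pulse to V_max followed by the long
    test step; the mean current over the final ``tail_mean_ms`` of the test
    step is normalized to the pre-pulse peak.
    """
    try:
        pre = test_window(ps, 0)
        test = test_window(ps, 1)
    except ValueError as e:
        raise ProtocolMismatchError(
            "persistent-current sweep needs pre-pulse + test step") from e
    i_pre = peak_current(ps, pre, blank_ms=1.5)
    k0, k1 = test
    n_tail = max(int(round(tail_mean_ms / ps.dt)), 1)
    i_end = float(np.mean(ps.i_leak_subtracted[k1 - n_tail:k1]))
    if i_pre == 0:
        raise InsufficientDataError("zero pre-pulse peak")
    return 100.0 * i_end / i_pre


# ----------------------------------------------------------------------
# tail currents


def _biexp(t, a_fast, tau_fast, a_slow, tau_slow, c):
    return a_fast * np.exp(-t / tau_fast) + a_slow * np.exp(-t / tau_slow) + c


def fit_tail_arrays(t: np.ndarray, y: np.ndarray,
                    window_ms: float = 20.0) -> TailFit:
    """Bi-exponential fit of a normalized tail transient.

    ``t`` in ms from the repolarization sample, ``y`` the normalized current
    (inward negative, extremum ~ -1).  Falls back to a single exponential
    (flagged) when the two time constants are not separated by >= 1.5x.
    """
    keep = t <= window_ms
    t, y = t[keep], y[keep]
    y0 = y[np.argmax(np.abs(y))]
    model = Model(_biexp)
    pars = model.make_params(
        a_fast=0.7 * y0, tau_fast=0.2, a_slow=0.3 * y0, tau_slow=1.5, c=0.0)
    pars["tau_fast"].set(min=1e-3, max=50.0)
    pars["tau_slow"].set(min=1e-3, max=200.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(y, pars, t=t)
    fallback = False
    if res.success:
        p = res.params
        a_f, tf = p["a_fast"].value, p["tau_fast"].value
        a_s, ts = p["a_slow"].value, p["tau_slow"].value
        c = p["c"].value
        if tf > ts:  # enforce tau_fast < tau_slow by relabeling
            a_f, a_s, tf, ts = a_s, a_f, ts, tf
        if ts / tf < 1.5:
            fallback = True
    else:
        fallback = True
    if fallback:
        single = Model(lambda t, a, tau, c: a * np.exp(-t / tau) + c)
        spars = single.make_params(a=y0, tau=0.5, c=0.0)
        spars["tau"].set(min=1e-3, max=200.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sres = single.fit(y, spars, t=t)
        if not sres.success:
            raise FitFailureError("tail fit failed (bi- and single-exponential)")
        a_f, tf = sres.params["a"].value, sres.params["tau"].value
        a_s, ts, c = 0.0, np.inf, sres.params["c"].value
        res = sres

    def curve(tt):
        if np.isinf(ts):
            return a_f * np.exp(-tt / tf) + c
        return _biexp(tt, a_f, tf, a_s, ts, c)

    # full width at half-extremum on the fitted curve; instantaneous rise so
    # the left crossing is at t = 0
    peak_val = curve(0.0)
    half = peak_val / 2.0
    try:
        hw = brentq(lambda tt: curve(tt) - half, 0.0, window_ms)
    except ValueError:
        hw = np.nan
    # integral of the fitted curve over the window
    tf_term = a_f * tf * (1.0 - np.exp(-window_ms / tf))
    ts_term = 0.0 if np.isinf(ts) else a_s * ts * (1.0 - np.exp(-window_ms / ts))
    area = tf_term + ts_term + c * window_ms
    return TailFit(
        tau_fast=tf, tau_slow=ts, a_fast=a_f, a_slow=a_s, c=c,
        half_width=float(hw), norm_area=float(area),
        residual_sse=float(np.sum(res.residual ** 2)),
        single_exp_fallback=fallback,
    )


def fit_tail(ps: ProcessedSweep, window_ms: float = 20.0,
             norm_within_ms: float = 0.5) -> TailFit:
    """Locate the repolarization segment of a tail sweep, normalize, and fit.

    The trace is normalized by its extremum within the first
    ``norm_within_ms`` of the repolarization.
    """
    try:
        k0, k1 = test_window(ps, 1)
    except ValueError as e:
        raise ProtocolMismatchError("tail sweep needs pre-step + repolarization "
                                    "segments") from e
    dt = ps.dt
    k1 = min(k1, k0 + int(round(window_ms / dt)) + 1)
    y = ps.i_density[k0:k1]
    t = (np.arange(len(y))) * dt
    n0 = max(int(round(norm_within_ms / dt)), 1)
    norm = np.max(np.abs(y[:n0]))
    if norm == 0:
        raise InsufficientDataError("no tail current to normalize")
    return fit_tail_arrays(t, y / norm, window_ms=window_ms)


# ----------------------------------------------------------------------
# open-probability proxy


def gating_charge_on(ps: ProcessedSweep, window_ms: float = 10.0) -> float:
    """Integrated ON-gating charge (pA*ms) at the step onset.

    Meant for leak-subtracted sweeps stepped to the reversal potential, where
    ionic current vanishes and the integral isolates Q_ON.
    """
    k0, k1 = test_window(ps)
    k1 = min(k1, k0 + int(round(window_ms / ps.dt)))
    return float(np.trapezoid(ps.i_leak_subtracted[k0:k1], dx=ps.dt))


def po_proxy(q_on_a, i_tail_a, q_on_b=None, i_tail_b=None,
             labels=("A", "B")) -> PoProxy:
    """Per-group I_tail-vs-Q_ON linear regression; optional slope comparison.

    Slopes (1/ms) estimate relative channel open probability.  With two
    groups, equality of slopes is tested with the extra-sum-of-squares F test
    on the interaction term of a pooled linear model.
    """
    import statsmodels.api as sm

    groups = [(np.asarray(q_on_a, float), np.asarray(i_tail_a, float))]
    if q_on_b is not None:
        groups.append((np.asarray(q_on_b, float), np.asarray(i_tail_b, float)))
    slopes, ses, r2s = {}, {}, {}
    for lbl, (q, it) in zip(labels, groups):
        if len(q) < 5:
            raise InsufficientDataError(f"po_proxy needs >= 5 cells per group "
                                        f"(group {lbl} has {len(q)})")
        X = sm.add_constant(q)
        fit = sm.OLS(it, X).fit()
        slopes[lbl], ses[lbl], r2s[lbl] = (
            float(fit.params[1]), float(fit.bse[1]), float(fit.rsquared))
    f_stat = p_val = None
    if len(groups) == 2:
        q = np.concatenate([g[0] for g in groups])
        it = np.concatenate([g[1] for g in groups])
        grp = np.concatenate([np.zeros(len(groups[0][0])),
                              np.ones(len(groups[1][0]))])
        X_full = np.column_stack([np.ones_like(q), q, grp, q * grp])
        X_null = np.column_stack([np.ones_like(q), q, grp])
        fit_full = sm.OLS(it, X_full).fit()
        fit_null = sm.OLS(it, X_null).fit()
        ftest = fit_full.compare_f_test(fit_null)
        f_stat, p_val = float(ftest[0]), float(ftest[1])
    return PoProxy(slopes=slopes, slope_se=ses, r2=r2s,
                   f_statistic=f_stat, p_value=p_val)


# ----------------------------------------------------------------------
# sustained subthreshold depolarization


def normalized_plateau_current(ps: ProcessedSweep, conductance_at_v: float
                               ) -> dict:
    """Scale a normalized subthreshold trace by the conductance at its voltage.

    The sweep must contain a 20-ms pre-pulse to V_max followed by the long
    test step (e.g. 5 s at -20 mV); the test trace normalized to the
    pre-pulse peak is multiplied by ``conductance_at_v`` (the normalized G-V
    value at the test voltage).  Returns the scaled trace and its value at
    the peak and at 300 ms.
    """
    try:
        pre = test_window(ps, 0)
        k0, k1 = test_window(ps, 1)
    except ValueError as e:
        raise ProtocolMismatchError("needs pre-pulse + test step") from e
    i_pre = peak_current(ps, pre)
    trace = median3(ps.i_leak_subtracted[k0:k1]) / abs(i_pre) * conductance_at_v
    dt = ps.dt
    t = np.arange(len(trace)) * dt
    pk_idx = int(np.argmax(np.abs(trace)))
    k300 = min(int(round(300.0 / dt)), len(trace) - 1)
    return {
        "t_ms": t, "trace": trace,
        "peak": float(trace[pk_idx]),
        "at_300ms": float(trace[k300]),
    }
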