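"""Run-down-corrected concentration-response analysis.

Steady-state inhibition of the peak Ca2+ current by a dihydropyridine
blocker is measured sweep-by-sweep at the pharmacology cadence, corrected
for the linear drug-independent current decline ("run-down") observed in
control cells, and fitted with a one-parameter Hill curve

    inhibition(c) = 100 * c / (c + IC50)        (Hill slope 1, 0-100 fixed)

with the 95 % confidence interval computed on log(IC50).  Two datasets are
compared with the extra-sum-of-squares F test against a shared-IC50 null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Model
from scipy import stats

from .gating_analysis import FitFailureError, InsufficientDataError

__all__ = [
    "DoseResponseFit", "BaselineUnstableError",
    "rundown_correct", "steady_state_inhibition", "fit_hill", "hill_f_test",
]


class BaselineUnstableError(ValueError):
    """Pre-drug baseline drifts beyond the allowed slope; cell rejected."""


@dataclass
class DoseResponseFit:
    ic50: float                       # nM
    ci95: tuple[float, float]         # nM
    hill_slope: float = 1.0
    top: float = 100.0
    bottom: float = 0.0
    inhibition: pd.DataFrame | None = None   # per-concentration %
    comparison_f: float | None = None
    comparison_p: float | None = None


def rundown_correct(drug_peaks: pd.DataFrame, control_peaks: pd.DataFrame,
                    n_baseline: int = 3,
                    baseline_slope_limit: float = 0.02) -> pd.DataFrame:
    """Correct a drug peak series for linear run-down from control cells.

    Both inputs need columns (sweep_index, time_s, peak_pa).  The drug series
    must start with >= ``n_baseline`` drug-free sweeps whose relative linear
    drift per sweep stays below ``baseline_slope_limit`` (fraction/sweep).
    The control series (drug-free cell, same cadence) is fitted with a line
    in relative peak vs time; the observed relative drug current is divided
    by that line at matching times.  Adds columns ``rel``, ``control_fit``,
    ``rel_corrected`` and ``inhibition`` (fractional, 1 - corrected current).
    """
    d = drug_peaks.sort_values("sweep_index").reset_index(drop=True).copy()
    if len(d) < n_baseline + 1:
        raise InsufficientDataError("need baseline sweeps plus drug sweeps")
    base = d.iloc[:n_baseline]
    base_mean = float(np.mean(np.abs(base["peak_pa"])))
    if base_mean == 0:
        raise InsufficientDataError("zero baseline current")
    slope = np.polyfit(base["sweep_index"], np.abs(base["peak_pa"]) / base_mean, 1)[0]
    if abs(slope) > baseline_slope_limit:
        raise BaselineUnstableError(
            f"baseline drift {slope:+.3f}/sweep exceeds {baseline_slope_limit}")
    d["rel"] = np.abs(d["peak_pa"]) / base_mean

    c = control_peaks.sort_values("sweep_index")
    c_rel = np.abs(c["peak_pa"]) / float(np.mean(np.abs(c["peak_pa"].iloc[:n_baseline])))
    coef = np.polyfit(c["time_s"], c_rel, 1)
    t0 = float(np.mean(d["time_s"].iloc[:n_baseline]))
    fit_at = np.polyval(coef, d["time_s"]) / np.polyval(coef, t0)
    d["control_fit"] = np.maximum(fit_at, 1e-6)
    d["rel_corrected"] = d["rel"] / d["control_fit"]
    d["inhibition"] = 1.0 - d["rel_corrected"]
    return d


def steady_state_inhibition(corrected: pd.DataFrame, n_last: int = 3) -> float:
    """Steady-state fractional inhibition: mean of the last ``n_last`` sweeps."""
    return float(np.mean(corrected["inhibition"].iloc[-n_last:]))


def _hill(c, log_ic50):
    ic50 = 10.0 ** log_ic50
    return 100.0 * c / (c + ic50)


def _fit_log_ic50(conc, inh):
    conc = np.asarray(conc, float)
    inh = np.asarray(inh, float)
    model = Model(_hill)
    mid = conc[np.argmin(np.abs(inh - 50.0))]
    pars = model.make_params(log_ic50=np.log10(max(mid, 1e-3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(inh, pars, c=conc)
    if not res.success:
        raise FitFailureError(f"Hill fit failed: {res.message}")
    return res


def fit_hill(concentrations, inhibition,
             concentrations_b=None, inhibition_b=None) -> DoseResponseFit:
    """Constrained Hill fit (slope 1, bottom 0, top 100); IC50 with 95 % CI.

    Inhibition is in percent.  When a second dataset is supplied, the two
    separate fits are compared with the extra-sum-of-squares F test against
    a single shared IC50, and the returned fit describes the first dataset
    with the comparison statistics attached.
    """
    conc = np.asarray(concentrations, float)
    inh = np.asarray(inhibition, float)
    if len(conc) < 4:
        raise InsufficientDataError("need >= 4 concentrations")
    span = np.log10(conc.max() / conc.min())
    if span < 1.5:
        raise InsufficientDataError(
            f"concentrations must span >= 1.5 log units (got {span:.2f})")
    order = np.argsort(conc)
    if np.any(np.diff(inh[order]) < -10.0):
        warnings.warn("inhibition decreases with concentration beyond tolerance")
    res = _fit_log_ic50(conc, inh)
    log_ic50 = res.params["log_ic50"].value
    se = res.params["log_ic50"].stderr
    if se is None or not np.isfinite(se):
        se = 0.0
    dof = max(len(conc) - 1, 1)
    tcrit = stats.t.ppf(0.975, dof)
    ci = (10.0 ** (log_ic50 - tcrit * se), 10.0 ** (log_ic50 + tcrit * se))
    fit = DoseResponseFit(
        ic50=float(10.0 ** log_ic50), ci95=(float(ci[0]), float(ci[1])),
        inhibition=pd.DataFrame({"conc_nM": conc, "inhibition_pct": inh}),
    )
    if concentrations_b is not None:
        f, p = hill_f_test((conc, inh),
                           (np.asarray(concentrations_b, float),
                            np.asarray(inhibition_b, float)))
        fit.comparison_f, fit.comparison_p = f, p
    return fit


def hill_f_test(data_a, data_b) -> tuple[float, float]:
    """Extra-sum-of-squares F test: separate IC50s vs one shared IC50."""
    ca, ia = data_a
    cb, ib = data_b
    sse_a = float(np.sum(_fit_log_ic50(ca, ia).residual ** 2))
    sse_b = float(np.sum(_fit_log_ic50(cb, ib).residual ** 2))
    sse_sep = sse_a + sse_b
    c_all = np.concatenate([ca, cb])
    i_all = np.concatenate([ia, ib])
    sse_shared = float(np.sum(_fit_log_ic50(c_all, i_all).residual ** 2))
    n = len(c_all)
    df_sep = n - 2
    df_extra = 1
    if df_sep <= 0:
        raise InsufficientDataError("too few points for F test")
    sse_sep = max(sse_sep, 1e-30)  # noiseless synthetic data guard
    f = ((sse_shared - sse_sep) / df_extra) / (sse_sep / df_sep)
    p = float(stats.f.sf(f, df_extra, df_sep))
    return float(f), p
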