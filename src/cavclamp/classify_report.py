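"""Gain-/loss-of-function classification and report rendering.

A variant is called GOF when any enhancement rule fires: a pronounced
hyperpolarizing shift of activation, a substantially increased
non-inactivating current fraction, or a clearly enlarged subthreshold
window current.  It is called LOF when activation is shifted depolarized
and no enhancement rule fires; otherwise indeterminate.  Thresholds are
configurable; the defaults distill the qualitative diagnostic rule
(pronounced negative activation shifts and/or pronounced slowing of
inactivation mark pathogenic, function-enhancing variants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .gating_analysis import GatingFits, InsufficientDataError

__all__ = [
    "ClassifierThresholds", "VariantVerdict",
    "classify_variant", "compare_groups", "render_report",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    gof_act_shift_mv: float = -5.0        # Δ V_0.5,act at or below -> enhancement
    lof_act_shift_mv: float = 3.0         # Δ V_0.5,act at or above -> reduction
    plateau_increase_points: float = 10.0  # Δ non-inactivating %, at or above
    window_ratio: float = 2.0             # subthreshold window current ratio


@dataclass
class VariantVerdict:
    variant: str
    delta_v_act: float
    delta_v_inact: float
    window_ratio_at_subthreshold: float | None
    persistent_delta: float               # percentage points
    inactivation_slowing: bool
    tail_slowing: bool
    verdict: str                          # GOF | LOF | indeterminate
    evidence: dict = field(default_factory=dict)


def _subthreshold_window_ratio(wt: GatingFits, mut: GatingFits,
                               v_sub: float = -40.0) -> float | None:
    if wt.window is None or mut.window is None:
        return None
    def at(df, v):
        i = (df["v"] - v).abs().idxmin()
        if abs(df["v"].loc[i] - v) > 2.5:
            return None
        return float(df["window_density"].loc[i])
    w_wt, w_mut = at(wt.window, v_sub), at(mut.window, v_sub)
    if w_wt is None or w_mut is None or w_wt == 0:
        return None
    return abs(w_mut) / abs(w_wt)


def classify_variant(wt: GatingFits, mut: GatingFits,
                     thresholds: ClassifierThresholds | None = None
                     ) -> VariantVerdict:
    """Rule-based GOF/LOF verdict from paired wild-type and mutant fits."""
    th = thresholds or ClassifierThresholds()
    if wt.activation is None or mut.activation is None \
            or wt.inactivation is None or mut.inactivation is None:
        raise InsufficientDataError("activation and SSI fits required for both")
    d_act = mut.activation.v_half_act - wt.activation.v_half_act
    d_inact = mut.inactivation.v_half_inact - wt.inactivation.v_half_inact
    d_plateau = 100.0 * (mut.inactivation.plateau - wt.inactivation.plateau)
    w_ratio = _subthreshold_window_ratio(wt, mut)

    slower_inact = False
    if wt.profile_ca and mut.profile_ca:
        r_wt = wt.profile_ca.r_values.get(250.0)
        r_mut = mut.profile_ca.r_values.get(250.0)
        if r_wt is not None and r_mut is not None:
            slower_inact = r_mut > r_wt + 10.0
    tail_slowing = False
    if wt.tail and mut.tail:
        common = set(wt.tail) & set(mut.tail)
        tail_slowing = any(
            mut.tail[v].tau_slow > 1.5 * wt.tail[v].tau_slow for v in common)

    rules = {
        "activation_shift_gof": d_act <= th.gof_act_shift_mv,
        "plateau_increase": d_plateau >= th.plateau_increase_points,
        "window_current_increase": (w_ratio is not None
                                    and w_ratio >= th.window_ratio),
        "activation_shift_lof": d_act >= th.lof_act_shift_mv,
    }
    enhancement = (rules["activation_shift_gof"] or rules["plateau_increase"]
                   or rules["window_current_increase"])
    if enhancement:
        verdict = "GOF"
    elif rules["activation_shift_lof"]:
        verdict = "LOF"
    else:
        verdict = "indeterminate"
    return VariantVerdict(
        variant=mut.variant,
        delta_v_act=float(d_act), delta_v_inact=float(d_inact),
        window_ratio_at_subthreshold=w_ratio,
        persistent_delta=float(d_plateau),
        inactivation_slowing=bool(slower_inact),
        tail_slowing=bool(tail_slowing),
        verdict=verdict, evidence=rules,
    )


def compare_groups(a, b, test: str = "t", n_comparisons: int = 1):
    """Standard two-group comparison: t, Mann-Whitney U, or one-way ANOVA.

    Returns (statistic, p); p is Bonferroni-adjusted by ``n_comparisons``
    when several voltages/time points are compared in a family.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need n >= 3 per group")
    if test == "t":
        s, p = stats.ttest_ind(a, b)
    elif test == "mannwhitney":
        s, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "anova":
        s, p = stats.f_oneway(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(s), float(min(p * n_comparisons, 1.0))


def render_report(fits: dict, verdicts: list[VariantVerdict],
                  out_dir, config: dict | None = None) -> dict:
    """Write tidy CSV summary tables and JSON verdicts.

    ``fits`` maps variant name -> :class:`GatingFits`.  Produces
    ``gating_parameters.csv`` (activation/SSI parameters per variant),
    ``r_values.csv`` (inactivation time course), ``verdicts.json`` and a
    ``run_log.json`` echoing the resolved configuration.  Returns the paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, gf in fits.items():
        rows.append({
            "group": name,
            "v_half_act_mv": gf.activation.v_half_act if gf.activation else np.nan,
            "k_act_mv": gf.activation.slope_act if gf.activation else np.nan,
            "v_rev_mv": gf.iv.v_rev if gf.iv else np.nan,
            "v_half_inact_mv": gf.inactivation.v_half_inact if gf.inactivation else np.nan,
            "k_inact_mv": gf.inactivation.slope_inact if gf.inactivation else np.nan,
            "non_inactivating_pct": 100.0 * gf.inactivation.plateau
            if gf.inactivation else np.nan,
        })
    params_path = out / "gating_parameters.csv"
    pd.DataFrame(rows).to_csv(params_path, index=False)

    r_rows = []
    for name, gf in fits.items():
        for prof, carrier in ((gf.profile_ca, "Ca"), (gf.profile_ba, "Ba")):
            if prof is None:
                continue
            for t, r in prof.r_values.items():
                r_rows.append({"group": name, "carrier": carrier,
                               "time_ms": t, "r_pct": r})
    r_path = out / "r_values.csv"
    pd.DataFrame(r_rows, columns=["group", "carrier", "time_ms", "r_pct"]
                 ).to_csv(r_path, index=False)

    verdicts_path = out / "verdicts.json"
    verdicts_path.write_text(json.dumps(
        [asdict(v) for v in verdicts], indent=1, sort_keys=True, default=str))
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(
        {"config": config or {}, "variants": sorted(fits),
         "n_verdicts": len(verdicts)}, indent=1, sort_keys=True))
    if not fits:
        import warnings
        warnings.warn("empty analysis set; report contains headers only")
    return {"gating_parameters": params_path, "r_values": r_path,
            "verdicts": verdicts_path, "run_log": log_path}
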