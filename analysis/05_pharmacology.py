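"""Isradipine concentration-response of WT_L vs S652L_L.

Simulates run-down-contaminated pharmacology recordings (100-ms steps to
V_max at 0.1 Hz, 3 drug-free baseline sweeps, drug-free control cells),
corrects for run-down, fits constrained Hill curves (slope 1, 0-100 fixed)
and compares the two IC50s with the extra-sum-of-squares F test.

Writes results/dose_response.csv and results/ic50_fits.json.

Run from the repository root:  python analysis/05_pharmacology.py
"""

import json
from pathlib import Path

import pandas as pd

from cavclamp import load_variant
from cavclamp.channel_sim import SimConfig
from cavclamp.pharmacology import hill_f_test
from cavclamp.pipeline import (
    DEFAULT_CONCENTRATIONS_NM,
    run_dose_response,
    run_iv_analysis,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(noise_sd=0.0, seed=1)
    rows, fits, data = [], {}, {}
    for name in ("WT_L", "S652L_L"):
        p = load_variant(name)
        v_max = run_iv_analysis(p, cfg)["v_max"]
        fit, inhibition = run_dose_response(p, cfg, v_max)
        fits[name] = fit
        data[name] = (list(DEFAULT_CONCENTRATIONS_NM), inhibition)
        for c, inh in zip(DEFAULT_CONCENTRATIONS_NM, inhibition):
            rows.append({"group": name, "conc_nM": c, "inhibition_pct": inh})
        print(f"{name}: IC50 {fit.ic50:5.1f} nM "
              f"(95% CI {fit.ci95[0]:.1f} - {fit.ci95[1]:.1f})")
    f_stat, p_val = hill_f_test(data["WT_L"], data["S652L_L"])
    fold = fits["WT_L"].ic50 / fits["S652L_L"].ic50
    print(f"\nS652L_L is {fold:.2f}x more sensitive to isradipine than WT_L "
          f"(extra-sum-of-squares F = {f_stat:.1f}, p = {p_val:.2e}).")
    pd.DataFrame(rows).to_csv(OUT / "dose_response.csv", index=False)
    (OUT / "ic50_fits.json").write_text(json.dumps({
        name: {"ic50_nM": fit.ic50, "ci95_nM": list(fit.ci95)}
        for name, fit in fits.items()
    } | {"fold_change": fold, "f_statistic": f_stat, "p_value": p_val},
        indent=1, sort_keys=True))
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
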