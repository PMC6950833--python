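"""Simulate example whole-cell recordings for every packaged variant.

Writes compact example sweep archives (CSV + JSON sidecar, shared schema)
under results/raw/: a coarse I-V family and a 5-s Ca2+ inactivation sweep
per variant, with realistic recording noise.  The downstream analysis
scripts re-simulate the full-resolution families in memory; these files
document the raw-data format and give a quick visual check of the model.

Run from the repository root:  python analysis/01_simulate_recordings.py
"""

from pathlib import Path

import numpy as np

from cavclamp import list_variants, load_variant
from cavclamp.channel_sim import SimConfig, simulate_protocol, simulate_sweep
from cavclamp.io import write_sweeps
from cavclamp.pipeline import cmd, inactivation_sweep
from cavclamp.protocols import build_iv_protocol

OUT = Path(__file__).resolve().parents[1] / "results" / "raw"
SEED = 2024


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(noise_sd=2.0, seed=SEED, dt=0.1)  # 10 kHz archive rate
    for name in list_variants():
        p = load_variant(name)
        prot = build_iv_protocol(cmd(-89.0), cmd(-60.0), cmd(40.0), 20.0, 50.0,
                                 sample_rate=1.0 / cfg.dt)
        recs = simulate_protocol(p, prot, cfg)
        write_sweeps(recs, OUT / f"{name.lower()}_iv_example.csv")
        segs = inactivation_sweep(0.0, cfg.junction_offset, duration=1000.0)
        rec = simulate_sweep(p, segs, cfg, protocol_name="inactivation")
        write_sweeps([rec], OUT / f"{name.lower()}_inactivation_example.csv")
        # step-pulse peak (excludes the large repolarization tail transient)
        peak = min(
            r.current[np.abs(r.command_v - v) < 1e-6].min()
            for r, v in zip(recs, prot.meta["test_voltages"]))
        print(f"{name}: wrote I-V example ({len(recs)} sweeps, "
              f"test-pulse peak {peak:.0f} pA) and 1-s Ca2+ inactivation sweep")
    print(f"\nraw examples in {OUT}")


if __name__ == "__main__":
    main()
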