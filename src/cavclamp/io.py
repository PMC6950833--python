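"""Shared sweep CSV + sidecar JSON schema.

One CSV per protocol run: a ``time_ms`` column, then per sweep a pair of
columns ``v{i}_mV`` (command voltage) and ``i{i}_pA``; a sidecar JSON file
carries capacitance, carrier, protocol name, seed and per-sweep metadata.
Round-trips :class:`~cavclamp.channel_sim.SweepRecording` lists losslessly
up to float formatting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .channel_sim import SweepRecording

__all__ = ["write_sweeps", "read_sweeps"]


def write_sweeps(recs: list[SweepRecording], csv_path) -> None:
    csv_path = Path(csv_path)
    n = max(len(r.time) for r in recs)
    cols = {"time_ms": np.full(n, np.nan)}
    cols["time_ms"][: len(recs[0].time)] = recs[0].time
    for r in recs:
        v = np.full(n, np.nan)
        i = np.full(n, np.nan)
        v[: len(r.command_v)] = r.command_v
        i[: len(r.current)] = r.current
        cols[f"v{r.sweep_index}_mV"] = v
        cols[f"i{r.sweep_index}_pA"] = i
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    sidecar = {
        "capacitance_pF": recs[0].capacitance,
        "carrier": recs[0].carrier,
        "protocol_name": recs[0].protocol_name,
        "n_sweeps": len(recs),
        "sweeps": [
            {"sweep_index": r.sweep_index, "n_samples": len(r.time), "meta": r.meta}
            for r in recs
        ],
    }
    csv_path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True, default=str))


def read_sweeps(csv_path) -> list[SweepRecording]:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    recs = []
    for entry in side["sweeps"]:
        idx = entry["sweep_index"]
        ns = entry["n_samples"]
        recs.append(SweepRecording(
            time=df["time_ms"].to_numpy()[:ns],
            command_v=df[f"v{idx}_mV"].to_numpy()[:ns],
            current=df[f"i{idx}_pA"].to_numpy()[:ns],
            capacitance=side["capacitance_pF"],
            carrier=side["carrier"],
            protocol_name=side["protocol_name"],
            sweep_index=idx,
            meta=entry.get("meta", {}),
        ))
    return recs
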