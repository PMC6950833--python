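"""Raw sweep conditioning: junction correction, leak subtraction, QC.

Turns :class:`~cavclamp.channel_sim.SweepRecording` objects into
:class:`ProcessedSweep` objects carrying junction-corrected voltages,
leak-subtracted currents and current densities (pA/pF), plus a prospective
amplitude-based quality-control verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channel_sim import SweepRecording

__all__ = [
    "ProcessedSweep",
    "correct_junction",
    "leak_subtract_offline",
    "leak_subtract_p4",
    "qc_filter",
    "median3",
    "peak_current",
    "test_window",
]

QC_MIN_PA = 100.0   # prospective inclusion window on peak current magnitude
QC_MAX_PA = 1000.0


@dataclass
class ProcessedSweep:
    """A sweep after junction correction and (optionally) leak subtraction."""

    time: np.ndarray
    command_v: np.ndarray
    v_corrected: np.ndarray
    i_leak_subtracted: np.ndarray
    capacitance: float
    carrier: str
    protocol_name: str
    sweep_index: int
    junction_offset: float
    leak_subtracted: bool = False
    qc_pass: bool = True
    qc_reason: str = ""
    meta: dict = field(default_factory=dict)

    @property
    def i_density(self) -> np.ndarray:
        """Current density in pA/pF."""
        return self.i_leak_subtracted / self.capacitance

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def holding_v(self) -> float:
        return float(self.v_corrected[0])


def correct_junction(rec: SweepRecording, offset: float = -9.3) -> ProcessedSweep:
    """Shift command voltages by the liquid-junction offset; currents untouched."""
    return ProcessedSweep(
        time=rec.time,
        command_v=rec.command_v,
        v_corrected=rec.command_v + offset,
        i_leak_subtracted=rec.current.copy(),
        capacitance=rec.capacitance,
        carrier=rec.carrier,
        protocol_name=rec.protocol_name,
        sweep_index=rec.sweep_index,
        junction_offset=offset,
        meta=dict(rec.meta),
    )


def _segments_ms(ps: ProcessedSweep) -> list[tuple[float, float, dict]]:
    out, t0 = [], 0.0
    for seg in ps.meta.get("segments", []):
        out.append((t0, t0 + seg["duration"], seg))
        t0 += seg["duration"]
    return out


def test_window(ps: ProcessedSweep, index: int = 0,
                exclude_leak_step: bool = True) -> tuple[int, int]:
    """Sample bounds [k0, k1) of the ``index``-th non-holding segment.

    Segments at the holding potential (and, by default, the hyperpolarizing
    leak step) are skipped.  Falls back to command-voltage transitions when
    no segment metadata is available.
    """
    dt = ps.dt
    hp = ps.command_v[0]
    segs = _segments_ms(ps)
    found = 0
    for t0, t1, seg in segs:
        if seg["v_start"] == hp and seg["v_end"] == hp:
            continue
        if exclude_leak_step and seg["kind"] == "step" and seg["v_start"] < hp:
            continue
        if found == index:
            return int(round(t0 / dt)), int(round(t1 / dt))
        found += 1
    if segs:
        raise ValueError(f"no non-holding segment with index {index}")
    # fallback: contiguous runs where command deviates from holding
    dev = np.abs(ps.command_v - hp) > 1e-9
    edges = np.flatnonzero(np.diff(dev.astype(int)))
    starts = [int(e) + 1 for e in edges[::2]]
    ends = [int(e) + 1 for e in edges[1::2]] + [len(dev)]
    if index >= len(starts):
        raise ValueError(f"no non-holding run with index {index}")
    return starts[index], ends[index]


def median3(x: np.ndarray) -> np.ndarray:
    """3-sample running median (edge samples passed through)."""
    if len(x) < 3:
        return x.copy()
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def peak_current(ps: ProcessedSweep, window: tuple[int, int] | None = None,
                 smooth: bool = True, blank_ms: float = 0.0) -> float:
    """Signed extremum (largest |I|) of the (median-smoothed) trace in a window.

    ``blank_ms`` skips the initial samples of the window, excluding the
    gating/charging transient at the step onset from the peak search.
    """
    k0, k1 = window if window is not None else test_window(ps)
    if blank_ms > 0:
        k0 = min(k0 + int(round(blank_ms / ps.dt)), k1 - 1)
    seg = ps.i_leak_subtracted[k0:k1]
    if smooth:
        seg = median3(seg)
    idx = int(np.argmax(np.abs(seg)))
    return float(seg[idx])


def leak_subtract_offline(ps: ProcessedSweep,
                          hyper_step: dict | None = None) -> ProcessedSweep:
    """Linear leak subtraction from a hyperpolarizing calibration step.

    The leak conductance is estimated as (steady step current - holding
    baseline) / dV using the mean over the final 60 % of the step; the line
    I_leak(V) = I_hold + g*(V - V_hold) is then subtracted at every sample.
    Exact for a linear leak; idempotent up to noise.
    """
    dt = ps.dt
    hp_cmd = ps.command_v[0]
    if hyper_step is None:
        ls = ps.meta.get("leak_step")
        if ls is None:
            raise ValueError("recording has no hyperpolarizing leak step "
                             "(protocol-mismatch)")
        hyper_step = {"v_from": hp_cmd, "v_to": hp_cmd + ls[0], "duration": ls[1]}
    v_to = hyper_step["v_to"]
    mask = np.abs(ps.command_v - v_to) < 1e-6
    if not mask.any():
        raise ValueError("hyperpolarizing step voltage not found in sweep "
                         "(protocol-mismatch)")
    k = np.flatnonzero(mask)
    k0, k1 = k[0], k[-1] + 1
    n = k1 - k0
    steady = ps.i_leak_subtracted[k0 + int(0.4 * n):k1]
    i_step = float(np.mean(steady))
    base_mask = np.abs(ps.command_v[:k0] - hp_cmd) < 1e-6
    if not base_mask.any():
        raise ValueError("no holding baseline before leak step")
    i_hold = float(np.mean(ps.i_leak_subtracted[:k0][base_mask]))
    g = (i_step - i_hold) / (v_to - hyper_step["v_from"])  # nS
    leak_line = i_hold + g * (ps.command_v - hp_cmd)
    out = replace(ps, i_leak_subtracted=ps.i_leak_subtracted - leak_line,
                  leak_subtracted=True)
    out.meta = dict(ps.meta, leak_g_nS=g, leak_method="offline_step")
    return out


def leak_subtract_p4(rec_main: SweepRecording,
                     rec_subpulses: list[SweepRecording],
                     *, polarity: int = -1,
                     junction_offset: float = -9.3) -> ProcessedSweep:
    """P/4 online-style leak subtraction.

    Four sub-sweeps at 1/4 command amplitude (``polarity=-1``: mirrored about
    holding) are baseline-corrected and summed; for a linear leak the sum
    equals (minus) the main sweep's leak component relative to holding.
    """
    if len(rec_subpulses) != 4:
        raise ValueError(f"P/4 requires exactly 4 sub-sweeps, got {len(rec_subpulses)}")
    ps = correct_junction(rec_main, junction_offset)
    n = len(ps.i_leak_subtracted)

    def pre_pulse_baseline(cmd_v, current):
        # mean current over the initial holding segment only (tail currents
        # after the pulse would otherwise contaminate the baseline)
        dev = np.flatnonzero(np.abs(cmd_v - cmd_v[0]) > 1e-6)
        k1 = dev[0] if dev.size else len(cmd_v)
        return float(np.mean(current[:k1]))

    i_base_main = pre_pulse_baseline(rec_main.command_v, rec_main.current)
    acc = np.zeros(n)
    for sub in rec_subpulses:
        if len(sub.current) != n:
            raise ValueError("sub-sweep sample count differs from main sweep")
        acc += sub.current - pre_pulse_baseline(sub.command_v, sub.current)
    corrected = (ps.i_leak_subtracted - i_base_main) - float(polarity) * acc
    out = replace(ps, i_leak_subtracted=corrected, leak_subtracted=True)
    out.meta = dict(ps.meta, leak_method="p4", p4_polarity=polarity)
    return out


def qc_filter(recs: list[ProcessedSweep], min_peak: float = QC_MIN_PA,
              max_peak: float = QC_MAX_PA,
              peaks: list[float] | None = None
              ) -> tuple[list[ProcessedSweep], list[ProcessedSweep]]:
    """Prospective amplitude window: keep |peak| in the closed interval.

    Recordings with peak current magnitude below ``min_peak`` or above
    ``max_peak`` (measured post-leak-subtraction at the test pulse) are
    excluded; boundaries are kept.  Returns (kept, excluded) partition.
    """
    kept, excluded = [], []
    for i, ps in enumerate(recs):
        pk = peaks[i] if peaks is not None else peak_current(ps)
        mag = abs(pk)
        ps.meta = dict(ps.meta, qc_peak_pa=pk)
        if mag < min_peak:
            ps.qc_pass, ps.qc_reason = False, f"|peak| {mag:.1f} pA < {min_peak} pA"
            excluded.append(ps)
        elif mag > max_peak:
            ps.qc_pass, ps.qc_reason = False, f"|peak| {mag:.1f} pA > {max_peak} pA"
            excluded.append(ps)
        else:
            ps.qc_pass, ps.qc_reason = True, ""
            kept.append(ps)
    return kept, excluded
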