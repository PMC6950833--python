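"""Action-potential-waveform train analysis.

Per-sweep repolarization-phase peak currents, peak decay across the train,
cumulative inward Ca2+ charge (normalized to a pre-train ramp reference),
and fluorescence normalization.  The repolarization window runs from the
start of the +20 -> -70 mV downstroke ramp to the end of the
afterhyperpolarization ramp; only inward (negative) current counts toward
the Ca2+ charge, excluding the outward gating/passive component at the
spike peak.
"""

from __future__ import annotations

import numpy as np

from .gating_analysis import InsufficientDataError, ProtocolMismatchError
from .preprocessing import ProcessedSweep

__all__ = [
    "TrainSummary", "repolarization_window", "peak_per_sweep", "train_decay",
    "integrate_charge", "normalize_fluorescence",
]

from dataclasses import dataclass, field


@dataclass
class TrainSummary:
    peak_per_sweep: list          # pA/pF
    decay_pct: float
    cum_charge: np.ndarray        # normalized, per sweep (cumulative)
    first_ap_peak: float          # pA/pF
    f_over_f0_end: float | None = None
    meta: dict = field(default_factory=dict)


def repolarization_window(ps: ProcessedSweep) -> tuple[int, int]:
    """Sample bounds of the downstroke + afterhyperpolarization ramps."""
    segs = ps.meta.get("segments")
    if not segs:
        raise ProtocolMismatchError("sweep has no segment metadata")
    dt = ps.dt
    t0 = 0.0
    start = end = None
    for seg in segs:
        t1 = t0 + seg["duration"]
        if seg["kind"] == "ramp" and seg["v_end"] < seg["v_start"]:
            if start is None:
                start = t0
            end = t1
        elif seg["kind"] == "ramp" and start is not None:
            end = t1  # afterhyperpolarization ramp following the downstroke
        t0 = t1
    if start is None:
        raise ProtocolMismatchError("no repolarization ramp found (not an APW sweep)")
    return int(round(start / dt)), int(round(end / dt))


def peak_per_sweep(train: list[ProcessedSweep]) -> list[float]:
    """Inward extremum (pA/pF) in the repolarization window of each sweep."""
    peaks = []
    for ps in train:
        k0, k1 = repolarization_window(ps)
        seg = ps.i_density[k0:k1 + 1]
        peaks.append(float(seg.min()))
    return peaks


def train_decay(peaks: list[float]) -> float:
    """Percent decrease of peak magnitude from the first 3 to the last 3 sweeps."""
    if len(peaks) < 10:
        raise InsufficientDataError("train decay needs >= 10 sweeps")
    mags = np.abs(np.asarray(peaks, float))
    first = float(np.mean(mags[:3]))
    last = float(np.mean(mags[-3:]))
    if first == 0:
        raise InsufficientDataError("zero initial peak")
    return 100.0 * (first - last) / first


def integrate_charge(train: list[ProcessedSweep],
                     reference_pa: float | None = None) -> np.ndarray:
    """Cumulative inward charge per sweep, normalized to the ramp reference.

    The reference (maximal inward current in a pre-train ramp, pA) is taken
    from ``meta['ramp_reference_pa']`` unless given.  Only inward (negative)
    current contributes; the result is non-decreasing, in units of ms
    (pA*ms / pA).
    """
    if reference_pa is None:
        reference_pa = train[0].meta.get("ramp_reference_pa")
    if reference_pa is None:
        raise ProtocolMismatchError("no pre-train ramp reference in metadata")
    ref = abs(float(reference_pa))
    if ref == 0:
        raise InsufficientDataError("zero ramp reference current")
    per_sweep = []
    for ps in train:
        inward = np.minimum(ps.i_leak_subtracted, 0.0)
        per_sweep.append(-np.trapezoid(inward, dx=ps.dt))
    return np.cumsum(per_sweep) / ref


def normalize_fluorescence(raw_f: np.ndarray, f0: float,
                           current_density: float) -> np.ndarray:
    """Normalize a fluorescence series to baseline and current density.

    Returns (raw_f / f0) / |current_density|; homogeneous of degree -1 in
    the density so expression differences cancel.
    """
    if f0 <= 0:
        raise ValueError("f0 must be > 0")
    if current_density == 0:
        raise ValueError("current density must be nonzero")
    return np.asarray(raw_f, float) / f0 / abs(current_density)
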