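"""Voltage-clamp command protocols.

A protocol is an ordered list of sweeps; each sweep is a list of piecewise
command-voltage segments (steps and ramps).  Voltages are *command* voltages,
i.e. before liquid-junction correction; the correction is applied downstream
by :mod:`cavclamp.preprocessing`.  Time within a sweep is measured in ms from
the first sample; inter-sweep gaps are metadata, not samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "Segment",
    "VoltageProtocol",
    "build_iv_protocol",
    "build_ssi_protocol",
    "build_apw_train",
    "build_tail_protocol",
    "build_pharm_protocol",
    "p4_subsweeps",
]

#: default holding segment flanking test pulses, ms
HOLD_PAD_MS = 5.0


@dataclass(frozen=True)
class Segment:
    """One piecewise-linear command-voltage segment.

    ``kind`` is ``"step"`` (constant voltage) or ``"ramp"`` (linear from
    ``v_start`` to ``v_end``); ``duration`` is in ms and must be positive.
    """

    kind: str
    v_start: float
    v_end: float
    duration: float

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError(f"segment kind must be 'step' or 'ramp', got {self.kind!r}")
        if not self.duration > 0:
            raise ValueError("segment duration must be > 0")
        if self.kind == "step" and self.v_start != self.v_end:
            raise ValueError("step segment requires v_start == v_end")

    @staticmethod
    def step(v: float, duration: float) -> "Segment":
        return Segment("step", v, v, duration)

    @staticmethod
    def ramp(v_start: float, v_end: float, duration: float) -> "Segment":
        return Segment("ramp", v_start, v_end, duration)


@dataclass
class VoltageProtocol:
    """A named family of sweeps sharing holding potential and sample rate.

    ``inter_sweep_interval`` is in seconds, ``sample_rate`` in kHz.
    ``starts_at_hold`` records whether sweeps begin/end at the holding
    potential (the APW train deliberately does not).
    """

    name: str
    holding_potential: float
    sweeps: list[list[Segment]]
    inter_sweep_interval: float = 5.0
    sample_rate: float = 50.0
    starts_at_hold: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")
        if any(len(s) == 0 for s in self.sweeps):
            raise ValueError("all sweeps must be non-empty")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_duration(self, i: int) -> float:
        """Total duration of sweep ``i`` in ms (exact sum of segments)."""
        return float(sum(s.duration for s in self.sweeps[i]))

    def n_samples(self, i: int) -> int:
        return int(round(self.sweep_duration(i) * self.sample_rate))

    def command_waveform(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """Sampled (time ms, command mV) arrays for sweep ``i``.

        Sample k sits at t = k * dt; each sample takes the voltage of the
        segment whose half-open interval [t0, t1) contains it, so segment
        boundaries are reproduced exactly for any sample rate.
        """
        dt = 1.0 / self.sample_rate
        n = self.n_samples(i)
        t = np.arange(n) * dt
        v = np.empty(n)
        t0 = 0.0
        for seg in self.sweeps[i]:
            t1 = t0 + seg.duration
            mask = (t >= t0 - 1e-12) & (t < t1 - 1e-12)
            if seg.kind == "step":
                v[mask] = seg.v_start
            else:
                frac = (t[mask] - t0) / seg.duration
                v[mask] = seg.v_start + frac * (seg.v_end - seg.v_start)
            t0 = t1
        return t, v

    def segment_bounds(self, i: int) -> list[tuple[float, float, Segment]]:
        """(t_start, t_end, segment) triples for sweep ``i``, in ms."""
        out, t0 = [], 0.0
        for seg in self.sweeps[i]:
            out.append((t0, t0 + seg.duration, seg))
            t0 += seg.duration
        return out

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "holding_potential": self.holding_potential,
            "inter_sweep_interval": self.inter_sweep_interval,
            "sample_rate": self.sample_rate,
            "starts_at_hold": self.starts_at_hold,
            "meta": self.meta,
            "sweeps": [[asdict(s) for s in sw] for sw in self.sweeps],
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "VoltageProtocol":
        doc = json.loads(text)
        sweeps = [[Segment(**s) for s in sw] for sw in doc.pop("sweeps")]
        return VoltageProtocol(sweeps=sweeps, **doc)


def _padded(segs: list[Segment], hp: float, pad: float = HOLD_PAD_MS) -> list[Segment]:
    return [Segment.step(hp, pad), *segs, Segment.step(hp, pad)]


def build_iv_protocol(
    hp: float,
    v_min: float,
    v_max: float,
    increment: float,
    duration: float,
    *,
    inter_sweep_interval: float = 5.0,
    sample_rate: float = 50.0,
    leak_step: tuple[float, float] | None = None,
) -> VoltageProtocol:
    """Square-pulse current-voltage family: one sweep per test potential.

    Test potentials run from ``v_min`` to ``v_max`` in ``increment`` mV steps;
    each sweep is a single ``duration``-ms step from ``hp``, flanked by short
    holding segments.  ``leak_step`` optionally inserts a (dV, duration_ms)
    hyperpolarizing step before the test pulse for offline leak subtraction.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if v_min > v_max:
        raise ValueError("v_min must be <= v_max")
    n = int(np.floor((v_max - v_min) / increment + 1e-9)) + 1
    voltages = v_min + increment * np.arange(n)
    sweeps = []
    for v in voltages:
        segs: list[Segment] = []
        if leak_step is not None:
            dv, dur = leak_step
            segs += [Segment.step(hp + dv, dur), Segment.step(hp, HOLD_PAD_MS)]
        segs.append(Segment.step(float(v), duration))
        sweeps.append(_padded(segs, hp))
    return VoltageProtocol(
        "iv", hp, sweeps, inter_sweep_interval, sample_rate,
        meta={"test_voltages": [float(v) for v in voltages],
              "leak_step": list(leak_step) if leak_step else None},
    )


def build_ssi_protocol(
    hp: float,
    vmax: float,
    cond_min: float,
    cond_max: float,
    increment: float,
    *,
    pulse_duration: float = 20.0,
    conditioning_duration: float = 5000.0,
    recovery_gap: float = 500.0,
    sample_rate: float = 50.0,
) -> VoltageProtocol:
    """Steady-state inactivation family.

    Each sweep: 20-ms control pulse to ``vmax``, recovery gap at ``hp``,
    5-s conditioning step, then 20-ms test pulse to ``vmax``.  Inter-sweep
    interval 30 s.  Availability = test peak / control peak.
    """
    if increment <= 0:
        raise ValueError("increment must be > 0")
    n = int(np.floor((cond_max - cond_min) / increment + 1e-9)) + 1
    voltages = cond_min + increment * np.arange(n)
    sweeps = []
    for v in voltages:
        segs = [
            Segment.step(vmax, pulse_duration),
            Segment.step(hp, recovery_gap),
            Segment.step(float(v), conditioning_duration),
            Segment.step(vmax, pulse_duration),
        ]
        sweeps.append(_padded(segs, hp))
    return VoltageProtocol(
        "ssi", hp, sweeps, 30.0, sample_rate,
        meta={"conditioning_voltages": [float(v) for v in voltages], "vmax": vmax},
    )


#: the action-potential-waveform command: (kind, v_start, v_end, duration ms)
APW_SEGMENTS = (
    ("step", -60.0, -60.0, 2.5),
    ("ramp", -60.0, 20.0, 1.0),
    ("ramp", 20.0, -70.0, 1.5),
    ("ramp", -70.0, -60.0, 5.0),   # afterhyperpolarization
    ("step", -60.0, -60.0, 90.0),
)


def build_apw_train(
    n_sweeps: int, frequency: float, *, hp: float = -80.0, sample_rate: float = 50.0
) -> VoltageProtocol:
    """Action-potential-waveform train from a -80 mV holding potential.

    Each 100-ms sweep is the 5-segment spike waveform (2.5-ms step to -60,
    1-ms upstroke ramp to +20, 1.5-ms repolarization ramp to -70, 5-ms
    afterhyperpolarization ramp to -60, 90 ms at -60); sweep cadence is
    1/frequency.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    sweep = [Segment(k, a, b, d) for k, a, b, d in APW_SEGMENTS]
    period_ms = 1000.0 / frequency
    gap_s = max(0.0, (period_ms - 100.0) / 1000.0)
    return VoltageProtocol(
        "apw_train", hp, [list(sweep) for _ in range(n_sweeps)],
        gap_s, sample_rate, starts_at_hold=False,
        meta={"frequency_hz": frequency},
    )


def build_tail_protocol(
    pre_v: float,
    repol_list: list[float],
    pre_duration: float,
    tail_duration: float,
    *,
    hp: float = -89.0,
    sample_rate: float = 50.0,
) -> VoltageProtocol:
    """Tail-current family: strong pre-step then repolarization steps."""
    if not repol_list:
        raise ValueError("repol_list must be non-empty")
    sweeps = [
        _padded([Segment.step(pre_v, pre_duration), Segment.step(float(v), tail_duration)], hp)
        for v in repol_list
    ]
    return VoltageProtocol(
        "tail", hp, sweeps, 5.0, sample_rate,
        meta={"pre_v": pre_v, "repol_voltages": [float(v) for v in repol_list]},
    )


def build_pharm_protocol(
    vmax: float, n_sweeps: int, *, hp: float = -89.0, sample_rate: float = 50.0
) -> VoltageProtocol:
    """Pharmacology monitor: identical 100-ms steps to V_max at 0.1 Hz.

    At least three sweeps are required so that a stable drug-free baseline
    can be established before drug application.
    """
    if n_sweeps < 3:
        raise ValueError("n_sweeps must be >= 3 (baseline requirement)")
    sweep = _padded([Segment.step(vmax, 100.0)], hp)
    return VoltageProtocol(
        "pharm", hp, [list(sweep) for _ in range(n_sweeps)], 10.0, sample_rate,
        meta={"vmax": vmax},
    )


def p4_subsweeps(sweep: list[Segment], hp: float, polarity: int = -1) -> list[list[Segment]]:
    """Four P/4 leak sub-sweeps: the sweep scaled to 1/4 amplitude about ``hp``.

    ``polarity=-1`` (default) mirrors the command about the holding potential,
    so depolarizing test pulses become small hyperpolarizing ones that do not
    open channels.
    """
    if polarity not in (-1, 1):
        raise ValueError("polarity must be +1 or -1")
    scaled = [
        Segment(
            s.kind,
            hp + polarity * (s.v_start - hp) / 4.0,
            hp + polarity * (s.v_end - hp) / 4.0,
            s.duration,
        )
        for s in sweep
    ]
    return [list(scaled) for _ in range(4)]
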