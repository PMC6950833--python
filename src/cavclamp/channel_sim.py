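"""Synthetic whole-cell recordings from a kinetic Cav1.3 gating model.

The simulator turns a :class:`~cavclamp.protocols.VoltageProtocol` into
:class:`SweepRecording` objects that statistically emulate tsA-201/HEK-293
whole-cell Ca2+/Ba2+ current recordings: Hodgkin-Huxley-style activation with
a fast and a slow deactivation pathway, bi-exponential voltage-dependent
inactivation (VDI) with a persistent (non-inactivating) fraction, Ca2+-
dependent inactivation (CDI) driven by instantaneous inward Ca2+ flux, linear
ohmic driving force, linear leak, ON-gating charge injections at step onsets,
steady-state dihydropyridine block, linear run-down, and Gaussian noise.

Inward current is negative.  Gates on piecewise-constant segments advance by
the exact first-order relaxation (``gate_update_exact``); inside ramps the
same update is applied at fixed dt.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources

import numpy as np

from .protocols import Segment, VoltageProtocol

__all__ = [
    "VariantParams",
    "SimConfig",
    "SweepRecording",
    "gate_update_exact",
    "steady_state_activation",
    "steady_state_inactivation",
    "apply_block",
    "simulate_sweep",
    "simulate_protocol",
    "simulate_fluorescence",
    "load_variant",
    "list_variants",
]

_REF_HP = -89.0  # mV, reference holding potential for Q_ON scaling


@dataclass
class VariantParams:
    """Full kinetic parameterization of one channel variant.

    Voltage parameters are in the liquid-junction-corrected frame (the frame
    in which gating statistics are conventionally reported); the simulator
    adds the junction offset to command voltages before evaluating them.
    """

    name: str
    # activation: Boltzmann steady state, bell-shaped time constant
    v_half_act: float          # mV
    slope_act: float           # mV
    tau_act_max: float         # ms, peak of the tau_m(V) bell
    tau_act_v: float           # mV, voltage of the bell peak
    tau_act_k: float           # mV, width of the bell
    # driving force
    g_max: float               # nS
    v_rev: float               # mV
    # voltage-dependent inactivation: two gates plus persistent pathway
    frac_fast: float
    frac_slow: float
    frac_persistent: float
    tau_fast_0: float          # ms, peak of the bell-shaped tau(V)
    tau_slow_0: float          # ms, peak of the bell-shaped tau(V)
    tau_v_dep: float           # mV, width of the VDI tau(V) bell
    # steady-state inactivation voltage dependence (shared by both VDI gates)
    v_half_inact: float        # mV
    slope_inact: float         # mV
    v_tau_vdi: float = -10.0   # mV, voltage of the VDI tau(V) bell peak
    # Ca2+-dependent inactivation: two flux-driven sub-gates
    cdi_coupling: float = 0.0        # 1/pC, fast sub-gate
    tau_cdi_recovery: float = 150.0  # ms, fast sub-gate
    cdi_coupling_slow: float = 0.0   # 1/pC
    tau_cdi_recovery_slow: float = 1000.0  # ms
    cdi_frac_fast: float = 1.0       # weight of the fast sub-gate
    # deactivation: slow second pathway
    tail_slow_frac: float = 0.0      # fraction of channels in the slow pathway
    tau_tail_slow: float = 1.0       # ms, slow deactivation tau at -40 mV
    # gating charge
    q_on_total: float = 150.0        # pA*ms for a step from -89 mV to v_rev
    tau_q: float = 0.2               # ms
    # pharmacology
    ic50: float = 60.0               # nM isradipine
    hill_slope: float = 1.0
    rundown_rate: float = 3.0        # %/min, applied at pharmacology cadence

    def __post_init__(self) -> None:
        fsum = self.frac_fast + self.frac_slow + self.frac_persistent
        if abs(fsum - 1.0) > 1e-9:
            raise ValueError(f"VDI pathway fractions must sum to 1, got {fsum}")
        for nm in ("tau_act_max", "tau_fast_0", "tau_slow_0", "tau_cdi_recovery",
                   "tau_cdi_recovery_slow", "tau_tail_slow", "tau_q"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        for nm in ("slope_act", "slope_inact"):
            if not getattr(self, nm) > 0:
                raise ValueError(f"{nm} must be > 0")
        if not self.ic50 > 0:
            raise ValueError("ic50 must be > 0")
        if not 0.0 <= self.cdi_frac_fast <= 1.0:
            raise ValueError("cdi_frac_fast must be in [0, 1]")
        if not 0.0 <= self.tail_slow_frac < 1.0:
            raise ValueError("tail_slow_frac must be in [0, 1)")

    # -- voltage dependences ------------------------------------------
    def m_inf(self, v):
        return 1.0 / (1.0 + np.exp(-(v - self.v_half_act) / self.slope_act))

    def tau_m(self, v):
        return self.tau_act_max / np.cosh((v - self.tau_act_v) / self.tau_act_k)

    def tau_m_slow(self, v):
        # slow deactivation pathway shares the bell shape, scaled so that its
        # tau equals tau_tail_slow at -40 mV
        return self.tau_m(v) * (self.tau_tail_slow / self.tau_m(-40.0))

    def h_inf(self, v):
        return 1.0 / (1.0 + np.exp((v - self.v_half_inact) / self.slope_inact))

    def tau_vdi_fast(self, v):
        # bell-shaped: inactivation slows toward the bell peak and speeds up
        # both at depolarized (deep inactivation) and hyperpolarized
        # (recovery) voltages
        return self.tau_fast_0 / np.cosh((np.asarray(v) - self.v_tau_vdi)
                                         / self.tau_v_dep)

    def tau_vdi_slow(self, v):
        return self.tau_slow_0 / np.cosh((np.asarray(v) - self.v_tau_vdi)
                                         / self.tau_v_dep)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "VariantParams":
        missing = [k for k in ("name", "v_half_act", "slope_act", "g_max", "v_rev",
                               "v_half_inact", "slope_inact") if k not in d]
        if missing:
            raise ValueError(f"variant parameter file missing keys: {missing}")
        unknown = set(d) - set(VariantParams.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown variant parameter keys: {sorted(unknown)}")
        return VariantParams(**d)

    def hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class SimConfig:
    """Acquisition-side configuration of a simulated recording."""

    dt: float = 0.02                 # ms (50 kHz)
    noise_sd: float = 2.0            # pA
    leak_conductance: float = 0.5    # nS, reversal at 0 mV
    capacitance: float = 12.0        # pF
    carrier: str = "Ca"              # "Ca" or "Ba"
    junction_offset: float = -9.3    # mV, added to command voltage downstream
    seed: int = 0
    enable_p4: bool = False
    drug_concentration_nM: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 0.1:
            raise ValueError("dt must be in (0, 0.1] ms")
        if not self.capacitance > 0:
            raise ValueError("capacitance must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.carrier not in ("Ca", "Ba"):
            raise ValueError("carrier must be 'Ca' or 'Ba'")


@dataclass
class SweepRecording:
    """One sampled sweep: time (ms), command voltage (mV), current (pA)."""

    time: np.ndarray
    command_v: np.ndarray
    current: np.ndarray
    capacitance: float
    carrier: str
    protocol_name: str
    sweep_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.command_v) == len(self.current)):
            raise ValueError("time/command/current arrays must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.capacitance > 0:
            raise ValueError("capacitance must be > 0")


# ----------------------------------------------------------------------
# elementary updates


def gate_update_exact(x0: float, x_inf: float, tau: float, dt: float) -> float:
    """Exact relaxation of dx/dt = (x_inf - x)/tau over dt at constant voltage."""
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return x_inf + (x0 - x_inf) * np.exp(-dt / tau)


def steady_state_activation(v, p: VariantParams):
    """Boltzmann activation steady state m_inf(V); 0.5 at V = V_0.5."""
    return p.m_inf(v)


def steady_state_inactivation(v, p: VariantParams):
    """VDI availability at infinite time: persistent + Boltzmann gate."""
    return p.frac_persistent + (1.0 - p.frac_persistent) * p.h_inf(v)


def apply_block(p: VariantParams, concentration: float) -> float:
    """Steady-state blocked fraction c/(c + IC50), Hill slope 1."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        return 0.0
    return concentration / (concentration + p.ic50)


# ----------------------------------------------------------------------
# gate integration


def _gate_path(x_inf: np.ndarray, decay: np.ndarray, x0: float) -> np.ndarray:
    """Sequential first-order gate path x[n+1] = xinf[n] + (x[n]-xinf[n])*decay[n].

    Exact on piecewise-constant voltage (decay = exp(-dt/tau)); fixed-dt
    stepping elsewhere.  Delegates to a numba kernel when available.
    """
    return _kernel_gate_path(x_inf, decay, x0)


def _cdi_path(drive: np.ndarray, dt: float, p: VariantParams,
              c0: tuple[float, float]) -> tuple[np.ndarray, tuple[float, float]]:
    """Two flux-driven CDI sub-gates, semi-implicit fixed-dt integration.

    ``drive[n]`` is the inward channel current magnitude per unit h_cdi (pA);
    each sub-gate inactivates at rate coupling * |I_Ca| (1/ms, with |I_Ca| in
    pC/ms) and recovers first-order with its own time constant.
    """
    h, cf, cs = _kernel_cdi_path(
        drive, dt,
        p.cdi_coupling * 1e-3, p.cdi_coupling_slow * 1e-3,
        p.tau_cdi_recovery, p.tau_cdi_recovery_slow,
        p.cdi_frac_fast, c0[0], c0[1],
    )
    return h, (cf, cs)


def _py_gate_path(x_inf, decay, x0):
    n = x_inf.shape[0]
    out = np.empty(n)
    x = x0
    for i in range(n):
        out[i] = x
        x = x_inf[i] + (x - x_inf[i]) * decay[i]
    return out


def _py_cdi_path(drive, dt, gf, gs, trf, trs, wf, cf, cs):
    n = drive.shape[0]
    ws = 1.0 - wf
    out = np.empty(n)
    for i in range(n):
        h = wf * cf + ws * cs
        out[i] = h
        d = drive[i] * h
        cf = (cf + dt / trf) / (1.0 + dt * gf * d + dt / trf)
        cs = (cs + dt / trs) / (1.0 + dt * gs * d + dt / trs)
    return out, cf, cs


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _kernel_gate_path = njit(cache=False)(_py_gate_path)
    _kernel_cdi_path = njit(cache=False)(_py_cdi_path)
except ImportError:  # pragma: no cover
    _kernel_gate_path = _py_gate_path
    _kernel_cdi_path = _py_cdi_path


@dataclass
class _GateState:
    m_f: float
    m_s: float
    h_f: float
    h_s: float
    c_f: float = 1.0
    c_s: float = 1.0

    @staticmethod
    def at_rest(p: VariantParams, v_mem: float) -> "_GateState":
        m = float(p.m_inf(v_mem))
        h = float(p.h_inf(v_mem))
        return _GateState(m, m, h, h, 1.0, 1.0)


def _simulate_arrays(p: VariantParams, segs: list[Segment], cfg: SimConfig,
                     state: _GateState, scale: float):
    """Noiseless channel + leak + gating current for one sweep; advances state."""
    prot = VoltageProtocol("_tmp", segs[0].v_start, [list(segs)],
                           0.0, 1.0 / cfg.dt, starts_at_hold=False)
    t, v_cmd = prot.command_waveform(0)
    v = v_cmd + cfg.junction_offset  # membrane voltage
    dt = cfg.dt

    # per-sample steady states and decay factors (left-sample voltage)
    m_inf = p.m_inf(v)
    tm_f = p.tau_m(v)
    tm_s = p.tau_m_slow(v)
    h_inf = p.h_inf(v)
    th_f = p.tau_vdi_fast(v)
    th_s = p.tau_vdi_slow(v)

    m_f = _gate_path(m_inf, np.exp(-dt / tm_f), state.m_f)
    m_s = _gate_path(m_inf, np.exp(-dt / tm_s), state.m_s)
    h_f = _gate_path(h_inf, np.exp(-dt / th_f), state.h_f)
    h_s = _gate_path(h_inf, np.exp(-dt / th_s), state.h_s)

    m_tot = (1.0 - p.tail_slow_frac) * m_f + p.tail_slow_frac * m_s
    avail = p.frac_fast * h_f + p.frac_slow * h_s + p.frac_persistent

    block = apply_block(p, cfg.drug_concentration_nM)
    g_eff = p.g_max * scale * (1.0 - block)
    drive_per_h = g_eff * m_tot * avail * np.maximum(p.v_rev - v, 0.0)

    use_cdi = cfg.carrier == "Ca" and (p.cdi_coupling > 0 or p.cdi_coupling_slow > 0)
    if use_cdi:
        h_cdi, (cf, cs) = _cdi_path(drive_per_h, dt, p, (state.c_f, state.c_s))
    else:
        h_cdi = np.ones_like(v)
        cf, cs = state.c_f, state.c_s

    i_chan = g_eff * m_tot * avail * h_cdi * (v - p.v_rev)
    i_leak = cfg.leak_conductance * v

    # ON/OFF gating-charge injections at step-onset boundaries
    i_gate = np.zeros_like(v)
    if p.q_on_total > 0:
        bounds = prot.segment_bounds(0)
        v_prev = v[0] - cfg.junction_offset  # command frame; deltas identical
        for t0, t1, seg in bounds:
            dv = seg.v_start - v_prev
            if abs(dv) > 1e-9 and seg.kind == "step":
                q = p.q_on_total * dv / (p.v_rev - _REF_HP)
                k0 = int(round(t0 / dt))
                tt = t[k0:] - t0
                i_gate[k0:] += (q / p.tau_q) * np.exp(-tt / p.tau_q)
            v_prev = seg.v_end

    i_total = i_chan + i_leak + i_gate
    if not np.all(np.isfinite(i_total)):
        raise FloatingPointError(
            f"non-finite current in simulation of {p.name} "
            f"(first bad sample {int(np.argmax(~np.isfinite(i_total)))})"
        )

    new_state = _GateState(float(m_f[-1]), float(m_s[-1]),
                           float(h_f[-1]), float(h_s[-1]), cf, cs)
    # advance the linear gates one more step so the carried state refers to
    # the sample *after* the last recorded one (continuous trains)
    new_state.m_f = gate_update_exact(new_state.m_f, m_inf[-1], tm_f[-1], dt)
    new_state.m_s = gate_update_exact(new_state.m_s, m_inf[-1], tm_s[-1], dt)
    new_state.h_f = gate_update_exact(new_state.h_f, h_inf[-1], th_f[-1], dt)
    new_state.h_s = gate_update_exact(new_state.h_s, h_inf[-1], th_s[-1], dt)
    return t, v_cmd, i_total, new_state


def simulate_sweep(p: VariantParams, sweep: list[Segment], cfg: SimConfig,
                   *, sweep_index: int = 0, protocol_name: str = "adhoc",
                   scale: float = 1.0, state: _GateState | None = None,
                   _return_state: bool = False):
    """Simulate one sweep; returns a :class:`SweepRecording`.

    Gates start from rest at the first segment's (membrane) voltage unless an
    explicit carried ``state`` is given.  ``scale`` multiplies the channel
    conductance (run-down).  Noise is Gaussian, seeded by (seed, sweep_index)
    so identical configurations are bit-identical.
    """
    if state is None:
        state = _GateState.at_rest(p, sweep[0].v_start + cfg.junction_offset)
    t, v_cmd, i_total, new_state = _simulate_arrays(p, sweep, cfg, state, scale)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, sweep_index])
        i_total = i_total + rng.normal(0.0, cfg.noise_sd, size=i_total.shape)
    rec = SweepRecording(
        time=t, command_v=v_cmd, current=i_total,
        capacitance=cfg.capacitance, carrier=cfg.carrier,
        protocol_name=protocol_name, sweep_index=sweep_index,
        meta={
            "segments": [asdict(s) for s in sweep],
            "params_hash": p.hash(), "variant": p.name,
            "seed": cfg.seed, "scale": scale,
            "junction_offset": cfg.junction_offset,
            "drug_concentration_nM": cfg.drug_concentration_nM,
        },
    )
    if _return_state:
        return rec, new_state
    return rec


def simulate_protocol(p: VariantParams, prot: VoltageProtocol, cfg: SimConfig,
                      *, apply_rundown: bool | None = None) -> list[SweepRecording]:
    """Simulate every sweep of a protocol.

    Gate state is carried across sweeps for gap-free trains (inter-sweep
    interval 0); otherwise each sweep starts from rest at the holding
    potential, assuming full recovery during the 5-30 s intervals.  Run-down
    (linear % per minute of elapsed recording time) is applied to pharmacology
    protocols by default; pass ``apply_rundown`` to override.
    """
    if apply_rundown is None:
        apply_rundown = prot.name == "pharm"
    continuous = prot.inter_sweep_interval == 0.0 and prot.n_sweeps > 1
    recs: list[SweepRecording] = []
    state: _GateState | None = None
    elapsed_ms = 0.0
    for i in range(prot.n_sweeps):
        scale = 1.0
        if apply_rundown and p.rundown_rate > 0:
            scale = max(0.0, 1.0 - p.rundown_rate / 100.0 * elapsed_ms / 60000.0)
        rec, state = simulate_sweep(
            p, prot.sweeps[i], cfg, sweep_index=i, protocol_name=prot.name,
            scale=scale, state=state if continuous else None, _return_state=True,
        )
        rec.meta["elapsed_s"] = elapsed_ms / 1000.0
        for k, v in prot.meta.items():
            rec.meta.setdefault(k, v)
        recs.append(rec)
        elapsed_ms += prot.sweep_duration(i) + prot.inter_sweep_interval * 1000.0
    return recs


def simulate_fluorescence(train: list[SweepRecording], kappa: float,
                          extrusion_tau: float) -> tuple[np.ndarray, np.ndarray]:
    """First-order cytosolic Ca2+ indicator signal from an APW train.

    dF/dt = kappa * |I_Ca,inward| - (F - F0)/extrusion_tau, reported as F/F0
    on the concatenated train time base (kappa in 1/pC, tau in ms).  Requires
    the Ca2+ carrier; with infinite extrusion_tau the signal is proportional
    to cumulative inward charge.
    """
    if not train:
        raise ValueError("empty train")
    if any(r.carrier != "Ca" for r in train):
        raise ValueError("fluorescence requires Ca carrier recordings")
    i_all = np.concatenate([r.current for r in train])
    dt = float(train[0].time[1] - train[0].time[0])
    t_all = np.arange(i_all.shape[0]) * dt
    inward = np.maximum(-i_all, 0.0)  # pA
    decay = np.exp(-dt / extrusion_tau) if np.isfinite(extrusion_tau) else 1.0
    src = kappa * 1e-3 * inward * dt  # dimensionless increment per sample
    # exponential-Euler on the linear extrusion: s[n] = decay*s[n-1] + src[n]
    from scipy.signal import lfilter

    s = lfilter([1.0], [1.0, -decay], src)
    return t_all, 1.0 + s


# ----------------------------------------------------------------------
# packaged variant parameter sets

_VARIANT_FILES = {
    "WT_L": "wt_l.json",
    "WT_S": "wt_s.json",
    "S652L_L": "s652l_l.json",
    "S652L_S": "s652l_s.json",
    "S652W_L": "s652w_l.json",
}


def list_variants() -> list[str]:
    return sorted(_VARIANT_FILES)


def load_variant(name: str) -> VariantParams:
    """Load a packaged, calibrated variant parameter set by name."""
    key = name.upper()
    if key not in _VARIANT_FILES:
        raise KeyError(f"unknown variant {name!r}; available: {list_variants()}")
    path = resources.files("cavclamp").joinpath("data/variants", _VARIANT_FILES[key])
    return VariantParams.from_dict(json.loads(path.read_text()))
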