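import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cavclamp import load_variant
from cavclamp.channel_sim import SimConfig, SweepRecording
from cavclamp.preprocessing import correct_junction
from cavclamp.protocols import Segment

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

VARIANTS = ("WT_L", "S652L_L", "WT_S", "S652L_S", "S652W_L")


@pytest.fixture(scope="session")
def noiseless_cfg():
    return SimConfig(noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def wt_l():
    return load_variant("WT_L")


@pytest.fixture(scope="session")
def s652l_l():
    return load_variant("S652L_L")


@pytest.fixture(scope="session")
def gating_fits_all(noiseless_cfg):
    """Full pipeline gating fits for every packaged variant (noiseless)."""
    from cavclamp.pipeline import variant_gating_fits

    return {name: variant_gating_fits(load_variant(name), noiseless_cfg)
            for name in VARIANTS}


def make_processed_step(current, v_test=-10.0, hp=-89.0, duration=50.0,
                        dt=0.02, capacitance=12.0, pad=5.0, carrier="Ca",
                        pre_pulse=None):
    """Synthetic ProcessedSweep: hold / (pre-pulse) / step / hold.

    ``current`` is either a scalar (constant during the step, 0 at holding)
    or a callable t_ms -> pA evaluated inside the step window (t from step
    onset).  ``pre_pulse`` is an optional (v, duration_ms, peak_pa) tuple.
    """
    segs = [Segment.step(hp, pad)]
    if pre_pulse is not None:
        segs.append(Segment.step(pre_pulse[0], pre_pulse[1]))
    segs += [Segment.step(v_test, duration), Segment.step(hp, pad)]
    total = sum(s.duration for s in segs)
    n = int(round(total / dt))
    t = np.arange(n) * dt
    v = np.full(n, hp)
    i = np.zeros(n)
    t0 = pad
    if pre_pulse is not None:
        k0, k1 = int(round(t0 / dt)), int(round((t0 + pre_pulse[1]) / dt))
        v[k0:k1] = pre_pulse[0]
        i[k0:k1] = pre_pulse[2]
        t0 += pre_pulse[1]
    k0, k1 = int(round(t0 / dt)), int(round((t0 + duration) / dt))
    v[k0:k1] = v_test
    if callable(current):
        i[k0:k1] = current(t[k0:k1] - t0)
    else:
        i[k0:k1] = current
    rec = SweepRecording(
        time=t, command_v=v, current=i, capacitance=capacitance,
        carrier=carrier, protocol_name="synthetic", sweep_index=0,
        meta={"segments": [
            {"kind": s.kind, "v_start": s.v_start, "v_end": s.v_end,
             "duration": s.duration} for s in segs]},
    )
    return correct_junction(rec, 0.0)
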