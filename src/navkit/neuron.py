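"""Single-compartment conductance-based cortical pyramidal neuron with
wild-type and L1624Q sodium-current parameterizations.

Model
-----
A regular-spiking cortical pyramidal parameterization in the
Traub-lineage Hodgkin-Huxley form: transient Na+ (m^3 h), persistent
Na+ (mp^3, no inactivation gate), delayed-rectifier K+ (n^4), a slow
non-inactivating M-type K+ current (p), and leak.  The current-balance
equation per unit membrane area (mV, ms, mS/cm^2, uA/cm^2):

    C_m dV/dt = I_inj - g_Na m^3 h (V - E_Na) - g_NaP mp (V - E_Na)
                      - g_Kdr n^4 (V - E_K) - g_KM p (V - E_K)
                      - g_leak (V - E_leak)

Variant effects
---------------
* Accelerated fast-inactivation onset: both h-gate rates are multiplied
  by ``inact_rate_multiplier`` (1.485 for L1624Q at 37 degC), which
  scales 1/tau_h uniformly and leaves h_inf unchanged.
* Persistent current: the NaP conductance is set to
  ``0.10 * g_Na * persistent_fraction`` (fraction 1.8% for WT, 4.6% for
  L1624Q), and the NaP activation gate uses the fast-Na m rates scaled
  by 1000 (effectively instantaneous, hence integrated with
  exponential-Euler gate updates, which are unconditionally stable).
  The NaP gate enters linearly (one activation gate, the standard INaP
  form); the exponent is a parameter.

The two effects can be toggled independently to build separate-effect
models; with both toggles off the "variant" neuron is exactly the
wild-type neuron.

Numbers
-------
Gating kinetics are the classic regular-spiking cortical rate functions
(V_T = -56.2 mV); conductances are g_Na 56, g_Kdr 3, g_KM 0.02,
g_leak 0.03 mS/cm^2 with E_Na +50, E_K -90, E_leak -63 mV.  Relative to
the textbook regular-spiking set, the K+ reserve and adaptation are
reduced and the leak reversal depolarized, which places the model in
the regime where the variant contrast expresses itself: the wild-type
neuron has a stable rest while the L1624Q persistent current outweighs
the subthreshold restoring currents, so the variant keeps firing once
depolarized, and the weaker delayed-rectifier reserve brings
depolarization block inside the 400 pA ramp window.  The compartment
area (1.8e-5 cm^2) is calibrated so the wild-type rheobase for a 1 s
step falls in the 1-5 pA range, putting the excitability transitions in
the 1-100 pA stimulus window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "VariantSpec", "NeuronParams", "StimulusProgram", "SimTrace",
    "IntegrationError", "WT_PERSISTENT_FRACTION", "LQ_PERSISTENT_FRACTION",
    "LQ_INACT_RATE_MULTIPLIER",
    "wt_variant", "lq_variant", "persistent_only_variant",
    "inactivation_only_variant", "build_neuron", "resting_potential",
    "build_stimulus", "integrate", "test_pulse_peak_current",
    "firing_rate_curve", "persistent_firing_test", "ramp_block_test",
    "rheobase", "stimulus_preset", "SCENARIO_PRESETS",
]

# Model-level variant constants (fractions of the modelled fast Na
# conductance assigned to the non-inactivating component).
WT_PERSISTENT_FRACTION = 0.018
LQ_PERSISTENT_FRACTION = 0.046
LQ_INACT_RATE_MULTIPLIER = 1.485

NAP_RATE_SCALE = 1000.0
SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0
BLOCK_V_MV = -30.0
BLOCK_MIN_MS = 100.0


class IntegrationError(RuntimeError):
    """Numerical blow-up; the message names the failure time."""


@dataclass(frozen=True)
class VariantSpec:
    """Sodium-current perturbations of one channel variant.

    ``apply_*`` toggles support separate-effect models: a disabled
    effect reverts to the wild-type value for that axis.
    """
    inact_rate_multiplier: float = 1.0
    persistent_fraction: float = WT_PERSISTENT_FRACTION
    apply_inactivation_effect: bool = True
    apply_persistent_effect: bool = True
    label: str = "custom"

    def __post_init__(self):
        if not (self.inact_rate_multiplier > 0) or not math.isfinite(self.inact_rate_multiplier):
            raise ValueError(f"inact_rate_multiplier must be finite > 0: "
                             f"{self.inact_rate_multiplier}")
        if not (0.0 <= self.persistent_fraction < 1.0):
            raise ValueError(f"persistent_fraction must be in [0, 1): "
                             f"{self.persistent_fraction}")

    @property
    def effective_multiplier(self) -> float:
        return self.inact_rate_multiplier if self.apply_inactivation_effect else 1.0

    @property
    def effective_fraction(self) -> float:
        return (self.persistent_fraction if self.apply_persistent_effect
                else WT_PERSISTENT_FRACTION)


def wt_variant() -> VariantSpec:
    return VariantSpec(1.0, WT_PERSISTENT_FRACTION, True, True, "WT")


def lq_variant() -> VariantSpec:
    return VariantSpec(LQ_INACT_RATE_MULTIPLIER, LQ_PERSISTENT_FRACTION,
                       True, True, "L1624Q")


def persistent_only_variant() -> VariantSpec:
    """L1624Q persistent current on wild-type kinetics."""
    return VariantSpec(LQ_INACT_RATE_MULTIPLIER, LQ_PERSISTENT_FRACTION,
                       False, True, "persistent-only")


def inactivation_only_variant() -> VariantSpec:
    """L1624Q inactivation acceleration with wild-type persistent current."""
    return VariantSpec(LQ_INACT_RATE_MULTIPLIER, LQ_PERSISTENT_FRACTION,
                       True, False, "inactivation-only")


@dataclass(frozen=True)
class NeuronParams:
    """Parameter set of the single-compartment model (units in module
    docstring).  ``area_cm2`` converts injected pA to uA/cm^2."""
    g_na: float = 56.0
    g_nap: float = 0.10 * 56.0 * WT_PERSISTENT_FRACTION
    g_kdr: float = 3.0
    g_km: float = 0.02
    g_leak: float = 0.03
    e_na: float = 50.0
    e_k: float = -90.0
    e_leak: float = -63.0
    v_t: float = -56.2
    tau_max_km: float = 608.0
    c_m: float = 1.0
    area_cm2: float = 1.8e-5
    h_rate_scale: float = 1.0
    nap_rate_scale: float = NAP_RATE_SCALE
    nap_gate_exponent: int = 1
    temperature: float = 37.0
    label: str = "WT"

    def __post_init__(self):
        for name in ("g_na", "g_nap", "g_kdr", "g_km", "g_leak"):
            g = getattr(self, name)
            if not (g >= 0) or not math.isfinite(g):
                raise ValueError(f"{name} must be finite >= 0: {g}")
        # equality permitted for degenerate test configurations
        if not (self.e_k <= self.e_leak <= self.e_na):
            raise ValueError(
                f"require E_K <= E_leak <= E_Na, got {self.e_k}, "
                f"{self.e_leak}, {self.e_na}")
        if self.c_m <= 0 or self.area_cm2 <= 0:
            raise ValueError("c_m and area_cm2 must be > 0")
        if self.h_rate_scale <= 0 or not math.isfinite(self.h_rate_scale):
            raise ValueError(f"h_rate_scale must be finite > 0: {self.h_rate_scale}")

    def replace(self, **kwargs) -> "NeuronParams":
        return replace(self, **kwargs)


def build_neuron(variant: VariantSpec, nap_mode: str = "tenth_gna",
                 **overrides) -> NeuronParams:
    """Parameterize the neuron for a channel variant.

    Parameters
    ----------
    variant : VariantSpec
    nap_mode : {"tenth_gna", "current_matched"}
        "tenth_gna" (default): g_NaP = 0.10 * g_Na * fraction.
        "current_matched": g_NaP chosen so the open NaP current at 0 mV
        equals `fraction` of the peak transient-Na current at 0 mV from
        a -120 mV holding potential (the alternative reading of the
        persistent-fraction calibration).
    **overrides
        Any :class:`NeuronParams` field (e.g. ``area_cm2``).
    """
    base = NeuronParams(label=variant.label, **{
        k: v for k, v in overrides.items() if k != "g_nap"})
    frac = variant.effective_fraction
    if nap_mode == "tenth_gna":
        g_nap = 0.10 * base.g_na * frac
    elif nap_mode == "current_matched":
        probe = base.replace(g_nap=0.0,
                             h_rate_scale=variant.effective_multiplier)
        peak = abs(test_pulse_peak_current(probe, holding_v=-120.0,
                                           test_v=0.0, transient_only=True))
        mp_inf = _m_inf_np(0.0, base.v_t)
        open_nap = mp_inf ** base.nap_gate_exponent * abs(0.0 - base.e_na)
        g_nap = frac * peak / open_nap
    else:
        raise ValueError(f"unknown nap_mode {nap_mode!r}")
    if "g_nap" in overrides:
        g_nap = overrides["g_nap"]
    return base.replace(g_nap=g_nap,
                        h_rate_scale=variant.effective_multiplier)


# ---------------------------------------------------------------------------
# gating rate functions (vectorized numpy forms, used for analytic
# voltage-clamp and steady states; the integrator kernel re-implements
# them in scalar numba form)

def _efun(x):
    """x / (exp(x) - 1), with its limit 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-9
    safe = np.where(small, 1.0, x)
    return np.where(small, 1.0 - x / 2.0, safe / np.expm1(safe))


def _rates_m(v, v_t):
    u = np.asarray(v, dtype=float) - v_t
    am = 1.28 * _efun((13.0 - u) / 4.0)
    bm = 1.4 * _efun((u - 40.0) / 5.0)
    return am, bm


def _rates_h(v, v_t):
    u = np.asarray(v, dtype=float) - v_t
    ah = 0.128 * np.exp((17.0 - u) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - u) / 5.0))
    return ah, bh


def _rates_n(v, v_t):
    u = np.asarray(v, dtype=float) - v_t
    an = 0.16 * _efun((15.0 - u) / 5.0)
    bn = 0.5 * np.exp((10.0 - u) / 40.0)
    return an, bn


def _km_inf_tau(v, tau_max):
    v = np.asarray(v, dtype=float)
    p_inf = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    tau = tau_max / (3.3 * np.exp((v + 35.0) / 20.0) + np.exp(-(v + 35.0) / 20.0))
    return p_inf, tau


def _m_inf_np(v, v_t):
    am, bm = _rates_m(v, v_t)
    return am / (am + bm)


def steady_gates(v: float, params: NeuronParams) -> tuple:
    """(m, h, n, p, mp) at their steady-state values for voltage v."""
    am, bm = _rates_m(v, params.v_t)
    ah, bh = _rates_h(v, params.v_t)
    an, bn = _rates_n(v, params.v_t)
    p_inf, _ = _km_inf_tau(v, params.tau_max_km)
    m = float(am / (am + bm))
    return (m, float(ah / (ah + bh)), float(an / (an + bn)),
            float(p_inf), m)


def _steady_current(v: float, params: NeuronParams) -> float:
    m, h, n, p, mp = steady_gates(v, params)
    return (params.g_na * m ** 3 * h * (v - params.e_na)
            + params.g_nap * mp ** params.nap_gate_exponent * (v - params.e_na)
            + params.g_kdr * n ** 4 * (v - params.e_k)
            + params.g_km * p * (v - params.e_k)
            + params.g_leak * (v - params.e_leak))


def resting_potential(params: NeuronParams) -> float:
    """Zero-stimulus fixed point of the full steady-state I-V curve,
    found by bracketing between E_K and -40 mV."""
    lo, hi = params.e_k + 1.0, -40.0
    f_lo, f_hi = _steady_current(lo, params), _steady_current(hi, params)
    if f_lo * f_hi > 0:
        # fall back to a scan for the first bracketing pair
        vs = np.linspace(lo, hi, 201)
        fs = np.array([_steady_current(v, params) for v in vs])
        idx = np.flatnonzero(fs[:-1] * fs[1:] <= 0)
        if idx.size == 0:
            raise IntegrationError("no zero-stimulus resting point found")
        lo, hi = float(vs[idx[0]]), float(vs[idx[0] + 1])
    return float(brentq(_steady_current, lo, hi, args=(params,), xtol=1e-10))


# ---------------------------------------------------------------------------
# integrator kernel

@njit(cache=False)
def _kernel(stim, dt, v0, m0, h0, n0, p0, mp0,
            g_na, g_nap, g_kdr, g_km, g_leak,
            e_na, e_k, e_leak, v_t, tau_max, c_m,
            h_scale, nap_scale, nap_exp, v_lo, v_hi, spike_out):
    nt = stim.shape[0]
    v_rec = np.empty(nt)
    v, m, h, n, p, mp = v0, m0, h0, n0, p0, mp0
    n_spikes = 0
    t_last_spike = -1.0e9
    gate_min = 1.0
    gate_max = 0.0
    fail = -1
    v_prev = v
    for i in range(nt):
        u = v - v_t
        # m
        x = (13.0 - u) / 4.0
        if abs(x) < 1e-9:
            am = 1.28 * (1.0 - x / 2.0)
        else:
            am = 1.28 * x / (math.exp(x) - 1.0)
        x = (u - 40.0) / 5.0
        if abs(x) < 1e-9:
            bm = 1.4 * (1.0 - x / 2.0)
        else:
            bm = 1.4 * x / (math.exp(x) - 1.0)
        # h (scaled)
        ah = h_scale * 0.128 * math.exp((17.0 - u) / 18.0)
        bh = h_scale * 4.0 / (1.0 + math.exp((40.0 - u) / 5.0))
        # n
        x = (15.0 - u) / 5.0
        if abs(x) < 1e-9:
            an = 0.16 * (1.0 - x / 2.0)
        else:
            an = 0.16 * x / (math.exp(x) - 1.0)
        bn = 0.5 * math.exp((10.0 - u) / 40.0)
        # KM
        p_inf = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
        tau_p = tau_max / (3.3 * math.exp((v + 35.0) / 20.0)
                           + math.exp(-(v + 35.0) / 20.0))

        # exponential-Euler gate updates (stable for the stiff NaP gate)
        tm = 1.0 / (am + bm)
        m = am * tm + (m - am * tm) * math.exp(-dt / tm)
        th = 1.0 / (ah + bh)
        h = ah * th + (h - ah * th) * math.exp(-dt / th)
        tn = 1.0 / (an + bn)
        n = an * tn + (n - an * tn) * math.exp(-dt / tn)
        p = p_inf + (p - p_inf) * math.exp(-dt / tau_p)
        tmp = 1.0 / (nap_scale * (am + bm))
        mp_inf = am / (am + bm)
        mp = mp_inf + (mp - mp_inf) * math.exp(-dt / tmp)

        for g in (m, h, n, p, mp):
            if g < gate_min:
                gate_min = g
            if g > gate_max:
                gate_max = g

        i_ion = (g_na * m * m * m * h * (v - e_na)
                 + g_nap * mp ** nap_exp * (v - e_na)
                 + g_kdr * n * n * n * n * (v - e_k)
                 + g_km * p * (v - e_k)
                 + g_leak * (v - e_leak))
        v = v + dt * (stim[i] - i_ion) / c_m
        v_rec[i] = v

        if v_prev < 0.0 and v >= 0.0:
            t = (i + 1) * dt
            if t - t_last_spike >= 1.0:
                if n_spikes < spike_out.shape[0]:
                    spike_out[n_spikes] = t
                n_spikes += 1
                t_last_spike = t
        v_prev = v

        if not (v_lo <= v <= v_hi) or v != v:
            fail = i
            break
    return v_rec, n_spikes, fail, gate_min, gate_max


# ---------------------------------------------------------------------------
# stimulus programs

@dataclass(frozen=True)
class StimulusProgram:
    """Current-injection program.

    kind:
      * "step" — constant `amplitude` pA for `duration` ms, zero after;
      * "pulse_then_off" — alias of "step" emphasizing the off period;
      * "ramp" — amplitude rising from `start` to `stop` pA over
        `duration` ms, exponentially in amplitude by default
        ("slowly increasing"), or linearly with ramp_shape="linear".
    An optional pre-stimulus (amplitude, duration) precedes the program.
    """
    kind: str = "step"
    amplitude: float = 0.0
    start: float = 0.0
    stop: float = 0.0
    duration: float = 1000.0
    pre_stimulus: Optional[tuple] = None
    ramp_shape: str = "exp"

    def __post_init__(self):
        if self.kind not in ("step", "pulse_then_off", "ramp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.kind == "ramp":
            if not (self.stop > self.start):
                raise ValueError("ramp needs start < stop")
            if self.ramp_shape == "exp" and self.start <= 0:
                raise ValueError("exponential ramp needs start > 0")


def build_stimulus(program: StimulusProgram, total_ms: float, dt: float) -> np.ndarray:
    """Sampled injected-current waveform in pA, length round(total/dt)."""
    nt = int(round(total_ms / dt))
    t = (np.arange(nt) + 0.5) * dt  # midpoint convention
    stim = np.zeros(nt)
    t0 = 0.0
    if program.pre_stimulus is not None:
        amp, dur = program.pre_stimulus
        stim[(t >= t0) & (t < t0 + dur)] = amp
        t0 += dur
    tp = t - t0
    active = (tp >= 0) & (tp < program.duration)
    if program.kind in ("step", "pulse_then_off"):
        stim[active] = program.amplitude
    else:
        frac = tp[active] / program.duration
        if program.ramp_shape == "exp":
            stim[active] = program.start * (program.stop / program.start) ** frac
        elif program.ramp_shape == "linear":
            stim[active] = program.start + (program.stop - program.start) * frac
        else:
            raise ValueError(f"unknown ramp_shape {program.ramp_shape!r}")
    return stim


SCENARIO_PRESETS = {
    # four 1 s steps spanning the threshold region
    "low_steps": dict(kind="step", amplitude=2.0, duration=1000.0),
    # f-I curve steps (amplitude swept by firing_rate_curve)
    "fi_step": dict(kind="step", amplitude=10.0, duration=1000.0),
    # brief pulse, then observe self-sustained firing
    "persistent_firing": dict(kind="pulse_then_off", amplitude=10.0,
                              duration=50.0),
    # slow exponential ramp from rest
    "ramp_rest": dict(kind="ramp", start=0.002, stop=400.0, duration=10000.0),
    # same ramp after a brief firing-inducing pre-stimulus
    "ramp_prestim": dict(kind="ramp", start=0.002, stop=400.0,
                         duration=10000.0, pre_stimulus=(10.0, 10.0)),
}


def stimulus_preset(name: str, **overrides) -> StimulusProgram:
    if name not in SCENARIO_PRESETS:
        raise KeyError(f"unknown scenario preset {name!r}; "
                       f"available: {sorted(SCENARIO_PRESETS)}")
    kwargs = dict(SCENARIO_PRESETS[name])
    kwargs.update(overrides)
    return StimulusProgram(**kwargs)


# ---------------------------------------------------------------------------
# simulation driver and excitability metrics

@dataclass
class SimTrace:
    """Membrane-potential time course plus derived spike metrics."""
    time: np.ndarray
    v_m: np.ndarray
    stimulus: np.ndarray  # pA
    spike_times: np.ndarray
    dt: float
    fired_after_offset: Optional[bool] = None
    block_onset_current: Optional[float] = None
    gate_min: float = float("nan")
    gate_max: float = float("nan")

    def rate_in_window(self, t0: float, t1: float) -> float:
        """Mean firing rate (spikes/s) between t0 and t1 (ms)."""
        n = int(np.sum((self.spike_times >= t0) & (self.spike_times < t1)))
        return 1000.0 * n / (t1 - t0)


def integrate(params: NeuronParams, stim, duration: float,
              dt: float = 0.005) -> SimTrace:
    """Integrate the model under a stimulus program.

    Parameters
    ----------
    params : NeuronParams
    stim : StimulusProgram or ndarray
        A program, or a pre-sampled pA waveform of length
        ``round(duration/dt)``.
    duration : float, ms
    dt : float, ms
        Default 0.005 ms (the 1000x NaP rates are handled by
        exponential-Euler gate updates; dt is set by voltage accuracy).

    The integration starts from the model's zero-stimulus fixed point;
    identical inputs give identical traces.

    Raises
    ------
    IntegrationError
        If V leaves [E_K - 10, E_Na + 10] mV, naming the failure time.
    """
    if isinstance(stim, StimulusProgram):
        stim_pa = build_stimulus(stim, duration, dt)
    else:
        stim_pa = np.asarray(stim, dtype=float)
        if stim_pa.shape[0] != int(round(duration / dt)):
            raise ValueError("stimulus array length does not match duration/dt")
    stim_density = stim_pa * 1e-6 / params.area_cm2

    try:
        v0 = resting_potential(params)
    except IntegrationError:
        # No subthreshold fixed point (e.g. a pacemaking variant whose
        # persistent current outweighs the restoring currents at every
        # subthreshold voltage): start from the leak reversal.
        v0 = params.e_leak
    m0, h0, n0, p0, mp0 = steady_gates(v0, params)
    spike_buf = np.empty(int(duration) + 16)
    v_rec, n_spikes, fail, gmin, gmax = _kernel(
        stim_density, dt, v0, m0, h0, n0, p0, mp0,
        params.g_na, params.g_nap, params.g_kdr, params.g_km, params.g_leak,
        params.e_na, params.e_k, params.e_leak, params.v_t,
        params.tau_max_km, params.c_m, params.h_rate_scale,
        params.nap_rate_scale, params.nap_gate_exponent,
        params.e_k - 10.0, params.e_na + 10.0, spike_buf)
    if fail >= 0:
        raise IntegrationError(
            f"membrane potential out of bounds at t = {fail * dt:.3f} ms "
            f"({params.label})")
    time = (np.arange(stim_pa.shape[0]) + 1) * dt
    spikes = spike_buf[:min(n_spikes, spike_buf.shape[0])].copy()
    return SimTrace(time=time, v_m=v_rec, stimulus=stim_pa,
                    spike_times=spikes, dt=dt, gate_min=gmin, gate_max=gmax)


def test_pulse_peak_current(params: NeuronParams, holding_v: float = -120.0,
                            test_v: float = 0.0, pulse_ms: float = 20.0,
                            dt: float = 0.0005,
                            transient_only: bool = False) -> float:
    """Peak total Na+ current under a commanded voltage step
    (voltage-clamp mode: gates driven by the commanded potential).

    With the membrane held at `holding_v` until the gates reach steady
    state and then stepped to `test_v`, every gate relaxes
    mono-exponentially, so the current is evaluated in closed form on a
    fine time grid.  Returns the signed peak (inward negative) in
    uA/cm^2.
    """
    t = np.arange(int(round(pulse_ms / dt)) + 1) * dt
    m0, h0, n0, p0, mp0 = steady_gates(holding_v, params)
    am, bm = _rates_m(test_v, params.v_t)
    ah, bh = _rates_h(test_v, params.v_t)
    ah, bh = ah * params.h_rate_scale, bh * params.h_rate_scale
    tau_m, m_inf = 1.0 / (am + bm), am / (am + bm)
    tau_h, h_inf = 1.0 / (ah + bh), ah / (ah + bh)
    m = m_inf + (m0 - m_inf) * np.exp(-t / tau_m)
    h = h_inf + (h0 - h_inf) * np.exp(-t / tau_h)
    drive = test_v - params.e_na
    i_na = params.g_na * m ** 3 * h * drive
    if not transient_only:
        tau_mp = tau_m / params.nap_rate_scale
        mp = m_inf + (mp0 - m_inf) * np.exp(-t / tau_mp)
        i_na = i_na + params.g_nap * mp ** params.nap_gate_exponent * drive
    return float(i_na[np.argmax(np.abs(i_na))])


def firing_rate_curve(params: NeuronParams, amplitudes: Iterable[float],
                      duration: float = 1000.0, dt: float = 0.005) -> dict:
    """Steady-state f-I curve: spike count in the final 500 ms of a 1 s
    step, times 2 (spikes/s).  Integration failures at individual
    amplitudes yield NaN for that amplitude only."""
    out = {}
    for amp in amplitudes:
        if amp < 0:
            raise ValueError(f"amplitude must be >= 0: {amp}")
        prog = StimulusProgram(kind="step", amplitude=float(amp),
                               duration=duration)
        try:
            trace = integrate(params, prog, duration, dt)
        except IntegrationError:
            out[float(amp)] = float("nan")
            continue
        out[float(amp)] = trace.rate_in_window(duration - 500.0, duration)
    return out


def persistent_firing_test(params: NeuronParams, pulse_pa: float = 10.0,
                           pulse_ms: float = 50.0, total_ms: float = 1000.0,
                           dt: float = 0.005) -> tuple:
    """Does firing continue to the end of the simulation after the
    stimulus is removed?

    Returns ``(fired_after_offset, n_spikes_after_offset, trace)``.
    "Continues to the end" means at least one post-offset spike exists
    and the terminal silent period is no longer than twice the largest
    post-offset inter-spike interval (100 ms when fewer than two
    post-offset spikes exist).
    """
    if pulse_ms >= total_ms:
        raise ValueError("pulse must end before the simulation does")
    prog = StimulusProgram(kind="pulse_then_off", amplitude=pulse_pa,
                           duration=pulse_ms)
    trace = integrate(params, prog, total_ms, dt)
    post = trace.spike_times[trace.spike_times > pulse_ms]
    if post.size == 0:
        fired = False
    else:
        tail = total_ms - post[-1]
        if post.size >= 2:
            max_isi = float(np.max(np.diff(post)))
            fired = tail <= 2.0 * max_isi
        else:
            fired = tail <= 100.0
    trace.fired_after_offset = fired
    return fired, int(post.size), trace


def ramp_block_test(params: NeuronParams,
                    ramp: Optional[StimulusProgram] = None,
                    pre_stimulus: Optional[tuple] = None,
                    dt: float = 0.005) -> Optional[float]:
    """Depolarization-block onset current during a slow ramp.

    Block is a terminal spike-free period of at least ``BLOCK_MIN_MS``
    with V sustained above ``BLOCK_V_MV``; the onset current is the
    injected current at the last spike.  Returns None when no block
    (or no spiking at all) occurs before the ramp ends.
    """
    if ramp is None:
        ramp = stimulus_preset("ramp_rest")
    if pre_stimulus is not None:
        ramp = replace(ramp, pre_stimulus=pre_stimulus)
    pre_ms = ramp.pre_stimulus[1] if ramp.pre_stimulus else 0.0
    total = pre_ms + ramp.duration
    trace = integrate(params, ramp, total, dt)
    if trace.spike_times.size == 0:
        return None
    t_last = float(trace.spike_times[-1])
    if total - t_last < BLOCK_MIN_MS:
        return None  # still firing at ramp end
    # terminal contiguous run with V above the block level; the run may
    # begin just before the last (shrinking) spike of the transition
    above = trace.v_m > BLOCK_V_MV
    n_run = 0
    for i in range(above.size - 1, -1, -1):
        if above[i]:
            n_run += 1
        else:
            break
    if n_run * dt < BLOCK_MIN_MS:
        return None
    i_last = int(min(round(t_last / dt), trace.stimulus.size - 1))
    onset = float(trace.stimulus[i_last])
    trace.block_onset_current = onset
    return onset


def rheobase(params: NeuronParams, resolution: float = 0.25,
             i_max: float = 100.0, duration: float = 1000.0,
             dt: float = 0.005) -> Optional[float]:
    """Smallest 1 s step amplitude evoking at least one spike, by
    bisection to `resolution` pA.  None if even `i_max` is silent."""
    if resolution <= 0:
        raise ValueError("resolution must be > 0")

    def fires(amp: float) -> bool:
        prog = StimulusProgram(kind="step", amplitude=amp, duration=duration)
        try:
            trace = integrate(params, prog, duration, dt)
        except IntegrationError:
            return True  # blow-up at high drive counts as excitable
        return trace.spike_times.size > 0

    if not fires(i_max):
        return None
    lo, hi = 0.0, i_max
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi
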