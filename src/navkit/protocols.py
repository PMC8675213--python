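"""Voltage-clamp protocol definitions and the four standard presets.

The presets mirror the standard NaV characterization battery:

* ``activation`` — 10 ms steps from a -130 mV holding potential to
  -100..+70 mV in 10 mV increments (peak I-V, conductance-voltage
  curve, onset kinetics, current density at 0 mV).
* ``ssfi`` — steady-state fast inactivation: 200 ms prepulses from
  -130 to +10 mV followed by a 19 ms test pulse to 0 mV.
* ``recovery`` — recovery from fast inactivation: 200 ms conditioning
  at 0 mV, a -90 mV recovery interval of increasing duration, then a
  19 ms test pulse to 0 mV.
* ``persistent`` — a single 50 ms pulse from -130 to 0 mV for the
  persistent (non-inactivating) current fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["VClampProtocol", "protocol_preset", "PROTOCOL_KINDS"]

PROTOCOL_KINDS = ("activation", "ssfi", "recovery", "persistent")


@dataclass(frozen=True)
class VClampProtocol:
    """One voltage-clamp stimulus protocol.

    ``baseline_ms`` is a short pre-step segment at the holding potential
    included in every emitted sweep so analyses can measure a baseline.
    For ``recovery``, ``step_duration`` is the 0 mV conditioning-pulse
    duration and ``recovery_times`` the -90 mV interval durations.
    """

    kind: str
    holding_v: float
    step_voltages: tuple = ()
    step_duration: float = 10.0
    test_pulse_v: float = 0.0
    test_pulse_duration: float = 19.0
    recovery_times: tuple = ()
    recovery_v: float = -90.0
    sample_interval: float = 0.02
    baseline_ms: float = 1.0

    def __post_init__(self):
        if self.kind not in PROTOCOL_KINDS:
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.kind != "recovery":
            if len(self.step_voltages) == 0:
                raise ValueError("step_voltages must be non-empty")
            vs = list(self.step_voltages)
            if any(b <= a for a, b in zip(vs, vs[1:])):
                raise ValueError("step_voltages must be strictly increasing")
        else:
            if len(self.recovery_times) == 0:
                raise ValueError("recovery protocol needs recovery_times")
            ts = list(self.recovery_times)
            if any(t < 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
                raise ValueError("recovery_times must be non-negative, strictly increasing")
        if self.step_duration <= 0 or self.test_pulse_duration <= 0:
            raise ValueError("durations must be > 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.sample_interval > self.step_duration / 50.0:
            raise ValueError(
                f"sample_interval {self.sample_interval} ms too coarse for "
                f"{self.step_duration} ms steps (need <= step_duration/50)"
            )

    @property
    def sweep_keys(self) -> tuple:
        """Per-sweep condition labels: step voltages (mV) for voltage
        protocols, recovery intervals (ms) for the recovery protocol."""
        return self.recovery_times if self.kind == "recovery" else self.step_voltages


def protocol_preset(name: str, sample_interval: Optional[float] = None,
                    **overrides) -> VClampProtocol:
    """Build one of the named standard protocols.

    Parameters
    ----------
    name : {"activation", "ssfi", "recovery", "persistent"}
    sample_interval : float, optional
        Sampling interval in ms (default 0.02 ms, i.e. 50 kHz).
    **overrides
        Any :class:`VClampProtocol` field.
    """
    presets = {
        "activation": dict(
            kind="activation",
            holding_v=-130.0,
            step_voltages=tuple(range(-100, 80, 10)),
            step_duration=10.0,
        ),
        "ssfi": dict(
            kind="ssfi",
            holding_v=-130.0,
            step_voltages=tuple(range(-130, 20, 10)),
            step_duration=200.0,
            test_pulse_v=0.0,
            test_pulse_duration=19.0,
        ),
        "recovery": dict(
            kind="recovery",
            holding_v=-130.0,
            step_voltages=(0.0,),
            step_duration=200.0,
            test_pulse_v=0.0,
            test_pulse_duration=19.0,
            recovery_times=(0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0,
                            30.0, 50.0, 80.0, 120.0, 200.0),
            recovery_v=-90.0,
        ),
        "persistent": dict(
            kind="persistent",
            holding_v=-130.0,
            step_voltages=(0.0,),
            step_duration=50.0,
        ),
    }
    if name not in presets:
        raise KeyError(f"unknown protocol preset {name!r}; "
                       f"available: {sorted(presets)}")
    kwargs = presets[name]
    if sample_interval is not None:
        kwargs["sample_interval"] = sample_interval
    kwargs.update(overrides)
    return VClampProtocol(**kwargs)
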