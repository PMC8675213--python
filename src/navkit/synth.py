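"""Synthetic whole-cell voltage-clamp sweep generation.

The generator is deliberately phenomenological rather than mechanistic:
each sweep is a stylized pulse whose peak, decay time constant,
non-inactivating plateau, availability scaling and recovery scaling are
*exactly* the values stored in the :class:`~navkit.phenotypes.ChannelPhenotype`.
That gives the analysis stage a ground truth it can be tested against to
machine precision.  (A mechanistic m3h model lives in :mod:`navkit.neuron`.)

Waveform model for a depolarizing pulse to voltage V:

* peak amplitude ``I_pk(V) = -density * C_m * a_inf(V) (V - v_rev) /
  (a_inf(0) (0 - v_rev))`` so the 0 mV sweep peaks at exactly
  ``density * C_m`` (inward-negative);
* a 0.1 ms stylized rising ramp (exponential shape, normalized to reach
  the peak exactly at its end) standing in for activation, which the
  analyses never fit;
* after the peak, single-exponential decay with the phenotype's
  ``tau_onset(V)`` toward the persistent plateau ``f_persistent * I_pk``.

SSFI sweeps scale the 0 mV test-pulse peak by the availability Boltzmann
``h_inf(prepulse V)``; recovery sweeps scale it by the double-exponential
recovered fraction at the sweep's recovery interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .phenotypes import ChannelPhenotype
from .protocols import VClampProtocol

__all__ = [
    "TraceSet",
    "simulate_protocol",
    "generate_cohort",
    "generate_cell_suite",
    "sample_cell_phenotypes",
    "boltzmann_asc",
    "boltzmann_desc",
    "recovered_fraction",
]

RISE_MS = 0.1  # stylized activation ramp duration


def boltzmann_asc(v, v_half, k):
    """Ascending Boltzmann 1 / (1 + exp((v_half - v)/k))."""
    return 1.0 / (1.0 + np.exp((v_half - np.asarray(v, dtype=float)) / k))


def boltzmann_desc(v, v_half, k):
    """Descending Boltzmann 1 / (1 + exp((v - v_half)/k))."""
    return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - v_half) / k))


def recovered_fraction(t, tau_fast, tau_slow, frac_fast):
    """Double-exponential recovery: 1 - A_f e^(-t/tau_f) - (1-A_f) e^(-t/tau_s)."""
    t = np.asarray(t, dtype=float)
    return 1.0 - frac_fast * np.exp(-t / tau_fast) - (1.0 - frac_fast) * np.exp(-t / tau_slow)


@dataclass
class TraceSet:
    """A set of current sweeps sharing one time base.

    ``sweep_keys`` holds the per-sweep condition: command voltage (mV)
    for activation/ssfi/persistent protocols, recovery interval (ms)
    for the recovery protocol.  ``currents`` is (n_sweeps, n_samples)
    in pA, inward-negative.
    """

    time: np.ndarray
    sweep_keys: np.ndarray
    currents: np.ndarray
    capacitance: float
    protocol: VClampProtocol
    genotype: str = ""
    temperature: float = float("nan")
    phenotype_id: str = ""
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.sweep_keys = np.asarray(self.sweep_keys, dtype=float)
        self.currents = np.atleast_2d(np.asarray(self.currents, dtype=float))
        if self.currents.shape != (len(self.sweep_keys), len(self.time)):
            raise ValueError(
                f"currents shape {self.currents.shape} does not match "
                f"{len(self.sweep_keys)} sweeps x {len(self.time)} samples"
            )
        if not self.capacitance > 0:
            raise ValueError(f"capacitance must be > 0: {self.capacitance}")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweep_keys)

    def sweep(self, key: float) -> np.ndarray:
        """Current array for the sweep whose condition equals `key`."""
        idx = np.flatnonzero(np.isclose(self.sweep_keys, key))
        if idx.size == 0:
            raise KeyError(f"no sweep at condition {key}")
        return self.currents[idx[0]]


def _pulse(t_rel: np.ndarray, i_pk: float, tau: float, f: float) -> np.ndarray:
    """Stylized pulse current on a time axis relative to pulse onset.

    Zero before onset; normalized exponential ramp over RISE_MS reaching
    i_pk exactly; then exponential decay toward f * i_pk.
    """
    out = np.zeros_like(t_rel)
    tau_r = RISE_MS / 3.0
    rising = (t_rel >= 0) & (t_rel < RISE_MS)
    norm = 1.0 - np.exp(-RISE_MS / tau_r)
    out[rising] = i_pk * (1.0 - np.exp(-t_rel[rising] / tau_r)) / norm
    after = t_rel >= RISE_MS
    out[after] = i_pk * (f + (1.0 - f) * np.exp(-(t_rel[after] - RISE_MS) / tau))
    return out


def _peak_current(phen: ChannelPhenotype, v: float, capacitance: float) -> float:
    """Signed peak current (pA) at command voltage v, normalized so the
    0 mV peak magnitude equals density * C_m."""
    a = boltzmann_asc(v, phen.v_half_act, phen.k_act)
    a0 = boltzmann_asc(0.0, phen.v_half_act, phen.k_act)
    return -phen.density_at_0mV * capacitance * float(a) * (v - phen.v_rev) / (
        float(a0) * (0.0 - phen.v_rev)
    )


def simulate_protocol(
    phenotype: ChannelPhenotype,
    protocol: VClampProtocol,
    capacitance: float = 15.0,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
) -> TraceSet:
    """Generate one cell's sweep set for a protocol.

    Parameters
    ----------
    phenotype : ChannelPhenotype
        Ground-truth generative parameters.
    protocol : VClampProtocol
        Stimulus protocol (see :func:`navkit.protocols.protocol_preset`).
    capacitance : float
        Whole-cell capacitance in pF.
    noise_sd : float
        Standard deviation of i.i.d. zero-mean Gaussian noise, pA.
        With ``noise_sd = 0`` the output is bit-reproducible.
    seed : int, optional
        Noise seed; required only when ``noise_sd > 0``.

    Raises
    ------
    ValueError
        Non-positive capacitance, out-of-range protocol voltages, or
        negative noise_sd.
    KeyError
        Never for tau lookup (table interpolation clamps); kept for
        future strict modes.
    """
    if capacitance <= 0:
        raise ValueError(f"capacitance must be > 0: {capacitance}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0: {noise_sd}")
    for v in protocol.step_voltages:
        if not (-130.0 <= v <= 70.0):
            raise ValueError(f"step voltage {v} mV outside [-130, 70]")

    dt = protocol.sample_interval
    base = protocol.baseline_ms
    f = phenotype.f_persistent

    if protocol.kind in ("activation", "persistent"):
        total = base + protocol.step_duration
        time = np.arange(round(total / dt) + 1) * dt
        rows = []
        for v in protocol.step_voltages:
            i_pk = _peak_current(phenotype, v, capacitance)
            tau = phenotype.tau_onset(v)
            rows.append(_pulse(time - base, i_pk, tau, f))
        currents = np.array(rows)
    elif protocol.kind == "ssfi":
        total = base + protocol.test_pulse_duration
        time = np.arange(round(total / dt) + 1) * dt
        i_pk0 = _peak_current(phenotype, protocol.test_pulse_v, capacitance)
        tau = phenotype.tau_onset(protocol.test_pulse_v)
        rows = []
        for vpre in protocol.step_voltages:
            h = float(boltzmann_desc(vpre, phenotype.v_half_inact, phenotype.k_inact))
            rows.append(_pulse(time - base, i_pk0 * h, tau, f))
        currents = np.array(rows)
    elif protocol.kind == "recovery":
        max_rec = max(protocol.recovery_times)
        total = base + protocol.step_duration + max_rec + protocol.test_pulse_duration
        time = np.arange(round(total / dt) + 1) * dt
        i_pk0 = _peak_current(phenotype, protocol.test_pulse_v, capacitance)
        tau = phenotype.tau_onset(protocol.test_pulse_v)
        cond = _pulse(time - base, i_pk0, tau, f)
        cond[time >= base + protocol.step_duration] = 0.0
        rows = []
        for t_rec in protocol.recovery_times:
            frac = float(
                recovered_fraction(t_rec, phenotype.rec_tau_fast,
                                   phenotype.rec_tau_slow, phenotype.rec_frac_fast)
            )
            test_start = base + protocol.step_duration + t_rec
            test = _pulse(time - test_start, i_pk0 * frac, tau, f)
            test[time >= test_start + protocol.test_pulse_duration] = 0.0
            rows.append(cond + test)
        currents = np.array(rows)
    else:  # pragma: no cover - guarded by VClampProtocol validation
        raise ValueError(f"unknown protocol kind {protocol.kind!r}")

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        currents = currents + rng.normal(0.0, noise_sd, size=currents.shape)

    return TraceSet(
        time=time,
        sweep_keys=np.asarray(protocol.sweep_keys, dtype=float),
        currents=currents,
        capacitance=capacitance,
        protocol=protocol,
        genotype=phenotype.genotype,
        temperature=phenotype.temperature,
        phenotype_id=f"{phenotype.genotype}@{phenotype.temperature:g}C",
        noise_sd=noise_sd,
        seed=seed,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Multiplicative factors with mean exactly 1 and fractional SD cv."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=n))


def sample_cell_phenotypes(
    phenotype: ChannelPhenotype,
    n_cells: int,
    cell_variability: float,
    seed: int,
    capacitance_mean: float = 15.0,
) -> List[tuple]:
    """Draw per-cell (phenotype, capacitance) pairs for a cohort.

    Each cell perturbs density, every onset tau, and the persistent
    fraction by independent mean-1 log-normal factors with fractional SD
    ``cell_variability``; capacitance is log-normal around
    ``capacitance_mean`` with the same fractional SD.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if cell_variability < 0:
        raise ValueError("cell_variability must be >= 0")
    rng = np.random.default_rng(seed)
    dens_f = _lognormal_factors(rng, cell_variability, n_cells)
    tau_f = _lognormal_factors(rng, cell_variability, n_cells)
    pers_f = _lognormal_factors(rng, cell_variability, n_cells)
    cap_f = _lognormal_factors(rng, cell_variability, n_cells)
    cells = []
    for i in range(n_cells):
        perturbed = phenotype.with_(
            density_at_0mV=phenotype.density_at_0mV * dens_f[i],
            tau_onset_table={v: t * tau_f[i] for v, t in phenotype.tau_onset_table.items()},
            f_persistent=min(phenotype.f_persistent * pers_f[i], 0.5),
        )
        cells.append((perturbed, capacitance_mean * cap_f[i]))
    return cells


def generate_cohort(
    phenotype: ChannelPhenotype,
    protocol: VClampProtocol,
    n_cells: int,
    cell_variability: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    capacitance_mean: float = 15.0,
) -> List[TraceSet]:
    """Generate a cohort of cells for one protocol.

    The seed fixes both the cell-level perturbations and every cell's
    noise stream; the same seed always yields the identical cohort.
    """
    cells = sample_cell_phenotypes(phenotype, n_cells, cell_variability, seed,
                                   capacitance_mean)
    ss = np.random.SeedSequence(seed).spawn(n_cells)
    out = []
    for i, (phen_i, cap_i) in enumerate(cells):
        noise_seed = int(ss[i].generate_state(1)[0] % (2**31)) if noise_sd > 0 else None
        out.append(simulate_protocol(phen_i, protocol, cap_i, noise_sd, noise_seed))
    return out


def generate_cell_suite(
    phenotype: ChannelPhenotype,
    protocols: dict,
    n_cells: int,
    cell_variability: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    capacitance_mean: float = 15.0,
) -> List[dict]:
    """Generate a cohort where each cell is recorded under several
    protocols (same per-cell phenotype across protocols).

    Parameters
    ----------
    protocols : dict
        name -> VClampProtocol.

    Returns
    -------
    list of dict
        One dict per cell mapping protocol name -> TraceSet.
    """
    cells = sample_cell_phenotypes(phenotype, n_cells, cell_variability, seed,
                                   capacitance_mean)
    ss = np.random.SeedSequence(seed).spawn(n_cells * max(1, len(protocols)))
    out = []
    k = 0
    for phen_i, cap_i in cells:
        rec = {}
        for name, proto in protocols.items():
            noise_seed = int(ss[k].generate_state(1)[0] % (2**31)) if noise_sd > 0 else None
            k += 1
            rec[name] = simulate_protocol(phen_i, proto, cap_i, noise_sd, noise_seed)
        out.append(rec)
    return out
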