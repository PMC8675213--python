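"""Per-cell electrophysiology measurements from voltage-clamp sweeps.

Implements the standard NaV whole-cell analysis battery on a
:class:`~navkit.synth.TraceSet`:

* baseline-subtracted peak currents per sweep and the peak I-V;
* normalized conductance-voltage curve G(V) = I_pk / (V - V_rev), with
  V_rev either supplied or estimated from the zero crossing of the
  peak I-V, fitted with an ascending Boltzmann;
* current density |I_pk(0 mV)| / C_m in pA/pF;
* single-exponential fast-inactivation onset time constants on the
  -30..+20 mV reporting grid;
* steady-state fast inactivation (availability) curve and descending
  Boltzmann fit;
* recovery from fast inactivation, double-exponential fit;
* persistent (non-inactivating) current fraction, measured both at the
  end of the 50 ms pulse and over the 25-30 ms window as a
  stabilization check.

Peak detection skips the first 0.05 ms of each depolarizing step, the
stylized capacitive/rising region the generator emits; "end of pulse"
is operationalized as the mean over the final 2 ms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .fits import (BoltzmannFit, DoubleExpFit, ExpFit, FitError,
                   fit_boltzmann, fit_double_exp_recovery,
                   fit_exponential_decay)
from .synth import TraceSet

__all__ = [
    "CellMetrics", "ProtocolMismatchError", "TAU_REPORT_GRID",
    "measure_peaks", "estimate_v_rev", "conductance_curve",
    "fit_gv_boltzmann", "fit_onset_tau", "current_density",
    "ssfi_availability", "ssfi_curve", "recovery_fractions",
    "recovery_curve", "persistent_fraction", "analyze_cell",
    "metrics_table",
]

# Reporting grid for onset time constants.
TAU_REPORT_GRID = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0)

PEAK_SKIP_MS = 0.05   # skip stylized rising/capacitive region
END_WINDOW_MS = 2.0   # "end of pulse" averaging window


class ProtocolMismatchError(ValueError):
    """The TraceSet's protocol cannot support the requested measurement."""


def _require_kind(traces: TraceSet, kind: str, op: str) -> None:
    if traces.protocol.kind != kind:
        raise ProtocolMismatchError(
            f"{op} needs a {kind!r} protocol, got {traces.protocol.kind!r}")


def _baseline(traces: TraceSet, row: np.ndarray) -> float:
    pre = traces.time < traces.protocol.baseline_ms
    if not np.any(pre):
        return 0.0
    return float(np.mean(row[pre]))


def _signed_extremum(y: np.ndarray) -> float:
    if y.size == 0:
        raise ValueError("empty window for peak detection")
    return float(y[np.argmax(np.abs(y))])


def _window_peak(traces: TraceSet, row: np.ndarray, t0: float, t1: float,
                 subtract_baseline: bool = True) -> float:
    base = _baseline(traces, row) if subtract_baseline else 0.0
    mask = (traces.time >= t0) & (traces.time <= t1)
    return _signed_extremum(row[mask] - base)


def measure_peaks(traces: TraceSet) -> Dict[float, float]:
    """Baseline-subtracted signed peak current (pA) per activation sweep.

    The extremum is taken within the depolarizing step, excluding the
    first ``PEAK_SKIP_MS`` after step onset.
    """
    _require_kind(traces, "activation", "measure_peaks")
    p = traces.protocol
    t0 = p.baseline_ms + PEAK_SKIP_MS
    t1 = p.baseline_ms + p.step_duration
    out = {}
    for key, row in zip(traces.sweep_keys, traces.currents):
        if row.size == 0:
            raise ValueError(f"empty sweep at {key} mV")
        out[float(key)] = _window_peak(traces, row, t0, t1)
    return out


def estimate_v_rev(peaks: Dict[float, float]) -> float:
    """Reversal potential from the zero crossing of the peak I-V,
    by linear interpolation between the bracketing voltages.

    Scans from the most depolarized end for the first sign change; the
    upper limb of the NaV I-V is locally linear there.
    """
    vs = np.array(sorted(peaks), dtype=float)
    iv = np.array([peaks[v] for v in vs])
    for i in range(len(vs) - 1, 0, -1):
        a, b = iv[i - 1], iv[i]
        if a == 0.0:
            return float(vs[i - 1])
        if a * b < 0:
            w = -a / (b - a)
            return float(vs[i - 1] + w * (vs[i] - vs[i - 1]))
    raise FitError("peak I-V has no zero crossing; cannot estimate V_rev")


def conductance_curve(peaks: Dict[float, float],
                      v_rev: Optional[float] = None) -> Dict[float, float]:
    """Normalized conductance G(V) = I_pk / (V - V_rev), max-normalized.

    Voltages within 0.5 mV of V_rev are excluded (vanishing driving
    force).  Raises :class:`~navkit.fits.FitError` when fewer than 4
    usable voltages remain or all peaks are zero.
    """
    if all(p == 0 for p in peaks.values()):
        raise FitError("all peak currents are zero; conductance undefined")
    if v_rev is None:
        v_rev = estimate_v_rev(peaks)
    g = {}
    for v in sorted(peaks):
        if abs(v - v_rev) < 0.5:
            continue
        g[v] = peaks[v] / (v - v_rev)
    if len(g) < 4:
        raise FitError(f"only {len(g)} voltages usable for conductance")
    gmax = max(g.values())
    if gmax <= 0:
        raise FitError("non-positive maximal conductance")
    return {v: val / gmax for v, val in g.items()}


def fit_gv_boltzmann(traces: TraceSet,
                     v_rev: Optional[float] = None) -> BoltzmannFit:
    """Ascending Boltzmann fit of the normalized G-V curve."""
    peaks = measure_peaks(traces)
    g = conductance_curve(peaks, v_rev=v_rev)
    return fit_boltzmann(g, ascending=True)


def fit_onset_tau(traces: TraceSet,
                  voltages: Iterable[float] = TAU_REPORT_GRID,
                  strict: bool = False) -> Dict[float, ExpFit]:
    """Single-exponential fits of fast-inactivation onset per voltage.

    The fit window runs from the sweep's peak sample to the end of the
    depolarizing step.  Non-decaying sweeps raise
    :class:`~navkit.fits.FitError` when ``strict``; otherwise they are
    excluded (an empty result still raises).
    """
    _require_kind(traces, "activation", "fit_onset_tau")
    p = traces.protocol
    t_end = p.baseline_ms + p.step_duration
    out: Dict[float, ExpFit] = {}
    errors = []
    for v in voltages:
        row = traces.sweep(v)
        base = _baseline(traces, row)
        mask = (traces.time >= p.baseline_ms + PEAK_SKIP_MS) & (traces.time <= t_end)
        t_win = traces.time[mask]
        y_win = row[mask] - base
        i_pk = int(np.argmax(np.abs(y_win)))
        try:
            out[float(v)] = fit_exponential_decay(t_win[i_pk:], y_win[i_pk:])
        except FitError as exc:
            if strict:
                raise FitError(f"onset fit at {v} mV: {exc}") from exc
            errors.append(f"{v} mV: {exc}")
    if not out:
        raise FitError("onset fit failed at every requested voltage: "
                       + "; ".join(errors))
    return out


def current_density(traces: TraceSet) -> float:
    """|peak current at 0 mV| / capacitance, in pA/pF."""
    peaks = measure_peaks(traces)
    if not any(np.isclose(v, 0.0) for v in peaks):
        raise ProtocolMismatchError("activation protocol lacks a 0 mV sweep")
    v0 = min(peaks, key=lambda v: abs(v))
    return abs(peaks[v0]) / traces.capacitance


def ssfi_availability(traces: TraceSet) -> Dict[float, float]:
    """Normalized channel availability per prepulse voltage (test-pulse
    peak magnitudes, max-normalized)."""
    _require_kind(traces, "ssfi", "ssfi_availability")
    p = traces.protocol
    t0 = p.baseline_ms + PEAK_SKIP_MS
    t1 = p.baseline_ms + p.test_pulse_duration
    peaks = {}
    for key, row in zip(traces.sweep_keys, traces.currents):
        peaks[float(key)] = abs(_window_peak(traces, row, t0, t1))
    pmax = max(peaks.values())
    if pmax <= 0:
        raise FitError("all SSFI test-pulse peaks are zero")
    return {v: peaks[v] / pmax for v in sorted(peaks)}


def ssfi_curve(traces: TraceSet) -> BoltzmannFit:
    """Descending Boltzmann fit of steady-state fast inactivation."""
    return fit_boltzmann(ssfi_availability(traces), ascending=False)


def recovery_fractions(traces: TraceSet) -> Dict[float, float]:
    """Fraction recovered per recovery interval: test-pulse peak divided
    by the conditioning-pulse peak of the same sweep."""
    _require_kind(traces, "recovery", "recovery_fractions")
    p = traces.protocol
    cond0 = p.baseline_ms + PEAK_SKIP_MS
    cond1 = p.baseline_ms + p.step_duration
    out = {}
    for t_rec, row in zip(traces.sweep_keys, traces.currents):
        cond_peak = abs(_window_peak(traces, row, cond0, cond1))
        if cond_peak == 0:
            raise FitError(f"zero conditioning peak at t_rec={t_rec} ms")
        t_test = p.baseline_ms + p.step_duration + float(t_rec)
        test_peak = abs(_window_peak(traces, row, t_test + PEAK_SKIP_MS,
                                     t_test + p.test_pulse_duration))
        out[float(t_rec)] = test_peak / cond_peak
    return out


def recovery_curve(traces: TraceSet) -> DoubleExpFit:
    """Double-exponential fit of the fraction-recovered vs time curve."""
    frac = recovery_fractions(traces)
    if len(frac) < 8:
        raise FitError(f"recovery fit wants >= 8 recovery times, got {len(frac)}")
    t = np.array(sorted(frac), dtype=float)
    y = np.array([frac[k] for k in sorted(frac)])
    return fit_double_exp_recovery(t, y)


def persistent_fraction(traces: TraceSet,
                        stability_warn: float = 0.20) -> tuple:
    """Persistent current as a percentage of peak.

    Returns ``(pct_end, pct_25_30)``: the mean |current| over the final
    ``END_WINDOW_MS`` of the depolarizing pulse, and over the 25-30 ms
    window, each divided by the peak magnitude and expressed in percent.
    A ``UserWarning`` is issued when the two differ by more than
    ``stability_warn`` relatively (persistent level not stabilized).
    """
    _require_kind(traces, "persistent", "persistent_fraction")
    p = traces.protocol
    row = traces.currents[0]
    base = _baseline(traces, row)
    y = row - base
    t = traces.time
    step0, step1 = p.baseline_ms, p.baseline_ms + p.step_duration
    win = (t >= step0 + PEAK_SKIP_MS) & (t <= step1)
    peak = np.max(np.abs(y[win]))
    if peak == 0:
        raise FitError("zero peak current; persistent fraction undefined")
    end_mask = (t >= step1 - END_WINDOW_MS) & (t <= step1)
    mid_mask = (t >= step0 + 25.0) & (t <= step0 + 30.0)
    pct_end = 100.0 * float(np.mean(np.abs(y[end_mask]))) / peak
    pct_25_30 = (100.0 * float(np.mean(np.abs(y[mid_mask]))) / peak
                 if np.any(mid_mask) else float("nan"))
    if np.isfinite(pct_25_30) and max(pct_end, pct_25_30) > 0.01:
        rel = abs(pct_end - pct_25_30) / max(pct_end, pct_25_30)
        if rel > stability_warn:
            warnings.warn(
                f"persistent current not stabilized: end {pct_end:.3g}% vs "
                f"25-30 ms {pct_25_30:.3g}% (rel. diff {rel:.0%})",
                UserWarning, stacklevel=2)
    return pct_end, pct_25_30


@dataclass
class CellMetrics:
    """All measured quantities for one cell."""

    genotype: str = ""
    temperature: float = float("nan")
    current_density_0mV: Optional[float] = None
    gv_fit: Optional[BoltzmannFit] = None
    ssfi_fit: Optional[BoltzmannFit] = None
    tau_onset_by_v: Dict[float, float] = field(default_factory=dict)
    recovery_fit: Optional[DoubleExpFit] = None
    persistent_pct_end: Optional[float] = None
    persistent_pct_25_30: Optional[float] = None


def analyze_cell(suite: Dict[str, TraceSet],
                 v_rev: Optional[float] = None) -> CellMetrics:
    """Run every applicable measurement on one cell's protocol suite.

    Parameters
    ----------
    suite : dict
        Protocol name ("activation", "ssfi", "recovery", "persistent")
        -> TraceSet.  Any subset is accepted; absent protocols leave the
        corresponding metrics unset.
    v_rev : float, optional
        Override the I-V-estimated reversal potential for the G-V curve.
    """
    some = next(iter(suite.values()))
    m = CellMetrics(genotype=some.genotype, temperature=some.temperature)
    if "activation" in suite:
        act = suite["activation"]
        m.current_density_0mV = current_density(act)
        m.gv_fit = fit_gv_boltzmann(act, v_rev=v_rev)
        taus = fit_onset_tau(act)
        m.tau_onset_by_v = {v: f.tau for v, f in taus.items()}
    if "ssfi" in suite:
        m.ssfi_fit = ssfi_curve(suite["ssfi"])
    if "recovery" in suite:
        m.recovery_fit = recovery_curve(suite["recovery"])
    if "persistent" in suite:
        m.persistent_pct_end, m.persistent_pct_25_30 = \
            persistent_fraction(suite["persistent"])
    return m


def metrics_table(cells: List[CellMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-cell table of measured quantities."""
    rows = []
    for i, m in enumerate(cells):
        row = {
            "cell_id": i,
            "genotype": m.genotype,
            "temperature_C": m.temperature,
            "density_pA_pF": m.current_density_0mV,
            "v_half_act_mV": m.gv_fit.v_half if m.gv_fit else None,
            "k_act_mV": m.gv_fit.k if m.gv_fit else None,
            "v_half_inact_mV": m.ssfi_fit.v_half if m.ssfi_fit else None,
            "k_inact_mV": m.ssfi_fit.k if m.ssfi_fit else None,
        }
        for v in TAU_REPORT_GRID:
            row[f"tau_ms_at_{v:g}"] = m.tau_onset_by_v.get(v)
        row["rec_tau_fast_ms"] = m.recovery_fit.tau_fast if m.recovery_fit else None
        row["rec_tau_slow_ms"] = m.recovery_fit.tau_slow if m.recovery_fit else None
        row["persistent_pct"] = m.persistent_pct_end
        rows.append(row)
    return pd.DataFrame(rows)
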