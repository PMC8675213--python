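"""Curve fits for voltage-clamp analysis: Boltzmann, single- and
double-exponential.

All fits are deterministic: initial values follow fixed rules computed
from the data (no random restarts), so identical input always yields
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["BoltzmannFit", "ExpFit", "DoubleExpFit", "FitError",
           "fit_boltzmann", "fit_exponential_decay", "fit_double_exp_recovery"]


class FitError(RuntimeError):
    """A fit could not be performed or did not converge.  Carries the
    offending data summary in its message."""


@dataclass(frozen=True)
class BoltzmannFit:
    """Boltzmann fit y = 1 / (1 + exp(+-(v_half - V)/k)).

    ``k`` is reported positive for both the ascending (activation) and
    descending (availability) forms; ``ascending`` records which form
    was fitted.
    """
    v_half: float
    k: float
    residual_norm: float
    ascending: bool = True

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        if self.ascending:
            return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))
        return 1.0 / (1.0 + np.exp((v - self.v_half) / self.k))


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential-plus-offset fit I(t) = amplitude e^(-t/tau) + offset."""
    tau: float
    amplitude: float
    offset: float
    residual_norm: float


@dataclass(frozen=True)
class DoubleExpFit:
    """Double-exponential recovery fit
    f(t) = 1 - frac_fast e^(-t/tau_fast) - (1 - frac_fast) e^(-t/tau_slow).

    ``degenerate`` is set when the two time constants were not separable
    and a single-exponential fallback was used (then tau_fast == tau_slow).
    """
    tau_fast: float
    tau_slow: float
    frac_fast: float
    residual_norm: float
    degenerate: bool = False

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return (1.0 - self.frac_fast * np.exp(-t / self.tau_fast)
                - (1.0 - self.frac_fast) * np.exp(-t / self.tau_slow))


def _half_crossing(v: np.ndarray, y: np.ndarray, level: float) -> float:
    """Voltage at which y crosses `level`, by linear interpolation on the
    first bracketing pair; falls back to the voltage of the closest point."""
    for i in range(len(v) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            w = (level - y0) / (y1 - y0)
            return float(v[i] + w * (v[i + 1] - v[i]))
    return float(v[np.argmin(np.abs(y - level))])


def fit_boltzmann(xy: dict, ascending: bool = True) -> BoltzmannFit:
    """Least-squares Boltzmann fit of voltage -> normalized value data.

    Parameters
    ----------
    xy : dict
        Voltage (mV) -> value (dimensionless, roughly in [0, 1]).
    ascending : bool
        True for the activation form (rises with depolarization),
        False for the availability (SSFI) form.

    Notes
    -----
    Initialization is deterministic: v_half0 is the voltage of half
    maximum by linear interpolation, k0 = 7 mV.

    Raises
    ------
    FitError
        Fewer than 4 points or non-convergence.
    """
    if len(xy) < 4:
        raise FitError(f"Boltzmann fit needs >= 4 points, got {len(xy)}")
    v = np.array(sorted(xy), dtype=float)
    y = np.array([xy[k] for k in sorted(xy)], dtype=float)

    v_half0 = _half_crossing(v, y, 0.5)
    k0 = 7.0

    if ascending:
        def model(vv, v_half, k):
            return 1.0 / (1.0 + np.exp((v_half - vv) / k))
    else:
        def model(vv, v_half, k):
            return 1.0 / (1.0 + np.exp((vv - v_half) / k))

    try:
        popt, _ = curve_fit(model, v, y, p0=[v_half0, k0],
                            bounds=([v.min() - 100.0, 0.1], [v.max() + 100.0, 100.0]),
                            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Boltzmann fit failed: {exc}; v_half0={v_half0:.3g}") from exc
    resid = float(np.linalg.norm(model(v, *popt) - y))
    return BoltzmannFit(v_half=float(popt[0]), k=float(popt[1]),
                        residual_norm=resid, ascending=ascending)


def fit_exponential_decay(t: np.ndarray, y: np.ndarray,
                          min_decay_fraction: float = 0.05) -> ExpFit:
    """Fit y(t) = A e^(-t/tau) + C to a decaying segment.

    Works for either sign of A (inward currents decay upward toward the
    plateau).  tau0 comes from the log-linear slope over the first
    decade of the decay; A0 and C0 from the segment endpoints.

    Raises
    ------
    FitError
        If the segment does not decay (|A| below ``min_decay_fraction``
        of the initial magnitude) or the fit fails.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise FitError(f"exponential fit needs >= 5 samples, got {t.size}")
    t0 = t - t[0]
    c0 = float(y[-1])
    a0 = float(y[0] - c0)
    scale = max(abs(y[0]), abs(c0), 1e-30)
    if abs(a0) < min_decay_fraction * scale:
        raise FitError(
            f"trace does not decay (amplitude {a0:.3g} vs level {scale:.3g})")

    # log-linear slope over the first decade of |y - C|
    resid0 = np.abs(y - c0)
    mask = resid0 > 0.1 * abs(a0)
    tau0 = None
    if mask.sum() >= 3:
        tt = t0[mask]
        ll = np.log(resid0[mask])
        slope = np.polyfit(tt, ll, 1)[0]
        if slope < 0:
            tau0 = -1.0 / slope
    if tau0 is None or not np.isfinite(tau0):
        tau0 = max((t0[-1] - t0[0]) / 5.0, 1e-3)

    def model(tt, tau, a, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(model, t0, y, p0=[tau0, a0, c0],
                            bounds=([1e-6, -np.inf, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit failed: {exc}") from exc
    resid = float(np.linalg.norm(model(t0, *popt) - y))
    return ExpFit(tau=float(popt[0]), amplitude=float(popt[1]),
                  offset=float(popt[2]), residual_norm=resid)


def fit_double_exp_recovery(t: np.ndarray, frac: np.ndarray,
                            separation_tol: float = 0.05) -> DoubleExpFit:
    """Fit recovered fraction vs recovery time with a double exponential.

    Falls back to a single-exponential when the two time constants
    collapse (ratio within ``separation_tol``) or the double fit fails;
    the result then carries ``degenerate=True`` with
    tau_fast == tau_slow.

    Raises
    ------
    FitError
        Fewer than 5 points, or both fits fail.
    """
    t = np.asarray(t, dtype=float)
    frac = np.asarray(frac, dtype=float)
    if t.size < 5:
        raise FitError(f"recovery fit needs >= 5 time points, got {t.size}")

    def model2(tt, tau_f, tau_s, a_f):
        return 1.0 - a_f * np.exp(-tt / tau_f) - (1.0 - a_f) * np.exp(-tt / tau_s)

    def model1(tt, tau):
        return 1.0 - np.exp(-tt / tau)

    # deterministic init: tau0 from the time to ~63% recovery
    i63 = int(np.argmin(np.abs(frac - 0.632)))
    tau0 = max(float(t[i63]), float(t[t > 0].min()) if np.any(t > 0) else 1.0)

    result = None
    try:
        popt, _ = curve_fit(model2, t, frac,
                            p0=[tau0 / 3.0, tau0 * 3.0, 0.7],
                            bounds=([1e-6, 1e-6, 0.0], [np.inf, np.inf, 1.0]),
                            maxfev=20000)
        tau_f, tau_s, a_f = popt
        if tau_f > tau_s:  # canonical ordering
            tau_f, tau_s, a_f = tau_s, tau_f, 1.0 - a_f
        resid = float(np.linalg.norm(model2(t, *popt) - frac))
        if tau_f / tau_s > 1.0 - separation_tol:
            result = None  # collapsed: treat as degenerate
        else:
            result = DoubleExpFit(tau_fast=float(tau_f), tau_slow=float(tau_s),
                                  frac_fast=float(a_f), residual_norm=resid)
    except (RuntimeError, ValueError):
        result = None

    if result is not None:
        return result

    try:
        popt1, _ = curve_fit(model1, t, frac, p0=[tau0],
                             bounds=([1e-6], [np.inf]), maxfev=10000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"recovery fit failed (double and single): {exc}") from exc
    tau = float(popt1[0])
    resid = float(np.linalg.norm(model1(t, *popt1) - frac))
    return DoubleExpFit(tau_fast=tau, tau_slow=tau, frac_fast=1.0,
                        residual_norm=resid, degenerate=True)
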