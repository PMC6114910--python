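"""Kinematic and energetic metrics of undulatory swimming.

Operates on trajectory records (real simulations or synthetic fixtures):
swimming speed, tailbeat amplitude and frequency, body wavelength, duty
cycle of the activation signal, Strouhal number St = 2fA/U, the
neuromechanical phase-lag profile

    φ_i = (t_act,i − t_curve,i) / (t_act,i+1 − t_act,i),

(positive when the muscle becomes active after peak curvature, i.e. while
shortening), the activation and curvature wave speeds

    v_a = (∂θ/∂t)/(∂θ/∂s),     V = (∂φ_H/∂t)/(∂φ_H/∂s),

where φ_H is the phase of the analytic (Hilbert-transformed) curvature
signal, and the cost of transport

    CoT = (ΣW⁺ + f_neg·Σ|W⁻|) / (T·mass),

positive muscle work plus a fraction of the magnitude of negative work per
cycle, divided by cycle period and body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.signal import hilbert, find_peaks

__all__ = [
    "KinematicsSeries",
    "MetricsReport",
    "swimming_speed",
    "tailbeat_metrics",
    "duty_cycle",
    "phase_lag_profile",
    "wave_speeds",
    "strouhal",
    "cost_of_transport",
    "body_wavelength",
]


@dataclass
class KinematicsSeries:
    """Midline kinematics: time (s), positions (n_t, n_s, 2) in cm, body
    length L (cm).  Tail tip and center of mass are derived on demand."""

    time: np.ndarray
    positions: np.ndarray
    L: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.time.ndim != 1 or self.positions.shape[0] != self.time.size:
            raise ValueError("positions must be (n_t, n_s, 2) matching time")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def com(self) -> np.ndarray:
        return self.positions.mean(axis=1)

    @property
    def tail_y(self) -> np.ndarray:
        return self.positions[:, -1, 1]


@dataclass
class MetricsReport:
    """Flat report of every swimming metric (units in field names' docs).

    speed in L/s, amplitude and wavelength in L, frequency in Hz, duty as a
    fraction, St dimensionless, phase_lag_profile per body position (cycle
    fraction), wavespeed ratio dimensionless, CoT in erg/(s·g) absolute and
    dimensionless when normalized to a control run.
    """

    speed: float | None = None
    amplitude: float | None = None
    frequency: float | None = None
    wavelength: float | None = None
    duty: float | None = None
    strouhal: float | None = None
    wavespeed_ratio: float | None = None
    cot: float | None = None
    cot_normalized: float | None = None

    def recompute_strouhal(self) -> float:
        return strouhal(self.frequency, self.amplitude, self.speed)

    def as_dict(self) -> dict:
        return asdict(self)


def swimming_speed(series: KinematicsSeries, window: tuple = (6.0, 10.0)) -> float:
    """Mean center-of-mass speed over the averaging window, in L/s.

    Measured as net COM displacement over the window divided by its
    duration (the lateral COM wobble within a beat averages out).
    """
    t0, t1 = window
    t = series.time
    if t[0] > t0 + 1e-9 or t[-1] < t1 - 1e-9:
        raise ValueError(f"series does not cover the window {window}")
    com = series.com
    c0 = np.array([np.interp(t0, t, com[:, k]) for k in range(2)])
    c1 = np.array([np.interp(t1, t, com[:, k]) for k in range(2)])
    return float(np.linalg.norm(c1 - c0) / (t1 - t0) / series.L)


def _upward_crossings(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    s = np.signbit(y)
    idx = np.nonzero(s[:-1] & ~s[1:])[0]
    # linear interpolation of the crossing time
    return t[idx] - y[idx] * (t[idx + 1] - t[idx]) / (y[idx + 1] - y[idx])


def tailbeat_metrics(series: KinematicsSeries,
                     window: tuple | None = None) -> tuple[float, float]:
    """(amplitude in L, frequency in Hz) of the tail-tip oscillation.

    The tail transverse signal is detrended (linear fit removed); frequency
    is 1/mean interval between upward zero crossings, amplitude is half the
    mean peak-to-trough excursion per cycle.  Requires at least 3 cycles.
    """
    t = series.time
    y = series.tail_y.copy()
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, y = t[sel], y[sel]
    y = y - np.polyval(np.polyfit(t, y, 1), t)
    crossings = _upward_crossings(t, y)
    if crossings.size >= 5:
        # second pass: subtract the running mean over one estimated period
        # (removes residual drift the global line missed) and crop the
        # half-window boundary artifacts
        period_n = max(3, int(round(np.median(np.diff(crossings))
                                    / np.median(np.diff(t)))))
        if y.size > 3 * period_n:
            kernel = np.ones(period_n) / period_n
            pad = period_n // 2
            ypad = np.pad(y, pad, mode="reflect")
            running = np.convolve(ypad, kernel, "same")[pad:pad + y.size]
            y = y - running
            t, y = t[period_n:-period_n], y[period_n:-period_n]
            crossings = _upward_crossings(t, y)
    if crossings.size < 4:  # 3 full cycles
        raise ValueError("need at least 3 full tailbeat cycles")
    freq = 1.0 / np.median(np.diff(crossings))
    n_per = max(3, int(round((t.size - 1) / crossings.size / 4)))
    peaks, _ = find_peaks(y, distance=n_per)
    troughs, _ = find_peaks(-y, distance=n_per)
    amp = 0.5 * (np.mean(y[peaks]) - np.mean(y[troughs]))
    return float(amp / series.L), float(freq)


def duty_cycle(time: np.ndarray, sigma: np.ndarray, n_cycles: int = 6) -> float:
    """Mean on-fraction per cycle of a binary activation array.

    ``sigma`` has shape (n_t, ...) with segments in trailing axes; cycles
    are delimited by 0→1 onsets of each segment's own signal and the last
    ``n_cycles`` full cycles are averaged, then the mean is taken across
    segments.
    """
    time = np.asarray(time, dtype=float)
    sig = np.asarray(sigma)
    flat = sig.reshape(sig.shape[0], -1)
    if not flat.any():
        raise ValueError("activation signal has no activity")
    duties = []
    for col in range(flat.shape[1]):
        s = flat[:, col].astype(np.int8)
        if s.min() == 1:  # never switches off: duty is exactly 1
            duties.append(1.0)
            continue
        onsets = np.nonzero((s[1:] == 1) & (s[:-1] == 0))[0] + 1
        if onsets.size < 2:
            continue
        use = onsets[-(n_cycles + 1):]
        t_span = time[use[-1]] - time[use[0]]
        if t_span <= 0:
            continue
        i0, i1 = use[0], use[-1]
        # sample counting over an integer number of cycles [onset, onset)
        dt_local = np.diff(time[i0:i1 + 1])
        duties.append(np.sum(s[i0:i1] * dt_local) / t_span)
    if not duties:
        raise ValueError("no segment had enough activation cycles")
    return float(np.mean(duties))


def phase_lag_profile(time: np.ndarray, curvature: np.ndarray,
                      sigma: np.ndarray) -> np.ndarray:
    """Neuromechanical phase lag φ(s) for one body side.

    Parameters
    ----------
    time : (n_t,) sample times.
    curvature : (n_t, n_s) signed midline curvature at each body position;
        the *shortening* sign for the chosen side (peaks of this signal mark
        maximal bending toward that side).
    sigma : (n_t, n_s) binary activation of the same side.

    For each position, each curvature peak is paired with the closest
    activation onset (ties toward the earlier onset) and their time offset
    is normalized by the local onset-to-onset period.  Positions or cycles
    with no matching onset are excluded (NaN).
    """
    time = np.asarray(time, dtype=float)
    kap = np.asarray(curvature, dtype=float)
    sig = np.asarray(sigma)
    n_s = kap.shape[1]
    out = np.full(n_s, np.nan)
    dt_med = np.median(np.diff(time))
    for s in range(n_s):
        col = sig[:, s].astype(np.int8)
        onsets_idx = np.nonzero((col[1:] == 1) & (col[:-1] == 0))[0] + 1
        if onsets_idx.size < 2:
            continue
        t_on = time[onsets_idx]
        periods = np.diff(t_on)
        min_dist = max(1, int(0.5 * np.mean(periods) / dt_med))
        pk, _ = find_peaks(kap[:, s], distance=min_dist)
        if pk.size == 0:
            continue
        lags = []
        for tp in time[pk]:
            d = t_on - tp
            order = np.lexsort((t_on, np.abs(d)))  # ties -> earlier onset
            j = order[0]
            if j >= periods.size:
                j = periods.size - 1
            period = periods[j]
            # a genuine match lies within half a period; peaks whose onset
            # fell outside the series (edges) are excluded
            if np.abs(d[order[0]]) > 0.5 * period:
                continue
            lags.append(d[order[0]] / period)
        if lags:
            out[s] = np.mean(lags)
    return out


def wave_speeds(time: np.ndarray, s: np.ndarray, theta: np.ndarray,
                curvature: np.ndarray, *, s_band: tuple = (0.5, 0.8),
                n_beats: int = 7) -> tuple[float, float, float]:
    """Activation wave speed ⟨v_a⟩, curvature wave speed ⟨V⟩, and their
    ratio ⟨V⟩/⟨v_a⟩.

    ``theta`` (n_t, n_s) are unwrapped oscillator phases mapped to body
    positions ``s`` (same units as desired speed); ``curvature`` (n_t, n_s)
    is the signed curvature.  v_a = θ_t/θ_s by central differences; V uses
    the unwrapped phase of the analytic signal of curvature along time.
    Averages are taken over the arclength band ``s_band`` (fractions of the
    body) and the last ``n_beats`` tail beats.
    """
    time = np.asarray(time, dtype=float)
    s = np.asarray(s, dtype=float)
    if not (np.allclose(np.diff(time), np.diff(time)[0], rtol=1e-6) and
            np.allclose(np.diff(s), np.diff(s)[0], rtol=1e-6)):
        raise ValueError("wave_speeds requires uniform sampling in t and s")
    theta = np.asarray(theta, dtype=float)
    kap = np.asarray(curvature, dtype=float)

    # kinematic phase speed: points of constant phase move at −θ_t/θ_s,
    # positive for a head-to-tail wave (θ decreasing along the body)
    th_t = np.gradient(theta, time, axis=0)
    th_s = np.gradient(theta, s, axis=1)
    va = -th_t / th_s

    phase = np.unwrap(np.angle(hilbert(kap, axis=0)), axis=0)
    # align spatially before differencing along s
    phase = np.unwrap(phase, axis=1)
    ph_t = np.gradient(phase, time, axis=0)
    ph_s = np.gradient(phase, s, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        V = -ph_t / ph_s

    span = s[-1] - s[0]
    band = (s >= s[0] + s_band[0] * span) & (s <= s[0] + s_band[1] * span)
    # estimate beat period from the mean phase rate
    w_mean = np.abs(th_t[:, band]).mean()
    T = 2.0 * np.pi / w_mean
    t_lo = time[-1] - n_beats * T
    tsel = time >= max(t_lo, time[0])
    with np.errstate(invalid="ignore"):
        va_mean = float(np.nanmean(va[np.ix_(tsel, band)]))
        V_sub = V[np.ix_(tsel, band)]
        V_mean = float(np.nanmean(V_sub[np.isfinite(V_sub)]))
    return va_mean, V_mean, V_mean / va_mean


def strouhal(f: float, A: float, U: float) -> float:
    """St = 2fA/U (A and U in consistent units)."""
    if U == 0:
        raise ZeroDivisionError("swimming speed is zero; Strouhal undefined")
    return 2.0 * f * A / U


def body_wavelength(s: np.ndarray, curvature: np.ndarray) -> float:
    """Mean body wavelength (units of s): twice the mean spacing of the
    zero crossings of κ along the body, averaged over time frames."""
    kap = np.asarray(curvature, dtype=float)
    lams = []
    for row in kap:
        sign = np.signbit(row)
        idx = np.nonzero(sign[:-1] != sign[1:])[0]
        if idx.size >= 2:
            z = s[idx] - row[idx] * (s[idx + 1] - s[idx]) / (row[idx + 1] - row[idx])
            lams.append(2.0 * np.mean(np.diff(z)))
    if not lams:
        raise ValueError("no curvature zero crossings found")
    return float(np.mean(lams))


def cost_of_transport(time: np.ndarray, power: np.ndarray, period: float,
                      mass: float, f_neg: float = 0.3,
                      control_cot: float | None = None):
    """Cost of transport from per-segment muscle power.

    ``power`` (n_t, ...) is the instantaneous contractile power −P_c·v_c per
    segment (positive while the active muscle shortens).  Positive work and
    ``f_neg`` times the magnitude of negative work over the last full cycle
    are summed, divided by cycle period and body mass.  When
    ``control_cot`` is given the normalized value is also returned.
    """
    time = np.asarray(time, dtype=float)
    p = np.asarray(power, dtype=float).reshape(time.size, -1)
    t1 = time[-1]
    sel = time >= t1 - period
    if time[sel][0] > t1 - period + (time[1] - time[0]):
        raise ValueError("series shorter than one full cycle")
    tt = time[sel]
    pp = p[sel]
    w_pos = np.trapezoid(np.clip(pp, 0.0, None), tt, axis=0).sum()
    w_neg = np.trapezoid(np.clip(-pp, 0.0, None), tt, axis=0).sum()
    cot = (w_pos + f_neg * w_neg) / (period * mass)
    if control_cot is None:
        return float(cot), None
    if control_cot == 0:
        raise ValueError("control CoT is zero; cannot normalize")
    return float(cot), float(cot / control_cot)
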