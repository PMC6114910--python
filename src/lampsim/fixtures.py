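"""Synthetic traveling-wave kinematics and activation patterns with exact
ground truth.

These fixtures emulate the midline kinematics the closed-loop swimmer
produces — a transverse traveling wave with a smooth amplitude envelope,
superposed on uniform forward translation — so that every analysis metric
(speed, amplitude, frequency, wavelength, duty cycle, phase lag, wave
speeds) can be verified against known generating parameters without running
the fluid solver.  A curvature *driver* variant feeds a prescribed
sinusoidal curvature wave straight into the CPG feedback port for open-loop
entrainment experiments.

All generators are deterministic given the seed of their optional
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lampsim.metrics import KinematicsSeries

__all__ = [
    "WaveSpec",
    "make_traveling_wave",
    "analytic_curvature",
    "make_activation_pattern",
    "make_curvature_driver",
]


@dataclass(frozen=True)
class WaveSpec:
    """Specification of a synthetic traveling body wave.

    frequency in Hz; wavelength in body lengths L; head/tail amplitude of
    the linear envelope in L; translation speed in L/s (along −x, the
    direction opposite the head-to-tail wave); duration in s; n_s midline
    samples and dt sampling interval; optional Gaussian measurement noise
    (cm) with its seed.
    """

    frequency: float = 1.0
    wavelength: float = 0.75
    amp_head: float = 0.02
    amp_tail: float = 0.12
    speed: float = 0.5
    duration: float = 10.0
    n_s: int = 129
    dt: float = 0.01
    L: float = 12.56
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency <= 0 or self.wavelength <= 0:
            raise ValueError("frequency and wavelength must be positive")
        if self.duration < 2.0 / self.frequency:
            raise ValueError("duration must cover at least two cycles")

    @property
    def wave_speed(self) -> float:
        """Phase speed of the body wave, L/s (frequency × wavelength)."""
        return self.frequency * self.wavelength


def _envelope(spec: WaveSpec, s_frac: np.ndarray) -> np.ndarray:
    return (spec.amp_head + (spec.amp_tail - spec.amp_head) * s_frac) * spec.L


def _wave_phase(spec: WaveSpec, s_frac: np.ndarray, t: np.ndarray) -> np.ndarray:
    """2π(f·t − s/Λ) broadcast to (n_t, n_s)."""
    return 2.0 * np.pi * (spec.frequency * t[:, None]
                          - s_frac[None, :] / spec.wavelength)


def make_traveling_wave(spec: WaveSpec) -> KinematicsSeries:
    """Midline y(s,t) = A(s)·sin(2π(ft − s/Λ)) on a translating straight
    backbone.  Returns a KinematicsSeries of shape (n_t, n_s, 2)."""
    t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    s_frac = np.linspace(0.0, 1.0, spec.n_s)
    y = _envelope(spec, s_frac)[None, :] * np.sin(_wave_phase(spec, s_frac, t))
    x = (s_frac * spec.L)[None, :] - spec.speed * spec.L * t[:, None]
    pos = np.stack([np.broadcast_to(x, y.shape), y], axis=-1).copy()
    if spec.noise > 0.0:
        rng = np.random.default_rng(spec.seed)
        pos = pos + rng.normal(0.0, spec.noise, size=pos.shape)
    return KinematicsSeries(time=t, positions=pos, L=spec.L)


def analytic_curvature(spec: WaveSpec, t: np.ndarray,
                       s_frac: np.ndarray) -> np.ndarray:
    """Small-amplitude curvature κ(s,t) ≈ −y_ss of the synthetic wave
    (1/cm), exact for the linearized sinusoid (the envelope's second
    derivative vanishes for the linear envelope)."""
    k = 2.0 * np.pi / (spec.wavelength * spec.L)
    A = _envelope(spec, s_frac)
    phase = _wave_phase(spec, s_frac, t)
    dA = spec.amp_tail - spec.amp_head  # dA/ds, envelope linear in arclength
    # y = A(s)·sin φ with φ_s = −k and A″ = 0:
    # y_ss = 2A′φ_s·cos φ + A·φ_s²·(−sin φ); κ ≈ y_ss for a flat backbone,
    # positive toward +y (the right side)
    return -2.0 * dA * k * np.cos(phase) - A[None, :] * k ** 2 * np.sin(phase)


def make_activation_pattern(spec: WaveSpec, duty: float, lag_profile,
                            t: np.ndarray | None = None,
                            s_frac: np.ndarray | None = None) -> np.ndarray:
    """Binary activation (n_t, n_s) for the *right* side of the body.

    Onsets are offset from the local curvature peaks by
    ``lag_profile(s_frac)`` cycle fractions (positive = onset after the
    peak, the muscle turning on while already shortening).  Curvature peaks
    of κ ≈ y_ss: rightward bending (κ > 0) peaks where sin(phase) = +1.
    """
    if not 0.0 < duty < 1.0:
        raise ValueError("duty must lie in (0, 1)")
    if t is None:
        t = np.arange(0.0, spec.duration + 0.5 * spec.dt, spec.dt)
    if s_frac is None:
        s_frac = np.linspace(0.0, 1.0, spec.n_s)
    lag = np.asarray(lag_profile(s_frac), dtype=float)
    # κ(φ) = −(A k²·sin φ + 2A′k·cos φ) = −R·sin(φ + ψ): the curvature
    # maximum sits at φ = 3π/2 − ψ, with ψ the envelope-slope phase shift
    k = 2.0 * np.pi / (spec.wavelength * spec.L)
    A = _envelope(spec, s_frac)
    dA = spec.amp_tail - spec.amp_head
    psi = np.arctan2(2.0 * dA * k, A * k ** 2)
    peak_cycles = 0.75 - psi / (2.0 * np.pi)
    phase = _wave_phase(spec, s_frac, t) / (2.0 * np.pi)  # in cycles
    x = phase - peak_cycles[None, :] - lag[None, :]
    frac = x - np.floor(x)
    return (frac < duty).astype(np.int8)


def make_curvature_driver(spec: WaveSpec, kappa_amp: float,
                          n_osc: int):
    """Prescribed per-oscillator curvature wave κ_i(t) for open-loop CPG
    entrainment tests.

    Returns a function ``driver(t) -> (n_osc,) array`` giving the signed
    curvature (1/cm) at each oscillator position at time ``t``:
    κ_i(t) = κ₀·sin(2π(f·t − s_i/Λ)).
    """
    s_frac = (np.arange(n_osc) + 0.5) / n_osc

    def driver(t: float) -> np.ndarray:
        return kappa_amp * np.sin(2.0 * np.pi * (
            spec.frequency * t - s_frac / spec.wavelength))

    return driver
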