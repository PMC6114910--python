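"""Proprioceptive curvature feedback from midline shape to the CPG.

Edge cells — intraspinal stretch receptors — sense local body bending and
feed it back additively into the phase dynamics.  Two functional forms are
modeled:

* magnitude feedback (M):  η(κ_i) = η_m·|κ_i|, identical on both sides;
* directional feedback (D): η(κ_i) = (−1)^k·η_d·κ_i with k = 1 on the left
  and k = 2 on the right, so a rightward bend (positive curvature) with
  η_d > 0 excites the right chain and inhibits the left.

Curvature is the planar signed curvature of the midline,

    κ = (x′y″ − y′x″) / ((x′)² + (y′)²)^{3/2},

computed with central finite differences in the spatial parameterization.
Sign convention: positive κ bends toward the animal's right side, which this
package places at +y when the body lies along +x, head first.  Curvature is
boxcar-smoothed over segments i−5…i+5, and the last few tail segments
receive no input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeedbackConfig",
    "CurvatureField",
    "midline_curvature",
    "segment_curvature",
    "smooth_boxcar",
    "feedback_term",
]

#: Documented gain ranges (cm·rad/s) inside which phase velocities remain
#: positive and a realistic activation wave is sustained.
MAGNITUDE_GAIN_RANGE = 0.09
DIRECTIONAL_GAIN_RANGE = 20.0


@dataclass(frozen=True)
class FeedbackConfig:
    """Feedback mode and gain.

    mode : {"none", "magnitude", "directional"}
    gain : float
        η_m or η_d in cm·rad/s (κ carries 1/cm, so η·κ lands in rad/s).
    smooth_halfwidth : int
        Boxcar half-width in oscillator segments (the ±5 of the model).
    tail_silent_segments : int
        Trailing segments that receive no curvature input.
    """

    mode: str = "none"
    gain: float = 0.0
    smooth_halfwidth: int = 5
    tail_silent_segments: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("none", "magnitude", "directional"):
            raise ValueError(f"unknown feedback mode {self.mode!r}")
        if self.smooth_halfwidth < 0:
            raise ValueError("smooth_halfwidth must be >= 0")

    @property
    def gain_range(self) -> float:
        """Full admissible |gain| for this mode (inf for mode 'none')."""
        if self.mode == "magnitude":
            return MAGNITUDE_GAIN_RANGE
        if self.mode == "directional":
            return DIRECTIONAL_GAIN_RANGE
        return np.inf


@dataclass
class CurvatureField:
    """Signed curvature sampled along the midline (1/cm) with arclength (cm)."""

    kappa: np.ndarray
    arclength: np.ndarray

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.kappa.shape != self.arclength.shape:
            raise ValueError("kappa and arclength must have matching shapes")


def midline_curvature(points: np.ndarray) -> CurvatureField:
    """Signed curvature of an ordered 2D midline polyline.

    Parameters
    ----------
    points : (n, 2) array
        Midline coordinates in cm, ordered head to tail; n ≥ 5 and
        consecutive points distinct.

    Returns
    -------
    CurvatureField
        κ per sample (1/cm, positive toward the right/+y side) and the
        cumulative arclength per sample.

    Derivatives are taken with respect to the cumulative-arclength
    parameterization, which makes the estimate insensitive to non-uniform
    sampling of the same curve.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must have shape (n, 2)")
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 midline points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise ValueError("consecutive midline points must be distinct")
    s = np.concatenate(([0.0], np.cumsum(seg)))
    xp = np.gradient(pts[:, 0], s)
    yp = np.gradient(pts[:, 1], s)
    xpp = np.gradient(xp, s)
    ypp = np.gradient(yp, s)
    denom = (xp ** 2 + yp ** 2) ** 1.5
    kappa = (xp * ypp - yp * xpp) / denom
    return CurvatureField(kappa=kappa, arclength=s)


def smooth_boxcar(values: np.ndarray, halfwidth: int) -> np.ndarray:
    """Mean over a ±halfwidth window, truncated at the array ends."""
    if halfwidth == 0:
        return np.asarray(values, dtype=float).copy()
    v = np.asarray(values, dtype=float)
    n = v.size
    csum = np.concatenate(([0.0], np.cumsum(v)))
    idx = np.arange(n)
    lo = np.maximum(idx - halfwidth, 0)
    hi = np.minimum(idx + halfwidth, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def segment_curvature(field: CurvatureField, config: FeedbackConfig,
                      n_osc: int, *, head_fraction: float = 0.125) -> np.ndarray:
    """Map a midline curvature field to per-oscillator curvatures κ_i.

    The first ``head_fraction`` of the body is the passive head and carries
    no oscillators; oscillator i is assigned the curvature at the arclength
    fraction of its muscle segment midpoint.  The result is boxcar-smoothed
    over ±``config.smooth_halfwidth`` oscillator segments (window truncated
    at the anterior boundary) and the last ``config.tail_silent_segments``
    entries are zeroed.
    """
    if n_osc < 1:
        raise ValueError("n_osc must be positive")
    s = field.arclength
    total = s[-1]
    # midpoints of the n_osc active segments spanning (head_fraction, 1) of
    # the body, expressed as arclength
    frac = head_fraction + (1.0 - head_fraction) * (np.arange(n_osc) + 0.5) / n_osc
    kappa_i = np.interp(frac * total, s, field.kappa)
    kappa_i = smooth_boxcar(kappa_i, config.smooth_halfwidth)
    nz = config.tail_silent_segments
    if nz > 0:
        kappa_i[-nz:] = 0.0
    return kappa_i


def feedback_term(kappa_i: np.ndarray | float, config: FeedbackConfig) -> np.ndarray:
    """Additive CPG input η(κ_i) for both sides, shape (2, n).

    Row 0 is the left side (k = 1), row 1 the right side (k = 2).  In
    magnitude mode both rows equal η_m·|κ|; in directional mode the right
    side receives +η_d·κ and the left side −η_d·κ ((−1)^k with k = 1 left,
    k = 2 right).
    """
    kappa = np.atleast_1d(np.asarray(kappa_i, dtype=float))
    if config.mode == "none":
        return np.zeros((2, kappa.size))
    if config.mode == "magnitude":
        row = config.gain * np.abs(kappa)
        return np.stack([row, row])
    if config.mode == "directional":
        right = config.gain * kappa
        return np.stack([-right, right])
    raise ValueError(f"unknown feedback mode {config.mode!r}")
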