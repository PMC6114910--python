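"""Central pattern generator: a double chain of coupled phase oscillators.

The lamprey CPG is modeled as two chains (left and right body side) of ``n``
phase oscillators.  Oscillator ``i`` on side ``k`` evolves as

    dθ_{k,i}/dt = ω + Σ_j α_{i,j} sin(θ_{k,j} − θ_{k,i} − ψ_{ij})
                  + α_c sin(θ_{k,i} − θ_{k*,i}) + η(κ_i)

where ``k*`` is the opposite side, ψ_{ij} = (i−j)·ψ̄ is the built-in
intersegmental phase shift, and η(κ_i) is an additive proprioceptive
feedback input supplied per oscillator and per side.  Ipsilateral coupling
strengths decay exponentially with segment distance, with different
amplitudes and length constants for ascending (i−j < 0) and descending
(i−j > 0) connections.

The sign of the contralateral term matters: writing the segment's phase
difference d = θ_1 − θ_2, the pair obeys dd/dt = 2α_c·sin d, whose stable
fixed point is the observed left–right antiphase d = π (an extra +π inside
this sine would instead lock the two sides in phase — sustained
co-contraction — and the alternating activation wave would collapse).

Muscle activation is obtained by thresholding sin θ: a segment is "on"
whenever sin θ ≥ τ, which for a phase advancing at constant rate yields a
duty cycle of (π − 2 arcsin τ)/(2π).

Side convention used throughout the package: index ``0`` (k = 1) is the left
side, index ``1`` (k = 2) is the right side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CPGParams",
    "CPGState",
    "coupling_strength",
    "coupling_matrix",
    "phase_velocity",
    "step_cpg",
    "activation_from_phase",
    "calibrate_threshold",
    "tuned_state",
    "LEFT",
    "RIGHT",
]

LEFT = 0   # k = 1
RIGHT = 1  # k = 2

#: Duty cycle the default activation threshold is calibrated to (the burst
#: proportion of freely swimming lampreys used to tune the control case).
CONTROL_DUTY_CYCLE = 0.36


def calibrate_threshold(duty_target: float) -> float:
    """Activation threshold τ giving ``duty_target`` at constant phase rate.

    For θ(t) = ωt the condition sin θ ≥ τ holds on an arc of measure
    π − 2 arcsin τ per cycle, so τ = cos(π·duty_target) makes the on-fraction
    exactly ``duty_target``.

    Parameters
    ----------
    duty_target : float
        Desired on-fraction per cycle, strictly between 0 and 1.
    """
    if not 0.0 < duty_target < 1.0:
        raise ValueError(f"duty_target must lie in (0, 1), got {duty_target}")
    return float(np.cos(np.pi * duty_target))


@dataclass(frozen=True)
class CPGParams:
    """Parameters of the double oscillator chain.

    Attributes
    ----------
    omega : float
        Natural frequency ω in rad/s.
    A_asc, A_desc : float
        Amplitudes of the ascending/descending ipsilateral coupling, rad/s.
    lambda_asc, lambda_desc : float
        Exponential decay lengths of the coupling, in segments.
    alpha_c : float
        Contralateral coupling strength, rad/s (ten times the strongest
        descending connection in the default parameter set).
    psi_bar : float
        Intersegmental phase shift ψ̄, rad; ψ_{ij} = (i−j)·ψ̄.
    n_seg : int
        Number of oscillators per side.
    tau : float
        Activation threshold applied to sin θ.
    """

    omega: float = 2.0 * np.pi
    A_asc: float = 1.0
    A_desc: float = 10.0
    lambda_asc: float = 40.0
    lambda_desc: float = 5.0
    alpha_c: float = 81.87
    psi_bar: float = 2.0 * np.pi / 280.0
    n_seg: int = 280
    tau: float = field(default_factory=lambda: calibrate_threshold(CONTROL_DUTY_CYCLE))

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.n_seg < 2:
            raise ValueError("n_seg must be at least 2")
        if not -1.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (-1, 1)")
        if self.lambda_asc <= 0 or self.lambda_desc <= 0:
            raise ValueError("coupling decay lengths must be positive")

    def with_segments(self, n_seg: int) -> "CPGParams":
        """Copy with a different chain length, rescaling ψ̄ so the chain
        still carries one full activation wave (ψ̄ = 2π/n_seg)."""
        return replace(self, n_seg=n_seg, psi_bar=2.0 * np.pi / n_seg)


@dataclass
class CPGState:
    """Phases of the double chain, shape (2, n_seg), stored unwrapped."""

    theta: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != 2:
            raise ValueError("theta must have shape (2, n_seg)")
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("phases must be finite")

    def copy(self) -> "CPGState":
        return CPGState(self.theta.copy(), self.time)


def tuned_state(params: CPGParams, *, perturbation: float = 0.0,
                rng: np.random.Generator | None = None) -> CPGState:
    """Traveling-wave initial condition at which the chain is a relative
    equilibrium: ipsilateral neighbors offset by ψ̄ and the two sides in
    antiphase, so every sine term in the phase dynamics vanishes.

    ``perturbation`` adds uniform random phase noise of that half-width
    (rad) to probe robustness of the steady pattern.
    """
    i = np.arange(params.n_seg, dtype=float)
    theta = np.empty((2, params.n_seg))
    theta[LEFT] = -i * params.psi_bar
    theta[RIGHT] = -i * params.psi_bar + np.pi
    if perturbation:
        rng = np.random.default_rng() if rng is None else rng
        theta += rng.uniform(-perturbation, perturbation, size=theta.shape)
    return CPGState(theta)


def coupling_strength(i: int, j: int, params: CPGParams) -> float:
    """Ipsilateral coupling strength α_{i,j} (rad/s) between oscillators
    ``i`` and ``j`` (1-based, as segments are numbered head to tail).

    Ascending connections (i−j < 0) use amplitude ``A_asc`` and decay length
    ``lambda_asc``; descending (i−j > 0) use ``A_desc``/``lambda_desc``.
    Self-coupling is zero.
    """
    n = params.n_seg
    if not (1 <= i <= n and 1 <= j <= n):
        raise IndexError(f"oscillator indices must lie in [1, {n}], got ({i}, {j})")
    if i == j:
        return 0.0
    d = abs(i - j)
    if i < j:
        return params.A_asc * np.exp(-d / params.lambda_asc)
    return params.A_desc * np.exp(-d / params.lambda_desc)


def coupling_matrix(params: CPGParams) -> np.ndarray:
    """Dense matrix α_{i,j} over the whole chain (zero diagonal)."""
    idx = np.arange(params.n_seg)
    diff = idx[:, None] - idx[None, :]  # i - j, 0-based == 1-based difference
    d = np.abs(diff)
    asc = params.A_asc * np.exp(-d / params.lambda_asc)
    desc = params.A_desc * np.exp(-d / params.lambda_desc)
    alpha = np.where(diff < 0, asc, desc)
    np.fill_diagonal(alpha, 0.0)
    return alpha


class _CouplingOperator:
    """Precomputed complex form of the ipsilateral coupling sum.

    Σ_j α_{i,j} sin(θ_j − θ_i − ψ_{ij}) = Im[ e^{−iθ_i} (M z)_i ],
    with M_{ij} = α_{i,j} e^{−i ψ_{ij}} and z_j = e^{i θ_j}; evaluating the
    sum costs one complex matrix-vector product instead of an n×n sine grid.
    """

    def __init__(self, params: CPGParams) -> None:
        alpha = coupling_matrix(params)
        idx = np.arange(params.n_seg)
        psi = (idx[:, None] - idx[None, :]) * params.psi_bar
        self.M = alpha * np.exp(-1j * psi)

    def __call__(self, theta_side: np.ndarray) -> np.ndarray:
        z = np.exp(1j * theta_side)
        return np.imag(np.conj(z) * (self.M @ z))


_OPERATOR_CACHE: dict[tuple, _CouplingOperator] = {}


def _coupling_operator(params: CPGParams) -> _CouplingOperator:
    key = (params.n_seg, params.A_asc, params.A_desc,
           params.lambda_asc, params.lambda_desc, params.psi_bar)
    op = _OPERATOR_CACHE.get(key)
    if op is None:
        op = _OPERATOR_CACHE[key] = _CouplingOperator(params)
        if len(_OPERATOR_CACHE) > 32:  # bound the cache for sweeps
            _OPERATOR_CACHE.pop(next(iter(_OPERATOR_CACHE)))
    return op


def phase_velocity(state: CPGState, feedback: np.ndarray | float,
                   params: CPGParams) -> np.ndarray:
    """Right-hand side dθ/dt of the double chain, shape (2, n_seg).

    ``feedback`` is the additive per-oscillator, per-side input η(κ_i) in
    rad/s (broadcastable to theta's shape).
    """
    theta = state.theta
    fb = np.broadcast_to(np.asarray(feedback, dtype=float), theta.shape)
    op = _coupling_operator(params)
    dtheta = np.empty_like(theta)
    for k in (LEFT, RIGHT):
        dtheta[k] = params.omega + op(theta[k])
    # contralateral term: stabilizes left-right antiphase (see module note)
    cross = params.alpha_c * np.sin(theta[LEFT] - theta[RIGHT])
    dtheta[LEFT] += cross
    dtheta[RIGHT] -= cross  # sin is odd: sin(θ_R − θ_L) = −sin(θ_L − θ_R)
    return dtheta + fb


def step_cpg(state: CPGState, feedback: np.ndarray | float, dt: float,
             params: CPGParams) -> CPGState:
    """Advance the chain one step of classical RK4 with feedback held fixed.

    Deterministic given state and feedback; raises if any phase becomes
    non-finite (naming the first offending oscillator).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    th0 = state.theta

    def rhs(th: np.ndarray) -> np.ndarray:
        return phase_velocity(CPGState(th, state.time), feedback, params)

    k1 = rhs(th0)
    k2 = rhs(th0 + 0.5 * dt * k1)
    k3 = rhs(th0 + 0.5 * dt * k2)
    k4 = rhs(th0 + dt * k3)
    theta = th0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(theta)):
        k, i = np.argwhere(~np.isfinite(theta))[0]
        raise FloatingPointError(
            f"non-finite phase after step at side {k}, oscillator {i}")
    return CPGState(theta, state.time + dt)


def activation_from_phase(state: CPGState, tau: float) -> np.ndarray:
    """Binary activation σ per side per oscillator: 1 where sin θ ≥ τ."""
    return (np.sin(state.theta) >= tau).astype(np.int8)
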