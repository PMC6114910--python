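"""Calcium-activated Hill-type muscle for the lateral body segments.

Each lateral segment carries a muscle unit with three coupled parts:

1. *Calcium kinetics* gated by the binary CPG signal σ: free calcium C_f is
   released from the sarcoplasmic reticulum while σ = 1 and resequestered
   while σ = 0; bound calcium C_b on the myofibrils drives contraction:

       dC_f/dt = (k4·C_b − k3·C_f)(1 − C_b) + k1(C − C_f − C_b)
                 + k2·C_f·(C − S − C_f − C_b)
       dC_b/dt = −(k4·C_b − k3·C_f)(1 − C_b)

   with k1 = σ·k̄1, k2 = (1−σ)·k̄2, k3 = k̄3·m, k4 = k̄4·m.

2. *Work-dependent deactivation*: the variable m integrates mechanical work
   done during loaded shortening and relaxes back to 1 otherwise:

       dm/dt = −k_m1·P_c·v_c   (v_c < 0),    dm/dt = −k_m2·(m − 1)  (v_c ≥ 0)

   where P_c here is the contractile force normalized by the segment's
   maximal force so m stays O(1).

3. *Hill-type force generation*: a contractile element (CE) in series with
   an elastic stretch element (SE).  The CE force is

       P_c = P0 · α(v_c) · λ(l_c) · C_b,

   scaled by the taper factor (ratio of local to maximal cross-sectional
   area, elliptical cross-sections ⇒ area ∝ width²).  The exact shapes of
   α and λ are configurable; the defaults are a standard Hill hyperbola in
   shortening with a shallow capped linear branch in lengthening, and a
   quadratic length–tension curve, both normalized to 1 at (v_c = 0,
   l_c = rest).

Sign convention (stated here because it fixes the behaviour of the work
variable): **shortening is v_c < 0**, so −k_m1·P_c·v_c > 0 and m grows while
the active muscle shortens under load.

The skin is a tension-only spring along the same segment, resisting
extension beyond rest length but not compression.  A passive segment
stiffness scaled by bound calcium (calcium-dependent passive stiffness) can
be switched on; it is on by default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MuscleParams",
    "CalciumMuscleState",
    "rate_constants",
    "calcium_derivatives",
    "work_deactivation_derivative",
    "force_velocity",
    "force_length",
    "contractile_force",
    "taper_factor",
    "MuscleBank",
]


@dataclass(frozen=True)
class MuscleParams:
    """Parameters of the calcium/Hill muscle unit (cgs units, rates in 1/s).

    The calcium pool sizes are dimensionless (normalized by the number of
    binding sites) and must satisfy S > C > 1 so the muscle can fully
    activate and the calcium can fully resequester within a cycle.
    """

    kbar1: float = 8.0      # SR release rate while active
    kbar2: float = 25.0     # resequestration rate while inactive
    kbar3: float = 45.0     # binding rate scale (× m)
    kbar4: float = 30.0     # unbinding rate scale (× m)
    km1: float = 1.0        # work-deactivation gain (normalized force × cm/s)
    km2: float = 5.0        # recovery rate of m toward 1
    Ctot: float = 2.0       # total calcium C
    Ssites: float = 6.0     # sequestering sites S
    P0: float = 4.0e4       # maximal contractile force, dyn
    v_max: float = 8.0      # max shortening speed of the CE, cm/s
    a_hill: float = 0.25    # curvature of the Hill hyperbola
    len_slope: float = 0.5  # lengthening branch slope of α
    alpha_max: float = 1.5  # cap of α in lengthening
    lam_width: float = 0.4  # relative length deviation at which λ reaches 0
    se_strain: float = 0.05  # SE strain under P0 (sets series stiffness)
    se_rate: float = 200.0   # k_se / c_se, 1/s (slow relaxation rate)
    junction_rate: float = 4000.0  # c_se / μ, 1/s (fast overdamped rate)
    ce_fraction: float = 0.5  # fraction of segment rest length taken by CE
    k_skin: float = 2.0e4    # skin spring stiffness, dyn/cm per unit strain
    k_passive_ca: float = 1.0e4  # calcium-scaled passive stiffness, dyn/cm
    passive_ca: bool = True  # calcium-dependent passive stiffness flag

    def __post_init__(self) -> None:
        if not self.Ssites > self.Ctot > 1.0:
            raise ValueError("require S > C > 1 for the calcium pools")
        for name in ("kbar1", "kbar2", "kbar3", "kbar4", "km1", "km2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be nonnegative")

    def replace(self, **kw) -> "MuscleParams":
        return replace(self, **kw)


@dataclass
class CalciumMuscleState:
    """Per-segment muscle state arrays (any common shape, e.g. (2, n)).

    Cf, Cb, m are dimensionless; lc is the CE length in cm and vc its rate
    of change in cm/s (negative while shortening).
    """

    Cf: np.ndarray
    Cb: np.ndarray
    m: np.ndarray
    lc: np.ndarray
    vc: np.ndarray

    @classmethod
    def resting(cls, shape: tuple, lc_rest: np.ndarray | float) -> "CalciumMuscleState":
        z = np.zeros(shape)
        return cls(Cf=z.copy(), Cb=z.copy(), m=np.ones(shape),
                   lc=np.broadcast_to(np.asarray(lc_rest, float), shape).copy(),
                   vc=z.copy())

    def copy(self) -> "CalciumMuscleState":
        return CalciumMuscleState(self.Cf.copy(), self.Cb.copy(), self.m.copy(),
                                  self.lc.copy(), self.vc.copy())


def rate_constants(sigma, m, params: MuscleParams):
    """Gated rates (k1, k2, k3, k4): k1 = σ·k̄1, k2 = (1−σ)·k̄2,
    k3 = k̄3·m, k4 = k̄4·m."""
    sigma = np.asarray(sigma, dtype=float)
    m = np.asarray(m, dtype=float)
    return (sigma * params.kbar1, (1.0 - sigma) * params.kbar2,
            params.kbar3 * m, params.kbar4 * m)


def calcium_derivatives(Cf, Cb, sigma, m, params: MuscleParams):
    """(dC_f/dt, dC_b/dt) of the mass-action calcium model."""
    k1, k2, k3, k4 = rate_constants(sigma, m, params)
    exchange = (k4 * Cb - k3 * Cf) * (1.0 - Cb)
    dCf = (exchange + k1 * (params.Ctot - Cf - Cb)
           + k2 * (Cf * (params.Ctot - params.Ssites - Cf - Cb)))
    dCb = -exchange
    return dCf, dCb


def work_deactivation_derivative(m, Pc_norm, vc, params: MuscleParams):
    """dm/dt: −k_m1·P_c·v_c while shortening (v_c < 0), relaxation
    −k_m2·(m − 1) otherwise.  ``Pc_norm`` is the contractile force
    normalized by the segment's maximal force."""
    m = np.asarray(m, dtype=float)
    vc = np.asarray(vc, dtype=float)
    Pc_norm = np.asarray(Pc_norm, dtype=float)
    shortening = vc < 0.0
    return np.where(shortening, -params.km1 * Pc_norm * vc,
                    -params.km2 * (m - 1.0))


def force_velocity(vc, params: MuscleParams):
    """Normalized Hill force–velocity curve α(v_c), α(0) = 1.

    Shortening (v_c < 0): hyperbolic drop to 0 at |v_c| = v_max.
    Lengthening (v_c > 0): shallow linear rise capped at alpha_max.
    """
    vc = np.asarray(vc, dtype=float)
    vhat = vc / params.v_max
    with np.errstate(divide="ignore", invalid="ignore"):
        short = (1.0 + vhat) / (1.0 - vhat / params.a_hill)  # vhat in [-1, 0]
    short = np.clip(np.nan_to_num(short, nan=0.0, posinf=0.0, neginf=0.0),
                    0.0, 1.0)
    length = np.minimum(1.0 + params.len_slope * vhat, params.alpha_max)
    return np.where(vhat < 0.0, short, length)


def force_length(lc, lc_rest, params: MuscleParams):
    """Normalized length–tension curve λ(l_c): quadratic with λ = 1 at rest
    and λ = 0 at |l_c − rest|/rest = lam_width."""
    lc = np.asarray(lc, dtype=float)
    strain = (lc - lc_rest) / lc_rest
    return np.clip(1.0 - (strain / params.lam_width) ** 2, 0.0, None)


def contractile_force(vc, lc, Cb, taper, params: MuscleParams,
                      lc_rest=None):
    """Contractile force P_c = P0·α(v_c)·λ(l_c)·C_b, scaled by the taper
    factor (local/maximal cross-sectional area)."""
    if lc_rest is None:
        lc_rest = params.ce_fraction  # interpreted as rest length directly
    return (params.P0 * np.asarray(taper, float) * force_velocity(vc, params)
            * force_length(lc, lc_rest, params) * np.asarray(Cb, float))


def taper_factor(widths: np.ndarray) -> np.ndarray:
    """Taper factor per segment from the local body width profile.

    With elliptical out-of-plane cross-sections, area ∝ width², so the
    factor is (w / w_max)².
    """
    w = np.asarray(widths, dtype=float)
    return (w / w.max()) ** 2


class MuscleBank:
    """Vectorized bank of muscle units for the active lateral segments.

    One unit per (side, segment).  The CE/SE pair is integrated with the
    same fixed-step RK4 as the calcium ODEs: the SE is a spring–damper and
    the CE/SE junction carries a small mass chosen so the pair is strongly
    overdamped (the body itself is massless; the junction mass is a
    numerical regularization, sized via ``junction_rate``).

    Parameters
    ----------
    rest_lengths : (n,) array
        Rest length of each active lateral segment, cm.
    tapers : (n,) array
        Taper factor per segment (dimensionless area ratio).
    params : MuscleParams
    """

    def __init__(self, rest_lengths: np.ndarray, tapers: np.ndarray,
                 params: MuscleParams) -> None:
        self.params = params
        self.l_rest = np.asarray(rest_lengths, dtype=float)
        self.taper = np.asarray(tapers, dtype=float)
        n = self.l_rest.size
        self.lc_rest = params.ce_fraction * self.l_rest
        self.lse_rest = (1.0 - params.ce_fraction) * self.l_rest
        self.P0_seg = params.P0 * self.taper          # (n,)
        # series stiffness: SE stretches by se_strain·l_rest under P0_seg
        self.k_se = self.P0_seg / (params.se_strain * self.l_rest)
        self.c_se = self.k_se / params.se_rate
        self.mu = self.c_se / params.junction_rate
        self.state = CalciumMuscleState.resting((2, n), self.lc_rest)

    # ---- dynamics ----------------------------------------------------

    def _derivs(self, st: CalciumMuscleState, sigma: np.ndarray,
                ls: np.ndarray):
        p = self.params
        dCf, dCb = calcium_derivatives(st.Cf, st.Cb, sigma, st.m, p)
        Pc = (self.P0_seg * force_velocity(st.vc, p)
              * force_length(st.lc, self.lc_rest, p) * st.Cb)
        dm = work_deactivation_derivative(st.m, Pc / self.P0_seg, st.vc, p)
        Tse = self.k_se * (ls - st.lc - self.lse_rest)
        dvc = (Tse - Pc - self.c_se * st.vc) / self.mu
        return dCf, dCb, dm, st.vc, dvc, Pc, Tse

    def step(self, sigma: np.ndarray, seg_lengths: np.ndarray, dt: float):
        """Advance all units one RK4 step.

        Parameters
        ----------
        sigma : (2, n) binary activation.
        seg_lengths : (2, n) current lateral segment lengths, cm.
        dt : timestep, s.

        Returns
        -------
        tension : (2, n) array
            Total axial tension each segment exerts on its endpoints
            (positive pulls the endpoints together): tapered SE tension,
            plus tension-only skin, plus the optional C_b-scaled passive
            stiffness.
        Pc : (2, n) array
            Contractile-element force after the step (for work accounting).
        """
        st = self.state
        sigma = np.asarray(sigma, dtype=float)
        ls = np.asarray(seg_lengths, dtype=float)

        def rhs(y):
            tmp = CalciumMuscleState(*y)
            d = self._derivs(tmp, sigma, ls)
            return d[:5]

        y0 = (st.Cf, st.Cb, st.m, st.lc, st.vc)
        k1 = rhs(y0)
        k2 = rhs(tuple(y + 0.5 * dt * k for y, k in zip(y0, k1)))
        k3 = rhs(tuple(y + 0.5 * dt * k for y, k in zip(y0, k2)))
        k4 = rhs(tuple(y + dt * k for y, k in zip(y0, k3)))
        ynew = tuple(y + (dt / 6.0) * (a + 2 * b + 2 * c + d)
                     for y, a, b, c, d in zip(y0, k1, k2, k3, k4))
        self.state = CalciumMuscleState(*[np.asarray(v) for v in ynew])
        st = self.state

        p = self.params
        Pc = (self.P0_seg * force_velocity(st.vc, p)
              * force_length(st.lc, self.lc_rest, p) * st.Cb)
        Tse = self.k_se * (ls - st.lc - self.lse_rest)
        tension = Tse * 1.0  # SE stiffness already carries the taper via P0_seg
        # tension-only skin: resists extension beyond rest length only
        stretch = ls - self.l_rest
        tension = tension + p.k_skin * np.clip(stretch, 0.0, None) / self.l_rest
        if p.passive_ca:
            tension = tension + p.k_passive_ca * st.Cb * stretch / self.l_rest
        if not np.all(np.isfinite(tension)):
            k, i = np.argwhere(~np.isfinite(tension))[0]
            raise FloatingPointError(
                f"non-finite muscle force at side {k}, segment {i}")
        return tension, Pc

    def stable_dt(self) -> float:
        """RK4 stability bound set by the fastest (junction) mode."""
        return 2.7 / float(self.params.junction_rate)


def endpoint_forces(tension: np.ndarray, p_head: np.ndarray,
                    p_tail: np.ndarray):
    """Equal-and-opposite axial endpoint forces for segment tensions.

    Positive tension pulls the endpoints together.  Returns (F_head,
    F_tail) with F_head + F_tail = 0 per segment.

    ``p_head``/``p_tail`` are (..., 2) endpoint coordinate arrays matching
    the shape of ``tension``.
    """
    d = p_tail - p_head
    ln = np.linalg.norm(d, axis=-1, keepdims=True)
    if np.any(ln == 0.0):
        raise ValueError("zero-length muscle segment")
    u = d / ln
    F_head = np.asarray(tension)[..., None] * u
    return F_head, -F_head
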