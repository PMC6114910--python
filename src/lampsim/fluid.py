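"""2D incompressible Navier–Stokes on a periodic staggered grid, coupled to
the body through the immersed boundary method, plus a fast resistive backend.

The fluid obeys

    ρ (∂u/∂t + u·∇u) = −∇p + μ∇²u + f,    ∇·u = 0,

with the Eulerian force density f obtained by spreading the Lagrangian body
forces with a regularized delta function, and body points advected at the
locally interpolated fluid velocity (no-slip):

    f(x) = Σ_l F_l δ_h(x − X_l) Δs_l,      dX_l/dt = Σ_cells u δ_h(x − X_l) h².

δ_h is the classical 4-point cosine-free kernel (compact support 4h, even,
satisfying the zeroth- and first-moment conditions), which makes spreading
and interpolation exact adjoints of one another.

The solver is a classical projection method on a MAC grid: explicit
conservative central advection, Crank–Nicolson diffusion and the pressure
projection both solved spectrally (the domain is periodic; the no-stress
walls of the reference setup are approximated by a large domain — a
documented fidelity caveat).

The *resistive* backend replaces the fluid by a local anisotropic drag law
mapping node force to node velocity.  It exists to exercise the closed
sensorimotor loop cheaply; it does not produce trustworthy hydrodynamic
forces and is never used for hydrodynamic quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluidState",
    "DomainConfig",
    "discrete_delta",
    "spread_forces",
    "interpolate_velocity",
    "navier_stokes_step",
    "discrete_divergence",
    "resistive_velocities",
]

MPAS_TO_CGS = 0.01  # 1 mPa·s = 0.01 g/(cm·s)


@dataclass(frozen=True)
class DomainConfig:
    """Rectangular periodic fluid domain.

    Defaults follow the reference setup: 7.5 body lengths long by 3.0 body
    lengths high, with the resolution expressed as cells across the domain
    length.
    """

    Lx: float
    Ly: float
    nx: int
    rho: float = 1.0            # g/cm^3
    mu: float = MPAS_TO_CGS     # 1 mPa·s in cgs

    @property
    def h(self) -> float:
        return self.Lx / self.nx

    @property
    def ny(self) -> int:
        return int(round(self.Ly / self.h))


@dataclass
class FluidState:
    """MAC-grid velocity field: u at x-faces, v at y-faces, shape (nx, ny).

    u[i, j] sits at (i·h, (j+½)·h), v[i, j] at ((i+½)·h, j·h).
    """

    u: np.ndarray
    v: np.ndarray
    domain: DomainConfig
    time: float = 0.0

    @classmethod
    def at_rest(cls, domain: DomainConfig) -> "FluidState":
        shape = (domain.nx, domain.ny)
        return cls(np.zeros(shape), np.zeros(shape), domain)

    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max(), 0.0))


# ---------------------------------------------------------------------------
# regularized delta function
# ---------------------------------------------------------------------------

def discrete_delta(r):
    """1D weight function φ(r) of the 4-point immersed boundary kernel.

    Support |r| < 2 (grid units); even; Σ_j φ(r − j) = 1 and
    Σ_j (j − r)·φ(r − j) = 0 for every r.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    near = r <= 1.0
    mid = (r > 1.0) & (r < 2.0)
    rn = r[near]
    out[near] = (3.0 - 2.0 * rn + np.sqrt(1.0 + 4.0 * rn - 4.0 * rn ** 2)) / 8.0
    rm = r[mid]
    out[mid] = (5.0 - 2.0 * rm - np.sqrt(-7.0 + 12.0 * rm - 4.0 * rm ** 2)) / 8.0
    return out


def _stencil(pos: np.ndarray, h: float, n: int, offset: float):
    """Indices (n_pts, 4) and weights for the 4-point kernel along one axis.

    ``offset`` is the grid-line offset of the target points in units of h
    (0 for face-aligned, 0.5 for cell-centered coordinates).
    """
    g = pos / h - offset
    base = np.floor(g).astype(int)
    idx = base[:, None] + np.arange(-1, 3)[None, :]
    w = discrete_delta(g[:, None] - idx)
    return idx % n, w


def spread_forces(forces: np.ndarray, positions: np.ndarray, ds: np.ndarray,
                  domain: DomainConfig):
    """Spread Lagrangian forces (dyn) to Eulerian force densities (dyn/cm³
    per unit depth → dyn/cm² in 2D) on the staggered faces.

    Conservative: h²·Σ_cells f equals Σ_l F_l·Δs_l... with ds absorbed the
    total Eulerian force equals the total Lagrangian force.
    """
    pos = np.asarray(positions, dtype=float)
    F = np.asarray(forces, dtype=float)
    ds = np.broadcast_to(np.asarray(ds, dtype=float), pos.shape[0])
    h, nx, ny = domain.h, domain.nx, domain.ny
    if not (np.all(np.isfinite(pos))):
        raise ValueError("body node positions must be finite")
    fu = np.zeros((nx, ny))
    fv = np.zeros((nx, ny))
    # x-faces at (i·h, (j+1/2)h)
    ix, wx = _stencil(pos[:, 0], h, nx, 0.0)
    iy, wy = _stencil(pos[:, 1], h, ny, 0.5)
    amp = (F[:, 0] * ds) / h ** 2
    np.add.at(fu, (ix[:, :, None], iy[:, None, :]),
              amp[:, None, None] * wx[:, :, None] * wy[:, None, :])
    # y-faces at ((i+1/2)h, j·h)
    ix, wx = _stencil(pos[:, 0], h, nx, 0.5)
    iy, wy = _stencil(pos[:, 1], h, ny, 0.0)
    amp = (F[:, 1] * ds) / h ** 2
    np.add.at(fv, (ix[:, :, None], iy[:, None, :]),
              amp[:, None, None] * wx[:, :, None] * wy[:, None, :])
    return fu, fv


def interpolate_velocity(state: FluidState, positions: np.ndarray) -> np.ndarray:
    """Interpolate the staggered velocity field to body points (no-slip)."""
    pos = np.asarray(positions, dtype=float)
    d = state.domain
    h, nx, ny = d.h, d.nx, d.ny
    out = np.empty_like(pos)
    ix, wx = _stencil(pos[:, 0], h, nx, 0.0)
    iy, wy = _stencil(pos[:, 1], h, ny, 0.5)
    out[:, 0] = np.sum(state.u[ix[:, :, None], iy[:, None, :]]
                       * wx[:, :, None] * wy[:, None, :], axis=(1, 2))
    ix, wx = _stencil(pos[:, 0], h, nx, 0.5)
    iy, wy = _stencil(pos[:, 1], h, ny, 0.0)
    out[:, 1] = np.sum(state.v[ix[:, :, None], iy[:, None, :]]
                       * wx[:, :, None] * wy[:, None, :], axis=(1, 2))
    return out


# ---------------------------------------------------------------------------
# projection solver
# ---------------------------------------------------------------------------

def _advection(u, v, h):
    """Conservative central advection terms at the u- and v-faces."""
    # u at centers (i+1/2, j+1/2-ish): average along x
    u_c = 0.5 * (u + np.roll(u, -1, axis=0))          # at cell centers (x)
    duu_dx = (u_c ** 2 - np.roll(u_c ** 2, 1, axis=0)) / h
    # corner values at (i, j)
    u_corner = 0.5 * (u + np.roll(u, 1, axis=1))
    v_corner = 0.5 * (v + np.roll(v, 1, axis=0))
    uv = u_corner * v_corner
    duv_dy = (np.roll(uv, -1, axis=1) - uv) / h
    adv_u = duu_dx + duv_dy

    v_c = 0.5 * (v + np.roll(v, -1, axis=1))
    dvv_dy = (v_c ** 2 - np.roll(v_c ** 2, 1, axis=1)) / h
    duv_dx = (np.roll(uv, -1, axis=0) - uv) / h
    adv_v = dvv_dy + duv_dx
    return adv_u, adv_v


class _SpectralOps:
    """Cached FFT symbols of the staggered difference operators."""

    def __init__(self, domain: DomainConfig):
        nx, ny, h = domain.nx, domain.ny, domain.h
        kx = 2.0 * np.pi * np.fft.fftfreq(nx)
        ky = 2.0 * np.pi * np.fft.fftfreq(ny)
        self.gx = ((np.exp(1j * kx) - 1.0) / h)[:, None]
        self.gy = ((np.exp(1j * ky) - 1.0) / h)[None, :]
        self.lap = -(np.abs(self.gx) ** 2 + np.abs(self.gy) ** 2)
        self.lap_safe = self.lap.copy()
        self.lap_safe[0, 0] = 1.0


_OPS_CACHE: dict[tuple, _SpectralOps] = {}


def _ops(domain: DomainConfig) -> _SpectralOps:
    key = (domain.nx, domain.ny, round(domain.h, 12))
    if key not in _OPS_CACHE:
        _OPS_CACHE[key] = _SpectralOps(domain)
    return _OPS_CACHE[key]


def navier_stokes_step(state: FluidState, force, dt: float) -> FluidState:
    """One projection step: explicit advection + body force, Crank–Nicolson
    diffusion, spectral pressure projection.  Raises if the advective CFL
    number exceeds 1."""
    d = state.domain
    h, rho, nu = d.h, d.rho, d.mu / d.rho
    umax = state.max_speed()
    if umax * dt / h > 1.0:
        raise RuntimeError(
            f"CFL violated (u_max·dt/h = {umax * dt / h:.2f} > 1); "
            f"reduce dt below {h / umax:.2e} s")
    fu, fv = force
    adv_u, adv_v = _advection(state.u, state.v, h)
    u_star = state.u + dt * (-adv_u + fu / rho)
    v_star = state.v + dt * (-adv_v + fv / rho)

    ops = _ops(d)
    fac = (1.0 + 0.5 * dt * nu * ops.lap) / (1.0 - 0.5 * dt * nu * ops.lap)
    u_hat = np.fft.fft2(u_star) * fac
    v_hat = np.fft.fft2(v_star) * fac

    div_hat = ops.gx * u_hat + ops.gy * v_hat
    phi_hat = div_hat / ops.lap_safe
    phi_hat[0, 0] = 0.0
    # gradient back to faces: factor (1 - e^{-i k h})/h = -conj(g)
    u_hat -= -np.conj(ops.gx) * phi_hat
    v_hat -= -np.conj(ops.gy) * phi_hat
    u_new = np.real(np.fft.ifft2(u_hat))
    v_new = np.real(np.fft.ifft2(v_hat))
    return FluidState(u_new, v_new, d, state.time + dt)


def discrete_divergence(state: FluidState) -> np.ndarray:
    """Cell-centered divergence (diagnostic for the projection)."""
    h = state.domain.h
    return ((np.roll(state.u, -1, axis=0) - state.u)
            + (np.roll(state.v, -1, axis=1) - state.v)) / h


# ---------------------------------------------------------------------------
# resistive backend
# ---------------------------------------------------------------------------

def resistive_velocities(forces: np.ndarray, tangents: np.ndarray,
                         gamma_t: float, gamma_n: float) -> np.ndarray:
    """Local anisotropic drag law: node velocity from node force.

    Force is decomposed along the local unit tangent; the tangential part
    moves against drag ``gamma_t`` and the normal part against ``gamma_n``
    (dyn·s/cm per node).  Doubling the drag halves the velocity.
    """
    t = np.asarray(tangents, dtype=float)
    F = np.asarray(forces, dtype=float)
    ft = np.sum(F * t, axis=1, keepdims=True) * t
    fn = F - ft
    return ft / gamma_t + fn / gamma_n
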