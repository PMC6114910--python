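"""Closed-loop simulation harness: configuration, the sensorimotor loop,
gain sweeps, and trajectory I/O.

Per timestep, in order: (1) midline curvature from the body state, smoothed
to per-oscillator values; (2) feedback terms; (3) CPG phase step;
(4) activation thresholding; (5) calcium/muscle step; (6) force assembly
(passive network + muscle endpoint forces); (7) body advection by the
selected fluid backend ("ib" immersed boundary Navier–Stokes, or
"resistive" local drag law for cheap closed-loop exercise).

Feedback is sampled once per step from the body state at the start of the
step (explicit coupling).  A single fixed timestep is shared by the CPG,
muscle and body updates; the fluid solver sub-steps if its CFL condition
demands.

Trajectories are written to an HDF5 container with a versioned schema and
can be streamed frame by frame.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace

import h5py
import numpy as np
import yaml

from lampsim import body as body_mod
from lampsim import metrics as metrics_mod
from lampsim.cpg import (CPGParams, CPGState, activation_from_phase,
                         phase_velocity, step_cpg, tuned_state)
from lampsim.feedback import (FeedbackConfig, feedback_term,
                              midline_curvature, segment_curvature)
from lampsim.fluid import (DomainConfig, FluidState, interpolate_velocity,
                           navier_stokes_step, spread_forces)
from lampsim.metrics import KinematicsSeries, MetricsReport
from lampsim.muscle import MuscleBank, MuscleParams, endpoint_forces

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "SimulationError",
    "run_cpg_only",
    "run_simulation",
    "gain_sweep",
    "write_trajectory",
    "read_trajectory",
    "reduced_config",
]

SCHEMA_VERSION = 1


class SimulationError(RuntimeError):
    """Aborted simulation; carries the trajectory up to the last good frame."""

    def __init__(self, message: str, record: "TrajectoryRecord | None" = None):
        super().__init__(message)
        self.record = record


@dataclass(frozen=True)
class BodyConfig:
    L: float = 12.56            # body length, cm
    n_lat: int = 320            # lateral segments per side
    head_fraction: float = 0.125
    k_scale: float = body_mod.DEFAULT_K_SCALE  # spring stiffness scale, dyn/cm^2


@dataclass(frozen=True)
class FluidConfig:
    domain_x: float = 7.5       # domain length, body lengths
    domain_y: float = 3.0       # domain height, body lengths
    nx: int = 256               # cells across the domain length
    rho: float = 1.0            # g/cm^3
    mu: float = 0.01            # g/(cm s); 1 mPa·s
    mu_boost: float = 1.0       # Reynolds-reduction factor on mu
    start_fraction: float = 0.78  # head x-position as a fraction of Lx


@dataclass(frozen=True)
class ResistiveConfig:
    gamma_t: float = 10.0       # tangential drag per node, dyn s/cm
    gamma_n: float = 20.0       # normal drag per node, dyn s/cm
    refresh_steps: int = 25     # implicit-operator refactorization cadence


@dataclass(frozen=True)
class SimulationConfig:
    """Complete configuration of a closed-loop run (cgs units)."""

    cpg: CPGParams = field(default_factory=CPGParams)
    feedback: FeedbackConfig = field(default_factory=FeedbackConfig)
    muscle: MuscleParams = field(default_factory=MuscleParams)
    body: BodyConfig = field(default_factory=BodyConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    resistive: ResistiveConfig = field(default_factory=ResistiveConfig)
    backend: str = "ib"         # "ib" or "resistive"
    dt: float = 2.0e-4          # shared CPG/muscle/body timestep, s
    duration: float = 10.0      # simulated time, s
    output_dt: float = 0.01     # trajectory frame cadence, s
    perturb_phases: float = 0.0  # initial CPG phase noise half-width, rad
    seed: int = 0
    allow_gain_overrange: bool = False
    negative_phase_abort: float = 0.25  # sustained-negative window, s

    def __post_init__(self) -> None:
        if self.backend not in ("ib", "resistive"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        gain_ok = abs(self.feedback.gain) <= self.feedback.gain_range
        if not gain_ok and not self.allow_gain_overrange:
            raise ValueError(
                f"feedback gain {self.feedback.gain} outside the documented "
                f"stable range |gain| < {self.feedback.gain_range}; set "
                f"allow_gain_overrange to force")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kw = dict(raw)
        for key, sub in (("cpg", CPGParams), ("feedback", FeedbackConfig),
                         ("muscle", MuscleParams), ("body", BodyConfig),
                         ("fluid", FluidConfig), ("resistive", ResistiveConfig)):
            if key in kw and isinstance(kw[key], dict):
                kw[key] = sub(**kw[key])
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class TrajectoryRecord:
    """Per-frame arrays of a run plus a metadata manifest.

    arrays: time (n_f,), positions (n_f, n_nodes, 2), theta (n_f, 2, n_osc),
    sigma (n_f, 2, n_osc), kappa (n_f, n_osc), Cb/Cf/m/Pc/vc
    (n_f, 2, n_act).  meta: schema version, config hash, backend, body
    layout, achieved Reynolds number.
    """

    time: np.ndarray
    positions: np.ndarray
    theta: np.ndarray
    sigma: np.ndarray
    kappa: np.ndarray
    Cf: np.ndarray
    Cb: np.ndarray
    m: np.ndarray
    Pc: np.ndarray
    vc: np.ndarray
    meta: dict

    _ARRAYS = ("time", "positions", "theta", "sigma", "kappa",
               "Cf", "Cb", "m", "Pc", "vc")

    def kinematics(self) -> KinematicsSeries:
        n_mid = int(self.meta["n_mid"])
        return KinematicsSeries(time=self.time,
                                positions=self.positions[:, : n_mid + 1],
                                L=float(self.meta["L"]))

    def muscle_power(self) -> np.ndarray:
        """Instantaneous contractile power delivered by each unit,
        −P_c·v_c (erg/s), positive while the active muscle shortens."""
        return -self.Pc * self.vc


def write_trajectory(record: TrajectoryRecord, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["meta"] = json.dumps(record.meta, default=float)
        for name in TrajectoryRecord._ARRAYS:
            fh.create_dataset(name, data=getattr(record, name))


def read_trajectory(path) -> TrajectoryRecord:
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"trajectory schema version {version!r} != {SCHEMA_VERSION}")
        arrays = {}
        for name in TrajectoryRecord._ARRAYS:
            if name not in fh:
                raise ValueError(f"truncated trajectory file: missing {name!r}")
            arrays[name] = fh[name][...]
        meta = json.loads(fh.attrs["meta"])
    return TrajectoryRecord(meta=meta, **arrays)


def iter_frames(path, batch: int = 256):
    """Stream (time, positions) batches without loading the whole file."""
    with h5py.File(path, "r") as fh:
        n = fh["time"].shape[0]
        for lo in range(0, n, batch):
            hi = min(lo + batch, n)
            yield fh["time"][lo:hi], fh["positions"][lo:hi]


# ---------------------------------------------------------------------------
# CPG-only runs (control calibration, open-loop entrainment)
# ---------------------------------------------------------------------------

def run_cpg_only(params: CPGParams, duration: float, dt: float = 1.0e-3,
                 feedback_fn=None, output_every: int = 1,
                 initial: CPGState | None = None):
    """Integrate the CPG chain alone (no mechanics).

    ``feedback_fn(t) -> (n,) or (2, n) array`` supplies the per-oscillator
    feedback input (e.g. a prescribed curvature driver through
    :func:`lampsim.feedback.feedback_term`); default zero.

    Returns (time (n_f,), theta (n_f, 2, n), sigma (n_f, 2, n)).
    """
    state = tuned_state(params) if initial is None else initial.copy()
    n_steps = int(round(duration / dt))
    times, thetas, sigmas = [], [], []
    for step in range(n_steps + 1):
        if step % output_every == 0:
            times.append(state.time)
            thetas.append(state.theta.copy())
            sigmas.append(activation_from_phase(state, params.tau))
        if step == n_steps:
            break
        fb = 0.0 if feedback_fn is None else feedback_fn(state.time)
        state = step_cpg(state, fb, dt, params)
    return np.asarray(times), np.asarray(thetas), np.asarray(sigmas)


# ---------------------------------------------------------------------------
# full closed loop
# ---------------------------------------------------------------------------

class _ClosedLoop:
    """Mutable state of one closed-loop run."""

    def __init__(self, config: SimulationConfig):
        self.cfg = config
        c = config
        self.geom = body_mod.build_body(L=c.body.L, n_lat=c.body.n_lat,
                                        head_fraction=c.body.head_fraction,
                                        k_scale=c.body.k_scale)
        g = self.geom
        if c.cpg.n_seg != g.n_active_seg:
            raise ValueError(
                f"CPG chain length {c.cpg.n_seg} must equal the number of "
                f"active lateral segments {g.n_active_seg}")
        rng = np.random.default_rng(c.seed)
        self.cpg_state = tuned_state(c.cpg, perturbation=c.perturb_phases,
                                     rng=rng)
        heads_l, tails_l = g.lateral_segment_nodes(0)
        heads_r, tails_r = g.lateral_segment_nodes(1)
        self.seg_heads = np.stack([heads_l, heads_r])   # (2, n_act)
        self.seg_tails = np.stack([tails_l, tails_r])
        rest_len = np.linalg.norm(g.rest[tails_l] - g.rest[heads_l], axis=1)
        self.bank = MuscleBank(rest_len, g.active_tapers(), c.muscle)

        # body placed straight, head toward +Lx side, swimming toward -x
        x = g.rest.copy()
        if c.backend == "ib":
            dom = DomainConfig(Lx=c.fluid.domain_x * g.L,
                               Ly=c.fluid.domain_y * g.L,
                               nx=c.fluid.nx, rho=c.fluid.rho,
                               mu=c.fluid.mu * c.fluid.mu_boost)
            x[:, 0] += c.fluid.start_fraction * dom.Lx - g.L
            x[:, 1] += 0.5 * dom.Ly
            self.fluid = FluidState.at_rest(dom)
            # quadrature weight per node: filament spacing
            ds = np.empty(g.n_nodes)
            ds[: g.n_mid + 1] = g.L / g.n_mid
            ds[g.n_mid + 1:] = g.L / g.n_lat
            self.node_ds = ds
        else:
            self.fluid = None
            self._resistive_lu = None
            self._steps_since_refresh = 0
        self.body_state = body_mod.BodyState(x=x, v=np.zeros_like(x))
        self.neg_time = 0.0

    # -- semi-implicit resistive stepping ------------------------------

    def _muscle_axial_elements(self):
        """Axial stiffness of the active lateral segments for the implicit
        operator: muscle series stiffness plus the (upper-bound) skin and
        calcium-passive stiffnesses, both sides flattened."""
        i = self.seg_heads.ravel()
        j = self.seg_tails.ravel()
        p = self.cfg.muscle
        k_seg = (self.bank.k_se + (p.k_skin + p.k_passive_ca) / self.bank.l_rest)
        return i, j, np.tile(k_seg, 2)

    def _refresh_resistive_operator(self) -> None:
        """Factorize (Γ + dt·K) at the current configuration.

        Γ is the block-diagonal anisotropic drag (γ_t along the local
        filament tangent, γ_n normal to it) and K the spring network plus
        muscle series stiffness linearized at the current node positions.
        Solving (Γ + dt·K)·v = F treats the stiff elastic modes implicitly,
        so the overdamped body can be stepped at the shared loop timestep.
        """
        import scipy.sparse as sp
        from scipy.sparse.linalg import splu

        c, g = self.cfg, self.geom
        x = self.body_state.x
        K = body_mod.linearized_stiffness(g, x,
                                          extra_axial=self._muscle_axial_elements())
        t = self._tangents(x)
        gt, gn = c.resistive.gamma_t, c.resistive.gamma_n
        # Γ = γ_n I + (γ_t − γ_n) t̂t̂ᵀ per node
        blocks = np.empty((g.n_nodes, 2, 2))
        for a in range(2):
            for b in range(2):
                blocks[:, a, b] = (gt - gn) * t[:, a] * t[:, b]
            blocks[:, a, a] += gn
        gamma = sp.block_diag([sp.coo_matrix(b) for b in blocks], format="csc")
        self._resistive_lu = splu((gamma + c.dt * K).tocsc())
        self._steps_since_refresh = 0

    # -- one step ------------------------------------------------------

    def step(self) -> None:
        c, g = self.cfg, self.geom
        dt = c.dt
        x = self.body_state.x

        # (1) curvature of the midline, mapped and smoothed to oscillators
        field = midline_curvature(x[: g.n_mid + 1])
        kappa_i = segment_curvature(field, c.feedback, c.cpg.n_seg,
                                    head_fraction=c.body.head_fraction)
        self.kappa_i = kappa_i

        # (2) feedback terms, (3) CPG step, (4) activation
        fb = feedback_term(kappa_i, c.feedback)
        dtheta = phase_velocity(self.cpg_state, fb, c.cpg)
        if dtheta.min() < 0.0:
            self.neg_time += dt
            if self.neg_time > c.negative_phase_abort:
                raise SimulationError(
                    "sustained negative phase velocities (feedback out of "
                    f"range): min dθ/dt = {dtheta.min():.2f} rad/s at "
                    f"t = {self.cpg_state.time:.3f} s")
        else:
            self.neg_time = 0.0
        self.cpg_state = step_cpg(self.cpg_state, fb, dt, c.cpg)
        sigma = activation_from_phase(self.cpg_state, c.cpg.tau)
        self.sigma = sigma

        # (5) muscle step on current segment lengths
        p_head = x[self.seg_heads]
        p_tail = x[self.seg_tails]
        seg_len = np.linalg.norm(p_tail - p_head, axis=-1)
        tension, Pc = self.bank.step(sigma, seg_len, dt)
        self.Pc = Pc

        # (6) assemble forces
        passive = body_mod.passive_elastic_forces(self.body_state, g)
        muscle_nodes = np.zeros_like(passive)
        F_head, F_tail = endpoint_forces(tension, p_head, p_tail)
        np.add.at(muscle_nodes, self.seg_heads.ravel(),
                  F_head.reshape(-1, 2))
        np.add.at(muscle_nodes, self.seg_tails.ravel(),
                  F_tail.reshape(-1, 2))
        forces, _ = body_mod.assemble_forces(passive, muscle_nodes)

        # (7) advect the body with the chosen backend
        if c.backend == "resistive":
            if (self._resistive_lu is None
                    or self._steps_since_refresh >= c.resistive.refresh_steps):
                self._refresh_resistive_operator()
            v = self._resistive_lu.solve(forces.ravel()).reshape(-1, 2)
            self._steps_since_refresh += 1
        else:
            fu, fv = spread_forces(forces, x, self.node_ds,
                                   self.fluid.domain)
            n_sub = max(1, int(np.ceil(
                2.0 * self.fluid.max_speed() * dt / self.fluid.domain.h)))
            for _ in range(n_sub):
                self.fluid = navier_stokes_step(self.fluid, (fu, fv),
                                                dt / n_sub)
            v = interpolate_velocity(self.fluid, x)
        if not np.all(np.isfinite(v)):
            raise SimulationError(
                f"numerical blow-up at t = {self.body_state.time:.3f} s")
        self.body_state = body_mod.BodyState(x + dt * v, v,
                                             self.body_state.time + dt)

    def _tangents(self, x: np.ndarray) -> np.ndarray:
        g = self.geom
        t = np.zeros_like(x)
        for lo, hi in ((0, g.n_mid + 1),
                       (g.off_left, g.off_left + g.n_lat + 1),
                       (g.off_right, g.off_right + g.n_lat + 1)):
            seg = x[lo:hi]
            d = np.gradient(seg, axis=0)
            d /= np.linalg.norm(d, axis=1, keepdims=True)
            t[lo:hi] = d
        return t


def run_simulation(config: SimulationConfig,
                   progress=None) -> tuple[TrajectoryRecord, MetricsReport]:
    """Run the closed loop and compute the metrics report.

    Raises :class:`SimulationError` (carrying the partial trajectory) on
    sustained negative phase velocities or numerical blow-up.
    """
    loop = _ClosedLoop(config)
    n_steps = int(round(config.duration / config.dt))
    every = max(1, int(round(config.output_dt / config.dt)))
    frames = {name: [] for name in TrajectoryRecord._ARRAYS}

    def snapshot():
        st = loop.bank.state
        frames["time"].append(loop.body_state.time)
        frames["positions"].append(loop.body_state.x.copy())
        frames["theta"].append(loop.cpg_state.theta.copy())
        frames["sigma"].append(getattr(loop, "sigma",
                                       np.zeros((2, config.cpg.n_seg), np.int8)))
        frames["kappa"].append(getattr(loop, "kappa_i",
                                       np.zeros(config.cpg.n_seg)))
        frames["Cf"].append(st.Cf.copy())
        frames["Cb"].append(st.Cb.copy())
        frames["m"].append(st.m.copy())
        frames["Pc"].append(getattr(loop, "Pc", np.zeros_like(st.Cb)))
        frames["vc"].append(st.vc.copy())

    meta = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config.config_hash(),
        "backend": config.backend,
        "L": config.body.L,
        "n_mid": loop.geom.n_mid,
        "n_lat": config.body.n_lat,
        "n_osc": config.cpg.n_seg,
        "dt": config.dt,
        "head_fraction": config.body.head_fraction,
        "mass": body_mass(loop.geom, config.fluid.rho),
        "mu_effective": config.fluid.mu * config.fluid.mu_boost,
    }

    def build_record():
        return TrajectoryRecord(
            meta=meta, **{k: np.asarray(v) for k, v in frames.items()})

    snapshot()
    for step in range(1, n_steps + 1):
        try:
            loop.step()
        except SimulationError as err:
            err.record = build_record()
            raise
        if step % every == 0:
            snapshot()
            if progress is not None:
                progress(step, n_steps)
    record = build_record()
    report = compute_report(record, config)
    meta["reynolds"] = reynolds_number(record, config)
    return record, report


def body_mass(geom: body_mod.BodyGeometry, rho: float) -> float:
    """Mass (g) of the neutrally buoyant 2D swimmer: plan area × ρ per unit
    depth."""
    s = np.linspace(0.0, geom.L, geom.widths.size)
    return float(rho * np.trapezoid(geom.widths, s))


def reynolds_number(record: TrajectoryRecord, config: SimulationConfig) -> float:
    """Achieved Re = ρ·U·L/μ_eff from the measured swimming speed."""
    kin = record.kinematics()
    t = kin.time
    w0 = max(t[0], t[-1] - 4.0)
    try:
        U = metrics_mod.swimming_speed(kin, window=(w0, t[-1])) * kin.L
    except ValueError:
        return float("nan")
    mu_eff = config.fluid.mu * config.fluid.mu_boost
    return config.fluid.rho * U * kin.L / mu_eff


def compute_report(record: TrajectoryRecord,
                   config: SimulationConfig | None = None,
                   control_cot: float | None = None) -> MetricsReport:
    """Extract every metric the model reports from a trajectory record.

    Everything needed lives in the record and its manifest; ``config`` is
    accepted for symmetry with :func:`run_simulation` call sites.
    """
    kin = record.kinematics()
    t = kin.time
    report = MetricsReport()
    try:
        amp, freq = metrics_mod.tailbeat_metrics(
            kin, window=(max(t[0], t[-1] - 6.0), t[-1]))
        report.amplitude, report.frequency = amp, freq
    except ValueError:
        freq = None
    w0 = max(t[0], t[-1] - 4.0)
    if t[-1] - w0 > 1.0:
        report.speed = metrics_mod.swimming_speed(kin, window=(w0, t[-1]))
    try:
        report.duty = metrics_mod.duty_cycle(t, record.sigma)
    except ValueError:
        pass
    if report.frequency and report.speed:
        report.strouhal = metrics_mod.strouhal(report.frequency,
                                               report.amplitude, report.speed)
    # wavelength and wave speeds from the stored per-oscillator curvature
    n_osc = record.kappa.shape[1]
    g_L = float(record.meta["L"])
    head = float(record.meta["head_fraction"])
    s = g_L * (head + (1.0 - head) * (np.arange(n_osc) + 0.5) / n_osc)
    steady = t >= max(t[0], t[-1] - 6.0)
    try:
        report.wavelength = metrics_mod.body_wavelength(
            s, record.kappa[steady]) / g_L
    except ValueError:
        pass
    theta_s = record.theta[:, 1, :]  # right side
    try:
        _, _, ratio = metrics_mod.wave_speeds(
            t[steady], s, theta_s[steady], record.kappa[steady])
        report.wavespeed_ratio = ratio
    except ValueError:
        pass
    if freq:
        period = 1.0 / freq
        mass = float(record.meta["mass"])
        cot, cot_norm = metrics_mod.cost_of_transport(
            t, record.muscle_power(), period, mass,
            control_cot=control_cot)
        report.cot, report.cot_normalized = cot, cot_norm
    return report


def gain_sweep(config: SimulationConfig, mode: str, gains,
               progress=None) -> list[dict]:
    """One closed-loop run per gain; returns a tidy list of rows.

    Each row carries the gain, the percent-of-range gain (η_m scaled by
    0.09, η_d by 20 cm·rad/s), the metrics, and an ``error`` field when an
    individual run aborted (the sweep continues).
    """
    rows = []
    control_cot = None
    base = replace(config, feedback=replace(config.feedback, mode=mode,
                                            gain=0.0))
    gains = list(gains)
    if 0.0 not in gains:
        gains = [0.0] + gains
    # control first so every other row can be normalized against it
    ordered = [0.0] + sorted(g for g in gains if g != 0.0)
    for gain in ordered:
        fb = FeedbackConfig(mode=mode if gain != 0.0 else mode, gain=gain,
                            smooth_halfwidth=config.feedback.smooth_halfwidth,
                            tail_silent_segments=config.feedback.tail_silent_segments)
        cfg = replace(base, feedback=fb)
        row = {"gain": gain,
               "gain_percent": 100.0 * gain / fb.gain_range}
        try:
            record, report = run_simulation(cfg, progress=progress)
            if gain == 0.0:
                control_cot = report.cot
            report = compute_report(record, cfg, control_cot=control_cot)
            row.update(report.as_dict())
            row["error"] = ""
        except SimulationError as err:
            row["error"] = str(err)
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# desk-scale configuration
# ---------------------------------------------------------------------------

def reduced_config(*, backend: str = "resistive", n_osc: int = 70,
                   duration: float = 10.0, dt: float = 2.0e-4,
                   nx: int = 128, mu_boost: float = 100.0,
                   feedback: FeedbackConfig | None = None,
                   seed: int = 0) -> SimulationConfig:
    """Desk-scale closed-loop configuration.

    The chain is shortened (default 70 oscillators per side, keeping the
    7:1 active-to-head ratio of the full body), the body spring scale and
    muscle force are reduced together so the emergent curvature amplitude
    stays in the physiological range (tail curvature a few tenths of 1/cm),
    and the fluid backend runs at reduced resolution and Reynolds number.
    ψ̄ is rescaled to keep one full activation wave on the chain.
    """
    if n_osc % 7:
        raise ValueError("n_osc must be a multiple of 7 to keep the 7:1 "
                         "active-to-head segment ratio")
    n_lat = n_osc * 8 // 7
    cpg = CPGParams().with_segments(n_osc)
    muscle = MuscleParams(P0=2.0e5, se_strain=0.10, k_skin=2.0e4,
                          k_passive_ca=1.0e4)
    body = BodyConfig(n_lat=n_lat, k_scale=1.0e5)
    fluid = FluidConfig(domain_x=4.0, domain_y=2.0, nx=nx,
                        mu_boost=mu_boost)
    return SimulationConfig(
        cpg=cpg, muscle=muscle, body=body, fluid=fluid,
        feedback=feedback or FeedbackConfig(),
        backend=backend, dt=dt, duration=duration, seed=seed)
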