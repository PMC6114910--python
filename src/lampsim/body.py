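"""Three-filament spring-network body of the swimmer.

The body is a planar sandwich of three filaments — a midline discretized
into 2n segments and two lateral filaments (left/right) of n segments each —
connected by passive Hookean springs:

* axial springs between consecutive midline nodes (and next-nearest
  neighbors, which penalize extension of the chain),
* transverse crosslinks from each lateral node to the matching midline node
  (every other midline node, since the midline has twice the resolution),
* diagonal crosslinks to the neighboring matched midline nodes, which give
  the sandwich its shear and bending stiffness.

There is no structural damping: the surrounding viscous fluid damps the
network.  The lateral filaments themselves carry the muscle units and the
tension-only skin springs (see :mod:`lampsim.muscle`); the skin of the
passive head region, which has no muscle units, is kept here with the other
passive elements.

The body outline follows the measured profile: an ellipse-shaped head whose
width grows to a maximum of 10% of the body length about 6% down the body,
then decreases linearly to 0.1% of the body length at the tail.  The first
eighth of the body is the passive head with no muscular activity.

The macroscopic bending stiffness of the network is not an input; a single
stiffness scale multiplies all spring constants and is calibrated so that a
static end-moment test on the network recovers the target Young's modulus
(0.76 MPa by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BodyGeometry",
    "BodyState",
    "build_body",
    "width_profile",
    "passive_elastic_forces",
    "linearized_stiffness",
    "assemble_forces",
    "bending_stiffness_check",
    "calibrate_stiffness",
]

MPA_TO_CGS = 1.0e7  # 1 MPa = 1e7 dyn/cm^2

#: Stiffness scale (dyn/cm^2) calibrated so the default full-resolution
#: geometry measures E = 0.76 MPa in the static end-moment test
#: (see calibrate_stiffness).
DEFAULT_K_SCALE = 9.4398e7


def width_profile(frac: np.ndarray, L: float, *, w_max_frac: float = 0.10,
                  w_tail_frac: float = 0.001,
                  head_peak_frac: float = 19.0 / 320.0) -> np.ndarray:
    """Body width (cm) at arclength fractions ``frac`` in [0, 1].

    Quarter-ellipse rise over the snout to ``w_max_frac``·L at
    ``head_peak_frac`` of the body, then linear taper to ``w_tail_frac``·L
    at the tail tip.
    """
    q = np.asarray(frac, dtype=float)
    w_max = w_max_frac * L
    w_tail = w_tail_frac * L
    head = w_max * np.sqrt(np.clip(1.0 - ((head_peak_frac - q) / head_peak_frac) ** 2,
                                   0.0, None))
    tail = w_max + (w_tail - w_max) * (q - head_peak_frac) / (1.0 - head_peak_frac)
    # the snout tip never collapses below the tail width (keeps the three
    # filament tips distinct)
    return np.maximum(np.where(q <= head_peak_frac, head, tail), w_tail)


@dataclass
class BodyGeometry:
    """Discretized rest geometry and passive spring network.

    Node layout in the flat coordinate array: midline nodes 0..2n, then the
    left lateral nodes (at +y... no: left at −y? see below), then right.
    The **right** lateral filament lies at +y when the body rests along +x
    head-first, matching the curvature sign convention (positive κ bends
    toward the right side).
    """

    L: float
    n_lat: int                      # segments per lateral filament
    head_fraction: float            # passive head fraction of the body
    k_scale: float
    rest: np.ndarray                # (n_nodes, 2) rest positions, cm
    widths: np.ndarray              # (n_lat + 1,) width at lateral nodes, cm
    # Hookean springs: midline axial + crosslinks + diagonals
    spring_i: np.ndarray = field(repr=False, default=None)
    spring_j: np.ndarray = field(repr=False, default=None)
    spring_k: np.ndarray = field(repr=False, default=None)
    spring_r0: np.ndarray = field(repr=False, default=None)
    # tension-only skin springs of the passive head region
    skin_i: np.ndarray = field(repr=False, default=None)
    skin_j: np.ndarray = field(repr=False, default=None)
    skin_k: np.ndarray = field(repr=False, default=None)
    skin_r0: np.ndarray = field(repr=False, default=None)

    @property
    def n_mid(self) -> int:
        return 2 * self.n_lat

    @property
    def n_nodes(self) -> int:
        return (self.n_mid + 1) + 2 * (self.n_lat + 1)

    @property
    def off_left(self) -> int:
        return self.n_mid + 1

    @property
    def off_right(self) -> int:
        return self.n_mid + 1 + self.n_lat + 1

    @property
    def n_head_seg(self) -> int:
        """Passive lateral segments at the head (no muscle)."""
        return int(round(self.head_fraction * self.n_lat))

    @property
    def n_active_seg(self) -> int:
        return self.n_lat - self.n_head_seg

    def lateral_segment_nodes(self, side: int):
        """Global node indices (head_end, tail_end) of the active lateral
        segments on ``side`` (0 = left, 1 = right), each (n_active_seg,)."""
        off = self.off_left if side == 0 else self.off_right
        p = np.arange(self.n_head_seg, self.n_lat)
        return off + p, off + p + 1

    def midline_nodes(self) -> np.ndarray:
        return np.arange(self.n_mid + 1)

    def active_tapers(self) -> np.ndarray:
        """Taper factor (area ratio, elliptical sections) per active segment."""
        wmid = 0.5 * (self.widths[:-1] + self.widths[1:])
        w = wmid[self.n_head_seg:]
        return (w / wmid.max()) ** 2


@dataclass
class BodyState:
    """Current node positions (cm) and velocities (cm/s)."""

    x: np.ndarray
    v: np.ndarray
    time: float = 0.0

    def copy(self) -> "BodyState":
        return BodyState(self.x.copy(), self.v.copy(), self.time)


def build_body(L: float = 12.56, n_lat: int = 320,
               head_fraction: float = 0.125,
               k_scale: float = DEFAULT_K_SCALE,
               cross_stiffness: float = 1.0,
               diag_stiffness: float = 1.0,
               diag_span: int = 2,
               mid_stiffness: float = 25.0,
               skin_stiffness: float = 1.0) -> BodyGeometry:
    """Construct the rest geometry and passive spring network.

    ``k_scale`` (dyn/cm²) multiplies every spring constant; individual
    spring constants are k = k_scale·stiffness_weight·w_local/r0, i.e.
    proportional to the local body width (cross-sectional area per unit
    depth) and inversely proportional to rest length, the scaling of an
    elastic rod segment.
    """
    if n_lat < 8:
        raise ValueError("n_lat must be at least 8")
    n_mid = 2 * n_lat
    s_mid = np.linspace(0.0, L, n_mid + 1)
    s_lat = np.linspace(0.0, L, n_lat + 1)
    widths = width_profile(s_lat / L, L)

    rest = np.zeros(((n_mid + 1) + 2 * (n_lat + 1), 2))
    rest[: n_mid + 1, 0] = s_mid
    off_l = n_mid + 1
    off_r = off_l + n_lat + 1
    rest[off_l: off_l + n_lat + 1, 0] = s_lat
    rest[off_l: off_l + n_lat + 1, 1] = -0.5 * widths   # left at −y
    rest[off_r: off_r + n_lat + 1, 0] = s_lat
    rest[off_r: off_r + n_lat + 1, 1] = +0.5 * widths   # right at +y

    w_mid_nodes = width_profile(s_mid / L, L)

    ii, jj, ww = [], [], []

    def add(i, j, weight):
        ii.append(np.asarray(i, dtype=int))
        jj.append(np.asarray(j, dtype=int))
        ww.append(np.asarray(weight, dtype=float))

    # midline axial, nearest and next-nearest; the multiplier keeps the
    # stiff midline filament near-inextensible under muscle compression
    m = np.arange(n_mid)
    add(m, m + 1, mid_stiffness * w_mid_nodes[:-1])
    m2 = np.arange(n_mid - 1)
    add(m2, m2 + 2, 0.5 * mid_stiffness * w_mid_nodes[:-2])
    for off in (off_l, off_r):
        p = np.arange(n_lat + 1)
        # transverse crosslinks to the matched midline node (every other)
        add(off + p, 2 * p, cross_stiffness * w_mid_nodes[2 * p])
        # near-diagonals to the unmatched (odd) midline neighbors; these
        # pin the odd midline nodes transversally, suppressing grid-scale
        # buckling of the midline chain under muscle compression
        pn = np.arange(n_lat + 1)
        add(off + pn[1:], 2 * pn[1:] - 1,
            cross_stiffness * w_mid_nodes[2 * pn[1:] - 1])
        add(off + pn[:-1], 2 * pn[:-1] + 1,
            cross_stiffness * w_mid_nodes[2 * pn[:-1] + 1])
        # diagonals spanning ``diag_span`` lateral segments fore and aft;
        # the span gives the sandwich its shear stiffness, which converts
        # differential lateral-filament strain into midline bending
        pd = np.arange(diag_span, n_lat + 1)
        add(off + pd, 2 * (pd - diag_span),
            diag_stiffness * w_mid_nodes[2 * pd - diag_span])
        pu = np.arange(n_lat + 1 - diag_span)
        add(off + pu, 2 * (pu + diag_span),
            diag_stiffness * w_mid_nodes[2 * pu + diag_span])

    spring_i = np.concatenate(ii)
    spring_j = np.concatenate(jj)
    weight = np.concatenate(ww)
    r0 = np.linalg.norm(rest[spring_j] - rest[spring_i], axis=1)
    if np.any(r0 <= 0):
        raise ValueError("degenerate spring with zero rest length")
    # stiffness of an elastic rod segment, k = (E·A)/length, with the length
    # floored at the lateral spacing so very short transverse links near the
    # snout do not dominate the stiffness spectrum
    spring_k = k_scale * weight / np.maximum(r0, L / n_lat)

    # head-region skin (tension-only); active-region skin lives with the
    # muscle units
    n_head = int(round(head_fraction * n_lat))
    si, sj, sw = [], [], []
    for off in (off_l, off_r):
        p = np.arange(n_head)
        si.append(off + p)
        sj.append(off + p + 1)
        sw.append(skin_stiffness * widths[p])
    skin_i = np.concatenate(si)
    skin_j = np.concatenate(sj)
    skin_r0 = np.linalg.norm(rest[skin_j] - rest[skin_i], axis=1)
    skin_k = k_scale * np.concatenate(sw) / skin_r0

    return BodyGeometry(L=L, n_lat=n_lat, head_fraction=head_fraction,
                        k_scale=k_scale, rest=rest, widths=widths,
                        spring_i=spring_i, spring_j=spring_j,
                        spring_k=spring_k, spring_r0=r0,
                        skin_i=skin_i, skin_j=skin_j,
                        skin_k=skin_k, skin_r0=skin_r0)


def _spring_forces(x, i, j, k, r0, tension_only=False):
    d = x[j] - x[i]
    ln = np.linalg.norm(d, axis=1)
    if np.any(ln == 0.0):
        raise ValueError("zero-length elastic element")
    ext = ln - r0
    if tension_only:
        ext = np.clip(ext, 0.0, None)
    f = (k * ext / ln)[:, None] * d  # force on i, toward j when stretched
    forces = np.zeros_like(x)
    np.add.at(forces, i, f)
    np.add.at(forces, j, -f)
    return forces


def passive_elastic_forces(state: BodyState, geometry: BodyGeometry) -> np.ndarray:
    """Passive Hookean node forces (dyn), including head-region skin."""
    g = geometry
    forces = _spring_forces(state.x, g.spring_i, g.spring_j,
                            g.spring_k, g.spring_r0)
    forces += _spring_forces(state.x, g.skin_i, g.skin_j,
                             g.skin_k, g.skin_r0, tension_only=True)
    return forces


def assemble_forces(passive: np.ndarray, muscle: np.ndarray):
    """Sum passive and muscle node forces; also return the total force and
    total torque about the centroid-of-force-application, which must both
    vanish for a free swimmer built from equal-and-opposite pairs.
    """
    total = passive + muscle
    net_force = total.sum(axis=0)
    return total, net_force


def net_torque(forces: np.ndarray, x: np.ndarray) -> float:
    """Total torque (z-component) of node forces about the node centroid."""
    r = x - x.mean(axis=0)
    return float(np.sum(r[:, 0] * forces[:, 1] - r[:, 1] * forces[:, 0]))


# ---------------------------------------------------------------------------
# static bending test / stiffness calibration
# ---------------------------------------------------------------------------

def linearized_stiffness(geometry: BodyGeometry,
                         x: np.ndarray | None = None,
                         extra_axial: tuple | None = None):
    """Sparse linearized stiffness matrix (2n × 2n) of the spring network.

    Each spring contributes k·t̂t̂ᵀ along its unit tangent evaluated at the
    configuration ``x`` (rest geometry by default); the tension-only skin
    is linearized at its tensile stiffness.  ``extra_axial`` optionally
    adds further axial elements as (i_idx, j_idx, k) — used by the harness
    to include the muscle series stiffness in implicit stepping.
    """
    import scipy.sparse as sp

    g = geometry
    n = g.n_nodes
    if x is None:
        x = g.rest
    i_all = np.concatenate([g.spring_i, g.skin_i])
    j_all = np.concatenate([g.spring_j, g.skin_j])
    k_all = np.concatenate([g.spring_k, g.skin_k])
    if extra_axial is not None:
        ei, ej, ek = extra_axial
        i_all = np.concatenate([i_all, ei])
        j_all = np.concatenate([j_all, ej])
        k_all = np.concatenate([k_all, ek])
    d = x[j_all] - x[i_all]
    ln = np.linalg.norm(d, axis=1)
    t = d / ln[:, None]
    rows, cols, vals = [], [], []
    for a in range(2):
        for b in range(2):
            kab = k_all * t[:, a] * t[:, b]
            for (ii, jj, s) in ((i_all, i_all, 1.0), (j_all, j_all, 1.0),
                                (i_all, j_all, -1.0), (j_all, i_all, -1.0)):
                rows.append(2 * ii + a)
                cols.append(2 * jj + b)
                vals.append(s * kab)
    return sp.coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(2 * n, 2 * n)).tocsr()


def _linear_static_solve(geometry: BodyGeometry,
                         ext_forces: np.ndarray) -> np.ndarray:
    """Small-displacement equilibrium of the spring network: K·d = f with
    one node pinned and one rotation dof fixed; the applied couples are
    self-equilibrated so the reactions vanish.
    """
    import scipy.sparse as sp
    from scipy.sparse.linalg import spsolve

    g = geometry
    n = g.n_nodes
    K = linearized_stiffness(geometry)
    # pin rigid modes at unloaded nodes (constraints realizable by rigid
    # motion of the deformed shape, so they carry no reaction for the
    # self-equilibrated couples): midline node 2 fully, transverse dof of
    # the mid-body midline node
    pinned = [4, 5, 2 * (g.n_mid // 2) + 1]
    free = np.setdiff1d(np.arange(2 * n), pinned)
    f = ext_forces.ravel()
    sol = np.zeros(2 * n)
    Kff = K[np.ix_(free, free)] + 1e-9 * sp.eye(free.size, format="csr")
    sol[free] = spsolve(Kff.tocsc(), f[free])
    return g.rest + sol.reshape(-1, 2)


def bending_stiffness_check(geometry: BodyGeometry, *,
                            moment: float | None = None) -> float:
    """Measure the macroscopic Young's modulus E (MPa) of the network.

    Applies equal and opposite couples at the two ends of the body (zero
    net force and torque), solves the linearized static equilibrium, and
    reads E from beam theory, E = M/(κ·I), with κ the measured midline
    curvature and I = w³/12 the second moment of the local cross-section
    (unit depth).  κ and I are averaged over the mid-body.
    """
    g = geometry
    I_mid = g.widths ** 3 / 12.0
    if moment is None:
        # aim for a gentle arc: κ·L ≈ 0.15 at the expected stiffness
        E_guess = g.k_scale
        moment = 0.15 / g.L * E_guess * np.median(I_mid)

    # couple at each end: transverse force pair on midline nodes
    ext = np.zeros_like(g.rest)
    arm_nodes = max(4, g.n_mid // 40)
    f_end = moment / (g.rest[arm_nodes, 0] - g.rest[0, 0])
    # head couple
    ext[0, 1] = -f_end
    ext[arm_nodes, 1] = f_end
    # tail couple (opposite sense) -> both ends curve the beam the same way
    ext[g.n_mid, 1] = -f_end
    ext[g.n_mid - arm_nodes, 1] = f_end

    x = _linear_static_solve(geometry, ext)
    mid = x[: g.n_mid + 1]
    from lampsim.feedback import midline_curvature  # local import, no cycle
    kappa = midline_curvature(mid).kappa
    # mid-body average, away from the loaded ends
    lo, hi = int(0.35 * g.n_mid), int(0.65 * g.n_mid)
    kap = np.abs(kappa[lo:hi]).mean()
    I_local = np.interp(np.linspace(0.35, 0.65, hi - lo),
                        np.linspace(0, 1, g.widths.size), I_mid).mean()
    E_cgs = moment / (kap * I_local)
    return E_cgs / MPA_TO_CGS


def calibrate_stiffness(E_target_mpa: float = 0.76, *, n_lat: int = 320,
                        L: float = 12.56, iterations: int = 3,
                        k_scale0: float = DEFAULT_K_SCALE, **kw) -> float:
    """Stiffness scale k_scale for which the static bending test returns
    ``E_target_mpa``.  The network response is linear in k_scale, so a few
    fixed-point updates k ← k·E_target/E_measured suffice."""
    k = k_scale0
    for _ in range(iterations):
        geom = build_body(L=L, n_lat=n_lat, k_scale=k, **kw)
        e = bending_stiffness_check(geom)
        k *= E_target_mpa / e
        if abs(e - E_target_mpa) / E_target_mpa < 0.01:
            break
    return k
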