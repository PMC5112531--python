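"""Damped explicit quasi-static relaxation of the growing bilayer.

The solver integrates damped Newton dynamics toward mechanical equilibrium
(div sigma = 0) with central differences while the cortical growth
multiplier ramps up slowly.  Density is a free numerical parameter (mass
scaling): only the quasi-static limit matters, monitored by the
kinetic/strain energy ratio.

Element formulation: bilinear quads (2D plane strain) / trilinear hexes
(3D) with selective reduced integration -- full Gauss quadrature for the
isochoric neo-Hookean term, center-point quadrature for the volumetric
penalty (no locking, no hourglassing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .mesh import CORTEX, BilayerMesh, build_bilayer_mesh
from ..synthetic import make_perturbation


def _shape_gradients(xi: np.ndarray, dim: int) -> np.ndarray:
    """Gradients of the multilinear shape functions at reference point xi.

    Returns an (n_nodes, dim) array; node order matches the mesh builder.
    """
    if dim == 2:
        r, s = xi
        return 0.25 * np.array([
            [-(1 - s), -(1 - r)],
            [(1 - s), -(1 + r)],
            [(1 + s), (1 + r)],
            [-(1 + s), (1 - r)],
        ])
    r, s, t = xi
    out = np.empty((8, 3))
    signs = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
             (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]
    for a, (sr, ss, st) in enumerate(signs):
        out[a, 0] = 0.125 * sr * (1 + ss * s) * (1 + st * t)
        out[a, 1] = 0.125 * ss * (1 + sr * r) * (1 + st * t)
        out[a, 2] = 0.125 * st * (1 + sr * r) * (1 + ss * s)
    return out


def _quadrature(dim: int):
    """(points, weights) for full Gauss quadrature plus the center point."""
    a = 1.0 / np.sqrt(3.0)
    if dim == 2:
        pts = [(-a, -a), (a, -a), (a, a), (-a, a), (0.0, 0.0)]
        wts = [1.0, 1.0, 1.0, 1.0, 4.0]
    else:
        pts = [(sx * a, sy * a, sz * a)
               for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
        pts.append((0.0, 0.0, 0.0))
        wts = [1.0] * 8 + [8.0]
    return np.asarray(pts), np.asarray(wts)


class Discretization:
    """Precomputed reference-configuration quadrature data for a mesh."""

    def __init__(self, mesh: BilayerMesh):
        self.mesh = mesh
        dim = mesh.dim
        pts, wts = _quadrature(dim)
        nq = len(wts)
        ne = mesh.n_elements
        npe = mesh.elements.shape[1]
        self.gradN0 = np.empty((ne, nq, npe, dim))
        self.wdet = np.empty((ne, nq))
        X = mesh.nodes[mesh.elements]  # (ne, npe, dim)
        for q, (xi, w) in enumerate(zip(pts, wts)):
            dN = _shape_gradients(np.asarray(xi), dim)   # (npe, dim)
            Jref = np.einsum("eai,aj->eij", X, dN)       # dX/dxi
            det = np.linalg.det(Jref)
            if (det <= 0).any():
                raise ValueError("non-positive element Jacobian in reference mesh")
            self.gradN0[:, q] = np.einsum("aj,ejk->eak", dN, np.linalg.inv(Jref))
            self.wdet[:, q] = w * det
        # lumped mass per node for unit density (reference volume share)
        vol = self.wdet[:, :-1].sum(axis=1)
        self.element_volume = vol
        m = np.zeros(mesh.n_nodes)
        np.add.at(m, mesh.elements.ravel(),
                  np.repeat(vol / npe, npe))
        self.unit_mass = m
        self.n_quad = nq

    def deformation_gradients(self, x: np.ndarray) -> np.ndarray:
        """F at every quadrature point, shape (ne, nq, dim, dim)."""
        xe = x[self.mesh.elements]
        return np.einsum("eai,eqaj->eqij", xe, self.gradN0)


@dataclass
class GrowthField:
    """Per-element isotropic growth driver.

    ``rate_multiplier`` scales the cortex growth rate per element (0 in the
    non-growing core, 1 in the cortex, ``patch_multiplier`` in the special
    area); the baseline cortex multiplier ramps linearly in time,
    g(t) = 1 + (g_max - 1) min(t / ramp_time, 1), and element growth is
    g_e(t) = 1 + rate_multiplier * (g(t) - 1).
    """

    rate_multiplier: np.ndarray
    g_max: float = 1.6
    ramp_time: float = 100.0

    def baseline(self, t: float) -> float:
        return 1.0 + (self.g_max - 1.0) * min(max(t, 0.0) / self.ramp_time, 1.0)

    def ramp_fraction(self, t: float) -> float:
        return min(max(t, 0.0) / self.ramp_time, 1.0)

    def g_elements(self, t: float) -> np.ndarray:
        return 1.0 + self.rate_multiplier * (self.baseline(t) - 1.0)


@dataclass
class QuadratureState:
    """Per-integration-point kinematics and stress.

    All arrays are indexed (element, quadrature point, ...); the last
    quadrature point of each element is the center (volumetric) point.
    """

    F: np.ndarray        # (e, q, d, d) total deformation gradient
    G: np.ndarray        # (e, d, d) growth tensor
    A: np.ndarray        # (e, q, d, d) elastic tensor
    sigma: np.ndarray    # (e, q, d, d) Cauchy stress, Pa
    p: np.ndarray        # (e, q) penalty pressure, Pa
    lambdas: np.ndarray  # (e, q, 3) elastic principal stretches
    W: np.ndarray        # (e, q) strain-energy density, Pa

    @property
    def detA(self) -> np.ndarray:
        return np.linalg.det(self.A)

    def center_detA(self) -> np.ndarray:
        """det A at the volumetric (center) integration points."""
        return self.detA[:, -1]

    def reconstruction_error(self) -> float:
        """max |A G - F| over all points (kinematic consistency)."""
        AG = np.einsum("eqij,ejk->eqik", self.A, self.G)
        return float(np.abs(AG - self.F).max())


def evaluate_state(disc: Discretization, x: np.ndarray, g_elem: np.ndarray,
                   mu_elem: np.ndarray, bulk: float) -> QuadratureState:
    """Full kinematic/stress state at every quadrature point."""
    mesh = disc.mesh
    d = mesh.dim
    F = disc.deformation_gradients(x)
    G = g_elem[:, None, None] * np.eye(d)[None]
    A = F / g_elem[:, None, None, None]
    J = np.linalg.det(A)
    if (J <= 0).any():
        raise ValueError("element inversion: det A <= 0")
    B = np.einsum("eqij,eqkj->eqik", A, A)
    p = bulk * (J - 1.0)
    sigma = (mu_elem[:, None, None, None] / J[..., None, None]
             * (B - np.eye(d)[None, None])) + p[..., None, None] * np.eye(d)[None, None]
    svals = np.linalg.svd(A, compute_uv=False)
    if d == 2:
        lambdas = np.concatenate([svals, np.ones(svals.shape[:2] + (1,))], axis=-1)
    else:
        lambdas = svals
    I1 = np.einsum("eqij,eqij->eq", A, A)
    W = (0.5 * mu_elem[:, None] * (I1 - d) - mu_elem[:, None] * np.log(J)
         + 0.5 * bulk * (J - 1.0) ** 2)
    return QuadratureState(F=F, G=G, A=A, sigma=sigma, p=p, lambdas=lambdas, W=W)


def internal_forces(disc: Discretization, x: np.ndarray, g_elem: np.ndarray,
                    mu_elem: np.ndarray, bulk: float) -> np.ndarray:
    """Nodal internal forces -dE/dx (numpy reference assembly).

    Mirrors the numba kernels: isochoric first Piola stress at the full
    Gauss points, volumetric penalty at the center point, both pulled back
    to the reference configuration with the growth Jacobian factor
    g^(d-1).
    """
    mesh = disc.mesh
    d = mesh.dim
    F = disc.deformation_gradients(x)
    A = F / g_elem[:, None, None, None]
    J = np.linalg.det(A)
    if (J <= 0).any():
        raise ValueError("element inversion: det A <= 0")
    invT = np.swapaxes(np.linalg.inv(A), -1, -2)
    P = np.empty_like(A)
    P[:, :-1] = mu_elem[:, None, None, None] * (A[:, :-1] - invT[:, :-1])
    P[:, -1] = (bulk * (J[:, -1] - 1.0) * J[:, -1])[:, None, None] * invT[:, -1]
    scale = (disc.wdet * g_elem[:, None] ** (d - 1))[..., None, None]
    fe = -np.einsum("eqik,eqak->eai", P * scale, disc.gradN0)
    f = np.zeros_like(x)
    np.add.at(f, mesh.elements.ravel(), fe.reshape(-1, d))
    return f


def total_energy(disc: Discretization, x: np.ndarray, g_elem: np.ndarray,
                 mu_elem: np.ndarray, bulk: float) -> float:
    """Total strain energy (reference volume integral of g^d W)."""
    mesh = disc.mesh
    d = mesh.dim
    state = evaluate_state(disc, x, g_elem, mu_elem, bulk)
    gd = g_elem[:, None] ** d
    Wiso = state.W - 0.5 * bulk * (np.linalg.det(state.A) - 1.0) ** 2
    Wvol = state.W - Wiso
    e_iso = (Wiso[:, :-1] * disc.wdet[:, :-1] * gd).sum()
    e_vol = (Wvol[:, -1] * disc.wdet[:, -1] * gd[:, 0]).sum()
    return float(e_iso + e_vol)


@dataclass
class SolverState:
    """Node positions/velocities of the explicit integrator."""

    x: np.ndarray
    v: np.ndarray
    t: float = 0.0


def step_explicit(state: SolverState, disc: Discretization, mat_mu: np.ndarray,
                  bulk: float, growth: GrowthField, dt: float,
                  damping: float, free: np.ndarray,
                  stiffness_multiplier: np.ndarray | None = None) -> SolverState:
    """One damped central-difference step (numpy reference path).

    ``free`` is an (n_nodes, dim) boolean mask of unconstrained dofs.
    The production loop runs the numerically identical numba kernels; this
    single-step path is the readable reference used for verification.
    """
    t_new = state.t + dt
    frac = growth.ramp_fraction(t_new)
    g_elem = growth.g_elements(t_new)
    mu_elem = mat_mu if stiffness_multiplier is None else \
        mat_mu * (1.0 + (stiffness_multiplier - 1.0) * frac)
    f = internal_forces(disc, state.x, g_elem, mu_elem, bulk)
    m = disc.unit_mass[:, None]
    c1 = 1.0 - 0.5 * damping * dt
    c2 = 1.0 / (1.0 + 0.5 * damping * dt)
    v = (c1 * state.v + dt * f / m) * c2
    v = np.where(free, v, 0.0)
    return SolverState(x=state.x + dt * v, v=v, t=t_new)


# ---------------------------------------------------------------------------
# simulation driver


@dataclass
class SimConfig:
    """Configuration for a growth run.

    Geometry defaults are the desk-scale 2D cross-section (100 x 25 mm
    plate, 2 mm cortex); the full-plate geometry is available by setting
    ``length``/``depth``/``width``.  ``mode`` selects homogeneous growth, a
    fast-growing special area, or a stiffening special area with
    homogeneous growth.
    """

    # geometry / mesh
    length: float = 100.0
    depth: float = 25.0
    width: float | None = None          # set for a 3D run
    cortex_thickness: float = 2.0
    dx_cortex: float = 1.25
    n_cortex_layers: int = 2
    patch_width: float = 10.0           # ~0.7x the homogeneous fold wavelength

    # material
    mu: float = 330.0
    bulk_factor: float = 400.0
    density: float = 1.0

    # growth / mode
    mode: str = "homogeneous"           # homogeneous | fast_patch | stiff_patch
    g_max: float = 2.2                  # past the equal-modulus surface threshold
    patch_multiplier: float = 1.2       # fast_patch growth-rate ratio
    stiff_final: float = 2.0            # stiff_patch final modulus ratio
    stiff_ramp_fraction: float = 0.5    # stiffness fully ramped by this point
                                        # of the growth ramp (~instability onset)

    # perturbation
    perturb_amplitude: float = 0.05     # mm (2.5% of the 2 mm cortex)
    mirror_perturbation: bool = False   # flip the perturbation field left-right
    seed: int = 0

    # integration
    ramp_time: float = 150.0
    settle_time: float = 40.0           # extra time at g_max before giving up
    hold_settle_time: float = 60.0      # post-fold relaxation budget
    quasistatic_ratio: float = 0.02     # target kinetic/strain energy at rest
    damping: float = 0.6
    dt_safety: float = 0.6
    steps_per_frame: int = 500
    detect_amp_factor: float = 1.0      # freeze growth once amplitude = 1x cortex
    hold_damping: float = 3.0           # stronger damping while the fold relaxes
    amplitude_stop_factor: float = 3.0  # stop recording at fold amplitude 3x cortex
    contact_gap: float = 0.5            # mm, minimum top-surface gap
    boundary: str = "plate"             # plate (rollers) | free

    def __post_init__(self) -> None:
        for name in ("length", "depth", "cortex_thickness", "dx_cortex", "mu",
                     "bulk_factor", "density", "g_max", "ramp_time", "damping",
                     "dt_safety"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("homogeneous", "fast_patch", "stiff_patch"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def bulk_penalty(self) -> float:
        return self.bulk_factor * self.mu

    def build_mesh(self) -> BilayerMesh:
        return build_bilayer_mesh(length=self.length, depth=self.depth,
                                  cortex_thickness=self.cortex_thickness,
                                  dx_cortex=self.dx_cortex,
                                  n_cortex_layers=self.n_cortex_layers,
                                  patch_width=self.patch_width,
                                  width=self.width)


@dataclass
class SimResult:
    """Recorded trajectory and diagnostics of one growth run."""

    times: np.ndarray        # (frames,)
    g: np.ndarray            # baseline cortex growth per frame
    top_x: np.ndarray        # (frames, n_top) surface profile abscissae
    top_h: np.ndarray        # (frames, n_top) surface heights
    kinetic: np.ndarray
    strain: np.ndarray
    max_det_err: np.ndarray  # max |det A - 1| at the volumetric points
    status: str              # folded | grown | no_instability | contact
    config: SimConfig
    seed: int
    final_state: QuadratureState | None = None
    center: float = 0.0      # patch center abscissa, mm
    mirrored_perturbation: bool = False

    @property
    def folded(self) -> bool:
        return self.status in ("folded", "contact")

    def profile(self, frame: int = -1) -> tuple[np.ndarray, np.ndarray]:
        return self.top_x[frame], self.top_h[frame]

    def fold_amplitude(self, frame: int = -1) -> float:
        h = self.top_h[frame]
        x = self.top_x[frame]
        resid = h - np.polyval(np.polyfit(x, h, 1), x)
        return float(resid.max() - resid.min())

    def dominant_wavelength(self, frame: int = -1) -> float:
        """Fold wavelength from the peak of the height spectrum."""
        x, h = self.profile(frame)
        xi = np.linspace(x.min(), x.max(), len(x))
        hi = np.interp(xi, x, h)
        hi = hi - hi.mean()
        spec = np.abs(np.fft.rfft(hi * np.hanning(len(hi))))
        freqs = np.fft.rfftfreq(len(hi), d=xi[1] - xi[0])
        k = 1 + int(np.argmax(spec[1:]))
        return float(1.0 / freqs[k])


def _top_contact(x_top: np.ndarray, gap: float) -> bool:
    """Detect near self-contact between non-adjacent top-surface nodes."""
    tree = cKDTree(x_top)
    pairs = tree.query_pairs(gap, output_type="ndarray")
    if len(pairs) == 0:
        return False
    return bool((np.abs(pairs[:, 0] - pairs[:, 1]) > 4).any())


def _free_mask(mesh: BilayerMesh, boundary: str) -> np.ndarray:
    free = np.ones((mesh.n_nodes, mesh.dim), dtype=bool)
    if boundary == "free":
        return free
    free[mesh.bottom_nodes(), mesh.dim - 1] = False   # no normal motion at base
    for ax, ids in enumerate(mesh.lateral_nodes()):   # rollers on lateral faces
        free[ids, ax] = False
    return free


def run_simulation(config: SimConfig) -> SimResult:
    """Run one growth simulation to its stop criterion.

    Applies the seeded perturbation, ramps growth (with the special-area
    growth multiplier in ``fast_patch`` mode or the growth-dependent
    stiffness ramp in ``stiff_patch`` mode), integrates the damped explicit
    dynamics, and records top-surface frames.  Deterministic given
    ``config.seed``.
    """
    mesh = config.build_mesh()
    d = mesh.dim
    top_ids_flat = mesh.top_surface_nodes()
    # seed the imperfection in the reference configuration: the perturbed
    # geometry is stress-free, so the run starts at exact equilibrium
    pert = make_perturbation(mesh, config.perturb_amplitude, config.seed)
    disp = pert.displacements[::-1] if config.mirror_perturbation \
        else pert.displacements
    mesh.nodes[pert.node_ids, d - 1] += disp
    disc = Discretization(mesh)

    gmul = (mesh.layer == CORTEX).astype(np.float64)
    smul = np.ones(mesh.n_elements)
    if config.mode == "fast_patch":
        gmul[mesh.special] = config.patch_multiplier
    elif config.mode == "stiff_patch":
        smul[mesh.special] = config.stiff_final
    growth = GrowthField(rate_multiplier=gmul, g_max=config.g_max,
                         ramp_time=config.ramp_time)
    mu0 = np.full(mesh.n_elements, config.mu)
    bulk = config.bulk_penalty

    x = mesh.nodes.copy()
    v = np.zeros_like(x)
    mass = disc.unit_mass * config.density
    free = _free_mask(mesh, config.boundary)

    # stable step from the penalized P-wave speed and smallest element edge
    h_min = min(config.dx_cortex, config.cortex_thickness / config.n_cortex_layers)
    c_p = np.sqrt((config.bulk_penalty + 2.0 * config.mu * config.stiff_final)
                  / config.density)
    dt = config.dt_safety * h_min / c_p

    top_ids = top_ids_flat
    t_end = config.ramp_time + config.settle_time
    times, gs, txs, ths, kes, ses, dets = [], [], [], [], [], [], []
    status = "grown"
    t = 0.0
    amp_stop = config.amplitude_stop_factor * config.cortex_thickness

    # kernel growth/stiffness parameters; frozen once the fold has formed so
    # the pattern can relax to (near) equilibrium before it is recorded
    phase = "ramp"
    k_mu0, k_smul = mu0, smul
    k_gmax, k_ramp = config.g_max, config.ramp_time
    stiff_ramp = config.stiff_ramp_fraction * config.ramp_time
    k_sramp = stiff_ramp
    k_damp = config.damping
    hold_t0 = None
    frac_hold = None
    amp_detect = config.detect_amp_factor * config.cortex_thickness

    def stiff_fraction(t_now):
        return min(max(t_now, 0.0) / stiff_ramp, 1.0)

    def current_fields(t_now):
        if phase == "ramp":
            sfrac = stiff_fraction(t_now)
            return growth.g_elements(t_now), mu0 * (1.0 + (smul - 1.0) * sfrac)
        g_elem = 1.0 + gmul * (growth.baseline(hold_t0) - 1.0)
        return g_elem, mu0 * (1.0 + (smul - 1.0) * frac_hold)

    max_frames = int(np.ceil((t_end + config.hold_settle_time)
                             / (dt * config.steps_per_frame))) + 4
    for _ in range(max_frames):
        if d == 2:
            rc = _kernels.relax2d(x, v, mesh.elements, disc.gradN0, disc.wdet,
                                  gmul, k_mu0, k_smul, bulk, mass, k_damp,
                                  dt, t, config.steps_per_frame,
                                  k_ramp, k_sramp, k_gmax,
                                  np.ascontiguousarray(free[:, 0]),
                                  np.ascontiguousarray(free[:, 1]))
        else:
            rc = _kernels.relax3d(x, v, mesh.elements, disc.gradN0, disc.wdet,
                                  gmul, k_mu0, k_smul, bulk, mass, k_damp,
                                  dt, t, config.steps_per_frame,
                                  k_ramp, k_sramp, k_gmax, free)
        if rc != _kernels.OK:
            raise RuntimeError(f"element inversion at t={t:.3f}, "
                               f"step {rc} of the current frame")
        if not np.isfinite(x).all():
            raise RuntimeError(f"numerical blow-up (non-finite nodes) at t={t:.3f}")
        t += config.steps_per_frame * dt
        g_elem, mu_elem = current_fields(t)
        ke = 0.5 * float((mass[:, None] * v * v).sum())
        se = total_energy(disc, x, g_elem, mu_elem, bulk)
        state = evaluate_state(disc, x, g_elem, mu_elem, bulk)
        times.append(t)
        gs.append(growth.baseline(min(t, hold_t0) if hold_t0 is not None else t))
        if d == 2:
            txs.append(x[top_ids, 0].copy())
            ths.append(x[top_ids, 1].copy())
        else:  # record the centerline profile of the 3D top surface
            ypos = x[top_ids, 1]
            mid = np.abs(ypos - np.median(ypos)) < config.dx_cortex
            txs.append(x[top_ids[mid], 0].copy())
            ths.append(x[top_ids[mid], 2].copy())
        kes.append(ke)
        ses.append(se)
        dets.append(float(np.abs(state.center_detA() - 1.0).max()))

        xx, hh = txs[-1], ths[-1]
        resid = hh - np.polyval(np.polyfit(xx, hh, 1), xx)
        amp = resid.max() - resid.min()
        contact = d == 2 and _top_contact(np.column_stack([xx, hh]),
                                          config.contact_gap)
        if phase == "ramp" and (amp >= amp_detect or contact or t >= t_end):
            if amp < 0.1 * config.cortex_thickness:
                status = "no_instability"
                break
            # freeze growth and stiffness at their current levels and let the
            # instability develop/relax under stronger damping
            phase = "hold"
            hold_t0 = t
            frac_hold = stiff_fraction(t)
            status = "contact" if contact else \
                ("folded" if amp >= amp_detect else "grown")
            k_mu0 = mu0 * (1.0 + (smul - 1.0) * frac_hold)
            k_smul = np.ones_like(smul)
            k_gmax = growth.baseline(t)
            k_ramp = 1e-12  # ramp fraction saturates immediately
            k_sramp = 1e-12
            k_damp = config.hold_damping
        elif phase == "hold":
            if contact and status != "contact":
                status = "contact"
            if amp >= amp_detect and status == "grown":
                status = "folded"
            settled = se > 0 and ke / se <= config.quasistatic_ratio
            if contact or settled or t - hold_t0 >= config.hold_settle_time:
                break

    g_elem, mu_elem = current_fields(t)
    final_state = evaluate_state(disc, x, g_elem, mu_elem, bulk)
    # frames can have unequal lengths in 3D centerline mode; pad by truncation
    m = min(len(a) for a in txs)
    return SimResult(times=np.asarray(times), g=np.asarray(gs),
                     top_x=np.asarray([a[:m] for a in txs]),
                     top_h=np.asarray([a[:m] for a in ths]),
                     kinetic=np.asarray(kes), strain=np.asarray(ses),
                     max_det_err=np.asarray(dets), status=status,
                     config=config, seed=config.seed, final_state=final_state,
                     center=config.length / 2.0)
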