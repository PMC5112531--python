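"""Synthetic inputs: longitudinal cortical surface pairs, seeded perturbation
fields for the growth simulator, and the packaged gyral/sulcal parcel
thickness table.

The surface generator emulates the longitudinal structure of a fetal
white/pial surface series over pseudo-gestational weeks 25-31: a corrugated
sheet whose ridges ("gyral" vertices, positive generative curvature) thicken
at a faster linear rate than its valleys ("sulcal" vertices), with i.i.d.
Gaussian residuals around the linear trajectory.  All timepoints share one
mesh topology, so cross-time vertex correspondence is the identity -- the
stand-in for spherical registration, which is out of scope.
"""

from __future__ import annotations

import importlib.resources as resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .surfaces import SurfaceSeries, TriSurface

#: Pseudo-gestational weeks spanned by a synthetic series.
WEEKS = tuple(range(25, 32))

#: Minimum admissible thickness (mm); trajectories are floored here.
MIN_THICKNESS = 0.1


@dataclass
class SynthGrowthParams:
    """Generative parameters for a synthetic longitudinal surface series.

    Defaults for the growth slopes and residual noise follow the fetal
    growth-rate statistics (gyral 0.35, sulcal 0.10, sd 0.26 mm/week);
    geometry defaults give a 200 x 200 mm sheet with 4 sinusoidal ridges
    of 5 mm amplitude on a 60 x 60 vertex grid; the ~3.4 mm vertex spacing
    keeps the closest-vertex thickness measurement exact across the
    gyral/sulcal thickness step (see the methods note).
    """

    gyral_slope: float = 0.35      # mm/week on ridge vertices
    sulcal_slope: float = 0.10     # mm/week on valley vertices
    noise_sd: float = 0.26         # mm, i.i.d. per vertex per timepoint
    baseline_thickness: float = 2.0  # mm at week 25
    fold_wavelength: float | None = None  # mm; derived from n_folds if None
    fold_amplitude: float = 5.0    # mm
    n_folds: int = 4
    seed: int = 0
    sheet_size: float = 200.0      # mm
    grid_n: int = 60               # vertices per side
    harmonic: float = 0.08         # relative amplitude of the 2nd-harmonic sinusoid
    phase: float = 0.4             # rad; keeps curvature zeros off grid lines

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_thickness <= 0:
            raise ValueError("baseline_thickness must be > 0")
        if self.fold_amplitude < 0:
            raise ValueError("fold_amplitude must be >= 0")
        if self.n_folds < 1:
            raise ValueError("n_folds must be >= 1")
        if self.grid_n < 4:
            raise ValueError("grid_n must be >= 4")
        if self.fold_wavelength is None:
            self.fold_wavelength = self.sheet_size / self.n_folds


@dataclass
class PerturbationField:
    """Small out-of-plane offsets seeded onto the top surface of a bilayer mesh."""

    node_ids: np.ndarray
    displacements: np.ndarray  # mm, zero mean, |d| <= amplitude
    amplitude: float
    seed: int


def _height_derivatives(params: SynthGrowthParams, x: np.ndarray, y: np.ndarray):
    """Analytic height z(x, y) of the corrugated sheet and its derivatives."""
    a = params.fold_amplitude
    k = 2.0 * np.pi / params.fold_wavelength
    e = params.harmonic
    p1 = params.phase
    p2 = p1 + 1.3
    u1 = k * x + p1
    u2 = 2.0 * k * x + p2
    z = a * (np.sin(u1) + e * np.sin(u2))
    zx = a * k * (np.cos(u1) + 2.0 * e * np.cos(u2))
    zy = np.zeros_like(z)
    zxx = -a * k * k * (np.sin(u1) + 4.0 * e * np.sin(u2))
    zyy = np.zeros_like(z)
    zxy = np.zeros_like(z)
    return z, zx, zy, zxx, zxy, zyy


def _graph_shape_operator_mpc(zx, zy, zxx, zxy, zyy):
    """Signed principal curvature of largest magnitude for a height field.

    Sign convention: convex toward the upward (outward) normal is positive,
    so ridges are positive and valleys negative.
    """
    n = np.sqrt(1.0 + zx**2 + zy**2)
    # First fundamental form inverse times second fundamental form (with the
    # second form taken against the upward normal: II = -H/n).
    e11 = 1.0 + zx**2
    e12 = zx * zy
    e22 = 1.0 + zy**2
    det = e11 * e22 - e12**2
    h11, h12, h22 = -zxx / n, -zxy / n, -zyy / n
    s11 = (e22 * h11 - e12 * h12) / det
    s12 = (e22 * h12 - e12 * h22) / det
    s21 = (-e12 * h11 + e11 * h12) / det
    s22 = (-e12 * h12 + e11 * h22) / det
    tr = s11 + s22
    dt = s11 * s22 - s12 * s21
    disc = np.sqrt(np.maximum(tr**2 / 4.0 - dt, 0.0))
    k1 = tr / 2.0 + disc
    k2 = tr / 2.0 - disc
    return np.where(np.abs(k1) >= np.abs(k2), k1, k2)


def _grid_faces(n: int) -> np.ndarray:
    """Two CCW triangles (seen from +z) per cell of an n x n vertex grid."""
    idx = np.arange(n * n).reshape(n, n)
    v00 = idx[:-1, :-1].ravel()
    v10 = idx[:-1, 1:].ravel()
    v01 = idx[1:, :-1].ravel()
    v11 = idx[1:, 1:].ravel()
    return np.concatenate([np.stack([v00, v10, v11], axis=1),
                           np.stack([v00, v11, v01], axis=1)])


def make_surface_series(params: SynthGrowthParams) -> SurfaceSeries:
    """Generate a 7-timepoint (weeks 25-31) white/pial surface series.

    The white surface is a corrugated sheet, identical at every timepoint;
    vertices are labelled gyral (+1) or sulcal (-1) by the sign of the
    analytic generative curvature.  Thickness of vertex v at week w is
    ``baseline + slope(v) * (w - 25) + eps`` with ``eps ~ N(0, noise_sd)``,
    floored at 0.1 mm; the pial surface is the white surface offset along
    the outward vertex normal by that thickness.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n = params.grid_n
    lin = np.linspace(0.0, params.sheet_size, n)
    yy, xx = np.meshgrid(lin, lin, indexing="ij")
    x, y = xx.ravel(), yy.ravel()
    z, zx, zy, zxx, zxy, zyy = _height_derivatives(params, x, y)
    gen_mpc = _graph_shape_operator_mpc(zx, zy, zxx, zxy, zyy)
    label = np.where(gen_mpc >= 0.0, 1, -1)
    slope = np.where(label > 0, params.gyral_slope, params.sulcal_slope)

    vertices = np.column_stack([x, y, z])
    faces = _grid_faces(n)
    base = TriSurface(vertices, faces)
    normals = base.vertex_normals()

    weeks = list(WEEKS)
    thickness = (params.baseline_thickness
                 + slope[None, :] * (np.asarray(weeks, float)[:, None] - weeks[0])
                 + rng.normal(0.0, params.noise_sd, (len(weeks), len(x))))
    thickness = np.maximum(thickness, MIN_THICKNESS)

    # Offsetting along the normal is injective only while the offset stays
    # below the radius of curvature on the concave side.
    kappa_concave = np.maximum(-gen_mpc, 0.0)
    worst = float((thickness.max(axis=0) * kappa_concave).max())
    if worst >= 0.95:
        i = int((thickness.max(axis=0) * kappa_concave).argmax())
        raise ValueError(
            "degenerate pial offset: fold_amplitude "
            f"{params.fold_amplitude} mm gives a radius of curvature "
            f"{1.0 / kappa_concave[i]:.2f} mm that cannot carry thickness "
            f"{thickness[:, i].max():.2f} mm without self-intersection")

    white, pial = [], []
    for i, _w in enumerate(weeks):
        ws = base.copy()
        ws.scalars["thickness"] = thickness[i].copy()
        ws.scalars["gyral_label"] = label.astype(np.float64)
        ws.scalars["gen_mpc"] = gen_mpc.copy()
        ps = TriSurface(vertices + normals * thickness[i][:, None], faces)
        white.append(ws)
        pial.append(ps)
    return SurfaceSeries(timepoints=weeks, white=white, pial=pial)


def make_perturbation(mesh, amplitude: float, seed: int) -> PerturbationField:
    """Uniform random out-of-plane offsets on the top-surface nodes of a
    bilayer mesh, de-meaned, with max |offset| <= amplitude.

    Deterministic given ``seed``.  Warns when the amplitude exceeds 10% of
    the cortex thickness, where it is no longer negligible relative to the
    model.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    if amplitude > 0.1 * mesh.cortex_thickness:
        warnings.warn("perturbation amplitude exceeds 10% of cortex thickness; "
                      "it should be negligible relative to the model",
                      stacklevel=2)
    node_ids = np.asarray(mesh.top_surface_nodes(), dtype=np.int64)
    if node_ids.size == 0:
        raise ValueError("mesh has no top-surface nodes")
    rng = np.random.default_rng(seed)
    d = rng.uniform(-amplitude, amplitude, node_ids.size)
    d -= d.mean()
    peak = np.abs(d).max()
    if peak > amplitude:
        d *= amplitude / peak
    return PerturbationField(node_ids=node_ids, displacements=d,
                             amplitude=amplitude, seed=seed)


def table1_fixture() -> pd.DataFrame:
    """The packaged gyral/sulcal parcel thickness table.

    30 gyral and 31 sulcal Destrieux parcels with their average cortical
    thickness (mm); columns ``parcel``, ``class``, ``thickness_mm``.
    """
    with resources.files("gyrogen.data").joinpath("table1_parcels.csv").open() as f:
        return pd.read_csv(f)
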