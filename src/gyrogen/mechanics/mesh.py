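"""Structured bilayer plate meshes.

The plate is a thin, finely meshed cortex band on top of a thicker,
coarsely meshed core.  2D meshes (plane-strain cross-section) use bilinear
quadrilaterals; 3D meshes use trilinear hexahedra.  A centered "special
area" element set inside the cortex carries the heterogeneous growth or
stiffness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CORE, CORTEX = 0, 1


@dataclass
class BilayerMesh:
    """Nodes/elements of the cortex+core plate.

    ``layer`` holds one label per element (CORTEX=1 for the top band of
    thickness ``cortex_thickness``, CORE=0 below); ``special`` flags the
    centered special-area elements (a subset of the cortex).
    """

    nodes: np.ndarray          # (n, dim) coordinates, mm
    elements: np.ndarray       # (e, 4) quads or (e, 8) hexes
    layer: np.ndarray          # (e,) CORE/CORTEX
    special: np.ndarray        # (e,) bool, subset of cortex
    cortex_thickness: float    # mm
    dims: tuple                # plate extents, mm
    dim: int = field(init=False)

    def __post_init__(self) -> None:
        self.dim = self.nodes.shape[1]
        if self.special.any() and not (self.layer[self.special] == CORTEX).all():
            raise ValueError("special area must lie inside the cortex")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def depth(self) -> float:
        return self.dims[-1]

    def top_surface_nodes(self) -> np.ndarray:
        """Node ids on the free (top) surface, sorted by in-plane position."""
        up = self.nodes[:, -1]
        ids = np.flatnonzero(np.abs(up - up.max()) < 1e-9)
        order = np.lexsort(self.nodes[ids, :-1].T[::-1])
        return ids[order]

    def bottom_nodes(self) -> np.ndarray:
        up = self.nodes[:, -1]
        return np.flatnonzero(np.abs(up - up.min()) < 1e-9)

    def lateral_nodes(self) -> list[np.ndarray]:
        """One node-id array per in-plane axis, both extreme faces combined."""
        out = []
        for ax in range(self.dim - 1):
            c = self.nodes[:, ax]
            out.append(np.flatnonzero((np.abs(c - c.min()) < 1e-9)
                                      | (np.abs(c - c.max()) < 1e-9)))
        return out

    def element_centers(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def undeformed_jacobians(self) -> np.ndarray:
        """Min corner Jacobian per element (positive for a valid mesh)."""
        from .solver import _shape_gradients
        dets = []
        for conn in self.elements:
            x = self.nodes[conn]
            corners = np.array(np.meshgrid(*[[-1.0, 1.0]] * self.dim)).T.reshape(-1, self.dim)
            best = np.inf
            for xi in corners:
                dN = _shape_gradients(xi, self.dim)
                best = min(best, np.linalg.det(dN.T @ x))
            dets.append(best)
        return np.asarray(dets)


def _depth_levels(depth: float, cortex_thickness: float, n_cortex_layers: int,
                  grading: float = 1.6, core_cap_ratio: float = 4.0) -> np.ndarray:
    """Through-depth node levels: fine cortex band on top, graded core below."""
    if cortex_thickness >= depth:
        raise ValueError("cortex thicker than the plate")
    if n_cortex_layers < 2:
        raise ValueError("need >= 2 element layers through the cortex")
    h = cortex_thickness / n_cortex_layers
    steps = [h] * n_cortex_layers
    remaining = depth - cortex_thickness
    s = h * grading
    core_steps = []
    while remaining > 1e-9:
        s = min(s, core_cap_ratio * h, remaining)
        core_steps.append(s)
        remaining -= s
        s *= grading
    # smooth the leftover into the last steps rather than leaving a sliver
    if len(core_steps) >= 2 and core_steps[-1] < 0.5 * core_steps[-2]:
        merged = core_steps.pop() + core_steps.pop()
        core_steps.append(merged / 2.0)
        core_steps.append(merged / 2.0)
    steps = core_steps[::-1] + steps  # bottom -> top
    levels = np.concatenate([[0.0], np.cumsum(steps)])
    levels[-1] = depth
    return levels


def build_bilayer_mesh(length: float = 100.0, depth: float = 25.0,
                       cortex_thickness: float = 2.0, dx_cortex: float = 1.25,
                       n_cortex_layers: int = 2, patch_width: float = 0.0,
                       width: float | None = None,
                       patch_full_thickness: bool = True) -> BilayerMesh:
    """Build a structured bilayer plate mesh.

    2D (plane-strain cross-section, the default) when ``width`` is None,
    3D (hexahedra) otherwise.  The mesh is uniform in-plane at the cortex
    resolution ``dx_cortex`` and graded through depth so core elements are
    coarser than cortex elements.  ``patch_width`` > 0 creates the centered
    special-area element set (full cortex thickness by default).
    """
    if patch_width > length or (width is not None and patch_width > width):
        raise ValueError("special-area patch wider than the plate")
    nx = max(2, int(round(length / dx_cortex))) + 1
    xs = np.linspace(0.0, length, nx)
    levels = _depth_levels(depth, cortex_thickness, n_cortex_layers)

    if width is None:
        xg, yg = np.meshgrid(xs, levels, indexing="xy")
        nodes = np.column_stack([xg.ravel(), yg.ravel()])
        n_cols, n_rows = nx, len(levels)

        def nid(i, j):
            return j * n_cols + i

        elems, lab = [], []
        for j in range(n_rows - 1):
            for i in range(n_cols - 1):
                elems.append([nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)])
                lab.append(CORTEX if 0.5 * (levels[j] + levels[j + 1])
                           > depth - cortex_thickness - 1e-9 else CORE)
        elements = np.asarray(elems, dtype=np.int64)
        layer = np.asarray(lab, dtype=np.int8)
        dims = (length, depth)
    else:
        ny = max(2, int(round(width / dx_cortex))) + 1
        ys = np.linspace(0.0, width, ny)
        zg, yg, xg = np.meshgrid(levels, ys, xs, indexing="ij")
        nodes = np.column_stack([xg.ravel(), yg.ravel(), zg.ravel()])
        n_cols, n_rows, n_lvls = nx, ny, len(levels)

        def nid3(i, j, k):
            return (k * n_rows + j) * n_cols + i

        elems, lab = [], []
        for k in range(n_lvls - 1):
            for j in range(n_rows - 1):
                for i in range(n_cols - 1):
                    elems.append([nid3(i, j, k), nid3(i + 1, j, k),
                                  nid3(i + 1, j + 1, k), nid3(i, j + 1, k),
                                  nid3(i, j, k + 1), nid3(i + 1, j, k + 1),
                                  nid3(i + 1, j + 1, k + 1), nid3(i, j + 1, k + 1)])
                    lab.append(CORTEX if 0.5 * (levels[k] + levels[k + 1])
                               > depth - cortex_thickness - 1e-9 else CORE)
        elements = np.asarray(elems, dtype=np.int64)
        layer = np.asarray(lab, dtype=np.int8)
        dims = (length, width, depth)

    mesh = BilayerMesh(nodes=nodes, elements=elements, layer=layer,
                       special=np.zeros(len(elements), dtype=bool),
                       cortex_thickness=cortex_thickness, dims=dims)
    if patch_width > 0:
        centers = mesh.element_centers()
        inside = np.ones(mesh.n_elements, dtype=bool)
        for ax, extent in enumerate(dims[:-1]):
            inside &= np.abs(centers[:, ax] - extent / 2.0) <= patch_width / 2.0
        inside &= layer == CORTEX
        if patch_full_thickness is False:
            inside &= centers[:, -1] > depth - cortex_thickness / 2.0
        mesh.special = inside
    return mesh
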