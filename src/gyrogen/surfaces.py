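"""Triangle-mesh surface containers.

``TriSurface`` is the in-memory representation of a white- or gray-matter
surface: vertices, faces, and named per-vertex scalar fields (thickness,
maximal principal curvature, growth-rate slope, R^2 ...).  ``SurfaceSeries``
holds a longitudinal sequence of white/pial surface pairs over gestational
weeks that share one mesh topology, so that vertex correspondence across
time is the identity map.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


@dataclass
class TriSurface:
    """A triangle mesh with per-vertex scalar fields.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array
        Indices into ``vertices``; consistent counterclockwise winding so
        that face normals point outward.
    scalars : dict of str -> (n,) float array
    """

    vertices: np.ndarray
    faces: np.ndarray
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (m, 3) array")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("faces reference vertices outside the vertex array")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted outward vertex normals."""
        return np.asarray(self.to_trimesh().vertex_normals, dtype=np.float64)

    def area(self) -> float:
        return float(self.to_trimesh().area)

    def is_manifold(self) -> bool:
        """Every edge shared by at most two faces."""
        m = self.to_trimesh()
        edges = np.sort(m.edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool((counts <= 2).all())

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy(),
                          {k: v.copy() for k, v in self.scalars.items()})

    def save_ply(self, path: str | Path) -> None:
        self.to_trimesh().export(str(path), encoding="ascii")

    @classmethod
    def load_ply(cls, path: str | Path) -> "TriSurface":
        m = trimesh.load(str(path), process=False)
        return cls(np.asarray(m.vertices), np.asarray(m.faces))


def topology_token(faces: np.ndarray, n_vertices: int) -> str:
    """Digest identifying a (vertex count, face list) topology."""
    h = hashlib.sha1()
    h.update(np.int64(n_vertices).tobytes())
    h.update(np.ascontiguousarray(faces, dtype=np.int64).tobytes())
    return h.hexdigest()[:16]


@dataclass
class SurfaceSeries:
    """Longitudinal white/pial surface pairs on a shared topology.

    ``timepoints`` are pseudo-gestational-week labels; ``white[i]`` and
    ``pial[i]`` are the surfaces at ``timepoints[i]``.  All surfaces must
    have identical vertex counts and face arrays (identity correspondence
    across time), asserted by ``topology_id``.
    """

    timepoints: list
    white: list
    pial: list
    topology_id: str = ""

    def __post_init__(self) -> None:
        if not (len(self.timepoints) == len(self.white) == len(self.pial)):
            raise ValueError("timepoints, white and pial must have equal length")
        toks = {topology_token(s.faces, s.n_vertices) for s in self.white + self.pial}
        if len(toks) != 1:
            raise ValueError("all surfaces in a series must share one topology")
        tok = toks.pop()
        if self.topology_id and self.topology_id != tok:
            raise ValueError("topology_id does not match the surfaces")
        self.topology_id = tok

    @property
    def n_vertices(self) -> int:
        return self.white[0].n_vertices

    def thickness_matrix(self) -> np.ndarray:
        """Per-timepoint 'thickness' scalar stacked as a (T, n) array."""
        return np.stack([s.scalars["thickness"] for s in self.white])
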