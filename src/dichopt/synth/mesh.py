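"""Synthetic cortical ribbon meshes (paired pial / white surfaces).

A ribbon is a pair of triangle meshes with 1:1 vertex correspondence and a
shared face list; the segment from a pial vertex to its white partner is
that vertex's cortical column.  Three fixture shapes are provided:

``slab``
    Two parallel planes — equivolume depth equals Euclidean depth.
``wedge``
    A cylindrical sector (pial at the outer radius), giving a constant
    per-vertex pial:white neighborhood-area ratio and an analytic
    equivolume solution, the canonical curvature fixture.
``sinusoidal``
    A folded sheet (both surfaces offset copies of a sine carpet).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MeshPair:
    """Corresponding pial and white triangle meshes defining a ribbon.

    Attributes
    ----------
    vertices_pial, vertices_white : (V, 3) float arrays, mm
        1:1 corresponding vertex coordinates (depth 0 and depth 1 ends of
        each cortical column).
    faces : (F, 3) int array
        Triangle vertex indices, shared by both surfaces.
    """

    vertices_pial: np.ndarray
    vertices_white: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices_pial = np.asarray(self.vertices_pial, dtype=float)
        self.vertices_white = np.asarray(self.vertices_white, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices_pial.shape != self.vertices_white.shape:
            raise ValueError("pial and white vertex arrays must have the same shape")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (F, 3) index array")

    @property
    def n_vertices(self) -> int:
        return self.vertices_pial.shape[0]

    def neighborhood_areas(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-vertex 1-ring neighborhood areas (mm^2) on each surface.

        Each triangle contributes one third of its area to each of its
        three vertices (barycentric area weighting).
        """
        a_p = _vertex_areas(self.vertices_pial, self.faces)
        a_w = _vertex_areas(self.vertices_white, self.faces)
        return a_p, a_w

    def column_vectors(self) -> np.ndarray:
        """(V, 3) vectors from pial to white vertices."""
        return self.vertices_white - self.vertices_pial


def _triangle_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = (vertices[faces[:, k]] for k in range(3))
    return 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=1)


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = _triangle_areas(vertices, faces)
    areas = np.zeros(vertices.shape[0])
    for k in range(3):
        np.add.at(areas, faces[:, k], tri / 3.0)
    return areas


def _grid_faces(nu: int, nv: int) -> np.ndarray:
    """Triangulate a regular (nu x nv) vertex grid."""
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[:-1, 1:].ravel()
    d = idx[1:, 1:].ravel()
    return np.concatenate([np.stack([a, b, c], 1), np.stack([b, d, c], 1)])


def make_cortical_ribbon(
    shape: str = "slab",
    n_vertices: int = 400,
    thickness: float = 2.0,
    extent: float = 20.0,
    area_ratio: float = 2.0,
    fold_amplitude: float = 2.0,
    fold_wavelength: float = 10.0,
) -> MeshPair:
    """Build a synthetic pial/white mesh pair.

    Parameters
    ----------
    shape :
        ``"slab"``, ``"wedge"`` or ``"sinusoidal"``.
    n_vertices :
        Approximate vertex count per surface (>= 4); realized on a square
        grid.
    thickness :
        Cortical thickness in mm (> 0).
    extent :
        Lateral extent of the sheet in mm (slab/sinusoidal), or the axial
        length of the wedge.
    area_ratio :
        Wedge only: target per-vertex pial:white neighborhood-area ratio
        (> 1), realized exactly by the outer/inner radius ratio.
    fold_amplitude, fold_wavelength :
        Sinusoidal only: fold geometry in mm.
    """
    if n_vertices < 4:
        raise ValueError("n_vertices must be >= 4")
    if thickness <= 0:
        raise ValueError("thickness must be positive")

    n_side = max(2, int(round(np.sqrt(n_vertices))))
    u = np.linspace(0.0, extent, n_side)
    faces = _grid_faces(n_side, n_side)

    if shape == "slab":
        xx, yy = np.meshgrid(u, u, indexing="ij")
        pial = np.stack([xx.ravel(), yy.ravel(), np.zeros(n_side**2)], 1)
        white = pial + np.array([0.0, 0.0, thickness])
        meta = {"shape": "slab"}
    elif shape == "wedge":
        if area_ratio <= 1:
            raise ValueError("wedge area_ratio must exceed 1")
        # Outer (pial) radius chosen so r_pial / r_white == area_ratio;
        # triangle areas on a cylindrical sector scale exactly with radius.
        r_w = thickness / (area_ratio - 1.0)
        r_p = r_w + thickness
        # split the vertex budget for ~isotropic spacing at mid-radius
        arc = 0.5 * (r_p + r_w) * (2 * np.pi / 3)
        n_theta = max(2, int(round(np.sqrt(n_vertices * arc / extent))))
        n_z = max(2, n_vertices // n_theta)
        theta = np.linspace(-np.pi / 3, np.pi / 3, n_theta)
        tt, zz = np.meshgrid(theta, np.linspace(0.0, extent, n_z), indexing="ij")
        faces = _grid_faces(n_theta, n_z)
        pial = np.stack(
            [r_p * np.cos(tt.ravel()), r_p * np.sin(tt.ravel()), zz.ravel()], 1
        )
        white = np.stack(
            [r_w * np.cos(tt.ravel()), r_w * np.sin(tt.ravel()), zz.ravel()], 1
        )
        meta = {"shape": "wedge", "r_pial": r_p, "r_white": r_w, "area_ratio": area_ratio}
    elif shape == "sinusoidal":
        xx, yy = np.meshgrid(u, u, indexing="ij")
        zz = fold_amplitude * np.sin(2 * np.pi * xx / fold_wavelength)
        pial = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], 1)
        white = pial + np.array([0.0, 0.0, thickness])
        meta = {"shape": "sinusoidal"}
    else:
        raise ValueError(f"unknown ribbon shape {shape!r}")

    mesh = MeshPair(pial, white, faces, metadata=meta)
    tri_p = _triangle_areas(mesh.vertices_pial, mesh.faces)
    tri_w = _triangle_areas(mesh.vertices_white, mesh.faces)
    if np.any(tri_p <= 0) or np.any(tri_w <= 0):
        raise ValueError("ribbon has degenerate (zero-area) faces")
    return mesh


def validate_ribbon(mesh: MeshPair) -> dict:
    """Check that a mesh pair is a usable cortical ribbon.

    Verifies finite coordinates, non-degenerate faces on both surfaces,
    strictly positive column lengths, and that no column direction flips
    relative to the mean column direction of its faces (a folded-through
    ribbon would self-intersect).  Returns a report dict with ``valid``
    plus individual flags; raises nothing.
    """
    report: dict = {}
    report["finite"] = bool(
        np.isfinite(mesh.vertices_pial).all() and np.isfinite(mesh.vertices_white).all()
    )
    tri_p = _triangle_areas(mesh.vertices_pial, mesh.faces)
    tri_w = _triangle_areas(mesh.vertices_white, mesh.faces)
    report["nondegenerate_faces"] = bool((tri_p > 1e-12).all() and (tri_w > 1e-12).all())
    cols = mesh.column_vectors()
    lengths = np.linalg.norm(cols, axis=1)
    report["positive_thickness"] = bool((lengths > 1e-9).all())
    # Columns within each face should agree in direction (no local eversion).
    face_cols = cols[mesh.faces]  # (F, 3, 3)
    mean_dir = face_cols.mean(axis=1)
    dots = np.einsum("fij,fj->fi", face_cols, mean_dir)
    report["consistent_columns"] = bool((dots > 0).all())
    report["valid"] = all(
        report[k]
        for k in ("finite", "nondegenerate_faces", "positive_thickness", "consistent_columns")
    )
    return report
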