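"""Mesh morphometry: surface area, biovolume, extents, equivalent diameters.

The quantities mirror the standard phytoplankton size descriptors: total
surface area (μm²), biovolume (μm³, the volume enclosed by the outer cell
surface), the three principal extents (length ≥ width ≥ depth, μm) and the
spherical-equivalent diameters

    d_esa = sqrt(SA / π)          (sphere of equal surface area)
    d_esv = (6 V / π)^(1/3)       (sphere of equal volume)

By the isoperimetric inequality d_esa ≥ d_esv for every closed surface, with
equality only for a sphere; the gap between the two diameters is therefore a
simple shape-irregularity index.

Biovolume requires a watertight, consistently oriented mesh; watertightness is
also what a 3D-print slicer needs, so the same QC flags serve both purposes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .mesh_io import TriangleMesh

__all__ = [
    "MorphometryReport",
    "NotWatertightError",
    "surface_area",
    "biovolume",
    "equivalent_diameters",
    "principal_extents",
    "axis_aligned_extents",
    "check_watertight",
    "fix_orientation",
    "measure",
]


class NotWatertightError(ValueError):
    """Raised when volume is requested of an open or inconsistently wound mesh."""


@dataclass(frozen=True)
class MorphometryReport:
    """Morphometric summary of one mesh (all lengths in μm)."""

    surface_area: float  # μm²
    biovolume: float  # μm³
    length: float
    width: float
    depth: float
    d_esa: float  # diameter of the sphere with equal surface area
    d_esv: float  # diameter of the sphere with equal volume
    sa_to_v: float  # μm⁻¹
    watertight: bool
    consistently_oriented: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _cross_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-face area vector magnitudes times two (‖(v1−v0)×(v2−v0)‖)."""
    v = mesh.vertices
    f = mesh.faces
    return np.linalg.norm(
        np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]]), axis=1
    )


def surface_area(mesh: TriangleMesh) -> float:
    """Total surface area: Σ_faces ½‖(v1−v0)×(v2−v0)‖.

    Invariant under rigid motion and vertex re-ordering; degenerate faces
    contribute zero.
    """
    return float(0.5 * _cross_areas(mesh).sum())


def biovolume(mesh: TriangleMesh, *, auto_fix_orientation: bool = False) -> float:
    """Enclosed volume by the divergence theorem: |Σ_faces v0·(v1×v2)| / 6.

    The signed-tetrahedron sum is taken with an absolute value at the end, so
    a globally inverted mesh (all windings flipped, a convention found in STL
    files in the wild) still yields a positive volume.  Requires a watertight,
    consistently oriented mesh; pass ``auto_fix_orientation=True`` to repair
    mixed windings first.

    Raises
    ------
    NotWatertightError
        If the mesh has boundary edges, or mixed winding without
        ``auto_fix_orientation``.
    """
    watertight, oriented, n_boundary = check_watertight(mesh)
    if not watertight:
        raise NotWatertightError(
            f"mesh is not watertight: {n_boundary} boundary edge(s)"
        )
    if not oriented:
        if not auto_fix_orientation:
            raise NotWatertightError(
                "mesh winding is inconsistent; pass auto_fix_orientation=True to repair"
            )
        mesh = fix_orientation(mesh)
    v = mesh.vertices
    f = mesh.faces
    signed = np.einsum("ij,ij->i", v[f[:, 0]], np.cross(v[f[:, 1]], v[f[:, 2]]))
    return float(abs(signed.sum()) / 6.0)


def equivalent_diameters(surface_area: float, biovolume: float) -> tuple[float, float]:
    """Spherical-equivalent diameters (d_esa, d_esv) from SA (μm²) and V (μm³).

    d_esa = sqrt(SA/π); d_esv = (6V/π)^(1/3).
    """
    if surface_area <= 0 or biovolume <= 0:
        raise ValueError("surface area and biovolume must be positive")
    d_esa = math.sqrt(surface_area / math.pi)
    d_esv = (6.0 * biovolume / math.pi) ** (1.0 / 3.0)
    return d_esa, d_esv


def principal_extents(mesh: TriangleMesh) -> tuple[float, float, float]:
    """Extents along the principal axes of the mesh surface.

    The axes are the eigenvectors of the exact area-weighted covariance of the
    surface, ∫ (x − x̄)(x − x̄)ᵀ dA evaluated in closed form per triangle, so
    the result is independent of how the surface happens to be triangulated
    (a per-vertex weighting would be skewed by, e.g., the diagonal split of a
    quad).  The returned extents (max − min vertex projection) are sorted
    descending, so length ≥ width ≥ depth.  Rotation invariant.  Sign/ordering
    ambiguity of eigenvectors does not affect extents; exact ties in extent
    are broken by the lexicographic order of the corresponding
    (sign-normalised) axis vectors, keeping output deterministic.
    """
    if mesh.n_vertices < 4:
        raise ValueError("need at least 4 vertices for principal extents")
    v = mesh.vertices
    f = mesh.faces
    areas = 0.5 * _cross_areas(mesh)
    total = float(areas.sum())
    if total <= 0:
        raise ValueError("degenerate mesh: zero total face area")
    tri = v[f]  # (m, 3, 3)
    tri_centroids = tri.mean(axis=1)
    centroid = (areas[:, None] * tri_centroids).sum(axis=0) / total
    # closed form: ∫_T x xᵀ dA = (A/12) (Σ_i v_i v_iᵀ + s sᵀ) with s = Σ_i v_i
    centred = tri - centroid
    s = centred.sum(axis=1)
    second = (np.einsum("tik,til->tkl", centred, centred)
              + np.einsum("tk,tl->tkl", s, s))
    cov = np.einsum("t,tkl->kl", areas / 12.0, second) / total
    centred = v - centroid
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        raise ValueError("degenerate (flat or linear) vertex cloud")
    # normalise eigenvector signs so the largest-magnitude entry is positive
    for k in range(3):
        col = eigvecs[:, k]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            eigvecs[:, k] = -col
    proj = centred @ eigvecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = sorted(range(3), key=lambda k: (-extents[k], tuple(eigvecs[:, k])))
    e = extents[order]
    return float(e[0]), float(e[1]), float(e[2])


def axis_aligned_extents(mesh: TriangleMesh) -> tuple[float, float, float]:
    """Extents of the axis-aligned bounding box, sorted descending.

    Alternative to :func:`principal_extents` for meshes already posed in a
    meaningful frame (e.g. length along x after manual alignment).
    """
    e = np.sort(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0))[::-1]
    return float(e[0]), float(e[1]), float(e[2])


def _edge_tables(mesh: TriangleMesh):
    f = mesh.faces
    # directed edges of each face, in winding order
    directed = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    undirected = np.sort(directed, axis=1)
    return directed, undirected


def check_watertight(mesh: TriangleMesh) -> tuple[bool, bool, int]:
    """QC flags: (watertight, consistently_oriented, boundary_edge_count).

    Watertight iff every undirected edge is shared by exactly two faces (the
    condition a print slicer needs).  Consistently oriented iff every shared
    edge is traversed once in each direction, i.e. neighbouring faces agree on
    which side is outside.
    """
    if mesh.n_faces == 0:
        return False, True, 0
    directed, undirected = _edge_tables(mesh)
    _, und_inverse, und_counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    boundary = int((und_counts[und_inverse] == 1).sum())
    watertight = bool((und_counts == 2).all())
    # orientation: every directed edge must be unique (each undirected edge is
    # then traversed once per direction wherever it is shared twice)
    n_unique_directed = len(np.unique(directed, axis=0))
    oriented = n_unique_directed == len(directed)
    return watertight, oriented, boundary


def fix_orientation(mesh: TriangleMesh) -> TriangleMesh:
    """Repair mixed winding by propagating one orientation per connected shell.

    Breadth-first walk over the face-adjacency graph; a face is flipped when it
    traverses a shared edge in the same direction as its already-visited
    neighbour.  The absolute orientation (outward vs inward) of each shell is
    whatever the first face visited had; volume computations take an absolute
    value, so this is sufficient.
    """
    f = mesh.faces.copy()
    m = len(f)
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for i in range(m):
        for a, b in ((f[i, 0], f[i, 1]), (f[i, 1], f[i, 2]), (f[i, 2], f[i, 0])):
            edge_faces.setdefault((min(a, b), max(a, b)), []).append(i)

    def directed_edges(tri):
        return ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))

    visited = np.zeros(m, dtype=bool)
    for seed in range(m):
        if visited[seed]:
            continue
        visited[seed] = True
        queue = [seed]
        while queue:
            i = queue.pop()
            for a, b in directed_edges(f[i]):
                for j in edge_faces[(min(a, b), max(a, b))]:
                    if j == i or visited[j]:
                        continue
                    # consistent neighbours traverse the shared edge oppositely
                    if (a, b) in directed_edges(f[j]):
                        f[j, [1, 2]] = f[j, [2, 1]]
                    visited[j] = True
                    queue.append(j)
    return TriangleMesh(mesh.vertices.copy(), f, name=mesh.name,
                        source_format=mesh.source_format)


def measure(mesh: TriangleMesh, *, auto_fix_orientation: bool = False,
            extents: str = "principal") -> MorphometryReport:
    """Full morphometric report for one mesh.

    ``extents`` selects ``"principal"`` (default) or ``"aabb"`` axis-aligned
    bounding-box extents.
    """
    watertight, oriented, _ = check_watertight(mesh)
    sa = surface_area(mesh)
    vol = biovolume(mesh, auto_fix_orientation=auto_fix_orientation)
    if extents == "principal":
        length, width, depth = principal_extents(mesh)
    elif extents == "aabb":
        length, width, depth = axis_aligned_extents(mesh)
    else:
        raise ValueError(f"unknown extents mode {extents!r}")
    d_esa, d_esv = equivalent_diameters(sa, vol)
    return MorphometryReport(
        surface_area=sa,
        biovolume=vol,
        length=length,
        width=width,
        depth=depth,
        d_esa=d_esa,
        d_esv=d_esv,
        sa_to_v=sa / vol,
        watertight=watertight,
        consistently_oriented=oriented,
    )
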