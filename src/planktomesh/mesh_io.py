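"""Reading and writing triangle meshes in STL (binary and ASCII) and OBJ.

STL stores an unindexed triangle soup; on load, vertices that agree exactly
(bitwise float equality) are merged into a single indexed vertex so that
topological queries (watertightness, orientation) are meaningful.  OBJ is read
geometry-only: ``v`` and ``f`` records; texture/normal indices in ``v/vt/vn``
face references are ignored, and faces with more than three vertices are
fan-triangulated.

Coordinates are treated as micrometres by default throughout the toolkit; STL
and OBJ carry no unit metadata, so a scale factor can be applied at the CLI.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["TriangleMesh", "MeshFormatError", "read_mesh", "write_mesh"]

_STL_HEADER_BYTES = 80
_STL_RECORD_BYTES = 50  # 12 floats (normal + 3 vertices) + uint16 attribute


class MeshFormatError(ValueError):
    """Raised when a mesh file is malformed or a mesh violates invariants."""


@dataclass
class TriangleMesh:
    """Indexed triangle mesh with micrometre coordinates.

    Faces are triples of 0-based vertex indices; counter-clockwise winding
    (seen from outside) encodes the outward normal.
    """

    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray  # (m, 3) int64
    name: str = ""
    source_format: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (m, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshFormatError("non-finite vertex coordinate")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise MeshFormatError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def degenerate_faces(self) -> np.ndarray:
        """Boolean mask of faces that repeat a vertex index."""
        f = self.faces
        return (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])

    def scaled(self, factor: float) -> "TriangleMesh":
        """Return a copy with coordinates multiplied by ``factor``."""
        return TriangleMesh(self.vertices * float(factor), self.faces.copy(),
                            name=self.name, source_format=self.source_format)


def _index_soup(triangles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge exactly-equal vertices of an (m, 3, 3) triangle soup.

    Exact bitwise equality keeps the operation deterministic; a tolerance-based
    weld would be a separate, lossy repair step.
    """
    flat = triangles.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return vertices, faces


# ---------------------------------------------------------------------------
# STL
# ---------------------------------------------------------------------------

def _looks_binary_stl(data: bytes) -> bool:
    if len(data) < _STL_HEADER_BYTES + 4:
        return False
    (n_tri,) = struct.unpack_from("<I", data, _STL_HEADER_BYTES)
    expected = _STL_HEADER_BYTES + 4 + n_tri * _STL_RECORD_BYTES
    return len(data) == expected


def _read_stl_binary(data: bytes, name: str) -> tuple[np.ndarray, np.ndarray]:
    (n_tri,) = struct.unpack_from("<I", data, _STL_HEADER_BYTES)
    body = np.frombuffer(data, dtype=np.uint8,
                         offset=_STL_HEADER_BYTES + 4).reshape(n_tri, _STL_RECORD_BYTES)
    floats = body[:, :48].copy().view("<f4").reshape(n_tri, 4, 3).astype(np.float64)
    triangles = floats[:, 1:, :]  # drop the stored normal; geometry is authoritative
    return _index_soup(triangles)


def _read_stl_ascii(text: str) -> tuple[np.ndarray, np.ndarray]:
    coords: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line.startswith("vertex"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MeshFormatError(f"malformed vertex at line {lineno}: {line!r}")
        try:
            coords.append([float(p) for p in parts[1:]])
        except ValueError as exc:
            raise MeshFormatError(f"bad coordinate at line {lineno}: {line!r}") from exc
    if not coords or len(coords) % 3:
        raise MeshFormatError(f"ASCII STL vertex count {len(coords)} is not a multiple of 3")
    triangles = np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)
    return _index_soup(triangles)


# ---------------------------------------------------------------------------
# OBJ
# ---------------------------------------------------------------------------

def _read_obj(text: str) -> tuple[np.ndarray, np.ndarray]:
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0] == "v":
            if len(parts) < 4:
                raise MeshFormatError(f"malformed v record at line {lineno}")
            try:
                vertices.append([float(p) for p in parts[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"bad coordinate at line {lineno}") from exc
        elif parts[0] == "f":
            if len(parts) < 4:
                raise MeshFormatError(f"face with <3 vertices at line {lineno}")
            idx = []
            for token in parts[1:]:
                head = token.split("/")[0]  # ignore vt/vn references
                try:
                    i = int(head)
                except ValueError as exc:
                    raise MeshFormatError(f"bad face index at line {lineno}") from exc
                # OBJ is 1-based; negative indices count from the end
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            # fan triangulation for quads and larger polygons
            for k in range(1, len(idx) - 1):
                faces.append([idx[0], idx[k], idx[k + 1]])
        # vt, vn, mtllib, usemtl, o, g, s: geometry-irrelevant, skipped
    return (np.asarray(vertices, dtype=np.float64).reshape(-1, 3),
            np.asarray(faces, dtype=np.int64).reshape(-1, 3))


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def read_mesh(path: str | Path, drop_degenerate: bool = True) -> TriangleMesh:
    """Read an STL (binary or ASCII) or OBJ file into a :class:`TriangleMesh`.

    Format is auto-detected: binary STL by the 80-byte-header/triangle-count
    size consistency, ASCII STL by a leading ``solid`` keyword, otherwise OBJ.
    Shared STL vertices are merged by exact coordinate equality.

    Parameters
    ----------
    path:
        File to read.
    drop_degenerate:
        If true (default), faces repeating a vertex index are silently dropped;
        if false, their presence raises :class:`MeshFormatError`.
    """
    path = Path(path)
    data = path.read_bytes()
    name = path.stem

    if _looks_binary_stl(data):
        vertices, faces = _read_stl_binary(data, name)
        fmt = "stl-binary"
    else:
        try:
            text = data.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise MeshFormatError(f"{path}: neither a valid binary STL nor text") from exc
        stripped = text.lstrip()
        if stripped.startswith("solid") and "facet" in text:
            vertices, faces = _read_stl_ascii(text)
            fmt = "stl-ascii"
        else:
            vertices, faces = _read_obj(text)
            fmt = "obj"

    mesh = TriangleMesh(vertices, faces, name=name, source_format=fmt)
    bad = mesh.degenerate_faces()
    if bad.any():
        if not drop_degenerate:
            raise MeshFormatError(f"{path}: {int(bad.sum())} degenerate face(s)")
        mesh = TriangleMesh(mesh.vertices, mesh.faces[~bad], name=name, source_format=fmt)
    return mesh


def _face_normals(mesh: TriangleMesh) -> np.ndarray:
    v = mesh.vertices
    f = mesh.faces
    n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(norm > 0, n / norm, 0.0)
    return unit


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh as ``stl-binary``, ``stl-ascii`` or ``obj``.

    Binary STL uses little-endian 32-bit floats, an 80-byte header, 50-byte
    facet records and a zero attribute byte count, so a 12-face mesh produces
    exactly ``84 + 12*50`` bytes.  If ``format`` is omitted it is inferred from
    the file suffix (``.stl`` -> binary STL, ``.obj`` -> OBJ).
    """
    path = Path(path)
    if mesh.n_faces == 0:
        raise MeshFormatError("refusing to write an empty mesh")
    if format is None:
        suffix = path.suffix.lower()
        format = {"(none)": None, ".stl": "stl-binary", ".obj": "obj"}.get(suffix)
        if format is None:
            raise MeshFormatError(f"cannot infer format from suffix {suffix!r}")
    if format == "stl-binary":
        _write_stl_binary(mesh, path)
    elif format == "stl-ascii":
        _write_stl_ascii(mesh, path)
    elif format == "obj":
        _write_obj(mesh, path)
    else:
        raise MeshFormatError(f"unknown format {format!r}")


def _write_stl_binary(mesh: TriangleMesh, path: Path) -> None:
    header = mesh.name.encode("utf-8", "replace")[:_STL_HEADER_BYTES]
    header = header.ljust(_STL_HEADER_BYTES, b"\0")
    normals = _face_normals(mesh).astype("<f4")
    tris = mesh.vertices[mesh.faces].astype("<f4")  # (m, 3, 3)
    records = np.zeros((mesh.n_faces, _STL_RECORD_BYTES), dtype=np.uint8)
    records[:, :12] = normals.view(np.uint8).reshape(mesh.n_faces, 12)
    records[:, 12:48] = tris.reshape(mesh.n_faces, 9).view(np.uint8).reshape(mesh.n_faces, 36)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(struct.pack("<I", mesh.n_faces))
        fh.write(records.tobytes())


def _write_stl_ascii(mesh: TriangleMesh, path: Path) -> None:
    normals = _face_normals(mesh)
    tris = mesh.vertices[mesh.faces]
    lines = [f"solid {mesh.name}"]
    for n, tri in zip(normals, tris):
        lines.append(f"  facet normal {n[0]:.9g} {n[1]:.9g} {n[2]:.9g}")
        lines.append("    outer loop")
        for v in tri:
            lines.append(f"      vertex {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append(f"endsolid {mesh.name}")
    Path(path).write_text("\n".join(lines) + "\n")


def _write_obj(mesh: TriangleMesh, path: Path) -> None:
    lines = [f"# {mesh.name}"] if mesh.name else []
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for f in mesh.faces:
        lines.append(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
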