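"""Synthetic fixtures: watertight plankton-like meshes and SEM-like image pairs.

Every mesh generator produces a closed, consistently oriented surface whose
exact surface area and volume are known from :mod:`.shape_models`, so the
morphometry code can be validated against closed forms without any external
model files.  Presets approximate the gross morphology of the two study
organisms: a pyriform drop for a Prorocentrum micans-like dinoflagellate
(length 40 μm, width 25 μm) and an elongated prolate spheroid for a
Halamphora-like diatom (length ~16.3 μm, width ~3.9 μm).

The image-pair generator renders a filled ellipse with a radial intensity
gradient on a dark background, then applies a known monotone brightness
transform plus optional Gaussian noise — the ground truth needed to test
masking, histogram matching and the per-pixel relative-difference statistic.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .image_compare import GrayImage
from .mesh_io import TriangleMesh
from .shape_models import GeometricShape, drop_profile, prolate_spheroid

__all__ = [
    "make_icosphere",
    "make_revolution",
    "make_preset_mesh",
    "jitter_mesh",
    "make_image_pair",
    "gamma_transform",
    "PRESETS",
]

MAX_REFINEMENT = 7  # 20·4^7 ≈ 328k faces: keeps fixtures desk-scale


# ---------------------------------------------------------------------------
# Icosphere
# ---------------------------------------------------------------------------

def make_icosphere(radius: float, subdivisions: int = 3) -> TriangleMesh:
    """Geodesic sphere: regular icosahedron, each edge bisected ``subdivisions``
    times, all vertices projected onto the sphere of the given radius.

    The result has exactly ``20 * 4**subdivisions`` faces, is watertight and
    consistently outward-oriented, and every vertex lies at distance
    ``radius`` from the origin to float precision.  Its area and volume
    converge to 4πr² and (4/3)πr³ from below (inscribed polyhedron).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 <= subdivisions <= MAX_REFINEMENT:
        raise ValueError(f"subdivisions must be in [0, {MAX_REFINEMENT}]")

    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)

    for _ in range(subdivisions):
        verts_list = [v for v in verts]
        midpoint: dict[tuple[int, int], int] = {}

        def mid(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            if key not in midpoint:
                midpoint[key] = len(verts_list)
                verts_list.append((verts_list[i] + verts_list[j]) / 2.0)
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = mid(a, b), mid(b, c), mid(c, a)
            new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=np.int64)

    verts = verts * (radius / np.linalg.norm(verts, axis=1, keepdims=True))
    return TriangleMesh(verts, faces, name=f"icosphere_r{radius:g}_s{subdivisions}")


# ---------------------------------------------------------------------------
# Surfaces of revolution
# ---------------------------------------------------------------------------

def _revolution_stations(shape: GeometricShape, n_z: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Interior (z, r>0) stations plus the two pole z-coordinates.

    Curved sections are sampled by angle rather than uniformly in z, so the
    inscribed surface converges quickly to the closed form.
    """
    d = shape.dimensions
    if shape.kind in ("prolate_spheroid", "oblate_spheroid"):
        a, c = d["a"], d["c"]
        theta = np.linspace(0.0, math.pi, n_z + 2)[1:-1]
        return c * np.cos(theta)[::-1], a * np.sin(theta)[::-1], -c, c
    if shape.kind == "capsule":
        r, h = d["r"], d["h"]
        n_cap = max(2, n_z // 4)
        n_cyl = max(1, n_z - 2 * n_cap)
        phi = np.linspace(0.0, math.pi / 2.0, n_cap + 1)[1:]
        z_bot = -h / 2.0 - r * np.cos(phi)
        r_bot = r * np.sin(phi)
        z_cyl = np.linspace(-h / 2.0, h / 2.0, n_cyl + 2)[1:-1]
        r_cyl = np.full_like(z_cyl, r)
        z_top = h / 2.0 + r * np.cos(phi)[::-1]
        r_top = r * np.sin(phi)[::-1]
        z = np.concatenate([z_bot, z_cyl, z_top])
        rr = np.concatenate([r_bot, r_cyl, r_top])
        return z, rr, -h / 2.0 - r, h / 2.0 + r
    if shape.kind == "drop_of_revolution":
        length = d["length"]
        z_s = d["shoulder"] * length
        half = n_z // 2
        # anterior quarter-ellipse sampled by angle (rounded tip)
        t = np.linspace(0.0, math.pi / 2.0, half + 1)[1:]
        z_ant = z_s - z_s * np.cos(t)
        u = np.linspace(0.0, 1.0, n_z - half + 1)[1:-1]
        z_post = z_s + u * (length - z_s)
        z = np.concatenate([z_ant, z_post])
        rr = np.array([shape.profile(float(zz)) for zz in z])
        return z, rr, 0.0, length
    raise ValueError(f"cannot revolve shape kind {shape.kind!r}")


def make_revolution(shape: GeometricShape, n_theta: int = 64, n_z: int = 64) -> TriangleMesh:
    """Tessellate a solid of revolution (spheroid, capsule or drop) about the
    z-axis into a watertight triangle mesh.

    Poles are closed with triangle fans (no degenerate quads), which
    guarantees watertightness at any resolution.  Morphometry of the output
    converges to the :mod:`.shape_models` closed forms as ``n_theta`` and
    ``n_z`` grow (inscribed surface, so area and volume converge from below).
    """
    if n_theta < 8 or n_z < 4:
        raise ValueError("need n_theta >= 8 and n_z >= 4")
    z, r, z_lo, z_hi = _revolution_stations(shape, n_z)
    n_rings = len(z)
    angles = 2.0 * math.pi * np.arange(n_theta) / n_theta
    cos_a, sin_a = np.cos(angles), np.sin(angles)

    verts = np.empty((2 + n_rings * n_theta, 3))
    verts[0] = (0.0, 0.0, z_lo)
    verts[1] = (0.0, 0.0, z_hi)
    ring0 = 2
    for j in range(n_rings):
        base = ring0 + j * n_theta
        verts[base:base + n_theta, 0] = r[j] * cos_a
        verts[base:base + n_theta, 1] = r[j] * sin_a
        verts[base:base + n_theta, 2] = z[j]

    faces: list[list[int]] = []
    nxt = lambda i: (i + 1) % n_theta
    for i in range(n_theta):  # bottom fan, outward (−z) normal
        faces.append([0, ring0 + nxt(i), ring0 + i])
    for j in range(n_rings - 1):
        lo = ring0 + j * n_theta
        hi = lo + n_theta
        for i in range(n_theta):
            faces.append([lo + i, lo + nxt(i), hi + nxt(i)])
            faces.append([lo + i, hi + nxt(i), hi + i])
    top = ring0 + (n_rings - 1) * n_theta
    for i in range(n_theta):  # top fan, outward (+z) normal
        faces.append([1, top + i, top + nxt(i)])

    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64),
                        name=f"revolution_{shape.kind}")


#: Named surrogate cells with the study organisms' gross dimensions (μm).
PRESETS: dict[str, GeometricShape] = {
    "p-micans-like": drop_profile(length=40.0, max_width=25.0, shoulder=0.5),
    "halamphora-like": prolate_spheroid(a=1.97, c=8.135),
}


def make_preset_mesh(name: str, n_theta: int = 128, n_z: int = 128) -> TriangleMesh:
    """Tessellated surrogate for one of the named plankton presets."""
    try:
        shape = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    mesh = make_revolution(shape, n_theta=n_theta, n_z=n_z)
    mesh.name = name
    return mesh


def jitter_mesh(mesh: TriangleMesh, amplitude_fraction: float = 0.01,
                seed: int = 0) -> TriangleMesh:
    """Biological-variability fixture: displace vertices along their normals
    by uniform noise of amplitude ``amplitude_fraction`` times the mesh's
    half-diagonal.  At the default 1% the mesh stays watertight and free of
    self-intersections; topology is untouched.
    """
    if not 0 <= amplitude_fraction <= 0.01:
        raise ValueError("amplitude_fraction must be in [0, 0.01]")
    v = mesh.vertices
    f = mesh.faces
    face_n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    vert_n = np.zeros_like(v)
    for k in range(3):
        np.add.at(vert_n, f[:, k], face_n)
    norms = np.linalg.norm(vert_n, axis=1, keepdims=True)
    vert_n = np.where(norms > 0, vert_n / np.where(norms > 0, norms, 1.0), 0.0)
    scale = 0.5 * np.linalg.norm(v.max(axis=0) - v.min(axis=0))
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-1.0, 1.0, size=len(v))[:, None] * amplitude_fraction * scale
    return TriangleMesh(v + offsets * vert_n, f.copy(),
                        name=f"{mesh.name}_jitter", source_format=mesh.source_format)


# ---------------------------------------------------------------------------
# SEM-like image pairs
# ---------------------------------------------------------------------------

def gamma_transform(gamma: float) -> Callable[[np.ndarray], np.ndarray]:
    """Monotone brightness map v -> v**gamma on normalised [0, 1] intensities."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return lambda x: np.power(x, gamma)


def make_image_pair(width: int = 256, height: int = 256,
                    transform: Callable[[np.ndarray], np.ndarray] | None = None,
                    noise_sd: float = 0.0, seed: int = 0,
                    bit_depth: int = 8) -> tuple[GrayImage, GrayImage, np.ndarray]:
    """Reference/distorted grayscale pair with a known foreground mask.

    The reference shows a filled ellipse (semi-axes 35% and 25% of the frame)
    whose interior carries a radial intensity gradient — bright at the centre,
    darker toward the rim — on a near-black background, loosely emulating a
    rounded cell on an SEM filter.  The distorted image is
    ``transform(reference) + N(0, noise_sd)``, clipped and quantised to the
    bit depth.  Deterministic for a given seed.

    Returns ``(reference, distorted, true_mask)`` where ``true_mask`` is the
    exact boolean foreground used for rendering.
    """
    if width < 16 or height < 16:
        raise ValueError("image must be at least 16x16")
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    maxval = 2 ** bit_depth - 1
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    ax, ay = 0.35 * width, 0.25 * height
    rho = np.sqrt(((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2)
    mask = rho <= 1.0

    background = 0.03  # normalised; dark but nonzero, like a coated filter
    fg = 0.9 - 0.55 * rho  # radial ramp: 0.9 at centre down to 0.35 at rim
    ref_norm = np.where(mask, fg, background)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    ref_q = np.clip(np.rint(ref_norm * maxval), 0, maxval).astype(dtype)

    if transform is None:
        dist_norm = ref_q.astype(np.float64) / maxval
    else:
        dist_norm = np.asarray(transform(ref_q.astype(np.float64) / maxval), dtype=np.float64)
    dist = dist_norm * maxval
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        dist = dist + rng.normal(0.0, noise_sd, size=dist.shape)
    dist_q = np.clip(np.rint(dist), 0, maxval).astype(dtype)

    return (GrayImage(ref_q, bit_depth=bit_depth),
            GrayImage(dist_q, bit_depth=bit_depth),
            mask)
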