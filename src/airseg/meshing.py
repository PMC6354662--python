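"""Surface meshes from masks: marching cubes, STL I/O, divergence-theorem
volume, scaling, and hollow-shell derivation."""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes

from .grid import Mask

__all__ = [
    "TriangleMesh",
    "MeshError",
    "mask_to_mesh",
    "mesh_volume",
    "scale_mesh",
    "hollow_shell",
    "write_stl",
    "read_stl",
]


class MeshError(ValueError):
    """Invalid or unsupported mesh data."""


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (n, 3) world mm, ``faces`` (m, 3)
    vertex indices, outward-oriented for watertight meshes."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise MeshError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_watertight(self) -> bool:
        """Every undirected edge shared by exactly two faces, each directed
        edge used exactly once (consistent orientation)."""
        if self.n_faces == 0:
            return False
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        if any(c != 1 for c in directed.values()):
            return False
        return all((b, a) in directed for (a, b) in directed)

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)


def mask_to_mesh(mask: Mask) -> TriangleMesh:
    """Isosurface of the binary field at level 0.5 in world coordinates.

    The field is zero-padded by one voxel, so any mask (including one touching
    the grid boundary) yields a closed surface.
    """
    if not mask.data.any():
        raise MeshError("cannot mesh an empty mask")
    field = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(field, level=0.5, spacing=mask.spacing)
    # index i_p in the padded grid maps to voxel center origin + (i_p - 0.5)*s
    offset = np.asarray(mask.origin) - 0.5 * np.asarray(mask.spacing)
    verts = verts + offset
    mesh = TriangleMesh(verts, faces)
    if mesh_signed_volume(mesh) < 0:
        mesh = TriangleMesh(verts, faces[:, ::-1])
    return mesh


def mesh_signed_volume(mesh: TriangleMesh) -> float:
    """Signed volume by the divergence theorem (sum of signed tetrahedra)."""
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)
    cross = np.cross(tri[:, 1], tri[:, 2])
    return float(np.einsum("ij,ij->", tri[:, 0], cross) / 6.0)


def mesh_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume (mm^3) of a watertight, outward-oriented mesh."""
    if not mesh.is_watertight():
        raise MeshError("mesh is not watertight; volume undefined")
    vol = mesh_signed_volume(mesh)
    if vol <= 0:
        raise MeshError(
            f"mesh is inward-oriented (signed volume {vol:.6g} mm^3); flip faces"
        )
    return vol


def scale_mesh(mesh: TriangleMesh, factor: float) -> TriangleMesh:
    """Uniform scaling about the vertex centroid; volume scales by factor^3."""
    if factor <= 0:
        raise MeshError(f"scale factor must be positive, got {factor}")
    c = mesh.centroid()
    return TriangleMesh(c + (mesh.vertices - c) * factor, mesh.faces)


def hollow_shell(mask: Mask, wall_mm: float) -> Mask:
    """Wall of thickness ``wall_mm`` around the cavity: dilation by a
    physical ball minus the cavity itself.  The wall must be at least one
    voxel thick on every axis so the rasterized shell is watertight."""
    if wall_mm < max(mask.spacing):
        raise MeshError(
            f"wall {wall_mm} mm is thinner than the largest voxel dimension "
            f"{max(mask.spacing)} mm"
        )
    radii = [int(np.ceil(wall_mm / s)) for s in mask.spacing]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    ball = (
        sum((g * s) ** 2 for g, s in zip(grids, mask.spacing)) <= wall_mm**2
    )
    dilated = ndimage.binary_dilation(mask.data, structure=ball)
    return Mask(dilated & ~mask.data, spacing=mask.spacing, origin=mask.origin)


# ---------------------------------------------------------------------------
# STL I/O (binary canonical; ASCII accepted on read)
# ---------------------------------------------------------------------------


def write_stl(mesh: TriangleMesh, path) -> None:
    """Binary little-endian STL: 80-byte header, uint32 count, 50-byte facets."""
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, lengths, out=np.zeros_like(normals), where=lengths > 0)
    with open(path, "wb") as fh:
        fh.write(b"airseg binary STL".ljust(80, b"\x00"))
        fh.write(struct.pack("<I", len(tri)))
        record = np.zeros(
            len(tri),
            dtype=[("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")],
        )
        record["normal"] = normals
        record["verts"] = tri
        fh.write(record.tobytes())


def _read_stl_ascii(text: str) -> TriangleMesh:
    verts = []
    for line in text.splitlines():
        tokens = line.split()
        if tokens[:1] == ["vertex"]:
            verts.append([float(t) for t in tokens[1:4]])
    if not verts or len(verts) % 3:
        raise MeshError("malformed ASCII STL: vertex count not a multiple of 3")
    return _index_triangles(np.asarray(verts, dtype=np.float64))


def _index_triangles(flat_vertices: np.ndarray) -> TriangleMesh:
    """Merge duplicate vertices of a triangle soup into an indexed mesh."""
    uniq, inverse = np.unique(flat_vertices, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return TriangleMesh(uniq, faces)


def read_stl(path) -> TriangleMesh:
    """Read binary or ASCII STL; duplicate vertices are merged."""
    raw = Path(path).read_bytes()
    if len(raw) < 84:
        # could still be a tiny ASCII file
        if raw.lstrip().startswith(b"solid"):
            return _read_stl_ascii(raw.decode("ascii", "replace"))
        raise MeshError(f"{path}: file too short to be a binary STL")
    (count,) = struct.unpack_from("<I", raw, 80)
    expected = 84 + 50 * count
    if raw.lstrip().startswith(b"solid") and len(raw) != expected:
        return _read_stl_ascii(raw.decode("ascii", "replace"))
    if len(raw) < expected:
        raise MeshError(
            f"{path}: truncated binary STL ({len(raw)} bytes, facet count "
            f"{count} needs {expected})"
        )
    record = np.frombuffer(
        raw,
        dtype=[("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")],
        count=count,
        offset=84,
    )
    flat = record["verts"].reshape(-1, 3).astype(np.float64)
    return _index_triangles(flat)
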