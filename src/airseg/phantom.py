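"""Synthetic CBCT-like phantoms with analytically known cavity volumes.

A phantom is a grid of air (default grayscale -1000) containing one or more
parametric cavities, each wrapped in a soft-tissue-mimic wall (300), inside
a bone "skull" box shell (800).  Partial volume is emulated by Gaussian
blur, detector noise by additive Gaussian noise.  Ground-truth cavity
volumes are closed-form, never rasterized, so the image-derived measurement
can be validated against an independent gold standard.

Each cavity wall may carry a locally thinned patch ("dent").  The highest
threshold that keeps the cavity disconnected from the outside is then pinned
by that thinnest region, which reproduces the few-percent overestimation of
threshold-based volumetry: boundary voxels below the resulting threshold are
allocated to air.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import Volume
from .roi import LandmarkSet
from .stats import MeasurementTable

__all__ = [
    "Ellipsoid",
    "Capsule",
    "ShapeUnion",
    "Dent",
    "Channel",
    "PhantomSpec",
    "GroundTruth",
    "PhantomError",
    "analytic_volume",
    "generate_phantom",
    "nasal_pair_spec",
    "simulate_measurement_sessions",
]


class PhantomError(ValueError):
    """Invalid phantom specification."""


# ---------------------------------------------------------------------------
# Parametric shapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid with semi-axes (a, b, c) in mm."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise PhantomError(f"semi-axes must be positive, got {self.semi_axes}")

    def analytic_volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * math.pi * a * b * c

    def bounds(self):
        return tuple(
            (self.center[i] - self.semi_axes[i], self.center[i] + self.semi_axes[i])
            for i in range(3)
        )

    def contains_grid(self, xc, yc, zc) -> np.ndarray:
        a, b, c = self.semi_axes
        cx, cy, cz = self.center
        return (
            ((xc - cx) / a) ** 2 + ((yc - cy) / b) ** 2 + ((zc - cz) / c) ** 2
        ) <= 1.0

    def seed(self):
        return self.center

    def to_dict(self):
        return {"kind": "ellipsoid", "center": list(self.center),
                "semi_axes": list(self.semi_axes)}


@dataclass(frozen=True)
class Capsule:
    """Cylinder of radius r between p0 and p1, capped with hemispheres."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise PhantomError(f"capsule radius must be positive, got {self.radius}")
        if np.allclose(self.p0, self.p1):
            raise PhantomError("capsule endpoints coincide")

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.p1, self.p0)))

    def analytic_volume(self) -> float:
        r = self.radius
        return math.pi * r * r * self.length + 4.0 / 3.0 * math.pi * r**3

    def bounds(self):
        return tuple(
            (
                min(self.p0[i], self.p1[i]) - self.radius,
                max(self.p0[i], self.p1[i]) + self.radius,
            )
            for i in range(3)
        )

    def contains_grid(self, xc, yc, zc) -> np.ndarray:
        p0 = np.asarray(self.p0)
        d = np.subtract(self.p1, self.p0)
        dd = float(d @ d)
        rx, ry, rz = xc - p0[0], yc - p0[1], zc - p0[2]
        t = np.clip((rx * d[0] + ry * d[1] + rz * d[2]) / dd, 0.0, 1.0)
        qx, qy, qz = rx - t * d[0], ry - t * d[1], rz - t * d[2]
        return qx * qx + qy * qy + qz * qz <= self.radius**2

    def seed(self):
        return tuple((np.asarray(self.p0) + self.p1) / 2.0)

    def to_dict(self):
        return {"kind": "capsule", "p0": list(self.p0), "p1": list(self.p1),
                "radius": self.radius}


@dataclass(frozen=True)
class ShapeUnion:
    """Union of pairwise-disjoint shapes; volumes add.

    Disjointness is enforced conservatively via bounding boxes, which keeps
    the closed-form volume valid without a general intersection test.
    """

    members: tuple

    def __post_init__(self):
        members = tuple(self.members)
        if len(members) < 2:
            raise PhantomError("a union needs at least two members")
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                bi, bj = members[i].bounds(), members[j].bounds()
                if all(bi[ax][0] < bj[ax][1] and bj[ax][0] < bi[ax][1] for ax in range(3)):
                    raise PhantomError(
                        f"union members {i} and {j} overlap (bounding boxes "
                        "intersect); no closed-form volume"
                    )
        object.__setattr__(self, "members", members)

    def analytic_volume(self) -> float:
        return sum(m.analytic_volume() for m in self.members)

    def bounds(self):
        bs = [m.bounds() for m in self.members]
        return tuple(
            (min(b[ax][0] for b in bs), max(b[ax][1] for b in bs)) for ax in range(3)
        )

    def contains_grid(self, xc, yc, zc) -> np.ndarray:
        out = self.members[0].contains_grid(xc, yc, zc)
        for m in self.members[1:]:
            out = out | m.contains_grid(xc, yc, zc)
        return out

    def seed(self):
        return self.members[0].seed()

    def to_dict(self):
        return {"kind": "union", "members": [m.to_dict() for m in self.members]}


def analytic_volume(shape) -> float:
    """Closed-form volume (mm^3) of a parametric shape."""
    return shape.analytic_volume()


def shape_from_dict(doc: dict):
    kind = doc.get("kind")
    if kind == "ellipsoid":
        return Ellipsoid(tuple(doc["center"]), tuple(doc["semi_axes"]))
    if kind == "capsule":
        return Capsule(tuple(doc["p0"]), tuple(doc["p1"]), float(doc["radius"]))
    if kind == "union":
        return ShapeUnion(tuple(shape_from_dict(m) for m in doc["members"]))
    raise PhantomError(f"unknown shape kind {kind!r}")


# ---------------------------------------------------------------------------
# Phantom specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dent:
    """Locally thinned wall: within ``radius`` mm of ``center``, the wall is
    reduced to ``patch_mm`` (wall material beyond that depth becomes air)."""

    center: tuple[float, float, float]
    radius: float
    patch_mm: float


@dataclass(frozen=True)
class Channel:
    """Cylindrical air connection (e.g. a sinus ostium) carved through walls."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    links: tuple[str, str] = ("", "")

    def midpoint(self):
        return tuple((np.asarray(self.p0) + self.p1) / 2.0)

    def axis(self):
        d = np.subtract(self.p1, self.p0)
        return tuple(d / np.linalg.norm(d))


_DEFAULT_LEVELS = {"air": -1000.0, "soft": 300.0, "bone": 800.0}


@dataclass(frozen=True)
class PhantomSpec:
    cavities: dict
    wall_mm: float = 2.0
    sinus_chambers: dict = field(default_factory=dict)
    channels: tuple = ()
    dents: tuple = ()
    material_levels: dict = field(default_factory=lambda: dict(_DEFAULT_LEVELS))
    noise_sd: float = 0.0
    blur_sigma_mm: float = 0.0
    spacing: tuple[float, float, float] = (0.4, 0.4, 0.4)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    extent_mm: tuple[float, float, float] = (44.0, 36.0, 40.0)
    skull_wall_mm: float = 2.0
    skull_margin_mm: float = 2.0
    outer_seed: tuple[float, float, float] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        levels = self.material_levels
        if not levels["air"] < levels["soft"] < levels["bone"]:
            raise PhantomError(f"material levels must be ordered air < soft < bone: {levels}")
        if min(self.spacing) <= 0:
            raise PhantomError(f"spacing must be positive, got {self.spacing}")
        if self.noise_sd < 0 or self.blur_sigma_mm < 0:
            raise PhantomError("noise_sd and blur_sigma_mm must be >= 0")
        if self.wall_mm <= 0:
            raise PhantomError("wall_mm must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(self.extent_mm[ax] / self.spacing[ax])) for ax in range(3)
        )

    def to_json(self) -> str:
        doc = {
            "cavities": {k: v.to_dict() for k, v in self.cavities.items()},
            "sinus_chambers": {k: v.to_dict() for k, v in self.sinus_chambers.items()},
            "channels": [
                {"p0": list(c.p0), "p1": list(c.p1), "radius": c.radius,
                 "links": list(c.links)}
                for c in self.channels
            ],
            "dents": [
                {"center": list(d.center), "radius": d.radius, "patch_mm": d.patch_mm}
                for d in self.dents
            ],
            "wall_mm": self.wall_mm,
            "material_levels": self.material_levels,
            "noise_sd": self.noise_sd,
            "blur_sigma_mm": self.blur_sigma_mm,
            "spacing": list(self.spacing),
            "origin": list(self.origin),
            "extent_mm": list(self.extent_mm),
            "skull_wall_mm": self.skull_wall_mm,
            "skull_margin_mm": self.skull_margin_mm,
            "outer_seed": list(self.outer_seed) if self.outer_seed else None,
            "rng_seed": self.rng_seed,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        doc = json.loads(text)
        return cls(
            cavities={k: shape_from_dict(v) for k, v in doc["cavities"].items()},
            sinus_chambers={
                k: shape_from_dict(v) for k, v in doc.get("sinus_chambers", {}).items()
            },
            channels=tuple(
                Channel(tuple(c["p0"]), tuple(c["p1"]), float(c["radius"]),
                        tuple(c.get("links", ("", ""))))
                for c in doc.get("channels", ())
            ),
            dents=tuple(
                Dent(tuple(d["center"]), float(d["radius"]), float(d["patch_mm"]))
                for d in doc.get("dents", ())
            ),
            wall_mm=float(doc.get("wall_mm", 2.0)),
            material_levels=doc.get("material_levels", dict(_DEFAULT_LEVELS)),
            noise_sd=float(doc.get("noise_sd", 0.0)),
            blur_sigma_mm=float(doc.get("blur_sigma_mm", 0.0)),
            spacing=tuple(doc.get("spacing", (0.4, 0.4, 0.4))),
            origin=tuple(doc.get("origin", (0.0, 0.0, 0.0))),
            extent_mm=tuple(doc.get("extent_mm", (44.0, 36.0, 40.0))),
            skull_wall_mm=float(doc.get("skull_wall_mm", 2.0)),
            skull_margin_mm=float(doc.get("skull_margin_mm", 2.0)),
            outer_seed=tuple(doc["outer_seed"]) if doc.get("outer_seed") else None,
            rng_seed=int(doc.get("rng_seed", 0)),
        )


@dataclass(frozen=True)
class GroundTruth:
    """Analytic gold standard recorded at generation time."""

    cavity_volumes: dict  # name -> mm^3 (closed form, never rasterized)
    seeds: dict  # name -> world mm point inside the cavity
    landmarks: LandmarkSet
    roi_y_bounds: tuple[float, float]
    outer_seed: tuple[float, float, float]
    adjacency: tuple  # (cavity_name, sinus_name, channel) triples

    def to_json(self) -> str:
        lm = {
            k: list(getattr(self.landmarks, k))
            for k in ("ba", "nasion", "ethmoid_pi", "septum_post_ant", "nares_post")
        }
        lm["convention"] = "LPS"
        return json.dumps(
            {
                "cavity_volumes_mm3": self.cavity_volumes,
                "seeds": {k: list(v) for k, v in self.seeds.items()},
                "landmarks": lm,
                "roi_y_bounds": list(self.roi_y_bounds),
                "outer_seed": list(self.outer_seed),
                "adjacency": [
                    {"cavity": a, "sinus": b,
                     "channel": {"p0": list(c.p0), "p1": list(c.p1), "radius": c.radius}}
                    for a, b, c in self.adjacency
                ],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _grid_centers(spec: PhantomSpec):
    nx, ny, nz = spec.grid_shape
    ox, oy, oz = spec.origin
    sx, sy, sz = spec.spacing
    xc = (ox + (np.arange(nx) + 0.5) * sx)[:, None, None]
    yc = (oy + (np.arange(ny) + 0.5) * sy)[None, :, None]
    zc = (oz + (np.arange(nz) + 0.5) * sz)[None, None, :]
    return xc, yc, zc


def _check_fits(spec: PhantomSpec) -> None:
    lo = np.asarray(spec.origin)
    hi = lo + np.asarray(spec.extent_mm)
    for name, shape in {**spec.cavities, **spec.sinus_chambers}.items():
        for ax, (blo, bhi) in enumerate(shape.bounds()):
            if blo - spec.wall_mm < lo[ax] or bhi + spec.wall_mm > hi[ax]:
                raise PhantomError(
                    f"shape {name!r} plus wall exceeds the grid on axis {ax} "
                    f"({blo - spec.wall_mm:.1f}..{bhi + spec.wall_mm:.1f} vs "
                    f"{lo[ax]:.1f}..{hi[ax]:.1f})"
                )


def _auto_landmarks(spec: PhantomSpec, z_roof: float):
    """Consistent landmark set bracketing the cavity extent, clamped to the grid."""
    bounds = [shape.bounds() for shape in spec.cavities.values()]
    y_lo = min(b[1][0] for b in bounds)
    y_hi = max(b[1][1] for b in bounds)
    x_mid = float(np.mean([np.mean(b[0]) for b in bounds]))
    grid_y_hi = spec.origin[1] + spec.extent_mm[1]
    grid_z_hi = spec.origin[2] + spec.extent_mm[2]
    margin = 2.0
    y_ant = max(y_lo - margin, spec.origin[1] + 1.0)
    y_post = min(y_hi + margin, grid_y_hi - 1.5)
    z_roof = min(z_roof, grid_z_hi - 2.0)
    z_mid = float(np.mean([np.mean(b[2]) for b in bounds]))
    landmarks = LandmarkSet(
        ba=(x_mid, min(y_post + 1.0, grid_y_hi - 0.25), z_roof),
        nasion=(x_mid, max(y_ant - 1.0, spec.origin[1] + 0.25), z_roof),
        ethmoid_pi=(x_mid, (y_ant + y_post) / 2.0,
                    min(z_roof + 1.5, grid_z_hi - 0.25)),
        septum_post_ant=(x_mid, y_post, z_mid),
        nares_post=(x_mid, y_ant, z_mid),
    )
    return landmarks, (y_ant, y_post)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Rasterize a phantom and return it with its analytic ground truth.

    Deterministic given ``spec.rng_seed``.  Labeling: cavity/sinus interiors
    and everything not wall or skull get the air level; the wall (points
    within ``wall_mm`` of a cavity, minus dents and channels) gets the soft
    level; the skull box shell gets the bone level.  The label volume is then
    Gaussian-blurred (partial-volume emulation) and Gaussian noise is added.
    """
    if not spec.cavities:
        raise PhantomError("phantom needs at least one cavity")
    _check_fits(spec)
    xc, yc, zc = _grid_centers(spec)
    levels = spec.material_levels

    all_shapes = {**spec.cavities, **spec.sinus_chambers}
    inside = np.zeros(spec.grid_shape, dtype=bool)
    for shape in all_shapes.values():
        inside |= shape.contains_grid(xc, yc, zc)

    # wall: distance band around the cavities, minus dents
    dist = ndimage.distance_transform_edt(~inside, sampling=spec.spacing)
    shell = (dist > 0) & (dist <= spec.wall_mm)
    for dent in spec.dents:
        ball = (
            (xc - dent.center[0]) ** 2
            + (yc - dent.center[1]) ** 2
            + (zc - dent.center[2]) ** 2
        ) <= dent.radius**2
        shell &= ~(ball & (dist > dent.patch_mm))

    labels = np.full(spec.grid_shape, levels["air"], dtype=np.float64)
    labels[shell] = levels["soft"]

    if spec.skull_wall_mm > 0:
        lo = np.asarray(spec.origin) + spec.skull_margin_mm
        hi = np.asarray(spec.origin) + np.asarray(spec.extent_mm) - spec.skull_margin_mm
        w = spec.skull_wall_mm
        in_outer = (
            (xc >= lo[0]) & (xc <= hi[0])
            & (yc >= lo[1]) & (yc <= hi[1])
            & (zc >= lo[2]) & (zc <= hi[2])
        )
        in_inner = (
            (xc >= lo[0] + w) & (xc <= hi[0] - w)
            & (yc >= lo[1] + w) & (yc <= hi[1] - w)
            & (zc >= lo[2] + w) & (zc <= hi[2] - w)
        )
        skull = in_outer & ~in_inner & ~shell & ~inside
        labels[skull] = levels["bone"]

    for channel in spec.channels:
        carve = Capsule(channel.p0, channel.p1, channel.radius).contains_grid(xc, yc, zc)
        labels[carve] = levels["air"]

    if spec.blur_sigma_mm > 0:
        sigmas = [spec.blur_sigma_mm / s for s in spec.spacing]
        labels = ndimage.gaussian_filter(labels, sigma=sigmas, mode="nearest")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        labels = labels + rng.normal(0.0, spec.noise_sd, size=labels.shape)

    volume = Volume(labels, spacing=spec.spacing, origin=spec.origin)

    shape_top = max(b[2][1] for b in (s.bounds() for s in spec.cavities.values()))
    z_roof = shape_top + spec.wall_mm + 2.0
    landmarks, y_bounds = _auto_landmarks(spec, z_roof)
    landmarks.validate_inside(volume)

    if spec.outer_seed is not None:
        outer_seed = spec.outer_seed
    else:
        # air point inside the skull, anterior to every shell
        y_lo_shell = min(b[1][0] for b in (s.bounds() for s in all_shapes.values()))
        outer_seed = (
            float(np.mean([spec.origin[0], spec.origin[0] + spec.extent_mm[0]])),
            (spec.origin[1] + spec.skull_margin_mm + spec.skull_wall_mm
             + (y_lo_shell - spec.wall_mm)) / 2.0,
            float(np.mean([spec.origin[2], spec.origin[2] + spec.extent_mm[2]])),
        )

    truth = GroundTruth(
        cavity_volumes={k: v.analytic_volume() for k, v in spec.cavities.items()},
        seeds={k: v.seed() for k, v in all_shapes.items()},
        landmarks=landmarks,
        roi_y_bounds=y_bounds,
        outer_seed=outer_seed,
        adjacency=tuple(
            (c.links[0], c.links[1], c) for c in spec.channels if all(c.links)
        ),
    )
    return volume, truth


def nasal_pair_spec(
    spacing: float = 0.4, noise_sd: float = 30.0, rng_seed: int = 0
) -> PhantomSpec:
    """Default accuracy fixture: a left/right cavity pair near 1,220 and
    830 mm^3, each wall carrying a thin patch (two voxels) that pins the
    disconnecting threshold at a sub-voxel partial-volume depth.
    """
    left = Ellipsoid(center=(30.2, 18.0, 18.0), semi_axes=(5.2, 6.0, 9.34))
    right = Ellipsoid(center=(13.8, 18.0, 18.0), semi_axes=(4.6, 5.4, 7.98))
    dents = (
        Dent(center=(30.2 + 5.2, 18.0, 18.0), radius=2.5, patch_mm=2.0 * spacing),
        Dent(center=(13.8 - 4.6, 18.0, 18.0), radius=2.5, patch_mm=2.0 * spacing),
    )
    return PhantomSpec(
        cavities={"left": left, "right": right},
        wall_mm=2.0,
        dents=dents,
        noise_sd=noise_sd,
        blur_sigma_mm=spacing,
        spacing=(spacing, spacing, spacing),
        extent_mm=(44.0, 36.0, 40.0),
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Repeated-measurement simulation (fixtures for the reliability statistics)
# ---------------------------------------------------------------------------


def simulate_measurement_sessions(
    true_volumes,
    bias,
    error_sd: float,
    n_sessions: int = 2,
    rng_seed: int = 0,
    unit: str = "mm3",
) -> MeasurementTable:
    """Per object and session: measurement = truth + session bias + N(0, sd).

    ``bias`` may be a scalar (applied to every session after the first, the
    first session being the reference) or a sequence of per-session offsets.
    Deterministic given ``rng_seed``.
    """
    if error_sd < 0:
        raise ValueError(f"error_sd must be >= 0, got {error_sd}")
    true_volumes = np.asarray(true_volumes, dtype=float)
    if np.isscalar(bias) or np.ndim(bias) == 0:
        offsets = np.array([0.0] + [float(bias)] * (n_sessions - 1))
    else:
        offsets = np.asarray(bias, dtype=float)
        if offsets.shape != (n_sessions,):
            raise ValueError(
                f"bias must be scalar or length-{n_sessions}, got shape {offsets.shape}"
            )
    rng = np.random.default_rng(rng_seed)
    noise = (
        rng.normal(0.0, error_sd, size=(len(true_volumes), n_sessions))
        if error_sd > 0
        else np.zeros((len(true_volumes), n_sessions))
    )
    values = true_volumes[:, None] + offsets[None, :] + noise
    return MeasurementTable(
        object_ids=[f"object_{i + 1}" for i in range(len(true_volumes))],
        session_ids=[f"session_{j + 1}" for j in range(n_sessions)],
        values=values,
        unit=unit,
    )
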