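"""Nasal-airway region of interest built from five anatomical landmarks.

The ROI is bounded anteriorly/posteriorly by two coronal planes (constant y
in the LPS frame), superiorly by a natural cubic spline through basion, the
posterior-inferior ethmoid point and nasion, extruded along x.  No inferior
or lateral geometric cut is applied: the palate and the cavity walls bound
the airway naturally through the air mask downstream, and the septum tissue
separates left from right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline

from .grid import Mask, Volume

__all__ = [
    "LandmarkError",
    "LandmarkSet",
    "load_landmarks",
    "save_landmarks",
    "coronal_bound_planes",
    "superior_spline",
    "build_roi_mask",
]


class LandmarkError(ValueError):
    """Landmark set violates its geometric invariants."""


_POINT_KEYS = ("ba", "nasion", "ethmoid_pi", "septum_post_ant", "nares_post")


@dataclass(frozen=True)
class LandmarkSet:
    """The five ROI-defining points, world mm, LPS.

    ba
        Basion.
    nasion
        Nasion (N).
    ethmoid_pi
        Most posterior-inferior point of the ethmoid sinuses.
    septum_post_ant
        Most anterior point of the posterior border of the nasal septum
        (posterior ROI boundary).
    nares_post
        Most posterior point of the anterior nasal nares (anterior ROI
        boundary).
    """

    ba: tuple[float, float, float]
    nasion: tuple[float, float, float]
    ethmoid_pi: tuple[float, float, float]
    septum_post_ant: tuple[float, float, float]
    nares_post: tuple[float, float, float]

    def __post_init__(self):
        for key in _POINT_KEYS:
            p = np.asarray(getattr(self, key), dtype=float)
            if p.shape != (3,) or not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {key!r} must be a finite 3-vector")
            object.__setattr__(self, key, tuple(float(v) for v in p))
        if not self.nares_post[1] < self.septum_post_ant[1]:
            raise LandmarkError(
                "anterior boundary must be strictly anterior to the posterior one: "
                f"nares_post.y={self.nares_post[1]} vs "
                f"septum_post_ant.y={self.septum_post_ant[1]}"
            )
        if not self.nasion[1] < self.ethmoid_pi[1] < self.ba[1]:
            raise LandmarkError(
                "spline knots must satisfy nasion.y < ethmoid_pi.y < ba.y, got "
                f"{self.nasion[1]}, {self.ethmoid_pi[1]}, {self.ba[1]}"
            )

    def validate_inside(self, volume: Volume) -> None:
        bounds = volume.world_bounds()
        for key in _POINT_KEYS:
            p = getattr(self, key)
            for ax in range(3):
                lo, hi = bounds[ax]
                if not lo <= p[ax] < hi:
                    raise LandmarkError(
                        f"landmark {key!r} = {p} outside volume bounds on axis {ax} "
                        f"({lo}..{hi})"
                    )


def load_landmarks(path) -> LandmarkSet:
    """Load a landmark JSON file ({ba: [x,y,z], ..., convention: 'LPS'})."""
    doc = json.loads(Path(path).read_text())
    convention = doc.get("convention")
    if convention != "LPS":
        raise LandmarkError(f"landmark file convention must be 'LPS', got {convention!r}")
    missing = [k for k in _POINT_KEYS if k not in doc]
    if missing:
        raise LandmarkError(f"landmark file missing keys: {missing}")
    return LandmarkSet(**{k: tuple(doc[k]) for k in _POINT_KEYS})


def save_landmarks(landmarks: LandmarkSet, path) -> None:
    doc = {k: list(getattr(landmarks, k)) for k in _POINT_KEYS}
    doc["convention"] = "LPS"
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def coronal_bound_planes(landmarks: LandmarkSet) -> tuple[float, float]:
    """(y_anterior, y_posterior): the two coronal boundary planes in mm."""
    y_ant = landmarks.nares_post[1]
    y_post = landmarks.septum_post_ant[1]
    if not y_ant < y_post:
        raise LandmarkError(
            f"degenerate ROI: y_anterior={y_ant} not strictly less than y_posterior={y_post}"
        )
    return (y_ant, y_post)


def superior_spline(landmarks: LandmarkSet):
    """Superior boundary z_sup(y): natural cubic spline through the three
    midsagittal knots (nasion, ethmoid_pi, ba), linearly extrapolated
    outside the knot span.  Returns a callable accepting scalars or arrays.
    """
    knots = sorted(
        [
            (landmarks.nasion[1], landmarks.nasion[2]),
            (landmarks.ethmoid_pi[1], landmarks.ethmoid_pi[2]),
            (landmarks.ba[1], landmarks.ba[2]),
        ]
    )
    ys = np.array([k[0] for k in knots])
    zs = np.array([k[1] for k in knots])
    if not (ys[0] < ys[1] < ys[2]):
        raise LandmarkError(f"spline knot y values must be strictly increasing: {ys}")
    spline = CubicSpline(ys, zs, bc_type="natural")
    d0 = float(spline(ys[0], 1))
    d2 = float(spline(ys[2], 1))
    z0, z2 = float(zs[0]), float(zs[2])

    def z_sup(y):
        y = np.asarray(y, dtype=float)
        inside = spline(y)
        below = z0 + d0 * (y - ys[0])
        above = z2 + d2 * (y - ys[2])
        out = np.where(y < ys[0], below, np.where(y > ys[2], above, inside))
        return out if out.ndim else float(out)

    return z_sup


def build_roi_mask(volume: Volume, landmarks: LandmarkSet) -> Mask:
    """Boolean ROI mask: voxel centers with y_ant <= y <= y_post and z <= z_sup(y)."""
    landmarks.validate_inside(volume)
    y_ant, y_post = coronal_bound_planes(landmarks)
    z_sup = superior_spline(landmarks)

    yc = volume.axis_centers(1)
    zc = volume.axis_centers(2)
    y_ok = (yc >= y_ant) & (yc <= y_post)
    roof = np.asarray(z_sup(yc))  # (ny,)
    yz = y_ok[:, None] & (zc[None, :] <= roof[:, None])  # (ny, nz)
    data = np.broadcast_to(yz[None, :, :], volume.shape)
    if not data.any():
        raise LandmarkError(
            f"empty ROI: no voxel center satisfies y in [{y_ant}, {y_post}] "
            "and z <= z_sup(y)"
        )
    return Mask(np.ascontiguousarray(data), spacing=volume.spacing, origin=volume.origin)
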