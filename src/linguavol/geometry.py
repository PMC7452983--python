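"""Landmark-defined measurement planes and half-space operations on masks.

The three planes that bound the measurement region are constructed from six
named landmarks:

* **occlusal plane** — through the central cusps of both lower first molars
  and the incisal edge of the lower right central incisor; its normal is
  oriented *superiorly* (the lingual frenulum lies on the negative side).
* **posterior plane** — through the distal cusps of the upper second molars,
  perpendicular to the occlusal plane; normal oriented *anteriorly* (the
  incisal edge lies on the positive side).
* **inferior plane** — through the lingual frenulum, parallel to the
  occlusal plane; it shares the occlusal plane's (superior) normal.

Half-space membership is decided at voxel centres with the deterministic
``>= 0`` / ``< 0`` split, so clipping by a plane and by its reverse
partitions any mask exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, InputError
from .grids import BinaryMask

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "Plane",
    "occlusal_plane",
    "posterior_plane",
    "inferior_plane",
    "signed_distance",
    "clip_mask",
    "mask_volume",
]

#: Landmark names required by the plane constructions.
LANDMARK_NAMES = (
    "lower_first_molar_central_cusp_left",
    "lower_first_molar_central_cusp_right",
    "incisal_edge_lower_right_central_incisor",
    "upper_second_molar_distal_cusp_left",
    "upper_second_molar_distal_cusp_right",
    "lingual_frenulum",
)

_CONTAINMENT_TOL_MM = 1e-6
_UNIT_TOL = 1e-9


@dataclass
class LandmarkSet:
    """Named anatomical points in world millimetres."""

    points: dict[str, np.ndarray] = field(default_factory=dict)
    #: names present in the source file that are not in ``LANDMARK_NAMES``
    unknown_names: tuple[str, ...] = ()

    def __post_init__(self):
        clean: dict[str, np.ndarray] = {}
        for name, p in self.points.items():
            arr = np.asarray(p, dtype=float).reshape(-1)
            if arr.size != 3 or not np.all(np.isfinite(arr)):
                raise InputError(f"landmark {name!r} is not a finite 3-vector: {p!r}")
            clean[name] = arr
        self.points = clean
        self.unknown_names = tuple(n for n in self.points if n not in LANDMARK_NAMES)

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.points[name]
        except KeyError:
            raise GeometryError(f"required landmark {name!r} is missing") from None

    def __contains__(self, name: str) -> bool:
        return name in self.points

    def translated(self, offset) -> "LandmarkSet":
        off = np.asarray(offset, dtype=float)
        return LandmarkSet({k: v + off for k, v in self.points.items()})


@dataclass
class Plane:
    """Oriented plane: a point on the plane plus a unit normal."""

    point_mm: np.ndarray
    normal: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.point_mm = np.asarray(self.point_mm, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = float(np.linalg.norm(n))
        if not np.isfinite(norm) or norm < _UNIT_TOL:
            raise GeometryError(f"plane normal is degenerate: {self.normal!r}")
        self.normal = n / norm

    def reversed(self) -> "Plane":
        return Plane(self.point_mm, -self.normal, self.label)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "point_mm": [float(v) for v in self.point_mm],
            "normal": [float(v) for v in self.normal],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Plane":
        return cls(d["point_mm"], d["normal"], d.get("label", ""))


def signed_distance(plane: Plane, point) -> np.ndarray | float:
    """Signed distance (mm) of point(s) from the plane, positive along the normal.

    ``point`` may be a 3-vector or an (..., 3) array.
    """
    p = np.asarray(point, dtype=float)
    d = (p - plane.point_mm) @ plane.normal
    return float(d) if d.ndim == 0 else d


def occlusal_plane(landmarks: LandmarkSet) -> Plane:
    """Plane through both lower first molar central cusps and the incisal edge
    of the lower right central incisor, normal oriented superiorly (so the
    lingual frenulum has negative signed distance)."""
    a = landmarks["lower_first_molar_central_cusp_left"]
    b = landmarks["lower_first_molar_central_cusp_right"]
    c = landmarks["incisal_edge_lower_right_central_incisor"]
    n = np.cross(b - a, c - a)
    area2 = float(np.linalg.norm(n))  # twice the triangle area
    if area2 / 2.0 < 1e-6:
        raise GeometryError(
            "occlusal landmarks are collinear "
            f"(triangle area {area2 / 2.0:.2e} mm^2 < 1e-6 mm^2)"
        )
    plane = Plane(a, n, label="occlusal")
    fren = landmarks["lingual_frenulum"]
    if signed_distance(plane, fren) > 0:
        plane = plane.reversed()
    return plane


def posterior_plane(landmarks: LandmarkSet, occlusal: Plane) -> Plane:
    """Plane through the distal cusps of both upper second molars,
    perpendicular to the occlusal plane, normal oriented anteriorly (so the
    incisal edge has positive signed distance).

    The plane containing two points and perpendicular to a given plane is
    unique: its normal is proportional to ``n_occ x (cusp_R - cusp_L)``.
    """
    left = landmarks["upper_second_molar_distal_cusp_left"]
    right = landmarks["upper_second_molar_distal_cusp_right"]
    seg = right - left
    seg_norm = float(np.linalg.norm(seg))
    if seg_norm < 1e-6:
        raise GeometryError("upper second molar distal cusps are coincident")
    # Degenerate when the cusp segment is (anti)parallel to the occlusal normal.
    if np.linalg.norm(np.cross(seg / seg_norm, occlusal.normal)) < 1e-9:
        raise GeometryError(
            "upper second molar cusps are stacked along the occlusal normal; "
            "posterior plane orientation is undetermined"
        )
    n = np.cross(occlusal.normal, seg)
    plane = Plane(left, n, label="posterior")
    incisor = landmarks["incisal_edge_lower_right_central_incisor"]
    if signed_distance(plane, incisor) < 0:
        plane = plane.reversed()
    return plane


def inferior_plane(landmarks: LandmarkSet, occlusal: Plane) -> Plane:
    """Plane through the lingual frenulum parallel to the occlusal plane,
    sharing its superior normal."""
    fren = landmarks["lingual_frenulum"]
    return Plane(fren, occlusal.normal, label="inferior")


def _center_distance_field(mask: BinaryMask, plane: Plane) -> np.ndarray:
    """Signed distance of every voxel centre, as a broadcast sum (cheap)."""
    ax, ay, az = mask.axes()
    nx, ny, nz = plane.normal
    p = plane.point_mm
    return (
        ((ax - p[0]) * nx)[:, None, None]
        + ((ay - p[1]) * ny)[None, :, None]
        + ((az - p[2]) * nz)[None, None, :]
    )


def clip_mask(mask: BinaryMask, plane: Plane, keep: str = "positive") -> BinaryMask:
    """Retain exactly the voxels whose centres lie on one side of the plane.

    ``keep='positive'`` keeps centres with signed distance >= 0,
    ``keep='negative'`` keeps centres with signed distance < 0; together the
    two calls partition the mask.
    """
    if keep not in ("positive", "negative"):
        raise InputError(f"keep must be 'positive' or 'negative', got {keep!r}")
    d = _center_distance_field(mask, plane)
    side = d >= 0 if keep == "positive" else d < 0
    return BinaryMask.like(mask, mask.values & side)


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in cm^3: voxel count times voxel volume (pure counting,
    no partial-volume weighting)."""
    return mask.count * mask.voxel_volume_mm3 / 1000.0
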