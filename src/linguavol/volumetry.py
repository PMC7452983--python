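"""Oral cavity capacity (OCC) and tongue volume (TV) measurement.

OCC is the capacity of the space surrounded by the dental arches and the
palate, bounded behind by the posterior plane and below by the inferior
plane; it *includes* the space occupied by the tongue.  On an impression
scan this is realized as a seeded flood fill over (material + tongue
space) — the impression material is the cast of the free oral space —
after a small morphological closing that seals thin leaks, then clipped
to the anterior side of the posterior plane and the superior side of the
inferior plane.  TV is the tongue space restricted to the OCC mask, and
the TV/OCC ratio is reported in percent.

Duplicate impressions taken in one session are combined by averaging the
component volumes and recomputing the ratio from the averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, SegmentationError
from .geometry import (
    LandmarkSet,
    Plane,
    clip_mask,
    inferior_plane,
    mask_volume,
    occlusal_plane,
    posterior_plane,
    signed_distance,
)
from .grids import BinaryMask, VoxelGrid
from .imaging_io import (
    OralSegmentation,
    classify_cavities,
    enclosed_cavities,
    largest_component,
    threshold_segment,
)

__all__ = [
    "VolumeReport",
    "SubjectTimeline",
    "measure_occ",
    "measure_tv",
    "tv_occ_ratio",
    "average_duplicates",
    "tongue_morphometrics",
    "TongueMorphometrics",
    "default_seed_point",
    "measure_scan",
    "measure_subject",
]

#: leak-sealing closing radius in voxels (thin interdental gaps)
DEFAULT_CLOSING_RADIUS_VOX = 2


@dataclass
class VolumeReport:
    """Measured volumes of one impression (cm^3) with provenance."""

    occ_cm3: float
    tv_cm3: float
    ratio_pct: float = None  # type: ignore[assignment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.occ_cm3 < 0 or self.tv_cm3 < -1e-12:
            raise InputError("volumes must be nonnegative")
        if self.tv_cm3 > self.occ_cm3 * (1 + 1e-9) + 1e-12:
            raise InputError(
                f"tongue volume {self.tv_cm3} cm^3 exceeds cavity volume {self.occ_cm3} cm^3"
            )
        expected = tv_occ_ratio(self.tv_cm3, self.occ_cm3) if self.occ_cm3 > 0 else 0.0
        if self.ratio_pct is None:
            self.ratio_pct = expected
        elif abs(self.ratio_pct - expected) > 1e-9 * max(1.0, expected):
            raise InputError("ratio_pct inconsistent with occ/tv components")


@dataclass
class SubjectTimeline:
    """Averaged and per-duplicate reports of one subject across sessions."""

    subject_id: int | str
    reports: dict[str, VolumeReport | None] = field(default_factory=dict)
    duplicates: dict[str, list[VolumeReport]] = field(default_factory=dict)

    def available_timepoints(self) -> list[str]:
        return [t for t, r in self.reports.items() if r is not None]


def _ball(radius_vox: int) -> np.ndarray:
    r = int(radius_vox)
    g = np.arange(-r, r + 1)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    return X * X + Y * Y + Z * Z <= r * r


def default_seed_point(landmarks: LandmarkSet, occlusal: Plane, depth_mm: float = 2.0) -> np.ndarray:
    """Midpoint of the frenulum->incisor segment, moved to ``depth_mm``
    below the occlusal plane (an interior point of the cavity cast)."""
    mid = 0.5 * (
        landmarks["lingual_frenulum"]
        + landmarks["incisal_edge_lower_right_central_incisor"]
    )
    return mid - (signed_distance(occlusal, mid) + depth_mm) * occlusal.normal


def measure_occ(
    seg: OralSegmentation,
    occlusal: Plane,
    posterior: Plane,
    inferior: Plane,
    seed_point=None,
    landmarks: LandmarkSet | None = None,
    closing_radius_vox: int = DEFAULT_CLOSING_RADIUS_VOX,
) -> tuple[float, BinaryMask]:
    """Flood-fill the cavity cast and clip it to the measurement planes.

    Returns the OCC volume in cm^3 and its mask.  A fill that reaches the
    grid boundary means the cast leaked out of the measurement region and
    is reported as an error rather than a volume.
    """
    material = seg.material_mask
    fillable = material.values | seg.tongue_mask.values
    if closing_radius_vox > 0:
        fillable = ndimage.binary_closing(fillable, structure=_ball(closing_radius_vox))
        fillable |= material.values | seg.tongue_mask.values
    if seed_point is None:
        if landmarks is None:
            raise InputError("measure_occ needs a seed_point or landmarks")
        seed_point = default_seed_point(landmarks, occlusal)
    idx = np.round(
        (np.asarray(seed_point, dtype=float) - np.asarray(material.origin_mm))
        / np.asarray(material.spacing_mm)
    ).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(material.dims)):
        raise SegmentationError(f"seed point {seed_point} lies outside the grid")
    if not fillable[tuple(idx)]:
        raise SegmentationError(
            f"seed point {seed_point} is not inside the fillable (material + tongue) region"
        )
    labels, _ = ndimage.label(fillable, structure=ndimage.generate_binary_structure(3, 3))
    comp = labels == labels[tuple(idx)]
    n_border = int(comp[[0, -1], :, :].sum() + comp[:, [0, -1], :].sum() + comp[:, :, [0, -1]].sum())
    if n_border:
        raise SegmentationError(
            f"flood fill leaked to the grid boundary ({n_border} boundary voxels); "
            "increase the closing radius or check the segmentation"
        )
    occ_mask = BinaryMask.like(material, comp)
    occ_mask = clip_mask(occ_mask, posterior, keep="positive")
    occ_mask = clip_mask(occ_mask, inferior, keep="positive")
    return mask_volume(occ_mask), occ_mask


def measure_tv(seg: OralSegmentation, occ_mask: BinaryMask) -> tuple[float, BinaryMask]:
    """Tongue volume: the tongue space restricted to the OCC mask."""
    seg.tongue_mask.require_same_lattice(occ_mask)
    tv_mask = BinaryMask.like(occ_mask, seg.tongue_mask.values & occ_mask.values)
    return mask_volume(tv_mask), tv_mask


def tv_occ_ratio(tv_cm3: float, occ_cm3: float) -> float:
    """TV as a percentage of OCC."""
    if occ_cm3 <= 0:
        raise InputError("TV/OCC ratio undefined for nonpositive OCC")
    return 100.0 * tv_cm3 / occ_cm3


def average_duplicates(reports: list[VolumeReport]) -> VolumeReport:
    """Componentwise mean of duplicate impressions; the ratio is recomputed
    from the averaged volumes (ratio of averages, not average of ratios)."""
    if not reports:
        raise InputError("cannot average an empty list of reports")
    occ = float(np.mean([r.occ_cm3 for r in reports]))
    tv = float(np.mean([r.tv_cm3 for r in reports]))
    return VolumeReport(
        occ_cm3=occ, tv_cm3=tv,
        provenance={"n_duplicates": len(reports)},
    )


@dataclass
class TongueMorphometrics:
    """Descriptive tongue profiles along the anterior axis."""

    bin_centers_mm: np.ndarray      # distance along the anterior axis
    dorsum_height_mm: np.ndarray    # max signed distance to the occlusal plane
    width_mm: np.ndarray            # lateral extent projected on the occlusal plane
    ap_width_ratio: float           # mean width, anterior third / posterior third


def tongue_morphometrics(
    seg: OralSegmentation,
    occlusal: Plane,
    landmarks: LandmarkSet,
    bin_width_mm: float = 2.0,
) -> TongueMorphometrics:
    """Dorsum-height and outline-width profiles of the tongue space.

    The anterior axis is the frenulum->incisal-edge direction projected
    onto the occlusal plane; widths are measured perpendicular to it on
    the occlusal-plane projection of the tongue voxels.
    """
    tongue = seg.tongue_mask
    if tongue.count == 0:
        raise InputError("tongue mask is empty")
    fren = landmarks["lingual_frenulum"]
    inc = landmarks["incisal_edge_lower_right_central_incisor"]
    axis = inc - fren
    axis = axis - np.dot(axis, occlusal.normal) * occlusal.normal
    norm = float(np.linalg.norm(axis))
    if norm < 1e-9:
        raise InputError("anterior axis is degenerate (incisor above frenulum)")
    u = axis / norm
    v = np.cross(occlusal.normal, u)

    idx = np.argwhere(tongue.values)
    pts = np.asarray(tongue.origin_mm) + idx * np.asarray(tongue.spacing_mm)
    rel = pts - fren
    t = rel @ u
    lat = rel @ v
    height = signed_distance(occlusal, pts)

    t0 = float(t.min())
    nbins = max(int(np.ceil((float(t.max()) - t0) / bin_width_mm)), 1)
    which = np.minimum(((t - t0) / bin_width_mm).astype(int), nbins - 1)
    centers = t0 + (np.arange(nbins) + 0.5) * bin_width_mm
    widths = np.zeros(nbins)
    dorsum = np.full(nbins, np.nan)
    voxel = float(min(tongue.spacing_mm))
    for b in range(nbins):
        m = which == b
        if not m.any():
            continue
        widths[b] = float(lat[m].max() - lat[m].min()) + voxel
        dorsum[b] = float(height[m].max())
    occupied = np.flatnonzero(widths > 0)
    third = max(len(occupied) // 3, 1)
    posterior_bins = occupied[:third]
    anterior_bins = occupied[-third:]
    ap = float(widths[anterior_bins].mean() / widths[posterior_bins].mean())
    return TongueMorphometrics(
        bin_centers_mm=centers,
        dorsum_height_mm=dorsum,
        width_mm=widths,
        ap_width_ratio=ap,
    )


def measure_scan(
    grid: VoxelGrid,
    landmarks: LandmarkSet,
    threshold: float | str = "auto",
    closing_radius_vox: int = DEFAULT_CLOSING_RADIUS_VOX,
    seal_radius_vox: int = 1,
) -> VolumeReport:
    """Full single-scan pipeline: segment, build planes, measure OCC and TV.

    ``seal_radius_vox`` closes single-voxel noise pinholes in thin
    impression walls before cavity extraction; without it a pinhole opens
    an enclosed space to the background and the cavity is lost.
    """
    mask = threshold_segment(grid, threshold)
    material = largest_component(mask, connectivity=26)
    if seal_radius_vox > 0:
        material = BinaryMask.like(
            material,
            ndimage.binary_closing(material.values, structure=_ball(seal_radius_vox))
            | material.values,
        )
    cavities = enclosed_cavities(material, connectivity=6)
    occl = occlusal_plane(landmarks)
    seg = classify_cavities(material, cavities, landmarks, occl)
    post = posterior_plane(landmarks, occl)
    inf = inferior_plane(landmarks, occl)
    occ, occ_mask = measure_occ(
        seg, occl, post, inf, landmarks=landmarks, closing_radius_vox=closing_radius_vox
    )
    tv, _ = measure_tv(seg, occ_mask)
    return VolumeReport(
        occ_cm3=occ, tv_cm3=tv,
        provenance={
            "threshold": threshold,
            "closing_radius_vox": closing_radius_vox,
            **seg.provenance,
        },
    )


def measure_subject(
    subject_id,
    sessions: dict[str, list[tuple[VoxelGrid, LandmarkSet]] | None],
    threshold: float | str = "auto",
    closing_radius_vox: int = DEFAULT_CLOSING_RADIUS_VOX,
) -> SubjectTimeline:
    """Measure every duplicate of every session and assemble a timeline.

    Missing sessions (``None`` or empty) are kept as explicit gaps so that
    downstream statistics can refuse pairwise tests on them.  Stage errors
    are annotated with the session they came from.
    """
    timeline = SubjectTimeline(subject_id=subject_id)
    for timepoint, scans in sessions.items():
        if not scans:
            timeline.reports[timepoint] = None
            timeline.duplicates[timepoint] = []
            continue
        reports = []
        for k, (grid, landmarks) in enumerate(scans, start=1):
            try:
                reports.append(
                    measure_scan(grid, landmarks, threshold, closing_radius_vox)
                )
            except Exception as exc:
                raise type(exc)(
                    f"subject {subject_id}, session {timepoint}, duplicate {k}: {exc}"
                ) from exc
        timeline.duplicates[timepoint] = reports
        timeline.reports[timepoint] = average_duplicates(reports)
    return timeline
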