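"""Volume and landmark I/O plus impression-pattern segmentation.

An impression pattern is a cast of the oral cavity: the scanned material
occupies the free intraoral space and the anatomy (tongue, tooth crowns)
appears as *enclosed negative spaces* inside the material body.  The
segmentation route is therefore: threshold the scan, keep the largest
connected component (the impression body), extract its enclosed cavities
by hole filling and subtraction, and classify the cavity nearest the
lingual frenulum on the inferior side of the occlusal plane as the tongue
space.

World axes follow the package convention (+x subject-left, +y anterior,
+z superior).  DICOM and MetaImage data (LPS) have the y axis negated on
read; NIfTI data (RAS) have the x axis negated.  Only axis-aligned
volumes are accepted; oblique acquisitions are rejected with a
diagnostic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import InputError, SegmentationError
from .geometry import LandmarkSet, Plane, signed_distance
from .grids import BinaryMask, VoxelGrid

__all__ = [
    "OralSegmentation",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "threshold_segment",
    "auto_threshold",
    "largest_component",
    "enclosed_cavities",
    "classify_cavities",
]

_FORMATS = ("nifti", "metaimage", "dicom_series")


@dataclass
class OralSegmentation:
    """Impression body plus its classified negative spaces."""

    material_mask: BinaryMask
    tongue_mask: BinaryMask
    other_cavities: list[BinaryMask] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.material_mask.require_same_lattice(self.tongue_mask)
        if np.any(self.material_mask.values & self.tongue_mask.values):
            raise SegmentationError("tongue mask overlaps the material mask")


# ---------------------------------------------------------------------------
# volume I/O


def _infer_format(path: str | Path) -> str:
    p = Path(path)
    if p.is_dir():
        return "dicom_series"
    name = p.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    raise InputError(f"cannot infer volume format from {path!s}")


def _from_signed_diag(values: np.ndarray, scales, offsets) -> VoxelGrid:
    """Build a grid in package axes from per-axis signed scales, flipping
    axes stored in decreasing world order so spacing stays positive."""
    values = np.asarray(values)
    origin = [0.0, 0.0, 0.0]
    spacing = [0.0, 0.0, 0.0]
    for i in range(3):
        s, t = float(scales[i]), float(offsets[i])
        if s < 0:
            values = np.flip(values, axis=i)
            t = t + s * (values.shape[i] - 1)
            s = -s
        spacing[i], origin[i] = s, t
    return VoxelGrid(values=np.ascontiguousarray(values), spacing_mm=spacing, origin_mm=origin)


def _read_nifti(path: Path) -> VoxelGrid:
    import nibabel as nib

    img = nib.load(str(path))
    aff = img.affine
    rot = aff[:3, :3]
    if np.count_nonzero(np.abs(rot) > 1e-6 * np.abs(rot).max()) != 3 or np.any(
        np.abs(rot - np.diag(np.diag(rot))) > 1e-6
    ):
        raise InputError(f"{path}: oblique NIfTI orientations are not supported")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise InputError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    # RAS -> package axes: negate x.
    scales = np.diag(rot).copy()
    offsets = aff[:3, 3].copy()
    scales[0], offsets[0] = -scales[0], -offsets[0]
    return _from_signed_diag(data, scales, offsets)


def _write_nifti(grid: VoxelGrid, path: Path) -> None:
    import nibabel as nib

    aff = np.eye(4)
    aff[0, 0] = -grid.spacing_mm[0]
    aff[1, 1] = grid.spacing_mm[1]
    aff[2, 2] = grid.spacing_mm[2]
    aff[0, 3] = -grid.origin_mm[0]
    aff[1, 3] = grid.origin_mm[1]
    aff[2, 3] = grid.origin_mm[2]
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), aff)
    nib.save(img, str(path))


def _read_metaimage(path: Path) -> VoxelGrid:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise InputError(f"{path}: expected a 3-D volume")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if np.any(np.abs(np.abs(direction) - np.eye(3)) > 1e-6):
        raise InputError(f"{path}: oblique MetaImage orientations are not supported")
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.transpose(data, (2, 1, 0))
    scales = np.diag(direction) * np.asarray(img.GetSpacing())
    offsets = np.asarray(img.GetOrigin(), dtype=float)
    # LPS -> package axes: negate y.
    scales[1], offsets[1] = -scales[1], -offsets[1]
    return _from_signed_diag(data, scales, offsets)


def _write_metaimage(grid: VoxelGrid, path: Path) -> None:
    import SimpleITK as sitk

    # package axes -> LPS: negate y origin; flip the y axis so spacing stays +.
    ox, oy, oz = grid.origin_mm
    ny = grid.dims[1]
    img = sitk.GetImageFromArray(np.transpose(
        np.asarray(grid.values, dtype=np.float32)[:, ::-1, :], (2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing_mm))
    img.SetOrigin((ox, -(oy + grid.spacing_mm[1] * (ny - 1)), oz))
    sitk.WriteImage(img, str(path))


def _read_dicom_series(path: Path) -> VoxelGrid:
    import pydicom

    files = sorted(
        p for p in Path(path).iterdir() if p.is_file() and p.suffix.lower() in (".dcm", "")
    )
    if not files:
        raise InputError(f"{path}: no DICOM files found")
    slices = []
    for f in files:
        try:
            slices.append(pydicom.dcmread(str(f)))
        except Exception as exc:  # pragma: no cover - passthrough diagnostics
            raise InputError(f"{path}: cannot parse {f.name}: {exc}") from exc
    iop = np.asarray(getattr(slices[0], "ImageOrientationPatient", [1, 0, 0, 0, 1, 0]), float)
    if not np.allclose(iop, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise InputError(f"{path}: oblique DICOM orientations are not supported")
    normal = np.cross(iop[:3], iop[3:])
    positions = [float(np.dot(np.asarray(s.ImagePositionPatient, float), normal)) for s in slices]
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = sorted(positions)
    steps = np.diff(positions)
    if len(steps) == 0:
        raise InputError(f"{path}: a DICOM series needs at least two slices")
    step = float(np.median(steps))
    bad = np.where(np.abs(steps - step) > 1e-3 * max(abs(step), 1.0))[0]
    if bad.size:
        i = int(bad[0])
        raise InputError(
            f"{path}: non-uniform slice spacing; gap of {steps[i]:.4f} mm between "
            f"slice positions {positions[i]:.3f} and {positions[i + 1]:.3f} "
            f"(expected {step:.4f} mm) — missing or duplicated slice?"
        )
    row_sp, col_sp = (float(v) for v in slices[0].PixelSpacing)
    stack = np.stack([s.pixel_array for s in slices], axis=-1)  # (row=y, col=x, z)
    values = np.transpose(stack, (1, 0, 2)).astype(np.float32)  # (x, y, z) in LPS
    ipp = np.asarray(slices[0].ImagePositionPatient, float)
    scales = np.array([col_sp, row_sp, step])
    offsets = np.array([ipp[0], ipp[1], positions[0]])
    # LPS -> package axes: negate y.
    scales[1], offsets[1] = -scales[1], -offsets[1]
    return _from_signed_diag(values, scales, offsets)


def read_volume(path: str | Path, format: str | None = None) -> VoxelGrid:
    """Read a voxel volume (NIfTI, MetaImage or a DICOM series directory)
    into the package's world-axis convention."""
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise InputError(f"unknown volume format {fmt!r}; expected one of {_FORMATS}")
    path = Path(path)
    if fmt == "dicom_series":
        if not path.is_dir():
            raise InputError(f"{path}: a DICOM series must be a directory")
        return _read_dicom_series(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    return _read_nifti(path) if fmt == "nifti" else _read_metaimage(path)


def write_volume(grid: VoxelGrid, path: str | Path, format: str | None = None) -> None:
    """Write a grid to NIfTI or MetaImage (DICOM export is out of scope)."""
    fmt = format or _infer_format(path)
    if fmt == "dicom_series":
        raise InputError("DICOM series are read-only")
    path = Path(path)
    if str(path.parent):
        os.makedirs(path.parent, exist_ok=True)
    if fmt == "nifti":
        _write_nifti(grid, path)
    elif fmt == "metaimage":
        _write_metaimage(grid, path)
    else:
        raise InputError(f"unknown volume format {fmt!r}")


# ---------------------------------------------------------------------------
# landmark I/O


def _reject_duplicates(pairs):
    seen = set()
    out = {}
    for k, v in pairs:
        if k in seen:
            raise InputError(f"duplicate landmark name {k!r} in file")
        seen.add(k)
        out[k] = v
    return out


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Read a JSON object mapping landmark names to [x, y, z] in mm."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such landmark file")
    try:
        with open(path) as fh:
            raw = json.load(fh, object_pairs_hook=_reject_duplicates)
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise InputError(f"{path}: landmark file must be a JSON object")
    return LandmarkSet({str(k): v for k, v in raw.items()})


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    payload = {k: [float(v) for v in p] for k, p in landmarks.points.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# segmentation


def auto_threshold(values: np.ndarray, bins: int = 128) -> float:
    """Midpoint between the two dominant modes of the intensity histogram.

    The histogram is lightly smoothed; the two most populous local maxima
    (background and material) define the threshold as the midpoint of their
    bin centres.  Grids without two distinct modes are rejected.
    """
    v = np.asarray(values)
    lo, hi = float(v.min()), float(v.max())
    if not np.isfinite([lo, hi]).all() or hi - lo <= 0:
        raise SegmentationError(
            "auto threshold needs a grid with a nonzero intensity range"
        )
    hist, edges = np.histogram(v, bins=bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(hist.astype(float), sigma=2.0, mode="nearest")
    interior = smooth[1:-1]
    is_peak = (interior >= smooth[:-2]) & (interior >= smooth[2:])
    peak_idx = np.where(is_peak)[0] + 1
    # collapse plateaus
    keep = []
    for i in peak_idx:
        if keep and i - keep[-1] <= 2 and smooth[i] == smooth[keep[-1]]:
            continue
        keep.append(int(i))
    if smooth[0] >= smooth[1]:
        keep.insert(0, 0)
    if smooth[-1] >= smooth[-2]:
        keep.append(bins - 1)
    if len(keep) < 2:
        raise SegmentationError("intensity histogram is not bimodal; supply a threshold")
    keep = sorted(keep, key=lambda i: smooth[i], reverse=True)[:2]
    return float(0.5 * (centers[min(keep)] + centers[max(keep)]))


def threshold_segment(grid: VoxelGrid, threshold: float | str = "auto") -> BinaryMask:
    """Binarize a scan: voxels with intensity >= threshold are material.

    ``threshold='auto'`` picks the midpoint between the two dominant
    histogram modes; the value used is recorded nowhere else, so callers
    wanting provenance should call :func:`auto_threshold` themselves.
    """
    thr = auto_threshold(grid.values) if threshold == "auto" else float(threshold)
    return BinaryMask.like(grid, grid.values >= thr)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise InputError(f"connectivity must be 6 or 26, got {connectivity}")


def largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Largest connected component; ties broken by smallest minimum linear
    index (C order)."""
    if mask.count == 0:
        raise SegmentationError("cannot take the largest component of an empty mask")
    labels, n = ndimage.label(mask.values, structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = np.flatnonzero(sizes == sizes.max())
    if len(best) > 1:
        flat = labels.ravel()
        best = [min(best, key=lambda lab: int(np.argmax(flat == lab)))]
    return BinaryMask.like(mask, labels == best[0])


def enclosed_cavities(material: BinaryMask, connectivity: int = 6) -> list[BinaryMask]:
    """Connected components of (hole-filled material) minus material.

    Background regions reaching the grid boundary are open to the outside
    and therefore not enclosed; hole filling excludes them by construction.
    Cavities are returned largest first.
    """
    if material.count == 0:
        raise SegmentationError("material mask is empty")
    filled = ndimage.binary_fill_holes(material.values, structure=_structure(connectivity))
    holes = filled & ~material.values
    labels, n = ndimage.label(holes, structure=_structure(connectivity))
    if n == 0:
        return []
    # Defensive boundary check: enclosed cavities can never touch the border.
    border = np.zeros_like(holes)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    touching = set(np.unique(labels[border & holes])) - {0}
    out = []
    for lab in range(1, n + 1):
        if lab in touching:
            continue
        out.append(BinaryMask.like(material, labels == lab))
    out.sort(key=lambda m: m.count, reverse=True)
    return out


def classify_cavities(
    material: BinaryMask,
    cavities: list[BinaryMask],
    landmarks: LandmarkSet,
    occlusal: Plane,
) -> OralSegmentation:
    """Identify the tongue space among the enclosed cavities.

    The tongue cavity is the one whose voxel set lies nearest (minimum
    Euclidean distance) to the lingual frenulum landmark *and* whose
    centroid is on the inferior side of the occlusal plane.  Everything
    else is returned unclassified.
    """
    if not cavities:
        raise SegmentationError("no enclosed cavities to classify")
    fren = landmarks["lingual_frenulum"]
    best_i, best_d = None, np.inf
    for i, cav in enumerate(cavities):
        idx = np.argwhere(cav.values)
        pts = np.asarray(cav.origin_mm) + idx * np.asarray(cav.spacing_mm)
        centroid = pts.mean(axis=0)
        if signed_distance(occlusal, centroid) >= 0:
            continue  # superior to the occlusal plane: not the tongue
        d = float(np.min(np.linalg.norm(pts - fren, axis=1)))
        if d < best_d:
            best_i, best_d = i, d
    if best_i is None:
        raise SegmentationError(
            "tongue space not found: no enclosed cavity has its centroid "
            "inferior to the occlusal plane"
        )
    others = [c for i, c in enumerate(cavities) if i != best_i]
    return OralSegmentation(
        material_mask=material,
        tongue_mask=cavities[best_i],
        other_cavities=others,
        provenance={
            "tongue_rule": "nearest cavity to lingual frenulum with centroid inferior to occlusal plane",
            "tongue_frenulum_distance_mm": best_d,
            "n_cavities": len(cavities),
        },
    )
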