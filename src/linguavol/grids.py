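"""Voxel containers: scalar grids and binary masks on a regular lattice.

World coordinates are right-handed patient coordinates in millimetres:
+x subject-left, +y anterior, +z superior.  A voxel is the axis-aligned
cell centred on its lattice point; every membership decision in the
package (clipping, counting) is made at voxel centres.  ``origin_mm`` is
the world position of the centre of voxel (0, 0, 0) and array axis ``i``
maps to world axis ``i`` (x, y, z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["VoxelGrid", "BinaryMask"]


def _as_triple(v) -> tuple[float, float, float]:
    a = np.asarray(v, dtype=float).reshape(-1)
    if a.size != 3 or not np.all(np.isfinite(a)):
        raise InputError(f"expected a finite length-3 vector, got {v!r}")
    return (float(a[0]), float(a[1]), float(a[2]))


@dataclass
class _Lattice:
    spacing_mm: tuple[float, float, float] = field(default=(1.0, 1.0, 1.0))
    origin_mm: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        self.spacing_mm = _as_triple(self.spacing_mm)
        self.origin_mm = _as_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise InputError(f"voxel spacing must be positive, got {self.spacing_mm}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(int(n) for n in self.values.shape)  # type: ignore[attr-defined]

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing_mm
        return sx * sy * sz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis."""
        return tuple(
            self.origin_mm[i] + self.spacing_mm[i] * np.arange(self.dims[i])
            for i in range(3)
        )

    def same_lattice(self, other: "_Lattice", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing_mm, other.spacing_mm, atol=tol)
            and np.allclose(self.origin_mm, other.origin_mm, atol=tol)
        )

    def require_same_lattice(self, other: "_Lattice") -> None:
        if not self.same_lattice(other):
            raise InputError(
                "lattice mismatch: "
                f"dims {self.dims} vs {other.dims}, "
                f"spacing {self.spacing_mm} vs {other.spacing_mm}, "
                f"origin {self.origin_mm} vs {other.origin_mm}"
            )


@dataclass
class VoxelGrid(_Lattice):
    """Scalar intensities on a regular 3-D lattice."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        super().__post_init__()
        if self.values is None:
            raise InputError("VoxelGrid requires a value array")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InputError(
                f"VoxelGrid values must be a non-empty 3-D array, got shape {self.values.shape}"
            )


@dataclass
class BinaryMask(_Lattice):
    """Boolean voxel membership sharing a grid's lattice geometry."""

    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        super().__post_init__()
        if self.values is None:
            raise InputError("BinaryMask requires a value array")
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise InputError(
                f"BinaryMask values must be a non-empty 3-D array, got shape {self.values.shape}"
            )

    @classmethod
    def like(cls, template: _Lattice, values: np.ndarray) -> "BinaryMask":
        return cls(
            spacing_mm=template.spacing_mm,
            origin_mm=template.origin_mm,
            values=values,
        )

    @property
    def count(self) -> int:
        return int(self.values.sum())
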