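"""Synthetic impression-pattern phantoms with known ground truth.

Two phantom families are provided:

* a **cuboid** phantom — the digital analogue of the acrylic
  30 x 30 x 61 mm block used for the method-error protocol; and
* a parametric **oral-cavity** phantom — an impression-material body whose
  enclosed negative spaces encode the tongue, and tooth imprints of the
  upper and lower arches, bounded above by a palate dome and laterally by
  a parabolic dental arch.

The oral model lives in "mouth" coordinates (+x subject-left, +y anterior,
+z superior) with the occlusal plane at z = 0, the posterior plane at the
upper arch's y = 0 and the inferior plane at the lingual frenulum depth.
Every region is the union, per (x, y) column, of z-intervals with analytic
endpoints, so ground-truth volumes are computed by fine in-plane
quadrature with *exact* vertical extents (the oracle; at least 4x finer
in-plane than the requested voxel spacing).  Voxelization of the same
indicator functions produces the scan grids, so truth and phantom always
describe the same geometry.

Volumes requested through a partial :class:`GroundTruth` are honoured by
uniform rescaling of the cavity (exact, volumes scale with the cube of the
scale factor) and by solving the tongue dorsum height against the oracle
(bisection; monotone by construction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .geometry import LandmarkSet
from .grids import VoxelGrid

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "SurgeryParams",
    "CohortPreset",
    "CohortDataset",
    "STUDY2020",
    "TIMEPOINTS",
    "make_cuboid_phantom",
    "make_oral_phantom",
    "apply_surgery",
    "make_cohort",
    "simulate_scan",
    "oracle_voxelize",
]

TIMEPOINTS = ("T0", "T1", "T2", "T3")

#: default material intensity against a zero background
MATERIAL_INTENSITY = 100.0


# ---------------------------------------------------------------------------
# specs and truths


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom.  All lengths in mm."""

    kind: str = "oral"  # {"cuboid", "oral"}
    spacing_mm: float = 0.4
    margin_mm: float = 6.0

    # cuboid only -----------------------------------------------------------
    dimensions_mm: tuple[float, float, float] = (30.0, 30.0, 61.0)
    #: place the cuboid faces on voxel-cell boundaries (exact voxel count)
    align_to_grid: bool = False

    # oral cavity shape -----------------------------------------------------
    arch_width_mm: float = 46.0       # inner lateral diameter at the molars
    arch_depth_mm: float = 52.0       # posterior plane to anterior arch front
    palate_height_mm: float = 12.0    # dome apex above the occlusal plane
    palate_rim_height_mm: float = 2.0
    floor_depth_mm: float = 15.0      # occlusal plane to lingual frenulum
    floor_thickness_mm: float = 7.0   # material below the inferior plane
    posterior_extension_mm: float = 8.0

    # tongue ----------------------------------------------------------------
    tongue_fill_fraction: float = 0.5675  # TV / OCC when volumes are not pinned
    tongue_shape: float = 0.35            # 0 = triangular outline, 1 = parabolic

    # surgery displacements (already applied to the geometry) ---------------
    mandibular_setback_mm: float = 0.0
    maxilla_advance_mm: float = 0.0
    maxilla_impaction_mm: float = 0.0

    # clearances and tooth imprints (scale with the phantom) ----------------
    wall_clearance_mm: float = 1.2
    floor_clearance_mm: float = 1.5
    palate_clearance_mm: float = 1.2
    tooth_radius_mm: float = 1.1
    tooth_height_mm: float = 2.2
    tooth_inset_mm: float = 3.0
    tooth_clearance_mm: float = 1.2

    material_intensity: float = MATERIAL_INTENSITY

    _MM_FIELDS = (
        "arch_width_mm", "arch_depth_mm", "palate_height_mm",
        "palate_rim_height_mm", "floor_depth_mm", "floor_thickness_mm",
        "posterior_extension_mm", "mandibular_setback_mm",
        "maxilla_advance_mm", "maxilla_impaction_mm", "wall_clearance_mm",
        "floor_clearance_mm", "palate_clearance_mm", "tooth_radius_mm",
        "tooth_height_mm", "tooth_inset_mm", "tooth_clearance_mm",
    )

    def __post_init__(self):
        if self.kind not in ("cuboid", "oral"):
            raise InputError(f"unknown phantom kind {self.kind!r}")
        if self.spacing_mm <= 0:
            raise InputError("voxel spacing must be positive")
        if self.kind == "cuboid":
            dims = tuple(float(d) for d in self.dimensions_mm)
            if len(dims) != 3 or min(dims) <= 0:
                raise InputError(f"cuboid dimensions must be 3 positive lengths, got {dims}")
            smallest = min(dims)
        else:
            if not 0.0 < self.tongue_fill_fraction < 1.0:
                raise InputError("tongue fill fraction must be strictly between 0 and 1")
            if not 0.0 <= self.tongue_shape <= 1.0:
                raise InputError("tongue shape parameter must be in [0, 1]")
            for name in ("arch_width_mm", "arch_depth_mm", "palate_height_mm",
                         "floor_depth_mm", "floor_thickness_mm"):
                if getattr(self, name) <= 0:
                    raise InputError(f"{name} must be positive")
            if self.palate_rim_height_mm >= self.palate_height_mm:
                raise InputError("palate rim must be lower than the dome apex")
            smallest = min(self.arch_width_mm, self.arch_depth_mm,
                           self.palate_height_mm, self.floor_depth_mm)
        if self.spacing_mm > smallest / 10.0:
            raise InputError(
                f"spacing {self.spacing_mm} mm is too coarse for the smallest "
                f"dimension {smallest} mm (need spacing <= dimension/10)"
            )

    def scaled(self, factor: float) -> "PhantomSpec":
        """Uniformly rescale every linear dimension (volumes scale by factor**3)."""
        if factor <= 0:
            raise InputError("scale factor must be positive")
        changes = {name: getattr(self, name) * factor for name in self._MM_FIELDS}
        if self.kind == "cuboid":
            changes["dimensions_mm"] = tuple(d * factor for d in self.dimensions_mm)
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dimensions_mm"] = list(d["dimensions_mm"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InputError(f"unknown phantom spec fields: {sorted(unknown)}")
        d = dict(d)
        if "dimensions_mm" in d:
            d["dimensions_mm"] = tuple(d["dimensions_mm"])
        return cls(**d)


@dataclass
class GroundTruth:
    """True volumes (cm^3) and the landmarks of a phantom.

    Used both as generator output and, partially filled, as a volume
    request passed to :func:`make_oral_phantom`.
    """

    occ_cm3: float | None = None
    tv_cm3: float | None = None
    ratio_pct: float | None = None
    landmarks: LandmarkSet | None = None

    def __post_init__(self):
        if self.occ_cm3 is not None and self.tv_cm3 is not None:
            if self.occ_cm3 <= 0 or self.tv_cm3 < 0:
                raise InputError("volumes must be positive")
            if self.tv_cm3 > self.occ_cm3:
                raise InputError(
                    f"infeasible truth: TV {self.tv_cm3} cm^3 exceeds OCC {self.occ_cm3} cm^3"
                )
            if self.ratio_pct is None:
                self.ratio_pct = 100.0 * self.tv_cm3 / self.occ_cm3


@dataclass(frozen=True)
class SurgeryParams:
    """Signed skeletal displacements of a bimaxillary procedure (mm)."""

    mandibular_setback_mm: float = 0.0
    maxilla_advance_mm: float = 0.0
    maxilla_impaction_mm: float = 0.0

    def __post_init__(self):
        for name in ("mandibular_setback_mm", "maxilla_advance_mm", "maxilla_impaction_mm"):
            if not np.isfinite(getattr(self, name)):
                raise InputError(f"{name} must be finite")
        if self.mandibular_setback_mm < 0:
            raise InputError("mandibular setback must be >= 0 for the Class III preset")


# ---------------------------------------------------------------------------
# cuboid phantom


def make_cuboid_phantom(spec: PhantomSpec, seed: int = 0) -> tuple[VoxelGrid, GroundTruth]:
    """Solid axis-aligned cuboid of impression material on background.

    Unless ``spec.align_to_grid`` is set, the cuboid is shifted by a random
    sub-voxel offset (seeded) so that replicates sample different
    face-to-lattice alignments, as physical repositioning would.
    """
    if spec.kind != "cuboid":
        raise InputError("make_cuboid_phantom needs a spec with kind='cuboid'")
    h = spec.spacing_mm
    rng = np.random.default_rng(seed)
    dims = np.asarray(spec.dimensions_mm, dtype=float)
    n_margin = int(np.ceil(spec.margin_mm / h))
    shape = tuple(int(np.ceil(d / h)) + 2 * n_margin + 1 for d in dims)
    offset = np.zeros(3) if spec.align_to_grid else rng.uniform(0.0, h, size=3)
    # voxel centres at origin + k*h; faces of the material at [0, L] per axis
    origin = tuple(h / 2.0 - n_margin * h - offset[i] for i in range(3))
    grid = VoxelGrid(values=np.zeros(shape, dtype=np.float32),
                     spacing_mm=(h, h, h), origin_mm=origin)
    ax, ay, az = grid.axes()
    inside = (
        ((ax >= 0) & (ax <= dims[0]))[:, None, None]
        & ((ay >= 0) & (ay <= dims[1]))[None, :, None]
        & ((az >= 0) & (az <= dims[2]))[None, None, :]
    )
    grid.values[inside] = spec.material_intensity
    truth = GroundTruth(occ_cm3=float(np.prod(dims)) / 1000.0, tv_cm3=0.0, ratio_pct=0.0)
    return grid, truth


# ---------------------------------------------------------------------------
# oral cavity model


class _OralModel:
    """Analytic column model of the oral phantom for one spec.

    Exposes vectorized per-(x, y) column descriptions of the impression
    block, the tongue envelope and the tooth imprints; both the quadrature
    oracle and the voxelizer are thin consumers of these maps.
    """

    #: tooth imprint positions as fractions of arch depth, per side
    TOOTH_FRACTIONS = (0.06, 0.20, 0.34, 0.48, 0.62, 0.76, 0.88)
    DORSUM_DROOP = 0.35

    def __init__(self, spec: PhantomSpec, dorsum_height_mm: float | None = None):
        if spec.kind != "oral":
            raise InputError("oral model needs a spec with kind='oral'")
        s = spec
        self.spec = s
        self.W2 = s.arch_width_mm / 2.0
        self.D = s.arch_depth_mm
        self.sb = s.mandibular_setback_mm
        self.adv = s.maxilla_advance_mm
        self.H = s.palate_height_mm - s.maxilla_impaction_mm
        self.H_rim = s.palate_rim_height_mm
        if self.H <= self.H_rim + 0.5:
            raise InputError("maxillary impaction flattens the palate dome completely")
        if self.sb >= self.D / 2.0 or abs(self.adv) >= self.D / 2.0:
            raise InputError("jaw displacement exceeds half the arch depth")
        self.z_inf = -s.floor_depth_mm
        self.z_floor = self.z_inf - s.floor_thickness_mm
        self.y_back = -s.posterior_extension_mm
        # tongue envelope, world coordinates: the base stays anchored near the
        # posterior plane (hyoid attachment) while the tip follows the lower
        # arch front, so a setback shortens the tongue anteriorly
        self.z_tongue_bottom = self.z_inf + s.floor_clearance_mm
        self.y_tongue_back = 0.8 * self.D / 52.0
        self.y_tongue_tip = self.D - self.sb - 3.0 * self.D / 52.0
        if self.y_tongue_tip <= self.y_tongue_back + 0.1 * self.D:
            raise InputError("mandibular setback leaves no room for the tongue")
        self.taper_k = 1.0 + s.tongue_shape
        self.dorsum_height = dorsum_height_mm
        self.teeth = self._build_teeth()

    # -- base arch ----------------------------------------------------------
    def arch_halfwidth(self, y_hat: np.ndarray) -> np.ndarray:
        """Inner half-width of the (unshifted) arch at frame coordinate y_hat."""
        y_hat = np.asarray(y_hat, dtype=float)
        t = np.clip(1.0 - np.maximum(y_hat, 0.0) / self.D, 0.0, None)
        return self.W2 * np.sqrt(t)

    def w_upper(self, y):
        return self.arch_halfwidth(np.asarray(y, dtype=float) - self.adv)

    def w_lower(self, y):
        return self.arch_halfwidth(np.asarray(y, dtype=float) + self.sb)

    def z_palate(self, x, w_up):
        """Palate dome height above the occlusal plane for |x| <= w_up."""
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(w_up > 1e-9, (np.asarray(x) / np.maximum(w_up, 1e-9)) ** 2, 1.0)
        return self.H_rim + (self.H - self.H_rim) * np.clip(1.0 - frac, 0.0, 1.0)

    # -- tooth imprints ------------------------------------------------------
    def _build_teeth(self) -> list[dict]:
        s = self.spec
        teeth = []
        for frac in self.TOOTH_FRACTIONS:
            y_hat = frac * self.D
            w = float(self.arch_halfwidth(np.array(y_hat)))
            r_c = w - s.tooth_inset_mm
            if r_c <= s.tooth_radius_mm + 0.5:
                continue
            for side in (-1.0, 1.0):
                # upper arch: pockets hang below the palate surface
                outer = min(r_c + s.tooth_radius_mm, w - 0.2)
                z_top = float(self.z_palate(np.array(outer), np.array(w))) - s.palate_clearance_mm
                teeth.append({
                    "arch": "upper",
                    "cx": side * r_c,
                    "cy": y_hat + self.adv,
                    "r": s.tooth_radius_mm,
                    "z0": z_top - s.tooth_height_mm,
                    "z1": z_top,
                })
                # lower arch: pockets sit in the floor below the inferior plane
                teeth.append({
                    "arch": "lower",
                    "cx": side * r_c,
                    "cy": y_hat - self.sb,
                    "r": s.tooth_radius_mm,
                    "z0": self.z_inf - s.floor_clearance_mm - s.tooth_height_mm,
                    "z1": self.z_inf - s.floor_clearance_mm,
                })
        return teeth

    @staticmethod
    def _tooth_footprint(tooth, X, Y, grow: float = 0.0):
        r = tooth["r"] + grow
        return (np.abs(X - tooth["cx"]) / r) ** 4 + (np.abs(Y - tooth["cy"]) / r) ** 4 <= 1.0

    # -- 2-D column maps ----------------------------------------------------
    def column_maps(self, x: np.ndarray, y: np.ndarray) -> dict:
        """Precompute per-column quantities on the (x, y) tensor grid."""
        X = np.asarray(x, dtype=float)[:, None]
        Y = np.asarray(y, dtype=float)[None, :]
        w_up = self.w_upper(Y)
        w_low = self.w_lower(Y)
        behind = Y < self.y_back  # impression body trimmed at a fixed depth
        up_in = (np.abs(X) <= w_up) & (w_up > 1e-9) & ~behind
        low_in = (np.abs(X) <= w_low) & (w_low > 1e-9) & ~behind
        z_pal = np.where(up_in, self.z_palate(X, w_up), 0.0)
        maps = {
            "x": X, "y": Y, "w_up": w_up, "w_low": w_low,
            "up_in": up_in, "low_in": low_in, "z_pal": z_pal,
        }
        maps.update(self._tongue_maps(X, Y, w_low, up_in, z_pal))
        return maps

    def _tongue_maps(self, X, Y, w_low, up_in, z_pal) -> dict:
        s = self.spec
        span = self.y_tongue_tip - self.y_tongue_back
        frac = (Y - self.y_tongue_back) / span
        in_y = (frac >= 0.0) & (frac <= 1.0)
        fr = np.clip(frac, 0.0, 1.0)
        # outline taper on top of the arch's own narrowing: the posterior
        # body keeps the full arch width and only the anterior part narrows
        # toward the tip, so realistic fill fractions (~0.45-0.8) stay feasible
        s_tip = np.clip((fr - 0.35) / 0.65, 0.0, 1.0)
        taper = ((1.0 - s_tip ** self.taper_k) ** (1.0 / self.taper_k)) ** 0.7
        w_eff = np.minimum(w_low, np.where(self.adv < 0, self.w_upper(Y), np.inf))
        a = np.clip(w_eff - s.wall_clearance_mm, 0.0, None) * taper * in_y
        in_tongue = in_y & (np.abs(X) < a) & (a > 1e-9)
        # vertical cap: palate minus clearance where under the upper arch,
        # just below the occlusal plane elsewhere
        z_cap = np.where(up_in, z_pal - s.palate_clearance_mm, -s.palate_clearance_mm)
        # gently curved underside (0.5 mm lateral rise): an exactly flat,
        # axis-aligned face would quantize to whole voxel layers when counted
        with np.errstate(divide="ignore", invalid="ignore"):
            xa = np.where(a > 1e-9, np.abs(X) / np.maximum(a, 1e-9), 0.0)
        z_bot = self.z_tongue_bottom + 0.5 * xa ** 2
        eta = 0.3 + 0.7 * (1.0 - fr ** 1.5) ** 0.7
        with np.errstate(divide="ignore", invalid="ignore"):
            lateral = 1.0 - self.DORSUM_DROOP * np.where(a > 1e-9, (X / np.maximum(a, 1e-9)) ** 2, 1.0)
        dorsum_shape = np.where(in_tongue, eta * lateral, 0.0)
        return {"tongue_in": in_tongue, "z_cap": z_cap, "z_bot": z_bot,
                "dorsum_shape": dorsum_shape}

    def tongue_top(self, maps: dict, dorsum_height_mm: float) -> np.ndarray:
        """Upper tongue surface per column (valid where ``tongue_in``).

        A 1.5 mm minimum body thickness (fading out only as the dorsum
        height itself goes to zero) keeps the anterior wedge from thinning
        into sub-voxel sheets that no scan could resolve.
        """
        profile = np.maximum(dorsum_height_mm * maps["dorsum_shape"],
                             min(1.5, dorsum_height_mm))
        return np.minimum(maps["z_bot"] + profile, maps["z_cap"])

    # -- oracle volumes ------------------------------------------------------
    def _grid_1d(self, lo, hi, dx):
        n = max(int(np.ceil((hi - lo) / dx)), 2)
        return lo + (np.arange(n) + 0.5) * (hi - lo) / n, (hi - lo) / n

    def quadrature_maps(self, dx: float) -> tuple[dict, float]:
        """Column maps over the measurement bounds: anterior to the
        posterior plane (y >= advance) and above the inferior plane."""
        xmax = self.W2 + 1.0
        ymax = self.D + max(self.adv, 0.0) + 1.0
        x, hx = self._grid_1d(-xmax, xmax, dx)
        y, hy = self._grid_1d(self.adv, ymax, dx)
        maps = self.column_maps(x, y)
        maps["_cell_area"] = hx * hy
        return maps, hx * hy

    def occ_volume_cm3(self, maps: dict) -> float:
        """OCC = block between the planes, minus tooth imprint pockets."""
        height = (
            maps["up_in"] * maps["z_pal"]
            + maps["low_in"] * self.spec.floor_depth_mm
        ).astype(float)
        total = float(height.sum()) * maps["_cell_area"]
        X, Y = maps["x"], maps["y"]
        for tooth in self.teeth:
            z0 = max(tooth["z0"], self.z_inf)
            z1 = tooth["z1"]
            if z1 <= z0:
                continue
            fp = self._tooth_footprint(tooth, X, Y)
            total -= float(fp.sum()) * (z1 - z0) * maps["_cell_area"]
        return total / 1000.0

    def tongue_volume_cm3(self, maps: dict, dorsum_height_mm: float) -> float:
        """Tongue volume inside the measurement bounds for a dorsum height."""
        top = self.tongue_top(maps, dorsum_height_mm)
        z_bot = maps["z_bot"]
        height = np.where(maps["tongue_in"], np.clip(top - z_bot, 0.0, None), 0.0)
        total = float(height.sum())
        X, Y = maps["x"], maps["y"]
        grow = self.spec.tooth_clearance_mm
        for tooth in self.teeth:
            if tooth["arch"] != "upper":
                continue
            fp = self._tooth_footprint(tooth, X, Y, grow=grow)
            sel = fp & maps["tongue_in"]
            if not sel.any():
                continue
            t0, t1 = tooth["z0"] - grow, tooth["z1"] + grow
            overlap = np.clip(
                np.minimum(top[sel], t1) - np.maximum(z_bot[sel], t0), 0.0, None
            )
            total -= float(overlap.sum())
        return total * maps["_cell_area"] / 1000.0

    def tongue_ceiling_cm3(self, maps: dict) -> tuple[float, float]:
        """Largest realizable tongue volume and the dorsum height bound."""
        # large enough that even the flattest dorsum columns saturate at the cap
        h_max = (self.H + abs(self.z_tongue_bottom)) * 2.0 / 0.18
        return self.tongue_volume_cm3(maps, h_max), h_max

    def solve_dorsum_height(self, tv_target_cm3: float, dx: float) -> float:
        """Bisect the dorsum height so that tongue volume hits the target."""
        maps, _ = self.quadrature_maps(dx)
        v_max, h_max = self.tongue_ceiling_cm3(maps)
        if tv_target_cm3 > v_max * (1.0 + 1e-9):
            raise InputError(
                f"requested tongue volume {tv_target_cm3:.2f} cm^3 exceeds the "
                f"feasible maximum {v_max:.2f} cm^3 for this cavity"
            )
        lo, hi = 0.0, h_max
        for _ in range(70):
            mid = 0.5 * (lo + hi)
            v = self.tongue_volume_cm3(maps, mid)
            if abs(v - tv_target_cm3) <= 2e-4 * max(tv_target_cm3, 1e-9):
                return mid
            if v < tv_target_cm3:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # -- membership on 3-D grids --------------------------------------------
    def regions_3d(self, maps: dict, z: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluate material/tongue/teeth membership at voxel centres."""
        if self.dorsum_height is None:
            raise InputError("dorsum height not set; build the model through make_oral_phantom")
        Z = np.asarray(z, dtype=float)[None, None, :]
        up = maps["up_in"][:, :, None] & (Z >= 0.0) & (Z <= maps["z_pal"][:, :, None])
        low = maps["low_in"][:, :, None] & (Z >= self.z_floor) & (Z < 0.0)
        block = up | low
        top = self.tongue_top(maps, self.dorsum_height)
        tongue = (
            maps["tongue_in"][:, :, None]
            & (Z >= maps["z_bot"][:, :, None])
            & (Z <= top[:, :, None])
        )
        teeth3d = np.zeros_like(block)
        jacket3d = np.zeros_like(block)
        X, Y = maps["x"], maps["y"]
        grow = self.spec.tooth_clearance_mm
        zv = np.asarray(z, dtype=float)
        for tooth in self.teeth:
            fp = self._tooth_footprint(tooth, X, Y)
            zin = (zv >= tooth["z0"]) & (zv <= tooth["z1"])
            teeth3d |= fp[:, :, None] & zin[None, None, :]
            if tooth["arch"] == "upper":
                fpg = self._tooth_footprint(tooth, X, Y, grow=grow)
                zing = (zv >= tooth["z0"] - grow) & (zv <= tooth["z1"] + grow)
                jacket3d |= fpg[:, :, None] & zing[None, None, :]
        tongue &= ~jacket3d
        material = block & ~tongue & ~teeth3d
        return {"block": block, "tongue": tongue, "teeth": teeth3d, "material": material}

    # -- landmarks -----------------------------------------------------------
    def landmarks(self) -> LandmarkSet:
        y_m6_hat = 0.30 * self.D
        x_m6 = float(self.arch_halfwidth(np.array(y_m6_hat))) - 1.0
        y_inc_hat = 0.96 * self.D
        pts = {
            "lower_first_molar_central_cusp_left": [x_m6, y_m6_hat - self.sb, 0.0],
            "lower_first_molar_central_cusp_right": [-x_m6, y_m6_hat - self.sb, 0.0],
            "incisal_edge_lower_right_central_incisor": [-1.2, y_inc_hat - self.sb, 0.0],
            "upper_second_molar_distal_cusp_left": [self.W2 - 1.0, self.adv, 2.0],
            "upper_second_molar_distal_cusp_right": [-(self.W2 - 1.0), self.adv, 2.0],
            "lingual_frenulum": [0.0, self.y_tongue_back + 1.5, self.z_inf],
        }
        return LandmarkSet(pts)


def _oral_quadrature_dx(spacing_mm: float) -> float:
    # >= 4x finer in-plane than the phantom voxels, never coarser than 0.1 mm
    return min(spacing_mm / 4.0, 0.1)


def make_oral_phantom(
    spec: PhantomSpec,
    truth_request: GroundTruth | None = None,
    seed: int = 0,
    clamp_tv: bool = False,
) -> tuple[VoxelGrid, LandmarkSet, GroundTruth]:
    """Generate an oral-cavity impression phantom.

    ``truth_request`` may pin ``occ_cm3`` and/or ``tv_cm3``; the cavity is
    rescaled uniformly for OCC and the tongue dorsum height is solved for
    TV, so the returned :class:`GroundTruth` matches the request to well
    within 0.5 %.  Without a request the tongue is sized to
    ``spec.tongue_fill_fraction`` of the cavity.

    A requested tongue volume beyond the family's geometric ceiling is an
    error by default; with ``clamp_tv=True`` it is clamped to the ceiling
    (the returned truth always reports the realized volume), which is what
    the cohort generator uses for rare extreme draws.
    """
    if spec.kind != "oral":
        raise InputError("make_oral_phantom needs a spec with kind='oral'")
    dx = _oral_quadrature_dx(spec.spacing_mm)

    occ_req = truth_request.occ_cm3 if truth_request else None
    tv_req = truth_request.tv_cm3 if truth_request else None

    model = _OralModel(spec)
    maps, _ = model.quadrature_maps(dx)
    occ = model.occ_volume_cm3(maps)
    if occ_req is not None:
        for _ in range(2):  # one corrective pass absorbs quadrature drift
            lam = float(np.cbrt(occ_req / occ))
            spec = spec.scaled(lam)
            model = _OralModel(spec)
            maps, _ = model.quadrature_maps(dx)
            occ = model.occ_volume_cm3(maps)
        if abs(occ - occ_req) > 5e-3 * occ_req:
            raise InputError("could not rescale the cavity to the requested OCC")

    tv_target = tv_req if tv_req is not None else spec.tongue_fill_fraction * occ
    if not 0.0 <= tv_target < occ:
        raise InputError(
            f"infeasible request: tongue volume {tv_target:.2f} cm^3 vs OCC {occ:.2f} cm^3"
        )
    if clamp_tv:
        v_max, _ = model.tongue_ceiling_cm3(maps)
        tv_target = min(tv_target, 0.97 * v_max)
    if tv_target <= 1e-12:
        h_d = 0.0
        tv = 0.0
    else:
        h_d = model.solve_dorsum_height(tv_target, dx)
        tv = model.tongue_volume_cm3(maps, h_d)
    model.dorsum_height = h_d

    landmarks = model.landmarks()
    truth = GroundTruth(occ_cm3=occ, tv_cm3=tv, landmarks=landmarks)

    grid = _voxelize_oral(model, seed)
    return grid, landmarks, truth


def _voxelize_oral(model: _OralModel, seed: int) -> VoxelGrid:
    spec = model.spec
    h = spec.spacing_mm
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, h, size=3)
    m = spec.margin_mm
    x_lo, x_hi = -(model.W2 + m), model.W2 + m
    y_lo, y_hi = model.y_back - m, model.D + max(model.adv, 0.0) + m
    z_lo, z_hi = model.z_floor - m, model.H + m

    def axis(lo, hi, off):
        n = int(np.ceil((hi - lo) / h)) + 1
        return lo + off + h * np.arange(n)

    ax = axis(x_lo, x_hi, offset[0])
    ay = axis(y_lo, y_hi, offset[1])
    az = axis(z_lo, z_hi, offset[2])
    maps = model.column_maps(ax, ay)
    regions = model.regions_3d(maps, az)
    values = np.where(regions["material"], np.float32(spec.material_intensity),
                      np.float32(0.0))
    return VoxelGrid(values=values, spacing_mm=(h, h, h),
                     origin_mm=(float(ax[0]), float(ay[0]), float(az[0])))


def oracle_voxelize(spec: PhantomSpec, dorsum_height_mm: float, factor: int = 4) -> dict:
    """Independent 3-D voxel-counting oracle at ``factor`` x finer spacing.

    Counts voxel centres of the analytically defined regions inside the
    measurement bounds; used to cross-check the column-quadrature truth.
    """
    model = _OralModel(spec, dorsum_height_mm=dorsum_height_mm)
    h = spec.spacing_mm / factor
    xmax = model.W2 + 1.0
    ymax = model.D + max(model.adv, 0.0) + 1.0
    ax = np.arange(-xmax + h / 2, xmax, h)
    ay = np.arange(model.adv + h / 2, ymax, h)
    az = np.arange(model.z_inf + h / 2, model.H + 1.0, h)
    maps = model.column_maps(ax, ay)
    vox = h ** 3 / 1000.0
    occ = tv = 0.0
    chunk = max(int(2e7 // (len(ax) * len(ay))), 1)
    for k0 in range(0, len(az), chunk):
        regions = model.regions_3d(maps, az[k0:k0 + chunk])
        occ += float((regions["block"] & ~regions["teeth"]).sum()) * vox
        tv += float(regions["tongue"].sum()) * vox
    return {"occ_cm3": occ, "tv_cm3": tv}


def apply_surgery(spec: PhantomSpec, params: SurgeryParams) -> PhantomSpec:
    """Displace the jaws of an oral phantom spec.

    Mandibular setback translates the lower arch (and with it the tongue
    and the lower landmarks) posteriorly; maxillary advance shifts the
    upper arch anteriorly; impaction lowers the palate dome.  Positive
    setback strictly reduces the cavity between the planes.
    """
    if spec.kind != "oral":
        raise InputError("apply_surgery needs an oral phantom spec")
    out = replace(
        spec,
        mandibular_setback_mm=spec.mandibular_setback_mm + params.mandibular_setback_mm,
        maxilla_advance_mm=spec.maxilla_advance_mm + params.maxilla_advance_mm,
        maxilla_impaction_mm=spec.maxilla_impaction_mm + params.maxilla_impaction_mm,
    )
    _OralModel(out)  # validates displacement magnitudes against the arch
    return out


# ---------------------------------------------------------------------------
# scan simulator


def simulate_scan(
    grid: VoxelGrid,
    blur_sigma_mm: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> VoxelGrid:
    """Partial-volume blur plus additive Gaussian noise; geometry unchanged."""
    if blur_sigma_mm < 0 or noise_sd < 0:
        raise InputError("blur and noise magnitudes must be nonnegative")
    values = np.asarray(grid.values, dtype=np.float32)
    if blur_sigma_mm > 0:
        sigmas = [blur_sigma_mm / s for s in grid.spacing_mm]
        values = ndimage.gaussian_filter(values, sigma=sigmas).astype(np.float32)
    else:
        values = values.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.shape).astype(np.float32)
    return VoxelGrid(values=values, spacing_mm=grid.spacing_mm, origin_mm=grid.origin_mm)


# ---------------------------------------------------------------------------
# longitudinal cohort generator


@dataclass(frozen=True)
class CohortPreset:
    """Population parameters of a longitudinal cohort (volumes in cm^3)."""

    occ_mean: tuple[float, float, float, float]
    occ_sd: tuple[float, float, float, float]
    tv_mean: tuple[float, float, float, float]
    tv_sd: tuple[float, float, float, float]
    #: Pearson correlation between per-subject T0->T1 decreases of OCC and TV
    delta_corr: float = 0.676
    #: within-measure across-time correlation (subject tracking)
    time_corr: float = 0.85
    n_duplicates: int = 2
    #: per-duplicate multiplicative volume noise (impression repeatability)
    occ_jitter_sd: float = 0.018
    tv_jitter_sd: float = 0.038
    #: per-session landmark marking noise, mm per coordinate
    landmark_noise_sd_mm: float = 0.3
    #: surgical displacement population (mean, sd) in mm
    setback: tuple[float, float] = (7.61, 2.33)
    advance: tuple[float, float] = (1.76, 1.98)
    impaction: tuple[float, float] = (2.06, 1.90)

    def __post_init__(self):
        for name in ("occ_sd", "tv_sd"):
            if min(getattr(self, name)) < 0:
                raise InputError("preset SDs must be >= 0")
        if not -1.0 <= self.delta_corr <= 1.0 or not -1.0 <= self.time_corr <= 1.0:
            raise InputError("correlations must lie in [-1, 1]")
        if any(t >= o for t, o in zip(self.tv_mean, self.occ_mean)):
            raise InputError("preset requires TV mean < OCC mean at every timepoint")
        if self.n_duplicates < 1:
            raise InputError("need at least one impression per session")

    def cross_corr(self) -> float:
        """Same-time cross-measure correlation solving the delta-correlation.

        With correlation structure R = C_meas (x) C_time (Kronecker), the
        T0->T1 delta correlation is linear in the cross-measure level r_b;
        solve for it in closed form.
        """
        sO0, sO1 = self.occ_sd[0], self.occ_sd[1]
        sT0, sT1 = self.tv_sd[0], self.tv_sd[1]
        rw = self.time_corr
        var_do = sO0 ** 2 + sO1 ** 2 - 2 * rw * sO0 * sO1
        var_dt = sT0 ** 2 + sT1 ** 2 - 2 * rw * sT0 * sT1
        base = sO0 * sT0 + sO1 * sT1 - rw * (sO0 * sT1 + sO1 * sT0)
        if base <= 0 or var_do <= 0 or var_dt <= 0:
            raise InputError("preset SD/correlation combination is degenerate")
        r_b = self.delta_corr * np.sqrt(var_do * var_dt) / base
        if abs(r_b) >= 0.999:
            raise InputError(
                f"delta correlation {self.delta_corr} is unreachable with "
                f"time correlation {self.time_corr} (needs |r_b| = {abs(r_b):.3f})"
            )
        return float(r_b)


#: Cohort preset calibrated to the study's printed summary statistics:
#: skeletal Class III adults measured before surgery and 1/3/6 months after.
STUDY2020 = CohortPreset(
    occ_mean=(38.79, 32.35, 32.37, 32.01),
    occ_sd=(4.55, 3.84, 3.48, 3.20),
    tv_mean=(22.09, 17.85, 17.92, 18.57),
    tv_sd=(4.18, 3.54, 3.34, 3.31),
)

PRESETS = {"study2020": STUDY2020}


@dataclass
class CohortDataset:
    """Latent volumes, duplicate targets and phantom recipes for a cohort."""

    preset: CohortPreset
    base_spec: PhantomSpec
    latent: pd.DataFrame   # subject_id, timepoint, occ_cm3, tv_cm3
    frame: pd.DataFrame    # + duplicate, occ/tv targets, seeds
    surgery: pd.DataFrame  # per-subject displacements

    @property
    def n_subjects(self) -> int:
        return self.latent["subject_id"].nunique()

    @property
    def n_phantoms(self) -> int:
        return len(self.frame)

    def truth_table(self) -> pd.DataFrame:
        """Per-duplicate target volumes (the generator matches them <0.5%)."""
        t = self.frame[["subject_id", "timepoint", "duplicate"]].copy()
        t["occ_cm3_true"] = self.frame["occ_cm3_target"]
        t["tv_cm3_true"] = self.frame["tv_cm3_target"]
        t["ratio_pct_true"] = 100.0 * t["tv_cm3_true"] / t["occ_cm3_true"]
        return t

    def build_phantom(
        self, subject_id: int, timepoint: str, duplicate: int, spacing_mm: float | None = None
    ) -> tuple[VoxelGrid, LandmarkSet, GroundTruth]:
        """Voxelize one impression: surgery-adjusted spec, pinned volumes,
        noisy landmarks."""
        sel = self.frame[
            (self.frame.subject_id == subject_id)
            & (self.frame.timepoint == timepoint)
            & (self.frame.duplicate == duplicate)
        ]
        if len(sel) != 1:
            raise InputError(
                f"no phantom recipe for subject {subject_id}, {timepoint}, duplicate {duplicate}"
            )
        row = sel.iloc[0]
        spec = self.base_spec
        if spacing_mm is not None:
            spec = replace(spec, spacing_mm=spacing_mm)
        if timepoint != "T0":
            srow = self.surgery[self.surgery.subject_id == subject_id].iloc[0]
            spec = apply_surgery(spec, SurgeryParams(
                mandibular_setback_mm=float(srow.setback_mm),
                maxilla_advance_mm=float(srow.advance_mm),
                maxilla_impaction_mm=float(srow.impaction_mm),
            ))
        request = GroundTruth(occ_cm3=float(row.occ_cm3_target), tv_cm3=float(row.tv_cm3_target))
        grid, landmarks, truth = make_oral_phantom(
            spec, request, seed=int(row.phantom_seed), clamp_tv=True
        )
        sd = self.preset.landmark_noise_sd_mm
        if sd > 0:
            lrng = np.random.default_rng(int(row.landmark_seed))
            noisy = {k: v + lrng.normal(0.0, sd, size=3) for k, v in landmarks.points.items()}
            landmarks = LandmarkSet(noisy)
        return grid, landmarks, truth


def make_cohort(
    preset: CohortPreset,
    n_subjects: int,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> CohortDataset:
    """Draw a longitudinal cohort of latent volumes and phantom recipes.

    Latent (OCC_t, TV_t) are multivariate normal with the preset means/SDs
    and a Kronecker correlation (exchangeable across time, cross-measure
    level solved so the T0->T1 decrease correlation matches the preset),
    truncated by resampling to 0 < TV_t < max_fill * OCC_t.  Each session
    yields ``n_duplicates`` impression recipes with independent
    multiplicative volume jitter and landmark marking noise.
    """
    if n_subjects < 2:
        raise InputError("a cohort needs at least 2 subjects")
    if base_spec is None:
        base_spec = PhantomSpec(kind="oral")
    k = len(TIMEPOINTS)
    means = np.concatenate([preset.occ_mean, preset.tv_mean])
    sds = np.concatenate([preset.occ_sd, preset.tv_sd])
    r_b = preset.cross_corr()
    c_time = np.full((k, k), preset.time_corr) + (1 - preset.time_corr) * np.eye(k)
    c_meas = np.array([[1.0, r_b], [r_b, 1.0]])
    corr = np.kron(c_meas, c_time)
    chol = np.linalg.cholesky(corr)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    rows = np.empty((n_subjects, 2 * k))
    filled = 0
    for _ in range(200):
        if filled >= n_subjects:
            break
        need = n_subjects - filled
        z = rng.standard_normal((need, 2 * k)) @ chol.T
        x = means + sds * z
        occ, tv = x[:, :k], x[:, k:]
        ok = np.all((tv > 0) & (occ > 0) & (tv < occ), axis=1)
        good = x[ok]
        take = min(len(good), need)
        rows[filled:filled + take] = good[:take]
        filled += take
    if filled < n_subjects:
        raise InputError("could not draw a feasible cohort; preset too extreme")

    latent_records, frame_records, surgery_records = [], [], []
    child_seeds = ss.spawn(n_subjects)
    for i in range(n_subjects):
        sid = i + 1
        srng = np.random.default_rng(child_seeds[i])
        setback = float(np.clip(srng.normal(*preset.setback), 0.5,
                                min(12.0, base_spec.arch_depth_mm / 4.5)))
        advance = float(np.clip(srng.normal(*preset.advance), -1.5, 3.5))
        impaction = float(np.clip(srng.normal(*preset.impaction), 0.0,
                                  min(4.5, base_spec.palate_height_mm
                                      - base_spec.palate_rim_height_mm - 2.0)))
        surgery_records.append({"subject_id": sid, "setback_mm": setback,
                                "advance_mm": advance, "impaction_mm": impaction})
        for t_i, tp in enumerate(TIMEPOINTS):
            occ_t = float(rows[i, t_i])
            tv_t = float(rows[i, k + t_i])
            latent_records.append({"subject_id": sid, "timepoint": tp,
                                   "occ_cm3": occ_t, "tv_cm3": tv_t})
            # one placement per session: duplicates differ only through the
            # jitter model, so zero jitter reproduces identical impressions
            session_seed = int(srng.integers(0, 2 ** 31 - 1))
            for dup in range(1, preset.n_duplicates + 1):
                for _ in range(100):
                    occ_d = occ_t * (1.0 + srng.normal(0.0, preset.occ_jitter_sd))
                    tv_d = tv_t * (1.0 + srng.normal(0.0, preset.tv_jitter_sd))
                    if 0 < tv_d < occ_d:
                        break
                frame_records.append({
                    "subject_id": sid, "timepoint": tp, "duplicate": dup,
                    "occ_cm3_target": occ_d, "tv_cm3_target": tv_d,
                    "phantom_seed": session_seed,
                    "landmark_seed": int(srng.integers(0, 2 ** 31 - 1)),
                })
    return CohortDataset(
        preset=preset,
        base_spec=base_spec,
        latent=pd.DataFrame(latent_records),
        frame=pd.DataFrame(frame_records),
        surgery=pd.DataFrame(surgery_records),
    )
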