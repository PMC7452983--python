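# Methods

## Measurement model

An impression pattern scanned at isotropic resolution is represented as a
`VoxelGrid` in right-handed patient coordinates (+x subject-left,
+y anterior, +z superior); DICOM/MetaImage (LPS) and NIfTI (RAS) data are
converted on read, and only axis-aligned acquisitions are accepted.  A
voxel is the axis-aligned cell centred on its lattice point; every
membership decision — thresholding, plane clipping, volume counting — is
made at voxel centres.  Volumes are pure voxel counts times the voxel
volume, with no partial-volume weighting; the voxelization error this
leaves is first-order in the spacing times the surface area and is
characterized empirically (below) instead.

Segmentation proceeds in five steps: (1) binarize at a threshold — the
automatic mode takes the midpoint between the two dominant modes of a
lightly smoothed intensity histogram, which for a blurred two-level scan
localizes boundaries at the half-maximum, i.e. at the true surface;
(2) keep the largest 26-connected component (the impression body);
(3) close the body with a 1-voxel ball, which repairs single-voxel noise
pinholes in thin walls (without this, one flipped voxel opens an enclosed
space to the background and the cavity is lost); (4) extract enclosed
cavities as the 6-connected components of (hole-filled body) minus body —
6-connectivity for cavities prevents diagonal leaks through one-voxel
corners; (5) classify as the tongue the cavity nearest the lingual
frenulum landmark whose centroid lies inferior to the occlusal plane.

The three measurement planes are exact constructions from six landmarks;
containment is enforced to 1e-6 mm and unit-normal/orthogonality to 1e-9,
far below the voxel scale.  With one upper-second-molar cusp per side the
posterior plane through both cusps perpendicular to the occlusal plane is
uniquely determined (normal proportional to n_occ x (cusp_R − cusp_L));
this two-cusp rule resolves the ambiguity of a "plane through the distal
cusp of the upper second molar".  Plane clipping keeps voxel centres with
signed distance >= 0 (or < 0 for the complementary side), a deterministic
tie-break that makes the two half-spaces an exact partition.

OCC is measured as a seeded flood fill over (material + tongue space): the
material is the cast of the free oral space, so material plus the tongue
cavity is exactly the capacity between the arches.  The fill set is first
closed with a 2-voxel ball (configurable) to seal thin interdental leaks;
the default seed is the midpoint of the frenulum-to-incisor segment moved
2 mm below the occlusal plane — by connectivity any interior seed is
equivalent.  A fill that reaches the grid boundary is reported as a leak,
never as a volume.  The mask is then clipped to the anterior side of the
posterior plane and the superior side of the inferior plane.  TV is the
tongue cavity intersected with the OCC mask, so TV <= OCC holds by
construction.  Duplicate impressions from one session are combined by
averaging the component volumes and recomputing the ratio from the
averages (ratio of averages, matching a protocol that averages volumes),
not by averaging per-impression ratios.

Tongue morphometrics are descriptive: the anterior axis is the
frenulum-to-incisor direction projected onto the occlusal plane; in 2 mm
bins along it the package reports the maximum signed height of tongue
voxels over the occlusal plane and the lateral extent of their projection,
plus the anterior/posterior width ratio (mean width of the anterior third
over the posterior third), which discriminates triangular from parabolic
tongue outlines.

## Synthetic phantoms and what they do (not) show

The **cuboid phantom** is a solid 30 x 30 x 61 mm block (54.9 cm^3) at
0.2 mm voxels.  Replicates re-place the block at random sub-voxel offsets,
so repeated runs sample different face-to-lattice alignments; with
`align_to_grid` the faces sit on voxel-cell boundaries and the counted
volume is exact.

The **oral phantom** is a parametric impression body defined per
(x, y)-column by analytic z-intervals: a parabolic dental arch (inner
half-width W/2 sqrt(1 − y/D)) bounds the body laterally, a palate dome
(rim 2 mm, apex 12 mm above the occlusal plane) forms its top surface, and
the floor extends 7 mm below the inferior plane, which lies 15 mm below
occlusion.  Defaults (arch width 46 mm, depth 52 mm) give a cavity of
about 36.5 cm^3 between the planes, in the range of adult oral capacities.
Enclosed negative spaces encode the anatomy: a tongue cavity (arch-
conformal body with a posterior-anchored base, a dorsum profile that
decays toward the tip, a taper that narrows only the anterior 65% of its
length — the shape parameter interpolates a triangular (0) to parabolic
(1) outline — a gently curved underside, and a 1.5 mm minimum body
thickness), and 28 small superellipsoid tooth-imprint pockets along both
arches, kept fully enclosed in material (1.2–1.5 mm clearances) so that
cavity extraction and classification are exercised.  Landmarks are placed
on this geometry: molar cusps and the incisal edge on the occlusal plane,
upper second molar cusps on the posterior plane, the frenulum at the
inferior plane just behind the tongue base.

Ground truth is computed by the column oracle: in-plane quadrature at
least 4x finer than the requested voxel spacing (never coarser than
0.1 mm) with *exact* z-extents, equivalent to a voxelization infinitely
fine in z; a genuine 3-D voxel-counting oracle cross-checks it in the
tests.  Requested volumes are honoured by uniform rescaling of all linear
dimensions (OCC scales exactly with the cube of the factor) and by
bisecting the dorsum height for TV (monotone by construction), to within
0.5%.  The family has a geometric fill ceiling (about 0.71 pre-op,
falling to about 0.63 after a large setback); cohort draws beyond it are
clamped to 97% of the ceiling with the realized volume recorded as truth —
censoring leaves OCC statistics exactly unbiased and shifts the T0 ratio
mean by under 0.2 points, whereas rejection-resampling would bias the
latent cohort itself.

**Surgery** acts on the spec: mandibular setback translates the lower
arch (and the lower landmarks) posteriorly and shortens the tongue
anteriorly — the tongue base stays anchored near the posterior plane, as
the hyoid attachment does not follow the mandible — maxillary advance
shifts the upper arch anteriorly, and impaction lowers the palate dome.
Positive setback strictly decreases OCC; a 7.6 mm setback removes about
16% of the default cavity, matching the magnitude surgery produces.

The **scan simulator** applies a Gaussian blur (default sigma of one
voxel, a partial-volume analogue) and additive Gaussian noise (default SD
5% of the material–background contrast).  It does not model beam
hardening, scatter, or impression-material deformation, and the phantom
is schematic anatomy; passing tests therefore demonstrate the
correctness and numerical stability of the measurement chain, not
performance on clinical scans.

The **cohort generator** draws per-subject latent (OCC_t, TV_t) for
T0–T3 from a multivariate normal matching the study's printed means and
SDs (OCC 38.79/32.35/32.37/32.01 ± 4.55/3.84/3.48/3.20 cm^3; TV
22.09/17.85/17.92/18.57 ± 4.18/3.54/3.34/3.31 cm^3), truncated by
resampling to 0 < TV < OCC.  The correlation structure is a Kronecker
product: exchangeable across time within each measure (default 0.85,
chosen so subjects track their own size over the study, which gives
per-subject percent decreases a realistic spread) times a 2 x 2
cross-measure block whose level is solved in closed form so that the
T0→T1 decrease correlation equals the printed 0.676.  Surgical
displacements per subject follow the printed populations (setback
7.61 ± 2.33 mm, advance 1.76 ± 1.98 mm, impaction 2.06 ± 1.90 mm,
clipped to geometrically valid ranges).  Each session yields two
duplicate impressions sharing one placement; duplicates differ through
independent multiplicative volume jitter (SD 1.8% OCC, 3.8% TV) and
landmark marking noise (SD 0.3 mm per coordinate).  These jitter
magnitudes are a calibration, set so the pipeline-measured intra-subject
coefficients of variation land in the 2–4% range reported for repeated
impressions, not a derived quantity.

## Statistics

All tests are two-sided, all SDs use the n−1 denominator, and the default
significance level is 0.05 (configurable).  Holm–Šidák: sort raw p
ascending, adjusted_i = max_{j<=i} 1 − (1 − p_j)^(m−j+1), capped at 1 —
adjusted values are monotone and never below raw.  The one-way
repeated-measures ANOVA computes the within-subject F and refers it to an
F distribution with both degrees of freedom multiplied by the
Greenhouse–Geisser epsilon of the sample timepoint covariance
(double-centred; epsilon lies in [1/(k−1), 1] and equals 1 under compound
symmetry).  The two-way within-subject ANOVA (measure × time) tests each
effect against its own subject-interaction mean square; post hoc cell
comparisons use single-step Šidák over all cells tested.  The decrease
regression is OLS of ΔTV on ΔOCC (decreases positive, T0 − T1), with
Pearson r and p from t = r sqrt((n−2)/(1−r²)).  Ratio-change groups: I
for changes within ±2.0 percentage points (boundaries inclusive, reading
"within −2.0 to +2.0" literally), II above, III below.

Under null cohorts with no timepoint effect but study-like per-timepoint
SDs and exchangeable subject tracking, the GG-corrected ANOVA rejects at
about 4.2% for alpha = 0.05 (n = 15, k = 4) — the expected mild
conservatism of the correction; under exact compound symmetry it is more
conservative still, which is why the type-I property is checked under
the study-like null.

## Numerical choices and problem sizes

- Tolerances: plane containment 1e-6 mm, orthogonality/unit norm 1e-9;
  truth pinning 0.5%; dorsum bisection to 0.02% of the target.
- Measurement accuracy at 0.4 mm voxels with default scan simulation:
  OCC within about 0.5% of truth (mean bias +0.4%), TV within about 1%
  (mean bias −0.2%, spread 0.6%); both comfortably inside the documented
  2% budget.  At the 0.8 mm spacing used by the fast tests the spread
  roughly doubles and test tolerances are widened accordingly.
- The end-to-end validation protocols use the study sizes: 7 cuboid
  replicates at 0.2 mm, and a 15-subject cohort (120 impressions) at
  0.4 mm.  Unit and property tests run coarser, smaller configurations.
- Degenerate inputs are errors, not silent results: constant-intensity
  grids in auto-threshold mode, empty masks, collinear occlusal
  landmarks, cusps stacked along the occlusal normal, a frenulum on the
  occlusal plane yields a zero-thickness slab and zero volumes
  downstream, flood fills that reach the grid boundary, incomplete
  repeated-measures designs, and zero-variance regressors.

## Known limitations

- The phantom's lateral OCC boundary coincides with the impression body's
  own surface; separating intra-arch from buccal/tray material on a real
  scan would need an additional trimming step the package does not model.
- Tooth imprints are floating enclosed pockets rather than open crown
  imprints; they exist to exercise cavity classification.
- The latent-volume model is normal with truncation; the study's summary
  statistics do not constrain the tails, so tail behaviour is a choice.
- Scans are processed at native spacing; no resampling between
  acquisition and analysis grids is performed.
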