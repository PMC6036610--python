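# Methods

## The residual-volume metric

Two segmentations of the same anatomy, a reference `S_ref` and an
alternative `S_alt`, are compared through the symmetric difference of the
solids they enclose, `R = (S_ref ∪ S_alt) − (S_ref ∩ S_alt)`. The package
reports the volume of `R` in cm³, its percentage of the reference volume
(`100·V_R/V_ref` — the denominator is always the reference, never the
alternative or the union), and its average thickness `V_R / A_R` in mm,
where `A_R` is the total surface area of the residual.

Two semantic choices deserve emphasis:

* **Booleans are computed on voxel masks, not on meshes.** Mesh booleans
  are numerically fragile and implementation-dependent; the voxel XOR is
  exact, deterministic, and satisfies the set-algebra identities
  (inclusion–exclusion, symmetry, the triangle inequality) to the last
  bit. Masks must share one grid; mismatched grids are an error, never a
  silent resample. Workflows that start from STL files are rasterised onto
  a common grid first (a logged approximation with a user-chosen pitch).
* **The thickness denominator is the whole boundary of the shell**, inner
  and outer faces and all disconnected islands. For a shell of physical
  thickness `t` and large lateral extent, `V/A → t/2`. We follow the
  metric's volume-over-area definition verbatim rather than inserting a
  factor-of-two "correction"; users reading the thickness as a physical
  gap should double it. An empty residual reports thickness as NaN with a
  warning — 0/0 must not print as 0.

## Segmentation

Bone is segmented by an inclusive HU window (defaults 226 and 3071 HU,
the conventional bone preset of clinical segmentation software; both
bounds inclusive, matching the usual lower/upper-threshold convention),
optionally cropped to a voxel-index box that is reused verbatim across
all configurations, then reduced to one connected component under face
adjacency (6-connectivity by default; 18/26 available). Instead of an
interactive seed, the default keeps the largest component, with ties
broken by the smallest linear voxel index so results are reproducible;
an explicit seed voxel may be given.

## Surface extraction and measurement

`extract_surface` emits the exact boundary of the voxel set: one quad
(two triangles) per exposed voxel face, each voxel being the closed box
centred on its voxel centre. The surface is closed by construction, also
for masks touching the grid edge, and the enclosed volume — computed by
the divergence theorem as a sum of signed tetrahedra — equals the
voxel-count volume identically. We evaluated interpolating isosurfaces
(marching cubes at level 0.5 on the padded indicator) and rejected them
for this purpose: on a binary mask the marching-cubes surface chamfers
every 90° edge, which shrinks a 10³-voxel cube by 1.4 % in volume and
6 % in area and reduces a single voxel to 1/6 of its volume, while the
voxel-boundary surface is exact for these cases and within ~0.1 % for a
0.5 mm-sampled sphere. For a *metric* tool, exactness and determinism
beat smooth cosmetics; an optional Laplacian smoothing pass exists for
visualisation but is off by default because it does not preserve volume.

Two caveats follow from this choice. The voxel-boundary area of an
oblique surface carries the Manhattan (staircase) factor, so absolute
areas of curved shells are overestimated relative to the smooth surface;
thickness values are correspondingly conservative (smaller). And at
edges where two voxels meet diagonally the surface touches itself
(an edge shared by four faces); the mesh is still closed and consistently
oriented — `mesh_volume` checks closedness by directed-edge balance and
reports the open-edge count on failure — but it is not strictly
2-manifold there.

Units: volumes in cm³, areas in cm², thicknesses in mm, matching how
such measurements are reported clinically.

## ROI SNR assessment

A disk ROI is a slice index, an in-plane centre in mm, and a radius
(default 3.75 mm, a ~7.5 mm-diameter disk). Voxel membership is a
centre-in-disk test — deterministic and identical to how viewer ROIs
behave — and the member index set is computed once per ROI and applied
unchanged to every configuration, so SNR differences can only come from
the images. Statistics are the mean HU, the sample SD (n−1; at least two
voxels required), and SNR = mean/SD; a constant ROI yields +inf SNR with
a warning rather than an exception.

## The synthetic phantom

`default_phantom_spec()` builds a 64×96×96-voxel, 0.5 mm isotropic
phantom (32×48×48 mm field of view): an arched hollow ellipsoid shell of
2 mm wall ("mandible", 1200 HU) intersected by a 3 mm plate with two
3 mm-radius holes ("maxilla/orbits", 1100 HU), two air ellipsoids
("sinuses", −1000 HU), all in soft tissue at 70 HU. Parameters with
units and defaults:

| parameter | default | meaning |
|---|---|---|
| `spacing_mm` | 0.5 iso | reconstruction grid (clinical thin-slice bone protocols) |
| `soft_tissue_hu` | 70 | muscle-like background attenuation |
| bone HU | 1100–1200 | cortical bone; inside the 226–3071 window |
| `psf_sigma_mm` | 0.4 | Gaussian resolution surrogate; gives interfaces the ~1-voxel ramp of a real reconstruction (without it, noise could not move the threshold contour smoothly and dose trends would be step-like) |
| `texture_sigma_hu` | 5 | smooth seeded soft-tissue heterogeneity |
| shell thickness | ≥ 2·spacing | enforced so structures are resolvable |

The ground-truth mask is the exact centre-in-solid voxelisation and is
*not* blurred; the HU volume carries PSF and texture. Everything is
deterministic given the spec's seed.

## The dose surrogate

The manufacturer noise-insertion used in clinical dose-simulation studies
operates on raw sinograms and is proprietary; this package uses an
image-space surrogate: additive zero-mean Gaussian noise with
`SD = sigma_full / sqrt(d)` for dose fraction `d` (quantum-noise scaling
with tube current), with `sigma_full = 25 HU` by default, chosen so the
full-dose soft-tissue SNR on the phantom lands in the range typical of
clinical head protocols (FBP ≈ 2.8, iterative-like ≈ 5 at 70 HU). The
iterative-reconstruction surrogate is a brute-force bilateral filter
(3³ neighbourhood, spatial σ 0.5 voxel, range σ 150 HU): with bone
contrast ≈ 1000 HU the range kernel suppresses cross-edge averaging, so
flat-region noise drops (≈ 2× SNR gain) while bone edges stay put — the
qualitative behaviour the experiment needs. No claim of equivalence to
any vendor algorithm is made. Noise is independent per configuration;
each configuration's seed is derived deterministically from the sweep's
master seed.

## The dose-sweep experiment

`run_dose_sweep` simulates every (reconstruction, dose) configuration
from one noiseless phantom, segments each (threshold → optional crop →
largest 6-connected component), and compares each segmentation to the
reference configuration — by default the highest dose with the
iterative-like reconstruction, mirroring the clinical choice of the
best-quality dataset as reference. The reference row is a
self-comparison and reports exactly zero residual. ROI SNR is measured
on four quadrant soft-tissue disks on a low slice, identical voxel sets
across configurations.

What the phantom does and does not show: it reproduces the *structure*
of the dose experiment — monotone residual-versus-dose, the
reconstruction ordering, thin-shell residual morphology, noise-inflated
model volume, SNR ∝ √dose — with residual fractions that happen to fall
in the low single-digit percent range. It does not emulate patient
anatomy, scanner noise texture (correlated, non-Gaussian), beam
hardening, or vendor STL smoothing, so absolute agreement with any
patient study is out of reach by design; conclusions transfer at the
level of trends and orderings, not absolute values.

## Numerical and design notes

* Thresholds are inclusive on both ends; enlarging the window can only
  add voxels (monotonicity is property-tested).
* Grid geometry is `(slice, row, column)`-indexed; physical position =
  origin + index·spacing per axis. Only axis-aligned volumes are
  accepted; oblique DICOM geometry raises an error rather than being
  silently mis-measured. Non-uniform slice gaps (relative tolerance
  10⁻³) and mixed-series directories are rejected.
* STL stores float32; round-trip comparisons use float32 epsilon.
  Vertex deduplication on read is exact-match (tolerance 10⁻⁸ mm).
* The STL rasteriser fills columns by crossing parity along the slice
  axis, with a distinct sub-voxel jitter per axis so scan lines cannot
  hit triangle edges exactly (equal jitter would cancel along 45°
  edges).
* `resample_to_reference` offers nearest-neighbour (default) and
  trilinear interpolation and refuses disjoint extents.
* Problem sizes in the test suite and acceptance script (64³ masks,
  the 64×96×96 phantom, 5 phantom seeds, 10 noise seeds for the SNR
  law) were chosen as the smallest sizes at which the measured
  quantities are stable to well within the asserted tolerances.

## Known limitations

* Masks of different grids are never compared implicitly; resampling is
  explicit and approximate.
* The voxel-boundary surface is blocky; exported STLs are faithful to
  the segmentation, not smoothed for printing aesthetics.
* The dose surrogate's noise is white; real CT noise is spatially
  correlated, which changes how speckle attaches to bone at fixed SD.
* Region-growing is a connected-component filter; there is no editing,
  atlas, or learning-based segmentation.
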