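# residualstl

Quality metrics for 3D-printable anatomic models segmented from CT.

When the same anatomy is segmented from two CT datasets — acquired at
different radiation doses, reconstructed with different algorithms, or
processed by different operators — the two STL surface models will not be
identical. `residualstl` quantifies that difference with the **residual
STL volume**: the physical volume occupied by exactly one of the two
models,

```
R = (S_ref ∪ S_alt) − (S_ref ∩ S_alt)
```

the symmetric difference of the enclosed solids. Three descriptors
characterise it:

* **v_residual** — the absolute residual volume (cm³);
* **fraction** — 100 · v_residual / v_ref, the residual as a percentage of
  the reference model volume;
* **thickness** — v_residual / area_residual (mm), the average thickness
  of the residual shell. A thin shell (≪ voxel size) means the models
  disagree only at tissue boundaries; a thick residual signals bulk
  segmentation error. Note the denominator is the *total* boundary area of
  the shell (inner and outer faces), so a shell of physical thickness *t*
  reads ≈ *t*/2.

The package is aimed at imaging scientists and 3D-printing labs who need
to validate acquisition or segmentation protocols — for example, how far
CT dose can be reduced before bone models change meaningfully.

## What is included

* **I/O** — DICOM series / NIfTI / NRRD volume reading (HU, physical
  geometry), binary and ASCII STL read/write.
* **Segmentation** — HU-window thresholding (default 226–3071 HU, the
  conventional bone window), voxel-index cropping, connected-component
  ("region growing") selection with 6/18/26 connectivity.
* **Meshing** — exact voxel-boundary surface extraction (closed by
  construction; enclosed volume equals the voxel-count volume), mesh
  volume via the divergence theorem, surface area.
* **Residual metric** — voxel-exact boolean algebra plus meshed reports;
  mesh-input workflows are rasterised onto a common grid first.
* **Image quality** — disk-ROI mean/SD/SNR statistics replicated on
  identical voxel sets across configurations.
* **Synthetic data** — a maxillofacial-like CT phantom (thin curved bone
  shells, plates with holes, air cavities in soft tissue) and a
  radiation-dose degradation surrogate (noise SD ∝ dose⁻¹ᐟ², optional
  edge-preserving smoothing standing in for iterative reconstruction), so
  the full dose-sweep experiment runs with no patient data.

## Worked example

Run the dose-reduction experiment on the default phantom (5 dose
fractions × 2 reconstruction surrogates, reference = full dose with the
iterative-like reconstruction):

```python
import residualstl as r

table = r.run_dose_sweep(r.default_phantom_spec(seed=1), seed=1)
print(table[["recon", "dose", "fraction_pct", "thickness_mm", "snr_mean"]])
```

```
      recon  dose  fraction_pct  thickness_mm  snr_mean
0   ir-like   0.2      3.622412      0.087816  2.131118
1   ir-like   0.3      2.834306      0.086589  2.673474
2   ir-like   0.4      2.442650      0.085746  3.021827
3   ir-like   0.5      2.209256      0.085605  3.484776
4   ir-like   1.0      0.000000           NaN  5.066201
5  fbp-like   0.2      4.119575      0.088727  1.185016
6  fbp-like   0.3      3.216370      0.087539  1.488812
7  fbp-like   0.4      2.640876      0.086510  1.729065
8  fbp-like   0.5      2.455439      0.085810  1.957198
9  fbp-like   1.0      1.753657      0.084828  2.705183
```

Reading the table: the residual fraction falls monotonically as dose
rises, is smaller for the iterative-like reconstruction than for the
FBP-like one at every dose, and every residual is a thin shell
(≈ 0.09 mm average thickness on a 0.5 mm grid — boundary flicker, not
anatomy). The reference configuration compares with itself, so its
residual is identically zero and its thickness undefined. SNR rises with
dose and with the iterative-like reconstruction.

The same pipeline is available from the shell:

```sh
residualstl segment --input ct_series/ --out mask.nii.gz
residualstl mesh    --input mask.nii.gz --out bone.stl
residualstl compare --ref bone_ref.stl --alt bone_alt.stl --grid 0.5
residualstl compare-masks --ref a.nii.gz --alt b.nii.gz --residual-stl residual.stl
residualstl snr     --config snr.yaml --out snr.csv
residualstl synth   --out phantom/
residualstl sweep   --config sweep.yaml --out results/ --seed 1
```

`compare` prints the full report as JSON, e.g. for two identical models
`"v_residual": 0.0, "fraction": 0.0`.

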