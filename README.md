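# gubquant

Quantitative analysis pipeline for fetal gubernaculum studies:

* **3D confocal quantification** — segment a cleared-organ volume from its
  nuclear counterstain channel (anisotropic median filter → plane-by-plane
  rolling-ball background subtraction → grayscale ellipsoidal closing →
  hysteresis thresholding), partition it into tip/core regions, and report
  regional mean raw immunofluorescence intensities and the tip:core ratio.
* **Micropipette-aspiration mechanics** — apparent elastic modulus from the
  elastic half-space model `E_app = 3·a·Δp / (2π·L·Φ(a, w))` with a
  dimensionless pipette wall function, anatomic position banding
  (base ≤ 25%, midportion 40–60%, tip ≥ 75% of organ height), and regional /
  gestational-day group comparisons.
* **Muscle-fiber morphometry** — object measurement (area, feret min/max by
  rotating calipers, aspect), the background-exclusion rule (objects with
  aspect < 5 or area < 500 µm² are deleted), and log-scale group summaries.
* **Synthetic data** — ground-truthed generators for all of the above:
  organ-shaped confocal phantoms with voxel-exact masks, aspiration cohorts
  drawn through the forward mechanical model, and fiber/debris tables with a
  hidden true-class column.
* **Statistics** — self-contained one-way / two-way ANOVA, pooled/Welch t,
  exact & normal-approximation Mann-Whitney U, and paired tests, all
  oracle-tested against independent implementations.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the end-to-end recovery criteria
(segmentation Dice ≥ 0.90 vs generative ground truth, forward–inverse
modulus roundtrip to 1e-12, power/type-I recovery of the regional
contrasts, exact filter/statistics oracles).

## CLI

```sh
gubquant simulate volume --config phantom.yaml --seed 1 --out sim/
gubquant simulate aspiration --config cohort.yaml --seed 1 --out sim/
gubquant simulate fibers --seed 1 --out sim/

gubquant segment --in sim/volume.tif --out seg/            # + optional --params/--exclude
gubquant quantify --volume sim/volume.tif --mask seg/organ_mask.tif \
    --landmark 130,70,70 --fraction 0.25 --out quant/
gubquant aspirate --in sim/aspiration.csv --out mech/      # --phi-form product|ratio
gubquant fibers --in sim/fibers.csv --out fib/             # or a labeled-mask TIFF + --pixel-um
gubquant stats --in tidy.csv --test anova --out report.json
```

## Data conventions

* Volumes are TIFF with a JSON sidecar (`<file>.tif.json`) carrying
  `spacing_um: [z, y, x]`, `channels: [roles]`, and sample metadata;
  axis order in memory is `(C, Z, Y, X)`. A volume without spacing
  metadata must be given `--spacing` / `spacing_um=` explicitly —
  physical-unit kernels are undefined without it.
* Aspiration pressures are stored as positive magnitudes (a −70 kPa
  suction enters as `dp_kpa = 70`).
* The wall function's algebraic form is configurable (`product`, the
  default, or `ratio`); both depend only on `w/a` and require `w < 8a`.
* Manual observer steps (abdominal-wall exclusion, tip tracing) are file
  inputs, never automated; `default_tip_partition` is a geometric
  stand-in used only for synthetic pipelines.
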