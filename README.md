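# ldscope

Quantification of lipid-droplet (LD) and plastid dynamics in the diatom
*Phaeodactylum tricornutum* from confocal and brightfield microscopy.

When *P. tricornutum* is starved of nitrogen it stores neutral lipids in
cytoplasmic LDs while dismantling its thylakoid membranes; on nitrogen
resupply the LDs fragment and are degraded. Quantifying this cycle from
images requires several coupled measurements per sample:

* **3D organelle modelling** from two-channel confocal z-stacks —
  BODIPY-stained LDs and the chlorophyll-autofluorescent thylakoid
  region are segmented per cell; each object gets a volume and a
  barycenter, and every LD a distance to the plastid,
  `d = √((x_LD−x_P)² + (y_LD−y_P)² + (z_LD−z_P)²)`;
* **population cell morphometry** from brightfield mosaics — cells are
  separated from background, debris and bubbles by a trained pixel
  classifier, screened by shape descriptors (area, circularity, aspect
  ratio, roundness, solidity), and their volumes estimated with the
  prolate-spheroid model `V = π/6 · W² · L` (W = fitted-ellipse minor
  axis, L = Feret diameter);
* **derived LD statistics** — counts, total LD volume per cell
  (V_Lipid), the fraction of LD volume held by the two largest LDs (the
  inequality indicator separating the Pt4 strategy, two dominant LDs,
  from the Pt1 strategy, many comparable LDs), and close (≤ 5 µm) vs
  distant (> 5 µm) LD–plastid distance classes;
* **pigment quantification** from 90 %-acetone extract spectra
  (trichromatic chlorophyll a / c equations) and **group statistics**
  (Shapiro–Wilk, one-way ANOVA with Fisher's LSD compact letter
  display, asterisk-coded t-tests, division rates).

The raw micrographs behind the original study are not deposited, so the
package includes a first-class synthetic-scene generator
(`ldscope.synthetic`) that renders brightfield mosaics, confocal stacks
and spectra with exact ground truth under the study's conditions
(fusiform cells 3.5–4.4 µm wide and 22.6–28.6 µm long, 0.1 µm z-step,
the two ecotypes' LD strategies, debris and bubbles). Every pipeline
stage is validated by recovering that truth.

## Worked example

Simulate a Pt4-like cell stack, model its organelles and compute the LD
metrics:

```python
from ldscope import synthetic, objects3d, ldmetrics

cfg = synthetic.SceneConfig(ecotype_label="Pt4", n_cells=1,
                            ld_strategy="two_large_dominant",
                            ld_total_volume_um3=8.0, pixel_size_um=0.072,
                            seed=21)
stack, mask, truth = synthetic.generate_confocal_stack(cfg)
rec = objects3d.model_cell(stack, mask, ecotype="Pt4",
                           voxel_size_um=(0.072, 0.072, 0.1))

vols = [o.volume_um3 for o in rec.lds]
print(f"LDs found: {len(vols)}  (planted: {len(truth.lds)})")
print(f"total LD volume: {sum(vols):.2f} um^3  "
      f"(truth: {truth.lds.volume_um3.sum():.2f})")
print(f"two largest hold: {ldmetrics.fraction_two_largest(vols):.1f} %")
d = objects3d.ld_plastid_distance(rec.lds[0], rec.thylakoid)
print(f"LD 1 to plastid: {d:.2f} um -> {ldmetrics.classify_distance(d)}")
```

prints

```
LDs found: 4  (planted: 4)
total LD volume: 8.27 um^3  (truth: 8.00)
two largest hold: 92.5 %
LD 1 to plastid: 0.98 um -> close
```

— the cell carries its planted two-dominant-LD signature: all four LDs
are recovered with a 3 % total-volume error, ~93 % of the lipid volume
sits in the two largest droplets (the Pt4 accumulation mode; a
many-medium cell scores ≤ 75 %), and the first LD lies in the close
distance class.

The same stages are available from the shell:

```bash
ldscope simulate stack --ecotype Pt4 --strategy two_large_dominant \
    --seed 21 --out stack.tif
ldscope segment-3d --stack stack.tif --ecotype Pt4 --out objects.csv
ldscope metrics --objects objects.csv --ecotype Pt4 --out metrics.csv
ldscope run --seed 5 --out run_dir    # full synthetic pipeline
```

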