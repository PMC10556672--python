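# Methods

`ldscope` quantifies lipid-droplet (LD) and plastid dynamics in the
fusiform diatom *Phaeodactylum tricornutum* from two imaging modalities —
2D brightfield mosaics for population cell morphometry and two-channel
3D confocal stacks (chlorophyll autofluorescence + BODIPY 505/515) for
per-cell organelle modelling — and reports the derived group statistics.
Because the corresponding raw microscope data are not publicly deposited,
the package ships a synthetic-scene generator with exact ground truth;
all quantitative validation is recovery of known truth under the
generator's default study conditions.

## Cell model and brightfield morphometry

**Outline.** A fusiform cell profile is modelled as a symmetric lens:
the intersection of two disks of radius `R = (L²/4 + W²/4)/W`, giving a
spindle with tip-to-tip length exactly `L` and maximal thickness exactly
`W`. The model was chosen because the measurement conventions downstream
only require that the fitted-ellipse minor axis approximate the width
and the Feret diameter the length. For this shape the moment-equivalent
ellipse has minor axis 0.958 W and the Feret diameter equals L, so the
prolate-spheroid volume estimate carries a systematic ≈ −8 % bias
relative to truth; this is well inside the 15 % recovery tolerance the
package tests, and it is a property of the measurement convention, not
of the implementation.

**Volume.** Cell volume uses the prolate-spheroid model
`V = π/6 · W² · L` with `W` = minor axis of the second-central-moment
equivalent ellipse and `L` = Feret diameter (maximum pairwise distance
between pixel centers, computed exactly via the convex hull).

**Segmentation.** Per-pixel features are the raw intensity, Sobel
gradient magnitude, moving-maximum filters at several radii (default 2,
12 and 25 px) and the orientation-pooled energy (max and mean over
angles) of a Gabor bank (default one frequency, 0.1 cycles/px, 4
orientations). Two design points matter and were found necessary:

* *Orientation pooling.* Raw per-orientation Gabor planes make the
  classifier orientation-sensitive — cells lying at angles unseen during
  training fragment into stripes. Pooling the energy across orientations
  removes the dependence.
* *Multi-scale maxima.* Debris blobs overlap cells in absolute
  intensity; what separates a thin elongated cell from a wide dark blob
  is whether a ~2.5 µm neighbourhood reaches bright background. The
  largest maximum-filter scale supplies exactly that context.

A bootstrap-aggregated decision-tree ensemble (random forest, 30 trees,
≤ 60 000 training pixels subsampled deterministically) maps features to
a per-pixel probability of the "cell" class. Training annotations in
synthetic runs emulate the manual workflow: ~20 % of the cells of one
mosaic are annotated over their full footprint — deliberately spanning
the visible contrast range, as an annotator iterating on a training
image would — plus an equal number of background pixels placed clear of
cell outlines. The probability map is thresholded at 0.5 (the map is the
deliverable; the threshold is a reporting convention), 8-connected
components are measured, and particles pass the shape screen: area
25–200 µm², circularity 0–0.4, and per-ecotype AR ≥ 3 / roundness ≤ 0.3
/ solidity ≥ 0.55 (Pt1) or AR ≥ 3.5 / roundness ≤ 0.3 / solidity ≥ 0.5
(Pt4). Touching cells are not split; merged blobs fail the screen by
design. All measurements are converted to µm before filtering.

## 3D confocal object modelling

Stacks are `(z, y, x)` with default voxel 0.072 × 0.072 × 0.1 µm.
Each channel is preprocessed with a Gaussian smooth at its physical
scale (thylakoid 0.3 µm; LD 0.1 µm) followed by baseline subtraction
and clipping at zero. The background parameter (thylakoid 0.2 µm; LD
0.2 µm Pt1 / 0.4 µm Pt4) is interpreted as the *fine scale of local
contrast to preserve*; the baseline itself is estimated with a Gaussian
at `max(10 × background, 4 × smooth, 2 µm)`. A literal Gaussian baseline
at the background scale would cancel every object larger than that scale
(a plateau minus its own slight blur leaves only a thin shell), so the
commercial tool whose parameter names are preserved here cannot be doing
that; the large-scale-baseline reading keeps the parameters meaningful
while removing offsets and slow gradients.

Binarisation is Otsu by default (overridable); the original analysis
fixed smoothing/background but set the level visually. Objects are
26-connected components; with splitting enabled, each component is
watershed-divided on its anisotropy-corrected Euclidean distance
transform, seeded at smoothed-EDT maxima separated by at least half the
component's inscribed radius. Objects whose geometric barycenter falls
outside the cell mask are removed. Volume is voxel count × voxel
volume; barycenters are unweighted voxel-center centroids
(coordinate = (index + 0.5) × voxel size, origin at the stack corner) —
intensity weighting would be an equally defensible convention, but the
geometric one is the simplest consistent with a barycenter of a
segmented body. The LD–plastid distance is the Euclidean distance
between the LD and plastid barycenters in µm.

The thylakoid region is segmented from the chlorophyll channel without
splitting, and the largest in-cell object is retained as the single
plastid region (fusiform cells carry one central bilobed plastid); this
guarantees exactly one thylakoid object per cell.

## LD metrics and group reporting

Per cell: LD count, total LD volume (V_Lipid), per-LD volumes, the
percentage of total LD volume in the two largest LDs (the
inequality-of-distribution indicator; reported only for cells with ≥ 3
LDs, configurable), LD size classes (basal 0.005–0.7 µm³ inclusive at
the upper boundary vs large; volumes below 0.005 µm³ are flagged as
likely sub-detection) and distance classes (close ≤ 5 µm inclusive,
distant > 5 µm). Per group: means and sample SDs; the mean individual
LD volume V_Lipid/LD is defined as the **ratio of the group means**
mean(V_Lipid)/mean(count). This definition reproduces all twelve
published group-table values from their printed marginals to within one
unit in the last printed decimal, which the mean of per-cell ratios does
not; it is reported without a dispersion, since no per-cell quantity has
it as its mean. Cells with zero LDs enter the count/volume means but
not the two-largest fraction.

## Pigments

Chlorophyll a and c (c1+c2) concentrations come from the trichromatic
90 %-acetone equations (`chl a = 11.85 A664 − 1.54 A647 − 0.08 A630`;
`chl c = 24.52 A630 − 1.67 A664 − 7.60 A647`, µg/mL at 1 cm), applied
after subtracting A750 for turbidity (standard practice, toggleable) and
normalising to the cuvette path. Coefficients live in a YAML config so
another solvent system can be swapped in. Per-cell content is
concentration × extract volume / (culture volume × density), in
pg/cell; the extract volume depends on the number of lysis cycles and
is always a required input. Negative raw concentrations are clipped to
zero and logged. Anchor wavelengths missing from a spectrum are
interpolated only when the grid spacing is ≤ 2 nm.

## Statistics

Within-ecotype time effects: Shapiro–Wilk normality per group (failures
are logged, not fatal — the original procedure's fallback is unstated),
then one-way ANOVA over the six sampling times; when the global F is
significant at α = 0.05, all pairwise Fisher's LSD tests use the pooled
MSE with N − k degrees of freedom, deliberately uncorrected for
multiplicity. Letters are assigned by the insert-and-absorb algorithm so
that two groups share a letter iff their LSD pair is not significant,
with 'a' on the highest mean; soundness is verified exhaustively over
all significance patterns up to six groups. Between-ecotype contrasts
use a two-sample t-test, pooled-variance by default (the variant is not
derivable from the reported procedure; a Welch switch exists), with
asterisk bands ns / * (0.01 < p < 0.05) / ** (0.001 < p < 0.01) /
*** (p < 0.001); p exactly on a boundary maps to the weaker band.
Division rates are log2(N₂/N₁)/Δt — doublings per day. The global
ANOVA's type-I error is checked by simulation (6 groups × 25, 1 000
replicates): rejection ≈ 5 %.

## Synthetic scenes: what they emulate, and what they do not

**Brightfield mosaics.** Dark lens-shaped cells at random positions and
orientations on a bright background with a weak illumination field and
Gaussian pixel noise, plus distractors: soft elliptical debris blobs
(round enough that the circularity/AR screen rejects them — they supply
the filter stage's true negatives) and high-contrast bubble rings. Cell
contrast varies per cell (uniform 0.38–0.5 darkness on a 0.85
background). Placement is rejection sampling with bounded retries; the
truth table records only placed cells.

**Confocal stacks.** One or more cells with the long axis along x; the
envelope is the lens profile revolved about the axis. The plastid is a
bilobed union of two ellipsoids on the axis, sized to a target thylakoid
volume; its symmetric construction puts the true barycenter at the cell
center. LDs are spheres with volumes drawn by strategy — `basal_only`
(all in 0.005–0.7 µm³), `two_large_dominant` (two LDs holding ~90 % of
the total plus a basal set; the Pt4 mode), `many_medium` (5–8
comparable LDs, two largest ≤ 72 % by construction; the Pt1 mode) and
`fragmented_distant` (10–18 small LDs, 75 % of them placed > 5 µm from
the plastid barycenter; the 24 h post-resupply state) — and placed
non-overlapping inside the envelope. Signal is blurred with an
isotropic-in-xy Gaussian (0.1 µm default; the emulated data are
post-deconvolution, so no full PSF model) and converted to Poisson
photon counts over a uniform background, matching photon-counting
detection.

**Absorbance spectra.** Sums of Gaussian bands whose heights at the
630/647/664 nm anchors are constructed to invert exactly through the
trichromatic equations, plus cosmetic Soret-region bands, optional flat
turbidity and Gaussian noise.

Not emulated: triradiate/oval morphotypes, touching/overlapping cells in
2D, non-spherical or intensity-graded LDs, plastid asymmetry, detector
artifacts, chromatic offsets, and any culture-growth kinetics beyond an
exponential density series. Passing recovery tests therefore
demonstrates correctness of the measurement chain under these idealised
conditions, not robustness to every property of real micrographs.

## Problem sizes and numerical choices

Validation studies run at: 200 planted cells (8 mosaics of 25, 0.1 µm/px)
for 2D recovery; 30 single-cell stacks for 3D recovery (20 in the
reproduction script); 8 stacks per strategy for the discrimination study
(6 in the script); 1 000 replicates for the ANOVA null calibration.
Degenerate inputs are defined throughout: constant images yield zero
edge features (flagged); empty foregrounds yield empty tables; particles
under 5 px are dropped; single-pixel Feret is 0; collinear particles
fall back to brute-force Feret; zero-variance samples are rejected by
the statistical tests with explicit errors. Determinism: every stochastic
component takes a seed; identical configuration + seed reproduces
images bit-identically and pipeline CSVs byte-identically.

## Known limitations

* The background-subtraction semantics of the original commercial 3D
  modelling tool are proprietary; the large-scale-baseline approximation
  preserves the parameter names but is not a reimplementation.
* The ~−4 % width bias of the moment ellipse on lens-shaped cells (hence
  ~−8 % on volumes) is inherent to the printed measurement convention.
* V_Lipid/LD is reported without a dispersion (see above).
* The pixel classifier ships untrained; real-data use requires a label
  mask (the CLI's `--labels`), mirroring the interactive training of the
  original workflow.
* 2D segmentation does not split touching cells; dense fields will lose
  merged pairs to the shape screen rather than resolve them.
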