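# Methods

This note records the models behind each pipeline, the parameters that
matter, the numerical conventions, and what the synthetic phantoms do and
do not establish about real data.

## 2D section quantification

The planar pipeline models a stained section as per-channel intensity
images sharing one pixel size, with signal of interest sitting on a
smooth background. Preprocessing is a median filter (disk footprint,
default radius 1 px) followed by local background subtraction and
clipping at zero. Two background operators are exposed because "local
background subtraction" admits both readings in common imaging software:

* `rolling_ball` (default): the morphological rolling-ball estimate at
  radius 50 µm. Note the ball geometry couples intensity units to
  spatial units — signal must be tall relative to the ball's sagitta
  over an object's width, as it is in real micrographs (hundreds to
  thousands of counts). The synthetic sections use a foreground level of
  1000 for the same reason.
* `gaussian_highpass`: subtraction of a Gaussian blur at sigma 50 µm.

Binarization is strict (`value > threshold`). Thresholds default to
per-channel Otsu with explicit overrides; whichever value is used is
logged, since a run is only reproducible given its resolved thresholds.
Objects below `min_object_px` (default 10) are removed as staining
artifacts; the rule is strict, so a 10-pixel object survives and a
9-pixel one does not. Object connectivity defaults to 8 (diagonal pixels
touch), configurable to 4.

Plaques are dilated by a Euclidean radius (default 10 µm — the value is a
package choice, recorded in every output, since only "a region
surrounding the plaques" is specified by the procedure this reimplements)
to capture plaque-adjacent microglia. Per ROI, the pipeline reports
percent positive area per marker, plaque count/areas (in px and µm²,
since the averaging unit is ambiguous in the source procedure), the
percentage of marker signal inside the dilated plaque region, the
reverse overlap of plaques by marker, and optional masked mean
intensities (which also cover astrocyte-marker intensity readouts).
Overlap ratios with empty denominators (no plaques, or no marker signal,
in a sparse section) return 0 with a logged flag rather than raising, so
batch runs complete. Per-mouse summaries are unweighted means over
sections, matching the 7–12-sections-per-mouse averaging design.

## 3D microglia reconstruction

The volume pipeline assumes three aligned channels (Iba1, methoxy-X04,
Aβ) with known, possibly anisotropic voxel sizes.

* **Resampling** to `iso_voxel` (default 0.5 µm) uses local-mean pooling:
  each output voxel is the overlap-weighted mean of input voxels, exact
  block means for integer factors (mean intensity is conserved).
* **Background** is a Gaussian blur at `bg_kernel_um` (default 10 µm),
  subtracted and clipped at zero; requires isotropic input.
* **Surfaces**: methoxy-X04 and Aβ by a single strict threshold; Iba1 by
  a bipartite threshold — voxels below `iba1_low_threshold` seed
  background, above `iba1_high_threshold` seed microglia, and the
  undecided band is resolved by random-walker segmentation. The
  "diffusion constant" maps to the edge-weight sharpness parameter β
  (default 10) of the standard combinatorial-Dirichlet formulation, the
  conventional reading when no formulation is otherwise specified. Seeded
  voxels are authoritative: the output always contains every
  above-high voxel and no below-low voxel, whatever the solver returns.
  Degenerate inputs (no seed of one class) return the empty or full mask
  with a warning instead of raising.
* **Soma seeding**: local thickness is 2 × the Euclidean distance
  transform — the conventional reading of "surface diameter". Candidate
  voxels have thickness ≥ `min_soma_diameter_um` (default 7 µm); peaks
  are selected greedily in order of decreasing thickness with
  lexicographic (z, y, x) tie-breaking, suppressing candidates within
  `min_soma_spacing_um` (default 10 µm) of an accepted peak. The spacing
  rule is applied at the peak level (non-maximum suppression) rather
  than between candidate regions; at 0.5 µm voxels the discretization
  error of thickness is ≈ ±0.5 µm, so phantom diameters near the 7 µm
  cut should be read with that tolerance.
* **Cell assignment**: every surface voxel gets the label of the
  geodesically nearest peak, where geodesic distance is shortest-path
  within the mask on the 26-connected lattice with Euclidean edge
  lengths (multi-source Dijkstra). This is the watershed of the surface
  on the distance-to-peak landscape, computed exactly; ties within
  float tolerance go to the lowest peak id, which makes results
  deterministic and lets a brute-force oracle reproduce them bit for
  bit. Voxels unreachable from every peak (disconnected crumbs) stay
  unlabeled with a warning.
* **Classification**: a cell is methoxy-X04(+) iff it overlaps the
  methoxy surface in at least `methoxy_min_voxels` voxels (default 1; a
  count threshold is exposed because the FACS gate this mirrors is
  intensity-based, not binary). Distance to the nearest plaque voxel is
  measured from the cell surface; `proximity_um` (default 10 µm, a
  package choice recorded in the output) defines "proximal".

## Brain-wide plaque maps

Inputs begin at segmented per-section masks; registration is out of
scope and the atlas label volume is assumed aligned to the grid frame.
Pixels (default 0.35 µm) are binned by floor division into grid voxels
(default 10 µm), so the total positive-pixel count is conserved and a
voxel's count is bounded by (grid/pixel)². Section z positions must be
multiples of the sectioning interval (default 100 µm).

Plaque objects are connected components of positive voxels under face
(6-) adjacency by default — the literal reading of "adjacent and
orthogonally adjacent" — with 26-connectivity exposed; within a section
plane the two differ only by diagonals. Because the sectioning interval
exceeds the grid voxel, objects structurally cannot span sections: the
z-resolution for separating plaques equals the sectioning interval, and
the test suite asserts this as a property rather than assuming it.

Each object is assigned to the structure under its centroid voxel (a
majority-vote alternative is easy to add; centroid assignment is the
default because objects are compact at 10 µm resolution). Structure
volume is atlas-voxel count × voxel volume. Density is reported twice:
raw objects/mm³, and multiplied by `section_interval / grid_voxel` — a
first-order correction for plaques lying between sampled planes — with
the correction flagged, because the choice is not derivable from the
outputs it reproduces. Ontology rollup sums counts, signal and volumes
over each structure's descendants and recomputes densities from the
sums, so children always sum to their parent. Hemisphere restriction
(quantification is conventionally reported for one hemisphere) is a
midplane mask applied to grid and atlas alike; with hemisphere-specific
structure labels it commutes with summarization.

## Omics statistics

Analyte processing: log₂(peak area / internal-standard area); features
detected in fewer than 75 % of samples are removed (detected-in-exactly-
75 % is kept); per-sample median scaling subtracts each sample's
observed-value median. Gene-count filtering keeps genes with more than
10 reads in at least `min_samples` samples, where `min_samples` is the
minimum replicate-group size of the design; technical replicates are
summed by biological sample id before filtering.

Per-feature models are ordinary least squares on complete cases against
a design of intercept + condition + categorical nuisance covariates (sex,
batch/take-down day) with first-observed-level reference coding, plus
optional numeric surrogate-variable columns. Features with residual
df < 1 are skipped with a logged reason. A rank-deficient design raises
an error naming the collinear columns. Surrogate variables can be
estimated as the top right singular vectors of the residual matrix after
fitting known covariates — a deliberately simple, non-iterative
estimator; externally estimated SVs can equally be passed as columns.
Repeated-measures designs (methoxy-X04(+) vs (−) cells from the same
animal) are handled by the paired route: within-subject differences
followed by an intercept-only fit, the transparent special case of a
subject random effect for balanced pairs; unbalanced subjects are
dropped with a log message. Samples are equally weighted throughout.

Variance moderation shrinks per-feature variances toward an
inverse-chi-square prior fitted by moment-matching on log s² (Newton
inversion of the trigamma function); the posterior variance is the
df-weighted average and the moderated df adds the prior df, capped at
the pooled residual df. When the observed dispersion of log-variances
does not exceed its sampling expectation, the prior df is infinite and
the pooled variance is the arithmetic mean of the per-feature variances,
so identical input variances moderate to exactly that variance. The
TREAT test evaluates H₀: |log₂FC| ≤ τ (default τ = log₂ 1.2) via the
two threshold-offset tail probabilities; at τ = 0 it reduces exactly to
the two-sided moderated t-test. FDR is Benjamini–Hochberg. Significance
rules are named presets recorded in the output: `analyte` requires
|2^b − 1| > 0.20 — evaluated as |b| > log₂(1.2), the symmetric log-scale
form — and q < 0.10, both strict; `gene` requires q ≤ 0.10, inclusive.
Signature extraction keeps genes with log₂FC ≥ 1, inclusive.

Gene-set activity scores restrict the matrix to the set's genes, center
each gene, and weight genes by their loadings on the first principal
component of the centered submatrix (sign-oriented so the score
correlates positively with the set's mean centered profile, the
orientation recorded); a sample's score is the weighted average of
centered expression, equal to the PC1 projection up to a positive
scalar. Sets with one present gene require an explicit single-gene
fallback. Enrichment uses the weighted running sum (hits step by
|stat| / Σ|stat| with exponent 1 on the ranking statistic, misses by
1/(N−K)); the enrichment score is the extremum of largest magnitude and
the leading edge is the set members at or before a positive extremum
(at or after a negative one). Permutation p-values are out of scope;
downstream scoring instead averages the moderated t over a leading-edge
gene universe fixed across comparisons, so scores are comparable between
comparisons. Overlap tests are exact hypergeometric upper tails.

## Synthetic phantoms

The generators emulate the statistical structure the pipelines assume:
disk/sphere/capsule geometry rasterized by the centers-inside rule (so
planted areas and counts are integer-exact), additive Gaussian noise
clipped at zero, linear background ramps, grid-voxel-aligned plaque
planting on sampled section planes, and two-genotype omics designs
balanced over sex and two batches with per-feature
missing-completely-at-random detection. Generator defaults mirror the
study designs the pipelines target: 0.35 µm section pixels at 100 µm
intervals on a 10 µm grid; 0.5 µm isotropic confocal voxels with
7–10 µm somata; omics experiments of 200 features at n = 10 per group
with noise sd 0.25 log₂ units, batch sd 0.2, sex sd 0.1.

They deliberately omit optical point-spread functions, photobleaching,
registration error, realistic microglial morphology, intensity-dependent
noise, and informative missingness. Passing the phantom tests therefore
establishes the correctness of the computations under their stated
conventions — not robustness to the optical and biochemical artifacts of
real acquisitions, whose thresholds remain operator-set inputs.

## Problem sizes and runtime

The test suite and the acceptance script are sized to run on one CPU in
a few minutes total: oracle sweeps use ≥ 1000 random grids up to 20³ for
component labeling, 64² masks for dilation, 12³ volumes for geodesic
assignment, and full enumeration up to a 20-gene universe for
hypergeometric tails; calibration uses 100 null replicates (200 features,
n = 10/group) and 20 powered replicates. Determinism is checked by
hashing every file a CLI run writes across repeated invocations.

## Known limitations

* The random-walker β and all manual thresholds are inputs; nothing here
  chooses them from data.
* The brainwide density correction assumes plaques are small relative to
  the sectioning interval (no partial-volume modeling across planes).
* The residual-SVD surrogate estimator does not iterate feature weights
  and can absorb real signal if effects are strong and widespread.
* The paired repeated-measures route requires balanced pairs; the
  consensus-correlation alternative is not implemented.
* Percent-area metrics depend on the resolved thresholds; Otsu defaults
  are only sensible for clearly bimodal channels.
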