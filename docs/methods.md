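# Methods

## The f-measure

A whole colony growing on agar is modelled as a dense central mass with
filamentous (pseudohyphal) protrusions radiating outward.  The f-measure
is the total protrusion area: `f = A_outer − A_inner`, where `A_outer`
is the area enclosed by the outer boundary of the whole object and
`A_inner` the area enclosed by the boundary of the central mass alone.
The package reports areas as pixel counts of filled regions; boundary
polygons are computed only for QC overlays.  This avoids polygon-versus-
pixel half-open ambiguities — every area is the size of a set of pixels.

### Segmentation pipeline

1. **Standardize.**  The image is collapsed to grayscale with ITU-R 601
   luminance weights and rescaled directly to the working resolution
   (default 2560×1920, the native 4:3 camera frame; most tests and
   simulations use proportionally smaller frames).  Rescaling is a direct
   resize to the fixed output, so non-4:3 inputs are stretched — the
   deliberate fixed-output behaviour of a batch measurement tool.
2. **Binarize.**  Gaussian blur with a 5×5 kernel, sigma derived from the
   kernel size by the common convention `0.3·((k−1)/2 − 1) + 0.8`
   (≈1.1 for k=5), followed by a global threshold.  The default is Otsu's
   method on the blurred image — parameter-free and reproducible — with a
   fixed-value override for difficult illumination.  Colony polarity
   (dark-on-light by default) decides which side of the threshold is
   foreground.  An all-foreground or all-background result raises
   `NoColonyFound` rather than returning a degenerate mask.
3. **Fill voids.**  Filaments that overlap or curl back onto the mass
   enclose background voids.  All enclosed holes are filled by default; a
   `min_void_area_px2` cutoff restricts filling to small voids for
   conservative use.
4. **Boundaries.**  A filled object has a single outer contour, so the
   central-mass boundary cannot be "the second contour" of the same mask.
   `A_inner` is instead obtained by morphological opening with a
   Euclidean disk (default radius 15 px at full resolution, 12 px at
   640×480), which removes every protrusion thinner than about twice the
   radius and leaves the central mass.  The opening is computed with two
   distance transforms (erode: EDT ≥ r; dilate: EDT of complement ≤ r,
   clipped to the input for anti-extensivity), which is exact for a disk
   and O(n) regardless of radius.  An opening that erases the whole
   object raises `OpeningTooAggressive`.

The opening radius is the one genuinely load-bearing tunable: it must
exceed half the widest filament and stay well below the core radius.  At
the defaults (colonies hundreds of pixels across, filaments 8–20 px
wide) any radius in 11–25 px behaves equivalently.

Calibrated output (mm²) uses `f · (pixel_size_um/1000)²`; the default
pixel size, 2.2 µm sensor pixels at 2.5× magnification = 0.88 µm, matches
a typical colony-imaging setup.  Published f-measures of the screen this
package accompanies are on an unstated scale, so the package treats px²
as primary and mm² as optional.

## Statistical chain

Per-colony f-measures are strictly positive and right-skewed with SD of
the same order as the mean, and spread differs strongly between dose
groups, so normal-theory ANOVA is avoided throughout.

* **Outlier removal** uses the Iglewicz–Hoaglin modified z-score
  `M_i = 0.6745(x_i − median)/MAD` with the conventional |M| > 3.5
  cutoff, applied in a single pass (no re-iteration after deletion).
  When MAD = 0 the score is undefined; nothing is flagged and a
  `DegenerateScaleWarning` is emitted.  Removal is non-destructive: the
  report keeps all values, scores and flags.
* **Filter scope.**  The filter pools each strain's values across doses
  (`outlier_groupby=("strain",)`).  This choice is deliberate: a filter
  blind to dose labels leaves the surviving values exchangeable across
  groups under the null hypothesis, so the downstream rank test keeps its
  nominal level (measured type-I error 0.042–0.049 across skew levels,
  n = 10/group).  Filtering within each strain × dose group instead
  shrinks within-group spread in a data-dependent way and inflates the
  chain's type-I error to 0.07–0.12 under the same conditions.  The
  trade-off: a pooled filter can clip genuine values from a very strong,
  very tight dose effect (it removes the extreme tail of the pooled
  sample).  At the package's reference conditions (n = 30/group, doubled
  filament load, imaging noise) detection power remains ≥ 0.95; the
  strain × dose scope stays available via `outlier_groupby`.
* **Kruskal–Wallis** on mid-ranks with tie correction, p from the χ²
  upper tail with df = k−1 (two for three dose groups).  An all-constant
  pooled sample is reported as H = 0, p = 1.  For the small group sizes
  typical of colony assays the χ² approximation is checked against the
  exhaustively enumerated permutation distribution
  (`filamentry.permutation`): in the decision-relevant tail
  (exact p ≤ 0.15) the two agree within 0.03 for every three-group
  design with ≥ 3 colonies per dose and N ≤ 12.  In the *center* of the
  null distribution the χ² approximation can deviate by up to ~0.1 at
  these sizes — irrelevant for significance decisions, but worth knowing
  if p-values near 0.5 are interpreted quantitatively.
* **Dunn's post-hoc test** on joint mid-ranks with the tie term
  `Σ(t³−t)/(12(N−1))` in the variance, two-sided normal p-values,
  Bonferroni-corrected with m = k(k−1)/2 = 3 and capped at 1.  Post-hoc
  testing is gated on the strain's Kruskal–Wallis p < α, mirroring the
  sequential procedure of the accompanying screen.
* **Summaries and relative changes.**  Group mean ± sample SD per
  strain × dose (by default on the filtered data).  A strain is N.D.
  (no filamentation) when every colony at every dose measures below
  `nd_epsilon`; N.D. strains are summarized but excluded from testing.
  When driven from images, `nd_epsilon` defaults to 0.5% of the median
  `A_inner`, so rasterization crumbs never count as filamentation.
  Relative change between group means is `100·(m_b − m_a)/m_a`, reported
  for significant pairs (or recomputed for an explicit pair list with
  `reproduce_printed_tables`, which prints a gap marker where a baseline
  mean is missing or non-positive).  Multiple-testing control is applied
  within strains only; no correction is made across strains.

One notational caveat: published tables of this assay family sometimes
label the statistic "χ²(3)" for three groups; the package reports the
standard df = k−1 = 2.

## Synthetic data

**Colony images** are a filled disk (radius default 90 px in a 640×480
frame — a scaled-down 4:3 camera geometry chosen to keep simulation
sweeps fast; the geometry-to-frame ratios match full-size frames) with
straight radial capsules attached to the core boundary.  Capsule angles
are uniform by default; a "spaced" placement mode (random rotation plus
jittered equal spacing) guarantees mutually resolvable protrusions.  The
spaced mode exists because a dense uniform draw — e.g. 24 filaments
20 px wide on a 565 px circumference — fuses protrusions into an annular
mass; the fused area then genuinely belongs to the opened central
object, and "protrusion area" is no longer a well-posed target for any
boundary-based measure.  Overlapping filaments are unioned before
counting, so ground truth never double-counts.  Ground truth is exact
pixel counting on the noiseless painted mask; additive Gaussian noise
(default SD 8 intensity units, clipped to [0, 255]) is applied after
painting and never alters the truth.  Generators are pure functions of
their spec including the seed.

**Cohorts** draw per-colony f-measures from lognormal distributions
moment-matched to a target mean and SD per strain × dose (positive
support and right skew, consistent with SD ≈ mean in real screens), with
optional multiplicative outlier spikes.  Default n = 30 colonies per
group (ten photographed colonies × three replicate plates per
condition).

What the generator does **not** emulate: agar texture and illumination
gradients, curved or branching filaments, multi-colony scenes, and the
optical blur of real microscopy.  Passing tests therefore demonstrate
that the pipeline recovers areas of resolvable radial protrusions under
additive noise — not that it is robust to uneven illumination or
touching colonies.

## Reference operating characteristics

Computed by `scripts/acceptance.py` and asserted in the test-suite, at
problem sizes chosen to keep a full run in minutes on one CPU:

* ground-truth recovery: 50 seeded colonies, filament widths 8–20 px,
  counts 4–24, noise SD ≤ 10 — median relative error of f vs the painted
  protrusion area ≈ 0.03 (tolerated: ≤ 0.15);
* a protrusion-free disk scores f ≤ 2% of its core area; annular voids
  are filled before measurement; 90° rotation changes f by < 3%;
* type-I error of the filter + Kruskal–Wallis chain: 1000 simulated
  null strains, n = 10/group — rejection rate ≈ 0.04–0.05 at α = 0.05;
* power: 200 image-level assays, n = 30/group, 100 µM filament count
  doubled (compact 256×192 frames) — detection rate ≥ 0.95.

## Known limitations

* One colony per image; no plate-level detection or cropping.
* `A_inner` via opening assumes protrusions thinner than the opening
  diameter; merged protrusion bundles wider than that are attributed to
  the central mass.
* The strain-pooled outlier filter can trim the extreme tail of a very
  strong dose effect (see above).
* Published per-colony data for the accompanying screen were never
  deposited, so its χ²/p values and group means cannot be re-derived
  from raw data; only the relative-change table is recomputable (from
  the published means), and the package verifies exactly that.
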