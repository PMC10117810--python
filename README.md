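# filamentry

Quantification of whole-colony pseudohyphal (filamentous) growth in
*Saccharomyces cerevisiae*, and nonparametric comparison of that phenotype
across strains and quorum-sensing-molecule doses.

Under nitrogen limitation (e.g. SLAD agar), some yeast strains switch from
the ellipsoidal yeast form to chains of elongated cells that radiate from
the colony edge as filamentous protrusions; aromatic alcohols such as
2-phenylethanol (2-PE) modulate the switch.  `filamentry` is for
microbiologists who photograph whole colonies under a brightfield
microscope and want a single reproducible number per colony — the
**f-measure** — plus a defensible statistical comparison of that number
across strains and 2-PE doses.

## The measurement and the model

For each colony image the pipeline computes

```
f  =  A_outer − A_inner
```

where `A_outer` is the area enclosed by the boundary of all filamentous
protrusions and `A_inner` the area enclosed by the boundary of the central
colony mass.  The image is rescaled to a fixed working resolution,
converted to grayscale, smoothed with a 5×5 Gaussian kernel, thresholded
(Otsu by default), enclosed voids are filled, `A_outer` is the pixel area
of the dominant object, and `A_inner` the area of the same object after a
morphological opening with a disk that strips protrusions thinner than
twice its radius.  Areas are pixel counts (optionally calibrated to mm²).

Per-colony f-measures are right-skewed with unequal spread across groups,
so inference is rank-based.  For each strain with colonies at doses
0/100/200 µM:

1. outliers are removed once by the Iglewicz–Hoaglin modified z-score
   `M_i = 0.6745 (x_i − x̃)/MAD`, |M| > 3.5, pooled within the strain;
2. a tie-corrected Kruskal–Wallis test compares the dose groups
   (p from χ² with df = k−1);
3. for significant strains, Dunn's pairwise rank tests with Bonferroni
   correction (`p_adj = min(1, 3·p_raw)`) identify which dose pairs
   differ, and the signed relative change `100·(m_b − m_a)/m_a` of the
   group means is reported for those pairs.

Strains with no filamentation at any dose are classified N.D. and
excluded from inference.  A synthetic-data module generates colony images
with exact pixel-counted ground truth and cohorts with moment-matched
lognormal f-measures, so the whole chain is testable without micrographs.

## Worked example

```python
from filamentry import (SyntheticColonySpec, generate_colony_image,
                        measure_image, PreprocessConfig,
                        FilamentationComparison)
from filamentry.synthetic import SyntheticCohortSpec, generate_cohort

# one synthetic colony with known protrusion area
spec = SyntheticColonySpec(n_filaments=12, filament_width_px=10, rng_seed=42)
image, truth = generate_colony_image(spec)
config = PreprocessConfig(target_resolution=(640, 480), opening_radius_px=12)
res = measure_image(image, config)
print(f"f-measure = {res.f_measure_px2:.0f} px^2 "
      f"(ground truth {truth.filament_area_px2} px^2)")

# a dose-responding strain: cohort moments taken from a published screen
targets = {("YMD4538", 0.0): (0.689, 0.243),
           ("YMD4538", 100.0): (1.472, 0.836),
           ("YMD4538", 200.0): (1.074, 0.257)}
cohort = generate_cohort(SyntheticCohortSpec(strains=("YMD4538",),
                                             targets=targets,
                                             n_per_group=30, rng_seed=7))
print(FilamentationComparison(cohort).fit().summary())
```

prints

```
f-measure = 10665 px^2 (ground truth 12278 px^2)

Whole-colony filamentation dose-response comparison
=======================================================
colonies: 90  (outliers removed: 3, |modified z| > 3.5)
...
Kruskal–Wallis per strain (df = k − 1)
-------------------------------------------------------
 strain       H  df      p  significant
YMD4538 47.2800   2 0.0000         True

Dunn pairwise tests, Bonferroni-adjusted
-------------------------------------------------------
 strain   dose_a   dose_b       z  p_raw  p_adj  significant
YMD4538   0.0000 100.0000 -6.1427 0.0000 0.0000         True
YMD4538   0.0000 200.0000 -5.6886 0.0000 0.0000         True
YMD4538 100.0000 200.0000  0.6058 0.5446 1.0000        False
```

The measured f-measure recovers the painted protrusion area to ~13% here;
the comparison flags the built-in dose effect (f rises from a mean of
0.69 to 1.47 at 100 µM) and attributes it to the 0→100 and 0→200 µM
pairs, exactly as the cohort was constructed.

A command-line interface mirrors the library:

```bash
filamentry simulate fixtures/ --n-per-group 10 --seed 1   # images + manifest
filamentry measure fixtures/*.png --out f.csv             # per-image f
filamentry compare f_measures.csv --out-dir tables/       # stats chain
filamentry run manifest.csv --out-dir assay_out/          # end to end
filamentry reproduce-tables --out relative_changes.csv    # from group means
```

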