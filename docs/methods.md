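# Methods

## Scope and data model

The package quantifies the image-derived and tabular endpoints of the bovine
in-vitro maturation (IVM) / fertilization (IVF) / embryo culture (IVC)
screening assay. All imaging flows through one container, a
`MultiChannelScene`: a nonnegative float array indexed `(z, channel, y, x)`
(z optional) with a channel→role map (`hoechst`, `tunel`, `ethd1`, `mito`,
`brightfield`). Scenes are stored as multi-page 16-bit TIFF with a JSON
sidecar; raw intensities are never rescaled, so results are identical for
8- and 16-bit acquisitions.

## Mitochondrial distribution (relative peripheral intensity)

The oocyte is segmented per z-plane by Otsu thresholding, keeping the
largest connected component with holes filled. The equatorial section is
the plane with the maximal cross-section area (ties broken toward the stack
middle). The diameter of a non-circular mask is defined as the equivalent
circular diameter `2·sqrt(area/π)` — well defined and stable for the nearly
circular oocyte. The center compartment is the disc out to 80% of the
radius around the mask centroid (`center_fraction = 0.8`, i.e. the inner
80% of the diameter, leaving a 10% band on each side); the cortex is the
rest of the mask. The metric is the ratio of per-pixel means,
cortex/center. The annulus holds ~36% of the disc *area*, but per-pixel
means normalise the area difference away. A zero center mean yields NaN
(flagged), never infinity. No peripheral-vs-diffuse cut-off is imposed;
group comparison is left to the statistics layer. By default the ratio is
computed on the single equatorial plane; `aggregate_planes=True` averages
over all segmentable planes instead (the averaging convention is not fixed
by the assay description; the single-plane default matches the
"maximum projection section" reading).

## Cumulus expansion

Projected COC area = pixel count of the largest Otsu component after hole
filling (the darker oocyte shadow inside the cumulus is included by the
fill). Fold-increase is the exact quotient `A_after / A_before`, reported at
full precision with a one-decimal convenience column. Note the widely used
worked figure of "2.8-fold" for 38,061/13,231 px is a truncation of 2.877;
the package reports the exact quotient and rounds half-up only in the
reporting layer. Only the 2-D projection is measured — the method does not
account for the third dimension or separate oocyte from cumulus volume, a
documented limitation of the underlying assay that is reproduced, not
corrected, here.

## Nucleus cytometry

Detection on the Hoechst channel: (1) background subtraction with a
morphological white top-hat (disk radius `bg_radius_px = 15` px, chosen to
exceed the nucleus radius so spots survive while offsets and illumination
gradients are removed — the fast equivalent of rolling-ball subtraction for
spot images); (2) Gaussian denoising (σ = 1.5 px); (3) thresholding at
`max(Otsu, median + 5·MAD·1.4826)` — the robust noise floor prevents Otsu
from splitting pure noise when true foreground is sparse, as in a marker
channel with a handful of positive nuclei; (4) watershed on the *denoised
intensity*, seeded at its local maxima (`min_distance = 3` px). Intensity
(rather than distance-transform) watershed separates overlapping spot-like
nuclei for as long as their summed intensity stays bimodal, well past the
point where the merged binary footprint becomes convex. (5) particle-size
filter, defaulting to `[0.25, 4] × median` component area (no pixel
calibration is assumed); border-touching particles are excluded.

Positivity: a nucleus is TUNEL- or EthD1-positive iff ≥ `overlap_min = 0.5`
of its pixel area overlaps the thresholded marker mask (area overlap is
robust to slight channel misregistration; the ≥ rule makes the boundary
case positive). Classes follow the marker logic (healthy / apoptotic =
TUNEL only / necrotic_only = EthD1 only / secondary = both); the necrotic
rate counts EthD1⁺ with or without TUNEL. Three planes, evenly spaced
through the informative depth range (planes whose mean intensity exceeds
the stack minimum by 5% of the dynamic range), are pooled without
inter-plane nucleus matching — at 10 µm plane spacing a cumulus nucleus
(~10 µm) rarely appears twice; pooled identical planes leave the rates
unchanged, so residual double counting biases counts, not rates.

## Statistics

* Contingency endpoints: Pearson χ² of independence (no Yates correction,
  the R×C default of the assay's original software; a toggle exists), cells
  with expected count < 5 flagged. Post hoc: pooled two-proportion z-tests,
  `z = (p̂₁−p̂₂)/sqrt(p̂(1−p̂)(1/n₁+1/n₂))`, two-sided, Bonferroni factor =
  number of comparisons performed. The default family is all group pairs
  (mirroring SPSS column-proportion behaviour); a vs-reference family is
  available for vehicle-anchored reporting. Degenerate pooled proportions
  (0 or 1) fall back to Fisher's exact test, flagged.
* Normal endpoints: one-way ANOVA (F with k−1, N−k df) and Tukey HSD from
  the studentized-range distribution (statsmodels). All-constant input is
  reported as "no effect" rather than a 0/0 F.
* Nonparametric endpoints: Kruskal–Wallis H with tie correction (scipy) and
  Dunn's pairwise z from pooled mean ranks with tie-corrected variance
  `(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ+1/nⱼ)`, Bonferroni-adjusted
  (implemented in-package; verified against a vectorised permutation null
  in the tests).
* Percentages are reported both at full precision and as half-up integers,
  matching the convention of printed screen tables.

## Synthetic data generator

The generator produces the *study conditions* the analysis stages are
validated under:

* Oocyte scenes: spheres rendered as z-stacks of circular cross-sections;
  intensity is two-level (center `base_intensity = 100`, cortex
  `base × true_ratio`), so the true ratio is exact before noise. Default
  `true_ratio = 1.4` (the vehicle-group mean of the assay), i.i.d. Gaussian
  pixel noise, clipped at zero. Single-cell, centered; no polar body.
* Expansion pairs: star-convex blobs (low-order radial harmonics scaled by
  an `irregularity ∈ [0,1]` knob) rasterized and rescaled to the requested
  pixel area within 1%. Defaults reproduce the 13,231 px / 2.877-fold
  worked example.
* Nucleus fields: 2-D Gaussian spots truncated at 3σ (σ = 3 px, amplitude
  150) at uniform positions with a minimum separation (default 14 px ≈ 4.7σ;
  0 produces touching nuclei as a watershed stress case), constant
  background 10, optional linear gradient (amplitude 15), Gaussian noise
  (noise SD 30 ⇒ spot SNR 5). Default density ~250 nuclei per 512 px frame,
  the order observed in a confocal COC cross-section; no public pixel
  calibration exists for the assay, so density and diameter are
  user-overridable.
* Outcome tables: one multinomial draw per group; steroid concentrations
  from zero-truncated normals with the assay's vehicle vs high-DES
  pregnenolone (2.79 ± 0.28 → 7.30 ± 0.89 ng/ml) and progesterone
  (6.40 ± 0.47 → 11.20 ± 0.86 ng/ml) means as defaults, three replicates.

All randomness derives from one root seed via `SeedSequence` substreams;
identical arguments give bit-identical scenes.

What the generator does **not** emulate: irregular nucleus shapes, optical
PSF and z-blur, cumulus-cell migration, spatially correlated noise,
staining heterogeneity. Passing recovery tests therefore demonstrates the
correctness of the measurement logic under controlled conditions, not
segmentation performance on real confocal data.

## Numerical and design choices

* Otsu is the automatic threshold everywhere a threshold is needed
  (parameter-free, reproducible); every threshold and size window is
  logged per run.
* Equator/plane tie-breaks: toward the stack middle; plane selection uses
  `lo + floor((i+1)·span/(n+1))` over the informative range.
* The Kruskal–Wallis p-value is asymptotic (χ², df = k−1); the permutation
  cross-check in the tests uses 3 groups × 25 observations, where the
  asymptotic approximation is inside the Monte-Carlo CI of 10⁵
  permutations. At a few observations per group the asymptotic tail p can
  differ from the exact one by ~0.005–0.01.
* Simulation sizes in tests and the default pipeline (oocyte radius 60 px,
  100-seed ensembles, 2,000 null replicates, 500 power replicates) were
  chosen to give stable Monte-Carlo estimates at interactive runtimes.

## Known limitations

* Counts, not tracked objects: no nucleus identity across planes.
* The blastocyst-rate denominator is the number of presumptive zygotes
  entering culture; the package does not model attrition between IVF and
  IVC.
* The H statistic of a published screen cannot be reproduced without its
  raw per-COC rates; the package computes H for whatever groups are
  supplied and makes no attempt to match a printed value.
* Visual meiotic staging is out of scope: the statistics consume staged
  counts, they do not stage images.
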