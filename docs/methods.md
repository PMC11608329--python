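# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `mitonuc`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## The two-level distribution model

Let a cell contain organelles *i* = 1…n with areas *A*ᵢ (µm²), lengths
*L*ᵢ (µm) and assigned cluster counts *k*ᵢ.

**Array (population level), computed over all organelles including empty
ones:** the count histogram over {0, 1, 2, 3, ≥4}; the empty fraction
*f*₀ = #{kᵢ = 0}/n; mean clusters per mitochondrion k̄; the mean of
per-organelle ratios ⟨kᵢ/Aᵢ⟩; and the pooled density Σkᵢ/ΣAᵢ. The last
two answer different questions (organelle-weighted vs area-weighted
density) and are both reported rather than conflated; they differ whenever
count density correlates with organelle size.

**Longitudinal (single-organelle level), computed over a filtered
subset:** organelles must bear clusters, and an optional length cap
(3 µm or 6 µm are the caps used in practice for fragmented vs elongated
phenotypes) restricts the comparison to a common length range. Reported:
per-organelle linear densities kᵢ/Lᵢ and their mean; pooled normalized
arc positions of clusters; and OLS of kᵢ on Lᵢ over individual organelles
(slope = clusters/µm, intercept, r², two-sided p for slope ≠ 0, via
`scipy.stats.linregress`). With fewer than 3 usable organelles the
regression is reported as undefined rather than extrapolated.

Conditioning caveat: restricting to cluster-bearing organelles biases
density and regression upward by a factor 1/(1 − e^(−λL)) per organelle
under Poisson placement at rate λ. For parameter-recovery validation the
package therefore regresses over *all* organelles of a no-excess scene
(where slope → λ and intercept → 0 hold exactly); the filtered variant is
what `mitonuc analyze` reports for real cells, where the filter is part
of the measurement definition.

## Cluster detection

Detection replaces a manual brightness/contrast adjustment with a
deterministic contract:

1. **White top-hat**, structuring-element radius 0.3 µm (default;
   ≈ 2× the PSF-limited spot radius). Removes any background varying on
   scales larger than a spot; a spatially uniform offset is removed
   exactly, making counts invariant to added diffuse background on
   noiseless images.
2. **Per-organelle pedestal subtraction.** A diffuse background confined
   to a tube *narrower* than the structuring element is not removed by
   the top-hat — it survives as a pedestal whose height differs per
   organelle (strongest in fusion-null-like cells with high soluble-TFAM
   background). The median top-hat value within each mask component is
   subtracted, so peak prominence is measured against the local
   background.
3. **Prominence test.** Local maxima (8-neighborhood) inside the mask are
   kept when the residual exceeds `min_prominence` (default 5) times the
   robust noise scale — the median absolute deviation of in-mask
   residuals scaled to SD. MAD is used because spots themselves are
   outliers of the intensity distribution. A relative floor of 10⁻⁶ of
   the in-mask maximum suppresses flat zero plateaus on noiseless images
   while preserving gain invariance. Raising `min_prominence` can only
   remove peaks, so counts are monotonically non-increasing in it.
4. **Sub-resolution merge.** Peaks closer than `merge_radius_um`
   (default 0.25 µm) are one cluster; the centroid is the
   intensity-weighted mean of the merged peaks. This is a definition, not
   a heuristic: the counting unit is the diffraction-limited cluster, and
   no attempt is made to de-mix sub-resolution nucleoids.
5. **Footprints** grow from each kept peak by watershed on the residual,
   floored at `min_spot_area_px` (default 4) pixels; integrated
   intensities are background-subtracted residual sums.

## Organelle morphometry

Organelles are 8-connected components of the mask (components below
`min_area_um2`, default 0.05 µm², dropped). Length is measured on the
morphological skeleton converted to a weighted pixel graph (orthogonal
steps = 1 pixel edge, diagonal = √2): the diametral path (longest
shortest path between endpoints; exact double-sweep on trees, endpoint
all-pairs otherwise) with two corrections:

- **End caps.** A skeleton retracts from organelle tips by roughly one
  tube radius per end. The retraction is measured per end by ray casting
  from the path end along its outward tangent to the mask boundary,
  capped at the distance-transform value there (the ray alone over-runs
  when the end tangent is unstable; the EDT alone over-corrects flat ends
  by taking the side-wall distance). Without the correction a 1 µm
  capsule reads ~30% short.
- **Staircase smoothing.** A digital 8-connected path overestimates
  smooth curved lengths by up to ~8%; path node coordinates are smoothed
  with a 5-node moving average (endpoints pinned) before summing steps.

Verified accuracy on analytic shapes: straight bars of 1–6 µm within
1.2%, arbitrarily oriented capsules within 4.3% (worst case at 1 µm),
a quarter-circle arc of radius 2 µm within 4.2% (bounds asserted in the
test suite at 5%/7%). Degenerate cases are deterministic: blob-like masks
whose skeleton collapses to ≤ 2 pixels fall back to the maximum Feret
diameter (fragmented round mitochondria must not read as zero length, or
per-length densities diverge); pure-cycle skeletons use half the loop
weight. Edge-touching organelles are flagged, not removed; exclusion is a
switch because no universal border rule exists.

**Arc positions** are absolute coordinates along the organelle: the
start-cap distance plus the smoothed-path arc length of the node nearest
the cluster centroid, normalized by the organelle length and clipped to
[0, 1]. Normalizing by the raw path length instead would pile clusters
near organelle tips onto exactly 0 and 1 and visibly distort the
uniformity of pooled positions.

**Assignment**: each cluster belongs to the organelle under its centroid
pixel; centroids that round onto background are snapped to the nearest
labeled pixel within 2 px, otherwise the cluster is flagged unassigned
and excluded from all densities (counted and reported separately).

## Colocalization

"Colocalization coefficient" means thresholded Manders here, because the
two directions are biologically distinct: M1 = fraction of above-threshold
channel-A intensity over channel-B's above-threshold region, M2 the
converse. Thresholds are per-channel Otsu within the analysis region
(default region: union of the two channels' Otsu foregrounds, a cell-area
proxy that keeps empty background from diluting the coefficients) or
caller-fixed. Pearson's r over the region is emitted as a secondary,
symmetric summary, never as M1/M2. Costes randomization and object-based
colocalization are out of scope. Line profiles sample channels by
bilinear interpolation at half-pixel steps along a physical segment,
averaged across an optional perpendicular width.

## Synthetic scenes and what they do (not) show

The generator emulates live-cell confocal imaging of nucleoid and
mitochondrial channels on a 2D grid (default 0.04 µm/px — a typical
super-resolution-mode lateral sampling; the acquisition geometry of
5-plane stacks at 0.19 µm steps is representable but scenes are generated
as the 2D projections the analysis consumes):

- **Organelles** are non-overlapping 2D capsules (rejection-sampled with
  bounded retries; surfaces at least 0.2 µm apart so segmentation can
  separate neighbors), lengths from a clipped lognormal.
- **Clusters**: each organelle is forced empty with probability
  `empty_excess`, else carries K ~ Poisson(λ·L) clusters, λ = 1 µm⁻¹ by
  default. Positions are uniform along the midline subject to a minimum
  separation of 0.4 µm (≈ two-point resolvability at the simulated PSF).
  The hard core is principled: ground-truth clusters must themselves be
  resolvable entities, or the truth would list objects that no counting
  at this resolution could distinguish — by the cluster definition they
  *are* one object. The exact sampler (uniforms on a shrunken interval,
  sorted, re-expanded) is used; K is reduced if the midline cannot hold
  it (a ≲2% effect on mean counts at λ = 1).
- **Nucleoid channel**: Gaussian spots of σ = 0.09 µm (a 70–110 nm object
  convolved with a near-diffraction PSF) plus a per-organelle uniform
  diffuse background emitting `diffuse_fraction` of the organelle's
  signal (soluble-TFAM phenotype); **mito channel**: capsule interiors,
  lightly blurred; optional striped cristae-like channel (default period
  0.25 µm) and a large nuclear blob (dsDNA-dye mode). Poisson then
  Gaussian noise; one explicit RNG stream per scene.
- **Presets** fix length distributions and diffuse levels per phenotype
  (e.g. fragmented ≤3 µm and diffuse-heavy for the fusion-null;
  elongated for overexpression) and calibrate `empty_excess` by closed
  form so the *expected observed* empty fraction — forced empties plus
  Poisson zeros E[e^(−λL)] under the preset's length law, evaluated by
  Gauss–Legendre quadrature — equals the preset target (13%, 52%, 24%,
  10%, 17%, 22%). Observed percentages are calibration targets, not raw
  parameters, because Poisson zeros alone already produce empties.

What passing synthetic tests does **not** show: real mitochondria branch
and form networks (capsules do not); real PSFs are anisotropic and depth
dependent; real backgrounds are structured, not uniform-per-organelle;
and segmentation quality on real data depends on staining, not on the
generator's high-contrast channels. The generator validates the
*measurement machinery* — detection, geometry, assignment, statistics —
not biological claims.

## Validation conditions (as run by tests and `scripts/acceptance.py`)

- Exactness: noiseless diffuse-free 20-organelle scene → detected count
  equals truth, F1 = 1.0 at 0.2 µm match radius.
- Empty-fraction recovery: wild-type-like and fusion-null-like presets,
  ≥1000 organelles through the full pipeline → measured fraction within
  the 95% binomial interval of the calibration target (the acceptance
  script accumulates 4000 organelles for a sharper estimate against the
  same interval).
- Rate recovery: λ = 1 µm⁻¹, no forced empties, lognormal lengths
  (median 3 µm, σ_log 0.35, clipped to [1.5, 6] µm — a tubular network
  where the K ≥ 1 conditioning bias is a few percent), scenes accumulated
  until ≥500 cluster-bearing organelles → mean density and OLS slope
  within 10% of 1.0, intercept within ±0.3.
- Length oracles, Manders closed forms, conservation identities
  (histogram sums to 1; density × area = assigned count exactly), filter
  semantics on a constructed 10-bar scene, and byte-identical
  reruns under a fixed seed.

## Known limitations

2D only (projection is the measured object; no 3D skeletons or spot
fitting); no machine-learning segmentation (external masks are accepted
instead); no de-mixing of sub-resolution nucleoids; no significance
testing across conditions (`compare_groups` is descriptive mean ± SEM by
design); capsule-only synthetic shapes; thresholded-Manders only (no
Costes).
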