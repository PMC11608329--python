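# mitonuc

Quantification of mitochondrial nucleoid distribution from fluorescence
microscopy, for cell biologists studying mtDNA organization (e.g. under
perturbations of mitochondrial fusion or cristae-shaping proteins such as
OPA1).

Mitochondrial DNA is packaged into nucleoids, ~70–110 nm protein–DNA
complexes that appear in light microscopy as diffraction-limited foci;
at confocal resolution each focus is a nucleoid *cluster*, possibly
containing several nucleoids, and the cluster is the unit this package
counts. `mitonuc` separates nucleoid distribution into two components
measured on the same cell:

1. **Array in the mitochondrial population.** Over *all* labeled
   organelles — including "empty" ones with no detected cluster — the
   package reports the cluster-count histogram over {0, 1, 2, 3, ≥4}, the
   empty fraction *f*₀, the mean cluster count per mitochondrion, the mean
   of per-organelle count/area ratios, and the total count density
   N/A_total (clusters · µm⁻²).

2. **Intramitochondrial longitudinal distribution.** Over a filtered
   subset (organelles bearing clusters, optionally capped in length), the
   per-organelle linear density *k*ᵢ/*L*ᵢ (clusters · µm⁻¹), the pooled
   normalized arc positions of clusters along each organelle's midline,
   and the ordinary least-squares regression *k*ᵢ = β·*L*ᵢ + α over single
   organelles with its r² and the two-sided p-value for β ≠ 0.

The asymmetry is the point of the model: empty organelles belong to the
population-level array but carry no information about within-organelle
placement.

The package also computes directional thresholded Manders coefficients
M1/M2 and line intensity profiles for nucleoid-to-cristae (dsDNA vs Mic60)
proximity, and ships a ground-truthed synthetic scene generator so every
pipeline stage is testable against a known answer (see
`docs/methods.md`).

## Pipeline

TIFF z-stacks → maximum-intensity projection → mitochondrial mask (Otsu,
or an externally produced mask, e.g. from FIJI thresholding or Trainable
Weka, ingested as-is) → cluster detection (white top-hat, per-organelle
background pedestal subtraction, prominence test in robust noise units,
sub-resolution merge) → per-organelle morphometry (area; length as the
skeleton graph's diametral path with end-cap correction and staircase
smoothing) → cluster-to-organelle assignment → array + longitudinal
statistics → CSV/JSON outputs with a full run report.

All interfaces use physical units (µm); pixel conversions are internal.
Column schemas for every output table are in
`src/mitonuc/output_schema.json`.

## Worked example

Generate one synthetic wild-type-like cell (50 organelles, 1 cluster/µm
placement rate, empty fraction calibrated to 13%) and analyze it:

```sh
mitonuc simulate --preset wt_like --n-scenes 1 --seed 7 --out scenes
mitonuc analyze --mito scenes/scene_000/mito.tif \
                --nucleoid scenes/scene_000/nucleoid.tif \
                --out results
# analyzed 50 organelles, 149 clusters -> results
```

`results/summary.json` then contains (values from this exact run):

| quantity | value | meaning |
|---|---|---|
| `empty_fraction` | 0.12 | 6 of 50 organelles carry no cluster (preset target 0.13) |
| `count_histogram` | 0.12, 0.12, 0.22, 0.08, 0.46 | fractions with 0/1/2/3/≥4 clusters |
| `mean_clusters_per_mito` | 2.98 | array-level abundance |
| `clusters_per_total_area` | 3.47 µm⁻² | 149 clusters over 42.9 µm² of mask |
| `mean_clusters_per_um` | 1.17 | linear density over the 44 cluster-bearing organelles |
| regression slope / intercept / r² | 0.881 / 0.72 / 0.44 | count rises ≈1 per µm of organelle length |

The measured linear density and slope recover the generator's placement
rate of 1 cluster/µm to within sampling error of a single 50-organelle
cell; `results/run_report.json` records every parameter and input hash
needed to reproduce the run byte-for-byte.

Other commands: `mitonuc simulate --preset opa1_null_like` (fragmented,
52% empty, strong diffuse background), `mitonuc benchmark` (scores
detection against scene ground truth over a parameter grid), and
`mitonuc coloc` (standalone Manders M1/M2 between two TIFFs).

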