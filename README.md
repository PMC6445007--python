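# mdcyto — multiparameter deformability cytometry

`mdcyto` extracts a **21-parameter physical phenotype** from high-speed
bright-field video of single cells deforming in the extensional flow of a
cross-slot microfluidic device, and provides the downstream analysis that
makes those parameters useful: an iterative SVM protocol that ranks
parameters by the classification signal they add, and a 2D
stochastic-neighbor embedding (viSNE-style) of the phenotype space.

It is written for researchers doing mechanophenotyping of suspended
cells — for example stem cells and their differentiated progeny, where
size and deformability alone often fail to separate populations and the
additional morphology and kinetics parameters carry the signal.

Because real instrument recordings are rarely shareable, the package
includes a first-class synthetic-video generator with full ground truth,
so every stage — segmentation, radial morphometry, feature extraction,
classification, embedding — can be exercised and validated end to end on
a laptop.

## The measurements

Each cell is recorded as a frame sequence (default 2 µs/frame, emulating
a ~500 000 fps camera) while it enters the extensional flow, deforms and
partially relaxes. Per frame, the cell is segmented and its boundary
expressed in a radial coordinate system: `r_membrane(θ)`, the distance
from the area centroid to the membrane at each integer degree θ. The
four parameter categories are built from two primitives:

- the **radial profile** of the pre-deformation reference frame, and
- the **aspect-ratio trace** `D(t) = l_vertical(t) / l_horizontal(t)`.

| category | parameters (registry names) |
|---|---|
| size (4) | `mean_diameter` = 2·Σθ r(θ)/360, `area` (shoelace on the 360-gon), `perimeter`, `equivalent_diameter` = √(4·area/π) |
| deformability (5) | `max_deformation` D_max, `relative_deformability` D_max/D₀, `deformation_gain` D_max−D₀, `size_normalized_deformation` D_max/equivalent_diameter, `final_deformation` D_end |
| morphology (6) | `surface_roughness_5deg` = Σθ \|r(θ) − MA₅(θ)\|, `cell_shape_30deg` = Σθ \|r(θ) − MA₃₀(θ)\|, `initial_aspect_ratio` D₀, `circularity`, `normalized_roughness`, `normalized_shape` |
| kinetics (6) | `mean_deformation_rate` (mean positive ΔD/Δt), `mean_relaxation_rate` (mean negative ΔD/Δt), `max_deformation_rate`, `min_deformation_rate`, `time_to_max_deformation`, `net_deformation_change` = D_end − D₀ |

MA_n is a trailing circular moving average over [θ−n°, θ]: the short
window isolates high-frequency surface roughness, the long window
low-frequency cell shape. Increases of D are recorded as deformation,
decreases as relaxation.

Parameter importance is ranked the way the field does it: an RBF-kernel
SVM is trained on the baseline pair {`mean_diameter`, `max_deformation`}
(the quantities classic deformability cytometry measures), then features
are added greedily, one at a time, keeping at each step the parameter
that maximises 5-fold cross-validated accuracy (grid search for C and γ
on 500 cells/class; CV on up to 5000 cells/class).

## Worked example

Simulate two populations — larger, rougher, more deformable "stem"-like
cells against smaller, smoother, stiffer "differentiated"-like cells —
then extract phenotypes, classify and embed, all from one config:

```yaml
# config.yaml
seed: 7
out_dir: demo_out
simulate:
  n_cells_per_class: 25
  classes:
    stem:           {base_radius_px: [14, 20], d_max: [1.8, 2.6], roughness_amplitude: [0.03, 0.07]}
    differentiated: {base_radius_px: [9, 14],  d_max: [1.2, 1.7], roughness_amplitude: [0.0, 0.02]}
  render: {frame_shape_px: [128, 128], n_frames: 24}
classify: {mode: full, train_per_class: 25, subset_per_class: 15, folds: 3}
embed:
  perplexity: 12
  n_iter: 500
  color_by: [mean_diameter, max_deformation, surface_roughness_5deg, mean_relaxation_rate]
```

```bash
mdc run --config config.yaml
```

This writes `demo_out/features.csv` (one row per cell, the 21 registry
columns plus cell id, label and QC flags), per-cell TIFF stacks, a
`classification.json`, embedding coordinates and four recolored scatter
plots. The classification report from this exact run:

```json
{
  "baseline_accuracy_pct": 64.7,
  "full_accuracy_pct": 100.0,
  "improvement_points": 35.3,
  "baseline_params": [0.125, 0.0078125],
  "full_params": [0.125, 0.0078125]
}
```

Read: size + peak deformation alone classify these two populations at
~65% (the size ranges overlap), while the full 21-parameter phenotype —
which also sees the roughness contrast — separates them completely; the
`*_params` pairs are the (C, γ) chosen by the grid search. The recolored
embeddings show the same story: the two clusters separate in the 2D map,
and recoloring by `surface_roughness_5deg` shows the gradient that
drives it.

The stages are also available individually (`mdc simulate`,
`mdc extract`, `mdc featurize`, `mdc classify`, `mdc embed`) and as a
library API — `render_sequence`, `build_trace`,
`phenotype_from_sequence`, sklearn-style `RBFPhenotypeSVM`,
`ForwardPhenotypeSelector` and `PhenotypeEmbedding` estimators.

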