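# Methods

This note documents the models, estimators and design choices behind
`mdcyto`, in the order data flows through the package.

## Synthetic deforming-cell videos

**Latent cell model.** A cell is a star-shaped contour around its
centroid,

    r(θ, t) = r_ell(θ; a(t), b(t)) · (1 + Σ_k ε_k cos(kθ + φ_k)),

where `r_ell` is the polar radius of an ellipse with vertical semi-axis
`a(t) = r0·√D(t)` and horizontal semi-axis `b(t) = r0/√D(t)`. This
parameterisation was chosen so that the four phenotype categories have
orthogonal ground-truth knobs: the unperturbed contour conserves area
(π·r0², so size is controlled by `r0` alone), its vertical/horizontal
extent ratio equals `D(t)` exactly (deformability controlled by the
trace alone), and boundary modes perturb morphology without moving size
or D. Low harmonics (k = 2–4) model gross cell shape; high harmonics
(k = 8–24) model surface roughness. The split straddles the 30° and 5°
moving-average cutoffs, so each morphology score responds to its own
knob. Contours with total mode amplitude ≥ 0.5 are rejected (no longer
star-shaped about the centroid).

**Deformation trace.** `D(t)` starts at a resting aspect ratio `D0 ≥ 1`,
rises by a smoothstep to `Dmax` at a peak frame, then decays by a
smoothstep toward `Dmax − relax_fraction·(Dmax − D0)`. Monotone
segments make the kinetics parameters analytically predictable (e.g. no
spurious sign changes in ΔD), which the recovery tests exploit.

**Imaging model.** Bright-field contrast is emulated as a dark rim band
(default width 2.5 px, gray level 0.15) drawn inward from the latent
contour, a slightly-brighter-than-background interior (0.70 vs 0.55),
Gaussian optical blur (σ = 1 px) and additive Gaussian sensor noise
(σ = 0.01 gray levels). Frames are rasterised on a 4× supersampled grid
and box-averaged down, emulating pixel-area integration of irradiance;
without this, hard rasterisation quantises the true edge to pixel
boundaries and no extractor can recover sub-pixel geometry. The default
frame interval is 2 µs (≈500 000 fps). All generation is a pure
function of (parameters, seed); identical inputs give bit-identical
frames.

The generator emulates: one focused cell per frame, dark-rimmed convex
blobs, sub-pixel edge information carried in gray levels, monotone
deform/relax cycles. It does **not** emulate: optical halos beyond a
single Gaussian PSF, motion blur, debris or multiple cells, focus
drift, asymmetric (non-star-shaped) cells, or viscoelastic trace shapes
beyond the smoothstep family. Passing tests therefore demonstrate
correctness of the measurement pipeline under a clean but non-trivial
imaging model, not robustness to every artifact of real recordings.

## Contour extraction

Frames are segmented by thresholding the *darkness* image
`max(median(frame) − frame, 0)` with Otsu's method (the median is a
robust background estimate; the cell rim is the only darker-than-
background structure), followed by hole filling, removal of
border-touching components, and keeping the largest component. Blank
frames raise a "no cell detected" signal and are dropped (never
interpolated), keeping their timestamps out of the trace.

Two boundary representations are provided:

- **Mask path** (`extract_radial_profile`): the 0.5 iso-contour of the
  Gaussian-smoothed (σ = 0.8) binary mask, traced by marching squares,
  densified along the polyline, binned into 360 one-degree bins by mean
  radius about the area centroid (empty bins filled by circular
  interpolation), and smoothed by a ±1-bin circular average. Accuracy
  is limited by mask quantisation: worst-bin error ≈ 0.3–0.45 px on
  rasterised analytic shapes (≤ 0.5 px asserted), because a binary mask
  cannot represent where inside a pixel the true edge fell.
- **Grayscale path** (`radial_profile_from_frame`, used by
  `build_trace`): 360 rays from the area centroid sample the darkness
  field bilinearly at 0.25 px steps; on each ray the outer rim edge is
  the outermost crossing of 0.63 × the local rim peak beyond the
  maximum. The 0.63 level comes from a 1-D model of a dark band of
  width w blurred by σ: the band peak is A·(2Φ(w/2σ)−1) while the value
  at the true outer edge is ≈ A/2, and their ratio is ≈ 0.63, nearly
  constant for w/σ in 1.5–4 (crossing at half the peak instead sits
  ~0.3σ outside the edge). Scaling by the *local* peak makes the rule
  robust to rim attenuation at highly curved tips. Typical edge error
  is < 0.1 px, which is what makes 1–3% recovery of deformation and
  diameter possible.

Extents are bounding extents of the boundary (`l_vertical` across rows,
`l_horizontal` across cols; the extension axis is vertical by
convention, with a configurable axis swap). Fitted-ellipse axes would be
an alternative; bounding extents were chosen as the simpler, convention-
free reading and are exact for the analytic ellipse on the 1° grid.

The **pre-deformation reference frame** is the earliest retained frame
before `D(t)` first exceeds its running minimum by `entry_threshold`
(default 0.05). If the cell is already deforming on its first usable
frame, the frame is still used and the cell flagged. Size and
morphology are measured on this reference profile only.

## Phenotype parameters

The registry fixes 21 named parameters (order, units, category,
provenance tag `paper|artifact`); 11 are named measurements of the
original m-DC parameter set (including the classic pair), 10 are
documented reconstructions completing the set of 21. Choices worth
recording:

- **Absolute deviations in the morphology sums.** Signed deviations
  from a circular moving average integrate to ≈ 0 around any closed
  contour, making a signed score degenerate; the scores therefore
  accumulate |r − MA|. The scores are *sums* over the 360 bins (each
  bin counted once), so their scale is 360× the mean deviation and
  grows linearly with cell radius; `normalized_roughness` and
  `normalized_shape` divide by the mean radius for scale-free variants.
- **Trailing windows.** MA_n averages bins [θ−n, θ] inclusive (n+1
  bins), wrapping circularly. Window sizes 5° and 30° are the
  defaults; both are configurable.
- **Angular sum as a diameter.** The raw angular sum Σθ r(θ) is
  reported as `mean_diameter = 2Σr/360` so the number has length units;
  the raw sum is recoverable by a constant factor.
- **Two size normalisations.** "Peak deformation normalised by size" is
  implemented as `size_normalized_deformation = D_max /
  equivalent_diameter` and kept separate from `relative_deformability
  = D_max / D0` (deformation relative to the pre-deformation aspect
  ratio rather than a circular baseline); both are in the registry.
- **Physical time.** Rates divide by the frame interval in µs; when no
  interval is available Δt = 1 frame and the unit is flagged in the
  output sidecar. `net_deformation_change` is the telescoped kinetics
  sum and equals `D_end − D0` to machine precision (asserted at 1e−12).
- **Missing values** are empty CSV fields (never zero) plus a QC flag.

## Classification protocol

Two-class RBF-SVM throughout (scikit-learn's SVC behind the package's
surface). Features are standardised to training mean/sd (sd floored at
1e−12) inside every fold — never on pooled data — because the registry
mixes units spanning orders of magnitude (px² vs 1/µs).

- **Grid search** on a seeded subset of 500 cells/class over
  C ∈ 2^{−3..7}, γ ∈ 2^{−7..3}, scored by internal stratified 5-fold
  CV; ties break toward smaller C then smaller γ (the grid is iterated
  in sorted order and only strict improvements replace the incumbent).
- **Accuracy** is mean held-out accuracy of a stratified 5-fold CV on a
  seeded subsample of up to 5000 cells/class, in percent. A fitted
  model can also be scored on a balanced 1:1 mixture with hidden truth
  (balance enforced to ±1 row, otherwise the chance level itself would
  shift); both readings are reported separately where relevant.
- **Forward selection** starts from {mean_diameter, max_deformation}
  and greedily adds, five times, the remaining parameter maximising CV
  accuracy; all candidate evaluations at a step share the same seed and
  hence the same folds, and ties break by registry order. One grid
  search on the full feature set fixes (C, γ) for the whole selection
  run — re-searching per candidate would multiply cost ~100× and lets
  hyperparameters, not features, drive the ranking.

On pure-noise data the greedy argmax over ~19 candidates is biased
above 50% by the max-order statistic (≈ +2–3 CV standard errors); the
chance-calibration checks therefore apply to plain CV accuracies, and
the null forward-selection trajectory is only bounded at small n with a
band matched to its CV standard error.

## Embedding

Standardised phenotype vectors are projected to 2D with t-SNE
(Euclidean distances, PCA initialisation, perplexity 30, 1000
iterations, auto learning rate; all exposed). The embedding is
deterministic under a fixed seed. Recoloring by one registry parameter
per category is pure presentation. A perplexity too large for the row
count raises an error that states the usable maximum.

## Validation studies and problem sizes

The studies that the test suite and `scripts/acceptance.py` run, with
the sizes chosen for a single-CPU desk run:

- **Parameter recovery:** 100 rendered videos (30 frames, 128×128),
  r0 ~ U(8, 25) px, Dmax ~ U(1.2, 3), roughness amplitude
  ε ~ U(0, 0.08) on a fixed probe harmonic k = 12 (fixing the probe
  frequency makes amplitude recovery comparable across cells; a random
  harmonic would confound amplitude with blur attenuation, which rises
  steeply with k/r). Checks: median |relative error| of
  `max_deformation` and `equivalent_diameter`, and Spearman correlation
  between `surface_roughness_5deg` and the ground-truth boundary
  amplitude *in pixels* (ε·r0 — the unit-consistent comparison, since
  the score accumulates pixel deviations and scales with cell size by
  construction).
- **Classification:** baseline-vs-full comparison and chance
  calibration at the protocol scale (grid on 500/class, CV on
  5000/class); the repeated first-selection study (20 independent
  seeded runs, single informative parameter at 4 sd) at 1000
  cells/class so twenty repetitions of the 19-candidate step remain
  affordable.
- **Embedding:** three 8-sd-separated populations, 300 cells each;
  silhouette of the true labels in 2D and bit-determinism under reruns.

## Known limitations

- One cell per sequence; no tracking, collision handling or multi-cell
  frames.
- Segmentation assumes a dark-rimmed cell on a roughly uniform
  background; it is not tuned for phase-contrast or fluorescence data.
- The grayscale edge localiser assumes a rim darker than both interior
  and background; rim-less (uniformly dark) cells fall back to similar
  behavior but were not a design target.
- Extents are bounding-box extents; for strongly rough cells a single
  protruding mode can dominate `D`.
- No viscoelastic model fitting: the kinetics parameters are
  phenomenological summaries of D(t), not moduli.
- Physical calibration (µm per pixel) is carried as a config scalar but
  all internal computation is in pixels.
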