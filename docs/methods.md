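# Methods

`morphoflow` analyzes imaging flow cytometry data without antibodies: every
event (cell) is a small multi-channel image, and cell populations are defined
by intrinsic morphological and fluorescent features rather than by marker
gates.  This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the synthetic
benchmarks do and do not demonstrate.

## Pipeline model

The pipeline treats a sample as a set of per-event image stacks (brightfield
BF, darkfield/side-scatter SSC, a nuclear dye channel DNA, optional
fluorescence channels FL*) and proceeds:

1. **Compensation.** Fluorescence spillover is modeled linearly: the detected
   per-pixel vector is `S^T · true`, with `S` the spillover matrix (rows =
   true channels, diagonal 1).  Compensation solves this system per pixel and
   clamps negatives at 0.  BF and SSC are scatter/transmission channels and
   are not mixed.
2. **Background subtraction.** Per channel, the median of the pixels outside
   the cell mask is subtracted and the result clamped at 0.  BF is special:
   it has a *bright* background with darker cells, so it is converted to
   absorbance (background − value, clamped at 0).  After this step every
   channel has background ≈ 0 and positive in-cell signal, which makes the
   in-mask intensity statistics on BF meaningful.
3. **Segmentation.** The cell mask is the largest connected component of an
   Otsu threshold on the BF gradient magnitude (Sobel), closed with a
   radius-3 disc, hole-filled and eroded by 1 px (the Otsu gradient ring
   straddles the true boundary by about one pixel).  The nucleus is an Otsu
   threshold on DNA inside the cell mask, forced to be a subset of it.
4. **Features.** The panel is an open analog of the feature families used by
   commercial imaging-cytometry software: geometry on the cell and nucleus
   masks (area, perimeter, equivalent-circle diameter, major/minor axis,
   aspect ratio = minor/major, circularity = 4πA/P², shape ratio = solidity),
   the N/C area ratio, five intensity statistics per channel (integrated,
   mean, max pixel, contrast = in-mask RMS about the mean, gradient RMS as a
   focus proxy), and a granularity spectrum G(s), s = 1..3 px, on BF and SSC:
   the fraction of in-mask integrated intensity removed by a grayscale
   opening with a disc of radius s.
   Numerical choices worth knowing:
   - Granularity discs are city-block (diamond) structuring elements.
     Discrete Euclidean discs are not exactly open with respect to smaller
     ones, so openings by them are not guaranteed nested; diamonds of radius
     s form a true granulometry (each is the s-fold dilation of the unit
     diamond), making G(s) monotone non-decreasing in s by construction.
   - Mean, max, contrast and granularity are computed on the 1-px-eroded
     mask: boundary pixels are mixed cell/background, and on features with
     small within-population variance even one contaminated pixel acts as a
     binary outlier flag that can seed spurious clusters.  Integrated
     intensity uses the full mask (a sum is robust because the background is
     ~0 after subtraction, and it must conserve total signal); gradient RMS
     uses the full mask on purpose, since edge sharpness is the focus signal.
5. **Gating.** In order: focused (BF gradient RMS above a threshold,
   defaulting to the Otsu split of the per-sample distribution), nucleated
   (DNA integrated intensity above the KDE valley between the debris band
   and the first mode at least one decade above it; the gate is left open
   with a warning when no debris band exists), singlet (a polygon in
   cell-area vs aspect-ratio space; the default box keeps aspect ratio ≥ 0.8
   and area ≤ 2.5× the median nucleated area).  Additional manual gates are
   arbitrary feature-space polygons in the configuration.
6. **Preprocessing.**
   - *Trimming*: Spearman correlations of all feature pairs over all events
     of a reference sample; of any pair with |ρ| ≥ 0.85 the later-listed
     (panel-order) feature is dropped.  Keeping the earlier feature makes the
     outcome deterministic and predictable from the panel.
   - *Replicate QC*: each sample's vector of per-feature means is Spearman-
     correlated against the element-wise median of the other samples'
     vectors (leave-one-out, robust to a single bad replicate); samples
     below 0.85 are dropped.
   - *Logicle*: fluorescence intensity statistics are transformed with the
     standard biexponential logicle scale.  Parameters are auto-estimated
     per feature: T = observed maximum, M = 4.5 decades, W from the 5th
     percentile of negative values (0.5 when there are none), A = 0.  The
     forward transform inverts the biexponential by bisection to 1e-10.
   - *DNA landmark normalization*: per sample, a Gaussian KDE (Silverman
     bandwidth) of the logicle-scaled DNA intensity provides up to two
     highest-prominence modes — the 2N and 4N DNA-content peaks.  Each
     sample is warped onto the per-landmark medians across samples with a
     monotone piecewise-linear map (identity slope outside the landmarks).
     This is a shift-and-stretch analog of Gaussian-weighted landmark
     normalization: simpler, monotone by construction, and sufficient to
     remove multiplicative per-sample intensity drift.
   - *Scaling*: every surviving feature is divided by its pooled standard
     deviation, equalizing feature contributions to the clustering metric.
7. **Clustering.** Density estimates use the standard kNN estimator
   `density(i) = k / (n · V_d · r_k(i)^d)` (computed in log space; only
   density *ranks* matter downstream, so overflow in `r^d` is harmless).
   Each event points at the highest-density point among itself and its k
   nearest neighbors, with ties broken by event index so the order is strict
   and the pointer graph provably acyclic; basins of attraction of the
   self-pointing modes are the clusters.
   **Weak-mode merging.** The log kNN density of a finite sample fluctuates
   with asymptotic standard deviation ≈ 1/√k, so a single smooth population
   throws off several shallow local modes; without a merge step the
   cluster-count-vs-k curve decays smoothly and has no elbow.  Two clusters
   are therefore merged when the log density of the densest cross-boundary
   neighbor pair (the saddle) lies within `merge_strength/√k` of the weaker
   of the two peak log densities — i.e. when the dip separating them is
   indistinguishable from estimator noise (default strength 4, a 4-sigma
   criterion; 0 disables merging).  Scaling the threshold with the noise
   keeps small-k fragmentation in check while leaving genuine valleys —
   whose depth does not shrink with k — untouched at large k, where a fixed
   threshold would over-merge real populations.
   **k selection.** k is scanned over a grid (default 5..150 step 5, with
   the neighbor search amortized at the largest k) and the elbow of the
   (k, number of clusters) curve is taken: the grid point with maximum
   perpendicular distance from the chord joining the curve's endpoints in
   log-log space.  For a curve made of two line segments this is exactly
   their joint.  The curve is returned so over/under-clustering can be
   checked visually.
8. **Visualization.** A force-directed (Fruchterman-Reingold) layout of the
   union-of-kNN graph (weight 1/(1+distance)), subsampled to a per-cluster
   cap, seeded and with a fixed iteration count; disconnected components are
   laid out independently and placed side by side.  Exported as coordinates
   plus graphML.
9. **Differential abundance.** Counts per cluster and sample are modeled
   NB(μ, φ) with variance μ + φμ² and offset log(sample total), so the test
   concerns relative abundance.  A single common dispersion is estimated by
   maximizing the Cox-Reid-adjusted profile likelihood (−½ log det X'WX per
   cluster×condition fit); the adjustment matters because plain ML with two
   parameters per cluster and ~12 samples biases φ low by ~1/6, which would
   inflate the type-I error of the subsequent tests.  Each cluster then gets
   a likelihood-ratio test (χ², 1 df) of the condition effect in a log-link
   NB GLM — LRT rather than Wald for better behavior at 4–8 replicates —
   followed by Benjamini-Hochberg FDR across clusters.  logFC is reported in
   log2.  The contrast direction is the sorted order of the condition
   labels, so relabeling conditions negates logFC deterministically.
   A one-way ANOVA + BH path on relative abundances handles simple
   multi-group comparisons.
10. **Classifier.** A small dense-block CNN maps 32×32×3 stacks (BF, SSC,
    DNA; center-cropped or zero-padded, extra pixel on the trailing side) to
    class probabilities.  Three dense blocks (each: three 3×3 convolutions
    on the concatenation of the block input and all previous outputs, leaky
    ReLU slope 0.1, then a 3×3 stride-2 transition) take 32×32 to 4×4 with
    87 final feature maps; the 1392-long flattened vector feeds a fully
    connected output layer.  Only the final width (87) and the spatial path
    are architecture constants; the growth rate (default 4) and intermediate
    transition widths (default 8, 16) are configurable and deliberately
    small so training runs on one CPU.  Training: softmax cross-entropy +
    L2 (λ = 1e-4), Adam, batches sampled with replacement, learning rate
    0.001 decaying by 1% every 100 iterations (a constant 0.0006 is also
    accepted via config), stratified 80/10/10 split, test metrics logged
    every 100 iterations with a divergence warning when the test loss rises
    >20% above its minimum while the train loss keeps falling.  Inputs are
    scaled per channel by the 99.5th percentile of the training set.  The
    network, backprop and Adam are implemented directly on numpy arrays
    (im2col convolutions with reused workspaces); training is deterministic
    for a fixed seed on a given platform.
    Per-event inference returns the full probability vector (sums to 1
    within 1e-6), the argmax class, and a reliability report: the fraction
    of events with maximum probability above 0.5, flagged when that
    fraction is low — the signal that the classifier does not transfer to
    the data at hand.  De-novo clusters with overlapping morphology can be
    merged into training classes through an explicit cluster→class map
    before training.

## Synthetic data

The generator produces multi-channel event images with known ground truth so
every downstream stage is testable without instrument data.  It emulates:
distinct populations parameterized by size, N/C ratio, granularity and
log-normal marker intensity; 2N/4N DNA-content bimodality (total nuclear
intensity proportional to ploidy); per-sample multiplicative intensity
drift; linear fluorescence spillover; doublets (two overlapping
same-population cells, 30–50% mask overlap — the high-area, low-aspect
signature the singlet gate keys on); and debris (small fragments without
nuclear signal).  Cells are ellipses with low-order harmonic boundary
irregularity — without it, discrete shape features of smooth rasterized
ellipses take quantized values whose lattice forms artificial density modes.
Granularity scales both the SSC intensity and the log-sd of the
multiplicative speckle, because the granularity spectrum measures a removed
*fraction* and is invariant to pure intensity scaling.  Aspect ratios are
drawn unimodally (half-normal below 1); a flat distribution would also be
split by mode-seeking.

Default study conditions: 64×64 px frames; four hematopoietic-like
populations (small high-N/C cells 35%, medium progenitors 25%, large
agranular 25%, large granular 15%) with FL1 means about a decade apart and
deliberately not ordered by size; the mixture is non-cycling, because a
cycling (4N) compartment of any abundance is a fifth population in its own
right — all 4N cells share the DNA-high signature and legitimately cluster
together — and the benchmark is defined as four populations
(DNA-normalization fixtures use a dedicated 35%-4N population instead); 3%
doublets, 3% debris; background noise σ = 0.3 on fluorescence channels and
σ = 2 on BF; quantization to 16-bit integers available behind a flag and off
by default (the compensation round-trip is exact only on the float path).

What passing on these fixtures does **not** show: robustness to focus drift
and flow artifacts, point-spread-function optics, autofluorescence,
non-linear spillover, segmentation of touching or irregular real cells, or
cluster structure as subtle as real tissue; population separations here are
deliberately clear, so recovery scores are upper bounds on real-data
behavior.

## Benchmark problem sizes

The repository's acceptance checks run at sizes chosen for a single CPU:
population recovery uses 4 samples × 4,000 events (≈15k retained events, 17
post-trim features; ARI vs ground truth ≈ 0.99, elbow at exactly 4
clusters); NB calibration uses 20 clusters, 6 vs 6 samples × 10,000 events,
2,000 null replicates (type-I ≈ 0.05 at α = 0.05) and 500 planted-logFC=2
replicates; the classifier benchmark trains 2,000 iterations at batch 64 on
2,000 images of the four default populations (held-out accuracy ≈ 1.0).
The full-protocol settings (25,000 iterations, batch 256) remain the
configuration defaults.

## Known limitations

- The NB model uses one common dispersion; no per-cluster (tagwise) or
  trended dispersion, no quasi-likelihood F-tests.
- The logicle parameter estimate assumes a non-degenerate positive signal;
  all-non-positive features are rejected rather than offset automatically.
- DNA landmark alignment assumes up to two modes; aneuploid or >2-peak
  distributions are aligned on the modes found, with a warning.
- Force-directed layouts are seeded and reproducible but not isometric;
  between-cluster distances in the layout are not quantitative.
- Classifier determinism holds within one platform/BLAS; bit-identical
  training across different BLAS builds is not guaranteed.
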