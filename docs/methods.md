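# Methods

## Scope and data model

`ionvox` analyses multichannel 3D ion-count volumes of the kind produced by
secondary-ion mass spectrometry (SIMS/NanoSIMS) imaging of single cells:
one stack of 2D count images per detected isotope (e.g. 12C, 19F, 31P,
81Br, 127I, 194Pt, 197Au), acquired plane by plane as the primary beam
erodes the sample. Counts are nonnegative integers; the axis convention is
(z, y, x) with 0-based indices, and all window and radius parameters are
given in pixels of the original acquisition frame.

## Denoising

Low-current acquisitions produce sparse counts in which signal is
distinguished from noise by local *density*, not intensity. The filter sums
a channel over a block of planes, computes for every positive pixel
(summed count > 0, exactly) the mean Euclidean distance to its k = 25
nearest positive pixels, and keeps pixels with mean distance at or below a
cutoff. The cutoff is a per-channel parameter; when not set it defaults to
the Otsu threshold of the mean-distance histogram, which sits in the valley
between the dense (signal) and sparse (noise) modes. The resulting 2D mask
is applied to every plane. The filter is translation- and
rotation-equivariant and idempotent.

## Voxel features and normalisation

A "voxel" is a 3D sliding window summarised by the per-channel mean count.
Only fully contained windows are emitted — a truncated window would bias
the mean — and window centers are reported in original-frame pixels so
that downstream distances are true pixel distances. The number of windows
per axis is floor((L − w) / s) + 1.

Three normalisations are provided, matching the three analysis recipes:

* **z-score** per channel over the pooled sampled voxels (population sd;
  a constant channel yields zeros plus a logged warning rather than an
  error, so degenerate synthetic inputs cannot kill a run);
* **log2(x + 1e-4)**, the small pseudocount avoiding log of empty voxels;
* **per-FOV 20–95 percentile normalisation** (channel mean scaled to 1,
  then the 20th→0 and 95th→1 percentile span mapped linearly, clipped to
  [0, 1]); percentiles use linear interpolation between order statistics.
  Because the percentile map is invariant to positive scaling, the initial
  mean-scaling cannot change the result; it is kept for fidelity to the
  published procedure and a test asserts the equivalence. The drug channel
  is instead clipped globally to a fixed [0.01, 0.05] mean-count window
  before rescaling, since per-FOV scaling would inflate untreated fields.

The multi-FOV recipe also removes the bottom 20% of voxels per FOV by
carbon (12C) counts — voxels over bare substrate — with stable-sort tie
handling so exactly floor(0.2 n) rows are dropped deterministically.
"Middle 40 planes" is implemented as a centered slab with the extra plane
on the leading side when the remainder is odd.

## Neighborhood identification

Voxels are grouped by agglomerative clustering (Ward linkage, Euclidean
distance — the linkage is a configurable choice; Ward is the default for
compact feature clusters and is deterministic for a fixed row order).
Two routes mirror the published pipelines: clustering directly on
normalised features, or clustering on a 2D Barnes-Hut t-SNE embedding
(perplexity 30, 1000 iterations, PCA initialisation, fixed seed) into 40
fine clusters. Fine clusters are merged into the final neighborhoods
either by an explicit user-supplied merge map (the reproducible version of
manual annotation) or automatically by Ward-clustering the fine-cluster
mean profiles into the requested final count. Correlation distance was
rejected for the automatic merge because it is unstable for near-constant
profiles (a background cluster low in every channel); Euclidean distance
on the normalised profiles handles that case cleanly.

## Interaction testing

Two voxels interact when their center distance is ≤ r (default 5 px,
isotropic Euclidean in 3D). For K neighborhoods the observed K×K matrix of
unordered interacting pairs (diagonal = same-label pairs, each pair counted
once) is compared to a label-shuffle null: the interacting-pair set depends
only on geometry, so it is built once with a k-d tree and each of the
n_perm = 1000 permutations merely recounts labels. One-sided p-values use
the add-one rule p = (#{permuted counts beyond observed} + 1) / (n_perm+1)
with strict inequalities — ties count toward neither tail, which makes the
test slightly conservative for sparse counts — and the attainable floor is
1/(n_perm + 1). Enrichment is log2(observed / mean permuted count),
reported as NaN when either side is zero rather than silently
pseudocounted. Counting each pair twice would cancel in the ratio (a test
asserts this). Permutations are performed within one FOV/cell, never
across FOVs. The permutation stream is `numpy.random.default_rng(seed)`
drawing one `permutation(n)` per iteration; a naive all-pairs reference
implementation consumes the identical stream and must agree bit for bit.

## Drug quantification

Per-neighborhood drug levels are summarised as count distributions or,
after clip normalisation, as the fraction of drug-positive voxels per
(FOV, neighborhood); the default positivity rule is normalised value > 0,
i.e. raw mean count above the lower clip limit. Conditions are compared
per neighborhood with a two-sided Wilcoxon rank-sum test on per-FOV
fractions, with FOVs (not cells) as the test unit. For combined n ≤ 12 the
null distribution of the midrank sum is enumerated exactly over all group
assignments and the smaller tail doubled (capped at 1); larger samples use
the normal approximation with tie correction.

## Splicing analysis

Each gene's exon counts out of (exon + intron) totals are modelled with a
binomial GLM with condition as the sole covariate, fit independently per
gene; genes are selected at Benjamini–Hochberg adjusted p < 0.05. Genes
with degenerate counts (zero totals, complete separation) are flagged with
p = NaN rather than crashing the run. The immature-enrichment score is

    IE = log2( Σ_treatment exon/intron  /  Σ_control exon/intron )

with the sums over per-replicate ratios as printed (the alternative — sum
counts before taking the ratio — differs under unequal depths; the
per-replicate form is depth-invariant per replicate and is what is
implemented). A zero intron count in any replicate leaves IE undefined
(NaN plus a flag); a pseudocount option exists but defaults off. IE is
antisymmetric under swapping condition labels and invariant to rescaling
any single replicate's depth.

## Synthetic data

The phantom generator renders parametric subcellular structures —
cytoplasm, a nuclear (euchromatin) region, heterochromatin blobs,
nucleoli, speckles, optionally lamina and bare substrate — onto a voxel
grid, resolves overlaps with a fixed precedence (speckle > nucleolus >
perinucleolar rim > heterochromatin > lamina > euchromatin > cytoplasm >
background), and draws independent Poisson counts per channel with
per-(structure, channel) mean intensities. Defaults mimic summed
acquisitions: carbon high wherever there is organic material, phosphorus
tracking chromatin density, each antibody channel dominated by its target.
Drug partitioning is a per-structure multiplier on a base intensity
(speckle-enriched 3×, heterochromatin-depleted 0.3×); the multipliers are
free parameters of the phantom, not calibrated measurements. Because an
acquired slab of a few hundred nanometres is thinner than any of these
organelles, structure geometries are cylindrical in z by default (the
organelle spans the slab). Structure radii are large relative to a 10 px
analysis window, as they are in real rasters at 10–20 nm/px pitch. In the
two-condition drug phantom the drug channel is sparse (0.02 counts/px
base), putting per-voxel means in the 0.01–0.05 range the global clip
normalisation expects. What the phantom does **not** model: detector dead
time, topography and matrix effects, beam drift, charging, and any
correlation between channels beyond shared geometry — so passing tests
demonstrate correctness of the analysis logic, not robustness to those
instrumental artefacts.

The splicing generator draws each replicate's total fragment count from a
negative binomial (variance μ + αμ²; Poisson at α = 0) and splits it
binomially between exon and intron by the gene's exon/intron ratio
(log2 ratios ~ Normal(2, 1)); affected genes have their treatment ratio
multiplied by a known fold. The hierarchical form keeps the conditional
exon|total distribution exactly binomial — the model the per-gene GLM
assumes — so false-discovery control is testable; an optional
`ratio_dispersion` adds extra-binomial ratio noise for robustness studies.
Totals are floored at 1 fragment so every replicate is informative.

The edge generator produces `amplitude · Φ((x − x0)/σ)` plus optional
Gaussian noise — the exact profile of an ideal edge imaged with a Gaussian
PSF — for which the 84–16% criterion returns 2σ.

## Metrology

The 84–16% lateral resolution estimator normalises a line scan to plateau
levels estimated as the medians of the outer 20% of samples on each side,
then finds the 16% and 84% crossings by linear interpolation between
samples; it is invariant to affine intensity transforms and scan-direction
reversal, and refuses profiles whose plateau difference is within 3
standard deviations of the plateau noise. A linear ramp of length L yields
0.68 L. The ion-yield/resolution tradeoff is an ordinary least-squares fit
with R²; the axial sputter rate is thickness divided by the number of
planes needed to erode it, with a helper that finds the erosion
breakthrough as the half-asymptote crossing of a substrate/organic signal
ratio (asymptote = median of the last 10% of planes). Barcode capacity
counts unordered label subsets by exhaustive enumeration, cross-checked
against the binomial coefficient.

## Problem sizes used in validation

The test suite and the acceptance script regenerate everything from
scratch at sizes chosen to keep the full run in the minutes range while
leaving clear statistical margins: a 20×560×560 single-cell phantom with
4000 sampled voxels for neighborhood recovery (adjusted Rand index
comfortably above 0.8 across seeds); ten 12×120×120 FOVs with 800 voxels
each for the two-condition drug comparison; 200 replicates of 400 random
voxels for permutation-test calibration; 300 genes at mean depth 500 (3+3
replicates) for splicing recovery and 100 null replicates of 100 genes for
FDR control. Larger runs only tighten the same comparisons.

## Known limitations

* The automatic profile-based merge is a stand-in for expert annotation;
  on real data the explicit merge-map route is preferred.
* The nucleus mask (Otsu + closing + hole fill on the summed phosphorus
  image) assumes a single dominant intensity mode per class; dim or
  touching nuclei need per-dataset tuning of the exposed parameters.
* Interaction distances treat z pixels as isotropic with x/y, as the
  published 5-pixel radius does; strongly anisotropic acquisitions would
  need a rescaled radius.
* The Wilcoxon comparison treats FOVs as exchangeable units; with 1–2
  cells per FOV this conflates cell- and field-level variation.
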