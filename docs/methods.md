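# Methods

This note documents the models, parameters and design choices behind
`lucmap`, stage by stage, including the points where the underlying
method's published description is ambiguous and this implementation had
to commit to a reading.

## Data model

A sample is one labelled pixel-year: four band series (NDVI, EVI, NIR,
MIR) of 23 sixteen-day composites over an agricultural year running
Sep 1 – Aug 31; a map year is labelled by its harvest calendar year.
Values are stored on the physical scale (MOD13Q1 integers ÷ 10⁴), so
NDVI and EVI lie in [−1, 1] and the reflectance bands in [0, 1]. The
feature vector is the fixed band-major concatenation
NDVI₁..₂₃, EVI₁..₂₃, NIR₁..₂₃, MIR₁..₂₃ (92 values). The class
vocabulary has nine training classes (codes 1–9, in lexicographic
order) and four auxiliary classes (water, urban, sugarcane, secondary
vegetation; codes 10–13); code 0 is no-data. Rasters are plain pixel
arrays written as TIFF with a CSV code-table sidecar; no map-projection
metadata is attached or interpreted.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not any fitted spectra. Mean curves are sums of at most two Gaussian
bumps plus a baseline per band: forest NDVI is high (≥ 0.83) and nearly
flat; cerrado has a mild, phase-lagged seasonal swing (woody savanna);
pasture greens sharply with the first rains and browns in the dry
season; single-crop classes have one wet-season peak; double-crop
classes have a soybean peak followed by a second-cycle peak whose
timing, width and amplitude distinguish millet, corn, sunflower and
cotton (in harvest order), with the soybean planting window also
shifting slightly between systems. EVI and NIR are derived from NDVI
(lower amplitude, biomass-driven); MIR is specified independently
because it responds to soil exposure and canopy water, and runs
anti-phase to NDVI for every class. The curve shapes were chosen once
so that the closest class pairs sit at squared distances of roughly
0.7–1 in the 92-dimensional space — comparable to real MODIS
phenological contrasts — and were not revisited afterwards.

Noise is i.i.d. Gaussian per observation, sd 0.05 for NDVI/EVI and 0.03
for NIR/MIR, clipped to the valid ranges. Label noise is injected by
*relabelling*: a mislabelled sample keeps its true-class series and
carries a label drawn uniformly from the other eight classes — exactly
the error model the SOM quality control is designed to catch. Scenes
are rectangular patches (with per-year labels) on a background class;
mask rectangles must be disjoint; reference layers are derived from the
first-year truth (Forest/Non-Forest/Deforestation inside the declared
Amazon rectangle, Anthropized/Non-Anthropized on its complement). All
draws flow from one seeded generator, so every artifact is
bit-reproducible.

What the generator does *not* emulate: mixed pixels, spatially
correlated noise, clouds or compositing artifacts, class proportions of
any real landscape, or within-class phenological diversity (each class
has a single mean curve). Passing tests on this data therefore show
that the pipeline's machinery is correct and self-consistent, not that
the accuracy figures transfer to real imagery.

## SOM quality control

Online Kohonen training: weights are initialised uniformly within the
per-feature data range; per presented sample the best-matching unit
(smallest Euclidean distance in the raw 92-dim space) and its lattice
neighbours move toward the sample. The learning rate decays linearly
0.05 → 0.01 and the neighbourhood radius from max(xdim, ydim)/2 to 1
over the whole schedule (default 100 epochs). The lattice kernel is
Gaussian with the radius as its 3σ support: by the end of training
essentially only the BMU moves, so neurons decouple into distinct
prototypes (with a fixed 1σ reading, a 2×1 grid never separates two
well-separated clusters — the neighbour keeps 61% of the update
weight). Grid side defaults to ⌈√(5·√n)⌉ (Kohonen's heuristic).

Neurons are labelled by majority vote of the samples they attract; ties
break toward the globally more frequent class, then lexicographically.
Reliability is estimated over repeated runs (default 20; run r uses
seed + r): a sample's frequency for class c is the fraction of runs in
which its BMU was labelled c. Whether the original procedure counted
neuron-level or cluster-of-neurons-level labels is ambiguous; BMU-label
frequency is used here. Samples are retained iff their own-label
frequency is ≥ the threshold (default 0.80, inclusive).

## SVM classification

RBF SVM with the published cost C = 1 and γ = 1/92. γ equal to the
reciprocal of the feature dimension is the libsvm/e1071 default, and
e1071-style fitting standardises features by default — so the scaler is
treated as part of the model: each feature is standardised to zero mean
and unit variance on the training set (per fold during
cross-validation), and γ = 1/92 applies to the standardised space. On
the raw [−1, 1] scale the same γ leaves the kernel nearly constant
(γ·d² ≈ 0.01 between the closest classes) and the classifier sits on a
knife edge where slight class imbalance or a few percent of label noise
collapses whole class pairs; with standardisation it is robust to both.
Multiclass decomposition is one-vs-one (the conventional SVM default);
probabilities come from Platt scaling with pairwise coupling, seeded.
Cross-validation is stratified k-fold (default 5), falling back to a
plain shuffled split with a warning when a class has fewer members than
folds. Raster cubes are classified by building each pixel's feature
vector exactly as for samples; the label map is the probability argmax
with ties resolved to the lowest class code.

## Bayesian smoothing

The published description gives the qualitative behaviour but no
posterior formula. This implementation works on logits: probabilities
are clamped to [ε, 1−ε] (ε = 10⁻⁶) and mapped to log-odds, and per
class the posterior logit is (s²·x + σ²·m)/(s² + σ²), where m and s²
are the mean and n−1 sample variance of the neighbours' logits over the
Chebyshev-radius window (default 1, i.e. 3×3) excluding the centre,
truncated at raster edges (s² = 0 when a pixel has fewer than two
neighbours; the original logit is kept when it has none, or when both
s² and σ² are zero). This Gaussian conjugate form reproduces every
defining property: σ² = 0 is the identity; increasing σ² pulls the
posterior monotonically toward the neighbourhood mean; a noisy
neighbourhood (large s²) protects the original value; unanimous
neighbours (s² = 0, σ² > 0) pull the pixel fully to their mean.
Smoothed probabilities are renormalised inverse logits; labels are the
posterior argmax. σ² = 10 is the published default. Smoothing runs on
the probability cube before masks and rules.

## Consistency rules

Base-map fusion evaluates five per-pixel rules against the reference
layers in fixed order, first match wins (the Amazon-Forest rule must
override the rest). The trajectory rules operate on the letter alphabet
F, C, P, S, where S aggregates exactly the five soy-\* classes;
fallow-cotton contains no soybean cycle and is opaque to the rules, as
are auxiliary classes, secondary vegetation and no-data.

The ten rules are applied with **position-major scanning**: windows
slide left to right over the trajectory, and at each starting position
the rules are tried in numbered order, the first match rewriting its
starred positions in place before the scan advances. Per-position rule
priority, rather than one whole-trajectory pass per rule, is essential:
rule 1 (C→F\* ⟹ C→C\*) applied as a full pass would consume the C,F
subsequence inside the cerrado-blip patterns that rules 5–7 repair
(F,C,F,F would end as F,C,C,C instead of F,F,F,F). Position-major
scanning reproduces all ten published rewrites exactly and still fires
anywhere in a long trajectory. A second full application is a no-op on
all ten worked examples. Whether the original rules were anchored to
the 2001 base year or slid over the sequence is ambiguous; sliding was
chosen because anchoring would leave mid-series clearings uncorrected.
Rule application is single-pass (no fixed-point iteration). Pixels
under the water/urban/sugarcane masks are frozen — they neither match
nor are rewritten — and are finally overwritten with their auxiliary
code (precedence water > urban > sugarcane) on every year.

## Validation

Confusion matrices use rows = predicted, columns = reference. Overall
accuracy is trace/total; user's accuracy is the diagonal over the row
sum, producer's over the column sum; undefined ratios are reported as
NaN, never 0. No-data and auxiliary-class pixels (including secondary
vegetation, which has no counterpart in the truth vocabulary) are
excluded from map comparisons. Area series multiply class pixel counts
by a pixel area (default 6.25 ha, the 250 m cell). Percentages are
reported to one decimal.

## Pipeline and problem sizes

The orchestrated run is qc → train/cv → per-year classify → smooth →
rules → validate, with a single master seed fanning out to per-stage
seeds (master·1000 + stage offset, mod 2³¹) so stages can be re-run in
isolation. Default study conditions for the synthetic end-to-end run:
9 classes × 100 samples with 10% injected mislabels, 20 SOM runs of 100
epochs for quality control, and a 30×30-pixel, four-year scene whose
patches include a forest→pasture→forest regrowth trajectory; these
sizes keep a full run to a few minutes on one CPU while exercising
every stage, and are the conditions at which the recovery floors
(≥ 80% of mislabels removed, ≥ 95% of clean samples retained, ≥ 0.9
cross-validated accuracy, ≥ 95% final-map agreement) are asserted.

## Known limitations

- Rasters carry no geographic metadata; alignment is by array shape.
- The logit-space conjugate posterior is one reading of "Bayesian
  neighbourhood smoothing"; smoothing raw probabilities instead would
  satisfy the σ² = 0 identity but not the variance-weighting behaviour
  as cleanly.
- The synthetic generator's single mean curve per class makes classes
  more homogeneous than real landscapes; reported synthetic accuracies
  are upper bounds on realism, by construction.
- Reliability estimation re-trains the SOM from scratch per run, which
  dominates pipeline runtime at production settings.
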