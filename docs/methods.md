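# Methods

This note documents the models and procedures implemented in `cdtl`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Slice selection by co-occurrence entropy

A volume's axial slices are scored by the entropy of their gray-level
co-occurrence matrix (GLCM). Each slice is first quantized per slice by
uniform min–max binning into `levels` gray levels (a constant slice maps
entirely to bin 0 and scores entropy 0 — never an error). The GLCM at
offset (distance *D*, direction *θ*) counts co-occurrences of quantized
levels at pixel pairs; with `symmetric=true` both orderings are counted;
the count matrix is normalized to sum 1. For the `"mean4"` direction the
four per-angle *normalized* matrices are averaged entrywise. Entropy is
`−Σ p log p` with `0·log 0 := 0`, in nats (`log_base="e"`, default) or
bits.

Conventions that the literature leaves open and that are fixed here:

- **GLCM parameters**: `D=1`, `θ=0°`, `levels=64`, symmetric, natural
  log. These are standard texture-analysis defaults; 64 levels keeps the
  matrices small and desk-scale runtime low. All are configurable, and
  `"mean4"` is available when directional isotropy matters.
- **Angle convention**: angles run counter-clockwise with the image row
  axis pointing down, so `45°` is the offset (−D, +D). This is the
  classical convention; scikit-image's diagonal angles mirror it
  (its 135° equals this package's 45° under symmetric counting), and on
  diagonals scikit-image rounds the Euclidean displacement while this
  package steps `D` pixels along the direction.
- **Ranking** is within-subject, descending entropy, ties broken by
  ascending slice index for determinism.
- **Entropy is computed on quantized intensities**, not raw floats, so
  ranking is invariant to affine intensity rescaling of a slice and to
  any relabeling of gray levels.

Two selection rules cover the two stages: `top_entropy(n=20)` per
subject for the base task, and `middle(n=30)` — a contiguous window
starting at `floor((N−n)/2)` — for the target task, where central slices
carry hippocampus, cortex, and ventricles.

## Class decomposition

Features are reduced by PCA (fitted on training rows only; fractional
`n_components`, default 0.95 explained variance, selects the smallest
sufficient count) and standardized *after* reduction. Each parent class
is clustered by k-means (`k=2` per class by default; seeded, 10
restarts, tolerance 1e-6, ≤300 iterations) within its own samples.
Subclass labels use the invertible syntax `"<parent>#<index>"`; cluster
indices are renumbered by ascending centroid norm so the labeling does
not depend on k-means' internal ordering. Classes with fewer samples
than `k` fall back to `k=1` with a warning (or raise, when fallback is
disabled).

Reassembly of subclass predictions supports two modes and defaults to
`argmax_map` (the parent of the highest-scoring subclass — the simplest
faithful reading of "reassemble"); `prob_sum` sums subclass
probabilities into parent scores. The two can disagree (e.g. subclass
scores 0.35/0.05/0.30/0.30 give parent A under `argmax_map` and parent B
at 0.60 under `prob_sum`); both are exposed so the choice is auditable.

Silhouette diagnostics are computed per parent class over its own
samples, in the reduced/standardized space — the space the clustering
actually saw. A parent with fewer than two nonempty subclasses is
reported as undefined rather than 0.

## Backbones and the transfer protocol

The decomposition and transfer mechanisms are backbone-agnostic, so the
backbone is a contract (`BackboneSpec`): a trainable classifier exposing
`predict_scores` (rows sum to 1), a penultimate-representation
`transform`, body/head parameter digests (SHA-256 over parameter bytes),
and `replace_head`. Two desk-scale reference implementations ship:

- `reference_cnn`: one 3×3 convolution (8 maps), ReLU, 4×4 average
  pooling, a 32-unit hidden dense layer (ReLU), and a softmax head,
  written in numpy and trained with Adam on cross-entropy. Fully
  deterministic given the seed. Body = conv + hidden layer; head = final
  dense layer. `n_trainable_tail_layers` freezes the body bottom-up
  (0 = head only, 1 = hidden too, ≥2 = everything).
- `deterministic_texture`: pooled local texture statistics (per-cell
  mean, SD, and mean absolute horizontal/vertical differences on a 4×4
  grid → 64 features) with a logistic-regression head. No trainable body
  parameters, so feature extraction is identical across calls — this
  backbone makes end-to-end runs bit-reproducible.

Training defaults mirror the published protocol (200 epochs, batch 50,
Adam, learning rate 1e-4); tests and the acceptance script use reduced
epochs (2–40) and a higher rate (1–2e-3) scaled to the small synthetic
problems. The "top 13 layers adopted" / "top two layers adjusted"
notions of large pretrained architectures map onto the single
`n_trainable_tail_layers` knob; exact layer indexing into AlexNet/VGG19
is out of scope, as is ImageNet pretraining.

**Transfer** (`freeze_and_replace_head` → head-only `fit`): the body
digest is recorded before the head is replaced with a fresh layer of the
new width, and verified unchanged after retraining — a digest mismatch
raises an internal-consistency error. The base stage decomposes its two
classes into four subclasses; the target stage is trained directly as a
binary head by default (a config flag can decompose the target too).

## Evaluation

- Subject-grouped, label-stratified folds: within each class, subjects
  are shuffled (seeded) and dealt round-robin, so every subject is held
  out exactly once and per-class fold sizes differ by ≤1. This exact
  construction is used instead of a generic grouped-stratified splitter
  to guarantee the balance property.
- Leakage audit: every fitted component records the subject set it was
  trained on; cross-validation verifies each is a subset of the fold's
  training subjects.
- Slice→subject aggregation (the slice-to-subject decision rule is not
  standardized in the literature): default `slice_majority` — modal
  slice prediction, ties broken by higher mean score — with
  `mean_score` (average score vector, then arg-max) as the alternative.
  Both slice-level and subject-level reports are emitted.
- Metrics are the standard confusion-matrix identities; any zero
  denominator yields an undefined marker (`None`/JSON `null`), never a
  silent 0 or 1. This matters for small single-class strata, where
  accuracy can be 1.0 while sensitivity and F1 are meaningless.
- AUC uses the rank (Mann–Whitney) formulation with ties counted 0.5;
  the CI is a seeded stratified percentile bootstrap (default 1000
  resamples, α=0.05), chosen because it is distribution-free and
  reproducible.
- Oversampling equalizes *subject* counts per class by duplicating
  whole subjects (all their slices, under suffixed ids), optionally
  within each stratum independently; originals are always retained, and
  a single-class stratum is left unchanged with a warning. The pipeline
  applies it to training folds only.

## Synthetic data: what it emulates, and what it does not

`make_phantom` builds volumes whose central axial band (fraction 1/3 of
the depth, centered) holds white-noise-plus-midscale texture of
amplitude `texture_scale=1`, while outer slices hold heavily smoothed
noise of amplitude `background_noise=0.1`. Because quantization is
per-slice min–max, amplitude alone cannot separate the bands; the
correlation structure does — neighboring pixels of smoothed noise
co-occur near the diagonal of the GLCM (low entropy), white noise fills
it (high entropy). The entropy ranking must therefore recover the band
for the right reason, and the test can fail if the ranking is wrong.

`make_classification_task` plants a two-axis latent geometry rendered
through fixed smooth quadrant-localized templates: axis 0 separates the
classes (mean gap `12·exp(−class_overlap)` within-cluster SDs), axis 1
separates two subclusters per class (gap `subcluster_separation`,
default 8 SDs). Confining each template to its own image quadrant keeps
the pooled texture features block-linear in the latent coordinates, so
the planted geometry survives feature extraction, PCA, and
standardization without the axes mixing. Subjects draw a latent vector
(unit SD); their slices add small latent jitter (SD 0.3) plus pixel
noise (SD 0.02), giving the within-subject correlation that makes
subject-grouped CV necessary. The `checkerboard` layout alternates the
class-axis sign with the subcluster (an XOR corner arrangement) to model
irregular class boundaries where decomposition is essential information.
`make_transfer_pair` draws base and target tasks from the same template
family with the target's class means contracted by `target_shift`
(default 0.5) — harder, but sharing feature structure, so transfer is
beneficial by construction.

Passing tests on these generators show that each mechanism does what it
claims under the statistical structure it assumes — they do not show
clinical performance. The generators contain no anatomy, no scanner
physics, no atrophy patterns, and no site effects; real MCI-conversion
data is harder in ways these fixtures do not model.

## Problem sizes

Tests and the acceptance script run at desk scale: 48×48×90 phantoms,
32×32 images, 20 subjects per class with 4–10 slices each, 3–10 folds,
2–40 epochs. The acceptance script averages the stochastic directional
properties (transfer gain, decomposition gain) over 5 generator seeds
and scores them at slice level on a 50% holdout to reduce estimator
variance; both remain small-sample estimates and their values vary by a
few percentage points across seeds.

## Known limitations

- The reference CNN is intentionally small; it demonstrates the
  protocol, not state-of-the-art image classification.
- PCA + k-means decomposition assumes subcluster structure is visible in
  the extractor's feature space after standardization; subclusters
  encoded in directions PCA discards will not be found.
- The silhouette diagnostic is computed in the reduced space and is not
  comparable across different reduction settings.
- JPEG export is supported for parity with legacy datasets but is lossy;
  PNG is the default and the round-trip-exact path.
- `class_overlap` and `target_shift` control task difficulty through a
  single latent gap; real task pairs differ in richer ways.
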