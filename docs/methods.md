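# Methods

## Representation learner

The encoder maps an RGB field-of-view image to a feature vector f(x); a
two-layer MLP projector g maps features to the latent z = g(f(x)), which is
L2-normalized so that temperature-scaled dot products are cosine
similarities. z is used both in the contrastive losses and as the downstream
feature vector.

A minibatch samples N anchor images; each anchor is paired with one
uniformly sampled replicate of the same compound (excluding the anchor
itself when the compound has ≥ 2 images; single-image compounds self-pair).
Replicates take the role augmentations play in standard contrastive
pipelines, so the learned invariances are exactly the nuisances that
separate replicate acquisitions — plate, well, batch. Positives are sampled
independently per anchor, so an image may appear more than once in a batch;
the losses are well-defined under duplication.

Both losses average over the 2N anchors of the multiviewed batch. The
denominator set A(i) contains all 2N−1 other entries, including the
anchor's replicate. The supervised positive set P(i) is every same-label
entry plus the replicate (labels come from each compound's *first*
annotation only). The sum-over-positives sits **outside** the logarithm (the
"L_out" form); an inside-the-log variant exists in the literature and is
not what is implemented here. Log-sum-exp is computed with max-subtraction;
latent rows are contract-checked to unit norm (tolerance 1e-3) and NaN-free.

Training alternates phases at **epoch granularity**: phase A steps the
InfoNCE loss over batches covering the full image set, then phase B steps
`supervised_weight ×` the supervised loss over batches drawn from annotated
images. With no annotations phase B is skipped and the run is bit-identical
to pure self-supervised training at the same seed. Batch-level interleaving
would be an equally defensible reading; epoch-level is fixed here and
logged. The optimizer is RMSProp (momentum-free, adaptive) at learning rate
10^-2.5, no scheduler, no augmentations.

### Hyperparameters

| parameter | default | meaning |
|---|---|---|
| temperature τ | 0.07 | sharpness of the contrastive softmax |
| learning_rate | 10^-2.5 ≈ 0.0032 | RMSProp step size |
| projector_dim | 224 | width of z |
| batch_size N | 40 | anchor pairs per multiview batch |
| max_epochs | 250 | upper bound on training epochs |
| supervised_weight | 1.0 | scale of phase-B gradients |
| backbone | small_cnn | 2×(conv3×3+ReLU+avgpool) → dense feature head |

The encoder is a compact CNN (8 and 16 channels, two 2× poolings, dense
feature layer, default width 128) written in numpy with explicit backprop;
it trains on 48×48 RGB images in seconds per epoch on one CPU. Benchmarks
use projector_dim 64 and feature_dim 128.

## Downstream classification

Latents are extracted in evaluation mode (deterministic). Classifiers:

* **Random forest** — 500 trees, √-features, seeded. Single-label mode fits
  one multiclass forest on primary labels; multilabel mode fits
  binary-relevance one-vs-rest forests over the class vocabulary; classes
  with no training positives are dropped with a warning.
* **MLP head** — dense 512 → 256 → C, ReLU, 50% dropout on the first two
  layers, softmax cross-entropy (single-label) or per-class sigmoid BCE
  (multilabel), RMSProp at 10^-2.5, early stopping on a 10% held-out slice
  of the training images with patience 10, best weights restored.

Multilabel label sets are thresholded at score ≥ 0.5 (configurable; this
choice strongly affects exact-match accuracy and is a convention, not a
claim about any reference pipeline).

Cross-validation operates on **treatments**: annotated compounds are
partitioned into folds (stratified by primary label where a class has at
least `fold_count` compounds, round-robin into the emptiest folds
otherwise), and every image inherits its compound's fold. Train/test
compound disjointness is asserted on every fold. Metrics are computed per
image; compound-level aggregation happens only in the replicate-vote report.

## Metrics

* **Exact-match accuracy**: fraction of images whose predicted label *set*
  equals the ground-truth set.
* **Macro PR AUC**: per-class average precision (step integration, not
  trapezoidal — the two conventions differ) averaged over classes with ≥ 1
  positive; empty classes are excluded and logged.
* **Class deconvolution**: per class and fold, precision = TP/(TP+FP),
  recall = TP/(TP+FN), F1 = 2PR/(P+R), with 0/0 defined as 0. Metrics are
  computed **per fold and then averaged** over the folds in which the class
  appears (pooling counts first is available behind a flag). Note the
  fold-mean of F1 is not the harmonic mean of fold-mean precision and
  recall. Classes with fold-mean precision ≥ 10% are flagged as reliable.

## Ranking by batchwise contrastive loss

Each image is scored by its per-anchor InfoNCE term inside seeded batches of
`batch_size` anchors; a compound's score aggregates its replicates' scores
(`min` — the most self-consistent replicate — by default, `mean` exposed).
Because the score depends on which negatives share a batch, the scoring can
be repeated over `n_rounds` fresh seeded batchings with per-image averaging
(default 1 round). Controls and annotated compounds are excluded from the
ranking; the top-n lowest-loss compounds are reported with the top-k classes
by replicate vote (ties broken lexically).

## Synthetic screens

The generator emulates the *structure* of a Cell Painting screen, not its
photometry: K latent phenotype classes, each a signed direction over
per-channel generative parameters (baseline, blob rate/radius/amplitude,
texture frequency/amplitude); compounds = class direction × signal_strength
+ stable compound jitter (sd 0.3 in class-scale units); images = sinusoidal
texture + Poisson-placed Gaussian blobs, clipped to [0,1]. Replicates spread
over ≥ 2 synthetic plates with per-plate×channel gain/offset
(`batch_effect`). Controls draw from the class-free background process.
`annotation_fraction` of compounds get their true class as first label;
`multilabel_fraction` of those get one correlated extra label.

`replicate_noise` models **phenotype consistency across replicate wells**.
A failed replicate in a real screen does not produce an arbitrary image — it
reverts toward the vehicle phenotype or toward another response present in
the assay. Each replicate's parameters are therefore mixed by fraction
α = min(3·replicate_noise, 1) toward a freshly drawn confounder phenotype
(random class or control, with its own jitter), plus pixel noise and
blob-position jitter. With replicate_noise = 0, replicates are bit-identical
up to batch effects. Two consequences matter for interpretation: noisy
replicates stay *on the phenotype manifold* (so they remain surrounded by
negatives and their InfoNCE loss rises), and an encoder cannot become
invariant to this inconsistency the way it can to plain pixel noise.

What the generator does **not** model: real cell morphology, illumination
gradients, plate-layout artifacts, dose response, class imbalance of real
annotation systems. Passing benchmarks show the workflow recovers planted
structure under controlled conditions; they are not evidence about any real
screen.

## Benchmarks (problem sizes chosen for minutes-scale CPU runs)

* **Method comparison** — 10 classes, 80 compounds × 4 replicates, 5-channel
  48×48 images → RGB, 50% annotated, small CNN, 15 epochs, shared 5-fold
  treatment-level split; semisupervised vs self-supervised-only embeddings
  under an identical downstream single-label RF, plus the majority-class
  baseline.
* **Ranking** — 5 classes, 60 compounds × 6 replicates, 50% annotated,
  replicate-noise levels cycling over mixing fractions {0, 0.2, 0.4, 0.6,
  0.8}; encoder trained 2 epochs self-supervised; scoring in batches of 90
  anchors averaged over 32 seeded rounds, compound aggregate `mean`;
  reported: Spearman between compound score and noise level over unannotated
  compounds, and whether a zero-noise compound reaches the top-10.

The short training of the ranking encoder is deliberate. Replicate-invariance
training progressively collapses exactly the replicate-consistency
differences the batchwise loss ranks on; at a few hundred images the encoder
can memorize every image within ~10 epochs, a regime a full-scale run over
hundreds of thousands of images never enters. Two epochs organize the latent
space while leaving consistency differences measurable. Multi-round score
averaging addresses the sensitivity of per-anchor losses to batch
composition.

## Numerical and degenerate-input conventions

* Losses: max-subtracted log-sum-exp; N = 1 yields loss exactly 0 (the
  denominator equals the numerator); identical embeddings yield ln(2N−1).
* Latent normalization enforced at 1e-3; NaN latents rejected.
* A trailing 1-anchor chunk during batching is folded into the previous
  batch (its loss would be identically 0).
* Constant images survive resize and normalization unchanged (max-reference
  normalization maps all-zero images to all-zero).
* Ranking ties are broken by compound_id lexical order; replicate-vote ties
  by class name.
* Every stage is deterministic given its seed: generation, splits, batch
  sampling, training (numpy RNG streams), forests, scoring.

## Known limitations

* The channel→RGB conversion is an explicit user-supplied C×3 mixing matrix
  (default: channels partitioned over R/G/B with overlap averaging); no
  claim of equivalence with any external imaging tool's conversion.
* The encoder is a small CNN; the architecture is configurable in width but
  not in topology.
* Multilabel thresholding at 0.5 and the min/mean ranking aggregates are
  conventions; both materially affect their respective metrics and are
  exposed in configuration.
* Batchwise loss scores conflate a compound's replicate consistency with its
  phenotypic distinctiveness (a compound with a near neighbor in latent
  space scores worse); multi-round averaging reduces the batch-composition
  part of this, not the intrinsic part.
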