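# Methods

## The problem

Vendor odor catalogs describe how a chemical smells as a binary checklist
over ~150 verbal descriptors ("rose", "balsamic", ...).  Two properties of
such catalogs defeat naive supervised learning of descriptors from
physicochemical inputs.  First, the table is extremely sparse (typically
over 98% zeros), so a model minimizing squared error profits from
predicting all zeros.  Second, annotators use near-synonymous descriptors
*mutually exclusively*: a chemical labeled "rose" is almost never also
labeled "violet", even though the two describe overlapping impressions, so
the sample correlation between semantically close descriptor columns is
close to zero and carries no usable structure.

odorlex implements the two-part remedy this package is built around:
recover the semantic neighbourhoods of descriptors from *pre-trained word
embeddings* rather than from the catalog itself, coarsen the target by
clustering descriptors and OR-ing their columns, and predict the resulting
cluster labels from a chemical's electron-ionization (EI) mass spectrum
with a small feed-forward network pipeline.

## Pipeline

1. **Catalog ingest and rarity filter.**  Descriptor names are lowercased
   on ingest so they can key into an embedding vocabulary.  Descriptors
   occurring fewer than `min_count` times (default 4, i.e. "three times or
   less" removed) are dropped; chemicals are never dropped, and all-zero
   rows only produce a warning.

2. **Spectrum windowing and normalization.**  Unit-resolution EI spectra
   are restricted to m/z 51..262 inclusive (212 bins): below ~50 the
   signal is dominated by fragments of odorless air constituents, and high
   m/z implies volatility too low to smell.  All retained intensities are
   divided by the single dataset-wide maximum, giving values in [0, 1] on
   one common scale.  A per-spectrum normalization exists behind a flag
   for sensitivity studies only; it changes the matrix and is not the
   default.  Non-integer m/z is rounded to the nearest bin with a warning.

3. **Descriptor dissimilarity.**  Two constructions of the descriptor ×
   descriptor dissimilarity matrix are compared throughout:
   `1 - Pearson r` of the binary catalog columns (the baseline that
   collapses under exclusive annotation), and `1 - cosine` of the
   descriptors' word vectors (range [0, 2], no clipping).  Zero-variance
   columns have undefined correlations; their r is set to 0 (dissimilarity
   1) with a warning so the matrix stays total.  Out-of-vocabulary policy
   for embeddings: exact lowercase match, else hyphen/space tokens
   averaged ("tutti frutti"), else a hard error listing the words.

4. **Classical MDS** (double-centering + eigendecomposition) provides the
   2-D maps used for visual inspection.  It is deterministic, negative
   eigenvalues are truncated at zero, and missing positive eigenvalues pad
   the output with zero columns under a warning.  Stress-majorization MDS
   was deliberately not used: the eigendecomposition route is exact on
   Euclidean-realizable inputs and has no iteration state.

5. **UPGMA clustering.**  Unweighted-average linkage, implemented directly
   so the merge order is fully deterministic: active clusters are keyed by
   their smallest original leaf, and among pairs whose distances are equal
   — where "equal" means within 1e-9, absorbing float round-off between
   the recursive linkage update and the exact all-pairs mean — the
   lexicographically smallest key pair merges first.  The tree is cut by
   cluster *count* (undo the last K-1 merges), not by height; a height cut
   is exposed as `cut_at_height` for comparison.  Cluster indices are
   ordered by first-appearing leaf for stable outputs.

6. **OR-rule labels.**  Chemical i carries cluster c iff at least one
   member descriptor of c applies to i.  At K = n descriptors this reduces
   to the original catalog; as K shrinks, per-chemical positive bits can
   only merge, never multiply.

7. **Networks.**  All networks are sigmoid-activated feed-forward models
   trained by per-sample stochastic gradient descent with a momentum term,

       w(t+1) = w(t) - eta * dE/dw + alpha * (w(t) - w(t-1)),

   where E is the mean squared error over output neurons plus an L2
   penalty `lambda * sum(w^2)` (biases unpenalized; the penalty's gradient
   is `2*lambda*w`).  eta and alpha decay geometrically once per epoch.
   Weights start N(0, 0.1^2) from a seeded generator; biases start at
   zero (standard practice; nonzero bias init only pushes sigmoids toward
   saturation).  Sample order is reshuffled every epoch from the run seed,
   so a fixed seed reproduces the loss trace bitwise.

   The full-scale architecture is a five-layer sandglass autoencoder
   [212, 85, 30, 85, 212] whose 30-unit bottleneck yields the feature
   vector, a four-layer mapper [30, 50, 20, K] from features to cluster
   labels, and their exact concatenation — a six-layer predictor — which
   is briefly fine-tuned end to end.  Full-scale schedule constants
   (eta 0.5/0.3, alpha 0.3/0.1, decay 0.99, lambda 3e-7/2e-7) ship as the
   `PredictorConfig` defaults.

8. **Thresholding.**  The assembled network's continuous outputs are
   binarized by one global step-function threshold shared across all K
   outputs, chosen from the grid {0.01, ..., 0.99} to maximize balanced
   accuracy (mean of pooled TP and TN rates) on the *training* portion
   only; ties take the smallest threshold.  Plain concordance was
   rejected as the objective: on a ~98%-sparse target it is maximized by
   predicting all zeros.

9. **Evaluation.**  k-fold cross-validation over a seeded uniform
   permutation (999 samples in 5 folds split [200, 200, 200, 200, 199];
   remainders go to the first folds).  No stratification by default (a
   flagless seeded permutation matches the absence of any stated
   stratification scheme); the autoencoder is retrained per fold on
   training spectra only, the leakage-free choice.  Rates are pooled over
   all chemical × cluster cells: TP = % of desired-1 cells predicted 1,
   TN = % of desired-0 cells predicted 0, so TP+FN = TN+FP = 100 exactly;
   an all-ones or all-zeros truth leaves the undefined rate as NaN, never
   0.  `sweep_k` repeats the whole procedure per K and also reports the
   per-cluster positive counts, because a single huge cluster can make
   accuracy look excellent while the prediction carries almost no
   information.

## Synthetic worlds

The generator builds linked catalog/spectra/embedding bundles with the
structure the method assumes, so every stage is testable offline:

* each chemical draws 1–3 latent odor groups;
* **exclusive mode** (default) marks exactly one randomly chosen member
  descriptor per active group — reproducing the vanishing within-group
  correlations of exclusively annotated catalogs — while non-exclusive
  mode marks each member with probability 0.8, the high-correlation
  regime of graded sensory panels;
* embeddings place each group's members around its own orthonormal
  direction (scale `group_separation`, member noise sd 0.05); separations
  above ~0.5 make the planted partition recoverable by UPGMA on cosine
  distances;
* spectra mix nonnegative per-group basis patterns with positive weights
  plus Gaussian noise clipped at zero, so cluster labels are learnable
  from spectra; with zero noise and `latent_rank = G` the spectrum matrix
  has numerical rank exactly G.

Descriptor names come from a fixed list of real odor vocabulary so the
embedding lookup path is exercised; injected rare descriptors occur at
most 3 times (exercising the rarity filter), and the last of them carries
no embedding vector, exercising the out-of-vocabulary error path.

What the generator does **not** emulate: real fragmentation chemistry
(basis spectra are random nonnegative patterns, not fragment series),
correlated annotation errors, descriptor polysemy, or the long-tailed
descriptor frequency distribution of a real catalog.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
the embedding-vs-correlation contrast behaves as designed when the data
have the assumed structure — not that any particular accuracy level
transfers to real catalog/spectral data.

## Desk-scale study conditions

Full-scale training (10^5–10^6 epochs on 212-bin spectra) is far beyond
an interactive run, so the shipped study conditions are scaled down as a
package-level choice: 180 chemicals, 6 planted groups × 5 descriptors,
64-bin spectra, autoencoder [64, 32, 10, 32, 64], mapper [10, 24, 12, K],
epochs 400/300/150 (`scaled_predictor_config`).  The schedule constants
are rescaled too (eta 2.0/1.0, alpha 0.5, decay 0.998): under the
full-scale 0.99^tau decay the cumulative step budget, sum over tau of
eta0 * 0.99^tau ≈ 100 * eta0, is spent within ~500 epochs, while
sigmoid+MSE training starts on a gradient plateau — a few hundred epochs
at the full-scale constants move the loss barely at all, which is exactly
why the full-scale recipe needs its enormous epoch counts.  The relaxed
decay keeps the per-epoch step useful across the shorter run.

## Numerical choices and degenerate inputs

* Sigmoid is computed in the numerically stable split form; no overflow
  for any finite input.
* DistanceMatrix construction symmetrizes and zero-clips at tolerance
  1e-12 so downstream clustering sees exact symmetry.
* Training raises on a non-finite gradient or loss (divergence signal)
  rather than continuing silently.
* `fit_threshold` with a truth column entirely 0 or 1 falls back to the
  defined rate alone (nan-mean), and `confusion_rates` reports the
  undefined rate as NaN.
* An all-zero spectrum window across the dataset is an error (the global
  maximum is undefined); an all-zero catalog is likewise rejected by the
  rarity filter rather than silently returning nothing.

## Known limitations

* Per-sample SGD in pure NumPy is the simplest faithful rendering of the
  training rule but is overhead-bound; full-scale epoch counts are
  impractical without vectorized batching, which would change the update
  semantics.
* The global threshold is shared across outputs; per-output thresholds
  could raise TP on rare clusters but have no analog in the evaluation
  design here.
* Word vectors are consumed as given; training the skip-gram model and
  its corpus handling are out of scope (the provenance hyperparameters —
  400 hidden units, window 10, minimum count 5 — are carried only as
  embedding metadata).
* Real-data headline accuracies depend on the specific catalog, spectral
  library and embedding corpus; this package reproduces the method and
  its internal contrasts, not those dataset-bound figures.
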