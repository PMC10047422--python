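# Methods

This note documents the models, conventions and design choices behind
`infframe`, in the spirit of the methods documentation of packages like
scanpy or statsmodels: what each stage computes, which knobs matter, what the
synthetic data does and does not emulate, and where the design was genuinely
open.

## The pipeline

The package treats informative-frame selection as clustering-as-classification:
frames are embedded, projected to a low-dimensional space, clustered, and each
cluster is then assigned a ground-truth category by a bijection that maximizes
total intersection. Only the last two stages (labeling, evaluation) ever see
ground-truth labels; embedding, reduction and clustering are fully
unsupervised. The pipeline orchestrator enforces this: labels flow only into
`labeling`/`evaluation` (and into the tuning cost for fixed-k methods, which
scores candidate clusterings *through* those stages).

### Feature embedding

* `cnn-vgg16-random`: a VGG16-architecture tower (thirteen 3×3 convolutions
  with 2×2 max pools, then the first 4096-unit fully connected layer) with
  **random, untrained** weights — He-initialized Gaussians fixed by the seed,
  zero biases, ReLU activations. The classifier head and the second FC layer
  are dropped; the output is the post-ReLU activation of the first FC layer
  (D = 4096). Which of the two 4096-unit layers survives the truncation is
  genuinely ambiguous; we output the first and record the choice in
  `backend_tag`. Implemented directly in numpy (im2col + matmul), float32.
  Inputs are bilinearly resized to `input_size` (default 224, any multiple of
  32) and scaled to [0, 1]; no mean subtraction. Random convolutional
  features preserve coarse image statistics well enough for the downstream
  stages, at roughly 5 s per frame at 224 — tests use `input_size=32`.
* `pixel-downsample`: luma grayscale, bilinear resize to 32×32, flattened
  (D = 1024), scaled to [0, 1]. Exists so the full pipeline runs in seconds;
  it is the default in tests and the CLI.

### Dimensionality reduction

PCA is computed from first principles: eigenvectors of the sample covariance
of the column-centered matrix, obtained via thin SVD (identical estimator,
no D×D covariance materialized), components ordered by descending eigenvalue
with a deterministic sign convention, explained-variance ratios exposed.
Columns are centered but not variance-scaled. Default d = 50 — on CNN
embeddings of the four-category frame sets, ~80% of variance sits in the top
50 components. t-SNE and UMAP are wrapped (scikit-learn, umap-learn): their
objectives are standard and re-deriving them adds nothing scheme-specific;
the wrapper owns parameter validation, seeding and provenance (`params_`
records the implementation and version). Manifold methods default to d = 2,
the space in which clustering performs best and figures are drawn. The output
dimensionality used for clustering is exposed (`n_components`) rather than
hard-coded.

### Clustering

All four algorithms are wrapped from scikit-learn — the scheme's contribution
lies in the labeling/tuning/evaluation stages, not in re-implementing Lloyd
iterations or eigensolvers. The module owns the uniform result contract
(`ClusterResult`): integer labels, −1 reserved for DBSCAN noise, `k_found`
counting non-noise clusters. K-means is the mini-batch variant with seeded
initialization. Euclidean distances throughout. Hyperparameter spaces (used by
tuning): k-means {batch size 32–1024, n_init 1–10}; agglomerative {linkage ∈
ward/average/complete/single}; spectral {affinity nearest-neighbors (5–30
neighbors) or RBF (γ log-uniform 1e-3–10)}; DBSCAN {eps log-uniform over a
data-scaled decade around the median nearest-neighbor distance, MinPts 3–20}.

### Automatic cluster labeling

The greedy rule iterates clusters in ascending id order and maps each to its
argmax category. Two deliberate conventions:

* **Collision repair.** The greedy pass can map two clusters to one category,
  violating the required bijection. The mapping then falls back to exhaustive
  maximization over all K! bijections (24 candidates at K = 4) and is flagged
  `mode="optimal"`. The repair is flagged, never silent.
* **Tie rule.** Argmax ties break to the lowest category index in the fixed
  order (I, B, S, U); ties between equally good bijections break to the
  lexicographically first assignment. Both rules make the mapping
  deterministic.

Noise points are excluded from the contingency table and the mapping; in
downstream metrics they are mapped to a reserved `unassigned` value that is
never a true positive and counts as a false negative for the point's true
category.

### Tuning

The two cost functions are evaluated exactly as written in the pipeline's
search algorithm: the fixed-k branch from macro-averaged recall and precision
(uniform class weights), the DBSCAN branch from the noise count, the recovered
cluster count and σ. **σ convention:** mean squared deviation of per-cluster
counts from the expected per-class count (180 for the full dataset scale) — a
population variance about a fixed reference, zero exactly when every cluster
hits the target. A sample variance of the counts would not vanish there,
which contradicts the cost's intent; the choice is documented here because the
verbal definition admits both readings. Defaults α = 100, β = 0.01, K = 4,
budget 200 evaluations; the only stopping rule is budget exhaustion.

Bayesian optimization uses a Gaussian-process surrogate (Matérn 5/2 + white
noise, standardized targets) with expected improvement maximized over a
256-point random candidate pool, after a random initialization of a third of
the budget (at most 10 points). Random search draws uniform points. Both are
bit-reproducible given the space seed. Parameters are encoded to the unit
cube (log dims in log space, choices as scaled indices) for the surrogate.

### Evaluation

* Precision, sensitivity (recall) and F1 are one-vs-rest per category;
  zero-denominator cases return 0 (this reproduces the all-zero rows printed
  for degenerate spectral clusterings).
* **Summaries use the midpoint median and Tukey-hinge IQR** (halves split at
  the median, median included in both halves at odd length). This is
  load-bearing: it is the quartile convention under which every published
  summary cell reproduces from its four per-class values. Table comparisons
  additionally go through exact decimal arithmetic with round-half-up at two
  decimals (`rounded_summary`), because float arithmetic can land exact .005
  boundaries on the wrong side (0.845 − 0.76 → 0.0849…99 → 0.08 instead of
  0.09).
* ROC/AUC uses the rank (Mann–Whitney) statistic with midranks for ties, so
  constant scores give exactly 0.5. For hard clusterings the per-category
  score of a point is the negative Euclidean distance to the centroid of the
  cluster mapped to that category, standardized per category (an affine
  per-column transform, which leaves AUC invariant). How ROC curves are drawn
  from hard assignments is not standardized anywhere; this construction is
  deterministic and documented, and is the package's own choice.
* Silhouette and Calinski–Harabasz are computed directly from their
  definitions (pairwise-distance means; BGSS/WGSS with arithmetic-mean
  centroids). Library implementations serve as independent cross-checks in
  tests, at 1e-9 relative tolerance. Singletons get silhouette 0; a zero
  WGSS yields +inf with a warning.
* Cluster-number determination sweeps k = 2..6 (default), clusters with
  seeded mini-batch k-means per k, and returns the CH argmax (ties → smallest
  k).
* The exact Wilcoxon signed-rank test drops zero differences, midranks tied
  absolute differences, takes the smaller signed-rank sum as the statistic,
  and enumerates all 2^n sign assignments for the two-sided p (capped at 1).
  It is meant for the small paired samples that arise when comparing
  per-class recall profiles (n = 4); the implementation guards n ≤ 15.

## The synthetic frame generator

The generator emulates the four NBI frame-quality categories at 128×128
(the pipeline is size-agnostic; real frames are 1920×1072) with measurable
pixel criteria, intensities 0–255:

* **I (informative)**: a greenish mucosa base with band-limited noise, dark
  curvilinear strokes as vessel proxies, a strong fixed radial vignette
  (endoscope illumination), and small specular specks capped at 10% of the
  area (2% by default).
* **B (blurred)**: the *same* sharp base (same seed) under a wide Gaussian
  blur (σ = 8 px default) followed by motion smear — a blend toward the
  global mean whose strength, residual illumination tilt and exposure vary
  per frame. Blur alone leaves coarse pixel statistics almost unchanged
  (local averaging commutes with downsampling), so the smear — physically,
  motion averaging the vignette away — is what makes B separable from I in
  the 32×32 pixel backend; the per-frame smear/tilt/exposure variation gives
  the class a smooth low-dimensional within-class manifold instead of a
  point mass, which manifold methods otherwise shred into arbitrary islands.
* **S (specular/saliva)**: bright blobs, white or light green with equal
  probability, painted until they cover at least half the image area (60%
  target by default); every blob pixel has max channel ≥ 230.
* **U (underexposed)**: dark noise below intensity 40 over at least 90% of
  pixels (95% by default), with one regularly exposed disk inside the
  allowed 10% bright budget.

Operational thresholds — dark pixel: max channel < 40; specular pixel: max
channel ≥ 230 — are the generator's own definitions; the category criteria
are stated as area fractions only. The sharpness ordering (Laplacian-response
variance of I strictly above B for the same seed) is the measurable proxy for
"visible vessels vs widespread blur".

What the generator does **not** emulate: real laryngeal anatomy and
vasculature topology, temporal (video) structure, the acquisition system's
optics and color response, mixed or borderline frames, class imbalance, and
inter-rater ambiguity. Passing tests therefore demonstrate that the pipeline's
machinery is correct and that it recovers well-separated quality categories —
not that real NBI frames are this separable. The blob generator
(`generate_blob_embeddings`) stands in for CNN embeddings where image content
is irrelevant: isotropic Gaussians at simplex vertices pairwise exactly
`separation` apart (when the number of clusters is at most the
dimensionality).

## Problem sizes and numerical choices

Tests and acceptance checks run the frame pipeline at 45–60 frames per
category (180–240 frames) with the pixel backend, and blob benchmarks at the
full 4 × 180 scale; these sizes keep every property statistically stable
while the whole suite completes in a few minutes on one CPU. Stage seeds are
derived from the master seed by hashing the stage name (SHA-256, reduced below
2^31), so any single stage can be re-run from its saved artifact
bit-identically. Degenerate inputs fail loudly: zero-variance PCA input,
single-cluster silhouette, K = N Calinski–Harabasz, empty search spaces and
all-noise DBSCAN results all raise (or, where the pipeline must continue,
score as a large penalty).

## Known limitations

* The random-weight CNN backend is slow in pure numpy at full 224 resolution
  (~5 s/frame on one core) — usable for the 720-frame scale the pipeline
  targets, but not for video-rate screening.
* Cluster labeling requires as many clusters as categories; K ≠ G signals
  that cluster-count determination failed rather than attempting a
  many-to-one label transfer.
* t-SNE has no out-of-sample transform; the reducer is transductive
  (`fit_transform`) for the manifold methods.
* The BO driver models categorical dimensions as scaled indices in a single
  GP, which is crude for deeply conditional spaces; the spaces used here are
  small and low-dimensional, where it is adequate and the random-search
  fallback closes any gap.
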