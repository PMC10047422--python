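"""Published per-class benchmark metrics on the NBI-InfFrames dataset.

These are the printed per-class precision / recall (sensitivity) / F1 values
for the four-category informative-frame-selection task, used as fixed inputs
to the package's summary statistics and paired significance tests: an SVM on
hand-crafted features (the baseline), a fine-tuned SqueezeNet, a fine-tuned
VGG16, and the unsupervised UMAP + agglomerative pipeline this package
implements.  Class order is (B, I, S, U).
"""

CLASS_ORDER = ("B", "I", "S", "U")

PRECISION = {
    "svm": (0.76, 0.91, 0.78, 0.76),
    "squeezenet": (0.94, 0.97, 0.93, 0.97),
    "vgg16": (0.92, 0.97, 0.93, 0.92),
    "umap_agglo": (0.89, 0.99, 0.99, 0.94),
}

RECALL = {
    "svm": (0.83, 0.91, 0.62, 0.85),
    "squeezenet": (0.94, 1.00, 0.91, 0.94),
    "vgg16": (0.96, 0.97, 0.88, 0.93),
    "umap_agglo": (0.98, 0.94, 0.89, 0.97),
}

F1 = {
    "svm": (0.79, 0.91, 0.69, 0.80),
    "squeezenet": (0.94, 0.98, 0.91, 0.95),
    "vgg16": (0.94, 0.97, 0.91, 0.93),
    "umap_agglo": (0.93, 0.97, 0.94, 0.95),
}

#: Published summary cells (median, IQR) for every method x metric pair.
SUMMARY = {
    ("svm", "precision"): (0.77, 0.09),
    ("svm", "recall"): (0.84, 0.16),
    ("svm", "f1"): (0.80, 0.12),
    ("squeezenet", "precision"): (0.96, 0.04),
    ("squeezenet", "recall"): (0.94, 0.05),
    ("squeezenet", "f1"): (0.95, 0.04),
    ("vgg16", "precision"): (0.93, 0.03),
    ("vgg16", "recall"): (0.95, 0.06),
    ("vgg16", "f1"): (0.94, 0.04),
    ("umap_agglo", "precision"): (0.97, 0.08),
    ("umap_agglo", "recall"): (0.96, 0.06),
    ("umap_agglo", "f1"): (0.95, 0.03),
}

#: UMAP + mini-batch-k-means per-class metrics (class order B, I, S, U),
#: used to cross-check the summary-statistic conventions on a second table.
UMAP_KMEANS = {
    "precision": (0.89, 1.00, 0.93, 0.90),
    "recall": (0.98, 0.95, 0.86, 0.93),
    "f1": (0.94, 0.97, 0.89, 0.92),
}
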