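import numpy as np
import pytest

import infframe as iff


@pytest.fixture(scope="session")
def small_frames():
    """24 labeled frames, 6 per category."""
    return iff.generate_frame_set(6, seed=11)


@pytest.fixture(scope="session")
def blob_data():
    """Well-separated 4-cluster Gaussian blobs (720 x 50, separation 20 sd)."""
    X, labels = iff.generate_blob_embeddings(
        iff.BlobSpec(n_clusters=4, n_per_cluster=180, dim=50, separation=20.0,
                     noise_sd=1.0, seed=2))
    return X, labels


@pytest.fixture(scope="session")
def pipeline_result():
    """Shared end-to-end run: frames -> pixel embedding -> UMAP -> ward."""
    frames = iff.generate_frame_set(60, seed=7)
    X = iff.extract_embeddings(frames, backend="pixel-downsample", seed=1)
    Y = iff.reduce(X, "umap", seed=8)
    result = iff.cluster(Y, "agglomerative", {"n_clusters": 4, "linkage": "ward"}, seed=1)
    mapping = iff.greedy_label_map(iff.contingency(result, frames.labels))
    return frames, X, Y, result, mapping
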