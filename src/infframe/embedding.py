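"""Frame -> fixed-length feature vectors.

Two backends share one transformer interface:

``cnn-vgg16-random``
    A forward pass through a randomly initialized VGG16-architecture network
    truncated after the first 4096-unit fully connected activation (the
    classifier head and second FC layer are dropped).  Weights are drawn once
    from a seeded fan-in-scaled Gaussian (He) initialization; no training is
    involved.  Implemented directly in numpy (im2col convolutions), so it is
    heavyweight but dependency-free.
``pixel-downsample``
    Grayscale bilinear downsample to 32x32, flattened to 1024 features.  Fast
    enough that the whole pipeline runs in seconds; the default in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

from .synthdata import FrameSet

BACKENDS = ("cnn-vgg16-random", "pixel-downsample")

# VGG16 convolutional configuration: channel widths, "M" = 2x2 max pool.
_VGG16_CFG = (64, 64, "M", 128, 128, "M", 256, 256, 256, "M",
              512, 512, 512, "M", 512, 512, 512, "M")


@dataclass
class EmbeddingMatrix:
    """N x D feature matrix with row-aligned frame identifiers."""

    values: np.ndarray
    frame_ids: list[str] = field(default_factory=list)
    backend_tag: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("embedding matrix must be N x D with N >= 1, D >= 2")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding matrix contains non-finite entries")
        if not self.frame_ids:
            self.frame_ids = [f"frame_{i:05d}" for i in range(len(self.values))]
        if len(self.frame_ids) != len(self.values):
            raise ValueError("frame_ids must align with rows")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def save(self, path) -> None:
        header = self.backend_tag or "embedding"
        np.savetxt(path, self.values, delimiter="\t", header=header)

    @classmethod
    def load(cls, path) -> "EmbeddingMatrix":
        with open(path) as fh:
            first = fh.readline()
        tag = first[1:].strip() if first.startswith("#") else ""
        values = np.loadtxt(path, delimiter="\t", ndmin=2)
        return cls(values, backend_tag=tag)


def _as_image_stack(frames) -> np.ndarray:
    if isinstance(frames, FrameSet):
        return frames.images
    arr = np.asarray(frames)
    if arr.ndim == 3:
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError("expected a FrameSet or an (N, H, W, 3) image array")
    return arr


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return img.astype(np.float32)
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((size, size), Image.BILINEAR), dtype=np.float32)


class _RandomVGG16:
    """Seeded random-weight VGG16 feature tower truncated at the first FC layer."""

    def __init__(self, input_size: int, seed: int):
        if input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")
        self.input_size = input_size
        rng = np.random.default_rng(seed)
        self.conv_w, self.conv_b = [], []
        c_in = 3
        for item in _VGG16_CFG:
            if item == "M":
                continue
            fan_in = c_in * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (item, c_in, 3, 3)).astype(np.float32)
            self.conv_w.append(w)
            self.conv_b.append(np.zeros(item, dtype=np.float32))
            c_in = item
        s = input_size // 32
        flat = 512 * s * s
        self.fc_w = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, 4096)).astype(np.float32)
        self.fc_b = np.zeros(4096, dtype=np.float32)

    @staticmethod
    def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
        # x: (H, W, C_in) -> (H, W, C_out), padding 1
        h, wd, c = x.shape
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(0, 1))
        cols = win.transpose(0, 1, 3, 4, 2).reshape(h * wd, 9 * c)
        wm = w.transpose(2, 3, 1, 0).reshape(9 * c, -1)
        return (cols @ wm + b).reshape(h, wd, -1)

    @staticmethod
    def _maxpool2(x: np.ndarray) -> np.ndarray:
        h, w, c = x.shape
        return x.reshape(h // 2, 2, w // 2, 2, c).max(axis=(1, 3))

    def forward(self, img: np.ndarray) -> np.ndarray:
        x = _resize(img, self.input_size) / 255.0
        li = 0
        for item in _VGG16_CFG:
            if item == "M":
                x = self._maxpool2(x)
            else:
                x = np.maximum(self._conv3x3(x, self.conv_w[li], self.conv_b[li]), 0.0)
                li += 1
        return np.maximum(x.reshape(-1) @ self.fc_w + self.fc_b, 0.0)


class FrameEmbedder(TransformerMixin, BaseEstimator):
    """Map RGB frames to feature vectors.

    Parameters
    ----------
    backend : {"pixel-downsample", "cnn-vgg16-random"}
        Feature extractor.  The CNN backend outputs 4096 features, the pixel
        backend 1024.
    input_size : int
        Side length the CNN backend resizes frames to (multiple of 32).
    random_state : int
        Seed for the CNN weight initialization.
    """

    def __init__(self, backend: str = "pixel-downsample", input_size: int = 224,
                 random_state: int = 0):
        self.backend = backend
        self.input_size = input_size
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; expected one of {BACKENDS}")
        images = _as_image_stack(X)
        if len(images) == 0:
            raise ValueError("empty frame set")
        if self.backend == "cnn-vgg16-random":
            self.net_ = _RandomVGG16(self.input_size, self.random_state)
            self.n_features_ = 4096
            self.backend_tag_ = (f"cnn-vgg16-random(fc1,seed={self.random_state},"
                                 f"input={self.input_size})")
        else:
            self.net_ = None
            self.n_features_ = 1024
            self.backend_tag_ = "pixel-downsample(32x32-gray)"
        return self

    def transform(self, X) -> np.ndarray:
        images = _as_image_stack(X)
        if len(images) == 0:
            raise ValueError("empty frame set")
        if self.backend == "cnn-vgg16-random":
            out = np.stack([self.net_.forward(img) for img in images])
        else:
            gray_w = np.array([0.299, 0.587, 0.114], dtype=np.float32)
            feats = []
            for img in images:
                gray = (img.astype(np.float32) @ gray_w)
                pil = Image.fromarray(gray)
                small = np.asarray(pil.resize((32, 32), Image.BILINEAR), dtype=np.float32)
                feats.append(small.reshape(-1) / 255.0)
            out = np.stack(feats)
        return out.astype(np.float64)


def extract_embeddings(frames, backend: str = "pixel-downsample", seed: int = 0,
                       input_size: int = 224) -> EmbeddingMatrix:
    """Convenience wrapper returning an :class:`EmbeddingMatrix`."""
    est = FrameEmbedder(backend=backend, input_size=input_size, random_state=seed)
    values = est.fit(frames).transform(frames)
    ids = frames.frame_ids if isinstance(frames, FrameSet) else []
    return EmbeddingMatrix(values, list(ids), est.backend_tag_)
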