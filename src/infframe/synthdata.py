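"""Synthetic narrow-band-imaging laryngoscopy frames and Gaussian-blob embeddings.

The generator emulates the four frame-quality categories used for informative
frame selection in NBI laryngoscopy:

``B``
    blurred — homogeneous, widespread motion blur;
``I``
    informative — adequate exposure, sharp curvilinear vessel structure,
    specular reflections covering at most 10% of the image area;
``S``
    saliva / specular reflections — bright white or light-green bubbles and
    blobs overlapping at least half of the image area;
``U``
    underexposed — a high percentage of dark pixels (at least 90% of pixels
    below intensity 40 on the 0–255 scale).

Each category is defined by a machine-checkable pixel predicate (see
:func:`category_predicate`), so every downstream stage of the pipeline can be
tested without the real dataset.  A second generator produces isotropic
Gaussian blobs as a fast stand-in for CNN feature embeddings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

#: Canonical category order; ties and integer codes follow this order.
CATEGORIES = ("I", "B", "S", "U")

#: Intensity (0-255) at or above which a pixel's max channel counts as specular.
BRIGHT_THRESHOLD = 230
#: Intensity (0-255) below which a pixel's max channel counts as dark.
DARK_THRESHOLD = 40


@dataclass(frozen=True)
class FrameSpec:
    """Parameters of one synthetic frame.

    ``reflection_fraction`` is the target fraction of image area covered by
    specular highlights (max channel >= 230); ``dark_fraction`` the target
    fraction of dark pixels (max channel < 40); ``blur_sigma`` the Gaussian
    blur scale in pixels used for category B.
    """

    category: str
    width: int = 128
    height: int = 128
    reflection_fraction: float | None = None
    dark_fraction: float | None = None
    blur_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        rf = self.reflection_fraction
        if rf is None:
            rf = {"I": 0.02, "S": 0.6}.get(self.category, 0.0)
            object.__setattr__(self, "reflection_fraction", rf)
        df = self.dark_fraction
        if df is None:
            df = 0.95 if self.category == "U" else 0.0
            object.__setattr__(self, "dark_fraction", df)
        if not (0.0 <= rf <= 1.0 and 0.0 <= df <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if self.category == "I" and rf > 0.10:
            raise ValueError("informative frames allow at most 10% specular area")
        if self.category == "S" and rf < 0.50:
            raise ValueError("specular frames require at least 50% highlight area")
        if self.category == "U" and df < 0.90:
            raise ValueError("underexposed frames require at least 90% dark pixels")
        if self.blur_sigma <= 0:
            raise ValueError("blur_sigma must be positive")


@dataclass
class FrameSet:
    """A stack of frames with optional aligned ground-truth categories."""

    images: np.ndarray  # (N, H, W, 3) uint8
    labels: list[str] | None = None
    frame_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.images = np.asarray(self.images)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError("images must be an (N, H, W, 3) array")
        if self.labels is not None and len(self.labels) != len(self.images):
            raise ValueError("labels must align with images")
        if not self.frame_ids:
            self.frame_ids = [f"frame_{i:05d}" for i in range(len(self.images))]

    def __len__(self) -> int:
        return len(self.images)

    def save(self, folder: str | Path) -> Path:
        """Write PNGs into per-category subfolders plus a labels manifest."""
        folder = Path(folder)
        folder.mkdir(parents=True, exist_ok=True)
        labels = self.labels if self.labels is not None else ["unlabeled"] * len(self)
        with open(folder / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            for fid, img, lab in zip(self.frame_ids, self.images, labels):
                sub = folder / lab
                sub.mkdir(exist_ok=True)
                path = sub / f"{fid}.png"
                Image.fromarray(img).save(path)
                writer.writerow([str(path.relative_to(folder)), lab])
        return folder / "manifest.csv"

    @classmethod
    def load(cls, folder: str | Path) -> "FrameSet":
        """Read a folder written by :meth:`save`, or loose PNG/JPEG files."""
        folder = Path(folder)
        manifest = folder / "manifest.csv"
        images, labels, ids = [], [], []
        if manifest.exists():
            with open(manifest, newline="") as fh:
                for rel, lab in csv.reader(fh):
                    images.append(np.asarray(Image.open(folder / rel).convert("RGB")))
                    labels.append(lab)
                    ids.append(Path(rel).stem)
            has_labels = any(l != "unlabeled" for l in labels)
            return cls(np.stack(images), labels if has_labels else None, ids)
        paths = sorted(p for p in folder.rglob("*") if p.suffix.lower() in {".png", ".jpg", ".jpeg"})
        if not paths:
            raise FileNotFoundError(f"no images found under {folder}")
        for p in paths:
            images.append(np.asarray(Image.open(p).convert("RGB")))
            lab = p.parent.name if p.parent != folder else None
            labels.append(lab)
            ids.append(p.stem)
        has_labels = all(l in CATEGORIES for l in labels)
        return cls(np.stack(images), list(labels) if has_labels else None, ids)


@dataclass(frozen=True)
class BlobSpec:
    """Isotropic Gaussian mixture standing in for CNN embeddings."""

    n_clusters: int = 4
    n_per_cluster: int = 180
    dim: int = 50
    separation: float = 20.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.n_per_cluster < 1:
            raise ValueError("need at least 1 point per cluster")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


# ---------------------------------------------------------------------------
# frame rendering internals

def _rng_for(spec: FrameSpec) -> np.random.Generator:
    code = CATEGORIES.index(spec.category)
    return np.random.default_rng(np.random.SeedSequence([spec.seed, code]))


def _vignette(h: int, w: int) -> np.ndarray:
    """Radial illumination falloff shared by all frames of a set.

    The strong fixed vignette is what anchors informative frames to a common
    illumination pattern; blurring plus smear flattens it, which is how the
    blurred class becomes separable even in coarse pixel space.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r2 = ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2
    return np.clip(1.0 - 0.8 * r2, 0.12, 1.0)


def _stamp_disk(mask: np.ndarray, cy: float, cx: float, radius: float) -> None:
    h, w = mask.shape
    y0, y1 = max(0, int(cy - radius)), min(h, int(cy + radius) + 1)
    x0, x1 = max(0, int(cx - radius)), min(w, int(cx + radius) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _vessel_mask(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Random smooth curvilinear strokes as a proxy for submucosal vessels."""
    mask = np.zeros((h, w), dtype=bool)
    n_strokes = 6 + int(rng.integers(0, 3))
    for _ in range(n_strokes):
        y, x = rng.uniform(0, h), rng.uniform(0, w)
        theta = rng.uniform(0, 2 * np.pi)
        curvature = rng.normal(0.0, 0.25)
        thickness = rng.uniform(1.0, 2.0)
        for _ in range(int(0.6 * max(h, w))):
            _stamp_disk(mask, y, x, thickness)
            theta += curvature * 0.3 + rng.normal(0.0, 0.05)
            y += 2.0 * np.sin(theta)
            x += 2.0 * np.cos(theta)
            if not (-5 < y < h + 5 and -5 < x < w + 5):
                break
    return mask


def _informative_base(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Shared sharp base for I and B frames: tissue + noise + vessels, float RGB."""
    base_color = np.array([95.0, 150.0, 120.0])  # greenish NBI mucosa
    noise = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
    noise = noise / max(noise.std(), 1e-9) * 7.0
    img = _vignette(h, w)[..., None] * (base_color[None, None, :] + noise[..., None])
    vessels = _vessel_mask(h, w, rng)
    img[vessels] *= np.array([0.55, 0.50, 0.55])  # dark brownish vessels
    return img


def _paint_highlights(img: np.ndarray, target_fraction: float, rng: np.random.Generator,
                      radius_range: tuple[float, float], light_green: bool,
                      hard_cap: float = 1.0) -> np.ndarray:
    """Paint bright blobs until coverage reaches target_fraction; returns mask.

    Coverage never exceeds ``hard_cap`` (disks that would overshoot it are
    discarded), which keeps informative frames within their 10% specular bound.
    """
    h, w = img.shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    n_pix = h * w
    while mask.sum() < target_fraction * n_pix:
        r = rng.uniform(*radius_range)
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        trial = mask.copy()
        _stamp_disk(trial, cy, cx, r)
        if trial.sum() > hard_cap * n_pix:
            break
        mask = trial
    if light_green and rng.random() < 0.5:
        color = np.array([215.0, 252.0, 215.0])
    else:
        color = np.array([250.0, 250.0, 248.0])
    img[mask] = color + rng.normal(0, 1.5, (int(mask.sum()), 3))
    return mask


def generate_frame(spec: FrameSpec) -> np.ndarray:
    """Render one synthetic frame as an (H, W, 3) uint8 array.

    The returned image satisfies its category's measurable predicate:
    S-frames have >= 50% of pixels with max channel >= 230, U-frames have
    >= 90% of pixels with max channel < 40, I-frames cap specular coverage
    at 10%, and B-frames are the blurred+smeared rendition of the same sharp
    base an I-frame with the same seed would use (so Laplacian variance of I
    strictly exceeds that of B).  Deterministic given ``spec``.
    """
    h, w = spec.height, spec.width
    rng = _rng_for(spec)
    cat = spec.category

    if cat in ("I", "B"):
        # identical base per seed so that sharpness ordering is testable
        base_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
        img = _informative_base(h, w, base_rng)
        if cat == "I":
            frac = min(spec.reflection_fraction, 0.10)
            if frac > 0:
                _paint_highlights(img, frac, rng, (1.5, 3.5), light_green=False,
                                  hard_cap=0.10)
        else:
            img = gaussian_filter(img, (spec.blur_sigma, spec.blur_sigma, 0))
            # motion smear: how much structure survives, the residual
            # illumination tilt and the exposure all vary frame to frame
            w_keep = rng.uniform(0.15, 0.45)
            img = w_keep * img + (1.0 - w_keep) * img.mean(axis=(0, 1), keepdims=True)
            yy, xx = np.mgrid[0:h, 0:w]
            tilt = (rng.normal(0.0, 12.0) * (2 * xx / max(w - 1, 1) - 1)
                    + rng.normal(0.0, 12.0) * (2 * yy / max(h - 1, 1) - 1))
            img = img + tilt[..., None]
            img *= rng.uniform(0.92, 1.08)
    elif cat == "S":
        base_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
        img = 0.8 * _informative_base(h, w, base_rng)
        target = max(spec.reflection_fraction, 0.50)
        _paint_highlights(img, target, rng, (6.0, 20.0), light_green=True)
    elif cat == "U":
        noise = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 2.0)
        noise = noise / max(noise.std(), 1e-9) * 5.0
        dark = np.clip(18.0 + noise, 2.0, DARK_THRESHOLD - 2.0)
        img = np.repeat(dark[..., None], 3, axis=2) * np.array([0.9, 1.0, 0.95])
        bright_budget = min(0.1, 1.0 - spec.dark_fraction)
        if bright_budget > 0.005:
            mask = np.zeros((h, w), dtype=bool)
            radius = np.sqrt(bright_budget * h * w / np.pi) * 0.9
            _stamp_disk(mask, rng.uniform(0, h), rng.uniform(0, w), radius)
            img[mask] = np.array([110.0, 150.0, 125.0])
    else:  # pragma: no cover - guarded by FrameSpec
        raise ValueError(cat)

    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def category_predicate(category: str, image: np.ndarray) -> bool:
    """Check a frame against its category's measurable pixel criterion."""
    peak = image.max(axis=2).astype(float)
    bright = (peak >= BRIGHT_THRESHOLD).mean()
    dark = (peak < DARK_THRESHOLD).mean()
    if category == "S":
        return bright >= 0.50
    if category == "U":
        return dark >= 0.90
    if category == "I":
        return bright <= 0.10
    if category == "B":
        return bright <= 0.10 and dark <= 0.10
    raise ValueError(f"unknown category {category!r}")


def generate_frame_set(n_per_class: int, size: int = 128, seed: int = 0) -> FrameSet:
    """Generate ``4 * n_per_class`` labeled frames, shuffled deterministically."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images, labels = [], []
    for cat in CATEGORIES:
        for i in range(n_per_class):
            sub = int(np.random.default_rng(
                np.random.SeedSequence([seed, CATEGORIES.index(cat), i])
            ).integers(0, 2**31 - 1))
            spec = FrameSpec(cat, width=size, height=size, seed=sub)
            images.append(generate_frame(spec))
            labels.append(cat)
    order = np.random.default_rng(seed).permutation(len(images))
    images = np.stack(images)[order]
    labels = [labels[i] for i in order]
    return FrameSet(images, labels)


def generate_blob_embeddings(spec: BlobSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw points from isotropic Gaussians at centers pairwise ``separation`` apart.

    Centers sit on scaled canonical basis vectors (a regular simplex), so every
    pair of centers is exactly ``separation`` apart when ``dim >= n_clusters``.
    Returns ``(X, labels)`` with ``X`` of shape (n_clusters*n_per_cluster, dim).
    """
    rng = np.random.default_rng(spec.seed)
    k, n, d = spec.n_clusters, spec.n_per_cluster, spec.dim
    centers = np.zeros((k, d))
    scale = spec.separation / np.sqrt(2.0)
    for i in range(k):
        centers[i, i % d] += scale * (1 + i // d)  # exact simplex when k <= d
    X = np.concatenate(
        [centers[i] + spec.noise_sd * rng.standard_normal((n, d)) for i in range(k)]
    )
    labels = np.repeat(np.arange(k), n)
    return X, labels
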