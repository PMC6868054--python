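"""Desk-scale binary image data with the structure of reduced, binarized digits.

The hierarchical experiments use 12x12 binary images (144 visible units).
Because the original reduced image datasets require external downloads, this
module generates synthetic stand-ins: per class a fixed random balanced
prototype, with samples drawn by independent pixel flips.  Utilities to
nearest-neighbor-reduce and median-binarize user-supplied 28x28 grayscale
images, and to occlude images for pattern-completion experiments, are
included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageDataset",
    "OcclusionMask",
    "make_synthetic_dataset",
    "reduce_and_binarize",
    "occlude",
    "IMAGE_SIDE",
    "N_PIXELS",
]

IMAGE_SIDE = 12
N_PIXELS = IMAGE_SIDE * IMAGE_SIDE
_MIN_PROTO_DIST = 20  # pixels, minimum pairwise prototype Hamming distance


@dataclass
class ImageDataset:
    """Binary images (rows of length 144), labels, and train/test split tags."""

    images: np.ndarray
    labels: np.ndarray
    split: np.ndarray  # "train" / "test" per row
    n_classes: int
    prototypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.split = np.asarray(self.split)
        if self.images.ndim != 2 or self.images.shape[1] != N_PIXELS:
            raise ValueError(f"images must be rows of length {N_PIXELS}")
        if not np.isin(self.images, (0, 1)).all():
            raise ValueError("pixel values must be 0/1")
        if self.labels.max(initial=-1) >= self.n_classes:
            raise ValueError("label out of range")

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.split == split
        return self.images[m], self.labels[m]

    @property
    def n_images(self) -> int:
        return int(self.images.shape[0])


@dataclass
class OcclusionMask:
    """Boolean mask of occluded pixels (True = no input), with its scheme tag."""

    mask: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (N_PIXELS,):
            raise ValueError(f"mask must have length {N_PIXELS}")
        if self.scheme not in ("salt&pepper", "patch"):
            raise ValueError("scheme must be 'salt&pepper' or 'patch'")


def _draw_prototypes(n_classes: int, rng: np.random.Generator) -> np.ndarray:
    """Balanced random prototypes with pairwise Hamming distance >= 20."""
    for _attempt in range(1000):
        protos = np.zeros((n_classes, N_PIXELS), dtype=np.uint8)
        for c in range(n_classes):
            on = rng.choice(N_PIXELS, size=N_PIXELS // 2, replace=False)
            protos[c, on] = 1
        dists = [
            int(np.sum(protos[a] != protos[b]))
            for a in range(n_classes) for b in range(a + 1, n_classes)
        ]
        if not dists or min(dists) >= _MIN_PROTO_DIST:
            return protos
    raise RuntimeError("could not draw sufficiently distinct prototypes")


def make_synthetic_dataset(n_classes: int = 3, per_class: int = 100,
                           flip_prob: float = 0.05, seed: int = 0,
                           test_fraction: float = 0.2) -> ImageDataset:
    """Prototype-plus-pixel-flip dataset of 12x12 binary images.

    Each class has a fixed, balanced (half on) random prototype; samples are
    the prototype with i.i.d. pixel flips at ``flip_prob``.  Reproducible
    from (parameters, seed).
    """
    if n_classes < 2:
        raise ValueError("need at least two classes")
    if not 0 <= flip_prob < 0.5:
        raise ValueError("flip_prob must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    protos = _draw_prototypes(n_classes, rng)
    images = np.repeat(protos, per_class, axis=0)
    labels = np.repeat(np.arange(n_classes), per_class)
    flips = rng.random(images.shape) < flip_prob
    images = np.where(flips, 1 - images, images).astype(np.uint8)
    n = images.shape[0]
    order = rng.permutation(n)
    images, labels = images[order], labels[order]
    n_test = int(round(test_fraction * n))
    split = np.array(["test"] * n_test + ["train"] * (n - n_test))
    return ImageDataset(images=images, labels=labels, split=split,
                        n_classes=n_classes, prototypes=protos)


def reduce_and_binarize(gray: np.ndarray, side: int = IMAGE_SIDE) -> np.ndarray:
    """Nearest-neighbor reduce a square grayscale image and median-binarize.

    Output pixel j maps to input index floor((j + 0.5) * n_in / n_out) per
    axis; a pixel becomes 1 iff its gray value strictly exceeds the
    per-image median (so a constant image maps to all zeros).
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2 or gray.shape[0] != gray.shape[1]:
        raise ValueError("input must be a square grayscale image")
    n_in = gray.shape[0]
    idx = np.floor((np.arange(side) + 0.5) * n_in / side).astype(int)
    small = gray[np.ix_(idx, idx)]
    return (small > np.median(small)).astype(np.uint8).ravel()


def occlude(image: np.ndarray, scheme: str = "salt&pepper",
            fraction: float = 0.25, seed: int = 0
            ) -> tuple[np.ndarray, OcclusionMask]:
    """Mark a fraction of pixels as receiving no input.

    salt&pepper draws a uniform pixel subset without replacement; patch
    places a contiguous rectangle of the nearest realizable shape at a
    seeded random position.  Occluded pixels are tagged, not flipped: the
    returned image equals the input.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    image = np.asarray(image, dtype=np.uint8)
    if image.shape != (N_PIXELS,):
        raise ValueError(f"image must have length {N_PIXELS}")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * N_PIXELS))
    mask = np.zeros(N_PIXELS, dtype=bool)
    if scheme == "salt&pepper":
        mask[rng.choice(N_PIXELS, size=k, replace=False)] = True
    elif scheme == "patch":
        # nearest realizable rectangle to k pixels (square-ish)
        best = None
        for h in range(1, IMAGE_SIDE + 1):
            w = max(1, min(IMAGE_SIDE, int(round(k / h))))
            err = abs(h * w - k) + 0.01 * abs(h - w)
            if best is None or err < best[0]:
                best = (err, h, w)
        _, h, w = best
        r0 = rng.integers(0, IMAGE_SIDE - h + 1)
        c0 = rng.integers(0, IMAGE_SIDE - w + 1)
        m2 = mask.reshape(IMAGE_SIDE, IMAGE_SIDE)
        m2[r0:r0 + h, c0:c0 + w] = True
    else:
        raise ValueError("scheme must be 'salt&pepper' or 'patch'")
    return image.copy(), OcclusionMask(mask=mask, scheme=scheme)
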