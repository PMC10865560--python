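"""Peri-sinus probabilistic atlas, patch sampling, and prediction stitching.

The atlas is the voxel-wise mean of aligned binary delineations; training
patches are drawn with probability proportional to atlas value so that
the networks see the peri-sinus region rather than empty background.
At prediction time a sliding patch grid with 50% overlap covers the
atlas bounding box (dilated by a safety margin) and the per-patch softmax
outputs are averaged where patches overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import PATCH_SHAPE, LabelMap, Patch, Volume3D

__all__ = [
    "ProbAtlas",
    "build_atlas",
    "sample_patch_centers",
    "extract_patch",
    "insert_patch",
    "stitch_predictions",
    "inference_patch_origins",
]


class DegenerateAtlasError(ValueError):
    pass


@dataclass
class ProbAtlas:
    """Mean of binary peri-sinus delineations in template space."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    n_sources: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("atlas values must lie in [0, 1]")

    @property
    def shape(self):
        return self.data.shape


def build_atlas(masks: list[LabelMap]) -> ProbAtlas:
    """Voxel-wise arithmetic mean of binary masks on a common grid."""
    if not masks:
        raise ValueError("build_atlas needs at least one mask")
    ref = masks[0]
    acc = np.zeros(ref.shape, dtype=np.float64)
    for m in masks:
        if not ref.same_grid(m):
            raise ValueError("all masks must share one grid")
        acc += (np.asarray(m.data) > 0)
    return ProbAtlas(acc / len(masks), ref.spacing, ref.affine.copy(), len(masks))


def sample_patch_centers(atlas: ProbAtlas, n: int, seed: int) -> list[tuple[int, int, int]]:
    """Draw ``n`` voxel centers with probability proportional to atlas value."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = atlas.data.ravel()
    total = p.sum()
    if total <= 0:
        raise DegenerateAtlasError("atlas is identically zero")
    rng = np.random.default_rng(seed)
    flat = rng.choice(p.size, size=n, p=p / total)
    return [tuple(int(i) for i in np.unravel_index(f, atlas.shape)) for f in flat]


def extract_patch(v, center, shape: tuple[int, int, int] = PATCH_SHAPE) -> Patch:
    """Extract a fixed-shape patch centred at ``center``; zero-pad outside.

    ``v`` may be a Volume3D/LabelMap or a bare 3-D array.
    """
    data = np.asarray(v.data if hasattr(v, "data") else v)
    center = tuple(int(c) for c in center)
    for c, dim in zip(center, data.shape):
        if not (0 <= c < dim):
            raise ValueError(f"center {center} outside grid {data.shape}")
    origin = tuple(c - s // 2 for c, s in zip(center, shape))
    out = np.zeros(shape, dtype=data.dtype)
    pad_mask = np.ones(shape, dtype=bool)
    src, dst = [], []
    for o, s, dim in zip(origin, shape, data.shape):
        lo, hi = max(o, 0), min(o + s, dim)
        src.append(slice(lo, hi))
        dst.append(slice(lo - o, hi - o))
    out[tuple(dst)] = data[tuple(src)]
    pad_mask[tuple(dst)] = False
    return Patch(out, origin, pad_mask)


def insert_patch(target: np.ndarray, patch_data: np.ndarray, origin) -> None:
    """Write the in-bounds part of a patch into ``target`` (inverse of extract)."""
    for_shape = patch_data.shape[:3]
    src, dst = [], []
    for o, s, dim in zip(origin, for_shape, target.shape):
        lo, hi = max(o, 0), min(o + s, dim)
        if lo >= hi:
            return
        dst.append(slice(lo, hi))
        src.append(slice(lo - o, hi - o))
    target[tuple(dst)] = patch_data[tuple(src)]


def stitch_predictions(patches, grid_shape, n_classes: int | None = None) -> np.ndarray:
    """Average overlapping per-class probability patches onto a full grid.

    ``patches`` is a sequence of ``(probs, origin)`` with channels-last
    probabilities of shape ``spatial + (n_classes,)``.  Voxels covered by
    no patch receive background probability 1.  The result sums to 1 at
    every voxel.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("no patches to stitch")
    counts = {p[0].shape[-1] for p in patches}
    if len(counts) != 1:
        raise ValueError("patches disagree on class count")
    k = counts.pop()
    if n_classes is not None and k != n_classes:
        raise ValueError(f"expected {n_classes} classes, got {k}")
    acc = np.zeros(tuple(grid_shape) + (k,), dtype=np.float64)
    cov = np.zeros(grid_shape, dtype=np.float64)
    for probs, origin in patches:
        sp = probs.shape[:3]
        src, dst = [], []
        ok = True
        for o, s, dim in zip(origin, sp, grid_shape):
            lo, hi = max(o, 0), min(o + s, dim)
            if lo >= hi:
                ok = False
                break
            dst.append(slice(lo, hi))
            src.append(slice(lo - o, hi - o))
        if not ok:
            continue
        acc[tuple(dst)] += probs[tuple(src)]
        cov[tuple(dst)] += 1.0
    covered = cov > 0
    acc[covered] /= cov[covered][..., None]
    acc[~covered, 0] = 1.0
    return acc


def inference_patch_origins(region_mask: np.ndarray,
                            patch_shape: tuple[int, int, int] = PATCH_SHAPE,
                            overlap: float = 0.5,
                            dilate: int = 8) -> list[tuple[int, int, int]]:
    """Sliding-grid patch origins covering the positive region of a mask.

    The bounding box of ``region_mask > 0`` is dilated by ``dilate``
    voxels; origins advance by ``patch * (1 - overlap)`` and are clipped
    so that patches stay inside the volume wherever the volume is large
    enough.
    """
    region_mask = np.asarray(region_mask)
    pos = np.argwhere(region_mask > 0)
    if pos.size == 0:
        raise DegenerateAtlasError("inference region is empty")
    lo = np.maximum(pos.min(axis=0) - dilate, 0)
    hi = np.minimum(pos.max(axis=0) + dilate + 1, region_mask.shape)
    strides = [max(int(s * (1 - overlap)), 1) for s in patch_shape]
    axes = []
    for a in range(3):
        start = lo[a]
        stop = max(hi[a] - patch_shape[a], start)
        pts = list(range(start, stop + 1, strides[a]))
        if pts[-1] != stop:
            pts.append(stop)
        max_origin = max(region_mask.shape[a] - patch_shape[a], 0)
        axes.append(sorted({min(max(p, 0), max_origin) for p in pts}))
    return [(i, j, k) for i in axes[0] for j in axes[1] for k in axes[2]]
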