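"""Vessel segmentation, patch protocol, metrics, and centerline tracing.

The default segmenter is classical multiscale Hessian vesselness
(Frangi) tuned for dark tubular structures on brighter tissue, followed
by thresholding and small-object cleanup. A :class:`VesselPredictor`
can replace it with any patch-probability model (e.g. a trained U-net)
via the extract/stitch patch protocol; masks are scored by pixelwise
accuracy, recall and specificity; the mask is thinned to an 8-connected
skeleton and traced into branch-free centerline paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol

import numpy as np
from skimage import morphology

from .geometry import CenterlinePath

__all__ = [
    "SegMetrics",
    "VesselPredictor",
    "enhance_vessels",
    "segment_vessels",
    "extract_patches",
    "stitch_patches",
    "evaluate_segmentation",
    "skeletonize",
    "trace_centerline",
    "extract_centerlines",
]


@dataclass
class SegMetrics:
    """Confusion-matrix scores of a predicted mask against a reference.

    A ratio whose denominator is zero (e.g. recall with no true vessel
    pixels) is reported as None, never as 0.
    """

    accuracy: float | None
    recall: float | None
    specificity: float | None


class VesselPredictor(Protocol):
    """Patch-probability interface for pluggable learned segmenters.

    A conforming model maps an image patch to a same-shape vessel
    probability map in [0, 1]; patches are produced by
    :func:`extract_patches`, predictions merged by
    :func:`stitch_patches` (overlap-averaged), and binarized at 0.5.

    Reference training protocol for a U-net behind this interface:
    256 x 256 patches with overlap, batch size 16, cross-entropy + Dice
    loss, Adam at learning rate 0.001, ~1e4 iterations with 5-fold
    cross-validation. Training such a model is out of scope here.
    """

    def __call__(self, patch: np.ndarray) -> np.ndarray: ...


def enhance_vessels(frame_green: np.ndarray,
                    scales_px=(2.0, 3.0, 5.0, 8.0, 12.0, 18.0, 26.0, 36.0),
                    beta: float = 0.5) -> np.ndarray:
    """Multiscale Hessian vesselness for dark tubular structures.

    Frangi-style filter: at each scale sigma the gamma-normalized
    Hessian eigenvalues (|l1| <= |l2|) score anisotropy
    exp(-(l1/l2)^2 / (2 beta^2)) and structureness
    1 - exp(-S^2 / (2 gamma^2)), S = sqrt(l1^2 + l2^2), keeping only
    dark ridges (l2 > 0). The structureness scale gamma is shared
    across scales (half the strongest S anywhere), so scales that see
    only noise are not amplified to full response the way per-scale
    adaptive normalization would. Output in [0, 1] is the per-pixel
    maximum over ``scales_px``; a constant image maps to all zeros.
    """
    scales = [float(s) for s in scales_px]
    if not scales or any(s <= 0 for s in scales):
        raise ValueError("scales_px must be non-empty and positive")
    img = np.asarray(frame_green, dtype=float)
    if img.std() == 0:
        return np.zeros_like(img)

    from skimage.feature import hessian_matrix, hessian_matrix_eigvals

    per_scale = []
    s_max = 0.0
    for s in scales:
        H = hessian_matrix(img, sigma=s, mode="reflect",
                           use_gaussian_derivatives=True)
        l2, l1 = hessian_matrix_eigvals(H)  # l2 >= l1 by value
        # gamma-normalize and order by magnitude
        l1, l2 = l1 * s ** 2, l2 * s ** 2
        swap = np.abs(l1) > np.abs(l2)
        l1, l2 = np.where(swap, l2, l1), np.where(swap, l1, l2)
        strength = np.hypot(l1, l2)
        per_scale.append((l1, l2, strength))
        s_max = max(s_max, float(strength.max()))
    if s_max == 0:
        return np.zeros_like(img)
    gamma = 0.5 * s_max

    resp = np.zeros_like(img)
    for l1, l2, strength in per_scale:
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
        v = np.exp(-rb2 / (2 * beta ** 2)) * (1.0 - np.exp(-strength ** 2
                                                           / (2 * gamma ** 2)))
        v[l2 <= 0] = 0.0  # dark vessels only: dip has positive curvature
        np.maximum(resp, v, out=resp)
    return np.clip(resp, 0.0, 1.0)


def segment_vessels(enhancement: np.ndarray, threshold: float = 0.28,
                    min_object_px: int = 64) -> np.ndarray:
    """Binarize a vesselness/probability image and clean small artifacts."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    mask = np.asarray(enhancement, dtype=float) >= threshold
    if min_object_px > 1:
        # strictly-below-threshold semantics: keep objects of exactly
        # min_object_px pixels
        mask = morphology.remove_small_objects(mask, max_size=min_object_px - 1)
        mask = morphology.remove_small_holes(mask, max_size=min_object_px - 1)
    return mask


def extract_patches(image: np.ndarray, patch_px: int, stride_px: int) -> list:
    """Tile an image into overlapping patches covering every pixel.

    Origins advance by ``stride_px``; the final patch along each axis is
    anchored to the image border so coverage is complete. Returns a list
    of (patch, (oy, ox)).
    """
    h, w = image.shape[:2]
    if patch_px > min(h, w):
        raise ValueError("patch_px must not exceed the image")
    if not (1 <= stride_px <= patch_px):
        raise ValueError("stride must satisfy 1 <= stride <= patch size")

    def _origins(dim: int) -> list:
        o = list(range(0, dim - patch_px + 1, stride_px))
        if o[-1] + patch_px < dim:
            o.append(dim - patch_px)
        return o

    return [(image[oy:oy + patch_px, ox:ox + patch_px], (oy, ox))
            for oy in _origins(h) for ox in _origins(w)]


def stitch_patches(patches_with_origins, out_shape: tuple) -> np.ndarray:
    """Reassemble patches by per-pixel arithmetic mean over overlaps."""
    acc = np.zeros(out_shape, dtype=np.float64)
    cnt = np.zeros(out_shape, dtype=np.int64)
    for patch, (oy, ox) in patches_with_origins:
        ph, pw = patch.shape[:2]
        acc[oy:oy + ph, ox:ox + pw] += patch
        cnt[oy:oy + ph, ox:ox + pw] += 1
    if np.any(cnt == 0):
        raise ValueError("stitch leaves uncovered pixels")
    return acc / cnt


def evaluate_segmentation(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Pixelwise accuracy, recall (sensitivity) and specificity."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = int(np.sum(pred & truth))
    tn = int(np.sum(~pred & ~truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    total = tp + tn + fp + fn

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return SegMetrics(accuracy=ratio(tp + tn, total),
                      recall=ratio(tp, tp + fn),
                      specificity=ratio(tn, tn + fp))


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to a 1-px-wide, 8-connected medial skeleton."""
    return morphology.skeletonize(np.asarray(mask).astype(bool))


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbors(skel: np.ndarray, y: int, x: int) -> list:
    h, w = skel.shape
    return [(y + dy, x + dx) for dy, dx in _NBRS
            if 0 <= y + dy < h and 0 <= x + dx < w and skel[y + dy, x + dx]]


def _degree_map(skel: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    kernel = np.ones((3, 3), dtype=int)
    kernel[1, 1] = 0
    deg = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    deg[~skel.astype(bool)] = 0
    return deg


def trace_centerline(skeleton: np.ndarray, endpoint: tuple,
                     smooth_window: int = 5) -> CenterlinePath:
    """Walk a skeleton from an endpoint to the next endpoint or branch.

    ``endpoint`` must be a skeleton pixel of degree 1. The walk stops at
    a pixel of degree >= 3 (branch point) or degree 1 (the other end);
    closed loops are rejected.
    """
    skel = np.asarray(skeleton).astype(bool)
    y, x = endpoint
    if not skel[y, x]:
        raise ValueError("endpoint is not a skeleton pixel")
    deg = _degree_map(skel)
    if deg[y, x] != 1:
        raise ValueError(f"endpoint must have degree 1, got {deg[y, x]}")
    path = [(y, x)]
    prev = None
    cur = (y, x)
    while True:
        nbrs = [p for p in _neighbors(skel, *cur) if p != prev]
        if prev is not None:
            # avoid stepping back diagonally onto a pixel 8-adjacent to prev
            nbrs = [p for p in nbrs if p not in path[-2:]]
        if not nbrs:
            break
        nxt = nbrs[0]
        if len(nbrs) > 1:
            # prefer 4-connected continuation for a unique walk
            four = [p for p in nbrs
                    if abs(p[0] - cur[0]) + abs(p[1] - cur[1]) == 1]
            nxt = four[0] if four else nbrs[0]
        if nxt in path:
            raise ValueError("loop not supported")
        path.append(nxt)
        if deg[nxt] != 2:
            break
        prev, cur = cur, nxt
    if len(path) < 2:
        raise ValueError("degenerate skeleton segment")
    return CenterlinePath(np.asarray(path, dtype=float),
                          smooth_window=smooth_window)


def extract_centerlines(skeleton: np.ndarray, min_length_px: float = 10.0,
                        smooth_window: int = 5) -> list:
    """Trace every branch-free segment reachable from an endpoint.

    Segments shorter than ``min_length_px`` of arc are dropped. Pure
    cycles (no endpoints) are not traced.
    """
    skel = np.asarray(skeleton).astype(bool)
    deg = _degree_map(skel)
    endpoints = [tuple(p) for p in np.argwhere(deg == 1)]
    paths, seen = [], set()
    for ep in endpoints:
        if ep in seen:
            continue
        try:
            path = trace_centerline(skel, ep, smooth_window=smooth_window)
        except ValueError:
            continue
        start = tuple(int(v) for v in path.points[0])
        end = tuple(int(v) for v in path.points[-1])
        seen.update({start, end})
        if path.length >= min_length_px:
            paths.append(path)
    return paths
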