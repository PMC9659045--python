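"""Low-rank + sparse video decomposition by principal component pursuit.

Stacking each registered frame as a column of a matrix D, the static
scene (tissue and vessel walls) is well approximated by a low-rank
component L, while the few moving red blood cells (and residual motion)
land in a sparse component S. The decomposition solves

    min ||L||_* + lambda * ||S||_1   s.t.  D = L + S

by the inexact augmented-Lagrangian method: alternating singular-value
thresholding for L and elementwise soft thresholding for S, with an
increasing penalty. lambda defaults to 1/sqrt(max(m, n)), the standard
choice under which exact recovery of incoherent low-rank plus sparse
models is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ImageSequence

__all__ = [
    "VideoMatrix",
    "RPCAResult",
    "video_to_matrix",
    "matrix_to_video",
    "rpca_decompose",
    "sparse_video",
]


@dataclass
class VideoMatrix:
    """Flattened video: one column per frame, row-major pixel order."""

    D: np.ndarray
    frame_shape: tuple
    pixel_size_um: float
    frame_interval_s: float
    crop_box: tuple | None = None  # (y, x, h, w) within the source frame

    def __post_init__(self) -> None:
        if self.D.ndim != 2:
            raise ValueError("D must be 2-D (pixels x frames)")
        if self.D.shape[0] != int(np.prod(self.frame_shape)):
            raise ValueError("frame_shape inconsistent with D")


@dataclass
class RPCAResult:
    """Outcome of principal component pursuit on a video matrix."""

    L: np.ndarray
    S: np.ndarray
    lam: float
    iterations: int
    converged: bool
    residual: float
    residual_history: list = field(default_factory=list)
    meta: VideoMatrix | None = None


def video_to_matrix(seq, crop_box: tuple | None = None) -> VideoMatrix:
    """Flatten the green channel of a (corrected) sequence into columns.

    ``seq`` may be an ImageSequence or CorrectedSequence (anything with
    ``green()`` and calibration attributes).
    """
    frames = seq.green()  # (T, H, W) float
    T, H, W = frames.shape
    if crop_box is not None:
        y, x, h, w = (int(v) for v in crop_box)
        if y < 0 or x < 0 or y + h > H or x + w > W or h <= 0 or w <= 0:
            raise ValueError("crop_box must lie inside the frame")
        frames = frames[:, y:y + h, x:x + w]
    else:
        h, w = H, W
    D = frames.reshape(T, h * w).T.astype(np.float64)
    return VideoMatrix(D=D, frame_shape=(h, w),
                       pixel_size_um=seq.pixel_size_um,
                       frame_interval_s=seq.frame_interval_s,
                       crop_box=crop_box)


def matrix_to_video(M: np.ndarray, meta: VideoMatrix) -> np.ndarray:
    """Inverse of :func:`video_to_matrix`: (T, h, w) frame stack."""
    h, w = meta.frame_shape
    return M.T.reshape(-1, h, w)


def _soft(x: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def rpca_decompose(D, lam: float | None = None, tol: float = 1e-7,
                   max_iter: int = 500) -> RPCAResult:
    """Inexact-ALM principal component pursuit.

    Parameters
    ----------
    D
        VideoMatrix or plain 2-D array.
    lam
        Sparsity weight; None selects 1/sqrt(max(m, n)).
    tol
        Convergence threshold on ||D - L - S||_F / ||D||_F.
    """
    meta = D if isinstance(D, VideoMatrix) else None
    A = D.D if isinstance(D, VideoMatrix) else np.asarray(D, dtype=np.float64)
    if not np.all(np.isfinite(A)):
        raise ValueError("non-finite entries in input matrix")
    if tol <= 0:
        raise ValueError("tol must be positive")
    m, n = A.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(m, n))
    if lam <= 0:
        raise ValueError("lambda must be positive")

    norm_f = np.linalg.norm(A)
    if norm_f == 0:
        return RPCAResult(L=np.zeros_like(A), S=np.zeros_like(A), lam=lam,
                          iterations=1, converged=True, residual=0.0,
                          residual_history=[0.0], meta=meta)
    norm_2 = np.linalg.norm(A, 2)
    norm_inf = np.abs(A).max() / lam
    dual_norm = max(norm_2, norm_inf)
    Y = A / dual_norm
    mu = 1.25 / norm_2
    mu_max = mu * 1e7
    rho = 1.5

    L = np.zeros_like(A)
    S = np.zeros_like(A)
    history = []
    converged = False
    it = 0
    sv = 10  # predicted rank for the partial SVD
    for it in range(1, max_iter + 1):
        S = _soft(A - L + Y / mu, lam / mu)
        U, sig, Vt = _svd_partial(A - S + Y / mu, sv)
        svp = int(np.sum(sig > 1.0 / mu))
        sv = min(svp + 1 if svp < sv else min(svp + round(0.05 * n), n),
                 min(m, n))
        L = (U[:, :svp] * (sig[:svp] - 1.0 / mu)) @ Vt[:svp]
        Z = A - L - S
        Y = Y + mu * Z
        mu = min(mu * rho, mu_max)
        res = np.linalg.norm(Z) / norm_f
        history.append(float(res))
        if res < tol:
            converged = True
            break
    return RPCAResult(L=L, S=S, lam=float(lam), iterations=it,
                      converged=converged, residual=history[-1],
                      residual_history=history, meta=meta)


def _svd_partial(M: np.ndarray, k: int):
    """Top-k SVD: randomized range-finder when k << min(m, n).

    Two power iterations suffice here because video matrices have
    rapidly decaying spectra; the fixed probe seed keeps the whole
    decomposition deterministic. Falls back to a full economy SVD when
    the requested rank is not small.
    """
    m, n = M.shape
    k = max(1, min(k, min(m, n)))
    if k >= min(m, n) // 4 or min(m, n) <= 64:
        return np.linalg.svd(M, full_matrices=False)
    rng = np.random.default_rng(12345)
    p = min(k + 10, min(m, n))
    Q = M @ rng.standard_normal((n, p))
    for _ in range(2):
        Q, _ = np.linalg.qr(M @ (M.T @ Q))
    B = Q.T @ M
    Ub, s, Vt = np.linalg.svd(B, full_matrices=False)
    return Q @ Ub, s, Vt


def sparse_video(result: RPCAResult, allow_partial: bool = False) -> ImageSequence:
    """Reshape |S| to frames, robustly rescaled to [0, 1].

    The absolute value treats both polarities of the sparse component
    as moving-particle signal; intensities are divided by the 99.5th
    percentile of |S| (saturation-resistant) and clipped.
    """
    if result.meta is None:
        raise ValueError("result carries no video metadata")
    if not result.converged and not allow_partial:
        raise ValueError("decomposition did not converge "
                         "(pass allow_partial=True to use it anyway)")
    frames = np.abs(matrix_to_video(result.S, result.meta))
    scale = np.percentile(frames, 99.5)
    if scale > 0:
        frames = np.clip(frames / scale, 0.0, 1.0)
    return ImageSequence(frames, pixel_size_um=result.meta.pixel_size_um,
                         frame_interval_s=result.meta.frame_interval_s)
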