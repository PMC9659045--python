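"""Centerline geometry: ordered subpixel point chains along a vessel.

A :class:`CenterlinePath` is the 1-D sampling domain for both the
kymograph (space-time image) and the transverse diameter profiles, so it
carries cumulative arc length and per-point unit tangents.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CenterlinePath"]


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """Edge-preserving moving average along axis 0 (window must be odd)."""
    if window <= 1 or len(a) < window:
        return a
    pad = window // 2
    padded = np.pad(a, [(pad, pad)] + [(0, 0)] * (a.ndim - 1), mode="edge")
    kernel = np.ones(window) / window
    out = np.empty_like(a, dtype=float)
    if a.ndim == 1:
        out = np.convolve(padded, kernel, mode="valid")
    else:
        for j in range(a.shape[1]):
            out[:, j] = np.convolve(padded[:, j], kernel, mode="valid")
    return out


@dataclass
class CenterlinePath:
    """Ordered chain of subpixel points (y, x) along one vessel.

    Parameters
    ----------
    points
        (N, 2) array of (row, col) coordinates, ordered along the vessel.
        Consecutive raw points are expected to be <= sqrt(2) px apart
        (8-connected skeleton steps) before any resampling.
    smooth_window
        Odd window of the moving average applied to the coordinates
        before computing tangents; stabilizes normals against the
        staircase pattern of pixel skeletons. 1 disables smoothing.
    """

    points: np.ndarray
    smooth_window: int = 5
    arclength: np.ndarray = field(init=False)
    tangents: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
            raise ValueError("centerline needs an (N>=2, 2) point array")
        self.points = pts
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps <= 0):
            raise ValueError("arc length must be strictly increasing")
        self.arclength = np.concatenate([[0.0], np.cumsum(steps)])
        sm = _moving_average(pts, self.smooth_window)
        grad = np.gradient(sm, axis=0)
        norms = np.linalg.norm(grad, axis=1)
        norms[norms == 0] = 1.0
        self.tangents = grad / norms[:, None]

    @property
    def length(self) -> float:
        """Total arc length in pixels."""
        return float(self.arclength[-1])

    def point_at(self, s) -> np.ndarray:
        """Interpolate (y, x) at arc length(s) ``s`` (clipped to range)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        y = np.interp(s, self.arclength, self.points[:, 0])
        x = np.interp(s, self.arclength, self.points[:, 1])
        return np.stack([y, x], axis=-1)

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent interpolated at arc length(s) ``s``."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        ty = np.interp(s, self.arclength, self.tangents[:, 0])
        tx = np.interp(s, self.arclength, self.tangents[:, 1])
        t = np.stack([ty, tx], axis=-1)
        n = np.linalg.norm(t, axis=-1, keepdims=True)
        n[n == 0] = 1.0
        return t / n

    def resample(self, spacing: float = 1.0) -> "CenterlinePath":
        """Return a copy with points at equal arc-length ``spacing``."""
        n = max(2, int(np.floor(self.length / spacing)) + 1)
        s = np.arange(n) * spacing
        return CenterlinePath(self.point_at(s), smooth_window=self.smooth_window)

    def to_dict(self) -> dict:
        return {"points": self.points.tolist(), "smooth_window": self.smooth_window}

    @classmethod
    def from_dict(cls, d: dict) -> "CenterlinePath":
        return cls(np.asarray(d["points"], dtype=float),
                   smooth_window=int(d.get("smooth_window", 5)))
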