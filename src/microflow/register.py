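"""Body-motion correction by template matching against the first frame.

The animal's breathing and movement shift whole frames rigidly. Each
frame is aligned to the first (target) frame by the integer translation
maximizing normalized cross-correlation of a template region. Integer
shifts keep intensities unresampled; residual sub-pixel motion is small
enough for the sparse/low-rank decomposition downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ImageSequence, translate_frame

__all__ = ["CorrectedSequence", "register_sequence"]


@dataclass
class CorrectedSequence:
    """Registered video plus the per-frame corrections that produced it.

    ``shifts[t] = (dx, dy)`` is the translation applied to frame t to
    align it to frame 0 (so shifts[0] == (0, 0)); ``clipped[t]`` flags
    frames whose best match sat on the search-radius boundary, i.e.
    motion may have exceeded the search range.
    """

    sequence: ImageSequence
    shifts: np.ndarray
    clipped: np.ndarray
    target_index: int = 0

    @property
    def frames(self) -> np.ndarray:
        return self.sequence.frames

    @property
    def pixel_size_um(self) -> float:
        return self.sequence.pixel_size_um

    @property
    def frame_interval_s(self) -> float:
        return self.sequence.frame_interval_s

    def green(self) -> np.ndarray:
        return self.sequence.green()


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-mean normalized cross-correlation of two equal-shape patches."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def register_sequence(seq: ImageSequence, template_box: tuple | None = None,
                      search_radius_px: int = 5) -> CorrectedSequence:
    """Align every frame to the first by integer-shift template matching.

    Parameters
    ----------
    seq
        The calibrated input video; matching runs on the green channel.
    template_box
        (y, x, h, w) region of frame 0 used as the template; None uses
        the full frame inset by the search radius.
    search_radius_px
        Maximum |dx|, |dy| searched. Ties are broken by smallest shift
        magnitude, then smallest dy, then smallest dx; a best match on
        the search boundary is flagged in ``clipped``.
    """
    if search_radius_px < 0:
        raise ValueError("search radius must be >= 0")
    green = seq.green()
    T, H, W = green.shape
    r = search_radius_px
    if template_box is None:
        y, x, h, w = r, r, H - 2 * r, W - 2 * r
    else:
        y, x, h, w = (int(v) for v in template_box)
    if y < 0 or x < 0 or y + h > H or x + w > W or h <= 0 or w <= 0:
        raise ValueError("template_box must lie inside the frame")
    if y - r < 0 or x - r < 0 or y + h + r > H or x + w + r > W:
        raise ValueError("template_box must be inset by the search radius")
    template = green[0, y:y + h, x:x + w]
    if np.ptp(template) == 0:
        raise ValueError("degenerate template: zero variance")

    # candidate shifts ordered by the tie-break rule so the first
    # maximum encountered wins
    cands = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)]
    cands.sort(key=lambda s: (s[0] ** 2 + s[1] ** 2, abs(s[0]), abs(s[1]),
                              s[0], s[1]))

    shifts = np.zeros((T, 2), dtype=int)
    clipped = np.zeros(T, dtype=bool)
    out = np.empty_like(seq.frames)
    out[0] = seq.frames[0]
    for t in range(1, T):
        frame = green[t]
        best_score, best = -np.inf, (0, 0)
        for dy, dx in cands:
            patch = frame[y + dy:y + dy + h, x + dx:x + dx + w]
            score = _ncc(template, patch)
            if score > best_score + 1e-12:
                best_score, best = score, (dy, dx)
        dy, dx = best
        # frame content sits at (+dy, +dx) relative to the target, so
        # the applied correction is the negation
        shifts[t] = (-dx, -dy)
        clipped[t] = max(abs(dy), abs(dx)) >= r > 0
        out[t] = translate_frame(seq.frames[t], -dy, -dx)

    corrected = ImageSequence(out, pixel_size_um=seq.pixel_size_um,
                              frame_interval_s=seq.frame_interval_s)
    return CorrectedSequence(sequence=corrected, shifts=shifts,
                             clipped=clipped, target_index=0)
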