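"""Kymograph construction and Fourier-domain velocimetry.

Moving red blood cells sampled along a vessel centerline form oblique
streaks in the space-time image (kymograph). The streak slope in px/frame
is the flow speed. Rather than fitting individual streaks, the speed is
read off the 2-D Fourier spectrum: the streaks concentrate spectral
energy on a line through the origin orthogonal to them, and the angle
theta' between that dominant line and the temporal-frequency (v) axis
satisfies

    velocity [px/frame] = cot(theta')

which is converted to um/s with the pixel size and frame interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import CenterlinePath
from .io import ImageSequence

__all__ = [
    "Kymograph",
    "SpectrumOrientation",
    "VelocityEstimate",
    "build_kymograph",
    "estimate_orientation",
    "velocity_from_angle",
    "estimate_velocity",
]

#: below this fraction of band energy on the dominant line the estimate
#: is flagged low-confidence
QUALITY_ENERGY_RATIO = 0.02


@dataclass
class Kymograph:
    """Space-time image: row = time (frames), column = distance (px).

    ``image[t, i]`` is the sparse-video intensity at the i-th equal
    arc-length point of the centerline section at frame t0 + t.
    """

    image: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    centerline_id: int | None = None
    t0: int = 0

    def __post_init__(self) -> None:
        img = np.asarray(self.image, dtype=float)
        if img.ndim != 2:
            raise ValueError("kymograph image must be 2-D")
        if img.shape[0] < 8 or img.shape[1] < 8:
            raise ValueError("kymograph needs at least 8 frames and 8 px of path")
        if not (self.pixel_size_um > 0 and self.frame_interval_s > 0):
            raise ValueError("calibration must be positive")
        self.image = img

    @property
    def n_time(self) -> int:
        return self.image.shape[0]

    @property
    def n_space(self) -> int:
        return self.image.shape[1]


@dataclass
class SpectrumOrientation:
    """Dominant spectral line of a kymograph.

    theta_prime_rad is measured from the temporal-frequency (v) axis,
    in (0, pi/2]; direction_sign is +1 when flow runs toward increasing
    arc length, -1 otherwise.
    """

    theta_prime_rad: float
    energy_ratio: float
    band: tuple
    direction_sign: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.theta_prime_rad <= math.pi / 2 + 1e-12):
            raise ValueError("theta' must lie in (0, pi/2]")
        if not (0.0 <= self.energy_ratio <= 1.0):
            raise ValueError("energy_ratio must lie in [0, 1]")


@dataclass
class VelocityEstimate:
    """Flow speed with its spectral diagnostics."""

    velocity_um_s: float
    velocity_px_per_frame: float
    theta_prime_rad: float
    quality: float
    n_frames: int
    direction_sign: int = 1

    @property
    def low_confidence(self) -> bool:
        return self.quality < QUALITY_ENERGY_RATIO


def build_kymograph(sparse_seq: ImageSequence, path: CenterlinePath,
                    t0: int = 0, n_frames: int = 150,
                    section: tuple | None = None,
                    centerline_id: int | None = None) -> Kymograph:
    """Sample the sparse video along a centerline section frame by frame.

    Row t of the result is the bilinear sample of frame ``t0 + t`` at
    points spaced 1 px in arc length along ``section = (s_start, s_end)``
    (default: the whole path).
    """
    frames = sparse_seq.green()
    T = frames.shape[0]
    n_frames = min(n_frames, T - t0)
    if t0 < 0 or n_frames < 8:
        raise ValueError("frame window [t0, t0+n) must lie in the sequence "
                         "and span at least 8 frames")
    s0, s1 = section if section is not None else (0.0, path.length)
    if not (0.0 <= s0 < s1 <= path.length + 1e-9):
        raise ValueError("section must lie within the centerline path")
    if s1 - s0 < 8.0:
        raise ValueError("section shorter than 8 px")
    s = np.arange(s0, s1 + 1e-9, 1.0)
    pts = path.point_at(s)  # (n_space, 2) as (y, x)
    coords = pts.T  # (2, n_space) for map_coordinates
    image = np.empty((n_frames, len(s)))
    for t in range(n_frames):
        image[t] = ndimage.map_coordinates(frames[t0 + t], coords, order=1,
                                           mode="nearest")
    return Kymograph(image, sparse_seq.pixel_size_um,
                     sparse_seq.frame_interval_s,
                     centerline_id=centerline_id, t0=t0)


def _square_crop(img: np.ndarray) -> np.ndarray:
    """Center-crop to N x N with N = min(n_space, n_time).

    Cropping instead of resampling keeps the px/frame scale of the
    streak slope intact.
    """
    n = min(img.shape)
    r0 = (img.shape[0] - n) // 2
    c0 = (img.shape[1] - n) // 2
    return img[r0:r0 + n, c0:c0 + n]


def estimate_orientation(k: Kymograph, band: tuple | None = None,
                         angle_step_deg: float = 0.25,
                         pad_factor: int = 4) -> SpectrumOrientation:
    """Find the dominant line of the 2-D Fourier magnitude spectrum.

    The kymograph is center-cropped to a square, mean-subtracted and
    Hann-windowed (suppressing the axis-aligned cross of edge leakage),
    then zero-padded by ``pad_factor`` for finer spectral sampling. For
    every candidate angle theta' from the v axis, the mean spectral
    magnitude along the line through the origin at that angle is
    accumulated over the radial ``band``; the best angle on the grid is
    refined by parabolic interpolation.
    """
    z = _square_crop(np.asarray(k.image, dtype=float))
    n = z.shape[0]
    z = z - z.mean()
    wy = np.hanning(n)
    z = z * wy[:, None] * wy[None, :]
    p = pad_factor * n
    mag = np.abs(np.fft.fftshift(np.fft.fft2(z, s=(p, p))))
    c = p // 2
    if band is None:
        band = (2.0, 0.45 * n)  # in units of the unpadded frequency grid
    r_min, r_max = band
    if not (0 < r_min < r_max <= n / 2):
        raise ValueError("band must satisfy 0 < r_min < r_max <= N/2")
    radii = np.arange(r_min * pad_factor, r_max * pad_factor, 0.5)
    if len(radii) == 0:
        raise ValueError("no signal: empty radial band")

    # total band energy (annulus), DC excluded by r_min
    yy, xx = np.ogrid[-c:p - c, -c:p - c]
    rr = np.hypot(yy, xx)
    annulus = (rr >= r_min * pad_factor) & (rr <= r_max * pad_factor)
    band_energy = float(mag[annulus].sum())
    if band_energy <= 0:
        raise ValueError("no signal: zero-energy band")

    thetas = np.deg2rad(np.arange(angle_step_deg, 90.0 + 1e-9, angle_step_deg))
    # sample both symmetric halves of each candidate line; the two sign
    # branches correspond to flow direction along the path
    best = None
    scores = {}
    for sign in (+1, -1):
        du = np.sin(thetas)          # column offsets (u axis)
        dv = -sign * np.cos(thetas)  # row offsets (v axis)
        rows = c + radii[None, :] * dv[:, None]
        cols = c + radii[None, :] * du[:, None]
        vals = ndimage.map_coordinates(mag, [rows.ravel(), cols.ravel()],
                                       order=1, mode="constant")
        vals = vals.reshape(len(thetas), len(radii))
        rows2 = c - radii[None, :] * dv[:, None]
        cols2 = c - radii[None, :] * du[:, None]
        vals2 = ndimage.map_coordinates(mag, [rows2.ravel(), cols2.ravel()],
                                        order=1, mode="constant")
        line = vals.mean(axis=1) + vals2.reshape(vals.shape).mean(axis=1)
        scores[sign] = line
        i = int(np.argmax(line))
        if best is None or line[i] > best[2]:
            best = (sign, i, float(line[i]))

    sign, i, peak = best
    line = scores[sign]
    theta = thetas[i]
    if 0 < i < len(thetas) - 1:
        y0, y1, y2 = line[i - 1], line[i], line[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            theta = theta + np.clip(delta, -1, 1) * np.deg2rad(angle_step_deg)
    theta = float(np.clip(theta, 1e-6, math.pi / 2))

    # energy along the refined line (thickness ~ one padded bin each side)
    du, dv = math.sin(theta), -sign * math.cos(theta)
    rows = np.concatenate([c + radii * dv, c - radii * dv])
    cols = np.concatenate([c + radii * du, c - radii * du])
    line_vals = ndimage.map_coordinates(mag, [rows, cols], order=1,
                                        mode="constant")
    line_energy = float(line_vals.sum()) * 0.5 * 2.0  # samples at 0.5 spacing
    energy_ratio = float(np.clip(line_energy / band_energy, 0.0, 1.0))
    return SpectrumOrientation(theta_prime_rad=theta, energy_ratio=energy_ratio,
                               band=(float(r_min), float(r_max)),
                               direction_sign=int(sign))


def velocity_from_angle(o: SpectrumOrientation, pixel_size_um: float,
                        frame_interval_s: float,
                        n_frames: int = 0) -> VelocityEstimate:
    """Convert the dominant-line angle to physical flow speed.

    velocity = cot(theta') px/frame = cot(theta') * pixel_size / interval.
    theta' = pi/2 means stationary; theta' -> 0 is an unresolvable,
    effectively infinite slope.
    """
    if not (pixel_size_um > 0 and frame_interval_s > 0):
        raise ValueError("calibration must be positive")
    th = o.theta_prime_rad
    if th <= 1e-9:
        raise ValueError("unresolvable slope: theta' = 0")
    v_px = math.cos(th) / math.sin(th)
    return VelocityEstimate(
        velocity_um_s=v_px * pixel_size_um / frame_interval_s,
        velocity_px_per_frame=v_px,
        theta_prime_rad=th,
        quality=o.energy_ratio,
        n_frames=n_frames,
        direction_sign=o.direction_sign,
    )


def estimate_velocity(sparse_seq: ImageSequence, path: CenterlinePath,
                      t0: int = 0, n_frames: int = 150,
                      section: tuple | None = None,
                      band: tuple | None = None,
                      angle_step_deg: float = 0.25) -> VelocityEstimate:
    """Full velocimetry chain: kymograph -> spectrum orientation -> speed."""
    k = build_kymograph(sparse_seq, path, t0=t0, n_frames=n_frames,
                        section=section)
    o = estimate_orientation(k, band=band, angle_step_deg=angle_step_deg)
    return velocity_from_angle(o, k.pixel_size_um, k.frame_interval_s,
                               n_frames=k.n_time)
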