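"""Synthetic microcirculation videos, kymographs and cohorts with ground truth.

Every downstream stage is validated against scenes generated here: dark
vessels on brighter tissue (strongest contrast in the green channel,
where hemoglobin absorbs), sparse bright particles advected along the
centerline at a constant per-vessel speed (the red-blood-cell signal),
integer-pixel rigid jitter emulating body motion, saturated specular
blobs, and additive Gaussian noise. Identical specs (including the seed)
produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import CenterlinePath
from .io import ImageSequence, translate_frame
from .kymo import Kymograph

__all__ = [
    "VesselSpec",
    "SceneSpec",
    "GroundTruth",
    "render_scene",
    "render_kymograph",
    "simulate_cohort",
]

#: peak added intensity of a particle splat, on the [0, 1] scale; kept
#: well below the static vessel/tissue contrast — the moving-cell signal
#: in real videos is subtle, which is why a sparse/low-rank separation
#: is needed at all
PARTICLE_PEAK = 0.15


@dataclass
class VesselSpec:
    """One straight or polyline vessel.

    polyline_points are (x, y) pixel coordinates; velocity sign follows
    the polyline direction; rbc_rate is the expected number of particles
    entering the vessel per second.
    """

    polyline_points: list
    width_um: float
    velocity_um_s: float
    rbc_rate: float = 30.0
    contrast: float = 0.5

    def __post_init__(self) -> None:
        if len(self.polyline_points) < 2:
            raise ValueError("vessel polyline needs at least 2 points")
        if not self.width_um > 0:
            raise ValueError("width_um must be positive")
        if self.rbc_rate < 0:
            raise ValueError("rbc_rate must be non-negative")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must lie in (0, 1]")


@dataclass
class SceneSpec:
    """Full description of a synthetic video.

    Defaults emulate the imaging regime the pipeline targets: 0.64 um
    pixels and a frame interval short enough that microcirculatory
    speeds up to ~500 um/s stay below ~8 px/frame, the range where
    kymograph streaks remain well resolved over ~150 frames.
    """

    height_px: int
    width_px: int
    vessels: list
    tissue_level: float = 0.75
    texture_sd: float = 0.05
    noise_sd: float = 0.01
    jitter_px: int = 0
    specular_blobs: int = 0
    pixel_size_um: float = 0.64
    frame_interval_s: float = 0.01
    n_frames: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 8 or self.width_px < 8:
            raise ValueError("frame must be at least 8 x 8 px")
        if not (0 < self.tissue_level <= 1):
            raise ValueError("tissue_level must lie in (0, 1]")
        if (self.noise_sd < 0 or self.texture_sd < 0 or self.jitter_px < 0
                or self.specular_blobs < 0):
            raise ValueError("noise_sd, texture_sd, jitter_px, specular_blobs "
                             "must be >= 0")
        if not (self.pixel_size_um > 0 and self.frame_interval_s > 0):
            raise ValueError("calibration must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class GroundTruth:
    """Everything the renderer knew: the oracle for downstream stages."""

    vessel_mask: np.ndarray                 # bool (H, W), jitter-free geometry
    centerlines: list                       # CenterlinePath per vessel
    velocities_um_s: list
    widths_um: list
    shifts: np.ndarray                      # (n_frames, 2) applied (dx, dy)
    particle_positions: list = field(default_factory=list)
    # particle_positions[t] is an (n_t, 2) array of (y, x) centers in
    # jitter-free scene coordinates


def _vessel_distance_field(shape, path: CenterlinePath) -> np.ndarray:
    """Per-pixel distance to the (densely resampled) centerline."""
    from scipy.spatial import cKDTree

    dense = path.resample(0.25)
    tree = cKDTree(dense.points)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d, _ = tree.query(pts, workers=1)
    return d.reshape(shape)


def render_scene(spec: SceneSpec) -> tuple[ImageSequence, GroundTruth]:
    """Render the video described by ``spec`` together with its truth.

    Frames are RGB uint16. Vessel pixels are darkened relative to tissue
    by ``contrast`` in the green channel (half of it in red/blue);
    particles are isotropic Gaussian bright spots (sigma ~ width/4)
    advected along the centerline at the vessel's constant speed.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # static tissue texture: smooth mottling of the background, shared by
    # all frames (real tissue is never uniform; it also anchors the
    # motion-correction stage the way real texture does)
    tissue = np.full((h, w), spec.tissue_level, dtype=np.float64)
    if spec.texture_sd > 0:
        tex = gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), 1.0)
        sd = tex.std()
        if sd > 0:
            tissue *= 1.0 + tex * (spec.texture_sd / sd)
    base = np.repeat(tissue[:, :, None], 3, axis=2)
    mask = np.zeros((h, w), dtype=bool)
    centerlines, paths_px = [], []
    for v in spec.vessels:
        pts = np.asarray([(y, x) for (x, y) in v.polyline_points], dtype=float)
        if (pts[:, 0].min() < 0 or pts[:, 0].max() > h - 1
                or pts[:, 1].min() < 0 or pts[:, 1].max() > w - 1):
            raise ValueError("vessel polyline exits the frame")
        path = CenterlinePath(pts).resample(1.0)
        centerlines.append(path)
        width_px = v.width_um / spec.pixel_size_um
        dist = _vessel_distance_field((h, w), path)
        mask |= dist <= width_px / 2
        # rounded cross-profile (light traverses more blood near the
        # vessel axis than near the wall); the super-Gaussian is built so
        # the darkening reaches exactly half its peak at the nominal
        # wall, making the profile FWHM equal the nominal width
        fall = np.exp(-np.log(2.0) * (2.0 * dist / width_px) ** 4)
        base[..., 1] *= 1.0 - v.contrast * fall
        base[..., 0] *= 1.0 - 0.5 * v.contrast * fall
        base[..., 2] *= 1.0 - 0.5 * v.contrast * fall
        paths_px.append((path, width_px))

    for _ in range(spec.specular_blobs):
        cy, cx = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
        rad = rng.uniform(2.0, 5.0)
        yy, xx = np.mgrid[0:h, 0:w]
        base[np.hypot(yy - cy, xx - cx) <= rad] = 1.0

    # particle itineraries: spawn time (frames) and entry end per vessel
    particles = []  # (vessel index, spawn_frame, lateral, amplitude)
    for vi, v in enumerate(spec.vessels):
        path, width_px = paths_px[vi]
        v_px = v.velocity_um_s * spec.frame_interval_s / spec.pixel_size_um
        if abs(v_px) > 1e-9:
            transit = path.length / abs(v_px)
            n_exp = v.rbc_rate * spec.frame_interval_s * (spec.n_frames + transit)
            n = int(rng.poisson(n_exp))
            spawn = rng.uniform(-transit, spec.n_frames, size=n)
        else:
            n = int(rng.poisson(v.rbc_rate * spec.frame_interval_s * spec.n_frames))
            spawn = rng.uniform(0, path.length, size=n)  # static arc position
        lateral = rng.uniform(-width_px / 4, width_px / 4, size=n)
        amp = PARTICLE_PEAK * rng.uniform(0.6, 1.0, size=n)
        particles.append((spawn, lateral, amp, v_px, path, width_px))

    shifts = np.zeros((spec.n_frames, 2), dtype=int)
    if spec.jitter_px > 0 and spec.n_frames > 1:
        shifts[1:] = rng.integers(-spec.jitter_px, spec.jitter_px + 1,
                                  size=(spec.n_frames - 1, 2))

    frames = np.empty((spec.n_frames, h, w, 3), dtype=np.uint16)
    particle_positions = []
    for t in range(spec.n_frames):
        img = base.copy()
        centers = []
        for spawn, lateral, amp, v_px, path, width_px in particles:
            if abs(v_px) > 1e-9:
                s = (t - spawn) * v_px
                if v_px < 0:
                    s = path.length + s
            else:
                s = spawn
            vis = (s >= 0) & (s <= path.length)
            if not np.any(vis):
                continue
            sv = s[vis]
            pts = path.point_at(sv)
            tans = path.tangent_at(sv)
            normals = np.column_stack([tans[:, 1], -tans[:, 0]])
            ctrs = pts + lateral[vis, None] * normals
            sigma = max(1.0, width_px / 4)
            _splat(img, ctrs, amp[vis], sigma)
            centers.append(ctrs)
        particle_positions.append(
            np.concatenate(centers) if centers else np.empty((0, 2)))
        img = np.clip(img, 0.0, 1.0)
        dx, dy = shifts[t]
        img = translate_frame(img, int(dy), int(dx))
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
            img = np.clip(img, 0.0, 1.0)
        frames[t] = np.round(img * 65535.0).astype(np.uint16)

    seq = ImageSequence(frames, pixel_size_um=spec.pixel_size_um,
                        frame_interval_s=spec.frame_interval_s)
    truth = GroundTruth(vessel_mask=mask, centerlines=centerlines,
                        velocities_um_s=[v.velocity_um_s for v in spec.vessels],
                        widths_um=[v.width_um for v in spec.vessels],
                        shifts=shifts, particle_positions=particle_positions)
    return seq, truth


def _splat(img: np.ndarray, centers: np.ndarray, amps: np.ndarray,
           sigma: float) -> None:
    """Add Gaussian bright spots to an RGB float image in place."""
    h, w = img.shape[:2]
    r = int(np.ceil(3 * sigma))
    for (cy, cx), a in zip(centers, amps):
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        y0c, y1c = max(y0, 0), min(y1, h)
        x0c, x1c = max(x0, 0), min(x1, w)
        if y0c >= y1c or x0c >= x1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        g = a * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        img[y0c:y1c, x0c:x1c, 1] += g
        img[y0c:y1c, x0c:x1c, 0] += 0.5 * g
        img[y0c:y1c, x0c:x1c, 2] += 0.5 * g


def render_kymograph(velocity_px_per_frame: float, n_space: int = 150,
                     n_time: int = 150, streak_width_px: float = 1.5,
                     streak_rate: float = 0.15, noise_sd: float = 0.05,
                     seed: int = 0) -> Kymograph:
    """Directly synthesize a kymograph with streaks of known slope.

    Each streak is a Gaussian ridge along the line l = c + v*t, so its
    slope in the (distance, time) image is exactly
    ``velocity_px_per_frame``. Calibration is set to 1 um/px and 1 s per
    frame so estimated velocities read directly in px/frame.
    """
    if n_space < 8 or n_time < 8:
        raise ValueError("kymograph needs n_space, n_time >= 8")
    rng = np.random.default_rng(seed)
    v = float(velocity_px_per_frame)
    n = max(3, int(rng.poisson(streak_rate * n_time)))
    lo = min(0.0, -v * n_time) - 2 * streak_width_px
    hi = n_space + max(0.0, -v * n_time) + 2 * streak_width_px
    c = rng.uniform(lo, hi, size=n)
    a = rng.uniform(0.5, 1.0, size=n)
    tt = np.arange(n_time)[:, None]
    ll = np.arange(n_space)[None, :]
    img = np.zeros((n_time, n_space))
    for cj, aj in zip(c, a):
        img += aj * np.exp(-((ll - cj - v * tt) ** 2)
                           / (2 * streak_width_px ** 2))
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return Kymograph(img, pixel_size_um=1.0, frame_interval_s=1.0)


def simulate_cohort(group_effects: dict, n_rats: int = 5,
                    timepoints=None, noise_sd: float = 0.0,
                    seed: int = 0, quantity: str = "velocity_um_s") -> pd.DataFrame:
    """Longitudinal per-subject measurements following per-group trends.

    ``group_effects`` maps group name -> sequence of true means, one per
    timepoint. Each subject's value is the group mean plus i.i.d.
    Gaussian noise. Emulates a design of a few small groups measured at
    a shared grid of timepoints (e.g. every 2 h relative to surgery).
    """
    if timepoints is None or len(timepoints) == 0:
        raise ValueError("timepoints must be a non-empty list")
    if n_rats < 2:
        raise ValueError("need at least 2 subjects per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group, trend in group_effects.items():
        trend = np.asarray(trend, dtype=float)
        if len(trend) != len(timepoints):
            raise ValueError(f"trend for {group!r} must match timepoints")
        for rat in range(n_rats):
            noise = rng.normal(0.0, noise_sd, size=len(trend)) if noise_sd > 0 \
                else np.zeros(len(trend))
            for tp, mu, eps in zip(timepoints, trend, noise):
                rows.append({"group": group, "subject_id": f"{group}_{rat}",
                             "timepoint_h": tp, "quantity": quantity,
                             "value": mu + eps})
    return pd.DataFrame(rows)
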