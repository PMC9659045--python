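"""Shared synthetic fixtures.

Everything is generated at test time from seeded scene specs; session
scope keeps the expensive renders and decompositions to one per run.
"""

import pytest

from microflow.register import register_sequence
from microflow.rpca import rpca_decompose, video_to_matrix
from microflow.synth import SceneSpec, VesselSpec, render_scene


def two_vessel_spec(seed: int = 0, noise_sd: float = 0.0, jitter_px: int = 3) -> SceneSpec:
    """Field-of-view-like scene: two oblique vessels in a mostly-tissue frame."""
    return SceneSpec(
        height_px=96, width_px=200, texture_sd=0.05,
        vessels=[
            VesselSpec(polyline_points=[(8, 20), (190, 40)], width_um=10.0,
                       velocity_um_s=150.0, rbc_rate=20.0),
            VesselSpec(polyline_points=[(30, 88), (180, 62)], width_um=8.0,
                       velocity_um_s=-100.0, rbc_rate=15.0),
        ],
        noise_sd=noise_sd, jitter_px=jitter_px, specular_blobs=2, seed=seed)


def single_vessel_spec(width_um: float = 12.0, velocity_um_s: float = 150.0,
                       seed: int = 5, **kw) -> SceneSpec:
    defaults = dict(height_px=64, width_px=200, noise_sd=0.01, jitter_px=2,
                    specular_blobs=1)
    defaults.update(kw)
    return SceneSpec(
        vessels=[VesselSpec(polyline_points=[(10, 22), (190, 40)],
                            width_um=width_um, velocity_um_s=velocity_um_s,
                            rbc_rate=15.0)],
        seed=seed, **defaults)


@pytest.fixture(scope="session")
def jittered_scene():
    """Noise-free jittered scene plus its ground truth."""
    spec = two_vessel_spec(seed=1)
    seq, truth = render_scene(spec)
    return spec, seq, truth


@pytest.fixture(scope="session")
def capillary_rpca():
    """Registered + RPCA-decomposed capillary scene (shared, it is slow)."""
    spec = single_vessel_spec(width_um=6.4, velocity_um_s=150.0, seed=5)
    seq, truth = render_scene(spec)
    corr = register_sequence(seq, search_radius_px=3)
    margin = 4
    crop = (margin, margin, spec.height_px - 2 * margin,
            spec.width_px - 2 * margin)
    result = rpca_decompose(video_to_matrix(corr, crop_box=crop))
    return spec, truth, corr, result, margin
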