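"""Shared fixtures: small phantoms generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mmoct import phantom

PITCH_AIR = 1.7 / 256  # mm/px, instrument default
N_TISSUE = 1.4
DZ_TISSUE = PITCH_AIR / N_TISSUE


@pytest.fixture(scope="session")
def uniform_speckled_stack():
    """Speckled uniform-attenuation stack (mu_co = 2 mm^-1) + ground truth."""
    spec = phantom.uniform_phantom(2.0, 1.0, width_px=256, depth_px=256, seed=11)
    stack, gt = phantom.generate_cpoct_stack(spec)
    return spec, stack, gt


@pytest.fixture(scope="session")
def small_compression_series():
    """Linear 100 kPa tissue under a 100 kPa silicone layer, 4 load steps."""
    spec = phantom.PhantomSpec(
        layers=[phantom.Layer("tissue", 160, 2.0, 1.0, phantom.LinearLaw(100.0))],
        reference_layer=phantom.ReferenceLayer(48, 100.0),
        width_px=48,
        depth_px=224,
        seed=7,
        noise_floor=1e-4,
    )
    series, gt = phantom.generate_compression_series(spec, [0.0, 0.5, 1.0, 1.5, 2.0])
    return spec, series, gt


def noiseless_exponential_stack(mu: float, depth: int = 256, width: int = 4):
    """Deterministic exponential columns (no speckle, no noise)."""
    from mmoct import CPOCTStack

    intensity = np.exp(-2.0 * mu * DZ_TISSUE * np.arange(depth))[:, None]
    img = np.broadcast_to(intensity, (depth, width)).copy()
    return CPOCTStack(co=img, cross=img, axial_pitch_air=PITCH_AIR)
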