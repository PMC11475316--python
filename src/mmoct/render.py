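"""Color-map rendering of quantitative parameter images.

Attenuation maps use a rainbow scale from blue (scale minimum) to red
(scale maximum), clamped to a fixed display range (default 0–12 mm^-1).
Stiffness maps use the *inverted* polarity: stiff areas render blue and
soft areas red, on a 0–600 kPa range.  Invalid pixels render in a
reserved neutral gray so they are never mistaken for in-range values.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from .containers import AttenuationMap, StiffnessMap

INVALID_GRAY = (128, 128, 128)


def _to_rgb(
    values: np.ndarray,
    valid: np.ndarray,
    vmin: float,
    vmax: float,
    invert: bool,
) -> np.ndarray:
    if vmin >= vmax:
        raise ValueError(f"vmin ({vmin}) must be < vmax ({vmax})")
    t = np.clip((np.nan_to_num(values, nan=vmin) - vmin) / (vmax - vmin), 0.0, 1.0)
    if invert:
        t = 1.0 - t
    rgba = colormaps["jet"](t)
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[~valid] = INVALID_GRAY
    return rgb


def render_map(amap: AttenuationMap, vmin: float = 0.0, vmax: float = 12.0) -> np.ndarray:
    """RGB (uint8) rendering of an attenuation map; blue = vmin, red = vmax."""
    return _to_rgb(amap.values, amap.valid_mask, vmin, vmax, invert=False)


def render_stiffness(smap: StiffnessMap, vmin: float = 0.0, vmax: float = 600.0) -> np.ndarray:
    """RGB (uint8) rendering of a stiffness map; blue = stiff, red = soft."""
    return _to_rgb(smap.values, smap.valid_mask, vmin, vmax, invert=True)
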