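"""Depth-resolved attenuation mapping of a phantom with a layer boundary.

A two-layer phantom (4 then 6 mm^-1) is imaged, corrected for the noise
floor, converted to an attenuation map, and the layer interface is
localized from the map itself.  The rendered map uses the 0-12 mm^-1
rainbow scale (blue = low, red = high).
"""

import numpy as np
from matplotlib import image as mpl_image

from mmoct import compensate_signal, estimate_attenuation, generate_cpoct_stack, render_map
from mmoct.attenuation import locate_layer_boundary
from mmoct.phantom import Layer, PhantomSpec

spec = PhantomSpec(
    layers=[Layer("superficial", 112, 4.0, 2.0), Layer("deep", 144, 6.0, 3.0)],
    width_px=1024, depth_px=256, seed=1, noise_floor=1e-5,
)
stack, truth = generate_cpoct_stack(spec)
corrected = compensate_signal(stack, spec.noise_floor)
amap = estimate_attenuation(corrected, "co", energy_fraction=1e-3)

vals = np.where(amap.valid_mask, amap.values, np.nan)
print(f"superficial layer median: {np.nanmedian(vals[:86]):.2f} mm^-1 (truth 4.0)")
print(f"deep layer median:        {np.nanmedian(vals[116:]):.2f} mm^-1 (truth 6.0)")
print(f"boundary localized at row {locate_layer_boundary(amap)} (truth 112)")

mpl_image.imsave("attenuation_map.png", render_map(amap))
print("wrote attenuation_map.png (blue -> red over 0-12 mm^-1, gray = invalid)")
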