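"""Depth-resolved attenuation-coefficient mapping for CP OCT stacks.

The estimator is the single-scattering depth-resolved formulation: with
corrected intensity ``I[i]`` at axial pixel ``i`` and tissue-depth pitch
``Δ`` (mm), every pixel of every A-scan gets

    mu_hat[i] = I[i] / (2 * Δ * Σ_{j>i} I[j])

which on an infinite noiseless exponential column equals the closed form
``(exp(2 μ Δ) − 1) / (2 Δ)`` — i.e. ``μ`` up to the first-order
discretization factor ``1 + μΔ``, negligible at this instrument's pitch.

Two practical corrections are applied before the ratio:

* **Signal compensation** (:func:`compensate_signal`): subtract the
  additive noise floor (clipped at zero, keeping tail sums nonnegative)
  and divide out the depth sensitivity roll-off of the instrument.

* **Tail extension** (default): the tail sum only covers the recorded
  scan, which biases the estimate upward wherever the signal has not
  fully decayed in-scan — at the weakest clinically observed attenuation
  (~1.7 mm^-1) the bias reaches +14% at mid-depth.  The default
  ``tail="extend"`` estimates the deep-tissue decay rate from the lateral
  mean profile and adds the analytic geometric remainder beyond the last
  pixel, which is exact for exponential columns and vanishes when the
  decay completes in-scan.

Per-pixel ratios of speckled intensities are strongly skewed (the median
of an exponential variate is ln 2 of its mean), so quantitative maps are
computed from a lateral boxcar average of the intensity (default width
21 px ≈ 0.1 mm, axial width 1 so layer boundaries stay sharp).  Pass
``smooth=None`` for the raw per-pixel estimator.

Pixels whose remaining tail energy falls below a configurable fraction of
the column total are flagged invalid rather than silently zeroed; the
deepest pixel is always invalid.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .containers import AttenuationMap, CPOCTStack


def compensate_signal(
    stack: CPOCTStack,
    noise_floor: float | str = 0.0,
    sensitivity_profile: np.ndarray | str = "flat",
) -> CPOCTStack:
    """Subtract the additive noise floor and divide out the depth gain.

    ``noise_floor`` is an intensity value or ``"auto"`` (median intensity
    of the deepest 5% of pixels, per lateral position).  Subtraction is
    clipped at zero.  ``sensitivity_profile`` is a per-depth gain (> 0) or
    ``"flat"``.
    """
    depth = stack.shape[0]
    if isinstance(sensitivity_profile, str):
        if sensitivity_profile != "flat":
            raise ValueError("sensitivity_profile must be 'flat' or a per-depth array")
        gain = np.ones(depth)
    else:
        gain = np.asarray(sensitivity_profile, dtype=float)
        if gain.shape != (depth,):
            raise ValueError(f"sensitivity_profile must have shape ({depth},)")
        if np.any(gain <= 0):
            raise ValueError("sensitivity_profile must be > 0 at all depths")

    channels = {}
    n_tail = max(1, int(round(0.05 * depth)))
    for name in ("co", "cross"):
        img = stack.channel(name)
        if noise_floor == "auto":
            floor = np.median(img[-n_tail:, :], axis=0)[None, :]
        else:
            floor = float(noise_floor)
            if floor < 0:
                raise ValueError("noise_floor must be >= 0")
        corrected = np.clip(img - floor, 0.0, None) / gain[:, None]
        if not corrected.any():
            warnings.warn(
                f"channel {name!r}: all-zero image after noise subtraction",
                stacklevel=2,
            )
        channels[name] = corrected

    return CPOCTStack(
        co=channels["co"],
        cross=channels["cross"],
        axial_pitch_air=stack.axial_pitch_air,
        lateral_pitch=stack.lateral_pitch,
        n_tissue=stack.n_tissue,
        wavelength_um=stack.wavelength_um,
        metadata={**stack.metadata, "compensated": True},
    )


def _tail_decay_rate(img: np.ndarray, dz_mm: float, fit_rows: int) -> float:
    """Deep-tissue attenuation (mm^-1) from a log-linear fit of the
    lateral-mean intensity over the deepest ``fit_rows`` rows that still
    carry signal (above 1% of the profile peak), so a clipped-noise
    plateau at the bottom of a strongly attenuated scan cannot flatten
    the fitted slope."""
    profile = img.mean(axis=1)
    above = np.nonzero(profile >= 0.01 * profile.max())[0]
    if above.size < 2:
        return np.inf  # no signal left: nothing beyond the scan either
    hi = above[-1] + 1
    lo = max(0, hi - fit_rows)
    rows = np.arange(lo, hi, dtype=float)
    tail = profile[lo:hi]
    pos = tail > 0
    if pos.sum() < 2:
        return np.inf
    slope = np.polyfit(rows[pos], np.log(tail[pos]), 1)[0]
    mu = -slope / (2.0 * dz_mm)
    return max(mu, 1e-3)


def estimate_attenuation(
    stack: CPOCTStack,
    channel: str = "co",
    *,
    smooth: tuple[int, int] | None = (1, 21),
    tail: str = "extend",
    energy_fraction: float = 0.01,
    tail_fit_rows: int = 48,
) -> AttenuationMap:
    """Depth-resolved attenuation map for one polarization channel.

    Parameters
    ----------
    smooth
        Boxcar (axial, lateral) intensity averaging window in pixels
        applied before the ratio; ``None`` disables smoothing.
    tail
        ``"extend"`` (default) adds the analytic exponential remainder
        beyond the deepest pixel to every tail sum; ``"none"`` uses the
        truncated in-scan sum only.
    energy_fraction
        Pixels whose tail sum is below this fraction of the column's
        total energy are marked invalid (tail-truncation guard).
    """
    if tail not in ("extend", "none"):
        raise ValueError("tail must be 'extend' or 'none'")
    img = stack.channel(channel).astype(float)
    if smooth is not None:
        img = np.clip(ndimage.uniform_filter(img, size=smooth, mode="nearest"), 0.0, None)
    depth = img.shape[0]
    dz = stack.delta_z_mm

    # Exclusive reversed cumulative sum: S[i] = sum_{j>i} I[j].
    tail_sum = np.cumsum(img[::-1], axis=0)[::-1] - img

    if tail == "extend":
        mu_deep = _tail_decay_rate(img, dz, min(tail_fit_rows, max(depth // 4, 2)))
        if np.isfinite(mu_deep):
            r = np.exp(-2.0 * mu_deep * dz)
            tail_sum = tail_sum + img[-1:, :] * (r / (1.0 - r))

    total = tail_sum[0] + img[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        values = img / (2.0 * dz * tail_sum)
    valid = tail_sum > np.maximum(energy_fraction * total, 0.0)[None, :]
    valid &= tail_sum > 0
    valid[-1, :] = False  # deepest pixel: tail is (mostly) extrapolation
    values[~valid] = np.nan

    return AttenuationMap(
        values=np.where(valid, values, np.nan),
        channel=channel,
        valid_mask=valid,
        delta_z_mm=dz,
        metadata={
            "smooth": smooth,
            "tail": tail,
            "energy_fraction": energy_fraction,
            **stack.metadata,
        },
    )


def locate_layer_boundary(
    amap: AttenuationMap,
    smooth_px: int = 11,
    edge_fraction: float = 0.4,
) -> int:
    """Axial row index of the strongest layer interface in a map.

    Works on the lateral-mean attenuation profile over rows where at
    least half the pixels are valid (the deepest 15% of those rows are
    dropped as noise-prone).  Because the depth-resolved estimator
    approaches the *deeper* layer's value smoothly over one extinction
    length above an interface, the gradient of the profile peaks at the
    interface but is smeared leftward by smoothing; the boundary is
    therefore taken as the deep edge of the gradient peak — the last row
    whose gradient still exceeds ``edge_fraction`` of the peak value.
    """
    vals = np.where(amap.valid_mask, amap.values, np.nan)
    frac_valid = amap.valid_mask.mean(axis=1)
    rows = np.nonzero(frac_valid >= 0.5)[0]
    if rows.size < 3 * smooth_px:
        raise ValueError("too few valid rows to localize a boundary")
    rows = rows[: max(1, int(rows.size * 0.85))]
    profile = np.nanmean(vals[rows], axis=1)
    p = ndimage.uniform_filter1d(profile, smooth_px, mode="nearest")
    g = np.gradient(p)
    g[:smooth_px] = 0.0
    g[-smooth_px:] = 0.0
    i = i0 = int(np.argmax(np.abs(g)))
    sign, peak = np.sign(g[i0]), abs(g[i0])
    while i + 1 < g.size and sign * g[i + 1] >= edge_fraction * peak:
        i += 1
    return int(rows[i])


def closed_form_estimate(mu: float, dz_mm: float, n_tail: float = np.inf) -> float:
    """Value the depth-resolved estimator attains on a noiseless
    exponential column with true attenuation ``mu`` (mm^-1).

    For an infinite tail this is ``(exp(2 μ Δ) − 1) / (2 Δ)``; with a
    truncated tail of ``n_tail`` remaining pixels the geometric sum gives
    the additional factor ``1 / (1 − exp(−2 μ Δ n_tail))``.
    """
    x = 2.0 * mu * dz_mm
    base = np.expm1(x) / (2.0 * dz_mm)
    n_tail = np.asarray(n_tail, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(np.isinf(n_tail), 1.0, -np.expm1(-x * n_tail))
        out = base / factor
    return float(out) if out.ndim == 0 else out
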