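"""Compression optical coherence elastography (C-OCE).

Processing chain for phase-sensitive B-scan series acquired under
quasi-static uniaxial compression with a calibrated reference silicone
layer on the sample surface:

1. :func:`interframe_phasor` — per-pixel complex product of consecutive
   frames; its argument is the interframe phase change.
2. :func:`vector_strain` — the "vector" method: axial phase gradient from
   lagged phasor products averaged *as complex numbers* over a window
   before taking the argument, which avoids explicit phase unwrapping and
   yields a phasor-magnitude quality metric in [0, 1].
3. :func:`accumulate` / :func:`estimate_strain_series` — cumulative strain
   per frame (small-strain additivity), quality propagated as the running
   minimum.
4. :func:`stress_from_reference` — applied stress per frame from the
   laterally averaged cumulative strain of the linearly elastic reference
   layer (Hooke's law, stress assumed depth-uniform under the uniaxial
   loading contract).
5. :func:`tangent_modulus` / :func:`stiffness_map` — tissue stiffness as
   the tangent Young's modulus dσ/dε at a pre-chosen applied stress
   (default 1 kPa), from a least-squares line through the stress–strain
   samples inside a ±0.5 kPa window.

Sign convention: compressive strain is positive.  In the common-path
geometry compression shortens the optical path between probe and
scatterer, so the interframe phase *decreases* with compressive strain
and the estimator negates the averaged-phasor argument.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import CompressionSeries, StiffnessMap, StrainField, StressStrainCurve


class StrainWrapError(RuntimeError):
    """Interframe phase exceeded the unwrap-free limit for too many pixels."""


@dataclass
class StrainSlice:
    """Single-transition output of the vector method."""

    strain: np.ndarray
    quality: np.ndarray
    valid: np.ndarray


def interframe_phasor(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Per-pixel product ``frame_b * conj(frame_a)``.

    Its argument is the phase change from ``frame_a`` to ``frame_b``,
    Δφ = −4π·n·Δu/λ for a path shortening Δu.
    """
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ValueError(
            f"frame shape mismatch: {frame_a.shape} vs {frame_b.shape}"
        )
    return frame_b * np.conj(frame_a)


def _complex_boxcar(c: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    re = ndimage.uniform_filter(c.real, size=window, mode="nearest")
    im = ndimage.uniform_filter(c.imag, size=window, mode="nearest")
    return re + 1j * im


def vector_strain(
    phasor: np.ndarray,
    *,
    axial_pitch_air_mm: float,
    wavelength_um: float,
    lag: int = 4,
    window: tuple[int, int] = (8, 8),
    wrap_margin: float = 0.98,
    check_mask: np.ndarray | None = None,
    max_flagged_fraction: float = 0.01,
) -> StrainSlice:
    """Axial strain from one interframe phasor field by the vector method.

    The lagged product ``c(x, z) = b(x, z+lag) * conj(b(x, z))`` is
    averaged complex-wise over ``window`` (axial, lateral) pixels; the
    strain is ``−arg⟨c⟩ · λ / (4π · lag · axial_pitch_air)`` (the tissue
    index cancels between the phase term and the tissue-depth pitch).
    Quality is ``|⟨c⟩| / ⟨|c|⟩``.  Pixels whose averaged-phasor argument
    approaches ±π (``wrap_margin``) are flagged invalid; if more than
    ``max_flagged_fraction`` of the checked pixels are flagged a
    :class:`StrainWrapError` advises smaller load steps.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if window[0] < 1 or window[1] < 1:
        raise ValueError("window must be >= (1, 1)")
    depth, width = phasor.shape
    if lag >= depth:
        raise ValueError("lag must be smaller than the frame depth")

    c = phasor[lag:, :] * np.conj(phasor[:-lag, :])
    c_full = np.zeros_like(phasor)
    c_full[: depth - lag, :] = c
    c_avg = _complex_boxcar(c_full, window)
    mag_avg = ndimage.uniform_filter(np.abs(c_full), size=window, mode="nearest")

    phi = np.angle(c_avg)
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(mag_avg > 0, np.abs(c_avg) / mag_avg, 0.0)
    quality = np.clip(quality, 0.0, 1.0)

    # 4π·n·lag·Δz_tissue/λ with Δz_tissue = pitch_air/n → the n cancels.
    k = 4.0 * np.pi * lag * axial_pitch_air_mm * 1000.0 / wavelength_um
    strain = -phi / k

    flagged = np.abs(phi) >= wrap_margin * np.pi
    valid = ~flagged
    valid[depth - lag :, :] = False

    check = np.ones_like(flagged) if check_mask is None else check_mask
    check = check & (np.arange(depth)[:, None] < depth - lag)
    n_checked = int(check.sum())
    if n_checked and flagged[check].sum() > max_flagged_fraction * n_checked:
        frac = flagged[check].mean()
        raise StrainWrapError(
            f"{frac:.1%} of checked pixels exceed the unwrap-free phase "
            f"limit; reduce the per-step load increment"
        )
    return StrainSlice(strain=strain, quality=quality, valid=valid)


def accumulate(slices: list[StrainSlice]) -> StrainField:
    """Cumulative strain from a series of interframe estimates.

    ``cumulative[k] = Σ interframe[0..k]``; quality per frame is the
    minimum over the contributing transitions, validity the logical AND.
    """
    if not slices:
        raise ValueError("at least one interframe strain slice required")
    interframe = np.stack([s.strain for s in slices])
    quality = np.minimum.accumulate(np.stack([s.quality for s in slices]), axis=0)
    valid = np.logical_and.accumulate(np.stack([s.valid for s in slices]), axis=0)
    return StrainField(
        interframe=interframe,
        cumulative=np.cumsum(interframe, axis=0),
        quality=quality,
        valid=valid,
    )


def estimate_strain_series(
    series: CompressionSeries,
    *,
    lag: int = 4,
    window: tuple[int, int] = (8, 8),
    wrap_margin: float = 0.98,
) -> StrainField:
    """Vector-method strain for every consecutive frame pair, accumulated."""
    if series.n_frames < 2:
        raise ValueError("strain estimation requires at least 2 frames")
    slices = []
    for m in range(series.n_frames - 1):
        b = interframe_phasor(series.frames[m], series.frames[m + 1])
        slices.append(
            vector_strain(
                b,
                axial_pitch_air_mm=series.axial_pitch_air,
                wavelength_um=series.wavelength_um,
                lag=lag,
                window=window,
                wrap_margin=wrap_margin,
                check_mask=series.tissue_mask,
            )
        )
    return accumulate(slices)


def stress_from_reference(
    field: StrainField,
    series: CompressionSeries,
    *,
    margin_px: int = 8,
) -> np.ndarray:
    """Applied stress per loaded frame, kPa, from the reference layer.

    The cumulative strain is averaged laterally (and axially) over the
    interior of the silicone rows — ``margin_px`` rows are trimmed at
    both interfaces to avoid window/lag cross-talk — and converted with
    σ = E_ref · ε_ref.  A nonmonotone stress sequence under monotone
    loading triggers a warning (downstream tangent fits carry the flag).
    """
    r0, r1 = series.reference_region
    lo, hi = r0 + margin_px, r1 - margin_px
    if hi <= lo:
        raise ValueError("reference_region too thin for the requested margin")
    eps_ref = field.cumulative[:, lo:hi, :].mean(axis=(1, 2))
    stress = series.e_ref_kpa * eps_ref
    if np.any(np.diff(stress) < 0):
        warnings.warn(
            "nonmonotone applied stress under monotone loading", stacklevel=2
        )
    return stress


def stress_strain_curve(
    field: StrainField,
    stress_kpa: np.ndarray,
    mask: np.ndarray,
) -> StressStrainCurve:
    """ROI-averaged stress–strain samples, with the (0, 0) origin included."""
    if stress_kpa.shape[0] != field.n_transitions:
        raise ValueError("stress_kpa must have one value per loaded frame")
    eps = [field.cumulative[k][mask & field.valid[k]].mean()
           for k in range(field.n_transitions)]
    return StressStrainCurve(
        strain=np.concatenate([[0.0], eps]),
        stress_kpa=np.concatenate([[0.0], stress_kpa]),
    )


def tangent_modulus(
    curve: StressStrainCurve,
    stress_level: float = 1.0,
    stress_window: float = 0.5,
) -> float:
    """Tangent Young's modulus dσ/dε (kPa) at ``stress_level`` kPa.

    Least-squares slope of stress on strain over the curve points with
    stress inside ``stress_level ± stress_window``.  The curve must reach
    ``stress_level + stress_window``.
    """
    if curve.stress_kpa.max() < stress_level + stress_window:
        raise ValueError(
            "insufficient compression range: curve reaches "
            f"{curve.stress_kpa.max():.3g} kPa < "
            f"{stress_level + stress_window:.3g} kPa"
        )
    sel = np.abs(curve.stress_kpa - stress_level) <= stress_window
    if sel.sum() < 2:
        raise ValueError(
            "insufficient compression range: fewer than 2 stress samples "
            "inside the tangent window"
        )
    eps, sig = curve.strain[sel], curve.stress_kpa[sel]
    slope = np.polyfit(eps, sig, 1)[0]
    return float(slope)


def stiffness_map(
    field: StrainField,
    stress_kpa: np.ndarray,
    *,
    stress_level: float = 1.0,
    stress_window: float = 0.5,
    min_points: int = 3,
) -> StiffnessMap:
    """Per-pixel tangent modulus map at ``stress_level`` kPa.

    Vectorized least squares of σ on the per-pixel cumulative strain over
    the frames whose applied stress lies in the tangent window.
    """
    sel = np.abs(stress_kpa - stress_level) <= stress_window
    if stress_kpa.max() < stress_level + stress_window or sel.sum() < min_points:
        raise ValueError(
            "insufficient compression range for a per-pixel tangent fit"
        )
    eps = field.cumulative[sel]  # [k_sel, depth, lat]
    sig = stress_kpa[sel][:, None, None]
    eps_c = eps - eps.mean(axis=0)
    sig_c = sig - sig.mean()
    var = (eps_c**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (eps_c * sig_c).sum(axis=0) / var
    valid = (var > 0) & np.all(field.valid[sel], axis=0) & (slope > 0)
    values = np.where(valid, slope, np.nan)
    return StiffnessMap(values=values, valid_mask=valid, stress_level_kpa=stress_level)
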