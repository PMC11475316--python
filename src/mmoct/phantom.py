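"""Synthetic OCT phantoms with fully known ground truth.

Two generators emulate the acquisition products of a multimodal OCT
instrument (1.3 µm center wavelength, 256 depth px over ~1.7 mm in air,
512 lateral px over 2.4 mm):

* :func:`generate_cpoct_stack` — speckled two-channel (co/cross
  polarization) intensity B-scans with per-layer exponential depth
  attenuation, an additive noise floor and an optional sensitivity
  roll-off.  Speckle is fully developed: per-pixel squared magnitude of an
  independent circular complex Gaussian field (unit mean, unit contrast).

* :func:`generate_compression_series` — complex phase-sensitive B-scans
  under stepwise uniaxial compression with a linearly elastic reference
  silicone layer on top.  Each frame is the *same* base speckle field
  phase-modulated by the accumulated axial displacement; per-layer strain
  follows a prescribed linear or exponential stress–strain law.  The
  generator rejects load programs whose per-step strain would wrap the
  interframe phase across the vector-method lag.

Ground truth (per-pixel attenuation and stiffness maps, per-frame
displacement fields, applied stresses) is returned alongside every stack
so estimator tests can compare against exact values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .containers import CompressionSeries, CPOCTStack

# Nominal attenuation of the translucent reference silicone, mm^-1.
# Cosmetic only: phase-based strain processing is amplitude-insensitive.
_MU_SILICONE = 0.2


class PhantomError(ValueError):
    """Invalid phantom specification or infeasible load program."""


@dataclass(frozen=True)
class LinearLaw:
    """Hookean stress–strain law: sigma = E * eps (E in kPa)."""

    E: float

    def strain(self, stress_kpa: float) -> float:
        return stress_kpa / self.E

    def tangent(self, stress_kpa: float) -> float:
        return self.E


@dataclass(frozen=True)
class ExponentialLaw:
    """Nonlinear law sigma(eps) = (E_inf/k) * (exp(k*eps) - 1).

    The tangent modulus grows linearly with stress, E(sigma) = E_inf +
    k*sigma, so a single dimensionless parameter ``k`` controls the
    stiffening rate; ``E_inf`` (kPa) is the zero-stress tangent.  The
    inverse is closed-form: eps(sigma) = ln(1 + k*sigma/E_inf) / k.
    """

    E_inf: float
    k: float

    def strain(self, stress_kpa: float) -> float:
        return math.log1p(self.k * stress_kpa / self.E_inf) / self.k

    def tangent(self, stress_kpa: float) -> float:
        return self.E_inf + self.k * stress_kpa


@dataclass(frozen=True)
class Layer:
    """One tissue layer: geometry, per-channel attenuation, elasticity."""

    name: str
    thickness_px: int
    mu_co: float  # mm^-1, tissue depth
    mu_cross: float
    law: LinearLaw | ExponentialLaw = LinearLaw(100.0)


@dataclass(frozen=True)
class ReferenceLayer:
    """Pre-calibrated linearly elastic silicone on the sample surface."""

    thickness_px: int = 48
    E_ref: float = 100.0  # kPa


@dataclass
class PhantomSpec:
    """Full description of a synthetic sample and the scan geometry."""

    layers: list[Layer]
    reference_layer: ReferenceLayer = field(default_factory=ReferenceLayer)
    axial_pitch_air: float = 1.7 / 256  # mm/px in air
    lateral_pitch: float = 2.4 / 512  # mm/px
    n_tissue: float = 1.4
    wavelength_um: float = 1.3
    noise_floor: float = 1e-3  # additive intensity noise mean (I0 = 1)
    sensitivity_decay: float = 0.0  # exponential roll-off rate, per mm of air depth
    width_px: int = 512
    depth_px: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise PhantomError("layers: at least one layer required")
        total = sum(l.thickness_px for l in self.layers)
        if total > self.depth_px:
            raise PhantomError(
                f"layers: thicknesses sum to {total} px > depth_px={self.depth_px}"
            )
        for l in self.layers:
            if l.thickness_px <= 0:
                raise PhantomError(f"layer {l.name!r}: thickness_px must be > 0")
            if l.mu_co < 0 or l.mu_cross < 0:
                raise PhantomError(f"layer {l.name!r}: attenuation must be >= 0")
            if isinstance(l.law, LinearLaw) and l.law.E <= 0:
                raise PhantomError(f"layer {l.name!r}: modulus must be > 0")
            if isinstance(l.law, ExponentialLaw) and (l.law.E_inf <= 0 or l.law.k <= 0):
                raise PhantomError(f"layer {l.name!r}: E_inf and k must be > 0")
        if self.reference_layer.E_ref <= 0:
            raise PhantomError("reference_layer.E_ref must be > 0")
        if self.axial_pitch_air <= 0:
            raise PhantomError("axial_pitch_air must be > 0")
        if self.n_tissue < 1:
            raise PhantomError("n_tissue must be >= 1")
        if self.noise_floor < 0:
            raise PhantomError("noise_floor must be >= 0")

    @property
    def delta_z_mm(self) -> float:
        return self.axial_pitch_air / self.n_tissue


@dataclass
class GroundTruth:
    """Exact per-pixel truth accompanying every generated phantom."""

    mu_map_co: np.ndarray | None = None  # mm^-1
    mu_map_cross: np.ndarray | None = None
    stiffness_map: np.ndarray | None = None  # tangent modulus at 1 kPa, kPa
    displacement_fields: np.ndarray | None = None  # [n_frames, depth, lat], um
    applied_stress_per_frame: np.ndarray | None = None  # kPa
    layer_slices: dict[str, slice] = field(default_factory=dict)
    layer_cumulative_strains: dict[str, np.ndarray] = field(default_factory=dict)
    noiseless_mean: dict[str, np.ndarray] = field(default_factory=dict)


def _layer_profile(spec: PhantomSpec, attr: str, depth: int, offset: int = 0) -> np.ndarray:
    """Per-row value of a layer attribute; the last layer extends to the
    bottom of the scan (deep tissue continues beyond the named layers)."""
    prof = np.empty(depth, dtype=float)
    row = offset
    for layer in spec.layers:
        val = getattr(layer, attr) if attr != "tangent1" else layer.law.tangent(1.0)
        prof[row : row + layer.thickness_px] = val
        row += layer.thickness_px
    prof[row:] = prof[row - 1]  # extend deepest layer
    return prof


def _layer_slices(spec: PhantomSpec, offset: int = 0) -> dict[str, slice]:
    out = {}
    row = offset
    for layer in spec.layers:
        out[layer.name] = slice(row, row + layer.thickness_px)
        row += layer.thickness_px
    return out


def _sensitivity(spec: PhantomSpec) -> np.ndarray:
    z_air = np.arange(spec.depth_px) * spec.axial_pitch_air
    return np.exp(-spec.sensitivity_decay * z_air)


def _speckle(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-mean intensity speckle: |CN(0,1)|^2 (exponential, contrast 1)."""
    g = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return 0.5 * np.abs(g) ** 2


def generate_cpoct_stack(spec: PhantomSpec) -> tuple[CPOCTStack, GroundTruth]:
    """Speckled two-channel intensity stack with known attenuation maps.

    Per channel, the noiseless ensemble-mean intensity follows the
    Beer–Lambert law in tissue depth with the per-layer attenuation
    profile, times the depth sensitivity profile; each pixel carries
    independent fully developed speckle plus additive exponential noise
    with mean ``spec.noise_floor``.
    """
    rng = np.random.default_rng(spec.seed)
    depth, width = spec.depth_px, spec.width_px
    dz = spec.delta_z_mm
    sens = _sensitivity(spec)[:, None]

    gt = GroundTruth(layer_slices=_layer_slices(spec))
    stack_channels = {}
    for attr, key in (("mu_co", "co"), ("mu_cross", "cross")):
        mu = _layer_profile(spec, attr, depth)
        # cumulative attenuation to the top of pixel i: I_i ∝ exp(-2 μΔ i)
        cum = np.concatenate([[0.0], np.cumsum(mu[:-1]) * dz])
        mean_i = sens * np.exp(-2.0 * cum)[:, None]
        speckle = _speckle(rng, (depth, width))
        noise = spec.noise_floor * _speckle(rng, (depth, width))
        stack_channels[key] = mean_i * speckle + noise
        mu_map = np.broadcast_to(mu[:, None], (depth, width)).copy()
        setattr(gt, f"mu_map_{key}", mu_map)
        gt.noiseless_mean[key] = np.broadcast_to(mean_i, (depth, width)).copy()

    stack = CPOCTStack(
        co=stack_channels["co"],
        cross=stack_channels["cross"],
        axial_pitch_air=spec.axial_pitch_air,
        lateral_pitch=spec.lateral_pitch,
        n_tissue=spec.n_tissue,
        wavelength_um=spec.wavelength_um,
        metadata={"seed": spec.seed, "noise_floor": spec.noise_floor,
                  "sensitivity_decay": spec.sensitivity_decay, "kind": "phantom"},
    )
    return stack, gt


def max_step_strain(
    axial_pitch_air_mm: float = 1.7 / 256,
    wavelength_um: float = 1.3,
    max_lag: int = 4,
) -> float:
    """Largest per-step strain increment that keeps the interframe phase
    change across ``max_lag`` axial pixels below pi (no-unwrap limit)."""
    pitch_um = axial_pitch_air_mm * 1000.0
    return wavelength_um / (4.0 * max_lag * pitch_um)


def generate_compression_series(
    spec: PhantomSpec,
    stress_steps: list[float] | np.ndarray,
    max_lag: int = 4,
) -> tuple[CompressionSeries, GroundTruth]:
    """Phase-sensitive compression series with a reference silicone layer.

    ``stress_steps`` (kPa) must start at 0 and increase strictly.  Frame
    ``m`` is the shared base speckle field phase-modulated by the
    accumulated axial displacement under stress ``stress_steps[m]``, plus
    independent complex noise.  The common-path sign convention is used:
    compression shortens the optical path to the probe, so phase decreases
    with compressive strain and compressive strain is positive.

    Raises :class:`PhantomError` if any per-step strain increment in any
    layer would push the interframe phase change across ``max_lag`` pixels
    beyond pi (the unwrap-free processing limit).
    """
    stress = np.asarray(stress_steps, dtype=float)
    if stress.size < 1 or stress[0] != 0.0:
        raise PhantomError("stress_steps must start at 0 kPa")
    if np.any(np.diff(stress) <= 0):
        raise PhantomError("stress_steps must be strictly increasing")

    ref = spec.reference_layer
    depth, width = spec.depth_px, spec.width_px
    tissue_depth = depth - ref.thickness_px
    if tissue_depth <= 0 or sum(l.thickness_px for l in spec.layers) > tissue_depth:
        raise PhantomError(
            "layers: thicknesses plus reference layer exceed depth_px"
        )
    dz_mm = spec.delta_z_mm
    eps_limit = max_step_strain(spec.axial_pitch_air, spec.wavelength_um, max_lag)

    # Cumulative strain per row for every frame, plus the wrap-limit check.
    laws = {"reference": LinearLaw(ref.E_ref)}
    laws.update({l.name: l.law for l in spec.layers})
    cum_strain = {name: np.array([law.strain(s) for s in stress])
                  for name, law in laws.items()}
    for name, eps in cum_strain.items():
        steps = np.diff(eps)
        bad = np.nonzero(steps >= eps_limit)[0]
        if bad.size:
            raise PhantomError(
                f"layer {name!r}, load step {bad[0] + 1}: per-step strain "
                f"{steps[bad[0]]:.4g} exceeds the unwrap-free limit "
                f"{eps_limit:.4g} for lag {max_lag}; use smaller stress steps"
            )

    slices = {"reference": slice(0, ref.thickness_px)}
    slices.update(_layer_slices(spec, offset=ref.thickness_px))
    # Per-row strain profile per frame (deepest layer extends to the bottom).
    eps_rows = np.zeros((stress.size, depth))
    for name, sl in slices.items():
        eps_rows[:, sl] = cum_strain[name][:, None]
    last = spec.layers[-1].name
    eps_rows[:, slices[last].stop:] = cum_strain[last][:, None]

    # Path shortening u (um) between probe and the top of pixel i.
    dz_um = dz_mm * 1000.0
    u = np.concatenate(
        [np.zeros((stress.size, 1)), np.cumsum(eps_rows[:, :-1], axis=1) * dz_um],
        axis=1,
    )

    rng = np.random.default_rng(spec.seed)
    mu = np.empty(depth)
    mu[slices["reference"]] = _MU_SILICONE
    mu[ref.thickness_px:] = _layer_profile(spec, "mu_co", tissue_depth)
    cum_att = np.concatenate([[0.0], np.cumsum(mu[:-1]) * dz_mm])
    amp = (_sensitivity(spec) * np.exp(-2.0 * cum_att)) ** 0.5

    g = (rng.standard_normal((depth, width)) + 1j * rng.standard_normal((depth, width)))
    base = amp[:, None] * g / np.sqrt(2.0)

    phase = -4.0 * np.pi * spec.n_tissue * u[:, :, None] / spec.wavelength_um
    frames = base[None, :, :] * np.exp(1j * phase)
    if spec.noise_floor > 0:
        noise = (rng.standard_normal(frames.shape) + 1j * rng.standard_normal(frames.shape))
        frames = frames + np.sqrt(spec.noise_floor / 2.0) * noise

    tissue_mask = np.zeros((depth, width), dtype=bool)
    tissue_mask[ref.thickness_px:, :] = True

    stiffness = np.empty(depth)
    stiffness[slices["reference"]] = ref.E_ref
    stiffness[ref.thickness_px:] = _layer_profile(spec, "tangent1", tissue_depth)

    series = CompressionSeries(
        frames=frames,
        axial_pitch_air=spec.axial_pitch_air,
        n_tissue=spec.n_tissue,
        wavelength_um=spec.wavelength_um,
        reference_region=(0, ref.thickness_px),
        e_ref_kpa=ref.E_ref,
        tissue_mask=tissue_mask,
        metadata={"seed": spec.seed, "stress_steps": stress.tolist(),
                  "noise_floor": spec.noise_floor, "kind": "phantom"},
    )
    gt = GroundTruth(
        stiffness_map=np.broadcast_to(stiffness[:, None], (depth, width)).copy(),
        displacement_fields=np.broadcast_to(
            u[:, :, None], (stress.size, depth, width)
        ).copy(),
        applied_stress_per_frame=stress,
        layer_slices=slices,
        layer_cumulative_strains=cum_strain,
    )
    return series, gt


def uniform_phantom(
    mu_co: float,
    mu_cross: float | None = None,
    *,
    width_px: int = 512,
    depth_px: int = 256,
    seed: int = 0,
    noise_floor: float = 1e-3,
    law: LinearLaw | ExponentialLaw = LinearLaw(100.0),
) -> PhantomSpec:
    """Single uniform tissue layer filling the whole scan depth."""
    return PhantomSpec(
        layers=[Layer("tissue", depth_px, mu_co,
                      mu_co if mu_cross is None else mu_cross, law)],
        width_px=width_px,
        depth_px=depth_px,
        seed=seed,
        noise_floor=noise_floor,
    )
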