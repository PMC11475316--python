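"""Core data containers for the multimodal OCT processing chain.

Two acquisition products flow through the pipeline: a cross-polarization
OCT intensity stack (two channels, ``co`` and ``cross``) that feeds the
attenuation-coefficient stage, and a phase-sensitive compression series
(ordered complex B-scans under increasing uniaxial load, with a calibrated
silicone reference layer on top) that feeds the elastography stage.  Stage
outputs are per-pixel quantitative maps with explicit validity masks:
invalid pixels are flagged, never silently zeroed.

All containers are plain dataclasses that validate their invariants on
construction and raise ``ValueError`` with a message naming the offending
field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Tissue classes used throughout the statistics and diagnostics stages.
TISSUE_CLASSES = (
    "proliferative",
    "secretory",
    "atrophic",
    "non_atypical",
    "EIN",
    "EC_low",
    "EC_high",
    "EC_clear",
    "EC_serous",
)

#: Quantitative modalities and their units.
MODALITIES = {"att_co": "mm^-1", "att_cross": "mm^-1", "stiffness": "kPa"}


@dataclass
class CPOCTStack:
    """Two-channel (co/cross polarization) OCT intensity B-scan.

    Arrays are indexed ``[depth, lateral]``; depth pixel pitch is specified
    in air (``axial_pitch_air``, mm/px) and converted to tissue depth via
    the tissue refractive index ``n_tissue``.
    """

    co: np.ndarray
    cross: np.ndarray
    axial_pitch_air: float  # mm per pixel, in air
    lateral_pitch: float = 2.4 / 512  # mm per pixel
    n_tissue: float = 1.4
    wavelength_um: float = 1.3
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.co = np.asarray(self.co, dtype=float)
        self.cross = np.asarray(self.cross, dtype=float)
        if self.co.ndim != 2:
            raise ValueError("co: expected a 2-D [depth, lateral] array")
        if self.co.shape != self.cross.shape:
            raise ValueError(
                f"co/cross shape mismatch: {self.co.shape} vs {self.cross.shape}"
            )
        if np.any(self.co < 0) or np.any(self.cross < 0):
            raise ValueError("intensities must be non-negative")
        if self.axial_pitch_air <= 0:
            raise ValueError("axial_pitch_air must be > 0")
        if self.n_tissue < 1:
            raise ValueError("n_tissue must be >= 1")

    @property
    def delta_z_mm(self) -> float:
        """Axial pixel pitch in tissue depth, mm."""
        return self.axial_pitch_air / self.n_tissue

    @property
    def shape(self) -> tuple[int, int]:
        return self.co.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in ("co", "cross"):
            raise ValueError(f"unknown channel {name!r}; expected 'co' or 'cross'")
        return self.co if name == "co" else self.cross


@dataclass
class CompressionSeries:
    """Ordered complex-valued B-scans acquired under stepwise compression.

    ``frames`` is ``[n_frames, depth, lateral]``.  ``reference_region`` is
    the half-open depth-row interval occupied by the pre-calibrated,
    linearly elastic silicone reference layer whose strain converts to
    applied stress through ``e_ref_kpa``.
    """

    frames: np.ndarray
    axial_pitch_air: float
    n_tissue: float
    wavelength_um: float
    reference_region: tuple[int, int]
    e_ref_kpa: float
    tissue_mask: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames: expected [n_frames, depth, lateral]")
        if not np.iscomplexobj(self.frames):
            raise ValueError("frames must be complex-valued")
        if self.frames.shape[0] < 1:
            raise ValueError("frames: at least one frame required")
        if self.e_ref_kpa <= 0:
            raise ValueError("e_ref_kpa must be > 0")
        r0, r1 = self.reference_region
        if not (0 <= r0 < r1 <= self.frames.shape[1]):
            raise ValueError("reference_region rows out of range")
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.tissue_mask.shape != self.frames.shape[1:]:
            raise ValueError("tissue_mask shape must match frame shape")
        if self.tissue_mask[r0:r1].any():
            raise ValueError("reference_region must be disjoint from tissue_mask")
        if self.axial_pitch_air <= 0:
            raise ValueError("axial_pitch_air must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def delta_z_mm(self) -> float:
        return self.axial_pitch_air / self.n_tissue


@dataclass
class AttenuationMap:
    """Per-pixel attenuation coefficient, mm^-1, with a validity mask."""

    values: np.ndarray
    channel: str
    valid_mask: np.ndarray
    delta_z_mm: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.channel not in ("co", "cross"):
            raise ValueError("channel must be 'co' or 'cross'")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if np.any(self.values[self.valid_mask] < 0):
            raise ValueError("valid attenuation values must be >= 0")


@dataclass
class StiffnessMap:
    """Per-pixel tangent Young's modulus, kPa, with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    stress_level_kpa: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if np.any(self.values[self.valid_mask] <= 0):
            raise ValueError("valid stiffness values must be > 0")


@dataclass
class StrainField:
    """Interframe and cumulative axial strain estimates.

    ``interframe[k]`` is the strain of transition ``k`` (frame k -> k+1);
    ``cumulative[k]`` is the running sum of transitions ``0..k`` (small-
    strain additivity).  ``quality`` is the vector-method phasor-magnitude
    confidence in [0, 1], propagated through accumulation as the running
    minimum.  Compressive strain is positive.
    """

    interframe: np.ndarray
    cumulative: np.ndarray
    quality: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.interframe, self.cumulative, self.quality, self.valid)}
        if len(shapes) != 1:
            raise ValueError("strain field arrays must share one shape")
        if np.any(self.quality > 1 + 1e-9):
            raise ValueError("quality must be <= 1")

    @property
    def n_transitions(self) -> int:
        return self.interframe.shape[0]


@dataclass
class StressStrainCurve:
    """Ordered (tissue strain, applied stress kPa) samples for one region."""

    strain: np.ndarray
    stress_kpa: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_kpa = np.asarray(self.stress_kpa, dtype=float)
        if self.strain.shape != self.stress_kpa.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress_kpa must be 1-D and equal length")


@dataclass(frozen=True)
class ContrastSpec:
    """One-vs-rest diagnostic contrast over tissue classes."""

    positive_classes: frozenset
    negative_classes: frozenset
    modality: str
    direction: str = "high"  # "high": higher values call positive; "low": lower

    def __post_init__(self) -> None:
        pos = frozenset(self.positive_classes)
        neg = frozenset(self.negative_classes)
        object.__setattr__(self, "positive_classes", pos)
        object.__setattr__(self, "negative_classes", neg)
        if not pos or not neg:
            raise ValueError("positive_classes and negative_classes must be nonempty")
        if pos & neg:
            raise ValueError(f"contrast class sets overlap: {sorted(pos & neg)}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")


@dataclass
class ROCResult:
    """ROC sweep, AUC and (optionally) a selected operating point."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    direction: str
    modality: str | None = None
    chosen_threshold: float | None = None
    se: float | None = None  # sensitivity, percent
    sp: float | None = None  # specificity, percent

    def __post_init__(self) -> None:
        if not (0.0 - 1e-12 <= self.auc <= 1.0 + 1e-12):
            raise ValueError("auc must lie in [0, 1]")
        if np.any(np.diff(self.tpr) < -1e-12) or np.any(np.diff(self.fpr) < -1e-12):
            raise ValueError("TPR and FPR must be nondecreasing along the sweep")
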