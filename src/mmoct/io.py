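"""Array-container I/O and provenance records.

The canonical interchange format is a named-array container (NumPy
``.npz``) with a JSON metadata sidecar of the same stem — complex-valued
compression frames do not fit standard bio-image formats cleanly.
Intensity stacks can additionally be exported as multi-page TIFF for
viewing in standard tools.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import tifffile

from . import __version__
from .containers import CompressionSeries, CPOCTStack

SCHEMA = "mmoct-container-1"

_COMMON_META = ("axial_pitch_air", "n_tissue", "wavelength_um")
_REQUIRED_META = {
    "cpoct": _COMMON_META + ("lateral_pitch",),
    "compression": _COMMON_META + ("reference_region", "e_ref_kpa"),
}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_container(path: str | Path, obj: CPOCTStack | CompressionSeries) -> Path:
    """Write a stack or compression series as ``.npz`` + JSON sidecar."""
    path = Path(path).with_suffix(".npz")
    if isinstance(obj, CPOCTStack):
        kind = "cpoct"
        arrays = {"co": obj.co, "cross": obj.cross}
        meta: dict[str, Any] = {
            "axial_pitch_air": obj.axial_pitch_air,
            "lateral_pitch": obj.lateral_pitch,
            "n_tissue": obj.n_tissue,
            "wavelength_um": obj.wavelength_um,
        }
    elif isinstance(obj, CompressionSeries):
        kind = "compression"
        arrays = {"frames": obj.frames, "mask": obj.tissue_mask}
        meta = {
            "axial_pitch_air": obj.axial_pitch_air,
            "n_tissue": obj.n_tissue,
            "wavelength_um": obj.wavelength_um,
            "reference_region": list(obj.reference_region),
            "e_ref_kpa": obj.e_ref_kpa,
        }
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    np.savez_compressed(path, **arrays)
    sidecar = {"schema": SCHEMA, "kind": kind, "meta": meta,
               "extra": _jsonable(obj.metadata)}
    _sidecar(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_container(path: str | Path) -> CPOCTStack | CompressionSeries:
    """Read a container written by :func:`write_container`.

    Raises ``FileNotFoundError`` for missing files, ``ValueError`` for an
    unrecognized schema or for missing metadata (naming the field).
    """
    path = Path(path).with_suffix(".npz")
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = _sidecar(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if sidecar.get("schema") != SCHEMA:
        raise ValueError(
            f"unrecognized container schema {sidecar.get('schema')!r}; expected {SCHEMA!r}"
        )
    kind = sidecar.get("kind")
    if kind not in _REQUIRED_META:
        raise ValueError(f"unrecognized container kind {kind!r}")
    meta = sidecar.get("meta", {})
    for fieldname in _REQUIRED_META[kind]:
        if fieldname not in meta:
            raise ValueError(f"container metadata missing required field {fieldname!r}")
    data = np.load(path)
    extra = sidecar.get("extra", {})
    if kind == "cpoct":
        return CPOCTStack(
            co=data["co"],
            cross=data["cross"],
            axial_pitch_air=meta["axial_pitch_air"],
            lateral_pitch=meta["lateral_pitch"],
            n_tissue=meta["n_tissue"],
            wavelength_um=meta["wavelength_um"],
            metadata=extra,
        )
    return CompressionSeries(
        frames=data["frames"],
        axial_pitch_air=meta["axial_pitch_air"],
        n_tissue=meta["n_tissue"],
        wavelength_um=meta["wavelength_um"],
        reference_region=tuple(meta["reference_region"]),
        e_ref_kpa=meta["e_ref_kpa"],
        tissue_mask=data["mask"],
        metadata=extra,
    )


def write_tiff(path: str | Path, stack: CPOCTStack) -> Path:
    """Intensity-only export as a two-page (co, cross) float32 TIFF."""
    path = Path(path).with_suffix(".tif")
    tifffile.imwrite(
        path, np.stack([stack.co, stack.cross]).astype(np.float32)
    )
    return path


def read_tiff(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read back a two-page TIFF written by :func:`write_tiff`."""
    pages = tifffile.imread(Path(path))
    return pages[0], pages[1]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serializable configuration."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(path: str | Path, config: dict, seed: int) -> Path:
    """JSON provenance record: config hash, package version, seed."""
    record = {
        "config_hash": config_hash(config),
        "mmoct_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
    }
    path = Path(path)
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
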