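"""Published reference values for endometrial tissue classes.

Median [Q1; Q3] attenuation coefficients (co/cross polarization, mm^-1)
and tangent Young's moduli (kPa) reported for ex vivo endometrial tissue
in normal states (proliferative, secretory, atrophic), hyperplasia
(non-atypical, EIN) and endometrial-cancer subtypes.  The package uses
these numbers to parameterize synthetic phantoms and cohorts — they are
inputs, not quantities this package re-derives from patient data.

Synthetic cohorts are drawn from per-class log-normal distributions
matched to the median and interquartile bounds, a standard choice for
positive, right-skewed biomechanical and optical tissue parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MODALITIES, TISSUE_CLASSES

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


@dataclass(frozen=True)
class Quartiles:
    """Median with interquartile bounds and a display unit."""

    median: float
    q1: float
    q3: float
    unit: str  # "mm^-1" or "kPa"

    @property
    def formatted(self) -> str:
        if self.unit == "kPa":
            return f"{self.median:.0f} [{self.q1:.0f}; {self.q3:.0f}]"
        return f"{self.median:.2f} [{self.q1:.2f}; {self.q3:.2f}]"

    def __str__(self) -> str:  # lookup(...).att_co prints as "1.73 [1.50; 1.99]"
        return self.formatted

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln X matched to the median and quartiles."""
        mu = np.log(self.median)
        sigma = (np.log(self.q3) - np.log(max(self.q1, 1e-9))) / (2 * _Z75)
        return mu, max(sigma, 1e-6)


@dataclass(frozen=True)
class ReferenceEntry:
    morphology: str
    att_co: Quartiles
    att_cross: Quartiles
    stiffness: Quartiles

    def modality(self, name: str) -> Quartiles:
        if name not in MODALITIES:
            raise KeyError(f"unknown modality {name!r}")
        return getattr(self, name)


def _entry(cls, co, cross, stiff) -> ReferenceEntry:
    return ReferenceEntry(
        cls,
        Quartiles(*co, "mm^-1"),
        Quartiles(*cross, "mm^-1"),
        Quartiles(*stiff, "kPa"),
    )


#: Reported Me [Q1; Q3] per class: (att_co mm^-1, att_cross mm^-1, stiffness kPa).
REFERENCE_VALUES: dict[str, ReferenceEntry] = {
    "proliferative": _entry("proliferative", (1.73, 1.50, 1.99), (0.61, 0.47, 0.76), (60, 47, 73)),
    "secretory": _entry("secretory", (2.43, 2.16, 2.72), (1.37, 1.01, 1.65), (51, 37, 66)),
    "atrophic": _entry("atrophic", (2.96, 2.66, 3.26), (0.75, 0.56, 1.01), (69, 31, 85)),
    "non_atypical": _entry("non_atypical", (3.16, 2.69, 3.30), (2.15, 1.62, 2.53), (25, 6, 34)),
    "EIN": _entry("EIN", (3.14, 2.90, 3.32), (2.02, 1.69, 2.72), (172, 124, 305)),
    "EC_low": _entry("EC_low", (5.37, 5.14, 6.07), (4.56, 3.45, 5.19), (311, 192, 497)),
    "EC_high": _entry("EC_high", (5.20, 4.88, 5.93), (3.88, 3.06, 4.70), (414, 318, 635)),
    "EC_clear": _entry("EC_clear", (3.25, 2.83, 3.46), (2.32, 1.98, 2.68), (327, 273, 468)),
    "EC_serous": _entry("EC_serous", (5.33, 5.19, 5.61), (2.37, 1.95, 3.04), (343, 239, 524)),
}

#: Reported operating points per contrast and modality:
#: (threshold in modality units, sensitivity %, specificity %).
REPORTED_OPERATING_POINTS = {
    ("ec_vs_non_tumorous", "att_co"): (3.69, 86.1, 92.6),
    ("ec_vs_non_tumorous", "att_cross"): (2.27, 86.8, 87.0),
    ("ec_vs_non_tumorous", "stiffness"): (122.0, 93.2, 91.1),
    ("ein_vs_benign", "att_co"): (3.03, 65.5, 64.0),
    ("ein_vs_benign", "att_cross"): (1.67, 76.1, 76.1),
    ("ein_vs_benign", "stiffness"): (95.0, 87.2, 90.1),
}

_ALIASES = {
    "proliferative": "proliferative",
    "secretory": "secretory",
    "atrophic": "atrophic",
    "non-atypical": "non_atypical",
    "non_atypical": "non_atypical",
    "ein": "EIN",
    "low-grade": "EC_low",
    "ec_low": "EC_low",
    "high-grade": "EC_high",
    "ec_high": "EC_high",
    "clear cell": "EC_clear",
    "ec_clear": "EC_clear",
    "serous": "EC_serous",
    "ec_serous": "EC_serous",
}


def lookup(morphology: str) -> ReferenceEntry:
    """Reference entry for a tissue class; accepts common display aliases.

    >>> str(lookup("Proliferative").att_co)
    '1.73 [1.50; 1.99]'
    """
    key = _ALIASES.get(morphology.strip().lower().replace(" ", " "))
    if key is None:
        raise KeyError(
            f"unknown endometrial morphology {morphology!r}; "
            f"known classes: {sorted(set(_ALIASES.values()))}"
        )
    return REFERENCE_VALUES[key]


def reference_values() -> list[dict]:
    """All reference entries as records (morphology + formatted quantities)."""
    out = []
    for cls, e in REFERENCE_VALUES.items():
        out.append(
            {
                "morphology": cls,
                "att_co": e.att_co.formatted,
                "att_cross": e.att_cross.formatted,
                "stiffness": e.stiffness.formatted,
            }
        )
    return out


def sample_class_values(
    tissue_class: str,
    modality: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` values from the class/modality-matched log-normal."""
    q = REFERENCE_VALUES[tissue_class].modality(modality)
    mu, sigma = q.lognormal_params()
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def synthetic_measurement_table(
    classes: dict[str, int],
    modalities: tuple[str, ...] = ("att_co", "att_cross", "stiffness"),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Synthetic MeasurementTable drawn from the reference distributions.

    ``classes`` maps tissue class -> number of region-mean measurements.
    The same per-class draw count applies to every modality; values across
    modalities are drawn independently (no within-region correlation).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for cls, n in classes.items():
        if cls not in TISSUE_CLASSES:
            raise KeyError(f"unknown tissue class {cls!r}")
        for modality in modalities:
            vals = sample_class_values(cls, modality, n, rng)
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "sample_id": f"{cls}_synth",
                        "tissue_class": cls,
                        "modality": modality,
                        "region_id": i,
                        "value": float(v),
                        "row0": -1,
                        "col0": -1,
                    }
                )
    return pd.DataFrame(rows)


def split_n_across(classes: tuple[str, ...], total: int) -> dict[str, int]:
    """Spread ``total`` measurements as evenly as possible across classes."""
    base, extra = divmod(total, len(classes))
    return {c: base + (1 if i < extra else 0) for i, c in enumerate(classes)}
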