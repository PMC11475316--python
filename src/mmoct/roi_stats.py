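"""Region-of-interest sampling and group statistics.

Quantitative maps are summarized by the mean value of randomly placed,
non-overlapping, axis-aligned measurement regions (default ten regions
of 10×10 px) inside a tissue mask — mirroring the measurement protocol
used for endometrial parameter maps.  Region means are pooled into a
measurement table and compared across tissue classes with the
Mann–Whitney U test under Bonferroni correction, the family being all
class pairs within one modality.

Descriptive statistics are reported as ``Me [Q1; Q3]`` with the linear-
interpolation quartile convention; attenuation renders with two decimals
and stiffness as integers.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MODALITIES


@dataclass(frozen=True)
class Region:
    """One measurement region (top-left corner, shape, mean value)."""

    row: int
    col: int
    height: int
    width: int
    mean: float


def _region_sums(mask: np.ndarray, h: int, w: int) -> np.ndarray:
    """Sum of ``mask`` over every h×w window via an integral image."""
    ii = np.zeros((mask.shape[0] + 1, mask.shape[1] + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(mask, axis=0), axis=1)
    return ii[h:, w:] - ii[:-h, w:] - ii[h:, :-w] + ii[:-h, :-w]


def sample_rois(
    values: np.ndarray,
    mask: np.ndarray,
    n_regions: int = 10,
    region_shape: tuple[int, int] = (10, 10),
    seed: int | np.random.Generator = 0,
    valid_mask: np.ndarray | None = None,
) -> list[Region]:
    """Uniformly random non-overlapping regions fully inside ``mask``.

    Each region's value is the mean of ``values`` over the region
    intersected with ``valid_mask`` (invalid pixels are excluded; a
    region with no valid pixel is discarded as a placement).  Raises
    ``ValueError`` reporting the achieved count when ``n_regions``
    non-overlapping placements cannot be found.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = region_shape
    mask = np.asarray(mask, dtype=bool)
    if valid_mask is None:
        valid_mask = np.ones_like(mask)
    if mask.shape[0] < h or mask.shape[1] < w:
        raise ValueError(
            f"mask {mask.shape} smaller than one {h}x{w} region; placed 0 of {n_regions}"
        )

    fits = _region_sums(mask, h, w) >= h * w - 0.5  # fully inside the mask
    candidates = np.argwhere(fits)
    if candidates.size == 0:
        raise ValueError(f"mask admits no {h}x{w} region; placed 0 of {n_regions}")
    order = rng.permutation(len(candidates))

    chosen: list[Region] = []
    occupied: list[tuple[int, int]] = []
    for idx in order:
        r, c = map(int, candidates[idx])
        if any(abs(r - ro) < h and abs(c - co) < w for ro, co in occupied):
            continue
        sel = valid_mask[r : r + h, c : c + w]
        if not sel.any():
            continue
        region_vals = values[r : r + h, c : c + w][sel]
        chosen.append(Region(r, c, h, w, float(np.nanmean(region_vals))))
        occupied.append((r, c))
        if len(chosen) == n_regions:
            return chosen
    raise ValueError(
        f"insufficient mask area: placed {len(chosen)} of {n_regions} "
        f"non-overlapping {h}x{w} regions"
    )


def regions_to_rows(
    regions: list[Region],
    sample_id: str,
    tissue_class: str,
    modality: str,
) -> list[dict]:
    """MeasurementTable rows for a set of sampled regions."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return [
        {
            "sample_id": sample_id,
            "tissue_class": tissue_class,
            "modality": modality,
            "region_id": i,
            "value": reg.mean,
            "row0": reg.row,
            "col0": reg.col,
        }
        for i, reg in enumerate(regions)
    ]


def describe(values, unit: str | None = None) -> dict:
    """Median and quartiles with the ``Me [Q1; Q3]`` display string.

    Quartiles use linear interpolation between order statistics.  Unit
    "kPa" formats as integers, anything else with two decimals.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("describe requires at least one value")
    me, q1, q3 = np.percentile(values, [50, 25, 75])
    if unit == "kPa":
        formatted = f"{me:.0f} [{q1:.0f}; {q3:.0f}]"
    else:
        formatted = f"{me:.2f} [{q1:.2f}; {q3:.2f}]"
    return {"median": float(me), "q1": float(q1), "q3": float(q3), "formatted": formatted}


def _enumerated_u_pvalue(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney p by full enumeration of labelings.

    Permutation-exact: the U statistic (number of (x, y) pairs with
    x > y, ties counted half) is recomputed for every way of relabeling
    the pooled observations, and the two-sided p-value is the fraction of
    labelings at least as far from the null mean n1*n2/2 as the observed
    U.  Valid with ties.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    greater = (pooled[:, None] > pooled[None, :]) + 0.5 * (
        pooled[:, None] == pooled[None, :]
    )
    np.fill_diagonal(greater, 0.0)
    center = n1 * (n - n1) / 2.0
    u_obs = greater[:n1, n1:].sum()
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    idx = np.arange(n)
    for combo in itertools.combinations(idx, n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(combo)] = True
        u = greater[np.ix_(sel, ~sel)].sum()
        if abs(u - center) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return float(u_obs), count / total


def mann_whitney_u(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test: (U of the first group, p-value).

    ``method="auto"`` uses the exact full-enumeration null distribution
    when both groups have at most 8 values, and the normal approximation
    with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError("method must be 'auto', 'exact' or 'asymptotic'")
    if method == "exact" or (method == "auto" and len(x) <= 8 and len(y) <= 8):
        return _enumerated_u_pvalue(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_mann_whitney(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise class comparisons per modality with Bonferroni correction.

    Returns one row per (modality, class_a, class_b) with the U statistic,
    raw p, Bonferroni-adjusted p (family = all class pairs within the
    modality) and a significance flag (adjusted p < alpha).  Classes with
    fewer than two values are skipped with a warning.
    """
    required = {"tissue_class", "modality", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"measurement table must have columns {sorted(required)}")
    rows = []
    for modality, sub in table.groupby("modality", sort=False):
        groups = {
            cls: g["value"].to_numpy() for cls, g in sub.groupby("tissue_class", sort=False)
        }
        usable = {}
        for cls, vals in groups.items():
            if len(vals) < 2:
                warnings.warn(
                    f"{modality}: class {cls!r} has fewer than 2 values; skipped",
                    stacklevel=2,
                )
            else:
                usable[cls] = vals
        pairs = list(itertools.combinations(sorted(usable), 2))
        n_family = len(pairs)
        for a, b in pairs:
            u, p = mann_whitney_u(usable[a], usable[b])
            p_adj = min(1.0, p * n_family)
            rows.append(
                {
                    "modality": modality,
                    "class_a": a,
                    "class_b": b,
                    "U": u,
                    "p_raw": p,
                    "p_adjusted": p_adj,
                    "significant": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["modality", "class_a", "class_b", "U", "p_raw", "p_adjusted", "significant"],
    )
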