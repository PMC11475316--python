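"""End-to-end synthetic-cohort pipeline.

Chains the stages — phantom generation, signal compensation, attenuation
mapping, compression elastography, ROI sampling, group statistics and
ROC threshold selection — over a cohort of synthetic samples whose
ground-truth parameters are drawn per class from the published reference
distributions, so within-class spread exists and the statistics/ROC
stages operate on non-degenerate data.

All randomness flows from ``RunConfig.seed`` through
``numpy.random.SeedSequence``; a fixed config yields byte-identical CSV
and JSON outputs.  Every output directory carries a JSON provenance
record (config hash, package version, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import image as mpl_image

from . import attenuation, diagnostics, elastography, phantom, reference, render, roi_stats
from .containers import TISSUE_CLASSES
from .io import config_hash, write_provenance


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "mmoct_run"
    seed: int = 0
    classes: tuple[str, ...] = TISSUE_CLASSES
    n_samples_per_class: int = 2
    # phantom geometry
    width_px: int = 128
    depth_px: int = 256
    noise_floor: float = 1e-3
    # attenuation stage
    atten_smooth: tuple[int, int] = (1, 21)
    atten_vmax: float = 12.0
    # elastography stage
    lag: int = 4
    window: tuple[int, int] = (8, 8)
    stress_level_kpa: float = 1.0
    stress_window_kpa: float = 0.5
    e_ref_kpa: float = 100.0
    max_stress_kpa: float = 2.0
    # ROI stage
    n_regions: int = 10
    region_shape: tuple[int, int] = (10, 10)
    # statistics / diagnostics
    alpha: float = 0.05
    threshold_policy: str = "youden"

    def validate(self) -> None:
        for name, cond in [
            ("n_samples_per_class", self.n_samples_per_class >= 1),
            ("width_px", self.width_px >= self.region_shape[1]),
            ("depth_px", self.depth_px >= 64),
            ("noise_floor", self.noise_floor >= 0),
            ("lag", self.lag >= 1),
            ("window", self.window[0] >= 1 and self.window[1] >= 1),
            ("stress_level_kpa", self.stress_level_kpa > 0),
            ("stress_window_kpa", 0 < self.stress_window_kpa < self.stress_level_kpa + 1),
            ("e_ref_kpa", self.e_ref_kpa > 0),
            ("max_stress_kpa", self.max_stress_kpa >= self.stress_level_kpa + self.stress_window_kpa),
            ("n_regions", self.n_regions >= 1),
            ("alpha", 0 < self.alpha < 1),
        ]:
            if not cond:
                raise ValueError(f"invalid configuration parameter: {name}")
        unknown = set(self.classes) - set(TISSUE_CLASSES)
        if unknown:
            raise ValueError(f"invalid configuration parameter: classes ({sorted(unknown)})")
        if self.threshold_policy not in diagnostics.THRESHOLD_POLICIES:
            raise ValueError("invalid configuration parameter: threshold_policy")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def _sample_truth(cls: str, rng: np.random.Generator) -> dict[str, float]:
    """Per-sample ground-truth parameters drawn from the class reference
    distributions; tangent modulus clipped to the phantom-feasible range."""
    entry = reference.REFERENCE_VALUES[cls]
    draw = lambda q: float(rng.lognormal(*q.lognormal_params()))
    return {
        "mu_co": min(max(draw(entry.att_co), 0.2), 10.0),
        "mu_cross": min(max(draw(entry.att_cross), 0.1), 10.0),
        "stiffness": min(max(draw(entry.stiffness), 15.0), 700.0),
    }


def _stress_steps(cfg: RunConfig, e_tissue: float) -> np.ndarray:
    """Uniform load program reaching max_stress with per-step strain safely
    below the unwrap-free limit in the softest layer."""
    eps_limit = phantom.max_step_strain(max_lag=cfg.lag)
    e_min = min(e_tissue, cfg.e_ref_kpa)
    n_steps = max(8, math.ceil(cfg.max_stress_kpa / (e_min * 0.8 * eps_limit)))
    return np.linspace(0.0, cfg.max_stress_kpa, n_steps + 1)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chain and write maps, tables, statistics and ROC files.

    Returns a bundle with the measurement table, comparison matrix, ROC
    results and output paths.  Deterministic given the config.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seed = np.random.SeedSequence(config.seed)

    ref_thickness = 48
    tissue_depth = config.depth_px - ref_thickness
    rows: list[dict] = []
    rendered = False

    for ci, cls in enumerate(config.classes):
        for si in range(config.n_samples_per_class):
            ss = np.random.SeedSequence(entropy=root_seed.entropy, spawn_key=(ci, si))
            child = ss.generate_state(2)
            rng = np.random.default_rng(child[0])
            truth = _sample_truth(cls, rng)
            sample_id = f"{cls}_{si:02d}"

            # --- CP OCT stack -> attenuation maps -----------------------
            spec = phantom.uniform_phantom(
                truth["mu_co"], truth["mu_cross"],
                width_px=config.width_px, depth_px=config.depth_px,
                seed=int(child[1]), noise_floor=config.noise_floor,
            )
            stack, _ = phantom.generate_cpoct_stack(spec)
            corrected = attenuation.compensate_signal(stack, config.noise_floor)
            endo_mask = np.ones(stack.shape, dtype=bool)
            for k, channel in enumerate(("co", "cross")):
                amap = attenuation.estimate_attenuation(
                    corrected, channel, smooth=config.atten_smooth
                )
                regions = roi_stats.sample_rois(
                    amap.values, endo_mask & amap.valid_mask,
                    n_regions=config.n_regions,
                    region_shape=config.region_shape,
                    seed=np.random.default_rng(int(child[0]) + 1 + k),
                    valid_mask=amap.valid_mask,
                )
                rows += roi_stats.regions_to_rows(
                    regions, sample_id, cls, f"att_{channel}"
                )
                if not rendered:
                    mpl_image.imsave(
                        out / f"attenuation_{channel}_{sample_id}.png",
                        render.render_map(amap, 0.0, config.atten_vmax),
                    )

            # --- compression series -> stiffness map --------------------
            oce_spec = phantom.PhantomSpec(
                layers=[phantom.Layer(
                    "endometrium", tissue_depth, truth["mu_co"],
                    truth["mu_cross"], phantom.LinearLaw(truth["stiffness"]),
                )],
                reference_layer=phantom.ReferenceLayer(ref_thickness, config.e_ref_kpa),
                width_px=config.width_px, depth_px=config.depth_px,
                seed=int(child[1]) + 1, noise_floor=config.noise_floor,
            )
            steps = _stress_steps(config, truth["stiffness"])
            series, _ = phantom.generate_compression_series(
                oce_spec, steps, max_lag=config.lag
            )
            strain = elastography.estimate_strain_series(
                series, lag=config.lag, window=config.window
            )
            stress = elastography.stress_from_reference(strain, series)
            smap = elastography.stiffness_map(
                strain, stress,
                stress_level=config.stress_level_kpa,
                stress_window=config.stress_window_kpa,
            )
            margin = config.lag + config.window[0]
            oce_mask = np.zeros(stack.shape, dtype=bool)
            oce_mask[ref_thickness + margin : config.depth_px - 2 * margin, :] = True
            regions = roi_stats.sample_rois(
                smap.values, oce_mask & smap.valid_mask,
                n_regions=config.n_regions,
                region_shape=config.region_shape,
                seed=np.random.default_rng(int(child[0]) + 3),
                valid_mask=smap.valid_mask,
            )
            rows += roi_stats.regions_to_rows(regions, sample_id, cls, "stiffness")
            if not rendered:
                mpl_image.imsave(
                    out / f"stiffness_{sample_id}.png",
                    render.render_stiffness(smap),
                )
                rendered = True

    table = pd.DataFrame(rows)
    table.to_csv(out / "measurements.csv", index=False)

    descriptives = []
    for (cls, modality), g in table.groupby(["tissue_class", "modality"], sort=True):
        unit = "kPa" if modality == "stiffness" else "mm^-1"
        d = roi_stats.describe(g["value"], unit=unit)
        descriptives.append({"tissue_class": cls, "modality": modality, **d})
    desc_df = pd.DataFrame(descriptives)
    desc_df.to_csv(out / "descriptives.csv", index=False)

    matrix = roi_stats.pairwise_mann_whitney(table, alpha=config.alpha)
    matrix.to_csv(out / "comparisons.csv", index=False)

    roc_summary = {}
    roc_results = {}
    present = set(config.classes)
    contrasts = []
    if diagnostics.EC_CLASSES & present and diagnostics.NON_TUMOROUS_CLASSES & present:
        contrasts.append(("ec_vs_non_tumorous", diagnostics.ec_vs_non_tumorous))
    if "EIN" in present and diagnostics.BENIGN_CLASSES & present:
        contrasts.append(("ein_vs_benign", diagnostics.ein_vs_benign))
    for name, make in contrasts:
        for modality in ("att_co", "att_cross", "stiffness"):
            spec_c = make(modality)
            spec_c = diagnostics.ContrastSpec(
                spec_c.positive_classes & present,
                spec_c.negative_classes & present,
                modality, spec_c.direction,
            )
            result = diagnostics.select_threshold(
                diagnostics.roc(table, spec_c), policy=config.threshold_policy
            )
            roc_results[(name, modality)] = result
            roc_summary[f"{name}/{modality}"] = {
                "auc": result.auc,
                "threshold": result.chosen_threshold,
                "se_pct": result.se,
                "sp_pct": result.sp,
            }
            pd.DataFrame(
                {"threshold": result.thresholds, "tpr": result.tpr, "fpr": result.fpr}
            ).to_csv(out / f"roc_{name}_{modality}.csv", index=False)
    (out / "roc_summary.json").write_text(
        json.dumps(roc_summary, indent=2, sort_keys=True)
    )

    cfg_dict = asdict(config)
    write_provenance(out / "provenance.json", cfg_dict, config.seed)

    return {
        "table": table,
        "descriptives": desc_df,
        "comparisons": matrix,
        "roc": roc_results,
        "roc_summary": roc_summary,
        "out_dir": out,
        "config_hash": config_hash(cfg_dict),
    }
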