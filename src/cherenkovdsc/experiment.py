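"""Full synthetic experiment: 6 phantoms x 3 plans x N replicates.

For every cell the pipeline generates the plan's dose map, simulates and
accumulates the gated frame stack for the phantom's skin tone, applies a
random setup perturbation (phantom removed and re-positioned), and runs the
30%-plan / 15-45%-image threshold sweep.  Replicates are then summarised per
cell and the intensity-vs-colorimetry trends fitted across phantoms.

Seeding: every random stream derives from the master seed through a
counter-based scheme keyed on fixed (phantom, plan, replicate) indices, so
adding or removing cells never shifts the streams of the remaining cells.
Acquisition noise is seeded per cell; the setup perturbation is seeded per
(plan, replicate) and therefore *shared across phantoms*, pairing the setup
error so that across-phantom comparisons isolate the optical effect of
melanin (a common-random-numbers design).  All seeds are logged in the
manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .comparison import (
    DEFAULT_SWEEP,
    ROISpec,
    SweepResult,
    difference_map,
    roi_mean_intensity,
    sweep_max_dsc,
    threshold_mask,
)
from .optics import EmissionModel, SkinToneProfile
from .regression import FitResult, GridSummary, fit_exponential_decay, fit_linear_r2, summarize_dsc_grid
from .synthetic import (
    PLAN_TYPES,
    CherenkovImage,
    DeliverySpec,
    DoseMap,
    DoseMapParams,
    accumulate_frames,
    default_delivery,
    generate_dose_map,
    make_phantom_presets,
    perturb_setup,
    simulate_family_images,
    simulate_frames,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "acquisition_seed",
    "compare_files",
    "derive_seed",
    "run_cell",
    "run_experiment",
    "setup_seed",
]

logger = logging.getLogger(__name__)

PRESET_ORDER = ("I", "II", "III", "IV", "V", "VI")
_PLAN_INDEX = {plan: i for i, plan in enumerate(PLAN_TYPES)}
_PRESET_INDEX = {name: i for i, name in enumerate(PRESET_ORDER)}

# stream tags for the counter-based seed derivation
_STREAM_ACQUISITION = 1
_STREAM_SETUP = 2


def derive_seed(master_seed: int, *key: int) -> int:
    """Derive an independent 31-bit seed from the master seed and a key."""
    ss = np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


def acquisition_seed(master_seed: int, preset_idx: int, plan_idx: int, replicate: int) -> int:
    """Frame-noise seed: one per (phantom, plan, replicate) cell."""
    return derive_seed(master_seed, _STREAM_ACQUISITION, preset_idx, plan_idx, replicate)


def setup_seed(master_seed: int, plan_idx: int, replicate: int) -> int:
    """Setup-perturbation seed: shared across phantoms within (plan, replicate)."""
    return derive_seed(master_seed, _STREAM_SETUP, plan_idx, replicate)


@dataclass
class ExperimentConfig:
    """Fully serialisable description of one synthetic experiment."""

    shape: tuple[int, int] = (256, 256)
    spacing_mm: float = 2.0
    prescription: float = 500.0
    plans: tuple[str, ...] = PLAN_TYPES
    n_replicates: int = 3
    master_seed: int = 0
    plan_fraction: float = 0.30
    sweep_start: float = 0.15
    sweep_stop: float = 0.45
    sweep_step: float = 0.01
    max_shift_px: float = 2.0
    max_rotation_deg: float = 1.0
    ambient_fraction: float = 0.01
    leakage_fraction: float = 0.01
    read_noise_fraction: float = 0.005
    n_frames: dict = field(
        default_factory=lambda: {"tangent": 60, "field_in_field": 80, "vmat": 240}
    )
    mu_factor: dict = field(
        default_factory=lambda: {"tangent": 1.0, "field_in_field": 1.0, "vmat": 2.0}
    )
    mi_ref: float = 37.0
    k_mi: float | None = None  # None -> EmissionModel default (ln 10 / 83)
    b_star: float = 17.0
    paired_acquisition: bool = True
    output_dir: str | None = None
    save_images: bool = True

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.plans = tuple(self.plans)
        unknown = [p for p in self.plans if p not in PLAN_TYPES]
        if unknown:
            raise ValueError(f"unknown plan types {unknown}; expected subset of {PLAN_TYPES}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sweep_step <= 0 or self.sweep_stop < self.sweep_start:
            raise ValueError("invalid sweep range")

    @property
    def emission_model(self) -> EmissionModel:
        if self.k_mi is None:
            return EmissionModel(mi_ref=self.mi_ref)
        return EmissionModel(mi_ref=self.mi_ref, k_mi=self.k_mi)

    @property
    def thresholds(self) -> np.ndarray:
        n = int(round((self.sweep_stop - self.sweep_start) / self.sweep_step))
        return np.round(self.sweep_start + self.sweep_step * np.arange(n + 1), 10)

    def delivery(self, plan_type: str) -> DeliverySpec:
        base = default_delivery(
            plan_type,
            prescription=self.prescription,
            ambient_fraction=self.ambient_fraction,
            leakage_fraction=self.leakage_fraction,
            read_noise_fraction=self.read_noise_fraction,
        )
        return dataclasses.replace(
            base,
            n_frames=int(self.n_frames.get(plan_type, base.n_frames)),
            mu_factor=float(self.mu_factor.get(plan_type, base.mu_factor)),
        )

    def dose_params(self) -> DoseMapParams:
        return DoseMapParams(prescription=self.prescription)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["shape"] = list(self.shape)
        d["plans"] = list(self.plans)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError("experiment config must be a YAML mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class CellResult:
    """One (phantom, plan, replicate) acquisition and its sweep."""

    image: CherenkovImage
    sweep: SweepResult
    acquisition_seed: int
    setup_seed: int


def run_cell(
    dose: DoseMap,
    profile: SkinToneProfile,
    config: ExperimentConfig,
    acq_seed: int,
    pert_seed: int,
) -> CellResult:
    """Simulate one acquisition and run the threshold-sweep comparison."""
    delivery = config.delivery(dose.plan_type)
    stack = simulate_frames(dose, profile, config.emission_model, delivery, seed=acq_seed)
    image = accumulate_frames(stack)
    image = perturb_setup(
        image,
        pert_seed,
        max_shift_px=config.max_shift_px,
        max_rotation_deg=config.max_rotation_deg,
    )
    sweep = sweep_max_dsc(
        dose, image, plan_fraction=config.plan_fraction, thresholds=config.thresholds
    )
    return CellResult(image=image, sweep=sweep, acquisition_seed=acq_seed, setup_seed=pert_seed)


@dataclass
class ExperimentResult:
    """Everything the experiment produced, in memory."""

    table: pd.DataFrame
    summary: GridSummary
    fits: dict
    manifest: dict


def _central_roi(dose: DoseMap, half_frac: float = 0.06) -> ROISpec:
    """Interior plateau ROI centred on the dose maximum (the "breast" ROI)."""
    r, c = np.unravel_index(int(np.argmax(dose.values)), dose.shape)
    h = max(2, int(round(half_frac * min(dose.shape))))
    ny, nx = dose.shape
    return ROISpec(
        row_start=max(0, r - h),
        row_stop=min(ny, r + h),
        col_start=max(0, c - h),
        col_stop=min(nx, c + h),
        label="breast",
    )


def _background_roi(shape: tuple[int, int]) -> ROISpec:
    h = max(4, min(shape) // 16)
    return ROISpec(row_start=0, row_stop=h, col_start=0, col_stop=h, label="out_of_field")


def _fit_trends(
    presets: list[SkinToneProfile],
    intensities: list[float],
) -> dict:
    """Linear (vs CIE-L) and exponential (vs MI) trend fits of the measured,
    background-corrected ROI intensities normalised to type I."""
    ref = intensities[0]
    norm = [v / ref for v in intensities]
    linear = fit_linear_r2([p.l_star for p in presets], norm)
    exponential = fit_exponential_decay([p.melanin_index for p in presets], norm)
    return {
        "normalized_intensity": dict(zip([p.fitzpatrick_type for p in presets], norm)),
        "linear_vs_cie_l": dataclasses.asdict(linear),
        "exponential_vs_mi": dataclasses.asdict(exponential),
    }


def run_experiment(config: ExperimentConfig | None = None) -> ExperimentResult:
    """Run the full synthetic study and, optionally, write all artifacts.

    Returns the replicate table, the per-cell summary, the trend fits, and a
    manifest logging every seed.  If ``config.output_dir`` is set, images,
    masks, difference maps, tables and the manifest are written there; the
    directory is created (and verified writable) before any simulation.
    """
    if config is None:
        config = ExperimentConfig()

    out: Path | None = None
    if config.output_dir is not None:
        out = Path(config.output_dir)
        try:
            out.mkdir(parents=True, exist_ok=True)
            probe = out / ".write_probe"
            probe.write_text("")
            probe.unlink()
        except OSError as exc:
            raise OSError(f"output directory {out} is not writable: {exc}") from exc

    presets = make_phantom_presets(b_star=config.b_star)
    model = config.emission_model
    dose_maps = {
        plan: generate_dose_map(
            plan, shape=config.shape, spacing_mm=config.spacing_mm, params=config.dose_params()
        )
        for plan in config.plans
    }

    rows: list[dict] = []
    cell_seeds: list[dict] = []
    # measured tone-trend intensities come from the first configured plan,
    # replicate 0 (one image per phantom, as in a single calibration field)
    trend_plan = config.plans[0]
    trend_intensities: dict[str, float] = {}

    def handle_cell(preset, plan, rep, image, acq_seed, pert_seed) -> None:
        dose = dose_maps[plan]
        sweep = sweep_max_dsc(
            dose, image, plan_fraction=config.plan_fraction, thresholds=config.thresholds
        )
        rows.append(
            {
                "skin_type": preset.fitzpatrick_type,
                "melanin_index": preset.melanin_index,
                "plan": plan,
                "replicate": rep,
                "max_dsc": sweep.max_dsc,
                "argmax_threshold": sweep.argmax_threshold,
                "acquisition_seed": acq_seed,
                "setup_seed": pert_seed,
            }
        )
        cell_seeds.append(
            {
                "skin_type": preset.fitzpatrick_type,
                "plan": plan,
                "replicate": rep,
                "acquisition_seed": acq_seed,
                "setup_seed": pert_seed,
            }
        )
        logger.info(
            "cell %s/%s rep %d: max DSC %.4f at image threshold %.2f",
            preset.fitzpatrick_type, plan, rep, sweep.max_dsc, sweep.argmax_threshold,
        )
        logger.debug("sweep curve: %s", sweep.to_dict())

        if plan == trend_plan and rep == 0:
            roi = _central_roi(dose)
            bg_roi = _background_roi(dose.shape)
            signal = roi_mean_intensity(image, roi).mean
            background = roi_mean_intensity(image, bg_roi).mean
            trend_intensities[preset.fitzpatrick_type] = max(signal - background, 1e-12)

        if out is not None and config.save_images:
            stem = f"{preset.fitzpatrick_type}_{plan}_rep{rep}"
            _io.write_grid_tiff(out / f"image_{stem}.tif", image.values, config.spacing_mm)
            sweep.write_json(out / f"sweep_{stem}.json")
            plan_mask = threshold_mask(dose.values, config.plan_fraction, "raw_max")
            image_mask = threshold_mask(
                image.values, sweep.argmax_threshold, "robust_max", "image"
            )
            _io.write_difference_png(
                out / f"diff_{stem}.png", difference_map(plan_mask, image_mask)
            )

    for plan in config.plans:
        plan_idx = _PLAN_INDEX[plan]
        dose = dose_maps[plan]
        delivery = config.delivery(plan)
        for rep in range(config.n_replicates):
            pert = setup_seed(config.master_seed, plan_idx, rep)
            if config.paired_acquisition:
                # one coupled draw for all six tones: shot noise and setup
                # error are shared so across-tone contrasts are paired
                family_seed = acquisition_seed(config.master_seed, 0, plan_idx, rep)
                images = simulate_family_images(
                    dose, presets, config.emission_model, delivery, seed=family_seed
                )
                for preset in presets:
                    image = perturb_setup(
                        images[preset.fitzpatrick_type],
                        pert,
                        max_shift_px=config.max_shift_px,
                        max_rotation_deg=config.max_rotation_deg,
                    )
                    handle_cell(preset, plan, rep, image, family_seed, pert)
            else:
                for preset in presets:
                    p_idx = _PRESET_INDEX[preset.fitzpatrick_type]
                    acq = acquisition_seed(config.master_seed, p_idx, plan_idx, rep)
                    cell = run_cell(dose, preset, config, acq, pert)
                    handle_cell(preset, plan, rep, cell.image, acq, pert)

    table = pd.DataFrame(rows)
    summary = summarize_dsc_grid(table)
    fits = _fit_trends(
        presets, [trend_intensities[p.fitzpatrick_type] for p in presets]
    )
    manifest = {
        "config": config.to_dict(),
        "n_cells": len(cell_seeds),
        "cells": cell_seeds,
    }

    if out is not None:
        for plan, dose in dose_maps.items():
            _io.write_grid_tiff(out / f"dose_{plan}.tif", dose.values, config.spacing_mm)
        table.to_csv(out / "experiment_table.csv", index=False)
        summary.per_cell.to_csv(out / "dsc_summary.csv", index=False)
        (out / "trend_fits.json").write_text(json.dumps(fits, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        config.to_yaml(out / "config.yaml")

    return ExperimentResult(table=table, summary=summary, fits=fits, manifest=manifest)


def compare_files(
    plan_path,
    image_path,
    out_dir=None,
    plan_fraction: float = 0.30,
    thresholds=None,
) -> SweepResult:
    """Run the threshold-sweep comparison on two co-registered grid files.

    Accepts TIFF (with optional JSON sidecar), PNG or CSV grids.  Writes the
    sweep result as JSON and the best-threshold difference map as PNG when
    ``out_dir`` is given.  Raises on shape mismatch before writing anything.
    """
    plan_values, _ = _io.read_grid(plan_path)
    image_values, _ = _io.read_grid(image_path)
    if plan_values.shape != image_values.shape:
        raise ValueError(
            f"shape mismatch: plan {plan_values.shape} vs image {image_values.shape}"
        )
    sweep = sweep_max_dsc(
        plan_values, image_values, plan_fraction=plan_fraction, thresholds=thresholds
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sweep.write_json(out / "sweep_result.json")
        sweep.write_csv(out / "sweep_result.csv")
        plan_mask = threshold_mask(plan_values, plan_fraction, "raw_max")
        image_mask = threshold_mask(
            image_values, sweep.argmax_threshold, "robust_max", "image"
        )
        _io.write_difference_png(
            out / "difference_map.png", difference_map(plan_mask, image_mask)
        )
    return sweep
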