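"""Synthetic phenomics experiments with known ground truth.

Emulates a greenhouse pot experiment: G genotypes x 2 water treatments
(well-watered at 80% of field capacity, stressed at 50%) x R replicate pots,
imaged daily. Latent per-pot shoot biomass follows logistic growth

    B(d) = K / (1 + ((K - B0)/B0) * exp(-r * d))

with rate r = base_rate * exp(genotype effect) * (treatment multiplier if
stressed); genotype effects are N(0, genotype_rate_sd^2) on the log-rate
scale. An exponential mode (B = B0 * exp(r d)) is available for analytic
growth-rate tests. Daily water loss is transpiration proportional to biomass
plus constant soil evaporation; pots are weighed and re-watered to the
treatment's target weight each day, producing a watering ledger. Image
features are noisy allometric functions of latent biomass (projected area
~ B^(2/3), linear extents ~ B^(1/3)); NIR mean gray is inversely affine in
tissue water fraction. All randomness flows from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    BiomassTable,
    ExperimentDesign,
    FeatureTable,
    PlantKey,
    Treatment,
    WateringLedger,
)
from .image_features import GEOMETRY_FEATURES, NIR_FEATURES, VIEWS

__all__ = ["SimConfig", "GroundTruth", "simulate_experiment", "render_plant_images"]


@dataclass
class SimConfig:
    """Study-scale defaults: 24 genotypes x 2 treatments x 3 reps, daily
    observation for 26 days from stress imposition (day 0)."""

    n_genotypes: int = 24
    n_reps: int = 3
    n_days: int = 26
    growth_model: str = "logistic"  # or "exponential"
    base_rate: float = 0.12  # d^-1, well-watered log-scale growth rate
    treatment_growth_multiplier: float = 0.5  # stressed rate fraction
    genotype_rate_sd: float = 0.15  # SD of per-genotype log-rate effects
    genotype_wue_sd: float = 0.10  # SD of per-genotype log transpiration-rate
    # effects; genotypes genuinely differ in water used per unit biomass
    residual_sd: float = 0.05  # per-observation biomass noise (fraction)
    feature_noise_sd: float = 0.05  # lognormal sigma on image features
    initial_biomass_g: float = 0.5
    max_biomass_g: float = 40.0
    # allometric powers linking image features to biomass: leafy seedlings
    # keep a near-constant specific leaf area, so projected area is close
    # to proportional to shoot mass (mild self-shading keeps it sublinear)
    area_power: float = 0.9
    length_power: float = 0.35
    transpiration_coeff: float = 40.0  # ml water per g biomass per day
    evaporation_ml_per_day: float = 10.0
    water_noise_sd: float = 0.03  # fraction of daily water loss
    fc_target: dict = field(
        default_factory=lambda: {"control": 0.8, "stressed": 0.5}
    )
    tare_g: float = 500.0
    dry_soil_weight_g: float = 14000.0
    field_capacity_g: float = 3500.0
    nir_dry_gray: float = 230.0  # mean gray of fully dry tissue
    nir_gray_span: float = 100.0  # gray drop from dry to saturated tissue
    # log-rate boost for the first genotype, in units of genotype_rate_sd
    # (a "planted" fast grower for recovery experiments)
    planted_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 2 or self.n_reps < 1 or self.n_days < 2:
            raise ValueError("need >= 2 genotypes, >= 1 rep, >= 2 days")
        if not (0 < self.treatment_growth_multiplier <= 1):
            raise ValueError("treatment_growth_multiplier must be in (0, 1]")
        for name in (
            "base_rate",
            "initial_biomass_g",
            "max_biomass_g",
            "transpiration_coeff",
            "field_capacity_g",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.growth_model not in ("logistic", "exponential"):
            raise ValueError("growth_model must be 'logistic' or 'exponential'")


@dataclass
class GroundTruth:
    """Latent quantities the pipeline is later asked to recover."""

    biomass: pd.DataFrame  # plant_id, day, biomass_g (noise-free latent)
    observed_biomass: pd.DataFrame  # plant_id, day, biomass_g (with noise)
    rates: dict  # plant_id -> true growth rate r (d^-1)
    genotype_effects: dict  # genotype -> log-rate effect
    genotype_wue_effects: dict  # genotype -> log transpiration-rate effect
    water_use: pd.DataFrame  # plant_id, day, wu_ml (true daily loss, day >= 1)
    water_fraction: pd.DataFrame  # plant_id, day, tissue water fraction
    sigma2_log_rate: float  # generative genotype variance on log-rate scale
    config: dict


def _latent_trajectory(cfg: SimConfig, r: float, days: np.ndarray) -> np.ndarray:
    b0, k = cfg.initial_biomass_g, cfg.max_biomass_g
    if cfg.growth_model == "exponential":
        return b0 * np.exp(r * days)
    return k / (1.0 + ((k - b0) / b0) * np.exp(-r * days))


# Per-view allometric scales: top view sees the canopy (largest area),
# side views see the profile. Areas in px, lengths in px.
_VIEW_AREA_SCALE = {"top": 2000.0, "side0": 1200.0, "side90": 1150.0}
_VIEW_HEIGHT_SCALE = {"top": 55.0, "side0": 80.0, "side90": 78.0}
_VIEW_ASPECT = {"top": 1.1, "side0": 1.6, "side90": 1.55}


def _view_features(
    rng, view: str, b: float, water_frac: float, sd: float,
    area_power: float = 0.9, length_power: float = 0.35,
) -> dict:
    """Noisy monotone feature set for one view at latent biomass b (grams)."""

    def jitter(x):
        return x * math.exp(rng.normal(0.0, sd))

    area = jitter(_VIEW_AREA_SCALE[view] * b**area_power)
    height = jitter(_VIEW_HEIGHT_SCALE[view] * b**length_power * _VIEW_ASPECT[view])
    width = jitter(_VIEW_HEIGHT_SCALE[view] * b**length_power)
    solidity = min(0.98, max(0.4, 0.80 + rng.normal(0.0, 0.02)))
    hull_area = area / solidity
    # leafy outlines are long relative to a disk of the same area
    perimeter = jitter(3.2 * math.sqrt(area) * 2.0)
    compactness = 4.0 * math.pi * area / perimeter**2
    bbox_area = width * height
    feats = {
        "projected_area": area,
        "convex_hull_area": hull_area,
        "perimeter": perimeter,
        "bbox_width": width,
        "bbox_height": height,
        "bbox_area": bbox_area,
        "max_caliper_length": 1.15 * max(width, height),
        "equivalent_diameter": math.sqrt(4.0 * area / math.pi),
        "compactness": min(1.0, compactness),
        "eccentricity": min(0.99, max(0.1, 0.7 + rng.normal(0.0, 0.03))),
        "centroid_y": 0.55 * height,
        "hull_solidity": solidity,
        "extent": min(1.0, area / bbox_area) if bbox_area > 0 else 0.0,
        "aspect_ratio": height / width if width > 0 else 0.0,
        "nir_mean_gray": 0.0,  # filled by caller
    }
    return feats


def simulate_experiment(
    config: SimConfig,
) -> tuple[ExperimentDesign, FeatureTable, WateringLedger, BiomassTable, GroundTruth]:
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    days = np.arange(cfg.n_days)

    genotypes = [f"G{i + 1:02d}" for i in range(cfg.n_genotypes)]
    g_eff = {g: rng.normal(0.0, cfg.genotype_rate_sd) for g in genotypes}
    if cfg.planted_effect_sd:
        g_eff[genotypes[0]] = cfg.planted_effect_sd * cfg.genotype_rate_sd
    w_eff = {g: rng.normal(0.0, cfg.genotype_wue_sd) for g in genotypes}

    plants: list[PlantKey] = []
    for g in genotypes:
        for trt in (Treatment.WELL_WATERED, Treatment.WATER_STRESSED):
            tag = "WW" if trt is Treatment.WELL_WATERED else "WS"
            for rep in range(1, cfg.n_reps + 1):
                plants.append(PlantKey(f"{g}-{tag}-{rep}", g, trt, rep))
    design = ExperimentDesign(plants=plants, days=list(days))

    feat_rows, ledger_rows, bio_rows = [], [], []
    truth_bio, truth_obs, truth_wu, truth_wf = [], [], [], []
    rates = {}

    fc = cfg.field_capacity_g
    base_weight = cfg.tare_g + cfg.dry_soil_weight_g

    for p in plants:
        mult = (
            1.0
            if p.treatment is Treatment.WELL_WATERED
            else cfg.treatment_growth_multiplier
        )
        r = cfg.base_rate * math.exp(g_eff[p.genotype]) * mult
        rates[p.plant_id] = r
        latent = _latent_trajectory(cfg, r, days)
        obs = latent * np.exp(rng.normal(0.0, cfg.residual_sd, size=latent.shape))

        frac_key = "control" if p.treatment is Treatment.WELL_WATERED else "stressed"
        target = base_weight + cfg.fc_target[frac_key] * fc

        # tissue water fraction: well-watered plants stay hydrated; stressed
        # plants dry down over the experiment
        if p.treatment is Treatment.WELL_WATERED:
            wf = np.full(cfg.n_days, 0.85)
        else:
            wf = 0.85 - 0.25 * days / max(1, cfg.n_days - 1)
        wf = np.clip(wf + rng.normal(0.0, 0.01, size=wf.shape), 0.0, 1.0)

        weight_after_prev = target  # pot starts at its target weight (day 0)
        for i, d in enumerate(days):
            if i == 0:
                before, after, added = target, target, 0.0
            else:
                loss = (
                    cfg.transpiration_coeff
                    * math.exp(w_eff[p.genotype])
                    * latent[i - 1]
                    + cfg.evaporation_ml_per_day
                )
                loss *= math.exp(rng.normal(0.0, cfg.water_noise_sd))
                before = weight_after_prev - loss
                after = max(target, before)
                added = after - before
                truth_wu.append((p.plant_id, int(d), loss))
            ledger_rows.append((p.plant_id, int(d), before, after, added))
            weight_after_prev = after

            row = {"plant_id": p.plant_id, "day": int(d)}
            for view in VIEWS:
                f = _view_features(
                    rng, view, obs[i], wf[i], cfg.feature_noise_sd,
                    cfg.area_power, cfg.length_power,
                )
                gray = cfg.nir_dry_gray - cfg.nir_gray_span * wf[i]
                f["nir_mean_gray"] = float(
                    np.clip(gray + rng.normal(0.0, 2.0), 0.0, 255.0)
                )
                row.update({f"{k}.{view}": v for k, v in f.items()})
            feat_rows.append(row)

            truth_bio.append((p.plant_id, int(d), float(latent[i])))
            truth_obs.append((p.plant_id, int(d), float(obs[i])))
            truth_wf.append((p.plant_id, int(d), float(wf[i])))

        fresh = float(
            latent[-1] * math.exp(rng.normal(0.0, cfg.residual_sd))
        )
        dry = 0.15 * fresh
        bio_rows.append((p.plant_id, fresh, dry, int(days[-1])))

    features = FeatureTable(pd.DataFrame(feat_rows))
    ledger = WateringLedger(
        pd.DataFrame(
            ledger_rows,
            columns=[
                "pot_id",
                "day",
                "weight_before_g",
                "weight_after_g",
                "water_added_ml",
            ],
        ),
        tare_g=cfg.tare_g,
        dry_soil_weight_g=cfg.dry_soil_weight_g,
    )
    biomass = BiomassTable(
        pd.DataFrame(
            bio_rows,
            columns=["plant_id", "fresh_weight_g", "dry_weight_g", "harvest_day"],
        )
    )
    truth = GroundTruth(
        biomass=pd.DataFrame(truth_bio, columns=["plant_id", "day", "biomass_g"]),
        observed_biomass=pd.DataFrame(
            truth_obs, columns=["plant_id", "day", "biomass_g"]
        ),
        rates=rates,
        genotype_effects=g_eff,
        genotype_wue_effects=w_eff,
        water_use=pd.DataFrame(truth_wu, columns=["plant_id", "day", "wu_ml"]),
        water_fraction=pd.DataFrame(
            truth_wf, columns=["plant_id", "day", "water_fraction"]
        ),
        sigma2_log_rate=cfg.genotype_rate_sd**2,
        config=asdict(cfg),
    )
    return design, features, ledger, biomass, truth


# ---------------------------------------------------------------------------
# Image rendering: elliptical green blob stand-ins for plant silhouettes.
# ---------------------------------------------------------------------------

PLANT_RGB = (0, 160, 0)
BACKGROUND_RGB = (245, 245, 245)
NIR_BACKGROUND = 30


def _ellipse_mask(canvas: tuple[int, int], area_px: float, aspect: float) -> np.ndarray:
    h, w = canvas
    if area_px <= 0:
        return np.zeros((h, w), dtype=bool)
    # semi-axes solving pi*a*b = area with b/a = aspect (vertical/horizontal)
    a = math.sqrt(area_px / (math.pi * aspect))
    b = a * aspect
    if 2 * b > h or 2 * a > w:
        raise ValueError(
            f"requested area {area_px:.0f}px with aspect {aspect} exceeds "
            f"canvas {canvas}"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def render_plant_images(
    area_px: dict,
    nir_gray: float,
    canvas_size: tuple[int, int] = (256, 256),
    aspect: dict | None = None,
    salt_noise: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Render RGB + NIR images for the three views of one plant-day.

    ``area_px`` maps view name -> requested projected area in pixels. The
    rendered foreground pixel count matches the request within rasterization
    error (~2%). ``salt_noise`` adds that many isolated plant-colored pixels
    outside the blob (for testing morphological cleanup). Returns a dict
    ``{view: (rgb uint8 HxWx3, nir uint8 HxW, mask bool HxW)}``.
    """
    aspect = aspect or {"top": 1.0, "side0": 1.6, "side90": 1.55}
    rng = rng or np.random.default_rng(0)
    out = {}
    for view, area in area_px.items():
        mask = _ellipse_mask(canvas_size, area, aspect.get(view, 1.0))
        rgb = np.empty((*canvas_size, 3), dtype=np.uint8)
        rgb[...] = BACKGROUND_RGB
        rgb[mask] = PLANT_RGB
        if salt_noise > 0:
            h, w = canvas_size
            placed = 0
            while placed < salt_noise:
                y, x = rng.integers(0, h), rng.integers(0, w)
                # keep speckles isolated from the blob and from each other
                y0, y1 = max(0, y - 2), min(h, y + 3)
                x0, x1 = max(0, x - 2), min(w, x + 3)
                if not mask[y0:y1, x0:x1].any() and tuple(rgb[y, x]) != PLANT_RGB:
                    rgb[y, x] = PLANT_RGB
                    placed += 1
        nir = np.full(canvas_size, NIR_BACKGROUND, dtype=np.uint8)
        nir[mask] = int(round(np.clip(nir_gray, 0, 255)))
        out[view] = (rgb, nir, mask)
    return out
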