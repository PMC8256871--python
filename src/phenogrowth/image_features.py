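"""Plant segmentation and image-feature extraction.

Segmentation follows the classic phenotyping-platform recipe: within a
region of interest, each pixel is assigned to the class (plant/background)
of its nearest reference color in RGB Euclidean distance; the plant mask is
then cleaned by erosion and dilation, small components are dropped, and the
survivors are composed into a single object. Geometric descriptors of that
silhouette, plus the mean NIR gray value under the mask, are the biomass
predictors. Higher NIR gray means higher reflectance, i.e. drier tissue.

The per-view feature registry defines 14 geometric features + 1 NIR feature;
across the three views (top, side0, side90) the geometry-only predictor set
therefore has 42 columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure, morphology

from .core_io import FeatureTable, IntegrityError

__all__ = [
    "GEOMETRY_FEATURES",
    "NIR_FEATURES",
    "VIEWS",
    "SegmentationParams",
    "PlantMask",
    "ViewFeatures",
    "segment_plant",
    "extract_geometric_features",
    "nir_mean_gray",
    "build_feature_table",
]

VIEWS = ("top", "side0", "side90")

GEOMETRY_FEATURES = (
    "projected_area",
    "convex_hull_area",
    "perimeter",
    "bbox_width",
    "bbox_height",
    "bbox_area",
    "max_caliper_length",
    "equivalent_diameter",
    "compactness",
    "eccentricity",
    "centroid_y",
    "hull_solidity",
    "extent",
    "aspect_ratio",
)
NIR_FEATURES = ("nir_mean_gray",)


@dataclass
class SegmentationParams:
    foreground_refs: list  # reference RGB triples for the plant class
    background_refs: list
    roi: tuple | None = None  # (row0, col0, row1, col1); None = whole image
    erosion_radius: int = 0
    dilation_radius: int = 0
    min_component_area: int = 0

    def __post_init__(self):
        if not self.foreground_refs or not self.background_refs:
            raise ValueError("need >= 1 reference color per class")
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise ValueError("morphology radii must be >= 0")


@dataclass
class PlantMask:
    mask: np.ndarray  # bool raster aligned to the source image
    plant_id: str = ""
    day: int = -1
    view: str = ""

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.pixel_count == 0


@dataclass
class ViewFeatures:
    values: dict = field(default_factory=dict)
    missing: bool = False


def segment_plant(rgb_image: np.ndarray, params: SegmentationParams) -> PlantMask:
    """Nearest-reference-color classification + morphological cleanup.

    Returns an empty PlantMask (not an error) when nothing survives; the
    caller treats that as a missing observation.
    """
    img = np.asarray(rgb_image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")

    if params.roi is not None:
        r0, c0, r1, c1 = params.roi
    else:
        r0, c0, r1, c1 = 0, 0, img.shape[0], img.shape[1]
    window = img[r0:r1, c0:c1]

    fg = np.asarray(params.foreground_refs, dtype=float)  # (kf, 3)
    bg = np.asarray(params.background_refs, dtype=float)  # (kb, 3)
    px = window.reshape(-1, 3)
    d_fg = ((px[:, None, :] - fg[None]) ** 2).sum(-1).min(1)
    d_bg = ((px[:, None, :] - bg[None]) ** 2).sum(-1).min(1)
    local = (d_fg < d_bg).reshape(window.shape[:2])

    if params.erosion_radius > 0:
        local = morphology.erosion(
            local, morphology.disk(params.erosion_radius)
        )
    if params.dilation_radius > 0:
        local = morphology.dilation(
            local, morphology.disk(params.dilation_radius)
        )
    if params.min_component_area > 0:
        local = morphology.remove_small_objects(
            local, min_size=params.min_component_area
        )

    mask = np.zeros(img.shape[:2], dtype=bool)
    mask[r0:r1, c0:c1] = local
    return PlantMask(mask=mask)


def extract_geometric_features(mask: PlantMask) -> ViewFeatures:
    """Silhouette geometry of the composed plant object.

    Compactness is the isoperimetric ratio 4*pi*A/P^2. All features are in
    pixel units (no distance calibration).
    """
    if mask.empty:
        return ViewFeatures(
            values={k: np.nan for k in GEOMETRY_FEATURES}, missing=True
        )
    labeled = mask.mask.astype(np.uint8)
    props = measure.regionprops(labeled)[0]
    area = float(props.area)
    perimeter = float(props.perimeter) if props.perimeter > 0 else 1.0
    r0, c0, r1, c1 = props.bbox
    width, height = float(c1 - c0), float(r1 - r0)
    compactness = min(1.0, 4.0 * np.pi * area / perimeter**2)
    values = {
        "projected_area": area,
        "convex_hull_area": float(props.area_convex),
        "perimeter": perimeter,
        "bbox_width": width,
        "bbox_height": height,
        "bbox_area": width * height,
        "max_caliper_length": float(props.feret_diameter_max),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "compactness": compactness,
        "eccentricity": float(props.eccentricity),
        "centroid_y": float(props.centroid[0]),
        "hull_solidity": float(props.solidity),
        "extent": float(props.extent),
        "aspect_ratio": height / width if width > 0 else np.nan,
    }
    return ViewFeatures(values=values)


def nir_mean_gray(nir_image: np.ndarray, mask: PlantMask) -> float:
    """Mean 8-bit NIR intensity under the RGB-derived plant mask."""
    if mask.empty:
        return float("nan")
    nir = np.asarray(nir_image, dtype=float)
    if nir.shape != mask.mask.shape:
        raise ValueError("NIR image not aligned with mask")
    return float(nir[mask.mask].mean())


def build_feature_table(per_view: list[dict]) -> FeatureTable:
    """Assemble per-view feature dicts into one row per (plant_id, day).

    ``per_view`` entries: {"plant_id", "day", "view", "features": ViewFeatures,
    "nir_mean_gray": float (optional)}. Missing views leave their columns NaN;
    conflicting duplicates raise.
    """
    rows: dict[tuple, dict] = {}
    for entry in per_view:
        view = entry["view"]
        if view not in VIEWS:
            raise ValueError(f"unknown view {view!r}; expected one of {VIEWS}")
        key = (str(entry["plant_id"]), int(entry["day"]))
        row = rows.setdefault(key, {"plant_id": key[0], "day": key[1]})
        vf: ViewFeatures = entry["features"]
        for name, value in vf.values.items():
            col = f"{name}.{view}"
            if col in row and not (
                np.isnan(row[col]) or np.isclose(row[col], value, equal_nan=True)
            ):
                raise IntegrityError(
                    f"conflicting duplicate for {key} column {col}"
                )
            row[col] = value
        if "nir_mean_gray" in entry:
            row[f"nir_mean_gray.{view}"] = entry["nir_mean_gray"]

    all_cols = ["plant_id", "day"] + [
        f"{feat}.{view}" for view in VIEWS for feat in (*GEOMETRY_FEATURES, *NIR_FEATURES)
    ]
    df = pd.DataFrame(list(rows.values()))
    for c in all_cols:
        if c not in df.columns:
            df[c] = np.nan
    return FeatureTable(df[all_cols])
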