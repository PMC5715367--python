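"""The four end-to-end assay pipelines.

Each pipeline maps plate images plus a layout to one record per detected
seedling, applying the assay's printed segmentation rules:

* salt - VIS saturation rule (S > 49 under stress, S > 74 under standard
  growth) AND a gray-band filter keeping gray in [0, 140] or [150, 255];
  FLUO S > 20; 16 hue classes per modality joined into a 32-length color
  profile; survival called downstream by two-group clustering.
* arsenic - VIS R < 254, G < 246, B < 254 against the backlit near-white
  field; FLUO S > 50; germination (seed vs seedling) called downstream.
* freezing - VIS-only B < 127 AND (R - B)/(R + B) > 0.20; objects with area
  in (10000, 40000) px; 32 hue classes and the yellowish damage index.
* phosphate - VIS-only; mean auto-local threshold on gray, embossed-grid
  removal (horizontal runs > 50 px, vertical > 240 px, 1 px erosion, border
  row bands 50-260 and 1698-1798), root objects (area > 109,
  circularity < 0.70, distance < 145) merged with shoot objects
  (23 < Bri < 138, area > 10, circularity > 0.099, distance < 130); the
  root-length proxy is the merged plant's major axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import imgproc, plants, screen
from .imgproc import (
    Assay,
    Clause,
    Condition,
    Modality,
    PixelRule,
    PlateImage,
)
from .plants import ObjectFilterSpec, PlateLayout

logger = logging.getLogger(__name__)

__all__ = [
    "AssayConfig",
    "default_config",
    "run_salt_plate",
    "run_arsenic_plate",
    "run_freezing_plate",
    "run_phosphate_plate",
    "segment_plate",
    "records_to_frame",
    "analyze_records",
]


@dataclass
class AssayConfig:
    """Per-assay constants; the defaults reproduce every printed threshold."""

    assay: Assay
    pixel_rules: dict  # keyed (modality, condition) or modality
    filters: dict  # keyed by modality or part name
    n_hue_classes: int = 16
    green_classes: tuple[int, ...] = screen.GREEN_CLASSES_16
    yellow_classes: tuple[int, ...] = plants.YELLOW_CLASSES_32
    clustering_linkage: str = "average"
    test: str = "fisher"  # fisher_on_groups | anova_on_major_axis
    seeds_per_plate: int = 36
    replicates: int = 3
    local_threshold_radius: int = 15
    local_threshold_offset: float = 0.0
    grid_max_h_run: int = 50
    grid_max_v_run: int = 240
    grid_erode_px: int = 1
    grid_row_bands: tuple = ((50, 260), (1698, 1798))


def _salt_vis_rule(condition: Condition) -> PixelRule:
    s_min = 74 if condition == Condition.STANDARD else 49
    return PixelRule.of(
        Clause("S", "gt", s_min),
        Clause("gray", "in", ((0, 140), (150, 255))),
    )


def default_config(assay: Assay | str) -> AssayConfig:
    assay = Assay(assay)
    if assay == Assay.SALT:
        return AssayConfig(
            assay=assay,
            pixel_rules={
                (Modality.VIS, Condition.STRESS): _salt_vis_rule(Condition.STRESS),
                (Modality.VIS, Condition.STANDARD): _salt_vis_rule(Condition.STANDARD),
                Modality.FLUO: PixelRule.of(Clause("S", "gt", 20)),
            },
            filters={
                Modality.VIS: ObjectFilterSpec(min_area=40, max_dist_to_center=130),
                Modality.FLUO: ObjectFilterSpec(min_area=20),
            },
            test="fisher",
            seeds_per_plate=36,
            replicates=3,
        )
    if assay == Assay.ARSENIC:
        return AssayConfig(
            assay=assay,
            pixel_rules={
                Modality.VIS: PixelRule.of(
                    Clause("R", "lt", 254),
                    Clause("G", "lt", 246),
                    Clause("B", "lt", 254),
                ),
                Modality.FLUO: PixelRule.of(Clause("S", "gt", 50)),
            },
            filters={
                Modality.VIS: ObjectFilterSpec(
                    min_area=10, circ_min=0.099, max_dist_to_center=130
                ),
                Modality.FLUO: ObjectFilterSpec(min_area=20),
            },
            test="fisher",
            seeds_per_plate=36,
            replicates=3,
        )
    if assay == Assay.FREEZING:
        return AssayConfig(
            assay=assay,
            pixel_rules={
                Modality.VIS: PixelRule.of(
                    Clause("B", "lt", 127),
                    Clause("normdiff_RB", "gt", 0.20),
                )
            },
            filters={Modality.VIS: ObjectFilterSpec(min_area=10000, max_area=40000)},
            n_hue_classes=32,
            test="fisher",
            seeds_per_plate=60,
            replicates=3,
        )
    return AssayConfig(
        assay=Assay.PHOSPHATE,
        pixel_rules={
            "shoot": PixelRule.of(Clause("Bri", "gt", 23), Clause("Bri", "lt", 138))
        },
        filters={
            "root": ObjectFilterSpec(min_area=109, circ_max=0.70, max_dist_to_center=145),
            "shoot": ObjectFilterSpec(
                min_area=10, circ_min=0.099, max_dist_to_center=130
            ),
        },
        test="anova",
        seeds_per_plate=6,
        replicates=2,
    )


def _vis_rule(config: AssayConfig, condition: Condition) -> PixelRule:
    rules = config.pixel_rules
    if (Modality.VIS, condition) in rules:
        return rules[(Modality.VIS, condition)]
    return rules[Modality.VIS]


def _base_record(plate: PlateImage, layout: PlateLayout, cell, line) -> dict:
    return {
        "assay": plate.assay.value,
        "condition": plate.condition.value,
        "plate_id": plate.plate_id,
        "cell": cell,
        "line": line,
    }


def _hue_columns(prefix: str, fractions: np.ndarray) -> dict:
    return {f"{prefix}_hue_{i:02d}": float(v) for i, v in enumerate(fractions)}


def _run_two_modality(
    vis: PlateImage,
    fluo: PlateImage,
    layout: PlateLayout,
    config: AssayConfig,
) -> list[dict]:
    if vis is None or fluo is None:
        raise ValueError(
            f"{config.assay.value} assay needs both VIS and FLUO images"
        )
    condition = vis.condition
    k = config.n_hue_classes

    vis_hsb = imgproc.rgb_to_hsb(vis)
    vis_gray = imgproc.to_gray(vis)
    vis_mask = imgproc.apply_pixel_rule(
        vis, _vis_rule(config, condition), cache={"hsb": vis_hsb, "gray": vis_gray}
    )
    vis_comps = imgproc.label_components(vis_mask)
    vis_comps = plants.filter_objects(vis_comps, config.filters[Modality.VIS], layout)
    vis_by_cell = plants.select_largest_per_cell(vis_comps, layout)

    fluo_hsb = imgproc.rgb_to_hsb(fluo)
    fluo_gray = imgproc.to_gray(fluo)
    fluo_mask = imgproc.apply_pixel_rule(
        fluo, config.pixel_rules[Modality.FLUO], cache={"hsb": fluo_hsb}
    )
    fluo_comps = imgproc.label_components(fluo_mask)
    fluo_comps = plants.filter_objects(
        fluo_comps, config.filters[Modality.FLUO], layout
    )
    fluo_by_cell = plants.select_largest_per_cell(fluo_comps, layout)

    records = []
    for cell in sorted(set(vis_by_cell) | set(fluo_by_cell)):
        vc = vis_by_cell.get(cell)
        fc = fluo_by_cell.get(cell)
        rec = _base_record(vis, layout, cell, layout.line_of(cell))
        primary = vc if vc is not None else fc
        gray = vis_gray if vc is not None else fluo_gray
        rec.update(plants.compute_morphology(primary, gray).as_dict())
        vis_frac = (
            plants.hue_class_histogram(vc, vis_hsb, k)
            if vc is not None
            else np.zeros(k)
        )
        fluo_frac = (
            plants.hue_class_histogram(fc, fluo_hsb, k)
            if fc is not None
            else np.zeros(k)
        )
        rec.update(_hue_columns("vis", vis_frac))
        rec.update(_hue_columns("fluo", fluo_frac))
        rec["vis_missing"] = vc is None
        rec["fluo_missing"] = fc is None
        records.append(rec)
    return records


def run_salt_plate(
    vis: PlateImage,
    fluo: PlateImage,
    layout: PlateLayout,
    config: AssayConfig | None = None,
) -> list[dict]:
    """Salt-assay pipeline: one record per detected seedling with the joined
    16 + 16 hue-class color profile and the eight shape features."""
    return _run_two_modality(vis, fluo, layout, config or default_config(Assay.SALT))


def run_arsenic_plate(
    vis: PlateImage,
    fluo: PlateImage,
    layout: PlateLayout,
    config: AssayConfig | None = None,
) -> list[dict]:
    """Arsenic-assay pipeline (germination phenotype; seeds stay brown and
    dark under fluorescence, seedlings green and strongly fluorescent)."""
    return _run_two_modality(
        vis, fluo, layout, config or default_config(Assay.ARSENIC)
    )


def run_freezing_plate(
    vis: PlateImage,
    layout: PlateLayout,
    config: AssayConfig | None = None,
) -> list[dict]:
    """Freezing-assay pipeline: large objects only, 32 hue classes, and the
    yellowish damage fraction with the > 50% damaged call."""
    config = config or default_config(Assay.FREEZING)
    hsb = imgproc.rgb_to_hsb(vis)
    gray = imgproc.to_gray(vis)
    mask = imgproc.apply_pixel_rule(vis, _vis_rule(config, vis.condition))
    comps = imgproc.label_components(mask)
    comps = plants.filter_objects(comps, config.filters[Modality.VIS], layout)
    records = []
    for comp in comps:
        # round plates carry no grid; the nearest layout region supplies the
        # line identity but no exclusive cell assignment
        d = np.hypot(
            layout.cell_centers[:, 0] - comp.centroid[0],
            layout.cell_centers[:, 1] - comp.centroid[1],
        )
        region = int(np.argmin(d))
        rec = _base_record(vis, layout, None, layout.line_of(region))
        rec.update(plants.compute_morphology(comp, gray).as_dict())
        frac = plants.hue_class_histogram(comp, hsb, config.n_hue_classes)
        rec.update(_hue_columns("vis", frac))
        damage, damaged = plants.yellow_damage_fraction(
            comp, hsb, config.yellow_classes, config.n_hue_classes
        )
        rec["damage_fraction"] = damage
        rec["damaged"] = damaged
        records.append(rec)
    return records


def run_phosphate_plate(
    vis: PlateImage,
    layout: PlateLayout,
    config: AssayConfig | None = None,
) -> list[dict]:
    """Phosphate-assay pipeline: local-mean dark-object mask, grid-artifact
    removal, root/shoot object rules, shoot-root merge, and the major-axis
    root-length proxy."""
    config = config or default_config(Assay.PHOSPHATE)
    gray = imgproc.to_gray(vis)
    dark = imgproc.local_mean_threshold(
        gray, radius=config.local_threshold_radius, offset=config.local_threshold_offset
    )
    h = vis.shape[0]
    bands = [(lo, hi) for lo, hi in config.grid_row_bands if lo < h]
    dark = imgproc.remove_grid_artifacts(
        dark,
        max_h_run=config.grid_max_h_run,
        max_v_run=config.grid_max_v_run,
        erode_px=config.grid_erode_px,
        excluded_row_bands=bands,
    )
    root_comps = plants.filter_objects(
        imgproc.label_components(dark), config.filters["root"], layout
    )
    shoot_mask = imgproc.apply_pixel_rule(vis, config.pixel_rules["shoot"])
    shoot_comps = plants.filter_objects(
        imgproc.label_components(shoot_mask), config.filters["shoot"], layout
    )
    shoot_by_cell = plants.select_largest_per_cell(shoot_comps, layout)
    merged = plants.merge_shoot_root(
        sorted(shoot_by_cell.values(), key=lambda c: c.label), root_comps, layout
    )
    records = []
    for plant in merged:
        cell = plant.cell
        line = layout.line_of(cell) if cell is not None else "unknown"
        plant.line_id = line
        rec = _base_record(vis, layout, cell, line)
        rec.update(plants.compute_morphology(plant, gray).as_dict())
        rec["root_detected"] = "root" in plant.parts
        records.append(rec)
    return records


def segment_plate(
    images: dict,
    layout: PlateLayout,
    config: AssayConfig | None = None,
    assay: Assay | str | None = None,
) -> list[dict]:
    """Dispatch a plate (dict modality -> PlateImage) to its assay pipeline."""
    vis = images.get(Modality.VIS) or images.get("VIS")
    if vis is None:
        raise ValueError("a VIS image is required for every assay")
    assay = Assay(assay) if assay is not None else vis.assay
    config = config or default_config(assay)
    fluo = images.get(Modality.FLUO) or images.get("FLUO")
    if assay == Assay.SALT:
        return run_salt_plate(vis, fluo, layout, config)
    if assay == Assay.ARSENIC:
        return run_arsenic_plate(vis, fluo, layout, config)
    if assay == Assay.FREEZING:
        return run_freezing_plate(vis, layout, config)
    return run_phosphate_plate(vis, layout, config)


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(records)


def analyze_records(
    records: pd.DataFrame,
    assay: Assay | str,
    wild_type: str = "Col-0",
    config: AssayConfig | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Main-trait statistics for one condition's records.

    Salt/arsenic: two-group clustering of the joined color profiles defines
    alive (germinated) vs dead (seed); freezing: the rule-based damaged
    call; each is tabulated per line and tested with Fisher's exact test
    against wild type.  Phosphate: one-way ANOVA on the major axis.  BH
    adjustment across lines.  Returns (per-line results, augmented records).
    """
    assay = Assay(assay)
    config = config or default_config(assay)
    records = records.copy()
    if assay in (Assay.SALT, Assay.ARSENIC):
        k = config.n_hue_classes
        cols = [f"vis_hue_{i:02d}" for i in range(k)] + [
            f"fluo_hue_{i:02d}" for i in range(k)
        ]
        profiles = records[cols].to_numpy(float)
        grouping = screen.two_group_color_clustering(
            profiles,
            green_classes=config.green_classes,
            linkage=config.clustering_linkage,
        )
        records["group"] = grouping.labels
        records["alive"] = grouping.alive
        good = records["alive"]
    elif assay == Assay.FREEZING:
        good = ~records["damaged"].astype(bool)
        records["alive"] = good
    else:
        tab = records.rename(columns={"major_axis": "value"})[["line", "value"]]
        results = screen.line_significance(
            tab, test="anova", wild_type=wild_type, alpha=alpha
        )
        return results, records
    counts = (
        pd.DataFrame({"line": records["line"], "good": good.astype(bool)})
        .groupby("line")["good"]
        .agg(n_group1="sum", n_group2=lambda s: int((~s).sum()))
        .reset_index()
    )
    results = screen.line_significance(
        counts, test="fisher", wild_type=wild_type, alpha=alpha
    )
    return results, records
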