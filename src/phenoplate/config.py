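"""Configuration: named threshold keys, YAML round-trip, validation.

Every printed segmentation threshold is surfaced as a named key whose
default equals the published value, so a run configuration documents its own
provenance and any override is explicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assays
from .imgproc import Assay, Clause, Condition, Modality, PixelRule
from .plants import ObjectFilterSpec, PlateLayout

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "RunConfig",
    "assay_defaults",
    "build_assay_config",
    "validate_config",
    "layout_to_dict",
    "layout_from_dict",
    "save_layout",
    "load_layout",
    "write_csv",
]


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or missing paths."""


#: named threshold keys per assay; defaults are the published values
ASSAY_DEFAULTS: dict[str, dict] = {
    "salt": {
        "vis_s_threshold_stress": 49,
        "vis_s_threshold_standard": 74,
        "vis_gray_band_keep": [[0, 140], [150, 255]],
        "fluo_s_threshold": 20,
        "vis_min_area": 40,
        "vis_max_dist": 130,
        "fluo_min_area": 20,
        "hue_classes": 16,
        "clustering_linkage": "average",
    },
    "arsenic": {
        "vis_r_max": 254,
        "vis_g_max": 246,
        "vis_b_max": 254,
        "fluo_s_threshold": 50,
        "vis_min_area": 10,
        "vis_circ_min": 0.099,
        "vis_max_dist": 130,
        "fluo_min_area": 20,
        "hue_classes": 16,
        "clustering_linkage": "average",
    },
    "freezing": {
        "b_max": 127,
        "rb_index_min": 0.20,
        "min_area": 10000,
        "max_area": 40000,
        "hue_classes": 32,
        "yellow_classes": [0, 1, 2, 3, 4],
    },
    "phosphate": {
        "local_threshold_radius": 15,
        "local_threshold_offset": 0.0,
        "grid_max_h_run": 50,
        "grid_max_v_run": 240,
        "grid_erode_px": 1,
        "grid_row_bands": [[50, 260], [1698, 1798]],
        "root_min_area": 109,
        "root_circ_max": 0.70,
        "root_max_dist": 145,
        "shoot_bri_min": 23,
        "shoot_bri_max": 138,
        "shoot_min_area": 10,
        "shoot_circ_min": 0.099,
        "shoot_max_dist": 130,
    },
}


def assay_defaults(assay: str) -> dict:
    if assay not in ASSAY_DEFAULTS:
        raise ConfigError(f"unknown assay {assay!r}")
    return dict(ASSAY_DEFAULTS[assay])


def _merge(assay: str, overrides: dict | None) -> dict:
    opts = assay_defaults(assay)
    for key, val in (overrides or {}).items():
        if key not in opts:
            raise ConfigError(f"unknown configuration key {key!r} for assay {assay!r}")
        default = opts[key]
        if isinstance(default, bool) or isinstance(val, bool):
            raise ConfigError(f"unexpected boolean for key {key!r}")
        if isinstance(default, (int, float)) and not isinstance(val, (int, float)):
            raise ConfigError(
                f"key {key!r} expects a number, got {type(val).__name__}"
            )
        if isinstance(default, (list, str)) and not isinstance(val, type(default)):
            raise ConfigError(
                f"key {key!r} expects {type(default).__name__}, "
                f"got {type(val).__name__}"
            )
        opts[key] = val
    return opts


def build_assay_config(assay: str, overrides: dict | None = None) -> assays.AssayConfig:
    """AssayConfig from named keys; defaults reproduce the printed rules."""
    o = _merge(assay, overrides)
    if assay == "salt":
        def vis_rule(s_min):
            return PixelRule.of(
                Clause("S", "gt", s_min),
                Clause("gray", "in", tuple(tuple(r) for r in o["vis_gray_band_keep"])),
            )

        cfg = assays.default_config(Assay.SALT)
        cfg.pixel_rules = {
            (Modality.VIS, Condition.STRESS): vis_rule(o["vis_s_threshold_stress"]),
            (Modality.VIS, Condition.STANDARD): vis_rule(o["vis_s_threshold_standard"]),
            Modality.FLUO: PixelRule.of(Clause("S", "gt", o["fluo_s_threshold"])),
        }
        cfg.filters = {
            Modality.VIS: ObjectFilterSpec(
                min_area=o["vis_min_area"], max_dist_to_center=o["vis_max_dist"]
            ),
            Modality.FLUO: ObjectFilterSpec(min_area=o["fluo_min_area"]),
        }
    elif assay == "arsenic":
        cfg = assays.default_config(Assay.ARSENIC)
        cfg.pixel_rules = {
            Modality.VIS: PixelRule.of(
                Clause("R", "lt", o["vis_r_max"]),
                Clause("G", "lt", o["vis_g_max"]),
                Clause("B", "lt", o["vis_b_max"]),
            ),
            Modality.FLUO: PixelRule.of(Clause("S", "gt", o["fluo_s_threshold"])),
        }
        cfg.filters = {
            Modality.VIS: ObjectFilterSpec(
                min_area=o["vis_min_area"],
                circ_min=o["vis_circ_min"],
                max_dist_to_center=o["vis_max_dist"],
            ),
            Modality.FLUO: ObjectFilterSpec(min_area=o["fluo_min_area"]),
        }
    elif assay == "freezing":
        cfg = assays.default_config(Assay.FREEZING)
        cfg.pixel_rules = {
            Modality.VIS: PixelRule.of(
                Clause("B", "lt", o["b_max"]),
                Clause("normdiff_RB", "gt", o["rb_index_min"]),
            )
        }
        cfg.filters = {
            Modality.VIS: ObjectFilterSpec(
                min_area=o["min_area"], max_area=o["max_area"]
            )
        }
        cfg.yellow_classes = tuple(o["yellow_classes"])
    else:
        cfg = assays.default_config(Assay.PHOSPHATE)
        cfg.pixel_rules = {
            "shoot": PixelRule.of(
                Clause("Bri", "gt", o["shoot_bri_min"]),
                Clause("Bri", "lt", o["shoot_bri_max"]),
            )
        }
        cfg.filters = {
            "root": ObjectFilterSpec(
                min_area=o["root_min_area"],
                circ_max=o["root_circ_max"],
                max_dist_to_center=o["root_max_dist"],
            ),
            "shoot": ObjectFilterSpec(
                min_area=o["shoot_min_area"],
                circ_min=o["shoot_circ_min"],
                max_dist_to_center=o["shoot_max_dist"],
            ),
        }
        cfg.local_threshold_radius = int(o["local_threshold_radius"])
        cfg.local_threshold_offset = float(o["local_threshold_offset"])
        cfg.grid_max_h_run = int(o["grid_max_h_run"])
        cfg.grid_max_v_run = int(o["grid_max_v_run"])
        cfg.grid_erode_px = int(o["grid_erode_px"])
        cfg.grid_row_bands = tuple(tuple(b) for b in o["grid_row_bands"])
    if "hue_classes" in o:
        cfg.n_hue_classes = int(o["hue_classes"])
    if "clustering_linkage" in o:
        cfg.clustering_linkage = str(o["clustering_linkage"])
    return cfg


_RUN_KEYS = {
    "assay": str,
    "wild_type": str,
    "seed": int,
    "verbosity": str,
    "out_dir": str,
    "images_dir": str,
    "layout": str,
    "lines": dict,
    "replicates": int,
    "condition": str,
    "thresholds": dict,
}


@dataclass
class RunConfig:
    """Validated end-to-end run description (simulate -> segment -> stats ->
    triage)."""

    assay: str
    wild_type: str = "Col-0"
    seed: int = 0
    verbosity: str = "INFO"
    out_dir: str = "phenoplate-out"
    images_dir: str | None = None
    layout: str | None = None
    lines: dict = field(default_factory=dict)  # line id -> effect overrides
    replicates: int | None = None
    condition: str = "stress"
    thresholds: dict = field(default_factory=dict)

    def assay_config(self) -> assays.AssayConfig:
        return build_assay_config(self.assay, self.thresholds)

    def digest(self) -> str:
        payload = {k: getattr(self, k) for k in _RUN_KEYS if hasattr(self, k)}
        return hashlib.md5(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:10]


def validate_config(source: str | Path | dict) -> RunConfig:
    """Load + validate a run configuration (YAML path or dict).

    Unknown keys and type mismatches raise ConfigError naming the key;
    threshold overrides are checked against the assay's named defaults.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    if "assay" not in raw:
        raise ConfigError("configuration must name an 'assay'")
    for key, val in raw.items():
        if key not in _RUN_KEYS:
            raise ConfigError(f"unknown configuration key {key!r}")
        want = _RUN_KEYS[key]
        if val is not None and not isinstance(val, want):
            raise ConfigError(
                f"key {key!r} expects {want.__name__}, got {type(val).__name__}"
            )
    cfg = RunConfig(**raw)
    if cfg.assay not in ASSAY_DEFAULTS:
        raise ConfigError(f"unknown assay {cfg.assay!r}")
    _merge(cfg.assay, cfg.thresholds)  # validates threshold keys/types
    for path_key in ("images_dir", "layout"):
        p = getattr(cfg, path_key)
        if p is not None and not Path(p).exists():
            raise ConfigError(f"{path_key} {p!r} does not exist")
    return cfg


def layout_to_dict(layout: PlateLayout) -> dict:
    return {
        "shape": layout.shape,
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "cell_centers": [[float(x), float(y)] for x, y in layout.cell_centers],
        "cell_to_line": {int(k): str(v) for k, v in layout.cell_to_line.items()},
        "image_shape": list(layout.image_shape),
    }


def layout_from_dict(d: dict) -> PlateLayout:
    return PlateLayout(
        shape=d["shape"],
        n_rows=int(d["n_rows"]),
        n_cols=int(d["n_cols"]),
        cell_centers=np.asarray(d["cell_centers"], dtype=float),
        cell_to_line={int(k): str(v) for k, v in d["cell_to_line"].items()},
        image_shape=tuple(d["image_shape"]),
    )


def save_layout(layout: PlateLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(layout_to_dict(layout), fh)


def load_layout(path: str | Path) -> PlateLayout:
    with open(path) as fh:
        return layout_from_dict(yaml.safe_load(fh))


def write_csv(df: pd.DataFrame, path: str | Path, meta: str = "") -> None:
    """CSV with a header comment carrying the tool version and config hash."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# phenoplate {__version__} {meta}\n")
        df.to_csv(fh, index=False)
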