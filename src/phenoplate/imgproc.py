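"""Low-level pixel operations shared by all assay pipelines.

Color-space conversion, rule-based foreground masks, local-mean thresholding,
connected-component labeling, and removal of embossed plate-grid artifacts.

Conventions
-----------
* Images are ``H x W x 3`` uint8 rasters; coordinates are 0-based with the
  origin at the top-left corner, ``x`` rightward (columns) and ``y`` downward
  (rows).
* Hue, saturation and brightness (HSB) live on the 8-bit scale ``[0, 255]``,
  the convention of the imaging software the printed thresholds come from.
  The hue of achromatic pixels (S = 0) is defined as 0.
* All rule comparisons are strict (``<`` / ``>``); boundary values are
  excluded, exactly as the thresholds are typeset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "Modality",
    "Assay",
    "Condition",
    "PlateImage",
    "PixelRule",
    "Component",
    "rgb_to_hsb",
    "to_gray",
    "apply_pixel_rule",
    "local_mean_threshold",
    "label_components",
    "remove_grid_artifacts",
]


class Modality(str, Enum):
    VIS = "VIS"
    FLUO = "FLUO"


class Assay(str, Enum):
    SALT = "salt"
    ARSENIC = "arsenic"
    FREEZING = "freezing"
    PHOSPHATE = "phosphate"


class Condition(str, Enum):
    STANDARD = "standard"
    STRESS = "stress"


#: assay -> modalities it images (freezing and phosphate are VIS-only)
VALID_MODALITIES = {
    Assay.SALT: (Modality.VIS, Modality.FLUO),
    Assay.ARSENIC: (Modality.VIS, Modality.FLUO),
    Assay.FREEZING: (Modality.VIS,),
    Assay.PHOSPHATE: (Modality.VIS,),
}


@dataclass
class PlateImage:
    """An 8-bit RGB plate photograph bound to its acquisition metadata."""

    pixels: np.ndarray
    modality: Modality = Modality.VIS
    assay: Assay = Assay.SALT
    condition: Condition = Condition.STRESS
    plate_id: str = ""

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.assay = Assay(self.assay)
        self.condition = Condition(self.condition)
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if self.modality not in VALID_MODALITIES[self.assay]:
            raise ValueError(
                f"modality {self.modality.value} is not acquired for the "
                f"{self.assay.value} assay"
            )
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def rgb_to_hsb(image: PlateImage | np.ndarray) -> np.ndarray:
    """Convert an RGB raster to HSB, all three channels on ``[0, 255]``.

    Standard HSV with hue rescaled from degrees by ``255 / 360`` and
    saturation/brightness by 255; results are rounded to integers.
    Achromatic pixels (max = min) get hue 0; black pixels get saturation 0.

    Returns an ``H x W x 3`` uint8 array ordered (H, S, Bri).
    """
    rgb = _pixels(image).astype(np.float32)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    mx = np.max(rgb, axis=-1)
    mn = np.min(rgb, axis=-1)
    delta = mx - mn

    chrom = delta > 0
    safe_delta = np.where(chrom, delta, 1.0)
    rc = (mx - r) / safe_delta
    gc = (mx - g) / safe_delta
    bc = (mx - b) / safe_delta
    hue_deg = bc - gc  # max == r branch
    hue_deg = np.where((mx == g) & (g != r), 2.0 + rc - bc, hue_deg)
    hue_deg = np.where((mx == b) & (b != r) & (b != g), 4.0 + gc - rc, hue_deg)
    hue_deg = (hue_deg * 60.0) % 360.0
    hue_deg = np.where(chrom, hue_deg, 0.0)

    h = np.rint(hue_deg * np.float32(255.0 / 360.0))
    s = np.where(mx > 0, np.rint(255.0 * delta / np.where(mx > 0, mx, 1.0)), 0.0)
    out = np.stack([h, s, np.rint(mx)], axis=-1)
    return out.astype(np.uint8)


def to_gray(image: PlateImage | np.ndarray, weights: str = "mean") -> np.ndarray:
    """Grayscale transform, rounded to uint8.

    ``weights="mean"`` (default) is the unweighted channel mean; ``"luma"``
    uses Rec.601 weights (0.299, 0.587, 0.114).
    """
    rgb = _pixels(image).astype(np.float64)
    if weights == "mean":
        g = rgb.mean(axis=-1)
    elif weights == "luma":
        g = rgb @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"unknown grayscale weighting {weights!r}")
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)


_CHANNELS = ("R", "G", "B", "H", "S", "Bri", "gray", "normdiff_RB")
_OPS = ("lt", "gt", "in")


@dataclass(frozen=True)
class Clause:
    """One condition of a pixel rule: ``channel <op> value``.

    ``op`` is ``"lt"`` / ``"gt"`` (strict) or ``"in"`` with a union of closed
    ranges ``[(lo, hi), ...]`` (endpoints included, matching the typeset
    "between 0 and 140 and from 150 to 255" phrasing).
    """

    channel: str
    op: str
    value: float | tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.op not in _OPS:
            raise ValueError(f"unknown comparator {self.op!r}")
        lo, hi = (-1.0, 1.0) if self.channel == "normdiff_RB" else (0.0, 255.0)
        if self.op == "in":
            ranges = tuple(tuple(map(float, r)) for r in self.value)
            object.__setattr__(self, "value", ranges)
            vals = [v for r in ranges for v in r]
        else:
            vals = [float(self.value)]
        for v in vals:
            if not lo <= v <= hi:
                raise ValueError(
                    f"constant {v} out of range [{lo}, {hi}] for channel {self.channel}"
                )


@dataclass(frozen=True)
class PixelRule:
    """An AND-combination of clauses defining a foreground mask."""

    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        clauses = tuple(
            c if isinstance(c, Clause) else Clause(*c) for c in self.clauses
        )
        if not clauses:
            raise ValueError("a pixel rule needs at least one clause")
        object.__setattr__(self, "clauses", clauses)

    @classmethod
    def of(cls, *clauses) -> "PixelRule":
        return cls(tuple(clauses))


def _pixels(image: PlateImage | np.ndarray) -> np.ndarray:
    return image.pixels if isinstance(image, PlateImage) else np.asarray(image)


def _channel_raster(image, name: str, cache: dict) -> np.ndarray:
    rgb = _pixels(image)
    if name in ("R", "G", "B"):
        return rgb[..., "RGB".index(name)].astype(np.float64)
    if name in ("H", "S", "Bri"):
        if "hsb" not in cache:
            cache["hsb"] = rgb_to_hsb(rgb)
        return cache["hsb"][..., ("H", "S", "Bri").index(name)].astype(np.float64)
    if name == "gray":
        if "gray" not in cache:
            cache["gray"] = to_gray(rgb)
        return cache["gray"].astype(np.float64)
    if name == "normdiff_RB":
        r = rgb[..., 0].astype(np.float64)
        b = rgb[..., 2].astype(np.float64)
        denom = r + b
        with np.errstate(divide="ignore", invalid="ignore"):
            nd = np.where(denom > 0, (r - b) / denom, 0.0)
        return nd
    raise ValueError(f"unknown channel {name!r}")  # pragma: no cover


def apply_pixel_rule(
    image: PlateImage | np.ndarray, rule: PixelRule, cache: dict | None = None
) -> np.ndarray:
    """Evaluate a pixel rule; returns a boolean foreground mask.

    Derived channels (H, S, Bri, gray, normdiff_RB) are computed internally
    and shared across clauses; a ``cache`` dict (keys ``"hsb"``/``"gray"``)
    may carry precomputed rasters to avoid repeated conversion.
    """
    cache = {} if cache is None else cache
    mask: np.ndarray | None = None
    for clause in rule.clauses:
        ch = _channel_raster(image, clause.channel, cache)
        if clause.op == "lt":
            m = ch < clause.value
        elif clause.op == "gt":
            m = ch > clause.value
        else:
            m = np.zeros(ch.shape, dtype=bool)
            for lo, hi in clause.value:
                m |= (ch >= lo) & (ch <= hi)
        mask = m if mask is None else (mask & m)
    assert mask is not None
    return mask


def local_mean_threshold(
    gray: np.ndarray, radius: int = 15, offset: float = 0.0
) -> np.ndarray:
    """Adaptive mean threshold for dark objects on a bright (backlit) field.

    A pixel is foreground iff ``gray(p) < mean(window) - offset`` where the
    square window of half-size ``radius`` is clipped at the image borders
    (border pixels average over the part of the window inside the image).
    Window sums use an exact integral image so a constant raster yields an
    exactly empty mask under the strict comparison.  If ``radius`` exceeds
    both image dimensions the local mean degenerates to the global mean
    (logged).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    gray = np.asarray(gray)
    h, w = gray.shape
    if radius >= h and radius >= w:
        logger.warning(
            "local_mean_threshold radius %d exceeds image size %dx%d; "
            "falling back to the global mean",
            radius,
            h,
            w,
        )
        return gray < gray.mean() - offset
    acc_dtype = np.int64 if np.issubdtype(gray.dtype, np.integer) else np.float64
    integral = np.zeros((h + 1, w + 1), dtype=acc_dtype)
    np.cumsum(np.cumsum(gray, axis=0, dtype=acc_dtype), axis=1, out=integral[1:, 1:])
    r0 = np.clip(np.arange(h) - radius, 0, h)
    r1 = np.clip(np.arange(h) + radius + 1, 0, h)
    c0 = np.clip(np.arange(w) - radius, 0, w)
    c1 = np.clip(np.arange(w) + radius + 1, 0, w)
    sums = (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    )
    counts = np.outer(r1 - r0, c1 - c0)
    local_mean = sums / counts
    return gray < local_mean - offset


_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class Component:
    """One connected component of a binary mask.

    ``mask`` is a tight boolean crop; ``offset`` is its (row, col) position in
    the full image.  ``centroid`` is the arithmetic mean of the pixel
    coordinates as (x, y).  ``cell`` is filled in by the object filter.
    """

    label: int
    mask: np.ndarray
    offset: tuple[int, int]
    area: int
    centroid: tuple[float, float]
    cell: int | None = None
    dist_to_cell: float | None = None

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max_exclusive, col_max_exclusive)."""
        r0, c0 = self.offset
        return (r0, c0, r0 + self.mask.shape[0], c0 + self.mask.shape[1])

    def coords(self) -> np.ndarray:
        """Pixel coordinates in full-image frame, shape (n, 2) as (row, col)."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.offset[0], cc + self.offset[1]])

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.offset
        out[r0 : r0 + self.mask.shape[0], c0 : c0 + self.mask.shape[1]] = self.mask
        return out


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Maximal connected components of a boolean mask (region labeling).

    Labels are contiguous from 1 in raster-scan order of each component's
    first pixel, the order produced by contour-tracing labelers.  The default
    8-connectivity matches those labelers; 4-connectivity is available.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labeled, n = ndimage.label(np.asarray(mask, dtype=bool), structure=structure)
    out: list[Component] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labeled)
    for i, sl in enumerate(slices, start=1):
        crop = labeled[sl] == i
        rr, cc = np.nonzero(crop)
        r0, c0 = sl[0].start, sl[1].start
        area = int(crop.sum())
        cy = float(rr.mean() + r0)
        cx = float(cc.mean() + c0)
        out.append(
            Component(
                label=i, mask=crop, offset=(r0, c0), area=area, centroid=(cx, cy)
            )
        )
    return out


def _clear_long_runs(mask: np.ndarray, max_run: int, axis: int) -> np.ndarray:
    """Clear contiguous foreground runs longer than ``max_run`` along an axis."""
    if max_run <= 0:
        return np.zeros_like(mask) if max_run == 0 else mask
    structure = np.zeros((3, 3), dtype=bool)
    structure[1, 1] = True
    if axis == 1:  # horizontal runs
        structure[1, 0] = structure[1, 2] = True
    else:  # vertical runs
        structure[0, 1] = structure[2, 1] = True
    labeled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labeled.ravel())
    keep = sizes <= max_run
    keep[0] = False
    return keep[labeled]


def remove_grid_artifacts(
    mask: np.ndarray,
    max_h_run: int = 50,
    max_v_run: int = 240,
    erode_px: int = 1,
    excluded_row_bands: Sequence[tuple[int, int]] = (),
) -> np.ndarray:
    """Remove embossed plate-grid lines and border rows from a foreground mask.

    In order: horizontal foreground runs strictly longer than ``max_h_run``
    pixels are cleared, then vertical runs strictly longer than ``max_v_run``,
    then ``erode_px`` rounds of binary erosion, then every row inside the
    inclusive 0-based bands ``(y_lo, y_hi)`` is cleared.  Never adds pixels.
    """
    if max_h_run < 0 or max_v_run < 0 or erode_px < 0:
        raise ValueError("run lengths and erosion size must be >= 0")
    out = np.asarray(mask, dtype=bool)
    out = _clear_long_runs(out, max_h_run, axis=1)
    out = _clear_long_runs(out, max_v_run, axis=0)
    if erode_px > 0:
        out = ndimage.binary_erosion(out, structure=_STRUCT_4, iterations=erode_px)
    h = out.shape[0]
    for y_lo, y_hi in excluded_row_bands:
        lo = max(0, int(y_lo))
        hi = min(h - 1, int(y_hi))
        if y_hi >= h:
            logger.warning(
                "excluded row band (%d, %d) clipped to image height %d", y_lo, y_hi, h
            )
        if lo <= hi:
            out[lo : hi + 1, :] = False
    return out
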