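"""From labeled components to per-seedling "digital plants".

Geometric/colorimetric object filtering, per-grid-cell selection, shoot-root
merging for vertically grown plates, the eight morpho-colorimetric features,
hue-class color profiles, and the yellowish freezing-damage index.

Feature conventions
-------------------
* perimeter: length of the traced outer contour polygon through border pixel
  centers (Moore neighbor tracing), axis steps counting 1 and diagonal steps
  sqrt(2); interior holes are ignored.  For plants made of several connected
  parts (e.g. a merged shoot + root that do not touch) the outer contours of
  the parts are summed.
* circularity: the normalized ratio 4*pi*area / perimeter**2 (1 for a disk,
  -> 0 for elongated objects).  The raw ratio perimeter**2 / area is also
  reported as ``raw_circularity``.
* compactness: area / perimeter.
* major/minor axis: axis lengths of the equivalent ellipse derived from the
  second central moments of the pixel set (each pixel treated as a unit
  square, i.e. a 1/12 variance term per coordinate), the moment-of-inertia
  definition of the axis about which the body is easiest to rotate.
* eccentricity: major/minor axis ratio (>= 1).
* hisgreypeak: modal gray intensity of the plant pixels; the lowest intensity
  wins ties.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .imgproc import Component

logger = logging.getLogger(__name__)

__all__ = [
    "PlateLayout",
    "ObjectFilterSpec",
    "DigitalPlant",
    "MorphoProfile",
    "trace_outer_contour",
    "contour_perimeter",
    "filter_objects",
    "select_largest_per_cell",
    "merge_shoot_root",
    "compute_morphology",
    "hue_class_histogram",
    "yellow_damage_fraction",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "compactness",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "hisgreypeak",
)


@dataclass
class PlateLayout:
    """Mapping from plate geometry to mutant-line identity.

    ``cell_centers`` are (x, y) pixel coordinates; ``cell_to_line`` maps the
    cell index (position in ``cell_centers``) to a line id.  Round freezing
    plates carry centers purely as line-identity regions (seedlings are not
    assigned a unique cell).
    """

    shape: str  # "square_grid" | "round"
    n_rows: int
    n_cols: int
    cell_centers: np.ndarray  # (n, 2) float, (x, y)
    cell_to_line: dict[int, str]
    image_shape: tuple[int, int]  # (H, W)

    def __post_init__(self) -> None:
        if self.shape not in ("square_grid", "round"):
            raise ValueError(f"unknown layout shape {self.shape!r}")
        self.cell_centers = np.atleast_2d(np.asarray(self.cell_centers, dtype=float))
        h, w = self.image_shape
        if len(self.cell_centers) and (
            (self.cell_centers[:, 0] < 0).any()
            or (self.cell_centers[:, 0] >= w).any()
            or (self.cell_centers[:, 1] < 0).any()
            or (self.cell_centers[:, 1] >= h).any()
        ):
            raise ValueError("cell centers must lie inside the image")

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    def line_of(self, cell: int) -> str:
        return self.cell_to_line[cell]

    @classmethod
    def square_grid(
        cls,
        n_rows: int,
        n_cols: int,
        image_shape: tuple[int, int],
        lines: "str | list[str]" = "unknown",
        margin: float | None = None,
    ) -> "PlateLayout":
        """Evenly spaced grid of cell centers; ``lines`` is one id for the
        whole plate or one id per cell (row-major)."""
        h, w = image_shape
        my = margin if margin is not None else h / (2 * n_rows)
        mx = margin if margin is not None else w / (2 * n_cols)
        ys = np.linspace(my, h - my, n_rows)
        xs = np.linspace(mx, w - mx, n_cols)
        centers = np.array([(x, y) for y in ys for x in xs])
        if isinstance(lines, str):
            mapping = {i: lines for i in range(n_rows * n_cols)}
        else:
            if len(lines) != n_rows * n_cols:
                raise ValueError("need one line id per cell")
            mapping = dict(enumerate(lines))
        return cls("square_grid", n_rows, n_cols, centers, mapping, image_shape)


@dataclass(frozen=True)
class ObjectFilterSpec:
    """Strict object bounds: area > min_area, area < max_area,
    circ_min < circularity < circ_max, distance-to-nearest-cell-center
    < max_dist_to_center.  Unset bounds (None) are not applied."""

    min_area: int = 0
    max_area: int | None = None
    circ_min: float | None = None
    circ_max: float | None = None
    max_dist_to_center: float | None = None

    def __post_init__(self) -> None:
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        if self.max_area is not None and self.max_area <= self.min_area:
            raise ValueError("max_area must exceed min_area")
        if (
            self.circ_min is not None
            and self.circ_max is not None
            and self.circ_max <= self.circ_min
        ):
            raise ValueError("circ_max must exceed circ_min")


@dataclass
class DigitalPlant:
    """The pixel set segmented as one seedling."""

    mask: np.ndarray  # tight boolean crop
    offset: tuple[int, int]  # (row, col) of the crop in the full image
    centroid: tuple[float, float]  # (x, y)
    cell: int | None
    line_id: str
    parts: dict = field(default_factory=dict)  # e.g. {"shoot": Component, "root": ...}

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def coords(self) -> np.ndarray:
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([rr + self.offset[0], cc + self.offset[1]])

    @classmethod
    def from_component(
        cls, comp: Component, line_id: str, cell: int | None = None
    ) -> "DigitalPlant":
        return cls(
            mask=comp.mask.copy(),
            offset=comp.offset,
            centroid=comp.centroid,
            cell=cell if cell is not None else comp.cell,
            line_id=line_id,
        )


@dataclass
class MorphoProfile:
    area: int
    perimeter: float
    circularity: float
    compactness: float
    major_axis: float
    minor_axis: float
    eccentricity: float
    hisgreypeak: int
    raw_circularity: float = float("nan")
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


# Moore neighborhood in clockwise order starting East: (drow, dcol)
_MOORE = (
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
    (-1, -1),
    (-1, 0),
    (-1, 1),
)
_STEP_LEN = tuple(math.sqrt(dr * dr + dc * dc) for dr, dc in _MOORE)


def trace_outer_contour(mask: np.ndarray) -> list[tuple[int, int]]:
    """Moore-neighbor trace of the outer contour of the largest foreground
    structure touching the topmost-leftmost foreground pixel.

    Returns the closed sequence of border pixel coordinates (row, col); a
    single isolated pixel yields a one-element contour.
    """
    m = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(m)
    if rows.size == 0:
        return []
    # topmost, then leftmost foreground pixel
    start = (int(rows[0]), int(cols[0]))
    order = np.lexsort((cols, rows))
    start = (int(rows[order[0]]), int(cols[order[0]]))

    h, w = m.shape

    def fg(r: int, c: int) -> bool:
        return 0 <= r < h and 0 <= c < w and m[r, c]

    contour = [start]
    # we arrived at `start` moving East from its (background) West neighbor,
    # so the backtrack direction is West (index 4)
    backtrack = 4
    current = start
    first_move: int | None = None
    while True:
        nxt = None
        for k in range(1, 9):
            d = (backtrack + k) % 8
            nr, nc = current[0] + _MOORE[d][0], current[1] + _MOORE[d][1]
            if fg(nr, nc):
                nxt = (nr, nc)
                move = d
                break
        if nxt is None:  # isolated pixel
            return contour
        # Jacob's stopping criterion: back at the start about to repeat the
        # initial move
        if current == start and first_move is not None and move == first_move:
            if len(contour) > 1 and contour[-1] == start:
                contour.pop()
            return contour
        if first_move is None:
            first_move = move
        contour.append(nxt)
        # backtrack points from the new pixel to the previous one
        backtrack = (move + 4) % 8
        current = nxt
        if len(contour) > 4 * (h * w):  # pragma: no cover - safety net
            raise RuntimeError("contour tracing failed to terminate")


def contour_perimeter(contour: list[tuple[int, int]]) -> float:
    """Polygonal length of a closed contour: 1 per axis step, sqrt(2) per
    diagonal step, including the closing segment."""
    n = len(contour)
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        r0, c0 = contour[i]
        r1, c1 = contour[(i + 1) % n]
        dr, dc = abs(r1 - r0), abs(c1 - c0)
        if dr == 0 and dc == 0:
            continue
        total += math.sqrt(2.0) if (dr and dc) else 1.0
    return total


def _mask_perimeter(mask: np.ndarray) -> float:
    """Sum of outer-contour lengths over the connected parts of ``mask``."""
    from scipy import ndimage

    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    total = 0.0
    for sl, i in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        total += contour_perimeter(trace_outer_contour(labeled[sl] == i))
    return total


def component_circularity(comp: Component) -> float:
    """Normalized circularity 4*pi*A/P^2 of a component (nan if degenerate)."""
    p = _mask_perimeter(comp.mask)
    if p <= 0:
        return float("nan")
    return 4.0 * math.pi * comp.area / (p * p)


def filter_objects(
    components: list[Component],
    spec: ObjectFilterSpec,
    layout: PlateLayout | None = None,
) -> list[Component]:
    """Drop components violating any bound of ``spec``; survivors are
    annotated with their nearest cell (``comp.cell``) and the distance to its
    center when a layout is given."""
    needs_dist = spec.max_dist_to_center is not None
    if needs_dist and (layout is None or layout.n_cells == 0):
        raise ValueError("distance bound requires a layout with cell centers")
    out: list[Component] = []
    centers = layout.cell_centers if layout is not None and layout.n_cells else None
    for comp in components:
        if not comp.area > spec.min_area:
            continue
        if spec.max_area is not None and not comp.area < spec.max_area:
            continue
        if spec.circ_min is not None or spec.circ_max is not None:
            circ = component_circularity(comp)
            if not np.isfinite(circ):
                continue
            if spec.circ_min is not None and not circ > spec.circ_min:
                continue
            if spec.circ_max is not None and not circ < spec.circ_max:
                continue
        if centers is not None:
            d = np.hypot(
                centers[:, 0] - comp.centroid[0], centers[:, 1] - comp.centroid[1]
            )
            nearest = int(np.argmin(d))
            if needs_dist and not d[nearest] < spec.max_dist_to_center:
                continue
            comp.cell = nearest
            comp.dist_to_cell = float(d[nearest])
        out.append(comp)
    return out


def select_largest_per_cell(
    components: list[Component], layout: PlateLayout
) -> dict[int, Component]:
    """Keep only the largest object in each grid cell (lowest label on ties);
    cells with no object are absent from the map."""
    best: dict[int, Component] = {}
    for comp in components:
        if comp.cell is None:
            d = np.hypot(
                layout.cell_centers[:, 0] - comp.centroid[0],
                layout.cell_centers[:, 1] - comp.centroid[1],
            )
            comp.cell = int(np.argmin(d))
        cur = best.get(comp.cell)
        if cur is None or comp.area > cur.area or (
            comp.area == cur.area and comp.label < cur.label
        ):
            best[comp.cell] = comp
    return best


def _grid_column(layout: PlateLayout, x: float) -> int:
    """Index of the nearest distinct column of cell centers."""
    col_xs = np.unique(np.round(layout.cell_centers[:, 0], 3))
    return int(np.argmin(np.abs(col_xs - x)))


def merge_shoot_root(
    shoots: list[Component],
    roots: list[Component],
    layout: PlateLayout,
) -> list[DigitalPlant]:
    """Pair each shoot with at most one root in the same grid column.

    The chosen root is the one whose topmost pixel lies nearest below the
    shoot centroid; the merged plant is the union of both pixel sets.
    Unpaired shoots become shoot-only plants; unpaired roots are dropped.
    """
    root_info = []
    for r in roots:
        top_y = r.offset[0]  # topmost row of the component
        root_info.append((_grid_column(layout, r.centroid[0]), top_y, r))
    used = [False] * len(root_info)
    plants: list[DigitalPlant] = []
    for shoot in sorted(shoots, key=lambda c: c.label):
        col = _grid_column(layout, shoot.centroid[0])
        cy = shoot.centroid[1]
        best_i = None
        best_gap = None
        for i, (rcol, top_y, _r) in enumerate(root_info):
            if used[i] or rcol != col or top_y < cy:
                continue
            gap = top_y - cy
            if best_gap is None or gap < best_gap:
                best_gap, best_i = gap, i
        if best_i is None:
            plant = DigitalPlant.from_component(
                shoot, line_id="", cell=shoot.cell
            )
            plant.parts = {"shoot": shoot}
            plants.append(plant)
            continue
        used[best_i] = True
        root = root_info[best_i][2]
        r0 = min(shoot.offset[0], root.offset[0])
        c0 = min(shoot.offset[1], root.offset[1])
        r1 = max(shoot.bbox[2], root.bbox[2])
        c1 = max(shoot.bbox[3], root.bbox[3])
        merged = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        for part in (shoot, root):
            pr, pc = part.offset
            merged[
                pr - r0 : pr - r0 + part.mask.shape[0],
                pc - c0 : pc - c0 + part.mask.shape[1],
            ] |= part.mask
        rr, cc = np.nonzero(merged)
        centroid = (float(cc.mean() + c0), float(rr.mean() + r0))
        plant = DigitalPlant(
            mask=merged,
            offset=(r0, c0),
            centroid=centroid,
            cell=shoot.cell,
            line_id="",
            parts={"shoot": shoot, "root": root},
        )
        plants.append(plant)
    return plants


def _equivalent_ellipse_axes(coords: np.ndarray) -> tuple[float, float]:
    """Axis lengths (major, minor) of the second-central-moment equivalent
    ellipse; each pixel contributes a 1/12 unit-square variance term."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(coords) + np.eye(2) / 12.0
    eigvals = np.linalg.eigvalsh(cov)
    minor, major = (float(x) for x in np.sort(eigvals))
    return 4.0 * math.sqrt(major), 4.0 * math.sqrt(minor)


def compute_morphology(
    plant: DigitalPlant | Component, gray: np.ndarray
) -> MorphoProfile:
    """The eight morpho-colorimetric features of one digital plant.

    Plants with fewer than 4 pixels get a degenerate profile (flagged, with
    nan for ratios whose perimeter convention collapses) rather than raising.
    """
    mask = plant.mask
    r0, c0 = plant.offset
    area = int(mask.sum())
    if area == 0:
        raise ValueError("plant pixel set is empty")
    perimeter = _mask_perimeter(mask)
    degenerate = area < 4
    if perimeter > 0:
        circularity = 4.0 * math.pi * area / perimeter**2
        raw_circ = perimeter**2 / area
        compactness = area / perimeter
    else:
        circularity = raw_circ = compactness = float("nan")
    coords = np.column_stack(np.nonzero(mask)).astype(float)
    # (row, col) -> (y, x); axes are orientation-free so order is irrelevant
    major, minor = _equivalent_ellipse_axes(coords)
    ecc = major / minor if minor > 0 else float("inf")
    sub = gray[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
    vals = np.asarray(sub)[mask].astype(np.intp)
    hisgreypeak = int(np.bincount(vals, minlength=256).argmax())
    return MorphoProfile(
        area=area,
        perimeter=perimeter,
        circularity=circularity,
        compactness=compactness,
        major_axis=major,
        minor_axis=minor,
        eccentricity=ecc,
        hisgreypeak=hisgreypeak,
        raw_circularity=raw_circ,
        degenerate=degenerate,
    )


def hue_class_histogram(
    plant: DigitalPlant | Component,
    hsb: np.ndarray,
    n_classes: int = 16,
    exclude_achromatic: bool = False,
) -> np.ndarray:
    """Fractions of plant pixels per hue class.

    The class of a pixel is ``floor(H * K / 256)`` on the 8-bit hue scale.
    Achromatic pixels (S = 0, hue defined as 0) are counted in class 0 unless
    ``exclude_achromatic`` is set.  Fractions sum to 1 over the counted
    pixels (an all-achromatic plant with exclusion on yields all zeros).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 hue classes")
    r0, c0 = plant.offset
    mask = plant.mask
    sub = hsb[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
    hue = sub[..., 0][mask].astype(np.intp)
    if exclude_achromatic:
        sat = sub[..., 1][mask]
        hue = hue[sat > 0]
    classes = hue * n_classes // 256
    counts = np.bincount(classes, minlength=n_classes).astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


#: hue bins (width 8 on [0,255], centers 4,12,20,28,36) counted as yellowish
#: leaf damage, i.e. hue in [0, 40) - red through yellow tones
YELLOW_CLASSES_32 = (0, 1, 2, 3, 4)


def yellow_damage_fraction(
    plant: DigitalPlant | Component,
    hsb: np.ndarray,
    yellow_classes: tuple[int, ...] = YELLOW_CLASSES_32,
    n_classes: int = 32,
) -> tuple[float, bool]:
    """Freezing leaf-damage index: fraction of plant pixels in the yellowish
    hue classes, and the damaged flag (strictly more than 50% damage)."""
    fractions = hue_class_histogram(plant, hsb, n_classes=n_classes)
    frac = float(fractions[list(yellow_classes)].sum())
    return frac, frac > 0.5
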