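"""Ground-truth synthetic plate generator.

Renders the four plate formats the analysis pipelines expect — square
36-cell grids for salt and arsenic (visible + fluorescence modalities),
round ~60-seedling plates for freezing, and backlit vertical 6-seed plates
with embossed grid lines for phosphate — with per-line effect parameters
(survival / germination probability, damage fraction, root-length shift)
and a truth table per rendered seedling.

Backgrounds are constructed to fail the matching assay's pixel rules and
seedling tissue to pass them; the freezing foreground index
(R - B)/(R + B) is 0 at pure green regardless of saturation, so freezing
tissue is drawn yellow-green (hue ~72 on the 0-255 scale) at high
saturation, while salt/arsenic tissue is mid-green (hue ~85).

Everything is deterministic for a fixed (config, seed): each plate draws
from its own generator seeded from (experiment seed, plate index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb

from .imgproc import Assay, Condition, Modality, PlateImage
from .plants import PlateLayout

logger = logging.getLogger(__name__)

__all__ = [
    "LineEffectSpec",
    "default_layout",
    "generate_plate",
    "generate_experiment",
    "expected_calls",
    "simulate_survival_counts",
    "save_experiment",
]

#: default image side per assay (phosphate needs rows up to 1798 so the
#: printed crop bands are exercised; the others share the plate frame size)
IMAGE_SIDE = 1800


@dataclass(frozen=True)
class LineEffectSpec:
    """Per-line phenotype parameters driving the generator.

    Probabilities are per seedling; hue parameters are (mean, sd) on the
    8-bit hue scale, truncated to [0, 255].  Defaults are the wild-type
    condition of the screen (survival/germination ~0.65 under semi-lethal
    stress, mild freezing damage, 250 px roots under phosphate limitation).
    """

    line_id: str
    survival_prob: float = 0.65
    germination_prob: float = 0.65
    damage_mean: float = 0.30
    damage_kappa: float = 8.0  # beta concentration of per-seedling damage
    root_length_mean: float = 250.0
    root_length_sd: float = 25.0
    blob_radius: tuple[float, float] = (12.0, 18.0)
    seed_radius: tuple[float, float] = (5.0, 8.0)
    rosette_radius: tuple[float, float] = (62.0, 75.0)  # freezing
    hue_alive: tuple[float, float] = (85.0, 8.0)
    hue_dead: tuple[float, float] = (22.0, 6.0)
    hue_seed: tuple[float, float] = (15.0, 5.0)
    hue_freezing_alive: tuple[float, float] = (72.0, 6.0)

    def __post_init__(self) -> None:
        for p in (self.survival_prob, self.germination_prob, self.damage_mean):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


WILD_TYPE = "Col-0"

#: per-assay experiment design: (seedlings per plate, biological replicates)
DESIGNS = {
    Assay.SALT: (36, 3),
    Assay.ARSENIC: (36, 3),
    Assay.FREEZING: (60, 3),
    Assay.PHOSPHATE: (6, 2),
}


def default_layout(
    assay: Assay | str, line: str = WILD_TYPE, side: int = IMAGE_SIDE
) -> PlateLayout:
    """The plate layout the study design uses for one line per plate."""
    assay = Assay(assay)
    if assay in (Assay.SALT, Assay.ARSENIC):
        return PlateLayout.square_grid(6, 6, (side, side), lines=line)
    if assay == Assay.PHOSPHATE:
        xs = np.linspace(side / 12, side - side / 12, 6)
        centers = np.column_stack([xs, np.full(6, 470.0)])
        return PlateLayout(
            "square_grid", 1, 6, centers, {i: line for i in range(6)}, (side, side)
        )
    # freezing: round plate; centers are line-identity regions only.
    # 180 px spacing packs 60 positions inside the dish circle while
    # leaving clearance for the largest rosette silhouettes.
    spacing = side / 10.0
    pts = []
    half = side / 2
    for iy in range(-5, 5):
        for ix in range(-5, 5):
            if np.hypot(ix + 0.5, iy + 0.5) <= 4.53:
                pts.append((half + (ix + 0.5) * spacing, half + (iy + 0.5) * spacing))
    pts.sort(key=lambda p: (p[1], p[0]))
    pts = pts[:60]
    return PlateLayout(
        "round", 0, 0, np.array(pts), {i: line for i in range(len(pts))}, (side, side)
    )


def _trunc_normal(rng, mean, sd, lo, hi, size):
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def _paint_pixels(img, rr, cc, hue, sat, val):
    """Write HSV-specified pixels (arrays on [0,1]) into an RGB uint8 image."""
    hsv = np.stack([hue, sat, val], axis=-1)
    rgb = np.clip(np.rint(hsv_to_rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    img[rr, cc] = rgb


def _rosette_mask(
    rng, radius: float, n_lobes: int = 4, compact: bool = False
) -> np.ndarray:
    """Union of offset disks - a lumpy, roughly round rosette silhouette.

    ``compact`` keeps every lobe inside the base-disk extent (used for the
    densely packed freezing plates so neighbors never touch)."""
    r_int = int(np.ceil(radius * (1.05 if compact else 1.6))) + 2
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    mask = xx**2 + yy**2 <= radius**2
    off_rng = (0.2, 0.4) if compact else (0.3, 0.6)
    lobe_rng = (0.35, 0.55) if compact else (0.45, 0.65)
    for _ in range(n_lobes):
        ang = rng.uniform(0, 2 * np.pi)
        off = rng.uniform(*off_rng) * radius
        lobe_r = rng.uniform(*lobe_rng) * radius
        ox, oy = off * np.cos(ang), off * np.sin(ang)
        mask |= (xx - ox) ** 2 + (yy - oy) ** 2 <= lobe_r**2
    return mask


def _blit(img_mask_painter, mask, cx, cy, shape):
    """Translate a centered local mask to image coordinates, clipped."""
    r = mask.shape[0] // 2
    rr, cc = np.nonzero(mask)
    rr = rr - r + int(round(cy))
    cc = cc - r + int(round(cx))
    ok = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[ok], cc[ok]


def _paint_tissue(img, rng, mask, cx, cy, hue_ms, sat_rng, val_rng):
    rr, cc = _blit(None, mask, cx, cy, img.shape[:2])
    n = rr.size
    hue = _trunc_normal(rng, hue_ms[0], hue_ms[1], 0, 255, n) / 255.0
    sat = rng.uniform(*sat_rng, n)
    val = rng.uniform(*val_rng, n)
    _paint_pixels(img, rr, cc, hue, sat, val)
    return rr, cc


def _achromatic_background(rng, side: int, level: int, noise: int) -> np.ndarray:
    """Gray background with channel-identical noise (saturation stays 0)."""
    base = rng.integers(level - noise, level + noise + 1, size=(side, side))
    return np.repeat(base[..., None], 3, axis=-1).astype(np.uint8)


def _render_salt_like(
    assay: Assay,
    layout: PlateLayout,
    spec: LineEffectSpec,
    rng: np.random.Generator,
    condition: Condition,
    plate_id: str,
) -> tuple[dict[Modality, PlateImage], pd.DataFrame]:
    side = layout.image_shape[0]
    if assay == Assay.ARSENIC:
        # backlit near-white field: every pixel fails R < 254
        vis = np.empty((side, side, 3), dtype=np.uint8)
        vis[..., 0] = rng.integers(254, 256, size=(side, side))
        vis[..., 1] = rng.integers(248, 256, size=(side, side))
        vis[..., 2] = rng.integers(254, 256, size=(side, side))
    else:
        vis = _achromatic_background(rng, side, 128, 4)
    fluo = _achromatic_background(rng, side, 12, 3)
    germinal = assay == Assay.ARSENIC
    p_good = spec.germination_prob if germinal else spec.survival_prob
    if condition == Condition.STANDARD:
        p_good = 1.0  # no stress: everything survives/germinates
    rows = []
    for cell, (cx, cy) in enumerate(layout.cell_centers):
        jx, jy = rng.uniform(-20, 20, 2)
        cx, cy = cx + jx, cy + jy
        good = rng.random() < p_good
        if germinal and not good:
            status = "seed"
            radius = rng.uniform(*spec.seed_radius)
            mask = _rosette_mask(rng, radius, n_lobes=1)
            _paint_tissue(vis, rng, mask, cx, cy, spec.hue_seed, (0.55, 0.75), (0.45, 0.62))
            # seeds barely fluoresce: low saturation keeps them out of the
            # FLUO foreground rule
            _paint_tissue(fluo, rng, mask, cx, cy, (8, 4), (0.02, 0.06), (0.15, 0.25))
        else:
            status = "alive" if good else "dead"
            radius = rng.uniform(*spec.blob_radius)
            mask = _rosette_mask(rng, radius)
            hue = spec.hue_alive if good else spec.hue_dead
            _paint_tissue(vis, rng, mask, cx, cy, hue, (0.6, 0.85), (0.55, 0.8))
            if good:
                _paint_tissue(
                    fluo, rng, mask, cx, cy, (0, 3), (0.75, 0.95), (0.5, 0.75)
                )
            else:
                _paint_tissue(
                    fluo, rng, mask, cx, cy, (0, 3), (0.01, 0.05), (0.1, 0.2)
                )
        rows.append(
            {
                "plate_id": plate_id,
                "assay": assay.value,
                "condition": condition.value,
                "cell": cell,
                "line": layout.line_of(cell),
                "status": status,
                "x": cx,
                "y": cy,
                "true_damage": np.nan,
                "true_root_length": np.nan,
            }
        )
    images = {
        Modality.VIS: PlateImage(vis, Modality.VIS, assay, condition, plate_id),
        Modality.FLUO: PlateImage(fluo, Modality.FLUO, assay, condition, plate_id),
    }
    return images, pd.DataFrame(rows)


def _render_freezing(
    layout: PlateLayout,
    spec: LineEffectSpec,
    rng: np.random.Generator,
    condition: Condition,
    plate_id: str,
) -> tuple[dict[Modality, PlateImage], pd.DataFrame]:
    side = layout.image_shape[0]
    vis = _achromatic_background(rng, side, 70, 4)
    damage_mean = 0.02 if condition == Condition.STANDARD else spec.damage_mean
    a = max(damage_mean * spec.damage_kappa, 1e-3)
    b = max((1 - damage_mean) * spec.damage_kappa, 1e-3)
    rows = []
    for cell, (cx, cy) in enumerate(layout.cell_centers):
        jx, jy = rng.uniform(-12, 12, 2)
        cx, cy = cx + jx, cy + jy
        radius = rng.uniform(*spec.rosette_radius)
        mask = _rosette_mask(rng, radius, n_lobes=5, compact=True)
        d = float(rng.beta(a, b))
        rr, cc = _blit(None, mask, cx, cy, vis.shape[:2])
        n = rr.size
        damaged_px = rng.random(n) < d
        hue = np.where(
            damaged_px,
            _trunc_normal(rng, spec.hue_dead[0], spec.hue_dead[1], 0, 39, n),
            # healthy tissue stays below H ~ 80: nearer pure green the
            # (R - B)/(R + B) index of the assay rule collapses to 0
            _trunc_normal(
                rng, spec.hue_freezing_alive[0], spec.hue_freezing_alive[1], 48, 80, n
            ),
        )
        sat = rng.uniform(0.82, 0.95, n)
        val = rng.uniform(0.55, 0.8, n)
        _paint_pixels(vis, rr, cc, hue / 255.0, sat, val)
        realized = float(damaged_px.mean())
        rows.append(
            {
                "plate_id": plate_id,
                "assay": Assay.FREEZING.value,
                "condition": condition.value,
                "cell": cell,
                "line": layout.line_of(cell),
                "status": "damaged" if realized > 0.5 else "undamaged",
                "x": cx,
                "y": cy,
                "true_damage": realized,
                "true_root_length": np.nan,
            }
        )
    images = {
        Modality.VIS: PlateImage(vis, Modality.VIS, Assay.FREEZING, condition, plate_id)
    }
    return images, pd.DataFrame(rows)


def _render_phosphate(
    layout: PlateLayout,
    spec: LineEffectSpec,
    rng: np.random.Generator,
    condition: Condition,
    plate_id: str,
) -> tuple[dict[Modality, PlateImage], pd.DataFrame]:
    side = layout.image_shape[0]
    # constant backlit field: the mean auto-local threshold with offset 0
    # tags anything below its window mean, so the background carries no noise
    img = np.full((side, side, 3), 210, dtype=np.uint8)
    # embossed grid: full-length lines slightly darker than the backlit
    # field; 550 px spacing keeps horizontal lines out of the root zone
    for x in range(275, side, 550):
        img[:, x : x + 2] = 185
    for y in range(275, side, 550):
        img[y : y + 2, :] = 185
    length_mean = spec.root_length_mean
    if condition == Condition.STANDARD:
        length_mean *= 1.3  # unrestricted phosphate: longer roots
    rows = []
    for cell, (cx, cy) in enumerate(layout.cell_centers):
        shoot_y = cy - 70.0
        jx = rng.uniform(-10, 10)
        sx = cx + jx
        shoot_r = rng.uniform(9, 13)
        mask = _rosette_mask(rng, shoot_r, n_lobes=3)
        _paint_tissue(img, rng, mask, sx, shoot_y, spec.hue_alive, (0.5, 0.7), (0.3, 0.42))
        length = float(
            np.clip(rng.normal(length_mean, spec.root_length_sd), 60, 1100)
        )
        # the root emerges just below the shoot silhouette so the dark mask
        # segments shoot and root as separate objects
        top = int(round(shoot_y + shoot_r * 1.4 + 3))
        bottom = int(round(shoot_y + shoot_r + length))
        amp = rng.uniform(3.0, 5.0)
        period = rng.uniform(80.0, 120.0)
        phase = rng.uniform(0, 2 * np.pi)
        ys = np.arange(top, bottom + 1)
        xs = np.rint(sx + amp * np.sin(2 * np.pi * ys / period + phase)).astype(int)
        for w in (-1, 0, 1):
            xw = np.clip(xs + w, 0, side - 1)
            img[ys, xw] = 20
        rows.append(
            {
                "plate_id": plate_id,
                "assay": Assay.PHOSPHATE.value,
                "condition": condition.value,
                "cell": cell,
                "line": layout.line_of(cell),
                "status": "alive",
                "x": sx,
                "y": shoot_y,
                "true_damage": np.nan,
                "true_root_length": float(bottom - top),
            }
        )
    images = {
        Modality.VIS: PlateImage(
            img, Modality.VIS, Assay.PHOSPHATE, condition, plate_id
        )
    }
    return images, pd.DataFrame(rows)


def generate_plate(
    assay: Assay | str,
    layout: PlateLayout,
    spec: LineEffectSpec,
    seed: int | tuple = 0,
    condition: Condition | str = Condition.STRESS,
    plate_id: str | None = None,
) -> tuple[dict[Modality, PlateImage], pd.DataFrame]:
    """Render one plate (all modalities the assay acquires) plus its truth
    table.  Deterministic for fixed (layout, spec, seed)."""
    assay = Assay(assay)
    condition = Condition(condition)
    if assay in (Assay.SALT, Assay.ARSENIC) and layout.shape != "square_grid":
        raise ValueError(f"{assay.value} assay needs a square_grid layout")
    if assay == Assay.FREEZING and layout.shape != "round":
        raise ValueError("freezing assay needs a round layout")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pid = plate_id or f"{assay.value}-{spec.line_id}-{seed}"
    if assay in (Assay.SALT, Assay.ARSENIC):
        return _render_salt_like(assay, layout, spec, rng, condition, pid)
    if assay == Assay.FREEZING:
        return _render_freezing(layout, spec, rng, condition, pid)
    return _render_phosphate(layout, spec, rng, condition, pid)


def generate_experiment(
    assay: Assay | str,
    line_specs: list[LineEffectSpec],
    seed: int = 0,
    n_replicates: int | None = None,
    condition: Condition | str = Condition.STRESS,
    side: int = IMAGE_SIDE,
):
    """Full experiment: one plate per line per replicate (the study design:
    36 seeds x 3 replicates for salt/arsenic, 60 x 3 freezing, 6 x 2
    phosphate).  Yields ``(images, layout, truth)`` per plate; plate RNG
    streams derive from (experiment seed, plate index)."""
    assay = Assay(assay)
    if n_replicates is None:
        n_replicates = DESIGNS[assay][1]
    idx = 0
    for spec in line_specs:
        layout = default_layout(assay, line=spec.line_id, side=side)
        for rep in range(n_replicates):
            images, truth = generate_plate(
                assay,
                layout,
                spec,
                seed=(seed, idx),
                condition=condition,
                plate_id=f"{assay.value}-{spec.line_id}-r{rep + 1}",
            )
            truth["replicate"] = rep + 1
            yield images, layout, truth
            idx += 1


def expected_calls(
    truth: pd.DataFrame,
    assay: Assay | str,
    wild_type: str = WILD_TYPE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Oracle per-line significance computed on *true* seedling statuses.

    Fisher's exact test on true alive/germinated/damaged counts (or one-way
    ANOVA on true root lengths for phosphate) with BH adjustment - the
    expected calls an ideal pipeline should recover.
    """
    from . import screen

    assay = Assay(assay)
    if assay == Assay.PHOSPHATE:
        tab = truth.rename(columns={"true_root_length": "value"})[["line", "value"]]
        return screen.line_significance(tab, test="anova", wild_type=wild_type, alpha=alpha)
    if assay == Assay.FREEZING:
        good = truth["status"] == "undamaged"
    elif assay == Assay.ARSENIC:
        good = truth["status"] != "seed"
    else:
        good = truth["status"] == "alive"
    counts = (
        pd.DataFrame({"line": truth["line"], "good": good})
        .groupby("line")["good"]
        .agg(n_group1="sum", n_group2=lambda s: int((~s).sum()))
        .reset_index()
    )
    return screen.line_significance(
        counts, test="fisher", wild_type=wild_type, alpha=alpha
    )


def simulate_survival_counts(
    line_probs: dict[str, float],
    n_per_line: int,
    seed: int = 0,
    wild_type: str = WILD_TYPE,
) -> pd.DataFrame:
    """Status-level simulation (no images): binomial survival counts per
    line, the input for screen-calibration studies."""
    rng = np.random.default_rng(seed)
    rows = []
    for line, p in line_probs.items():
        alive = int(rng.binomial(n_per_line, p))
        rows.append({"line": line, "n_group1": alive, "n_group2": n_per_line - alive})
    if wild_type not in line_probs:
        raise ValueError("wild-type line must be included")
    return pd.DataFrame(rows)


def save_experiment(plates, out_dir: str | Path) -> pd.DataFrame:
    """Write plate PNGs plus the master truth CSV; returns the truth table."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    for images, layout, truth in plates:
        for modality, plate in images.items():
            Image.fromarray(plate.pixels).save(
                out / f"{plate.plate_id}-{modality.value}.png"
            )
        truths.append(truth)
    master = pd.concat(truths, ignore_index=True)
    master.to_csv(out / "truth.csv", index=False)
    return master
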