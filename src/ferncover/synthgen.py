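"""Synthetic-data stage: rendered well images and simulated cover tables.

Everything downstream of the experimental design can be exercised without any
real photographs: this module draws well images with per-species ground-truth
masks (for the imaging and attribution stages) and simulates well-level cover
tables with the statistical structure the mixed-model analysis assumes
(gamma-distributed cover around a deterministic growth mean, with a
multiplicative plate random effect).

Growth model
------------
Per-spore area follows a discrete logistic recursion with two competition
channels, stepped weekly from sowing (week 0):

``a_i(t+1) = a_i(t) * (1 + r_s * g_i * max(0, 1 - C_s(t) / K_s))``

where ``g_i = exp(-theta * L_i)`` is a density-based interference factor
(``L_i`` is the mean competition weight ``alpha[s_i, s_j]`` over the 19
neighbours, emulating early pheromone/resource interference at fixed sowing
density) and ``C_s(t) = sum_j alpha[s, s_j] * a_j(t)`` is the
competition-weighted well area driving late logistic saturation.  The model
is an invented stand-in calibrated to qualitative patterns only: exponential
early growth that saturates by week 10, monoculture cover ranking
F > B > A, the strongest competitor overyielding when rare and the weakest
underyielding under competition.

Rendering
---------
Gametophytes are drawn as star-convex polygon blobs (random radial harmonics)
smoothed by morphological closing, then trimmed/grown pixel-by-pixel so every
ground-truth mask hits its target pixel count exactly; measurement error in
round-trip tests therefore isolates the classification step.  Coloration is
sampled in HSV inside a species-specific green-yellow hue band on a pale agar
background that never satisfies the default green rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.morphology import closing as _closing
from skimage.morphology import dilation as _dilation
from skimage.morphology import footprint_rectangle

from .design import (
    SPORES_PER_WELL,
    WELL_RADIUS_MM,
    SporePlacement,
    WellAssignment,
    place_spores,
)

WEEK_MIN, WEEK_MAX = 4, 10
DEFAULT_PX_PER_MM2 = 2190.0  # calibration constant at the reference magnification

# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Per-species growth and competition parameters (areas in mm²).

    ``r`` is the intrinsic weekly relative growth rate, ``a0`` the
    per-gametophyte area at germination, ``k_well`` the well-level carrying
    capacity, ``alpha[s][t]`` the per-capita effect of species ``t`` on
    ``s`` (1 on the diagonal), and ``theta`` the strength of density-based
    interference.
    """

    r: dict[str, float] = field(
        default_factory=lambda: {"A": 1.7, "B": 1.9, "F": 2.2}
    )
    a0: dict[str, float] = field(
        default_factory=lambda: {"A": 0.004, "B": 0.0055, "F": 0.007}
    )
    k_well: dict[str, float] = field(
        default_factory=lambda: {"A": 120.0, "B": 160.0, "F": 220.0}
    )
    alpha: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "A": {"A": 1.0, "B": 1.2, "F": 1.6},
            "B": {"A": 0.8, "B": 1.0, "F": 1.3},
            "F": {"A": 0.5, "B": 0.7, "F": 1.0},
        }
    )
    theta: float = 0.4

    def __post_init__(self) -> None:
        for s in self.r:
            if self.r[s] <= 0 or self.a0[s] <= 0 or self.k_well[s] <= 0:
                raise ValueError(f"growth parameters for {s} must be positive")
            if self.alpha[s][s] != 1.0:
                raise ValueError(f"alpha[{s}][{s}] must be 1")


def default_perpendicularity(week: int) -> float:
    """Fraction of true gametophyte area visible from above at a given week.

    Gametophytes grow increasingly upright late in development; the default
    keeps the full area visible through week 5 and declines linearly to 0.7
    by week 10.  Within a week all species share the factor, so wells remain
    directly comparable within each observation date.
    """
    if week <= 5:
        return 1.0
    return 1.0 - 0.3 * (week - 5) / 5.0


@dataclass(frozen=True)
class AppearanceParams:
    """Rendering parameters: species coloration and scene composition.

    Hue ranges sit in the green-yellow band, ordered by species (the sexual
    species renders greenest, the weak apomict most yellow-green); the parts
    below the yellow-band ceiling pick up the standard +10° hue shift before
    classification, mirroring tissue that is "not green enough" straight off
    the camera.  Saturation is co-varied with hue so that, *after* the
    assumed hue-shift dialect, every gametophyte pixel carries a narrowly
    distributed green-channel excess (``green_excess_8bit``); the default
    classification threshold sits at the midpoint between that excess and
    the background, which keeps mean-pooled boundary blocks unbiased.
    """

    hue_range_deg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "A": (70.0, 80.0),
            "B": (78.0, 88.0),
            "F": (86.0, 96.0),
        }
    )
    #: mean, SD of the post-shift green-channel excess in 8-bit counts; the
    #: mean is set so the midpoint to the (hue-shifted) agar background falls
    #: exactly on the default classification threshold
    green_excess_8bit: tuple[float, float] = (42.3, 3.0)
    val_range: tuple[float, float] = (0.66, 0.78)
    assumed_shift: tuple[float, float, float] = (30.0, 90.0, 10.0)  # band lo/hi, offset
    background_rgb: tuple[int, int, int] = (205, 200, 188)
    background_noise: int = 3
    algae_rate: float = 0.0  # fraction of background pixels speckled with algae
    algae_rgb: tuple[int, int, int] = (96, 118, 62)
    spore_rgb: tuple[int, int, int] = (75, 60, 45)
    spore_radius_mm: float = 0.06
    perpendicularity: "callable" = default_perpendicularity

    def __post_init__(self) -> None:
        for s, (lo, hi) in self.hue_range_deg.items():
            if not (30.0 <= lo < hi <= 150.0):
                raise ValueError(f"hue range for {s} must lie within [30, 150] deg")


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic structure of the simulated cover table.

    ``gamma_shape`` is the shape of the multiplicative mean-1 gamma noise on
    well-level cover (``inf`` switches noise off); ``sigma_plate`` is the SD
    of the log-scale plate random intercept; ``missing_spores`` lists how
    many spores to lose in how many wells (default: 17 spores across 5
    wells, the loss pattern of a 120-well run).
    """

    gamma_shape: float = 25.0
    sigma_plate: float = 0.15
    missing_spores: tuple[int, ...] = (2, 3, 3, 4, 5)

    def __post_init__(self) -> None:
        if not (self.gamma_shape > 0):
            raise ValueError("gamma_shape must be > 0")
        if self.sigma_plate < 0:
            raise ValueError("sigma_plate must be >= 0")


# ---------------------------------------------------------------------------
# Growth simulation
# ---------------------------------------------------------------------------


def _grow_well(
    species: list[str],
    alive: np.ndarray,
    growth: GrowthParams,
    weeks: list[int],
) -> np.ndarray:
    """Weekly per-spore areas for one well; shape (len(weeks), n_spores)."""
    n = len(species)
    r = np.array([growth.r[s] for s in species])
    a0 = np.array([growth.a0[s] for s in species])
    k = np.array([growth.k_well[s] for s in species])
    amat = np.array([[growth.alpha[s][t] for t in species] for s in species])

    # density-based interference: mean competition weight over live neighbours,
    # normalised by the nominal 19 neighbours of a full well
    load = (amat * alive[None, :]).sum(axis=1) - np.diag(amat) * alive
    g = np.exp(-growth.theta * load / (SPORES_PER_WELL - 1))

    a = np.where(alive, a0, 0.0)
    out = np.empty((len(weeks), n))
    for week in range(0, max(weeks) + 1):
        if week in weeks:
            out[weeks.index(week)] = a
        crowd = amat @ a  # competition-weighted well area seen by each spore
        a = a * (1.0 + r * g * np.clip(1.0 - crowd / k, 0.0, None))
        a = np.where(alive, a, 0.0)
    return out


def simulate_growth(
    placements: list[SporePlacement],
    growth: GrowthParams | None = None,
    weeks: "range | list[int]" = range(WEEK_MIN, WEEK_MAX + 1),
    perpendicularity: "callable" = default_perpendicularity,
) -> pd.DataFrame:
    """True per-spore areas over the observation weeks, one row per spore-week.

    Returns columns plate_id, well, spore_index, species, week, area_mm2
    (true area) and visible_area_mm2 (area projected onto the image plane
    after the perpendicularity factor).  Missing spores contribute 0.
    """
    growth = growth or GrowthParams()
    weeks = list(weeks)
    if any(w < WEEK_MIN or w > WEEK_MAX for w in weeks):
        raise ValueError(f"weeks must lie in {WEEK_MIN}..{WEEK_MAX}")

    rows = []
    by_well: dict[tuple[int, str], list[SporePlacement]] = {}
    for p in placements:
        by_well.setdefault((p.plate_id, p.well), []).append(p)
    for (plate, well), ps in by_well.items():
        ps = sorted(ps, key=lambda p: p.spore_index)
        alive = np.array([not p.aborted_or_missing for p in ps])
        areas = _grow_well([p.species for p in ps], alive, growth, weeks)
        for wi, week in enumerate(weeks):
            perp = perpendicularity(week)
            for si, p in enumerate(ps):
                rows.append(
                    {
                        "plate_id": plate,
                        "well": well,
                        "spore_index": p.spore_index,
                        "species": p.species,
                        "week": week,
                        "area_mm2": areas[wi, si],
                        "visible_area_mm2": areas[wi, si] * perp,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Blob rendering
# ---------------------------------------------------------------------------


def _star_polygon(rng: np.random.Generator, n_vertices: int = 16) -> np.ndarray:
    """Unit star-convex outline: radius per angle with smooth harmonics."""
    phase = rng.uniform(0, 2 * np.pi, size=3)
    amp = rng.uniform(0.05, 0.16, size=3)
    phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    rho = 1.0 + sum(a * np.cos((k + 2) * phi + p) for k, (a, p) in enumerate(zip(amp, phase)))
    return np.clip(rho, 0.35, None)


def _shoelace(x: np.ndarray, y: np.ndarray) -> float:
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _adjust_to_count(
    mask: np.ndarray, target: int, center: tuple[float, float], free: np.ndarray
) -> np.ndarray:
    """Trim or grow a blob mask pixel-by-pixel until it has `target` pixels.

    Removal peels the pixels farthest from the blob center; growth adds the
    nearest free (unoccupied, in-canvas) neighbours.  Guarantees an exact
    count whenever enough free space exists.
    """
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    count = int(mask.sum())
    if count > target:
        ys, xs = np.nonzero(mask)
        order = np.argsort(d2[ys, xs])[::-1]
        drop = order[: count - target]
        mask[ys[drop], xs[drop]] = False
    while int(mask.sum()) < target:
        ring = _dilation(mask, footprint_rectangle((3, 3))) & ~mask & free
        ys, xs = np.nonzero(ring)
        if ys.size == 0:
            break  # no room left; caller tolerates the shortfall
        need = target - int(mask.sum())
        order = np.argsort(d2[ys, xs])[:need]
        mask[ys[order], xs[order]] = True
    return mask


def render_blob(
    rng: np.random.Generator,
    canvas_shape: tuple[int, int],
    center_rc: tuple[float, float],
    target_px: int,
    occupied: np.ndarray | None = None,
) -> np.ndarray:
    """Rasterize one gametophyte blob of exactly ``target_px`` pixels.

    Star-convex polygon outline, morphological closing for smooth lobes,
    then exact pixel-count adjustment avoiding ``occupied`` pixels.
    """
    if target_px <= 0:
        return np.zeros(canvas_shape, dtype=bool)
    free = np.ones(canvas_shape, dtype=bool) if occupied is None else ~occupied
    rho = _star_polygon(rng)
    phi = np.linspace(0, 2 * np.pi, len(rho), endpoint=False)
    unit_area = _shoelace(rho * np.cos(phi), rho * np.sin(phi))
    scale = np.sqrt(target_px / unit_area)
    rr, cc = draw_polygon(
        center_rc[0] + scale * rho * np.sin(phi),
        center_rc[1] + scale * rho * np.cos(phi),
        shape=canvas_shape,
    )
    mask = np.zeros(canvas_shape, dtype=bool)
    mask[rr, cc] = True
    if target_px >= 16:
        mask = _closing(mask, footprint_rectangle((3, 3)))
    mask &= free
    return _adjust_to_count(mask, target_px, center_rc, free)


def _sample_species_rgb(
    rng: np.random.Generator, appearance: AppearanceParams, species: str, n: int
) -> np.ndarray:
    lo, hi = appearance.hue_range_deg[species]
    band_lo, band_hi, offset = appearance.assumed_shift
    hue = rng.uniform(lo, hi, n)
    # hue after the standard yellow-band shift the measurement dialect applies
    hue_eff = np.where((hue >= band_lo) & (hue <= band_hi), hue + offset, hue)
    # green-over-red excess of a green-sector HSV pixel is chroma*(h-60)/60;
    # fix the post-shift excess by solving for chroma given the sampled hue
    mean, sd = appearance.green_excess_8bit
    g8 = np.clip(rng.normal(mean, sd, n), mean - 2.5 * sd, mean + 2.5 * sd)
    factor = np.clip((hue_eff - 60.0) / 60.0, 0.05, 1.0)
    chroma = g8 / 255.0 / factor
    val = rng.uniform(*appearance.val_range, n)
    sat = np.clip(chroma / val, 0.05, 0.95)
    hsv = np.stack([hue / 360.0, sat, val], axis=-1)
    return np.clip(np.rint(hsv2rgb(hsv[None, :, :])[0] * 255), 0, 255).astype(np.uint8)


def _background(
    rng: np.random.Generator, shape: tuple[int, int], appearance: AppearanceParams
) -> np.ndarray:
    base = np.array(appearance.background_rgb, dtype=np.int16)
    img = base[None, None, :] + rng.integers(
        -appearance.background_noise, appearance.background_noise + 1, size=shape + (3,)
    )
    img = np.clip(img, 0, 255).astype(np.uint8)
    if appearance.algae_rate > 0:
        spots = rng.random(shape) < appearance.algae_rate
        img[spots] = np.array(appearance.algae_rgb, dtype=np.uint8)
    return img


def well_canvas_shape(px_per_mm2: float) -> tuple[int, int]:
    side = int(np.ceil(2 * WELL_RADIUS_MM * np.sqrt(px_per_mm2)))
    return side, side


def _mm_to_rc(x_mm: float, y_mm: float, px_per_mm: float, side: int) -> tuple[float, float]:
    # origin at well center; x rightward -> columns, y downward -> rows
    return side / 2.0 + y_mm * px_per_mm, side / 2.0 + x_mm * px_per_mm


def render_well_image(
    placements: list[SporePlacement],
    visible_areas_mm2: dict[int, float],
    appearance: AppearanceParams | None = None,
    px_per_mm2: float = DEFAULT_PX_PER_MM2,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Render one well at one observation date.

    ``visible_areas_mm2`` maps spore_index to the projected area to draw.
    Returns the 8-bit RGB image and one boolean ground-truth mask per
    species; masks are disjoint by construction and their union is exactly
    the rendered foreground.
    """
    appearance = appearance or AppearanceParams()
    rng = np.random.default_rng(seed)
    px_per_mm = np.sqrt(px_per_mm2)
    shape = well_canvas_shape(px_per_mm2)
    img = _background(rng, shape, appearance)

    occupied = np.zeros(shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    total_target = sum(
        visible_areas_mm2.get(p.spore_index, 0.0) for p in placements
    ) * px_per_mm2
    if total_target > 0.6 * shape[0] * shape[1]:
        raise ValueError("requested blob area exceeds the well raster")
    for p in placements:
        if p.aborted_or_missing:
            continue
        target = int(round(visible_areas_mm2.get(p.spore_index, 0.0) * px_per_mm2))
        if target <= 0:
            continue
        center = _mm_to_rc(p.x_mm, p.y_mm, px_per_mm, shape[0])
        blob = render_blob(rng, shape, center, target, occupied)
        occupied |= blob
        masks.setdefault(p.species, np.zeros(shape, dtype=bool))
        masks[p.species] |= blob
        img[blob] = _sample_species_rgb(rng, appearance, p.species, int(blob.sum()))
    return img, masks


def render_sowing_image(
    placements: list[SporePlacement],
    species_subset: "set[str] | None" = None,
    appearance: AppearanceParams | None = None,
    px_per_mm2: float = DEFAULT_PX_PER_MM2,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Photograph taken right after sowing: dark spore dots on agar.

    ``species_subset`` restricts which species' spores are visible — the
    first-sowing image of a two-species well shows only the first species,
    the second image shows both.  Missing spores are never drawn.
    """
    appearance = appearance or AppearanceParams()
    rng = np.random.default_rng(seed)
    px_per_mm = np.sqrt(px_per_mm2)
    shape = well_canvas_shape(px_per_mm2)
    img = _background(rng, shape, appearance)
    radius = max(1.5, appearance.spore_radius_mm * px_per_mm)
    for p in placements:
        if p.aborted_or_missing:
            continue
        if species_subset is not None and p.species not in species_subset:
            continue
        rr, cc = draw_disk(_mm_to_rc(p.x_mm, p.y_mm, px_per_mm, shape[0]), radius, shape=shape)
        img[rr, cc] = appearance.spore_rgb
    return img


def render_calibration_square(
    area_mm2: float = 100.0,
    px_per_mm2: float = DEFAULT_PX_PER_MM2,
    seed: int | np.random.Generator = 0,
    margin_px: int = 12,
    block_align: int = 2,
) -> np.ndarray:
    """A red reference square of known area on a plain background.

    The red region contains exactly ``round(area_mm2 * px_per_mm2)`` pixels,
    laid out as an even-sided square plus complete ``block_align``-sized
    tiles for the remainder, all aligned to the ``block_align`` raster grid.
    The alignment keeps block-downsampled red counts exact (no partially
    covered pooling blocks), so calibration can be validated to the pixel at
    the standard processing factor.
    """
    if px_per_mm2 <= 0:
        raise ValueError("px_per_mm2 must be positive")
    rng = np.random.default_rng(seed)
    target = int(round(area_mm2 * px_per_mm2))
    ba = max(1, int(block_align))
    margin_px = (margin_px // ba) * ba
    side = int(np.floor(np.sqrt(target)))
    side -= side % ba
    extra = target - side * side  # laid as ba-wide tile columns right of the square
    n_cols = -(-extra // (side if side else 1)) if side else 1
    shape = (
        max(side, ba) + 2 * margin_px,
        side + (n_cols + 1) * ba + 2 * margin_px,
    )
    img = np.clip(
        np.array([235, 232, 228], dtype=np.int16)[None, None, :]
        + rng.integers(-2, 3, size=shape + (3,)),
        0,
        255,
    ).astype(np.uint8)
    sq = np.zeros(shape, dtype=bool)
    sq[margin_px : margin_px + side, margin_px : margin_px + side] = True
    # remainder: full ba x ba tiles stacked in columns flush with the square
    placed = 0
    col = margin_px + side
    row = margin_px
    while placed < extra:
        tile = min(ba * ba, extra - placed)
        rr = np.arange(tile) // ba + row
        cc = np.arange(tile) % ba + col
        sq[rr, cc] = True
        placed += tile
        row += ba
        if row + ba > margin_px + max(side, ba):
            row = margin_px
            col += ba
    red = np.array([190, 45, 40], dtype=np.int16)
    noise = rng.integers(-5, 6, size=(int(sq.sum()), 3))
    img[sq] = np.clip(red[None, :] + noise, 0, 255).astype(np.uint8)
    return img


# ---------------------------------------------------------------------------
# Cover-table simulation
# ---------------------------------------------------------------------------


def gamma_noise(rng: np.random.Generator, shape_nu: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative gamma noise; shape ``inf`` returns exact ones."""
    if np.isinf(shape_nu):
        return np.ones(size)
    return rng.gamma(shape_nu, 1.0 / shape_nu, size)


def simulate_cover_table(
    design: list[WellAssignment],
    growth: GrowthParams | None = None,
    noise: NoiseParams | None = None,
    seed: int | np.random.Generator = 0,
    weeks: "range | list[int]" = range(WEEK_MIN, WEEK_MAX + 1),
    px_per_mm2: float = DEFAULT_PX_PER_MM2,
    dropped_plate_weeks: "dict[int, tuple[int, ...]] | None" = None,
    perpendicularity: "callable" = default_perpendicularity,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a deposited-style data set directly, without rendering images.

    Well-level cover is ``deterministic growth mean x exp(plate effect) x
    mean-1 gamma noise``; the week-5 per-species split follows the species'
    true area shares, so species pixels sum exactly to the well total.

    Returns ``(cover, week5)``: one row per well-week with total pixels and
    mm², and one row per well-species at week 5 with per-species pixels.
    Ratio columns (theoretical area, raw and standardized ratio) are not
    filled in here — the analysis stage computes them.

    ``dropped_plate_weeks`` removes observations (e.g. ``{8: (9, 10)}`` drops
    weeks 9-10 of plate 8, emulating plates that could not be recorded late
    in a run); by default the last three plates of a 10-plate design lose
    weeks 9 and 10.
    """
    growth = growth or GrowthParams()
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    weeks = list(weeks)
    if any(w < WEEK_MIN or w > WEEK_MAX for w in weeks):
        raise ValueError(f"weeks must lie in {WEEK_MIN}..{WEEK_MAX}")

    plate_ids = sorted({a.plate_id for a in design})
    if dropped_plate_weeks is None:
        dropped_plate_weeks = (
            {p: (9, 10) for p in plate_ids[-3:]} if len(plate_ids) == 10 else {}
        )
    plate_effect = {
        p: float(rng.normal(0.0, noise.sigma_plate)) for p in plate_ids
    }

    # choose the missing-spore wells once, uniformly over the design
    n_deficient = len(noise.missing_spores)
    deficient: dict[int, int] = {}
    if n_deficient:
        idx = rng.choice(len(design), size=min(n_deficient, len(design)), replace=False)
        deficient = {int(i): int(n) for i, n in zip(idx, noise.missing_spores)}

    cover_rows = []
    week5_rows = []
    for di, a in enumerate(design):
        labels: list[str] = []
        for code, n in a.combination.counts:
            labels.extend([code] * n)
        alive = np.ones(len(labels), dtype=bool)
        n_miss = deficient.get(di, 0)
        if n_miss:
            alive[rng.choice(len(labels), size=n_miss, replace=False)] = False
        areas = _grow_well(labels, alive, growth, weeks)  # (n_weeks, 20)
        species = np.array(labels)
        eff = np.exp(plate_effect[a.plate_id])
        for wi, week in enumerate(weeks):
            if week in dropped_plate_weeks.get(a.plate_id, ()):
                continue
            visible = areas[wi] * perpendicularity(week)
            mu = float(visible.sum())
            y = mu * eff * float(gamma_noise(rng, noise.gamma_shape, 1)[0])
            cover_rows.append(
                {
                    "plate_id": a.plate_id,
                    "well": a.well,
                    "plate_well": a.label,
                    "week": week,
                    "species_1": a.combination.counts[0][0],
                    "n_1": a.combination.counts[0][1],
                    "species_2": a.combination.counts[1][0]
                    if len(a.combination.counts) > 1
                    else "",
                    "n_2": a.combination.counts[1][1]
                    if len(a.combination.counts) > 1
                    else 0,
                    "bordering_sides": a.bordering_sides,
                    "n_spores_sown": int(alive.sum()),
                    "total_pixels": y * px_per_mm2,
                    "total_area_mm2": y,
                }
            )
            if week == 5:
                for code, n_sown in a.combination.counts:
                    share = (
                        float(visible[species == code].sum()) / mu if mu > 0 else 0.0
                    )
                    week5_rows.append(
                        {
                            "plate_id": a.plate_id,
                            "well": a.well,
                            "plate_well": a.label,
                            "week": week,
                            "species": code,
                            "n_spores_of_species": n_sown,
                            "n_spores_sown": int(alive.sum()),
                            "pixels_species": y * share * px_per_mm2,
                            "area_species_mm2": y * share,
                            "total_pixels": y * px_per_mm2,
                            "total_area_mm2": y,
                        }
                    )
    return pd.DataFrame(cover_rows), pd.DataFrame(week5_rows)


def default_missing_plan(
    design: list[WellAssignment],
    noise: NoiseParams,
    seed: int | np.random.Generator = 0,
) -> dict[tuple[int, str], int]:
    """Pick which wells lose how many spores, mirroring the table simulator."""
    rng = np.random.default_rng(seed)
    n = len(noise.missing_spores)
    idx = rng.choice(len(design), size=min(n, len(design)), replace=False)
    return {
        (design[int(i)].plate_id, design[int(i)].well): int(m)
        for i, m in zip(idx, noise.missing_spores)
    }


def placements_for_design(
    design: list[WellAssignment],
    seed: int = 0,
    min_spacing_mm: float | None = None,
    missing_plan: "dict[tuple[int, str], int] | None" = None,
) -> list[SporePlacement]:
    """Spore placements for every well of a design, seed-deterministic."""
    from .design import DEFAULT_MIN_SPACING_MM

    spacing = DEFAULT_MIN_SPACING_MM if min_spacing_mm is None else min_spacing_mm
    rng = np.random.default_rng(seed)
    out: list[SporePlacement] = []
    for a in design:
        n_miss = (missing_plan or {}).get((a.plate_id, a.well), 0)
        out.extend(place_spores(a, rng, min_spacing_mm=spacing, n_missing=n_miss))
    return out
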