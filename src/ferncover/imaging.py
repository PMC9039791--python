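"""Cover measurement: hue shifting, color classification, calibration.

The measurement chain mirrors a green-pixel leaf-area workflow: (1) shift
part of the yellow hue band toward green so pale gametophyte tissue is
countable, (2) classify pixels as green by channel dominance after an
optional block-downsampling step, (3) convert pixel counts to mm² using a
calibration constant obtained from photographs of red reference squares of
known area.

The classification rule (target channel must exceed each other channel by
``min_excess`` counts and reach ``min_value``) is this package's own
re-implementation of the green/red detection idea; its defaults are
calibrated on the synthetic fixtures and, like any color threshold, should
be re-calibrated per imaging setup.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from skimage.color import hsv2rgb, rgb2hsv

# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HueShiftSpec:
    """Shift hues inside a band by a fixed offset (degrees).

    Default: the yellow band [30°, 90°] moved +10°, turning yellow-green
    tissue green while leaving background and red references untouched.
    ``falloff='cosine'`` tapers the offset smoothly to zero at the band
    edges instead of the default hard window.
    """

    band_deg: tuple[float, float] = (30.0, 90.0)
    offset_deg: float = 10.0
    falloff: str = "none"  # {"none", "cosine"}

    def __post_init__(self) -> None:
        lo, hi = self.band_deg
        if not (0.0 <= lo < hi < 360.0):
            raise ValueError(f"band must lie within [0, 360): {self.band_deg}")
        if not np.isfinite(self.offset_deg):
            raise ValueError("offset must be finite")
        if self.falloff not in ("none", "cosine"):
            raise ValueError(f"unknown falloff: {self.falloff!r}")


@dataclass(frozen=True)
class ColorRule:
    """Channel-dominance classification rule for green or red pixels.

    A (possibly downsampled) pixel is positive iff the target channel
    exceeds each of the other two by at least ``min_excess`` counts and is
    at least ``min_value``.  ``downsample_factor`` block-averages the image
    by that linear factor first (the "processing speed" dial: it changes
    how many pixels are analyzed), so counts are reported in downsampled
    pixels and calibration must use the same factor.
    """

    target: str = "green"  # {"green", "red"}
    min_excess: int = 10
    min_value: int = 40
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        if self.target not in ("green", "red"):
            raise ValueError(f"unknown target: {self.target!r}")
        if self.min_excess < 0 or not (0 <= self.min_value <= 255):
            raise ValueError("min_excess >= 0 and min_value in 0..255 required")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")


#: classification dialect of the study: green rule at 2x linear downsampling.
#: min_excess 20 sits midway between the gametophyte tissue's green-channel
#: excess (~45 counts after the hue shift) and the agar background (~0), so
#: partially covered pooling blocks classify without systematic bias.
DEFAULT_GREEN_RULE = ColorRule("green", 20, 40, 2)
DEFAULT_RED_RULE = ColorRule("red", 10, 40, 2)


@dataclass(frozen=True)
class Calibration:
    """Pixels-per-mm² conversion estimated from reference squares."""

    px_per_mm2: float
    n_observations: int = 1
    source_area_mm2: float = 100.0

    def __post_init__(self) -> None:
        if not (self.px_per_mm2 > 0):
            raise ValueError("px_per_mm2 must be positive")


@dataclass(frozen=True)
class GreenMask:
    """Binary classification raster with its positive-pixel count."""

    mask: np.ndarray
    count: int

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "GreenMask":
        return cls(mask, int(mask.sum()))


@dataclass(frozen=True)
class CoverObservation:
    """Calibrated green cover of one well at one observation date."""

    plate_id: int
    well: str
    week: int
    pixels: int
    area_mm2: float


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _check_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image of shape (H, W, 3)")
    return image


def shift_hue_band(image: np.ndarray, spec: HueShiftSpec | None = None) -> np.ndarray:
    """Return a copy with in-band hues offset; all other pixels untouched.

    Hue uses the standard 0-360° hexagon convention.  Zero-saturation pixels
    have no defined hue and are never modified; saturation and value are
    preserved exactly for shifted pixels (up to 8-bit rounding).
    """
    spec = spec or HueShiftSpec()
    image = _check_rgb(image)
    hsv = rgb2hsv(image)
    hue = hsv[..., 0] * 360.0
    lo, hi = spec.band_deg
    in_band = (hue >= lo) & (hue <= hi) & (hsv[..., 1] > 0)
    if not in_band.any():
        return image.copy()
    if spec.falloff == "cosine":
        # full offset at band center, tapering to 0 at the edges
        mid, half = (lo + hi) / 2.0, (hi - lo) / 2.0
        offset = spec.offset_deg * np.cos(np.pi / 2.0 * (hue - mid) / half)
    else:
        offset = np.full_like(hue, spec.offset_deg)
    sub = hsv[in_band]
    sub[:, 0] = ((hue[in_band] + offset[in_band]) % 360.0) / 360.0
    out = image.copy()
    out[in_band] = np.clip(np.rint(hsv2rgb(sub[None, :, :])[0] * 255.0), 0, 255).astype(
        np.uint8
    )
    return out


def downsample_mean(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-average by an integer linear factor (trailing remainder cropped).

    Returns float64 channel means so the classification threshold sees the
    un-rounded block averages.
    """
    if factor == 1:
        return np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    h2, w2 = h // factor, w // factor
    trimmed = image[: h2 * factor, : w2 * factor].astype(np.float64)
    return trimmed.reshape(h2, factor, w2, factor, 3).mean(axis=(1, 3))


def classify_color(image: np.ndarray, rule: ColorRule | None = None) -> GreenMask:
    """Classify pixels by channel dominance after block downsampling."""
    rule = rule or DEFAULT_GREEN_RULE
    image = _check_rgb(image)
    pooled = downsample_mean(image, rule.downsample_factor)
    t = 1 if rule.target == "green" else 0
    others = [c for c in range(3) if c != t]
    mask = (
        (pooled[..., t] >= pooled[..., others[0]] + rule.min_excess)
        & (pooled[..., t] >= pooled[..., others[1]] + rule.min_excess)
        & (pooled[..., t] >= rule.min_value)
    )
    return GreenMask.from_mask(mask)


def calibrate(
    square_images: list[np.ndarray],
    known_area_mm2: float = 100.0,
    red_rule: ColorRule | None = None,
) -> Calibration:
    """Average red-pixel count over reference squares -> pixels per mm².

    Squares must be photographed at the same magnification and processed at
    the same downsampling factor as the sample images.
    """
    red_rule = red_rule or DEFAULT_RED_RULE
    if not square_images:
        raise ValueError("need at least one reference-square image")
    counts = []
    for i, img in enumerate(square_images):
        c = classify_color(img, red_rule).count
        if c == 0:
            raise ValueError(f"reference image {i} contains no red pixels")
        counts.append(c)
    return Calibration(
        px_per_mm2=float(np.mean(counts)) / known_area_mm2,
        n_observations=len(counts),
        source_area_mm2=known_area_mm2,
    )


def pixels_to_area(count: int, calibration: Calibration) -> float:
    """Pixel count -> mm² via the calibration constant."""
    if count < 0:
        raise ValueError("pixel count must be >= 0")
    return count / calibration.px_per_mm2


def jpeg_recode(image: np.ndarray, quality: int = 95) -> np.ndarray:
    """Round-trip through JPEG, emulating the study's processing dialect.

    Chroma subsampling is disabled: color thresholding is the very next
    step, and 4:2:0 chroma would smear hue across gametophyte boundaries.
    """
    buf = io.BytesIO()
    Image.fromarray(_check_rgb(image)).save(
        buf, format="JPEG", quality=quality, subsampling=0
    )
    buf.seek(0)
    return np.asarray(Image.open(buf).convert("RGB"))


def measure_well(
    image: np.ndarray,
    calibration: Calibration,
    hue_spec: HueShiftSpec | None = None,
    green_rule: ColorRule | None = None,
    plate_id: int = 0,
    well: str = "",
    week: int = 4,
    jpeg_dialect: bool = False,
) -> CoverObservation:
    """Full measurement chain: hue shift -> green classification -> mm²."""
    if jpeg_dialect:
        image = jpeg_recode(image)
    shifted = shift_hue_band(image, hue_spec)
    mask = classify_color(shifted, green_rule)
    return CoverObservation(
        plate_id=plate_id,
        well=well,
        week=week,
        pixels=mask.count,
        area_mm2=pixels_to_area(mask.count, calibration),
    )


def outline_area_mm2(mask: np.ndarray, px_per_mm2: float) -> float:
    """Polygon-outline area of a binary mask, in mm².

    Emulates outlining each gametophyte with a polygon tool: every connected
    component's outer contour is traced at the half-level and its shoelace
    area taken.  Serves as the independent oracle for ratio-of-estimates
    comparisons against the pixel-counting chain.  ``px_per_mm2`` must be at
    the mask's own (full) resolution, not a downsampled calibration.
    """
    from skimage.measure import find_contours, label

    total_px = 0.0
    lab = label(mask)
    for region in range(1, lab.max() + 1):
        comp = lab == region
        padded = np.pad(comp.astype(float), 1)
        contours = find_contours(padded, 0.5)
        if not contours:
            continue
        c = max(contours, key=len)
        x, y = c[:, 1], c[:, 0]
        total_px += 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return total_px / px_per_mm2


def naive_classify(image: np.ndarray, rule: ColorRule) -> np.ndarray:
    """Brute-force per-pixel reference for :func:`classify_color`.

    Plain Python loops, kept deliberately independent of the vectorized
    implementation; used as the exact-equivalence oracle in tests.
    """
    image = _check_rgb(image)
    f = rule.downsample_factor
    h, w = image.shape[0] // f, image.shape[1] // f
    t = 1 if rule.target == "green" else 0
    others = [c for c in range(3) if c != t]
    out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        for j in range(w):
            sums = [0.0, 0.0, 0.0]
            for di in range(f):
                for dj in range(f):
                    for ch in range(3):
                        sums[ch] += float(image[i * f + di, j * f + dj, ch])
            means = [s / (f * f) for s in sums]
            out[i, j] = (
                means[t] >= means[others[0]] + rule.min_excess
                and means[t] >= means[others[1]] + rule.min_excess
                and means[t] >= rule.min_value
            )
    return out
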