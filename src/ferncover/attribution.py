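"""Week-5 per-species cover via sowing-image registration and deletion.

At week 5 gametophytes do not yet physically overlap, so each one can still
be traced back to the spore it grew from.  Species identity comes from the
pair of sowing photographs of a two-species well: the first image shows only
the first species' spores, the second shows both, so spots present in both
images belong to species 1 and spots appearing only in the second belong to
species 2.  One species is then deleted from the week-5 image (painted over
with background) and the well is re-measured with the *same* classification
settings: the remaining pixels belong to the kept species, and the drop from
the unaltered total is attributed to the deleted species.  The subtraction
conserves pixels exactly by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops

from .imaging import _check_rgb

DEFAULT_TOLERANCE_MM = 0.4
MIN_SPOT_PX = 3


@dataclass(frozen=True)
class SpeciesCover:
    """Green pixels attributed to one species in one well at week 5."""

    plate_id: int
    well: str
    species: str
    pixels: int
    area_mm2: float
    method: str  # {"deletion-difference", "ground-truth"}

    def __post_init__(self) -> None:
        if self.pixels < 0:
            raise ValueError("pixels must be >= 0")


@dataclass(frozen=True)
class SpotLabel:
    """A detected spore spot with its inferred species label."""

    x_px: float
    y_px: float
    species_rank: int  # 1 = first-sown species, 2 = second-sown


def detect_spots(
    image: np.ndarray, darkness_threshold: int = 50, min_px: int = MIN_SPOT_PX
) -> np.ndarray:
    """Centroids (x, y in px) of dark spore spots on the agar background.

    A pixel is spot-like if its luminance falls ``darkness_threshold`` counts
    below the image median (the agar dominates the frame, so the median is a
    robust background estimate); connected components smaller than ``min_px``
    are discarded as debris.
    """
    image = _check_rgb(image)
    lum = image.astype(np.float64).mean(axis=2)
    dark = lum < np.median(lum) - darkness_threshold
    lab = label(dark)
    out = []
    for region in regionprops(lab):
        if region.num_pixels >= min_px:
            r, c = region.centroid
            out.append((c, r))
    return np.asarray(out, dtype=np.float64).reshape(-1, 2)


def register_spore_species(
    image_first_sowing: np.ndarray,
    image_both_sowings: np.ndarray,
    px_per_mm: float,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
) -> tuple[list[SpotLabel], bool]:
    """Infer each spore's species from the pair of co-registered sowing images.

    Spots in the combined image are matched (nearest neighbour, within a
    tolerance radius) against the first-sowing image: matched spots are the
    first species, the rest the second.  Returns the labelled spots and a
    flag that is True when any first-image spot finds no partner — such
    wells cannot be attributed reliably and should be excluded.
    """
    first = detect_spots(image_first_sowing)
    both = detect_spots(image_both_sowings)
    tol_px = tolerance_mm * px_per_mm

    labels: list[SpotLabel] = []
    unresolved = False
    if len(first) == 0:
        labels = [SpotLabel(x, y, 2) for x, y in both]
        return labels, False
    if len(both) == 0:
        return [], len(first) > 0

    tree = cKDTree(both)
    matched: set[int] = set()
    for x, y in first:
        d, j = tree.query([x, y])
        if d <= tol_px and j not in matched:
            matched.add(int(j))
        else:
            unresolved = True  # a first-sowing spore vanished or drifted away
    for j, (x, y) in enumerate(both):
        labels.append(SpotLabel(float(x), float(y), 1 if j in matched else 2))
    return labels, unresolved


def delete_species(
    image: np.ndarray,
    species_mask: np.ndarray,
    background_rgb: tuple[int, int, int] = (205, 200, 188),
) -> np.ndarray:
    """Paint one species out of the image (replaced by background color)."""
    image = _check_rgb(image)
    if species_mask.shape != image.shape[:2]:
        raise ValueError("mask shape must match image")
    out = image.copy()
    out[species_mask] = np.array(background_rgb, dtype=np.uint8)
    return out


def attribute_by_difference(
    total_pixels: int,
    altered_pixels: int,
    deleted_species: str,
    kept_species: str,
    plate_id: int = 0,
    well: str = "",
    px_per_mm2: float = 1.0,
) -> tuple[SpeciesCover, SpeciesCover]:
    """Split a well's green pixels between two species by subtraction.

    The altered (one-species-deleted) count belongs to the kept species; the
    difference from the unaltered total belongs to the deleted one.  An
    altered count above the total signals inconsistent processing settings
    between the two measurement passes and is rejected.
    """
    if not (0 <= altered_pixels <= total_pixels):
        raise ValueError(
            f"altered count {altered_pixels} outside [0, total={total_pixels}]: "
            "total and altered images must be measured with identical settings"
        )
    kept = SpeciesCover(
        plate_id, well, kept_species, altered_pixels,
        altered_pixels / px_per_mm2, "deletion-difference",
    )
    deleted = SpeciesCover(
        plate_id, well, deleted_species, total_pixels - altered_pixels,
        (total_pixels - altered_pixels) / px_per_mm2, "deletion-difference",
    )
    return kept, deleted
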