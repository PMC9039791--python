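"""Replacement-series experimental design for well-plate spore competition.

Generates and validates the layout of a gametophyte competition experiment:
which species combinations exist, where each combination sits on each plate,
and where the individual spores land inside a well.

The design is a *replacement series*: total spore density per well is held
fixed (20 spores) while the species proportions vary (20:0, 15:5, 10:10).
Plates are standard 12-well plates, 3 rows (A-C) by 4 columns (1-4), and
every plate carries each combination exactly once.  Across plates, each
combination additionally occupies a distinct well position (a Latin-rectangle
style constraint) so that position-in-plate effects cannot confound the
combination effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Plate geometry
# ---------------------------------------------------------------------------

N_ROWS = 3
N_COLS = 4
WELLS_PER_PLATE = N_ROWS * N_COLS
ROW_LETTERS = "ABC"
SPORES_PER_WELL = 20
WELL_RADIUS_MM = 11.0  # 12-well plate, well radius 1.1 cm
#: spores are sown only in the central half-radius of the well, avoiding the
#: agar meniscus near the wall
SOWING_RADIUS_MM = 0.5 * WELL_RADIUS_MM
DEFAULT_MIN_SPACING_MM = 0.8

DEFAULT_RATIOS = ((20, 0), (15, 5), (10, 10))


def well_label(row: int, col: int) -> str:
    """Label a well position in column-number + row-letter style (e.g. ``4B``).

    ``row`` and ``col`` are 0-based indices; rows map to letters A-C and
    columns to numbers 1-4.
    """
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well position out of range: row={row}, col={col}")
    return f"{col + 1}{ROW_LETTERS[row]}"


def parse_well_label(label: str) -> tuple[int, int]:
    """Inverse of :func:`well_label`: ``"4B"`` -> ``(1, 3)`` as (row, col)."""
    label = label.strip().upper()
    if len(label) != 2 or not label[0].isdigit() or label[1] not in ROW_LETTERS:
        raise ValueError(f"malformed well label: {label!r}")
    col = int(label[0]) - 1
    row = ROW_LETTERS.index(label[1])
    if not (0 <= col < N_COLS):
        raise ValueError(f"column out of range in well label: {label!r}")
    return row, col


def bordering_sides(row: int, col: int) -> int:
    """Number of plate-boundary edges the well at (row, col) touches.

    On a 3x4 plate a corner well (e.g. 4A) has 2 bordering sides, a
    non-corner edge well has 1, and the two interior wells (2B, 3B) have 0.
    The count is a nuisance covariate for edge effects (light, evaporation).
    """
    return int(row in (0, N_ROWS - 1)) + int(col in (0, N_COLS - 1))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesProfile:
    """A species entering the competition experiment.

    The gametophyte generation of an apomictic fern retains the sporophyte's
    ploidy (unreduced spores), whereas a sexual species produces gametophytes
    at half the sporophyte ploidy.  Both facts are enforced as invariants.
    """

    code: str
    name: str
    reproduction: str  # {"apomict", "sexual"}
    ploidy_sporophyte: int
    ploidy_gametophyte: int

    def __post_init__(self) -> None:
        if self.reproduction not in ("apomict", "sexual"):
            raise ValueError(f"unknown reproduction type: {self.reproduction!r}")
        if self.ploidy_sporophyte < 2:
            raise ValueError("sporophyte ploidy must be >= 2")
        if self.ploidy_gametophyte < 1:
            raise ValueError("gametophyte ploidy must be >= 1")
        if self.reproduction == "apomict":
            if self.ploidy_gametophyte != self.ploidy_sporophyte:
                raise ValueError(
                    f"{self.code}: apomict gametophyte ploidy must equal "
                    f"sporophyte ploidy"
                )
        else:
            if self.ploidy_sporophyte != 2 * self.ploidy_gametophyte:
                raise ValueError(
                    f"{self.code}: sexual gametophyte ploidy must be half the "
                    f"sporophyte ploidy"
                )


#: The three wood-fern species of the study system: two apomicts (diploid
#: D. affinis, triploid D. borreri) and a sexual tetraploid (D. filix-mas,
#: diploid gametophytes).
DEFAULT_SPECIES = (
    SpeciesProfile("A", "Dryopteris affinis", "apomict", 2, 2),
    SpeciesProfile("B", "Dryopteris borreri", "apomict", 3, 3),
    SpeciesProfile("F", "Dryopteris filix-mas", "sexual", 4, 2),
)

ALLOWED_COUNTS = frozenset({20, 15, 10, 5})


@dataclass(frozen=True)
class SporeCombination:
    """A species -> spore-count assignment for one well (counts sum to 20)."""

    counts: tuple[tuple[str, int], ...]  # sorted (code, n) pairs, n > 0

    def __post_init__(self) -> None:
        codes = [c for c, _ in self.counts]
        ns = [n for _, n in self.counts]
        if len(set(codes)) != len(codes):
            raise ValueError(f"duplicate species code in combination: {codes}")
        if sum(ns) != SPORES_PER_WELL:
            raise ValueError(f"spore counts must sum to {SPORES_PER_WELL}: {ns}")
        if len(ns) > 2:
            raise ValueError("at most two species per well")
        if not all(n in ALLOWED_COUNTS for n in ns):
            raise ValueError(f"spore counts must be from {sorted(ALLOWED_COUNTS)}: {ns}")

    @classmethod
    def of(cls, **counts: int) -> "SporeCombination":
        return cls(tuple(sorted((c, n) for c, n in counts.items() if n > 0)))

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.counts)

    @property
    def is_monoculture(self) -> bool:
        return len(self.counts) == 1

    def count_of(self, code: str) -> int:
        return dict(self.counts).get(code, 0)

    @property
    def label(self) -> str:
        return "".join(f"{c}{n}" for c, n in self.counts)

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


@dataclass(frozen=True)
class WellAssignment:
    """One combination placed at one well position on one plate."""

    plate_id: int
    row: int
    col: int
    combination: SporeCombination

    @property
    def well(self) -> str:
        return well_label(self.row, self.col)

    @property
    def bordering_sides(self) -> int:
        return bordering_sides(self.row, self.col)

    @property
    def label(self) -> str:
        """Plate-well label in ``K<plate>-<well>`` style, e.g. ``K5-4B``."""
        return f"K{self.plate_id}-{self.well}"


@dataclass(frozen=True)
class SporePlacement:
    """A single sown spore: species label and position in mm from well center.

    x increases rightward and y downward, matching raster conventions so that
    placements map directly onto image coordinates.
    """

    plate_id: int
    well: str
    spore_index: int  # 1..20
    species: str
    x_mm: float
    y_mm: float
    aborted_or_missing: bool = False


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_combinations(
    species: list[str] | tuple[str, ...],
    ratios: tuple[tuple[int, int], ...] = DEFAULT_RATIOS,
) -> list[SporeCombination]:
    """All spore combinations of the replacement series, in deterministic order.

    Monocultures come first (one per species, from the ``(20, 0)`` ratio),
    then for each asymmetric ratio every *ordered* pair of distinct species,
    then the symmetric 10:10 ratio once per unordered pair.  With 3 species
    and the standard ratios this yields 3 + 6 + 3 = 12 combinations.
    """
    species = list(species)
    if len(set(species)) != len(species):
        raise ValueError(f"duplicate species codes: {species}")
    for hi, lo in ratios:
        if hi + lo != SPORES_PER_WELL:
            raise ValueError(f"ratio counts must sum to {SPORES_PER_WELL}: {(hi, lo)}")

    out: list[SporeCombination] = []
    seen: set[tuple[tuple[str, int], ...]] = set()

    def push(combo: SporeCombination) -> None:
        if combo.counts not in seen:
            seen.add(combo.counts)
            out.append(combo)

    for hi, lo in ratios:
        if lo == 0:
            for s in species:
                push(SporeCombination.of(**{s: hi}))
        else:
            for s, t in itertools.permutations(species, 2):
                # 10:10 of {X, Y} is unordered: dedup via canonical counts
                push(SporeCombination.of(**{s: hi, t: lo}))
    return out


def build_design(
    combinations: list[SporeCombination],
    n_plates: int,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 2000,
) -> list[WellAssignment]:
    """Assign every combination to a well on every plate.

    Each plate receives a permutation of all combinations, with the cross-
    plate constraint that no combination ever repeats a well position.  This
    is a random Latin rectangle built plate-by-plate with restart-on-conflict;
    it is feasible for ``n_plates <= 12`` (wells per plate).
    """
    if len(combinations) != WELLS_PER_PLATE:
        raise ValueError(
            f"need exactly {WELLS_PER_PLATE} combinations for a "
            f"{N_ROWS}x{N_COLS} plate, got {len(combinations)}"
        )
    if n_plates > WELLS_PER_PLATE:
        raise ValueError(
            f"unique-position constraint infeasible for n_plates={n_plates} > "
            f"{WELLS_PER_PLATE}; use <= {WELLS_PER_PLATE} plates"
        )
    rng = np.random.default_rng(seed)
    n_c = len(combinations)
    # used[c] = set of well indices already taken by combination c
    positions = [(r, c) for r in range(N_ROWS) for c in range(N_COLS)]

    def try_build() -> list[list[int]] | None:
        used: list[set[int]] = [set() for _ in range(n_c)]
        plates: list[list[int]] = []
        for _plate in range(n_plates):
            # random greedy matching of combinations to free wells, with
            # per-plate retries before declaring a dead end
            for _attempt in range(200):
                perm = rng.permutation(n_c)
                taken: dict[int, int] = {}  # well index -> combination index
                ok = True
                for ci in perm:
                    free = [w for w in range(n_c) if w not in taken and w not in used[ci]]
                    if not free:
                        ok = False
                        break
                    taken[int(rng.choice(free))] = int(ci)
                if ok:
                    row = [0] * n_c
                    for w, ci in taken.items():
                        row[w] = ci
                        used[ci].add(w)
                    plates.append(row)
                    break
            else:
                return None
        return plates

    for _restart in range(max_restarts):
        plates = try_build()
        if plates is not None:
            break
    else:  # pragma: no cover - practically unreachable for n_plates <= 12
        raise RuntimeError("could not satisfy the unique-position constraint")

    out: list[WellAssignment] = []
    for p, row in enumerate(plates, start=1):
        for w, ci in enumerate(row):
            r, c = positions[w]
            out.append(WellAssignment(p, r, c, combinations[ci]))
    return out


def place_spores(
    assignment: WellAssignment,
    seed: int | np.random.Generator = 0,
    min_spacing_mm: float = DEFAULT_MIN_SPACING_MM,
    sowing_radius_mm: float = SOWING_RADIUS_MM,
    n_missing: int = 0,
    max_tries: int = 20000,
) -> list[SporePlacement]:
    """Scatter the well's 20 spores randomly but evenly in the central region.

    Uniform rejection sampling in the disk of radius ``sowing_radius_mm``
    (half the well radius) subject to a minimum pairwise spacing.  Species
    labels follow the combination's counts in randomized order.  ``n_missing``
    spores are flagged as lost (never germinated / blown away) at random.
    """
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    for code, n in assignment.combination.counts:
        labels.extend([code] * n)
    rng.shuffle(labels)

    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < len(labels):
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {len(labels)} spores with spacing "
                f"{min_spacing_mm} mm in radius {sowing_radius_mm} mm"
            )
        tries += 1
        # uniform in disk
        u, theta = rng.random(), rng.random() * 2 * np.pi
        r = sowing_radius_mm * np.sqrt(u)
        x, y = r * np.cos(theta), r * np.sin(theta)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_spacing_mm**2 for px, py in pts):
            pts.append((x, y))

    missing_idx = set()
    if n_missing:
        missing_idx = set(rng.choice(len(labels), size=n_missing, replace=False).tolist())
    return [
        SporePlacement(
            assignment.plate_id,
            assignment.well,
            i + 1,
            labels[i],
            float(x),
            float(y),
            aborted_or_missing=(i in missing_idx),
        )
        for i, (x, y) in enumerate(pts)
    ]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def design_to_frame(design: list[WellAssignment]) -> pd.DataFrame:
    rows = []
    for a in design:
        counts = a.combination.counts
        s1, n1 = counts[0]
        s2, n2 = counts[1] if len(counts) > 1 else ("", 0)
        rows.append(
            {
                "plate_id": a.plate_id,
                "well": a.well,
                "species_1": s1,
                "n_1": n1,
                "species_2": s2,
                "n_2": n2,
                "bordering_sides": a.bordering_sides,
            }
        )
    return pd.DataFrame(rows)


def frame_to_design(df: pd.DataFrame) -> list[WellAssignment]:
    out = []
    for rec in df.to_dict("records"):
        counts = {str(rec["species_1"]): int(rec["n_1"])}
        if rec.get("species_2") and int(rec.get("n_2") or 0) > 0:
            counts[str(rec["species_2"])] = int(rec["n_2"])
        row, col = parse_well_label(str(rec["well"]))
        out.append(
            WellAssignment(int(rec["plate_id"]), row, col, SporeCombination.of(**counts))
        )
    return out


def placements_to_frame(placements: list[SporePlacement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "plate_id": p.plate_id,
                "well": p.well,
                "spore_index": p.spore_index,
                "species": p.species,
                "x_mm": p.x_mm,
                "y_mm": p.y_mm,
                "aborted_or_missing": p.aborted_or_missing,
            }
            for p in placements
        ]
    )
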