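"""Shared fixtures: designs, rendered fixtures and calibrations are built
once per session at a reduced raster scale so the suite stays fast."""

import numpy as np
import pytest

import ferncover as fc
from ferncover import design as dg
from ferncover import imaging as im
from ferncover import synthgen as sg

#: raster scale used by image fixtures (px per mm^2); well canvas ~500 px
FIXTURE_SCALE = 900.0


@pytest.fixture(scope="session")
def combinations():
    return fc.enumerate_combinations(["A", "B", "F"])


@pytest.fixture(scope="session")
def full_design(combinations):
    """The study-sized layout: 10 plates x 12 wells."""
    return fc.build_design(combinations, 10, seed=101)


@pytest.fixture(scope="session")
def calibration():
    squares = [
        sg.render_calibration_square(100.0, FIXTURE_SCALE, seed=i) for i in range(5)
    ]
    return im.calibrate(squares, 100.0, im.DEFAULT_RED_RULE)


@pytest.fixture(scope="session")
def mixture_well(combinations):
    """One rendered 15:5 well at week 5 with placements, truth and masks."""
    a = next(
        x
        for x in fc.build_design(combinations, 1, seed=7)
        if x.combination.label == "A15B5"
    )
    placements = dg.place_spores(a, seed=8)
    truth = sg.simulate_growth(placements, weeks=[5])
    areas = dict(zip(truth["spore_index"], truth["visible_area_mm2"]))
    img, masks = sg.render_well_image(
        placements, areas, px_per_mm2=FIXTURE_SCALE, seed=9
    )
    return {
        "assignment": a,
        "placements": placements,
        "truth": truth,
        "areas": areas,
        "image": img,
        "masks": masks,
    }


@pytest.fixture(scope="session")
def cover_tables(full_design):
    """Simulated deposited-style tables for the 10-plate design."""
    return sg.simulate_cover_table(full_design, seed=202)
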