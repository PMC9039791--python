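"""End-to-end pipeline: design -> synthesis -> imaging -> attribution -> stats.

A single config object carries every tunable the workflow uses (spore
counts, hue-shift offset, classification thresholds, calibration scale,
model presets, seed); its hash is stamped into every CSV header so any
output file can be traced to the exact settings that produced it, and
reruns with the same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from . import attribution, design as design_mod, imaging, stats, synthgen

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, in one inspectable, hashable object."""

    species: tuple[str, ...] = ("A", "B", "F")
    n_plates: int = 10
    seed: int = 0
    min_spacing_mm: float = design_mod.DEFAULT_MIN_SPACING_MM
    px_per_mm2: float = synthgen.DEFAULT_PX_PER_MM2
    weeks: tuple[int, ...] = tuple(range(4, 11))
    render_weeks: tuple[int, ...] = tuple(range(4, 11))
    n_calibration_squares: int = 10
    calibration_area_mm2: float = 100.0
    hue_band_deg: tuple[float, float] = (30.0, 90.0)
    hue_offset_deg: float = 10.0
    hue_falloff: str = "none"
    green_min_excess: int = 20
    green_min_value: int = 40
    red_min_excess: int = 10
    red_min_value: int = 40
    downsample_factor: int = 2
    jpeg_dialect: bool = True
    gamma_shape: float = 25.0
    sigma_plate: float = 0.15
    missing_spores: tuple[int, ...] = (2, 3, 3, 4, 5)
    presets: tuple[str, ...] = ("bordering", "monoculture_species", "combinations")
    ratio_method: str = "well-total"

    # -- derived parameter objects -----------------------------------------
    def hue_spec(self) -> imaging.HueShiftSpec:
        return imaging.HueShiftSpec(self.hue_band_deg, self.hue_offset_deg, self.hue_falloff)

    def green_rule(self) -> imaging.ColorRule:
        return imaging.ColorRule(
            "green", self.green_min_excess, self.green_min_value, self.downsample_factor
        )

    def red_rule(self) -> imaging.ColorRule:
        return imaging.ColorRule(
            "red", self.red_min_excess, self.red_min_value, self.downsample_factor
        )

    def noise(self) -> synthgen.NoiseParams:
        return synthgen.NoiseParams(self.gamma_shape, self.sigma_plate, self.missing_spores)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML loses tuple-ness; restore it for fields typed as tuples
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[f.name]
                )
        return cls(**raw)


def demo_config(**overrides) -> PipelineConfig:
    """A two-plate, low-resolution configuration that runs in seconds."""
    base = dict(
        n_plates=2,
        px_per_mm2=300.0,
        render_weeks=(4, 5),
        missing_spores=(2,),
        presets=("bordering", "monoculture_species"),
    )
    base.update(overrides)
    return PipelineConfig(**base)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# ferncover config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


def read_output_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, write_images: bool = True
) -> dict:
    """Run every stage on synthetic data and write all artifacts to ``outdir``.

    Stages: experimental design, spore placement, growth simulation with
    well-level gamma noise and a plate random effect, image rendering,
    calibration, cover measurement, week-5 species attribution by deletion
    differencing, ratio standardization, well filtering, and the mixed-model
    presets.  Returns a dict of the in-memory tables and fitted results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_dir, mask_dir = outdir / "images", outdir / "masks"
    if write_images:
        img_dir.mkdir(exist_ok=True)
        mask_dir.mkdir(exist_ok=True)
    log_lines = [f"config_hash={config.config_hash()}", f"seed={config.seed}"]
    for key, val in sorted(config.to_dict().items()):
        log_lines.append(f"param {key}={val}")

    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(6)
    rng_noise = np.random.default_rng(seeds[3])

    # --- stage 1: design ---------------------------------------------------
    combos = design_mod.enumerate_combinations(list(config.species))
    if len(combos) != design_mod.WELLS_PER_PLATE:
        raise RuntimeError(
            f"design stage: {len(combos)} combinations do not fill a "
            f"{design_mod.WELLS_PER_PLATE}-well plate"
        )
    design = design_mod.build_design(combos, config.n_plates, np.random.default_rng(seeds[0]))
    _write_csv(design_mod.design_to_frame(design), outdir / "design.csv", config)

    # --- stage 2: placements and growth -------------------------------------
    noise = config.noise()
    missing_plan = synthgen.default_missing_plan(
        design, noise, np.random.default_rng(seeds[1])
    )
    placements = synthgen.placements_for_design(
        design, np.random.default_rng(seeds[2]),
        min_spacing_mm=config.min_spacing_mm, missing_plan=missing_plan,
    )
    _write_csv(design_mod.placements_to_frame(placements), outdir / "placements.csv", config)
    growth = synthgen.GrowthParams()
    truth = synthgen.simulate_growth(placements, growth, list(config.weeks))

    # well-level biological noise applied to the true areas before rendering:
    # one multiplicative factor per well-week (plate effect x mean-1 gamma)
    plate_ids = sorted({a.plate_id for a in design})
    plate_effect = {p: float(rng_noise.normal(0, config.sigma_plate)) for p in plate_ids}
    factors: dict[tuple[int, str, int], float] = {}
    for a in design:
        for week in config.weeks:
            g = float(synthgen.gamma_noise(rng_noise, config.gamma_shape, 1)[0])
            factors[(a.plate_id, a.well, week)] = np.exp(plate_effect[a.plate_id]) * g
    truth["noisy_visible_mm2"] = [
        v * factors[(p, w, wk)]
        for v, p, w, wk in zip(
            truth["visible_area_mm2"], truth["plate_id"], truth["well"], truth["week"]
        )
    ]

    # --- stage 3: calibration ----------------------------------------------
    cal_rng = np.random.default_rng(seeds[4])
    squares = [
        synthgen.render_calibration_square(
            config.calibration_area_mm2, config.px_per_mm2, cal_rng
        )
        for _ in range(config.n_calibration_squares)
    ]
    if not squares:
        raise RuntimeError("calibration stage: no reference squares configured")
    calibration = imaging.calibrate(squares, config.calibration_area_mm2, config.red_rule())
    log_lines.append(
        f"calibration px_per_mm2={calibration.px_per_mm2:.4f} "
        f"(n={calibration.n_observations}, downsample={config.downsample_factor})"
    )

    # --- stage 4: render + measure ------------------------------------------
    render_rng = np.random.default_rng(seeds[5])
    by_well: dict[tuple[int, str], list] = {}
    for p in placements:
        by_well.setdefault((p.plate_id, p.well), []).append(p)
    appearance = synthgen.AppearanceParams()
    hue_spec, green_rule = config.hue_spec(), config.green_rule()

    meas_rows, species_rows = [], []
    truth_idx = truth.set_index(["plate_id", "well", "week", "spore_index"])
    design_by_key = {(a.plate_id, a.well): a for a in design}
    for (plate, well), ps in sorted(by_well.items()):
        a = design_by_key[(plate, well)]
        for week in config.render_weeks:
            areas = {
                p.spore_index: float(
                    truth_idx.loc[(plate, well, week, p.spore_index), "noisy_visible_mm2"]
                )
                for p in ps
            }
            img, masks = synthgen.render_well_image(
                ps, areas, appearance, config.px_per_mm2, render_rng
            )
            if write_images:
                stem = f"K{plate}-{well}_w{week}"
                tifffile.imwrite(img_dir / f"{stem}.tif", img)
                Image.fromarray(img).save(img_dir / f"{stem}.jpg", quality=95)
                for sp, m in masks.items():
                    Image.fromarray(m.astype(np.uint8) * 255).save(
                        mask_dir / f"{stem}_{sp}.png"
                    )
            obs = imaging.measure_well(
                img, calibration, hue_spec, green_rule,
                plate_id=plate, well=well, week=week, jpeg_dialect=config.jpeg_dialect,
            )
            n_sown = design_mod.SPORES_PER_WELL - missing_plan.get((plate, well), 0)
            meas_rows.append(
                {
                    "plate_id": plate,
                    "well": well,
                    "plate_well": f"K{plate}-{well}",
                    "week": week,
                    "species_1": a.combination.counts[0][0],
                    "n_1": a.combination.counts[0][1],
                    "species_2": a.combination.counts[1][0]
                    if len(a.combination.counts) > 1 else "",
                    "n_2": a.combination.counts[1][1]
                    if len(a.combination.counts) > 1 else 0,
                    "bordering_sides": a.bordering_sides,
                    "n_spores_sown": n_sown,
                    "total_pixels": obs.pixels,
                    "total_area_mm2": obs.area_mm2,
                }
            )

            # --- stage 5: week-5 attribution -----------------------------
            if week == 5 and not a.combination.is_monoculture:
                sp1, sp2 = a.combination.species
                first = synthgen.render_sowing_image(
                    ps, {sp1}, appearance, config.px_per_mm2, render_rng
                )
                both = synthgen.render_sowing_image(
                    ps, None, appearance, config.px_per_mm2, render_rng
                )
                _, unresolved = attribution.register_spore_species(
                    first, both, np.sqrt(config.px_per_mm2)
                )
                if unresolved:
                    warnings.warn(f"K{plate}-{well}: unresolved spore registration")
                altered = attribution.delete_species(
                    img, masks.get(sp1, np.zeros(img.shape[:2], bool)),
                    appearance.background_rgb,
                )
                alt_obs = imaging.measure_well(
                    altered, calibration, hue_spec, green_rule,
                    plate_id=plate, well=well, week=week,
                    jpeg_dialect=config.jpeg_dialect,
                )
                kept, deleted = attribution.attribute_by_difference(
                    obs.pixels, min(alt_obs.pixels, obs.pixels), sp1, sp2,
                    plate, well, calibration.px_per_mm2,
                )
                for sc in (kept, deleted):
                    species_rows.append(
                        {
                            "plate_id": plate,
                            "well": well,
                            "week": 5,
                            "species": sc.species,
                            "n_spores_of_species": a.combination.count_of(sc.species),
                            "n_spores_sown": n_sown,
                            "pixels_species": sc.pixels,
                            "area_species_mm2": sc.area_mm2,
                            "total_pixels": obs.pixels,
                            "total_area_mm2": obs.area_mm2,
                            "method": sc.method,
                        }
                    )
            elif week == 5:
                (sp1, n1), = a.combination.counts
                species_rows.append(
                    {
                        "plate_id": plate,
                        "well": well,
                        "week": 5,
                        "species": sp1,
                        "n_spores_of_species": n1,
                        "n_spores_sown": design_mod.SPORES_PER_WELL
                        - missing_plan.get((plate, well), 0),
                        "pixels_species": obs.pixels,
                        "area_species_mm2": obs.area_mm2,
                        "total_pixels": obs.pixels,
                        "total_area_mm2": obs.area_mm2,
                        "method": "monoculture",
                    }
                )

    cover = pd.DataFrame(meas_rows)
    week5 = pd.DataFrame(species_rows)
    _write_csv(cover, outdir / "measurements.csv", config)

    # --- stage 6: ratios and models ------------------------------------------
    cover_f, report = stats.filter_wells(cover)
    week5_f, _ = stats.filter_wells(week5) if len(week5) else (week5, {})
    log_lines.append(f"filter_wells: {report}")
    ratios = stats.standardize_ratios(
        stats.build_ratio_records(week5_f, config.ratio_method)
    )
    _write_csv(ratios, outdir / "ratios.csv", config)

    model_frames = {}
    for preset in config.presets:
        results, _fits = stats.run_preset(cover_f, preset)
        frame = stats.model_results_to_frame(results)
        model_frames[preset] = frame
        _write_csv(frame, outdir / f"model_{preset}.csv", config)

    lmm_rows = []
    lmm_results = {}
    for sp in config.species:
        try:
            res = stats.fit_ratio_lmm(ratios, sp)
        except ValueError as exc:
            log_lines.append(f"ratio LMM skipped for {sp}: {exc}")
            continue
        lmm_results[sp] = res
        lmm_rows.append(
            {
                "species": sp,
                "chisq": res.chi_square,
                "df": res.df,
                "p": res.p_value,
                "converged": res.converged,
                "n_obs": res.n_obs,
            }
        )
        for c in res.contrasts:
            lmm_rows.append(
                {
                    "species": sp,
                    "contrast": f"{c.group_a} vs {c.group_b}",
                    "estimate": c.estimate,
                    "se": c.se,
                    "t": c.t_value,
                    "p_tukey": c.p_tukey,
                }
            )
    if lmm_rows:
        _write_csv(pd.DataFrame(lmm_rows), outdir / "model_week5_lmm.csv", config)

    import ferncover

    log_lines.append(f"version={getattr(ferncover, '__version__', 'dev')}")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return {
        "design": design,
        "placements": placements,
        "calibration": calibration,
        "cover": cover,
        "cover_filtered": cover_f,
        "filter_report": report,
        "week5": week5,
        "ratios": ratios,
        "models": model_frames,
        "ratio_lmm": lmm_results,
    }


# ---------------------------------------------------------------------------
# Deposited-table reader
# ---------------------------------------------------------------------------

COVER_COLUMNS = [
    "plate_id", "well", "week", "species_1", "n_1", "species_2", "n_2",
    "n_spores_sown", "total_pixels", "total_area_mm2",
]
WEEK5_COLUMNS = [
    "plate_id", "well", "week", "species", "n_spores_of_species",
    "n_spores_sown", "pixels_species", "area_species_mm2",
    "total_pixels", "total_area_mm2",
]


def read_deposited_table(
    cover_path: str | Path,
    week5_path: str | Path | None = None,
    column_map: dict[str, str] | None = None,
    px_per_mm2: float = synthgen.DEFAULT_PX_PER_MM2,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a deposited-style cover data set so the analysis presets can run.

    ``column_map`` renames columns of the file to the canonical schema
    (useful when the deposited file uses its own header names).  Pixel and
    mm² columns complete each other through ``px_per_mm2`` when only one is
    present.  Missing required columns are reported by name.
    """

    def _load(path: Path, required: list[str], label: str) -> pd.DataFrame:
        df = pd.read_csv(path, comment="#")
        if column_map:
            df = df.rename(columns=column_map)
        # an absent second species serializes as an empty cell
        if "species_2" in df.columns:
            df["species_2"] = df["species_2"].fillna("")
        if "n_2" in df.columns:
            df["n_2"] = df["n_2"].fillna(0).astype(int)
        if "total_area_mm2" not in df.columns and "total_pixels" in df.columns:
            df["total_area_mm2"] = df["total_pixels"] / px_per_mm2
        if "total_pixels" not in df.columns and "total_area_mm2" in df.columns:
            df["total_pixels"] = df["total_area_mm2"] * px_per_mm2
        if label == "week5":
            if "area_species_mm2" not in df.columns and "pixels_species" in df.columns:
                df["area_species_mm2"] = df["pixels_species"] / px_per_mm2
            if "pixels_species" not in df.columns and "area_species_mm2" in df.columns:
                df["pixels_species"] = df["area_species_mm2"] * px_per_mm2
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{label} table is missing columns: {missing}")
        return df

    cover = _load(Path(cover_path), COVER_COLUMNS, "cover")
    week5 = (
        _load(Path(week5_path), WEEK5_COLUMNS, "week5") if week5_path else None
    )
    return cover, week5
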