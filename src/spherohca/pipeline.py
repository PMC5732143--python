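"""End-to-end orchestration: simulate/load -> segment -> quantify ->
dose-response -> profile, with tidy CSV interchange between stages."""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atp import LuminescenceTable, process_luminescence
from .config import RunConfig
from .doseresponse import DoseResponseModel, normalize_to_control
from .exceptions import NoObjectError, SpheroHCAError
from .fluorescence import quantify_channel
from .geometry import AcquisitionGeometry
from .hca import build_hca_table, classify_effects, compute_static_threshold
from .plate import Condition, PlateLayout
from .segmentation import (
    AreaFilter,
    apply_area_filter,
    compute_morphometrics,
    segment_brightfield,
)
from .simulate import (
    ImageStack,
    SpheroidPhenotypeParams,
    simulate_drug_response,
    simulate_plate,
)

log = logging.getLogger(__name__)

RESPONSE_PARAMETERS = ("Area", "P2A", "CE", "LysoT", "ATP")


@dataclass
class PipelineResult:
    out_dir: Path
    morphometrics: pd.DataFrame | None = None
    responses: pd.DataFrame | None = None
    fits: pd.DataFrame | None = None
    profile: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    failure: dict | None = None
    timings: dict = field(default_factory=dict)


def build_simulated_layout(cfg: RunConfig) -> PlateLayout:
    sim = cfg.simulate
    conditions = [
        Condition(
            cell_line=sim.cell_line,
            seeded_cells=sim.seeded_cells,
            drug=sim.drug if c > 0 else "vehicle",
            concentration=float(c),
        )
        for c in sim.concentrations
    ]
    layout = PlateLayout.default_96(replicates_per_condition=sim.replicates)
    return layout.assign_block(conditions)


def _params_for_condition_factory(cfg: RunConfig):
    sim = cfg.simulate
    base = SpheroidPhenotypeParams(
        seeded_cells=sim.seeded_cells,
        growth_rate=sim.growth_rate,
        noise_sd=sim.noise_sd,
    )

    def params_for(cond: Condition) -> SpheroidPhenotypeParams:
        return simulate_drug_response(
            base, sim.model, sim.ec50s, sim.hill, [cond.concentration]
        )[0]

    return params_for


def load_stacks(images_dir, geometry: AcquisitionGeometry) -> dict[str, ImageStack]:
    """Load ``{well}_{day}_{channel}.tif`` images into per-well stacks."""
    import tifffile

    stacks: dict[str, ImageStack] = {}
    found: dict[str, dict] = {}
    for path in sorted(Path(images_dir).glob("*.tif")):
        well, day, channel = path.stem.split("_", 2)
        found.setdefault(well, {})[(float(day), channel)] = tifffile.imread(path)
    for well, images in found.items():
        times = sorted({t for t, _ in images})
        stack = ImageStack(well_id=well, timepoints=times, geometry=geometry)
        stack.images = images
        stacks[well] = stack
    return stacks


def measure_stacks(
    stacks: dict[str, ImageStack],
    layout: PlateLayout,
    cfg: RunConfig,
) -> pd.DataFrame:
    """Segment and quantify every (well, time) frame into a long table."""
    rows = []
    missing_fluor = False
    for well in sorted(stacks):
        stack = stacks[well]
        cond = layout.well_assignments.get(well)
        cell_line = cond.cell_line if cond else ""
        min_area = cfg.min_area_for(cell_line)
        for t in stack.timepoints:
            bf = stack.images.get((t, "brightfield"))
            if bf is None:
                continue
            raw_mask = segment_brightfield(bf, cfg.geometry, cfg.segmentation)
            filtered = apply_area_filter(raw_mask, AreaFilter(min_area))
            row = {
                "well": well,
                "time_days": t,
                "cell_line": cell_line,
                "drug": cond.drug if cond else "",
                "concentration": cond.concentration if cond else np.nan,
                "object_count": filtered.object_count,
            }
            try:
                rec = compute_morphometrics(
                    filtered, cfg.geometry, mode=cfg.morphometry_mode
                )
            except NoObjectError:
                rows.append(row)
                continue
            row.update(
                area_px2=rec.area_px2,
                area_um2=rec.area_um2,
                perimeter_um=rec.perimeter_um,
                shape_p2a=rec.shape_p2a,
                circ_diameter_um=rec.circ_diameter_um,
                sphere_volume_pl=rec.sphere_volume_pl,
                aspect_ratio_lwr=rec.aspect_ratio_lwr,
            )
            sph_mask = (
                filtered.selected_mask()
                if cfg.morphometry_mode == "largest"
                else filtered.union_mask()
            )
            for channel, prefix in (("apoptosis", "ce"), ("lyso", "lyso")):
                img = stack.images.get((t, channel))
                if img is None:
                    missing_fluor = True
                    continue
                fr = quantify_channel(
                    img, sph_mask, cfg.geometry, channel=channel
                )
                row.update(
                    {
                        f"{prefix}_area_um2": fr.fluor_area_um2,
                        f"{prefix}_total": fr.total_intensity,
                        f"{prefix}_total_raw": fr.total_intensity_raw,
                        f"{prefix}_avg": fr.average_intensity,
                        f"{prefix}_area_fraction": fr.area_fraction,
                    }
                )
            rows.append(row)
    if missing_fluor:
        warnings.warn(
            "fluorescence channels missing; morphometrics-only output",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def tidy_responses(
    morpho: pd.DataFrame, viability: pd.DataFrame | None
) -> pd.DataFrame:
    """Final-timepoint per-well values in tidy (parameter, value) form."""
    final_t = morpho.time_days.max()
    last = morpho[morpho.time_days == final_t]
    mapping = {
        "Area": "area_um2",
        "P2A": "shape_p2a",
        "CE": "ce_total",
        "LysoT": "lyso_total",
    }
    rows = []
    for param, col in mapping.items():
        if col not in last.columns:
            continue
        for _, r in last.iterrows():
            rows.append(
                {
                    "well": r.well,
                    "drug": r.drug,
                    "concentration": r.concentration,
                    "parameter": param,
                    "value": r[col],
                }
            )
    if viability is not None:
        for _, r in viability.iterrows():
            rows.append(
                {
                    "well": r.well,
                    "drug": r.drug,
                    "concentration": r.concentration,
                    "parameter": "ATP",
                    "value": r.viability,
                }
            )
    return pd.DataFrame(rows).dropna(subset=["value"])


def fit_all_parameters(responses: pd.DataFrame, cfg: RunConfig):
    """Fit each parameter's dose-response curve; returns (fits table,
    results dict keyed by parameter)."""
    fit_rows, results = [], {}
    for param, grp in responses.groupby("parameter"):
        try:
            model = DoseResponseModel.from_dataframe(grp, parameter=param)
            res = model.fit(cfg.fit.kind, cfg.fit.n_starts, cfg.fit.seed)
        except SpheroHCAError as exc:
            log.warning("fit failed for %s: %s", param, exc)
            continue
        results[param] = res
        for e in res.ec50s:
            fit_rows.append(
                {
                    "parameter": param,
                    "model": res.model,
                    "label": e.label,
                    "ec50": e.value,
                    "censored": e.censored,
                    "ci_low": e.ci[0] if e.ci else np.nan,
                    "ci_high": e.ci[1] if e.ci else np.nan,
                    "aicc": res.aicc,
                    "no_effect": res.no_effect,
                }
            )
    return pd.DataFrame(fit_rows), results


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full pipeline per the run configuration.

    Stage failures leave partial outputs on disk plus ``failure.json``;
    the returned result records the failed stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(out_dir=out)
    stage = "setup"
    t0 = _time.time()
    try:
        if cfg.design_csv:
            from .designio import read_design

            layout = read_design(cfg.design_csv)
        elif cfg.simulate is not None:
            layout = build_simulated_layout(cfg)
        else:
            raise SpheroHCAError("neither design_csv nor simulate configured")

        stage = "acquire"
        lum_df = None
        if cfg.images_dir:
            stacks = load_stacks(cfg.images_dir, cfg.geometry)
        else:
            stacks, lum, truth = simulate_plate(
                layout,
                _params_for_condition_factory(cfg),
                cfg.simulate.timepoints,
                seed=cfg.seed,
            )
            result.truth = truth
            truth.to_csv(out / "ground_truth.csv", index=False)
            lum_df = lum
            lum.to_csv(out / "luminescence.csv", index=False)
        result.timings["acquire"] = _time.time() - t0

        stage = "segment_quantify"
        t1 = _time.time()
        morpho = measure_stacks(stacks, layout, cfg)
        result.morphometrics = morpho
        morpho.to_csv(out / "morphometrics.csv", index=False)
        result.timings["segment_quantify"] = _time.time() - t1

        stage = "atp"
        viability = None
        if lum_df is not None:
            table = LuminescenceTable(
                data=lum_df[["well", "rlu"]],
                blank_wells=set(lum_df.loc[lum_df.is_blank, "well"]),
            )
            viability = process_luminescence(table, layout)

        stage = "dose_response"
        t2 = _time.time()
        responses = tidy_responses(morpho, viability)
        result.responses = responses
        responses.to_csv(out / "responses.csv", index=False)
        fits, fit_results = fit_all_parameters(responses, cfg)
        result.fits = fits
        fits.to_csv(out / "fits.csv", index=False)
        result.timings["dose_response"] = _time.time() - t2

        stage = "profile"
        if "ATP" in fit_results:
            atp_curve = fit_results["ATP"].curve
            drug = next(
                (c.drug for c in layout.conditions() if not c.is_vehicle), ""
            )
            cell_line = layout.conditions()[0].cell_line
            thr = compute_static_threshold(
                atp_curve, alpha=cfg.threshold_alpha, drug=drug,
                cell_line=cell_line,
            )
            ec50s = [e for r in fit_results.values() for e in r.ec50s]
            profile = classify_effects(
                ec50s, thr, drug=drug, cell_line=cell_line
            )
            table = build_hca_table([profile])
            result.profile = table
            table.to_csv(out / "profile.csv", index=False)

        stage = "log"
        cfg_text = json.dumps(
            {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
        )
        (out / "run_log.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "seed": cfg.seed,
                    "config_hash": hashlib.sha256(
                        cfg_text.encode()
                    ).hexdigest()[:16],
                    "timings_s": {
                        k: round(v, 3) for k, v in result.timings.items()
                    },
                },
                indent=2,
            )
        )
    except Exception as exc:
        result.failure = {"stage": stage, "error": str(exc),
                          "type": type(exc).__name__}
        (out / "failure.json").write_text(json.dumps(result.failure, indent=2))
        raise
    return result
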