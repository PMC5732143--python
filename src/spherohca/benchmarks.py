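"""Reference benchmark computations run by the acceptance script and tests.

Each function recomputes a headline quantity of the workflow from scratch:
the worked plate/geometry arithmetic, the end-to-end recovery of the
volume-per-seeded-cell slope from rendered images, and the Monte-Carlo
recovery of the lower EC50 of a biphasic growth-arrest curve.

The biphasic simulation emulates the growth-arrest/cytotoxicity response of
slow-proliferating prostate-cancer spheroids to the NAE inhibitor MLN4924:
lower EC50 18 nM (growth arrest), upper EC50 600 nM (cytotoxic onset,
tabulated as a '>600' bound), nine log-spaced concentrations over
1-1000 nM, six replicate spheroids per concentration and 10% control-scale
Gaussian noise.  The per-phase Hill slope is 2 so that the intermediate
quiescent plateau (flat response between roughly 25 and 100 nM) is present
in the simulated curves, as it is in the measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .doseresponse import fit_biphasic, simulate_curve
from .geometry import AcquisitionGeometry
from .kinetics import volume_per_cell_slope
from .plate import (
    PlateLayout,
    count_usable_wells,
    dye_final_concentration,
    max_conditions,
    plan_dilution,
)
from .segmentation import (
    AreaFilter,
    apply_area_filter,
    compute_morphometrics,
    estimate_sphere_volume,
    segment_brightfield,
    shape_p2a,
)
from .simulate import SpheroidPhenotypeParams, render_well


def circle_p2a(radius_um: float = 200.0) -> float:
    """P2A from the closed-form perimeter and area of a circle (== 1)."""
    return shape_p2a(2 * np.pi * radius_um, np.pi * radius_um**2)


def worked_examples() -> dict:
    """The plate-arithmetic quantities printed in the protocol."""
    layout = PlateLayout.default_96()
    plan = plan_dilution(stock=2e6, final=500.0, wells=6)  # 2 mM stock, nM units
    return {
        "circle_p2a": circle_p2a(),
        "usable_wells": count_usable_wells(layout),
        "drug_concentrations_per_plate": max_conditions(
            layout, replicates=6, reserve_vehicle=True
        ),
        "working_volume_per_condition_ul": plan.total_volume_ul,
        "dye_final_um": dye_final_concentration(
            2.0, replaced_volume_ul=100.0, well_volume_ul=200.0
        ),
    }


@dataclass(frozen=True)
class BiphasicTruth:
    """Ground-truth biphasic growth-arrest condition (concentrations in nM)."""

    ec50_1: float = 18.0
    ec50_2: float = 600.0
    hill: float = 2.0
    fraction: float = 0.55
    left: float = 1.0
    right: float = 0.25
    noise_sd: float = 0.10
    n_replicates: int = 6

    def concentrations(self) -> np.ndarray:
        return np.logspace(0.0, 3.0, 9)


MLN_VCAP_AREA = BiphasicTruth()

VOLUME_PER_CELL_PL = 12.0
SEEDING_DENSITIES = (500, 1000, 2000, 3000, 4000)


def volume_slope_recovery(
    seed: int = 0,
    densities=SEEDING_DENSITIES,
    replicates: int = 4,
    min_area_px2: int = 1000,
) -> dict:
    """Render plates across seeding densities, segment, estimate sphere
    volumes and regress volume on seeded cells.

    Returns the recovered slope (pL/cell), its confidence interval and the
    number of images measured.  The generator truth is 12 pL of occupied
    volume per seeded cell.
    """
    geometry = AcquisitionGeometry()
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x76])
    seeds = iter(ss.generate_state(len(densities) * replicates))
    points = []
    for cells in densities:
        params = SpheroidPhenotypeParams(
            seeded_cells=int(cells), volume_per_cell_pl=VOLUME_PER_CELL_PL
        )
        for _ in range(replicates):
            images, _ = render_well(
                params, geometry, time_days=0.0, seed=int(next(seeds)) & 0x7FFFFFFF
            )
            mask = apply_area_filter(
                segment_brightfield(images["brightfield"], geometry),
                AreaFilter(min_area_px2),
            )
            rec = compute_morphometrics(mask, geometry)
            points.append((cells, estimate_sphere_volume(rec)))
    fit = volume_per_cell_slope(points)
    return {
        "slope_pl_per_cell": fit.slope,
        "intercept_pl": fit.intercept,
        "slope_ci": fit.slope_ci,
        "n_images": len(points),
        "true_slope": VOLUME_PER_CELL_PL,
    }


def ec50_recovery(
    seed: int = 0,
    n_repeats: int = 200,
    truth: BiphasicTruth = MLN_VCAP_AREA,
    n_starts: int = 6,
) -> dict:
    """Monte-Carlo recovery of the lower EC50 by the biphasic fitter."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xEC])
    seeds = ss.generate_state(n_repeats)
    lower = []
    for i, s in enumerate(seeds):
        curve = simulate_curve(
            [truth.ec50_1, truth.ec50_2],
            hills=truth.hill,
            fraction=truth.fraction,
            left=truth.left,
            right=truth.right,
            concentrations=truth.concentrations(),
            n_replicates=truth.n_replicates,
            noise_sd=truth.noise_sd,
            seed=int(s) & 0x7FFFFFFF,
        )
        res = fit_biphasic(curve, n_starts=n_starts, seed=i)
        lower.append(res.ec50s[0].value)
    lower = np.asarray(lower)
    return {
        "median_lower_ec50_nm": float(np.median(lower)),
        "iqr": (float(np.percentile(lower, 25)), float(np.percentile(lower, 75))),
        "median_abs_log10_error": float(
            np.median(np.abs(np.log10(lower / truth.ec50_1)))
        ),
        "n_repeats": n_repeats,
        "true_lower_ec50_nm": truth.ec50_1,
    }
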