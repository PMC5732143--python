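"""Ground-truthed synthetic well images for single-spheroid cultures.

One U-bottom well holds one centered spheroid.  The generator renders, per
well and timepoint, a bright-field channel (dark-rimmed textured object on a
bright background), an apoptosis-reporter channel (caspase substrate:
nutrient-deprived core above a diameter threshold, plus drug-induced
peripheral signal) and a lysosomal-dye channel (outer metabolically active
shell, saturating uptake kinetics).  Every rendered image carries its
ground-truth mask and true feature record, so segmentation, quantification
and curve fitting can be tested against known answers.

The spheroid size law is volumetric: the initial equivalent-sphere volume is
``seeded_cells * volume_per_cell_pl`` (default 12 pL of occupied volume per
seeded cell) and grows exponentially at ``growth_rate`` per day.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry
from .exceptions import ValidationError
from .plate import Condition, PlateLayout

UM3_PER_PL = 1000.0  # 1 pL = 1e3 um^3

#: spheroids wider than this cannot be reliably captured in one field of view
MAX_DIAMETER_UM = 800.0

CHANNELS = ("brightfield", "apoptosis", "lyso")

# Bright-field rendering constants (16-bit intensity scale).  The instrument
# contrast is not a measured quantity; these are free generator parameters.
BF_BACKGROUND = 32000.0
BF_INTERIOR = 18000.0
BF_RIM = 8000.0
BF_TEXTURE_SD = 2000.0
RIM_WIDTH_PX = 3


@dataclass
class SpheroidPhenotypeParams:
    """Ground-truth phenotype of one spheroid.

    Parameters
    ----------
    seeded_cells : int
        Cells dispensed into the well.
    volume_per_cell_pl : float
        Occupied volume per seeded cell (pL); sets the initial size.
    growth_rate : float
        Exponential volume growth rate (1/day).
    roughness : float
        Boundary-perturbation amplitude; 0 renders a perfect disk.
    disruption : str
        'none', 'unilateral_bleb' (off-center lobe) or 'fragmentation'
        (satellite objects below the usual area filter).
    core_apoptosis_threshold_um : float
        Equivalent diameter above which the nutrient-deprived core turns
        caspase-positive irrespective of treatment.
    halo_apoptosis : bool
        Drug-induced peripheral apoptotic signal.
    apoptosis_amplitude : float
        Intensity of the drug-induced apoptotic signal.
    uptake_rate_per_h, uptake_plateau : float
        Saturating dye-uptake kinetics I(t) = plateau * (1 - exp(-k t));
        the default rate reaches 95% of plateau at 8 h.
    center_offset_um : float
        Displacement of the spheroid from the well center.
    noise_sd : float
        Additive Gaussian read noise (intensity units).
    viability : float
        Fraction of metabolically active volume; scales the simulated ATP
        luminescence endpoint.
    """

    seeded_cells: int = 2000
    volume_per_cell_pl: float = 12.0
    growth_rate: float = 0.10
    roughness: float = 0.0
    disruption: str = "none"
    core_apoptosis_threshold_um: float = 450.0
    halo_apoptosis: bool = False
    apoptosis_amplitude: float = 0.0
    uptake_rate_per_h: float = float(np.log(20.0) / 8.0)
    uptake_plateau: float = 3000.0
    center_offset_um: float = 0.0
    noise_sd: float = 200.0
    viability: float = 1.0

    def __post_init__(self):
        if self.roughness < 0:
            raise ValidationError("roughness must be >= 0")
        if self.disruption not in ("none", "unilateral_bleb", "fragmentation"):
            raise ValidationError(f"unknown disruption {self.disruption!r}")

    def volume_pl(self, time_days: float) -> float:
        """True occupied volume at ``time_days`` (exponential growth)."""
        return (
            self.seeded_cells
            * self.volume_per_cell_pl
            * float(np.exp(self.growth_rate * time_days))
        )

    def radius_um(self, time_days: float) -> float:
        """Equivalent-sphere radius at ``time_days``."""
        v_um3 = self.volume_pl(time_days) * UM3_PER_PL
        return float((3.0 * v_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))


@dataclass
class GroundTruth:
    """True mask and features for one rendered (well, time) frame."""

    mask: np.ndarray
    radius_um: float
    equiv_diameter_um: float
    sphere_volume_pl: float
    area_px2: int
    area_um2: float
    viability: float

    def as_row(self) -> dict:
        return {
            "radius_um": self.radius_um,
            "equiv_diameter_um": self.equiv_diameter_um,
            "sphere_volume_pl": self.sphere_volume_pl,
            "area_px2": self.area_px2,
            "area_um2": self.area_um2,
            "viability": self.viability,
        }


@dataclass
class ImageStack:
    """Per-well multi-channel, multi-timepoint image set."""

    well_id: str
    timepoints: list[float]
    geometry: AcquisitionGeometry
    images: dict = field(default_factory=dict)  # (time, channel) -> 2-D array
    ground_truth: dict = field(default_factory=dict)  # time -> GroundTruth

    def __post_init__(self):
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ValidationError("timepoints must be strictly increasing")

    def image(self, time: float, channel: str) -> np.ndarray:
        return self.images[(time, channel)]


def _boundary_radius(
    base_r_px: float, theta: np.ndarray, roughness: float, rng: np.random.Generator
) -> np.ndarray:
    """Polar boundary r(theta): disk radius modulated by band-limited modes."""
    r = np.full_like(theta, base_r_px, dtype=float)
    if roughness > 0:
        for k in range(2, 9):
            amp = roughness * rng.normal() / k
            phase = rng.uniform(0, 2 * np.pi)
            r *= 1.0 + amp * np.cos(k * theta + phase)
    return np.maximum(r, 1.0)


def _rasterize(
    geometry: AcquisitionGeometry,
    r_px: float,
    center_px: tuple[float, float],
    roughness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    n = geometry.image_px
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    dy, dx = yy - center_px[0], xx - center_px[1]
    rad = np.hypot(dy, dx)
    if roughness == 0:
        return rad <= r_px
    theta = np.arctan2(dy, dx)
    # evaluate the perturbed boundary on a dense angular grid, then look up
    grid = np.linspace(-np.pi, np.pi, 1441)
    bound = _boundary_radius(r_px, grid, roughness, rng)
    bound_at = np.interp(theta, grid, bound, period=2 * np.pi)
    return rad <= bound_at


def _band_limited_noise(
    shape: tuple[int, int], sd: float, sigma_px: float, rng: np.random.Generator
) -> np.ndarray:
    from scipy.ndimage import gaussian_filter

    raw = rng.normal(0.0, 1.0, shape)
    smooth = gaussian_filter(raw, sigma_px)
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def render_well(
    params: SpheroidPhenotypeParams,
    geometry: AcquisitionGeometry | None = None,
    time_days: float = 0.0,
    seed: int = 0,
    staining_time_h: float = 24.0,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Render all three channels for one well at one timepoint.

    Returns ``(images, ground_truth)`` where ``images`` maps channel name to
    a uint16 array.  Identical arguments (including seed) give bit-identical
    output.
    """
    if time_days < 0:
        raise ValidationError("time must be >= 0")
    geometry = geometry or AcquisitionGeometry()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5]))

    r_um = params.radius_um(time_days)
    d_um = 2 * r_um
    if d_um > min(MAX_DIAMETER_UM, geometry.fov_um):
        warnings.warn(
            f"spheroid diameter {d_um:.0f} um exceeds the usable field of view",
            stacklevel=2,
        )

    px = geometry.pixel_size_um
    r_px = r_um / px
    n = geometry.image_px
    center = (n / 2 + params.center_offset_um / px, n / 2)
    mask = _rasterize(geometry, r_px, center, params.roughness, rng)

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    rad = np.hypot(yy - center[0], xx - center[1])

    if params.disruption == "unilateral_bleb":
        # off-center lobe merged with the main body
        bleb_c = (center[0] - 1.05 * r_px, center[1] + 0.3 * r_px)
        bleb = np.hypot(yy - bleb_c[0], xx - bleb_c[1]) <= 0.45 * r_px
        mask = mask | bleb
    satellites = np.zeros_like(mask)
    if params.disruption == "fragmentation":
        for i in range(3):
            ang = 2 * np.pi * i / 3 + 0.5
            sc = (
                center[0] + (r_px + 30) * np.sin(ang),
                center[1] + (r_px + 30) * np.cos(ang),
            )
            satellites |= np.hypot(yy - sc[0], xx - sc[1]) <= 14
        satellites &= ~mask

    objects = mask | satellites

    # --- bright field: bright background, dark rim, textured interior
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(objects, iterations=RIM_WIDTH_PX)
    rim = objects & ~interior
    bf = np.full((n, n), BF_BACKGROUND)
    bf[interior] = BF_INTERIOR
    bf[rim] = BF_RIM
    texture = _band_limited_noise((n, n), BF_TEXTURE_SD, 2.0, rng)
    bf[interior] += texture[interior]

    # --- apoptosis reporter
    apo = np.zeros((n, n))
    rim_depth_um = params.core_apoptosis_threshold_um / 2.0
    if d_um > params.core_apoptosis_threshold_um:
        core_r_px = (r_um - rim_depth_um) / px
        apo[(rad <= core_r_px) & mask] = 4000.0
    if params.apoptosis_amplitude > 0:
        if params.halo_apoptosis:
            halo = (rad > 0.85 * r_px) & (rad <= 1.10 * r_px)
            apo[halo] += params.apoptosis_amplitude
        else:
            apo[mask] += params.apoptosis_amplitude

    # --- lysosomal dye: outer shell, saturating uptake
    lyso = np.zeros((n, n))
    shell_um = 75.0  # metabolically active outer layer
    shell = (rad <= r_px) & (rad > max(r_px - shell_um / px, 0)) & mask
    uptake = params.uptake_plateau * (
        1.0 - np.exp(-params.uptake_rate_per_h * staining_time_h)
    )
    lyso[shell] = uptake
    lyso[mask & ~shell] = 0.15 * uptake

    images = {}
    for name, img in (("brightfield", bf), ("apoptosis", apo), ("lyso", lyso)):
        noisy = img + (
            rng.normal(0.0, params.noise_sd, (n, n)) if params.noise_sd > 0 else 0.0
        )
        images[name] = np.clip(noisy, 0, 65535).astype(np.uint16)

    truth = GroundTruth(
        mask=objects,
        radius_um=r_um,
        equiv_diameter_um=d_um,
        sphere_volume_pl=params.volume_pl(time_days),
        area_px2=int(objects.sum()),
        area_um2=float(objects.sum()) * px * px,
        viability=params.viability,
    )
    return images, truth


def render_stack(
    params: SpheroidPhenotypeParams,
    geometry: AcquisitionGeometry,
    well: str,
    timepoints: list[float],
    seed: int = 0,
    staining_time_h: float = 24.0,
) -> ImageStack:
    """Render a full per-well time series into an :class:`ImageStack`."""
    stack = ImageStack(well_id=well, timepoints=list(timepoints), geometry=geometry)
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _well_key(well)])
    child_seeds = ss.generate_state(len(timepoints))
    for t, s in zip(timepoints, child_seeds):
        images, truth = render_well(
            params, geometry, time_days=t, seed=int(s) & 0x7FFFFFFF,
            staining_time_h=staining_time_h,
        )
        for ch, img in images.items():
            stack.images[(t, ch)] = img
        stack.ground_truth[t] = truth
    return stack


def _well_key(well: str) -> int:
    from .plate import parse_well_id

    r, c = parse_well_id(well)
    return r * 12 + c


def _hill_fraction(conc, ec50s, hill: float) -> float:
    """Mean Hill occupancy over one or more half-maximal concentrations."""
    ec50s = np.atleast_1d(np.asarray(ec50s, dtype=float))
    if np.any(ec50s <= 0):
        raise ValidationError("ec50s must be > 0")
    if conc < 0:
        raise ValidationError("concentrations must be >= 0")
    if conc == 0:
        return 0.0
    fr = conc**hill / (conc**hill + ec50s**hill)
    return float(fr.mean())


def simulate_drug_response(
    base: SpheroidPhenotypeParams,
    model: str,
    ec50s,
    hill: float = 1.0,
    concentrations=(),
) -> list[SpheroidPhenotypeParams]:
    """Derive per-concentration phenotypes from a base phenotype.

    ``model`` selects which parameter responds through a Hill function of
    concentration: 'arrest' slows growth, 'disruption' roughens and (above
    half-occupancy) blebs the boundary, 'apoptosis' adds a peripheral
    caspase signal and lowers viability, 'uptake_suppression' lowers the dye
    plateau and viability.  Concentration 0 returns the base unchanged.
    """
    if model not in ("arrest", "disruption", "apoptosis", "uptake_suppression"):
        raise ValidationError(f"unknown drug-response model {model!r}")
    out = []
    for c in concentrations:
        fr = _hill_fraction(c, ec50s, hill)
        p = dataclasses.replace(base)
        if model == "arrest":
            p.growth_rate = base.growth_rate * (1.0 - fr)
        elif model == "disruption":
            p.roughness = base.roughness + 0.5 * fr
            if fr > 0.5:
                p.disruption = "unilateral_bleb"
        elif model == "apoptosis":
            p.apoptosis_amplitude = base.apoptosis_amplitude + 4000.0 * fr
            p.halo_apoptosis = fr > 0 or base.halo_apoptosis
            p.viability = base.viability * (1.0 - fr)
        elif model == "uptake_suppression":
            p.uptake_plateau = base.uptake_plateau * (1.0 - fr)
            p.viability = base.viability * (1.0 - fr)
        out.append(p)
    return out


LUMINESCENCE_PER_PL = 10.0  # RLU per pL of viable volume (U-bottom format)
BLANK_RLU = 500.0


def simulate_plate(
    layout: PlateLayout,
    params_for_condition,
    timepoints,
    seed: int = 0,
    lum_noise_cv: float = 0.05,
    format_scaling: float = 1.0,
    blank_wells=("A1", "A2", "A3"),
    render_images: bool = True,
    staining_time_h: float = 24.0,
):
    """Simulate every assigned well of a plate.

    Parameters
    ----------
    params_for_condition : callable
        ``Condition -> SpheroidPhenotypeParams``.
    format_scaling : float
        Multiplies all luminescence (flat-bottom remeasurement gives up to
        ~3x the U-bottom signal).
    render_images : bool
        If False, skip pixel rendering and emit ground truth only.

    Returns
    -------
    stacks : dict well -> ImageStack (empty if ``render_images`` is False)
    luminescence : DataFrame (well, rlu, plate_format, is_blank)
    truth_table : DataFrame of per-(well, time) ground-truth features
    """
    layout.validate()
    geometry = AcquisitionGeometry()
    timepoints = list(timepoints)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x1F]))
    stacks: dict[str, ImageStack] = {}
    truth_rows = []
    lum_rows = []
    fmt = "u_bottom" if format_scaling == 1.0 else "flat_bottom"

    for well in sorted(layout.well_assignments):
        cond = layout.well_assignments[well]
        params = params_for_condition(cond)
        if render_images:
            stack = render_stack(
                params, geometry, well, timepoints, seed=seed,
                staining_time_h=staining_time_h,
            )
            stacks[well] = stack
            truths = stack.ground_truth
        else:
            truths = {
                t: GroundTruth(
                    mask=None,
                    radius_um=params.radius_um(t),
                    equiv_diameter_um=2 * params.radius_um(t),
                    sphere_volume_pl=params.volume_pl(t),
                    area_px2=0,
                    area_um2=float(np.pi * params.radius_um(t) ** 2),
                    viability=params.viability,
                )
                for t in timepoints
            }
        for t, tr in truths.items():
            row = {"well": well, "time_days": t, "condition_drug": cond.drug,
                   "concentration": cond.concentration,
                   "cell_line": cond.cell_line, "seeded_cells": cond.seeded_cells}
            row.update(tr.as_row())
            truth_rows.append(row)
        final_truth = truths[timepoints[-1]]
        noise = rng.normal(1.0, lum_noise_cv) if lum_noise_cv > 0 else 1.0
        rlu = (
            BLANK_RLU
            + LUMINESCENCE_PER_PL
            * final_truth.sphere_volume_pl
            * final_truth.viability
            * noise
        ) * format_scaling
        lum_rows.append(
            {"well": well, "rlu": rlu, "plate_format": fmt, "is_blank": False}
        )

    for bw in blank_wells:
        noise = rng.normal(1.0, lum_noise_cv) if lum_noise_cv > 0 else 1.0
        lum_rows.append(
            {
                "well": bw,
                "rlu": BLANK_RLU * noise * format_scaling,
                "plate_format": fmt,
                "is_blank": True,
            }
        )

    return stacks, pd.DataFrame(lum_rows), pd.DataFrame(truth_rows)


def write_stacks(stacks: dict[str, ImageStack], out_dir) -> list[Path]:
    """Write 16-bit grayscale TIFFs named ``{well}_{day}_{channel}.tif``."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for well, stack in stacks.items():
        for (t, ch), img in stack.images.items():
            path = out_dir / f"{well}_{t:g}_{ch}.tif"
            tifffile.imwrite(path, img)
            written.append(path)
    return written
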