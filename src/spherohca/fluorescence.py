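"""Fluorescence quantification within and around the spheroid mask.

Both reporter channels (apoptosis substrate, lysosomal vital dye) are
quantified the same way: the background level is estimated robustly outside
a dilated copy of the bright-field spheroid mask, pixels above
``background + k * MAD`` form the fluorescence mask, and intensity totals
are accumulated on background-subtracted values.  Signal may legitimately
extend beyond the bright-field mask (apoptotic halo), so the fluorescence
area fraction can exceed 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi

from .geometry import AcquisitionGeometry
from .exceptions import GeometryError, NoObjectError
from .segmentation import MorphometricRecord


@dataclass
class FluorescenceRecord:
    channel: str
    fluor_area_px2: int
    fluor_area_um2: float
    total_intensity: float  # background-subtracted
    total_intensity_raw: float
    average_intensity: float
    background: float
    threshold: float
    area_fraction: float  # fluor area / spheroid area (nan if no spheroid)


class NormalizedSignal(NamedTuple):
    area_fraction: float
    intensity_per_um2: float


def quantify_channel(
    image: np.ndarray,
    spheroid_mask: np.ndarray,
    geometry: AcquisitionGeometry | None = None,
    channel: str = "fluor",
    k_mad: float = 6.0,
    dilate_px: int = 10,
    shell_um: float | None = None,
) -> FluorescenceRecord:
    """Quantify one fluorescence channel against the bright-field mask.

    ``shell_um`` restricts the measurement to an annular band of that depth
    inside the spheroid boundary (outer-layer dye accumulation); default is
    the whole image above threshold.
    """
    geometry = geometry or AcquisitionGeometry()
    image = np.asarray(image, dtype=float)
    spheroid_mask = np.asarray(spheroid_mask, dtype=bool)
    if image.shape != spheroid_mask.shape:
        raise GeometryError(
            f"image shape {image.shape} != mask shape {spheroid_mask.shape}"
        )

    outside = ~ndi.binary_dilation(spheroid_mask, iterations=dilate_px)
    bg_pixels = image[outside] if outside.any() else image.ravel()
    background = float(np.median(bg_pixels))
    mad = float(np.median(np.abs(bg_pixels - background)))
    threshold = background + k_mad * 1.4826 * mad

    fmask = image > threshold
    if shell_um is not None and spheroid_mask.any():
        depth_px = max(int(round(shell_um / geometry.pixel_size_um)), 1)
        inner = ndi.binary_erosion(spheroid_mask, iterations=depth_px)
        fmask &= spheroid_mask & ~inner

    sub = np.clip(image - background, 0.0, None)
    px = geometry.pixel_size_um
    area_px2 = int(fmask.sum())
    total = float(sub[fmask].sum())
    total_raw = float(image[fmask].sum())
    sph_area = int(spheroid_mask.sum())
    return FluorescenceRecord(
        channel=channel,
        fluor_area_px2=area_px2,
        fluor_area_um2=area_px2 * px * px,
        total_intensity=total,
        total_intensity_raw=total_raw,
        average_intensity=total / area_px2 if area_px2 else 0.0,
        background=background,
        threshold=threshold,
        area_fraction=area_px2 / sph_area if sph_area else float("nan"),
    )


def normalize_signal_to_spheroid(
    record: FluorescenceRecord, morpho: MorphometricRecord
) -> NormalizedSignal:
    """Normalize a fluorescence record to the spheroid's projected area.

    Distinguishes drug-specific signal from the size-dependent core signal:
    a constant core on a growing spheroid gives a decreasing score.
    """
    if morpho.area_um2 <= 0:
        raise NoObjectError("spheroid area is zero")
    return NormalizedSignal(
        area_fraction=record.fluor_area_um2 / morpho.area_um2,
        intensity_per_um2=record.total_intensity / morpho.area_um2,
    )
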