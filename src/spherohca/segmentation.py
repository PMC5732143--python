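"""Bright-field spheroid segmentation and morphometric feature extraction.

The segmentation path is: intensity threshold (Otsu) on the smoothed
bright-field image (spheroids are darker than the background), morphological
closing, hole filling and connected-component labeling, followed by an area
filter that removes debris and selects the spheroid.  A blank-image guard
returns an empty mask instead of thresholding pure noise.

Morphometrics follow the high-content convention for single objects:

* ``shape_p2a = P^2 / (4 pi A)`` — the isoperimetric roundness quotient,
  1 for a perfect circle, larger for irregular shapes;
* ``circ_diameter = 2 sqrt(A / pi)`` — equivalent circular diameter;
* ``sphere_volume = (pi/6) d^3`` — volume of the sphere with that diameter,
  reported in pL (1 pL = 1000 um^3);
* ``aspect_ratio_lwr`` — major/minor axis ratio of the moment-matched
  ellipse (length-to-width ratio).

The perimeter estimator is the 4-direction Crofton formula, which converges
to the true perimeter for digitized convex shapes; naive boundary tracing
overestimates P and breaks the P2A -> 1 calibration on rasterized disks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

from .geometry import AcquisitionGeometry
from .exceptions import NoObjectError

UM3_PER_PL = 1000.0


@dataclass
class SegmentationOptions:
    smooth_sigma_px: float = 2.0
    closing_radius_px: int = 3
    min_speck_px2: int = 20
    #: blank guard: require the Otsu split to separate classes by at least
    #: this many robust noise SDs, else return an empty mask
    blank_contrast_sds: float = 6.0


@dataclass
class AreaFilter:
    """Minimum object area in px^2 (e.g. 1,000 for VCaP, 3,000 for LNCaP)."""

    min_area_px2: int = 1000

    def __post_init__(self):
        if self.min_area_px2 < 0:
            raise ValueError("min_area_px2 must be >= 0")


@dataclass
class ObjectMask:
    """Candidate objects from one bright-field image."""

    mask: np.ndarray  # boolean union of all retained objects
    labels: np.ndarray  # labeled image (0 = background)
    areas_px2: list[int] = field(default_factory=list)
    selected_object: int | None = None  # label id of the selected spheroid

    @property
    def object_count(self) -> int:
        return len(self.areas_px2)

    def selected_mask(self) -> np.ndarray:
        if self.selected_object is None:
            raise NoObjectError("no object selected")
        return self.labels == self.selected_object

    def union_mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class MorphometricRecord:
    """Shape features of one (possibly multi-part) spheroid object."""

    area_px2: int
    area_um2: float
    perimeter_um: float
    shape_p2a: float
    circ_diameter_um: float
    sphere_volume_pl: float
    aspect_ratio_lwr: float
    centroid_um: tuple[float, float]


def _robust_noise_sd(image: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of a high-pass residual."""
    med = ndi.median_filter(image, size=3)
    resid = image - med
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def segment_brightfield(
    image: np.ndarray,
    geometry: AcquisitionGeometry | None = None,
    options: SegmentationOptions | None = None,
) -> ObjectMask:
    """Segment dark objects on a bright background.

    Deterministic for fixed input and options.  A uniform or blank image
    yields an empty mask (``object_count == 0``), not an exception.
    """
    options = options or SegmentationOptions()
    if geometry is not None:
        geometry.check_image(image)
    img = np.asarray(image, dtype=float)
    smooth = ndi.gaussian_filter(img, options.smooth_sigma_px)

    from skimage.filters import threshold_otsu

    lo, hi = smooth.min(), smooth.max()
    empty = ObjectMask(
        mask=np.zeros(img.shape, bool), labels=np.zeros(img.shape, np.int32)
    )
    if hi - lo < 1e-12:
        return empty
    th = threshold_otsu(smooth)
    fg = smooth < th
    # blank guard: the split must separate real structure, not read noise
    noise = _robust_noise_sd(img)
    contrast = smooth[~fg].mean() - smooth[fg].mean() if fg.any() and (~fg).any() else 0
    if noise > 0 and contrast < options.blank_contrast_sds * noise:
        return empty

    closed = morphology.closing(fg, morphology.disk(options.closing_radius_px))
    filled = ndi.binary_fill_holes(closed)
    labels, n = ndi.label(filled)
    areas = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1)).astype(int)
    # drop sub-speck components outright; the area filter handles the rest
    for lab in np.flatnonzero(areas < options.min_speck_px2) + 1:
        labels[labels == lab] = 0
    labels, _ = ndi.label(labels > 0)
    n = int(labels.max())
    areas = ndi.sum_labels(np.ones_like(labels), labels, range(1, n + 1)).astype(int)
    return ObjectMask(
        mask=labels > 0,
        labels=labels.astype(np.int32),
        areas_px2=list(areas),
    )


def apply_area_filter(mask: ObjectMask, area_filter: AreaFilter) -> ObjectMask:
    """Drop objects at or below the minimum area; select the largest survivor."""
    labels = mask.labels.copy()
    kept, kept_areas = [], []
    for lab, area in zip(range(1, mask.object_count + 1), mask.areas_px2):
        if area > area_filter.min_area_px2:
            kept.append(lab)
            kept_areas.append(area)
        else:
            labels[labels == lab] = 0
    selected = kept[int(np.argmax(kept_areas))] if kept else None
    return ObjectMask(
        mask=labels > 0,
        labels=labels,
        areas_px2=kept_areas,
        selected_object=selected,
    )


def perimeter_um(binary: np.ndarray, geometry: AcquisitionGeometry) -> float:
    """Crofton (4-direction) perimeter, in microns."""
    return float(measure.perimeter_crofton(binary, directions=4)) * geometry.pixel_size_um


def shape_p2a(perimeter: float, area: float) -> float:
    """Isoperimetric roundness P^2/(4 pi A); 1 for a perfect circle."""
    if area <= 0:
        raise NoObjectError("zero area")
    return perimeter**2 / (4.0 * np.pi * area)


def compute_morphometrics(
    mask: ObjectMask,
    geometry: AcquisitionGeometry | None = None,
    mode: str = "largest",
) -> MorphometricRecord:
    """Compute the morphometric feature record for the selected object.

    ``mode='largest'`` measures the selected (largest filtered) object;
    ``mode='union'`` measures the union of all retained objects, which is
    how a drug-disrupted spheroid appears as one enlarged irregular object.
    """
    geometry = geometry or AcquisitionGeometry()
    if mode == "largest":
        binary = mask.selected_mask()
    elif mode == "union":
        if mask.object_count == 0:
            raise NoObjectError("no objects to measure")
        binary = mask.union_mask()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    px = geometry.pixel_size_um
    area_px2 = int(binary.sum())
    if area_px2 == 0:
        raise NoObjectError("empty selection")
    area_um2 = area_px2 * px * px
    perim = perimeter_um(binary, geometry)
    p2a = shape_p2a(perim, area_um2)
    circ_d = 2.0 * float(np.sqrt(area_um2 / np.pi))
    volume_pl = (np.pi / 6.0) * circ_d**3 / UM3_PER_PL

    props = measure.regionprops(binary.astype(np.uint8))[0]
    minor = props.axis_minor_length
    lwr = props.axis_major_length / minor if minor > 0 else np.inf
    cy, cx = props.centroid
    return MorphometricRecord(
        area_px2=area_px2,
        area_um2=area_um2,
        perimeter_um=perim,
        shape_p2a=p2a,
        circ_diameter_um=circ_d,
        sphere_volume_pl=volume_pl,
        aspect_ratio_lwr=max(lwr, 1.0),
        centroid_um=(cy * px, cx * px),
    )


def estimate_sphere_volume(record: MorphometricRecord) -> float:
    """Equivalent-sphere volume (pL) from the equivalent circular diameter."""
    if record.circ_diameter_um <= 0:
        raise NoObjectError("zero diameter")
    return (np.pi / 6.0) * record.circ_diameter_um**3 / UM3_PER_PL
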