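"""Acquisition geometry: field of view, binning and pixel calibration."""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import GeometryError


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Square field of view imaged onto a square pixel grid.

    Defaults correspond to a 10x objective with 4x4 binning: an
    896.6 um x 896.6 um field captured as a 552 x 552 px image,
    i.e. 1.624 um/px.
    """

    fov_um: float = 896.6
    image_px: int = 552
    binning: int = 4

    @property
    def pixel_size_um(self) -> float:
        return self.fov_um / self.image_px

    @property
    def shape(self) -> tuple[int, int]:
        return (self.image_px, self.image_px)

    def check_image(self, image) -> None:
        if image.ndim != 2 or image.shape != self.shape:
            raise GeometryError(
                f"image shape {image.shape} does not match geometry {self.shape}"
            )

    def um_to_px(self, length_um: float) -> float:
        return length_um / self.pixel_size_um

    def px_to_um(self, length_px: float) -> float:
        return length_px * self.pixel_size_um
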