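"""ATP-luminescence endpoint processing.

Raw relative light units (RLU) are blank-subtracted (mean of blank wells,
negatives clipped to zero), normalized to the vehicle-control mean, and
averaged per condition.  Lysates remeasured in a flat-bottom plate gain up
to ~3x signal relative to the U-bottom plate; the scaling factor between
paired formats is estimated robustly as the median of per-well ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import NormalizationError, ValidationError
from .plate import PlateLayout

log = logging.getLogger(__name__)

PLATE_FORMATS = ("u_bottom", "flat_bottom", "monolayer_2d")


@dataclass
class LuminescenceTable:
    """Per-well raw luminescence with blank bookkeeping."""

    data: pd.DataFrame  # columns: well, rlu
    blank_wells: set[str] = field(default_factory=set)
    plate_format: str = "u_bottom"

    def __post_init__(self):
        if self.plate_format not in PLATE_FORMATS:
            raise ValidationError(f"unknown plate format {self.plate_format!r}")
        if not self.blank_wells:
            raise ValidationError("blank wells required for subtraction")
        missing = self.blank_wells - set(self.data.well)
        if missing:
            raise ValidationError(f"blank wells {sorted(missing)} not in table")

    @classmethod
    def from_csv(cls, path, plate_format: str = "u_bottom"):
        df = pd.read_csv(path)
        if "is_blank" in df:
            blanks = set(df.loc[df.is_blank.astype(bool), "well"])
            df = df[["well", "rlu"]]
        else:
            blanks = set()
        return cls(data=df, blank_wells=blanks, plate_format=plate_format)

    def blank_mean(self) -> float:
        return float(
            self.data.loc[self.data.well.isin(self.blank_wells), "rlu"].mean()
        )


def process_luminescence(
    table: LuminescenceTable, layout: PlateLayout
) -> pd.DataFrame:
    """Blank-subtract, normalize to vehicle, aggregate per condition.

    Returns one row per well (columns: well, drug, concentration,
    viability) plus condition means/SDs merged in; viability 1 means the
    vehicle-control ATP level.
    """
    blank = table.blank_mean()
    vehicle_wells = [
        w for w, c in layout.well_assignments.items() if c.is_vehicle
    ]
    if not vehicle_wells:
        raise ValidationError("layout has no vehicle wells")
    df = table.data.set_index("well")
    vehicle_vals = (
        df.loc[[w for w in vehicle_wells if w in df.index], "rlu"] - blank
    )
    vmean = float(vehicle_vals.mean())
    if vmean <= 0:
        raise NormalizationError(
            f"vehicle mean ({vmean:.3g}) not above blank; degenerate control"
        )
    rows = []
    n_clipped = 0
    for well, cond in sorted(layout.well_assignments.items()):
        if well not in df.index:
            continue
        val = float(df.loc[well, "rlu"]) - blank
        if val < 0:
            val = 0.0
            n_clipped += 1
        rows.append(
            {
                "well": well,
                "cell_line": cond.cell_line,
                "drug": cond.drug,
                "concentration": cond.concentration,
                "viability": val / vmean,
            }
        )
    if n_clipped:
        log.info("clipped %d negative blank-subtracted wells to 0", n_clipped)
    out = pd.DataFrame(rows)
    agg = (
        out.groupby(["drug", "concentration"])["viability"]
        .agg(viability_mean="mean", viability_sd="std", n="count")
        .reset_index()
    )
    return out.merge(agg, on=["drug", "concentration"])


@dataclass
class FormatScaling:
    factor: float
    n_pairs: int
    low_confidence: bool


def estimate_format_scaling(paired: pd.DataFrame) -> FormatScaling:
    """Median-of-ratios scale factor between two plate formats.

    ``paired`` needs columns ``rlu_flat`` and ``rlu_u`` (one row per well).
    Zero-denominator pairs are excluded; a single surviving pair is
    returned flagged low-confidence.
    """
    if not {"rlu_flat", "rlu_u"} <= set(paired.columns):
        raise ValidationError("columns rlu_flat and rlu_u required")
    ok = paired["rlu_u"] != 0
    if not ok.any():
        raise ValidationError("all pairs have zero U-bottom signal")
    ratios = (paired.loc[ok, "rlu_flat"] / paired.loc[ok, "rlu_u"]).to_numpy()
    return FormatScaling(
        factor=float(np.median(ratios)),
        n_pairs=int(ok.sum()),
        low_confidence=int(ok.sum()) < 3,
    )
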