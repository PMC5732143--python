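"""Experimental-design CSV reading and validation.

The design table has one row per assigned well with columns: well,
cell_line, seeded_cells, drug, concentration, concentration_unit,
treatment_start_day, replicate_group.  Edge wells may not be assigned
(uneven evaporation); validation errors name the offending rows.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .exceptions import ValidationError
from .plate import Condition, PlateLayout, parse_well_id

REQUIRED_COLUMNS = [
    "well",
    "cell_line",
    "seeded_cells",
    "drug",
    "concentration",
    "concentration_unit",
    "treatment_start_day",
    "replicate_group",
]


def read_design(path) -> PlateLayout:
    """Parse and validate a design CSV into a :class:`PlateLayout`."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValidationError(f"{path.name}: design file is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    dup = df.well[df.well.duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"{path.name}: duplicate wells {sorted(dup.unique())}"
        )

    layout = PlateLayout.default_96(allow_partial=True)
    for idx, row in df.iterrows():
        well = str(row.well).strip().upper()
        parse_well_id(well)  # malformed ids raise here
        if well in layout.excluded_wells:
            raise ValidationError(
                f"{path.name} row {idx + 2}: well {well} is an excluded edge well"
            )
        drug = str(row.drug).strip()
        conc = float(row.concentration)
        if drug.lower() in ("vehicle", "dmso", "control"):
            drug, conc = "vehicle", 0.0
        layout.well_assignments[well] = Condition(
            cell_line=str(row.cell_line),
            seeded_cells=int(row.seeded_cells),
            drug=drug,
            concentration=conc,
            concentration_unit=str(row.concentration_unit),
            treatment_start=float(row.treatment_start_day),
        )
    counts = pd.Series(
        [c for c in layout.well_assignments.values()]
    ).value_counts()
    layout.replicates_per_condition = int(counts.iloc[0]) if len(counts) else 0
    layout.validate()
    return layout


def write_design(layout: PlateLayout, path) -> None:
    rows = []
    for well, cond in sorted(layout.well_assignments.items()):
        rows.append(
            {
                "well": well,
                "cell_line": cond.cell_line,
                "seeded_cells": cond.seeded_cells,
                "drug": cond.drug,
                "concentration": cond.concentration,
                "concentration_unit": cond.concentration_unit,
                "treatment_start_day": cond.treatment_start,
                "replicate_group": f"{cond.drug}_{cond.concentration:g}",
            }
        )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
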