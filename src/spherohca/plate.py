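"""96-well plate design: layouts, conditions and dilution arithmetic.

A single spheroid grows in each U-bottom well.  Edge wells (row A, row H,
columns 1 and 12) suffer uneven evaporation and are excluded by default,
leaving a 6 x 10 block of 60 usable wells.  Drug solutions are applied by
half-volume medium replacement: 100 uL of the 200 uL well volume is replaced
with a 2x working solution, so the working concentration is twice the final
one and the solvent carried over is halved.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .exceptions import DilutionError, GeometryError, ValidationError

ROW_LETTERS = "ABCDEFGH"

#: final DMSO/DMF fraction (percent) above which a warning is raised
SOLVENT_WARN_PERCENT = 0.5


def well_id(row: int, col: int) -> str:
    """0-based (row, col) -> plate-reader well id, e.g. (1, 1) -> 'B2'."""
    return f"{ROW_LETTERS[row]}{col + 1}"


def parse_well_id(well: str) -> tuple[int, int]:
    """'B2' -> (1, 1).  Raises ValidationError on malformed ids."""
    well = well.strip().upper()
    if len(well) < 2 or well[0] not in ROW_LETTERS or not well[1:].isdigit():
        raise ValidationError(f"malformed well id {well!r}")
    return ROW_LETTERS.index(well[0]), int(well[1:]) - 1


def edge_wells(rows: int = 8, cols: int = 12) -> set[str]:
    """Well ids on the outer rim of a rows x cols plate."""
    return {
        well_id(r, c)
        for r, c in itertools.product(range(rows), range(cols))
        if r in (0, rows - 1) or c in (0, cols - 1)
    }


@dataclass(frozen=True)
class Condition:
    """One experimental condition applied to a set of replicate wells."""

    cell_line: str
    seeded_cells: int
    drug: str = "vehicle"
    concentration: float = 0.0
    concentration_unit: str = "nM"
    treatment_start: float = 0.0  # days after seeding

    def __post_init__(self):
        if self.concentration < 0:
            raise ValidationError("concentration must be >= 0")
        if self.drug == "vehicle" and self.concentration != 0:
            raise ValidationError("vehicle condition implies concentration 0")

    @property
    def is_vehicle(self) -> bool:
        return self.drug == "vehicle" or self.concentration == 0


@dataclass
class PlateLayout:
    """Map of a microtiter plate to conditions, with excluded-well bookkeeping.

    Parameters
    ----------
    rows, cols : int
        Plate geometry; only 8 x 12 (96-well) is supported by the pipeline.
    well_assignments : dict
        well id -> :class:`Condition`.
    excluded_wells : set
        Wells never assigned (edge wells by default).
    replicates_per_condition : int
        Expected replicate count; assignment sets deviating from it must be
        flagged with ``allow_partial``.
    """

    rows: int = 8
    cols: int = 12
    well_assignments: dict[str, Condition] = field(default_factory=dict)
    excluded_wells: set[str] = field(default_factory=set)
    replicates_per_condition: int = 6
    allow_partial: bool = False

    @classmethod
    def default_96(cls, exclude_edges: bool = True, **kw) -> "PlateLayout":
        excl = edge_wells() if exclude_edges else set()
        return cls(rows=8, cols=12, excluded_wells=excl, **kw)

    def validate(self) -> None:
        if (self.rows, self.cols) != (8, 12):
            raise GeometryError(
                f"unsupported plate geometry {self.rows}x{self.cols}; expected 8x12"
            )
        all_wells = self.all_wells()
        for w in self.excluded_wells:
            if w not in all_wells:
                raise ValidationError(f"excluded well {w} outside plate")
        for w in self.well_assignments:
            if w not in all_wells:
                raise ValidationError(f"assigned well {w} outside plate")
            if w in self.excluded_wells:
                raise ValidationError(f"condition assigned to excluded well {w}")
        if not self.allow_partial:
            counts: dict[Condition, int] = {}
            for cond in self.well_assignments.values():
                counts[cond] = counts.get(cond, 0) + 1
            for cond, n in counts.items():
                if n != self.replicates_per_condition:
                    raise ValidationError(
                        f"condition {cond.drug}@{cond.concentration} has {n} wells, "
                        f"expected {self.replicates_per_condition} "
                        "(set allow_partial=True to accept)"
                    )

    def all_wells(self) -> set[str]:
        return {
            well_id(r, c)
            for r, c in itertools.product(range(self.rows), range(self.cols))
        }

    def usable_wells(self) -> list[str]:
        return sorted(self.all_wells() - self.excluded_wells)

    def conditions(self) -> list[Condition]:
        seen: list[Condition] = []
        for cond in self.well_assignments.values():
            if cond not in seen:
                seen.append(cond)
        return seen

    def wells_for(self, condition: Condition) -> list[str]:
        return sorted(
            w for w, c in self.well_assignments.items() if c == condition
        )

    def assign_block(self, conditions: list[Condition], order: str = "by_column"):
        """Assign conditions to the usable block, ``replicates_per_condition``
        wells each, filling column-by-column (default) or row-by-row."""
        usable = self.usable_wells()
        if order == "by_column":
            usable.sort(key=lambda w: (parse_well_id(w)[1], parse_well_id(w)[0]))
        needed = len(conditions) * self.replicates_per_condition
        if needed > len(usable):
            raise ValidationError(
                f"{needed} wells needed but only {len(usable)} usable"
            )
        it = iter(usable)
        for cond in conditions:
            for _ in range(self.replicates_per_condition):
                self.well_assignments[next(it)] = cond
        return self


@dataclass
class DilutionPlan:
    """Arithmetic of one drug dilution applied to a plate."""

    stock_conc: float
    stock_solvent: str
    working_conc: float
    final_conc: float
    volume_per_well_ul: float
    wells_per_condition: int
    total_volume_ul: float
    solvent_fraction_working: float  # percent
    solvent_fraction_final: float  # percent
    mode: str = "half_volume"


def count_usable_wells(layout: PlateLayout) -> int:
    """Number of wells available for conditions (excluded wells removed)."""
    if (layout.rows, layout.cols) != (8, 12):
        raise GeometryError(
            f"unsupported plate geometry {layout.rows}x{layout.cols}"
        )
    return len(layout.all_wells() - layout.excluded_wells)


def max_conditions(
    layout: PlateLayout, replicates: int, reserve_vehicle: bool = True
) -> int:
    """Drug-concentration slots available on one plate.

    With 60 usable wells, 6 replicates and a reserved vehicle control this
    gives 9 testable drug concentrations.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    slots = count_usable_wells(layout) // replicates
    return slots - 1 if reserve_vehicle else slots


def plan_dilution(
    stock: float,
    final: float,
    wells: int,
    volume_added_per_well_ul: float = 100.0,
    stock_solvent: str = "DMSO",
    mode: str = "half_volume",
    solvent_warn_percent: float = SOLVENT_WARN_PERCENT,
) -> DilutionPlan:
    """Plan the working solution for one condition.

    In ``half_volume`` mode (the default protocol) half the well volume is
    replaced with a 2x working solution, so ``working = 2 * final`` and the
    final solvent fraction is half the working one.  ``full_volume`` mode
    replaces all medium with a 1x solution.
    """
    if wells < 0:
        raise ValidationError("wells must be >= 0")
    if final < 0 or stock <= 0:
        raise ValidationError("concentrations must be positive")
    factor = 2.0 if mode == "half_volume" else 1.0
    working = factor * final
    if stock < working:
        raise DilutionError(
            f"stock {stock} weaker than required working concentration {working}"
        )
    frac_working = 100.0 * working / stock if working > 0 else 0.0
    frac_final = frac_working / factor
    if frac_final > solvent_warn_percent:
        warnings.warn(
            f"final {stock_solvent} fraction {frac_final:.3g}% exceeds "
            f"{solvent_warn_percent}%",
            stacklevel=2,
        )
    return DilutionPlan(
        stock_conc=stock,
        stock_solvent=stock_solvent,
        working_conc=working,
        final_conc=final,
        volume_per_well_ul=volume_added_per_well_ul,
        wells_per_condition=wells,
        total_volume_ul=wells * volume_added_per_well_ul,
        solvent_fraction_working=frac_working,
        solvent_fraction_final=frac_final,
        mode=mode,
    )


def dye_final_concentration(
    working_dye_conc: float, replaced_volume_ul: float, well_volume_ul: float
) -> float:
    """Final in-well dye concentration after adding/replacing medium.

    Assumes the pre-existing dye concentration in the well is zero, so the
    final concentration is the working one scaled by the volume ratio, e.g.
    a 2 uM working solution replacing 100 of 200 uL gives 1 uM.
    """
    if replaced_volume_ul < 0 or well_volume_ul <= 0:
        raise ValidationError("volumes must be positive")
    if replaced_volume_ul > well_volume_ul:
        raise ValidationError("replaced volume exceeds well volume")
    return working_dye_conc * replaced_volume_ul / well_volume_ul
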