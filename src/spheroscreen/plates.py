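"""Microtiter-plate layout for 3D-spheroid screening campaigns.

A 384-well plate (16 rows A-P x 24 columns) is laid out so that the full
perimeter is excluded from analysis (edge effect), the two interior columns
flanking the compound block carry the controls (DMSO vehicle on the left,
the cytotoxic positive control on the right), and the remaining interior
block receives one test compound per well.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

#: Well roles used throughout the pipeline.
ROLE_COMPOUND = "compound"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_EDGE = "edge_excluded"
ROLE_EMPTY = "empty"

ROLES = (ROLE_COMPOUND, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EDGE, ROLE_EMPTY)


class CapacityError(ValueError):
    """Raised when more compounds are requested than interior wells exist."""


def well_name(row: int, col: int) -> str:
    """Return the plate-convention well name, e.g. (0, 0) -> 'A1'."""
    if row < 0 or row >= 26:
        raise ValueError(f"row index {row} out of range for letter naming")
    return f"{string.ascii_uppercase[row]}{col + 1}"


@dataclass(frozen=True)
class WellAssignment:
    """Role and compound assignment of a single well."""

    row: int
    col: int
    well: str
    role: str
    compound_id: str | None = None
    concentration_nM: float | None = None


@dataclass
class PlateLayout:
    """Roles and compound assignments for every well of one plate.

    Wells are stored row-major (A1, A2, ..., P24); the layout is fully
    deterministic for fixed inputs so replicate plates of the same
    compound chunk are identical up to their plate id.
    """

    plate_id: str
    n_rows: int
    n_cols: int
    wells: list[WellAssignment] = field(default_factory=list)

    def wells_with_role(self, role: str) -> list[WellAssignment]:
        return [w for w in self.wells if w.role == role]

    @property
    def compound_wells(self) -> list[WellAssignment]:
        return self.wells_with_role(ROLE_COMPOUND)

    @property
    def negative_wells(self) -> list[WellAssignment]:
        return self.wells_with_role(ROLE_NEGATIVE)

    @property
    def positive_wells(self) -> list[WellAssignment]:
        return self.wells_with_role(ROLE_POSITIVE)

    def to_frame(self) -> pd.DataFrame:
        """Plate map as a tidy table (plate_id, well, role, compound_id, concentration_nM)."""
        return pd.DataFrame(
            {
                "plate_id": self.plate_id,
                "well": [w.well for w in self.wells],
                "role": [w.role for w in self.wells],
                "compound_id": [w.compound_id for w in self.wells],
                "concentration_nM": [w.concentration_nM for w in self.wells],
            }
        )


def interior_capacity(n_rows: int = 16, n_cols: int = 24) -> int:
    """Number of wells available for compounds: interior block minus control columns.

    The perimeter (1 row/column on each side) is edge-excluded and one
    interior column per control flanks the compound block, leaving
    (n_rows - 2) x (n_cols - 4) compound wells -- 280 on a 384-well plate.
    """
    return max(0, (n_rows - 2) * (n_cols - 4))


def gen_plate_layout(
    n_rows: int = 16,
    n_cols: int = 24,
    compound_ids: Sequence[str] = (),
    concentration_nM: float | None = None,
    plate_id: str = "plate1",
) -> PlateLayout:
    """Build a screening plate layout.

    Perimeter wells carry role ``edge_excluded``; column 2 (DMSO 0.1%
    vehicle) and column ``n_cols - 1`` (positive control, Foretinib 30 uM in
    the assay this emulates) carry the controls on their interior rows;
    compounds fill the interior block row-major; leftover interior wells
    are ``empty``.

    Raises
    ------
    CapacityError
        If ``compound_ids`` exceeds the interior compound capacity; the
        message names the overflow count.
    """
    if n_rows < 4 or n_cols < 6:
        raise ValueError("plate must be at least 4 rows x 6 columns")
    capacity = interior_capacity(n_rows, n_cols)
    n_cpd = len(compound_ids)
    if n_cpd > capacity:
        raise CapacityError(
            f"{n_cpd} compounds exceed the {capacity} interior compound wells "
            f"({n_cpd - capacity} too many)"
        )
    neg_col = 1
    pos_col = n_cols - 2
    wells: list[WellAssignment] = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            name = well_name(r, c)
            if r in (0, n_rows - 1) or c in (0, n_cols - 1):
                wells.append(WellAssignment(r, c, name, ROLE_EDGE))
            elif c == neg_col:
                wells.append(WellAssignment(r, c, name, ROLE_NEGATIVE))
            elif c == pos_col:
                wells.append(WellAssignment(r, c, name, ROLE_POSITIVE))
            elif k < n_cpd:
                wells.append(
                    WellAssignment(
                        r, c, name, ROLE_COMPOUND, str(compound_ids[k]), concentration_nM
                    )
                )
                k += 1
            else:
                wells.append(WellAssignment(r, c, name, ROLE_EMPTY))
    return PlateLayout(plate_id=plate_id, n_rows=n_rows, n_cols=n_cols, wells=wells)
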