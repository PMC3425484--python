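"""Well-level plate data: coordinate conventions, validation and CSV I/O.

A plate is a standard 96-well grid, rows ``A``–``H`` top to bottom and
columns ``1``–``12`` left to right.  Wells are named letter+number
(``"C7"``).  Edge wells are excluded from experimentation to avoid
incubation edge effects; the default exclusion mask removes rows A and B
and columns 1 and 12, leaving 60 usable wells.

The on-disk dialect is a long-format CSV with one row per well and header
``plate_id,assay,replicate,well,role,construct_id,value``.  Reading and
writing round-trip losslessly (modulo column order).
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError

ROWS = "ABCDEFGH"
COLS = tuple(range(1, 13))

ASSAYS = ("viability", "cell_count")

ROLES = (
    "sample",
    "empty_vector",
    "control_mirna",
    "positive_control",
    "excluded_edge",
    "blank",
)

PLATE_CSV_COLUMNS = [
    "plate_id",
    "assay",
    "replicate",
    "well",
    "role",
    "construct_id",
    "value",
]

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


def well_name(row: str, col: int) -> str:
    return f"{row}{col}"


def parse_well(name: str) -> tuple[str, int]:
    """Split a well name like ``"C7"`` into ``("C", 7)``; validates range."""
    m = _WELL_RE.match(str(name).strip())
    if not m:
        raise ValidationError(f"malformed well name {name!r}")
    row, col = m.group(1), int(m.group(2))
    if col not in COLS:
        raise ValidationError(f"well column out of range in {name!r}")
    return row, col


@dataclass(frozen=True)
class ExclusionMask:
    """Rows and columns whose wells never carry samples.

    The default mirrors the screen layout: rows A and B and columns 1 and
    12 excluded, leaving a 6 x 10 block of 60 usable wells.  The mask is
    configurable because the printed layout is asymmetric (A/B rather than
    A/H) and other screens use other margins.
    """

    excluded_rows: frozenset[str] = frozenset()
    excluded_cols: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        rows = frozenset(self.excluded_rows)
        cols = frozenset(self.excluded_cols)
        object.__setattr__(self, "excluded_rows", rows)
        object.__setattr__(self, "excluded_cols", cols)
        if not rows <= set(ROWS):
            raise ValidationError(f"unknown rows in mask: {sorted(rows - set(ROWS))}")
        if not cols <= set(COLS):
            raise ValidationError(f"unknown columns in mask: {sorted(cols - set(COLS))}")
        if len(rows) >= len(ROWS) or len(cols) >= len(COLS):
            raise ValidationError("exclusion mask leaves no usable well")

    @classmethod
    def default_edge(cls) -> "ExclusionMask":
        return cls(excluded_rows=frozenset("AB"), excluded_cols=frozenset({1, 12}))

    @classmethod
    def empty(cls) -> "ExclusionMask":
        return cls()

    def excludes(self, row: str, col: int) -> bool:
        return row in self.excluded_rows or col in self.excluded_cols

    def usable_wells(self) -> list[str]:
        """Well names not excluded by the mask, row-major order."""
        return [
            well_name(r, c)
            for r in ROWS
            if r not in self.excluded_rows
            for c in COLS
            if c not in self.excluded_cols
        ]

    def to_dict(self) -> dict:
        return {
            "excluded_rows": sorted(self.excluded_rows),
            "excluded_cols": sorted(self.excluded_cols),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExclusionMask":
        return cls(
            excluded_rows=frozenset(d.get("excluded_rows", ())),
            excluded_cols=frozenset(int(c) for c in d.get("excluded_cols", ())),
        )


@dataclass
class WellRecord:
    """One well's readout plus its role on the plate.

    ``value`` is the raw readout: absorbance (AU) for viability, a nucleus
    count for cell_count (kept integral).  Excluded-edge and blank wells
    never contribute to plate statistics.
    """

    row: str
    col: int
    role: str
    construct_id: str | None = None
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.row not in ROWS or self.col not in COLS:
            raise ValidationError(f"well coordinate ({self.row},{self.col}) out of range")
        if self.role not in ROLES:
            raise ValidationError(f"unknown well role {self.role!r}")
        if self.value < 0:
            raise ValidationError(
                f"negative readout {self.value} in well {self.name}"
            )

    @property
    def name(self) -> str:
        return well_name(self.row, self.col)

    @property
    def usable(self) -> bool:
        return self.role not in ("excluded_edge", "blank")


@dataclass
class PlateGrid:
    """A single physical plate for one assay and replicate."""

    plate_id: str
    assay: str
    replicate: int
    wells: dict[str, WellRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValidationError(
                f"plate {self.plate_id}: unknown assay {self.assay!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"plate {self.plate_id}: replicate must be >= 1")
        for name, w in self.wells.items():
            if name != w.name:
                raise ValidationError(
                    f"plate {self.plate_id}: well keyed {name!r} but named {w.name!r}"
                )
            if self.assay == "cell_count" and w.usable and float(w.value) != int(w.value):
                raise ValidationError(
                    f"plate {self.plate_id} well {name}: cell_count value must be integral"
                )

    def add_well(self, well: WellRecord) -> None:
        if well.name in self.wells:
            raise ValidationError(
                f"plate {self.plate_id}: duplicate well {well.name}"
            )
        self.wells[well.name] = well

    def usable_wells(self) -> list[WellRecord]:
        return [w for w in self.wells.values() if w.usable]

    def usable_values(self) -> list[float]:
        return [w.value for w in self.usable_wells()]

    def apply_mask(self, mask: ExclusionMask) -> None:
        """Relabel masked wells as excluded_edge (idempotent)."""
        for w in self.wells.values():
            if mask.excludes(w.row, w.col):
                w.role = "excluded_edge"


def read_plates(path, mask: ExclusionMask | None = None) -> list[PlateGrid]:
    """Read plates from the long-format CSV and apply the exclusion mask.

    Wells falling inside the mask are relabelled ``excluded_edge``
    regardless of the role recorded in the file, so the mask convention is
    enforced uniformly downstream.  Validation errors name the plate and
    well concerned.
    """
    if mask is None:
        mask = ExclusionMask.default_edge()
    try:
        df = pd.read_csv(
            path, dtype={"construct_id": "string"}, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError:
        return []
    missing = set(PLATE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"plate CSV missing columns: {sorted(missing)}")

    plates: list[PlateGrid] = []
    for (plate_id, assay, replicate), grp in df.groupby(
        ["plate_id", "assay", "replicate"], sort=False
    ):
        plate = PlateGrid(str(plate_id), str(assay), int(replicate))
        for rec in grp.itertuples(index=False):
            try:
                row, col = parse_well(rec.well)
                cid = None if pd.isna(rec.construct_id) else str(rec.construct_id)
                well = WellRecord(row, col, str(rec.role), cid, float(rec.value))
                plate.add_well(well)
            except ValidationError as exc:
                raise ValidationError(
                    f"plate {plate_id} well {rec.well}: {exc}"
                ) from None
        plate.apply_mask(mask)
        # re-run invariants after masking (cell_count integrality on usable wells)
        PlateGrid(plate.plate_id, plate.assay, plate.replicate, plate.wells)
        plates.append(plate)
    return plates


def write_plates(plates: Iterable[PlateGrid], path) -> None:
    rows = []
    for p in plates:
        for name in sorted(p.wells, key=lambda n: (n[0], int(n[1:]))):
            w = p.wells[name]
            rows.append(
                {
                    "plate_id": p.plate_id,
                    "assay": p.assay,
                    "replicate": p.replicate,
                    "well": name,
                    "role": w.role,
                    "construct_id": "" if w.construct_id is None else w.construct_id,
                    "value": w.value,
                }
            )
    pd.DataFrame(rows, columns=PLATE_CSV_COLUMNS).to_csv(path, index=False)


def read_bscore_table(path):
    """Read a per-construct replicate B-score table (CSV or TSV).

    The layout mirrors the screen's supplementary score table: one row per
    construct with two replicate B-score columns per assay
    (``viability_rep1,viability_rep2,cell_count_rep1,cell_count_rep2``).
    Missing replicates are tolerated: the construct is flagged and its
    mean is computed over the available replicates, with a warning.

    Returns a :class:`~mirscreen.screen_stats.BScoreTable`.
    """
    from .screen_stats import BScoreTable

    table = BScoreTable()
    if os.path.getsize(path) == 0:
        return table
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        return table
    if df.empty and len(df.columns) == 0:
        return table
    if "construct_id" not in df.columns:
        raise ValidationError("B-score table lacks a construct_id column")
    for assay in ASSAYS:
        cols = [c for c in df.columns if c.startswith(assay + "_rep")]
        if not cols:
            continue
        for rec in df.itertuples(index=False):
            cid = str(getattr(rec, "construct_id"))
            vals = [getattr(rec, c) for c in cols]
            n_missing = sum(pd.isna(v) for v in vals)
            if n_missing:
                warnings.warn(
                    f"construct {cid}: {n_missing} missing {assay} replicate(s); "
                    "mean over available replicates",
                    stacklevel=2,
                )
            for v in vals:
                table.add_replicate(cid, assay, float(v) if not pd.isna(v) else float("nan"))
    return table
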