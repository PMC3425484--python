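import numpy as np
import pytest

from mirscreen.plate_io import ROWS, ExclusionMask, PlateGrid, WellRecord


def build_plate(
    values,
    plate_id="P1",
    assay="viability",
    replicate=1,
    construct_prefix="c",
    mask=None,
    fill_edges=True,
):
    """Lay out ``values`` row-major over the usable wells of a 96-well plate."""
    if mask is None:
        mask = ExclusionMask.default_edge()
    plate = PlateGrid(plate_id, assay, replicate)
    usable = mask.usable_wells()
    assert len(values) <= len(usable)
    if fill_edges:
        for r in ROWS:
            for c in range(1, 13):
                if mask.excludes(r, c):
                    plate.add_well(WellRecord(r, c, "excluded_edge", None, 0.0))
    for i, v in enumerate(values):
        name = usable[i]
        r, c = name[0], int(name[1:])
        plate.add_well(WellRecord(r, c, "sample", f"{construct_prefix}{i + 1:03d}", float(v)))
    return plate


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
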