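import numpy as np
import pytest

from mifcyto.model import MARKERS, STROMA, Cell, ImageROI


def make_markers(*positive: str) -> dict:
    """Marker mapping with DAPI on and the named markers positive."""
    m = {k: False for k in MARKERS}
    m["DAPI"] = True
    for name in positive:
        m[name] = True
    return m


def make_cell(cell_id: str, x: float, y: float, *positive: str,
              compartment: str = STROMA) -> Cell:
    return Cell(cell_id=cell_id, x_um=x, y_um=y,
                markers=make_markers(*positive), compartment=compartment)


def make_roi(cells, *, image_id="img0", sample_id="s0",
             stroma_area_mm2=0.5, tumor_area_mm2=0.25,
             field_width_um=1000.0, field_height_um=1000.0) -> ImageROI:
    return ImageROI.from_cells(
        cells, image_id=image_id, sample_id=sample_id,
        stroma_area_mm2=stroma_area_mm2, tumor_area_mm2=tumor_area_mm2,
        field_width_um=field_width_um, field_height_um=field_height_um)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
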