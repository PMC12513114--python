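import numpy as np
import pytest

from immunoprox import CellRecord, ImageCellTable


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_cells(coords, labels=None, markers=None, image_id="img1",
               patient_id="p1", region="T"):
    """Build CellRecords from coordinates plus optional labels/markers."""
    cells = []
    for i, (x, y) in enumerate(coords):
        cells.append(
            CellRecord(
                cell_id=f"c{i}",
                image_id=image_id,
                patient_id=patient_id,
                region=region,
                x=float(x),
                y=float(y),
                markers=None if markers is None else dict(markers[i]),
                phenotype=None if labels is None else labels[i],
            )
        )
    return cells


def make_table(coords, labels=None, markers=None, **kw):
    cells = make_cells(coords, labels=labels, markers=markers, **kw)
    return ImageCellTable(
        image_id=cells[0].image_id,
        patient_id=cells[0].patient_id,
        region=cells[0].region,
        cells=cells,
    )
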