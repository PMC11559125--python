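import numpy as np
import pytest

from spotstitch import build_stitched_sample
from spotstitch.fixtures import FixtureSpec, make_group_fixture
from spotstitch.geometry import (
    AffineTransform,
    GroupPlan,
    compute_rescale_factors,
)
from spotstitch.spaceranger_io import CaptureArea, CountMatrix, ScaleFactors

# a small, fast group: 20x24 array per area, two areas half-overlapping,
# third adjacent across a gap and rotated 180 degrees
SMALL = FixtureSpec(n_rows=20, n_cols=24, seed=11)


@pytest.fixture(scope="session")
def group_fixture(tmp_path_factory):
    return make_group_fixture(SMALL, tmp_path_factory.mktemp("group"))


@pytest.fixture(scope="session")
def stitched(group_fixture):
    return build_stitched_sample(group_fixture.areas, group_fixture.plan)


def hex_grid_spots(n_rows, n_cols, pitch_px, margin=None, jitter=0.0, rng=None):
    """An equal-parity hexagonal spot table in local fullres pixels."""
    import pandas as pd

    if margin is None:
        margin = pitch_px
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    keep = (rows % 2) == (cols % 2)
    rows, cols = rows[keep], cols[keep]
    x = margin + cols * pitch_px / 2.0
    y = margin + rows * pitch_px * np.sqrt(3) / 2.0
    if jitter:
        rng = rng or np.random.default_rng(0)
        x = x + rng.uniform(-jitter, jitter, x.size)
        y = y + rng.uniform(-jitter, jitter, y.size)
    return pd.DataFrame(
        {
            "barcode": [f"S{r:02d}X{c:02d}-1" for r, c in zip(rows, cols)],
            "in_tissue": 1,
            "array_row": rows,
            "array_col": cols,
            "pxl_row_in_fullres": y,
            "pxl_col_in_fullres": x,
        }
    )


def toy_area(area_id, d=55.0, h=0.2, n_rows=8, n_cols=10, counts_value=1, jitter=0.0):
    """A minimal in-memory capture area with constant counts."""
    import scipy.sparse as sp

    pitch = d * 100.0 / 55.0
    spots = hex_grid_spots(n_rows, n_cols, pitch, jitter=jitter)
    n = len(spots)
    counts = CountMatrix(
        genes=["G1", "G2"],
        barcodes=spots["barcode"].tolist(),
        counts=sp.csr_matrix(np.full((2, n), counts_value, dtype=np.int64)),
    )
    sf = ScaleFactors(spot_diameter_fullres=d, tissue_hires_scalef=h)
    return CaptureArea(area_id=area_id, spots=spots, scalefactors=sf, counts=counts)


def identity_plan(areas, group_id="g"):
    return GroupPlan(
        group_id=group_id,
        members=[a.area_id for a in areas],
        transforms={a.area_id: AffineTransform.identity() for a in areas},
        rescale=compute_rescale_factors({a.area_id: a.scalefactors for a in areas}),
    )
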