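import numpy as np
import pytest
from hypothesis import settings

from eatq.geometry import Contour, ContourStack

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def square(side=1.0, origin=(0.0, 0.0), clockwise=False, **kw):
    x0, y0 = origin
    pts = [(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)]
    if clockwise:
        pts = pts[::-1]
    defaults = dict(slice_index=0, phase="end_diastole", structure="eat", role="outer")
    defaults.update(kw)
    return Contour(points=np.array(pts, dtype=float), **defaults)


@pytest.fixture
def make_square():
    return square


@pytest.fixture
def prism_stack():
    """10 slices, each a 25x20 mm rectangle (500 mm^2), spacing 6 mm."""
    contours = [
        Contour(
            points=np.array([(0, 0), (25, 0), (25, 20), (0, 20)], dtype=float),
            slice_index=i,
            phase="end_diastole",
            structure="eat",
        )
        for i in range(10)
    ]
    return ContourStack(
        contours=contours,
        slice_thickness_mm=5.0,
        inter_slice_gap_mm=1.0,
        n_slices=10,
        subject_id="prism",
    )
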