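import numpy as np
import pytest

from atriarecon.contours import Contour
from atriarecon.geometry import ImagePlane
from atriarecon.phantoms import SliceStrategy, generate_strategy, make_phantom


@pytest.fixture
def axial_plane() -> ImagePlane:
    """A simple axial slice with 1.5 mm pixels, origin at (-100, -80, 40)."""
    return ImagePlane(
        origin=(-100.0, -80.0, 40.0),
        u_dir=(1.0, 0.0, 0.0),
        v_dir=(0.0, 1.0, 0.0),
        spacing=(1.5, 1.5),
        n_rows=128,
        n_cols=128,
        plane_id="AX",
    )


def circle_contour(
    radius_px: float,
    center_rowcol=(0.0, 0.0),
    n: int = 256,
    plane_id: str = "",
    frame: int = 0,
) -> Contour:
    """Regular n-gon approximating a circle, in (row, col) pixels."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    rows = center_rowcol[0] + radius_px * np.sin(t)
    cols = center_rowcol[1] + radius_px * np.cos(t)
    return Contour(points=np.column_stack([rows, cols]), plane_id=plane_id, frame=frame)


@pytest.fixture(scope="session")
def sphere_phantom():
    """The 55 ml spherical phantom (radius 23.59 mm)."""
    return make_phantom("sphere", 55.0)


@pytest.fixture(scope="session")
def sphere_dataset(sphere_phantom):
    """Noise-free aligned-strategy slicing of the 55 ml sphere."""
    return generate_strategy(sphere_phantom, SliceStrategy("D1"))


@pytest.fixture(scope="session")
def validation_report():
    """The full noise-free 5-shape x 3-strategy suite at the 1 mm grid.

    Shared session-wide: several agreement and invariance checks read
    different aspects of the same run.
    """
    from atriarecon.pipeline import RunConfig, run_validation_suite

    return run_validation_suite(RunConfig(grid_mm=1.0))
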