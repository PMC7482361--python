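import numpy as np
import pytest

from tendonmetrics.geometry import Contour, ContourStack


def circle_contour(
    radius: float,
    z: float,
    slice_index: int,
    n: int = 96,
    center=(0.0, 0.0),
) -> Contour:
    """A regular n-gon approximating a circle in the plane z = const."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    verts = np.column_stack(
        [
            center[0] + radius * np.cos(theta),
            center[1] + radius * np.sin(theta),
            np.full(n, z),
        ]
    )
    return Contour(vertices=verts, slice_index=slice_index)


def cylinder_stack(
    radius: float, length: float, n_slices: int, n_vertices: int = 96
) -> ContourStack:
    zs = np.linspace(0.0, length, n_slices)
    return ContourStack(
        contours=[
            circle_contour(radius, z, i, n=n_vertices) for i, z in enumerate(zs)
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
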