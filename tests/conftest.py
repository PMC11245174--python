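import numpy as np
import pytest

from carotid_xsec.phantom import (
    PhantomSpec,
    constant_radius,
    constant_thickness,
    make_phantom,
)


def straight_tube_spec(**overrides) -> PhantomSpec:
    """A phantom whose three branches are collinear: one straight tube.

    Setting all branch directions to +z collapses the bifurcation, which
    makes analytic slice-wise checks exact.
    """
    kwargs = dict(
        branch_directions={"CCA": (0, 0, 1), "ICA": (0, 0, 1), "ECA": (0, 0, 1)},
        branch_offsets_mm={"ICA": (0, 0, 0), "ECA": (0, 0, 0)},
        lumen_radius_mm=constant_radius(3.0),
        wall_thickness_mm=constant_thickness(1.0),
        noise_sigma=0.0,
        supersample=1,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def straight_phantom():
    spec = straight_tube_spec()
    volume, truth = make_phantom(spec)
    return spec, volume, truth


@pytest.fixture
def circle_contours():
    """Concentric circles r=3 (inner) and r=4 (outer), 360 vertices."""
    th = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    inner = 3.0 * np.column_stack([np.cos(th), np.sin(th)])
    outer = 4.0 * np.column_stack([np.cos(th), np.sin(th)])
    return inner, outer
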