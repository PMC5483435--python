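import numpy as np
import pytest

import tractokit as tk


@pytest.fixture
def ref10() -> tk.SpatialReference:
    """10^3 unit-voxel grid with identity affine (voxel centers at integers)."""
    return tk.SpatialReference.isotropic((10, 10, 10), 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170042)


@pytest.fixture
def unit_cube() -> tk.RoiMesh:
    """Axis-aligned unit cube centered at the origin."""
    return tk.box_roi((0.0, 0.0, 0.0), (0.5, 0.5, 0.5))


def make_tractogram(rng: np.random.Generator, ref, n=5, npts=20, scale=6.0, offset=2.0):
    """Random jagged polylines inside the grid."""
    streamlines = []
    for _ in range(n):
        pts = offset + scale * rng.random((npts, 3))
        streamlines.append(pts)
    return tk.Tractogram.from_arrays(streamlines, ref)


@pytest.fixture
def phantom_suite():
    """Small deterministic suite covering smooth and jittered bundles."""
    specs = {
        "straight": tk.PhantomSpec(kind="straight", n_streamlines=10, step=0.5,
                                   length=40.0, cross_section=2.0, seed=1),
        "arc": tk.PhantomSpec(kind="arc", n_streamlines=10, step=0.5, arc_angle=120.0,
                              curvature_radius=20.0, cross_section=2.0, seed=2),
        "helix": tk.PhantomSpec(kind="helix", n_streamlines=10, step=0.5, arc_angle=180.0,
                                curvature_radius=15.0, helix_pitch=20.0,
                                cross_section=2.0, seed=3),
        "random_walk": tk.PhantomSpec(kind="random_walk", n_streamlines=10, step=0.5,
                                      length=30.0, angular_jitter=10.0,
                                      cross_section=2.0, seed=4),
    }
    return {name: tk.generate_bundle(spec) for name, spec in specs.items()}
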