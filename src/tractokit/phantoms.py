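"""Seeded synthetic streamline bundles, ROIs and analytic scalar maps.

No tractography dataset ships with this package; every algorithm is
exercised on generated geometry instead.  The generators emulate the two
regimes that matter for linearization and selection:

* *deterministic-like* streamlines — smooth, low local curvature (straight,
  circular-arc and helical centerlines), which compress aggressively;
* *probabilistic-like* streamlines — a unit-speed random walk whose
  direction is perturbed at every step by a random angle (folded-normal
  magnitude, uniform azimuth in the plane orthogonal to the current
  direction), which emulates the sharp local direction changes of
  probabilistic tracking and compresses poorly.

Bundles are built by rigidly offsetting one centerline per streamline by a
uniform-disk jitter in the plane orthogonal to the initial direction, so
every streamline keeps an exactly uniform step length.  Defaults follow a
typical single-subject acquisition: a 50^3 grid at 2 mm isotropic and a
0.5 mm tracking step size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import SpatialReference, Tractogram, point_to_voxel
from .selection import RoiMesh, box_roi
from .tractometry import MetricMap

__all__ = [
    "PhantomSpec",
    "default_reference",
    "generate_bundle",
    "analytic_metric",
    "bundle_scenario",
]

_KINDS = ("straight", "arc", "helix", "random_walk")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic bundle.

    ``length`` is the total arc length in mm (straight / random_walk);
    ``arc_angle`` (degrees) and ``curvature_radius`` (mm) shape arcs and
    helices; ``angular_jitter`` is the per-step direction perturbation in
    degrees (random_walk); ``cross_section`` the bundle radius in mm.
    """

    kind: str
    n_streamlines: int = 20
    step: float = 0.5
    length: float = 60.0
    arc_angle: float = 90.0
    curvature_radius: float = 25.0
    helix_pitch: float = 20.0
    angular_jitter: float = 10.0
    cross_section: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.angular_jitter < 0:
            raise ValueError("angular_jitter must be >= 0")
        if self.cross_section < 0:
            raise ValueError("cross_section must be >= 0")


def default_reference() -> SpatialReference:
    """The default phantom grid: 50^3 voxels at 2 mm isotropic."""
    return SpatialReference.isotropic((50, 50, 50), voxel_size=2.0)


def _grid_center_world(ref: SpatialReference) -> np.ndarray:
    from .core_io import grid_to_world

    return grid_to_world(np.asarray(ref.dims, dtype=np.float64) / 2.0, ref)


def _walk_centerline(spec: PhantomSpec, start: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-speed walk; zero jitter degenerates to an exact straight line."""
    n_steps = int(round(spec.length / spec.step))
    sigma = np.deg2rad(spec.angular_jitter)
    direction = np.array([1.0, 0.0, 0.0])
    steps = np.empty((n_steps, 3))
    for i in range(n_steps):
        if sigma > 0:
            angle = abs(rng.normal(0.0, sigma))
            azimuth = rng.uniform(0.0, 2.0 * np.pi)
            # Orthonormal frame around the current direction.
            helper = np.array([0.0, 0.0, 1.0])
            if abs(direction[2]) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            u = np.cross(direction, helper)
            u /= np.linalg.norm(u)
            v = np.cross(direction, u)
            tilt = np.cos(azimuth) * u + np.sin(azimuth) * v
            direction = np.cos(angle) * direction + np.sin(angle) * tilt
            direction /= np.linalg.norm(direction)
        steps[i] = direction
    pts = np.empty((n_steps + 1, 3))
    pts[0] = start
    np.cumsum(steps * spec.step, axis=0, out=pts[1:])
    pts[1:] += start
    return pts


def _centerline(spec: PhantomSpec, center: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if spec.kind in ("straight", "random_walk"):
        s = spec if spec.kind == "random_walk" else replace(spec, angular_jitter=0.0)
        start = center - np.array([spec.length / 2.0, 0.0, 0.0])
        return _walk_centerline(s, start, rng)
    if spec.kind == "arc":
        R = spec.curvature_radius
        span = np.deg2rad(spec.arc_angle)
        dtheta = spec.step / R
        n_steps = int(round(span / dtheta))
        theta = (np.arange(n_steps + 1) - n_steps / 2.0) * dtheta + np.pi / 2.0
        # Apex of the arc (theta = pi/2) sits at the bundle center.
        pts = np.column_stack(
            [R * np.cos(theta), R * np.sin(theta) - R, np.zeros(n_steps + 1)]
        )
        return pts + center
    if spec.kind == "helix":
        R = spec.curvature_radius
        c = spec.helix_pitch / (2.0 * np.pi)
        span = np.deg2rad(spec.arc_angle)
        dtheta = spec.step / np.hypot(R, c)  # arc-length parametrization
        n_steps = int(round(span / dtheta))
        theta = np.arange(n_steps + 1) * dtheta
        pts = np.column_stack([R * (np.cos(theta) - 1.0), R * np.sin(theta), c * theta])
        return pts + center
    raise ValueError(f"unknown kind {spec.kind!r}")  # pragma: no cover


def generate_bundle(spec: PhantomSpec, ref: SpatialReference | None = None) -> Tractogram:
    """Generate a reproducible bundle of ``n_streamlines`` inside ``ref``.

    Raises if any generated point falls outside the grid.
    """
    ref = ref if ref is not None else default_reference()
    root = np.random.default_rng(spec.seed)
    offsets_rng, walk_rng = root.spawn(2)
    center = _grid_center_world(ref)

    # Per-streamline rigid offset: uniform disk in the plane orthogonal to
    # the initial direction (+x for all kinds as constructed here... arc and
    # helix start tangent differs, but a rigid translation is shape-neutral).
    r = spec.cross_section * np.sqrt(offsets_rng.uniform(0, 1, spec.n_streamlines))
    phi = offsets_rng.uniform(0, 2 * np.pi, spec.n_streamlines)
    offsets = np.column_stack([np.zeros_like(r), r * np.cos(phi), r * np.sin(phi)])

    streamlines = []
    for i in range(spec.n_streamlines):
        cl = _centerline(spec, center, walk_rng)
        streamlines.append(cl + offsets[i])
    t = Tractogram(streamlines, ref)
    vox = point_to_voxel(np.vstack(streamlines), ref)
    if np.any(vox < 0) or np.any(vox >= np.asarray(ref.dims)):
        raise ValueError("generated geometry exceeds the grid; shrink the phantom")
    return t


def analytic_metric(
    pattern: str,
    ref: SpatialReference | None = None,
    *,
    value: float = 0.7,
    axis: int = 0,
    center: "np.typing.ArrayLike | None" = None,
) -> MetricMap:
    """Closed-form scalar map evaluated at voxel centers.

    ``constant`` fills the grid with ``value``; ``axis_gradient`` assigns the
    normalized voxel-center coordinate ``(i + 0.5) / dims[axis]`` along
    ``axis``; ``radial`` the distance from ``center`` (world mm; defaults to
    the central voxel's center) normalized to [0, 1].
    """
    ref = ref if ref is not None else default_reference()
    dims = ref.dims
    if pattern == "constant":
        vals = np.full(dims, float(value))
    elif pattern == "axis_gradient":
        coord = (np.arange(dims[axis]) + 0.5) / dims[axis]
        shape = [1, 1, 1]
        shape[axis] = dims[axis]
        vals = np.broadcast_to(coord.reshape(shape), dims).copy()
    elif pattern == "radial":
        from .core_io import grid_to_world

        if center is None:
            center = grid_to_world(np.asarray(dims) // 2 + 0.5, ref)
        center = np.asarray(center, dtype=np.float64)
        ii, jj, kk = np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")
        grid_pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) + 0.5
        world = grid_to_world(grid_pts, ref)
        dist = np.linalg.norm(world - center, axis=1).reshape(dims)
        vals = dist / dist.max() if dist.max() > 0 else dist
    else:
        raise ValueError(f"unknown metric pattern {pattern!r}")
    return MetricMap(vals, ref)


def bundle_scenario(name: str, seed: int = 0) -> tuple[Tractogram, RoiMesh, MetricMap]:
    """Canonical test scenes: a curved (CC-like) or straight (CST-like) bundle.

    ``cc_like``: high-curvature arc bundle with a 5x5x5 mm box on the arc
    apex.  ``cst_like``: straight bundle with the same box at its midpoint.
    The metric is an axis gradient.  Fully seeded and reproducible.
    """
    ref = default_reference()
    center = _grid_center_world(ref)
    if name == "cc_like":
        spec = PhantomSpec(
            kind="arc",
            n_streamlines=50,
            step=0.5,
            arc_angle=120.0,
            curvature_radius=20.0,
            cross_section=2.0,
            seed=seed,
        )
    elif name == "cst_like":
        spec = PhantomSpec(
            kind="straight",
            n_streamlines=50,
            step=0.5,
            length=60.0,
            cross_section=2.0,
            seed=seed,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}")
    bundle = generate_bundle(spec, ref)
    # Generic-position ROI: offset from the exact bundle midpoint so results
    # never hinge on accidental alignment between the box and the sampling
    # (or post-compression keeping) lattice.
    roi = box_roi(center + np.array([4.1, 0.0, 0.0]), (2.5, 2.5, 2.5))
    metric = analytic_metric("axis_gradient", ref, axis=0)
    return bundle, roi, metric
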