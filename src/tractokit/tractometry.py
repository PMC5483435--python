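"""Streamline-to-voxel mapping and bundle metric statistics.

Classical tractometry identifies the voxels a bundle occupies from the
streamline *points* alone.  With a small uniform step size that is adequate,
but once streamlines are linearized (or tracked with a variable step size)
the surviving points are sparse and the point-based map both misses voxels
crossed only by a segment and mis-weights the densely sampled regions — the
voxel mapping bias.  The fix is rasterization: an Amanatides–Woo traversal
(:func:`traverse_segment`) enumerates every voxel each segment passes
through, making the voxel support — and hence mean FA/MD/AD/RD and bundle
volume — nearly invariant to compression.

Both mappings are provided: ``mode="point"`` is the biased baseline,
``mode="segment"`` the robust method.  Voxel weights can count once per
streamline (``per_streamline``, the default: the only weighting invariant
under resampling of the same geometry) or once per sample
(``per_sample``: per point, or per segment-voxel incidence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import nibabel as nib

from .core_io import (
    SpatialReference,
    Streamline,
    Tractogram,
    world_to_grid,
)

__all__ = [
    "MetricMap",
    "VoxelWeightMap",
    "BundleSummary",
    "RobustnessRecord",
    "load_metric_map",
    "save_metric_map",
    "traverse_segment",
    "streamline_voxels",
    "bundle_weight_map",
    "bundle_summary",
    "robustness_statistic",
    "weight_difference_map",
]


@dataclass(frozen=True)
class MetricMap:
    """A 3D scalar map (e.g. FA, MD) on the grid of a :class:`SpatialReference`."""

    values: np.ndarray
    reference: SpatialReference

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != self.reference.dims:
            raise ValueError(
                f"metric shape {v.shape} does not match grid dims {self.reference.dims}"
            )
        if not np.isfinite(v).all():
            raise ValueError("metric map contains non-finite values")
        object.__setattr__(self, "values", v)


def load_metric_map(path) -> MetricMap:
    """Read a NIfTI scalar volume together with its grid context."""
    img = nib.load(path)
    values = np.asarray(img.get_fdata(), dtype=np.float64)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D scalar volume, got shape {values.shape}")
    ref = SpatialReference.from_affine(img.affine, values.shape)
    return MetricMap(values, ref)


def save_metric_map(values: np.ndarray, ref: SpatialReference, path) -> None:
    """Write a 3D grid (e.g. a weight-difference map) as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), ref.affine), path)


@dataclass
class VoxelWeightMap:
    """Sparse voxel -> positive weight mapping supporting bundle statistics."""

    weights: dict[tuple[int, int, int], float]
    mode: str  # "point" | "segment"
    weighting: str  # "per_streamline" | "per_sample"
    reference: SpatialReference

    def __post_init__(self) -> None:
        if self.mode not in ("point", "segment"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.weighting not in ("per_streamline", "per_sample"):
            raise ValueError(f"unknown weighting {self.weighting!r}")

    @property
    def n_voxels(self) -> int:
        return len(self.weights)

    def voxel_set(self) -> set[tuple[int, int, int]]:
        return set(self.weights)


@dataclass(frozen=True)
class BundleSummary:
    """Bundle-level statistics of one metric over one voxel weight map."""

    mean_binary: float
    mean_weighted: float
    n_voxels: int
    volume: float  # mm^3

    def to_dict(self) -> dict:
        return {
            "mean_binary": self.mean_binary,
            "mean_weighted": self.mean_weighted,
            "n_voxels": self.n_voxels,
            "volume": self.volume,
        }


@dataclass(frozen=True)
class RobustnessRecord:
    """Relative change of a bundle mean under compression: R = |M_c - M_0| / |M_0|."""

    m_b0: float
    m_bc: float
    r: float

    def to_dict(self) -> dict:
        return {"m_b0": self.m_b0, "m_bc": self.m_bc, "r": self.r}


# ---------------------------------------------------------------------------
# Voxel traversal
# ---------------------------------------------------------------------------

def _clip_to_grid(g0: np.ndarray, g1: np.ndarray, dims: np.ndarray):
    """Liang–Barsky clip of the closed segment to the grid box [0, dims]^3."""
    d = g1 - g0
    t0, t1 = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if g0[ax] < 0.0 or g0[ax] > dims[ax]:
                return None
            continue
        ta = (0.0 - g0[ax]) / d[ax]
        tb = (dims[ax] - g0[ax]) / d[ax]
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1:
            return None
    return t0, t1


def traverse_segment(g0, g1, dims) -> list[tuple[int, int, int]]:
    """Voxels the closed segment ``g0 -> g1`` (continuous grid coords) crosses.

    Amanatides–Woo grid marching: voxels are emitted in order from ``g0`` to
    ``g1``; the part of the segment outside ``[0, dims)`` is clipped out; a
    zero-length segment yields its single containing voxel.  When two
    crossing parameters tie (the segment hits a voxel corner/edge exactly),
    axes step in fixed x -> y -> z order, so the intermediate voxel is
    included deterministically.
    """
    g0 = np.asarray(g0, dtype=np.float64)
    g1 = np.asarray(g1, dtype=np.float64)
    if not (np.isfinite(g0).all() and np.isfinite(g1).all()):
        raise ValueError("non-finite segment endpoints")
    dims = np.asarray(dims, dtype=np.int64)

    d = g1 - g0
    if np.all(d == 0.0):
        v = np.floor(g0).astype(np.int64)
        if np.all(v >= 0) and np.all(v < dims):
            return [tuple(v)]
        return []

    clip = _clip_to_grid(g0, g1, dims)
    if clip is None:
        return []
    t_in, t_out = clip
    a = g0 + t_in * d
    b = g0 + t_out * d
    v = np.clip(np.floor(a).astype(np.int64), 0, dims - 1)
    w = np.clip(np.floor(b).astype(np.int64), 0, dims - 1)

    step = np.sign(d).astype(np.int64)
    with np.errstate(divide="ignore"):
        t_delta = np.where(d != 0.0, np.abs(1.0 / np.where(d != 0, d, 1.0)), np.inf)
        next_boundary = v + (step > 0)
        t_max = np.where(d != 0.0, (next_boundary - g0) / np.where(d != 0, d, 1.0), np.inf)

    out = [tuple(v)]
    # Each step moves exactly one axis one voxel toward the exit voxel, so
    # the Manhattan distance bounds the loop even under float ties.
    for _ in range(int(np.abs(w - v).sum())):
        ax = int(np.argmin(t_max))  # ties -> lowest axis: x before y before z
        v = v.copy()
        v[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        if v[ax] < 0 or v[ax] >= dims[ax]:
            break
        out.append(tuple(v))
        if np.array_equal(v, w):
            break
    return out


def streamline_voxels(
    s: Streamline, ref: SpatialReference, mode: str = "segment"
) -> set[tuple[int, int, int]]:
    """Voxel set a streamline occupies under the point- or segment-based map.

    Point mode floors each point's grid coordinate; segment mode unions
    :func:`traverse_segment` over consecutive point pairs and is always a
    superset of point mode.  Out-of-grid points contribute nothing (a
    warning counts them).
    """
    g = world_to_grid(np.asarray(s, dtype=np.float64), ref)
    dims = np.asarray(ref.dims)
    if mode == "point":
        vox = np.floor(g).astype(np.int64)
        in_grid = np.all((vox >= 0) & (vox < dims), axis=1)
        n_out = int((~in_grid).sum())
        if n_out:
            warnings.warn(f"{n_out} point(s) outside the grid were ignored", stacklevel=2)
        return {tuple(v) for v in vox[in_grid]}
    if mode == "segment":
        voxels: set[tuple[int, int, int]] = set()
        for i in range(len(g) - 1):
            voxels.update(traverse_segment(g[i], g[i + 1], dims))
        return voxels
    raise ValueError(f"unknown mode {mode!r}")


def bundle_weight_map(
    bundle: Tractogram,
    ref: SpatialReference | None = None,
    mode: str = "segment",
    weighting: str = "per_streamline",
) -> VoxelWeightMap:
    """Accumulate voxel weights over a bundle.

    ``per_streamline``: each streamline adds 1 to every voxel of its voxel
    set (a streamline counts once per voxel, however densely sampled).
    ``per_sample``: point mode adds 1 per point in the voxel; segment mode
    adds 1 per segment-voxel incidence.
    """
    if len(bundle) == 0:
        raise ValueError("bundle is empty")
    ref = ref if ref is not None else bundle.reference
    weights: dict[tuple[int, int, int], float] = {}
    dims = np.asarray(ref.dims)
    for s in bundle:
        if weighting == "per_streamline":
            for v in streamline_voxels(s, ref, mode):
                weights[v] = weights.get(v, 0.0) + 1.0
        elif weighting == "per_sample":
            if mode == "point":
                g = world_to_grid(np.asarray(s), ref)
                vox = np.floor(g).astype(np.int64)
                in_grid = np.all((vox >= 0) & (vox < dims), axis=1)
                n_out = int((~in_grid).sum())
                if n_out:
                    warnings.warn(
                        f"{n_out} point(s) outside the grid were ignored", stacklevel=2
                    )
                for v in vox[in_grid]:
                    key = tuple(v)
                    weights[key] = weights.get(key, 0.0) + 1.0
            elif mode == "segment":
                g = world_to_grid(np.asarray(s), ref)
                for i in range(len(g) - 1):
                    for key in traverse_segment(g[i], g[i + 1], dims):
                        weights[key] = weights.get(key, 0.0) + 1.0
            else:
                raise ValueError(f"unknown mode {mode!r}")
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
    return VoxelWeightMap(weights, mode=mode, weighting=weighting, reference=ref)


def bundle_summary(w: VoxelWeightMap, m: MetricMap) -> BundleSummary:
    """Binary and weighted bundle means of a metric, voxel count and volume."""
    if w.reference.dims != m.reference.dims or not np.allclose(
        w.reference.affine, m.reference.affine, atol=1e-6
    ):
        raise ValueError("weight map and metric map are on different grids")
    if w.n_voxels == 0:
        raise ValueError("empty weight map")
    idx = np.array(sorted(w.weights), dtype=np.int64)
    wts = np.array([w.weights[tuple(v)] for v in idx], dtype=np.float64)
    vals = m.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return BundleSummary(
        mean_binary=float(vals.mean()),
        mean_weighted=float((wts * vals).sum() / wts.sum()),
        n_voxels=w.n_voxels,
        volume=w.n_voxels * w.reference.voxel_volume,
    )


def robustness_statistic(m_b0: float, m_bc: float) -> RobustnessRecord:
    """Relative deviation of a compressed bundle mean from the uncompressed one."""
    if m_b0 == 0:
        raise ValueError("uncompressed mean must be nonzero")
    return RobustnessRecord(
        m_b0=float(m_b0), m_bc=float(m_bc), r=abs(m_bc - m_b0) / abs(m_b0)
    )


def weight_difference_map(w_orig: VoxelWeightMap, w_comp: VoxelWeightMap) -> np.ndarray:
    """Dense per-voxel ``w_orig - w_comp`` grid (0 where neither is defined)."""
    if w_orig.reference.dims != w_comp.reference.dims or not np.allclose(
        w_orig.reference.affine, w_comp.reference.affine, atol=1e-6
    ):
        raise ValueError("weight maps are on different grids")
    diff = np.zeros(w_orig.reference.dims, dtype=np.float64)
    for v, wt in w_orig.weights.items():
        diff[v] += wt
    for v, wt in w_comp.weights.items():
        diff[v] -= wt
    return diff
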