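"""Domain types, TCK/TRK streamline I/O and world<->grid coordinate transforms.

The canonical coordinate space throughout the package is world RAS
millimeters.  TrackVis (``.trk``) files store points in voxel-mm space; the
conversion happens at the I/O boundary (nibabel applies the header transform
on load and its inverse on save), so every algorithm in this package only
ever sees RAS mm polylines.

The grid convention: a :class:`SpatialReference` affine maps *voxel indices*
(center convention) to world mm.  :func:`world_to_grid` additionally shifts
by +0.5 so that voxel ``(i, j, k)`` occupies the half-open cube
``[i, i+1) x [j, j+1) x [k, k+1)`` in grid coordinates and ``floor`` is the
point->voxel map.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import nibabel as nib
from nibabel.streamlines import Tractogram as _NibTractogram

__all__ = [
    "TractogramError",
    "UnknownFormatError",
    "HeaderError",
    "TruncatedFileError",
    "Streamline",
    "SpatialReference",
    "Tractogram",
    "SegmentStats",
    "as_streamline",
    "read_tractogram",
    "write_tractogram",
    "world_to_grid",
    "grid_to_world",
    "point_to_voxel",
    "segment_stats",
]


class TractogramError(Exception):
    """Base class for streamline I/O and validation errors."""


class UnknownFormatError(TractogramError):
    """File extension / requested format is not a supported tractogram format."""


class HeaderError(TractogramError):
    """The file header could not be parsed under the named standard."""


class TruncatedFileError(TractogramError):
    """The file body ended before the header-declared data was read."""


#: A streamline is an ordered 3D polyline in world millimeters: a float64
#: array of shape (n_points, 3) with n_points >= 2, finite coordinates and
#: no two consecutive points identical.
Streamline = np.ndarray


def as_streamline(points: "np.typing.ArrayLike", dedup: bool = True) -> Streamline:
    """Validate (and optionally dedup) a point sequence into a streamline.

    Parameters
    ----------
    points
        Sequence of 3D coordinates in world mm.
    dedup
        Remove consecutive duplicate points (zero-length segments break
        distance and traversal math).  A warning is emitted when points are
        dropped.

    Raises
    ------
    ValueError
        On non-finite coordinates, wrong shape, or fewer than 2 points after
        deduplication.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError(f"streamline must have shape (n, 3), got {pts.shape}")
    if not np.isfinite(pts).all():
        raise ValueError("streamline contains non-finite coordinates")
    if dedup and len(pts) > 1:
        keep = np.ones(len(pts), dtype=bool)
        keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
        if not keep.all():
            warnings.warn(
                f"removed {int((~keep).sum())} consecutive duplicate point(s)",
                stacklevel=2,
            )
            pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("streamline must have at least 2 distinct points")
    return pts


@dataclass(frozen=True)
class SpatialReference:
    """Voxel grid context: affine (voxel-center index -> world mm) and shape.

    Attributes
    ----------
    affine
        4x4 invertible matrix mapping voxel indices (center convention) to
        world RAS mm.
    dims
        Grid shape, three positive integers.
    voxel_sizes
        Edge lengths of a voxel in mm; must equal the column norms of the
        affine's 3x3 block.
    """

    affine: np.ndarray
    dims: tuple[int, int, int]
    voxel_sizes: tuple[float, float, float]

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=np.float64)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "affine", aff)
        dims = tuple(int(d) for d in self.dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"dims must be 3 positive integers, got {self.dims}")
        object.__setattr__(self, "dims", dims)
        vs = tuple(float(v) for v in self.voxel_sizes)
        col_norms = np.linalg.norm(aff[:3, :3], axis=0)
        if any(v <= 0 for v in vs):
            raise ValueError("voxel sizes must be positive")
        if not np.allclose(vs, col_norms, rtol=1e-4):
            raise ValueError(
                f"voxel_sizes {vs} inconsistent with affine column norms {col_norms}"
            )
        object.__setattr__(self, "voxel_sizes", vs)

    @classmethod
    def from_affine(cls, affine: "np.typing.ArrayLike", dims: Sequence[int]) -> "SpatialReference":
        aff = np.asarray(affine, dtype=np.float64)
        return cls(aff, tuple(dims), tuple(np.linalg.norm(aff[:3, :3], axis=0)))

    @classmethod
    def isotropic(cls, dims: Sequence[int], voxel_size: float = 1.0) -> "SpatialReference":
        """Axis-aligned grid with the world origin at the center of voxel 0."""
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls.from_affine(aff, dims)

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (|det| of the 3x3 block)."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass
class Tractogram:
    """A collection of streamlines sharing one world space / voxel grid."""

    streamlines: list[Streamline]
    reference: SpatialReference

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self) -> Iterator[Streamline]:
        return iter(self.streamlines)

    def __getitem__(self, i: int) -> Streamline:
        return self.streamlines[i]

    @property
    def total_points(self) -> int:
        return sum(len(s) for s in self.streamlines)

    @classmethod
    def from_arrays(
        cls,
        arrays: Iterable["np.typing.ArrayLike"],
        reference: SpatialReference,
        dedup: bool = True,
    ) -> "Tractogram":
        return cls([as_streamline(a, dedup=dedup) for a in arrays], reference)


@dataclass(frozen=True)
class SegmentStats:
    """Maximum / mean Euclidean length over all consecutive-point segments."""

    max_len: float
    mean_len: float
    n_segments: int

    def __post_init__(self) -> None:
        if not (self.max_len >= self.mean_len > 0):
            raise ValueError("requires max_len >= mean_len > 0")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_EXTENSIONS = {".tck": "tck", ".trk": "trk"}


def _resolve_format(path: str | os.PathLike, fmt: str) -> str:
    fmt = fmt.lower()
    if fmt == "auto":
        ext = os.path.splitext(os.fspath(path))[1].lower()
        if ext not in _EXTENSIONS:
            raise UnknownFormatError(
                f"cannot infer tractogram format from extension {ext!r}; "
                "expected .tck or .trk"
            )
        return _EXTENSIONS[ext]
    if fmt not in ("tck", "trk"):
        raise UnknownFormatError(f"unsupported tractogram format {fmt!r}")
    return fmt


def _reference_for_points(streamlines: list[Streamline]) -> SpatialReference:
    # TCK carries no grid; synthesize a unit-voxel grid that bounds the data.
    if not streamlines:
        return SpatialReference.isotropic((1, 1, 1))
    all_pts = np.vstack(streamlines)
    hi = np.maximum(np.ceil(all_pts.max(axis=0) + 1.0), 1.0)
    return SpatialReference.isotropic(tuple(int(d) for d in hi))


def read_tractogram(
    path: str | os.PathLike,
    format: str = "auto",
    reference: SpatialReference | None = None,
) -> Tractogram:
    """Read a TCK or TRK file into world RAS mm.

    Points are returned in world RAS mm regardless of on-disk dialect (TRK's
    voxel-mm coordinates are converted using the header transform).  For TCK
    files, which carry no voxel grid, ``reference`` supplies the grid
    context; if omitted, a unit-voxel grid bounding the data is synthesized.

    Raises
    ------
    UnknownFormatError, HeaderError, TruncatedFileError
    """
    fmt = _resolve_format(path, format)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    from nibabel.streamlines.tractogram_file import (
        DataError as _NibDataError,
        HeaderError as _NibHeaderError,
    )

    try:
        f = nib.streamlines.load(os.fspath(path), lazy_load=False)
    except (_NibHeaderError, nib.filebasedimages.ImageFileError, ValueError, KeyError) as exc:
        raise HeaderError(f"could not parse {fmt} header of {path}: {exc}") from exc
    except (_NibDataError, OSError) as exc:
        raise TruncatedFileError(f"truncated or unreadable body in {path}: {exc}") from exc

    expected = {"tck": nib.streamlines.TckFile, "trk": nib.streamlines.TrkFile}[fmt]
    if not isinstance(f, expected):
        raise UnknownFormatError(
            f"{path} is a {type(f).__name__}, not the requested {fmt.upper()} format"
        )

    if reference is None:
        if fmt == "trk":
            hdr = f.header
            reference = SpatialReference.from_affine(
                np.asarray(hdr["voxel_to_rasmm"], dtype=np.float64),
                tuple(int(d) for d in hdr["dimensions"]),
            )
        else:
            reference = None  # filled in below from the data

    streamlines = []
    for arr in f.streamlines:
        streamlines.append(as_streamline(np.asarray(arr, dtype=np.float64)))
    if reference is None:
        reference = _reference_for_points(streamlines)
    return Tractogram(streamlines, reference)


def write_tractogram(
    t: Tractogram, path: str | os.PathLike, format: str = "auto"
) -> None:
    """Write a tractogram as TCK or TRK; ``read_tractogram`` inverts it."""
    fmt = _resolve_format(path, format)
    nib_t = _NibTractogram(
        [np.asarray(s, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if fmt == "trk":
        header = {
            "voxel_to_rasmm": t.reference.affine.astype(np.float32),
            "voxel_sizes": np.asarray(t.reference.voxel_sizes, dtype=np.float32),
            "dimensions": np.asarray(t.reference.dims, dtype=np.int16),
            "voxel_order": "RAS",
        }
        nib.streamlines.save(nib_t, os.fspath(path), header=header)
    else:
        nib.streamlines.save(nib_t, os.fspath(path))


# ---------------------------------------------------------------------------
# Coordinate transforms
# ---------------------------------------------------------------------------

def world_to_grid(points: "np.typing.ArrayLike", ref: SpatialReference) -> np.ndarray:
    """Map world mm point(s) to continuous grid coordinates.

    Voxel ``(i,j,k)`` occupies ``[i,i+1)^3`` in grid coordinates, so
    ``floor(world_to_grid(p))`` is the containing voxel.  With an identity
    affine the world origin (center of voxel 0) maps to ``(0.5, 0.5, 0.5)``.
    """
    p = np.asarray(points, dtype=np.float64)
    if not np.isfinite(p).all():
        raise ValueError("non-finite world coordinates")
    inv = ref.inverse_affine
    g = p @ inv[:3, :3].T + inv[:3, 3]
    return g + 0.5


def grid_to_world(grid_coords: "np.typing.ArrayLike", ref: SpatialReference) -> np.ndarray:
    """Inverse of :func:`world_to_grid`."""
    g = np.asarray(grid_coords, dtype=np.float64) - 0.5
    return g @ ref.affine[:3, :3].T + ref.affine[:3, 3]


def point_to_voxel(points: "np.typing.ArrayLike", ref: SpatialReference) -> np.ndarray:
    """Integer voxel index of world point(s): ``floor(world_to_grid(p))``."""
    return np.floor(world_to_grid(points, ref)).astype(np.int64)


def segment_stats(t: Tractogram) -> SegmentStats:
    """Exact max/mean Euclidean segment length over the whole tractogram."""
    if len(t) == 0:
        raise ValueError("segment_stats requires at least one streamline")
    total = 0.0
    max_len = 0.0
    n = 0
    for s in t:
        lens = np.linalg.norm(np.diff(s, axis=0), axis=1)
        total += float(lens.sum())
        max_len = max(max_len, float(lens.max()))
        n += len(lens)
    return SegmentStats(max_len=max_len, mean_len=total / n, n_segments=n)
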