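"""MET/MLD-constrained streamline linearization (lossy point removal).

Linearization discards (near-)collinear points from a streamline under two
constraints:

* **MET** (maximum error threshold, mm): no discarded point may lie farther
  than this from the infinite line through its two enclosing kept points.
* **MLD** (maximum linearization distance, mm): consecutive kept points may
  be at most this far apart (Euclidean), which bounds the cost of the
  backward-verification step and, downstream, the size of the extended
  neighborhood used by segment-based ROI selection.

The algorithm is a greedy forward scan with backward verification.  From the
last kept point ``a`` it tries to extend the candidate chord one input point
at a time.  Three cases arise for the chord ``a -> next``:

* Case A — every intermediate point is within MET of the chord and ``next``
  is within MLD of ``a``: the candidate advances (intermediate points are
  provisionally discarded).
* Case B — an intermediate point exceeds MET: the previous candidate (the
  last point for which the chord verified) is kept and the scan restarts
  from it.
* Case C — ``next`` is strictly farther than MLD from ``a``: same as B.

Keeping the *previous* candidate (not the violating point) guarantees the
MET error bound by construction: the chord to the kept point is always the
last one that passed full backward verification.

With ``met=0`` only exactly-collinear points are removed (within a 1e-12 mm
tolerance for float noise).  Input steps longer than MLD are never created
by the algorithm and never split: both endpoints of an over-long input step
are kept unchanged, so the MLD output bound holds whenever all input steps
respect it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import Streamline, Tractogram

__all__ = [
    "LinearizationParams",
    "CompressionReport",
    "perpendicular_distance",
    "linearize_streamline",
    "linearize_tractogram",
]

#: Collinearity tolerance used when met == 0 (mm).
_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class LinearizationParams:
    """The two knobs of the compression algorithm.

    Defaults (met 0.2 mm, mld 5 mm) are the configuration appropriate for
    probabilistic-like tractograms at a 0.5 mm step size; pass
    ``mld=float('inf')`` for unconstrained linearization.
    """

    met: float = 0.2
    mld: float = 5.0

    def __post_init__(self) -> None:
        if not (self.met >= 0):
            raise ValueError("met must be >= 0")
        if not (self.mld > 0):
            raise ValueError("mld must be > 0 (use inf for unconstrained)")


@dataclass(frozen=True)
class CompressionReport:
    """Point-count bookkeeping for one linearization run.

    ``point_reduction`` is the fraction of points discarded overall;
    ``per_streamline_ratios`` the same fraction per streamline.
    """

    points_before: int
    points_after: int
    point_reduction: float
    per_streamline_ratios: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.points_after > self.points_before:
            raise ValueError("points_after cannot exceed points_before")

    def to_dict(self) -> dict:
        return {
            "points_before": self.points_before,
            "points_after": self.points_after,
            "point_reduction": self.point_reduction,
            "per_streamline_ratios": list(self.per_streamline_ratios),
        }


def perpendicular_distance(p, a, b) -> float:
    """Distance (mm) from ``p`` to the infinite line through ``a`` and ``b``.

    Cross-product formula; symmetric in ``a``/``b``; zero iff ``p`` is
    collinear with them.  Raises on a degenerate (zero-length) line.
    """
    p = np.asarray(p, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    d = b - a
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("degenerate line: a == b")
    return float(np.linalg.norm(np.cross(p - a, d)) / nd)


def _max_line_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Max distance of ``pts`` (k,3) to the infinite line a->b (vectorized)."""
    d = b - a
    nd = np.linalg.norm(d)
    if nd == 0.0:
        raise ValueError("degenerate line: a == b")
    return float(np.linalg.norm(np.cross(pts - a, d), axis=1).max() / nd)


def _linearize_run(pts: np.ndarray, met: float, mld: float) -> list[int]:
    """Greedy scan over one run whose input steps all respect MLD.

    Returns kept indices into ``pts`` (first and last always kept).
    """
    n = len(pts)
    kept = [0]
    a = 0
    cand = 1
    while cand < n - 1:
        nxt = cand + 1
        # Case C: next candidate strictly beyond MLD from the last kept point.
        if np.linalg.norm(pts[nxt] - pts[a]) > mld:
            kept.append(cand)
            a = cand
            cand = a + 1
            continue
        # Backward verification of every point since the last kept point.
        if _max_line_distance(pts[a + 1 : nxt], pts[a], pts[nxt]) > met:
            kept.append(cand)  # Case B
            a = cand
            cand = a + 1
            continue
        cand = nxt  # Case A
    kept.append(n - 1)
    return kept


def linearize_streamline(s: Streamline, params: LinearizationParams) -> Streamline:
    """Linearize one streamline; output points are a subsequence of the input.

    First and last points are always kept; every discarded point lies within
    MET of the line through its enclosing kept points; consecutive kept
    points are within MLD whenever the input steps are.
    """
    pts = np.asarray(s, dtype=np.float64)
    met = params.met if params.met > 0 else _COLLINEAR_TOL
    mld = params.mld
    step_lens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    # Input steps longer than MLD are kept verbatim: split the polyline at
    # each over-long step, linearize the runs independently and rejoin, so
    # both endpoints of the long step survive unchanged.
    breaks = np.flatnonzero(step_lens > mld)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(pts)]))
    kept: list[int] = []
    for lo, hi in zip(starts, ends):
        if hi - lo == 1:
            kept.append(lo)
            continue
        kept.extend(lo + k for k in _linearize_run(pts[lo:hi], met, mld))
    return pts[np.array(sorted(set(kept)), dtype=np.intp)]


def linearize_tractogram(
    t: Tractogram, params: LinearizationParams = LinearizationParams()
) -> tuple[Tractogram, CompressionReport]:
    """Apply :func:`linearize_streamline` per streamline and report totals."""
    out = [linearize_streamline(s, params) for s in t]
    before = t.total_points
    after = sum(len(s) for s in out)
    ratios = tuple(
        1.0 - len(c) / len(o) for c, o in zip(out, t.streamlines)
    )
    report = CompressionReport(
        points_before=before,
        points_after=after,
        point_reduction=(1.0 - after / before) if before else 0.0,
        per_streamline_ratios=ratios,
    )
    return Tractogram(out, t.reference), report
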