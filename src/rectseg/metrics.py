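"""Segmentation agreement metrics: Dice overlap on regions, Hausdorff and
discrete Fréchet distances on extracted boundary contours, and pseudo-
volumetric per-case aggregation.

Conventions
-----------
* Dice on two empty masks is 1.0 (perfect agreement on absence); exactly one
  empty mask gives 0.0.
* Boundaries are sub-pixel 0.5-level contours in physical mm (or voxel units
  on request); only the largest contour per slice enters the distance
  metrics, matching the largest-connected-component post-processing.
* The Fréchet distance of two closed contours is minimized over a coarse
  grid of cyclic start-point shifts and over traversal orientation; open
  polylines are compared as given.
* Per case, Dice is computed once over the stacked 3D masks while the
  distances are computed per slice and summarized by their median across
  slices where both masks are nonempty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.spatial.distance import directed_hausdorff
from skimage import measure


@dataclass
class Contour:
    """Ordered boundary polyline in physical coordinates (mm)."""

    points: np.ndarray  # (n, 2)
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must have shape (n, 2)")
        if self.closed and len(self.points) < 3:
            raise ValueError("a closed contour needs at least 3 points")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area(self) -> float:
        """Enclosed (shoelace) area; meaningful for closed contours."""
        p = self.points
        x, y = p[:, 0], p[:, 1]
        return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))

    @property
    def perimeter(self) -> float:
        p = self.points
        q = np.vstack([p, p[:1]]) if self.closed else p
        return float(np.sum(np.hypot(*np.diff(q, axis=0).T)))


@dataclass
class MetricRecord:
    """Per-case, per-region agreement: Dice / HD / FD triple."""

    case_id: str
    region: str
    dice: float
    hausdorff: float
    frechet: float
    n_slices_evaluated: int
    comparison: str = ""
    extra: dict = field(default_factory=dict)


def dice(x: np.ndarray, y: np.ndarray) -> float:
    """Dice similarity coefficient 2|X∩Y| / (|X|+|Y|) of two binary masks."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    nx, ny = int(x.sum()), int(y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    return 2.0 * int((x & y).sum()) / (nx + ny)


def extract_boundary(mask: np.ndarray, spacing=(1.0, 1.0)) -> list[Contour]:
    """Sub-pixel 0.5-level boundary contours of a 2D binary mask.

    Contours are returned in physical coordinates (row/col index times
    spacing), ordered by enclosed area descending.  The mask is zero-padded
    before extraction so objects touching the image border still yield
    closed contours.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("extract_boundary expects a 2D mask")
    if not np.any(mask):
        return []
    padded = np.pad(mask.astype(np.float64), 1)
    contours = []
    for pts in measure.find_contours(padded, 0.5):
        closed = bool(np.allclose(pts[0], pts[-1]))
        if closed:
            pts = pts[:-1]
        if len(pts) < 3:
            continue
        pts = (pts - 1.0) * np.asarray(spacing, dtype=np.float64)
        contours.append(Contour(points=pts, closed=closed))
    contours.sort(key=lambda c: c.area, reverse=True)
    return contours


def _as_points(c) -> np.ndarray:
    if isinstance(c, Contour):
        return c.points
    p = np.asarray(c, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("expected a Contour or an (n, 2) point array")
    return p


def hausdorff(a, b) -> float:
    """Symmetric Hausdorff distance between two contours' point sets."""
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("hausdorff requires nonempty contours")
    return max(directed_hausdorff(pa, pb)[0], directed_hausdorff(pb, pa)[0])


@njit(cache=False)
def _dfd_from_matrix(d: np.ndarray) -> float:
    """Discrete Fréchet distance from a pairwise distance matrix (DP)."""
    n, m = d.shape
    dp = np.empty(m)
    dp[0] = d[0, 0]
    for j in range(1, m):
        dp[j] = max(dp[j - 1], d[0, j])
    for i in range(1, n):
        diag = dp[0]
        if d[i, 0] > dp[0]:
            dp[0] = d[i, 0]
        for j in range(1, m):
            tmp = dp[j]
            best = tmp
            if diag < best:
                best = diag
            if dp[j - 1] < best:
                best = dp[j - 1]
            dp[j] = best if best > d[i, j] else d[i, j]
            diag = tmp
    return dp[m - 1]


def frechet(a, b, exact_shifts: bool = False) -> float:
    """Discrete Fréchet distance between two contours.

    For a pair in which the first contour is closed, the distance is
    minimized over cyclic shifts of its start point (every ``max(1, n//64)``-th
    shift, or all shifts when *exact_shifts* is true) and over its traversal
    orientation.  Open polylines are compared in the given order and
    orientation.
    """
    ca = a if isinstance(a, Contour) else None
    pa, pb = _as_points(a), _as_points(b)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("frechet requires nonempty contours")
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    closed = ca.closed if ca is not None else False
    if not closed:
        return float(_dfd_from_matrix(d))
    n = d.shape[0]
    step = 1 if exact_shifts else max(1, n // 64)
    best = np.inf
    for mat in (d, d[::-1]):
        for s in range(0, n, step):
            rolled = np.ascontiguousarray(np.roll(mat, -s, axis=0))
            val = _dfd_from_matrix(rolled)
            if val < best:
                best = val
    return float(best)


def evaluate_case(
    pred: np.ndarray,
    ref: np.ndarray,
    spacing,
    region: str = "",
    case_id: str = "",
    units: str = "mm",
    comparison: str = "",
) -> MetricRecord:
    """Pseudo-volumetric per-case agreement between prediction and reference.

    *pred* and *ref* are binary volumes (rows, cols, slices).  Dice is
    computed over the stacked 3D masks; HD and FD are computed per slice on
    the largest boundary contour of each mask, on slices where both masks
    are nonempty, and summarized by the median.  Slices where exactly one
    mask is empty are excluded from the distance medians but still count in
    the 3D Dice.
    """
    pred = np.asarray(pred).astype(bool)
    ref = np.asarray(ref).astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {ref.shape}")
    if pred.ndim != 3:
        raise ValueError("evaluate_case expects 3D volumes")
    if units == "mm":
        sp2d = (float(spacing[0]), float(spacing[1]))
    elif units == "voxel":
        sp2d = (1.0, 1.0)
    else:
        raise ValueError("units must be 'mm' or 'voxel'")

    d3 = dice(pred, ref)
    hds, fds = [], []
    for z in range(pred.shape[2]):
        p, r = pred[:, :, z], ref[:, :, z]
        if not (p.any() and r.any()):
            continue
        cp = extract_boundary(p, sp2d)
        cr = extract_boundary(r, sp2d)
        if not cp or not cr:
            continue
        hds.append(hausdorff(cp[0], cr[0]))
        fds.append(frechet(cp[0], cr[0]))
    return MetricRecord(
        case_id=case_id,
        region=region,
        dice=float(d3),
        hausdorff=float(np.median(hds)) if hds else float("nan"),
        frechet=float(np.median(fds)) if fds else float("nan"),
        n_slices_evaluated=len(hds),
        comparison=comparison,
    )
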