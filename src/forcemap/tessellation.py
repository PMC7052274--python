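"""Spatial tessellation of the observed region and displacement assignment.

The local likelihood treats drift and diffusivity as constant inside each
spatial bin, so the tessellation sets the spatial resolution of the whole
inference.  Two schemes are provided:

* ``grid_tessellate`` — regular axis-aligned grid with half-open cells; the
  workhorse for simulated data where occupancy is roughly uniform.
* ``count_balanced_tessellate`` — recursive rank bisection of a k-d tree so
  that every leaf holds (nearly) the same number of points, emulating
  experimental pipelines that keep the statistical power per bin constant.

Displacements are attributed to bins by their *start* point: the local
parameters describe the jump law at the position the jump originates from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Bin",
    "Tessellation",
    "BinAssignment",
    "grid_tessellate",
    "count_balanced_tessellate",
    "assign",
]


@dataclass(frozen=True)
class Bin:
    """Axis-aligned rectangular bin [lo, hi) with its centroid."""

    bin_id: int
    centroid: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    occupied: bool = True


@dataclass(frozen=True)
class Tessellation:
    """A disjoint cover of the data bounding box by rectangular bins."""

    bins: list
    kind: str          # "grid" or "count_balanced"
    lo: np.ndarray     # bounding box lower corner
    hi: np.ndarray     # bounding box upper corner
    d: int
    # grid-specific fast lookup
    _h: float | None = None
    _shape: tuple | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def centroids(self) -> np.ndarray:
        return np.asarray([b.centroid for b in self.bins])

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Bin index for each point; −1 for points outside the bounding box.

        Interior cell edges follow the half-open convention (a point on an
        edge belongs to the higher-index cell); the outer upper faces of the
        bounding box are closed so the extremal data points stay inside.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.all((points >= self.lo) & (points <= self.hi), axis=1)
        out = np.full(len(points), -1, dtype=np.int64)
        if not inside.any():
            return out
        pts = points[inside]
        if self.kind == "grid":
            idx = np.floor((pts - self.lo) / self._h).astype(np.int64)
            shape = np.asarray(self._shape)
            idx = np.minimum(idx, shape - 1)  # close the top faces
            flat = np.ravel_multi_index(tuple(idx.T), self._shape)
            out[np.flatnonzero(inside)] = flat
        else:
            ids = np.zeros(len(pts), dtype=np.int64)
            for b in self.bins:
                in_bin = np.all(pts >= b.lo, axis=1)
                for k in range(self.d):
                    top = np.isclose(b.hi[k], self.hi[k])
                    if top:
                        in_bin &= pts[:, k] <= b.hi[k]
                    else:
                        in_bin &= pts[:, k] < b.hi[k]
                ids[in_bin] = b.bin_id
            out[np.flatnonzero(inside)] = ids
        return out


@dataclass(frozen=True)
class BinAssignment:
    """Displacement indices grouped by bin (start-point rule)."""

    bin_of: np.ndarray              # per-displacement bin index, −1 = outside
    n_bins: int
    indices: dict = field(default_factory=dict)  # bin -> array of indices

    @property
    def n_assigned(self) -> int:
        return int(np.sum(self.bin_of >= 0))

    @property
    def n_outside(self) -> int:
        return int(np.sum(self.bin_of < 0))

    def counts(self) -> np.ndarray:
        c = np.zeros(self.n_bins, dtype=np.int64)
        inside = self.bin_of[self.bin_of >= 0]
        np.add.at(c, inside, 1)
        return c


def grid_tessellate(points: np.ndarray, bin_size: float) -> Tessellation:
    """Regular grid over the bounding box of ``points`` with pitch ``bin_size``.

    Cells are half-open [x0, x0+h); empty cells are retained but flagged
    ``occupied=False`` so downstream maps can show "no data".
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("at least one point is required")
    d = points.shape[1]
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    shape = tuple(max(1, int(np.ceil((hi[k] - lo[k]) / bin_size)) or 1)
                  for k in range(d))
    # degenerate axes (all points equal) get a single cell of width bin_size
    hi_cover = lo + np.asarray(shape) * bin_size
    tess = Tessellation(bins=[], kind="grid", lo=lo, hi=np.maximum(hi, lo),
                        d=d, _h=float(bin_size), _shape=shape)
    occupancy = np.zeros(int(np.prod(shape)), dtype=np.int64)
    np.add.at(occupancy, tess.locate(points), 1)
    bins = []
    for flat in range(int(np.prod(shape))):
        idx = np.unravel_index(flat, shape)
        blo = lo + np.asarray(idx) * bin_size
        bhi = np.minimum(blo + bin_size, hi_cover)
        bins.append(Bin(bin_id=flat, centroid=(blo + bhi) / 2.0, lo=blo,
                        hi=bhi, occupied=bool(occupancy[flat] > 0)))
    tess.bins.extend(bins)
    return tess


def count_balanced_tessellate(points: np.ndarray, target_n: int,
                              tolerance: int = 0) -> Tessellation:
    """k-d rank bisection giving every leaf ≈ ``target_n`` points.

    A node holding N points is meant to become k = round(N/target_n) leaves;
    it is split at rank N·⌊k/2⌋/k along the alternating axis and both halves
    recurse.  Every final leaf then holds ⌊N/k⌋ or ⌈N/k⌉ points, which stays
    inside [target_n − tolerance, target_n + tolerance] whenever the total
    count allows it.  Deterministic given the points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_pts, d = points.shape
    if target_n < 4:
        raise ValueError("target_n must be at least 4")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if n_pts < target_n:
        raise ValueError(
            f"cannot balance {n_pts} points into bins of ~{target_n}")
    lo = points.min(axis=0)
    hi = points.max(axis=0)
    leaves: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    def split(idx: np.ndarray, blo: np.ndarray, bhi: np.ndarray,
              axis: int) -> None:
        n = len(idx)
        k = int(round(n / target_n))
        if k <= 1 or n <= target_n + tolerance:
            leaves.append((idx, blo, bhi))
            return
        k_left = k // 2
        rank = int(round(n * k_left / k))
        order = idx[np.argsort(points[idx, axis], kind="stable")]
        cut = 0.5 * (points[order[rank - 1], axis] + points[order[rank], axis])
        left_hi = bhi.copy()
        left_hi[axis] = cut
        right_lo = blo.copy()
        right_lo[axis] = cut
        nxt = (axis + 1) % d
        split(order[:rank], blo, left_hi, nxt)
        split(order[rank:], right_lo, bhi, nxt)

    split(np.arange(n_pts), lo.copy(), hi.copy(), 0)
    bins = []
    for bin_id, (idx, blo, bhi) in enumerate(leaves):
        centroid = points[idx].mean(axis=0)
        bins.append(Bin(bin_id=bin_id, centroid=centroid, lo=blo, hi=bhi,
                        occupied=len(idx) > 0))
    return Tessellation(bins=bins, kind="count_balanced", lo=lo, hi=hi, d=d)


def assign(ds, tess: Tessellation) -> BinAssignment:
    """Assign each displacement to the bin containing its start point."""
    if len(ds) == 0:
        return BinAssignment(bin_of=np.empty(0, dtype=np.int64),
                             n_bins=tess.n_bins)
    bin_of = tess.locate(ds.start)
    if not (bin_of >= 0).any():
        warnings.warn("no displacement start falls inside the tessellated box",
                      stacklevel=2)
    indices = {int(b): np.flatnonzero(bin_of == b)
               for b in np.unique(bin_of[bin_of >= 0])}
    return BinAssignment(bin_of=bin_of, n_bins=tess.n_bins, indices=indices)
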