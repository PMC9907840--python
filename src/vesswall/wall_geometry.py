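"""Radial/tangential parameterization of an annular vessel wall.

Every wall pixel receives a normalized depth (0 at the lumen-facing inner
boundary, 1 at the outer boundary), a depth bin (default 100 bins of equal
depth width), an angular sector (default 20), and — via the layer partition —
one of the three arterial layers (tunica intima, media, adventitia), which
are assumed to be of equal width across the wall.

Two depth parameterizations are provided. The canonical ``distance`` method
uses the ratio of Euclidean distance transforms to the lumen and to the
exterior, which is well defined for irregular, non-convex walls. The
``spokes`` method casts rays from the lumen centroid and normalizes each
pixel's radius between the ray's inner and outer wall crossings; it matches
the ray-based construction used in classical radial profiling but degrades
on strongly concave contours.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "TopologyError",
    "LayerPartition",
    "DepthBinMap",
    "WallGeometry",
    "extract_wall_boundaries",
    "compute_depth",
    "assign_depth_bins",
    "assign_sectors",
    "layer_of_bin",
    "build_geometry",
    "LAYERS",
]

LAYERS = ("intima", "media", "adventitia")


class TopologyError(ValueError):
    """Wall mask is not a single annulus with exactly one hole."""


@dataclass(frozen=True)
class LayerPartition:
    """Contiguous inner->outer grouping of depth bins into the three layers.

    Defaults follow the equal-thirds convention for 100 bins: intima covers
    bins [0, 33), media [33, 66), adventitia [66, n_bins). With 100 bins the
    leftover bin goes to the adventitia (33/33/34).
    """

    n_bins: int = 100
    boundaries: tuple[int, int] = (33, 66)

    def __post_init__(self) -> None:
        lo, hi = self.boundaries
        if not (0 < lo < hi < self.n_bins):
            raise ValueError(f"boundaries {self.boundaries} invalid for n_bins={self.n_bins}")

    @classmethod
    def equal_thirds(cls, n_bins: int = 100) -> "LayerPartition":
        return cls(n_bins=n_bins, boundaries=(n_bins // 3, 2 * n_bins // 3))

    def bin_slices(self) -> dict[str, slice]:
        lo, hi = self.boundaries
        return {
            "intima": slice(0, lo),
            "media": slice(lo, hi),
            "adventitia": slice(hi, self.n_bins),
        }

    def layer_index_of_bins(self) -> np.ndarray:
        """Integer layer index (0/1/2) per bin index."""
        lo, hi = self.boundaries
        idx = np.zeros(self.n_bins, dtype=int)
        idx[lo:hi] = 1
        idx[hi:] = 2
        return idx


def layer_of_bin(bin_index: int, partition: LayerPartition | None = None) -> str:
    """Layer name for one depth bin under a partition."""
    partition = partition or LayerPartition()
    if not 0 <= bin_index < partition.n_bins:
        raise IndexError(f"bin {bin_index} out of range [0, {partition.n_bins})")
    lo, hi = partition.boundaries
    if bin_index < lo:
        return "intima"
    if bin_index < hi:
        return "media"
    return "adventitia"


@dataclass
class DepthBinMap:
    """Integer bin label per wall pixel (-1 off the wall)."""

    bins: np.ndarray
    n_bins: int
    wall: np.ndarray

    def counts(self) -> np.ndarray:
        """Wall-pixel count per bin."""
        return np.bincount(self.bins[self.wall], minlength=self.n_bins)


@dataclass
class WallGeometry:
    wall: np.ndarray
    inner_boundary: np.ndarray  # (N, 2) row/col contour
    outer_boundary: np.ndarray
    lumen_centroid: tuple[float, float]
    depth: np.ndarray  # NaN off the wall
    sector: np.ndarray | None = None  # -1 off the wall
    n_sectors: int = 0
    failed_spokes: int = 0
    depth_method: str = "distance"
    bin_map: DepthBinMap | None = None
    partition: LayerPartition = field(default_factory=LayerPartition)


def _wall_regions(wall: np.ndarray):
    """Split the raster into wall / lumen hole / exterior, validating topology."""
    wall = np.asarray(wall).astype(bool)
    n_comp = ndimage.label(wall)[1]
    if n_comp != 1:
        raise TopologyError(f"wall mask has {n_comp} connected components (expected 1)")
    filled = ndimage.binary_fill_holes(wall)
    holes = filled & ~wall
    n_holes = ndimage.label(holes)[1]
    if n_holes != 1:
        kind = "no interior hole (solid region)" if n_holes == 0 else f"{n_holes} interior holes"
        raise TopologyError(f"wall mask has {kind} (expected exactly 1)")
    return wall, holes, ~filled


def extract_wall_boundaries(wall: np.ndarray):
    """Inner/outer closed contours and the lumen centroid of an annular mask.

    Returns ``(inner_contour, outer_contour, lumen_centroid)`` where contours
    are (N, 2) arrays of (row, col) vertices from marching squares and the
    centroid is the mean coordinate of the lumen (hole) pixels.
    """
    wall, holes, _ = _wall_regions(wall)
    filled = wall | holes
    outer = max(measure.find_contours(filled.astype(float), 0.5), key=len)
    inner = max(measure.find_contours(holes.astype(float), 0.5), key=len)
    rows, cols = np.nonzero(holes)
    centroid = (float(rows.mean()), float(cols.mean()))
    return inner, outer, centroid


def _depth_by_distance(wall: np.ndarray, holes: np.ndarray, exterior: np.ndarray) -> np.ndarray:
    d_in = ndimage.distance_transform_edt(~holes)
    d_out = ndimage.distance_transform_edt(~exterior)
    depth = np.full(wall.shape, np.nan)
    w = wall
    depth[w] = d_in[w] / (d_in[w] + d_out[w])
    return depth


def _depth_by_spokes(
    wall: np.ndarray, centroid: tuple[float, float], n_spokes: int
) -> tuple[np.ndarray, int]:
    cr, cc = centroid
    rows, cols = np.nonzero(wall)
    radius = np.hypot(rows - cr, cols - cc)
    r_max = radius.max() + 2.0

    angles = np.arange(n_spokes) * (2 * np.pi / n_spokes)
    # March each ray at half-pixel steps; record first/last wall crossing.
    steps = np.arange(0.5, r_max, 0.5)
    r_inner = np.full(n_spokes, np.nan)
    r_outer = np.full(n_spokes, np.nan)
    h, w_ = wall.shape
    for k, th in enumerate(angles):
        rr = cr - np.sin(th) * steps  # image rows grow downward; -sin keeps CCW angles
        ccs = cc + np.cos(th) * steps
        ok = (rr >= 0) & (rr < h) & (ccs >= 0) & (ccs < w_)
        hits = np.zeros(steps.shape, bool)
        hits[ok] = wall[rr[ok].round().astype(int), ccs[ok].round().astype(int)]
        idx = np.nonzero(hits)[0]
        if idx.size >= 2:
            r_inner[k] = steps[idx[0]]
            r_outer[k] = steps[idx[-1]]
    failed = int(np.isnan(r_inner).sum())
    if failed:
        warnings.warn(f"{failed}/{n_spokes} spokes failed to cross the wall", stacklevel=3)
        if failed > 0.1 * n_spokes:
            raise ValueError(
                f"{failed}/{n_spokes} spokes failed to intersect both boundaries; "
                "wall too irregular for the spokes method"
            )

    valid = ~np.isnan(r_inner)
    theta = np.mod(np.arctan2(-(rows - cr), cols - cc), 2 * np.pi)
    # Nearest spoke by angle; fall back to nearest valid spoke if its ray failed.
    nearest = np.mod(np.round(theta / (2 * np.pi / n_spokes)).astype(int), n_spokes)
    if failed:
        valid_idx = np.nonzero(valid)[0]
        ang_diff = np.abs(
            np.angle(np.exp(1j * (theta[:, None] - angles[valid_idx][None, :])))
        )
        nearest = valid_idx[np.argmin(ang_diff, axis=1)]
    span = r_outer[nearest] - r_inner[nearest]
    span[span <= 0] = np.nan
    d = (radius - r_inner[nearest]) / span
    depth = np.full(wall.shape, np.nan)
    depth[rows, cols] = np.clip(d, 0.0, 1.0)
    # Isolated pixels on degenerate spokes: clamp via wall mean to stay finite.
    bad = wall & np.isnan(depth)
    if bad.any():
        depth[bad] = np.nanmean(depth[wall])
    return depth, failed


def compute_depth(
    wall: np.ndarray,
    method: str = "distance",
    n_spokes: int = 360,
) -> tuple[np.ndarray, int]:
    """Normalized wall depth in [0, 1] for every wall pixel.

    Returns ``(depth, failed_spokes)``; ``failed_spokes`` is 0 for the
    distance method.
    """
    wall, holes, exterior = _wall_regions(wall)
    if method == "distance":
        return _depth_by_distance(wall, holes, exterior), 0
    if method == "spokes":
        rows, cols = np.nonzero(holes)
        centroid = (float(rows.mean()), float(cols.mean()))
        return _depth_by_spokes(wall, centroid, n_spokes)
    raise ValueError(f"unknown depth method {method!r}")


def assign_depth_bins(depth: np.ndarray, n_bins: int = 100) -> DepthBinMap:
    """Bin depths into ``floor(depth * n_bins)``, last bin right-closed."""
    if n_bins < 3:
        raise ValueError(f"n_bins must be >= 3, got {n_bins}")
    depth = np.asarray(depth, dtype=float)
    wall = np.isfinite(depth)
    bins = np.full(depth.shape, -1, dtype=np.int32)
    bins[wall] = np.clip((depth[wall] * n_bins).astype(int), 0, n_bins - 1)
    return DepthBinMap(bins=bins, n_bins=n_bins, wall=wall)


def assign_sectors(
    wall: np.ndarray, lumen_centroid: tuple[float, float], n_sectors: int = 20
) -> np.ndarray:
    """Angular sector label per wall pixel (-1 elsewhere).

    Angles are measured counter-clockwise from the +x (east) axis about the
    lumen centroid; sector 0 starts due east.
    """
    wall = np.asarray(wall).astype(bool)
    cr, cc = lumen_centroid
    r, c = int(round(cr)), int(round(cc))
    in_bounds = 0 <= r < wall.shape[0] and 0 <= c < wall.shape[1]
    if not in_bounds or wall[r, c]:
        raise ValueError("lumen centroid does not fall in the lumen interior")
    rows, cols = np.nonzero(wall)
    theta = np.mod(np.arctan2(-(rows - cr), cols - cc), 2 * np.pi)
    sector = np.full(wall.shape, -1, dtype=np.int32)
    sector[rows, cols] = np.minimum(
        (theta * n_sectors / (2 * np.pi)).astype(int), n_sectors - 1
    )
    return sector


def build_geometry(
    wall: np.ndarray,
    depth_method: str = "distance",
    n_bins: int = 100,
    n_sectors: int = 20,
    n_spokes: int = 360,
    partition: LayerPartition | None = None,
) -> WallGeometry:
    """Full wall parameterization: boundaries, depth, bins and sectors."""
    inner, outer, centroid = extract_wall_boundaries(wall)
    depth, failed = compute_depth(wall, method=depth_method, n_spokes=n_spokes)
    bin_map = assign_depth_bins(depth, n_bins=n_bins)
    sector = assign_sectors(wall, centroid, n_sectors=n_sectors)
    return WallGeometry(
        wall=np.asarray(wall).astype(bool),
        inner_boundary=inner,
        outer_boundary=outer,
        lumen_centroid=centroid,
        depth=depth,
        sector=sector,
        n_sectors=n_sectors,
        failed_spokes=failed,
        depth_method=depth_method,
        bin_map=bin_map,
        partition=partition or LayerPartition.equal_thirds(n_bins),
    )
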