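"""Delaunay-Rayleigh threshold binarization (DRTB).

The segmentation criterion is spatial, not chromatic: stomatal centers on a
leaf are spread with the statistics of a regular point process, so the
Delaunay edge lengths of correctly segmented centroids follow a
Rayleigh-like frequency distribution. The algorithm scans every candidate
binarization level ``l``, extracts region centroids at each level, and
keeps the level whose Delaunay edge-length histogram is closest (RMSD) to
the best-fitting Rayleigh distribution:

    l_hat = argmin_l min_sigma RMSD(sigma, l)

Pipeline per level: binarize -> label connected components -> discard
area outliers by median absolute deviation -> centroids (first-order
moments) -> Delaunay triangulation -> edge-length histogram -> Rayleigh
fit. Levels yielding fewer than three usable (non-collinear) centroids are
marked invalid (RMSD = +inf) rather than raising mid-scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import Delaunay as _SciDelaunay, QhullError

__all__ = [
    "MADFilterParams", "RegionSet", "Tessellation", "DistanceHistogram",
    "FitResult", "ScanConfig", "SegmentationResult",
    "DegenerateGeometryError", "NoTessellationError",
    "binarize", "label_regions", "mad_filter", "centroids", "delaunay",
    "edge_distances", "distance_histogram", "rayleigh_pdf",
    "rayleigh_bin_mass", "rmsd", "fit_sigma", "scan_levels",
    "optimal_level", "segment", "segment_at_level",
]


class DegenerateGeometryError(ValueError):
    """Fewer than 3 points, or all points collinear: no triangulation exists."""


class NoTessellationError(RuntimeError):
    """Every scanned binarization level failed to produce a triangulation."""


@dataclass(frozen=True)
class MADFilterParams:
    """Robust area-outlier rejection: region i is kept iff
    ``|r_i - median(r)| / MAD < cutoff`` with
    ``MAD = b * median(|r - median(r)|)``.

    b : normality constant, 1.4826 (makes MAD consistent for a Gaussian).
    cutoff : rejection threshold in MAD units, default 3.
    """

    b: float = 1.4826
    cutoff: float = 3.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.cutoff <= 0:
            raise ValueError("b and cutoff must be > 0")


@dataclass
class RegionSet:
    """Labeled connected components of a binary mask.

    labels : 2-D int array, 0 = background, regions numbered 1..n_regions.
    areas : pixel count per region (index i -> label i+1).
    inlier : boolean flag per region (area filters write here).
    """

    labels: np.ndarray
    areas: np.ndarray
    inlier: np.ndarray

    @property
    def n_regions(self) -> int:
        return int(self.areas.size)

    @property
    def inlier_labels(self) -> np.ndarray:
        return np.flatnonzero(self.inlier) + 1


@dataclass
class Tessellation:
    """Delaunay triangulation of centroid points.

    points : (k, 2) array of (x, y) vertices.
    triangles : (n, 3) vertex-index triples.
    distances : length-3n vector of per-triangle edge lengths (shared edges
        contribute once per triangle).
    """

    points: np.ndarray
    triangles: np.ndarray
    distances: np.ndarray

    @property
    def n_triangles(self) -> int:
        return int(self.triangles.shape[0])


@dataclass
class DistanceHistogram:
    """Empirical occurrence probabilities of Delaunay edge lengths."""

    bin_edges: np.ndarray
    probs: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class FitResult:
    """Outcome of one binarization level: fitted Rayleigh sigma and RMSD."""

    level: float
    sigma: float
    rmsd: float
    n_regions: int
    n_triangles: int

    @property
    def valid(self) -> bool:
        return np.isfinite(self.rmsd)


def _default_levels() -> np.ndarray:
    return np.round(np.arange(0.01, 1.00, 0.01), 2)


def _default_sigma_grid() -> np.ndarray:
    return np.round(np.arange(0.5, 150.0 + 1e-9, 0.5), 2)


@dataclass
class ScanConfig:
    """Configuration of the threshold scan.

    levels : binarization levels to traverse (unit interval, exclusive ends).
    sigma_grid : Rayleigh sigma candidates, pixels.
    bin_width : edge-length histogram bin width, pixels.
    connectivity : 4 or 8, for connected-component labeling.
    mad : area-outlier filter parameters.
    min_area : speckle guard; regions below this pixel area are discarded
        before the MAD filter.
    invert : scan 1 - F instead of F (dark-object images).
    drop_border : discard regions touching the image border.
    unique_edges : count each shared Delaunay edge once instead of once per
        triangle (sensitivity analysis).
    """

    levels: np.ndarray = field(default_factory=_default_levels)
    sigma_grid: np.ndarray = field(default_factory=_default_sigma_grid)
    bin_width: float = 1.0
    connectivity: int = 8
    mad: MADFilterParams = field(default_factory=MADFilterParams)
    min_area: int = 4
    invert: bool = False
    drop_border: bool = False
    unique_edges: bool = False

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.float64)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=np.float64)
        if self.levels.size == 0 or np.any((self.levels <= 0) | (self.levels >= 1)):
            raise ValueError("levels must be a nonempty grid inside (0, 1)")
        if self.sigma_grid.size == 0 or np.any(self.sigma_grid <= 0):
            raise ValueError("sigma_grid must be nonempty and positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass
class SegmentationResult:
    """Final segmentation at the optimal level."""

    best: FitResult
    scan: list
    mask: np.ndarray
    regions: RegionSet
    centroids: np.ndarray
    tessellation: Tessellation


# ---------------------------------------------------------------------------
# elementary operations


def binarize(f: np.ndarray, level: float) -> np.ndarray:
    """Threshold operator: 1 where ``f > level`` (strict), else 0."""
    f = np.asarray(f, dtype=np.float64)
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    return (f > level).astype(np.uint8)


def label_regions(mask: np.ndarray, connectivity: int = 8) -> RegionSet:
    """Label maximal connected components of the foreground."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(np.asarray(mask) != 0, structure=structure)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    return RegionSet(labels=labels, areas=areas,
                     inlier=np.ones(n, dtype=bool))


def mad_filter(areas: np.ndarray,
               params: MADFilterParams = MADFilterParams()) -> np.ndarray:
    """Boolean inlier flags for region areas under the MAD criterion.

    Degenerate rule: when MAD is zero (all areas equal, or a single region)
    every region is an inlier — identical areas carry no outlier evidence.
    """
    areas = np.asarray(areas, dtype=np.float64)
    if areas.size == 0:
        raise ValueError("empty area vector")
    med = np.median(areas)
    mad = params.b * np.median(np.abs(areas - med))
    if mad == 0:
        return np.ones(areas.size, dtype=bool)
    return np.abs(areas - med) / mad < params.cutoff


def centroids(regions: RegionSet) -> np.ndarray:
    """Sub-pixel mass centers of the inlier regions, as (x, y) with x = column
    and y = row (origin top-left, 0-based), via first-order moments."""
    labels = regions.labels
    n = regions.n_regions
    if n == 0 or not regions.inlier.any():
        return np.empty((0, 2), dtype=np.float64)
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    m00 = np.bincount(lab, minlength=n + 1)[1:].astype(np.float64)
    m10 = np.bincount(lab, weights=xs, minlength=n + 1)[1:]
    m01 = np.bincount(lab, weights=ys, minlength=n + 1)[1:]
    keep = regions.inlier
    return np.column_stack((m10[keep] / m00[keep], m01[keep] / m00[keep]))


def delaunay(points: np.ndarray) -> Tessellation:
    """Delaunay triangulation of (x, y) points: no vertex falls strictly
    inside any triangle's circumcircle. Raises DegenerateGeometryError for
    fewer than 3 points or a collinear set."""
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise DegenerateGeometryError(
            "need at least 3 two-dimensional points")
    try:
        tri = _SciDelaunay(points)
    except QhullError as exc:
        raise DegenerateGeometryError(str(exc)) from exc
    if tri.simplices.shape[0] == 0:
        raise DegenerateGeometryError("triangulation is empty")
    tess = Tessellation(points=points, triangles=tri.simplices.copy(),
                        distances=np.empty(0))
    tess.distances = edge_distances(tess)
    return tess


def edge_distances(tess: Tessellation, unique_edges: bool = False) -> np.ndarray:
    """Euclidean edge lengths, three per triangle in the order
    (v1,v2), (v2,v3), (v1,v3); shared edges contribute once per triangle
    (length 3n), or once in total with ``unique_edges``."""
    if tess.n_triangles == 0:
        raise ValueError("empty tessellation")
    t = tess.triangles
    if unique_edges:
        pairs = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        pairs = np.unique(np.sort(pairs, axis=1), axis=0)
        diffs = tess.points[pairs[:, 0]] - tess.points[pairs[:, 1]]
        return np.hypot(diffs[:, 0], diffs[:, 1])
    p = tess.points
    d12 = np.linalg.norm(p[t[:, 0]] - p[t[:, 1]], axis=1)
    d23 = np.linalg.norm(p[t[:, 1]] - p[t[:, 2]], axis=1)
    d13 = np.linalg.norm(p[t[:, 0]] - p[t[:, 2]], axis=1)
    return np.column_stack((d12, d23, d13)).ravel()


def distance_histogram(d: np.ndarray, bin_width: float = 1.0) -> DistanceHistogram:
    """Normalized occurrence frequencies of the edge lengths, on bins of the
    given width covering [0, max(d) + bin_width)."""
    d = np.asarray(d, dtype=np.float64)
    if d.size == 0:
        raise ValueError("empty distance vector")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = int(np.floor(d.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1, dtype=np.float64) * bin_width
    counts, _ = np.histogram(d, bins=edges)
    return DistanceHistogram(bin_edges=edges, probs=counts / counts.sum())


def rayleigh_pdf(x, sigma: float):
    """Rayleigh density ``(x / sigma^2) exp(-x^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    out = (x / sigma**2) * np.exp(-(x**2) / (2 * sigma**2))
    return out if out.ndim else float(out)


def rayleigh_bin_mass(bin_edges: np.ndarray, sigma) -> np.ndarray:
    """Rayleigh probability mass per histogram bin (CDF differences);
    ``sigma`` may be a scalar or a vector (one row of masses per sigma)."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    scalar = sigma.ndim == 0
    s = np.atleast_1d(sigma)[:, None]
    cdf = 1.0 - np.exp(-(edges[None, :] ** 2) / (2.0 * s**2))
    mass = np.diff(cdf, axis=1)
    return mass[0] if scalar else mass


def rmsd(hist: DistanceHistogram, sigma: float) -> float:
    """Root-mean-square deviation between the empirical frequencies and the
    binned Rayleigh mass at the given sigma; both operands are probability
    masses, averaged over the histogram's bins."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    mass = rayleigh_bin_mass(hist.bin_edges, sigma)
    return float(np.sqrt(np.mean((mass - hist.probs) ** 2)))


def fit_sigma(hist: DistanceHistogram,
              sigma_grid: Sequence[float]) -> tuple[float, float]:
    """Grid-search the Rayleigh sigma minimizing the RMSD to the histogram.
    Ties break toward the smaller sigma. Returns (sigma_hat, rmsd_min)."""
    grid = np.asarray(sigma_grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty sigma grid")
    if np.any(grid <= 0):
        raise ValueError("sigma grid must be positive")
    mass = rayleigh_bin_mass(hist.bin_edges, grid)
    errs = np.sqrt(np.mean((mass - hist.probs[None, :]) ** 2, axis=1))
    i = int(np.argmin(errs))  # first minimum = smallest sigma on sorted grid
    return float(grid[i]), float(errs[i])


# ---------------------------------------------------------------------------
# level scan


def _filter_regions(regions: RegionSet, config: ScanConfig) -> RegionSet:
    """Apply the speckle floor, optional border rejection, and MAD filter."""
    inlier = regions.areas >= config.min_area
    if config.drop_border:
        lab = regions.labels
        border = np.unique(np.concatenate(
            [lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
        border = border[border > 0]
        inlier[border - 1] = False
    if inlier.any():
        flags = mad_filter(regions.areas[inlier], config.mad)
        final = np.zeros_like(inlier)
        final[np.flatnonzero(inlier)] = flags
        inlier = final
    regions.inlier = inlier
    return regions


def _evaluate_level(f: np.ndarray, level: float,
                    config: ScanConfig) -> tuple[FitResult, np.ndarray | None]:
    mask = binarize(f, level)
    regions = _filter_regions(label_regions(mask, config.connectivity), config)
    pts = centroids(regions)
    n_inlier = int(regions.inlier.sum())
    if pts.shape[0] < 3:
        return FitResult(level, np.nan, np.inf, n_inlier, 0), None
    try:
        tess = delaunay(pts)
    except DegenerateGeometryError:
        return FitResult(level, np.nan, np.inf, n_inlier, 0), None
    d = tess.distances if not config.unique_edges else edge_distances(
        tess, unique_edges=True)
    hist = distance_histogram(d, config.bin_width)
    sigma_hat, err = fit_sigma(hist, config.sigma_grid)
    return (FitResult(level, sigma_hat, err, n_inlier, tess.n_triangles),
            pts)


def scan_levels(f: np.ndarray, config: ScanConfig = None,
                progress=None) -> list:
    """Traverse the binarization level grid and fit a Rayleigh distribution
    to the Delaunay edge-length frequencies at each level.

    Returns one FitResult per level (invalid levels carry rmsd = +inf).
    Raises NoTessellationError if no level yields a triangulation.
    ``progress`` is an optional callback ``(FitResult) -> None``.
    """
    if config is None:
        config = ScanConfig()
    f = np.asarray(f, dtype=np.float64)
    if config.invert:
        f = 1.0 - f
    results = []
    for level in config.levels:
        fit, _ = _evaluate_level(f, float(level), config)
        results.append(fit)
        if progress is not None:
            progress(fit)
    if not any(r.valid for r in results):
        raise NoTessellationError(
            "no valid tessellation at any binarization level: every level "
            "produced fewer than 3 usable centroids (image may be constant "
            "or lack separable regions)")
    return results


def optimal_level(scan: Sequence[FitResult]) -> FitResult:
    """The FitResult with minimum RMSD; ties break toward the smaller level."""
    valid = [r for r in scan if r.valid]
    if not valid:
        raise NoTessellationError("no valid level in scan")
    return min(valid, key=lambda r: (r.rmsd, r.level))


def segment_at_level(f: np.ndarray, level: float,
                     config: ScanConfig = None) -> tuple[np.ndarray, RegionSet,
                                                         np.ndarray, Tessellation]:
    """Materialize the segmentation at one level: binary mask, filtered
    regions, centroids and tessellation."""
    if config is None:
        config = ScanConfig()
    f = np.asarray(f, dtype=np.float64)
    if config.invert:
        f = 1.0 - f
    mask = binarize(f, level)
    regions = _filter_regions(label_regions(mask, config.connectivity), config)
    pts = centroids(regions)
    tess = delaunay(pts)
    return mask, regions, pts, tess


def segment(f: np.ndarray, config: ScanConfig = None,
            progress=None) -> SegmentationResult:
    """Full DRTB run: scan all levels, pick the RMSD-minimizing one, and
    return the final segmentation at that level."""
    if config is None:
        config = ScanConfig()
    scan = scan_levels(f, config, progress=progress)
    best = optimal_level(scan)
    mask, regions, pts, tess = segment_at_level(f, best.level, config)
    return SegmentationResult(best=best, scan=scan, mask=mask,
                              regions=regions, centroids=pts,
                              tessellation=tess)
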