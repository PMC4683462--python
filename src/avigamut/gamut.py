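"""Colour-gamut metrics: convex-hull volume/overlap and chromatic loci.

Two complementary measures of occupied colour space.  The convex hull is
the total enclosed volume (sensitive to outliers, mostly empty space); the
chromatic-locus grid partitions the space into 0.022-edge cubic cells and
counts occupied cells, plus the number of patches per cell as an abundance
index.

The grid is anchored at the achromatic origin with half-open [lo, hi)
cells; direct 3D flooring is used, which is identical to intersecting two
2D grids on the yz and yx planes because the planes share the y axis and
the cell edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .visual import TETRA_VOLUME

#: edge length of a chromatic-locus cell (tetra-space units)
DEFAULT_CELL_SIZE = 0.022


def _as_points(points) -> np.ndarray:
    """Accept an (n, 3) array or a DataFrame with x, y, z columns."""
    if isinstance(points, pd.DataFrame):
        return points[["x", "y", "z"]].to_numpy(float)
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts.reshape(1, 3)
    return pts


@dataclass
class HullResult:
    volume: float
    n_vertices: int
    degenerate: bool


@dataclass
class OverlapResult:
    intersection_volume: float
    frac_of_a: float
    frac_of_b: float
    method: str
    mc_se: float | None = None


@dataclass
class LocusMap:
    """Occupied chromatic loci: integer cell index -> member count.

    ``cells`` maps (ix, iy, iz) to the list of member row indices of the
    input; counts follow from the list lengths.
    """

    cell_size: float = DEFAULT_CELL_SIZE
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    cells: dict[tuple[int, int, int], list[int]] = field(default_factory=dict)

    @property
    def n_occupied(self) -> int:
        return len(self.cells)

    @property
    def n_points(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def counts(self) -> dict[tuple[int, int, int], int]:
        return {k: len(v) for k, v in self.cells.items()}


def hull_volume(points) -> HullResult:
    """3D convex-hull volume; degenerate input gives volume 0, not an error.

    Fewer than four points, or points that are coplanar/collinear, span no
    volume: flagged ``degenerate``.
    """
    pts = _as_points(points)
    if pts.shape[0] < 4:
        return HullResult(0.0, pts.shape[0], True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return HullResult(0.0, pts.shape[0], True)
    return HullResult(float(hull.volume), len(hull.vertices), False)


def _interior_point(equations: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Chebyshev centre of the polytope {x : Ax + b <= 0}.

    Returns (point, radius); radius <= 0 means the interior is empty.
    """
    A = equations[:, :3]
    b = -equations[:, 3]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    res = linprog(
        c=[0.0, 0.0, 0.0, -1.0],
        A_ub=np.hstack([A, norms]),
        b_ub=b,
        bounds=[(None, None)] * 3 + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[3] <= 0:
        return None, 0.0
    return res.x[:3], float(res.x[3])


def hull_overlap(a, b, method: str = "exact", n_samples: int = 100_000,
                 rng=None) -> OverlapResult:
    """Volume of the intersection of the convex hulls of two point sets.

    Exact method: stack the facet inequalities of both hulls, find an
    interior point of their intersection (Chebyshev-centre linear program)
    and take the convex hull of the half-space intersection vertices.
    Monte-Carlo method: rejection sampling in the bounding box of the
    smaller hull; ``mc_se`` is the binomial standard error of the estimate.

    Degenerate hulls, or an empty intersection, give zero overlap.
    """
    ra, rb = hull_volume(a), hull_volume(b)
    if ra.degenerate or rb.degenerate:
        return OverlapResult(0.0, 0.0, 0.0, method)
    pa, pb = _as_points(a), _as_points(b)
    hull_a, hull_b = ConvexHull(pa), ConvexHull(pb)

    if method == "exact":
        eqs = np.vstack([hull_a.equations, hull_b.equations])
        centre, radius = _interior_point(eqs)
        if centre is None or radius < 1e-12:
            return OverlapResult(0.0, 0.0, 0.0, "exact")
        try:
            hs = HalfspaceIntersection(eqs, centre)
            inter_vol = float(ConvexHull(hs.intersections).volume)
        except QhullError:
            return OverlapResult(0.0, 0.0, 0.0, "exact")
        inter_vol = min(inter_vol, ra.volume, rb.volume)
        return OverlapResult(inter_vol, inter_vol / ra.volume,
                             inter_vol / rb.volume, "exact")

    if method == "monte_carlo":
        rng = np.random.default_rng(rng)
        small_pts, small_hull, small_vol = (
            (pa, hull_a, ra.volume) if ra.volume <= rb.volume
            else (pb, hull_b, rb.volume)
        )
        big_hull = hull_b if ra.volume <= rb.volume else hull_a
        lo, hi = small_pts.min(axis=0), small_pts.max(axis=0)
        box_vol = float(np.prod(hi - lo))
        samples = rng.uniform(lo, hi, size=(n_samples, 3))
        in_small = _inside(small_hull, samples)
        n_small = int(in_small.sum())
        if n_small == 0:
            return OverlapResult(0.0, 0.0, 0.0, "monte_carlo", mc_se=np.nan)
        in_both = _inside(big_hull, samples[in_small])
        p = in_both.mean()
        # estimate via the box: vol = box_vol * P(in both); SE from the
        # binomial count over all box samples
        p_box = in_both.sum() / n_samples
        inter_vol = box_vol * p_box
        se = box_vol * np.sqrt(p_box * (1.0 - p_box) / n_samples)
        inter_vol = min(inter_vol, ra.volume, rb.volume)
        return OverlapResult(inter_vol, inter_vol / ra.volume,
                             inter_vol / rb.volume, "monte_carlo",
                             mc_se=float(se))

    raise ValueError(f"unknown method {method!r}")


def _inside(hull: ConvexHull, pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    return np.all(pts @ hull.equations[:, :3].T + hull.equations[:, 3]
                  <= tol, axis=1)


def locus_indices(points, cell_size: float = DEFAULT_CELL_SIZE,
                  origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Integer (ix, iy, iz) cell index of every point, half-open cells."""
    pts = _as_points(points)
    return np.floor((pts - np.asarray(origin)) / cell_size).astype(np.int64)


def rasterize_loci(points, cell_size: float = DEFAULT_CELL_SIZE,
                   origin=(0.0, 0.0, 0.0)) -> LocusMap:
    """Bin points into the 3D chromatic-locus grid.

    Every point lands in exactly one cell (half-open [lo, hi) bounds, so a
    boundary point belongs to the higher-index cell).
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    idx = locus_indices(points, cell_size, origin)
    cells: dict[tuple[int, int, int], list[int]] = {}
    for row, key in enumerate(map(tuple, idx)):
        cells.setdefault(key, []).append(row)
    return LocusMap(cell_size=cell_size, origin=tuple(origin), cells=cells)


@dataclass
class LocusSummary:
    n_occupied: int
    n_points: int
    abundance: dict[int, int]          # patches-per-locus -> number of loci
    mass_fraction: float               # smallest fraction of loci holding >= p
    mass_p: float


def locus_summary(lmap: LocusMap, mass_p: float = 0.5) -> LocusSummary:
    """Occupancy and abundance summary of a locus map.

    ``mass_fraction`` is the smallest fraction of occupied loci that
    together hold at least ``mass_p`` of all patches (loci sorted by count,
    most crowded first) -- the "half of all patches sit in x% of loci"
    statistic.
    """
    counts = np.array(sorted((len(v) for v in lmap.cells.values()),
                             reverse=True))
    if counts.size == 0:
        return LocusSummary(0, 0, {}, 0.0, mass_p)
    total = int(counts.sum())
    cum = np.cumsum(counts)
    k = int(np.searchsorted(cum, mass_p * total) + 1)
    hist: dict[int, int] = {}
    for c in counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    return LocusSummary(int(counts.size), total, hist, k / counts.size, mass_p)


@dataclass
class LocusPartition:
    n_shared: int
    n_only_a: int
    n_only_b: int

    @property
    def n_union(self) -> int:
        return self.n_shared + self.n_only_a + self.n_only_b

    @property
    def frac_shared(self) -> float:
        return self.n_shared / self.n_union if self.n_union else 0.0

    @property
    def frac_only_a(self) -> float:
        return self.n_only_a / self.n_union if self.n_union else 0.0

    @property
    def frac_only_b(self) -> float:
        return self.n_only_b / self.n_union if self.n_union else 0.0


def shared_unique_loci(a: LocusMap, b: LocusMap) -> LocusPartition:
    """Partition the union of occupied loci into shared / only-a / only-b."""
    if a.cell_size != b.cell_size or a.origin != b.origin:
        raise ValueError("locus maps use different grids")
    sa, sb = set(a.cells), set(b.cells)
    return LocusPartition(len(sa & sb), len(sa - sb), len(sb - sa))


def project_2d(points, plane: str = "yz",
               cell_size: float = DEFAULT_CELL_SIZE,
               origin=(0.0, 0.0, 0.0)) -> dict[tuple[int, int], int]:
    """2D occupancy grid on the yz or yx plane (Fig-style shadow plots).

    Equals the 3D locus map marginalised over the dropped axis.
    """
    axes = {"yz": (1, 2), "yx": (1, 0)}
    if plane not in axes:
        raise ValueError(f"plane must be 'yz' or 'yx', got {plane!r}")
    i, j = axes[plane]
    idx3 = locus_indices(points, cell_size, origin)
    grid: dict[tuple[int, int], int] = {}
    for row in idx3:
        key = (int(row[i]), int(row[j]))
        grid[key] = grid.get(key, 0) + 1
    return grid


def volume_fraction(vol: float, denominator: str = "tetra",
                    reference_volume: float | None = None) -> float:
    """Express a hull volume as a fraction of a named denominator.

    ``denominator="tetra"`` uses the full theoretical tetrahedron volume
    (~0.2165); ``"reference"`` uses a caller-supplied volume (e.g. the
    whole-sample hull).
    """
    if denominator == "tetra":
        return vol / TETRA_VOLUME
    if denominator == "reference":
        if not reference_volume:
            raise ValueError("reference denominator requires reference_volume")
        return vol / reference_volume
    raise ValueError(f"unknown denominator {denominator!r}")
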