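"""Voronoi-tessellation density analysis of localization point patterns.

Each localization gets a first-rank local density (itself plus its
edge-adjacent cells over their summed area); clusters are connected
components of above-average-density points under tessellation adjacency;
two-channel co-localization is quantified by the Spearman rank correlation
of paired local densities and by Manders fractions of points falling in the
other channel's dense region. Even/odd-frame splitting and vertical
flipping provide artificial positive and negative controls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, QhullError, Voronoi, cKDTree
from scipy.stats import spearmanr
from shapely.geometry import Polygon, box

from .errors import NanolocError

DEFAULT_DENSITY_FACTOR = 1.0
DEFAULT_MIN_CLUSTER_LOCS = 25


@dataclass
class DensityMap:
    """Per-localization Voronoi densities for one channel.

    ``density`` holds the first-rank density in localizations/nm^2 (NaN for
    flagged boundary points whose own cell is unbounded). ``mean_density``
    is the dataset-average density (bounded points over their summed
    clipped cell area); it is the reference value for dense-point
    thresholds. ``mean_cell_density`` (per-point mean of 1/A_i) and
    ``mean_first_rank_density`` are reported for diagnostics.

    Note that on a CSR null roughly half the points exceed the
    dataset-average density, which puts a 1x threshold at the Delaunay
    site-percolation point: chance runs of dense points are expected there,
    and a factor of ~2 is needed for a clean null.
    """

    points: np.ndarray  # (n, 2) nm
    cell_area: np.ndarray  # nm^2, NaN for unbounded cells
    density: np.ndarray  # first-rank, localizations/nm^2
    flagged: np.ndarray  # bool, unbounded own cell
    adjacency: sparse.csr_matrix  # symmetric edge-adjacency
    mean_density: float = float("nan")
    mean_cell_density: float = float("nan")
    mean_first_rank_density: float = float("nan")

    @property
    def n(self) -> int:
        return len(self.points)


def _clipped_cell_area(vertices: np.ndarray, bbox) -> float:
    # Voronoi cells are convex; clip to the data bounding box so that cells
    # of near-boundary points do not extend arbitrarily far outside the field
    cell = Polygon(vertices[ConvexHull(vertices).vertices])
    return float(cell.intersection(bbox).area)


def voronoi_densities(table: pd.DataFrame) -> DensityMap:
    """Tessellate a localization table and compute first-rank densities.

    The first-rank density of point i counts the point and its N_i
    edge-adjacent neighbors over the total area of their cells; neighbors
    with unbounded cells are skipped, and points whose own cell is unbounded
    are flagged and excluded from the dataset mean.
    """
    points = table[["x", "y"]].to_numpy(dtype=np.float64)
    n = len(points)
    if n < 4:
        raise NanolocError("need at least 4 localizations to tessellate")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise NanolocError("all localizations are collinear")
    try:
        vor = Voronoi(points)
    except QhullError as exc:
        raise NanolocError(f"tessellation failed: {exc}") from exc

    bbox = box(
        points[:, 0].min(), points[:, 1].min(), points[:, 0].max(), points[:, 1].max()
    )
    cell_area = np.full(n, np.nan)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if not region or -1 in region:
            continue
        cell_area[i] = _clipped_cell_area(vor.vertices[region], bbox)
    flagged = ~np.isfinite(cell_area)

    pairs = vor.ridge_points
    row = np.concatenate([pairs[:, 0], pairs[:, 1]])
    col = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adjacency = sparse.csr_matrix(
        (np.ones(len(row), dtype=bool), (row, col)), shape=(n, n)
    )

    # neighbor count and summed neighbor area, restricted to bounded cells
    bounded_area = np.where(flagged, 0.0, cell_area)
    bounded_flag = (~flagged).astype(np.float64)
    neighbor_area = adjacency @ bounded_area
    neighbor_count = adjacency @ bounded_flag

    density = np.full(n, np.nan)
    ok = ~flagged
    denom = cell_area.copy()
    denom[ok] += neighbor_area[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        density[ok] = (neighbor_count[ok] + 1.0) / denom[ok]

    total_bounded_area = float(np.nansum(cell_area))
    with np.errstate(invalid="ignore", divide="ignore"):
        cell_density = 1.0 / cell_area
    return DensityMap(
        points=points,
        cell_area=cell_area,
        density=density,
        flagged=flagged,
        adjacency=adjacency,
        mean_density=(
            float(ok.sum()) / total_bounded_area if total_bounded_area > 0 else float("nan")
        ),
        mean_cell_density=float(np.nanmean(cell_density[ok])) if ok.any() else float("nan"),
        mean_first_rank_density=float(np.nanmean(density[ok])) if ok.any() else float("nan"),
    )


@dataclass
class Cluster:
    indices: np.ndarray  # row indices into the source table
    member_ids: np.ndarray  # localization ids
    area: float  # nm^2, sum of member cell areas
    diameter: float  # nm, equivalent-circle

    @property
    def n_locs(self) -> int:
        return len(self.indices)


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    n_dense: int = 0
    n_non_dense: int = 0
    n_flagged: int = 0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def diameters(self) -> np.ndarray:
        return np.array([c.diameter for c in self.clusters])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(len(self.clusters)),
                "n_locs": [c.n_locs for c in self.clusters],
                "area_nm2": [c.area for c in self.clusters],
                "diameter_nm": [c.diameter for c in self.clusters],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _dense_mask(dm: DensityMap, density_factor: float, use_first_rank: bool) -> np.ndarray:
    """Above-threshold points relative to the dataset-average density.

    The default compares the *single-cell* density 1/A_i: the first-rank
    (neighborhood-smoothed) density marks background points that merely
    border a cluster as dense — their many tiny-cell neighbors dominate the
    neighborhood — which annexes a ring of large background cells to every
    cluster and inflates its area.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        values = dm.density if use_first_rank else 1.0 / dm.cell_area
    return ~dm.flagged & (values >= density_factor * dm.mean_density)


def segment_clusters(
    table: pd.DataFrame,
    density_factor: float = DEFAULT_DENSITY_FACTOR,
    min_locs: int = DEFAULT_MIN_CLUSTER_LOCS,
    density_map: DensityMap | None = None,
    use_first_rank: bool = False,
) -> ClusterSet:
    """Segment clusters as adjacency-connected runs of above-threshold points.

    Points whose cell density exceeds ``density_factor`` times the
    dataset-average density are "dense" (see :func:`_dense_mask`); clusters
    are connected components of dense points under Voronoi edge adjacency,
    discarding components smaller than ``min_locs``. Cluster area sums the
    member cell areas and the diameter uses the equivalent-circle
    convention ``2*sqrt(area/pi)``.
    """
    dm = voronoi_densities(table) if density_map is None else density_map
    dense = _dense_mask(dm, density_factor, use_first_rank)
    ids = table["id"].to_numpy() if "id" in table.columns else np.arange(dm.n)

    clusters: list[Cluster] = []
    if dense.any():
        sub = dm.adjacency[dense][:, dense]
        n_comp, labels = connected_components(sub, directed=False)
        dense_idx = np.flatnonzero(dense)
        for comp in range(n_comp):
            members = dense_idx[labels == comp]
            if len(members) < min_locs:
                continue
            area = float(np.sum(dm.cell_area[members]))
            clusters.append(
                Cluster(
                    indices=members,
                    member_ids=ids[members],
                    area=area,
                    diameter=2.0 * math.sqrt(area / math.pi),
                )
            )
    clusters.sort(key=lambda c: -c.n_locs)
    return ClusterSet(
        clusters=clusters,
        n_dense=int(dense.sum()),
        n_non_dense=int((~dense & ~dm.flagged).sum()),
        n_flagged=int(dm.flagged.sum()),
    )


def cluster_diameters(clusters: ClusterSet) -> np.ndarray:
    """Equivalent-circle diameters (nm) of every cluster."""
    return clusters.diameters()


@dataclass
class ColocResult:
    """Two-channel co-localization summary."""

    rho: float  # Spearman over pooled A+B query points
    rho_a: float  # query points restricted to channel A localizations
    rho_b: float
    m_a: float = float("nan")  # fraction of A in B's dense region
    m_b: float = float("nan")
    n: int = 0  # query points used for the pooled rho


def _density_at(dm: DensityMap, tree: cKDTree, query: np.ndarray) -> np.ndarray:
    _, nearest = tree.query(query)
    return dm.density[nearest]


def spearman_coloc(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    roi: tuple[float, float, float, float] | None = None,
) -> ColocResult:
    """Spearman rank correlation of paired local densities of two channels.

    Every localization position p of either channel contributes the pair
    (density of the A-cell containing p, density of the B-cell containing
    p); ties are mid-ranked. ``roi`` (xmin, ymin, xmax, ymax) restricts the
    query positions while densities are computed on the full tables.
    """
    dm_a = voronoi_densities(table_a)
    dm_b = voronoi_densities(table_b)
    tree_a = cKDTree(dm_a.points)
    tree_b = cKDTree(dm_b.points)

    def in_roi(points: np.ndarray) -> np.ndarray:
        if roi is None:
            return np.ones(len(points), dtype=bool)
        xmin, ymin, xmax, ymax = roi
        return (
            (points[:, 0] >= xmin)
            & (points[:, 0] <= xmax)
            & (points[:, 1] >= ymin)
            & (points[:, 1] <= ymax)
        )

    def rho_over(query: np.ndarray) -> tuple[float, int]:
        da = _density_at(dm_a, tree_a, query)
        db = _density_at(dm_b, tree_b, query)
        ok = np.isfinite(da) & np.isfinite(db)
        if ok.sum() < 3:
            raise NanolocError("too few valid density pairs in region")
        da, db = da[ok], db[ok]
        if np.ptp(da) == 0 or np.ptp(db) == 0:
            raise NanolocError("degenerate (constant) densities")
        rho = spearmanr(da, db).statistic
        return float(rho), int(ok.sum())

    pts_a = dm_a.points[in_roi(dm_a.points)]
    pts_b = dm_b.points[in_roi(dm_b.points)]
    if len(pts_a) == 0 or len(pts_b) == 0:
        raise NanolocError("a channel has no localizations inside the ROI")
    rho_a, _ = rho_over(pts_a)
    rho_b, _ = rho_over(pts_b)
    rho, n = rho_over(np.vstack([pts_a, pts_b]))
    return ColocResult(rho=rho, rho_a=rho_a, rho_b=rho_b, n=n)


def manders_coloc(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    density_factor: float = DEFAULT_DENSITY_FACTOR,
    use_first_rank: bool = False,
) -> tuple[float, float]:
    """Manders fractions via the point-in-dense-Voronoi-cell test.

    M_A is the fraction of channel-A localizations lying inside channel B's
    dense region (the union of B cells with first-rank density above
    ``density_factor`` times B's mean), and symmetrically for M_B.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise NanolocError("empty channel")
    dm_a = voronoi_densities(table_a)
    dm_b = voronoi_densities(table_b)

    def fraction_inside(points: np.ndarray, dm_other: DensityMap) -> float:
        dense = _dense_mask(dm_other, density_factor, use_first_rank)
        tree = cKDTree(dm_other.points)
        _, nearest = tree.query(points)
        return float(np.mean(dense[nearest]))

    m_a = fraction_inside(dm_a.points, dm_b)
    m_b = fraction_inside(dm_b.points, dm_a)
    return m_a, m_b


def coloc_report(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    roi=None,
    density_factor: float = DEFAULT_DENSITY_FACTOR,
) -> ColocResult:
    """Spearman and Manders statistics in one ColocResult."""
    result = spearman_coloc(table_a, table_b, roi=roi)
    result.m_a, result.m_b = manders_coloc(table_a, table_b, density_factor)
    return result


def control_positive(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Artificial positive control: even frames vs odd frames of one stack."""
    if table["frame"].nunique() < 2:
        raise NanolocError("need at least two distinct frames to split")
    even = table["frame"] % 2 == 0
    return table[even].reset_index(drop=True), table[~even].reset_index(drop=True)


def control_negative(
    table: pd.DataFrame,
    bounding_box: tuple[float, float, float, float] | None = None,
) -> pd.DataFrame:
    """Artificial negative control: flip localizations vertically in the box.

    ``bounding_box`` is (xmin, ymin, xmax, ymax); by default the data's own
    bounding box, which makes the operation an involution.
    """
    if bounding_box is None:
        bounding_box = (
            table["x"].min(), table["y"].min(),
            table["x"].max(), table["y"].max(),
        )
    xmin, ymin, xmax, ymax = bounding_box
    if ((table["x"] < xmin) | (table["x"] > xmax) | (table["y"] < ymin) | (table["y"] > ymax)).any():
        raise NanolocError("localization outside the bounding box")
    out = table.copy()
    out["y"] = (ymin + ymax) - out["y"]
    return out
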