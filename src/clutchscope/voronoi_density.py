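"""Voronoi-tessellation density analysis of localization point clouds.

Every localization receives the cell of space closer to it than to any other
localization; the inverse cell measure (area in 2D, volume in 3D) is its local
density.  Cells are clipped to the nuclear mask (and to the axial slab in 3D)
so that densities at the periphery and around excluded regions are not
underestimated by unbounded polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from ._geometry import bounded_voronoi_2d, voronoi_cell_volumes_3d
from .locdata_io import LocalizationTable, NuclearMask

__all__ = [
    "VoronoiDensityMap",
    "DensityDistribution",
    "tessellate",
    "compaction_fold",
    "density_distribution",
    "compare_distributions",
    "colorize",
    "DENSITY_BINS_2D",
    "DENSITY_BINS_3D",
]

#: default log-binning ranges for cumulative density distributions
DENSITY_BINS_2D = (0.1e-9, 0.94)     # nm^-2
DENSITY_BINS_3D = (5e-7, 0.0025)     # nm^-3
N_DENSITY_BINS = 300


@dataclass
class VoronoiDensityMap:
    """Per-localization Voronoi cell measures and densities."""

    measures: np.ndarray          # nm² (2D) or nm³ (3D); NaN for dropped cells
    dimension: int
    mask: NuclearMask
    clipped: np.ndarray | None = None   # True where the cell touched the mask edge
    polygons: list | None = None        # 2D only: shapely cell geometries

    @property
    def densities(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1.0 / self.measures

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.measures) & (self.measures > 0)

    def __len__(self) -> int:
        return len(self.measures)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "id": np.arange(len(self.measures)),
            "measure": self.measures,
            "density": self.densities,
        })
        if self.clipped is not None:
            df["clipped"] = self.clipped
        return df


@dataclass
class DensityDistribution:
    """Normalized cumulative density histograms across replicates."""

    bin_edges: np.ndarray               # len n_bins + 1, log-spaced densities
    cumulative: np.ndarray              # (n_replicates, n_bins), each in [0, 1]
    median: np.ndarray = field(init=False)
    iqr_lo: np.ndarray = field(init=False)
    iqr_hi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.median = np.median(self.cumulative, axis=0)
        self.iqr_lo = np.percentile(self.cumulative, 25, axis=0)
        self.iqr_hi = np.percentile(self.cumulative, 75, axis=0)


def tessellate(table: LocalizationTable, mask: NuclearMask,
               dimension: int = 2,
               z_bounds: tuple[float, float] | None = None) -> VoronoiDensityMap:
    """Tessellate localizations and return per-point clipped cell measures.

    2D cells are exact clipped polygons; 3D cells are convex polyhedra clipped
    to the prism of the mask polygon over the z slab (``z_bounds``, defaulting
    to the data's z extent).
    """
    if dimension not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    n_min = 2 if dimension == 2 else 5
    if len(table) < n_min:
        raise ValueError(f"{dimension}D tessellation requires >= {n_min} points")
    if dimension == 2:
        pts = table.xy
        if len(pts) > 2:
            _check_nondegenerate(pts)
        cells = bounded_voronoi_2d(pts, mask)
        measures = np.array([c.area if not c.is_empty else np.nan for c in cells])
        measures[measures == 0.0] = np.nan
        # a cell is "clipped" when the raw Voronoi polygon lost area to the mask
        clipped = np.zeros(len(cells), dtype=bool)
        edges = [mask.boundary.exterior] + [p.exterior for p in mask.exclusions]
        for i, cell in enumerate(cells):
            clipped[i] = cell.is_empty or any(cell.distance(e) < 1e-9 for e in edges)
        return VoronoiDensityMap(measures, 2, mask, clipped=clipped, polygons=cells)

    if not table.has("z"):
        raise ValueError("3D tessellation requires a z column")
    pts = np.column_stack([table.xy, table.column("z").astype(float)])
    _check_nondegenerate(pts)
    vols = voronoi_cell_volumes_3d(pts, mask, z_bounds=z_bounds)
    vols = np.where(vols > 0, vols, np.nan)
    return VoronoiDensityMap(vols, 3, mask)


def _check_nondegenerate(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * (1 + np.abs(points).max()))
    if rank < points.shape[1]:
        raise ValueError("points are collinear/coplanar; tessellation is degenerate")


def compaction_fold(vmap: VoronoiDensityMap, hetero_pct: float = 15.0,
                    eu_pct: float = 85.0, weight: str = "count") -> float:
    """Density contrast between the smallest- and largest-cell classes.

    Cells at or below the ``hetero_pct`` area percentile are the dense
    (heterochromatic) class; cells at or above ``eu_pct`` the sparse
    (euchromatic) class.  Returns the ratio of class mean densities.

    ``weight='count'`` (default) averages density per cell; ``weight='area'``
    weights each cell's density by its measure.
    """
    areas = vmap.measures[vmap.valid]
    if len(areas) < 100:
        raise ValueError("compaction_fold requires >= 100 valid cells")
    lo_cut = np.percentile(areas, hetero_pct)
    hi_cut = np.percentile(areas, eu_pct)
    hetero = areas[areas <= lo_cut]
    eu = areas[areas >= hi_cut]
    if hetero.size == 0 or eu.size == 0:
        raise ValueError("empty percentile class")
    if weight == "count":
        return float(np.mean(1.0 / hetero) / np.mean(1.0 / eu))
    if weight == "area":
        return float((hetero.size / hetero.sum()) / (eu.size / eu.sum()))
    raise ValueError("weight must be 'count' or 'area'")


def density_distribution(maps: Sequence[VoronoiDensityMap],
                         bin_lo: float | None = None,
                         bin_hi: float | None = None,
                         n_bins: int = N_DENSITY_BINS) -> DensityDistribution:
    """Cumulative log-binned density histograms, one replicate per map."""
    if not maps:
        raise ValueError("at least one replicate map is required")
    dim = maps[0].dimension
    if bin_lo is None or bin_hi is None:
        lo, hi = DENSITY_BINS_2D if dim == 2 else DENSITY_BINS_3D
        bin_lo = lo if bin_lo is None else bin_lo
        bin_hi = hi if bin_hi is None else bin_hi
    if not 0 < bin_lo < bin_hi:
        raise ValueError("require 0 < bin_lo < bin_hi")
    edges = np.logspace(np.log10(bin_lo), np.log10(bin_hi), n_bins + 1)
    rows = []
    for m in maps:
        d = m.densities[m.valid]
        # out-of-range densities are accumulated into the end bins
        counts, _ = np.histogram(np.clip(d, edges[0], edges[-1]), bins=edges)
        cum = np.cumsum(counts) / max(len(d), 1)
        rows.append(cum)
    return DensityDistribution(edges, np.asarray(rows, float))


def compare_distributions(a: DensityDistribution, b: DensityDistribution,
                          pooled: tuple[np.ndarray, np.ndarray] | None = None):
    """Two-sample KS test between the per-bin median cumulative curves.

    Treating the binned median values as samples follows the source analysis;
    it is statistically unconventional, so a secondary KS on pooled per-cell
    densities is returned as well when ``pooled`` provides the raw samples.

    Returns ``(D, p)`` or ``(D, p, D_pooled, p_pooled)``.
    """
    if a.bin_edges.shape != b.bin_edges.shape or not np.allclose(a.bin_edges, b.bin_edges):
        raise ValueError("distributions must share identical binning")
    res = ks_2samp(a.median, b.median, method="auto")
    if pooled is None:
        return float(res.statistic), float(res.pvalue)
    res2 = ks_2samp(pooled[0], pooled[1])
    return float(res.statistic), float(res.pvalue), float(res2.statistic), float(res2.pvalue)


def colorize(vmap: VoronoiDensityMap, lo: float = 0.001, hi: float = 0.02,
             black_tail: float = 0.5):
    """Map cell densities to display values on the [lo, hi] scale.

    Returns ``(scaled, black)``: ``scaled`` in [0, 1] (log interpolation from
    ``lo`` -> 0 to ``hi`` -> 1, clipped) and a boolean flag marking the largest
    ``black_tail`` percent of cells by measure (the sentinel/black class).
    """
    if len(vmap) == 0:
        raise ValueError("empty density map")
    d = vmap.densities
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (np.log10(d) - np.log10(lo)) / (np.log10(hi) - np.log10(lo))
    scaled = np.clip(scaled, 0.0, 1.0)
    areas = vmap.measures
    order = np.argsort(np.where(np.isfinite(areas), areas, -np.inf), kind="stable")
    n_black = int(np.ceil(black_tail / 100.0 * np.count_nonzero(vmap.valid)))
    black = np.zeros(len(areas), dtype=bool)
    if n_black > 0:
        valid_sorted = [i for i in order[::-1] if np.isfinite(areas[i])]
        black[valid_sorted[:n_black]] = True
    return scaled, black
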