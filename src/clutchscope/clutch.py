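"""Distance-based segmentation of histone localizations into nucleosome
clutches, island grouping and per-dataset quality-control metrics.

Segmentation is single-linkage: localizations within ``eps`` of each other are
chained into connected components, and components below ``min_size`` are
discarded.  Groups of clutches in close mutual proximity form "islands",
interpreted as higher-order folding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, cKDTree

from .locdata_io import LocalizationTable, NuclearMask, render_gaussian

__all__ = [
    "Clutch",
    "ClutchSet",
    "IslandSet",
    "QCReport",
    "segment_clutches",
    "group_islands",
    "occupancy",
    "nyquist_metric",
    "localization_precision",
    "frc_resolution",
    "qc_gate",
    "QC_THRESHOLDS",
    "DEFAULT_EPS",
    "DEFAULT_MIN_SIZE",
]

DEFAULT_EPS = 40.0        # nm; ~2x the median lateral localization precision
DEFAULT_MIN_SIZE = 5
DEFAULT_ISLAND_LINK = 1.5 * DEFAULT_EPS

#: strict-inequality QC thresholds per condition
QC_THRESHOLDS = {
    "control": {"occupancy": 35.0, "clustered_area": 15.0, "clusters_per_island": 3.0},
    "treated": {"occupancy": 25.0, "clustered_area": 10.0, "clusters_per_island": 1.5},
}

NYQUIST_MAX = 32.0  # nm/localization, inclusive upper bound for dataset selection


@dataclass
class Clutch:
    id: int
    member_ids: np.ndarray
    centroid: tuple[float, float]
    sd: float                 # mean per-axis standard deviation of members, nm
    area: float               # convex hull area, nm² (disk fallback below 3 members)
    n_locs: int
    island: int = -1


@dataclass
class ClutchSet:
    clutches: list[Clutch]
    labels: np.ndarray | None = None   # per-localization clutch id, -1 = unclustered

    def __len__(self) -> int:
        return len(self.clutches)

    @property
    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.clutches], float).reshape(-1, 2)

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.clutches], float)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.n_locs for c in self.clutches], int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": [c.id for c in self.clutches],
            "x": [c.centroid[0] for c in self.clutches],
            "y": [c.centroid[1] for c in self.clutches],
            "sd": [c.sd for c in self.clutches],
            "area": [c.area for c in self.clutches],
            "n_locs": [c.n_locs for c in self.clutches],
            "island": [c.island for c in self.clutches],
        })


@dataclass
class IslandSet:
    membership: dict[int, list[int]]     # island id -> clutch ids

    @property
    def sizes(self) -> np.ndarray:
        return np.array([len(v) for v in self.membership.values()], int)

    @property
    def clusters_per_island(self) -> float:
        sizes = self.sizes
        return float(sizes.mean()) if sizes.size else math.nan

    @property
    def percent_isolated(self) -> float:
        sizes = self.sizes
        total = sizes.sum()
        return float(100.0 * np.count_nonzero(sizes == 1) / total) if total else math.nan


@dataclass
class QCReport:
    occupancy: float
    clustered_area: float
    clusters_per_island: float
    nyquist: float = math.nan            # nm/localization (worse of the two variants)
    frc_resolution: float = math.nan
    precision_median: float = math.nan
    passed: bool | None = None
    failures: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Segmentation


def _connected_labels(points: np.ndarray, eps: float) -> np.ndarray:
    """Single-linkage component label per point (KD-tree pair graph)."""
    n = len(points)
    tree = cKDTree(points)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    return labels


def segment_clutches(table: LocalizationTable, eps: float = DEFAULT_EPS,
                     min_size: int = DEFAULT_MIN_SIZE) -> ClutchSet:
    """Segment localizations into clutches by single-linkage chaining.

    Two localizations belong to the same clutch when they are connected by a
    chain of steps each no longer than ``eps``.  Components with fewer than
    ``min_size`` members are discarded (their label is set to -1).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if len(table) == 0:
        return ClutchSet([], labels=np.empty(0, int))
    xy = table.xy
    raw = _connected_labels(xy, eps)
    labels = np.full(len(xy), -1, dtype=int)
    clutches: list[Clutch] = []
    for comp in np.unique(raw):
        members = np.nonzero(raw == comp)[0]
        if len(members) < min_size:
            continue
        cid = len(clutches)
        labels[members] = cid
        pts = xy[members]
        centroid = pts.mean(axis=0)
        sd = float(np.mean(pts.std(axis=0, ddof=1))) if len(pts) > 1 else 0.0
        clutches.append(Clutch(
            id=cid,
            member_ids=members,
            centroid=(float(centroid[0]), float(centroid[1])),
            sd=sd,
            area=_hull_area(pts, sd),
            n_locs=len(members),
        ))
    return ClutchSet(clutches, labels=labels)


def _hull_area(pts: np.ndarray, sd: float) -> float:
    if len(pts) >= 3:
        try:
            return float(ConvexHull(pts).volume)  # 2D "volume" is area
        except Exception:
            pass  # collinear members
    return float(math.pi * sd * sd)


def group_islands(clutches: ClutchSet, xy: np.ndarray | None = None,
                  link: float = DEFAULT_ISLAND_LINK) -> IslandSet:
    """Join clutches whose minimum inter-member distance is <= ``link``.

    ``xy`` supplies member coordinates (the localization table the clutches
    were segmented from); when omitted, centroids are used as single-member
    proxies.  The relation is closed transitively.
    """
    if link <= 0:
        raise ValueError("link must be positive")
    n = len(clutches)
    if n == 0:
        return IslandSet({})
    if xy is not None and clutches.labels is not None:
        keep = clutches.labels >= 0
        pts = np.asarray(xy, float)[keep]
        owner = clutches.labels[keep]
    else:
        pts = clutches.centroids
        owner = np.arange(n)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(link, output_type="ndarray")
    ci = owner[pairs[:, 0]]
    cj = owner[pairs[:, 1]]
    cross = ci != cj
    graph = sparse.coo_matrix(
        (np.ones(np.count_nonzero(cross)), (ci[cross], cj[cross])), shape=(n, n)
    )
    _, island_labels = connected_components(graph, directed=False)
    membership: dict[int, list[int]] = {}
    for cid, isl in enumerate(island_labels):
        membership.setdefault(int(isl), []).append(cid)
        clutches.clutches[cid].island = int(isl)
    return IslandSet(membership)


# ---------------------------------------------------------------------------
# Dataset metrics


def _occupied_bins(xy: np.ndarray, origin: np.ndarray, pixel: float) -> int:
    ij = np.floor((xy - origin) / pixel).astype(np.int64)
    return len({(int(a), int(b)) for a, b in ij})


def occupancy(table: LocalizationTable, mask: NuclearMask,
              fine: float = 20.0, coarse: float = 160.0) -> float:
    """Super-resolved vs diffraction-scale occupied-area ratio, in percent.

    Both grids are anchored at the mask bounding-box origin.
    """
    if not fine < coarse:
        raise ValueError("fine pixel must be smaller than coarse pixel")
    xy = table.xy
    origin = np.array(mask.boundary.bounds[:2])
    n_coarse = _occupied_bins(xy, origin, coarse)
    if n_coarse == 0:
        raise ValueError("no occupied coarse bins; occupancy undefined")
    n_fine = _occupied_bins(xy, origin, fine)
    return 100.0 * (n_fine * fine * fine) / (n_coarse * coarse * coarse)


def clustered_area_percent(clutches: ClutchSet, table: LocalizationTable,
                           mask: NuclearMask, fine: float = 20.0) -> float:
    """Percent of localization-occupied area covered by clutch hulls."""
    xy = table.xy
    origin = np.array(mask.boundary.bounds[:2])
    loc_area = _occupied_bins(xy, origin, fine) * fine * fine
    if loc_area == 0:
        raise ValueError("no localizations")
    return 100.0 * clutches.areas.sum() / loc_area


def nyquist_metric(table: LocalizationTable, mask: NuclearMask,
                   slab: float = 120.0, fine: float = 20.0) -> tuple[float, float]:
    """Nyquist-style sampling metric, nm per localization.

    ``(slab * area_per_localization) ** (1/3)`` evaluated with two reference
    areas: (i) the usable mask area (diffraction-scale estimate) and (ii) the
    summed area of occupied ``fine``-nm bins (super-resolved estimate).
    """
    n = len(table)
    if n == 0:
        raise ValueError("empty table")
    a_mask = mask.usable_area
    origin = np.array(mask.boundary.bounds[:2])
    a_fine = _occupied_bins(table.xy, origin, fine) * fine * fine
    return (
        float((a_mask / n * slab) ** (1.0 / 3.0)),
        float((a_fine / n * slab) ** (1.0 / 3.0)),
    )


def localization_precision(table: LocalizationTable, min_consecutive: int = 5,
                           chain_radius: float = 100.0):
    """Lateral precision from point clouds persisting over sequential frames.

    Localizations are linked frame-to-frame (nearest neighbour within
    ``chain_radius``; no frame gaps).  Chains spanning at least
    ``min_consecutive`` frames yield one precision sample each: the pooled
    per-axis standard deviation sqrt((sx² + sy²)/2).

    Returns ``(median, (q25, q75), per_cloud)``; empty input yields NaNs.
    """
    if not table.has("frame"):
        raise ValueError("localization_precision requires frame indices")
    frames = table.column("frame").astype(int)
    xy = table.xy
    order = np.argsort(frames, kind="stable")
    chains: list[list[int]] = []
    active: dict[int, tuple[np.ndarray, int]] = {}  # chain idx -> (last xy, last frame)
    for f in np.unique(frames):
        idx = order[np.searchsorted(frames[order], [f, f + 1])[0]:
                    np.searchsorted(frames[order], [f, f + 1])[1]]
        prev = {k: v for k, v in active.items() if v[1] == f - 1}
        taken: set[int] = set()
        if prev:
            keys = list(prev.keys())
            tree = cKDTree(np.array([prev[k][0] for k in keys]))
            dists, nearest = tree.query(xy[idx], k=1,
                                        distance_upper_bound=chain_radius)
        for pos, i in enumerate(idx):
            linked = False
            if prev and np.isfinite(dists[pos]):
                k = keys[nearest[pos]]
                if k not in taken:
                    chains[k].append(int(i))
                    active[k] = (xy[i], f)
                    taken.add(k)
                    linked = True
            if not linked:
                chains.append([int(i)])
                active[len(chains) - 1] = (xy[i], f)
    per_cloud = []
    for chain in chains:
        if len(chain) >= min_consecutive:
            pts = xy[chain]
            var = pts.var(axis=0, ddof=1)
            per_cloud.append(math.sqrt(0.5 * (var[0] + var[1])))
    per_cloud = np.asarray(per_cloud)
    if per_cloud.size == 0:
        return math.nan, (math.nan, math.nan), per_cloud
    return (float(np.median(per_cloud)),
            (float(np.percentile(per_cloud, 25)), float(np.percentile(per_cloud, 75))),
            per_cloud)


def frc_resolution(table: LocalizationTable, pixel: float = 20.0,
                   threshold: float = 1.0 / 7.0, sigma: float = 10.0,
                   seed: int = 0, smooth_bins: int = 5) -> float:
    """Fourier ring correlation resolution of a localization dataset.

    The table is split into random halves (seeded), each half rendered, and
    the ring-wise spectral correlation computed; resolution is the inverse of
    the first frequency at which the smoothed curve drops below ``threshold``.
    Returns NaN when the curve never crosses (no resolvable structure).
    """
    if len(table) < 1000:
        raise ValueError("frc_resolution requires >= 1000 localizations")
    rng = np.random.default_rng(seed)
    half = rng.random(len(table)) < 0.5
    xy = table.xy
    pad = 2 * sigma
    extent = (xy[:, 0].min() - pad, xy[:, 0].max() + pad,
              xy[:, 1].min() - pad, xy[:, 1].max() + pad)
    img1 = render_gaussian(table.take(np.nonzero(half)[0]), sigma=sigma,
                           pixel_size=pixel, extent=extent).values
    img2 = render_gaussian(table.take(np.nonzero(~half)[0]), sigma=sigma,
                           pixel_size=pixel, extent=extent).values
    size = max(img1.shape)
    f1 = np.fft.fftshift(np.fft.fft2(img1, s=(size, size)))
    f2 = np.fft.fftshift(np.fft.fft2(img2, s=(size, size)))
    fy, fx = np.indices((size, size))
    r = np.hypot(fx - size // 2, fy - size // 2).astype(int)
    n_rings = size // 2
    num = np.bincount(r.ravel(), weights=(f1 * np.conj(f2)).real.ravel(),
                      minlength=n_rings)[:n_rings]
    den1 = np.bincount(r.ravel(), weights=np.abs(f1).ravel() ** 2,
                       minlength=n_rings)[:n_rings]
    den2 = np.bincount(r.ravel(), weights=np.abs(f2).ravel() ** 2,
                       minlength=n_rings)[:n_rings]
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = num / np.sqrt(den1 * den2)
    frc = np.nan_to_num(frc)
    if smooth_bins > 1:
        # smooth the non-DC rings only; the huge zero-frequency term must not
        # leak into its neighbours
        kernel = np.ones(smooth_bins) / smooth_bins
        padded = np.pad(frc[1:], smooth_bins, mode="edge")
        frc = np.concatenate([[frc[0]],
                              np.convolve(padded, kernel,
                                          mode="same")[smooth_bins:-smooth_bins]])
    freqs = np.arange(n_rings) / (size * pixel)  # cycles per nm
    below = np.nonzero(frc[1:] < threshold)[0]
    # a crossing within the lowest rings is indistinguishable from the field
    # envelope (image edges correlate between halves even for pure noise):
    # report not-determined rather than a field-scale pseudo-resolution
    k_min = max(4, smooth_bins)
    if below.size == 0 or below[0] + 1 <= k_min:
        return math.nan
    k = below[0] + 1
    # linear interpolation of the crossing frequency
    f_cross = np.interp(threshold, [frc[k], frc[k - 1]], [freqs[k], freqs[k - 1]])
    return float(1.0 / f_cross)


def qc_gate(report: QCReport, condition: str = "control") -> QCReport:
    """Apply the strict-inequality dataset-selection thresholds.

    All three cluster metrics must exceed their per-condition thresholds; a
    value exactly at the threshold fails.  The Nyquist metric, when present,
    must be <= 32 nm/localization (inclusive) for both density variants.
    """
    if condition not in QC_THRESHOLDS:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{sorted(QC_THRESHOLDS)}")
    thresholds = QC_THRESHOLDS[condition]
    failures = []
    for name, cut in thresholds.items():
        if not getattr(report, name) > cut:
            failures.append(f"{name} <= {cut}")
    if not math.isnan(report.nyquist) and report.nyquist > NYQUIST_MAX:
        failures.append(f"nyquist > {NYQUIST_MAX}")
    report.failures = failures
    report.passed = not failures
    return report
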