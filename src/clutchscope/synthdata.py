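"""Synthetic two-channel nuclei with known ground truth.

Generates H2B localizations as Gaussian clutches grouped into islands, DNA
localizations split into a clutch-associated pool (confined within a
controllable clutch-DNA radius around a parent clutch) and a uniform
clutch-free background, plus fiducial beads, frame-indexed drift, a smooth
chromatic warp between channels and astigmatic width-versus-z encoding.
Every stochastic choice flows from a single seed, so identical seeds produce
identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .alignment3d import DriftTrajectory, PolynomialWarp2D, ZCalibration
from .locdata_io import LocalizationTable, NuclearMask

__all__ = [
    "NucleusModel",
    "DnaModel",
    "AcquisitionModel",
    "GroundTruth",
    "make_ellipse_mask",
    "simulate_nucleus",
    "condition_presets",
    "apply_distortions",
    "default_z_calibration",
]


@dataclass
class NucleusModel:
    """Geometry of clutch islands inside an elliptical nucleus."""

    mask_radii: tuple[float, float] = (6000.0, 5000.0)   # nm semi-axes
    n_exclusions: int = 0                                # nucleolar holes
    exclusion_radius: float = 800.0
    n_islands: int = 32
    clutches_per_island_mean: float = 4.0                # Poisson (min 1)
    island_spread: float = 130.0                         # nm sd of clutch centers
    min_center_spacing: float = 215.0                    # nm, reject closer centers
    clutch_sd: float = 25.0                              # nm H2B spread per clutch
    locs_per_clutch_mean: float = 100.0                  # Poisson


@dataclass
class DnaModel:
    """Partition of DNA localizations into clutch-associated and free pools."""

    association_fraction: float = 0.717
    clutch_dna_radius: float = 70.0       # nm
    profile: str = "step"                 # 'step' (uniform disk) or 'gaussian'
    total_dna: int = 150_000
    crowding_boost: float = 1.0           # extra associated weight for clutches with NND < 50 nm
    # micron-scale modulation of the clutch-free pool: real nuclei show large
    # density variation between regions, which keeps per-clutch background
    # densities overdispersed relative to pure Poisson counting
    background_domain_fraction: float = 0.5
    background_domain_sd: float = 800.0   # nm
    n_background_domains: int = 60

    def __post_init__(self):
        if not 0 <= self.association_fraction <= 1:
            raise ValueError("association_fraction must be in [0, 1]")
        if self.profile not in ("step", "gaussian"):
            raise ValueError("profile must be 'step' or 'gaussian'")


@dataclass
class AcquisitionModel:
    """Optical / temporal distortions applied to the ideal geometry."""

    loc_noise_sd: float = 0.0             # nm, isotropic localization noise
    frames: int = 2000
    blink_mean: float = 1.0               # mean consecutive frames per emitter
    drift_per_frame: tuple[float, float, float] = (0.0, 0.0, 0.0)  # nm/frame linear
    drift_random_walk: float = 0.0        # nm/sqrt(frame) random-walk amplitude
    warp: PolynomialWarp2D | None = None  # applied to channel b
    z_offset: float = 0.0                 # nm added to channel b z
    n_beads: int = 0
    bead_noise_sd: float = 3.0
    astigmatism: ZCalibration | None = None
    slab_halfwidth: float = 60.0          # nm, |z| extent of generated localizations


@dataclass
class GroundTruth:
    clutch_centers: np.ndarray
    clutch_island: np.ndarray
    h2b_parent: np.ndarray                # clutch index per H2B localization
    dna_parent: np.ndarray                # clutch index (-1 = background) per DNA loc
    association_fraction: float
    clutch_dna_radius: float
    drift: DriftTrajectory | None = None
    warp: PolynomialWarp2D | None = None
    z_offset: float = 0.0
    bead_positions: np.ndarray | None = None


def make_ellipse_mask(radii: tuple[float, float] = (6000.0, 5000.0),
                      n_vertices: int = 64,
                      exclusions: Sequence[tuple[float, float, float]] = ()) -> NuclearMask:
    """Elliptical nuclear mask; exclusions are (cx, cy, radius) disks."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    boundary = Polygon(np.column_stack([radii[0] * np.cos(t), radii[1] * np.sin(t)]))
    holes = [Point(cx, cy).buffer(r, quad_segs=16) for cx, cy, r in exclusions]
    return NuclearMask(boundary, holes)


def default_z_calibration() -> ZCalibration:
    """A plausible astigmatic width model over ±400 nm.

    Widths in nm: symmetric quadratic curves offset in z so that
    Wx - Wy is monotone through the focal plane.
    """
    # W(z) = w0 + a (z -+ d)^2 expanded to cubic coefficient form
    w0, a, d = 350.0, 6e-4, 200.0
    cx = np.array([0.0, a, -2 * a * d, w0 + a * d * d])
    cy = np.array([0.0, a, +2 * a * d, w0 + a * d * d])
    return ZCalibration(cx, cy, (-400.0, 400.0), 0.0)


# ---------------------------------------------------------------------------


def _sample_in_mask(rng: np.random.Generator, mask: NuclearMask, n: int,
                    margin: float = 0.0) -> np.ndarray:
    """Rejection-sample uniform points in the usable mask area."""
    xmin, ymin, xmax, ymax = mask.boundary.bounds
    out = np.empty((0, 2))
    geom = mask.usable if margin == 0 else mask.usable.buffer(-margin)
    if geom.is_empty or geom.area <= 0:
        raise ValueError("sampling geometry is empty; mask/margin infeasible")
    import shapely

    while len(out) < n:
        cand = rng.uniform([xmin, ymin], [xmax, ymax], size=(max(2 * n, 128), 2))
        inside = shapely.contains(geom, shapely.points(cand))
        out = np.vstack([out, cand[inside]])
    return out[:n]


def _sample_background(rng: np.random.Generator, mask: NuclearMask, n: int,
                       dna: "DnaModel") -> np.ndarray:
    """Clutch-free DNA: uniform pool plus micron-scale density domains."""
    if n == 0:
        return np.empty((0, 2))
    n_dom = rng.binomial(n, dna.background_domain_fraction) \
        if dna.background_domain_fraction > 0 else 0
    parts = [_sample_in_mask(rng, mask, n - n_dom)] if n - n_dom else []
    if n_dom:
        centers = _sample_in_mask(rng, mask, dna.n_background_domains)
        pts = np.empty((0, 2))
        while len(pts) < n_dom:
            m = max(2 * (n_dom - len(pts)), 256)
            cand = (centers[rng.integers(0, len(centers), m)]
                    + rng.normal(0.0, dna.background_domain_sd, (m, 2)))
            keep = mask.contains_points(cand)
            pts = np.vstack([pts, cand[keep]])
        parts.append(pts[:n_dom])
    return np.vstack(parts)


def simulate_nucleus(model: NucleusModel, dna: DnaModel, acq: AcquisitionModel,
                     seed: int = 0):
    """Generate one synthetic nucleus.

    Returns a dict with keys ``h2b``, ``dna``, ``beads_a``, ``beads_b``
    (:class:`LocalizationTable`), ``mask`` and ``truth``.
    """
    rng = np.random.default_rng(seed)
    exclusions = []
    mask = make_ellipse_mask(model.mask_radii)
    if model.n_exclusions:
        centers = _sample_in_mask(rng, mask, model.n_exclusions,
                                  margin=2.0 * model.exclusion_radius)
        exclusions = [(cx, cy, model.exclusion_radius) for cx, cy in centers]
        mask = make_ellipse_mask(model.mask_radii, exclusions=exclusions)

    # -- clutch geometry ---------------------------------------------------
    margin = model.island_spread * 3 + 200.0
    island_centers = _sample_in_mask(rng, mask, model.n_islands, margin=margin)
    if len(island_centers) < model.n_islands:
        raise ValueError("islands overflow the mask; geometry infeasible")
    # minimum spacing is enforced globally (also across overlapping islands):
    # sub-spacing centre pairs would merge under downstream single-linkage
    # segmentation and leave orphan DNA blobs in neighbouring polygons
    centers, island_of = [], []
    min_sq = model.min_center_spacing ** 2
    for isl, c in enumerate(island_centers):
        k = max(1, rng.poisson(model.clutches_per_island_mean))
        for _ in range(k):
            placed = False
            for _attempt in range(100):
                p = c + rng.normal(0.0, model.island_spread, 2)
                if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sq
                       for q in centers):
                    placed = True
                    break
            if placed:
                centers.append(p)
                island_of.append(isl)
    centers = np.asarray(centers)
    island_of = np.asarray(island_of)
    keep = mask.contains_points(centers)
    centers, island_of = centers[keep], island_of[keep]
    n_clutches = len(centers)

    # -- H2B channel -------------------------------------------------------
    locs_per = np.maximum(1, rng.poisson(model.locs_per_clutch_mean, n_clutches))
    h2b_parent = np.repeat(np.arange(n_clutches), locs_per)
    h2b_xy = centers[h2b_parent] + rng.normal(0.0, model.clutch_sd,
                                              (len(h2b_parent), 2))
    h2b_z = rng.uniform(-acq.slab_halfwidth, acq.slab_halfwidth, len(h2b_parent))

    # -- DNA channel -------------------------------------------------------
    n_assoc = rng.binomial(dna.total_dna, dna.association_fraction)
    weights = locs_per.astype(float)
    if dna.crowding_boost != 1.0 and n_clutches > 1:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(centers).query(centers, k=2)
        weights = np.where(d[:, 1] < 50.0, weights * dna.crowding_boost, weights)
    weights /= weights.sum()
    dna_parent_assoc = rng.choice(n_clutches, size=n_assoc, p=weights)
    if dna.profile == "step":
        rr = dna.clutch_dna_radius * np.sqrt(rng.random(n_assoc))
    else:
        rr = np.abs(rng.normal(0.0, dna.clutch_dna_radius / 2.0, n_assoc))
    theta = rng.uniform(0, 2 * np.pi, n_assoc)
    assoc_xy = centers[dna_parent_assoc] + np.column_stack(
        [rr * np.cos(theta), rr * np.sin(theta)])
    n_bg = dna.total_dna - n_assoc
    bg_xy = _sample_background(rng, mask, n_bg, dna)
    dna_xy = np.vstack([assoc_xy, bg_xy])
    dna_parent = np.concatenate([dna_parent_assoc, np.full(n_bg, -1)])
    dna_z = rng.uniform(-acq.slab_halfwidth, acq.slab_halfwidth, len(dna_xy))

    # shuffle DNA records so pool membership is not encoded in record order
    perm = rng.permutation(len(dna_xy))
    dna_xy, dna_parent, dna_z = dna_xy[perm], dna_parent[perm], dna_z[perm]

    h2b_frames = _blink_frames(rng, len(h2b_xy), acq)
    dna_frames = _blink_frames(rng, len(dna_xy), acq)

    h2b = LocalizationTable.from_arrays(
        h2b_xy[:, 0], h2b_xy[:, 1], z=h2b_z, frame=h2b_frames,
        channel=np.full(len(h2b_xy), "h2b"), provenance="synthetic:h2b")
    dna_table = LocalizationTable.from_arrays(
        dna_xy[:, 0], dna_xy[:, 1], z=dna_z, frame=dna_frames,
        channel=np.full(len(dna_xy), "dna"), provenance="synthetic:dna")

    # -- fiducial beads ----------------------------------------------------
    beads_a = beads_b = None
    bead_positions = None
    if acq.n_beads:
        bead_positions = np.column_stack([
            _sample_in_mask(rng, mask, acq.n_beads),
            rng.uniform(-acq.slab_halfwidth, acq.slab_halfwidth, acq.n_beads),
        ])
        beads_a = _bead_table(rng, bead_positions, acq)
        beads_b = _bead_table(rng, bead_positions, acq)

    truth = GroundTruth(
        clutch_centers=centers, clutch_island=island_of,
        h2b_parent=h2b_parent, dna_parent=dna_parent,
        association_fraction=dna.association_fraction,
        clutch_dna_radius=dna.clutch_dna_radius,
        warp=acq.warp, z_offset=acq.z_offset,
        bead_positions=bead_positions,
    )

    out = {"h2b": h2b, "dna": dna_table, "beads_a": beads_a, "beads_b": beads_b,
           "mask": mask, "truth": truth}
    return apply_distortions(out, acq, rng=rng)


def _blink_frames(rng, n, acq: AcquisitionModel) -> np.ndarray:
    """Frame index per localization; blink_mean > 1 chains consecutive frames."""
    if acq.blink_mean <= 1.0:
        return rng.integers(0, acq.frames, n)
    frames = np.empty(n, dtype=int)
    i = 0
    while i < n:
        run = 1 + rng.poisson(acq.blink_mean - 1.0)
        start = rng.integers(0, acq.frames)
        stop = min(i + run, n)
        frames[i:stop] = np.minimum(start + np.arange(stop - i), acq.frames - 1)
        i = stop
    return frames


def _bead_table(rng, positions: np.ndarray, acq: AcquisitionModel) -> LocalizationTable:
    """One localization per bead per frame with bead-level noise."""
    n_beads = len(positions)
    frames = np.tile(np.arange(acq.frames), n_beads)
    idx = np.repeat(np.arange(n_beads), acq.frames)
    xyz = positions[idx] + rng.normal(0.0, acq.bead_noise_sd, (len(idx), 3))
    return LocalizationTable.from_arrays(
        xyz[:, 0], xyz[:, 1], z=xyz[:, 2], frame=frames,
        channel=np.full(len(idx), "bead"), provenance="synthetic:beads")


def _drift_displacement(rng, acq: AcquisitionModel) -> np.ndarray:
    lin = np.outer(np.arange(acq.frames), acq.drift_per_frame)
    if acq.drift_random_walk:
        steps = rng.normal(0.0, acq.drift_random_walk, (acq.frames, 3))
        steps[0] = 0.0
        lin = lin + np.cumsum(steps, axis=0)
    return lin


def apply_distortions(tables: dict, acq: AcquisitionModel,
                      rng: np.random.Generator | None = None) -> dict:
    """Apply noise, drift, chromatic warp, z offset and astigmatic widths.

    Channel a = DNA + ``beads_a``; channel b = H2B + ``beads_b`` (the warped,
    z-offset channel).  The true drift trajectory is recorded on the truth
    object.  With a default acquisition model (all distortion amplitudes
    zero) the tables pass through unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    drift = None
    if any(acq.drift_per_frame) or acq.drift_random_walk:
        disp = _drift_displacement(rng, acq)
        drift = DriftTrajectory(np.arange(acq.frames), disp, reference_frame=0)
    out = dict(tables)
    for key in ("h2b", "dna", "beads_a", "beads_b"):
        table = out.get(key)
        if table is None:
            continue
        df = table.data.copy()
        is_channel_b = key in ("h2b", "beads_b")
        if acq.loc_noise_sd and key in ("h2b", "dna"):
            df["x"] = df["x"] + rng.normal(0, acq.loc_noise_sd, len(df))
            df["y"] = df["y"] + rng.normal(0, acq.loc_noise_sd, len(df))
            if "z" in df:
                df["z"] = df["z"] + rng.normal(0, acq.loc_noise_sd, len(df))
        if is_channel_b and acq.warp is not None:
            warped = acq.warp.apply(df[["x", "y"]].to_numpy(float))
            df["x"], df["y"] = warped[:, 0], warped[:, 1]
        if is_channel_b and acq.z_offset:
            df["z"] = df["z"] + acq.z_offset
        if drift is not None and "frame" in df:
            d = drift.at(df["frame"].to_numpy(int))
            df["x"] = df["x"] + d[:, 0]
            df["y"] = df["y"] + d[:, 1]
            if "z" in df:
                df["z"] = df["z"] + d[:, 2]
        if acq.astigmatism is not None and "z" in df:
            z = df["z"].to_numpy(float)
            df["wx"] = acq.astigmatism.wx(z)
            df["wy"] = acq.astigmatism.wy(z)
        out[key] = LocalizationTable(df, provenance=table.provenance)
    if "truth" in out and out["truth"] is not None:
        out["truth"].drift = drift
    return out


# ---------------------------------------------------------------------------
# Presets


#: fields in which the two condition presets are allowed to differ
PRESET_DIFF_FIELDS = {
    "association_fraction", "clutch_dna_radius", "locs_per_clutch_mean",
    "clutch_sd", "min_center_spacing", "crowding_boost",
}


def condition_presets(name: str) -> tuple[NucleusModel, DnaModel]:
    """Nucleus/DNA models emulating the control and hyperacetylated conditions.

    control: association fraction 0.717, clutch-DNA radius 70 nm, larger
    clutches; tsa: fraction 0.627, radius 40 nm, smaller clutches with the
    mean centre spacing reduced by 5 nm.  All other parameters are shared.
    """
    base = NucleusModel()
    if name == "control":
        return (
            replace(base, min_center_spacing=220.0),
            DnaModel(association_fraction=0.717, clutch_dna_radius=70.0,
                     crowding_boost=1.6),
        )
    if name == "tsa":
        return (
            replace(base, clutch_sd=20.0, locs_per_clutch_mean=70.0,
                    min_center_spacing=215.0),
            DnaModel(association_fraction=0.627, clutch_dna_radius=40.0),
        )
    raise ValueError(f"unknown preset {name!r}; expected 'control' or 'tsa'")
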