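"""Astigmatic z-calibration and the two-channel registration workflow.

The axial position of a localization is encoded in its elliptical widths
(Wx, Wy); a bead scan over a known z range yields third-order polynomial
width-versus-z curves that invert the encoding.  Channel overlay proceeds as
polynomial warp -> per-channel drift correction -> affine refinement -> rigid
z translation, each step fit on fiducial beads.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .locdata_io import LocalizationTable

__all__ = [
    "ZCalibration",
    "PolynomialWarp2D",
    "AffineTransform2D",
    "DriftTrajectory",
    "RegistrationReport",
    "fit_z_calibration",
    "assign_z",
    "regroup_frames",
    "fit_polynomial_warp",
    "group_fiducials",
    "estimate_drift",
    "correct_drift",
    "refine_affine",
    "align_z_rigid",
    "registration_report",
    "match_beads",
    "save_transforms",
    "load_transforms",
]

DEFAULT_REJECT = 0.5       # sqrt-nm distance threshold for z assignment
DEFAULT_Z_GRID = 1.0       # nm grid for the width-space inversion
DEFAULT_SMOOTH_WINDOW = 50  # frames, drift moving average
DEFAULT_CHAIN_RADIUS = 100.0  # nm, fiducial grouping
DEFAULT_PERSISTENCE = 0.5  # min fraction of frames a fiducial must appear in
DEFAULT_MATCH_RADIUS = 500.0  # nm, cross-channel bead matching


@dataclass
class ZCalibration:
    """Third-order polynomial width curves Wx(z), Wy(z) (coeffs high->low)."""

    cx: np.ndarray
    cy: np.ndarray
    z_range: tuple[float, float]
    rms: float = math.nan

    def wx(self, z):
        return np.polyval(self.cx, z)

    def wy(self, z):
        return np.polyval(self.cy, z)

    def to_dict(self):
        return {"cx": list(self.cx), "cy": list(self.cy),
                "z_range": list(self.z_range), "rms": self.rms}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["cx"]), np.asarray(d["cy"]),
                   tuple(d["z_range"]), d.get("rms", math.nan))


@dataclass
class PolynomialWarp2D:
    """Full second-order bivariate polynomial map (x, y) -> (x', y').

    Each output coordinate is a linear combination of the monomials
    ``(1, u, v, u², uv, v²)`` of the normalized coordinates
    ``u = (x - center_x) / scale``, ``v = (y - center_y) / scale``.
    Normalization keeps the quadratic design matrix well conditioned over
    tens-of-micron fields.
    """

    coeff_x: np.ndarray
    coeff_y: np.ndarray
    rms: float = math.nan
    center: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0

    def design(self, xy: np.ndarray) -> np.ndarray:
        u = (xy[:, 0] - self.center[0]) / self.scale
        v = (xy[:, 1] - self.center[1]) / self.scale
        return np.column_stack([np.ones_like(u), u, v, u * u, u * v, v * v])

    def apply(self, xy: np.ndarray) -> np.ndarray:
        A = self.design(np.asarray(xy, float))
        return np.column_stack([A @ self.coeff_x, A @ self.coeff_y])

    @classmethod
    def identity(cls) -> "PolynomialWarp2D":
        cx = np.zeros(6); cx[1] = 1.0
        cy = np.zeros(6); cy[2] = 1.0
        return cls(cx, cy, 0.0)

    def to_dict(self):
        return {"coeff_x": list(self.coeff_x), "coeff_y": list(self.coeff_y),
                "rms": self.rms, "center": list(self.center),
                "scale": self.scale}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["coeff_x"]), np.asarray(d["coeff_y"]),
                   d.get("rms", math.nan), tuple(d.get("center", (0.0, 0.0))),
                   d.get("scale", 1.0))


@dataclass
class AffineTransform2D:
    linear: np.ndarray          # 2x2
    translation: np.ndarray     # 2
    rms: float = math.nan

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, float) @ self.linear.T + self.translation

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), 0.0)

    def to_dict(self):
        return {"linear": self.linear.tolist(),
                "translation": self.translation.tolist(), "rms": self.rms}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["linear"]), np.asarray(d["translation"]),
                   d.get("rms", math.nan))


@dataclass
class DriftTrajectory:
    """Per-frame (dx, dy, dz) displacement, zero at the reference frame."""

    frames: np.ndarray          # all frames in the dataset's range
    displacement: np.ndarray    # (n_frames, 3)
    reference_frame: int
    n_extrapolated: int = 0

    def at(self, frame) -> np.ndarray:
        idx = np.clip(np.searchsorted(self.frames, frame), 0, len(self.frames) - 1)
        return self.displacement[idx]

    def to_dict(self):
        return {"frames": self.frames.tolist(),
                "displacement": self.displacement.tolist(),
                "reference_frame": int(self.reference_frame),
                "n_extrapolated": int(self.n_extrapolated)}

    @classmethod
    def from_dict(cls, d):
        return cls(np.asarray(d["frames"]), np.asarray(d["displacement"]),
                   d["reference_frame"], d.get("n_extrapolated", 0))


@dataclass
class RegistrationReport:
    residuals: np.ndarray       # per-bead 3D distance after alignment, nm
    z_offset: float = 0.0

    @property
    def mean(self) -> float:
        return float(np.mean(self.residuals))

    @property
    def sd(self) -> float:
        return float(np.std(self.residuals, ddof=0))

    def summary(self) -> str:
        return f"{self.mean:.1f} ± {self.sd:.1f} nm (n={len(self.residuals)})"


# ---------------------------------------------------------------------------
# z calibration / assignment


def fit_z_calibration(bead_scan: LocalizationTable, z: np.ndarray | None = None,
                      step: float = 10.0) -> ZCalibration:
    """Fit third-order Wx(z)/Wy(z) curves from an astigmatic bead scan.

    ``z`` gives the stage position per record; if omitted it is derived from
    the frame index as ``frame * step`` centred on the scan midpoint (the
    default emulates a 10 nm-step scan).
    """
    if not (bead_scan.has("wx") and bead_scan.has("wy")):
        raise ValueError("bead scan must carry wx and wy widths")
    wx = bead_scan.column("wx").astype(float)
    wy = bead_scan.column("wy").astype(float)
    if z is None:
        frames = bead_scan.column("frame").astype(float)
        z = (frames - frames.mean()) * step
    z = np.asarray(z, float)
    if len(np.unique(z)) < 20:
        raise ValueError("calibration scan must cover >= 20 distinct z positions")
    if np.any(wx <= 0) or np.any(wy <= 0):
        raise ValueError("widths must be positive")
    cx = np.polyfit(z, wx, 3)
    cy = np.polyfit(z, wy, 3)
    rms = float(np.sqrt(np.mean((np.polyval(cx, z) - wx) ** 2 +
                                (np.polyval(cy, z) - wy) ** 2)))
    z_range = (float(z.min()), float(z.max()))
    calib = ZCalibration(cx, cy, z_range, rms)
    # the width difference must identify z uniquely over the range
    grid = np.linspace(*z_range, 201)
    diff = calib.wx(grid) - calib.wy(grid)
    d = np.diff(diff)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(
            "calibration rejected: Wx(z) - Wy(z) is not monotone over the scan "
            "range, z is not identifiable from the widths"
        )
    return calib


def assign_z(table: LocalizationTable, calib: ZCalibration,
             grid_step: float = DEFAULT_Z_GRID,
             reject: float = DEFAULT_REJECT):
    """Assign z by nearest match in square-root width space.

    For each record, z minimizes ``(sqrt(wx) - sqrt(Wx(z)))² +
    (sqrt(wy) - sqrt(Wy(z)))²`` on a ``grid_step`` nm grid over the
    calibration range.  Records whose minimum distance exceeds ``reject``
    (sqrt-nm) or with non-positive widths are dropped.

    Returns ``(table_with_z, n_dropped)``.
    """
    if not (table.has("wx") and table.has("wy")):
        raise ValueError("assign_z requires wx and wy columns")
    wx = table.column("wx").astype(float)
    wy = table.column("wy").astype(float)
    ok = np.isfinite(wx) & np.isfinite(wy) & (wx > 0) & (wy > 0)
    zgrid = np.arange(calib.z_range[0], calib.z_range[1] + grid_step / 2, grid_step)
    sx = np.sqrt(np.clip(calib.wx(zgrid), 0, None))
    sy = np.sqrt(np.clip(calib.wy(zgrid), 0, None))
    z_out = np.full(len(table), np.nan)
    dist_out = np.full(len(table), np.inf)
    idx = np.nonzero(ok)[0]
    chunk = 20000
    for start in range(0, len(idx), chunk):
        sel = idx[start:start + chunk]
        dx = np.sqrt(wx[sel])[:, None] - sx[None, :]
        dy = np.sqrt(wy[sel])[:, None] - sy[None, :]
        D = dx * dx + dy * dy
        best = np.argmin(D, axis=1)
        z_out[sel] = zgrid[best]
        dist_out[sel] = np.sqrt(D[np.arange(len(sel)), best])
    keep = ok & (dist_out <= reject)
    out = table.with_columns(z=z_out).take(np.nonzero(keep)[0])
    return out, int(len(table) - keep.sum())


# ---------------------------------------------------------------------------
# Frame handling


def regroup_frames(table: LocalizationTable, group: int = 5) -> LocalizationTable:
    """Replace frame indices by ``floor(frame / group)``.

    Emulates, at the localization level, the raw-image summation of ``group``
    sequential frames into one effective exposure.
    """
    if group < 1:
        raise ValueError("group must be >= 1")
    if group == 1:
        return table
    if not table.has("frame"):
        raise ValueError("regroup_frames requires frame indices")
    return table.with_columns(frame=table.column("frame").astype(int) // group)


# ---------------------------------------------------------------------------
# Warps and affine refinement


def fit_polynomial_warp(beads_a: np.ndarray, beads_b: np.ndarray) -> PolynomialWarp2D:
    """Least-squares second-order warp mapping ``beads_a`` onto ``beads_b``."""
    beads_a = np.asarray(beads_a, float)
    beads_b = np.asarray(beads_b, float)
    if len(beads_a) != len(beads_b):
        raise ValueError("matched bead arrays must have equal length")
    if len(beads_a) < 6:
        raise ValueError("polynomial warp requires >= 6 matched bead pairs")
    center = tuple(beads_a.mean(axis=0))
    scale = float(max(beads_a.std(axis=0).max(), 1.0))
    warp = PolynomialWarp2D(np.zeros(6), np.zeros(6), center=center, scale=scale)
    A = warp.design(beads_a)
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError("bead layout is rank-deficient for a second-order fit")
    warp.coeff_x, *_ = np.linalg.lstsq(A, beads_b[:, 0], rcond=None)
    warp.coeff_y, *_ = np.linalg.lstsq(A, beads_b[:, 1], rcond=None)
    res = warp.apply(beads_a) - beads_b
    warp.rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    return warp


def refine_affine(beads_a: np.ndarray, beads_b: np.ndarray) -> AffineTransform2D:
    """Least-squares affine transform mapping ``beads_a`` onto ``beads_b``."""
    beads_a = np.asarray(beads_a, float)
    beads_b = np.asarray(beads_b, float)
    if len(beads_a) < 3:
        raise ValueError("affine refinement requires >= 3 matched beads")
    A = np.column_stack([beads_a, np.ones(len(beads_a))])
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("beads are collinear; affine fit is degenerate")
    sol, *_ = np.linalg.lstsq(A, beads_b, rcond=None)
    tf = AffineTransform2D(sol[:2].T.copy(), sol[2].copy())
    res = tf.apply(beads_a) - beads_b
    tf.rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    return tf


def align_z_rigid(z_a: np.ndarray, z_b: np.ndarray) -> float:
    """Rigid z offset (mean of z_a - z_b) to apply to channel b."""
    z_a = np.asarray(z_a, float)
    z_b = np.asarray(z_b, float)
    if z_a.size == 0 or z_a.shape != z_b.shape:
        raise ValueError("need matched beads with z in both channels")
    return float(np.mean(z_a - z_b))


# ---------------------------------------------------------------------------
# Fiducials and drift


@dataclass
class BeadCluster:
    indices: np.ndarray
    position: np.ndarray        # mean (x, y[, z])
    n_frames: int


def group_fiducials(table: LocalizationTable,
                    chain_radius: float = DEFAULT_CHAIN_RADIUS,
                    min_persistence: float = DEFAULT_PERSISTENCE) -> list[BeadCluster]:
    """Group fiducial localizations into per-bead clusters.

    Localizations within ``chain_radius`` are chained into clusters
    (gap-tolerant: spatial chaining does not require consecutive frames);
    clusters observed in fewer than ``min_persistence`` of the dataset's
    frames are discarded.
    """
    from scipy import sparse
    from scipy.sparse.csgraph import connected_components

    if len(table) == 0:
        raise ValueError("no fiducial localizations")
    xy = table.xy
    frames = table.column("frame").astype(int) if table.has("frame") else np.zeros(len(table), int)
    n_total_frames = int(frames.max() - frames.min() + 1)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(chain_radius, output_type="ndarray")
    graph = sparse.coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                              shape=(len(xy), len(xy)))
    _, labels = connected_components(graph, directed=False)
    clusters = []
    for lab in np.unique(labels):
        members = np.nonzero(labels == lab)[0]
        seen = len(np.unique(frames[members]))
        if seen / n_total_frames < min_persistence:
            continue
        cols = ["x", "y"] + (["z"] if table.has("z") else [])
        pos = table.data.iloc[members][cols].to_numpy(float).mean(axis=0)
        clusters.append(BeadCluster(members, pos, seen))
    if not clusters:
        raise ValueError("no persistent fiducial beads; registration cannot proceed")
    return clusters


def estimate_drift(table: LocalizationTable, clusters: list[BeadCluster],
                   smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                   reference_frame: int | None = None) -> DriftTrajectory:
    """Mean fiducial displacement per frame, smoothed and gap-interpolated."""
    if not clusters:
        raise ValueError("estimate_drift requires >= 1 persistent bead")
    frames = table.column("frame").astype(int)
    f_lo, f_hi = int(frames.min()), int(frames.max())
    all_frames = np.arange(f_lo, f_hi + 1)
    if reference_frame is None:
        reference_frame = f_lo
    has_z = table.has("z")
    dims = 3 if has_z else 2
    acc = np.zeros((len(all_frames), 3))
    wgt = np.zeros(len(all_frames))
    n_extrap = 0
    for cluster in clusters:
        cf = frames[cluster.indices]
        cols = ["x", "y"] + (["z"] if has_z else [])
        pos = table.data.iloc[cluster.indices][cols].to_numpy(float)
        # average duplicate observations within a frame
        order = np.argsort(cf, kind="stable")
        cf, pos = cf[order], pos[order]
        uf, start = np.unique(cf, return_index=True)
        means = np.add.reduceat(pos, start, axis=0) / np.diff(
            np.append(start, len(cf)))[:, None]
        # reference = mean over the window of frames nearest the reference
        # frame (a single-frame reference would inject its full localization
        # noise as a constant offset into the whole trajectory)
        wsel = np.argsort(np.abs(uf - reference_frame), kind="stable")
        ref_pos = means[wsel[:max(1, smooth_window)]].mean(axis=0)
        disp = means - ref_pos
        interp = np.empty((len(all_frames), dims))
        for d in range(dims):
            interp[:, d] = np.interp(all_frames, uf, disp[:, d])
        n_extrap += int((all_frames < uf[0]).sum() + (all_frames > uf[-1]).sum())
        acc[:, :dims] += interp
        wgt += 1.0
    traj = acc / wgt[:, None]
    if smooth_window > 1:
        # reflect padding: edge replication would over-weight the endpoint
        # samples, leaking their noise into the pinned reference value
        kernel = np.ones(smooth_window) / smooth_window
        for d in range(3):
            padded = np.pad(traj[:, d], smooth_window, mode="reflect")
            traj[:, d] = np.convolve(padded, kernel, mode="same")[smooth_window:-smooth_window]
    # pin the trajectory to zero at the reference frame
    traj = traj - traj[np.searchsorted(all_frames, reference_frame)]
    return DriftTrajectory(all_frames, traj, reference_frame, n_extrap)


def correct_drift(table: LocalizationTable, traj: DriftTrajectory) -> LocalizationTable:
    """Subtract the drift displacement of each record's frame."""
    frames = table.column("frame").astype(int)
    disp = traj.at(frames)
    df = table.data.copy()
    df["x"] = df["x"] - disp[:, 0]
    df["y"] = df["y"] - disp[:, 1]
    if table.has("z"):
        df["z"] = df["z"] - disp[:, 2]
    return LocalizationTable(df, provenance=table.provenance)


# ---------------------------------------------------------------------------
# Matching and reporting


def match_beads(pos_a: np.ndarray, pos_b: np.ndarray,
                radius: float = DEFAULT_MATCH_RADIUS):
    """Mutual-nearest-neighbour bead matching within ``radius`` (lateral)."""
    pos_a = np.asarray(pos_a, float)
    pos_b = np.asarray(pos_b, float)
    ta, tb = cKDTree(pos_a[:, :2]), cKDTree(pos_b[:, :2])
    _, ab = tb.query(pos_a[:, :2], distance_upper_bound=radius)
    _, ba = ta.query(pos_b[:, :2], distance_upper_bound=radius)
    pairs = [(i, j) for i, j in enumerate(ab)
             if j < len(pos_b) and ba[j] == i]
    if not pairs:
        return np.empty((0, 2), int)
    return np.asarray(pairs, int)


def registration_report(beads_a: np.ndarray, beads_b_aligned: np.ndarray,
                        z_offset: float = 0.0) -> RegistrationReport:
    """Per-bead 3D residual distances between matched, aligned bead positions."""
    beads_a = np.atleast_2d(np.asarray(beads_a, float))
    beads_b_aligned = np.atleast_2d(np.asarray(beads_b_aligned, float))
    res = np.linalg.norm(beads_a - beads_b_aligned, axis=1)
    return RegistrationReport(res, z_offset)


# ---------------------------------------------------------------------------
# Serialization


def save_transforms(path, warp: PolynomialWarp2D | None = None,
                    affine: AffineTransform2D | None = None,
                    z_offset: float | None = None,
                    drift_a: DriftTrajectory | None = None,
                    drift_b: DriftTrajectory | None = None,
                    calibration: ZCalibration | None = None) -> None:
    payload = {}
    if warp is not None:
        payload["warp"] = warp.to_dict()
    if affine is not None:
        payload["affine"] = affine.to_dict()
    if z_offset is not None:
        payload["z_offset"] = z_offset
    if drift_a is not None:
        payload["drift_a"] = drift_a.to_dict()
    if drift_b is not None:
        payload["drift_b"] = drift_b.to_dict()
    if calibration is not None:
        payload["calibration"] = calibration.to_dict()
    Path(path).write_text(json.dumps(payload))


def load_transforms(path) -> dict:
    payload = json.loads(Path(path).read_text())
    out = {}
    if "warp" in payload:
        out["warp"] = PolynomialWarp2D.from_dict(payload["warp"])
    if "affine" in payload:
        out["affine"] = AffineTransform2D.from_dict(payload["affine"])
    if "z_offset" in payload:
        out["z_offset"] = payload["z_offset"]
    for key in ("drift_a", "drift_b"):
        if key in payload:
            out[key] = DriftTrajectory.from_dict(payload[key])
    if "calibration" in payload:
        out["calibration"] = ZCalibration.from_dict(payload["calibration"])
    return out
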