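"""Mucociliary clearance (MCC) summary statistics from bead trajectories.

Angle convention
----------------
Each trajectory's direction is the angle θᵢ between the channel axis and
its start→end line, measured from the unit vector n̂ that points toward the
channel inlet: θ = 0° is flow exactly toward the inlet, ±180° toward the
outlet.  The polar order parameter is

    PO = û · n̂,   û = ⟨[sin θᵢ, cos θᵢ]⟩,

which with this convention reduces to the mean of cos θᵢ, so PO ∈ [−1, 1]:
1 for perfect alignment toward the inlet, −1 toward the outlet, and ≈0 for
isotropic or wall-bound (perpendicular) flow.  Reversing n̂ negates PO
exactly.

Coverage
--------
Per-step bead velocities are time-averaged on a regular Eulerian grid
(U(x, y) = u x̂ + v ŷ); the coherent area with measurable flow, A_mcc, is
the alpha-shape (concave hull with disk radius alpha) over the corner
points of active grid cells, and coverage is C_mcc = A_mcc / A_total.  The
area-averaged transport speed is M̄ = C_mcc · ⟨|U|⟩ with ⟨|U|⟩ the mean
flow magnitude over active cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

from .core import ChannelGeometry, TrajectorySet

logger = logging.getLogger(__name__)

DEFAULT_GRID_UM = 20.0


@dataclass
class VelocityField:
    """Time-averaged Eulerian velocity field on a regular grid."""

    grid_um: float
    u: np.ndarray  # (ny, nx) mean x-velocity, μm/s; NaN where inactive
    v: np.ndarray  # (ny, nx) mean y-velocity
    n_obs: np.ndarray  # (ny, nx) observation counts
    origin_um: tuple[float, float] = (0.0, 0.0)

    @property
    def active_mask(self) -> np.ndarray:
        return self.n_obs > 0

    @property
    def speed(self) -> np.ndarray:
        """Flow magnitude |U| per cell (NaN where inactive)."""
        return np.hypot(self.u, self.v)

    def active_cell_centers_um(self) -> np.ndarray:
        iy, ix = np.nonzero(self.active_mask)
        x = self.origin_um[0] + (ix + 0.5) * self.grid_um
        y = self.origin_um[1] + (iy + 0.5) * self.grid_um
        return np.column_stack([x, y])

    def active_cell_corners_um(self) -> np.ndarray:
        """Unique corner points of all active cells."""
        iy, ix = np.nonzero(self.active_mask)
        corners = set()
        for j, i in zip(iy, ix):
            for dj in (0, 1):
                for di in (0, 1):
                    corners.add((i + di, j + dj))
        pts = np.array(sorted(corners), dtype=float)
        if pts.size == 0:
            return pts.reshape(0, 2)
        pts[:, 0] = self.origin_um[0] + pts[:, 0] * self.grid_um
        pts[:, 1] = self.origin_um[1] + pts[:, 1] * self.grid_um
        return pts


@dataclass
class MCCStats:
    """Pooled per-sample MCC summary."""

    po: float
    coverage: float  # C_mcc
    area_avg_speed_um_s: float  # M̄
    mean_active_speed_um_s: float  # ⟨|U|⟩
    angle_hist_counts: np.ndarray
    angle_hist_edges_deg: np.ndarray
    n_trajectories: int


def trajectory_angles(
    tracks: TrajectorySet, geometry: ChannelGeometry
) -> np.ndarray:
    """Per-trajectory angle θᵢ (deg) of the start→end line from the inlet axis.

    Angles lie in (−180, 180]; trajectories with zero net displacement have
    no direction and are excluded (their count is logged).
    """
    n = geometry.n_hat
    angles = []
    dropped = 0
    for t in tracks:
        if t.n_nodes < 2:
            dropped += 1
            continue
        d = t.displacement_um()
        if d[0] == 0 and d[1] == 0:
            dropped += 1
            continue
        dot = d[0] * n[0] + d[1] * n[1]
        cross = n[0] * d[1] - n[1] * d[0]
        ang = np.degrees(np.arctan2(cross, dot))
        angles.append(180.0 if ang == -180.0 else float(ang))
    if dropped:
        logger.info("trajectory_angles: excluded %d degenerate tracks", dropped)
    return np.asarray(angles)


def polar_order(angles_deg: np.ndarray) -> float:
    """PO = û·n̂ with û the mean of [sin θᵢ, cos θᵢ] and n̂ the inlet axis.

    In the frame where θ is measured from n̂, n̂ = [0, 1], so PO is the mean
    cosine of the trajectory angles.  Raises on an empty angle set (PO is
    undefined without trajectories).
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise ValueError("PO undefined: empty angle set")
    th = np.radians(angles_deg)
    u_hat = np.array([np.mean(np.sin(th)), np.mean(np.cos(th))])
    n_hat = np.array([0.0, 1.0])  # inlet axis in the angle frame
    return float(u_hat @ n_hat)


def angle_histogram(
    angles_deg: np.ndarray, n_bins: int = 36
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of trajectory angles over (−180, 180] with equal bins."""
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    # np.histogram bins are half-open [lo, hi); shift exact -180 into the
    # (−180, 180] convention by mapping it to +180
    a = np.asarray(angles_deg, dtype=float).copy()
    a[a <= -180.0] += 360.0
    counts, _ = np.histogram(a, bins=edges)
    # right-closed: values exactly at +180 fall in the last bin already
    return counts, edges


def velocity_field(
    tracks: TrajectorySet,
    grid_um: float = DEFAULT_GRID_UM,
    field_size_um: tuple[float, float] | None = None,
) -> VelocityField:
    """Grid per-step velocities into a time-averaged Eulerian field.

    Each step's velocity is assigned to the grid cell containing the step
    midpoint (symmetric, avoids directional bias); a cell's (u, v) is the
    mean over all observations it received, since several beads may pass
    the same location.
    """
    if grid_um <= 0:
        raise ValueError("grid_um must be > 0")
    if field_size_um is None:
        field_size_um = tracks.field_size_um
    if field_size_um is None:
        raise ValueError("field_size_um unknown; pass it explicitly")
    nx = max(1, int(np.ceil(field_size_um[0] / grid_um)))
    ny = max(1, int(np.ceil(field_size_um[1] / grid_um)))
    su = np.zeros((ny, nx))
    sv = np.zeros((ny, nx))
    cnt = np.zeros((ny, nx), dtype=int)
    rate = tracks.frame_rate_hz
    for t in tracks:
        if t.n_nodes < 2:
            continue
        steps = t.step_vectors_um()
        dt = np.diff(t.frames) / rate
        vel = steps / dt[:, None]
        mx = 0.5 * (t.x_um[1:] + t.x_um[:-1])
        my = 0.5 * (t.y_um[1:] + t.y_um[:-1])
        ix = np.clip((mx // grid_um).astype(int), 0, nx - 1)
        iy = np.clip((my // grid_um).astype(int), 0, ny - 1)
        np.add.at(su, (iy, ix), vel[:, 0])
        np.add.at(sv, (iy, ix), vel[:, 1])
        np.add.at(cnt, (iy, ix), 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(cnt > 0, su / cnt, np.nan)
        v = np.where(cnt > 0, sv / cnt, np.nan)
    return VelocityField(grid_um, u, v, cnt)


def alpha_shape_area(points: np.ndarray, alpha_um: float) -> float:
    """Area of the alpha shape (concave hull) of a 2-D point set.

    The alpha shape keeps the Delaunay triangles whose circumradius does
    not exceed ``alpha_um``; its area is the summed area of kept triangles
    (Delaunay triangles are interior-disjoint).  Fewer than 3 points, or a
    degenerate (collinear) set, enclose zero area.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return 0.0
    try:
        tri = Delaunay(points)
    except Exception:  # collinear / degenerate input
        return 0.0
    area = 0.0
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        ab, ac, bc = b - a, c - a, c - b
        cross = abs(ab[0] * ac[1] - ab[1] * ac[0])
        if cross == 0:
            continue
        tri_area = 0.5 * cross
        # circumradius R = (|ab||ac||bc|) / (4 * area)
        r = (
            np.hypot(*ab) * np.hypot(*ac) * np.hypot(*bc) / (4.0 * tri_area)
        )
        if r <= alpha_um:
            area += tri_area
    return float(area)


def mcc_coverage(
    field: VelocityField,
    geometry: ChannelGeometry,
    alpha_um: float | None = None,
) -> float:
    """C_mcc: fraction of the field of view with measurable transport.

    The coherent active area is the alpha shape over the corner points of
    active grid cells (so a fully active grid covers the full field);
    ``alpha_um`` defaults to twice the grid spacing.  The result is clipped
    to [0, 1].
    """
    if alpha_um is None:
        alpha_um = 2.0 * field.grid_um
    if field.active_mask.sum() < 3:
        return 0.0
    pts = field.active_cell_corners_um()
    a_mcc = alpha_shape_area(pts, alpha_um)
    return float(np.clip(a_mcc / geometry.field_area_um2, 0.0, 1.0))


def area_avg_speed(field: VelocityField, coverage: float) -> float:
    """M̄ = C_mcc · ⟨|U|⟩, the coverage-weighted mean transport speed."""
    mask = field.active_mask
    if not mask.any():
        return 0.0
    mean_speed = float(np.nanmean(field.speed[mask]))
    return coverage * mean_speed


def compute_stats(
    tracks: TrajectorySet,
    geometry: ChannelGeometry,
    grid_um: float = DEFAULT_GRID_UM,
    alpha_um: float | None = None,
    n_bins: int = 36,
) -> MCCStats:
    """Full per-movie MCC summary from (already filtered) trajectories."""
    angles = trajectory_angles(tracks, geometry)
    po = polar_order(angles) if angles.size else float("nan")
    counts, edges = angle_histogram(angles, n_bins) if angles.size else (
        np.zeros(n_bins, dtype=int),
        np.linspace(-180, 180, n_bins + 1),
    )
    field = velocity_field(tracks, grid_um)
    cov = mcc_coverage(field, geometry, alpha_um)
    m_bar = area_avg_speed(field, cov)
    mask = field.active_mask
    mean_speed = float(np.nanmean(field.speed[mask])) if mask.any() else 0.0
    return MCCStats(
        po=po,
        coverage=cov,
        area_avg_speed_um_s=m_bar,
        mean_active_speed_um_s=mean_speed,
        angle_hist_counts=counts,
        angle_hist_edges_deg=edges,
        n_trajectories=int(angles.size),
    )


def pool_sample(
    per_movie_angles: list[np.ndarray],
    per_movie_stats: list[MCCStats],
    field_areas_um2: list[float] | None = None,
    n_bins: int = 36,
) -> MCCStats:
    """Pool several movies of one sample.

    Angles are concatenated before recomputing PO and the histogram (the
    statistic of the pooled trajectories, not a mean of per-movie POs);
    field-level metrics (coverage, speeds) are averaged weighted by field
    area.
    """
    if not per_movie_stats:
        raise ValueError("need at least one movie")
    angles = np.concatenate([np.asarray(a, dtype=float) for a in per_movie_angles])
    po = polar_order(angles) if angles.size else float("nan")
    counts, edges = angle_histogram(angles, n_bins) if angles.size else (
        np.zeros(n_bins, dtype=int),
        np.linspace(-180, 180, n_bins + 1),
    )
    w = np.asarray(
        field_areas_um2
        if field_areas_um2 is not None
        else [1.0] * len(per_movie_stats),
        dtype=float,
    )
    w = w / w.sum()
    cov = float(sum(wi * s.coverage for wi, s in zip(w, per_movie_stats)))
    m_bar = float(
        sum(wi * s.area_avg_speed_um_s for wi, s in zip(w, per_movie_stats))
    )
    mean_speed = float(
        sum(wi * s.mean_active_speed_um_s for wi, s in zip(w, per_movie_stats))
    )
    return MCCStats(
        po=po,
        coverage=cov,
        area_avg_speed_um_s=m_bar,
        mean_active_speed_um_s=mean_speed,
        angle_hist_counts=counts,
        angle_hist_edges_deg=edges,
        n_trajectories=int(angles.size),
    )
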