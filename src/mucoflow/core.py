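"""Core data containers shared across the pipeline.

All physical quantities carry explicit units in their names: positions in
micrometres (``_um``), times via acquisition frame rate (``frame_rate_hz``),
speeds in μm/s.  Frames are 0-based; the time of frame *k* is
``k / frame_rate_hz``.  Image coordinates have the origin at the top-left
corner, x pointing rightward along the channel axis and y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CalibrationError(ValueError):
    """Raised when required spatial/temporal calibration is missing or invalid."""


@dataclass
class VideoStack:
    """A calibrated grayscale frame sequence.

    Parameters
    ----------
    frames : ndarray, shape (t, y, x)
        Intensity values; any numeric dtype.
    frame_rate_hz : float
        Acquisition rate in frames per second.
    pixel_size_um : float
        Physical size of one pixel edge in micrometres.
    """

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (t, y, x) array, got shape {self.frames.shape}"
            )
        if self.frame_rate_hz <= 0:
            raise CalibrationError("frame_rate_hz must be > 0")
        if self.pixel_size_um <= 0:
            raise CalibrationError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate_hz / 2.0


@dataclass
class Spot:
    """A single bead detection in one frame (position in μm)."""

    frame: int
    x_um: float
    y_um: float
    intensity: float = 0.0


@dataclass
class Trajectory:
    """Time-ordered track of one bead.

    ``frames`` must be strictly increasing; positions are in μm.
    """

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    label: str | None = None  # optional ground-truth / classifier label

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.frames) == len(self.x_um) == len(self.y_um)):
            raise ValueError("frames, x_um, y_um must have equal length")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise ValueError(
                f"track {self.track_id}: frames must be strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_nodes(self) -> int:
        return len(self.frames)

    def displacement_um(self) -> np.ndarray:
        """Net start→end displacement vector (dx, dy) in μm."""
        return np.array(
            [self.x_um[-1] - self.x_um[0], self.y_um[-1] - self.y_um[0]]
        )

    def step_vectors_um(self) -> np.ndarray:
        """Per-step displacement vectors, shape (n_nodes - 1, 2)."""
        return np.column_stack([np.diff(self.x_um), np.diff(self.y_um)])

    def step_speeds_um_s(self, frame_rate_hz: float) -> np.ndarray:
        """Per-step speeds in μm/s (displacement / elapsed time per step)."""
        steps = self.step_vectors_um()
        dt = np.diff(self.frames) / frame_rate_hz
        return np.hypot(steps[:, 0], steps[:, 1]) / dt


@dataclass
class TrajectorySet:
    """A collection of trajectories with acquisition metadata."""

    trajectories: list[Trajectory]
    frame_rate_hz: float
    pixel_size_um: float | None = None
    field_size_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.trajectories]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def subset(self, keep: np.ndarray) -> "TrajectorySet":
        """New set containing trajectories where ``keep`` is True (order kept)."""
        kept = [t for t, k in zip(self.trajectories, keep) if k]
        return TrajectorySet(
            kept, self.frame_rate_hz, self.pixel_size_um, self.field_size_um
        )


@dataclass
class ChannelGeometry:
    """Channel-axis geometry used for angle and coverage statistics.

    ``inlet_direction`` is the unit vector n̂ pointing toward the channel
    inlet, in image coordinates (x rightward, y downward).  All trajectory
    angles are measured from this vector, so 0° means flow toward the inlet
    and ±180° toward the outlet.  ``field_area_um2`` is the total visible
    tissue surface area A_total.
    """

    inlet_direction: tuple[float, float] = (-1.0, 0.0)
    field_area_um2: float = 1200.0 * 1200.0

    def __post_init__(self) -> None:
        v = np.asarray(self.inlet_direction, dtype=float)
        n = np.hypot(v[0], v[1])
        if n == 0:
            raise ValueError("inlet_direction must be nonzero")
        self.inlet_direction = (v[0] / n, v[1] / n)
        if self.field_area_um2 <= 0:
            raise ValueError("field_area_um2 must be > 0")

    @property
    def n_hat(self) -> np.ndarray:
        return np.asarray(self.inlet_direction, dtype=float)

    def reversed(self) -> "ChannelGeometry":
        nx, ny = self.inlet_direction
        return ChannelGeometry((-nx, -ny), self.field_area_um2)
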