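"""Synthetic microscopy scenes with exact ground truth.

Every downstream stage of the pipeline (ciliary-beat-frequency mapping,
bead tracking, background classification, transport statistics and
immunofluorescence quantification) is exercised against scenes generated
here, for which the true frequencies, track labels, area fractions and
crescent lengths are known analytically.  All generators are
bit-reproducible under a fixed seed.

Default scene parameters mirror the acquisition conditions of the airway
chip assays they emulate: high-speed cilia recordings at 200 frames/s with
~3 px/μm over a 166 μm field, and bead transport movies at 30 frames/s over
~1200 μm fields with 1-μm tracer beads.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Trajectory, TrajectorySet, VideoStack

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthManifest:
    """Exact ground truth for one synthetic scene.

    Only the fields relevant to the scene type are populated.  The manifest
    round-trips losslessly through JSON and is sufficient to compute every
    downstream target metric without re-reading pixels.
    """

    track_labels: dict[int, str] | None = None  # track_id -> "mcc"|"background"
    patches: list[dict] | None = None  # cilia patches incl. frequency_hz
    positive_area_fraction: float | None = None
    crescent_lengths_um: list[float] | None = None
    field_size_um: tuple[float, float] | None = None
    pixel_size_um: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def total_crescent_length_um(self) -> float | None:
        if self.crescent_lengths_um is None:
            return None
        return float(sum(self.crescent_lengths_um))

    def to_json(self, path: str | Path) -> None:
        d = {
            "track_labels": self.track_labels,
            "patches": self.patches,
            "positive_area_fraction": self.positive_area_fraction,
            "crescent_lengths_um": self.crescent_lengths_um,
            "field_size_um": list(self.field_size_um) if self.field_size_um else None,
            "pixel_size_um": self.pixel_size_um,
            "extras": self.extras,
        }
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        labels = d.get("track_labels")
        if labels is not None:
            labels = {int(k): v for k, v in labels.items()}
        fs = d.get("field_size_um")
        return cls(
            track_labels=labels,
            patches=d.get("patches"),
            positive_area_fraction=d.get("positive_area_fraction"),
            crescent_lengths_um=d.get("crescent_lengths_um"),
            field_size_um=tuple(fs) if fs else None,
            pixel_size_um=d.get("pixel_size_um"),
            extras=d.get("extras", {}),
        )


# ---------------------------------------------------------------------------
# Ciliary beat scenes
# ---------------------------------------------------------------------------


@dataclass
class CiliaPatch:
    """A circular patch of beating cilia: intensity oscillates sinusoidally."""

    center_px: tuple[float, float]  # (x, y)
    radius_px: float
    frequency_hz: float
    phase_rad: float = 0.0
    amplitude: float = 40.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")


@dataclass
class CiliaSceneSpec:
    """Parameters of a synthetic high-speed ciliary beat recording."""

    field_size_px: tuple[int, int] = (160, 160)  # (height, width)
    pixel_size_um: float = 1.0 / 3.0
    frame_rate_hz: float = 200.0
    n_frames: int = 512
    patches: list[CiliaPatch] = field(default_factory=list)
    baseline: float = 100.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        nyquist = self.frame_rate_hz / 2.0
        for p in self.patches:
            if p.frequency_hz >= nyquist:
                raise ValueError(
                    f"patch frequency {p.frequency_hz} Hz is at or above the "
                    f"Nyquist limit {nyquist} Hz"
                )


def patch_mask(spec: CiliaSceneSpec, patch: CiliaPatch) -> np.ndarray:
    """Boolean mask of pixels inside one patch."""
    h, w = spec.field_size_px
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = patch.center_px
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= patch.radius_px**2


def gen_cilia_video(spec: CiliaSceneSpec) -> tuple[VideoStack, GroundTruthManifest]:
    """Render a cilia scene: sinusoidal patches on a noisy static background.

    Pixels inside patch *p* follow ``baseline + A_p sin(2π f_p t + φ_p)``
    plus Gaussian noise; all other pixels are baseline plus noise.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    t = np.arange(spec.n_frames) / spec.frame_rate_hz
    frames = np.full((spec.n_frames, h, w), spec.baseline, dtype=np.float32)
    patch_records = []
    for p in spec.patches:
        mask = patch_mask(spec, p)
        signal = p.amplitude * np.sin(
            2 * np.pi * p.frequency_hz * t + p.phase_rad
        )
        frames[:, mask] += signal[:, None].astype(np.float32)
        patch_records.append(
            {
                "center_px": list(p.center_px),
                "radius_px": p.radius_px,
                "frequency_hz": p.frequency_hz,
                "phase_rad": p.phase_rad,
                "amplitude": p.amplitude,
                "area_px": int(mask.sum()),
            }
        )
    frames += rng.normal(0.0, spec.noise_sd, frames.shape).astype(np.float32)
    video = VideoStack(frames, spec.frame_rate_hz, spec.pixel_size_um)
    manifest = GroundTruthManifest(
        patches=patch_records,
        pixel_size_um=spec.pixel_size_um,
        extras={
            "field_size_px": list(spec.field_size_px),
            "true_beat_density": float(
                sum(r["area_px"] for r in patch_records) / (h * w)
            ),
        },
    )
    return video, manifest


# ---------------------------------------------------------------------------
# Bead transport scenes
# ---------------------------------------------------------------------------


@dataclass
class FlowSceneSpec:
    """Parameters of a synthetic bead-transport movie.

    Directed (MCC) beads advance at a per-track speed drawn from
    ``Normal(mcc_speed_um_s)`` along ``mcc_direction_deg`` (measured from
    the inlet-pointing axis, 0° = toward the inlet) with small isotropic
    jitter per step.  Background beads perform Brownian motion with
    diffusion coefficient ``bg_diffusion_um2_s`` plus a slow constant drift
    — the motion regime observed in cell-free chips.  The default Brownian
    coefficient ~0.4 μm²/s is the Stokes–Einstein value for a 1-μm bead in
    aqueous buffer at room temperature.
    """

    field_size_um: tuple[float, float] = (1200.0, 1200.0)  # (width x, height y)
    frame_rate_hz: float = 30.0
    n_frames: int = 300
    n_mcc: int = 100
    n_background: int = 100
    mcc_direction_deg: float = 0.0
    mcc_speed_um_s: tuple[float, float] = (20.0, 5.0)  # (mean, sd) across tracks
    mcc_jitter_um: float = 0.3  # per-step isotropic positional jitter
    bg_diffusion_um2_s: float = 0.4
    bg_drift_um_s: tuple[float, float] = (0.3, 0.1)
    inlet_direction: tuple[float, float] = (-1.0, 0.0)
    track_len_range: tuple[int, int] = (20, 300)  # nodes, inclusive
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mcc < 0 or self.n_background < 0:
            raise ValueError("bead counts must be >= 0")
        if self.mcc_speed_um_s[0] < 0 or self.bg_diffusion_um2_s < 0:
            raise ValueError("speeds and diffusion must be >= 0")
        if self.track_len_range[0] < 2:
            raise ValueError("tracks need at least 2 nodes")


def _direction_unit(inlet_direction: tuple[float, float], angle_deg: float) -> np.ndarray:
    """Unit vector at ``angle_deg`` from the inlet axis (matches the angle
    convention of :func:`mucoflow.mcc.trajectory_angles`)."""
    nx, ny = inlet_direction
    n = math.hypot(nx, ny)
    nx, ny = nx / n, ny / n
    a = math.radians(angle_deg)
    return np.array(
        [nx * math.cos(a) - ny * math.sin(a), nx * math.sin(a) + ny * math.cos(a)]
    )


def gen_bead_tracks(spec: FlowSceneSpec) -> tuple[TrajectorySet, GroundTruthManifest]:
    """Simulate labeled bead trajectories (directed MCC vs background)."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate_hz
    w, h = spec.field_size_um
    direction = _direction_unit(spec.inlet_direction, spec.mcc_direction_deg)
    lo, hi = spec.track_len_range
    hi = min(hi, spec.n_frames)

    trajs: list[Trajectory] = []
    labels: dict[int, str] = {}
    tid = 0
    for kind, count in (("mcc", spec.n_mcc), ("background", spec.n_background)):
        for _ in range(count):
            n_nodes = int(rng.integers(lo, hi + 1))
            start_frame = int(rng.integers(0, spec.n_frames - n_nodes + 1))
            # start in an inner margin so typical tracks stay in the field
            x0 = rng.uniform(0.1 * w, 0.9 * w)
            y0 = rng.uniform(0.1 * h, 0.9 * h)
            if kind == "mcc":
                speed = max(0.0, rng.normal(*spec.mcc_speed_um_s))
                steps = speed * dt * direction + rng.normal(
                    0.0, spec.mcc_jitter_um, (n_nodes - 1, 2)
                )
            else:
                sd = math.sqrt(2.0 * spec.bg_diffusion_um2_s * dt)
                steps = rng.normal(0.0, sd, (n_nodes - 1, 2))
                steps += np.asarray(spec.bg_drift_um_s) * dt
            pos = np.vstack([[x0, y0], np.cumsum(steps, axis=0) + [x0, y0]])
            frames = np.arange(start_frame, start_frame + n_nodes)
            trajs.append(
                Trajectory(tid, frames, pos[:, 0], pos[:, 1], label=kind)
            )
            labels[tid] = kind
            tid += 1

    tset = TrajectorySet(
        trajs, spec.frame_rate_hz, field_size_um=spec.field_size_um
    )
    manifest = GroundTruthManifest(
        track_labels=labels,
        field_size_um=spec.field_size_um,
        extras={
            "mcc_direction_deg": spec.mcc_direction_deg,
            "mcc_speed_um_s": list(spec.mcc_speed_um_s),
            "inlet_direction": list(spec.inlet_direction),
        },
    )
    return tset, manifest


def render_bead_video(
    tracks: TrajectorySet,
    pixel_size_um: float,
    field_size_um: tuple[float, float],
    n_frames: int | None = None,
    psf_sigma_px: float = 1.5,
    peak_intensity: float = 180.0,
    background: float = 20.0,
    noise_sd: float = 3.0,
    overlap_warn_fraction: float = 0.2,
    seed: int = 0,
) -> VideoStack:
    """Render trajectories as a fluorescence movie of Gaussian spots.

    Each bead is an isotropic Gaussian of width ``psf_sigma_px``; intensities
    are clipped to the 8-bit range.  A warning is logged when the expected
    spot-area coverage exceeds ``overlap_warn_fraction`` (detection will then
    start to merge neighbouring spots).
    """
    rng = np.random.default_rng(seed)
    w_px = int(round(field_size_um[0] / pixel_size_um))
    h_px = int(round(field_size_um[1] / pixel_size_um))
    if n_frames is None:
        n_frames = max(int(t.frames[-1]) for t in tracks) + 1
    frames = np.full((n_frames, h_px, w_px), background, dtype=np.float32)

    n_per_frame = np.zeros(n_frames)
    half = int(math.ceil(4 * psf_sigma_px))
    span = np.arange(-half, half + 1)
    for traj in tracks:
        for f, x, y in zip(traj.frames, traj.x_um, traj.y_um):
            if f >= n_frames:
                continue
            cx, cy = x / pixel_size_um, y / pixel_size_um
            ix, iy = int(round(cx)), int(round(cy))
            xs = span + ix
            ys = span + iy
            ok_x = (xs >= 0) & (xs < w_px)
            ok_y = (ys >= 0) & (ys < h_px)
            if not (ok_x.any() and ok_y.any()):
                continue
            gx = np.exp(-((xs[ok_x] - cx) ** 2) / (2 * psf_sigma_px**2))
            gy = np.exp(-((ys[ok_y] - cy) ** 2) / (2 * psf_sigma_px**2))
            frames[f][np.ix_(ys[ok_y], xs[ok_x])] += peak_intensity * np.outer(
                gy, gx
            ).astype(np.float32)
            n_per_frame[f] += 1

    spot_area = math.pi * (3 * psf_sigma_px) ** 2
    coverage = n_per_frame.max() * spot_area / (w_px * h_px) if n_frames else 0
    if coverage > overlap_warn_fraction:
        logger.warning(
            "rendered spot density high (expected coverage %.2f); "
            "spots will overlap and tracking accuracy degrades",
            coverage,
        )
    frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)
    np.clip(frames, 0, 255, out=frames)
    return VideoStack(frames, tracks.frame_rate_hz, pixel_size_um)


# ---------------------------------------------------------------------------
# Immunofluorescence scenes
# ---------------------------------------------------------------------------


@dataclass
class ArcStroke:
    """A circular-arc stroke (crescent).  Length is exactly r·span."""

    center_um: tuple[float, float]
    radius_um: float
    theta_start_rad: float
    theta_span_rad: float

    @property
    def length_um(self) -> float:
        return self.radius_um * self.theta_span_rad

    def sample(self, step_um: float) -> np.ndarray:
        n = max(2, int(math.ceil(self.length_um / step_um)) + 1)
        th = self.theta_start_rad + np.linspace(0, self.theta_span_rad, n)
        cx, cy = self.center_um
        return np.column_stack([cx + self.radius_um * np.cos(th),
                                cy + self.radius_um * np.sin(th)])


@dataclass
class SegmentStroke:
    """A straight stroke between two points."""

    p0_um: tuple[float, float]
    p1_um: tuple[float, float]

    @property
    def length_um(self) -> float:
        return math.dist(self.p0_um, self.p1_um)

    def sample(self, step_um: float) -> np.ndarray:
        n = max(2, int(math.ceil(self.length_um / step_um)) + 1)
        t = np.linspace(0, 1, n)
        p0 = np.asarray(self.p0_um)
        p1 = np.asarray(self.p1_um)
        return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def gen_crescent_image(
    strokes: list,
    field_size_um: tuple[float, float],
    pixel_size_um: float = 1.0 / 3.0,
    width_um: float = 1.0,
    peak_intensity: float = 150.0,
    background: float = 20.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthManifest]:
    """Render curvilinear crescent strokes with a Gaussian cross-profile.

    ``width_um`` sets the Gaussian cross-profile width (σ = width/2).  The
    manifest records the exact analytic length of each stroke and, under
    ``extras['mask']``, the detectable ground-truth footprint: pixels whose
    noiseless stroke intensity rises more than max(3·noise_sd, 10% of
    peak) above background.
    """
    rng = np.random.default_rng(seed)
    w_px = int(round(field_size_um[0] / pixel_size_um))
    h_px = int(round(field_size_um[1] / pixel_size_um))
    img = np.zeros((h_px, w_px), dtype=np.float32)
    mask = np.zeros((h_px, w_px), dtype=bool)
    sigma_px = max(0.75, (width_um / pixel_size_um) / 2.0)
    half = int(math.ceil(3 * sigma_px))
    footprint_floor = max(3.0 * noise_sd, 0.1 * peak_intensity)
    lengths = []
    for s in strokes:
        pts_px = s.sample(step_um=pixel_size_um / 4.0) / pixel_size_um
        lengths.append(float(s.length_um))
        for px, py in pts_px:
            ix, iy = int(round(px)), int(round(py))
            xs = np.arange(max(0, ix - half), min(w_px, ix + half + 1))
            ys = np.arange(max(0, iy - half), min(h_px, iy + half + 1))
            if xs.size == 0 or ys.size == 0:
                continue
            d2 = (xs[None, :] - px) ** 2 + (ys[:, None] - py) ** 2
            window = peak_intensity * np.exp(-d2 / (2 * sigma_px**2))
            idx = np.ix_(ys, xs)
            img[idx] = np.maximum(img[idx], window)
            mask[idx] |= window >= footprint_floor
    img += background
    img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    manifest = GroundTruthManifest(
        crescent_lengths_um=lengths,
        field_size_um=field_size_um,
        pixel_size_um=pixel_size_um,
        extras={"mask": mask},
    )
    return img, manifest


def gen_marker_image(
    true_fraction: float,
    field_size_px: tuple[int, int] = (512, 512),
    blob_scale_px: float = 12.0,
    fg_intensity: float = 200.0,
    bg_intensity: float = 50.0,
    noise_sd: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruthManifest]:
    """Generate a marker image whose positive area is exactly ``true_fraction``.

    Smoothed random noise is thresholded at the quantile giving exactly the
    requested pixel count (bright blobs of spatial scale ``blob_scale_px``),
    then bimodal intensities plus Gaussian noise are applied.  Fractions of
    exactly 0 or 1 are valid but flagged degenerate in the manifest, since
    automatic thresholding of a unimodal image is undefined.
    """
    if not 0.0 <= true_fraction <= 1.0:
        raise ValueError("true_fraction must be in [0, 1]")
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    h, w = field_size_px
    latent = gaussian_filter(rng.standard_normal((h, w)), blob_scale_px)
    n_pos = int(round(true_fraction * h * w))
    mask = np.zeros((h, w), dtype=bool)
    if n_pos > 0:
        # top-n_pos pixels of the latent field -> exact pixel count
        order = np.argsort(latent, axis=None)[::-1][:n_pos]
        mask.flat[order] = True
    img = np.where(mask, fg_intensity, bg_intensity).astype(np.float32)
    img += rng.normal(0.0, noise_sd, img.shape).astype(np.float32)
    manifest = GroundTruthManifest(
        positive_area_fraction=float(n_pos) / (h * w),
        extras={
            "mask": mask,
            "degenerate": bool(true_fraction in (0.0, 1.0)),
        },
    )
    return img, manifest
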