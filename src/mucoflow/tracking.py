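"""Bead spot detection and trajectory linking.

Detection is Laplacian-of-Gaussian blob finding with sub-pixel centroid
refinement; linking is greedy mutual-nearest-neighbour association between
consecutive frames within a maximum displacement, with no gap closing.
Both are deterministic: ties are broken by smallest distance, then lowest
spot index.  This is sufficient at the bead dilutions used for mucociliary
transport assays, where spots are sparse.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy.ndimage import gaussian_laplace
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .core import Spot, Trajectory, TrajectorySet, VideoStack

logger = logging.getLogger(__name__)


def detect_spots(
    frame: np.ndarray,
    pixel_size_um: float,
    frame_index: int = 0,
    sigma_px: float = 1.5,
    intensity_floor: float = 10.0,
) -> list[Spot]:
    """Detect bright Gaussian-like spots in one grayscale frame.

    The negative Laplacian-of-Gaussian response at scale ``sigma_px`` is
    peak-picked; peaks whose background-subtracted intensity is below
    ``intensity_floor`` are discarded.  Positions are refined to sub-pixel
    precision with an intensity-weighted centroid over a ±2σ window and
    returned in μm.
    """
    img = np.asarray(frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D grayscale frame")
    if img.size and img.max() >= 255 and np.mean(img >= img.max()) > 0.01:
        logger.warning("frame %d appears saturated; detection proceeds", frame_index)

    # scale-normalized LoG; negative sign so bright blobs give positive peaks
    response = -(sigma_px**2) * gaussian_laplace(img, sigma_px)
    background = np.median(img)
    peaks = peak_local_max(
        response,
        min_distance=max(1, int(round(sigma_px))),
        threshold_abs=intensity_floor * 0.1,
        exclude_border=False,
    )
    h, w = img.shape
    half = max(2, int(math.ceil(2 * sigma_px)))
    spots: list[Spot] = []
    for py, px in peaks:
        y0, y1 = max(0, py - half), min(h, py + half + 1)
        x0, x1 = max(0, px - half), min(w, px + half + 1)
        window = img[y0:y1, x0:x1] - background
        window = np.clip(window, 0, None)
        total = window.sum()
        amp = img[py, px] - background
        if amp < intensity_floor or total <= 0:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        cy = float((ys * window).sum() / total)
        cx = float((xs * window).sum() / total)
        spots.append(
            Spot(
                frame=frame_index,
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                intensity=float(amp),
            )
        )
    spots.sort(key=lambda s: (s.y_um, s.x_um))
    return spots


def detect_all_spots(
    video: VideoStack, sigma_px: float = 1.5, intensity_floor: float = 10.0
) -> list[list[Spot]]:
    """Detect spots in every frame of a stack; returns per-frame lists."""
    return [
        detect_spots(
            video.frames[k],
            video.pixel_size_um,
            frame_index=k,
            sigma_px=sigma_px,
            intensity_floor=intensity_floor,
        )
        for k in range(video.n_frames)
    ]


def link_trajectories(
    spots_by_frame: list[list[Spot]],
    frame_rate_hz: float,
    max_disp_um: float,
    min_track_len: int = 5,
    pixel_size_um: float | None = None,
) -> TrajectorySet:
    """Link per-frame spots into trajectories by mutual nearest neighbours.

    A spot in frame k and a spot in frame k+1 are linked iff each is the
    other's nearest neighbour and their distance is below ``max_disp_um``.
    Unlinked spots start new tracks; tracks shorter than ``min_track_len``
    nodes are discarded.  No gap closing: a missed detection splits a track.
    """
    if max_disp_um <= 0:
        raise ValueError("max_disp_um must be > 0")
    active: dict[int, list[Spot]] = {}  # track_id -> spots, still linkable
    finished: list[list[Spot]] = []
    next_id = 0
    prev_tracks: list[int] = []  # track id carried by each spot of prev frame

    for frame_spots in spots_by_frame:
        if not prev_tracks:
            new_tracks = []
            for s in frame_spots:
                active[next_id] = [s]
                new_tracks.append(next_id)
                next_id += 1
            prev_tracks = new_tracks
            continue

        prev_spots = [active[tid][-1] for tid in prev_tracks]
        links = _mutual_nearest(prev_spots, frame_spots, max_disp_um)
        new_tracks = [-1] * len(frame_spots)
        linked_prev = set()
        for i_prev, j_cur in links:
            tid = prev_tracks[i_prev]
            active[tid].append(frame_spots[j_cur])
            new_tracks[j_cur] = tid
            linked_prev.add(i_prev)
        # terminate tracks that found no continuation
        for i, tid in enumerate(prev_tracks):
            if i not in linked_prev:
                finished.append(active.pop(tid))
        # start tracks for unlinked current spots
        for j, s in enumerate(frame_spots):
            if new_tracks[j] == -1:
                active[next_id] = [s]
                new_tracks[j] = next_id
                next_id += 1
        prev_tracks = [t for t in new_tracks if t != -1]

    finished.extend(active.values())

    trajs = []
    kept_id = 0
    for spots in finished:
        if len(spots) < min_track_len:
            continue
        trajs.append(
            Trajectory(
                kept_id,
                np.array([s.frame for s in spots]),
                np.array([s.x_um for s in spots]),
                np.array([s.y_um for s in spots]),
            )
        )
        kept_id += 1
    logger.info(
        "linking: %d tracks kept (>= %d nodes) of %d candidates",
        len(trajs),
        min_track_len,
        len(finished),
    )
    return TrajectorySet(trajs, frame_rate_hz, pixel_size_um)


def _mutual_nearest(
    prev_spots: list[Spot], cur_spots: list[Spot], max_disp_um: float
) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour pairs (prev index, cur index) within range."""
    if not prev_spots or not cur_spots:
        return []
    a = np.array([[s.x_um, s.y_um] for s in prev_spots])
    b = np.array([[s.x_um, s.y_um] for s in cur_spots])
    tree_b = cKDTree(b)
    d_ab, j_ab = tree_b.query(a, distance_upper_bound=max_disp_um)
    tree_a = cKDTree(a)
    d_ba, i_ba = tree_a.query(b, distance_upper_bound=max_disp_um)
    pairs = []
    for i in range(len(a)):
        j = j_ab[i]
        if j < len(b) and i_ba[j] == i and np.isfinite(d_ab[i]):
            pairs.append((float(d_ab[i]), i, int(j)))
    pairs.sort()  # smallest distance first, then lowest indices (determinism)
    return [(i, j) for _, i, j in pairs]


def track_video(
    video: VideoStack,
    sigma_px: float = 1.5,
    intensity_floor: float = 10.0,
    max_disp_um: float | None = None,
    min_track_len: int = 5,
    expected_speed_um_s: float = 20.0,
) -> TrajectorySet:
    """Detect and link beads in a movie.

    When ``max_disp_um`` is not given it defaults to 3× the expected
    per-frame displacement of directed transport at ``expected_speed_um_s``.
    """
    if max_disp_um is None:
        max_disp_um = 3.0 * expected_speed_um_s / video.frame_rate_hz
    spots = detect_all_spots(video, sigma_px=sigma_px, intensity_floor=intensity_floor)
    tset = link_trajectories(
        spots,
        video.frame_rate_hz,
        max_disp_um=max_disp_um,
        min_track_len=min_track_len,
        pixel_size_um=video.pixel_size_um,
    )
    tset.field_size_um = (
        video.frames.shape[2] * video.pixel_size_um,
        video.frames.shape[1] * video.pixel_size_um,
    )
    return tset
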