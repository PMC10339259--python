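import numpy as np
import pytest

from mucoflow import classify, synthetic
from mucoflow.core import ChannelGeometry, Trajectory, TrajectorySet

GEOMETRY = ChannelGeometry(inlet_direction=(-1.0, 0.0), field_area_um2=1200.0**2)


def make_track(track_id, points_um, frame_rate_hz=30.0, frames=None, label=None):
    """Trajectory from a list of (x, y) points at consecutive frames."""
    pts = np.asarray(points_um, dtype=float)
    if frames is None:
        frames = np.arange(len(pts))
    return Trajectory(track_id, frames, pts[:, 0], pts[:, 1], label=label)


def make_set(tracks, frame_rate_hz=30.0, field_size_um=(1200.0, 1200.0)):
    return TrajectorySet(tracks, frame_rate_hz, field_size_um=field_size_um)


@pytest.fixture(scope="session")
def geometry():
    return GEOMETRY


@pytest.fixture(scope="session")
def cilia_scene():
    """One 8 Hz circular patch, 200 fps, 512 frames."""
    spec = synthetic.CiliaSceneSpec(
        field_size_px=(80, 80),
        n_frames=512,
        patches=[synthetic.CiliaPatch((40, 40), 15, 8.0)],
        seed=11,
    )
    return spec, *synthetic.gen_cilia_video(spec)


@pytest.fixture(scope="session")
def labeled_bead_scene():
    """Default-condition mixed MCC/Brownian scene with ground-truth labels."""
    spec = synthetic.FlowSceneSpec(n_mcc=250, n_background=250, seed=21)
    tracks, manifest = synthetic.gen_bead_tracks(spec)
    labels = np.array([manifest.track_labels[t.track_id] for t in tracks])
    return tracks, labels, manifest


@pytest.fixture(scope="session")
def labeled_features(labeled_bead_scene):
    tracks, labels, _ = labeled_bead_scene
    return classify.feature_table(tracks, GEOMETRY), labels
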