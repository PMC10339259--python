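"""Background-flow rejection for bead trajectories.

Bead movies contain both genuine mucociliary transport (directed, fast,
persistent tracks) and background motion (Brownian wander plus slow bulk
drift, as seen in cell-free chips).  Trajectories are described by nine
kinematic features and classified either by a depth-limited decision tree
trained with stratified 5-fold cross-validation, or by a simplified rule:
a track is background iff its Euclidean distance, median speed and
directness all fall below threshold levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.tree import DecisionTreeClassifier

from .core import ChannelGeometry, Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

FEATURE_NAMES = [
    "mean_speed_um_s",
    "median_speed_um_s",
    "sd_speed_um_s",
    "path_length_um",
    "euclid_dist_um",
    "directness",
    "mean_flow_angle_deg",
    "n_nodes",
    "max_accel_um_s2",
]

#: Default thresholds of the simplified background rule, calibrated once on
#: the default synthetic benchmark by maximizing balanced accuracy
#: (see ThresholdClassifier.calibrate).  Background iff ALL three features
#: fall below their threshold.
DEFAULT_THRESHOLDS = {
    "euclid_dist_um": 26.5,
    "median_speed_um_s": 9.4,
    "directness": 0.79,
}

LABEL_SIGNAL = "mcc"
LABEL_BACKGROUND = "background"


def extract_features(
    traj: Trajectory,
    frame_rate_hz: float,
    geometry: ChannelGeometry | None = None,
) -> dict[str, float]:
    """Compute the nine kinematic features of one trajectory.

    Speeds come from consecutive displacements divided by elapsed time;
    directness is net (Euclidean) displacement over path length, defined as
    0 for a stationary track; the mean flow angle is the angle of the mean
    displacement vector relative to the inlet axis (0° = toward inlet);
    maximal acceleration is the largest speed change per unit time.
    """
    if traj.n_nodes < 2:
        raise ValueError(
            f"track {traj.track_id}: need >= 2 nodes to extract features"
        )
    geometry = geometry or ChannelGeometry()
    steps = traj.step_vectors_um()
    dt = np.diff(traj.frames) / frame_rate_hz
    step_len = np.hypot(steps[:, 0], steps[:, 1])
    speeds = step_len / dt

    path_length = float(step_len.sum())
    disp = traj.displacement_um()
    euclid = float(np.hypot(*disp))
    directness = euclid / path_length if path_length > 0 else 0.0

    mean_step = steps.mean(axis=0)
    if np.hypot(*mean_step) > 0:
        angle = _angle_from_inlet_deg(mean_step, geometry)
    else:
        angle = 0.0

    if len(speeds) >= 2:
        accel = np.abs(np.diff(speeds)) / dt[1:]
        max_accel = float(accel.max())
    else:
        max_accel = 0.0

    return {
        "mean_speed_um_s": float(speeds.mean()),
        "median_speed_um_s": float(np.median(speeds)),
        "sd_speed_um_s": float(speeds.std(ddof=0)),
        "path_length_um": path_length,
        "euclid_dist_um": euclid,
        "directness": float(directness),
        "mean_flow_angle_deg": float(angle),
        "n_nodes": float(traj.n_nodes),
        "max_accel_um_s2": max_accel,
    }


def _angle_from_inlet_deg(vec: np.ndarray, geometry: ChannelGeometry) -> float:
    """Signed angle (deg, in (-180, 180]) from the inlet axis to ``vec``."""
    n = geometry.n_hat
    dot = float(vec[0] * n[0] + vec[1] * n[1])
    cross = float(n[0] * vec[1] - n[1] * vec[0])
    ang = math.degrees(math.atan2(cross, dot))
    return 180.0 if ang == -180.0 else ang


def feature_table(
    tracks: TrajectorySet, geometry: ChannelGeometry | None = None
) -> pd.DataFrame:
    """Feature matrix for a trajectory set (one row per track)."""
    rows = []
    for t in tracks:
        feats = extract_features(t, tracks.frame_rate_hz, geometry)
        feats["track_id"] = t.track_id
        if t.label is not None:
            feats["label"] = t.label
        rows.append(feats)
    return pd.DataFrame(rows)


@dataclass
class TreeClassifier:
    """Decision tree over the nine features, with cross-validated accuracy.

    ``cv_accuracy`` is the mean held-out accuracy over stratified 5-fold
    splits — never training accuracy.  The model is refit on all data after
    cross-validation.  Deterministic under a fixed seed.
    """

    max_depth: int = 5
    min_samples_leaf: int = 5
    n_folds: int = 5
    seed: int = 0
    model: DecisionTreeClassifier | None = None
    cv_accuracy: float | None = None

    def fit(self, features: pd.DataFrame, labels: np.ndarray) -> "TreeClassifier":
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        if len(labels) < self.n_folds:
            raise ValueError("fewer samples than cross-validation folds")
        X = features[FEATURE_NAMES].to_numpy()
        tree = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
        )
        cv = StratifiedKFold(self.n_folds, shuffle=True, random_state=self.seed)
        scores = cross_val_score(tree, X, labels, cv=cv, scoring="accuracy")
        self.cv_accuracy = float(scores.mean())
        self.model = tree.fit(X, labels)
        logger.info(
            "decision tree: %d-fold CV accuracy %.4f (n=%d)",
            self.n_folds,
            self.cv_accuracy,
            len(labels),
        )
        return self

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            raise ValueError("classifier not fitted")
        return self.model.predict(features[FEATURE_NAMES].to_numpy())


@dataclass
class ThresholdClassifier:
    """Simplified three-feature background rule.

    A trajectory is background iff its Euclidean distance, median speed AND
    directness are all below their thresholds; otherwise it is signal.
    """

    euclid_max_um: float = DEFAULT_THRESHOLDS["euclid_dist_um"]
    median_speed_max_um_s: float = DEFAULT_THRESHOLDS["median_speed_um_s"]
    directness_max: float = DEFAULT_THRESHOLDS["directness"]

    def __post_init__(self) -> None:
        if min(self.euclid_max_um, self.median_speed_max_um_s, self.directness_max) <= 0:
            raise ValueError("thresholds must be > 0")

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        is_bg = (
            (features["euclid_dist_um"].to_numpy() < self.euclid_max_um)
            & (features["median_speed_um_s"].to_numpy() < self.median_speed_max_um_s)
            & (features["directness"].to_numpy() < self.directness_max)
        )
        return np.where(is_bg, LABEL_BACKGROUND, LABEL_SIGNAL)

    @classmethod
    def calibrate(
        cls,
        features: pd.DataFrame,
        labels: np.ndarray,
        n_grid: int = 15,
    ) -> "ThresholdClassifier":
        """Grid-search thresholds maximizing balanced accuracy on a labeled
        calibration set (quantile grid per feature; deterministic)."""
        labels = np.asarray(labels)
        is_bg_true = labels == LABEL_BACKGROUND
        if is_bg_true.all() or not is_bg_true.any():
            raise ValueError("calibration set must contain both classes")

        def grid(col):
            qs = np.linspace(0.02, 0.98, n_grid)
            return np.unique(np.quantile(features[col].to_numpy(), qs))

        best = (-1.0, None)
        e_grid = grid("euclid_dist_um")
        s_grid = grid("median_speed_um_s")
        d_grid = grid("directness")
        e = features["euclid_dist_um"].to_numpy()
        s = features["median_speed_um_s"].to_numpy()
        d = features["directness"].to_numpy()
        for et in e_grid:
            for st in s_grid:
                for dt_ in d_grid:
                    if min(et, st, dt_) <= 0:
                        continue
                    pred_bg = (e < et) & (s < st) & (d < dt_)
                    sens = (pred_bg & is_bg_true).sum() / is_bg_true.sum()
                    spec = (~pred_bg & ~is_bg_true).sum() / (~is_bg_true).sum()
                    bal = 0.5 * (sens + spec)
                    if bal > best[0]:
                        best = (bal, (float(et), float(st), float(dt_)))
        et, st, dt_ = best[1]
        logger.info(
            "threshold calibration: balanced accuracy %.4f at "
            "euclid<%.2f um, median speed<%.2f um/s, directness<%.3f",
            best[0], et, st, dt_,
        )
        return cls(et, st, dt_)


def accuracy(pred: np.ndarray, truth: np.ndarray) -> float:
    pred, truth = np.asarray(pred), np.asarray(truth)
    return float((pred == truth).mean())


def filter_background(tracks: TrajectorySet, classifier) -> TrajectorySet:
    """Return only trajectories the classifier labels as signal.

    Surviving trajectories are passed through untouched (same objects,
    same coordinates); removal counts are logged.
    """
    if len(tracks) == 0:
        return tracks
    feats = feature_table(tracks)
    pred = classifier.predict(feats)
    keep = pred == LABEL_SIGNAL
    kept = tracks.subset(keep)
    logger.info(
        "background filter: kept %d, removed %d of %d tracks",
        len(kept), int((~keep).sum()), len(tracks),
    )
    return kept
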