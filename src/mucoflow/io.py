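"""Reading and writing of pipeline artifacts.

Formats: grayscale multi-page TIFF for videos/images, plain CSV with header
``track_id,frame,x_um,y_um`` for trajectories, YAML for configuration and
JSON for ground-truth manifests.  Every reader validates calibration before
any computation so that no downstream metric is ever produced in pixels when
a μm calibration is available.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import CalibrationError, Trajectory, TrajectorySet, VideoStack

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def read_video(
    path: str | Path,
    frame_rate_hz: float | None = None,
    pixel_size_um: float | None = None,
) -> VideoStack:
    """Read a grayscale multi-page TIFF into a calibrated :class:`VideoStack`.

    TIFF files written by :func:`write_video` carry calibration in their
    ImageDescription tag; otherwise ``frame_rate_hz`` and ``pixel_size_um``
    must be supplied.  Explicit arguments override embedded metadata.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            frames = tf.asarray()
            meta = _embedded_calibration(tf)
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc

    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(
            f"{path}: expected grayscale stack, got shape {frames.shape}; "
            "extract a single channel before analysis"
        )
    rate = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if rate is None:
        raise CalibrationError(
            f"{path}: frame rate not embedded in file; pass frame_rate_hz"
        )
    if px is None:
        raise CalibrationError(
            f"{path}: pixel size not embedded in file; pass pixel_size_um"
        )
    return VideoStack(frames, float(rate), float(px))


def _embedded_calibration(tf: "tifffile.TiffFile") -> dict:
    desc = tf.pages[0].tags.get("ImageDescription")
    if desc is None:
        return {}
    try:
        meta = json.loads(desc.value)
    except (TypeError, ValueError):
        return {}
    return meta if isinstance(meta, dict) else {}


def write_video(stack: VideoStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF with calibration in ImageDescription."""
    meta = {
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_size_um": stack.pixel_size_um,
    }
    tifffile.imwrite(
        Path(path),
        stack.frames,
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 2-D TIFF image."""
    img = tifffile.imread(Path(path))
    if img.ndim == 3 and img.shape[0] == 1:
        img = img[0]
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected single-channel 2-D image, got shape {img.shape}"
        )
    return img


def write_tracks(tracks: TrajectorySet, path: str | Path) -> None:
    """Serialize trajectories to CSV (μm coordinates, 6 decimal places)."""
    rows = []
    for t in tracks:
        for f, x, y in zip(t.frames, t.x_um, t.y_um):
            rows.append((t.track_id, int(f), x, y))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.6f")


def read_tracks(
    path: str | Path,
    frame_rate_hz: float,
    pixel_size_um: float | None = None,
    coords_in_px: bool = False,
) -> TrajectorySet:
    """Read a trajectory CSV into a :class:`TrajectorySet`.

    The CSV must have columns ``track_id,frame,x_um,y_um`` (or ``x_px,y_px``
    with ``coords_in_px=True``, in which case ``pixel_size_um`` is required
    to convert).  Duplicate ``(track_id, frame)`` pairs or non-monotone
    frames within a track are schema errors.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = ["track_id", "frame"] + (
        ["x_px", "y_px"] if coords_in_px else ["x_um", "y_um"]
    )
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column '{c}'")
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise ValueError(f"{path}: duplicate (track_id, frame) pairs")
    if coords_in_px:
        if pixel_size_um is None:
            raise CalibrationError(
                f"{path}: pixel-unit coordinates need pixel_size_um to convert"
            )
        df = df.assign(
            x_um=df["x_px"] * pixel_size_um, y_um=df["y_px"] * pixel_size_um
        )
    trajs = []
    for tid, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: non-monotone frames in track {tid}")
        trajs.append(
            Trajectory(int(tid), frames, g["x_um"].to_numpy(), g["y_um"].to_numpy())
        )
    return TrajectorySet(trajs, frame_rate_hz, pixel_size_um)


@dataclass
class ResultTable:
    """Per-sample metric rows with units and provenance.

    ``units`` maps metric column → unit string (empty string for
    dimensionless); ``provenance`` records input file, config hash and seed.
    """

    data: pd.DataFrame
    units: dict[str, str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.data.columns if c not in self.units]
        if missing:
            raise ValueError(f"metric columns missing unit strings: {missing}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.provenance.items()):
                fh.write(f"# {k}: {v}\n")
            fh.write("# units: " + json.dumps(self.units) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ResultTable":
        prov: dict = {}
        units: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("# "):
                body_start = i
                break
            key, _, val = line[2:].strip().partition(": ")
            if key == "units":
                units = json.loads(val)
            else:
                prov[key] = val
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body_start:])))
        return cls(df, units, prov)


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping (for provenance)."""
    blob = json.dumps(cfg, sort_keys=True, default=_json_default)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
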