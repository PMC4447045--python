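"""I/O and coordinate/timing conventions shared by the whole pipeline.

Conventions
-----------
* Arena frame: meters, x/y on the floor plane, origin at an annotated floor
  corner.  Microphones are 3D points (they sit above the floor); the
  localization grid lies on the plane ``z = z_plane``.  All distances used for
  acoustic delays are full 3D Euclidean distances.
* Time base: the audio sample clock is authoritative.  Video frame times are
  derived through an affine :class:`SyncModel`.
* Tabular artifacts are CSV with a mandatory header.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile
from shapely.geometry import Polygon

__all__ = [
    "ArrayGeometry",
    "ArenaFloor",
    "TrackTable",
    "SyncModel",
    "read_recording",
    "write_recording",
    "read_tracks",
    "write_tracks",
    "frame_for_time",
    "load_config",
]

TRACK_COLUMNS = ["frame", "mouse_id", "x_m", "y_m", "heading_rad", "major_m", "minor_m"]


@dataclass(frozen=True)
class ArrayGeometry:
    """Microphone array geometry plus the acoustic constants that go with it.

    Parameters
    ----------
    mic_positions : (K, 3) array
        Microphone positions in the arena frame, meters.
    speed_of_sound : float
        Speed of sound in air, m/s.  343 m/s corresponds to ~20 °C at
        standard pressure; override for other ambient temperatures.
    sample_rate : float
        Audio sampling rate in Hz.
    """

    mic_positions: np.ndarray
    speed_of_sound: float = 343.0
    sample_rate: float = 450450.0

    def __post_init__(self):
        pos = np.asarray(self.mic_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("mic_positions must be a (K, 3) array")
        if pos.shape[0] < 2:
            raise ValueError("need at least 2 microphones")
        if len(np.unique(pos, axis=0)) != pos.shape[0]:
            raise ValueError("microphone positions must be distinct")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not 300.0 <= self.speed_of_sound <= 360.0:
            raise ValueError("speed_of_sound outside plausible range [300, 360] m/s")
        object.__setattr__(self, "mic_positions", pos)

    @property
    def n_mics(self) -> int:
        return self.mic_positions.shape[0]

    @property
    def dt(self) -> float:
        """Audio sample period in seconds."""
        return 1.0 / self.sample_rate


@dataclass(frozen=True)
class ArenaFloor:
    """Floor polygon of the arena (meters) and the height of the localization plane."""

    polygon: np.ndarray
    z_plane: float = 0.0

    def __post_init__(self):
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be an (V, 2) array with V >= 3")
        shp = Polygon(poly)
        if not shp.is_valid or not shp.is_simple:
            raise ValueError("floor polygon must be simple (non-self-intersecting)")
        if shp.area <= 0:
            raise ValueError("floor polygon must enclose a positive area")
        object.__setattr__(self, "polygon", poly)

    def as_shapely(self) -> Polygon:
        return Polygon(self.polygon)

    @property
    def area(self) -> float:
        return self.as_shapely().area

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return self.as_shapely().bounds

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized point-in-polygon test for an (N, 2) array."""
        import shapely

        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return shapely.contains_xy(self.as_shapely(), xy[:, 0], xy[:, 1])


@dataclass
class TrackTable:
    """Per-frame animal trajectories, as produced by a video tracker.

    One row per (frame, mouse): centroid, heading and fitted ellipse axes.
    Missing frames are reported, never silently interpolated.
    """

    table: pd.DataFrame
    frame_rate: float

    def __post_init__(self):
        df = self.table
        missing = set(TRACK_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"track table missing columns: {sorted(missing)}")
        dup = df.duplicated(subset=["frame", "mouse_id"])
        if dup.any():
            raise ValueError("duplicate (frame, mouse_id) rows in track table")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        h = df["heading_rad"].to_numpy(float)
        if np.any(h < -np.pi) or np.any(h >= np.pi):
            raise ValueError("headings must lie in [-pi, pi)")
        self.table = df.sort_values(["frame", "mouse_id"]).reset_index(drop=True)

    @property
    def mouse_ids(self) -> list:
        return sorted(self.table["mouse_id"].unique().tolist())

    @property
    def frames(self) -> np.ndarray:
        return np.sort(self.table["frame"].unique())

    def timestamps(self) -> np.ndarray:
        """Frame timestamps in seconds (frame index / frame rate)."""
        return self.frames / self.frame_rate

    def missing_frames(self) -> dict:
        """Report gaps: per mouse, the frames absent from the covered span."""
        report = {}
        lo, hi = int(self.frames.min()), int(self.frames.max())
        full = np.arange(lo, hi + 1)
        for mid in self.mouse_ids:
            have = self.table.loc[self.table["mouse_id"] == mid, "frame"].to_numpy()
            gaps = np.setdiff1d(full, have)
            if gaps.size:
                report[mid] = gaps.tolist()
        return report

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Rows for one frame, indexed by mouse_id; empty if the frame is missing."""
        rows = self.table[self.table["frame"] == frame]
        return rows.set_index("mouse_id")

    def nose_positions_at(self, frame: int) -> dict:
        """Nose point per mouse at a frame: centroid + half major axis along heading."""
        rows = self.positions_at(frame)
        out = {}
        for mid, r in rows.iterrows():
            dx = 0.5 * r["major_m"] * np.cos(r["heading_rad"])
            dy = 0.5 * r["major_m"] * np.sin(r["heading_rad"])
            out[mid] = np.array([r["x_m"] + dx, r["y_m"] + dy])
        return out


@dataclass(frozen=True)
class SyncModel:
    """Affine mapping between audio time and video frame index.

    frame = floor((t_audio - offset_s) * frame_rate)
    """

    frame_rate: float
    offset_s: float = 0.0
    n_frames: int | None = None

    def frame_of(self, t_audio: float) -> int:
        f = int(np.floor((t_audio - self.offset_s) * self.frame_rate))
        if f < 0 or (self.n_frames is not None and f >= self.n_frames):
            raise ValueError(f"time {t_audio} s maps outside the video record")
        return f

    def time_of(self, frame: int) -> float:
        """Start time of a frame on the audio clock."""
        return self.offset_s + frame / self.frame_rate


def frame_for_time(sync: SyncModel, t_audio: float) -> int:
    """Video frame containing audio time ``t_audio`` (seconds, audio clock)."""
    return sync.frame_of(t_audio)


# ---------------------------------------------------------------------------
# recordings

def write_recording(path: str, samples: np.ndarray, sample_rate: float) -> None:
    """Write an (N, K) float32 multichannel WAV; lossless round trip with read."""
    samples = np.asarray(samples)
    if samples.ndim == 1:
        samples = samples[:, None]
    wavfile.write(path, int(round(sample_rate)), samples.astype(np.float32))


def read_recording(path: str, geometry: ArrayGeometry | None = None):
    """Read a multichannel recording as (samples (N, K), sample_rate).

    PCM16 is scaled to [-1, 1); float32 is returned as stored (no resampling,
    no gain).  If ``geometry`` is given, the channel count must equal its K and
    the sample rate must match.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        rate, data = wavfile.read(path)
    except ValueError as e:
        size = os.path.getsize(path)
        raise ValueError(f"unreadable/truncated WAV at byte offset <= {size}: {e}") from e
    if data.ndim == 1:
        data = data[:, None]
    if data.dtype == np.int16:
        data = data.astype(np.float32) / 32768.0
    if geometry is not None:
        if data.shape[1] != geometry.n_mics:
            raise ValueError(
                f"channel-count mismatch: file has {data.shape[1]}, geometry K={geometry.n_mics}"
            )
        if rate != int(round(geometry.sample_rate)):
            raise ValueError(
                f"sample-rate mismatch: file {rate} Hz, geometry {geometry.sample_rate} Hz"
            )
    return data, float(rate)


def write_raw_recording(path: str, samples: np.ndarray, sample_rate: float) -> None:
    """Raw interleaved float32 with a JSON sidecar carrying shape and rate."""
    samples = np.asarray(samples, dtype=np.float32)
    samples.tofile(path)
    meta = {"n_samples": int(samples.shape[0]), "n_channels": int(samples.shape[1]),
            "dtype": "float32", "sample_rate": float(sample_rate)}
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh)


def read_raw_recording(path: str):
    with open(path + ".json") as fh:
        meta = json.load(fh)
    n, k = meta["n_samples"], meta["n_channels"]
    data = np.fromfile(path, dtype=np.float32)
    expected = n * k
    if data.size != expected:
        byte_off = data.size * 4
        raise ValueError(f"truncated raw recording: expected {expected * 4} bytes, "
                         f"stream ends at byte offset {byte_off}")
    return data.reshape(n, k), float(meta["sample_rate"])


# ---------------------------------------------------------------------------
# tracks

def write_tracks(path: str, tracks: TrackTable) -> None:
    tracks.table.to_csv(path, index=False, columns=TRACK_COLUMNS)


def read_tracks(path: str, frame_rate: float) -> TrackTable:
    """Read a tracker CSV into a validated :class:`TrackTable`."""
    df = pd.read_csv(path)
    return TrackTable(df, frame_rate)


# ---------------------------------------------------------------------------
# config

def load_config(path: str) -> dict:
    """Load a YAML config; materialize geometry/arena sections into domain types.

    Recognized sections: ``geometry`` (mic_positions, speed_of_sound,
    sample_rate), ``arena`` (polygon, z_plane) and free-form threshold keys.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    out = dict(cfg)
    if "geometry" in cfg:
        g = cfg["geometry"]
        out["geometry"] = ArrayGeometry(
            np.asarray(g["mic_positions"], dtype=float),
            speed_of_sound=float(g.get("speed_of_sound", 343.0)),
            sample_rate=float(g.get("sample_rate", 450450.0)),
        )
    if "arena" in cfg:
        a = cfg["arena"]
        out["arena"] = ArenaFloor(np.asarray(a["polygon"], dtype=float),
                                  z_plane=float(a.get("z_plane", 0.0)))
    return out
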