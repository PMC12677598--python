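"""Domain types, electrode-grid geometry, session container I/O and stream alignment.

The session container is a self-describing HDF5 file (groups ``/signals``,
``/impedances``, ``/layout``, ``/meta``) with a ``schema_version`` attribute.
All timestamps are seconds from session start (float64); feature bins are
half-open ``[t, t + bin)``.  Voltages are in microvolts, impedances in
megaohm at 1 kHz, planar distances in millimetres internally (the layout
constructor takes micrometres, matching how electrode pitch is usually
quoted for micro-ECoG arrays).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import (
    CorruptFileError,
    InvalidArgumentError,
    NoOverlapError,
    SchemaVersionError,
    SessionIOError,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "ecogpipe-session-1"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArrayLayout:
    """Regular planar electrode grid.

    Channels are ordered row-major from the top-left corner of the grid;
    every per-channel array in the pipeline follows this order.  Site
    coordinates are in millimetres, centred so the array centroid sits at
    the origin, with x increasing along columns and y decreasing along rows
    (top row has the largest y).
    """

    n_rows: int
    n_cols: int
    pitch_um: float
    diameter_um: float
    site_xy: np.ndarray          # (n_channels, 2) mm, centroid at origin
    channel_ids: np.ndarray      # (n_channels,) int

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pitch_mm(self) -> float:
        return self.pitch_um / 1000.0

    def density_per_cm2(self) -> float:
        """Channels per cm^2 of a pitch-aligned unit window (10 mm / pitch)^2."""
        return (10.0 / self.pitch_mm) ** 2

    def grid_indices(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) per channel, row-major order."""
        rows, cols = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.column_stack([rows, cols])

    def channel_at(self, row: int, col: int) -> int:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise InvalidArgumentError(f"grid position ({row}, {col}) outside layout")
        return row * self.n_cols + col


def build_layout(n_rows: int, n_cols: int, pitch_um: float,
                 diameter_um: float) -> ElectrodeArrayLayout:
    """Build a regular grid layout centred at the origin.

    Parameters mirror how micro-ECoG arrays are specified: a 16x16 grid at
    1250 um pitch with 850 um sites gives 256 channels at 64 channels/cm^2.
    """
    if n_rows < 1 or n_cols < 1:
        raise InvalidArgumentError("grid dimensions must be >= 1")
    if not (pitch_um > diameter_um > 0):
        raise InvalidArgumentError("require pitch > diameter > 0")
    pitch_mm = pitch_um / 1000.0
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = (cols - (n_cols - 1) / 2.0) * pitch_mm
    y = ((n_rows - 1) / 2.0 - rows) * pitch_mm
    site_xy = np.column_stack([x, y])
    return ElectrodeArrayLayout(
        n_rows=n_rows, n_cols=n_cols, pitch_um=float(pitch_um),
        diameter_um=float(diameter_um), site_xy=site_xy,
        channel_ids=np.arange(n_rows * n_cols),
    )


@dataclass
class SessionRecording:
    """Multichannel voltage recording plus per-channel metadata."""

    signals: np.ndarray          # (n_channels, n_samples), microvolts
    fs: float                    # Hz
    t0: float                    # epoch timestamp of first sample, s
    impedances: np.ndarray       # (n_channels,), MOhm at 1 kHz
    layout: ElectrodeArrayLayout
    channel_mask: np.ndarray = None  # (n_channels,) bool, True = included

    def __post_init__(self):
        self.signals = np.asarray(self.signals)
        n_ch = self.layout.n_channels
        if self.signals.shape[0] != n_ch:
            raise InvalidArgumentError(
                f"signals have {self.signals.shape[0]} rows, layout has {n_ch} channels")
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        self.impedances = np.asarray(self.impedances, dtype=float)
        if self.impedances.shape != (n_ch,):
            raise InvalidArgumentError("impedances must be one value per channel")
        if np.any(self.impedances < 0):
            raise InvalidArgumentError("impedances must be non-negative")
        if self.channel_mask is None:
            self.channel_mask = np.ones(n_ch, dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        if self.channel_mask.shape != (n_ch,):
            raise InvalidArgumentError("channel_mask must be one flag per channel")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds from session start."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class KinematicTrace:
    """Time-stamped 3-D position and per-axis velocity of one tracked effector."""

    timestamps: np.ndarray       # (n,), s, strictly increasing
    position: np.ndarray         # (n, 3)
    speed: np.ndarray            # (n, 3), units/s
    effector_label: str = "effector"

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.position = np.atleast_2d(np.asarray(self.position, dtype=float))
        self.speed = np.atleast_2d(np.asarray(self.speed, dtype=float))
        if self.timestamps.ndim != 1:
            raise InvalidArgumentError("timestamps must be 1-D")
        if len(self.timestamps) != len(self.position) or len(self.position) != len(self.speed):
            raise InvalidArgumentError("timestamps, position and speed must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise InvalidArgumentError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def t_start(self) -> float:
        return float(self.timestamps[0])

    @property
    def t_end(self) -> float:
        return float(self.timestamps[-1])

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "time_s": self.timestamps,
            "x": self.position[:, 0], "y": self.position[:, 1], "z": self.position[:, 2],
            "vx": self.speed[:, 0], "vy": self.speed[:, 1], "vz": self.speed[:, 2],
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, effector_label: str = "effector") -> "KinematicTrace":
        df = pd.read_csv(path)
        required = {"time_s", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise SessionIOError(f"kinematics CSV {path} missing columns {required - set(df.columns)}")
        t = df["time_s"].to_numpy(float)
        pos = df[["x", "y", "z"]].to_numpy(float)
        if {"vx", "vy", "vz"}.issubset(df.columns):
            spd = df[["vx", "vy", "vz"]].to_numpy(float)
        else:
            spd = np.gradient(pos, t, axis=0)
        return cls(timestamps=t, position=pos, speed=spd, effector_label=effector_label)


@dataclass
class RunConfig:
    """Run-wide parameters for preprocessing and decoding."""

    seed: int = 1
    band: tuple = (70.0, 150.0)          # high-gamma band, Hz
    bin_ms: float = 100.0                # feature bin duration
    notch_base: float = 50.0             # line frequency, Hz
    n_harmonics: int = 4                 # notches at base * {1..n}
    target_fs: float = 500.0             # decimation target, Hz
    impedance_threshold: float = 1.0     # MOhm; channels above are excluded
    split_ratio: float = 0.7             # chronological train fraction

    def __post_init__(self):
        low, high = self.band
        if not (0 < low < high < self.target_fs / 2):
            raise InvalidArgumentError("require 0 < band low < band high < target_fs/2")
        if self.bin_ms <= 0:
            raise InvalidArgumentError("bin_ms must be positive")
        if not (0 < self.split_ratio < 1):
            raise InvalidArgumentError("split_ratio must be in (0, 1)")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Session container I/O
# ---------------------------------------------------------------------------

def write_session(session: SessionRecording, path) -> None:
    """Write a session to the HDF5 container; signals round-trip bit-exactly."""
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.create_dataset("signals", data=session.signals)
            f.create_dataset("impedances", data=session.impedances)
            f.create_dataset("channel_mask", data=session.channel_mask)
            lay = f.create_group("layout")
            lay.attrs["n_rows"] = session.layout.n_rows
            lay.attrs["n_cols"] = session.layout.n_cols
            lay.attrs["pitch_um"] = session.layout.pitch_um
            lay.attrs["diameter_um"] = session.layout.diameter_um
            lay.create_dataset("site_xy", data=session.layout.site_xy)
            lay.create_dataset("channel_ids", data=session.layout.channel_ids)
            meta = f.create_group("meta")
            meta.attrs["fs"] = session.fs
            meta.attrs["t0"] = session.t0
    except OSError as exc:
        raise SessionIOError(f"cannot write session container {path}: {exc}") from exc


def read_session(path) -> SessionRecording:
    """Read a session container written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise SessionIOError(f"session container not found: {path}")
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise SchemaVersionError(
                    f"{path}: schema version {version!r}, expected {SCHEMA_VERSION!r}")
            lay = f["layout"]
            layout = ElectrodeArrayLayout(
                n_rows=int(lay.attrs["n_rows"]), n_cols=int(lay.attrs["n_cols"]),
                pitch_um=float(lay.attrs["pitch_um"]),
                diameter_um=float(lay.attrs["diameter_um"]),
                site_xy=lay["site_xy"][()], channel_ids=lay["channel_ids"][()],
            )
            return SessionRecording(
                signals=f["signals"][()], fs=float(f["meta"].attrs["fs"]),
                t0=float(f["meta"].attrs["t0"]), impedances=f["impedances"][()],
                layout=layout, channel_mask=f["channel_mask"][()],
            )
    except SchemaVersionError:
        raise
    except (OSError, KeyError) as exc:
        raise CorruptFileError(f"corrupt session container {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Stream alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignedStreams:
    """Per-bin pairing of feature bins with interpolated kinematics.

    ``bin_index[i]`` is the index of the i-th retained bin within the full
    binning of the neural session; ``position``/``speed`` are the kinematics
    linearly interpolated at that bin's right edge.
    """

    bin_index: np.ndarray        # (m,) int
    bin_edge_s: np.ndarray       # (m,) right edges, s
    position: np.ndarray         # (m, 3)
    speed: np.ndarray            # (m, 3)

    def __len__(self) -> int:
        return len(self.bin_index)


def align_streams(neural: SessionRecording, kin: KinematicTrace,
                  bin_ms: float) -> AlignedStreams:
    """Pair each feature bin with the kinematic value at the bin's right edge.

    Bins are half-open ``[t, t + bin)`` starting at the neural stream's first
    sample.  A bin is retained only if it lies entirely within the overlap of
    the two streams; kinematics are linearly interpolated at the right edge.
    """
    if bin_ms <= 0:
        raise InvalidArgumentError("bin_ms must be positive")
    dt = bin_ms / 1000.0
    neural_start, neural_end = 0.0, neural.duration
    if kin.t_start >= neural_end or kin.t_end <= neural_start:
        raise NoOverlapError(
            f"kinematics [{kin.t_start}, {kin.t_end}] s do not overlap "
            f"neural [{neural_start}, {neural_end}] s")
    n_bins = int(np.floor(neural.duration / dt))
    starts = np.arange(n_bins) * dt
    edges = starts + dt
    keep = (starts >= kin.t_start - 1e-12) & (edges <= min(neural_end, kin.t_end) + 1e-12)
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        raise NoOverlapError("no complete feature bin inside the stream overlap")
    t_query = edges[idx]
    pos = np.column_stack([
        np.interp(t_query, kin.timestamps, kin.position[:, a]) for a in range(3)])
    spd = np.column_stack([
        np.interp(t_query, kin.timestamps, kin.speed[:, a]) for a in range(3)])
    return AlignedStreams(bin_index=idx, bin_edge_s=t_query, position=pos, speed=spd)
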