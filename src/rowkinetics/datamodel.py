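"""Shared domain types, channel vocabularies and session I/O.

Conventions used throughout the package:

* SI units everywhere internally — metres, seconds, radians, newtons, watts.
  Mass-denominated force thresholds (the "20 kg / 10 kg" convention of rowing
  telemetry software) are converted at the boundary with g = 9.81 m/s².
* 0-based, half-open index slices ``[start, end)``; consecutive rowing cycles
  concatenate without overlap.
* Both rowing conditions (ergometer, boat) share the same types and differ
  only in their channel vocabulary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

G_ACCEL = 9.81  # m/s², used for kgf -> N conversion at the config boundary

ERGO_CONDITION = "ergometer"
BOAT_CONDITION = "boat"

#: channel vocabulary for the single ergometer stream (150 Hz native)
ERGO_CHANNELS = ["X_handle", "X_chest", "X_seat", "F_handle", "F_feet"]

#: channels of the boat-mounted instrumentation stream (gate + GPS box)
BOAT_CHANNELS = [
    "theta_port",
    "theta_starboard",
    "Fgate_x_port",
    "Fgate_y_port",
    "Fgate_x_starboard",
    "Fgate_y_starboard",
    "F_feet",
    "V_boat",
    "A_boat",
]

#: channels of each body-worn IMU stream (free acceleration, angular rate, tilt)
IMU_CHANNELS = ["acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z", "tilt"]

IMU_STREAMS = ["imu_pelvis", "imu_lumbar", "imu_thoracic"]

#: required streams/channels per condition
REQUIRED_STREAMS = {
    ERGO_CONDITION: {"ergo": ERGO_CHANNELS},
    BOAT_CONDITION: {
        "boat": BOAT_CHANNELS,
        "imu_boat": ["acc_x"],
        **{name: IMU_CHANNELS for name in IMU_STREAMS},
    },
}

TARGET_NAMES = ["Ff_x", "Fh_x", "Ph_x", "Pa", "Pt", "Pl"]


class SessionError(ValueError):
    """Raised for malformed sessions (missing channels, bad indices...)."""


@dataclass
class SensorStream:
    """Uniformly sampled multichannel time series.

    Parameters
    ----------
    sample_rate_hz : float
        Sampling frequency, > 0.
    t0_s : float
        Session-relative time of the first sample.
    channels : list of str
        Ordered channel names.
    values : ndarray, shape (n_samples, n_channels)
        Samples in SI units.
    """

    sample_rate_hz: float
    t0_s: float
    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.sample_rate_hz <= 0:
            raise SessionError("sample_rate_hz must be > 0")
        if self.values.shape[0] < 2:
            raise SessionError("a SensorStream needs at least 2 samples")
        if self.values.shape[1] != len(self.channels):
            raise SessionError(
                f"values has {self.values.shape[1]} columns for "
                f"{len(self.channels)} channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.sample_rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return a single channel as a 1-D array (a view, not a copy)."""
        try:
            j = self.channels.index(name)
        except ValueError as exc:
            raise SessionError(f"missing:{name}") from exc
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.channels)
        df.insert(0, "time_s", self.time_s)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SensorStream":
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise SessionError("stream too short")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SessionError("non-uniform sampling in CSV")
        channels = [c for c in df.columns if c != "time_s"]
        return cls(
            sample_rate_hz=1.0 / float(np.mean(dt)),
            t0_s=float(t[0]),
            channels=channels,
            values=df[channels].to_numpy(float),
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "SensorStream":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class SubjectProfile:
    """Anthropometry and condition of one rower."""

    subject_id: str
    height_m: float
    mass_kg: float
    condition: str

    def __post_init__(self) -> None:
        if not (1.0 < self.height_m < 2.5):
            raise SessionError(f"implausible height {self.height_m} m")
        if not (30.0 < self.mass_kg < 150.0):
            raise SessionError(f"implausible mass {self.mass_kg} kg")
        if self.condition not in (ERGO_CONDITION, BOAT_CONDITION):
            raise SessionError(f"unknown condition {self.condition!r}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "subject_id": self.subject_id,
                    "height_m": self.height_m,
                    "mass_kg": self.mass_kg,
                    "condition": self.condition,
                },
                indent=2,
            )
        )

    @classmethod
    def read_json(cls, path: str | Path) -> "SubjectProfile":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class RowingCycle:
    """One finish-to-finish slice of a session.

    Indices are sample indices into the session stream; the slice is
    half-open ``[start_idx, end_idx)``.  ``catch_idx`` marks the catch event
    (reference-signal minimum) inside the cycle.  The threshold-detected
    effective drive-phase window ``[drive_start_idx, drive_end_idx)`` is
    filled in after force-based detection and may be absent before it.
    """

    subject_id: str
    start_idx: int
    end_idx: int
    catch_idx: int
    stroke_rate_spm: float
    drive_start_idx: int | None = None
    drive_end_idx: int | None = None
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.start_idx < self.catch_idx < self.end_idx):
            raise SessionError(
                f"cycle indices must satisfy start < catch < end, got "
                f"{self.start_idx}, {self.catch_idx}, {self.end_idx}"
            )
        if self.drive_start_idx is not None or self.drive_end_idx is not None:
            if self.drive_start_idx is None or self.drive_end_idx is None:
                raise SessionError("drive window must set both indices")
            if not (
                self.start_idx <= self.drive_start_idx
                < self.drive_end_idx <= self.end_idx
            ):
                raise SessionError("drive window outside cycle bounds")

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx

    @property
    def drive_slice(self) -> slice:
        """Effective drive window as a slice relative to the session stream."""
        if self.drive_start_idx is None:
            raise SessionError("drive phase not detected for this cycle")
        return slice(self.drive_start_idx, self.drive_end_idx)

    @property
    def catch_to_finish_slice(self) -> slice:
        """Entire drive phase (catch to finish), relative to the session."""
        return slice(self.catch_idx, self.end_idx)


@dataclass
class KineticTargets:
    """The six target sequences of one cycle, aligned with the cycle samples.

    ``Ff_x`` horizontal foot-stretcher force (N); ``Fh_x`` handle chain
    tension on the ergometer or the port+starboard propulsive gate force on
    the boat (N); ``Ph_x`` handle power (W); ``Pa``/``Pt``/``Pl`` arm, trunk
    and leg segment powers (W).
    """

    Ff_x: np.ndarray
    Fh_x: np.ndarray
    Ph_x: np.ndarray
    Pa: np.ndarray
    Pt: np.ndarray
    Pl: np.ndarray

    def __post_init__(self) -> None:
        lengths = {len(getattr(self, n)) for n in TARGET_NAMES}
        if len(lengths) != 1:
            raise SessionError("target sequences must all have equal length")

    def __len__(self) -> int:
        return len(self.Ff_x)

    def as_matrix(self) -> np.ndarray:
        """Stack the six targets as a (n_samples, 6) matrix in canonical order."""
        return np.column_stack([getattr(self, n) for n in TARGET_NAMES])

    @classmethod
    def from_matrix(cls, mat: np.ndarray) -> "KineticTargets":
        mat = np.asarray(mat, float)
        if mat.ndim != 2 or mat.shape[1] != 6:
            raise SessionError("target matrix must be (n, 6)")
        return cls(**{n: mat[:, j] for j, n in enumerate(TARGET_NAMES)})

    def to_csv(self, path: str | Path, sample_rate_hz: float) -> None:
        df = pd.DataFrame(self.as_matrix(), columns=TARGET_NAMES)
        df.insert(0, "time_s", np.arange(len(self)) / sample_rate_hz)
        df.to_csv(path, index=False, float_format="%.9g")


@dataclass
class FeatureSet:
    """Per-cycle input matrix for the network plus its channel names.

    Scalar subject/session features (height, mass, drive durations...) are
    broadcast as constant channels so the per-cycle matrix is purely
    sequential: shape (cycle_length, n_inputs) with n_inputs = 16 on the
    ergometer and 18 on the boat.
    """

    channels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape[1] != len(self.channels):
            raise SessionError("feature matrix width must match channel names")

    @property
    def n_inputs(self) -> int:
        return len(self.channels)


def validate_session(
    streams: Mapping[str, SensorStream], profile: SubjectProfile
) -> list[str]:
    """Check that a session has the required streams/channels for its condition.

    Returns a list of human-readable issues; an empty list means the session
    is well-formed.  Issue vocabulary: ``missing:<stream or channel>``,
    ``length_mismatch:<stream>``, ``rate_mismatch:<stream>``, ``nan:<stream>``.
    """
    issues: list[str] = []
    required = REQUIRED_STREAMS[profile.condition]
    ref_len = None
    ref_rate = None
    for stream_name, channels in required.items():
        if stream_name not in streams:
            issues.append(f"missing:{stream_name}")
            continue
        stream = streams[stream_name]
        for ch in channels:
            if ch not in stream.channels:
                issues.append(f"missing:{ch}")
        if ref_len is None:
            ref_len, ref_rate = stream.n_samples, stream.sample_rate_hz
        else:
            if stream.n_samples != ref_len:
                issues.append(f"length_mismatch:{stream_name}")
            if not np.isclose(stream.sample_rate_hz, ref_rate, rtol=1e-6):
                issues.append(f"rate_mismatch:{stream_name}")
    return issues


def write_session(
    directory: str | Path,
    streams: Mapping[str, SensorStream],
    profile: SubjectProfile,
    targets: Sequence[KineticTargets] | None = None,
    cycles: Iterable[RowingCycle] | None = None,
) -> None:
    """Write a session as one CSV per stream plus subject metadata JSON.

    Ground-truth targets, when given, go under ``truth/`` as one CSV per cycle.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profile.to_json(directory / "subject.json")
    for name, stream in streams.items():
        stream.to_csv(directory / f"{name}.csv")
    if targets is not None:
        truth_dir = directory / "truth"
        truth_dir.mkdir(exist_ok=True)
        rate = next(iter(streams.values())).sample_rate_hz
        for i, tgt in enumerate(targets):
            tgt.to_csv(truth_dir / f"cycle_{i:04d}.csv", rate)
    if cycles is not None:
        rows = [
            {
                "subject_id": c.subject_id,
                "start_idx": c.start_idx,
                "catch_idx": c.catch_idx,
                "end_idx": c.end_idx,
                "stroke_rate_spm": c.stroke_rate_spm,
            }
            for c in cycles
        ]
        pd.DataFrame(rows).to_csv(directory / "cycles.csv", index=False)


def read_session(directory: str | Path) -> tuple[dict[str, SensorStream], SubjectProfile]:
    """Read back a session written by :func:`write_session`."""
    directory = Path(directory)
    profile = SubjectProfile.read_json(directory / "subject.json")
    streams = {
        p.stem: SensorStream.read_csv(p)
        for p in sorted(directory.glob("*.csv"))
        if p.stem != "cycles"
    }
    return streams, profile
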