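"""Network input features: per-cycle kinematic channel matrices and the
train-time z-normalization.

16 channels on the ergometer (positions, segment velocities and
accelerations, plus six subject/session scalars broadcast as constant
channels) and 18 on the boat (oar angular velocity, boat velocity and
acceleration, the three body-IMU horizontal velocities, the first principal
component of each IMU's acceleration and angular rate, plus six scalars).
No measured force or power ever enters the feature path — enforced by a
channel-name blacklist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datamodel import FeatureSet, RowingCycle, SensorStream, SubjectProfile
from .kinetics import ergo_segment_kinematics
from .preprocess import attach_drive_phase, differentiate, integrate_and_highpass

ERGO_FEATURES = [
    "X_handle", "X_chest", "X_seat",
    "V_handle", "V_arms", "V_trunk", "V_legs",
    "A_handle", "A_trunk", "A_legs",
    "height_m", "mass_kg",
    "prev_drive_duration_s", "curr_drive_duration_s",
    "prev_max_handle_speed_mps", "time_max_speed_to_catch_s",
]

BOAT_FEATURES = [
    "oar_angular_velocity", "V_boat", "A_boat",
    "V_imu_thoracic", "V_imu_lumbar", "V_imu_pelvis",
    "pca1_acc_thoracic", "pca1_acc_lumbar", "pca1_acc_pelvis",
    "pca1_gyro_thoracic", "pca1_gyro_lumbar", "pca1_gyro_pelvis",
    "prev_mean_boat_speed_mps", "prev_max_boat_speed_mps",
    "height_m", "mass_kg",
    "prev_drive_duration_s", "curr_drive_duration_s",
]

#: names that must never appear among input features (kinematics-only model)
FORBIDDEN_FEATURE_NAMES = {
    "F_handle", "F_feet", "Fh_x", "Ff_x",
    "Fgate_x_port", "Fgate_y_port", "Fgate_x_starboard", "Fgate_y_starboard",
    "Ph_x", "Pa", "Pt", "Pl",
}


class FeatureError(ValueError):
    pass


class NoPreviousCycleError(FeatureError):
    """First cycle of a session: previous-stroke scalars are undefined."""


def assert_no_forbidden_channels(channels: list[str]) -> None:
    bad = FORBIDDEN_FEATURE_NAMES.intersection(channels)
    if bad:
        raise FeatureError(f"force/power channels in feature path: {sorted(bad)}")


def first_principal_component(xyz: np.ndarray) -> np.ndarray:
    """Project a 3-axis signal onto its first principal axis.

    The signal is mean-centered and projected onto the leading right
    singular vector of the (n, 3) block.  The sign is fixed so the loading on
    the sensor's first (forward) axis is positive — the component is only
    defined up to sign otherwise.
    """
    xyz = np.asarray(xyz, float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise FeatureError("expected an (n, 3) signal block")
    centered = xyz - xyz.mean(axis=0)
    if np.allclose(centered, 0.0):
        raise FeatureError("degenerate_signal")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    nonzero = np.nonzero(np.abs(axis) > 1e-12)[0]
    if axis[nonzero[0]] < 0:
        axis = -axis
    return centered @ axis


@dataclass
class NormStats:
    """Per-channel mean/std of features and targets, fitted on training data."""

    feature_channels: list[str]
    target_channels: list[str]
    feature_mean: np.ndarray
    feature_std: np.ndarray
    target_mean: np.ndarray
    target_std: np.ndarray

    def transform_features(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_mean) / self.feature_std

    def transform_targets(self, Y: np.ndarray) -> np.ndarray:
        return (Y - self.target_mean) / self.target_std

    def inverse_targets(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.target_std + self.target_mean

    def to_dict(self) -> dict:
        return {
            "feature_channels": self.feature_channels,
            "target_channels": self.target_channels,
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "target_mean": self.target_mean.tolist(),
            "target_std": self.target_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(
            feature_channels=list(d["feature_channels"]),
            target_channels=list(d["target_channels"]),
            feature_mean=np.asarray(d["feature_mean"], float),
            feature_std=np.asarray(d["feature_std"], float),
            target_mean=np.asarray(d["target_mean"], float),
            target_std=np.asarray(d["target_std"], float),
        )


def _pooled_stats(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    pooled = np.concatenate(mats, axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    zero = std <= 0
    if np.any(zero):
        warnings.warn("zero-variance channel(s); std replaced by 1", stacklevel=3)
        std = np.where(zero, 1.0, std)
    return mean, std


def fit_norm(
    feature_mats: list[np.ndarray],
    target_mats: list[np.ndarray],
    feature_channels: list[str],
    target_channels: list[str],
) -> NormStats:
    """Fit per-channel normalization on the training cycles only."""
    if len(feature_mats) < 2:
        raise FeatureError("need at least 2 training cycles to fit normalization")
    f_mean, f_std = _pooled_stats(feature_mats)
    t_mean, t_std = _pooled_stats(target_mats)
    return NormStats(feature_channels, target_channels, f_mean, f_std, t_mean, t_std)


# ---------------------------------------------------------------------------
# session-level channel computation + per-cycle assembly
# ---------------------------------------------------------------------------

def _with_drive_phases(
    cycles: list[RowingCycle], force: np.ndarray
) -> list[RowingCycle]:
    if any(c.drive_start_idx is None for c in cycles):
        cycles = attach_drive_phase(list(cycles), force)
    return cycles


def ergo_feature_channels(
    stream: SensorStream, smooth_cutoff_hz: float | None = None
) -> dict[str, np.ndarray]:
    """Session-long sequential feature channels for an ergometer stream."""
    fs = stream.sample_rate_hz
    kin = ergo_segment_kinematics(
        stream.channel("X_handle"), stream.channel("X_chest"), stream.channel("X_seat"), fs
    )
    if smooth_cutoff_hz is not None:
        # recompute velocities with pre-smoothing for noisy sessions
        Vh = differentiate(kin.Xh, fs, smooth_cutoff_hz)
        Va = differentiate(kin.Xa, fs, smooth_cutoff_hz)
        Vt = differentiate(kin.Xt, fs, smooth_cutoff_hz)
        Vl = differentiate(kin.Xs, fs, smooth_cutoff_hz)
    else:
        Vh, Va, Vt, Vl = kin.Vh, kin.Va, kin.Vt, kin.Vl
    return {
        "X_handle": kin.Xh, "X_chest": kin.Xc, "X_seat": kin.Xs,
        "V_handle": Vh, "V_arms": Va, "V_trunk": Vt, "V_legs": Vl,
        "A_handle": differentiate(Vh, fs), "A_trunk": differentiate(Vt, fs),
        "A_legs": differentiate(Vl, fs),
    }


def build_ergo_features(
    cycle: RowingCycle,
    channels: dict[str, np.ndarray],
    profile: SubjectProfile,
    prev_cycle: RowingCycle | None,
    sample_rate_hz: float,
) -> FeatureSet:
    """Assemble the 16-channel ergometer feature matrix for one cycle.

    Needs the preceding cycle for the previous-stroke scalars (drive
    duration, maximum handle speed, and the flywheel spin-down proxy: time
    from the previous handle-speed maximum to the current catch).
    """
    if prev_cycle is None:
        raise NoPreviousCycleError("no_previous_cycle")
    if cycle.drive_start_idx is None or prev_cycle.drive_start_idx is None:
        raise FeatureError("drive phases must be detected before feature building")
    fs = sample_rate_hz
    sl = slice(cycle.start_idx, cycle.end_idx)
    vh_prev = channels["V_handle"][prev_cycle.start_idx : prev_cycle.end_idx]
    prev_max_idx = prev_cycle.start_idx + int(np.argmax(vh_prev))
    scalars = {
        "height_m": profile.height_m,
        "mass_kg": profile.mass_kg,
        "prev_drive_duration_s": (prev_cycle.drive_end_idx - prev_cycle.drive_start_idx) / fs,
        "curr_drive_duration_s": (cycle.drive_end_idx - cycle.drive_start_idx) / fs,
        "prev_max_handle_speed_mps": float(np.max(vh_prev)),
        "time_max_speed_to_catch_s": (cycle.catch_idx - prev_max_idx) / fs,
    }
    n = cycle.n_samples
    cols = []
    for name in ERGO_FEATURES:
        if name in channels:
            cols.append(channels[name][sl])
        else:
            cols.append(np.full(n, scalars[name]))
    assert_no_forbidden_channels(ERGO_FEATURES)
    return FeatureSet(channels=list(ERGO_FEATURES), values=np.column_stack(cols))


def boat_feature_channels(streams: dict[str, SensorStream]) -> dict[str, np.ndarray]:
    """Session-long sequential feature channels for a boat session.

    IMU horizontal velocities come from drift-free integration of the free
    acceleration; the 1PCA channels are fitted per IMU over the whole session
    and then sliced per cycle.
    """
    boat = streams["boat"]
    fs = boat.sample_rate_hz
    out = {
        "oar_angular_velocity": differentiate(boat.channel("theta_starboard"), fs),
        "V_boat": boat.channel("V_boat"),
        "A_boat": boat.channel("A_boat"),
    }
    for short, name in (("thoracic", "imu_thoracic"), ("lumbar", "imu_lumbar"),
                        ("pelvis", "imu_pelvis")):
        imu = streams[name]
        out[f"V_imu_{short}"] = integrate_and_highpass(imu.channel("acc_x"), fs)
        acc = np.column_stack([imu.channel(f"acc_{a}") for a in "xyz"])
        gyro = np.column_stack([imu.channel(f"gyro_{a}") for a in "xyz"])
        out[f"pca1_acc_{short}"] = first_principal_component(acc)
        out[f"pca1_gyro_{short}"] = first_principal_component(gyro)
    return out


def build_boat_features(
    cycle: RowingCycle,
    channels: dict[str, np.ndarray],
    profile: SubjectProfile,
    prev_cycle: RowingCycle | None,
    sample_rate_hz: float,
) -> FeatureSet:
    """Assemble the 18-channel boat feature matrix for one cycle."""
    if prev_cycle is None:
        raise NoPreviousCycleError("no_previous_cycle")
    if cycle.drive_start_idx is None or prev_cycle.drive_start_idx is None:
        raise FeatureError("drive phases must be detected before feature building")
    fs = sample_rate_hz
    sl = slice(cycle.start_idx, cycle.end_idx)
    v_prev = channels["V_boat"][prev_cycle.start_idx : prev_cycle.end_idx]
    scalars = {
        "prev_mean_boat_speed_mps": float(np.mean(v_prev)),
        "prev_max_boat_speed_mps": float(np.max(v_prev)),
        "height_m": profile.height_m,
        "mass_kg": profile.mass_kg,
        "prev_drive_duration_s": (prev_cycle.drive_end_idx - prev_cycle.drive_start_idx) / fs,
        "curr_drive_duration_s": (cycle.drive_end_idx - cycle.drive_start_idx) / fs,
    }
    n = cycle.n_samples
    cols = []
    for name in BOAT_FEATURES:
        if name in channels:
            cols.append(channels[name][sl])
        else:
            cols.append(np.full(n, scalars[name]))
    assert_no_forbidden_channels(BOAT_FEATURES)
    return FeatureSet(channels=list(BOAT_FEATURES), values=np.column_stack(cols))


def build_session_features(
    streams: dict[str, SensorStream],
    cycles: list[RowingCycle],
    profile: SubjectProfile,
    force: np.ndarray,
    smooth_cutoff_hz: float | None = None,
) -> tuple[list[RowingCycle], list[FeatureSet]]:
    """Build feature matrices for all cycles of a session with a prior cycle.

    ``force`` is the session-long handle/gate force used only for effective
    drive-phase detection (the drive durations are Table-style scalar
    features); it never enters a feature channel.  Returns the kept cycles
    (the first cycle of the session is dropped) and their FeatureSets.
    """
    condition = profile.condition
    cycles = _with_drive_phases(cycles, force)
    if condition == "ergometer":
        channels = ergo_feature_channels(streams["ergo"], smooth_cutoff_hz)
        build = build_ergo_features
        fs = streams["ergo"].sample_rate_hz
    else:
        channels = boat_feature_channels(streams)
        build = build_boat_features
        fs = streams["boat"].sample_rate_hz
    kept, feats = [], []
    for prev, cur in zip(cycles[:-1], cycles[1:]):
        feats.append(build(cur, channels, profile, prev, fs))
        kept.append(cur)
    return kept, feats
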