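"""Synthetic rowing-session generator with known ground-truth kinetics.

The generator is phenomenological: it emulates the cyclic drive/recovery
structure of rowing, the sequential legs → trunk → arms involvement, and
forces tied to the kinematics, without modelling hydrodynamics or the
flywheel.  Its purpose is to give every downstream stage (segmentation,
target computation, feature building, network training, evaluation) inputs
whose true forces and powers are known exactly.

Waveform family
---------------
Within the drive the handle (or oar-angle) velocity is a warped raised
cosine ``v(u) = sin²(π u^k)`` on drive fraction ``u ∈ [0, 1]``, with
``k = ln 0.5 / ln p`` so the velocity — and hence the force — peaks at the
requested fraction ``p`` of the drive.  Positions are the (monotone)
integrals of this profile; segment velocities are smooth bump-weighted
shares of the handle velocity with ordered timing.  The recovery mirrors the
drive in time, so segments return in reverse order.

Forces are tied to the kinematics: the handle/gate force is
``gain · max(V, 0)^1.5`` with the gain calibrated so a nominal cycle peaks at
the subject's ``peak_force_N``.  Kinematic inputs therefore carry the force
information the network must learn, and forces vanish identically during the
recovery.

Ground truth
------------
``true_targets`` are computed from the *noise-free* streams through the same
kinetics pipeline used for measured data, so with ``noise_sd = 0`` a
recomputation of the targets from the emitted streams reproduces the ground
truth to float precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import kinetics
from .datamodel import (
    BOAT_CONDITION,
    ERGO_CONDITION,
    IMU_CHANNELS,
    KineticTargets,
    RowingCycle,
    SensorStream,
    SubjectProfile,
)

#: per-channel measurement-noise standard deviations (SI units) at noise_sd=1
NOISE_DEFAULTS = {
    "X_handle": 0.003, "X_chest": 0.003, "X_seat": 0.003,
    "F_handle": 5.0, "F_feet": 5.0,
    "theta_port": 0.005, "theta_starboard": 0.005,
    "Fgate_x_port": 4.0, "Fgate_y_port": 4.0,
    "Fgate_x_starboard": 4.0, "Fgate_y_starboard": 4.0,
    "V_boat": 0.04, "A_boat": 0.08,
    "acc_x": 0.08, "acc_y": 0.08, "acc_z": 0.08,
    "gyro_x": 0.02, "gyro_y": 0.02, "gyro_z": 0.02,
    "tilt": 0.01,
}

FORCE_EXPONENT = 1.5  # force ~ velocity^1.5: peak force grows with peak speed


@dataclass
class TechniqueParams:
    """Subject-level technique parameters driving the waveform generator.

    ``force_peak_position`` is the fraction of the drive at which the
    handle/gate force peaks; ``segment_phase_offsets`` are the (ordered)
    centres of the legs, trunk and arms activity bumps on the drive fraction
    axis; ``noise_sd`` is a scalar multiplier applied to the per-channel
    defaults in :data:`NOISE_DEFAULTS`.
    """

    stroke_rate_spm: float
    drive_fraction: float
    peak_force_N: float
    force_peak_position: float
    segment_phase_offsets: tuple[float, float, float]
    arm_negative_power_flag: bool = False
    noise_sd: float = 1.0
    seed: int = 0
    # secondary shape parameters with sensible defaults
    handle_travel_m: float = 1.40
    foot_force_ratio: float = 1.18
    duration_jitter: float = 0.01   # relative SD, clipped at ±3%
    amplitude_jitter: float = 0.0167  # relative SD, clipped at ±5%
    peak_position_jitter: float = 0.004
    mean_boat_speed_mps: float = 4.6
    oar_sweep_rad: float = 1.6
    oar_catch_angle_rad: float = -1.0
    inner_lever_m: float = kinetics.DEFAULT_INNER_LEVER_M

    def __post_init__(self) -> None:
        if not (0.25 < self.drive_fraction < 0.6):
            raise ValueError("drive_fraction outside (0.25, 0.6)")
        if not (0.0 < self.force_peak_position < 1.0):
            raise ValueError("force_peak_position outside (0, 1)")
        o = self.segment_phase_offsets
        if not (o[0] < o[1] < o[2]):
            raise ValueError("segment phase offsets must be strictly ordered legs < trunk < arms")


@dataclass
class SimulatedSession:
    """A simulated session: noisy streams plus exact ground truth.

    ``streams`` are the emitted (noisy, possibly clock-offset) sensor
    streams; ``clean_streams`` the noise-free aligned versions from which
    ``true_targets`` were computed; ``cycles`` the constructed finish-to-
    finish cycle boundaries.
    """

    profile: SubjectProfile
    params: TechniqueParams
    streams: dict[str, SensorStream]
    clean_streams: dict[str, SensorStream]
    cycles: list[RowingCycle]
    true_targets: list[KineticTargets]

    @property
    def condition(self) -> str:
        return self.profile.condition

    def __iter__(self):
        # allow ``streams, truth = simulate_...(...)`` unpacking
        return iter((self.streams, self.true_targets))


def sample_subject(
    condition: str,
    seed: int,
    arm_fault_prob: float = 0.0,
    noise_sd: float = 1.0,
) -> tuple[SubjectProfile, TechniqueParams]:
    """Draw a subject profile and technique parameters for one rower.

    Anthropometry is drawn near the cohort statistics of competitive male
    scullers (≈1.85 m, ≈79 kg).  Technique parameters are drawn with
    inter-subject spreads well above the within-subject cycle jitter, so
    subjects are separable by their technique determinants.
    """
    rng = np.random.default_rng(seed)
    if condition == ERGO_CONDITION:
        height = rng.normal(1.855, 0.071)
        mass = rng.normal(77.4, 7.0)
        spm = rng.normal(20.0, 0.6)
        peak_force = (mass / 77.4) * rng.normal(820.0, 80.0)
        foot_ratio = rng.normal(1.18, 0.07)
    elif condition == BOAT_CONDITION:
        height = rng.normal(1.85, 0.05)
        mass = rng.normal(79.0, 6.7)
        spm = rng.normal(32.5, 1.5)
        peak_force = (mass / 79.0) * rng.normal(780.0, 80.0)
        foot_ratio = rng.normal(1.04, 0.02)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    height = float(np.clip(height, 1.60, 2.10))
    mass = float(np.clip(mass, 55.0, 120.0))
    profile = SubjectProfile(
        subject_id=f"S{seed:04d}", height_m=height, mass_kg=mass, condition=condition
    )
    offsets = np.sort(rng.normal([0.30, 0.55, 0.76], 0.03))
    # enforce a minimum separation so ordering is strict and bumps distinct
    for i in (1, 2):
        offsets[i] = max(offsets[i], offsets[i - 1] + 0.08)
    params = TechniqueParams(
        stroke_rate_spm=float(np.clip(spm, 14.0, 45.0)),
        drive_fraction=float(np.clip(rng.normal(0.36, 0.035), 0.29, 0.50)),
        peak_force_N=float(np.clip(peak_force, 350.0, 1400.0)),
        force_peak_position=float(rng.uniform(0.26, 0.46)),
        segment_phase_offsets=tuple(float(o) for o in offsets),
        arm_negative_power_flag=bool(rng.uniform() < arm_fault_prob),
        noise_sd=noise_sd,
        seed=int(seed),
        handle_travel_m=float(0.75 * height * rng.normal(1.0, 0.04)),
        foot_force_ratio=float(foot_ratio),
    )
    return profile, params


# ---------------------------------------------------------------------------
# drive-phase waveform machinery
# ---------------------------------------------------------------------------

_GRID = np.linspace(0.0, 1.0, 513)


def _warp_exponent(p: float) -> float:
    return math.log(0.5) / math.log(p)


def _drive_velocity(u: np.ndarray, p: float) -> np.ndarray:
    """Warped raised-cosine velocity profile peaking at drive fraction p."""
    k = _warp_exponent(p)
    return np.sin(np.pi * np.clip(u, 0.0, 1.0) ** k) ** 2


def _segment_weights(
    u: np.ndarray, offsets: tuple[float, float, float]
) -> np.ndarray:
    """Smooth partition of unity over the drive: rows legs/trunk/arms."""
    amps = np.array([1.15, 0.95, 0.90])
    sigma = 0.20
    bumps = amps[:, None] * np.exp(
        -0.5 * ((u[None, :] - np.asarray(offsets)[:, None]) / sigma) ** 2
    )
    return bumps / bumps.sum(axis=0, keepdims=True)


def _cycle_profiles(p: float, offsets, arm_fault: bool):
    """Cumulative displacement shares on the fine grid for one cycle.

    Returns (grid, I) with I of shape (3, n_grid): per-segment normalized
    cumulative displacement; I.sum(axis=0)[-1] == 1.
    """
    u = _GRID
    v = _drive_velocity(u, p)
    w = _segment_weights(u, offsets)
    v_seg = w * v[None, :]
    if arm_fault:
        # arms pull early, then yield mid-drive: a negative arm-velocity lobe
        # (balanced by the trunk) while the handle force is still high
        bump = 0.6 * v * np.exp(-0.5 * ((u - 0.55) / 0.06) ** 2)
        v_seg[2] -= bump
        v_seg[1] += bump
    total = np.trapezoid(v, u)
    I = np.concatenate(
        [np.zeros((3, 1)), np.cumsum((v_seg[:, 1:] + v_seg[:, :-1]) / 2 * np.diff(u), axis=1)],
        axis=1,
    ) / total
    v_norm = v / total
    return u, I, v_norm


def _interp_rows(x: np.ndarray, grid: np.ndarray, rows: np.ndarray) -> np.ndarray:
    return np.vstack([np.interp(x, grid, row) for row in rows])


@dataclass
class _CyclePlan:
    n: int          # samples in the cycle
    n_rec: int      # recovery samples (cycle starts at the finish)
    travel: float   # handle travel this cycle (m)
    p: float        # force/velocity peak position this cycle
    duration_s: float


def _plan_cycles(
    params: TechniqueParams, n_cycles: int, fs: float, rng: np.random.Generator
) -> list[_CyclePlan]:
    period = 60.0 / params.stroke_rate_spm
    plans = []
    for _ in range(n_cycles):
        dur = period * (1.0 + np.clip(rng.normal(0, params.duration_jitter), -0.03, 0.03))
        amp = 1.0 + np.clip(rng.normal(0, params.amplitude_jitter), -0.05, 0.05)
        p = float(np.clip(
            params.force_peak_position + rng.normal(0, params.peak_position_jitter),
            0.05, 0.95,
        ))
        n = max(int(round(dur * fs)), 8)
        n_rec = int(round(n * (1.0 - params.drive_fraction)))
        n_rec = min(max(n_rec, 2), n - 2)
        plans.append(_CyclePlan(n=n, n_rec=n_rec, travel=params.handle_travel_m * amp,
                                p=p, duration_s=n / fs))
    return plans


def _segment_positions_and_velocity(
    plan: _CyclePlan, params: TechniqueParams
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment positions (3, n) and analytic handle velocity (n,) for one cycle."""
    grid, I, v_norm = _cycle_profiles(
        plan.p, params.segment_phase_offsets, params.arm_negative_power_flag
    )
    n_drv = plan.n - plan.n_rec
    tau_d = n_drv / plan.n * plan.duration_s
    u_rec = np.arange(plan.n_rec) / plan.n_rec      # recovery phase in [0,1)
    u_drv = np.arange(n_drv) / n_drv                # drive phase in [0,1)
    # recovery mirrors the drive in time (arms return first)
    I_rec = _interp_rows(1.0 - u_rec, grid, I)
    I_drv = _interp_rows(u_drv, grid, I)
    X = plan.travel * np.concatenate([I_rec, I_drv], axis=1)
    vh = np.concatenate([
        -plan.travel * np.interp(1.0 - u_rec, grid, v_norm) / (plan.n_rec / plan.n * plan.duration_s),
        plan.travel * np.interp(u_drv, grid, v_norm) / tau_d,
    ])
    return X, vh


def _nominal_peak_handle_speed(params: TechniqueParams) -> float:
    """Peak handle (or gate tangential) speed of a nominal, jitter-free cycle."""
    grid, _, v_norm = _cycle_profiles(
        params.force_peak_position, params.segment_phase_offsets, False
    )
    period = 60.0 / params.stroke_rate_spm
    tau_d = params.drive_fraction * period
    return params.handle_travel_m * float(v_norm.max()) / tau_d


def _force_from_speed(v: np.ndarray, gain: float) -> np.ndarray:
    return gain * np.maximum(v, 0.0) ** FORCE_EXPONENT


def _add_noise(
    values: np.ndarray, channels: list[str], noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    out = values.copy()
    if noise_sd > 0:
        for j, ch in enumerate(channels):
            out[:, j] += rng.normal(0.0, NOISE_DEFAULTS[ch] * noise_sd, len(out))
    return out


# ---------------------------------------------------------------------------
# ergometer
# ---------------------------------------------------------------------------

def simulate_ergo_session(
    profile: SubjectProfile,
    params: TechniqueParams,
    n_cycles: int,
    sample_rate_hz: float = 150.0,
) -> SimulatedSession:
    """Simulate one ergometer session with ``n_cycles`` full rowing cycles.

    Emits handle/chest/seat positions and handle/foot forces.  One margin
    cycle is generated on each side (and partially emitted) so every finish
    event of the ``n_cycles`` core cycles is an interior maximum that
    segmentation can detect.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(params.seed)
    fs = sample_rate_hz
    plans = _plan_cycles(params, n_cycles + 2, fs, rng)  # 1 margin cycle each side

    base = np.array([0.0, 0.35, 0.45])  # seat-min, chest-min, handle-extra offsets
    gain = params.peak_force_N / _nominal_peak_handle_speed(params) ** FORCE_EXPONENT

    seg_parts, vh_parts = [], []
    for plan in plans:
        X, vh = _segment_positions_and_velocity(plan, params)
        seg_parts.append(X)
        vh_parts.append(vh)
    seg = np.concatenate(seg_parts, axis=1)  # rows: legs, trunk, arms cumulative shares
    vh = np.concatenate(vh_parts)

    X_seat = base[0] + seg[0]
    X_chest = base[1] + seg[0] + seg[1]
    X_handle = base[2] + seg[0] + seg[1] + seg[2]
    F_handle = _force_from_speed(vh, gain)
    F_feet = params.foot_force_ratio * F_handle

    # emitted window: core cycles plus ~30% of the surrounding recoveries
    starts = np.concatenate([[0], np.cumsum([p.n for p in plans])])
    w0 = starts[1] - int(0.3 * plans[0].n_rec)
    w1 = starts[n_cycles + 1] + int(0.3 * plans[n_cycles + 1].n_rec) + 1
    sl = slice(w0, w1)
    clean = np.column_stack([X_handle[sl], X_chest[sl], X_seat[sl], F_handle[sl], F_feet[sl]])
    channels = ["X_handle", "X_chest", "X_seat", "F_handle", "F_feet"]
    clean_stream = SensorStream(fs, 0.0, channels, clean)

    cycles = [
        RowingCycle(
            subject_id=profile.subject_id,
            start_idx=int(starts[i + 1] - w0),
            end_idx=int(starts[i + 2] - w0),
            catch_idx=int(starts[i + 1] + plans[i + 1].n_rec - w0),
            stroke_rate_spm=60.0 / plans[i + 1].duration_s,
        )
        for i in range(n_cycles)
    ]
    true_targets = kinetics.build_targets({"ergo": clean_stream}, cycles, ERGO_CONDITION)

    noisy = _add_noise(clean, channels, params.noise_sd, rng)
    noisy[:, 3] = np.maximum(noisy[:, 3], 0.0)  # chain tension is unidirectional
    streams = {"ergo": SensorStream(fs, 0.0, channels, noisy)}
    clean_streams = {"ergo": clean_stream}
    return SimulatedSession(profile, params, streams, clean_streams, cycles, true_targets)


# ---------------------------------------------------------------------------
# boat
# ---------------------------------------------------------------------------

def simulate_boat_session(
    profile: SubjectProfile,
    params: TechniqueParams,
    n_cycles: int,
    sample_rate_hz: float = 100.0,
    imu_delay_s: float = 0.0,
) -> SimulatedSession:
    """Simulate one on-water scull session with ``n_cycles`` cycles.

    Emits oar angles and gate force components per side, foot force, GPS
    boat velocity and boat acceleration, a boat-mounted IMU acceleration for
    synchronization, and three body IMU streams (pelvis / lumbar / thoracic).
    ``imu_delay_s`` delays all IMU streams relative to the GPS/gate logger by
    a constant offset, to exercise the synchronization stage; ground truth
    always corresponds to the aligned (zero-delay) streams.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(params.seed)
    fs = sample_rate_hz
    period = 60.0 / params.stroke_rate_spm
    margin = 1 + int(math.ceil(abs(imu_delay_s) / period))
    plans = _plan_cycles(params, n_cycles + 2 * margin, fs, rng)

    # gate force follows the stroke speed just like the ergometer handle force
    gain = params.peak_force_N / _nominal_peak_handle_speed(params) ** FORCE_EXPONENT

    seg_parts, vh_parts = [], []
    for plan in plans:
        X, vh = _segment_positions_and_velocity(plan, params)
        seg_parts.append(X)
        vh_parts.append(vh)
    seg = np.concatenate(seg_parts, axis=1)
    vh = np.concatenate(vh_parts)
    n_total = seg.shape[1]
    t = np.arange(n_total) / fs

    # oar angle follows the overall stroke profile, catch at the minimum
    stroke_shape = (seg[0] + seg[1] + seg[2]) / params.handle_travel_m  # 0..1 per cycle
    theta_star = params.oar_catch_angle_rad + params.oar_sweep_rad * stroke_shape
    theta_port = params.oar_catch_angle_rad + 0.985 * params.oar_sweep_rad * stroke_shape

    F_total = _force_from_speed(vh, gain)  # summed propulsive gate force, both sides
    Fx_star, Fx_port = 0.5 * F_total, 0.5 * F_total
    Fy_star, Fy_port = 0.35 * Fx_star, 0.35 * Fx_port
    F_feet = params.foot_force_ratio * F_total

    # boat speed fluctuates within the cycle: slowest around the catch
    phase = stroke_shape - stroke_shape.mean()
    V_boat = params.mean_boat_speed_mps * (1.0 + 0.07 * phase)
    A_boat = np.gradient(V_boat, 1.0 / fs)

    # body kinematics relative to the boat: pelvis follows the legs, the
    # thoracic IMU adds the trunk opening; lumbar sits in between
    X_Ip = seg[0]
    X_It = seg[0] + seg[1]
    X_Il = seg[0] + 0.5 * seg[1]
    V_Ip = np.gradient(X_Ip, 1.0 / fs)
    V_It = np.gradient(X_It, 1.0 / fs)
    V_Il = np.gradient(X_Il, 1.0 / fs)
    # pelvis tilt from vertical: flexed at the catch, laid back at the finish
    trunk_norm = seg[1] / max(seg[1].max(), 1e-12)
    tilt_p = 0.40 - 0.75 * trunk_norm
    tilt_l = 0.45 - 0.85 * trunk_norm
    tilt_t = 0.50 - 0.95 * trunk_norm

    def imu_values(vel, tilt, lead: float) -> tuple[np.ndarray, list[str]]:
        acc = np.gradient(vel, 1.0 / fs)
        gyro_x = np.gradient(tilt, 1.0 / fs)
        # secondary axes: attenuated, phase-led copies so the first principal
        # component is informative but not axis-aligned
        k = max(int(round(lead * fs)), 1)
        acc_y = 0.35 * np.roll(acc, -k)
        acc_z = 0.15 * np.roll(acc, k)
        gyro_y = 0.30 * np.roll(gyro_x, -k)
        gyro_z = 0.10 * np.roll(gyro_x, k)
        vals = np.column_stack([acc, acc_y, acc_z, gyro_x, gyro_y, gyro_z, tilt])
        return vals, list(IMU_CHANNELS)

    starts = np.concatenate([[0], np.cumsum([p.n for p in plans])])
    w0 = starts[margin] - int(0.3 * plans[margin - 1].n_rec)
    w1 = starts[margin + n_cycles] + int(0.3 * plans[margin + n_cycles].n_rec) + 1
    sl = slice(w0, w1)
    delay = int(round(imu_delay_s * fs))
    sl_imu = slice(w0 - delay, w1 - delay)

    boat_channels = [
        "theta_port", "theta_starboard",
        "Fgate_x_port", "Fgate_y_port", "Fgate_x_starboard", "Fgate_y_starboard",
        "F_feet", "V_boat", "A_boat",
    ]
    boat_full = np.column_stack([
        theta_port, theta_star, Fx_port, Fy_port, Fx_star, Fy_star, F_feet, V_boat, A_boat,
    ])
    imu_full = {
        "imu_pelvis": imu_values(V_Ip, tilt_p, 0.05),
        "imu_lumbar": imu_values(V_Il, tilt_l, 0.07),
        "imu_thoracic": imu_values(V_It, tilt_t, 0.09),
    }
    imu_boat_full = A_boat[:, None]

    clean_streams = {
        "boat": SensorStream(fs, 0.0, boat_channels, boat_full[sl]),
        "imu_boat": SensorStream(fs, 0.0, ["acc_x"], imu_boat_full[sl]),
    }
    for name, (vals, chs) in imu_full.items():
        clean_streams[name] = SensorStream(fs, 0.0, chs, vals[sl])

    cycles = [
        RowingCycle(
            subject_id=profile.subject_id,
            start_idx=int(starts[margin + i] - w0),
            end_idx=int(starts[margin + i + 1] - w0),
            catch_idx=int(starts[margin + i] + plans[margin + i].n_rec - w0),
            stroke_rate_spm=60.0 / plans[margin + i].duration_s,
        )
        for i in range(n_cycles)
    ]
    true_targets = kinetics.build_targets(
        clean_streams, cycles, BOAT_CONDITION, inner_lever_m=params.inner_lever_m
    )

    streams = {
        "boat": SensorStream(
            fs, 0.0, boat_channels,
            _add_noise(boat_full[sl], boat_channels, params.noise_sd, rng),
        ),
        "imu_boat": SensorStream(
            fs, 0.0, ["acc_x"],
            _add_noise(imu_boat_full[sl_imu], ["A_boat"], params.noise_sd, rng),
        ),
    }
    for name, (vals, chs) in imu_full.items():
        streams[name] = SensorStream(
            fs, 0.0, chs, _add_noise(vals[sl_imu], chs, params.noise_sd, rng)
        )
    return SimulatedSession(profile, params, streams, clean_streams, cycles, true_targets)


def simulate_session(
    profile: SubjectProfile, params: TechniqueParams, n_cycles: int, **kwargs
) -> SimulatedSession:
    """Dispatch on the profile's condition."""
    if profile.condition == ERGO_CONDITION:
        return simulate_ergo_session(profile, params, n_cycles, **kwargs)
    return simulate_boat_session(profile, params, n_cycles, **kwargs)
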