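"""Stream preprocessing: drift-free integration, synchronization, resampling,
differentiation, cycle segmentation and effective-drive-phase detection.

Boat sessions carry two independent clocks (the GPS/gate logger and the
wireless body IMUs); they are aligned by cross-correlating the boat velocity
measured by the GPS with the boat velocity obtained by integrating the
boat-mounted IMU acceleration, both high-pass filtered at 0.1 Hz to remove
integration drift and slow trends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from .datamodel import G_ACCEL, RowingCycle, SensorStream

#: effective drive-phase thresholds: onset above 20 kgf, offset below 10 kgf
DRIVE_ON_N = 20.0 * G_ACCEL   # 196.2 N
DRIVE_OFF_N = 10.0 * G_ACCEL  # 98.1 N

#: physiologically plausible cycle durations (50 spm .. 10 spm)
MIN_CYCLE_S = 60.0 / 50.0
MAX_CYCLE_S = 60.0 / 10.0


class PreprocessError(ValueError):
    pass


class SyncError(PreprocessError):
    pass


class DriveDetectionError(PreprocessError):
    pass


@dataclass(frozen=True)
class SyncResult:
    """Lag to apply to the IMU streams to align them with the GPS clock.

    ``lag_s > 0`` means the IMU streams lead and must be delayed;
    ``correlation`` is the normalized cross-correlation at the chosen lag.
    """

    lag_s: float
    correlation: float


def integrate_and_highpass(
    accel: np.ndarray,
    sample_rate_hz: float,
    cutoff_hz: float = 0.1,
    order: int = 2,
) -> np.ndarray:
    """Time-integrate an acceleration channel and high-pass the result.

    Cumulative trapezoidal integration turns m/s² into m/s; the zero-phase
    Butterworth high-pass removes the integration constant and drift, so the
    output is a zero-mean oscillatory velocity.
    """
    accel = np.asarray(accel, float)
    settling_s = 1.0 / cutoff_hz
    if (len(accel) - 1) / sample_rate_hz < 3.0 * settling_s:
        raise PreprocessError("too_short")
    vel = cumulative_trapezoid(accel, dx=1.0 / sample_rate_hz, initial=0.0)
    return highpass(vel, sample_rate_hz, cutoff_hz, order)


def highpass(
    x: np.ndarray, sample_rate_hz: float, cutoff_hz: float = 0.1, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth high-pass (applied forward and backward)."""
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=sample_rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, float))


def synchronize(
    gps_velocity: np.ndarray,
    imu_velocity: np.ndarray,
    sample_rate_hz: float,
    max_lag_s: float = 5.0,
    min_correlation: float = 0.5,
    edge_trim_s: float = 10.0,
) -> SyncResult:
    """Find the lag aligning an IMU-derived velocity with the GPS velocity.

    Both inputs must be identically filtered and sampled at the same rate.
    The lag maximizing the normalized cross-correlation within ±``max_lag_s``
    is returned; peak correlation below ``min_correlation`` raises
    :class:`SyncError` ("sync_failed").
    """
    a = np.asarray(gps_velocity, float)
    b = np.asarray(imu_velocity, float)
    a = (a - a.mean()) / (a.std() + 1e-30)
    b = (b - b.mean()) / (b.std() + 1e-30)
    max_lag = int(round(max_lag_s * sample_rate_hz))
    if max_lag < 1:
        raise SyncError("sync_failed")
    # slide a fixed-length core window of the IMU signal inside the GPS
    # signal: every candidate lag then compares windows of equal length, so
    # quasi-periodic signals cannot alias toward shorter overlaps and the
    # cycle-to-cycle jitter singles out the true lag.  The core is trimmed
    # by the 0.1 Hz high-pass settling time on top of the lag window, so the
    # position-locked filter edge transients of both signals stay outside
    # every compared window.
    n = min(len(a), len(b))
    trim = max_lag + int(round(edge_trim_s * sample_rate_hz))
    while n <= 2 * trim + 2 and trim > max_lag:
        trim = max(max_lag, trim // 2)  # short streams: give up trim, not sync
    if n <= 2 * trim + 2:
        raise SyncError("sync_failed")
    core = b[trim : n - trim]
    xcorr = signal.correlate(a[:n], core, mode="valid")
    # normalize by the per-window GPS norm (true normalized cross-correlation)
    csum = np.concatenate([[0.0], np.cumsum(a[:n] ** 2)])
    win_norm = np.sqrt(csum[len(core) :] - csum[: n - len(core) + 1])
    ncc = xcorr / (win_norm * np.linalg.norm(core) + 1e-30)
    # restrict candidates to the requested lag window
    lo, hi = trim - max_lag, trim + max_lag
    k = lo + int(np.argmax(ncc[lo : hi + 1]))
    lag_samples = k - trim
    seg_a = a[k : k + len(core)]
    corr = float(np.corrcoef(seg_a, core)[0, 1])
    if not np.isfinite(corr) or corr < min_correlation:
        raise SyncError("sync_failed")
    # positive lag: b happens later in a's frame -> shift b forward by lag
    return SyncResult(lag_s=lag_samples / sample_rate_hz, correlation=corr)


def apply_lag(stream: SensorStream, lag_s: float) -> SensorStream:
    """Shift a stream in time by ``lag_s`` (positive delays the stream).

    The shift is applied by moving ``t0_s``; callers that need sample-aligned
    streams should resample afterwards.
    """
    return SensorStream(
        sample_rate_hz=stream.sample_rate_hz,
        t0_s=stream.t0_s + lag_s,
        channels=list(stream.channels),
        values=stream.values.copy(),
    )


def resample(stream: SensorStream, target_hz: float) -> SensorStream:
    """Linearly interpolate a stream onto a uniform grid at ``target_hz``.

    The grid spans the original time range starting at ``t0_s``.
    """
    if target_hz <= 0:
        raise PreprocessError("target_hz must be > 0")
    t_old = stream.time_s
    n_new = int(np.floor(stream.duration_s * target_hz)) + 1
    t_new = stream.t0_s + np.arange(n_new) / target_hz
    values = np.column_stack(
        [np.interp(t_new, t_old, stream.values[:, j]) for j in range(len(stream.channels))]
    )
    return SensorStream(
        sample_rate_hz=target_hz, t0_s=stream.t0_s, channels=list(stream.channels), values=values
    )


def differentiate(
    x: np.ndarray, sample_rate_hz: float, smooth_cutoff_hz: float | None = None
) -> np.ndarray:
    """Time derivative by central finite differences.

    One-sided differences are used at the edges (a linear ramp differentiates
    exactly everywhere).  Optional zero-phase low-pass smoothing can be applied
    before differencing to tame measurement noise.
    """
    x = np.asarray(x, float)
    if smooth_cutoff_hz is not None:
        sos = signal.butter(2, smooth_cutoff_hz, btype="lowpass", fs=sample_rate_hz, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return np.gradient(x, 1.0 / sample_rate_hz)


def segment_cycles(
    reference: np.ndarray,
    sample_rate_hz: float,
    subject_id: str = "",
    min_cycle_s: float = MIN_CYCLE_S,
    max_cycle_s: float = MAX_CYCLE_S,
    prominence_fraction: float = 0.2,
) -> list[RowingCycle]:
    """Segment rowing cycles from a cyclic reference channel.

    The reference is the handle position (ergometer) or the starboard oar
    angle (boat): its maxima are finish events, its minima catch events.
    Cycles run finish-to-finish with the intervening minimum as the catch;
    cycles with implausible durations are discarded.
    """
    x = np.asarray(reference, float)
    rng_x = float(x.max() - x.min())
    if rng_x <= 0:
        return []
    prominence = prominence_fraction * rng_x
    distance = max(1, int(round(sample_rate_hz * MIN_CYCLE_S)))
    finishes, _ = signal.find_peaks(x, prominence=prominence, distance=distance)
    if len(finishes) < 2:
        return []
    catches, _ = signal.find_peaks(-x, prominence=prominence, distance=distance)
    cycles: list[RowingCycle] = []
    for s, e in zip(finishes[:-1], finishes[1:]):
        duration = (e - s) / sample_rate_hz
        if not (min_cycle_s <= duration <= max_cycle_s):
            continue
        inside = catches[(catches > s) & (catches < e)]
        if len(inside) == 0:
            continue
        catch = int(inside[np.argmin(x[inside])])
        cycles.append(
            RowingCycle(
                subject_id=subject_id,
                start_idx=int(s),
                end_idx=int(e),
                catch_idx=catch,
                stroke_rate_spm=60.0 / duration,
            )
        )
    return cycles


def detect_drive_phase(
    handle_force: np.ndarray,
    on_N: float = DRIVE_ON_N,
    off_N: float = DRIVE_OFF_N,
) -> tuple[int, int]:
    """Detect the effective drive phase within one cycle's force sequence.

    The phase starts at the first sample where the force exceeds ``on_N``
    (20 kgf) and ends at the first subsequent sample where it drops below
    ``off_N`` (10 kgf), exclusive.  Returns ``(drive_start, drive_end)`` as
    indices relative to the cycle.
    """
    f = np.asarray(handle_force, float)
    above = np.nonzero(f > on_N)[0]
    if len(above) == 0:
        raise DriveDetectionError("no_drive_detected")
    start = int(above[0])
    below = np.nonzero(f[start:] < off_N)[0]
    if len(below) == 0:
        warnings.warn("drive phase never fell below the offset threshold; "
                      "using the cycle end", stacklevel=2)
        return start, len(f)
    return start, start + int(below[0])


def attach_drive_phase(
    cycles: list[RowingCycle], force: np.ndarray, **kwargs
) -> list[RowingCycle]:
    """Detect and store the effective drive window for each cycle.

    Cycles in which no drive is detected are dropped.  ``force`` is the
    session-long handle/gate force channel.
    """
    kept = []
    for c in cycles:
        try:
            ds, de = detect_drive_phase(force[c.start_idx : c.end_idx], **kwargs)
        except DriveDetectionError:
            continue
        c.drive_start_idx = c.start_idx + ds
        c.drive_end_idx = c.start_idx + de
        kept.append(c)
    return kept


def drop_artifact_cycles(
    cycles: list[RowingCycle],
    channels: dict[str, np.ndarray],
    z_max: float = 6.0,
) -> list[RowingCycle]:
    """Drop cycles containing missing data or gross artifacts.

    A cycle is discarded when any required channel contains NaN inside the
    cycle, or any sample whose session-level z-score magnitude exceeds
    ``z_max``.
    """
    stats = {
        name: (np.nanmean(x), np.nanstd(x) + 1e-30) for name, x in channels.items()
    }
    kept = []
    for c in cycles:
        ok = True
        for name, x in channels.items():
            seg = x[c.start_idx : c.end_idx]
            if np.any(np.isnan(seg)):
                ok = False
                break
            mu, sd = stats[name]
            if np.any(np.abs(seg - mu) / sd > z_max):
                ok = False
                break
        if ok:
            kept.append(c)
    return kept
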