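"""Biomechanical target computation: forces and segment powers.

Three-segment (legs, trunk, arms) power decomposition of the rowing stroke.

Ergometer — cable sensors measure handle, chest and seat positions; with
handle and foot forces the powers follow Kleshnev's decomposition::

    Xa = Xh - Xc          arm length
    Xt = Xc - Xs          trunk opening
    Ph_x = Vh * Fh_x      handle power
    Pa   = Va * Fh_x      arm power
    Pt   = Vt * Fh_x      trunk power
    Pl   = Vl * Ff_x      leg power (Vl = d/dt seat position)

Boat — the gate force and oar angle give the power transferred to the oars,
and body-worn IMU velocities give the segment split::

    Ph = (Fh_x * li * cos(th) + Fh_y * li * sin(th)) * dth/dt   (per side, summed)
    Pl = Ff_x * Vl            with Vl = V_Ip - l_Ip * dth_Ip/dt * cos(th_Ip)
    Pt = Fh_x_sum * Vt        with Vt = V_It - V_Ip
    Pa = Ph + (Ff_x - Fh_x_sum) * V_boat - Pt - Pl

The trunk velocity is the difference between the thoracic and pelvis IMU
horizontal velocities (consistent with the ergometer trunk-opening
derivative); IMU velocities come from time-integrated, 0.1 Hz high-passed
free accelerations.  The inner lever ``li`` (gate-to-handle distance) and the
pelvis-IMU-to-seat distance ``l_Ip`` are rigging constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import KineticTargets, RowingCycle, SensorStream
from .preprocess import differentiate, integrate_and_highpass

#: default inboard lever arm of a scull oar, gate to handle (m)
DEFAULT_INNER_LEVER_M = 0.88
#: pelvis IMU to seat distance, identical for all subjects (m)
PELVIS_IMU_TO_SEAT_M = 0.15


class KineticsError(ValueError):
    pass


def _check_equal_lengths(*arrays: np.ndarray) -> None:
    lengths = {len(a) for a in arrays}
    if len(lengths) != 1:
        raise KineticsError(f"channel length mismatch: {sorted(lengths)}")


@dataclass
class ErgoKinematics:
    """Derived ergometer kinematics (positions m, velocities m/s)."""

    Xh: np.ndarray
    Xc: np.ndarray
    Xs: np.ndarray
    Xa: np.ndarray
    Xt: np.ndarray
    Vh: np.ndarray
    Va: np.ndarray
    Vt: np.ndarray
    Vl: np.ndarray


def ergo_segment_kinematics(
    Xh: np.ndarray, Xc: np.ndarray, Xs: np.ndarray, sample_rate_hz: float
) -> ErgoKinematics:
    """Arm length, trunk opening and segment velocities from cable positions.

    Leg extension is identified with the seat position, so ``Vl`` is the seat
    velocity.  Velocities are central finite differences of the positions.
    """
    Xh, Xc, Xs = (np.asarray(a, float) for a in (Xh, Xc, Xs))
    _check_equal_lengths(Xh, Xc, Xs)
    Xa = Xh - Xc
    Xt = Xc - Xs
    return ErgoKinematics(
        Xh=Xh, Xc=Xc, Xs=Xs, Xa=Xa, Xt=Xt,
        Vh=differentiate(Xh, sample_rate_hz),
        Va=differentiate(Xa, sample_rate_hz),
        Vt=differentiate(Xt, sample_rate_hz),
        Vl=differentiate(Xs, sample_rate_hz),
    )


def ergo_powers(
    kin: ErgoKinematics, Fh_x: np.ndarray, Ff_x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Handle and segment powers (Ph_x, Pa, Pt, Pl) on the ergometer."""
    Fh_x = np.asarray(Fh_x, float)
    Ff_x = np.asarray(Ff_x, float)
    _check_equal_lengths(kin.Vh, Fh_x, Ff_x)
    return kin.Vh * Fh_x, kin.Va * Fh_x, kin.Vt * Fh_x, kin.Vl * Ff_x


def boat_handle_power(
    theta: np.ndarray,
    theta_dot: np.ndarray,
    Fh_x: np.ndarray,
    Fh_y: np.ndarray,
    inner_lever_m: float = DEFAULT_INNER_LEVER_M,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Power transferred to one oar at the gate.

    Returns ``(Ph, Ph_x, Ph_y)`` where Ph = Ph_x + Ph_y; callers sum the port
    and starboard sides.
    """
    theta, theta_dot, Fh_x, Fh_y = (np.asarray(a, float) for a in (theta, theta_dot, Fh_x, Fh_y))
    _check_equal_lengths(theta, theta_dot, Fh_x, Fh_y)
    Ph_x = Fh_x * inner_lever_m * np.cos(theta) * theta_dot
    Ph_y = Fh_y * inner_lever_m * np.sin(theta) * theta_dot
    return Ph_x + Ph_y, Ph_x, Ph_y


def boat_segment_velocities(
    V_It: np.ndarray,
    V_Ip: np.ndarray,
    theta_Ip: np.ndarray,
    theta_dot_Ip: np.ndarray,
    l_Ip: float = PELVIS_IMU_TO_SEAT_M,
) -> tuple[np.ndarray, np.ndarray]:
    """Trunk and leg segment velocities from the body IMUs (boat frame).

    Vt = V_It - V_Ip; Vl = V_Ip - l_Ip * theta_dot_Ip * cos(theta_Ip), which
    removes the tilt-induced motion of the pelvis sensor relative to the seat.
    """
    V_It, V_Ip, theta_Ip, theta_dot_Ip = (
        np.asarray(a, float) for a in (V_It, V_Ip, theta_Ip, theta_dot_Ip)
    )
    _check_equal_lengths(V_It, V_Ip, theta_Ip, theta_dot_Ip)
    if l_Ip <= 0:
        raise KineticsError("l_Ip must be > 0")
    Vt = V_It - V_Ip
    Vl = V_Ip - l_Ip * theta_dot_Ip * np.cos(theta_Ip)
    return Vt, Vl


def boat_segment_powers(
    Ff_x: np.ndarray, Fh_x_sum: np.ndarray, Vt: np.ndarray, Vl: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trunk and leg powers on the boat: Pt = Fh_x_sum * Vt, Pl = Ff_x * Vl."""
    Ff_x, Fh_x_sum, Vt, Vl = (np.asarray(a, float) for a in (Ff_x, Fh_x_sum, Vt, Vl))
    _check_equal_lengths(Ff_x, Fh_x_sum, Vt, Vl)
    return Fh_x_sum * Vt, Ff_x * Vl


def boat_arm_power(
    Ph: np.ndarray,
    Ff_x: np.ndarray,
    Fh_x_sum: np.ndarray,
    V_boat: np.ndarray,
    Pt: np.ndarray,
    Pl: np.ndarray,
) -> np.ndarray:
    """Arm power as the power balance residual of the three-segment model.

    Pa = Ph + (Ff_x - Fh_x_sum) * V_boat - Pt - Pl: total rower power (oar
    power plus the power accelerating the rower's mass relative to the boat)
    minus the trunk and leg contributions.
    """
    Ph, Ff_x, Fh_x_sum, V_boat, Pt, Pl = (
        np.asarray(a, float) for a in (Ph, Ff_x, Fh_x_sum, V_boat, Pt, Pl)
    )
    _check_equal_lengths(Ph, Ff_x, Fh_x_sum, V_boat, Pt, Pl)
    return Ph + (Ff_x - Fh_x_sum) * V_boat - Pt - Pl


# ---------------------------------------------------------------------------
# session-level target assembly
# ---------------------------------------------------------------------------

def ergo_target_channels(
    stream: SensorStream, smooth_cutoff_hz: float | None = None
) -> dict[str, np.ndarray]:
    """Session-long target sequences for an ergometer stream.

    ``smooth_cutoff_hz`` applies low-pass pre-smoothing before the velocity
    differentiation — useful on noisy measured sessions, transparent (and
    off by default) on clean ones.
    """
    fs = stream.sample_rate_hz
    kin = ergo_segment_kinematics(
        stream.channel("X_handle"), stream.channel("X_chest"), stream.channel("X_seat"), fs
    )
    if smooth_cutoff_hz is not None:
        kin.Vh = differentiate(kin.Xh, fs, smooth_cutoff_hz)
        kin.Va = differentiate(kin.Xa, fs, smooth_cutoff_hz)
        kin.Vt = differentiate(kin.Xt, fs, smooth_cutoff_hz)
        kin.Vl = differentiate(kin.Xs, fs, smooth_cutoff_hz)
    Fh_x = stream.channel("F_handle")
    Ff_x = stream.channel("F_feet")
    Ph_x, Pa, Pt, Pl = ergo_powers(kin, Fh_x, Ff_x)
    return {"Ff_x": Ff_x, "Fh_x": Fh_x, "Ph_x": Ph_x, "Pa": Pa, "Pt": Pt, "Pl": Pl}


def boat_target_channels(
    streams: dict[str, SensorStream],
    inner_lever_m: float = DEFAULT_INNER_LEVER_M,
    l_Ip: float = PELVIS_IMU_TO_SEAT_M,
) -> dict[str, np.ndarray]:
    """Session-long target sequences for a boat session.

    IMU horizontal velocities are obtained by time-integrating the free
    acceleration along the boat axis and removing drift with the 0.1 Hz
    high-pass — the same treatment applied to the boat velocity during
    synchronization.
    """
    boat = streams["boat"]
    fs = boat.sample_rate_hz
    Ph = np.zeros(boat.n_samples)
    Fh_x_sum = np.zeros(boat.n_samples)
    for side in ("port", "starboard"):
        theta = boat.channel(f"theta_{side}")
        theta_dot = differentiate(theta, fs)
        Fx = boat.channel(f"Fgate_x_{side}")
        Fy = boat.channel(f"Fgate_y_{side}")
        Ph_side, _, _ = boat_handle_power(theta, theta_dot, Fx, Fy, inner_lever_m)
        Ph += Ph_side
        Fh_x_sum += Fx
    Ff_x = boat.channel("F_feet")
    V_boat = boat.channel("V_boat")

    V_It = integrate_and_highpass(streams["imu_thoracic"].channel("acc_x"), fs)
    V_Ip = integrate_and_highpass(streams["imu_pelvis"].channel("acc_x"), fs)
    theta_Ip = streams["imu_pelvis"].channel("tilt")
    theta_dot_Ip = differentiate(theta_Ip, fs)

    Vt, Vl = boat_segment_velocities(V_It, V_Ip, theta_Ip, theta_dot_Ip, l_Ip)
    Pt, Pl = boat_segment_powers(Ff_x, Fh_x_sum, Vt, Vl)
    Pa = boat_arm_power(Ph, Ff_x, Fh_x_sum, V_boat, Pt, Pl)
    return {"Ff_x": Ff_x, "Fh_x": Fh_x_sum, "Ph_x": Ph, "Pa": Pa, "Pt": Pt, "Pl": Pl}


def session_target_channels(
    streams: dict[str, SensorStream], condition: str, **kwargs
) -> dict[str, np.ndarray]:
    if condition == "ergometer":
        return ergo_target_channels(
            streams["ergo"], smooth_cutoff_hz=kwargs.get("smooth_cutoff_hz")
        )
    if condition == "boat":
        return boat_target_channels(
            streams, **{k: v for k, v in kwargs.items() if k != "smooth_cutoff_hz"}
        )
    raise KineticsError(f"unknown condition {condition!r}")


def build_targets(
    streams: dict[str, SensorStream],
    cycles: list[RowingCycle],
    condition: str,
    **kwargs,
) -> list[KineticTargets]:
    """Assemble the six per-cycle target sequences for a segmented session.

    Cycles extending past the stream end are dropped.  The ergometer handle
    force is the measured chain tension; the boat handle force is the summed
    port+starboard propulsive gate-force component.
    """
    channels = session_target_channels(streams, condition, **kwargs)
    n = len(next(iter(channels.values())))
    out = []
    for c in cycles:
        if c.end_idx > n:
            continue
        out.append(
            KineticTargets(
                **{name: ch[c.start_idx : c.end_idx].copy() for name, ch in channels.items()}
            )
        )
    return out
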