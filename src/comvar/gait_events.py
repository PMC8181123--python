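"""Stance detection from heel/toe markers, foot-strike angle, time normalization.

Right-foot stance is detected from the vertical kinematics of the heel and
toe markers.  Both signals are low-pass filtered with a zero-lag 4th-order
Butterworth response (two passes of a 2nd-order filter, 15 Hz cutoff by
default) before differentiation.  At foot strike the heel's vertical
velocity steps from its descent value to ~0; at toe off the toe's vertical
velocity steps from ~0 to its ascent value.  Both steps are located at the
half-height crossing of the filtered velocity, which is unbiased under the
symmetric smearing of a zero-lag filter.

Detected stance windows are resampled to 100 points with a natural cubic
spline and split into absorption (points 1-50) and propulsion (51-100)
phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt, find_peaks

from .errors import ConfigurationError, DetectionError, InvalidGeometryError

__all__ = [
    "MarkerTrack",
    "StanceCycle",
    "PhaseSplit",
    "detect_stance_events",
    "foot_strike_angle",
    "time_normalize",
    "phase_split",
]

N_NORMALIZED = 100
ABSORPTION = slice(0, 50)  # points 1-50, 1-based
PROPULSION = slice(50, 100)  # points 51-100


@dataclass(frozen=True)
class MarkerTrack:
    """Heel and toe marker trajectories at a uniform sampling rate.

    ``t`` in seconds (strictly increasing, uniform); ``heel``/``toe`` are
    (n, 3) lab-frame positions in meters.  ``vertical_axis`` names the
    gravity axis (default z = column 2).
    """

    t: np.ndarray
    heel: np.ndarray
    toe: np.ndarray
    vertical_axis: int = 2

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        heel = np.asarray(self.heel, dtype=float)
        toe = np.asarray(self.toe, dtype=float)
        if t.ndim != 1 or len(t) < 2:
            raise ConfigurationError("MarkerTrack needs at least 2 samples")
        dt = np.diff(t)
        if not np.all(dt > 0):
            raise ConfigurationError("sample times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ConfigurationError("sampling must be uniform")
        for name, arr in (("heel", heel), ("toe", toe)):
            if arr.shape != (len(t), 3):
                raise ConfigurationError(f"{name} must have shape (n_samples, 3)")
        if self.vertical_axis not in (0, 1, 2):
            raise ConfigurationError("vertical_axis must be 0, 1 or 2")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "heel", heel)
        object.__setattr__(self, "toe", toe)

    @property
    def rate(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass(frozen=True)
class StanceCycle:
    """One detected stance: frame indices of foot strike and toe off."""

    foot_strike_idx: int
    toe_off_idx: int

    def __post_init__(self) -> None:
        if self.toe_off_idx <= self.foot_strike_idx:
            raise ConfigurationError("toe off must come after foot strike")

    def normalize(self, channel: np.ndarray, n_points: int = N_NORMALIZED) -> np.ndarray:
        return time_normalize(channel, self.foot_strike_idx, self.toe_off_idx, n_points)


def _lowpass(x: np.ndarray, rate: float, cutoff_hz: float) -> np.ndarray:
    """Zero-lag 4th-order Butterworth response (2nd order, two passes)."""
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        return x
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, x, axis=0)


def _half_height_crossing(v: np.ndarray, i_extreme: int, level: float, direction: int) -> int:
    """Frame index where ``v`` crosses ``level``, scanning from ``i_extreme``.

    ``direction=+1`` scans forward (heel: descent velocity rising back to 0),
    ``direction=-1`` scans backward (toe: start of the ascent step).  The
    crossing is linearly interpolated and rounded to the nearest frame.
    """
    i = i_extreme
    if direction > 0:
        while i + 1 < len(v) and not (v[i] < level <= v[i + 1]):
            i += 1
        if i + 1 >= len(v):
            return -1
        frac = (level - v[i]) / (v[i + 1] - v[i])
        return int(round(i + frac))
    while i - 1 >= 0 and not (v[i - 1] < level <= v[i]):
        i -= 1
    if i - 1 < 0:
        return -1
    frac = (level - v[i - 1]) / (v[i] - v[i - 1])
    return int(round(i - 1 + frac))


def detect_stance_events(
    track: MarkerTrack,
    cutoff_hz: float = 15.0,
    min_cycles: int | None = None,
) -> list[StanceCycle]:
    """Detect (foot strike, toe off) pairs for every complete stance.

    Strides are segmented at the swing apices of the heel marker; foot
    strike is located at the end of the heel's descent (half-height crossing
    of its vertical velocity), toe off at the start of the toe's swing
    ascent.  Incomplete cycles at either end of the record are dropped.

    Raises :class:`DetectionError` when no plausible alternating pattern
    exists (e.g. a standing trial); warns when fewer than ``min_cycles``
    complete cycles are found.
    """
    z_axis = track.vertical_axis
    rate = track.rate
    heel_z = _lowpass(track.heel[:, z_axis], rate, cutoff_hz)
    toe_z = _lowpass(track.toe[:, z_axis], rate, cutoff_hz)
    span = float(heel_z.max() - heel_z.min())
    if span < 1e-6:
        raise DetectionError("heel marker shows no vertical excursion (standing trial?)")
    peaks, _ = find_peaks(heel_z, prominence=0.25 * span)
    if len(peaks) < 2:
        raise DetectionError("fewer than two heel swing apices found")
    v_heel = np.gradient(heel_z) * rate
    v_toe = np.gradient(toe_z) * rate

    # magnitude guards: a real descent/ascent must reach a sizable fraction
    # of the global velocity scale, so truncated cycles are dropped rather
    # than matched to filter ripple
    v_heel_scale = float(-v_heel.min())
    v_toe_scale = float(v_toe.max())
    strikes: list[int] = []
    bounds = list(peaks) + [len(heel_z) - 1]
    for p, nxt in zip(bounds[:-1], bounds[1:]):
        seg = v_heel[p:nxt]
        if len(seg) < 3:
            continue
        i_min = p + int(np.argmin(seg))
        v_min = v_heel[i_min]
        if v_min >= -0.3 * v_heel_scale:
            continue
        idx = _half_height_crossing(v_heel[:nxt], i_min, v_min / 2.0, +1)
        if idx > 0:
            strikes.append(idx)
    if not strikes:
        raise DetectionError("no foot strikes found")

    cycles: list[StanceCycle] = []
    strike_bounds = strikes[1:] + [len(toe_z) - 1]
    for fs, nxt in zip(strikes, strike_bounds):
        seg = v_toe[fs:nxt]
        if len(seg) < 3:
            continue
        i_max = fs + int(np.argmax(seg))
        v_max = v_toe[i_max]
        if v_max <= 0.3 * v_toe_scale:
            continue
        to = _half_height_crossing(v_toe, i_max, v_max / 2.0, -1)
        if to > fs:
            cycles.append(StanceCycle(foot_strike_idx=fs, toe_off_idx=to))
    if not cycles:
        raise DetectionError("no alternating foot-strike / toe-off pattern found")
    if min_cycles is not None and len(cycles) < min_cycles:
        warnings.warn(
            f"only {len(cycles)} complete stance cycles detected "
            f"(requested {min_cycles})",
            stacklevel=2,
        )
    return cycles


def foot_strike_angle(track: MarkerTrack, fs_idx: int) -> float:
    """Signed foot-strike angle in degrees at the given frame.

    Angle between the heel->toe (longitudinal foot) axis and the ground
    plane; positive when the toe is above the heel, i.e. a heel-first
    (rearfoot) strike.
    """
    if not 0 <= fs_idx < len(track.t):
        raise ConfigurationError(f"frame index {fs_idx} out of range")
    vec = track.toe[fs_idx] - track.heel[fs_idx]
    z = vec[track.vertical_axis]
    horiz = np.delete(vec, track.vertical_axis)
    h = float(np.linalg.norm(horiz))
    if h < 1e-12 and abs(z) < 1e-12:
        raise InvalidGeometryError("zero-length foot axis at strike frame")
    return float(np.degrees(np.arctan2(z, h)))


def time_normalize(
    channel: np.ndarray, fs_idx: int, to_idx: int, n_points: int = N_NORMALIZED
) -> np.ndarray:
    """Resample ``channel[fs_idx:to_idx]`` (inclusive) onto ``n_points``.

    A natural cubic spline is fit to the stance samples and evaluated at
    ``n_points`` equispaced positions spanning [fs_idx, to_idx]; the
    endpoints reproduce the original samples exactly.  ``channel`` may be
    1-D or (n_frames, k).
    """
    channel = np.asarray(channel, dtype=float)
    if to_idx - fs_idx < 3:
        raise ConfigurationError(
            f"stance from frame {fs_idx} to {to_idx} is too short to resample"
        )
    if not (0 <= fs_idx and to_idx < channel.shape[0]):
        raise ConfigurationError("stance indices out of range")
    frames = np.arange(fs_idx, to_idx + 1)
    spline = CubicSpline(frames, channel[fs_idx : to_idx + 1], bc_type="natural", axis=0)
    return spline(np.linspace(fs_idx, to_idx, n_points))


class PhaseSplit(NamedTuple):
    absorption: np.ndarray
    propulsion: np.ndarray
    means: tuple


def phase_split(series100: np.ndarray) -> PhaseSplit:
    """Split a 100-point normalized series into absorption / propulsion halves.

    Points 1-50 (1-based) form the absorption phase, 51-100 the propulsion
    phase; the per-phase arithmetic means are returned alongside the halves.
    """
    series100 = np.asarray(series100, dtype=float)
    if series100.shape[0] != N_NORMALIZED:
        raise ConfigurationError(
            f"normalized series must have {N_NORMALIZED} points, got {series100.shape[0]}"
        )
    absorption = series100[ABSORPTION]
    propulsion = series100[PROPULSION]
    return PhaseSplit(
        absorption=absorption,
        propulsion=propulsion,
        means=(absorption.mean(axis=0), propulsion.mean(axis=0)),
    )
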