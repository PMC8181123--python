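"""Synthetic running cohorts with controllable T/N/C structure.

The generator emulates the statistical structure the analysis assumes: a
cohort of runners, each measured in two states (PRE/POST), with 19 stance
cycles per state, joint-angle waveforms over 100 normalized time points for
all 50 generalized coordinates, and lab-frame pelvis / right-foot anchor
trajectories.  Marker tracks for event detection are generated separately
with known ground-truth events.

Waveforms are sums of three stance harmonics (1, cos(pi*tau), sin(pi*tau));
stride-to-stride noise perturbs the harmonic coefficients, not the samples,
so every cycle is smooth in time.  Between-subject structure is a constant
per-DOF offset.  The POST state can apply one manipulation:

- ``tolerance``: the mean configuration is shifted along the negative
  gradient of the PV_lab norm, lowering the mean PV so that the same
  dispersion produces a larger CV (Tolerance component expected positive).
- ``noise``: all cycle-noise SDs are scaled by (1 + magnitude) (Noise
  expected positive).
- ``covariation``: cycle deviations are projected partially out of the
  PV-sensitive direction (compensatory coupling), so measured variability
  drops below what the marginals imply (Covariation expected negative).

Defaults reflect the study conditions the analysis targets: 13 subjects,
19 cycles, 100 time points, 50 DOF, stride noise of ~0.5 deg per angle and
3 mm on the anchors, which places PV_lab norms near 0.05 m and PV_foot
norms near 0.85 m with CVs of a few percent / below one percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .body import BodyModel, build_body_model, default_profile
from .errors import ConfigurationError
from .gait_events import MarkerTrack
from .kinematics import whole_body_com

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_marker_tracks",
    "expected_component",
    "pv_norm_gradient",
]

_MANIPULATIONS = ("none", "tolerance", "noise", "covariation")

#: Default manipulation magnitudes: tolerance in radians of mean shift along
#: the PV-gradient direction; noise as fractional SD increase; covariation
#: as the mixing coefficient of the compensatory projection.
DEFAULT_MAGNITUDES = {"none": 0.0, "tolerance": 0.07, "noise": 1.0, "covariation": 0.8}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort dimensions, waveform/noise parameters, and the manipulation."""

    n_subjects: int = 13
    n_cycles: int = 19
    n_timepoints: int = 100
    cycle_noise_sd: float = 0.009  # rad per DOF (time-averaged)
    subject_sd: float = 0.02  # rad, between-subject offset
    anchor_noise_sd: float = 0.003  # m, pelvis/foot per-cycle noise
    manipulation: str = "none"
    magnitude: float | None = None  # None -> DEFAULT_MAGNITUDES[manipulation]
    # anchor trajectory parameters (meters unless noted)
    pelvis_height: float = 0.94
    pelvis_drop: float = 0.05
    foot_strike_x: float = 0.20
    foot_travel: float = 0.62
    foot_height: float = 0.07
    foot_y: float = -0.09
    # marker-track parameters
    cadence: float = 90.0  # strides/min
    stance_fraction: float = 0.35
    strike_angle_deg: float = 3.5
    marker_rate: float = 200.0  # Hz
    marker_noise_sd: float = 0.001  # m
    seed: int = 0

    def __post_init__(self) -> None:
        if self.manipulation not in _MANIPULATIONS:
            raise ConfigurationError(
                f"manipulation must be one of {_MANIPULATIONS}, got {self.manipulation!r}"
            )
        if min(self.n_subjects, self.n_cycles) < 2 or self.n_timepoints < 2:
            raise ConfigurationError("cohort dimensions must be at least 2")
        for name in ("cycle_noise_sd", "subject_sd", "anchor_noise_sd", "marker_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.magnitude is not None and self.magnitude < 0:
            raise ConfigurationError("magnitude must be >= 0")
        if not 0 < self.stance_fraction < 1:
            raise ConfigurationError("stance_fraction must be in (0, 1)")

    @property
    def effective_magnitude(self) -> float:
        if self.magnitude is None:
            return DEFAULT_MAGNITUDES[self.manipulation]
        return self.magnitude


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated cohort: angles, anchors, and the manipulation ground truth.

    ``angles``: (subjects, 2 states, cycles, time, 50) radians; state 0 is
    PRE, 1 POST.  ``pelvis``/``rfoot``: (subjects, 2, cycles, time, 3)
    lab-frame meters.  ``truth`` records the applied manipulation and the
    expected dominant component with its sign.
    """

    angles: np.ndarray
    pelvis: np.ndarray
    rfoot: np.ndarray
    truth: dict
    config: SyntheticConfig
    model: BodyModel = field(repr=False, default=None)  # type: ignore[assignment]

    def ev_lab(self, subject: int, state: int) -> np.ndarray:
        """EV array (cycles, time, 50) for the PV_lab analysis."""
        return self.angles[subject, state]

    def ev_foot(self, subject: int, state: int) -> np.ndarray:
        """EV array (cycles, time, 56): angles + pelvis + right-foot columns."""
        return np.concatenate(
            [
                self.angles[subject, state],
                self.pelvis[subject, state],
                self.rfoot[subject, state],
            ],
            axis=-1,
        )


def expected_component(config: SyntheticConfig) -> tuple[str, int]:
    """The component a manipulation must dominate, with its expected sign."""
    return {
        "none": ("none", 0),
        "tolerance": ("T", +1),
        "noise": ("N", +1),
        "covariation": ("C", -1),
    }[config.manipulation]


def pv_norm_gradient(q: np.ndarray, model: BodyModel, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of the PV_lab norm w.r.t. the 50 angles."""
    q = np.asarray(q, dtype=float)
    n = model.n_dof
    probe = np.repeat(q[None, :], 2 * n, axis=0)
    step = np.repeat(np.eye(n) * eps, 2, axis=0).reshape(n, 2, n)
    probe = probe.reshape(n, 2, n)
    probe[:, 0, :] += step[:, 0, :]
    probe[:, 1, :] -= step[:, 0, :]
    norms = np.linalg.norm(whole_body_com(probe.reshape(2 * n, n), model), axis=-1)
    norms = norms.reshape(n, 2)
    return (norms[:, 0] - norms[:, 1]) / (2 * eps)


# --- baseline running waveform ------------------------------------------------
# Harmonic coefficients (3, 50): rows are the basis functions
# [1, cos(pi*tau), sin(pi*tau)] over the normalized stance tau in [0, 1].
# Sagittal flexion/extension is the Y (third) Euler angle of each joint.


def _dof_index(model: BodyModel, segment: str, component: int) -> int:
    i = model.segment_index[segment]
    return int(model.dof_start[i]) + component

_Y = 2  # sagittal-plane (flexion) Euler component within a 3-DOF joint


def baseline_coefficients(model: BodyModel) -> np.ndarray:
    """The fixed baseline posture/waveform coefficients, shape (3, 50).

    A mid-stance running posture with a forward-leaning trunk, antiphase arm
    swing, a stance right leg sweeping from flexion to extension and a
    flexed swing left leg.  Amplitudes are radians.
    """
    A = np.zeros((3, model.n_dof))

    def put(segment: str, component: int, a0: float, a_cos: float = 0.0, a_sin: float = 0.0):
        d = _dof_index(model, segment, component)
        A[0, d], A[1, d], A[2, d] = a0, a_cos, a_sin

    put("pelvis", _Y, 0.10)  # root: forward lean of the pelvis in the lab
    # trunk flexed forward and leaning over the stance (right) leg; these set
    # the pelvis-anchored CoM offsets to the observed decimeter regime
    put("abdomen", _Y, 0.17)
    put("abdomen", 1, 0.13)
    put("thorax", _Y, 0.05)
    put("head", _Y, -0.08)
    # arms: antiphase swing, elbows flexed
    put("upper_arm_left", _Y, 0.10, 0.35)
    put("upper_arm_right", _Y, 0.10, -0.35)
    put("forearm_left", _Y, 1.30)
    put("forearm_right", _Y, 1.30)
    # right leg in stance: hip sweeps flexion -> extension, knee yields mid-stance
    put("thigh_right", _Y, 0.05, 0.45)
    put("shank_right", _Y, -0.15, 0.0, -0.25)
    put("foot_right", _Y, -0.10, 0.0, 0.20)
    # left leg in swing: antiphase hip, strongly flexed knee
    put("thigh_left", _Y, 0.05, -0.45)
    put("shank_left", _Y, -0.50, 0.0, -0.50)
    put("foot_left", _Y, -0.10)
    return A


def _basis(n_timepoints: int) -> np.ndarray:
    tau = np.linspace(0.0, 1.0, n_timepoints)
    return np.stack([np.ones_like(tau), np.cos(np.pi * tau), np.sin(np.pi * tau)])


def _anchor_base(config: SyntheticConfig, n_timepoints: int) -> tuple[np.ndarray, np.ndarray]:
    """Baseline pelvis and right-foot lab trajectories, each (time, 3)."""
    tau = np.linspace(0.0, 1.0, n_timepoints)
    pelvis = np.stack(
        [
            0.01 * np.sin(2 * np.pi * tau),
            0.005 * np.sin(2 * np.pi * tau),
            config.pelvis_height - config.pelvis_drop * tau + 0.01 * np.sin(2 * np.pi * tau),
        ],
        axis=-1,
    )
    rfoot = np.stack(
        [
            config.foot_strike_x - config.foot_travel * tau,
            np.full_like(tau, config.foot_y),
            np.full_like(tau, config.foot_height),
        ],
        axis=-1,
    )
    return pelvis, rfoot


def generate_cohort(config: SyntheticConfig, model: BodyModel | None = None) -> SyntheticCohort:
    """Generate a cohort; reproducible given ``config.seed``.

    PRE is baseline + subject offsets + i.i.d. harmonic-coefficient noise;
    POST applies the configured manipulation (see module docstring).
    """
    if model is None:
        model = build_body_model(default_profile())
    rng = np.random.default_rng(config.seed)
    S, C, T = config.n_subjects, config.n_cycles, config.n_timepoints
    n_dof = model.n_dof
    mag = config.effective_magnitude

    A = baseline_coefficients(model)  # (3, n_dof)
    B = _basis(T)  # (3, T)
    coeff_sd = config.cycle_noise_sd / math.sqrt(2.0)

    subject_offset = rng.normal(0.0, config.subject_sd, size=(S, n_dof))
    eps = rng.normal(0.0, coeff_sd, size=(S, 2, C, 3, n_dof))
    anchor_sd = config.anchor_noise_sd / math.sqrt(2.0)
    eps_anchor = rng.normal(0.0, anchor_sd, size=(S, 2, C, 3, 6))

    if config.manipulation == "noise":
        eps[:, 1] *= 1.0 + mag
        eps_anchor[:, 1] *= 1.0 + mag

    shift = np.zeros((S, n_dof))
    if config.manipulation in ("tolerance", "covariation"):
        # unit PV_lab-norm gradient at each subject's mean mid-stance posture
        mid = A[0] + A[2] + subject_offset  # basis values at tau=0.5: (1, 0, 1)
        grads = np.empty((S, n_dof))
        for s in range(S):
            g = pv_norm_gradient(mid[s], model)
            grads[s] = g / np.linalg.norm(g)
        if config.manipulation == "tolerance":
            shift = -mag * grads
        else:  # covariation: remove PV-affecting content from POST deviations
            proj = np.einsum("schd,sd->sch", eps[:, 1], grads)
            eps[:, 1] -= mag * proj[..., None] * grads[:, None, None, :]

    coeffs = A[None, None, None] + eps  # (S, 2, C, 3, n_dof)
    coeffs[:, :, :, 0, :] += subject_offset[:, None, None, :]
    coeffs[:, 1, :, 0, :] += shift[:, None, :]
    angles = np.einsum("sxchd,ht->sxctd", coeffs, B)

    pelvis_base, rfoot_base = _anchor_base(config, T)
    anchor_dev = np.einsum("sxchd,ht->sxctd", eps_anchor, B)  # (..., time, 6)
    pelvis = pelvis_base[None, None, None] + anchor_dev[..., :3]
    rfoot = rfoot_base[None, None, None] + anchor_dev[..., 3:]

    comp, sign = expected_component(config)
    truth = {
        "manipulation": config.manipulation,
        "magnitude": mag,
        "expected_component": comp,
        "expected_sign": sign,
    }
    return SyntheticCohort(
        angles=angles, pelvis=pelvis, rfoot=rfoot, truth=truth, config=config, model=model
    )


# --- marker tracks ------------------------------------------------------------

_HEEL_OFF = 0.30  # stride fraction at which the heel leaves the ground
_FOREFOOT_DOWN = 0.10  # stride fraction by which the toe is flat
_SWING_HEIGHT = 0.12  # m, marker apex during swing
_MARKER_BASE = 0.025  # m, marker height above the sole
_FOOT_AXIS = 0.20  # m, horizontal heel->toe marker separation


def _heel_profile(phi: np.ndarray) -> np.ndarray:
    z = np.zeros_like(phi)
    swing = phi > _HEEL_OFF
    u = (phi[swing] - _HEEL_OFF) / (1.0 - _HEEL_OFF)
    z[swing] = _SWING_HEIGHT * np.sin(np.pi * u)
    return z


def _toe_profile(phi: np.ndarray, stance_fraction: float, z_strike: float) -> np.ndarray:
    z = np.zeros_like(phi)
    early = phi < _FOREFOOT_DOWN
    z[early] = z_strike * 0.5 * (1.0 + np.cos(np.pi * phi[early] / _FOREFOOT_DOWN))
    swing = phi > stance_fraction
    u = (phi[swing] - stance_fraction) / (1.0 - stance_fraction)
    z[swing] = _SWING_HEIGHT * np.sin(np.pi * u) + z_strike * u
    return z


def _foot_x(phi: np.ndarray, stance_fraction: float, travel: float, x0: float) -> np.ndarray:
    x = np.empty_like(phi)
    stance = phi <= stance_fraction
    x[stance] = x0 - travel * phi[stance] / stance_fraction
    u = (phi[~stance] - stance_fraction) / (1.0 - stance_fraction)
    x[~stance] = x0 - travel + travel * 0.5 * (1.0 - np.cos(np.pi * u))
    return x


def generate_marker_tracks(
    config: SyntheticConfig,
    n_strides: int = 22,
    seed: int | None = None,
) -> tuple[MarkerTrack, list[tuple[int, int]]]:
    """Heel/toe marker track with ground-truth (strike, toe-off) frames.

    The heel lands with a finite descent velocity and stays on the ground
    until heel-off; the toe leaves the ground at the configured stance
    fraction with a finite ascent velocity, so both events are sharp.  The
    configured strike angle sets the toe height above the heel at contact.
    Additive Gaussian noise of ``config.marker_noise_sd`` is applied to all
    coordinates.
    """
    if n_strides < 2:
        raise ConfigurationError("need at least two strides")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    period = 60.0 / config.cadence
    dt = 1.0 / config.marker_rate
    t0 = 0.5 * period  # recording starts mid-swing: first stride is incomplete
    duration = t0 + n_strides * period + 0.5 * period
    t = np.arange(0.0, duration, dt)
    phi = ((t - t0) / period) % 1.0

    z_strike = _FOOT_AXIS * math.tan(math.radians(config.strike_angle_deg))
    heel = np.empty((len(t), 3))
    toe = np.empty((len(t), 3))
    heel[:, 0] = _foot_x(phi, config.stance_fraction, config.foot_travel, config.foot_strike_x)
    toe[:, 0] = heel[:, 0] + _FOOT_AXIS
    heel[:, 1] = config.foot_y
    toe[:, 1] = config.foot_y
    heel[:, 2] = _MARKER_BASE + _heel_profile(phi)
    toe[:, 2] = _MARKER_BASE + _toe_profile(phi, config.stance_fraction, z_strike)
    if config.marker_noise_sd > 0:
        heel = heel + rng.normal(0.0, config.marker_noise_sd, heel.shape)
        toe = toe + rng.normal(0.0, config.marker_noise_sd, toe.shape)

    events = []
    for k in range(n_strides + 1):
        t_strike = t0 + k * period
        t_toeoff = t_strike + config.stance_fraction * period
        i_strike = int(round(t_strike / dt))
        i_toeoff = int(round(t_toeoff / dt))
        if i_toeoff < len(t):
            events.append((i_strike, i_toeoff))
    return MarkerTrack(t=t, heel=heel, toe=toe), events


def with_manipulation(config: SyntheticConfig, kind: str, magnitude: float | None = None):
    """Convenience: a copy of ``config`` with a different POST manipulation."""
    return replace(config, manipulation=kind, magnitude=magnitude)
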