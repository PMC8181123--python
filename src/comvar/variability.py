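"""Coefficient-of-variation measures of stride-to-stride variability.

The CV (100 * sample SD / mean) is computed across stance cycles at each
normalized time point, for the 3D norm of the performance variable and for
its per-axis projections.  Per-axis CVs use the absolute component values by
default (reported per-axis lengths are positive); a signed-component mode is
available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UndefinedCVError
from .gait_events import phase_split
from .kinematics import CHANNELS, pv_channels

__all__ = ["PVSeries", "CVSeries", "cv_percent", "pv_cv"]


def cv_percent(x: np.ndarray, axis: int = 0, ddof: int = 1) -> np.ndarray:
    """Coefficient of variation in percent: ``100 * SD / mean``.

    Uses the sample SD (``ddof=1``) by default.  Requires at least two
    observations and a strictly positive mean along ``axis``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[axis] < 2:
        raise UndefinedCVError("CV needs at least two observations")
    mean = x.mean(axis=axis)
    if np.any(mean <= 0):
        raise UndefinedCVError("CV undefined for non-positive mean")
    return 100.0 * x.std(axis=axis, ddof=ddof) / mean


@dataclass(frozen=True)
class PVSeries:
    """Per-cycle performance-variable magnitudes over the normalized stance.

    ``values`` has shape (n_cycles, 100, 4): channels are the 3D norm and
    the x/y/z projections (absolute by default).
    """

    values: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3 or values.shape[2] != len(self.channels):
            raise ConfigurationError(
                f"PVSeries values must be (cycles, time, {len(self.channels)})"
            )
        if values.shape[0] < 2:
            raise ConfigurationError("PVSeries needs at least two cycles")
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("PVSeries contains non-finite values")
        object.__setattr__(self, "values", values)

    @classmethod
    def from_vectors(cls, vectors: np.ndarray, signed: bool = False) -> "PVSeries":
        """Build from PV 3-vectors of shape (cycles, time, 3).

        ``signed=True`` keeps signed axis components instead of magnitudes
        (the norm channel is always non-negative).
        """
        vectors = np.asarray(vectors, dtype=float)
        if vectors.ndim != 3 or vectors.shape[2] != 3:
            raise ConfigurationError("vectors must have shape (cycles, time, 3)")
        if signed:
            norm = np.linalg.norm(vectors, axis=-1, keepdims=True)
            values = np.concatenate([norm, vectors], axis=-1)
        else:
            values = pv_channels(vectors)
        return cls(values=values)


@dataclass(frozen=True)
class CVSeries:
    """Per-timepoint CV (%) and its absorption/propulsion phase means."""

    cv: np.ndarray  # (100, n_channels)
    phase_means: np.ndarray  # (2, n_channels): [absorption, propulsion]
    channels: tuple[str, ...] = CHANNELS


def pv_cv(series: PVSeries, ddof: int = 1) -> CVSeries:
    """CV across cycles, per normalized time point and channel."""
    cv = cv_percent(series.values, axis=0, ddof=ddof)
    _, _, (m_abs, m_prop) = phase_split(cv)
    return CVSeries(cv=cv, phase_means=np.stack([m_abs, m_prop]), channels=series.channels)
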