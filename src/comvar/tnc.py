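"""Tolerance / Noise / Covariation decomposition of PRE -> POST variability change.

The change in performance-variable variability between two states is
decomposed with five datasets:

- D1: measured execution variables (EVs) in the first state.
- D2: D1 with every EV column independently permuted across cycles, which
  destroys all covariation while preserving each marginal exactly.
- D3: D2 relocated to the second state's position in EV space (column means
  of D1 subtracted, column means of D5 added).
- D4: D5 column-permuted in the same way as D2.
- D5: measured EVs in the second state.

With V(.) the CV of the performance variable computed through the forward
model (mean CV over permutation replicates for the ensembles):

- Tolerance  T = V(D3) - V(D2)   (same dispersion, no covariation; only the
  position in EV space differs, i.e. the local sensitivity of the map)
- Noise      N = V(D4) - V(D3)   (same position, no covariation; only the
  marginal dispersion differs)
- Covariation C = [V(D2) - V(D1)] + [V(D5) - V(D4)]  (effect of destroying
  each state's covariation)

These telescope exactly: T + N + C = V(D5) - V(D1).  A positive component
means variability increased from the first to the second state due to that
factor.

Permutation replicates for D2 and D4 share index sets by default ("paired"),
which makes the null case D1 = D5 evaluate to exactly zero components;
independent index sets are available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .errors import ConfigurationError, UndefinedCVError
from .gait_events import phase_split
from .kinematics import CHANNELS, pv_channels

__all__ = [
    "TNCComponents",
    "permute_evs",
    "exhaustive_permutations",
    "shift_dataset",
    "dataset_variability",
    "tnc_components",
    "tnc_timecourse",
]

_EXHAUSTIVE_LIMIT = 200_000


@dataclass(frozen=True)
class TNCComponents:
    """T, N, C and the total CV change (percentage points of CV).

    Arrays share a trailing channel axis; for a time course the leading axis
    is the normalized time point.  ``T + N + C == total`` up to floating
    round-off (the decomposition telescopes algebraically).
    """

    T: np.ndarray
    N: np.ndarray
    C: np.ndarray
    total: np.ndarray
    channels: tuple[str, ...]

    def phase_means(self) -> dict[str, np.ndarray]:
        """Absorption/propulsion means per component, shape (2, n_channels).

        Only meaningful for 100-point time courses.
        """
        out = {}
        for name in ("T", "N", "C", "total"):
            _, _, (m_abs, m_prop) = phase_split(getattr(self, name))
            out[name] = np.stack([m_abs, m_prop])
        return out


def _as_matrix(ev: np.ndarray) -> np.ndarray:
    ev = np.asarray(ev, dtype=float)
    if ev.ndim != 2:
        raise ConfigurationError(f"EV matrix must be 2-D (cycles, EVs), got shape {ev.shape}")
    if ev.shape[0] < 2:
        raise ConfigurationError("EV matrix needs at least two cycles")
    if not np.all(np.isfinite(ev)):
        raise ConfigurationError("EV matrix contains non-finite values")
    return ev


def _permutation_indices(rng: np.random.Generator, n_perm: int, n: int, k: int) -> np.ndarray:
    """(n_perm, n, k) row orders, independent per replicate and per column."""
    return np.argsort(rng.random((n_perm, n, k)), axis=1)


def _apply_indices(ev: np.ndarray, idx: np.ndarray) -> np.ndarray:
    expanded = np.broadcast_to(ev, idx.shape)
    return np.take_along_axis(expanded, idx, axis=1)


def permute_evs(
    ev: np.ndarray,
    n_perm: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ensemble of column-wise row permutations of an EV matrix.

    Every EV column is permuted independently across cycles in each of the
    ``n_perm`` replicates, eliminating inter-EV covariation while preserving
    each column's marginal distribution exactly.  Reproducible given a seed.
    Returns an array of shape (n_perm, n_cycles, n_ev).
    """
    ev = _as_matrix(ev)
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = _permutation_indices(rng, n_perm, ev.shape[0], ev.shape[1])
    return _apply_indices(ev, idx)


def exhaustive_permutations(ev: np.ndarray) -> np.ndarray:
    """All (n!)^k column-wise permutation combinations of a tiny EV matrix."""
    ev = _as_matrix(ev)
    n, k = ev.shape
    total = math.factorial(n) ** k
    if total > _EXHAUSTIVE_LIMIT:
        raise ConfigurationError(
            f"exhaustive mode would enumerate {total} arrangements (limit {_EXHAUSTIVE_LIMIT})"
        )
    perms = list(permutations(range(n)))
    out = np.empty((total, n, k), dtype=float)
    for m, combo in enumerate(product(perms, repeat=k)):
        for col, perm in enumerate(combo):
            out[m, :, col] = ev[list(perm), col]
    return out


def shift_dataset(
    ev_ensemble: np.ndarray, from_means: np.ndarray, to_means: np.ndarray
) -> np.ndarray:
    """Relocate every replicate so its column means equal ``to_means``.

    Implements the D2 -> D3 move: subtract the first state's column means,
    add the second state's.
    """
    ev_ensemble = np.asarray(ev_ensemble, dtype=float)
    from_means = np.asarray(from_means, dtype=float)
    to_means = np.asarray(to_means, dtype=float)
    k = ev_ensemble.shape[-1]
    if from_means.shape != (k,) or to_means.shape != (k,):
        raise ConfigurationError(
            f"mean vectors must have shape ({k},) to match the EV columns"
        )
    return ev_ensemble + (to_means - from_means)


def _channel_values(forward, data: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    """Evaluate the forward map on stacked rows; return (N, n_channels) values."""
    y = np.asarray(forward(data), dtype=float)
    if y.ndim == 1:
        return y[:, None], ("value",)
    if y.ndim == 2 and y.shape[1] == 3:
        return pv_channels(y), CHANNELS
    raise ConfigurationError(
        f"forward map must return (N,) or (N, 3), got shape {y.shape}"
    )


def _cv(values: np.ndarray, axis: int = 0) -> np.ndarray:
    mean = values.mean(axis=axis)
    if np.any(mean <= 0):
        raise UndefinedCVError("PV magnitudes must have positive mean for a CV")
    return 100.0 * values.std(axis=axis, ddof=1) / mean


def dataset_variability(data: np.ndarray, forward, channel: str = "3d") -> float:
    """CV (%) of the PV for one dataset or a permutation ensemble.

    ``data`` is (cycles, EVs) for a single dataset or (replicates, cycles,
    EVs) for an ensemble, in which case the mean CV over replicates is
    returned.  ``channel`` is one of ``"3d"``, ``"x"``, ``"y"``, ``"z"``
    (or ``"value"`` for scalar forward maps).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        values, channels = _channel_values(forward, data)
        cvs = _cv(values)
    elif data.ndim == 3:
        m, n, k = data.shape
        values, channels = _channel_values(forward, data.reshape(m * n, k))
        cvs = _cv(values.reshape(m, n, -1), axis=1).mean(axis=0)
    else:
        raise ConfigurationError("data must be 2-D (dataset) or 3-D (ensemble)")
    if channel not in channels:
        raise ConfigurationError(f"channel {channel!r} not in {channels}")
    return float(cvs[channels.index(channel)])


def _decompose(
    D1: np.ndarray,
    D5: np.ndarray,
    forward,
    n_perm: int,
    rng: np.random.Generator,
    paired: bool,
    exhaustive: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, tuple[str, ...]]:
    n, k = D1.shape
    if exhaustive:
        D2 = exhaustive_permutations(D1)
        D4 = exhaustive_permutations(D5)
    else:
        idx2 = _permutation_indices(rng, n_perm, n, k)
        idx4 = idx2 if paired else _permutation_indices(rng, n_perm, n, k)
        D2 = _apply_indices(D1, idx2)
        D4 = _apply_indices(D5, idx4)
    delta = D5.mean(axis=0) - D1.mean(axis=0)
    D3 = D2 + delta
    m = D2.shape[0]
    stacked = np.concatenate(
        [D1, D5, D2.reshape(m * n, k), D3.reshape(m * n, k), D4.reshape(m * n, k)]
    )
    values, channels = _channel_values(forward, stacked)
    nch = values.shape[1]
    v1 = _cv(values[:n])
    v5 = _cv(values[n : 2 * n])
    ens = values[2 * n :].reshape(3, m, n, nch)
    v2, v3, v4 = _cv(ens, axis=2).mean(axis=1)
    T = v3 - v2
    N = v4 - v3
    C = (v2 - v1) + (v5 - v4)
    total = v5 - v1
    return T, N, C, total, channels


def tnc_components(
    D1: np.ndarray,
    D5: np.ndarray,
    forward,
    n_perm: int = 1000,
    seed: int | None = None,
    paired: bool = True,
    exhaustive: bool = False,
) -> TNCComponents:
    """Decompose the CV change between two EV matrices at one time point.

    ``forward`` maps EV rows to PV vectors (or scalars); see the module
    docstring for the component definitions.  ``paired`` reuses the D2
    permutation index sets for D4 (exact-zero null); ``exhaustive``
    enumerates every arrangement instead of Monte-Carlo sampling (tiny
    matrices only).
    """
    D1 = _as_matrix(D1)
    D5 = _as_matrix(D5)
    if D1.shape != D5.shape:
        raise ConfigurationError(
            f"D1 and D5 must share the EV layout, got {D1.shape} vs {D5.shape}"
        )
    rng = np.random.default_rng(seed)
    T, N, C, total, channels = _decompose(D1, D5, forward, n_perm, rng, paired, exhaustive)
    return TNCComponents(T=T, N=N, C=C, total=total, channels=channels)


def tnc_timecourse(
    pre: np.ndarray,
    post: np.ndarray,
    forward,
    n_perm: int = 1000,
    seed: int | None = None,
    paired: bool = True,
) -> TNCComponents:
    """Per-timepoint decomposition over the normalized stance.

    ``pre``/``post`` have shape (cycles, n_time, n_ev).  A separate
    decomposition is run at every time point (a single random stream seeded
    once keeps the run reproducible); phase means are available via
    :meth:`TNCComponents.phase_means`.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.ndim != 3 or post.ndim != 3 or pre.shape[1:] != post.shape[1:]:
        raise ConfigurationError(
            "pre/post must be (cycles, time, EVs) with matching time/EV axes"
        )
    rng = np.random.default_rng(seed)
    n_time = pre.shape[1]
    rows = []
    channels: tuple[str, ...] = ()
    for t in range(n_time):
        T, N, C, total, channels = _decompose(
            pre[:, t, :], post[:, t, :], forward, n_perm, rng, paired, False
        )
        rows.append((T, N, C, total))
    arrays = [np.stack([r[i] for r in rows]) for i in range(4)]
    return TNCComponents(
        T=arrays[0], N=arrays[1], C=arrays[2], total=arrays[3], channels=channels
    )
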