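"""Forward kinematics: generalized coordinates -> segment CoMs -> performance variables.

The generalized-coordinate vector ``q`` has 50 entries: 3 rotations orienting
the pelvis (root) relative to the lab axes, followed by the internal joint
angles in the model's segment order.  Each joint rotation uses an intrinsic
Z-X-Y Euler sequence; the 2-DOF neck joint uses the Z-X subsequence.  All
angles are radians.

Two performance variables are derived from the whole-body center of mass
(CoM):

- ``pv_lab``: the pelvis-anchored CoM expressed in lab-oriented axes
  (x anterior-posterior, y medio-lateral, z vertical) — a function of the
  50 angles only.
- ``pv_foot``: the CoM relative to the right foot,
  ``r_CoM + r_pelvis - r_rfoot``, where the pelvis and right-foot (malleolus
  midpoint) positions are lab-frame anchors.

A numba-compiled kernel evaluates the chain for large batches (the
permutation ensembles of the TNC stage); a pure-NumPy path is used otherwise
and serves as the installed fallback when numba is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyModel
from .errors import ConfigurationError

try:  # optional acceleration
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba present in the supported env
    _HAVE_NUMBA = False

__all__ = [
    "PVVector",
    "LabAnchors",
    "forward_segment_coms",
    "whole_body_com",
    "pv_lab",
    "pv_foot",
    "pv_lab_vectors",
    "pv_foot_vectors",
    "pv_channels",
    "ev_forward_lab",
    "ev_forward_foot",
]

CHANNELS: tuple[str, ...] = ("3d", "x", "y", "z")


@dataclass(frozen=True)
class PVVector:
    """A performance-variable sample: 3-vector, its norm, and |axis| projections."""

    v: np.ndarray
    norm: float
    axis_lengths: tuple[float, float, float]

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "PVVector":
        v = np.asarray(v, dtype=float)
        if v.shape != (3,):
            raise ConfigurationError(f"PV vector must have shape (3,), got {v.shape}")
        return cls(v=v, norm=float(np.linalg.norm(v)), axis_lengths=tuple(np.abs(v)))


@dataclass(frozen=True)
class LabAnchors:
    """Lab-frame pelvis and right-foot (malleolus midpoint) positions (m)."""

    r_pelvis: np.ndarray
    r_rfoot: np.ndarray

    def __post_init__(self) -> None:
        for name in ("r_pelvis", "r_rfoot"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape[-1] != 3 or not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"{name} must be finite with last axis 3")
            object.__setattr__(self, name, arr)


def _euler_zxy(angles: np.ndarray) -> np.ndarray:
    """Rotation matrices for intrinsic Z-X-Y Euler angles, batched.

    ``angles`` has shape (..., 3); returns (..., 3, 3) with
    ``R = Rz(a) @ Rx(b) @ Ry(c)``.
    """
    a, b, c = angles[..., 0], angles[..., 1], angles[..., 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    R = np.empty(angles.shape[:-1] + (3, 3), dtype=float)
    R[..., 0, 0] = ca * cc - sa * sb * sc
    R[..., 0, 1] = -sa * cb
    R[..., 0, 2] = ca * sc + sa * sb * cc
    R[..., 1, 0] = sa * cc + ca * sb * sc
    R[..., 1, 1] = ca * cb
    R[..., 1, 2] = sa * sc - ca * sb * cc
    R[..., 2, 0] = -cb * sc
    R[..., 2, 1] = sb
    R[..., 2, 2] = cb * cc
    return R


def _joint_angles(q: np.ndarray, model: BodyModel, i: int) -> np.ndarray:
    """Per-segment (.., 3) Euler angles from q, zero-padding 2-DOF joints."""
    s = int(model.dof_start[i])
    c = int(model.dof_count[i])
    ang = np.zeros(q.shape[:-1] + (3,), dtype=float)
    ang[..., :c] = q[..., s : s + c]
    return ang


def forward_segment_coms(q: np.ndarray, model: BodyModel) -> np.ndarray:
    """Segment CoM positions (m), pelvis-anchored, lab-oriented.

    ``q`` has shape (..., n_dof); the result has shape (..., 17, 3).
    Rotations are composed down the tree from the pelvis; the 3 root
    coordinates orient the pelvis relative to the lab axes.  Pelvis
    translation is excluded: positions are relative to the pelvis origin.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != model.n_dof:
        raise ConfigurationError(
            f"q has {q.shape[-1]} coordinates, model expects {model.n_dof}"
        )
    n_seg = model.n_segments
    R: list[np.ndarray] = [None] * n_seg  # type: ignore[list-item]
    P: list[np.ndarray] = [None] * n_seg  # type: ignore[list-item]
    coms = np.empty(q.shape[:-1] + (n_seg, 3), dtype=float)
    for i in range(n_seg):
        R_local = _euler_zxy(_joint_angles(q, model, i))
        parent = int(model.parent_index[i])
        if parent < 0:
            R[i] = R_local
            P[i] = np.zeros(q.shape[:-1] + (3,), dtype=float)
        else:
            R[i] = R[parent] @ R_local
            P[i] = P[parent] + (R[parent] @ model.attach[i])
        local_com = model.axes[i] * model.com_offsets[i]
        coms[..., i, :] = P[i] + (R[i] @ local_com)
    return coms


if _HAVE_NUMBA:

    @njit(cache=True, fastmath=True)
    def _com_kernel(q, parent, attach, axes, com_off, w, dof_start, dof_count):  # pragma: no cover
        n, n_seg = q.shape[0], parent.shape[0]
        out = np.zeros((n, 3))
        R = np.empty((n_seg, 3, 3))
        P = np.empty((n_seg, 3))
        for r in range(n):
            for i in range(n_seg):
                s = dof_start[i]
                a = q[r, s]
                b = q[r, s + 1]
                c = q[r, s + 2] if dof_count[i] == 3 else 0.0
                ca, sa = np.cos(a), np.sin(a)
                cb, sb = np.cos(b), np.sin(b)
                cc, sc = np.cos(c), np.sin(c)
                l00 = ca * cc - sa * sb * sc
                l01 = -sa * cb
                l02 = ca * sc + sa * sb * cc
                l10 = sa * cc + ca * sb * sc
                l11 = ca * cb
                l12 = sa * sc - ca * sb * cc
                l20 = -cb * sc
                l21 = sb
                l22 = cb * cc
                p = parent[i]
                if p < 0:
                    R[i, 0, 0] = l00
                    R[i, 0, 1] = l01
                    R[i, 0, 2] = l02
                    R[i, 1, 0] = l10
                    R[i, 1, 1] = l11
                    R[i, 1, 2] = l12
                    R[i, 2, 0] = l20
                    R[i, 2, 1] = l21
                    R[i, 2, 2] = l22
                    P[i, 0] = 0.0
                    P[i, 1] = 0.0
                    P[i, 2] = 0.0
                else:
                    for row in range(3):
                        r0 = R[p, row, 0]
                        r1 = R[p, row, 1]
                        r2 = R[p, row, 2]
                        R[i, row, 0] = r0 * l00 + r1 * l10 + r2 * l20
                        R[i, row, 1] = r0 * l01 + r1 * l11 + r2 * l21
                        R[i, row, 2] = r0 * l02 + r1 * l12 + r2 * l22
                        P[i, row] = (
                            P[p, row]
                            + r0 * attach[i, 0]
                            + r1 * attach[i, 1]
                            + r2 * attach[i, 2]
                        )
                ox = axes[i, 0] * com_off[i]
                oy = axes[i, 1] * com_off[i]
                oz = axes[i, 2] * com_off[i]
                for row in range(3):
                    out[r, row] += w[i] * (
                        P[i, row] + R[i, row, 0] * ox + R[i, row, 1] * oy + R[i, row, 2] * oz
                    )
        return out


def whole_body_com(q: np.ndarray, model: BodyModel) -> np.ndarray:
    """Whole-body CoM ``sum(r_i V_i) / sum(V_i)`` (m), pelvis-anchored.

    Accepts any leading batch shape in ``q``; large batches dispatch to the
    compiled kernel when numba is available.
    """
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != model.n_dof:
        raise ConfigurationError(
            f"q has {q.shape[-1]} coordinates, model expects {model.n_dof}"
        )
    w = model.weights()
    batch_shape = q.shape[:-1]
    n = int(np.prod(batch_shape)) if batch_shape else 1
    if _HAVE_NUMBA and n >= 64:
        flat = np.ascontiguousarray(q.reshape(n, model.n_dof))
        out = _com_kernel(
            flat,
            model.parent_index,
            model.attach,
            model.axes,
            model.com_offsets,
            w,
            model.dof_start,
            model.dof_count,
        )
        return out.reshape(batch_shape + (3,))
    coms = forward_segment_coms(q, model)
    return np.einsum("...ij,i->...j", coms, w)


def pv_lab_vectors(q: np.ndarray, model: BodyModel) -> np.ndarray:
    """PV_lab 3-vectors for any batch of configurations (= pelvis-anchored CoM)."""
    return whole_body_com(q, model)


def pv_foot_vectors(q: np.ndarray, anchors: LabAnchors, model: BodyModel) -> np.ndarray:
    """PV_foot 3-vectors: ``r_CoM + r_pelvis - r_rfoot`` (broadcasting anchors)."""
    return whole_body_com(q, model) + anchors.r_pelvis - anchors.r_rfoot


def pv_lab(q: np.ndarray, model: BodyModel) -> PVVector:
    """PV_lab for a single configuration, with norm and |axis| projections."""
    return PVVector.from_vector(whole_body_com(np.atleast_1d(q), model))


def pv_foot(q: np.ndarray, anchors: LabAnchors, model: BodyModel) -> PVVector:
    """PV_foot for a single configuration."""
    return PVVector.from_vector(pv_foot_vectors(np.atleast_1d(q), anchors, model))


def pv_channels(vectors: np.ndarray) -> np.ndarray:
    """Stack [norm, |x|, |y|, |z|] along a trailing channel axis.

    ``vectors`` (..., 3) -> (..., 4), channels ordered as :data:`CHANNELS`.
    """
    vectors = np.asarray(vectors, dtype=float)
    norm = np.linalg.norm(vectors, axis=-1, keepdims=True)
    return np.concatenate([norm, np.abs(vectors)], axis=-1)


def ev_forward_lab(model: BodyModel):
    """Forward map for PV_lab execution-variable matrices: (N, 50) -> (N, 3)."""

    def forward(ev: np.ndarray) -> np.ndarray:
        return pv_lab_vectors(np.asarray(ev, dtype=float), model)

    return forward


def ev_forward_foot(model: BodyModel):
    """Forward map for PV_foot EV matrices: (N, 50 + 6) -> (N, 3).

    Columns 50:53 are the lab-frame pelvis position, 53:56 the right-foot
    position; both are permutable execution variables alongside the angles.
    """
    n_dof = model.n_dof

    def forward(ev: np.ndarray) -> np.ndarray:
        ev = np.asarray(ev, dtype=float)
        if ev.shape[-1] != n_dof + 6:
            raise ConfigurationError(
                f"PV_foot EV matrix needs {n_dof + 6} columns, got {ev.shape[-1]}"
            )
        com = whole_body_com(ev[..., :n_dof], model)
        return com + ev[..., n_dof : n_dof + 3] - ev[..., n_dof + 3 :]

    return forward
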