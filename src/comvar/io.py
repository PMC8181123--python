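"""Delimited-file input/output for cohorts, markers, and profiles.

Schemas (all plain CSV, meters / radians / seconds unless declared):

- angles: long format with columns ``subject, state, cycle, time, dof,
  value``; ``state`` is ``pre``/``post``, ``cycle`` and ``time`` 0-based
  indices on the full grid, ``dof`` the 0-based generalized-coordinate
  index.  ``units="deg"`` converts on read/write.
- anchors: ``subject, state, cycle, time, px, py, pz, fx, fy, fz`` with the
  lab-frame pelvis (p) and right-foot (f) positions.
- markers: ``time, marker, x, y, z`` with marker in {heel, toe}.
- profile: YAML mapping with ``subject_id`` and ``measures`` (the 36 keys).

Readers validate strictly and raise :class:`~comvar.errors.SchemaError`
naming the offending column or key.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body import PROFILE_KEYS, AnthropometricProfile
from .errors import ConfigurationError, SchemaError
from .gait_events import MarkerTrack

__all__ = [
    "read_angles",
    "write_angles",
    "read_anchors",
    "write_anchors",
    "read_markers",
    "write_markers",
    "read_profile",
    "write_profile",
]

STATES = ("pre", "post")
_AXES = {"x": 0, "y": 1, "z": 2}


def _require_columns(df: pd.DataFrame, columns: tuple[str, ...], path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def _grid(df: pd.DataFrame, path, value_cols: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    """Reshape a long table onto the (subject, state, cycle, time, ...) grid."""
    subjects = sorted(df["subject"].unique())
    states = set(df["state"].unique())
    if not states <= set(STATES):
        raise SchemaError(f"{path}: state must be one of {STATES}, got {sorted(states)}")
    n_cycles = int(df["cycle"].max()) + 1
    n_time = int(df["time"].max()) + 1
    expected = len(subjects) * 2 * n_cycles * n_time
    key = ["subject", "state", "cycle", "time"]
    df = df.sort_values(key, key=lambda c: c.map({"pre": 0, "post": 1}) if c.name == "state" else c)
    if len(df) != expected:
        raise SchemaError(
            f"{path}: expected a full grid of {expected} rows "
            f"({len(subjects)} subjects x 2 states x {n_cycles} cycles x {n_time} times), "
            f"got {len(df)}"
        )
    values = df[list(value_cols)].to_numpy(dtype=float)
    shape = (len(subjects), 2, n_cycles, n_time, len(value_cols))
    return values.reshape(shape), subjects


def write_angles(path, angles: np.ndarray, units: str = "rad") -> None:
    """Write a (subjects, 2, cycles, time, n_dof) angle array in long format."""
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 5 or angles.shape[1] != 2:
        raise ConfigurationError("angles must be (subjects, 2 states, cycles, time, dof)")
    S, _, C, T, D = angles.shape
    idx = pd.MultiIndex.from_product(
        [range(S), STATES, range(C), range(T), range(D)],
        names=["subject", "state", "cycle", "time", "dof"],
    )
    values = angles.reshape(-1)
    if units == "deg":
        values = np.degrees(values)
    elif units != "rad":
        raise ConfigurationError("units must be 'rad' or 'deg'")
    pd.DataFrame({"value": values}, index=idx).reset_index().to_csv(path, index=False)


def read_angles(path, units: str = "rad") -> tuple[np.ndarray, list[str]]:
    """Read a long-format angle table; returns ((S, 2, C, T, D), subject labels)."""
    df = pd.read_csv(path)
    _require_columns(df, ("subject", "state", "cycle", "time", "dof", "value"), path)
    n_dof = int(df["dof"].max()) + 1
    wide = df.pivot_table(
        index=["subject", "state", "cycle", "time"], columns="dof", values="value", sort=False
    ).reset_index()
    value_cols = tuple(range(n_dof))
    for col in value_cols:
        if col not in wide.columns:
            raise SchemaError(f"{path}: missing dof index {col}")
    arr, subjects = _grid(wide, path, value_cols)
    if units == "deg":
        arr = np.radians(arr)
    elif units != "rad":
        raise ConfigurationError("units must be 'rad' or 'deg'")
    return arr, subjects


_ANCHOR_COLS = ("px", "py", "pz", "fx", "fy", "fz")


def write_anchors(path, pelvis: np.ndarray, rfoot: np.ndarray) -> None:
    """Write pelvis/right-foot anchors, each (subjects, 2, cycles, time, 3)."""
    pelvis = np.asarray(pelvis, dtype=float)
    rfoot = np.asarray(rfoot, dtype=float)
    if pelvis.shape != rfoot.shape or pelvis.ndim != 5 or pelvis.shape[-1] != 3:
        raise ConfigurationError("pelvis/rfoot must both be (subjects, 2, cycles, time, 3)")
    S, _, C, T, _ = pelvis.shape
    idx = pd.MultiIndex.from_product(
        [range(S), STATES, range(C), range(T)],
        names=["subject", "state", "cycle", "time"],
    )
    data = np.concatenate([pelvis, rfoot], axis=-1).reshape(-1, 6)
    pd.DataFrame(data, columns=list(_ANCHOR_COLS), index=idx).reset_index().to_csv(
        path, index=False
    )


def read_anchors(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read anchors; returns (pelvis, rfoot, subject labels)."""
    df = pd.read_csv(path)
    _require_columns(df, ("subject", "state", "cycle", "time") + _ANCHOR_COLS, path)
    arr, subjects = _grid(df, path, _ANCHOR_COLS)
    return arr[..., :3], arr[..., 3:], subjects


def write_markers(path, track: MarkerTrack) -> None:
    frames = []
    for name, arr in (("heel", track.heel), ("toe", track.toe)):
        frames.append(
            pd.DataFrame(
                {"time": track.t, "marker": name, "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2]}
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_markers(path, vertical_axis: str = "z") -> MarkerTrack:
    """Read a heel/toe marker table; ``vertical_axis`` names the gravity axis."""
    df = pd.read_csv(path)
    _require_columns(df, ("time", "marker", "x", "y", "z"), path)
    if vertical_axis not in _AXES:
        raise ConfigurationError("vertical_axis must be 'x', 'y' or 'z'")
    tracks = {}
    for name in ("heel", "toe"):
        sub = df[df["marker"] == name].sort_values("time")
        if sub.empty:
            raise SchemaError(f"{path}: no rows for marker '{name}'")
        tracks[name] = sub
    t = tracks["heel"]["time"].to_numpy(dtype=float)
    if not np.array_equal(t, tracks["toe"]["time"].to_numpy(dtype=float)):
        raise SchemaError(f"{path}: heel and toe markers must share sample times")
    return MarkerTrack(
        t=t,
        heel=tracks["heel"][["x", "y", "z"]].to_numpy(dtype=float),
        toe=tracks["toe"][["x", "y", "z"]].to_numpy(dtype=float),
        vertical_axis=_AXES[vertical_axis],
    )


def write_profile(path, profile: AnthropometricProfile) -> None:
    payload = {"subject_id": profile.subject_id, "measures": dict(profile.measures)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_profile(path) -> AnthropometricProfile:
    """Read and strictly validate an anthropometric profile YAML file."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "measures" not in payload:
        raise SchemaError(f"{path}: profile must be a mapping with a 'measures' key")
    measures = payload["measures"]
    if not isinstance(measures, dict):
        raise SchemaError(f"{path}: 'measures' must be a mapping")
    missing = [k for k in PROFILE_KEYS if k not in measures]
    if missing:
        raise SchemaError(f"{path}: missing measures: {', '.join(missing)}")
    try:
        return AnthropometricProfile(
            subject_id=str(payload.get("subject_id", Path(path).stem)),
            measures={k: float(v) for k, v in measures.items()},
        )
    except ConfigurationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
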