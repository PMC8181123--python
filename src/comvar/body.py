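"""Subject-specific volumetric body model.

The whole body is represented by 17 rigid segments, each a geometric solid
of revolution or an elliptical solid (sphere, ellipsoid, elliptical cylinder,
conical frustum), arranged in a kinematic tree rooted at the pelvis.  Under
the uniform-density assumption the segment volumes double as mass weights,
so the whole-body center of mass is the volume-weighted mean of the segment
centroids.  Segment dimensions come from a 36-entry anthropometric profile:
girths are converted to radii as ``c / (2*pi)``, breadths and depths to
semi-axes as ``b / 2``.

The default model carries 50 generalized coordinates: 3 rotations orienting
the pelvis in the lab frame plus 47 internal joint angles (fifteen 3-DOF
joints and one 2-DOF neck joint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError

__all__ = [
    "PROFILE_KEYS",
    "INFORMATIONAL_KEYS",
    "SEGMENT_NAMES",
    "AnthropometricProfile",
    "SolidSpec",
    "SegmentSpec",
    "BodyModel",
    "solid_volume",
    "solid_com_offset",
    "build_body_model",
    "mass_weights",
    "default_profile",
]

#: The 36 anthropometric measures (meters except body_mass in kilograms).
#: Girths are named ``*_circumference``; ``*_breadth`` / ``*_depth`` are
#: linear calipers.  ``hand_length``, ``stature`` and ``body_mass`` are
#: informational: with uniform density they do not enter the CoM weights.
PROFILE_KEYS: tuple[str, ...] = (
    "head_length",
    "head_breadth",
    "head_depth",
    "neck_length",
    "neck_circumference",
    "thorax_length",
    "thorax_breadth",
    "thorax_depth",
    "abdomen_length",
    "abdomen_breadth",
    "abdomen_depth",
    "pelvis_length",
    "pelvis_breadth",
    "pelvis_depth",
    "shoulder_breadth",
    "hip_breadth",
    "upper_arm_length",
    "upper_arm_proximal_circumference",
    "upper_arm_distal_circumference",
    "forearm_length",
    "forearm_proximal_circumference",
    "forearm_distal_circumference",
    "hand_length",
    "hand_circumference",
    "thigh_length",
    "thigh_proximal_circumference",
    "thigh_distal_circumference",
    "shank_length",
    "shank_proximal_circumference",
    "shank_distal_circumference",
    "foot_length",
    "foot_proximal_circumference",
    "foot_distal_circumference",
    "ankle_height",
    "stature",
    "body_mass",
)

INFORMATIONAL_KEYS: tuple[str, ...] = ("hand_length", "ankle_height", "stature", "body_mass")

SEGMENT_NAMES: tuple[str, ...] = (
    "pelvis",
    "abdomen",
    "thorax",
    "neck",
    "head",
    "upper_arm_left",
    "forearm_left",
    "hand_left",
    "upper_arm_right",
    "forearm_right",
    "hand_right",
    "thigh_left",
    "shank_left",
    "foot_left",
    "thigh_right",
    "shank_right",
    "foot_right",
)

_SOLID_KINDS = ("sphere", "ellipsoid", "elliptical_cylinder", "conical_frustum")


@dataclass(frozen=True)
class AnthropometricProfile:
    """One subject's 36 anthropometric measures.

    Parameters
    ----------
    subject_id
        Free-form label for the subject.
    measures
        Mapping with exactly the keys in :data:`PROFILE_KEYS`.  Lengths,
        breadths and circumferences are in meters; ``body_mass`` in kg.
    """

    subject_id: str
    measures: dict[str, float]

    def __post_init__(self) -> None:
        missing = [k for k in PROFILE_KEYS if k not in self.measures]
        if missing:
            raise ConfigurationError(
                f"profile '{self.subject_id}' is missing measures: {', '.join(missing)}"
            )
        extra = [k for k in self.measures if k not in PROFILE_KEYS]
        if extra:
            raise ConfigurationError(
                f"profile '{self.subject_id}' has unknown measures: {', '.join(extra)}"
            )
        for key, value in self.measures.items():
            if not (math.isfinite(value) and value > 0.0):
                raise ConfigurationError(
                    f"profile '{self.subject_id}': measure '{key}' must be a "
                    f"positive finite number, got {value!r}"
                )

    def __getitem__(self, key: str) -> float:
        return self.measures[key]


@dataclass(frozen=True)
class SolidSpec:
    """A geometric solid with its long axis as reference direction.

    ``kind`` selects the dimension keys:

    - ``sphere``: ``radius``
    - ``ellipsoid``: ``semi_axial`` (long semi-axis), ``semi_b``, ``semi_c``
    - ``elliptical_cylinder``: ``semi_a``, ``semi_b``, ``height``
    - ``conical_frustum``: ``r_proximal``, ``r_distal``, ``height``
      (``r_distal = 0`` degenerates to a cone, which is legal)
    """

    kind: str
    dimensions: dict[str, float]

    _REQUIRED = {
        "sphere": ("radius",),
        "ellipsoid": ("semi_axial", "semi_b", "semi_c"),
        "elliptical_cylinder": ("semi_a", "semi_b", "height"),
        "conical_frustum": ("r_proximal", "r_distal", "height"),
    }

    def __post_init__(self) -> None:
        if self.kind not in _SOLID_KINDS:
            raise InvalidGeometryError(f"unknown solid kind {self.kind!r}")
        required = self._REQUIRED[self.kind]
        missing = [k for k in required if k not in self.dimensions]
        if missing:
            raise InvalidGeometryError(
                f"{self.kind} requires dimensions {required}, missing {missing}"
            )
        for key in required:
            value = self.dimensions[key]
            lower_ok = value >= 0.0 if key == "r_distal" else value > 0.0
            if not (math.isfinite(value) and lower_ok):
                raise InvalidGeometryError(
                    f"{self.kind}: dimension '{key}' must be positive "
                    f"(r_distal may be 0), got {value!r}"
                )

    def __getitem__(self, key: str) -> float:
        return self.dimensions[key]


@dataclass(frozen=True)
class SegmentSpec:
    """One segment of the kinematic tree.

    ``attach_offset`` is the position of the segment's proximal joint in the
    parent segment's local frame; ``axis`` is the unit direction of the
    solid's long axis in the segment's own frame.  The root segment (pelvis)
    has ``parent=None``.
    """

    name: str
    solid: SolidSpec
    parent: str | None
    attach_offset: tuple[float, float, float]
    axis: tuple[float, float, float]
    n_dof: int = 3

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(a * a for a in self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise InvalidGeometryError(f"segment '{self.name}': axis must be a unit vector")
        if self.n_dof not in (2, 3):
            raise InvalidGeometryError(f"segment '{self.name}': n_dof must be 2 or 3")


@dataclass
class BodyModel:
    """17-segment volumetric model with the arrays forward kinematics needs.

    Segments are stored in topological order (parents before children); the
    generalized-coordinate vector is ``[3 root rotations, joint angles in
    segment order]`` with the per-joint DOF counts of ``dof_map``.
    """

    segments: list[SegmentSpec]
    volumes: np.ndarray  # (17,) m^3
    com_offsets: np.ndarray  # (17,) m, along the segment axis from the proximal joint
    # derived arrays, filled in __post_init__
    parent_index: np.ndarray = field(init=False)
    attach: np.ndarray = field(init=False)
    axes: np.ndarray = field(init=False)
    dof_start: np.ndarray = field(init=False)
    dof_count: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate segment names")
        index = {name: i for i, name in enumerate(names)}
        parent_index = np.empty(len(names), dtype=np.int64)
        n_roots = 0
        for i, seg in enumerate(self.segments):
            if seg.parent is None:
                parent_index[i] = -1
                n_roots += 1
            else:
                if seg.parent not in index:
                    raise ConfigurationError(
                        f"segment '{seg.name}' references unknown parent '{seg.parent}'"
                    )
                parent_index[i] = index[seg.parent]
                if parent_index[i] >= i:
                    raise ConfigurationError("segments must be in topological order")
        if n_roots != 1:
            raise ConfigurationError(f"expected exactly one root segment, found {n_roots}")
        self.parent_index = parent_index
        self.attach = np.array([s.attach_offset for s in self.segments], dtype=float)
        self.axes = np.array([s.axis for s in self.segments], dtype=float)
        self.dof_count = np.array([s.n_dof for s in self.segments], dtype=np.int64)
        self.dof_start = np.concatenate([[0], np.cumsum(self.dof_count)[:-1]])
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.com_offsets = np.asarray(self.com_offsets, dtype=float)
        if self.volumes.shape != (len(names),) or self.com_offsets.shape != (len(names),):
            raise ConfigurationError("volumes/com_offsets must have one entry per segment")
        if not np.all(self.volumes > 0):
            raise ConfigurationError("segment volumes must be positive")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_dof(self) -> int:
        """Total generalized coordinates (root rotations included)."""
        return int(self.dof_count.sum())

    @property
    def dof_map(self) -> dict[str, int]:
        """Rotational DOF per joint, keyed by the distal segment's name."""
        return {s.name: s.n_dof for s in self.segments}

    @property
    def segment_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.segments)}

    def weights(self) -> np.ndarray:
        return mass_weights(self)


def solid_volume(solid: SolidSpec) -> float:
    """Closed-form volume (m^3) of a solid.

    Sphere ``4/3 pi r^3``; ellipsoid ``4/3 pi a b c``; elliptical cylinder
    ``pi a b h``; conical frustum ``pi h (r1^2 + r1 r2 + r2^2) / 3``.
    """
    d = solid.dimensions
    if solid.kind == "sphere":
        return 4.0 / 3.0 * math.pi * d["radius"] ** 3
    if solid.kind == "ellipsoid":
        return 4.0 / 3.0 * math.pi * d["semi_axial"] * d["semi_b"] * d["semi_c"]
    if solid.kind == "elliptical_cylinder":
        return math.pi * d["semi_a"] * d["semi_b"] * d["height"]
    # conical frustum
    r1, r2, h = d["r_proximal"], d["r_distal"], d["height"]
    return math.pi * h * (r1 * r1 + r1 * r2 + r2 * r2) / 3.0


def solid_com_offset(solid: SolidSpec) -> float:
    """Centroid position (m) along the long axis, from the proximal end.

    Uniform density is assumed.  For the frustum the centroid is
    ``h (r1^2 + 2 r1 r2 + 3 r2^2) / (4 (r1^2 + r1 r2 + r2^2))`` from the
    proximal face, which reduces to ``h/4`` for a proximal-base cone.
    """
    d = solid.dimensions
    if solid.kind == "sphere":
        return d["radius"]
    if solid.kind == "ellipsoid":
        return d["semi_axial"]
    if solid.kind == "elliptical_cylinder":
        return d["height"] / 2.0
    r1, r2, h = d["r_proximal"], d["r_distal"], d["height"]
    return h * (r1 * r1 + 2.0 * r1 * r2 + 3.0 * r2 * r2) / (4.0 * (r1 * r1 + r1 * r2 + r2 * r2))


def _radius(circumference: float) -> float:
    return circumference / (2.0 * math.pi)


def _segment_specs(p: AnthropometricProfile) -> list[SegmentSpec]:
    up = (0.0, 0.0, 1.0)
    down = (0.0, 0.0, -1.0)
    fwd = (1.0, 0.0, 0.0)

    def cylinder(prefix: str) -> SolidSpec:
        return SolidSpec(
            "elliptical_cylinder",
            {
                "semi_a": p[f"{prefix}_breadth"] / 2.0,
                "semi_b": p[f"{prefix}_depth"] / 2.0,
                "height": p[f"{prefix}_length"],
            },
        )

    def frustum(prefix: str) -> SolidSpec:
        return SolidSpec(
            "conical_frustum",
            {
                "r_proximal": _radius(p[f"{prefix}_proximal_circumference"]),
                "r_distal": _radius(p[f"{prefix}_distal_circumference"]),
                "height": p[f"{prefix}_length"],
            },
        )

    neck = SolidSpec(
        "elliptical_cylinder",
        {
            "semi_a": _radius(p["neck_circumference"]),
            "semi_b": _radius(p["neck_circumference"]),
            "height": p["neck_length"],
        },
    )
    head = SolidSpec(
        "ellipsoid",
        {
            "semi_axial": p["head_length"] / 2.0,
            "semi_b": p["head_breadth"] / 2.0,
            "semi_c": p["head_depth"] / 2.0,
        },
    )
    hand = SolidSpec("sphere", {"radius": _radius(p["hand_circumference"])})

    shoulder = p["shoulder_breadth"] / 2.0
    hip = p["hip_breadth"] / 2.0
    specs = [
        SegmentSpec("pelvis", cylinder("pelvis"), None, (0.0, 0.0, 0.0), down),
        SegmentSpec("abdomen", cylinder("abdomen"), "pelvis", (0.0, 0.0, 0.0), up),
        SegmentSpec("thorax", cylinder("thorax"), "abdomen", (0.0, 0.0, p["abdomen_length"]), up),
        SegmentSpec("neck", neck, "thorax", (0.0, 0.0, p["thorax_length"]), up, n_dof=2),
        SegmentSpec("head", head, "neck", (0.0, 0.0, p["neck_length"]), up),
    ]
    for side, sign in (("left", 1.0), ("right", -1.0)):
        specs += [
            SegmentSpec(
                f"upper_arm_{side}",
                frustum("upper_arm"),
                "thorax",
                (0.0, sign * shoulder, p["thorax_length"]),
                down,
            ),
            SegmentSpec(
                f"forearm_{side}",
                frustum("forearm"),
                f"upper_arm_{side}",
                (0.0, 0.0, -p["upper_arm_length"]),
                down,
            ),
            SegmentSpec(
                f"hand_{side}", hand, f"forearm_{side}", (0.0, 0.0, -p["forearm_length"]), down
            ),
        ]
    for side, sign in (("left", 1.0), ("right", -1.0)):
        specs += [
            SegmentSpec(
                f"thigh_{side}",
                frustum("thigh"),
                "pelvis",
                (0.0, sign * hip, -p["pelvis_length"]),
                down,
            ),
            SegmentSpec(
                f"shank_{side}",
                frustum("shank"),
                f"thigh_{side}",
                (0.0, 0.0, -p["thigh_length"]),
                down,
            ),
            SegmentSpec(
                f"foot_{side}", frustum("foot"), f"shank_{side}", (0.0, 0.0, -p["shank_length"]), fwd
            ),
        ]
    order = {name: i for i, name in enumerate(SEGMENT_NAMES)}
    specs.sort(key=lambda s: order[s.name])
    return specs


def build_body_model(profile: AnthropometricProfile) -> BodyModel:
    """Build the 17-segment model for one subject.

    Radii are derived from circumferences as ``c / (2*pi)``, semi-axes from
    breadths/depths as ``b / 2``.  Raises :class:`ConfigurationError` naming
    the offending key if a measure is missing (profiles validate on
    construction, so this surfaces for hand-built measure dicts too).
    """
    segments = _segment_specs(profile)
    volumes = np.array([solid_volume(s.solid) for s in segments])
    com_offsets = np.array([solid_com_offset(s.solid) for s in segments])
    model = BodyModel(segments=segments, volumes=volumes, com_offsets=com_offsets)
    if model.n_segments != 17 or model.n_dof != 50:
        raise ConfigurationError(
            f"default model must have 17 segments / 50 DOF, got "
            f"{model.n_segments} / {model.n_dof}"
        )
    return model


def mass_weights(model: BodyModel) -> np.ndarray:
    """Normalized mass weights ``w_i = V_i / sum(V)`` (constant density)."""
    return model.volumes / model.volumes.sum()


#: Default male-runner profile used by the synthetic cohort (meters / kg).
_DEFAULT_MEASURES: dict[str, float] = {
    "head_length": 0.24,
    "head_breadth": 0.155,
    "head_depth": 0.19,
    "neck_length": 0.10,
    "neck_circumference": 0.38,
    "thorax_length": 0.30,
    "thorax_breadth": 0.30,
    "thorax_depth": 0.20,
    "abdomen_length": 0.20,
    "abdomen_breadth": 0.28,
    "abdomen_depth": 0.18,
    "pelvis_length": 0.12,
    "pelvis_breadth": 0.33,
    "pelvis_depth": 0.21,
    "shoulder_breadth": 0.38,
    "hip_breadth": 0.17,
    "upper_arm_length": 0.32,
    "upper_arm_proximal_circumference": 0.30,
    "upper_arm_distal_circumference": 0.26,
    "forearm_length": 0.27,
    "forearm_proximal_circumference": 0.27,
    "forearm_distal_circumference": 0.17,
    "hand_length": 0.19,
    "hand_circumference": 0.21,
    "thigh_length": 0.45,
    "thigh_proximal_circumference": 0.58,
    "thigh_distal_circumference": 0.39,
    "shank_length": 0.43,
    "shank_proximal_circumference": 0.37,
    "shank_distal_circumference": 0.23,
    "foot_length": 0.26,
    "foot_proximal_circumference": 0.25,
    "foot_distal_circumference": 0.16,
    "ankle_height": 0.08,
    "stature": 1.80,
    "body_mass": 68.0,
}


def default_profile(subject_id: str = "default") -> AnthropometricProfile:
    """The packaged reference profile (young trained male runner, 1.80 m)."""
    return AnthropometricProfile(subject_id=subject_id, measures=dict(_DEFAULT_MEASURES))
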