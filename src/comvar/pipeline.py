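"""End-to-end orchestration: cohort -> PV series -> CV -> TNC -> group tables.

The pipeline consumes either a synthetic cohort configuration or delimited
angle/anchor files plus an anthropometric profile, and produces, per
performance variable:

- per-subject phase means of vector length, CV, and the T/N/C components;
- group mean/SD time courses of length and CV over the normalized stance;
- a group-level statistics table (paired tests on lengths and CVs,
  one-sample tests on T/N/C), rounded for report plus a full-precision
  companion;
- a JSON manifest recording versions, seeds, permutation counts, and input
  hashes, so every output is traceable.

Runs are deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .body import BodyModel, build_body_model, default_profile
from .errors import ConfigurationError
from .io import read_anchors, read_angles, read_profile
from .kinematics import CHANNELS, ev_forward_foot, ev_forward_lab, pv_lab_vectors
from .stats import build_tables
from .synth import SyntheticConfig, generate_cohort
from .tnc import tnc_timecourse
from .variability import PVSeries, pv_cv

__all__ = ["RunConfig", "PVAnalysis", "analyze_arrays", "run_pipeline"]

PV_KINDS = ("lab", "foot")


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: input source, PV kinds, permutation and seed policy."""

    out_dir: str
    synthetic: SyntheticConfig | None = None
    angles_path: str | None = None
    anchors_path: str | None = None
    profile_path: str | None = None
    pv_kinds: tuple[str, ...] = PV_KINDS
    n_perm: int = 1000
    seed: int = 0
    paired_permutations: bool = True
    rounding: int = 3
    signed_axes: bool = False

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError("n_perm must be >= 1")
        bad = [k for k in self.pv_kinds if k not in PV_KINDS]
        if bad:
            raise ConfigurationError(f"unknown pv kinds {bad}; choose from {PV_KINDS}")
        if self.synthetic is None and not (self.angles_path and self.anchors_path):
            raise ConfigurationError("provide either a synthetic config or angle/anchor paths")


@dataclass
class PVAnalysis:
    """Per-subject and group results for one performance variable."""

    pv_kind: str
    lengths: np.ndarray  # (subjects, 2 states, 2 phases, 4 channels), m
    cvs: np.ndarray  # same shape, %
    tnc: dict[str, np.ndarray]  # component -> (subjects, 2 phases, 4), pp
    length_curves: np.ndarray  # (subjects, 2 states, 100, 4), m
    cv_curves: np.ndarray  # (subjects, 2 states, 100, 4), %
    table: pd.DataFrame


def _subject_seed(base: int, pv_index: int, subject: int) -> int:
    # deterministic per-(pv, subject) streams, well below 2**31
    return (base * 1000 + pv_index * 500 + subject) % (2**31 - 1)


def analyze_arrays(
    angles: np.ndarray,
    pelvis: np.ndarray,
    rfoot: np.ndarray,
    model: BodyModel,
    pv_kinds: tuple[str, ...] = PV_KINDS,
    n_perm: int = 1000,
    seed: int = 0,
    paired: bool = True,
    signed_axes: bool = False,
) -> dict[str, PVAnalysis]:
    """Full analysis of a cohort given as arrays.

    ``angles`` is (subjects, 2 states, cycles, time, n_dof); ``pelvis`` and
    ``rfoot`` are the matching (..., 3) lab anchors (required for the foot
    PV).  Returns one :class:`PVAnalysis` per requested PV kind.
    """
    angles = np.asarray(angles, dtype=float)
    S, n_states, C, T, D = angles.shape
    if n_states != 2:
        raise ConfigurationError("angles must contain exactly the PRE and POST states")
    results: dict[str, PVAnalysis] = {}
    for pv_index, kind in enumerate(pv_kinds):
        if kind == "lab":
            forward = ev_forward_lab(model)
            evs = angles
        else:
            forward = ev_forward_foot(model)
            evs = np.concatenate([angles, pelvis, rfoot], axis=-1)
        lengths = np.empty((S, 2, 2, len(CHANNELS)))
        cvs = np.empty_like(lengths)
        length_curves = np.empty((S, 2, T, len(CHANNELS)))
        cv_curves = np.empty_like(length_curves)
        tnc = {comp: np.empty((S, 2, len(CHANNELS))) for comp in ("T", "N", "C", "total")}
        for s in range(S):
            for st in range(2):
                vectors = forward(evs[s, st].reshape(C * T, -1)).reshape(C, T, 3)
                series = PVSeries.from_vectors(vectors, signed=signed_axes)
                mean_curve = series.values.mean(axis=0)  # (T, 4)
                length_curves[s, st] = mean_curve
                lengths[s, st, 0] = mean_curve[:50].mean(axis=0)
                lengths[s, st, 1] = mean_curve[50:].mean(axis=0)
                cv = pv_cv(series)
                cv_curves[s, st] = cv.cv
                cvs[s, st] = cv.phase_means
            components = tnc_timecourse(
                evs[s, 0],
                evs[s, 1],
                forward,
                n_perm=n_perm,
                seed=_subject_seed(seed, pv_index, s),
                paired=paired,
            )
            for comp, value in components.phase_means().items():
                tnc[comp][s] = value
        table = build_tables(f"PV_{kind}", lengths, cvs, tnc)
        results[kind] = PVAnalysis(
            pv_kind=kind,
            lengths=lengths,
            cvs=cvs,
            tnc=tnc,
            length_curves=length_curves,
            cv_curves=cv_curves,
            table=table,
        )
    return results


def _per_subject_frame(analysis: PVAnalysis) -> pd.DataFrame:
    rows = []
    S = analysis.lengths.shape[0]
    phases = ("absorption", "propulsion")
    for s in range(S):
        for pi, phase in enumerate(phases):
            for ci, ch in enumerate(CHANNELS):
                row = dict(pv=analysis.pv_kind, subject=s, phase=phase, channel=ch)
                for st, state in enumerate(("pre", "post")):
                    row[f"length_{state}"] = analysis.lengths[s, st, pi, ci]
                    row[f"cv_{state}"] = analysis.cvs[s, st, pi, ci]
                for comp in ("T", "N", "C", "total"):
                    row[comp] = analysis.tnc[comp][s, pi, ci]
                rows.append(row)
    return pd.DataFrame(rows)


def _curve_frame(analysis: PVAnalysis) -> pd.DataFrame:
    """Group mean/SD time courses of length and CV (figure-style export)."""
    rows = []
    for st, state in enumerate(("pre", "post")):
        for ci, ch in enumerate(CHANNELS):
            for t in range(analysis.length_curves.shape[2]):
                rows.append(
                    dict(
                        pv=analysis.pv_kind,
                        state=state,
                        channel=ch,
                        point=t + 1,
                        length_mean=analysis.length_curves[:, st, t, ci].mean(),
                        length_sd=analysis.length_curves[:, st, t, ci].std(ddof=1),
                        cv_mean=analysis.cv_curves[:, st, t, ci].mean(),
                        cv_sd=analysis.cv_curves[:, st, t, ci].std(ddof=1),
                    )
                )
    return pd.DataFrame(rows)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, PVAnalysis]:
    """Execute a full run and write the report bundle to ``config.out_dir``.

    On failure a ``FAILED.txt`` marker is left in the output directory so
    partial results are never mistaken for a completed run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED.txt"
    marker.write_text("run in progress / failed\n")
    inputs: dict[str, str] = {}
    try:
        if config.synthetic is not None:
            cohort = generate_cohort(replace(config.synthetic, seed=config.seed))
            angles, pelvis, rfoot = cohort.angles, cohort.pelvis, cohort.rfoot
            model = cohort.model
            inputs["synthetic"] = json.dumps(asdict(cohort.config), sort_keys=True)
        else:
            angles, _ = read_angles(config.angles_path)
            pelvis, rfoot, _ = read_anchors(config.anchors_path)
            profile = (
                read_profile(config.profile_path) if config.profile_path else default_profile()
            )
            model = build_body_model(profile)
            inputs = {
                "angles_sha256": _hash_file(config.angles_path),
                "anchors_sha256": _hash_file(config.anchors_path),
            }
            if config.profile_path:
                inputs["profile_sha256"] = _hash_file(config.profile_path)
        results = analyze_arrays(
            angles,
            pelvis,
            rfoot,
            model,
            pv_kinds=config.pv_kinds,
            n_perm=config.n_perm,
            seed=config.seed,
            paired=config.paired_permutations,
            signed_axes=config.signed_axes,
        )
        for kind, analysis in results.items():
            _per_subject_frame(analysis).to_csv(out / f"per_subject_pv_{kind}.csv", index=False)
            _curve_frame(analysis).to_csv(out / f"curves_pv_{kind}.csv", index=False)
            analysis.table.round(config.rounding).to_csv(out / f"table_pv_{kind}.csv", index=False)
            analysis.table.to_csv(out / f"table_pv_{kind}_full.csv", index=False)
        manifest = {
            "package": "comvar",
            "version": __version__,
            "seed": config.seed,
            "n_perm": config.n_perm,
            "pv_kinds": list(config.pv_kinds),
            "paired_permutations": config.paired_permutations,
            "inputs": inputs,
            "outputs": sorted(p.name for p in out.iterdir() if p.name != marker.name),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except BaseException:
        marker.write_text("run FAILED; outputs in this directory are partial\n")
        raise
    marker.unlink()
    return results
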