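"""Group-level inference on phase-averaged variability measures.

Vector lengths and their CVs are compared between states with dependent
t-tests; the T/N/C components, being PRE->POST change scores, are tested
against zero with one-sample t-tests.  Cohen's d is defined as ``|t| /
sqrt(n)`` (equivalently |mean difference| / SD of the differences), with
small < 0.5, medium 0.5-0.8, large > 0.8.  Tests are two-sided at alpha =
0.05 with no multiplicity correction by default; a Holm adjustment is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateTestError

__all__ = [
    "TestResult",
    "dependent_t",
    "one_sample_t",
    "effect_label",
    "build_tables",
    "CHANNEL_LABELS",
]

CHANNEL_LABELS: dict[str, str] = {
    "3d": "3D",
    "x": "anterior-posterior",
    "y": "medio-lateral",
    "z": "vertical",
}
PHASE_LABELS = ("absorption", "propulsion")
QUANTITIES = ("Length", "CV", "T", "N", "C")


@dataclass(frozen=True)
class TestResult:
    t: float
    p: float
    d: float
    label: str


def effect_label(d: float) -> str:
    """Cohen's d band: small < 0.5, medium 0.5-0.8, large > 0.8."""
    if d < 0:
        warnings.warn("negative Cohen's d; using its magnitude", stacklevel=2)
        d = abs(d)
    if d < 0.5:
        return "small"
    if d <= 0.8:
        return "medium"
    return "large"


def _finish(t: float, p: float, n: int) -> TestResult:
    d = abs(t) / np.sqrt(n)
    return TestResult(t=float(t), p=float(p), d=float(d), label=effect_label(float(d)))


def dependent_t(pre: np.ndarray, post: np.ndarray) -> TestResult:
    """Paired two-sided t-test between states, df = n - 1."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ConfigurationError("paired test needs matching 1-D samples with n >= 2")
    diff = post - pre
    if np.std(diff, ddof=1) == 0.0:
        if np.all(diff == 0.0):
            # identical samples: no change at all, not an ill-posed test
            return TestResult(t=0.0, p=1.0, d=0.0, label="small")
        raise DegenerateTestError("zero variance of the paired differences")
    res = sps.ttest_rel(post, pre)
    return _finish(res.statistic, res.pvalue, len(pre))


def one_sample_t(x: np.ndarray, mu0: float = 0.0) -> TestResult:
    """Two-sided one-sample t-test of the mean against ``mu0``, df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ConfigurationError("one-sample test needs a 1-D sample with n >= 2")
    if np.std(x, ddof=1) == 0.0:
        raise DegenerateTestError("zero sample variance")
    res = sps.ttest_1samp(x, mu0)
    return _finish(res.statistic, res.pvalue, len(x))


def _drop_missing(name: str, *arrays: np.ndarray) -> tuple[np.ndarray, ...]:
    mask = np.ones(arrays[0].shape[0], dtype=bool)
    for arr in arrays:
        mask &= np.isfinite(arr)
    if not mask.all():
        excluded = list(np.nonzero(~mask)[0])
        warnings.warn(f"{name}: excluding subjects with missing data: {excluded}", stacklevel=3)
    return tuple(arr[mask] for arr in arrays)


def build_tables(
    pv_label: str,
    lengths: np.ndarray,
    cvs: np.ndarray,
    tnc: dict[str, np.ndarray],
    channels: tuple[str, ...] = ("3d", "x", "y", "z"),
    adjust: str | None = None,
) -> pd.DataFrame:
    """Assemble the group-level summary table for one performance variable.

    Parameters
    ----------
    pv_label
        ``"PV_lab"`` or ``"PV_foot"`` (free-form).
    lengths, cvs
        Per-subject phase means, shape (n_subjects, 2 states, 2 phases,
        n_channels); state 0 is PRE, state 1 POST.  Lengths in meters, CVs
        in percent.
    tnc
        Mapping ``{"T": ..., "N": ..., "C": ...}`` of per-subject change
        scores, shape (n_subjects, 2 phases, n_channels), percentage points.
    adjust
        ``"holm"`` applies a Holm step-down correction to the p column.

    Returns one row per channel x quantity x phase (Length and CV rows carry
    PRE and POST mean +- SD with a dependent t-test; T/N/C rows carry the
    single change-score mean +- SD with a one-sample test against zero).
    Degenerate tests (zero variance, e.g. POST identical to PRE) produce NaN
    t and p with d = 0.
    """
    lengths = np.asarray(lengths, dtype=float)
    cvs = np.asarray(cvs, dtype=float)
    n_ch = len(channels)
    if lengths.ndim != 4 or lengths.shape[1:] != (2, 2, n_ch):
        raise ConfigurationError(
            f"lengths must be (subjects, 2 states, 2 phases, {n_ch}), got {lengths.shape}"
        )
    if cvs.shape != lengths.shape:
        raise ConfigurationError("cvs must match the shape of lengths")
    rows = []
    for ci, channel in enumerate(channels):
        for quantity in QUANTITIES:
            for pi, phase in enumerate(PHASE_LABELS):
                if quantity in ("Length", "CV"):
                    source = lengths if quantity == "Length" else cvs
                    pre, post = _drop_missing(
                        f"{pv_label} {quantity} {channel} {phase}",
                        source[:, 0, pi, ci],
                        source[:, 1, pi, ci],
                    )
                    try:
                        res = dependent_t(pre, post)
                        t, p, d, label = res.t, res.p, res.d, res.label
                    except DegenerateTestError:
                        t, p, d, label = np.nan, np.nan, 0.0, "small"
                    row = dict(
                        mean_pre=pre.mean(),
                        sd_pre=pre.std(ddof=1),
                        mean_post=post.mean(),
                        sd_post=post.std(ddof=1),
                    )
                else:
                    (x,) = _drop_missing(
                        f"{pv_label} {quantity} {channel} {phase}", tnc[quantity][:, pi, ci]
                    )
                    try:
                        res = one_sample_t(x)
                        t, p, d, label = res.t, res.p, res.d, res.label
                    except DegenerateTestError:
                        t, p, d, label = np.nan, np.nan, 0.0, "small"
                    row = dict(
                        mean_pre=x.mean(), sd_pre=x.std(ddof=1), mean_post=np.nan, sd_post=np.nan
                    )
                rows.append(
                    dict(
                        pv=pv_label,
                        channel=CHANNEL_LABELS.get(channel, channel),
                        quantity=quantity,
                        phase=phase,
                        **row,
                        t=t,
                        p=p,
                        d=d,
                        effect=label,
                    )
                )
    table = pd.DataFrame(rows)
    if adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        valid = table["p"].notna()
        adjusted = multipletests(table.loc[valid, "p"], method="holm")[1]
        table.loc[valid, "p_adjusted"] = adjusted
    elif adjust is not None:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    return table
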