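"""Permutation machinery and the five-dataset T/N/C decomposition."""

import itertools

import numpy as np
import pytest

from comvar.errors import ConfigurationError
from comvar.kinematics import ev_forward_lab
from comvar.tnc import (
    dataset_variability,
    exhaustive_permutations,
    permute_evs,
    shift_dataset,
    tnc_components,
    tnc_timecourse,
)

row_sum = lambda m: np.asarray(m).sum(axis=-1)  # noqa: E731  hand-enumerable toy PV


def oracle_cv(values):
    values = np.asarray(values, dtype=float)
    return 100.0 * values.std(ddof=1) / values.mean()


def oracle_tnc(D1, D5):
    """Exhaustive-permutation decomposition of a 3-cycle, 2-EV toy, by brute force."""
    perms = list(itertools.permutations(range(3)))
    delta = D5.mean(axis=0) - D1.mean(axis=0)

    def arrangements(M):
        out = []
        for p0 in perms:
            for p1 in perms:
                out.append(np.column_stack([M[list(p0), 0], M[list(p1), 1]]))
        return out

    V1 = oracle_cv(row_sum(D1))
    V5 = oracle_cv(row_sum(D5))
    d2s = arrangements(D1)
    d4s = arrangements(D5)
    V2 = np.mean([oracle_cv(row_sum(a)) for a in d2s])
    V3 = np.mean([oracle_cv(row_sum(a + delta)) for a in d2s])
    V4 = np.mean([oracle_cv(row_sum(a)) for a in d4s])
    return {"T": V3 - V2, "N": V4 - V3, "C": (V2 - V1) + (V5 - V4), "total": V5 - V1}


# --- permutation machinery ---------------------------------------------------


def test_permutation_preserves_marginals_exactly(rng):
    ev = rng.normal(size=(19, 7))
    ens = permute_evs(ev, 25, seed=3)
    assert ens.shape == (25, 19, 7)
    for rep in ens:
        np.testing.assert_array_equal(np.sort(rep, axis=0), np.sort(ev, axis=0))


def test_permutation_is_deterministic(rng):
    ev = rng.normal(size=(10, 4))
    a = permute_evs(ev, 50, seed=99)
    b = permute_evs(ev, 50, seed=99)
    np.testing.assert_array_equal(a, b)
    c = permute_evs(ev, 50, seed=100)
    assert not np.array_equal(a, c)


def test_single_column_matrix_invariant_under_permutation(rng):
    ev = rng.lognormal(0, 0.2, (12, 1))
    ens = permute_evs(ev, 40, seed=0)
    v_perm = dataset_variability(ens, row_sum, channel="value")
    assert v_perm == pytest.approx(dataset_variability(ev, row_sum, channel="value"), rel=1e-12)


def test_single_cycle_rejected():
    with pytest.raises(ConfigurationError):
        permute_evs(np.ones((1, 3)), 10, seed=0)


def test_exhaustive_enumeration_count(rng):
    ev = rng.normal(size=(3, 2))
    ens = exhaustive_permutations(ev)
    assert ens.shape == (36, 3, 2)
    unique = {tuple(rep.ravel()) for rep in ens}
    # identical multisets per column; each arrangement preserves marginals
    for rep in ens:
        np.testing.assert_array_equal(np.sort(rep, axis=0), np.sort(ev, axis=0))
    assert len(unique) <= 36


def test_shift_dataset_identity_and_inverse(rng):
    ens = permute_evs(rng.normal(2.0, 1.0, (8, 5)), 6, seed=1)
    means = ens.mean(axis=1)[0]
    same = shift_dataset(ens, means, means)
    np.testing.assert_array_equal(same, ens)
    target = np.arange(5, dtype=float)
    moved = shift_dataset(ens, ens[0].mean(axis=0), target)
    np.testing.assert_allclose(moved[0].mean(axis=0), target, atol=1e-12)
    back = shift_dataset(moved, target, ens[0].mean(axis=0))
    np.testing.assert_allclose(back, ens, atol=1e-12)
    with pytest.raises(ConfigurationError):
        shift_dataset(ens, means[:3], means[:3])


# --- dataset variability ------------------------------------------------------


def test_zero_dispersion_gives_zero_cv():
    ev = np.tile([1.0, 2.0, 3.0], (6, 1))
    assert dataset_variability(ev, row_sum, channel="value") == 0.0


def test_permutation_destroys_compensation():
    # perfectly negatively correlated columns: the row sum is constant
    D1 = np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]])
    v1 = dataset_variability(D1, row_sum, channel="value")
    v2 = dataset_variability(exhaustive_permutations(D1), row_sum, channel="value")
    assert v1 == 0.0
    assert v2 > 0.5


def test_independent_evs_unchanged_by_permutation(rng):
    ev = rng.lognormal(0.5, 0.15, (19, 5))
    v1 = dataset_variability(ev, row_sum, channel="value")
    v2 = dataset_variability(permute_evs(ev, 500, seed=7), row_sum, channel="value")
    assert v2 == pytest.approx(v1, rel=0.25)


# --- decomposition ------------------------------------------------------------


def test_null_components_exactly_zero_with_paired_permutations(rng):
    D1 = rng.normal(1.0, 0.1, (19, 6)) + 2.0
    res = tnc_components(D1, D1.copy(), row_sum, n_perm=50, seed=0, paired=True)
    assert np.all(res.T == 0.0)
    assert np.all(res.N == 0.0)
    assert np.all(res.C == 0.0)
    assert np.all(res.total == 0.0)


def test_independent_null_components_shrink_with_n_perm(rng):
    """|N| and |C| under the null fall as the permutation count grows."""
    magnitudes = {}
    for n_perm in (10, 100, 1000):
        acc = []
        for rep in range(15):
            D1 = rng.normal(3.0, 0.2, (19, 6))
            res = tnc_components(
                D1, D1.copy(), row_sum, n_perm=n_perm, seed=rep, paired=False
            )
            acc.append(abs(res.N[0]) + abs(res.C[0]))
        magnitudes[n_perm] = np.mean(acc)
    assert magnitudes[10] > magnitudes[100] > magnitudes[1000]


def test_additivity_is_exact(model, rng):
    forward = ev_forward_lab(model)
    for _ in range(60):
        D1 = rng.normal(0.0, 0.2, (5, 50))
        D5 = rng.normal(0.05, 0.25, (5, 50))
        res = tnc_components(D1, D5, forward, n_perm=8, seed=2, paired=rng.random() < 0.5)
        np.testing.assert_allclose(res.T + res.N + res.C, res.total, atol=1e-12)


def test_exhaustive_mode_matches_brute_force_oracle(rng):
    D1 = rng.lognormal(0.8, 0.2, (3, 2))
    D5 = rng.lognormal(0.9, 0.3, (3, 2))
    expected = oracle_tnc(D1, D5)
    res = tnc_components(D1, D5, row_sum, exhaustive=True)
    assert res.T[0] == pytest.approx(expected["T"], abs=1e-12)
    assert res.N[0] == pytest.approx(expected["N"], abs=1e-12)
    assert res.C[0] == pytest.approx(expected["C"], abs=1e-12)
    assert res.total[0] == pytest.approx(expected["total"], abs=1e-12)


def test_monte_carlo_converges_to_exhaustive(rng):
    D1 = rng.lognormal(0.8, 0.2, (3, 2))
    D5 = rng.lognormal(0.9, 0.3, (3, 2))
    exact = tnc_components(D1, D5, row_sum, exhaustive=True)
    err = {}
    for n_perm in (20, 20000):
        mc = tnc_components(D1, D5, row_sum, n_perm=n_perm, seed=5)
        err[n_perm] = max(
            abs(mc.T[0] - exact.T[0]), abs(mc.N[0] - exact.N[0]), abs(mc.C[0] - exact.C[0])
        )
    assert err[20000] < err[20]
    assert err[20000] < 0.05


def test_mismatched_layouts_rejected(rng):
    with pytest.raises(ConfigurationError):
        tnc_components(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)), row_sum, n_perm=5)


def test_timecourse_null_and_determinism(model, rng):
    forward = ev_forward_lab(model)
    pre = rng.normal(0.0, 0.15, (6, 100, 50))
    res = tnc_timecourse(pre, pre.copy(), forward, n_perm=10, seed=4)
    pm = res.phase_means()
    for comp in ("T", "N", "C", "total"):
        np.testing.assert_array_equal(pm[comp], 0.0)
    post = pre + rng.normal(0.0, 0.05, pre.shape)
    a = tnc_timecourse(pre, post, forward, n_perm=10, seed=4)
    b = tnc_timecourse(pre, post, forward, n_perm=10, seed=4)
    np.testing.assert_array_equal(a.T, b.T)
    np.testing.assert_array_equal(a.C, b.C)
    np.testing.assert_allclose(a.T + a.N + a.C, a.total, atol=1e-12)
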