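"""Score-based supremum permutation test."""

import numpy as np
import pytest
from dataclasses import replace

from cpcox.cptest import (TestConfig, _thresholded_pinv, permutation_test,
                          score_stat, sup_statistic, _candidates)
from cpcox.model import ChangePointCoxModel, FitConfig
from cpcox.simulate import SimConfig, sample_dataset


def _null_data(n=200, seed=7):
    cfg = replace(SimConfig(n=n, case_id=1, seed=seed, null_effects=True),
                  theta0=(-1.0, 0.0))
    return sample_dataset(cfg).drop_truth()


@pytest.fixture(scope="module")
def null_fit_and_q():
    d = _null_data()
    fit = ChangePointCoxModel(d, kind="linear-null").fit(FitConfig(seed=1))
    return d, fit.state.q_weight(d)


def test_statistic_zero_beyond_data_range(null_fit_and_q):
    d, q = null_fit_and_q
    f = (d.z[:, 0] < 1.0).astype(float)
    assert score_stat(d.x, q, d.e, d.e.max(), f) == 0.0


def test_statistic_nonnegative(null_fit_and_q):
    d, q = null_fit_and_q
    rng = np.random.default_rng(0)
    for _ in range(20):
        zeta = rng.uniform(d.e.min(), d.e.max())
        f = (d.z[:, rng.integers(0, d.r)] < rng.uniform(0, 2)).astype(float)
        assert score_stat(d.x, q, d.e, zeta, f) >= 0.0


def test_worked_example_matches_dense_algebra_oracle():
    """8-row dataset with hand-specified Q against explicit matrix algebra."""
    x = np.array([[1.0], [0.0], [1.0], [0.0], [1.0], [0.0], [1.0], [0.0]])
    q = np.array([0.5, -0.3, 0.8, -1.1, 0.2, 0.4, -0.6, 0.9])
    e = np.array([1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5])
    f = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])
    zeta = 2.2
    mask = e > zeta
    v = np.column_stack([x[:, 0], f])
    u = v[mask].T @ q[mask]
    sig = v[mask].T @ (v[mask] * (q[mask] ** 2)[:, None])
    vals, vecs = np.linalg.eigh(sig)
    keep = vals > 1e-8 * vals.max()
    oracle = float(((vecs.T @ u)[keep] ** 2 / vals[keep]).sum())
    assert score_stat(x, q, e, zeta, f) == pytest.approx(oracle, abs=1e-10)


def test_pinv_stability_under_tiny_perturbation():
    sig = np.array([[2.0, 0.3], [0.3, 0.5]])
    u = np.array([0.7, -0.4])
    s1 = u @ _thresholded_pinv(sig, 1e-8) @ u
    s2 = u @ _thresholded_pinv(sig + 1e-10 * np.eye(2), 1e-8) @ u
    assert abs(s1 - s2) < 1e-4


def test_sup_equals_nested_loop_oracle():
    d = _null_data(n=50, seed=3)
    fit = ChangePointCoxModel(d, kind="linear-null").fit(FitConfig(seed=0))
    q = fit.state.q_weight(d)
    cfg = TestConfig(k=4, n_z_candidates=5, seed=0)
    sup, arg = sup_statistic(d, q, cfg)
    zetas, cuts = _candidates(d, cfg)
    best, best_arg = -np.inf, None
    for zeta in zetas:
        for j in range(d.r):
            for c in range(cuts.shape[0]):
                f = (d.z[:, j] < cuts[c, j]).astype(float)
                s = score_stat(d.x, q, d.e, float(zeta), f, cfg.pinv_tol)
                if s > best + 1e-12:
                    best, best_arg = s, (float(zeta), j + 1, float(cuts[c, j]))
    assert sup == pytest.approx(best, abs=1e-9)
    assert arg == best_arg


def test_single_candidate_degenerate_sup(null_fit_and_q):
    d, q = null_fit_and_q
    cfg = TestConfig(k=1, n_z_candidates=1, zeta_quantile_range=(0.5, 0.5))
    sup, arg = sup_statistic(d, q, cfg)
    zeta = np.quantile(d.e, 0.5)
    fs = [(d.z[:, j] < np.quantile(d.z[:, j], 0.5)).astype(float)
          for j in range(d.r)]
    direct = max(score_stat(d.x, q, d.e, zeta, f, cfg.pinv_tol) for f in fs)
    assert sup == pytest.approx(direct, abs=1e-9)


def test_sup_monotone_in_candidate_set(null_fit_and_q):
    """Nested cut-off grids: the sup over a superset is never smaller."""
    d, q = null_fit_and_q
    s1, _ = sup_statistic(d, q, TestConfig(k=3, n_z_candidates=1))
    s3, _ = sup_statistic(d, q, TestConfig(k=3, n_z_candidates=3))
    # levels {1/2} subset of {1/4, 1/2, 3/4}
    assert s3 >= s1 - 1e-12


def test_permutation_pvalue_support_and_determinism():
    d = _null_data(n=150, seed=11)
    cfg = TestConfig(k=3, B=19, seed=5, null_kind="linear-null")
    r1 = permutation_test(d, cfg, FitConfig(seed=5))
    r2 = permutation_test(d, cfg, FitConfig(seed=5))
    assert r1.p_value == r2.p_value
    assert 0 < r1.p_value <= 1
    k = round(r1.p_value * 20)
    assert r1.p_value == pytest.approx(k / 20)
    assert len(r1.perm_stats) == 19
    # add-one convention
    expected = (1 + np.sum(r1.perm_stats >= r1.statistic)) / 20
    assert r1.p_value == pytest.approx(expected)


def test_pvalue_floor_and_ceiling():
    d = _null_data(n=120, seed=13)
    fit = ChangePointCoxModel(d, kind="linear-null").fit(FitConfig(seed=0))
    q = fit.state.q_weight(d)
    cfg = TestConfig(k=2, B=9, seed=0)
    obs, _ = sup_statistic(d, q, cfg)
    perm = np.full(9, obs - 1.0)
    assert (1 + np.sum(perm >= obs)) / 10 == pytest.approx(0.1)
    perm = np.full(9, obs + 1.0)
    assert (1 + np.sum(perm >= obs)) / 10 == pytest.approx(1.0)


def test_detects_planted_change_point():
    """Strong threshold effect: small p-value at modest B."""
    d = sample_dataset(SimConfig(n=400, case_id=1, seed=19)).drop_truth()
    res = permutation_test(d, TestConfig(k=5, B=39, seed=3,
                                         null_kind="linear-null"),
                           FitConfig(seed=3))
    assert res.p_value <= 0.1
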