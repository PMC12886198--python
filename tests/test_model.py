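"""Profiling estimation loop: initialization, block steps, convergence."""

import numpy as np
import pytest
from dataclasses import replace

from cpcox.datasets import CurrentStatusData
from cpcox.likelihood import hazard_value, loglik_from_h
from cpcox.model import (ChangePointCoxModel, FitConfig, LinearEffects,
                         profile_zeta)
from cpcox.network import NetConfig
from cpcox.simulate import SimConfig, sample_dataset


def test_initial_state_contract(small_dataset):
    model = ChangePointCoxModel(small_dataset, kind="deep-cp")
    st = model._initial_state(FitConfig())
    assert np.all(st.beta == 0) and np.all(st.gamma == 0)
    # mean(e), snapped to the nearest grid point
    assert st.zeta == pytest.approx(small_dataset.e.mean(), abs=0.005)
    assert st.zeta / 0.01 == pytest.approx(round(st.zeta / 0.01), abs=1e-9)
    assert np.all(st.hazard.coeffs == 0.1)
    assert st.hazard.dim == len(st.hazard.interior_knots) + 4


def test_unknown_kind_rejected(small_dataset):
    with pytest.raises(ValueError, match="kind"):
        ChangePointCoxModel(small_dataset, kind="magic")


def test_theta_update_is_ascent_and_stationary(small_dataset):
    model = ChangePointCoxModel(small_dataset, kind="deep-cp")
    st = model._initial_state(FitConfig(seed=1))
    ll0 = st.loglik(small_dataset)
    model._update_theta(st)
    ll1 = st.loglik(small_dataset)
    assert ll1 >= ll0 - 1e-8
    # at the new optimum the analytic score vanishes; a second call is a no-op
    beta1, gamma1 = st.beta.copy(), st.gamma.copy()
    assert np.max(np.abs(st.theta_score(small_dataset))) < 1e-5
    model._update_theta(st)
    assert np.allclose(st.beta, beta1, atol=1e-5)
    assert np.allclose(st.gamma, gamma1, atol=1e-5)


def test_theta_update_matches_dense_grid_oracle():
    """1-D treatment toy: (beta, gamma) against a 2-D grid search."""
    d = sample_dataset(SimConfig(n=800, case_id=1, seed=13))
    model = ChangePointCoxModel(d, kind="deep-cp")
    st = model._initial_state(FitConfig(seed=0))
    from cpcox.splines import build_knots
    model._update_theta(st)
    b_hat, g_hat = st.beta[0], st.gamma[0]

    lam_u = st.hazard(d.u)
    g, h = st.effects.predict(d.z)
    jump = st.jump(d.e)
    base = g + h * jump

    def ll(b, c):
        lp = d.x[:, 0] * b + base + d.x[:, 0] * c * jump
        return loglik_from_h(d.delta, hazard_value(lam_u, lp))

    bs = np.linspace(b_hat - 0.05, b_hat + 0.05, 51)
    cs = np.linspace(g_hat - 0.05, g_hat + 0.05, 51)
    vals = np.array([[ll(b, c) for c in cs] for b in bs])
    i, j = np.unravel_index(np.argmax(vals), vals.shape)
    assert abs(bs[i] - b_hat) <= 2e-3 + 1e-9
    assert abs(cs[j] - g_hat) <= 2e-3 + 1e-9


class _ConstHazard:
    def __call__(self, t):
        return np.full(len(np.atleast_1d(t)), 0.4)


def test_profile_zeta_flat_returns_smallest_grid_point(small_dataset):
    d = small_dataset
    grid = np.arange(1.6, 2.4, 0.01)
    z = profile_zeta(d, _ConstHazard()(d.u), np.array([0.3]), np.zeros(1),
                     np.zeros(d.n), np.zeros(d.n), grid, current_zeta=2.0)
    assert z == pytest.approx(grid[0])


def test_profile_zeta_matches_exhaustive_oracle():
    d = sample_dataset(SimConfig(n=500, case_id=1, seed=17))
    rng = np.random.default_rng(0)
    grid = np.arange(1.55, 2.45, 0.01)
    lam_u = np.sqrt(d.u) / 5
    beta, gamma = np.array([-1.0]), np.array([2.0])
    g = d.g_true
    h = d.h_true
    z = profile_zeta(d, lam_u, beta, gamma, g, h, grid, current_zeta=2.0)
    # brute force over the same grid
    best, best_z = -np.inf, None
    for zc in grid:
        jump = (d.e > zc).astype(float)
        lp = d.x @ beta + g + (d.x @ gamma + h) * jump
        ll = loglik_from_h(d.delta, hazard_value(lam_u, lp))
        if ll > best:
            best, best_z = ll, zc
    assert z == best_z
    assert d.e.min() < z < d.e.max()


def test_fit_stops_on_theta_stabilization(small_dataset):
    res = ChangePointCoxModel(small_dataset, kind="linear-cp").fit(
        FitConfig(seed=0, max_outer=30))
    assert res.converged
    assert np.max(np.abs(res.theta_path[-1] - res.theta_path[-2])) < 1e-3
    assert res.n_iter < 30


def test_block_ascent_along_the_path(small_dataset):
    for kind in ("deep-cp", "linear-cp", "deep-null", "linear-null"):
        res = ChangePointCoxModel(small_dataset, kind=kind).fit(
            FitConfig(seed=2, max_outer=6,
                      net=NetConfig(epochs=60, seed=2)))
        assert np.all(np.diff(res.loglik_path) >= -1e-6)
        assert np.all(res.state.hazard.coeffs >= 0)
        grid = np.linspace(*res.state.hazard.boundary, 200)
        assert np.all(np.diff(res.state.hazard(grid)) >= -1e-10)


def test_zeta_estimate_lies_on_gap_grid_and_in_range(small_dataset):
    res = ChangePointCoxModel(small_dataset, kind="deep-cp").fit(
        FitConfig(seed=3, max_outer=4, net=NetConfig(epochs=40, seed=3)))
    k = res.zeta / 0.01
    assert abs(k - round(k)) < 1e-9
    assert small_dataset.e.min() < res.zeta < small_dataset.e.max()


def test_null_fit_invariant_to_permuting_e(small_dataset):
    d = small_dataset
    cfg = FitConfig(seed=5, max_outer=4, net=NetConfig(epochs=40, seed=5))
    res1 = ChangePointCoxModel(d, kind="deep-null").fit(cfg)
    perm = np.random.default_rng(9).permutation(d.n)
    d2 = CurrentStatusData(d.delta, d.u, d.x, d.z, np.asarray(d.e)[perm])
    res2 = ChangePointCoxModel(d2, kind="deep-null").fit(cfg)
    assert np.allclose(res1.beta, res2.beta)
    assert res1.loglike == pytest.approx(res2.loglike, rel=1e-12)
    assert np.all(res1.gamma == 0)
    g1, h1 = res1.predict_effects(d.z[:5])
    assert np.all(h1 == 0)


def test_linear_cp_recovers_case1_parameters():
    d = sample_dataset(SimConfig(n=1000, case_id=1, seed=101))
    res = ChangePointCoxModel(d, kind="linear-cp").fit(FitConfig(seed=1))
    assert abs(res.beta[0] + 1.0) < 0.6
    assert abs(res.gamma[0] - 2.0) < 0.8
    assert abs(res.zeta - 2.0) < 0.15


def test_deep_cp_recovers_case1_parameters():
    d = sample_dataset(SimConfig(n=1000, case_id=1, seed=102))
    res = ChangePointCoxModel(d, kind="deep-cp").fit(FitConfig(seed=1))
    assert abs(res.beta[0] + 1.0) < 0.6
    assert abs(res.gamma[0] - 2.0) < 0.8
    assert abs(res.zeta - 2.0) < 0.15


def test_summary_renders(small_dataset):
    res = ChangePointCoxModel(small_dataset, kind="linear-cp").fit(
        FitConfig(seed=0))
    text = res.summary()
    assert "beta_1" in text and "gamma_1" in text and "zeta" in text
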