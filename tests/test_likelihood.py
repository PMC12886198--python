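"""Log-likelihood, hazard-scale quantity and score weight."""

import numpy as np
import pytest

from cpcox.datasets import CurrentStatusData
from cpcox.likelihood import (ModelState, hazard_value, log1mexp,
                              loglik_from_h, q_from_h)
from cpcox.model import ChangePointCoxModel, FitConfig
from cpcox.simulate import SimConfig, sample_dataset, truth_functions
from cpcox.splines import build_knots


class _FnHazard:
    degree = 3

    def __init__(self, fn):
        self.fn = fn

    def __call__(self, t):
        return self.fn(np.asarray(t, dtype=float))


class _FnEffects:
    def __init__(self, g, h):
        self.g, self.h = g, h

    def predict(self, z):
        z = np.atleast_2d(z)
        return self.g(z), self.h(z)


def _const_effects(gv, hv):
    return _FnEffects(lambda z: np.full(len(z), gv),
                      lambda z: np.full(len(z), hv))


def _toy_data(n=6, seed=0):
    rng = np.random.default_rng(seed)
    return CurrentStatusData(rng.binomial(1, 0.5, n), rng.uniform(0.5, 3, n),
                             rng.binomial(1, 0.5, (n, 1)),
                             rng.uniform(0, 2, (n, 2)), rng.uniform(1, 3, n))


def test_log1mexp_branches_agree():
    x = np.array([1e-8, 0.1, np.log(2) - 1e-9, np.log(2) + 1e-9, 5.0, 60.0])
    ref = np.log1p(-np.exp(-x.astype(np.longdouble))).astype(float)
    assert np.allclose(log1mexp(x), ref, rtol=1e-12)


def test_unit_hazard_state():
    d = _toy_data()
    st = ModelState(hazard=_FnHazard(lambda t: np.ones_like(t)),
                    beta=np.zeros(1), gamma=np.zeros(1),
                    effects=_const_effects(0.0, 0.0), zeta=2.0)
    assert np.allclose(st.h_eta(d), 1.0)


def test_h_eta_ignores_threshold_without_jump_effects():
    d = _toy_data(n=40, seed=2)
    for zeta in (1.2, 2.8):
        st = ModelState(hazard=_FnHazard(lambda t: t), beta=np.array([0.7]),
                        gamma=np.zeros(1), effects=_const_effects(-0.2, 0.0),
                        zeta=zeta)
        if zeta == 1.2:
            ref = st.h_eta(d)
        else:
            assert np.allclose(st.h_eta(d), ref)


def test_h_eta_hand_row():
    """Lambda(U)=0.5, beta'x=1, g=-0.2, gamma'x=0.3, h=0.1, e > zeta."""
    d = CurrentStatusData([1], [1.0], [[1.0]], [[0.0, 0.0]], [5.0])
    st = ModelState(hazard=_FnHazard(lambda t: np.full_like(t, 0.5)),
                    beta=np.array([1.0]), gamma=np.array([0.3]),
                    effects=_const_effects(-0.2, 0.1), zeta=2.0)
    assert st.h_eta(d)[0] == pytest.approx(0.5 * np.exp(1.2), rel=1e-12)
    assert st.h_eta(d)[0] == pytest.approx(1.66006, abs=5e-6)


def test_strict_threshold_convention():
    d = CurrentStatusData([1, 1], [1.0, 1.0], [[0.0], [0.0]],
                          [[0, 0], [0, 0]], [2.0, 2.0 + 1e-12])
    st = ModelState(hazard=_FnHazard(lambda t: np.ones_like(t)),
                    beta=np.zeros(1), gamma=np.zeros(1),
                    effects=_const_effects(0.0, 1.0), zeta=2.0)
    h = st.h_eta(d)
    assert h[0] == pytest.approx(1.0)          # e == zeta: no jump
    assert h[1] == pytest.approx(np.e)         # e > zeta: jump


def test_loglik_closed_forms():
    assert loglik_from_h([0], [0.0]) == 0.0
    assert loglik_from_h([1], [1.0]) == pytest.approx(np.log(1 - np.exp(-1)))
    assert loglik_from_h([1], [1.0]) == pytest.approx(-0.458675, abs=1e-6)


def test_q_weight_closed_forms():
    assert q_from_h([0], [2.0])[0] == pytest.approx(-2.0)
    assert q_from_h([1], [1.0])[0] == pytest.approx(
        np.exp(-1) / (1 - np.exp(-1)))
    assert q_from_h([1], [1.0])[0] == pytest.approx(0.581977, abs=1e-6)
    assert q_from_h([1], [500.0])[0] == pytest.approx(0.0, abs=1e-200)


def test_q_sign_structure():
    rng = np.random.default_rng(0)
    h = rng.uniform(0.01, 5, 50)
    assert np.all(q_from_h(np.ones(50), h) > 0)
    assert np.allclose(q_from_h(np.zeros(50), h), -h)


def _random_state(d, seed):
    rng = np.random.default_rng(seed)
    haz = build_knots(d.u, 2).with_coeffs(rng.uniform(0.05, 0.5, 6))
    b0, b1 = rng.normal(0, 0.4, 2)
    g0, g1 = rng.normal(0, 0.3, 2)
    eff = _FnEffects(lambda z: 0.3 * z[:, 0] - 0.2 * z[:, 1],
                     lambda z: 0.1 * z[:, 0] + 0.2)
    return ModelState(hazard=haz, beta=np.array([b0]), gamma=np.array([g1]),
                      effects=eff, zeta=float(np.median(d.e)))


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_analytic_theta_score_matches_finite_differences(seed):
    d = _toy_data(n=60, seed=seed)
    st = _random_state(d, seed + 10)
    score = st.theta_score(d)
    eps = 1e-6
    for k in range(2):
        def ll(delta_k):
            st2 = ModelState(hazard=st.hazard,
                             beta=st.beta + (delta_k if k == 0 else 0),
                             gamma=st.gamma + (delta_k if k == 1 else 0),
                             effects=st.effects, zeta=st.zeta)
            return st2.loglik(d)
        fd = (ll(eps) - ll(-eps)) / (2 * eps)
        assert score[k] == pytest.approx(fd, abs=1e-6)


def test_score_mean_zero_at_generating_state():
    cfg = SimConfig(n=100_000, case_id=1, seed=8)
    d = sample_dataset(cfg)
    g0, h0 = truth_functions(1, centered=True)
    st = ModelState(hazard=_FnHazard(lambda t: np.sqrt(t) / 5),
                    beta=np.array(cfg.beta0), gamma=np.array(cfg.gamma0),
                    effects=_FnEffects(g0, h0), zeta=cfg.zeta0)
    score = st.theta_score(d)
    q = st.q_weight(d)
    mc = 3 * np.std(st.xtilde(d) * q[:, None], axis=0) / np.sqrt(d.n)
    assert np.all(np.abs(score) < mc)


def test_loglik_invariant_to_row_permutation():
    d = _toy_data(n=50, seed=4)
    st = _random_state(d, 3)
    perm = np.random.default_rng(1).permutation(d.n)
    assert st.loglik(d) == pytest.approx(st.loglik(d.subset(perm)), rel=1e-12)
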