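"""Model ingredients: stem-cell rates, maturation rate, scenarios, derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sddestab as sd
from sddestab.rates import (DProfile, MaturationParams, Profile, StemCellParams,
                            eval_d, eval_g, eval_gamma, eval_q, rate_derivatives,
                            scenario)


def make_stem(**kw):
    base = dict(mu=1.0, mu_w=1.0, a=0.9, p=2.0, k_a=0.0, k_p=0.0)
    base.update(kw)
    return StemCellParams(**base)


class TestStemCellRates:
    @pytest.mark.parametrize("v, kw, expected", [
        (0.0, {}, (2 * 0.9 - 1) * 2.0 - 1.0),            # 0.6
        (0.3, {"p": 0.0}, -1.0),                          # q = -mu_w when p = 0
        (0.6, {"k_p": 1.0}, 0.0),                         # root of q for (s)_d
    ])
    def test_net_growth_rate_values(self, v, kw, expected):
        assert eval_q(v, make_stem(**kw)) == pytest.approx(expected, abs=1e-14)

    def test_net_growth_root_matches_bisection_oracle(self):
        # q(v) = (2a-1) p / (1+v) - mu_w for k_a=0, k_p=1: bisect for the root
        params = make_stem(k_p=1.0)
        lo, hi = 0.0, 10.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (2 * 0.9 - 1) * 2.0 / (1 + mid) - 1.0 > 0:
                lo = mid
            else:
                hi = mid
        assert eval_q(0.5 * (lo + hi), params) == pytest.approx(0.0, abs=1e-12)
        assert 0.5 * (lo + hi) == pytest.approx(0.6, abs=1e-10)

    @pytest.mark.parametrize("v, kw, expected", [
        (0.0, {}, 0.4),                                   # 2 (1-0.9) 2
        (0.5, {"p": 0.0}, 0.0),
        (0.6, {"k_p": 1.0}, 0.25),                        # 2 * 0.1 * 2 / 1.6
    ])
    def test_progenitor_inflow_values(self, v, kw, expected):
        assert eval_gamma(v, make_stem(**kw)) == pytest.approx(expected, abs=1e-14)

    def test_negative_mature_amount_rejected(self):
        with pytest.raises(ValueError):
            eval_q(-0.5, make_stem())

    def test_self_renewal_fraction_must_exceed_half(self):
        with pytest.raises(ValueError):
            make_stem(a=0.4)

    def test_rates_monotone_nonincreasing_in_v(self):
        params = make_stem(k_a=1.0, k_p=0.5)
        v = np.linspace(0.0, 20.0, 200)
        for f in (params.s, params.d_w):
            vals = f(v)
            assert np.all(np.diff(vals) <= 1e-14)
        assert params.s(v).max() <= params.a
        assert params.d_w(v).max() <= params.p
        # q is monotone under the single-regulation modes of the study
        for kw in ({"k_a": 1.0}, {"k_p": 1.0}):
            q = make_stem(**kw).q(v)
            assert np.all(np.diff(q) <= 1e-14)

    @given(st.floats(0.51, 0.99), st.floats(0.1, 5.0), st.floats(0.01, 3.0),
           st.booleans())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_q_decreases_to_negative_value(self, a, p, k, regulate_division):
        # a single regulated process pushes q monotonically below zero
        kw = {"k_p": k} if regulate_division else {"k_a": k}
        params = make_stem(a=a, p=p, **kw)
        v = np.geomspace(1e-3, 1e5, 100)
        q = params.q(v)
        assert np.all(np.diff(q) <= 1e-12)
        assert q[-1] < 0


class TestMaturationRate:
    def test_constant_component_value(self):
        mat = MaturationParams(g0=0.0, a_u=Profile.constant(1 / 3),
                               p_u=Profile.constant(0.3))
        for x, v in [(0.0, 0.0), (0.5, 2.0), (1.0, 7.3)]:
            assert eval_g(x, v, mat) == pytest.approx(0.4, abs=1e-14)

    def test_baseline_only(self):
        mat = MaturationParams(g0=1.0, p_u=Profile.constant(0.0))
        assert eval_g(0.3, 1.2, mat) == pytest.approx(1.0)

    def test_large_v_limit_is_baseline_when_k1_positive(self):
        mat = MaturationParams(g0=0.7, k1=1.0, a_u=Profile.constant(0.5),
                               p_u=Profile.constant(1.0))
        assert eval_g(0.5, 1e9, mat) == pytest.approx(0.7, rel=1e-6)

    def test_nonpositive_rate_rejected_at_construction(self):
        with pytest.raises(ValueError):
            MaturationParams(g0=0.0, a_u=Profile.constant(2.0),
                             p_u=Profile.constant(1.0))

    def test_default_net_production_is_zero_with_zero_derivatives(self):
        cfg = scenario("(s)_d,(pv)_0")
        assert eval_d(0.3, 1.0, cfg) == 0.0
        assert cfg.d.deriv_x(0.3, 1.0) == 0.0
        assert cfg.d.deriv_v(0.3, 1.0) == 0.0
        const = DProfile.constant(0.25)
        assert const(0.9, 3.0) == pytest.approx(0.25)


class TestScenarios:
    def test_division_regulated_fixed_delay_set(self):
        cfg = scenario("(s)_d,(pv)_0")
        assert (cfg.stem.k_a, cfg.stem.k_p) == (0.0, 1.0)
        assert (cfg.mat.k1, cfg.mat.k2) == (0.0, 0.0)
        assert (cfg.stem.mu_w, cfg.stem.a) == (1.0, 0.9)
        assert (cfg.mat.x1, cfg.mat.x2) == (0.0, 1.0)

    def test_self_renewal_regulated_with_increasing_maturation(self):
        cfg = scenario("(s)_s,(pv)_2")
        assert (cfg.stem.k_a, cfg.stem.k_p) == (1.0, 0.0)
        assert (cfg.mat.k1, cfg.mat.k2) == (0.0, 1.0)

    def test_quadratic_maturity_profile(self):
        cfg = scenario("(px)_1,quadratic")
        xs = np.linspace(0.0, 1.0, 11)
        np.testing.assert_allclose(cfg.mat.a_u(xs), 0.1 + 2.8 * (xs - 0.5) ** 2,
                                   atol=1e-14)
        assert cfg.mat.p_u(0.7) == pytest.approx(0.3)

    def test_px2_profiles(self):
        for shape, fun in [("constant", lambda x: 0.9 + 0 * x),
                           ("linear", lambda x: 0.99 - 0.18 * x),
                           ("quadratic", lambda x: 0.855 - 0.54 * (x - 0.5) ** 2)]:
            cfg = scenario(f"(px)_2,{shape}", p=2.0)
            xs = np.linspace(0, 1, 7)
            np.testing.assert_allclose(cfg.mat.a_u(xs), fun(xs), atol=1e-14)
            assert cfg.mat.p_u(0.5) == pytest.approx(2.0)

    def test_unknown_label_raises(self):
        with pytest.raises(KeyError):
            scenario("(s)_d,(pv)_9")

    def test_tau_fixes_constant_rate(self):
        cfg = scenario("(s)_d,(pv)_0", tau=2.5)
        assert cfg.mat.g(0.5, 3.0) == pytest.approx(0.4)

    def test_profile_tracking_follows_division_rate(self):
        cfg = scenario("(s)_d,(pv)_1", p=2.0)
        cfg2 = cfg.with_(p=7.0)
        assert cfg2.mat.p_u(0.3) == pytest.approx(7.0)
        assert cfg2.stem.p == 7.0


class TestDerivatives:
    def test_closed_forms_match_finite_differences(self, rng):
        labels = ["(s)_d,(pv)_1", "(s)_s,(pv)_2", "(s)_d,(pv)_2,(px)_1,quadratic",
                  "(s)_s,(pv)_1,(px)_2,linear"]
        step = 1e-6
        for _ in range(25):
            lab = labels[rng.integers(len(labels))]
            cfg = scenario(lab, mu=float(rng.uniform(0.2, 3)),
                           p=float(rng.uniform(1.5, 4)))
            der = rate_derivatives(cfg)
            v = float(rng.uniform(0.05, 3.0))
            x = float(rng.uniform(0.1, 0.9))
            stem, mat = cfg.stem, cfg.mat
            checks = [
                (der.q_prime(v), (stem.q(v + step) - stem.q(v - step)) / (2 * step)),
                (der.gamma_prime(v), (stem.gamma(v + step) - stem.gamma(v - step)) / (2 * step)),
                (der.D1g(x, v), (mat.g(x + step, v) - mat.g(x - step, v)) / (2 * step)),
                (der.D2g(x, v), (mat.g(x, v + step) - mat.g(x, v - step)) / (2 * step)),
                (der.D1D1g(x, v), (mat.D1g(x + step, v) - mat.D1g(x - step, v)) / (2 * step)),
                (der.D2D1g(x, v), (mat.D1g(x, v + step) - mat.D1g(x, v - step)) / (2 * step)),
            ]
            for exact, fd in checks:
                assert exact == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_q_prime_closed_form_for_regulated_division(self):
        stem = make_stem(k_p=1.0)
        v = 0.7
        assert stem.q_prime(v) == pytest.approx(-(2 * 0.9 - 1) * 2.0 / (1 + v) ** 2)

    def test_gamma_prime_at_zero_for_regulated_self_renewal(self):
        stem = make_stem(k_a=1.0)
        assert stem.gamma_prime(0.0) == pytest.approx(2 * 0.9 * 2.0)

    def test_maturity_derivative_vanishes_for_constant_profiles(self):
        cfg = scenario("(s)_d,(pv)_1")
        assert cfg.mat.D1g(0.4, 1.0) == 0.0
        assert cfg.mat.is_x_independent
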