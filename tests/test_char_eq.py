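"""Characteristic functions, kernel, simplified cascade, and root localisation."""

import cmath

import numpy as np
import pytest
from scipy.integrate import quad

import sddestab as sd
from sddestab import char_eq
from sddestab.char_eq import (build_context, chi, chi_simplified, chi_trivial,
                              find_roots, kernel_k)


def newton_root(f, z0, maxit=80):
    z = complex(z0)
    for _ in range(maxit):
        h = 1e-7 * (1 + abs(z))
        df = (f(z + h) - f(z - h)) / (2 * h)
        dz = f(z) / df
        z -= dz
        if abs(dz) < 1e-13 * (1 + abs(z)):
            break
    return z


class TestTrivialCharacteristic:
    def test_factorised_roots(self, fixed_delay_cfg):
        q0 = fixed_delay_cfg.stem.q(0.0)
        assert chi_trivial(q0, fixed_delay_cfg) == 0
        assert chi_trivial(-1.0, fixed_delay_cfg) == 0
        assert chi_trivial(0.0, fixed_delay_cfg) == pytest.approx(-q0 * 1.0)

    def test_root_localisation_finds_exactly_both(self, fixed_delay_cfg):
        roots = find_roots(lambda z: chi_trivial(z, fixed_delay_cfg),
                           {"re_lo": -2.0, "re_hi": 1.5, "im_hi": 1.0})
        got = sorted(r.z.real for r in roots)
        assert len(roots) == 2
        assert got[0] == pytest.approx(-1.0, abs=1e-10)
        assert got[1] == pytest.approx(fixed_delay_cfg.stem.q(0.0), abs=1e-10)


class TestKernel:
    def test_kernel_vanishes_without_production_and_maturity_dependence(
            self, fixed_delay_cfg, fixed_delay_eq):
        ctx = build_context(fixed_delay_cfg, fixed_delay_eq)
        assert ctx.kernel_zero
        for t in np.linspace(0, ctx.tau_v, 5):
            assert kernel_k(float(t), ctx) == 0.0

    def test_kernel_cancels_for_separable_rate(self):
        # g(x, v) = G(x) A(v) with d == 0: the three kernel terms cancel exactly
        cfg = sd.scenario("(s)_d,(pv)_1,(px)_1,quadratic", mu=0.8, p=2.0)
        eq = sd.positive_equilibrium(cfg)
        ctx = build_context(cfg, eq)
        assert not ctx.kernel_zero
        for t in np.linspace(0.05, 0.95, 5) * ctx.tau_v:
            assert abs(kernel_k(float(t), ctx)) < 1e-9

    def test_kernel_matches_independent_quadrature_oracle(self, px_cfg):
        eq = sd.positive_equilibrium(px_cfg)
        ctx = build_context(px_cfg, eq)
        mat, d, stem, v = px_cfg.mat, px_cfg.d, px_cfg.stem, eq.v
        y, tauv = ctx.y_of_t, ctx.tau_v

        def I(a, b):  # int_a^b D1g(y(theta), v) dtheta, adaptive Gauss-Kronrod
            return quad(lambda th: mat.D1g(float(y(th)), v), a, b,
                        epsabs=1e-13, epsrel=1e-13, limit=200)[0]

        for t in (0.25 * tauv, 0.5 * tauv, 0.8 * tauv):
            yt = float(y(t))
            term1 = d.deriv_v(yt, v) - mat.D2D1g(yt, v)
            term2 = -((d(mat.x1, v) - mat.D1g(mat.x1, v)) / mat.g(mat.x1, v)) \
                * np.exp(-I(t, tauv)) * mat.D2g(yt, v)
            inner = quad(lambda s: (d.deriv_x(float(y(s)), v)
                                    - mat.D1D1g(float(y(s)), v)) * np.exp(-I(t, s)),
                         t, tauv, epsabs=1e-13, epsrel=1e-13, limit=200)[0]
            oracle = stem.mu * v * (term1 + term2 - mat.D2g(yt, v) * inner)
            assert kernel_k(t, ctx) == pytest.approx(oracle, rel=1e-7)

    def test_kernel_domain_error(self, px_cfg):
        ctx = build_context(px_cfg)
        with pytest.raises(ValueError):
            kernel_k(ctx.tau_v + 0.5, ctx)


class TestChi:
    def test_value_at_origin(self, px_cfg):
        eq = sd.positive_equilibrium(px_cfg)
        ctx = build_context(px_cfg, eq)
        expected = px_cfg.stem.mu * eq.v * px_cfg.stem.q_prime(eq.v)
        assert complex(chi(0.0 + 0.0j, ctx)) == pytest.approx(expected, rel=1e-10)

    def test_general_form_reduces_to_fixed_delay_closed_form(self, fixed_delay_cfg,
                                                             fixed_delay_eq, rng):
        # up to the overall sign convention of the printed fixed-delay form
        ctx = build_context(fixed_delay_cfg, fixed_delay_eq)
        for _ in range(20):
            z = complex(rng.uniform(-2, 2), rng.uniform(-5, 5))
            full = chi(z, ctx)
            fixed = chi_simplified(z, fixed_delay_cfg, "e", eq=fixed_delay_eq)
            assert abs(full + fixed) < 1e-10 * max(1.0, abs(fixed))

    def test_conjugate_symmetry(self, px_cfg):
        ctx = build_context(px_cfg)
        for z in (0.3 + 1.7j, -1.1 + 0.4j, 2.0 - 3.0j):
            assert chi(np.conj(z), ctx) == pytest.approx(np.conj(chi(z, ctx)),
                                                         rel=1e-12)

    def test_matches_pseudospectral_eigenvalues_kernel_active(self, px_cfg):
        # two fully independent routes to the characteristic roots
        from sddestab.pseudospectral import jacobian_eigenvalues
        eq = sd.positive_equilibrium(px_cfg)
        ctx = build_context(px_cfg, eq)
        eigs = jacobian_eigenvalues(px_cfg, eq, M=20)
        for lam in eigs[:3]:
            root = newton_root(lambda z: chi(z, ctx), lam)
            assert abs(root - lam) < 1e-6


class TestSimplifiedCascade:
    def test_case_e_coefficient(self, fixed_delay_cfg, fixed_delay_eq):
        # 1 - mu_w / ((2a-1) p) with the study parameters
        val = chi_simplified(0.0 + 0j, fixed_delay_cfg, "e", eq=fixed_delay_eq)
        coef = 1.0 - 1.0 / ((2 * 0.9 - 1) * 2.0)
        assert coef == pytest.approx(0.375)
        assert complex(val) == pytest.approx(coef * 1.0 * 1.0)  # coef*mu*mu_w at z=0

    def test_case_b_at_origin(self, fixed_delay_cfg, fixed_delay_eq):
        stem, v = fixed_delay_cfg.stem, fixed_delay_eq.v
        val = chi_simplified(0.0 + 0j, fixed_delay_cfg, "b", eq=fixed_delay_eq)
        assert complex(val) == pytest.approx(stem.mu * v * stem.q_prime(v), rel=1e-12)

    def test_cascade_chain_consistency(self, fixed_delay_cfg, fixed_delay_eq, rng):
        # with the built-in division rate, case d equals minus case e exactly
        for _ in range(10):
            z = complex(rng.uniform(-2, 2), rng.uniform(-4, 4))
            d_val = chi_simplified(z, fixed_delay_cfg, "d", eq=fixed_delay_eq)
            e_val = chi_simplified(z, fixed_delay_cfg, "e", eq=fixed_delay_eq)
            assert abs(d_val + e_val) < 1e-12 * max(1.0, abs(e_val))
            c_val = chi_simplified(z, fixed_delay_cfg, "c", eq=fixed_delay_eq)
            assert abs(c_val - d_val) < 1e-12 * max(1.0, abs(d_val))

    def test_case_hypotheses_enforced(self, px_cfg):
        with pytest.raises(ValueError):
            chi_simplified(0j, px_cfg, "b")


class TestRootLocalisation:
    def test_single_negative_root_near_emergence(self):
        # just above the transcritical point the unique root is real, negative,
        # with slope q'(0) in the equilibrium amount
        cfg = sd.scenario("(s)_d,(pv)_0", p=1.30, tau=1.5)
        eq = sd.positive_equilibrium(cfg)
        ctx = build_context(cfg, eq)
        roots = find_roots(ctx, {"re_lo": -0.5, "re_hi": 0.4, "im_hi": 0.5})
        assert len(roots) == 1
        z = roots[0].z
        assert abs(z.imag) < 1e-10 and z.real < 0
        qp0 = cfg.stem.q_prime(0.0)
        assert z.real / eq.v == pytest.approx(qp0, rel=0.2)

    def test_imaginary_pair_on_analytic_boundary(self):
        from sddestab import analytic_boundary as ab
        eta = tau = 1.5
        lo, hi = ab.parametrisation_interval(eta)
        omega = lo + 0.78 * (hi - lo)
        m, r = ab.boundary_point(omega, eta)
        mu, p = ab.to_mu_p((m, r), tau, 1.0, 0.9)
        cfg = sd.scenario("(s)_d,(pv)_0", mu=mu, p=p, tau=tau)
        eq = sd.positive_equilibrium(cfg)
        ctx = build_context(cfg, eq)
        assert abs(chi(1j * omega / tau, ctx)) < 1e-8
        roots = find_roots(ctx, {"re_lo": -0.05, "re_hi": 0.05,
                                 "im_lo": 0.5 * omega / tau,
                                 "im_hi": 1.5 * omega / tau})
        assert len(roots) == 1
        assert abs(roots[0].z.real) < 1e-6
        assert roots[0].z.imag == pytest.approx(omega / tau, rel=1e-6)

    def test_no_unstable_roots_outside_apriori_bound(self, fixed_delay_cfg,
                                                     fixed_delay_eq):
        # scan certificate: the right-half-plane part of a generous rectangle
        # contains no roots beyond the a-priori bounded region
        stem = fixed_delay_cfg.stem
        bound = 10.0 * (stem.mu + stem.mu_w + stem.p)
        ctx = build_context(fixed_delay_cfg, fixed_delay_eq)
        roots = find_roots(ctx, {"re_lo": 1e-4, "re_hi": 2 * bound,
                                 "im_hi": 2 * bound})
        assert all(abs(r.z) <= bound for r in roots)
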