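"""Lyapunov exponents, contraction certificates, Hessian indicators."""

import numpy as np
import pytest

from pathlin import (
    LTISystem,
    ReactionNetwork,
    contraction_check,
    global_lyapunov_estimate,
    hessian_error_indicator,
    input_sensitivity_compare,
    local_lyapunov_exponent,
    make_toy_model,
    simulate_to_steady_state,
)
from pathlin.errors import ConfigurationError, SingularityError


class TestLocalLyapunov:
    def test_decay1_constant_rate(self, decay1):
        lam = local_lyapunov_exponent(
            decay1, np.array([2.0]), np.array([1.0]), T_s=0.3, u=np.array([4.0])
        )
        assert lam == pytest.approx(-2.0, abs=1e-6)

    def test_bind2_eigendirection(self, bind2):
        # (1, 1, -1)/sqrt(3) is the eigenvector of the -3 eigenvalue
        v = np.array([1.0, 1.0, -1.0]) / np.sqrt(3)
        lam = local_lyapunov_exponent(
            bind2, np.ones(3), v, T_s=0.2, u=np.array([2.0, 2.0])
        )
        assert lam == pytest.approx(-3.0, rel=0.01)

    def test_pure_rotation_zero(self):
        rot = LTISystem([[0.0, 1.0], [-1.0, 0.0]])
        lam = local_lyapunov_exponent(rot, np.zeros(2), np.array([1.0, 0.0]), T_s=0.5)
        assert lam == pytest.approx(0.0, abs=1e-6)

    def test_frozen_matches_variational_at_fixed_point(self, bind2):
        v = np.array([1.0, 0.0, 0.0])
        kw = dict(x=np.ones(3), y=v, T_s=0.2, u=np.array([2.0, 2.0]))
        assert local_lyapunov_exponent(bind2, frozen=True, **kw) == pytest.approx(
            local_lyapunov_exponent(bind2, frozen=False, **kw), abs=1e-6
        )

    def test_bad_arguments(self, decay1):
        with pytest.raises(ConfigurationError):
            local_lyapunov_exponent(decay1, np.array([1.0]), np.array([2.0]), T_s=0.1)
        with pytest.raises(ConfigurationError):
            local_lyapunov_exponent(decay1, np.array([1.0]), np.array([1.0]), T_s=0.0)


class TestGlobalLyapunov:
    def test_decay1_any_start(self, decay1):
        for x0 in (0.1, 2.0, 5.0):
            diag = global_lyapunov_estimate(
                decay1, np.array([x0]), np.array([4.0]), np.array([1.0]),
                T_s=0.25, n_steps=6,
            )
            assert diag.global_exponent == pytest.approx(-2.0, abs=1e-6)
            np.testing.assert_allclose(diag.local_exponents, -2.0, atol=1e-6)

    def test_affine_dominant_decay(self, affine8):
        """Tail exponent approaches the slowest eigenvalue of the chain."""
        ss = simulate_to_steady_state(affine8, np.array([2.0, 1.0]))
        A = affine8.jac(ss.x_ss)
        lam_max = np.max(np.linalg.eigvals(A).real)
        diag = global_lyapunov_estimate(
            affine8, ss.x_ss, np.array([2.0, 1.0]),
            np.ones(8), T_s=2.0, n_steps=30,
        )
        assert diag.local_exponents[-1] == pytest.approx(lam_max, rel=0.02)

    def test_single_step_equals_local(self, decay1):
        diag = global_lyapunov_estimate(
            decay1, np.array([1.5]), np.array([4.0]), np.array([1.0]),
            T_s=0.3, n_steps=1,
        )
        lam = local_lyapunov_exponent(
            decay1, np.array([1.5]), np.array([1.0]), T_s=0.3, u=np.array([4.0])
        )
        assert diag.global_exponent == pytest.approx(lam, abs=1e-9)

    def test_linear_system_local_equals_global(self):
        A = np.array([[-1.0, 0.3], [0.0, -0.5]])
        sys = LTISystem(A)
        diag = global_lyapunov_estimate(
            sys, np.array([1.0, 1.0]), None, np.array([1.0, 0.0]),
            T_s=0.4, n_steps=8,
        )
        # time-invariant linear flow: every local exponent equals the first
        np.testing.assert_allclose(
            diag.local_exponents, diag.local_exponents[0], atol=1e-6
        )


class TestContraction:
    def test_decay1_exponential(self, decay1):
        rep = contraction_check(
            decay1, [np.array([2.0])], T_s=0.5, u=np.array([4.0])
        )
        assert rep.c_max == pytest.approx(np.exp(-1.0), rel=1e-8)
        assert rep.is_contraction

    def test_bind2_near_anchor(self, bind2):
        rng = np.random.default_rng(1)
        samples = [
            np.maximum(1.0 + 0.1 * rng.standard_normal(3), 0.0) for _ in range(5)
        ]
        rep = contraction_check(bind2, samples, T_s=0.1, u=np.array([2.0, 2.0]))
        assert rep.is_contraction
        assert rep.c_max < 1.0

    def test_unstable_fixture_not_contraction(self):
        net = ReactionNetwork(
            species=["X"],
            reactions=[
                {"reactants": {"X": 1}, "products": {"X": 2}, "rate_param": "k_auto"},
                {"reactants": {"X": 1}, "products": {}, "rate_param": "k_deg"},
            ],
            parameters={"k_auto": 3.0, "k_deg": 1.0},
            inputs={"u": "X"},
        )
        rep = contraction_check(net, [np.array([1.0])], T_s=0.2, u=np.array([0.1]))
        assert not rep.is_contraction

    def test_small_Ts_limit_matches_spectral_abscissa(self):
        """log(c_max)/T_s -> max Re eigenvalue for normal Jacobians."""
        A = np.array([[-2.0, 1.0], [1.0, -2.0]])  # symmetric, eigs -1, -3
        sys = LTISystem(A)
        for T_s, tol in ((0.1, 0.05), (0.01, 0.005)):
            rep = contraction_check(sys, [np.zeros(2)], T_s=T_s)
            assert np.log(rep.c_max) / T_s == pytest.approx(-1.0, abs=tol)

    def test_collinear_segment_inequality(self, bind2):
        """||Phi(p)-Phi(q)|| <= c_max ||p-q|| along a sampled segment."""
        from pathlin.diagnostics import flow_with_variational

        u = np.array([2.0, 2.0])
        p = np.array([0.9, 0.95, 1.05])
        q = np.array([1.1, 1.05, 0.95])
        T_s = 0.2
        pts = [p + s * (q - p) for s in np.linspace(0, 1, 7)]
        rep = contraction_check(bind2, pts, T_s=T_s, u=u)
        phi_p, _ = flow_with_variational(bind2, p, u, T_s)
        phi_q, _ = flow_with_variational(bind2, q, u, T_s)
        assert np.linalg.norm(phi_p - phi_q) <= rep.c_max * np.linalg.norm(p - q)


class TestHessianIndicator:
    def test_affine_zero(self, affine8):
        rng = np.random.default_rng(2)
        ind = hessian_error_indicator(
            affine8, rng.uniform(0, 2, 8), rng.uniform(-0.5, 0.5, 8)
        )
        assert ind.norm == pytest.approx(0.0, abs=1e-12)

    def test_bind2_bilinear_term(self, bind2):
        a = 0.1
        ind = hessian_error_indicator(
            bind2, np.ones(3), np.array([a, a, 0.0]), u=np.array([2.0, 2.0])
        )
        # row A of the second-order term is the bilinear cross term -a^2
        assert ind.components[0] == pytest.approx(a * a, abs=1e-12)

    def test_quadratic_homogeneity(self, bind2):
        dx = np.array([0.05, -0.03, 0.02])
        base = hessian_error_indicator(bind2, np.ones(3), dx, u=np.array([2.0, 2.0]))
        double = hessian_error_indicator(
            bind2, np.ones(3), 2 * dx, u=np.array([2.0, 2.0])
        )
        assert double.norm == pytest.approx(4 * base.norm, abs=1e-10)

    def test_quarter_scaling_tracks_agreement_error(self, bind2, bind2_ss):
        """Halving du quarters the indicator and ~quarters e_ss."""
        from pathlin import build_agreement_system, linearize, simulate_agreement

        lin = linearize(bind2, bind2_ss)
        agr = build_agreement_system(bind2, lin)
        inds, errs = [], []
        for scale in (1.0, 0.5, 0.25):
            du = 0.2 * scale
            x_new = simulate_to_steady_state(
                bind2, np.array([2 + du, 2 + du])
            ).x_ss
            ind = hessian_error_indicator(
                bind2, bind2_ss.x_ss, x_new - bind2_ss.x_ss, u=bind2_ss.u_bf
            )
            res = simulate_agreement(agr, np.array([2 + du, 2 + du]))
            inds.append(ind.norm)
            errs.append(np.linalg.norm(res.e_ss))
        np.testing.assert_allclose(
            [inds[1] / inds[0], inds[2] / inds[1]], 0.25, atol=0.02
        )
        for ratio in (errs[1] / errs[0], errs[2] / errs[1]):
            assert 0.2 < ratio < 0.3


class TestInputSensitivity:
    def test_same_point_zero(self, bind2):
        cmp = input_sensitivity_compare(bind2, np.ones(3), np.ones(3))
        assert cmp.abs_diff == 0.0

    def test_affine_constant(self, affine8):
        rng = np.random.default_rng(3)
        cmp = input_sensitivity_compare(
            affine8, rng.uniform(0, 2, 8), rng.uniform(0, 2, 8)
        )
        assert cmp.abs_diff == pytest.approx(0.0, abs=1e-12)

    def test_bind2_shifted_anchor(self, bind2):
        cmp = input_sensitivity_compare(
            bind2, np.ones(3), np.array([1.06525, 1.06525, 1.13476])
        )
        assert cmp.abs_diff > 0.0
        assert cmp.S_anchor.shape == (3, 2)

    def test_singular_jacobian_raises(self):
        sys = LTISystem(np.zeros((2, 2)), np.eye(2))
        with pytest.raises(SingularityError):
            input_sensitivity_compare(sys, np.zeros(2), np.ones(2))
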