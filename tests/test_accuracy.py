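"""Perturbation formula, error metrics, the Monte Carlo workflow, ratios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pathlin import (
    ConfigurationError,
    GeneratorConfig,
    MetricUndefinedError,
    compute_metrics,
    fit_error_trend,
    generate_wnt_like_network,
    make_toy_model,
    perturb_inputs,
    relative_dataset_ratios,
    run_study,
    run_workflow,
    sample_base_inputs,
)
from pathlin.accuracy import MCReport, PerturbationSet
import pandas as pd


class TestPerturbInputs:
    def test_zero_noise_collapses(self):
        u = np.array([1.5, 3.0])
        d = np.array([0.3, 0.9])
        np.testing.assert_array_equal(perturb_inputs(u, 0.0, d), u)

    def test_extremes(self):
        u = np.array([2.0, 2.0])
        np.testing.assert_allclose(
            perturb_inputs(u, 0.5, np.array([0.0, 1.0])), [3.0, 1.0]
        )

    def test_midpoint_identity(self):
        u = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            perturb_inputs(u, 0.4, np.full(3, 0.5)), u, atol=1e-15
        )

    def test_direction_out_of_range(self):
        with pytest.raises(ConfigurationError):
            perturb_inputs(np.ones(2), 0.1, np.array([0.5, 1.2]))

    @given(
        r=st.floats(0.0, 0.99),
        d=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=3),
    )
    def test_multiplicative_bounds(self, r, d):
        u = np.array([0.5, 2.0, 7.0])
        ui = perturb_inputs(u, r, np.asarray(d))
        factors = ui / u
        assert np.all(factors >= 1 - r - 1e-12)
        assert np.all(factors <= 1 + r + 1e-12)

    def test_bounds_bulk_draws(self):
        rng = np.random.default_rng(0)
        u = rng.lognormal(0, 0.5, 4)
        for r in (0.1, 0.25, 0.5):
            d = rng.uniform(0, 1, (100_000, 4))
            ui = (1 + r - 2 * r * d) * u
            factors = ui / u
            assert factors.min() >= 1 - r and factors.max() <= 1 + r


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics(np.ones(3), np.ones(3), np.zeros(3))
        assert m.mse == 0.0 and m.mre_pct == 0.0

    def test_worked_example(self):
        m = compute_metrics(
            np.array([3.0, 1.0]), np.array([2.0, 1.0]), np.array([1.0, 1.0])
        )
        assert m.mse == pytest.approx(0.5)
        assert m.mre_pct == pytest.approx(25.0)
        assert m.std_ratio_pct == pytest.approx(100.0)

    def test_small_denominator_excluded(self):
        """Clipped-to-zero predictions against ~zero states stay finite."""
        x_lin = np.array([0.0, 1.0])
        x_non = np.array([1e-15, 1.0])
        m = compute_metrics(x_lin, x_non, np.array([0.5, 0.5]))
        assert m.n_excluded == 1
        assert np.isfinite(m.mre_pct)

    def test_all_excluded_raises(self):
        with pytest.raises(MetricUndefinedError):
            compute_metrics(np.zeros(2), np.zeros(2), np.ones(2))

    def test_scope_restriction_consistent(self):
        rng = np.random.default_rng(3)
        x_lin = rng.uniform(0.5, 2, 6)
        x_non = rng.uniform(0.5, 2, 6)
        x0 = rng.uniform(0.5, 2, 6)
        idx = np.array([1, 4, 5])
        direct = compute_metrics(x_lin, x_non, x0, scope_indices=idx)
        manual = compute_metrics(x_lin[idx], x_non[idx], x0[idx])
        assert direct.mse == pytest.approx(manual.mse)
        assert direct.mre_pct == pytest.approx(manual.mre_pct)
        assert direct.std_ratio_pct == pytest.approx(manual.std_ratio_pct)


class TestWorkflow:
    def test_affine_zero_error(self, affine8):
        base = np.abs(sample_base_inputs(4, 2, seed=1)) + 0.5
        rep = run_workflow(affine8, base, seed=2)
        assert np.all(rep.table.mre_pct < 1e-6)
        assert np.all(rep.table.mse < 1e-12)

    def test_directions_shared_across_r_noise(self):
        ps = PerturbationSet.draw(5, 3, seed=9)
        assert ps.directions.shape == (5, 3)
        assert np.all((ps.directions >= 0) & (ps.directions <= 1))

    def test_default_noise_levels(self, affine8):
        base = sample_base_inputs(2, 2, seed=0) + 0.5
        rep = run_workflow(affine8, base, seed=0)
        assert sorted(rep.table.r_noise.unique()) == [0.10, 0.25, 0.50]

    @pytest.mark.parametrize("seed", [4, 14, 24, 34])
    def test_mre_increases_with_noise_on_cascade(self, seed):
        """Error metrics grow strictly with r_noise on cascade models."""
        cfg = GeneratorConfig(
            n_ligands=2, n_receptors=2, n_coreceptors=1, n_readouts=4,
            depth=1, density=0.9, seed=seed,
        )
        net = generate_wnt_like_network(cfg)
        base = sample_base_inputs(8, net.n_inputs, seed=seed + 1)
        rep = run_workflow(net, base, seed=seed + 2)
        for scope in ("all_states", "readouts"):
            rows = rep.table[rep.table.scope == scope].sort_values("r_noise")
            mre = rows.mre_pct.to_numpy()
            mse = rows.mse.to_numpy()
            assert mre[0] < mre[1] < mre[2]
            assert mse[0] < mse[1] < mse[2]
            assert mre[2] / mre[0] > 3.0
        # linear model captures most of the response at the smallest level
        r10 = rep.table[
            (rep.table.scope == "all_states") & (rep.table.r_noise == 0.10)
        ]
        assert 0.0 < float(r10.std_ratio_pct.iloc[0]) <= 100.0

    def test_determinism(self, bind2):
        base = sample_base_inputs(3, 2, seed=1) + 0.5
        a = run_workflow(bind2, base, seed=7).table
        b = run_workflow(bind2, base, seed=7).table
        pd.testing.assert_frame_equal(a, b)

    def test_run_study_distinct_parameter_vectors(self, bind2):
        base = sample_base_inputs(2, 2, seed=2) + 0.5
        reports = run_study(bind2, base, n_workflows=2, seed=3)
        assert [r.workflow_id for r in reports] == [1, 2]
        # different parameter draws must give different metrics
        assert not np.allclose(
            reports[0].table.mre_pct, reports[1].table.mre_pct
        )


class TestTrendFit:
    def _report_from(self, r, mre):
        rows = pd.DataFrame(
            {
                "r_noise": r,
                "scope": "all_states",
                "std_ratio_pct": 0.0,
                "mre_pct": mre,
                "mse": 0.0,
                "n_excluded": 0,
            }
        )
        return MCReport(
            table=rows, per_sample=rows.assign(sample=0), n_samples=1,
            n_excluded_samples=0, seed=0, model_id="synthetic-rows",
        )

    def test_quadratic_slope(self):
        r = np.array([0.1, 0.2, 0.4])
        fit = fit_error_trend(self._report_from(r, 3.0 * r**2))
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.monotone

    def test_linear_slope(self):
        r = np.array([0.1, 0.2, 0.4])
        fit = fit_error_trend(self._report_from(r, 5.0 * r))
        assert fit.slope == pytest.approx(1.0, abs=1e-9)

    def test_exact_linear_flag(self):
        r = np.array([0.1, 0.2, 0.4])
        fit = fit_error_trend(self._report_from(r, np.zeros(3)))
        assert fit.exact_linear

    def test_bind2_sweep_second_order(self, bind2):
        base = np.full((12, 2), 2.0) * sample_base_inputs(12, 2, seed=8) ** 0.2
        rep = run_workflow(
            bind2, base, r_noise_list=(0.05, 0.1, 0.2, 0.4), seed=9
        )
        fit = fit_error_trend(rep)
        assert 1.5 < fit.slope < 2.5


class TestRelativeRatios:
    def test_identity_variant(self, bind2):
        ratios = relative_dataset_ratios(
            bind2, np.array([2.0, 2.0]), [np.array([2.0, 2.0])]
        )
        np.testing.assert_allclose(ratios[0], 1.0, atol=1e-8)

    def test_bind2_closed_form_ratio(self, bind2):
        u_base = np.array([2.0, 2.0])
        u_var = np.array([2.2, 2.2])
        nonlin = relative_dataset_ratios(bind2, u_base, [u_var])[0][0]
        linear = relative_dataset_ratios(bind2, u_base, [u_var], use_linear=True)[0][0]
        assert nonlin == pytest.approx(((-1 + np.sqrt(9.8)) / 2) ** 2, abs=1e-6)
        assert linear == pytest.approx(1 + 2 * 0.2 / 3, abs=1e-6)

    def test_upregulation_sign(self, bind2):
        u_base = np.array([2.0, 2.0])
        up = relative_dataset_ratios(bind2, u_base, [np.array([2.5, 2.5])])[0][0]
        down = relative_dataset_ratios(bind2, u_base, [np.array([1.5, 1.5])])[0][0]
        assert up > 1.0 > down

    def test_zero_base_output_rejected(self):
        net = make_toy_model("bind2")
        with pytest.raises(ConfigurationError):
            # zero inflow on A keeps the complex C at zero at base state
            relative_dataset_ratios(
                net, np.array([0.0, 2.0]), [np.array([1.0, 2.0])]
            )
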