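"""Saltelli design, Sobol' estimators, ranking and variability machinery."""

import numpy as np
import pytest

from graftdyn import (
    DegenerateAnalysisError,
    DomainError,
    SobolIndices,
    build_ranges,
    batch_qoi,
    convergence_protocol,
    design_size,
    estimate_indices,
    evaluate_design,
    generate_design,
    model_qoi_function,
    oat_sweep,
    qoi_L30,
    rank_by_total_index,
    simulate,
    variability_experiment,
)
from graftdyn.model import PARAM_NAMES
from graftdyn.sensitivity import design_from_bounds
from graftdyn.oracles import (
    ishigami_report,
    linear_analytic_indices,
    linear_report,
)


class TestRanges:
    def test_thirty_five_ranges_half_to_three_halves(self, nominal):
        ranges = build_ranges(nominal)
        assert len(ranges) == 35  # initial values are excluded by design
        by_name = {r.name: r for r in ranges}
        assert by_name["delta_L"].low == 0.0025
        assert by_name["delta_L"].high == 0.0075
        assert by_name["alpha_CL"].low == 5.0
        assert by_name["alpha_CL"].high == 15.0

    def test_design_has_no_initial_value_columns(self, nominal):
        design = generate_design(build_ranges(nominal), N=4)
        assert design.k == 35
        assert set(design.names) == set(PARAM_NAMES)


class TestDesign:
    @pytest.mark.parametrize("N, k, expected", [
        (175_000, 35, 6_475_000),
        (175_000, 6, 1_400_000),
        (4, 2, 16),
    ])
    def test_design_size_formula(self, N, k, expected):
        assert design_size(N, k) == expected

    def test_small_design_rows_within_bounds(self):
        lo, hi = np.array([0.0, 10.0]), np.array([1.0, 20.0])
        design = design_from_bounds(lo, hi, N=4, seed=0)
        X = design.matrix()
        assert X.shape == (16, 2)
        assert np.all(X >= lo) and np.all(X <= hi)

    def test_determinism_by_seed(self, nominal):
        ranges = build_ranges(nominal)
        d1 = generate_design(ranges, N=8, seed=7)
        d2 = generate_design(ranges, N=8, seed=7)
        d3 = generate_design(ranges, N=8, seed=8)
        np.testing.assert_array_equal(d1.matrix(), d2.matrix())
        assert not np.array_equal(d1.matrix(), d3.matrix())

    def test_marginals_cover_ranges(self, nominal):
        design = generate_design(build_ranges(nominal), N=256, seed=0)
        lo = np.array([r.low for r in build_ranges(nominal)])
        hi = np.array([r.high for r in build_ranges(nominal)])
        A = design.A
        assert np.all(A >= lo) and np.all(A <= hi)
        # scrambled Sobol' marginals are near-uniform: mean close to midpoint
        np.testing.assert_allclose(A.mean(axis=0), (lo + hi) / 2,
                                   rtol=0.05)


class TestEvaluation:
    def test_constant_rows_give_constant_vector(self, nominal):
        design = generate_design(build_ranges(nominal), N=2, seed=0)
        y = evaluate_design(design, lambda X: np.full(X.shape[0], 3.14))
        assert y.shape == (design.n_evaluations,)
        assert np.all(y == 3.14)

    def test_chunked_evaluation_preserves_order(self, nominal):
        design = generate_design(build_ranges(nominal), N=8, seed=1)
        f = lambda X: X[:, 0] * 7.0
        np.testing.assert_array_equal(
            evaluate_design(design, f, chunk_size=37),
            evaluate_design(design, f))

    def test_killing_switched_off_gives_initial_liver(self, nominal):
        theta = np.tile(nominal.params.to_array(), (5, 1))
        theta[:, PARAM_NAMES.index("alpha_CL")] = 0.0
        y = batch_qoi(theta, nominal.init)
        np.testing.assert_array_equal(y, np.full(5, 2e11))

    def test_batch_matches_adaptive_solver(self, nominal):
        rng = np.random.default_rng(5)
        ranges = build_ranges(nominal)
        theta = np.array([[rng.uniform(r.low, r.high) for r in ranges]
                          for _ in range(8)])
        fast = batch_qoi(theta, nominal.init)
        for row, expect in zip(theta, fast):
            p = nominal.params.replace(**dict(zip(PARAM_NAMES, row)))
            slow = qoi_L30(simulate(p, nominal.init))
            assert expect == pytest.approx(slow, rel=1e-4)


class TestEstimators:
    def test_additive_linear_matches_closed_form(self):
        report = linear_report(N=1024, seed=0)
        assert report.ok, report.describe()

    def test_ishigami_structure_detected(self):
        # x3 has zero first-order effect but a real interaction with x1
        report = ishigami_report(N=2048, seed=0)
        idx = report.indices
        assert abs(idx.S1[2]) < 0.02
        assert idx.ST[2] > 0.15
        assert idx.ST[0] > idx.S1[0]  # interaction lifts the total index

    def test_total_dominates_first_order_up_to_noise(self):
        report = linear_report(N=1024, seed=3)
        idx = report.indices
        assert np.all(idx.ST >= idx.S1 - 3 * (idx.S1_err + idx.ST_err))

    def test_degenerate_variance_raises(self, nominal):
        design = generate_design(build_ranges(nominal), N=8, seed=0)
        y = np.ones(design.n_evaluations)
        with pytest.raises(DegenerateAnalysisError):
            estimate_indices(design, y)

    def test_wrong_length_rejected(self, nominal):
        design = generate_design(build_ranges(nominal), N=8, seed=0)
        with pytest.raises(DomainError):
            estimate_indices(design, np.ones(10))


class TestRanking:
    def _indices(self, names, ST, S1=None):
        k = len(names)
        z = np.zeros(k)
        return SobolIndices(names=tuple(names), S1=np.asarray(S1) if S1 is not None else z,
                            S1_err=z, ST=np.asarray(ST), ST_err=z, N=8,
                            variance=1.0)

    def test_descending_by_total_index(self):
        idx = self._indices(["a", "b", "c"], [0.1, 0.7, 0.3])
        assert rank_by_total_index(idx) == ["b", "c", "a"]

    def test_top_k_zero_empty(self):
        idx = self._indices(["a", "b"], [0.5, 0.4])
        assert rank_by_total_index(idx, top_k=0) == []

    def test_all_equal_falls_back_to_name_order(self):
        idx = self._indices(["delta", "alpha", "beta"], [0.2, 0.2, 0.2])
        assert rank_by_total_index(idx) == ["alpha", "beta", "delta"]

    def test_tie_broken_by_first_order(self):
        idx = self._indices(["a", "b"], [0.2, 0.2], S1=[0.1, 0.15])
        assert rank_by_total_index(idx) == ["b", "a"]


class TestConvergenceProtocol:
    def test_linear_function_ranking_is_stable(self):
        c = np.array([4.0, 2.0, 1.0, 0.5])
        lo, hi = np.zeros(4), np.ones(4)
        S = linear_analytic_indices(c, lo, hi)
        truth = [f"x{i}" for i in np.argsort(-S)]

        def run(N, seed):
            design = design_from_bounds(lo, hi, N, seed=seed)
            return design, evaluate_design(design, lambda X: X @ c)

        from graftdyn.sensitivity import ConvergenceReport, ParameterRange
        ranges = [ParameterRange(f"x{i}", 0.5, 0.25, 0.75) for i in range(4)]
        # rescale the function to these ranges: same relative widths, so the
        # closed-form ranking is unchanged
        report = convergence_protocol(ranges, lambda X: X @ c,
                                      schedule=(256, 512), top_k=4, seed=0)
        assert isinstance(report, ConvergenceReport)
        assert report.stable
        assert list(report.rankings[-1]) == truth

    def test_non_increasing_schedule_rejected(self, nominal):
        with pytest.raises(DomainError):
            convergence_protocol(build_ranges(nominal), lambda X: X[:, 0],
                                 schedule=(512, 512))


class TestVariability:
    def test_full_top_set_reproduces_all_scheme(self, nominal):
        result = variability_experiment(nominal, PARAM_NAMES, n_samples=32,
                                        seed=11)
        np.testing.assert_array_equal(result.qoi_all, result.qoi_top_only)

    def test_empty_top_set_gives_constant_scheme(self, nominal):
        result = variability_experiment(nominal, (), n_samples=32, seed=11)
        assert np.ptp(result.qoi_top_only) == 0.0
        nominal_qoi = qoi_L30(simulate(nominal.params, nominal.init))
        assert result.qoi_top_only[0] == pytest.approx(nominal_qoi, rel=1e-4)

    def test_unknown_parameter_rejected(self, nominal):
        with pytest.raises(DomainError):
            variability_experiment(nominal, ("not_a_param",), n_samples=8)


class TestOatSweep:
    def test_unit_multiplier_matches_nominal(self, nominal):
        result = oat_sweep("alpha_CL", [1.0], nominal)
        traj, l30 = result[1.0]
        assert l30 == pytest.approx(
            qoi_L30(simulate(nominal.params, nominal.init)), rel=1e-12)

    def test_killing_sweep_monotone_in_multiplier(self, nominal):
        result = oat_sweep("alpha_CL", [0.5, 1.0, 1.5], nominal)
        l30 = [result[m][1] for m in (0.5, 1.0, 1.5)]
        assert l30[0] > l30[1] > l30[2]

    def test_unknown_parameter_rejected(self, nominal):
        with pytest.raises(DomainError):
            oat_sweep("nope", [1.0], nominal)
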