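"""Histogram binning, natural-spline basis, Poisson smooth, subgroups."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.interpolate import CubicSpline

from auccaliper.distribution import (
    Histogram,
    HistogramSpec,
    build_histogram,
    fit_poisson_spline,
    max_per_abstract,
    natural_spline_basis,
    spline_knots,
    subset_journal,
    subset_results_section,
    threshold_report,
)
from auccaliper.extraction import AUCMatch


def match(value, pmid="1", role="point", dp=3, label="RESULTS"):
    return AUCMatch(
        pmid=pmid,
        value=value,
        raw_token=f"{value:.{dp}f}",
        role=role,
        decimal_places=dp,
        was_percent=False,
        section_label=label,
    )


class TestBinning:
    @pytest.mark.parametrize("value,expected_lower", [
        (0.70, 0.69),     # half-open: 0.70 belongs to (0.69, 0.70]
        (0.690001, 0.69),
        (0.70001, 0.70),
        (0.01, 0.00),
        (0.999, 0.99),
    ])
    def test_half_open_convention(self, value, expected_lower):
        hist = build_histogram([value])
        (idx,) = np.nonzero(hist.counts)
        assert hist.spec.lower_edges[idx[0]] == pytest.approx(expected_lower)

    def test_one_decimal_values_excluded_and_counted(self):
        hist = build_histogram([match(0.8, dp=1), match(0.82, dp=2)])
        assert hist.n_values == 1
        assert hist.n_excluded_one_decimal == 1

    def test_ci_roles_excluded_by_default(self):
        ms = [match(0.7), match(0.6, role="ci_lower"), match(0.8, role="ci_upper")]
        hist = build_histogram(ms)
        assert hist.n_values == 1
        spec = HistogramSpec(roles_included=frozenset({"ci_lower"}))
        assert build_histogram(ms, spec).n_values == 1

    def test_out_of_range_value_is_hard_error(self):
        with pytest.raises(ValueError):
            build_histogram([1.2])
        with pytest.raises(ValueError):
            build_histogram(np.array([-0.1, 0.5]))

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 2**32 - 1))
    def test_conservation_under_fuzzing(self, seed):
        values = np.random.default_rng(seed).uniform(1e-6, 1 - 1e-9, size=500)
        hist = build_histogram(values)
        assert hist.counts.sum() == 500
        # each value in exactly one bin: lower < v <= upper
        for v in values[:20]:
            idx = np.nonzero(
                (hist.spec.lower_edges < v) & (v <= hist.spec.upper_edges)
            )[0]
            assert len(idx) == 1


class TestNaturalSplineBasis:
    mids = HistogramSpec().midpoints

    def test_shape_and_knot_placement(self):
        B = natural_spline_basis(self.mids, df=4)
        assert B.shape == (100, 4)
        knots = spline_knots(self.mids, df=4)
        assert len(knots) == 5  # 2 boundary + 3 interior
        np.testing.assert_allclose(
            knots[1:-1], np.quantile(self.mids, [0.25, 0.5, 0.75])
        )

    def test_linear_beyond_boundary_knots(self):
        knots = spline_knots(self.mids, df=4)
        left = np.linspace(knots[0] - 0.5, knots[0], 50)
        right = np.linspace(knots[-1], knots[-1] + 0.5, 50)
        for grid in (left, right):
            B = natural_spline_basis(grid, knots=knots)
            second = np.diff(B, n=2, axis=0)
            np.testing.assert_allclose(second, 0, atol=1e-9)

    def test_columns_are_natural_cubic_splines(self):
        """Independent oracle: a function is a natural cubic spline on a
        knot vector iff the natural cubic interpolant through its values
        at the knots reproduces it everywhere."""
        knots = spline_knots(self.mids, df=4)
        B_at_knots = natural_spline_basis(knots, knots=knots)
        probes = np.array([0.031, 0.27, 0.493, 0.61, 0.88])
        B_at_probes = natural_spline_basis(probes, knots=knots)
        for j in range(4):
            interp = CubicSpline(knots, B_at_knots[:, j], bc_type="natural")
            np.testing.assert_allclose(
                interp(probes), B_at_probes[:, j], atol=1e-10
            )

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError, match="knots"):
            natural_spline_basis(self.mids, knots=np.array([0.0, 0.5, 0.5, 0.9, 1.0]))


class TestPoissonSplineFit:
    def test_constant_counts_fit_flat(self):
        hist = build_histogram([])
        hist.counts[:] = 50
        fit = fit_poisson_spline(hist)
        np.testing.assert_allclose(fit.fitted, 50, rtol=1e-6)
        np.testing.assert_allclose(fit.residuals, 0, atol=1e-4)
        assert fit.converged

    def test_score_equation_sum_fitted_equals_sum_observed(self, rng):
        hist = build_histogram(rng.uniform(0.3, 0.999, size=5000))
        fit = fit_poisson_spline(hist)
        assert fit.fitted[fit.bin_mask].sum() == pytest.approx(
            hist.counts.sum(), rel=1e-6
        )
        assert fit.residuals[fit.bin_mask].sum() == pytest.approx(0, abs=1e-4)

    def test_coefficients_match_direct_likelihood_maximization(self):
        """20-bin toy: the IRLS solution must agree with a general-purpose
        optimizer maximizing the Poisson log-likelihood directly."""
        counts = np.arange(1.0, 21.0)
        hist = build_histogram([])
        hist.counts[:20] = counts
        fit = fit_poisson_spline(hist, fit_domain=(0.0, 0.20))

        x = hist.spec.midpoints[:20]
        X = np.column_stack([np.ones(20), natural_spline_basis(x, knots=fit.knots)])

        def negll(beta):
            eta = X @ beta
            return np.sum(np.exp(eta)) - np.sum(counts * eta)

        def grad(beta):
            return X.T @ (np.exp(X @ beta) - counts)

        res = optimize.minimize(
            negll, np.zeros(5), jac=grad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 500},
        )
        np.testing.assert_allclose(fit.coefficients, res.x, atol=1e-6)

    def test_all_zero_counts_hard_error(self):
        with pytest.raises(ValueError, match="zero"):
            fit_poisson_spline(build_histogram([]))

    def test_fit_domain_restricts_bins(self, rng):
        hist = build_histogram(rng.uniform(0.5, 0.999, size=2000))
        fit = fit_poisson_spline(hist, fit_domain=(0.5, 1.0))
        assert fit.bin_mask.sum() == 50
        assert np.isnan(fit.fitted[:50]).all()
        assert np.isfinite(fit.fitted[50:]).all()


class TestThresholdReport:
    def test_reports_adjacent_bins(self, rng):
        hist = build_histogram(rng.uniform(0.4, 0.999, size=20000))
        fit = fit_poisson_spline(hist, fit_domain=(0.4, 1.0))
        rep = threshold_report(hist, fit)
        entry = rep[0.7]
        assert entry.observed_below == hist.counts[69]
        assert entry.observed_above == hist.counts[70]
        assert entry.residual_above == pytest.approx(
            hist.counts[70] - fit.fitted[70]
        )

    def test_perfect_fit_gives_zero_residuals_unit_ratios(self):
        hist = build_histogram([])
        hist.counts[:] = 40
        fit = fit_poisson_spline(hist)
        rep = threshold_report(hist, fit)
        for e in rep:
            assert e.residual_above == pytest.approx(0, abs=1e-3)
            assert e.excess_ratio_above == pytest.approx(1, abs=1e-4)

    def test_misaligned_threshold_rejected(self, rng):
        hist = build_histogram(rng.uniform(0.01, 0.99, size=100))
        fit = fit_poisson_spline(hist)
        with pytest.raises(ValueError, match="grid"):
            threshold_report(hist, fit, [0.705])


class TestSubgroups:
    def test_max_per_abstract(self):
        ms = [match(0.71, pmid="a"), match(0.83, pmid="a"), match(0.6, pmid="b")]
        best = max_per_abstract(ms)
        assert sorted((m.pmid, m.value) for m in best) == [("a", 0.83), ("b", 0.6)]

    def test_max_per_abstract_tie_keeps_first(self):
        first = match(0.8, pmid="a", label="RESULTS")
        second = match(0.8, pmid="a", label="CONCLUSIONS")
        assert max_per_abstract([first, second]) == [first]

    def test_max_per_abstract_rejects_ci_roles(self):
        with pytest.raises(ValueError):
            max_per_abstract([match(0.7, role="ci_lower")])

    @pytest.mark.parametrize("label,kept", [
        ("RESULTS", True),
        ("RESULTS AND DISCUSSION", True),
        ("METHODS", False),
        ("", False),
    ])
    def test_results_section_filter(self, label, kept):
        out = subset_results_section([match(0.7, label=label)])
        assert bool(out) == kept

    def test_journal_filter_case_insensitive(self):
        ms = [match(0.7, pmid="a"), match(0.8, pmid="b")]
        journals = {"a": "PLoS One", "b": "Other Journal"}
        out = subset_journal(ms, journals, "plos one")
        assert [m.pmid for m in out] == ["a"]
        assert subset_journal([], {}, "plos one") == []
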