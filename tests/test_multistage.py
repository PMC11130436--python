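"""Quantal multistage model: summaries, closed form, MLE, GOF, selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benzrisk.exceptions import (
    IdentifiabilityError,
    ReferenceGroupError,
    SaturatedModelError,
)
from benzrisk.multistage import (
    DoseGroup,
    MultistageModel,
    MultistageResults,
    fit_multistage,
    multistage_probability,
    select_degree,
    summarize_cohort,
)
from benzrisk.simulate import generate_cohort


class TestDoseGroup:
    @pytest.mark.parametrize(
        "dose,n,cases",
        [(-1.0, 100, 1), (0.0, 0, 0), (0.0, 10, 11), (0.0, 10, -1)],
    )
    def test_invariants_enforced(self, dose, n, cases):
        with pytest.raises(ValueError):
            DoseGroup(dose, n, cases)


class TestSummarizeCohort:
    def test_published_incidence_and_rr(self, cohort_groups):
        """Crude incidences and RRs of the three cohort strata."""
        s = summarize_cohort(cohort_groups)
        assert s.incidence == pytest.approx([18 / 35804, 13 / 31923, 25 / 24605])
        # published display values (the reference stratum is truncated, not
        # rounded, in print: 18/35804 = 5.027e-4 appears as 5.02)
        assert s.incidence * 1e4 == pytest.approx([5.02, 4.07, 10.16], abs=0.01)
        assert s.relative_risk[0] == 1.0
        assert round(s.relative_risk[1], 2) == 0.81
        assert round(s.relative_risk[2], 2) == 2.02

    def test_requires_zero_dose_reference(self):
        with pytest.raises(ReferenceGroupError):
            summarize_cohort([DoseGroup(1.0, 100, 1), DoseGroup(2.0, 100, 2)])

    def test_zero_case_reference_convention(self):
        s = summarize_cohort([DoseGroup(0.0, 100, 0), DoseGroup(5.0, 100, 2)])
        assert s.incidence[0] == 0.0
        assert s.relative_risk[0] == 1.0
        assert np.isinf(s.relative_risk[1])


class TestProbability:
    def test_zero_dose_returns_background(self):
        assert multistage_probability(0.3, [1e-3, 1e-5], 0.0) == pytest.approx(0.3)

    def test_closed_form_hand_evaluation(self):
        # independent arithmetic with math.exp
        r, a1, d = 4.32e-4, 1.38e-6, 388.0
        expected = r + (1 - r) * (1 - math.exp(-a1 * d))
        assert multistage_probability(r, [a1], d) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(9.67e-4, abs=5e-7)

    def test_highest_group_risk_two_decimals(self, published_lms):
        assert round(published_lms.predict(86.79) * 1e4, 2) == 5.52

    def test_negative_dose_rejected(self, published_lms):
        with pytest.raises(ValueError):
            published_lms.predict(-1.0)

    @given(
        r=st.floats(0, 0.99),
        a=st.lists(st.floats(0, 1e-2), min_size=1, max_size=3),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_dose(self, r, a):
        """P(d) is non-decreasing on a dose grid for any valid parameters."""
        grid = np.linspace(0, 500, 60)
        p = multistage_probability(r, a, grid)
        assert np.all(np.diff(p) >= -1e-15)
        assert p[0] == pytest.approx(r, abs=1e-15)


class TestFit:
    def test_cohort_fit_recovers_published_parameters(self, cohort_groups):
        fit = fit_multistage(cohort_groups, degree=1)
        assert fit.converged
        assert fit.r == pytest.approx(4.32e-4, rel=0.02)
        assert fit.a1 == pytest.approx(1.38e-6, rel=0.03)

    def test_two_group_saturated_exact_solution(self):
        """With 2 groups and 2 parameters the MLE interpolates the data."""
        groups = [DoseGroup(0, 1000, 10), DoseGroup(100, 1000, 20)]
        fit = fit_multistage(groups, degree=1)
        assert fit.r == pytest.approx(0.01, abs=1e-10)
        a1_exact = -math.log(1 - (0.01 / 0.99)) / 100
        assert fit.a1 == pytest.approx(a1_exact, rel=1e-9)
        assert fit.predict(0) == pytest.approx(0.01, abs=1e-9)
        assert fit.predict(100) == pytest.approx(0.02, abs=1e-9)

    def test_single_group_unidentifiable(self):
        with pytest.raises(IdentifiabilityError):
            MultistageModel([DoseGroup(0, 100, 5)], degree=1)

    def test_degree_exceeding_groups_rejected(self, cohort_groups):
        with pytest.raises(IdentifiabilityError):
            MultistageModel(cohort_groups, degree=3)

    def test_all_zero_cases_pins_background(self):
        groups = [DoseGroup(0, 100, 0), DoseGroup(10, 100, 0), DoseGroup(50, 100, 0)]
        with pytest.warns(UserWarning):
            fit = fit_multistage(groups, degree=1)
        assert fit.r == 0.0
        assert fit.a1 == 0.0

    def test_flat_dose_response_gives_near_zero_slope(self):
        groups = [DoseGroup(0, 500, 25), DoseGroup(50, 500, 25), DoseGroup(100, 500, 25)]
        fit = fit_multistage(groups, degree=1)
        assert fit.r == pytest.approx(0.05, rel=1e-3)
        assert fit.a1 * 100 < 1e-6  # dose contribution negligible

    def test_beats_brute_force_grid(self):
        """MLE log-likelihood dominates a 50x50 (r, a1) grid oracle."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            r_true = rng.uniform(0.005, 0.05)
            a_true = rng.uniform(1e-4, 5e-3)
            doses = np.array([0.0, 20.0, 60.0, 150.0])
            groups = [
                DoseGroup(d, 400, int(rng.binomial(400, multistage_probability(r_true, [a_true], d))))
                for d in doses
            ]
            model = MultistageModel(groups, degree=1)
            fit = model.fit()
            rs = np.linspace(max(fit.r / 3, 1e-6), min(fit.r * 3 + 1e-4, 0.5), 50)
            as_ = np.linspace(max(fit.a1 / 3, 1e-9), fit.a1 * 3 + 1e-6, 50)
            grid_best = max(model.loglike(r, [a]) for r in rs for a in as_)
            assert fit.log_likelihood >= grid_best - 1e-7


class TestGof:
    def test_cohort_fit_gof(self, cohort_groups):
        """Degree-1 fit to the three strata leaves df=1 and p near 0.25."""
        g = fit_multistage(cohort_groups, degree=1).gof()
        assert g.df == 1
        assert 0.2 <= g.p_value <= 0.3
        assert g.chi_square >= 0

    def test_saturated_model_raises(self):
        fit = fit_multistage([DoseGroup(0, 1000, 10), DoseGroup(100, 1000, 20)], 1)
        with pytest.raises(SaturatedModelError):
            fit.gof()

    def test_perfect_fit_zero_chi_square(self):
        # equal observed proportions: fitted curve passes through all groups
        groups = [DoseGroup(0, 100, 10), DoseGroup(1, 100, 10), DoseGroup(2, 100, 10)]
        g = fit_multistage(groups, degree=1).gof()
        assert g.chi_square == pytest.approx(0.0, abs=1e-6)
        assert g.p_value == pytest.approx(1.0, abs=1e-3)


class TestSelectDegree:
    def test_three_groups_selects_degree_one(self, cohort_groups):
        fit = select_degree(cohort_groups, max_degree=1)
        assert fit.degree == 1

    def test_max_degree_two_on_three_groups_still_scorable_only_at_one(self, cohort_groups):
        # degree 2 saturates three groups (df=0) and cannot be scored
        fit = select_degree(cohort_groups, max_degree=2)
        assert fit.degree == 1


class TestRecovery:
    def test_binomial_simulation_recovers_slope(self, cohort_groups, published_lms):
        """Median refit of a1 over simulated cohorts stays near the truth."""
        refits = []
        for seed in range(60):
            sim = generate_cohort(published_lms, cohort_groups, seed=seed)
            refits.append(fit_multistage(sim, degree=1).a1)
        med = float(np.median(refits))
        assert med == pytest.approx(published_lms.a1, rel=0.15)


class TestSerialization:
    def test_json_round_trip(self, cohort_groups, tmp_path):
        fit = fit_multistage(cohort_groups, degree=1)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        back = MultistageResults.from_json(path)
        assert back.r == pytest.approx(fit.r)
        assert back.a1 == pytest.approx(fit.a1)
        assert back.degree == fit.degree

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MultistageResults.from_params(r=1.2, coefficients=[1e-6])
        with pytest.raises(ValueError):
            MultistageResults.from_params(r=0.1, coefficients=[-1e-6])
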