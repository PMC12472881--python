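"""NCA metrics, fold errors, sensitivity analysis, objective, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sirnapbpk.evaluate_fit import (FitSpec, aafe, afe, auc_trapezoid,
                                    classify_sensitivity, monte_carlo_fit,
                                    objective_function, performance_report,
                                    sensitivity_coefficient)
from sirnapbpk.synthetic_data import (DEFAULT_TISSUE_TIMES, StudyDesign,
                                      generate_study)


class TestAuc:
    def test_constant_curve(self):
        assert auc_trapezoid([0, 5, 10], [2.0, 2.0, 2.0]) == pytest.approx(20)

    def test_single_triangle(self):
        assert auc_trapezoid([0, 1], [0, 2]) == pytest.approx(1.0)

    def test_exponential_against_closed_form(self):
        k, c0 = 0.3, 10.0
        t = np.linspace(0, 60, 2000)
        auc = auc_trapezoid(t, c0 * np.exp(-k * t))
        assert auc == pytest.approx(c0 / k, rel=5e-3)

    def test_window_restriction_and_errors(self):
        t = [0, 1, 2, 3]
        v = [1, 1, 1, 1]
        assert auc_trapezoid(t, v, 1, 3) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            auc_trapezoid(t, v, 2.5, 2.6)  # fewer than 2 points inside


class TestFoldErrors:
    def test_identical_pairs(self):
        pairs = [(3.0, 3.0), (7.0, 7.0)]
        assert afe(pairs) == pytest.approx(1.0)
        assert aafe(pairs) == pytest.approx(1.0)

    def test_reciprocal_ratios(self):
        pairs = [(2.0, 1.0), (0.5, 1.0)]
        assert afe(pairs) == pytest.approx(1.0)
        assert aafe(pairs) == pytest.approx(2.0)

    def test_acceptance_band_edges(self):
        assert not performance_report([(0.49, 1.0)])["AFE_pass"]
        assert performance_report([(0.5, 1.0)])["AFE_pass"]
        assert performance_report([(2.0, 1.0)])["AFE_pass"]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            afe([(0.0, 1.0)])

    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3),
                    min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_afe_bounded_by_aafe_and_aafe_at_least_one(self, ratios):
        pairs = [(r, 1.0) for r in ratios]
        a, aa = afe(pairs), aafe(pairs)
        assert aa >= 1.0 - 1e-12
        assert a <= aa + 1e-12 and a >= 1.0 / aa - 1e-12


class TestSensitivity:
    @pytest.mark.parametrize("s, cls", [
        (0.5, "high"), (-0.7, "high"), (0.49, "medium"), (-0.3, "medium"),
        (0.2, "medium"), (0.19, "low"), (0.1, "low"), (0.05, "negligible"),
        (0.0, "negligible")])
    def test_who_classification_bands(self, s, cls):
        assert classify_sensitivity(s) == cls

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            classify_sensitivity(float("nan"))

    def test_proportional_output_has_unit_coefficient(self, mouse_param):
        """Plasma exposure is linear in the bioavailability, so S ~ 1."""
        s = sensitivity_coefficient(mouse_param, "F", "plasma",
                                    dose_mg_per_kg=1.0, t_end=500.0,
                                    rtol=1e-6, atol=1e-10)
        assert s == pytest.approx(1.0, abs=0.02)

    def test_disconnected_parameter_has_zero_coefficient(self, mouse_param):
        """The PD potency has no pathway back into the PK."""
        s = sensitivity_coefficient(mouse_param, "SC_50", "plasma",
                                    dose_mg_per_kg=1.0, t_end=500.0,
                                    rtol=1e-6, atol=1e-10)
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_formula_matches_derivative_on_closed_form_toy(self):
        """On a one-compartment toy with AUC = F*D/CL the relative-change
        ratio matches the analytic logarithmic derivative for the linear
        parameter and detects the null parameter."""
        def auc(F, CL):
            return F * 5.0 / CL

        p0, h = 0.4, 0.1
        s_f = ((auc(p0 * (1 + h), 2.0) - auc(p0, 2.0)) / auc(p0, 2.0)) / h
        assert s_f == pytest.approx(1.0, rel=1e-12)  # d ln AUC / d ln F = 1


@pytest.fixture(scope="module")
def noiseless(mouse_param):
    design = StudyDesign(
        species="mouse", compound="siRNA-1", doses_mg_per_kg=(3.0,),
        sampling_times={"liver": DEFAULT_TISSUE_TIMES},
        conc_cv=0.0, pd_sd_pct=0.0)
    obs, _ = generate_study(design, mouse_param, seed=0,
                            rtol=1e-6, atol=1e-10)
    return obs


class TestObjectiveAndFit:
    def test_zero_loss_at_generating_truth(self, mouse_param, noiseless):
        spec = FitSpec(base=mouse_param,
                       free={"k_endosome": (5e-4, 5e-2, "log")},
                       datasets=noiseless)
        loss = objective_function(spec, spec.encode(
            {"k_endosome": mouse_param.compound.k_endosome}))
        assert loss < 1e-6

    def test_perturbation_increases_loss(self, mouse_param, noiseless):
        """Local identifiability smoke test on noiseless data."""
        spec = FitSpec(base=mouse_param,
                       free={"k_endosome": (5e-4, 5e-2, "log")},
                       datasets=noiseless)
        truth = mouse_param.compound.k_endosome
        l0 = objective_function(spec, spec.encode({"k_endosome": truth}))
        l1 = objective_function(spec, spec.encode({"k_endosome": 2 * truth}))
        l2 = objective_function(spec, spec.encode({"k_endosome": 4 * truth}))
        assert l0 < l1 < l2

    def test_out_of_bounds_is_penalized(self, mouse_param, noiseless):
        spec = FitSpec(base=mouse_param,
                       free={"k_endosome": (5e-4, 5e-2, "log")},
                       datasets=noiseless)
        assert objective_function(spec, np.array([10.0])) >= 1e9

    def test_noiseless_recovery_within_five_percent(self, mouse_param,
                                                    noiseless):
        spec = FitSpec(base=mouse_param,
                       free={"k_endosome": (5e-4, 5e-2, "log")},
                       datasets=noiseless, n_starts=3, max_iter=60)
        fit = monte_carlo_fit(spec, seed=11)
        assert fit.parameters["k_endosome"] == pytest.approx(
            mouse_param.compound.k_endosome, rel=0.05)

    def test_same_seed_reproduces_trajectory(self, mouse_param, noiseless):
        spec = FitSpec(base=mouse_param,
                       free={"k_endosome": (5e-4, 5e-2, "log")},
                       datasets=noiseless, n_starts=2, max_iter=20)
        a = monte_carlo_fit(spec, seed=5)
        b = monte_carlo_fit(spec, seed=5)
        assert a.parameters == b.parameters
        assert a.start_history == b.start_history

    def test_recovery_error_shrinks_with_noise(self, mouse_param):
        """Recovery RMSE over replicate studies decreases as the residual
        CV drops 40% -> 5%."""
        rmse = []
        truth = mouse_param.compound.F
        for cv in (0.40, 0.05):
            errs = []
            for seed in (0, 1, 2):
                design = StudyDesign(
                    species="mouse", compound="siRNA-1",
                    doses_mg_per_kg=(3.0,),
                    sampling_times={"plasma": (1.0, 4.0, 8.0, 24.0, 96.0)},
                    conc_cv=cv)
                obs, _ = generate_study(design, mouse_param, seed=seed,
                                        rtol=1e-6, atol=1e-10)
                spec = FitSpec(base=mouse_param,
                               free={"F": (0.05, 1.0, "log")},
                               datasets=obs, n_starts=2, max_iter=40)
                fit = monte_carlo_fit(spec, seed=seed + 100)
                errs.append(fit.parameters["F"] / truth - 1.0)
            rmse.append(float(np.sqrt(np.mean(np.square(errs)))))
        assert rmse[1] < rmse[0]
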