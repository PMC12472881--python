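"""Transport and elimination primitives of the whole-body ODE system."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sirnapbpk.pbpk_core import (AssemblyError, ModelConfig, PoreConfig,
                                 WholeBodyModel, endosomal_trafficking_rhs,
                                 liver_passive_permeation,
                                 renal_filtration_rate,
                                 rnase_degradation_rate, sc_absorption_rhs,
                                 two_pore_coefficients, two_pore_flux)
from sirnapbpk.physiology import load_species_physiology


@pytest.fixture(scope="module")
def liver(mouse_phys):
    return mouse_phys.organs["liver"]


class TestTwoPore:
    def test_no_solute_no_flux(self, liver):
        assert two_pore_flux(0.0, 0.0, liver, 3.0) == 0.0

    def test_full_steric_exclusion(self, liver):
        cfg = PoreConfig()
        assert two_pore_flux(5.0, 0.0, liver, cfg.r_large_nm + 1.0, cfg) == 0.0

    def test_patlak_factor_exceeds_pure_convection(self, liver):
        """With an empty interstitium the solute flux is at least the
        convective flux J_v*(1-sigma)*C_v (Patlak factor >= 1)."""
        cfg = PoreConfig(circ_factor=0.0)  # both pore fluxes outward
        a, b = two_pore_coefficients(liver, 3.0, cfg)
        flux = two_pore_flux(4.0, 0.0, liver, 3.0, cfg)
        assert flux == pytest.approx(a * 4.0)
        # convective bound from the fluid fluxes and sieving coefficients
        from sirnapbpk.pbpk_core import _hindrance
        conv = 0.0
        for r, frac in ((cfg.r_small_nm, 1 - cfg.alpha_large),
                        (cfg.r_large_nm, cfg.alpha_large)):
            _, sigma = _hindrance(3.0 / r)
            conv += frac * liver.L_lymph * (1.0 - sigma)
        assert flux >= conv * 4.0

    def test_patlak_flux_matches_numerical_pore_solution(self):
        """The analytic Patlak flux agrees with a brute-force finite
        difference solution of steady convection-diffusion in one pore."""
        u, d, length = 0.8, 0.35, 1.0  # velocity, diffusivity, path
        c0, cl = 3.0, 1.0
        n = 4000
        x = np.linspace(0, length, n)
        h = x[1] - x[0]
        # interior: u*c' = d*c''  (central differences)
        main = np.full(n, -2 * d / h ** 2)
        upper = np.full(n - 1, d / h ** 2 - u / (2 * h))
        lower = np.full(n - 1, d / h ** 2 + u / (2 * h))
        A = np.diag(main) + np.diag(upper, 1) + np.diag(lower, -1)
        A[0, :] = 0; A[0, 0] = 1
        A[-1, :] = 0; A[-1, -1] = 1
        rhs = np.zeros(n); rhs[0] = c0; rhs[-1] = cl
        c = np.linalg.solve(A, rhs)
        mid = n // 2
        dc = (c[mid + 1] - c[mid - 1]) / (2 * h)
        flux_numeric = u * c[mid] - d * dc
        pe = u * length / d
        flux_patlak = u * (c0 - cl * math.exp(-pe)) / (1 - math.exp(-pe))
        assert flux_numeric == pytest.approx(flux_patlak, rel=5e-3)

    def test_flux_is_linear_in_concentrations(self, liver):
        """The Patlak flux decomposes as a*C_v - b*C_i with positive
        coefficients (forward convection-diffusion and back-diffusion)."""
        cfg = PoreConfig()
        a, b = two_pore_coefficients(liver, 3.0, cfg)
        assert a > 0 and b > 0
        assert two_pore_flux(3.0, 1.0, liver, 3.0, cfg) == pytest.approx(
            3.0 * a - 1.0 * b)
        # gradient reversal reverses the sign when back-flux dominates
        assert two_pore_flux(0.0, 5.0, liver, 3.0, cfg) < 0

    def test_rejects_nonpositive_radius(self, liver):
        with pytest.raises(ValueError):
            two_pore_flux(1.0, 0.0, liver, 0.0)


class TestEndosomalTrafficking:
    def test_zero_uptake_endosome_never_fills(self):
        up, re = endosomal_trafficking_rhs(1.0, 1.0, 0.5, 0.0, 1e-3)
        assert up == 0.0 and re > 0.0  # endosome only drains

    def test_zero_recycle_is_a_trap(self):
        up, re = endosomal_trafficking_rhs(0.0, 1.0, 0.5, 0.1, 0.0)
        assert re == 0.0 and up > 0.0

    def test_kidney_quasi_steady_state_ratio_matches_ode_oracle(self):
        """With the tabulated kidney rates the endosome:interstitial amount
        ratio relaxes to k_uptake/k_recycle; verified against a direct
        integration of the two-state exchange subsystem."""
        k_up, k_re = 24.98, 3.90e-4  # min^-1

        def rhs(t, y):
            up, re = endosomal_trafficking_rhs(0.0, y[0], y[1], k_up, k_re)
            return [-up + re, up - re]

        sol = solve_ivp(rhs, (0, 50.0), [1.0, 0.0], method="LSODA",
                        rtol=1e-10, atol=1e-14)
        ratio = sol.y[1, -1] / sol.y[0, -1]
        assert ratio == pytest.approx(k_up / k_re, rel=1e-2)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            endosomal_trafficking_rhs(0.0, 1.0, 0.0, -0.1, 0.0)


class TestEliminations:
    def test_rnase_disabled_in_liver(self):
        assert rnase_degradation_rate(5.0, 1.17, 1.21e-4, 0.01, "liver") == 0.0

    def test_rnase_zero_concentration(self):
        assert rnase_degradation_rate(0.0, 1.17, 1.21e-4, 0.01, "kidney") == 0.0

    def test_rnase_kidney_to_remaining_abundance_ratio(self):
        r_kid = rnase_degradation_rate(2.0, 1.17, 1.21e-4, 0.01, "kidney")
        r_rem = rnase_degradation_rate(2.0, 2.75e-2, 1.21e-4, 0.01, "muscle")
        assert r_kid / r_rem == pytest.approx(1.17 / 2.75e-2, rel=1e-12)
        assert r_kid / r_rem == pytest.approx(42.5, rel=2e-3)

    def test_filtration_bounds_and_linearity(self):
        assert renal_filtration_rate(3.0, 0.0, 0.1) == 0.0
        assert renal_filtration_rate(3.0, 1.0, 0.1) == pytest.approx(0.3)
        assert renal_filtration_rate(3.0, 1.0, 0.2) == pytest.approx(
            2 * renal_filtration_rate(3.0, 1.0, 0.1))

    def test_sc_absorption_halflife(self):
        # first-order depot: t1/2 = ln2 / ka ~ 0.825 h at the mouse rate
        ka = 0.84
        assert math.log(2) / ka == pytest.approx(0.825, abs=1e-3)
        assert sc_absorption_rhs(0.0, ka) == 0.0
        assert sc_absorption_rhs(2.0, ka) == pytest.approx(1.68)

    def test_liver_passive_symmetry_and_species_ratio(self):
        assert liver_passive_permeation(2.0, 2.0, 0.02, 100.0) == 0.0
        fwd = liver_passive_permeation(3.0, 1.0, 0.02, 100.0)
        rev = liver_passive_permeation(1.0, 3.0, 0.02, 100.0)
        assert fwd == -rev and fwd > 0
        mouse = liver_passive_permeation(2.0, 0.0, 0.02, 1.0)
        human = liver_passive_permeation(2.0, 0.0, 1.21e-4, 1.0)
        assert mouse / human == pytest.approx(0.02 / 1.21e-4, rel=1e-12)
        assert mouse / human == pytest.approx(165.3, rel=1e-3)


class TestWholeBodyAssembly:
    def test_zero_state_zero_dose_rhs_vanishes(self, mouse_param):
        model = WholeBodyModel(mouse_param)
        dy = model.rhs(0.0, model.initial_state())
        assert np.allclose(dy, 0.0, atol=1e-12)

    def test_state_names_are_order_independent_addressable(self, mouse_param):
        model = WholeBodyModel(mouse_param)
        assert model.index["liver.interstitial"] != model.index["depot"]
        assert len(model.names) == len(set(model.names)) == model.n_states
        for name in ("depot", "plasma.venous", "kidney.endosomal",
                     "risc.loaded", "pd.mrna", "sink.urine"):
            assert name in model.index

    def test_missing_kdr_blocks_pd_assembly(self):
        from sirnapbpk import assemble_parameterization
        param = assemble_parameterization("siRNA-2", "mouse")  # k_DR absent
        with pytest.raises(AssemblyError, match="k_DR"):
            WholeBodyModel(param)
        model = WholeBodyModel(param, config=ModelConfig(include_pd=False))
        assert model.n_states > 0

    def test_flux_ledger_matches_state_derivative(self, mouse_param):
        """Elimination entries in the ledger equal the sink derivatives of
        the right-hand side at the same state."""
        model = WholeBodyModel(mouse_param)
        rng = np.random.default_rng(7)
        y = model.initial_state()
        y[model.drug_state_indices()] += rng.uniform(
            0, 1e-4, size=model.drug_state_indices().size)
        dy = model.rhs(0.0, y)
        led = model.flux_ledger(0.0, y)
        assert led.elimination_total() == pytest.approx(
            dy[model.sink_indices()].sum(), rel=1e-10)
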