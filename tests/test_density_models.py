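"""Registry integrity, native-space round trips, and exact linear solves."""

import dataclasses

import numpy as np
import pytest

from scfsolub import (EvaluationError, FitConfig, deterministic_fit, fit,
                      get_model, linear_fit, density_models, association_models,
                      registry, reg_dataset)
from scfsolub.models import make_env
from scfsolub.models.base import y2_to_native
from scfsolub.fitting import aard
from scfsolub.simulate import SimulationConfig, simulate

DENSITY_KEYS = [m.key for m in density_models()]


class TestRegistry:
    def test_group_counts(self):
        groups = [m.group for m in density_models()]
        assert (groups.count("I"), groups.count("II"), groups.count("III")) == (8, 12, 5)
        assert len(registry()) == 28
        assert len(association_models()) == 3

    def test_chrastil_spec(self):
        m = get_model("chrastil")
        assert m.space == "lnS"
        assert m.n_params == 3
        assert m.linear_in_params
        assert m.depends_on == frozenset({"T", "rho"})

    def test_gordillo_spec(self):
        m = get_model("gordillo")
        assert m.n_params == 6
        assert m.depends_on == frozenset({"T", "P"})

    def test_registry_keys_unique(self):
        keys = [m.key for m in registry()]
        assert len(keys) == len(set(keys))


class TestPrediction:
    def test_chrastil_constant_model(self, reg):
        # b = c = 0 collapses Chrastil to S = e^a at every state point
        m = get_model("chrastil")
        env = make_env(reg)
        y = m.predict_y2(np.array([-3.0, 0.0, 0.0]), env)
        S = env.rho * (env.m_solute / env.m_solvent) * y / (1 - y)
        assert S == pytest.approx(np.full(24, np.exp(-3.0)), rel=1e-12)

    def test_mendez_teja_reduces_to_inverse_pressure(self, reg):
        # with all coefficients zero, T ln(y2 P) = 0 so y2 = 1/P
        m = get_model("mendez_teja")
        env = make_env(reg)
        y = m.predict_y2(np.zeros(3), env)
        assert y == pytest.approx(1.0 / env.P_bar, rel=1e-12)

    @pytest.mark.parametrize("key", DENSITY_KEYS)
    def test_native_space_round_trip(self, key, reg):
        # predict y2, then map it back to the native space: must equal the
        # parameterized right-hand side of the model's own equation
        spec = get_model(key)
        params = linear_fit(spec, reg)
        env = make_env(reg)
        y = spec.predict_y2(params, env)
        env_pred = dataclasses.replace(env, y2_obs=y)
        lhs = y2_to_native(spec.space, env_pred)
        rhs = spec.native(params, env)
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)

    def test_chrastil_log_density_slope_is_association_number(self, reg):
        # at fixed T, d lnS / d ln(rho) must equal the fitted b exactly
        from scfsolub.models.base import env_from_arrays
        m = get_model("chrastil")
        params = np.array([-36.0, 7.2, -4980.0])
        rho0, T0 = 800.0, 318.0
        h = 1e-6
        envs = [env_from_arrays([T0], [200.0], [rho0 * np.exp(s * h)],
                                reg.solvent, reg.solute) for s in (-1, 1)]
        lnS = [np.log(e.rho * (e.m_solute / e.m_solvent)
                      * m.predict_y2(params, e) / (1 - m.predict_y2(params, e)))
               for e in envs]
        slope = float((lnS[1][0] - lnS[0][0]) / (2 * h))
        assert slope == pytest.approx(7.2, rel=1e-6)

    def test_evaluation_error_names_model(self, reg):
        m = get_model("andonova_garlapati")
        env = make_env(reg)
        with pytest.raises(EvaluationError, match="andonova_garlapati"):
            m.predict_y2(np.array([-1.0, 1.0, 1.0]), env)  # log of a negative prefactor


class TestLinearFit:
    def test_exact_recovery_from_noise_free_data(self):
        truth = (-36.0, 7.2, -4980.0)
        ds = simulate(SimulationConfig(model="chrastil", params=truth, sigma=0.0, seed=0))
        est = linear_fit(get_model("chrastil"), ds)
        assert est == pytest.approx(truth, rel=1e-8)

    @pytest.mark.parametrize("key", ["chrastil", "kumar_johnston", "mendez_teja"])
    def test_residuals_orthogonal_to_design(self, key, reg):
        spec = get_model(key)
        params = linear_fit(spec, reg)
        env = make_env(reg)
        X, offset = spec.design(env)
        resid = y2_to_native(spec.space, env) - offset - X @ (
            params if spec.to_linear is None else spec.to_linear(params))
        assert np.abs(X.T @ resid).max() < 1e-6 * np.abs(X).max()

    def test_bartle_temperature_coefficient_matches_vaporization_heat(self, reg):
        # the AARD-refined Bartle fit must put c near -7220 K (dH_vap ~ 60 kJ/mol)
        res = deterministic_fit(get_model("bartle"), reg)
        c = res.coefficient("c", get_model("bartle"))
        assert -c * 8.314 / 1000 == pytest.approx(60.04, rel=0.03)

    def test_multistart_matches_brute_force_grid_oracle(self, reg):
        # 3-parameter Chrastil: exhaustive coarse lattice around the OLS
        # point, refined twice, must not beat the multistart optimum by
        # more than 1e-3 in AARD
        spec = get_model("chrastil")
        env = make_env(reg)
        obs = env.y2_obs

        def objective(p):
            try:
                return aard(obs, spec.predict_y2(np.asarray(p, float), env))
            except ArithmeticError:
                return np.inf

        center = linear_fit(spec, reg)
        width = np.abs(center) * 0.5
        best = (objective(center), center)
        for _ in range(3):
            axes = [np.linspace(c - w, c + w, 9) for c, w in zip(center, width)]
            for a in axes[0]:
                for b in axes[1]:
                    for c in axes[2]:
                        val = objective((a, b, c))
                        if val < best[0]:
                            best = (val, np.array([a, b, c]))
            center, width = best[1], width / 4
        fitted = fit(spec, reg, FitConfig(n_starts=4, seed=3))
        assert fitted.aard <= best[0] + 1e-3
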