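"""AARD/scorecard metrics and the multistart fitting contract."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scfsolub import (DegeneracyError, FitConfig, ValidationError, aard,
                      adjusted_r_squared, fit, fit_report, get_model,
                      linear_fit, density_models, scorecard)
from scfsolub.fitting import r_squared
from scfsolub.models import make_env
from scfsolub.simulate import SimulationConfig, simulate


class TestAard:
    def test_identical_vectors(self):
        assert aard([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_arithmetic(self):
        assert aard([1.0, 2.0], [1.1, 1.8]) == pytest.approx(10.0, rel=1e-12)

    @given(st.floats(1e-6, 1e6))
    def test_scale_invariance(self, lam):
        obs = np.array([1.0, 2.0, 5.0])
        pred = np.array([1.2, 1.9, 5.5])
        assert aard(lam * obs, lam * pred) == pytest.approx(aard(obs, pred), rel=1e-9)

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(ValidationError):
            aard([1.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            aard([1.0], [1.0, 2.0])


class TestScorecard:
    def test_perfect_fit(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        card = scorecard(obs, obs, q=2)
        assert (card.aard, card.r2, card.r_adj, card.sse, card.rmse) == (0, 1, 1, 0, 0)

    def test_adjusted_r2_hand_arithmetic(self):
        # |0.879 - 2 * 0.121 / 21|
        assert adjusted_r_squared(0.879, n=24, q=2) == pytest.approx(0.8674761904761905)

    def test_adjusted_r2_degenerate(self):
        with pytest.raises(DegeneracyError):
            adjusted_r_squared(0.9, n=3, q=2)

    def test_sse_equals_rmse_squared(self):
        rng = np.random.default_rng(0)
        obs = np.abs(rng.normal(1, 0.1, 20))
        pred = obs * (1 + 0.05 * rng.standard_normal(20))
        card = scorecard(obs, pred, q=2)
        assert card.sse == pytest.approx(card.rmse ** 2, rel=1e-14)
        assert card.rmse_mean == pytest.approx(card.rmse / np.sqrt(20), rel=1e-14)


class TestFit:
    def test_reproducible_bit_for_bit(self, reg):
        cfg = FitConfig(n_starts=6, seed=42)
        a = fit(get_model("gordillo"), reg, cfg)
        b = fit(get_model("gordillo"), reg, cfg)
        assert np.array_equal(a.params, b.params)
        assert a.aard == b.aard

    @pytest.mark.parametrize("key", ["chrastil", "gordillo", "assoc_pressure"])
    def test_improves_on_linear_initializer(self, key, reg, fast_config):
        spec = get_model(key)
        env = make_env(reg)
        ols = linear_fit(spec, reg)
        ols_aard = aard(env.y2_obs, spec.predict_y2(ols, env))
        result = fit(spec, reg, fast_config)
        assert result.aard <= ols_aard + 1e-9

    def test_metrics_recompute_from_stored_predictions(self, reg, fast_config):
        res = fit(get_model("reddy"), reg, fast_config)
        card = scorecard(make_env(reg).y2_obs, res.predicted, q=res.q)
        assert res.aard == pytest.approx(card.aard, rel=1e-12)
        assert res.sse == pytest.approx(card.sse, rel=1e-12)
        assert res.r2 == pytest.approx(card.r2, rel=1e-12)

    def test_noise_free_data_fits_exactly(self):
        ds = simulate(SimulationConfig(model="chrastil", params=(-36.0, 7.2, -4980.0),
                                       sigma=0.0, seed=0))
        res = fit(get_model("chrastil"), ds, FitConfig(n_starts=1, seed=0))
        assert res.aard < 1e-6

    def test_too_few_points_rejected(self, reg):
        tiny = reg.subset(308.0)  # 6 points
        with pytest.raises(DegeneracyError):
            fit(get_model("belghait"), tiny)  # 8 parameters

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            FitConfig(objective="nope")
        with pytest.raises(ValidationError):
            FitConfig(n_starts=0)


class TestFitReport:
    def test_full_density_battery_layout(self, reg, fast_config):
        report = fit_report(reg, density_models(), fast_config)
        model_rows = report[~report["model"].str.startswith("average")]
        avg_rows = report[report["model"].str.startswith("average")]
        assert len(model_rows) == 25
        assert len(avg_rows) == 3
        assert model_rows["converged"].all()
        assert (avg_rows["AARD_pct"] > 0).all()

    def test_empty_subset(self, reg, fast_config):
        assert fit_report(reg, [], fast_config).empty


def test_printed_r2_variant_differs_from_standard(reg, fast_config):
    res = fit(get_model("chrastil"), reg, fast_config)
    from scfsolub.fitting import r_squared_printed
    obs = make_env(reg).y2_obs
    assert r_squared(obs, res.predicted) != pytest.approx(
        r_squared_printed(obs, res.predicted), abs=1e-6)
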