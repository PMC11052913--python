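"""Data model, CSV round trips, and the sampling/solubility conversions."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scfsolub import (CO2, REGORAFENIB, ParseError, SamplingSetup,
                      SolubilityDataset, SolubilityRecord, ValidationError,
                      expanded_uncertainty, load_dataset,
                      mole_fraction_from_sampling, recomputed_solubility,
                      save_dataset, solubility_gL_from_y2, y2_from_solubility_gL)


class TestFixture:
    def test_shape_and_isotherms(self, reg):
        assert len(reg) == 24
        assert reg.temperatures == (308.0, 318.0, 328.0, 338.0)
        assert all(len(v) == 6 for v in reg.isotherms().values())

    def test_extreme_row_read_back(self, reg):
        last = reg.records[-1]
        assert (last.T, last.P) == (338.0, 270.0)
        assert last.rho == 783.0
        assert last.y2 == pytest.approx(6.44e-6, rel=1e-12)

    def test_mole_fraction_range(self, reg):
        y = reg.arrays()["y2"]
        assert y.min() == pytest.approx(3.1e-7)
        assert y.max() == pytest.approx(6.44e-6)

    def test_isothermal_monotonicity_in_pressure(self, reg):
        # within each isotherm both y2 and the solvent density rise with P
        for recs in reg.isotherms().values():
            y = [r.y2 for r in recs]
            rho = [r.rho for r in recs]
            assert all(a < b for a, b in zip(y, y[1:]))
            assert all(a < b for a, b in zip(rho, rho[1:]))

    def test_density_falls_with_temperature_at_fixed_pressure(self, reg):
        by_P = {}
        for r in reg.records:
            by_P.setdefault(r.P, []).append((r.T, r.rho))
        for rows in by_P.values():
            rows.sort()
            assert all(a[1] > b[1] for a, b in zip(rows, rows[1:]))

    def test_stored_solubility_column_is_flagged_inconsistent(self, reg):
        gaps = recomputed_solubility(reg)["relative_gap"].abs()
        assert gaps.notna().all()
        assert gaps.max() > 0.01  # stored g/L column disagrees with the y2 column


class TestIO:
    def test_round_trip(self, reg, tmp_path):
        path = tmp_path / "ds.csv"
        save_dataset(reg, path)
        again = load_dataset(path, solute=REGORAFENIB, solvent=CO2)
        assert again == reg

    def test_invalid_mole_fraction_names_field_and_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_bar,rho_kg_m3,y2\n308,120,769,1.5\n")
        with pytest.raises(ValidationError, match="y2"):
            load_dataset(path, solute=REGORAFENIB, solvent=CO2)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_bar,rho_kg_m3,y2\n308,oops,769,1e-6\n")
        with pytest.raises((ParseError, ValidationError), match="line 2"):
            load_dataset(path, solute=REGORAFENIB, solvent=CO2)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_bar,rho_kg_m3\n308,120,769\n")
        with pytest.raises(ParseError, match="y2"):
            load_dataset(path, solute=REGORAFENIB, solvent=CO2)

    def test_duplicate_state_point_rejected(self):
        rec = SolubilityRecord(T=308, P=120, rho=769, y2=1e-6)
        with pytest.raises(ValidationError, match="duplicate"):
            SolubilityDataset(records=(rec, rec), solute=REGORAFENIB, solvent=CO2)


class TestSamplingConversion:
    def test_zero_concentration_gives_zero(self):
        setup = SamplingSetup(loop_volume=6e-4, collection_volume=6e-3, concentration=0.0)
        assert mole_fraction_from_sampling(setup, 783.0, 44.01, 500.83) == 0.0

    def test_hand_arithmetic(self):
        # n_solute = 0.05*0.006/500.83, n_solvent = 0.0006*783/44.01
        setup = SamplingSetup(loop_volume=6e-4, collection_volume=6e-3, concentration=0.05)
        y2 = mole_fraction_from_sampling(setup, 783.0, 44.01, 500.83)
        assert y2 == pytest.approx(5.990056506199709e-07
                                   / (0.01067484662576687 + 5.990056506199709e-07), rel=1e-12)
        assert y2 == pytest.approx(5.611059915448557e-05, rel=1e-9)

    def test_scale_invariance(self):
        base = SamplingSetup(loop_volume=6e-4, collection_volume=6e-3, concentration=0.05)
        doubled = SamplingSetup(loop_volume=1.2e-3, collection_volume=1.2e-2, concentration=0.05)
        y1 = mole_fraction_from_sampling(base, 783.0, 44.01, 500.83)
        y2 = mole_fraction_from_sampling(doubled, 783.0, 44.01, 500.83)
        assert y1 == pytest.approx(y2, rel=1e-14)


class TestSolubilityConversion:
    def test_zero(self):
        assert solubility_gL_from_y2(783.0, 0.0, 44.01, 500.83) == 0.0

    def test_hand_arithmetic(self):
        S = solubility_gL_from_y2(783.0, 6.44e-6, 44.01, 500.83)
        assert S == pytest.approx(5.73838117603367e-2, rel=1e-12)

    def test_rejects_saturated_fraction(self):
        with pytest.raises(ValidationError):
            solubility_gL_from_y2(783.0, 1.0, 44.01, 500.83)

    def test_fixture_round_trip(self, reg):
        for r in reg.records:
            S = solubility_gL_from_y2(r.rho, r.y2, 44.01, 500.83)
            back = y2_from_solubility_gL(r.rho, S, 44.01, 500.83)
            assert back == pytest.approx(r.y2, rel=1e-12)

    @given(y2=st.floats(1e-9, 0.5), rho=st.floats(100.0, 1000.0))
    def test_round_trip_property(self, y2, rho):
        S = solubility_gL_from_y2(rho, y2, 44.01, 500.83)
        assert y2_from_solubility_gL(rho, S, 44.01, 500.83) == pytest.approx(y2, rel=1e-12)


class TestExpandedUncertainty:
    def test_single_term(self):
        assert expanded_uncertainty([(1.0, 0.01)], y=100.0, k=2.0) == pytest.approx(2.0)

    def test_two_equal_terms(self):
        U = expanded_uncertainty([(1.0, 0.03), (1.0, 0.03)], y=1.0, k=2.0)
        assert U == pytest.approx(2 * 0.03 * math.sqrt(2.0), rel=1e-12)

    def test_zero_uncertainties(self):
        assert expanded_uncertainty([(1.0, 0.0), (2.0, 0.0)], y=5.0) == 0.0

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            expanded_uncertainty([], y=1.0)
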