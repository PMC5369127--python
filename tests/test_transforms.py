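"""Dose arithmetic and sub-indicator construction."""

import numpy as np
import pytest

from cumrisk import build_referent_grid
from cumrisk.grid import RasterField
from cumrisk.transforms import (AgeClass, ExposureFactors, SubIndicator,
                                ToxicityTable, air_concentration_indicator,
                                average_daily_dose, combine_equity,
                                emission_score, hazard_quotient,
                                noise_indicator, soil_concentration_indicator,
                                water_exceedance_score)


def _field(grid, values, mask=None, name="f"):
    return RasterField(grid=grid, values=np.asarray(values, dtype=float),
                       mask=mask, name=name)


class TestDoseArithmetic:
    def test_add_direct_value(self):
        assert average_daily_dose(100.0, 1e-4, 1.0, 15.0) == \
            pytest.approx(6.6667e-4, rel=1e-4)

    def test_add_zero_concentration(self):
        assert average_daily_dose(0.0, 1e-4, 1.0, 15.0) == 0.0

    def test_add_linear_in_concentration(self):
        one = average_daily_dose(50.0, 5e-5, 0.5, 70.0)
        assert average_daily_dose(100.0, 5e-5, 0.5, 70.0) == pytest.approx(2 * one)

    def test_add_rejects_bad_body_weight(self):
        with pytest.raises(ValueError):
            average_daily_dose(1.0, 1e-4, 1.0, 0.0)

    @pytest.mark.parametrize("add, rfd, hq", [
        (0.001, 0.001, 1.0), (0.0, 0.5, 0.0), (0.002, 0.001, 2.0)])
    def test_hazard_quotient(self, add, rfd, hq):
        assert hazard_quotient(add, rfd) == pytest.approx(hq)

    def test_hazard_quotient_rejects_nonpositive_rfd(self):
        with pytest.raises(ValueError):
            hazard_quotient(1.0, 0.0)


class TestSoilIndicator:
    def _tox(self):
        return ToxicityTable(rfd={"A": 1e-3, "B": 1e-3})

    def _factors_one_class(self):
        return ExposureFactors([AgeClass("c", 1e-4, 1.0, 15.0)])

    def test_two_pollutants_sum(self, small_grid):
        # choose concentration so each pollutant gives cellwise HQ = 1
        conc = 1e-3 * 15.0 / 1e-4
        fields = {p: _field(small_grid, np.full(small_grid.shape, conc))
                  for p in ("A", "B")}
        out = soil_concentration_indicator(fields, self._factors_one_class(),
                                           self._tox())
        assert np.allclose(out.field.values, 2.0)

    def test_single_pollutant_equals_hq(self, small_grid):
        conc = np.full(small_grid.shape, 37.0)
        out = soil_concentration_indicator(
            {"A": _field(small_grid, conc)}, self._factors_one_class(),
            self._tox())
        expected = hazard_quotient(
            average_daily_dose(37.0, 1e-4, 1.0, 15.0), 1e-3)
        assert np.allclose(out.field.values, expected)

    def test_max_over_age_classes(self, small_grid):
        # three age classes engineered to give summed HQs 0.5, 1.2, 0.8
        factors = ExposureFactors([
            AgeClass("a", 0.5e-4, 1.0, 15.0),
            AgeClass("b", 1.2e-4, 1.0, 15.0),
            AgeClass("c", 0.8e-4, 1.0, 15.0)])
        conc = 1e-3 * 15.0 / 1e-4
        out = soil_concentration_indicator(
            {"A": _field(small_grid, np.full(small_grid.shape, conc))},
            factors, self._tox())
        assert np.allclose(out.field.values, 1.2)

    def test_missing_rfd_rejected(self, small_grid):
        with pytest.raises(KeyError, match="Zn"):
            soil_concentration_indicator(
                {"Zn": _field(small_grid, np.ones(small_grid.shape))},
                self._factors_one_class(), self._tox())

    def test_monotone_in_concentration(self, small_grid):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 50, small_grid.shape)
        lo = soil_concentration_indicator({"A": _field(small_grid, base)},
                                          self._factors_one_class(), self._tox())
        hi_vals = base.copy()
        hi_vals[3, 4] += 10.0
        hi = soil_concentration_indicator({"A": _field(small_grid, hi_vals)},
                                          self._factors_one_class(), self._tox())
        assert np.all(hi.field.values >= lo.field.values - 1e-15)
        assert hi.field.values[3, 4] > lo.field.values[3, 4]


class TestAirIndicator:
    def test_unit_ratios(self, small_grid):
        tox = ToxicityTable(air_standard={"X": 10.0, "Y": 20.0, "Z": 5.0})
        fields = {p: _field(small_grid, np.full(small_grid.shape, s))
                  for p, s in (("X", 10.0), ("Y", 20.0), ("Z", 5.0))}
        out = air_concentration_indicator(fields, tox)
        assert np.allclose(out.field.values, 3.0)

    def test_direct_arithmetic(self, small_grid):
        tox = ToxicityTable(air_standard={"X": 40.0, "Y": 40.0})
        fields = {"X": _field(small_grid, np.full(small_grid.shape, 20.0)),
                  "Y": _field(small_grid, np.full(small_grid.shape, 40.0))}
        assert np.allclose(air_concentration_indicator(fields, tox).field.values,
                           1.5)

    def test_zero_concentrations(self, small_grid):
        tox = ToxicityTable(air_standard={"X": 40.0})
        out = air_concentration_indicator(
            {"X": _field(small_grid, np.zeros(small_grid.shape))}, tox)
        assert np.allclose(out.field.values, 0.0)

    def test_linear_in_each_pollutant(self, small_grid):
        rng = np.random.default_rng(2)
        tox = ToxicityTable(air_standard={"X": 40.0, "Y": 30.0})
        x = rng.uniform(0, 50, small_grid.shape)
        y = rng.uniform(0, 50, small_grid.shape)
        base = air_concentration_indicator(
            {"X": _field(small_grid, x), "Y": _field(small_grid, y)}, tox)
        doubled = air_concentration_indicator(
            {"X": _field(small_grid, 2 * x), "Y": _field(small_grid, y)}, tox)
        np.testing.assert_allclose(doubled.field.values - base.field.values,
                                   x / 40.0, atol=1e-12)

    def test_missing_standard_rejected(self, small_grid):
        with pytest.raises(KeyError):
            air_concentration_indicator(
                {"Q": _field(small_grid, np.ones(small_grid.shape))},
                ToxicityTable())


class TestEmissionScore:
    _TOX = ToxicityTable(cancer_weight={"p": 1.0, "q": 0.0},
                         noncancer_weight={"p": 0.0, "q": 1.0})

    def test_hand_computed_equal_weight_average(self):
        # 1×3 grid; p = (0,2,1), q = (0,4,3):
        #   T  = (0,6,4) → scaled (0, 1, 2/3)
        #   Wc = (0,2,1) → scaled (0, 1, 1/2)
        #   Wn = (0,4,3) → scaled (0, 1, 3/4)
        # equal-weight mean  → (0, 1, (2/3 + 1/2 + 3/4)/3)
        g = build_referent_grid((0, 0, 3000, 1000), 1000)
        fields = {"p": _field(g, [[0.0, 2.0, 1.0]]),
                  "q": _field(g, [[0.0, 4.0, 3.0]])}
        out = emission_score(fields, self._TOX)
        np.testing.assert_allclose(
            out.field.values, [[0.0, 1.0, (2 / 3 + 0.5 + 0.75) / 3]],
            atol=1e-12)

    def test_minmax_endpoints(self):
        g = build_referent_grid((0, 0, 2000, 1000), 1000)
        out = emission_score({"p": _field(g, [[0.0, 5.0]]),
                              "q": _field(g, [[0.0, 3.0]])}, self._TOX)
        np.testing.assert_allclose(out.field.values, [[0.0, 1.0]])

    def test_single_cell_degenerate_domain_warns(self):
        g = build_referent_grid((0, 0, 1000, 1000), 1000)
        with pytest.warns(UserWarning, match="constant"):
            out = emission_score({"p": _field(g, [[3.0]])}, self._TOX)
        assert out.field.values[0, 0] == 0.0

    def test_scores_within_unit_interval(self, small_grid):
        rng = np.random.default_rng(3)
        fields = {p: _field(small_grid, rng.lognormal(0, 1, small_grid.shape))
                  for p in ("p", "q")}
        out = emission_score(fields, self._TOX)
        assert out.field.values.min() >= 0.0
        assert out.field.values.max() <= 1.0


class TestWaterScore:
    def test_four_year_average(self):
        assert water_exceedance_score([[1, 2, 3, 3]])[0] == pytest.approx(2.25)

    def test_all_zero(self):
        assert water_exceedance_score([[0, 0, 0, 0]])[0] == 0.0

    def test_single_year_identity(self):
        assert water_exceedance_score([[4]], n_years=1)[0] == 4.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            water_exceedance_score([[1, -1, 0, 0]])

    def test_matches_brute_force_threshold_counting(self):
        # raw concentration table → per-substance, per-year exceedance flags
        rng = np.random.default_rng(7)
        thresholds = {"As": 10.0, "F": 1.5}
        n_units, n_years = 6, 4
        conc = {s: rng.uniform(0, 2 * t, size=(n_units, n_years))
                for s, t in thresholds.items()}
        counts = np.zeros((n_units, n_years), dtype=int)
        for s, t in thresholds.items():
            counts += conc[s] > t
        brute = np.array([[sum(conc[s][u, y] > thresholds[s]
                               for s in thresholds)
                           for y in range(n_years)]
                          for u in range(n_units)]).sum(axis=1) / n_years
        np.testing.assert_allclose(water_exceedance_score(counts), brute)


class TestNoiseIndicator:
    def test_value_and_mask_passthrough(self, small_grid):
        rng = np.random.default_rng(4)
        mask = rng.random(small_grid.shape) < 0.1
        vals = np.where(mask, 68.0, 0.0)
        out = noise_indicator(_field(small_grid, vals, mask=mask))
        assert out.field.values[mask][0] == 68.0
        np.testing.assert_array_equal(out.field.mask, mask)

    def test_negative_lden_rejected(self, small_grid):
        with pytest.raises(ValueError):
            noise_indicator(_field(small_grid, np.full(small_grid.shape, -1.0)))


class TestCombineEquity:
    def test_identical_inputs_double(self, small_grid):
        from cumrisk.standardize import standardize_sub_indicator

        rng = np.random.default_rng(5)
        sub = SubIndicator(field=_field(small_grid,
                                        rng.uniform(0, 9, small_grid.shape)),
                           dimension="air_conc")
        combined = combine_equity(sub, sub, method="percentile_rank")
        single = standardize_sub_indicator(sub, "percentile_rank")
        np.testing.assert_allclose(combined.values, 2 * single.field.values,
                                   atol=1e-12)

    def test_equity_of_means_and_range(self, small_grid):
        from cumrisk.standardize import standardize_sub_indicator

        rng = np.random.default_rng(6)
        a = SubIndicator(field=_field(small_grid,
                                      rng.lognormal(0, 2, small_grid.shape)),
                         dimension="air_conc")
        b = SubIndicator(field=_field(small_grid,
                                      rng.uniform(0, 1, small_grid.shape)),
                         dimension="emission")
        for method in ("normal_score", "percentile_rank"):
            sa = standardize_sub_indicator(a, method)
            sb = standardize_sub_indicator(b, method)
            assert abs(sa.field.values.mean() - sb.field.values.mean()) < 1e-9
            combined = combine_equity(a, b, method=method)
            assert combined.values.min() >= 0.0
            assert combined.values.max() <= 2.0

    def test_grid_mismatch_rejected(self, small_grid):
        other = build_referent_grid((0, 0, 5000, 5000), 1000)
        a = SubIndicator(field=_field(small_grid, np.ones(small_grid.shape)),
                         dimension="air_conc")
        b = SubIndicator(field=RasterField(grid=other, values=np.ones(other.shape)),
                         dimension="emission")
        with pytest.raises(ValueError, match="grid"):
            combine_equity(a, b)
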