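"""Plate normalization, Hill fitting and IC50/MV statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistx import (
    AbsoluteIC50,
    DoseSeries,
    HillFit,
    NormalizationError,
    absolute_ic50,
    fit_hill,
    fit_table,
    hill_curve,
    mean_viability,
    normalize_plate,
)
from resistx.doseresp import read_plate_csv


class TestNormalizePlate:
    def test_viability_is_ratio_to_vehicle_median(self, simple_plate):
        series = normalize_plate(simple_plate)
        assert len(series) == 1
        s = series[0]
        # vehicle median is 100k: 100k/50k/10k/0 -> 1.0/0.5/0.1/0.0
        np.testing.assert_allclose(s.viability, [1.0, 0.5, 0.1, 0.0])
        assert s.compound == "drug" and s.cell_line == "L"

    def test_vehicle_median_normalizes_to_exactly_one(self, simple_plate):
        # normalization divides by the vehicle median, so re-dividing the
        # vehicle signals themselves must give a median of exactly 1.0
        veh = simple_plate[simple_plate["is_vehicle"]]["signal"]
        assert np.median(veh / veh.median()) == 1.0

    def test_per_plate_scaling(self, simple_plate):
        second = simple_plate.copy()
        second["plate_id"] = "P2"
        second["signal"] *= 7.0  # different gain, same biology
        series = normalize_plate(pd.concat([simple_plate, second],
                                           ignore_index=True))
        s = series[0]
        np.testing.assert_allclose(s.viability,
                                   [1.0, 1.0, 0.5, 0.5, 0.1, 0.1, 0.0, 0.0])

    def test_no_vehicle_wells_is_an_error(self, simple_plate):
        treated = simple_plate[~simple_plate["is_vehicle"]]
        with pytest.raises(NormalizationError, match="P1"):
            normalize_plate(treated)

    def test_zero_vehicle_median_is_degenerate(self, simple_plate):
        bad = simple_plate.copy()
        bad.loc[bad["is_vehicle"], "signal"] = 0.0
        with pytest.raises(NormalizationError, match="degenerate"):
            normalize_plate(bad)

    def test_schema_validation(self, simple_plate, tmp_path):
        bad = simple_plate.copy()
        bad.loc[3, "dose_uM"] = -1.0
        with pytest.raises(ValueError, match="negative dose|is_vehicle"):
            normalize_plate(bad)
        path = tmp_path / "p.csv"
        simple_plate.drop(columns=["signal"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_plate_csv(path)


class TestFitHill:
    def test_recovers_generating_parameters_on_clean_data(self, clean_series):
        fit = fit_hill(clean_series)
        assert fit.converged
        assert fit.top == pytest.approx(1.0, abs=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-6)
        assert fit.ec50 == pytest.approx(1.0, rel=1e-6)
        assert fit.slope == pytest.approx(1.0, rel=1e-6)

    def test_robust_downweights_single_outlier(self, doses9):
        d = np.repeat(doses9, 4)
        v = hill_curve(d, 1.0, 0.0, 1.0, 1.0).copy()
        i = 13
        v[i] *= 5.0
        series = DoseSeries("c", "l", d, v)
        robust = fit_hill(series, robust=True)
        ordinary = fit_hill(series, robust=False)
        assert robust.weights[i] < 0.05
        assert abs(robust.ec50 - 1.0) < 0.05
        assert abs(ordinary.ec50 - 1.0) > 2 * abs(robust.ec50 - 1.0)

    def test_robust_with_clean_data_matches_ordinary(self, doses9):
        rng = np.random.default_rng(42)
        d = np.repeat(doses9, 4)
        v = hill_curve(d, 1.0, 0.1, 0.5, 1.5) * rng.lognormal(0, 0.02, d.size)
        series = DoseSeries("c", "l", d, v)
        f_r = fit_hill(series, robust=True)
        f_o = fit_hill(series, robust=False)
        # symmetric small noise: biweight should not move the fit much
        assert f_r.ec50 == pytest.approx(f_o.ec50, rel=0.02)

    def test_flat_data_flagged_unidentifiable(self, doses9):
        d = np.repeat(doses9, 4)
        series = DoseSeries("c", "l", d, np.ones_like(d))
        fit = fit_hill(series)
        assert not fit.identifiable
        assert fit.top == pytest.approx(1.0, abs=0.01)
        assert fit.bottom == pytest.approx(1.0, abs=0.01)
        assert not absolute_ic50(fit, doses9).reached

    def test_fitted_curve_is_monotone_non_increasing(self, doses9):
        rng = np.random.default_rng(7)
        d = np.repeat(doses9, 4)
        v = hill_curve(d, 1.0, 0.2, 2.0, 1.2) * rng.lognormal(0, 0.05, d.size)
        fit = fit_hill(DoseSeries("c", "l", d, v))
        grid = np.geomspace(doses9[0], doses9[-1], 200)
        pred = fit.predict(grid)
        assert np.all(np.diff(pred) <= 1e-12)
        assert np.all(pred >= fit.bottom - 1e-9)
        assert np.all(pred <= fit.top + 1e-9)

    def test_too_few_doses_rejected(self):
        d = np.array([0.1, 1.0, 10.0])
        with pytest.raises(ValueError, match="4 distinct doses"):
            fit_hill(DoseSeries("c", "l", d, np.ones(3)))

    def test_parameter_recovery_under_noise(self, doses9):
        # quadruplicate, multiplicative noise CV 5%: EC50 comes back with
        # median relative error well under 10%
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            d = np.repeat(doses9, 4)
            v = hill_curve(d, 1, 0, 1, 1) * rng.lognormal(0, 0.05, d.size)
            errors.append(abs(fit_hill(DoseSeries("c", "l", d, v)).ec50 - 1))
        assert np.median(errors) < 0.10


class TestAbsoluteIC50:
    def test_midpoint_symmetry(self, doses9):
        fit = HillFit(top=1, bottom=0, ec50=1.0, slope=1.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=True)
        res = absolute_ic50(fit, doses9)
        assert res.value == pytest.approx(1.0)
        assert not res.extrapolated

    def test_insufficient_inhibition_not_reached(self, doses9):
        fit = HillFit(top=1, bottom=0.6, ec50=1.0, slope=2.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=True)
        assert not absolute_ic50(fit, doses9).reached

    def test_closed_form_inversion(self, doses9):
        # d = ec50 * ((top - 0.5)/(0.5 - bottom))**(1/slope); verified by
        # bisection on the curve itself
        from scipy.optimize import brentq
        fit = HillFit(top=1, bottom=0.2, ec50=0.5, slope=2.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=True)
        res = absolute_ic50(fit, doses9)
        assert res.value == pytest.approx(0.6455, abs=2e-4)
        root = brentq(lambda d: float(fit.predict(d)) - 0.5, 1e-6, 1e3)
        assert res.value == pytest.approx(root, rel=1e-10)

    def test_extrapolation_flag(self):
        fit = HillFit(top=1, bottom=0, ec50=100.0, slope=1.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=True)
        res = absolute_ic50(fit, np.array([0.01, 0.1, 1.0, 10.0]))
        assert res.reached and res.extrapolated

    def test_unconverged_fit_rejected(self, doses9):
        fit = HillFit(top=1, bottom=0, ec50=1.0, slope=1.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            absolute_ic50(fit, doses9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(slope=st.floats(0.2, 8.0), ec50=st.floats(1e-3, 1e3))
    def test_equals_ec50_for_full_range_curve(self, slope, ec50):
        fit = HillFit(top=1.0, bottom=0.0, ec50=ec50, slope=slope,
                      robust=False, weights=np.ones(1), rss=0.0,
                      converged=True)
        res = absolute_ic50(fit, [ec50 / 10, ec50 * 10])
        assert res.value == pytest.approx(ec50, rel=1e-12)


class TestMeanViability:
    @pytest.mark.parametrize("level,expected", [(1.0, 1.0), (0.0, 0.0)])
    def test_flat_curve(self, doses9, level, expected):
        fit = HillFit(top=level, bottom=level, ec50=1.0, slope=1.0,
                      robust=False, weights=np.ones(1), rss=0.0,
                      converged=True, identifiable=False)
        assert mean_viability(fit, doses9) == pytest.approx(expected)

    def test_matches_hand_evaluated_curve_mean(self, doses9):
        # ec50 at the geometric middle dose of the 3-fold series
        ec50 = doses9[4]
        fit = HillFit(top=1, bottom=0, ec50=ec50, slope=1.0, robust=False,
                      weights=np.ones(1), rss=0.0, converged=True)
        expected = np.mean(1.0 / (1.0 + doses9 / ec50))
        assert mean_viability(fit, doses9) == pytest.approx(expected,
                                                            rel=1e-12)
        assert 0.0 <= mean_viability(fit, doses9) <= 1.0


def test_fit_table_roundtrip(tmp_path, simple_plate, doses9):
    rng = np.random.default_rng(0)
    d = np.repeat(doses9, 4)
    series = [
        DoseSeries("a", "L", d,
                   hill_curve(d, 1, 0, 1, 1) * rng.lognormal(0, 0.03, d.size)),
        DoseSeries("b", "L", d,
                   hill_curve(d, 1, 0.7, 1, 1) * rng.lognormal(0, 0.03, d.size)),
    ]
    table = fit_table(series)
    assert list(table["compound"]) == ["a", "b"]
    assert table.loc[0, "ic50_reached"]
    assert not table.loc[1, "ic50_reached"]  # max inhibition ~30% < 50%
    assert table["converged"].all()
    path = tmp_path / "fits.csv"
    from resistx.doseresp import write_fit_table
    write_fit_table(table, path)
    back = pd.read_csv(path)
    assert back.loc[0, "ec50_uM"] == pytest.approx(table.loc[0, "ec50_uM"],
                                                   rel=1e-4)
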