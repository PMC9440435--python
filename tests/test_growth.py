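"""Growth dynamics: model fitting and selection, Timemax extraction,
GR / WUE arithmetic, tolerance indices and rescaling."""

import numpy as np
import pandas as pd
import pytest

from wheatpheno.growth import (
    MODEL_FORMS,
    GrowthFit,
    bell,
    extract_timemax,
    fit_growth_models,
    growth_rate,
    index_table,
    rescale_and_cluster,
    select_growth_model,
    tolerance_indices,
    water_use_efficiency,
)


def _series(das, values):
    return pd.DataFrame({"das": das, "value": values})


def _bell_fit(biomass, timemax, a=None, b=None, c=5.0, r2=0.95):
    """GrowthFit stub with a consistent bell parameterization."""
    return GrowthFit(
        model_name="bell",
        parameters={"a": a if a is not None else biomass,
                    "b": b if b is not None else timemax, "c": c},
        r_squared=r2,
        fit_p_value=1e-6,
        timemax=timemax,
        biomass_at_timemax=biomass,
        window=(24.0, 41.0),
        converged=True,
    )


class TestFitting:
    def test_noiseless_bell_recovered_exactly(self):
        das = np.arange(24, 42)
        fits = fit_growth_models(_series(das, bell(das, 20.0, 38.0, 6.0)),
                                 models=("bell",))
        f = fits[0]
        assert f.parameters["a"] == pytest.approx(20.0, rel=1e-6)
        assert f.parameters["b"] == pytest.approx(38.0, rel=1e-6)
        assert abs(f.parameters["c"]) == pytest.approx(6.0, rel=1e-6)
        assert f.r_squared == pytest.approx(1.0)
        assert f.fit_p_value < 1e-12

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(0)
        das = np.arange(24, 42)
        errors = []
        for _ in range(20):
            y = bell(das, 20.0, 38.0, 6.0) + rng.normal(0, 0.4, len(das))
            f = fit_growth_models(_series(das, np.clip(y, 0, None)),
                                  models=("bell",))[0]
            errors.append(
                [abs(f.parameters["a"] - 20) / 20,
                 abs(f.parameters["b"] - 38) / 38,
                 abs(abs(f.parameters["c"]) - 6) / 6]
            )
        assert (np.median(errors, axis=0) <= 0.05).all()

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="5 timepoints"):
            fit_growth_models(_series([25, 26, 27], [1, 2, 3]))

    def test_nonconvergence_recorded_not_fatal(self):
        das = np.arange(24, 40)
        y = bell(das, 20.0, 38.0, 6.0)
        fits = fit_growth_models(_series(das, y))
        assert {f.model_name for f in fits} == set(MODEL_FORMS)
        assert all(isinstance(f.converged, bool) for f in fits)


class TestSelection:
    def test_highest_r_squared_wins(self):
        a = _bell_fit(20.0, 37.0, r2=0.95)
        b = _bell_fit(20.0, 37.0, r2=0.88)
        assert select_growth_model([b, a]) is a

    def test_none_passing_gives_explicit_no_model(self):
        a = _bell_fit(20.0, 37.0, r2=0.5)
        b = _bell_fit(20.0, 37.0, r2=0.6)
        assert select_growth_model([a, b]) is None

    def test_bell_beats_linear_on_bell_data(self):
        rng = np.random.default_rng(1)
        das = np.arange(24, 42)
        y = bell(das, 20.0, 36.0, 5.0) + rng.normal(0, 0.4, len(das))
        fits = fit_growth_models(_series(das, np.clip(y, 0, None)),
                                 models=("bell", "linear", "exponential"))
        assert select_growth_model(fits).model_name == "bell"


class TestTimemax:
    def test_printed_pairing_bell_peak_inside_window(self):
        fit = _bell_fit(23.5, np.nan, a=23.5, b=37.0, c=5.0)
        tmax, bmax = extract_timemax(fit, (30.0, 41.0))
        assert tmax == 37.0
        assert bmax == pytest.approx(23.5)

    def test_peak_beyond_window_clamped(self):
        fit = _bell_fit(20.0, np.nan, a=20.0, b=45.0, c=5.0)
        tmax, bmax = extract_timemax(fit, (30.0, 41.0))
        assert tmax == 41.0
        assert bmax == pytest.approx(bell(41.0, 20.0, 45.0, 5.0))

    def test_monotone_logistic_argmax_at_boundary(self):
        fit = GrowthFit(
            model_name="logistic",
            parameters={"a": 20.0, "k": 0.5, "t0": 33.0},
            r_squared=0.99, fit_p_value=1e-9,
            timemax=np.nan, biomass_at_timemax=np.nan,
            window=(30.0, 41.0), converged=True,
        )
        tmax, _ = extract_timemax(fit, (30.0, 41.0))
        assert tmax == pytest.approx(41.0)

    @pytest.mark.parametrize("name,params", [
        ("bell", {"a": 20.0, "b": 36.5, "c": 5.0}),
        ("logistic", {"a": 18.0, "k": 0.4, "t0": 31.0}),
        ("gompertz", {"a": 18.0, "k": 0.4, "t0": 30.0}),
        ("quadratic", {"a2": -0.2, "a1": 14.0, "a0": -220.0}),
        ("linear", {"m": -0.5, "q": 40.0}),
        ("monomolecular", {"a": 20.0, "k": 0.3, "t0": 25.0}),
    ])
    def test_agrees_with_fine_grid_scan(self, name, params):
        fit = GrowthFit(
            model_name=name, parameters=params, r_squared=1.0,
            fit_p_value=0.0, timemax=np.nan, biomass_at_timemax=np.nan,
            window=(24.0, 41.0), converged=True,
        )
        tmax, bmax = extract_timemax(fit, (24.0, 41.0))
        grid = np.arange(24.0, 41.0 + 0.005, 0.01)
        curve = fit.curve(grid)
        assert abs(tmax - grid[np.argmax(curve)]) <= 0.011
        assert bmax == pytest.approx(curve.max(), rel=1e-6)


class TestRates:
    def test_gr_printed_formula(self):
        assert growth_rate(20.0, 10.0, 37.0, 30.0) == pytest.approx(
            np.log(10.0) / 7.0
        )

    def test_unit_gain_gives_zero(self):
        assert growth_rate(11.0, 10.0, 40.0, 30.0) == 0.0
        assert growth_rate(11.0, 10.0, 35.0, 30.0) == 0.0

    def test_interval_homogeneity(self):
        assert growth_rate(20.0, 10.0, 44.0, 30.0) == pytest.approx(
            growth_rate(20.0, 10.0, 37.0, 30.0) / 2
        )

    def test_nonpositive_gain_undefined(self):
        assert np.isnan(growth_rate(10.0, 10.0, 37.0, 30.0))

    def test_rgr_alternative(self):
        assert growth_rate(20.0, 10.0, 37.0, 30.0, method="rgr") == pytest.approx(
            (np.log(20.0) - np.log(10.0)) / 7.0
        )

    def test_wue_arithmetic(self):
        assert water_use_efficiency(10.0, 300.0, 0.0, 50.0) == pytest.approx(0.04)

    def test_wue_zero_gain(self):
        assert water_use_efficiency(0.0, 300.0, 0.0, 50.0) == 0.0

    def test_wue_zero_soil_loss_reduces_to_gain_over_water(self):
        assert water_use_efficiency(10.0, 250.0, 0.0, 0.0) == pytest.approx(
            10.0 / 250.0
        )

    def test_wue_nonpositive_denominator_undefined(self):
        assert np.isnan(water_use_efficiency(10.0, 40.0, 0.0, 50.0))


class TestToleranceIndices:
    def test_printed_fit_arithmetic(self):
        """Feeding the printed genotype fits through the index
        definitions: 12.9 g @36 (WW) and 12.7 g @35 (WD) give
        MP = 12.8 g, BRR = 12.7/12.9, IPS = 1 day."""
        out = tolerance_indices(
            "CMH82",
            {"WW38": _bell_fit(12.9, 36.0), "WD38": _bell_fit(12.7, 35.0)},
        )
        assert out.mean_productivity == pytest.approx(12.8)
        assert out.biomass_reduction == pytest.approx(12.7 / 12.9)
        assert out.biomass_reduction == pytest.approx(0.984, abs=5e-4)
        assert out.inflection_point_stability == pytest.approx(1.0)

    def test_identical_treatments_neutral_indices(self):
        fit = _bell_fit(15.0, 36.0)
        out = tolerance_indices(
            "X", {"WW38": fit, "WD38": fit},
            gr={"WW38": 0.3, "WD38": 0.3}, wue={"WW38": 0.04, "WD38": 0.04},
        )
        assert out.biomass_reduction == 1.0
        assert out.inflection_point_stability == 0.0
        assert out.gr_ratio == 1.0 and out.wue_ratio == 1.0

    def test_missing_fit_marks_unavailable(self):
        out = tolerance_indices("X", {"WW38": _bell_fit(15.0, 36.0), "WD38": None})
        assert not out.available
        assert np.isnan(out.mean_productivity)

    def test_equals_spreadsheet_recomputation_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            b_ww, b_wd = rng.uniform(5, 30, 2)
            t_ww, t_wd = rng.uniform(30, 41, 2)
            gr = {"WW38": rng.uniform(0.1, 0.5), "WD38": rng.uniform(0.1, 0.5)}
            wue = {"WW38": rng.uniform(0.01, 0.1), "WD38": rng.uniform(0.01, 0.1)}
            out = tolerance_indices(
                "X",
                {"WW38": _bell_fit(b_ww, t_ww), "WD38": _bell_fit(b_wd, t_wd)},
                gr=gr, wue=wue,
            )
            assert out.mean_productivity == (b_ww + b_wd) / 2
            assert out.biomass_reduction == b_wd / b_ww
            assert out.inflection_point_stability == t_ww - t_wd
            assert out.gr_ratio == gr["WD38"] / gr["WW38"]
            assert out.wue_ratio == wue["WD38"] / wue["WW38"]


class TestRescaleAndCluster:
    @staticmethod
    def _table(columns):
        return pd.DataFrame(columns, index=[f"g{i}" for i in
                                            range(len(next(iter(columns.values()))))])

    def test_min_max_rescaling(self):
        table = self._table({"mp": [10.0, 20.0, 30.0], "brr": [1.0, 2.0, 4.0]})
        rescaled, order, constant = rescale_and_cluster(table)
        np.testing.assert_allclose(rescaled["mp"], [0.0, 0.5, 1.0])
        assert constant == []

    def test_affine_invariance(self):
        base = self._table({"a": [1.0, 3.0, 7.0], "b": [0.0, 1.0, 2.0]})
        shifted = base * 3.0 + 100.0
        r1, _, _ = rescale_and_cluster(base)
        r2, _, _ = rescale_and_cluster(shifted)
        pd.testing.assert_frame_equal(r1, r2)

    def test_constant_column_flagged_at_half(self):
        table = self._table({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        rescaled, _, constant = rescale_and_cluster(table)
        assert constant == ["b"]
        assert (rescaled["b"] == 0.5).all()

    def test_identical_genotypes_cluster_first(self):
        table = self._table(
            {"a": [0.1, 0.1, 0.9, 0.5], "b": [0.2, 0.2, 0.8, 0.5]}
        )
        _, order, _ = rescale_and_cluster(table)
        assert abs(order.index("g0") - order.index("g1")) == 1

    def test_index_table_round_trip(self):
        sets = [
            tolerance_indices(
                "A", {"WW38": _bell_fit(20.0, 37.0), "WD38": _bell_fit(18.0, 36.0)}
            ),
            tolerance_indices(
                "B", {"WW38": _bell_fit(22.0, 38.0), "WD38": _bell_fit(11.0, 35.0)}
            ),
        ]
        table = index_table(sets)
        assert list(table.index) == ["A", "B"]
        assert table.loc["B", "biomass_reduction"] == pytest.approx(0.5)
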