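"""Quadratic trajectory fitting: exact recovery, oracles, turning points."""

from dataclasses import replace
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from callosum.generative import GenerativeModel, simulate_index_values
from callosum.cohort import make_cohort
from callosum.trajectories import (adjusted_r2, fit_all, fit_quadratic,
                                   table2_style, turning_age, curve_points)


def _exact_normal_equations(ages, values):
    """Independent oracle: solve the 3x3 normal equations in exact rational
    arithmetic (ages are integers, float values are exact binary rationals)."""
    a = [Fraction(int(v)) for v in ages]
    y = [Fraction(v) for v in values]
    cols = [[Fraction(1)] * len(a), a, [v * v for v in a]]
    xtx = [[sum(ci * cj for ci, cj in zip(c1, c2)) for c2 in cols] for c1 in cols]
    xty = [sum(ci * yi for ci, yi in zip(c, y)) for c in cols]
    # Gaussian elimination over the rationals
    m = [row + [b] for row, b in zip(xtx, xty)]
    for i in range(3):
        piv = next(r for r in range(i, 3) if m[r][i] != 0)
        m[i], m[piv] = m[piv], m[i]
        for r in range(3):
            if r != i:
                f = m[r][i] / m[i][i]
                m[r] = [mr - f * mi for mr, mi in zip(m[r], m[i])]
    return [float(m[i][3] / m[i][i]) for i in range(3)]


class TestFitQuadratic:
    def test_noiseless_generative_row_recovered_exactly(self):
        model = GenerativeModel.default(noise=0.0)
        ages = np.arange(21, 91)
        values = model.quadratic("FA", "DMN", ages)
        fit = fit_quadratic(ages, values)
        r = model.row("FA", "DMN")
        assert fit.C == pytest.approx(r.C, rel=1e-10)
        assert fit.A == pytest.approx(r.A, rel=1e-10)
        assert fit.B == pytest.approx(r.B, rel=1e-10)
        assert fit.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exact_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 41))
        ages = rng.integers(21, 91, size=n)
        while np.ptp(ages) == 0:
            ages = rng.integers(21, 91, size=n)
        values = (rng.normal(0.6, 0.1) + rng.normal(0, 0.01) * ages
                  + rng.normal(0, 1e-4) * ages**2 + rng.normal(0, 0.05, n))
        fit = fit_quadratic(ages, values)
        oc, oa, ob = _exact_normal_equations(ages, values)
        assert fit.C == pytest.approx(oc, rel=1e-10, abs=1e-12)
        assert fit.A == pytest.approx(oa, rel=1e-10, abs=1e-12)
        assert fit.B == pytest.approx(ob, rel=1e-10, abs=1e-12)

    def test_shift_invariance_of_raw_parameterization(self):
        """Fitting on centered ages and substituting back must reproduce the
        raw-age coefficients (conditioning guard)."""
        rng = np.random.default_rng(7)
        ages = rng.integers(21, 91, size=200)
        y = 0.6 + 2e-3 * ages - 3e-5 * ages**2 + rng.normal(0, 0.05, 200)
        fit = fit_quadratic(ages, y)
        m = ages.mean()
        shifted = fit_quadratic(ages - m, y)
        c = shifted.C - shifted.A * m + shifted.B * m**2
        a = shifted.A - 2 * shifted.B * m
        assert c == pytest.approx(fit.C, rel=1e-9)
        assert a == pytest.approx(fit.A, rel=1e-9)
        assert shifted.B == pytest.approx(fit.B, rel=1e-9)

    def test_estimates_consistent_at_large_n(self):
        model = GenerativeModel.default()
        ages = make_cohort(10_000, seed=8)["age"].to_numpy()
        values = simulate_index_values(model, "MD", "VA", ages, seed=9)
        fit = fit_quadratic(ages, values)
        r = model.row("MD", "VA")
        for est, true, se in [(fit.C, r.C, fit.se_C), (fit.A, r.A, fit.se_A),
                              (fit.B, r.B, fit.se_B)]:
            assert abs(est - true) < 3 * se

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_quadratic([50] * 10, np.arange(10.0))
        with pytest.raises(ValueError, match="4 usable"):
            fit_quadratic([30, 40, 50], [1.0, 2.0, 3.0])


class TestAdjustedR2:
    def test_formula(self):
        # 1 - (1 - 0.5) * 9 / 7
        assert adjusted_r2(0.5, 10) == pytest.approx(1 - 0.5 * 9 / 7)

    def test_never_exceeds_r2(self):
        for r2 in (0.0, 0.09, 0.5, 0.99):
            assert adjusted_r2(r2, 1086) <= r2


class TestTurningAge:
    def test_closed_form_against_grid_argmax(self):
        """-A/(2B) for the DA FA row must sit at 43.6 years and agree with a
        dense grid argmax of the fitted curve."""
        model = GenerativeModel.default(noise=0.0)
        ages = np.arange(21, 91)
        fit = fit_quadratic(ages, model.quadratic("FA", "DA", ages))
        tp = turning_age(fit)
        assert tp == pytest.approx(0.294e-2 / (2 * 0.337e-4), rel=1e-6)
        assert round(tp, 1) == 43.6
        grid = np.arange(21.0, 90.0, 0.001)
        assert abs(grid[np.argmax(fit.predict(grid))] - tp) < 0.002

    def test_no_turning_point_when_curvature_is_zero(self):
        fit = fit_quadratic(np.arange(21, 91), 0.1 + 0.002 * np.arange(21, 91))
        fit = replace(fit, B=0.0)
        assert turning_age(fit) is None

    def test_pure_quadratic_turns_at_zero_outside_range(self):
        ages = np.arange(21, 91)
        fit = fit_quadratic(ages, 1.0 - 1e-4 * ages.astype(float) ** 2)
        assert turning_age(fit) == pytest.approx(0.0, abs=1e-6)
        assert not fit.turning_in_range


class TestFitAll:
    @staticmethod
    def _study(n=60, seed=0):
        model = GenerativeModel.default()
        cohort = make_cohort(n, seed=seed)
        ages = cohort["age"].to_numpy()
        rows = []
        for rid, (index, network) in enumerate(sorted(model.table.index)):
            vals = simulate_index_values(model, index, network, ages,
                                         seed=np.random.SeedSequence([seed, rid]))
            for sid, v in zip(cohort["id"], vals):
                rows.append({"subject_id": sid, "network": network,
                             "index": index, "value": v, "value_residual": v})
        return cohort, pd.DataFrame(rows)

    def test_seven_networks_times_four_indices(self):
        cohort, di_long = self._study()
        fits = fit_all(di_long, cohort)
        assert len(fits) == 28
        assert (fits["status"] == "ok").all()
        styled = table2_style(fits)
        assert set(styled["index"]) == {"FA", "MD", "RD", "AD"}
        # FA intercepts on the printing scale stay order-one
        assert styled[styled["index"] == "FA"]["intercept"].between(0, 1.2).all()

    def test_sparse_cell_fails_without_stopping_the_run(self):
        cohort, di_long = self._study()
        cell = (di_long["network"] == "VIS") & (di_long["index"] == "FA")
        di_long.loc[cell.to_numpy().nonzero()[0][3:], "value_residual"] = np.nan
        fits = fit_all(di_long, cohort)
        assert len(fits) == 28
        failed = fits[(fits["network"] == "VIS") & (fits["index"] == "FA")]
        assert failed["status"].str.startswith("failed").all()
        assert (fits["status"] == "ok").sum() == 27

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_all(pd.DataFrame(), make_cohort(5, seed=0))

    def test_curve_points_follow_the_fit(self):
        cohort, di_long = self._study(n=40, seed=3)
        fits = fit_all(di_long, cohort)
        ok = fits[fits["status"] == "ok"].iloc[0]
        fit = fit_quadratic(
            cohort.set_index("id")["age"].reindex(
                di_long[(di_long.network == ok["network"])
                        & (di_long["index"] == ok["index"])]["subject_id"]),
            di_long[(di_long.network == ok["network"])
                    & (di_long["index"] == ok["index"])]["value_residual"],
        )
        pts = curve_points(fit, n_points=11)
        assert np.allclose(pts["value"], fit.predict(pts["age"]))
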