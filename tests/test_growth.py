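import numpy as np
import pytest

from natlab.growth import (
    GeneralizedMichaelisMentenGrowth,
    GeneralizedMMParameters,
    MichaelisMentenGrowth,
    MMParameters,
    fit_growth,
    gmm_eval,
    growth_table,
    mm_derivative,
    mm_eval,
    onset_search,
)
from natlab.tracking import MaximumTrajectory


class TestMichaelisMentenCurve:
    def test_intersects_origin_and_half_asymptote(self, cbr_params):
        assert mm_eval(cbr_params, 0.0) == 0.0
        assert mm_eval(cbr_params, cbr_params.b) == pytest.approx(cbr_params.m_max / 2)

    def test_negative_time_rejected(self, cbr_params):
        with pytest.raises(ValueError):
            mm_eval(cbr_params, -1.0)

    def test_published_rate_table_consistency(self):
        """Solving the curve from two tabulated days predicts a third.

        Independent oracle: the published chamber-number table gives
        (day 30 -> 33 chambers, day 360 -> 66 chambers); two-equation
        algebra yields the parameters, and the curve evaluated at day 90
        must reproduce the printed 52 chambers.
        """
        # closed-form solve of m*30/(b+30)=33 and m*360/(b+360)=66
        b = (66 * 30 * 360 - 33 * 360 * 30) / (33 * 360 - 66 * 30)
        m_max = 33 * (b + 30) / 30
        assert b == pytest.approx(36.0)
        assert m_max == pytest.approx(72.6)
        p = MMParameters(m_max, b)
        assert round(float(mm_eval(p, 90.0))) == 52

    def test_derivative_matches_finite_differences(self, cbr_params):
        t = np.linspace(1, 400, 50)
        h = 1e-4
        numeric = (mm_eval(cbr_params, t + h) - mm_eval(cbr_params, t - h)) / (2 * h)
        assert np.allclose(mm_derivative(cbr_params, t), numeric, rtol=1e-6)

    def test_rate_strictly_decreasing(self, cbr_params):
        t = np.linspace(0, 400, 100)
        assert np.all(np.diff(mm_derivative(cbr_params, t)) < 0)


class TestGeneralizedCurve:
    def test_starts_at_nepiont_and_midpoint(self, dir_params):
        assert gmm_eval(dir_params, 0.0) == pytest.approx(dir_params.m0)
        assert gmm_eval(dir_params, dir_params.b) == pytest.approx(
            (dir_params.m0 + dir_params.m_max) / 2
        )

    def test_asymptote(self, dir_params):
        far = gmm_eval(dir_params, 1e6 * dir_params.b)
        assert far == pytest.approx(dir_params.m_max, rel=1e-3)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneralizedMMParameters(500, 400, 50, 2)  # m0 >= m_max
        with pytest.raises(ValueError):
            GeneralizedMMParameters(300, 4000, 50, 0.9)  # not sigmoid


class TestFitting:
    def test_exact_mm_data_recovered(self):
        p = MMParameters(70.0, 40.0)
        t = np.array([5.0, 30.0, 80.0, 200.0, 350.0])
        fitted, chi2 = fit_growth(t, mm_eval(p, t), "cbr")
        assert fitted.m_max == pytest.approx(70.0, abs=1e-6)
        assert fitted.b == pytest.approx(40.0, abs=1e-6)
        assert chi2 == pytest.approx(0.0, abs=1e-10)

    def test_exact_generalized_data_recovered(self):
        p = GeneralizedMMParameters(300.0, 4000.0, 80.0, 1.6)
        t = np.array([2.0, 20.0, 60.0, 120.0, 250.0, 400.0])
        fitted, chi2 = fit_growth(t, gmm_eval(p, t), "dir")
        assert fitted.m_max == pytest.approx(4000.0, rel=1e-5)
        assert fitted.c == pytest.approx(1.6, rel=1e-4)
        assert chi2 == pytest.approx(0.0, abs=1e-8)

    def test_sklearn_estimator_interface(self):
        p = MMParameters(70.0, 40.0)
        t = np.array([5.0, 30.0, 80.0, 200.0])
        est = MichaelisMentenGrowth().fit(t, mm_eval(p, t))
        assert est.m_max_ == pytest.approx(70.0, abs=1e-5)
        assert np.allclose(est.predict(t), mm_eval(p, t), atol=1e-6)
        params = est.get_params()
        assert MichaelisMentenGrowth(**params).get_params() == params


class TestOnsetSearch:
    def make_traj(self, p, onset, dates=(0, 28, 61, 90, 122, 150, 210, 270)):
        t = np.array(dates, dtype=float)
        return MaximumTrajectory(t, np.asarray(mm_eval(p, t + onset)), 1, "noc", "max")

    def test_noiseless_onset_recovered_exactly(self):
        p = MMParameters(70.0, 40.0)
        onset = 42
        traj = self.make_traj(p, onset)
        fit = onset_search(
            traj, "cbr",
            pseudo_values=(float(mm_eval(p, 1.0)), float(mm_eval(p, onset / 2.0))),
        )
        assert fit.onset_days == onset
        assert fit.parameters.m_max == pytest.approx(70.0, abs=1e-5)
        assert fit.parameters.b == pytest.approx(40.0, abs=1e-4)

    def test_coarse_grid_enumerates_five_day_steps(self):
        from natlab.growth import _candidate_onsets

        assert _candidate_onsets((10, 70, 5)) == list(range(10, 71, 5))

    def test_reported_fit_beats_all_candidates(self):
        p = MMParameters(70.0, 40.0)
        traj = self.make_traj(p, 30)
        best = onset_search(traj, "cbr")
        for L in range(10, 71, 5):
            alt = onset_search(traj, "cbr", fixed_onset=L)
            assert best.fit_quality <= alt.fit_quality + 1e-12

    def test_too_short_trajectory_rejected(self):
        traj = MaximumTrajectory(np.array([0.0, 30.0, 60.0]), np.array([10.0, 20.0, 30.0]),
                                 1, "noc", "max")
        with pytest.raises(Exception, match="4 trajectory points"):
            onset_search(traj, "cbr")

    def test_chambers_saturate_before_diameter(self):
        """Chamber number reaches half its asymptote earlier than diameter.

        The nonlinear coupling of the two characters (fast early chamber
        building, prolonged diameter increase) shows as a smaller fitted
        half-saturation time for the chamber curve.
        """
        cbr = MMParameters(72.6, 36.0)
        dirp = GeneralizedMMParameters(293.7, 4500.0, 75.0, 1.4)
        onset = 25
        t = np.array([0.0, 30.0, 60.0, 95.0, 125.0, 180.0, 240.0, 300.0])
        noc_traj = MaximumTrajectory(t, np.asarray(mm_eval(cbr, t + onset)), 1, "noc", "max")
        td_traj = MaximumTrajectory(t, np.asarray(gmm_eval(dirp, t + onset)), 1, "td", "max")
        f_cbr = onset_search(noc_traj, "cbr",
                             pseudo_values=(float(mm_eval(cbr, 1)), float(mm_eval(cbr, onset / 2))))
        f_dir = onset_search(td_traj, "dir", fixed_onset=f_cbr.onset_days,
                             pseudo_values=(float(gmm_eval(dirp, 1)), float(gmm_eval(dirp, onset / 2))))
        # day at 50% of asymptote: b for the MM curve, b for the sigmoid
        assert f_cbr.parameters.b < f_dir.parameters.b


class TestGrowthTable:
    def test_values_monotone_and_rates_telescope(self, cbr_params):
        from natlab.growth import GrowthFit

        fit = GrowthFit(cbr_params, onset_days=20, trajectory_kind="max", fit_quality=0.0)
        days = list(range(1, 31))
        rows = growth_table(fit, days)
        values = [r["value"] for r in rows]
        assert values == sorted(values)
        total = sum(r["per_day_rate"] for r in rows)
        expected = float(mm_eval(cbr_params, 30.0) - mm_eval(cbr_params, 0.0))
        assert total == pytest.approx(expected, abs=0.06 * len(days))
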