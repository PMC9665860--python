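"""Joint logistic curve fitting, concentration estimation and diagnostics."""

import math

import numpy as np
import pytest
from scipy import optimize

from rppaquant import (
    CurveFit,
    DilutionSeries,
    FitOptions,
    SlideError,
    estimate_excluded,
    fit_diagnostics,
    fit_supercurve,
    infer_design,
    read_slide_file,
    response,
    series_from_slide,
)
from rppaquant.simulate import generate_slide, simulate_slide

from conftest import small_scenario


def _curve(alpha, beta, gamma):
    return CurveFit(alpha=alpha, beta=beta, gamma=gamma, rss=0.0, r2=1.0,
                    n_series_used=0, n_spots_used=0, converged=True, n_iterations=0)


def _slide_series(tmp_path, scenario, excluded=()):
    path, truth = generate_slide(scenario, "AB", tmp_path)
    slide = read_slide_file(path)
    design = infer_design(slide)
    return series_from_slide(slide, design, excluded_series=excluded), truth


class TestResponse:
    @pytest.mark.parametrize(
        "x,alpha,beta,gamma,expected",
        [
            (-30.0, 100.0, 1000.0, 1.0, 100.0),  # lower asymptote
            (0.0, 100.0, 1000.0, 1.0, 600.0),  # midpoint alpha + beta/2
            (2.0, 0.0, 1.0, 1.0, 0.8807970779778823),  # 1/(1+e^-2)
        ],
    )
    def test_values(self, x, alpha, beta, gamma, expected):
        assert response(x, _curve(alpha, beta, gamma)) == pytest.approx(expected, abs=1e-9)

    def test_strictly_increasing_and_bounded(self):
        fit = _curve(50.0, 500.0, 0.7)
        xs = np.linspace(-12, 12, 400)
        ys = response(xs, fit)
        assert np.all(np.diff(ys) > 0)
        assert np.all(ys > fit.alpha) and np.all(ys < fit.alpha + fit.beta)


class TestFitSupercurve:
    def test_noise_free_recovery(self, tmp_path):
        scenario = small_scenario(31)
        series, truth = _slide_series(tmp_path, scenario)
        fit, estimates = fit_supercurve(series)
        assert fit.converged
        assert fit.r2 >= 1 - 1e-9
        assert abs(fit.alpha - scenario.alpha) / scenario.alpha <= 1e-6
        assert abs(fit.beta - scenario.beta) / scenario.beta <= 1e-6
        assert abs(fit.gamma - scenario.gamma) / scenario.gamma <= 1e-6
        for est in estimates:
            if est.series_id in truth.x_true:
                err = abs(est.x - truth.x_true[est.series_id])
                assert err / max(1.0, abs(truth.x_true[est.series_id])) <= 1e-6

    def test_constant_intensities_mean_no_signal(self):
        series = [
            DilutionSeries(f"S{i}", d=[0, -1, -2], y=[500.0, 500.0, 500.0])
            for i in range(10)
        ]
        with pytest.raises(SlideError, match="no signal"):
            fit_supercurve(series)

    def test_too_few_series_rejected(self):
        series = [
            DilutionSeries(f"S{i}", d=[0, -1], y=[100.0 * i, 50.0 * i])
            for i in range(4)
        ]
        with pytest.raises(SlideError, match="at least 8"):
            fit_supercurve(series)

    def test_exclusion_matches_absence(self, tmp_path):
        scenario = small_scenario(32, noise_sd=100.0, outliers=(("S005", 5.0),))
        series, _ = _slide_series(tmp_path, scenario)
        series_wo = [s for s in series if s.series_id != "S005"]
        for s in series:
            s.excluded_from_fit = s.excluded_from_fit or s.series_id == "S005"
        _, est_with_exclusion = fit_supercurve(series)
        _, est_absent = fit_supercurve(series_wo)
        by_id = {e.series_id: e for e in est_absent}
        for e in est_with_exclusion:
            if e.series_id in by_id and e.series_id != "S005":
                assert abs(e.x - by_id[e.series_id].x) <= 1e-6
        excluded_est = next(e for e in est_with_exclusion if e.series_id == "S005")
        assert not excluded_est.in_fit
        assert math.isfinite(excluded_est.x)

    def test_permutation_invariance(self, tmp_path):
        series, _ = _slide_series(tmp_path, small_scenario(33, noise_sd=200.0))
        fit1, est1 = fit_supercurve(series)
        fit2, est2 = fit_supercurve(list(reversed(series)))
        assert fit1.rss == pytest.approx(fit2.rss, rel=1e-9)
        x1 = {e.series_id: e.x for e in est1}
        for e in est2:
            assert e.x == pytest.approx(x1[e.series_id], abs=1e-8)

    def test_row_shuffle_of_input_file_changes_nothing(self, tmp_path):
        path, _ = generate_slide(small_scenario(34, noise_sd=150.0), "AB", tmp_path)
        lines = path.read_text().splitlines()
        header, body = lines[0], lines[1:]
        rng = np.random.default_rng(0)
        shuffled = [body[i] for i in rng.permutation(len(body))]
        path2 = tmp_path / "AB_shuffled.txt"
        path2.write_text("\n".join([header] + shuffled) + "\n")

        x_by_id = {}
        for p in (path, path2):
            slide = read_slide_file(p)
            design = infer_design(slide)
            _, est = fit_supercurve(series_from_slide(slide, design))
            x_by_id[p.name] = {e.series_id: e.x for e in est}
        a, b = x_by_id.values()
        assert set(a) == set(b)
        for sid in a:
            assert a[sid] == pytest.approx(b[sid], abs=1e-6)

    def test_identifiability_anchor(self, tmp_path):
        """With the curve frozen, shifting all positions raises the RSS."""
        series, _ = _slide_series(tmp_path, small_scenario(35, noise_sd=100.0))
        fit, estimates = fit_supercurve(series)

        def rss_at(shift):
            total = 0.0
            for est in estimates:
                s = next(s for s in series if s.series_id == est.series_id)
                r = response(est.x + shift + s.d, fit) - s.y
                total += float(r @ r)
            return total

        base = rss_at(0.0)
        for delta in (-0.5, -0.05, 0.05, 0.5):
            assert rss_at(delta) > base

    def test_alternating_matches_simultaneous_oracle(self, tmp_path):
        """12-series slides: alternating RSS equals a joint optimizer's."""
        scenario = small_scenario(
            36, n_samples=12, n_replicate_series=0, n_main_cols=3,
            n_sub_cols=4, n_main_rows=1, noise_sd=400.0,
        )
        series, _ = _slide_series(tmp_path, scenario)
        fit, est = fit_supercurve(series)

        d_all = np.concatenate([s.d for s in series])
        y_all = np.concatenate([s.y for s in series])
        idx = np.repeat(np.arange(len(series)), [s.y.size for s in series])
        x_hat = np.array([next(e.x for e in est if e.series_id == s.series_id)
                          for s in series])

        def resid(theta):
            a, b, g = theta[:3]
            return a + b / (1 + np.exp(-g * (theta[3:][idx] + d_all))) - y_all

        theta0 = np.concatenate([[fit.alpha, fit.beta, fit.gamma], x_hat])
        sol = optimize.least_squares(resid, theta0, method="lm", xtol=1e-15, ftol=1e-15)
        oracle_rss = float(sol.fun @ sol.fun)
        assert fit.rss <= oracle_rss * (1 + 1e-6)
        assert abs(fit.rss - oracle_rss) <= 1e-6 * oracle_rss


class TestEstimateExcluded:
    def test_exact_inverse_of_forward_model(self):
        fit = _curve(200.0, 40000.0, 0.8)
        d = np.array([0.0, -1.0, -2.0, -3.0])
        series = DilutionSeries("Q", d=d, y=response(1.5 + d, fit))
        est = estimate_excluded(series, fit)
        assert est.x == pytest.approx(1.5, abs=1e-6)
        assert not est.in_fit

    def test_all_baseline_flags_below_detection(self):
        fit = _curve(200.0, 40000.0, 0.8)
        series = DilutionSeries("Q", d=[0, -1, -2], y=[200.0, 200.0, 200.0])
        est = estimate_excluded(series, fit)
        assert "BelowDetection" in est.flags
        assert est.x == FitOptions().x_bounds[0]

    def test_all_saturated_flags_saturated(self):
        fit = _curve(200.0, 40000.0, 0.8)
        top = 200.0 + 40000.0
        series = DilutionSeries("Q", d=[0, -1, -2], y=[top, top, top])
        est = estimate_excluded(series, fit)
        assert "Saturated" in est.flags
        assert est.x == FitOptions().x_bounds[1]

    @pytest.mark.parametrize("lift", [10.0, 100.0, 1000.0])
    def test_monotone_in_intensity(self, lift):
        fit = _curve(200.0, 40000.0, 0.8)
        d = np.array([0.0, -1.0, -2.0, -3.0])
        base = response(0.5 + d, fit)
        x_low = estimate_excluded(DilutionSeries("Q", d=d, y=base), fit).x
        x_high = estimate_excluded(DilutionSeries("Q", d=d, y=base + lift), fit).x
        assert x_high >= x_low

    def test_heldout_coverage(self, tmp_path):
        """Held-out series' truth lies within 2 SE most of the time."""
        hits = total = 0
        for seed in range(40, 70):
            scenario = small_scenario(seed, noise_sd=400.0)
            path, truth = generate_slide(scenario, "AB", tmp_path / str(seed))
            slide = read_slide_file(path)
            design = infer_design(slide)
            series = series_from_slide(slide, design, excluded_series=("S010",))
            fit, est = fit_supercurve(series)
            e = next(e for e in est if e.series_id == "S010")
            if math.isfinite(e.se_x) and e.se_x > 0:
                total += 1
                hits += abs(e.x - truth.x_true["S010"]) <= 2 * e.se_x
        assert total >= 25
        assert hits / total >= 0.85


class TestDiagnostics:
    def test_noise_free_slide_has_no_candidates(self, tmp_path):
        series, _ = _slide_series(tmp_path, small_scenario(37))
        fit, est = fit_supercurve(series)
        diag = fit_diagnostics(fit, est)
        assert diag.r2 >= 1 - 1e-9
        assert diag.exclusion_candidates == []

    def test_scaled_series_ranks_first(self, tmp_path):
        scenario = small_scenario(38, noise_sd=100.0, outliers=(("S003", 5.0),))
        series, _ = _slide_series(tmp_path, scenario)
        fit, est = fit_supercurve(series)
        diag = fit_diagnostics(fit, est)
        assert diag.ranked_series[0] == "S003"
        assert "S003" in diag.exclusion_candidates

    def test_noisy_slide_r2(self, tmp_path):
        series, _ = _slide_series(tmp_path, small_scenario(39, noise_sd=400.0))
        fit, _ = fit_supercurve(series)
        assert fit.r2 >= 0.95
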