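"""Single-exponential and secondary titration fits."""

import io
import warnings

import numpy as np
import pytest

import myokin as mk
from myokin.errors import (
    CurvatureWarning,
    FitFailureError,
    UnreliableRateError,
    UnsaturatedTitrationError,
    WideIntervalWarning,
)


def _trace(time, signal, **kw):
    defaults = dict(signal_type="light_scattering", atp=100.0)
    defaults.update(kw)
    return mk.KineticTrace(time=np.asarray(time), signal=np.asarray(signal), **defaults)


class TestSingleExponential:
    def test_noiseless_decay_exact(self):
        t = np.linspace(0, 0.1, 200)
        fit = mk.fit_single_exponential(_trace(t, 0.2 + 1.0 * np.exp(-70.0 * t)))
        assert fit.k_obs == pytest.approx(70.0, rel=1e-9)
        assert fit.amplitude == pytest.approx(-1.0, rel=1e-6)
        assert fit.offset == pytest.approx(0.2, abs=1e-9)

    def test_noiseless_fast_rise_exact(self):
        # rise at the wild-type plateau rate with a 3.5% amplitude
        t = np.linspace(0, 0.02, 400)
        signal = 1.0 * (1 + 0.035 * (1 - np.exp(-286.0 * t)))
        fit = mk.fit_single_exponential(_trace(t, signal, signal_type="trp_fluorescence"))
        assert fit.k_obs == pytest.approx(286.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(+0.035, rel=1e-4)

    def test_constant_signal_fails(self):
        t = np.linspace(0, 0.1, 100)
        with pytest.raises(FitFailureError):
            mk.fit_single_exponential(_trace(t, np.ones_like(t)))

    def test_under_resolved_rate_refused(self):
        # half-life far below the sampling interval
        t = np.linspace(0, 1.0, 60)
        y = np.exp(-500.0 * t)
        with pytest.raises((UnreliableRateError, FitFailureError)):
            mk.fit_single_exponential(_trace(t, y))

    def test_window_restricts_fit(self):
        t = np.linspace(0, 0.2, 400)
        y = np.exp(-30.0 * t)
        fit = mk.fit_single_exponential(_trace(t, y), window=(0.01, 0.2))
        assert fit.k_obs == pytest.approx(30.0, rel=1e-6)
        assert fit.n_points < 400

    def test_noisy_se_calibration(self, wt):
        """Nominal ±1 s.e. intervals from the exponential fit cover the
        generating rate at close to the Gaussian 68% level."""
        hits = 0
        n = 200
        for seed in range(n):
            trace = mk.make_dissociation_trace(wt, atp=100.0, noise_frac=0.02, seed=seed)
            fit = mk.fit_single_exponential(trace)
            hits += abs(fit.k_obs - 70.0) <= fit.k_obs_se
        assert 0.60 <= hits / n <= 0.76


class TestLinearTitration:
    def test_exact_slope(self):
        conc = np.array([25.0, 50.0, 100.0, 200.0, 400.0])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=0.70 * conc)
        fit = mk.fit_linear_titration(series)
        assert fit.params["K1k2_acto"] == pytest.approx(0.70, rel=1e-12)

    def test_scaling_doubles_slope(self):
        conc = np.array([25.0, 50.0, 100.0, 200.0])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=1.40 * conc)
        assert mk.fit_linear_titration(series).params["K1k2_acto"] == pytest.approx(1.40)

    def test_noisy_slope_within_two_se(self, wt):
        rng = np.random.default_rng(0)
        conc = np.repeat([25.0, 50.0, 100.0, 200.0, 400.0], 5)
        kobs = 0.70 * conc * (1 + 0.05 * rng.standard_normal(conc.size))
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        fit = mk.fit_linear_titration(series)
        assert abs(fit.params["K1k2_acto"] - 0.70) < 2 * fit.se["K1k2_acto"]

    def test_curvature_flagged(self, wt):
        # rates drawn from the saturating hyperbola, not the linear regime
        conc = np.array([25.0, 100.0, 400.0, 1600.0, 6400.0])
        kobs = np.array([mk.analytic_kobs_binding(wt, c) for c in conc])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        with pytest.warns(CurvatureWarning):
            mk.fit_linear_titration(series)

    def test_wrong_ligand_rejected(self):
        series = mk.TitrationSeries(
            ligand="ADP", conc=[0.0, 100.0, 200.0], kobs=[70.0, 50.0, 40.0],
            fixed_atp=100.0,
        )
        with pytest.raises(ValueError):
            mk.fit_linear_titration(series)


class TestADPCompetition:
    def test_exact_kad_from_noiseless_series(self, wt):
        series = mk.make_competition_series(wt, noise_frac=0.0)
        fit = mk.fit_adp_competition(series)
        assert fit.params["K_AD"] == pytest.approx(406.0, rel=1e-6)

    def test_krel_normalization(self, wt):
        series = mk.make_competition_series(wt, noise_frac=0.0)
        fit = mk.fit_adp_competition(series)
        krel = fit.extras["krel"]
        adp = fit.extras["adp"]
        assert krel[adp == 0] == pytest.approx(1.0)
        # half-relaxation at [ADP] = K_AD
        at_kad = 1.0 / (1.0 + 406.0 / fit.params["K_AD"])
        assert at_kad == pytest.approx(0.5, abs=1e-6)

    def test_missing_anchor_rejected(self):
        series = mk.TitrationSeries(
            ligand="ADP", conc=[100.0, 400.0], kobs=[50.0, 35.0], fixed_atp=100.0
        )
        with pytest.raises(ValueError):
            mk.fit_adp_competition(series)

    def test_grid_search_oracle_agreement(self, r759e):
        """The competition fit agrees with a dense grid search over the same
        least-squares objective within 0.5%."""
        series = mk.make_competition_series(r759e, reps=2, noise_frac=0.02, seed=3)
        fit = mk.fit_adp_competition(series)
        k0 = series.k0
        krel = series.kobs / k0
        grid = np.linspace(200.0, 800.0, 12001)
        sse = [np.sum((krel - 1.0 / (1.0 + series.conc / g)) ** 2) for g in grid]
        best = grid[int(np.argmin(sse))]
        assert fit.params["K_AD"] == pytest.approx(best, rel=0.005)


class TestHyperbolicTitration:
    def test_exact_round_trip_of_table_values(self, wt):
        conc = np.array([10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0])
        kobs = np.array([mk.analytic_kobs_binding(wt, c) for c in conc])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        fit = mk.fit_hyperbolic_titration(series)
        assert fit.params["K1k2_s1"] == pytest.approx(6.0, rel=1e-6)
        assert fit.params["k_hyd_sum"] == pytest.approx(308.0, rel=1e-6)
        assert fit.params["K05"] == pytest.approx(51.333, abs=1e-3)

    def test_k05_identity_holds(self, r759e):
        conc = np.array([10.0, 40.0, 160.0, 640.0])
        kobs = np.array([mk.analytic_kobs_binding(r759e, c) for c in conc])
        fit = mk.fit_hyperbolic_titration(
            mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        )
        assert fit.params["K05"] == pytest.approx(
            fit.params["k_hyd_sum"] / fit.params["K1k2_s1"], rel=1e-9
        )

    def test_unsaturated_grid_signalled(self, wt):
        # all concentrations far below half-saturation look like a line
        conc = np.array([0.5, 1.0, 2.0, 4.0])
        kobs = np.array([mk.analytic_kobs_binding(wt, c) for c in conc])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        with pytest.raises(UnsaturatedTitrationError):
            mk.fit_hyperbolic_titration(series)

    def test_plateau_unsampled_warns(self, wt):
        conc = np.array([5.0, 10.0, 20.0, 40.0, 80.0])
        kobs = np.array([mk.analytic_kobs_binding(wt, c) for c in conc])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        with pytest.warns(WideIntervalWarning):
            fit = mk.fit_hyperbolic_titration(series)
        assert "plateau_unsampled" in fit.notes

    def test_grid_search_oracle_agreement(self, r759e):
        """Hyperbola fit matches a dense grid-search minimizer of the same
        objective within 0.5% on a six-concentration series."""
        rng = np.random.default_rng(8)
        conc = np.array([10.0, 20.0, 40.0, 160.0, 320.0, 640.0])
        kobs = np.array([
            mk.analytic_kobs_binding(r759e, c) * (1 + 0.02 * rng.standard_normal())
            for c in conc
        ])
        series = mk.TitrationSeries(ligand="ATP", conc=conc, kobs=kobs)
        fit = mk.fit_hyperbolic_titration(series)

        k2_grid = np.linspace(2.0, 3.5, 301)
        kmax_grid = np.linspace(180.0, 280.0, 401)
        k2m, kmm = np.meshgrid(k2_grid, kmax_grid, indexing="ij")
        sse = np.zeros_like(k2m)
        for c, k in zip(conc, kobs):
            sse += (k - kmm * c / (kmm / k2m + c)) ** 2
        i, j = np.unravel_index(np.argmin(sse), sse.shape)
        assert fit.params["K1k2_s1"] == pytest.approx(k2_grid[i], rel=0.005)
        assert fit.params["k_hyd_sum"] == pytest.approx(kmax_grid[j], rel=0.005)


class TestSeriesCSV:
    def test_round_trip(self, wt):
        series = mk.make_competition_series(wt, noise_frac=0.02, seed=6)
        buf = io.StringIO()
        series.to_csv(buf)
        buf.seek(0)
        back = mk.TitrationSeries.from_csv(buf)
        assert back.ligand == "ADP"
        assert back.fixed_atp == series.fixed_atp
        assert back.k0 == pytest.approx(series.k0)
        assert np.allclose(back.kobs, series.kobs)
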