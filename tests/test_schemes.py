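"""Closed-form observed-rate models, elementary-rate construction, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import myokin as mk
from myokin.errors import (
    ConstructionError,
    IncompletePresetError,
    InvalidConditionError,
    SignalSchemeMismatchError,
)

LN2 = np.log(2.0)


def _fit_trace(trace):
    return mk.fit_single_exponential(trace).k_obs


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

class TestDissociationModel:
    def test_wild_type_at_100uM(self, wt):
        assert mk.analytic_kobs_dissociation(wt, 100.0) == pytest.approx(70.0)

    def test_adp_at_kad_halves_the_rate(self, wt):
        k0 = mk.analytic_kobs_dissociation(wt, 100.0)
        assert mk.analytic_kobs_dissociation(wt, 100.0, wt.k_ad) == pytest.approx(k0 / 2)

    def test_zero_ligand_limit(self, wt):
        assert mk.analytic_kobs_dissociation(wt, 1e-12) < 1e-10

    def test_nonpositive_atp_rejected(self, wt):
        with pytest.raises(InvalidConditionError):
            mk.analytic_kobs_dissociation(wt, 0.0)
        with pytest.raises(InvalidConditionError):
            mk.analytic_kobs_dissociation(wt, -5.0)

    def test_missing_kad_with_adp_signals_incomplete_preset(self):
        preset = mk.GenotypePreset(label="partial", k1k2_acto=0.7)
        assert mk.analytic_kobs_dissociation(preset, 100.0) == pytest.approx(70.0)
        with pytest.raises(IncompletePresetError):
            mk.analytic_kobs_dissociation(preset, 100.0, adp=50.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        atp=st.floats(1.0, 1000.0),
        datp=st.floats(0.1, 100.0),
        adp=st.floats(0.0, 2000.0),
        dadp=st.floats(0.1, 500.0),
    )
    def test_monotone_in_both_ligands(self, atp, datp, adp, dadp):
        wt = mk.load_preset("wild-type")
        k = mk.analytic_kobs_dissociation
        assert k(wt, atp + datp, adp) > k(wt, atp, adp)
        assert k(wt, atp, adp + dadp) < k(wt, atp, adp)


class TestBindingHyperbola:
    def test_printed_worked_example(self):
        # single-dataset wild-type stopped-flow parameters at 10 μM ATP
        preset = mk.GenotypePreset(label="wt-single", k1k2_s1=6.6, k_hyd_sum=286.0)
        k = mk.analytic_kobs_binding(preset, 10.0)
        assert k == pytest.approx(53.625, rel=1e-6)
        assert k == pytest.approx(54.7, rel=0.05)

    def test_half_saturation_and_limits(self, wt):
        k05 = wt.k_hyd_sum / wt.k1k2_s1
        assert mk.analytic_kobs_binding(wt, k05) == pytest.approx(wt.k_hyd_sum / 2)
        assert mk.analytic_kobs_binding(wt, 0.0) == 0.0
        assert mk.analytic_kobs_binding(wt, 1e9) == pytest.approx(wt.k_hyd_sum, rel=1e-3)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(atp=st.floats(0.1, 5000.0), datp=st.floats(0.1, 1000.0))
    def test_increasing_and_bounded(self, atp, datp):
        wt = mk.load_preset("wild-type")
        lo = mk.analytic_kobs_binding(wt, atp)
        hi = mk.analytic_kobs_binding(wt, atp + datp)
        assert lo < hi < wt.k_hyd_sum

    def test_low_atp_limb_is_linear(self, wt):
        # well below K0.5 the rate approximates K1k+2·[ATP]
        assert mk.analytic_kobs_binding(wt, 0.01) == pytest.approx(
            wt.k1k2_s1 * 0.01, rel=2e-4
        )


class TestPredictedK05:
    @pytest.mark.parametrize(
        "genotype, expected", [("wild-type", 51.33), ("R759E", 82.59), ("R759E/N509K", 40.4)]
    )
    def test_table_ratios(self, registry, genotype, expected):
        assert mk.predicted_K05(registry[genotype]) == pytest.approx(expected, abs=0.01)

    @pytest.mark.parametrize("genotype", ["wild-type", "R759E", "R759E/N509K"])
    def test_matches_reported_half_saturation(self, registry, genotype):
        preset = registry[genotype]
        assert mk.predicted_K05(preset) == pytest.approx(preset.k05, rel=0.15)

    def test_degenerate_preset(self):
        preset = mk.GenotypePreset(label="deg", k1k2_s1=1e-300, k_hyd_sum=300.0)
        # formally positive but numerically degenerate: a zero-slope preset
        with pytest.raises((ConstructionError, IncompletePresetError)):
            mk.predicted_K05(mk.GenotypePreset(label="none", k_hyd_sum=300.0))
        assert mk.predicted_K05(preset) > 1e100


# ---------------------------------------------------------------------------
# elementary rates
# ---------------------------------------------------------------------------

class TestMicroFromPreset:
    def test_scheme2_composites(self, wt):
        micro = mk.micro_from_preset(wt, "scheme2")
        assert micro.k_plus1 / micro.k_minus1 * micro.k_plus2 == pytest.approx(
            wt.k1k2_acto, rel=1e-9
        )
        assert micro.adp_off / micro.adp_on == pytest.approx(wt.k_ad, rel=1e-9)

    def test_scheme1_composites_and_split(self, wt):
        micro = mk.micro_from_preset(wt, "scheme1", hydrolysis_equilibrium=3.0)
        assert micro.k_plus3 == pytest.approx(231.0)
        assert micro.k_minus3 == pytest.approx(77.0)
        assert micro.k_plus3 + micro.k_minus3 == pytest.approx(wt.k_hyd_sum)
        assert micro.k_plus1 / micro.k_minus1 * micro.k_plus2 == pytest.approx(
            wt.k1k2_s1, rel=1e-9
        )
        assert micro.k_plus2 >= 100.0 * wt.k_hyd_sum

    def test_degenerate_preset_fails_construction(self):
        preset = mk.GenotypePreset(label="no-s1")
        with pytest.raises(IncompletePresetError):
            mk.micro_from_preset(preset, "scheme1")

    def test_rate_cap_enforced(self, wt):
        with pytest.raises(ConstructionError):
            mk.micro_from_preset(wt, "scheme1", stiffness_factor=1e5)

    def test_stiffness_floor(self, wt):
        with pytest.raises(ValueError):
            mk.micro_from_preset(wt, "scheme2", stiffness_factor=5.0)


# ---------------------------------------------------------------------------
# ODE simulation
# ---------------------------------------------------------------------------

class TestSimulateScheme:
    def test_no_ligand_no_flux(self, wt):
        micro = mk.micro_from_preset(wt, "scheme2")
        traj = mk.simulate_scheme(micro, atp=0.0, adp=0.0, duration=1.0)
        assert np.allclose(traj.occupancy("A.M"), 1.0)

    @pytest.mark.parametrize("scheme, atp", [("scheme1", 50.0), ("scheme2", 100.0)])
    def test_conservation_and_bounds(self, wt, scheme, atp):
        micro = mk.micro_from_preset(wt, scheme)
        traj = mk.simulate_scheme(micro, atp=atp, duration=0.1, n_points=300)
        total = traj.occupancies.sum(axis=1)
        assert np.max(np.abs(total - 1.0)) < 1e-8
        assert traj.occupancies.min() >= 0.0
        assert traj.occupancies.max() <= 1.0

    def test_starts_fully_in_initial_state(self, wt):
        micro = mk.micro_from_preset(wt, "scheme1")
        traj = mk.simulate_scheme(micro, atp=100.0, duration=0.05)
        assert traj.occupancy("M")[0] == pytest.approx(1.0)

    def test_scheme2_oracle_matches_closed_form(self, wt):
        """Light-scattering decays from the simulated scheme reproduce the
        competition equation within 2% across the ATP × ADP design."""
        micro = mk.micro_from_preset(wt, "scheme2", stiffness_factor=100.0)
        for atp in (25.0, 50.0, 100.0, 250.0, 500.0):
            for adp in (0.0, wt.k_ad / 2, wt.k_ad):
                k_true = mk.analytic_kobs_dissociation(wt, atp, adp)
                times = np.geomspace(5 * LN2 / k_true / 2000, 5 * LN2 / k_true, 200)
                traj = mk.simulate_scheme(micro, atp=atp, adp=adp, times=times)
                trace = mk.observable_projection(traj, "light_scattering")
                assert _fit_trace(trace) == pytest.approx(k_true, rel=0.02)

    def test_scheme1_limits_match_hyperbola(self, r759e):
        """Tryptophan transients from the simulated scheme recover the
        hyperbola's two limbs: the linear binding regime at low [ATP] and
        the hydrolysis plateau k+3 + k-3 at saturation."""
        micro = mk.micro_from_preset(r759e, "scheme1")
        for atp, target in [(5.0, mk.analytic_kobs_binding(r759e, 5.0)),
                            (5000.0, r759e.k_hyd_sum)]:
            k_ref = mk.analytic_kobs_binding(r759e, atp)
            times = 1.5e-3 + np.geomspace(5 * LN2 / k_ref / 2000, 5 * LN2 / k_ref, 200)
            traj = mk.simulate_scheme(micro, atp=atp, times=times)
            trace = mk.observable_projection(traj, "trp_fluorescence")
            assert _fit_trace(trace) == pytest.approx(target, rel=0.05)

    def test_split_invariance(self, wt):
        """Only the sum k+3 + k-3 is observable: the fitted rate is invariant
        (within 2%) to how the sum is split between forward and reverse."""
        rates = []
        for eq in (0.5, 3.0, 9.0):
            micro = mk.micro_from_preset(wt, "scheme1", hydrolysis_equilibrium=eq)
            k_ref = mk.analytic_kobs_binding(wt, 100.0)
            times = 1.5e-3 + np.geomspace(5 * LN2 / k_ref / 2000, 5 * LN2 / k_ref, 200)
            traj = mk.simulate_scheme(micro, atp=100.0, times=times)
            rates.append(_fit_trace(mk.observable_projection(traj, "trp_fluorescence")))
        assert np.ptp(rates) / np.mean(rates) < 0.02


class TestObservableProjection:
    def test_light_scattering_starts_maximal_ends_at_floor(self, wt):
        micro = mk.micro_from_preset(wt, "scheme2")
        k = mk.analytic_kobs_dissociation(wt, 500.0)
        traj = mk.simulate_scheme(micro, atp=500.0, duration=10 * LN2 / k)
        trace = mk.observable_projection(traj, "light_scattering", amplitude=2.0, floor=0.5)
        assert trace.signal[0] == pytest.approx(2.5)
        assert trace.signal[-1] == pytest.approx(0.5, abs=1e-2)

    def test_trp_amplitude_in_configured_band(self, wt):
        micro = mk.micro_from_preset(wt, "scheme1")
        k = mk.analytic_kobs_binding(wt, 100.0)
        traj = mk.simulate_scheme(micro, atp=100.0, duration=8 * LN2 / k)
        trace = mk.observable_projection(traj, "trp_fluorescence", relative_amplitude=0.035)
        change = (trace.signal.max() - trace.signal.min()) / trace.signal.min()
        assert 0.03 <= change <= 0.04

    def test_scheme_signal_mismatch_rejected(self, wt):
        micro = mk.micro_from_preset(wt, "scheme1")
        traj = mk.simulate_scheme(micro, atp=100.0, duration=0.05)
        with pytest.raises(SignalSchemeMismatchError):
            mk.observable_projection(traj, "light_scattering")
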