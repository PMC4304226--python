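"""Kinetics simulator: survival quadrature, protocols, fixtures, rendering."""

import numpy as np
import pytest

from cryoftir.bandfit import GaussianBand, fit_n_bands
from cryoftir.fixtures import (
    TABLE_BANDS,
    fixture_names,
    make_fixture,
    model_from_dict,
    model_to_dict,
)
from cryoftir.simulate import (
    BarrierDistribution,
    Exchange,
    Protocol,
    Schedule,
    SpeciesNetwork,
    SubstateModel,
    monte_carlo_survival,
    photolysis_difference,
    render_class_difference,
    render_series,
    run_protocol,
    survival_fraction,
)
from cryoftir.spectra import GAUSS_AREA_FACTOR, BandRegion
from cryoftir.tds import R_GAS, build_tds_map, extract_peaks

from conftest import single_substate_model


class TestSurvivalFraction:
    def test_frozen_limit_survival_is_one(self):
        bd = BarrierDistribution(10.0, 2.0)
        assert survival_fraction(bd, Schedule.constant(0.0, 1000.0)) == pytest.approx(1.0)

    def test_delta_barrier_constant_temperature_closed_form(self):
        H, T, t, nu = 10.0, 60.0, 500.0, 10**8.5
        bd = BarrierDistribution(H, 0.0)
        k = nu * np.exp(-H * 1e3 / (R_GAS * T))
        got = survival_fraction(bd, Schedule.constant(T, t), prefactor=nu)
        assert got == pytest.approx(np.exp(-k * t), rel=1e-6)

    def test_quadrature_agrees_with_monte_carlo_on_random_schedules(self):
        rng = np.random.default_rng(42)
        n_mol = 100_000
        for i in range(10):
            bd = BarrierDistribution(rng.uniform(3, 30), rng.uniform(0, 5))
            if rng.integers(0, 2) == 0:
                sched = Schedule.constant(rng.uniform(10, 120), rng.uniform(100, 2000))
            else:
                T0 = rng.uniform(4, 40)
                sched = Schedule.ramp(T0, T0 + rng.uniform(20, 150), 1 / 60)
            q = survival_fraction(bd, sched)
            mc = monte_carlo_survival(bd, sched, n_molecules=n_mol, seed=i)
            se = max(np.sqrt(max(q * (1 - q), 0.0) / n_mol), 1e-5)
            assert abs(mc - q) <= 3 * se


class TestRunProtocol:
    def test_zero_power_zero_duration_leaves_populations_unchanged(self):
        model = single_substate_model(12.0)
        res = run_protocol(model, Protocol.flash_4K(duration=0.0, power=0.0))
        pops = res.populations["A1945"]
        assert pops["bound"][-1] == pytest.approx(1.0, abs=1e-12)
        assert pops["photoproduct"][-1] == pytest.approx(0.0, abs=1e-12)

    def test_frozen_flash_yield_without_rebinding(self):
        # barriers far above R*T*ln(prefactor*t): photolysis yield only
        model = single_substate_model(30.0)
        res = run_protocol(model, Protocol.flash_4K(duration=10.0, power=300.0))
        kp = model.photolysis_coeff * 300.0
        expected = 1 - np.exp(-kp * 10.0)
        assert res.populations["A1945"]["photoproduct"][-1] == pytest.approx(
            expected, rel=1e-6)

    def test_full_power_flash_saturates_photolysis(self):
        model = single_substate_model(30.0)
        res = run_protocol(model, Protocol.flash_4K())
        assert res.populations["A1945"]["photoproduct"][-1] > 0.999

    def test_unknown_protocol_kind_rejected(self):
        with pytest.raises(ValueError):
            run_protocol(single_substate_model(12.0), Protocol("anneal", 10.0))

    @pytest.mark.parametrize("protocol", [
        Protocol.flash_4K(),
        Protocol.slow_cool(),
        Protocol.constant_illumination(10.0, 2000.0),
        Protocol.tds_ramp(T_end=80.0),
    ], ids=lambda p: p.kind)
    def test_mass_conservation_substates(self, protocol):
        model = make_fixture("L-Arg", "CO")
        res = run_protocol(model, protocol)
        total = sum(
            res.populations[s.label]["bound"] + res.populations[s.label]["photoproduct"]
            for s in model.substates
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    @pytest.mark.parametrize("protocol", [
        Protocol.flash_4K(),
        Protocol.constant_illumination(300.0, 2000.0),
        Protocol.tds_ramp(T_end=80.0),
    ], ids=lambda p: p.kind)
    def test_mass_conservation_network(self, protocol):
        model = make_fixture("wo_substrate", "NO")
        res = run_protocol(model, protocol)
        total = sum(res.populations[k] for k in SpeciesNetwork.STATES)
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_truth_record_embeds_inputs(self):
        model = make_fixture("NOHA", "CO")
        res = run_protocol(model, Protocol.flash_4K(), seed=77)
        assert res.truth["seed"] == 77
        assert res.truth["protocol"]["kind"] == "flash_4K"
        assert res.truth["prefactor"] > 0

    def test_higher_barrier_means_higher_peak_temperature(self):
        peaks = []
        for H in [5.0, 8.0, 12.0, 16.0, 20.0]:
            model = single_substate_model(H, 1.0)
            flash = run_protocol(model, Protocol.flash_4K())
            ramp = run_protocol(model, Protocol.tds_ramp(), initial_state=flash.final_state)
            series = render_series(model, ramp)
            tmap = build_tds_map(series)
            found = extract_peaks(tmap, 1e-6, regions=[BandRegion(1900, 1990)])
            peaks.append(max(found, key=lambda p: p.amplitude).T_peak)
        assert all(a < b for a, b in zip(peaks, peaks[1:]))


class TestProtocolEquivalence:
    """Single-site models populate only one kinetic state regardless of protocol."""

    def test_slow_cool_and_flash_share_band_inventory(self):
        model = single_substate_model(12.0, 1.0)
        specs = {}
        for name, proto in [("flash", Protocol.flash_4K()),
                            ("slow_cool", Protocol.slow_cool())]:
            res = run_protocol(model, proto)
            p = res.populations["A1945"]["photoproduct"][-1]
            assert p > 0.1
            specs[name] = photolysis_difference(model, photolysis=p)
        for name, spec in specs.items():
            fit = fit_n_bands(spec, 1, BandRegion(2100, 2160), "photoproduct", 6.0)
            assert len(fit.bands) == 1
            assert fit.bands[0].center == pytest.approx(2130, abs=0.5)

    def test_single_site_photoproduct_map_is_single_signed(self):
        model = single_substate_model(12.0, 1.0)
        flash = run_protocol(model, Protocol.flash_4K())
        ramp = run_protocol(model, Protocol.tds_ramp(), initial_state=flash.final_state)
        series = render_series(model, ramp)
        tmap = build_tds_map(series)
        m = BandRegion(2080, 2160).mask(tmap.grid)
        assert np.all(tmap.delta[:, m] <= 1e-15)  # pure photoproduct loss
        a = BandRegion(1900, 1990).mask(tmap.grid)
        assert np.all(tmap.delta[:, a] >= -1e-15)  # pure A-band gain

    def test_two_site_exchange_produces_mirror_imaged_contours(self):
        # CO rotation: photoproduct population transfers 2131 -> 2144 around
        # 12 K while rebinding is frozen out by a high barrier
        model = single_substate_model(
            60.0,
            photo_bands=[GaussianBand(2131, 6, 50.0), GaussianBand(2144, 6, 50.0)],
            exchange=Exchange(0, 1, BarrierDistribution(2.4, 0.0)),
        )
        flash = run_protocol(model, Protocol.flash_4K())
        ramp = run_protocol(model, Protocol.tds_ramp(T_end=40.0),
                            initial_state=flash.final_state)
        series = render_series(model, ramp)
        tmap = build_tds_map(series)
        loss = integrate_band_rows(tmap, BandRegion(2125, 2137))
        gain = integrate_band_rows(tmap, BandRegion(2138, 2150))
        assert loss.sum() < 0 < gain.sum()
        # mirror-imaged up to the ~5% band tails crossing the window cut
        np.testing.assert_allclose(gain, -loss, rtol=0.05, atol=1e-10)
        assert abs(np.argmax(gain) - np.argmin(loss)) <= 1


def integrate_band_rows(tmap, region):
    m = region.mask(tmap.grid)
    return np.trapezoid(tmap.delta[:, m], tmap.grid.values[m], axis=1)


class TestSpeciesNetworkPhotochemistry:
    def test_low_power_leaves_5c_unpopulated_high_power_saturates(self):
        model = make_fixture("wo_substrate", "NO")
        five_c = {}
        for power in (0.3, 300.0):
            res = run_protocol(model, Protocol.constant_illumination(power))
            five_c[power] = res.populations["5C-ferric-NO"][-1]
        assert five_c[0.3] < 0.02 * model.initial_ferrous
        assert five_c[300.0] > 0.95 * model.initial_ferrous

    def test_ferric_no_photolyzes_even_at_low_power(self):
        model = make_fixture("wo_substrate", "NO")
        res = run_protocol(model, Protocol.constant_illumination(0.3))
        photolyzed = res.populations["NO-photoproduct"][-1]
        # low power still photodissociates NO from the 6C ferric heme
        # (photostationary with the fast-rebinding fraction)
        assert photolyzed > 0.5 * model.initial_ferric

    def test_broad_photoproduct_band_hides_below_noise(self):
        """The unbound-NO band conserves integrated extinction but is so
        broad its peak amplitude stays below twice the 1% noise floor."""
        model = make_fixture("wo_substrate", "NO")
        diff = photolysis_difference(model, 1.0, noise_pct=0.0)
        peak_amp = np.max(np.abs(diff.delta_absorbance))
        sigma = 0.01 * peak_amp
        broad_amp = (model.initial_ferric / model.extinction_ratio) / (
            model.photoproduct_band.fwhm * GAUSS_AREA_FACTOR)
        assert broad_amp < 2 * sigma

    def test_5c_dark_recovery_happens_between_80_and_120_K(self):
        model = make_fixture("wo_substrate", "NO")
        lit = run_protocol(model, Protocol.constant_illumination(300.0))
        ramp = run_protocol(model, Protocol.tds_ramp(), initial_state=lit.final_state)
        n5 = ramp.populations["5C-ferric-NO"]
        T = ramp.temperatures
        decay = -(np.diff(n5))
        T_peak = T[np.argmax(decay)]
        assert 80.0 <= T_peak <= 120.0
        assert n5[-1] < 0.01 * n5[0]


class TestFixtures:
    def test_eight_fixture_names(self):
        assert len(fixture_names()) == 8

    def test_larg_co_band_counts(self):
        model = make_fixture("L-Arg", "CO")
        assert len(model.substates) == 3
        assert len(model.photoproduct_sets["flash"]) == 4

    def test_wo_substrate_no_has_ferrous_and_5c_states(self):
        model = make_fixture("wo_substrate", "NO")
        assert model.ferrous_band.center == 1616
        assert sorted(b.center for b in model.fivec_bands) == [1814, 1818]

    @pytest.mark.parametrize("name", fixture_names())
    def test_fractions_sum_to_100(self, name):
        sample, ligand = name.split(":")
        model = make_fixture(sample, ligand)
        if isinstance(model, SubstateModel):
            assert sum(s.population_fraction for s in model.substates) == pytest.approx(100)
            for key, bands in model.photoproduct_sets.items():
                assert sum(b.area for b in bands) == pytest.approx(100)
        else:
            assert sum(abs(b.area) for b in model.bound_bands) == pytest.approx(100)
            if model.fivec_bands:
                assert sum(abs(b.area) for b in model.fivec_bands) == pytest.approx(100)

    def test_unknown_names_rejected(self):
        with pytest.raises(ValueError):
            make_fixture("myoglobin", "CO")
        with pytest.raises(ValueError):
            make_fixture("L-Arg", "O2")

    @pytest.mark.parametrize("name", ["L-Arg:CO", "wo_substrate:NO"])
    def test_serialization_round_trip(self, name):
        sample, ligand = name.split(":")
        model = make_fixture(sample, ligand)
        clone = model_from_dict(model_to_dict(model))
        assert model_to_dict(clone) == model_to_dict(model)


class TestRendering:
    def test_zero_populations_render_flat(self):
        model = single_substate_model(12.0)
        res = run_protocol(model, Protocol.flash_4K(duration=0.0, power=0.0))
        diff = photolysis_difference(model, photolysis=0.0)
        np.testing.assert_array_equal(diff.delta_absorbance, 0.0)
        del res

    def test_full_photolysis_difference_recovers_table_centers(self):
        model = make_fixture("wo_substrate", "CO")
        diff = render_class_difference(model, "bound", noise_pct=1.0, seed=3)
        fit = fit_n_bands(diff, 3, BandRegion(1800, 2000), "bound", 10.0)
        got = sorted(b.center for b in fit.bands)
        for got_c, (true_c, _) in zip(got, TABLE_BANDS["wo_substrate"]["bound_CO"]):
            assert got_c == pytest.approx(true_c, abs=0.5)

    def test_noise_scales_with_tallest_amplitude(self):
        model = make_fixture("H4B", "CO")
        clean = photolysis_difference(model, 1.0)
        noisy = photolysis_difference(model, 1.0, noise_pct=1.0, seed=5)
        resid = noisy.delta_absorbance - clean.delta_absorbance
        sigma = np.std(resid)
        expected = 0.01 * np.max(np.abs(clean.delta_absorbance))
        assert sigma == pytest.approx(expected, rel=0.15)
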