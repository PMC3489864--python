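"""Clock-model builders, modulation-factor contracts, perturbation
transforms, and the combinatorial phase theory."""

import numpy as np
import pytest

from circadde.clock import (CCE_SITES, GENES, CoreClockParams,
                            apply_knockdown, apply_ld_forcing,
                            build_core_clock_model, build_nr_loop_model,
                            build_per2_model, limit_cycle, modulation_trace)
from circadde.cosinor import circular_diff
from circadde.dde import detect_period, get_param, integrate, steady_state, \
    with_param
from circadde.fitting import measure_phases
from circadde.phasors import (antiphase_synergy_reduction,
                              combined_modulator_phase, halflife_phase_shift,
                              phase_range_prediction)


class TestBasalContract:
    """Vanishing regulator concentrations return the basal rates."""

    def models(self):
        yield build_per2_model()
        yield build_nr_loop_model()
        yield build_core_clock_model(CoreClockParams())

    def test_every_factor_is_basal_at_zero_regulators(self):
        for m in self.models():
            for g in m.variable_names:
                for f in m.productions[g]:
                    assert f.value(0.0) == pytest.approx(f.basal, abs=1e-14)

    def test_production_at_zero_state_is_basal_product(self):
        m = build_core_clock_model(CoreClockParams())
        zero = np.zeros(m.n)
        for g in GENES:
            expected = m.production_scale[g] * np.prod(
                [f.basal for f in m.productions[g]])
            assert m.production(g, x=zero) == pytest.approx(expected)

    def test_factor_bounded_for_nonnegative_inputs(self):
        for m in self.models():
            for g in m.variable_names:
                for f in m.productions[g]:
                    xs = np.linspace(0, 50, 300)
                    vals = np.array([f.value(x) for x in xs])
                    hi = f.basal * max(1.0, f.strength)
                    assert np.all(vals >= 0) and np.all(vals <= hi + 1e-12)


class TestPer2Model:
    def test_nonstandard_exponent_warns(self):
        with pytest.warns(UserWarning, match="two E-box"):
            build_per2_model(exponent=3)

    def test_calibrated_oscillates_near_24h_at_8h_delay(self,
                                                        per2_calibrated):
        model, info = per2_calibrated
        assert info["period_h"] == pytest.approx(24.0, abs=0.5)
        assert info["rel_amplitude"] > 0.5

    def test_damped_below_onset(self, per2_calibrated):
        model, _ = per2_calibrated
        m = with_param(model, "tau:Per2:Per2", 4.0)
        traj = integrate(m, steady_state(m) + 0.5, 600.0, step=0.05)
        assert not detect_period(traj, "Per2").oscillating

    def test_self_modulator_peak_lags_trough_by_exactly_tau(
            self, per2_calibrated):
        # inhibitory self-factor peaks exactly where the delayed mRNA
        # is at its trough: lag(modulator peak, mRNA trough) = tau
        from circadde.clock import modulator_antiphase_lag
        model, _ = per2_calibrated
        tau = get_param(model, "tau:Per2:Per2")
        traj = limit_cycle(model, t_end=480.0)
        lag = modulator_antiphase_lag(model, traj, "Per2", "Per2")
        assert lag == pytest.approx(tau, abs=0.1)


@pytest.fixture(scope="module")
def nr_loop():
    from circadde.clock import calibrate_nr_loop_model
    return calibrate_nr_loop_model(seed=0, n_starts=5)


def _peak_width_half_prominence(traj, gene):
    info = detect_period(traj, gene, cv_threshold=np.inf)
    t1 = traj.times[-1]
    t = np.linspace(t1 - info.period_h, t1, 2400, endpoint=False)
    x = traj(t)[:, traj.variable_names.index(gene)]
    half = 0.5 * (x.max() + x.min())
    return info.period_h * np.mean(x > half)


class TestNrLoop:
    def test_missing_delays_rejected(self):
        with pytest.raises(ValueError, match="delays"):
            build_nr_loop_model(tau_bmal1=None)

    def test_calibrated_loop_sustains_24h_class_oscillation(self, nr_loop):
        model, info = nr_loop
        assert info["period_h"] == pytest.approx(24.0, abs=1.0)
        assert info["separation_h"] == pytest.approx(17.0, abs=1.5)

    def test_larger_delays_sharpen_peaks(self, nr_loop):
        # delay growth also lengthens the period, so sharpness is the
        # Bmal1 peak's width as a fraction of its own cycle
        model, _ = nr_loop
        widths = []
        for ds in (-1.0, 0.0, 1.0):
            m = with_param(model, "tau:Rev-erba:Bmal1",
                           get_param(model, "tau:Rev-erba:Bmal1") + ds)
            m = with_param(m, "tau:Bmal1:Rev-erba",
                           get_param(m, "tau:Bmal1:Rev-erba") + ds)
            traj = limit_cycle(m, t_end=600.0)
            info = detect_period(traj, "Bmal1", cv_threshold=np.inf)
            widths.append(_peak_width_half_prominence(traj, "Bmal1")
                          / info.period_h)
        assert widths[0] > widths[1] > widths[2]

    def test_phase_difference_controlled_by_delay_and_degradation_not_basal(
            self, nr_loop):
        model, _ = nr_loop

        def separation_change(param):
            out = []
            for f in (0.85, 1.15):
                m = with_param(model, param, get_param(model, param) * f)
                traj = limit_cycle(m, t_end=600.0)
                _, ph, _ = measure_phases(traj)
                out.append(abs(circular_diff(
                    (ph["Bmal1"] - ph["Rev-erba"]) % 24.0, 17.0)))
            return max(out)

        strong = [separation_change("tau:Bmal1:Rev-erba"),
                  separation_change("deg:Rev-erba")]
        weak = [separation_change("basal:Bmal1:Rev-erba"),
                separation_change("basal:Rev-erba:Bmal1")]
        assert min(strong) > max(weak)


class TestCoreClockBuild:
    def test_factor_table_mismatch_is_reported(self):
        p = CoreClockParams()
        p.factors[("Bmal1", "Dbp")] = {"basal": 1.0}
        with pytest.raises(ValueError, match="site table"):
            build_core_clock_model(p)

    def test_missing_degradation_reported(self):
        p = CoreClockParams()
        del p.degradation_rates["Cry1"]
        with pytest.raises(ValueError, match="degradation"):
            build_core_clock_model(p)

    def test_exponents_match_site_counts(self):
        m = build_core_clock_model(CoreClockParams())
        for g in GENES:
            counts = {r: n for _c, r, _role, n in CCE_SITES[g]}
            for f in m.productions[g]:
                assert f.exponent == counts[f.regulator]


class TestPerturbationTransforms:
    def test_knockdown_fraction_one_is_identity(self, liver_model):
        m = apply_knockdown(liver_model, "Dbp", 1.0)
        a = integrate(liver_model, np.ones(6), 100.0, step=0.1)
        b = integrate(m, np.ones(6), 100.0, step=0.1)
        assert np.array_equal(a.states, b.states)

    def test_knockdown_fraction_out_of_range(self, liver_model):
        with pytest.raises(ValueError, match="fraction"):
            apply_knockdown(liver_model, "Dbp", 1.2)

    def test_zero_forcing_is_identity(self, liver_model):
        m = apply_ld_forcing(liver_model, "Per2", 0.0)
        a = integrate(liver_model, np.ones(6), 100.0, step=0.1)
        b = integrate(m, np.ones(6), 100.0, step=0.1)
        assert np.allclose(a.states, b.states, rtol=1e-12)

    def test_negative_forcing_rejected(self, liver_model):
        with pytest.raises(ValueError, match="strength"):
            apply_ld_forcing(liver_model, "Per2", -0.5)

    def test_unknown_gene_rejected(self, liver_model):
        with pytest.raises(KeyError):
            apply_knockdown(liver_model, "Nr1d2", 0.5)


class TestModulationTrace:
    def test_product_of_traces_is_production(self, liver_model, liver_cycle):
        for gene in ("Cry1", "Dbp", "Bmal1"):
            mt = modulation_trace(liver_model, liver_cycle, gene)
            recon = np.prod(list(mt.factor_traces.values()), axis=0) \
                * liver_model.production_scale[gene]
            assert np.allclose(recon, mt.production, rtol=1e-12)

    def test_unknown_gene_rejected(self, liver_model, liver_cycle):
        with pytest.raises(KeyError):
            modulation_trace(liver_model, liver_cycle, "Npas2")

    def test_bmal1_production_peaks_at_delayed_reverba_minimum(
            self, liver_model, liver_cycle):
        mt = modulation_trace(liver_model, liver_cycle, "Bmal1")
        _, ph, _ = measure_phases(liver_cycle)
        tau = liver_model.productions["Bmal1"][0].delay_h
        rev_min = (ph["Rev-erba"] + 12.0 + tau * 24.0 / mt.period_h) % 24.0
        assert abs(circular_diff(mt.phases["production"][0], rev_min)) < 1.0

    def test_dbp_production_phase_between_its_ebox_modulators(
            self, liver_model, liver_cycle):
        mt = modulation_trace(liver_model, liver_cycle, "Dbp")
        phB = mt.phases["Bmal1"][0]
        phP = mt.phases["Per2"][0]
        prod = mt.phases["production"][0]
        span = (phP - phB) % 24.0
        assert span < 12.0
        assert 0.0 <= (prod - phB) % 24.0 <= span


class TestPhasorTheory:
    def test_single_component_keeps_phase(self):
        ph, amp = combined_modulator_phase([(0.4, 9.0)])
        assert ph == pytest.approx(9.0, abs=0.01)
        assert amp == pytest.approx(0.4, abs=1e-6)

    def test_equal_amplitudes_give_midpoint_phase(self):
        ph, _ = combined_modulator_phase([(0.5, 4.0), (0.5, 10.0)])
        assert ph == pytest.approx(7.0, abs=0.01)

    def test_unequal_amplitudes_match_dense_product_oracle(self):
        ph, _ = combined_modulator_phase([(0.8, 5.0), (0.2, 15.0)])
        t = np.linspace(0, 24, 240000, endpoint=False)
        w = 2 * np.pi / 24
        prod = (1 + 0.8 * np.cos(w * (t - 5.0))) \
            * (1 + 0.2 * np.cos(w * (t - 15.0)))
        assert abs(circular_diff(ph, t[np.argmax(prod)])) < 0.5

    def test_all_zero_amplitudes_undefined(self):
        ph, amp = combined_modulator_phase([(0.0, 5.0), (0.0, 12.0)])
        assert ph is None and amp == 0.0

    def test_synergy_zero_inhibitor_is_identity(self):
        eq = antiphase_synergy_reduction((0.5, 6.0), (0.0, 18.0))
        assert eq.amplitude == pytest.approx(0.5)
        assert eq.phase_ct == pytest.approx(6.0)

    def test_exact_antiphase_pair_enlarges_amplitude(self):
        eq = antiphase_synergy_reduction((0.3, 6.0), (0.3, 18.0))
        assert eq.amplitude == pytest.approx(0.6, abs=1e-9)
        assert eq.phase_ct == pytest.approx(6.0, abs=1e-9)

    def test_synergy_rms_error_below_10pct(self):
        act, inh = (0.3, 6.0), (0.3, 18.0)
        eq = antiphase_synergy_reduction(act, inh)
        t = np.linspace(0, 24, 2400, endpoint=False)
        w = 2 * np.pi / 24
        # inhibitory modulation of an antiphase regulator, first harmonic
        exact = (1 + 0.3 * np.cos(w * (t - 6.0))) \
            * (1 - 0.3 * np.cos(w * (t - 18.0)))
        approx = 1 + eq.amplitude * np.cos(w * (t - eq.phase_ct))
        rms = np.sqrt(np.mean((exact - approx) ** 2))
        assert rms / np.mean(exact) < 0.10

    def test_non_antiphase_pair_warns(self):
        with pytest.warns(UserWarning, match="antiphase"):
            antiphase_synergy_reduction((0.3, 6.0), (0.3, 10.0))

    def test_halflife_shift_limits(self):
        assert halflife_phase_shift(1e6) == pytest.approx(0.0, abs=1e-5)
        assert halflife_phase_shift(1e-9) == pytest.approx(6.0, abs=1e-3)

    def test_halflife_shift_two_hour_halflife(self):
        d = np.log(2) / 2.0
        assert halflife_phase_shift(d) == pytest.approx(2.47, abs=0.01)

    def test_phase_range_eboxes_covers_printed_interval(self):
        lo, hi = phase_range_prediction({"E"})
        # attainable E-box window brackets the canonical CT 6-13 band
        assert lo <= 6.0 and hi >= 13.0
        assert lo == pytest.approx(5.0, abs=1.5)

    def test_phase_range_e_and_d_matches_printed_interval(self):
        lo, hi = phase_range_prediction({"E", "D"})
        assert lo == pytest.approx(6.0, abs=1.5)
        assert hi == pytest.approx(18.0, abs=1.5)

    def test_phase_range_rre_starts_at_modulator_phase(self):
        lo, hi = phase_range_prediction({"R"})
        assert lo == pytest.approx(22.0, abs=0.1)
        assert hi == pytest.approx(4.0, abs=0.1)  # + 6 h half-life span

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            phase_range_prediction(set())
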