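import numpy as np
import pytest
from scipy.integrate import solve_ivp

from retistim.cable import (
    GATES,
    RATE_FUNCTIONS,
    REGIONS,
    ChannelParams,
    ConfigurationError,
    Morphometry,
    RegionConductances,
    SampledWaveform,
    SimResult,
    StimulusWaveform,
    build_cable,
    detect_spikes,
    initiation_site,
    make_waveform,
    simulate,
)
from retistim.fields import point_source_potential
from retistim.geometry import GeometryError
from retistim.thresholds import neuron_threshold, point_source_scenario

FARADAY = 96485.332


def straight_path(length_um, extra=200.0):
    n = int(length_um + extra) + 1
    return np.column_stack(
        [np.linspace(0, length_um + extra, n), np.zeros(n), np.zeros(n)]
    )


class TestMorphometry:
    def test_default_total_3000(self):
        m = Morphometry()
        assert m.total_length_um == 3000.0

    def test_compartment_count(self, straight_chain):
        assert straight_chain.n_compartments == 3000

    def test_straight_path_collinear(self, straight_chain):
        c = straight_chain.centers_um
        assert np.allclose(c[:, 1:], 0.0)
        assert np.allclose(np.diff(c[:, 0]), 1.0)

    def test_membrane_area_closed_form(self, straight_chain):
        m = straight_chain.morphometry
        for region in REGIONS:
            sl = straight_chain.region_slice(region)
            total = straight_chain.area_cm2[sl].sum()
            expected = np.pi * m.diameters_um[region] * m.lengths_um[region] * 1e-8
            assert total == pytest.approx(expected, rel=1e-12)

    def test_compartment_length_must_divide(self):
        with pytest.raises(ConfigurationError):
            Morphometry(compartment_length_um=7.0)

    def test_short_path_raises(self):
        with pytest.raises(GeometryError):
            build_cable(Morphometry(), straight_path(1000.0, extra=0.0))

    def test_with_total_length(self):
        m = Morphometry().with_total_length(1500.0)
        assert m.total_length_um == 1500.0
        with pytest.raises(ConfigurationError):
            Morphometry().with_total_length(100.0)

    def test_socb_na_must_dominate(self):
        gb = {r: RegionConductances(100.0, 20.0, 0.0, 0.065, 1.5) for r in REGIONS}
        with pytest.raises(ConfigurationError):
            ChannelParams(gbar=gb)


class TestWaveform:
    def test_five_pulse_onsets(self):
        spec = StimulusWaveform()
        assert spec.n_pulses == 5
        assert np.allclose(spec.pulse_onsets_ms, [0.0, 50.0, 100.0, 150.0, 200.0])

    def test_charge_balance_exact(self):
        wave = make_waveform(123.4, StimulusWaveform())
        assert wave.charge_nC() == pytest.approx(0.0, abs=1e-9)

    def test_cathodic_first(self):
        wave = make_waveform(100.0, StimulusWaveform())
        first = wave.samples_uA[np.nonzero(wave.samples_uA)[0][0]]
        assert first < 0

    def test_unbalanced_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            StimulusWaveform(anodic_width_ms=0.9, anodic_scale=1.0)

    def test_asymmetric_balanced_ok(self):
        spec = StimulusWaveform(anodic_width_ms=0.9, anodic_scale=0.5)
        wave = make_waveform(50.0, spec)
        assert wave.charge_nC() == pytest.approx(0.0, abs=1e-9)

    def test_pulse_must_fit(self):
        with pytest.raises(ConfigurationError):
            StimulusWaveform(pulse_width_ms=30.0, frequency_hz=20.0)


class TestRestingState:
    def test_zero_field_quiescent(self, straight_chain):
        spec = StimulusWaveform(train_duration_ms=300.0, dt_ms=0.01)
        res = simulate(
            straight_chain,
            np.zeros(3000),
            make_waveform(0.0, spec),
            dt_ms=0.01,
            record_every=10**9,
        )
        assert len(res.event_times_ms) == 0
        assert np.max(np.abs(res.final_V - straight_chain.rest_V)) < 0.5

    def test_gates_bounded_and_ca_positive(self, straight_chain, short_wave_spec):
        chain, ve = point_source_scenario(100.0)
        res = simulate(chain, ve, make_waveform(300.0, short_wave_spec), dt_ms=0.01)
        assert res.final_gates.min() >= 0.0 and res.final_gates.max() <= 1.0
        assert res.final_ca.min() > 0.0


class TestIntegration:
    def test_zero_field_no_spikes(self, straight_chain, short_wave_spec):
        res = simulate(
            straight_chain, np.zeros(3000), make_waveform(500.0, short_wave_spec), dt_ms=0.01
        )
        assert len(res.event_times_ms) == 0

    def test_temporal_convergence(self, short_wave_spec):
        chain, ve = point_source_scenario(100.0)
        peaks = {}
        for dt in (0.01, 0.005):
            wave = make_waveform(60.0, StimulusWaveform(train_duration_ms=20.0, dt_ms=dt))
            res = simulate(chain, ve, wave, dt_ms=dt, record_every=1)
            peaks[dt] = res.V_rec.max()
        assert abs(peaks[0.01] - peaks[0.005]) / abs(peaks[0.005]) < 0.01

    def test_suprathreshold_every_pulse(self, short_wave_spec):
        chain, ve = point_source_scenario(100.0)
        spec5 = StimulusWaveform(train_duration_ms=250.0, dt_ms=0.01)
        res = simulate(chain, ve, make_waveform(100.0, spec5), dt_ms=0.01)
        det = detect_spikes(res, spec5.pulse_onsets_ms)
        assert det["spikes_per_pulse"].tolist() == [1, 1, 1, 1, 1]

    def test_overshoot(self, short_wave_spec):
        chain, ve = point_source_scenario(100.0)
        res = simulate(
            chain, ve, make_waveform(100.0, short_wave_spec), dt_ms=0.01, record_every=2
        )
        assert res.V_rec.max() > 0.0


@pytest.fixture(scope="module")
def tiny():
    m = Morphometry(
        lengths_um={r: 1.0 for r in REGIONS},
        diameters_um={r: 10.0 for r in REGIONS},
    )
    p = ChannelParams()
    chain = build_cable(m, straight_path(5.0, extra=5.0), p, settle_ms=50.0)
    return chain, p


class TestSingleCompartmentOracle:
    """The production integrator against an independently hand-coded ODE
    solve of the same rate functions (five identical compartments, constant
    intracellular drive into the first one)."""

    def _reference(self, chain, p, i_inj_nA, t_eval):
        n = chain.n_compartments
        gb = np.empty((n, 5))
        shifts = p.na_shift_by_region()
        leak = p.leak_by_region()
        shift_c = np.array([shifts[REGIONS[ri]] for ri in chain.region_index])
        gl = np.array([leak[REGIONS[ri]] for ri in chain.region_index]) * 1e3 * chain.area_cm2
        for ri, r in enumerate(REGIONS):
            g = p.gbar[r]
            mask = chain.region_index == ri
            for ci, dens in enumerate((g.g_na, g.g_k, g.g_ka, g.g_kca, g.g_ca)):
                gb[mask, ci] = dens * 1e3 * chain.area_cm2[mask]
        cap = p.cm_uF_cm2 * chain.area_cm2 * 1e3

        def rhs(t, y):
            V = y[:n]
            gates = y[n : 7 * n].reshape(n, 6)
            ca = y[7 * n :]
            eca = p.nernst_prefactor_mV * np.log(p.ca_out_mM / ca)
            gna = gb[:, 0] * gates[:, 0] ** 3 * gates[:, 1]
            gk = gb[:, 1] * gates[:, 2] ** 4
            gka = gb[:, 2] * gates[:, 3] ** 3 * gates[:, 4]
            rat = (ca / p.ca_dissoc_mM) ** 2
            gkca = gb[:, 3] * rat / (1 + rat)
            gca = gb[:, 4] * gates[:, 5] ** 3
            ii = (
                gna * (V - p.e_na_mV)
                + (gk + gka + gkca) * (V - p.e_k_mV)
                + gca * (V - eca)
                + gl * (V - p.e_leak_mV)
            )
            ax = np.zeros(n)
            for i in range(n - 1):
                g = chain.axial_uS[i]
                ax[i] += g * (V[i + 1] - V[i])
                ax[i + 1] += g * (V[i] - V[i + 1])
            dV = (-ii + ax + i_inj_nA) / cap
            dg = np.empty((n, 6))
            for gi, gname in enumerate(GATES):
                fa, fb = RATE_FUNCTIONS[gname]
                vv = V - shift_c if gname == "m" else V
                a, b = fa(vv), fb(vv)
                dg[:, gi] = a * (1 - gates[:, gi]) - b * gates[:, gi]
            ica_dens = (gca * 1e-3 / chain.area_cm2) * (V - eca)
            influx = np.maximum(-ica_dens / (2 * FARADAY * 0.1) / (chain.diameter_um / 4), 0.0)
            dca = influx - (ca - p.ca_rest_mM) / p.ca_tau_ms
            return np.concatenate([dV, dg.ravel(), dca])

        y0 = np.concatenate([chain.rest_V, chain.rest_gates.ravel(), chain.rest_ca])
        sol = solve_ivp(rhs, (0, t_eval[-1]), y0, rtol=1e-10, atol=1e-11, dense_output=True, method="LSODA")
        return sol.sol(t_eval)[:n].T

    def test_action_potential_matches_ode(self, tiny):
        chain, p = tiny
        n = chain.n_compartments
        i_inj = np.zeros(n)
        i_inj[0] = 0.3  # strong constant drive -> spiking
        dt = 0.001
        wave = SampledWaveform(
            samples_uA=np.zeros(int(8.0 / dt)), dt_ms=dt, pulse_onsets_ms=np.array([])
        )
        res = simulate(
            chain, np.zeros(n), wave, dt_ms=dt, i_intra_nA=i_inj,
            record_every=1, record_compartments=np.arange(n),
        )
        v_ref = self._reference(chain, p, i_inj, res.t_rec_ms)
        assert res.V_rec.max() > 0.0  # one spike with positive overshoot
        assert np.max(np.abs(res.V_rec - v_ref)) < 0.5

    def test_resting_drift(self, tiny):
        chain, _ = tiny
        n = chain.n_compartments
        wave = SampledWaveform(
            samples_uA=np.zeros(int(300.0 / 0.01)), dt_ms=0.01, pulse_onsets_ms=np.array([])
        )
        res = simulate(chain, np.zeros(n), wave, dt_ms=0.01, record_every=10**9)
        assert np.max(np.abs(res.final_V - chain.rest_V)) < 0.5


class TestSpikeAnalysis:
    def _fake_result(self, comps, times):
        return SimResult(
            t_rec_ms=np.array([]),
            V_rec=np.zeros((0, 0)),
            recorded_compartments=np.array([]),
            event_compartments=np.asarray(comps),
            event_times_ms=np.asarray(times, dtype=float),
            final_V=np.array([]),
            final_gates=np.zeros((0, 6)),
            final_ca=np.array([]),
            dt_ms=0.01,
            spike_threshold_mV=0.0,
            aborted_missed_window=False,
        )

    def test_subthreshold_zero_spikes(self):
        det = detect_spikes(self._fake_result([], []), np.array([0.0, 50.0]))
        assert det["spikes_per_pulse"].tolist() == [0, 0]

    def test_refractory_merging(self):
        res = self._fake_result([7, 7, 7], [1.0, 1.4, 3.0])
        det = detect_spikes(res)
        assert det["per_compartment"][7].tolist() == [1.0, 3.0]

    def test_initiation_single_compartment(self):
        res = self._fake_result([42], [2.0])
        site = initiation_site(res)
        assert site["compartment"] == 42

    def test_initiation_tie_break_smaller_index(self):
        res = self._fake_result([90, 17], [1.0, 1.0])
        assert initiation_site(res)["compartment"] == 17

    def test_no_spike_returns_none(self):
        assert initiation_site(self._fake_result([], [])) is None


class TestNeuralProperties:
    def test_strength_duration_non_increasing(self):
        chain, ve = point_source_scenario(100.0)
        thresholds = []
        for pw in (0.1, 0.45, 1.0):
            spec = StimulusWaveform(
                pulse_width_ms=pw, train_duration_ms=25.0, dt_ms=0.005
            )
            r = neuron_threshold(chain, ve, spec, dt_ms=0.01)
            thresholds.append(r.threshold_uA)
        assert thresholds[0] >= thresholds[1] >= thresholds[2]

    def test_refractoriness_2ms(self):
        chain, ve = point_source_scenario(100.0)
        spec1 = StimulusWaveform(train_duration_ms=25.0)
        r = neuron_threshold(chain, ve, spec1, dt_ms=0.005)
        amp = r.bracket_hi_uA  # just suprathreshold for a single pulse
        spec2 = StimulusWaveform(train_duration_ms=4.0, frequency_hz=500.0, dt_ms=0.005)
        res = simulate(chain, ve, make_waveform(amp, spec2), dt_ms=0.005)
        init = initiation_site(res)
        comp_spikes = detect_spikes(res)["per_compartment"][init["compartment"]]
        # the initiating compartment fires for pulse 1 but not for the
        # identical pulse 2 ms later (refractory)
        assert len(comp_spikes) >= 1
        assert not np.any((comp_spikes >= 2.0) & (comp_spikes < 4.0))

    def test_spatial_convergence_1um_vs_2um(self):
        thr = {}
        for h in (1.0, 2.0):
            m = Morphometry(compartment_length_um=h)
            chain, ve = point_source_scenario(150.0, morphometry=m)
            spec = StimulusWaveform(train_duration_ms=25.0)
            thr[h] = neuron_threshold(chain, ve, spec, dt_ms=0.01).threshold_uA
        assert abs(thr[1.0] - thr[2.0]) / thr[1.0] < 0.02

    def test_distance_threshold_increase(self):
        spec = StimulusWaveform(train_duration_ms=25.0)
        ts = [
            neuron_threshold(*point_source_scenario(d), wave_spec=spec, dt_ms=0.01).threshold_uA
            for d in (50.0, 150.0, 300.0)
        ]
        assert ts[0] < ts[1] < ts[2]
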