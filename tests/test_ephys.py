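"""Feature-extraction tests: closed-form constructions plus recovery of the
generator's ground truth on simulated cells."""

import numpy as np
import pytest

from ctamem import ephys as ep
from ctamem.synthetic import NeuronSimParams, StepProtocol, simulate_neuron_sweeps

DT = 0.1


def make_sweep(v, step_pa=200.0, step_onset=100.0, step_offset=400.0, **kw):
    n = v.size
    defaults = dict(dt_ms=DT, voltage_mv=v, step_pa=step_pa,
                    step_onset_ms=step_onset, step_offset_ms=step_offset,
                    seal_onset_ms=5.0, seal_offset_ms=20.0,
                    baseline_start_ms=step_onset - 50.0,
                    baseline_end_ms=step_onset)
    defaults.update(kw)
    return ep.Sweep(**defaults)


def triangle_spike(thr=-45.0, peak=35.0, trough=-53.0, rise_mv=2.0,
                   fall_mv=1.0, base=-70.0, at_ms=200.0, total_ms=500.0):
    """Flat trace with one sampled triangular AP (slopes exact on the grid)."""
    n = int(total_ms / DT)
    v = np.full(n, base)
    i0 = int(at_ms / DT)
    up = np.arange(base, thr, 0.5)              # 5 V/s approach ramp
    v[i0 - up.size:i0] = up
    rise = np.arange(thr, peak + 1e-9, rise_mv)
    fall = np.arange(peak - fall_mv, trough - 1e-9, -fall_mv)
    wav = np.concatenate([rise, fall])[:n - i0]   # may truncate at trace end
    v[i0:i0 + wav.size] = wav
    v[i0 + wav.size:] = trough
    return make_sweep(v)


class TestDetectSpikes:
    def test_flat_trace_empty(self):
        sw = make_sweep(np.full(5000, -70.0))
        assert ep.detect_spikes(sw) == []

    def test_voltage_clamp_rejected(self):
        sw = make_sweep(np.full(5000, -70.0), mode="voltage-clamp")
        with pytest.raises(ep.ModeError):
            ep.detect_spikes(sw)

    def test_counts_and_times_match_stamp_truth(self, quiet_cell):
        _, sweeps, truth = quiet_cell
        for sw in sweeps:
            key = f"{sw.step_pa:g}"
            expected = truth["spike_times_ms"][key]
            events = ep.detect_spikes(sw)
            assert len(events) == len(expected)
            for e, t in zip(events, expected):
                assert abs(e.time_ms - t) <= sw.dt_ms + 1e-9

    def test_subthreshold_noise_rarely_false_positives(self):
        bad = 0
        for seed in range(100):
            p = NeuronSimParams(noise_sd_mv=1.0, seed=seed)
            proto = StepProtocol(amplitudes_pa=(100.0,),
                                 step_duration_ms=500.0, tail_ms=50.0)
            ss, _ = simulate_neuron_sweeps(p, proto)
            bad += bool(ep.detect_spikes(ss.sweeps[0]))
        assert bad <= 1


class TestAPMetrics:
    def test_threshold_at_slope_crossing_of_constructed_ramp(self):
        sw = triangle_spike(rise_mv=2.0)   # approach at 5 V/s, then 20 V/s
        evs = ep.ap_metrics(sw, ep.detect_spikes(sw))
        assert len(evs) == 1
        assert evs[0].threshold_mv == pytest.approx(-45.0)

    def test_triangle_closed_form_amplitude_and_half_width(self):
        # thr -45, peak +35, rise 200 V/s, fall 100 V/s
        sw = triangle_spike(thr=-45.0, peak=35.0, rise_mv=20.0, fall_mv=10.0)
        ev = ep.ap_metrics(sw, ep.detect_spikes(sw))[0]
        assert ev.amplitude_mv == pytest.approx(80.0)
        assert ev.half_width_ms == pytest.approx(40 / 200 + 40 / 100, abs=1e-9)
        assert ev.post_min_mv == pytest.approx(-53.0)

    def test_stamped_population_recovery(self, quiet_cell):
        """Threshold within 1 mV, half-width within 1 sample of stamp truth."""
        _, sweeps, truth = quiet_cell
        ap = truth["ap"]
        checked = 0
        for sw in sweeps:
            if sw.step_pa <= 0:
                continue
            for ev in ep.ap_metrics(sw, ep.detect_spikes(sw)):
                if ev.truncated:
                    continue
                assert abs(ev.threshold_mv - ap["threshold_mv"]) <= 1.0
                assert abs(ev.half_width_ms - ap["half_width_ms"]) <= DT
                assert abs(ev.amplitude_mv - ap["amplitude_mv"]) <= 1.0
                checked += 1
        assert checked > 20

    def test_edge_truncation_flagged(self):
        sw = triangle_spike(at_ms=499.0, total_ms=500.0)
        evs = ep.ap_metrics(sw, ep.detect_spikes(sw))
        assert all(e.truncated for e in evs)


class TestAHP:
    def test_mahp_closed_form(self, quiet_cell):
        """Stamp trough depth is the exact mAHP; recovery within 5%."""
        params, sweeps, _ = quiet_cell
        res = ep.ahp_metrics(sweeps)
        assert res.mahp_mv == pytest.approx(params.trough_depth_mv, rel=0.05)
        assert res.sahp_mv > 0

    def test_band_missing_raises(self):
        sw = make_sweep(np.full(5000, -70.0), step_pa=100.0)
        with pytest.raises(ep.BandMissingError):
            ep.ahp_metrics(ep.SweepSet("c", [sw]))

    def test_sahp_closed_form_magnitude(self):
        # baseline -78; post-step trough -78.9 -> sAHP 0.9 mV
        v = np.full(8000, -78.0)
        sw = make_sweep(v, step_pa=250.0, step_onset=100.0, step_offset=600.0)
        i0 = sw.idx(100.0)
        i1 = sw.idx(600.0)
        # 15 stamped spikes -> 30 Hz... keep 6 spikes over 500 ms = 12 Hz
        for k in range(6):
            at = 150.0 + k * 80.0
            j = sw.idx(at)
            wav = np.concatenate([np.arange(-45.0, 35.0 + 1e-9, 20.0),
                                  np.arange(25.0, -53.0 - 1e-9, -10.0)])
            v[j:j + wav.size] = wav
        v[i1 + 100:i1 + 200] = -78.9   # post-step slow trough
        res = ep.ahp_metrics(ep.SweepSet("c", [make_sweep(
            v, step_pa=250.0, step_onset=100.0, step_offset=600.0)]))
        assert res.sahp_mv == pytest.approx(0.9, abs=1e-9)


class TestSag:
    def test_closed_form_quarter(self):
        v = np.full(10000, -70.0)
        sw = make_sweep(v, step_pa=-100.0, step_onset=100.0, step_offset=900.0)
        a, b = sw.idx(100.0), sw.idx(900.0)
        v[a:b] = -90.0
        v[b - int(0.2 * (b - a)):b] = -85.0
        assert ep.sag_ratio(sw) == pytest.approx((-85 + 90) / (-70 + 90))

    def test_no_sag_is_zero(self):
        v = np.full(10000, -70.0)
        sw = make_sweep(v, step_pa=-100.0, step_onset=100.0, step_offset=900.0)
        a, b = sw.idx(100.0), sw.idx(900.0)
        v[a:b] = -90.0
        assert ep.sag_ratio(sw) == 0.0

    def test_positive_step_rejected(self):
        sw = make_sweep(np.full(1000, -70.0), step_pa=100.0)
        with pytest.raises(ep.ProtocolError):
            ep.sag_ratio(sw)

    def test_simulated_sag_matches_numerical_oracle(self, sag_cell):
        _, sweeps, truth = sag_cell
        measured = ep.sag_ratio(sweeps.by_step(-100.0))
        assert measured == pytest.approx(truth["sag_ratio"], rel=0.02)


class TestPassive:
    def test_seal_ohms_law(self, quiet_cell):
        params, sweeps, _ = quiet_cell
        pp = ep.passive_properties(sweeps)
        assert pp.input_resistance_mohm == pytest.approx(params.r_m_mohm,
                                                         rel=0.01)

    def test_junction_correction_applied(self, quiet_cell):
        params, sweeps, _ = quiet_cell
        pp = ep.passive_properties(sweeps)
        assert pp.v_rest_mv == pytest.approx(params.e_leak_mv - 10.0, abs=0.01)

    def test_missing_seal_test_raises(self):
        sw = make_sweep(np.full(1000, -70.0), seal_onset_ms=10.0,
                        seal_offset_ms=10.0)
        with pytest.raises(ep.ProtocolError):
            ep.passive_properties(ep.SweepSet("c", [sw]))


class TestFIAndRheobase:
    @staticmethod
    def _fake_set(points, duration_ms=1000.0):
        sweeps = []
        for cur, rate in points:
            n_spk = int(round(rate * duration_ms / 1000.0))
            v = np.full(int(1200 / DT), -70.0)
            sw = make_sweep(v, step_pa=cur, step_onset=100.0,
                            step_offset=100.0 + duration_ms)
            for k in range(n_spk):
                j = sw.idx(150.0 + k * (duration_ms - 100) / max(n_spk, 1))
                wav = np.concatenate([np.arange(-45.0, 35.0 + 1e-9, 20.0),
                                      np.arange(25.0, -53.0 - 1e-9, -10.0)])
                v[j:j + wav.size] = wav
            sweeps.append(sw)
        return ep.SweepSet("c", sweeps)

    def test_two_point_intercept_closed_form(self):
        ss = self._fake_set([(100.0, 0.0), (150.0, 5.0), (200.0, 15.0)])
        fi = ep.fi_and_rheobase(ss)
        assert fi.rheobase_pa == pytest.approx(125.0)

    def test_rheobase_invariant_to_appending_higher_steps(self):
        a = ep.fi_and_rheobase(
            self._fake_set([(100.0, 0.0), (150.0, 5.0), (200.0, 15.0)]))
        b = ep.fi_and_rheobase(
            self._fake_set([(100.0, 0.0), (150.0, 5.0), (200.0, 15.0),
                            (250.0, 22.0), (300.0, 28.0)]))
        assert a.rheobase_pa == pytest.approx(b.rheobase_pa)

    def test_lif_analytic_rheobase_within_half_step(self, quiet_cell):
        params, sweeps, _ = quiet_cell
        fi = ep.fi_and_rheobase(sweeps)
        assert abs(fi.rheobase_pa - params.rheobase_pa) <= 25.0

    def test_no_spikes_flags_undefined(self):
        ss = self._fake_set([(100.0, 0.0), (150.0, 0.0)])
        fi = ep.fi_and_rheobase(ss)
        assert np.isnan(fi.rheobase_pa)
        assert "rheobase-undefined" in fi.flags

    def test_one_spike_method_brackets(self):
        ss = self._fake_set([(100.0, 0.0), (150.0, 5.0), (200.0, 15.0)])
        fi = ep.fi_and_rheobase(ss, method="one_spike")
        assert 100.0 < fi.rheobase_pa <= 150.0


class TestAccommodation:
    def test_regular_train_is_one(self):
        sw = make_sweep(np.full(1000, -70.0), step_onset=0.0, step_offset=50.0)
        evs = [ep.SpikeEvent(index=0, time_ms=t) for t in (5, 15, 25, 35, 45)]
        assert ep.accommodation_ratio(sw, evs) == pytest.approx(1.0)

    def test_closed_form_isi_ratio(self):
        times = np.cumsum([5, 50, 60, 70, 80.0])
        sw = make_sweep(np.full(5000, -70.0), step_onset=0.0, step_offset=400.0)
        evs = [ep.SpikeEvent(index=0, time_ms=t) for t in times]
        assert ep.accommodation_ratio(sw, evs) == pytest.approx(80 / 50)

    def test_too_few_spikes_raises(self):
        sw = make_sweep(np.full(1000, -70.0), step_onset=0.0, step_offset=50.0)
        evs = [ep.SpikeEvent(index=0, time_ms=t) for t in (5, 15, 25)]
        with pytest.raises(ValueError):
            ep.accommodation_ratio(sw, evs)

    def test_increases_with_adaptation_increment(self):
        ratios = []
        for inc in (0.4, 1.2):
            p = NeuronSimParams(sahp_increment_mv=inc, seed=0)
            proto = StepProtocol(amplitudes_pa=(350.0,))
            ss, _ = simulate_neuron_sweeps(p, proto)
            ratios.append(ep.accommodation_ratio(ss.sweeps[0]))
        assert ratios[0] > 1.0
        assert ratios[1] > ratios[0]


class TestQC:
    @staticmethod
    def _cell(series=20.0, drift=1.0):
        c = ep.CellFeatures(cell_id="c")
        c.series_resistance_mohm = series
        c.drift_mv = drift
        return c

    def test_boundaries_are_strict(self):
        cells = [self._cell(series=31.0), self._cell(series=30.0),
                 self._cell(drift=10.0), self._cell(drift=10.5)]
        kept, excluded = ep.qc_filter(cells)
        assert len(kept) == 2 and len(excluded) == 2
        reasons = {c.series_resistance_mohm: r for c, r in excluded}
        assert reasons[31.0] == ["series-resistance"]

    def test_partition_conserves_cells(self, rng):
        cells = [self._cell(series=rng.uniform(10, 40),
                            drift=rng.uniform(0, 15)) for _ in range(20)]
        kept, excluded = ep.qc_filter(cells)
        assert len(kept) + len(excluded) == 20

    def test_empty_input_ok(self):
        assert ep.qc_filter([]) == ([], [])


def test_time_origin_invariance(quiet_cell):
    """Shifting the protocol in time leaves every feature unchanged."""
    params, _, _ = quiet_cell
    base = StepProtocol(amplitudes_pa=(-100.0, 0.0, 200.0, 300.0, 350.0))
    shifted = StepProtocol(amplitudes_pa=base.amplitudes_pa,
                           baseline_ms=base.baseline_ms + 100.0,
                           seal_onset_ms=base.seal_onset_ms + 100.0)
    f0 = ep.extract_features(simulate_neuron_sweeps(params, base)[0])
    f1 = ep.extract_features(simulate_neuron_sweeps(params, shifted)[0])
    assert f1.rheobase_pa == pytest.approx(f0.rheobase_pa, abs=1.0)
    assert f1.ap_threshold_mv == pytest.approx(f0.ap_threshold_mv, abs=0.1)
    assert f1.input_resistance_mohm == pytest.approx(
        f0.input_resistance_mohm, rel=0.005)


def test_resampling_tolerance(quiet_cell):
    """Halving dt moves AP metrics by less than the stated tolerances."""
    params, _, _ = quiet_cell
    proto = StepProtocol(amplitudes_pa=(300.0,))
    fine = StepProtocol(amplitudes_pa=(300.0,), dt_ms=0.05)
    e0 = ep.ap_metrics(*((s := simulate_neuron_sweeps(params, proto)[0]
                          .sweeps[0]), ep.detect_spikes(s)))
    e1 = ep.ap_metrics(*((s := simulate_neuron_sweeps(params, fine)[0]
                          .sweeps[0]), ep.detect_spikes(s)))
    assert abs(e0[5].threshold_mv - e1[5].threshold_mv) <= 1.0
    assert abs(e0[5].half_width_ms - e1[5].half_width_ms) <= 0.1
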