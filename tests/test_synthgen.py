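"""Simulator: scene statistics, photocurrent calibration, determinism."""

import numpy as np
import pytest

from optomap import (OpsinModel, SceneConfig, StimulationProtocol, make_scene,
                     photocurrent_at, simulate_mapping_experiment,
                     simulate_spike_response)
from optomap._rng import substream
from optomap.opsin import hill_from_two_points
from optomap.synthgen import build_stim_registry, gcamp_kernel, epsc_kernel


class TestScene:
    def test_scene_has_requested_cells_and_one_patched(self):
        scene = make_scene(SceneConfig(n_cells=43, seed=7))
        assert len(scene.neurons) == 43
        assert sum(n.is_patched for n in scene.neurons) == 1

    def test_zero_connection_probability_yields_no_connections(self):
        scene = make_scene(SceneConfig(n_cells=50, p_connect=0.0, seed=1))
        assert scene.true_connection_ids() == set()

    def test_same_seed_reproduces_scene_exactly(self):
        a = make_scene(SceneConfig(n_cells=20, seed=5))
        b = make_scene(SceneConfig(n_cells=20, seed=5))
        for na, nb in zip(a.neurons, b.neurons):
            assert (na.x, na.y, na.expresses_opsin, na.synaptic_amplitude) == \
                   (nb.x, nb.y, nb.expresses_opsin, nb.synaptic_amplitude)

    def test_adding_cells_preserves_existing_draws(self):
        small = make_scene(SceneConfig(n_cells=10, seed=9))
        big = make_scene(SceneConfig(n_cells=30, seed=9))
        for ns, nb in zip(small.neurons, big.neurons[:10]):
            assert ns.x == nb.x and ns.y == nb.y
            assert ns.expresses_indicator == nb.expresses_indicator

    def test_positions_inside_field(self):
        cfg = SceneConfig(n_cells=200, seed=2)
        pos = make_scene(cfg).positions()
        assert np.all(pos[:, 0] >= 0) and np.all(pos[:, 0] <= cfg.field_width)
        assert np.all(pos[:, 1] >= 0) and np.all(pos[:, 1] <= cfg.field_height)

    def test_synaptic_amplitude_positive_iff_connected(self):
        scene = make_scene(SceneConfig(n_cells=80, p_connect=0.3, seed=4))
        for n in scene.neurons:
            assert (n.synaptic_amplitude > 0) == n.connected_to_patched

    @pytest.mark.parametrize("bad", [
        {"n_cells": 0}, {"p_connect": 1.5}, {"p_indicator": -0.1},
        {"construct": "other"}, {"field_width": 0.0},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            SceneConfig(**bad)


class TestOpsinModel:
    def test_targeted_dendritic_attenuation_is_tenfold_at_50um(self, targeted_model):
        ratio = (photocurrent_at(50, "dendrite", 1.0, targeted_model)
                 / photocurrent_at(0, "soma", 1.0, targeted_model))
        assert ratio == pytest.approx(0.10, abs=1e-12)

    def test_targeted_axonal_attenuation_is_fivefold_at_20um(self, targeted_model):
        ratio = (photocurrent_at(20, "axon", 1.0, targeted_model)
                 / photocurrent_at(0, "soma", 1.0, targeted_model))
        assert ratio == pytest.approx(0.20, abs=1e-12)

    def test_nontargeted_dendritic_attenuation_is_twofold_at_50um(self, nontargeted_model):
        ratio = (photocurrent_at(50, "dendrite", 1.0, nontargeted_model)
                 / photocurrent_at(0, "soma", 1.0, nontargeted_model))
        assert ratio == pytest.approx(0.50, abs=1e-12)

    def test_zero_distance_returns_somatic_amplitude(self, targeted_model):
        p = 1.7
        assert photocurrent_at(0, "soma", p, targeted_model) == \
            pytest.approx(targeted_model.somatic_current(p))

    def test_power_curve_passes_through_calibration_points(self):
        for model in (OpsinModel.targeted(), OpsinModel.nontargeted()):
            for power, current in model.power_calibration:
                assert model.somatic_current(power) == pytest.approx(current)

    def test_power_curve_saturates(self, targeted_model):
        # concave and monotone: equal power steps give shrinking gains
        i1 = targeted_model.somatic_current(1.0)
        i2 = targeted_model.somatic_current(2.0)
        i3 = targeted_model.somatic_current(3.0)
        assert i2 - i1 > i3 - i2 > 0

    def test_hill_solution_rejects_superlinear_points(self):
        with pytest.raises(ValueError):
            hill_from_two_points(1.0, 10.0, 2.0, 30.0)

    def test_spike_probability_unity_on_soma_at_threshold(self, targeted_model):
        assert targeted_model.spike_probability(
            0, 0, targeted_model.threshold_power) == pytest.approx(1.0)

    def test_spike_probability_halves_at_half_fwhm(self, targeted_model):
        m = targeted_model
        on_soma = m.spike_probability(0, 0, m.threshold_power)
        assert m.spike_probability(m.fwhm_lateral / 2, 0, m.threshold_power) \
            == pytest.approx(0.5 * on_soma, abs=1e-12)
        assert m.spike_probability(0, m.fwhm_axial / 2, m.threshold_power) \
            == pytest.approx(0.5 * on_soma, abs=1e-12)

    def test_spike_probability_negligible_far_from_soma(self, targeted_model):
        assert targeted_model.spike_probability(
            100, 0, targeted_model.threshold_power) < 1e-10

    def test_latency_decreases_with_power_toward_floor(self, targeted_model):
        m = targeted_model
        assert m.latency_mean(m.threshold_power) == pytest.approx(m.latency_at_threshold)
        assert m.latency_mean(10.0) < m.latency_mean(2.0) < m.latency_at_threshold
        assert m.latency_mean(100.0) == pytest.approx(m.latency_floor, rel=1e-6)

    def test_negative_domain_rejected(self, targeted_model):
        with pytest.raises(ValueError):
            photocurrent_at(-1, "dendrite", 1.0, targeted_model)
        with pytest.raises(ValueError):
            photocurrent_at(1, "dendrite", -1.0, targeted_model)


class TestSpikeResponse:
    def test_threshold_on_soma_spikes_every_trial(self, targeted_model):
        rng = substream(0, 99)
        n_spiking = sum(
            len(simulate_spike_response(0, 0, targeted_model.threshold_power,
                                        targeted_model, rng)) > 0
            for _ in range(50))
        assert n_spiking == 50

    def test_far_offset_never_spikes(self, targeted_model):
        rng = substream(1, 99)
        assert all(
            len(simulate_spike_response(100, 0, targeted_model.threshold_power,
                                        targeted_model, rng)) == 0
            for _ in range(20))

    def test_suprathreshold_pulse_gives_trains_of_2_to_4(self, targeted_model):
        rng = substream(2, 99)
        counts = {len(simulate_spike_response(0, 0, 2.29, targeted_model, rng))
                  for _ in range(100)}
        assert counts <= {2, 3, 4}
        assert len(counts) > 1  # actually varies

    def test_spike_times_within_pulse(self, targeted_model):
        rng = substream(3, 99)
        for _ in range(50):
            times = simulate_spike_response(0, 0, 2.29, targeted_model, rng,
                                            stim_duration=150.0)
            assert np.all(times > 0) and np.all(times < 155.0)


class TestProtocolAndRegistry:
    def test_first_two_targets_land_on_frames_2_and_4(self):
        proto = StimulationProtocol(target_ids=(7, 8, 9))
        reg = build_stim_registry(proto, absolute=False)
        # 0-based frames 1 and 3 = 1-based frames 2 and 4
        assert reg[(7, 0)] == 1
        assert reg[(8, 0)] == 3

    def test_43_targets_last_stimulation_on_frame_86_of_trial_1(self):
        proto = StimulationProtocol(target_ids=tuple(range(43)))
        reg = build_stim_registry(proto, absolute=False)
        assert reg[(42, 0)] + 1 == 86  # 1-based frame number

    def test_absolute_registry_shifts_by_baseline_block(self):
        proto = StimulationProtocol(target_ids=(0, 1), n_baseline_frames=10)
        rel = build_stim_registry(proto, absolute=False)
        ab = build_stim_registry(proto, absolute=True)
        assert all(ab[k] - rel[k] == 10 for k in rel)

    def test_trial_offset_is_full_pass_length(self):
        proto = StimulationProtocol(target_ids=tuple(range(5)))
        reg = build_stim_registry(proto, absolute=False)
        assert reg[(0, 1)] - reg[(0, 0)] == proto.frames_per_trial

    @pytest.mark.parametrize("bad", [
        {"target_ids": ()}, {"target_ids": (1, 1)},
        {"target_ids": (1,), "stim_duration": 0},
        {"target_ids": (1,), "n_trials": 0},
    ])
    def test_invalid_protocol_rejected(self, bad):
        with pytest.raises(ValueError):
            StimulationProtocol(**bad)


class TestKernels:
    def test_gcamp_kernel_unit_peak_and_causal(self):
        t = np.linspace(-1, 6, 2000)
        k = gcamp_kernel(t, 0.18, 1.0)
        assert k[t < 0].max() == 0
        assert k.max() == pytest.approx(1.0, abs=1e-3)

    def test_epsc_kernel_unit_peak_fast_rise(self):
        t = np.linspace(-5, 50, 5000)
        k = epsc_kernel(t)
        assert k.max() == pytest.approx(1.0, abs=1e-4)
        assert k[t < 0].max() == 0

    def test_doubling_spike_count_increases_transient_peak(self):
        t = np.linspace(0, 5, 100)
        one = gcamp_kernel(t, 0.18, 1.0)
        assert np.max(2 * one) > np.max(one)


class TestEndToEndBundle:
    def test_bundle_deterministic_under_seed(self):
        cfg = SceneConfig(n_cells=12, seed=21)
        a = simulate_mapping_experiment(cfg)
        b = simulate_mapping_experiment(cfg)
        assert np.array_equal(a.fluorescence.traces, b.fluorescence.traces)
        for key in a.currents.sweeps:
            assert np.array_equal(a.currents.sweeps[key], b.currents.sweeps[key])
        assert a.ground_truth.connections == b.ground_truth.connections

    def test_noise_free_nonspiking_trace_is_constant(self):
        cfg = SceneConfig(n_cells=8, seed=1, noise_sd_imaging=0.0,
                          p_opsin=0.0, p_high_baseline=0.0,
                          offtarget_prob=0.0)
        bundle = simulate_mapping_experiment(cfg, with_currents=False)
        for row in bundle.fluorescence.traces:
            assert np.ptp(row) == pytest.approx(0.0)

    def test_indicator_negative_cells_carry_no_transient(self):
        cfg = SceneConfig(n_cells=10, seed=6, noise_sd_imaging=0.0,
                          p_indicator=0.0, p_high_baseline=0.0,
                          offtarget_prob=0.0)
        bundle = simulate_mapping_experiment(cfg, with_currents=False)
        spiking = {tid for (tid, _t), lat
                   in bundle.ground_truth.spike_latencies.items() if len(lat)}
        assert spiking  # cells do spike...
        for row in bundle.fluorescence.traces:
            assert np.ptp(row) == pytest.approx(0.0)  # ...but report nothing

    def test_every_epsc_traces_to_a_ground_truth_spike(self, clean_bundle):
        """Conservation at zero noise: sweep deviations occur only at
        spike-driven EPSC times or direct-current epochs."""
        b = clean_bundle
        ct = b.currents
        for (tid, trial), sweep in ct.sweeps.items():
            n = b.scene.neuron(tid)
            has_events = np.any(np.abs(sweep) > 1e-9)
            expect = (n.connected_to_patched
                      and len(b.ground_truth.spike_latencies[(tid, trial)]) > 0) \
                or tid in b.ground_truth.direct_targets
            assert has_events == expect

    def test_epsc_onset_follows_spike_by_synaptic_delay(self, clean_bundle):
        b = clean_bundle
        ct = b.currents
        for (tid, trial), sweep in ct.sweeps.items():
            n = b.scene.neuron(tid)
            if not n.connected_to_patched or tid in b.ground_truth.direct_targets:
                continue
            lats = b.ground_truth.spike_latencies[(tid, trial)]
            if len(lats) == 0:
                continue
            first_dev = np.argmax(np.abs(sweep) > 1e-9)
            t_first = first_dev / ct.sample_rate * 1000.0
            expected = ct.stim_onset_ms + lats.min() + n.synaptic_delay_mean
            assert t_first == pytest.approx(expected, abs=1.0)

    def test_direct_current_locked_to_stimulation_epoch(self, targeted_model):
        cfg = SceneConfig(n_cells=6, seed=13, noise_sd_ephys=0.0,
                          spontaneous_epsc_rate=0.0, p_connect=0.0,
                          offtarget_prob=0.0)
        bundle = simulate_mapping_experiment(cfg)
        ct = bundle.currents
        for tid, amp in bundle.ground_truth.direct_targets.items():
            sweep = ct.sweeps[(tid, 0)]
            t = np.arange(len(sweep)) / ct.sample_rate * 1000.0
            pre = sweep[t < ct.stim_onset_ms]
            assert np.all(np.abs(pre) < 1e-9)
            during = sweep[(t > ct.stim_onset_ms + 20) & (t < ct.stim_offset_ms)]
            assert np.all(during < -0.5 * amp)
            late = sweep[t > ct.stim_offset_ms + 100]
            assert np.all(np.abs(late) < 0.01 * amp)

    def test_unknown_protocol_targets_rejected(self):
        cfg = SceneConfig(n_cells=5, seed=0)
        proto = StimulationProtocol(target_ids=(99,))
        with pytest.raises(ValueError):
            simulate_mapping_experiment(cfg, protocol=proto)

    def test_offtarget_parameters_follow_construct(self):
        t = SceneConfig(construct="targeted")
        n = SceneConfig(construct="nontargeted")
        assert t.resolved("offtarget_prob") == pytest.approx(0.054)
        assert t.resolved("offtarget_distance_scale") == pytest.approx(18.9)
        assert n.resolved("offtarget_prob") == pytest.approx(0.152)
        assert n.resolved("offtarget_distance_scale") == pytest.approx(40.6)
        assert n.resolved("direct_response_fraction") == pytest.approx(0.2875)

    def test_nontargeted_mode_produces_direct_responses(self):
        cfg = SceneConfig(n_cells=60, seed=8, construct="nontargeted")
        bundle = simulate_mapping_experiment(cfg, with_fluorescence=False,
                                             with_currents=False)
        frac = len(bundle.ground_truth.direct_targets) / 59
        assert 0.1 < frac < 0.5  # Bernoulli(0.2875) over 59 targets
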