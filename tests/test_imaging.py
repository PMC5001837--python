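"""Imaging analysis: ΔF/F arithmetic, transient rule, QC, responses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optomap import (SceneConfig, StimulationProtocol, classify_responses,
                     compute_dff, detect_transients, exclude_high_baseline,
                     map_stimulus_frames, simulate_mapping_experiment)
from optomap.imaging import TransientEvent
from optomap.pipeline import PipelineConfig, analyze_imaging


def brute_force_transients(trace, mu, sd, k_sd=3.0, min_frames=2):
    """Independent oracle: scan every frame, collect threshold runs."""
    thresh = mu + k_sd * sd
    events, run = [], []
    for i, v in enumerate(list(trace) + [-np.inf]):
        if v > thresh:
            run.append(i)
        else:
            if len(run) >= min_frames:
                events.append((run[0], len(run)))
            run = []
    return events


class TestComputeDff:
    def test_thirty_percent_rise(self):
        trace = np.array([100.0] * 10 + [130.0])
        dff, invalid = compute_dff(trace)
        assert not invalid
        assert dff[0, -1] == pytest.approx(0.30)

    def test_constant_trace_gives_zero(self):
        dff, _ = compute_dff(np.full((3, 20), 7.0))
        assert np.allclose(dff, 0.0)

    def test_negative_deflection_sign(self):
        trace = np.array([100.0] * 10 + [50.0])
        dff, _ = compute_dff(trace)
        assert dff[0, -1] == pytest.approx(-0.50)

    def test_round_trip_recovers_raw_trace(self):
        rng = np.random.default_rng(0)
        traces = 100 + rng.normal(0, 5, size=(4, 50))
        dff, _ = compute_dff(traces)
        f0 = traces[:, :10].mean(axis=1, keepdims=True)
        assert np.allclose(dff * f0 + f0, traces, atol=1e-10)

    def test_nonpositive_baseline_flagged(self):
        traces = np.vstack([np.full(30, 100.0), np.full(30, 0.0)])
        dff, invalid = compute_dff(traces)
        assert 1 in invalid and 0 not in invalid
        assert np.all(np.isnan(dff[1]))

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.zeros((1, 5)), n_baseline_frames=10)


class TestDetectTransients:
    def test_two_frame_event_detected(self):
        # baseline mean 0, SD ~0 → noise floor SD; excursion of 4 clears 3 SD
        tr = np.array([0.0] * 10 + [0, 0, 4, 4, 0])
        events = detect_transients(tr, noise_floor=1.0)
        assert len(events) == 1
        assert events[0].onset_frame == 12
        assert events[0].duration_frames == 2

    def test_single_frame_excursions_rejected(self):
        tr = np.array([0.0] * 10 + [0, 4, 0, 4, 0])
        assert detect_transients(tr, noise_floor=1.0) == []

    def test_subthreshold_run_rejected(self):
        tr = np.array([0.0] * 10 + [2.9, 2.9, 2.9])
        assert detect_transients(tr, noise_floor=1.0) == []

    def test_peak_dff_reported(self):
        tr = np.array([0.0] * 10 + [5.0, 7.0, 6.0, 0.0])
        ev = detect_transients(tr, noise_floor=1.0)[0]
        assert ev.peak_dff == pytest.approx(7.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1, 8, allow_nan=False), min_size=15, max_size=60))
    def test_matches_brute_force_oracle(self, values):
        tr = np.asarray(values)
        base = tr[:10]
        mu, sd = base.mean(), base.std(ddof=1)
        if sd == 0:
            sd = 0.05
        events = detect_transients(tr, noise_floor=0.05)
        expected = brute_force_transients(tr, mu, sd)
        assert [(e.onset_frame, e.duration_frames) for e in events] == expected


class TestExcludeHighBaseline:
    def test_single_outlier_excluded(self):
        # nine cells at 100, one at 200: mean 110, SD 31.62, cutoff 173.2
        traces = np.vstack([np.full(20, 100.0)] * 9 + [np.full(20, 200.0)])
        report = exclude_high_baseline(traces)
        assert report.excluded_cells == [9]
        assert report.cutoff == pytest.approx(173.24, abs=0.01)

    def test_equal_baselines_no_exclusion(self):
        report = exclude_high_baseline(np.full((10, 20), 50.0))
        assert report.excluded_cells == []

    def test_two_cells_cannot_exclude(self):
        traces = np.vstack([np.full(20, 100.0), np.full(20, 500.0)])
        with pytest.warns(UserWarning):
            report = exclude_high_baseline(traces)
        assert report.excluded_cells == []

    def test_robust_variant_excludes_gross_outlier(self):
        traces = np.vstack([np.full(20, 100.0)] * 9 + [np.full(20, 400.0)])
        report = exclude_high_baseline(traces, robust=True)
        assert report.excluded_cells == [9]


class TestStimulusRegistry:
    def test_matches_paper_frame_numbering(self):
        proto = StimulationProtocol(target_ids=(0, 1, 2))
        reg = map_stimulus_frames(proto, absolute=False)
        assert reg[(0, 0)] + 1 == 2 and reg[(1, 0)] + 1 == 4

    def test_overflow_detected(self):
        proto = StimulationProtocol(target_ids=tuple(range(10)))
        with pytest.raises(ValueError):
            map_stimulus_frames(proto, n_frames=5)

    def test_unit_spacing_warns_of_window_overlap(self):
        proto = StimulationProtocol(target_ids=(0, 1), stim_every_n_frames=1)
        with pytest.warns(UserWarning):
            map_stimulus_frames(proto, absolute=False)


class TestClassifyResponses:
    def _registry(self, targets=(0, 1), trials=4, start=10, spacing=2, per=12):
        return {(t, tr): start + tr * per + i * spacing
                for i, t in enumerate(targets) for tr in range(trials)}

    def test_transient_in_all_trials_is_responsive(self):
        reg = self._registry()
        events = [TransientEvent(0, reg[(0, tr)], 2, 1.0) for tr in range(4)]
        summary = classify_responses(events, reg)
        assert summary.responsive[0] is True
        assert summary.responsive[1] is False

    def test_two_of_four_trials_not_responsive(self):
        reg = self._registry()
        events = [TransientEvent(0, reg[(0, tr)], 2, 1.0) for tr in range(2)]
        summary = classify_responses(events, reg)
        assert summary.responsive[0] is False
        assert summary.n_trials_with_event[0] == 2

    def test_offtarget_event_distance(self):
        reg = self._registry()
        positions = np.array([[0.0, 0.0], [20.0, 0.0]])
        # cell 1 fires during cell 0's window in all trials
        events = [TransientEvent(1, reg[(0, tr)] + 1, 2, 1.0) for tr in range(4)]
        summary = classify_responses(events, reg, positions, cell_ids=[0, 1])
        assert len(summary.offtarget_events) == 1
        assert summary.offtarget_events[0]["distance_um"] == pytest.approx(20.0)
        assert summary.offtarget_probability == pytest.approx(0.5)

    def test_excluded_cells_never_counted(self):
        reg = self._registry()
        events = [TransientEvent(0, reg[(0, tr)], 2, 1.0) for tr in range(4)]
        summary = classify_responses(events, reg, excluded_cells=[0])
        assert 0 not in summary.responsive

    def test_responsive_fraction_example(self):
        reg = {(t, tr): 10 + tr * 100 + t * 2 for t in range(43) for tr in range(4)}
        events = [TransientEvent(t, reg[(t, tr)], 2, 1.0)
                  for t in range(35) for tr in range(4)]
        summary = classify_responses(events, reg)
        assert summary.n_responsive == 35
        assert summary.responsive_fraction == pytest.approx(35 / 43)


class TestPipelineImagingStage:
    def test_excluded_cells_absent_from_events(self):
        cfg = SceneConfig(n_cells=30, seed=17, p_high_baseline=0.3)
        bundle = simulate_mapping_experiment(cfg, with_currents=False)
        summary, events, qc, _ = analyze_imaging(
            bundle.fluorescence, PipelineConfig(scene=cfg))
        assert qc.excluded_cells  # the 30% rate guarantees some
        assert not ({ev.cell_id for ev in events} & set(qc.excluded_cells))

    def test_noise_free_full_expression_all_spiking_targets_responsive(self):
        cfg = SceneConfig(n_cells=25, seed=19, noise_sd_imaging=0.0,
                          p_indicator=1.0, p_high_baseline=0.0,
                          spontaneous_epsc_rate=0.0)
        bundle = simulate_mapping_experiment(cfg, with_currents=False)
        summary, _, _, _ = analyze_imaging(
            bundle.fluorescence, PipelineConfig(scene=cfg))
        spiking = bundle.ground_truth.spiking_targets(4, min_trials=3)
        for tid in spiking:
            assert summary.responsive[tid], f"target {tid} spiked but not responsive"
        assert summary.responsive_fraction == pytest.approx(1.0, abs=0.05)
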