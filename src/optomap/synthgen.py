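"""Forward simulation of TF photostimulation mapping experiments.

Generates, from a :class:`~optomap.scene.SceneConfig` and a
:class:`StimulationProtocol`, everything one experiment produces:

* ground-truth evoked spikes per (target, trial), including off-target
  co-activations of neighbouring opsin-expressing cells;
* GCaMP6s fluorescence traces sampled at the imaging frame rate, with one
  photostimulation per alternate frame;
* whole-cell voltage-clamp current sweeps at 10 kHz per (target, trial), with
  direct photocurrents, evoked EPSCs, spontaneous EPSCs and recording noise.

Everything is keyed off a single seed through splittable substreams, so an
:class:`ExperimentBundle` is bit-identical on re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._rng import EPHYS, GCAMP, OFFTARGET, SPIKES, SPONT, substream
from .ephys import CurrentTraceSet
from .imaging import FluorescenceTraceSet
from .opsin import OpsinModel, photocurrent_at
from .scene import Scene, SceneConfig, make_scene


@dataclass(frozen=True)
class StimulationProtocol:
    """Sequential single-spot stimulation protocol.

    Targets are stimulated in fixed order, one 150 ms pulse at the onset of
    every ``stim_every_n_frames``-th imaging frame, repeated for ``n_trials``
    passes over the full target list. ``first_stim_frame`` is the 0-based
    frame of the first pulse within the stimulation clock (default 1, i.e.
    the second frame). ``n_baseline_frames`` stimulus-free frames are recorded
    before the stimulation clock starts, providing the ΔF/F baseline.
    """

    target_ids: tuple[int, ...]
    stim_duration: float = 150.0          # ms
    n_trials: int = 4
    power: float = 2.29                   # mW/µm²
    frame_rate: float = 1.5               # Hz
    stim_every_n_frames: int = 2
    first_stim_frame: int = 1             # 0-based within the stimulation clock
    n_baseline_frames: int = 10
    sweep_pre_ms: float = 100.0
    sweep_post_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.stim_duration <= 0:
            raise ValueError("stim_duration must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if len(self.target_ids) == 0:
            raise ValueError("protocol must list at least one target")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("target_ids must be unique")
        if self.frame_rate <= 0 or self.stim_every_n_frames < 1:
            raise ValueError("invalid frame parameters")
        if self.power < 0:
            raise ValueError("power must be non-negative")

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def frames_per_trial(self) -> int:
        """Stimulation-clock frames consumed by one pass over all targets."""
        return self.first_stim_frame + self.n_targets * self.stim_every_n_frames

    @property
    def n_frames_total(self) -> int:
        # +2 tail frames so the last response window fits
        return self.n_baseline_frames + self.n_trials * self.frames_per_trial + 2

    @property
    def sweep_duration_ms(self) -> float:
        return self.sweep_pre_ms + self.stim_duration + self.sweep_post_ms

    @classmethod
    def for_scene(cls, scene: Scene, **overrides) -> "StimulationProtocol":
        return cls(target_ids=tuple(scene.target_ids()), **overrides)


@dataclass
class GroundTruth:
    """What actually happened, for validating the analysis chain.

    ``spike_latencies`` maps (target_id, trial) → spike times in ms from that
    stimulation's light onset (empty array = no spikes). ``offtarget`` lists
    reproducible off-target activations as
    (target_id, offtarget_cell_id, distance_µm) — the victim cell fires on
    every trial of that target. ``direct_targets`` are targets whose
    stimulation drives a direct photocurrent in the patched cell.
    """

    spike_latencies: dict[tuple[int, int], np.ndarray]
    offtarget: list[tuple[int, int, float]]
    offtarget_latencies: dict[tuple[int, int, int], np.ndarray]
    connections: set[int]
    direct_targets: dict[int, float]  # target_id → direct current amplitude pA

    def spiking_targets(self, n_trials: int, min_trials: int = 1) -> set[int]:
        counts: dict[int, int] = {}
        for (tid, _trial), lat in self.spike_latencies.items():
            if len(lat):
                counts[tid] = counts.get(tid, 0) + 1
        return {tid for tid, c in counts.items() if c >= min_trials}


@dataclass
class ExperimentBundle:
    scene: Scene
    protocol: StimulationProtocol
    model: OpsinModel
    fluorescence: Optional[FluorescenceTraceSet]
    currents: Optional[CurrentTraceSet]
    ground_truth: GroundTruth


# --------------------------------------------------------------------- spikes

def _first_spike_latency(power: float, model: OpsinModel,
                         rng: np.random.Generator) -> float:
    """Truncated-normal (> 0) first-spike latency in ms."""
    mu = model.latency_mean(power)
    sd = model.latency_jitter(power)
    for _ in range(100):
        lat = rng.normal(mu, sd)
        if lat > 0:
            return float(lat)
    return mu  # pathological jitter/mean combination; fall back to the mean


def simulate_spike_response(lateral_offset: float, axial_offset: float,
                            power: float, model: OpsinModel,
                            rng: np.random.Generator,
                            stim_duration: float = 150.0) -> np.ndarray:
    """Spike times (ms from light onset) for one stimulation trial.

    Spike probability is the model's separable Gaussian profile scaled by the
    on-soma probability; supra-threshold on-soma pulses evoke short trains of
    2–4 action potentials within the pulse, threshold-level pulses a single
    spike.
    """
    p = model.spike_probability(lateral_offset, axial_offset, power)
    if rng.random() >= p:
        return np.empty(0)
    if power > 1.2 * model.threshold_power:
        n_spikes = int(rng.integers(2, 5))
    else:
        n_spikes = 1
    first = _first_spike_latency(power, model, rng)
    times = [first]
    for _ in range(n_spikes - 1):
        times.append(times[-1] + rng.uniform(25.0, 45.0))
    times = np.array([t for t in times if t < stim_duration + 5.0])
    return times


def _simulate_ground_truth(scene: Scene, protocol: StimulationProtocol,
                           model: OpsinModel) -> GroundTruth:
    cfg = scene.config
    seed = cfg.seed
    patched = scene.patched

    spike_latencies: dict[tuple[int, int], np.ndarray] = {}
    for tid in protocol.target_ids:
        neuron = scene.neuron(tid)
        for trial in range(protocol.n_trials):
            rng = substream(seed, SPIKES, tid, trial)
            if neuron.expresses_opsin:
                lat = simulate_spike_response(
                    0.0, 0.0, protocol.power, model, rng, protocol.stim_duration)
            else:
                lat = np.empty(0)
            spike_latencies[(tid, trial)] = lat

    # Reproducible off-target activations: per target, one Bernoulli draw.
    # The co-activated cell must express opsin and indicator (unobservable
    # activations are not modelled) and lie within the construct's sensitive
    # dendritic reach (2 × distance scale); among eligible cells the victim
    # is drawn with weight ∝ 1/distance, the chance of a radial dendrite
    # crossing the stimulation spot. The victim fires on every trial.
    p_off = cfg.resolved("offtarget_prob")
    d_scale = cfg.resolved("offtarget_distance_scale")
    offtarget: list[tuple[int, int, float]] = []
    offtarget_latencies: dict[tuple[int, int, int], np.ndarray] = {}
    pos = scene.positions()
    for tid in protocol.target_ids:
        rng = substream(seed, OFFTARGET, tid)
        if rng.random() >= p_off:
            continue
        candidates = [n.id for n in scene.neurons
                      if n.expresses_opsin and n.expresses_indicator
                      and n.id != tid and not n.is_patched]
        if not candidates:
            continue
        d = np.linalg.norm(pos[candidates] - pos[tid], axis=1)
        reach = d <= 2.0 * d_scale
        if reach.any():
            d = d[reach]
            candidates = [c for c, keep in zip(candidates, reach) if keep]
            # dendrite-crossing chance (∝ 1/d) times dendritic opsin
            # attenuation along the process (∝ exp(−d/λ_dendrite))
            w = (np.exp(-d / model.dendrite_length_constant)
                 / np.maximum(d, 5.0))
            j = int(rng.choice(len(candidates), p=w / w.sum()))
        else:
            j = int(np.argmin(d))  # sparse field: nearest observable cell
        victim = candidates[j]
        offtarget.append((tid, victim, float(d[j])))
        for trial in range(protocol.n_trials):
            lat = _first_spike_latency(protocol.power, model, rng)
            offtarget_latencies[(tid, victim, trial)] = np.array([lat])

    # Direct photocurrents in the patched cell: geometric (stimulation spot
    # within reach of the patched soma) plus, for the nontargeted construct, a
    # configured fraction of targets whose dendritic-arbor overlap drives
    # direct current.
    direct_targets: dict[int, float] = {}
    dr_frac = cfg.resolved("direct_response_fraction")
    for tid in protocol.target_ids:
        d = float(np.linalg.norm(pos[tid] - pos[patched.id]))
        if d <= cfg.direct_reach:
            direct_targets[tid] = photocurrent_at(
                d, "dendrite", protocol.power, model)
            continue
        if dr_frac > 0:
            rng = substream(seed, OFFTARGET, tid, 1)
            if rng.random() < dr_frac:
                # dendritic hit: sizeable but sub-somatic amplitude
                direct_targets[tid] = float(
                    model.somatic_current(protocol.power)
                    * np.exp(rng.uniform(np.log(0.1), np.log(0.8))))

    return GroundTruth(
        spike_latencies=spike_latencies,
        offtarget=offtarget,
        offtarget_latencies=offtarget_latencies,
        connections=scene.true_connection_ids(),
        direct_targets=direct_targets,
    )


# ---------------------------------------------------------------- gcamp trace

def gcamp_kernel(t_s: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials calcium transient, t in seconds."""
    t = np.asarray(t_s, dtype=float)
    k = np.where(t >= 0,
                 (1.0 - np.exp(-np.maximum(t, 0) / rise_tau))
                 * np.exp(-np.maximum(t, 0) / decay_tau), 0.0)
    t_peak = rise_tau * np.log1p(decay_tau / rise_tau)
    peak = (1.0 - np.exp(-t_peak / rise_tau)) * np.exp(-t_peak / decay_tau)
    return k / peak


def _stim_clock_frame(protocol: StimulationProtocol, target_index: int,
                      trial: int) -> int:
    """0-based stimulation-clock frame of target #target_index in ``trial``."""
    return (trial * protocol.frames_per_trial + protocol.first_stim_frame
            + target_index * protocol.stim_every_n_frames)


def build_stim_registry(protocol: StimulationProtocol,
                        absolute: bool = True) -> dict[tuple[int, int], int]:
    """Map (target_id, trial) → stimulation frame (0-based).

    With ``absolute=True`` (default) frames include the pre-stimulation
    baseline block and index directly into simulated traces.
    """
    off = protocol.n_baseline_frames if absolute else 0
    reg = {}
    for k, tid in enumerate(protocol.target_ids):
        for trial in range(protocol.n_trials):
            reg[(tid, trial)] = off + _stim_clock_frame(protocol, k, trial)
    return reg


def simulate_gcamp_traces(scene: Scene, protocol: StimulationProtocol,
                          truth: GroundTruth) -> FluorescenceTraceSet:
    """Render per-cell fluorescence traces from ground-truth spikes.

    Frames are sampled at their midpoints (raster scan integrates over the
    frame). Each spike adds one transient kernel scaled by the per-spike
    ΔF/F amplitude; indicator-negative cells carry baseline and noise only.
    """
    cfg = scene.config
    n_frames = protocol.n_frames_total
    frame_period = 1.0 / protocol.frame_rate
    frame_times = (np.arange(n_frames) + 0.5) * frame_period  # s, midpoints
    registry = build_stim_registry(protocol, absolute=True)

    # absolute spike times in seconds, per cell
    spike_times: dict[int, list[tuple[float, int]]] = {n.id: [] for n in scene.neurons}
    for (tid, trial), lats in truth.spike_latencies.items():
        if len(lats) == 0:
            continue
        t0 = registry[(tid, trial)] * frame_period
        spike_times[tid].extend((t0 + lat / 1000.0, 1) for lat in lats)
    for (tid, victim, trial), lats in truth.offtarget_latencies.items():
        t0 = registry[(tid, trial)] * frame_period
        spike_times[victim].extend((t0 + lat / 1000.0, 1) for lat in lats)

    traces = np.zeros((len(scene.neurons), n_frames))
    for n in scene.neurons:
        rng = substream(cfg.seed, GCAMP, n.id)
        f0 = n.baseline_fluorescence
        tr = np.full(n_frames, f0)
        if n.expresses_indicator:
            for t_spk, count in spike_times[n.id]:
                tr += (cfg.transient_amplitude * count * f0
                       * gcamp_kernel(frame_times - t_spk,
                                      cfg.gcamp_rise_tau, cfg.gcamp_decay_tau))
        if cfg.noise_sd_imaging > 0:
            tr += rng.normal(0.0, cfg.noise_sd_imaging * f0, size=n_frames)
        traces[n.id] = tr

    return FluorescenceTraceSet(
        traces=traces,
        frame_rate=protocol.frame_rate,
        cell_ids=[n.id for n in scene.neurons],
        cell_positions=scene.positions(),
        stim_registry=registry,
        n_baseline_frames=protocol.n_baseline_frames,
        n_trials=protocol.n_trials,
    )


# --------------------------------------------------------------- patch traces

def epsc_kernel(t_ms: np.ndarray, rise_tau: float = 1.0,
                decay_tau: float = 5.0) -> np.ndarray:
    """Unit-peak EPSC waveform (positive; caller applies sign), t in ms."""
    t = np.asarray(t_ms, dtype=float)
    k = np.where(t >= 0,
                 (np.exp(-np.maximum(t, 0) / decay_tau)
                  - np.exp(-np.maximum(t, 0) / rise_tau)), 0.0)
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * np.log(decay_tau / rise_tau)
    peak = np.exp(-t_peak / decay_tau) - np.exp(-t_peak / rise_tau)
    return k / peak


def direct_current_waveform(t_ms: np.ndarray, amplitude: float,
                            stim_onset: float, stim_offset: float,
                            on_tau: float, off_tau: float) -> np.ndarray:
    """ChR2 photocurrent: exponential activation at light onset, exponential
    deactivation beginning at light offset. Returned positive (inward
    magnitude); caller applies the voltage-clamp sign."""
    t = np.asarray(t_ms, dtype=float)
    out = np.zeros_like(t)
    during = (t >= stim_onset) & (t < stim_offset)
    out[during] = amplitude * (1.0 - np.exp(-(t[during] - stim_onset) / on_tau))
    level_at_off = amplitude * (1.0 - np.exp(-(stim_offset - stim_onset) / on_tau))
    after = t >= stim_offset
    out[after] = level_at_off * np.exp(-(t[after] - stim_offset) / off_tau)
    return out


def simulate_patch_recording(scene: Scene, protocol: StimulationProtocol,
                             truth: GroundTruth, model: OpsinModel,
                             sample_rate: float = 10_000.0) -> CurrentTraceSet:
    """Voltage-clamp sweeps (pA, inward negative at −70 mV) per (target, trial).

    Each sweep spans pre-stimulus baseline, the 150 ms light pulse, and a
    post-stimulus tail. Components: direct photocurrent (onset/offset locked
    to the light), one EPSC per ground-truth presynaptic spike of a connected
    target (spike time + synaptic delay, sub-millisecond trial-to-trial delay
    jitter), spontaneous Poisson EPSCs, and Gaussian recording noise.
    """
    cfg = scene.config
    n_samp = int(round(protocol.sweep_duration_ms / 1000.0 * sample_rate))
    t_ms = np.arange(n_samp) / sample_rate * 1000.0
    stim_on = protocol.sweep_pre_ms
    stim_off = stim_on + protocol.stim_duration

    sweeps: dict[tuple[int, int], np.ndarray] = {}
    for tid in protocol.target_ids:
        neuron = scene.neuron(tid)
        direct_amp = truth.direct_targets.get(tid, 0.0)
        for trial in range(protocol.n_trials):
            rng = substream(cfg.seed, EPHYS, tid, trial)
            sweep = np.zeros(n_samp)
            if direct_amp > 0:
                onset_jit = rng.uniform(0.2, 0.8)  # conduction/gating delay, sub-ms
                sweep -= direct_current_waveform(
                    t_ms, direct_amp, stim_on + onset_jit, stim_off + onset_jit,
                    model.chr2_on_tau, model.chr2_off_tau)
            if neuron.connected_to_patched:
                for lat in truth.spike_latencies[(tid, trial)]:
                    delay = neuron.synaptic_delay_mean + rng.normal(0.0, 0.2)
                    t_evt = stim_on + lat + max(delay, 2.0)
                    amp = neuron.synaptic_amplitude * max(0.2, rng.normal(1.0, 0.15))
                    sweep -= amp * epsc_kernel(t_ms - t_evt)
            # spontaneous EPSCs over the whole sweep
            rng_sp = substream(cfg.seed, SPONT, tid, trial)
            if cfg.spontaneous_epsc_rate > 0:
                n_spont = rng_sp.poisson(
                    cfg.spontaneous_epsc_rate * protocol.sweep_duration_ms / 1000.0)
                for _ in range(n_spont):
                    t_evt = rng_sp.uniform(0.0, protocol.sweep_duration_ms)
                    amp = cfg.synaptic_amplitude_median * float(
                        np.exp(rng_sp.normal(0.0, cfg.synaptic_amplitude_sigma)))
                    sweep -= amp * epsc_kernel(t_ms - t_evt)
            if cfg.noise_sd_ephys > 0:
                sweep += rng.normal(0.0, cfg.noise_sd_ephys, size=n_samp)
            sweeps[(tid, trial)] = sweep

    return CurrentTraceSet(
        sweeps=sweeps,
        sample_rate=sample_rate,
        stim_onset_ms=stim_on,
        stim_offset_ms=stim_off,
        holding_potential=-70.0,
        n_trials=protocol.n_trials,
    )


# ------------------------------------------------------------------ top level

def simulate_mapping_experiment(config: SceneConfig,
                                protocol: Optional[StimulationProtocol] = None,
                                model: Optional[OpsinModel] = None,
                                with_fluorescence: bool = True,
                                with_currents: bool = True) -> ExperimentBundle:
    """Simulate one complete mapping experiment.

    With no explicit protocol, every non-patched cell is stimulated in id
    order under the default protocol. The opsin model defaults to the stock
    parameter set for the scene's construct.
    """
    scene = make_scene(config)
    if protocol is None:
        protocol = StimulationProtocol.for_scene(scene)
    if model is None:
        model = OpsinModel.for_construct(config.construct)
    missing = set(protocol.target_ids) - {n.id for n in scene.neurons}
    if missing:
        raise ValueError(f"protocol targets absent from scene: {sorted(missing)}")
    truth = _simulate_ground_truth(scene, protocol, model)
    fluo = simulate_gcamp_traces(scene, protocol, truth) if with_fluorescence else None
    curr = (simulate_patch_recording(scene, protocol, truth, model)
            if with_currents else None)
    return ExperimentBundle(scene=scene, protocol=protocol, model=model,
                            fluorescence=fluo, currents=curr, ground_truth=truth)
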