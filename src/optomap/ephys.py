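"""Patched-cell current analysis: event detection, kinetics, classification.

Operates on 10 kHz voltage-clamp sweeps recorded while single cells are
photostimulated. Inward currents are negative (holding −70 mV); amplitudes
are reported as signed peaks, magnitudes where noted.

Events are detected on a low-pass-filtered copy of each sweep as excursions
beyond k·SD of the pre-stimulus noise (MAD-based SD estimate). Each event is
then classified:

* ``direct`` — photocurrent of the recorded cell itself: onset < 2 ms after
  light onset and the current persists to light offset, decay commencing
  within a tolerance of the offset ("offset-locked");
* ``synaptic_candidate`` — latency ≥ 2 ms with a 10–90% rise time < 10 ms;
* ``spontaneous`` — anything before light onset or failing both patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as _signal


@dataclass
class CurrentTraceSet:
    """Voltage-clamp sweeps indexed by (target_id, trial)."""

    sweeps: dict[tuple[int, int], np.ndarray]
    sample_rate: float = 10_000.0
    stim_onset_ms: float = 100.0
    stim_offset_ms: float = 250.0
    holding_potential: float = -70.0
    n_trials: int = 4

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.sweeps.values()}
        if len(lengths) > 1:
            raise ValueError("all sweeps must have equal length")
        if self.stim_offset_ms <= self.stim_onset_ms:
            raise ValueError("stim_offset_ms must exceed stim_onset_ms")

    @property
    def stim_duration_ms(self) -> float:
        return self.stim_offset_ms - self.stim_onset_ms

    def target_ids(self) -> list[int]:
        return sorted({t for t, _ in self.sweeps})


@dataclass
class DetectedEvent:
    onset_ms: float
    peak_pA: float                       # signed (inward negative)
    end_ms: float = float("nan")         # end of the detection region
    noise_sd: float = float("nan")       # pA, MAD-based noise SD of the sweep
    latency_ms: Optional[float] = None   # onset − stim onset; None pre-stimulus
    rise_10_90_ms: Optional[float] = None
    decay_tau_ms: Optional[float] = None
    offset_locked: bool = False
    classification: str = "unclassified"
    flags: list[str] = field(default_factory=list)


@dataclass
class DetectionParams:
    k_sd: float = 4.0
    lowpass_hz: float = 1000.0
    noise_window_ms: tuple[float, float] = (0.0, 90.0)
    min_separation_ms: float = 2.0   # merge sub-threshold gaps shorter than this
    min_duration_ms: float = 1.0     # reject sub-threshold-duration noise blips
    noise_floor_pA: float = 0.5      # lower bound on the noise-SD estimate


@dataclass
class ThresholdPowerResult:
    cell_id: int
    powers: list[float]
    spikes_per_10_trials: list[int]
    threshold_power: Optional[float]
    monotonic: bool = True


def _lowpass(sweep: np.ndarray, sample_rate: float, cutoff_hz: float) -> np.ndarray:
    nyq = sample_rate / 2.0
    if cutoff_hz >= nyq:
        return sweep.astype(float)
    sos = _signal.butter(4, cutoff_hz / nyq, output="sos")
    return _signal.sosfiltfilt(sos, sweep)


def detect_events(sweep: np.ndarray, sample_rate: float = 10_000.0,
                  params: Optional[DetectionParams] = None
                  ) -> tuple[list[DetectedEvent], list[str]]:
    """Detect inward-current events in one sweep.

    Returns (events, sweep_flags). Noise SD is the MAD-scaled SD of the
    low-pass-filtered pre-stimulus window; events are contiguous regions more
    than ``k_sd`` SDs below baseline, merged across very short gaps and split
    where the trace recovers past ``resplit_fraction`` of the shallower of two
    adjacent local peaks. Onsets are found by extrapolating the initial slope
    of the crossing segment back to baseline.
    """
    params = params or DetectionParams()
    sweep = np.asarray(sweep, dtype=float)
    flags: list[str] = []
    if len(sweep) < 10 or np.ptp(sweep) == 0:
        if np.ptp(sweep) == 0 and len(sweep) >= 10:
            flags.append("flat-sweep")
        return [], flags

    filt = _lowpass(sweep, sample_rate, params.lowpass_hz)
    ms_per_samp = 1000.0 / sample_rate
    i0 = int(params.noise_window_ms[0] / ms_per_samp)
    i1 = max(i0 + 2, int(params.noise_window_ms[1] / ms_per_samp))
    noise = filt[i0:i1]
    baseline = float(np.median(noise))
    sd = float(1.4826 * np.median(np.abs(noise - baseline)))
    if sd < params.noise_floor_pA:
        if sd == 0.0:
            flags.append("zero-noise-window")
        sd = params.noise_floor_pA
    thresh = baseline - params.k_sd * sd

    below = filt < thresh
    if not below.any():
        return [], flags
    padded = np.diff(np.concatenate(([0], below.astype(int), [0])))
    starts = list(np.nonzero(padded == 1)[0])
    ends = list(np.nonzero(padded == -1)[0])

    # merge regions separated by very short sub-threshold gaps
    min_gap = int(params.min_separation_ms / ms_per_samp)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events: list[DetectedEvent] = []
    for s, e in merged:
        seg = filt[s:e]
        bounds = _split_region(seg, params.k_sd * sd) + [e - s]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if (b1 - b0) * ms_per_samp < params.min_duration_ms:
                continue
            events.append(_make_event(filt, s + b0, s + b1, baseline,
                                      thresh, ms_per_samp, sd))
    return events, flags


def _split_region(seg: np.ndarray, prominence: float) -> list[int]:
    """Start boundaries (indices into seg) separating distinguishable peaks.

    Overlapping events are split at the most-recovered sample between
    consecutive inward peaks of at least threshold-level prominence.
    """
    if len(seg) < 5:
        return [0]
    peaks, _ = _signal.find_peaks(-seg, prominence=prominence)
    if len(peaks) <= 1:
        return [0]
    bounds = [0]
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        bounds.append(int(p0 + np.argmax(seg[p0:p1])))
    return bounds


def _make_event(filt: np.ndarray, s: int, e: int, baseline: float,
                thresh: float, ms_per_samp: float,
                noise_sd: float) -> DetectedEvent:
    seg = filt[s:e]
    pk = int(np.argmin(seg))
    peak_val = float(seg[pk] - baseline)
    # onset: extrapolate the crossing segment back to baseline
    onset_idx = float(s)
    if s > 0:
        y0, y1 = filt[s - 1] - baseline, filt[s] - baseline
        if y1 < y0:  # descending through threshold
            frac = y0 / (y0 - y1) if (y0 - y1) != 0 else 0.0
            onset_idx = (s - 1) + float(np.clip(frac, 0.0, 1.0))
    return DetectedEvent(onset_ms=onset_idx * ms_per_samp, peak_pA=peak_val,
                         end_ms=e * ms_per_samp, noise_sd=noise_sd)


def event_features(event: DetectedEvent, sweep: np.ndarray,
                   sample_rate: float = 10_000.0,
                   stim_onset_ms: float = 100.0,
                   lowpass_hz: float = 1000.0) -> DetectedEvent:
    """Fill latency, 10–90% rise time and decay tau for a detected event.

    Rise time is measured between the linear-interpolation crossings of 10%
    and 90% of the peak amplitude on the rising phase; decay tau comes from a
    log-linear fit over the post-peak decay down to 20% of peak.
    """
    sweep = np.asarray(sweep, dtype=float)
    filt = _lowpass(sweep, sample_rate, lowpass_hz)
    ms_per_samp = 1000.0 / sample_rate
    onset_idx = event.onset_ms / ms_per_samp
    i_on = int(np.floor(onset_idx))

    # baseline local to the event onset
    b0 = max(0, i_on - int(5.0 / ms_per_samp))
    baseline = float(np.median(filt[b0:i_on + 1])) if i_on > b0 else float(filt[i_on])

    # peak bounded by the event's own detection region (fall back to 100 ms)
    if np.isfinite(event.end_ms) and event.end_ms > event.onset_ms:
        i_end = min(len(filt), int(np.ceil(event.end_ms / ms_per_samp)) + 1)
    else:
        i_end = min(len(filt), i_on + int(100.0 / ms_per_samp))
    seg = filt[i_on:i_end] - baseline
    if len(seg) < 2:
        event.flags.append("event-at-sweep-edge")
        return event
    pk = int(np.argmin(seg))
    peak = float(seg[pk])
    event.peak_pA = peak
    if pk >= len(seg) - 2 or i_on + pk >= len(filt) - 2:
        event.flags.append("peak-at-sweep-edge")

    event.latency_ms = (event.onset_ms - stim_onset_ms
                        if event.onset_ms >= stim_onset_ms else None)

    def crossing(level: float) -> Optional[float]:
        # first index (fractional) where the rising phase passes `level`
        # (level negative, between 0 and peak)
        for i in range(pk + 1):
            if seg[i] <= level:
                if i == 0:
                    return 0.0
                y0, y1 = seg[i - 1], seg[i]
                return (i - 1) + (level - y0) / (y1 - y0) if y1 != y0 else float(i)
        return None

    c10 = crossing(0.1 * peak)
    c90 = crossing(0.9 * peak)
    if c10 is not None and c90 is not None:
        event.rise_10_90_ms = max(0.0, (c90 - c10) * ms_per_samp)

    # decay tau: log-linear fit from peak until recovery to 20% of peak
    tail = seg[pk:]
    stop = np.nonzero(tail > 0.2 * peak)[0]
    n_tail = int(stop[0]) if len(stop) else len(tail)
    tail = tail[:n_tail]
    if len(tail) >= 4:
        y = np.abs(tail)
        t = np.arange(len(tail)) * ms_per_samp
        good = y > 0
        if good.sum() >= 4:
            slope, _ = np.polyfit(t[good], np.log(y[good]), 1)
            if slope < 0:
                event.decay_tau_ms = float(-1.0 / slope)
    return event


def compute_jitter(latencies) -> float:
    """Sample SD (n−1) of event latencies across trials, in ms."""
    lat = np.asarray(list(latencies), dtype=float)
    if len(lat) < 2:
        raise ValueError("jitter requires at least 2 latencies")
    return float(np.std(lat, ddof=1))


def classify_direct(event: DetectedEvent, sweep: np.ndarray,
                    sample_rate: float = 10_000.0,
                    stim_onset_ms: float = 100.0,
                    stim_offset_ms: float = 250.0,
                    direct_latency_ms: float = 2.0,
                    max_rise_ms: float = 10.0,
                    offset_tolerance_ms: float = 10.0,
                    lowpass_hz: float = 1000.0) -> DetectedEvent:
    """Assign direct / synaptic_candidate / spontaneous to one event.

    Direct photocurrents are locked to the light: onset within
    ``direct_latency_ms`` of stimulus onset, current sustained at ≥ half peak
    up to the light offset, and decay (recovery past half peak) beginning no
    earlier than ``offset_tolerance_ms`` before the offset.
    """
    if event.onset_ms < stim_onset_ms:
        event.classification = "spontaneous"
        return event
    if event.latency_ms is None:
        event.latency_ms = event.onset_ms - stim_onset_ms

    filt = _lowpass(np.asarray(sweep, dtype=float), sample_rate, lowpass_hz)
    ms_per_samp = 1000.0 / sample_rate
    i_on = int(event.onset_ms / ms_per_samp)
    b0 = max(0, i_on - int(5.0 / ms_per_samp))
    baseline = float(np.median(filt[b0:i_on + 1])) if i_on > b0 else 0.0
    peak = event.peak_pA

    # time of first recovery past half peak after the event onset
    half_level = baseline + 0.5 * peak
    i_half = None
    seg = filt[i_on:]
    below = seg <= half_level
    if below.any():
        first_below = int(np.argmax(below))
        rec = np.nonzero(~below[first_below:])[0]
        if len(rec):
            i_half = (i_on + first_below + int(rec[0])) * ms_per_samp

    sustained = i_half is None or i_half >= stim_offset_ms - offset_tolerance_ms
    event.offset_locked = bool(
        event.latency_ms < direct_latency_ms and sustained)

    if event.offset_locked:
        event.classification = "direct"
    elif (event.latency_ms >= direct_latency_ms
          and event.rise_10_90_ms is not None
          and event.rise_10_90_ms < max_rise_ms):
        event.classification = "synaptic_candidate"
    else:
        event.classification = "spontaneous"
    return event


def analyze_sweep(sweep: np.ndarray, sample_rate: float = 10_000.0,
                  stim_onset_ms: float = 100.0, stim_offset_ms: float = 250.0,
                  params: Optional[DetectionParams] = None
                  ) -> list[DetectedEvent]:
    """Detect, featurise and classify all events in one sweep."""
    events, _flags = detect_events(sweep, sample_rate, params)
    out = []
    for ev in events:
        ev = event_features(ev, sweep, sample_rate, stim_onset_ms)
        # filter-edge artifacts: peak vanishes against the local baseline
        if np.isfinite(ev.noise_sd) and abs(ev.peak_pA) < 2.0 * ev.noise_sd:
            continue
        ev = classify_direct(ev, sweep, sample_rate, stim_onset_ms, stim_offset_ms)
        out.append(ev)
    return out


def analyze_current_set(ctset: CurrentTraceSet,
                        params: Optional[DetectionParams] = None
                        ) -> dict[tuple[int, int], list[DetectedEvent]]:
    """Run the full per-sweep analysis over a CurrentTraceSet."""
    return {
        key: analyze_sweep(sweep, ctset.sample_rate, ctset.stim_onset_ms,
                           ctset.stim_offset_ms, params)
        for key, sweep in ctset.sweeps.items()
    }


def measure_threshold_power(outcomes: dict[float, int], n_trials: int = 10,
                            cell_id: int = 0) -> ThresholdPowerResult:
    """Minimum tested power with spikes on every one of ``n_trials`` trials.

    ``outcomes`` maps power (mW/µm²) → number of trials with ≥ 1 spike.
    Non-monotonic outcomes (a full-success power below a partial one) are
    resolved by the strict minimum and flagged.
    """
    if not outcomes:
        raise ValueError("at least one power must be tested")
    powers = sorted(outcomes)
    spikes = [outcomes[p] for p in powers]
    full = [p for p in powers if outcomes[p] == n_trials]
    threshold = min(full) if full else None
    monotonic = spikes == sorted(spikes)
    if threshold is not None:
        above = [outcomes[p] for p in powers if p >= threshold]
        if any(v < n_trials for v in above):
            monotonic = False
    return ThresholdPowerResult(cell_id=cell_id, powers=powers,
                                spikes_per_10_trials=spikes,
                                threshold_power=threshold, monotonic=monotonic)


def estimate_reversal(holding_potentials, amplitudes) -> float:
    """Reversal potential (mV): zero crossing of amplitude vs holding line."""
    v = np.asarray(list(holding_potentials), dtype=float)
    i = np.asarray(list(amplitudes), dtype=float)
    if len(v) < 2 or len(np.unique(v)) < 2:
        raise ValueError("need amplitudes at >= 2 distinct holding potentials")
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValueError("amplitude does not depend on holding potential")
    return float(-intercept / slope)
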