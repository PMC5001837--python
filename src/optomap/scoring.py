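"""Connection scoring: the five-criterion synaptic connection call.

A candidate presynaptic target is scored against five criteria, all of which
must pass for a monosynaptic excitatory connection to be called:

1. every matched postsynaptic event has latency ≥ 2 ms from stimulus onset
   (rules out direct photocurrents);
2. a matched event occurs in at least 3 of 4 trials (reproducibility);
3. the across-trial jitter (sample SD of matched latencies) is < 14 ms
   (rules out coincident spontaneous events);
4. the mean 10–90% rise time is < 10 ms (monosynaptic kinetics);
5. a calcium transient confirms the stimulated cell actually spiked.

Connectivity rate = connected pairs / candidate presynaptic cells with a
verified calcium response. Rates from optical mapping are compared with
paired-recording counts by Fisher's exact test (two-sided, point-probability
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .ephys import DetectedEvent, compute_jitter
from .imaging import ResponseSummary


@dataclass(frozen=True)
class ConnectionCriteria:
    min_latency_ms: float = 2.0
    min_trials: int = 3
    max_jitter_ms: float = 14.0
    max_rise_ms: float = 10.0
    require_calcium_transient: bool = True
    match_window_after_offset_ms: float = 50.0

    def __post_init__(self) -> None:
        if min(self.min_latency_ms, self.max_jitter_ms, self.max_rise_ms) <= 0:
            raise ValueError("criteria thresholds must be positive")
        if self.min_trials < 1:
            raise ValueError("min_trials must be >= 1")


@dataclass
class ConnectionCall:
    presynaptic_target_id: int
    connected: bool
    criteria_passed: dict[str, bool]
    matched_events: dict[int, Optional[DetectedEvent]]
    mean_latency_ms: Optional[float]
    jitter_ms: Optional[float]
    mean_rise_ms: Optional[float]


@dataclass
class MapResult:
    calls: dict[int, ConnectionCall]
    n_targets: int
    n_responsive: int
    n_connected: int
    connectivity_rate: float
    responsive_fraction: float
    offtarget_probability: float
    offtarget_mean_distance_um: float
    direct_response_fraction: float
    connected_ids: list[int] = field(default_factory=list)


def score_connection(events_by_trial: dict[int, Sequence[DetectedEvent]],
                     responsive: bool,
                     criteria: ConnectionCriteria = ConnectionCriteria(),
                     n_trials: int = 4,
                     stim_onset_ms: float = 100.0,
                     stim_duration_ms: float = 150.0,
                     target_id: int = -1) -> ConnectionCall:
    """Score one candidate presynaptic target.

    Per trial, the earliest ``synaptic_candidate`` event whose onset lies
    within [stimulus onset, stimulus offset + 50 ms] is matched; the five
    criteria are then evaluated on the matched events.
    """
    if n_trials < criteria.min_trials:
        raise ValueError(
            f"n_trials={n_trials} below min_trials={criteria.min_trials}")

    window_end = (stim_onset_ms + stim_duration_ms
                  + criteria.match_window_after_offset_ms)
    matched: dict[int, Optional[DetectedEvent]] = {}
    for trial in range(n_trials):
        cands = [ev for ev in events_by_trial.get(trial, ())
                 if ev.classification == "synaptic_candidate"
                 and stim_onset_ms <= ev.onset_ms <= window_end]
        matched[trial] = min(cands, key=lambda ev: ev.onset_ms) if cands else None

    hits = [ev for ev in matched.values() if ev is not None]
    latencies = [ev.latency_ms for ev in hits if ev.latency_ms is not None]
    rises = [ev.rise_10_90_ms for ev in hits if ev.rise_10_90_ms is not None]

    passed = {
        "latency": bool(hits) and all(
            lat >= criteria.min_latency_ms for lat in latencies),
        "trials": len(hits) >= criteria.min_trials,
        "jitter": (len(latencies) >= 2
                   and compute_jitter(latencies) < criteria.max_jitter_ms),
        "rise_time": bool(rises) and float(np.mean(rises)) < criteria.max_rise_ms,
        "calcium_transient": (responsive
                              if criteria.require_calcium_transient else True),
    }
    return ConnectionCall(
        presynaptic_target_id=target_id,
        connected=all(passed.values()),
        criteria_passed=passed,
        matched_events=matched,
        mean_latency_ms=float(np.mean(latencies)) if latencies else None,
        jitter_ms=(compute_jitter(latencies) if len(latencies) >= 2 else None),
        mean_rise_ms=float(np.mean(rises)) if rises else None,
    )


def connectivity_rate(n_connected: int, n_responsive: int) -> float:
    """Connected pairs / responsive candidate presynaptic cells."""
    if n_responsive == 0:
        raise ZeroDivisionError(
            "connectivity rate undefined with no responsive cells")
    return n_connected / n_responsive


def compare_rates_fisher(a_connected: int, a_total: int,
                         b_connected: int, b_total: int
                         ) -> tuple[float, float]:
    """Two-sided Fisher's exact test comparing two connection counts.

    Returns (odds_ratio, p). The two-sided p sums the probabilities of all
    tables (fixed margins) no more probable than the observed one.
    """
    for name, (c, t) in {"a": (a_connected, a_total),
                         "b": (b_connected, b_total)}.items():
        if c < 0 or t < 0 or c > t:
            raise ValueError(f"invalid counts for group {name}: {c}/{t}")
    table = [[a_connected, a_total - a_connected],
             [b_connected, b_total - b_connected]]
    if a_total == 0 or b_total == 0 or (a_connected + b_connected) == 0 \
            or (a_total - a_connected + b_total - b_connected) == 0:
        import warnings
        warnings.warn("degenerate margin: Fisher p = 1 by convention")
        odds = _stats.fisher_exact(table).statistic if a_total and b_total else float("nan")
        return float(odds), 1.0
    res = _stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def score_map(events_by_target: dict[int, dict[int, Sequence[DetectedEvent]]],
              responses: ResponseSummary,
              criteria: ConnectionCriteria = ConnectionCriteria(),
              n_trials: int = 4,
              stim_onset_ms: float = 100.0,
              stim_duration_ms: float = 150.0) -> MapResult:
    """Score every responsive candidate of one experiment into a MapResult.

    Only targets with a verified calcium response enter the connectivity-rate
    denominator (candidates without one cannot be scored as connected under
    criterion 5, matching how a lack of connection is defined).
    """
    calls: dict[int, ConnectionCall] = {}
    direct_count = 0
    for tid, by_trial in events_by_target.items():
        responsive = responses.responsive.get(tid, False)
        calls[tid] = score_connection(
            by_trial, responsive, criteria, n_trials,
            stim_onset_ms, stim_duration_ms, target_id=tid)
        if any(ev.classification == "direct"
               for evs in by_trial.values() for ev in evs):
            direct_count += 1

    connected = [tid for tid, c in calls.items() if c.connected]
    n_resp = responses.n_responsive
    rate = (connectivity_rate(len(connected), n_resp)
            if n_resp else float("nan"))
    dists = [d for d in responses.offtarget_distances if np.isfinite(d)]
    return MapResult(
        calls=calls,
        n_targets=responses.n_targets,
        n_responsive=n_resp,
        n_connected=len(connected),
        connectivity_rate=rate,
        responsive_fraction=responses.responsive_fraction,
        offtarget_probability=responses.offtarget_probability,
        offtarget_mean_distance_um=float(np.mean(dists)) if dists else float("nan"),
        direct_response_fraction=(direct_count / len(events_by_target)
                                  if events_by_target else 0.0),
        connected_ids=sorted(connected),
    )


def build_direct_current_map(positions: np.ndarray,
                             peak_currents: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble per-position peak direct currents into a 2-D grid map.

    ``positions`` is (n, 2) stimulation coordinates (µm) lying on a
    rectangular grid; ``peak_currents`` the corresponding direct-current
    magnitudes (pA, 0 where no direct event occurred). Returns
    (map, x_levels, y_levels) with map[j, i] the current at
    (x_levels[i], y_levels[j]); grid positions not stimulated are 0.
    Duplicate positions are an error.
    """
    positions = np.asarray(positions, dtype=float)
    peak_currents = np.asarray(peak_currents, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    if len(positions) != len(peak_currents):
        raise ValueError("positions and currents must align")
    seen = set()
    for xy in map(tuple, np.round(positions, 6)):
        if xy in seen:
            raise ValueError(f"duplicate grid position {xy}")
        seen.add(xy)
    xs = np.unique(np.round(positions[:, 0], 6))
    ys = np.unique(np.round(positions[:, 1], 6))
    grid = np.zeros((len(ys), len(xs)))
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: j for j, y in enumerate(ys)}
    for (x, y), c in zip(np.round(positions, 6), np.abs(peak_currents)):
        grid[yi[y], xi[x]] = c
    return grid, xs, ys
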