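"""Calcium-imaging analysis: ΔF/F, transient detection, QC, response classing.

The analysis chain mirrors how GCaMP6s movies are scored in sequential
single-cell photostimulation experiments:

1. ΔF/F per ROI against the mean of 10 stimulus-free baseline frames;
2. significant transients = runs of ≥ 2 consecutive frames more than 3
   baseline SDs above the baseline mean;
3. cells whose baseline fluorescence exceeds the across-cell mean by more
   than 2 SDs are excluded (GCaMP overexpression causes aberrant responses);
4. a stimulated target is "responsive" when a transient onsets within its own
   stimulation window reproducibly across trials; transients in other cells
   during that window are off-target activations.

Frames are 0-based internally; user-facing reports use 1-based frame numbers
(so the first stimulated spot is at "frame 2").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class FluorescenceTraceSet:
    """Per-cell fluorescence time series plus the stimulus-frame registry.

    ``traces`` is (n_cells, n_frames) raw fluorescence (a.u.); row order
    matches ``cell_ids``. ``stim_registry`` maps (target_id, trial) to the
    absolute 0-based stimulation frame.
    """

    traces: np.ndarray
    frame_rate: float
    cell_ids: list[int]
    cell_positions: Optional[np.ndarray] = None  # (n_cells, 2) µm
    stim_registry: dict[tuple[int, int], int] = field(default_factory=dict)
    n_baseline_frames: int = 10
    n_trials: int = 1

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D cell × frame array")
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValueError("cell_ids length must match trace rows")
        n_frames = self.traces.shape[1]
        for key, f in self.stim_registry.items():
            if not (0 <= f < n_frames):
                raise ValueError(f"stimulation frame {f} for {key} outside trace")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    def row_of(self, cell_id: int) -> int:
        return self.cell_ids.index(cell_id)


@dataclass
class TransientEvent:
    """One significant calcium transient."""

    cell_id: int
    onset_frame: int          # 0-based
    duration_frames: int
    peak_dff: float
    associated_target: Optional[int] = None


@dataclass
class ImagingQCReport:
    excluded_cells: list[int]
    reasons: dict[int, str]
    baseline_means: dict[int, float]
    population_mean: float
    population_sd: float
    cutoff: float


def compute_dff(traces: np.ndarray,
                n_baseline_frames: int = 10) -> tuple[np.ndarray, dict[int, str]]:
    """ΔF/F = (F − F0)/F0 with per-cell F0 = mean of the first baseline frames.

    Returns (dff, invalid) where ``invalid`` maps row index → reason for cells
    with non-positive F0; those rows are NaN and must be excluded downstream.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim == 1:
        traces = traces[None, :]
    if traces.shape[1] <= n_baseline_frames:
        raise ValueError("trace shorter than the baseline window")
    f0 = traces[:, :n_baseline_frames].mean(axis=1)
    invalid = {i: f"non-positive baseline F0 ({f0[i]:.3g})"
               for i in np.nonzero(f0 <= 0)[0]}
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (traces - f0[:, None]) / f0[:, None]
    for i in invalid:
        dff[i] = np.nan
    return dff, invalid


def detect_transients(dff: np.ndarray, k_sd: float = 3.0, min_frames: int = 2,
                      n_baseline_frames: int = 10,
                      noise_floor: float = 0.05,
                      cell_ids: Optional[Sequence[int]] = None
                      ) -> list[TransientEvent]:
    """Find significant transients per cell.

    A transient is a maximal run of consecutive frames with
    ΔF/F > baseline_mean + k_sd · baseline_SD lasting at least ``min_frames``.
    Baseline mean/SD come from the cell's own first ``n_baseline_frames``
    frames (the only epoch guaranteed stimulus-free). A cell with zero
    baseline SD falls back to ``noise_floor`` as its SD.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.ndim == 1:
        dff = dff[None, :]
    ids = list(cell_ids) if cell_ids is not None else list(range(dff.shape[0]))
    events: list[TransientEvent] = []
    for row, cid in enumerate(ids):
        tr = dff[row]
        if np.any(np.isnan(tr)):
            continue
        base = tr[:n_baseline_frames]
        mu = base.mean()
        sd = base.std(ddof=1) if len(base) > 1 else 0.0
        if sd < 1e-9:  # numerically zero baseline SD
            sd = noise_floor
        above = tr > mu + k_sd * sd
        # maximal runs of consecutive True
        padded = np.diff(np.concatenate(([0], above.astype(int), [0])))
        starts = np.nonzero(padded == 1)[0]
        ends = np.nonzero(padded == -1)[0]
        for s, e in zip(starts, ends):
            if e - s >= min_frames:
                events.append(TransientEvent(
                    cell_id=cid, onset_frame=int(s), duration_frames=int(e - s),
                    peak_dff=float(tr[s:e].max())))
    return events


def exclude_high_baseline(traces: np.ndarray, n_baseline_frames: int = 10,
                          k_sd: float = 2.0, robust: bool = False,
                          cell_ids: Optional[Sequence[int]] = None
                          ) -> ImagingQCReport:
    """Exclude cells whose baseline fluorescence is an outlier across cells.

    A cell is excluded when its baseline mean exceeds the across-cell mean by
    more than ``k_sd`` sample SDs (or, with ``robust=True``, the median by
    ``k_sd`` scaled MADs). Needs at least 3 cells; with fewer, no exclusion is
    possible and a warning is emitted.
    """
    traces = np.asarray(traces, dtype=float)
    ids = list(cell_ids) if cell_ids is not None else list(range(traces.shape[0]))
    base = traces[:, :n_baseline_frames].mean(axis=1)
    means = {cid: float(b) for cid, b in zip(ids, base)}
    if traces.shape[0] < 3:
        warnings.warn("fewer than 3 cells: baseline QC exclusion not possible")
        return ImagingQCReport([], {}, means, float(np.mean(base)),
                               float("nan"), float("inf"))
    if robust:
        centre = float(np.median(base))
        spread = float(1.4826 * np.median(np.abs(base - centre)))
    else:
        centre = float(np.mean(base))
        spread = float(np.std(base, ddof=1))
    cutoff = centre + k_sd * spread
    excluded = [cid for cid, b in zip(ids, base) if b > cutoff]
    reasons = {cid: f"baseline {means[cid]:.1f} > cutoff {cutoff:.1f}"
               for cid in excluded}
    return ImagingQCReport(excluded, reasons, means, centre, spread, cutoff)


def map_stimulus_frames(protocol, n_frames: Optional[int] = None,
                        absolute: bool = True) -> dict[tuple[int, int], int]:
    """Stimulation frame per (target_id, trial), 0-based.

    Target k (1-based) of trial t is stimulated at clock frame
    ``first_stim_frame + (k−1)·stim_every_n_frames`` plus the trial offset;
    with defaults the first target lands on the second frame and subsequent
    targets on every other frame. ``absolute=True`` adds the pre-stimulation
    baseline block so the indices address simulated/recorded traces directly.
    With ``stim_every_n_frames == 1`` consecutive response windows overlap; a
    warning is emitted.
    """
    from .synthgen import build_stim_registry  # local: avoid import cycle

    if protocol.stim_every_n_frames < 2:
        warnings.warn("stim_every_n_frames < 2: response windows of "
                      "neighbouring targets overlap")
    reg = build_stim_registry(protocol, absolute=absolute)
    if n_frames is not None:
        worst = max(reg.values()) + 1  # +1: response window extends one frame
        if worst >= n_frames:
            raise ValueError(
                f"registry frame {worst} exceeds trace length {n_frames}")
    return reg


@dataclass
class ResponseSummary:
    """Per-target responsiveness and off-target statistics for one experiment."""

    responsive: dict[int, bool]
    n_trials_with_event: dict[int, int]
    n_targets: int
    n_responsive: int
    responsive_fraction: float
    offtarget_events: list[dict]      # target, cell, n_trials, distance (µm or nan)
    offtarget_probability: float      # reproducible off-target pairs / n targets
    offtarget_distances: list[float]


def classify_responses(events: list[TransientEvent],
                       registry: dict[tuple[int, int], int],
                       cell_positions: Optional[np.ndarray] = None,
                       cell_ids: Optional[Sequence[int]] = None,
                       min_trials: int = 3,
                       window_frames: int = 2,
                       excluded_cells: Sequence[int] = ()) -> ResponseSummary:
    """Classify transients as target responses or off-target activations.

    A target is responsive when a transient onsets within its own response
    window (stimulation frame + the following ``window_frames − 1`` frames)
    in at least ``min_trials`` trials. An off-target event is a transient in a
    different, non-excluded cell onsetting within a target's window; it is
    counted (once per cell–target pair) when reproducible in ≥ ``min_trials``
    trials, and its distance is the in-plane Euclidean separation of the two
    cells. Off-target probability = reproducible pairs / number of targets.
    """
    excluded = set(excluded_cells)
    targets = sorted({tid for tid, _ in registry.keys()})
    targets = [t for t in targets if t not in excluded]
    trials = sorted({tr for _, tr in registry.keys()})

    onsets: dict[int, list[int]] = {}
    for ev in events:
        if ev.cell_id in excluded:
            continue
        onsets.setdefault(ev.cell_id, []).append(ev.onset_frame)

    def hit(cell: int, frame: int) -> bool:
        return any(frame <= o < frame + window_frames
                   for o in onsets.get(cell, ()))

    responsive: dict[int, bool] = {}
    n_with: dict[int, int] = {}
    pair_hits: dict[tuple[int, int], int] = {}
    for tid in targets:
        count = sum(1 for tr in trials if hit(tid, registry[(tid, tr)]))
        n_with[tid] = count
        responsive[tid] = count >= min_trials
        for cell in onsets:
            if cell == tid:
                continue
            c = sum(1 for tr in trials if hit(cell, registry[(tid, tr)]))
            if c >= min_trials:
                pair_hits[(tid, cell)] = c

    if cell_ids is not None and cell_positions is not None:
        pos = {cid: cell_positions[i] for i, cid in enumerate(cell_ids)}
    else:
        pos = {}
    off_events = []
    distances = []
    for (tid, cell), c in sorted(pair_hits.items()):
        if tid in pos and cell in pos:
            d = float(np.hypot(*(np.asarray(pos[cell]) - np.asarray(pos[tid]))))
            distances.append(d)
        else:
            d = float("nan")
        off_events.append({"target": tid, "cell": cell, "n_trials": c,
                           "distance_um": d})

    n_resp = sum(responsive.values())
    return ResponseSummary(
        responsive=responsive,
        n_trials_with_event=n_with,
        n_targets=len(targets),
        n_responsive=n_resp,
        responsive_fraction=(n_resp / len(targets)) if targets else float("nan"),
        offtarget_events=off_events,
        offtarget_probability=(len(off_events) / len(targets)) if targets else 0.0,
        offtarget_distances=distances,
    )
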