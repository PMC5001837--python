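"""Readers and writers for the pipeline's file dialects.

All files are plain text: CSV with a mandatory header row ('.' decimal,
comma separator), JSON for structured records, YAML for configuration. Units
are encoded in column names (time_s, time_ms, distance_um, current_pA);
fluorescence is dimensionless. Frame indices in user-facing files are
1-based; in-memory indices are 0-based.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ephys import CurrentTraceSet, DetectedEvent
from .imaging import FluorescenceTraceSet, ImagingQCReport, TransientEvent
from .scene import Scene, SceneConfig
from .scoring import MapResult
from .synthgen import StimulationProtocol


# ----------------------------------------------------------------- config io

def load_scene_config(path) -> SceneConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SceneConfig(**data)


def save_scene_config(config: SceneConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_protocol(path) -> StimulationProtocol:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "target_ids" in data:
        data["target_ids"] = tuple(data["target_ids"])
    return StimulationProtocol(**data)


def save_protocol(protocol: StimulationProtocol, path) -> None:
    data = asdict(protocol)
    data["target_ids"] = list(data["target_ids"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ------------------------------------------------------------- fluorescence

def write_fluorescence_csv(fset: FluorescenceTraceSet, path) -> None:
    """Rows = frames, columns = cell_<id>, first column frame timestamps (s)."""
    times = (np.arange(fset.n_frames) + 0.5) / fset.frame_rate
    df = pd.DataFrame({"time_s": times})
    for i, cid in enumerate(fset.cell_ids):
        df[f"cell_{cid}"] = fset.traces[i]
    df.to_csv(path, index=False, float_format="%.6g")


def write_registry_json(fset: FluorescenceTraceSet, path) -> None:
    """Stimulus registry with 1-based frame indices (user-facing)."""
    payload = {
        "frame_rate_hz": fset.frame_rate,
        "n_baseline_frames": fset.n_baseline_frames,
        "n_trials": fset.n_trials,
        "frame_indexing": "1-based",
        "stimulations": [
            {"target": tid, "trial": trial, "frame": frame + 1}
            for (tid, trial), frame in sorted(fset.stim_registry.items())
        ],
    }
    if fset.cell_positions is not None:
        payload["cell_positions_um"] = {
            str(cid): [float(x), float(y)]
            for cid, (x, y) in zip(fset.cell_ids, fset.cell_positions)
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_fluorescence_csv(trace_path, registry_path) -> FluorescenceTraceSet:
    df = pd.read_csv(trace_path)
    cell_cols = [c for c in df.columns if c.startswith("cell_")]
    cell_ids = [int(c.split("_", 1)[1]) for c in cell_cols]
    traces = df[cell_cols].to_numpy().T
    with open(registry_path) as fh:
        reg = json.load(fh)
    registry = {(s["target"], s["trial"]): s["frame"] - 1
                for s in reg["stimulations"]}
    positions = None
    if "cell_positions_um" in reg:
        positions = np.array([reg["cell_positions_um"][str(cid)]
                              for cid in cell_ids])
    return FluorescenceTraceSet(
        traces=traces, frame_rate=float(reg["frame_rate_hz"]),
        cell_ids=cell_ids, cell_positions=positions, stim_registry=registry,
        n_baseline_frames=int(reg["n_baseline_frames"]),
        n_trials=int(reg.get("n_trials", 1)))


# ------------------------------------------------------------------ currents

def write_currents(ctset: CurrentTraceSet, outdir) -> None:
    """One CSV per (target, trial) plus an index JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index = {
        "sample_rate_hz": ctset.sample_rate,
        "stim_onset_ms": ctset.stim_onset_ms,
        "stim_offset_ms": ctset.stim_offset_ms,
        "holding_potential_mV": ctset.holding_potential,
        "n_trials": ctset.n_trials,
        "sweeps": [],
    }
    for (tid, trial), sweep in sorted(ctset.sweeps.items()):
        name = f"sweep_t{tid:03d}_r{trial}.csv"
        t_ms = np.arange(len(sweep)) / ctset.sample_rate * 1000.0
        pd.DataFrame({"time_ms": t_ms, "current_pA": sweep}).to_csv(
            outdir / name, index=False, float_format="%.5g")
        index["sweeps"].append({"target": tid, "trial": trial, "file": name})
    with open(outdir / "index.json", "w") as fh:
        json.dump(index, fh, indent=1)


def read_currents(indir) -> CurrentTraceSet:
    indir = Path(indir)
    with open(indir / "index.json") as fh:
        index = json.load(fh)
    sweeps = {}
    for entry in index["sweeps"]:
        df = pd.read_csv(indir / entry["file"])
        sweeps[(entry["target"], entry["trial"])] = df["current_pA"].to_numpy()
    return CurrentTraceSet(
        sweeps=sweeps, sample_rate=float(index["sample_rate_hz"]),
        stim_onset_ms=float(index["stim_onset_ms"]),
        stim_offset_ms=float(index["stim_offset_ms"]),
        holding_potential=float(index["holding_potential_mV"]),
        n_trials=int(index["n_trials"]))


# --------------------------------------------------------------- scene truth

def write_scene_json(scene: Scene, path) -> None:
    payload = {
        "config": asdict(scene.config),
        "patched_id": scene.patched_id,
        "neurons": [
            {"id": n.id, "x": n.x, "y": n.y, "z": n.z,
             "expresses_opsin": n.expresses_opsin,
             "expresses_indicator": n.expresses_indicator,
             "high_baseline": n.high_baseline,
             "baseline_fluorescence": n.baseline_fluorescence,
             "is_patched": n.is_patched,
             "connected_to_patched": n.connected_to_patched,
             "synaptic_amplitude_pA": n.synaptic_amplitude,
             "synaptic_delay_ms": n.synaptic_delay_mean}
            for n in scene.neurons
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


# ---------------------------------------------------------- events & results

def events_to_frame(events: list[TransientEvent]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cell": ev.cell_id, "onset_frame": ev.onset_frame + 1,  # 1-based
         "duration_frames": ev.duration_frames, "peak_dff": ev.peak_dff,
         "associated_target": ev.associated_target}
        for ev in events
    ])


def ephys_events_to_frame(events_by_key: dict[tuple[int, int], list[DetectedEvent]]
                          ) -> pd.DataFrame:
    rows = []
    for (tid, trial), events in sorted(events_by_key.items()):
        for ev in events:
            rows.append({
                "target": tid, "trial": trial, "onset_ms": ev.onset_ms,
                "peak_pA": ev.peak_pA, "latency_ms": ev.latency_ms,
                "rise_10_90_ms": ev.rise_10_90_ms,
                "decay_tau_ms": ev.decay_tau_ms,
                "offset_locked": ev.offset_locked,
                "classification": ev.classification,
            })
    return pd.DataFrame(rows)


def qc_report_to_dict(report: ImagingQCReport) -> dict:
    return {
        "excluded_cells": report.excluded_cells,
        "reasons": report.reasons,
        "population_mean": report.population_mean,
        "population_sd": report.population_sd,
        "cutoff": report.cutoff,
    }


def map_result_to_dict(result: MapResult) -> dict:
    return {
        "n_targets": result.n_targets,
        "n_responsive": result.n_responsive,
        "n_connected": result.n_connected,
        "connectivity_rate": result.connectivity_rate,
        "responsive_fraction": result.responsive_fraction,
        "offtarget_probability": result.offtarget_probability,
        "offtarget_mean_distance_um": result.offtarget_mean_distance_um,
        "direct_response_fraction": result.direct_response_fraction,
        "connected_ids": result.connected_ids,
        "calls": {
            str(tid): {
                "connected": call.connected,
                "criteria_passed": call.criteria_passed,
                "mean_latency_ms": call.mean_latency_ms,
                "jitter_ms": call.jitter_ms,
                "mean_rise_ms": call.mean_rise_ms,
            } for tid, call in sorted(result.calls.items())
        },
    }


def calls_to_frame(result: MapResult) -> pd.DataFrame:
    rows = []
    for tid, call in sorted(result.calls.items()):
        row = {"target": tid, "connected": call.connected,
               "mean_latency_ms": call.mean_latency_ms,
               "jitter_ms": call.jitter_ms, "mean_rise_ms": call.mean_rise_ms}
        row.update({f"criterion_{name}": ok
                    for name, ok in call.criteria_passed.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# --------------------------------------------------------------------- movie

def write_movie_tiff(fset: FluorescenceTraceSet, path,
                     field_size_um: tuple[float, float] = (200.0, 300.0),
                     pixels: int = 128, cell_radius_um: float = 6.0) -> None:
    """Render a simple synthetic movie: one Gaussian blob per cell, one TIFF
    page per frame. Intended for visual inspection, not quantitative use."""
    import tifffile

    if fset.cell_positions is None:
        raise ValueError("cell positions are required to render a movie")
    w_um, h_um = field_size_um
    ny = pixels
    nx = max(8, int(round(pixels * w_um / h_um)))
    yy, xx = np.meshgrid(np.linspace(0, h_um, ny), np.linspace(0, w_um, nx),
                         indexing="ij")
    sig2 = cell_radius_um ** 2
    blobs = [np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sig2))
             for x, y in fset.cell_positions]
    frames = np.zeros((fset.n_frames, ny, nx), dtype=np.float32)
    for i in range(fset.n_cells):
        frames += fset.traces[i][:, None, None] * blobs[i][None, :, :]
    tifffile.imwrite(path, frames, photometric="minisblack")
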