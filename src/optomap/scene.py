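"""Virtual-slice scene generation.

A Scene is the hidden ground truth of one mapping experiment: neuron positions
within the usable field of view, which cells express the opsin and the calcium
indicator, which cells are synaptically connected to the single patched
(recorded) neuron, and per-connection synaptic parameters.

Geometry follows the experimental layout: stimulation points and imaging are
confined to a ~200 × 300 µm region of the microscope field, neurons lie in a
single axial plane, and one neuron near the field centre is patched in
whole-cell mode while all others are sequential photostimulation targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from ._rng import CELL, substream

#: Default off-target / direct-response outcome parameters per construct.
#: Off-target probability is per stimulated target cell; distance scale (µm)
#: sets the reach over which a non-target cell can be co-activated.
CONSTRUCT_DEFAULTS = {
    "targeted": {"offtarget_prob": 0.054, "offtarget_distance_scale": 18.9,
                 "direct_response_fraction": 0.0},
    "nontargeted": {"offtarget_prob": 0.152, "offtarget_distance_scale": 40.6,
                    "direct_response_fraction": 0.2875},
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the virtual slice.

    Probabilities: ``p_connect`` is the chance an opsin-expressing target is
    presynaptic to the patched cell (10% average connection probability in
    layer II/III); ``p_indicator`` the chance a cell carries enough GCaMP6s to
    report its spikes (separate viral construct, ~80% co-infection);
    ``p_high_baseline`` the chance an indicator-positive cell overexpresses
    GCaMP (inflated baseline, excluded by QC).
    """

    n_cells: int = 43
    field_width: float = 200.0     # µm, x
    field_height: float = 300.0    # µm, y
    p_connect: float = 0.10
    p_opsin: float = 1.0
    p_indicator: float = 0.80
    p_high_baseline: float = 0.02
    construct: str = "targeted"
    spontaneous_epsc_rate: float = 1.0   # events/s in the patched cell
    noise_sd_imaging: float = 0.05       # ΔF/F units
    noise_sd_ephys: float = 2.0          # pA
    baseline_fluorescence: float = 100.0  # a.u.
    high_baseline_factor: float = 3.5
    transient_amplitude: float = 0.4     # ΔF/F per action potential
    gcamp_rise_tau: float = 0.18         # s
    gcamp_decay_tau: float = 1.0         # s
    synaptic_amplitude_median: float = 25.0  # pA
    synaptic_amplitude_sigma: float = 0.4    # lognormal shape
    synaptic_delay_mean: float = 3.0         # ms
    synaptic_delay_sd: float = 0.5
    dendrite_length: float = 150.0       # µm, radial segments
    n_dendrites: int = 4
    direct_reach: float = 15.0           # µm: spot-to-soma distance that drives
                                         # a direct photocurrent in the patched cell
    offtarget_prob: Optional[float] = None            # None → construct default
    offtarget_distance_scale: Optional[float] = None  # µm
    direct_response_fraction: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("p_connect", "p_opsin", "p_indicator", "p_high_baseline"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.construct not in CONSTRUCT_DEFAULTS:
            raise ValueError(f"construct must be one of {sorted(CONSTRUCT_DEFAULTS)}")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.noise_sd_imaging < 0 or self.noise_sd_ephys < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.spontaneous_epsc_rate < 0:
            raise ValueError("spontaneous_epsc_rate must be non-negative")

    def resolved(self, name: str) -> float:
        """Off-target/direct parameter with construct-dependent default."""
        v = getattr(self, name)
        if v is None:
            return CONSTRUCT_DEFAULTS[self.construct][name]
        return v

    def with_seed(self, seed: int) -> "SceneConfig":
        return replace(self, seed=seed)


@dataclass
class Neuron:
    id: int
    x: float
    y: float
    z: float
    expresses_opsin: bool
    expresses_indicator: bool
    high_baseline: bool
    baseline_fluorescence: float
    is_patched: bool = False
    dendrite_nodes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    connected_to_patched: bool = False
    synaptic_amplitude: float = 0.0    # pA, > 0 iff connected
    synaptic_delay_mean: float = 0.0   # ms

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Scene:
    config: SceneConfig
    neurons: list[Neuron]

    @property
    def patched(self) -> Neuron:
        return next(n for n in self.neurons if n.is_patched)

    @property
    def patched_id(self) -> int:
        return self.patched.id

    def positions(self) -> np.ndarray:
        """(n_cells, 2) array of xy positions, row order = neuron id."""
        return np.array([[n.x, n.y] for n in self.neurons])

    def target_ids(self) -> list[int]:
        """All non-patched cells, in id order (stimulation order)."""
        return [n.id for n in self.neurons if not n.is_patched]

    def true_connection_ids(self) -> set[int]:
        return {n.id for n in self.neurons if n.connected_to_patched}

    def neuron(self, cell_id: int) -> Neuron:
        return self.neurons[cell_id]


def _dendrite_nodes(x: float, y: float, z: float, n_dendrites: int,
                    length: float, rng: np.random.Generator) -> np.ndarray:
    """Straight radial dendritic segments with nodes every 25 µm."""
    angles = rng.uniform(0, 2 * np.pi, size=n_dendrites)
    radii = np.arange(25.0, length + 1e-9, 25.0)
    nodes = [
        (x + r * np.cos(a), y + r * np.sin(a), z)
        for a in angles for r in radii
    ]
    return np.array(nodes) if nodes else np.zeros((0, 3))


def make_scene(config: SceneConfig) -> Scene:
    """Draw a virtual slice from ``config``.

    Each neuron consumes only its own random substream, so increasing
    ``n_cells`` leaves all existing neurons' draws unchanged. The patched
    neuron is the cell closest to the field centre (mirroring the practice of
    patching a central cell so targets surround it).
    """
    cfg = config
    neurons: list[Neuron] = []
    for i in range(cfg.n_cells):
        rng = substream(cfg.seed, CELL, i)
        x = rng.uniform(0.0, cfg.field_width)
        y = rng.uniform(0.0, cfg.field_height)
        z = 0.0
        opsin = rng.random() < cfg.p_opsin
        indicator = rng.random() < cfg.p_indicator
        high = indicator and (rng.random() < cfg.p_high_baseline)
        f0 = cfg.baseline_fluorescence * (cfg.high_baseline_factor if high else 1.0)
        # per-cell fluorescence heterogeneity (±10%)
        f0 *= rng.normal(1.0, 0.1)
        f0 = max(f0, 0.2 * cfg.baseline_fluorescence)
        connected = opsin and (rng.random() < cfg.p_connect)
        amp = 0.0
        delay = 0.0
        if connected:
            amp = cfg.synaptic_amplitude_median * float(
                np.exp(rng.normal(0.0, cfg.synaptic_amplitude_sigma)))
            delay = max(2.0, rng.normal(cfg.synaptic_delay_mean, cfg.synaptic_delay_sd))
        nodes = _dendrite_nodes(x, y, z, cfg.n_dendrites, cfg.dendrite_length, rng)
        neurons.append(Neuron(
            id=i, x=x, y=y, z=z,
            expresses_opsin=opsin, expresses_indicator=indicator,
            high_baseline=high, baseline_fluorescence=f0,
            dendrite_nodes=nodes,
            connected_to_patched=connected,
            synaptic_amplitude=amp, synaptic_delay_mean=delay,
        ))

    centre = np.array([cfg.field_width / 2.0, cfg.field_height / 2.0])
    d2 = [((n.x - centre[0]) ** 2 + (n.y - centre[1]) ** 2) for n in neurons]
    patched_idx = int(np.argmin(d2))
    neurons[patched_idx].is_patched = True
    # the patched cell is the postsynaptic read-out, not a candidate presynaptic
    neurons[patched_idx].connected_to_patched = False
    neurons[patched_idx].synaptic_amplitude = 0.0
    neurons[patched_idx].synaptic_delay_mean = 0.0
    return Scene(config=cfg, neurons=neurons)
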