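"""Opsin photocurrent and spiking response models.

Parameterises how a channelrhodopsin-expressing neuron responds to a temporally
focused (TF) two-photon stimulation disc: photocurrent amplitude as a function
of incident power density and of the distance of the stimulation spot from the
soma along dendritic or axonal processes, and the probability/latency of evoked
action potentials as the spot is displaced laterally or axially.

Two stock parameter sets are provided:

* ``OpsinModel.targeted()`` — soma-targeted ChR2 (Kv2.1 trafficking motif):
  photocurrent falls 10-fold 50 µm along a dendrite and 5-fold 20 µm down the
  axon; spike-probability FWHM 11.1 µm lateral / 23.3 µm axial; threshold power
  density 0.88 mW/µm².
* ``OpsinModel.nontargeted()`` — conventional ChR2-EYFP: 2-fold dendritic
  decline at 50 µm, broader resolution (19.6 / 36.2 µm), threshold
  2.75 mW/µm².

Distance attenuation is exponential, ``I(d) = I_soma(P) · exp(-d/λ)``, with a
compartment-specific length constant λ. Amplitude versus power follows a Hill
curve with coefficient 1 solved exactly through two calibration points
(current at threshold power, current at 3.63 mW/µm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

_LN2_4 = 4.0 * math.log(2.0)


def hill_from_two_points(p1: float, i1: float, p2: float, i2: float) -> tuple[float, float]:
    """Solve ``I(P) = I_max · P / (P + K)`` through two (power, current) points.

    Returns (I_max, K). Requires 0 < p1 < p2 and 0 < i1 < i2 with
    i1/p1 > i2/p2 (sub-linear growth), otherwise no positive solution exists.
    """
    if not (0 < p1 < p2 and 0 < i1 < i2):
        raise ValueError("calibration points must satisfy 0 < p1 < p2, 0 < i1 < i2")
    denom = i1 * p2 - i2 * p1
    if denom <= 0:
        raise ValueError("calibration points imply super-linear growth; no Hill-1 solution")
    K = p1 * p2 * (i2 - i1) / denom
    i_max = i1 * (p1 + K) / p1
    return i_max, K


@dataclass(frozen=True)
class OpsinModel:
    """Response model for one ChR2 construct.

    Length constants are in µm, powers in mW/µm², currents in pA, times in ms.
    ``power_calibration`` holds two (power, somatic current) anchor points that
    define the Hill amplitude-vs-power curve.
    """

    construct: str
    dendrite_length_constant: float
    axon_length_constant: float
    threshold_power: float
    fwhm_lateral: float
    fwhm_axial: float
    latency_at_threshold: float
    latency_floor: float
    latency_jitter_sd: float
    power_calibration: tuple[tuple[float, float], tuple[float, float]]
    chr2_on_tau: float = 2.0
    chr2_off_tau: float = 12.0
    latency_power_scale: float = 1.0  # mW/µm² e-folding of latency shortening
    spike_gamma: float = 4.0          # steepness of sub-threshold probability
    hill_imax: float = field(init=False)
    hill_k: float = field(init=False)

    def __post_init__(self) -> None:
        for name in (
            "dendrite_length_constant", "axon_length_constant", "threshold_power",
            "fwhm_lateral", "fwhm_axial", "latency_at_threshold", "latency_floor",
            "latency_jitter_sd", "chr2_on_tau", "chr2_off_tau",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        (p1, i1), (p2, i2) = self.power_calibration
        i_max, k = hill_from_two_points(p1, i1, p2, i2)
        object.__setattr__(self, "hill_imax", i_max)
        object.__setattr__(self, "hill_k", k)

    # ------------------------------------------------------------------ stock
    @classmethod
    def targeted(cls, **overrides) -> "OpsinModel":
        """Soma-targeted ChR2-Kv2.1 defaults."""
        params = dict(
            construct="targeted",
            dendrite_length_constant=50.0 / math.log(10.0),   # 10-fold at 50 µm
            axon_length_constant=20.0 / math.log(5.0),        # 5-fold at 20 µm
            threshold_power=0.88,
            fwhm_lateral=11.1,
            fwhm_axial=23.3,
            latency_at_threshold=38.98,
            latency_floor=9.3,
            latency_jitter_sd=6.8,
            power_calibration=((0.88, 222.70), (3.63, 760.5)),
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def nontargeted(cls, **overrides) -> "OpsinModel":
        """Conventional ChR2-EYFP defaults."""
        params = dict(
            construct="nontargeted",
            dendrite_length_constant=50.0 / math.log(2.0),    # 2-fold at 50 µm
            axon_length_constant=20.0 / math.log(2.0),
            threshold_power=2.75,
            fwhm_lateral=19.6,
            fwhm_axial=36.2,
            latency_at_threshold=38.98,
            latency_floor=9.3,
            latency_jitter_sd=6.8,
            power_calibration=((2.75, 261.06), (3.63, 308.3)),
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def for_construct(cls, construct: str, **overrides) -> "OpsinModel":
        if construct == "targeted":
            return cls.targeted(**overrides)
        if construct == "nontargeted":
            return cls.nontargeted(**overrides)
        raise ValueError(f"unknown construct {construct!r}")

    # ------------------------------------------------------------- responses
    def somatic_current(self, power: float) -> float:
        """Peak somatic photocurrent (pA) at ``power`` mW/µm² (Hill-1 curve)."""
        if power < 0:
            raise ValueError("power must be non-negative")
        return self.hill_imax * power / (power + self.hill_k)

    def length_constant(self, compartment: str) -> float:
        if compartment in ("soma", "dendrite"):
            return self.dendrite_length_constant
        if compartment == "axon":
            return self.axon_length_constant
        raise ValueError(f"unknown compartment {compartment!r}")

    def spike_probability(self, lateral_offset: float, axial_offset: float,
                          power: float) -> float:
        """Probability of evoking ≥1 spike for a spot displaced from the soma.

        Separable unit-peak Gaussians in lateral/axial offset with the model
        FWHMs, scaled by the on-soma probability, which reaches 1 exactly at
        threshold power (the 10/10-trials definition of threshold).
        """
        if power < 0:
            raise ValueError("power must be non-negative")
        p_soma = min(1.0, (power / self.threshold_power) ** self.spike_gamma)
        g_lat = math.exp(-_LN2_4 * (lateral_offset / self.fwhm_lateral) ** 2)
        g_ax = math.exp(-_LN2_4 * (axial_offset / self.fwhm_axial) ** 2)
        return p_soma * g_lat * g_ax

    def latency_mean(self, power: float) -> float:
        """Mean first-spike latency (ms): exponential shortening above threshold."""
        if power <= self.threshold_power:
            return self.latency_at_threshold
        span = self.latency_at_threshold - self.latency_floor
        return self.latency_floor + span * math.exp(
            -(power - self.threshold_power) / self.latency_power_scale
        )

    def latency_jitter(self, power: float) -> float:
        """Across-trial latency SD (ms), shrinking with the mean latency:
        the configured jitter applies at threshold power and scales down
        proportionally as stronger stimulation drives faster, more
        deterministic spike initiation."""
        return (self.latency_jitter_sd
                * self.latency_mean(power) / self.latency_at_threshold)


def photocurrent_at(distance: float, compartment: str, power: float,
                    model: OpsinModel) -> float:
    """Photocurrent (pA) when the TF spot sits ``distance`` µm from the soma
    along the given compartment. Somatic stimulation at distance 0 returns the
    full Hill-curve amplitude."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if power < 0:
        raise ValueError("power must be non-negative")
    lam = model.length_constant(compartment)
    return model.somatic_current(power) * math.exp(-distance / lam)


def photocurrent_profile(distances: np.ndarray, compartment: str, power: float,
                         model: OpsinModel) -> np.ndarray:
    """Vectorised ``photocurrent_at`` over an array of distances."""
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    lam = model.length_constant(compartment)
    return model.somatic_current(power) * np.exp(-d / lam)
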