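"""Spatial-profile and resolution statistics.

Distance profiles (photocurrent versus spot distance along a dendrite or
axon) are fit with a single exponential ``I(x) = A·exp(−x/λ) + C``; two
groups of profiles are compared by an extra-sum-of-squares F-test (one shared
curve for the pooled points versus separate curves per group). Resolution
curves (spike probability versus lateral/axial spot offset, 10 trials per
offset) are summarised by their full width at half maximum, found by linear
interpolation between sampled offsets. Mann-Whitney rank-sum comparisons and
power-density arithmetic complete the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as _optimize
from scipy import stats as _stats


@dataclass
class DistanceProfile:
    """Photocurrent magnitudes measured along one process."""

    distances: np.ndarray   # µm, strictly increasing from 0
    currents: np.ndarray    # pA magnitudes
    cell_id: int = 0
    compartment: str = "dendrite"

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if len(self.distances) != len(self.currents):
            raise ValueError("distances and currents must align")
        if len(self.distances) and (np.any(np.diff(self.distances) <= 0)
                                    or self.distances[0] != 0):
            raise ValueError("distances must strictly increase from 0")
        if np.any(self.currents < 0):
            raise ValueError("currents must be magnitudes (>= 0)")


@dataclass
class ExponentialFit:
    amplitude: float
    length_constant: float
    offset: float
    rss: float
    n_points: int
    converged: bool
    fixed_offset: bool = False
    degenerate: bool = False


@dataclass
class ResolutionCurve:
    """Spike probability versus spot offset along one axis."""

    axis: str                # "lateral" or "axial"
    offsets: np.ndarray      # µm, includes 0
    spike_probability: np.ndarray
    n_trials: int = 10

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.spike_probability = np.asarray(self.spike_probability, dtype=float)
        if len(self.offsets) != len(self.spike_probability):
            raise ValueError("offsets and probabilities must align")
        if np.any((self.spike_probability < 0) | (self.spike_probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        if 0.0 not in self.offsets:
            raise ValueError("curve must include offset 0")


# ------------------------------------------------------------------- fitting

def _exp_model(x: np.ndarray, a: float, lam: float, c: float) -> np.ndarray:
    return a * np.exp(-x / lam) + c


def fit_exponential(distances, currents, fix_offset: bool = False
                    ) -> ExponentialFit:
    """Least-squares exponential fit with multi-start initialisation.

    Starts λ at several fractions of the x-span and keeps the lowest-RSS
    solution. A flat profile is flagged degenerate (λ unidentifiable).
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(currents, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 points for an exponential fit")
    if np.ptp(y) == 0:
        return ExponentialFit(0.0, float("nan"), float(y[0]), 0.0, len(x),
                              converged=False, fixed_offset=fix_offset,
                              degenerate=True)
    span = max(np.ptp(x), 1e-9)
    amp0 = float(y[np.argmin(x)] - y.min())
    c0 = 0.0 if fix_offset else float(y.min())
    best: Optional[tuple[float, np.ndarray]] = None
    for lam0 in (span / 10.0, span / 3.0, span):
        try:
            if fix_offset:
                popt, _ = _optimize.curve_fit(
                    lambda xx, a, lam: _exp_model(xx, a, lam, 0.0),
                    x, y, p0=[max(amp0, 1e-6), lam0],
                    bounds=([-np.inf, 1e-9], [np.inf, np.inf]), maxfev=10_000)
                params = np.array([popt[0], popt[1], 0.0])
            else:
                popt, _ = _optimize.curve_fit(
                    _exp_model, x, y, p0=[max(amp0, 1e-6), lam0, c0],
                    bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                    maxfev=10_000)
                params = np.asarray(popt)
        except RuntimeError:
            continue
        rss = float(np.sum((y - _exp_model(x, *params)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, params)
    if best is None:
        return ExponentialFit(float("nan"), float("nan"), float("nan"),
                              float("nan"), len(x), converged=False,
                              fixed_offset=fix_offset)
    rss, (a, lam, c) = best
    return ExponentialFit(float(a), float(lam), float(c), rss, len(x),
                          converged=True, fixed_offset=fix_offset)


def fit_profile(profile: DistanceProfile, fix_offset: bool = False
                ) -> ExponentialFit:
    return fit_exponential(profile.distances, profile.currents, fix_offset)


def _pool(profiles: Sequence[DistanceProfile]) -> tuple[np.ndarray, np.ndarray]:
    x = np.concatenate([p.distances for p in profiles])
    y = np.concatenate([p.currents for p in profiles])
    return x, y


def compare_fits_ftest(profiles_a: Sequence[DistanceProfile],
                       profiles_b: Sequence[DistanceProfile],
                       fix_offset: bool = False) -> tuple[float, float]:
    """Extra-sum-of-squares F-test: one shared exponential vs per-group fits.

    Null model fits a single curve to the pooled points of both groups;
    alternative fits each group separately.
    F = ((RSS_shared − RSS_sep)/Δdf) / (RSS_sep/df_sep) with Δdf = k (number
    of curve parameters) and df_sep = n_total − 2k. Returns (F, p).
    """
    xa, ya = _pool(profiles_a)
    xb, yb = _pool(profiles_b)
    k = 2 if fix_offset else 3
    n = len(xa) + len(xb)
    df_sep = n - 2 * k
    if df_sep <= 0:
        raise ValueError("not enough points for separate fits")
    shared = fit_exponential(np.concatenate([xa, xb]),
                             np.concatenate([ya, yb]), fix_offset)
    fa = fit_exponential(xa, ya, fix_offset)
    fb = fit_exponential(xb, yb, fix_offset)
    if not (shared.converged and fa.converged and fb.converged):
        raise RuntimeError("one of the exponential fits failed to converge")
    rss_sep = fa.rss + fb.rss
    rss_shared = shared.rss
    if rss_sep <= 0:
        return float("inf") if rss_shared > rss_sep else 0.0, 0.0
    f_stat = max(0.0, (rss_shared - rss_sep) / k) / (rss_sep / df_sep)
    p = float(_stats.f.sf(f_stat, k, df_sep))
    return float(f_stat), p


# ---------------------------------------------------------------------- fwhm

def compute_fwhm(offsets, values) -> float:
    """Full width at half maximum by linear interpolation of a sampled curve.

    The maximum must be interior and the curve must fall below half maximum
    on both sides of it; otherwise a ValueError identifies the failing side.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    pk = int(np.argmax(y))
    half = y[pk] / 2.0

    def crossing(side: str) -> float:
        idx = range(pk, 0, -1) if side == "left" else range(pk, len(x) - 1)
        for i in idx:
            j = i - 1 if side == "left" else i + 1
            if y[j] < half <= y[i]:
                return float(x[j] + (x[i] - x[j]) * (half - y[j]) / (y[i] - y[j]))
        raise ValueError(f"curve never falls below half maximum on the {side} side")

    left = crossing("left")
    right = crossing("right")
    return float(right - left)


def fwhm_of_curve(curve: ResolutionCurve) -> float:
    return compute_fwhm(curve.offsets, curve.spike_probability)


# ------------------------------------------------------------------- scalars

def power_density(power_mw: float, spot_diameter_um: float = 10.0) -> float:
    """Incident power density (mW/µm²) of a flat disc of given diameter."""
    if power_mw <= 0 or spot_diameter_um <= 0:
        raise ValueError("power and spot diameter must be positive")
    return power_mw / (np.pi * (spot_diameter_um / 2.0) ** 2)


def fold_decline(distances, currents, distance: float) -> float:
    """I(0)/I(distance) with linear interpolation between sampled distances."""
    x = np.asarray(distances, dtype=float)
    y = np.asarray(currents, dtype=float)
    if distance < x.min() or distance > x.max() or 0.0 < x.min():
        raise ValueError("profile must cover both 0 and the query distance")
    i0 = float(np.interp(0.0, x, y))
    i_d = float(np.interp(distance, x, y))
    if i_d == 0:
        warnings.warn("current at query distance is 0: infinite fold decline")
        return float("inf")
    return i0 / i_d


def compare_groups_ranksum(values_a, values_b) -> tuple[float, float]:
    """Mann-Whitney U comparison of two independent groups.

    Exact enumeration when both groups have ≤ 8 values and no ties; otherwise
    the normal approximation with tie correction. Returns (U, two-sided p).
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) \
        else "asymptotic"
    res = _stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                              use_continuity=False)
    return float(res.statistic), float(min(1.0, res.pvalue))
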