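"""Circular density of clinical event times with bootstrap bands.

Event times (e.g. allograft reperfusion clock times) live on the 24-h
circle. The density estimate is a wrapped-Gaussian kernel: each event
contributes a Gaussian of SD h summed over wrap offsets of +/-24 h until the
added mass is negligible, and the result is normalized to integrate to 1
over one circle. Pointwise 95% confidence bands come from resampling events
with replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircularDensity",
    "circular_density",
    "bootstrap_bands",
    "peak_trough_ratio",
    "reference_bandwidth",
    "PeakTroughResult",
]

_CIRCLE = 24.0


@dataclass(frozen=True)
class CircularDensity:
    grid: np.ndarray  # hours on [0, 24)
    density: np.ndarray  # per-hour, integrates to 1 over the circle
    bandwidth: float  # hours
    n_events: int
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_boot: int = 0
    seed: int | None = None


def _wrapped_kde(grid: np.ndarray, events: np.ndarray, h: float) -> np.ndarray:
    # enough wrap offsets that the farthest neglected tail is < 1e-12
    k_max = int(np.ceil((8.0 * h + _CIRCLE) / _CIRCLE))
    offsets = np.arange(-k_max, k_max + 1) * _CIRCLE
    d = grid[:, None, None] - events[None, :, None] + offsets[None, None, :]
    dens = np.exp(-0.5 * (d / h) ** 2).sum(axis=(1, 2))
    dens /= events.size * h * np.sqrt(2 * np.pi)
    # renormalize on the periodic grid (rectangle rule is exact-in-spirit here)
    step = grid[1] - grid[0]
    dens /= dens.sum() * step
    return dens


def reference_bandwidth(events: np.ndarray) -> float:
    """Circular normal-reference bandwidth in hours.

    Uses the circular SD sqrt(-2 ln R) mapped to hours in Silverman's rule
    1.06 sigma n^(-1/5); falls back to 2 h when the sample is too uniform
    for a meaningful resultant.
    """
    ang = 2 * np.pi * np.asarray(events, float) / _CIRCLE
    R = np.abs(np.exp(1j * ang).mean())
    if R < 1e-3:
        sigma_h = _CIRCLE / np.sqrt(12.0)  # SD of a uniform circle, linearized
    else:
        sigma_h = np.sqrt(-2.0 * np.log(R)) * _CIRCLE / (2 * np.pi)
    h = 1.06 * sigma_h * len(events) ** (-0.2)
    return float(np.clip(h, 0.25, 6.0))


def circular_density(
    event_times,
    h: float | str = "auto",
    grid_step: float = 0.25,
) -> CircularDensity:
    """Wrapped-Gaussian kernel density of event clock times.

    Parameters
    ----------
    event_times
        Hours, reduced mod 24; at least 5 events.
    h
        Kernel SD in hours, or ``"auto"`` for the circular normal-reference
        rule.
    """
    ev = np.mod(np.asarray(list(event_times), float), _CIRCLE)
    if ev.size < 5:
        raise ValueError("need at least 5 events")
    if isinstance(h, str):
        if h != "auto":
            raise ValueError(f"unknown bandwidth {h!r}")
        h = reference_bandwidth(ev)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(0.0, _CIRCLE, grid_step)
    dens = _wrapped_kde(grid, ev, float(h))
    return CircularDensity(grid=grid, density=dens, bandwidth=float(h), n_events=ev.size)


def bootstrap_bands(
    event_times,
    h: float | str = "auto",
    n_boot: int = 1000,
    seed: int = 0,
    grid_step: float = 0.25,
) -> CircularDensity:
    """Density with pointwise 2.5/97.5 percentile bands from resampling
    events with replacement. Seeded and reproducible."""
    if n_boot < 100:
        warnings.warn("fewer than 100 bootstrap replicates gives unstable bands", stacklevel=2)
    base = circular_density(event_times, h=h, grid_step=grid_step)
    ev = np.mod(np.asarray(list(event_times), float), _CIRCLE)
    rng = np.random.default_rng(seed)
    reps = np.empty((n_boot, base.grid.size))
    for i in range(n_boot):
        sample = rng.choice(ev, size=ev.size, replace=True)
        reps[i] = _wrapped_kde(base.grid, sample, base.bandwidth)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return CircularDensity(
        grid=base.grid,
        density=base.density,
        bandwidth=base.bandwidth,
        n_events=ev.size,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class PeakTroughResult:
    ratio: float  # max(density) / min(density); inf flagged below
    peak_h: float
    trough_h: float
    infinite: bool
    ci_nonoverlap: bool | None  # ci_low at peak > ci_high at trough; None without bands


def peak_trough_ratio(d: CircularDensity) -> PeakTroughResult:
    """Peak-to-trough density ratio plus the band non-overlap criterion
    (lower CI at the peak exceeding the upper CI at the trough)."""
    i, j = int(np.argmax(d.density)), int(np.argmin(d.density))
    trough = d.density[j]
    infinite = trough < 1e-12
    ratio = float("inf") if infinite else float(d.density[i] / trough)
    nonoverlap = None
    if d.ci_low is not None and d.ci_high is not None:
        nonoverlap = bool(d.ci_low[i] > d.ci_high[j])
    return PeakTroughResult(
        ratio=ratio,
        peak_h=float(d.grid[i]),
        trough_h=float(d.grid[j]),
        infinite=infinite,
        ci_nonoverlap=nonoverlap,
    )


def relative_density(cases: CircularDensity, reference: CircularDensity) -> np.ndarray:
    """Case density divided by reference density on a shared grid — a
    relative-risk style view when both case and all-comer event times are in
    hand. Extension beyond the conditional-density default."""
    if cases.grid.size != reference.grid.size or not np.allclose(cases.grid, reference.grid):
        raise ValueError("densities must share a grid")
    return cases.density / reference.density
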