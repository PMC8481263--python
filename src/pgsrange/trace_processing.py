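"""From detector traces and event lists to per-bin counts.

Each recorded trace is decomposed into up to three exponentially
modified Gaussian (EMG) pulses; every fit is summarised by the triple
(area, mode, height) plus an adjusted R-squared.  Event filtering then
applies an outlier cut on the pooled adjusted-R-squared distribution
(mean - 7.5 sd), in-spill selection, a non-paralyzable dead-time
correction, and finally fixed-edge histogramming into 2048 bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .synthetic_data import SpillStructure, emg_pulse

__all__ = [
    "PulseFit",
    "fit_pulses",
    "r2_threshold_filter",
    "select_in_spill",
    "correct_dead_time",
    "correct_dead_time_rate",
    "histogram_events",
]

#: nominal dead-time operating regime; corrections above this warn
DEAD_TIME_WARN_LEVEL = 0.15


@dataclass
class PulseFit:
    """One fitted EMG pulse summarised as the reported triple."""

    area: float
    mode: float
    height: float
    r2_adjusted: float
    overflow: bool = False
    pileup: bool = False
    discarded: bool = False
    params: dict = field(default_factory=dict)  # natural (mu, sigma, tau)

    @property
    def accepted(self) -> bool:
        return not (self.overflow or self.pileup or self.discarded)


def _emg_sum(t, theta):
    y = np.zeros_like(t, dtype=float)
    for j in range(len(theta) // 3):
        area, mu, log_sigma = theta[3 * j], theta[3 * j + 1], theta[3 * j + 2]
        sigma = np.exp(log_sigma)
        y += emg_pulse(t, area, mu, sigma, 3.0 * sigma)
    return y


def fit_pulses(
    trace,
    max_peaks: int = 3,
    *,
    pileup_separation: float | None = None,
    clip_level: float | None = None,
    min_prominence: float | None = None,
) -> list[PulseFit]:
    """Least-squares EMG decomposition of one trace.

    Peak candidates come from a prominence-based search; at most
    ``max_peaks`` (largest first) are fitted jointly.  Overflow is
    flagged when the trace shows a clipped plateau (three or more
    consecutive samples at the maximum, or at ``clip_level`` when
    given); pile-up when fitted modes are closer than
    ``pileup_separation`` (default twice the fitted Gaussian width).
    Non-convergent fits are flagged discarded rather than raised.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    t = np.arange(trace.size, dtype=float)

    level = np.max(trace) if clip_level is None else clip_level
    at_top = trace >= level - 1e-9 * max(abs(level), 1.0)
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], at_top.view(np.int8), [0])))))
    overflow = bool(at_top.any() and np.max(runs[::2], initial=0) >= 3)

    if min_prominence is None:
        noise = np.median(np.abs(np.diff(trace))) / 0.6745 if trace.size > 1 else 0.0
        min_prominence = max(5.0 * noise, 1e-3 * np.ptp(trace), 1e-12)
    peaks, props = find_peaks(trace, prominence=min_prominence)
    if peaks.size == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:max_peaks]
    peaks = np.sort(peaks[order])

    theta0 = []
    for p in peaks:
        height = trace[p]
        sigma0 = max(trace.size / 50.0, 2.0)
        area0 = max(height, 1e-9) * sigma0 * 3.0
        theta0 += [area0, float(p), np.log(sigma0)]
    discarded = False
    try:
        sol = least_squares(
            lambda th: _emg_sum(t, th) - trace, theta0, method="lm", max_nfev=4000
        )
        theta = sol.x
        discarded = not sol.success
    except Exception:
        theta = np.asarray(theta0, dtype=float)
        discarded = True

    model = _emg_sum(t, theta)
    ssr = float(np.sum((trace - model) ** 2))
    sst = float(np.sum((trace - trace.mean()) ** 2))
    n, p = trace.size, theta.size
    r2 = 1.0 - ssr / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else r2

    fits: list[PulseFit] = []
    sigmas, modes = [], []
    for j in range(len(theta) // 3):
        area, mu, log_sigma = theta[3 * j], theta[3 * j + 1], theta[3 * j + 2]
        sigma = float(np.exp(log_sigma))
        tau = 3.0 * sigma
        window = np.linspace(mu - 4 * sigma, mu + 4 * sigma + 8 * tau, 2001)
        shape = emg_pulse(window, area, mu, sigma, tau)
        i = int(np.argmax(shape))
        modes.append(float(window[i]))
        sigmas.append(sigma)
        fits.append(
            PulseFit(
                area=float(area),
                mode=float(window[i]),
                height=float(shape[i]),
                r2_adjusted=float(r2_adj),
                overflow=overflow,
                discarded=discarded or area <= 0,
                params={"mu": float(mu), "sigma": sigma, "tau": tau},
            )
        )
    if len(fits) >= 2:
        sep = pileup_separation if pileup_separation is not None else 2.0 * max(sigmas)
        if np.min(np.diff(np.sort(modes))) < sep:
            for f in fits:
                f.pileup = True
    return fits


def r2_threshold_filter(fits: list[PulseFit]) -> tuple[list[PulseFit], float]:
    """Outlier cut on the pooled adjusted-R-squared distribution.

    The threshold is mean - 7.5 sd over all finite values (pooled per
    run, not per trace); fits at or above it are accepted.  With an
    all-identical sample the sd is zero, the threshold equals the mean
    and everything passes.
    """
    values = np.array([f.r2_adjusted for f in fits], dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 2:
        raise ValueError("need at least 2 fits with finite adjusted R-squared")
    threshold = float(values[finite].mean() - 7.5 * values[finite].std())
    accepted = [f for f, v, ok in zip(fits, values, finite) if ok and v >= threshold]
    return accepted, threshold


def select_in_spill(events, spill_structure: SpillStructure | list, time_column: str = "time_s"):
    """Keep only events whose timestamp falls inside a spill interval."""
    intervals = (
        spill_structure.intervals()
        if isinstance(spill_structure, SpillStructure)
        else list(spill_structure)
    )
    if not intervals:
        raise ValueError("no spill intervals declared")
    times = np.asarray(events[time_column], dtype=float)
    keep = np.zeros(times.size, dtype=bool)
    for start, end in intervals:
        keep |= (times >= start) & (times < end)
    return events[keep]


def correct_dead_time(observed_counts, dead_time_fraction: float):
    """Non-paralyzable dead-time correction as live-time scaling.

    corrected = observed / (1 - DT) with DT the measured dead-time
    fraction; monotone in both arguments.  DT above the 15% operating
    regime triggers a warning, DT >= 1 is an error.
    """
    dt = float(dead_time_fraction)
    if not 0.0 <= dt < 1.0:
        raise ValueError("dead_time_fraction must be in [0, 1)")
    if dt > DEAD_TIME_WARN_LEVEL:
        warnings.warn(
            f"dead-time fraction {dt:.2f} above the {DEAD_TIME_WARN_LEVEL:.0%} regime",
            stacklevel=2,
        )
    return np.asarray(observed_counts, dtype=float) / (1.0 - dt)


def correct_dead_time_rate(observed_rate, tau_s: float):
    """Rate-form non-paralyzable correction m = n / (1 - n*tau).

    For use when an event rate and a per-event dead time are available
    instead of a measured dead-time fraction.
    """
    n = np.asarray(observed_rate, dtype=float)
    if tau_s < 0:
        raise ValueError("dead time per event must be >= 0")
    loss = n * tau_s
    if np.any(loss >= 1.0):
        raise ValueError("observed rate implies dead-time fraction >= 1")
    return n / (1.0 - loss)


def histogram_events(values, bin_edges) -> np.ndarray:
    """Histogram with half-open [low, high) bins, last bin closed.

    Values exactly on an interior edge go to the right-hand bin (the
    numpy convention); the returned counts plus out-of-range events
    conserve the input total.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return counts.astype(float)
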