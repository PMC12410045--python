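"""PSTH construction and onset-latency estimation.

The estimator works on a trial-averaged PSTH smoothed with a 5-ms square
filter: it selects the first post-onset local maximum exceeding the
spontaneous mean plus seven spontaneous standard deviations (with a small
prominence requirement), walks back to the preceding qualifying local
minimum, fits a quadratic to the smoothed rates between the two, finds the
time at which the quadratic reaches 25% of the peak rate, and shifts the
result by +1.5 ms to undo the smearing of the centered smoothing filter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal

from .simulate import UnitRecording, TRIAL_WINDOW_MS

__all__ = ["Psth", "LatencyEstimate", "compute_psth", "smooth", "estimate_onset"]

SMOOTH_WIDTH_MS = 5.0
THRESHOLD_N_SD = 7.0
PROMINENCE_FRAC_SD = 0.05
CROSSING_FRAC = 0.25
SMOOTH_SHIFT_MS = 1.5
#: stand-in spontaneous SD (spikes/s) when the baseline is exactly constant
DEGENERATE_SD_EPS = 0.1


@dataclass(frozen=True)
class Psth:
    """Binned, trial-averaged firing rate over [-100, +300) ms."""

    bin_width_ms: float
    bin_starts_ms: np.ndarray
    rate: np.ndarray  # spikes/s
    n_trials: int
    smoothed: bool = False
    spont_mean: float = 0.0
    spont_sd: float = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rate) < 0):
            raise ValueError("rates must be non-negative")

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return self.bin_starts_ms + self.bin_width_ms / 2.0


@dataclass(frozen=True)
class LatencyEstimate:
    onset_ms: Optional[float]
    peak_time_ms: Optional[float]
    peak_rate: Optional[float]
    threshold_used: float
    flags: tuple[str, ...] = ()


def _spont_stats(rate: np.ndarray, starts: np.ndarray) -> tuple[float, float]:
    pre = rate[(starts >= -100.0) & (starts < 0.0)]
    if pre.size == 0:
        return 0.0, 0.0
    return float(pre.mean()), float(pre.std(ddof=0))


def compute_psth(rec: UnitRecording, bin_width_ms: float = 1.0) -> Psth:
    """Trial-averaged PSTH in spikes/s on the [-100, +300) ms window."""
    if rec.n_trials < 1:
        raise ValueError("recording has no trials")
    lo, hi = TRIAL_WINDOW_MS
    edges = np.arange(lo, hi + bin_width_ms / 2, bin_width_ms)
    counts = np.zeros(edges.size - 1)
    for tr in rec.trials:
        c, _ = np.histogram(tr.spike_ms, bins=edges)
        counts += c
    rate = counts / rec.n_trials / (bin_width_ms / 1000.0)
    starts = edges[:-1]
    m, s = _spont_stats(rate, starts)
    return Psth(
        bin_width_ms=bin_width_ms,
        bin_starts_ms=starts,
        rate=rate,
        n_trials=rec.n_trials,
        smoothed=False,
        spont_mean=m,
        spont_sd=s,
    )


def smooth(psth: Psth, width_ms: float = SMOOTH_WIDTH_MS) -> Psth:
    """Centered square-filter smoothing; edge windows truncate and renormalize."""
    w = max(int(round(width_ms / psth.bin_width_ms)), 1)
    kernel = np.ones(w)
    num = np.convolve(psth.rate, kernel, mode="same")
    den = np.convolve(np.ones_like(psth.rate), kernel, mode="same")
    sm = num / den
    m, s = _spont_stats(sm, psth.bin_starts_ms)
    return replace(psth, rate=sm, smoothed=True, spont_mean=m, spont_sd=s)


def _local_extrema(x: np.ndarray, minima: bool = False):
    """Indices and prominences of local extrema; plateaus take the first bin."""
    y = -x if minima else x
    idx, props = signal.find_peaks(y, prominence=0.0, plateau_size=(1, None))
    left = props.get("left_edges", idx)
    return np.asarray(left, dtype=int), props["prominences"]


def _quadratic_crossing(
    coeffs: np.ndarray, target: float, t_lo: float, t_hi: float
) -> Optional[float]:
    """Earliest t in [t_lo, t_hi] where the quadratic equals ``target``."""
    a, b, c = coeffs
    roots = np.roots([a, b, c - target])
    real = sorted(r.real for r in roots if abs(r.imag) < 1e-9)
    for r in real:
        if t_lo - 1e-9 <= r <= t_hi + 1e-9:
            return float(min(max(r, t_lo), t_hi))
    return None


def estimate_onset(psth: Psth) -> LatencyEstimate:
    """Onset latency from a smoothed PSTH; never raises on pathological input."""
    if not psth.smoothed:
        psth = smooth(psth)
    flags: list[str] = []
    sd = psth.spont_sd
    if sd == 0.0:
        sd = DEGENERATE_SD_EPS
        flags.append("degenerate-baseline")
    threshold = psth.spont_mean + THRESHOLD_N_SD * sd
    prom_min = PROMINENCE_FRAC_SD * sd

    t = psth.bin_centers_ms
    rate = psth.rate
    post = t > 0
    max_idx, max_prom = _local_extrema(rate)
    peak_i = None
    for i, p in zip(max_idx, max_prom):
        if not post[i]:
            continue
        if rate[i] > threshold and p > prom_min:
            peak_i = int(i)
            break
        if rate[i] > threshold and p <= prom_min:
            flags.append("low-prominence")
    if peak_i is None:
        flags.append("no-peak")
        return LatencyEstimate(
            onset_ms=None,
            peak_time_ms=None,
            peak_rate=None,
            threshold_used=threshold,
            flags=tuple(dict.fromkeys(flags)),
        )
    peak_rate = float(rate[peak_i])
    peak_time = float(t[peak_i])

    min_idx, min_prom = _local_extrema(rate, minima=True)
    qualifying = [
        int(i) for i, p in zip(min_idx, min_prom) if i < peak_i and p > prom_min
    ]
    if qualifying:
        min_i = max(qualifying)
    else:
        # no qualifying local minimum: take the lowest post-onset bin
        # before the peak (the onset cannot precede the stimulus)
        first_post = int(np.argmax(post))
        lo_i = min(first_post, peak_i - 1) if peak_i > 0 else 0
        min_i = lo_i + int(np.argmin(rate[lo_i:peak_i])) if peak_i > lo_i else lo_i
        flags.append("fallback-to-min")

    t_lo, t_hi = float(t[min_i]), peak_time
    seg = slice(min_i, peak_i + 1)
    if peak_i - min_i + 1 >= 3:
        coeffs = np.polyfit(t[seg], rate[seg], 2)
    else:
        # too few bins for a quadratic: fall back to a line
        coeffs = np.concatenate([[0.0], np.polyfit(t[seg], rate[seg], 1)])
        flags.append("short-segment")

    onset = _quadratic_crossing(coeffs, CROSSING_FRAC * peak_rate, t_lo, t_hi)
    if onset is None:
        # high-baseline fallback: 25% of the rise above the spontaneous mean
        target = psth.spont_mean + CROSSING_FRAC * (peak_rate - psth.spont_mean)
        onset = _quadratic_crossing(coeffs, target, t_lo, t_hi)
        flags.append("fallback-threshold")
    if onset is None:
        onset = t_lo
        flags.append("fallback-to-min")
    onset += SMOOTH_SHIFT_MS
    return LatencyEstimate(
        onset_ms=float(onset),
        peak_time_ms=peak_time,
        peak_rate=peak_rate,
        threshold_used=threshold,
        flags=tuple(dict.fromkeys(flags)),
    )
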