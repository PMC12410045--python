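"""Frequency-response areas and best-frequency extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import UnitRecording

__all__ = ["Fra", "compute_fra", "best_frequency"]

RESPONSE_WINDOW_MS = (0.0, 100.0)
N_LOUD_LEVELS = 3


@dataclass(frozen=True)
class Fra:
    """Mean spike count per tone in [0, 100) ms, frequencies x levels.

    Levels are dB attenuation (0 = loudest); rows follow ``frequencies_hz``
    ascending, columns ``levels_db`` ascending.
    """

    unit_id: str
    frequencies_hz: np.ndarray
    levels_db: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        if r.shape != (len(self.frequencies_hz), len(self.levels_db)):
            raise ValueError("response matrix shape mismatch")
        if np.any(r < 0):
            raise ValueError("response entries must be non-negative")


def compute_fra(rec: UnitRecording) -> Fra:
    """Mean [0, 100) ms spike count per (frequency, level) cell."""
    if rec.protocol.name != "fra":
        raise ValueError(f"expected an fra recording, got {rec.protocol.name!r}")
    freqs = np.array(rec.protocol.frequencies())
    levels = np.array(sorted({tr.level_db_attn for tr in rec.trials}))
    t0, t1 = RESPONSE_WINDOW_MS
    sums = np.zeros((freqs.size, levels.size))
    n = np.zeros((freqs.size, levels.size))
    fi = {f: i for i, f in enumerate(freqs)}
    li = {l: j for j, l in enumerate(levels)}
    for tr in rec.trials:
        if tr.frequency_hz is None:
            continue
        i, j = fi[tr.frequency_hz], li[tr.level_db_attn]
        sums[i, j] += np.count_nonzero((tr.spike_ms >= t0) & (tr.spike_ms < t1))
        n[i, j] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, sums / np.maximum(n, 1), 0.0)
    return Fra(
        unit_id=rec.unit_id, frequencies_hz=freqs, levels_db=levels, response=mean
    )


def best_frequency(fra: Fra, n_levels: int = N_LOUD_LEVELS) -> float:
    """Frequency with the largest summed response over the loudest levels.

    "Loudest" means the numerically smallest attenuations.  Ties break
    toward the lowest frequency (argmax takes the first index).
    """
    if len(fra.levels_db) < n_levels:
        raise ValueError(
            f"need at least {n_levels} attenuation levels, got {len(fra.levels_db)}"
        )
    loud = np.argsort(fra.levels_db)[:n_levels]
    summed = fra.response[:, loud].sum(axis=1)
    return float(fra.frequencies_hz[int(np.argmax(summed))])
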