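"""Construction of the nine stimulation protocols as reproducible event logs.

Protocols are pure event sequences (onset time, frequency, attenuation,
duration); no audio is synthesized.  Presentation order is a seeded uniform
permutation of a fixed count multiset, so per-frequency counts are exact and
only the order is random.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ToneEvent",
    "ToneProtocol",
    "FREQ_MIN_HZ",
    "FREQ_MAX_HZ",
    "FREQ_RATIO",
    "build_oddball",
    "build_rare",
    "build_equal",
    "build_diverse_broad",
    "build_diverse_narrow",
    "build_fra",
    "build_bbn",
    "PROTOCOL_NAMES",
]

FREQ_MIN_HZ = 1000.0
FREQ_MAX_HZ = 64000.0
#: test-frequency separation f2/f1
FREQ_RATIO = 1.44

PURE_TONE_N_EVENTS = 500
PURE_TONE_ISI_MS = 300.0
PURE_TONE_DUR_MS = 30.0

PROTOCOL_NAMES = (
    "bbn",
    "fra",
    "oddball_f1std",
    "oddball_f2std",
    "rare_f1",
    "rare_f2",
    "equal",
    "diverse_broad",
    "diverse_narrow",
)


class InfeasibleDesignError(ValueError):
    """Raised when no frequency ladder fits inside the allowed range."""


@dataclass(frozen=True)
class ToneEvent:
    """A single stimulus slot.

    ``frequency_hz`` is ``None`` for silence slots (rare condition) and for
    broadband-noise tokens (bbn protocol).
    """

    onset_ms: float
    frequency_hz: Optional[float]
    level_db_attn: float = 0.0
    duration_ms: float = PURE_TONE_DUR_MS


@dataclass(frozen=True)
class ToneProtocol:
    name: str
    events: tuple[ToneEvent, ...]
    f1_hz: Optional[float]
    f2_hz: Optional[float]
    isi_ms: float
    seed: int
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol name {self.name!r}")
        onsets = [e.onset_ms for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.events)

    def frequencies(self) -> list[float]:
        """Distinct tone frequencies in ascending order (silence excluded)."""
        return sorted({e.frequency_hz for e in self.events if e.frequency_hz is not None})

    def frequency_counts(self) -> dict[Optional[float], int]:
        counts: dict[Optional[float], int] = {}
        for e in self.events:
            counts[e.frequency_hz] = counts.get(e.frequency_hz, 0) + 1
        return counts

    def tone_probability_map(self) -> dict[float, float]:
        """Per-frequency presentation probability relative to all slots."""
        n = self.n_events
        return {
            f: c / n
            for f, c in self.frequency_counts().items()
            if f is not None
        }


def _check_freq(f_hz: float) -> None:
    if not (FREQ_MIN_HZ <= f_hz <= FREQ_MAX_HZ):
        raise ValueError(
            f"frequency {f_hz} Hz outside allowed range "
            f"[{FREQ_MIN_HZ:g}, {FREQ_MAX_HZ:g}] Hz"
        )


def _check_pair(f1_hz: float, f2_hz: float) -> None:
    _check_freq(f1_hz)
    _check_freq(f2_hz)
    if not math.isclose(f2_hz / f1_hz, FREQ_RATIO, rel_tol=1e-9):
        raise ValueError(
            f"f2/f1 must equal {FREQ_RATIO} (got {f2_hz / f1_hz:.6f})"
        )


def _tone_sequence(
    name: str,
    labels: Sequence[Optional[float]],
    f1_hz: Optional[float],
    f2_hz: Optional[float],
    seed: int,
    level_db_attn: float = 0.0,
    metadata: Optional[dict] = None,
) -> ToneProtocol:
    """Shuffle a fixed multiset of frequency labels into a 500-slot sequence."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    events = tuple(
        ToneEvent(
            onset_ms=i * PURE_TONE_ISI_MS,
            frequency_hz=labels[j],
            level_db_attn=level_db_attn,
            duration_ms=PURE_TONE_DUR_MS,
        )
        for i, j in enumerate(order)
    )
    return ToneProtocol(
        name=name,
        events=events,
        f1_hz=f1_hz,
        f2_hz=f2_hz,
        isi_ms=PURE_TONE_ISI_MS,
        seed=seed,
        metadata=metadata or {},
    )


def build_oddball(
    f1_hz: float,
    f2_hz: float,
    standard_is_f1: bool = True,
    seed: int = 0,
    level_db_attn: float = 0.0,
) -> ToneProtocol:
    """475 standard / 25 deviant presentations in pseudorandom order."""
    _check_pair(f1_hz, f2_hz)
    std, dev = (f1_hz, f2_hz) if standard_is_f1 else (f2_hz, f1_hz)
    labels = [std] * 475 + [dev] * 25
    name = "oddball_f1std" if standard_is_f1 else "oddball_f2std"
    return _tone_sequence(
        name, labels, f1_hz, f2_hz, seed, level_db_attn,
        metadata={"standard_hz": std, "deviant_hz": dev},
    )


def build_rare(
    f_hz: float,
    seed: int = 0,
    which: str = "f1",
    level_db_attn: float = 0.0,
) -> ToneProtocol:
    """25 tones embedded in 475 explicit silence slots (500 slots total)."""
    _check_freq(f_hz)
    if which not in ("f1", "f2"):
        raise ValueError("which must be 'f1' or 'f2'")
    labels: list[Optional[float]] = [f_hz] * 25 + [None] * 475
    f1 = f_hz if which == "f1" else None
    f2 = f_hz if which == "f2" else None
    return _tone_sequence(f"rare_{which}", labels, f1, f2, seed, level_db_attn)


def build_equal(
    f1_hz: float, f2_hz: float, seed: int = 0, level_db_attn: float = 0.0
) -> ToneProtocol:
    """250 presentations of each test frequency."""
    _check_pair(f1_hz, f2_hz)
    labels = [f1_hz] * 250 + [f2_hz] * 250
    return _tone_sequence("equal", labels, f1_hz, f2_hz, seed, level_db_attn)


def _broad_ladder(f1_hz: float) -> tuple[list[float], int]:
    """12-rung ladder at ratio 1.44 with f1/f2 at rungs 6 and 7 (1-based),
    shifted by whole rungs when needed to stay inside [1, 64] kHz.

    Returns (ladder, index of f1 within it).  Smallest shift wins, downward
    on ties.
    """
    for shift in (0, -1, 1, -2, 2, -3, 3, -4, 4, -5, 5):
        i1 = 5 - shift
        if not 0 <= i1 <= 10:
            continue
        ladder = [f1_hz * FREQ_RATIO ** (k - i1) for k in range(12)]
        # tolerate rounding at the range edges
        if ladder[0] >= FREQ_MIN_HZ * (1 - 1e-9) and ladder[-1] <= FREQ_MAX_HZ * (1 + 1e-9):
            return ladder, i1
    raise InfeasibleDesignError(
        f"no 12-rung ladder at ratio {FREQ_RATIO} around f1={f1_hz} Hz fits "
        f"inside [{FREQ_MIN_HZ:g}, {FREQ_MAX_HZ:g}] Hz"
    )


def feasible_broad_f1(f1_hz: float) -> float:
    """Nearest f1 for which a 12-rung 1.44-ladder containing f1/f2 fits 1-64 kHz.

    With 12 rungs spanning a factor of 1.44**11 ~ 55.4 against an allowed
    range of 64, f1 must fall within one of eleven narrow bands
    [1000, 64000/1.44**11] * 1.44**j; an arbitrary f1 usually does not.
    This helper snaps f1 (in log frequency) into the nearest band, mirroring
    the practice of using shared test frequencies that need not coincide
    with a unit's best frequency.
    """
    band_hi = FREQ_MAX_HZ / FREQ_RATIO**11  # ~1155.98 Hz
    best = None
    for j in range(11):
        lo = FREQ_MIN_HZ * FREQ_RATIO**j
        hi = band_hi * FREQ_RATIO**j
        snapped = min(max(f1_hz, lo), hi)
        d = abs(math.log(snapped / f1_hz))
        if best is None or d < best[0]:
            best = (d, snapped)
    return best[1]


def build_diverse_broad(
    f1_hz: float, f2_hz: float, seed: int = 0, level_db_attn: float = 0.0
) -> ToneProtocol:
    """f1/f2 25 times each plus 10 filler frequencies 45 times each.

    Fillers extend the f1-f2 ladder at the same 1.44 ratio; f1 and f2 sit in
    the middle of the 12-frequency ladder unless that would leave the
    1-64 kHz range, in which case the ladder is shifted by whole rungs.
    """
    _check_pair(f1_hz, f2_hz)
    ladder, i1 = _broad_ladder(f1_hz)
    ladder[i1] = f1_hz
    ladder[i1 + 1] = f2_hz
    labels: list[Optional[float]] = []
    for k, f in enumerate(ladder):
        labels += [f] * (25 if k in (i1, i1 + 1) else 45)
    assert len(labels) == PURE_TONE_N_EVENTS
    return _tone_sequence(
        "diverse_broad", labels, f1_hz, f2_hz, seed, level_db_attn,
        metadata={"ladder_hz": ladder},
    )


def build_diverse_narrow(
    f1_hz: float, f2_hz: float, seed: int = 0, level_db_attn: float = 0.0
) -> ToneProtocol:
    """20 log-spaced frequencies, 25 presentations each, spanning ~1 octave.

    The adjacent ratio r satisfies r**9 = 1.44 so that f1 is the 6th and f2
    the 15th frequency of the sequence.
    """
    _check_pair(f1_hz, f2_hz)
    r = FREQ_RATIO ** (1.0 / 9.0)
    freqs = [f1_hz * r ** (k - 5) for k in range(20)]
    if freqs[0] < FREQ_MIN_HZ * (1 - 1e-9) or freqs[-1] > FREQ_MAX_HZ * (1 + 1e-9):
        raise InfeasibleDesignError(
            f"diverse-narrow ladder around f1={f1_hz} Hz leaves the "
            f"[{FREQ_MIN_HZ:g}, {FREQ_MAX_HZ:g}] Hz range"
        )
    freqs[5] = f1_hz
    freqs[14] = f2_hz
    labels: list[Optional[float]] = [f for f in freqs for _ in range(25)]
    return _tone_sequence(
        "diverse_narrow", labels, f1_hz, f2_hz, seed, level_db_attn,
        metadata={"ladder_hz": freqs},
    )


def build_fra(
    seed: int = 0,
    max_attn_db: float = 60.0,
) -> ToneProtocol:
    """Frequency-response-area protocol.

    37 frequencies at 6/octave from 1 to 64 kHz, 10 repeats each (370 bursts
    per attenuation level), ISI 500 ms, 50 ms bursts.  Levels run from 0 dB
    attenuation downward in 10 dB steps; the frequency order within each
    level block is an independent seeded shuffle.
    """
    if max_attn_db < 0 or max_attn_db % 10:
        raise ValueError("max_attn_db must be a non-negative multiple of 10")
    freqs = [FREQ_MIN_HZ * 2 ** (k / 6.0) for k in range(37)]
    levels = [10.0 * i for i in range(int(max_attn_db) // 10 + 1)]
    rng = np.random.default_rng(seed)
    events = []
    t = 0.0
    for level in levels:
        labels = np.repeat(freqs, 10)
        rng.shuffle(labels)
        for f in labels:
            events.append(
                ToneEvent(onset_ms=t, frequency_hz=float(f),
                          level_db_attn=level, duration_ms=50.0)
            )
            t += 500.0
    return ToneProtocol(
        name="fra",
        events=tuple(events),
        f1_hz=None,
        f2_hz=None,
        isi_ms=500.0,
        seed=seed,
        metadata={"frequencies_hz": freqs, "levels_db": levels},
    )


def build_bbn(seed: int = 0) -> ToneProtocol:
    """Broadband-noise protocol: 280 bursts, 7 levels x 40 repeats, ISI 500 ms.

    Noise tokens carry no frequency (``frequency_hz is None``).
    """
    levels = np.repeat([10.0 * i for i in range(7)], 40)
    rng = np.random.default_rng(seed)
    rng.shuffle(levels)
    events = tuple(
        ToneEvent(onset_ms=i * 500.0, frequency_hz=None,
                  level_db_attn=float(lv), duration_ms=200.0)
        for i, lv in enumerate(levels)
    )
    return ToneProtocol(
        name="bbn",
        events=events,
        f1_hz=None,
        f2_hz=None,
        isi_ms=500.0,
        seed=seed,
        metadata={"levels_db": [10.0 * i for i in range(7)]},
    )
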