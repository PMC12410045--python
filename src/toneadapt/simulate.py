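"""Ground-truth adapting model neurons and inhomogeneous-Poisson spike trains.

Each simulated unit carries Gaussian log-frequency tuning, a
resource-depletion adaptation channel with exponential recovery, a boxcar
evoked response with a controllable onset latency, spontaneous Poisson
firing, and an optional multiplicative deviance boost applied only to the
5%-probability tone of oddball protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .stimuli import (
    FREQ_RATIO,
    feasible_broad_f1,
    ToneProtocol,
    build_diverse_broad,
    build_diverse_narrow,
    build_equal,
    build_oddball,
    build_rare,
    build_bbn,
    build_fra,
)

__all__ = [
    "GroundTruthUnit",
    "UnitRecording",
    "Trial",
    "simulate_unit",
    "simulate_population",
    "build_protocol_set",
    "resource_trace",
    "TRIAL_WINDOW_MS",
]

#: per-trial spike window relative to event onset, half-open
TRIAL_WINDOW_MS = (-100.0, 300.0)


@dataclass(frozen=True)
class GroundTruthUnit:
    """Parameters of one simulated neuron.

    ``sigma_adapt`` and ``tau_adapt_ms`` are the adaptation-channel width
    (natural-log frequency units) and recovery time constant of the
    resource dynamics; ``dev_gain`` adds a deviance-sensitive response
    component on oddball deviants (0 = pure-adaptation unit).
    """

    unit_id: str
    bf_hz: float
    tuning_sigma: float
    a_rate: float
    spont_rate: float
    onset_ms: float
    resp_dur_ms: float
    sigma_adapt: float
    tau_adapt_ms: float
    dev_gain: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a_rate < 0:
            raise ValueError("a_rate must be >= 0")
        if self.spont_rate < 0:
            raise ValueError("spont_rate must be >= 0")
        if self.sigma_adapt <= 0:
            raise ValueError("sigma_adapt must be > 0")
        if self.tau_adapt_ms <= 0:
            raise ValueError("tau_adapt_ms must be > 0")
        if self.dev_gain < 0:
            raise ValueError("dev_gain must be >= 0")
        if self.tuning_sigma <= 0:
            raise ValueError("tuning_sigma must be > 0")


@dataclass(frozen=True)
class Trial:
    trial_index: int
    frequency_hz: Optional[float]
    level_db_attn: float
    spike_ms: np.ndarray  # sorted, within TRIAL_WINDOW_MS

    def __post_init__(self) -> None:
        s = np.asarray(self.spike_ms, dtype=float)
        object.__setattr__(self, "spike_ms", s)
        if s.size and (s.min() < TRIAL_WINDOW_MS[0] or s.max() >= TRIAL_WINDOW_MS[1]):
            raise ValueError("spike times outside the trial window")
        if np.any(np.diff(s) < 0):
            raise ValueError("spike times must be sorted")


@dataclass(frozen=True)
class UnitRecording:
    """Per-trial spike times of one unit on one protocol, onset-aligned."""

    unit_id: str
    protocol: ToneProtocol
    trials: tuple[Trial, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled_count(self, t0_ms: float, t1_ms: float) -> int:
        """Total spikes in [t0, t1) pooled over all trials."""
        return int(
            sum(
                np.count_nonzero((tr.spike_ms >= t0_ms) & (tr.spike_ms < t1_ms))
                for tr in self.trials
            )
        )

    def counts_per_trial(self, t0_ms: float, t1_ms: float) -> np.ndarray:
        return np.array(
            [
                np.count_nonzero((tr.spike_ms >= t0_ms) & (tr.spike_ms < t1_ms))
                for tr in self.trials
            ],
            dtype=int,
        )


def _depletion_kernel(channels: np.ndarray, f_hz: float, sigma: float) -> np.ndarray:
    """U(g, f) = exp(-(ln(f/g))^2 / (2 sigma^2)) for each channel center g."""
    z = np.log(f_hz / channels)
    return np.exp(-(z**2) / (2.0 * sigma**2))


def resource_trace(
    protocol: ToneProtocol, sigma_adapt: float, tau_adapt_ms: float
) -> dict[float, np.ndarray]:
    """Deterministic resource traces x_g per distinct stimulus frequency.

    Returns, for every distinct tone frequency g, the value of x_g at each
    event onset (before depletion by that event).  Per event the order is:
    respond with the current x, deplete the presented tone's channels, then
    recover exponentially until the next onset.  Silence slots cause
    recovery only.
    """
    freqs = np.array(protocol.frequencies(), dtype=float)
    if freqs.size == 0:
        return {}
    x = np.ones(freqs.size)
    out = np.empty((protocol.n_events, freqs.size))
    events = protocol.events
    for n, ev in enumerate(events):
        out[n] = x
        if ev.frequency_hz is not None:
            x = x * (1.0 - _depletion_kernel(freqs, ev.frequency_hz, sigma_adapt))
        if n + 1 < len(events):
            d = events[n + 1].onset_ms - ev.onset_ms
            x = 1.0 - (1.0 - x) * math.exp(-d / tau_adapt_ms)
    return {float(f): out[:, j] for j, f in enumerate(freqs)}


def _deviant_frequency(protocol: ToneProtocol) -> Optional[float]:
    if protocol.name in ("oddball_f1std", "oddball_f2std"):
        return protocol.metadata.get(
            "deviant_hz",
            protocol.f2_hz if protocol.name == "oddball_f1std" else protocol.f1_hz,
        )
    return None


def _evoked_rates(unit: GroundTruthUnit, protocol: ToneProtocol) -> np.ndarray:
    """Expected evoked rate (spikes/s) for every event of the protocol."""
    n = protocol.n_events
    rates = np.zeros(n)
    if protocol.name == "bbn":
        # broadband tokens drive the unit at its peak rate, untuned and
        # unadapted; they bypass the frequency channels entirely
        rates[:] = unit.a_rate
        return rates
    traces = resource_trace(protocol, unit.sigma_adapt, unit.tau_adapt_ms)
    dev_hz = _deviant_frequency(protocol)
    for i, ev in enumerate(protocol.events):
        g = ev.frequency_hz
        if g is None:
            continue
        tuning = math.exp(
            -(math.log(g / unit.bf_hz) ** 2) / (2.0 * unit.tuning_sigma**2)
        )
        r = unit.a_rate * tuning * traces[g][i]
        if dev_hz is not None and g == dev_hz:
            r *= 1.0 + unit.dev_gain
        rates[i] = r
    return rates


def _draw_segment(
    rng: np.random.Generator, rate_hz: float, t0: float, t1: float
) -> np.ndarray:
    """Homogeneous-Poisson spike times on [t0, t1) at rate_hz spikes/s."""
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    return rng.uniform(t0, t1, size=n)


def simulate_unit(
    unit: GroundTruthUnit, protocol: ToneProtocol, seed: Optional[int] = None
) -> UnitRecording:
    """Simulate one unit on one protocol.

    Each trial is an independent inhomogeneous-Poisson draw on
    [-100, 300) ms: spontaneous rate throughout, plus the adapted evoked
    rate on [onset, onset + resp_dur).  The evoked rate follows the
    deterministic resource trace of the protocol's event sequence.
    """
    rng = np.random.default_rng(unit.seed if seed is None else seed)
    rates = _evoked_rates(unit, protocol)
    lo, hi = TRIAL_WINDOW_MS
    trials = []
    for i, ev in enumerate(protocol.events):
        spikes = _draw_segment(rng, unit.spont_rate, lo, hi)
        resp0 = unit.onset_ms
        resp1 = min(unit.onset_ms + unit.resp_dur_ms, hi)
        if rates[i] > 0:
            spikes = np.concatenate(
                [spikes, _draw_segment(rng, rates[i], resp0, resp1)]
            )
        spikes.sort()
        trials.append(
            Trial(
                trial_index=i,
                frequency_hz=ev.frequency_hz,
                level_db_attn=ev.level_db_attn,
                spike_ms=spikes,
            )
        )
    return UnitRecording(unit_id=unit.unit_id, protocol=protocol, trials=tuple(trials))


def build_protocol_set(
    f1_hz: float,
    f2_hz: float,
    seed: int = 0,
    names: Sequence[str] = (
        "oddball_f1std",
        "oddball_f2std",
        "rare_f1",
        "rare_f2",
        "equal",
        "diverse_broad",
        "diverse_narrow",
    ),
    max_attn_db: float = 60.0,
) -> dict[str, ToneProtocol]:
    """Build the named protocols around a test-frequency pair.

    Each protocol gets an independent seed derived from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    subseeds = {n: int(s.generate_state(1)[0]) for n, s in zip(names, ss.spawn(len(names)))}
    builders = {
        "oddball_f1std": lambda s: build_oddball(f1_hz, f2_hz, True, s),
        "oddball_f2std": lambda s: build_oddball(f1_hz, f2_hz, False, s),
        "rare_f1": lambda s: build_rare(f1_hz, s, which="f1"),
        "rare_f2": lambda s: build_rare(f2_hz, s, which="f2"),
        "equal": lambda s: build_equal(f1_hz, f2_hz, s),
        "diverse_broad": lambda s: build_diverse_broad(f1_hz, f2_hz, s),
        "diverse_narrow": lambda s: build_diverse_narrow(f1_hz, f2_hz, s),
        "bbn": lambda s: build_bbn(s),
        "fra": lambda s: build_fra(s, max_attn_db=max_attn_db),
    }
    unknown = set(names) - set(builders)
    if unknown:
        raise ValueError(f"unknown protocol names: {sorted(unknown)}")
    return {n: builders[n](subseeds[n]) for n in names}


_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "bf_hz": (2000.0, 32000.0),  # log-uniform
    "tuning_sigma": (0.3, 0.8),
    "a_rate": (60.0, 150.0),
    "spont_rate": (1.0, 8.0),
    "onset_ms": (12.0, 30.0),
    "resp_dur_ms": (30.0, 40.0),
    "sigma_adapt": (0.2, 0.6),
    "tau_adapt_ms": (200.0, 600.0),
}


def draw_unit(
    rng: np.random.Generator,
    unit_id: str,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    dev_gain: float = 0.0,
    seed: int = 0,
) -> GroundTruthUnit:
    """Draw one unit's parameters uniformly (bf log-uniformly) from ranges."""
    r = dict(_DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    lo, hi = r["bf_hz"]
    bf = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    u = lambda k: float(rng.uniform(*r[k]))
    return GroundTruthUnit(
        unit_id=unit_id,
        bf_hz=bf,
        tuning_sigma=u("tuning_sigma"),
        a_rate=u("a_rate"),
        spont_rate=u("spont_rate"),
        onset_ms=u("onset_ms"),
        resp_dur_ms=u("resp_dur_ms"),
        sigma_adapt=u("sigma_adapt"),
        tau_adapt_ms=u("tau_adapt_ms"),
        dev_gain=dev_gain,
        seed=seed,
    )


def simulate_population(
    n_units: int,
    seed: int = 0,
    ranges: Optional[dict[str, tuple[float, float]]] = None,
    protocol_names: Sequence[str] = (
        "oddball_f1std",
        "oddball_f2std",
        "rare_f1",
        "rare_f2",
        "equal",
        "diverse_broad",
        "diverse_narrow",
    ),
    dev_gain: float = 0.0,
    unit_prefix: str = "unit",
) -> tuple[list[GroundTruthUnit], dict[str, dict[str, UnitRecording]]]:
    """Simulate ``n_units`` model neurons on a protocol set each.

    Test frequencies are centered on each unit's best frequency
    (f1 = bf / sqrt(1.44), f2 = bf * sqrt(1.44)).  Returns the ground-truth
    units and recordings[unit_id][protocol_name].
    """
    if n_units < 0:
        raise ValueError("n_units must be >= 0")
    if not protocol_names:
        raise ValueError("protocol set must not be empty")
    master = np.random.SeedSequence(seed)
    units: list[GroundTruthUnit] = []
    recordings: dict[str, dict[str, UnitRecording]] = {}
    for i, ss in enumerate(master.spawn(n_units)):
        s_params, s_prot, s_sim = ss.spawn(3)
        rng = np.random.default_rng(s_params)
        unit = draw_unit(
            rng,
            unit_id=f"{unit_prefix}{i:04d}",
            ranges=ranges,
            dev_gain=dev_gain,
            seed=int(s_sim.generate_state(1)[0]),
        )
        half = math.sqrt(FREQ_RATIO)
        f1 = unit.bf_hz / half
        if "diverse_broad" in protocol_names:
            # an arbitrary f1 rarely admits a 12-rung ladder inside 1-64 kHz;
            # snap to the nearest feasible test frequency (real test
            # frequencies were shared across units and often off-best-frequency)
            f1 = feasible_broad_f1(f1)
        f2 = f1 * FREQ_RATIO
        protos = build_protocol_set(
            f1, f2, seed=int(s_prot.generate_state(1)[0]), names=protocol_names
        )
        sim_seeds = np.random.SeedSequence(unit.seed).spawn(len(protos))
        recordings[unit.unit_id] = {
            name: simulate_unit(unit, proto, seed=int(s.generate_state(1)[0]))
            for (name, proto), s in zip(protos.items(), sim_seeds)
        }
        units.append(unit)
    return units, recordings
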