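"""SSA response tables, CSI/SI indices, and the narrow-channel adaptation model.

The adaptation model describes the expected steady-state response to a
frequency f0 embedded in a random tone sequence at fixed inter-stimulus
interval d.  A Gaussian-in-log-frequency channel centered on f0 is depleted
by each tone according to its spectral distance, U(f0, f) =
exp(-(ln(f/f0))^2 / (2 sigma^2)), and recovers exponentially with time
constant tau between presentations (per-interval persistence
delta = exp(-d/tau)).  With adaptation load u = sum_f p_f U(f0, f), the
normalized steady-state response is (1 - delta) / (1 - (1 - u) * delta),
the fixed point of the respond -> deplete -> recover recursion.  Model
parameters (sigma, delta) are fitted per unit to the rare-normalized mean
responses of the non-rare conditions by nonlinear least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .simulate import UnitRecording
from .responsiveness import ResponsivenessResult

__all__ = [
    "SsaResponseTable",
    "SsaIndices",
    "AnfcFit",
    "compute_response_table",
    "select_ssa_units",
    "select_anfc_units",
    "csi",
    "si",
    "anfc_expected",
    "adaptation_load",
    "fit_anfc",
    "loo_deviant_error",
]

RESPONSE_WINDOW_MS = (0.0, 40.0)
MIN_RARE_SPIKES = 5
CONDITIONS = ("standard", "deviant", "equal", "rare", "diverse_broad", "diverse_narrow")
FIT_CONDITIONS = ("standard", "deviant", "equal", "diverse_broad", "diverse_narrow")

SIGMA_BOUNDS = (0.01, 10.0)
DELTA_BOUNDS = (0.0, 0.9999)
SIGMA_STARTS = (0.18, 0.36, 1.0)
DELTA_STARTS = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class SsaResponseTable:
    """Mean [0, 40) ms spike counts per (test frequency x condition).

    ``raw[(freq, cond)]`` with freq in {"f1", "f2"} holds the mean count per
    presentation; ``normalized`` divides each by the same frequency's rare
    mean (None when the rare mean is zero or missing).  ``prob_maps[(freq,
    cond)]`` carries the presentation-probability map of the sequence the
    cell was measured in, keyed by tone frequency in Hz.
    """

    unit_id: str
    f1_hz: float
    f2_hz: float
    isi_ms: float
    raw: dict
    normalized: dict
    rare_total_spikes: dict  # pooled 40-ms counts per test frequency
    prob_maps: dict
    flags: tuple[str, ...] = ()
    ssa_selected: Optional[bool] = None
    anfc_selected: Optional[bool] = None

    def frequency_hz(self, which: str) -> float:
        return self.f1_hz if which == "f1" else self.f2_hz


@dataclass(frozen=True)
class SsaIndices:
    csi: Optional[float]
    si1: Optional[float]
    si2: Optional[float]


@dataclass(frozen=True)
class AnfcFit:
    unit_id: str
    sigma: float
    delta: float
    tau_ms: float
    predicted: dict  # (freq, cond) -> model prediction, normalized units
    sse_full: float
    observations: dict  # (freq, cond) -> normalized measurement used in the fit
    loo_predicted_deviant: Optional[dict] = None
    loo_error_normalized: Optional[float] = None
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# response tables


def _mean_count(rec: UnitRecording, freq_hz: float) -> tuple[Optional[float], int]:
    """(mean spike count in [0, 40) per presentation of freq, pooled total)."""
    t0, t1 = RESPONSE_WINDOW_MS
    counts = [
        np.count_nonzero((tr.spike_ms >= t0) & (tr.spike_ms < t1))
        for tr in rec.trials
        if tr.frequency_hz == freq_hz
    ]
    if not counts:
        return None, 0
    return float(np.mean(counts)), int(np.sum(counts))


_CONDITION_SOURCE = {
    # (freq, condition) -> protocol that carries it
    ("f1", "standard"): "oddball_f1std",
    ("f1", "deviant"): "oddball_f2std",
    ("f2", "standard"): "oddball_f2std",
    ("f2", "deviant"): "oddball_f1std",
    ("f1", "equal"): "equal",
    ("f2", "equal"): "equal",
    ("f1", "rare"): "rare_f1",
    ("f2", "rare"): "rare_f2",
    ("f1", "diverse_broad"): "diverse_broad",
    ("f2", "diverse_broad"): "diverse_broad",
    ("f1", "diverse_narrow"): "diverse_narrow",
    ("f2", "diverse_narrow"): "diverse_narrow",
}


def compute_response_table(
    recordings: Mapping[str, UnitRecording], unit_id: Optional[str] = None
) -> SsaResponseTable:
    """Build the per-unit response table from the seven tone-sequence recordings.

    ``recordings`` maps protocol name -> recording; missing protocols leave
    absent cells (logged in flags).  All present recordings must share f1,
    f2 and ISI.
    """
    flags: list[str] = []
    f1 = f2 = None
    isi = None
    uid = unit_id
    for name, rec in recordings.items():
        p = rec.protocol
        uid = uid or rec.unit_id
        if p.f1_hz is not None:
            if f1 is not None and not math.isclose(f1, p.f1_hz, rel_tol=1e-9):
                raise ValueError("recordings disagree on f1")
            f1 = p.f1_hz
        if p.f2_hz is not None:
            if f2 is not None and not math.isclose(f2, p.f2_hz, rel_tol=1e-9):
                raise ValueError("recordings disagree on f2")
            f2 = p.f2_hz
        if isi is not None and isi != p.isi_ms:
            raise ValueError("recordings disagree on ISI")
        isi = p.isi_ms
    if f1 is None or f2 is None:
        raise ValueError("test frequencies could not be determined")

    raw: dict = {}
    prob_maps: dict = {}
    rare_totals: dict = {}
    for (which, cond), proto_name in _CONDITION_SOURCE.items():
        rec = recordings.get(proto_name)
        if rec is None:
            raw[(which, cond)] = None
            flags.append(f"missing-{proto_name}")
            continue
        freq = f1 if which == "f1" else f2
        mean, total = _mean_count(rec, freq)
        raw[(which, cond)] = mean
        prob_maps[(which, cond)] = rec.protocol.tone_probability_map()
        if cond == "rare":
            rare_totals[which] = total
    normalized: dict = {}
    for which in ("f1", "f2"):
        rare = raw.get((which, "rare"))
        for cond in CONDITIONS:
            v = raw.get((which, cond))
            if v is None or rare is None or rare == 0:
                normalized[(which, cond)] = None
                if rare == 0 and v is not None:
                    flags.append(f"zero-rare-{which}")
            else:
                normalized[(which, cond)] = v / rare
    return SsaResponseTable(
        unit_id=uid or "unknown",
        f1_hz=f1,
        f2_hz=f2,
        isi_ms=isi,
        raw=raw,
        normalized=normalized,
        rare_total_spikes=rare_totals,
        prob_maps=prob_maps,
        flags=tuple(dict.fromkeys(flags)),
    )


# ---------------------------------------------------------------------------
# unit selection


def select_ssa_units(
    table: SsaResponseTable,
    responsiveness: Sequence[ResponsivenessResult],
    alpha: float = 0.01,
    min_rare_spikes: int = MIN_RARE_SPIKES,
) -> bool:
    """Significant response (p < alpha on any tested protocol) and at least
    ``min_rare_spikes`` pooled 40-ms spikes for one rare frequency."""
    significant = any(r.p_value < alpha for r in responsiveness)
    enough = any(
        total >= min_rare_spikes for total in table.rare_total_spikes.values()
    )
    return significant and enough


def select_anfc_units(table: SsaResponseTable) -> bool:
    """SSA-selected and mean deviant response strictly above mean standard."""
    if table.ssa_selected is False:
        return False
    d = [table.raw.get(("f1", "deviant")), table.raw.get(("f2", "deviant"))]
    s = [table.raw.get(("f1", "standard")), table.raw.get(("f2", "standard"))]
    if any(v is None for v in d + s):
        return False
    return float(np.mean(d)) > float(np.mean(s))


# ---------------------------------------------------------------------------
# indices


def csi(table: SsaResponseTable) -> Optional[float]:
    """(d(f1)+d(f2)-s(f1)-s(f2)) / (d(f1)+d(f2)+s(f1)+s(f2)) on raw means."""
    vals = [
        table.raw.get(("f1", "deviant")),
        table.raw.get(("f2", "deviant")),
        table.raw.get(("f1", "standard")),
        table.raw.get(("f2", "standard")),
    ]
    if any(v is None for v in vals):
        return None
    d1, d2, s1, s2 = vals
    denom = d1 + d2 + s1 + s2
    if denom <= 0:
        return None
    return (d1 + d2 - s1 - s2) / denom


def si(table: SsaResponseTable, which: str) -> Optional[float]:
    """Frequency-specific index (d(f)-s(f)) / (d(f)+s(f))."""
    d = table.raw.get((which, "deviant"))
    s = table.raw.get((which, "standard"))
    if d is None or s is None or d + s <= 0:
        return None
    return (d - s) / (d + s)


def ssa_indices(table: SsaResponseTable) -> SsaIndices:
    return SsaIndices(csi=csi(table), si1=si(table, "f1"), si2=si(table, "f2"))


# ---------------------------------------------------------------------------
# adaptation model


def adaptation_load(
    sigma: float, prob_map: Mapping[float, float], f0_hz: float
) -> float:
    """u = sum_f p_f * exp(-(ln(f/f0))^2 / (2 sigma^2))."""
    return float(
        sum(
            p * math.exp(-(math.log(f / f0_hz) ** 2) / (2.0 * sigma**2))
            for f, p in prob_map.items()
        )
    )


def anfc_expected(
    sigma: float,
    delta: float,
    prob_map: Mapping[float, float],
    f0_hz: float,
) -> float:
    """Normalized steady-state response (1-delta)/(1-(1-u)*delta)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if not 0.0 <= delta < 1.0:
        raise ValueError("delta must be in [0, 1)")
    u = adaptation_load(sigma, prob_map, f0_hz)
    return (1.0 - delta) / (1.0 - (1.0 - u) * delta)


def _fit_observations(table: SsaResponseTable) -> list[tuple[str, str, float, dict]]:
    """(freq, cond, normalized value, prob map) for every usable fit cell."""
    obs = []
    for which in ("f1", "f2"):
        for cond in FIT_CONDITIONS:
            v = table.normalized.get((which, cond))
            pm = table.prob_maps.get((which, cond))
            if v is not None and pm:
                obs.append((which, cond, float(v), pm))
    return obs


def _solve(obs, f0_of) -> tuple[float, float, float, np.ndarray]:
    """Multi-start bounded least squares over (sigma, delta)."""
    y = np.array([v for (_, _, v, _) in obs])

    def residuals(x):
        s, d = x
        pred = np.array(
            [anfc_expected(s, d, pm, f0_of(which)) for (which, _, _, pm) in obs]
        )
        return pred - y

    best = None
    for s0 in SIGMA_STARTS:
        for d0 in DELTA_STARTS:
            sol = least_squares(
                residuals,
                x0=[s0, d0],
                bounds=([SIGMA_BOUNDS[0], DELTA_BOUNDS[0]],
                        [SIGMA_BOUNDS[1], DELTA_BOUNDS[1]]),
            )
            if best is None or sol.cost < best.cost - 1e-15:
                best = sol
    s, d = best.x
    return float(s), float(d), float(best.cost), residuals(best.x)


def fit_anfc(
    table: SsaResponseTable,
    min_observations: int = 4,
) -> AnfcFit:
    """Per-unit nonlinear least-squares fit of (sigma, delta).

    Fits the rare-normalized mean responses of the non-rare conditions
    (up to 10 cells: 2 test frequencies x 5 conditions) against the
    steady-state model with each condition's exact presentation
    probabilities.  tau is derived as -ISI/ln(delta).
    """
    obs = _fit_observations(table)
    flags = list(table.flags)
    usable = {w for (w, _, _, _) in obs}
    if len(usable) == 1:
        flags.append("partial-fit")
    if len(obs) < min_observations:
        raise ValueError(
            f"fit refused: only {len(obs)} usable observations (< {min_observations})"
        )
    f0_of = lambda which: table.frequency_hz(which)
    s, d, cost, res = _solve(obs, f0_of)
    sse_full = float(np.mean(res**2))
    tau = math.inf if d <= 0 else -table.isi_ms / math.log(d)
    predicted = {
        (which, cond): anfc_expected(s, d, pm, f0_of(which))
        for (which, cond, _, pm) in obs
    }
    return AnfcFit(
        unit_id=table.unit_id,
        sigma=s,
        delta=d,
        tau_ms=tau,
        predicted=predicted,
        sse_full=sse_full,
        observations={(w, c): v for (w, c, v, _) in obs},
        flags=tuple(dict.fromkeys(flags)),
    )


def loo_deviant_error(table: SsaResponseTable, full_fit: Optional[AnfcFit] = None) -> AnfcFit:
    """Leave-the-deviants-out sensitivity analysis.

    Refits (sigma, delta) on the non-deviant cells, predicts the deviant
    responses, and normalizes the mean squared prediction error by the mean
    squared residual of the full fit.  Returns the full fit augmented with
    the LOO fields.
    """
    if full_fit is None:
        full_fit = fit_anfc(table)
    obs = _fit_observations(table)
    held_out = [(w, c, v, pm) for (w, c, v, pm) in obs if c == "deviant"]
    kept = [(w, c, v, pm) for (w, c, v, pm) in obs if c != "deviant"]
    if not held_out or len(kept) < 2:
        return replace(full_fit, flags=full_fit.flags + ("loo-refused",))
    f0_of = lambda which: table.frequency_hz(which)
    s, d, _, _ = _solve(kept, f0_of)
    loo_pred = {w: anfc_expected(s, d, pm, f0_of(w)) for (w, _, _, pm) in held_out}
    err = float(
        np.mean([(loo_pred[w] - v) ** 2 for (w, _, v, _) in held_out])
    )
    if full_fit.sse_full <= 1e-20:
        # exact model data: the raw prediction error is reported but the
        # normalization by the full-fit residual is undefined
        return replace(
            full_fit,
            loo_predicted_deviant=loo_pred,
            flags=full_fit.flags + ("loo-undefined",),
        )
    return replace(
        full_fit,
        loo_predicted_deviant=loo_pred,
        loo_error_normalized=err / full_fit.sse_full,
    )
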