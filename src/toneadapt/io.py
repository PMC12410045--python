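"""Delimited-text interchange for protocols, spikes, and results tables.

All tables are plain CSV with documented headers; times in ms, frequencies
in Hz, absent values (silence slots, noise tokens) written as NA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Union

import pandas as pd

from .stimuli import ToneEvent, ToneProtocol
from .simulate import GroundTruthUnit, Trial, UnitRecording

__all__ = [
    "write_events",
    "read_events",
    "write_spikes",
    "read_spikes",
    "write_units",
    "read_units",
    "recording_from_tables",
]

EVENT_COLUMNS = [
    "protocol",
    "trial_index",
    "onset_ms",
    "frequency_hz",
    "level_db_attn",
    "duration_ms",
]
SPIKE_COLUMNS = ["unit_id", "protocol", "trial_index", "spike_ms"]

PathLike = Union[str, Path]


class ParseError(ValueError):
    pass


def events_frame(protocol: ToneProtocol) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protocol": protocol.name,
            "trial_index": range(protocol.n_events),
            "onset_ms": [e.onset_ms for e in protocol.events],
            "frequency_hz": [e.frequency_hz for e in protocol.events],
            "level_db_attn": [e.level_db_attn for e in protocol.events],
            "duration_ms": [e.duration_ms for e in protocol.events],
        }
    )


def write_events(protocol: ToneProtocol, path: PathLike) -> None:
    df = events_frame(protocol)
    df.to_csv(path, index=False, na_rep="NA")
    meta = {
        "name": protocol.name,
        "f1_hz": protocol.f1_hz,
        "f2_hz": protocol.f2_hz,
        "isi_ms": protocol.isi_ms,
        "seed": protocol.seed,
    }
    sidecar = Path(path).with_suffix(".meta.yaml")
    import yaml

    sidecar.write_text(yaml.safe_dump(meta, sort_keys=False))


def read_events(path: PathLike) -> ToneProtocol:
    df = pd.read_csv(path, na_values=["NA"])
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad = df.index[df["frequency_hz"].notna() & (df["frequency_hz"] <= 0)]
    if len(bad):
        raise ParseError(f"{path}: non-positive frequency at line {bad[0] + 2}")
    events = tuple(
        ToneEvent(
            onset_ms=float(r.onset_ms),
            frequency_hz=None if pd.isna(r.frequency_hz) else float(r.frequency_hz),
            level_db_attn=float(r.level_db_attn),
            duration_ms=float(r.duration_ms),
        )
        for r in df.itertuples()
    )
    sidecar = Path(path).with_suffix(".meta.yaml")
    f1 = f2 = None
    seed = 0
    name = str(df["protocol"].iloc[0])
    isi = (
        float(df["onset_ms"].iloc[1] - df["onset_ms"].iloc[0])
        if len(df) > 1
        else 0.0
    )
    if sidecar.exists():
        import yaml

        meta = yaml.safe_load(sidecar.read_text())
        name = meta.get("name", name)
        f1 = meta.get("f1_hz")
        f2 = meta.get("f2_hz")
        isi = meta.get("isi_ms", isi)
        seed = meta.get("seed", 0)
    return ToneProtocol(
        name=name, events=events, f1_hz=f1, f2_hz=f2, isi_ms=isi, seed=seed
    )


def spikes_frame(recordings: Iterable[UnitRecording]) -> pd.DataFrame:
    rows = []
    for rec in recordings:
        for tr in rec.trials:
            for t in tr.spike_ms:
                rows.append((rec.unit_id, rec.protocol.name, tr.trial_index, t))
    return pd.DataFrame(rows, columns=SPIKE_COLUMNS)


def write_spikes(recordings: Iterable[UnitRecording], path: PathLike) -> None:
    spikes_frame(recordings).to_csv(path, index=False)


def read_spikes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SPIKE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def recording_from_tables(
    unit_id: str, protocol: ToneProtocol, spikes: pd.DataFrame
) -> UnitRecording:
    """Reassemble a UnitRecording from a spike table and its protocol.

    Units listed with no spikes yield empty trials, not an error.
    """
    sel = spikes[
        (spikes["unit_id"] == unit_id) & (spikes["protocol"] == protocol.name)
    ]
    by_trial = {
        int(k): g["spike_ms"].to_numpy() for k, g in sel.groupby("trial_index")
    }
    trials = []
    for i, ev in enumerate(protocol.events):
        s = by_trial.get(i)
        trials.append(
            Trial(
                trial_index=i,
                frequency_hz=ev.frequency_hz,
                level_db_attn=ev.level_db_attn,
                spike_ms=sorted(s) if s is not None else [],
            )
        )
    return UnitRecording(unit_id=unit_id, protocol=protocol, trials=tuple(trials))


def write_units(units: Iterable[GroundTruthUnit], path: PathLike) -> None:
    pd.DataFrame([u.__dict__ for u in units]).to_csv(path, index=False)


def read_units(path: PathLike) -> list[GroundTruthUnit]:
    df = pd.read_csv(path)
    return [GroundTruthUnit(**{k: row[k] for k in df.columns}) for _, row in df.iterrows()]
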