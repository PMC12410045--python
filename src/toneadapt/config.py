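"""Run configuration: every analysis constant in one place, YAML round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

__all__ = ["RunConfig", "PopulationConfig"]


@dataclass
class PopulationConfig:
    n_units: int = 8
    dev_gain: float = 0.0
    ranges: dict = field(default_factory=dict)


@dataclass
class RunConfig:
    """Defaults collect every numeric analysis constant; all overridable."""

    seed: int = 0
    out_dir: str = "toneadapt_out"

    # protocol parameters
    f1_hz: Optional[float] = None  # None: center on each unit's best frequency
    f2_hz: Optional[float] = None
    isi_ms: float = 300.0
    freq_ratio: float = 1.44
    fra_max_attn_db: float = 60.0

    # analysis parameters
    bin_width_ms: float = 1.0
    smooth_width_ms: float = 5.0
    activity_threshold_spikes: int = 30
    onset_threshold_n_sd: float = 7.0
    onset_prominence_frac_sd: float = 0.05
    onset_crossing_frac: float = 0.25
    onset_shift_ms: float = 1.5
    ssa_window_ms: float = 40.0
    min_rare_spikes: int = 5
    alpha: float = 0.01
    alpha_rare: float = 0.005  # Bonferroni for two rare-frequency tests

    # simulated populations, keyed by group label
    populations: dict = field(
        default_factory=lambda: {
            "adapting": {"n_units": 8, "dev_gain": 0.0, "ranges": {}},
            "deviance_sensitive": {"n_units": 8, "dev_gain": 0.5, "ranges": {}},
        }
    )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
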