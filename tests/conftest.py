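import numpy as np
import pytest

import toneadapt as ta
from toneadapt.simulate import Trial, UnitRecording
from toneadapt.stimuli import feasible_broad_f1

#: a test-frequency pair that admits every protocol (diverse-broad included)
F1 = feasible_broad_f1(8000.0)
F2 = F1 * 1.44


@pytest.fixture(scope="session")
def f_pair():
    return F1, F2


@pytest.fixture(scope="session")
def protocol_set():
    return ta.build_protocol_set(F1, F2, seed=7)


@pytest.fixture
def unit():
    return ta.GroundTruthUnit(
        unit_id="u0",
        bf_hz=np.sqrt(F1 * F2),
        tuning_sigma=0.5,
        a_rate=150.0,
        spont_rate=3.0,
        onset_ms=20.0,
        resp_dur_ms=35.0,
        sigma_adapt=0.4,
        tau_adapt_ms=400.0,
        dev_gain=0.0,
        seed=3,
    )


@pytest.fixture
def session_recordings(unit, protocol_set):
    return {
        name: ta.simulate_unit(unit, proto, seed=i)
        for i, (name, proto) in enumerate(protocol_set.items())
    }


def make_recording(trial_spikes, protocol=None, unit_id="u", frequencies=None):
    """Build a UnitRecording from a list of per-trial spike-time lists."""
    if protocol is None:
        protocol = ta.build_bbn(0)
    trials = []
    for i, spikes in enumerate(trial_spikes):
        ev = protocol.events[i]
        f = frequencies[i] if frequencies is not None else ev.frequency_hz
        trials.append(
            Trial(
                trial_index=i,
                frequency_hz=f,
                level_db_attn=ev.level_db_attn,
                spike_ms=np.sort(np.asarray(spikes, dtype=float)),
            )
        )
    return UnitRecording(unit_id=unit_id, protocol=protocol, trials=tuple(trials))
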