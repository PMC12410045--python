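import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import toneadapt as ta
from toneadapt.ssa import (
    _CONDITION_SOURCE,
    CONDITIONS,
    FIT_CONDITIONS,
    SsaResponseTable,
    adaptation_load,
    anfc_expected,
)
from toneadapt.responsiveness import ResponsivenessResult

from conftest import F1, F2, make_recording


def make_table(raw, rare_totals=None, f1=F1, f2=F2, protocols=None):
    """Assemble a table from raw means; prob maps come from real protocols."""
    protocols = protocols or ta.build_protocol_set(f1, f2, seed=0)
    prob_maps = {
        key: protocols[src].tone_probability_map()
        for key, src in _CONDITION_SOURCE.items()
        if src in protocols
    }
    normalized = {}
    for which in ("f1", "f2"):
        rare = raw.get((which, "rare"))
        for cond in CONDITIONS:
            v = raw.get((which, cond))
            normalized[(which, cond)] = (
                v / rare if (v is not None and rare) else None
            )
    return SsaResponseTable(
        unit_id="u",
        f1_hz=f1,
        f2_hz=f2,
        isi_ms=300.0,
        raw=raw,
        normalized=normalized,
        rare_total_spikes=rare_totals or {"f1": 50, "f2": 50},
        prob_maps=prob_maps,
    )


def model_table(sigma, delta, f1=F1, f2=F2, rare_mean=2.0, noise=None, rng=None):
    """Raw means generated exactly (or noisily) from the steady-state model."""
    protocols = ta.build_protocol_set(f1, f2, seed=0)
    raw = {("f1", "rare"): rare_mean, ("f2", "rare"): rare_mean}
    for which in ("f1", "f2"):
        f0 = f1 if which == "f1" else f2
        for cond in FIT_CONDITIONS:
            pm = protocols[_CONDITION_SOURCE[(which, cond)]].tone_probability_map()
            v = anfc_expected(sigma, delta, pm, f0) * rare_mean
            if noise:
                v = max(v + rng.normal(0, noise), 1e-6)
            raw[(which, cond)] = v
    return make_table(raw, protocols=protocols)


def _res(p):
    return ResponsivenessResult("u", "bbn", 100, 1.0, 10, p, True, p < 0.01)


class TestComputeResponseTable:
    def test_constant_two_spikes(self, protocol_set):
        recs = {
            name: make_recording(
                [[10.0, 30.0]] * proto.n_events, protocol=proto
            )
            for name, proto in protocol_set.items()
            if name not in ("bbn", "fra")
        }
        table = ta.compute_response_table(recs, unit_id="u")
        for which in ("f1", "f2"):
            for cond in CONDITIONS:
                assert table.raw[(which, cond)] == pytest.approx(2.0)
                assert table.normalized[(which, cond)] == pytest.approx(1.0)

    def test_spikes_outside_window_count_zero(self, protocol_set):
        recs = {
            name: make_recording([[45.0]] * proto.n_events, protocol=proto)
            for name, proto in protocol_set.items()
            if name not in ("bbn", "fra")
        }
        table = ta.compute_response_table(recs, unit_id="u")
        assert all(
            table.raw[(w, c)] == 0.0 for w in ("f1", "f2") for c in CONDITIONS
        )

    def test_missing_condition_flagged(self, protocol_set):
        recs = {
            name: make_recording([[10.0]] * proto.n_events, protocol=proto)
            for name, proto in protocol_set.items()
            if name not in ("bbn", "fra", "equal")
        }
        table = ta.compute_response_table(recs, unit_id="u")
        assert table.raw[("f1", "equal")] is None
        assert "missing-equal" in table.flags

    def test_adaptation_ordering_on_simulated_units(self):
        # dev_gain = 0: normalized standard < deviant < 1 on average
        stds, devs = [], []
        for seed in range(12):
            units, recs = ta.simulate_population(
                1, seed=seed, dev_gain=0.0,
                ranges={"spont_rate": (0.0, 0.0), "a_rate": (150.0, 250.0)},
            )
            table = ta.compute_response_table(recs[units[0].unit_id])
            for w in ("f1", "f2"):
                if table.normalized[(w, "standard")] is not None:
                    stds.append(table.normalized[(w, "standard")])
                    devs.append(table.normalized[(w, "deviant")])
        assert np.mean(stds) < np.mean(devs) < 1.0


class TestSelection:
    def test_ssa_selected(self):
        t = make_table({}, rare_totals={"f1": 6, "f2": 0})
        assert ta.select_ssa_units(t, [_res(0.005)]) is True

    def test_ssa_rejected_low_rare_counts(self):
        t = make_table({}, rare_totals={"f1": 4, "f2": 4})
        assert ta.select_ssa_units(t, [_res(0.005)]) is False

    def test_ssa_rejected_not_significant(self):
        t = make_table({}, rare_totals={"f1": 25, "f2": 25})
        assert ta.select_ssa_units(t, [_res(0.02)]) is False

    @pytest.mark.parametrize(
        "d,s,expected",
        [((3.0, 3.0), (1.0, 1.0), True),
         ((1.0, 1.0), (1.0, 1.0), False),
         ((0.0, 4.0), (1.0, 1.0), True)],
    )
    def test_anfc_selection_rule(self, d, s, expected):
        raw = {
            ("f1", "deviant"): d[0], ("f2", "deviant"): d[1],
            ("f1", "standard"): s[0], ("f2", "standard"): s[1],
        }
        assert ta.select_anfc_units(make_table(raw)) is expected


class TestIndices:
    def test_symmetric_zero(self):
        raw = {
            ("f1", "deviant"): 2.0, ("f2", "deviant"): 3.0,
            ("f1", "standard"): 2.0, ("f2", "standard"): 3.0,
        }
        t = make_table(raw)
        assert ta.csi(t) == pytest.approx(0.0)
        assert ta.si(t, "f1") == pytest.approx(0.0)
        assert ta.si(t, "f2") == pytest.approx(0.0)

    def test_hand_values(self):
        raw = {
            ("f1", "deviant"): 2.0, ("f2", "deviant"): 2.0,
            ("f1", "standard"): 1.0, ("f2", "standard"): 1.0,
        }
        assert ta.csi(make_table(raw)) == pytest.approx(1.0 / 3.0)
        raw = {("f1", "deviant"): 3.0, ("f1", "standard"): 1.0}
        assert ta.si(make_table(raw), "f1") == pytest.approx(0.5)

    def test_zero_denominator_undefined(self):
        raw = {
            ("f1", "deviant"): 0.0, ("f2", "deviant"): 0.0,
            ("f1", "standard"): 0.0, ("f2", "standard"): 0.0,
        }
        assert ta.csi(make_table(raw)) is None

    @given(
        d1=st.floats(0, 10), d2=st.floats(0, 10),
        s1=st.floats(0, 10), s2=st.floats(0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_sign_consistency(self, d1, d2, s1, s2):
        raw = {
            ("f1", "deviant"): d1, ("f2", "deviant"): d2,
            ("f1", "standard"): s1, ("f2", "standard"): s2,
        }
        t = make_table(raw)
        c = ta.csi(t)
        if c is not None:
            assert -1.0 <= c <= 1.0
            assert np.sign(c) == np.sign(d1 + d2 - s1 - s2)


class TestAnfcExpected:
    def test_delta_zero_unadapted(self):
        pm = {F1: 0.95, F2: 0.05}
        assert anfc_expected(0.5, 0.0, pm, F1) == pytest.approx(1.0)

    def test_single_frequency_recursion_fixed_point(self):
        # iterate respond -> deplete -> recover to convergence and compare
        pm = {F1: 1.0}
        sigma, delta = 0.3, 0.5
        x = 1.0
        for _ in range(200):
            x = 1.0 - (1.0 - x * (1.0 - 1.0)) * delta  # U(f0,f0) = 1
        assert anfc_expected(sigma, delta, pm, F1) == pytest.approx(x, abs=1e-12)
        assert x == pytest.approx(0.5)

    def test_distant_tones_no_depletion(self):
        pm = {F1 * 1000: 1.0}
        assert anfc_expected(0.1, 0.9, pm, F1) == pytest.approx(1.0, abs=1e-6)

    @given(
        sigma=st.floats(0.05, 5.0),
        d1=st.floats(0.01, 0.98),
        d2=st.floats(0.01, 0.98),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_delta(self, sigma, d1, d2):
        if abs(d1 - d2) < 1e-9:
            return
        pm = {F1: 0.95, F2: 0.05}
        lo, hi = sorted([d1, d2])
        assert anfc_expected(sigma, hi, pm, F1) < anfc_expected(sigma, lo, pm, F1)

    def test_decreasing_in_load(self):
        delta = 0.6
        vals = [
            (1.0 - delta) / (1.0 - (1.0 - u) * delta)
            for u in np.linspace(0.01, 1.0, 50)
        ]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            anfc_expected(0.0, 0.5, {F1: 1.0}, F1)
        with pytest.raises(ValueError):
            anfc_expected(0.5, 1.0, {F1: 1.0}, F1)

    @pytest.mark.parametrize("sigma", [0.1, 0.3, 0.6, 1.0, 2.0])
    @pytest.mark.parametrize("delta", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_deviant_below_diverse_broad(self, sigma, delta):
        # the model predicts smaller responses to deviants than to the same
        # tone in the diverse-broad sequence
        protocols = ta.build_protocol_set(F1, F2, seed=0)
        for which in ("f1", "f2"):
            f0 = F1 if which == "f1" else F2
            pm_dev = protocols[
                _CONDITION_SOURCE[(which, "deviant")]
            ].tone_probability_map()
            pm_db = protocols["diverse_broad"].tone_probability_map()
            assert anfc_expected(sigma, delta, pm_dev, f0) < anfc_expected(
                sigma, delta, pm_db, f0
            )


class TestFitAnfc:
    def test_exact_recovery(self):
        t = model_table(0.4, 0.6)
        fit = ta.fit_anfc(t)
        assert fit.sigma == pytest.approx(0.4, abs=1e-3)
        assert fit.delta == pytest.approx(0.6, abs=1e-3)
        assert fit.sse_full == pytest.approx(0.0, abs=1e-12)
        assert fit.tau_ms == pytest.approx(-300.0 / math.log(0.6), rel=1e-3)

    def test_unadapted_unit_delta_zero(self):
        raw = {("f1", "rare"): 2.0, ("f2", "rare"): 2.0}
        for which in ("f1", "f2"):
            for cond in FIT_CONDITIONS:
                raw[(which, cond)] = 2.0
        fit = ta.fit_anfc(make_table(raw))
        assert fit.delta == pytest.approx(0.0, abs=1e-3)
        assert fit.sse_full == pytest.approx(0.0, abs=1e-8)

    def test_too_few_observations_refused(self):
        raw = {
            ("f1", "rare"): 2.0,
            ("f1", "standard"): 1.0,
            ("f1", "deviant"): 1.5,
        }
        with pytest.raises(ValueError):
            ta.fit_anfc(make_table(raw))

    def test_partial_fit_single_frequency_flagged(self):
        raw = {("f1", "rare"): 2.0}
        for cond in FIT_CONDITIONS:
            raw[("f1", cond)] = 1.2
        fit = ta.fit_anfc(make_table(raw))
        assert "partial-fit" in fit.flags

    def test_predictions_in_unit_interval(self):
        rng = np.random.default_rng(0)
        t = model_table(0.5, 0.5, noise=0.1, rng=rng)
        fit = ta.fit_anfc(t)
        assert all(0.0 < v <= 1.0 for v in fit.predicted.values())


class TestLooDeviantError:
    def test_model_exact_data_zero_numerator(self):
        t = model_table(0.4, 0.6)
        fit = ta.loo_deviant_error(t)
        assert "loo-undefined" in fit.flags
        for w in ("f1", "f2"):
            assert fit.loo_predicted_deviant[w] == pytest.approx(
                t.normalized[(w, "deviant")], abs=1e-6
            )

    def test_error_increases_with_deviant_inflation(self):
        rng = np.random.default_rng(1)
        errors = []
        for bump in [0.0, 0.1, 0.25, 0.5]:
            rng_i = np.random.default_rng(1)
            t = model_table(0.4, 0.6, noise=0.02, rng=rng_i)
            raw = dict(t.raw)
            for w in ("f1", "f2"):
                raw[(w, "deviant")] = raw[(w, "deviant")] + bump * 2.0
            t2 = make_table(raw)
            fit = ta.loo_deviant_error(t2)
            errors.append(fit.loo_error_normalized)
        assert all(b > a for a, b in zip(errors, errors[1:]))

    def test_monte_carlo_recovery_within_20pct(self):
        ranges = {
            "sigma_adapt": (0.4, 0.4),
            "tau_adapt_ms": (400.0, 400.0),
            "spont_rate": (1.0, 4.0),
            "a_rate": (100.0, 200.0),
        }
        units, recs = ta.simulate_population(20, seed=42, ranges=ranges)
        sigmas, taus = [], []
        for u in units:
            table = ta.compute_response_table(recs[u.unit_id])
            fit = ta.fit_anfc(table)
            sigmas.append(fit.sigma)
            taus.append(fit.tau_ms)
        assert abs(np.median(sigmas) / 0.4 - 1) < 0.2
        assert abs(np.median(taus) / 400.0 - 1) < 0.2
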