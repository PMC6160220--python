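import numpy as np
import pytest

from ca1degen.efeatures import (
    FEATURE_NAMES,
    SpikeTrain,
    adaptation_index,
    aggregate_statistics,
    classify_etype,
    detect_spikes,
    extract_features,
    floored_sd,
)
from ca1degen.simulator import VoltageTrace


def synth_trace(spike_times=(), amplitude=0.4, baseline=-65.0, total=700.0,
                dt=0.1, stim=(100.0, 500.0), deflection=0.0):
    """Construct a stylized trace with triangular 55 mV spikes at given times."""
    t = np.arange(0.0, total + dt / 2, dt)
    v = np.full_like(t, baseline)
    on, off = stim
    v[(t >= on) & (t <= off)] += deflection
    for ts in spike_times:
        mask = np.abs(t - ts) <= 1.0
        v[mask] = baseline + 55.0 * (1.0 - np.abs(t[mask] - ts))
        post = (t > ts + 1.0) & (t <= ts + 3.0)
        v[post] = baseline - 8.0  # afterhyperpolarization
    return VoltageTrace(time=t, voltage=v, protocol_amplitude=amplitude,
                        stim_start=on, stim_end=off)


def trace_from_isis(isis, first=150.0, **kw):
    times = np.concatenate([[first], first + np.cumsum(isis)])
    return synth_trace(times, **kw)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert detect_spikes(synth_trace()).n == 0

    def test_constructed_spike_times_recovered(self):
        tr = synth_trace([100.0, 200.0, 350.0])
        st = detect_spikes(tr, threshold=-20.0)
        assert st.n == 3
        assert np.allclose(st.spike_times, [100.0, 200.0, 350.0], atol=2 * tr.dt + 0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trains_counts_match_generator(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(0, 15))
        times = np.sort(rng.choice(np.arange(110, 490, 5), size=n, replace=False)).astype(float)
        tr = synth_trace(times)
        assert detect_spikes(tr).n == n

    def test_strictly_increasing_invariant(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([3.0, 2.0]))


class TestExtractFeatures:
    def test_input_resistance_from_hyperpolarizing_step(self):
        tr = synth_trace(amplitude=-0.4, deflection=-8.0)
        (fv,) = extract_features(tr, ["input_resistance"])
        assert fv.value == pytest.approx(20.0, rel=1e-3)  # -8 mV / -0.4 nA

    def test_adaptation_index_arithmetic(self):
        isis = np.array([10.0, 12.0, 14.0, 16.0])
        expected = np.mean([2 / 22, 2 / 26, 2 / 30])
        assert adaptation_index(isis) == pytest.approx(expected)
        tr = trace_from_isis(isis)
        (fv,) = extract_features(tr, ["adaptation_index"])
        assert fv.value == pytest.approx(expected, abs=0.01)

    def test_constant_isi_train_has_zero_adaptation(self):
        assert adaptation_index([20.0, 20.0, 20.0]) == 0.0

    def test_undefined_features_flagged_not_zero(self):
        tr = synth_trace()  # no spikes
        for fv in extract_features(tr, ["mean_ISI", "adaptation_index",
                                        "time_to_first_spike"]):
            assert not fv.defined and fv.value is None

    def test_voltage_features(self):
        tr = synth_trace(amplitude=0.4, deflection=12.0)
        out = {f.name: f.value for f in extract_features(
            tr, ["voltage_base", "steady_state_voltage", "voltage_deflection"])}
        assert out["voltage_base"] == pytest.approx(-65.0, abs=1e-6)
        assert out["steady_state_voltage"] == pytest.approx(-53.0, abs=1e-6)
        assert out["voltage_deflection"] == pytest.approx(12.0, abs=1e-6)

    def test_unknown_feature_rejected(self):
        with pytest.raises(KeyError):
            extract_features(synth_trace(), ["sag_ratio"])

    def test_invariant_to_post_stimulus_padding(self):
        isis = [15.0, 18.0, 22.0]
        a = trace_from_isis(isis, total=700.0)
        b = trace_from_isis(isis, total=1000.0)
        names = [f for f in FEATURE_NAMES if f != "ISI_values"]
        fa = {f.name: f.value for f in extract_features(a, names) if f.defined}
        fb = {f.name: f.value for f in extract_features(b, names) if f.defined}
        assert fa.keys() == fb.keys()
        for k in fa:
            assert fa[k] == pytest.approx(fb[k], abs=1e-9)


class TestAggregateStatistics:
    def test_two_cell_pooling(self):
        cells = [[trace_from_isis([20, 20, 20, 20][:3], amplitude=0.4)],
                 [trace_from_isis([10, 10, 10, 10, 10], amplitude=0.4)]]
        stats = aggregate_statistics(cells, ["spike_count"], apply_sd_floor=False)
        mean, sd, n = stats.stats[("spike_count", 0.4)]
        assert (mean, n) == (5.0, 2)
        assert sd == pytest.approx(np.std([4, 6], ddof=1))

    def test_single_trace_gets_sd_floor(self):
        cells = [[trace_from_isis([20, 25, 30], amplitude=0.4)]]
        stats = aggregate_statistics(cells, ["spike_count"])
        mean, sd, n = stats.stats[("spike_count", 0.4)]
        assert n == 1 and sd == floored_sd(0.0, mean) and sd > 0

    def test_all_undefined_feature_omitted_with_warning(self):
        cells = [[synth_trace()], [synth_trace()]]
        with pytest.warns(UserWarning, match="undefined in every trace"):
            stats = aggregate_statistics(cells, ["mean_ISI"])
        assert ("mean_ISI", 0.4) not in stats.stats

    def test_moments_match_generator_exactly(self, rng):
        counts = rng.integers(3, 12, size=50)
        cells = []
        for c in counts:
            times = 110.0 + 20.0 * np.arange(c)
            cells.append([synth_trace(times, amplitude=0.4)])
        stats = aggregate_statistics(cells, ["spike_count"], apply_sd_floor=False)
        mean, sd, n = stats.stats[("spike_count", 0.4)]
        assert mean == pytest.approx(counts.mean())
        assert sd == pytest.approx(np.std(counts, ddof=1))
        assert n == 50


class TestClassifyEtype:
    def test_constant_rate_is_cnac(self):
        tr = trace_from_isis([20, 20, 20, 20])
        assert classify_etype([tr]) == "cNAC"

    def test_accommodating_is_cac(self):
        tr = trace_from_isis([10, 13, 17, 22])
        assert classify_etype([tr]) == "cAC"

    def test_initial_burst_is_bac(self):
        tr = trace_from_isis([3, 4, 20, 22, 24])
        assert classify_etype([tr]) == "bAC"

    def test_insufficient_spikes_unclassifiable(self):
        tr = trace_from_isis([30, 40])  # 3 spikes only
        assert classify_etype([tr]) == "unclassifiable"

    def test_lowest_suprathreshold_amplitude_preferred(self):
        near = trace_from_isis([10, 13, 17, 22], amplitude=0.4)
        strong = trace_from_isis([8] * 30, amplitude=0.8)
        assert classify_etype([strong, near]) == "cAC"


def test_generated_ensembles_recover_their_labels(pyr_ensemble, interneuron_ensembles):
    """The heuristic classifier recovers the generating e-type label for
    >=95% of cells across all four labelled synthetic ensembles."""
    hits = total = 0
    for ens in [pyr_ensemble, *interneuron_ensembles.values()]:
        label = ens.population.label
        for cell in ens.traces:
            hits += classify_etype(cell) == label
            total += 1
    assert hits / total >= 0.95
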