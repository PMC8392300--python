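"""Activity metrics: active electrodes, MFR, burst detection, ISI, network bursts."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import meanet as m
from meanet.types import Burst, BurstSet


def brute_force_bursts(train, max_isi, min_spikes):
    """Exhaustive scan over all maximal spike runs (independent oracle)."""
    train = list(train)
    n = len(train)
    isi_short = [train[i + 1] - train[i] <= max_isi for i in range(n - 1)]
    out = []
    for i in range(n):
        for j in range(i, n):
            if all(isi_short[k] for k in range(i, j)):
                maximal = (i == 0 or not isi_short[i - 1]) and (j == n - 1 or not isi_short[j])
                if maximal and j - i + 1 >= min_spikes:
                    out.append((train[i], train[j], j - i + 1))
    return out


spike_trains = st.lists(
    st.floats(0.0, 100.0, allow_nan=False, allow_infinity=False), min_size=0, max_size=60
).map(sorted)


class TestActiveElectrodes:
    def test_all_silent_gives_zero(self, trains_factory):
        n, mask = m.active_electrodes(trains_factory({}, duration=600.0))
        assert n == 0 and not mask.any()

    def test_one_hz_everywhere_gives_64(self, trains_factory):
        trains = trains_factory({e: list(np.arange(0.0, 60.0)) for e in range(64)}, duration=60.0)
        n, mask = m.active_electrodes(trains)
        assert n == 64 and mask.all()

    def test_criterion_is_five_per_minute(self, trains_factory):
        trains = trains_factory({0: [1, 2, 3, 4, 5], 1: [1, 2, 3, 4]}, duration=60.0)
        _, mask = m.active_electrodes(trains, min_rate=5.0)
        assert mask[0] and not mask[1]


class TestMeanFiringRate:
    def test_sixty_spikes_in_sixty_seconds(self, trains_factory):
        trains = trains_factory({5: list(np.linspace(0.5, 59.5, 60))}, duration=60.0)
        mask = np.zeros(64, dtype=bool)
        mask[5] = True
        assert m.mean_firing_rate(trains, mask) == pytest.approx(1.0)

    def test_empty_mask_gives_zero(self, trains_factory):
        trains = trains_factory({0: [1.0, 2.0]}, duration=10.0)
        assert m.mean_firing_rate(trains, np.zeros(64, dtype=bool)) == 0.0

    def test_additivity_over_pooled_electrode_groups(self, rng, trains_factory):
        # pooled MFR equals the active-count-weighted mean of per-group MFRs
        spikes = {e: list(rng.uniform(0, 100, rng.integers(20, 80))) for e in range(10)}
        trains = trains_factory(spikes, duration=100.0)
        mask_a = np.zeros(64, dtype=bool)
        mask_a[:4] = True
        mask_b = np.zeros(64, dtype=bool)
        mask_b[4:10] = True
        pooled = m.mean_firing_rate(trains, mask_a | mask_b)
        weighted = (4 * m.mean_firing_rate(trains, mask_a) + 6 * m.mean_firing_rate(trains, mask_b)) / 10
        assert pooled == pytest.approx(weighted)


class TestDetectBursts:
    def test_slow_train_has_no_bursts(self):
        assert m.detect_bursts(np.arange(0.0, 20.0, 1.0)) == []

    def test_constructed_burst(self):
        train = np.concatenate([np.arange(5) * 0.01 + 1.0, [5.0, 9.0]])
        bursts = m.detect_bursts(train, max_isi=0.1, min_spikes=5)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.n_spikes == 5
        assert b.start == pytest.approx(1.0)
        assert b.end - b.start == pytest.approx(0.04)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            m.detect_bursts(np.array([1.0, 0.5, 2.0]))

    @given(train=spike_trains, max_isi=st.floats(0.01, 2.0), min_spikes=st.integers(2, 6))
    def test_equivalent_to_exhaustive_scan(self, train, max_isi, min_spikes):
        got = [(b.start, b.end, b.n_spikes) for b in m.detect_bursts(np.array(train), max_isi, min_spikes)]
        assert got == brute_force_bursts(train, max_isi, min_spikes)

    def test_oracle_equivalence_on_random_trains(self, rng):
        for _ in range(100):
            train = np.sort(rng.uniform(0, 60, rng.integers(0, 200)))
            got = [(b.start, b.end, b.n_spikes) for b in m.detect_bursts(train)]
            assert got == brute_force_bursts(train, 0.1, 5)


class TestMeanBurstRate:
    def test_no_bursts_gives_zero(self):
        bs = BurstSet(bursts=[[] for _ in range(64)])
        assert m.mean_burst_rate(bs, duration=600.0) == 0.0

    def test_ten_bursts_in_ten_minutes(self):
        bursts = [[] for _ in range(64)]
        bursts[0] = [Burst(i * 60.0, i * 60.0 + 0.1, 5) for i in range(10)]
        mask = np.zeros(64, dtype=bool)
        mask[0] = True
        assert m.mean_burst_rate(BurstSet(bursts=bursts), 600.0, mask) == pytest.approx(1.0)


class TestIsiStats:
    def test_regular_spikes(self, trains_factory):
        trains = trains_factory({0: [0.0, 1.0, 2.0]}, duration=10.0)
        isis, mean = m.isi_stats(trains)
        np.testing.assert_allclose(isis[0], [1.0, 1.0])
        assert mean == pytest.approx(1.0)

    def test_single_spike_contributes_nothing(self, trains_factory):
        trains = trains_factory({0: [5.0]}, duration=10.0)
        isis, mean = m.isi_stats(trains)
        assert isis[0].size == 0 and np.isnan(mean)

    def test_isi_shrinks_with_maturation(self):
        t8 = m.simulate_spiketrains(m.make_preset("DAI8"), 600.0, seed=0)
        t21 = m.simulate_spiketrains(m.make_preset("DAI21"), 600.0, seed=0)
        _, isi8 = m.isi_stats(t8, m.active_electrodes(t8)[1])
        _, isi21 = m.isi_stats(t21, m.active_electrodes(t21)[1])
        assert isi21 < isi8


class TestNetworkBursts:
    def test_no_bursts_no_network_bursts(self):
        bs = BurstSet(bursts=[[] for _ in range(64)])
        assert m.detect_network_bursts(bs, duration=600.0) == []

    def test_all_electrodes_bursting_together(self):
        bursts = [[Burst(1.0, 1.1, 6)] for _ in range(64)]
        nb = m.detect_network_bursts(BurstSet(bursts=bursts), duration=10.0, n_active=64)
        assert len(nb) == 1
        assert nb[0].n_electrodes == 64
        assert nb[0].start <= 1.0 < 1.1 <= nb[0].end + 1e-9

    def test_generator_event_count_recovered(self):
        from meanet.synthetic import DevPreset

        preset = DevPreset(
            label="nb",
            n_active=64,
            rate_active=0.1,
            burst_rate=0.2,
            netburst_rate=2.0,
            participation=0.9,
        )
        counts = []
        for seed in range(5):
            trains = m.simulate_spiketrains(preset, 600.0, seed=seed)
            bursts = m.detect_bursts_set(trains)
            counts.append(len(m.detect_network_bursts(bursts, 600.0, n_active=64)))
        assert np.mean(counts) == pytest.approx(20.0, abs=5.0)

    def test_min_fraction_validated(self):
        with pytest.raises(ValueError):
            m.detect_network_bursts(BurstSet(bursts=[[]]), duration=1.0, min_fraction=0.0)
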