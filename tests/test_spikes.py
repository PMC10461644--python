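import numpy as np
import pytest

from retinaphys import merg, spikes
from retinaphys.core_io import Recording, SpikeTrain, StimulusEpoch
from retinaphys.spikes import (PSTH, ResponseMetrics, cohort_table,
                               compute_psth, detect_spikes, response_metrics,
                               sort_units)
from retinaphys.synthetic import RGCRateModel, simulate_spike_train

RATE = 25000.0
TEMPLATE = -1.0 * np.concatenate([np.linspace(0, 1, 8), np.linspace(1, 0, 17)[1:]])


def embed_spikes(times, duration, amplitude=40.0, noise_sd=5.0, seed=0,
                 rate=RATE):
    """White-noise channel with negative spike templates at given times."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    v = rng.normal(0, noise_sd, n)
    kept = []
    for t in times:
        i = int(round(t * rate))
        if 0 <= i and i + TEMPLATE.size < n:
            v[i:i + TEMPLATE.size] += amplitude * TEMPLATE
            kept.append((i + np.argmin(TEMPLATE)) / rate)
    return Recording(samples=v[None, :], rate=rate, channels=("ch0",)), np.array(kept)


def highpass(rec):
    return merg.butterworth_filter(
        rec, merg.FilterSpec(order=2, cutoff=200.0, kind="highpass"))


class TestDetectSpikes:
    def test_zero_trace_no_spikes(self):
        rec = Recording(samples=np.zeros((1, 25000)), rate=RATE, channels=("c",))
        (train,) = detect_spikes(rec)
        assert len(train) == 0

    def test_invalid_threshold(self):
        rec = Recording(samples=np.zeros((1, 100)), rate=RATE, channels=("c",))
        with pytest.raises(ValueError):
            detect_spikes(rec, threshold_k=0.0)

    def test_refractory_merges_double_crossing(self):
        """Two crossings 0.5 ms apart with a 1 ms refractory: one event."""
        v = np.zeros(25000)
        sigma_target = 1.0
        rng = np.random.default_rng(0)
        v += rng.normal(0, sigma_target, v.size)
        for i in (12500, 12500 + int(0.0005 * RATE)):
            v[i] = -30.0
        rec = Recording(samples=v[None, :], rate=RATE, channels=("c",))
        (train,) = detect_spikes(rec, threshold_k=5.0, refractory=0.001)
        assert len(train) == 1

    def test_sensitivity_and_false_positives(self):
        """SNR 8 embedded trains, k=4: sensitivity >= 0.98 with false-positive
        rate < 0.5 Hz (25 seeds)."""
        sens, fp_rates = [], []
        for seed in range(25):
            model = RGCRateModel(base=15.0, on_gain=0.0, off_gain=0.0,
                                 refractory=0.003)
            train, _ = simulate_spike_train(model, [], 20.0, seed=1000 + seed)
            rec, true_times = embed_spikes(train.times, 20.0, amplitude=40.0,
                                           noise_sd=5.0, seed=seed)
            (det,) = detect_spikes(highpass(rec), threshold_k=4.0,
                                   refractory=0.001)
            if true_times.size == 0:
                continue
            matched = np.array([np.min(np.abs(det.times - t)) < 0.001
                                for t in true_times])
            false_pos = sum(np.min(np.abs(true_times - t)) > 0.001
                            for t in det.times)
            sens.append(matched.mean())
            fp_rates.append(false_pos / 20.0)
        assert np.mean(sens) >= 0.98
        assert np.mean(fp_rates) < 0.5


class TestSortUnits:
    def test_two_units_amplitude_ratio_two(self):
        """Two units with 2:1 spike amplitudes on one channel: two clusters
        with >= 95% label agreement."""
        agreements = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            n = int(30.0 * RATE)
            v = rng.normal(0, 5.0, n)
            t1, _ = simulate_spike_train(
                RGCRateModel(base=8.0, on_gain=0, off_gain=0, refractory=0.005),
                [], 30.0, seed=100 + seed)
            t2, _ = simulate_spike_train(
                RGCRateModel(base=8.0, on_gain=0, off_gain=0, refractory=0.005),
                [], 30.0, seed=200 + seed)
            truth = []
            for label, (train, amp) in enumerate([(t1, 60.0), (t2, 30.0)]):
                for t in train.times:
                    i = int(t * RATE)
                    if i + TEMPLATE.size < n:
                        v[i:i + TEMPLATE.size] += amp * TEMPLATE
                        truth.append((t + np.argmin(TEMPLATE) / RATE, label))
            truth.sort()
            tt = np.array([a for a, _ in truth])
            lab = np.array([b for _, b in truth])
            rec = Recording(samples=v[None, :], rate=RATE, channels=("ch0",))
            units = sort_units(highpass(rec),
                               detect_spikes(highpass(rec), 4.0, 0.001))
            assert len(units) == 2
            correct = total = 0
            for ui, u in enumerate(units):
                for t in u.times:
                    j = np.argmin(np.abs(tt - t))
                    if abs(tt[j] - t) < 0.001:
                        total += 1
                        correct += lab[j] == ui
            agreements.append(max(correct, total - correct) / total)
        assert min(agreements) >= 0.95

    def test_identical_waveforms_single_cluster(self):
        rng = np.random.default_rng(0)
        n = int(20.0 * RATE)
        v = rng.normal(0, 1.0, n)
        train, _ = simulate_spike_train(
            RGCRateModel(base=10.0, on_gain=0, off_gain=0, refractory=0.005),
            [], 20.0, seed=5)
        for t in train.times:
            i = int(t * RATE)
            if i + TEMPLATE.size < n:
                v[i:i + TEMPLATE.size] += 50.0 * TEMPLATE
        rec = Recording(samples=v[None, :], rate=RATE, channels=("ch0",))
        units = sort_units(highpass(rec), detect_spikes(highpass(rec), 5.0, 0.001))
        assert len(units) == 1

    def test_few_events_single_unit(self):
        rec = Recording(samples=np.zeros((1, 25000)), rate=RATE, channels=("c",))
        sparse = SpikeTrain(times=np.array([0.1, 0.2, 0.3]), channel="c")
        with pytest.warns(UserWarning):
            units = sort_units(rec, [sparse])
        assert len(units) == 1
        np.testing.assert_array_equal(units[0].times, sparse.times)


class TestPSTH:
    def test_count_conserved_under_refinement(self, trial_epochs):
        rng = np.random.default_rng(2)
        train = SpikeTrain(times=np.sort(rng.uniform(0, 45, 400)))
        coarse = compute_psth(train, trial_epochs, 0.1, (0.0, 1.5))
        fine = compute_psth(train, trial_epochs, 0.01, (0.0, 1.5))
        assert coarse.counts.sum() == fine.counts.sum()

    def test_rate_normalization(self):
        ep = StimulusEpoch(onset=1.0, duration=1.0, flux=1e15)
        train = SpikeTrain(times=np.array([1.01, 1.02, 1.03]))
        psth = compute_psth(train, [ep, StimulusEpoch(onset=10.0, duration=1.0,
                                                      flux=1e15)], 0.05, (0, 1))
        assert psth.rate[0] == pytest.approx(3 / (0.05 * 2))

    def test_nonuniform_bins_rejected(self):
        with pytest.raises(ValueError):
            PSTH(bin_edges=np.array([0.0, 0.1, 0.3]), counts=np.array([1, 2]),
                 n_trials=1)


class TestResponseMetrics:
    def test_basal_rate_uniform_spikes(self):
        """10 spikes spread over a 2-s pre-window in one trial: 5 Hz."""
        ep = StimulusEpoch(onset=5.0, duration=1.0, flux=1e15)
        train = SpikeTrain(times=5.0 - 2.0 + 0.2 * np.arange(10) + 0.1)
        m = response_metrics(train, [ep], pre_window=2.0)
        assert m.basal_rate == pytest.approx(5.0)

    def test_empty_train(self):
        ep = StimulusEpoch(onset=5.0, duration=1.0, flux=1e15)
        m = response_metrics(SpikeTrain(times=np.array([])), [ep])
        assert m.rclass == "none"
        assert m.basal_rate == 0.0 and m.peak_rate == 0.0

    def test_basal_rate_shift_invariance(self, trial_epochs):
        rng = np.random.default_rng(9)
        times = np.sort(rng.uniform(0, 45, 300))
        m1 = response_metrics(SpikeTrain(times=times), trial_epochs)
        shift = 3.0
        shifted = [StimulusEpoch(onset=e.onset + shift, duration=e.duration,
                                 flux=e.flux, background=e.background)
                   for e in trial_epochs]
        m2 = response_metrics(SpikeTrain(times=times + shift), shifted)
        assert m1.basal_rate == pytest.approx(m2.basal_rate)

    def test_pure_on_cell_recovery(self, trial_epochs):
        """Pure-ON cells at default SNR: classified ON with onset within one
        bin of the true latency in >= 95/100 seeds."""
        class_hits = onset_hits = 0
        for s in range(100):
            model = RGCRateModel(base=10.0, on_gain=60.0, off_gain=0.0)
            train, truth = simulate_spike_train(
                model, trial_epochs, trial_epochs[-1].offset + 2.0,
                seed=3000 + s)
            m = response_metrics(train, trial_epochs)
            class_hits += m.rclass == "ON"
            if m.rclass == "ON":
                onset_hits += abs(m.onset - truth["on_latency"]) <= 0.05
        assert class_hits >= 95
        assert onset_hits >= 95

    def test_three_class_accuracy(self, trial_epochs):
        """Labelled three-class mixture at default SNR: >= 90% accuracy over
        99 cells (33 per class, fixed seeds)."""
        correct = 0
        n_per = 33
        for ci, (og, fg) in enumerate([(60.0, 0.0), (0.0, 60.0), (60.0, 60.0)]):
            for s in range(n_per):
                model = RGCRateModel(base=10.0, on_gain=og, off_gain=fg)
                train, truth = simulate_spike_train(
                    model, trial_epochs, trial_epochs[-1].offset + 2.0,
                    seed=5000 + ci * n_per + s)
                correct += response_metrics(train, trial_epochs).rclass == \
                    truth["rclass"]
        assert correct / (3 * n_per) >= 0.90


class TestCohortTable:
    @staticmethod
    def metrics_with_classes(counts):
        out = []
        k = 0
        for rclass, n in counts.items():
            for _ in range(n):
                out.append(ResponseMetrics(unit_id=f"u{k}", basal_rate=5.0,
                                           peak_rate=50.0, onset=0.1,
                                           time_to_peak=0.2, rclass=rclass))
                k += 1
        return out

    def test_murine_fraction_split(self):
        """58 ON / 6 OFF of 64 cells: 90.6% / 9.4%."""
        t = cohort_table(self.metrics_with_classes({"ON": 58, "OFF": 6}))
        assert 100 * t["fractions"]["ON"] == pytest.approx(90.6, abs=0.05)
        assert 100 * t["fractions"]["OFF"] == pytest.approx(9.4, abs=0.05)

    def test_bovine_fraction_split(self):
        """27 ON / 30 OFF of 57 cells: 47.4% / 52.6%."""
        t = cohort_table(self.metrics_with_classes({"ON": 27, "OFF": 30}))
        assert 100 * t["fractions"]["ON"] == pytest.approx(47.4, abs=0.05)
        assert 100 * t["fractions"]["OFF"] == pytest.approx(52.6, abs=0.05)

    def test_single_class(self):
        t = cohort_table(self.metrics_with_classes({"ON": 12}))
        assert t["fractions"]["ON"] == 1.0
        assert sum(v for v in t["fractions"].values()) == 1.0

    def test_fractions_match_mixing_proportions(self, trial_epochs):
        """Classified fractions over a deterministic 1/3-1/3-1/3 mixture of
        simulated cells stay within 3% of the generator proportions."""
        metrics = []
        n_per = 60
        for ci, (og, fg) in enumerate([(60.0, 0.0), (0.0, 60.0), (60.0, 60.0)]):
            for s in range(n_per):
                model = RGCRateModel(base=10.0, on_gain=og, off_gain=fg)
                train, _ = simulate_spike_train(
                    model, trial_epochs, trial_epochs[-1].offset + 2.0,
                    seed=7000 + ci * n_per + s)
                metrics.append(response_metrics(train, trial_epochs))
        t = cohort_table(metrics)
        for c in ("ON", "OFF", "ON_OFF"):
            assert t["fractions"][c] == pytest.approx(1 / 3, abs=0.03)
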