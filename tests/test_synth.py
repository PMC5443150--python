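import numpy as np
import pytest

from spade_stp.synth import (InjectionSpec, RateModel, generate_background,
                             inject_multiple, inject_stp)


class TestBackground:
    def test_stationary_poisson_moments(self):
        # 1000 seeded realizations of one 15 Hz neuron over 1 s: mean count
        # within 3 SE of 15 and Fano factor near 1
        rng = np.random.default_rng(0)
        model = RateModel(kind="stationary", rate=15.0)
        counts = np.array([generate_background(model, 1, 1000.0, rng)
                           .spike_counts()[0] for _ in range(1000)])
        se = np.sqrt(15.0 / 1000)
        assert abs(counts.mean() - 15.0) < 3 * se
        assert 0.8 < counts.var() / counts.mean() < 1.25

    def test_coherent_step_expected_count(self):
        # 0.9 s at 10 Hz plus 0.1 s at 60 Hz -> 15 expected spikes
        rng = np.random.default_rng(1)
        model = RateModel(kind="coherent_step")
        counts = np.array([generate_background(model, 1, 1000.0, rng)
                           .spike_counts()[0] for _ in range(1000)])
        se = np.sqrt(15.0 / 1000)
        assert abs(counts.mean() - 15.0) < 3 * se
        # spikes concentrate in the jump interval
        allspk = np.concatenate(
            [generate_background(model, 5, 1000.0, rng).trains[i]
             for _ in range(50) for i in range(5)])
        in_jump = np.mean((allspk >= 600) & (allspk < 700))
        assert abs(in_jump - 6.0 / 15.0) < 0.05

    def test_heterogeneous_gradient(self):
        rng = np.random.default_rng(2)
        model = RateModel(kind="heterogeneous")
        counts = np.zeros(100)
        for _ in range(50):
            counts += generate_background(model, 100, 1000.0, rng).spike_counts()
        counts /= 50
        assert abs(counts[0] - 5.0) < 3 * np.sqrt(5 / 50)
        assert abs(counts[-1] - 24.8) < 3 * np.sqrt(24.8 / 50)

    def test_propagation_groups_jump_in_sequence(self):
        rng = np.random.default_rng(3)
        model = RateModel(kind="propagation")
        segs = model.profiles(100, 1000.0)
        # group 0 jumps at 50 and 550 ms; group 19 at 145 and 645 ms
        assert (50.0, 55.0, 100.0) in segs[0]
        assert (145.0, 150.0, 100.0) in segs[99]
        tr = generate_background(model, 100, 1000.0, rng)
        assert tr.n_neurons == 100

    def test_zero_duration_empty(self):
        tr = generate_background(RateModel(rate=20.0), 5, 0.0,
                                 np.random.default_rng(0))
        assert tr.total_spikes() == 0


class TestInjection:
    def test_deterministic_placement(self):
        bg = generate_background(RateModel(rate=0.0), 5, 1000.0,
                                 np.random.default_rng(0))
        data, gt = inject_stp(bg, InjectionSpec(z=3, c=1, lag=5.0),
                              np.random.default_rng(0), onsets=np.array([100.0]))
        assert list(data.trains[0]) == [100.0]
        assert list(data.trains[1]) == [105.0]
        assert list(data.trains[2]) == [110.0]
        assert gt.neurons == (0, 1, 2) and gt.lags == (0.0, 5.0, 10.0)

    def test_ground_truth_spikes_present(self):
        rng = np.random.default_rng(4)
        bg = generate_background(RateModel(rate=10.0), 12, 1000.0, rng)
        data, gt = inject_stp(bg, InjectionSpec(z=10, c=10, lag=5.0), rng)
        for i, n in enumerate(gt.neurons):
            for onset in gt.onsets:
                assert np.any(np.isclose(data.trains[n], onset + gt.lags[i]))
        # z=10 at 5 ms lag spans 45 ms, fitting a 50 ms analysis window
        assert max(gt.lags) == 45.0

    def test_occurrences_fit_recording(self):
        rng = np.random.default_rng(5)
        bg = generate_background(RateModel(rate=10.0), 10, 200.0, rng)
        data, gt = inject_stp(bg, InjectionSpec(z=10, c=20, lag=5.0), rng)
        assert gt.onsets.max() + 45.0 < 200.0

    def test_too_short_recording_rejected(self):
        bg = generate_background(RateModel(rate=10.0), 10, 40.0,
                                 np.random.default_rng(0))
        with pytest.raises(ValueError, match="too short"):
            inject_stp(bg, InjectionSpec(z=10, c=1, lag=5.0),
                       np.random.default_rng(0))

    def test_injection_adds_z_times_c_spikes(self):
        rng = np.random.default_rng(6)
        bg = generate_background(RateModel(rate=10.0), 10, 1000.0, rng)
        data, gt = inject_stp(bg, InjectionSpec(z=5, c=7, lag=5.0), rng)
        assert data.total_spikes() == bg.total_spikes() + 35


class TestMultipleInjection:
    def test_distinct_neuron_sets(self):
        rng = np.random.default_rng(7)
        bg = generate_background(RateModel(rate=10.0), 100, 1000.0, rng)
        specs = [InjectionSpec(z=5, c=10, neuron_choice="random")] * 2
        data, truths = inject_multiple(bg, specs, rng)
        assert len(truths) == 2
        assert set(truths[0].neurons) != set(truths[1].neurons)

    def test_identical_forced_sets_rejected(self):
        rng = np.random.default_rng(8)
        bg = generate_background(RateModel(rate=10.0), 10, 1000.0, rng)
        specs = [InjectionSpec(z=3, c=2, neurons=(0, 1, 2))] * 2
        with pytest.raises(ValueError, match="distinct"):
            inject_multiple(bg, specs, rng)

    def test_partial_overlap_allowed(self):
        rng = np.random.default_rng(9)
        bg = generate_background(RateModel(rate=10.0), 6, 1000.0, rng)
        specs = [InjectionSpec(z=3, c=2, neurons=(0, 1, 2)),
                 InjectionSpec(z=3, c=2, neurons=(2, 3, 4))]
        data, truths = inject_multiple(bg, specs, rng)
        assert set(truths[0].neurons) & set(truths[1].neurons) == {2}
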