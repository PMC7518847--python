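"""Single-neuron metric tests: selectivity phases, ramp class, AP
detectability, preprocessing, SNR."""

import numpy as np
import pytest

import spikefluor as sf
from conftest import make_selective_binned


class TestClassifySelectivity:
    def test_constant_offset_is_monophasic_right(self):
        rng = np.random.default_rng(0)
        b = make_selective_binned(rng, offset_right=5.0, noise_sd=1.0)
        lab = sf.classify_selectivity(b)
        assert lab.category == "monophasic"
        assert lab.preference == "right"
        assert all(s > 0 for *_, s in lab.significant_runs)

    def test_sign_flip_is_multiphasic(self):
        rng = np.random.default_rng(1)
        n_bins = 60
        profile = np.r_[np.full(n_bins // 2, 5.0), np.full(n_bins // 2, -5.0)]
        b = make_selective_binned(rng, offset_profile=profile, noise_sd=1.0)
        lab = sf.classify_selectivity(b)
        assert lab.category == "multiphasic"
        signs = {s for *_, s in lab.significant_runs}
        assert signs == {1, -1}

    def test_null_is_mostly_nonselective(self):
        rng = np.random.default_rng(2)
        labs = [sf.classify_selectivity(make_selective_binned(rng, n_trials=200))
                for _ in range(50)]
        frac = np.mean([l.category != "nonselective" for l in labs])
        assert frac <= 0.1  # run-length requirement strongly suppresses FPs

    def test_label_swap_symmetry(self):
        """Swapping trial labels swaps preference and flips run signs but
        preserves the category."""
        rng = np.random.default_rng(3)
        n_bins = 60
        profile = np.r_[np.full(30, 5.0), np.full(30, -5.0)]
        for b in (make_selective_binned(rng, offset_right=4.0),
                  make_selective_binned(rng, offset_profile=profile)):
            lab = sf.classify_selectivity(b)
            swapped = sf.classify_selectivity(b.swap_labels())
            assert lab.category == swapped.category
            if lab.preference != "none":
                assert {lab.preference, swapped.preference} == {"left", "right"}
            assert [(a, z, -s) for a, z, s in lab.significant_runs] == \
                swapped.significant_runs
        del n_bins

    def test_insufficient_trials_rejected(self):
        rng = np.random.default_rng(4)
        b = make_selective_binned(rng, n_trials=20)  # 10 per type
        with pytest.raises(ValueError, match="trials"):
            sf.classify_selectivity(b)

    def test_short_runs_do_not_count(self):
        """A large offset confined to fewer than 5 bins is not selectivity."""
        rng = np.random.default_rng(5)
        profile = np.zeros(60)
        profile[10:13] = 8.0
        b = make_selective_binned(rng, offset_profile=profile, n_trials=200)
        lab = sf.classify_selectivity(b)
        assert lab.category == "nonselective"


class TestClassifyRamp:
    def _binned_rates(self, rng, base_rate, delay_rate, n_trials=60):
        prof = sf.synthesis.RateProfile(
            lambda t, tt: np.where(t < 2.3, base_rate,
                                   np.where(t < 3.6, delay_rate, base_rate)))
        epochs = sf.EpochSchedule()
        trials = []
        for i in range(n_trials):
            tt = "left" if i % 2 else "right"
            st = sf.sample_poisson_train(prof, 0.0, epochs.trial_end, rng, tt)
            trials.append(sf.SpikeTrain(st, tt, True, epochs))
        return sf.bin_spike_ensemble(sf.TrialEnsemble(trials))

    def test_ramp_down(self):
        rng = np.random.default_rng(0)
        assert sf.classify_ramp(self._binned_rates(rng, 10.0, 2.0)) == "ramp_down"

    def test_ramp_up(self):
        rng = np.random.default_rng(1)
        assert sf.classify_ramp(self._binned_rates(rng, 2.0, 10.0)) == "ramp_up"

    def test_flat_is_other_at_alpha(self):
        rng = np.random.default_rng(2)
        out = [sf.classify_ramp(self._binned_rates(rng, 5.0, 5.0, n_trials=40))
               for _ in range(40)]
        # under the null the paired test fires at ~alpha
        assert np.mean([o != "other" for o in out]) < 0.2

    def test_ramp_down_selectivity_lost_more_than_ramp_up(self, epochs):
        """Through a slow saturating transform, ramp-down selectivity is
        obscured more often than ramp-up selectivity."""
        rng = np.random.default_rng(7)
        params = sf.S2FParams(tau_r=0.07, tau_d=1.4, F_m=3.0, k=1.5, c_half=1.2,
                              sigma_e=0.06)

        def survival(archetype, baseline):
            kept = 0
            n_neurons = 12
            for n in range(n_neurons):
                prof = sf.make_archetype(archetype, epochs, baseline=baseline,
                                         delta=6.0, preference="right")
                trials, fluor = [], []
                for i in range(60):
                    tt = "left" if i % 2 else "right"
                    st = sf.sample_poisson_train(prof, 0.0, epochs.trial_end, rng, tt)
                    s = sf.SpikeTrain(st, tt, True, epochs)
                    trials.append(s)
                    fluor.append(sf.simulate_fluorescence(s, params, rng_seed=rng))
                lab_f = sf.classify_selectivity(sf.bin_fluor_trials(fluor))
                kept += lab_f.category != "nonselective"
            return kept / n_neurons

        up = survival("ramp_up", baseline=2.0)
        down = survival("ramp_down", baseline=12.0)
        assert down < up


class TestApSnippets:
    def _recording(self, spike_times, params, duration=60.0, seed=0):
        epochs = sf.EpochSchedule(0.0, 1.0, 2.0, 3.0, duration)
        st = sf.SpikeTrain(spike_times, "left", epochs=epochs)
        f = sf.simulate_fluorescence(st, params, rng_seed=seed)
        return f.values, f.frame_times, np.asarray(spike_times, dtype=float)

    def test_spike_free_recording_only_baseline(self):
        vals, ft, spk = self._recording([], sf.S2FParams(sigma_e=0.02))
        groups = sf.extract_ap_snippets(vals, ft, spk)
        assert list(groups) == [0] and len(groups[0]) > 0

    def test_group_sizes_match_constructed_bursts(self):
        """Isolated 1..5-spike bursts land in the matching AP-count groups."""
        params = sf.S2FParams(tau_r=0.05, tau_d=0.5, sigma_e=0.01)
        times = []
        expected = {}
        t = 5.0
        for n in (1, 2, 3, 4, 5, 1, 2):
            times.extend(t + 0.02 * np.arange(n))
            expected[n] = expected.get(n, 0) + 1
            t += 6.0
        vals, ft, spk = self._recording(np.array(times), params)
        groups = sf.extract_ap_snippets(vals, ft, spk)
        for n, cnt in expected.items():
            assert len(groups.get(n, [])) == cnt, (n, {k: len(v) for k, v in groups.items()})

    def test_peak_grows_with_ap_count_noise_free(self):
        params = sf.S2FParams(tau_r=0.05, tau_d=0.5)
        times = []
        t = 5.0
        for n in (1, 2, 3, 4, 5):
            times.extend(t + 0.02 * np.arange(n))
            t += 6.0
        vals, ft, spk = self._recording(np.array(times), params)
        groups = sf.extract_ap_snippets(vals, ft, spk)
        peaks = [np.mean([s.max() for s in groups[n]]) for n in (1, 2, 3, 4, 5)]
        assert np.all(np.diff(peaks) > 0)


class TestDetectability:
    def test_identical_distributions_give_zero_dprime(self):
        rng = np.random.default_rng(0)
        base = [rng.normal(0, 1, 10) for _ in range(200)]
        snippets = {0: base[:100], 1: base[100:]}
        res = sf.detectability(snippets)
        assert abs(res.d_prime) < 0.3
        assert res.auc == pytest.approx(0.5, abs=0.1)

    def test_unit_shift_gives_unit_dprime(self):
        rng = np.random.default_rng(1)
        snippets = {
            0: [np.array([x]) for x in rng.normal(0, 1, 4000)],
            1: [np.array([x]) for x in rng.normal(1, 1, 4000)],
        }
        res = sf.detectability(snippets)
        assert res.d_prime == pytest.approx(1.0, abs=0.08)
        assert res.auc > 0.5

    def test_auc_equals_pairwise_comparison_count(self):
        """Trapezoid AUC equals the exhaustive pairwise identity
        (ties counted half) on a small fixed sample."""
        base = [np.array([v]) for v in (0.0, 0.2, 0.4, 0.6, 0.8)]
        ap = [np.array([v]) for v in (0.3, 0.5, 0.7, 0.9, 1.1)]
        res = sf.detectability({0: base, 1: ap})
        pairs = 0.0
        for a in (0.3, 0.5, 0.7, 0.9, 1.1):
            for b in (0.0, 0.2, 0.4, 0.6, 0.8):
                pairs += 1.0 if a > b else (0.5 if a == b else 0.0)
        assert res.auc == pytest.approx(pairs / 25, abs=1e-12)

    def test_dprime_auc_sign_agreement(self):
        rng = np.random.default_rng(2)
        for shift in (-0.8, 0.8):
            snippets = {
                0: [np.array([x]) for x in rng.normal(0, 1, 500)],
                1: [np.array([x]) for x in rng.normal(shift, 1, 500)],
            }
            res = sf.detectability(snippets)
            assert (res.d_prime > 0) == (res.auc > 0.5)

    def test_zero_variance_baseline_rejected(self):
        snippets = {0: [np.array([1.0])] * 5, 1: [np.array([2.0])] * 5}
        with pytest.raises(ValueError, match="variance"):
            sf.detectability(snippets)


class TestPreprocessing:
    def test_neuropil_correction_formula(self):
        rng = np.random.default_rng(0)
        f = rng.normal(1, 0.1, 100)
        np.testing.assert_allclose(sf.neuropil_correct(f, f, r=0.7), 0.3 * f,
                                   atol=1e-12)

    def test_outlier_trial_flagged(self):
        rng = np.random.default_rng(1)
        m = rng.normal(0, 1, size=(20, 100))
        m[3, :40] = np.median(m) + 5 * m.std()  # 40% of points far out
        flags = sf.flag_outlier_trials(m)
        assert flags[3]

    def test_mild_trial_kept(self):
        rng = np.random.default_rng(2)
        m = rng.normal(0, 1, size=(20, 100))
        m[3, :10] = np.median(m) + 5 * m.std()  # only 10%
        flags = sf.flag_outlier_trials(m)
        assert not flags[3]

    def test_preprocess_wrapper(self, epochs):
        rng = np.random.default_rng(3)
        ft = np.arange(0.0335, 5.1, 0.067)
        traces = [sf.FluorTrace(ft, rng.normal(0, 1, ft.size), "left", True, epochs)
                  for _ in range(10)]
        npil = [np.full(ft.size, 1.0) for _ in range(10)]
        out, keep = sf.preprocess_fluor(traces, npil, r=0.7)
        assert keep.all()
        np.testing.assert_allclose(out[0].values, traces[0].values - 0.7,
                                   atol=1e-12)


class TestEstimateSnr:
    def test_noise_estimate_scales_linearly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 4096)
        noises = []
        for sigma in (0.5, 1.0, 2.0):
            # snr = range/noise; recover noise from a known range
            vals = sigma * base
            snr = sf.estimate_snr(vals)
            rng_amp = vals.max() - np.median(vals)
            noises.append(rng_amp / snr)
        ratios = np.diff(np.log(noises))
        np.testing.assert_allclose(ratios, np.log(2), atol=0.1)

    def test_low_frequency_signal_ignored(self):
        rng = np.random.default_rng(1)
        n = 4096
        noise = rng.normal(0, 1, n)
        slow = 20 * np.sin(2 * np.pi * 0.05 * np.arange(n) * 0.067)
        n0 = (noise.max() - np.median(noise)) / sf.estimate_snr(noise)
        v = noise + slow
        n1 = (v.max() - np.median(v)) / sf.estimate_snr(v)
        assert abs(n1 - n0) / n0 < 0.1

    def test_amplitude_doubling_doubles_noise(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1, 1024)
        n1 = (v.max() - np.median(v)) / sf.estimate_snr(v)
        v2 = 2 * v
        n2 = (v2.max() - np.median(v2)) / sf.estimate_snr(v2)
        assert n2 == pytest.approx(2 * n1, rel=1e-9)

    def test_constant_trace_sentinel(self):
        assert sf.estimate_snr(np.ones(128)) == np.inf

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            sf.estimate_snr(np.arange(10))


class TestSubtractBaseline:
    def test_removes_first_window_mean(self):
        v = np.r_[np.full(10, 2.0), np.full(10, 5.0)]
        out = sf.subtract_baseline(v, 10)
        assert out[:10].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[10:].mean() == pytest.approx(3.0, abs=1e-12)
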