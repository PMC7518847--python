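"""Synthetic-data generator tests: Poisson statistics, artifact
simulations, slow-baseline scenario, peakiness sensitivity sets."""

import numpy as np
import pytest

import spikefluor as sf
from spikefluor.synthesis import make_archetype


class TestPoissonGeneration:
    def test_zero_rate_no_spikes(self):
        rng = np.random.default_rng(0)
        assert sf.sample_poisson_train(0.0, 0.0, 5.0, rng).size == 0

    def test_constant_rate_mean_count(self):
        """10 Hz over 5 s, 200 trials: mean count 50 within 3 sigma."""
        rng = np.random.default_rng(1)
        counts = [sf.sample_poisson_train(10.0, 0.0, 5.0, rng).size
                  for _ in range(200)]
        se = np.sqrt(50 / 200)
        assert abs(np.mean(counts) - 50) < 3 * se

    def test_population_reproducible_by_seed(self):
        mix = {"monophasic_sel": 0.5, "nonselective": 0.5}
        a = sf.generate_population(4, mix, n_trials_per_type=20, rng_seed=5)
        b = sf.generate_population(4, mix, n_trials_per_type=20, rng_seed=5)
        for ea, eb in zip(a, b):
            for ta, tb in zip(ea.trials, eb.trials):
                assert np.array_equal(ta.spike_times, tb.spike_times)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="20 trials"):
            sf.generate_population(2, {"nonselective": 1.0}, n_trials_per_type=10)

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sf.generate_population(2, {"nonselective": 0.5}, n_trials_per_type=20)

    def test_nonselective_population_stays_nonselective(self):
        """Null archetype: the selectivity classifier labels >= 90% of
        neurons non-selective at 200 trials per type."""
        pop = sf.generate_population(
            20, {"nonselective": 1.0}, n_trials_per_type=200, rng_seed=2
        )
        labels = [sf.classify_selectivity(sf.bin_spike_ensemble(e)) for e in pop]
        frac_ns = np.mean([l.category == "nonselective" for l in labels])
        assert frac_ns >= 0.9

    def test_archetype_constraints(self, epochs):
        t = np.linspace(0, epochs.trial_end, 500)
        down = make_archetype("ramp_down", epochs, baseline=10.0)
        pres = t < epochs.sample_start
        delay = (t >= epochs.delay_start) & (t < epochs.response_start)
        for tt in ("left", "right"):
            r = down.rate(t, tt)
            assert r[pres].mean() > r[delay].mean()
        up = make_archetype("ramp_up", epochs, baseline=2.0)
        for tt in ("left", "right"):
            r = up.rate(t, tt)
            assert r[pres].mean() < r[delay].mean()

    def test_negative_rate_rejected(self):
        prof = sf.synthesis.RateProfile(lambda t, tt: np.full_like(t, -1.0))
        with pytest.raises(ValueError, match=">= 0"):
            prof.rate(np.linspace(0, 1, 10), "left")


class TestExtendPretrial:
    def test_zero_rate_only_shifts_window(self, epochs):
        st = sf.SpikeTrain([1.0, 2.0], "left", epochs=epochs)
        ext = sf.extend_pretrial(st, 3.0, 0.0, rng_seed=0)
        assert np.array_equal(ext.spike_times, st.spike_times)
        assert ext.t_start == -3.0

    def test_added_count_matches_poisson_mean(self, epochs):
        st = sf.SpikeTrain([1.0], "left", epochs=epochs)
        added = [
            sf.extend_pretrial(st, 5.0, 4.0, rng_seed=s).n_spikes - 1
            for s in range(1000)
        ]
        se = np.sqrt(20 / 1000)
        assert abs(np.mean(added) - 20) < 4 * se

    def test_deterministic_by_seed(self, epochs):
        st = sf.SpikeTrain([1.0], "left", epochs=epochs)
        a = sf.extend_pretrial(st, 2.0, 5.0, rng_seed=7)
        b = sf.extend_pretrial(st, 2.0, 5.0, rng_seed=7)
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_invalid_extension_rejected(self, epochs):
        st = sf.SpikeTrain([1.0], "left", epochs=epochs)
        with pytest.raises(ValueError):
            sf.extend_pretrial(st, -1.0, 4.0)


class TestMergeNeurons:
    def _pop(self, n, seed=0, n_trials=20):
        return sf.generate_population(
            n, {"nonselective": 1.0}, n_trials_per_type=n_trials, rng_seed=seed
        )

    def test_p_zero_is_identity(self):
        pop = self._pop(4)
        out = sf.merge_neurons(pop, 0.0, rng_seed=1)
        assert out is not pop and len(out) == 4
        for a, b in zip(pop, out):
            assert a is b

    def test_p_one_two_neurons_sums_counts(self):
        pop = self._pop(2, seed=3)
        out = sf.merge_neurons(pop, 1.0, rng_seed=1)
        assert len(out) == 1
        merged = out[0]
        for tt in ("left", "right"):
            total_in = sum(t.n_spikes for e in pop for t in e.by_type(tt))
            total_out = sum(t.n_spikes for t in merged.by_type(tt))
            assert total_out == total_in  # distinct Poisson spikes, no ties

    def test_merging_opposite_ramps_yields_multiphasic(self, epochs):
        """Merging a ramp-up-right with a ramp-down-left cell produces a
        multiphasic unit at a frequency matching a direct simulation of
        the merged rate profile."""
        rng_master = np.random.default_rng(99)
        n_rep, n_trials = 30, 100
        mid = 0.5 * (epochs.sample_start + epochs.trial_end)
        up = sf.synthesis.RateProfile(
            lambda t, tt: 3.0 + 8.0 * ((t >= epochs.sample_start) & (t < mid))
            * (tt == "right"))
        down = sf.synthesis.RateProfile(
            lambda t, tt: 3.0 + 8.0 * (t >= mid) * (tt == "left"))

        def one_unit(rng):
            trials = []
            for prof in (up, down):
                tr = []
                for tt in ("left", "right"):
                    for _ in range(n_trials):
                        st = sf.sample_poisson_train(prof, 0.0, epochs.trial_end,
                                                     rng, tt)
                        tr.append(sf.SpikeTrain(st, tt, True, epochs))
                trials.append(sf.TrialEnsemble(tr))
            return sf.merge_neurons(trials, 1.0, rng_seed=rng.integers(2**31))[0]

        # oracle: simulate the summed rate profile directly
        def oracle_unit(rng):
            tr = []
            for tt in ("left", "right"):
                for _ in range(n_trials):
                    s1 = sf.sample_poisson_train(up, 0.0, epochs.trial_end, rng, tt)
                    s2 = sf.sample_poisson_train(down, 0.0, epochs.trial_end, rng, tt)
                    tr.append(sf.SpikeTrain(np.unique(np.r_[s1, s2]), tt, True, epochs))
            return sf.TrialEnsemble(tr)

        merged_multi = np.mean([
            sf.classify_selectivity(sf.bin_spike_ensemble(one_unit(rng_master)))
            .category == "multiphasic"
            for _ in range(n_rep)
        ])
        oracle_multi = np.mean([
            sf.classify_selectivity(sf.bin_spike_ensemble(oracle_unit(rng_master)))
            .category == "multiphasic"
            for _ in range(n_rep)
        ])
        assert merged_multi > 0.5
        # binomial agreement between the two estimates
        se = np.sqrt(2 * 0.25 / n_rep)
        assert abs(merged_multi - oracle_multi) < 4 * se


class TestResampleToRate:
    def test_target_above_current_rejected(self, epochs):
        st = sf.SpikeTrain(np.linspace(0.1, 5.0, 10), "left", epochs=epochs)
        with pytest.raises(ValueError, match="thinning"):
            sf.resample_to_rate(st, 100.0)

    def test_target_equal_is_identity(self, epochs):
        st = sf.SpikeTrain(np.linspace(0.1, 5.0, 10), "left", epochs=epochs)
        cur = st.n_spikes / (st.t_end - st.t_start)
        out = sf.resample_to_rate(st, cur, rng_seed=0)
        assert np.array_equal(out.spike_times, st.spike_times)

    def test_retained_fraction(self, epochs):
        """10 Hz thinned to 1 Hz keeps ~10% of spikes."""
        rng = np.random.default_rng(6)
        kept = total = 0
        for s in range(1000):
            st = sf.SpikeTrain(sf.sample_poisson_train(10.0, 0.0, 5.0, rng),
                               "left", epochs=epochs)
            cur = st.n_spikes / 5.0
            if cur < 1.0:
                continue
            out = sf.resample_to_rate(st, 1.0, rng_seed=s, current_rate=cur)
            kept += out.n_spikes
            total += st.n_spikes
        assert kept / total == pytest.approx(0.1, abs=0.01)

    def test_thinning_preserves_psth_shape(self, epochs):
        """Profile shape survives thinning: normalized PSTHs correlate."""
        prof = make_archetype("ramp_up", epochs, baseline=15.0, delta=30.0)
        rng = np.random.default_rng(8)
        trials, thinned = [], []
        for _ in range(300):
            st = sf.SpikeTrain(
                sf.sample_poisson_train(prof, 0.0, epochs.trial_end, rng, "right"),
                "right", epochs=epochs)
            trials.append(st)
            thinned.append(sf.resample_to_rate(st, 10.0, rng_seed=rng.integers(2**31),
                                               current_rate=25.0))
        p1 = sf.bin_spike_ensemble(sf.TrialEnsemble(trials)).matrix.mean(axis=0)
        p2 = sf.bin_spike_ensemble(sf.TrialEnsemble(thinned)).matrix.mean(axis=0)
        r = np.corrcoef(p1 / p1.max(), p2 / p2.max())[0, 1]
        assert r > 0.95


class TestSlowBaseline:
    def test_phasic_equal_baseline_unity_ratio(self):
        """No phasic modulation: plain peak/ramp ratio ~ 1 in spikes."""
        t = np.linspace(0, 6.07, 2000)
        r = np.where(t < 1, 3.0, np.where(t < 5, 3 + 0.5 * (t - 1), 5.0))
        r[(t >= 5.0) & (t < 5.07)] = 5.0
        ratio = sf.peak_over_ramp_ratio(t, r, 5.0)
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_spike_domain_ratio_by_construction(self):
        """On the true rate function the plain ratio is 30 / 5 = 6."""
        t = np.linspace(0, 6.07, 5000)
        r = np.where(t < 1, 3.0,
                     np.where(t < 5, 3 + 2 * (t - 1) / 4,
                              np.where(t < 5.07, 30.0, 3.0)))
        assert sf.peak_over_ramp_ratio(t, r, 5.0) == pytest.approx(6.0, rel=0.01)

    def test_fluorescence_reduces_detectability(self):
        """A slow sigmoidal transform shrinks the phasic-over-ramp ratio
        relative to the spike domain."""
        ens = sf.slow_baseline_scenario(n_trials=100, rng_seed=0)
        params = sf.default_distribution("6s", seed=0).samples[0]
        out = sf.slow_baseline_ratios(ens, params, rng_seed=0)
        assert out["fluor_ratio"] < out["spike_ratio"]
        assert out["reduction_factor"] > 1.0

    def test_scenario_rate_structure(self):
        ens = sf.slow_baseline_scenario(n_trials=400, rng_seed=3)
        b = sf.bin_spike_ensemble(ens, 0.1)
        psth = b.matrix.mean(axis=0)
        t = b.bin_centers
        assert psth[t < 1.0].mean() == pytest.approx(3.0, abs=0.5)
        assert psth[(t > 4.5) & (t < 4.9)].mean() == pytest.approx(4.8, abs=0.6)


class TestPeakinessSensitivitySet:
    def test_variant1_identical_noise_free_traces(self):
        ens, params = sf.peakiness_sensitivity_set(1, n_neurons=5, rng_seed=0)
        assert len({id(p) for p in params}) >= 1
        assert all(p == params[0] for p in params)
        t0 = ens[0].trials[0].spike_times
        for e in ens:
            for tr in e.trials:
                assert np.array_equal(tr.spike_times, t0)

    def test_variant2_jitter_stays_in_frame(self):
        ens, _ = sf.peakiness_sensitivity_set(2, n_neurons=5, rng_seed=0)
        ref = sf.peakiness_sensitivity_set(1, n_neurons=1, rng_seed=0)[0][0]
        frame = np.floor(ref.trials[0].spike_times[0] / sf.FRAME_INTERVAL)
        for e in ens:
            for tr in e.trials:
                frames = np.floor(tr.spike_times / sf.FRAME_INTERVAL)
                assert np.all(frames == frame)

    def test_variant6_spreads_parameters(self):
        _, params = sf.peakiness_sensitivity_set(6, n_neurons=30, rng_seed=1)
        assert np.var([p.tau_d for p in params]) > 0
        assert np.var([p.k for p in params]) > 0
        assert np.var([p.c_half for p in params]) > 0

    def test_variant3_rate_range(self):
        ens, _ = sf.peakiness_sensitivity_set(3, n_neurons=10, rng_seed=2,
                                              n_trials_per_type=40)
        rates = [e.mean_rate() for e in ens]
        assert min(rates) < 0.5 and max(rates) > 3.0

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="1..7"):
            sf.peakiness_sensitivity_set(9)
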