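"""Tests of ITC estimation, rate-bin extraction, peak contrasts, the TLI,
and per-channel topography, against analytic and Monte-Carlo oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

import tripletlearn as tl
from tripletlearn.design import TONE_RATE, TRIPLET_RATE
from tripletlearn.epochs import standard_epochs
from tripletlearn.fixtures import make_phase_epochs
from tripletlearn.spectral import (compute_itc, compute_tli, exact_bin,
                                   extract_rate_bins, itc_topography,
                                   peak_vs_neighbors, subject_tli)


def rayleigh_mean_itc(n, n_rep=10_000, seed=0):
    """Monte-Carlo oracle: E[ |mean of n uniform unit phasors| ]."""
    rng = np.random.default_rng(seed)
    ph = rng.uniform(0, 2 * np.pi, size=(n_rep, n))
    return np.abs(np.exp(1j * ph).mean(axis=1)).mean()


class TestComputeITC:
    def test_identical_phases_give_unit_itc(self):
        eps = make_phase_epochs(12, bin_index=6, phase_rule="identical")
        sp = compute_itc(eps)
        assert sp.itc[0, 6] == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_pairs_cancel(self):
        eps = make_phase_epochs(10, bin_index=6, phase_rule="alternating")
        sp = compute_itc(eps)
        assert sp.itc[0, 6] == pytest.approx(0.0, abs=1e-9)

    def test_uniform_phases_match_rayleigh_expectation(self):
        # analytic E[ITC] = sqrt(pi)/(2 sqrt(N)); N=100 -> 0.0886
        n, n_rep = 100, 300
        vals = [compute_itc(make_phase_epochs(
            n, bin_index=6, phase_rule="uniform", seed=s)).itc[0, 6]
            for s in range(n_rep)]
        analytic = np.sqrt(np.pi) / (2 * np.sqrt(n))
        oracle = rayleigh_mean_itc(n)
        assert analytic == pytest.approx(0.0886, abs=5e-4)
        assert oracle == pytest.approx(analytic, abs=2e-3)
        # MC error of the mean over n_rep replicates ~ 0.0463/sqrt(n_rep)
        assert np.mean(vals) == pytest.approx(oracle, abs=0.011)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6),
           seed=st.integers(min_value=0, max_value=10))
    def test_scaling_invariance(self, scale, seed):
        # ITC is a phase-only statistic: amplitude scaling cannot move it
        eps = make_phase_epochs(20, bin_index=9, phase_rule="uniform",
                                seed=seed)
        a = compute_itc(eps).itc
        eps.data = eps.data * scale
        b = compute_itc(eps).itc
        assert np.allclose(a, b)

    def test_common_time_shift_invariance(self):
        eps = make_phase_epochs(20, bin_index=9, phase_rule="uniform", seed=2)
        a = compute_itc(eps).itc
        eps.data = np.roll(eps.data, 17, axis=2)
        b = compute_itc(eps).itc
        assert np.allclose(a[0, 9], b[0, 9], atol=1e-6)

    def test_block_average_equals_single_block_when_identical(self):
        eps = make_phase_epochs(24, bin_index=6, phase_rule="uniform", seed=3)
        one = compute_itc(eps)
        eps2 = make_phase_epochs(24, bin_index=6, phase_rule="uniform",
                                 seed=3)
        eps2.blocks = np.repeat([0, 1], 12)
        # make block 1 an exact copy of block 0
        eps2.data[12:] = eps2.data[:12]
        two = compute_itc(eps2)
        single = compute_itc(make_phase_epochs(12, bin_index=6,
                                               phase_rule="uniform", seed=3))
        assert np.allclose(two.itc, single.itc)
        assert not np.allclose(one.itc[0, 6], two.itc[0, 6])

    def test_surrogate_null_distribution_is_rayleigh(self):
        # ITC of phase-randomized epochs follows the Rayleigh null
        n, n_sets = 20, 150
        vals = np.array([compute_itc(make_phase_epochs(
            n, bin_index=6, phase_rule="uniform", seed=100 + s)).itc[0, 6]
            for s in range(n_sets)])
        rng = np.random.default_rng(9)
        ph = rng.uniform(0, 2 * np.pi, size=(n_sets * 10, n))
        oracle = np.abs(np.exp(1j * ph).mean(axis=1))
        ks = sst.ks_2samp(vals, oracle)
        assert ks.pvalue > 0.01

    def test_too_few_epochs_rejected(self):
        eps = make_phase_epochs(1, bin_index=6)
        with pytest.raises(ValueError):
            compute_itc(eps)

    def test_complex_average_mode_bounded(self):
        eps = make_phase_epochs(30, bin_index=6, phase_rule="uniform", seed=4)
        sp = compute_itc(eps, mode="complex-average")
        assert np.all(sp.itc >= 0) and np.all(sp.itc <= 1 + 1e-12)
        with pytest.raises(ValueError):
            compute_itc(eps, mode="nonsense")


class TestRateBins:
    def test_exact_bins_for_5p4s_epochs(self):
        assert exact_bin(5.4, TONE_RATE) == 18
        assert exact_bin(5.4, TRIPLET_RATE) == 6
        eps = make_phase_epochs(4, bin_index=6)
        sp = compute_itc(eps)
        assert round(sp.freqs[18], 2) == 3.33
        assert round(sp.freqs[6], 2) == 1.11
        assert sp.freqs[1] == pytest.approx(1 / 5.4)
        bins = extract_rate_bins(sp)
        assert bins["bin_tone"] == 18 and bins["bin_triplet"] == 6
        assert set(bins["harmonics"]) == {2.22, 4.44}

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            exact_bin(5.0, TONE_RATE)


class TestPeakVsNeighbors:
    def test_control_frequencies_around_tone_peak(self):
        rng = np.random.default_rng(5)
        itcs = rng.uniform(0.1, 0.2, size=(6, 28))
        itcs[:, 18] += 0.3
        res = peak_vs_neighbors(itcs, 5.4, TONE_RATE, offset_bins=2)
        assert round(res.control_freqs[0], 2) == 2.96
        assert round(res.control_freqs[1], 2) == 3.70
        assert res.p < 0.01 and res.d > 0

    def test_triplet_peak_control_frequencies(self):
        rng = np.random.default_rng(6)
        itcs = rng.uniform(0.1, 0.2, size=(5, 28))
        res = peak_vs_neighbors(itcs, 5.4, TRIPLET_RATE, offset_bins=2)
        # +-2 bins from 1.11 Hz: 0.74 and 1.48 Hz on the exact grid
        assert round(res.control_freqs[0], 2) == 0.74
        assert round(res.control_freqs[1], 2) == 1.48

    def test_zero_contrasts_boundary(self):
        itcs = np.full((4, 28), 0.2)
        res = peak_vs_neighbors(itcs, 5.4, TONE_RATE)
        assert res.t == 0.0 and res.p == 0.5 and res.d == 0.0

    def test_offset_out_of_range(self):
        itcs = np.full((4, 20), 0.2)
        with pytest.raises(ValueError):
            peak_vs_neighbors(itcs, 5.4, TONE_RATE, offset_bins=3)
        with pytest.raises(ValueError):
            peak_vs_neighbors(itcs[:2], 5.4, TONE_RATE)


class TestTLI:
    def test_ratio_arithmetic(self):
        assert compute_tli(0.5, 0.5).tli == pytest.approx(1.0)
        assert compute_tli(0.2, 0.5).tli == pytest.approx(0.4)

    def test_zero_tone_itc_rejected(self):
        with pytest.raises(ValueError):
            compute_tli(0.2, 0.0)

    def test_null_subject_tli_matches_rayleigh_ratio(self):
        # no triplet modulation, heavy *white* noise (independent epochs):
        # both bins sit at the same Rayleigh floor, so the null TLI is
        # the ratio of two i.i.d. floor ITCs with median ~ 1.  (With 1/f
        # noise adjacent epochs correlate at low frequencies and the
        # triplet-rate floor rises above the tone-rate floor.)
        spec = tl.SequenceSpec(n_blocks=1, triplets_per_block=120,
                               p_statistical=0, p_acoustic=0, p_double=0,
                               targets_per_block=0, seed=21)
        ev = tl.generate_sequence(spec)
        tlis = []
        for s in range(12):
            prof = tl.SubjectProfile(seed=s, tone_lock=0.0, triplet_lock=0.0,
                                     noise_amplitude=3000.0,
                                     noise_exponent=0.0, artifact_rate=0.0)
            rec = tl.simulate_recording(ev, prof, srate=100.0)
            eps, _ = standard_epochs(rec, threshold=np.inf)
            tlis.append(subject_tli(compute_itc(eps)).tli)
        # MC oracle for the median of the ratio of two i.i.d. Rayleigh
        # floor ITCs (N = 20 epochs)
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 2 * np.pi, size=(2, 4000, 20))
        floor = np.abs(np.exp(1j * ph).mean(axis=2))
        ratio_median = np.median(floor[0] / floor[1])
        assert ratio_median == pytest.approx(1.0, abs=0.1)
        assert np.median(tlis) == pytest.approx(ratio_median, abs=0.5)


class TestTopography:
    def test_frontocentral_gain_visible_at_tone_bin(self, small_events):
        prof = tl.SubjectProfile(seed=4, artifact_rate=0.0)
        rec = tl.simulate_recording(small_events, prof, srate=100.0)
        eps, _ = standard_epochs(rec, cluster=False)
        topo = itc_topography(eps)
        inside = topo.loc[topo["in_cluster"], "itc_tone"].mean()
        outside = topo.loc[~topo["in_cluster"], "itc_tone"].mean()
        assert inside >= outside

    def test_identical_channels_identical_itc(self):
        eps = make_phase_epochs(8, bin_index=6, phase_rule="uniform", seed=7)
        data = np.repeat(eps.data, 3, axis=1)
        eps.data = data
        eps.ch_names = ["Cz", "C1", "C2"]
        sp = compute_itc(eps)
        assert np.allclose(sp.itc[0], sp.itc[1])
        assert np.allclose(sp.itc[0], sp.itc[2])

    def test_pure_noise_channel_near_rayleigh_floor(self):
        rng = np.random.default_rng(8)
        n = 40
        eps = make_phase_epochs(n, bin_index=6, phase_rule="uniform", seed=9)
        eps.data = rng.standard_normal(eps.data.shape)
        sp = compute_itc(eps)
        floor = np.sqrt(np.pi) / (2 * np.sqrt(n))
        assert sp.itc[0, 18] < 3 * floor
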