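"""Tests of triplet selection, excision, de-meaning, epoching, rejection,
and cluster averaging against hand-derived oracles."""

import numpy as np
import pandas as pd
import pytest

import tripletlearn as tl
from tripletlearn.epochs import (EpochSet, cluster_average, cut_epochs,
                                 demean_per_tone, excise_and_concatenate,
                                 reject_epochs,
                                 select_standard_triplets, standard_epochs)
from tripletlearn.fixtures import make_toy_block
from tripletlearn.simulate import FRONTOCENTRAL, simulate_recording

from conftest import build_recording


class TestSelection:
    def test_hand_derived_keep_drop_sets(self):
        # 8 triplets, deviants at 3 and 4, target in 7 (1-based):
        # kept {1,2,6,8}; 3,4 deviant; 5 post-deviant; 7 target
        toy = make_toy_block(8, deviant_triplets=(3, 4),
                             target_triplets=(7,))
        sel = select_standard_triplets(toy).set_index("triplet_index")
        assert list(sel.index[sel["keep"]]) == [0, 1, 5, 7]
        assert sel.loc[2, "reason"] == "deviant"
        assert sel.loc[3, "reason"] == "deviant"
        assert sel.loc[4, "reason"] == "post_deviant"
        assert sel.loc[6, "reason"] == "target"

    def test_all_standard_all_kept(self):
        sel = select_standard_triplets(make_toy_block(5))
        assert sel["keep"].all()

    def test_all_deviant_none_kept(self):
        sel = select_standard_triplets(
            make_toy_block(4, deviant_triplets=(1, 2, 3, 4)))
        assert not sel["keep"].any()

    def test_blocks_are_independent(self):
        # deviant in the last triplet of block 0 must not taint block 1
        b0 = make_toy_block(3, deviant_triplets=(3,), block=0)
        b1 = make_toy_block(3, block=1)
        events = pd.concat([b0, b1], ignore_index=True)
        sel = select_standard_triplets(events)
        first_of_b1 = sel[(sel["block"] == 1) & (sel["triplet_index"] == 0)]
        assert first_of_b1["keep"].item()


def _toy_recording_for(events, srate=100.0, fill=None):
    n_tri = events["triplet_index"].max() + 1
    n_samp = int(round(n_tri * 0.9 * srate)) + 50
    if fill is None:
        rng = np.random.default_rng(0)
        data = rng.standard_normal((17, n_samp))
    else:
        data = np.tile(fill[:n_samp], (17, 1))
    return build_recording(data, srate=srate, events=events,
                           block_bounds=[(0, n_samp)])


class TestExcision:
    def test_all_kept_is_identity_per_block(self):
        events = make_toy_block(4)
        rec = _toy_recording_for(events, srate=100.0)
        sel = select_standard_triplets(events)
        std = excise_and_concatenate(rec, sel)
        assert np.array_equal(std.blocks[0],
                              rec.signal[:, :4 * 90])

    def test_keep_two_of_three_lengths(self):
        # keep triplets {1,3}: target in the middle one drops only itself
        events = make_toy_block(3, target_triplets=(2,))
        rec = _toy_recording_for(events, srate=500.0)
        sel = select_standard_triplets(events)
        assert list(sel["keep"]) == [True, False, True]
        std = excise_and_concatenate(rec, sel)
        assert std.blocks[0].shape[1] == 2 * 450
        # retained samples bit-identical, in original order
        assert np.array_equal(std.blocks[0][:, :450], rec.signal[:, :450])
        assert np.array_equal(std.blocks[0][:, 450:],
                              rec.signal[:, 900:1350])

    def test_keep_none_yields_empty(self):
        events = make_toy_block(2, deviant_triplets=(1, 2))
        rec = _toy_recording_for(events)
        std = excise_and_concatenate(rec, select_standard_triplets(events))
        assert std.blocks[0].shape[1] == 0
        with pytest.raises(ValueError):
            tl.compute_itc(cut_epochs(std))

    def test_unsupported_srate_rejected(self):
        events = make_toy_block(2)
        rec = _toy_recording_for(events, srate=100.0)
        rec.srate = 125.0   # 0.3 s * 125 = 37.5 samples: not representable
        with pytest.raises(ValueError):
            excise_and_concatenate(rec, select_standard_triplets(events))


class TestDemean:
    def _std(self, values_per_window, srate=100.0):
        """StandardSignal with one block whose 300-ms windows carry the
        given per-window sample values."""
        spw = int(round(0.3 * srate))
        sig = np.concatenate([np.asarray(v, dtype=float) if np.ndim(v)
                              else np.full(spw, float(v))
                              for v in values_per_window])
        events = make_toy_block(len(values_per_window) // 3)
        rec = build_recording(np.tile(sig, (17, 1)), srate=srate,
                              events=events,
                              block_bounds=[(0, sig.size)])
        sel = select_standard_triplets(events)
        return excise_and_concatenate(rec, sel)

    def test_constant_signal_becomes_zero(self):
        std = self._std([7.0] * 6)
        out = demean_per_tone(std)
        assert np.allclose(out.blocks[0], 0.0)

    def test_piecewise_constant_per_window_becomes_zero(self):
        std = self._std([1.0, -2.0, 3.0, 4.0, -5.0, 6.0])
        out = demean_per_tone(std)
        assert np.allclose(out.blocks[0], 0.0)

    def test_ramp_minus_mean(self):
        spw = 30
        ramp = np.arange(spw, dtype=float)
        std = self._std([ramp, 0.0, 0.0, 0.0, 0.0, 0.0])
        out = demean_per_tone(std)
        assert np.allclose(out.blocks[0][:, :spw], ramp - ramp.mean())
        assert np.allclose(out.blocks[0][:, spw:], 0.0)

    def test_non_tiling_registry_rejected(self):
        std = self._std([1.0] * 6)
        std.registry = std.registry.iloc[:-1]
        with pytest.raises(ValueError):
            demean_per_tone(std)


class TestCutAndReject:
    def _epochs_from(self, n_triplets, srate=100.0):
        events = make_toy_block(n_triplets)
        rec = _toy_recording_for(events, srate=srate)
        std = excise_and_concatenate(rec, select_standard_triplets(events))
        return cut_epochs(std)

    @pytest.mark.parametrize("n_triplets,n_epochs", [
        (13, 2),   # floor(13/6)
        (6, 1),
        (5, 0),
    ])
    def test_epoch_counts(self, n_triplets, n_epochs):
        eps = self._epochs_from(n_triplets)
        assert eps.n_epochs == n_epochs
        if n_epochs:
            assert eps.data.shape[2] == round(5.4 * eps.srate)

    def test_epochs_are_unmodified_slices(self):
        events = make_toy_block(12)
        rec = _toy_recording_for(events)
        std = excise_and_concatenate(rec, select_standard_triplets(events))
        eps = cut_epochs(std)
        # selection/excision/epoching never alter sample values
        assert np.array_equal(eps.data[0], rec.signal[:, :540])
        assert np.array_equal(eps.data[1], rec.signal[:, 540:1080])

    def test_reject_none_when_quiet(self):
        eps = EpochSet(data=np.zeros((3, 1, 540)), srate=100.0,
                       ch_names=["FC-cluster"], blocks=np.zeros(3, int),
                       last_triplet_index=np.arange(3) * 6 + 5,
                       retained_count=(np.arange(3) + 1) * 6)
        kept, dropped = reject_epochs(eps)
        assert dropped == 0 and kept.n_epochs == 3

    def test_reject_exactly_the_spiked_epoch(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((4, 1, 540))
        data[2, 0, 100] += 400.0
        eps = EpochSet(data=data, srate=100.0, ch_names=["FC-cluster"],
                       blocks=np.zeros(4, int),
                       last_triplet_index=np.arange(4) * 6 + 5,
                       retained_count=(np.arange(4) + 1) * 6)
        kept, dropped = reject_epochs(eps, threshold=300.0)
        assert dropped == 1
        assert np.array_equal(kept.retained_count, [6, 12, 24])

    def test_infinite_threshold_keeps_all(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((5, 1, 540)) * 1e4
        eps = EpochSet(data=data, srate=100.0, ch_names=["FC-cluster"],
                       blocks=np.zeros(5, int),
                       last_triplet_index=np.arange(5) * 6 + 5,
                       retained_count=(np.arange(5) + 1) * 6)
        kept, dropped = reject_epochs(eps, threshold=np.inf)
        assert dropped == 0

    def test_all_rejected_raises(self):
        data = np.zeros((2, 1, 540))
        data[:, 0, 0] = 1000.0
        eps = EpochSet(data=data, srate=100.0, ch_names=["FC-cluster"],
                       blocks=np.zeros(2, int),
                       last_triplet_index=np.arange(2) * 6 + 5,
                       retained_count=(np.arange(2) + 1) * 6)
        with pytest.raises(ValueError):
            reject_epochs(eps, threshold=300.0)


class TestClusterAverage:
    def _eps(self, data):
        from tripletlearn.simulate import default_montage
        names = default_montage().ch_names
        return EpochSet(data=data, srate=100.0, ch_names=names,
                        blocks=np.zeros(data.shape[0], int),
                        last_triplet_index=np.arange(data.shape[0]) * 6 + 5,
                        retained_count=(np.arange(data.shape[0]) + 1) * 6)

    def test_identical_channels_pass_through(self):
        rng = np.random.default_rng(3)
        s = rng.standard_normal(540)
        data = np.tile(s, (2, 17, 1))
        out = cluster_average(self._eps(data))
        assert out.data.shape[1] == 1
        assert np.allclose(out.data[0, 0], s)

    def test_opposite_channels_cancel(self):
        from tripletlearn.simulate import default_montage
        names = default_montage().ch_names
        data = np.zeros((1, 17, 540))
        v = np.sin(np.linspace(0, 10, 540))
        data[0, names.index("F1")] = v
        data[0, names.index("F2")] = -v
        out = cluster_average(self._eps(data))
        assert np.allclose(out.data, 0.0)

    def test_matches_brute_force_mean(self):
        from tripletlearn.simulate import default_montage
        names = default_montage().ch_names
        rng = np.random.default_rng(4)
        data = rng.standard_normal((3, 17, 540))
        out = cluster_average(self._eps(data))
        idx = [names.index(c) for c in FRONTOCENTRAL]
        assert np.allclose(out.data[:, 0, :], data[:, idx, :].mean(axis=1))

    def test_missing_channel_named_in_error(self):
        data = np.zeros((1, 2, 540))
        eps = EpochSet(data=data, srate=100.0, ch_names=["Cz", "M1"],
                       blocks=np.zeros(1, int),
                       last_triplet_index=np.array([5]),
                       retained_count=np.array([6]))
        with pytest.raises(ValueError, match="F1"):
            cluster_average(eps)


def test_pipeline_epoch_count_bound(small_events):
    rec = tl.simulate_recording(small_events, tl.SubjectProfile(seed=2),
                                srate=100.0)
    eps, log = standard_epochs(rec)
    sel = select_standard_triplets(small_events)
    bound = sum(int(s["keep"].sum()) // 6
                for _, s in sel.groupby("block"))
    assert eps.n_epochs <= bound
    assert log["n_kept_triplets"] == int(sel["keep"].sum())
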