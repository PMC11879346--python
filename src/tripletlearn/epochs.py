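"""Standard-triplet selection, excision, per-tone de-meaning, 5.4-s
epoching, and peak-to-peak rejection.

The analysis keeps only *standard* triplets: triplets containing any
deviant (statistical, acoustic, double) are dropped, triplets
immediately following a deviant triplet are dropped, and triplets
containing a behavioral target tone are dropped.  The 0.9-s spans of
the retained triplets are excised from the continuous data and
concatenated in order within each block; the splice discontinuities are
attenuated by de-meaning each 0-300 ms tone window; finally
non-overlapping epochs of 6 triplets (5.4 s, 18 tones) are cut within
blocks and epochs whose peak-to-peak amplitude exceeds 300 uV are
rejected.

The pipeline order is fixed:
select -> excise -> re-reference -> de-mean -> epoch -> reject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import rereference_array
from .simulate import FRONTOCENTRAL, Recording

EPOCH_TRIPLETS = 6
EPOCH_LENGTH = 5.4          # seconds, = 6 triplets x 0.9 s
P2P_THRESHOLD = 300.0       # uV
_SOA = 0.300


def _samples_per_soa(srate: float) -> int:
    spw = _SOA * srate
    if abs(spw - round(spw)) > 1e-9:
        raise ValueError(
            f"srate {srate} Hz gives a non-integer number of samples per "
            "300-ms tone window; use a rate with srate*0.3 integer "
            "(e.g. 100, 200, 500 Hz)")
    return int(round(spw))


def select_standard_triplets(events: pd.DataFrame) -> pd.DataFrame:
    """Per-triplet keep/drop flags with drop reasons.

    Reasons (first matching wins): ``deviant`` for any deviant triplet,
    ``post_deviant`` for the triplet immediately following a deviant
    triplet within the same block, ``target`` for triplets containing a
    target tone.  Blocks are independent: the first triplet of a block
    is never post_deviant.
    """
    if events is None or len(events) == 0:
        raise ValueError("empty event table")
    per = (events.sort_values(["block", "triplet_index", "position"])
           .groupby(["block", "triplet_index"], sort=True))
    tab = pd.DataFrame({
        "is_deviant": per[["is_statistical_deviant", "is_acoustic_deviant",
                           "is_double_deviant"]].any().any(axis=1),
        "has_target": per["is_target"].any(),
        "triplet_id": per["triplet_id"].first(),
        "onset": per["onset"].first(),
    }).reset_index()
    post = (tab.groupby("block")["is_deviant"].shift(1, fill_value=False))
    reason = np.select(
        [tab["is_deviant"], post, tab["has_target"]],
        ["deviant", "post_deviant", "target"], default="",
    )
    tab["reason"] = reason
    tab["keep"] = reason == ""
    return tab[["block", "triplet_index", "triplet_id", "onset",
                "keep", "reason"]]


@dataclass
class StandardSignal:
    """Excised, concatenated standard-only continuous data per block.

    ``registry`` has one row per retained tone: block, retained triplet
    ordinal (within block), original triplet_index, position (1-3), and
    ``sample`` = onset sample in the block's concatenated signal.
    """

    blocks: dict[int, np.ndarray]       # block -> (n_channels, n_samples)
    registry: pd.DataFrame
    srate: float
    ch_names: list[str]

    def n_retained(self, block: int) -> int:
        reg = self.registry
        return int((reg["block"] == block).sum()) // 3


def excise_and_concatenate(recording: Recording,
                           selection: pd.DataFrame) -> StandardSignal:
    """Cut the 0.9-s span of every kept triplet and concatenate in order.

    Retained samples are bit-identical to the input.
    """
    spw = _samples_per_soa(recording.srate)
    span = 3 * spw
    blocks: dict[int, np.ndarray] = {}
    reg_rows = []
    for b, sel in selection.groupby("block"):
        start_b, stop_b = recording.block_bounds[int(b)]
        kept = sel[sel["keep"]]
        pieces = []
        for out_ord, (_, row) in enumerate(kept.iterrows()):
            s0 = start_b + int(round(row["onset"] * recording.srate))
            if s0 + span > stop_b:
                raise ValueError(
                    f"triplet {int(row['triplet_index'])} of block {b} "
                    "extends past the recorded samples")
            pieces.append(recording.signal[:, s0:s0 + span])
            for pos in range(3):
                reg_rows.append((int(b), out_ord, int(row["triplet_index"]),
                                 pos + 1, out_ord * span + pos * spw))
        blocks[int(b)] = (np.concatenate(pieces, axis=1) if pieces
                          else np.empty((recording.signal.shape[0], 0)))
    registry = pd.DataFrame(
        reg_rows, columns=["block", "retained_ordinal", "triplet_index",
                           "position", "sample"])
    return StandardSignal(blocks=blocks, registry=registry,
                          srate=recording.srate, ch_names=recording.ch_names)


def rereference_standard(std: StandardSignal,
                         reference=("M1", "M2")) -> StandardSignal:
    """Mastoid re-referencing of the excised continuous data."""
    blocks = {b: rereference_array(sig, std.ch_names, reference)
              for b, sig in std.blocks.items()}
    return StandardSignal(blocks=blocks, registry=std.registry,
                          srate=std.srate, ch_names=std.ch_names)


def demean_per_tone(std: StandardSignal) -> StandardSignal:
    """Subtract the mean of each 0-300 ms tone window, per channel.

    The windows must tile each block's signal exactly (they do by
    construction after excision); enforced before reshaping.
    """
    spw = _samples_per_soa(std.srate)
    out = {}
    for b, sig in std.blocks.items():
        n_ch, n_samp = sig.shape
        reg = std.registry[std.registry["block"] == b]
        if n_samp != len(reg) * spw:
            raise ValueError(f"registry does not tile block {b} signal "
                             f"({len(reg)} tones x {spw} != {n_samp})")
        if n_samp == 0:
            out[b] = sig.copy()
            continue
        expected = np.arange(len(reg)) * spw
        if not np.array_equal(np.sort(reg["sample"].to_numpy()), expected):
            raise ValueError(f"overlapping or non-tiling registry in block {b}")
        w = sig.reshape(n_ch, -1, spw)
        out[b] = (w - w.mean(axis=2, keepdims=True)).reshape(n_ch, n_samp)
    return StandardSignal(blocks=out, registry=std.registry,
                          srate=std.srate, ch_names=std.ch_names)


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch provenance.

    ``last_triplet_index`` is the original within-block ordinal of the
    last triplet covered by the epoch; ``retained_count`` the number of
    retained triplets up to and including the epoch, within its block.
    """

    data: np.ndarray            # (n_epochs, n_channels, n_samples)
    srate: float
    ch_names: list[str]
    blocks: np.ndarray          # per-epoch block index
    last_triplet_index: np.ndarray
    retained_count: np.ndarray
    epoch_length: float = EPOCH_LENGTH

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(data=self.data[mask], srate=self.srate,
                        ch_names=list(self.ch_names),
                        blocks=self.blocks[mask],
                        last_triplet_index=self.last_triplet_index[mask],
                        retained_count=self.retained_count[mask],
                        epoch_length=self.epoch_length)


def cut_epochs(std: StandardSignal,
               triplets_per_epoch: int = EPOCH_TRIPLETS) -> EpochSet:
    """Group consecutive retained triplets into non-overlapping epochs.

    Leftover triplets (< triplets_per_epoch) at a block end are
    discarded; epochs never span block boundaries and always start at a
    triplet-initial tone onset.
    """
    spw = _samples_per_soa(std.srate)
    span = 3 * spw
    ep_len = triplets_per_epoch * span
    data, blocks, last_tri, ret_count = [], [], [], []
    for b in sorted(std.blocks):
        sig = std.blocks[b]
        reg = std.registry[std.registry["block"] == b]
        n_tri = len(reg) // 3
        n_ep = n_tri // triplets_per_epoch
        tri_orig = (reg[reg["position"] == 1]
                    .sort_values("retained_ordinal")["triplet_index"]
                    .to_numpy())
        for k in range(n_ep):
            data.append(sig[:, k * ep_len:(k + 1) * ep_len])
            blocks.append(b)
            last_tri.append(int(tri_orig[(k + 1) * triplets_per_epoch - 1]))
            ret_count.append((k + 1) * triplets_per_epoch)
    n_ch = len(std.ch_names)
    arr = (np.stack(data) if data
           else np.empty((0, n_ch, ep_len)))
    return EpochSet(data=arr, srate=std.srate, ch_names=list(std.ch_names),
                    blocks=np.asarray(blocks, dtype=int),
                    last_triplet_index=np.asarray(last_tri, dtype=int),
                    retained_count=np.asarray(ret_count, dtype=int),
                    epoch_length=ep_len / std.srate)


def reject_epochs(epochs: EpochSet, threshold: float = P2P_THRESHOLD
                  ) -> tuple[EpochSet, int]:
    """Drop epochs whose peak-to-peak amplitude exceeds the threshold.

    Evaluated on every channel present: if the set was cluster-averaged
    first, this is the cluster-average criterion; on multichannel sets
    any offending channel rejects the epoch.  Returns (kept, n_dropped).
    """
    if epochs.n_epochs == 0:
        return epochs, 0
    p2p = epochs.data.max(axis=2) - epochs.data.min(axis=2)
    bad = (p2p > threshold).any(axis=1)
    if bad.all():
        raise ValueError(
            f"all {epochs.n_epochs} epochs exceed the {threshold} uV "
            "peak-to-peak threshold; check amplitude units/filtering")
    return epochs.select(~bad), int(bad.sum())


def cluster_average(epochs: EpochSet,
                    channels: tuple[str, ...] = FRONTOCENTRAL) -> EpochSet:
    """Unweighted mean over the fronto-central cluster channels."""
    missing = [c for c in channels if c not in epochs.ch_names]
    if missing:
        raise ValueError(f"cluster channel(s) missing: {missing}")
    idx = [epochs.ch_names.index(c) for c in channels]
    avg = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return EpochSet(data=avg, srate=epochs.srate, ch_names=["FC-cluster"],
                    blocks=epochs.blocks,
                    last_triplet_index=epochs.last_triplet_index,
                    retained_count=epochs.retained_count,
                    epoch_length=epochs.epoch_length)


def standard_epochs(recording: Recording, *, cluster: bool = True,
                    threshold: float = P2P_THRESHOLD,
                    triplets_per_epoch: int = EPOCH_TRIPLETS,
                    reference=("M1", "M2")) -> tuple[EpochSet, dict]:
    """The fixed-order epoching pipeline for one (preprocessed) recording.

    select -> excise -> re-reference -> de-mean -> epoch
    [-> cluster-average] -> reject.  With ``cluster=True`` the rejection
    criterion is evaluated on the cluster-average signal (the analysis
    signal); with ``cluster=False`` all channels are kept and rejection
    is per-channel (topography mode).
    """
    selection = select_standard_triplets(recording.events)
    std = excise_and_concatenate(recording, selection)
    std = rereference_standard(std, reference)
    std = demean_per_tone(std)
    eps = cut_epochs(std, triplets_per_epoch)
    if cluster:
        eps = cluster_average(eps)
    eps, n_dropped = reject_epochs(eps, threshold)
    log = {
        "n_triplets": len(selection),
        "n_kept_triplets": int(selection["keep"].sum()),
        "drop_reasons": selection.loc[~selection["keep"], "reason"]
        .value_counts().to_dict(),
        "n_epochs_before_rejection": eps.n_epochs + n_dropped,
        "n_epochs_rejected": n_dropped,
    }
    return eps, log
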