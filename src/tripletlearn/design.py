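"""Triplet-structured tone sequence design.

A continuous stream of six tones (labelled A-F) is organised into two
hidden triplets (e.g. ABC and DEF) presented back to back at a constant
stimulus onset asynchrony of 300 ms (220 ms tone + 80 ms silence), so the
tone rate is 3.33 Hz and the triplet rate 1.11 Hz.  Transitional
probabilities are the only segmentation cue: within a triplet they are
high (100% first-to-second, 90% second-to-third once deviants are in
place), between triplets the successor is drawn independently (50%).

Occasionally the final tone of a triplet deviates: a *statistical*
deviant swaps in the other triplet's final tone, an *acoustic* deviant
keeps the identity but changes apparent location, and a *double* deviant
does both.  A sparse target tone (for the behavioral detection task)
replaces single tones at positions balanced across the experiment.

Deviant categories are assigned by exact counts per block (round(p * n))
rather than per-triplet Bernoulli draws so that design percentages hold
exactly in every block.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

TONE_LABELS = ("A", "B", "C", "D", "E", "F")
TARGET_LABEL = "target"

#: stimulus onset asynchrony implied by the default tone/ISI durations (s)
SOA = 0.300
TONE_RATE = 1.0 / SOA          # 3.333... Hz
TRIPLET_RATE = 1.0 / (3 * SOA)  # 1.111... Hz

EVENT_COLUMNS = [
    "onset", "duration", "trial_type", "block", "triplet_index",
    "triplet_id", "position", "tone_id",
    "is_statistical_deviant", "is_acoustic_deviant", "is_double_deviant",
    "is_target",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Design parameters of the tone-triplet experiment.

    Defaults reproduce the published design: 6 blocks of 400 triplets,
    8% statistical / 18% acoustic / 2% double deviants, 8 targets per
    block (48 in total), 36 min of exposure.
    """

    n_blocks: int = 6
    triplets_per_block: int = 400
    tone_duration: float = 0.220
    isi: float = 0.080
    n_tones: int = 6
    p_statistical: float = 0.08
    p_acoustic: float = 0.18
    p_double: float = 0.02
    targets_per_block: int = 8
    seed: int = 0
    counterbalance_id: int = 0

    @property
    def soa(self) -> float:
        return self.tone_duration + self.isi

    @property
    def deviant_counts(self) -> tuple[int, int, int]:
        """Exact per-block counts (statistical, acoustic, double)."""
        return (
            round(self.p_statistical * self.triplets_per_block),
            round(self.p_acoustic * self.triplets_per_block),
            round(self.p_double * self.triplets_per_block),
        )

    def validate(self) -> None:
        if self.n_blocks < 1 or self.triplets_per_block < 1:
            raise ValueError("need at least one block of one triplet")
        if self.n_tones != 6:
            raise ValueError("the design uses exactly six tones (two triplets)")
        if not (self.tone_duration > 0 and self.isi >= 0):
            raise ValueError("tone_duration must be > 0 and isi >= 0")
        if not 0 <= self.p_statistical + self.p_acoustic + self.p_double < 1:
            raise ValueError("deviant probabilities must sum to < 1")
        n_stat, n_ac, n_dbl = self.deviant_counts
        n_dev = n_stat + n_ac + n_dbl
        if n_dev >= self.triplets_per_block:
            raise ValueError(
                f"deviant counts ({n_stat}+{n_ac}+{n_dbl}) do not leave room "
                f"for standard triplets in a block of {self.triplets_per_block}"
            )
        if self.targets_per_block > self.triplets_per_block - n_dev:
            raise ValueError(
                "not enough standard triplets to host "
                f"{self.targets_per_block} targets per block"
            )
        if self.targets_per_block < 0:
            raise ValueError("targets_per_block must be >= 0")


def counterbalance_scheme(counterbalance_id: int) -> dict[int, tuple[str, str, str]]:
    """Return the tone->triplet assignment for a counterbalancing id.

    Schemes enumerate the 10 partitions of the six tones into two triplets
    (triplet 1 always contains tone A) crossed with the 6 within-triplet
    position permutations applied to both triplets: 60 schemes, indexed
    modulo 60.
    """
    partitions = [c for c in itertools.combinations(TONE_LABELS, 3) if "A" in c]
    perms = list(itertools.permutations(range(3)))
    p_idx, perm_idx = divmod(int(counterbalance_id) % 60, 6)
    first = partitions[p_idx]
    second = tuple(t for t in TONE_LABELS if t not in first)
    perm = perms[perm_idx]
    return {
        1: tuple(first[i] for i in perm),
        2: tuple(second[i] for i in perm),
    }


def _target_positions(spec: SequenceSpec, rng: np.random.Generator) -> list[int]:
    """Within-triplet positions (1..3) for all targets, balanced overall."""
    total = spec.n_blocks * spec.targets_per_block
    pos = np.tile([1, 2, 3], math.ceil(total / 3))[:total]
    rng.shuffle(pos)
    return pos.tolist()


def generate_sequence(spec: SequenceSpec) -> pd.DataFrame:
    """Generate the full event table for one participant.

    Returns a DataFrame with one row per tone (see EVENT_COLUMNS); the
    spec is attached as ``events.attrs['spec']``.  Onsets are seconds
    from block start.  Triplet identities are drawn i.i.d. (immediate
    repetitions allowed); deviant categories are mutually exclusive and
    assigned by exact counts; targets land only in standard triplets,
    one per triplet.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    scheme = counterbalance_scheme(spec.counterbalance_id)
    n_stat, n_ac, n_dbl = spec.deviant_counts
    tgt_positions = iter(_target_positions(spec, rng))

    rows: list[tuple] = []
    for block in range(spec.n_blocks):
        tpb = spec.triplets_per_block
        triplet_ids = rng.integers(1, 3, size=tpb)
        order = rng.permutation(tpb)
        stat_idx = set(order[:n_stat])
        ac_idx = set(order[n_stat:n_stat + n_ac])
        dbl_idx = set(order[n_stat + n_ac:n_stat + n_ac + n_dbl])
        standard = [i for i in range(tpb)
                    if i not in stat_idx and i not in ac_idx and i not in dbl_idx]
        target_triplets = dict.fromkeys(
            rng.choice(standard, size=spec.targets_per_block, replace=False))
        for t in target_triplets:
            target_triplets[t] = next(tgt_positions)

        for i in range(tpb):
            tid = int(triplet_ids[i])
            other = 2 if tid == 1 else 1
            tones = list(scheme[tid])
            is_stat = i in stat_idx
            is_dbl = i in dbl_idx
            is_ac = i in ac_idx
            if is_stat or is_dbl:  # identity replacement by the other final tone
                tones[2] = scheme[other][2]
            tgt_pos = target_triplets.get(i)
            for pos in range(3):
                tone_id = tones[pos]
                is_target = tgt_pos == pos + 1
                if is_target:
                    tone_id = TARGET_LABEL
                flag_row = pos == 2  # deviant flags live on the final tone
                trial_type = "standard"
                if is_target:
                    trial_type = "target"
                elif flag_row and is_dbl:
                    trial_type = "double_deviant"
                elif flag_row and is_stat:
                    trial_type = "statistical_deviant"
                elif flag_row and is_ac:
                    trial_type = "acoustic_deviant"
                rows.append((
                    i * 3 * spec.soa + pos * spec.soa,
                    spec.tone_duration, trial_type, block, i, tid, pos + 1,
                    tone_id,
                    flag_row and is_stat, flag_row and is_ac,
                    flag_row and is_dbl, is_target,
                ))

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events.attrs["spec"] = spec
    return events


def total_exposure(spec: SequenceSpec) -> float:
    """Total stimulation time in seconds (n_blocks x triplets x 3 x SOA)."""
    spec.validate()
    return spec.n_blocks * spec.triplets_per_block * 3 * spec.soa


def _triplet_category(sub: pd.DataFrame) -> str:
    last = sub.iloc[2]
    if last.is_double_deviant:
        return "double"
    if last.is_statistical_deviant:
        return "statistical"
    if last.is_acoustic_deviant:
        return "acoustic"
    if sub.is_target.any():
        return "target"
    return "standard"


def empirical_statistics(events: pd.DataFrame) -> dict:
    """Summarise an event table against its design claims.

    Returns a dict with:

    ``identity_transitions``
        row-stochastic DataFrame of P(next tone | current tone), counted
        over consecutive tones within blocks.
    ``triplet_transitions`` / ``triplet_transition_probs``
        2x2 counts / row-normalised probabilities of triplet t -> t+1.
    ``category_counts``
        triplets per category (standard/statistical/acoustic/double/target).
    ``p_second_to_third_canonical``
        fraction of triplets whose final tone identity was NOT replaced
        by a deviant manipulation (statistical or double), i.e. the
        designed second-to-third transitional probability (0.90 by
        design; targets are a task overlay counted separately).
    ``p_triplet_successor``
        marginal probability of each triplet identity as successor.
    """
    if events is None or len(events) == 0:
        raise ValueError("empty event table")

    ids = events["tone_id"].to_numpy()
    blocks = events["block"].to_numpy()
    same_block = blocks[1:] == blocks[:-1]
    trans = pd.crosstab(
        pd.Series(ids[:-1][same_block], name="current"),
        pd.Series(ids[1:][same_block], name="next"),
    )
    identity_transitions = trans.div(trans.sum(axis=1), axis=0)

    per_triplet = (
        events.sort_values(["block", "triplet_index", "position"])
        .groupby(["block", "triplet_index"], sort=True)
    )
    cats = per_triplet.apply(_triplet_category, include_groups=False)
    tids = per_triplet["triplet_id"].first()

    # triplet-to-triplet transitions within blocks
    tt_counts = np.zeros((2, 2), dtype=int)
    for _, s in tids.groupby(level=0):
        v = s.to_numpy()
        for a, b in zip(v[:-1], v[1:]):
            tt_counts[a - 1, b - 1] += 1
    tt = pd.DataFrame(tt_counts, index=[1, 2], columns=[1, 2])
    row_sums = tt.sum(axis=1).replace(0, 1)
    succ_total = tt.to_numpy().sum()

    # canonical second->third transition over all triplets
    finals = events[events["position"] == 3]
    n_replaced = (finals["is_statistical_deviant"]
                  | finals["is_double_deviant"]).sum()
    p_canonical = 1.0 - n_replaced / len(finals)

    return {
        "identity_transitions": identity_transitions,
        "triplet_transitions": tt,
        "triplet_transition_probs": tt.div(row_sums, axis=0),
        "category_counts": cats.value_counts().to_dict(),
        "p_second_to_third_canonical": float(p_canonical),
        "p_triplet_successor": {
            1: float(tt[1].sum() / succ_total) if succ_total else np.nan,
            2: float(tt[2].sum() / succ_total) if succ_total else np.nan,
        },
        "n_triplet_transitions": int(succ_total),
    }


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write a BIDS-style events table (one TSV, block column included)."""
    out = events.copy()
    for c in ("is_statistical_deviant", "is_acoustic_deviant",
              "is_double_deviant", "is_target"):
        out[c] = out[c].astype(int)
    out.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_events_tsv(path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    for c in ("is_statistical_deviant", "is_acoustic_deviant",
              "is_double_deviant", "is_target"):
        events[c] = events[c].astype(bool)
    return events
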