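"""Deterministic miniature fixtures for tests and demos.

Everything here is generated in memory from a seed: hand-checkable toy
event tables, epoch sets with prescribed FFT phases at a chosen bin,
and small cohorts that run end to end in seconds.  No real EEG data is
shipped or required.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import EVENT_COLUMNS, SOA, SequenceSpec
from .epochs import EpochSet
from .simulate import Cohort, EffectSpec, simulate_cohort

PHASE_RULES = ("identical", "uniform", "alternating")


def make_toy_block(n_triplets: int, deviant_triplets=(), target_triplets=(),
                   block: int = 0) -> pd.DataFrame:
    """Deterministic one-block event table for rule-based tests.

    ``deviant_triplets`` and ``target_triplets`` are 1-based triplet
    ordinals; deviants are statistical (identity replacement at
    position 3), targets sit at position 2.  Triplet identities
    alternate ABC/DEF.
    """
    if n_triplets < 1:
        raise ValueError("need at least one triplet")
    deviants = set(deviant_triplets)
    targets = set(target_triplets)
    for s, what in ((deviants, "deviant"), (targets, "target")):
        bad = [i for i in s if not 1 <= i <= n_triplets]
        if bad:
            raise ValueError(f"{what} ordinal(s) out of range: {bad}")
    overlap = deviants & targets
    if overlap:
        raise ValueError(f"triplet(s) {sorted(overlap)} marked both "
                         "deviant and target")
    tones = {1: ("A", "B", "C"), 2: ("D", "E", "F")}
    rows = []
    for i in range(n_triplets):
        tid = 1 if i % 2 == 0 else 2
        other = 2 if tid == 1 else 1
        trio = list(tones[tid])
        is_dev = (i + 1) in deviants
        has_tgt = (i + 1) in targets
        if is_dev:
            trio[2] = tones[other][2]
        for pos in range(3):
            tone_id = trio[pos]
            is_target = has_tgt and pos == 1
            if is_target:
                tone_id = "target"
            trial_type = ("target" if is_target
                          else "statistical_deviant" if is_dev and pos == 2
                          else "standard")
            rows.append((i * 3 * SOA + pos * SOA, 0.220, trial_type, block,
                         i, tid, pos + 1, tone_id,
                         is_dev and pos == 2, False, False, is_target))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def make_phase_epochs(n_epochs: int, bin_index: int,
                      phase_rule: str = "identical",
                      srate: float = 100.0, epoch_length: float = 5.4,
                      seed: int = 0, amplitude: float = 1.0) -> EpochSet:
    """Epochs that are pure sinusoids with a prescribed FFT phase at one
    bin: ``identical`` (all 0), ``uniform`` (i.i.d. on [0, 2pi)), or
    ``alternating`` (0, pi, 0, pi, ...).
    """
    if phase_rule not in PHASE_RULES:
        raise ValueError(f"phase_rule must be one of {PHASE_RULES}")
    n_samp = int(round(epoch_length * srate))
    if not 1 <= bin_index <= n_samp // 2:
        raise ValueError("bin_index outside the FFT grid")
    rng = np.random.default_rng(seed)
    if phase_rule == "identical":
        phases = np.zeros(n_epochs)
    elif phase_rule == "uniform":
        phases = rng.uniform(0, 2 * np.pi, size=n_epochs)
    else:
        phases = np.where(np.arange(n_epochs) % 2 == 0, 0.0, np.pi)
    t = np.arange(n_samp) / srate
    f = bin_index / epoch_length
    data = amplitude * np.cos(2 * np.pi * f * t[None, :] + phases[:, None])
    return EpochSet(data=data[:, None, :], srate=srate,
                    ch_names=["FC-cluster"],
                    blocks=np.zeros(n_epochs, dtype=int),
                    last_triplet_index=np.arange(n_epochs) * 6 + 5,
                    retained_count=(np.arange(n_epochs) + 1) * 6,
                    epoch_length=epoch_length)


def mini_sequence_spec(seed: int = 0) -> SequenceSpec:
    """Scaled-down sequence: 2 blocks of 90 triplets (~4.5 min total)."""
    return SequenceSpec(n_blocks=2, triplets_per_block=90, seed=seed)


def make_mini_cohort(preset: str = "empirical", n_per_group: int = 8,
                     seed: int = 0, srate: float = 100.0) -> Cohort:
    """Small cohort (default 8+8 subjects, 2 short blocks) for
    end-to-end runs in seconds.

    ``null`` zeroes the group difference and all brain-behavior
    correlations; ``empirical`` uses the study-calibrated effects
    (standardized TLI group difference 0.64, TLI-spelling rho 0.35,
    control tone-rate ITC below dyslexia's).
    """
    if preset == "null":
        effect = EffectSpec(d=0.0, rho=0.0, rho_reading=0.0, tone_gap=0.0)
    elif preset == "empirical":
        effect = EffectSpec()
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return simulate_cohort(n_per_group, n_per_group, effect=effect,
                           seed=seed, sequence_spec=mini_sequence_spec(seed),
                           srate=srate)
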