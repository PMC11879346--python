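"""Bad-channel handling, Kaiser-windowed FIR band-pass filtering, and
mastoid re-referencing of continuous recordings.

Filter orders are derived from the stated transition bandwidths and the
maximum passband deviation through the Kaiser design formula, so they
adapt to the sampling rate instead of hard-coding orders that assume
500 Hz.  Filters are linear-phase FIR applied with group-delay
compensation (centred convolution), i.e. effectively zero-phase --
phase distortion would corrupt the ITC phase estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .simulate import Recording


@dataclass(frozen=True)
class PreprocConfig:
    bad_channel_z: float = 3.0
    hp_cutoff: float = 0.2
    hp_transition: float = 0.4
    lp_cutoff: float = 30.0
    lp_transition: float = 5.0
    max_passband_deviation: float = 0.001
    reference: tuple[str, str] = ("M1", "M2")

    def validate(self, srate: float | None = None) -> None:
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")
        if srate is not None and self.lp_cutoff >= srate / 2:
            raise ValueError("lp_cutoff must be below Nyquist")
        if not 0 < self.max_passband_deviation < 1:
            raise ValueError("max_passband_deviation must be in (0, 1)")
        if len(self.reference) != 2:
            raise ValueError("reference must name exactly two channels")


def detect_bad_channels(recording: Recording, z: float = 3.0) -> list[str]:
    """Channels whose signal variance is an outlier across channels.

    The variance of every channel is z-scored across channels (sample
    SD); channels with \|z\| exceeding the threshold are flagged.
    Deterministic; requires at least 3 channels.
    """
    data = recording.signal
    if data.shape[0] < 3:
        raise ValueError("bad-channel detection needs >= 3 channels")
    var = data.var(axis=1)
    sd = var.std(ddof=1)
    if sd == 0:
        return []
    zscores = (var - var.mean()) / sd
    bad = [name for name, zz in zip(recording.ch_names, zscores)
           if abs(zz) > z]
    if len(bad) == data.shape[0]:
        raise ValueError("all channels flagged as bad; degenerate recording")
    return bad


def repair_channels(recording: Recording, bad: list[str],
                    n_neighbors: int = 4) -> Recording:
    """Replace bad channels by the inverse-distance-weighted mean of
    their nearest good neighbors; good channels are returned bit-exact.
    """
    if not bad:
        return recording
    names = recording.ch_names
    unknown = [b for b in bad if b not in names]
    if unknown:
        raise ValueError(f"bad channels not in montage: {unknown}")
    good = [n for n in names if n not in bad]
    if not good:
        raise ValueError("no good channels left to repair from")
    pos = recording.montage.positions
    out = recording.signal.copy()
    for b in bad:
        pb = np.asarray(pos[b])
        dists = np.array([np.linalg.norm(np.asarray(pos[g]) - pb)
                          for g in good])
        order = np.argsort(dists)[:n_neighbors]
        w = 1.0 / np.maximum(dists[order], 1e-12)
        w /= w.sum()
        idxs = [names.index(good[k]) for k in order]
        out[names.index(b)] = w @ recording.signal[idxs]
    return recording.copy_with(out)


def _kaiser_fir(cutoff: float, transition: float, deviation: float,
                srate: float, pass_zero: bool) -> np.ndarray:
    ripple_db = -20.0 * np.log10(deviation)
    numtaps, beta = sps.kaiserord(ripple_db, transition / (srate / 2.0))
    if numtaps % 2 == 0:
        numtaps += 1  # type-I linear phase, valid for high-pass
    return sps.firwin(numtaps, cutoff, window=("kaiser", beta),
                      pass_zero=pass_zero, fs=srate)


def filter_array(data: np.ndarray, srate: float,
                 config: PreprocConfig | None = None) -> np.ndarray:
    """High-pass then low-pass an (n_channels, n_samples) array."""
    config = config or PreprocConfig()
    config.validate(srate)
    hp = _kaiser_fir(config.hp_cutoff, config.hp_transition,
                     config.max_passband_deviation, srate, pass_zero=False)
    lp = _kaiser_fir(config.lp_cutoff, config.lp_transition,
                     config.max_passband_deviation, srate, pass_zero=True)
    out = sps.fftconvolve(data, hp[None, :], mode="same", axes=1)
    out = sps.fftconvolve(out, lp[None, :], mode="same", axes=1)
    return out


def bandpass(recording: Recording,
             config: PreprocConfig | None = None) -> Recording:
    """Zero-phase band-pass of a recording, block by block.

    Each block is filtered separately so that filter edge effects do not
    bleed across the breaks between blocks.
    """
    config = config or PreprocConfig()
    config.validate(recording.srate)
    out = recording.signal.copy()
    for start, stop in recording.block_bounds:
        out[:, start:stop] = filter_array(
            recording.signal[:, start:stop], recording.srate, config)
    return recording.copy_with(out)


def rereference_array(data: np.ndarray, ch_names: list[str],
                      reference: tuple[str, str] = ("M1", "M2")) -> np.ndarray:
    """Subtract the algebraic mean of the two reference channels from
    every channel (including the references, whose mean becomes 0)."""
    missing = [r for r in reference if r not in ch_names]
    if missing:
        raise ValueError(f"reference channel(s) missing: {missing}")
    idx = [ch_names.index(r) for r in reference]
    ref = data[idx].mean(axis=0, keepdims=True)
    return data - ref


def rereference(recording: Recording,
                reference: tuple[str, str] = ("M1", "M2")) -> Recording:
    return recording.copy_with(
        rereference_array(recording.signal, recording.ch_names, reference))


def preprocess(recording: Recording,
               config: PreprocConfig | None = None) -> tuple[Recording, dict]:
    """Full continuous-data path: detect bad channels, repair, band-pass.

    Mastoid re-referencing is *not* applied here -- the epoching
    pipeline applies it after excision of non-standard triplets, which
    is where the analysis procedure places it.  Returns the cleaned
    recording and a log dict (bad channels, filter settings).
    """
    config = config or PreprocConfig()
    bad = detect_bad_channels(recording, config.bad_channel_z)
    rec = repair_channels(recording, bad)
    rec = bandpass(rec, config)
    log = {"bad_channels": bad, "config": config.__dict__.copy()}
    return rec, log
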