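"""Time-resolved TLI over a block and logarithmic curve fitting.

The TLI is recomputed in sliding windows of 30 consecutive
non-overlapping 5.4-s epochs (window length 162 s) shifted in steps of
one epoch, and expressed as a function of the number of triplets
presented so far.  A logarithmic model y = a*log(x) + b (natural log)
is fitted to the time course by ordinary least squares; the slope a
summarises how quickly triplet-structure tracking builds up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import TONE_RATE, TRIPLET_RATE
from .epochs import EpochSet
from .spectral import exact_bin

X_CONVENTIONS = ("retained", "presented")


@dataclass
class LogFit:
    a: float          # slope on log(x)
    b: float          # intercept
    rss: float


@dataclass
class LearningCurve:
    x: np.ndarray          # triplets presented at each window's last epoch
    tli: np.ndarray
    itc_triplet: np.ndarray
    itc_tone: np.ndarray
    window_epochs: int
    step_seconds: float
    x_convention: str
    subject_id: str = ""
    fit: LogFit | None = None


def fit_log(x: np.ndarray, y: np.ndarray) -> LogFit:
    """OLS fit of y = a*log(x) + b (natural logarithm)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 points to fit the logarithmic model")
    if np.any(x <= 0):
        raise ValueError("x must be strictly positive for log(x)")
    a, b = np.polyfit(np.log(x), y, 1)
    resid = y - (a * np.log(x) + b)
    return LogFit(a=float(a), b=float(b), rss=float(resid @ resid))


def sliding_tli(epochs: EpochSet, window_epochs: int = 30,
                x_convention: str = "retained",
                subject_id: str = "", fit: bool = True) -> LearningCurve:
    """Windowed TLI over the surviving epochs of a single block.

    Windows advance by one epoch (5.4 s); windows that would extend past
    the last epoch are dropped.  ``x`` counts triplets up to the
    window's last epoch, in retained standard triplets ("retained",
    default) or in all presented triplets including excluded ones
    ("presented", using the epoch provenance).
    """
    if x_convention not in X_CONVENTIONS:
        raise ValueError(f"x_convention must be one of {X_CONVENTIONS}")
    if len(np.unique(epochs.blocks)) > 1:
        raise ValueError("sliding_tli expects epochs from a single block")
    n = epochs.n_epochs
    if n < window_epochs:
        raise ValueError(
            f"need >= {window_epochs} surviving epochs for one window, "
            f"got {n}")

    n_samp = epochs.data.shape[2]
    window = np.hanning(n_samp)
    spec = np.fft.rfft(epochs.data * window, axis=2)
    k_tri = exact_bin(epochs.epoch_length, TRIPLET_RATE)
    k_tone = exact_bin(epochs.epoch_length, TONE_RATE)
    phasors = spec[:, 0, [k_tri, k_tone]]
    phasors = phasors / np.abs(phasors)

    n_win = n - window_epochs + 1
    itc_tri = np.empty(n_win)
    itc_tone = np.empty(n_win)
    xs = np.empty(n_win)
    for i in range(n_win):
        w = phasors[i:i + window_epochs]
        itc = np.abs(w.mean(axis=0))
        itc_tri[i], itc_tone[i] = itc
        last = i + window_epochs - 1
        if x_convention == "retained":
            xs[i] = epochs.retained_count[last]
        else:
            xs[i] = epochs.last_triplet_index[last] + 1
    if np.any(itc_tone <= 0):
        raise ValueError("tone-rate ITC vanished in a window; TLI undefined")
    tli = itc_tri / itc_tone
    curve = LearningCurve(x=xs, tli=tli, itc_triplet=itc_tri,
                          itc_tone=itc_tone, window_epochs=window_epochs,
                          step_seconds=epochs.epoch_length,
                          x_convention=x_convention, subject_id=subject_id)
    if fit and n_win >= 3:
        curve.fit = fit_log(xs, tli)
    return curve


def group_mean_fit(curves: list[LearningCurve]) -> LogFit:
    """Fit the log model to the across-subject mean TLI time course.

    Curves are truncated to the shortest common length (subjects can
    differ in surviving epochs); the x grid of the first curve is used.
    """
    if not curves:
        raise ValueError("no curves")
    n = min(len(c.tli) for c in curves)
    if n < 3:
        raise ValueError("common time course too short to fit")
    mean_tli = np.mean([c.tli[:n] for c in curves], axis=0)
    return fit_log(curves[0].x[:n], mean_tli)
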