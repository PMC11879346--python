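"""Forward simulation of continuous multichannel EEG for the tone paradigm.

Real recordings from the paradigm are not redistributable, so every
downstream stage is exercised on simulated data with a known ground
truth.  The forward model is deliberately simple but preserves the
statistical structure the analysis depends on:

* each tone elicits a damped ~10 Hz oscillatory response from a single
  source with a fronto-central scalp topography;
* per-tone latency jitter (``tone_lock``, expressed as phase jitter in
  radians at the 3.33 Hz tone rate) controls inter-trial coherence at
  the tone rate;
* triplet-initial tones receive an amplitude boost and latency shift
  whose depth follows a latent logarithmic learning curve
  ``a*log(x) + b`` in the number of triplets heard so far -- a periodic
  (period-3) modulation of the tone responses, so coherence at the
  1.11 Hz triplet rate and its harmonics (2.22, 4.44 Hz) emerges
  naturally rather than from an injected sinusoid;
* 1/f^exponent background noise per channel, plus occasional
  high-amplitude transient artifacts at Poisson times.

Mastoid channels carry (almost) no evoked signal so that mastoid
re-referencing behaves as with real data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import design
from .design import SequenceSpec, generate_sequence

FRONTOCENTRAL = ("F1", "F2", "Fz", "FC1", "FC2", "FCz", "C1", "C2", "Cz")
MASTOIDS = ("M1", "M2")

# schematic 2-D positions on a unit head (x: left-right, y: back-front)
_DEFAULT_POSITIONS: dict[str, tuple[float, float]] = {
    "F3": (-0.35, 0.40), "F1": (-0.15, 0.40), "Fz": (0.0, 0.40),
    "F2": (0.15, 0.40), "F4": (0.35, 0.40),
    "FC1": (-0.15, 0.20), "FCz": (0.0, 0.20), "FC2": (0.15, 0.20),
    "C3": (-0.40, 0.0), "C1": (-0.15, 0.0), "Cz": (0.0, 0.0),
    "C2": (0.15, 0.0), "C4": (0.40, 0.0),
    "Pz": (0.0, -0.35), "Oz": (0.0, -0.75),
    "M1": (-0.85, -0.45), "M2": (0.85, -0.45),
}


@dataclass(frozen=True)
class Montage:
    """Channel layout with the fronto-central analysis cluster and mastoids."""

    positions: dict[str, tuple[float, float]]
    cluster: tuple[str, ...] = FRONTOCENTRAL
    mastoids: tuple[str, ...] = MASTOIDS

    def __post_init__(self):
        names = list(self.positions)
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names in montage")
        missing = [c for c in (*self.cluster, *self.mastoids)
                   if c not in self.positions]
        if missing:
            raise ValueError(f"montage is missing required channels: {missing}")

    @property
    def ch_names(self) -> list[str]:
        return list(self.positions)

    def evoked_gains(self, sigma: float = 0.45) -> np.ndarray:
        """Topographic gain of the evoked source: Gaussian falloff from FCz.

        Mastoids get a near-zero gain (0.02) regardless of distance.
        """
        fcz = np.asarray(self.positions["FCz"])
        gains = np.array([
            np.exp(-np.sum((np.asarray(p) - fcz) ** 2) / (2 * sigma ** 2))
            for p in self.positions.values()
        ])
        for i, name in enumerate(self.positions):
            if name in self.mastoids:
                gains[i] = 0.02
        return gains


def default_montage() -> Montage:
    return Montage(positions=dict(_DEFAULT_POSITIONS))


@dataclass(frozen=True)
class SubjectProfile:
    """Latent generative parameters of one simulated participant."""

    subject_id: str = "sub-01"
    group: str = "control"                 # control | dyslexia
    tone_lock: float = 0.6                 # phase-jitter SD (rad) at tone rate
    triplet_lock: float = 0.35             # modulation depth scale, >= 0
    learn_a: float = 0.12                  # latent curve tli(x) = a*log(x)+b
    learn_b: float = 0.2
    noise_amplitude: float = 12.0          # uV RMS of background noise
    noise_exponent: float = 1.0            # 1/f slope
    artifact_rate: float = 0.5             # events per minute
    artifact_amplitude: float = 400.0      # uV
    spelling_z: float = 0.0
    reading_speed_z: float = 0.0
    reading_comprehension_z: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.group not in ("control", "dyslexia"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.tone_lock < 0 or self.triplet_lock < 0:
            raise ValueError("tone_lock and triplet_lock must be >= 0")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be >= 0")

    def latent_modulation(self, x: np.ndarray) -> np.ndarray:
        """Monotone map g(x) >= 0 from triplets heard to modulation depth."""
        x = np.maximum(np.asarray(x, dtype=float), 1.0)
        return np.clip(self.learn_a * np.log(x) + self.learn_b, 0.0, None)


@dataclass
class Recording:
    """Continuous multichannel signal plus its event table."""

    signal: np.ndarray          # (n_channels, n_samples), uV
    srate: float
    montage: Montage
    events: pd.DataFrame
    block_bounds: list[tuple[int, int]]   # [start, stop) samples per block
    subject_id: str = "sub-01"

    @property
    def ch_names(self) -> list[str]:
        return self.montage.ch_names

    def block_signal(self, block: int) -> np.ndarray:
        start, stop = self.block_bounds[block]
        return self.signal[:, start:stop]

    def copy_with(self, signal: np.ndarray) -> "Recording":
        return Recording(signal=signal, srate=self.srate, montage=self.montage,
                         events=self.events, block_bounds=self.block_bounds,
                         subject_id=self.subject_id)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal((n_channels, n_samples))
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samples)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    cur = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x / cur * rms


def _evoked_kernel(srate: float, f0: float = 10.0, tau: float = 0.1,
                   duration: float = 0.35, amplitude: float = 5.0) -> np.ndarray:
    """Tone-evoked response: damped ~10 Hz oscillation riding on a slower
    biphasic (N1-P2-like) deflection.

    The slow component gives the response realistic spectral energy in
    the 1-4 Hz range; without it the 3.33 Hz tone-rate ITC of the
    periodic tone train would be far weaker than in real auditory data.
    """
    t = np.arange(0, duration, 1.0 / srate)
    fast = np.sin(2 * np.pi * f0 * t) * np.exp(-t / tau)
    slow = 1.2 * np.sin(2 * np.pi * 2.8 * t) * np.exp(-t / 0.12)
    return amplitude * (fast + slow)


def simulate_recording(events: pd.DataFrame, profile: SubjectProfile,
                       montage: Montage | None = None,
                       srate: float = 500.0) -> Recording:
    """Render a continuous EEG recording for one subject.

    Latency jitter is common to all channels (single evoked source), so
    the per-block source trace is built first and projected through the
    montage gains; noise and artifacts are added on top.
    """
    if events is None or len(events) == 0:
        raise ValueError("empty event table")
    if srate < 100:
        raise ValueError("srate must be >= 100 Hz to represent the 10 Hz kernel")
    profile.validate()
    montage = montage or default_montage()

    rng = np.random.default_rng(profile.seed)
    kernel = _evoked_kernel(srate)
    gains = montage.evoked_gains()
    n_ch = len(gains)
    pad = 0.6  # seconds of tail after the last tone of a block

    blocks = sorted(events["block"].unique())
    segs: list[np.ndarray] = []
    bounds: list[tuple[int, int]] = []
    cursor = 0
    triplets_seen = 0
    jitter_sd_s = profile.tone_lock / (2 * np.pi * design.TONE_RATE)

    for b in blocks:
        ev = events[events["block"] == b]
        n_samp = int(round((ev["onset"].max() + pad) * srate)) + len(kernel)
        source = np.zeros(n_samp)
        onsets = ev["onset"].to_numpy()
        positions = ev["position"].to_numpy()
        tri_ord = ev["triplet_index"].to_numpy()
        jit = rng.normal(0.0, jitter_sd_s, size=len(ev))
        depth = profile.triplet_lock * profile.latent_modulation(
            triplets_seen + tri_ord + 1)
        amp = np.where(positions == 1, 1.0 + depth, 1.0)
        lat = np.where(positions == 1, 0.02 * depth, 0.0)
        starts = np.round((onsets + jit + lat) * srate).astype(int)
        starts = np.clip(starts, 0, n_samp - len(kernel))
        for s, a in zip(starts, amp):
            source[s:s + len(kernel)] += a * kernel
        seg = np.outer(gains, source)
        noise = _pink_noise(rng, n_ch, n_samp, profile.noise_exponent,
                            profile.noise_amplitude)
        # mastoids sit far from the cortical noise sources: damp their
        # background so re-referencing does not swamp the scalp channels
        for i, name in enumerate(montage.positions):
            if name in montage.mastoids:
                noise[i] *= 0.3
        seg += noise

        dur_min = n_samp / srate / 60.0
        n_art = rng.poisson(profile.artifact_rate * dur_min)
        art_len = int(round(0.3 * srate))
        bump = np.hanning(art_len)
        mastoid_idx = [i for i, name in enumerate(montage.positions)
                       if name in montage.mastoids]
        for _ in range(n_art):
            s = int(rng.integers(0, max(1, n_samp - art_len)))
            sign = rng.choice([-1.0, 1.0])
            # heterogeneous scalp topography (otherwise re-referencing
            # would cancel a common-mode transient); mastoids barely see it
            weights = rng.uniform(0.5, 1.5, size=n_ch)
            weights[mastoid_idx] = 0.1
            seg[:, s:s + art_len] += (sign * profile.artifact_amplitude
                                      * np.outer(weights, bump))

        segs.append(seg)
        bounds.append((cursor, cursor + n_samp))
        cursor += n_samp
        triplets_seen += int(tri_ord.max()) + 1

    return Recording(signal=np.concatenate(segs, axis=1), srate=srate,
                     montage=montage, events=events,
                     block_bounds=bounds, subject_id=profile.subject_id)


@dataclass(frozen=True)
class EffectSpec:
    """Group/correlation structure of a simulated cohort.

    ``d``: standardized latent TLI difference (control minus dyslexia).
    ``rho``: Pearson correlation of spelling with the latent TLI trait.
    ``rho_reading``: same for both reading scores (0 in the study's data).
    ``tone_gap``: relative tone_lock difference (control jitters more,
    hence the lower tone-rate ITC seen in controls).
    """

    d: float = 0.64
    rho: float = 0.35
    rho_reading: float = 0.0
    tone_gap: float = 0.3
    base_tone_lock: float = 0.6
    base_triplet_lock: float = 0.35
    base_learn_a: float = 0.12
    base_learn_b: float = 0.2
    trait_scale: float = 0.35  # how strongly the latent trait moves locks


@dataclass
class Cohort:
    profiles: list[SubjectProfile]
    behavior: pd.DataFrame
    recordings: list[Recording] | None = None


def simulate_cohort(n_control: int, n_dyslexia: int,
                    effect: EffectSpec | None = None,
                    seed: int = 0,
                    sequence_spec: SequenceSpec | None = None,
                    srate: float = 500.0,
                    profiles_only: bool = False) -> Cohort:
    """Draw a cohort of subject profiles (and optionally their recordings).

    The latent trait t_i ~ N(+-d/2, 1) (control positive) drives the
    triplet-locking parameters monotonically; ``spelling_z`` is built as
    rho * z(t) + sqrt(1-rho^2) * noise so the population correlation
    with the latent TLI trait equals ``rho`` by construction.
    """
    if n_control < 2 or n_dyslexia < 2:
        raise ValueError("need at least 2 subjects per group")
    effect = effect or EffectSpec()
    rng = np.random.default_rng(seed)

    groups = ["control"] * n_control + ["dyslexia"] * n_dyslexia
    offsets = np.where(np.array(groups) == "control",
                       effect.d / 2.0, -effect.d / 2.0)
    trait = rng.standard_normal(len(groups)) + offsets
    zt = (trait - trait.mean()) / trait.std(ddof=1)

    def mix(rho: float) -> np.ndarray:
        noise = rng.standard_normal(len(groups))
        return rho * zt + np.sqrt(1.0 - rho ** 2) * noise

    spelling = mix(effect.rho)
    read_speed = mix(effect.rho_reading)
    read_comp = mix(effect.rho_reading)

    profiles = []
    for i, g in enumerate(groups):
        tone_lock = effect.base_tone_lock * (
            1.0 + (effect.tone_gap / 2.0 if g == "control"
                   else -effect.tone_gap / 2.0))
        profiles.append(SubjectProfile(
            subject_id=f"sub-{i + 1:02d}", group=g,
            tone_lock=max(0.0, tone_lock),
            triplet_lock=max(0.0, effect.base_triplet_lock
                             * (1.0 + effect.trait_scale * trait[i])),
            learn_a=max(0.0, effect.base_learn_a
                        * (1.0 + effect.trait_scale * trait[i])),
            learn_b=effect.base_learn_b,
            spelling_z=float(spelling[i]),
            reading_speed_z=float(read_speed[i]),
            reading_comprehension_z=float(read_comp[i]),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        ))

    behavior = pd.DataFrame({
        "subject_id": [p.subject_id for p in profiles],
        "group": groups,
        "latent_trait": trait,
        "spelling_z": spelling,
        "reading_speed_z": read_speed,
        "reading_comprehension_z": read_comp,
    })

    recordings = None
    if not profiles_only:
        spec = sequence_spec or SequenceSpec()
        recordings = []
        for p in profiles:
            ev = generate_sequence(replace(
                spec, seed=int(rng.integers(0, 2 ** 31 - 1))))
            recordings.append(simulate_recording(ev, p, srate=srate))
    return Cohort(profiles=profiles, behavior=behavior, recordings=recordings)
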