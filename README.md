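# tripletlearn

Frequency-tagging analysis of auditory statistical learning from EEG:
inter-trial phase coherence (ITC) at the tone and triplet presentation
rates, and the **Triplet Learning Index (TLI)** that quantifies neural
tracking of hidden triplet structure in a continuous tone stream.

## The paradigm and the analysis

Listeners hear a continuous stream of six tones (A–F) secretly organised
into two triplets (e.g. ABC, DEF).  Tones last 220 ms and are separated
by 80 ms of silence, so the stimulus onset asynchrony is exactly 300 ms:
tones arrive at 3.33 Hz and triplets at 1.11 Hz.  Within a triplet the
transitional probabilities are high (1.0 from first to second tone, 0.9
from second to third once occasional deviants are counted); across
triplet boundaries the next triplet is drawn independently (0.5).  The
only cue to the hidden chunk structure is statistics.

If the brain picks up that structure, its activity phase-locks not only
to the tone rate but also to the triplet rate.  Both are measured with
ITC over epochs of 5.4 s (six triplets, 18 tones), which puts the rates
on exact FFT bins (frequency resolution 1/5.4 Hz; triplet rate = bin 6,
tone rate = bin 18):

```
ITC(f)  = | (1/N) Σ_k exp(i φ_k(f)) |          (φ_k: phase of epoch k)
TLI     = ITC(1.11 Hz) / ITC(3.33 Hz)
```

The pipeline implements the full procedure around this statistic:

* **sequence design** (`tripletlearn.design`) — triplet streams with
  exact per-block counts of statistical / acoustic / double deviants
  (8% / 18% / 2% of 400 triplets per block) and 48 behavioral target
  tones balanced over within-triplet positions;
* **synthetic EEG** (`tripletlearn.simulate`) — a forward model with a
  fronto-central tone-evoked response, controllable phase-locking at
  both rates, a latent logarithmic learning curve, 1/f noise and
  transient artifacts, plus cohort generation with calibrated group and
  brain–behavior effect sizes (real recordings from this paradigm are
  not publicly distributable);
* **preprocessing** (`tripletlearn.preprocess`) — variance-based bad
  channel detection (|z| > 3), inverse-distance channel repair,
  Kaiser-window FIR band-pass (0.2–30 Hz, zero-phase);
* **epoching** (`tripletlearn.epochs`) — exclusion of deviant,
  post-deviant, and target triplets; excision and concatenation of the
  remaining standard triplets; mastoid re-referencing; per-tone
  de-meaning (0–300 ms windows); 5.4-s epochs within blocks; 300 µV
  peak-to-peak rejection; 9-channel fronto-central cluster averaging;
* **spectra and TLI** (`tripletlearn.spectral`) — per-block
  Hanning-windowed FFT phase coherence, rate-bin extraction,
  peak-vs-control-bin t-tests, per-channel topographies;
* **learning curves** (`tripletlearn.learning`) — sliding-window TLI
  (30 epochs = 162 s, step 5.4 s) with logarithmic fits
  y = a·log(x) + b;
* **group statistics** (`tripletlearn.stats`) — pooled-variance
  t-tests with Cohen's d, cluster-based permutation comparison of TLI
  time courses (runs of ≥ 2 adjacent suprathreshold points, max-cluster
  null over label permutations), z-standardization and one-sided
  Pearson brain–behavior correlations.

## Worked example

A scaled-down end-to-end run (8 + 8 simulated subjects, two short
blocks, 100 Hz) takes a couple of seconds:

```bash
$ tripletlearn run-all --mini --seed 11 --out-dir out/
TLI group test: t(14) = 0.65, p = 0.262, d = 0.33
report written to out/report.json
```

The report contains, per subject, the block-wise epoch counts, ITC at
both rates and the TLI, and at the cohort level the peak-vs-control-bin
tests (control bins ±2 around the peak, i.e. 2.96 and 3.70 Hz for the
tone rate), the group comparisons, the cluster test on the TLI time
course, the group log-fits, and the three behavior correlations.  From
the run above:

```
subjects tli: [0.502, 0.376, 0.429, 0.630, 0.175, 0.586, 0.614, 0.270, ...]
tli test:     {'t': 0.653, 'df': 14, 'p': 0.262, 'd': 0.326}
peak (control group, tone rate): t = 27.4, p < 1e-8, d = 9.7
spelling:     r = 0.310, one-sided p = 0.121
```

Every subject shows a massive tone-rate peak against its neighboring
bins; the TLI points in the direction injected by the simulation
(control > dyslexia) but a single mini cohort of 16 subjects is far too
small for that difference to be reliably significant — the calibration
of the group effect (d = 0.64) and of the TLI–spelling correlation
(ρ = 0.35) is verified over hundreds of replicate cohorts in the test
suite instead.  The full-scale configuration (`tripletlearn show-config`)
uses 6 blocks of 400 triplets at 500 Hz and 19 + 17 subjects.

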