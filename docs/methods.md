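# Methods

This note documents the models, parameter choices, numerical decisions,
and known limitations of the `tripletlearn` pipeline.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Sequence design

Two triplets built from six tones; triplet identity is drawn i.i.d. per
slot (immediate repetitions allowed), so the triplet-to-triplet
transitional probability is 0.5 and the within-triplet probabilities are
1.0 (first→second) and 0.9 (second→third, once final-tone replacements
are counted).  The generator assigns deviant categories by **exact
counts** per block — `round(p × triplets_per_block)` statistical (8%),
acoustic (18%), and double (2%) deviants, mutually exclusive — rather
than by per-triplet Bernoulli draws.  This makes the design percentages
hold exactly in every block and the 10%-replacement check deterministic.
A spec is rejected when the rounded counts cannot partition the block or
leave too few standard triplets to host the targets.

Targets (8 per block, 48 over six 400-triplet blocks) replace single
tones; their within-triplet positions are balanced over the experiment
(16 per position).  Targets are placed only in standard triplets, one
per triplet: a target triplet is later excluded wholesale anyway, and
keeping targets out of deviant triplets keeps the category bookkeeping
exact.  Counterbalancing of tone→triplet assignment and within-triplet
position is an enumerated list of 60 schemes (10 partitions of the six
tones with tone A anchored in triplet 1 × 6 position permutations)
selected by `counterbalance_id`.

The toy-sequence transition oracle in the tests uses the triplet order
ABC ABC ABC DEF, for which hand counting gives P(B→C) = 1,
P(C→A) = 2/3, P(C→D) = 1/3.

## 2. EEG forward model

The simulator is intentionally minimal but preserves every statistical
property the analysis consumes.

* **Evoked kernel.**  Each tone elicits a damped ~10 Hz oscillation
  (decay 100 ms) riding on a slower biphasic deflection
  (2.8 Hz component, decay 120 ms), peak amplitude ~5 µV at the
  fronto-central maximum.  The slow component matters: the tone-rate
  ITC of a periodic tone train is governed by the kernel's spectral
  energy at 3.33 Hz, and a pure 10 Hz damped sinusoid has almost none —
  real auditory P1–N1–P2 complexes do.
* **Topography.**  A single source projected through per-channel gains
  (Gaussian falloff from FCz on a schematic 2-D montage of 17
  channels).  Mastoids receive near-zero evoked gain (0.02) and damped
  background noise (×0.3), so mastoid re-referencing behaves as with
  real data instead of injecting the mastoids' full independent noise
  into every channel.
* **Tone-rate locking.**  `tone_lock` is the SD (radians, at 3.33 Hz)
  of a per-tone latency jitter common to all channels.  Because each
  5.4-s epoch sums 18 tones, per-tone jitter mostly attenuates the
  coherent amplitude (factor ≈ exp(−σ²/2)) rather than randomising the
  epoch phase; tone-rate ITC is therefore SNR-limited and monotone
  decreasing in `tone_lock` (verified on a 4-point grid).
* **Triplet-rate locking.**  Triplet-initial tones get an amplitude
  boost and small latency shift of depth
  `triplet_lock × g(x)`, with `g(x) = max(0, a·log x + b)` the latent
  learning curve in the number of triplets heard so far (cumulative
  across blocks).  This period-3 modulation of tone responses puts
  coherence at 1.11 Hz and its harmonics (2.22, 4.44 Hz) into the
  signal naturally; no 1.11 Hz sinusoid is ever injected.
* **Noise and artifacts.**  Per-channel 1/f^θ noise (default θ = 1,
  RMS 12 µV) and Poisson transient artifacts (default 0.5/min, 400 µV,
  300 ms raised-cosine) with a heterogeneous random scalp topography —
  a common-mode artifact would be removed exactly by re-referencing and
  could never trip the rejection threshold.
* **Sampling.**  Default 500 Hz (matching the acquisition rate); the
  epoching stage requires an integer number of samples per 300-ms SOA,
  so fast tests use 100 Hz (30 samples per tone, 540 per epoch; the
  rate bins stay exact).

**Cohorts.**  A latent trait t_i ~ N(±d/2, 1) (control positive)
drives `triplet_lock` and `learn_a` monotonically; `tone_lock` is
offset between groups (`tone_gap`) so that controls show *lower*
tone-rate ITC, the direction observed empirically.  Spelling scores are
constructed as ρ·z(t) + √(1−ρ²)·ε, so the population correlation with
the latent triplet-tracking trait equals ρ by construction; reading
scores default to ρ = 0.  The empirical preset uses d = 0.64 and
ρ = 0.35.  Effect calibration targets standardized effect sizes, not
raw ITC values, because raw values depend on the invented forward
model.  The calibration suites (ordering recovery, correlation
recovery, error rates) run on the latent/behavioral draws
(`profiles_only=True`), where the injected effects are exact; the
EEG-measurement link is verified separately by paired monotonicity
tests (TLI vs `triplet_lock`, fitted slope vs `learn_a`) on miniature
recordings, since measured TLI adds estimation noise that attenuates
standardized effects at desk scale.

## 3. Preprocessing

Bad channels are those whose signal variance, z-scored across channels
(sample SD), exceeds |z| = 3; they are repaired as the
inverse-distance-weighted mean of the 4 nearest good channels.  This is
a deliberate simplification of spherical-spline interpolation (the
montage is schematic anyway); the repair function is the single place
to swap in a spline backend.  ICA-based artifact removal is not
implemented: the artifact model of the simulator is matched to the
rejection rule the analysis itself defines (300 µV peak-to-peak per
epoch), and channel repair covers the stationary-noisy-channel case.

Filters are Kaiser-window linear-phase FIRs designed from the stated
transition widths and a maximum passband deviation of 0.001 (≈ 60 dB):
high-pass 0.2 Hz (transition 0.4 Hz), then low-pass 30 Hz (transition
5 Hz).  Orders come from the Kaiser design formula at the actual
sampling rate instead of hard-coding orders that assume 500 Hz.
Application is by centred convolution (group-delay compensated), i.e.
zero-phase — phase distortion would corrupt the downstream ITC phase
estimates.  Blocks are filtered separately so edge effects do not cross
the breaks.

Re-referencing subtracts the algebraic mean of the two mastoids from
**every** channel (the mastoids included, whose mean becomes zero).
In exact arithmetic a second application is therefore a no-op; the
operation is still not written as idempotent-by-construction, and
pipelines must apply it exactly once, at the prescribed position.

## 4. Epoch construction

The order is fixed and enforced by `standard_epochs`:

1. **select** — drop triplets containing any deviant; drop the triplet
   immediately following a deviant triplet (within the block; blocks
   are independent); drop triplets containing a target.  A triplet
   following a dropped *target* triplet is kept: only deviance
   propagates.  Reason precedence: deviant → post_deviant → target.
2. **excise** — concatenate the 0.9-s spans of the kept triplets in
   original order, per block; retained samples are bit-identical.
3. **re-reference** to the mastoid mean.
4. **de-mean** each tone's [onset, onset + 300 ms) window per channel
   (half-open, 0-based samples, onsets rounded to the nearest sample) —
   this attenuates the splice discontinuities created by excision.
5. **epoch** — consecutive groups of 6 retained triplets (5.4 s);
   leftovers (< 6) at a block end are discarded, never carried across
   blocks.
6. **cluster-average / reject** — for cluster analyses the 9
   fronto-central channels (F1, F2, Fz, FC1, FC2, FCz, C1, C2, Cz) are
   averaged first and the 300 µV peak-to-peak criterion is evaluated on
   that analysis signal; for topography analyses all channels are kept
   and any offending channel rejects the epoch.  Both modes exist
   because the original criterion's reference signal is not specified.

Under the full-scale defaults this leaves ~32–34 epochs per block per
subject.

## 5. ITC, TLI, and learning curves

ITC is the modulus of the mean unit phasor of the Hanning-windowed FFT
phases, computed separately per block (≥ 2 epochs) and averaged across
blocks without weighting.  No zero-padding: the FFT length equals the
5.4-s epoch, so 1.11/2.22/3.33/4.44 Hz are exact bins (6/12/18/24) and
rate values are read off the grid without interpolation; a mismatched
epoch length is an error, not an interpolation.  The Hanning window is
amplitude-preserving but irrelevant to a phase-only statistic.

An alternative estimator, `itc_mode="complex-average"`, computes
|mean spectrum| / mean |spectrum| — the coherence of the *averaged*
complex spectra.  It exists because descriptions of this analysis
family sometimes average FFT results before extracting phase angles,
which taken literally is not an ITC; the standard phase-only estimator
is the default and the variant is provided for comparison only.

TLI = ITC(triplet bin) / ITC(tone bin); a zero tone-rate ITC is an
error, not an infinity.  Note a null-TLI subtlety the tests document:
with white background noise the two bins share one Rayleigh floor and
the null TLI ratio has median ≈ 1, but with 1/f noise adjacent epochs
are correlated at low frequencies, which raises the triplet-bin floor
above the tone-bin floor.  Absolute TLI values are therefore less
interpretable than within-design comparisons (groups, time courses) —
one reason the analysis works with relative quantities.

Peak tests contrast the ITC at a rate bin with the mean of the two bins
±2 away (for the tone rate: 2.96 and 3.70 Hz; for the triplet rate:
0.74 and 1.48 Hz on this grid), one-sided one-sample t across subjects,
Cohen's d = mean/SD of the contrasts.  With zero contrast variance the
boundary case returns t = 0, p = 0.5.

**Sliding windows.**  TLI is recomputed in windows of 30 consecutive
surviving epochs (162 s), shifted by one epoch; windows that would
extend past the last epoch are dropped, not shrunk.  The x-axis counts
triplets up to the window's last epoch; the default convention counts
**retained** standard triplets (what the analysed data contains), with
`x_convention="presented"` switching to all presented triplets via the
epoch provenance.  The logarithmic model y = a·log(x) + b (natural
log — any other base only rescales a) is fitted by OLS, per subject
and to the group-mean curve (subjects truncated to the common length);
the group-mean fit is what figures should use.

## 6. Group statistics

All t-tests are pooled-variance with df = n₁ + n₂ − 2 (the reported
degrees of freedom in this literature are consistent with pooled, not
Welch, tests); Cohen's d uses the pooled sample SD, and
z-standardization the sample SD (n − 1).  The TLI group hypothesis is
directional (control > dyslexia, one-sided); ITC group comparisons are
two-sided; brain–behavior Pearson correlations are tested one-sided
(r > 0) and reported uncorrected across the three scores.

**Cluster-based permutation.**  Pointwise pooled t-tests at each time
point; maximal runs of ≥ 2 adjacent points with two-sided p < 0.05 and
a common sign form clusters scored by their summed t.  The null is the
maximum |cluster sum| over relabelings of subjects to groups — 1000
random permutations by default, with `exact=True` enumerating all
distinct relabelings on small instances.  Cluster
p = (1 + #{null ≥ |observed|}) / (n_perm + 1), so p can never be zero;
the exact mode uses the plain proportion.  Collecting clusters of both
signs against the absolute-max null gives two-sided family-wise
control; the directional group hypothesis is applied at the reporting
stage.  p-values are invariant to which group is labelled first.

## 7. Scaled-down configurations

The `--mini` configuration (2 blocks × 90 triplets, 8 + 8 subjects,
100 Hz, 3-epoch windows, 500 permutations) exists so the complete
pipeline runs in seconds; the statistical-property suites choose their
own problem sizes (e.g. 200–1000 replicates, 4 + 4 exhaustive
enumeration, 240–400-triplet single blocks for monotonicity checks) as
the smallest instances at which the property being tested is decisive.

## 8. Limitations

* The forward model is a single dipole-free gain pattern: no leadfield,
  no spatially correlated noise, no ocular/muscle topographies.
  Artifacts are generic transients; consequently the pipeline's
  bad-channel and rejection stages are exercised, but ICA-style source
  separation cannot be (and is not implemented).
* Passing tests demonstrate correctness of the *analysis* under a
  controlled generative model, and calibration of the simulated effect
  sizes — not that real dyslexic and control cohorts would reproduce
  any specific value.
* Epoch counts at mini scale are small enough that ITC small-sample
  bias (Rayleigh floor ~ √π/(2√N)) is material; comparisons in the
  tests always hold N constant across the conditions being compared.
* EDF import/export is not provided; recordings round-trip through a
  `.npy` + JSON-sidecar + events-TSV representation.
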