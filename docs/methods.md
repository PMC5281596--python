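# Methods

## The generative model

A recording is strictly linear:

    x_c(t) = noise_c(t) + Σ_events Σ_components g_{c,k} · A_k · exp(−(t − t_event − L_k)² / 2σ_k²)

* `g_{c,k}` — per-channel gain of component k's topography (0…1).
* `A_k`, `L_k`, `σ_k` — signed peak amplitude (μV), peak latency (ms) and
  Gaussian width (SD, ms).
* Exogenous components (P1, N1) are locked to fragment-1 onset and attached
  to every stimulus; the mismatch component (vMMN) is locked to fragment-2
  onset (the onset of deviance) and attached to a deviant only when
  `soa ≤ persistence_limit(category)` for the group. Persistence limits are
  the generative twin of the temporal-integration hypothesis: the young
  profile integrates only the whole character (pseudo-letter limit 0 ms,
  letter never), the older profile also integrates fragmented pseudo-letters
  up to 50 ms and letters only at 0 ms.
* `noise_c` — per-channel independent 1/f noise (spectral exponent 1.0,
  RMS 10 μV), synthesised in the frequency domain with the spectrum
  flattened below 0.1 Hz. An optional mixing matrix introduces spatial
  correlation, and an optional blink injector adds large frontal transients;
  both are off by default.

Default component parameters (older profile): P1 +3.0 μV at 110 ms
(SD 12 ms), N1 −3.7 μV at 177 ms (SD 25 ms, broader than the young
profile's −4.0 μV at 185 ms with SD 18 ms), vMMN −1.0 μV at 245 ms
(young: 235 ms) with SD 30 ms, maximal over PO8/PO10. Amplitudes and
latencies sit at the reported group means of this paradigm's literature;
the vMMN SOA dependence is all-or-none by default because published
summaries report presence/absence per SOA, not amplitude decay — a graded
`exp(−soa/τ)` decay is available via `soa_decay_constant`.

The noise scale is chosen as realistic broadband posterior EEG. It implies
subject-level difference-wave noise of roughly
`10 · sqrt(1/100 + 1/400) / sqrt(2) ≈ 0.8 μV` RMS after averaging (100
deviant epochs, 400 opposite-condition standard epochs, 2-channel ROI
pooling), i.e. a single-subject peak SNR near 1 for a −1 μV response —
comparable to real vMMN data, where group-level statistics are needed to
see the effect.

### What the generator emulates, and what it does not

Emulated: the session design (250 trials/sequence, deviant probability
exactly 0.2 split over two variants, 16 sequences = 4 SOAs × 2 deviant
categories × 2 repetitions, 600 ± 50 ms ITIs, 30 ms fragments), task-event
placement rules (300 ms frame thickenings every 5–15 s, side-balanced, never
overlapping a deviant pair or its preceding standard), acquisition (1000 Hz,
37 scalp + 2 EOG channels), and group-dependent presence/absence of the
mismatch response.

Not emulated: pixel-level stimulus rendering (events carry category /
variant / fragmentation labels only), volume conduction from cortical
sources (topographies are phenomenological gain maps), trial-to-trial
amplitude/latency jitter of components, non-stationary noise, alpha rhythms,
muscle or line artifacts, and any dependence of P1/N1 on stimulus category.
Passing tests therefore demonstrate that the *analysis chain* recovers what
the forward model injects under realistic noise levels — not that it is
robust to every artifact class of real recordings.

## Preprocessing conventions

* Band-pass 0.1–30 Hz realized as a 4th-order Butterworth (24 dB/octave)
  applied forward–backward (`sosfiltfilt`): zero phase, effective
  attenuation doubled; accepted and documented.
* Epochs are inclusive of both endpoints: −100…600 ms at 1 kHz = 701
  samples. Sample index = round(ms × rate / 1000); event durations use
  half-open intervals.
* Baseline = [−100, 0] ms relative to fragment-1 onset. The analysis time
  axis is the acquisition axis shifted by the SOA (0 = fragment-2 onset).
* The ±100 μV screen reads "amplitude change" in both senses: reject when
  any |sample| > 100 μV **or** when peak-to-peak > 200 μV on any channel
  (EOG included); each sub-criterion is selectable alone. The absolute
  reading sets the boundary: a 100 μV spike is retained, 101 μV rejected.
* Epochs whose window leaves the recording are kept as placeholders but
  flagged `out-of-bounds`.

## Detection

Pointwise one-sample t against zero across subjects per ROI-pooled
difference wave; runs of consecutive p < α are computed on the full series,
intersected with the 150–300 ms search window, and kept when they still span
at least `ceil(min_run·fs/1000)` samples (20 at the defaults). A run's
duration counts samples (20 samples at 1 kHz = 20 ms). Ties at peak
measurement resolve to the earliest sample; the 20 ms amplitude span around
the group peak is clipped at window edges and the clipping is reported.

Choices on points the criterion's verbal form leaves open:

* **Tails** — "against zero, p < .05" is read as two-tailed (conservative);
  a one-tailed variant is a flag.
* **Polarity** — only negative-going runs count toward `vmmn_present`,
  because a mismatch *negativity* is by definition negative; positive runs
  are still listed in the window table.
* **Zero variance across subjects** (exactly reproducible data, e.g.
  noiseless simulations) makes t undefined; such samples are flagged and
  scored p = 0 when the mean is nonzero, p = 1 otherwise.
* No correction is applied across conditions or ROIs beyond the run
  criterion itself, mirroring common practice for this paradigm. A
  family-wise sign-flip permutation test on the longest run
  (`permutation_max_run_test`) is provided but off by default.

### Measured false-positive behaviour (and why it is structural)

The type-I suite (200 null cohorts of 15 subjects, noise matched to the
generator defaults, both ROIs) measures an empirical `vmmn_present` rate of
≈ 0.10–0.12 — far above the nominal .05. This is a property of the
criterion, not of a particular noise spectrum: after the mandatory 0.1–30 Hz
zero-phase filter the noise autocorrelation time is ~15–20 ms, so 20
consecutive significant samples at 1000 Hz span roughly *one* correlation
length, and even white input noise yields double-digit false-positive rates.
Consecutive-point criteria control α only when the run length is several
correlation lengths (tens of samples at low sampling rates, hundreds at
1 kHz). Users who need family-wise control should use the permutation
option; the default remains the field's criterion so that results are
comparable.

## Statistics

ANOVAs go through pingouin (mixed one-between × one-within; one- and
two-way within), normalised to one table: SS, dfs, F, uncorrected p,
Greenhouse–Geisser ε (from the contrast-covariance eigenvalues;
ε ∈ [1/(k−1), 1]) with the corrected p for within effects with k > 2, and
partial η² = SS_effect / (SS_effect + SS_error). Two-level factors satisfy
sphericity trivially (ε = 1). Interaction rows of mixed designs are
GG-corrected with the within factor's ε where pingouin does not do so
itself. Constant data short-circuit to F = 0, η² = 0 by convention.
Tukey HSD works from summary statistics — q = |m_i − m_j| / sqrt(MS_e/n)
against the studentized-range distribution — because the paradigm's designs
are balanced.

Peak amplitudes and latencies enter ANOVAs only for conditions where the
runs criterion flagged a response (Age × ROI at SOA 0; SOA × ROI within a
group across its flagged SOAs), mirroring the paradigm's analysis logic.

The hit-rate scorer counts a task event as hit when the first unconsumed
response falls 200–1000 ms after thickening onset (a conventional RT
window; configurable). The 2AFC model is
`p(correct | soa) = 0.5 + (1 − λ)(p₀ − 0.5)·exp(−(soa − 30)/τ)` with
defaults p₀ = 0.9, τ = 10 ms, λ = 0.02 — near-ceiling integration at 30 ms
falling to chance by 50 ms. The 164-trial default session cannot be divided
exactly by six cells; trials are distributed as evenly as possible (SOA
counts 55/55/54, order split within SOA differing by ≤ 1), with a
`strict_balance` flag for exactly divisible designs.

## Problem sizes used by the test suites

The stochastic suites run at the full design sizes that matter statistically
(n = 15 subjects per group, 250-trial sequences, all 16 sequences for the
pattern checks) while trimming what does not:

* only the four ROI electrodes are simulated — with per-channel-independent
  noise the omitted channels cannot change any ROI statistic;
* type-I replicates draw subject-level averaged noise directly (the mean of
  m independent noise epochs is same-spectrum noise scaled by 1/√m), then
  apply the default band-pass and baseline; this is distributionally
  equivalent to averaging noise-only epochs and ~100× cheaper;
* the presence/absence pattern uses the majority verdict over 7 seeded
  cohorts per condition; detection power at default SNR is verified
  separately over 20 replicates.

## Known limitations

* EDF export is a minimal hand-written 16-bit writer (1 s records,
  zero-padded tail); it round-trips through mne's reader but does not cover
  EDF+ annotations.
* Mixed designs with two within factors are not wrapped (analyse per group
  or per level); none of the paradigm's reported ANOVAs need them.
* The runs criterion's anticonservativeness at 1 kHz is reported, not
  "fixed" — the default mirrors the field's practice.
* The forward model's components are deterministic per condition; latency
  jitter, habituation across a sequence, and refractoriness are not
  modelled.
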