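# vmmn

Analysis toolkit for **visual mismatch negativity (vMMN)** experiments with
fragmented-character oddball stimuli — the paradigm used to probe visual
temporal integration (stimulus persistence) at the level of automatic change
detection, e.g. when comparing young and older observers.

The package covers the full chain for this kind of study:

* **Constrained oddball scheduling** — 250-trial sequences with deviant
  probability exactly 0.2 (two variants per role, 0.1 each), character
  fragments of 30 ms at stimulus onset asynchronies (SOA) of 0/30/50/70 ms,
  600 ± 50 ms inter-trial intervals, and frame-thickening task events that are
  balanced over sides and never coincide with a deviant or the standard
  immediately before it.
* **Synthetic multichannel EEG** — a linear forward model (Gaussian evoked
  components × scalp topography over 1/f background noise, 37 scalp channels
  of the extended 10–20 montage + bipolar HEOG/VEOG at 1000 Hz) in which the
  mismatch response is injected for a deviant only when the SOA does not
  exceed the group's *persistence limit* for that stimulus category.
* **ERP preprocessing** — zero-phase 0.1–30 Hz Butterworth band-pass
  (24 dB/octave), epochs −100…600 ms around fragment-1 onset (701 samples at
  1 kHz), pre-stimulus baseline correction, ±100 μV artifact screen.
* **Difference waves** — opposite-condition subtraction: ERP to category X as
  deviant minus ERP to the physically identical X as standard from the
  role-swapped sequence.
* **Runs-based detection** — the statistical core, exposed in the
  model/results idiom: a pointwise one-sample t test of the subject
  difference waves against zero, with vMMN declared present when at least
  20 ms of *consecutive* samples satisfy p < .05 inside the a-priori
  150–300 ms window after change onset, in at least one parieto-occipital
  ROI (left = mean of PO7/PO9, right = mean of PO8/PO10), with
  negative-going polarity.
* **Statistics** — repeated-measures/mixed ANOVA with Greenhouse–Geisser
  correction and partial η², Tukey HSD post hocs from summary statistics,
  task hit-rate scoring, and two-alternative forced-choice (2AFC) scoring
  with a psychometric accuracy model.

## The detection statistic

For each ROI, subject-level difference waves `d_i(t)` (i = 1…n) are tested
pointwise:

    t(t) = mean_i d_i(t) / ( sd_i d_i(t) / sqrt(n) ),   df = n − 1

A vMMN is reported when there is a run of at least `ceil(20 ms × fs / 1000)`
consecutive samples with p(t) < .05 within 150–300 ms (analysis time zero =
onset of the second fragment, i.e. the onset of deviance) whose mean
difference is negative. Peak latency is the largest negativity in the window
(earliest sample on ties); peak amplitude is the mean over a 20 ms span
centred on the group-average peak.

Requiring a run instead of any single significant sample is the standard
guard against false positives from temporally autocorrelated ERP noise; note
that at a 1000 Hz sampling rate a 20-sample run is a *weak* guard (see
`docs/methods.md` for its measured false-positive behaviour).

## Worked example

Simulate 15 older-adult subjects at SOA 50 ms (pseudo-letter deviants), build
their opposite-condition difference waves, and fit the runs-based test:

```python
import numpy as np
from vmmn import RunConfig, VmmnTest
from vmmn.channels import ROI_CHANNELS
from vmmn.pipeline import simulate_subject

cfg = RunConfig(channel_labels=ROI_CHANNELS, seed=7)
subjects = [simulate_subject(cfg, "older", i, soas=(50.0,)) for i in range(15)]
series = {roi: np.vstack([s.diff_waves[("pseudo-letter", 50.0)][roi]
                          for s in subjects])
          for roi in ("left", "right")}
times = subjects[0].times_by_soa[50.0]
res = VmmnTest(series, times, condition={"group": "older",
                                         "category": "pseudo-letter",
                                         "soa": 50.0}).fit()
print(res.summary())
```

prints

```
Runs-based mismatch-negativity test
===================================
condition: {'group': 'older', 'category': 'pseudo-letter', 'soa': 50.0}
subjects:  15 (df = 14)
criterion: >= 20 ms consecutive p < 0.05 (two-tailed) in 150-300 ms, any-roi
vMMN present: True
significant windows:
    left:  220.0- 267.0 ms (48 ms)
   right:  199.0- 300.0 ms (102 ms)
  left peak: 242.0 ms, group-centered mean amplitude -0.66 μV
 right peak: 246.0 ms, group-centered mean amplitude -1.11 μV
```

The older profile's persistence limit for pseudo-letters is 50 ms, so the
injected −1.0 μV response at 245 ms is recovered: significant windows overlap
the injection, the right-ROI peak sits at 246 ms, and the group-peak-centred
amplitude is close to −1 μV. Running the same test on a young cohort (limit
0 ms) yields `vMMN present: False` at this SOA.

The full experiment — both groups, all four SOAs, both deviant categories,
detection tables, peak tables, hit-rate and 2AFC ANOVAs, a manifest with
checksums — runs from the command line:

```bash
vmmn run-all --seed 7 --out results/run1          # full 39-channel montage
vmmn simulate --group older --seed 7 --out sim/   # schedules (JSON) + EDF
vmmn preprocess --recording sim/older_letter_soa0_r0.edf \
               --schedule  sim/older_letter_soa0_r0.json --out pre/
```

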