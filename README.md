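# termvib

Analysis of substrate-borne vibrations produced by termite **body-shaking**
(also called tremulation or longitudinal oscillatory movement).  Workers of
subterranean termites such as *Reticulitermes flavipes* shake their whole
body back and forth, injecting velocity transients into the substrate that
a laser Doppler vibrometer can record.  The package is written for
behavioural bioacousticians who have (a) single-channel vibrometer velocity
traces and (b) video-scored behavior logs, and want to turn them into typed
vibration events and context statistics — and for anyone who wants to study
the pipeline itself on fully synthetic data.

## What it computes

A vibration event is a train of **pulses** (short supra-threshold velocity
transients).  Its internal structure is a sequence of **parts**: contiguous
pulse series with a homogeneous pulse rate.  The central quantity is the

```
frequency of a part  =  n_pulses / duration        [Hz]
```

— a pulse *rate*, not a spectral carrier frequency.  Events are classified
into body-shaking types **BS1..BS6 by their number of parts**; multi-part
events start with a fast part (tens of Hz) followed by slower parts,
separated by silent gaps.

Pipeline stages, each an importable function:

1. **Threshold** — `estimate_threshold`: sample ten random windows of the
   recording, take the median of `mean|v| + k·SD|v|` over windows.
2. **Pulse detection** — `detect_pulses`: local maxima of |v| above the
   threshold with an 8 ms refractory interval.
3. **Event grouping** — `group_events`: pulses separated by at most 0.5 s
   belong to one raw event.
4. **Segmentation & typing** — `segment_parts`, `classify_event`:
   inter-pulse-interval change-points split an event into parts;
   the part count is the BS type.
5. **Cross-linking** — `match_events`: an event is *unique* when exactly
   one scored body-shaking interval is concurrent with it; events
   concurrent with several behaviors are discarded from structure
   analyses.
6. **Statistics** — `bin_counts`, `occurrence_analysis`,
   `fit_structure_model`, `tukey_contrasts`: event counts per colony ×
   treatment × 15-s bin with Poisson count models (colony conditioned
   out), and linear mixed models of log duration / log pulse count /
   amplitude with colony random intercepts and Tukey-adjusted contrasts.

A first-class synthetic generator (`GeneratorConfig`, `synthesize_event`,
`generate_trial`, `generate_study`) emulates the full experimental design:
30 workers per box, 5-minute trials, a BS-type mixture dominated by
two-part events (two thirds), per-part pulse-rate targets
(BS2: 38.4 / 13.8 Hz, BS3: 47.2 / 25 Hz, BS4: 54 / 26.5 Hz), per-worker
Poisson event occurrence raised fivefold by reproductive presence, a
transient flashlight effect confined to the first 15-s bin, overlapping
events across workers, Gaussian background noise, and a per-colony
log-normal activity factor.

## Worked example

```python
import numpy as np
from termvib import *

cfg = GeneratorConfig()
trial = generate_trial(cfg, Treatment(reproductives=True, flashlight=False),
                       colony_id="c01", rng=np.random.default_rng(0))
events, matches, info = analyze_trial(trial, rng=np.random.default_rng(1))
print("stage counts:", info)

bs2 = [e for e in events if e.bs_type == 2 and e.unique_flag]
f1 = np.mean([e.parts[0].frequency for e in bs2])
f2 = np.mean([e.parts[1].frequency for e in bs2])
print("unique BS2 events: %d   mean part rates: %.1f Hz / %.1f Hz"
      % (len(bs2), f1, f2))
print("uniqueness fraction: %.2f" % uniqueness_fraction(matches))
```

prints

```
stage counts: {'threshold': 4.969596161374099, 'n_pulses': 730,
               'n_raw_events': 33, 'n_classified': 33, 'n_unique': 26}
unique BS2 events: 17   mean part rates: 55.0 Hz / 13.5 Hz
uniqueness fraction: 0.79
```

One simulated 5-minute R+ trial yielded 730 pulses in 33 events, 26 of
which were attributable to exactly one scored behavior.  The mean first-
part rate of the unique two-part events is elevated above the 38.4 Hz
baseline because reproductive presence adds pulses to — and shortens —
the first part (the configured first-part effects); the second part sits
at its 13.8 Hz target.

The same stages are scriptable from a shell:

```
termvib simulate --n-colonies 2 --out-dir runs/demo
termvib detect --trace runs/demo/c01_R+F-.wav --out runs/demo/events.csv
termvib crosslink --events runs/demo/events.csv \
    --log runs/demo/c01_R+F-_behavior.csv --out runs/demo/match.csv
termvib all --seed 0 --n-colonies 2 --out-dir runs/full
```

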