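# Methods

This note documents the models and numerical choices behind termvib: what
the synthetic generator emulates, how each pipeline stage works, which
parameters matter, and what the simulation-recovery tests do and do not
show about real recordings.

## Signal model

A body-shaking event is modelled as 1–6 **parts**.  Each part is a train
of `n >= 2` pulses evenly spaced over a span `d`, and its **frequency** is
defined throughout as the pulse rate `n / d` (Hz).  This is the quantity
of scientific interest — a repetition rate of whole-body oscillations —
and is deliberately distinct from the oscillation *inside* one pulse.

Each pulse is rendered as a damped sinusoid burst:
`sin(2π·f_c·t)·exp(-t/τ)` over `pulse_width = 4 ms`, with carrier
`f_c = 500 Hz` and `τ = pulse_width/3`, normalized to the configured peak
velocity.  The carrier sits an order of magnitude above every pulse rate,
so the burst's internal oscillation can never alias into a rate estimate;
it merely gives the pulse a realistic oscillatory shape and a finite
width.  The waveform peak is placed on the sample grid, so ground-truth
pulse times are reported both exactly (continuous design) and
sample-quantized (as rendered).

Sampling rate is 4 kHz: at least 2× the carrier and ~100× the fastest
pulse rate.  Background noise is white Gaussian with SD 1.0 in input
units; the default pulse amplitude of 10 gives SNR 10, the regime in
which detection recall is effectively 1.

## Generator: the emulated study

`generate_study` reproduces a crossed design: `n_colonies = 13` colonies
× 4 treatments (reproductives present/absent × flashlight present/absent),
one 300-s trial of 30 workers each.  Parameters, defaults, and reasons:

* `base_event_rate = 1e-3` events·worker⁻¹·s⁻¹ (R− baseline).  Gives ~9
  events per 30-worker R− trial and ~1400 events per 13-colony study —
  the scale of the 1306-event corpus the design is modelled on.
* `reproductive_rate_multiplier = 5.0`: reproductive presence raises
  occurrence strongly; the direction is the established finding, the
  magnitude is a free parameter.
* `flashlight_bin_multiplier = 3.0`, applied only inside the first 15-s
  bin of R+F+ trials: emulates the brief post-flash burst that appears
  only at 15 s and only with reproductives.  Chosen by an a-priori power
  calculation so that the bin-1 contrast is detectable after 20-bin
  multiplicity correction in ≥ 90% of replicate studies (log-rate-ratio
  ln 3 against Poisson totals of ~88 vs ~29 events gives z ≈ 5, beyond
  the adjusted critical value ≈ 3).
* `type_mixture = (0.15, 0.667, 0.10, 0.06, 0.012, 0.001)` over BS1..BS6:
  two-part events are two thirds of the corpus; five- and six-part events
  are rare curiosities.
* Part pulse-rate targets (Hz): BS1 40; BS2 38.4 / 13.8; BS3 47.2 / 25;
  BS4 54 / 26.5 (BS5/6 reuse BS4's).  The first part is always the fast
  one; parts 2..n share the low rate.
* `part_freq_rel_sd = 0.12`: per-event multiplicative jitter of the part
  rate.  Deliberately below the dispersions printed for real corpora
  (~17% for the fast BS2 part), because those pool colony, treatment and
  measurement variance that the generator models separately (colony
  factor, reproductive effects); the residual within-class jitter is
  smaller, and the frequency classes stay separable as they visibly are
  in clean recordings.
* `part_duration_mean = 0.25 s` (rel. SD 0.15) and
  `inter_part_gap = 0.15 s` (rel. SD 0.10).  The realized span of a part
  is `n/f` with `n = round(f·d_target)`, so the stored rate is exactly
  `n/duration`.
* Reproductive first-part effects: pulse count ×1.2 and duration ×0.85
  under R+, first part only (implemented as an effective first-part rate
  ×1.2/0.85 with the duration target ×0.85).  Reproductives add pulses to
  and shorten the first part; magnitudes are free parameters sized for
  well-powered recovery tests.
* `colony_random_sd = 0.3`: a log-normal per-colony rate factor shared by
  the colony's four trials — the generative counterpart of colony as a
  random factor.

Worker event onsets are homogeneous Poisson within each rate segment;
events whose waveform would overrun the trial end are dropped (a <1% edge
effect at 300 s).  Events of different workers may overlap — this is what
the uniqueness rule is for.

### What the generator does *not* emulate

No substrate transfer function or membrane mechanics (amplitudes carry no
distance dependence), no head-drumming or soldier behaviours, no
non-stationary background noise, no video-scoring errors (behavior logs
are exact).  Passing recovery tests therefore demonstrates correctness of
the *analysis* under the stated signal model, not robustness to rig
physics or scoring noise.

## Detection

`estimate_threshold` interprets "ten random points per recording" as ten
random 0.1-s windows; each contributes `mean|v| + k·SD|v|`, and the
median over windows is the threshold (floored at 1e-12 input units for
degenerate all-zero input).  The median resists windows that land on
events, though for events occupying a large fraction of a short trace the
estimate can still inflate — the synthetic cohorts therefore embed events
at ≤ ~20% occupancy, matching the sparseness of real 5-minute trials.

`k = 7` by default: the threshold then sits at
`(0.798 + 7·0.603)σ ≈ 5.0σ` of Gaussian noise (half-normal moments), and
`P(|N| > 5.0) × 1.2e6 samples < 1` expected false peak per 300-s trial at
4 kHz.  `k` is config-exposed.

`detect_pulses` keeps local maxima of |v| above threshold and suppresses
all but the largest peak within an 8-ms refractory interval (ties go to
the earlier peak).  8 ms sits above the pulse width (4 ms) and below the
shortest credible inter-pulse interval (54 Hz → 18.5 ms).  `group_events`
closes a raw event after a 0.5-s pulse-free gap — larger than any
inter-part gap, smaller than typical inter-event spacing.

## Segmentation

Part boundaries are found from inter-pulse intervals (IPIs), not spectra:
a rate change is an IPI-scale change by definition of the rate.

1. **Boundary rule.** An IPI is a boundary when it exceeds
   `gap_ratio = 3` times the running scale of non-boundary IPIs,
   iterated to a fixed point (the boundary set grows monotonically).
   The scale is the **lower quartile** of the non-boundary IPIs: in
   events with several slow parts the slow IPIs outnumber the fast
   first-part IPIs, so a median would drift onto the slow block and push
   the threshold up to the gap scale itself; the lower quartile stays
   anchored on the fastest train.
2. **Fragment merging.** Runs with fewer than `min_part_pulses = 2`
   pulses (no defined rate) merge into a neighbour.  A slow part whose
   own IPIs exceed the global threshold arrives here shattered into
   singletons; to keep its fragments from leaking into the adjacent fast
   part, an undersized neighbour is preferred whenever its gap is within
   `merge_ratio = 1.5`× of the alternative, otherwise the smaller gap
   wins (ties go left).
3. **Reassembly.** Adjacent parts re-join when the gap between them is at
   most `merge_ratio`× their internal IPI scale: fragments of one train
   are spaced at exactly that train's IPI (ratio ≈ 1), while a true
   boundary gap is ≥ `gap_ratio`× the slower IPI by construction.

Durations run first pulse to last pulse per part; the whole-event
duration spans the first pulse of P1 to the last pulse of the final part,
inter-part gaps included.  The BS type is the part count; events with
more than six parts keep their literal count and a `beyond_range` flag
and are excluded from BS-type summaries.  Events with a single pulse are
discarded (no rate is defined).

On noise-embedded single-event fixtures at the default SNR this recovers
the generated type for ~99% of events, with confusions confined to
adjacent part counts, and recovers mean part rates to well within 1%.

## Cross-linking

An event and a behavior interval match when their half-open intervals,
each expanded by `tolerance = 0.2 s`, intersect.  The tolerance absorbs
video-versus-laser clock skew and scoring latency; how strictly
"simultaneous" should be judged is genuinely open, so it is
config-exposed.  Unique events (exactly one match) enter structure
analyses; the uniqueness fraction falls monotonically with event rate, as
overlap becomes more likely.

## Statistics

**Occurrence.**  Events are counted per colony × treatment × 15-s bin
(half-open bins, totals conserved).  Counts are modelled with a Poisson
GLM containing colony as a **fixed** effect: no frequentist Poisson GLMM
with likelihood-ratio tests is available in the Python stack, and with 13
colony levels conditioning on colony fixed effects tests the same
within-colony contrasts while remaining numerically robust; the
`ModelReport.model_path` field records which path ran.  The analysis
mirrors the two-stage design: time (categorical) and reproductive
presence first (interaction simplified away when non-significant), then a
split by reproductive context with `time × flashlight` within each half
and per-bin flashlight contrasts.  The per-bin contrast family is
adjusted single-step Šidák across the 20 bins (the family is not an
all-pairwise set, where a studentized-range adjustment would apply).

**Structure.**  Duration and pulse counts are log-transformed (amplitude
is not) and modelled per reporting view — all parts pooled, first part,
parts 2–4, last part — with `bs_type * reproductives * flashlight` fixed
effects and a colony random intercept (linear mixed model, ML; several
optimizers are tried, and a colony fixed-effect OLS is the recorded
fallback when no mixed fit converges).  Only unique events of types
BS1–BS4 enter (five- and six-part events are too rare to model).
Interactions are removed stepwise, highest order first, at α = 0.05; each
retained effect gets a likelihood-ratio test on ML refits.  Pairwise type
contrasts are Tukey-adjusted via the studentized range on `√2·|t|` with
the residual degrees of freedom; with two levels the adjusted p equals
the raw p.

Analyses run at desk scale: recovery and calibration suites use 500–800
events per cohort, 50 replicate studies for effect recovery and 200 for
null calibration — sizes at which Monte-Carlo error is a small fraction
of each tested tolerance.

## Known limitations

* The threshold estimator assumes the recording is mostly background; a
  recording saturated with events inflates the threshold (see above).
* Segmentation resolves parts whose rates differ by roughly the
  `gap_ratio` margin; a two-part event whose slow-part IPI approaches the
  inter-part gap (low-rate tail draws) can collapse into one part — at
  the defaults this affects ~1% of two-part events, biasing nothing
  beyond a slight yield loss.
* Amplitude is carried through unmodelled (no emitter–receiver distance),
  so amplitude contrasts on synthetic data only exercise bookkeeping.
* The colony fixed-effect count model estimates within-colony effects; it
  does not generalize variance components to a colony population the way
  a true GLMM would.
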