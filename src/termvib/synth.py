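"""Synthetic vibrometer study generator.

Emulates the statistical structure of a body-shaking vibrometry study:
multi-part pulse-train events whose first part runs at a higher pulse rate
than the remaining parts, a type mixture dominated by two-part events,
per-worker Poisson occurrence raised by reproductive presence, a transient
flashlight effect confined to the first 15-s bin of R+F+ trials, Gaussian
background noise, and a per-colony log-normal activity factor shared by the
four treatments of a colony.

Every pulse is a short damped sinusoid burst.  The burst carrier (hundreds
of Hz) is deliberately far above every pulse *rate* (tens of Hz), so the
"frequency" of a part in the pulses-per-duration sense is band-separated
from the oscillation inside a single pulse.

Ground truth records the exact continuous-time design of each event: the
stored per-part ``frequency`` equals ``n_pulses / duration`` exactly, while
pulse times are additionally provided sample-quantized as they appear in
the rendered trace.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import GeneratorConfig
from .types import (
    ALL_TREATMENTS,
    BehaviorLog,
    BehaviorRecord,
    EventTruth,
    GroundTruth,
    PartTruth,
    Trace,
    Treatment,
    Trial,
)

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: Optional[RngLike]) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def pulse_template(cfg: GeneratorConfig) -> Tuple[np.ndarray, int]:
    """Unit-peak damped-sinusoid burst and the index of its peak sample.

    The burst is ``sin(2*pi*carrier*t) * exp(-t/tau)`` over ``pulse_width``
    seconds with ``tau = pulse_width/3``, rescaled to unit peak.
    """
    n = max(3, int(round(cfg.pulse_width * cfg.sample_rate)))
    t = np.arange(n) / cfg.sample_rate
    tau = cfg.pulse_width / 3.0
    y = np.sin(2.0 * np.pi * cfg.pulse_carrier * t) * np.exp(-t / tau)
    peak = int(np.argmax(np.abs(y)))
    y = y / abs(y[peak])
    return y, peak


def _jitter(rng: np.random.Generator, rel_sd: float, floor: float = 0.1) -> float:
    """Multiplicative 1 + N(0, rel_sd) jitter, floored away from zero."""
    return max(floor, 1.0 + rel_sd * rng.standard_normal())


def _design_event(
    bs_type: int,
    treatment: Treatment,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> List[dict]:
    """Draw the continuous-time design (per-part pulse times/amplitudes)."""
    if not 1 <= bs_type <= 6:
        raise ValueError(f"bs_type must be in 1..6, got {bs_type}")
    parts = []
    t_cursor = 0.0
    for i in range(1, bs_type + 1):
        if i == 1:
            f_mean = cfg.part_freq_high[bs_type]
        else:
            f_mean = cfg.part_freq_low[bs_type]
        f = f_mean * _jitter(rng, cfg.part_freq_rel_sd)
        d_target = cfg.part_duration_mean * _jitter(rng, cfg.part_duration_rel_sd)
        if i == 1 and treatment.reproductives:
            # Reproductives add pulses to the first part while shortening it;
            # the implied first-part pulse rate rises by pulse/duration.
            f *= (cfg.reproductive_firstpart_pulse_effect
                  / cfg.reproductive_firstpart_duration_effect)
            d_target *= cfg.reproductive_firstpart_duration_effect
        f = max(f, 2.0)
        n = max(2, int(round(f * d_target)))
        d = n / f
        f = n / d  # re-derive so the stored rate is bit-exact n/duration
        times = t_cursor + np.linspace(0.0, d, n)
        amps = cfg.pulse_amplitude * np.array(
            [_jitter(rng, cfg.pulse_amplitude_rel_sd) for _ in range(n)]
        )
        parts.append({"index": i, "n": n, "duration": d, "frequency": f,
                      "onset": t_cursor, "times": times, "amps": amps})
        gap = cfg.inter_part_gap * _jitter(rng, cfg.inter_part_gap_rel_sd)
        t_cursor = times[-1] + max(gap, 0.02)
    return parts


def synthesize_event(
    bs_type: int,
    treatment: Treatment,
    cfg: Optional[GeneratorConfig] = None,
    rng: Optional[RngLike] = None,
) -> Tuple[np.ndarray, EventTruth]:
    """Render one body-shaking event waveform plus its exact ground truth.

    The waveform contains ``bs_type`` parts: part 1 is a pulse train at the
    type's high pulse rate, parts 2..n run at the low rate, separated by
    silent inter-part gaps.  The returned waveform is noise-free; the first
    pulse peak sits one template-length into the array.

    Returns
    -------
    waveform : ndarray
        Noise-free velocity samples at ``cfg.sample_rate``.
    truth : EventTruth
        Per-part pulse counts, exact durations/frequencies and
        sample-quantized pulse times, relative to the first pulse.
    """
    cfg = cfg or GeneratorConfig()
    rng = _as_rng(rng)
    design = _design_event(bs_type, treatment, cfg, rng)
    tpl, peak = pulse_template(cfg)
    fs = cfg.sample_rate

    pad = len(tpl) / fs
    span = design[-1]["times"][-1]
    n_samples = int(np.ceil((pad + span) * fs)) + 2 * len(tpl)
    wav = np.zeros(n_samples)

    truth_parts = []
    for p in design:
        qtimes = []
        for t, a in zip(p["times"], p["amps"]):
            idx = int(round((pad + t) * fs))
            start = idx - peak
            wav[start:start + len(tpl)] += a * tpl
            qtimes.append(idx / fs - pad)
        truth_parts.append(PartTruth(
            index=p["index"], n_pulses=p["n"], duration=p["duration"],
            frequency=p["frequency"], onset=p["onset"],
            pulse_times=tuple(qtimes), amplitudes=tuple(p["amps"]),
        ))
    truth = EventTruth(worker_id="w0", onset=0.0, bs_type=bs_type,
                       parts=tuple(truth_parts))
    return wav, truth


def _draw_onsets(
    rate: float,
    flash_extra: float,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Homogeneous Poisson onsets, with an elevated rate in the first
    flashlight bin when ``flash_extra > 1``."""
    T, w = cfg.trial_duration, min(cfg.flashlight_bin_width, cfg.trial_duration)
    onsets = []
    n1 = rng.poisson(rate * flash_extra * w)
    onsets.append(rng.uniform(0.0, w, size=n1))
    if T > w:
        n2 = rng.poisson(rate * (T - w))
        onsets.append(rng.uniform(w, T, size=n2))
    return np.sort(np.concatenate(onsets))


def generate_trial(
    cfg: GeneratorConfig,
    treatment: Treatment,
    colony_id: str = "c01",
    rng: Optional[RngLike] = None,
    colony_rate_factor: float = 1.0,
    render_trace: bool = True,
) -> Trial:
    """Simulate one 5-minute recording of ``cfg.n_workers`` workers.

    Each worker emits events as a Poisson process at
    ``base_event_rate * (reproductive multiplier if R+) * colony factor``;
    in R+F+ trials the first flashlight bin gets an extra rate multiplier.
    Events may overlap across workers.  The trace is the sum of event
    waveforms plus Gaussian noise; the behavior log holds one
    "body-shaking" interval per ground-truth event.

    Events whose waveform would overrun the trial end are dropped (a small
    edge effect relative to a 300-s trial).
    """
    rng = _as_rng(rng)
    rate = cfg.base_event_rate * colony_rate_factor
    if treatment.reproductives:
        rate *= cfg.reproductive_rate_multiplier
    flash_extra = (cfg.flashlight_bin_multiplier
                   if (treatment.reproductives and treatment.flashlight) else 1.0)

    fs = cfg.sample_rate
    n_samples = int(round(cfg.trial_duration * fs))
    samples = (rng.normal(0.0, cfg.noise_sd, size=n_samples)
               if render_trace else None)
    tpl_len = max(3, int(round(cfg.pulse_width * fs)))
    pad = tpl_len / fs

    events: List[EventTruth] = []
    records: List[BehaviorRecord] = []
    for w in range(cfg.n_workers):
        worker = f"w{w:02d}"
        for onset in _draw_onsets(rate, flash_extra, cfg, rng):
            bs_type = int(rng.choice(6, p=cfg.type_mixture)) + 1
            wav, truth = synthesize_event(bs_type, treatment, cfg, rng)
            dur = truth.parts[-1].onset + truth.parts[-1].duration
            if onset + dur + 2 * pad >= cfg.trial_duration:
                continue
            ev = EventTruth(worker_id=worker, onset=float(onset),
                            bs_type=bs_type, parts=truth.parts)
            events.append(ev)
            records.append(BehaviorRecord(worker, "body-shaking",
                                          float(onset), float(onset + dur)))
            if render_trace:
                start = int(round(onset * fs)) - tpl_len
                start = max(start, 0)
                stop = min(start + len(wav), n_samples)
                samples[start:stop] += wav[: stop - start]

    flash_time = 0.0 if treatment.flashlight else None
    truth = GroundTruth(events=events, treatment=treatment,
                        colony_id=colony_id, flash_time=flash_time)
    trace = None
    if render_trace:
        trace = Trace(samples=samples, sample_rate=fs, t0=0.0,
                      colony_id=colony_id, treatment=treatment,
                      flash_time=flash_time)
    return Trial(trace=trace, log=BehaviorLog(records), truth=truth)


def generate_study(
    cfg: GeneratorConfig,
    n_colonies: int = 13,
    rng: Optional[RngLike] = None,
    render_trace: bool = False,
) -> List[Trial]:
    """Simulate the full crossed design: every colony runs the four
    treatments R+F+, R+F-, R-F+, R-F-, sharing one log-normal colony
    activity factor.

    Traces are rendered only on request (a 13-colony study holds 52 five-
    minute traces; ground truth and logs are enough for occurrence work).
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    rng = _as_rng(rng if rng is not None else cfg.seed)
    factors = np.exp(cfg.colony_random_sd * rng.standard_normal(n_colonies))
    trials = []
    for c in range(n_colonies):
        colony_id = f"c{c + 1:02d}"
        for treatment in ALL_TREATMENTS:
            trials.append(generate_trial(
                cfg, treatment, colony_id=colony_id, rng=rng,
                colony_rate_factor=float(factors[c]),
                render_trace=render_trace,
            ))
    return trials
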