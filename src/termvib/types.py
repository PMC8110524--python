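"""Core in-memory containers shared across the pipeline.

Times are seconds from trial start (t = 0 at recording onset; when a
flashlight was applied it ends at t = 0).  All intervals are half-open
[onset, offset).  Velocity units are the input units of the vibrometer
trace, consistent but arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class Treatment:
    """Social/stimulus context of one trial: R+/- x F+/-."""

    reproductives: bool
    flashlight: bool

    @property
    def label(self) -> str:
        return f"R{'+' if self.reproductives else '-'}F{'+' if self.flashlight else '-'}"


#: Trial order used by :func:`termvib.synth.generate_study`.
ALL_TREATMENTS = (
    Treatment(True, True), Treatment(True, False),
    Treatment(False, True), Treatment(False, False),
)


@dataclass
class Trace:
    """A uniformly sampled velocity signal with recording metadata."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    colony_id: Optional[str] = None
    treatment: Optional[Treatment] = None
    flash_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be strictly positive")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class BehaviorRecord:
    worker_id: str
    behavior: str
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.offset < self.onset:
            raise ValueError(
                f"behavior record offset {self.offset} precedes onset {self.onset}"
            )


@dataclass
class BehaviorLog:
    """Timed behavior intervals per worker from video scoring."""

    records: List[BehaviorRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.onset, r.offset))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


@dataclass(frozen=True)
class Pulse:
    """One supra-threshold velocity transient: time of the peak and its
    absolute peak amplitude."""

    time: float
    amplitude: float


@dataclass(frozen=True)
class NoiseThreshold:
    """Amplitude threshold estimated from random background windows."""

    threshold: float
    window_stats: tuple  # of (window_start_s, mean_abs, sd_abs)
    k: float


@dataclass(frozen=True)
class Part:
    """A contiguous pulse series with a homogeneous pulse rate.

    ``frequency`` is the pulse rate n_pulses/duration in Hz — a repetition
    rate, not a spectral carrier frequency.
    """

    index: int
    onset: float
    offset: float
    n_pulses: int
    amplitude: float

    def __post_init__(self) -> None:
        if self.n_pulses < 2:
            raise ValueError("a part needs at least 2 pulses")
        if self.offset <= self.onset:
            raise ValueError("part duration must be strictly positive")

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    @property
    def frequency(self) -> float:
        return self.n_pulses / self.duration


@dataclass
class VibrationEvent:
    """A typed multi-part vibration event (the detection-hierarchy root)."""

    parts: List[Part]
    colony_id: Optional[str] = None
    treatment: Optional[Treatment] = None
    unique_flag: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.parts:
            raise ValueError("an event must contain at least one part")
        for a, b in zip(self.parts, self.parts[1:]):
            if b.onset < a.offset:
                raise ValueError("parts must be ordered and non-overlapping")

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    @property
    def bs_type(self) -> int:
        """Body-shaking type = number of parts (BS1..BS6)."""
        return self.n_parts

    @property
    def beyond_range(self) -> bool:
        """True for events with more than six parts; such events are kept but
        excluded from BS-type summaries by default."""
        return self.n_parts > 6

    @property
    def onset(self) -> float:
        return self.parts[0].onset

    @property
    def offset(self) -> float:
        return self.parts[-1].offset

    @property
    def total_duration(self) -> float:
        """First pulse of P1 to last pulse of the final part, inclusive of
        inter-part gaps."""
        return self.offset - self.onset

    @property
    def total_pulses(self) -> int:
        return sum(p.n_pulses for p in self.parts)

    @property
    def mean_amplitude(self) -> float:
        n = self.total_pulses
        return sum(p.amplitude * p.n_pulses for p in self.parts) / n


# --------------------------------------------------------------------------
# Ground truth emitted by the synthetic generator

@dataclass(frozen=True)
class PartTruth:
    """Exact (pre-quantization) design of one generated part."""

    index: int
    n_pulses: int
    duration: float      # exact continuous-time first-to-last pulse span
    frequency: float     # == n_pulses / duration exactly
    onset: float         # event-relative time of first pulse
    pulse_times: tuple   # sample-quantized, event-relative
    amplitudes: tuple


@dataclass(frozen=True)
class EventTruth:
    worker_id: str
    onset: float         # trial time of the first pulse
    bs_type: int
    parts: tuple         # of PartTruth

    @property
    def offset(self) -> float:
        last = self.parts[-1]
        return self.onset + last.onset + last.duration

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class GroundTruth:
    """Per-trial generated truth used to score the pipeline."""

    events: List[EventTruth]
    treatment: Treatment
    colony_id: str
    flash_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.onset)


@dataclass
class Trial:
    """One simulated recording: trace (optional), behavior log, truth."""

    trace: Optional[Trace]
    log: BehaviorLog
    truth: GroundTruth

    @property
    def colony_id(self) -> str:
        return self.truth.colony_id

    @property
    def treatment(self) -> Treatment:
        return self.truth.treatment


@dataclass(frozen=True)
class MatchResult:
    """Outcome of cross-linking one vibration event to the behavior log."""

    event_id: int
    matched_behavior_ids: tuple
    unique_flag: bool
    discard_reason: Optional[str]  # None | "no-behavior-match" | "multiple-concurrent-behaviors"
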