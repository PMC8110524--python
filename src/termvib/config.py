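"""Configuration objects for the synthetic study generator and the analysis run.

The generator configuration pins down the full parameterization of a
synthetic vibrometry study: per-worker event rates, the body-shaking type
mixture, per-part pulse-rate targets, pulse morphology, background noise,
and the two social-context effects (reproductive presence, flashlight).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is outside its documented domain."""


#: Default mixture of body-shaking types BS1..BS6.  BS2 dominates (two thirds
#: of events); five- and six-part events are vanishingly rare.
DEFAULT_TYPE_MIXTURE = (0.15, 0.667, 0.10, 0.06, 0.012, 0.001)

#: Mean pulse rate (Hz, pulses per second of part) of the FIRST part of each
#: body-shaking type.  BS5/BS6 are too rare to have published rates and reuse
#: the BS4 values.
DEFAULT_PART_FREQ_HIGH: Mapping[int, float] = {
    1: 40.0, 2: 38.4, 3: 47.2, 4: 54.0, 5: 54.0, 6: 54.0,
}

#: Mean pulse rate (Hz) of parts 2..n (the "low" block).  BS1 has a single
#: part and therefore no low-rate block.
DEFAULT_PART_FREQ_LOW: Mapping[int, float] = {
    2: 13.8, 3: 25.0, 4: 26.5, 5: 26.5, 6: 26.5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic body-shaking study.

    Parameters
    ----------
    n_workers
        Workers per experimental box (30 in the study design).
    trial_duration
        Length of one recording in seconds (5-minute trials).
    sample_rate
        Vibrometer export rate in Hz.  4 kHz keeps the 500 Hz pulse carrier
        comfortably below Nyquist while staying desk-scale.
    base_event_rate
        Per-worker body-shaking rate (events / worker / s) in the absence of
        reproductives.  The default of 1e-3 yields ~9 events per 30-worker
        R- trial and a ~1400-event corpus over a 13-colony, 4-treatment
        study, matching the scale of the observed corpus.
    reproductive_rate_multiplier
        Rate multiplier applied when reproductives are present (R+).
    flashlight_bin_multiplier
        Extra rate multiplier applied ONLY within the first
        ``flashlight_bin_width`` seconds of R+F+ trials, emulating the brief
        post-flash burst of body-shaking.
    type_mixture
        Probability vector over BS1..BS6; renormalized on construction.
    part_freq_high, part_freq_low
        Mean pulse rate of the first part / later parts per type (Hz).
    part_freq_rel_sd
        Relative SD of per-event pulse-rate jitter around the type means.
    part_duration_mean, part_duration_rel_sd
        Target duration of one part (s) and its relative jitter.
    inter_part_gap
        Mean silent interval between consecutive parts (s).
    reproductive_firstpart_pulse_effect
        Multiplicative increase of the first-part pulse count under R+.
    reproductive_firstpart_duration_effect
        Multiplicative change of the first-part duration under R+ (<1:
        reproductives shorten the first part while adding pulses).
    pulse_width, pulse_carrier
        Width (s) and carrier frequency (Hz) of the damped burst standing in
        for one pulse.  The carrier is far above every pulse *rate*, so the
        burst oscillation never aliases into the rate measurement.
    pulse_amplitude, pulse_amplitude_rel_sd
        Peak velocity of a pulse (input units; default 10x the noise SD) and
        its relative jitter.
    noise_sd
        Gaussian background-noise SD (velocity units).
    colony_random_sd
        SD of the per-colony log-rate factor (colonies differ in overall
        vibratory activity).
    seed
        Default seed for generators constructed from this config.
    """

    n_workers: int = 30
    trial_duration: float = 300.0
    sample_rate: float = 4000.0
    base_event_rate: float = 1.0e-3
    reproductive_rate_multiplier: float = 5.0
    flashlight_bin_multiplier: float = 3.0
    flashlight_bin_width: float = 15.0
    type_mixture: tuple = DEFAULT_TYPE_MIXTURE
    part_freq_high: dict = field(default_factory=lambda: dict(DEFAULT_PART_FREQ_HIGH))
    part_freq_low: dict = field(default_factory=lambda: dict(DEFAULT_PART_FREQ_LOW))
    part_freq_rel_sd: float = 0.12
    part_duration_mean: float = 0.25
    part_duration_rel_sd: float = 0.15
    inter_part_gap: float = 0.15
    inter_part_gap_rel_sd: float = 0.10
    reproductive_firstpart_pulse_effect: float = 1.2
    reproductive_firstpart_duration_effect: float = 0.85
    pulse_width: float = 0.004
    pulse_carrier: float = 500.0
    pulse_amplitude: float = 10.0
    pulse_amplitude_rel_sd: float = 0.10
    noise_sd: float = 1.0
    colony_random_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        mix = tuple(float(p) for p in self.type_mixture)
        if len(mix) != 6:
            raise ConfigError("type_mixture must have 6 entries (BS1..BS6)")
        if any(p < 0 for p in mix):
            raise ConfigError("type_mixture entries must be >= 0")
        total = sum(mix)
        if total <= 0:
            raise ConfigError("type_mixture must have positive mass")
        if abs(total - 1.0) > 1e-12:  # keep already-normalized vectors stable
            mix = tuple(p / total for p in mix)
        object.__setattr__(self, "type_mixture", mix)

        for name in (
            "trial_duration", "sample_rate", "reproductive_rate_multiplier",
            "flashlight_bin_multiplier", "flashlight_bin_width",
            "part_duration_mean", "inter_part_gap", "pulse_width",
            "pulse_carrier", "pulse_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in (
            "base_event_rate", "noise_sd", "colony_random_sd",
            "part_freq_rel_sd", "part_duration_rel_sd", "inter_part_gap_rel_sd",
            "pulse_amplitude_rel_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_workers < 0:
            raise ConfigError("n_workers must be >= 0")
        if (self.reproductive_firstpart_pulse_effect <= 0
                or self.reproductive_firstpart_duration_effect <= 0):
            raise ConfigError("reproductive first-part effects must be > 0")
        for t in range(1, 7):
            if self.part_freq_high.get(t, 0.0) <= 0:
                raise ConfigError(f"part_freq_high missing/invalid for type {t}")
        for t in range(2, 7):
            low = self.part_freq_low.get(t, 0.0)
            if low <= 0:
                raise ConfigError(f"part_freq_low missing/invalid for type {t}")
            if self.part_freq_high[t] <= low:
                raise ConfigError(
                    f"part_freq_high must exceed part_freq_low for type {t}"
                )

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["type_mixture"] = list(self.type_mixture)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
        kw = dict(d)
        for key in ("part_freq_high", "part_freq_low"):
            if key in kw:
                kw[key] = {int(k): float(v) for k, v in kw[key].items()}
        if "type_mixture" in kw:
            kw["type_mixture"] = tuple(kw["type_mixture"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping")
        return cls.from_dict(d)


@dataclass(frozen=True)
class RunConfig:
    """Analysis-run parameters shared by the CLI subcommands."""

    threshold_k: float = 7.0
    threshold_n_windows: int = 10
    threshold_window_len: float = 0.1
    refractory: float = 0.008
    max_intra_event_gap: float = 0.5
    gap_ratio: float = 3.0
    min_part_pulses: int = 2
    crosslink_tolerance: float = 0.2
    bin_width: float = 15.0
    alpha: float = 0.05
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        for name in ("threshold_k", "threshold_window_len", "refractory",
                     "max_intra_event_gap", "gap_ratio", "bin_width"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if self.threshold_n_windows < 1:
            raise ConfigError("threshold_n_windows must be >= 1")
        if self.min_part_pulses < 2:
            raise ConfigError("min_part_pulses must be >= 2")
        if self.crosslink_tolerance < 0:
            raise ConfigError("crosslink_tolerance must be >= 0")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
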