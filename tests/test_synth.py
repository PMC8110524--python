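"""Generator behaviour: event construction, rates, effects, determinism."""

import numpy as np
import pytest

from termvib import (
    ConfigError,
    GeneratorConfig,
    Treatment,
    generate_study,
    generate_trial,
    synthesize_event,
)

RMINUS = Treatment(False, False)
RPLUS = Treatment(True, False)


class TestConfig:
    def test_mixture_renormalized(self):
        cfg = GeneratorConfig(type_mixture=(2, 2, 2, 2, 1, 1))
        assert pytest.approx(sum(cfg.type_mixture)) == 1.0
        assert cfg.type_mixture[0] == pytest.approx(0.2)

    @pytest.mark.parametrize("kw", [
        {"type_mixture": (1, 1, 1, 1, 1, -1)},
        {"sample_rate": 0.0},
        {"part_duration_mean": -0.1},
        {"part_freq_low": {2: 50.0, 3: 25.0, 4: 26.5, 5: 26.5, 6: 26.5}},
        {"reproductive_firstpart_duration_effect": 0.0},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ConfigError):
            GeneratorConfig(**kw)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_workers=7, seed=3)
        cfg.to_yaml(tmp_path / "gen.yaml")
        assert GeneratorConfig.from_yaml(tmp_path / "gen.yaml") == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ConfigError, match="unknown"):
            GeneratorConfig.from_dict({"n_wrkers": 3})


class TestSynthesizeEvent:
    def test_bad_type_rejected(self, default_cfg):
        with pytest.raises(ValueError, match="bs_type"):
            synthesize_event(7, RMINUS, default_cfg, np.random.default_rng(0))

    @pytest.mark.parametrize("bs_type", [1, 2, 3, 4, 5, 6])
    def test_part_count_and_frequency_identity(self, default_cfg, bs_type):
        """An event of type k holds k parts whose stored frequency is
        exactly n_pulses/duration, with part 1 the fastest."""
        _, truth = synthesize_event(bs_type, RMINUS, default_cfg,
                                    np.random.default_rng(bs_type))
        assert truth.bs_type == bs_type
        assert len(truth.parts) == bs_type
        for p in truth.parts:
            assert p.frequency == p.n_pulses / p.duration
        if bs_type >= 2:
            for later in truth.parts[1:]:
                assert truth.parts[0].frequency > later.frequency

    def test_bs1_single_series_near_40hz(self, default_cfg):
        rng = np.random.default_rng(0)
        freqs = [synthesize_event(1, RMINUS, default_cfg, rng)[1]
                 .parts[0].frequency for _ in range(300)]
        assert np.mean(freqs) == pytest.approx(40.0, rel=0.03)

    def test_bs2_part_frequencies_match_defaults(self, default_cfg):
        rng = np.random.default_rng(1)
        f1, f2 = [], []
        for _ in range(400):
            _, truth = synthesize_event(2, RMINUS, default_cfg, rng)
            f1.append(truth.parts[0].frequency)
            f2.append(truth.parts[1].frequency)
        assert np.mean(f1) == pytest.approx(38.4, rel=0.02)
        assert np.mean(f2) == pytest.approx(13.8, rel=0.02)

    def test_deterministic_pulse_count_without_jitter(self):
        """A 0.25 s part at a forced 40 Hz pulse rate holds exactly 10
        pulses when all jitter is switched off."""
        cfg = GeneratorConfig(part_freq_rel_sd=0.0, part_duration_rel_sd=0.0,
                              part_freq_high={1: 40.0, 2: 40.0, 3: 47.2,
                                              4: 54.0, 5: 54.0, 6: 54.0})
        _, truth = synthesize_event(2, RMINUS, cfg, np.random.default_rng(0))
        assert truth.parts[0].n_pulses == 10

    def test_waveform_finite_and_peak_bounded(self, default_cfg):
        wav, _ = synthesize_event(4, RMINUS, default_cfg,
                                  np.random.default_rng(3))
        assert np.all(np.isfinite(wav))
        bound = default_cfg.pulse_amplitude * (
            1 + 6 * default_cfg.pulse_amplitude_rel_sd)
        assert np.max(np.abs(wav)) <= bound

    def test_reproductives_affect_first_part_only(self, default_cfg):
        """R+ scales the first-part pulse count up by the configured factor
        and shortens its duration; later parts are untouched."""
        rng = np.random.default_rng(4)
        stats = {}
        for name, ctx in (("R-", RMINUS), ("R+", RPLUS)):
            n1, d1, n2 = [], [], []
            for _ in range(1500):
                _, truth = synthesize_event(2, ctx, default_cfg, rng)
                n1.append(truth.parts[0].n_pulses)
                d1.append(truth.parts[0].duration)
                n2.append(truth.parts[1].n_pulses)
            stats[name] = (np.mean(n1), np.mean(d1), np.mean(n2))
        pulse_ratio = stats["R+"][0] / stats["R-"][0]
        dur_ratio = stats["R+"][1] / stats["R-"][1]
        part2_ratio = stats["R+"][2] / stats["R-"][2]
        assert pulse_ratio == pytest.approx(
            default_cfg.reproductive_firstpart_pulse_effect, abs=0.05)
        assert dur_ratio == pytest.approx(
            default_cfg.reproductive_firstpart_duration_effect, abs=0.05)
        assert part2_ratio == pytest.approx(1.0, abs=0.05)


class TestGenerateTrial:
    def test_zero_rate_gives_pure_noise(self, default_cfg):
        cfg = default_cfg.replace(base_event_rate=0.0, trial_duration=30.0)
        trial = generate_trial(cfg, RMINUS, rng=np.random.default_rng(0))
        assert len(trial.log) == 0
        assert len(trial.truth.events) == 0
        assert np.std(trial.trace.samples) == pytest.approx(cfg.noise_sd,
                                                            rel=0.05)

    def test_log_mirrors_truth(self, default_cfg):
        trial = generate_trial(default_cfg, RPLUS,
                               rng=np.random.default_rng(1),
                               render_trace=False)
        assert len(trial.log) == len(trial.truth.events)
        for rec in trial.log:
            assert rec.behavior == "body-shaking"

    def test_reproductive_rate_multiplier_recovered(self, default_cfg):
        """Across replicate trials the R+/R- mean event-count ratio matches
        the generating multiplier (law of the Poisson process)."""
        rng = np.random.default_rng(2)
        counts = {}
        for name, ctx in (("R-", RMINUS), ("R+", RPLUS)):
            counts[name] = np.mean([
                len(generate_trial(default_cfg, ctx, rng=rng,
                                   render_trace=False).truth.events)
                for _ in range(200)
            ])
        ratio = counts["R+"] / counts["R-"]
        assert ratio == pytest.approx(
            default_cfg.reproductive_rate_multiplier, rel=0.10)

    def test_flashlight_boost_confined_to_first_bin(self, default_cfg):
        """In R+F+ trials the first 15-s bin runs at the extra multiplier;
        bins 2..20 keep the base R+ rate."""
        rng = np.random.default_rng(3)
        w = default_cfg.flashlight_bin_width
        first, rest = 0, 0
        n_trials = 300
        for _ in range(n_trials):
            trial = generate_trial(default_cfg, Treatment(True, True),
                                   rng=rng, render_trace=False)
            onsets = np.array([e.onset for e in trial.truth.events])
            first += np.sum(onsets < w)
            rest += np.sum(onsets >= w)
        n_rest_bins = default_cfg.trial_duration / w - 1
        ratio = first / (rest / n_rest_bins)
        assert ratio == pytest.approx(
            default_cfg.flashlight_bin_multiplier, rel=0.12)


class TestGenerateStudy:
    def test_study_size(self, default_cfg):
        cfg = default_cfg.replace(base_event_rate=1e-4)
        trials = generate_study(cfg, n_colonies=3,
                                rng=np.random.default_rng(0))
        assert len(trials) == 12
        labels = {(t.colony_id, t.treatment.label) for t in trials}
        assert len(labels) == 12

    def test_determinism(self, default_cfg):
        cfg = default_cfg.replace(trial_duration=20.0, n_workers=5,
                                  base_event_rate=5e-3)
        a = generate_study(cfg, 2, np.random.default_rng(7), render_trace=True)
        b = generate_study(cfg, 2, np.random.default_rng(7), render_trace=True)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.trace.samples, tb.trace.samples)
            assert [r.onset for r in ta.log] == [r.onset for r in tb.log]

    def test_degenerate_colony_effect(self, default_cfg):
        """With zero colony SD every colony shares the same expected rate:
        over many event draws the colony totals agree statistically."""
        cfg = default_cfg.replace(colony_random_sd=0.0, base_event_rate=5e-3)
        trials = generate_study(cfg, 2, np.random.default_rng(8))
        totals = {}
        for t in trials:
            totals[t.colony_id] = totals.get(t.colony_id, 0) + len(t.truth.events)
        a, b = totals.values()
        assert abs(a - b) < 4 * np.sqrt(a + b)

    def test_type_mixture_proportions(self, default_cfg):
        """Empirical BS-type proportions over >=2000 generated events match
        the configured mixture within 3 binomial SEs."""
        cfg = default_cfg.replace(base_event_rate=8e-3)
        trials = generate_study(cfg, 3, np.random.default_rng(9))
        types = np.concatenate([[e.bs_type for e in t.truth.events]
                                for t in trials])
        n = len(types)
        assert n >= 2000
        for k, p in enumerate(cfg.type_mixture, start=1):
            phat = np.mean(types == k)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) <= 3 * se + 1e-12
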