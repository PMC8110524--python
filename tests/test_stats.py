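"""Occurrence binning, count models, structure models and Tukey contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from termvib import (
    bin_counts,
    fit_occurrence_model,
    fit_structure_model,
    flashlight_bin_contrasts,
    occurrence_analysis,
    structure_table,
    study_grid,
    tukey_contrasts,
)


def _events(onsets, colony="c01", rep=False, flash=False):
    return pd.DataFrame({
        "colony_id": colony, "reproductives": rep, "flashlight": flash,
        "onset": list(onsets),
    })


class TestBinCounts:
    def test_full_grid_of_twenty_bins(self):
        table = bin_counts(_events([1.0]), bin_width=15.0,
                           trial_duration=300.0)
        assert len(table) == 20
        assert table["bin_index"].tolist() == list(range(1, 21))

    def test_half_open_bin_convention(self):
        table = bin_counts(_events([1.0, 14.9, 15.0]))
        counts = table.set_index("bin_index")["count"]
        assert counts[1] == 2 and counts[2] == 1

    def test_empty_log_keeps_grid(self):
        grid = pd.DataFrame({"colony_id": ["c01"], "reproductives": [False],
                             "flashlight": [False]})
        table = bin_counts(_events([]).iloc[:0], grid=grid)
        assert len(table) == 20
        assert (table["count"] == 0).all()

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            bin_counts(_events([1.0]), bin_width=0.0)

    @given(st.lists(st.floats(0.0, 299.99), max_size=40))
    def test_totals_conserved_and_order_invariant(self, onsets):
        a = bin_counts(_events(onsets))
        b = bin_counts(_events(sorted(onsets)))
        assert a["count"].sum() == len(onsets)
        pd.testing.assert_frame_equal(a, b)


class TestOccurrenceModel:
    def test_single_colony_rejected(self):
        table = bin_counts(_events([1.0, 2.0]))
        with pytest.raises(ValueError, match="colonies"):
            fit_occurrence_model(table)

    def test_reproductive_effect_recovered(self, truth_events, default_study):
        table = bin_counts(truth_events, grid=study_grid(default_study))
        report = fit_occurrence_model(table,
                                      ["C(bin_index)", "reproductives"])
        p = report.effects.set_index("effect").loc["reproductives", "p"]
        assert p < 0.05
        assert report.model_path == "poisson-glm-colony-fixed"

    def test_flash_contrast_only_first_bin(self, truth_events, default_study):
        """The generator confines the flashlight boost to the first 15-s
        bin of R+F+ trials; the per-bin contrasts find exactly that."""
        table = bin_counts(truth_events, grid=study_grid(default_study))
        con = flashlight_bin_contrasts(table[table["reproductives"]])
        sig = con[con["significant"]]["bin_index"].tolist()
        assert sig == [1]
        assert (con["p_adj"] >= con["p"] - 1e-12).all()

    def test_full_analysis_shapes(self, truth_events, default_study):
        table = bin_counts(truth_events, grid=study_grid(default_study))
        out = occurrence_analysis(table)
        assert set(out) == {"overall", "within_R+", "within_R-"}
        assert out["within_R+"].contrasts is not None
        assert len(out["within_R+"].contrasts) == 20


class TestStructureModel:
    def test_first_part_pulse_effect_recovered(self, truth_events):
        """The injected reproductive first-part pulse effect is detected
        on the first-part view of log pulse counts."""
        report = fit_structure_model(truth_events, "pulses", "first-part")
        eff = report.effects.set_index("effect")
        assert eff.loc["reproductives", "p"] < 0.05
        assert report.transform == "log"

    def test_type_effect_on_duration(self, truth_events):
        """Whole-event duration grows with the number of parts, so the
        type effect dominates the all-parts duration model."""
        report = fit_structure_model(truth_events, "duration", "all-parts")
        eff = report.effects.set_index("effect")
        assert eff.loc["C(bs_type)", "p"] < 1e-6
        assert report.contrasts is not None
        # duration orders BS1 < BS2 < BS3 < BS4 on the log scale
        c12 = report.contrasts.query("level_a == 1 and level_b == 4")
        assert float(c12["estimate"].iloc[0]) > 0

    def test_null_effects_not_invented(self, default_cfg):
        """With every context effect switched off, the reproductive term
        stays non-significant."""
        from termvib import events_frame_from_truth, generate_study
        cfg = default_cfg.replace(
            reproductive_firstpart_pulse_effect=1.0,
            reproductive_firstpart_duration_effect=1.0)
        trials = generate_study(cfg, 13, np.random.default_rng(21))
        ev = events_frame_from_truth(trials)
        report = fit_structure_model(ev, "pulses", "first-part")
        eff = report.effects.set_index("effect")
        if "reproductives" in eff.index and np.isfinite(
                eff.loc["reproductives", "p"]):
            assert eff.loc["reproductives", "p"] > 0.001

    def test_amplitude_untransformed(self, truth_events):
        report = fit_structure_model(truth_events, "amplitude", "all-parts")
        assert report.transform == "none"

    def test_empty_view_rejected(self, truth_events):
        only_bs1 = truth_events[truth_events["bs_type"] == 1]
        with pytest.raises(ValueError):
            fit_structure_model(only_bs1, "duration", "part3")

    def test_table_grid_covers_views(self, truth_events):
        grid = structure_table(truth_events, responses=("duration",),
                               views=("all-parts", "first-part", "part2"))
        assert set(grid) == {("duration", "all-parts"),
                             ("duration", "first-part"),
                             ("duration", "part2")}


class TestTukeyContrasts:
    @staticmethod
    def _fit(k, n=40, delta=0.0, seed=0):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(seed)
        g = np.repeat(np.arange(k), n)
        y = rng.normal(0, 1, k * n) + delta * g
        return smf.ols("y ~ C(g)", data=pd.DataFrame({"g": g, "y": y})).fit()

    def test_two_levels_adjusted_equals_raw(self):
        res = self._fit(2)
        con = tukey_contrasts(res, "g")
        assert len(con) == 1
        assert con["p_adj"].iloc[0] == pytest.approx(con["p"].iloc[0],
                                                     abs=1e-6)

    def test_four_levels_six_contrasts_adjusted_up(self):
        res = self._fit(4, delta=0.5)
        con = tukey_contrasts(res, "g")
        assert len(con) == 6
        assert (con["p_adj"] >= con["p"] - 1e-12).all()

    def test_null_rarely_significant(self):
        """Family-wise control: over null simulations the rate of any
        significant pair stays near alpha."""
        hits = sum(
            (tukey_contrasts(self._fit(4, seed=s), "g")["p_adj"] < 0.05).any()
            for s in range(60)
        )
        assert hits <= 9  # P(X > 9 | Binomial(60, 0.05)) < 0.002

    def test_absent_factor_rejected(self):
        res = self._fit(3)
        with pytest.raises(ValueError):
            tukey_contrasts(res, "nope")
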