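"""Occurrence and structure statistics for body-shaking events.

The statistical design mirrors the study: event counts are gridded per
colony x treatment x 15-s bin and modelled with Poisson count models;
structure responses (duration, number of pulses, amplitude) are modelled
per reporting view (all parts pooled, first part, individual parts, last
part) with the body-shaking type, reproductive presence, and flashlight as
fixed factors and colony as the grouping factor.  Durations and pulse
counts are log-transformed.  Models are simplified step-by-step by
removing non-significant interactions (highest order first), and each
retained effect is tested with a likelihood-ratio test on maximum-
likelihood fits.  Post hoc pairwise level contrasts carry studentized-
range (Tukey) family-wise adjustment.

Count models use a colony fixed-effect Poisson GLM: with a handful of
colony levels this conditions on colony exactly as a random intercept
would for the contrasts of interest, while staying numerically robust;
the report records which model path ran.  Structure models use a true
colony random intercept (linear mixed model, ML), falling back to a
colony fixed-effect OLS when the mixed fit does not converge.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .crosslink import match_events  # noqa: F401  (re-exported convenience)
from .types import Trial

STRUCTURE_RESPONSES = ("duration", "pulses", "amplitude")
STRUCTURE_VIEWS = ("all-parts", "first-part", "part2", "part3", "part4",
                   "last-part")


@dataclass
class ModelReport:
    """Likelihood-ratio effect table for one fitted model."""

    response: str
    transform: str                 # "log" | "none"
    model_path: str                # which estimation path actually ran
    effects: pd.DataFrame          # effect, lr_stat, df, p, retained
    contrasts: Optional[pd.DataFrame] = None
    notes: str = ""


# --------------------------------------------------------------------------
# occurrence table

def bin_counts(
    events: pd.DataFrame,
    bin_width: float = 15.0,
    trial_duration: float = 300.0,
    grid: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Count events per colony x treatment x time bin.

    Bins are half-open ``[(b-1)*w, b*w)`` with 1-based ``bin_index``; a
    300-s trial at the 15-s width gives bins 1..20.  Totals are conserved:
    the counts sum to the number of input events.

    Parameters
    ----------
    events
        One row per event with columns ``colony_id``, ``reproductives``,
        ``flashlight``, ``onset``.
    grid
        Optional frame of all colony x treatment combinations that were
        recorded; combinations with zero events then still contribute
        all-zero rows.  Defaults to the combinations present in ``events``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be strictly positive")
    n_bins = int(math.ceil(trial_duration / bin_width))
    keys = ["colony_id", "reproductives", "flashlight"]

    if grid is None:
        grid = events[keys].drop_duplicates()
    grid = grid[keys].drop_duplicates()
    full = grid.merge(pd.DataFrame({"bin_index": np.arange(1, n_bins + 1)}),
                      how="cross")

    if len(events):
        onset = events["onset"].to_numpy(dtype=float)
        if np.any((onset < 0) | (onset >= trial_duration)):
            raise ValueError("event onsets must lie within [0, trial_duration)")
        tagged = events.copy()
        tagged["bin_index"] = (onset // bin_width).astype(int) + 1
        counts = (tagged.groupby(keys + ["bin_index"], sort=False)
                  .size().rename("count").reset_index())
        out = full.merge(counts, how="left", on=keys + ["bin_index"])
        out["count"] = out["count"].fillna(0).astype(int)
    else:
        out = full.assign(count=0)
    return out.sort_values(keys + ["bin_index"]).reset_index(drop=True)


def events_frame_from_truth(
    trials: Sequence[Trial],
    tolerance: float = 0.2,
) -> pd.DataFrame:
    """Tabulate ground-truth events of simulated trials, event-table style.

    ``unique_flag`` marks events not concurrent (within ``tolerance``) with
    any other event of the same trial — the ground-truth analogue of the
    video cross-check.
    """
    rows = []
    for trial in trials:
        evs = trial.truth.events
        spans = [(e.onset, e.offset) for e in evs]
        for i, ev in enumerate(evs):
            lo, hi = ev.onset - tolerance, ev.offset + tolerance
            concurrent = any(
                j != i and lo < b + tolerance and a - tolerance < hi
                for j, (a, b) in enumerate(spans)
            )
            amps = [float(np.mean(p.amplitudes)) for p in ev.parts]
            npulses = [p.n_pulses for p in ev.parts]
            row = {
                "colony_id": trial.colony_id,
                "reproductives": trial.treatment.reproductives,
                "flashlight": trial.treatment.flashlight,
                "onset": ev.onset,
                "offset": ev.offset,
                "bs_type": ev.bs_type,
                "n_parts": len(ev.parts),
                "beyond_range": len(ev.parts) > 6,
                "total_duration": ev.duration,
                "total_pulses": int(sum(npulses)),
                "mean_amplitude": float(np.average(amps, weights=npulses)),
                "unique_flag": not concurrent,
            }
            for p in ev.parts[:6]:
                row[f"part{p.index}_duration"] = p.duration
                row[f"part{p.index}_pulses"] = p.n_pulses
                row[f"part{p.index}_frequency"] = p.frequency
                row[f"part{p.index}_amplitude"] = float(np.mean(p.amplitudes))
            rows.append(row)
    return pd.DataFrame(rows)


def study_grid(trials: Sequence[Trial]) -> pd.DataFrame:
    return pd.DataFrame([
        {"colony_id": t.colony_id,
         "reproductives": t.treatment.reproductives,
         "flashlight": t.treatment.flashlight}
        for t in trials
    ]).drop_duplicates().reset_index(drop=True)


# --------------------------------------------------------------------------
# model machinery

def _term_vars(term: str) -> set:
    return set(term.split(":"))


def _contains(term: str, other: str) -> bool:
    """True when ``other`` is a proper higher-order term containing ``term``."""
    return term != other and _term_vars(term) < _term_vars(other)


class _PoissonFitter:
    path = "poisson-glm-colony-fixed"

    def __init__(self, data: pd.DataFrame):
        self.data = data

    def fit(self, response: str, terms: Sequence[str]):
        rhs = " + ".join(["C(colony_id)"] + list(terms)) or "1"
        model = smf.glm(f"{response} ~ {rhs}", data=self.data,
                        family=sm.families.Poisson())
        return model.fit()


class _MixedFitter:
    """Colony random-intercept LMM (ML); OLS + colony fixed effect fallback."""

    def __init__(self, data: pd.DataFrame):
        self.data = data
        self.path = "lmm-colony-random"

    def _try_mixed(self, response: str, rhs: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(f"{response} ~ {rhs}", data=self.data,
                                groups=self.data["colony_id"])
            last = None
            for method in ("bfgs", "lbfgs", "powell"):
                try:
                    res = model.fit(reml=False, method=method, maxiter=500)
                except Exception as exc:  # noqa: BLE001 - try next optimizer
                    last = exc
                    continue
                if np.isfinite(res.llf):
                    return res
        raise last or ValueError("no optimizer reached a finite likelihood")

    def fit(self, response: str, terms: Sequence[str]):
        rhs = " + ".join(terms) or "1"
        if self.path == "lmm-colony-random":
            try:
                return self._try_mixed(response, rhs)
            except Exception:
                # one failure switches the whole analysis to the fallback so
                # every LR comparison uses a single consistent path
                self.path = "ols-colony-fixed"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return smf.ols(f"{response} ~ C(colony_id) + {rhs}",
                           data=self.data).fit()


def _n_params(res) -> int:
    params = getattr(res, "fe_params", None)
    if params is not None:
        return len(params)
    return len(res.params)


def _lr_test(full, reduced) -> Tuple[float, int, float]:
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    df = max(1, _n_params(full) - _n_params(reduced))
    return stat, df, float(sps.chi2.sf(stat, df))


def _drop_term(terms: Sequence[str], term: str) -> List[str]:
    return [t for t in terms if t != term]


def _stepwise(fitter, response: str, terms: List[str], alpha: float):
    """Remove non-significant interactions, highest order first.

    Returns the final term list, the final fit, and a per-effect LR table
    (tested by single-term deletion from the final model; main effects
    buried inside a retained interaction are reported untested).
    """
    terms = list(terms)
    full = fitter.fit(response, terms)
    while True:
        inter = [t for t in terms if ":" in t
                 and not any(_contains(t, o) for o in terms)]
        if not inter:
            break
        best = None
        for t in sorted(inter, key=lambda t: -t.count(":")):
            red = fitter.fit(response, _drop_term(terms, t))
            stat, df, p = _lr_test(full, red)
            if best is None or p > best[2]:
                best = (t, red, p)
        t, red, p = best
        if p > alpha:
            terms = _drop_term(terms, t)
            full = red
        else:
            break

    rows = []
    for t in terms:
        if any(_contains(t, o) for o in terms):
            rows.append({"effect": t, "lr_stat": np.nan, "df": np.nan,
                         "p": np.nan, "retained": True,
                         "note": "inside retained interaction"})
            continue
        red = fitter.fit(response, _drop_term(terms, t))
        stat, df, p = _lr_test(full, red)
        rows.append({"effect": t, "lr_stat": stat, "df": df, "p": p,
                     "retained": True, "note": ""})
    effects = pd.DataFrame(rows, columns=["effect", "lr_stat", "df", "p",
                                          "retained", "note"])
    return terms, full, effects


# --------------------------------------------------------------------------
# occurrence models

def fit_occurrence_model(
    table: pd.DataFrame,
    formula_terms: Sequence[str] = ("C(bin_index)", "reproductives"),
    alpha: float = 0.05,
) -> ModelReport:
    """Poisson count model on an occurrence table, colony conditioned out.

    Interactions in ``formula_terms`` are simplified step-by-step; every
    retained effect gets a likelihood-ratio test.  Requires at least two
    colonies (with one colony the colony term is vacuous and the model
    cannot separate colony activity from the tested effects).
    """
    if table["colony_id"].nunique() < 2:
        raise ValueError("occurrence model needs >= 2 colonies")
    for term in formula_terms:
        if ":" in term:
            continue
        col = term[2:-1] if term.startswith("C(") else term
        if col in table.columns and table[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs both levels present")
    fitter = _PoissonFitter(table)
    terms, fit, effects = _stepwise(fitter, "count", list(formula_terms), alpha)
    if not fit.converged:
        raise RuntimeError("Poisson occurrence model did not converge")
    return ModelReport(response="count", transform="none",
                       model_path=fitter.path, effects=effects)


def flashlight_bin_contrasts(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-bin flashlight contrasts within one reproductive context.

    Fits ``count ~ C(colony) + C(bin) * flashlight`` on a single-context
    occurrence table and reports the flashlight log-rate-ratio separately
    for every time bin, with single-step Sidak family-wise adjustment over
    the bins.  This is the "is the flash effect confined to the first
    bin?" question.
    """
    if table["reproductives"].nunique() != 1:
        raise ValueError("split the table by reproductive context first")
    if table["flashlight"].nunique() < 2:
        raise ValueError("both flashlight levels are required")
    fit = _PoissonFitter(table).fit(
        "count", ["C(bin_index)", "flashlight", "C(bin_index):flashlight"])
    params = fit.params
    cov = fit.cov_params()
    names = list(params.index)
    main = [n for n in names if n.startswith("flashlight[")]
    if len(main) != 1:
        raise RuntimeError(f"unexpected flashlight coding: {main}")
    main = main[0]
    bins = sorted(table["bin_index"].unique())
    ref = bins[0]
    rows = []
    k = len(bins)
    for b in bins:
        vec = pd.Series(0.0, index=names)
        vec[main] = 1.0
        if b != ref:
            inter = [n for n in names
                     if n.startswith(f"C(bin_index)[T.{b}]:flashlight[")]
            if len(inter) != 1:
                raise RuntimeError(f"missing interaction term for bin {b}")
            vec[inter[0]] = 1.0
        est = float(vec @ params)
        se = float(np.sqrt(vec @ cov @ vec))
        z = est / se if se > 0 else np.nan
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, 1.0 - (1.0 - p) ** k) if np.isfinite(p) else np.nan
        rows.append({"bin_index": b, "estimate": est, "se": se, "z": z,
                     "p": p, "p_adj": max(p_adj, p),
                     "significant": bool(p_adj < alpha)})
    return pd.DataFrame(rows)


def occurrence_analysis(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> Dict[str, object]:
    """The full occurrence procedure.

    Stage 1 models time (categorical) and reproductive presence together
    (interaction simplified away when non-significant).  Stage 2 splits
    the data by reproductive context and models time x flashlight within
    each half, with per-bin flashlight contrasts.
    """
    out: Dict[str, object] = {}
    out["overall"] = fit_occurrence_model(
        table,
        ["C(bin_index)", "reproductives", "C(bin_index):reproductives"],
        alpha=alpha,
    )
    for flag, key in ((True, "R+"), (False, "R-")):
        sub = table[table["reproductives"] == flag]
        report = fit_occurrence_model(
            sub, ["C(bin_index)", "flashlight", "C(bin_index):flashlight"],
            alpha=alpha,
        )
        report.contrasts = flashlight_bin_contrasts(sub, alpha=alpha)
        out[f"within_{key}"] = report
    return out


# --------------------------------------------------------------------------
# structure models

def _view_frame(events: pd.DataFrame, response: str, view: str) -> pd.Series:
    colmap = {"duration": "duration", "pulses": "pulses",
              "amplitude": "amplitude"}
    if response not in colmap:
        raise ValueError(f"unknown response {response!r}")
    if view == "all-parts":
        src = {"duration": "total_duration", "pulses": "total_pulses",
               "amplitude": "mean_amplitude"}[response]
        return events[src]
    if view == "first-part":
        part = np.ones(len(events), dtype=int)
    elif view == "last-part":
        part = events["n_parts"].to_numpy(dtype=int)
    elif view in ("part2", "part3", "part4"):
        part = np.full(len(events), int(view[-1]))
    else:
        raise ValueError(f"unknown view {view!r}")
    suffix = {"duration": "duration", "pulses": "pulses",
              "amplitude": "amplitude"}[response]
    vals = np.full(len(events), np.nan)
    for p in sorted(set(part)):
        col = f"part{p}_{suffix}"
        if col in events.columns:
            mask = part == p
            vals[mask] = events.loc[mask, col].to_numpy(dtype=float)
    return pd.Series(vals, index=events.index)


def fit_structure_model(
    events: pd.DataFrame,
    response: str = "duration",
    view: str = "all-parts",
    alpha: float = 0.05,
    max_bs_type: int = 4,
) -> ModelReport:
    """Mixed model of one structure response in one reporting view.

    Keeps unique events of types BS1..``max_bs_type`` (rarer types are too
    sparse to model), log-transforms durations and pulse counts, fits
    ``response ~ C(bs_type) * reproductives * flashlight`` with a colony
    random intercept (ML), simplifies the interactions stepwise and
    reports likelihood-ratio tests plus Tukey-adjusted pairwise type
    contrasts.
    """
    ev = events
    if "unique_flag" in ev.columns:
        ev = ev[ev["unique_flag"].fillna(False).astype(bool)]
    if "beyond_range" in ev.columns:
        ev = ev[~ev["beyond_range"].fillna(False).astype(bool)]
    ev = ev[ev["bs_type"] <= max_bs_type].copy()
    y = _view_frame(ev, response, view)
    ev = ev.assign(_y=y).dropna(subset=["_y"])
    if not len(ev):
        raise ValueError(f"no events provide view {view!r}")
    if ev["bs_type"].nunique() < 2:
        raise ValueError("structure model needs >= 2 body-shaking types")

    transform = "log" if response in ("duration", "pulses") else "none"
    if transform == "log":
        if (ev["_y"] <= 0).any():
            raise ValueError("log transform needs strictly positive values")
        ev["_y"] = np.log(ev["_y"])

    fitter = _MixedFitter(ev)
    terms = ["C(bs_type)", "reproductives", "flashlight",
             "C(bs_type):reproductives", "C(bs_type):flashlight",
             "reproductives:flashlight",
             "C(bs_type):reproductives:flashlight"]
    final_terms, fit, effects = _stepwise(fitter, "_y", terms, alpha)
    contrasts = None
    if not any(_contains("C(bs_type)", t) for t in final_terms):
        contrasts = tukey_contrasts(fit, "bs_type")
    return ModelReport(response=response, transform=transform,
                       model_path=fitter.path, effects=effects,
                       contrasts=contrasts,
                       notes=f"view={view}; n={len(ev)}")


def structure_table(
    events: pd.DataFrame,
    responses: Sequence[str] = STRUCTURE_RESPONSES,
    views: Sequence[str] = STRUCTURE_VIEWS,
    alpha: float = 0.05,
) -> Dict[Tuple[str, str], ModelReport]:
    """The responses x views grid of structure models.

    Views without data (e.g. fourth parts when no BS4 was kept) are
    skipped; the returned mapping holds a ModelReport per fitted cell.
    """
    out = {}
    for resp in responses:
        for view in views:
            try:
                out[(resp, view)] = fit_structure_model(
                    events, resp, view, alpha=alpha)
            except ValueError:
                continue
    return out


# --------------------------------------------------------------------------
# post hoc contrasts

def tukey_contrasts(fitres, factor: str, df_resid: Optional[float] = None
                    ) -> pd.DataFrame:
    """All pairwise level contrasts of a model factor, Tukey-adjusted.

    Works on any formula-fitted result whose parameters carry treatment-
    coded names (``C(factor)[T.level]``).  The family-wise adjustment uses
    the studentized range on ``sqrt(2)*|t|`` with the residual degrees of
    freedom (a large-sample value for z-based models); with two levels the
    adjusted p equals the raw p.
    """
    frame = fitres.model.data.frame
    if factor not in frame.columns:
        raise ValueError(f"factor {factor!r} not in the model frame")
    levels = sorted(pd.unique(frame[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")

    params = getattr(fitres, "fe_params", fitres.params)
    cov = fitres.cov_params()
    if isinstance(cov, pd.DataFrame):
        cov = cov.loc[params.index, params.index]
    cov = pd.DataFrame(np.asarray(cov), index=params.index,
                       columns=params.index)

    def pname(level):
        for cand in (f"C({factor})[T.{level}]", f"{factor}[T.{level}]"):
            if cand in params.index:
                return cand
        return None  # reference level

    if df_resid is None:
        df_resid = getattr(fitres, "df_resid", None)
    if df_resid is None or not np.isfinite(df_resid):
        df_resid = 1e7
    df_resid = max(float(df_resid), 2.0)

    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            na, nb = pname(levels[i]), pname(levels[j])
            est = ((params[nb] if nb else 0.0)
                   - (params[na] if na else 0.0))
            var = 0.0
            if na:
                var += cov.loc[na, na]
            if nb:
                var += cov.loc[nb, nb]
            if na and nb:
                var -= 2.0 * cov.loc[na, nb]
            se = float(np.sqrt(max(var, 0.0)))
            t = est / se if se > 0 else np.nan
            p_raw = 2.0 * sps.t.sf(abs(t), df_resid)
            p_adj = float(sps.studentized_range.sf(
                np.sqrt(2.0) * abs(t), k, df_resid))
            rows.append({
                "level_a": levels[i], "level_b": levels[j],
                "estimate": float(est), "se": se, "stat": float(t),
                "p": float(p_raw),
                "p_adj": float(min(1.0, max(p_adj, p_raw))),
            })
    return pd.DataFrame(rows)
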