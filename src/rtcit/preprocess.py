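"""Preregistered exclusion rules and per-participant summaries.

Trial-level filters (go trials only): any press under 150 ms, any press
above 800 ms, and any wrong-button press are dropped from RT summaries.
Omissions carry no RT and never enter an RT summary.  No-go trials pass
through untouched; they are scored separately as commission errors.

Participant-level filters: a participant is excluded when the go-trial
error rate reaches 50% for any of the probe, irrelevant or target
stimulus types, or when fewer than the full session's trials are
present.  "Error" counts both wrong-button presses and omissions (an
omission equally invalidates a go trial); this is configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignSpec

__all__ = ["filter_trials", "participant_qc", "summarize_participants"]

_GO_TYPES = ("probe", "irrelevant", "target")


def _annotate(trials: pd.DataFrame) -> pd.DataFrame:
    """Add is_go / pressed / wrong helper columns (copy)."""
    t = trials.copy()
    t["is_go"] = t["stim_type"].isin(_GO_TYPES)
    t["pressed"] = t["rt_ms"].notna()
    expected = np.where(t["stim_type"] == "target", "familiar", "unfamiliar")
    t["wrong"] = t["is_go"] & t["pressed"] & (t["response"] != expected)
    return t


def _trial_exclusion_reason(trials: pd.DataFrame,
                            design: DesignSpec) -> pd.Series:
    """Per-trial reason label, NaN for retained trials.

    Rules apply to go trials with a press; reasons are evaluated in a
    fixed order (rt_below_min, rt_above_max, wrong_button) so a trial
    violating several rules carries a deterministic single label.
    """
    t = _annotate(trials)
    reason = pd.Series(pd.NA, index=trials.index, dtype="object")
    reason[t["wrong"]] = "wrong_button"
    go_press = t["is_go"] & t["pressed"]
    reason[go_press & (t["rt_ms"] > design.deadline_ms)] = "rt_above_max"
    reason[go_press & (t["rt_ms"] < design.min_valid_rt_ms)] = "rt_below_min"
    return reason


def filter_trials(trials: pd.DataFrame, design: DesignSpec | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the trial-level filters.

    Returns ``(retained, exclusion_log)``: retained trials (go trials
    surviving all three rules, go omissions, and all no-go trials) and a
    log with one row and one reason per excluded trial
    (participant_id, trial_index, reason).
    """
    design = design or DesignSpec()
    reason = _trial_exclusion_reason(trials, design)
    excluded = reason.notna()
    log = trials.loc[excluded, ["participant_id", "trial_index"]].copy()
    log["reason"] = reason[excluded].values
    return trials.loc[~excluded].copy(), log.reset_index(drop=True)


def _error_table(trials: pd.DataFrame,
                 count_omissions_as_errors: bool) -> pd.DataFrame:
    """Per participant x go stimulus type: n trials and error count."""
    t = _annotate(trials)
    go = t[t["is_go"]].copy()
    go["omitted"] = ~go["pressed"]
    go["is_error"] = go["wrong"] | (go["omitted"] if count_omissions_as_errors
                                    else False)
    agg = (go.groupby(["participant_id", "stim_type"], sort=True)
           .agg(n=("is_error", "size"), errors=("is_error", "sum")))
    return agg.reset_index()


def participant_qc(trials: pd.DataFrame, design: DesignSpec | None = None,
                   count_omissions_as_errors: bool = True) -> pd.DataFrame:
    """Inclusion decision per participant, on the UNfiltered trials.

    Exclusion reasons are evaluated in fixed order: an incomplete
    session first, then a >= 50% error rate on any go stimulus type
    (probe before irrelevant before target), so each excluded
    participant carries exactly one primary reason.
    """
    design = design or DesignSpec()
    counts = trials.groupby("participant_id", sort=True).size()
    err = _error_table(trials, count_omissions_as_errors)
    rate = (err.assign(rate=err["errors"] / err["n"])
            .pivot(index="participant_id", columns="stim_type", values="rate")
            .reindex(counts.index))

    reason = pd.Series(None, index=counts.index, dtype="object")
    for stim in reversed(_GO_TYPES):  # probe ends up highest priority
        if stim in rate:
            reason[rate[stim] >= 0.5] = f"error_rate_{stim}"
    reason[counts < design.total_trials] = "incomplete_session"
    return pd.DataFrame({
        "participant_id": counts.index,
        "included": reason.isna().values,
        "exclusion_reason": reason.values,
    })


def summarize_participants(trials: pd.DataFrame,
                           design: DesignSpec | None = None,
                           count_omissions_as_errors: bool = True,
                           ) -> pd.DataFrame:
    """Full per-participant summary table.

    Probe/irrelevant RT means and the irrelevant-RT SD (sample, n-1) are
    computed over RETAINED go trials only; error rates and the no-go
    commission count over ALL trials.  ``cit_effect_ms`` is mean probe
    minus mean irrelevant RT; ``d_cit`` standardizes it by the
    within-participant irrelevant-RT SD.  Excluded participants keep
    their row with NaN RT summaries.
    """
    design = design or DesignSpec()
    retained, _ = filter_trials(trials, design)
    qc = participant_qc(trials, design, count_omissions_as_errors)
    out = qc.copy()

    out = out.merge(
        trials.groupby("participant_id", sort=True).size()
        .rename("n_trials_total").reset_index(), on="participant_id")

    err = _error_table(trials, count_omissions_as_errors)
    rates = (err.assign(rate=err["errors"] / err["n"])
             .pivot(index="participant_id", columns="stim_type", values="rate"))
    rates.columns = [f"error_rate_{c}" for c in rates.columns]
    out = out.merge(rates.reset_index(), on="participant_id", how="left")

    nogo = trials[trials["stim_type"] == "nogo"]
    commissions = (nogo.groupby("participant_id")["rt_ms"]
                   .apply(lambda s: int(s.notna().sum()))
                   .rename("nogo_error_count"))
    out = out.merge(commissions.reset_index(), on="participant_id", how="left")
    out["nogo_error_count"] = out["nogo_error_count"].fillna(0).astype(int)
    out["nogo_error_rate"] = out["nogo_error_count"] / design.n_nogo_trials

    ret = retained[retained["rt_ms"].notna()]
    stats = (ret[ret["stim_type"].isin(("probe", "irrelevant"))]
             .groupby(["participant_id", "stim_type"])["rt_ms"]
             .agg(["mean", "std", "count"]).unstack("stim_type"))
    for stim, col in (("probe", "mean_probe_rt_ms"),
                      ("irrelevant", "mean_irrelevant_rt_ms")):
        out[col] = out["participant_id"].map(
            stats[("mean", stim)] if ("mean", stim) in stats else pd.Series(dtype=float))
    out["sd_irrelevant_rt_ms"] = out["participant_id"].map(
        stats[("std", "irrelevant")] if ("std", "irrelevant") in stats
        else pd.Series(dtype=float))

    bad = out["included"] & (out["mean_probe_rt_ms"].isna()
                             | out["sd_irrelevant_rt_ms"].isna())
    if bad.any():
        raise ValueError(
            "no retained probe or irrelevant trials for included "
            f"participant(s) {out.loc[bad, 'participant_id'].tolist()[:5]}; "
            "summary undefined")

    out.loc[~out["included"], ["mean_probe_rt_ms", "mean_irrelevant_rt_ms",
                               "sd_irrelevant_rt_ms"]] = np.nan
    out["cit_effect_ms"] = out["mean_probe_rt_ms"] - out["mean_irrelevant_rt_ms"]
    out["d_cit"] = out["cit_effect_ms"] / out["sd_irrelevant_rt_ms"]

    cols = ["participant_id", "n_trials_total", "mean_probe_rt_ms",
            "mean_irrelevant_rt_ms", "sd_irrelevant_rt_ms", "cit_effect_ms",
            "d_cit", "error_rate_probe", "error_rate_irrelevant",
            "error_rate_target", "nogo_error_count", "nogo_error_rate",
            "included", "exclusion_reason"]
    return out[cols]
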