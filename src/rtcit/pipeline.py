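"""End-to-end orchestration: simulate -> preprocess -> score -> detect -> report.

Every stage is a pure function of its inputs and a seed; one master
seed spawns independent per-stage substreams, so toggling one stage
does not perturb another's draws.  All artifacts are plain CSV/JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (bf_correlation, bf_ttest, bonferroni_alpha,
                    cohen_d_one_sample, correlation_matrix, one_sample_t,
                    paired_t, pearson_r, sequential_bf)
from .design import STIM_TYPES, DesignSpec
from .detection import bootstrap_auc
from .preprocess import filter_trials, summarize_participants
from .scales import score_questionnaire
from .simulate import TraitModelConfig, simulate_cohort

__all__ = ["RunConfig", "load_config", "run_pipeline", "validate_inputs",
           "analyze_summaries"]

_DESIGN_KEYS = {f.name for f in fields(DesignSpec)}
_TRAIT_KEYS = {f.name for f in fields(TraitModelConfig)} - {
    "latent_correlation", "scales"}


@dataclass
class RunConfig:
    """Options of a full pipeline run (flat config-file keys)."""

    n_participants: int = 86
    seed: int = 0
    n_boot: int = 1000
    output_dir: str = "rtcit_run"
    sequential: bool = True
    resample_knowledgeable: bool = False
    count_omissions_as_errors: bool = True
    naive_n_formula: int | None = None  # default: knowledgeable count
    design: DesignSpec = field(default_factory=DesignSpec)
    traits: TraitModelConfig = field(default_factory=TraitModelConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError(
                "n_participants must be >= 4: the naive-SD formula (and the "
                "detection stage) is undefined below that")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")


def load_config(path: str | Path) -> RunConfig:
    """Read a flat key-value YAML config; unknown keys are rejected.

    Keys are either run options (``n_participants``, ``seed``, ...),
    design constants (``n_blocks``, ``deadline_ms``, ...) or trait-model
    parameters (``probe_shift_mean_ms``, ...).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    run_keys = {f.name for f in fields(RunConfig)} - {"design", "traits"}
    run, design, traits = {}, {}, {}
    for key, val in raw.items():
        if key in run_keys:
            run[key] = val
        elif key in _DESIGN_KEYS:
            design[key] = tuple(val) if key == "isi_options_ms" else val
        elif key in _TRAIT_KEYS:
            traits[key] = tuple(val) if isinstance(val, list) else val
        else:
            raise ValueError(f"unknown config key: {key!r}")
    return RunConfig(design=DesignSpec(**design),
                     traits=TraitModelConfig(**traits), **run)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)
    fields_ = dataclasses.asdict(config)
    fields_.pop("output_dir", None)  # hash identifies the run, not its path
    payload = json.dumps(fields_, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyze_summaries(summaries: pd.DataFrame, scores: pd.DataFrame,
                      min_n_sequential: int = 5,
                      sequential: bool = True) -> dict:
    """Group-level statistics on included participants.

    Returns the one-sample CIT-effect test (t, Cohen's d with CI, JZS
    BF10 both two-sided and directional), the correlation/BF matrix
    over the six preregistered measures, the headline correlation of
    the CIT effect with secondary psychopathy, and (optionally) its
    sequential BF trajectory.
    """
    inc = summaries[summaries["included"]].merge(scores, on="participant_id")
    n = len(inc)
    effect = inc["cit_effect_ms"].to_numpy()

    t, df = one_sample_t(effect)
    es = cohen_d_one_sample(effect)
    out: dict = {
        "n_included": n,
        "cit_effect": {
            "mean_ms": float(effect.mean()),
            "sd_ms": float(effect.std(ddof=1)),
            "t": t, "df": df,
            "d": es.d, "d_ci": [es.ci_low, es.ci_high],
            "bf10_directional": bf_ttest(t, n, alternative="greater").bf10,
            "bf10_two_sided": bf_ttest(t, n).bf10,
        },
    }

    measures = inc[["cit_effect_ms", "lsrp_total", "lsrp_primary",
                    "lsrp_secondary", "bis_total", "nogo_error_rate"]]
    mat, tidy = correlation_matrix(measures)
    out["correlations"] = {"matrix": mat, "tidy": tidy,
                           "bonferroni_alpha": bonferroni_alpha(
                               len(tidy))}

    r_main = pearson_r(inc["cit_effect_ms"], inc["lsrp_secondary"])
    main_bf = bf_correlation(r_main, n)
    out["main_hypothesis"] = {"r": r_main, "n": n, "bf01": main_bf.bf01,
                              "bf10": main_bf.bf10}
    if sequential and n >= min_n_sequential:
        traj = sequential_bf(inc["cit_effect_ms"].to_numpy(),
                             inc["lsrp_secondary"].to_numpy(),
                             min_n=min_n_sequential)
        out["sequential_bf01"] = traj

    if {"rating_probe_significance",
        "rating_irrelevant_significance"} <= set(inc.columns):
        a = inc["rating_probe_significance"].to_numpy(float)
        b = inc["rating_irrelevant_significance"].to_numpy(float)
        t_r, df_r = paired_t(a, b)
        es_r = cohen_d_one_sample(a - b)
        out["ratings"] = {
            "probe_mean": float(a.mean()), "probe_sd": float(a.std(ddof=1)),
            "irrelevant_mean": float(b.mean()),
            "irrelevant_sd": float(b.std(ddof=1)),
            "t": t_r, "df": df_r, "d": es_r.d,
            "bf10_directional": bf_ttest(t_r, n, alternative="greater").bf10,
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle.

    Writes trials.csv, questionnaire.csv, participant_summaries.csv,
    trial_exclusions.csv, scores.csv, correlation_matrix.csv,
    bootstrap_aucs.csv, sequential_bf.csv, run_summary.json and
    run_log.txt into ``config.output_dir``; returns the summary dict.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(config.seed)
    s_sim, s_detect = master.spawn(2)
    log: list[str] = [f"rtcit {__version__}",
                      f"master seed: {config.seed}",
                      f"config hash: {_config_hash(config)}"]

    cohort = simulate_cohort(config.n_participants, config.design,
                             config.traits, seed=s_sim)
    trials, questionnaire = cohort["trials"], cohort["questionnaire"]
    trials.to_csv(out_dir / "trials.csv", index=False, float_format="%.1f")
    questionnaire.to_csv(out_dir / "questionnaire.csv", index=False)
    log.append(f"simulate: {config.n_participants} participants, "
               f"{len(trials)} trials")

    retained, excl_log = filter_trials(trials, config.design)
    excl_log.to_csv(out_dir / "trial_exclusions.csv", index=False)
    summaries = summarize_participants(
        trials, config.design, config.count_omissions_as_errors)
    summaries.to_csv(out_dir / "participant_summaries.csv", index=False,
                     float_format="%.4f")
    n_inc = int(summaries["included"].sum())
    log.append(f"preprocess: {len(excl_log)} trials excluded, "
               f"{n_inc}/{len(summaries)} participants included")

    scores = score_questionnaire(questionnaire)
    scores.to_csv(out_dir / "scores.csv", index=False)
    log.append(f"score: {len(scores)} participants scored")

    analysis = analyze_summaries(summaries, scores,
                                 sequential=config.sequential)
    analysis["correlations"]["matrix"].to_csv(out_dir / "correlation_matrix.csv")
    if "sequential_bf01" in analysis:
        pd.DataFrame(analysis["sequential_bf01"],
                     columns=["n", "bf01"]).to_csv(
            out_dir / "sequential_bf.csv", index=False)

    dcits = summaries.loc[summaries["included"], "d_cit"].to_numpy()
    det, aucs = bootstrap_auc(
        dcits, n_formula=config.naive_n_formula, n_boot=config.n_boot,
        rng=np.random.default_rng(s_detect),
        resample_knowledgeable=config.resample_knowledgeable,
        return_samples=True)
    pd.DataFrame({"auc": aucs}).to_csv(out_dir / "bootstrap_aucs.csv",
                                       index=False)
    log.append(f"detect: mean AUC {det.auc_mean:.3f} "
               f"[{det.ci_low:.3f}, {det.ci_high:.3f}]")

    descr = summaries.loc[summaries["included"],
                          ["cit_effect_ms", "mean_probe_rt_ms",
                           "mean_irrelevant_rt_ms", "nogo_error_count"]]
    descr = pd.concat([descr.reset_index(drop=True),
                       scores[scores["participant_id"].isin(
                           summaries.loc[summaries["included"],
                                         "participant_id"])]
                       [["lsrp_total", "lsrp_primary", "lsrp_secondary",
                         "bis_total"]].reset_index(drop=True)], axis=1)
    descriptives = descr.agg(["mean", "std", "min", "max"]).T

    summary = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "n_participants": config.n_participants,
        "n_included": n_inc,
        "trials_per_participant": config.design.total_trials,
        "n_trials_excluded": len(excl_log),
        "descriptives": descriptives.round(4).to_dict(orient="index"),
        "cit_effect": analysis["cit_effect"],
        "main_hypothesis": analysis["main_hypothesis"],
        "bonferroni_alpha": analysis["correlations"]["bonferroni_alpha"],
        "detection": dataclasses.asdict(det) | {"seed": str(config.seed)},
    }
    if "ratings" in analysis:
        summary["ratings"] = analysis["ratings"]
    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return summary


# ---------------------------------------------------------------------------
# input validation

_TRIAL_COLUMNS = ["participant_id", "block", "trial_index", "item_id",
                  "stim_type", "isi_ms", "rt_ms", "response", "correct"]


def validate_inputs(trial_csv: str | Path | None = None,
                    questionnaire_csv: str | Path | None = None,
                    design: DesignSpec | None = None) -> dict:
    """Schema check of input tables; returns a violation report.

    Checks column presence, the stimulus-type and response vocabularies,
    RT ranges, and the 1-4 Likert range of questionnaire items.  The
    report maps each file to a list of human-readable violations
    (empty = valid).
    """
    design = design or DesignSpec()
    report: dict[str, list[str]] = {}

    if trial_csv is not None:
        issues: list[str] = []
        t = pd.read_csv(trial_csv)
        missing = [c for c in _TRIAL_COLUMNS if c not in t.columns]
        if missing:
            issues.append(f"missing columns: {missing}")
        else:
            bad = ~t["stim_type"].isin(STIM_TYPES)
            if bad.any():
                issues.append(f"{bad.sum()} rows with unknown stim_type "
                              f"(e.g. row {bad.idxmax()})")
            bad = ~t["response"].isin(("familiar", "unfamiliar", "none"))
            if bad.any():
                issues.append(f"{bad.sum()} rows with unknown response")
            rt = t["rt_ms"]
            bad = rt.notna() & ((rt <= 0) | (rt > design.stim_duration_ms))
            if bad.any():
                issues.append(
                    f"{bad.sum()} rows with rt_ms outside "
                    f"(0, {design.stim_duration_ms}] (e.g. row {bad.idxmax()})")
            bad = rt.isna() != (t["response"] == "none")
            if bad.any():
                issues.append(f"{bad.sum()} rows where rt_ms presence "
                              "disagrees with response")
        report[str(trial_csv)] = issues

    if questionnaire_csv is not None:
        issues = []
        q = pd.read_csv(questionnaire_csv)
        item_cols = ([f"lsrp_item_{i:02d}" for i in range(1, 27)]
                     + [f"bis_item_{i:02d}" for i in range(1, 31)])
        missing = [c for c in item_cols if c not in q.columns]
        if missing:
            issues.append(f"missing columns: {missing[:5]} ...")
        for col in item_cols:
            if col in q.columns:
                bad = ~q[col].isin((1, 2, 3, 4))
                if bad.any():
                    issues.append(f"{col}: {bad.sum()} values outside the "
                                  "1-4 Likert range")
        report[str(questionnaire_csv)] = issues

    report["valid"] = all(not v for v in report.values())
    return report
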