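"""End-to-end pipeline: simulate → preprocess → score → cohort statistics.

``run_pipeline`` renders (or loads) a cohort of EMG sessions, runs every
recording through the processing and scoring chain, assembles the cohort
table, and computes the group-level statistics: the two mixed ANOVAs
(acquisition and extinction), within-group paired t-tests (CS+ vs CS−),
the between-group test on conditioning strength, and the clinical
correlations within the patient group.  Outputs are plain TSV tables plus
a JSON run manifest (config hash, seed, package versions) so any result
can be regenerated from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .paradigm import ACQUISITION, CS_MINUS, CS_PLUS, EXTINCTION
from .preprocess import (ArtifactRule, PreprocessConfig, mark_artifacts,
                         preprocess_emg)
from .scoring import (ITI, ParticipantScores, ResponseWindowConfig,
                      detect_session_responses, filter_successful_acquisition,
                      score_participant)
from .stats import (FULLY_AWARE, anova_by_effect, classify_awareness,
                    independent_t, mixed_anova_2x2, paired_t, pearson_r)
from .synth import CohortDesign, CohortRecord, simulate_cohort

log = logging.getLogger("startlekit")


@dataclass
class PipelineConfig:
    design: CohortDesign = field(default_factory=CohortDesign)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    response: ResponseWindowConfig = field(default_factory=ResponseWindowConfig)
    artifact_rule: ArtifactRule = field(default_factory=ArtifactRule)
    welch: bool = False
    subset: str | None = None  # None | "successful" | "aware"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset not in (None, "successful", "aware"):
            raise ValueError(f"unknown subset {self.subset!r}")
        self.design = dataclasses.replace(self.design, seed=self.seed)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-participant processing

def process_recording(record: CohortRecord, pre_cfg: PreprocessConfig,
                      resp_cfg: ResponseWindowConfig,
                      rule: ArtifactRule) -> tuple[pd.DataFrame,
                                                   ParticipantScores]:
    """Process one participant: filter chain, artifact mask, detection,
    scoring.  Returns the per-trial response table and the scores."""
    processed = preprocess_emg(record.recording, pre_cfg)
    processed = mark_artifacts(processed, rule)
    responses = detect_session_responses(processed, record.schedule, resp_cfg)
    scores = score_participant(responses, record.schedule)
    rows = [{
        "participant_id": record.participant_id,
        "phase": r.trial_ref.phase,
        "trial_type": r.trial_ref.trial_type,
        "probe_onset_s": r.probe_time_s,
        "valid": int(r.valid),
        "reason": r.invalid_reason,
        "latency_ms": r.onset_latency_ms,
        "amplitude_uv": r.amplitude,
    } for r in responses]
    return pd.DataFrame(rows), scores


def scores_to_row(pid: str, group: str, scores: ParticipantScores,
                  covariates: dict) -> dict:
    row = {"participant_id": pid, "group": group,
           "scoreable": int(scores.scoreable),
           "iti_reference_uv": scores.iti_reference}
    for phase, prefix in ((ACQUISITION, "acq"), (EXTINCTION, "ext")):
        row[f"{prefix}_cs_plus"] = scores.proportional.get((phase, CS_PLUS))
        row[f"{prefix}_cs_minus"] = scores.proportional.get((phase, CS_MINUS))
        row[f"{prefix}_differential"] = scores.differential.get(phase)
        row[f"{prefix}_n_valid_iti"] = scores.n_valid.get((phase, ITI), 0)
    row.update(covariates)
    if {"cs_plus_correct", "cs_minus_correct"} <= covariates.keys():
        row["awareness"] = classify_awareness(
            bool(covariates["cs_plus_correct"]),
            bool(covariates["cs_minus_correct"]))
    return row


# ---------------------------------------------------------------------------
# cohort statistics

def cohort_statistics(cohort: pd.DataFrame, welch: bool = False
                      ) -> pd.DataFrame:
    """All group-level tests on a cohort scores table (one row each)."""
    rows: list[dict] = []

    def add(name: str, **kw) -> None:
        rows.append({"test": name, **kw})

    scored = cohort[cohort["scoreable"] == 1]
    for phase, prefix in ((ACQUISITION, "acq"), (EXTINCTION, "ext")):
        sub = scored.dropna(subset=[f"{prefix}_cs_plus",
                                    f"{prefix}_cs_minus"])
        try:
            res = anova_by_effect(mixed_anova_2x2(sub, phase=phase))
        except Exception as exc:
            log.warning("ANOVA (%s) failed: %s", phase, exc)
            continue
        for eff, r in res.items():
            add(f"anova_{prefix}_{eff}", statistic=r.F, df1=r.df_num,
                df2=r.df_den, p=r.p, effect_size=r.eta_p_sq, n=r.n)
        for grp, gsub in sub.groupby("group"):
            try:
                t = paired_t(gsub[f"{prefix}_cs_plus"],
                             gsub[f"{prefix}_cs_minus"])
                add(f"paired_t_{prefix}_{grp}", statistic=t.t, df1=t.df,
                    p=t.p, n=len(gsub))
            except ValueError as exc:
                log.warning("paired t (%s, %s) failed: %s", phase, grp, exc)

    # strength of conditioning (CS+ − CS− differential) between groups
    for prefix in ("acq", "ext"):
        col = f"{prefix}_differential"
        sub = scored.dropna(subset=[col])
        groups = sorted(sub["group"].unique())
        if len(groups) == 2:
            a = sub.loc[sub["group"] == groups[0], col]
            b = sub.loc[sub["group"] == groups[1], col]
            t = independent_t(a, b, welch=welch)
            add(f"independent_t_{col}", statistic=t.t, df1=t.df, p=t.p,
                n=len(sub))

    # clinical correlations within the patient group
    mdd = scored[scored["group"] == "MDD"]
    if "illness_duration_years" in mdd.columns:
        for prefix in ("acq", "ext"):
            sub = mdd.dropna(subset=["illness_duration_years",
                                     f"{prefix}_differential"])
            if len(sub) >= 3 and sub["illness_duration_years"].std() > 0:
                r = pearson_r(sub["illness_duration_years"],
                              sub[f"{prefix}_differential"])
                add(f"pearson_illness_{prefix}_differential", statistic=r.r,
                    df1=r.df, p=r.p, n=r.n)
    if "age" in mdd.columns:
        sub = mdd.dropna(subset=["age", "ext_differential"])
        if len(sub) >= 3 and sub["age"].std() > 0:
            r = pearson_r(sub["age"], sub["ext_differential"])
            add("pearson_age_ext_differential", statistic=r.r, df1=r.df,
                p=r.p, n=r.n)
    return pd.DataFrame(rows)


def apply_subset(cohort: pd.DataFrame, subset: str | None) -> pd.DataFrame:
    if subset is None:
        return cohort
    if subset == "successful":
        return cohort[cohort["acq_differential"] > 0]
    if subset == "aware":
        return cohort[cohort.get("awareness") == FULLY_AWARE]
    raise ValueError(f"unknown subset {subset!r}")


# ---------------------------------------------------------------------------
# entry point

@dataclass
class PipelineResult:
    trials: pd.DataFrame
    scores: pd.DataFrame
    stats: pd.DataFrame
    manifest: dict


def run_pipeline(config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Simulate a cohort and run the full analysis chain over it."""
    records = simulate_cohort(config.design)
    trial_frames: list[pd.DataFrame] = []
    score_rows: list[dict] = []
    for rec in records:
        try:
            trials, scores = process_recording(
                rec, config.preprocess, config.response, config.artifact_rule)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'score' failed for {rec.participant_id}") from exc
        trial_frames.append(trials)
        score_rows.append(scores_to_row(rec.participant_id, rec.params.group,
                                        scores, rec.params.covariates))
        log.info("processed %s (%s): %d valid trials", rec.participant_id,
                 rec.params.group, int(trials["valid"].sum()))

    trials = pd.concat(trial_frames, ignore_index=True)
    cohort = pd.DataFrame(score_rows)
    analysed = apply_subset(cohort, config.subset)
    stats = cohort_statistics(analysed, welch=config.welch)

    manifest = {
        "package": "startlekit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_participants": len(cohort),
        "n_analysed": len(analysed),
        "subset": config.subset,
        "versions": _versions(),
    }
    result = PipelineResult(trials, cohort, stats, manifest)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        trials.to_csv(out / "trials.tsv", sep="\t", index=False,
                      na_rep="n/a", float_format="%.6f")
        cohort.to_csv(out / "scores.tsv", sep="\t", index=False,
                      na_rep="n/a", float_format="%.6f")
        stats.to_csv(out / "stats.tsv", sep="\t", index=False,
                     na_rep="n/a", float_format="%.6f")
        from .io import write_manifest
        write_manifest(out / "manifest.json", manifest)
    return result


def _versions() -> dict[str, str]:
    import scipy
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}
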