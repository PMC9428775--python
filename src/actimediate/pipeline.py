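"""End-to-end orchestration: simulate (or load) → accelerometry → scale
scoring → complete-case filter → mediation → report tables.

Every stage consumes and produces plain data frames / CSVs with documented
schemas, so each is independently inspectable and re-runnable.  The whole
pipeline is deterministic under a fixed seed.

The complete-case filter retains participants with (1) complete covariates
(sex, SES decile), (2) complete mediator scores at both T0 and T1,
(3) included accelerometry (>=3 valid days) at baseline and (4) at final
follow-up; post-intervention (T1) accelerometry is deliberately not
required.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import accelerometry as acc
from . import mediation as med
from . import scales as sc
from . import synthetic as syn

__all__ = [
    "PipelineConfig",
    "CohortFlow",
    "filter_complete_cases",
    "describe_cohort",
    "pooled_wear_composition",
    "run_pipeline",
]

logger = logging.getLogger("actimediate.pipeline")

MEDIATORS = tuple(sc.DEFAULT_SCALES)


@dataclass(frozen=True)
class CohortFlow:
    """Counts along the complete-case filter chain."""

    considered: int
    complete_covariates: int
    complete_mediators: int
    valid_accel_t0: int
    valid_accel_t2: int

    @property
    def final_n(self) -> int:
        return self.valid_accel_t2

    @property
    def percentage(self) -> float:
        """Complete cases as a percentage of participants considered."""
        return 100.0 * self.final_n / self.considered

    def __post_init__(self) -> None:
        counts = [
            self.considered,
            self.complete_covariates,
            self.complete_mediators,
            self.valid_accel_t0,
            self.valid_accel_t2,
        ]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"filter counts must be nonincreasing: {counts}")

    def to_text(self) -> str:
        return (
            f"participants considered        {self.considered}\n"
            f"complete covariates            {self.complete_covariates}\n"
            f"complete mediators (T0 & T1)   {self.complete_mediators}\n"
            f"valid accelerometry at T0      {self.valid_accel_t0}\n"
            f"valid accelerometry at T2      {self.valid_accel_t2}\n"
            f"complete-case sample           {self.final_n} ({self.percentage:.1f}%)\n"
        )


@dataclass
class PipelineConfig:
    """One config object covering every stage.

    Exactly one input mode: set ``trial`` to simulate, or point
    ``participants_csv``/``epochs_csv`` at existing data.
    """

    out_dir: Path = Path("pipeline_out")
    seed: int = 0
    trial: syn.TrialConfig | None = None
    participants_csv: Path | None = None
    epochs_csv: Path | None = None
    epoch_len: int = 15
    t2_start_date: dt.date = dt.date(2024, 9, 2)
    cutpoints: acc.CutPoints = field(default_factory=acc.CutPoints)
    scales: Mapping[str, sc.ScaleDefinition] = field(
        default_factory=lambda: dict(sc.DEFAULT_SCALES)
    )
    analysis: med.AnalysisSpec = field(default_factory=med.AnalysisSpec)
    write_epochs: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("seed", "epoch_len", "write_epochs", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        for key in ("out_dir", "participants_csv", "epochs_csv"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        if raw.get("t2_start_date"):
            kwargs["t2_start_date"] = _as_date(raw["t2_start_date"])
        if raw.get("cutpoints"):
            kwargs["cutpoints"] = acc.CutPoints(**raw["cutpoints"])
        if raw.get("trial") is not None:
            kwargs["trial"] = _trial_config_from_dict(
                raw["trial"], kwargs.get("cutpoints"), raw.get("seed")
            )
        if raw.get("scales"):
            registry = dict(sc.DEFAULT_SCALES)
            for name, spec in raw["scales"].items():
                spec = dict(spec)
                spec["reverse_items"] = frozenset(spec.get("reverse_items", ()))
                registry[name] = sc.ScaleDefinition(name=name, **spec)
            kwargs["scales"] = registry
        if raw.get("analysis"):
            ana = dict(raw["analysis"])
            if "covariates" in ana:
                ana["covariates"] = tuple(ana["covariates"])
            kwargs["analysis"] = med.AnalysisSpec(**ana)
        return cls(**kwargs)


def _as_date(value) -> dt.date:
    return value if isinstance(value, dt.date) else dt.date.fromisoformat(str(value))


def _trial_config_from_dict(raw: dict, cutpoints, seed) -> syn.TrialConfig:
    raw = dict(raw)
    if "wear_profile" in raw:
        raw["wear_profile"] = syn.WearProfile(**raw["wear_profile"])
    if "missingness_rates" in raw:
        raw["missingness_rates"] = syn.MissingnessRates(**raw["missingness_rates"])
    if "b_true" in raw:
        raw["b_true"] = {
            tuple(k.split(":")): v for k, v in raw["b_true"].items()
        }
    for key in ("t0_start_date", "t2_start_date"):
        if key in raw:
            raw[key] = _as_date(raw[key])
    if cutpoints is not None and "cutpoints" not in raw:
        raw["cutpoints"] = cutpoints
    if seed is not None and "seed" not in raw:
        raw["seed"] = seed
    return syn.TrialConfig(**raw)


# ---------------------------------------------------------------------------
# complete-case filter


def filter_complete_cases(
    participants: pd.DataFrame,
    activity: pd.DataFrame,
    scores: pd.DataFrame,
    mediators: tuple[str, ...] = MEDIATORS,
) -> tuple[pd.DataFrame, CohortFlow]:
    """Apply the four complete-case conditions and build the analysis table.

    Returns one row per retained participant with arm, school, covariates,
    mediator scores at T0/T1 and behavior/wear averages at T0/T2.
    """
    considered = participants["participant_id"]
    n_considered = len(considered)

    cov_ok = participants["sex"].notna() & participants["ses_decile"].notna()
    ids_cov = set(participants.loc[cov_ok, "participant_id"])

    need = 2 * len(mediators)  # every mediator at T0 and T1
    relevant = scores[scores["scale"].isin(mediators)]
    med_counts = relevant[relevant["complete"]].groupby("participant_id").size()
    ids_med = {pid for pid, k in med_counts.items() if k >= need}

    def _included_ids(tp: str) -> set:
        sub = activity[(activity["time_point"] == tp) & activity["included"]]
        return set(sub["participant_id"])

    ids_t0 = _included_ids("T0")
    ids_t2 = _included_ids("T2")

    step1 = [p for p in considered if p in ids_cov]
    step2 = [p for p in step1 if p in ids_med]
    step3 = [p for p in step2 if p in ids_t0]
    step4 = [p for p in step3 if p in ids_t2]
    flow = CohortFlow(n_considered, len(step1), len(step2), len(step3), len(step4))
    if not step4:
        raise RuntimeError("complete-case filter removed every participant")

    base_cols = ["participant_id", "school_id", "arm", "sex", "ses_decile", "age_years"]
    table = participants.loc[
        participants["participant_id"].isin(step4), base_cols
    ].copy()

    wide_scores = relevant[relevant["complete"]].pivot_table(
        index="participant_id", columns=["scale", "time_point"], values="score"
    )
    for m in mediators:
        for tp, suffix in (("T0", "t0"), ("T1", "t1")):
            table[f"{m}_{suffix}"] = table["participant_id"].map(wide_scores[(m, tp)])

    for tp, suffix in (("T0", "t0"), ("T2", "t2")):
        sub = activity[activity["time_point"] == tp].set_index("participant_id")
        table[f"wear_{suffix}"] = table["participant_id"].map(sub["avg_wear_min"])
        for o, col in (
            ("sedentary", "avg_sedentary_min"),
            ("lpa", "avg_lpa_min"),
            ("mvpa", "avg_mvpa_min"),
        ):
            table[f"{o}_{suffix}"] = table["participant_id"].map(sub[col])
    return table.reset_index(drop=True), flow


# ---------------------------------------------------------------------------
# descriptives


def _mean_sd(series: pd.Series) -> tuple[float, float]:
    return float(series.mean()), float(series.std(ddof=1)) if len(series) > 1 else 0.0


def describe_cohort(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Baseline/follow-up descriptives by arm plus wear-time composition.

    Returns ``{"summary": ..., "composition": ...}``; the summary holds per
    arm n, age mean (SD), sex and SES-decile counts with percentages and
    activity means (SD) at T0 and T2, the composition the percent of wear
    time in each behavior per arm and pooled.
    """
    if table.empty:
        raise ValueError("analysis table is empty")
    rows = []
    for arm_value, grp in table.groupby("arm", sort=True):
        n = len(grp)
        age_m, age_sd = _mean_sd(grp["age_years"])
        rec = {"arm": arm_value, "n": n, "age_mean": age_m, "age_sd": age_sd}
        n_female = int((grp["sex"] == 1).sum())
        rec["female_n"] = n_female
        rec["female_pct"] = 100.0 * n_female / n
        for decile, k in grp["ses_decile"].value_counts().sort_index().items():
            rec[f"ses_decile_{int(decile)}_n"] = int(k)
        for suffix in ("t0", "t2"):
            for var in ("wear", "sedentary", "lpa", "mvpa"):
                m, sd = _mean_sd(grp[f"{var}_{suffix}"])
                rec[f"{var}_{suffix}_mean"] = m
                rec[f"{var}_{suffix}_sd"] = sd
        rows.append(rec)
    summary = pd.DataFrame(rows)

    comp_rows = []
    for label, grp in [("pooled", table)] + [
        (f"arm_{a}", g) for a, g in table.groupby("arm", sort=True)
    ]:
        wear = grp["wear_t0"].mean()
        comp_rows.append(
            {
                "group": label,
                **{
                    f"pct_{o}": 100.0 * grp[f"{o}_t0"].mean() / wear
                    for o in ("sedentary", "lpa", "mvpa")
                },
            }
        )
    return {"summary": summary, "composition": pd.DataFrame(comp_rows)}


def pooled_wear_composition(arm_stats: pd.DataFrame) -> dict[str, float]:
    """Percent of wear time per behavior from per-arm mean minutes.

    ``arm_stats`` needs columns ``n, wear, sedentary, lpa, mvpa`` (one row
    per arm, mean minutes/day); pooling weights arms by n.
    """
    weights = arm_stats["n"].to_numpy(dtype=float)
    pooled = {
        c: float(np.average(arm_stats[c].to_numpy(dtype=float), weights=weights))
        for c in ("wear", "sedentary", "lpa", "mvpa")
    }
    return {c: 100.0 * pooled[c] / pooled["wear"] for c in ("sedentary", "lpa", "mvpa")}


# ---------------------------------------------------------------------------
# report tables


def build_table2(
    table: pd.DataFrame,
    a_paths: Mapping[str, med.PathEstimate],
    mediators: tuple[str, ...] = MEDIATORS,
) -> pd.DataFrame:
    """Per mediator: raw means (SD) by arm at T0/T1 and the adjusted
    intervention effect (MAD) with CI and p."""
    rows = []
    for m in mediators:
        rec = {"mediator": m}
        for suffix, tp in (("t0", "T0"), ("t1", "T1")):
            for arm_value, name in ((0, "control"), (1, "intervention")):
                vals = table.loc[table["arm"] == arm_value, f"{m}_{suffix}"]
                rec[f"{name}_{tp}_mean"] = round(float(vals.mean()), 1)
                rec[f"{name}_{tp}_sd"] = round(float(vals.std(ddof=1)), 1)
        est = a_paths[m]
        rec.update(
            mad=round(est.coefficient, 2),
            ci_low=round(est.ci_low, 2),
            ci_high=round(est.ci_high, 2),
            p_value=round(est.p_value, 3),
            converged=est.converged,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def build_table3(results: list[med.MediationResult]) -> pd.DataFrame:
    """Per mediator-outcome pair: total, direct and indirect effects."""
    rows = []
    for r in results:
        rows.append(
            {
                "mediator": r.mediator,
                "outcome": r.outcome,
                "c": round(r.c.coefficient, 2),
                "c_ci_low": round(r.c.ci_low, 2),
                "c_ci_high": round(r.c.ci_high, 2),
                "c_p": round(r.c.p_value, 3),
                "c_prime": round(r.c_prime.coefficient, 2),
                "c_prime_ci_low": round(r.c_prime.ci_low, 2),
                "c_prime_ci_high": round(r.c_prime.ci_high, 2),
                "c_prime_p": round(r.c_prime.p_value, 3),
                "ab": round(r.ab_point, 2),
                "ab_ci_low": round(r.ab_ci_low, 2),
                "ab_ci_high": round(r.ab_ci_high, 2),
                "n_boot_used": r.n_boot_used,
                "n_boot_failed": r.n_boot_failed,
            }
        )
    columns = [
        "mediator", "outcome", "c", "c_ci_low", "c_ci_high", "c_p",
        "c_prime", "c_prime_ci_low", "c_prime_ci_high", "c_prime_p",
        "ab", "ab_ci_low", "ab_ci_high", "n_boot_used", "n_boot_failed",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class PipelineResult:
    participants: pd.DataFrame
    day_summaries: pd.DataFrame
    activity: pd.DataFrame
    scores: pd.DataFrame
    analysis_table: pd.DataFrame
    flow: CohortFlow
    descriptives: dict[str, pd.DataFrame]
    a_paths: dict[str, med.PathEstimate]
    gated: list[str]
    mediation: list[med.MediationResult]
    table2: pd.DataFrame
    table3: pd.DataFrame
    truth: syn.TrialTruth | None


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_epochs(
    config: PipelineConfig, participants: pd.DataFrame
) -> dict[tuple[str, str], list[acc.EpochSeries]]:
    frame = pd.read_csv(config.epochs_csv)
    series = acc.frame_to_series(frame, epoch_len=config.epoch_len)
    epochs: dict[tuple[str, str], list[acc.EpochSeries]] = {}
    for s in series:
        tp = "T2" if s.date >= config.t2_start_date else "T0"
        epochs.setdefault((s.participant_id, tp), []).append(s)
    return epochs


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write the report bundle to
    ``config.out_dir``.  Fully deterministic under a fixed seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # timestamp-free log format keeps the report bundle byte-reproducible
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("actimediate")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        return _run_pipeline_logged(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run_pipeline_logged(config: PipelineConfig, out: Path) -> PipelineResult:
    logger.info("config hash %s, seed %s", _config_hash(config), config.seed)

    truth = None
    if config.trial is not None:
        trial_cfg = config.trial
        if trial_cfg.seed != config.seed:
            trial_cfg = dataclasses.replace(trial_cfg, seed=config.seed)
        trial = syn.simulate_trial(trial_cfg)
        participants, epochs = trial.participants, trial.epochs
        truth = trial.truth
        truth.to_json(out / "truth.json")
        cutpoints = trial_cfg.cutpoints
        t2_start = trial_cfg.t2_start_date
        if config.write_epochs:
            all_series = [s for days in epochs.values() for s in days]
            acc.epochs_to_frame(all_series).to_csv(out / "epochs.csv", index=False)
    elif config.participants_csv is not None and config.epochs_csv is not None:
        participants = pd.read_csv(config.participants_csv)
        epochs = _load_epochs(config, participants)
        cutpoints = config.cutpoints
        t2_start = config.t2_start_date
    else:
        raise ValueError("config must set either trial (simulate) or input CSVs")
    participants.to_csv(out / "participants.csv", index=False)
    logger.info("stage simulate/load: %d participants", len(participants))

    ages = dict(zip(participants["participant_id"], participants["age_years"]))
    day_df, part_df = acc.summarize_cohort(epochs, cutpoints, ages)
    day_df.to_csv(out / "day_summaries.csv", index=False)
    part_df.to_csv(out / "participant_activity.csv", index=False)
    logger.info(
        "stage accelerometry: %d days, %d participant-time points",
        len(day_df),
        len(part_df),
    )

    scores = sc.score_table(participants, config.scales)
    scores.to_csv(out / "scores.csv", index=False)
    logger.info("stage scales: %d scores", len(scores))

    table, flow = filter_complete_cases(participants, part_df, scores)
    table.to_csv(out / "analysis_table.csv", index=False)
    (out / "cohort_flow.txt").write_text(flow.to_text())
    (out / "cohort_flow.json").write_text(
        json.dumps(dataclasses.asdict(flow) | {"final_n": flow.final_n, "percentage": flow.percentage}, indent=1)
    )
    logger.info("stage filter: %s", flow.to_text().replace("\n", "; "))

    descriptives = describe_cohort(table)
    descriptives["summary"].round(1).to_csv(out / "table1_summary.csv", index=False)
    descriptives["composition"].round(1).to_csv(out / "table1_composition.csv", index=False)

    spec = config.analysis
    if spec.seed != config.seed:
        spec = dataclasses.replace(spec, seed=config.seed)
    a_paths = {m: med.fit_a_path(table, m, spec) for m in MEDIATORS}
    gated = med.gate_mediators(a_paths, spec)
    logger.info("stage mediation: gated mediators %s", gated or "none")
    for m, est in a_paths.items():
        logger.info(
            "a path %s: %.3f (p=%.3f, converged=%s)", m, est.coefficient, est.p_value, est.converged
        )

    results = [
        med.bootstrap_indirect(table, m, o, spec)
        for m in gated
        for o in syn.OUTCOMES
    ]
    table2 = build_table2(table, a_paths)
    table3 = build_table3(results)
    table2.to_csv(out / "table2.csv", index=False)
    table3.to_csv(out / "table3.csv", index=False)
    if not gated:
        (out / "table3_note.txt").write_text(
            "No mediator showed a significant intervention effect at the "
            "screening threshold; no formal mediation models were fitted.\n"
        )
    return PipelineResult(
        participants=participants,
        day_summaries=day_df,
        activity=part_df,
        scores=scores,
        analysis_table=table,
        flow=flow,
        descriptives=descriptives,
        a_paths=a_paths,
        gated=gated,
        mediation=results,
        table2=table2,
        table3=table3,
        truth=truth,
    )
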