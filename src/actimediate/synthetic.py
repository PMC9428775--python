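"""Synthetic cluster-randomized activity-tracker trial generator.

Emulates a two-arm school-randomized trial in adolescents: ~9 schools per
arm with ~15 participants each, school-level random intercepts on both the
psychosocial mediator and behavior scales, ordinal Likert item responses
generated from latent mediator scores, intervention effects on mediators
(a paths) and behaviors (direct c' paths), mediator effects on behaviors
(b paths), and full-day accelerometer count streams whose classified
composition approximates real adolescent wear: roughly 750 min/day of wear
split ~70% sedentary, 25% light and 5% moderate-to-vigorous activity.

Every dataset ships with a :class:`TrialTruth` holding the realized
generating values, so downstream estimators can be checked by parameter
recovery.  Identical (config, seed) pairs produce byte-identical data.

The generating model, per participant i in school s(i) with arm A:

* latent mediator  M0 = mu_m + u_s + e0;  M1 = mu_m + rho_m (M0 - mu_m)
  + a_m A + u_s + e1
* behavior minutes Y2 = (1 - rho_y) mu_y + rho_y Y0 + c'_y A
  + sum_m b_{m,y} M1_m + v_s + covariate terms + e2
* item responses: each item's level is a rounded, clipped noisy copy of
  M / n_items (a thresholded latent-continuous model), so the summed score
  is monotone in expectation in the latent score and saturates at the scale
  floor and ceiling.

Missingness is completely at random per stage (survey per time point,
accelerometry per time point); an accelerometry-missing participant still
records days, but too few of them reach the valid-day wear threshold.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .accelerometry import CutPoints, EpochSeries
from .scales import DEFAULT_SCALES, ScaleDefinition

__all__ = [
    "OUTCOMES",
    "TrialConfig",
    "WearProfile",
    "MissingnessRates",
    "TrialTruth",
    "SimulatedTrial",
    "simulate_trial",
    "simulate_analysis_table",
    "simulate_likert_items",
    "simulate_epoch_day",
]

OUTCOMES = ("sedentary", "lpa", "mvpa")

#: baseline latent mediator means and between-person SDs (score units),
#: chosen to resemble published adolescent samples on these instruments
MEDIATOR_PROFILE: dict[str, tuple[float, float]] = {
    "self_efficacy": (19.2, 4.6),
    "peer_support": (15.3, 4.1),
    "family_support": (12.4, 3.7),
    "teacher_support": (11.3, 3.6),
    "self_regulation": (16.7, 4.3),
    "barriers": (20.4, 4.5),
    "enjoyment": (62.7, 10.3),
}


class ConfigError(ValueError):
    """Invalid trial configuration; the message names the offending field."""


@dataclass(frozen=True)
class WearProfile:
    """Target daily wear minutes and behavior composition."""

    wear_min_mean: float = 750.0
    wear_min_sd: float = 60.0
    fractions: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 0.70, "lpa": 0.25, "mvpa": 0.05}
    )
    #: Dirichlet concentration for person-level composition jitter
    composition_concentration: float = 60.0
    #: per-day SD of each class's minutes around the person-level target
    day_sd_min: float = 20.0


@dataclass(frozen=True)
class MissingnessRates:
    """Completely-at-random missingness probabilities per stage."""

    survey_t0: float = 0.029
    survey_t1: float = 0.029
    accel_t0: float = 0.099
    accel_t2: float = 0.293


@dataclass(frozen=True)
class TrialConfig:
    """Generating parameters of one synthetic trial.

    Effect maps: ``a_true`` gives the intervention effect on each mediator's
    latent T1 score (score units); ``b_true`` maps ``(mediator, outcome)`` to
    min/day per score unit; ``c_prime_true`` gives the direct intervention
    effect on each outcome (min/day).  Unlisted entries are zero.
    """

    n_schools_per_arm: int = 9
    participants_per_school: int = 15
    school_intercept_sd: float = 1.5  # mediator scale, score units
    school_intercept_sd_outcome: float = 12.0  # min/day
    a_true: Mapping[str, float] = field(default_factory=lambda: {"barriers": 1.8})
    b_true: Mapping[tuple[str, str], float] = field(default_factory=dict)
    c_prime_true: Mapping[str, float] = field(
        default_factory=lambda: {"sedentary": 22.5, "lpa": -16.4, "mvpa": -6.7}
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"sex": -10.0, "ses_decile": 1.0}
    )
    residual_sd_mediator: float = 4.0  # score units
    residual_sd_outcome: float = 40.0  # min/day
    mediator_stability: float = 0.6
    outcome_stability: float = 0.7
    wear_profile: WearProfile = field(default_factory=WearProfile)
    missingness_rates: MissingnessRates = field(default_factory=MissingnessRates)
    cutpoints: CutPoints = field(default_factory=CutPoints)
    days_per_time_point: int = 8
    t0_start_date: dt.date = dt.date(2024, 3, 4)
    t2_start_date: dt.date = dt.date(2024, 9, 2)
    epoch_len: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_schools_per_arm", "participants_per_school", "days_per_time_point"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "school_intercept_sd",
            "school_intercept_sd_outcome",
            "residual_sd_mediator",
            "residual_sd_outcome",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        fracs = self.wear_profile.fractions
        if set(fracs) != set(OUTCOMES):
            raise ConfigError("wear_profile.fractions must cover sedentary, lpa, mvpa")
        if any(v < 0 for v in fracs.values()) or abs(sum(fracs.values()) - 1.0) > 1e-9:
            raise ConfigError("wear_profile.fractions must be nonnegative and sum to 1")
        for name, rate in dataclasses.asdict(self.missingness_rates).items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness_rates.{name} must be in [0, 1]")
        unknown = set(self.a_true) - set(MEDIATOR_PROFILE)
        if unknown:
            raise ConfigError(f"a_true has unknown mediators: {sorted(unknown)}")
        for med, out in self.b_true:
            if med not in MEDIATOR_PROFILE or out not in OUTCOMES:
                raise ConfigError(f"b_true has unknown pair: {(med, out)!r}")
        unknown = set(self.c_prime_true) - set(OUTCOMES)
        if unknown:
            raise ConfigError(f"c_prime_true has unknown outcomes: {sorted(unknown)}")
        if self.t2_start_date <= self.t0_start_date + dt.timedelta(days=self.days_per_time_point):
            raise ConfigError("t2_start_date must fall after the T0 measurement window")


@dataclass
class TrialTruth:
    """Realized generating values of one simulated trial; never mutated by
    analysis stages."""

    config: TrialConfig
    schools: pd.DataFrame  # school_id, arm, ses_decile, u_<mediator>, v_<outcome>
    participants: pd.DataFrame  # latent scores, person-level behavior targets, flags

    def to_json(self, path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["t0_start_date"] = self.config.t0_start_date.isoformat()
        cfg["t2_start_date"] = self.config.t2_start_date.isoformat()
        cfg["b_true"] = {f"{m}:{o}": v for (m, o), v in self.config.b_true.items()}
        payload = {
            "config": cfg,
            "schools": self.schools.to_dict(orient="records"),
            "participants": self.participants.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


@dataclass
class SimulatedTrial:
    participants: pd.DataFrame
    epochs: dict[tuple[str, str], list[EpochSeries]]
    truth: TrialTruth


def simulate_likert_items(
    latent_score: float,
    scale: ScaleDefinition,
    rng: np.random.Generator,
    item_sd: float = 0.7,
) -> np.ndarray:
    """Ordinal item responses from a latent scale score.

    Each item's continuous value is ``latent_score / n_items`` plus Gaussian
    noise, rounded to the nearest level and clipped to the admissible range;
    the summed score is therefore monotone in expectation in the latent
    score and saturates at the scale floor/ceiling for extreme latents.
    """
    if not np.isfinite(latent_score):
        raise ValueError("latent_score must be finite")
    per_item = latent_score / scale.n_items
    values = rng.normal(per_item, item_sd, size=scale.n_items)
    return np.clip(np.rint(values), scale.level_min, scale.level_max).astype(int)


def simulate_epoch_day(
    targets: Mapping[str, float],
    cutpoints: CutPoints,
    rng: np.random.Generator,
    *,
    participant_id: str = "",
    date: dt.date = dt.date(2024, 1, 1),
    age_years: float | None = None,
    epoch_len: int = 15,
) -> EpochSeries:
    """One full day of epoch counts realizing a target class composition.

    ``targets`` gives intended sedentary/lpa/mvpa minutes; the remainder of
    the 24 h is nonwear, laid down as zero runs of at least the nonwear
    threshold (one block at each end of the day when long enough).  Wear
    epochs carry counts strictly inside their class's count band, so
    classification recovers the targets to within one epoch per class.
    """
    missing = set(OUTCOMES) - set(targets)
    if missing:
        raise ValueError(f"targets missing classes: {sorted(missing)}")
    if any(targets[c] < 0 for c in OUTCOMES):
        raise ValueError("targets must be nonnegative")
    per_min = 60 // epoch_len
    n_day = 1440 * per_min
    class_epochs = {c: int(round(targets[c] * per_min)) for c in OUTCOMES}
    wear_epochs = sum(class_epochs.values())
    nonwear_epochs = n_day - wear_epochs
    run_epochs = cutpoints.nonwear_run_min * per_min
    if nonwear_epochs < 0:
        raise ValueError(f"infeasible composition: {sum(targets.values()):.1f} min exceeds 24 h")
    if 0 < nonwear_epochs < run_epochs:
        raise ValueError(
            "infeasible composition: residual nonwear shorter than the "
            f"{cutpoints.nonwear_run_min}-min nonwear run threshold"
        )

    mvpa_thr = int(np.ceil(cutpoints.mvpa_threshold(age_years, epoch_len)))
    sed_max = int(np.floor(cutpoints.sedentary_max))
    bands = {
        "sedentary": (1, sed_max),
        "lpa": (sed_max + 1, mvpa_thr - 1),
        "mvpa": (mvpa_thr, 2 * mvpa_thr),
    }
    parts = []
    for c in OUTCOMES:
        lo, hi = bands[c]
        if class_epochs[c] == 0:
            continue
        if hi < lo:
            raise ValueError(f"cut-points leave no admissible counts for class {c!r}")
        parts.append(rng.integers(lo, hi + 1, size=class_epochs[c]))
    wear = np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    rng.shuffle(wear)

    if nonwear_epochs >= 2 * run_epochs:
        morning = run_epochs + int(
            rng.integers(0, nonwear_epochs - 2 * run_epochs + 1)
        )
    else:
        morning = nonwear_epochs
    evening = nonwear_epochs - morning
    counts = np.concatenate(
        [np.zeros(morning, dtype=np.int64), wear, np.zeros(evening, dtype=np.int64)]
    )
    return EpochSeries(
        participant_id=participant_id, date=date, counts=counts, epoch_len=epoch_len
    )


# ---------------------------------------------------------------------------
# trial-level generation


def _generate_core(config: TrialConfig, rng: np.random.Generator):
    """Schools, covariates, latent mediators and person-level behavior
    targets; shared by the full and table-only simulators."""
    n_schools = 2 * config.n_schools_per_arm
    n_per = config.participants_per_school
    n = n_schools * n_per

    school_ids = [f"S{k + 1:02d}" for k in range(n_schools)]
    school_arm = np.tile([0, 1], config.n_schools_per_arm)
    school_ses = rng.integers(1, 11, size=n_schools)
    u = {
        m: rng.normal(0.0, config.school_intercept_sd, size=n_schools)
        for m in MEDIATOR_PROFILE
    }
    v = {
        o: rng.normal(0.0, config.school_intercept_sd_outcome, size=n_schools)
        for o in OUTCOMES
    }
    schools = pd.DataFrame(
        {
            "school_id": school_ids,
            "arm": school_arm,
            "ses_decile": school_ses,
            **{f"u_{m}": u[m] for m in MEDIATOR_PROFILE},
            **{f"v_{o}": v[o] for o in OUTCOMES},
        }
    )

    school_idx = np.repeat(np.arange(n_schools), n_per)
    part = pd.DataFrame(
        {
            "participant_id": [f"P{k + 1:04d}" for k in range(n)],
            "school_id": np.repeat(school_ids, n_per),
            "arm": school_arm[school_idx],
            "sex": rng.integers(0, 2, size=n),  # 1 = female
            "ses_decile": school_ses[school_idx],
            "age_years": np.round(rng.normal(13.7, 0.4, size=n), 1),
        }
    )
    arm = part["arm"].to_numpy()

    # latent mediator trajectories
    for m, (mu, sd0) in MEDIATOR_PROFILE.items():
        m0 = mu + u[m][school_idx] + rng.normal(0.0, sd0, size=n)
        m1 = (
            mu
            + config.mediator_stability * (m0 - mu)
            + config.a_true.get(m, 0.0) * arm
            + u[m][school_idx]
            + rng.normal(0.0, config.residual_sd_mediator, size=n)
        )
        part[f"latent_{m}_t0"] = m0
        part[f"latent_{m}_t1"] = m1

    # person-level wear and behavior composition at baseline
    wp = config.wear_profile
    wear_t0 = rng.normal(wp.wear_min_mean, wp.wear_min_sd, size=n).clip(min=300.0)
    wear_t2 = (wear_t0 + rng.normal(0.0, 30.0, size=n)).clip(min=300.0)
    alpha = np.array([wp.fractions[c] for c in OUTCOMES]) * wp.composition_concentration
    comp = rng.dirichlet(alpha, size=n)
    part["wear_target_t0"] = wear_t0
    part["wear_target_t2"] = wear_t2
    for j, o in enumerate(OUTCOMES):
        part[f"target_{o}_t0"] = wear_t0 * comp[:, j]

    # follow-up behavior: ANCOVA-style generation around the baseline value
    cov_term = sum(
        eff * part[cov].to_numpy() for cov, eff in config.covariate_effects.items()
    )
    rho = config.outcome_stability
    for o in OUTCOMES:
        mu_o = wp.wear_min_mean * wp.fractions[o]
        y0 = part[f"target_{o}_t0"].to_numpy()
        med_term = sum(
            b * part[f"latent_{m}_t1"].to_numpy()
            for (m, oo), b in config.b_true.items()
            if oo == o
        )
        y2 = (
            (1 - rho) * mu_o
            + rho * y0
            + config.c_prime_true.get(o, 0.0) * arm
            + med_term
            + v[o][school_idx]
            + cov_term
            + rng.normal(0.0, config.residual_sd_outcome, size=n)
        )
        part[f"target_{o}_t2"] = np.clip(y2, 1.0, None)

    # rescale follow-up targets so each day stays inside 24 h minus nonwear
    tot2 = sum(part[f"target_{o}_t2"] for o in OUTCOMES)
    cap = 1440.0 - 2 * config.cutpoints.nonwear_run_min - 30.0
    scale = np.minimum(1.0, cap / tot2)
    for o in OUTCOMES:
        part[f"target_{o}_t2"] *= scale

    # completely-at-random stage missingness
    mr = config.missingness_rates
    part["miss_survey_t0"] = rng.random(n) < mr.survey_t0
    part["miss_survey_t1"] = rng.random(n) < mr.survey_t1
    part["miss_accel_t0"] = rng.random(n) < mr.accel_t0
    part["miss_accel_t2"] = rng.random(n) < mr.accel_t2
    return schools, part


def simulate_analysis_table(config: TrialConfig) -> tuple[pd.DataFrame, TrialTruth]:
    """Directly emit the merged participant-level analysis table.

    Skips the ordinal-item and epoch-stream layers: mediator scores are the
    latent continuous values and behavior minutes the person-level targets,
    with no missingness.  Intended for estimator calibration and recovery
    studies where the measurement layers would only add orthogonal noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schools, part = _generate_core(config, rng)
    table = part[
        ["participant_id", "school_id", "arm", "sex", "ses_decile", "age_years"]
    ].copy()
    table["wear_t0"] = part["wear_target_t0"]
    table["wear_t2"] = part["wear_target_t2"]
    for m in MEDIATOR_PROFILE:
        table[f"{m}_t0"] = part[f"latent_{m}_t0"]
        table[f"{m}_t1"] = part[f"latent_{m}_t1"]
    for o in OUTCOMES:
        table[f"{o}_t0"] = part[f"target_{o}_t0"]
        table[f"{o}_t2"] = part[f"target_{o}_t2"]
    return table, TrialTruth(config=config, schools=schools, participants=part)


def _participant_days(
    pid: str,
    targets: dict[str, float],
    start: dt.date,
    n_days: int,
    accel_missing: bool,
    config: TrialConfig,
    rng: np.random.Generator,
    age: float,
) -> list[EpochSeries]:
    wp = config.wear_profile
    days = []
    # an accelerometry-missing participant records too few adequate-wear days
    short_days = (
        set(rng.choice(n_days, size=max(n_days - 2, 0), replace=False))
        if accel_missing
        else set()
    )
    for d in range(n_days):
        day_t = {}
        for o in OUTCOMES:
            val = targets[o] + rng.normal(0.0, wp.day_sd_min)
            day_t[o] = max(val, 0.0)
        if d in short_days:
            day_t = {o: 0.28 * day_t[o] for o in OUTCOMES}
        days.append(
            simulate_epoch_day(
                day_t,
                config.cutpoints,
                rng,
                participant_id=pid,
                date=start + dt.timedelta(days=d),
                age_years=age,
                epoch_len=config.epoch_len,
            )
        )
    return days


def simulate_trial(config: TrialConfig) -> SimulatedTrial:
    """Generate a complete synthetic trial: participant table with Likert
    item responses at T0/T1, epoch count streams for 8 candidate days at T0
    and follow-up, and the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    schools, part = _generate_core(config, rng)

    item_blocks = []
    for scale in DEFAULT_SCALES.values():
        for tp, col_tp in (("t0", "T0"), ("t1", "T1")):
            miss = part[f"miss_survey_{tp}"].to_numpy()
            items = np.empty((len(part), scale.n_items), dtype=float)
            latents = part[f"latent_{scale.name}_{tp}"].to_numpy()
            for i in range(len(part)):
                if miss[i]:
                    items[i] = np.nan
                else:
                    items[i] = simulate_likert_items(latents[i], scale, rng)
            item_blocks.append(
                pd.DataFrame(items, columns=scale.item_columns(col_tp))
            )
    participants = pd.concat(
        [
            part[
                ["participant_id", "school_id", "arm", "sex", "ses_decile", "age_years"]
            ].reset_index(drop=True),
            *item_blocks,
        ],
        axis=1,
    )

    epochs: dict[tuple[str, str], list[EpochSeries]] = {}
    for i, rec in part.iterrows():
        pid = rec["participant_id"]
        age = rec["age_years"]
        for tp, start, miss_col in (
            ("T0", config.t0_start_date, "miss_accel_t0"),
            ("T2", config.t2_start_date, "miss_accel_t2"),
        ):
            suffix = "t0" if tp == "T0" else "t2"
            targets = {o: rec[f"target_{o}_{suffix}"] for o in OUTCOMES}
            epochs[(pid, tp)] = _participant_days(
                pid,
                targets,
                start,
                config.days_per_time_point,
                bool(rec[miss_col]),
                config,
                rng,
                age,
            )
    truth = TrialTruth(config=config, schools=schools, participants=part)
    return SimulatedTrial(participants=participants, epochs=epochs, truth=truth)
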