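"""Mixed-model mediation analysis for cluster-randomized trials.

Estimates the classic single-mediator path diagram on a participant-level
analysis table from a two-arm trial randomized at the school level:

* a path  — intervention effect on the post-intervention mediator,
  adjusted for its baseline value (``M1 ~ arm + M0 + covariates``);
* b and c' paths — mediator and direct intervention effects on the
  follow-up outcome, fitted jointly
  (``Y2 ~ arm + M1 + M0 + Y0 + covariates``);
* c path  — total intervention effect on the outcome (same model without
  the post-intervention mediator term);
* indirect effect — product of coefficients a×b, with percentile
  confidence intervals from a bootstrap that redraws whole schools with
  replacement (stratified by arm, preserving the randomized design) or,
  optionally, participants.

All models are linear mixed models with a random intercept per school,
fitted by REML.  Because the model class has exactly one variance ratio
lambda = sigma_u^2 / sigma_e^2, the REML criterion is profiled down to a
one-dimensional function of lambda and minimized by scalar search, with
generalized least squares in closed form at each evaluation; this is exact,
fast enough to sit inside a bootstrap loop, and behaves predictably when
the school variance hits the zero boundary (the fit is then identical to
ordinary least squares and the convergence flag is cleared).  Wald
confidence intervals and p-values use the normal approximation throughout.

Mediators are screened before formal mediation: only those with a
significant a path at ``alpha`` proceed, with no multiplicity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "AnalysisSpec",
    "PathEstimate",
    "MediationResult",
    "fit_lmm",
    "fit_a_path",
    "fit_outcome_model",
    "fit_total_effect",
    "gate_mediators",
    "bootstrap_indirect",
]


class RankDeficientError(ValueError):
    """Fixed-effect design is not full rank; names the collinear columns."""


@dataclass(frozen=True)
class AnalysisSpec:
    """Analysis configuration shared by every model in the mediation stage.

    ``covariates`` are adjustment terms common to all models; wear-time
    adjustment uses the baseline average in mediator models and the
    follow-up average in outcome models (both configurable).  Setting
    ``cluster_var=None`` disables the random intercept and fits plain OLS
    throughout.
    """

    cluster_var: str | None = "school_id"
    arm_var: str = "arm"
    covariates: tuple[str, ...] = ("sex", "ses_decile")
    a_path_wear: str | None = "wear_t0"
    outcome_wear: str | None = "wear_t2"
    alpha: float = 0.05
    n_boot: int = 1000
    ci_level: float = 0.95
    bootstrap_unit: str = "cluster"  # or "participant"
    max_boot_failure_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.bootstrap_unit not in ("cluster", "participant"):
            raise ValueError("bootstrap_unit must be 'cluster' or 'participant'")


@dataclass(frozen=True)
class PathEstimate:
    """One fixed-effect estimate (a mean adjusted difference for arm terms)."""

    path: str
    coefficient: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    converged: bool
    cluster_var_estimate: float


@dataclass
class MediationResult:
    mediator: str
    outcome: str
    a: PathEstimate
    b: PathEstimate
    c: PathEstimate
    c_prime: PathEstimate
    ab_point: float
    ab_ci_low: float
    ab_ci_high: float
    n_boot_used: int
    n_boot_failed: int


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify columns whose removal restores full rank
        culprits = [
            col
            for i, col in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(arr, i, axis=1)) == rank
        ]
        raise RankDeficientError(f"design is rank deficient; collinear columns: {culprits}")


def _wald(params, bses, n, converged, cluster_var, ci_level) -> dict[str, PathEstimate]:
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2)
    out = {}
    for name in params.index:
        coef, se = float(params[name]), float(bses[name])
        p = 2 * scipy.stats.norm.sf(abs(coef) / se) if se > 0 else (0.0 if coef else 1.0)
        out[name] = PathEstimate(
            path=name,
            coefficient=coef,
            se=se,
            ci_low=coef - z * se,
            ci_high=coef + z * se,
            p_value=float(p),
            n=n,
            converged=converged,
            cluster_var_estimate=cluster_var,
        )
    return out


def _profile_reml(y: np.ndarray, X: np.ndarray, group_idx: np.ndarray):
    """Random-intercept LMM by profiled REML.

    For V = sigma_e^2 (I + lambda Z Z') with one intercept per cluster,
    beta and sigma_e^2 have closed GLS forms given lambda, so the REML
    criterion reduces to a scalar function of lambda minimized by bounded
    Brent search on the log scale.  Returns (beta, cov_beta, sigma_u^2,
    sigma_e^2, boundary flag).
    """
    n, p = X.shape
    n_groups = group_idx.max() + 1
    group_n = np.bincount(group_idx, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    # per-group sums of design columns and response
    Sx = np.zeros((n_groups, p))
    np.add.at(Sx, group_idx, X)
    Sy = np.bincount(group_idx, weights=y, minlength=n_groups)

    def _solve(lam: float):
        c = lam / (1.0 + lam * group_n)  # shrinkage weight per cluster
        XtWX = XtX - (Sx.T * c) @ Sx
        XtWy = Xty - (Sx.T * c) @ Sy
        beta = np.linalg.solve(XtWX, XtWy)
        Sr = Sy - Sx @ beta
        rWr = (
            yty - 2.0 * beta @ Xty + beta @ XtX @ beta - float(c @ (Sr**2))
        )
        return beta, XtWX, max(rWr, 1e-300)

    def criterion(log_lam: float) -> float:
        lam = np.exp(log_lam)
        _, XtWX, rWr = _solve(lam)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        return (
            (n - p) * np.log(rWr)
            + float(np.sum(np.log1p(lam * group_n)))
            + logdet_x
        )

    res = scipy.optimize.minimize_scalar(
        criterion, bounds=(-18.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(np.exp(res.x))
    boundary = criterion(-40.0) <= res.fun or lam < 1e-8
    if boundary:
        lam = 0.0
    beta, XtWX, rWr = _solve(lam)
    sigma_e2 = rWr / (n - p)
    cov_beta = sigma_e2 * np.linalg.inv(XtWX)
    return beta, cov_beta, lam * sigma_e2, sigma_e2, boundary


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed: Sequence[str],
    cluster: str | None,
    ci_level: float = 0.95,
) -> dict[str, PathEstimate]:
    """REML random-intercept fit; one :class:`PathEstimate` per fixed effect.

    Complete cases only (rows with any NaN in the model variables are
    dropped).  A boundary school-variance estimate collapses the fit to OLS
    with ``converged=False`` on every estimate.
    """
    cols = [outcome, *fixed] + ([cluster] if cluster else [])
    df = data[cols].dropna()
    if cluster is not None and df[cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters for a random-intercept model")
    X = df[list(fixed)].astype(float)
    X.insert(0, "Intercept", 1.0)
    _check_rank(X)
    y = df[outcome].astype(float)
    n = len(df)

    if cluster is not None:
        group_idx = pd.factorize(df[cluster])[0]
        beta, cov_beta, var_re, _, boundary = _profile_reml(
            y.to_numpy(), X.to_numpy(), group_idx
        )
        params = pd.Series(beta, index=X.columns)
        bses = pd.Series(np.sqrt(np.diag(cov_beta)), index=X.columns)
        return _wald(params, bses, n, not boundary, var_re, ci_level)

    res = sm.OLS(y, X).fit()
    return _wald(res.params, res.bse, n, True, float("nan"), ci_level)


def _relabel(est: PathEstimate, label: str) -> PathEstimate:
    return replace(est, path=label)


def _a_fixed(mediator, spec, extra=()):
    fixed = [spec.arm_var, f"{mediator}_t0", *spec.covariates]
    if spec.a_path_wear:
        fixed.append(spec.a_path_wear)
    fixed.extend(c for c in extra if c not in fixed)
    return fixed


def _outcome_fixed(mediator, outcome, spec, with_m1=True):
    fixed = [spec.arm_var]
    if with_m1:
        fixed.append(f"{mediator}_t1")
    fixed += [f"{mediator}_t0", f"{outcome}_t0", *spec.covariates]
    if spec.outcome_wear:
        fixed.append(spec.outcome_wear)
    return fixed


def fit_a_path(
    data: pd.DataFrame,
    mediator: str,
    spec: AnalysisSpec,
    extra_covariates: Sequence[str] = (),
) -> PathEstimate:
    """Intervention effect on the T1 mediator, adjusted for its baseline
    value plus the covariate set; returns the arm coefficient (MAD)."""
    fixed = _a_fixed(mediator, spec, extra_covariates)
    fits = fit_lmm(data, f"{mediator}_t1", fixed, spec.cluster_var, spec.ci_level)
    return _relabel(fits[spec.arm_var], "a")


def fit_outcome_model(
    data: pd.DataFrame,
    mediator: str,
    outcome: str,
    spec: AnalysisSpec,
) -> tuple[PathEstimate, PathEstimate]:
    """Joint mediator (b) and direct intervention (c') effects on the T2
    outcome, adjusted for baseline mediator and baseline outcome."""
    fixed = _outcome_fixed(mediator, outcome, spec)
    fits = fit_lmm(data, f"{outcome}_t2", fixed, spec.cluster_var, spec.ci_level)
    return (
        _relabel(fits[f"{mediator}_t1"], "b"),
        _relabel(fits[spec.arm_var], "c_prime"),
    )


def fit_total_effect(
    data: pd.DataFrame,
    mediator: str,
    outcome: str,
    spec: AnalysisSpec,
) -> PathEstimate:
    """Total intervention effect (c) on the T2 outcome: the outcome model
    without the post-intervention mediator term."""
    fixed = _outcome_fixed(mediator, outcome, spec, with_m1=False)
    fits = fit_lmm(data, f"{outcome}_t2", fixed, spec.cluster_var, spec.ci_level)
    return _relabel(fits[spec.arm_var], "c")


def gate_mediators(
    a_paths: Mapping[str, PathEstimate], spec: AnalysisSpec
) -> list[str]:
    """Mediators whose a-path p-value clears ``alpha``; no multiplicity
    correction, preserving the screening-then-mediation design."""
    return [m for m, est in a_paths.items() if est.p_value < spec.alpha]


def _resample(data: pd.DataFrame, spec: AnalysisSpec, rng: np.random.Generator) -> pd.DataFrame:
    if spec.bootstrap_unit == "participant":
        idx = rng.integers(0, len(data), size=len(data))
        return data.iloc[idx].reset_index(drop=True)
    # cluster bootstrap, stratified by arm to preserve the randomized design
    pieces = []
    counter = 0
    for arm_value, arm_df in data.groupby(spec.arm_var, sort=True):
        clusters = np.sort(arm_df[spec.cluster_var].unique())
        draw = rng.choice(clusters, size=len(clusters), replace=True)
        for cid in draw:
            piece = arm_df[arm_df[spec.cluster_var] == cid].copy()
            # duplicated schools must stay distinct clusters in the refit
            piece[spec.cluster_var] = f"boot{counter}"
            counter += 1
            pieces.append(piece)
    return pd.concat(pieces, ignore_index=True)


def bootstrap_indirect(
    data: pd.DataFrame,
    mediator: str,
    outcome: str,
    spec: AnalysisSpec,
) -> MediationResult:
    """Product-of-coefficients indirect effect with percentile bootstrap CI.

    Each resample redraws sampling units with replacement (whole schools by
    default), refits the a-path and outcome models and records a×b; the CI
    is the empirical ``(1-ci_level)/2`` and ``1-(1-ci_level)/2`` quantiles
    of the successful resamples.  Resamples whose refits fail outright are
    dropped and counted; more than ``max_boot_failure_frac`` failures aborts
    with advice to use larger clusters or the participant-level bootstrap.
    Identical seeds give identical CIs.
    """
    a = fit_a_path(data, mediator, spec)
    b, c_prime = fit_outcome_model(data, mediator, outcome, spec)
    c = fit_total_effect(data, mediator, outcome, spec)

    rng = np.random.default_rng(spec.seed)
    draws = []
    n_failed = 0
    for _ in range(spec.n_boot):
        sample = _resample(data, spec, rng)
        try:
            a_i = fit_a_path(sample, mediator, spec)
            b_i, _ = fit_outcome_model(sample, mediator, outcome, spec)
            draws.append(a_i.coefficient * b_i.coefficient)
        except (RankDeficientError, ValueError, np.linalg.LinAlgError):
            n_failed += 1
    if n_failed > spec.max_boot_failure_frac * spec.n_boot:
        raise RuntimeError(
            f"{n_failed}/{spec.n_boot} bootstrap refits failed; consider larger "
            "clusters or bootstrap_unit='participant'"
        )
    tail = 100 * (1 - spec.ci_level) / 2
    lo, hi = np.percentile(draws, [tail, 100 - tail])
    return MediationResult(
        mediator=mediator,
        outcome=outcome,
        a=a,
        b=b,
        c=c,
        c_prime=c_prime,
        ab_point=a.coefficient * b.coefficient,
        ab_ci_low=float(lo),
        ab_ci_high=float(hi),
        n_boot_used=len(draws),
        n_boot_failed=n_failed,
    )
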