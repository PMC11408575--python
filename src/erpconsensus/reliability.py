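"""Reproducibility scoring: analytical and Monte-Carlo standard errors,
variance decomposition, Cronbach's alpha, and the condition-effect test.

The analytical standard error of a score over n contributing trials (or
subjects) is SD/√n with the n−1 sample SD.  The Monte-Carlo variant resamples
the pool of per-trial consensus labelings with replacement — no re-clustering
of the raw trials is needed — reruns across-trial consensus plus window
determination per iteration, and aggregates per-iteration standard errors as
mcSE = √(mean SE_r²).  Subject-level errors combine into the aggregated
measurement error MS(SE) (mean squared subject SE); the total variance is by
construction Var_all = Var_par + MS(SE), giving

    reliability = 1 − MS(SE) / Var_all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import consensus_across_trials
from .datamodel import EpochSet, Labeling, PipelineConfig, TemplateMap
from .pipeline import determine_time_window, score_window

__all__ = [
    "standard_error",
    "monte_carlo",
    "MCResult",
    "aggregate_reliability",
    "cronbach_alpha",
    "sem",
    "condition_test",
    "ConditionTest",
]

SCORE_ITEMS = ("tw_start", "tw_end", "innersim", "amplitude", "corr")


def standard_error(values: np.ndarray) -> float:
    """Sample standard error SD/√n (SD with the n−1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("standard error needs at least 2 values")
    return float(v.std(ddof=1) / np.sqrt(v.size))


@dataclass
class MCResult:
    """Monte-Carlo resampling outcome for one subject/condition."""

    R: int
    n_draw: int
    iteration_scores: pd.DataFrame      # subject-level score per iteration
    se_r: pd.DataFrame                  # per-iteration trial-level SEs
    mc_se: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.0


def monte_carlo(
    epochset: EpochSet,
    labelings: dict[int, Labeling],
    template: TemplateMap,
    cfg: PipelineConfig,
    n_draw: int | None = None,
    R: int = 1000,
    seed: int = 0,
) -> MCResult:
    """Resample the trial-labeling pool with replacement R times.

    Each iteration draws ``n_draw`` labelings (default: pool size), combines
    them with across-trial consensus, determines the window on the drawn
    trials' average, and scores the window on the subject average and on each
    drawn trial.  Per-iteration SE_r = SD_r/√n_draw over the trial-level
    scores; mcSE = √(mean SE_r²).  Iterations where no window can be
    identified are recorded as missing and excluded, with the missing rate
    reported.
    """
    pool = sorted(labelings)
    if not pool:
        raise ValueError("empty labeling pool")
    if n_draw is None:
        n_draw = len(pool)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    iter_rows, se_rows = [], []
    missing = 0
    for _ in range(R):
        drawn = [pool[j] for j in rng.integers(0, len(pool), size=n_draw)]
        lab = consensus_across_trials([labelings[i] for i in drawn], cfg.K)
        erp = epochset.erp(drawn)
        win = determine_time_window(lab, erp, epochset.times, cfg,
                                    template=template)
        if win is None:
            missing += 1
            continue
        score = score_window(erp, win, template, epochset.channels,
                             cfg.centered)
        iter_rows.append({k: getattr(score, k) for k in SCORE_ITEMS})
        trial_scores = []
        for i in drawn:
            try:
                s = score_window(epochset.trials[i], win, template,
                                 epochset.channels, cfg.centered)
            except ZeroDivisionError:
                continue
            trial_scores.append({k: getattr(s, k) for k in SCORE_ITEMS})
        tdf = pd.DataFrame(trial_scores)
        se_rows.append({k: float(tdf[k].std(ddof=1) / np.sqrt(len(tdf)))
                        for k in SCORE_ITEMS})
    se_df = pd.DataFrame(se_rows)
    mc_se = {k: float(np.sqrt(np.mean(se_df[k] ** 2))) for k in SCORE_ITEMS} \
        if len(se_df) else {}
    return MCResult(R=R, n_draw=n_draw,
                    iteration_scores=pd.DataFrame(iter_rows),
                    se_r=se_df, mc_se=mc_se, missing_rate=missing / R)


def aggregate_reliability(subject_ses: np.ndarray, subject_scores: np.ndarray
                          ) -> dict[str, float]:
    """Variance decomposition over subjects.

    MS(SE) is the mean squared subject standard error, Var_par the between-
    subject variance of the scores, Var_all their sum (exactly), and
    reliability = 1 − MS(SE)/Var_all.
    """
    ses = np.asarray(subject_ses, dtype=float)
    scores = np.asarray(subject_scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 subjects")
    ms_se = float(np.mean(ses**2))
    var_par = float(scores.var(ddof=1))
    var_all = var_par + ms_se
    if var_all == 0.0:
        raise ZeroDivisionError("reliability undefined: total variance is zero")
    return {"MS_SE": ms_se, "Var_par": var_par, "Var_all": var_all,
            "reliability": 1.0 - ms_se / var_all}


def cronbach_alpha(scores: np.ndarray) -> float:
    """Cronbach's alpha of a subjects × items score matrix."""
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2:
        raise ValueError("scores must be a subjects × items matrix")
    n, q = X.shape
    if q < 2 or n < 2:
        raise ValueError("need at least 2 items and 2 subjects")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ZeroDivisionError("alpha undefined: zero total variance")
    return float(q / (q - 1) * (1.0 - item_vars.sum() / total_var))


def sem(sd: float, alpha: float) -> float:
    """Standard error of measurement: SD·√(1−α)."""
    if alpha > 1.0:
        raise ValueError("alpha cannot exceed 1")
    return float(sd * np.sqrt(1.0 - alpha))


@dataclass
class ConditionTest:
    F: float
    df: tuple[int, int]
    p: float
    eta_p2: float
    capped: bool = False


def condition_test(scores: np.ndarray) -> ConditionTest:
    """One-way repeated-measures test of a 2-level condition factor.

    With two levels the RM-ANOVA F equals the squared paired-t statistic on
    the condition differences, with df (1, n−1); partial eta² = F/(F + n − 1).
    A zero-variance difference with nonzero mean yields an infinite F,
    reported capped.
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("scores must be n × 2 (paired conditions)")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = X[:, 0] - X[:, 1]
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return ConditionTest(0.0, (1, n - 1), 1.0, 0.0)
        return ConditionTest(np.inf, (1, n - 1), 0.0, 1.0, capped=True)
    t = d.mean() / (sd / np.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    return ConditionTest(float(F), (1, n - 1), p, float(F / (F + n - 1)))
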