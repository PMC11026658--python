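"""Preprocessing of response tables and descriptive/validation analyses.

Raw task files hold one row per (subject, trial) with the cue shown, the
delivered stimulus, the slider position on the 0.0-10.0 scale and the
report-phase yes/no answer.  Preprocessing rescales the slider to [0, 1],
maps predictions into contingency space, binarises them for the binary
observation model (responses at exactly 0.5 become missed trials there),
computes the per-subject certainty score and excludes subjects missing more
than 10 trials.  The report answer only validates stimulus detection and
never enters any likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import rw_traj_grad, rw_dual_traj_grad, softmax_prob
from .task import TrialSchedule, to_contingency_prediction

__all__ = [
    "SubjectResponses",
    "preprocess",
    "certainty_score",
    "binarise",
    "proportion_correct",
    "group_trajectory_validation",
    "spearman_matrix",
    "MAX_MISSED_TRIALS",
]

logger = logging.getLogger(__name__)

#: Subjects missing more than this many trials are excluded.
MAX_MISSED_TRIALS = 10

_REQUIRED_COLUMNS = ("subject_id", "trial", "cue", "resistance")


@dataclass
class SubjectResponses:
    """One subject's preprocessed trial series (contingency space).

    ``y`` holds continuous predictions in [0, 1] (NaN = missed), ``yb`` the
    binarised view (NaN also where y = 0.5, complete indecision), ``report``
    the report-phase answers, ``certainty`` the mean |y - 0.5| over answered
    trials.
    """

    subject_id: str
    y: np.ndarray
    yb: np.ndarray
    report: np.ndarray | None
    certainty: float
    n_missed: int


def certainty_score(y) -> float:
    """Mean absolute deviation of responses from 0.5 (indecision).

    Bounded in [0, 0.5]; invariant under the contingency reflection
    ``y -> 1 - y``.  Missed trials are ignored.
    """
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).any():
        raise ValueError("certainty undefined: no non-missing responses")
    return float(np.nanmean(np.abs(y - 0.5)))


def binarise(y) -> np.ndarray:
    """Binarise continuous predictions: >0.5 -> 1, <0.5 -> 0, 0.5 -> NaN."""
    y = np.asarray(y, dtype=float)
    yb = np.where(y > 0.5, 1.0, np.where(y < 0.5, 0.0, np.nan))
    return np.where(np.isnan(y), np.nan, yb)


def preprocess(
    raw: pd.DataFrame,
    schedule: TrialSchedule | None = None,
    max_missed: int = MAX_MISSED_TRIALS,
) -> dict[str, SubjectResponses]:
    """Turn a raw response table into per-subject contingency-space series.

    Expects columns ``subject_id, trial, cue, resistance`` plus a slider
    column (``slider_0_10`` on the task's 0-10 scale, or ``y`` already in
    [0, 1]) and optionally ``report_yes_no``.  Subjects with more than
    ``max_missed`` missed trials are dropped with a logged reason.
    """
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"raw table lacks columns {missing_cols}")
    if "slider_0_10" in raw.columns:
        y_raw = raw["slider_0_10"].to_numpy(dtype=float)
        bad = np.isfinite(y_raw) & ((y_raw < 0) | (y_raw > 10))
        if bad.any():
            raise ValueError(
                f"slider values outside [0, 10] at rows {np.where(bad)[0].tolist()}"
            )
        y_unit = y_raw / 10.0
    elif "y" in raw.columns:
        y_unit = raw["y"].to_numpy(dtype=float)
    else:
        raise ValueError("raw table needs a 'slider_0_10' or 'y' column")

    table = raw.assign(_y=y_unit).sort_values(["subject_id", "trial"])
    out: dict[str, SubjectResponses] = {}
    for sid, grp in table.groupby("subject_id", sort=True):
        if schedule is not None and len(grp) != schedule.n_trials:
            raise ValueError(
                f"subject {sid}: {len(grp)} rows vs "
                f"{schedule.n_trials} scheduled trials"
            )
        cue = grp["cue"].to_numpy(dtype=int)
        y = to_contingency_prediction(cue, grp["_y"].to_numpy())
        n_missed = int(np.isnan(y).sum())
        if n_missed > max_missed:
            logger.info(
                "excluding subject %s: %d missed trials (limit %d)",
                sid, n_missed, max_missed,
            )
            continue
        report = (
            grp["report_yes_no"].to_numpy(dtype=float)
            if "report_yes_no" in grp.columns
            else None
        )
        out[str(sid)] = SubjectResponses(
            subject_id=str(sid),
            y=y,
            yb=binarise(y),
            report=report,
            certainty=certainty_score(y),
            n_missed=n_missed,
        )
    return out


def _stack(responses: dict[str, SubjectResponses], attr: str) -> np.ndarray:
    return np.vstack([getattr(r, attr) for r in responses.values()])


def proportion_correct(
    responses: dict[str, SubjectResponses],
    schedule: TrialSchedule,
    reference=None,
):
    """Per-trial fraction of subjects whose binarised prediction matches o.

    Subjects with a missed (or exactly-0.5) response on a trial do not count
    toward that trial.  With ``reference`` (another per-trial series, e.g.
    from a different cohort) also returns the Pearson r and p comparing the
    two series.
    """
    YB = _stack(responses, "yb")
    if YB.shape[1] != schedule.n_trials:
        raise ValueError("responses and schedule trial counts differ")
    answered = ~np.isnan(YB)
    correct = (YB == schedule.o[None, :]) & answered
    with np.errstate(invalid="ignore"):
        series = correct.sum(axis=0) / answered.sum(axis=0)
    if reference is None:
        return series
    reference = np.asarray(reference, dtype=float)
    if reference.shape[0] != series.shape[0]:
        raise ValueError(
            f"reference has {reference.shape[0]} trials, expected "
            f"{series.shape[0]}"
        )
    res = stats.pearsonr(series, reference)
    return series, float(res.statistic), float(res.pvalue)


def group_trajectory_validation(
    fit, responses: dict[str, SubjectResponses], schedule: TrialSchedule
):
    """Correlate mean modelled predictions with mean observed predictions.

    The modelled series is the across-subject mean of the fitted prediction
    trajectory (softmax response probabilities for binary fits, the
    trajectory itself for continuous fits); the observed series is the mean
    binarised or continuous response per trial.  Returns a dict with the
    two series, Pearson ``r`` and ``p``; a zero-variance modelled series
    (e.g. a null model) yields ``r = 0.0`` with ``degenerate = True``.
    """
    o = schedule.o.astype(float)
    if isinstance(fit, list):  # per-subject binary fits
        rows = []
        for f in fit:
            est = f.estimates
            if "alpha_p" in est:
                V, _, _ = rw_dual_traj_grad(
                    o, schedule.s, est["alpha_p"], est["alpha_n"]
                )
            else:
                V, _ = rw_traj_grad(o, est["alpha"])
            rows.append(softmax_prob(V[0], est["beta"]))
        modelled = np.mean(rows, axis=0)
        observed = np.nanmean(_stack(responses, "yb"), axis=0)
    else:
        est = fit.estimates
        if "alpha_p" in est:
            V, _, _ = rw_dual_traj_grad(
                o, schedule.s,
                np.atleast_1d(est["alpha_p"]), np.atleast_1d(est["alpha_n"]),
            )
        else:
            V, _ = rw_traj_grad(o, np.atleast_1d(est["alpha"]))
        modelled = V.mean(axis=0)
        observed = np.nanmean(_stack(responses, "y"), axis=0)

    keep = np.isfinite(observed)
    if not keep.any():
        raise ValueError("no overlapping trials between model and data")
    mod, obs = modelled[keep], observed[keep]
    if np.ptp(mod) == 0 or np.ptp(obs) == 0:
        return {
            "modelled": modelled, "observed": observed,
            "r": 0.0, "p": 1.0, "degenerate": True,
        }
    res = stats.pearsonr(mod, obs)
    return {
        "modelled": modelled, "observed": observed,
        "r": float(res.statistic), "p": float(res.pvalue),
        "degenerate": False,
    }


def spearman_matrix(variables: pd.DataFrame, min_pairs: int = 3):
    """Pairwise Spearman rank correlations with uncorrected p-values.

    ``variables`` has one row per subject and one column per measure
    (questionnaire totals, fitted learning rates, certainty).  Missing
    entries are dropped pairwise; cells with fewer than ``min_pairs``
    complete pairs or a constant column are NaN (flagged via a warning from
    the caller's log).  Returns ``(rho, p)`` DataFrames; ``rho`` is
    symmetric with a unit diagonal.
    """
    cols = list(variables.columns)
    k = len(cols)
    rho = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    for i in range(k):
        xi = variables[cols[i]].to_numpy(dtype=float)
        for j in range(i + 1, k):
            xj = variables[cols[j]].to_numpy(dtype=float)
            keep = np.isfinite(xi) & np.isfinite(xj)
            if keep.sum() < min_pairs or np.ptp(xi[keep]) == 0 or (
                np.ptp(xj[keep]) == 0
            ):
                logger.warning(
                    "spearman cell (%s, %s) undefined "
                    "(constant column or <%d pairs)",
                    cols[i], cols[j], min_pairs,
                )
                r = p = np.nan
            else:
                res = stats.spearmanr(xi[keep], xj[keep])
                r, p = float(res.statistic), float(res.pvalue)
            rho.iloc[i, j] = rho.iloc[j, i] = r
            pval.iloc[i, j] = pval.iloc[j, i] = p
    return rho, pval
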