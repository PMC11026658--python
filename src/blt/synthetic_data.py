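"""Synthetic study generation.

Builds complete synthetic cohorts — trial schedules, per-subject response
tables on the raw 0-10 slider scale, questionnaire-like scores, and a
ground-truth record — so the whole pipeline (preprocessing, fitting,
recovery, correlation analyses) can be exercised end to end without any
empirical data.

Learning rates are drawn from the same truncated normal used for parameter
recovery; responses come from the recovery-module simulators on one shared
schedule (as in the real task, where every participant saw the same outcome
order).  Questionnaire scores are Gaussian with configurable marginals and
an optional target Spearman correlation to each subject's true learning
rate or realised certainty, implemented with a Gaussian copula.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .behaviour import certainty_score
from .recovery import (
    ALPHA_PRIOR_MEAN,
    ALPHA_PRIOR_VAR,
    draw_alpha,
    simulate_binary,
    simulate_continuous,
    simulate_dual_continuous,
)
from .task import TrialSchedule, build_schedule

__all__ = ["QuestionnaireSpec", "StudySpec", "StudyBundle", "generate_study",
           "DEFAULT_QUESTIONNAIRES"]


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Marginal and (optional) behavioural coupling of one instrument.

    ``target`` names the behavioural quantity the score should rank-correlate
    with (``"alpha"`` or ``"certainty"``); ``target_rho`` is the desired
    Spearman correlation (in (-1, 1); 0 or ``target=None`` gives an
    independent score).
    """

    name: str
    mean: float
    sd: float
    target: str | None = None
    target_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        if not -1.0 < self.target_rho < 1.0:
            raise ValueError(f"{self.name}: target_rho must lie in (-1, 1)")
        if self.target not in (None, "alpha", "certainty"):
            raise ValueError(f"{self.name}: unknown target {self.target!r}")


def _gauss_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    # IQR of a Gaussian is 2 * 0.6745 sd
    return float(median), float(iqr / 1.349)


#: Cosmetic default marginals for the standard instrument battery, derived
#: from typical healthy-cohort medians/IQRs (mean = median, sd = IQR/1.349).
DEFAULT_QUESTIONNAIRES: tuple[QuestionnaireSpec, ...] = tuple(
    QuestionnaireSpec(name, *_gauss_from_median_iqr(med, iqr))
    for name, med, iqr in [
        ("STAI-T", 36.5, 18.75), ("STAI-S", 33.0, 18.75),
        ("GAD-7", 2.5, 4.75), ("ASI-3", 17.5, 24.75),
        ("CESD", 10.0, 7.75), ("PANAS-P", 33.5, 8.5),
        ("PANAS-N", 18.0, 10.25), ("FSS", 35.0, 17.75),
        ("CD-RISC", 71.0, 18.25), ("GSE", 31.0, 19.0),
        ("MAIA", 21.29, 6.37), ("PCS-B", 11.5, 29.0),
        ("PVAQ-B", 32.5, 8.5),
    ]
)


@dataclass
class StudySpec:
    """Configuration of a synthetic cohort.

    Defaults mirror the standard task conditions: a 16-subject cohort on the
    80-trial, 80/20, four-reversal schedule, continuous responses with
    moderate noise, learning rates from the truncated normal used
    throughout.
    """

    n_subjects: int = 16
    schedule: dict = field(default_factory=dict)
    response_mode: str = "continuous"  # binary | continuous | dual
    alpha_mean: float = ALPHA_PRIOR_MEAN
    alpha_variance: float = ALPHA_PRIOR_VAR
    alpha_bounds: tuple = (0.0, 1.0)
    sigma: float = 0.2
    beta: float = 4.0
    missing_rate: float = 0.0
    report_lapse_rate: float = 0.0
    questionnaires: tuple = DEFAULT_QUESTIONNAIRES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.report_lapse_rate <= 1.0:
            raise ValueError("report_lapse_rate must lie in [0, 1]")
        if self.response_mode not in ("binary", "continuous", "dual"):
            raise ValueError(f"unknown response_mode {self.response_mode!r}")


@dataclass
class StudyBundle:
    """Generated study artefacts, writable as the CSV/JSON dialects the
    preprocessing pipeline consumes."""

    responses: pd.DataFrame
    questionnaires: pd.DataFrame
    truth: dict
    schedule: TrialSchedule

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.responses.to_csv(outdir / "responses.csv", index=False)
        self.questionnaires.to_csv(outdir / "questionnaires.csv", index=False)
        self.schedule.to_csv(outdir / "schedule.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2, sort_keys=True)


def _copula_scores(
    spec: QuestionnaireSpec, z_target: dict, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Gaussian-copula score with a requested Spearman rho to a latent."""
    eps = rng.standard_normal(n)
    if spec.target is None or spec.target_rho == 0.0:
        return spec.mean + spec.sd * eps
    # bivariate-normal latent correlation realising the target Spearman rho
    rho_l = 2.0 * np.sin(np.pi * spec.target_rho / 6.0)
    z = rho_l * z_target[spec.target] + np.sqrt(1.0 - rho_l**2) * eps
    return spec.mean + spec.sd * z


def generate_study(spec: StudySpec) -> StudyBundle:
    """Generate a full synthetic study from a :class:`StudySpec`.

    Deterministic for a fixed spec (including seed): the same spec always
    yields byte-identical CSV output.
    """
    rng = np.random.default_rng(spec.seed)
    schedule = build_schedule(seed=spec.seed, **spec.schedule)
    n, T = spec.n_subjects, schedule.n_trials

    truth: dict = {
        "seed": spec.seed,
        "response_mode": spec.response_mode,
        "schedule": {
            "n_trials": schedule.n_trials,
            "block_lengths": list(schedule.block_lengths),
            "p_high": schedule.p_high,
            "realization": schedule.realization,
            "seed": schedule.seed,
        },
    }

    if spec.response_mode == "dual":
        ap = draw_alpha(n, spec.alpha_mean, spec.alpha_variance,
                        spec.alpha_bounds, seed=rng)
        an = draw_alpha(n, spec.alpha_mean, spec.alpha_variance,
                        spec.alpha_bounds, seed=rng)
        Y = simulate_dual_continuous(ap, an, spec.sigma, schedule, rng)
        truth.update(alpha_p=ap.tolist(), alpha_n=an.tolist(),
                     sigma=spec.sigma)
        alpha_latent = ap  # couple questionnaires to the positive-valence rate
    else:
        alpha = draw_alpha(n, spec.alpha_mean, spec.alpha_variance,
                           spec.alpha_bounds, seed=rng)
        truth["alpha"] = alpha.tolist()
        alpha_latent = alpha
        if spec.response_mode == "binary":
            Y = simulate_binary(alpha, spec.beta, schedule, rng)
            truth["beta"] = spec.beta
        else:
            Y = simulate_continuous(alpha, spec.sigma, schedule, rng)
            truth["sigma"] = spec.sigma

    if spec.missing_rate > 0:
        Y = np.where(rng.random(Y.shape) < spec.missing_rate, np.nan, Y)

    # report phase: echo the true stimulus, with an optional lapse rate
    report = np.tile(schedule.resistance.astype(float), (n, 1))
    if spec.report_lapse_rate > 0:
        flip = rng.random(report.shape) < spec.report_lapse_rate
        report = np.where(flip, 1.0 - report, report)

    # back from contingency space to the raw cue-referenced slider scale
    y_raw = np.where(schedule.cue[None, :] == 1, Y, 1.0 - Y)
    subject_ids = [f"sub-{i + 1:03d}" for i in range(n)]
    responses = pd.DataFrame(
        {
            "subject_id": np.repeat(subject_ids, T),
            "trial": np.tile(np.arange(1, T + 1), n),
            "cue": np.tile(schedule.cue, n),
            "resistance": np.tile(schedule.resistance, n),
            "slider_0_10": np.round(10.0 * y_raw.ravel(), 6),
            "report_yes_no": report.ravel().astype(object),
        }
    )

    # latent normal scores for the copula: alpha through its generating CDF,
    # certainty through rank-based normal scores of the realised values
    sd = np.sqrt(spec.alpha_variance)
    a_, b_ = [(bnd - spec.alpha_mean) / sd for bnd in spec.alpha_bounds]
    u_alpha = stats.truncnorm.cdf(alpha_latent, a_, b_,
                                  loc=spec.alpha_mean, scale=sd)
    z_alpha = stats.norm.ppf(np.clip(u_alpha, 1e-12, 1 - 1e-12))
    cert = np.array([certainty_score(row) for row in Y])
    ranks = stats.rankdata(cert)
    z_cert = stats.norm.ppf((ranks - 0.5) / n)
    z_target = {"alpha": z_alpha, "certainty": z_cert}

    qdata = {"subject_id": subject_ids}
    qtruth = {}
    for q in spec.questionnaires:
        qdata[q.name] = np.round(
            _copula_scores(q, z_target, rng, n), 6
        )
        qtruth[q.name] = {"mean": q.mean, "sd": q.sd,
                          "target": q.target, "target_rho": q.target_rho}
    truth["questionnaires"] = qtruth
    truth["certainty"] = cert.tolist()

    return StudyBundle(
        responses=responses,
        questionnaires=pd.DataFrame(qdata),
        truth=truth,
        schedule=schedule,
    )
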