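"""Learning-trajectory classification and its random-rater null.

Participants are split into *learners* and *non-learners* by the sign of
the Pearson correlation between their per-phase overall d' (all abnormal
categories pooled) and the training-phase index 1..9: a strictly positive
coefficient marks a learner.  Because a sign split of noisy trajectories
could in principle manufacture a spurious post-training advantage for the
"learner" subgroup, :func:`null_simulation` applies the identical split to
cohorts of raters whose every response is uniform random, and measures the
post-minus-pre d' change within each subgroup.  Both subgroup means sit at
zero (the paper-scale run is 1000 cohorts of 15 raters), confirming that
the split itself confers no advantage.

Also here: pre/post/retention difference tables (:func:`phase_deltas`) and
Spearman agreement between mean human ratings and external model scores
(:func:`score_agreement`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import sdt

N_TRAINING_PHASES = 9

#: Scored (non-attention) trial counts per phase of the default schedule:
#: test phases show 80 normal / 120 abnormal, each training phase
#: 288 normal / 432 abnormal (4 blocks of 72/108).
TEST_PHASE_COUNTS = (80, 120)
TRAINING_PHASE_COUNTS = (288, 432)


@dataclass
class LearnerClassification:
    """Sign-of-correlation learning label for one participant."""

    participant_id: str
    dprime_by_phase: tuple
    pearson_r: float
    label: str  # "learner" | "non_learner"


@dataclass
class NullSimulationResult:
    """Subgroup post-minus-pre d' statistics under uniform-random rating."""

    n_runs: int
    n_participants_per_run: int
    learner_mean_delta: float
    nonlearner_mean_delta: float
    learner_ci95_halfwidth: float
    nonlearner_ci95_halfwidth: float
    seed: object = None
    run_learner_deltas: list = field(default_factory=list)
    run_nonlearner_deltas: list = field(default_factory=list)


@dataclass
class AgreementResult:
    spearman_rho: float
    p_value: float
    n: int


def training_trajectory(summaries: pd.DataFrame, participant_id=None) -> np.ndarray:
    """Ordered per-phase overall d' (phases 1..9) for one participant.

    ``summaries`` is a :func:`mammogist.sdt.phase_summaries` table; the
    trajectory uses the ``all_abnormal`` category group (all abnormal image
    types pooled against the phase's normal trials).
    """
    sub = summaries
    if participant_id is not None:
        sub = sub[sub["participant_id"] == participant_id]
    sub = sub[(sub["phase_type"] == "training") & (sub["category_group"] == "all_abnormal")]
    if sub["participant_id"].nunique() > 1:
        raise ValueError("summaries span several participants; pass participant_id")
    present = set(sub["phase_index"])
    missing = [p for p in range(1, N_TRAINING_PHASES + 1) if p not in present]
    if missing:
        raise ValueError(f"missing training phase(s): {missing}")
    sub = sub.sort_values("phase_index")
    return sub["dprime"].to_numpy()


def classify_learner(trajectory, participant_id: str = "") -> LearnerClassification:
    """Label a 9-phase d' trajectory by the sign of its Pearson correlation
    with the phase index.

    A zero-variance trajectory has an undefined correlation; it is
    classified ``non_learner`` with r recorded as 0, since a learner
    requires a strictly positive coefficient.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.shape != (N_TRAINING_PHASES,):
        raise ValueError(f"expected {N_TRAINING_PHASES} d' values, got shape {traj.shape}")
    if not np.all(np.isfinite(traj)):
        raise ValueError("trajectory contains non-finite values")
    phases = np.arange(1, N_TRAINING_PHASES + 1, dtype=float)
    if np.ptp(traj) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(phases, traj)[0, 1])
    label = "learner" if r > 0 else "non_learner"
    return LearnerClassification(participant_id, tuple(traj), r, label)


def classify_participants(summaries: pd.DataFrame) -> pd.DataFrame:
    """Classify every participant in a summary table; one row each."""
    rows = []
    for pid in summaries["participant_id"].unique():
        cls = classify_learner(training_trajectory(summaries, pid), pid)
        rows.append(
            {
                "participant_id": pid,
                "pearson_r": cls.pearson_r,
                "label": cls.label,
                **{f"dprime_phase_{i+1}": v for i, v in enumerate(cls.dprime_by_phase)},
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Random-rater null simulation
# --------------------------------------------------------------------------

def _uniform_phase_dprime(
    rng, n_runs, n_participants, n_normal, n_abnormal, threshold, integer_ratings,
    correction,
):
    """Per-(run, participant) d' for one phase of uniform-random rating."""
    shape = (n_runs, n_participants)
    if integer_ratings:
        # rating ~ uniform integer on 0..100; decision: rating > threshold
        p = (100 - threshold) / 101.0
    else:
        p = (100.0 - threshold) / 100.0
    n_hit = rng.binomial(n_abnormal, p, size=shape)
    n_fa = rng.binomial(n_normal, p, size=shape)
    return sdt.dprime_from_counts(n_hit, n_abnormal, n_fa, n_normal, correction)


def null_simulation(
    n_runs: int = 1000,
    n_participants: int = 15,
    seed=None,
    *,
    threshold: int = sdt.DEFAULT_THRESHOLD,
    integer_ratings: bool = True,
    correction: str = "loglinear",
    test_counts=TEST_PHASE_COUNTS,
    training_counts=TRAINING_PHASE_COUNTS,
    n_training_phases: int = N_TRAINING_PHASES,
) -> NullSimulationResult:
    """Learner/non-learner post-minus-pre d' under uniform-random rating.

    Each of ``n_runs`` cohorts contains ``n_participants`` simulated raters
    whose every rating is uniform random (integers 0-100 by default; a
    continuous-uniform alternative via ``integer_ratings=False``).  Each
    rater completes a pre-test, ``n_training_phases`` training phases and a
    post-test with the schedule's scored trial counts; per-phase d' is the
    thresholded, correction-adjusted signal-detection estimate.  Within
    each run, raters are split by the sign of the Pearson correlation
    between training d' and phase index, and the subgroup means of
    (post - pre) d' recorded.  Runs where a subgroup is empty contribute
    nothing to that subgroup.  95% CIs are mean +/- 1.96 SD/sqrt(runs).

    A rating drawn uniformly carries no information, so both subgroup
    means converge to 0: the sign split alone cannot manufacture a
    learning effect.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    rng = np.random.default_rng(seed)
    n_n_test, n_a_test = test_counts
    n_n_train, n_a_train = training_counts

    pre = _uniform_phase_dprime(
        rng, n_runs, n_participants, n_n_test, n_a_test, threshold,
        integer_ratings, correction,
    )
    training = np.empty((n_runs, n_participants, n_training_phases))
    for p in range(n_training_phases):
        training[:, :, p] = _uniform_phase_dprime(
            rng, n_runs, n_participants, n_n_train, n_a_train, threshold,
            integer_ratings, correction,
        )
    post = _uniform_phase_dprime(
        rng, n_runs, n_participants, n_n_test, n_a_test, threshold,
        integer_ratings, correction,
    )

    phases = np.arange(1, n_training_phases + 1, dtype=float)
    xc = phases - phases.mean()
    centred = training - training.mean(axis=2, keepdims=True)
    num = centred @ xc
    den = np.sqrt((centred ** 2).sum(axis=2) * (xc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    delta = post - pre
    is_learner = r > 0

    def subgroup_stats(mask):
        counts = mask.sum(axis=1)
        sums = np.where(mask, delta, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore"):
            run_means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        valid = run_means[counts > 0]
        if valid.size == 0:
            return float("nan"), float("nan"), []
        mean = float(valid.mean())
        sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
        half = 1.96 * sd / np.sqrt(valid.size)
        return mean, float(half), run_means.tolist()

    l_mean, l_half, l_runs = subgroup_stats(is_learner)
    n_mean, n_half, n_runs_list = subgroup_stats(~is_learner)
    return NullSimulationResult(
        n_runs=n_runs,
        n_participants_per_run=n_participants,
        learner_mean_delta=l_mean,
        nonlearner_mean_delta=n_mean,
        learner_ci95_halfwidth=l_half,
        nonlearner_ci95_halfwidth=n_half,
        seed=seed,
        run_learner_deltas=l_runs,
        run_nonlearner_deltas=n_runs_list,
    )


# --------------------------------------------------------------------------
# Test-phase deltas and model agreement
# --------------------------------------------------------------------------

def phase_deltas(summaries: pd.DataFrame):
    """Pre/post/retention changes in d' and criterion.

    Returns ``(per_participant, group_stats)``: simple differences
    (post - pre, retention - pre) per participant x category group, and
    their group means with 95% CIs (mean +/- 1.96 SD/sqrt(n)).  Missing
    phases yield NaN differences flagged in a ``complete`` column.
    """
    test = summaries[summaries["phase_type"].isin(("pretest", "posttest", "retention"))]
    rows = []
    for (pid, group), sub in test.groupby(["participant_id", "category_group"], sort=False):
        vals = {}
        for metric in ("dprime", "criterion"):
            for phase in ("pretest", "posttest", "retention"):
                sel = sub.loc[sub["phase_type"] == phase, metric]
                vals[(metric, phase)] = float(sel.iloc[0]) if len(sel) else np.nan
        row = {"participant_id": pid, "category_group": group}
        for metric in ("dprime", "criterion"):
            row[f"{metric}_post_minus_pre"] = (
                vals[(metric, "posttest")] - vals[(metric, "pretest")]
            )
            row[f"{metric}_retention_minus_pre"] = (
                vals[(metric, "retention")] - vals[(metric, "pretest")]
            )
        row["complete"] = not any(
            np.isnan(v) for v in vals.values()
        )
        rows.append(row)
    per_participant = pd.DataFrame(rows)

    stat_rows = []
    delta_cols = [
        "dprime_post_minus_pre",
        "dprime_retention_minus_pre",
        "criterion_post_minus_pre",
        "criterion_retention_minus_pre",
    ]
    for group, sub in per_participant.groupby("category_group", sort=False):
        for col in delta_cols:
            vals = sub[col].dropna().to_numpy()
            if vals.size == 0:
                continue
            sd = vals.std(ddof=1) if vals.size > 1 else 0.0
            stat_rows.append(
                {
                    "category_group": group,
                    "measure": col,
                    "mean": float(vals.mean()),
                    "ci95_halfwidth": float(1.96 * sd / np.sqrt(vals.size)),
                    "n": int(vals.size),
                }
            )
    return per_participant, pd.DataFrame(stat_rows)


def score_agreement(human_scores, model_scores) -> AgreementResult:
    """Spearman rank agreement between mean human ratings and model scores.

    Both inputs map stimulus identifiers to scores (mappings or pandas
    Series indexed by stimulus id).  Identifiers must align exactly; any
    orphans on either side are reported in the error.  Requires n >= 3.
    """
    human = pd.Series(dict(human_scores) if not isinstance(human_scores, pd.Series) else human_scores)
    model = pd.Series(dict(model_scores) if not isinstance(model_scores, pd.Series) else model_scores)
    only_h = sorted(set(human.index) - set(model.index))
    only_m = sorted(set(model.index) - set(human.index))
    if only_h or only_m:
        raise ValueError(
            f"misaligned stimulus identifiers; human-only: {only_h}, model-only: {only_m}"
        )
    if len(human) < 3:
        raise ValueError("at least 3 aligned stimuli are required")
    model = model.reindex(human.index)
    rho, p = stats.spearmanr(human.to_numpy(), model.to_numpy())
    return AgreementResult(float(rho), float(p), int(len(human)))
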