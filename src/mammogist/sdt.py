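"""Equal-variance signal-detection metrics for 0-100 rating data.

Ratings are binarised at a fixed threshold (default 50, matching the task
instruction and feedback rule: a rating strictly above 50 is an "abnormal"
decision).  From the resulting hit and false-alarm proportions:

    d' = z(hit) - z(fa)          sensitivity, 0 = chance
    c  = -(z(hit) + z(fa)) / 2   response bias, negative = liberal

where z is the standard-normal quantile function.  Extreme proportions are
handled by the log-linear correction (k + 0.5) / (n + 1), applied to every
cell so that corrected and uncorrected cells remain comparable; a clamping
alternative (0 -> 1/2n, 1 -> 1 - 1/2n) is available via ``correction``.

:func:`phase_summaries` produces the per participant x phase x category
summary table that downstream learning analyses consume.  Abnormal
categories are grouped as obvious, subtle, global (contralateral and prior
pooled) and all_abnormal; the false-alarm rate within a phase is computed
once from that phase's normal trials and shared across groups, since only
one pool of normal trials exists per phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import roc as _roc
from .trial_data import ABNORMAL_CATEGORIES, validate_trials

DEFAULT_THRESHOLD = 50

#: Abnormal-category groupings analysed throughout.
CATEGORY_GROUPS = {
    "obvious": ("obvious",),
    "subtle": ("subtle",),
    "global": ("contralateral", "prior"),
    "all_abnormal": ABNORMAL_CATEGORIES,
}

SUMMARY_COLUMNS = [
    "participant_id",
    "phase_type",
    "phase_index",
    "category_group",
    "n_abnormal",
    "n_normal",
    "hit_rate",
    "fa_rate",
    "dprime",
    "criterion",
    "auc_empirical",
]


def binarize_rating(rating, threshold: int = DEFAULT_THRESHOLD):
    """Binary decision for a rating: "abnormal" iff rating > threshold."""
    if np.ndim(rating) == 0:
        return "abnormal" if rating > threshold else "normal"
    return np.where(np.asarray(rating) > threshold, "abnormal", "normal")


@dataclass
class RateEstimate:
    """Hit and false-alarm proportions for one grouping of trials."""

    hit_rate: float
    fa_rate: float
    n_abnormal: int
    n_normal: int
    correction_applied: bool


def corrected_rate(k, n, correction: str = "loglinear"):
    """Proportion k/n mapped into the open interval (0, 1).

    ``"loglinear"`` returns (k + 0.5) / (n + 1) for every cell;
    ``"clamp"`` returns k/n with 0 and 1 replaced by 1/(2n) and
    1 - 1/(2n).  Works elementwise on arrays.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("grouping contains no trials of one class")
    if correction == "loglinear":
        return (k + 0.5) / (n + 1.0)
    if correction == "clamp":
        p = k / n
        p = np.where(p == 0.0, 1.0 / (2 * n), p)
        p = np.where(p == 1.0, 1.0 - 1.0 / (2 * n), p)
        return p
    raise ValueError(f"unknown correction {correction!r}")


def rates_from_counts(
    n_hit: int,
    n_abnormal: int,
    n_fa: int,
    n_normal: int,
    correction: str = "loglinear",
) -> RateEstimate:
    if n_abnormal < 1 or n_normal < 1:
        raise ValueError("both an abnormal and a normal class are required")
    extreme = n_hit in (0, n_abnormal) or n_fa in (0, n_normal)
    hit = float(corrected_rate(n_hit, n_abnormal, correction))
    fa = float(corrected_rate(n_fa, n_normal, correction))
    # loglinear touches every cell; clamp only extreme ones
    applied = True if correction == "loglinear" else extreme
    return RateEstimate(hit, fa, int(n_abnormal), int(n_normal), applied)


def rate_estimate(
    trials: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    correction: str = "loglinear",
) -> RateEstimate:
    """Hit/false-alarm rates for one grouping of trials.

    The grouping must contain at least one abnormal-ground-truth and one
    normal-ground-truth trial; otherwise a ``ValueError`` names the
    missing class.
    """
    truth = trials["ground_truth"].to_numpy()
    rating = trials["rating"].to_numpy()
    abnormal = truth == "abnormal"
    n_a, n_n = int(abnormal.sum()), int((~abnormal).sum())
    if n_a == 0 or n_n == 0:
        missing = "abnormal" if n_a == 0 else "normal"
        raise ValueError(f"grouping contains no {missing}-ground-truth trials")
    decision = rating > threshold
    return rates_from_counts(
        int(decision[abnormal].sum()), n_a, int(decision[~abnormal].sum()), n_n,
        correction,
    )


def _interior(rates: RateEstimate) -> tuple:
    hit, fa = rates.hit_rate, rates.fa_rate
    if not (0.0 < hit < 1.0 and 0.0 < fa < 1.0):
        raise ValueError(
            "rates must be interior to (0, 1); apply an extreme-proportion "
            "correction upstream"
        )
    return hit, fa


def dprime(rates: RateEstimate) -> float:
    """Sensitivity d' = z(hit) - z(fa); 0 means chance."""
    hit, fa = _interior(rates)
    return float(norm.ppf(hit) - norm.ppf(fa))


def criterion(rates: RateEstimate) -> float:
    """Response bias c = -(z(hit) + z(fa)) / 2; negative = liberal."""
    hit, fa = _interior(rates)
    return float(-(norm.ppf(hit) + norm.ppf(fa)) / 2.0)


def dprime_from_counts(n_hit, n_abnormal, n_fa, n_normal, correction="loglinear"):
    """Vectorised d' from decision counts (used by large simulations)."""
    hit = corrected_rate(n_hit, n_abnormal, correction)
    fa = corrected_rate(n_fa, n_normal, correction)
    return norm.ppf(hit) - norm.ppf(fa)


def phase_summaries(
    trials: pd.DataFrame,
    threshold: int = DEFAULT_THRESHOLD,
    correction: str = "loglinear",
    category_groups=None,
) -> pd.DataFrame:
    """Per participant x phase x category-group summary table.

    Only mammogram trials enter (attention and practice trials are
    excluded).  Within each phase the false-alarm rate comes from that
    phase's normal trials and is shared by all category groups.  The
    empirical AUC is the sliding-threshold ROC area of the group's
    abnormal ratings against the phase's normal ratings.
    """
    validate_trials(trials)
    groups = dict(CATEGORY_GROUPS) if category_groups is None else {
        k: CATEGORY_GROUPS[k] for k in category_groups
    }
    mam = trials[trials["trial_kind"] == "mammogram"]
    rows = []
    for (pid, phase_type, phase_index), sub in mam.groupby(
        ["participant_id", "phase_type", "phase_index"], sort=False
    ):
        normal_ratings = sub.loc[sub["ground_truth"] == "normal", "rating"].to_numpy()
        n_n = normal_ratings.size
        if n_n == 0:
            raise ValueError(
                f"participant {pid!r}, phase {phase_type}/{phase_index}: "
                "no normal-ground-truth trials"
            )
        n_fa = int((normal_ratings > threshold).sum())
        for group, cats in groups.items():
            ab = sub.loc[
                sub["category"].isin(cats) & (sub["ground_truth"] == "abnormal"),
                "rating",
            ].to_numpy()
            if ab.size == 0:
                raise ValueError(
                    f"participant {pid!r}, phase {phase_type}/{phase_index}, "
                    f"group {group!r}: no abnormal trials"
                )
            rates = rates_from_counts(
                int((ab > threshold).sum()), ab.size, n_fa, n_n, correction
            )
            rows.append(
                {
                    "participant_id": pid,
                    "phase_type": phase_type,
                    "phase_index": int(phase_index),
                    "category_group": group,
                    "n_abnormal": rates.n_abnormal,
                    "n_normal": rates.n_normal,
                    "hit_rate": rates.hit_rate,
                    "fa_rate": rates.fa_rate,
                    "dprime": dprime(rates),
                    "criterion": criterion(rates),
                    "auc_empirical": _roc.empirical_roc(normal_ratings, ab).auc,
                }
            )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
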