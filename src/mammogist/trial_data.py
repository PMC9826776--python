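"""Trial-level data model, I/O and filters for rating-scale gist experiments.

The unit of observation is a single trial: one participant views one
stimulus (a unilateral mammogram or an attention-check scene photograph)
and responds on a 0-100 confidence scale, where 0 means "certainly normal"
and 100 "certainly abnormal".  A full experiment is a flat table of such
trials spanning a pre-training test, nine feedback training phases, a
post-training test and a delayed retention test.

This module defines the table schema, validates it, reads and writes it as
delimited text, and implements the two data-quality filters applied before
any analysis:

* participant exclusion based on attention-check misses and degenerate
  (all-50) rating behaviour, and
* per-session timing summaries with a single-pass mean +/- 3 SD outlier
  exclusion.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Schema
# --------------------------------------------------------------------------

PHASE_TYPES = ("pretest", "training", "posttest", "retention")
TEST_PHASES = ("pretest", "posttest", "retention")
TRIAL_KINDS = ("mammogram", "attention", "practice")
CATEGORIES = (
    "normal",
    "obvious",
    "subtle",
    "contralateral",
    "prior",
    "scene_beach",
    "scene_forest",
)
ABNORMAL_CATEGORIES = ("obvious", "subtle", "contralateral", "prior")
GROUND_TRUTHS = ("normal", "abnormal")

#: Attention scenes map onto the normal/abnormal bookkeeping sides: the
#: instruction is "rate beaches as 0 and forests as 100".
SCENE_GROUND_TRUTH = {"scene_beach": "normal", "scene_forest": "abnormal"}

COLUMNS = [
    "participant_id",
    "session_index",
    "phase_type",
    "phase_index",
    "block_index",
    "trial_index",
    "trial_kind",
    "category",
    "ground_truth",
    "rating",
    "viewing_time_ms",
    "rating_time_ms",
    "max_viewing_time_ms",
    "feedback_given",
]

_INT_COLUMNS = ("session_index", "phase_index", "block_index", "trial_index", "rating")
_FLOAT_COLUMNS = ("viewing_time_ms", "rating_time_ms", "max_viewing_time_ms")


class SchemaError(ValueError):
    """The table is structurally malformed (missing/unparseable columns)."""


class ValidationError(ValueError):
    """A row violates a trial-record invariant."""


class ScheduleError(ValueError):
    """The experimental schedule implied by the table is malformed."""


@dataclass(frozen=True)
class TrialRecord:
    """One experimental trial (a single row of the trial table)."""

    participant_id: str
    session_index: int
    phase_type: str
    phase_index: int
    block_index: int
    trial_index: int
    trial_kind: str
    category: str
    ground_truth: str
    rating: int
    viewing_time_ms: float
    rating_time_ms: float
    max_viewing_time_ms: float
    feedback_given: bool


def _fail_row(idx, message: str) -> None:
    raise ValidationError(f"row {idx}: {message}")


def validate_trials(trials: pd.DataFrame) -> None:
    """Validate a trial table against the record invariants.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        naming the first offending row, if any row-level invariant fails.
    """
    missing = [c for c in COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    if len(trials) == 0:
        return

    def check(mask: pd.Series, message: str) -> None:
        bad = np.flatnonzero(np.asarray(mask))
        if bad.size:
            _fail_row(trials.index[bad[0]], message)

    rating = trials["rating"]
    check((rating < 0) | (rating > 100), "rating outside [0, 100]")
    check(~trials["phase_type"].isin(PHASE_TYPES), "unknown phase_type")
    check(~trials["trial_kind"].isin(TRIAL_KINDS), "unknown trial_kind")
    check(~trials["category"].isin(CATEGORIES), "unknown category")
    check(~trials["ground_truth"].isin(GROUND_TRUTHS), "unknown ground_truth")
    check(
        trials["viewing_time_ms"] > trials["max_viewing_time_ms"],
        "viewing_time_ms exceeds max_viewing_time_ms",
    )
    scene = trials["category"].isin(SCENE_GROUND_TRUTH)
    attention = trials["trial_kind"] == "attention"
    check(scene != attention, "scene categories and attention trial_kind must coincide")
    training = trials["phase_type"] == "training"
    check(training & ~trials["feedback_given"], "training trials must carry feedback")
    practice = trials["trial_kind"] == "practice"
    check(
        ~training & trials["feedback_given"] & ~practice,
        "test-phase trials carry no feedback except practice trials",
    )


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "True": True, "False": False,
}


def read_trials(path, sep: str = ",") -> pd.DataFrame:
    """Read and validate a delimited trial table.

    Parameters
    ----------
    path
        Path to a delimited text file with a header row naming all
        required columns (see :data:`COLUMNS`).
    sep
        Field delimiter; ``","`` (default) or ``"\\t"``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    out = pd.DataFrame(index=df.index)
    out["participant_id"] = df["participant_id"]
    for col in _INT_COLUMNS:
        try:
            out[col] = pd.to_numeric(df[col]).astype(int)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not integer-valued: {exc}") from None
    for col in _FLOAT_COLUMNS:
        try:
            out[col] = pd.to_numeric(df[col]).astype(float)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"column {col!r} is not numeric: {exc}") from None
    for col in ("phase_type", "trial_kind", "category", "ground_truth"):
        out[col] = df[col]
    fb = df["feedback_given"].map(_BOOL_MAP)
    if fb.isna().any():
        bad = df.index[fb.isna()][0]
        _fail_row(bad, "feedback_given is not a boolean")
    out["feedback_given"] = fb.astype(bool)
    out = out[COLUMNS]
    validate_trials(out)
    return out


def write_trials(trials: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a validated trial table as delimited text (UTF-8, header row)."""
    validate_trials(trials)
    trials[COLUMNS].to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Participant exclusion
# --------------------------------------------------------------------------

RULE_ATTENTION_TOTAL = "rule1_attention_total"
RULE_ATTENTION_SESSION = "rule2_attention_session"
RULE_FIFTY_RATINGS = "rule3_fifty_ratings"


@dataclass
class ExclusionReport:
    """Outcome of the pre-registered exclusion rules for one participant."""

    participant_id: str
    total_attention_missed: int
    max_attention_missed_one_session: int
    sessions_with_ge85pct_50_ratings: int
    excluded: bool
    reasons: list = field(default_factory=list)


def attention_missed(trials: pd.DataFrame) -> pd.Series:
    """Boolean mask over attention trials: decision on the wrong side of 50.

    A beach must be rated 50 or below, a forest above 50, mirroring the
    feedback rule applied to mammograms.
    """
    att = trials[trials["trial_kind"] == "attention"]
    beach = att["category"] == "scene_beach"
    return np.where(beach, att["rating"] > 50, att["rating"] <= 50)


def apply_exclusion_criteria(
    trials: pd.DataFrame,
    *,
    max_total_misses: int = 30,
    max_session_misses: int = 6,
    fifty_fraction: float = 0.85,
) -> list:
    """Apply the three participant-exclusion rules to a trial table.

    A participant is excluded for (1) missing more than ``max_total_misses``
    attention trials in total across the training phases, (2) missing more
    than ``max_session_misses`` in any one training session, or (3) rating
    ``fifty_fraction`` (default 85%) or more of the mammogram trials as
    exactly 50 in any testing session, or in more than one training session.

    Returns one :class:`ExclusionReport` per participant, in order of first
    appearance.  Raises :class:`ScheduleError` if a participant has a
    training session with no attention trials at all.
    """
    validate_trials(trials)
    reports = []
    for pid, sub in trials.groupby("participant_id", sort=False):
        training = sub[sub["phase_type"] == "training"]
        att = training[training["trial_kind"] == "attention"]
        train_phases = sorted(training["phase_index"].unique())
        for p in train_phases:
            if (att["phase_index"] == p).sum() == 0:
                raise ScheduleError(
                    f"participant {pid!r}: training session {p} has no attention trials"
                )
        missed = pd.Series(attention_missed(training), index=att.index)
        total_missed = int(missed.sum())
        by_session = missed.groupby(att["phase_index"]).sum()
        max_one_session = int(by_session.max()) if len(by_session) else 0

        mam = sub[sub["trial_kind"] == "mammogram"]
        fifty_sessions = 0
        test_flag = False
        for phase in TEST_PHASES:
            block = mam[mam["phase_type"] == phase]
            if len(block) and (block["rating"] == 50).mean() >= fifty_fraction:
                fifty_sessions += 1
                test_flag = True
        train_fifty = 0
        for p in train_phases:
            block = mam[(mam["phase_type"] == "training") & (mam["phase_index"] == p)]
            if len(block) and (block["rating"] == 50).mean() >= fifty_fraction:
                train_fifty += 1
        fifty_sessions += train_fifty

        reasons = []
        if total_missed > max_total_misses:
            reasons.append(RULE_ATTENTION_TOTAL)
        if max_one_session > max_session_misses:
            reasons.append(RULE_ATTENTION_SESSION)
        if test_flag or train_fifty > 1:
            reasons.append(RULE_FIFTY_RATINGS)
        reports.append(
            ExclusionReport(
                participant_id=pid,
                total_attention_missed=total_missed,
                max_attention_missed_one_session=max_one_session,
                sessions_with_ge85pct_50_ratings=fifty_sessions,
                excluded=bool(reasons),
                reasons=reasons,
            )
        )
    return reports


def exclusion_frame(reports) -> pd.DataFrame:
    """Exclusion reports as a flat table (reasons joined with ``;``)."""
    rows = []
    for r in reports:
        d = asdict(r)
        d["reasons"] = ";".join(d["reasons"])
        rows.append(d)
    return pd.DataFrame(rows)


def exclusion_json(reports) -> str:
    return json.dumps([asdict(r) for r in reports], indent=2)


# --------------------------------------------------------------------------
# Timing summaries
# --------------------------------------------------------------------------

SCREENS = ("mammogram", "rating", "feedback")


@dataclass
class TimingSummary:
    """Mean/median duration of one screen in one participant-session.

    Durations outside mean +/- 3 SD of the individual session are excluded
    in a single pass before averaging.  ``empty`` flags sessions where the
    screen produced no timing data (e.g. the feedback screen of a test
    phase), in which case the counts are zero and the statistics NaN.
    """

    participant_id: str
    session_index: int
    screen: str
    mean_ms: float
    median_ms: float
    n_excluded_outliers: int
    n_used: int
    empty: bool


def _screen_values(sub: pd.DataFrame, screen: str) -> np.ndarray:
    mam = sub[sub["trial_kind"] == "mammogram"]
    if screen == "mammogram":
        # free-viewing exposure exists only in training phases; test
        # exposures are fixed-duration and carry no information
        return mam.loc[mam["phase_type"] == "training", "viewing_time_ms"].to_numpy()
    if screen == "rating":
        return mam["rating_time_ms"].to_numpy()
    if screen == "feedback":
        if "feedback_time_ms" not in sub.columns:
            return np.empty(0)
        vals = sub.loc[sub["feedback_given"], "feedback_time_ms"]
        return pd.to_numeric(vals, errors="coerce").dropna().to_numpy()
    raise ValueError(f"unknown screen {screen!r}")


def timing_summaries(trials: pd.DataFrame, screens=SCREENS) -> list:
    """Per participant x session x screen timing summaries.

    The outlier pass is performed once: mean and SD are computed from all
    values in the participant-session, then values outside mean +/- 3 SD
    are dropped and the mean/median recomputed over the remainder.
    """
    validate_trials(trials)
    out = []
    for (pid, session), sub in trials.groupby(
        ["participant_id", "session_index"], sort=False
    ):
        for screen in screens:
            vals = _screen_values(sub, screen)
            if vals.size == 0:
                out.append(
                    TimingSummary(pid, int(session), screen,
                                  float("nan"), float("nan"), 0, 0, True)
                )
                continue
            mu, sd = vals.mean(), vals.std(ddof=0)
            keep = np.abs(vals - mu) <= 3 * sd if sd > 0 else np.ones(vals.size, bool)
            kept = vals[keep]
            out.append(
                TimingSummary(
                    pid, int(session), screen,
                    float(kept.mean()), float(np.median(kept)),
                    int(vals.size - kept.size), int(kept.size), False,
                )
            )
    return out


def timing_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([asdict(s) for s in summaries])
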