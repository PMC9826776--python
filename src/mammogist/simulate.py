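"""Synthetic gist-training experiments: pools, schedules, observers.

Generates complete experiments with the structure of the multi-session
mammography rating study — a 200-trial fixed test set shown at pre-test,
post-test and retention, nine training phases of four 184-trial blocks
(180 mammograms in a 72/27/27/54 normal/obvious/subtle/global mix plus 4
attention-check scenes, one per block quarter), trial-by-trial feedback in
training, and an adaptive maximum-viewing-time staircase — rated by
parametric observers, so that every analysis stage can be exercised
without human or image data.

Observers are either *random* (every rating uniform on 0-100) or
equal-variance signal-detection raters: on each trial a latent evidence
value x is drawn from N(0, 1) for normal stimuli or N(d_cat, 1) for
abnormal ones, where d_cat is the category's effective sensitivity
(baseline plus a per-completed-phase learning increment, clamped at 0),
and the rating is round(100 * Phi((x - c) / spread)) for a bias cutoff c
with its own per-phase drift.  Thresholding such ratings at 50 reproduces
the observer's generative hit/false-alarm structure, so sensitivity and
bias estimated downstream recover the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import sdt
from .trial_data import (
    ABNORMAL_CATEGORIES,
    COLUMNS,
    SCENE_GROUND_TRUTH,
    validate_trials,
)

# --------------------------------------------------------------------------
# Stimulus pools
# --------------------------------------------------------------------------

TRAINING_POOL_DEFAULTS = {
    "normal": 1558,
    "obvious": 1019,
    "subtle": 899,
    "contralateral": 1868,
    "prior": 324,
}
TEST_SET_DEFAULTS = {
    "normal": 80,
    "obvious": 30,
    "subtle": 30,
    "contralateral": 30,
    "prior": 30,
}


@dataclass
class StimulusPoolConfig:
    """Per-category stimulus counts for the training pool and test set."""

    training_counts: dict = field(default_factory=lambda: dict(TRAINING_POOL_DEFAULTS))
    test_counts: dict = field(default_factory=lambda: dict(TEST_SET_DEFAULTS))


@dataclass
class Pools:
    training: dict  # category -> ndarray of stimulus ids
    test: dict

    @property
    def training_size(self) -> int:
        return sum(len(v) for v in self.training.values())

    @property
    def test_size(self) -> int:
        return sum(len(v) for v in self.test.values())

    def test_abnormal_fraction(self) -> float:
        ab = sum(len(v) for c, v in self.test.items() if c in ABNORMAL_CATEGORIES)
        return ab / self.test_size


def build_pools(config: StimulusPoolConfig | None = None, seed=None) -> Pools:
    """Build training and test stimulus pools with unique identifiers.

    Test-set identifiers are disjoint from the training pool: the fixed
    test images are never shown during training.  ``seed`` is accepted for
    interface uniformity; identifier construction is deterministic.
    """
    config = config or StimulusPoolConfig()
    training = {
        cat: np.array([f"train_{cat}_{i:05d}" for i in range(n)])
        for cat, n in config.training_counts.items()
    }
    test = {
        cat: np.array([f"test_{cat}_{i:03d}" for i in range(n)])
        for cat, n in config.test_counts.items()
    }
    all_ids = np.concatenate(
        [v for v in training.values() if v.size]
        + [v for v in test.values() if v.size]
    )
    if len(np.unique(all_ids)) != all_ids.size:
        raise ValueError("stimulus identifiers overlap across pools")
    return Pools(training, test)


# --------------------------------------------------------------------------
# Schedule and staircase
# --------------------------------------------------------------------------

@dataclass
class ScheduleConfig:
    """Session structure of the experiment.

    Defaults reproduce the study schedule: 9 training phases of 4 blocks;
    each block shows 72 normal, 27 obvious, 27 subtle and 54 global
    abnormal mammograms plus 4 attention scenes (one per quarter); test
    phases show 3 practice trials then the fixed 200-stimulus test set at
    a fixed 500 ms exposure.  Maximum viewing time starts at 2500 ms and
    adapts per block: above a block d' of 0.2 it drops to 90% of the
    block's mean actual viewing time, below 0.05 it grows by 5%, capped
    at 2500 ms and floored at the 500 ms minimum exposure.
    """

    n_training_phases: int = 9
    blocks_per_phase: int = 4
    block_normals: int = 72
    block_obvious: int = 27
    block_subtle: int = 27
    block_global: int = 54
    attention_per_block: int = 4
    n_practice: int = 3
    start_max_ms: float = 2500.0
    floor_ms: float = 500.0
    ceiling_ms: float = 2500.0
    min_viewing_ms: float = 500.0
    test_exposure_ms: float = 500.0
    staircase_decrease_above: float = 0.2
    staircase_increase_below: float = 0.05
    decrease_factor: float = 0.9
    increase_factor: float = 1.05
    threshold: int = sdt.DEFAULT_THRESHOLD
    include_retention: bool = True

    @property
    def block_mammograms(self) -> int:
        return self.block_normals + self.block_obvious + self.block_subtle + self.block_global

    @property
    def block_total(self) -> int:
        return self.block_mammograms + self.attention_per_block


@dataclass
class StaircaseState:
    """Current maximum viewing time of the adaptive staircase."""

    max_viewing_ms: float = 2500.0
    floor_ms: float = 500.0
    ceiling_ms: float = 2500.0

    def __post_init__(self):
        if not self.floor_ms <= self.max_viewing_ms <= self.ceiling_ms:
            raise ValueError("max_viewing_ms outside [floor_ms, ceiling_ms]")


def staircase_update(
    state: StaircaseState,
    block_dprime: float,
    mean_actual_viewing_ms: float,
    *,
    decrease_above: float = 0.2,
    increase_below: float = 0.05,
    decrease_factor: float = 0.9,
    increase_factor: float = 1.05,
) -> StaircaseState:
    """One staircase step from a completed block.

    Block d' above ``decrease_above`` shortens the window to
    ``decrease_factor`` x the block's mean actual viewing time; below
    ``increase_below`` it lengthens it to ``increase_factor`` x the
    current maximum.  In the dead zone between the two bounds the window
    is unchanged.  The result is clamped to [floor, ceiling].
    """
    if block_dprime > decrease_above:
        new = decrease_factor * mean_actual_viewing_ms
    elif block_dprime < increase_below:
        new = increase_factor * state.max_viewing_ms
    else:
        new = state.max_viewing_ms
    new = min(max(new, state.floor_ms), state.ceiling_ms)
    return replace(state, max_viewing_ms=new)


# --------------------------------------------------------------------------
# Observers
# --------------------------------------------------------------------------

@dataclass
class ObserverModel:
    """Generative parameters of one simulated participant.

    ``d0`` maps abnormal categories to baseline sensitivity and
    ``delta_d`` to the per-completed-training-phase increment; effective
    sensitivity is clamped at 0.  ``c0``/``delta_c`` place and drift the
    bias cutoff on the evidence axis (negative drift = growing liberal
    tendency).  ``retention_decay`` is the fraction of the accumulated
    training change (in both sensitivity and bias) lost by the delayed
    retention test.  ``attention_miss_rate`` makes the observer fail
    attention checks at that rate, for exercising the exclusion rules.
    A ``random`` observer ignores every field and rates uniformly.
    """

    kind: str = "sdt"  # "sdt" | "random"
    d0: dict = field(default_factory=lambda: {c: 0.0 for c in ABNORMAL_CATEGORIES})
    delta_d: dict = field(default_factory=lambda: {c: 0.0 for c in ABNORMAL_CATEGORIES})
    c0: float = 0.0
    delta_c: float = 0.0
    spread: float = 1.0
    retention_decay: float = 0.0
    attention_miss_rate: float = 0.0
    label: str = ""

    def __post_init__(self):
        if self.kind not in ("sdt", "random"):
            raise ValueError(f"unknown observer kind {self.kind!r}")
        if self.spread <= 0:
            raise ValueError("spread must be positive")
        if not 0.0 <= self.retention_decay <= 1.0:
            raise ValueError("retention_decay must lie in [0, 1]")


@dataclass
class PhaseContext:
    """Where in the experiment a rating is made: how many training phases
    the observer has completed, and whether this is the retention test."""

    n_completed_phases: int = 0
    retention: bool = False


def random_observer(label: str = "random") -> ObserverModel:
    return ObserverModel(kind="random", label=label)


def sdt_observer(
    d0=None, delta_d=None, c0=0.0, delta_c=0.0, spread=1.0,
    retention_decay=0.0, attention_miss_rate=0.0, label="sdt",
) -> ObserverModel:
    """Equal-variance SDT observer; scalar d0/delta_d broadcast across
    abnormal categories."""
    def as_map(x, default):
        if x is None:
            return {c: default for c in ABNORMAL_CATEGORIES}
        if isinstance(x, dict):
            return {c: float(x.get(c, default)) for c in ABNORMAL_CATEGORIES}
        return {c: float(x) for c in ABNORMAL_CATEGORIES}

    return ObserverModel(
        kind="sdt", d0=as_map(d0, 0.0), delta_d=as_map(delta_d, 0.0),
        c0=c0, delta_c=delta_c, spread=spread,
        retention_decay=retention_decay,
        attention_miss_rate=attention_miss_rate, label=label,
    )


#: Baseline per-category sensitivity used by the cohort presets: obvious
#: lesions easiest, subtle harder, global (contralateral/prior) signals
#: weakest — the ordering the task is built around.
COHORT_BASELINE_D0 = {
    "obvious": 0.6,
    "subtle": 0.35,
    "contralateral": 0.2,
    "prior": 0.2,
}


def learner_observer(gain_per_phase: float = 0.022, label: str = "learner") -> ObserverModel:
    """Observer whose sensitivity grows each training phase (total gain
    ~0.2 d' over nine phases) and whose bias drifts liberal, with
    two-thirds of both changes lost by retention."""
    return sdt_observer(
        d0=dict(COHORT_BASELINE_D0),
        delta_d=gain_per_phase,
        c0=0.4, delta_c=-0.035, retention_decay=0.67, label=label,
    )


def static_observer(label: str = "static") -> ObserverModel:
    """Observer with the same baseline sensitivity and no learning."""
    return sdt_observer(d0=dict(COHORT_BASELINE_D0), c0=0.4, label=label)


def _effective_params(observer: ObserverModel, ctx: PhaseContext):
    n = ctx.n_completed_phases
    retain = 1.0 - observer.retention_decay if ctx.retention else 1.0
    d_eff = {
        cat: max(0.0, observer.d0[cat] + retain * observer.delta_d[cat] * n)
        for cat in ABNORMAL_CATEGORIES
    }
    c_eff = observer.c0 + retain * observer.delta_c * n
    return d_eff, c_eff


def _mammogram_ratings(observer, categories, ctx, rng) -> np.ndarray:
    categories = np.asarray(categories)
    if observer.kind == "random":
        return rng.integers(0, 101, size=categories.size)
    d_eff, c_eff = _effective_params(observer, ctx)
    mu = np.zeros(categories.size)
    for cat, d in d_eff.items():
        mu[categories == cat] = d
    x = rng.normal(mu, 1.0)
    ratings = np.rint(100.0 * ndtr((x - c_eff) / observer.spread))
    return np.clip(ratings, 0, 100).astype(int)


def _attention_ratings(observer, scene_categories, rng) -> np.ndarray:
    """Ratings for attention scenes: the correct side of 50 (beach low,
    forest high) unless the observer misses at its configured rate."""
    scenes = np.asarray(scene_categories)
    is_forest = scenes == "scene_forest"
    miss = rng.random(scenes.size) < (
        observer.attention_miss_rate if observer.kind == "sdt" else 0.0
    )
    high_side = is_forest ^ miss
    low = rng.integers(0, 51, size=scenes.size)
    high = rng.integers(51, 101, size=scenes.size)
    return np.where(high_side, high, low).astype(int)


def simulate_observer_rating(
    observer: ObserverModel, category: str, ctx: PhaseContext, rng
) -> int:
    """Single-trial rating (0-100) for one stimulus category."""
    if category in SCENE_GROUND_TRUTH:
        return int(_attention_ratings(observer, [category], rng)[0])
    return int(_mammogram_ratings(observer, [category], ctx, rng)[0])


# --------------------------------------------------------------------------
# Block sampling
# --------------------------------------------------------------------------

def _draw(pool: np.ndarray, k: int, cat: str, rng) -> np.ndarray:
    if k > pool.size:
        raise ValueError(
            f"pool exhausted: need {k} distinct {cat!r} stimuli, pool has {pool.size}"
        )
    return rng.choice(pool, size=k, replace=False)


def sample_training_block(pools: Pools, rng, schedule: ScheduleConfig | None = None):
    """One training block: ordered categories, stimulus ids, attention mask.

    Mammograms are drawn without replacement within the block (repeats may
    occur across blocks, never within one); the 54 global slots split
    between contralateral and prior in proportion to their pool sizes.
    One attention scene is placed uniformly at random within each quarter
    of the block.
    """
    schedule = schedule or ScheduleConfig()
    n_contra_pool = pools.training["contralateral"].size
    n_prior_pool = pools.training["prior"].size
    if n_contra_pool + n_prior_pool == 0:
        raise ValueError("pool exhausted: no global-category stimuli available")
    w = n_contra_pool / (n_contra_pool + n_prior_pool)
    n_contra = int(rng.binomial(schedule.block_global, w))
    n_contra = min(max(n_contra, schedule.block_global - n_prior_pool), n_contra_pool)
    counts = {
        "normal": schedule.block_normals,
        "obvious": schedule.block_obvious,
        "subtle": schedule.block_subtle,
        "contralateral": n_contra,
        "prior": schedule.block_global - n_contra,
    }
    cats, ids = [], []
    for cat, k in counts.items():
        drawn = _draw(pools.training[cat], k, cat, rng)
        cats.extend([cat] * k)
        ids.extend(drawn)
    order = rng.permutation(len(cats))
    mam_cats = np.asarray(cats, dtype=object)[order]
    mam_ids = np.asarray(ids, dtype=object)[order]

    total = schedule.block_total
    quarter = total // schedule.attention_per_block
    att_pos = np.array(
        [q * quarter + rng.integers(0, quarter) for q in range(schedule.attention_per_block)]
    )
    att_cats = rng.choice(["scene_beach", "scene_forest"], size=att_pos.size)

    categories = np.empty(total, dtype=object)
    stimulus_ids = np.empty(total, dtype=object)
    is_attention = np.zeros(total, dtype=bool)
    is_attention[att_pos] = True
    categories[att_pos] = att_cats
    stimulus_ids[att_pos] = [f"attention_{c[6:]}_{i}" for i, c in enumerate(att_cats)]
    categories[~is_attention] = mam_cats
    stimulus_ids[~is_attention] = mam_ids
    return categories, stimulus_ids, is_attention


# --------------------------------------------------------------------------
# Full experiment
# --------------------------------------------------------------------------

def _rating_times(rng, n) -> np.ndarray:
    # self-paced rating screen: right-skewed around ~1.5 s
    return rng.lognormal(np.log(1500.0), 0.4, size=n)


class _RowSink:
    def __init__(self):
        self.chunks = {c: [] for c in COLUMNS}

    def add(self, n, **cols):
        for c in COLUMNS:
            v = cols[c]
            self.chunks[c].append(
                np.full(n, v) if np.ndim(v) == 0 else np.asarray(v)
            )

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {c: np.concatenate(self.chunks[c]) for c in COLUMNS}
        )


def _test_phase_rows(
    sink, pid, observer, pools, schedule, ctx, rng, phase_type, session_index
):
    # 3 practice trials from the training pool, with feedback
    all_train = np.concatenate([v for v in pools.training.values() if v.size])
    practice_ids = rng.choice(all_train, size=schedule.n_practice, replace=False)
    practice_cats = np.array(
        [s.split("_")[1] for s in practice_ids], dtype=object
    )
    practice_truth = np.where(
        np.isin(practice_cats, ABNORMAL_CATEGORIES), "abnormal", "normal"
    )
    practice_ratings = _mammogram_ratings(observer, practice_cats, ctx, rng)

    test_cats = np.concatenate(
        [np.full(len(v), c, dtype=object) for c, v in pools.test.items()]
    )
    order = rng.permutation(test_cats.size)
    test_cats = test_cats[order]
    test_truth = np.where(np.isin(test_cats, ABNORMAL_CATEGORIES), "abnormal", "normal")
    test_ratings = _mammogram_ratings(observer, test_cats, ctx, rng)

    n_p, n_t = schedule.n_practice, test_cats.size
    sink.add(
        n_p,
        participant_id=pid, session_index=session_index, phase_type=phase_type,
        phase_index=0, block_index=0, trial_index=np.arange(1, n_p + 1),
        trial_kind="practice", category=practice_cats, ground_truth=practice_truth,
        rating=practice_ratings,
        viewing_time_ms=schedule.test_exposure_ms,
        rating_time_ms=_rating_times(rng, n_p),
        max_viewing_time_ms=schedule.test_exposure_ms,
        feedback_given=True,
    )
    sink.add(
        n_t,
        participant_id=pid, session_index=session_index, phase_type=phase_type,
        phase_index=0, block_index=0, trial_index=np.arange(n_p + 1, n_p + n_t + 1),
        trial_kind="mammogram", category=test_cats, ground_truth=test_truth,
        rating=test_ratings,
        viewing_time_ms=schedule.test_exposure_ms,
        rating_time_ms=_rating_times(rng, n_t),
        max_viewing_time_ms=schedule.test_exposure_ms,
        feedback_given=False,
    )


def simulate_experiment(
    observers,
    pools: Pools | None = None,
    schedule: ScheduleConfig | None = None,
    seed=None,
    participant_ids=None,
) -> pd.DataFrame:
    """Simulate the full experiment for a roster of observers.

    Each observer completes: pre-test (3 practice + 200 test trials),
    nine 736-trial training phases with feedback and the viewing-time
    staircase (state carried across blocks and phases, starting at
    2500 ms), a post-test, and a retention test.  The same fixed test set
    is reused across the three test phases, in fresh random order.
    Returns a validated trial table; fully reproducible from ``seed``.
    """
    pools = pools or build_pools()
    schedule = schedule or ScheduleConfig()
    observers = list(observers)
    if participant_ids is None:
        participant_ids = [f"P{i + 1:02d}" for i in range(len(observers))]
    sink = _RowSink()
    streams = np.random.SeedSequence(seed).spawn(len(observers))
    for pid, observer, stream in zip(participant_ids, observers, streams):
        rng = np.random.default_rng(stream)
        _test_phase_rows(
            sink, pid, observer, pools, schedule, PhaseContext(0), rng,
            "pretest", session_index=1,
        )
        state = StaircaseState(
            schedule.start_max_ms, schedule.floor_ms, schedule.ceiling_ms
        )
        for phase in range(1, schedule.n_training_phases + 1):
            ctx = PhaseContext(phase - 1)
            for block in range(1, schedule.blocks_per_phase + 1):
                cats, ids, is_att = sample_training_block(pools, rng, schedule)
                n = cats.size
                ratings = np.empty(n, dtype=int)
                ratings[~is_att] = _mammogram_ratings(observer, cats[~is_att], ctx, rng)
                ratings[is_att] = _attention_ratings(observer, cats[is_att], rng)
                truth = np.where(
                    np.isin(cats, ABNORMAL_CATEGORIES) | (cats == "scene_forest"),
                    "abnormal", "normal",
                )
                viewing = rng.uniform(schedule.min_viewing_ms, state.max_viewing_ms, n)
                kinds = np.where(is_att, "attention", "mammogram")
                sink.add(
                    n,
                    participant_id=pid, session_index=phase, phase_type="training",
                    phase_index=phase, block_index=block,
                    trial_index=np.arange(1, n + 1),
                    trial_kind=kinds, category=cats, ground_truth=truth,
                    rating=ratings, viewing_time_ms=viewing,
                    rating_time_ms=_rating_times(rng, n),
                    max_viewing_time_ms=state.max_viewing_ms,
                    feedback_given=True,
                )
                mam = ~is_att
                abnormal = np.isin(cats[mam], ABNORMAL_CATEGORIES)
                decisions = ratings[mam] > schedule.threshold
                block_d = float(
                    sdt.dprime_from_counts(
                        int(decisions[abnormal].sum()), int(abnormal.sum()),
                        int(decisions[~abnormal].sum()), int((~abnormal).sum()),
                    )
                )
                state = staircase_update(
                    state, block_d, float(viewing[mam].mean()),
                    decrease_above=schedule.staircase_decrease_above,
                    increase_below=schedule.staircase_increase_below,
                    decrease_factor=schedule.decrease_factor,
                    increase_factor=schedule.increase_factor,
                )
        n_phases = schedule.n_training_phases
        _test_phase_rows(
            sink, pid, observer, pools, schedule, PhaseContext(n_phases), rng,
            "posttest", session_index=n_phases,
        )
        if schedule.include_retention:
            _test_phase_rows(
                sink, pid, observer, pools, schedule,
                PhaseContext(n_phases, retention=True), rng,
                "retention", session_index=n_phases + 1,
            )
    trials = sink.frame()
    trials["rating"] = trials["rating"].astype(int)
    for col in ("session_index", "phase_index", "block_index", "trial_index"):
        trials[col] = trials[col].astype(int)
    trials["feedback_given"] = trials["feedback_given"].astype(bool)
    validate_trials(trials)
    return trials
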