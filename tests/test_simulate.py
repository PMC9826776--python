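"""Synthetic-experiment generator: pools, blocks, staircase, observers."""

import collections

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import chisquare

from mammogist import (
    StaircaseState,
    StimulusPoolConfig,
    apply_exclusion_criteria,
    build_pools,
    phase_summaries,
    sample_training_block,
    sdt_observer,
    simulate_experiment,
    simulate_observer_rating,
    staircase_update,
    static_observer,
    validate_trials,
)
from mammogist.simulate import PhaseContext, _mammogram_ratings, random_observer


class TestPools:
    def test_default_pool_and_test_set_sizes(self):
        pools = build_pools()
        assert pools.training_size == 5668
        assert pools.test_size == 200
        assert pools.test_abnormal_fraction() == pytest.approx(0.6)

    def test_identifiers_unique_and_disjoint(self):
        pools = build_pools()
        train = np.concatenate(list(pools.training.values()))
        test = np.concatenate(list(pools.test.values()))
        assert len(set(train)) == len(train)
        assert set(train).isdisjoint(test)

    def test_minimal_pools_fail_at_block_sampling(self, rng):
        pools = build_pools(
            StimulusPoolConfig(
                training_counts={c: 1 for c in ("normal", "obvious", "subtle",
                                                "contralateral", "prior")}
            )
        )
        with pytest.raises(ValueError, match="exhausted"):
            sample_training_block(pools, rng)


class TestTrainingBlock:
    def test_category_histogram_and_attention_count(self, rng):
        pools = build_pools()
        cats, ids, att = sample_training_block(pools, rng)
        assert cats.size == 184 and att.sum() == 4
        counts = collections.Counter(cats[~att])
        assert counts["normal"] == 72
        assert counts["obvious"] == 27 and counts["subtle"] == 27
        assert counts["contralateral"] + counts["prior"] == 54

    def test_one_attention_trial_per_quarter(self, rng):
        pools = build_pools()
        for _ in range(20):
            _, _, att = sample_training_block(pools, rng)
            pos = np.flatnonzero(att)
            assert (pos // 46 == np.arange(4)).all()

    def test_no_stimulus_repeats_within_block(self, rng):
        pools = build_pools()
        for _ in range(200):
            _, ids, att = sample_training_block(pools, rng)
            mam = ids[~att]
            assert len(set(mam)) == mam.size

    def test_different_seeds_change_order_not_counts(self):
        pools = build_pools()
        c1, _, a1 = sample_training_block(pools, np.random.default_rng(1))
        c2, _, a2 = sample_training_block(pools, np.random.default_rng(2))
        assert collections.Counter(c1[~a1].tolist())["normal"] == \
               collections.Counter(c2[~a2].tolist())["normal"] == 72


class TestStaircase:
    def test_good_block_shortens_to_90pct_of_mean_viewing(self):
        state = staircase_update(StaircaseState(2500), 0.3, 1000.0)
        assert state.max_viewing_ms == pytest.approx(900.0)

    def test_poor_block_grows_5pct_capped_at_ceiling(self):
        assert staircase_update(StaircaseState(2500), 0.04, 2500.0).max_viewing_ms == 2500.0
        assert staircase_update(StaircaseState(2000), 0.04, 1500.0).max_viewing_ms == pytest.approx(2100.0)

    def test_dead_zone_leaves_state_unchanged(self):
        assert staircase_update(StaircaseState(1800), 0.10, 900.0).max_viewing_ms == 1800.0

    def test_decrease_floored_at_minimum_exposure(self):
        assert staircase_update(StaircaseState(600), 0.5, 510.0).max_viewing_ms == 500.0

    @given(
        st.lists(
            st.tuples(st.floats(-1, 3), st.floats(0, 1)), min_size=1, max_size=50
        )
    )
    def test_state_always_within_bounds(self, history):
        state = StaircaseState(2500)
        for block_d, frac in history:
            viewing = state.floor_ms + frac * (state.max_viewing_ms - state.floor_ms)
            state = staircase_update(state, block_d, viewing)
            assert 500.0 <= state.max_viewing_ms <= 2500.0


class TestObservers:
    def test_random_observer_ratings_are_uniform(self):
        rng = np.random.default_rng(5)
        obs = random_observer()
        ratings = _mammogram_ratings(obs, np.array(["normal"] * 100_000), PhaseContext(0), rng)
        counts = np.bincount(ratings, minlength=101)
        _, p = chisquare(counts)
        assert p > 0.001

    def test_null_observer_is_category_blind(self):
        rng = np.random.default_rng(6)
        obs = sdt_observer(d0=0.0)
        a = _mammogram_ratings(obs, np.array(["obvious"] * 5000), PhaseContext(0), rng)
        b = _mammogram_ratings(obs, np.array(["normal"] * 5000), PhaseContext(0), rng)
        from scipy.stats import mannwhitneyu

        _, p = mannwhitneyu(a, b)
        assert p > 0.001

    def test_single_trial_interface(self, rng):
        obs = sdt_observer(d0=1.0)
        r = simulate_observer_rating(obs, "obvious", PhaseContext(0), rng)
        assert 0 <= r <= 100
        r_att = simulate_observer_rating(obs, "scene_beach", PhaseContext(0), rng)
        assert r_att <= 50  # attentive observer answers correctly

    def test_generative_dprime_round_trip(self):
        # d'(obvious)=1.0, c=0 at n=5000/class recovered within +/-0.1
        rng = np.random.default_rng(17)
        obs = sdt_observer(d0={"obvious": 1.0}, c0=0.0)
        from mammogist.sdt import dprime, rates_from_counts

        a = _mammogram_ratings(obs, np.array(["obvious"] * 5000), PhaseContext(0), rng)
        n = _mammogram_ratings(obs, np.array(["normal"] * 5000), PhaseContext(0), rng)
        rates = rates_from_counts(int((a > 50).sum()), 5000, int((n > 50).sum()), 5000)
        assert dprime(rates) == pytest.approx(1.0, abs=0.1)


class TestFullExperiment:
    def test_row_counts_per_participant(self, small_cohort_trials):
        per = small_cohort_trials.groupby("participant_id").size()
        assert (per == 203 + 9 * 736 + 203 + 203).all()

    def test_phase_category_mix(self, small_cohort_trials):
        one = small_cohort_trials[
            (small_cohort_trials["participant_id"] == "P01")
            & (small_cohort_trials["phase_type"] == "training")
            & (small_cohort_trials["phase_index"] == 3)
        ]
        mam = one[one["trial_kind"] == "mammogram"]
        counts = mam["category"].value_counts()
        assert counts["normal"] == 288
        assert counts["obvious"] == 108 and counts["subtle"] == 108
        assert counts.get("contralateral", 0) + counts.get("prior", 0) == 216
        assert (one["trial_kind"] == "attention").sum() == 16

    def test_table_passes_validation_and_exclusions(self, small_cohort_trials):
        validate_trials(small_cohort_trials)
        reports = apply_exclusion_criteria(small_cohort_trials)
        assert not any(r.excluded for r in reports)

    def test_same_seed_is_bit_identical(self):
        a = simulate_experiment([static_observer()], seed=3)
        b = simulate_experiment([static_observer()], seed=3)
        assert a.equals(b)

    def test_test_set_reused_across_test_phases(self, small_cohort_trials):
        mam = small_cohort_trials[
            (small_cohort_trials["participant_id"] == "P01")
            & (small_cohort_trials["trial_kind"] == "mammogram")
        ]
        sets = {
            phase: tuple(sorted(mam.loc[mam["phase_type"] == phase, "category"]))
            for phase in ("pretest", "posttest", "retention")
        }
        assert sets["pretest"] == sets["posttest"] == sets["retention"]

    def test_staircase_window_shrinks_for_competent_observer(self, small_cohort_trials):
        p1 = small_cohort_trials[
            (small_cohort_trials["participant_id"] == "P01")
            & (small_cohort_trials["phase_type"] == "training")
        ]
        maxes = p1.groupby(["phase_index", "block_index"])["max_viewing_time_ms"].first()
        assert maxes.iloc[0] == 2500.0
        assert maxes.iloc[-1] < 1000.0
        assert (maxes >= 500.0).all() and (maxes <= 2500.0).all()

    def test_inattentive_observer_is_flagged_by_rule_one(self):
        from mammogist.trial_data import attention_missed

        # at a 25% miss rate the expected miss count (36 of 144) sits above
        # the rule-1 threshold; the report must mirror the realised misses
        obs = static_observer()
        obs.attention_miss_rate = 0.25
        trials = simulate_experiment([obs], seed=21)
        (report,) = apply_exclusion_criteria(trials)
        realised = int(attention_missed(trials).sum())
        assert report.total_attention_missed == realised
        assert report.excluded == (realised > 30)
        # at a 50% miss rate the binomial tail leaves no doubt
        obs.attention_miss_rate = 0.5
        (report,) = apply_exclusion_criteria(simulate_experiment([obs], seed=22))
        assert report.excluded and report.total_attention_missed > 30

    def test_learning_increment_raises_late_phase_dprime(self):
        obs = sdt_observer(d0=0.3, delta_d=0.1)
        trials = simulate_experiment([obs], seed=9)
        summ = phase_summaries(trials)
        from mammogist import training_trajectory

        traj = training_trajectory(summ, "P01")
        assert np.polyfit(np.arange(1, 10), traj, 1)[0] > 0.05
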