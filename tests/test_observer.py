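"""Synthetic observers: parametric generative model and pair-search heuristic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from chasedot.design import build_design
from chasedot.exceptions import ConsistencyError, InvalidPairError
from chasedot.observer import (
    ASD_AGE,
    AGE_RANGE,
    GlmmParams,
    ObserverParams,
    ParticipantProfile,
    chase_statistics,
    heuristic_observer_response,
    response_probability,
    sample_cohort,
    simulate_study,
)
from chasedot.cues import eye_track
from chasedot.stimulus import TrialSpec, simulate_trial


class TestCohort:
    def test_cohort_sizes_and_groups(self):
        cohort = sample_cohort(24, GlmmParams(), np.random.default_rng(0))
        assert len(cohort) == 48
        assert sum(p.group for p in cohort) == 24

    def test_zero_sigma_gives_zero_intercepts(self):
        cohort = sample_cohort(5, GlmmParams(sigma_u=0.0), np.random.default_rng(0))
        assert all(p.random_intercept == 0.0 for p in cohort)

    def test_asd_age_mean_matches_truncated_normal(self):
        """Sampled ASD ages must match the truncated-normal mean oracle."""
        rng = np.random.default_rng(1)
        cohort = sample_cohort(5000, GlmmParams(), rng)
        ages = np.array([p.age for p in cohort if p.group == 1])
        mean, sd = ASD_AGE
        a = (AGE_RANGE[0] - mean) / sd
        b = (AGE_RANGE[1] - mean) / sd
        oracle = stats.truncnorm.mean(a, b, loc=mean, scale=sd)
        se = ages.std(ddof=1) / math.sqrt(len(ages))
        assert abs(ages.mean() - oracle) < 3 * se
        assert np.all((ages >= AGE_RANGE[0]) & (ages <= AGE_RANGE[1]))


class TestResponseProbability:
    def test_all_zero_model_gives_half(self):
        params = GlmmParams(beta_intercept=0, beta_group=0, beta_age=0,
                            beta_trialtype=0, beta_subtlety=0, beta_social=0,
                            beta_nonsocial=0, beta_group_x_subtlety=0, sigma_u=0)
        prof = ParticipantProfile(0, 0, 14.0, 0.0)
        trial = {"condition": "baseline", "subtlety": 45.0, "chase_present": True}
        assert response_probability(prof, trial, params) == pytest.approx(0.5)

    def test_default_model_td_age14_baseline_present_subtlety45(self):
        # eta = -1.13 + 0.17*14 + 0.23 - 0.05*45 = -0.77
        prof = ParticipantProfile(0, 0, 14.0, 0.0)
        trial = {"condition": "baseline", "subtlety": 45.0, "chase_present": True}
        p = response_probability(prof, trial, GlmmParams())
        assert p == pytest.approx(float(expit(-0.77)), abs=1e-12)
        assert p == pytest.approx(0.317, abs=5e-3)

    def test_group_contrast_positive_at_subtlety_75(self):
        # ASD − TD logit gap at 75 deg: −0.39 + 0.01·75 = +0.36
        params = GlmmParams()
        trial = {"condition": "baseline", "subtlety": 75.0, "chase_present": True}
        td = ParticipantProfile(0, 0, 14.0, 0.0)
        asd = ParticipantProfile(1, 1, 14.0, 0.0)
        p_td = response_probability(td, trial, params)
        p_asd = response_probability(asd, trial, params)
        assert p_asd > p_td


class TestSimulateStudy:
    def test_record_cardinality(self, small_study):
        design, cohort, responses, _ = small_study
        assert len(responses) == 16 * 225

    def test_correct_consistent_with_response(self, small_study):
        _, _, responses, _ = small_study
        derived = responses.response_present == responses.chase_present
        assert (responses.correct == derived).all()

    def test_cohort_design_mismatch_raises(self, small_study):
        design, cohort, _, params = small_study
        with pytest.raises(ConsistencyError):
            simulate_study(design, cohort[:-2], params, np.random.default_rng(0))

    def test_empirical_accuracy_matches_probability_in_fixed_cell(self):
        """Bernoulli faithfulness: cell means converge to the model p."""
        params = GlmmParams(sigma_u=0.0)
        rng = np.random.default_rng(3)
        design = build_design(2, rng=rng)
        prof = sample_cohort(1, params, np.random.default_rng(4))
        # many replicates of the same 2-participant design
        hits, total, expected = 0, 0, []
        for rep in range(80):
            resp = simulate_study(design, prof, params, np.random.default_rng(rep))
            cell = resp[(resp.condition == "baseline") & (resp.subtlety == 15.0)
                        & resp.chase_present]
            hits += int(cell.correct.sum())
            total += len(cell)
            if not expected:
                expected = [
                    response_probability(
                        p, {"condition": "baseline", "subtlety": 15.0,
                            "chase_present": True}, params)
                    for p in prof
                ]
        p_bar = float(np.mean(expected))
        ci = stats.binomtest(hits, total).proportion_ci(0.999)
        assert ci.low <= p_bar <= ci.high

    def test_accuracy_decreases_with_subtlety_over_replicates(self):
        params = GlmmParams()
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            design = build_design(12, rng=rng)
            cohort = sample_cohort(6, params, rng)
            resp = simulate_study(design, cohort, params, rng)
            acc = resp.groupby("subtlety").correct.mean()
            wins += int(acc[15.0] > acc[45.0] > acc[75.0])
        assert wins >= 19

    def test_social_beats_baseline_over_replicates(self):
        params = GlmmParams()
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            design = build_design(12, rng=rng)
            cohort = sample_cohort(6, params, rng)
            resp = simulate_study(design, cohort, params, rng)
            acc = resp.groupby("condition").correct.mean()
            wins += int(acc["social"] > acc["baseline"])
        assert wins >= 19


class TestChaseStatistics:
    def test_perfect_heat_seeking_on_static_sheep_gives_alignment_one(self):
        """A wolf marching straight at a static sheep scores exactly 1."""
        from chasedot.stimulus import SimConfig, Trajectory

        F = 100
        positions = np.zeros((F, 4, 2))
        positions[:, 0, 0] = 10.0  # sheep static due east
        positions[:, 3, 0] = -20.0 + 0.1 * np.arange(F)  # wolf closing, heading 0
        positions[:, 1, 1] = 8.0
        positions[:, 2, 1] = -8.0
        headings = np.zeros((F, 4))
        traj = Trajectory(
            positions=positions, headings=headings,
            roles=("sheep", "distractor", "distractor", "wolf"),
            update_log=np.zeros((F, 4), bool),
            override_log=np.zeros((F, 4), bool),
            reflect_log=np.zeros((F, 4), bool),
            spec=TrialSpec("baseline", 0.0, True, 0), config=SimConfig(),
        )
        scores = chase_statistics(traj, None, (3, 0))
        assert scores.heading_alignment == pytest.approx(1.0, abs=1e-12)
        assert scores.proximity > 0  # the pair is closing

    def test_independent_walkers_alignment_near_zero(self):
        vals = []
        for seed in range(300):
            traj = simulate_trial(TrialSpec("baseline", 45.0, False, seed))
            d1, d2 = [i for i, r in enumerate(traj.roles) if r == "distractor"][:2]
            vals.append(chase_statistics(traj, None, (d1, d2)).heading_alignment)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_alignment_higher_at_low_subtlety(self):
        """E[cos θ] = sin(s)/s at update events separates 15 from 75 deg."""
        def mean_alignment(subtlety, n=60):
            out = []
            for seed in range(n):
                traj = simulate_trial(TrialSpec("baseline", subtlety, True, seed))
                out.append(chase_statistics(
                    traj, None, (traj.wolf_index, traj.sheep_index)
                ).heading_alignment)
            return float(np.mean(out))

        a15, a75 = mean_alignment(15.0), mean_alignment(75.0)
        assert a15 > a75
        # closed-form gap at update instants, attenuated by sheep motion
        s15, s75 = math.radians(15), math.radians(75)
        gap_ceiling = math.sin(s15) / s15 - math.sin(s75) / s75
        assert 0.0 < a15 - a75 < gap_ceiling + 0.05

    def test_invisible_dot_in_pair_rejected(self, absent_trial):
        inv = absent_trial.roles.index("invisible_sheep")
        with pytest.raises(InvalidPairError):
            chase_statistics(absent_trial, None, (absent_trial.wolf_index, inv))


class TestHeuristicObserver:
    def test_infinite_criterion_always_absent(self, present_trial):
        params = ObserverParams(w_alignment=0, w_proximity=0, w_cue=0,
                                criterion=np.inf, noise_sd=0)
        rec = heuristic_observer_response(present_trial, None, params,
                                          np.random.default_rng(0))
        assert rec.response_present is False
        assert rec.correct is False  # the trial does contain a chase

    def test_alignment_observer_better_at_low_subtlety(self):
        """Noise-free alignment-only observer with a criterion calibrated at
        the pooled median score: accuracy at subtlety 15 beats subtlety 75."""
        params = ObserverParams(w_alignment=1.0, noise_sd=0.0)

        def best(traj):
            return max(
                chase_statistics(traj, None, (w, s)).combined(params)
                for w in traj.visible_indices
                for s in traj.visible_indices if w != s
            )

        scores = {}
        for sub in (15.0, 75.0):
            pres = [best(simulate_trial(TrialSpec("baseline", sub, True, 4000 + k)))
                    for k in range(100)]
            abst = [best(simulate_trial(TrialSpec("baseline", sub, False, 4200 + k)))
                    for k in range(100)]
            scores[sub] = (np.asarray(pres), np.asarray(abst))
        crit = float(np.median(np.concatenate(
            [v for pair in scores.values() for v in pair])))

        def accuracy(sub):
            p, a = scores[sub]
            return ((p > crit).mean() + (a <= crit).mean()) / 2.0

        assert accuracy(15.0) > accuracy(75.0)

    def test_gaze_cue_does_not_hurt_social_detection(self):
        """Adding the informative gaze statistic must not reduce accuracy."""
        rng = np.random.default_rng(1)
        base = ObserverParams(w_alignment=1.0, criterion=0.8, noise_sd=0.0)
        cued = ObserverParams(w_alignment=1.0, w_cue=1.0, criterion=1.75,
                              noise_sd=0.0)

        def accuracy(params, use_cue, n=20):
            ok = 0
            for seed in range(n):
                for present in (True, False):
                    traj = simulate_trial(
                        TrialSpec("social", 45.0, present, 2000 + seed))
                    cues = eye_track(traj) if use_cue else None
                    ok += heuristic_observer_response(traj, cues, params, rng).correct
            return ok / (2 * n)

        assert accuracy(cued, True) >= accuracy(base, False)

    def test_criterion_sweep_traces_monotone_roc(self):
        """Sweeping the criterion yields a valid ROC with area >= 0.5 at
        subtlety 15 for the true-pair alignment statistic."""
        scores_p, scores_a = [], []
        for seed in range(40):
            tp = simulate_trial(TrialSpec("baseline", 15.0, True, 3000 + seed))
            ta = simulate_trial(TrialSpec("baseline", 15.0, False, 3100 + seed))
            params = ObserverParams(w_alignment=1.0)
            for traj, acc in ((tp, scores_p), (ta, scores_a)):
                best = -np.inf
                for w in traj.visible_indices:
                    for s in traj.visible_indices:
                        if w != s:
                            best = max(best, chase_statistics(
                                traj, None, (w, s)).combined(params))
                acc.append(best)
        labels = np.r_[np.ones(len(scores_p)), np.zeros(len(scores_a))]
        scores = np.r_[scores_p, scores_a]
        auc = stats.mannwhitneyu(scores_p, scores_a, alternative="greater")
        u = auc.statistic / (len(scores_p) * len(scores_a))
        assert u >= 0.5
        # monotonicity of the swept ROC
        crits = np.quantile(scores, np.linspace(0, 1, 21))
        hit = [(np.asarray(scores_p) > c).mean() for c in crits]
        fa = [(np.asarray(scores_a) > c).mean() for c in crits]
        assert all(h1 >= h2 for h1, h2 in zip(hit, hit[1:]))
        assert all(f1 >= f2 for f1, f2 in zip(fa, fa[1:]))
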