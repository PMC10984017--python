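"""Generator ground truth, planted effects and determinism."""

import numpy as np
import pandas as pd
import pytest

import isoensemble as iso
from isoensemble.behavior import assign_ranks, percent_wins, segment_bouts
from isoensemble.synth import (
    CohortConfig,
    gen_calcium_population,
    gen_cohort,
    gen_identity_map,
    gen_lick_stream,
    gen_pose_session,
    gen_tournament,
)


class TestTournament:
    def test_infinite_skill_spread_orders_wins_by_rank(self):
        rec = gen_tournament(list("abcd"), skill_spread=np.inf, seed=0)
        pw = [percent_wins(rec, m) for m in "abcd"]
        assert pw == sorted(pw, reverse=True)
        assert pw[0] == 100.0 and pw[-1] == 0.0

    def test_zero_spread_is_fair_coin(self):
        # 2 mice, 5000 meetings/day x 1 day -> 10000 trials each
        rec = gen_tournament(["a", "b"], skill_spread=0.0, days=1,
                             meetings_per_day=5000, seed=1)
        pw = percent_wins(rec, "a")
        # 3-sigma binomial CI around 50%
        assert abs(pw - 50.0) < 300.0 * np.sqrt(0.25 / 10000)

    def test_every_pair_meets_each_day(self):
        rec = gen_tournament(list("abc"), days=3, seed=2)
        for day in (1, 2, 3):
            sub = rec.trials[rec.trials["day"] == day]
            pairs = {frozenset((a, b)) for a, b in zip(sub["mouse_a"], sub["mouse_b"])}
            assert pairs == {frozenset(p) for p in (("a", "b"), ("a", "c"), ("b", "c"))}

    def test_same_seed_identical(self):
        r1 = gen_tournament(list("abcd"), seed=9)
        r2 = gen_tournament(list("abcd"), seed=9)
        assert r1.trials.equals(r2.trials)

    def test_guards(self):
        with pytest.raises(ValueError):
            gen_tournament(["a"])
        with pytest.raises(ValueError):
            gen_tournament(["a", "b"], days=0)


class TestLickStream:
    def test_zero_rate_empty(self):
        s, gt = gen_lick_stream(600.0, 0.0, 10.0, seed=0)
        assert s.n_licks == 0 and len(gt) == 0

    def test_forced_five_bouts_of_ten(self):
        s, gt = gen_lick_stream(600.0, 0.5, 10.0, min_bout_licks=10,
                                ili_jitter=0.0, n_bouts=5, seed=1)
        assert s.n_licks == 50
        assert list(gt["n_licks"]) == [10] * 5

    def test_ground_truth_matches_segmentation(self):
        for seed in range(10):
            s, gt = gen_lick_stream(600.0, 2.0, 12.0, seed=seed)
            b = segment_bouts(s, ili_threshold_s=1.0, min_licks=3)
            assert list(b.bouts["n_licks"]) == list(gt["n_licks"])
            assert np.allclose(b.bouts["start_s"], gt["start_s"])

    def test_bout_count_poisson_mean(self):
        lam = 600.0 * 2.0 / 60.0  # 20 expected bouts
        counts = [len(gen_lick_stream(600.0, 2.0, 8.0, seed=s)[1])
                  for s in range(100)]
        # mean of 100 Poisson(20) draws, 3-sigma band
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 100)

    def test_gap_floor_respected(self):
        s, gt = gen_lick_stream(600.0, 2.0, 10.0, gap_floor_s=2.0, seed=3)
        gaps = gt["start_s"].to_numpy()[1:] - gt["end_s"].to_numpy()[:-1]
        assert (gaps >= 2.0).all()

    def test_infeasible_parameterization_rejected(self):
        with pytest.raises(ValueError):
            gen_lick_stream(10.0, 60.0, 50.0, n_bouts=40, seed=0)
        with pytest.raises(ValueError):
            gen_lick_stream(600.0, 1.0, 10.0, within_bout_ili_s=1.5,
                            gap_floor_s=2.0)

    def test_same_seed_identical(self):
        s1, g1 = gen_lick_stream(600.0, 2.0, 10.0, seed=5)
        s2, g2 = gen_lick_stream(600.0, 2.0, 10.0, seed=5)
        assert (s1.lick_times_s == s2.lick_times_s).all()
        assert g1.equals(g2)


class TestPoseSession:
    def test_no_episodes_zero_interaction(self):
        session, gt = gen_pose_session(30.0, 30.0, [], seed=0)
        ev = iso.pose.detect_interaction(
            iso.pose.head_body_distance(session),
            iso.pose.approach_angle(session), session.fps
        )
        assert iso.pose.interaction_time(ev) == 0.0 and len(gt) == 0

    def test_episode_frame_count_exact(self):
        _, gt = gen_pose_session(60.0, 30.0, [(20.0, 30.0)], seed=1)
        assert gt.loc[0, "end_frame"] - gt.loc[0, "start_frame"] == 300

    def test_rule_holds_inside_and_distance_violated_outside(self):
        session, gt = gen_pose_session(60.0, 30.0, [(10.0, 20.0)], seed=2)
        d = iso.pose.head_body_distance(session)
        a = iso.pose.approach_angle(session)
        f0, f1 = int(gt.loc[0, "start_frame"]), int(gt.loc[0, "end_frame"])
        assert (d[f0:f1] < 60.0).all() and (a[f0:f1] < 135.0).all()
        outside = np.ones(session.n_frames, bool)
        outside[f0:f1] = False
        assert (d[outside] > 60.0).all()

    def test_keypoints_inside_arena(self):
        session, _ = gen_pose_session(30.0, 30.0, [(5.0, 10.0)],
                                      arena_px=(400.0, 300.0), seed=3)
        for pts in (session.resident_head_xy, session.resident_body_xy,
                    session.intruder_body_xy):
            assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= 400).all()
            assert (pts[:, 1] >= 0).all() and (pts[:, 1] <= 300).all()

    def test_bad_episodes_rejected(self):
        with pytest.raises(ValueError):
            gen_pose_session(30.0, 30.0, [(5.0, 40.0)])
        with pytest.raises(ValueError):
            gen_pose_session(30.0, 30.0, [(5.0, 10.0), (8.0, 12.0)])

    def test_same_seed_identical(self):
        s1, _ = gen_pose_session(20.0, 30.0, [(5.0, 8.0)], seed=4)
        s2, _ = gen_pose_session(20.0, 30.0, [(5.0, 8.0)], seed=4)
        assert (s1.intruder_body_xy == s2.intruder_body_xy).all()


class TestCalcium:
    def test_noiseless_excited_amplitude_at_events(self):
        ev = np.array([10.0, 30.0])
        traces, ft, gt = gen_calcium_population(
            10, ev, duration_s=60.0, frac_excited=1.0, frac_inhibited=0.0,
            amplitude_z=3.0, noise_sd=0.0, fps=20.0, seed=0
        )
        idx = (ev * 20).astype(int)
        assert (traces[:, idx] >= 3.0 - 1e-9).all()

    def test_response_classes_partition_neurons(self):
        _, _, gt = gen_calcium_population(
            50, {"a": np.array([10.0]), "b": np.array([20.0])},
            duration_s=40.0, frac_excited=0.2, frac_inhibited=0.2, seed=1
        )
        per_class = gt.groupby("event_class")["response"].value_counts()
        for cls in ("a", "b"):
            assert per_class[cls].sum() == 50
            assert per_class[cls]["excited"] == 10
        # disjoint ensembles: no neuron responsive to both classes
        resp = gt[gt["response"] != "none"]
        assert not resp.duplicated("neuron_id").any()

    def test_fraction_guard(self):
        with pytest.raises(ValueError):
            gen_calcium_population(10, np.array([5.0]), duration_s=20.0,
                                   frac_excited=0.7, frac_inhibited=0.5)

    def test_same_seed_identical_traces(self):
        t1, _, _ = gen_calcium_population(5, np.array([5.0]), 20.0, seed=2)
        t2, _, _ = gen_calcium_population(5, np.array([5.0]), 20.0, seed=2)
        assert (t1 == t2).all()


class TestIdentityMap:
    def test_rate_one_all_span(self):
        m = gen_identity_map(4, 30, 1.0, seed=0)
        assert (m.groupby("global_id")["session"].nunique() == 4).all()

    def test_rate_zero_none_span(self):
        m = gen_identity_map(4, 30, 0.0, seed=1)
        assert (m.groupby("global_id")["session"].nunique() < 4).all()

    def test_per_session_quota_exact(self):
        m = gen_identity_map(3, 25, 0.4, seed=2)
        assert (m.groupby("session").size() == 25).all()
        assert not m.duplicated(["session", "local_id"]).any()

    def test_rate_out_of_range(self):
        with pytest.raises(ValueError):
            gen_identity_map(3, 10, 1.5)


class TestCohort:
    def test_true_ranks_recoverable_from_tournament(self):
        cohort = gen_cohort(CohortConfig(n_cages=2, seed=3))
        for cage, rec in cohort["tournaments"].items():
            ranks = assign_ranks(rec).set_index("mouse")["rank"]
            truth = cohort["mice"].query("cage == @cage").set_index("mouse")["rank"]
            assert (ranks.loc[truth.index] == truth).all()

    def test_every_stream_has_ground_truth(self):
        cohort = gen_cohort(CohortConfig(n_cages=1, seed=4))
        assert len(cohort["streams"]) == 4 * 2 * 2  # mice x conditions x spouts
        for (mouse, cond, spout), (stream, gt) in cohort["streams"].items():
            assert stream.mouse == mouse and stream.condition == cond
            assert int(gt["n_licks"].sum()) == stream.n_licks

    def test_planted_slope_sign_recovered_both_directions(self):
        for slope in (60.0, -60.0):
            signs = []
            for seed in range(10):
                cfg = CohortConfig(n_cages=4, rank_effect_alcohol=slope, seed=seed)
                cohort = gen_cohort(cfg)
                totals, ranks = [], []
                for (m, cond, spout), (s, _) in cohort["streams"].items():
                    if cond == "pre_SI" and spout == "alcohol":
                        totals.append(s.n_licks)
                        ranks.append(
                            int(cohort["mice"].set_index("mouse").loc[m, "rank"])
                        )
                signs.append(np.sign(np.corrcoef(ranks, totals)[0, 1]))
            assert (np.array(signs) == np.sign(slope)).mean() >= 0.9

    def test_analytic_licks_sd_close_to_empirical(self):
        cfg = CohortConfig()
        lam = cfg.bout_rate_per_min * cfg.session_s / 60.0
        totals = [
            gen_lick_stream(cfg.session_s, cfg.bout_rate_per_min,
                            cfg.expected_licks(1, False) / lam,
                            seed=s)[0].n_licks
            for s in range(150)
        ]
        assert np.std(totals) == pytest.approx(cfg.licks_sd(1, False), rel=0.25)
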