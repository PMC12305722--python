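"""Scan-search core: zigzag sweeps, station comparison rule, coarse-to-fine
refinement, oracle agreement, mode comparison, coverage."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gantryscan as gs

GEOM = gs.GantryGeometry()


class TestZigzag:
    def test_stated_order_for_s1_d1(self):
        assert gs.zigzag_indices(1, 1) == [
            (-1, -1), (-1, 0), (-1, 1), (0, 1), (0, 0), (0, -1),
            (1, -1), (1, 0), (1, 1),
        ]

    def test_d0_is_reverse_primary_traversal(self):
        order = gs.zigzag_indices(1, 0)
        assert [i for i, _ in order] == [1, 1, 1, 0, 0, 0, -1, -1, -1]
        assert order[0] == (1, -1)

    @pytest.mark.parametrize("s", [1, 2, 3])
    @pytest.mark.parametrize("d", [0, 1])
    def test_visits_each_lattice_point_exactly_once(self, s, d):
        order = gs.zigzag_indices(s, d)
        assert len(order) == (2 * s + 1) ** 2
        assert len(set(order)) == len(order)

    @pytest.mark.parametrize("s", [1, 2, 3])
    @pytest.mark.parametrize("d", [0, 1])
    def test_consecutive_poses_are_single_servo_steps(self, s, d):
        order = gs.zigzag_indices(s, d)
        for (i0, j0), (i1, j1) in zip(order, order[1:]):
            assert abs(i1 - i0) + abs(j1 - j0) == 1


def _mini_setup(score_fn=None):
    """Small phantom + config for fast search tests."""
    lesion = gs.LesionSpec.sphere((20.0, 20.0, 15.0), 12.0, -0.3)
    phantom = gs.build_phantom(extent=(40, 40, 30), lesions=[lesion], texture_seed=1)
    geom = gs.GantryGeometry(rail_length=40.0, image_width=40.0,
                             image_depth=30.0, lateral_center=20.0)
    config = gs.ScanConfig(slin0=8.0, nstep=5, x_start=4.0, s_theta=1,
                           alpha=2.0, epsilon=2.0, theta_max=10.0, phi_max=10.0)
    return phantom, geom, config


class ConstantScorer:
    def __init__(self, value=0.0):
        self.value = value

    def __call__(self, image):
        return gs.SliceScore(self.value, lesion_probabilities={})


class TestAngularSweep:
    def test_5x5_lattice_angles(self):
        phantom, geom, config = _mini_setup()
        config = dataclasses.replace(config, s_theta=2)
        trace = gs.angular_sweep(20.0, config, geom, phantom,
                                 gs.AnalyticScorer(), d=1)
        assert len(trace.visited) == 25
        pitches = {config.alpha * i for i, _ in trace.visited}
        assert pitches == {-4.0, -2.0, 0.0, 2.0, 4.0}

    def test_constant_scorer_tie_breaks_to_first_visited(self):
        phantom, geom, config = _mini_setup()
        trace = gs.angular_sweep(20.0, config, geom, phantom,
                                 ConstantScorer(0.0), d=1)
        assert trace.aprob == 0.0
        # first visited pose is (i, j) = (-1, -1) -> angles (-2, -2)
        assert (trace.theta_pos, trace.phi_pos) == (-2.0, -2.0)

    def test_aprob_is_max_of_scores(self):
        phantom, geom, config = _mini_setup()
        trace = gs.angular_sweep(20.0, config, geom, phantom,
                                 gs.AnalyticScorer(), d=0)
        assert trace.aprob == max(trace.scores)


class TestStationScan:
    def test_linear_preferred_when_lprob_higher(self):
        phantom, geom, config = _mini_setup()

        def scorer(image):
            untilted = image.pose.pitch == 0.0 and image.pose.roll == 0.0
            return gs.SliceScore(0.9 if untilted else 0.7, lesion_probabilities={})

        res = gs.station_scan(20.0, config, geom, phantom, scorer, station_index=0)
        assert res.lprob == 0.9
        # every genuinely tilted pose scores 0.7; the sweep's own (0, 0)
        # ties at 0.9 and the tie goes to the zero-angle pose
        tilted = [s for s, ij in zip(res.trace.scores, res.trace.visited)
                  if ij != (0, 0)]
        assert max(tilted) == 0.7
        assert res.best_pose == gs.ProbePose(x=20.0)
        assert res.best_score == res.lprob

    def test_exact_tie_goes_to_zero_angle_pose(self):
        phantom, geom, config = _mini_setup()
        res = gs.station_scan(20.0, config, geom, phantom,
                              ConstantScorer(0.3), station_index=0)
        assert res.best_pose == gs.ProbePose(x=20.0)

    def test_direction_alternates_with_station_index(self):
        phantom, geom, config = _mini_setup()
        scorer = gs.AnalyticScorer()
        r0 = gs.station_scan(20.0, config, geom, phantom, scorer, station_index=0)
        r1 = gs.station_scan(20.0, config, geom, phantom, scorer, station_index=1)
        assert r0.trace.d == 0 and r1.trace.d == 1

    def test_lesion_visible_only_at_tilt_wins_the_sweep(self):
        # lesion placed so the untilted plane at the station misses it but a
        # pitched plane reaches it; verify against exhaustive per-pose scoring
        lesion = gs.LesionSpec.sphere((26.0, 20.0, 22.0), 12.0, -0.3)
        phantom = gs.build_phantom(extent=(40, 40, 30), lesions=[lesion],
                                   texture_seed=2)
        geom = gs.GantryGeometry(rail_length=40.0, image_width=40.0,
                                 image_depth=30.0, lateral_center=20.0)
        config = gs.ScanConfig(slin0=8.0, nstep=5, x_start=4.0, s_theta=3,
                               alpha=2.0, epsilon=2.0, theta_max=10.0, phi_max=10.0)
        scorer = gs.AnalyticScorer()
        res = gs.station_scan(18.0, config, geom, phantom, scorer, station_index=0)
        assert res.lprob == 0.0
        assert res.best_score > 0.0
        assert res.best_pose.pitch != 0.0 or res.best_pose.roll != 0.0
        # exhaustive check over the station lattice
        lattice = [gs.ProbePose(x=18.0)] + [
            gs.ProbePose(x=18.0, pitch=2.0 * i, roll=2.0 * j)
            for (i, j) in gs.zigzag_indices(3, 1)
        ]
        _, best, _ = gs.brute_force_search(lattice, geom, phantom, scorer, config)
        assert res.best_score == best


class TestOptimalSliceSearch:
    def test_constant_zero_field_returns_first_pose(self):
        phantom, geom, config = _mini_setup()
        res = gs.optimal_slice_search(config, geom, phantom, ConstantScorer(0.0))
        assert res.Pmax == 0.0
        assert res.Lmax == res.evaluations[0].pose

    def test_refinement_step_sequence_32_to_1(self):
        phantom, geom, config = _mini_setup()
        geom = dataclasses.replace(geom, rail_length=160.0)
        config = dataclasses.replace(config, slin0=32.0, epsilon=1.0,
                                     nstep=5, x_start=4.0)
        res = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer())
        assert [r.step for r in res.rounds] == [32.0, 16.0, 8.0, 4.0, 2.0, 1.0]

    def test_agrees_exactly_with_oracle_on_visited_lattice(self):
        phantom, geom, config = _mini_setup()
        scorer = gs.AnalyticScorer()
        res = gs.optimal_slice_search(config, geom, phantom, scorer, seed=3)
        poses = [e.pose for e in res.evaluations]
        bp, bs, scores = gs.brute_force_search(poses, geom, phantom, scorer,
                                               config, seed=3)
        assert bp == res.Lmax
        assert bs == res.Pmax
        assert bs == max(scores)

    def test_best_of_round_non_decreasing(self):
        phantom, geom, config = _mini_setup()
        res = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer())
        bests = [r.best_score for r in res.rounds]
        assert np.all(np.diff(bests) >= 0)

    def test_evaluation_count_conservation(self):
        phantom, geom, config = _mini_setup()
        res = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer())
        per_station = 1 + (2 * config.s_theta + 1) ** 2
        expected = sum(len(r.stations) * per_station for r in res.rounds)
        assert res.n_evaluations == expected

    def test_deterministic_for_fixed_seed(self):
        phantom, geom, config = _mini_setup()
        a = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer(), seed=5)
        b = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer(), seed=5)
        assert a.Lmax == b.Lmax and a.Pmax == b.Pmax
        assert [e.probability for e in a.evaluations] == \
               [e.probability for e in b.evaluations]
        assert [e.pose for e in a.evaluations] == [e.pose for e in b.evaluations]

    def test_search_beats_exhaustive_enumeration_in_evaluations(self):
        phantom, geom, config = _mini_setup()
        geom = dataclasses.replace(geom, rail_length=160.0)
        config = dataclasses.replace(config, slin0=32.0, epsilon=1.0,
                                     nstep=5, x_start=4.0)
        res = gs.optimal_slice_search(config, geom, phantom, gs.AnalyticScorer())
        per_station = 1 + (2 * config.s_theta + 1) ** 2
        finest = (int(geom.rail_length / 1.0) + 1) * per_station
        assert res.n_evaluations < finest

    def test_invalid_config_rejected_before_scanning(self):
        phantom, geom, config = _mini_setup()
        bad = dataclasses.replace(config, epsilon=20.0)  # epsilon > slin0
        with pytest.raises(gs.ValidationError):
            gs.optimal_slice_search(bad, geom, phantom, gs.AnalyticScorer())

    @given(seed=st.integers(0, 10**6))
    @settings(deadline=None, max_examples=5)
    def test_oracle_upper_bounds_search_on_superlattice(self, seed):
        phantom, geom, config = _mini_setup()
        scorer = gs.AnalyticScorer()
        res = gs.optimal_slice_search(config, geom, phantom, scorer, seed=seed)
        # oracle over a strictly larger lattice can only do better
        lattice = [e.pose for e in res.evaluations] + [
            gs.ProbePose(x=x) for x in np.arange(0.0, 40.1, 1.0)
        ]
        _, best, _ = gs.brute_force_search(lattice, geom, phantom, scorer,
                                           config, seed=seed)
        assert best >= res.Pmax


class TestBruteForce:
    def test_single_pose_lattice(self):
        phantom, geom, config = _mini_setup()
        pose = gs.ProbePose(x=20.0)
        bp, bs, scores = gs.brute_force_search([pose], geom, phantom,
                                               gs.AnalyticScorer(), config)
        assert bp == pose and len(scores) == 1 and bs == scores[0]

    def test_empty_lattice_rejected(self):
        phantom, geom, config = _mini_setup()
        with pytest.raises(gs.ValidationError):
            gs.brute_force_search([], geom, phantom, gs.AnalyticScorer(), config)


class TestCompareLinearAngular:
    def test_off_axis_lesion_missed_by_linear_found_by_angular(self, two_tumor, scorer):
        config, phantom = two_tumor
        rep = gs.compare_linear_angular(config.scan, config.geometry, phantom,
                                        scorer, seed=config.seed)
        on_axis, off_axis = rep.lesions
        assert off_axis.linear_probability == 0.0
        assert not off_axis.detected_linear
        assert off_axis.angular_probability > rep.detection_threshold
        assert on_axis.linear_probability > rep.detection_threshold
        assert on_axis.detected_linear and on_axis.detected_angular
        # angular never does worse than linear on any lesion
        assert on_axis.angular_probability >= on_axis.linear_probability


class TestCoverage:
    def test_unscanned_region_stays_uncovered(self, small_phantom):
        geom = gs.GantryGeometry(rail_length=40.0, image_width=40.0,
                                 image_depth=30.0, lateral_center=20.0)
        hit, _, _ = gs.coverage_map([gs.ProbePose(x=5.0)], geom, small_phantom)
        # slab of half-thickness 1 mm around x = 5
        assert hit[4:7].any()
        assert not hit[:4].any()
        assert not hit[7:].any()

    def test_dense_linear_scan_fully_covers_centered_lesion(self, single_centered):
        config, phantom = single_centered
        geom = config.geometry
        # stations every slice_thickness mm across the lesion's x extent
        xs = np.arange(70.0, 90.0 + 1e-9, geom.slice_thickness)
        poses = [gs.ProbePose(x=x) for x in xs]
        _, tumor_frac, _ = gs.coverage_map(poses, geom, phantom)
        assert tumor_frac == 1.0

    def test_angular_schedule_covers_at_least_linear(self, two_tumor):
        config, phantom = two_tumor
        lin = gs.schedule_poses(config.scan, config.geometry, angular=False)
        ang = gs.schedule_poses(config.scan, config.geometry, angular=True)
        assert set(p.astuple() for p in lin) <= set(p.astuple() for p in ang)
        _, lt, ltot = gs.coverage_map(lin, config.geometry, phantom, voxel_stride=2)
        _, at, atot = gs.coverage_map(ang, config.geometry, phantom, voxel_stride=2)
        assert at >= lt
        assert atot >= ltot
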