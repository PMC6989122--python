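"""Kinematics, encounter detection/classification, small-cluster lifecycle."""
import numpy as np
import pytest

from flysocial.core import ArenaSpec, InputError, TrajectorySet
from flysocial.dynamics import (
    EncounterEvent,
    EncounterParams,
    SmallClusterEvent,
    classify_encounter_outcome,
    detect_encounters,
    kinematics,
    largest_component_series,
    net_outcome_difference,
    nucleus_stability_index,
    perievent_velocity,
    small_cluster_events,
    stage_summary,
)
from flysocial.synthetic import (
    SceneParams,
    ScriptedEncounter,
    gen_cluster_assembly,
    gen_group_trajectories,
)

BIG = ArenaSpec(radius=200.0)


def make_trajs(positions, frame_rate=50.0, body_length=2.5, arena=BIG):
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[1]
    return TrajectorySet(
        positions=pos,
        ids=list(range(n)),
        frame_rate=frame_rate,
        body_lengths=np.full(n, float(body_length)),
        arena=arena,
    )


class TestKinematics:
    def test_constant_velocity(self):
        t = np.arange(100)
        pos = np.stack([np.stack([t * 1.0, np.zeros(100)], axis=1)], axis=1)
        k = kinematics(make_trajs(pos), 0)
        assert np.allclose(k.speed[5:-5], 50.0)
        assert k.max_speed == pytest.approx(50.0, rel=1e-6)

    def test_stationary(self):
        pos = np.zeros((50, 1, 2))
        k = kinematics(make_trajs(pos), 0)
        assert np.all(k.speed == 0.0)
        assert k.max_accel == 0.0

    def test_constant_acceleration_ramp(self):
        """Speed ramp 0→20 mm/s over 2 s: finite differences recover the
        10 mm/s² analytic slope."""
        fps = 50.0
        t = np.arange(int(2 * fps) + 1) / fps
        x = 0.5 * 10.0 * t**2  # a = 10 mm/s^2
        pos = np.stack([np.stack([x, np.zeros_like(x)], axis=1)], axis=1)
        k = kinematics(make_trajs(pos, fps), 0)
        core = k.acceleration[5:-5]
        assert np.mean(core) == pytest.approx(10.0, rel=0.05)

    def test_too_short(self):
        with pytest.raises(InputError):
            kinematics(make_trajs(np.zeros((2, 1, 2))), 0)


class TestDetectEncounters:
    def test_hand_kinematics_onset(self):
        """A walks +x at 5 mm/s from (0,0) toward stationary B at (10,0):
        contact (1.5 BL = 3.75 mm) at t = 1.25 s."""
        fps = 50.0
        t = np.arange(int(4 * fps)) / fps
        ax = np.minimum(t * 5.0, 10.0 - 2.0)  # stop 2 mm short of B
        pos = np.stack(
            [
                np.stack([ax, np.zeros_like(ax)], axis=1),
                np.tile([10.0, 0.0], (len(t), 1)),
            ],
            axis=1,
        )
        events = detect_encounters(make_trajs(pos, fps))
        assert len(events) == 1
        ev = events[0]
        assert (ev.interactor_id, ev.interactee_id) == (0, 1)
        assert abs(ev.onset_frame - 1.25 * fps) <= 3

    def test_target_behind_no_event(self):
        """B directly behind walking A is outside the frontal 180° view."""
        fps = 50.0
        t = np.arange(int(4 * fps)) / fps
        ax = 3.0 + t * 5.0  # walking away from B at (0,0)
        pos = np.stack(
            [
                np.stack([ax, np.zeros_like(ax)], axis=1),
                np.tile([0.0, 0.0], (len(t), 1)),
            ],
            axis=1,
        )
        assert detect_encounters(make_trajs(pos, fps)) == []

    def test_matches_brute_force_predicate(self):
        """Vectorised detector equals an explicit per-frame loop over the
        same predicate on a scripted scene."""
        trajs, _ = gen_group_trajectories(
            SceneParams(n_flies=8, seed=5),
            [
                ScriptedEncounter(6.0, 0, 1, "move", "stay"),
                ScriptedEncounter(12.0, 2, 3, "stay", "move"),
            ],
        )
        p = EncounterParams()
        events = detect_encounters(trajs, p)

        from flysocial.dynamics import _qualifying_mask

        speed, vel, stationary = _qualifying_mask(trajs, p)
        brute = []
        n = trajs.n_flies
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                contact = 1.5 * 0.5 * (trajs.body_lengths[i] + trajs.body_lengths[j])
                run = None
                gap = int(round(p.merge_gap_s * trajs.frame_rate))
                runs = []
                for t in range(trajs.n_frames):
                    d = np.hypot(*(trajs.positions[t, j] - trajs.positions[t, i]))
                    ok = (
                        d <= contact
                        and speed[t, i] > p.stationary_speed
                        and stationary[t, j]
                        and float((trajs.positions[t, j] - trajs.positions[t, i]) @ vel[t, i]) >= 0.0
                    )
                    if ok:
                        if run is None:
                            run = [t, t]
                        elif t - run[1] <= max(1, gap):
                            run[1] = t
                        else:
                            runs.append(run)
                            run = [t, t]
                if run:
                    runs.append(run)
                for on, off in runs:
                    brute.append((i, j, on, off))
        got = [
            (e.interactor_id, e.interactee_id, e.onset_frame, e.offset_frame)
            for e in events
        ]
        assert sorted(got) == sorted(brute)

    def test_time_shift_invariance(self):
        trajs, _ = gen_group_trajectories(
            SceneParams(n_flies=4, seed=6), [ScriptedEncounter(6.0, 0, 1)]
        )
        ev1 = detect_encounters(trajs)
        shift = 100
        pos2 = np.concatenate(
            [np.repeat(trajs.positions[:1], shift, axis=0), trajs.positions], axis=0
        )
        trajs2 = TrajectorySet(
            positions=pos2,
            ids=trajs.ids,
            frame_rate=trajs.frame_rate,
            body_lengths=trajs.body_lengths,
            arena=trajs.arena,
        )
        ev2 = detect_encounters(trajs2)
        assert len(ev1) == len(ev2) == 1
        assert ev2[0].onset_frame - ev1[0].onset_frame == shift

    def test_missing_frames_rejected(self):
        pos = np.zeros((10, 2, 2))
        pos[3, 0] = np.nan
        with pytest.raises(InputError):
            detect_encounters(make_trajs(pos))


class TestOutcomes:
    def test_scripted_outcomes_recovered(self):
        outcomes = [("move", "stay"), ("stay", "move"), ("move", "move"), ("stay", "stay")]
        script = [
            ScriptedEncounter(6.0 + 8 * k, 2 * k, 2 * k + 1, a, b)
            for k, (a, b) in enumerate(outcomes)
        ]
        trajs, _ = gen_group_trajectories(SceneParams(n_flies=8, seed=7), script)
        events = detect_encounters(trajs)
        assert len(events) == 4
        got = {
            (e.interactor_id, e.interactee_id): classify_encounter_outcome(e, trajs)
            for e in events
        }
        for k, (a, b) in enumerate(outcomes):
            assert got[(2 * k, 2 * k + 1)] == (a, b)

    def test_undetermined_without_coverage(self):
        pos = np.zeros((100, 2, 2))
        pos[:, 1, 0] = 3.0
        trajs = make_trajs(pos)
        ev = EncounterEvent(0, 1, 10, 95, 1.7)
        assert classify_encounter_outcome(ev, trajs) == ("undetermined", "undetermined")

    def test_net_outcome_difference(self):
        outcomes = (
            [("stay", "stay")] * 60 + [("move", "move")] * 25 + [("move", "stay")] * 15
        )
        assert net_outcome_difference(outcomes) == pytest.approx(35.0)


class TestSmallClusters:
    def test_sitting_cluster_is_mini(self):
        trajs, truth = gen_cluster_assembly([0.0] * 5, duration_s=80.0)
        events = small_cluster_events(trajs)
        assert len(events) == 1
        ev = events[0]
        assert ev.cls == "mini"
        # independent oracle: first frame where all five form one
        # proximity-connected component
        from scipy.sparse.csgraph import connected_components

        bl = trajs.body_lengths
        thr = 1.5 * 0.5 * (bl[:, None] + bl[None, :])
        for t in range(trajs.n_frames):
            diff = trajs.positions[t][:, None, :] - trajs.positions[t][None, :, :]
            d = np.hypot(diff[..., 0], diff[..., 1])
            n_comp, _ = connected_components((d <= thr), directed=False)
            if n_comp == 1:
                break
        assert abs(ev.onset_frame - t) <= 2

    def test_dispersal_makes_transient(self):
        trajs, _ = gen_cluster_assembly([0.0] * 5, disperse_at_s=32.0, duration_s=60.0)
        events = small_cluster_events(trajs)
        assert len(events) == 1
        assert events[0].cls == "transient"
        assert 20.0 < events[0].lifetime_s < 35.0

    def test_four_flies_never_qualify(self):
        trajs, _ = gen_cluster_assembly([0.0] * 4, duration_s=80.0)
        assert small_cluster_events(trajs) == []

    @pytest.mark.parametrize(
        "lifetime_s,expected",
        [(4.9, None), (5.0, "transient"), (60.0, "transient"), (60.1, "mini")],
    )
    def test_lifetime_boundaries_exact(self, lifetime_s, expected):
        """Class boundaries honoured exactly at 5 s and 60 s."""
        fps = 10.0
        n_co = int(round(lifetime_s * fps)) + 1
        total = n_co + 50
        pos = np.zeros((total, 5, 2))
        for k in range(5):
            pos[:, k, 0] = 3.0 * k
        pos[n_co:, :, 1] = np.arange(5) * 100.0  # scatter afterwards
        trajs = make_trajs(pos, frame_rate=fps)
        events = small_cluster_events(trajs)
        if expected is None:
            assert events == []
        else:
            assert len(events) == 1
            assert events[0].cls == expected


class TestNSI:
    def _event(self, sizes, fps=1.0):
        return SmallClusterEvent(
            onset_frame=0,
            end_frame=len(sizes) - 1,
            cls="mini",
            size_series=list(sizes),
            member_sets=[frozenset(range(s)) for s in sizes],
            frame_rate=fps,
        )

    def test_growth(self):
        ev = self._event([10] * 60 + [12] * 10)
        assert nucleus_stability_index(ev) == pytest.approx(0.2)
        assert not ev.nsi_truncated

    def test_shrink(self):
        ev = self._event([10] * 60 + [4] * 10)
        assert nucleus_stability_index(ev) == pytest.approx(-0.6)

    def test_constant_zero(self):
        ev = self._event([10] * 70)
        assert nucleus_stability_index(ev) == 0.0

    def test_truncated_flagged(self):
        ev = self._event([10] * 20 + [8] * 10)
        assert nucleus_stability_index(ev) == pytest.approx(-0.2)
        assert ev.nsi_truncated


class TestStageSummary:
    def test_linear_growth_crossings(self):
        """Linear growth 0→50 flies over 25 min crosses 10 at 5 min and 25
        at 12.5 min."""
        fps = 1.0
        frames = int(25 * 60 * fps) + 1
        curve = np.linspace(0.0, 50.0, frames)
        trajs = make_trajs(np.zeros((frames, 1, 2)), frame_rate=fps)
        s = stage_summary(trajs, cluster_series=curve)
        assert s.time_to_size[10] == pytest.approx(5.0, abs=0.02)
        assert s.time_to_size[25] == pytest.approx(12.5, abs=0.02)
        assert not s.partial

    def test_encounters_counted_per_stage(self):
        fps = 1.0
        frames = int(21 * 60 * fps)
        trajs = make_trajs(np.zeros((frames, 1, 2)), frame_rate=fps)
        events = [
            EncounterEvent(0, 1, int((5 + 0.1 * k) * 60 * fps), 0, 0.0)
            for k in range(30)
        ]
        s = stage_summary(trajs, encounters=events)
        assert s.encounter_count == (30, 0, 0)

    def test_counts_sum_to_window_total(self):
        fps = 2.0
        frames = int(20 * 60 * fps)
        trajs = make_trajs(np.zeros((frames, 1, 2)), frame_rate=fps)
        rng = np.random.default_rng(1)
        onsets = rng.uniform(0, 20 * 60, 200)
        events = [EncounterEvent(0, 1, int(t * fps), 0, 0.0) for t in onsets]
        s = stage_summary(trajs, encounters=events)
        in_window = sum(
            1 for t in onsets if 5 * 60 <= int(t * fps) / fps < 20 * 60
        )
        assert sum(s.encounter_count) == in_window

    def test_no_cluster_marks_empty(self):
        trajs = make_trajs(np.zeros((100, 1, 2)), frame_rate=1.0)
        s = stage_summary(trajs, cluster_series=np.ones(100))
        assert s.time_to_size[10] is None
        assert s.partial


class TestPeriEventVelocity:
    def test_constant_speed_flat_trace(self):
        fps = 50.0
        t = np.arange(int(6 * fps)) / fps
        ax = t * 5.0
        pos = np.stack(
            [
                np.stack([ax, np.zeros_like(ax)], axis=1),
                np.tile([40.0, 30.0], (len(t), 1)),
            ],
            axis=1,
        )
        trajs = make_trajs(pos, fps)
        ev = EncounterEvent(0, 1, 150, 160, 0.2)
        pv = perievent_velocity([ev], trajs)
        assert np.allclose(pv.mean_interactor, 5.0, atol=0.05)

    def test_truncated_event_excluded(self):
        pos = np.zeros((100, 2, 2))
        trajs = make_trajs(pos, 50.0)
        ev = EncounterEvent(0, 1, 5, 10, 0.1)  # window reaches before t=0
        pv = perievent_velocity([ev], trajs)
        assert pv.truncated_events == [0]

    def test_scripted_deceleration_visible(self):
        """An interactor that walks then halts at contact shows a negative
        speed slope just before the offset."""
        trajs, truth = gen_group_trajectories(
            SceneParams(n_flies=4, seed=8), [ScriptedEncounter(6.0, 0, 1, "stay", "stay")]
        )
        events = detect_encounters(trajs)
        assert len(events) == 1
        pv = perievent_velocity(events, trajs)
        # interactor trace around onset is near the scripted walking speed
        mid = pv.mean_interactor[len(pv.lags_s) // 2]
        assert mid == pytest.approx(5.0, rel=0.1)

    def test_largest_component_series_growth(self):
        trajs, truth = gen_cluster_assembly(
            [0.0, 0.0, 0.0, 0.0, 0.0, 10.0], duration_s=30.0
        )
        series = largest_component_series(trajs)
        assert series[-1] == 6
        assert series[0] <= 2
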