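"""Nearest-neighbor selection, sequence tracking, modification semantics,
motion decomposition, and ground-truth evaluation."""

import numpy as np
import pytest

from phtrack.phdetect import DetectedPoint, PersistenceBar, PipelineParams
from phtrack.synthdata import gen_model_series
from phtrack.trackcore import (
    TrackingError,
    TrackParams,
    decompose_motion,
    evaluate,
    modify_track,
    select_points,
    track_sequence,
)

MODEL_PARAMS = PipelineParams.from_values(150, 5, 0, 0, 1, 14, 50)


def det(x, y, death=10.0):
    bar = PersistenceBar(birth=0.0, death=death,
                         death_simplex=np.zeros((3, 2)),
                         simplex_indices=(0, 1, 2))
    return DetectedPoint(position=np.array([x, y], float), death=death,
                         bar=bar)


class TestSelectPoints:
    def test_exact_match_is_identity(self):
        dets = [det(0, 0), det(5, 5)]
        pos, idx = select_points(np.array([[0, 0], [5, 5.0]]), dets)
        assert np.allclose(pos, [[0, 0], [5, 5]])
        assert list(idx) == [0, 1]

    def test_picks_nearer_point(self):
        pos, idx = select_points(np.array([[0.0, 0.0]]),
                                 [det(1, 0), det(5, 0)])
        assert np.allclose(pos, [[1, 0]]) and idx[0] == 0

    def test_forced_collision_is_allowed(self):
        pos, idx = select_points(np.array([[0.0, 0.0], [10.0, 0.0]]),
                                 [det(4, 0)])
        assert np.allclose(pos, [[4, 0], [4, 0]])
        assert idx[0] == idx[1] == 0

    def test_tie_broken_by_larger_death(self):
        pos, _ = select_points(np.array([[0.0, 0.0]]),
                               [det(1, 0, death=5), det(-1, 0, death=9)])
        assert np.allclose(pos, [[-1, 0]])

    def test_empty_detections_error(self):
        with pytest.raises(TrackingError):
            select_points(np.array([[0.0, 0.0]]), [])

    def test_unique_assignment_resolves_collision(self):
        prev = np.array([[0.0, 0.0], [1.0, 0.0]])
        dets = [det(0.5, 0), det(8, 0)]
        pos, idx = select_points(prev, dets, unique_assignment=True)
        assert sorted(idx) == [0, 1]


class TestTrackSequence:
    def test_noiseless_series_tracks_all_cells(self):
        s = gen_model_series("none", seed=1)
        tp = TrackParams(n_cells=3, init=s.truth[0])
        tr = track_sequence(s.frames, MODEL_PARAMS, tp)
        assert tr.positions.shape == (10, 3, 2)
        assert tr.collisions == []
        assert evaluate(tr, s.truth).mean < 1.5

    def test_single_frame_sequence(self):
        s = gen_model_series("none", n_frames=1, seed=2)
        tr = track_sequence(s.frames, MODEL_PARAMS,
                            TrackParams(n_cells=3, init=s.truth[0]))
        assert tr.n_frames == 1
        d = np.linalg.norm(tr.positions[0] - s.truth[0], axis=1)
        assert d.max() < 1.5

    def test_frame_stride_subsamples(self):
        s = gen_model_series("none", n_frames=10, seed=3)
        frames = s.frames * 15  # 150 frames
        tr = track_sequence(frames[:145], MODEL_PARAMS,
                            TrackParams(n_cells=3, init=s.truth[0],
                                        frame_stride=5))
        assert tr.n_frames == 29

    def test_blank_frame_raises_with_frame_id(self):
        s = gen_model_series("none", n_frames=3, seed=4)
        frames = list(s.frames)
        frames[1] = np.full_like(frames[1], 220)
        with pytest.raises(TrackingError, match="frame 1"):
            track_sequence(frames, MODEL_PARAMS,
                           TrackParams(n_cells=3, init=s.truth[0]))

    def test_deterministic_rerun_bit_identical(self):
        s = gen_model_series("two", seed=5)
        tp = TrackParams(n_cells=3, init=s.truth[0])
        a = track_sequence(s.frames, MODEL_PARAMS, tp)
        b = track_sequence(s.frames, MODEL_PARAMS, tp)
        assert (a.positions == b.positions).all()
        assert (a.selected_index == b.selected_index).all()

    @pytest.mark.parametrize("regime", ["none", "two", "three"])
    def test_parameter_recovery_all_regimes(self, regime):
        s = gen_model_series(regime, seed=11)
        tr = track_sequence(s.frames, MODEL_PARAMS,
                            TrackParams(n_cells=3, init=s.truth[0]))
        assert evaluate(tr, s.truth).mean < 1.5


class TestModifyTrack:
    @pytest.fixture()
    def tracked(self):
        s = gen_model_series("two", seed=6)
        tr = track_sequence(s.frames, MODEL_PARAMS,
                            TrackParams(n_cells=3, init=s.truth[0]))
        return s, tr

    def test_modify_to_same_candidate_changes_only_provenance(self, tracked):
        _s, tr = tracked
        same = int(tr.selected_index[4, 1])
        out = modify_track(tr, frame=4, cell=1, candidate_index=same)
        assert (out.positions == tr.positions).all()
        assert out.provenance[4, 1] == "modified"
        assert (out.provenance[:4] == "auto").all()

    def test_earlier_frames_untouched(self, tracked):
        _s, tr = tracked
        other = (int(tr.selected_index[5, 0]) + 1) % len(tr.candidates[5])
        out = modify_track(tr, frame=5, cell=0, candidate_index=other)
        assert (out.positions[:5] == tr.positions[:5]).all()
        assert np.allclose(out.positions[5, 0],
                           tr.candidates[5][other].position)

    def test_later_frames_reselected_forward(self, tracked):
        _s, tr = tracked
        other = (int(tr.selected_index[3, 2]) + 1) % len(tr.candidates[3])
        out = modify_track(tr, frame=3, cell=2, candidate_index=other)
        # frame 4 selection must be the nearest candidate to the new
        # frame-3 position, per the Markov selection rule
        pos, idx = select_points(out.positions[3], tr.candidates[4])
        assert (out.selected_index[4] == idx).all()

    def test_invalid_candidate_lists_available(self, tracked):
        _s, tr = tracked
        with pytest.raises(IndexError, match="available"):
            modify_track(tr, frame=2, cell=0, candidate_index=999)

    def test_never_a_freehand_coordinate(self, tracked):
        _s, tr = tracked
        out = modify_track(tr, frame=6, cell=1,
                           candidate_index=len(tr.candidates[6]) - 1)
        for i in range(out.n_frames):
            cand = np.array([d.position for d in out.candidates[i]])
            for k in range(out.n_cells):
                d = np.linalg.norm(cand - out.positions[i, k], axis=1)
                assert d.min() < 1e-12


class TestDecomposeMotion:
    def test_rigid_rotation_fixed_barycenter(self):
        th = np.linspace(0, np.pi, 8)
        pos = np.stack(
            [np.c_[np.cos(th), np.sin(th)], np.c_[-np.cos(th), -np.sin(th)]],
            axis=1,
        )
        bary, rel = decompose_motion(pos)
        assert np.allclose(bary, 0)
        assert np.allclose(np.linalg.norm(rel, axis=-1), 1)

    def test_pure_translation_constant_relative(self):
        drift = np.arange(6, dtype=float)[:, None] * [1.0, 2.0]
        pos = np.stack([drift + [0, 0], drift + [3, 1]], axis=1)
        _bary, rel = decompose_motion(pos)
        assert np.allclose(rel, rel[0])

    def test_recomposition_exact_and_relative_sums_zero(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, 100, size=(10, 3, 2))
        bary, rel = decompose_motion(pos)
        assert np.abs(bary[:, None, :] + rel - pos).max() <= 1e-12
        assert np.abs(rel.sum(axis=1)).max() <= 1e-12


class TestEvaluate:
    def _track_with(self, positions):
        from phtrack.trackcore import Track

        f, n = positions.shape[:2]
        return Track(
            positions=positions,
            provenance=np.full((f, n), "auto", dtype=object),
            candidates=[[] for _ in range(f)],
            selected_index=np.zeros((f, n), dtype=int),
        )

    def test_perfect_track_zero_error(self):
        truth = np.random.default_rng(9).uniform(0, 50, size=(5, 3, 2))
        ev = evaluate(self._track_with(truth.copy()), truth)
        assert ev.mean == 0 and ev.std == 0

    def test_constant_offset(self):
        truth = np.zeros((4, 2, 2))
        ev = evaluate(self._track_with(truth + [1.0, 0.0]), truth)
        assert ev.mean == pytest.approx(1.0) and ev.std == pytest.approx(0.0)
        assert ev.per_cell_distances.shape == (4, 2)

    def test_shape_mismatch_rejected(self):
        truth = np.zeros((4, 2, 2))
        with pytest.raises(ValueError):
            evaluate(self._track_with(truth), np.zeros((5, 2, 2)))
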