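import numpy as np
import pytest

from gaitsym import (
    DegenerateWeightsError,
    InsufficientDataError,
    PlaneWeights,
    RegionVectors,
    SequenceFeatures,
    basic_index,
    combined_index,
    fit_weights,
    frame_index,
    segment_index,
)
from oracles import oracle_basic_index


def rv(seed=0, scale=1.0):
    gen = np.random.default_rng(seed)
    return RegionVectors(*(gen.normal(size=(4, 3)) * scale))


def constant_sequence(v, n=5):
    return SequenceFeatures(frames=[v] * n)


class TestFrameIndex:
    def test_constant_sequence_gives_the_per_frame_value(self):
        v = rv(3)
        expect = basic_index(v, "transverse")
        assert frame_index(constant_sequence(v), "transverse").value == \
            pytest.approx(expect)

    def test_arithmetic_mean_of_two_frames(self):
        # construct frames with known sagittal indices 0.2 and 0.6
        def frame(total):
            half = total / 2
            uL = np.array([0.0, np.sin(half), -np.cos(half)])
            uR = np.array([0.0, 0.0, -1.0])
            return RegionVectors(vTL=uL, vTR=uR, vBL=uL, vBR=uR)

        seq = SequenceFeatures(frames=[frame(0.2), frame(0.6)])
        assert frame_index(seq, "sagittal").value == pytest.approx(0.4,
                                                                   abs=1e-9)

    def test_random_frames_match_oracle_mean(self):
        frames = [rv(i) for i in range(20)]
        seq = SequenceFeatures(frames=frames)
        for plane in ("transverse", "sagittal", "coronal"):
            expect = np.mean([oracle_basic_index(f, plane) for f in frames])
            assert frame_index(seq, plane).value == pytest.approx(expect,
                                                                  abs=1e-12)

    def test_degenerate_frames_dropped_not_zeroed(self):
        good = rv(1)
        bad = RegionVectors(vTL=[0, 1, 0], vTR=[1, 0, -1],
                            vBL=[1, 1, -1], vBR=[1, -1, -1])
        seq = SequenceFeatures(frames=[good, bad, good])
        expect = basic_index(good, "transverse")
        assert frame_index(seq, "transverse").value == pytest.approx(expect)


class TestSegmentIndex:
    def test_idempotent_on_constant_sequence(self):
        v = rv(7)
        for plane in ("transverse", "sagittal", "coronal"):
            assert segment_index(constant_sequence(v), plane).value == \
                pytest.approx(basic_index(v, plane), abs=1e-12)

    def test_mean_posture_differs_from_mean_of_angles(self):
        # two frames, each individually asymmetric, mirror over time:
        # the mean posture is symmetric (segment ~ 0) while the per-frame
        # mean stays large
        a = RegionVectors(vTL=[1, 0, -1], vTR=[1, 0, -1],
                          vBL=[1, 0, -1], vBR=[1, 0, -1])
        b = RegionVectors(vTL=[-1, 0, -1], vTR=[-1, 0, -1],
                          vBL=[-1, 0, -1], vBR=[-1, 0, -1])
        seq = SequenceFeatures(frames=[a, b])
        assert segment_index(seq, "transverse").value == pytest.approx(0.0,
                                                                       abs=1e-6)
        # per frame: top and bottom pairs each pi/2 apart -> index pi
        assert frame_index(seq, "transverse").value == pytest.approx(np.pi)

    def test_equals_index_of_averaged_vectors(self):
        frames = [rv(i) for i in range(8)]
        seq = SequenceFeatures(frames=frames)
        mean = RegionVectors(
            vTL=np.mean([f.vTL for f in frames], axis=0),
            vTR=np.mean([f.vTR for f in frames], axis=0),
            vBL=np.mean([f.vBL for f in frames], axis=0),
            vBR=np.mean([f.vBR for f in frames], axis=0))
        for plane in ("transverse", "sagittal", "coronal"):
            assert segment_index(seq, plane).value == pytest.approx(
                oracle_basic_index(mean, plane), abs=1e-12)


class TestOrderInvariance:
    def test_permuting_frames_changes_neither_index(self):
        frames = [rv(i) for i in range(12)]
        seq = SequenceFeatures(frames=frames)
        gen = np.random.default_rng(0)
        perm = SequenceFeatures(
            frames=[frames[i] for i in gen.permutation(12)])
        for plane in ("transverse", "sagittal", "coronal"):
            assert frame_index(seq, plane).value == pytest.approx(
                frame_index(perm, plane).value, abs=1e-12)
            assert segment_index(seq, plane).value == pytest.approx(
                segment_index(perm, plane).value, abs=1e-12)

    def test_prefix_consistency_on_constant_sequence(self):
        v = rv(5)
        for plane in ("transverse", "sagittal", "coronal"):
            vals_f = {frame_index(constant_sequence(v, n), plane).value
                      for n in (1, 3, 9)}
            vals_s = {segment_index(constant_sequence(v, n), plane).value
                      for n in (1, 3, 9)}
            assert max(vals_f) - min(vals_f) < 1e-12
            assert max(vals_s) - min(vals_s) < 1e-12


class TestFitWeights:
    @staticmethod
    def _sequence_with_sagittal_index(s, pitch=0.3):
        """One-frame sequence whose segment sagittal index is exactly ``s``
        while the transverse index is pinned at pi (both pairs pi/2) and the
        coronal index at 2*(pi - 2*pitch), independent of ``s``.

        Left/right vectors differ only in their y/z pitch angle
        (pitch +- s/4 per pair; the index sums two pairs).
        """
        uL = np.array([1.0, np.tan(pitch + s / 4), -1.0])
        uR = np.array([1.0, np.tan(pitch - s / 4), -1.0])
        return SequenceFeatures(
            frames=[RegionVectors(vTL=uL, vTR=uR, vBL=uL, vBR=uR)])

    def test_population_variance_hand_computed(self):
        # two training runs with sagittal indices 0.1 and 0.3
        seqs = [self._sequence_with_sagittal_index(0.1),
                self._sequence_with_sagittal_index(0.3)]
        assert segment_index(seqs[0], "sagittal").value == pytest.approx(0.1)
        w = fit_weights(seqs, scheme="segment")
        assert w.ws == pytest.approx(0.01, abs=1e-9)  # var({0.1, 0.3})

    def test_identical_training_runs_rejected(self):
        seqs = [self._sequence_with_sagittal_index(0.2)] * 2
        with pytest.raises(DegenerateWeightsError):
            fit_weights(seqs, scheme="segment")

    def test_pinned_planes_get_zero_weight(self):
        seqs = [self._sequence_with_sagittal_index(s)
                for s in (0.1, 0.4, 0.25)]
        w = fit_weights(seqs, scheme="segment")
        assert w.wt == pytest.approx(0.0, abs=1e-18)
        assert w.wc == pytest.approx(0.0, abs=1e-18)
        assert w.ws > 0.0
        # combination then reduces to the sagittal term
        probe = self._sequence_with_sagittal_index(0.3)
        combo = combined_index(probe, PlaneWeights(0.0, w.ws, 0.0),
                               scheme="segment")
        assert combo.value == pytest.approx(
            w.ws * segment_index(probe, "sagittal").value, abs=1e-12)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_weights([self._sequence_with_sagittal_index(0.1)],
                        scheme="segment")

    def test_weights_json_record(self):
        from gaitsym import weights_to_json
        w = PlaneWeights(wt=0.1, ws=0.2, wc=0.0)
        rec = weights_to_json(w, scheme="segment", trained_on=["s1", "s2"])
        assert rec == {"wt": 0.1, "ws": 0.2, "wc": 0.0, "scheme": "segment",
                       "trained_on": ["s1", "s2"]}


class TestCombinedIndex:
    def test_unit_weight_recovers_single_plane(self):
        seq = SequenceFeatures(frames=[rv(11)])
        w = PlaneWeights(wt=1.0, ws=0.0, wc=0.0)
        assert combined_index(seq, w, scheme="segment").value == \
            segment_index(seq, "transverse").value

    def test_all_zero_weights_rejected_by_invariant(self):
        with pytest.raises(DegenerateWeightsError):
            PlaneWeights(wt=0.0, ws=0.0, wc=0.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(Exception):
            PlaneWeights(wt=-0.1, ws=1.0, wc=0.0)

    def test_hand_evaluated_weighted_sum(self):
        # frames engineered so It = 0.1 and Is = 0.2 exactly, then
        # w = (2, 3, 0) must give 2*0.1 + 3*0.2 = 0.8
        zhat = np.array([0.0, 0.0, -1.0])
        # transverse angle to zhat: atan(x/-z) = 0.05; sagittal: 0.1
        uL = np.array([np.tan(0.05), np.tan(0.1), -1.0])
        frame = RegionVectors(vTL=uL, vTR=zhat, vBL=uL, vBR=zhat)
        seq = SequenceFeatures(frames=[frame])
        assert segment_index(seq, "transverse").value == pytest.approx(0.1)
        assert segment_index(seq, "sagittal").value == pytest.approx(0.2)
        w = PlaneWeights(wt=2.0, ws=3.0, wc=0.0)
        assert combined_index(seq, w, scheme="segment").value == \
            pytest.approx(0.8, abs=1e-9)
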