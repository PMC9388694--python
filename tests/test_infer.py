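"""Fusion rules, volume segmentation, thickness mapping."""

import numpy as np
import pytest

from octskin.infer import (
    FusionThresholds,
    ThicknessMap,
    fuse_eq2,
    fuse_practical,
    mean_thickness,
    segment_volume,
    thickness_deviation,
    thickness_map,
)
from octskin.labels import one_hot
from octskin.net import ProbMaps
from octskin.phantom import PhantomParams, make_volume


def brute_force_eq2(n_o, n_c, th):
    """Oracle: literal per-pixel evaluation of the thresholded fusion rule."""
    out = np.zeros(n_o.shape, dtype=np.uint8)
    for i in range(n_o.shape[0]):
        for j in range(n_o.shape[1]):
            if n_o[i, j] < th.t_o1 and n_c[i, j] < th.t_c1:
                out[i, j] = 2
            elif th.t_o1 <= n_o[i, j] < th.t_o2 and n_c[i, j] < th.t_c2:
                out[i, j] = 1
    return out


class TestFuseEq2:
    def test_scab_branch_at_default_thresholds(self):
        with pytest.warns(RuntimeWarning, match="epidermis branch"):
            out = fuse_eq2(np.array([[0.4]]), np.array([[0.4]]))
        assert out[0, 0] == 2

    def test_epidermis_branch_with_separated_thresholds(self):
        th = FusionThresholds(0.3, 0.7, 0.5, 0.5)
        out = fuse_eq2(np.array([[0.5]]), np.array([[0.2]]), th)
        assert out[0, 0] == 1

    def test_high_contour_probability_always_background(self, rng):
        th = FusionThresholds(0.3, 0.7, 0.4, 0.6)
        n_o = rng.random((8, 8))
        n_c = np.full((8, 8), max(th.t_c1, th.t_c2))
        assert (fuse_eq2(n_o, n_c, th) == 0).all()

    def test_matches_brute_force_on_random_maps(self, rng):
        for th in (FusionThresholds(0.3, 0.7, 0.5, 0.5), FusionThresholds(0.2, 0.9, 0.3, 0.8)):
            n_o = rng.random((16, 16))
            n_c = rng.random((16, 16))
            assert (fuse_eq2(n_o, n_c, th) == brute_force_eq2(n_o, n_c, th)).all()

    def test_default_thresholds_make_epidermis_branch_empty(self, rng):
        n_o = rng.random((32, 32))
        n_c = rng.random((32, 32))
        with pytest.warns(RuntimeWarning):
            out = fuse_eq2(n_o, n_c)
        assert not (out == 1).any()
        assert (out == brute_force_eq2(n_o, n_c, FusionThresholds())).all()

    def test_shape_mismatch_and_bad_thresholds(self):
        with pytest.raises(ValueError, match="shape"):
            fuse_eq2(np.zeros((4, 4)), np.zeros((5, 5)))
        with pytest.raises(ValueError):
            FusionThresholds(t_o1=0.9, t_o2=0.1)
        with pytest.raises(ValueError):
            FusionThresholds(t_c1=1.5)


class TestFusePractical:
    def test_confident_onehot_returns_argmax(self, rng):
        mask = rng.integers(0, 3, (12, 12))
        probs = ProbMaps(object=one_hot(mask), contour=np.zeros((12, 12)))
        assert (fuse_practical(probs) == mask).all()

    def test_all_background_stays_background(self, rng):
        po = np.zeros((3, 8, 8))
        po[0] = 1.0
        probs = ProbMaps(object=po, contour=rng.random((8, 8)))
        assert (fuse_practical(probs) == 0).all()

    def test_boundary_uncertain_pixels_snap_to_nearer_side(self):
        # column: rows 0-3 background, 4-5 uncertain, 6-9 epidermis
        po = np.zeros((3, 10, 1))
        po[0, :5] = 1.0
        po[1, 5:] = 1.0
        pc = np.zeros((10, 1))
        pc[4:6] = 0.9
        out = fuse_practical(ProbMaps(object=po, contour=pc))
        assert out[4, 0] == 0  # nearer to the background side (row 3)
        assert out[5, 0] == 1  # nearer to the epidermis side (row 6)

    def test_uncertain_run_with_agreeing_sides_keeps_argmax(self):
        # a thin epidermis band fully covered by the contour response must
        # survive: both contour-free neighbors are background
        po = np.zeros((3, 12, 2))
        po[0] = 1.0
        po[0, 5:8] = 0.0
        po[1, 5:8] = 1.0
        pc = np.zeros((12, 2))
        pc[3:10] = 0.9
        out = fuse_practical(ProbMaps(object=po, contour=pc))
        assert (out[5:8] == 1).all()
        assert (out[:5] == 0).all() and (out[8:] == 0).all()

    def test_agrees_with_eq2_on_constructed_inputs(self):
        # confident interior, zero contour: argmax equals the literal rule
        # with thresholds that carve the same regions
        mask = np.zeros((6, 6), dtype=int)
        mask[2:4] = 1
        po = one_hot(mask)
        pc = np.zeros((6, 6))
        th = FusionThresholds(0.4, 0.6, 0.5, 0.5)
        scalar = np.where(mask == 1, 0.5, 0.9)  # epidermis band in [t_o1, t_o2)
        assert (fuse_practical(ProbMaps(po, pc), th) == fuse_eq2(scalar, pc, th)).all()


class TestSegmentVolume:
    def test_oracle_probabilities_recover_truth(self, small_volume):
        _, truth, _ = small_volume
        stack = truth.class_masks

        def oracle(bscan_index=[0]):
            def predict(bscan):
                m = stack[predict.calls]
                predict.calls += 1
                return one_hot(m), np.zeros(m.shape)
            predict.calls = 0
            return predict

        pred = segment_volume(oracle(), np.zeros(stack.shape, dtype=np.float32))
        assert (pred == stack).all()
        assert set(np.unique(pred)) <= {0, 1, 2}

    def test_cleanup_removes_small_islands(self):
        mask = np.zeros((1, 16, 16), dtype=np.uint8)
        mask[0, 4:8, :] = 1
        mask[0, 12, 12] = 1  # speckle island

        def predict(bscan):
            return one_hot(mask[0]), np.zeros((16, 16))

        pred = segment_volume(predict, np.zeros((1, 16, 16), dtype=np.float32), cleanup=True)
        assert pred[0, 12, 12] == 0
        assert (pred[0, 4:8] == 1).all()
        kept = segment_volume(predict, np.zeros((1, 16, 16), dtype=np.float32), cleanup=False)
        assert kept[0, 12, 12] == 1

    def test_non_divisible_bscan_is_padded_and_cropped(self):
        from octskin.net import MultitaskUNet, NetConfig

        net = MultitaskUNet(NetConfig(depth=2, base_channels=4, seed=0))
        vol = np.random.default_rng(0).random((2, 30, 26)).astype(np.float32)
        pred = segment_volume(net, vol)
        assert pred.shape == (2, 30, 26)


class TestThickness:
    def test_80px_band_maps_to_640um(self, flat_params):
        _, truth = make_volume(flat_params, 2)
        tmap = thickness_map(truth.class_masks, pitch_um=8.0)
        assert tmap.px.shape == (flat_params.width, 2)
        assert tmap.valid.all()
        assert (tmap.px == 80).all()
        assert (tmap.um == 640.0).all()

    def test_alines_without_epidermis_are_undefined(self):
        mask = np.zeros((1, 10, 4), dtype=np.uint8)
        mask[0, 3:6, 0] = 1
        tmap = thickness_map(mask)
        assert tmap.valid[0, 0] and tmap.px[0, 0] == 3
        assert not tmap.valid[1:, 0].any()

    def test_largest_run_wins_and_ties_go_shallower(self):
        mask = np.zeros((1, 20, 2), dtype=np.uint8)
        mask[0, 2:4, 0] = 1   # 2-px run
        mask[0, 8:13, 0] = 1  # 5-px run (largest)
        mask[0, 2:4, 1] = 1   # tie: two 2-px runs
        mask[0, 8:10, 1] = 1
        tmap = thickness_map(mask)
        assert tmap.px[0, 0] == 5
        assert tmap.px[1, 0] == 2

    def test_phantom_truth_thickness_recovered_exactly(self, small_volume):
        _, truth, params = small_volume
        tmap = thickness_map(truth.class_masks, pitch_um=params.pitch_um)
        assert tmap.valid.all()
        assert (tmap.px == truth.thickness_px).all()
        assert np.allclose(tmap.um, truth.thickness_px * params.pitch_um)

    def test_thickness_invariant_to_horizontal_flip(self, small_volume):
        _, truth, _ = small_volume
        tmap = thickness_map(truth.class_masks)
        flipped = thickness_map(truth.class_masks[:, :, ::-1])
        assert (flipped.px == tmap.px[::-1]).all()

    def test_mean_thickness_statistics(self):
        px = np.concatenate([np.full(8, 10.0), np.full(8, 30.0)])[:, None]
        tmap = ThicknessMap(px=px, valid=np.ones_like(px, bool), pitch_um=8.0)
        mean, sd, n = mean_thickness(tmap)
        assert mean == pytest.approx(20 * 8.0)
        assert sd == pytest.approx(10 * 8.0)
        assert n == 16
        const = ThicknessMap(px=np.full((4, 1), 80.0), valid=np.ones((4, 1), bool), pitch_um=8.0)
        assert mean_thickness(const) == (640.0, 0.0, 4)

    def test_mean_thickness_requires_valid_alines(self):
        tmap = ThicknessMap(px=np.zeros((4, 1)), valid=np.zeros((4, 1), bool))
        with pytest.raises(ValueError, match="undefined"):
            mean_thickness(tmap)
        ok = ThicknessMap(px=np.ones((4, 1)), valid=np.ones((4, 1), bool))
        with pytest.raises(ValueError, match="undefined"):
            mean_thickness(ok, region=np.zeros((4, 1), bool))

    def test_thickness_deviation_basic_and_symmetric(self):
        base = ThicknessMap(px=np.full((6, 2), 40.0), valid=np.ones((6, 2), bool), pitch_um=8.0)
        shifted = ThicknessMap(px=base.px + 2, valid=base.valid, pitch_um=8.0)
        mean, sd, devs = thickness_deviation([base], [base])
        assert (mean, sd) == (0.0, 0.0)
        mean, sd, _ = thickness_deviation([shifted], [base])
        assert mean == pytest.approx(16.0)  # 2 px at 8 um/px
        assert thickness_deviation([base], [shifted])[0] == pytest.approx(mean)

    def test_thickness_deviation_grid_mismatch(self):
        a = ThicknessMap(px=np.ones((4, 1)), valid=np.ones((4, 1), bool))
        b = ThicknessMap(px=np.ones((5, 1)), valid=np.ones((5, 1), bool))
        with pytest.raises(ValueError, match="mismatch"):
            thickness_deviation([a], [b])
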