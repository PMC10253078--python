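import numpy as np
import pytest

from boneage.alignment import (
    AffineTransform,
    AlignmentUndecidableError,
    PoseDecision,
    RotationUndecidableError,
    apply_alignment,
    compose_alignment,
    compose_corruption,
    compute_rotation,
    decide_flip,
    decide_mirror,
    decide_pose,
    transform_boxes,
)
from boneage.detection_io import DetectionBox, DetectionSet
from boneage.synthetic import canonical_layout, corrupt_layout


def _mirror_layout(d):
    return DetectionSet(
        boxes=[
            DetectionBox(b.class_id, 1 - b.cx, b.cy, b.w, b.h, b.conf) for b in d.boxes
        ],
        image_id=d.image_id,
    )


def _flip_layout(d):
    return DetectionSet(
        boxes=[
            DetectionBox(b.class_id, b.cx, 1 - b.cy, b.w, b.h, b.conf) for b in d.boxes
        ],
        image_id=d.image_id,
    )


class TestMirrorDecision:
    def test_canonical_not_mirrored(self, canonical):
        assert decide_mirror(canonical) is False

    def test_reflected_layout_detected(self, canonical):
        assert decide_mirror(_mirror_layout(canonical)) is True

    def test_tie_means_no_mirror(self):
        det = DetectionSet(
            boxes=[DetectionBox(8, 0.5, 0.2, 0.1, 0.1), DetectionBox(0, 0.5, 0.8, 0.1, 0.1)]
        )
        assert decide_mirror(det) is False

    def test_missing_reference_set_raises(self):
        det = DetectionSet(boxes=[DetectionBox(0, 0.5, 0.5, 0.1, 0.1)])
        with pytest.raises(AlignmentUndecidableError):
            decide_mirror(det)


class TestFlipDecision:
    def test_canonical_not_flipped(self, canonical):
        assert decide_flip(canonical) is False

    def test_flipped_layout_detected(self, canonical):
        assert decide_flip(_flip_layout(canonical)) is True

    def test_rotated_180_is_mirror_plus_flip(self, canonical):
        rotated = corrupt_layout(
            canonical, PoseDecision(mirror=True, flip=True, rotation_deg=0.0)
        )
        pose = decide_pose(rotated)
        assert pose.mirror and pose.flip
        assert pose.rotation_deg == pytest.approx(0.0, abs=1e-9)


class TestRotation:
    def test_canonical_is_vertical(self, canonical):
        angle, valid = compute_rotation(canonical)
        assert valid
        assert angle == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("true_deg", [30.0, -30.0, 59.0, -59.0, 1.0])
    def test_recovers_known_tilt(self, canonical, true_deg):
        tilted = corrupt_layout(canonical, PoseDecision(rotation_deg=true_deg))
        angle, _ = compute_rotation(tilted)
        assert angle == pytest.approx(true_deg, abs=1e-9)

    def test_antiparallel_gives_180(self):
        det = DetectionSet(
            boxes=[
                DetectionBox(14, 0.5, 0.8, 0.1, 0.1),  # fingertip below
                DetectionBox(1, 0.5, 0.2, 0.1, 0.1),  # wrist above
            ]
        )
        angle, _ = compute_rotation(det)
        assert angle == pytest.approx(180.0)

    def test_missing_roi_flags_invalid(self):
        det = DetectionSet(boxes=[DetectionBox(1, 0.5, 0.5, 0.1, 0.1)])
        angle, valid = compute_rotation(det)
        assert angle == 0.0 and not valid
        with pytest.raises(RotationUndecidableError):
            compute_rotation(det, strict=True)


class TestComposeAlignment:
    def test_all_off_is_identity(self):
        t = compose_alignment(PoseDecision(), (100, 80))
        assert t.is_identity()

    def test_mirror_point_map(self):
        t = compose_alignment(PoseDecision(mirror=True), (100, 80))
        pts = t.apply_points([[0.0, 0.0], [99.0, 10.0]])
        np.testing.assert_allclose(pts, [[99.0, 0.0], [0.0, 10.0]], atol=1e-12)

    def test_mirror_plus_180_equals_flip(self):
        w, h = 64, 64
        mirror_rot = (
            AffineTransform.rotation(180.0, w, h) @ AffineTransform.mirror_horizontal(w)
        )
        flip = AffineTransform.flip_vertical(h)
        np.testing.assert_allclose(mirror_rot.matrix, flip.matrix, atol=1e-12)

    def test_corruption_is_exact_inverse(self):
        pose = PoseDecision(mirror=True, flip=False, rotation_deg=23.0)
        align = compose_alignment(pose, (64, 64))
        corrupt = compose_corruption(pose, (64, 64))
        np.testing.assert_allclose(
            (align @ corrupt).matrix, np.eye(3), atol=1e-12
        )


class TestApplyAlignment:
    def test_identity_pixel_identical(self):
        img = np.arange(64 * 64, dtype=np.uint8).reshape(64, 64)
        out = apply_alignment(img, AffineTransform.identity())
        assert out.dtype == img.dtype
        np.testing.assert_array_equal(out, img)

    def test_double_mirror_is_involution(self):
        rng = np.random.default_rng(0)
        img = (rng.random((32, 32)) * 255).astype(np.uint8)
        t = AffineTransform.mirror_horizontal(32)
        np.testing.assert_array_equal(apply_alignment(apply_alignment(img, t), t), img)

    def test_rotation_round_trip_within_tolerance(self):
        rng = np.random.default_rng(1)
        img = (rng.random((64, 64)) * 255).astype(np.uint8)
        fwd = AffineTransform.rotation(90.0, 64, 64)
        back = AffineTransform.rotation(-90.0, 64, 64)
        out = apply_alignment(apply_alignment(img, fwd), back)
        interior = (slice(8, -8), slice(8, -8))
        diff = np.abs(out[interior].astype(int) - img[interior].astype(int))
        assert diff.max() <= 2

    def test_singular_transform_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform(np.zeros((3, 3)))


class TestTransformBoxes:
    def test_identity_preserves_boxes(self, canonical):
        out = transform_boxes(canonical, AffineTransform.identity(), (256, 256))
        for a, b in zip(canonical.boxes, out.boxes):
            assert a.cx == pytest.approx(b.cx, abs=1e-12)
            assert a.w == pytest.approx(b.w, abs=1e-12)

    def test_mirror_reflects_cx_only(self, canonical):
        out = transform_boxes(
            canonical, AffineTransform.mirror_horizontal(256), (256, 256)
        )
        for a, b in zip(canonical.boxes, out.boxes):
            assert b.cx == pytest.approx(1 - a.cx, abs=1e-9)
            assert b.cy == pytest.approx(a.cy, abs=1e-12)
            assert (b.w, b.h) == pytest.approx((a.w, a.h), abs=1e-9)

    def test_90_degree_rotation_swaps_box_sides(self):
        det = DetectionSet(boxes=[DetectionBox(3, 0.5, 0.5, 0.2, 0.1)])
        t = AffineTransform.rotation(90.0, 100, 100)
        out = transform_boxes(det, t, (100, 100))
        assert out.boxes[0].w == pytest.approx(0.1, abs=1e-9)
        assert out.boxes[0].h == pytest.approx(0.2, abs=1e-9)

    def test_off_canvas_box_dropped(self):
        det = DetectionSet(boxes=[DetectionBox(3, 0.02, 0.5, 0.02, 0.02)])
        shift = AffineTransform(np.array([[1, 0, -50], [0, 1, 0], [0, 0, 1]], float))
        out = transform_boxes(det, shift, (100, 100))
        assert out.boxes == []

    def test_class_and_confidence_preserved(self, canonical):
        t = AffineTransform.rotation(17.0, 256, 256)
        out = transform_boxes(canonical, t, (256, 256))
        assert [b.class_id for b in out.boxes] == [b.class_id for b in canonical.boxes]


class TestRoundTrip:
    def test_pose_recovery_random_poses(self, canonical):
        """Mirror/flip/rotation recovered exactly from box-level corruptions."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            true = PoseDecision(
                mirror=bool(rng.random() < 0.5),
                flip=bool(rng.random() < 0.5),
                rotation_deg=float(rng.uniform(-60, 60)),
            )
            corrupted = corrupt_layout(canonical, true)
            decided = decide_pose(corrupted)
            assert decided.mirror == true.mirror
            assert decided.flip == true.flip
            assert decided.rotation_deg == pytest.approx(true.rotation_deg, abs=0.5)

    def test_idempotent_on_aligned_layout(self, canonical):
        pose = decide_pose(canonical)
        assert not pose.mirror and not pose.flip
        assert abs(pose.rotation_deg) <= 0.5

    def test_image_and_box_transforms_commute_on_peak(self, canonical):
        """A delta peak at a box centre stays at the transformed box centre."""
        size = 256
        img = np.zeros((size, size))
        box = canonical.boxes[4]
        px, py = int(round(box.cx * size - 0.5)), int(round(box.cy * size - 0.5))
        img[py, px] = 1.0
        t = compose_corruption(PoseDecision(mirror=True, rotation_deg=20.0), (size, size))
        warped = apply_alignment(img, t)
        moved = transform_boxes(canonical, t, (size, size))
        nb = [b for b in moved.boxes if b.class_id == box.class_id][0]
        qx, qy = int(round(nb.cx * size - 0.5)), int(round(nb.cy * size - 0.5))
        window = warped[qy - 1 : qy + 2, qx - 1 : qx + 2]
        assert window.sum() == pytest.approx(1.0, abs=0.05)
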