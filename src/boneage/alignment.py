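"""Hand-pose normalisation from detected ROI geometry.

Clinical hand radiographs arrive left-right mirrored, upside down, or rotated.
Before ROI cropping every hand is brought to the canonical pose — palm down,
middle finger vertical and pointing up — using only the detected ROI centres:

* mirror test: the mean x coordinate of ROI classes {8, 15, 16, 17} (ulnar
  column) must lie left of that of classes {0, 9, 10, 11} (radial/thumb
  column); if not, the image is mirrored.
* flip test (after mirror correction): the mean y of classes {11, 13, 14, 17}
  (fingertip band) must lie above that of classes {0, 8, 1, 2} (wrist band);
  if not, the image is flipped vertically.
* rotation (after both): the signed angle between the ROI-14 -> ROI-1 segment
  (middle fingertip to wrist) and the downward image vertical; the correction
  rotates by its negative so the segment becomes vertical with ROI 14 on top.

Ties (equal means) leave the image untouched. All geometry uses normalised
top-left-origin coordinates (x rightwards, y downwards); pixel transforms use
the centre-of-pixel convention ``x_pix = cx * W - 0.5`` so that the mirror of
pixel column ``x`` is ``W - 1 - x`` and of a normalised centre ``cx`` is
``1 - cx``. Positive rotation angles are clockwise on screen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from skimage.transform import AffineTransform as _SkAffine, warp as _sk_warp

from .detection_io import DetectionBox, DetectionSet

#: ROI classes on the ulnar (little-finger) side; must be left of MIRROR_RIGHT.
MIRROR_LEFT_CLASSES = (8, 15, 16, 17)
MIRROR_RIGHT_CLASSES = (0, 9, 10, 11)
#: ROI classes near the fingertips; must be above FLIP_BOTTOM (wrist band).
FLIP_TOP_CLASSES = (11, 13, 14, 17)
FLIP_BOTTOM_CLASSES = (0, 8, 1, 2)

ROTATION_WRIST_CLASS = 1
ROTATION_FINGERTIP_CLASS = 14


class AlignmentUndecidableError(ValueError):
    """A reference ROI set required by a pose test is entirely missing."""


class RotationUndecidableError(ValueError):
    """ROI 1 or ROI 14 is missing, so the rotation angle cannot be computed."""


@dataclass(frozen=True)
class PoseDecision:
    """The alignment verdict for one image.

    ``rotation_deg`` is the signed clockwise angle (degrees, in (-180, 180])
    by which the ROI-14 -> ROI-1 segment deviates from the downward vertical;
    ``rotation_valid`` is False when the angle could not be decided and was
    defaulted to 0.
    """

    mirror: bool = False
    flip: bool = False
    rotation_deg: float = 0.0
    rotation_valid: bool = True


class AffineTransform:
    """Rigid 2-D pixel-coordinate transform (3x3 homogeneous matrix).

    Restricted to compositions of reflections, rotations and translations;
    ``ops`` records the composition order for provenance.
    """

    def __init__(self, matrix: np.ndarray, ops: tuple[str, ...] = ()):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (3, 3):
            raise ValueError(f"expected 3x3 matrix, got {matrix.shape}")
        if abs(np.linalg.det(matrix[:2, :2])) < 1e-12:
            raise ValueError("transform is singular")
        self.matrix = matrix
        self.ops = ops

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), ())

    @classmethod
    def mirror_horizontal(cls, width: int) -> "AffineTransform":
        """Left-right mirror: pixel (x, y) -> (W-1-x, y)."""
        m = np.array([[-1.0, 0.0, width - 1.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        return cls(m, ("mirror",))

    @classmethod
    def flip_vertical(cls, height: int) -> "AffineTransform":
        """Up-down flip: pixel (x, y) -> (x, H-1-y)."""
        m = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, height - 1.0], [0.0, 0.0, 1.0]])
        return cls(m, ("flip",))

    @classmethod
    def rotation(cls, degrees_cw: float, width: int, height: int) -> "AffineTransform":
        """Clockwise-on-screen rotation about the image centre."""
        t = np.deg2rad(degrees_cw)
        c, s = np.cos(t), np.sin(t)
        cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pre = np.array([[1.0, 0.0, -cx], [0.0, 1.0, -cy], [0.0, 0.0, 1.0]])
        post = np.array([[1.0, 0.0, cx], [0.0, 1.0, cy], [0.0, 0.0, 1.0]])
        return cls(post @ rot @ pre, (f"rotate({degrees_cw:+.3f})",))

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return AffineTransform(self.matrix @ other.matrix, other.ops + self.ops)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), tuple(f"inv({o})" for o in reversed(self.ops))
        )

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.allclose(self.matrix, np.eye(3), atol=tol))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) pixel points."""
        pts = np.asarray(pts, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        out = hom @ self.matrix.T
        return out[:, :2]


def _mean_coord(d: DetectionSet, classes: tuple[int, ...], axis: str) -> float:
    vals = [getattr(b, axis) for b in d.boxes if b.class_id in classes]
    if not vals:
        raise AlignmentUndecidableError(
            f"no ROI of classes {classes} present in {d.image_id!r}"
        )
    return float(np.mean(vals))


def decide_mirror(d: DetectionSet) -> bool:
    """True iff the hand is left-right mirrored.

    Compares mean x centroids of the ulnar-side classes {8,15,16,17} against
    the radial-side classes {0,9,10,11}; strict inequality, so a tie means no
    mirror.
    """
    return _mean_coord(d, MIRROR_LEFT_CLASSES, "cx") > _mean_coord(
        d, MIRROR_RIGHT_CLASSES, "cx"
    )


def decide_flip(d: DetectionSet) -> bool:
    """True iff the hand is upside down (to be applied after mirror correction).

    Compares mean y centroids of the fingertip classes {11,13,14,17} against
    the wrist classes {0,8,1,2}; ties mean no flip.
    """
    return _mean_coord(d, FLIP_TOP_CLASSES, "cy") > _mean_coord(
        d, FLIP_BOTTOM_CLASSES, "cy"
    )


def compute_rotation(d: DetectionSet, strict: bool = False) -> tuple[float, bool]:
    """Signed clockwise angle (degrees) of the middle-finger axis off vertical.

    Uses the segment from the ROI-14 centre (middle fingertip) to the ROI-1
    centre (wrist); the returned angle lies in (-180, 180] and rotating the
    image by its negative makes the segment vertical with ROI 14 above ROI 1.

    Returns ``(angle, valid)``; when either ROI is missing the result is
    ``(0.0, False)``, or :class:`RotationUndecidableError` if ``strict``.
    """
    by_class = {b.class_id: b for b in reversed(d.boxes)}
    top = by_class.get(ROTATION_FINGERTIP_CLASS)
    bottom = by_class.get(ROTATION_WRIST_CLASS)
    if top is None or bottom is None:
        if strict:
            raise RotationUndecidableError(
                f"ROI 1 and/or ROI 14 missing in {d.image_id!r}"
            )
        return 0.0, False
    vx = bottom.cx - top.cx
    vy = bottom.cy - top.cy
    angle = float(np.degrees(np.arctan2(-vx, vy)))
    if angle <= -180.0:  # wrap the -0.0 branch of atan2 into (-180, 180]
        angle += 360.0
    return angle, True


def _mirror_boxes(d: DetectionSet) -> DetectionSet:
    return DetectionSet(
        boxes=[_dc_replace(b, cx=1.0 - b.cx) for b in d.boxes], image_id=d.image_id
    )


def _flip_boxes(d: DetectionSet) -> DetectionSet:
    return DetectionSet(
        boxes=[_dc_replace(b, cy=1.0 - b.cy) for b in d.boxes], image_id=d.image_id
    )


def decide_pose(d: DetectionSet, strict_rotation: bool = False) -> PoseDecision:
    """Run the three pose tests in order: mirror, then flip, then rotation.

    The flip test sees mirror-corrected coordinates and the rotation sees
    mirror- and flip-corrected coordinates, matching the sequential correction
    the transform applies.
    """
    mirror = decide_mirror(d)
    corrected = _mirror_boxes(d) if mirror else d
    flip = decide_flip(corrected)
    if flip:
        corrected = _flip_boxes(corrected)
    angle, valid = compute_rotation(corrected, strict=strict_rotation)
    return PoseDecision(mirror=mirror, flip=flip, rotation_deg=angle, rotation_valid=valid)


def compose_alignment(
    pose: PoseDecision, image_size: tuple[int, int]
) -> AffineTransform:
    """Build the correcting transform: mirror, then flip, then de-rotation.

    ``image_size`` is (width, height). Flags that are off contribute the
    identity; the rotation component rotates by ``-rotation_deg`` so that the
    middle-finger axis becomes vertical.
    """
    width, height = image_size
    t = AffineTransform.identity()
    if pose.mirror:
        t = AffineTransform.mirror_horizontal(width) @ t
    if pose.flip:
        t = AffineTransform.flip_vertical(height) @ t
    if pose.rotation_deg != 0.0:
        t = AffineTransform.rotation(-pose.rotation_deg, width, height) @ t
    return t


def compose_corruption(
    pose: PoseDecision, image_size: tuple[int, int]
) -> AffineTransform:
    """The forward corruption whose exact inverse is :func:`compose_alignment`."""
    return compose_alignment(pose, image_size).inverse()


def apply_alignment(image: np.ndarray, transform: AffineTransform) -> np.ndarray:
    """Resample a grayscale image under a pixel transform.

    Bilinear interpolation, zero fill outside the canvas, output size equals
    input size. The identity transform returns a pixel-identical copy.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    if transform.is_identity():
        return image.copy()
    inv = np.linalg.inv(transform.matrix)
    out = _sk_warp(
        image.astype(float),
        inverse_map=_SkAffine(matrix=inv),
        order=1,
        cval=0.0,
        preserve_range=True,
        clip=False,
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(image.dtype)


def transform_boxes(
    d: DetectionSet, transform: AffineTransform, image_size: tuple[int, int]
) -> DetectionSet:
    """Map detection boxes through a pixel transform.

    Each box's four corners are mapped and replaced by their axis-aligned
    bounding box (exact for the rigid transforms used here: the mapped centre
    stays the AABB centre), then clamped to the unit square. Boxes mapped
    entirely off-canvas are dropped with a warning.
    """
    from .detection_io import logger

    width, height = image_size
    out: list[DetectionBox] = []
    for b in d.boxes:
        cx_p, cy_p = b.cx * width - 0.5, b.cy * height - 0.5
        hw, hh = b.w * width / 2.0, b.h * height / 2.0
        corners = np.array(
            [
                [cx_p - hw, cy_p - hh],
                [cx_p + hw, cy_p - hh],
                [cx_p - hw, cy_p + hh],
                [cx_p + hw, cy_p + hh],
            ]
        )
        mapped = transform.apply_points(corners)
        x0, y0 = mapped.min(axis=0)
        x1, y1 = mapped.max(axis=0)
        # back to normalised coordinates
        nx0, nx1 = (x0 + 0.5) / width, (x1 + 0.5) / width
        ny0, ny1 = (y0 + 0.5) / height, (y1 + 0.5) / height
        if nx1 <= 0 or ny1 <= 0 or nx0 >= 1 or ny0 >= 1:
            logger.warning(
                "box class %d of %s mapped off-canvas; dropped", b.class_id, d.image_id
            )
            continue
        nx0, nx1 = max(0.0, nx0), min(1.0, nx1)
        ny0, ny1 = max(0.0, ny0), min(1.0, ny1)
        out.append(
            DetectionBox(
                class_id=b.class_id,
                cx=(nx0 + nx1) / 2.0,
                cy=(ny0 + ny1) / 2.0,
                w=nx1 - nx0,
                h=ny1 - ny0,
                conf=b.conf,
            )
        )
    return DetectionSet(boxes=out, image_id=d.image_id)


def align_sample(
    image: np.ndarray, detections: DetectionSet, strict_rotation: bool = False
) -> tuple[np.ndarray, DetectionSet, PoseDecision, AffineTransform]:
    """End-to-end pose normalisation of one image and its detections."""
    pose = decide_pose(detections, strict_rotation=strict_rotation)
    height, width = image.shape
    t = compose_alignment(pose, (width, height))
    return (
        apply_alignment(image, t),
        transform_boxes(detections, t, (width, height)),
        pose,
        t,
    )


__all__ = [
    "PoseDecision",
    "AffineTransform",
    "AlignmentUndecidableError",
    "RotationUndecidableError",
    "MIRROR_LEFT_CLASSES",
    "MIRROR_RIGHT_CLASSES",
    "FLIP_TOP_CLASSES",
    "FLIP_BOTTOM_CLASSES",
    "decide_mirror",
    "decide_flip",
    "compute_rotation",
    "decide_pose",
    "compose_alignment",
    "compose_corruption",
    "apply_alignment",
    "transform_boxes",
    "align_sample",
]
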