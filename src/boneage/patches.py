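"""ROI patch extraction: crop the 18 aligned regions into a fixed stack.

After pose normalisation each detected ROI is cropped as a square patch
(side = max(w, h) grown by a margin), resized to 58x58, and stacked into a
(18, 58, 58) array indexed by ROI class. Missing ROI channels are zero with
their ``present_mask`` entry false, keeping the tensor shape fixed for
batching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .detection_io import NUM_ROI_CLASSES, DetectionSet, dedupe_detections

PATCH_SIZE = 58
DEFAULT_MARGIN = 0.1


@dataclass
class RoiStack:
    """18 cropped, resized ROI patches for one sample.

    ``data`` has shape (18, 58, 58) with intensities in [0, 1]; channel index
    is the ROI class id. Channels of absent ROIs are all-zero and flagged in
    ``present_mask``.
    """

    data: np.ndarray
    present_mask: np.ndarray = field(
        default_factory=lambda: np.ones(NUM_ROI_CLASSES, dtype=bool)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if self.data.shape != (NUM_ROI_CLASSES, PATCH_SIZE, PATCH_SIZE):
            raise ValueError(
                f"RoiStack data must have shape "
                f"({NUM_ROI_CLASSES}, {PATCH_SIZE}, {PATCH_SIZE}), got {self.data.shape}"
            )
        if self.present_mask.shape != (NUM_ROI_CLASSES,):
            raise ValueError("present_mask must have shape (18,)")


def _to_unit_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        return image.astype(np.float64) / np.iinfo(image.dtype).max
    return image.astype(np.float64)


def crop_rois(
    image: np.ndarray,
    detections: DetectionSet,
    margin: float = DEFAULT_MARGIN,
    patch_size: int = PATCH_SIZE,
) -> RoiStack:
    """Crop every detected ROI into a square patch and stack by class id.

    The crop is centred on the box centre with side ``max(w, h) * (1 + 2*margin)``
    in pixels, intersected with the canvas, then resized to
    ``patch_size x patch_size`` with bilinear interpolation. Integer images are
    scaled to [0, 1] by their dtype range.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    image = _to_unit_float(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {image.shape}")
    height, width = image.shape
    det = dedupe_detections(detections)
    data = np.zeros((NUM_ROI_CLASSES, patch_size, patch_size), dtype=np.float32)
    mask = np.zeros(NUM_ROI_CLASSES, dtype=bool)
    for box in det.boxes:
        cx_p = box.cx * width - 0.5
        cy_p = box.cy * height - 0.5
        half = max(box.w * width, box.h * height) * (1.0 + 2.0 * margin) / 2.0
        x0 = max(0, int(round(cx_p - half)))
        x1 = min(width, int(round(cx_p + half)) + 1)
        y0 = max(0, int(round(cy_p - half)))
        y1 = min(height, int(round(cy_p + half)) + 1)
        if x1 <= x0 or y1 <= y0:
            continue
        crop = image[y0:y1, x0:x1]
        patch = _sk_resize(
            crop,
            (patch_size, patch_size),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        data[box.class_id] = patch.astype(np.float32)
        mask[box.class_id] = True
    return RoiStack(data=data, present_mask=mask)


def batch_stacks(stacks: list[RoiStack]) -> np.ndarray:
    """Stack N :class:`RoiStack` objects into an (N, 18, 58, 58) array."""
    if not stacks:
        raise ValueError("cannot batch an empty list of stacks")
    shapes = {s.data.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"mixed stack shapes: {shapes}")
    return np.stack([s.data for s in stacks], axis=0)


def save_stack(path, stack: RoiStack, **provenance) -> None:
    """Persist a stack (npz archive with data, mask and provenance strings)."""
    np.savez_compressed(
        path,
        data=stack.data,
        present_mask=stack.present_mask,
        **{k: np.array(str(v)) for k, v in provenance.items()},
    )


def load_stack(path) -> RoiStack:
    with np.load(path) as archive:
        return RoiStack(data=archive["data"], present_mask=archive["present_mask"])


__all__ = [
    "RoiStack",
    "PATCH_SIZE",
    "DEFAULT_MARGIN",
    "crop_rois",
    "batch_stacks",
    "save_stack",
    "load_stack",
]
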