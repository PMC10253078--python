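"""Synthetic hand-radiograph corpus generator.

Produces fully self-contained fixtures in the exact external formats the
pipeline consumes: PNG images, YOLO text detection labels, an
``id,boneage,male`` CSV and a ground-truth JSON. Each sample is a stylised
left hand in the canonical pose — 18 ROI blobs laid out like the TW3 key
regions (wrist at the bottom, middle fingertip at the top, ulnar column on
the left) — optionally pose-corrupted by mirror/flip/rotation with the exact
forward transforms the alignment module inverts.

Appearance is deliberately schematic: each ROI is a Gaussian blob whose
radius and peak intensity grow monotonically with *effective age*
``age + delta * [sex == female]`` (females appear skeletally older at equal
chronological age; default offset 24 months). This gives the age signal a
known, recoverable structure for end-to-end training tests; it does not
attempt radiographic realism.

Randomness is split into independent streams (ages/sexes, pose, noise) so
each can be held fixed on its own; a given spec + seed is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .alignment import PoseDecision, apply_alignment, compose_corruption, transform_boxes
from .detection_io import (
    DetectionBox,
    DetectionSet,
    SampleRecord,
    write_yolo_labels,
)

#: Canonical 18-ROI layout: class id -> (cx, cy, w, h), normalised.
#: Satisfies the alignment inequalities: ulnar classes {8,15,16,17} left of
#: radial classes {0,9,10,11}; fingertip classes {11,13,14,17} above wrist
#: classes {0,8,1,2}; ROI 14 directly above ROI 1.
CANONICAL_BOXES: dict[int, tuple[float, float, float, float]] = {
    0: (0.80, 0.80, 0.08, 0.08),
    1: (0.50, 0.85, 0.10, 0.08),
    2: (0.60, 0.78, 0.08, 0.08),
    3: (0.35, 0.60, 0.08, 0.08),
    4: (0.50, 0.62, 0.08, 0.08),
    5: (0.65, 0.60, 0.08, 0.08),
    6: (0.42, 0.45, 0.07, 0.07),
    7: (0.50, 0.42, 0.07, 0.07),
    8: (0.20, 0.75, 0.08, 0.08),
    9: (0.80, 0.50, 0.07, 0.07),
    10: (0.78, 0.35, 0.07, 0.07),
    11: (0.75, 0.22, 0.06, 0.06),
    12: (0.58, 0.35, 0.07, 0.07),
    13: (0.42, 0.22, 0.06, 0.06),
    14: (0.50, 0.15, 0.06, 0.06),
    15: (0.20, 0.45, 0.07, 0.07),
    16: (0.25, 0.30, 0.06, 0.06),
    17: (0.30, 0.20, 0.06, 0.06),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions of the synthetic corpus."""

    n_samples: int = 500
    image_size: int = 256
    age_min_months: float = 1.0
    age_max_months: float = 228.0
    sex_offset_months: float = 24.0  # females appear this much older
    female_fraction: float = 0.5
    mirror_prob: float = 0.5
    flip_prob: float = 0.5
    rotation_bound_deg: float = 30.0
    noise_sd: float = 0.02
    #: fraction of samples whose label files keep only ``dropout_keep`` classes
    dropout_fraction: float = 0.0
    dropout_keep: int = 10
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Per-sample generative truth recorded alongside the corrupted outputs."""

    image_id: str
    age_months: float
    sex: str
    pose: PoseDecision

    def to_dict(self) -> dict:
        return {
            "image_id": self.image_id,
            "age_months": self.age_months,
            "sex": self.sex,
            "mirror": self.pose.mirror,
            "flip": self.pose.flip,
            "rotation_deg": self.pose.rotation_deg,
        }


def canonical_layout(image_id: str = "canonical") -> DetectionSet:
    """The fixed 18-box canonical left-hand layout."""
    boxes = [
        DetectionBox(class_id=cid, cx=cx, cy=cy, w=w, h=h)
        for cid, (cx, cy, w, h) in sorted(CANONICAL_BOXES.items())
    ]
    return DetectionSet(boxes=boxes, image_id=image_id)


def blob_params(
    age_months: float, sex: str, spec: SyntheticSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI blob sigmas (pixels) and peak intensities for one sample.

    Both grow monotonically (affinely) with effective age
    ``age + offset * [female]``; sigma stays within the ROI box so the boxes
    tightly enclose the visible blobs.
    """
    eff = age_months + (spec.sex_offset_months if sex == "female" else 0.0)
    frac = eff / (spec.age_max_months + spec.sex_offset_months)
    layout = canonical_layout()
    sides = np.array([max(b.w, b.h) * spec.image_size for b in layout.boxes])
    sigmas = sides / 6.0 * (0.55 + 0.45 * frac)
    peaks = np.full(len(sides), 0.35 + 0.60 * frac)
    return sigmas, peaks


def render_sample(
    age_months: float,
    sex: str,
    spec: SyntheticSpec,
    rng_noise: np.random.Generator | None = None,
) -> tuple[np.ndarray, DetectionSet]:
    """Render one canonical-pose image and its detection boxes.

    Deterministic given (age, sex, spec) except for the additive noise drawn
    from ``rng_noise`` (omit it for a noiseless image).
    """
    size = spec.image_size
    layout = canonical_layout()
    sigmas, peaks = blob_params(age_months, sex, spec)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    image = np.zeros((size, size), dtype=float)
    for box, sigma, peak in zip(layout.boxes, sigmas, peaks):
        cx_p = box.cx * size - 0.5
        cy_p = box.cy * size - 0.5
        half = max(box.w, box.h) * size / 2.0 + 3.0 * sigma
        x0, x1 = int(max(0, cx_p - half)), int(min(size, cx_p + half + 1))
        y0, y1 = int(max(0, cy_p - half)), int(min(size, cy_p + half + 1))
        local = peak * np.exp(
            -((xx[y0:y1, x0:x1] - cx_p) ** 2 + (yy[y0:y1, x0:x1] - cy_p) ** 2)
            / (2.0 * sigma**2)
        )
        np.maximum(image[y0:y1, x0:x1], local, out=image[y0:y1, x0:x1])
    if rng_noise is not None and spec.noise_sd > 0:
        image = image + rng_noise.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)
    return (image * 255.0).round().astype(np.uint8), layout


def corrupt_pose(
    image: np.ndarray,
    boxes: DetectionSet,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, DetectionSet, PoseDecision]:
    """Apply a random mirror/flip/rotation corruption, recording the truth.

    The forward transform is the exact inverse of the correction the
    alignment module composes for the same :class:`PoseDecision`, so the
    recorded truth round-trips through pose estimation.
    """
    pose = PoseDecision(
        mirror=bool(rng.random() < spec.mirror_prob),
        flip=bool(rng.random() < spec.flip_prob),
        rotation_deg=float(
            rng.uniform(-spec.rotation_bound_deg, spec.rotation_bound_deg)
        ),
    )
    size = (image.shape[1], image.shape[0])
    t = compose_corruption(pose, size)
    return apply_alignment(image, t), transform_boxes(boxes, t, size), pose


def corrupt_layout(
    boxes: DetectionSet, pose: PoseDecision, image_size: int = 256
) -> DetectionSet:
    """Box-only pose corruption for a known decision (no image resampling)."""
    t = compose_corruption(pose, (image_size, image_size))
    return transform_boxes(boxes, t, (image_size, image_size))


def _spawn_streams(seed: int) -> tuple[np.random.Generator, ...]:
    labels, pose, noise = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(labels),
        np.random.default_rng(pose),
        np.random.default_rng(noise),
    )


def sample_population(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Draw ages (uniform over the age range, months) and sexes."""
    ages = rng.uniform(spec.age_min_months, spec.age_max_months, spec.n_samples)
    sexes = ["female" if u < spec.female_fraction else "male"
             for u in rng.random(spec.n_samples)]
    return ages, sexes


def generate_corpus(
    spec: SyntheticSpec, out_dir: str | Path
) -> tuple[list[SampleRecord], list[GroundTruth]]:
    """Write a complete corpus to ``out_dir``.

    Layout: ``images/<id>.png``, ``labels/<id>.txt``, ``labels.csv``
    (``id,boneage,male``) and ``truth.json``. The first
    ``round(dropout_fraction * n)`` samples keep only ``dropout_keep`` ROI
    classes in their label files (the images are untouched), exercising the
    completeness filter deterministically.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    rng_labels, rng_pose, rng_noise = _spawn_streams(spec.seed)
    ages, sexes = sample_population(spec, rng_labels)
    n_dropout = int(round(spec.dropout_fraction * spec.n_samples))

    records: list[SampleRecord] = []
    truths: list[GroundTruth] = []
    csv_rows = ["id,boneage,male"]
    for i in range(spec.n_samples):
        image_id = f"s{i:05d}"
        image, layout = render_sample(ages[i], sexes[i], spec, rng_noise)
        image, boxes, pose = corrupt_pose(image, layout, spec, rng_pose)
        if i < n_dropout:
            keep = sorted(
                rng_labels.choice(18, size=spec.dropout_keep, replace=False)
            )
            boxes = DetectionSet(
                boxes=[b for b in boxes.boxes if b.class_id in keep],
                image_id=boxes.image_id,
            )
        image_path = out_dir / "images" / f"{image_id}.png"
        label_path = out_dir / "labels" / f"{image_id}.txt"
        iio.imwrite(image_path, image)
        write_yolo_labels(boxes, label_path)
        csv_rows.append(
            f"{image_id},{ages[i]:.3f},{'TRUE' if sexes[i] == 'male' else 'FALSE'}"
        )
        records.append(
            SampleRecord(
                image_id=image_id,
                sex=sexes[i],
                boneage_months=float(ages[i]),
                image_path=image_path,
                label_path=label_path,
            )
        )
        truths.append(
            GroundTruth(image_id=image_id, age_months=float(ages[i]),
                        sex=sexes[i], pose=pose)
        )
    (out_dir / "labels.csv").write_text("\n".join(csv_rows) + "\n")
    (out_dir / "truth.json").write_text(
        json.dumps({"spec": asdict(spec), "samples": [t.to_dict() for t in truths]},
                   indent=1)
    )
    return records, truths


__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "CANONICAL_BOXES",
    "canonical_layout",
    "blob_params",
    "render_sample",
    "corrupt_pose",
    "corrupt_layout",
    "sample_population",
    "generate_corpus",
]
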