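"""Detection label I/O and sample filtering.

The first stage of the pipeline is an external object detector that localises
the 18 TW3-style regions of interest (ROIs) on a hand radiograph and writes
one text label file per image in the YOLO dialect::

    class_id cx cy w h [conf]

with normalised coordinates (origin top-left, x rightwards, y downwards).
This module reads and writes those files, reads the RSNA-style label table
(``id,boneage,male``), deduplicates detections to at most one box per ROI
class, and applies the data-cleaning rule that removes samples with fewer
than 14 distinct ROI classes detected.

The detector itself is out of scope; any callable ``path -> DetectionSet``
satisfies the detector contract (see :func:`filter_complete_samples`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

logger = logging.getLogger("boneage")

NUM_ROI_CLASSES = 18
#: Data-cleaning threshold: samples with fewer distinct ROI classes are removed.
MIN_ROI_CLASSES = 14


class LabelParseError(ValueError):
    """A detection label file line could not be parsed."""


class LabelValidationError(ValueError):
    """A parsed value violates the detection-box contract."""


class SchemaError(ValueError):
    """The label table is missing a required column."""


@dataclass(frozen=True)
class DetectionBox:
    """One detected ROI: class index 0-17 plus a normalised box.

    ``cx, cy`` are the box centre, ``w, h`` its size, all as fractions of the
    image; ``conf`` is the detector confidence (1.0 for hand-made labels).
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.class_id < NUM_ROI_CLASSES:
            raise LabelValidationError(
                f"class_id {self.class_id} outside [0, {NUM_ROI_CLASSES - 1}]"
            )


@dataclass
class DetectionSet:
    """All detections for one image."""

    boxes: list[DetectionBox] = field(default_factory=list)
    image_id: str = ""

    def class_ids(self) -> set[int]:
        return {b.class_id for b in self.boxes}

    def by_class(self) -> dict[int, DetectionBox]:
        """Map class id -> box. Requires the set to be deduplicated."""
        out = {b.class_id: b for b in self.boxes}
        if len(out) != len(self.boxes):
            raise LabelValidationError(
                f"{self.image_id}: duplicate class ids; dedupe first"
            )
        return out


@dataclass
class SampleRecord:
    """One study sample: identity, sex, bone age and file references.

    Sex is encoded downstream as the 2-vector (0,1) for males and (1,0) for
    females before entering the model.
    """

    image_id: str
    sex: str  # "male" | "female"
    boneage_months: float
    image_path: Path | None = None
    label_path: Path | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.boneage_months < 0:
            raise ValueError(f"boneage_months must be >= 0, got {self.boneage_months}")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def parse_yolo_labels(path: str | Path) -> DetectionSet:
    """Read a YOLO text label file into a :class:`DetectionSet`.

    Lines carry 5 fields (``class cx cy w h``) or 6 (plus confidence).
    Coordinates are clamped to [0, 1]; input order is preserved. Malformed
    lines raise :class:`LabelParseError` naming the line number; class ids
    outside [0, 17] raise :class:`LabelValidationError`.
    """
    path = Path(path)
    boxes: list[DetectionBox] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) not in (5, 6):
            raise LabelParseError(
                f"{path}:{lineno}: expected 5 or 6 fields, got {len(fields)}"
            )
        try:
            cls = int(float(fields[0]))
            vals = [float(f) for f in fields[1:]]
        except ValueError as exc:
            raise LabelParseError(f"{path}:{lineno}: non-numeric field") from exc
        conf = vals[4] if len(vals) == 5 else 1.0
        boxes.append(
            DetectionBox(
                class_id=cls,
                cx=_clamp01(vals[0]),
                cy=_clamp01(vals[1]),
                w=_clamp01(vals[2]),
                h=_clamp01(vals[3]),
                conf=_clamp01(conf),
            )
        )
    return DetectionSet(boxes=boxes, image_id=path.stem)


def write_yolo_labels(detections: DetectionSet, path: str | Path) -> None:
    """Write a label file; 6 decimal places, confidence always included."""
    lines = [
        f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f} {b.conf:.6f}"
        for b in detections.boxes
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def dedupe_detections(detections: DetectionSet) -> DetectionSet:
    """Keep, per ROI class, only the highest-confidence box.

    Ties are broken by earliest input order; overall input order of the
    surviving boxes is preserved. Idempotent.
    """
    best: dict[int, tuple[int, DetectionBox]] = {}
    for idx, box in enumerate(detections.boxes):
        kept = best.get(box.class_id)
        if kept is None or box.conf > kept[1].conf:
            best[box.class_id] = (idx, box)
    order = sorted(best.values(), key=lambda t: t[0])
    return DetectionSet(boxes=[b for _, b in order], image_id=detections.image_id)


DetectionLoader = Callable[[Path], DetectionSet]


def filter_complete_samples(
    records: Iterable[SampleRecord],
    min_classes: int = MIN_ROI_CLASSES,
    loader: DetectionLoader = parse_yolo_labels,
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Partition samples by detection completeness.

    A sample is kept when its deduplicated detections cover at least
    ``min_classes`` distinct ROI classes; in the source study this removes
    radiographs with dysplasia, lesions or failed detections. Samples whose
    label file cannot be read are routed to ``dropped`` with a logged reason.

    Returns ``(kept, dropped)``; the two lists partition the input.
    """
    kept: list[SampleRecord] = []
    dropped: list[SampleRecord] = []
    for rec in records:
        try:
            if rec.label_path is None:
                raise FileNotFoundError("record has no label_path")
            det = dedupe_detections(loader(Path(rec.label_path)))
        except (OSError, ValueError) as exc:
            logger.warning("sample %s dropped: %s", rec.image_id, exc)
            dropped.append(rec)
            continue
        if len(det.class_ids()) >= min_classes:
            kept.append(rec)
        else:
            dropped.append(rec)
    return kept, dropped


def _find_column(columns: Sequence[str], *prefixes: str) -> str:
    for col in columns:
        low = col.strip().lower()
        if any(low == p or low.startswith(p) for p in prefixes):
            return col
    raise SchemaError(f"no column matching {prefixes} in {list(columns)}")


_TRUTHY = {"true", "1", "1.0", "t", "yes", "m", "male"}
_FALSY = {"false", "0", "0.0", "f", "no", "female"}


def load_label_table(
    path: str | Path,
    images_dir: str | Path | None = None,
    labels_dir: str | Path | None = None,
) -> list[SampleRecord]:
    """Read an RSNA-dialect CSV (``id,boneage,male``) into sample records.

    Column matching is case-insensitive and prefix-tolerant (``boneage`` /
    ``boneage_months``). When ``images_dir``/``labels_dir`` are given, file
    references ``<id>.png`` / ``<id>.txt`` are attached to each record.
    """
    df = pd.read_csv(path, dtype=str)
    id_col = _find_column(df.columns, "id", "image_id")
    age_col = _find_column(df.columns, "boneage")
    male_col = _find_column(df.columns, "male", "sex")
    records: list[SampleRecord] = []
    for idx, row in df.iterrows():
        try:
            age = float(row[age_col])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"row {idx}: non-numeric bone age {row[age_col]!r}") from exc
        flag = str(row[male_col]).strip().lower()
        if flag in _TRUTHY:
            sex = "male"
        elif flag in _FALSY:
            sex = "female"
        else:
            raise ValueError(f"row {idx}: unrecognised male flag {row[male_col]!r}")
        image_id = str(row[id_col]).strip()
        records.append(
            SampleRecord(
                image_id=image_id,
                sex=sex,
                boneage_months=age,
                image_path=Path(images_dir) / f"{image_id}.png" if images_dir else None,
                label_path=Path(labels_dir) / f"{image_id}.txt" if labels_dir else None,
            )
        )
    return records


def sex_code(sex: str):
    """The study's sex code vector: male -> (0,1), female -> (1,0)."""
    import numpy as np

    if sex == "male":
        return np.array([0.0, 1.0])
    if sex == "female":
        return np.array([1.0, 0.0])
    raise ValueError(f"unknown sex label {sex!r}")


__all__ = [
    "DetectionBox",
    "DetectionSet",
    "SampleRecord",
    "LabelParseError",
    "LabelValidationError",
    "SchemaError",
    "NUM_ROI_CLASSES",
    "MIN_ROI_CLASSES",
    "parse_yolo_labels",
    "write_yolo_labels",
    "dedupe_detections",
    "filter_complete_samples",
    "load_label_table",
    "sex_code",
]
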