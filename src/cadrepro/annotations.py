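"""Data model and file I/O for paired-exam lesion annotations.

A study consists of patients imaged twice (an initial exam and a short-term
follow-up with no disease change). Ground truth is a set of lesion bounding
boxes per exam; lesion identity is stable across the pair, so the same
``lesion_id`` appears in both exams with (possibly different) boxes. Detector
output is a set of scored boxes per exam.

Coordinates are continuous pixels, origin at the top-left corner, x rightward
and y downward; a box covers the half-open region [x_min, x_max) x
[y_min, y_max).

On-disk formats (auto-detected by extension):

* Ground-truth CSV — columns ``patient_id, exam_id, role, lesion_id, x_min,
  y_min, x_max, y_max, size_mm, width, height`` (``size_mm`` may be blank;
  ``width``/``height`` default to 1024 when the columns are absent).
* Detections CSV — columns ``exam_id, x_min, y_min, x_max, y_max, confidence``.
* JSON — one object per exam carrying the same fields (see
  :func:`write_dataset` for the exact layout).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "Box",
    "Lesion",
    "Detection",
    "Exam",
    "ExamPair",
    "Dataset",
    "AnnotationError",
    "MalformedBoxError",
    "SchemaError",
    "DuplicateExamError",
    "PairingError",
    "load_dataset",
    "write_dataset",
]

DEFAULT_IMAGE_SIZE = 1024

GT_COLUMNS = [
    "patient_id", "exam_id", "role", "lesion_id",
    "x_min", "y_min", "x_max", "y_max", "size_mm", "width", "height",
]
DET_COLUMNS = ["exam_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


class AnnotationError(ValueError):
    """Base class for annotation validation failures."""


class MalformedBoxError(AnnotationError):
    """Box with non-positive extent (x_min >= x_max or y_min >= y_max)."""


class SchemaError(AnnotationError):
    """Input file does not conform to the documented schema."""


class DuplicateExamError(AnnotationError):
    """The same exam_id occurs more than once."""


class PairingError(AnnotationError):
    """Exams cannot be paired, or lesion identities do not match across a pair."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        vals = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(v) for v in vals):
            raise MalformedBoxError(f"non-finite box coordinates: {vals}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise MalformedBoxError(
                f"degenerate box: [{self.x_min}, {self.x_max}) x "
                f"[{self.y_min}, {self.y_max})"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class Lesion:
    """Ground-truth lesion box with identity stable across an exam pair."""

    lesion_id: str
    exam_id: str
    box: Box
    size_mm: float | None = None

    def __post_init__(self) -> None:
        if self.size_mm is not None and not self.size_mm > 0:
            raise AnnotationError(f"size_mm must be positive, got {self.size_mm}")


@dataclass(frozen=True)
class Detection:
    """Detector output: a scored box. Only the score *ordering* matters."""

    exam_id: str
    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.confidence):
            raise AnnotationError(f"non-finite confidence: {self.confidence}")


@dataclass(frozen=True)
class Exam:
    exam_id: str
    patient_id: str
    role: str  # "initial" | "followup"
    width: int = DEFAULT_IMAGE_SIZE
    height: int = DEFAULT_IMAGE_SIZE

    def __post_init__(self) -> None:
        if self.role not in ("initial", "followup"):
            raise AnnotationError(f"role must be initial/followup, got {self.role!r}")
        if not (self.width > 0 and self.height > 0):
            raise AnnotationError("image dimensions must be positive")


@dataclass(frozen=True)
class ExamPair:
    """Initial and follow-up exam of one patient, sharing lesion identities."""

    patient_id: str
    initial: Exam
    followup: Exam
    initial_lesions: tuple[Lesion, ...]
    followup_lesions: tuple[Lesion, ...]

    def __post_init__(self) -> None:
        if self.initial.role != "initial" or self.followup.role != "followup":
            raise PairingError(
                f"pair for {self.patient_id!r}: exam roles do not match slots"
            )
        init_ids = [l.lesion_id for l in self.initial_lesions]
        fu_ids = [l.lesion_id for l in self.followup_lesions]
        for ids, exam in ((init_ids, self.initial), (fu_ids, self.followup)):
            if len(ids) != len(set(ids)):
                raise PairingError(f"duplicate lesion_id in exam {exam.exam_id!r}")
        if set(init_ids) != set(fu_ids):
            odd = set(init_ids) ^ set(fu_ids)
            raise PairingError(
                f"patient {self.patient_id!r}: lesion ids {sorted(odd)} present "
                "in only one exam of the pair"
            )

    @property
    def lesion_ids(self) -> tuple[str, ...]:
        return tuple(l.lesion_id for l in self.initial_lesions)


@dataclass
class Dataset:
    """A collection of exam pairs plus detector output per exam."""

    pairs: list[ExamPair]
    detections: dict[str, list[Detection]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pair in self.pairs:
            for exam in (pair.initial, pair.followup):
                if exam.exam_id in seen:
                    raise DuplicateExamError(f"duplicate exam_id {exam.exam_id!r}")
                seen.add(exam.exam_id)
        for exam_id in list(self.detections):
            if exam_id not in seen:
                raise PairingError(
                    f"detections refer to unknown exam_id {exam_id!r}"
                )
            if not self.detections[exam_id]:  # normalise: no empty lists
                del self.detections[exam_id]

    def exams(self) -> Iterator[Exam]:
        for pair in self.pairs:
            yield pair.initial
            yield pair.followup

    def lesions_for(self, exam_id: str) -> tuple[Lesion, ...]:
        for pair in self.pairs:
            if pair.initial.exam_id == exam_id:
                return pair.initial_lesions
            if pair.followup.exam_id == exam_id:
                return pair.followup_lesions
        raise KeyError(exam_id)

    def detections_for(self, exam_id: str) -> list[Detection]:
        return self.detections.get(exam_id, [])

    @property
    def n_lesions(self) -> int:
        return sum(len(p.initial_lesions) for p in self.pairs)


# ---------------------------------------------------------------------------
# I/O


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    v = float(value)
    return None if math.isnan(v) else v


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _gt_records_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, GT_COLUMNS[:8], path)
    if "size_mm" not in df.columns:
        df["size_mm"] = None
    if "width" not in df.columns:
        df["width"] = DEFAULT_IMAGE_SIZE
    if "height" not in df.columns:
        df["height"] = DEFAULT_IMAGE_SIZE
    return df.to_dict("records")


def _det_records_from_csv(path: Path) -> list[dict]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, DET_COLUMNS, path)
    return df.to_dict("records")


def _gt_records_from_json(path: Path) -> list[dict]:
    exams = json.loads(path.read_text())
    if not isinstance(exams, list):
        raise SchemaError(f"{path}: expected a JSON array of exam objects")
    records = []
    for exam in exams:
        try:
            base = {k: exam[k] for k in ("patient_id", "exam_id", "role")}
        except KeyError as e:
            raise SchemaError(f"{path}: exam object missing key {e}") from e
        base["width"] = exam.get("width", DEFAULT_IMAGE_SIZE)
        base["height"] = exam.get("height", DEFAULT_IMAGE_SIZE)
        for lesion in exam.get("lesions", []):
            records.append({**base, **lesion})
    return records


def _det_records_from_json(path: Path) -> list[dict]:
    exams = json.loads(path.read_text())
    if not isinstance(exams, list):
        raise SchemaError(f"{path}: expected a JSON array of exam objects")
    records = []
    for exam in exams:
        if "exam_id" not in exam:
            raise SchemaError(f"{path}: exam object missing key 'exam_id'")
        for det in exam.get("detections", []):
            records.append({"exam_id": exam["exam_id"], **det})
    return records


def _read_records(path, kind: str) -> list[dict]:
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        return (_gt_records_from_json if kind == "gt" else _det_records_from_json)(path)
    if suffix in (".csv", ".tsv", ".txt", ""):
        return (_gt_records_from_csv if kind == "gt" else _det_records_from_csv)(path)
    raise SchemaError(f"unrecognised annotation format: {path}")


def load_dataset(gt_path, det_path) -> Dataset:
    """Load ground truth and detections and assemble a validated Dataset.

    Exams are paired by ``patient_id`` via their ``role``; every patient must
    contribute exactly one initial and one followup exam, and every lesion_id
    must occur in both exams of its pair.
    """
    gt_records = _read_records(gt_path, "gt")
    det_records = _read_records(det_path, "det")

    exams: dict[str, Exam] = {}
    lesions: dict[str, list[Lesion]] = {}
    for rec in gt_records:
        try:
            exam = Exam(
                exam_id=str(rec["exam_id"]),
                patient_id=str(rec["patient_id"]),
                role=str(rec["role"]),
                width=int(rec["width"]),
                height=int(rec["height"]),
            )
        except KeyError as e:
            raise SchemaError(f"{gt_path}: ground-truth record missing {e}") from e
        if exam.exam_id in exams:
            if exams[exam.exam_id] != exam:
                raise DuplicateExamError(
                    f"exam_id {exam.exam_id!r} has inconsistent metadata"
                )
        else:
            exams[exam.exam_id] = exam
        box = Box(float(rec["x_min"]), float(rec["y_min"]),
                  float(rec["x_max"]), float(rec["y_max"]))
        lesions.setdefault(exam.exam_id, []).append(
            Lesion(
                lesion_id=str(rec["lesion_id"]),
                exam_id=exam.exam_id,
                box=box,
                size_mm=_opt_float(rec.get("size_mm")),
            )
        )

    by_patient: dict[str, dict[str, Exam]] = {}
    for exam in exams.values():
        slot = by_patient.setdefault(exam.patient_id, {})
        if exam.role in slot:
            raise DuplicateExamError(
                f"patient {exam.patient_id!r} has two {exam.role!r} exams"
            )
        slot[exam.role] = exam

    pairs = []
    for patient_id in sorted(by_patient):
        slot = by_patient[patient_id]
        if set(slot) != {"initial", "followup"}:
            raise PairingError(
                f"patient {patient_id!r} lacks a complete initial/followup pair"
            )
        pairs.append(
            ExamPair(
                patient_id=patient_id,
                initial=slot["initial"],
                followup=slot["followup"],
                initial_lesions=tuple(lesions.get(slot["initial"].exam_id, [])),
                followup_lesions=tuple(lesions.get(slot["followup"].exam_id, [])),
            )
        )

    detections: dict[str, list[Detection]] = {}
    for rec in det_records:
        exam_id = str(rec["exam_id"])
        if exam_id not in exams:
            raise PairingError(
                f"{det_path}: detection refers to unknown exam_id {exam_id!r}"
            )
        box = Box(float(rec["x_min"]), float(rec["y_min"]),
                  float(rec["x_max"]), float(rec["y_max"]))
        detections.setdefault(exam_id, []).append(
            Detection(exam_id=exam_id, box=box, confidence=float(rec["confidence"]))
        )

    return Dataset(pairs=pairs, detections=detections)


def write_dataset(dataset: Dataset, gt_path, det_path) -> None:
    """Write a dataset to disk; ``load_dataset`` of the output reproduces it."""
    gt_path, det_path = Path(gt_path), Path(det_path)
    gt_rows, det_rows = [], []
    for pair in dataset.pairs:
        for exam, exam_lesions in (
            (pair.initial, pair.initial_lesions),
            (pair.followup, pair.followup_lesions),
        ):
            for lesion in exam_lesions:
                gt_rows.append({
                    "patient_id": exam.patient_id,
                    "exam_id": exam.exam_id,
                    "role": exam.role,
                    "lesion_id": lesion.lesion_id,
                    "x_min": lesion.box.x_min,
                    "y_min": lesion.box.y_min,
                    "x_max": lesion.box.x_max,
                    "y_max": lesion.box.y_max,
                    "size_mm": lesion.size_mm,
                    "width": exam.width,
                    "height": exam.height,
                })
            for det in dataset.detections_for(exam.exam_id):
                det_rows.append({
                    "exam_id": det.exam_id,
                    "x_min": det.box.x_min,
                    "y_min": det.box.y_min,
                    "x_max": det.box.x_max,
                    "y_max": det.box.y_max,
                    "confidence": det.confidence,
                })
    if gt_path.suffix.lower() == ".json":
        _write_json(dataset, gt_path, det_path)
        return
    pd.DataFrame(gt_rows, columns=GT_COLUMNS).to_csv(gt_path, index=False)
    pd.DataFrame(det_rows, columns=DET_COLUMNS).to_csv(det_path, index=False)


def _write_json(dataset: Dataset, gt_path: Path, det_path: Path) -> None:
    gt_objs, det_objs = [], []
    for pair in dataset.pairs:
        for exam, exam_lesions in (
            (pair.initial, pair.initial_lesions),
            (pair.followup, pair.followup_lesions),
        ):
            gt_objs.append({
                "exam_id": exam.exam_id,
                "patient_id": exam.patient_id,
                "role": exam.role,
                "width": exam.width,
                "height": exam.height,
                "lesions": [
                    {
                        "lesion_id": l.lesion_id,
                        "x_min": l.box.x_min, "y_min": l.box.y_min,
                        "x_max": l.box.x_max, "y_max": l.box.y_max,
                        "size_mm": l.size_mm,
                    }
                    for l in exam_lesions
                ],
            })
            det_objs.append({
                "exam_id": exam.exam_id,
                "detections": [
                    {
                        "x_min": d.box.x_min, "y_min": d.box.y_min,
                        "x_max": d.box.x_max, "y_max": d.box.y_max,
                        "confidence": d.confidence,
                    }
                    for d in dataset.detections_for(exam.exam_id)
                ],
            })
    gt_path.write_text(json.dumps(gt_objs, indent=1, ensure_ascii=False))
    det_path.write_text(json.dumps(det_objs, indent=1, ensure_ascii=False))
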